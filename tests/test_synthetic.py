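import numpy as np
import pytest
from scipy import stats

from ssmnet.mass_calc import PROTONATED
from ssmnet.spectra_io import Group, read_mgf
from ssmnet.synthetic import (
    CompoundSpec,
    ExperimentConfig,
    VariantModel,
    generate_experiment,
    make_epoxyketone_default_config,
)


def tiny_config(seed=1):
    """One condition, no extra variants, no contaminants/media, no noise."""
    compounds = [
        CompoundSpec(
            compound_id=f"CPD_{i}",
            formula=f"C{10 + i}H{20 + 2 * i}N2O4",
            family_id="fam",
            fragment_mzs=(80.0, 120.0 + i, 160.0),
            fragment_intensities=(10.0, 50.0, 30.0),
            rt=2.0 + i,
            base_intensity=1e5,
            condition_effects={"A1": 1.0},
        )
        for i in range(3)
    ]
    return ExperimentConfig(
        compounds=compounds,
        conditions={"A1": 2},
        n_blanks=0,
        n_beds=0,
        variants=VariantModel(
            probability={k: 0.0 for k in VariantModel().probability},
            intensity_factor=VariantModel().intensity_factor,
        ),
        intensity_cv=0.0,
        fragment_cv=0.0,
        mz_jitter_sd=0.0,
        rt_jitter_sd=0.0,
        n_noise_peaks=0,
        seed=seed,
    )


class TestDefaultConfig:
    def test_family_protonated_mz_round_to_printed_values(self):
        config = make_epoxyketone_default_config()
        epoxy = [c for c in config.compounds if c.family_id == "epoxyketone"]
        mzs = sorted({round(c.mz_protonated, 2) for c in epoxy})
        assert mzs == [343.19, 345.20, 399.25, 401.26]

    def test_stereoisomer_pair_at_6p6_and_7p4_minutes(self):
        config = make_epoxyketone_default_config()
        isomers = [
            c for c in config.compounds
            if c.formula == "C20H36N2O6" and c.family_id == "epoxyketone"
        ]
        assert sorted(c.rt for c in isomers) == [6.6, 7.4]

    def test_experiment_scale(self):
        config = make_epoxyketone_default_config()
        n_samples = sum(config.conditions.values()) + config.n_blanks + config.n_beds
        n_compounds = sum(1 for c in config.compounds if c.category == "compound")
        assert n_samples == 12
        assert n_compounds == 25

    def test_yaml_round_trip(self, tmp_path):
        config = make_epoxyketone_default_config(seed=9)
        path = config.to_yaml(tmp_path / "config.yaml")
        back = ExperimentConfig.from_yaml(path)
        assert back == config


class TestGeneration:
    def test_same_seed_byte_identical(self, tmp_path):
        digests = []
        for run in ("a", "b"):
            out = tmp_path / run
            generate_experiment(make_epoxyketone_default_config(seed=5), out)
            digests.append(
                {p.name: p.read_bytes() for p in sorted(out.iterdir())}
            )
        assert digests[0] == digests[1]

    def test_noise_free_single_condition_spectrum_count(self, tmp_path):
        config = tiny_config()
        bundle = generate_experiment(config, tmp_path / "tiny")
        total = sum(len(v) for v in bundle.spectra_by_sample.values())
        assert total == len(config.compounds) * sum(config.conditions.values())

    def test_ground_truth_covers_every_emitted_spectrum(self, bundle):
        emitted = {
            s.spectrum_id
            for spectra in bundle.spectra_by_sample.values()
            for s in spectra
        }
        assert emitted == set(bundle.ground_truth.spectra["spectrum_id"])

    def test_contaminants_present_in_every_blank_mgf(self, bundle):
        blanks = [r for r in bundle.manifest if r.group is Group.BLANK]
        assert blanks
        gt = bundle.ground_truth.spectra
        for rec in blanks:
            spectra = read_mgf(bundle.output_dir / rec.file_path)
            cats = set(
                gt[gt["spectrum_id"].isin([s.spectrum_id for s in spectra])]["category"]
            )
            assert cats == {"contaminant"}

    def test_emitted_protonated_mz_within_jitter(self, bundle):
        gt = bundle.ground_truth
        mh = gt.spectra[gt.spectra["variant"] == PROTONATED.name]
        by_compound = gt.compounds.set_index("compound_id")["mz_protonated"]
        tol = 6 * bundle.ground_truth.config.mz_jitter_sd
        for sid, cid in zip(mh["spectrum_id"], mh["compound_id"]):
            sample = sid.split("|")[0]
            spectrum = next(
                s for s in bundle.spectra_by_sample[sample] if s.spectrum_id == sid
            )
            assert abs(spectrum.precursor_mz - by_compound[cid]) <= tol

    def test_invalid_config_rejected_before_writing(self, tmp_path):
        config = tiny_config()
        config.compounds[0].fragment_mzs = (1e6,)  # above [M+H]+
        config.compounds[0].fragment_intensities = (1.0,)
        out = tmp_path / "invalid"
        with pytest.raises(ValueError):
            generate_experiment(config, out)
        assert not out.exists() or not list(out.iterdir())


class TestPlantedStructure:
    def test_same_family_true_cosines_high(self, bundle):
        pairs = bundle.ground_truth.same_family_pairs()
        epoxy = pairs[pairs["family_id"] == "epoxyketone"]
        assert len(epoxy) == 10  # C(5, 2)
        assert (epoxy["true_cosine"] >= 0.6).mean() >= 0.9

    def test_condition_effects_recoverable_by_regression(self, bundle):
        # observed vs planted log fold change across compounds: slope 1 +- 0.1
        gt = bundle.ground_truth
        mh = gt.spectra[
            (gt.spectra["variant"] == PROTONATED.name)
            & (gt.spectra["category"] == "compound")
            & (gt.spectra["group"] == Group.SAMPLE.value)
        ]
        observed = mh.groupby(["compound_id", "condition"])["realized_intensity"].mean()
        truth = gt.true_fold_changes("A1")
        x, y = [], []
        for _, row in truth.iterrows():
            cid, cond, tfc = row["compound_id"], row["condition"], row["true_fold_change"]
            if (cid, cond) in observed.index and (cid, "A1") in observed.index:
                x.append(np.log(tfc))
                y.append(np.log(observed[(cid, cond)] / observed[(cid, "A1")]))
        fit = stats.linregress(x, y)
        assert fit.slope == pytest.approx(1.0, abs=0.1)
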