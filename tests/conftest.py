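import pytest

from ssmnet import (
    Peak,
    PipelineConfig,
    Spectrum,
    generate_experiment,
    make_epoxyketone_default_config,
    run_pipeline,
    score_recovery,
)


def make_spectrum(peaks, precursor=400.0, spectrum_id="s", **kwargs):
    """Build a Spectrum from (mz, intensity) pairs."""
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        peaks=tuple(Peak(m, i) for m, i in peaks),
        **kwargs,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default synthetic media experiment (seed 42, 12 samples)."""
    config = make_epoxyketone_default_config(seed=42)
    return generate_experiment(config, tmp_path_factory.mktemp("exp42"))


@pytest.fixture(scope="session")
def result(bundle):
    """Full pipeline run on the default synthetic experiment."""
    return run_pipeline(
        PipelineConfig(
            manifest=str(bundle.manifest_path),
            output_dir=str(bundle.output_dir / "run"),
        )
    )


@pytest.fixture(scope="session")
def recovery(bundle, result):
    return score_recovery(bundle.ground_truth, result)
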