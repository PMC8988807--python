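import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssmnet.similarity import (
    MatchKind,
    cosine_similarity,
    library_match,
    oracle_similarity,
    weight_and_normalize,
)
from conftest import make_spectrum


def random_spectrum(rng, n_peaks=6, grid_spacing=2.0, precursor_grid=True):
    """Random spectrum whose m/z sit near a coarse grid, so that direct and
    precursor-shifted candidate matches actually occur between two draws."""
    mz = rng.choice(np.arange(60.0, 360.0, grid_spacing), size=n_peaks, replace=False)
    mz = np.sort(mz + rng.normal(0.0, 0.005, n_peaks))
    intensity = rng.uniform(1.0, 100.0, n_peaks)
    if precursor_grid:
        precursor = float(rng.choice(np.arange(380.0, 420.0, grid_spacing)))
    else:
        precursor = float(rng.uniform(380.0, 420.0))
    return make_spectrum(list(zip(mz, intensity)), precursor=precursor)


class TestWeights:
    def test_single_peak_has_unit_weight(self):
        assert weight_and_normalize([123.0]) == pytest.approx([1.0])

    def test_sqrt_weighting(self):
        w = weight_and_normalize([4.0, 9.0])
        np.testing.assert_allclose(w, np.array([2.0, 3.0]) / math.sqrt(13.0))

    def test_equal_intensities_give_uniform_weights(self):
        w = weight_and_normalize([7.0] * 5)
        np.testing.assert_allclose(w, np.full(5, 1 / math.sqrt(5)))

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError):
            weight_and_normalize([0.0, 0.0])


class TestGreedyCosine:
    def test_self_similarity_is_one_with_all_peaks_matched(self):
        s = make_spectrum([(100.0, 4.0), (110.0, 9.0), (150.0, 2.0)])
        r = cosine_similarity(s, s)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.n_matched == 3

    def test_disjoint_peaks_score_zero(self):
        a = make_spectrum([(100.0, 1.0), (110.0, 1.0)])
        b = make_spectrum([(200.0, 1.0), (210.0, 1.0)])
        r = cosine_similarity(a, b, allow_shift=False)
        assert r.score == 0.0 and r.n_matched == 0

    def test_swapped_intensities_give_12_over_13(self):
        # weights (2,3)/sqrt(13) vs (3,2)/sqrt(13): products 6/13 + 6/13
        a = make_spectrum([(100.0, 4.0), (110.0, 9.0)])
        b = make_spectrum([(100.0, 9.0), (110.0, 4.0)])
        r = cosine_similarity(a, b, frag_tol=0.025)
        assert r.score == pytest.approx(12 / 13, abs=1e-9)

    def test_precursor_shifted_peak_matches_in_modified_mode(self):
        a = make_spectrum([(100.0, 1.0), (300.0, 1.0)], precursor=400.0)
        b = make_spectrum([(100.0, 1.0), (302.0, 1.0)], precursor=402.0)
        direct = cosine_similarity(a, b, allow_shift=False)
        modified = cosine_similarity(a, b, allow_shift=True)
        assert direct.score == pytest.approx(0.5, abs=1e-9)
        assert modified.score == pytest.approx(1.0, abs=1e-9)
        kinds = {m.kind for m in modified.matches}
        assert kinds == {MatchKind.DIRECT, MatchKind.SHIFTED}

    def test_negative_tolerance_rejected(self):
        s = make_spectrum([(100.0, 1.0)])
        with pytest.raises(ValueError):
            cosine_similarity(s, s, frag_tol=-1.0)

    def test_empty_spectrum_rejected(self):
        s = make_spectrum([(100.0, 1.0)])
        empty = make_spectrum([])
        with pytest.raises(ValueError):
            cosine_similarity(s, empty)

    @pytest.mark.parametrize("allow_shift", [False, True])
    def test_symmetry_and_bounds_on_random_pairs(self, allow_shift):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = random_spectrum(rng), random_spectrum(rng)
            r_ab = cosine_similarity(a, b, frag_tol=0.025, allow_shift=allow_shift)
            r_ba = cosine_similarity(b, a, frag_tol=0.025, allow_shift=allow_shift)
            assert abs(r_ab.score - r_ba.score) < 1e-9
            assert 0.0 <= r_ab.score <= 1.0 + 1e-9

    def test_self_similarity_is_maximal(self):
        rng = np.random.default_rng(2)
        a = random_spectrum(rng)
        for _ in range(50):
            b = random_spectrum(rng)
            assert (
                cosine_similarity(a, a, allow_shift=True).score
                >= cosine_similarity(a, b, allow_shift=True).score - 1e-9
            )


class TestOracle:
    def test_oracle_matches_greedy_on_unambiguous_instance(self):
        a = make_spectrum([(100.0, 4.0), (110.0, 9.0)])
        b = make_spectrum([(100.0, 9.0), (110.0, 4.0)])
        g = cosine_similarity(a, b)
        o = oracle_similarity(a, b)
        assert o.score == pytest.approx(g.score, abs=1e-12)

    def test_identity_scores_one(self):
        s = make_spectrum([(100.0, 1.0), (150.0, 2.0), (200.0, 3.0)])
        assert oracle_similarity(s, s).score == pytest.approx(1.0, abs=1e-9)

    def test_oracle_dominates_greedy_on_random_instances(self):
        rng = np.random.default_rng(3)
        agree = 0
        n = 300
        for _ in range(n):
            a = random_spectrum(rng, n_peaks=5)
            b = random_spectrum(rng, n_peaks=5)
            g = cosine_similarity(a, b, frag_tol=1.0, allow_shift=True)
            o = oracle_similarity(a, b, frag_tol=1.0, allow_shift=True)
            assert g.score <= o.score + 1e-9
            agree += abs(g.score - o.score) < 1e-9
        assert agree / n >= 0.95  # documents greedy's quality

    def test_instance_too_large_rejected(self):
        big = make_spectrum([(100.0 + i, 1.0) for i in range(10)])
        with pytest.raises(ValueError, match="16"):
            oracle_similarity(big, big)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    mzs=st.lists(
        st.floats(min_value=60.0, max_value=300.0), min_size=2, max_size=6, unique=True
    ),
    intensities=st.lists(
        st.floats(min_value=0.1, max_value=100.0), min_size=6, max_size=6
    ),
)
def test_greedy_never_exceeds_oracle(mzs, intensities):
    a = make_spectrum(list(zip(sorted(mzs), intensities)))
    b = make_spectrum(
        [(m + 0.01, i) for m, i in zip(sorted(mzs), reversed(intensities[: len(mzs)]))]
    )
    g = cosine_similarity(a, b, frag_tol=0.05, allow_shift=True)
    o = oracle_similarity(a, b, frag_tol=0.05, allow_shift=True)
    assert g.score <= o.score + 1e-9


class TestMatchmsCrossCheck:
    """Independent reference: matchms' ModifiedCosine on pre-sqrt spectra."""

    def test_scores_agree_with_matchms(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(40):
            a = random_spectrum(rng)
            b = random_spectrum(rng)
            ours = cosine_similarity(a, b, frag_tol=0.025, allow_shift=True)
            ma = matchms.Spectrum(
                mz=a.mz,
                intensities=np.sqrt(a.intensity),
                metadata={"precursor_mz": a.precursor_mz},
                metadata_harmonization=False,
            )
            mb = matchms.Spectrum(
                mz=b.mz,
                intensities=np.sqrt(b.intensity),
                metadata={"precursor_mz": b.precursor_mz},
                metadata_harmonization=False,
            )
            theirs = ModifiedCosine(tolerance=0.025, intensity_power=1.0).pair(ma, mb)
            assert ours.score == pytest.approx(float(theirs["score"]), abs=1e-6)
            checked += 1
        assert checked == 40


class TestLibraryMatch:
    def library(self):
        return [
            make_spectrum([(100.0, 1.0), (110.0, 2.0), (120.0, 3.0), (130.0, 4.0)],
                          precursor=400.0, spectrum_id="lib0"),
            make_spectrum([(100.0, 4.0), (110.0, 3.0), (120.0, 2.0), (130.0, 1.0)],
                          precursor=400.0, spectrum_id="lib1"),
            make_spectrum([(210.0, 1.0), (220.0, 1.0), (230.0, 1.0), (240.0, 1.0)],
                          precursor=500.0, spectrum_id="lib2"),
        ]

    def test_identical_entry_ranks_first_with_score_one(self):
        lib = self.library()
        hits = library_match(lib[1], lib, min_score=0.5)
        assert hits[0][0].spectrum_id == "lib1"
        assert hits[0][1].score == pytest.approx(1.0, abs=1e-9)

    def test_unreachable_min_score_gives_no_hits(self):
        lib = self.library()
        assert library_match(lib[0], lib, min_score=1.1) == []

    def test_threshold_separates_hits(self):
        lib = self.library()
        query = lib[0]
        all_hits = library_match(query, lib, min_score=0.0)
        scores = [r.score for _, r in all_hits]
        assert scores == sorted(scores, reverse=True)
        cut = (scores[0] + scores[1]) / 2 if len(scores) > 1 else 0.5
        fewer = library_match(query, lib, min_score=cut)
        assert len(fewer) < len(all_hits)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            library_match(self.library()[0], [], min_score=0.5)
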