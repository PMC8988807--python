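import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssmnet.mass_calc import (
    DEFAULT_ADDUCT_RULES,
    MS1Scan,
    PROTONATED,
    AdductRule,
    adduct_mz,
    eic_apex_regions,
    eic_area,
    extract_eic,
    formula_union,
    monoisotopic_mass,
    parse_formula,
    read_ms1_csv,
    within_tolerance,
    write_ms1_csv,
)

RULES = {r.name: r for r in DEFAULT_ADDUCT_RULES}


class TestMonoisotopicMass:
    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass("") == 0.0

    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("H2O", 18.0106),  # 2*1.0078250319 + 15.9949146221
            ("C20H36N2O6", 400.2573),  # elemental sum, cross-checked externally
            ("2H2O", 36.0211),  # leading multiplier
        ],
    )
    def test_known_masses_to_4dp(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-5)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            monoisotopic_mass("C2Xx3")

    def test_mass_additive_under_formula_union(self):
        a, b = "C16H26N2O6", "C4H8"
        union = formula_union(a, b)
        assert monoisotopic_mass(union) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )
        assert union == parse_formula("C20H34N2O6")


class TestAdductArithmetic:
    @pytest.mark.parametrize(
        "formula,printed_mz",
        [
            ("C20H36N2O6", 401.26),  # dihydroeponemycin
            ("C20H34N2O6", 399.25),  # eponemycin
            ("C16H28N2O6", 345.20),  # dihydro TMC-86A
            ("C16H26N2O6", 343.19),  # TMC-86A
        ],
    )
    def test_protonated_epoxyketones_round_to_printed_values(self, formula, printed_mz):
        mz = adduct_mz(monoisotopic_mass(formula), PROTONATED)
        assert round(mz, 2) == printed_mz

    def test_zero_neutral_mass_gives_proton_mass(self):
        assert adduct_mz(0.0, PROTONATED) == pytest.approx(1.007276)

    def test_zero_charge_rejected(self):
        rule = AdductRule("bad", 1.0, charge=0)
        with pytest.raises(ValueError):
            rule.mz(100.0)

    def test_dimer_rule_doubles_neutral_mass(self):
        m = monoisotopic_mass("C20H36N2O6")
        assert RULES["[2M+H]+"].mz(m) == pytest.approx(2 * m + 1.007276, abs=1e-9)

    def test_neutral_mass_inverts_mz(self):
        m = 400.2573
        for rule in DEFAULT_ADDUCT_RULES:
            assert rule.neutral_mass(rule.mz(m)) == pytest.approx(m, abs=1e-9)

    def test_congener_offsets_match_family_mass_relations(self):
        # saturation (2H) and acyl-chain (C4H8) offsets between congeners
        mh = lambda f: adduct_mz(monoisotopic_mass(f), PROTONATED)
        assert mh("C20H36N2O6") - mh("C20H34N2O6") == pytest.approx(2.01565, abs=1e-4)
        assert mh("C20H36N2O6") - mh("C16H28N2O6") == pytest.approx(56.0626, abs=1e-4)
        assert mh("C20H34N2O6") - mh("C16H26N2O6") == pytest.approx(56.0626, abs=1e-4)


class TestTolerance:
    @pytest.mark.parametrize(
        "a,b,tol,expected",
        [
            (401.264, 401.26, 0.01, True),
            (401.28, 401.26, 0.01, False),
            (123.456, 123.456, 0.0, True),
        ],
    )
    def test_window_membership(self, a, b, tol, expected):
        assert within_tolerance(a, b, tol) is expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            within_tolerance(1.0, 1.0, -0.01)


def scan(rt, pairs):
    return MS1Scan(rt, np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))


class TestEIC:
    def test_one_point_per_scan_with_zero_outside_window(self):
        scans = [
            scan(1.0, [(100.0, 5.0)]),
            scan(2.0, [(401.262, 500.0)]),
            scan(3.0, [(500.0, 1.0)]),
        ]
        assert extract_eic(scans, 401.26, 0.01) == [(1.0, 0.0), (2.0, 500.0), (3.0, 0.0)]

    def test_in_window_peaks_summed_within_scan(self):
        scans = [scan(1.0, [(401.255, 300.0), (401.265, 200.0)])]
        assert extract_eic(scans, 401.26, 0.01) == [(1.0, 500.0)]

    def test_zero_tolerance_without_exact_match_is_all_zero(self):
        scans = [scan(1.0, [(401.262, 500.0)])]
        assert extract_eic(scans, 401.26, 0.0) == [(1.0, 0.0)]

    def test_unordered_scans_rejected(self):
        scans = [scan(2.0, [(100.0, 1.0)]), scan(1.0, [(100.0, 1.0)])]
        with pytest.raises(ValueError, match="ordered"):
            extract_eic(scans, 100.0, 0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tols=st.tuples(st.floats(0, 0.5), st.floats(0, 0.5)))
    def test_total_signal_monotone_in_tolerance(self, tols):
        scans = [
            scan(0.5, [(401.2, 10.0), (401.26, 20.0)]),
            scan(1.0, [(401.3, 5.0), (401.5, 7.0)]),
        ]
        lo, hi = sorted(tols)
        total = lambda t: sum(i for _, i in extract_eic(scans, 401.26, t))
        assert total(lo) <= total(hi) + 1e-12

    def test_apex_regions_separates_two_gaussians(self):
        rts = np.arange(5.0, 9.0, 0.02)
        inten = 100 * np.exp(-0.5 * ((rts - 6.6) / 0.04) ** 2) + 60 * np.exp(
            -0.5 * ((rts - 7.4) / 0.04) ** 2
        )
        eic = list(zip(rts, inten))
        regions = eic_apex_regions(eic, min_fraction=0.1)
        assert len(regions) == 2
        assert regions[0][0] <= 6.6 <= regions[0][1]
        assert regions[1][0] <= 7.4 <= regions[1][1]

    def test_area_is_trapezoidal(self):
        eic = [(0.0, 0.0), (1.0, 2.0), (2.0, 0.0)]
        assert eic_area(eic) == pytest.approx(2.0)


def test_ms1_csv_round_trip(tmp_path):
    scans = {
        "s1": [scan(0.5, [(100.0, 1.0), (200.0, 2.0)]), scan(1.0, [(100.0, 3.0)])],
        "s2": [scan(0.5, [(150.0, 4.0)])],
    }
    path = write_ms1_csv(scans, tmp_path / "ms1.csv")
    back = read_ms1_csv(path)
    assert set(back) == {"s1", "s2"}
    for sid in scans:
        for orig, rt in zip(scans[sid], back[sid]):
            assert rt.rt == pytest.approx(orig.rt, abs=1e-6)
            np.testing.assert_allclose(rt.mz, orig.mz, atol=1e-5)
            np.testing.assert_allclose(rt.intensity, orig.intensity, rtol=1e-5)
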