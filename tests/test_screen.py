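"""Screen rules: masking, normalization, hits, fast-acting flags, plate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aldscreen.screen import (
    NormalizationConfig,
    ScreenConfigError,
    ScreenQCError,
    analyze_plate,
    call_hits,
    flag_fast_acting,
    mask_toxic_wells,
    normalize_to_controls,
    reduction_vs_neutral,
    robust_z_prime,
    signal_to_background,
)

CFG = NormalizationConfig()


def _wells(rows):
    return pd.DataFrame(
        rows, columns=["well", "role", "compound", "dose_uM", "n_cells", "fraction_high"]
    )


def _plate(sample_rows):
    controls = [
        ("A01", "dmso", "", 0.0, 100, 0.10),
        ("A02", "dmso", "", 0.0, 100, 0.10),
        ("B01", "deab", "DEAB", 10.0, 100, 0.00),
        ("B02", "deab", "DEAB", 10.0, 100, 0.00),
    ]
    return _wells(controls + sample_rows)


class TestMasking:
    def test_strict_boundary(self):
        wells = _plate([
            ("C01", "sample", "X", 10.0, 49, 0.10),   # 51% reduced -> masked
            ("C02", "sample", "Y", 10.0, 50, 0.10),   # exactly 50% -> kept
            ("C03", "sample", "Z", 10.0, 100, 0.10),  # untouched
        ])
        masked = mask_toxic_wells(wells, CFG)
        assert masked.tolist() == [False, False, False, False, True, False, False]

    def test_missing_neutral_controls_is_config_error(self):
        wells = _wells([("C01", "sample", "X", 10.0, 50, 0.1)])
        with pytest.raises(ScreenConfigError):
            mask_toxic_wells(wells, CFG)


class TestNormalization:
    def test_anchors_and_midpoint(self):
        wells = _plate([("C01", "sample", "X", 10.0, 100, 0.05)])
        eff = normalize_to_controls(wells, CFG)
        assert eff.iloc[0] == pytest.approx(0.0)    # dmso well -> 0%
        assert eff.iloc[2] == pytest.approx(100.0)  # deab well -> 100%
        assert eff.iloc[4] == pytest.approx(50.0)   # halfway between anchors

    def test_degenerate_anchors_qc_error(self):
        wells = _wells([
            ("A01", "dmso", "", 0.0, 100, 0.10),
            ("B01", "deab", "", 0.0, 100, 0.10),
        ])
        with pytest.raises(ScreenQCError):
            normalize_to_controls(wells, CFG)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-0.5, 0.5))
    def test_affine_invariance_under_shift(self, c):
        wells = _plate([("C01", "sample", "X", 10.0, 100, 0.07)])
        base = normalize_to_controls(wells, CFG)
        shifted = wells.copy()
        shifted["fraction_high"] = shifted["fraction_high"] + c
        assert np.allclose(normalize_to_controls(shifted, CFG), base)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_reduction_invariant_under_scaling(self, c):
        wells = _plate([("C01", "sample", "X", 10.0, 100, 0.07)])
        base = reduction_vs_neutral(wells, CFG)
        scaled = wells.copy()
        scaled["fraction_high"] = scaled["fraction_high"] * c
        assert np.allclose(reduction_vs_neutral(scaled, CFG), base)


class TestHitCalling:
    def test_boundary_and_mask_precedence(self):
        # fractions are binary-exact so the 25% boundary is hit exactly
        wells = _wells([
            ("A01", "dmso", "", 0.0, 100, 0.5),
            ("A02", "dmso", "", 0.0, 100, 0.5),
            ("B01", "deab", "DEAB", 10.0, 100, 0.0),
            ("B02", "deab", "DEAB", 10.0, 100, 0.0),
            ("C01", "sample", "A", 10.0, 100, 0.3125),  # 37.5% reduction -> hit
            ("C02", "sample", "B", 10.0, 100, 0.375),   # exactly 25% -> not a hit
            ("C03", "sample", "C", 10.0, 40, 0.125),    # 75% reduction but masked
        ])
        masked = mask_toxic_wells(wells, CFG)
        assert masked.tolist() == [False, False, False, False, False, False, True]
        hits = call_hits(wells, masked, CFG)
        # rows 2,3 are the deab controls: 100% reduction, unmasked -> hits by the
        # bare rule; sample rows are C01 (hit), C02 (boundary), C03 (masked)
        assert hits.tolist() == [False, False, True, True, True, False, False]

    def test_zero_neutral_fraction_not_evaluable(self):
        wells = _wells([
            ("A01", "dmso", "", 0.0, 100, 0.0),
            ("A02", "dmso", "", 0.0, 100, 0.0),
            ("B01", "deab", "", 0.0, 100, 0.2),
            ("C01", "sample", "X", 10.0, 100, 0.0),
        ])
        masked = mask_toxic_wells(wells, CFG)
        red = reduction_vs_neutral(wells, CFG)
        assert red.isna().all()
        assert not call_hits(wells, masked, CFG).any()


class TestHitRulesAgainstBruteForce:
    """Independent re-implementation of the masking + hit rules, enumerated
    on a hand-built 24-well toy plate including both boundary wells."""

    def _brute_force(self, wells):
        dmso_n = float(np.median(
            [r.n_cells for r in wells.itertuples() if r.role == "dmso"]))
        dmso_f = float(np.median(
            [r.fraction_high for r in wells.itertuples() if r.role == "dmso"]))
        masked, hits = [], []
        for r in wells.itertuples():
            reduced_by = 100.0 * (dmso_n - r.n_cells) / dmso_n
            m = reduced_by > 50.0
            frac_reduction = 100.0 * (dmso_f - r.fraction_high) / dmso_f
            masked.append(m)
            hits.append((not m) and frac_reduction > 25.0)
        return masked, hits

    def test_toy_plate_flags_match(self, rng):
        rows = [(f"A{c:02d}", "dmso", "", 0.0, 200, 0.10) for c in range(1, 5)]
        rows += [(f"B{c:02d}", "deab", "DEAB", 10.0, 200, 0.0) for c in range(1, 5)]
        # samples spanning both rule boundaries and random fill
        rows += [
            ("C01", "sample", "c1", 10.0, 99, 0.10),    # 50.5% reduced -> masked
            ("C02", "sample", "c2", 10.0, 100, 0.10),   # exactly 50% -> kept
            ("C03", "sample", "c3", 10.0, 101, 0.10),   # kept
            ("C04", "sample", "c4", 10.0, 200, 0.075),  # exactly 25% -> no hit
            ("D01", "sample", "c5", 10.0, 200, 0.0749), # just past 25% -> hit
            ("D02", "sample", "c6", 10.0, 200, 0.13),   # negative reduction
            ("D03", "sample", "c7", 10.0, 80, 0.01),    # masked despite reduction
        ]
        for i in range(9):
            rows.append((f"E{i + 1:02d}", "sample", f"r{i}", 10.0,
                         int(rng.integers(60, 260)),
                         float(rng.uniform(0, 0.15))))
        wells = _wells(rows)
        masked = mask_toxic_wells(wells, CFG)
        hits = call_hits(wells, masked, CFG)
        bf_masked, bf_hits = self._brute_force(wells)
        assert masked.tolist() == bf_masked
        assert hits.tolist() == bf_hits


class TestFastActing:
    @pytest.mark.parametrize(
        "e2h,washoff,expected",
        [(94.0, 5.0, True),     # the DEAB-like direct-inhibitor pattern
         (10.0, 80.0, False),
         (90.0, 90.0, False),   # strong 2 h effect but no rebound
         (74.9, 5.0, False),
         (75.0, 24.9, True)],   # thresholds: >= t_fast, < t_rebound
    )
    def test_rule_table(self, e2h, washoff, expected):
        assert flag_fast_acting(e2h, washoff) is expected

    def test_missing_measurement_not_evaluable(self):
        assert flag_fast_acting(None, 5.0) is None
        assert flag_fast_acting(94.0, float("nan")) is None


class TestRobustZPrime:
    def test_zero_spread_is_exactly_one(self):
        assert robust_z_prime([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == 1.0

    def test_worked_example(self):
        rz = robust_z_prime([0.0, 0.1, 0.2], [1.0, 1.1, 1.2])
        assert rz == pytest.approx(1 - 3 * (0.14826 + 0.14826) / 1.0, abs=1e-12)
        assert rz == pytest.approx(0.11044, abs=1e-5)

    def test_matches_brute_force_formula(self, rng):
        def brute(pos, neg):
            med = lambda v: float(np.median(v))
            mad = lambda v: med(np.abs(np.asarray(v) - med(v)))
            return 1 - 3 * (1.4826 * mad(pos) + 1.4826 * mad(neg)) / abs(
                med(pos) - med(neg))

        for _ in range(100):
            pos = rng.normal(0.02, 0.01, rng.integers(3, 16))
            neg = rng.normal(0.2, 0.03, rng.integers(3, 16))
            assert robust_z_prime(pos, neg) == pytest.approx(brute(pos, neg))

    def test_equal_medians_sentinel(self):
        assert robust_z_prime([0.1, 0.1, 0.2], [0.1, 0.1, 0.3]) == float("-inf")

    def test_too_few_wells(self):
        with pytest.raises(ScreenQCError):
            robust_z_prime([0.1, 0.2], [0.5, 0.6, 0.7])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=12),
           st.lists(st.floats(2, 3), min_size=3, max_size=12))
    def test_never_exceeds_one(self, pos, neg):
        assert robust_z_prime(pos, neg) <= 1.0

    def test_decreases_with_spread_at_fixed_medians(self):
        tight = robust_z_prime([0.09, 0.10, 0.11], [0.49, 0.50, 0.51])
        wide = robust_z_prime([0.05, 0.10, 0.15], [0.45, 0.50, 0.55])
        assert wide < tight


class TestSignalToBackground:
    def test_arithmetic(self):
        assert signal_to_background([0.2, 0.2], [0.1, 0.1]) == pytest.approx(2.0)

    def test_identical_groups(self):
        assert signal_to_background([0.1, 0.3], [0.1, 0.3]) == pytest.approx(1.0)

    def test_zero_background_infinite(self):
        assert signal_to_background([0.2], [0.0]) == float("inf")


class TestAnalyzePlate:
    def test_followup_classifies_fast_acting_hits(self):
        wells = _plate([
            ("C01", "sample", "slow", 10.0, 100, 0.04),   # 60% reduction
            ("C02", "sample", "mimic", 10.0, 100, 0.004),  # 96% reduction
            ("C03", "sample", "inert", 10.0, 100, 0.10),
        ])
        # need >=3 controls per group for RZ'; extend controls
        extra = _wells([("A03", "dmso", "", 0.0, 100, 0.10),
                        ("B03", "deab", "DEAB", 10.0, 100, 0.0)])
        wells = pd.concat([wells, extra], ignore_index=True)
        followup = pd.DataFrame({
            "compound": ["slow", "mimic"],
            "effect_2h": [12.0, 94.0],
            "effect_washoff": [80.0, 5.0],
        })
        res = analyze_plate(wells, CFG, followup=followup)
        assert res.fast_acting["mimic"] is True
        assert res.fast_acting["slow"] is False
        assert res.n_masked == 0
        assert res.rz_prime <= 1.0
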