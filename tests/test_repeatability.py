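"""Reliability statistics: ANOVA components, ICC(1,1), CR, Bland-Altman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octrepeat.repeatability import (
    CR_CONSTANT,
    bland_altman,
    classify_icc,
    coefficient_of_repeatability,
    cr_grid,
    icc_grid,
    icc_oneway,
    oneway_anova,
    repeatability_table,
)


def flat(groups):
    """(values, units) arrays from a list of per-unit value tuples."""
    values, units = [], []
    for i, g in enumerate(groups):
        values.extend(g)
        units.extend([f"u{i}"] * len(g))
    return np.array(values, dtype=float), np.array(units)


def bruteforce_icc(groups):
    """Independent sums-of-squares oracle, plain Python arithmetic."""
    a = len(groups)
    ns = [len(g) for g in groups]
    n_total = sum(ns)
    grand = sum(sum(g) for g in groups) / n_total
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ssw = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    if len(set(ns)) == 1:
        k = ns[0]
    else:
        k = (n_total - sum(n * n for n in ns) / n_total) / (a - 1)
    if msw == 0.0:
        return 1.0
    return (msb - msw) / (msb + (k - 1) * msw)


THREE_UNITS = [(1.0, 2.0), (3.0, 4.0), (9.0, 10.0)]


class TestOnewayAnova:
    def test_hand_computed_mean_squares(self):
        vc = oneway_anova(*flat(THREE_UNITS))
        assert vc.msb == pytest.approx(34.667, abs=1e-3)
        assert vc.msw == pytest.approx(0.5)
        assert vc.k_eff == 2.0

    def test_unbalanced_k0(self):
        groups = [(1.0, 2.0), (3.0, 4.0), (9.0, 10.0, 11.0)]
        vc = oneway_anova(*flat(groups))
        # k0 = (7 - 17/7) / 2
        assert vc.k_eff == pytest.approx(2.2857, abs=1e-4)
        assert vc.group_sizes == (2, 2, 3)

    def test_identical_sessions_zero_msw(self):
        vc = oneway_anova(*flat([(5.0, 5.0), (7.0, 7.0)]))
        assert vc.msw == 0.0
        assert vc.msb > 0.0

    def test_single_session_units_dropped(self, caplog):
        values, units = flat([(1.0, 2.0), (3.0, 4.0), (9.0,)])
        with caplog.at_level("WARNING"):
            vc = oneway_anova(values, units)
        assert vc.n_units == 2
        assert "single session" in caplog.text

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match=">= 2 units"):
            oneway_anova(*flat([(1.0, 2.0), (9.0,)]))

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            oneway_anova(*flat([(5.0, 5.0), (5.0, 5.0)]))


class TestICC:
    def test_hand_computed_point_estimate(self):
        vc = oneway_anova(*flat(THREE_UNITS))
        res = icc_oneway(vc)
        assert res.icc == pytest.approx(0.9716, abs=1e-4)
        assert res.classification == "excellent"

    def test_perfect_repeatability(self):
        vc = oneway_anova(*flat([(5.0, 5.0), (9.0, 9.0)]))
        res = icc_oneway(vc)
        assert res.icc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_negative_lower_bound(self):
        # MSB = 0, MSW = 40.5: the k=2 estimator floor of -1
        vc = oneway_anova(*flat([(1.0, 10.0), (10.0, 1.0)]))
        assert vc.msb == pytest.approx(0.0, abs=1e-12)
        assert vc.msw == pytest.approx(40.5)
        assert icc_oneway(vc).icc == pytest.approx(-1.0)

    def test_ci_brackets_point_estimate_random(self, rng):
        for _ in range(500):
            a = rng.integers(2, 6)
            groups = [tuple(rng.integers(0, 5, rng.integers(2, 4)).astype(float))
                      for _ in range(a)]
            values, units = flat(groups)
            try:
                vc = oneway_anova(values, units)
            except ValueError:
                continue
            res = icc_oneway(vc)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_on_balanced_data(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.normal(50, 5, size=(12, 3)) + rng.normal(
            0, 4, size=(12, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 3),
            "raters": np.tile(np.arange(3), 12),
            "ratings": values.ravel(),
        })
        # the one-way single-measures row comes first in pingouin's output
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).iloc[0]
        units = np.repeat(np.arange(12), 3)
        vc = oneway_anova(values.ravel(), units)
        res = icc_oneway(vc)
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-9)
        # pingouin rounds its CI bounds to two decimals
        assert res.ci_low == pytest.approx(ref["CI95"][0], abs=6e-3)
        assert res.ci_high == pytest.approx(ref["CI95"][1], abs=6e-3)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(0.1, 100.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, a, b):
        values, units = flat(THREE_UNITS)
        icc1 = icc_oneway(oneway_anova(values, units)).icc
        icc2 = icc_oneway(oneway_anova(a * values + b, units)).icc
        assert icc2 == pytest.approx(icc1, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("icc,expected", [
        (0.92, "excellent"),
        (0.95, "excellent"),
        (0.90, "moderate"),   # boundary assigned to "between"
        (0.85, "moderate"),
        (0.80, "moderate"),
        (0.79, "insufficient"),
        (0.75, "insufficient"),
        (-0.3, "insufficient"),
    ])
    def test_thresholds(self, icc, expected):
        assert classify_icc(icc) == expected


class TestCR:
    def test_published_constant(self):
        # within-subject SD of exactly 1 um -> CR 2.77 um
        vc = oneway_anova(*flat([(0.0, 2.0), (10.0, 12.0), (5.0, 7.0)]))
        assert vc.msw == pytest.approx(2.0)  # sd of each pair diff sqrt(2)
        res = coefficient_of_repeatability(vc)
        assert res.sw == pytest.approx(np.sqrt(2.0))
        unit_sw = type(vc)(n_units=vc.n_units, group_sizes=vc.group_sizes,
                           msb=vc.msb, msw=1.0, k_eff=vc.k_eff)
        assert coefficient_of_repeatability(unit_sw).cr == 2.77
        assert CR_CONSTANT == 2.77

    def test_hand_computed_cr(self):
        vc = oneway_anova(*flat(THREE_UNITS))
        assert coefficient_of_repeatability(vc).cr == pytest.approx(
            2.77 * np.sqrt(0.5), abs=1e-9)

    def test_identical_repeats_zero(self):
        vc = oneway_anova(*flat([(5.0, 5.0), (9.0, 9.0)]))
        assert coefficient_of_repeatability(vc).cr == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.01, 1000.0))
    def test_scale_equivariance(self, a):
        values, units = flat(THREE_UNITS)
        cr1 = coefficient_of_repeatability(oneway_anova(values, units)).cr
        cr2 = coefficient_of_repeatability(oneway_anova(a * values, units)).cr
        assert cr2 == pytest.approx(a * cr1, rel=1e-12)


class TestBlandAltman:
    def test_hand_computed_pairs(self):
        res = bland_altman(*flat(THREE_UNITS))
        assert res.points.shape == (3, 2)
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (-1.0, -1.0)

    def test_identical_sessions_on_zero_line(self):
        res = bland_altman(*flat([(5.0, 5.0), (9.0, 9.0)]))
        assert np.allclose(res.points[:, 1], 0.0)

    def test_three_sessions_three_pairs(self):
        res = bland_altman(*flat([(1.0, 2.0, 3.0)]))
        assert res.points.shape == (3, 2)
        np.testing.assert_allclose(sorted(res.points[:, 1]), [-2.0, -1.0, -1.0])

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="no session pairs"):
            bland_altman(*flat([(1.0,), (2.0,)]))

    def test_loa_half_width_approximates_cr(self):
        """With pure session noise, 1.96 sd(diff) = 1.96 sqrt(2) sigma ~ CR."""
        rng = np.random.default_rng(3)
        sigma_w = 1.5
        groups = [tuple(10.0 + rng.normal(0, sigma_w, 2)) for _ in range(1500)]
        values, units = flat(groups)
        res = bland_altman(values, units)
        half_width = 1.96 * res.sd_diff
        assert half_width == pytest.approx(1.96 * np.sqrt(2) * sigma_w,
                                           rel=0.05)
        cr = coefficient_of_repeatability(oneway_anova(values, units)).cr
        assert half_width == pytest.approx(cr, rel=0.05)


def _long_table(rng, estimates=("A",), layers=("RNFL",), n_eyes=6,
                sessions=3, group="HC"):
    rows = []
    for e in range(n_eyes):
        subject, eye = f"{group}{e // 2}", ["OD", "OS"][e % 2]
        base = rng.normal(90, 6)
        for est in estimates:
            for layer in layers:
                for s in range(1, sessions + 1):
                    rows.append({
                        "subject_id": subject, "eye": eye, "group": group,
                        "session": s, "device": "spectralis",
                        "estimate": est, "layer": layer,
                        "thickness_um": base + rng.normal(0, 1.0),
                        "n_cells": 100,
                    })
    return pd.DataFrame(rows)


class TestRepeatabilityTable:
    def test_grid_shape_and_na_cells(self, rng):
        table = pd.concat([
            _long_table(rng, estimates=("A", "B"),
                        layers=("RNFL", "GCL", "OPL")),
            _long_table(rng, estimates=("K",), layers=("RNFL", "GCIP")),
        ])
        res = repeatability_table(table, "mixed")
        assert len(res) == 2 * 3 + 2
        grid = icc_grid(res)
        assert list(grid.index) == ["A", "B", "K"]
        assert list(grid.columns) == ["RNFL", "GCL", "GCIP", "OPL"]
        assert grid.loc["K", "GCL"] == "NA"
        assert grid.loc["A", "GCL"] != "NA"
        cr = cr_grid(res)
        assert cr.loc["K", "OPL"] == "NA"

    def test_single_estimate_full_layer_row(self, rng):
        layers = ("RNFL", "GCL", "IPL", "GCIP", "INL", "OPL", "ONL")
        res = repeatability_table(_long_table(rng, layers=layers), "mixed")
        assert len(res) == 7
        assert list(res["layer"]) == list(layers)

    def test_cohort_filter(self, rng):
        table = pd.concat([
            _long_table(rng, group="HC"),
            _long_table(rng, group="MS", sessions=2),
        ])
        hc = repeatability_table(table, "HC")
        mixed = repeatability_table(table, "mixed")
        assert hc.iloc[0]["n_obs"] == 18
        assert mixed.iloc[0]["n_obs"] == 30
        assert mixed.iloc[0]["k_eff"] == pytest.approx(
            (30 - (6 * 9 + 6 * 4) / 30) / 11)
        with pytest.raises(ValueError, match="unknown cohort"):
            repeatability_table(table, "ALL")

    def test_grid_cell_format(self, rng):
        res = repeatability_table(_long_table(rng), "mixed")
        cell = icc_grid(res).loc["A", "RNFL"]
        assert "[" in cell and "–" in cell
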