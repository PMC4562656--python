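"""Reliability statistics for repeated thickness measurements.

The reliability model is a one-way ANOVA with the eye as the measurement
unit and sessions as replicates:

    x_ij = mu + b_i + e_ij,   b_i ~ (0, sigma_b^2),  e_ij ~ (0, sigma_w^2)

From the between- and within-unit mean squares (MSB, MSW) this module
computes

* ICC(1,1) = (MSB - MSW) / (MSB + (k_eff - 1) MSW), the single-measures
  intraclass correlation, with the exact F-based 95% confidence interval;
  for unbalanced designs k_eff is the standard k0 = (N - sum n_i^2 / N)/(a-1).
* the coefficient of repeatability CR = 2.77 * s_w with s_w = sqrt(MSW);
  2.77 is the conventional printed rounding of sqrt(2) * 1.96 and is kept
  as-is so published tables reproduce digit-for-digit.
* Bland-Altman bias and limits of agreement over every unordered session
  pair of every unit.

Negative ICC point estimates are reported unclamped: the estimator ranges
over (-1/(k_eff - 1), 1], and truncating at zero would bias simulation
studies built on these statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import LAYERS

__all__ = [
    "CR_CONSTANT",
    "VarianceComponents",
    "ICCResult",
    "CRResult",
    "BlandAltmanResult",
    "oneway_anova",
    "icc_oneway",
    "coefficient_of_repeatability",
    "bland_altman",
    "classify_icc",
    "repeatability_table",
    "icc_grid",
    "cr_grid",
]

logger = logging.getLogger(__name__)

#: Printed rounding of sqrt(2) * 1.96 used for the repeatability coefficient.
CR_CONSTANT = 2.77

ESTIMATE_ORDER = tuple("ABCDEFGHIJKL")


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA mean squares for a single estimate x layer cell."""

    n_units: int
    group_sizes: tuple[int, ...]
    msb: float
    msw: float
    k_eff: float

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def df_between(self) -> int:
        return self.n_units - 1

    @property
    def df_within(self) -> int:
        return self.n_total - self.n_units


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    classification: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class CRResult:
    cr: float
    sw: float


@dataclass(frozen=True)
class BlandAltmanResult:
    points: np.ndarray  # (n_pairs, 2): pair mean, pair difference
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def _group_values(
    values: Sequence[float] | np.ndarray,
    units: Sequence,
) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    units = np.asarray(units)
    if values.shape != units.shape:
        raise ValueError("values and units must have equal length")
    groups = []
    for u in pd.unique(units):
        groups.append(values[units == u])
    return groups


def oneway_anova(
    values: Sequence[float] | np.ndarray,
    units: Sequence,
) -> VarianceComponents:
    """Between/within mean squares with the eye (unit) as the grouping factor.

    Units with fewer than two sessions are dropped with a logged warning.
    Raises when fewer than two usable units remain or when the data carry no
    variance at all (MSB = MSW = 0).
    """
    groups = _group_values(values, units)
    usable = [g for g in groups if g.size >= 2]
    dropped = len(groups) - len(usable)
    if dropped:
        logger.warning("dropping %d unit(s) with a single session", dropped)
    a = len(usable)
    if a < 2:
        raise ValueError(f"need >= 2 units with >= 2 sessions, have {a}")
    sizes = np.array([g.size for g in usable])
    n_total = int(sizes.sum())
    grand = float(np.concatenate(usable).mean())
    means = np.array([g.mean() for g in usable])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in usable))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    if msb == 0.0 and msw == 0.0:
        raise ValueError("degenerate data: zero total variance")
    if np.all(sizes == sizes[0]):
        k_eff = float(sizes[0])
    else:
        k_eff = (n_total - float(np.sum(sizes**2)) / n_total) / (a - 1)
    return VarianceComponents(
        n_units=a, group_sizes=tuple(int(s) for s in sizes),
        msb=msb, msw=msw, k_eff=k_eff,
    )


def classify_icc(icc: float) -> str:
    """Excellent above 0.9, moderate in [0.8, 0.9], insufficient below 0.8."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.8:
        return "moderate"
    return "insufficient"


def icc_oneway(vc: VarianceComponents, alpha: float = 0.05) -> ICCResult:
    """ICC(1,1) point estimate with its exact F-based confidence interval.

    With F = MSB/MSW on (a-1, N-a) degrees of freedom the bounds are
    (F/f* - 1)/(F/f* + k_eff - 1) with f* the upper and lower alpha/2 F
    quantiles.  When MSW = 0 the ICC is exactly 1 with a degenerate CI.
    """
    k = vc.k_eff
    if vc.msw == 0.0:
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         classification=classify_icc(1.0))
    icc = (vc.msb - vc.msw) / (vc.msb + (k - 1.0) * vc.msw)
    f_obs = vc.msb / vc.msw
    df1, df2 = vc.df_between, vc.df_within
    f_hi = sps.f.ppf(1.0 - alpha / 2.0, df1, df2)
    f_lo = sps.f.ppf(alpha / 2.0, df1, df2)
    fl = f_obs / f_hi
    fu = f_obs / f_lo
    ci_low = (fl - 1.0) / (fl + k - 1.0)
    ci_high = (fu - 1.0) / (fu + k - 1.0)
    # guard against last-ulp inversions in degenerate cases (e.g. MSB = 0,
    # where estimate and both bounds coincide at -1/(k-1))
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(icc=float(icc), ci_low=float(ci_low),
                     ci_high=float(ci_high),
                     classification=classify_icc(float(icc)))


def coefficient_of_repeatability(vc: VarianceComponents) -> CRResult:
    """CR = 2.77 x within-subject SD; the 95% bound on a repeat difference."""
    sw = float(np.sqrt(vc.msw))
    return CRResult(cr=CR_CONSTANT * sw, sw=sw)


def bland_altman(
    values: Sequence[float] | np.ndarray,
    units: Sequence,
) -> BlandAltmanResult:
    """Difference-vs-mean analysis over all unordered session pairs.

    Within each unit every unordered pair (j < l, in input order)
    contributes ((x_j + x_l)/2, x_j - x_l); a three-session unit therefore
    contributes three pairs.  Limits of agreement are bias -/+ 1.96 sd of
    the differences.
    """
    groups = _group_values(values, units)
    pts = []
    for g in groups:
        for j in range(g.size):
            for l in range(j + 1, g.size):
                pts.append(((g[j] + g[l]) / 2.0, g[j] - g[l]))
    if not pts:
        raise ValueError("no session pairs: every unit has < 2 sessions")
    points = np.array(pts)
    diffs = points[:, 1]
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltmanResult(
        points=points, bias=bias, sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff, loa_high=bias + 1.96 * sd_diff,
    )


def _unit_key(df: pd.DataFrame) -> pd.Series:
    return df["subject_id"].astype(str) + ":" + df["eye"].astype(str)


def repeatability_table(
    table: pd.DataFrame,
    cohort: str = "mixed",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ICC and CR per (estimate, layer) cell of a long repeated-measures table.

    ``cohort`` filters by group: "mixed" keeps everything, "HC"/"MS" keep one
    group.  Output rows follow the estimate order A-L and the layer order
    RNFL..ONL; cells without usable data (e.g. GCL under the Cirrus
    estimates) are absent from the output and render as NA in the wide
    grids (:func:`icc_grid`, :func:`cr_grid`).
    """
    if cohort not in ("mixed", "HC", "MS"):
        raise ValueError(f"unknown cohort filter {cohort!r}")
    df = table if cohort == "mixed" else table[table["group"] == cohort]
    if df.empty:
        raise ValueError(f"no data after cohort filter {cohort!r}")
    rows = []
    estimates = [e for e in ESTIMATE_ORDER if e in set(df["estimate"])]
    estimates += sorted(set(df["estimate"]) - set(ESTIMATE_ORDER))
    layer_order = [l for l in LAYERS if l in set(df["layer"])]
    for est in estimates:
        for layer in layer_order:
            cell = df[(df["estimate"] == est) & (df["layer"] == layer)]
            if cell.empty:
                continue
            units = _unit_key(cell)
            try:
                vc = oneway_anova(cell["thickness_um"].to_numpy(), units)
            except ValueError:
                logger.warning("skipping %s x %s: not analysable", est, layer)
                continue
            icc = icc_oneway(vc, alpha=alpha)
            cr = coefficient_of_repeatability(vc)
            rows.append({
                "estimate": est, "layer": layer,
                "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
                "classification": icc.classification,
                "cr_um": cr.cr, "sw_um": cr.sw,
                "n_eyes": vc.n_units, "n_obs": vc.n_total,
                "k_eff": vc.k_eff, "msb": vc.msb, "msw": vc.msw,
            })
    return pd.DataFrame(rows)


def _grid(result: pd.DataFrame, fmt) -> pd.DataFrame:
    estimates = [e for e in ESTIMATE_ORDER if e in set(result["estimate"])]
    layers = [l for l in LAYERS if l in set(result["layer"])]
    grid = pd.DataFrame("NA", index=estimates, columns=layers, dtype=object)
    for _, row in result.iterrows():
        grid.loc[row["estimate"], row["layer"]] = fmt(row)
    grid.index.name = "estimate"
    return grid


def icc_grid(result: pd.DataFrame) -> pd.DataFrame:
    """Estimates x layers grid of "icc [low-high]" cells (2 decimals)."""
    return _grid(
        result,
        lambda r: f"{r['icc']:.2f} [{r['ci_low']:.2f}–{r['ci_high']:.2f}]",
    )


def cr_grid(result: pd.DataFrame) -> pd.DataFrame:
    """Estimates x layers grid of CR in um (2 decimals)."""
    return _grid(result, lambda r: f"{r['cr_um']:.2f}")
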