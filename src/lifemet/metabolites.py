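"""Metabolite-matrix handling: fasting-time adjustment, descriptive summaries
and percentile spans.

The 49-metabolite NMR panel falls into seven biological groups (17
lipoprotein subclasses, 12 amino acids, 6 fatty acids, 2 fluid-balance
markers, 6 energy-metabolism metabolites, 5 products of bacterial
co-metabolism and O-phosphoethanolamine).  Plasma samples drawn after
variable fasting times (0-17 h) carry a fasting signal that is removed
before any association analysis: each metabolite is regressed on fasting
hours by ordinary least squares and the residuals are recalibrated to the
metabolite's sample mean, so adjusted concentrations keep their original
scale but are uncorrelated with fasting time.

Weighted quantiles use a step-function inversion of the cumulative weights
that reduces exactly to the linear-interpolation (type-7) convention at
equal weights and exactly to row duplication for integer weights; the
resulting 10th/90th percentile spans are the units in which metabolite rate
differences are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteMatrix",
    "GROUPS",
    "fasting_adjust",
    "summarize_by_category",
    "percentile_span",
    "weighted_quantile",
]

GROUPS = (
    "lipoprotein",
    "amino_acid",
    "fatty_acid",
    "fluid_balance",
    "energy",
    "bacterial",
    "phosphoethanolamine",
)


@dataclass
class MetaboliteMatrix:
    """An n x M metabolite concentration matrix with group taxonomy.

    ``values`` is a DataFrame (rows = participants, columns = metabolites);
    ``groups`` maps every column to one of :data:`GROUPS`; ``units`` carries
    per-metabolite unit labels as metadata only.
    """

    values: pd.DataFrame
    groups: dict
    fasting_adjusted: bool = False
    units: dict = field(default_factory=dict)
    allow_missing: bool = False

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        missing = [c for c in cols if c not in self.groups]
        extra = [g for g in self.groups if g not in cols]
        if missing or extra:
            raise ValueError(
                f"group taxonomy must cover all metabolites exactly once; "
                f"missing={missing}, extra={extra}"
            )
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown metabolite groups: {sorted(bad)}")
        if not self.allow_missing and self.values.isna().any().any():
            raise ValueError(
                "metabolite matrix contains missing values; exclude rows upstream"
            )

    @property
    def names(self) -> list:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)

    def group_members(self, group: str) -> list:
        return [m for m in self.names if self.groups[m] == group]


def fasting_adjust(matrix: MetaboliteMatrix, fasting_hours) -> MetaboliteMatrix:
    """Remove the linear fasting-time signal from every metabolite.

    Per metabolite: OLS of concentration on fasting hours (with intercept),
    keep the residual and add back the metabolite's sample mean.  Column
    means are preserved and the output is numerically uncorrelated with
    fasting hours.  A second application is a no-op.
    """
    if matrix.fasting_adjusted:
        raise ValueError("matrix is already fasting-adjusted")
    fh = np.asarray(fasting_hours, dtype=float)
    if fh.shape[0] != matrix.n:
        raise ValueError("fasting_hours length must match the number of rows")
    Y = matrix.values.to_numpy(dtype=float)
    if np.ptp(fh) == 0.0:
        warnings.warn(
            "fasting hours are constant; adjustment is a no-op", UserWarning
        )
        return replace(matrix, fasting_adjusted=True)
    X = np.column_stack([np.ones_like(fh), fh])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid + Y.mean(axis=0)
    out = pd.DataFrame(adjusted, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=out, fasting_adjusted=True)


def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Weighted quantiles by cumulative-weight step-function inversion.

    With equal weights this is exactly the linear-interpolation (type-7)
    quantile; with integer weights it exactly equals computing the type-7
    quantile on the row-duplicated sample.  Each sorted point x_(k) with
    weight w_k occupies the flat position interval
    [C_{k-1}, C_{k-1} + max(w_k - 1, 0)] / (S - 1), where C_k is the
    cumulative weight and S the total; the quantile function interpolates
    linearly between consecutive intervals.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-d")
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((qs < 0) | (qs > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    if weights is None:
        return np.quantile(x, qs)
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match values in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    C = np.cumsum(ws)
    S = C[-1]
    if S <= 1.0:
        # degenerate total mass; fall back to the unweighted convention
        return np.quantile(x, qs)
    left = np.concatenate([[0.0], C[:-1]])
    width = np.maximum(ws - 1.0, 0.0)
    # anchor positions (normalized) and values of the step function
    pos = np.empty(2 * xs.size)
    val = np.empty(2 * xs.size)
    pos[0::2] = left
    pos[1::2] = left + width
    val[0::2] = xs
    val[1::2] = xs
    pos /= S - 1.0
    target = np.clip(qs, pos[0], pos[-1])
    return np.interp(target, pos, val)


def summarize_by_category(
    matrix: MetaboliteMatrix,
    categories,
    weights=None,
) -> pd.DataFrame:
    """Weighted median and IQR of each metabolite within each HLS category.

    Returns a long-format table (metabolite, group, category, median, q25,
    q75, iqr, n); categories with no members are flagged absent via NaN
    cells.
    """
    cats = np.asarray(categories)
    if cats.shape[0] != matrix.n:
        raise ValueError("categories must align with matrix rows")
    w = None if weights is None else np.asarray(weights, dtype=float)
    rows = []
    levels = ("low", "medium", "high") if set(cats) <= {"low", "medium", "high"} else sorted(set(cats))
    for cat in levels:
        mask = cats == cat
        for name in matrix.names:
            rec = {"metabolite": name, "group": matrix.groups[name], "category": cat,
                   "n": int(mask.sum())}
            if mask.sum() == 0:
                rec.update(median=np.nan, q25=np.nan, q75=np.nan, iqr=np.nan)
            else:
                v = matrix.values.loc[mask, name].to_numpy()
                wv = None if w is None else w[mask]
                q25, med, q75 = weighted_quantile(v, [0.25, 0.5, 0.75], wv)
                rec.update(median=med, q25=q25, q75=q75, iqr=q75 - q25)
            rows.append(rec)
    return pd.DataFrame(rows)


def percentile_span(values, weights=None) -> tuple:
    """Weighted 10th and 90th percentiles of a metabolite distribution.

    The span p90 - p10 is the contrast unit for metabolite rate differences
    ("comparing the 90th to the 10th percentiles").  Degenerate (constant)
    input is an error because downstream rescaling divides by the span.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations for a p10-p90 span")
    p10, p90 = weighted_quantile(x, [0.10, 0.90], weights)
    if p90 - p10 <= 0:
        raise ValueError("degenerate metabolite distribution: p90 - p10 is not positive")
    return float(p10), float(p90)
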