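"""Healthy Lifestyle Score (HLS) construction.

The HLS is a 0-5 composite of five binary adherence components:

* diet        -- alternate Mediterranean diet score (aMED, alcohol item
                 excluded, range 0-8) at or above the fixed threshold 5,
                 i.e. the top ~40% of a typical distribution;
* alcohol     -- moderate intake: 5-15 g/day for women, 5-30 g/day for men;
* activity    -- at least 600 MET-minutes/week of moderate-or-vigorous
                 leisure-time physical activity;
* bmi         -- body mass index in the healthy range [18.5, 25.0) kg/m2;
* smoking     -- never smoker.

Totals are categorised as low (0-1), medium (2) and high (3-5) adherence.
Three sensitivity variants are provided: ``a`` keeps the alcohol item inside
the aMED (range 0-9) while retaining the separate alcohol component, ``b``
drops the alcohol component entirely (total range 0-4), and ``c`` also
awards the alcohol point to non-drinkers (0 g/day).

All interval rules are closed ("between 5 and 15 g/day" means [5, 15]);
the BMI upper bound is treated as [18.5, 25.0) so that no value between
24.9 and 25 falls in a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifestyleInputs",
    "HlsResult",
    "energy_inclusion",
    "compute_amed",
    "score_components",
    "score_cohort",
    "hls_category_table",
    "categorize",
    "AMED_HEALTHY_ITEMS",
    "AMED_ADVERSE_ITEMS",
]

VARIANTS = ("main", "a", "b", "c")
SMOKING_LEVELS = ("never", "former", "current")

#: aMED items scored 1 when intake >= cohort median.
AMED_HEALTHY_ITEMS = (
    "vegetables",
    "legumes",
    "fruit",
    "nuts",
    "whole_grains",
    "fish",
    "mufa_sfa_ratio",
)
#: aMED items scored 1 when intake < cohort median (adverse).
AMED_ADVERSE_ITEMS = ("red_processed_meat",)

_ENERGY_RANGE = {"female": (500.0, 3500.0), "male": (800.0, 4000.0)}
_ALCOHOL_RANGE = {"female": (5.0, 15.0), "male": (5.0, 30.0)}
AMED_THRESHOLD = 5
LTPA_THRESHOLD = 600.0
BMI_RANGE = (18.5, 25.0)  # [lo, hi)


@dataclass(frozen=True)
class LifestyleInputs:
    """Per-participant inputs to the five-component score."""

    sex: str                 # "male" | "female"
    energy_intake: float     # kcal/day
    amed: int                # precomputed aMED integer (0-8, or 0-9 under variant a)
    alcohol: float           # g/day
    ltpa: float              # MET-minutes/week, moderate-or-vigorous leisure
    bmi: float               # kg/m2
    smoking: str             # "never" | "former" | "current"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(
                f"smoking must be one of {SMOKING_LEVELS}, got {self.smoking!r}"
            )
        for field in ("energy_intake", "alcohol", "ltpa"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be nonnegative")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")


@dataclass(frozen=True)
class HlsResult:
    """Scored components for one participant."""

    component_points: dict  # name -> 0/1
    total: int
    category: str            # low | medium | high
    amed_used: int
    variant: str

    def __post_init__(self) -> None:
        assert self.total == sum(self.component_points.values())


def energy_inclusion(sex: str, energy_intake: float) -> bool:
    """Inclusion filter on daily energy intake.

    True iff intake lies in [500, 3500] kcal/day for women and
    [800, 4000] kcal/day for men (inclusive bounds).
    """
    if sex not in _ENERGY_RANGE:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    lo, hi = _ENERGY_RANGE[sex]
    return lo <= energy_intake <= hi


def _alcohol_item_point(sex: str, alcohol: float) -> int:
    lo, hi = _ALCOHOL_RANGE[sex]
    return int(lo <= alcohol <= hi)


def compute_amed(
    amed_items: Mapping[str, float],
    cohort_medians: Mapping[str, float],
    exclude_alcohol: bool = True,
    sex: str | None = None,
) -> int:
    """Alternate Mediterranean diet score from item intakes and cohort medians.

    Healthy items score 1 when intake >= the cohort median (values exactly at
    the median count as meeting the cut-off); the adverse red/processed-meat
    item scores 1 when intake < median.  With ``exclude_alcohol`` (the
    default) the result ranges 0-8; otherwise the alcohol item contributes a
    ninth point when intake lies in the sex-specific moderate range, and
    ``sex`` is required.
    """
    needed = list(AMED_HEALTHY_ITEMS) + list(AMED_ADVERSE_ITEMS)
    missing = [k for k in needed if k not in amed_items]
    missing += [k for k in needed if k not in cohort_medians and k in amed_items]
    if missing:
        raise ValueError(f"missing aMED items or medians: {sorted(set(missing))}")
    score = 0
    for item in AMED_HEALTHY_ITEMS:
        score += int(amed_items[item] >= cohort_medians[item])
    for item in AMED_ADVERSE_ITEMS:
        score += int(amed_items[item] < cohort_medians[item])
    if not exclude_alcohol:
        if "alcohol" not in amed_items:
            raise ValueError("missing aMED items or medians: ['alcohol']")
        if sex is None:
            raise ValueError("sex is required to score the aMED alcohol item")
        score += _alcohol_item_point(sex, amed_items["alcohol"])
    return score


def categorize(total: int) -> str:
    """Map an HLS total to the low / medium / high adherence category."""
    if total <= 1:
        return "low"
    if total == 2:
        return "medium"
    return "high"


def score_components(
    inputs: LifestyleInputs,
    amed: int | None = None,
    amed_threshold: int = AMED_THRESHOLD,
    variant: str = "main",
) -> HlsResult:
    """Score the five HLS components for one participant.

    ``amed`` overrides the value carried in ``inputs``; the diet point uses
    the fixed threshold aMED >= 5 by default (``amed_threshold`` exposes the
    empirical top-40% alternative).  The energy-intake inclusion filter is
    assumed to have been applied upstream.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    amed_used = int(inputs.amed if amed is None else amed)
    points: dict[str, int] = {}
    points["diet"] = int(amed_used >= amed_threshold)
    if variant != "b":
        pt = _alcohol_item_point(inputs.sex, inputs.alcohol)
        if variant == "c" and inputs.alcohol == 0:
            pt = 1
        points["alcohol"] = pt
    points["activity"] = int(inputs.ltpa >= LTPA_THRESHOLD)
    points["bmi"] = int(BMI_RANGE[0] <= inputs.bmi < BMI_RANGE[1])
    points["smoking"] = int(inputs.smoking == "never")
    total = sum(points.values())
    return HlsResult(
        component_points=points,
        total=total,
        category=categorize(total),
        amed_used=amed_used,
        variant=variant,
    )


def score_cohort(
    participants: pd.DataFrame,
    variant: str = "main",
    amed_threshold: int = AMED_THRESHOLD,
) -> pd.DataFrame:
    """Vectorised HLS scoring over a participant table.

    Expects columns ``sex`` (male/female), ``amed``, ``alcohol``, ``ltpa``,
    ``bmi``, ``smoking`` (never/former/current).  Returns a frame indexed
    like the input with the five component indicators, ``hls_total`` and
    ``hls_category``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    df = participants
    bad = set(df["smoking"].unique()) - set(SMOKING_LEVELS)
    if bad:
        raise ValueError(f"unknown smoking levels: {sorted(bad)}")
    female = df["sex"].eq("female").to_numpy()
    out = pd.DataFrame(index=df.index)
    out["diet"] = (df["amed"].to_numpy() >= amed_threshold).astype(int)
    if variant != "b":
        alc = df["alcohol"].to_numpy(dtype=float)
        hi = np.where(female, _ALCOHOL_RANGE["female"][1], _ALCOHOL_RANGE["male"][1])
        pt = ((alc >= 5.0) & (alc <= hi)).astype(int)
        if variant == "c":
            pt = np.where(alc == 0.0, 1, pt)
        out["alcohol"] = pt
    out["activity"] = (df["ltpa"].to_numpy(dtype=float) >= LTPA_THRESHOLD).astype(int)
    bmi = df["bmi"].to_numpy(dtype=float)
    out["bmi"] = ((bmi >= BMI_RANGE[0]) & (bmi < BMI_RANGE[1])).astype(int)
    out["smoking"] = df["smoking"].eq("never").astype(int)
    comp_cols = [c for c in ("diet", "alcohol", "activity", "bmi", "smoking") if c in out]
    out["hls_total"] = out[comp_cols].sum(axis=1)
    out["hls_category"] = [categorize(t) for t in out["hls_total"]]
    out["variant"] = variant
    return out


def hls_category_table(
    results: pd.DataFrame | Iterable[HlsResult],
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Counts and (weighted) proportions of participants per HLS category."""
    if isinstance(results, pd.DataFrame):
        cats = results["hls_category"].to_numpy()
    else:
        cats = np.array([r.category for r in results])
    if cats.size == 0:
        raise ValueError("no results to tabulate")
    w = np.ones(cats.size) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for cat in ("low", "medium", "high"):
        mask = cats == cat
        rows.append(
            {"category": cat, "n": int(mask.sum()), "weighted_prop": w[mask].sum() / w.sum()}
        )
    return pd.DataFrame(rows).set_index("category")
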