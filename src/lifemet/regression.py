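"""Survey-weighted linear and Poisson-rate models and the metabolome screen.

Point estimates solve weight-weighted estimating equations (weighted least
squares; weighted Poisson score with a log person-years offset) and
variances are weight-aware sandwich estimators,

    (X' W X)^{-1} [ sum_i w_i^2 s_i s_i' ] (X' W X)^{-1},

which are consistent under independent weighted sampling -- the design the
cohort simulator emulates (no strata or PSUs).  Two-sided p-values use the
normal reference for the sandwich z statistics.

The metabolome-wide screen fits one weighted linear model per metabolite
(metabolite as response, HLS as exposure, plus the Model 1 / Model 2
covariate sets) and controls the false discovery rate at 2.5% with
q-values computed with the pi0 tuning parameter lambda fixed at 0, under
which pi0 = 1 and the q-values coincide with Benjamini-Hochberg step-up
adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CovariateSpec",
    "FitResult",
    "ScreenResult",
    "WeightedLinearModel",
    "WeightedPoissonModel",
    "weighted_lm",
    "weighted_poisson_rate",
    "qvalues",
    "screen_metabolome",
]

M1_TERMS = ["age", "sex", "education"]
M2_TERMS = M1_TERMS + ["hypertension", "total_cholesterol", "lipid_lowering"]


@dataclass(frozen=True)
class CovariateSpec:
    """Adjustment sets: Model 1 (age, sex, education) and Model 2 (Model 1
    plus prevalent hypertension, total plasma cholesterol and
    lipid-lowering medication)."""

    model_id: str = "M2"
    terms: tuple = ()

    def __post_init__(self) -> None:
        if self.model_id not in ("M1", "M2"):
            raise ValueError("model_id must be 'M1' or 'M2'")
        if not self.terms:
            object.__setattr__(
                self, "terms", tuple(M1_TERMS if self.model_id == "M1" else M2_TERMS)
            )

    def design(self, df: pd.DataFrame, extra: list | None = None) -> pd.DataFrame:
        """Design matrix with intercept from a cohort table.

        Categorical sex/education/no-yes columns are accepted either as
        0/1 numerics or as strings and are coerced to indicators.
        """
        cols = {}
        for term in list(self.terms) + list(extra or []):
            s = df[term]
            if s.dtype == object:
                if term == "sex":
                    cols[term] = s.eq("male").astype(float)
                else:
                    uniq = sorted(s.unique())
                    if len(uniq) > 2:
                        raise ValueError(f"cannot code non-binary column {term!r}")
                    cols[term] = s.eq(uniq[-1]).astype(float)
            else:
                cols[term] = s.astype(float)
        X = pd.DataFrame(cols, index=df.index)
        X.insert(0, "const", 1.0)
        return X


@dataclass
class FitResult:
    """A coefficient vector with sandwich covariance and scale metadata."""

    params: pd.Series
    cov: pd.DataFrame
    scale: str  # "identity" (mean differences) or "log" (rate ratios)
    n: int
    weighted_n: float
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = list(self.params.index)
        C = self.cov.to_numpy()
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.names)

    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues())), index=self.names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues(),
                "p": self.pvalues(),
            }
        )
        ci = self.conf_int()
        out["ci_lower"], out["ci_upper"] = ci["lower"], ci["upper"]
        if self.scale == "log":
            out["rate_ratio"] = np.exp(self.params)
            out["rr_lower"] = np.exp(ci["lower"])
            out["rr_upper"] = np.exp(ci["upper"])
        return out


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(A, mode="economic", pivoting=True)
        dropped = [X.columns[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear columns: {dropped}"
        )


class WeightedLinearModel:
    """Survey-weighted linear regression with sandwich variance.

    Thin statsmodels WLS wrapper: the whitened HC0 covariance of WLS equals
    the weight-aware sandwich above.  Estimates are invariant to rescaling
    all weights by a positive constant.
    """

    def __init__(self, endog, exog: pd.DataFrame, weights=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.weights = (
            np.ones(len(self.endog)) if weights is None else np.asarray(weights, float)
        )
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        _check_full_rank(exog)

    def fit(self) -> FitResult:
        res = sm.WLS(self.endog, self.exog, weights=self.weights).fit(cov_type="HC0")
        return FitResult(
            params=res.params,
            cov=pd.DataFrame(
                res.cov_params(), index=self.exog.columns, columns=self.exog.columns
            ),
            scale="identity",
            n=len(self.endog),
            weighted_n=float(self.weights.sum()),
        )


class WeightedPoissonModel:
    """Survey-weighted Poisson rate model with log person-years offset.

    exp(coef) are incidence rate ratios; with no covariates the fitted rate
    equals total events / total person-years exactly.
    """

    def __init__(self, events, person_years, exog: pd.DataFrame, weights=None):
        self.events = np.asarray(events, dtype=float)
        py = np.asarray(person_years, dtype=float)
        if np.any(py <= 0):
            raise ValueError("person-years must be positive")
        if np.any(self.events < 0) or np.any(self.events != np.round(self.events)):
            raise ValueError("events must be nonnegative integers")
        self.offset = np.log(py)
        self.exog = exog
        self.weights = (
            np.ones(len(self.events)) if weights is None else np.asarray(weights, float)
        )
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        _check_full_rank(exog)

    def fit(self, maxiter: int = 100) -> FitResult:
        model = sm.GLM(
            self.events,
            self.exog,
            family=sm.families.Poisson(),
            offset=self.offset,
            var_weights=self.weights,
        )
        res = model.fit(maxiter=maxiter, cov_type="HC0")
        if not res.converged:
            raise RuntimeError(
                f"weighted Poisson IRLS did not converge in {maxiter} iterations; "
                f"deviance trace ends at {res.deviance:.4g}"
            )
        slopes = res.params.to_numpy()[1:] if len(res.params) > 1 else np.zeros(0)
        if slopes.size and np.any(np.abs(slopes) > 15):
            warnings.warn(
                "extreme coefficients suggest separation in the Poisson fit",
                UserWarning,
            )
        return FitResult(
            params=res.params,
            cov=pd.DataFrame(
                res.cov_params(), index=self.exog.columns, columns=self.exog.columns
            ),
            scale="log",
            n=len(self.events),
            weighted_n=float(self.weights.sum()),
        )


def weighted_lm(y, design: pd.DataFrame, weights=None) -> FitResult:
    """Functional form of :class:`WeightedLinearModel`."""
    return WeightedLinearModel(y, design, weights).fit()


def weighted_poisson_rate(events, person_years, design: pd.DataFrame, weights=None) -> FitResult:
    """Functional form of :class:`WeightedPoissonModel` (offset = log person-years)."""
    return WeightedPoissonModel(events, person_years, design, weights).fit()


def qvalues(p, lambda_: float = 0.0) -> np.ndarray:
    """q-values with the pi0 tuning parameter ``lambda_``.

    With lambda = 0 the null-proportion estimate pi0 is 1 and the q-values
    equal Benjamini-Hochberg step-up adjusted p-values: sort p descending,
    take the running minimum of p * m / rank.  For lambda > 0 pi0 is the
    Storey estimate #{p > lambda} / (m (1 - lambda)), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must lie in [0, 1)")
    m = p.size
    pi0 = 1.0 if lambda_ == 0 else min(1.0, np.mean(p > lambda_) / (1 - lambda_))
    order = np.argsort(p, kind="stable")[::-1]  # descending p
    ranks = np.arange(m, 0, -1)  # m, m-1, ..., 1
    q_sorted = np.minimum.accumulate(pi0 * p[order] * m / ranks)
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ScreenResult:
    """One metabolite's row of the metabolome-wide screen."""

    metabolite: str
    group: str
    md: float          # mean difference per 1-point HLS, metabolite units
    ci: tuple
    p: float
    q: float = np.nan
    selected: bool = False
    model_id: str = "M2"
    error: str | None = None


def screen_metabolome(
    matrix,
    hls_total,
    covariates: CovariateSpec,
    cohort: pd.DataFrame,
    weights=None,
    fdr: float = 0.025,
    standardize: bool = False,
) -> pd.DataFrame:
    """Metabolome-wide association screen of the HLS.

    One weighted linear model per metabolite (response = fasting-adjusted
    concentration, optionally z-scored; exposure = HLS total; adjustment =
    ``covariates``), sandwich p-values, q-values at lambda = 0 and selection
    at q <= ``fdr``.  Per-metabolite failures are recorded, not raised.
    """
    if not matrix.fasting_adjusted:
        raise ValueError("screen requires a fasting-adjusted metabolite matrix")
    hls = np.asarray(hls_total, dtype=float)
    base = covariates.design(cohort)
    X = base.copy()
    X.insert(1, "hls", hls)
    results: list[ScreenResult] = []
    for name in matrix.names:
        y = matrix.values[name].to_numpy(dtype=float)
        if standardize:
            sd = y.std(ddof=1)
            if sd > 0:
                y = (y - y.mean()) / sd
        try:
            fit = weighted_lm(y, X, weights)
            ci = fit.conf_int().loc["hls"]
            results.append(
                ScreenResult(
                    metabolite=name,
                    group=matrix.groups[name],
                    md=float(fit.params["hls"]),
                    ci=(float(ci["lower"]), float(ci["upper"])),
                    p=float(fit.pvalues()["hls"]),
                    model_id=covariates.model_id,
                )
            )
        except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
            results.append(
                ScreenResult(
                    metabolite=name,
                    group=matrix.groups[name],
                    md=np.nan,
                    ci=(np.nan, np.nan),
                    p=np.nan,
                    model_id=covariates.model_id,
                    error=str(exc),
                )
            )
    ok = [r for r in results if r.error is None]
    if ok:
        q = qvalues(np.array([r.p for r in ok]))
        for r, qi in zip(ok, q):
            r.q = float(qi)
            r.selected = bool(qi <= fdr)
    out = pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "group": [r.group for r in results],
            "md": [r.md for r in results],
            "ci_lower": [r.ci[0] for r in results],
            "ci_upper": [r.ci[1] for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "selected": [r.selected for r in results],
            "model_id": [r.model_id for r in results],
            "error": [r.error for r in results],
        }
    )
    return out
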