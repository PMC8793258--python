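"""Probit Bayesian kernel machine regression (BKMR-P) with spike-slab
variable selection.

Model: for subject i with binary outcome y_i, metabolite row z_i and
confounders x_i,

    y_i = 1( z*_i > 0 ),     z* ~ N( h + X beta, I_n ),
    h ~ GP(0, lambda * K_r),   K_r[i,j] = exp( - sum_m r_m (z_im - z_jm)^2 ),

with spike-slab relevance parameters: delta_m ~ Bernoulli(pi) and, given
delta_m = 1, a Gamma(2, r_slab_scale) slab on r_m (hard-capped at r_max);
the effective kernel uses delta_m * r_m.  lambda (the GP variance scale)
has a Gamma prior and beta a flat prior.  The slab's shape matters: as
r_m grows the kernel tends to the identity and an active component
degenerates into a pure variance inflation that the likelihood cannot tell
from noise (the probit latent scale is unidentified), while as r_m -> 0 it
degenerates into a shared intercept; the Gamma(2, .) slab keeps prior mass
where a component must express itself as correlation structure, without
which every inclusion probability would sit at its prior.

Inference is Gibbs sampling on the *marginalised* model: h is integrated
out, so z* ~ N(X beta, V) with V = I + lambda K, and the sampler
alternates (i) coordinate-wise truncated-normal updates of z* (Albert-Chib
augmentation, numba-compiled), (ii) a conjugate GLS draw of beta, (iii) a
log-random-walk Metropolis step on lambda, and (iv) one Metropolis
birth/death/jitter move on a randomly chosen (delta_m, r_m) pair per
iteration.  The GP surface h is drawn from its Gaussian conditional only
when response summaries are requested.  When no component is active the
kernel term vanishes (h = 0) and the sampler is exactly Bayesian probit
regression on X.

The posterior inclusion probability (PIP) of metabolite m is the posterior
mean of delta_m; metabolites with PIP above 0.20 are flagged as relevant.

For the incident-diabetes setting the binary indicator over the
administratively censored follow-up window is modelled directly; follow-up
time must not be entered as a covariate, because under administrative
censoring the event time is part of the outcome and a time covariate
quasi-separates the probit fit (see the methods note on person-time
handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.linalg.lapack import dpotri
from scipy.spatial.distance import cdist

from ._truncnorm import kernel_update, probit_latent_sweep, symmetrize_lower

__all__ = [
    "BkmrPriors",
    "McmcControls",
    "ProbitKernelMachine",
    "KernelMachinePosterior",
    "gaussian_kernel",
]

PIP_THRESHOLD = 0.20


def _inv_from_chol(c, low) -> np.ndarray:
    """Symmetric inverse from a Cholesky factor via LAPACK dpotri."""
    inv, info = dpotri(c, lower=low)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    if low:
        return symmetrize_lower(np.ascontiguousarray(inv))
    return np.triu(inv) + np.triu(inv, 1).T


def gaussian_kernel(Z, r) -> np.ndarray:
    """Gaussian kernel K_ij = exp(-sum_m r_m (z_im - z_jm)^2).

    r = 0 gives the all-ones matrix; r_m -> inf drives K to the identity
    for rows distinct in metabolite m.
    """
    Z = np.asarray(Z, dtype=float)
    r = np.asarray(r, dtype=float)
    if r.shape != (Z.shape[1],):
        raise ValueError(f"r has length {r.shape}, expected ({Z.shape[1]},)")
    if np.any(r < 0):
        raise ValueError("kernel relevance parameters must be nonnegative")
    active = r > 0
    if not active.any():
        return np.ones((Z.shape[0], Z.shape[0]))
    E = Z[:, active] * np.sqrt(r[active])
    D = cdist(E, E, metric="sqeuclidean")
    return np.exp(-D)


def _cross_kernel(Z1, Z2, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    active = r > 0
    if not active.any():
        return np.ones((Z1.shape[0], Z2.shape[0]))
    E1 = Z1[:, active] * np.sqrt(r[active])
    E2 = Z2[:, active] * np.sqrt(r[active])
    return np.exp(-cdist(E1, E2, metric="sqeuclidean"))


@dataclass(frozen=True)
class BkmrPriors:
    """Priors for the spike-slab kernel machine.

    r_slab_scale: scale of the Gamma(2, r_slab_scale) slab on active
        relevances r_m.  The shape-2 rise suppresses the tiny-r regime
        (where an active component is indistinguishable from a shared
        intercept) and the decay penalises the large-r regime (where the
        kernel degenerates to the identity and a component is a pure
        variance inflation); both regimes would otherwise pin inclusion
        probabilities at their prior.
    r_max: hard numerical cap on r_m.
    inclusion_prior: Bernoulli probability pi of delta_m = 1.
    lambda_shape/lambda_scale: Gamma prior on the GP variance scale.
    """

    r_slab_scale: float = 0.05
    r_max: float = 10.0
    inclusion_prior: float = 0.25
    lambda_shape: float = 1.0
    lambda_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclusion_prior <= 1.0:
            raise ValueError("inclusion_prior must lie in [0, 1]")
        if min(self.r_max, self.r_slab_scale, self.lambda_shape, self.lambda_scale) <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class McmcControls:
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    r_proposal_sd: float = 0.6   # log-random-walk sd for active r_m
    r_birth_scale: float = 0.05  # gamma proposal scale for newborn r_m
    lambda_proposal_sd: float = 0.5
    n_component_moves: int = 1   # spike-slab moves per iteration

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


class _ChainState:
    __slots__ = ("z", "beta", "lam", "r", "delta", "chol", "K", "logdet")


class ProbitKernelMachine:
    """Spike-slab probit kernel machine regression model.

    Parameters
    ----------
    y : binary outcome vector.
    Z : n x M exposure matrix (columns are standardized internally).
    X : confounder design; a constant column is appended when absent.
    priors, mcmc : hyperparameters and chain controls.
    """

    def __init__(
        self,
        y,
        Z,
        X=None,
        priors: BkmrPriors | None = None,
        mcmc: McmcControls | None = None,
    ):
        self.y = np.asarray(y, dtype=np.int64)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")
        Zdf = pd.DataFrame(Z) if not isinstance(Z, pd.DataFrame) else Z
        self.exposure_names = [str(c) for c in Zdf.columns]
        Zin = Zdf.to_numpy(dtype=float)
        if Zin.shape[0] != self.y.shape[0]:
            raise ValueError("Z rows must match y")
        sd = Zin.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant exposure columns cannot be standardized")
        self._z_mean, self._z_sd = Zin.mean(axis=0), sd
        self.Z = (Zin - self._z_mean) / self._z_sd
        if X is None:
            self.X = np.ones((len(self.y), 1))
            self.confounder_names = ["const"]
        else:
            Xdf = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
            A = Xdf.to_numpy(dtype=float)
            names = [str(c) for c in Xdf.columns]
            if not np.any(np.all(A == A[0, :], axis=0)):
                A = np.column_stack([np.ones(len(A)), A])
                names = ["const"] + names
            self.X = A
            self.confounder_names = names
        self.priors = priors or BkmrPriors()
        self.mcmc = mcmc or McmcControls()
        self.n, self.M = self.Z.shape
        # cache per-metabolite squared-distance matrices when affordable
        if self.n * self.n * self.M <= 40_000_000:
            self._D = np.stack(
                [(self.Z[:, j, None] - self.Z[None, :, j]) ** 2 for j in range(self.M)]
            )
        else:
            self._D = None
        self._eye = np.eye(self.n)

    # --- covariance bookkeeping ---------------------------------------

    def _kernel(self, r_eff) -> np.ndarray:
        """Gaussian kernel for the active relevances, using the cached
        distance stack when available."""
        active = np.flatnonzero(r_eff > 0)
        if self._D is not None and active.size:
            return np.exp(-np.tensordot(r_eff[active], self._D[active], axes=1))
        return gaussian_kernel(self.Z, r_eff)

    def _refresh(self, st: _ChainState) -> None:
        """Recompute K/chol/logdet of V = I + lambda K for the current
        state; ``chol`` and ``K`` are None when no component is active."""
        r_eff = st.r * st.delta
        if not np.any(r_eff > 0):
            st.chol, st.K, st.logdet = None, None, 0.0
            return
        st.K = self._kernel(r_eff)
        V = st.lam * st.K
        V[np.diag_indices_from(V)] += 1.0
        c, low = cho_factor(V, lower=True, check_finite=False)
        st.chol = (c, low)
        st.logdet = 2.0 * np.sum(np.log(np.diag(c)))

    def _loglik_K(self, resid, lam, K) -> tuple:
        """Marginal log-likelihood given a precomputed kernel matrix;
        the Cholesky factor is None for the identity covariance (K None)."""
        if K is None:
            return -0.5 * float(resid @ resid), None, 0.0
        V = lam * K
        V[np.diag_indices_from(V)] += 1.0
        try:
            c, low = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        quad = resid @ cho_solve((c, low), resid, check_finite=False)
        return -0.5 * (logdet + quad), (c, low), logdet

    def _updated_kernel(self, st, m, r_new):
        """Kernel after setting component m's relevance to r_new."""
        r_prop = st.r * st.delta
        dr = r_new - r_prop[m]
        r_prop[m] = r_new
        if not np.any(r_prop > 0):
            return None, r_prop
        if self._D is not None:
            base = st.K if st.K is not None else np.ones((self.n, self.n))
            return kernel_update(base, self._D[m], dr), r_prop
        return self._kernel(r_prop), r_prop

    def _quad(self, st, resid) -> float:
        if st.chol is None:
            return float(resid @ resid)
        return float(resid @ cho_solve(st.chol, resid, check_finite=False))

    def _component_move(self, st, m, r_eff, ll_cur, resid, rng) -> bool:
        """One Metropolis birth/death/jitter move on (delta_m, r_m).

        Birth proposals draw r' ~ Exp(r_birth_scale); the acceptance ratio
        carries the spike-slab prior (Bernoulli(pi) x Uniform(0, r_max)),
        the proposal density, and the birth/death move-probability
        asymmetry (birth proposed w.p. 1 from inactive, death w.p. 0.5
        from active).  Jitter moves are log random walks whose uniform
        slab prior cancels, leaving the Jacobian r'/r.
        """
        pr, mc, n = self.priors, self.mcmc, self.n

        def log_slab(r):
            # Gamma(2, r_slab_scale) slab density (hard cap at r_max
            # ignored in the normalisation; its mass there is negligible)
            return np.log(r) - r / pr.r_slab_scale - 2.0 * np.log(pr.r_slab_scale)

        def log_g(r):
            # birth proposal: 0.5 Gamma(2, r_birth_scale) + 0.5 U(0, r_max);
            # the uniform leg keeps death moves reversible from any active r
            return np.logaddexp(
                np.log(0.5) + np.log(r) - r / mc.r_birth_scale
                - 2.0 * np.log(mc.r_birth_scale),
                np.log(0.5) - np.log(pr.r_max),
            )

        if st.delta[m] == 0:
            if pr.inclusion_prior <= 0:
                return False
            if rng.random() < 0.5:
                r_new = rng.gamma(2.0, mc.r_birth_scale)
            else:
                r_new = rng.uniform(0.0, pr.r_max)
            if r_new >= pr.r_max:
                return False
            K_prop, _ = self._updated_kernel(st, m, r_new)
            ll_prop, chol_prop, logdet_prop = self._loglik_K(resid, st.lam, K_prop)
            log_prior = (
                np.log(pr.inclusion_prior)
                - np.log(1 - pr.inclusion_prior + 1e-300)
                + log_slab(r_new)
            )
            logr = ll_prop - ll_cur + log_prior - log_g(r_new) + np.log(0.5)
            if np.log(rng.random()) < logr:
                st.delta[m], st.r[m] = 1.0, r_new
                st.chol, st.K, st.logdet = chol_prop, K_prop, logdet_prop
                return True
            return False
        if rng.random() < 0.5:
            # death
            K_prop, r_prop = self._updated_kernel(st, m, 0.0)
            ll_prop, chol_prop, logdet_prop = self._loglik_K(resid, st.lam, K_prop)
            r_old = st.r[m]
            log_prior = (
                np.log(1 - pr.inclusion_prior + 1e-300)
                - np.log(pr.inclusion_prior + 1e-300)
                - log_slab(r_old)
            )
            logr = ll_prop - ll_cur + log_prior + log_g(r_old) + np.log(2.0)
            if np.log(rng.random()) < logr:
                st.delta[m], st.r[m] = 0.0, 0.0
                st.chol, st.K, st.logdet = chol_prop, K_prop, logdet_prop
                return True
            return False
        # jitter
        r_new = st.r[m] * np.exp(mc.r_proposal_sd * rng.normal())
        if r_new >= pr.r_max:
            return False
        K_prop, _ = self._updated_kernel(st, m, r_new)
        ll_prop, chol_prop, logdet_prop = self._loglik_K(resid, st.lam, K_prop)
        # slab prior ratio + log-RW Jacobian r'/r
        logr = (
            ll_prop - ll_cur
            + log_slab(r_new) - log_slab(st.r[m])
            + np.log(r_new / st.r[m])
        )
        if np.log(rng.random()) < logr:
            st.r[m] = r_new
            st.chol, st.K, st.logdet = chol_prop, K_prop, logdet_prop
            return True
        return False

    # --- sampler -------------------------------------------------------

    def fit(self, progress: bool = False) -> "KernelMachinePosterior":
        pr, mc = self.priors, self.mcmc
        rng = np.random.default_rng(mc.seed)
        n, M, p = self.n, self.M, self.X.shape[1]

        st = _ChainState()
        st.z = np.where(self.y == 1, 0.5, -0.5).astype(float)
        st.beta = np.zeros(p)
        st.lam = 1.0
        st.r = np.zeros(M)
        st.delta = np.zeros(M)
        self._refresh(st)

        keep = (mc.n_iter - mc.burn_in) // mc.thin
        draws = {
            "delta": np.empty((keep, M)),
            "r": np.empty((keep, M)),
            "lam": np.empty(keep),
            "beta": np.empty((keep, p)),
            "zstar": np.empty((keep, n)),
        }
        comp_props = comp_accepts = 0
        k = 0
        Q = self._eye
        q_fresh = False  # Q matches st.chol
        for it in range(mc.n_iter):
            resid = st.z - self.X @ st.beta
            r_eff = st.r * st.delta
            # (i) GP variance scale lambda
            if np.any(r_eff > 0):
                ll_cur = -0.5 * (st.logdet + self._quad(st, resid))
                lam_prop = st.lam * np.exp(mc.lambda_proposal_sd * rng.normal())
                ll_prop, chol_prop, logdet_prop = self._loglik_K(resid, lam_prop, st.K)
                logr = (
                    ll_prop
                    - ll_cur
                    + pr.lambda_shape * np.log(lam_prop / st.lam)  # prior + Jacobian
                    - (lam_prop - st.lam) / pr.lambda_scale
                )
                if np.log(rng.random()) < logr:
                    st.lam = lam_prop
                    st.chol, st.logdet = chol_prop, logdet_prop
                    q_fresh = False
            else:
                # conditional is the prior when the kernel is inactive
                st.lam = rng.gamma(pr.lambda_shape, pr.lambda_scale)
            # (ii) spike-slab component moves on random (delta_m, r_m) pairs
            for _ in range(mc.n_component_moves):
                m = int(rng.integers(M))
                comp_props += 1
                r_eff = st.r * st.delta
                ll_cur = -0.5 * (st.logdet + self._quad(st, resid))
                if self._component_move(st, m, r_eff, ll_cur, resid, rng):
                    comp_accepts += 1
                    q_fresh = False
            # one precision-matrix refresh serves the latent sweep and beta,
            # and is skipped entirely when no move changed the covariance
            if not q_fresh:
                Q = self._eye if st.chol is None else _inv_from_chol(*st.chol)
                q_fresh = True
            # (iii) latent probit variables
            mu = self.X @ st.beta
            u = rng.random(n)
            probit_latent_sweep(st.z, mu, Q, self.y, u)
            if not np.isfinite(st.z).all():
                raise FloatingPointError(f"nonfinite latent value at iteration {it}")
            # (iv) confounder coefficients: GLS draw (flat prior)
            XtQ = self.X.T if st.chol is None else self.X.T @ Q
            A = XtQ @ self.X
            Ainv = np.linalg.inv(A)
            bmean = Ainv @ (XtQ @ st.z)
            st.beta = bmean + cholesky(Ainv, lower=True) @ rng.normal(size=p)

            if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0 and k < keep:
                draws["delta"][k] = st.delta
                draws["r"][k] = st.r
                draws["lam"][k] = st.lam
                draws["beta"][k] = st.beta
                draws["zstar"][k] = st.z
                k += 1

        acc_rate = comp_accepts / max(comp_props, 1)
        if not 0.1 <= acc_rate <= 0.6:
            warnings.warn(
                f"component-move acceptance rate {acc_rate:.2f} outside [0.1, 0.6]; "
                "consider adjusting proposal scales",
                UserWarning,
            )
        return KernelMachinePosterior(self, draws, acc_rate)


class KernelMachinePosterior:
    """Retained MCMC draws and posterior summaries."""

    def __init__(self, model: ProbitKernelMachine, draws: dict, acceptance_rate: float):
        self.model = model
        self.draws = draws
        self.acceptance_rate = acceptance_rate
        self.n_draws = draws["lam"].shape[0]

    def pips(self, threshold: float = PIP_THRESHOLD) -> pd.DataFrame:
        """Posterior inclusion probabilities with a relevance flag."""
        pip = self.draws["delta"].mean(axis=0)
        return pd.DataFrame(
            {
                "metabolite": self.model.exposure_names,
                "pip": pip,
                "relevant": pip > threshold,
            }
        )

    def _predict_h(self, Znew_std: np.ndarray, idx: int, rng) -> np.ndarray:
        """Draw h at new standardized points for retained draw ``idx``."""
        m = self.model
        r_eff = self.draws["r"][idx] * self.draws["delta"][idx]
        lam = self.draws["lam"][idx]
        beta = self.draws["beta"][idx]
        z = self.draws["zstar"][idx]
        if not np.any(r_eff > 0):
            return np.zeros(Znew_std.shape[0])
        V = lam * gaussian_kernel(m.Z, r_eff)
        V[np.diag_indices_from(V)] += 1.0
        cf = cho_factor(V, lower=True)
        Kx = lam * _cross_kernel(Znew_std, m.Z, r_eff)
        resid = z - m.X @ beta
        mean = Kx @ cho_solve(cf, resid)
        Kxx = lam * gaussian_kernel(Znew_std, r_eff * 1.0)
        cov = Kxx - Kx @ cho_solve(cf, Kx.T)
        cov = (cov + cov.T) / 2
        # numerically guard the predictive covariance
        ev_min = np.linalg.eigvalsh(cov).min()
        if ev_min < -1e-6:
            raise np.linalg.LinAlgError("predictive covariance not PSD")
        jitter = max(0.0, -ev_min) + 1e-10
        L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        return mean + L @ rng.normal(size=cov.shape[0])

    def _std(self, Znew: np.ndarray) -> np.ndarray:
        m = self.model
        return (np.asarray(Znew, float) - m._z_mean) / m._z_sd

    def overall_risk(
        self,
        quantiles=(0.25, 0.35, 0.45, 0.5, 0.55, 0.65, 0.75),
        n_samples: int = 100,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Posterior h contrast: all exposures at a quantile vs all at the
        median.  The contrast at the median is identically zero."""
        qs = np.asarray(quantiles, dtype=float)
        if np.any((qs <= 0) | (qs >= 1)):
            raise ValueError("quantiles must lie strictly in (0, 1)")
        m = self.model
        Zraw = m.Z * m._z_sd + m._z_mean
        pts = np.stack(
            [np.quantile(Zraw, q, axis=0) for q in qs] + [np.quantile(Zraw, 0.5, axis=0)]
        )
        pts_std = self._std(pts)
        rng = np.random.default_rng(seed)
        idxs = np.linspace(0, self.n_draws - 1, min(n_samples, self.n_draws)).astype(int)
        contrasts = np.empty((idxs.size, qs.size))
        for row, i in enumerate(idxs):
            h = self._predict_h(pts_std, i, rng)
            contrasts[row] = h[:-1] - h[-1]
        med_mask = qs == 0.5
        contrasts[:, med_mask] = 0.0  # exact self-contrast
        lo, hi = np.quantile(contrasts, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "quantile": qs,
                "contrast": contrasts.mean(axis=0),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )

    def univariate_response(
        self,
        metabolite,
        grid=None,
        n_samples: int = 100,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Exposure-response curve for one metabolite, the others held at
        their medians."""
        m = self.model
        if isinstance(metabolite, str):
            j = m.exposure_names.index(metabolite)
        else:
            j = int(metabolite)
        Zraw = m.Z * m._z_sd + m._z_mean
        if grid is None:
            grid = np.linspace(
                np.quantile(Zraw[:, j], 0.05), np.quantile(Zraw[:, j], 0.95), 11
            )
        grid = np.asarray(grid, dtype=float)
        if grid.min() < Zraw[:, j].min() or grid.max() > Zraw[:, j].max():
            warnings.warn("grid extends beyond the observed exposure range", UserWarning)
        pts = np.tile(np.quantile(Zraw, 0.5, axis=0), (grid.size, 1))
        pts[:, j] = grid
        pts_std = self._std(pts)
        rng = np.random.default_rng(seed)
        idxs = np.linspace(0, self.n_draws - 1, min(n_samples, self.n_draws)).astype(int)
        curves = np.empty((idxs.size, grid.size))
        for row, i in enumerate(idxs):
            curves[row] = self._predict_h(pts_std, i, rng)
        lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "grid": grid,
                "h_mean": curves.mean(axis=0),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )

    def summary(self) -> pd.DataFrame:
        tab = self.pips()
        tab["r_mean_active"] = [
            self.draws["r"][self.draws["delta"][:, j] == 1, j].mean()
            if (self.draws["delta"][:, j] == 1).any()
            else np.nan
            for j in range(self.model.M)
        ]
        return tab

    def plot_pips(self, ax=None, threshold: float = PIP_THRESHOLD):
        import matplotlib.pyplot as plt

        tab = self.pips(threshold)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(tab))))
        ax.barh(tab["metabolite"], tab["pip"])
        ax.axvline(threshold, ls="--", color="grey")
        ax.set_xlabel("posterior inclusion probability")
        return ax
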