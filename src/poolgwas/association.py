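"""Per-variant weighted mixed-effects logistic association scan.

For each variant the model is

    logit P(T2D) = b0 + bs*BAF + b1*HT + b2*COB + b3*DYL
                   + bb*BAT + br*REP + bk*PHI + u_pool,
    u_pool ~ N(0, tau^2),

fitted to the pool-replicate measurement units with frequency weights equal
to each pool's member count (each unit's log-likelihood contribution is
multiplied by n).

Two inference methods are provided.

``method="score"`` (default, used for genome scans): the statistic is a
sandwich Wald-type test built around the model's score for bs. The null
(no-BAF) model is fitted by ridge-stabilized weighted logistic regression
(a weakly-informative penalty of one prior SD per standardized covariate,
which prevents quasi-separation of the ~14 pool outcomes); the score is
U = sum_u r_u * BAF_u with r = w*(y - mu^). Its variance is computed from
the pooled-measurement model rather than from the outcome likelihood:

    Var(U) = p^(1-p^) * R' C R + sum_u r_u^2 * v_rep(p^),

where R is the pool-summed contrast and C the kinship-derived covariance
coefficient matrix of pool allele frequencies (diagonal: binomial sampling
of n_g relatives, (1 + 2(n_g-1) phi_g)/(2 n_g); off-diagonal: relatives
split across pools), and v_rep(p) = a + b*p(1-p) is the replicate-level
pooling + array variance fitted from duplicate measurements
(MacGregor-style). T = U / sqrt(Var U) is referred
to the standard normal; the reported slope is the one-step estimate
beta = U / I with I the model information, and SE = sqrt(Var U) / I so that
beta/SE = T. The rationale: across variants the outcome vector is fixed —
the only randomness is in the measured BAF — so an outcome-likelihood SE is
structurally miscalibrated for a scan, while the measurement-model variance
calibrates it by construction.

``method="wald"``: full per-variant maximum likelihood. For a given tau^2
the joint penalized log-likelihood is maximized over (beta, u) by
Newton–Raphson (tau^2 = 0 reduces exactly to plain weighted logistic
regression); tau^2 may be fixed or profiled over the Laplace-approximated
marginal likelihood

    l_p(tau^2) = l_joint(beta^, u^) - 1/2 * sum_g log(1 + tau^2 * H_g)

on a log-spaced grid with parabolic refinement. Note that for pool-constant
outcomes with large frequency weights each pool's weighted Bernoulli
likelihood is all-or-nothing, so this marginal likelihood is typically
monotone in tau^2 and the profile estimate escapes to the grid edge; the
Wald mode is intended for small fixtures, oracle checks and data with
within-pool outcome variation, not for calibrated genome scans.

The scan also reports a pool-level overdispersion moment estimate of tau^2
(the excess of squared latent pool residuals over their binomial sampling
term, with a degrees-of-freedom correction) as a diagnostic.

All per-variant quantities are computed batched over variants (vectorized
Newton with a Schur complement on the block-diagonal random-effect block),
so genome-scale scans are array operations, not Python loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import ConfigError, InputError
from .pooling import PoolBAFMatrix

#: Median of the chi-square distribution with 1 df (lambda denominator).
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_AUTOSOMES = {str(c) for c in range(1, 23)}


# ---------------------------------------------------------------------------
# Panel filtering and scan-level constants
# ---------------------------------------------------------------------------

def filter_panel(panel: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep autosomal (1–22) variants with MAF >= 1%.

    The MAF filter is strict at the boundary: exactly 1% is retained, only
    MAF < 0.01 is excluded. Returns the filtered panel and a tally of
    exclusions per criterion.
    """
    chrom = panel["chrom"].astype(str).str.replace("^chr", "", regex=True)
    autosomal = chrom.isin(_AUTOSOMES).to_numpy()
    low_maf = (panel["maf"].to_numpy() < 0.01) & autosomal
    keep = autosomal & ~low_maf
    tally = {
        "input": len(panel),
        "non_autosomal": int((~autosomal).sum()),
        "low_maf": int(low_maf.sum()),
        "retained": int(keep.sum()),
    }
    if tally["retained"] == 0:
        warnings.warn("panel filter retained no variants", stacklevel=2)
    return panel.loc[keep].reset_index(drop=True), tally


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    return alpha / m


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi2(1) over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 2:
        raise InputError("genomic inflation needs at least 2 p-values")
    if ((p <= 0) | (p > 1)).any():
        raise InputError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values: lambda is unstable", stacklevel=2)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


# ---------------------------------------------------------------------------
# Model specification and records
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed-effect layout and fitting options for the per-variant model.

    ``covariates`` are unit-table columns entering as numeric fixed effects;
    ``factors`` enter as drop-first indicator sets. ``method`` is "score"
    (sandwich score test, default) or "wald" (full per-variant ML). For the
    Wald method ``tau2`` is "profile" or a fixed non-negative float.
    ``reference`` selects the null distribution ("normal" or "t").
    ``ridge`` scales the stabilizing penalty of the score method's null fit
    (prior precision per squared standardized-covariate unit)."""

    covariates: tuple[str, ...] = ("HT_prop", "COB_prop", "DL_prop", "phi")
    factors: tuple[str, ...] = ("chip", "replicate")
    weight_column: str = "n"
    method: str = "score"
    tau2: object = "profile"
    reference: str = "normal"
    ridge: float = 1.0
    tau2_grid: np.ndarray | None = None
    max_iter: int = 50
    gtol: float = 1e-8

    def grid(self) -> np.ndarray:
        if self.tau2_grid is not None:
            return np.asarray(self.tau2_grid, dtype=float)
        return np.concatenate([[0.0], np.logspace(-2, 2, 13)])


@dataclass
class AssociationRecord:
    variant: str
    beta: float
    se: float
    stat: float
    p: float
    tau2: float
    converged: bool
    aliased: bool


@dataclass
class GwasSummary:
    """Scan-level summary: multiplicity, inflation, significance set."""

    m: int
    alpha: float
    alpha_star: float
    significant: list = field(default_factory=list)
    lambda_gc: float = float("nan")
    pooling_error: dict | None = None
    n_converged: int = 0
    tau2_null: float = float("nan")
    dropped_columns: tuple = ()


# ---------------------------------------------------------------------------
# Batched penalized Newton machinery
# ---------------------------------------------------------------------------

def _joint_pll(X, y, w, P, inv_tau2, beta, b, pen=None):
    """Penalized joint log-likelihood and linear predictor, per variant."""
    eta = np.einsum("mup,mp->mu", X, beta) + b @ P.T
    ll = (w * (y * eta - np.logaddexp(0.0, eta))).sum(axis=1)
    inv_safe = np.where(np.isinf(inv_tau2), 0.0, inv_tau2)  # b is 0 where tau2 is 0
    out = ll - 0.5 * (b**2 * inv_safe[:, None]).sum(axis=1)
    if pen is not None:
        out = out - 0.5 * (pen * beta**2).sum(axis=1)
    return out, eta


def _newton(X, y, w, P, inv_tau2, beta, b, max_iter=50, gtol=1e-8, ridge=1e-8, pen=None):
    """Maximize the joint penalized log-likelihood for every variant.

    ``inv_tau2 = inf`` rows have the random effect pinned at zero (the plain
    weighted-logistic boundary). ``pen`` is an optional per-coefficient
    ridge (used by the score method's null fit only). Returns updated
    (beta, b), the linear predictor, a converged flag and the penalized
    log-likelihood.
    """
    M, U, p = X.shape
    eye = np.eye(p)
    pen_vec = np.zeros(p) if pen is None else np.asarray(pen, dtype=float)
    inv_safe = np.where(np.isinf(inv_tau2), 0.0, inv_tau2)
    pll, eta = _joint_pll(X, y, w, P, inv_tau2, beta, b, pen)
    converged = np.zeros(M, dtype=bool)
    stalled = np.zeros(M, dtype=bool)
    for _ in range(max_iter):
        mu = expit(eta)
        Wd = w * mu * (1.0 - mu)
        r = w * (y - mu)
        gbeta = np.einsum("mu,mup->mp", r, X) - pen_vec * beta
        gb = r @ P - b * inv_safe[:, None]
        gb_eff = np.where(np.isinf(inv_tau2)[:, None], 0.0, gb)
        gmax = np.maximum(np.abs(gbeta).max(axis=1), np.abs(gb_eff).max(axis=1))
        converged |= gmax < gtol
        active = ~(converged | stalled)
        if not active.any():
            break
        ia = np.flatnonzero(active)
        Xa, Wa = X[ia], Wd[ia]
        A = np.einsum("mui,mu,muj->mij", Xa, Wa, Xa) + np.diag(pen_vec)
        Bm = np.einsum("mui,mu,ug->mig", Xa, Wa, P)
        D = Wa @ P + inv_tau2[ia, None]
        invD = np.where(np.isinf(D), 0.0, 1.0 / D)
        BD = Bm * invD[:, None, :]
        S = A - BD @ Bm.transpose(0, 2, 1) + ridge * eye
        rhs = gbeta[ia] - np.einsum("mig,mg->mi", BD, gb[ia])
        try:
            dbeta = np.linalg.solve(S, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            dbeta = np.linalg.solve(S + 1e-4 * eye, rhs[:, :, None])[:, :, 0]
        db = invD * (gb[ia] - np.einsum("mig,mi->mg", Bm, dbeta))
        step = np.ones(len(ia))
        pll_old = pll[ia]
        pll_new, eta_new, nb, nbb = pll_old, eta[ia], beta[ia], b[ia]
        for _half in range(30):
            nb = beta[ia] + step[:, None] * dbeta
            nbb = b[ia] + step[:, None] * db
            pll_new, eta_new = _joint_pll(X[ia], y, w, P, inv_tau2[ia], nb, nbb, pen)
            ok = pll_new >= pll_old - 1e-10 * (1.0 + np.abs(pll_old))
            if ok.all():
                break
            step = np.where(ok, step, step / 2.0)
            if (step < 1e-8).all():
                break
        accept = pll_new >= pll_old - 1e-10 * (1.0 + np.abs(pll_old))
        beta[ia[accept]] = nb[accept]
        b[ia[accept]] = nbb[accept]
        pll[ia[accept]] = pll_new[accept]
        eta[ia[accept]] = eta_new[accept]
        stalled[ia[~accept]] = True
    return beta, b, eta, converged, pll


def _laplace_profile(eta, y, w, P, inv_tau2, pll):
    """Laplace marginal log-likelihood given the joint mode."""
    mu = expit(eta)
    H = (w * mu * (1.0 - mu)) @ P
    tau2 = np.where(np.isinf(inv_tau2), 0.0, 1.0 / np.where(inv_tau2 == 0, np.inf, inv_tau2))
    logdet = 0.5 * np.log1p(tau2[:, None] * H).sum(axis=1)
    return pll - logdet


def _beta_covariance(X, eta, w, P, inv_tau2, ridge=1e-12):
    """Beta-block of the inverse joint Hessian (conditional Wald covariance)."""
    M, U, p = X.shape
    mu = expit(eta)
    Wd = w * mu * (1.0 - mu)
    A = np.einsum("mui,mu,muj->mij", X, Wd, X)
    Bm = np.einsum("mui,mu,ug->mig", X, Wd, P)
    D = Wd @ P + inv_tau2[:, None]
    invD = np.where(np.isinf(D), 0.0, 1.0 / D)
    S = A - (Bm * invD[:, None, :]) @ Bm.transpose(0, 2, 1) + ridge * np.eye(p)
    return np.linalg.inv(S)


def _replicate_variance(baf: np.ndarray, units: pd.DataFrame, pq: np.ndarray):
    """Per-variant replicate-level variance from duplicate rows.

    The replicate-to-replicate noise has an array component (constant
    across variants) and a pipetting component that scales with the
    variant's allele-frequency variance p(1-p); the per-variant squared
    replicate differences are therefore summarized by the moment model
    v(pq) = a + b*pq (least squares, both coefficients floored at zero).
    Returns the per-variant variance vector (or zeros when no pool has
    duplicates).
    """
    diffs = []
    for _, grp in units.groupby("pool_id"):
        pos = units.index.get_indexer(grp.sort_values("replicate").index)
        for a, b in zip(pos[:-1], pos[1:]):
            diffs.append(baf[a] - baf[b])
    if not diffs:
        return np.zeros(baf.shape[1])
    e = np.mean([d**2 / 2.0 for d in diffs], axis=0)  # per-variant Var(d)/2
    if e.size < 10:
        return np.full(baf.shape[1], float(e.mean()))
    X = np.column_stack([np.ones_like(pq), pq])
    coef, *_ = np.linalg.lstsq(X, e, rcond=None)
    a, b = coef
    if b < 0:
        a, b = float(e.mean()), 0.0
    if a < 0:
        a, b = 0.0, float(e.mean() / max(pq.mean(), 1e-12))
    return a + b * pq


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

class MixedLogitScan:
    """Batched per-variant weighted mixed-logistic association scan.

    Construct once from the measurement-unit table (shared design), then call
    :meth:`scan` with a (units x variants) BAF matrix. Shared design columns
    that are linearly dependent are pruned up front (greedy rank check,
    tolerance 1e-8) and reported in ``dropped_columns``.
    """

    def __init__(self, units: pd.DataFrame, spec: ModelSpec | None = None,
                 pool_af_cov: pd.DataFrame | None = None):
        self.spec = spec or ModelSpec()
        if self.spec.method not in ("score", "wald"):
            raise ConfigError(f"unknown method {self.spec.method!r}")
        self.units = units.reset_index(drop=True)
        self.y = self.units["T2D"].to_numpy(dtype=float)
        self.w = self.units[self.spec.weight_column].to_numpy(dtype=float)
        if (self.w <= 0).any():
            raise InputError("frequency weights must be positive")
        pools, self._pool_codes = np.unique(self.units["pool_id"], return_inverse=True)
        self.n_pools = len(pools)
        pool_outcome = pd.Series(self.y).groupby(self._pool_codes).first()
        if (pool_outcome == 1).sum() < 2 or (pool_outcome == 0).sum() < 2:
            raise InputError("need at least 2 pools in each outcome class")
        self.P = np.zeros((len(self.units), self.n_pools))
        self.P[np.arange(len(self.units)), self._pool_codes] = 1.0
        first = self.units.groupby("pool_id", sort=True).first()
        self._pool_n = first["n"].to_numpy(dtype=float)
        self._pool_phi = (
            first["phi"].to_numpy(dtype=float) if "phi" in first else np.zeros(self.n_pools)
        )
        # pool AF covariance coefficients: full kinship-derived matrix when
        # available, otherwise the within-pool diagonal approximation
        if pool_af_cov is not None:
            self._af_cov = pool_af_cov.loc[pools, pools].to_numpy(dtype=float)
        else:
            self._af_cov = np.diag(
                (1.0 + 2.0 * (self._pool_n - 1.0) * self._pool_phi) / (2.0 * self._pool_n)
            )

        cols, names = [np.ones(len(self.units))], ["const"]
        for f in self.spec.factors:
            d = pd.get_dummies(self.units[f].astype("category"), prefix=f, drop_first=True)
            for c in d.columns:
                cols.append(d[c].to_numpy(dtype=float))
                names.append(str(c))
        for c in self.spec.covariates:
            cols.append(self.units[c].to_numpy(dtype=float))
            names.append(c)
        Z = np.column_stack(cols)
        keep, dropped = self._prune(Z, names)
        self.Z0 = Z[:, keep]
        self.column_names = [names[i] for i in keep]
        self.dropped_columns = tuple(names[i] for i in dropped)
        # weighted projector for per-variant BAF aliasing checks
        WZ = self.Z0 * self.w[:, None]
        self._ZtWZ_inv = np.linalg.pinv(self.Z0.T @ WZ)
        self._WZ = WZ
        # pool-level fixed-effect count (+1 for BAF, which is pool-level up
        # to replicate noise): degrees of freedom for the moment estimator
        pool_means = np.linalg.lstsq(self.P, self.Z0, rcond=None)[0]
        within = self.Z0 - self.P @ pool_means
        self._n_pool_level = int((np.abs(within).max(axis=0) < 1e-10).sum()) + 1
        self._null_cache: dict | None = None

    def _prune(self, Z, names, tol=1e-8):
        sw = np.sqrt(self.w)
        keep, dropped = [], []
        basis = np.empty((Z.shape[0], 0))
        for j in range(Z.shape[1]):
            col = sw * Z[:, j]
            if basis.shape[1]:
                col = col - basis @ (basis.T @ col)
            nrm = np.linalg.norm(col)
            if nrm > tol * max(1.0, np.linalg.norm(sw * Z[:, j])):
                keep.append(j)
                basis = np.column_stack([basis, col / nrm])
            else:
                dropped.append(j)
        return keep, dropped

    # -- shared helpers ----------------------------------------------------
    def _design(self, baf):
        M = baf.shape[1]
        p = self.Z0.shape[1] + 1
        X = np.empty((M, len(self.units), p))
        X[:, :, 0] = self.Z0[:, 0]
        X[:, :, 1] = baf.T
        X[:, :, 2:] = self.Z0[None, :, 1:]
        return X

    def _aliased(self, baf):
        coef = self._ZtWZ_inv @ (self._WZ.T @ baf)
        resid = baf - self.Z0 @ coef
        wsd = np.sqrt((self.w[:, None] * resid**2).sum(axis=0) / self.w.sum())
        return wsd < 1e-8

    def _ridge_penalty(self):
        """Weakly-informative ridge: unit prior SD per standardized covariate."""
        w = self.w
        mean = np.average(self.Z0, axis=0, weights=w)
        sd2 = np.average((self.Z0 - mean) ** 2, axis=0, weights=w)
        pen = self.spec.ridge * sd2
        pen[0] = 0.0  # intercept unpenalized
        return pen

    def null_fit(self) -> dict:
        """Ridge-stabilized weighted-logistic null (no-BAF) fit, cached.

        Also computes the pool-level overdispersion moment estimate of
        tau^2: the excess of squared latent pool residuals t_g = S_g/W_g
        over their sampling term 1/W_g, divided by G - p_pool.
        """
        if self._null_cache is not None:
            return self._null_cache
        y, w, P = self.y, self.w, self.P
        Z0 = self.Z0
        pen = self._ridge_penalty()
        X0 = Z0[None, :, :]
        beta = np.zeros((1, Z0.shape[1]))
        b = np.zeros((1, self.n_pools))
        inv = np.full(1, np.inf)
        beta, b, eta, conv, _ = _newton(
            X0, y, w, P, inv, beta, b, max_iter=200, gtol=self.spec.gtol, pen=pen
        )
        if not conv[0]:
            warnings.warn("null model fit did not fully converge", stacklevel=3)
        mu = expit(eta[0])
        r = w * (y - mu)
        Wd = w * mu * (1.0 - mu)
        Wg = np.maximum(Wd @ P, 1e-10)
        t = (r @ P) / Wg
        dof = max(1, self.n_pools - (self._n_pool_level - 1))
        tau2 = float(max(0.0, ((t**2 - 1.0 / Wg).sum()) / dof))
        A = Z0.T @ (Wd[:, None] * Z0) + np.diag(pen)
        self._null_cache = {
            "beta": beta[0], "mu": mu, "r": r, "Wd": Wd,
            "tau2": tau2, "A_inv": np.linalg.inv(A), "converged": bool(conv[0]),
        }
        return self._null_cache

    # -- public fitting ----------------------------------------------------
    def scan(self, baf: np.ndarray, variant_ids=None) -> pd.DataFrame:
        """Fit every variant; returns one row per variant (order preserved)."""
        baf = np.asarray(baf, dtype=float)
        if baf.ndim != 2 or baf.shape[0] != len(self.units):
            raise InputError("BAF matrix must be (n_units, n_variants)")
        if not np.isfinite(baf).all():
            raise InputError("BAF values must be finite")
        M = baf.shape[1]
        if variant_ids is None:
            variant_ids = np.array([f"v{i}" for i in range(M)])
        aliased = self._aliased(baf)
        ok = np.flatnonzero(~aliased)
        out = pd.DataFrame(
            {
                "variant": np.asarray(variant_ids, dtype=object),
                "beta": np.nan,
                "se": np.nan,
                "stat": np.nan,
                "p": np.nan,
                "tau2": np.nan,
                "converged": False,
                "aliased": aliased,
            }
        )
        if ok.size:
            if self.spec.method == "score":
                res = self._fit_score(baf[:, ok])
            else:
                res = self._fit_wald(baf[:, ok])
            for col in ("beta", "se", "stat", "p", "tau2"):
                out.loc[ok, col] = res[col]
            out.loc[ok, "converged"] = res["converged"]
        return out

    # -- score/sandwich method --------------------------------------------
    def _fit_score(self, baf):
        null = self.null_fit()
        r, Wd = null["r"], null["Wd"]
        w, P = self.w, self.P
        U_v = baf.T @ r
        # model information for the one-step slope (bread)
        h = self.Z0.T @ (Wd[:, None] * baf)
        xWx = (Wd[:, None] * baf * baf).sum(axis=0)
        info = np.maximum(xWx - (h * (null["A_inv"] @ h)).sum(axis=0), 1e-300)
        # measurement-model variance (meat)
        phat = (self.w @ baf) / self.w.sum()
        pq = np.clip(phat * (1.0 - phat), 0.0, 0.25)
        v_rep = _replicate_variance(baf, self.units, pq)
        if len(self.units) == self.n_pools:
            warnings.warn(
                "single replicate per pool: replicate variance unavailable, "
                "score variance uses the sampling term only",
                stacklevel=3,
            )
        Rg = r @ P
        shared = float(Rg @ self._af_cov @ Rg)  # R' Cov(q) R / p(1-p)
        var_u = pq * shared + v_rep * float((r**2).sum())
        good = var_u > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(good, U_v / np.sqrt(var_u), np.nan)
        beta = U_v / info
        se = np.where(good, np.sqrt(var_u) / info, np.nan)
        pval = self._p_from_stat(stat)
        conv = good & np.isfinite(stat) & null["converged"]
        return {
            "beta": beta,
            "se": se,
            "stat": stat,
            "p": np.where(conv, pval, np.nan),
            "tau2": np.full(baf.shape[1], null["tau2"]),
            "converged": conv,
        }

    # -- full per-variant ML (Wald) method ----------------------------------
    def _fit_wald(self, baf):
        spec = self.spec
        X = self._design(baf)
        M, U, p = X.shape
        y, w, P = self.y, self.w, self.P

        if spec.tau2 != "profile":
            tau2_fin = np.full(M, float(spec.tau2))
            if tau2_fin[0] < 0:
                raise ConfigError("fixed tau2 must be >= 0")
            beta = np.zeros((M, p))
            b = np.zeros((M, self.n_pools))
            inv = np.where(tau2_fin > 0, 1.0 / np.maximum(tau2_fin, 1e-300), np.inf)
            beta, b, eta, conv, pll = _newton(
                X, y, w, P, inv, beta, b, spec.max_iter, spec.gtol
            )
            return self._wald_result(X, eta, w, P, inv, beta, tau2_fin, conv)

        grid = spec.grid()
        inv_grid = np.where(grid > 0, 1.0 / np.maximum(grid, 1e-300), np.inf)
        beta = np.zeros((M, p))
        b = np.zeros((M, self.n_pools))
        lp_all = np.full((M, len(grid)), -np.inf)
        best = {
            "lp": np.full(M, -np.inf),
            "idx": np.zeros(M, dtype=int),
            "beta": np.zeros((M, p)),
            "b": np.zeros((M, self.n_pools)),
            "conv": np.zeros(M, dtype=bool),
        }
        for gi, _tau2 in enumerate(grid):
            inv = np.full(M, inv_grid[gi])
            beta, b, eta, conv, pll = _newton(
                X, y, w, P, inv, beta.copy(), b.copy(), spec.max_iter, spec.gtol
            )
            lp = _laplace_profile(eta, y, w, P, inv, pll)
            lp_all[:, gi] = lp
            better = lp > best["lp"]
            for key, val in (("lp", lp), ("beta", beta), ("b", b), ("conv", conv)):
                best[key][better] = val[better]
            best["idx"][better] = gi

        tau2_fin = grid[best["idx"]]
        # parabolic refinement in log tau2 for interior optima
        interior = (best["idx"] >= 2) & (best["idx"] <= len(grid) - 2)
        cand = np.flatnonzero(interior)
        if cand.size:
            i0 = best["idx"][cand]
            x0, x1, x2 = (np.log(grid[i0 - 1]), np.log(grid[i0]), np.log(grid[i0 + 1]))
            f0, f1, f2 = lp_all[cand, i0 - 1], lp_all[cand, i0], lp_all[cand, i0 + 1]
            denom = f0 - 2 * f1 + f2
            with np.errstate(divide="ignore", invalid="ignore"):
                xs = x1 - 0.5 * (f2 - f0) / denom * (x2 - x1)
            good = np.isfinite(xs) & (denom < 0) & (xs > x0) & (xs < x2)
            ref = cand[good]
            if ref.size:
                tau2_ref = tau2_fin.copy()
                tau2_ref[ref] = np.exp(xs[good])
                inv_ref = np.where(tau2_ref > 0, 1.0 / tau2_ref, np.inf)
                b2, bb2, eta2, conv2, pll2 = _newton(
                    X, y, w, P, inv_ref,
                    best["beta"].copy(), best["b"].copy(), spec.max_iter, spec.gtol,
                )
                lp2 = _laplace_profile(eta2, y, w, P, inv_ref, pll2)
                use = np.zeros(M, dtype=bool)
                use[ref] = lp2[ref] >= best["lp"][ref]
                tau2_fin = np.where(use, tau2_ref, tau2_fin)
                best["beta"][use] = b2[use]
                best["b"][use] = bb2[use]
                best["conv"][use] = conv2[use]

        inv_fin = np.where(tau2_fin > 0, 1.0 / np.maximum(tau2_fin, 1e-300), np.inf)
        eta_fin = np.einsum("mup,mp->mu", X, best["beta"]) + best["b"] @ P.T
        return self._wald_result(X, eta_fin, w, P, inv_fin, best["beta"], tau2_fin, best["conv"])

    def _wald_result(self, X, eta, w, P, inv_tau2, beta, tau2, conv):
        cov = _beta_covariance(X, eta, w, P, inv_tau2)
        se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
        bs = beta[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = bs / se
        pval = self._p_from_stat(stat)
        good = np.isfinite(stat) & conv  # non-converged records get missing p
        return {
            "beta": bs,
            "se": se,
            "stat": stat,
            "p": np.where(good, pval, np.nan),
            "tau2": tau2,
            "converged": conv & np.isfinite(stat),
        }

    def _p_from_stat(self, stat):
        with np.errstate(invalid="ignore"):
            if self.spec.reference == "t":
                df = max(self.n_pools - self._n_pool_level, 1)
                pval = 2.0 * stats.t.sf(np.abs(stat), df)
            else:
                pval = 2.0 * stats.norm.sf(np.abs(stat))
        return np.clip(pval, np.finfo(float).tiny, 1.0)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def fit_variant(
    units: pd.DataFrame, baf_column, spec: ModelSpec | None = None, variant_id: str = "v0"
) -> AssociationRecord:
    """Fit the model for one variant's BAF column (Wald method by default).

    Single-variant fits default to the full-ML Wald method because the
    score method's replicate variance component is estimated across many
    variants.
    """
    if spec is None:
        spec = ModelSpec(method="wald")
    scanner = MixedLogitScan(units, spec)
    row = scanner.scan(np.asarray(baf_column, dtype=float).reshape(-1, 1), [variant_id]).iloc[0]
    return AssociationRecord(
        variant=row["variant"],
        beta=row["beta"],
        se=row["se"],
        stat=row["stat"],
        p=row["p"],
        tau2=row["tau2"],
        converged=bool(row["converged"]),
        aliased=bool(row["aliased"]),
    )


def run_gwas(
    baf_matrix: PoolBAFMatrix,
    panel: pd.DataFrame | None = None,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    pooling_error: bool = True,
) -> tuple[pd.DataFrame, GwasSummary]:
    """Scan every (retained) variant and summarize the genome-wide result.

    If ``panel`` is given it is first passed through :func:`filter_panel`
    (autosomes, MAF >= 1%) and the BAF columns are subset to the retained
    variants by id; chrom/pos are merged into the output records.
    """
    from .pooling import estimate_pooling_error

    baf = baf_matrix.baf
    ids = np.asarray(baf_matrix.variant_ids)
    merged = None
    if panel is not None:
        filtered, _ = filter_panel(panel)
        keep_ids = set(filtered["id"])
        col = np.array([v in keep_ids for v in ids])
        baf = baf[:, col]
        ids = ids[col]
        merged = filtered.set_index("id")
    scanner = MixedLogitScan(baf_matrix.units, spec, pool_af_cov=baf_matrix.pool_af_cov)
    records = scanner.scan(baf, ids)
    if merged is not None:
        records["chrom"] = merged.loc[records["variant"], "chrom"].to_numpy()
        records["pos"] = merged.loc[records["variant"], "pos"].to_numpy()
    m = len(records)
    if m == 0:
        raise InputError("no variants to test")
    alpha_star = bonferroni_threshold(m, alpha)
    valid = records["p"].notna()
    sig = records.loc[valid & (records["p"] < alpha_star), "variant"].tolist()
    lam = float("nan")
    if valid.sum() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = genomic_inflation(records.loc[valid, "p"])
    tau2_null = float("nan")
    if scanner.spec.method == "score":
        tau2_null = scanner.null_fit()["tau2"]
    summary = GwasSummary(
        m=m,
        alpha=alpha,
        alpha_star=alpha_star,
        significant=sorted(sig),
        lambda_gc=lam,
        pooling_error=estimate_pooling_error(baf_matrix) if pooling_error else None,
        n_converged=int(records["converged"].sum()),
        tau2_null=tau2_null,
        dropped_columns=scanner.dropped_columns,
    )
    return records, summary
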