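"""GBLUP genomic prediction in four flavors, fit by Gibbs sampling.

Models (all with a flat prior on fixed effects and scaled-inverse-chi-square
priors on variance components):

- UV:    y = 1 mu + u + e,           u ~ N(0, G s2_u)
- FIXED: y = X b + u + e,            X = intercept + QTL-peak marker dosages,
         G rebuilt from the remaining markers
- ME/MS: y = 1 mu + u + v + e,       v ~ N(0, G_v s2_v) with G_v built from
         standardized auxiliary phenotypes (other environments / stages)

G follows VanRaden: G = Z Z' / (2 sum p_j (1 - p_j)) with Z the
column-centered dosage matrix.  G_v = n M M' / trace(M M') with M the
standardized auxiliary-phenotype matrix (trace(G_v) = n exactly).

The sampler reparameterises each kernel through its eigendecomposition and,
per training mask, a second orthogonal rotation that diagonalises the
likelihood normal equations, so every conditional draw is elementwise — an
exact Gibbs scheme with O(n k) cost per sweep.  A deterministic solver of the
mixed-model equations at fixed variance ratios serves as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "GRM",
    "AuxKernel",
    "GSFit",
    "CVResult",
    "vanraden_grm",
    "build_fixed_design",
    "build_aux_kernel",
    "fit_gblup",
    "mme_blup",
    "reml_variance_ratio",
    "cross_validate",
    "variance_proportions",
]


@dataclass
class GRM:
    G: np.ndarray
    m: int
    allele_freq: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.G, self.G.T):
            raise ValueError("G must be symmetric")
        if not np.isfinite(self.G).all():
            raise ValueError("G must be finite")


@dataclass
class AuxKernel:
    Gv: np.ndarray
    t_minus_1: int

    def __post_init__(self) -> None:
        n = self.Gv.shape[0]
        if abs(np.trace(self.Gv) - n) > 1e-8:
            raise ValueError("trace(G_v) must equal n")


@dataclass
class GSFit:
    mu: float
    beta: np.ndarray
    u: dict[str, np.ndarray]  # posterior-mean effects per kernel
    var: dict[str, float]  # posterior-mean variance components (incl. 'eps')
    var_samples: dict[str, np.ndarray]
    gebv: np.ndarray  # sum of kernel effects (+ X beta when fixed design present)
    fixed_part: np.ndarray

    @property
    def proportions(self) -> dict[str, float]:
        tot = sum(self.var.values())
        return {k: v / tot for k, v in self.var.items()}


@dataclass
class CVResult:
    r_mp: np.ndarray  # (reps, folds)
    folds: np.ndarray  # (reps, n) fold assignment
    seeds: np.ndarray
    model: str = ""

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.r_mp))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.r_mp, ddof=1))


def _impute_mean(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    if np.isnan(M).any():
        col = np.nanmean(M, axis=0)
        M = np.where(np.isnan(M), col[None, :], M)
    return M


def vanraden_grm(markers: np.ndarray | pd.DataFrame) -> GRM:
    """VanRaden genomic relationship matrix from 0/2 dosage codes.

    Missing entries are mean-imputed per marker before centering.
    """
    M = _impute_mean(np.asarray(markers, float))
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all markers are monomorphic; VanRaden denominator is zero")
    Z = M - 2.0 * p[None, :]
    G = Z @ Z.T / denom
    return GRM(G=G, m=M.shape[1], allele_freq=p)


def build_fixed_design(
    peak_markers: list[str], markers: pd.DataFrame
) -> tuple[np.ndarray, GRM, list[str]]:
    """Fixed-effect design from QTL-peak markers + GRM from the rest.

    Returns (X with intercept and p dosage columns, GRM on the m - p remaining
    markers, names of the remaining markers).
    """
    missing = [m for m in peak_markers if m not in markers.columns]
    if missing:
        raise ValueError(f"peak markers absent from the matrix: {missing}")
    n = markers.shape[0]
    p = len(peak_markers)
    if p >= n:
        raise ValueError(f"p = {p} peak markers >= n = {n} individuals")
    rest = [m for m in markers.columns if m not in set(peak_markers)]
    if p == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), _impute_mean(markers[peak_markers].to_numpy()) - 1.0])
    grm = vanraden_grm(markers[rest])
    return X, grm, rest


def build_aux_kernel(aux_phenotypes: np.ndarray | pd.DataFrame) -> AuxKernel:
    """Auxiliary-phenotype kernel G_v = n M M' / trace(M M').

    Columns are standardized to zero mean, unit population variance; missing
    values are mean-imputed (logged via warning).
    """
    A = np.asarray(aux_phenotypes, float)
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[1] < 1:
        raise ValueError("need >= 1 auxiliary vector")
    if np.isnan(A).any():
        warnings.warn("auxiliary phenotypes contain missing values; mean-imputed", stacklevel=2)
        A = _impute_mean(A)
    sd = A.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance auxiliary vector")
    M = (A - A.mean(axis=0)) / sd
    n = M.shape[0]
    MMt = M @ M.T
    Gv = n * MMt / np.trace(MMt)
    return AuxKernel(Gv=Gv, t_minus_1=M.shape[1])


def _kernel_factor(K: np.ndarray, ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigen square-root of a PSD kernel; drops near-null directions."""
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError("kernel is not positive semi-definite")
    keep = w > max(ridge, 1e-10 * w.max())
    return U[:, keep] * np.sqrt(w[keep])[None, :], w[keep]


def fit_gblup(
    y: np.ndarray,
    kernels: dict[str, np.ndarray],
    X: np.ndarray | None = None,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    seed: int | np.random.Generator = 0,
    df_prior: float = 5.0,
    r2_prior: float = 0.5,
    train: np.ndarray | None = None,
) -> GSFit:
    """Gibbs sampler for the (multi-kernel) GBLUP model.

    ``y`` may contain NaN for individuals to predict; alternatively pass a
    boolean ``train`` mask.  Kernels cover all individuals; only training rows
    enter the likelihood, so test-individual effects are predicted through
    the kernel covariance.  Priors are scaled-inverse-chi-square with
    ``df_prior`` degrees of freedom and scales set from an ``r2_prior``
    variance split, divided equally among kernels.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, float)
    n = len(y)
    if train is None:
        train = ~np.isnan(y)
    train = np.asarray(train, bool)
    yt = y[train]
    nt = int(train.sum())
    if nt < 3:
        raise ValueError("need >= 3 training individuals")

    if X is None:
        X = np.ones((n, 1))
    Xt = X[train]
    XtX = Xt.T @ Xt
    XtX_inv = np.linalg.pinv(XtX)
    L_beta = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(X.shape[1]))

    # per kernel: P (n x k) maps rotated coefficients to individual effects,
    # Wt (nt x k) is its training block, lam (k) the likelihood eigenvalues
    parts = {}
    for name, K in kernels.items():
        F, _ = _kernel_factor(K)
        W = F[train]
        WtW = W.T @ W
        lam, V = np.linalg.eigh(WtW)
        lam = np.clip(lam, 0.0, None)
        parts[name] = {
            "P": F @ V,
            "Wt": W @ V,
            "lam": lam,
            "b": np.zeros(F.shape[1]),
        }

    vy = float(np.var(yt))
    n_k = max(len(kernels), 1)
    S0 = {name: vy * r2_prior / n_k * (df_prior + 2) / df_prior for name in kernels}
    S0_eps = vy * (1 - r2_prior) * (df_prior + 2) / df_prior
    var = {name: vy * r2_prior / n_k for name in kernels}
    var_eps = vy * (1 - r2_prior) if vy > 0 else 1.0
    var_eps = max(var_eps, 1e-8)

    beta = np.zeros(X.shape[1])
    resid = yt - Xt @ beta

    keep = n_iter - burn_in
    acc_u = {name: np.zeros(n) for name in kernels}
    acc_beta = np.zeros(X.shape[1])
    var_samples = {name: np.empty(keep) for name in kernels}
    var_samples["eps"] = np.empty(keep)

    for it in range(n_iter):
        # fixed effects (flat prior)
        resid = resid + Xt @ beta
        bhat = XtX_inv @ (Xt.T @ resid)
        beta = bhat + L_beta @ rng.standard_normal(X.shape[1]) * np.sqrt(var_eps)
        resid = resid - Xt @ beta

        # kernel effects, rotated basis: diagonal conditional
        for name, pt in parts.items():
            Wt, lam, b = pt["Wt"], pt["lam"], pt["b"]
            resid = resid + Wt @ b
            prec = lam / var_eps + 1.0 / var[name]
            mean = (Wt.T @ resid) / var_eps / prec
            b = mean + rng.standard_normal(len(lam)) / np.sqrt(prec)
            pt["b"] = b
            resid = resid - Wt @ b
            ss = float(b @ b) + df_prior * S0[name]
            var[name] = ss / rng.chisquare(df_prior + len(lam))
            var[name] = max(var[name], 1e-10)

        ss_e = float(resid @ resid) + df_prior * S0_eps
        var_eps = ss_e / rng.chisquare(df_prior + nt)
        var_eps = max(var_eps, 1e-10)

        if it >= burn_in:
            j = it - burn_in
            for name, pt in parts.items():
                acc_u[name] += pt["P"] @ pt["b"]
                var_samples[name][j] = var[name]
            acc_beta += beta
            var_samples["eps"][j] = var_eps

    u_mean = {name: acc_u[name] / keep for name in kernels}
    beta_mean = acc_beta / keep
    fixed_part = X @ beta_mean
    gebv = np.sum(list(u_mean.values()), axis=0) if u_mean else np.zeros(n)
    if X.shape[1] > 1:
        gebv = gebv + fixed_part - np.mean(fixed_part)
    var_mean = {name: float(var_samples[name].mean()) for name in var_samples}
    return GSFit(
        mu=float(beta_mean[0]),
        beta=beta_mean,
        u=u_mean,
        var=var_mean,
        var_samples=var_samples,
        gebv=gebv,
        fixed_part=fixed_part,
    )


def mme_blup(
    y: np.ndarray,
    kernels: dict[str, np.ndarray],
    variance_ratios: dict[str, float],
    X: np.ndarray | None = None,
    train: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Deterministic mixed-model-equation BLUPs at fixed variance ratios.

    ``variance_ratios[name] = s2_name / s2_eps``.  Returns (beta_hat, effects
    per kernel over all individuals).  Oracle for the Gibbs sampler.
    """
    y = np.asarray(y, float)
    n = len(y)
    if train is None:
        train = ~np.isnan(y)
    train = np.asarray(train, bool)
    yt = y[train]
    if X is None:
        X = np.ones((n, 1))
    Xt = X[train]
    V = np.eye(int(train.sum()))
    for name, K in kernels.items():
        V = V + variance_ratios[name] * K[np.ix_(train, train)]
    Vi = np.linalg.inv(V)
    XtViX = Xt.T @ Vi @ Xt
    beta = np.linalg.solve(XtViX, Xt.T @ Vi @ yt)
    r = Vi @ (yt - Xt @ beta)
    effects = {}
    for name, K in kernels.items():
        effects[name] = variance_ratios[name] * K[:, train] @ r
    return beta, effects


def reml_variance_ratio(y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None) -> float:
    """REML estimate of s2_u / s2_eps for a single-kernel model."""
    y = np.asarray(y, float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def negll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        Vi = 1.0 / d
        XtViX = (Xr * Vi[:, None]).T @ Xr
        b = np.linalg.solve(XtViX, (Xr * Vi[:, None]).T @ yr)
        r = yr - Xr @ b
        q = X.shape[1]
        s2 = float(r @ (Vi * r)) / (n - q)
        _, ld = np.linalg.slogdet(XtViX)
        return float(np.sum(np.log(d)) + (n - q) * np.log(s2) + ld)

    res = minimize_scalar(negll, bounds=(-8, 8), method="bounded")
    return float(np.exp(res.x))


def cross_validate(
    y: np.ndarray,
    kernels: dict[str, np.ndarray],
    X: np.ndarray | None = None,
    folds: int = 5,
    reps: int = 100,
    seed: int = 0,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    model: str = "UV",
) -> CVResult:
    """Replicated k-fold cross-validation of a GBLUP model.

    Per replicate, a uniform random partition into ``folds`` folds; test-fold
    phenotypes are masked and r_MP is the Pearson correlation between test
    GEBVs and the observed values.  Auxiliary kernels (built from other
    environments/stages) legitimately cover all individuals; only the target
    phenotype is masked.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < folds:
        raise ValueError("need n >= folds")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=reps)
    r_mp = np.full((reps, folds), np.nan)
    assign = np.empty((reps, n), dtype=int)
    for rep in range(reps):
        rng = np.random.default_rng(rep_seeds[rep])
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f in range(folds):
            fold_of[perm[f::folds]] = f
        assign[rep] = fold_of
        for f in range(folds):
            test = fold_of == f
            fit = fit_gblup(
                y,
                kernels,
                X=X,
                n_iter=n_iter,
                burn_in=burn_in,
                seed=np.random.default_rng(rng.integers(0, 2**31 - 1)),
                train=~test,
            )
            pred = fit.gebv[test]
            obs = y[test]
            if np.std(pred) == 0 or np.std(obs) == 0:
                warnings.warn("constant GEBV or phenotype in a test fold; r_MP set to 0", stacklevel=2)
                r_mp[rep, f] = 0.0
            else:
                r_mp[rep, f] = float(np.corrcoef(pred, obs)[0, 1])
    return CVResult(r_mp=r_mp, folds=assign, seeds=rep_seeds, model=model)


def variance_proportions(fit: GSFit) -> pd.DataFrame:
    """Posterior-mean variance components and their proportions (sum to 1)."""
    props = fit.proportions
    return pd.DataFrame(
        {
            "component": list(fit.var.keys()),
            "variance": list(fit.var.values()),
            "proportion": [props[k] for k in fit.var],
        }
    )
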