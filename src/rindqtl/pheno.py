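"""Phenotype statistics: ANOVA variance components, broad-sense heritability,
BLUEs, stage standardization/clustering, and phenotypic/genetic correlations.

All estimators work on the long-format phenotype table produced by
:mod:`rindqtl.simulate` (columns line, env, stage, rep, value) restricted to a
single stage, except :func:`correlations` which uses pairs of stages.

The ANOVA model is the two-way mixed model with replicates nested in
environments::

    y_ijk = mu + g_i + e_j + ge_ij + r_k(j) + eps_ijk

and variance components come from the expected-mean-square identities of the
balanced design (method of moments):

    s2_eps = MSE
    s2_ge  = (MS_GE - MSE) / r
    s2_g   = (MS_G - MS_GE) / (r e)

Broad-sense heritability on an entry-mean basis is

    H2 = s2_g / (s2_g + s2_ge / e + s2_eps / (r e)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "CorrelationResult",
    "StageClustering",
    "anova_components",
    "broad_sense_heritability",
    "estimate_blue",
    "standardize_stage_matrix",
    "standardize_and_cluster",
    "correlations",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    e: int
    r: int
    sigma2_rep: float = 0.0
    truncated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")
        for name in ("sigma2_g", "sigma2_ge", "sigma2_eps", "sigma2_rep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CorrelationResult:
    """Phenotypic and genetic correlation matrices over stages."""

    stages: tuple[str, ...]
    r_p: pd.DataFrame  # averaged over environments
    r_p_by_env: dict[str, pd.DataFrame]
    r_g: pd.DataFrame
    components: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


@dataclass
class StageClustering:
    distances: pd.DataFrame  # stages x stages Euclidean distances
    linkage: np.ndarray  # scipy linkage matrix
    newick: str
    method: str
    imputed: tuple[str, ...] = ()


def _check_balanced(table: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Return values as (n_lines, n_envs, n_reps) array; raise naming missing cells."""
    required = {"line", "env", "rep", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {sorted(missing_cols)}")
    lines = sorted(table["line"].unique())
    envs = sorted(table["env"].unique())
    reps = sorted(table["rep"].unique())
    piv = table.pivot_table(index="line", columns=["env", "rep"], values="value", aggfunc="count")
    full = pd.MultiIndex.from_product([envs, reps])
    piv = piv.reindex(index=lines, columns=full)
    bad = []
    arr = piv.to_numpy()
    if np.isnan(arr).any() or (arr != 1).any():
        for i, ln in enumerate(lines):
            for j, (ev, rp) in enumerate(full):
                c = arr[i, j]
                if np.isnan(c) or c != 1:
                    bad.append(f"(line={ln}, env={ev}, rep={rp}: {0 if np.isnan(c) else int(c)} obs)")
        raise ValueError(
            "unbalanced phenotype table; each line x env x rep cell needs exactly one "
            f"observation; offending cells: {', '.join(bad[:20])}"
            + ("..." if len(bad) > 20 else "")
        )
    wide = table.pivot_table(index="line", columns=["env", "rep"], values="value")
    wide = wide.reindex(index=lines, columns=full)
    y = wide.to_numpy().reshape(len(lines), len(envs), len(reps))
    return y, lines, envs, reps


def _mean_squares(y: np.ndarray) -> dict[str, float]:
    """Mean squares of the balanced two-way model with reps nested in envs."""
    n, e, r = y.shape
    grand = y.mean()
    line_m = y.mean(axis=(1, 2))
    env_m = y.mean(axis=(0, 2))
    le_m = y.mean(axis=2)
    er_m = y.mean(axis=0)
    ss_g = e * r * np.sum((line_m - grand) ** 2)
    ss_e = n * r * np.sum((env_m - grand) ** 2)
    ss_rep = n * np.sum((er_m - env_m[:, None]) ** 2)
    ss_ge = r * np.sum((le_m - line_m[:, None] - env_m[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_g - ss_e - ss_rep - ss_ge
    out = {"MS_G": ss_g / (n - 1)}
    if e > 1:
        out["MS_E"] = ss_e / (e - 1)
        out["MS_GE"] = ss_ge / ((n - 1) * (e - 1))
    if r > 1:
        out["MS_R"] = ss_rep / (e * (r - 1))
    df_err = (n - 1) * e * (r - 1) if e > 1 else (n - 1) * (r - 1)
    if e == 1:
        # single environment: ge is not estimable, absorb into error
        ss_err = ss_tot - ss_g - ss_rep
        df_err = (n - 1) * (r - 1) if r > 1 else 0
    out["MSE"] = ss_err / df_err if df_err > 0 else 0.0
    return out


def anova_components(table: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components from a balanced trial.

    Negative moment estimates are truncated to zero and recorded in
    ``truncated``.  With a single environment the genotype-by-environment term
    is dropped and ``sigma2_ge`` is reported as 0.
    """
    y, lines, envs, reps = _check_balanced(table)
    n, e, r = y.shape
    if n < 2:
        raise ValueError("need >= 2 lines")
    ms = _mean_squares(y)
    truncated: list[str] = []
    s2_eps = ms["MSE"]
    if e > 1:
        s2_ge = (ms["MS_GE"] - ms["MSE"]) / r if r > 1 else 0.0
        if r == 1:
            # no replication: GE confounded with error; MSE holds the GE+eps mix
            s2_eps = ms["MS_GE"]
        s2_g = (ms["MS_G"] - (ms["MS_GE"] if r > 1 else s2_eps)) / (r * e)
        if r > 1:
            s2_g = (ms["MS_G"] - ms["MS_GE"]) / (r * e)
    else:
        s2_ge = 0.0
        s2_g = (ms["MS_G"] - ms["MSE"]) / r
    s2_rep = (ms.get("MS_R", ms["MSE"]) - ms["MSE"]) / n if r > 1 else 0.0
    vals = {"sigma2_g": s2_g, "sigma2_ge": s2_ge, "sigma2_eps": s2_eps, "sigma2_rep": s2_rep}
    for k, v in vals.items():
        if v < 0:
            truncated.append(k)
            vals[k] = 0.0
    return VarianceComponents(
        sigma2_g=vals["sigma2_g"],
        sigma2_ge=vals["sigma2_ge"],
        sigma2_eps=vals["sigma2_eps"],
        sigma2_rep=vals["sigma2_rep"],
        e=e,
        r=r,
        truncated=tuple(truncated),
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability H2 = s2_g/(s2_g + s2_ge/e + s2_eps/(re))."""
    denom = vc.sigma2_g + vc.sigma2_ge / vc.e + vc.sigma2_eps / (vc.r * vc.e)
    if denom == 0.0:
        warnings.warn("all variance components are zero; H2 defined as 0", stacklevel=2)
        return 0.0
    return vc.sigma2_g / denom


def estimate_blue(
    table: pd.DataFrame,
    components: VarianceComponents | None = None,
    method: str = "moments",
) -> pd.Series:
    """Per-line BLUEs across environments by generalized least squares.

    Genotype is fixed; environment, genotype x environment and replicate
    within environment are random with variances from the moment estimators
    (``method="moments"``, default) or from REML on the same covariance
    structure (``method="reml"``).  On a balanced table the BLUEs collapse to
    simple line means.
    """
    required = {"line", "env", "rep", "value"}
    if required - set(table.columns):
        raise ValueError(f"phenotype table missing columns: {sorted(required - set(table.columns))}")
    df = table.dropna(subset=["value"]).reset_index(drop=True)
    lines = sorted(df["line"].unique())
    envs = sorted(df["env"].unique())
    if not lines:
        raise ValueError("no lines with observations")
    n, e = len(lines), len(envs)

    if components is None:
        components = anova_components(table)  # raises informatively if unbalanced
    if method == "reml":
        y, _, _, _ = _check_balanced(table)
        components = _reml_components(y, components)
    elif method != "moments":
        raise ValueError("method must be 'moments' or 'reml'")

    yv = df["value"].to_numpy(float)
    N = yv.size
    line_idx = pd.Categorical(df["line"], categories=lines).codes
    env_idx = pd.Categorical(df["env"], categories=envs).codes
    er_key = pd.Categorical(df["env"].astype(str) + "/" + df["rep"].astype(str)).codes
    le_idx = line_idx * e + env_idx

    V = np.zeros((N, N))
    V += components.sigma2_ge * (le_idx[:, None] == le_idx[None, :])
    V += components.sigma2_rep * (er_key[:, None] == er_key[None, :])
    V += components.sigma2_eps * np.eye(N)
    if np.all(np.diag(V) == 0):
        V += 1e-10 * np.eye(N)

    # genotype fixed; environment enters as a sum-to-zero fixed contrast so
    # each line's BLUE is on the across-environment mean scale
    X = np.zeros((N, n + max(e - 1, 0)))
    X[np.arange(N), line_idx] = 1.0
    for j in range(e - 1):
        X[:, n + j] = (env_idx == j).astype(float) - (env_idx == e - 1).astype(float)
    Vi_y = np.linalg.solve(V, yv)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    return pd.Series(beta[:n], index=pd.Index(lines, name="line"), name="BLUE")


def _reml_components(y: np.ndarray, start: VarianceComponents) -> VarianceComponents:
    """REML refinement of (s2_ge, s2_rep, s2_eps) by direct likelihood search."""
    n, e, r = y.shape
    yv = y.reshape(-1)
    N = yv.size
    line_idx = np.repeat(np.arange(n), e * r)
    env_idx = np.tile(np.repeat(np.arange(e), r), n)
    rep_idx = np.tile(np.arange(e * r), n)
    le_idx = line_idx * e + env_idx
    X = np.zeros((N, n + e))
    X[np.arange(N), line_idx] = 1.0
    X[np.arange(N), n + env_idx] = 1.0  # env fixed in the REML working model
    Zge = (le_idx[:, None] == le_idx[None, :]).astype(float)
    Zrep = (rep_idx[:, None] == rep_idx[None, :]).astype(float)

    def negll(logv: np.ndarray) -> float:
        vge, vrep, veps = np.exp(logv)
        V = vge * Zge + vrep * Zrep + veps * np.eye(N)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        sign, logdet_x = np.linalg.slogdet(XtViX + 1e-10 * np.eye(X.shape[1]))
        P = Vi - Vi @ X @ np.linalg.pinv(XtViX) @ X.T @ Vi
        return float(2 * np.log(np.diag(L)).sum() + logdet_x + yv @ P @ yv)

    x0 = np.log(
        np.maximum([start.sigma2_ge, start.sigma2_rep, start.sigma2_eps], 1e-4)
    )
    res = minimize(negll, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-6})
    vge, vrep, veps = np.exp(res.x)
    return VarianceComponents(
        sigma2_g=start.sigma2_g, sigma2_ge=vge, sigma2_eps=veps, sigma2_rep=vrep, e=e, r=r
    )


def standardize_stage_matrix(stage_matrix: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Center and scale each stage column to zero mean, unit population variance.

    Missing values are imputed by the stage mean (logged) before scaling.
    Raises on a zero-variance column.
    """
    m = stage_matrix.copy().astype(float)
    imputed = tuple(c for c in m.columns if m[c].isna().any())
    for c in imputed:
        log.info("imputing %d missing BLUEs in stage %s by the stage mean", m[c].isna().sum(), c)
        m[c] = m[c].fillna(m[c].mean())
    sd = m.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance stage column(s): {bad}")
    z = (m - m.mean(axis=0)) / sd
    return z, imputed


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_dist - node.dist:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return rec(tree, tree.dist) + ";"


def standardize_and_cluster(stage_matrix: pd.DataFrame, method: str = "complete") -> StageClustering:
    """Euclidean distances between standardized stage columns + agglomerative tree.

    ``D_AB = sqrt(sum_i (Y_iA - Y_iB)^2)`` over lines i, computed on columns
    standardized to zero mean and unit population variance.  Complete linkage
    by default; the linkage rule is recorded on the result.
    """
    if stage_matrix.shape[1] < 2 or stage_matrix.shape[0] < 2:
        raise ValueError("need >= 2 stages and >= 2 lines")
    z, imputed = standardize_stage_matrix(stage_matrix)
    pts = z.to_numpy().T  # stages as points in line-space
    condensed = pdist(pts, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=method)
    labels = list(stage_matrix.columns)
    dmat = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    return StageClustering(
        distances=dmat,
        linkage=Z,
        newick=_linkage_to_newick(Z, labels),
        method=method,
        imputed=imputed,
    )


def _cross_products(ya: np.ndarray, yb: np.ndarray) -> dict[str, float]:
    """Mean cross-products mirroring the EMS decomposition, for two traits."""
    n, e, r = ya.shape
    ga, gb = ya.mean(axis=(1, 2)), yb.mean(axis=(1, 2))
    ea_, eb_ = ya.mean(axis=(0, 2)), yb.mean(axis=(0, 2))
    lea, leb = ya.mean(axis=2), yb.mean(axis=2)
    grand_a, grand_b = ya.mean(), yb.mean()
    cp_g = e * r * np.sum((ga - grand_a) * (gb - grand_b)) / (n - 1)
    dev_a = lea - ga[:, None] - ea_[None, :] + grand_a
    dev_b = leb - gb[:, None] - eb_[None, :] + grand_b
    cp_ge = r * np.sum(dev_a * dev_b) / ((n - 1) * (e - 1)) if e > 1 else 0.0
    res_a = ya - lea[:, :, None]
    res_b = yb - leb[:, :, None]
    df_err = n * e * (r - 1)
    cp_eps = np.sum(res_a * res_b) / df_err if df_err > 0 else 0.0
    return {"MCP_G": cp_g, "MCP_GE": cp_ge, "MCP_eps": cp_eps}


def correlations(table: pd.DataFrame) -> CorrelationResult:
    """Phenotypic and genetic correlations between all stage pairs.

    r_p is the Pearson correlation of per-line means within each environment
    (also averaged across environments); r_g comes from method-of-moments
    genetic covariances, ``cov_g = (MCP_G - MCP_GE) / (r e)``, the multivariate
    analog of the EMS variance-component rules, truncated to [-1, 1].
    """
    stages = tuple(sorted(table["stage"].unique(), key=list(table["stage"]).index))
    envs = sorted(table["env"].unique())
    n_shared = table.groupby("stage")["line"].nunique().min()
    if n_shared < 3:
        raise ValueError("need >= 3 shared lines for correlations")

    per_env: dict[str, pd.DataFrame] = {}
    for ev in envs:
        sub = table[table["env"] == ev]
        wide = sub.pivot_table(index="line", columns="stage", values="value")[list(stages)]
        per_env[ev] = wide.corr()
    r_p = sum(per_env.values()) / len(per_env)

    # genetic correlations from the multi-environment replicated data
    s = len(stages)
    rg = np.eye(s)
    comps: dict[tuple[str, str], dict[str, float]] = {}
    ys = {}
    for st in stages:
        y, lines, _, _ = _check_balanced(table[table["stage"] == st].drop(columns="stage"))
        ys[st] = y
    e = next(iter(ys.values())).shape[1]
    r = next(iter(ys.values())).shape[2]
    var_g = {}
    for st in stages:
        cp = _cross_products(ys[st], ys[st])
        var_g[st] = max((cp["MCP_G"] - cp["MCP_GE"]) / (r * e), 0.0) if e > 1 else max(
            (cp["MCP_G"] - cp["MCP_eps"]) / r, 0.0
        )
    for i in range(s):
        for j in range(i + 1, s):
            a, b = stages[i], stages[j]
            cp = _cross_products(ys[a], ys[b])
            cov_g = (cp["MCP_G"] - cp["MCP_GE"]) / (r * e) if e > 1 else (
                cp["MCP_G"] - cp["MCP_eps"]
            ) / r
            denom = np.sqrt(var_g[a] * var_g[b])
            val = cov_g / denom if denom > 0 else np.nan
            val = float(np.clip(val, -1.0, 1.0)) if np.isfinite(val) else np.nan
            rg[i, j] = rg[j, i] = val
            comps[(a, b)] = {"cov_g": cov_g, "v_gA": var_g[a], "v_gB": var_g[b], **cp}
    r_g = pd.DataFrame(rg, index=list(stages), columns=list(stages))
    return CorrelationResult(
        stages=stages, r_p=r_p, r_p_by_env=per_env, r_g=r_g, components=comps
    )
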