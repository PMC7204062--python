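"""Composite interval mapping (CIM) for selfed RIL populations.

The scan is regression-based (Haley-Knott style): at each pseudo-marker
position the phenotype is regressed on the expected genotype dosage given the
flanking observed markers, plus background marker cofactors chosen by forward
selection and excluded within a window of the test position.  The LOD score is

    LOD = (n / 2) * log10(RSS_null / RSS_full)

where the null model contains the same cofactors but no dosage term.  Dosage
is coded -1/+1 for the two homozygote classes, so the fitted coefficient is
half the difference between homozygote means: a positive additive effect
means the parent-2 allele increases the trait.

Genome-wide significance comes from phenotype permutations (cofactors
re-selected per permutation); support intervals use the LOD-drop rule; QTL
from many stage x environment scans merge into pleiotropic QTL by transitive
physical-interval overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mapqc import MarkerMatrix
from .simulate import haldane_r, ril_expansion

__all__ = [
    "GenotypeProbGrid",
    "ScanResult",
    "QTLInterval",
    "PleiotropicQTL",
    "genotype_probabilities",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "call_qtl",
    "merge_pleiotropic",
    "qtl_name",
]

ENV_CODES = {"E1": "A", "E2": "B", "E3": "C"}
STAGE_CODES = {"V10": "a", "DTS": "b", "AS10": "c", "AS20": "d", "AS30": "e", "AS40": "f", "AS50": "g"}


@dataclass
class GenotypeProbGrid:
    """Pseudo-marker grid with P(parent-2 homozygote) per line x position.

    Also carries the observed marker dosages and map needed by the scan, so a
    grid is a self-contained scan context.
    """

    positions: pd.DataFrame  # chrom, pos_cM, pos_bp, at_marker
    prob2: np.ndarray  # (n_lines, n_positions)
    marker_map: pd.DataFrame  # marker, chrom, pos_cM, pos_bp
    marker_dosage: np.ndarray  # (n_lines, n_markers), -1/+1, mean-imputed
    lines: tuple[str, ...] = ()

    @property
    def dosage(self) -> np.ndarray:
        """Expected dosage on the -1/+1 scale."""
        return 2.0 * self.prob2 - 1.0

    @property
    def n_positions(self) -> int:
        return self.prob2.shape[1]


@dataclass
class ScanResult:
    positions: pd.DataFrame
    lod: np.ndarray
    effect: np.ndarray
    cofactors: list[str]
    cofactor_pos: pd.DataFrame | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if (self.lod < -1e-9).any():
            raise ValueError("LOD must be non-negative")
        self.lod = np.maximum(self.lod, 0.0)


@dataclass(frozen=True)
class QTLInterval:
    name: str
    chrom: int
    peak_cM: float
    peak_bp: int
    lod: float
    additive_effect: float
    pve: float
    ci_lo_cM: float
    ci_hi_cM: float
    ci_lo_bp: int
    ci_hi_bp: int

    def __post_init__(self) -> None:
        if not (self.ci_lo_cM <= self.peak_cM <= self.ci_hi_cM):
            raise ValueError("support interval must contain the peak")
        if not 0.0 <= self.pve <= 100.0:
            raise ValueError("PVE must lie in [0, 100]")


@dataclass(frozen=True)
class PleiotropicQTL:
    name: str
    chrom: int
    start_bp: int
    end_bp: int
    length_mb: float
    members: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.members)


def qtl_name(env: str, stage: str, population: str, chrom: int, index: int = 0) -> str:
    """QTL name code: q + environment letter + population letter + stage letter
    + chromosome number (e.g. qAhb1: environment A, high-oil population, DTS).

    ``env`` may be a raw environment label (mapped A/B/C in order) or already
    a single letter; ``stage`` likewise.  A trailing ``-k`` suffix
    disambiguates multiple QTL on one chromosome.
    """
    e = ENV_CODES.get(env, env if len(env) == 1 else env[-1])
    s = STAGE_CODES.get(stage, stage if len(stage) == 1 else stage[-1].lower())
    suffix = f"-{index}" if index else ""
    return f"q{e}{population}{s}{chrom}{suffix}"


def genotype_probabilities(
    linkage_map: pd.DataFrame,
    genotypes: MarkerMatrix,
    step_cM: float = 1.0,
) -> GenotypeProbGrid:
    """Conditional homozygote probabilities on a pseudo-marker grid.

    Two-state Markov interpolation: the transition probability across a gap of
    d cM is the RIL-expanded Haldane recombinant fraction R(d).  At an
    observed non-missing marker the observed class has probability 1; between
    markers the probability is the normalized product of the two transition
    terms.  Lines missing a flank use the nearest informative marker on that
    side; positions with no informative flank at all get probability 0.5.
    """
    lm = linkage_map.merge(genotypes.map[["marker"]], on="marker", how="inner")
    if lm.empty:
        raise ValueError("linkage map and genotypes share no markers")
    geno = genotypes.geno[lm["marker"].tolist()].to_numpy()
    geno = np.where(geno == 1.0, np.nan, geno)
    n = geno.shape[0]

    pos_rows = []
    prob_cols = []
    for ch in sorted(lm["chrom"].unique()):
        sel = (lm["chrom"] == ch).to_numpy()
        cm = lm.loc[sel, "pos_cM"].to_numpy()
        bp = lm.loc[sel, "pos_bp"].to_numpy()
        if len(cm) == 0:
            raise ValueError(f"empty chromosome {ch}")
        sub = geno[:, sel]
        grid = np.unique(np.concatenate([np.arange(cm[0], cm[-1] + 1e-9, step_cM), cm]))
        at_marker = np.isin(grid, cm)
        grid_bp = np.interp(grid, cm, bp)
        probs = np.full((n, len(grid)), 0.5)
        for i in range(n):
            inf = np.nonzero(~np.isnan(sub[i]))[0]
            if len(inf) == 0:
                continue
            mpos = cm[inf]
            state2 = (sub[i, inf] == 2.0).astype(float)  # 1 if parent-2
            ridx = np.searchsorted(mpos, grid, side="left")
            lidx = np.searchsorted(mpos, grid, side="right") - 1
            has_l = lidx >= 0
            has_r = ridx < len(mpos)
            dl = np.where(has_l, grid - mpos[np.clip(lidx, 0, None)], np.inf)
            dr = np.where(has_r, mpos[np.clip(ridx, None, len(mpos) - 1)] - grid, np.inf)
            Rl = ril_expansion(haldane_r(np.where(np.isfinite(dl), dl, 0.0)))
            Rr = ril_expansion(haldane_r(np.where(np.isfinite(dr), dr, 0.0)))
            sl = state2[np.clip(lidx, 0, None)]
            sr = state2[np.clip(ridx, None, len(mpos) - 1)]
            # P(transition keeps/changes state) across each side
            w2 = np.ones(len(grid))
            w0 = np.ones(len(grid))
            w2 *= np.where(has_l, np.where(sl == 1.0, 1 - Rl, Rl), 1.0)
            w0 *= np.where(has_l, np.where(sl == 0.0, 1 - Rl, Rl), 1.0)
            w2 *= np.where(has_r, np.where(sr == 1.0, 1 - Rr, Rr), 1.0)
            w0 *= np.where(has_r, np.where(sr == 0.0, 1 - Rr, Rr), 1.0)
            tot = w0 + w2
            probs[i] = np.where(tot > 0, w2 / tot, 0.5)
        prob_cols.append(probs)
        for g, b, am in zip(grid, grid_bp, at_marker):
            pos_rows.append({"chrom": ch, "pos_cM": float(g), "pos_bp": int(round(b)), "at_marker": bool(am)})

    positions = pd.DataFrame(pos_rows)
    prob2 = np.concatenate(prob_cols, axis=1)

    dos = genotypes.geno[lm["marker"].tolist()].to_numpy() - 1.0
    dos = np.where(np.isin(dos + 1.0, (0.0, 2.0)), dos, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    mmap = lm[["marker", "chrom", "pos_cM", "pos_bp"]].reset_index(drop=True)
    return GenotypeProbGrid(
        positions=positions,
        prob2=prob2,
        marker_map=mmap,
        marker_dosage=dos,
        lines=tuple(genotypes.geno.index),
    )


def select_cofactors(y: np.ndarray, grid: GenotypeProbGrid, n_cofactors: int) -> list[int]:
    """Forward stepwise selection of background marker cofactors.

    Greedy RSS reduction with proper orthogonalization against the current
    design (intercept included).  Returns marker indices into
    ``grid.marker_map``.
    """
    n = len(y)
    max_allowed = max(n // 10, 1)
    if n_cofactors > max_allowed:
        warnings.warn(
            f"n_cofactors {n_cofactors} exceeds n/10; truncated to {max_allowed}",
            stacklevel=2,
        )
        n_cofactors = max_allowed
    X = grid.marker_dosage
    Q = np.ones((n, 1)) / np.sqrt(n)
    resid_y = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    chosen: list[int] = []
    for _ in range(n_cofactors):
        norms = np.einsum("ij,ij->j", Xr, Xr)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(norms > 1e-12, (Xr.T @ resid_y) ** 2 / norms, -np.inf)
        score[chosen] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]) or score[j] <= 0:
            break
        chosen.append(j)
        q = Xr[:, j] / np.sqrt(norms[j])
        resid_y = resid_y - q * (q @ resid_y)
        Xr = Xr - np.outer(q, q @ Xr)
    return chosen


def cim_scan(
    phenotype: np.ndarray | pd.Series,
    grid: GenotypeProbGrid,
    n_cofactors: int = 5,
    window_cM: float = 10.0,
    cofactors: list[int] | None = None,
) -> ScanResult:
    """Composite interval mapping scan of one phenotype vector.

    With ``n_cofactors=0`` this reduces exactly to simple interval mapping.
    Pre-selected cofactor indices may be passed to skip re-selection.
    """
    y = np.asarray(phenotype, float)
    if cofactors is None:
        cofactors = select_cofactors(y, grid, n_cofactors) if n_cofactors > 0 else []
    n = len(y)
    D = grid.dosage
    pos = grid.positions
    cof_chrom = grid.marker_map["chrom"].to_numpy()[cofactors] if cofactors else np.empty(0, int)
    cof_cm = grid.marker_map["pos_cM"].to_numpy()[cofactors] if cofactors else np.empty(0)
    cof_X = grid.marker_dosage[:, cofactors] if cofactors else np.empty((n, 0))

    P = grid.n_positions
    lod = np.zeros(P)
    effect = np.zeros(P)
    pos_chrom = pos["chrom"].to_numpy()
    pos_cm = pos["pos_cM"].to_numpy()

    # active-cofactor mask per position -> group positions by identical masks
    if len(cofactors):
        excl = (pos_chrom[:, None] == cof_chrom[None, :]) & (
            np.abs(pos_cm[:, None] - cof_cm[None, :]) <= window_cM
        )
    else:
        excl = np.zeros((P, 0), dtype=bool)
    keys = [tuple(row) for row in ~excl]
    groups: dict[tuple, list[int]] = {}
    for p, k in enumerate(keys):
        groups.setdefault(k, []).append(p)

    for mask, idxs in groups.items():
        active = np.asarray(mask, bool)
        C = np.column_stack([np.ones(n), cof_X[:, active]]) if active.any() else np.ones((n, 1))
        Q, _ = np.linalg.qr(C)
        ry = y - Q @ (Q.T @ y)
        rss0 = float(ry @ ry)
        Dg = D[:, idxs]
        RD = Dg - Q @ (Q.T @ Dg)
        dn = np.einsum("ij,ij->j", RD, RD)
        dy = RD.T @ ry
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(dn > 1e-12, dy / dn, 0.0)
            rss1 = rss0 - np.where(dn > 1e-12, dy**2 / dn, 0.0)
        rss1 = np.maximum(rss1, 1e-300)
        lod[idxs] = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
        effect[idxs] = beta

    cof_names = grid.marker_map["marker"].to_numpy()[cofactors].tolist() if cofactors else []
    cof_pos = grid.marker_map.iloc[cofactors][["marker", "chrom", "pos_cM"]] if cofactors else None
    return ScanResult(positions=pos, lod=lod, effect=effect, cofactors=cof_names, cofactor_pos=cof_pos)


def permutation_threshold(
    phenotype: np.ndarray | pd.Series,
    grid: GenotypeProbGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    n_cofactors: int = 5,
    window_cM: float = 10.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The empirical (1 - alpha) quantile of the genome-wide maximum LOD over
    ``n_perm`` permutations of the phenotype; cofactors are re-selected for
    every permutation.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; threshold will be noisy", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    maxes = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        res = cim_scan(yp, grid, n_cofactors=n_cofactors, window_cM=window_cM)
        maxes[b] = res.lod.max()
    if alpha >= 1.0:
        return float(maxes.min())
    return float(np.quantile(maxes, 1.0 - alpha, method="higher"))


def call_qtl(
    scan: ScanResult,
    threshold: float,
    drop: float = 1.5,
    phenotype: np.ndarray | None = None,
    grid: GenotypeProbGrid | None = None,
    env: str = "E1",
    stage: str = "V10",
    population: str = "h",
) -> list[QTLInterval]:
    """Peaks above the threshold with LOD-drop support intervals and PVE.

    Peaks must be separated by at least the support-interval width or by a
    LOD valley below the threshold.  PVE comes from a single-QTL fit at the
    peak (requires ``phenotype`` and ``grid``; otherwise reported as the
    LOD-implied R^2 of the scan model).
    """
    out: list[QTLInterval] = []
    pos = scan.positions
    for ch in sorted(pos["chrom"].unique()):
        sel = (pos["chrom"] == ch).to_numpy()
        cm = pos.loc[sel, "pos_cM"].to_numpy()
        bp = pos.loc[sel, "pos_bp"].to_numpy()
        lod = scan.lod[sel].copy()
        eff = scan.effect[sel]
        available = lod > threshold
        while available.any():
            p = int(np.argmax(np.where(available, lod, -np.inf)))
            peak_lod = lod[p]
            lo = p
            while lo > 0 and lod[lo - 1] >= peak_lod - drop:
                lo -= 1
            hi = p
            while hi < len(lod) - 1 and lod[hi + 1] >= peak_lod - drop:
                hi += 1
            width = cm[hi] - cm[lo]
            if phenotype is not None and grid is not None:
                gsel = np.nonzero(sel)[0]
                x = grid.dosage[:, gsel[p]]
                yv = np.asarray(phenotype, float)
                X = np.column_stack([np.ones(len(yv)), x])
                beta, rss1, *_ = np.linalg.lstsq(X, yv, rcond=None)
                rss1 = float(rss1[0]) if len(rss1) else float(np.sum((yv - X @ beta) ** 2))
                rss0 = float(np.sum((yv - yv.mean()) ** 2))
                pve = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else 0.0
            else:
                n_eff = 200
                pve = float(100.0 * (1.0 - 10.0 ** (-2.0 * peak_lod / n_eff)))
            idx = len([q for q in out if q.chrom == ch]) + 1
            out.append(
                QTLInterval(
                    name=qtl_name(env, stage, population, int(ch), idx),
                    chrom=int(ch),
                    peak_cM=float(cm[p]),
                    peak_bp=int(bp[p]),
                    lod=float(peak_lod),
                    additive_effect=float(eff[p]),
                    pve=float(np.clip(pve, 0.0, 100.0)),
                    ci_lo_cM=float(cm[lo]),
                    ci_hi_cM=float(cm[hi]),
                    ci_lo_bp=int(bp[lo]),
                    ci_hi_bp=int(bp[hi]),
                )
            )
            # mask the support interval, its separation zone, and the rest of
            # this contiguous above-threshold segment
            seg_lo, seg_hi = p, p
            while seg_lo > 0 and lod[seg_lo - 1] > threshold:
                seg_lo -= 1
            while seg_hi < len(lod) - 1 and lod[seg_hi + 1] > threshold:
                seg_hi += 1
            near = (cm >= cm[lo] - max(width, 1e-9)) & (cm <= cm[hi] + max(width, 1e-9))
            seg = np.zeros_like(available)
            seg[seg_lo : seg_hi + 1] = True
            available &= ~(near | seg)
    # single-QTL-per-chromosome names drop the -k suffix
    renamed = []
    counts: dict[int, int] = {}
    for q in out:
        counts[q.chrom] = counts.get(q.chrom, 0) + 1
    for q in out:
        if counts[q.chrom] == 1:
            renamed.append(replace(q, name=q.name.rsplit("-", 1)[0]))
        else:
            renamed.append(q)
    return renamed


def merge_pleiotropic(qtl_lists: list[QTLInterval] | list[list[QTLInterval]]) -> list[PleiotropicQTL]:
    """Merge QTL whose physical support intervals chain-overlap.

    Per chromosome, intervals are sorted by start and merged transitively:
    A-B overlapping and B-C overlapping puts A, B, C in one pleiotropic QTL
    spanning the union, even if A and C are disjoint.  Physical length is
    (end - start) in Mb, rounded to 2 decimals.
    """
    flat: list[QTLInterval] = []
    for item in qtl_lists:
        if isinstance(item, QTLInterval):
            flat.append(item)
        else:
            flat.extend(item)
    out: list[PleiotropicQTL] = []
    by_chrom: dict[int, list[QTLInterval]] = {}
    for q in flat:
        by_chrom.setdefault(q.chrom, []).append(q)
    for ch in sorted(by_chrom):
        qs = sorted(by_chrom[ch], key=lambda q: (q.ci_lo_bp, q.ci_hi_bp))
        clusters: list[list[QTLInterval]] = []
        cur = [qs[0]]
        cur_end = qs[0].ci_hi_bp
        for q in qs[1:]:
            if q.ci_lo_bp <= cur_end:
                cur.append(q)
                cur_end = max(cur_end, q.ci_hi_bp)
            else:
                clusters.append(cur)
                cur = [q]
                cur_end = q.ci_hi_bp
        clusters.append(cur)
        multi = len(clusters) > 1
        for k, cl in enumerate(clusters, start=1):
            start = min(q.ci_lo_bp for q in cl)
            end = max(q.ci_hi_bp for q in cl)
            name = f"pQTL{ch}-{k}" if multi else f"pQTL{ch}"
            out.append(
                PleiotropicQTL(
                    name=name,
                    chrom=ch,
                    start_bp=start,
                    end_bp=end,
                    length_mb=round((end - start) / 1e6, 2),
                    members=tuple(q.name for q in cl),
                )
            )
    return out
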