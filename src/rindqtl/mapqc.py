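"""Marker QC, segregation tests, sliding-window bin calling, and Kosambi maps.

Works on a :class:`MarkerMatrix` (lines x markers parental codes 0/1/2/NaN
with physical positions).  Marker order is always taken from physical
coordinates; de-novo ordering is out of scope.  The linkage map applies the
inverse RIL expansion ``r = R / (2 (1 - R))`` to observed adjacent-marker
recombinant fractions before the Kosambi map function
``d = 25 ln((1 + 2r) / (1 - 2r))`` cM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerMatrix",
    "BinMap",
    "kosambi_d",
    "kosambi_r",
    "qc_filter",
    "segregation_test",
    "call_bins",
    "recombination_and_map",
]

VALID_CODES = (0.0, 1.0, 2.0)


@dataclass
class MarkerMatrix:
    """Lines x markers codes {0, 1, 2, NaN} plus marker chrom / pos_bp."""

    geno: pd.DataFrame
    map: pd.DataFrame  # columns marker, chrom, pos_bp [, pos_cM]

    def __post_init__(self) -> None:
        vals = self.geno.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, VALID_CODES)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} at line "
                f"{self.geno.index[i]!r}, marker {self.geno.columns[j]!r}"
            )
        if list(self.map["marker"]) != list(self.geno.columns):
            raise ValueError("map marker order must match genotype columns")
        for _, sub in self.map.groupby("chrom"):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise ValueError("pos_bp must be non-decreasing within each chromosome")

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    @property
    def missing_rate(self) -> pd.Series:
        return self.geno.isna().mean(axis=0)

    @property
    def maf(self) -> pd.Series:
        """Minor allele frequency; heterozygotes contribute half to each allele."""
        vals = self.geno.to_numpy()
        n_called = (~np.isnan(vals)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p2 = np.nansum(vals, axis=0) / (2 * n_called)  # freq of the parent-2 allele
        maf = np.minimum(p2, 1 - p2)
        return pd.Series(maf, index=self.geno.columns)

    def subset(self, markers: list[str]) -> "MarkerMatrix":
        keep = self.map["marker"].isin(markers)
        return MarkerMatrix(self.geno[markers], self.map[keep].reset_index(drop=True))


@dataclass
class BinMap:
    """Recombination bins tiling each chromosome, with representative columns."""

    bins: pd.DataFrame  # bin, chrom, start_bp, end_bp, n_markers
    geno: pd.DataFrame  # lines x bins parental codes
    members: dict[str, list[str]] = field(default_factory=dict)

    def as_marker_matrix(self) -> MarkerMatrix:
        """Bins re-expressed as a MarkerMatrix (bin midpoint as position)."""
        mp = pd.DataFrame(
            {
                "marker": self.bins["bin"],
                "chrom": self.bins["chrom"],
                "pos_bp": ((self.bins["start_bp"] + self.bins["end_bp"]) // 2).astype(np.int64),
            }
        )
        return MarkerMatrix(self.geno, mp)


def kosambi_d(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance in cM: d = 25 ln((1 + 2r) / (1 - 2r))."""
    r = np.asarray(r, float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("r must lie in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Inverse Kosambi map function: r = tanh(2 d / 100) / 2."""
    return 0.5 * np.tanh(2.0 * np.asarray(d_cM, float) / 100.0)


def qc_filter(
    matrix: MarkerMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Remove markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Both thresholds are strict inequalities, so boundary markers (exactly 20%
    missing, exactly 5% MAF) are retained.  Returns the filtered matrix and a
    per-marker report (missing_rate, maf, removed, reason).
    """
    miss = matrix.missing_rate
    maf = matrix.maf
    removed_miss = miss > max_missing
    removed_maf = maf < min_maf
    reason = np.where(
        removed_miss & removed_maf,
        "missing+maf",
        np.where(removed_miss, "missing", np.where(removed_maf, "maf", "")),
    )
    report = pd.DataFrame(
        {
            "marker": matrix.geno.columns,
            "missing_rate": miss.to_numpy(),
            "maf": maf.to_numpy(),
            "removed": (removed_miss | removed_maf).to_numpy(),
            "reason": reason,
        }
    )
    keep = report.loc[~report["removed"], "marker"].tolist()
    if not keep:
        raise ValueError("QC removed every marker")
    return matrix.subset(keep), report


def segregation_test(
    matrix: MarkerMatrix, alpha: float = 0.05
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Chi-square test of 1:1 parental segregation at every marker (df = 1).

    Heterozygote calls are excluded from the counts.  Markers with P < alpha
    (strict) are removed as distorted.  Raises if any marker has zero
    informative (homozygous) calls.
    """
    vals = matrix.geno.to_numpy()
    n0 = (vals == 0.0).sum(axis=0)
    n2 = (vals == 2.0).sum(axis=0)
    total = n0 + n2
    if (total == 0).any():
        bad = matrix.geno.columns[total == 0].tolist()
        raise ValueError(f"no informative homozygous calls at marker(s): {bad}")
    chi2 = (n0 - n2) ** 2 / total
    pval = stats.chi2.sf(chi2, df=1)
    removed = pval < alpha
    report = pd.DataFrame(
        {
            "marker": matrix.geno.columns,
            "n_parent1": n0,
            "n_parent2": n2,
            "chi2": chi2,
            "p_value": pval,
            "removed": removed,
        }
    )
    keep = report.loc[~report["removed"], "marker"].tolist()
    if not keep:
        raise ValueError("segregation test removed every marker")
    return matrix.subset(keep), report


def _window_calls(x: np.ndarray, window: int, vote: float) -> np.ndarray:
    """Majority-vote genotype call per sliding window (step 1) for one line.

    Returns an array of length m - window + 1 with values 0, 2, or NaN
    (ambiguous / uninformative).
    """
    is0 = (x == 0.0).astype(float)
    is2 = (x == 2.0).astype(float)
    k0 = np.convolve(is0, np.ones(window), mode="valid")
    k2 = np.convolve(is2, np.ones(window), mode="valid")
    tot = k0 + k2
    call = np.full(len(k0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac0 = np.where(tot > 0, k0 / tot, 0.0)
        frac2 = np.where(tot > 0, k2 / tot, 0.0)
    call[(tot > 0) & (frac0 >= vote)] = 0.0
    call[(tot > 0) & (frac2 >= vote)] = 2.0
    return call


def call_bins(
    matrix: MarkerMatrix,
    window_size: int = 15,
    step: int = 1,
    vote_threshold: float = 0.7,
) -> BinMap:
    """Sliding-window bin calling to absorb genotyping errors.

    Per line, windows of ``window_size`` physically consecutive SNPs are
    genotype-called by majority vote when the majority fraction among
    informative calls is >= ``vote_threshold`` (ambiguous otherwise);
    consecutive identical window calls merge, and a breakpoint is placed at
    the physical midpoint between the centers of the flanking informative
    windows where the call changes.  The union of breakpoints across lines
    delimits population-level bins; adjacent bins with identical population
    columns collapse.  Each bin's representative genotype per line is the
    majority vote of its member-marker calls.
    """
    if step != 1:
        raise NotImplementedError("only step=1 sliding windows are supported")
    all_bins = []
    geno_cols = {}
    members: dict[str, list[str]] = {}
    bin_no = 0
    for ch in sorted(matrix.map["chrom"].unique()):
        sel = matrix.map["chrom"] == ch
        mk = matrix.map.loc[sel, "marker"].tolist()
        bp = matrix.map.loc[sel, "pos_bp"].to_numpy()
        X = matrix.geno[mk].to_numpy()
        X = np.where(X == 1.0, np.nan, X)  # residual hets treated as missing
        n, m = X.shape
        w = window_size
        if w > m:
            warnings.warn(
                f"window_size {w} exceeds {m} markers on chromosome {ch}; "
                "using a single whole-chromosome window",
                stacklevel=2,
            )
            w = m
        centers = bp[np.arange(m - w + 1)] / 2 + bp[np.arange(w - 1, m)] / 2

        breakpoints: set[float] = set()
        for i in range(n):
            calls = _window_calls(X[i], w, vote_threshold)
            inf = np.nonzero(~np.isnan(calls))[0]
            if len(inf) < 2:
                continue
            change = np.nonzero(np.diff(calls[inf]) != 0)[0]
            for c in change:
                left, right = inf[c], inf[c + 1]
                breakpoints.add((centers[left] + centers[right]) / 2.0)

        edges = np.concatenate([[bp[0]], np.sort(np.fromiter(breakpoints, float)), [bp[-1] + 1]])
        # assign markers to half-open [edge, next_edge) intervals
        assign = np.clip(np.searchsorted(edges, bp, side="right") - 1, 0, len(edges) - 2)
        chrom_bins = []
        for b in range(len(edges) - 1):
            idx = np.nonzero(assign == b)[0]
            if len(idx) == 0:
                continue
            sub = X[:, idx]
            c0 = (sub == 0.0).sum(axis=1)
            c2 = (sub == 2.0).sum(axis=1)
            col = np.full(n, np.nan)
            col[c0 > c2] = 0.0
            col[c2 > c0] = 2.0
            chrom_bins.append(
                {
                    "chrom": ch,
                    "start_bp": int(bp[idx[0]]),
                    "end_bp": int(bp[idx[-1]]),
                    "col": col,
                    "markers": [mk[j] for j in idx],
                }
            )
        # collapse adjacent bins with identical population columns
        merged = [chrom_bins[0]]
        for nb in chrom_bins[1:]:
            prev = merged[-1]
            a, b_ = prev["col"], nb["col"]
            same = np.all((a == b_) | (np.isnan(a) & np.isnan(b_)))
            if same:
                prev["end_bp"] = nb["end_bp"]
                prev["markers"].extend(nb["markers"])
            else:
                merged.append(nb)
        for mb in merged:
            bin_no += 1
            name = f"bin{bin_no:04d}"
            all_bins.append(
                {
                    "bin": name,
                    "chrom": mb["chrom"],
                    "start_bp": mb["start_bp"],
                    "end_bp": mb["end_bp"],
                    "n_markers": len(mb["markers"]),
                }
            )
            geno_cols[name] = mb["col"]
            members[name] = mb["markers"]

    bins_df = pd.DataFrame(all_bins)
    geno_df = pd.DataFrame(geno_cols, index=matrix.geno.index)
    return BinMap(bins=bins_df, geno=geno_df, members=members)


def recombination_and_map(
    matrix: MarkerMatrix | BinMap, ril_correction: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kosambi linkage map from adjacent-pair recombinant fractions.

    For each physically adjacent marker (or bin) pair, the observed
    recombinant fraction R is the mismatch frequency among lines homozygous
    at both; the per-meiosis fraction is recovered by the inverse RIL
    expansion ``r = R / (2 (1 - R))`` (toggle with ``ril_correction``), capped
    at 0.4999, then converted to cM with the Kosambi function.  Returns the
    linkage map (marker, chrom, pos_bp, pos_cM) and a per-chromosome
    collinearity report (Spearman rank correlation between bp and cM orders).
    """
    if isinstance(matrix, BinMap):
        matrix = matrix.as_marker_matrix()
    rows = []
    collin = []
    for ch in sorted(matrix.map["chrom"].unique()):
        sel = matrix.map["chrom"] == ch
        mk = matrix.map.loc[sel, "marker"].tolist()
        bp = matrix.map.loc[sel, "pos_bp"].to_numpy()
        X = matrix.geno[mk].to_numpy()
        X = np.where(X == 1.0, np.nan, X)
        cum = 0.0
        rows.append({"marker": mk[0], "chrom": ch, "pos_bp": int(bp[0]), "pos_cM": 0.0})
        for j in range(1, len(mk)):
            a, b = X[:, j - 1], X[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() == 0:
                d = 0.0
            else:
                R = float(np.mean(a[ok] != b[ok]))
                if R >= 0.5:
                    warnings.warn(
                        f"adjacent recombinant fraction >= 0.5 between {mk[j - 1]} and "
                        f"{mk[j]}; capped",
                        stacklevel=2,
                    )
                    R = 0.49995
                r = R / (2.0 * (1.0 - R)) if ril_correction else R
                r = min(r, 0.4999)
                d = float(kosambi_d(r))
            cum += d
            rows.append({"marker": mk[j], "chrom": ch, "pos_bp": int(bp[j]), "pos_cM": cum})
        sub_cm = np.asarray([row["pos_cM"] for row in rows if row["chrom"] == ch])
        if len(mk) <= 2 or np.ptp(sub_cm) == 0:
            rho = np.nan if np.ptp(sub_cm) == 0 and len(mk) > 2 else 1.0
        else:
            rho = stats.spearmanr(bp, sub_cm).statistic
        collin.append({"chrom": ch, "length_cM": cum, "n_markers": len(mk), "spearman_bp_cM": rho})
    return pd.DataFrame(rows), pd.DataFrame(collin)
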