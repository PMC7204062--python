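"""Synthetic biparental RIL populations with known genetic architecture.

Generates the three inputs the rest of the pipeline consumes — a genetic map,
a lines x markers genotype matrix, and a long-format multi-stage /
multi-environment phenotype table — from a single :class:`SimConfig`, while
recording the ground truth (QTL positions and effects, crossover locations,
per-line genetic values, variance components) needed for recovery tests.

The meiosis model is Haldane: crossovers form a Poisson process on the
centimorgan scale with no interference, so the per-meiosis recombination
fraction over a gap of ``d`` cM is ``r = (1 - exp(-2 d / 100)) / 2``.  Selfing
to fixation inflates that to the observed RIL recombinant fraction
``R = 2 r / (1 + 2 r)``; the default "F-infinity" mode applies this expansion
directly as a two-state Markov chain along each chromosome, which is exact for
pairwise marker probabilities and fully vectorised.  An explicit
generation-by-generation selfing mode is available for validation.

Genotype coding: 0 = parent-1 homozygote, 2 = parent-2 homozygote,
1 = residual heterozygote (explicit mode only), NaN = missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STAGES = ("V10", "DTS", "AS10", "AS20", "AS30", "AS40", "AS50")

__all__ = [
    "STAGES",
    "ChromosomeSpec",
    "QTLSpec",
    "DistortionSpec",
    "SimConfig",
    "TrueArchitecture",
    "RILGenotypes",
    "default_stage_correlation",
    "haldane_r",
    "ril_expansion",
    "simulate_genetic_map",
    "simulate_ril_population",
    "inject_artifacts",
    "simulate_phenotypes",
]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Per-meiosis recombination fraction for a Haldane (no-interference) model."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def ril_expansion(r: np.ndarray | float) -> np.ndarray | float:
    """Observed recombinant fraction in a selfed RIL: R = 2r / (1 + 2r)."""
    r = np.asarray(r, float)
    return 2.0 * r / (1.0 + 2.0 * r)


def default_stage_correlation() -> np.ndarray:
    """Stage-stage genetic correlation emulating the field pattern.

    The five post-silking stages are tightly correlated (0.9), silking (DTS)
    moderately so (0.75), and the vegetative V10 stage is a weakly correlated
    outgroup (0.25-0.30).
    """
    c = np.full((7, 7), 0.9)
    np.fill_diagonal(c, 1.0)
    c[1, 2:] = c[2:, 1] = 0.75
    c[0, 1] = c[1, 0] = 0.30
    c[0, 2:] = c[2:, 0] = 0.25
    return c


@dataclass(frozen=True)
class ChromosomeSpec:
    length_cM: float
    length_bp: int
    n_markers: int


@dataclass(frozen=True)
class QTLSpec:
    """A simulated QTL: chromosome (1-based), position, per-stage additive effects.

    The additive effect is half the difference between the two homozygote
    classes on the phenotype scale (kg/mm^2); a positive value means the
    parent-2 allele increases the trait.
    """

    chrom: int
    pos_cM: float
    effects: tuple[float, ...]  # one entry per stage


@dataclass(frozen=True)
class DistortionSpec:
    """Segregation distortion at a locus: parent-1 transmission probability."""

    chrom: int
    pos_cM: float
    p1_frequency: float


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic RIL population.

    Defaults emulate a maize biparental RIL population phenotyped for rind
    penetrometer resistance at seven stages in two environments with two
    replicates: ~200 selfed lines, 10 chromosomes, grand mean ~4 kg/mm^2,
    per-stage broad-sense heritabilities spanning ~0.45-0.85 with the
    vegetative stage lowest.
    """

    n_lines: int = 200
    chromosomes: tuple[ChromosomeSpec, ...] = tuple(
        ChromosomeSpec(150.0, 150_000_000, 75) for _ in range(10)
    )
    selfing_generations: int = 8
    qtl: tuple[QTLSpec, ...] = ()
    stage_names: tuple[str, ...] = STAGES
    genetic_corr: np.ndarray = field(default_factory=default_stage_correlation)
    h2_target: tuple[float, ...] | None = (0.45, 0.70, 0.80, 0.85, 0.85, 0.80, 0.75)
    n_envs: int = 2
    n_reps: int = 2
    mean: float = 4.0
    env_effects: tuple[float, ...] = (0.0, 0.35)
    polygenic_sd: float | tuple[float, ...] = 0.35
    gxe_sd: float | tuple[float, ...] = 0.25
    residual_sd: float | tuple[float, ...] = 0.4
    rep_sd: float = 0.0
    missing_rate: float = 0.0
    distortion: tuple[DistortionSpec, ...] = ()
    marker_spacing: str = "even"  # "even" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, float)
        self.validate()

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for c in self.chromosomes:
            if c.length_cM < 0 or c.length_bp <= 0:
                raise ValueError(f"non-positive chromosome length: {c}")
            if c.n_markers < 2:
                raise ValueError("each chromosome needs >= 2 markers")
        s = len(self.stage_names)
        g = self.genetic_corr
        if g.shape != (s, s):
            raise ValueError("genetic_corr shape must match stage count")
        if not np.allclose(g, g.T) or not np.allclose(np.diag(g), 1.0):
            raise ValueError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(g).min() < -1e-8:
            raise ValueError("genetic_corr must be positive semi-definite")
        if self.h2_target is not None:
            if len(self.h2_target) != s:
                raise ValueError("h2_target needs one value per stage")
            if not all(0.0 <= h <= 1.0 for h in self.h2_target):
                raise ValueError("h2_target values must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.env_effects) != self.n_envs:
            raise ValueError("env_effects needs one value per environment")
        for q in self.qtl:
            if len(q.effects) != s:
                raise ValueError("QTL effects need one value per stage")
            if not 1 <= q.chrom <= len(self.chromosomes):
                raise ValueError(f"QTL chromosome {q.chrom} out of range")
            if not 0 <= q.pos_cM <= self.chromosomes[q.chrom - 1].length_cM:
                raise ValueError("QTL position outside chromosome")
        if self.marker_spacing not in ("even", "random"):
            raise ValueError("marker_spacing must be 'even' or 'random'")

    def per_stage(self, value: float | Sequence[float]) -> np.ndarray:
        v = np.asarray(value, float)
        if v.ndim == 0:
            v = np.full(len(self.stage_names), float(v))
        if v.shape != (len(self.stage_names),):
            raise ValueError("per-stage parameter has wrong length")
        return v


@dataclass
class TrueArchitecture:
    """Ground truth recorded while simulating, for recovery tests."""

    qtl: tuple[QTLSpec, ...]
    # crossovers[line][chrom] -> sorted array of crossover positions (cM)
    crossovers: list[list[np.ndarray]]
    # initial parental state (0 or 2) at the start of each chromosome
    initial_state: np.ndarray  # (n_lines, n_chrom)
    genetic_values: pd.DataFrame | None = None  # lines x stages (g_i)
    gxe_values: np.ndarray | None = None  # (n_lines, n_envs, n_stages)
    variance_components: dict | None = None

    def genotype_at(self, chrom: int, pos_cM: float) -> np.ndarray:
        """Parental code (0/2) of every line at an arbitrary map position."""
        n = len(self.crossovers)
        out = np.empty(n, dtype=float)
        for i in range(n):
            flips = int(np.searchsorted(self.crossovers[i][chrom - 1], pos_cM))
            state = self.initial_state[i, chrom - 1]
            out[i] = state if flips % 2 == 0 else 2 - state
        return out


@dataclass
class RILGenotypes:
    """Lines x markers parental-code matrix plus its physical/genetic map."""

    geno: pd.DataFrame  # index = line IDs, columns = marker IDs, float codes
    map: pd.DataFrame  # columns marker, chrom, pos_bp, pos_cM

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def copy(self) -> "RILGenotypes":
        return RILGenotypes(self.geno.copy(), self.map.copy())


def simulate_genetic_map(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Build a marker map: columns marker, chrom, pos_bp, pos_cM.

    Markers are evenly spaced or uniform-at-random (``config.marker_spacing``)
    with the first and last markers pinned to the chromosome ends, so each
    chromosome's map length equals its configured length exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for ci, c in enumerate(config.chromosomes, start=1):
        m = c.n_markers
        if config.marker_spacing == "even":
            cm = np.linspace(0.0, c.length_cM, m)
            bp = np.linspace(1, c.length_bp, m).round().astype(np.int64)
        else:
            cm = np.sort(rng.uniform(0.0, c.length_cM, m))
            cm[0], cm[-1] = 0.0, c.length_cM
            bp = np.sort(rng.uniform(1, c.length_bp, m)).round().astype(np.int64)
            bp[0], bp[-1] = 1, c.length_bp
            bp = np.maximum.accumulate(bp)
        for j in range(m):
            rows.append((f"m{ci:02d}_{j + 1:04d}", ci, int(bp[j]), float(cm[j])))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "pos_cM"])


def _simulate_chrom_finf(
    cm: np.ndarray, n_lines: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """F-infinity Markov chain along one chromosome.

    Returns (codes n_lines x m in {0,2}, initial states, crossover lists).
    """
    m = len(cm)
    gaps = np.diff(cm)
    R = ril_expansion(haldane_r(gaps))
    init = rng.integers(0, 2, size=n_lines) * 2  # 0 or 2
    switches = rng.random((n_lines, m - 1)) < R[None, :]
    parity = np.concatenate(
        [np.zeros((n_lines, 1), dtype=int), np.cumsum(switches, axis=1) % 2], axis=1
    )
    codes = np.where(parity == 0, init[:, None], 2 - init[:, None]).astype(float)
    # crossover positions: one per switched interval, uniform within the gap
    xovers: list[np.ndarray] = []
    u = rng.random((n_lines, m - 1))
    for i in range(n_lines):
        idx = np.nonzero(switches[i])[0]
        xovers.append(np.sort(cm[idx] + u[i, idx] * gaps[idx]))
    return codes, init, xovers


def _meiosis(hom1: tuple[np.ndarray, np.ndarray], hom2, length_cM: float, rng):
    """One gamete from a pair of homolog mosaics.

    A mosaic is (breakpoints ascending within (0, L), labels of len+1 segments).
    """
    n_xo = rng.poisson(length_cM / 100.0)
    xo = np.sort(rng.uniform(0.0, length_cM, n_xo))
    cur = int(rng.integers(0, 2))
    breaks: list[float] = []
    labels: list[int] = []
    bounds = np.concatenate([[0.0], xo, [length_cM]])
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        b, l = (hom1, hom2)[cur]
        i0 = int(np.searchsorted(b, lo, side="right"))
        i1 = int(np.searchsorted(b, hi, side="left"))
        piece_bounds = [lo, *b[i0:i1]]
        piece_labels = l[i0 : i1 + 1]
        for j, lab in enumerate(piece_labels):
            if labels and labels[-1] == lab:
                continue  # merge with previous identical segment
            if labels:
                breaks.append(piece_bounds[j])
            labels.append(int(lab))
        cur = 1 - cur
    return np.asarray(breaks), np.asarray(labels)


def _simulate_chrom_selfing(
    cm: np.ndarray, n_lines: int, generations: int, length_cM: float, rng
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Explicit selfing: F1 het, then `generations` rounds of self-pollination."""
    m = len(cm)
    codes = np.empty((n_lines, m), float)
    init = np.zeros(n_lines, dtype=int)
    xovers: list[np.ndarray] = []

    def eval_mosaic(mos, pos):
        b, l = mos
        return np.asarray([l[int(np.searchsorted(b, p, side="right"))] for p in pos])

    for i in range(n_lines):
        h1 = (np.asarray([]), np.asarray([0]))  # parent-1 chromosome
        h2 = (np.asarray([]), np.asarray([1]))  # parent-2 chromosome
        for _ in range(generations):
            g1 = _meiosis(h1, h2, length_cM, rng)
            g2 = _meiosis(h1, h2, length_cM, rng)
            h1, h2 = g1, g2
        a1 = eval_mosaic(h1, cm)
        a2 = eval_mosaic(h2, cm)
        codes[i] = a1 + a2  # 0, 1 (het), or 2
        init[i] = int(codes[i, 0]) if codes[i, 0] in (0.0, 2.0) else 0
        flips = np.nonzero(np.diff(codes[i]) != 0)[0]
        xovers.append((cm[flips] + cm[flips + 1]) / 2.0)
    return codes, init, xovers


def simulate_ril_population(
    genetic_map: pd.DataFrame,
    n_lines: int,
    selfing_generations: int = 8,
    seed: int | np.random.Generator = 0,
    mode: str = "finf",
    distortion: Sequence[DistortionSpec] = (),
) -> tuple[RILGenotypes, TrueArchitecture]:
    """Simulate a selfed biparental RIL population on a given map.

    ``mode="finf"`` (default) draws fully homozygous lines from the two-state
    Markov chain with RIL-expanded recombinant fractions; ``mode="selfing"``
    runs explicit generation-by-generation selfing (residual heterozygotes
    coded 1).  Distortion is applied by rejection: lines are resampled until
    the configured parent-1 transmission frequency holds in expectation at the
    distorted locus, which preserves linkage structure around it.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(genetic_map["chrom"].unique())
    all_codes = []
    init_all = np.zeros((n_lines, len(chroms)), dtype=int)
    xovers: list[list[np.ndarray]] = [[] for _ in range(n_lines)]
    dist_by_chrom = {}
    for d in distortion:
        dist_by_chrom.setdefault(d.chrom, []).append(d)

    for k, ch in enumerate(chroms):
        sub = genetic_map[genetic_map["chrom"] == ch]
        cm = sub["pos_cM"].to_numpy()
        length = float(cm[-1])

        def draw(n):
            if mode == "finf":
                return _simulate_chrom_finf(cm, n, rng)
            elif mode == "selfing":
                return _simulate_chrom_selfing(cm, n, selfing_generations, length, rng)
            raise ValueError(f"unknown mode {mode!r}")

        specs = dist_by_chrom.get(ch, [])
        if not specs:
            codes, init, xo = draw(n_lines)
        else:
            # rejection sampling against the distorted locus
            spec = specs[0]
            p1 = spec.p1_frequency
            keep_p1 = min(1.0, p1 / (1.0 - p1)) if p1 < 0.5 else 1.0
            keep_p2 = min(1.0, (1.0 - p1) / p1) if p1 > 0.5 else 1.0
            kept_codes, kept_init, kept_xo = [], [], []
            n_have = 0
            while n_have < n_lines:
                c, ini, xo_ = draw(n_lines)
                mi = int(np.argmin(np.abs(cm - spec.pos_cM)))
                is_p1 = c[:, mi] == 0
                acc = np.where(is_p1, rng.random(len(c)) < keep_p1, rng.random(len(c)) < keep_p2)
                for i in np.nonzero(acc)[0]:
                    if n_have >= n_lines:
                        break
                    kept_codes.append(c[i])
                    kept_init.append(ini[i])
                    kept_xo.append(xo_[i])
                    n_have += 1
            codes = np.asarray(kept_codes)
            init = np.asarray(kept_init)
            xo = kept_xo
        all_codes.append(codes)
        init_all[:, k] = init
        for i in range(n_lines):
            xovers[i].append(xo[i])

    geno = np.concatenate(all_codes, axis=1)
    lines = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    gdf = pd.DataFrame(geno, index=lines, columns=genetic_map["marker"].tolist())
    arch = TrueArchitecture(qtl=(), crossovers=xovers, initial_state=init_all)
    return RILGenotypes(gdf, genetic_map.copy()), arch


def inject_artifacts(
    genotypes: RILGenotypes,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> RILGenotypes:
    """Return a copy with i.i.d. missingness and parental-code flips injected.

    The input object is never modified. Errors flip homozygote codes 0 <-> 2;
    heterozygotes are left alone.  Missingness is applied after errors.
    """
    if not 0.0 <= missing_rate < 1.0 or not 0.0 <= error_rate < 1.0:
        raise ValueError("rates must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = genotypes.copy()
    vals = out.geno.to_numpy(copy=True)
    if error_rate > 0:
        flip = (rng.random(vals.shape) < error_rate) & np.isin(vals, (0.0, 2.0))
        vals[flip] = 2.0 - vals[flip]
    if missing_rate > 0:
        miss = rng.random(vals.shape) < missing_rate
        vals[miss] = np.nan
    out.geno = pd.DataFrame(vals, index=out.geno.index, columns=out.geno.columns)
    return out


def simulate_phenotypes(
    genotypes: RILGenotypes,
    architecture: TrueArchitecture,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw phenotypes from y_ijk = mu + g_i + e_j + ge_ij + r_k(j) + eps_ijk.

    Per-stage genetic values are the sum of configured QTL contributions
    (evaluated at the true mosaic positions) and a polygenic value drawn with
    the configured stage correlation matrix.  When ``config.h2_target`` is
    set, the per-stage residual SD is solved from the heritability identity
    H2 = s2_g / (s2_g + s2_ge/e + s2_eps/(r e)) using the realized genetic
    variance; otherwise ``config.residual_sd`` is used as given.

    Returns a long-format table (line, env, stage, rep, value) and stores the
    ground truth on ``architecture``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = genotypes.n_lines
    stages = list(config.stage_names)
    s = len(stages)
    e, r = config.n_envs, config.n_reps

    poly_sd = config.per_stage(config.polygenic_sd)
    gxe_sd = config.per_stage(config.gxe_sd)

    # polygenic values with the target stage correlation
    corr = config.genetic_corr
    # eigen square root tolerates semi-definite matrices (e.g. duplicated stages)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w))
    poly = rng.standard_normal((n, s)) @ root.T * poly_sd[None, :]

    qtl_part = np.zeros((n, s))
    for q in config.qtl:
        x = architecture.genotype_at(q.chrom, q.pos_cM) - 1.0  # -1 / +1
        qtl_part += x[:, None] * np.asarray(q.effects)[None, :]
    g = qtl_part + poly

    var_g = g.var(axis=0, ddof=1)
    var_ge = gxe_sd**2
    if config.h2_target is not None:
        h2 = np.asarray(config.h2_target, float)
        var_eps = r * e * (var_g * (1.0 - h2) / np.where(h2 > 0, h2, np.inf)) - r * var_ge
        var_eps = np.clip(var_eps, 0.0, None)
    else:
        var_eps = config.per_stage(config.residual_sd) ** 2
    eps_sd = np.sqrt(var_eps)

    env_eff = np.asarray(config.env_effects, float)
    rep_eff = rng.normal(0.0, config.rep_sd, size=(e, r)) if config.rep_sd > 0 else np.zeros((e, r))
    ge = rng.normal(0.0, 1.0, size=(n, e, s)) * gxe_sd[None, None, :]
    eps = rng.normal(0.0, 1.0, size=(n, e, s, r)) * eps_sd[None, None, :, None]

    y = (
        config.mean
        + g[:, None, :, None]
        + env_eff[None, :, None, None]
        + ge[:, :, :, None]
        + rep_eff[None, :, None, :]
        + eps
    )

    lines = genotypes.geno.index.to_numpy()
    idx = pd.MultiIndex.from_product(
        [lines, [f"E{j + 1}" for j in range(e)], stages, list(range(1, r + 1))],
        names=["line", "env", "stage", "rep"],
    )
    table = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()

    architecture.qtl = tuple(config.qtl)
    architecture.genetic_values = pd.DataFrame(g, index=lines, columns=stages)
    architecture.gxe_values = ge
    architecture.variance_components = {
        "var_g": var_g,
        "var_ge": var_ge,
        "var_eps": var_eps,
        "var_rep": config.rep_sd**2,
        "mean": config.mean,
        "env_effects": env_eff,
    }
    return table
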