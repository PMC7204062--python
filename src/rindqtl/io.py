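"""Delimited-text file formats, config parsing, and run manifests.

All pipeline artifacts are tab-separated text or JSON so every run is
diffable.  NA tokens "NA", "" and "-" parse as missing.  Readers validate
codes, coordinate monotonicity, and duplicate IDs, and name the offending
file/row/field on failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mapqc import MarkerMatrix
from .simulate import ChromosomeSpec, DistortionSpec, QTLSpec, RILGenotypes, SimConfig

NA_TOKENS = ["NA", "", "-"]

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "load_sim_config",
    "write_manifest",
    "file_digest",
]


def write_genotypes(path: str | Path, geno: pd.DataFrame) -> None:
    out = geno.copy()
    out.index.name = "line"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotypes(path: str | Path, map_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Lines x markers genotype table with 0/1/2/NA codes."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path.name}: duplicate line IDs: {dup[:5]}")
    vals = df.to_numpy(dtype=object)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            v = vals[i, j]
            if v is np.nan or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}: row {i + 2}: non-numeric genotype {v!r} "
                    f"for marker {df.columns[j]!r}"
                ) from None
            if fv not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"{path.name}: row {i + 2}: invalid genotype code {v!r} "
                    f"for marker {df.columns[j]!r} (allowed: 0/1/2/NA)"
                )
    return df.astype(float)


def write_map(path: str | Path, map_df: pd.DataFrame) -> None:
    map_df.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> pd.DataFrame:
    """Marker map table: marker, chrom, pos_bp [, pos_cM]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_TOKENS, keep_default_na=False)
    need = {"marker", "chrom", "pos_bp"}
    if need - set(df.columns):
        raise ValueError(f"{path.name}: map requires columns {sorted(need)}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"{path.name}: duplicate marker IDs: {dup[:5]}")
    for col in ("pos_bp", "pos_cM"):
        if col in df.columns:
            for ch, sub in df.groupby("chrom"):
                if not sub[col].is_monotonic_increasing:
                    bad = sub.index[sub[col].diff() < 0][0]
                    raise ValueError(
                        f"{path.name}: row {bad + 2}: {col} not monotone on chromosome {ch}"
                    )
    return df


def write_phenotypes(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-format phenotype table: line, env, stage, rep, value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_TOKENS, keep_default_na=False)
    need = {"line", "env", "stage", "rep", "value"}
    if need - set(df.columns):
        raise ValueError(f"{path.name}: phenotype table requires columns {sorted(need)}")
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
    if len(bad):
        raise ValueError(f"{path.name}: row {bad[0] + 2}: non-numeric value {df.loc[bad[0], 'value']!r}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).info(
            "%s: %d missing phenotype values (design may be unbalanced)", path.name, n_missing
        )
    return df


def read_marker_matrix(geno_path: str | Path, map_path: str | Path) -> MarkerMatrix:
    geno = read_genotypes(geno_path)
    mp = read_map(map_path)
    order = mp["marker"].tolist()
    missing = set(order) - set(geno.columns)
    if missing:
        raise ValueError(f"markers in map but not in genotypes: {sorted(missing)[:5]}")
    return MarkerMatrix(geno[order], mp)


def load_sim_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Parse a YAML/JSON SimConfig file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs: dict = {}
    if "n_lines" in raw:
        kwargs["n_lines"] = int(raw["n_lines"])
    if "chromosomes" in raw:
        kwargs["chromosomes"] = tuple(
            ChromosomeSpec(float(c["length_cM"]), int(c["length_bp"]), int(c["n_markers"]))
            for c in raw["chromosomes"]
        )
    if "qtl" in raw:
        kwargs["qtl"] = tuple(
            QTLSpec(int(q["chrom"]), float(q["pos_cM"]), tuple(float(x) for x in q["effects"]))
            for q in raw["qtl"]
        )
    if "distortion" in raw:
        kwargs["distortion"] = tuple(
            DistortionSpec(int(d["chrom"]), float(d["pos_cM"]), float(d["p1_frequency"]))
            for d in raw["distortion"]
        )
    for key in (
        "selfing_generations",
        "stage_names",
        "genetic_corr",
        "h2_target",
        "n_envs",
        "n_reps",
        "mean",
        "env_effects",
        "polygenic_sd",
        "gxe_sd",
        "residual_sd",
        "rep_sd",
        "missing_rate",
        "marker_spacing",
        "seed",
    ):
        if key in raw:
            v = raw[key]
            if isinstance(v, list):
                v = tuple(v) if key != "genetic_corr" else np.asarray(v, float)
            kwargs[key] = v
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SimConfig(**kwargs)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    params: dict,
    inputs: dict[str, str | Path] | None = None,
    config_snapshot: dict | None = None,
) -> Path:
    """Write a run manifest sufficient to reproduce the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "parameters": _jsonable(params),
        "inputs": {k: {"path": str(v), "sha256_16": file_digest(v)} for k, v in (inputs or {}).items()},
        "config": _jsonable(config_snapshot) if config_snapshot else None,
    }
    path = out_dir / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
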