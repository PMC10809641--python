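"""Readers and writers for the plain-text formats used across the pipeline.

Coordinate conventions
----------------------
Internally every position is 0-based; intervals are half-open ``[start, end)``.
Probe-manifest TSVs follow the array-manifest convention of 1-based positions
and are converted on ingest (and back on write). BED and WGBS tables are
0-based natively.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError

MANIFEST_COLUMNS = ["cpg_id", "chrom", "pos", "gene"]
WGBS_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples beta matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise DataError(f"empty beta matrix: {path}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise DataError(f"missing beta values are not permitted (e.g. features {bad})")
    values = df.to_numpy(dtype=float)
    if values.min() < 0.0 or values.max() > 1.0:
        raise DataError("beta values must lie in [0, 1]")
    if df.index.duplicated().any():
        raise DataError("duplicate feature ids in beta matrix")
    return df


def write_beta_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest; positions are converted from 1-based to 0-based.

    Returns a frame indexed by ``cpg_id`` with columns ``chrom``, ``pos``
    (0-based) and ``gene`` (semicolon-joined symbols, empty string if
    unannotated).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} lacks columns: {missing}")
    df = df.set_index("cpg_id")
    if df.index.duplicated().any():
        raise DataError("duplicate cpg ids in manifest")
    df["pos"] = df["pos"].astype(int) - 1
    if (df["pos"] < 0).any():
        raise DataError("manifest positions must be >= 1 (1-based)")
    df["gene"] = df["gene"].fillna("").astype(str)
    return df[["chrom", "pos", "gene"]]


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write an internal (0-based) manifest as a 1-based TSV."""
    out = manifest.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index_label="cpg_id")


def manifest_genes(manifest: pd.DataFrame) -> pd.Series:
    """Per-CpG tuple of gene symbols (may be empty)."""
    return manifest["gene"].map(
        lambda g: tuple(s for s in str(g).split(";") if s) if g else ()
    )


# ---------------------------------------------------------------------------
# phenotypes / generic tables
# ---------------------------------------------------------------------------

def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise DataError(f"phenotype table {path} lacks a sample_id column")
    return df.set_index("sample_id")


def write_phenotype_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# WGBS counts
# ---------------------------------------------------------------------------

def read_wgbs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in WGBS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"WGBS table {path} lacks columns: {missing}")
    if (df["total_count"] < 1).any():
        raise DataError("WGBS rows with zero total count must be omitted")
    if (df["meth_count"] > df["total_count"]).any() or (df["meth_count"] < 0).any():
        raise DataError("need 0 <= meth_count <= total_count")
    return df[WGBS_COLUMNS]


def write_wgbs_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions (BED + detail TSV)
# ---------------------------------------------------------------------------

def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write classified regions as BED: name=LMR|UMR, score=round(1000*mean_meth)."""
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            name = row.get("region_class", "region")
            score = int(round(1000 * float(row["mean_methylation"]))) if "mean_methylation" in row else 0
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{name}\t{score}\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed BED line: {line!r}")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["region_class"] = parts[3]
            if len(parts) > 4:
                row["mean_methylation"] = int(parts[4]) / 1000.0
            rows.append(row)
    return pd.DataFrame(rows)


def write_regions_tsv(regions: pd.DataFrame, path: str | Path) -> None:
    regions.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_regions_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise DataError(f"region table {path} lacks column {col}")
    return df


# ---------------------------------------------------------------------------
# blocklist / GMT / RNK
# ---------------------------------------------------------------------------

def read_blocklist(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_blocklist(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(probes):
            fh.write(f"{p}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name TAB description TAB member TAB member ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed GMT line (need name, description, >=1 member): {line[:80]!r}")
            name = parts[0]
            if name in sets:
                raise DataError(f"duplicate gene-set name in GMT: {name}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise DataError(f"empty gene set in GMT: {name}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"], comment="#")
    s = pd.Series(df["weight"].to_numpy(dtype=float), index=df["gene"].astype(str))
    if s.index.duplicated().any():
        raise DataError("duplicate genes in RNK file")
    return s


def write_rnk(ranking: pd.Series, path: str | Path) -> None:
    ranking.to_csv(path, sep="\t", header=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
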