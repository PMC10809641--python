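"""Low-methylated-region calling from WGBS-like count data.

A deliberately transparent segmentation: pooled-count smoothing, cutoff
thresholding into maximal runs, CpG-count classification into LMR vs UMR,
and a permutation-based FDR calibration of the (cutoff, min-CpG) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, DataError

REGION_COLUMNS = ["chrom", "start", "end", "n_cpgs", "mean_methylation", "region_class"]


@dataclass
class Methylome:
    """Ordered per-CpG counts: columns chrom, pos, meth_count, total_count."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "pos", "meth_count", "total_count"):
            if col not in t.columns:
                raise DataError(f"methylome table lacks column {col}")
        if (t["total_count"] < 1).any():
            raise DataError("retained CpGs must have total_count >= 1")
        if ((t["meth_count"] < 0) | (t["meth_count"] > t["total_count"])).any():
            raise DataError("need 0 <= meth_count <= total_count")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise DataError(f"positions not strictly increasing on {chrom}")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grp = self.table[self.table["chrom"] == chrom]
        return (
            grp["pos"].to_numpy(dtype=int),
            grp["meth_count"].to_numpy(dtype=float),
            grp["total_count"].to_numpy(dtype=float),
        )


@dataclass
class SegmentationParams:
    meth_cutoff: float = 0.5
    min_cpgs: int = 4
    smoothing_window: int = 3
    lmr_max_cpgs: int = 30
    fdr_target: float = 0.05
    n_shuffles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.meth_cutoff < 1:
            raise ConfigurationError("meth_cutoff must be in (0, 1)")
        if self.min_cpgs < 1:
            raise ConfigurationError("min_cpgs must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigurationError("smoothing_window must be odd and >= 1")
        if not 0 < self.fdr_target < 1:
            raise ConfigurationError("fdr_target must be in (0, 1)")
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")


def _smooth_arrays(meth: np.ndarray, total: np.ndarray, window: int) -> np.ndarray:
    """Pooled windowed fraction: (sum meth)/(sum total) over a centered window
    of `window` CpGs, truncated at the ends."""
    half = window // 2
    n = meth.size
    csum_m = np.concatenate(([0.0], np.cumsum(meth)))
    csum_t = np.concatenate(([0.0], np.cumsum(total)))
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum_m[hi] - csum_m[lo]) / (csum_t[hi] - csum_t[lo])


def smooth_methylation(methylome: Methylome, window: int = 3) -> dict[str, np.ndarray]:
    """Per-chromosome smoothed methylation fractions (see `_smooth_arrays`)."""
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 1")
    out = {}
    for chrom in methylome.chromosomes():
        _, meth, total = methylome.chrom_arrays(chrom)
        if meth.size == 0:
            warnings.warn(f"chromosome {chrom} has no CpGs; skipped")
            continue
        out[chrom] = _smooth_arrays(meth, total, window)
    return out


def segment_hypomethylated(
    methylome: Methylome, params: SegmentationParams
) -> pd.DataFrame:
    """Maximal runs of >= min_cpgs consecutive CpGs with smoothed level < cutoff.

    Region start = first member CpG position; end = last member CpG + 1
    (half-open). ``mean_methylation`` pools raw counts over member CpGs.
    Returned regions are unclassified (``region_class`` = "").
    """
    rows = []
    for chrom in methylome.chromosomes():
        pos, meth, total = methylome.chrom_arrays(chrom)
        if pos.size == 0:
            continue
        level = _smooth_arrays(meth, total, params.smoothing_window)
        below = level < params.meth_cutoff
        # run boundaries of the boolean mask
        padded = np.concatenate(([False], below, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < params.min_cpgs:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[s]),
                    "end": int(pos[e - 1]) + 1,
                    "n_cpgs": int(e - s),
                    "mean_methylation": float(meth[s:e].sum() / total[s:e].sum()),
                    "region_class": "",
                }
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def classify_segments(regions: pd.DataFrame, lmr_max_cpgs: int = 30) -> pd.DataFrame:
    """LMR if n_cpgs <= lmr_max_cpgs (inclusive boundary), else UMR."""
    out = regions.copy()
    out["region_class"] = np.where(out["n_cpgs"] <= lmr_max_cpgs, "LMR", "UMR")
    return out


def _permute_methylome(methylome: Methylome, rng: np.random.Generator) -> Methylome:
    """Shuffle (meth,total) pairs across positions within each chromosome."""
    parts = []
    for chrom in methylome.chromosomes():
        grp = methylome.table[methylome.table["chrom"] == chrom]
        perm = rng.permutation(len(grp))
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "meth_count": grp["meth_count"].to_numpy()[perm],
                    "total_count": grp["total_count"].to_numpy()[perm],
                }
            )
        )
    return Methylome(pd.concat(parts, ignore_index=True))


def calibrate_fdr(
    methylome: Methylome,
    params: SegmentationParams,
    m_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6),
    n_grid: tuple[int, ...] = (3, 4, 5, 6),
) -> tuple[float, int, pd.DataFrame]:
    """Select the least stringent (cutoff m, min-CpGs n) with estimated FDR
    <= ``params.fdr_target``.

    FDR estimate per grid point = mean segment count over within-chromosome
    permutations / observed segment count, capped at 1 (1.0 when nothing is
    observed). "Least stringent" = largest cutoff m (admits more CpGs) among
    passing points, then smallest n (admits shorter runs).
    """
    rng = np.random.default_rng(params.seed)
    nulls = [_permute_methylome(methylome, rng) for _ in range(params.n_shuffles)]

    records = []
    any_observed = False
    for m in m_grid:
        for n in n_grid:
            p = SegmentationParams(
                meth_cutoff=m,
                min_cpgs=n,
                smoothing_window=params.smoothing_window,
                lmr_max_cpgs=params.lmr_max_cpgs,
                fdr_target=params.fdr_target,
                n_shuffles=params.n_shuffles,
                seed=params.seed,
            )
            observed = len(segment_hypomethylated(methylome, p))
            null_mean = float(np.mean([len(segment_hypomethylated(nm, p)) for nm in nulls]))
            if observed > 0:
                any_observed = True
                fdr = min(1.0, null_mean / observed)
            else:
                fdr = 1.0
            records.append(
                {"m": m, "n": n, "observed": observed, "null_mean": null_mean, "fdr": fdr}
            )
    table = pd.DataFrame(records)
    if not any_observed:
        raise CalibrationError("no segments observed at any grid point")
    passing = table[table["fdr"] <= params.fdr_target]
    if passing.empty:
        raise CalibrationError(
            f"no grid point achieves FDR <= {params.fdr_target} "
            f"(best {table['fdr'].min():.3f})"
        )
    best = passing.sort_values(
        ["m", "n"], ascending=[False, True], kind="stable"
    ).iloc[0]
    return float(best["m"]), int(best["n"]), table


def intersect_with_probes(
    regions: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Keep LMR-class regions containing >= 1 manifest CpG; UMRs excluded.

    Raises on chromosome names present in regions but absent from the
    manifest (coordinate-system mismatch guard).
    """
    manifest_chroms = set(manifest["chrom"])
    region_chroms = set(regions["chrom"])
    unknown = sorted(region_chroms - manifest_chroms)
    if unknown:
        raise DataError(f"region chromosomes absent from manifest: {unknown}")

    chrom_positions = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in manifest.groupby("chrom", sort=False)
    }
    lmrs = regions[regions["region_class"] == "LMR"]
    keep = []
    for i, r in lmrs.iterrows():
        pos = chrom_positions[r["chrom"]]
        lo = np.searchsorted(pos, int(r["start"]), side="left")
        hi = np.searchsorted(pos, int(r["end"]), side="left")
        keep.append(hi > lo)
    kept = lmrs[np.asarray(keep, dtype=bool)] if len(lmrs) else lmrs
    report = {
        "n_lmr_in": int(len(lmrs)),
        "n_umr_excluded": int((regions["region_class"] == "UMR").sum()),
        "n_dropped_no_probe": int(len(lmrs) - len(kept)),
        "n_kept": int(len(kept)),
    }
    return kept.reset_index(drop=True), report
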