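"""Probe filtering, quantile normalization and CpG-to-LMR aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

DETECTION_P_DEFAULT = 0.01


@dataclass
class BetaMatrix:
    """Features x samples methylation fractions in [0, 1].

    ``feature_level`` records whether rows are single CpGs or LMR averages.
    """

    values: pd.DataFrame
    feature_level: str = "cpg"

    def __post_init__(self) -> None:
        if self.feature_level not in ("cpg", "lmr"):
            raise DataError(f"unknown feature_level: {self.feature_level}")
        if self.values.index.duplicated().any():
            raise DataError("duplicate feature ids in beta matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def validate(self) -> "BetaMatrix":
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise DataError("missing beta values are not permitted")
        if arr.min() < 0 or arr.max() > 1:
            raise DataError("beta values must lie in [0, 1]")
        return self


@dataclass
class ProbeQC:
    """Per-probe detection p-values plus a probe blocklist.

    ``detection_p`` is probes x samples; a probe fails QC if its detection p
    exceeds ``detection_threshold`` in ANY sample, or if it is blocklisted.
    """

    detection_p: pd.DataFrame
    blocklist: set[str] = field(default_factory=set)
    detection_threshold: float = DETECTION_P_DEFAULT

    def __post_init__(self) -> None:
        arr = self.detection_p.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise DataError("detection p-values must lie in [0, 1]")


def filter_probes(beta: BetaMatrix, qc: ProbeQC) -> tuple[BetaMatrix, dict]:
    """Drop probes failing detection p in any sample or on the blocklist.

    Returns the filtered matrix (probe order preserved) and a removal report
    with counts per reason. Probes flagged by both rules count once, under
    ``detection_p`` (checked first).
    """
    missing = beta.feature_ids.difference(qc.detection_p.index)
    if len(missing):
        raise DataError(
            f"{len(missing)} probes in beta absent from detection-p table "
            f"(e.g. {missing[:5].tolist()})"
        )
    detp = qc.detection_p.loc[beta.feature_ids]
    fails_detp = (detp > qc.detection_threshold).any(axis=1).to_numpy()
    blocked = beta.feature_ids.isin(qc.blocklist)
    keep = ~fails_detp & ~blocked
    report = {
        "n_input": int(len(beta.feature_ids)),
        "n_kept": int(keep.sum()),
        "removed_detection_p": int(fails_detp.sum()),
        "removed_blocklist": int((blocked & ~fails_detp).sum()),
        "detection_threshold": float(qc.detection_threshold),
    }
    out = BetaMatrix(values=beta.values.loc[keep], feature_level=beta.feature_level)
    return out, report


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Full quantile normalization across samples.

    After normalization every sample's sorted value vector equals the
    across-sample mean of order statistics; within-sample ranks are
    preserved; tied values receive the mean of their tied reference
    quantiles.
    """
    if beta.values.empty:
        raise DataError("cannot quantile-normalize an empty matrix")
    arr = beta.values.to_numpy(dtype=float)
    n_feat, n_samp = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.take_along_axis(arr, order, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(n_samp):
        col = arr[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = reference.copy()
        # average reference values over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_feat]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[idx, j] = assigned
    return BetaMatrix(
        values=pd.DataFrame(out, index=beta.values.index, columns=beta.values.columns),
        feature_level=beta.feature_level,
    )


def lmr_average(
    beta: BetaMatrix, regions: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[BetaMatrix, dict]:
    """Average CpG betas within each region to one LMR-level feature.

    Regions overlapping zero CpGs in ``beta`` are dropped (count reported).
    Output feature ids are ``chrom:start-end``; value per sample is the
    unweighted mean over member CpGs.
    """
    if beta.feature_level != "cpg":
        raise DataError("lmr_average expects a CpG-level matrix")
    missing = beta.feature_ids.difference(manifest.index)
    if len(missing):
        raise DataError(
            f"{len(missing)} CpGs in beta absent from manifest (e.g. {missing[:5].tolist()})"
        )
    coords = manifest.loc[beta.feature_ids, ["chrom", "pos"]]
    rows = []
    ids = []
    n_dropped = 0
    chrom_positions = {}
    for chrom, grp in coords.groupby("chrom", sort=False):
        pos = grp.sort_values("pos", kind="stable")
        chrom_positions[chrom] = (pos["pos"].to_numpy(), pos.index.to_numpy())

    for _, r in regions.iterrows():
        chrom = r["chrom"]
        if chrom not in chrom_positions:
            n_dropped += 1
            continue
        pos, cpg_ids = chrom_positions[chrom]
        lo = np.searchsorted(pos, int(r["start"]), side="left")
        hi = np.searchsorted(pos, int(r["end"]), side="left")
        if hi <= lo:
            n_dropped += 1
            continue
        members = cpg_ids[lo:hi]
        rows.append(beta.values.loc[members].mean(axis=0))
        ids.append(f"{chrom}:{int(r['start'])}-{int(r['end'])}")
    report = {"n_regions_in": int(len(regions)), "n_regions_dropped": n_dropped, "n_features_out": len(ids)}
    if not ids:
        raise DataError("no region overlaps any CpG in the beta matrix")
    out = BetaMatrix(
        values=pd.DataFrame(rows, index=pd.Index(ids, name="lmr_id")),
        feature_level="lmr",
    )
    return out, report
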