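"""Gene rankings, preranked set enrichment, and the cross-source consensus.

Three ranking arms feed the enrichment: clock coefficients summed per gene,
per-CpG methylation-vs-prediction correlations averaged per gene, and
expression-vs-prediction correlations. Enrichment uses the weighted
Kolmogorov-Smirnov running-sum statistic with a gene-label permutation null
and sign-conditional NES normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import ClockModel
from .errors import DataError, RankingError
from .evaluate import pearson_test
from .io import manifest_genes
from .preprocess import BetaMatrix

P_CUT_DEFAULT = 0.05
N_PERM_DEFAULT = 1000
TOP_K_DEFAULT = 20


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    es: float
    nes: float | None
    p_value: float | None
    n_perm: int
    source: str = ""

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "set_size": self.set_size,
            "es": self.es,
            "nes": self.nes,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "source": self.source,
        }


def _sort_ranking(weights: dict[str, float], source_tag: str) -> pd.Series:
    if not weights:
        raise RankingError(f"empty gene ranking for source {source_tag!r}")
    s = pd.Series(weights, dtype=float)
    if s.isna().any():
        raise RankingError("NaN weights in gene ranking")
    # stable sort: weight descending, gene id ascending on ties
    s = s.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    s.attrs["source_tag"] = source_tag
    s.index.name = "gene"
    s.name = "weight"
    return s


def _feature_gene_map(
    model: ClockModel, manifest: pd.DataFrame, regions: pd.DataFrame | None
) -> list[tuple[str, tuple[str, ...]]]:
    """Per retained model feature, the deduplicated genes of its member CpGs."""
    genes = manifest_genes(manifest)
    if model.feature_level == "cpg":
        out = []
        for fid in model.feature_ids:
            if fid not in genes.index:
                raise DataError(f"model feature {fid} absent from manifest")
            out.append((fid, genes[fid]))
        return out
    if regions is None:
        raise DataError("LMR-level models need the region table to map member CpGs")
    chrom_sorted = {}
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        chrom_sorted[chrom] = (pos[order], grp.index.to_numpy()[order])
    out = []
    for fid in model.feature_ids:
        chrom, span = fid.split(":")
        start, end = (int(v) for v in span.split("-"))
        pos, ids = chrom_sorted.get(chrom, (np.array([]), np.array([])))
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        member_genes = tuple(dict.fromkeys(g for cid in ids[lo:hi] for g in genes[cid]))
        out.append((fid, member_genes))
    return out


def rank_from_coefficients(
    model: ClockModel,
    manifest: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    source_tag: str = "coefficient",
) -> pd.Series:
    """Gene weight = sum of coefficients of features annotated to the gene.

    Each feature's coefficient goes once to every distinct gene of its member
    CpGs; unannotated features are dropped.
    """
    weights: dict[str, float] = {}
    n_unannotated = 0
    for (fid, gene_tuple), coef in zip(
        _feature_gene_map(model, manifest, regions), model.coefficients
    ):
        if not gene_tuple:
            n_unannotated += 1
            continue
        for g in gene_tuple:
            weights[g] = weights.get(g, 0.0) + float(coef)
    if n_unannotated:
        warnings.warn(f"{n_unannotated} features without gene annotation dropped")
    return _sort_ranking(weights, source_tag)


def rank_from_methylation_correlation(
    beta: BetaMatrix,
    predictions: pd.Series,
    manifest: pd.DataFrame,
    p_cut: float = P_CUT_DEFAULT,
    source_tag: str = "methylation_correlation",
) -> pd.Series:
    """Per-CpG Pearson r against the predictions, p>p_cut discarded, then
    gene weight = mean r over the gene's surviving CpGs."""
    if beta.values.shape[1] < 3:
        raise DataError("need at least 3 samples for correlation ranking")
    pred = predictions.loc[beta.values.columns].to_numpy(dtype=float)
    genes = manifest_genes(manifest)
    arr = beta.values.to_numpy(dtype=float)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for i, fid in enumerate(beta.values.index):
        row = arr[i]
        if np.ptp(row) == 0:
            continue
        r, p = pearson_test(row, pred)
        if p > p_cut:
            continue
        if fid not in genes.index:
            raise DataError(f"CpG {fid} absent from manifest")
        for g in genes[fid]:
            sums[g] = sums.get(g, 0.0) + r
            counts[g] = counts.get(g, 0) + 1
    weights = {g: sums[g] / counts[g] for g in sums}
    return _sort_ranking(weights, source_tag)


def rank_from_expression_correlation(
    tpm: pd.DataFrame,
    predictions: pd.Series,
    p_cut: float = P_CUT_DEFAULT,
    source_tag: str = "expression_correlation",
) -> pd.Series:
    """Gene expression vs prediction Pearson ranking (duplicate gene rows
    averaged after the p-filter)."""
    if tpm.shape[1] < 3:
        raise DataError("need at least 3 samples for correlation ranking")
    pred = predictions.loc[tpm.columns].to_numpy(dtype=float)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    arr = tpm.to_numpy(dtype=float)
    for i, gene in enumerate(tpm.index):
        row = arr[i]
        if np.ptp(row) == 0:
            continue
        r, p = pearson_test(row, pred)
        if p > p_cut:
            continue
        sums[gene] = sums.get(gene, 0.0) + r
        counts[gene] = counts.get(gene, 0) + 1
    weights = {g: sums[g] / counts[g] for g in sums}
    return _sort_ranking(weights, source_tag)


def enrichment_score(
    ranking: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted KS running-sum enrichment score.

    Walking the ranking top to bottom, hits add |weight|^exponent (normalized
    to sum 1 over the set), misses subtract 1/(N - set size). ES is the
    running-sum value of maximal absolute deviation from zero (signed).
    Returns (ES, running sum, hit indices).
    """
    genes = ranking.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n = genes.size
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise DataError("gene set does not intersect the ranking")
    if n_hit == n:
        raise DataError("degenerate gene set: covers the entire ranking")
    w = np.abs(ranking.to_numpy(dtype=float)) ** weight_exponent
    hit_mass = w * in_set
    denom = hit_mass.sum()
    if denom == 0:
        # all hit weights zero: fall back to unweighted hits
        hit_mass = in_set.astype(float)
        denom = hit_mass.sum()
    step = hit_mass / denom - (~in_set) / (n - n_hit)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[i_max], -1.0, 1.0))
    return es, running, np.flatnonzero(in_set)


def permutation_null(
    ranking: pd.Series,
    gene_set,
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float | None, float | None, float]:
    """Gene-label permutation null for one set: returns (NES, nominal p, ES).

    Null ES values come from random same-size gene sets drawn from the
    ranking. NES = ES / mean |null ES| over null values sharing ES's sign;
    nominal p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign).
    NES/p are None when no null value shares the sign (reported, not dropped).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    genes = ranking.index.to_numpy()
    restricted = [g for g in gene_set if g in set(genes)]
    size = len(restricted)
    es, _, _ = enrichment_score(ranking, restricted, weight_exponent)
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        fake = genes[rng.choice(genes.size, size=size, replace=False)]
        null_es[i], _, _ = enrichment_score(ranking, fake, weight_exponent)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if same_sign.size == 0:
        return None, None, es
    nes = es / np.abs(same_sign).mean()
    p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    return float(nes), float(p), es


def score_collection(
    ranking: pd.Series,
    collection: dict[str, list[str]],
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    weight_exponent: float = 1.0,
    source: str = "",
) -> list[EnrichmentResult]:
    """Score every set in a collection against one ranking."""
    results = []
    gene_universe = set(ranking.index)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(collection))
    for set_seed, (name, members) in zip(seeds, sorted(collection.items())):
        restricted = [g for g in members if g in gene_universe]
        if not restricted:
            warnings.warn(f"gene set {name} does not intersect ranking; skipped")
            continue
        if len(restricted) == len(gene_universe):
            warnings.warn(f"gene set {name} covers the entire ranking; skipped")
            continue
        nes, p, es = permutation_null(
            ranking, restricted, n_perm=n_perm, seed=int(set_seed),
            weight_exponent=weight_exponent,
        )
        results.append(
            EnrichmentResult(
                set_name=name, set_size=len(restricted), es=es, nes=nes,
                p_value=p, n_perm=n_perm, source=source,
            )
        )
    return results


def truncate_top(results: list[EnrichmentResult], top_k: int = TOP_K_DEFAULT) -> list[EnrichmentResult]:
    """Keep the top_k results by |NES| (ties: nominal p, then set name)."""
    scored = [r for r in results if r.nes is not None]
    scored.sort(key=lambda r: (-abs(r.nes), r.p_value, r.set_name))
    return scored[:top_k]


def run_preranked(
    rankings: dict[str, pd.Series],
    collection: dict[str, list[str]],
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    top_k: int = TOP_K_DEFAULT,
    weight_exponent: float = 1.0,
) -> tuple[dict[str, list[EnrichmentResult]], dict[str, list[EnrichmentResult]]]:
    """Score the collection against every ranking source.

    Returns (truncated per-source top lists, full untruncated tables).
    """
    if not rankings:
        raise DataError("need at least one ranking")
    if not collection:
        raise DataError("need at least one gene set")
    full: dict[str, list[EnrichmentResult]] = {}
    top: dict[str, list[EnrichmentResult]] = {}
    # one shared seed: identical rankings must yield identical tables
    for source, ranking in rankings.items():
        results = score_collection(
            ranking, collection, n_perm=n_perm, seed=seed,
            weight_exponent=weight_exponent, source=source,
        )
        full[source] = results
        top[source] = truncate_top(results, top_k)
    return top, full


def consensus(
    per_source_results: dict[str, list[EnrichmentResult]],
    min_sources: int = 1,
) -> pd.DataFrame:
    """Cross-source overlap table.

    Pathways appearing in at least ``min_sources`` of the (truncated) source
    lists are retained with their support count and mean |NES| over
    supporting sources, sorted by mean |NES| descending (ties by name).
    """
    k = len(per_source_results)
    if k < 1:
        raise DataError("need at least one source")
    if min_sources > k:
        raise DataError(f"min_sources={min_sources} exceeds the {k} sources")
    support: dict[str, list[float]] = {}
    sizes: dict[str, int] = {}
    for results in per_source_results.values():
        for r in results:
            if r.nes is None:
                continue
            support.setdefault(r.set_name, []).append(abs(r.nes))
            sizes[r.set_name] = r.set_size
    rows = [
        {
            "pathway": name,
            "n_sources": len(vals),
            "mean_abs_nes": float(np.mean(vals)),
            "set_size": sizes[name],
        }
        for name, vals in support.items()
        if len(vals) >= min_sources
    ]
    df = pd.DataFrame(rows, columns=["pathway", "n_sources", "mean_abs_nes", "set_size"])
    return df.sort_values(
        ["mean_abs_nes", "pathway"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
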