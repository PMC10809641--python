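"""Synthetic cohort generator.

Produces beta matrices with planted low-methylated regions and
progression-linked CpGs, multi-rater phenotype panels, WGBS-like count data
and expression matrices — everything downstream stages consume, with known
ground truth, so the whole pipeline is testable without restricted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError
from .preprocess import BetaMatrix

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "RatingsTable",
    "simulate_cohort",
    "simulate_panel_ratings",
    "simulate_wgbs",
    "simulate_expression",
    "make_gene_set_collection",
    "write_cohort",
]

#: scale bounds for panel-rated wrinkle grades
WRINKLE_SCALE = (1.0, 100.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the design of the study the pipeline emulates: ~30 raters
    with per-subject rating SDs near 11.85 (wrinkle scale) and 6.55 years
    (visual age), WGBS coverage averaging 14x, ages spanning 29-84 years.
    """

    n_subjects: int = 300
    n_cpgs: int = 2000
    n_lmrs: int = 40
    lmr_cpg_range: tuple[int, int] = (5, 15)
    n_signal_features: int = 50
    effect_size: float = 0.01
    n_age_features: int = 50
    age_effect_size: float = 0.008
    age_range: tuple[float, float] = (29.0, 84.0)
    progression_sd: float = 4.0
    age_coupling: float = 0.0
    rater_count: int = 30
    rater_sd_wrinkle: float = 11.85
    rater_sd_age: float = 6.55
    wgbs_mean_coverage: float = 14.0
    beta_noise_sd: float = 0.02
    wrinkle_slope: float = 1.0
    wrinkle_intercept: float = 0.0
    wrinkle_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_cpgs", "n_lmrs", "rater_count"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.lmr_cpg_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("lmr_cpg_range must satisfy 1 <= min <= max")
        if self.n_signal_features < 0:
            raise ConfigurationError("n_signal_features must be >= 0")
        if self.n_age_features < 0:
            raise ConfigurationError("n_age_features must be >= 0")
        if self.rater_sd_wrinkle < 0 or self.rater_sd_age < 0:
            raise ConfigurationError("rater SDs must be >= 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must satisfy min < max")
        if self.wgbs_mean_coverage <= 0:
            raise ConfigurationError("wgbs_mean_coverage must be > 0")
        if self.beta_noise_sd < 0:
            raise ConfigurationError("beta_noise_sd must be >= 0")
        # every planted LMR needs at least one background CpG on each side
        if self.n_cpgs < self.n_lmrs * (self.lmr_cpg_range[1] + 2):
            raise ConfigurationError(
                "n_cpgs too small to host n_lmrs regions of lmr_cpg_range size"
            )


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort (per subject + planted features)."""

    chronological_age: np.ndarray
    true_progression: np.ndarray
    true_visual_age: np.ndarray
    true_wrinkle: np.ndarray
    signal_feature_ids: list[str]
    planted_lmr_regions: pd.DataFrame  # chrom, start, end, n_cpgs
    age_feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.true_visual_age - self.chronological_age, self.true_progression
        ):
            raise ConfigurationError(
                "visual age minus chronological age must equal progression exactly"
            )

    def to_dict(self) -> dict:
        return {
            "chronological_age": self.chronological_age.tolist(),
            "true_progression": self.true_progression.tolist(),
            "true_visual_age": self.true_visual_age.tolist(),
            "true_wrinkle": self.true_wrinkle.tolist(),
            "signal_feature_ids": list(self.signal_feature_ids),
            "planted_lmr_regions": self.planted_lmr_regions.to_dict(orient="list"),
            "age_feature_ids": list(self.age_feature_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        return cls(
            chronological_age=np.asarray(d["chronological_age"], dtype=float),
            true_progression=np.asarray(d["true_progression"], dtype=float),
            true_visual_age=np.asarray(d["true_visual_age"], dtype=float),
            true_wrinkle=np.asarray(d["true_wrinkle"], dtype=float),
            signal_feature_ids=list(d["signal_feature_ids"]),
            planted_lmr_regions=pd.DataFrame(d["planted_lmr_regions"]),
            age_feature_ids=list(d.get("age_feature_ids", [])),
        )


@dataclass
class RatingsTable:
    """Per-subject panel ratings with their mean and SD."""

    ratings: np.ndarray  # subjects x raters
    mean: np.ndarray
    sd: np.ndarray


def simulate_panel_ratings(
    truth: np.ndarray,
    rater_count: int,
    rater_sd: float,
    seed: int,
    clip_range: tuple[float, float] | None = None,
) -> RatingsTable:
    """Simulate an expert panel: i.i.d. Gaussian rater noise around truth.

    The reported phenotype is the mean over raters; the per-subject SD over
    raters is returned alongside. ``clip_range`` bounds individual ratings
    (use ``WRINKLE_SCALE`` for the 1-100 wrinkle scale).
    """
    if rater_count < 1:
        raise ConfigurationError("rater_count must be >= 1")
    if rater_sd < 0:
        raise ConfigurationError("rater_sd must be >= 0")
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    ratings = truth[:, None] + rng.normal(0.0, rater_sd, size=(truth.size, rater_count))
    if clip_range is not None:
        ratings = np.clip(ratings, *clip_range)
    return RatingsTable(
        ratings=ratings, mean=ratings.mean(axis=1), sd=ratings.std(axis=1, ddof=1) if rater_count > 1 else np.zeros(truth.size)
    )


def _build_manifest(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out CpGs on two chromosomes and plant LMR index windows.

    Returns (manifest frame, planted-region frame, per-CpG in-LMR mask).
    """
    n = cfg.n_cpgs
    sizes = rng.integers(cfg.lmr_cpg_range[0], cfg.lmr_cpg_range[1] + 1, cfg.n_lmrs)
    # carve the CpG index space into n_lmrs equal blocks; drop each run at a
    # random offset inside its block, leaving >=1 background CpG on both sides
    block = n // cfg.n_lmrs
    starts = []
    for i, size in enumerate(sizes):
        lo = i * block + 1
        hi = (i + 1) * block - int(size) - 1
        if hi < lo:
            raise ConfigurationError("n_cpgs too small for requested LMR layout")
        starts.append(int(rng.integers(lo, hi + 1)))
    in_lmr = np.zeros(n, dtype=bool)
    lmr_index = np.full(n, -1, dtype=int)
    for k, (s, size) in enumerate(zip(starts, sizes)):
        in_lmr[s : s + size] = True
        lmr_index[s : s + size] = k

    gaps = rng.integers(50, 301, size=n)
    half = n // 2
    chroms = np.where(np.arange(n) < half, "chr1", "chr2")
    pos = np.empty(n, dtype=int)
    pos[:half] = 1000 + np.cumsum(gaps[:half])
    pos[half:] = 1000 + np.cumsum(gaps[half:])

    pool_size = max(20, n // 10)
    gene_pool = np.array([f"GENE{i:04d}" for i in range(pool_size)])
    n_genes_per_cpg = rng.choice([0, 1, 2], size=n, p=[0.2, 0.6, 0.2])
    genes = []
    for k in n_genes_per_cpg:
        if k == 0:
            genes.append("")
        else:
            picks = rng.choice(pool_size, size=k, replace=False)
            genes.append(";".join(gene_pool[picks]))

    manifest = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "gene": genes},
        index=pd.Index([f"cg{i:07d}" for i in range(n)], name="cpg_id"),
    )

    regions = []
    for k in range(cfg.n_lmrs):
        members = np.flatnonzero(lmr_index == k)
        regions.append(
            {
                "chrom": chroms[members[0]],
                "start": int(pos[members[0]]),
                "end": int(pos[members[-1]]) + 1,
                "n_cpgs": int(members.size),
            }
        )
    return manifest, pd.DataFrame(regions), in_lmr


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (beta matrix, phenotype table, manifest, truth).

    Construction:

    * CpGs inside planted LMRs get low baselines (uniform 0.05-0.25), the
      background high baselines (uniform 0.65-0.95).
    * ``n_signal_features`` CpGs drawn from LMR members get their beta shifted
      by ``effect_size * true_progression`` per subject (then clipped); a
      disjoint set of ``n_age_features`` background CpGs is shifted by
      ``age_effect_size * (age - age-range midpoint)``.
    * Phenotypes are panel means over ``rater_count`` noisy raters.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_truth, rng_beta, ss_wr, ss_va = ss.spawn(5)
    rng = np.random.default_rng(rng_layout)
    manifest, planted, in_lmr = _build_manifest(cfg, rng)

    lmr_members = np.flatnonzero(in_lmr)
    if cfg.n_signal_features > lmr_members.size:
        raise ConfigurationError(
            f"n_signal_features={cfg.n_signal_features} exceeds the "
            f"{lmr_members.size} LMR-overlapping CpGs"
        )
    signal_idx = np.sort(rng.choice(lmr_members, size=cfg.n_signal_features, replace=False))
    signal_ids = manifest.index[signal_idx].tolist()
    background = np.setdiff1d(np.flatnonzero(~in_lmr), signal_idx)
    if cfg.n_age_features > background.size:
        raise ConfigurationError("n_age_features exceeds the background CpG count")
    age_idx = np.sort(rng.choice(background, size=cfg.n_age_features, replace=False))
    age_ids = manifest.index[age_idx].tolist()

    rng_t = np.random.default_rng(rng_truth)
    age = rng_t.uniform(*cfg.age_range, size=cfg.n_subjects)
    midpoint = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    progression = rng_t.normal(0.0, cfg.progression_sd, size=cfg.n_subjects)
    progression += cfg.age_coupling * (age - midpoint)
    visual = age + progression
    progression = visual - age  # re-derive so the identity is float-exact
    wrinkle = cfg.wrinkle_intercept + cfg.wrinkle_slope * visual
    wrinkle = wrinkle + rng_t.normal(0.0, cfg.wrinkle_noise_sd, size=cfg.n_subjects)
    wrinkle = np.clip(wrinkle, *WRINKLE_SCALE)

    truth = CohortTruth(
        chronological_age=age,
        true_progression=progression,
        true_visual_age=visual,
        true_wrinkle=wrinkle,
        signal_feature_ids=signal_ids,
        planted_lmr_regions=planted,
        age_feature_ids=age_ids,
    )

    rng_b = np.random.default_rng(rng_beta)
    baseline = np.where(
        in_lmr,
        rng_b.uniform(0.05, 0.25, size=cfg.n_cpgs),
        rng_b.uniform(0.65, 0.95, size=cfg.n_cpgs),
    )
    values = np.tile(baseline[:, None], (1, cfg.n_subjects))
    values[signal_idx, :] += cfg.effect_size * progression[None, :]
    values[age_idx, :] += cfg.age_effect_size * (age[None, :] - midpoint)
    if cfg.beta_noise_sd > 0:
        values = values + rng_b.normal(0.0, cfg.beta_noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_subjects)]
    beta = BetaMatrix(
        values=pd.DataFrame(values, index=manifest.index, columns=sample_ids),
        feature_level="cpg",
    )

    wr_panel = simulate_panel_ratings(
        wrinkle, cfg.rater_count, cfg.rater_sd_wrinkle,
        seed=ss_wr.generate_state(1)[0], clip_range=WRINKLE_SCALE,
    )
    va_panel = simulate_panel_ratings(
        visual, cfg.rater_count, cfg.rater_sd_age, seed=ss_va.generate_state(1)[0]
    )
    phenotypes = pd.DataFrame(
        {
            "chronological_age": age,
            "wrinkle_grade": wr_panel.mean,
            "visual_age": va_panel.mean,
            "wrinkle_panel_sd": wr_panel.sd,
            "visual_age_panel_sd": va_panel.sd,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return beta, phenotypes, manifest, truth


def simulate_wgbs(
    planted_lmrs: pd.DataFrame,
    manifest: pd.DataFrame,
    mean_coverage: float = 14.0,
    seed: int = 0,
    lmr_level: float = 0.1,
    background_level: float = 0.85,
    true_methylation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw per-CpG WGBS counts over the manifest's CpG positions.

    Total counts are Poisson(``mean_coverage``); methylated counts are
    binomial given the CpG's true methylation (``lmr_level`` inside planted
    regions, ``background_level`` outside, unless ``true_methylation``
    overrides per CpG). Zero-coverage CpGs are omitted, matching real WGBS
    tables.
    """
    if mean_coverage <= 0:
        raise ConfigurationError("mean_coverage must be > 0")
    rng = np.random.default_rng(seed)
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    if true_methylation is None:
        p = np.full(len(manifest), background_level, dtype=float)
        for _, r in planted_lmrs.iterrows():
            inside = (chrom == r["chrom"]) & (pos >= r["start"]) & (pos < r["end"])
            p[inside] = lmr_level
    else:
        p = np.asarray(true_methylation, dtype=float)
        if p.shape != (len(manifest),):
            raise ConfigurationError("true_methylation must have one value per manifest CpG")
    total = rng.poisson(mean_coverage, size=len(manifest))
    keep = total > 0
    meth = rng.binomial(total[keep], p[keep])
    df = pd.DataFrame(
        {
            "chrom": chrom[keep],
            "pos": pos[keep],
            "meth_count": meth,
            "total_count": total[keep],
        }
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_expression(
    progression: np.ndarray,
    n_genes: int,
    n_effect_genes: int,
    effect_r: float,
    seed: int,
    gene_names: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """TPM-like genes x subjects matrix with planted progression correlation.

    The first ``n_effect_genes`` genes (in a seeded random order) carry a
    latent component correlated ``effect_r`` with progression; expression is
    exponentiated so all values are positive and the correlation sign is
    preserved.
    """
    if not 0 <= effect_r < 1:
        raise ConfigurationError("effect_r must be in [0, 1)")
    if n_effect_genes > n_genes:
        raise ConfigurationError("n_effect_genes must be <= n_genes")
    progression = np.asarray(progression, dtype=float)
    n = progression.size
    rng = np.random.default_rng(seed)
    z_prog = (progression - progression.mean())
    sd = z_prog.std()
    z_prog = z_prog / sd if sd > 0 else z_prog

    if gene_names is None:
        gene_names = [f"GENE{i:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ConfigurationError("gene_names length must equal n_genes")
    effect_mask = np.zeros(n_genes, dtype=bool)
    effect_mask[rng.choice(n_genes, size=n_effect_genes, replace=False)] = True

    noise = rng.normal(0.0, 1.0, size=(n_genes, n))
    latent = noise.copy()
    latent[effect_mask] = effect_r * z_prog[None, :] + np.sqrt(1 - effect_r**2) * noise[effect_mask]
    base = rng.uniform(1.0, 6.0, size=n_genes)  # per-gene log-abundance
    tpm = np.exp(base[:, None] + 0.5 * latent)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(tpm, index=pd.Index(gene_names, name="gene"), columns=sample_ids)


def make_gene_set_collection(
    genes: list[str],
    n_sets: int = 10,
    set_size_range: tuple[int, int] = (5, 20),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Toy gene-set collection drawn from a gene universe (GMT-compatible)."""
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ConfigurationError("empty gene universe")
    lo, hi = set_size_range
    hi = min(hi, len(genes))
    lo = min(lo, hi)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SET_{i:03d}"] = [genes[j] for j in sorted(members)]
    return sets


def write_cohort(
    outdir: str | Path,
    beta: BetaMatrix,
    phenotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    truth: CohortTruth,
    wgbs: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write all cohort artifacts as plain text; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    io.write_beta_tsv(beta.values, outdir / "beta.tsv", index_label="cpg_id")
    paths["beta"] = str(outdir / "beta.tsv")
    io.write_phenotype_tsv(phenotypes, outdir / "phenotypes.tsv")
    paths["phenotypes"] = str(outdir / "phenotypes.tsv")
    io.write_manifest_tsv(manifest, outdir / "manifest.tsv")
    paths["manifest"] = str(outdir / "manifest.tsv")
    io.write_json(truth.to_dict(), outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    with open(outdir / "planted_lmrs.bed", "w") as fh:
        for _, r in truth.planted_lmr_regions.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\tplanted\t0\n")
    paths["planted_lmrs"] = str(outdir / "planted_lmrs.bed")
    if wgbs is not None:
        io.write_wgbs_tsv(wgbs, outdir / "wgbs.tsv")
        paths["wgbs"] = str(outdir / "wgbs.tsv")
    if expression is not None:
        expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene", float_format="%.10g")
        paths["expression"] = str(outdir / "expression.tsv")
    return paths
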