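"""Config-driven end-to-end orchestration.

Stages: simulate -> preprocess -> lmr -> train -> evaluate -> enrich.
Each stage reads its inputs from files written by the previous stage, so
stages can be toggled off and re-runs resume from serialized intermediates.
Identical configs produce byte-identical outputs (timings live in a
separate, excluded file).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock, enrich, evaluate, io, lmr, preprocess, synth
from .errors import ConfigurationError, EpiclockError
from .preprocess import BetaMatrix

STAGES = ("simulate", "preprocess", "lmr", "train", "evaluate", "enrich")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {name: True for name in STAGES},
    "simulate": {},  # SimulationConfig fields
    "qc": {"detection_fail_fraction": 0.01, "blocklist_fraction": 0.01},
    "segmentation": {
        "smoothing_window": 3,
        "fdr_target": 0.05,
        "n_shuffles": 5,
        "lmr_max_cpgs": 30,
        "calibrate": True,
        "meth_cutoff": 0.5,
        "min_cpgs": 4,
    },
    "clock": {
        "k": 10,
        "p": 0.8,
        "n_bins": 10,
        "n_lambda": 100,
        "ratio": 1e-6,
        "models": [
            {"outcome": "wrinkle_grade", "level": "cpg"},
            {"outcome": "visual_age", "level": "cpg"},
            {"outcome": "progression", "level": "lmr"},
            {"outcome": "progression", "level": "cpg"},
        ],
    },
    "expression": {"n_genes": 200, "n_effect_genes": 30, "effect_r": 0.5},
    "enrichment": {
        "p_cut": 0.05,
        "n_perm": 200,
        "top_k": 20,
        "min_sources": 2,
        "n_sets": 12,
        "set_size_range": [5, 20],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    unknown = set(cfg) - set(DEFAULT_CONFIG) - {"outdir"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(cfg: dict, stage: str) -> int:
    # stable per-stage seeds derived from the global seed
    h = hashlib.sha256(f"{cfg['seed']}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little")


class PipelineRunner:
    def __init__(self, cfg: dict, outdir: str | Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "stages": {},
        }
        self.timings: dict = {}

    # -- helpers ----------------------------------------------------------
    def _dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.manifest["stages"][stage] = {
            name: {"path": str(p.relative_to(self.outdir)), "sha256": _sha256(p)}
            for name, p in outputs.items()
        }

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        d = self._dir("simulate")
        sim_cfg = dict(self.cfg["simulate"])
        sim_cfg.setdefault("seed", _stage_seed(self.cfg, "simulate"))
        if "lmr_cpg_range" in sim_cfg:
            sim_cfg["lmr_cpg_range"] = tuple(sim_cfg["lmr_cpg_range"])
        if "age_range" in sim_cfg:
            sim_cfg["age_range"] = tuple(sim_cfg["age_range"])
        scfg = synth.SimulationConfig(**sim_cfg)
        beta, phenotypes, manifest, truth = synth.simulate_cohort(scfg)
        wgbs = synth.simulate_wgbs(
            truth.planted_lmr_regions, manifest,
            mean_coverage=scfg.wgbs_mean_coverage,
            seed=_stage_seed(self.cfg, "simulate.wgbs"),
        )
        ecfg = self.cfg["expression"]
        gene_pool = sorted({g for gs in io.manifest_genes(manifest) for g in gs})
        n_genes = min(int(ecfg["n_genes"]), len(gene_pool))
        expression = synth.simulate_expression(
            truth.true_progression,
            n_genes=n_genes,
            n_effect_genes=min(int(ecfg["n_effect_genes"]), n_genes),
            effect_r=float(ecfg["effect_r"]),
            seed=_stage_seed(self.cfg, "simulate.expression"),
            gene_names=gene_pool[:n_genes],
            sample_ids=list(beta.sample_ids),
        )
        synth.write_cohort(d, beta, phenotypes, manifest, truth, wgbs=wgbs, expression=expression)

        # synthetic probe QC: a small fraction of probes fail detection or
        # land on the blocklist, exercising the filtering stage
        rng = np.random.default_rng(_stage_seed(self.cfg, "simulate.qc"))
        qc_cfg = self.cfg["qc"]
        n_probe, n_samp = beta.values.shape
        detp = rng.uniform(0.0, 0.005, size=(n_probe, n_samp))
        n_fail = int(round(qc_cfg["detection_fail_fraction"] * n_probe))
        fail_rows = rng.choice(n_probe, size=n_fail, replace=False)
        detp[fail_rows, rng.integers(0, n_samp, size=n_fail)] = 0.5
        pd.DataFrame(detp, index=beta.feature_ids, columns=beta.sample_ids).to_csv(
            d / "detection_p.tsv", sep="\t", index_label="cpg_id", float_format="%.6g"
        )
        n_block = int(round(qc_cfg["blocklist_fraction"] * n_probe))
        blocked = rng.choice(beta.feature_ids.to_numpy(), size=n_block, replace=False)
        io.write_blocklist(blocked, d / "blocklist.txt")

        gmt_genes = gene_pool[:n_genes]
        e = self.cfg["enrichment"]
        sets = synth.make_gene_set_collection(
            gmt_genes, n_sets=int(e["n_sets"]),
            set_size_range=tuple(e["set_size_range"]),
            seed=_stage_seed(self.cfg, "simulate.gmt"),
        )
        io.write_gmt(sets, d / "gene_sets.gmt")
        self._record("simulate", {p.name: p for p in sorted(d.iterdir())})

    def stage_preprocess(self) -> None:
        d = self._dir("preprocess")
        sim = self.outdir / "simulate"
        beta = BetaMatrix(io.read_beta_tsv(sim / "beta.tsv"), "cpg")
        detp = pd.read_csv(sim / "detection_p.tsv", sep="\t", index_col=0)
        qc = preprocess.ProbeQC(
            detection_p=detp, blocklist=io.read_blocklist(sim / "blocklist.txt")
        )
        filtered, report = preprocess.filter_probes(beta, qc)
        normalized = preprocess.quantile_normalize(filtered)
        io.write_beta_tsv(normalized.values, d / "beta_norm.tsv", index_label="cpg_id")
        io.write_json(report, d / "filter_report.json")
        self._record("preprocess", {p.name: p for p in sorted(d.iterdir())})

    def stage_lmr(self) -> None:
        d = self._dir("lmr")
        sim = self.outdir / "simulate"
        wgbs = io.read_wgbs_tsv(sim / "wgbs.tsv")
        methylome = lmr.Methylome(wgbs)
        seg_cfg = self.cfg["segmentation"]
        params = lmr.SegmentationParams(
            meth_cutoff=float(seg_cfg["meth_cutoff"]),
            min_cpgs=int(seg_cfg["min_cpgs"]),
            smoothing_window=int(seg_cfg["smoothing_window"]),
            lmr_max_cpgs=int(seg_cfg["lmr_max_cpgs"]),
            fdr_target=float(seg_cfg["fdr_target"]),
            n_shuffles=int(seg_cfg["n_shuffles"]),
            seed=_stage_seed(self.cfg, "lmr"),
        )
        if seg_cfg.get("calibrate", True):
            m, n, fdr_table = lmr.calibrate_fdr(methylome, params)
            params = lmr.SegmentationParams(
                meth_cutoff=m, min_cpgs=n,
                smoothing_window=params.smoothing_window,
                lmr_max_cpgs=params.lmr_max_cpgs,
                fdr_target=params.fdr_target,
                n_shuffles=params.n_shuffles, seed=params.seed,
            )
            fdr_table.to_csv(d / "fdr_table.tsv", sep="\t", index=False, float_format="%.10g")
        segments = lmr.segment_hypomethylated(methylome, params)
        classified = lmr.classify_segments(segments, params.lmr_max_cpgs)
        manifest = io.read_manifest_tsv(sim / "manifest.tsv")
        lmrs, report = lmr.intersect_with_probes(classified, manifest)
        io.write_regions_bed(classified, d / "segments.bed")
        io.write_regions_tsv(lmrs, d / "lmrs.tsv")
        io.write_json(report, d / "intersect_report.json")

        beta = BetaMatrix(io.read_beta_tsv(self.outdir / "preprocess" / "beta_norm.tsv"), "cpg")
        beta_lmr, avg_report = preprocess.lmr_average(beta, lmrs, manifest)
        io.write_beta_tsv(beta_lmr.values, d / "beta_lmr.tsv", index_label="lmr_id")
        io.write_json(avg_report, d / "lmr_average_report.json")
        self._record("lmr", {p.name: p for p in sorted(d.iterdir())})

    def _load_level(self, level: str) -> BetaMatrix:
        if level == "cpg":
            return BetaMatrix(io.read_beta_tsv(self.outdir / "preprocess" / "beta_norm.tsv"), "cpg")
        return BetaMatrix(io.read_beta_tsv(self.outdir / "lmr" / "beta_lmr.tsv"), "lmr")

    def stage_train(self) -> None:
        d = self._dir("train")
        phenotypes = io.read_phenotype_tsv(self.outdir / "simulate" / "phenotypes.tsv")
        ccfg = self.cfg["clock"]
        for spec in ccfg["models"]:
            outcome_kind, level = spec["outcome"], spec["level"]
            tag = f"{outcome_kind}_{level}"
            beta = self._load_level(level)
            y = clock.make_outcome(phenotypes, outcome_kind)
            part = clock.stratified_partition(
                y, p=float(ccfg["p"]), n_bins=int(ccfg["n_bins"]),
                seed=_stage_seed(self.cfg, f"train.partition.{tag}"),
            )
            X = beta.values[part.train_ids].T
            grid = clock.lambda_path(X, y.loc[part.train_ids], n_lambda=int(ccfg["n_lambda"]),
                                     ratio=float(ccfg["ratio"]))
            model, cv = clock.cv_train(
                X, y.loc[part.train_ids], k=int(ccfg["k"]), lambda_grid=grid,
                seed=_stage_seed(self.cfg, f"train.cv.{tag}"),
                outcome_kind=outcome_kind, feature_level=level,
            )
            payload = model.to_dict()
            payload["provenance"] = {
                "config_hash": self.manifest["config_hash"],
                "seed": self.cfg["seed"],
            }
            io.write_json(payload, d / f"model_{tag}.json")
            cv.to_frame().to_csv(d / f"cv_{tag}.tsv", sep="\t", index=False, float_format="%.10g")
            io.write_json(
                {"train_ids": part.train_ids, "test_ids": part.test_ids,
                 "p": part.p, "n_bins": part.n_bins},
                d / f"partition_{tag}.json",
            )
        self._record("train", {p.name: p for p in sorted(d.iterdir())})

    def stage_evaluate(self) -> None:
        d = self._dir("evaluate")
        phenotypes = io.read_phenotype_tsv(self.outdir / "simulate" / "phenotypes.tsv")
        reports = {}
        for spec in self.cfg["clock"]["models"]:
            tag = f"{spec['outcome']}_{spec['level']}"
            model = clock.ClockModel.from_dict(io.read_json(self.outdir / "train" / f"model_{tag}.json"))
            part = io.read_json(self.outdir / "train" / f"partition_{tag}.json")
            beta = self._load_level(spec["level"])
            test = BetaMatrix(beta.values[part["test_ids"]], beta.feature_level)
            report = evaluate.validate_clock(model, test, phenotypes, dataset_label="test")
            reports[tag] = report.to_dict()
        io.write_json(reports, d / "validation.json")
        frame = pd.DataFrame(reports).T
        frame.to_csv(d / "validation.tsv", sep="\t", index_label="model", float_format="%.10g")
        self._record("evaluate", {p.name: p for p in sorted(d.iterdir())})

    def stage_enrich(self) -> None:
        d = self._dir("enrich")
        sim = self.outdir / "simulate"
        ecfg = self.cfg["enrichment"]
        manifest = io.read_manifest_tsv(sim / "manifest.tsv")
        collection = io.read_gmt(sim / "gene_sets.gmt")

        tag = "progression_lmr"
        model = clock.ClockModel.from_dict(io.read_json(self.outdir / "train" / f"model_{tag}.json"))
        part = io.read_json(self.outdir / "train" / f"partition_{tag}.json")
        regions = io.read_regions_tsv(self.outdir / "lmr" / "lmrs.tsv")
        beta_lmr = self._load_level("lmr")
        beta_cpg = self._load_level("cpg")
        test_ids = part["test_ids"]
        predictions = clock.predict(model, BetaMatrix(beta_lmr.values[test_ids], "lmr"))
        expression = pd.read_csv(sim / "expression.tsv", sep="\t", index_col=0)

        rankings = {
            "coefficient": enrich.rank_from_coefficients(model, manifest, regions),
            "methylation_test": enrich.rank_from_methylation_correlation(
                BetaMatrix(beta_cpg.values[test_ids], "cpg"), predictions, manifest,
                p_cut=float(ecfg["p_cut"]),
            ),
            "expression_test": enrich.rank_from_expression_correlation(
                expression[test_ids], predictions, p_cut=float(ecfg["p_cut"]),
            ),
        }
        for name, ranking in rankings.items():
            io.write_rnk(ranking, d / f"ranking_{name}.rnk")
        top, full = enrich.run_preranked(
            rankings, collection, n_perm=int(ecfg["n_perm"]),
            seed=_stage_seed(self.cfg, "enrich"), top_k=int(ecfg["top_k"]),
        )
        for source, results in full.items():
            enrich.results_to_frame(results).to_csv(
                d / f"enrichment_{source}.tsv", sep="\t", index=False, float_format="%.10g"
            )
        table = enrich.consensus(top, min_sources=int(ecfg["min_sources"]))
        table.to_csv(d / "consensus.tsv", sep="\t", index=False, float_format="%.10g")
        self._record("enrich", {p.name: p for p in sorted(d.iterdir())})

    # -- driver -----------------------------------------------------------
    def run(self) -> dict:
        stage_fns = {
            "simulate": self.stage_simulate,
            "preprocess": self.stage_preprocess,
            "lmr": self.stage_lmr,
            "train": self.stage_train,
            "evaluate": self.stage_evaluate,
            "enrich": self.stage_enrich,
        }
        for stage in STAGES:
            if not self.cfg["stages"].get(stage, True):
                continue
            t0 = time.perf_counter()
            try:
                stage_fns[stage]()
            except EpiclockError as exc:
                raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
            self.timings[stage] = time.perf_counter() - t0
        io.write_json(self.manifest, self.outdir / "run_manifest.json")
        io.write_json(self.timings, self.outdir / "timings.json")
        return self.manifest


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the run manifest."""
    return PipelineRunner(cfg, outdir).run()
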