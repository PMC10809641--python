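import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epiclock.clock import ClockModel
from epiclock.enrich import (
    EnrichmentResult,
    consensus,
    enrichment_score,
    permutation_null,
    rank_from_coefficients,
    rank_from_expression_correlation,
    rank_from_methylation_correlation,
    run_preranked,
    truncate_top,
)
from epiclock.errors import DataError, RankingError
from epiclock.preprocess import BetaMatrix


def brute_force_es(ranking: pd.Series, gene_set, exponent=1.0):
    """All-prefix running-sum maximum, computed independently."""
    genes = list(ranking.index)
    in_set = [g in set(gene_set) for g in genes]
    n = len(genes)
    n_hit = sum(in_set)
    w = np.abs(ranking.to_numpy()) ** exponent
    denom = sum(wi for wi, h in zip(w, in_set) if h)
    best = 0.0
    running = 0.0
    for i in range(n):
        if in_set[i]:
            running += w[i] / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def _model(feature_ids, coefficients):
    k = len(feature_ids)
    return ClockModel(
        outcome_kind="progression", feature_level="cpg",
        feature_ids=list(feature_ids), intercept=0.0,
        coefficients=np.asarray(coefficients, dtype=float),
        feature_means=np.zeros(k), feature_sds=np.ones(k), lam=1.0,
    )


def _manifest(rows):
    df = pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos", "gene"])
    return df.set_index("cpg_id")


class TestRankFromCoefficients:
    def test_summing_rule(self):
        model = _model(["cpg1", "cpg2", "cpg3"], [0.5, 0.3, -0.2])
        manifest = _manifest(
            [("cpg1", "chr1", 10, "geneA"), ("cpg2", "chr1", 20, "geneA"),
             ("cpg3", "chr1", 30, "geneB")]
        )
        ranking = rank_from_coefficients(model, manifest)
        assert list(ranking.index) == ["geneA", "geneB"]
        assert ranking["geneA"] == pytest.approx(0.8)
        assert ranking["geneB"] == pytest.approx(-0.2)

    def test_unannotated_feature_dropped(self):
        model = _model(["cpg1", "cpg2"], [0.5, 0.9])
        manifest = _manifest(
            [("cpg1", "chr1", 10, "geneA"), ("cpg2", "chr1", 20, "")]
        )
        with pytest.warns(UserWarning, match="without gene annotation"):
            ranking = rank_from_coefficients(model, manifest)
        assert list(ranking.index) == ["geneA"]

    def test_multi_gene_cpg_contributes_to_both(self):
        model = _model(["cpg1"], [0.4])
        manifest = _manifest([("cpg1", "chr1", 10, "geneA;geneB")])
        ranking = rank_from_coefficients(model, manifest)
        assert ranking["geneA"] == pytest.approx(0.4)
        assert ranking["geneB"] == pytest.approx(0.4)

    def test_empty_annotation_raises(self):
        model = _model(["cpg1"], [0.4])
        manifest = _manifest([("cpg1", "chr1", 10, "")])
        with pytest.warns(UserWarning):
            with pytest.raises(RankingError):
                rank_from_coefficients(model, manifest)

    def test_lmr_model_uses_member_cpgs(self):
        model = ClockModel(
            outcome_kind="progression", feature_level="lmr",
            feature_ids=["chr1:5-25"], intercept=0.0,
            coefficients=np.array([0.7]), feature_means=np.zeros(1),
            feature_sds=np.ones(1), lam=1.0,
        )
        manifest = _manifest(
            [("cpg1", "chr1", 10, "geneA"), ("cpg2", "chr1", 20, "geneA;geneB"),
             ("cpg3", "chr1", 100, "geneC")]
        )
        regions = pd.DataFrame([{"chrom": "chr1", "start": 5, "end": 25}])
        ranking = rank_from_coefficients(model, manifest, regions)
        # geneA appears in two member CpGs but is deduplicated per feature
        assert ranking["geneA"] == pytest.approx(0.7)
        assert ranking["geneB"] == pytest.approx(0.7)
        assert "geneC" not in ranking.index


class TestRankFromMethylationCorrelation:
    def _setup(self, rng, n=40):
        pred = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        rows = {
            "cpg_pos": 0.9 * pred.to_numpy() + 0.1 * rng.normal(size=n),
            "cpg_pos2": 0.8 * pred.to_numpy() + 0.2 * rng.normal(size=n),
            "cpg_null": rng.normal(size=n),
        }
        arr = pd.DataFrame(rows).T
        arr = (arr - arr.min().min()) / (arr.max().max() - arr.min().min())
        beta = BetaMatrix(pd.DataFrame(arr.to_numpy(), index=rows.keys(), columns=pred.index), "cpg")
        manifest = _manifest(
            [("cpg_pos", "chr1", 10, "geneA"), ("cpg_pos2", "chr1", 20, "geneA"),
             ("cpg_null", "chr1", 30, "geneB")]
        )
        return beta, pred, manifest

    def test_gene_weight_is_mean_of_member_r(self, rng):
        beta, pred, manifest = self._setup(rng)
        ranking = rank_from_methylation_correlation(beta, pred, manifest)
        r1 = stats.pearsonr(beta.values.loc["cpg_pos"], pred)[0]
        r2 = stats.pearsonr(beta.values.loc["cpg_pos2"], pred)[0]
        assert ranking["geneA"] == pytest.approx((r1 + r2) / 2)

    def test_high_p_cpgs_discarded(self, rng):
        beta, pred, manifest = self._setup(rng)
        ranking = rank_from_methylation_correlation(beta, pred, manifest, p_cut=0.05)
        # the null CpG fails the p <= 0.05 filter for this seed
        p_null = stats.pearsonr(beta.values.loc["cpg_null"], pred)[1]
        assert p_null > 0.05
        assert "geneB" not in ranking.index

    def test_type_one_survival_rate(self):
        # DERIVED: fraction of null CpGs passing p <= 0.05 near nominal
        rng = np.random.default_rng(77)
        n, n_cpgs = 100, 2000
        pred = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        arr = rng.uniform(size=(n_cpgs, n))
        ids = [f"cg{i}" for i in range(n_cpgs)]
        beta = BetaMatrix(pd.DataFrame(arr, index=ids, columns=pred.index), "cpg")
        manifest = _manifest([(i, "chr1", 10 + j, f"gene{j}") for j, i in enumerate(ids)])
        ranking = rank_from_methylation_correlation(beta, pred, manifest)
        frac = len(ranking) / n_cpgs
        assert abs(frac - 0.05) < 0.02

    def test_no_survivor_raises(self, rng):
        pred = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        beta = BetaMatrix(
            pd.DataFrame([[0.5, 0.5, 0.5, 0.5]], index=["cpg1"], columns=pred.index), "cpg"
        )
        manifest = _manifest([("cpg1", "chr1", 10, "geneA")])
        with pytest.raises(RankingError):
            rank_from_methylation_correlation(beta, pred, manifest)


class TestRankFromExpressionCorrelation:
    def test_single_surviving_gene(self, rng):
        pred = pd.Series(np.linspace(0, 1, 20), index=[f"s{i}" for i in range(20)])
        vals = 3 * pred.to_numpy() + 0.05 * rng.normal(size=20) + 1
        tpm = pd.DataFrame([vals], index=["geneA"], columns=pred.index)
        ranking = rank_from_expression_correlation(tpm, pred)
        assert list(ranking.index) == ["geneA"]
        assert ranking["geneA"] > 0.9

    def test_duplicate_rows_averaged(self, rng):
        pred = pd.Series(np.linspace(0, 1, 30), index=[f"s{i}" for i in range(30)])
        v1 = pred.to_numpy() + 0.1 * rng.normal(size=30)
        v2 = pred.to_numpy() + 0.3 * rng.normal(size=30)
        tpm = pd.DataFrame([v1 + 1, v2 + 1], index=["geneA", "geneA"], columns=pred.index)
        ranking = rank_from_expression_correlation(tpm, pred)
        r1 = stats.pearsonr(v1, pred)[0]
        r2 = stats.pearsonr(v2, pred)[0]
        assert ranking["geneA"] == pytest.approx((r1 + r2) / 2)

    def test_anticorrelated_genes_rank_bottom(self, rng):
        pred = pd.Series(np.linspace(0, 1, 25), index=[f"s{i}" for i in range(25)])
        up = pred.to_numpy() + 0.05 * rng.normal(size=25) + 2
        down = -pred.to_numpy() + 0.05 * rng.normal(size=25) + 2
        tpm = pd.DataFrame([up, down], index=["up", "down"], columns=pred.index)
        ranking = rank_from_expression_correlation(tpm, pred)
        assert list(ranking.index) == ["up", "down"]
        assert ranking["down"] < 0


class TestEnrichmentScore:
    def _ranking(self, n=10):
        return pd.Series(
            np.linspace(5, 0.5, n), index=[f"g{i}" for i in range(n)], name="weight"
        )

    def test_top_gene_set_scores_one(self):
        ranking = self._ranking()
        es, _, _ = enrichment_score(ranking, {"g0"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one(self):
        ranking = self._ranking()
        es, _, _ = enrichment_score(ranking, {"g9"})
        assert es == pytest.approx(-1.0)

    def test_five_gene_toy_against_brute_force(self):
        ranking = pd.Series(
            [3.0, 2.0, 1.0, 1.0, 1.0], index=["g1", "g2", "g3", "g4", "g5"]
        )
        gene_set = {"g1", "g3"}
        es, _, _ = enrichment_score(ranking, gene_set)
        assert es == pytest.approx(brute_force_es(ranking, gene_set))

    def test_scale_invariance(self, rng):
        ranking = pd.Series(
            rng.normal(size=20), index=[f"g{i}" for i in range(20)]
        ).sort_values(ascending=False)
        gene_set = {"g3", "g7", "g11"}
        es1, _, _ = enrichment_score(ranking, gene_set)
        es2, _, _ = enrichment_score(ranking * 37.5, gene_set)
        assert es1 == pytest.approx(es2)

    def test_disjoint_set_raises(self):
        with pytest.raises(DataError):
            enrichment_score(self._ranking(), {"absent"})

    def test_full_cover_set_raises(self):
        ranking = self._ranking(4)
        with pytest.raises(DataError, match="degenerate"):
            enrichment_score(ranking, set(ranking.index))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_streaming_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        weights = rng.normal(size=n)
        ranking = pd.Series(
            weights, index=[f"g{i}" for i in range(n)]
        ).sort_values(ascending=False, kind="stable")
        k = int(rng.integers(1, n))
        gene_set = set(rng.choice(ranking.index.to_numpy(), size=k, replace=False))
        es, _, _ = enrichment_score(ranking, gene_set)
        assert es == pytest.approx(brute_force_es(ranking, gene_set), abs=1e-12)


class TestPermutationNull:
    def _planted(self):
        # 50-gene ranking, the 5-gene set occupies the top 5 positions
        weights = np.concatenate([np.linspace(10, 9, 5), np.linspace(1, 0.1, 45)])
        return pd.Series(weights, index=[f"g{i}" for i in range(50)])

    def test_planted_set_significant(self):
        ranking = self._planted()
        nes, p, es = permutation_null(ranking, {f"g{i}" for i in range(5)},
                                      n_perm=1000, seed=3)
        assert es > 0.9
        assert nes > 1.5
        assert p <= 0.01

    def test_p_lower_bound(self):
        ranking = self._planted()
        _, p, _ = permutation_null(ranking, {f"g{i}" for i in range(5)},
                                   n_perm=200, seed=1)
        assert p >= 1 / 201

    def test_deterministic_given_seed(self):
        ranking = self._planted()
        a = permutation_null(ranking, {"g2", "g30"}, n_perm=100, seed=9)
        b = permutation_null(ranking, {"g2", "g30"}, n_perm=100, seed=9)
        assert a == b

    def test_null_p_approximately_uniform(self):
        # DERIVED: KS distance of nominal p against U(0,1) under the null
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(200):
            weights = rng.normal(size=60)
            ranking = pd.Series(
                weights, index=[f"g{i}" for i in range(60)]
            ).sort_values(ascending=False, kind="stable")
            gene_set = set(rng.choice(ranking.index.to_numpy(), size=8, replace=False))
            _, p, _ = permutation_null(ranking, gene_set, n_perm=99,
                                       seed=int(rng.integers(2**31)))
            ps.append(p)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.1


class TestRunPrerankedAndConsensus:
    def _rankings(self, rng, n_genes=40):
        genes = [f"g{i}" for i in range(n_genes)]
        out = {}
        for src in ("a", "b"):
            out[src] = pd.Series(
                rng.normal(size=n_genes), index=genes
            ).sort_values(ascending=False, kind="stable")
        return out

    def test_small_collection_untruncated(self, rng):
        rankings = self._rankings(rng)
        sets = {f"S{i}": [f"g{j}" for j in range(i, i + 5)] for i in range(3)}
        top, full = run_preranked(rankings, sets, n_perm=50, seed=1)
        assert all(len(v) <= 3 for v in top.values())

    def test_thirty_sets_truncated_to_twenty(self, rng):
        rankings = self._rankings(rng)
        sets = {f"S{i:02d}": [f"g{(i * 3 + j) % 40}" for j in range(5)] for i in range(30)}
        top, full = run_preranked(rankings, sets, n_perm=50, seed=1)
        assert all(len(v) == 20 for v in top.values())
        assert all(len(v) == 30 for v in full.values())

    def test_identical_rankings_identical_results(self, rng):
        base = self._rankings(rng)["a"]
        rankings = {"x": base, "y": base.copy()}
        sets = {f"S{i}": [f"g{j}" for j in range(i, i + 6)] for i in range(4)}
        top, _ = run_preranked(rankings, sets, n_perm=50, seed=5)
        for rx, ry in zip(top["x"], top["y"]):
            assert rx.set_name == ry.set_name
            assert rx.es == pytest.approx(ry.es)
            assert rx.nes == pytest.approx(ry.nes)

    def _result(self, name, nes, source):
        return EnrichmentResult(
            set_name=name, set_size=5, es=0.5, nes=nes, p_value=0.01,
            n_perm=100, source=source,
        )

    def test_consensus_overlap_structure(self):
        # X in 7/7 sources, Y in 6/7, Z in 5/7; min_sources=6 keeps X, Y
        per_source = {}
        for k in range(7):
            results = [self._result("X", 2.0 + 0.1 * k, f"s{k}")]
            if k < 6:
                results.append(self._result("Y", 1.5, f"s{k}"))
            if k < 5:
                results.append(self._result("Z", 3.0, f"s{k}"))
            per_source[f"s{k}"] = results
        table = consensus(per_source, min_sources=6)
        assert list(table["pathway"]) == ["X", "Y"]
        assert table.loc[table["pathway"] == "X", "n_sources"].iloc[0] == 7
        assert table.loc[table["pathway"] == "Y", "n_sources"].iloc[0] == 6

    def test_consensus_ten_pathway_structure(self):
        # 5 sets in 7/7 and 5 in 6/7 -> consensus of exactly 10 at min 6
        per_source = {f"s{k}": [] for k in range(7)}
        for i in range(5):
            for k in range(7):
                per_source[f"s{k}"].append(self._result(f"ALL{i}", 2.0 + i, f"s{k}"))
        for i in range(5):
            for k in range(6):
                per_source[f"s{k}"].append(self._result(f"SIX{i}", 1.0 + i, f"s{k}"))
        table = consensus(per_source, min_sources=6)
        assert len(table) == 10
        assert sorted(table["pathway"]) == sorted(
            [f"ALL{i}" for i in range(5)] + [f"SIX{i}" for i in range(5)]
        )
        # sorted by mean |NES| descending
        assert (table["mean_abs_nes"].diff().dropna() <= 0).all()

    def test_disjoint_sources_empty(self):
        per_source = {
            "a": [self._result("P1", 1.0, "a")],
            "b": [self._result("P2", 1.0, "b")],
        }
        table = consensus(per_source, min_sources=2)
        assert table.empty

    def test_single_source_resorted(self):
        results = [
            self._result("low", 0.5, "a"),
            self._result("high", -3.0, "a"),
            self._result("mid", 1.0, "a"),
        ]
        table = consensus({"a": results}, min_sources=1)
        assert list(table["pathway"]) == ["high", "mid", "low"]

    def test_truncate_ordering(self):
        results = [
            self._result("a", 1.0, "s"),
            self._result("b", -2.0, "s"),
            self._result("c", 1.5, "s"),
        ]
        top = truncate_top(results, top_k=2)
        assert [r.set_name for r in top] == ["b", "c"]
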