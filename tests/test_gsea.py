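import numpy as np
import pandas as pd
import pytest

from recscreen import GeneSetCollection, RunConfig, enrichment_score, gsea
from recscreen.gsea import make_ranked_list


def ranked_frame(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    df = pd.DataFrame({"gene": genes, "score": scores})
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def brute_force_es(genes, scores, gene_set, weight):
    """Direct O(N) running-sum walk, independent of the implementation."""
    N = len(genes)
    hits = [g in set(gene_set) for g in genes]
    Nh = sum(hits)
    wsum = sum(abs(s) ** weight for g, s, h in zip(genes, scores, hits) if h)
    run, best = 0.0, 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            run += (abs(s) ** weight / wsum) if wsum > 0 else 1.0 / Nh
        else:
            run -= 1.0 / (N - Nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_all_genes_in_set_gives_one(self):
        ranked = ranked_frame([3.0, 2.0, 1.0])
        es, leading = enrichment_score(ranked, ranked["gene"].tolist())
        assert es == pytest.approx(1.0)
        assert leading == ranked["gene"].tolist()

    def test_weight_zero_top_ranks_by_hand(self):
        # 5 genes, set at ranks 1-2; unweighted running sum peaks after the
        # second hit at 2/2 - 0/3 = 1
        ranked = ranked_frame([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _ = enrichment_score(ranked, ["g0", "g1"], weight=0.0)
        assert es == pytest.approx(1.0)

    def test_disjoint_set_skipped(self):
        ranked = ranked_frame([2.0, 1.0])
        assert enrichment_score(ranked, ["absent"]) is None

    def test_matches_brute_force_walk(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 100))
            ranked = ranked_frame(np.sort(rng.normal(size=n))[::-1])
            k = int(rng.integers(2, max(3, n // 3)))
            gene_set = list(rng.choice(ranked["gene"], size=k, replace=False))
            for weight in (0.0, 1.0, 1.5):
                es, _ = enrichment_score(ranked, gene_set, weight=weight)
                oracle = brute_force_es(
                    ranked["gene"].tolist(), ranked["score"].tolist(),
                    gene_set, weight,
                )
                assert es == pytest.approx(oracle, abs=1e-12)

    def test_reversed_list_negates_es(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = ranked_frame(scores)
        flipped = ranked_frame(-scores[::-1],
                               genes=ranked["gene"].tolist()[::-1])
        gene_set = list(rng.choice(ranked["gene"], size=8, replace=False))
        es, _ = enrichment_score(ranked, gene_set)
        es_rev, _ = enrichment_score(flipped, gene_set)
        assert es == pytest.approx(-es_rev, abs=1e-12)


def collection_of(sets):
    coll = GeneSetCollection()
    for name, members in sets.items():
        coll.add(name, "test", members)
    return coll


class TestGsea:
    cfg = RunConfig(seed=0, gsea_set_min=5, gsea_set_max=100,
                    gsea_permutations=500)

    def test_undersized_set_excluded(self, caplog):
        rng = np.random.default_rng(2)
        ranked = ranked_frame(np.sort(rng.normal(size=50))[::-1])
        coll = collection_of({
            "tiny": ranked["gene"].tolist()[:4],
            "ok": ranked["gene"].tolist()[:10],
        })
        with caplog.at_level("INFO", logger="recscreen"):
            out = gsea(ranked, coll, self.cfg)
        assert out["set"].tolist() == ["ok"]
        assert "tiny" in caplog.text

    def test_empty_collection_after_filter_errors(self):
        ranked = ranked_frame(np.arange(30.0)[::-1])
        coll = collection_of({"tiny": ranked["gene"].tolist()[:2]})
        with pytest.raises(ValueError, match="no gene sets"):
            gsea(ranked, coll, self.cfg)

    def test_planted_top_set_enriched(self):
        rng = np.random.default_rng(7)
        ranked = ranked_frame(np.sort(rng.normal(size=200))[::-1])
        planted = ranked["gene"].tolist()[:15]
        sets = {"planted": planted}
        for i in range(10):
            sets[f"r{i}"] = list(rng.choice(ranked["gene"], 15, replace=False))
        out = gsea(ranked, collection_of(sets), self.cfg).set_index("set")
        assert out.loc["planted", "nes"] > 0
        assert out.loc["planted", "fdr_q"] < 0.25
        assert out.loc["planted", "p"] == out["p"].min()

    def test_null_p_roughly_uniform(self):
        """Fraction of null sets at p < 0.05 stays near 0.05."""
        rng = np.random.default_rng(11)
        ps = []
        for seed in range(10):
            scores = rng.normal(size=150)
            ranked = ranked_frame(np.sort(scores)[::-1])
            sets = {
                f"r{i}": list(rng.choice(ranked["gene"], 12, replace=False))
                for i in range(50)
            }
            out = gsea(ranked, collection_of(sets), self.cfg, seed=seed)
            ps.extend(out["p"].tolist())
        frac = np.mean(np.asarray(ps) < 0.05)
        assert frac == pytest.approx(0.05, abs=0.03)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        ranked = ranked_frame(np.sort(rng.normal(size=60))[::-1])
        sets = {f"s{i}": list(rng.choice(ranked["gene"], 10, replace=False))
                for i in range(5)}
        a = gsea(ranked, collection_of(sets), self.cfg)
        b = gsea(ranked, collection_of(sets), self.cfg)
        pd.testing.assert_frame_equal(a, b)


class TestMakeRankedList:
    def test_orders_by_mean_rec_descending(self):
        rec = pd.DataFrame({
            "compound": "c", "gene": ["a", "a", "b", "b"],
            "timepoint": ["6h", "24h", "6h", "24h"],
            "rec": [0.5, 0.7, -0.2, -0.4],
        })
        ranked = make_ranked_list(rec, "c")
        assert ranked["gene"].tolist() == ["a", "b"]
        assert ranked["score"].tolist() == pytest.approx([0.6, -0.3])

    def test_single_timepoint_slice(self):
        rec = pd.DataFrame({
            "compound": "c", "gene": ["a", "b"],
            "timepoint": ["6h", "6h"], "rec": [-0.5, 0.1],
        })
        ranked = make_ranked_list(rec, "c", "6h")
        assert ranked["gene"].tolist() == ["b", "a"]

    def test_unknown_compound_errors(self):
        rec = pd.DataFrame({"compound": ["c"], "gene": ["a"],
                            "timepoint": ["6h"], "rec": [0.0]})
        with pytest.raises(KeyError):
            make_ranked_list(rec, "nope")
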