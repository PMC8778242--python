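import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from recscreen import (
    RunConfig,
    bh_fdr,
    rank_rec,
    rec_exact_p,
    rec_permutation_p,
    rec_score,
    rec_table,
    robust_z,
)
from tests.conftest import build_tensor


class TestRobustZ:
    def test_treated_at_control_median_is_zero(self):
        controls = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        z, absent = robust_z(np.array([3.0]), controls)
        assert z[0] == 0.0 and not absent[0]

    def test_zero_mad_flagged_absent(self, caplog):
        controls = np.array([[2.0, 2.0, 2.0]])
        with caplog.at_level("WARNING", logger="recscreen"):
            z, absent = robust_z(np.array([5.0]), controls)
        assert absent[0] and np.isnan(z[0])
        assert "zero control MAD" in caplog.text

    def test_matches_direct_formula_on_five_replicates(self):
        controls = np.array([[3.1, 2.9, 3.5, 2.2, 4.0]])
        treated = np.array([5.7])
        med = np.median(controls[0])
        mad = np.median(np.abs(controls[0] - med))
        expected = (5.7 - med) / (1.4826 * mad)
        z, _ = robust_z(treated, controls)
        assert z[0] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_controls_errors(self):
        with pytest.raises(ValueError, match="3 control"):
            robust_z(np.array([1.0]), np.array([[1.0, 2.0]]))


class TestRecScore:
    def test_all_lines_down_gives_minus_one(self):
        z = np.full((1, 1, 10, 1), -3.0)
        t = build_tensor(z)
        rec, n = rec_score(t, "c0", "g0", "t0", z_thr=2.0)
        assert rec == -1.0 and n == 10

    def test_all_subthreshold_gives_zero(self):
        t = build_tensor(np.full((1, 1, 5, 1), 1.5))
        rec, _ = rec_score(t, "c0", "g0", "t0", z_thr=2.0)
        assert rec == 0.0

    def test_mixed_counts(self):
        z = np.array([3, 2, 2.5, 4, 2, 2, -2, -3, 0, 1.0]).reshape(1, 1, 10, 1)
        rec, n = rec_score(build_tensor(z), "c0", "g0", "t0", z_thr=2.0)
        assert rec == pytest.approx((6 - 2) / 10) and n == 10

    def test_absent_lines_excluded_from_denominator(self):
        z = np.array([3.0, -3.0, np.nan, np.nan]).reshape(1, 1, 4, 1)
        rec, n = rec_score(build_tensor(z), "c0", "g0", "t0")
        assert n == 2 and rec == 0.0
        # removing the absent lines entirely must not change rec
        z2 = z[:, :, :2, :]
        rec2, _ = rec_score(build_tensor(z2), "c0", "g0", "t0")
        assert rec2 == rec

    def test_missing_gene_errors(self):
        t = build_tensor(np.zeros((1, 1, 3, 1)))
        with pytest.raises(KeyError):
            rec_score(t, "c0", "nope", "t0")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(arrays(float, (1, 3, 4, 1),
                  elements=st.floats(-6, 6, allow_nan=False)))
    def test_antisymmetry(self, z):
        t_pos = build_tensor(z)
        t_neg = build_tensor(-z)
        for g in t_pos.genes:
            r_pos, _ = rec_score(t_pos, "c0", g, "t0")
            r_neg, _ = rec_score(t_neg, "c0", g, "t0")
            assert r_pos == -r_neg
            p_pos = rec_exact_p(t_pos, "c0", g, "t0")
            p_neg = rec_exact_p(t_neg, "c0", g, "t0")
            assert p_pos == pytest.approx(p_neg, abs=1e-12)


class TestPermutationNull:
    @staticmethod
    def brute_force_p(z_cols, gene_index, z_thr=2.0):
        """Enumerate every per-line gene assignment of a (genes, lines)
        slice and count how often |rec*| >= |rec_obs|."""
        G, L = z_cols.shape
        signs = (z_cols >= z_thr).astype(float) - (z_cols <= -z_thr)
        obs = abs(signs[gene_index].sum() / L)
        hits = total = 0
        for assign in itertools.product(range(G), repeat=L):
            s = sum(signs[g, line] for line, g in enumerate(assign))
            total += 1
            if abs(s / L) >= obs - 1e-12:
                hits += 1
        return hits / total

    def test_matches_exhaustive_enumeration_on_tiny_tensor(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            z_cols = rng.normal(0, 2.0, size=(3, 2))
            t = build_tensor(z_cols[None, :, :, None])
            expected = self.brute_force_p(z_cols, 0)
            got = rec_permutation_p(t, "c0", "g0", "t0", B=999, seed=0)
            assert got == pytest.approx(expected, abs=1e-12)
            # exact convolution path agrees with enumeration too
            assert rec_exact_p(t, "c0", "g0", "t0") == pytest.approx(
                expected, abs=1e-12
            )

    def test_rec_zero_has_p_one(self):
        z = np.zeros((1, 3, 4, 1))
        t = build_tensor(z)
        assert rec_permutation_p(t, "c0", "g0", "t0", B=999) == 1.0

    def test_single_gene_tensor_errors(self):
        t = build_tensor(np.zeros((1, 1, 4, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            rec_permutation_p(t, "c0", "g0", "t0")

    def test_small_B_rejected(self):
        t = build_tensor(np.zeros((1, 3, 4, 1)))
        with pytest.raises(ValueError, match="B"):
            rec_permutation_p(t, "c0", "g0", "t0", B=10)

    def test_monte_carlo_close_to_exact_on_larger_tensor(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1.8, size=(1, 50, 8, 1))
        t = build_tensor(z)
        exact = rec_exact_p(t, "c0", "g0", "t0")
        mc = rec_permutation_p(t, "c0", "g0", "t0", B=9999, seed=5)
        assert mc == pytest.approx(exact, abs=0.03)

    def test_compound_null_variant_runs(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1.5, size=(25, 3, 6, 1))
        t = build_tensor(z)
        p = rec_permutation_p(t, "c0", "g0", "t0", B=999, null="compound")
        assert 0 < p <= 1


class TestBhFdr:
    @staticmethod
    def step_up(p):
        """Independent BH step-up oracle."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_textbook_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_empty_list(self):
        assert bh_fdr([]).size == 0

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), self.step_up(p), atol=1e-12)


class TestRanking:
    def make_results(self, recs, ps):
        return pd.DataFrame({
            "compound": [f"c{i}" for i in range(len(recs))],
            "gene": "g", "timepoint": "6h",
            "rec": recs, "p": ps,
        })

    def test_most_negative_first(self):
        res = self.make_results([-1.0, -0.4, 0.2], [0.1, 0.1, 0.1])
        assert rank_rec(res, "g", "6h", 2) == ["c0", "c1"]

    def test_tie_broken_by_smaller_p(self):
        res = self.make_results([-0.5, -0.5], [0.01, 0.001])
        assert rank_rec(res, "g", "6h", 1) == ["c1"]

    def test_top_k_larger_than_list_warns(self):
        res = self.make_results([-0.5, 0.1], [0.1, 0.1])
        with pytest.warns(UserWarning, match="full list"):
            out = rank_rec(res, "g", "6h", 10)
        assert len(out) == 2

    def test_top_k_below_one_errors(self):
        res = self.make_results([-0.5], [0.1])
        with pytest.raises(ValueError):
            rank_rec(res, "g", "6h", 0)


class TestRecTable:
    def test_ranks_are_a_permutation_within_slice(self):
        rng = np.random.default_rng(9)
        t = build_tensor(rng.normal(0, 2, size=(8, 5, 6, 2)))
        tab = rec_table(t, RunConfig(seed=0))
        for _, sl in tab.groupby(["gene", "timepoint"]):
            assert sorted(sl["rank_neg"]) == list(range(1, len(sl) + 1))
        assert tab["rec"].between(-1, 1).all()
        assert tab["fdr"].between(0, 1).all()

    def test_deterministic_for_equal_config(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 2, size=(5, 4, 6, 2))
        a = rec_table(build_tensor(z), RunConfig(seed=3))
        b = rec_table(build_tensor(z), RunConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)
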