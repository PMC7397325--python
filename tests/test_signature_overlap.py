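import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prostasig import (
    GeneSet,
    SimConfig,
    bh_adjust,
    generate_cohort,
    generate_signature_collection,
    gsea_enrichment,
    hypergeom_overlap,
    moderated_t_de,
    pairwise_overlap_matrix,
)
from prostasig.errors import ConfigError, DegenerateInputError
from prostasig.signature_overlap import _ks_running_score


def _enumeration_oracle(N: int, m: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all n-subsets."""
    universe = list(range(N))
    a = set(universe[:m])
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(a & set(draw)) >= k
    return hits / total


class TestHypergeomOverlap:
    @staticmethod
    def _sets(N, m, n, k):
        universe = GeneSet("U", frozenset(f"g{i}" for i in range(N)))
        a = GeneSet("A", frozenset(f"g{i}" for i in range(m)))
        b = GeneSet("B", frozenset(f"g{i}" for i in range(m - k, m - k + n)))
        return a, b, universe

    def test_disjoint_sets_have_p_exactly_one(self):
        a, b, u = self._sets(12, 4, 4, 0)
        r = hypergeom_overlap(a, b, u)
        assert r.k == 0 and r.p == 1.0

    def test_complete_overlap_closed_form(self):
        # N=10, m=n=k=5 -> p = 1/C(10,5) = 1/252
        a, b, u = self._sets(10, 5, 5, 5)
        r = hypergeom_overlap(a, b, u)
        assert r.p == pytest.approx(1 / 252, rel=1e-12)

    @pytest.mark.parametrize("N, m, n, k", [
        (8, 3, 4, 1), (10, 5, 5, 3), (12, 6, 4, 2), (15, 7, 6, 4), (15, 10, 8, 5),
    ])
    def test_matches_enumeration_oracle(self, N, m, n, k):
        a, b, u = self._sets(N, m, n, k)
        r = hypergeom_overlap(a, b, u)
        assert r.k == k
        assert r.p == pytest.approx(_enumeration_oracle(N, m, n, k), abs=1e-12)

    def test_extreme_overlap_survives_underflow(self):
        # huge universe, huge overlap: p far below float underflow of the
        # naive sum, but finite and positive in log space
        genes = [f"g{i}" for i in range(20000)]
        u = GeneSet("U", frozenset(genes))
        a = GeneSet("A", frozenset(genes[:500]))
        b = GeneSet("B", frozenset(genes[:450] + genes[10000:10050]))
        r = hypergeom_overlap(a, b, u)
        assert 0.0 < r.p < 1e-300
        assert r.log10_p < -300

    def test_set_outside_universe_rejected(self):
        u = GeneSet("U", frozenset({"g1", "g2"}))
        a = GeneSet("A", frozenset({"zz"}))
        b = GeneSet("B", frozenset({"g1"}))
        with pytest.raises(DegenerateInputError):
            hypergeom_overlap(a, b, u)


class TestPairwiseOverlap:
    def test_disjoint_sets_all_null(self):
        sets = [GeneSet(f"S{i}", frozenset(f"g{i}_{j}" for j in range(5))) for i in range(3)]
        universe = frozenset(g for s in sets for g in s.genes)
        table = pairwise_overlap_matrix(sets, universe)
        off = table[table.set_a != table.set_b]
        assert (off.p == 1.0).all()
        assert (table[table.set_a == table.set_b].k == 5).all()

    def test_duplicated_set_attains_minimal_p(self):
        genes = [f"g{i}" for i in range(30)]
        s = GeneSet("S", frozenset(genes[:6]))
        dup = GeneSet("S2", frozenset(genes[:6]))
        other = GeneSet("T", frozenset(genes[6:12]))
        table = pairwise_overlap_matrix([s, dup, other], frozenset(genes))
        p_dup = table[(table.set_a == "S") & (table.set_b == "S2")].p.iloc[0]
        assert p_dup == min(table.p)
        assert p_dup == pytest.approx(1 / stats.binom(30, 6).pmf(0) ** 0, abs=1)  # sanity: <=1
        assert p_dup < 1e-5

    def test_converging_pairs_rank_below_null_pairs(self):
        cfg = SimConfig(seed=3)
        expr, _, truth = generate_cohort(cfg)
        sets = generate_signature_collection(truth, cfg, overlap_fraction=0.6, seed=4)
        table = pairwise_overlap_matrix(sets, frozenset(expr.index))
        table = table[table.set_a < table.set_b]
        same = table.apply(lambda r: r.set_a.split("_")[1] == r.set_b.split("_")[1], axis=1)
        assert table[same].p.max() < table[~same].p.min()


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # p (0.01, 0.02, 0.03, 0.04): p_(i) * 4/i = .04, .04, .04, .04
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    def test_monotone_and_order_invariant(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        shuffled = list(reversed(p))
        assert np.allclose(sorted(bh_adjust(shuffled)), sorted(adj))


class TestModeratedT:
    @staticmethod
    def _matrix(rng, n_genes, groups):
        n = sum(groups)
        X = rng.normal(size=(n_genes, n))
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{j}" for j in range(n)])
        labels = pd.Series(
            np.repeat(np.arange(1, len(groups) + 1), groups), index=m.columns)
        return m, labels

    def test_null_control_yields_no_significant_genes(self):
        total = 0
        for seed in range(20):
            m, labels = self._matrix(np.random.default_rng(seed), 1000, (10, 10, 10))
            res = moderated_t_de(m, labels, fdr_threshold=0.001)
            total += sum(len(v) for v in res.significant.values())
        assert total <= 2

    def test_spiked_gene_detected(self):
        rng = np.random.default_rng(1)
        m, labels = self._matrix(rng, 500, (50, 50))
        m.iloc[0] = rng.normal(0, 0.5, size=100)
        m.iloc[0, :50] += 1.5
        res = moderated_t_de(m, labels)
        assert "g0" in res.significant[1]

    def test_small_fold_change_excluded_despite_tiny_p(self):
        rng = np.random.default_rng(2)
        m, labels = self._matrix(rng, 200, (30, 30))
        delta = np.log2(1.3)  # below the 1.4-fold filter
        m.iloc[0] = rng.normal(0, 0.01, size=60)
        m.iloc[0, :30] += delta
        res = moderated_t_de(m, labels)
        row = res.table[(res.table.subgroup == 1) & (res.table.gene == "g0")].iloc[0]
        assert row.adj_p < res.fdr_threshold
        assert not row.significant

    def test_zero_prior_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(3)
        m, labels = self._matrix(rng, 100, (15, 20))
        res = moderated_t_de(m, labels, prior_df=0.0)
        mine = res.table[res.table.subgroup == 1].set_index("gene")
        t_ref, p_ref = stats.ttest_ind(m.iloc[:, :15], m.iloc[:, 15:], axis=1, equal_var=True)
        assert np.allclose(mine.loc[m.index, "t"], t_ref, atol=1e-10)
        assert np.allclose(mine.loc[m.index, "p"], p_ref, atol=1e-10)

    def test_small_subgroup_rejected(self):
        m, labels = self._matrix(np.random.default_rng(4), 50, (2, 10))
        with pytest.raises(ConfigError, match="1"):
            moderated_t_de(m, labels)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_reference(self, tmp_path):
        """Independent oracle: limma's eBayes on the same two-group design."""
        rng = np.random.default_rng(0)
        n1, n2, G = 12, 18, 300
        X = rng.normal(0, 1, size=(G, n1 + n2)) * rng.gamma(2, 0.5, size=(G, 1)) ** 0.5
        X[:20, :n1] += 1.0
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(G)],
                         columns=[f"s{j}" for j in range(n1 + n2)])
        labels = pd.Series([1] * n1 + [2] * n2, index=m.columns)
        res = moderated_t_de(m, labels)
        mine = res.table[res.table.subgroup == 1].set_index("gene")

        m.to_csv(tmp_path / "x.tsv", sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
        grp <- factor(c(rep("A",{n1}), rep("B",{n2})))
        design <- model.matrix(~0+grp)
        fit <- lmFit(x, design)
        cf <- contrasts.fit(fit, makeContrasts(grpA-grpB, levels=design))
        eb <- eBayes(cf)
        out <- data.frame(gene=rownames(x), t=eb$t[,1], p=eb$p.value[,1],
                          d0=eb$df.prior, s02=eb$s2.prior)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert res.prior[1]["d0"] == pytest.approx(ref.d0.iloc[0], rel=1e-4)
        assert res.prior[1]["s0_sq"] == pytest.approx(ref.s02.iloc[0], rel=1e-4)
        joined = mine.join(ref, rsuffix="_ref")
        assert np.allclose(joined.t, joined.t_ref, atol=1e-8)
        assert np.allclose(joined.p, joined.p_ref, atol=1e-8)


def _gsea_oracle(ranked_scores, hit, weight=1.0):
    """Plain-python running sum, independent of the vectorised implementation."""
    w = [abs(s) ** weight if weight else 1.0 for s in ranked_scores]
    hit_total = sum(wi for wi, h in zip(w, hit) if h)
    miss_total = sum(1 for h in hit if not h)
    running, best = 0.0, 0.0
    for wi, h in zip(w, hit):
        running += wi / hit_total if h else -1.0 / miss_total
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaEnrichment:
    @staticmethod
    def _ranking(n=10):
        return pd.Series(np.arange(n, 0, -1, dtype=float),
                         index=[f"s{i}" for i in range(n)])

    def test_top_ranked_members_reach_extreme_score(self):
        scores = self._ranking(50)
        es, _ = gsea_enrichment(scores, {"s0", "s1", "s2"}, n_perm=200, seed=0)
        assert es > 0.9

    def test_hand_running_sum_on_ten_items(self):
        scores = self._ranking(10)
        members = {"s0", "s1", "s2"}
        es, _ = gsea_enrichment(scores, members, n_perm=10, seed=0)
        hit = [s in members for s in scores.index]
        assert es == pytest.approx(_gsea_oracle(scores.to_numpy(), hit), abs=1e-12)
        # by hand: hits carry weights 10,9,8 (sum 27); all three precede any
        # miss, so the running sum peaks at exactly 1.0
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_random_members_give_null_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for seed in range(11):
            scores = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
            members = set(rng.choice(scores.index, 12, replace=False))
            _, p = gsea_enrichment(scores, members, n_perm=300, seed=seed)
            ps.append(p)
        assert 0.2 < np.median(ps) < 0.8

    def test_unweighted_statistic_invariant_to_monotone_rescaling(self):
        scores = pd.Series([9.0, 7.0, 5.0, 3.0, 2.0, 1.0],
                           index=[f"s{i}" for i in range(6)])
        members = {"s1", "s3"}
        es1, p1 = gsea_enrichment(scores, members, n_perm=500, seed=2, weight=0.0)
        es2, p2 = gsea_enrichment(scores ** 3, members, n_perm=500, seed=2, weight=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)
        assert p1 == p2

    @pytest.mark.parametrize("members", [set(), {"s0", "s1", "s2", "s3", "s4", "s5"}])
    def test_degenerate_member_sets_rejected(self, members):
        scores = pd.Series([3.0, 2.0, 1.0, 0.5, 0.2, 0.1],
                           index=[f"s{i}" for i in range(6)])
        with pytest.raises(DegenerateInputError):
            gsea_enrichment(scores, members, n_perm=10, seed=0)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            members = set(rng.choice(scores.index, int(rng.integers(1, n - 1)) or 1,
                                     replace=False))
            es, _ = gsea_enrichment(scores, members, n_perm=5, seed=0)
            order = np.argsort(-scores.to_numpy(), kind="stable")
            ranked = scores.to_numpy()[order]
            hit = [scores.index[i] in members for i in order]
            assert es == pytest.approx(_gsea_oracle(ranked, hit), abs=1e-12)
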