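"""Decoder propagation, permutation enrichment, BH, candidate selection."""

import numpy as np
import pytest
from scipy import stats

from acidae.containers import ExpressionCompendium
from acidae.dae import DenoisingAutoencoder
from acidae.signatures import (
    EnrichmentResult,
    NodeGeneVector,
    bh_adjust,
    extract_gene_set,
    node_gene_vector,
    permutation_gsea,
    read_gmt,
    select_candidates,
    tally_term_directions,
    write_gmt,
)


def test_gmt_round_trip(tmp_path):
    sets = {"TERM_A": ["g2", "g1"], "TERM_B": ["g3"]}
    p = tmp_path / "sets.gmt"
    write_gmt(p, sets)
    assert read_gmt(p) == {"TERM_A": ["g1", "g2"], "TERM_B": ["g3"]}


def zero_weight_dae(n_genes=6, bottleneck=2):
    m = DenoisingAutoencoder(hidden1=4, hidden2=3, bottleneck=bottleneck,
                             dtype="float64")
    m.n_features_in_ = n_genes
    m._init_params(n_genes, np.random.default_rng(0))
    for p in m._params():
        p[...] = 0.0
    return m


class TestNodeGeneVector:
    def test_zero_decoder_gives_flat_half(self):
        v = node_gene_vector(zero_weight_dae(), 0)
        np.testing.assert_allclose(v.output, 0.5)
        np.testing.assert_allclose(v.baseline, 0.5)
        np.testing.assert_allclose(v.signed_score, 0.0)

    def test_matches_manual_decoder_evaluation(self):
        m = zero_weight_dae(n_genes=2, bottleneck=1)
        rng = np.random.default_rng(3)
        for p in m._params():
            p[...] = rng.normal(size=p.shape)
        v = node_gene_vector(m, 0)
        sig = lambda z: 1 / (1 + np.exp(-z))
        a = np.array([1.0])
        d2 = sig(a @ m.W3_.T + m.c3_)
        d1 = sig(d2 @ m.W2_.T + m.c2_)
        manual = sig(d1 @ m.W1_.T + m.c1_)
        np.testing.assert_allclose(v.output, manual)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            node_gene_vector(zero_weight_dae(bottleneck=2), 5)


class TestExtractGeneSet:
    def vec(self, out):
        out = np.asarray(out, dtype=float)
        return NodeGeneVector(0, 0, out, np.full_like(out, 0.5))

    def test_top1(self):
        s = extract_gene_set([self.vec([0.9, 0.1, 0.5])], ["g1", "g2", "g3"], cutoff=1)
        assert s.genes == {"g1"}

    def test_tie_broken_lexicographically(self):
        vs = [self.vec([0.9, 0.1, 0.5]), self.vec([0.1, 0.9, 0.5])]
        s = extract_gene_set(vs, ["g1", "g2", "g3"], cutoff=1)
        assert s.genes == {"g1"}  # all means equal 0.5; lexicographic wins

    def test_fractional_cutoff(self):
        s = extract_gene_set([self.vec(np.linspace(1, 0, 10))],
                             [f"g{i}" for i in range(10)], cutoff=0.3)
        assert len(s.genes) == 3

    def test_empty_vector_list_rejected(self):
        with pytest.raises(ValueError):
            extract_gene_set([], ["g1"], cutoff=1)


class TestPermutationGsea:
    def test_extreme_term_hits_plus_one_floor(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.zeros(100)
        scores[:10] = 1.0
        r = permutation_gsea(scores, genes, genes[:10], n_perm=1000, seed=0)
        assert r.p_value == pytest.approx(1 / 1001)
        assert r.direction == "up"

    def test_degenerate_equal_scores(self):
        genes = [f"g{i}" for i in range(50)]
        r = permutation_gsea(np.ones(50) * 0.3, genes, genes[:8], n_perm=500, seed=0)
        assert r.p_value == 1.0

    def test_down_direction(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.zeros(100)
        scores[:10] = -1.0
        r = permutation_gsea(scores, genes, genes[:10], n_perm=500, seed=0)
        assert r.direction == "down"

    def test_size_bounds_skip(self):
        genes = [f"g{i}" for i in range(100)]
        r = permutation_gsea(np.zeros(100), genes, genes[:3], n_perm=500, seed=0)
        assert r.skipped is not None

    def test_ks_statistic_extreme_and_degenerate(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.zeros(100)
        scores[:10] = 1.0
        r = permutation_gsea(scores, genes, genes[:10], n_perm=500, seed=0,
                             statistic="ks")
        assert r.statistic == pytest.approx(1.0)  # all hits before any miss
        assert r.p_value < 0.1  # null can tie the extreme ES via top-ranked genes
        assert r.direction == "up"
        # down-shifted term genes give a negative enrichment score
        down = permutation_gsea(-scores, genes, genes[:10], n_perm=500, seed=0,
                                statistic="ks")
        assert down.direction == "down"
        assert down.statistic < 0

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="statistic"):
            permutation_gsea(np.zeros(50), [f"g{i}" for i in range(50)],
                             [f"g{i}" for i in range(10)], n_perm=200,
                             statistic="median")

    def test_null_p_values_roughly_uniform(self, rng):
        scores = rng.normal(size=400)
        genes = [f"g{i}" for i in range(400)]
        ps = []
        for t in range(60):
            term = rng.choice(genes, size=15, replace=False)
            ps.append(permutation_gsea(scores, genes, term, n_perm=2000,
                                       seed=t).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    def test_matches_brute_force_step_up(self, rng):
        def brute(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                rank = n - rank_from_top
                prev = min(prev, p[i] * n / rank)
                adj[i] = prev
            return adj

        for _ in range(1000):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 25))
            np.testing.assert_allclose(bh_adjust(p), brute(p), atol=1e-12)


class TestTally:
    def mk(self, term, direction, padj, node=0):
        return EnrichmentResult(term=term, statistic=1.0 if direction == "up" else -1.0,
                                direction=direction, p_value=padj, n_permutations=100,
                                n_term_genes=10, node=node, p_adjusted=padj)

    def test_counting(self):
        res = [self.mk("T1", "up", 1e-5, 0), self.mk("T1", "up", 1e-5, 1),
               self.mk("T1", "down", 1e-5, 2), self.mk("T1", "up", 0.2, 3)]
        tab = tally_term_directions(res, padj_threshold=0.0005)
        assert tab.loc[0, ["n_nodes_up", "n_nodes_down"]].tolist() == [2, 1]

    def test_empty(self):
        assert tally_term_directions([], 0.0005).empty

    def test_matches_brute_force(self, rng):
        res = [self.mk(f"T{rng.integers(5)}", rng.choice(["up", "down"]),
                       float(rng.uniform(0, 0.01)), i) for i in range(200)]
        tab = tally_term_directions(res, padj_threshold=0.005).set_index("term")
        for term in {r.term for r in res}:
            up = sum(1 for r in res if r.term == term and r.direction == "up"
                     and r.p_adjusted <= 0.005)
            down = sum(1 for r in res if r.term == term and r.direction == "down"
                       and r.p_adjusted <= 0.005)
            if up or down:
                assert tab.loc[term].tolist() == [up, down]
            else:
                assert term not in tab.index


def compendium_from_condition_means(cond_means, n_rep=2):
    """Exact replicate-constant compendium from per-condition mean rows."""
    conds = list(cond_means)
    n_genes = len(next(iter(cond_means.values())))
    values = np.column_stack([np.repeat(np.asarray(cond_means[c], float)[:, None],
                                        n_rep, axis=1) for c in conds])
    samples = [f"{c}_rep{i}" for c in conds for i in range(1, n_rep + 1)]
    cond_of = {s: s.rsplit("_rep", 1)[0] for s in samples}
    return ExpressionCompendium(values.reshape(n_genes, -1),
                                [f"g{i}" for i in range(n_genes)], samples, cond_of)


class TestSelectCandidates:
    def test_hand_example_half_fraction_rejected(self):
        comp = compendium_from_condition_means(
            {"acid": [5.0], "heat": [4.4], "osmo": [4.6]})
        (cand,) = select_candidates(comp, {"g0"}, ["acid"], ["heat", "osmo"])
        np.testing.assert_allclose(sorted(cand.log2_fcs), [0.4, 0.6])
        assert cand.fraction_passing == 0.5
        assert not cand.selected

    def test_all_comparisons_passing_selected(self):
        comp = compendium_from_condition_means(
            {"acid": [6.0], "heat": [5.0], "osmo": [5.2]})
        (cand,) = select_candidates(comp, {"g0"}, ["acid"], ["heat", "osmo"])
        assert cand.selected

    def test_boundary_13_of_14_fails_14_of_14_passes(self):
        # 2 acid x 7 other conditions = 14 comparisons
        others = [f"o{i}" for i in range(7)]
        base = {c: [4.0, 4.0] for c in others}
        base["acid1"] = [6.0, 6.0]
        base["acid2"] = [6.0, 4.2]  # gene2: acid2-vs-o* lfc = 0.2 -> 7/14 fail
        comp = compendium_from_condition_means(base)
        cands = {c.gene_id: c for c in select_candidates(
            comp, {"g0", "g1"}, ["acid1", "acid2"], others)}
        assert cands["g0"].selected
        assert not cands["g1"].selected
        # exactly one failing comparison rejects at frac_min=0.95
        base["acid2"] = [6.0, 5.6]
        base["o0"] = [4.0, 5.2]  # g1: acid2 vs o0 lfc 0.4, all 13 others pass
        comp = compendium_from_condition_means(base)
        cands = {c.gene_id: c for c in select_candidates(
            comp, {"g0", "g1"}, ["acid1", "acid2"], others)}
        assert cands["g1"].fraction_passing == pytest.approx(13 / 14)
        assert not cands["g1"].selected

    def test_matches_brute_force_filter(self, rng):
        conds = ["acid1", "acid2", "h", "e", "o"]
        n_genes = 40
        comp = compendium_from_condition_means(
            {c: rng.normal(5, 1, n_genes) for c in conds})
        sig = {f"g{i}" for i in rng.choice(n_genes, 20, replace=False)}
        got = {c.gene_id: c.selected
               for c in select_candidates(comp, sig, ["acid1", "acid2"], ["h", "e", "o"])}
        means = {c: {g: comp.values[i, comp.column_indices(comp.samples_of_condition(c))].mean()
                     for i, g in enumerate(comp.gene_ids)} for c in conds}
        for g in sig:
            lfcs = [means[a][g] - means[o][g]
                    for a in ("acid1", "acid2") for o in ("h", "e", "o")]
            assert got[g] == (np.mean(np.array(lfcs) >= 0.5) >= 0.95)

    def test_sorted_by_acid_expression(self):
        comp = compendium_from_condition_means(
            {"acid": [5.0, 8.0, 7.0], "h": [1.0, 1.0, 1.0]})
        cands = select_candidates(comp, {"g0", "g1", "g2"}, ["acid"], ["h"])
        assert [c.gene_id for c in cands] == ["g1", "g2", "g0"]

    def test_disjointness_enforced(self, small_compendium):
        with pytest.raises(ValueError, match="disjoint"):
            select_candidates(small_compendium, {"gA"}, ["acid"], ["acid"])
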