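"""miRNA-pair similarity: symmetric BMA route, asymmetric weighted route,
significance weights, and edge-set thresholding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_annotations, random_dag
from mirsignet.go_semantics import build_dag, information_content
from mirsignet.mirna_similarity import (
    SimilarityEdge,
    build_edge_set,
    gosemsim_mirna_similarity,
    mirgofs_like_similarity,
    term_significance_weights,
)


@pytest.fixture
def annotated_world():
    rng = np.random.default_rng(42)
    dag = random_dag(rng, 12)
    gene_terms = random_annotations(rng, dag, 10)
    corpus = information_content(dag, gene_terms)
    return dag, corpus, set(gene_terms)


class TestSymmetricSimilarity:
    def test_identical_target_sets_score_one(self, annotated_world):
        dag, corpus, genes = annotated_world
        targets = set(sorted(genes)[:3])
        assert gosemsim_mirna_similarity(targets, targets, corpus, dag) == pytest.approx(1.0)

    def test_symmetry(self, annotated_world):
        dag, corpus, genes = annotated_world
        gs = sorted(genes)
        a, b = set(gs[:3]), set(gs[3:7])
        s1 = gosemsim_mirna_similarity(a, b, corpus, dag)
        s2 = gosemsim_mirna_similarity(b, a, corpus, dag)
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0

    def test_empty_target_set_is_error(self, annotated_world):
        dag, corpus, genes = annotated_world
        with pytest.raises(ValueError, match="target"):
            gosemsim_mirna_similarity(set(), {"g0"}, corpus, dag)


class TestSignificanceWeights:
    def test_exact_hypergeometric_tail(self):
        # universe of 10 genes, 4 carrying term T, 5 targets of which 3 carry T:
        # upper tail = (C(4,3) C(6,2) + C(4,4) C(6,1)) / C(10,5) = 66/252
        dag = build_dag(
            namespace={"root": "BP", "T": "BP"},
            parents={"root": set(), "T": {"root"}},
        )
        genes = {f"g{i}": ({"T"} if i < 4 else {"root"}) for i in range(10)}
        corpus = information_content(dag, genes)
        targets = {"g0", "g1", "g2", "g8", "g9"}  # 3 of 5 carry T
        w = term_significance_weights(targets, corpus, dag, set(genes))
        p = 66 / 252
        expected = min(1.0, -math.log10(p) / math.log10(10))
        assert w["T"] == pytest.approx(expected, abs=1e-12)

    def test_uninformative_term_gets_minimal_weight(self):
        dag = build_dag(namespace={"root": "BP"}, parents={"root": set()})
        genes = {f"g{i}": {"root"} for i in range(6)}
        corpus = information_content(dag, genes)
        w = term_significance_weights({"g0", "g1"}, corpus, dag, set(genes))
        assert 0.0 < w["root"] <= 1e-6  # p = 1 -> floor

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_uni = int(rng.integers(4, 12))
            dag = build_dag(
                namespace={"root": "BP", "T": "BP"},
                parents={"root": set(), "T": {"root"}},
            )
            carriers = set(rng.choice(n_uni, size=int(rng.integers(1, n_uni + 1)), replace=False))
            genes = {
                f"g{i}": ({"T"} if i in carriers else {"root"}) for i in range(n_uni)
            }
            corpus = information_content(dag, genes)
            n_t = int(rng.integers(1, n_uni + 1))
            targets = {f"g{i}" for i in rng.choice(n_uni, size=n_t, replace=False)}
            k = len({f"g{i}" for i in carriers} & targets)
            if k == 0:
                continue
            # exact tail by enumeration over the hypergeometric support
            K = len(carriers)
            p = sum(
                math.comb(K, j) * math.comb(n_uni - K, n_t - j)
                for j in range(k, min(K, n_t) + 1)
            ) / math.comb(n_uni, n_t)
            w = term_significance_weights(targets, corpus, dag, set(genes))
            expected = min(1.0, max(1e-6, -math.log10(p) / math.log10(n_uni)))
            assert w["T"] == pytest.approx(expected, abs=1e-9)


class TestAsymmetricSimilarity:
    def test_identical_sets_score_one(self, annotated_world):
        dag, corpus, genes = annotated_world
        t = set(sorted(genes)[:4])
        assert mirgofs_like_similarity(t, t, corpus, dag, genes) == pytest.approx(1.0)

    def test_disjoint_namespaces_score_zero(self):
        dag = build_dag(
            namespace={"r1": "BP", "r2": "MF", "x": "BP", "y": "MF"},
            parents={"r1": set(), "r2": set(), "x": {"r1"}, "y": {"r2"}},
        )
        corpus = information_content(dag, {"ga": {"x"}, "gb": {"y"}})
        # each gene annotates only its own namespace: every cross affinity is 0
        s = mirgofs_like_similarity({"ga"}, {"gb"}, corpus, dag, {"ga", "gb"})
        assert s == 0.0

    def test_directed_sums_match_enumeration_oracle(self):
        # chain root -> M -> L, one namespace; closures computable by hand
        dag = build_dag(
            namespace={"root": "BP", "M": "BP", "L": "BP"},
            parents={"root": set(), "M": {"root"}, "L": {"M"}},
        )
        genes = {"gA": {"L"}, "gB": {"M"}, "gC": {"root"}, "gD": {"L"}}
        corpus = information_content(dag, genes)
        universe = set(genes)
        got = mirgofs_like_similarity({"gA"}, {"gB"}, corpus, dag, universe)

        # brute-force: affinity(t, s) = |cl(t) & cl(s)| / |cl(t) | cl(s)|
        # where cl = ancestors | descendants (both reflexive)
        cl = {t: dag.ancestors(t) | dag.descendants(t) for t in dag.terms}

        def aff(t, s):
            return len(cl[t] & cl[s]) / len(cl[t] | cl[s])

        terms_a = sorted(corpus.gene_terms["gA"])  # {L, M, root}
        terms_b = sorted(corpus.gene_terms["gB"])  # {M, root}
        w_a = term_significance_weights({"gA"}, corpus, dag, universe)
        w_b = term_significance_weights({"gB"}, corpus, dag, universe)
        s_ab = sum(w_a[t] * max(aff(t, s) for s in terms_b) for t in terms_a) / sum(
            w_a[t] for t in terms_a
        )
        s_ba = sum(w_b[t] * max(aff(t, s) for s in terms_a) for t in terms_b) / sum(
            w_b[t] for t in terms_b
        )
        assert got == pytest.approx((s_ab + s_ba) / 2, abs=1e-12)

    def test_subset_direction_dominates(self, annotated_world):
        # when A's terms are a subset of B's, S(A->B) = 1 >= S(B->A),
        # so the averaged score exceeds the reverse-gap bound
        dag, corpus, genes = annotated_world
        gs = sorted(genes)
        sub, sup = {gs[0]}, {gs[0], gs[1], gs[2]}
        s = mirgofs_like_similarity(sub, sup, corpus, dag, genes)
        assert 0.5 <= s <= 1.0  # S(sub->sup) contributes a full 1/2


class TestBuildEdgeSet:
    MIRNAS = {"hsa-miR-1", "hsa-miR-2", "hsa-miR-3"}

    def test_cutoff_is_inclusive(self):
        pair = ("hsa-miR-1", "hsa-miR-2")
        assert build_edge_set(self.MIRNAS, {pair: 0.59}, {pair: 0.59}) == []
        edges = build_edge_set(self.MIRNAS, {pair: 0.6}, {})
        assert len(edges) == 1 and edges[0].w_combined == pytest.approx(0.6)

    def test_pair_in_both_sources_merges_to_one_edge(self):
        pair = ("hsa-miR-2", "hsa-miR-1")  # unordered input
        edges = build_edge_set(self.MIRNAS, {pair: 0.7}, {("hsa-miR-1", "hsa-miR-2"): 0.9})
        assert len(edges) == 1
        e = edges[0]
        assert (e.mirna_a, e.mirna_b) == ("hsa-miR-1", "hsa-miR-2")
        assert e.w_sym == 0.7 and e.w_asym == 0.9 and e.w_combined == 0.9

    def test_per_source_threshold_before_union(self):
        pair = ("hsa-miR-1", "hsa-miR-2")
        edges = build_edge_set(self.MIRNAS, {pair: 0.3}, {pair: 0.8})
        assert len(edges) == 1
        assert edges[0].w_sym is None and edges[0].w_asym == 0.8

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.floats(0, 1))
    def test_raising_threshold_never_adds_edges(self, weights, thr):
        mirnas = {f"hsa-miR-{i}" for i in range(len(weights) + 1)}
        scores = {
            (f"hsa-miR-{i}", f"hsa-miR-{i + 1}"): w for i, w in enumerate(weights)
        }
        lo = {(e.mirna_a, e.mirna_b) for e in build_edge_set(mirnas, scores, {}, min(thr, 0.5))}
        hi = {(e.mirna_a, e.mirna_b) for e in build_edge_set(mirnas, scores, {}, max(thr, 0.5))}
        assert hi <= lo

    def test_self_loops_rejected(self):
        assert build_edge_set(self.MIRNAS, {("hsa-miR-1", "hsa-miR-1"): 0.9}, {}) == []
        with pytest.raises(ValueError):
            SimilarityEdge("hsa-miR-1", "hsa-miR-1", w_sym=0.9)
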