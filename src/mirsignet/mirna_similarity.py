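"""Functional similarity of miRNA pairs from their consensus target genes.

Two complementary scores are computed per miRNA pair:

* a symmetric score — best-match-average (BMA) aggregation of pairwise
  gene similarities between the two target sets, where gene similarity is
  itself MICA-based (Lin by default);
* an asymmetric, significance-weighted score (``mirgofs_like``) — term-level
  affinity is the Jaccard index of the terms' combined ancestor+descendant
  closures, each side's terms are weighted by the hypergeometric enrichment
  significance of the term in that miRNA's target set, a directed score
  averages each term's best affinity in the other set, and the two directions
  are averaged into one reported value.

The asymmetric measure is a declared approximation of the MIRGOFS family of
measures: it realizes closure-aware term affinity, per-term significance
weighting and asymmetric set comparison, without claiming to reproduce any
published tool's exact numbers.

Pairs from either source survive when their score reaches the similarity
threshold (default 0.6); surviving pairs are merged into single edges that
carry both weights, with the combined weight being the maximum present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .go_semantics import AnnotationCorpus, GoDag, bma, gene_similarity

logger = logging.getLogger(__name__)

#: Default inclusion cutoff on either similarity source.
DEFAULT_THRESHOLD = 0.6

#: Floor keeping significance weights strictly positive.
_WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class SimilarityEdge:
    """One undirected miRNA pair with its per-source and combined weights."""

    mirna_a: str
    mirna_b: str
    w_sym: float | None = None
    w_asym: float | None = None

    def __post_init__(self) -> None:
        if self.mirna_a >= self.mirna_b:
            raise ValueError("edge endpoints must satisfy mirna_a < mirna_b")
        if self.w_sym is None and self.w_asym is None:
            raise ValueError("edge must carry at least one weight")

    @property
    def w_combined(self) -> float:
        return max(w for w in (self.w_sym, self.w_asym) if w is not None)


def gosemsim_mirna_similarity(
    targets_a: set[str],
    targets_b: set[str],
    corpus: AnnotationCorpus,
    dag: GoDag,
    method: str = "lin",
    cache: dict | None = None,
) -> float:
    """Symmetric miRNA similarity: BMA over the target-set gene-pair matrix.

    ``cache`` (optional dict) memoizes gene-pair similarities across calls,
    which matters when scoring all miRNA pairs of a corpus.
    """
    if not targets_a or not targets_b:
        raise ValueError("empty target set; both miRNAs need consensus targets")
    ga, gb = sorted(targets_a), sorted(targets_b)
    m = np.zeros((len(ga), len(gb)))
    for i, a in enumerate(ga):
        for j, b in enumerate(gb):
            key = (a, b, method) if a <= b else (b, a, method)
            if cache is not None and key in cache:
                m[i, j] = cache[key]
            else:
                m[i, j] = gene_similarity(corpus, dag, a, b, method)
                if cache is not None:
                    cache[key] = m[i, j]
    return bma(m)


def term_significance_weights(
    target_genes: set[str],
    corpus: AnnotationCorpus,
    dag: GoDag,
    universe: set[str],
) -> dict[str, float]:
    """Enrichment weight per ontology term annotated in a target set.

    For a term annotating K of the N universe genes and k of the n target
    genes, p is the hypergeometric upper tail P(X >= k).  The weight maps p
    to (0, 1] via -log10(p) / cap, capped at 1, where cap = log10(N) — the
    magnitude of the smallest achievable single-draw p given the universe
    size — so one vanishing p-value cannot dominate; a tiny floor keeps
    uninformative terms (p = 1) strictly positive.
    """
    if not universe:
        raise ValueError("empty annotation universe")
    targets = {g for g in target_genes if g in corpus.gene_terms}
    uni = {g for g in universe if g in corpus.gene_terms}
    if not targets <= uni:
        raise ValueError("target genes must be a subset of the universe")
    n_universe = len(uni)
    cap = math.log10(n_universe) if n_universe > 1 else 1.0
    term_targets: dict[str, int] = {}
    for g in targets:
        for t in corpus.gene_terms[g]:
            term_targets[t] = term_targets.get(t, 0) + 1
    term_universe: dict[str, int] = {}
    for g in uni:
        for t in corpus.gene_terms[g]:
            term_universe[t] = term_universe.get(t, 0) + 1
    weights: dict[str, float] = {}
    for t, k in term_targets.items():
        p = float(hypergeom.sf(k - 1, n_universe, term_universe[t], len(targets)))
        p = min(max(p, 1e-300), 1.0)
        weights[t] = min(1.0, max(_WEIGHT_FLOOR, -math.log10(p) / cap))
    return weights


def _closure_affinity(dag: GoDag, t1: str, t2: str, closure_cache: dict) -> float:
    """Jaccard of the terms' unions of ancestor and descendant closures."""
    def closures(t: str) -> frozenset[str]:
        c = closure_cache.get(t)
        if c is None:
            c = closure_cache[t] = dag.ancestors(t) | dag.descendants(t)
        return c

    c1, c2 = closures(t1), closures(t2)
    inter = len(c1 & c2)
    return inter / len(c1 | c2) if inter else 0.0


def mirgofs_like_similarity(
    targets_a: set[str],
    targets_b: set[str],
    corpus: AnnotationCorpus,
    dag: GoDag,
    universe: set[str],
    cache: dict | None = None,
) -> float:
    """Asymmetric significance-weighted similarity, averaged over directions.

    S(A->B) is the weighted mean, over A's annotated terms, of each term's
    best closure affinity among B's terms; the returned value is
    (S(A->B) + S(B->A)) / 2 and lies in [0, 1].
    """
    if not targets_a or not targets_b:
        raise ValueError("empty target set; both miRNAs need consensus targets")
    closure_cache = cache if cache is not None else {}

    def term_set(targets: set[str]) -> list[str]:
        terms: set[str] = set()
        for g in targets:
            terms |= corpus.gene_terms.get(g, frozenset())
        return sorted(terms)

    terms_a, terms_b = term_set(targets_a), term_set(targets_b)
    if not terms_a or not terms_b:
        raise ValueError("target sets carry no ontology annotation")
    w_a = term_significance_weights(targets_a, corpus, dag, universe)
    w_b = term_significance_weights(targets_b, corpus, dag, universe)

    def directed(src: list[str], dst: list[str], w: dict[str, float]) -> float:
        total_w = sum(w.get(t, _WEIGHT_FLOOR) for t in src)
        if total_w <= 0:
            return 0.0
        acc = 0.0
        for t in src:
            best = max(_closure_affinity(dag, t, s, closure_cache) for s in dst)
            acc += w.get(t, _WEIGHT_FLOOR) * best
        return acc / total_w

    return (directed(terms_a, terms_b, w_a) + directed(terms_b, terms_a, w_b)) / 2.0


def build_edge_set(
    mirnas: set[str],
    sym_scores: dict[tuple[str, str], float],
    asym_scores: dict[tuple[str, str], float],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SimilarityEdge]:
    """Threshold each source, union the surviving pairs, merge duplicates.

    A pair enters when either source reaches the threshold; the edge carries
    whichever weights passed (per-source cutoff before merging).  Self-loops
    and pairs outside ``mirnas`` are ignored.  Output is sorted.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")

    def norm(pair: tuple[str, str]) -> tuple[str, str] | None:
        a, b = pair
        if a == b or a not in mirnas or b not in mirnas:
            return None
        return (a, b) if a < b else (b, a)

    passing: dict[tuple[str, str], dict[str, float]] = {}
    for scores, tag in ((sym_scores, "w_sym"), (asym_scores, "w_asym")):
        for pair, w in scores.items():
            key = norm(pair)
            if key is not None and w >= threshold:
                passing.setdefault(key, {})[tag] = w
    return [
        SimilarityEdge(mirna_a=a, mirna_b=b, **ws)
        for (a, b), ws in sorted(passing.items())
    ]
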