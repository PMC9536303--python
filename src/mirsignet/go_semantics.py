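"""Gene Ontology DAG handling and information-content semantic similarity.

The ontology is a rooted DAG per namespace (biological process, molecular
function, cellular component) whose edges are ``is_a``/``part_of`` parent
links.  Gene annotations are propagated to all ancestors (the "true-path"
rule); a term's annotation probability p(t) is the fraction of annotated
genes in its namespace carrying the term after propagation, and its
information content is IC(t) = -ln p(t).  Term similarity follows the
most-informative-common-ancestor (MICA) family:

    Lin(t1, t2)    = 2 IC(MICA) / (IC(t1) + IC(t2))
    Resnik(t1, t2) = IC(MICA) / max IC in the namespace      (scaled to [0,1])

and gene / gene-set similarity aggregates pairwise term scores by the
best-match average (BMA): the mean of the row-wise maxima and the column-wise
maxima of the similarity matrix, averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

#: Parent-edge relations retained from the ontology file.
PARENT_RELATIONS = ("is_a", "part_of")


class OntologyFormatError(ValueError):
    """Raised for cyclic or rootless ontology input."""


@dataclass
class GoDag:
    """Ontology DAG: term namespaces, parent links, one root per namespace."""

    namespace: dict[str, str]
    parents: dict[str, frozenset[str]]
    roots: dict[str, str]
    _children: dict[str, set[str]] | None = field(default=None, repr=False)
    _up_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    @property
    def children(self) -> dict[str, set[str]]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.namespace}
            for term, ps in self.parents.items():
                for p in ps:
                    ch[p].add(term)
            self._children = ch
        return self._children

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive up-closure of ``term`` (memoized)."""
        cached = self._up_cache.get(term)
        if cached is None:
            closure = {term}
            for p in self.parents.get(term, ()):
                closure |= self.ancestors(p)
            cached = self._up_cache[term] = frozenset(closure)
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive-transitive down-closure of ``term``."""
        closure: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t not in closure:
                closure.add(t)
                stack.extend(self.children.get(t, ()))
        return frozenset(closure)


def build_dag(
    namespace: dict[str, str], parents: dict[str, frozenset[str] | set[str]]
) -> GoDag:
    """Assemble and validate a :class:`GoDag` from term/parent mappings."""
    parents = {t: frozenset(parents.get(t, ())) for t in namespace}
    g = nx.DiGraph()
    g.add_nodes_from(namespace)
    for t, ps in parents.items():
        for p in ps:
            if p not in namespace:
                raise OntologyFormatError(f"term {t} has unknown parent {p}")
            g.add_edge(t, p)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise OntologyFormatError(f"ontology contains a cycle: {cycle}")
    roots: dict[str, str] = {}
    for term, ns in namespace.items():
        if not parents[term]:
            if ns in roots:
                raise OntologyFormatError(
                    f"namespace {ns!r} has multiple roots: {roots[ns]}, {term}"
                )
            roots[ns] = term
    for ns in set(namespace.values()):
        if ns not in roots:
            raise OntologyFormatError(f"namespace {ns!r} has no root term")
    return GoDag(namespace=namespace, parents=parents, roots=roots)


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology file into a validated :class:`GoDag`.

    Obsolete terms are excluded; ``is_a`` and ``part_of`` links become parent
    edges; namespaces are kept separate, each with a single root.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete terms
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        namespace[node] = data.get("namespace", "default")
        parents[node] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel in PARENT_RELATIONS and parent in namespace:
            parents[child].add(parent)
    return build_dag(namespace, parents)


def term_closure(dag: GoDag, term: str, direction: str = "up") -> frozenset[str]:
    """Reflexive-transitive closure of a term: ancestors (up) or descendants (down)."""
    if term not in dag:
        raise KeyError(f"unknown ontology term {term!r}")
    if direction == "up":
        return dag.ancestors(term)
    if direction == "down":
        return dag.descendants(term)
    raise ValueError("direction must be 'up' or 'down'")


@dataclass
class AnnotationCorpus:
    """Propagated gene annotations with per-term probabilities and IC."""

    gene_terms: dict[str, frozenset[str]]
    term_p: dict[str, float]
    ic: dict[str, float]
    max_ic: dict[str, float]          # per namespace
    n_genes: dict[str, int]           # annotated genes per namespace

    def terms_of(self, gene: str, namespace_of: dict[str, str], ns: str) -> frozenset[str]:
        return frozenset(t for t in self.gene_terms.get(gene, ()) if namespace_of[t] == ns)


def information_content(dag: GoDag, gene_terms: dict[str, set[str]]) -> AnnotationCorpus:
    """Propagate annotations and derive p(t) and IC(t) per namespace.

    p(t) is the fraction of genes (annotated in t's namespace) that carry t
    after ancestor propagation — equivalently, the fraction annotated to t or
    any of its descendants.  Genes with no valid terms are dropped with a
    warning; unknown terms are ignored per gene with a warning.
    """
    propagated: dict[str, frozenset[str]] = {}
    for gene, terms in gene_terms.items():
        valid = [t for t in terms if t in dag]
        if len(valid) < len(terms):
            logger.warning("gene %s: %d unknown terms ignored", gene, len(terms) - len(valid))
        if not valid:
            logger.warning("gene %s has no valid ontology terms; dropped", gene)
            continue
        closure: set[str] = set()
        for t in valid:
            closure |= dag.ancestors(t)
        propagated[gene] = frozenset(closure)

    counts: dict[str, int] = {}
    ns_genes: dict[str, set[str]] = {}
    for gene, terms in propagated.items():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
            ns_genes.setdefault(dag.namespace[t], set()).add(gene)
    n_genes = {ns: len(gs) for ns, gs in ns_genes.items()}

    term_p: dict[str, float] = {}
    ic: dict[str, float] = {}
    max_ic: dict[str, float] = {}
    for t, c in counts.items():
        ns = dag.namespace[t]
        p = c / n_genes[ns]
        term_p[t] = p
        ic[t] = -math.log(p)
        if ic[t] > max_ic.get(ns, 0.0):
            max_ic[ns] = ic[t]
    for ns in n_genes:
        max_ic.setdefault(ns, 0.0)
    return AnnotationCorpus(
        gene_terms=propagated, term_p=term_p, ic=ic, max_ic=max_ic, n_genes=n_genes
    )


def term_similarity(
    corpus: AnnotationCorpus, dag: GoDag, t1: str, t2: str, method: str = "lin"
) -> float:
    """MICA-based similarity of two terms, in [0, 1].

    Cross-namespace pairs score 0 (no common ancestor exists).  Resnik is
    normalized by the largest IC observed in the pair's namespace so both
    methods share the [0, 1] scale.
    """
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"unknown ontology term {t!r}")
        if t not in corpus.ic:
            raise KeyError(f"term {t!r} has no annotation-derived IC")
    ns = dag.namespace[t1]
    if ns != dag.namespace[t2]:
        logger.warning("cross-namespace pair (%s, %s): similarity 0", t1, t2)
        return 0.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    ic_mica = max((corpus.ic.get(a, 0.0) for a in common), default=0.0)
    if method == "lin":
        denom = corpus.ic[t1] + corpus.ic[t2]
        return 2.0 * ic_mica / denom if denom > 0 else 0.0
    if method == "resnik":
        mx = corpus.max_ic.get(ns, 0.0)
        return ic_mica / mx if mx > 0 else 0.0
    raise ValueError(f"unknown method {method!r}; use 'lin' or 'resnik'")


def bma(matrix: np.ndarray) -> float:
    """Best-match average: (mean of row maxima + mean of column maxima) / 2."""
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("BMA of an empty similarity matrix is undefined")
    return float((m.max(axis=1).mean() + m.max(axis=0).mean()) / 2.0)


def _term_matrix(
    corpus: AnnotationCorpus, dag: GoDag, terms_a: list[str], terms_b: list[str], method: str
) -> np.ndarray:
    out = np.zeros((len(terms_a), len(terms_b)))
    for i, ta in enumerate(terms_a):
        for j, tb in enumerate(terms_b):
            out[i, j] = term_similarity(corpus, dag, ta, tb, method)
    return out


def gene_similarity(
    corpus: AnnotationCorpus, dag: GoDag, gene_a: str, gene_b: str, method: str = "lin"
) -> float:
    """BMA similarity of two genes' propagated informative term sets.

    Zero-IC terms (the namespace roots and anything annotating every gene)
    carry no information and are excluded, so a gene is always similarity 1
    to itself.  Computed per namespace over the namespaces in which both
    genes have informative terms, then averaged; genes sharing no such
    namespace score 0.
    """
    for g in (gene_a, gene_b):
        if g not in corpus.gene_terms:
            raise KeyError(f"gene {g!r} is not annotated in the corpus")

    def informative(gene: str, ns: str) -> list[str]:
        return sorted(
            t
            for t in corpus.gene_terms[gene]
            if dag.namespace[t] == ns and corpus.ic.get(t, 0.0) > 0.0
        )

    sims: list[float] = []
    namespaces = {dag.namespace[t] for t in corpus.gene_terms[gene_a]} & {
        dag.namespace[t] for t in corpus.gene_terms[gene_b]
    }
    for ns in sorted(namespaces):
        terms_a = informative(gene_a, ns)
        terms_b = informative(gene_b, ns)
        if terms_a and terms_b:
            sims.append(bma(_term_matrix(corpus, dag, terms_a, terms_b, method)))
    return float(np.mean(sims)) if sims else 0.0


def load_annotations(path: str | Path, gene_col: str = "gene", term_col: str = "go_term") -> dict[str, set[str]]:
    """Read a ``gene<TAB>go_term`` table (GAF-like column subset) into a mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).dropna()
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(gene, set()).add(term)
    return out
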