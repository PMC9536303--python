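"""Shared fixtures: a tiny hand-built ontology corpus and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mirsignet.go_semantics import build_dag, information_content


@pytest.fixture
def small_corpus():
    """Four-gene corpus on the DAG root -> {A, B}, A -> C (all one namespace).

    Propagated annotation probabilities by hand:
        p(root) = 1, p(A) = 0.5, p(B) = 0.5, p(C) = 0.25
    """
    dag = build_dag(
        namespace={"root": "BP", "A": "BP", "B": "BP", "C": "BP"},
        parents={"root": set(), "A": {"root"}, "B": {"root"}, "C": {"A"}},
    )
    gene_terms = {"g1": {"C"}, "g2": {"A"}, "g3": {"B"}, "g4": {"B"}}
    corpus = information_content(dag, gene_terms)
    return dag, corpus


def random_dag(rng: np.random.Generator, n_terms: int, ns: str = "BP"):
    """Random layered DAG for oracle comparisons (root = term 0)."""
    terms = [f"T{i}" for i in range(n_terms)]
    namespace = {t: ns for t in terms}
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i) + 1))
        idx = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[j] for j in sorted(idx)}
    return build_dag(namespace, parents)


def random_annotations(rng: np.random.Generator, dag, n_genes: int):
    terms = sorted(dag.terms)
    out = {}
    for i in range(n_genes):
        k = int(rng.integers(1, 4))
        idx = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        out[f"g{i}"] = {terms[j] for j in sorted(idx)}
    return out
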