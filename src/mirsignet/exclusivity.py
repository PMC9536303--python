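"""Mutually exclusive miRNA signature modules across neoplasm networks.

A candidate module is a maximal clique (>= 3 miRNAs) of one group's pruned
similarity network.  A module is mutually exclusive when its full member set
occurs as a clique in exactly one network of the collection — individual
members may still appear in, and even belong to modules of, other groups;
exclusivity is a set-level property.

Significance is assessed against a degree-preserving rewiring null: each
replicate rewires every other network by double-edge swaps (10·E attempted
swaps), and the add-one permutation p-value is the fraction of replicates in
which the module reappears as a clique in at least one other network.
Benjamini–Hochberg correction is applied across all tested candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .networks import NeoplasmNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3
DEFAULT_N_PERM = 999
DEFAULT_ALPHA = 0.05

#: Attempted double-edge swaps per edge when rewiring a network.
SWAP_ATTEMPTS_PER_EDGE = 10


@dataclass(frozen=True)
class SignatureModule:
    """A reported neoplasm-specific miRNA module."""

    group: str
    members: frozenset[str]
    density: float
    host_count: int
    p_value: float
    q_value: float

    @property
    def size(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "members": ";".join(sorted(self.members)),
            "size": self.size,
            "density": self.density,
            "host_count": self.host_count,
            "p_value": self.p_value,
            "q_value": self.q_value,
        }


def unique_mirnas(networks: list[NeoplasmNetwork]) -> dict[str, set[str]]:
    """miRNAs appearing in exactly one network's node set, keyed by group."""
    if not networks:
        raise ValueError("need at least one network")
    counts: dict[str, int] = {}
    for net in networks:
        for m in net.nodes:
            counts[m] = counts.get(m, 0) + 1
    return {
        net.group: {m for m in net.nodes if counts[m] == 1} for net in networks
    }


def restrict_candidates_to_unique(
    candidates: dict[str, list[frozenset[str]]],
    networks: list[NeoplasmNetwork],
) -> dict[str, list[frozenset[str]]]:
    """Optional pre-filter: keep only candidates made of group-unique miRNAs.

    Off by default in the selection pipeline — reported modules may
    legitimately contain miRNAs shared across groups, since exclusivity is
    a property of the full set — but useful to reproduce stricter
    unique-first workflows.
    """
    uniq = unique_mirnas(networks)
    return {
        g: [m for m in mods if m <= uniq.get(g, set())]
        for g, mods in candidates.items()
    }


def enumerate_candidate_modules(
    net: NeoplasmNetwork, min_size: int = DEFAULT_MIN_SIZE
) -> list[frozenset[str]]:
    """All maximal cliques of size >= min_size, in deterministic order."""
    import networkx as nx

    if not net.pruned:
        raise ValueError(f"network {net.group!r} must be pruned before module search")
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    cliques = [frozenset(c) for c in nx.find_cliques(net.graph) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: tuple(sorted(c)))


def exclusivity_census(
    module: frozenset[str] | set[str], networks: list[NeoplasmNetwork]
) -> int:
    """Number of networks containing the full member set as a clique.

    Membership alone does not count: all member pairs must be edges.  The
    census deliberately does not enforce member-level uniqueness — a miRNA
    may sit in modules of several groups.
    """
    if len(module) < 3:
        raise ValueError("census is defined for modules of size >= 3")
    return sum(net.has_clique(module) for net in networks)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def rewire_edge_set(
    edges: list[tuple[str, str]], rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Degree-preserving randomization by attempted double-edge swaps.

    Runs ``SWAP_ATTEMPTS_PER_EDGE * E`` attempts; an attempt replaces edges
    (a, b), (c, d) with (a, d), (c, b) when that creates neither self-loops
    nor parallel edges.  Node degrees are invariant.
    """
    edges = [_edge_key(a, b) for a, b in edges]
    eset = set(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return eset
    n_attempts = SWAP_ATTEMPTS_PER_EDGE * n_edges
    picks = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for (i, j), flip in zip(picks, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = _edge_key(a, d), _edge_key(c, b)
        if e1 in eset or e2 in eset:
            continue
        eset.discard(_edge_key(a, b))
        eset.discard(_edge_key(c, d))
        eset.add(e1)
        eset.add(e2)
        edges[i], edges[j] = e1, e2
    return eset


def _is_clique_in(module: frozenset[str], eset: set[tuple[str, str]]) -> bool:
    ms = sorted(module)
    return all(
        _edge_key(a, b) in eset for i, a in enumerate(ms) for b in ms[i + 1:]
    )


def _batch_permutation_pvalues(
    candidates: list[tuple[str, frozenset[str]]],
    networks: list[NeoplasmNetwork],
    n_perm: int,
    seed: int,
) -> list[float]:
    """Add-one permutation p-values for (host group, module) candidates.

    Each replicate rewires every network once (shared across candidates);
    a candidate scores a hit when it reappears as a clique in any network
    other than its host.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    nets = sorted(networks, key=lambda n: n.group)
    base_edges = {
        net.group: [_edge_key(a, b) for a, b in sorted(net.graph.edges())]
        for net in nets
    }
    hits = np.zeros(len(candidates), dtype=int)
    for _ in range(n_perm):
        rewired = {g: rewire_edge_set(e, rng) for g, e in base_edges.items()}
        for k, (host, module) in enumerate(candidates):
            if any(
                g != host and _is_clique_in(module, eset)
                for g, eset in rewired.items()
            ):
                hits[k] += 1
    return [(1 + int(h)) / (n_perm + 1) for h in hits]


def permutation_significance(
    module: frozenset[str] | set[str],
    networks: list[NeoplasmNetwork],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Permutation p-value for one module already exclusive in the data."""
    module = frozenset(module)
    hosts = [net.group for net in networks if net.has_clique(module)]
    if len(hosts) != 1:
        raise ValueError(
            f"module must be exclusive in the observed data (found in {len(hosts)} networks)"
        )
    return _batch_permutation_pvalues([(hosts[0], module)], networks, n_perm, seed)[0]


def _module_density(module: frozenset[str], net: NeoplasmNetwork) -> float:
    ms = sorted(module)
    k = len(ms)
    n_int = sum(
        net.graph.has_edge(a, b) for i, a in enumerate(ms) for b in ms[i + 1:]
    )
    return 2.0 * n_int / (k * (k - 1))


def select_signature_modules(
    candidates: dict[str, list[frozenset[str]]],
    networks: list[NeoplasmNetwork],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[SignatureModule]:
    """Score candidates, keep significant exclusive modules per group.

    Pipeline: reject candidates below 3 members; keep those whose member set
    is a clique in exactly one network (which must be the candidate's own
    group); compute permutation p-values under the rewiring null; BH-correct
    across all tested candidates; report modules with q <= alpha, dropping
    any that is a subset of another reported module of the same group; rank
    by (q ascending, density descending, size descending, members).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    by_group = {net.group: net for net in networks}
    tested: list[tuple[str, frozenset[str]]] = []
    for group in sorted(candidates):
        if group not in by_group:
            raise KeyError(f"candidate group {group!r} has no network")
        for module in candidates[group]:
            module = frozenset(module)
            if len(module) < DEFAULT_MIN_SIZE:
                logger.info("rejecting size-%d candidate in %s", len(module), group)
                continue
            host_count = exclusivity_census(module, networks)
            if host_count != 1 or not by_group[group].has_clique(module):
                continue
            tested.append((group, module))
    if not tested:
        logger.info("no exclusive candidate modules to test")
        return []
    pvals = _batch_permutation_pvalues(tested, networks, n_perm, seed)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    kept = [
        SignatureModule(
            group=g,
            members=m,
            density=_module_density(m, by_group[g]),
            host_count=1,
            p_value=float(p),
            q_value=float(q),
        )
        for (g, m), p, q in zip(tested, pvals, qvals)
        if q <= alpha
    ]
    # drop modules nested inside a larger reported module of the same group
    filtered = [
        mod
        for mod in kept
        if not any(
            other is not mod
            and other.group == mod.group
            and mod.members < other.members
            for other in kept
        )
    ]
    filtered.sort(
        key=lambda m: (m.q_value, -m.density, -m.size, tuple(sorted(m.members)), m.group)
    )
    if not filtered:
        logger.info("no modules passed q <= %.3g", alpha)
    return filtered
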