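"""Recovery harnesses: run the analysis on synthetic worlds and score it
against the planted truth.

These run the real pipeline stages (edge thresholding, network construction,
decile pruning, clique enumeration, exclusivity selection) on in-memory
synthetic association worlds, skipping only file round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exclusivity import (
    SignatureModule,
    enumerate_candidate_modules,
    select_signature_modules,
)
from .harmonize import AssociationRecord
from .mirna_similarity import build_edge_set
from .networks import build_neoplasm_network, prune_top_decile
from .synthetic_data import AssociationWorld, simulate_association_world


def run_world(
    world: AssociationWorld,
    threshold: float = 0.6,
    percentile: float = 90.0,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[SignatureModule]:
    """Threshold, build, prune and select modules for one synthetic world."""
    records = [
        AssociationRecord(mirna=m, disease_term="", group=g, sources=("synthetic",))
        for g, members in sorted(world.group_members.items())
        for m in members
    ]
    mirnas = {r.mirna for r in records}
    edges = build_edge_set(mirnas, world.sym_scores, world.asym_scores, threshold)
    nets = [
        prune_top_decile(build_neoplasm_network(g, records, edges), percentile)
        for g in sorted(world.group_members)
    ]
    candidates = {
        net.group: enumerate_candidate_modules(net)
        for net in nets
        if net.graph.number_of_nodes() >= 3
    }
    return select_signature_modules(candidates, nets, alpha=alpha, n_perm=n_perm, seed=seed)


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    n_seeds: int


def planted_recovery(
    seeds: list[int],
    n_perm: int = 199,
    **world_kwargs,
) -> RecoveryResult:
    """Mean precision/recall of module recovery over several seeded worlds."""
    precisions, recalls = [], []
    for seed in seeds:
        world = simulate_association_world(seed=seed, **world_kwargs)
        modules = run_world(world, n_perm=n_perm, seed=seed)
        truth = {
            (g, m) for g, mods in world.truth.planted_modules.items() for m in mods
        }
        found = {(m.group, m.members) for m in modules}
        tp = len(truth & found)
        precisions.append(tp / len(found) if found else 1.0)
        recalls.append(tp / len(truth) if truth else 1.0)
    n = len(seeds)
    return RecoveryResult(
        precision=sum(precisions) / n, recall=sum(recalls) / n, n_seeds=n
    )


def null_module_rate(seeds: list[int], n_perm: int = 199, **world_kwargs) -> float:
    """Fraction of module-free worlds in which no significant module is reported."""
    clean = 0
    for seed in seeds:
        world = simulate_association_world(
            planted_module_sizes=(), seed=seed, **world_kwargs
        )
        if not run_world(world, n_perm=n_perm, seed=seed):
            clean += 1
    return clean / len(seeds)
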