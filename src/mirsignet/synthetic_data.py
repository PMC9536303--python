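"""Seeded synthetic worlds for every pipeline stage.

Three generators cover the three kinds of input the pipeline consumes:

* an ontology world — a layered random DAG per namespace with genes
  annotated to random leaves, exercising parsing, propagation, IC and
  similarity end to end;
* target-prediction tables — per-tool miRNA/gene tables with a planted
  consensus core (pairs voted by at least ``min_tools`` tools) and
  tool-specific noise (pairs voted by fewer), so the vote filter's expected
  output is known exactly;
* an association world — miRNA–neoplasm association tables in four source
  dialects with injected duplicates and name-case noise, a group map, and a
  global miRNA-pair similarity score table in which one exclusive module per
  group is planted with mutually high scores.

In the association world, similarity scores are planted directly rather than
derived through the ontology: shared background miRNAs carry mid-range
scores (surviving the 0.6 threshold, straddling the per-network top-decile
cutoff), planted module pairs carry top-range scores (always above the
cutoff), and filler pairs carry low scores that the pruning removes.  This
keeps the module-recovery question decoupled from the ontology machinery,
which the ontology world tests separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .go_semantics import GoDag, build_dag
from .harmonize import DIALECTS

#: Study-condition defaults for the association world.
DEFAULT_N_GROUPS = 10
DEFAULT_GROUP_SIZE = 60
DEFAULT_N_BACKGROUND = 20
DEFAULT_MODULE_SIZES = (3, 4, 5, 6)

#: Score bands (low, high) per pair class, and filler edge density.
DEFAULT_SIMILARITY_PROFILE = {
    "module": (0.92, 0.99),
    "background": (0.70, 0.90),
    "filler": (0.60, 0.70),
    "filler_density": 0.30,
}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated association world."""

    planted_modules: dict[str, list[frozenset[str]]]
    background_mirnas: frozenset[str]
    consensus_pairs: frozenset[tuple[str, str]]
    generator_config: dict
    n_true_pairs: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_modules": {
                    g: [sorted(m) for m in mods]
                    for g, mods in sorted(self.planted_modules.items())
                },
                "background_mirnas": sorted(self.background_mirnas),
                "consensus_pairs": sorted(map(list, self.consensus_pairs)),
                "generator_config": self.generator_config,
                "n_true_pairs": self.n_true_pairs,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_modules={
                g: [frozenset(m) for m in mods]
                for g, mods in d["planted_modules"].items()
            },
            background_mirnas=frozenset(d["background_mirnas"]),
            consensus_pairs=frozenset(tuple(p) for p in d["consensus_pairs"]),
            generator_config=d["generator_config"],
            n_true_pairs=d["n_true_pairs"],
        )


# ---------------------------------------------------------------------------
# ontology world


def simulate_ontology_world(
    n_terms: int,
    n_genes: int,
    branching: float = 2.0,
    seed: int = 0,
    namespaces: tuple[str, ...] = ("BP",),
) -> tuple[GoDag, dict[str, set[str]]]:
    """Layered random DAG per namespace plus random leaf annotations.

    Layer 0 holds the namespace root; each subsequent layer is ``branching``
    times wider, and every non-root term draws 1–2 parents from the layer
    directly above.  Each gene is annotated to 1–3 random leaves of each
    namespace.  Deterministic for a fixed seed.
    """
    if n_terms < 3:
        raise ValueError("n_terms must be >= 3")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if branching < 1.0:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)

    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    counter = 0
    leaves_by_ns: dict[str, list[str]] = {}
    for ns in namespaces:
        layers: list[list[str]] = []
        remaining = n_terms
        width = 1
        while remaining > 0:
            take = min(int(width), remaining)
            layer = []
            for _ in range(take):
                counter += 1
                term = f"GO:{counter:07d}"
                namespace[term] = ns
                layer.append(term)
            layers.append(layer)
            remaining -= take
            width = max(int(round(width * branching)), int(width) + 1)
        for depth, layer in enumerate(layers):
            for term in layer:
                if depth == 0:
                    parents[term] = set()
                else:
                    above = layers[depth - 1]
                    k = 1 if len(above) == 1 else int(rng.integers(1, 3))
                    idx = rng.choice(len(above), size=min(k, len(above)), replace=False)
                    parents[term] = {above[i] for i in sorted(idx)}
        with_children = {p for ps in parents.values() for p in ps}
        leaves_by_ns[ns] = [
            t for t in namespace if namespace[t] == ns and t not in with_children
        ]

    dag = build_dag(namespace, parents)
    gene_terms: dict[str, set[str]] = {}
    for i in range(n_genes):
        gene = f"G{i + 1:04d}"
        terms: set[str] = set()
        for ns in namespaces:
            leaves = leaves_by_ns[ns]
            k = int(rng.integers(1, min(3, len(leaves)) + 1))
            idx = rng.choice(len(leaves), size=k, replace=False)
            terms |= {leaves[j] for j in sorted(idx)}
        gene_terms[gene] = terms
    return dag, gene_terms


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a DAG as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag.namespace):
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic term {term}",
            f"namespace: {dag.namespace[term]}",
        ]
        lines += [f"is_a: {p} ! parent" for p in sorted(dag.parents[term])]
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(gene_terms: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"gene": g, "go_term": t}
        for g in sorted(gene_terms)
        for t in sorted(gene_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene", "go_term"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target predictions


def simulate_target_predictions(
    mirnas: list[str],
    genes: list[str],
    n_tools: int = 5,
    consensus_rate: float = 0.05,
    noise_rate: float = 0.05,
    seed: int = 0,
    min_tools: int = 4,
) -> tuple[dict[str, pd.DataFrame], frozenset[tuple[str, str]]]:
    """Per-tool prediction tables with a planted consensus core plus noise.

    Each (miRNA, gene) pair independently becomes a consensus pair (planted
    into ``min_tools``..``n_tools`` random tools) with probability
    ``consensus_rate``, or a noise pair (planted into 1..``min_tools``-1
    tools) with probability ``noise_rate``.  The returned truth is exactly
    the set of pairs the vote filter must recover.
    """
    if n_tools < min_tools:
        raise ValueError("n_tools must be >= min_tools")
    for name, rate in (("consensus_rate", consensus_rate), ("noise_rate", noise_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tools = [f"tool{k + 1}" for k in range(n_tools)]
    rows: dict[str, list[dict[str, str]]] = {t: [] for t in tools}
    consensus: set[tuple[str, str]] = set()
    for mirna in mirnas:
        draws = rng.random(len(genes))
        for gi, gene in enumerate(genes):
            if draws[gi] < consensus_rate:
                k = int(rng.integers(min_tools, n_tools + 1))
                consensus.add((mirna, gene))
            elif draws[gi] < consensus_rate + noise_rate:
                k = int(rng.integers(1, min_tools))
            else:
                continue
            idx = rng.choice(n_tools, size=k, replace=False)
            for t in sorted(idx):
                rows[tools[t]].append({"mirna": mirna, "gene": gene})
    tables = {
        t: pd.DataFrame(rows[t], columns=["mirna", "gene"]) for t in tools
    }
    return tables, frozenset(consensus)


# ---------------------------------------------------------------------------
# association world


@dataclass
class AssociationWorld:
    """Everything the harmonize → modules stages need, plus ground truth."""

    association_tables: dict[str, pd.DataFrame]   # dialect -> raw table
    group_map: pd.DataFrame                       # disease_term, group
    sym_scores: dict[tuple[str, str], float]
    asym_scores: dict[tuple[str, str], float]
    truth: SyntheticTruth
    group_members: dict[str, list[str]] = field(default_factory=dict)


def _case_mangle(mirna: str, rng: np.random.Generator) -> str:
    """Occasionally emit the precursor-style lower-case spelling."""
    return mirna.replace("miR", "mir") if rng.random() < 0.2 else mirna


def simulate_association_world(
    n_groups: int = DEFAULT_N_GROUPS,
    group_size: int = DEFAULT_GROUP_SIZE,
    n_background: int = DEFAULT_N_BACKGROUND,
    planted_module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
    similarity_profile: dict | None = None,
    seed: int = 0,
) -> AssociationWorld:
    """Association tables with planted group-exclusive modules.

    Each group receives one planted module (size cycling through
    ``planted_module_sizes``; pass an empty tuple for a module-free null
    world) whose miRNAs occur in that group only and score in the top
    similarity band with each other.  ``n_background`` miRNAs are shared by
    every group and fully connected in the mid band; remaining filler
    miRNAs are group-private with sparse low-band scores.  Every score is
    emitted into the symmetric source, the asymmetric source, or both.
    """
    profile = dict(DEFAULT_SIMILARITY_PROFILE, **(similarity_profile or {}))
    for size in planted_module_sizes:
        if size < 3:
            raise ValueError("planted module sizes must be >= 3")
    max_module = max(planted_module_sizes, default=0)
    if group_size < n_background + max_module:
        raise ValueError("group_size must cover background plus the largest module")
    rng = np.random.default_rng(seed)

    background = [f"hsa-miR-{9000 + i}" for i in range(n_background)]
    groups = [f"Group{g + 1:02d} Neoplasms" for g in range(n_groups)]
    planted: dict[str, list[frozenset[str]]] = {}
    group_members: dict[str, list[str]] = {}
    next_id = 10000
    for gi, group in enumerate(groups):
        module: list[str] = []
        if planted_module_sizes:
            size = planted_module_sizes[gi % len(planted_module_sizes)]
            module = [f"hsa-miR-{next_id + i}" for i in range(size)]
            next_id += size
        n_filler = group_size - n_background - len(module)
        filler = [f"hsa-miR-{next_id + i}" for i in range(n_filler)]
        next_id += n_filler
        planted[group] = [frozenset(module)] if module else []
        group_members[group] = sorted(module + background + filler)

    def band(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(lo + (hi - lo) * rng.random())

    scores: dict[tuple[str, str], float] = {}

    def put(a: str, b: str, value: float) -> None:
        scores[(a, b) if a < b else (b, a)] = value

    for i, a in enumerate(background):
        for b in background[i + 1:]:
            put(a, b, band(profile["background"]))
    for group in groups:
        for mod in planted[group]:
            ms = sorted(mod)
            for i, a in enumerate(ms):
                for b in ms[i + 1:]:
                    put(a, b, band(profile["module"]))
        members = group_members[group]
        remaining = [
            (a, b)
            for i, a in enumerate(members)
            for b in members[i + 1:]
            if ((a, b) if a < b else (b, a)) not in scores
        ]
        # exact count (not Bernoulli) so per-network edge totals, and hence
        # pruning cutoff ranks, are stable across groups and seeds
        n_filler_edges = int(round(profile["filler_density"] * len(remaining)))
        idx = rng.choice(len(remaining), size=n_filler_edges, replace=False)
        for i in sorted(idx):
            put(*remaining[i], band(profile["filler"]))

    sym_scores: dict[tuple[str, str], float] = {}
    asym_scores: dict[tuple[str, str], float] = {}
    for pair in sorted(scores):
        route = rng.integers(0, 3)
        if route in (0, 2):
            sym_scores[pair] = scores[pair]
        if route in (1, 2):
            asym_scores[pair] = scores[pair]

    dialects = [d for d in sorted(DIALECTS) if d != "synthetic"]
    aliases = {
        g: [f"{g.lower()} type a", f"{g} subtype B"] for g in groups
    }
    gmap_rows = [
        {"disease_term": alias, "group": g}
        for g in groups
        for alias in aliases[g]
    ]
    raw_rows: dict[str, list[dict[str, str]]] = {d: [] for d in dialects}
    n_true_pairs = 0
    for group in groups:
        for mirna in group_members[group]:
            n_true_pairs += 1
            n_sources = int(rng.integers(1, 4))
            idx = rng.choice(len(dialects), size=n_sources, replace=False)
            for di in sorted(idx):
                d = dialects[di]
                cols = DIALECTS[d]
                alias = aliases[group][int(rng.integers(0, len(aliases[group])))]
                row = {
                    cols["mirna"]: _case_mangle(mirna, rng),
                    cols["disease_term"]: alias,
                }
                raw_rows[d].append(row)
                if rng.random() < 0.05:  # exact duplicate row
                    raw_rows[d].append(dict(row))
    tables = {
        d: pd.DataFrame(raw_rows[d], columns=list(DIALECTS[d].values()))
        for d in dialects
    }
    truth = SyntheticTruth(
        planted_modules=planted,
        background_mirnas=frozenset(background),
        consensus_pairs=frozenset(),
        generator_config={
            "n_groups": n_groups,
            "group_size": group_size,
            "n_background": n_background,
            "planted_module_sizes": list(planted_module_sizes),
            "similarity_profile": {
                k: list(v) if isinstance(v, tuple) else v for k, v in profile.items()
            },
            "seed": seed,
        },
        n_true_pairs=n_true_pairs,
    )
    return AssociationWorld(
        association_tables=tables,
        group_map=pd.DataFrame(gmap_rows, columns=["disease_term", "group"]),
        sym_scores=sym_scores,
        asym_scores=asym_scores,
        truth=truth,
        group_members=group_members,
    )


def write_world(world: AssociationWorld, outdir: str | Path, seed: int = 0) -> None:
    """Write a complete input directory: association tables per dialect,
    group map, per-tool target tables, OBO + annotations, similarity scores
    and the truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for dialect, df in world.association_tables.items():
        df.to_csv(out / f"associations_{dialect}.tsv", sep="\t", index=False)
    world.group_map.to_csv(out / "group_map.tsv", sep="\t", index=False)

    all_mirnas = sorted({m for ms in world.group_members.values() for m in ms})
    dag, gene_terms = simulate_ontology_world(
        n_terms=40, n_genes=30, branching=2.0, seed=seed
    )
    write_obo(dag, out / "ontology.obo")
    write_annotations(gene_terms, out / "annotations.tsv")
    tool_tables, _ = simulate_target_predictions(
        all_mirnas[: min(20, len(all_mirnas))], sorted(gene_terms), seed=seed
    )
    for tool, df in tool_tables.items():
        df.to_csv(out / f"targets_{tool}.tsv", sep="\t", index=False)

    for name, score_map in (("sym", world.sym_scores), ("asym", world.asym_scores)):
        pd.DataFrame(
            [
                {"mirna_a": a, "mirna_b": b, "score": s}
                for (a, b), s in sorted(score_map.items())
            ],
            columns=["mirna_a", "mirna_b", "score"],
        ).to_csv(out / f"similarity_{name}.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(world.truth.to_json())
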