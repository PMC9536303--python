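"""End-to-end orchestration: raw tables in, signature-module report out.

Stages run in a fixed order — harmonize associations, consensus targets,
miRNA-pair similarity, per-group networks (raw and pruned), topology
reports, exclusive-module selection — and every stage's output is written
before the next starts, so a run can be audited or resumed from any
intermediate file.  All stochastic steps draw from the single configured
seed; two runs with the same config are byte-identical.

miRNA-pair similarity comes either from precomputed score tables (the
``scores_sym`` / ``scores_asym`` inputs, as produced by the synthetic-data
generator or an external similarity tool) or, when those are absent, from
the in-package GO route: consensus targets + ontology + annotations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exclusivity import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_SIZE,
    DEFAULT_N_PERM,
    enumerate_candidate_modules,
    select_signature_modules,
)
from .go_semantics import information_content, load_annotations, parse_obo
from .harmonize import (
    association_summary,
    deduplicate_associations,
    load_group_map,
    map_records,
    read_association_table,
    write_associations,
)
from .mirna_similarity import (
    DEFAULT_THRESHOLD,
    build_edge_set,
    gosemsim_mirna_similarity,
    mirgofs_like_similarity,
)
from .networks import (
    DEFAULT_PRUNE_PERCENTILE,
    build_neoplasm_network,
    degree_distribution_fit,
    prune_top_decile,
    write_edge_list,
)
from .targets import DEFAULT_MIN_TOOLS, consensus_targets, read_target_predictions

logger = logging.getLogger(__name__)

_FIXTURE_SHA256 = {
    "table1.tsv": "a091c39f9c172dd68a1c035ff5aeee13a30b58f9ee07b64fc56b185a07353050",
    "table2.tsv": "055a5f3d25585350729ff179365b293216ecab246a4b6a6ee3318ede49406f09",
}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializes to/from YAML."""

    associations: dict[str, str] = field(default_factory=dict)  # dialect -> path
    group_map: str | None = None
    tools: dict[str, str] = field(default_factory=dict)          # tool -> path
    obo: str | None = None
    annotations: str | None = None
    scores_sym: str | None = None
    scores_asym: str | None = None
    min_tools: int = DEFAULT_MIN_TOOLS
    similarity_threshold: float = DEFAULT_THRESHOLD
    similarity_method: str = "lin"
    prune_percentile: float = DEFAULT_PRUNE_PERCENTILE
    min_module_size: int = DEFAULT_MIN_SIZE
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    outdir: str = "mirsignet_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_score_table(path: str) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_a": str, "mirna_b": str})
    return {
        (a, b) if a < b else (b, a): float(s)
        for a, b, s in zip(df["mirna_a"], df["mirna_b"], df["score"])
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "warnings": [],
    }

    def stage(name: str, **counts) -> None:
        logger.info("stage %s: %s", name, counts)
        manifest["stages"][name] = counts

    # -- harmonize ---------------------------------------------------------
    try:
        gmap = load_group_map(config.group_map) if config.group_map else None
        raw = []
        for dialect in sorted(config.associations):
            raw.extend(read_association_table(config.associations[dialect], dialect))
        mapped = map_records(raw, gmap) if gmap else raw
        records = deduplicate_associations(mapped)
    except Exception as exc:  # noqa: BLE001 - abort names the stage
        raise RuntimeError(f"stage 'harmonize' failed: {exc}") from exc
    write_associations(records, out / "associations.tsv")
    association_summary(records).to_csv(out / "association_summary.tsv", sep="\t", index=False)
    stage("harmonize", n_raw=len(raw), n_deduplicated=len(records))
    if not records:
        manifest["warnings"].append("no mapped associations; downstream outputs are empty")

    groups = sorted({r.group for r in records})
    mirnas = {r.mirna for r in records}

    # -- consensus targets -------------------------------------------------
    cmap = None
    if config.tools:
        try:
            preds = read_target_predictions(config.tools)
            cmap = consensus_targets(preds, config.min_tools)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'targets' failed: {exc}") from exc
        cmap.to_frame().to_csv(out / "consensus_targets.tsv", sep="\t", index=False)
        stage("targets", n_predictions=len(preds), n_consensus_pairs=len(cmap.votes))

    # -- similarity edges --------------------------------------------------
    try:
        if config.scores_sym or config.scores_asym:
            sym = _load_score_table(config.scores_sym) if config.scores_sym else {}
            asym = _load_score_table(config.scores_asym) if config.scores_asym else {}
        elif config.obo and config.annotations and cmap is not None:
            sym, asym = _go_route_scores(config, cmap, mirnas)
        else:
            sym, asym = {}, {}
            manifest["warnings"].append(
                "no similarity inputs (scores or obo+annotations+tools); edge set empty"
            )
        edges = build_edge_set(mirnas, sym, asym, config.similarity_threshold)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'similarity' failed: {exc}") from exc
    pd.DataFrame(
        [
            {
                "mirna_a": e.mirna_a, "mirna_b": e.mirna_b,
                "w_sym": e.w_sym, "w_asym": e.w_asym, "w_combined": e.w_combined,
            }
            for e in edges
        ],
        columns=["mirna_a", "mirna_b", "w_sym", "w_asym", "w_combined"],
    ).to_csv(out / "similarity_edges.tsv", sep="\t", index=False)
    stage("similarity", n_scored_pairs=len(sym) + len(asym), n_edges=len(edges))

    # -- networks ----------------------------------------------------------
    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    pruned_nets = []
    reports = []
    try:
        for group in groups:
            net = build_neoplasm_network(group, records, edges)
            write_edge_list(net, nets_dir / f"{_slug(group)}.raw.tsv")
            pruned = prune_top_decile(net, config.prune_percentile)
            write_edge_list(pruned, nets_dir / f"{_slug(group)}.pruned.tsv")
            pruned_nets.append(pruned)
            if pruned.graph.number_of_nodes() >= 2:
                reports.append(degree_distribution_fit(pruned).to_dict())
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'networks' failed: {exc}") from exc
    (out / "topology_reports.json").write_text(json.dumps(reports, indent=2))
    stage(
        "networks",
        n_groups=len(groups),
        n_pruned_edges=sum(n.n_edges for n in pruned_nets),
    )

    # -- modules -----------------------------------------------------------
    try:
        candidates = {
            net.group: enumerate_candidate_modules(net, config.min_module_size)
            for net in pruned_nets
            if net.graph.number_of_nodes() >= config.min_module_size
        }
        modules = select_signature_modules(
            candidates,
            pruned_nets,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'modules' failed: {exc}") from exc
    rows = [m.to_dict() for m in modules]
    pd.DataFrame(
        rows,
        columns=["group", "members", "size", "density", "host_count", "p_value", "q_value"],
    ).to_csv(out / "signature_modules.tsv", sep="\t", index=False)
    (out / "signature_modules.json").write_text(json.dumps(rows, indent=2))
    stage(
        "modules",
        n_candidates=sum(len(c) for c in candidates.values()),
        n_reported=len(modules),
    )
    if candidates and not modules:
        manifest["warnings"].append("no significant mutually exclusive modules detected")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _go_route_scores(config: PipelineConfig, cmap, mirnas: set[str]):
    """Score all miRNA pairs through the ontology route (both measures)."""
    dag = parse_obo(config.obo)
    corpus = information_content(dag, load_annotations(config.annotations))
    universe = set(corpus.gene_terms)
    scored = sorted(
        m for m in mirnas if cmap.targets(m) and cmap.targets(m) & universe
    )
    sym: dict[tuple[str, str], float] = {}
    asym: dict[tuple[str, str], float] = {}
    gene_cache: dict = {}
    closure_cache: dict = {}
    for i, a in enumerate(scored):
        ta = cmap.targets(a) & universe
        for b in scored[i + 1:]:
            tb = cmap.targets(b) & universe
            sym[(a, b)] = gosemsim_mirna_similarity(
                ta, tb, corpus, dag, config.similarity_method, cache=gene_cache
            )
            asym[(a, b)] = mirgofs_like_similarity(
                ta, tb, corpus, dag, universe, cache=closure_cache
            )
    return sym, asym


def _slug(group: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in group.lower())


def load_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged printed-table transcriptions (checksum-verified).

    Returns ``(summary, modules)``: the 30-group association summary
    (columns group, n_mirnas, n_pairs) and the 17 reported signature
    modules (columns group, members, size; members semicolon-joined).
    """
    frames = []
    for name in ("table1.tsv", "table2.tsv"):
        ref = resources.files("mirsignet.data").joinpath(name)
        blob = ref.read_bytes()
        digest = hashlib.sha256(blob).hexdigest()
        if digest != _FIXTURE_SHA256[name]:
            raise ValueError(f"fixture {name} checksum mismatch: {digest}")
        import io

        frames.append(pd.read_csv(io.BytesIO(blob), sep="\t"))
    summary, modules = frames
    modules = modules.assign(size=modules["members"].str.split(";").map(len))
    return summary, modules


def module_multiplicity(modules: pd.DataFrame) -> pd.Series:
    """Per-miRNA count of reported modules it belongs to (across groups)."""
    from collections import Counter

    counts = Counter(
        m for members in modules["members"] for m in members.split(";")
    )
    return pd.Series(counts).sort_values(ascending=False)
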