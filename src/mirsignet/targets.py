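"""Consensus miRNA target-gene maps from multi-tool prediction tables.

Target predictions from independent tools (microT_CDS-, TargetScan-, miRDB-,
PicTar- and miRanda-style exports) are combined by vote counting: a gene is
accepted as a target of a miRNA only when at least ``min_tools`` distinct
tools predict the pair.  Votes count tools, never rows, so duplicated rows in
a single export cannot inflate support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Default consensus threshold: "more than three" of the five tools.
DEFAULT_MIN_TOOLS = 4


@dataclass(frozen=True)
class TargetPrediction:
    mirna: str
    gene: str
    tool: str


@dataclass
class ConsensusTargetMap:
    """miRNA -> consensus gene set, with per-pair distinct-tool vote counts."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    votes: dict[tuple[str, str], int] = field(default_factory=dict)

    def targets(self, mirna: str) -> set[str]:
        return self.entries.get(mirna, set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna": m, "gene": g, "n_tools": self.votes[(m, g)]}
            for m in sorted(self.entries)
            for g in sorted(self.entries[m])
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "n_tools"])


def read_target_predictions(paths: dict[str, str | Path]) -> list[TargetPrediction]:
    """Read per-tool ``mirna<TAB>gene`` tables (extra columns ignored).

    Predictions are deduplicated within each tool, so the later vote count
    reflects distinct tools only.
    """
    if len(set(paths)) != len(paths):
        raise ValueError("duplicate tool identifiers in path mapping")
    preds: list[TargetPrediction] = []
    for tool in sorted(paths):
        df = pd.read_csv(paths[tool], sep="\t", dtype=str)
        if not {"mirna", "gene"} <= set(df.columns):
            raise ValueError(f"tool {tool!r} table must have 'mirna' and 'gene' columns")
        seen: set[tuple[str, str]] = set()
        for mirna, gene in zip(df["mirna"], df["gene"]):
            if not isinstance(mirna, str) or not isinstance(gene, str):
                continue
            pair = (mirna, gene)
            if pair not in seen:
                seen.add(pair)
                preds.append(TargetPrediction(mirna=mirna, gene=gene, tool=tool))
    return preds


def consensus_targets(
    preds: list[TargetPrediction], min_tools: int = DEFAULT_MIN_TOOLS
) -> ConsensusTargetMap:
    """Keep (miRNA, gene) pairs voted by at least ``min_tools`` distinct tools."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    n_tools = len({p.tool for p in preds})
    if preds and min_tools > n_tools:
        raise ValueError(
            f"min_tools={min_tools} exceeds the {n_tools} tools present in the input"
        )
    tool_votes: dict[tuple[str, str], set[str]] = {}
    for p in preds:
        tool_votes.setdefault((p.mirna, p.gene), set()).add(p.tool)
    cmap = ConsensusTargetMap()
    for (mirna, gene), tools in tool_votes.items():
        if len(tools) >= min_tools:
            cmap.entries.setdefault(mirna, set()).add(gene)
            cmap.votes[(mirna, gene)] = len(tools)
    return cmap
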