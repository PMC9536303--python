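"""Harmonization of miRNA–neoplasm association tables.

Association evidence comes from heterogeneous database exports (miR2Disease,
miRCancer, dbDEMC, HMDD and synthetic emulations thereof), each with its own
column layout and its own conventions for miRNA capitalization and disease
wording.  This module normalizes miRNA names to miRBase-style canonical form,
maps raw disease terms onto a curated neoplasm-group vocabulary, and collapses
duplicate (miRNA, group) links while remembering which sources supported them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel group label for disease terms absent from the group map.
UNMAPPED = "UNMAPPED"

#: Registered source dialects: dialect name -> column mapping for the raw TSV.
#: Each maps the canonical fields (mirna, disease_term) to the column names
#: used by that database's export.
DIALECTS: dict[str, dict[str, str]] = {
    "mir2disease": {"mirna": "miRNA", "disease_term": "Disease"},
    "mircancer": {"mirna": "mirId", "disease_term": "Cancer"},
    "dbdemc": {"mirna": "miRNA_ID", "disease_term": "Cancer_Type"},
    "hmdd": {"mirna": "mir", "disease_term": "disease"},
    "synthetic": {"mirna": "mirna", "disease_term": "disease_term"},
}


class DialectError(ValueError):
    """Raised for an unregistered source dialect or a bad dialect config."""


class MirnaNameError(ValueError):
    """Raised when a string contains no recognizable miRNA token."""


@dataclass(frozen=True, order=True)
class AssociationRecord:
    """One (miRNA, disease term, neoplasm group, source) link."""

    mirna: str
    disease_term: str
    group: str = UNMAPPED
    sources: tuple[str, ...] = ()


@dataclass
class GroupMap:
    """Curated mapping from normalized disease term to neoplasm-group label.

    Terms whose normalized key maps to more than one group are ambiguous and
    are dropped at load time (lookups of such terms return ``UNMAPPED``),
    mirroring manual-curation practice where ambiguous disease wordings are
    removed rather than guessed.
    """

    entries: dict[str, str] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    @property
    def groups(self) -> set[str]:
        return set(self.entries.values())

    def lookup(self, disease_term: str) -> str:
        key = normalize_disease_term(disease_term)
        if key in self.ambiguous:
            return UNMAPPED
        return self.entries.get(key, UNMAPPED)


_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_disease_term(term: str) -> str:
    """Case-fold, strip punctuation and collapse whitespace for map lookup."""
    term = _PUNCT_RE.sub(" ", term.lower())
    return _WS_RE.sub(" ", term).strip()


def load_group_map(path: str | Path) -> GroupMap:
    """Read a two-column ``disease_term<TAB>group`` table into a GroupMap."""
    df = pd.read_csv(path, sep="\t", dtype=str).dropna()
    gmap = GroupMap()
    for term, group in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = normalize_disease_term(term)
        prior = gmap.entries.get(key)
        if prior is not None and prior != group:
            logger.warning(
                "ambiguous disease term %r maps to %r and %r; dropped", term, prior, group
            )
            gmap.ambiguous.add(key)
            del gmap.entries[key]
        elif key not in gmap.ambiguous:
            gmap.entries[key] = group
    return gmap


# miRNA token: optional species prefix, mir/let stem, numeric id, optional
# letter variants, precursor indices and arm suffixes, e.g. hsa-miR-199a-1-5p.
_MIRNA_RE = re.compile(
    r"^(?:(?P<prefix>[a-z]{3,4})-)?(?P<stem>mir|let)-?(?P<rest>\d+[a-z]*(?:-\d+)?(?:-[35]p)?)$",
    re.IGNORECASE,
)


def normalize_mirna_name(raw: str, species_prefix: str = "hsa") -> str:
    """Normalize a miRNA label to canonical miRBase-style form.

    The species prefix is lower-cased and added when missing; the mature stem
    is re-cased to ``miR`` (``let`` stays lower-case); numeric ids, letter
    variants, precursor indices and -5p/-3p arm suffixes are kept verbatim
    (lower-cased).

    >>> normalize_mirna_name("hsa-mir-320a-3p")
    'hsa-miR-320a-3p'
    >>> normalize_mirna_name("miR-34a")
    'hsa-miR-34a'
    """
    if not raw or not raw.strip():
        raise MirnaNameError("empty miRNA name")
    m = _MIRNA_RE.match(raw.strip())
    if m is None:
        raise MirnaNameError(f"no recognizable miRNA token in {raw!r}")
    prefix = (m.group("prefix") or species_prefix).lower()
    stem = "let" if m.group("stem").lower() == "let" else "miR"
    return f"{prefix}-{stem}-{m.group('rest').lower()}"


def read_association_table(path: str | Path, dialect: str) -> list[AssociationRecord]:
    """Read one database export into raw association records.

    The disease term is kept verbatim; ``group`` is left UNMAPPED until
    :func:`map_to_group` is applied.  Rows whose miRNA field cannot be
    normalized are skipped with a logged warning naming the row.
    """
    if dialect not in DIALECTS:
        raise DialectError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        )
    cols = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for canonical, col in cols.items():
        if col not in df.columns:
            raise DialectError(
                f"dialect {dialect!r} expects column {col!r} in {path}"
            )
    records: list[AssociationRecord] = []
    mirna_col = df[cols["mirna"]].tolist()
    term_col = df[cols["disease_term"]].tolist()
    for idx, (raw_mirna, raw_term) in enumerate(zip(mirna_col, term_col)):
        if not isinstance(raw_mirna, str) or not isinstance(raw_term, str):
            logger.warning("skipping malformed row %d of %s", idx, path)
            continue
        try:
            mirna = normalize_mirna_name(raw_mirna)
        except MirnaNameError as exc:
            logger.warning("skipping row %d of %s: %s", idx, path, exc)
            continue
        records.append(
            AssociationRecord(mirna=mirna, disease_term=raw_term, sources=(dialect,))
        )
    return records


def map_to_group(disease_term: str, gmap: GroupMap) -> str:
    """Closed-world lookup of a disease term's neoplasm group.

    Returns the configured group label, or ``UNMAPPED`` for unknown or
    ambiguous terms; groups are never invented.
    """
    return gmap.lookup(disease_term)


def map_records(records: list[AssociationRecord], gmap: GroupMap) -> list[AssociationRecord]:
    """Assign groups to raw records, dropping UNMAPPED ones with a warning."""
    mapped: list[AssociationRecord] = []
    n_dropped = 0
    for rec in records:
        group = map_to_group(rec.disease_term, gmap)
        if group == UNMAPPED:
            n_dropped += 1
            continue
        mapped.append(replace(rec, group=group))
    if n_dropped:
        logger.warning("dropped %d records with unmapped/ambiguous disease terms", n_dropped)
    return mapped


def deduplicate_associations(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Collapse records to unique (miRNA, group) pairs, merging sources.

    Output is sorted by (group, mirna); each surviving record carries the
    sorted union of the source tags that reported the pair.  Records still
    flagged UNMAPPED are dropped (with a warning) rather than propagated.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    terms: dict[tuple[str, str], str] = {}
    n_unmapped = 0
    for rec in records:
        if rec.group == UNMAPPED:
            n_unmapped += 1
            continue
        key = (rec.group, rec.mirna)
        merged.setdefault(key, set()).update(rec.sources)
        terms.setdefault(key, rec.disease_term)
    if n_unmapped:
        logger.warning("dropped %d UNMAPPED records during deduplication", n_unmapped)
    return [
        AssociationRecord(
            mirna=mirna, disease_term=terms[(group, mirna)], group=group,
            sources=tuple(sorted(merged[(group, mirna)])),
        )
        for group, mirna in sorted(merged)
    ]


def association_summary(records: list[AssociationRecord]) -> pd.DataFrame:
    """Per-group distinct-miRNA counts plus a TOTAL row.

    The TOTAL row reports the number of distinct miRNAs across all groups
    (a miRNA associated with several groups counts once).
    """
    if not records:
        return pd.DataFrame(columns=["group", "n_mirnas"])
    by_group: dict[str, set[str]] = {}
    for rec in records:
        by_group.setdefault(rec.group, set()).add(rec.mirna)
    rows = [{"group": g, "n_mirnas": len(s)} for g, s in sorted(by_group.items())]
    rows.append(
        {"group": "TOTAL", "n_mirnas": len(set().union(*by_group.values()))}
    )
    return pd.DataFrame(rows)


def write_associations(records: list[AssociationRecord], path: str | Path) -> None:
    """Write deduplicated associations as ``mirna, group, sources`` TSV."""
    pd.DataFrame(
        {
            "mirna": [r.mirna for r in records],
            "group": [r.group for r in records],
            "sources": [";".join(r.sources) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
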