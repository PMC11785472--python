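"""Best-hit taxonomy assignment of 16S sequences against a small
SILVA-style reference, with rank-dependent lineage truncation.

The classifier is deliberately transparent: the best hit is the reference
sequence with the highest percent identity under a global (minimum edit
distance) alignment, and the assigned lineage is the hit's lineage truncated
at the deepest rank whose identity threshold the query still meets
(98.7% species, 94.5% genus, 86.5% family, 82.0% order, 78.5% class,
75.0% phylum — the widely used full-length-16S rank thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    lineage: tuple[str, ...]  # up to 7 ranks, left-filled
    sequence: str


@dataclass(frozen=True)
class RankThresholds:
    species: float = 98.7
    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0
    class_: float = 78.5
    phylum: float = 75.0

    def as_pairs(self) -> list[tuple[str, float]]:
        """(rank, threshold) pairs from shallow to deep."""
        return [
            ("phylum", self.phylum), ("class", self.class_), ("order", self.order),
            ("family", self.family), ("genus", self.genus), ("species", self.species),
        ]

    def __post_init__(self) -> None:
        vals = [self.phylum, self.class_, self.order, self.family, self.genus, self.species]
        if sorted(vals) != vals or len(set(vals)) != len(vals):
            raise ValueError("rank thresholds must strictly increase with rank depth")


@dataclass(frozen=True)
class TaxonomyAssignment:
    lineage: tuple[str, ...]
    best_hit: Optional[str]
    identity_percent: float
    supported_rank: Optional[str]

    def rank_name(self, rank: str) -> str:
        idx = RANKS.index(rank)
        return self.lineage[idx] if idx < len(self.lineage) else ""

    @property
    def unclassified(self) -> bool:
        return self.supported_rank is None


UNCLASSIFIED = TaxonomyAssignment(lineage=(), best_hit=None, identity_percent=0.0,
                                  supported_rank=None)


def _parse_lineage(text: str) -> tuple[str, ...]:
    ranks = [r.strip() for r in text.split(";")]
    if len(ranks) > 7:
        raise ValueError(f"lineage has more than 7 ranks: {text!r}")
    while ranks and ranks[-1] == "":
        ranks.pop()
    if any(r == "" for r in ranks):
        raise ValueError(f"lineage has a gap between filled ranks: {text!r}")
    return tuple(ranks)


def load_reference(path: str | Path) -> list[ReferenceEntry]:
    """Parse a FASTA whose headers carry semicolon-delimited lineages.

    Header format: ``>id domain;phylum;class;order;family;genus;species``
    (trailing ranks may be absent). Duplicate ids are an error.
    """
    entries: list[ReferenceEntry] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        if len(parts) < 2 or not chunks:
            raise ValueError(f"malformed reference record: {header!r}")
        ref_id, lineage_text = parts
        if ref_id in seen:
            raise ValueError(f"duplicate reference id: {ref_id!r}")
        seen.add(ref_id)
        try:
            lineage = _parse_lineage(lineage_text)
        except ValueError as exc:
            raise ValueError(f"record {ref_id!r}: {exc}") from None
        entries.append(ReferenceEntry(ref_id, lineage, "".join(chunks).upper()))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    flush()
    if not entries:
        import warnings
        warnings.warn(f"reference {path} is empty", stacklevel=2)
    return entries


def global_identity(a: str, b: str) -> float:
    """Percent identity over gap-free columns of a minimum-edit-distance
    global alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = mismatches = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
    denom = matches + mismatches
    return 100.0 * matches / denom if denom else 0.0


def _cigar_ops(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def classify_16s(
    query: str,
    reference: Sequence[ReferenceEntry],
    thresholds: RankThresholds = RankThresholds(),
) -> TaxonomyAssignment:
    """Assign a lineage to a 16S query by best-hit identity.

    Ties on identity go to the lexicographically smallest ref_id. The
    lineage is truncated at the deepest rank whose threshold the identity
    meets; below the phylum threshold the query is unclassified at all ranks.
    Queries shorter than 500 nt are refused.
    """
    if not reference:
        raise ValueError("empty reference")
    if len(query) < 500:
        raise ValueError(f"query too short for classification ({len(query)} < 500 nt)")
    query = query.upper()
    best_id, best_identity, best_lineage = None, -1.0, ()
    for entry in sorted(reference, key=lambda e: e.ref_id):
        ident = global_identity(query, entry.sequence)
        if ident > best_identity:
            best_id, best_identity, best_lineage = entry.ref_id, ident, entry.lineage
    if best_identity < thresholds.phylum:
        return TaxonomyAssignment((), best_id, best_identity, None)
    supported = "phylum"
    for rank, thr in thresholds.as_pairs():
        if best_identity >= thr:
            supported = rank
    # do not claim a rank deeper than the hit's lineage actually fills
    depth = RANKS.index(supported) + 1
    lineage = best_lineage[:depth]
    actual_depth = len(lineage)
    supported = RANKS[actual_depth - 1] if actual_depth else None
    return TaxonomyAssignment(lineage, best_id, best_identity, supported)


def phylum_label(assignment: TaxonomyAssignment) -> str:
    """Display label for composition profiles: the phylum name, except that
    Pseudomonadota (syn. Proteobacteria) members are reported at class level;
    unclassified sequences are labelled "Unclassified"."""
    if assignment.unclassified or len(assignment.lineage) < 2:
        return "Unclassified"
    phylum = assignment.lineage[1]
    if phylum in ("Pseudomonadota", "Proteobacteria"):
        if len(assignment.lineage) >= 3:
            return assignment.lineage[2]
        return phylum
    return phylum


def classification_table(
    assignments: dict[str, TaxonomyAssignment]
) -> pd.DataFrame:
    """Tabulate assignments: asv_id, identity, supported_rank, 7 rank columns."""
    rows = []
    for asv_id, a in assignments.items():
        row = {"asv_id": asv_id,
               "identity_percent": round(a.identity_percent, 3),
               "best_hit": a.best_hit or "",
               "supported_rank": a.supported_rank or ""}
        for i, rank in enumerate(RANKS):
            row[rank] = a.lineage[i] if i < len(a.lineage) else ""
        rows.append(row)
    return pd.DataFrame(rows)


def read_classification_table(path: str | Path) -> dict[str, TaxonomyAssignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        lineage = tuple(x for x in (row[r] for r in RANKS) if x != "")
        out[str(row["asv_id"])] = TaxonomyAssignment(
            lineage=lineage,
            best_hit=row["best_hit"] or None,
            identity_percent=float(row["identity_percent"]),
            supported_rank=row["supported_rank"] or None,
        )
    return out
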