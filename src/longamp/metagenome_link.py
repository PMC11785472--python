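"""Metagenome-bin (MAG) quality filtering, coverage-based abundance, and
reconciliation of MAG taxonomy with amplicon (ASV) taxonomy.

High quality means completeness strictly above 80% and contamination
strictly below 10%. Bins with mean coverage below six-fold are additionally
flagged: successful binning is not expected below that depth, so absence of
a MAG is uninformative there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .taxonomy import TaxonomyAssignment, _parse_lineage

COMPLETENESS_MIN = 80.0   # strict >
CONTAMINATION_MAX = 10.0  # strict <
LOW_COVERAGE_FOLD = 6.0


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    lineage: tuple[str, ...]
    completeness: float
    contamination: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.mag_id}: completeness outside [0, 100]")
        if self.contamination < 0.0 or self.coverage < 0.0:
            raise ValueError(f"{self.mag_id}: negative contamination or coverage")


@dataclass
class ReconciliationReport:
    matched: list[tuple[str, str, str]]   # (asv_id, mag_id, match_rank)
    asv_only: list[str]                   # taxa with ASVs but no matching MAG
    mag_only: list[str]                   # taxa with MAGs but no matching ASV


def load_mag_table(path: str | Path) -> list[MagRecord]:
    """Read a minimal MAG summary TSV: mag_id, lineage, completeness,
    contamination, coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "lineage": str})
    required = {"mag_id", "lineage", "completeness", "contamination", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAG table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(MagRecord(
                mag_id=row["mag_id"],
                lineage=_parse_lineage(row["lineage"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                coverage=float(row["coverage"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"MAG table row {i} ({row.get('mag_id', '?')}): {exc}") from None
    return records


def filter_mags(
    records: Sequence[MagRecord],
) -> tuple[list[MagRecord], list[MagRecord], list[str]]:
    """Split records into high-quality and rejected; flag low-coverage bins.

    High quality: completeness > 80 AND contamination < 10 (strict).
    Low coverage: coverage < 6-fold (flagged regardless of quality bucket).
    """
    high, rejected, low_cov = [], [], []
    for rec in records:
        if rec.completeness > COMPLETENESS_MIN and rec.contamination < CONTAMINATION_MAX:
            high.append(rec)
        else:
            rejected.append(rec)
        if rec.coverage < LOW_COVERAGE_FOLD:
            low_cov.append(rec.mag_id)
    return high, rejected, low_cov


def mag_abundance(records: Sequence[MagRecord]) -> dict[str, float]:
    """Relative abundance of each MAG as its share of summed mean coverage."""
    if not records:
        raise ValueError("no records")
    total = sum(r.coverage for r in records)
    if total == 0:
        raise ValueError("all coverages are zero")
    return {r.mag_id: r.coverage / total for r in records}


def _taxon_at(lineage: tuple[str, ...], rank_idx: int) -> str:
    return lineage[rank_idx] if len(lineage) > rank_idx else ""


def reconcile(
    asv_assignments: Mapping[str, TaxonomyAssignment],
    mags: Sequence[MagRecord],
) -> ReconciliationReport:
    """Match ASV taxa to MAG taxa at genus level, family as weak fallback.

    Each ASV is matched to a MAG of the same genus (match_rank "genus"); when
    either side lacks a genus, a family-level match is accepted and recorded
    as "family (weak)". Unmatched ASV taxa land in ``asv_only``, unmatched
    MAG taxa in ``mag_only`` (each taxon listed once).
    """
    GENUS, FAMILY = 5, 4
    matched: list[tuple[str, str, str]] = []
    matched_asvs: set[str] = set()
    matched_mags: set[str] = set()
    for asv_id, a in sorted(asv_assignments.items()):
        genus = _taxon_at(a.lineage, GENUS)
        family = _taxon_at(a.lineage, FAMILY)
        hit = None
        rank = None
        if genus:
            for mag in mags:
                if _taxon_at(mag.lineage, GENUS) == genus:
                    hit, rank = mag, "genus"
                    break
        if hit is None and family:
            for mag in mags:
                mag_genus = _taxon_at(mag.lineage, GENUS)
                if (not genus or not mag_genus) and _taxon_at(mag.lineage, FAMILY) == family:
                    hit, rank = mag, "family (weak)"
                    break
        if hit is not None:
            matched.append((asv_id, hit.mag_id, rank))
            matched_asvs.add(asv_id)
            matched_mags.add(hit.mag_id)
    asv_only = sorted({
        _taxon_at(a.lineage, GENUS) or _taxon_at(a.lineage, FAMILY) or "Unclassified"
        for asv_id, a in asv_assignments.items() if asv_id not in matched_asvs
    })
    mag_only = sorted({
        _taxon_at(m.lineage, GENUS) or _taxon_at(m.lineage, FAMILY) or "Unclassified"
        for m in mags if m.mag_id not in matched_mags
    })
    return ReconciliationReport(matched=matched, asv_only=asv_only, mag_only=mag_only)


def report_table(report: ReconciliationReport) -> pd.DataFrame:
    rows = [{"bucket": "matched", "asv_id": a, "mag_id": m, "match_rank": r}
            for a, m, r in report.matched]
    rows += [{"bucket": "asv_only", "asv_id": "", "mag_id": "", "match_rank": "", "taxon": t}
             for t in report.asv_only]
    rows += [{"bucket": "mag_only", "asv_id": "", "mag_id": "", "match_rank": "", "taxon": t}
             for t in report.mag_only]
    return pd.DataFrame(rows)
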