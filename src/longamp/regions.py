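"""Split full 16S-ITS ASVs at the 1492r primer site and compare sequence
pairs: global alignment, substitution/indel accounting, and Kimura
2-parameter distance.

The 1492r site lies near the 3' end of the 16S gene; cutting *before* the
site leaves the primer region with the downstream (ITS + partial 23S)
fragment, cutting *after* it keeps the site with the 16S gene. Both
conventions are supported; ``before_site`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from Bio import Align

from .amplicon_io import PrimerSpec, PrimerMatch, find_primer, PRIMER_16S_1492R_PLUS

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class RegionSplit:
    seq_16s: str
    seq_downstream: str
    cut_position: int
    primer_mismatches: int
    no_site_found: bool = False  # degenerate split: whole ASV kept as 16S


@dataclass(frozen=True)
class PairwiseDiff:
    aligned_length: int
    matches: int
    substitutions: int
    transitions: int
    transversions: int
    indel_events: int
    indel_bases: int
    identity_percent: float


@dataclass(frozen=True)
class K2PDistance:
    d: float
    p_fraction: float
    q_fraction: float


class SaturationError(ValueError):
    """Substitution proportions outside the domain of the K2P log terms."""


def default_1492r_spec(max_mismatches: int = 2) -> PrimerSpec:
    return PrimerSpec(
        name="16S_1492r_plus",
        sequence=PRIMER_16S_1492R_PLUS,
        max_mismatches=max_mismatches,
        search_window=None,
    )


def split_at_1492r(
    asv: str,
    primer_1492r: Optional[PrimerSpec] = None,
    mode: Literal["before_site", "after_site"] = "before_site",
    search_start: int = 1200,
    search_end: int = 1700,
) -> RegionSplit:
    """Cut a full ASV into 16S and downstream (ITS + partial 23S) regions.

    The plus-strand 1492r site is searched in ``asv[search_start:search_end]``.
    If no match passes the mismatch tolerance, a degenerate split is returned
    (whole sequence as 16S) with ``no_site_found=True``.
    """
    if len(asv) < 1400:
        raise ValueError("ASV shorter than 1400 nt violates the upstream length filter")
    primer = primer_1492r or default_1492r_spec()
    window = asv[search_start:min(search_end, len(asv))]
    match = find_primer(window, PrimerSpec(primer.name, primer.sequence,
                                           primer.max_mismatches, None)) if window else None
    if match is None:
        return RegionSplit(asv, "", len(asv), 0, no_site_found=True)
    start = search_start + match.start
    end = search_start + match.end
    cut = start if mode == "before_site" else end
    return RegionSplit(asv[:cut], asv[cut:], cut, match.mismatches)


_DEFAULT_SCORING = dict(match=1.0, mismatch=-1.0, gap_open=4.0, gap_extend=1.0)


def align_pair(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Global end-to-end alignment; returns the two gapped strings.

    Affine gap cost: a gap of length k costs gap_open + k * gap_extend, so a
    contiguous 12-nt indel is strongly preferred over scattered single gaps.
    Traceback is deterministic (the highest-priority optimal path).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def count_diffs(alignment: tuple[str, str]) -> PairwiseDiff:
    """Column-walk accounting of an alignment.

    Contiguous gap runs (in either row) count as one indel event carrying
    their length in indel_bases. Substitutions split into transitions
    (A<->G, C<->T) and transversions. Columns containing N are excluded from
    every count. Identity is over gap-free columns:
    100 * matches / (matches + substitutions).
    """
    ga, gb = alignment
    if len(ga) != len(gb):
        raise ValueError("alignment rows differ in length")
    matches = transitions = transversions = 0
    indel_events = indel_bases = 0
    in_gap = False
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            indel_bases += 1
            if not in_gap:
                indel_events += 1
                in_gap = True
            continue
        in_gap = False
        if x == "N" or y == "N":
            continue
        if x == y:
            matches += 1
        elif (x, y) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    subs = transitions + transversions
    denom = matches + subs
    identity = 100.0 * matches / denom if denom else 0.0
    return PairwiseDiff(
        aligned_length=len(ga),
        matches=matches,
        substitutions=subs,
        transitions=transitions,
        transversions=transversions,
        indel_events=indel_events,
        indel_bases=indel_bases,
        identity_percent=identity,
    )


def k2p_from_proportions(p: float, q: float) -> K2PDistance:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are the transition and transversion proportions over gap-free,
    non-N columns. Raises :class:`SaturationError` when 1-2P-Q <= 0 or
    1-2Q <= 0.
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated proportions P={p}, Q={q}")
    return K2PDistance(d=-0.5 * math.log(w1) - 0.25 * math.log(w2), p_fraction=p, q_fraction=q)


def k2p_distance(a: str, b: str) -> K2PDistance:
    """K2P distance between two unaligned sequences (aligned internally).

    Proportions are taken over gap-free, non-N columns (matches plus
    substitutions) of the global alignment.
    """
    diff = count_diffs(align_pair(a, b))
    denom = diff.matches + diff.substitutions
    if denom == 0:
        raise ValueError("no comparable columns")
    return k2p_from_proportions(diff.transitions / denom, diff.transversions / denom)
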