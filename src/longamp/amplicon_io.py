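"""Read-level I/O: FASTQ parsing, degenerate-primer location, orientation,
trimming, and quality filtering of long amplicon reads.

Coordinates are 0-based, half-open everywhere. Quality scores are standard
FASTQ Phred+33; per-base error probability is p = 10**(-Q/10).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# IUPAC nucleotide codes mapped to the base sets they denote.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Primers used for 16S-ITS amplification (27f forward on the 16S gene,
# 130r reverse on the 23S gene) and the 1492r site used to cut the 16S
# gene out of the full amplicon.
PRIMER_16S_27F = "AGAGTTTGATCMTGGCTCAG"
PRIMER_23S_130R = "GGGTTBCCCCATTCRG"
PRIMER_16S_1492R_PLUS = "AGTCGTAACAAGGTARCC"


class InvalidAlphabetError(ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


def iupac_matches(base: str, code: str) -> bool:
    """True iff ``base`` belongs to the set of bases the IUPAC ``code`` denotes.

    ``N`` matches every base. Raises :class:`InvalidAlphabetError` for
    characters outside the IUPAC alphabet.
    """
    try:
        return base in IUPAC_SETS[code]
    except KeyError:
        raise InvalidAlphabetError(f"not an IUPAC code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise InvalidAlphabetError(f"not an IUPAC nucleotide: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PrimerSpec:
    """A degenerate primer with a mismatch budget and a search window.

    ``search_window`` is the number of bases, counted from the relevant read
    end, in which a match is sought; ``None`` scans the whole read.
    """

    name: str
    sequence: str
    max_mismatches: int = 2
    search_window: Optional[int] = 100

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        if seq != seq.upper() or any(c not in IUPAC_SETS for c in seq):
            raise InvalidAlphabetError(f"primer {self.name}: bad alphabet in {seq!r}")
        if self.max_mismatches < 0 or self.max_mismatches >= len(seq):
            raise ValueError("max_mismatches must satisfy 0 <= m < primer length")


@dataclass(frozen=True)
class PrimerMatch:
    start: int
    end: int
    mismatches: int
    strand: str = "plus"


@dataclass
class AmpliconRead:
    """One long consensus read with per-base Phred+33 qualities."""

    read_id: str
    sequence: str
    qualities: str
    run_id: str = ""
    strain_id: str = ""

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")

    def error_probabilities(self) -> np.ndarray:
        q = np.frombuffer(self.qualities.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
        return 10.0 ** (-q / 10.0)

    def expected_errors(self) -> float:
        return float(self.error_probabilities().sum())


@dataclass(frozen=True)
class FilterParams:
    """Read-level filter thresholds.

    ``max_expected_errors`` defaults to infinity: the published long-read
    denoising pipeline applies no expected-error cap by default, and the
    length/N filters carry the load for consensus reads. Set a finite value
    to enable the cap.
    """

    min_length: int = 1400
    max_expected_errors: float = float("inf")
    max_n: int = 0

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not self.max_expected_errors > 0:
            raise ValueError("max_expected_errors must be positive")


@dataclass
class Rejection:
    read_id: str
    reason: str


def _mismatch_count(window: str, primer: str, budget: int) -> int:
    """Ungapped IUPAC-aware mismatch count; stops early past the budget."""
    mm = 0
    for b, c in zip(window, primer):
        if b not in IUPAC_SETS[c]:
            mm += 1
            if mm > budget:
                return mm
    return mm


def find_primer(seq: str, primer: PrimerSpec, *, from_end: bool = False) -> Optional[PrimerMatch]:
    """Locate ``primer`` in ``seq`` by ungapped sliding-window comparison.

    Returns the lowest-mismatch hit inside the search window (ties go to the
    leftmost offset), or ``None`` if the best hit exceeds the primer's
    mismatch budget or the primer is longer than the sequence.

    ``from_end=True`` anchors the search window at the 3' end of the read
    instead of the 5' end.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    plen = len(primer.sequence)
    if plen > len(seq):
        return None
    if primer.search_window is None:
        lo, hi = 0, len(seq) - plen
    elif from_end:
        lo = max(0, len(seq) - primer.search_window)
        hi = len(seq) - plen
    else:
        lo, hi = 0, min(primer.search_window, len(seq)) - plen
    best: Optional[PrimerMatch] = None
    for off in range(lo, hi + 1):
        mm = _mismatch_count(seq[off:off + plen], primer.sequence, primer.max_mismatches)
        if mm <= primer.max_mismatches and (best is None or mm < best.mismatches):
            best = PrimerMatch(start=off, end=off + plen, mismatches=mm)
            if mm == 0:
                break
    return best


def orient_and_trim(
    read: AmpliconRead, fwd: PrimerSpec, rev: PrimerSpec
) -> AmpliconRead | Rejection:
    """Orient a read to the plus strand and cut out the insert between primers.

    ``rev`` is the reverse-primer oligo (5'->3'); its binding site on the
    plus strand is its reverse complement near the 3' end. If both sites are
    found only after reverse-complementing the read, the reoriented insert is
    returned. Qualities are sliced identically to the sequence.
    """
    rev_site = PrimerSpec(
        name=rev.name + "_site",
        sequence=reverse_complement(rev.sequence),
        max_mismatches=rev.max_mismatches,
        search_window=rev.search_window,
    )
    for flip in (False, True):
        if flip:
            seq = str(Seq(read.sequence).reverse_complement())
            qual = read.qualities[::-1]
        else:
            seq, qual = read.sequence, read.qualities
        fm = find_primer(seq, fwd)
        rm = find_primer(seq, rev_site, from_end=True)
        if fm is not None and rm is not None and fm.end <= rm.start:
            if fm.end == rm.start:
                return Rejection(read.read_id, "empty_insert")
            return AmpliconRead(
                read_id=read.read_id,
                sequence=seq[fm.end:rm.start],
                qualities=qual[fm.end:rm.start],
                run_id=read.run_id,
                strain_id=read.strain_id,
            )
        if not flip:
            fwd_found, rev_found = fm is not None, rm is not None
    # neither orientation worked: report what was missing on the plus strand
    if fwd_found and not rev_found:
        return Rejection(read.read_id, "missing_reverse")
    if rev_found and not fwd_found:
        return Rejection(read.read_id, "missing_forward")
    return Rejection(read.read_id, "missing_both")


def filter_reads(
    reads: Iterable[AmpliconRead], params: FilterParams = FilterParams()
) -> tuple[list[AmpliconRead], list[Rejection]]:
    """Apply length / N-count / expected-error filters; never truncates.

    A read is kept iff length >= min_length, N count <= max_n and the sum of
    per-base error probabilities <= max_expected_errors. Each discarded read
    gets exactly one rejection reason (checked in that order).
    """
    kept: list[AmpliconRead] = []
    rejected: list[Rejection] = []
    for read in reads:
        if len(read.sequence) < params.min_length:
            rejected.append(Rejection(read.read_id, "too_short"))
        elif read.sequence.upper().count("N") > params.max_n:
            rejected.append(Rejection(read.read_id, "too_many_n"))
        elif read.expected_errors() > params.max_expected_errors:
            rejected.append(Rejection(read.read_id, "low_quality"))
        else:
            kept.append(read)
    return kept, rejected


# --------------------------------------------------------------------------
# File I/O

def read_fastq(path: str | Path, run_id: str = "", strain_id: str = "") -> Iterator[AmpliconRead]:
    """Yield reads from a FASTQ file (gzip-compressed if the name ends .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield AmpliconRead(rec.id, str(rec.seq).upper(), quals, run_id, strain_id)


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.qualities}\n")
            n += 1
    return n


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a run manifest TSV with columns run_id, strain_id, year, fastq_path."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "strain_id": str})
    missing = {"run_id", "strain_id", "fastq_path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["run_id"].duplicated().any():
        raise ValueError("duplicate run_id in manifest")
    return df


def write_rejection_log(rejections: Iterable[Rejection], path: str | Path) -> None:
    pd.DataFrame(
        [(r.read_id, r.reason) for r in rejections], columns=["read_id", "reason"]
    ).to_csv(path, sep="\t", index=False)
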