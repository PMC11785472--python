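"""Per-run dereplication, abundance-p-value denoising, and de-novo
two-parent chimera (bimera) flagging.

The denoiser is a single greedy pass over unique sequences in decreasing
abundance order. A unique sequence is absorbed into an existing ASV when the
probability of observing its read count as sequencing error from that ASV —
the Poisson upper tail of the expected error-read count — is at least the
partition threshold Omega; otherwise it founds a new ASV. Neighborhoods are
substitution-only: absorption candidates must have equal length and Hamming
distance at most ``max_neighbor_distance``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .amplicon_io import AmpliconRead


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    count: int
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class DenoiseParams:
    """Denoiser constants.

    error_rate
        Per-base substitution probability epsilon of the consensus reads.
    omega
        Partition threshold on the abundance p-value; p >= omega means the
        child is explainable as error reads from the parent.
    max_neighbor_distance
        Hamming cap on absorption candidates (equal-length sequences only).
    """

    error_rate: float = 0.001
    omega: float = 1e-40
    max_neighbor_distance: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.25:
            raise ValueError("error_rate must be in (0, 0.25)")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must be in (0, 1)")


@dataclass(frozen=True)
class ChimeraParams:
    min_parent_abundance: int = 6
    min_parent_fold: float = 2.0
    consensus_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_parent_abundance < 1:
            raise ValueError("min_parent_abundance must be >= 1")
        if self.min_parent_fold < 1.0:
            raise ValueError("min_parent_fold must be >= 1")


@dataclass
class DenoisedASV:
    sequence: str
    count: int
    run_id: str = ""
    chimera_flag: bool = False


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return int((_as_bytes(a) != _as_bytes(b)).sum())


def dereplicate(reads: Iterable[AmpliconRead | str], run_id: str = "") -> list[UniqueSequence]:
    """Group identical sequences (after uppercasing) and count them.

    Output is sorted by (count descending, sequence ascending); counts sum to
    the number of input reads.
    """
    counts: dict[str, int] = defaultdict(int)
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        counts[seq.upper()] += 1
    return [
        UniqueSequence(sequence=s, count=c, run_id=run_id)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def abundance_p_value(parent: UniqueSequence, child: UniqueSequence, error_rate: float) -> float:
    """P(X >= child.count) for X ~ Poisson(lambda), the abundance p-value.

    lambda = parent.count * (eps/3)**d * (1-eps)**(L-d) is the expected
    number of reads of the child sequence produced by independent per-base
    substitution errors on reads of the parent. d is the Hamming distance,
    which must be >= 1 (identical sequences are one unique).
    """
    if len(parent.sequence) != len(child.sequence):
        raise ValueError("abundance p-value is defined for equal-length sequences")
    d = hamming(parent.sequence, child.sequence)
    if d == 0:
        raise ValueError("identical sequences are a single unique, not parent/child")
    L = len(parent.sequence)
    lam = parent.count * (error_rate / 3.0) ** d * (1.0 - error_rate) ** (L - d)
    if child.count == 0:
        return 1.0
    # survival function of the Poisson: numerically stable upper tail
    return float(stats.poisson.sf(child.count - 1, lam))


def denoise_run(
    uniques: Sequence[UniqueSequence], params: DenoiseParams = DenoiseParams()
) -> list[DenoisedASV]:
    """Greedy single-pass partition of unique sequences into ASVs.

    Uniques are processed in (count desc, sequence asc) order; the most
    abundant founds the first ASV. Each subsequent unique is tested against
    every existing ASV of equal length within the Hamming cap: if the best
    abundance p-value is >= omega it is absorbed into that ASV (ties broken
    by higher ASV count, then lexicographically smaller sequence); otherwise
    it founds a new ASV. Absorbed counts accumulate on the ASV.
    """
    order = sorted(uniques, key=lambda u: (-u.count, u.sequence))
    asvs: list[DenoisedASV] = []
    by_length: dict[int, list[int]] = defaultdict(list)  # length -> asv indices
    for uniq in order:
        best_idx: Optional[int] = None
        best: tuple[float, int, str] | None = None
        for idx in by_length.get(len(uniq.sequence), ()):
            asv = asvs[idx]
            if hamming(asv.sequence, uniq.sequence) > params.max_neighbor_distance:
                continue
            p = abundance_p_value(
                UniqueSequence(asv.sequence, asv.count, asv.run_id), uniq, params.error_rate
            )
            # maximize p; ties -> more abundant ASV, then smaller sequence
            key = (p, asv.count, _neg_lex(asv.sequence))
            if best is None or key > best:
                best, best_idx = key, idx
        if best is not None and best[0] >= params.omega:
            asvs[best_idx].count += uniq.count
        else:
            asvs.append(DenoisedASV(uniq.sequence, uniq.count, uniq.run_id))
            by_length[len(uniq.sequence)].append(len(asvs) - 1)
    asvs.sort(key=lambda a: (-a.count, a.sequence))
    return asvs


class _neg_lex(str):
    """Orders strings reversed, so tuple-max prefers the lexicographically smaller."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _common_prefix_len(a: np.ndarray, b: np.ndarray) -> int:
    n = min(len(a), len(b))
    neq = a[:n] != b[:n]
    idx = int(np.argmax(neq))
    return n if not neq.any() else idx


def is_bimera(
    child: DenoisedASV,
    parents: Sequence[DenoisedASV],
    params: ChimeraParams = ChimeraParams(),
) -> bool:
    """Perfect-bimera test: child = exact prefix of one parent + exact suffix
    of another, both parents abundant enough.

    A parent qualifies when count >= min_parent_abundance and
    count >= min_parent_fold * child.count. The two parents must be distinct
    sequences and the child must not be identical to any parent. Segment
    matching is zero-mismatch and end-gap-free: the prefix aligns from the
    child's 5' end against the parent's 5' end, the suffix from the 3' ends.
    """
    cb = _as_bytes(child.sequence)
    qual = [
        p for p in parents
        if p.sequence != child.sequence
        and p.count >= params.min_parent_abundance
        and p.count >= params.min_parent_fold * child.count
    ]
    if len(qual) < 2:
        return False
    if any(p.sequence == child.sequence for p in parents):
        return False
    n = len(cb)
    pref = []  # (prefix_len, seq)
    suff = []
    for p in qual:
        pb = _as_bytes(p.sequence)
        pref.append((_common_prefix_len(cb, pb), p.sequence))
        suff.append((_common_prefix_len(cb[::-1], pb[::-1]), p.sequence))
    # need p1 != p2 with prefix + suffix covering the child and both non-empty
    pref.sort(reverse=True)
    suff.sort(reverse=True)
    for plen, pseq in pref[:2]:
        if plen < 1:
            break
        for slen, sseq in suff[:2]:
            if slen < 1:
                break
            if sseq != pseq and plen + slen >= n:
                return True
    return False


def flag_chimeras(
    per_run_asvs: dict[str, list[DenoisedASV]],
    params: ChimeraParams = ChimeraParams(),
) -> dict[str, list[DenoisedASV]]:
    """Set chimera flags by per-run bimera calls plus cross-run consensus.

    Within each run every ASV is tested against the other ASVs of that run.
    A sequence's final flag is True iff it was flagged in strictly more than
    ``consensus_fraction`` of the runs in which it occurs; the same final
    flag is applied to the sequence in every run.
    """
    occurrences: dict[str, int] = defaultdict(int)
    flagged: dict[str, int] = defaultdict(int)
    for run_id, asvs in per_run_asvs.items():
        for asv in asvs:
            occurrences[asv.sequence] += 1
            others = [a for a in asvs if a.sequence != asv.sequence]
            if is_bimera(asv, others, params):
                flagged[asv.sequence] += 1
    out: dict[str, list[DenoisedASV]] = {}
    for run_id, asvs in per_run_asvs.items():
        out[run_id] = [
            DenoisedASV(
                a.sequence, a.count, a.run_id,
                chimera_flag=(flagged[a.sequence] / occurrences[a.sequence]) > params.consensus_fraction,
            )
            for a in asvs
        ]
    return out


def write_asv_fasta(asvs: Sequence[DenoisedASV], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, asv in enumerate(asvs):
            fh.write(f">asv{i:04d} run={asv.run_id} count={asv.count}\n{asv.sequence}\n")
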