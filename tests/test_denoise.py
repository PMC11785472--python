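"""Dereplication, abundance-p-value partitioning, and bimera flagging."""

import math

import numpy as np
import pytest

from longamp.denoise import (
    ChimeraParams, DenoiseParams, DenoisedASV, UniqueSequence,
    abundance_p_value, dereplicate, denoise_run, flag_chimeras, hamming, is_bimera,
)

from conftest import random_seq


def poisson_tail_oracle(c: int, lam: float) -> float:
    """High-precision P(X >= c) via log-sum of pmf terms (independent of scipy)."""
    if c <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    logs = [k * math.log(lam) - math.lgamma(k + 1) - lam for k in range(c, c + 200)]
    m = max(logs)
    return math.exp(m) * sum(math.exp(x - m) for x in logs)


# ----------------------------------------------------------------- dereplicate

def test_dereplicate_groups_and_sorts():
    uniques = dereplicate(["TTTT", "AAAA", "AAAA", "AAAA", "CCCC", "CCCC"])
    assert [(u.sequence, u.count) for u in uniques] == [("AAAA", 3), ("CCCC", 2), ("TTTT", 1)]


def test_dereplicate_empty():
    assert dereplicate([]) == []


def test_dereplicate_case_normalisation():
    uniques = dereplicate(["acgt", "ACGT"])
    assert [(u.sequence, u.count) for u in uniques] == [("ACGT", 2)]


def test_dereplicate_conserves_read_count():
    rng = np.random.default_rng(0)
    reads = [random_seq(rng, 8) for _ in range(500)]
    uniques = dereplicate(reads)
    assert sum(u.count for u in uniques) == 500


# ----------------------------------------------------------- abundance p-value

def test_p_value_child_count_zero_is_one():
    # a hypothetical child observed zero times is always explainable
    parent = UniqueSequence("A" * 100, 50)
    child = UniqueSequence("A" * 99 + "C", 1)
    object.__setattr__(child, "count", 0)  # bypass the >=1 invariant for the boundary case
    assert abundance_p_value(parent, child, 0.001) == 1.0


def test_p_value_worked_example():
    """L=1000, eps=0.001, parent 1000, d=1, child 1: lambda ~ 0.1227, p ~ 0.115."""
    parent = UniqueSequence("A" * 1000, 1000)
    child = UniqueSequence("A" * 999 + "C", 1)
    lam = 1000 * (0.001 / 3) * 0.999 ** 999
    assert abs(lam - 0.1227) < 1e-3
    p = abundance_p_value(parent, child, 0.001)
    assert abs(p - (1 - math.exp(-lam))) < 1e-12
    assert abs(p - 0.115) < 1e-3


def test_p_value_high_count_below_omega():
    parent = UniqueSequence("A" * 1000, 1000)
    child = UniqueSequence("A" * 999 + "C", 50)
    p = abundance_p_value(parent, child, 0.001)
    lam = 1000 * (0.001 / 3) * 0.999 ** 999
    oracle = poisson_tail_oracle(50, lam)
    assert p < 1e-40
    assert p == pytest.approx(oracle, rel=1e-6)


def test_p_value_identical_sequences_error():
    parent = UniqueSequence("A" * 10, 5)
    child = UniqueSequence("A" * 10, 1)
    with pytest.raises(ValueError):
        abundance_p_value(parent, child, 0.001)


@pytest.mark.parametrize("seed", range(10))
def test_p_value_matches_oracle_and_monotonicity(seed):
    """Agrees with a log-space tail oracle; non-increasing in child count,
    non-decreasing in parent count."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(50, 500))
    d = int(rng.integers(1, 6))
    seq = random_seq(rng, L)
    child_seq = list(seq)
    for pos in rng.choice(L, size=d, replace=False):
        child_seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[child_seq[pos]]
    child_seq = "".join(child_seq)
    eps = float(rng.uniform(0.0005, 0.01))
    n_parent = int(rng.integers(10, 5000))
    lam = n_parent * (eps / 3) ** d * (1 - eps) ** (L - d)
    prev = None
    for c in (1, 2, 5, 10):
        p = abundance_p_value(UniqueSequence(seq, n_parent),
                              UniqueSequence(child_seq, c), eps)
        assert p == pytest.approx(poisson_tail_oracle(c, lam), rel=1e-6)
        if prev is not None:
            assert p <= prev + 1e-15
        prev = p
    p_small = abundance_p_value(UniqueSequence(seq, max(1, n_parent // 10)),
                                UniqueSequence(child_seq, 3), eps)
    p_large = abundance_p_value(UniqueSequence(seq, n_parent),
                                UniqueSequence(child_seq, 3), eps)
    assert p_large >= p_small - 1e-15


# ------------------------------------------------------------------ denoise_run

def test_denoise_single_unique():
    asvs = denoise_run([UniqueSequence("ACGT" * 50, 10)])
    assert [(a.sequence[:4], a.count) for a in asvs] == [("ACGT", 10)]


def test_denoise_absorbs_singleton_error():
    s = "A" * 1000
    s1 = "A" * 999 + "C"
    asvs = denoise_run([UniqueSequence(s, 1000), UniqueSequence(s1, 1)])
    assert len(asvs) == 1
    assert asvs[0].sequence == s and asvs[0].count == 1001


def test_denoise_splits_abundant_neighbor():
    s = "A" * 1000
    s2 = "A" * 999 + "C"
    asvs = denoise_run([UniqueSequence(s, 1000), UniqueSequence(s2, 50)])
    assert len(asvs) == 2
    assert sum(a.count for a in asvs) == 1050


def test_denoise_conservation_property():
    """Sum of ASV counts equals sum of unique counts for random inputs."""
    rng = np.random.default_rng(42)
    base = random_seq(rng, 300)
    uniques = [UniqueSequence(base, 500)]
    seen = {base}
    for i in range(30):
        mutant = list(base)
        for pos in rng.choice(300, size=int(rng.integers(1, 5)), replace=False):
            mutant[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[pos]]
        mutant = "".join(mutant)
        if mutant in seen:
            continue
        seen.add(mutant)
        uniques.append(UniqueSequence(mutant, int(rng.integers(1, 4))))
    asvs = denoise_run(uniques)
    assert sum(a.count for a in asvs) == sum(u.count for u in uniques)


@pytest.mark.parametrize("seed", range(20))
def test_denoise_recovers_templates_under_errors(seed):
    """At eps 0.001 with abundant templates, the ASV set equals the template
    set exactly: errors are absorbed, no template is lost."""
    rng = np.random.default_rng(seed)
    L = 1200
    templates = [random_seq(rng, L) for _ in range(3)]
    counts = [300, 120, 60]
    reads = []
    eps = 0.001
    for t, n in zip(templates, counts):
        arr = np.frombuffer(t.encode(), dtype=np.uint8)
        for _ in range(n):
            errs = np.nonzero(rng.random(L) < eps)[0]
            if len(errs):
                mut = arr.copy()
                for pos in errs:
                    alt = [b for b in b"ACGT" if b != mut[pos]]
                    mut[pos] = rng.choice(alt)
                reads.append(mut.tobytes().decode())
            else:
                reads.append(t)
    asvs = denoise_run(dereplicate(reads))
    assert sorted(a.sequence for a in asvs) == sorted(templates)
    assert sorted(a.count for a in asvs) == sorted(counts)


# -------------------------------------------------------------------- chimeras

def _parents_and_chimera(rng, length=1400, split=700):
    p1 = random_seq(rng, length)
    p2 = random_seq(rng, length)
    child = p1[:split] + p2[split:]
    return p1, p2, child


def test_is_bimera_detects_perfect_join():
    rng = np.random.default_rng(1)
    p1, p2, child = _parents_and_chimera(rng)
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 50)]
    assert is_bimera(DenoisedASV(child, 3), parents)


def test_is_bimera_respects_min_parent_abundance():
    """A parent with count 5 never qualifies (minimum is 6)."""
    rng = np.random.default_rng(2)
    p1, p2, child = _parents_and_chimera(rng)
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 5)]
    assert not is_bimera(DenoisedASV(child, 1), parents)
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 6)]
    assert is_bimera(DenoisedASV(child, 1), parents)


def test_is_bimera_respects_parent_fold():
    rng = np.random.default_rng(3)
    p1, p2, child = _parents_and_chimera(rng)
    # child count 30: parents must reach 2 x 30 = 60
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 59)]
    assert not is_bimera(DenoisedASV(child, 30), parents)
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 60)]
    assert is_bimera(DenoisedASV(child, 30), parents)


def test_sequence_is_not_its_own_chimera():
    rng = np.random.default_rng(4)
    p1, p2, _ = _parents_and_chimera(rng)
    parents = [DenoisedASV(p1, 100), DenoisedASV(p2, 50)]
    assert not is_bimera(DenoisedASV(p1, 3), parents)


def test_flag_chimeras_consensus_rule():
    rng = np.random.default_rng(5)
    p1, p2, child = _parents_and_chimera(rng)
    run = lambda with_child: (
        [DenoisedASV(p1, 100, ""), DenoisedASV(p2, 50, "")]
        + ([DenoisedASV(child, 2, "")] if with_child else [])
    )
    # flagged in its only run -> removed (1/1 > 0.5)
    out = flag_chimeras({"r1": run(True)})
    assert [a.chimera_flag for a in out["r1"] if a.sequence == child] == [True]
    # flagged in 2 of 2 runs -> removed
    out = flag_chimeras({"r1": run(True), "r2": run(True)})
    flags = [a.chimera_flag for rid in out for a in out[rid] if a.sequence == child]
    assert flags == [True, True]
    # present in 3 runs but only chimeric-looking in 1 (parents absent
    # elsewhere): 1/3 <= 0.5 -> kept everywhere
    runs = {"r1": run(True),
            "r2": [DenoisedASV(child, 2, "")],
            "r3": [DenoisedASV(child, 2, "")]}
    out = flag_chimeras(runs)
    flags = [a.chimera_flag for rid in out for a in out[rid] if a.sequence == child]
    assert flags == [False, False, False]


def test_hamming_requires_equal_length():
    with pytest.raises(ValueError):
        hamming("AAA", "AAAA")
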