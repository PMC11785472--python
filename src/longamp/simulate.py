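"""Synthetic non-axenic-culture amplicon experiments with ground truth.

The generator emulates the statistical structure the pipeline assumes: one
cyanobacterial host carrying two allelic 16S-ITS operon sequences (a few
substitutions plus one ITS indel apart), log-normally abundant heterotrophic
satellites drawn from the packaged synthetic reference, i.i.d. per-base
substitution errors, two-parent chimeric reads, optional run-specific
contaminants, and >= 2 replicate runs per strain. Every read's provenance is
recorded in a truth table so each pipeline stage can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import (
    AmpliconRead,
    PRIMER_16S_27F,
    PRIMER_16S_1492R_PLUS,
    PRIMER_23S_130R,
    reverse_complement,
)
from .reference_data import mini_reference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed realizations of the degenerate primer positions used when
# synthesising reads (M -> A, B -> C, R -> A)
FWD_SITE = PRIMER_16S_27F.replace("M", "A")
REV_OLIGO = PRIMER_23S_130R.replace("B", "C").replace("R", "A")
SITE_1492R = PRIMER_16S_1492R_PLUS.replace("R", "A")


@dataclass(frozen=True)
class CommunitySpec:
    """Composition of one simulated culture.

    The host contributes two allelic operon templates derived from one
    template by ``host_subs`` substitutions and a single deletion of
    ``host_indel_len`` bases, both placed downstream of the 1492r site (the
    ITS region). ``host_fraction`` is the host's share of reads, divided
    between the alleles by ``host_allele_split``; the remaining share is
    spread over ``n_heterotrophs`` satellites with normalised log-normal
    abundances.
    """

    host_ref_id: str = "Coleofasciculus_chthonoplastes"
    host_subs: int = 2
    host_indel_len: int = 12
    host_allele_split: tuple[float, float] = (0.55, 0.45)
    host_fraction: float = 0.4
    n_heterotrophs: int = 6
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.host_subs == 0 and self.host_indel_len == 0:
            raise ValueError("host alleles must differ at >= 1 position")
        if not 0.0 < self.host_fraction < 1.0:
            raise ValueError("host_fraction must be in (0, 1)")
        if abs(sum(self.host_allele_split) - 1.0) > 1e-9:
            raise ValueError("host_allele_split must sum to 1")


@dataclass(frozen=True)
class RunSpec:
    n_reads: int = 2000
    error_rate: float = 0.001
    chimera_rate: float = 0.0
    contaminant: Optional[tuple[str, int]] = None  # (sequence, count), this run only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chimera_rate < 0.5:
            raise ValueError("chimera_rate must be in [0, 0.5)")
        if self.contaminant is not None and self.contaminant[1] >= self.n_reads:
            raise ValueError("contaminant count must be below n_reads")


@dataclass
class Template:
    template_id: str
    sequence: str  # the trimmed insert (between, exclusive of, primer sites)
    taxon_ref_id: str
    abundance: float
    is_host: bool = False


@dataclass
class Community:
    templates: list[Template]

    @property
    def abundances(self) -> np.ndarray:
        return np.array([t.abundance for t in self.templates])

    def template(self, template_id: str) -> Template:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)


def _random_its(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _apply_substitutions(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def build_community(spec: CommunitySpec, seed: int) -> Community:
    """Deterministically build templates and abundances for one culture.

    Templates are trimmed inserts: 16S gene (from the packaged reference),
    the plus-strand 1492r site, and a synthetic ITS(+partial 23S) region, so
    the full read chain (27f site + insert + 130r binding site) is realistic
    once the run simulator adds the terminal primers.
    """
    rng = np.random.default_rng(seed)
    ref = {rid: (lineage, seq) for rid, lineage, seq in mini_reference()}
    if spec.host_ref_id not in ref:
        raise KeyError(f"host reference {spec.host_ref_id!r} not in mini-reference")
    host_genus = spec.host_ref_id.split("_")[0]
    het_pool = sorted(rid for rid in ref if not rid.startswith(host_genus))
    if spec.n_heterotrophs > len(het_pool):
        raise ValueError("n_heterotrophs exceeds the reference size")

    # host allele A: 16S + 1492r site + ITS; allele B mutated in the ITS only
    host_16s = ref[spec.host_ref_id][1]
    its_a = _random_its(rng, 860)
    allele_a = host_16s + SITE_1492R + its_a
    its_arr = its_a
    offset = len(host_16s) + len(SITE_1492R)
    sub_pos = rng.choice(len(its_arr) - spec.host_indel_len - 1,
                         size=spec.host_subs, replace=False) if spec.host_subs else np.array([], int)
    its_b = _apply_substitutions(its_arr, sub_pos, rng)
    if spec.host_indel_len:
        del_start = int(rng.integers(len(its_b) // 2, len(its_b) - spec.host_indel_len))
        its_b = its_b[:del_start] + its_b[del_start + spec.host_indel_len:]
    allele_b = host_16s + SITE_1492R + its_b

    templates = [
        Template("host_allele_A", allele_a, spec.host_ref_id,
                 spec.host_fraction * spec.host_allele_split[0], is_host=True),
        Template("host_allele_B", allele_b, spec.host_ref_id,
                 spec.host_fraction * spec.host_allele_split[1], is_host=True),
    ]
    chosen = rng.choice(het_pool, size=spec.n_heterotrophs, replace=False)
    weights = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=spec.n_heterotrophs)
    weights = weights / weights.sum() * (1.0 - spec.host_fraction)
    for rid, w in zip(chosen, weights):
        its_len = int(rng.integers(700, 900))
        seq = ref[rid][1] + SITE_1492R + _random_its(rng, its_len)
        templates.append(Template(f"het_{rid}", seq, rid, float(w)))
    return Community(templates=templates)


def contaminant_template(seed: int = 7, ref_id: str = "Hydrogenophaga_palleronii") -> str:
    """A full-length insert from a taxon outside the usual community, for
    injection into a single run (emulating a run-specific contamination)."""
    rng = np.random.default_rng(seed)
    ref = {rid: seq for rid, _, seq in mini_reference()}
    return ref[ref_id] + SITE_1492R + _random_its(rng, 820)


def choose_contaminant_ref(community: Community,
                           preferred: str = "Hydrogenophaga_palleronii") -> str:
    """A reference id whose genus is absent from ``community``, so an
    injected contaminant is genuinely foreign to the culture."""
    used_genera = {t.taxon_ref_id.split("_")[0] for t in community.templates}
    if preferred.split("_")[0] not in used_genera:
        return preferred
    for rid, _, _ in mini_reference():
        if rid.split("_")[0] not in used_genera:
            return rid
    raise ValueError("community uses every reference genus")


def _phred_char(error_rate: float) -> str:
    if error_rate <= 0:
        return chr(33 + 60)
    q = min(60, int(round(-10.0 * np.log10(error_rate))))
    return chr(33 + q)


def simulate_run(
    community: Community,
    run: RunSpec,
    run_id: str = "run1",
    strain_id: str = "strain1",
) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Draw one sequencing run and its per-read truth table.

    Reads are drawn multinomially from template abundances; a ``chimera_rate``
    fraction are instead two-parent joins at a uniform split inside the
    middle 60% of the insert. Substitution errors are i.i.d. at ``error_rate``
    with a uniform alternative base. Each read gets the terminal primer
    sequences, a random orientation, and constant qualities encoding the
    error rate. Truth rows sum to n_reads.
    """
    rng = np.random.default_rng(run.seed)
    templates = community.templates
    probs = community.abundances
    probs = probs / probs.sum()
    n_contam = run.contaminant[1] if run.contaminant else 0
    n_main = run.n_reads - n_contam

    rows = []
    reads: list[AmpliconRead] = []
    qchar = _phred_char(run.error_rate)
    is_chim = rng.random(n_main) < run.chimera_rate
    choice_a = rng.choice(len(templates), size=n_main, p=probs)
    choice_b = rng.choice(len(templates), size=n_main, p=probs)

    def emit(i: int, insert: str, template_id: str, chimera: bool, parents: str) -> None:
        errs = np.nonzero(rng.random(len(insert)) < run.error_rate)[0]
        if len(errs):
            insert = _apply_substitutions(insert, errs, rng)
        raw = FWD_SITE + insert + reverse_complement(REV_OLIGO)
        if rng.random() < 0.5:
            raw = reverse_complement(raw)
        read_id = f"{run_id}_r{i:05d}"
        reads.append(AmpliconRead(read_id, raw, qchar * len(raw), run_id, strain_id))
        rows.append({
            "read_id": read_id, "run_id": run_id, "strain_id": strain_id,
            "template_id": template_id, "is_chimera": chimera, "parents": parents,
            "n_errors": len(errs),
        })

    distinct_seqs = len({t.sequence for t in templates}) > 1
    for i in range(n_main):
        if is_chim[i] and distinct_seqs:
            pa = templates[choice_a[i]]
            pb = templates[choice_b[i]]
            while pb.sequence == pa.sequence:  # chimeras need two distinct parents
                pb = templates[rng.choice(len(templates), p=probs)]
            lo = min(len(pa.sequence), len(pb.sequence))
            split = int(rng.integers(int(0.2 * lo), int(0.8 * lo)))
            insert = pa.sequence[:split] + pb.sequence[split:]
            emit(i, insert, "chimera", True, f"{pa.template_id}|{pb.template_id}")
        else:
            t = templates[choice_a[i]]
            emit(i, t.sequence, t.template_id, False, "")
    if run.contaminant:
        seq, count = run.contaminant
        for j in range(count):
            emit(n_main + j, seq, "contaminant", False, "")
    truth = pd.DataFrame(rows)
    return reads, truth


def true_counts(truth: pd.DataFrame) -> pd.DataFrame:
    """Per (run, template) counts of non-chimeric reads."""
    sub = truth[~truth["is_chimera"]]
    return (sub.groupby(["run_id", "template_id"]).size()
            .rename("count").reset_index())


@dataclass
class Experiment:
    manifest: pd.DataFrame
    communities: dict[str, Community]
    reads: dict[str, list[AmpliconRead]]  # run_id -> raw reads
    truth: pd.DataFrame


def simulate_experiment(
    strains: Sequence[CommunitySpec] | int = 2,
    runs_per_strain: int = 2,
    n_reads: int = 2000,
    error_rate: float = 0.001,
    chimera_rate: float = 0.0,
    master_seed: int = 42,
    contaminants: Optional[dict[str, tuple[str, int]]] = None,
    out_dir: Optional[str | Path] = None,
) -> Experiment:
    """Simulate >= 1 strains with replicate runs sharing each community.

    ``contaminants`` maps run_id -> (sequence, count) for run-specific
    injections. With ``out_dir`` set, per-run FASTQ files, the manifest TSV
    (columns run_id, strain_id, year, fastq_path, seed) and the truth TSV are
    written; the same objects are always returned in memory. Fixed
    ``master_seed`` makes the whole experiment reproducible.
    """
    if runs_per_strain < 1:
        raise ValueError("runs_per_strain must be >= 1")
    if isinstance(strains, int):
        strains = [CommunitySpec() for _ in range(strains)]
    contaminants = contaminants or {}
    seed_rng = np.random.default_rng(master_seed)
    manifest_rows = []
    communities: dict[str, Community] = {}
    all_reads: dict[str, list[AmpliconRead]] = {}
    truths = []
    for si, spec in enumerate(strains):
        strain_id = f"strain{si + 1}"
        community = build_community(spec, int(seed_rng.integers(0, 2**31 - 1)))
        communities[strain_id] = community
        for ri in range(runs_per_strain):
            run_id = f"{strain_id}_run{ri + 1}"
            seed = int(seed_rng.integers(0, 2**31 - 1))
            run = RunSpec(n_reads=n_reads, error_rate=error_rate,
                          chimera_rate=chimera_rate,
                          contaminant=contaminants.get(run_id), seed=seed)
            reads, truth = simulate_run(community, run, run_id, strain_id)
            all_reads[run_id] = reads
            truths.append(truth)
            manifest_rows.append({"run_id": run_id, "strain_id": strain_id,
                                  "year": 2019 + ri, "fastq_path": f"{run_id}.fastq",
                                  "seed": seed})
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.concat(truths, ignore_index=True)
    exp = Experiment(manifest=manifest, communities=communities,
                     reads=all_reads, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .amplicon_io import write_fastq
        for run_id, reads in all_reads.items():
            write_fastq(reads, out / f"{run_id}.fastq")
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return exp
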