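"""Strain x run ASV table, replicate-based authentication, contaminant
flagging, operon-variant vs. second-strain calls, and composition /
prevalence / lineage statistics.

The central quality rule of the whole approach lives here: an ASV is
*authentic* only when the identical sequence was recovered in at least two
independent sequencing experiments of the same culture. Everything seen once
is a singleton — possibly real, possibly a PCR artefact or a run-specific
contamination — and is kept out of quantitative summaries.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .denoise import DenoisedASV
from .regions import align_pair, count_diffs, k2p_distance, SaturationError
from .taxonomy import TaxonomyAssignment, phylum_label, RANKS


@dataclass
class ASVTable:
    """Read counts per (ASV, run), with runs grouped into strains.

    ``counts`` is a DataFrame indexed by asv_id with one column per run_id;
    missing cells are 0. ``sequences`` maps asv_id -> exact sequence;
    ``run_to_strain`` maps run_id -> strain_id.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    run_to_strain: dict[str, str]

    def runs_of_strain(self, strain_id: str) -> list[str]:
        return [r for r, s in self.run_to_strain.items() if s == strain_id]

    @property
    def strains(self) -> list[str]:
        return sorted(set(self.run_to_strain.values()))

    def total(self, asv_id: str, strain_id: Optional[str] = None) -> int:
        cols = self.runs_of_strain(strain_id) if strain_id else list(self.counts.columns)
        return int(self.counts.loc[asv_id, cols].sum())


@dataclass(frozen=True)
class ASVStatus:
    authentic: bool
    singleton: bool
    n_runs_present: int
    suspected_contaminant: bool = False
    cannot_validate: bool = False


@dataclass(frozen=True)
class VariantCallParams:
    """Operationalisation of "similar counts" vs. "an order of magnitude".

    Two host ASVs are called ribosomal operon variants of one strain when
    they are nearly identical (identity >= min_identity) and their total
    counts are similar (ratio <= max_count_ratio). A count ratio of
    >= second_strain_ratio, or low identity, instead indicates a second
    co-cultured strain. Pairs in between stay unresolved.
    """

    max_count_ratio: float = 3.0
    min_identity: float = 99.0
    second_strain_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.max_count_ratio < self.second_strain_ratio):
            raise ValueError("need 1 <= max_count_ratio < second_strain_ratio")


@dataclass(frozen=True)
class VariantCall:
    asv_a: str
    asv_b: str
    count_ratio: float
    identity_percent: float
    k2p: float
    verdict: str  # operon_variants | second_strain | unresolved


@dataclass(frozen=True)
class CompositionProfile:
    strain_id: str
    proportions: dict[str, float]  # phylum-level label -> percent, sums to 100
    cyano_fraction: float
    excluded: bool = False


def build_table(
    per_run_asvs: Mapping[str, Sequence[DenoisedASV]],
    run_to_strain: Mapping[str, str],
) -> ASVTable:
    """Assemble the ASV x run count table from per-run denoised,
    non-chimeric ASVs. Rows are exact sequences; stable ids are assigned in
    (total count desc, sequence asc) order."""
    if len(set(per_run_asvs)) != len(list(per_run_asvs)):
        raise ValueError("duplicate run_id")
    unknown = set(per_run_asvs) - set(run_to_strain)
    if unknown:
        raise ValueError(f"runs without strain assignment: {sorted(unknown)}")
    totals: dict[str, int] = defaultdict(int)
    cells: dict[str, dict[str, int]] = defaultdict(dict)
    for run_id, asvs in per_run_asvs.items():
        for asv in asvs:
            if asv.chimera_flag:
                continue
            cells[asv.sequence][run_id] = cells[asv.sequence].get(run_id, 0) + asv.count
            totals[asv.sequence] += asv.count
    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    ids = {seq: f"ASV-{i + 1:03d}" for i, seq in enumerate(ordered)}
    run_ids = list(per_run_asvs)
    counts = pd.DataFrame(
        [[cells[seq].get(r, 0) for r in run_ids] for seq in ordered],
        index=[ids[s] for s in ordered],
        columns=run_ids,
        dtype=int,
    )
    return ASVTable(counts=counts,
                    sequences={ids[s]: s for s in ordered},
                    run_to_strain=dict(run_to_strain))


def authenticate(table: ASVTable, min_runs: int = 2) -> dict[tuple[str, str], ASVStatus]:
    """Per (strain, ASV) status from replicate occurrence.

    An ASV is authentic within a strain iff present (count > 0) in at least
    ``min_runs`` of that strain's runs; exactly one run makes it a singleton.
    Strains with a single run cannot validate anything: their ASVs are
    flagged ``cannot_validate``.
    """
    statuses: dict[tuple[str, str], ASVStatus] = {}
    for strain in table.strains:
        runs = table.runs_of_strain(strain)
        sub = table.counts[runs]
        present = (sub > 0).sum(axis=1)
        for asv_id, n in present.items():
            n = int(n)
            if n == 0:
                continue
            statuses[(strain, asv_id)] = ASVStatus(
                authentic=n >= min_runs and len(runs) >= min_runs,
                singleton=n == 1,
                n_runs_present=n,
                cannot_validate=len(runs) < min_runs,
            )
    return statuses


def _genus_of(assignment: Optional[TaxonomyAssignment]) -> str:
    if assignment is None or len(assignment.lineage) < 6:
        return ""
    return assignment.lineage[5]


def flag_contaminants(
    table: ASVTable,
    taxonomy: Mapping[str, TaxonomyAssignment],
    statuses: dict[tuple[str, str], ASVStatus],
    min_count: int = 50,
) -> dict[tuple[str, str], ASVStatus]:
    """Flag abundant run-specific sequences as suspected contaminants.

    A non-authentic ASV is flagged when its count reaches ``min_count`` in
    its single run and no ASV of the same genus occurs in any other run of
    the strain. ASVs without a genus-level classification are never flagged
    (their provenance cannot be cross-checked).
    """
    out = dict(statuses)
    for (strain, asv_id), status in statuses.items():
        if status.authentic or status.n_runs_present != 1:
            continue
        runs = table.runs_of_strain(strain)
        row = table.counts.loc[asv_id, runs]
        the_run = row[row > 0].index[0]
        if int(row[the_run]) < min_count:
            continue
        genus = _genus_of(taxonomy.get(asv_id))
        if not genus:
            continue
        other_runs = [r for r in runs if r != the_run]
        genus_elsewhere = False
        for other_id in table.counts.index:
            if other_id == asv_id:
                continue
            if _genus_of(taxonomy.get(other_id)) != genus:
                continue
            if (table.counts.loc[other_id, other_runs] > 0).any():
                genus_elsewhere = True
                break
        if not genus_elsewhere:
            out[(strain, asv_id)] = ASVStatus(
                authentic=status.authentic,
                singleton=status.singleton,
                n_runs_present=status.n_runs_present,
                suspected_contaminant=True,
                cannot_validate=status.cannot_validate,
            )
    return out


def classify_pair(
    total_a: int,
    total_b: int,
    identity_percent: float,
    params: VariantCallParams = VariantCallParams(),
) -> str:
    """Verdict for one host ASV pair from totals and percent identity."""
    hi, lo = max(total_a, total_b), min(total_a, total_b)
    if lo <= 0:
        raise ValueError("totals must be positive")
    ratio = hi / lo
    if identity_percent >= params.min_identity and ratio <= params.max_count_ratio:
        return "operon_variants"
    if identity_percent < params.min_identity or ratio >= params.second_strain_ratio:
        return "second_strain"
    return "unresolved"


def call_host_variants(
    host_asvs: Sequence[tuple[str, str, int]],
    params: VariantCallParams = VariantCallParams(),
) -> tuple[list[VariantCall], int]:
    """Classify every pair of host ASVs of one strain.

    ``host_asvs`` is a list of (asv_id, sequence, total count over runs).
    Returns the pairwise calls and the inferred number of co-cultured host
    strains: connected components of operon_variants edges (each host ASV not
    linked to another is its own strain).
    """
    n = len(host_asvs)
    if n < 2:
        return [], min(n, 1) if n else 0
    calls: list[VariantCall] = []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            id_a, seq_a, tot_a = host_asvs[i]
            id_b, seq_b, tot_b = host_asvs[j]
            diff = count_diffs(align_pair(seq_a, seq_b))
            try:
                k2p = k2p_distance(seq_a, seq_b).d
            except (SaturationError, ValueError):
                k2p = float("nan")
            verdict = classify_pair(tot_a, tot_b, diff.identity_percent, params)
            hi, lo = max(tot_a, tot_b), min(tot_a, tot_b)
            calls.append(VariantCall(id_a, id_b, hi / lo, diff.identity_percent, k2p, verdict))
            if verdict == "operon_variants":
                parent[find(i)] = find(j)
    return calls, len({find(i) for i in range(n)})


def composition(
    table: ASVTable,
    taxonomy: Mapping[str, TaxonomyAssignment],
    statuses: Mapping[tuple[str, str], ASVStatus],
    host_phylum: str = "Cyanobacteria",
) -> dict[str, CompositionProfile]:
    """Per-strain composition from authentic ASVs only.

    Counts are averaged across the strain's runs (zeros included), aggregated
    by phylum-level label (Pseudomonadota members at class level) and
    normalised to 100%. ``cyano_fraction`` is the share classified to the
    host phylum.
    """
    profiles: dict[str, CompositionProfile] = {}
    for strain in table.strains:
        runs = table.runs_of_strain(strain)
        agg: dict[str, float] = defaultdict(float)
        cyano = 0.0
        total = 0.0
        for asv_id in table.counts.index:
            status = statuses.get((strain, asv_id))
            if status is None or not status.authentic:
                continue
            mean_count = float(table.counts.loc[asv_id, runs].mean())
            if mean_count <= 0:
                continue
            assignment = taxonomy.get(asv_id)
            label = phylum_label(assignment) if assignment else "Unclassified"
            agg[label] += mean_count
            total += mean_count
            if assignment is not None and len(assignment.lineage) >= 2 \
                    and assignment.lineage[1] == host_phylum:
                cyano += mean_count
        if total == 0:
            profiles[strain] = CompositionProfile(strain, {}, 0.0, excluded=True)
            continue
        profiles[strain] = CompositionProfile(
            strain,
            {k: 100.0 * v / total for k, v in sorted(agg.items())},
            100.0 * cyano / total,
        )
    return profiles


def prevalence(
    strain_taxa: Mapping[str, Iterable[TaxonomyAssignment]],
) -> tuple[pd.DataFrame, list[str]]:
    """Occurrence of species-level taxa across strains and the core set.

    ``strain_taxa`` maps strain_id -> taxonomy assignments of its authentic
    ASVs. Occurrence counts the strains whose authentic ASVs include the
    species; a species is core when detected in strictly more than half of
    the strains. Only species-level classifications enter the test.
    """
    n_strains = len(strain_taxa)
    if n_strains < 2:
        raise ValueError("prevalence needs at least two strains")
    occurrence: dict[str, set[str]] = defaultdict(set)
    for strain, assignments in strain_taxa.items():
        for a in assignments:
            if a.supported_rank == "species" and len(a.lineage) == 7:
                occurrence[a.lineage[6]].add(strain)
    rows = [
        {"species": sp, "occurrence": len(strains), "n_strains": n_strains,
         "core": len(strains) > n_strains / 2}
        for sp, strains in sorted(occurrence.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    df = pd.DataFrame(rows, columns=["species", "occurrence", "n_strains", "core"])
    return df, [r["species"] for r in rows if r["core"]]


def lineage_statistics(
    table: ASVTable,
    taxonomy: Mapping[str, TaxonomyAssignment],
    statuses: Mapping[tuple[str, str], ASVStatus],
    host_phylum: str = "Cyanobacteria",
) -> tuple[pd.DataFrame, list[str]]:
    """Median/quartile/SD of heterotroph lineage proportions across strains.

    Proportions are recomputed per strain over authentic heterotroph ASVs
    only (host phylum excluded); strains without any such ASV are excluded
    and listed. Quantiles use linear interpolation; SD is the sample
    standard deviation. Fewer than two included strains is an error.
    """
    per_strain: dict[str, dict[str, float]] = {}
    excluded: list[str] = []
    for strain in table.strains:
        runs = table.runs_of_strain(strain)
        agg: dict[str, float] = defaultdict(float)
        for asv_id in table.counts.index:
            status = statuses.get((strain, asv_id))
            if status is None or not status.authentic:
                continue
            assignment = taxonomy.get(asv_id)
            if assignment is not None and len(assignment.lineage) >= 2 \
                    and assignment.lineage[1] == host_phylum:
                continue
            mean_count = float(table.counts.loc[asv_id, runs].mean())
            if mean_count <= 0:
                continue
            label = phylum_label(assignment) if assignment else "Unclassified"
            agg[label] += mean_count
        total = sum(agg.values())
        if total == 0:
            excluded.append(strain)
            continue
        per_strain[strain] = {k: 100.0 * v / total for k, v in agg.items()}
    if len(per_strain) < 2:
        raise ValueError("lineage statistics need at least two strains with "
                         "authentic heterotroph ASVs")
    labels = sorted({lab for props in per_strain.values() for lab in props})
    mat = pd.DataFrame(
        [[props.get(lab, 0.0) for lab in labels] for props in per_strain.values()],
        index=list(per_strain), columns=labels,
    )
    stats = pd.DataFrame({
        "median": mat.quantile(0.5),
        "q1": mat.quantile(0.25),
        "q3": mat.quantile(0.75),
        "sd": mat.std(ddof=1),
    })
    stats.index.name = "lineage"
    return stats, excluded


def summarize_accounting(
    table: ASVTable, statuses: Mapping[tuple[str, str], ASVStatus]
) -> dict:
    """Dataset-level ASV accounting.

    Returns total distinct ASVs, the authentic subset size, the median
    length of authentic ASVs, per-strain ASV / authentic / all-runs counts,
    and per-strain percentage of sequence counts carried by authentic ASVs
    (the artifact-control summary a replicate-validated study reports).
    """
    authentic_ids = {a for (s, a), st in statuses.items() if st.authentic}
    per_strain = {}
    for strain in table.strains:
        runs = table.runs_of_strain(strain)
        ids = [a for (s, a) in statuses if s == strain]
        auth = [a for a in ids if statuses[(strain, a)].authentic]
        n_runs = len(runs)
        all_runs = [a for a in ids if statuses[(strain, a)].n_runs_present == n_runs]
        total_counts = int(table.counts[runs].sum().sum())
        auth_counts = int(table.counts.loc[auth, runs].sum().sum()) if auth else 0
        per_strain[strain] = {
            "n_asvs": len(ids),
            "n_authentic": len(auth),
            "n_in_all_runs": len(all_runs),
            "pct_counts_authentic":
                100.0 * auth_counts / total_counts if total_counts else 0.0,
        }
    auth_lengths = sorted(len(table.sequences[a]) for a in authentic_ids)
    return {
        "n_asvs": len(table.counts.index),
        "n_authentic": len(authentic_ids),
        "median_length_authentic":
            float(np.median(auth_lengths)) if auth_lengths else float("nan"),
        "per_strain": per_strain,
    }


def status_table(
    table: ASVTable, statuses: Mapping[tuple[str, str], ASVStatus]
) -> pd.DataFrame:
    """Flatten per-(strain, ASV) statuses for TSV export."""
    rows = []
    for (strain, asv_id), s in sorted(statuses.items()):
        rows.append({
            "strain_id": strain, "asv_id": asv_id,
            "n_runs_present": s.n_runs_present,
            "authentic": s.authentic, "singleton": s.singleton,
            "suspected_contaminant": s.suspected_contaminant,
            "cannot_validate": s.cannot_validate,
            "length": len(table.sequences[asv_id]),
            "total_count": table.total(asv_id, strain),
        })
    return pd.DataFrame(rows)
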