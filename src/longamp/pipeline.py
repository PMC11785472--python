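"""End-to-end driver: raw reads -> trimmed/filtered reads -> per-run ASVs ->
chimera consensus -> strain x run table -> taxonomy -> statuses.

Thin orchestration over the stage modules; every stage is equally usable on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .amplicon_io import (
    AmpliconRead, FilterParams, PrimerSpec, Rejection,
    PRIMER_16S_27F, PRIMER_23S_130R,
    filter_reads, orient_and_trim,
)
from .denoise import ChimeraParams, DenoiseParams, DenoisedASV, dereplicate, denoise_run, flag_chimeras
from .community import ASVTable, ASVStatus, authenticate, build_table, flag_contaminants
from .regions import split_at_1492r
from .taxonomy import RankThresholds, ReferenceEntry, TaxonomyAssignment, classify_16s


def default_forward_primer(max_mismatches: int = 2, window: int = 100) -> PrimerSpec:
    return PrimerSpec("16S_27f", PRIMER_16S_27F, max_mismatches, window)


def default_reverse_primer(max_mismatches: int = 2, window: int = 100) -> PrimerSpec:
    return PrimerSpec("23S_130r", PRIMER_23S_130R, max_mismatches, window)


@dataclass
class RunResult:
    kept: list[AmpliconRead]
    rejected: list[Rejection]


def trim_and_filter_run(
    reads: Sequence[AmpliconRead],
    fwd: Optional[PrimerSpec] = None,
    rev: Optional[PrimerSpec] = None,
    params: FilterParams = FilterParams(),
) -> RunResult:
    """Orient, trim and filter one run's raw reads."""
    fwd = fwd or default_forward_primer()
    rev = rev or default_reverse_primer()
    trimmed: list[AmpliconRead] = []
    rejected: list[Rejection] = []
    for read in reads:
        result = orient_and_trim(read, fwd, rev)
        if isinstance(result, Rejection):
            rejected.append(result)
        else:
            trimmed.append(result)
    kept, rej2 = filter_reads(trimmed, params)
    return RunResult(kept=kept, rejected=rejected + rej2)


@dataclass
class PipelineResult:
    table: ASVTable
    statuses: dict[tuple[str, str], ASVStatus]
    taxonomy: dict[str, TaxonomyAssignment]
    per_run_asvs: dict[str, list[DenoisedASV]]  # chimera flags set
    rejections: dict[str, list[Rejection]]
    splits: dict[str, object]  # asv_id -> RegionSplit


def run_pipeline(
    reads_by_run: Mapping[str, Sequence[AmpliconRead]],
    run_to_strain: Mapping[str, str],
    reference: Optional[Sequence[ReferenceEntry]] = None,
    filter_params: FilterParams = FilterParams(),
    denoise_params: DenoiseParams = DenoiseParams(),
    chimera_params: ChimeraParams = ChimeraParams(),
    thresholds: RankThresholds = RankThresholds(),
    min_runs: int = 2,
    contaminant_min_count: int = 50,
) -> PipelineResult:
    """Run the full amplicon workflow on in-memory reads.

    Chimera consensus is evaluated within each strain's replicate runs.
    Taxonomy is assigned to the 16S region of each table ASV when a
    reference is given; otherwise all ASVs stay unclassified.
    """
    per_run: dict[str, list[DenoisedASV]] = {}
    rejections: dict[str, list[Rejection]] = {}
    for run_id, reads in reads_by_run.items():
        result = trim_and_filter_run(reads, params=filter_params)
        rejections[run_id] = result.rejected
        uniques = dereplicate(result.kept, run_id=run_id)
        per_run[run_id] = denoise_run(uniques, denoise_params)
    # chimera consensus within each strain's runs
    flagged: dict[str, list[DenoisedASV]] = {}
    strains = sorted(set(run_to_strain.values()))
    for strain in strains:
        strain_runs = {r: per_run[r] for r in per_run if run_to_strain[r] == strain}
        flagged.update(flag_chimeras(strain_runs, chimera_params))
    table = build_table(flagged, run_to_strain)
    statuses = authenticate(table, min_runs=min_runs)
    taxonomy: dict[str, TaxonomyAssignment] = {}
    splits: dict[str, object] = {}
    if reference:
        for asv_id, seq in table.sequences.items():
            split = split_at_1492r(seq)
            splits[asv_id] = split
            taxonomy[asv_id] = classify_16s(split.seq_16s, reference, thresholds)
        statuses = flag_contaminants(table, taxonomy, statuses,
                                     min_count=contaminant_min_count)
    return PipelineResult(table=table, statuses=statuses, taxonomy=taxonomy,
                          per_run_asvs=flagged, rejections=rejections, splits=splits)
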