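"""ASV table assembly, authentication, contaminant flags, operon-variant
calls, and composition/prevalence statistics."""

import numpy as np
import pandas as pd
import pytest

from longamp.community import (
    VariantCallParams, authenticate, build_table, call_host_variants,
    classify_pair, composition, flag_contaminants, lineage_statistics,
    prevalence, summarize_accounting,
)
from longamp.denoise import DenoisedASV
from longamp.taxonomy import TaxonomyAssignment

from conftest import random_seq


def _tax(*lineage, rank=None):
    rank = rank or ("species" if len(lineage) == 7 else None)
    return TaxonomyAssignment(tuple(lineage), "ref", 99.9, rank)


CYANO = ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Cyanobacteriales",
         "Coleofasciculaceae", "Coleofasciculus", "Coleofasciculus chthonoplastes")
ALPHA = ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Hyphomicrobiales",
         "Phyllobacteriaceae", "Nitratireductor", "Nitratireductor arenosus")
BACTE = ("Bacteria", "Bacteroidota", "Cytophagia", "Cytophagales",
         "Flammeovirgaceae", "Imperialibacter", "Imperialibacter roseus")
BETA = ("Bacteria", "Pseudomonadota", "Betaproteobacteria", "Burkholderiales",
        "Comamonadaceae", "Hydrogenophaga", "Hydrogenophaga palleronii")


def _table(cells, seqs=None, runs_per_strain=2):
    """cells: {seq_label: {run_id: count}}; run ids 's1_r1' map to strain 's1'."""
    rng = np.random.default_rng(0)
    seqs = seqs or {}
    run_ids = sorted({r for d in cells.values() for r in d})
    per_run = {r: [] for r in run_ids}
    for label, d in cells.items():
        seq = seqs.setdefault(label, random_seq(rng, 1500))
        for run_id, count in d.items():
            if count > 0:
                per_run[run_id].append(DenoisedASV(seq, count, run_id))
    run_to_strain = {r: r.split("_")[0] for r in run_ids}
    return build_table(per_run, run_to_strain), seqs


def test_build_table_shared_and_disjoint():
    table, _ = _table({
        "A": {"s1_r1": 10, "s1_r2": 5},
        "B": {"s2_r1": 7},
    })
    assert table.counts.shape == (2, 3)
    a_id = table.counts.index[0]  # highest total first
    assert table.counts.loc[a_id].tolist() == [10, 5, 0]


def test_build_table_stable_id_order():
    table, seqs = _table({"A": {"s1_r1": 5}, "B": {"s1_r1": 50}})
    assert table.sequences["ASV-001"] == seqs["B"]
    assert table.sequences["ASV-002"] == seqs["A"]


def test_build_table_empty_run_column_retained():
    rng = np.random.default_rng(1)
    per_run = {"s1_r1": [DenoisedASV(random_seq(rng, 1500), 5, "s1_r1")], "s1_r2": []}
    table = build_table(per_run, {"s1_r1": "s1", "s1_r2": "s1"})
    assert list(table.counts.columns) == ["s1_r1", "s1_r2"]
    assert (table.counts["s1_r2"] == 0).all()


def test_chimera_flagged_asvs_excluded():
    rng = np.random.default_rng(2)
    seq = random_seq(rng, 1500)
    per_run = {"s1_r1": [DenoisedASV(seq, 5, "s1_r1", chimera_flag=True)]}
    table = build_table(per_run, {"s1_r1": "s1"})
    assert table.counts.empty


def test_authenticate_replicate_rule():
    table, _ = _table({
        "A": {"s1_r1": 3, "s1_r2": 4, "s1_r3": 0, "s1_r4": 0},
        "B": {"s1_r1": 9},
        "C": {"s1_r1": 1, "s1_r2": 2, "s1_r3": 3, "s1_r4": 4},
    })
    statuses = authenticate(table)
    by_label = {}
    for (strain, asv_id), st in statuses.items():
        by_label[table.sequences[asv_id]] = st
    sts = {aid: st for (s, aid), st in statuses.items()}
    n_by_runs = sorted((st.n_runs_present, st.authentic, st.singleton) for st in sts.values())
    assert (1, False, True) in n_by_runs       # singleton, not authentic
    assert (2, True, False) in n_by_runs       # present twice -> authentic
    assert (4, True, False) in n_by_runs       # in all four runs


def test_authenticate_single_run_strain_cannot_validate():
    table, _ = _table({"A": {"s1_r1": 10}})
    statuses = authenticate(table)
    st = next(iter(statuses.values()))
    assert st.cannot_validate and not st.authentic


def test_flag_contaminants_rules():
    table, seqs = _table({
        "big_single": {"s1_r1": 500},
        "small_single": {"s1_r2": 3},
        "genus_mate": {"s1_r1": 80, "s1_r2": 60},
        "shared_genus_single": {"s1_r1": 400},
    })
    ids = {label: next(aid for aid, s in table.sequences.items() if s == seqs[label])
           for label in seqs}
    taxonomy = {
        ids["big_single"]: _tax(*BETA),
        ids["small_single"]: _tax(*ALPHA),
        ids["genus_mate"]: _tax(*BACTE),
        ids["shared_genus_single"]: _tax(*BACTE[:6], "Imperialibacter sp-2"),
    }
    statuses = flag_contaminants(table, taxonomy, authenticate(table))
    flagged = {aid for (s, aid), st in statuses.items() if st.suspected_contaminant}
    assert ids["big_single"] in flagged          # abundant, genus unique to its run
    assert ids["small_single"] not in flagged    # below min_count
    assert ids["shared_genus_single"] not in flagged  # genus present in the other run


@pytest.mark.parametrize("a,b,verdict", [
    (1445, 1336, "operon_variants"),
    (16057, 13988, "operon_variants"),
    (2219, 1638, "operon_variants"),
    (140, 115, "operon_variants"),
    (1900, 170, "second_strain"),
])
def test_printed_count_pairs(a, b, verdict):
    """The published worked-example count pairs, at high identity."""
    assert classify_pair(a, b, identity_percent=99.9) == verdict


def test_classify_pair_low_identity_is_second_strain():
    assert classify_pair(1000, 900, identity_percent=97.0) == "second_strain"


def test_classify_pair_between_ratios_unresolved():
    assert classify_pair(1000, 200, identity_percent=99.9) == "unresolved"


def test_call_host_variants_components():
    rng = np.random.default_rng(3)
    base = random_seq(rng, 2200)
    allele = base[:1800] + base[1812:]  # one 12-nt indel apart
    distant = random_seq(rng, 2200)
    host = [("A1", base, 1000), ("A2", allele, 800), ("B1", distant, 90)]
    calls, n_strains = call_host_variants(host)
    verdicts = {(c.asv_a, c.asv_b): c.verdict for c in calls}
    assert verdicts[("A1", "A2")] == "operon_variants"
    assert verdicts[("A1", "B1")] == "second_strain"
    assert n_strains == 2


def test_call_host_variants_fewer_than_two():
    assert call_host_variants([]) == ([], 0)
    calls, n = call_host_variants([("A", "ACGT" * 500, 10)])
    assert calls == [] and n == 1


def test_composition_proportions_and_averaging():
    table, seqs = _table({
        "cyano": {"s1_r1": 50, "s1_r2": 50},
        "bact": {"s1_r1": 25, "s1_r2": 25},
        "alpha": {"s1_r1": 10, "s1_r2": 30},
    })
    ids = {label: next(aid for aid, s in table.sequences.items() if s == seqs[label])
           for label in seqs}
    taxonomy = {ids["cyano"]: _tax(*CYANO), ids["bact"]: _tax(*BACTE),
                ids["alpha"]: _tax(*ALPHA)}
    profiles = composition(table, taxonomy, authenticate(table))
    p = profiles["s1"]
    # run average of 10 and 30 is 20 before normalisation
    assert p.proportions["Alphaproteobacteria"] == pytest.approx(100 * 20 / 95)
    assert p.proportions["Cyanobacteria"] == pytest.approx(100 * 50 / 95)
    assert p.cyano_fraction == pytest.approx(100 * 50 / 95)
    assert sum(p.proportions.values()) == pytest.approx(100.0, abs=1e-9)


def test_composition_only_cyano():
    table, seqs = _table({"cyano": {"s1_r1": 40, "s1_r2": 60}})
    aid = table.counts.index[0]
    profiles = composition(table, {aid: _tax(*CYANO)}, authenticate(table))
    assert profiles["s1"].cyano_fraction == pytest.approx(100.0)


def test_composition_excludes_strains_without_authentic_asvs():
    table, _ = _table({"x": {"s1_r1": 10}, "y": {"s1_r2": 5}})
    profiles = composition(table, {}, authenticate(table))
    assert profiles["s1"].excluded


def test_prevalence_core_boundary():
    """Core means detection in strictly more than half of the strains."""
    n = 32
    strain_taxa = {}
    for i in range(n):
        taxa = []
        if i < 26:
            taxa.append(_tax(*ALPHA))
        if i < 16:
            taxa.append(_tax(*BACTE))
        strain_taxa[f"s{i}"] = taxa
    df, core = prevalence(strain_taxa)
    row = df.set_index("species")
    assert row.loc["Nitratireductor arenosus", "occurrence"] == 26
    assert "Nitratireductor arenosus" in core
    assert row.loc["Imperialibacter roseus", "occurrence"] == 16
    assert "Imperialibacter roseus" not in core  # 16 is not > 16


def test_prevalence_ignores_non_species_assignments():
    genus_only = TaxonomyAssignment(ALPHA[:6], "ref", 96.0, "genus")
    df, core = prevalence({"s1": [genus_only], "s2": [genus_only]})
    assert df.empty and core == []


def test_lineage_statistics_values_and_exclusion():
    cells = {}
    # three strains with authentic heterotrophs, one (s4) with none
    for i, (b, a) in enumerate([(10, 90), (20, 80), (30, 70)], start=1):
        cells[f"bact{i}"] = {f"s{i}_r1": b, f"s{i}_r2": b}
        cells[f"alpha{i}"] = {f"s{i}_r1": a, f"s{i}_r2": a}
    cells["cyano4"] = {"s4_r1": 50, "s4_r2": 50}
    table, seqs = _table(cells)
    taxonomy = {}
    for label, seq in seqs.items():
        aid = next(a for a, s in table.sequences.items() if s == seq)
        if label.startswith("bact"):
            taxonomy[aid] = _tax(*BACTE)
        elif label.startswith("alpha"):
            taxonomy[aid] = _tax(*ALPHA)
        else:
            taxonomy[aid] = _tax(*CYANO)
    stats, excluded = lineage_statistics(table, taxonomy, authenticate(table))
    assert excluded == ["s4"]  # host-only culture drops out
    assert stats.loc["Bacteroidota", "median"] == pytest.approx(20.0)
    assert stats.loc["Alphaproteobacteria", "median"] == pytest.approx(80.0)
    assert stats.loc["Bacteroidota", "sd"] == pytest.approx(10.0)


def test_lineage_statistics_identical_profiles_sd_zero():
    cells = {f"alpha{i}": {f"s{i}_r1": 50, f"s{i}_r2": 50} for i in (1, 2)}
    table, seqs = _table(cells)
    taxonomy = {aid: _tax(*ALPHA) for aid in table.counts.index}
    stats, _ = lineage_statistics(table, taxonomy, authenticate(table))
    assert stats.loc["Alphaproteobacteria", "sd"] == pytest.approx(0.0)


def test_lineage_statistics_needs_two_strains():
    table, _ = _table({"alpha": {"s1_r1": 50, "s1_r2": 50}})
    taxonomy = {aid: _tax(*ALPHA) for aid in table.counts.index}
    with pytest.raises(ValueError):
        lineage_statistics(table, taxonomy, authenticate(table))


def test_summarize_accounting():
    table, _ = _table({
        "A": {"s1_r1": 90, "s1_r2": 90},
        "B": {"s1_r1": 10},
        "C": {"s1_r1": 5, "s1_r2": 5},
    })
    summary = summarize_accounting(table, authenticate(table))
    assert summary["n_asvs"] == 3
    assert summary["n_authentic"] == 2
    s = summary["per_strain"]["s1"]
    assert s["n_asvs"] == 3 and s["n_authentic"] == 2 and s["n_in_all_runs"] == 2
    assert s["pct_counts_authentic"] == pytest.approx(100 * 190 / 200)
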