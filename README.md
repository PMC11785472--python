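# longamp

Long-read 16S-ITS amplicon profiling of non-axenic cyanobacterial (or other
host) cultures: from circular-consensus reads to replicate-authenticated
amplicon sequence variants (ASVs), ribosomal operon-variant calls, microbiome
composition profiles, and reconciliation with metagenome-bin tables.

## The problem

Unicyanobacterial cultures are rarely axenic: a filamentous cyanobacterium
carries a community of heterotrophic satellites living on its exudates (the
*cyanosphere*). Full-length amplicons spanning the complete 16S rRNA gene,
the internally transcribed spacer, and ~130 nt of the 23S gene (primers
16S_27f / 23S_130r, inserts ~1.8–3 kb) resolve this community down to single
nucleotide differences — enough to distinguish allelic variants of the rRNA
operon within one genome from a second co-cultured strain.

The core quality rule: an ASV is **authentic** only when the *identical*
sequence is recovered in at least two independent sequencing experiments of
the same culture. Everything seen once is a singleton — possibly real,
possibly a PCR artefact or a run-specific contamination — and is kept out of
quantitative summaries.

The stage chain:

1. **amplicon_io** — IUPAC-aware primer location, orientation, trimming,
   and read filters (length ≥ 1400 nt, N-count, optional expected-error cap
   from Phred qualities).
2. **denoise** — per-run dereplication; greedy partition driven by the
   abundance p-value P(X ≥ n_child), X ~ Poisson(λ),
   λ = n_parent · (ε/3)^d · (1−ε)^(L−d), with threshold Ω = 1e-40; de-novo
   two-parent (bimera) detection with minimum parent abundance 6 and
   cross-run consensus.
3. **regions** — split each ASV at the plus-strand 1492r site into 16S and
   ITS(+partial 23S); global alignment, transition/transversion/indel
   accounting, and the Kimura 2-parameter distance
   d = −½·ln(1−2P−Q) − ¼·ln(1−2Q).
4. **taxonomy** — transparent best-hit classification against a SILVA-style
   reference with rank thresholds (species 98.7%, genus 94.5%, family 86.5%,
   order 82.0%, class 78.5%, phylum 75.0%).
5. **community** — strain × run ASV table, replicate authentication,
   contaminant flags, operon-variant vs. second-strain calls (count ratio ≤ 3
   and identity ≥ 99% vs. ratio ≥ 10 or low identity), composition at phylum
   level (Pseudomonadota at class level), prevalence/core taxa, lineage
   statistics.
6. **metagenome_link** — MAG quality filter (completeness > 80%,
   contamination < 10%, strict; coverage < 6× flagged), coverage-based
   abundances, genus-level ASV↔MAG reconciliation.
7. **simulate** — ground-truth generator: host with two allelic operon
   templates, log-normal heterotrophs, per-base errors, two-parent chimeras,
   run-specific contaminants, ≥ 2 replicate runs per strain.

## Worked example

```sh
longamp simulate --strains 1 --runs 2 --reads 800 --eps 0.001 \
    --chimera-rate 0.02 --seed 42 --out demo/sim
python -c "from longamp.reference_data import reference_fasta; reference_fasta('mini_ref.fasta')"
longamp profile --manifest demo/sim/manifest.tsv --ref mini_ref.fasta --out demo/out
```

`demo/out/host_variant_calls.tsv`:

```
strain_id  asv_a    asv_b    count_ratio  identity_percent  k2p       verdict          inferred_host_strains
strain1    ASV-002  ASV-003  1.204        99.913            0.000875  operon_variants  1
```

The two most abundant cyanobacterial ASVs have near-identical sequences
(99.9% identity; they differ by 2 substitutions and one 12-nt indel in the
ITS) and similar total counts (ratio 1.2), so they are called allelic
variants of the rRNA operon of a single host strain — not two co-cultured
strains, which would show either lower identity or an order-of-magnitude
count difference.

`demo/out/composition.tsv`:

```
strain_id  cyano_fraction  excluded  Alphaproteobacteria  Bacteroidota  Cyanobacteria  Spirochaetota  Verrucomicrobiota
strain1    44.192          False     34.393               14.212        44.192         2.141          5.062
```

Proportions are computed from authentic ASVs only, averaged over the two
runs, with Pseudomonadota reported at class level; they sum to 100%. The
host contributes 44% of authentic counts here; the remainder is the
heterotrophic cyanosphere.

Library use mirrors the CLI: `simulate_experiment` → `run_pipeline` →
`call_host_variants` / `composition` / `prevalence` / `reconcile`; see the
docstrings and `docs/methods.md`.

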