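# Methods

This note documents the models, parameters, and numerical choices behind
`longamp`, and what the synthetic-data tests do and do not establish about
real data.

## Read model and filtering

Reads are PacBio-style circular consensus sequences of a 16S-ITS amplicon:
forward primer site (16S_27f, `AGAGTTTGATCMTGGCTCAG`), insert, and the
reverse complement of the reverse primer oligo (23S_130r,
`GGGTTBCCCCATTCRG`). Primer matching is ungapped sliding-window comparison
with IUPAC-aware base sets, a per-primer mismatch budget (default 2 for the
20-mer forward and 16-mer reverse), and a search window of 100 nt from the
relevant read end (full-read scan available). Whether the original pipeline
tolerated mismatches is unknowable from the outside; the budget is therefore
an explicit parameter, not a claim.

Both primers must be found, in either read orientation; the insert between
them is returned with qualities sliced identically, never truncated.
Filters: length ≥ 1400 nt, at most 0 N bases, and an optional cap on the sum
of per-base error probabilities p = 10^(−Q/10). The expected-error cap
defaults to **infinity**: the published long-read denoising workflow applies
no expected-error cap by default, and a finite cap of ~2 would be
incoherent for ~2.3-kb inserts at consensus accuracy Q30 (expected errors
≈ 2.3 per read). The cap is configurable for users with shorter or cleaner
amplicons. Coordinates are 0-based half-open throughout.

## Denoising

Per run, identical sequences are dereplicated (uppercase-normalised) and
processed greedily in (count desc, sequence asc) order. A unique sequence u
is compared against each provisional ASV a of the same length within
Hamming distance ≤ 10. The *abundance p-value* is the Poisson upper tail

    λ = n_a · (ε/3)^d · (1−ε)^(L−d),   p = P(X ≥ n_u),  X ~ Poisson(λ)

i.e., the probability of seeing at least n_u error reads of u if all its
copies arose by independent substitution errors on reads of a. If the best
p ≥ Ω (default 1e-40) the unique is absorbed into the arg-max ASV (ties:
higher count, then lexicographically smaller sequence); otherwise it founds
a new ASV. Defaults: ε = 0.001, Ω = 1e-40, substitution-only neighborhoods
(length-discordant uniques always found new ASVs — indel errors are rare in
consensus reads). This is a deliberately simplified, fully documented
variant of abundance-p-value denoising: no error-rate learning, no repeated
partition refinement, no indel handling.

Consequence worth knowing: an ASV is an *observed* sequence. A template
represented by only a handful of reads may never be read error-free, in
which case its exact sequence cannot appear as an ASV — the same reason the
authentication rule treats rare sequences cautiously.

## Chimera (bimera) flagging

A sequence is a perfect bimera if it equals an exact prefix of one parent
followed by an exact suffix of another (both segments non-empty,
zero-mismatch, anchored at the respective ends), where each parent must have
count ≥ 6 (minimum parent abundance) and ≥ 2× the child's count. A child
identical to any parent is never a bimera. Flags are decided per run and
combined by strict-majority consensus over the runs in which the sequence
occurs; flagged sequences are excluded from all downstream tables. The
zero-mismatch segments and the 2× parent fold are configurable; pooled
(non-consensus) mode is available by calling `is_bimera` per combined run.

## Region split, alignment, K2P

The plus-strand 1492r site (`AGTCGTAACAAGGTARCC`) is located within ASV
positions 1200–1700 (≤ 2 mismatches). Default mode `before_site` assigns the
site itself to the downstream fragment, following the convention of cutting
*before* the primer sequence; `after_site` keeps it with the 16S gene. If no
site is found the whole ASV is kept as 16S and flagged.

`align_pair` is an end-to-end global alignment (match +1, mismatch −1, gap
of length k costs 4 + k) with a deterministic traceback; the strong
open-vs-extend asymmetry makes a contiguous 12-nt indel strictly preferable
to scattered gaps. Columns are then walked once: contiguous gap runs count
as one indel event; substitutions split into transitions (A↔G, C↔T) and
transversions; N columns are excluded. Identity = matches/(matches +
substitutions) over gap-free columns. K2P distance uses proportions P
(transitions) and Q (transversions) over those same columns:
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q), raising a saturation error when a log
argument is non-positive.

## Taxonomy

The classifier is best-hit percent identity under a minimum-edit-distance
global alignment (edlib), identity counted over gap-free columns, ties to
the smallest reference id. The assigned lineage is the hit's, truncated at
the deepest rank whose threshold the identity meets — species 98.7, genus
94.5, family 86.5, order 82.0, class 78.5, phylum 75.0 (the standard
full-length-16S thresholds); below 75% the query is unclassified. Queries
under 500 nt are refused. This replaces the naive-Bayes classifier of the
original workflow with a transparent, deterministic rule suited to the
small packaged reference; the two are not claimed equivalent. For
composition displays, Pseudomonadota (syn. Proteobacteria) members are
reported at class level.

The packaged mini-reference is **synthetic**: ~60 species across 29 genera
whose names mirror taxa typical of marine cyanobacterial cultures. Each
genus has a random ancestor (seeded by the genus name); species are the
ancestor mutated at 2%, so congeneric identities sit near the genus
threshold while different genera are unrelated. It is a test fixture and a
simulation source, not database data.

## Community analysis

Authentication: within a strain, an ASV is authentic iff present in ≥ 2 runs
(configurable); single-run strains are flagged `cannot_validate`. Suspected
contaminants: non-authentic ASVs with ≥ 50 reads (heuristic, configurable)
in their single run whose genus occurs in no other run of the strain.

Operon variants vs. second strain: "similar counts" is operationalised as a
total-count ratio ≤ 3 and "an order of magnitude apart" as ratio ≥ 10, with
an identity floor of 99% for the variant call; the published cases these
thresholds bracket have similar-count ratios up to 1.35 and a dissimilar
case near 11. Pairs between the ratio bounds at high identity are left
`unresolved` rather than forced, mirroring a manual-curation stance. The
number of co-cultured host strains is the number of connected components of
the operon-variant graph. K2P distance is reported per pair as a
phylogeny-free proxy for placement distance.

Composition: authentic ASVs only; counts averaged across a strain's runs
*including zeros* (run-averaging, not pooling; pooling available), grouped
by phylum-level label, normalised to 100%. Prevalence: a species-level taxon
is core when found in strictly more than half the strains; only
species-classified ASVs enter this test. Lineage statistics (median,
quartiles with linear interpolation, sample SD) are computed over
heterotroph-only proportions; strains without authentic heterotroph ASVs
are excluded and listed.

## MAG link

High-quality bins: completeness > 80 and contamination < 10, both strict, as
boundary tests verify; coverage < 6× is flagged because binning below
six-fold coverage is unreliable, so MAG absence is uninformative there.
Abundance is each bin's share of summed mean coverage. Reconciliation
matches ASV and MAG taxa at genus level, falling back to family (recorded
as a weak match) only when a genus is missing on one side — species-level
matching across two different taxonomies would overstate disagreement.

## Simulator

`build_community` makes templates as trimmed inserts: a 16S gene from the
mini-reference, the 1492r site, and a random ITS (700–900 nt; host ITS
860 nt). The host contributes two alleles differing by 2 substitutions and
one 12-nt deletion, both placed in the ITS — the structure long amplicons
are uniquely able to resolve. Defaults: host fraction 0.4 of reads (the real
range spans <5% to >95%; a mid-range default keeps both host and
heterotrophs well-sampled), allele split 0.55/0.45, 6 heterotrophs with
normalised log-normal(0, 1) abundances. `simulate_run` draws reads
multinomially, converts a `chimera_rate` fraction into two-parent joins
(distinct parents, split uniform in the middle 60%), applies i.i.d.
substitution errors with a uniform alternative base, adds the terminal
primer sequences, flips a fair coin for orientation, and encodes the error
rate as a constant Phred quality. Every read's provenance (template,
chimera parents, error count) is recorded. Error model is
substitution-only, matching the denoiser's declared scope.

What the simulator does *not* emulate: realistic per-base quality dynamics,
indel errors, length- and GC-dependent PCR bias, barcode effects, or
between-run drift of the community. Passing tests therefore establish the
internal correctness of each rule under the stated model, not performance
on real sequencer output.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale data chosen as the
package's own test conditions: end-to-end checks use 2 strains × 2 runs ×
2000 reads; the denoiser's error-absorption property uses 20 seeds of
1200-nt templates at counts ≥ 60, where the probability that a template
lacks an error-free read is negligible (<1e-7), so exact recovery is a
sharp expectation rather than a coin flip. At full insert length
(~2300 nt) and ε = 0.001 only ~10% of reads are error-free, so
low-abundance templates (tens of reads) occasionally fail exact-sequence
authentication; the acceptance report leaves such runs as measured. All
randomness is generator-seeded; fixed seeds reproduce byte-identical
simulations, tables, and reports.

## Known limitations

- The denoiser is single-pass greedy; it does not re-learn ε from data and
  can let an error sequence found an ASV when its template was never read
  error-free (rare above ~100 reads per template).
- Taxonomy identity uses minimum-edit-distance alignments; at high
  divergence (>15%) gap placement inflates identity relative to a
  fixed-scoring aligner, which is why rank thresholds are only trusted down
  to the phylum floor.
- The operon-variant call is a two-threshold heuristic on counts and
  identity; genuinely ambiguous pairs are reported `unresolved` on purpose.
- The ASV↔MAG reconciliation is name-based at genus rank; it cannot detect
  a MAG and an ASV of the same organism classified under different genus
  names by their respective references.
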