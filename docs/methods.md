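# Methods

## Scope and data model

The package analyses two-group digesta peptidomes. A peptide's identity is
its bare uppercase sequence over the 20-letter amino-acid alphabet;
modification notation is rejected rather than stripped, ambiguity codes
(B, J, O, U, X, Z) are invalid, and duplicate table rows merge by summing
per-sample intensities. Intensities are arbitrary-unit, non-negative, with
absence (an empty TSV cell) meaning "not detected" — distinct from zero.

Parent-protein coordinates are 1-based inclusive on the mature chain, the
milk-peptide literature convention (β-CN f(60–66) denotes residues 60–66 of
mature β-casein). The bundled FASTA carries the mature chains of the six
major bovine milk proteins with their UniProt accessions in the headers.

## Differential abundance

Peptides enter the test when detected (positive intensity) in at least
`min_detected` (default 2) replicates of at least one group; a peptide
passing in only one group is kept for set summaries but flagged
`not_tested`. Missing values are imputed before testing; the default
`half_group_min` strategy fills each missing cell with half the peptide's
minimum positive intensity within that group (global half-minimum when the
group has none), the usual left-censored-missingness heuristic for MS
intensities; a `zero` strategy is available.

The test is the equal-variance unpaired two-tailed Student's *t*
(df = n_a + n_b − 2), applied by default to log2-transformed intensities
because MS intensities are right-skewed and roughly log-normal; a raw-scale
mode exists. Zero pooled variance makes the statistic undefined and the
peptide is reported `not_tested`. Fold changes are computed on the raw group
means, oriented B over A with B the fortified group.

Volcano classification: `up` when log2FC ≥ +threshold and p < α, `down`
when log2FC ≤ −threshold and p < α, else `ns`. Defaults α = 0.05 (the
significance level the underlying study design uses) and a fold-change
threshold of 1 log2 unit (2-fold), the conventional volcano setting; both
are configurable, since published volcano plots often leave the fold-change
cutoff unstated. Boundary conventions: |log2FC| exactly at the threshold is
significant; p exactly at α is not. No multiple-testing correction is
applied by default (classification follows the raw p, as two-group
peptidomics screens typically report); Benjamini–Hochberg values can be
added as annotation via `adjust=True`.

Venn arithmetic treats a peptide as present in a group when detected in at
least one of its replicates. `venn_from_counts` performs the same arithmetic
from printed counts (n_a, n_b, shared), deriving uniques and the union, and
`percent_difference` implements the reference-relative percentage used when
comparing group quantities (e.g. "X% lower than the reference mean").

## Bioactive matching

The matcher's homology score is the longest common subsequence (LCS) of
query and reference under residue equivalence, normalised by the longer
length. Design rationale: the score had to (a) tolerate terminal extensions
and internal gaps, since detected digesta peptides are typically ragged
variants of catalogued bioactives; (b) be symmetric and bounded; (c) admit
an exhaustive brute-force oracle for verification. Positionwise identity
fails (a); local alignment with a substitution matrix adds parameters the
matching rule does not define. Equivalence-class LCS normalised by
max-length satisfies all three; the dynamic programme is verified against a
brute-force recursive oracle on random pairs in the test suite.

Default substitution groups are the three conservative classes
{V, I, L}, {D, E}, {R, K}; they are user-extensible but must stay pairwise
disjoint. An optional `collapse_il` mode treats I and L as identical
independently of the groups, because collision-induced dissociation cannot
distinguish them; it is off by default so that the default behaviour is
fully determined by the substitution groups alone.

The 80% threshold is **inclusive**. This matters: in the bundled example
set, the weakest best hit (EPVLGPVR vs EPVLGPVRGP) scores exactly
100·8/10 = 80.0%, so an exclusive reading would drop a genuine candidate.
Hit ordering is deterministic: homology descending, then smaller absolute
length difference, then database order; the best hit's parent provides the
candidate's parent attribution.

Normalising by the longer of the two lengths (rather than query length or
alignment length) is this package's choice; it is the strictest symmetric
option and reproduces the expected candidate set on the bundled example
data, but other MBPDB-style services may normalise differently.

## Parent-protein profiles

`locate` reports every (possibly overlapping) occurrence of a peptide in a
parent; `build_profile` adds, for each occurrence, 1 to the per-residue
count vector and the peptide's aggregated abundance (group mean after
imputation) to the per-residue abundance vector. Multiple occurrences all
contribute, and a peptide matching several parents contributes to each
parent's profile. Two invariants pin the accumulation down: the count total
equals Σ occurrences × length, and the abundance total equals
Σ occurrences × length × abundance. Exported profiles carry both the raw
cumulative abundance and a max-normalised column, since rendering
conventions differ. Profile comparison is the elementwise difference (b − a)
plus coverage, count and abundance totals.

## Synthetic digesta generator

The generator emulates the small-intestinal peptidome of a gavaged 40:60
casein:whey protein mix, so that the pipeline's statistical behaviour can be
validated against a known ground truth. It is a stand-in, not a model fit to
any dataset.

**Digestion.** Cleavage rules are classical specificities — pepsin (after
F, L, W, Y), trypsin (after K/R unless before P), chymotrypsin (after F, W, Y
unless before P) — applied jointly, emulating sequential gastric and
pancreatic proteolysis reaching the small intestine. Fragments span up to
`max_missed_cleavages` internal cut sites and are filtered to a length
window. Enumeration is deterministic and verified against brute force;
with zero missed cleavages and no window the fragments tile the protein
exactly.

**Defaults.** `max_missed_cleavages=7` and `length_window=(5, 30)` give
1583 distinct in-window peptides over the six bundled proteins — the
magnitude (1000–2000) reported for real intestinal digesta of such mixes,
and a realistic detectable-length range for peptidomics. The abundance
model is log-normal (μ = 1.0, σ = 1.2 in ln units) scaled by each protein's
mixture weight: σ ≈ 1.2 spans roughly three orders of magnitude of
intensity, typical of MS peptidomics. Replicate noise is multiplicative
normal with CV 0.1 (truncated at zero), matching well-behaved technical
triplicates; detection dropout removes a below-group-median peptide from a
replicate with probability 0.1, a simple flat model of
abundance-dependent missingness.

**Presets.** The `obcn`/`fbcn` presets set the β-casein mixture weight to
0.40 × 0.430 = 0.172 and 0.40 × 0.634 = 0.2536 respectively (casein is 40%
of protein; β-casein is 43.0% of casein in the ordinary mix and 63.4% in
the fortified one). The remaining casein weight is split over αs1-, αs2- and
κ-casein in the typical bovine proportions 37:10:12, and the 60% whey
fraction over β-lactoglobulin and α-lactalbumin 3:1 (the whey-protein-
isolate composition). The injected group effect multiplies a fraction
(default 0.25) of β-casein-derived peptides by 2^δ (default δ = 3) in the
fortified group; the truth ledger records exactly which peptides carry it.
With δ = 0 no peptide is marked affected and the two groups are
statistically identical.

All randomness derives from the single integer seed through one
`numpy.random.Generator`; identical seeds give byte-identical tables and
pipeline outputs.

**What the generator does not emulate.** Ionisation efficiency and
peptide-specific detectability, semi-specific or non-specific cleavage,
exopeptidase trimming (real digesta contain ragged N/C-termini beyond these
rule-based fragments), correlated replicate structure, and
abundance-dependent variance beyond the flat CV. Consequently, passing
recovery tests here shows the statistical pipeline is correct under the
assumed noise model, not that it is robust to every artefact of real MS
data. One visible consequence: with triplicates and 10% flat dropout,
almost every simulated peptide is detected at least once per group, so
group-specific peptide counts (the Venn uniques) are far smaller than in
real data, where detectability differences dominate; the fortified preset's
excess of reliably detected β-casein peptides is correspondingly a weak
signal (a net positive excess across paired seeds) while its abundance
excess is essentially deterministic.

## Pipeline and reproducibility

`run_all` chains ingest (file or preset) → Venn → filter/impute →
differential → bioactive matching → per-parent profiles → summary, writing
each stage to its own file; every summary count is recomputable from the
stage files. The manifest echoes configuration, package version and seed but
no timestamp, so identical-seed reruns are byte-identical. Failures abort
with a stage-named error and remove partial outputs. Logging (including
stage timing) goes to stderr only.

Problem sizes used by the validation suite: random-pair oracle checks at
lengths ≤ 12 (1000 pairs), random-protein digest checks at lengths ≤ 50,
recovery checks on the full six-protein preset (~1.6k peptides, three
replicates per group) over a handful of seeds, and the directional preset
comparison over 20 paired seeds — sizes at which the brute-force oracles
remain exact and the whole suite runs in seconds.

## Known limitations

- The homology normalisation choice (max-length) is validated only against
  the bundled example outcomes; threshold semantics of external MBPDB-style
  services may differ.
- The complete conservative-substitution list used by curated databases may
  exceed the three default groups; extend via `SubstitutionGroups` if so.
- Fixture protein sequences are single common variants (β-casein A2,
  β-lactoglobulin B); variant positions (e.g. A1's His67) are not modelled.
- The differential module assumes exactly two groups and equal-variance
  *t*-statistics; no paired or multi-factor designs.
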