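# Methods

This note records the models, conventions and numerical choices behind
`secretomap`, and what the synthetic studies do and do not demonstrate.

## Detection model and the k-of-n filter

Label-free MS detection at the protein level is treated as
presence/absence: a protein counts as detected in a sample when its peak
area exceeds a configurable floor (default 0, i.e. any positive area).
The retention rule — detected in at least k of the n biological
replicates of a stream, default 4 of 5 — guards against spurious
single-run identifications. Both k and n are configuration keys, and n
must equal the stream's actual sample count so that a mis-wired table
fails loudly. The filter is monotone in k, and every filtering stage
logs `n_in = n_retained + n_dropped`, from which the pipeline's funnel
report is assembled.

Accessions mapping to several genes contribute all of them (losslessness;
the ambiguity is logged); accessions missing from the ID map are reported
as unmapped, never silently discarded. "Expressed by the placenta" means
expression at or above a configurable floor (default 1.0 in the units of
the expression table) in the placenta column; the floor exists because a
zero-expression row is evidence of absence, not of low coverage, in the
emulated tables.

## Ortholog consensus

Assertions from any number of labelled sources are pooled per mouse gene
after identifier normalization (whitespace trimmed, trailing `.N` version
suffixes removed — source dialects differ). The number of **distinct**
human partners decides the class: 1 → one-to-one, >1 → one-to-many,
0 → unmapped. Two sources disagreeing on the partner is therefore
one-to-many and excluded — the conservative reading, since the gene's
human identity is ambiguous. Many-to-one (two mouse genes, one human
gene) is allowed, because classification is per mouse gene; occurrences
are logged. The three classes partition the input universe, order of
assertions is irrelevant, and added evidence can only move a gene
unmapped → one-to-one → one-to-many.

## Secretion rule

`secreted ⇔ (signal_peptide ∧ ¬er_lumen) ∨ (go_terms ∩ S ≠ ∅)` with
S = {GO:0005576 extracellular region, GO:0005615 extracellular space,
GO:0070062 extracellular exosome, GO:0044421 extracellular region part}
by default and configurable. The first clause is the conventional
ER/Golgi route (signal-peptide prediction is consumed as a boolean
annotation and never recomputed); the ER-lumen exclusion removes
residents whose signal peptide targets retention rather than export. The
second clause captures unconventional, leaderless secretion. GO matching
is against directly annotated terms — no ancestor propagation — which is
the simplest defensible convention when annotations are consumed as flat
term sets. Genes absent from the annotation table land in an explicit
`unannotated` bucket.

## Map integration and enrichment

The secretome map has one entry per gene in the union of the per-stream
secreted sets; `shared_with_human` requires a one-to-one ortholog whose
human placental expression clears the floor. Tissue enrichment compares
the target tissue against the **maximum** over all other tissues
(strictest comparator; the mean is available by configuration): a gene is
enriched when `expr(target) > fold × max(others)` with fold = 10 by
default. Over-representation of gene categories uses the exact
hypergeometric upper tail with Benjamini–Hochberg correction; the
complication overlays (PE, GDM, IUGR, SGA, LGA) and external gene-set
overlays (organoid secretome, STB expression, DAMP list) are consumed as
plain gene-set files.

## Plasma screen

Normalization divides every column by its internal-standard value (the
spiked bovine-insulin peptide measured in the same run), which makes the
result invariant to per-column rescaling — the point of the standard.
Pregnancy fold change is the ratio of group central values (arithmetic
mean by default, median by configuration); zeros are floored at half the
smallest positive value of the matrix before division so that proteins
undetected in the non-pregnant group get a large finite fold. The 1.5-fold
classification threshold is inclusive and configurable. Row Z-scores use
the population (ddof = 0) standard deviation — fixed here for
bit-reproducibility — and constant rows map to zeros with a warning.

Clustering is agglomerative average linkage under d = 1 − Spearman ρ,
applied to rows and columns. Ties in the minimal inter-cluster distance
(common with rank-based distances on short vectors) are broken by the
lexicographically smallest leaf label in the candidate clusters, making
the merge order and leaf order deterministic. Constant vectors have no
defined rank correlation and are rejected by name at the operation level;
the composed pipeline drops constant rows from the heat-map matrix with a
log message instead of failing the run. Merge heights are non-decreasing
(average linkage is reducible), and the tree exports to Newick with
branch lengths as height differences.

## MoM biomarker statistics

MoM = concentration / median(healthy concentrations at the same week and
analyte); the healthy-at-same-week reference is standard obstetric
screening practice and configurable. Even-sized reference groups use the
midpoint median, so the reference-group MoM median is exactly 1 per
stratum. MoM ratios are per-subject quotients; group effects are
summarized as `100 × (mean_case − mean_ref)/mean_ref` and tested with a
two-sample t-test (pooled Student by default, Welch by flag; `summary_ttest`
accepts mean ± SEM + n). The two-way group × week ANOVA is fixed-effects
with interaction and Type II sums of squares computed from nested
least-squares fits (SS(A|B) = RSS(B) − RSS(A+B), etc., F against the
full-model MSE); it equals Type I/III on balanced designs and is
cross-checked against an independent implementation in the tests. A
single-level week factor degrades to one-way ANOVA, where F(group) equals
the squared pooled t statistic. The two weekly samples per subject are
treated as independent observations — a known simplification in the
absence of a repeated-measures specification.

## Promoter scanning and TF networks

PWMs (MEME minimal format, read and written via Biopython) are
pseudocount-smoothed probability matrices scored as additive
log₂(p/background) over windows on both strands of the −1000..+100
promoter sequence; any N in a window scores −∞. The default hit threshold
is 60% of the motif's maximal achievable score, configurable in bits.
Enrichment is a two-sided Fisher exact test on the has-a-hit × set 2×2
table with BH across motifs — a deliberate threshold-based approximation
to rank-based enrichment scanners, declared as such. The TF funnel keeps
TFs predicted by both the motif route and the upstream-regulator table
(targets pooled), then requires syncytiotrophoblast expression and at
least one secretome-and-STB target (restricting surviving targets to that
intersection makes the filter idempotent), then intersects with the
curated complication-TF list; the result is a directed network with
dysregulation flags, exported as edge TSV and GraphML.

## Synthetic studies: what they emulate, and what they do not

The generator plants every quantity the pipeline measures: a secreted
gene set with conventional/unconventional/trap (signal + ER-lumen)
annotation patterns, stream memberships, one-to-one/one-to-many/unmapped
orthology with cross-source conflicts and versioned-identifier dialects,
placental expression with a 12-fold enriched subset against a 2-fold
background, plasma folds spanning 0.8–52 (including the 1.5 boundary),
week-specific GDM effects, and motif occurrences at 0.6 foreground vs
0.05 background rates. Abundances are log-normal; detection is Bernoulli
dropout independent of abundance — the simplest model supporting a
presence/absence filter. The default study conditions mirror the design
the pipeline targets: 5 replicates/stream, a 10 healthy / 6 GDM serum
cohort at weeks 12 and 28, a 3 non-pregnant / 8 pregnant plasma screen of
45 proteins, 1100-bp promoters. The default GDM effects (sFLT1 ×3.1 and
ANGPT2 ×1.97 at week 12 against an unchanged MIF; MIF ×1.4 at week 28,
encoding its failure to decline) reproduce ≈ +210% and +97% MoM-ratio
increases at large n.

Ground truth is written to a separate JSON that no pipeline stage reads
(leakage guard). What passing tests show: the implemented rules recover
exactly what they were defined to recover, with calibrated error rates.
What they do not show: robustness to abundance-dependent dropout,
peptide-to-protein inference artefacts, batch structure, correlated
biomarker panels, or annotation error in real databases — none of which
the generator models.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale by design: 300–500-gene
studies, 100-instance oracle sweeps of size ≤ 10, 10⁴ null replicates for
calibration, 20 cohort seeds at 200/group for effect recovery. Fisher and
hypergeometric p-values are discrete, so calibration asserts the type-I
band directly and checks uniformity through the conditionally randomized
p-value (exactly uniform under the null); the continuous t and F p-values
are KS-tested as-is. Determinism is asserted by manifest: a run records
the configuration hash, seed, and SHA-256 of every output file.
Degenerate inputs are handled explicitly: zero-variance t-tests return
p = 1 with a warning when means agree and are rejected otherwise;
constant ANOVA responses report F = 0; empty design cells, missing
tissues, zero internal standards and malformed assertion rows are
rejected naming the offender.
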