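# Methods

This note documents the models and procedures implemented in `mapklnc`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic data emulate (and do not), and the numerical conventions. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Discovery cascade

**Novelty exclusion.** A transcript is "known" when its genomic span
overlaps any reference gene interval by at least 1 bp. Reference gene
intervals are the union hulls of each gene's transcript spans. Two choices
were genuinely open and are exposed as options:

* *span vs. exon overlap* (`overlap="span"|"exon"`): span-level is the
  default because it is the conservative, most-excluding reading — a
  transcript inside a known gene's intron is not called novel.
* *strandedness* (`stranded=False` default): strand-agnostic exclusion is
  again the most-excluding reading; antisense candidates are sacrificed for
  specificity. Unknown strand (`.`) matches either.

**Structural filter.** Keep transcripts with ≥ 2 exons, summed exon length
strictly > 200 nt, and at least one intron strictly > 10 bp. All three
inequalities are strict: a 200-nt model or a 10-bp-intron model fails. The
filter is monotone in both thresholds (raising them never admits a
transcript), which the property tests exercise.

**Isoform merging.** Loci are single-linkage connected components of the
exonic-overlap graph (same chromosome, compatible strand; unknown strand
matches either). The merged model's exon set is the coalesced union of
member exons. Merging is idempotent, and the partition is tested against a
brute-force connected-components oracle.

**Coding potential.** Two transparent evidence channels replace the
black-box tools usually run at this stage (a profile-HMM domain search and
a trained logistic classifier), which keeps every classification decision
auditable:

* *ORF channel*: the longest complete ATG→stop ORF over all six frames
  (stop codon included in the length; ORFs without an in-frame stop count
  zero; any codon containing N can neither start nor extend an ORF). The
  channel fires when the ORF is ≥ 300 nt, or covers ≥ 50% of the transcript
  with a Fickett TESTCODE score ≥ 0.95. The TESTCODE statistic uses the
  published position-asymmetry and base-content lookup tables; 0.95 is its
  classical coding threshold.
* *Motif channel*: exact amino-acid motif matches in the six translated
  frames. Fires on any match.

Both channels positive → coding; both negative → ncRNA; exactly one → TUCP.
All thresholds are keyword arguments.

## Differential expression

Condition means are compared on the linear (FPKM) scale. A gene is
discarded only when its mean is below the 0.2 floor in *both* conditions.
log2FC = log2(mean_B / mean_A) with a configurable pseudo-count ε, default
0: a zero mean then gives ±∞, which deliberately passes any finite cut —
the planted simulations use non-zero means, and a finite ε would silently
shrink true fold changes. Directional calls use strict inequalities
(|log2FC| > 1 by default). The conserved set is the intersection of the up
sets and of the down sets separately; a gene that changes direction between
comparisons is conserved in neither.

The threshold filter on a supplied statistics table calls a gene at
|log2FC| > 0.58 (1.5-fold) and FDR < 0.05, computing Benjamini–Hochberg
adjusted p-values (via statsmodels) when an FDR column is absent. BH is the
field default when a procedure is not named. Prevalence ranking counts
samples strictly above 0.2 and returns genes expressed in strictly more
than 90% of samples, ranked by ascending mean expression.

## Cohort statistics

FPKM→TPM divides each sample column by its total and multiplies by 10⁶;
the operation is idempotent on TPM input. Preprocessing strips Ensembl
version suffixes (text after the first `.`), drops duplicate gene ids
(first occurrence kept; a `drop`-all policy is available), and keeps one
specimen per patient (lowest specimen order).

The group comparison reports mean, median, quartiles and Tukey whiskers
(furthest data point within 1.5×IQR of the box), with a two-sided
two-sample t-test. The classical equal-variance Student form is the
default — matching how such comparisons are usually reported — with Welch
behind a flag.

**Random-gene-set correlation null.** For a focal pair (a, b): Spearman ρ
is computed by rank-transforming (average ranks on ties) and taking the
Pearson product of the normalized rank vectors, which lets 2,000 gene-level
correlations be computed as one matrix product. 2,000 random genes are
drawn without replacement, excluding the focal pair and any constant gene
(constant genes are excluded from the pool up front with a warning — the
operational equivalent of resampling), and split into 10 disjoint sets of
200. Per set and per focal gene the result records the mean and sd of the
200 correlations, the Z-score of ρ(a, b) against them, and its rank among
them (rank 1 = highest; ties take the best rank by default, average by
option). Two details the originating analysis left open are configurable:
the Z denominator is the per-set sd (per-set Z values are then averaged),
and ties in ranking. Under full independence the focal-pair Z is
approximately standard normal; the acceptance suite measures this over 200
simulated cohorts.

## Kinome profiling

The plate model: luminescence is linear in remaining ATP. The ATP-standard
wells fit the line (least squares; a non-positive slope is a failed plate),
its intercept is the luminescence offset, and the no-ATP wells provide an
offset QC. Per experimental well, consumed = 250 nM − remaining. The
matched no-peptide well of the same sample measures sample-autonomous ATP
use and is subtracted; no-sample wells should read the full 250 nM.
Replicate wells of the same (sample, peptide) are averaged before
profiling.

Kinase activity is the unweighted mean of the activities of the kinase's
mapped peptide sensors (median by option); kinases with fewer than three
measured sensors are omitted. The mean is the minimal defensible
aggregation rule absent a published weighting.

Clustering uses the uncentered correlation distance
d(x, y) = 1 − Σxᵢyᵢ/(‖x‖‖y‖) — scale-invariant but, unlike Pearson, not
shift-invariant, so profiles with the same shape but different magnitude
regimes separate — with average linkage (UPGMA). The agglomeration is
implemented directly with deterministic tie-breaking (smallest cluster-id
pair) and is tested against both a brute-force O(n³) oracle and scipy's
average-linkage heights. Zero vectors have no defined angle and are
assigned the maximal distance 1 to every other item. Dendrograms export to
Newick with ultrametric branch lengths (node height = merge distance / 2).

Signature comparison expresses each treatment signature as log2 ratios to
a matched control signature and reports Pearson r over the shared kinases;
kinases with non-positive activity in any of the three signatures are
dropped (the log ratio is undefined) with a warning, and a constant
normalized signature is an error.

## Pharmacology

**Combination index.** CI = log2(E_ab / (E_a·E_b)) with all E as
control-normalized surviving fractions in (0, 1]; CI < 0 ⇔ the combination
kills more than Bliss independence predicts. A published variant of this
formula carries a minus sign inside the log; with fractional survivals
that argument is negative and the criterion "CI < 0 means synergy" cannot
hold, so the ratio form is the default and the literal form (with E
recoded as negative growth change) is available as `strict_sign=True` for
comparison. Single-agent margins (dose 0 rows/columns) are excluded from
the mean.

**Comparative Ct** assumes amplification efficiency exactly 2 (one cycle =
one doubling), the standard assumption when efficiencies are not reported:
fold = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_housekeeping per sample.

**N/C ratio.** Raw nuclear/cytoplasmic enrichment per gene is
2^(Ct_cyto − Ct_nuc) from fraction-specific Cts, normalized to a
nuclear-enriched reference RNA (e.g. MALAT1). No housekeeping normalizer is
used across fractions — the two fractions are not comparable through one.

**Tumor volume** V = 0.5·L·W² with the convention length ≥ width; violated
inputs warn and are swapped (configurable).

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuned:

| parameter | default | rationale |
|---|---|---|
| conditions / sizes | 5 conditions × n = 6 | three wild-type-vs-mutant comparisons with replicate-scale groups |
| planted DE | 20 up + 20 down of 2,000 genes, log2FC = 2 | clearly separated from the log2FC > 1 cut |
| expression noise | 0.3 log2 units | moderate biological+technical spread for cell-line FPKM |
| baseline abundance | log-uniform 1–100 FPKM | spans the expressed range above the 0.2 floor |
| planted pair | Spearman ρ = 0.4, unit log2 variance | tumor-cohort effect size of interest; the Gaussian copula uses Pearson r = 2·sin(πρ/6) so the rank correlation hits the target exactly in expectation |
| plate | slope 4 RLU/nM, offset 100 RLU, consumption 20–80 nM/peptide, background 5–15 nM/sample, CV 2% | keeps every well within the 0–250 nM dynamic range; 2% is plausible plate-reader noise |
| single-agent kill curves | exponential, ~17% survival at top dose | monotone curves spanning the informative effect range |
| Bliss deviation | −0.5 log2 | a clear but not extreme synergy |
| Ct tables | housekeeping Ct 20, target Ct 25, noise 0 | folds encoded exactly as ΔΔCt = −log2(fold) |

One synthetic chromosome (default 10 Mb) hosts all annotation features in
disjoint 20-kb slots: reference genes each overlapped by one assembled
transcript, planted novel lncRNAs (3 × 150-nt exons, 50-bp introns), and
noise transcripts cycling through the three structural-violation classes
(mono-exonic; exactly 200 nt; introns exactly 10 bp). Transcript sequences
are drawn i.i.d. per transcript — there is no genome-level sequence — and
planted lncRNA sequences are scrubbed of start codons on both strands so
the ORF channel classifies them ncRNA deterministically. Expression noise
is log-normal (Gaussian on log2), the simplest model consistent with
fold-change semantics. Determinism: all randomness flows from
`SimConfig.seed` through a fixed `SeedSequence` spawn order, so identical
configs give byte-identical artifacts.

What the synthetic data do **not** emulate — and hence what passing tests
do not show about real data: read-level sequencing artifacts and assembly
errors, realistic genome sequence composition (planted lncRNAs are
separable by construction, not by learned features), batch effects and
library-size variation, the heavy-tailed correlation structure of real
tumor transcriptomes (random-gene null calibration on real cohorts will be
wider), plate edge effects and spatial gradients, and qPCR efficiency
departures from 2.

## Problem sizes and tolerances

The recovery and calibration benchmarks (in `mapklnc.evaluation`, driven
by the acceptance tests and `scripts/acceptance.py`) use: 20 simulations
for conserved-DE recovery; 100 random matrices for TPM sums; 200 cohort
replicates (2,500 genes × 366 samples) for null-Z calibration; 100 random
8×8 matrices for the UPGMA oracle and 100 noisy plates for the dendrogram
top-split rate; 100 replicates for the mean combination index; 500
global-null replicates for the empirical FDR and 10,000 for t-test type-I
error — sizes at which the Monte-Carlo error is comfortably below each
check's tolerance. Exact identities (zero-noise round trips, Bliss
independence) are asserted at 1e-9 or machine precision.

## Known limitations

* The coding-potential classifier is a transparent rule-based stand-in;
  it will not reproduce the calls of a trained classifier or a real domain
  search on real transcripts.
* Kinase aggregation ignores peptide-sensor quality weights; published
  kinome pipelines apply additional normalization layers.
* The conserved-DE stage consumes expression matrices, not read counts; no
  dispersion model is fitted (a per-gene statistics table from such a model
  can be fed to the threshold filter).
* Tumor-vs-normal comparisons on real public cohorts require downloads this
  package deliberately does not perform; the cohort stage is validated on
  simulated cohorts with the same shapes (n = 366 tumor, n = 1305 normal).
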