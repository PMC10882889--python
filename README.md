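# mapklnc

A tested re-implementation of the computational pipeline used to discover and
characterize MAPK-responsive long non-coding RNAs (lncRNAs) in melanoma: from
assembled transcripts to novel-lncRNA candidates, through conserved
differential expression and tumor-vs-normal cohort statistics, to
peptide-sensor kinome profiling and the closed-form pharmacology arithmetic
(drug-combination index, comparative Ct, subcellular enrichment, tumor
volume). A synthetic-data generator with planted ground truth stands in for
the raw sequencing and plate data, so every stage is testable end to end
without downloads.

It is written for computational biologists who want to re-run, audit or adapt
this class of lncRNA-discovery analysis rather than re-derive it from a
methods section.

## The pipeline

1. **Discovery** (`mapklnc.discovery`). From assembled vs. reference
   annotations: drop transcripts overlapping any known gene by ≥ 1 bp, keep
   multi-exonic transcripts > 200 nt with at least one intron > 10 bp, merge
   isoforms into loci by single-linkage exonic overlap, and classify
   survivors by coding potential. Coding potential combines a six-frame
   ORF scan with the Fickett TESTCODE statistic and an amino-acid motif
   channel; both channels positive → *coding*, both negative → *ncRNA*,
   conflict → *TUCP* (transcript of unknown coding potential).
2. **Differential expression** (`mapklnc.de`). Per condition pair: gene
   means, an FPKM < 0.2 expression floor, strict |log2FC| > 1 calls, and the
   sign-consistent intersection across all comparisons. A separate threshold
   filter (|log2FC| > 0.58, Benjamini–Hochberg FDR < 0.05) applies to a
   precomputed per-gene statistics table, and prevalence ranking reports the
   genes expressed (> 0.2) in more than 90% of a patient cohort.
3. **Cohort statistics** (`mapklnc.cohort`). FPKM→TPM conversion
   (TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶), cohort preprocessing
   (gene-version stripping, de-duplication, first specimen per patient),
   boxplot-style group comparison with Student's t-test, and the
   random-gene-set correlation null: the Spearman ρ of a focal gene pair is
   ranked and Z-scored against its correlations with 10 disjoint sets of 200
   random genes.
4. **Kinome** (`mapklnc.kinome`). ATP-standard calibration of plate
   luminescence, background-corrected per-peptide ATP consumption, kinase
   activities as the mean over ≥ 3 mapped peptide sensors, hierarchical
   clustering with uncentered correlation and average linkage (UPGMA), and
   Pearson comparison of control-normalized treatment signatures.
5. **Pharmacology** (`mapklnc.pharm`). Combination index
   CI = log2(E_ab / (E_a · E_b)) with E the surviving fraction (CI < 0 ⇔
   synergy), comparative-Ct fold change 2^(−ΔΔCt), nuclear/cytoplasmic
   enrichment 2^(Ct_cyto − Ct_nuc) normalized to a nuclear reference RNA,
   growth normalization, and the caliper volume V = 0.5 · L · W².

`mapklnc.simulate` generates every input class with planted truth; the
numbered scripts under `analysis/` run the stages in order and write their
tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_discover_lncrnas.py
python analysis/04_cohort_correlation.py
```

prints, among other lines:

```
annotation: 50 reference transcripts, 85 assembled (5 planted novel lncRNAs)
85 assembled transcripts -> 5 structural candidates
classified ncRNA: 5; planted recovered: 5/5; false positives: 0
tumor: focal-pair Spearman rho = 0.341, mean rank vs 10×200 random genes = 1.0, mean Z = 6.57
normal: focal-pair Spearman rho = -0.016, mean rank vs 10×200 random genes = 125.9, mean Z = -0.33
```

The discovery cascade recovers exactly the five planted novel lncRNAs from
85 assembled transcripts (none of the 30 structural-noise or 50
known-gene-overlapping transcripts survive). In the simulated tumor cohort
(n = 366, planted Spearman ρ = 0.4) the focal gene pair ranks first in all
ten random-gene sets with a mean Z of 6.6 — the planted association is far
outside the cohort's background correlation structure — while in the normal
cohort (no planted correlation) its rank is indistinguishable from chance.

The same stages are available as a CLI (`mapklnc simulate|discover|de|cohort|kam|pharm`);
run `mapklnc --help` for the subcommands.

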