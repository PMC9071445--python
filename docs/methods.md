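# Methods

## Overview

`dartcall` implements DART-seq analysis: detection of m⁶A sites from the
C-to-U edits left by an APOBEC1–YTH fusion, and the downstream statistics a
compartment-resolved (soma vs neurite) study needs — differential editing,
per-RNA editing scores, metagene region enrichment, and paired
neurite/soma localization statistics. All stages are exercised on data from
the package's own synthetic generator, which plants sites and localization
effects with recorded ground truth.

## Site calling

Alignments are reduced to per-position base counts over *gene territory*:
annotated exons plus a downstream 3′UTR extension (default 5000 bp, clipped
at chromosome ends) that captures editing in unannotated UTR sequence. The
editing rate at a transcript-strand reference cytidine is

  %C2U = 100 · edited / (edited + unedited)

where on a plus-strand gene edited = T count and unedited = C count, and on
a minus-strand gene the plus-strand A and G counts. The denominator is
deliberately C+T rather than total coverage: stray non-C2U alleles count
toward the read-depth filter but do not dilute the conversion rate.

The calling cascade, per DART replicate against every knockout (KO)
control:

1. coverage ≥ 50 unique (deduplicated) reads;
2. ≥ 3 edited reads;
3. 1% ≤ %C2U ≤ 95%;
4. %C2U ≥ 1.25 × the control's %C2U for **every** KO control covered at
   ≥ `min_control_coverage` (default 10) reads at that position; positions
   with no adequately covered control are rejected.

Sites called in ≥ 2 replicates are merged (identity = chrom, position of
the edited C, strand), restricted to the RAC consensus (transcript-strand
3-mer `[AG]AC` ending at the C; the inferred m⁶A adenosine is one base 5′),
and finally kept as high-confidence when the unweighted replicate-mean WT
%C2U is ≥ 1.5 × the KO mean. A site uncovered in every KO gets a KO mean of
0 and is retained with a `no-control-coverage` flag. All threshold
comparisons are inclusive ("a minimum of", "at least").

Choices where the procedure was genuinely open:

- `min_control_coverage` guards the fold test against controls that are
  edit-free only because they are nearly unread; shallow controls are
  skipped rather than letting one of them veto or trivially pass a site.
- The fold test uses rate ratios (not pseudocounted count ratios); combined
  with the control-coverage floor this is deterministic and monotone in
  every threshold.
- "Three mutations" is enforced per replicate, since candidates are called
  per sample before merging.
- Replicate means are unweighted (a per-replicate average, not
  coverage-weighted); a different weighting would couple the confidence
  filter to library depth.
- Overlapping mate bases are counted once; on disagreement the higher base
  quality wins and ties are discarded. MAPQ ≥ 10 and base quality ≥ 20 by
  default; duplicate/secondary/supplementary/QC-fail reads are excluded.
  Deletion-spanned positions contribute nothing; insertions are ignored
  (pure substitution model).
- Default library orientation is `reverse` (dUTP); the simulator emits a
  forward-stranded library and its pipelines say so explicitly. Unstranded
  data are supported but cannot disambiguate genes overlapping on opposite
  strands — territory assignment then prefers the gene whose non-extended
  annotation contains the position, then the nearer annotated 3′ end.

## Annotation model

Coordinates are 0-based half-open internally (GTF converted on input, BED
written natively). Each gene is represented by one transcript — the longest
summed exon length, ties to the lexicographically smallest transcript_id —
partitioned into 5′UTR/CDS/3′UTR by the CDS genomic span. Noncoding genes
participate in site calling over their exons but are excluded from metagene
statistics, where their regions are undefined. The 3′UTR extension does not
stop at downstream neighbors; overlap is resolved at territory-map time as
above.

## Differential editing

Editing frequencies are compared between two groups with a binomial GLM on
the logit scale: one (edited, unedited) row per sample regressed on a group
indicator, Wald z on the group coefficient, two-sided normal p,
Benjamini–Hochberg adjustment across sites. No overdispersion term is
fitted — the model is the plain binomial likelihood. Complete separation
(a group with zero edited or zero unedited reads pooled) falls back to a
Haldane-corrected (+0.5) pooled 2×2 log-odds ratio and is flagged
`separation`. With identical covariates within groups the per-sample-row
fit coincides with the pooled 2×2, which is what the closed-form oracle in
the tests checks to 1e-8.

RNA-level contrasts pool (edited, unedited) within each sample across the
gene's called sites and reuse the same test. Pooling means sites shifting
in opposite directions can cancel at the gene level; this is inherent to
the aggregation and demonstrated by a constructed example in the tests.
The per-RNA editing score is the cumulative sum of replicate-mean %C2U over
called sites (percentage points; 0 for a gene with no sites).

## Metagene analysis

A site maps to (region, offset) on its gene's representative transcript;
the metagene coordinate rescales each region to unit width (5′UTR → [0,1),
CDS → [1,2), 3′UTR → [2,3), stop codon at 2.0). Sites in extended 3′UTR
territory map into the 3′UTR with the fraction computed over the extended
length. The region-enrichment test compares observed per-region counts to
expectations proportional to the median region lengths of the gene category
under study: expectedᵢ = N·mᵢ/Σm, χ² on 2 df. Expected counts are invariant
to rescaling all medians, which the tests assert.

## Localization statistics

Gene counts are normalized with median-of-ratios size factors. NB
dispersions are per-gene method-of-moments estimates (pooled within-group
variance), shrunk toward a `a₀ + a₁/mean` trend fitted across genes by
least squares on the (sign-retaining, clipped) raw estimates. Because the
raw moment estimator at 2–4 residual degrees of freedom is extremely noisy
— and an underestimated dispersion directly inflates Wald statistics — the
gene estimate enters with weight dof/(dof+20); the floor is 1e-8 and
dispersions are shared across conditions.

Enrichment (FC_N/S) per condition: NB GLM of counts on compartment with the
culture insert (pair) as a blocking covariate and log size factors as
offset; Wald p on the compartment coefficient, BH q. Genes with
baseMean < 10 or on the mitochondrial contig (default `chrM`/`MT`) are
`filtered`; significant genes at |FC| ≥ 1.5 and q ≤ 0.05 are labeled
neurite_enriched/neurite_depleted. The soma-only condition response (e.g.
KCl induction) uses the same machinery at a ±2-fold threshold.

Localization change (ΔFC_N/S) follows a dual-pipeline design with a
least-significant selection rule:

- **Pipeline 1** fits one NB GLM over all samples with compartment,
  condition, their interaction, and pair dummies nested in condition; the
  Wald p of the interaction tests whether the condition effect differs
  between compartments. The reported ΔFC_N/S is this interaction estimate
  in log2 units.
- **Pipeline 2** models each pair's neurite count with the paired,
  normalized soma count (+0.5) as an offset, testing the condition effect
  on the within-pair N/S ratio.
- Per gene, p_final = max(p₁, p₂) — the less significant pipeline decides —
  followed by BH adjustment. The max-p dominance is asserted on every run.

This keeps the published architecture (two parameterizations, per-insert
pairing, least-significant selection, ΔFC_N/S as the effect) while using
deterministic NB-GLM Wald tests in place of a posterior-sampling
implementation; swapping condition labels negates ΔFC_N/S and leaves
p_final unchanged to numerical precision (IRLS tolerance 1e-10).

FPKM uses normalized counts over the normalized library size and
kilobases of union exon; "expressed in neurites" means replicate-mean
neurite FPKM strictly greater than 5.

## Synthetic data

`simulate_genome` lays out alternating-strand genes (5′UTR 100–250 bp, CDS
300–700 bp, 3′UTR 200–500 bp, ~30% with one intron) on a single chromosome
with intergenic gaps sized so that extended 3′UTR territories never overlap
(with the default 5 kb extension the 50-gene genome is ≈ 0.5 Mb). Edit
sites are planted at recorded transcript offsets with `[AG]AC` context —
a fraction (default 20%) get a deliberately non-RAC `TAC` context to
exercise the motif filter — and WT conversion rates drawn uniformly from
10–50%. The background conversion rate is 0.1% everywhere, and KO samples
edit only at background.

`simulate_editing` draws per-position coverage from NB(mean 200,
dispersion 0.05) and edited reads binomially — the desk-scale analogue of
the deep replicated design. `simulate_reads` instead realizes the model
read by read (full-match single-end 50-mers, forward-stranded, constant
quality) and returns the editing table obtained by independently tallying
those reads, so pileup construction can be checked for exact equality; a
helper emits an overlapping proper pair to exercise mate deduplication.

`simulate_localization_counts` draws log-normal soma means (median 500),
plants |log2 FC_N/S| = 2 enrichment in 5% of genes and |Δlog2 FC_N/S| = 1
localization changes (random sign) in 10%, with NB dispersion 0.01,
2 pairs per condition and log-normal size factors recorded in the sample
sheet. Truths serialize to JSON/TSV and recovery tests read them back from
disk.

What the generator does **not** emulate: sequencing errors and quality
variation, splice-junction reads, UMI duplicates, alternative isoforms,
GC/positional coverage bias, and correlated biological replicate structure.
Passing recovery tests therefore demonstrates the correctness and
calibration of the algorithms under their stated model, not performance on
real libraries, where coverage is burstier and the KO background is less
uniform.

## Numerical conventions and limitations

- GLM fits use IRLS with tolerance 1e-10/1e-12; statistical oracles in the
  tests are closed-form or independently re-implemented.
- Problem sizes in tests and the acceptance script (50-gene genomes, ~10⁴
  editable positions, 2000 genes × 8 samples for localization, 2000
  simulated null sites) were chosen as the smallest scales at which the
  recovery and calibration properties are stable across seeds.
- Wald tests with plug-in dispersions are mildly anti-conservative at very
  small replicate numbers; the max-p rule compensates in the delta
  procedure (its null is conservative), and the binomial null calibration
  is verified empirically.
- Two-group contrasts only; no batch covariates beyond pairing, no
  fold-change shrinkage, no isoform-level analysis.
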