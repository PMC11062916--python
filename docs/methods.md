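# Methods

`mirreg` identifies microRNAs whose transcription is plausibly under the
direct control of a transcription factor (TF) in a tumour cohort. The
motivating setting is testicular germ cell tumours (TGCTs), where the
pluripotency factor NANOG on chromosome 12p is highly expressed in
seminoma (SEM) and embryonal carcinoma (EC) and low in teratoma (TERA)
and yolk sac tumour (YST), and where NANOG binding upstream of miRNA loci
can repress or activate them. The pipeline combines five independent
evidence layers into an auditable candidate list.

## Evidence model

**Binding.** TF ChIP-seq replicates are reduced to a consensus by strict
per-base intersection: a base belongs to the consensus only if every
replicate has a peak there (a minimum-coverage-fraction alternative is
available behind `consensus_min_fraction` but off by default). Each miRNA
locus contributes graded strand-aware upstream windows of 1, 2, 5 and
10 kb abutting its 5' end; a locus counts as bound when a consensus peak
overlaps the 10 kb window by at least `min_overlap_bp` (default 1 bp —
there is no principled minimum, so it is a config knob). The binding
record carries the smallest touched window and the gap (bp) between the
nearest qualifying peak edge and the 5' end, 0 when the peak covers it.
All coordinates are 0-based half-open internally; 1-based annotation
inputs are shifted on read, which removes any chance of off-by-one drift
between BED inputs and prose coordinates.

**Expression strata.** Counts are normalized to counts-per-million and
log2(x+1)-transformed (the pseudo-count of 1 is the usual choice and is
recorded in the config). Tumours are stratified on the driver gene either
into expression tertiles (H/M/L, descending; with ties broken by stable
sample-id order and the H stratum absorbing a remainder first) or by
explicit cutoffs with boundary values assigned to the upper stratum —
both conventions exist purely for determinism.

**Differential expression.** Between driver-high and driver-low samples,
each feature gets a two-sided Mann–Whitney rank-sum test on its log2-CPM
values, with log2 fold change as the difference of group means on the
log2 scale and Benjamini–Hochberg step-up control across all tested
features. A feature is *significant* only when FDR < α (default 0.05)
**and** its mean log2 normalized expression across both groups exceeds an
expression floor (default 1.0) — the floor suppresses significance calls
driven by near-zero counts. This is a deliberately simple, fully
specified stand-in for count-model DE (edgeR/DESeq2-style dispersion
estimation is out of scope); the rank-sum test is conservative and
distribution-free, which is the right trade-off when the decision
structure downstream (significant / not, direction) matters more than the
exact p-value. Sample-structure summaries (Spearman correlation with
average ranks, complete-linkage clustering on 1−ρ, PCA on feature-centred
data with the sign of each component fixed by its largest-magnitude
loading) are descriptive only.

**Cohort consistency.** Tumour-versus-normal microarray cohorts provide
linear fold changes per miRNA. After harmonizing names through a static
alias table (shipped as a small TSV; live miRBase synchronization is out
of scope), a miRNA is kept when its ratio is ≥ 1.5 or ≤ 1/1.5 — applied
on the linear ratio scale. Per-cohort calls are consolidated by union;
miRNAs called in opposite directions across cohorts are flagged
*discordant* and never count as confirmation, but stay in the output for
audit. A tumour-strata DE call is *cohort-consistent* when the unified
list contains the miRNA, non-discordant, with the same direction.

**Distance rule.** Predicted miRNA transcription start sites lie within
about 2 kb upstream for intergenic miRNAs and about 4 kb for intronic
miRNAs (whose promoters sit in host-gene territory), so binding evidence
is only accepted as promoter-proximal when the peak-to-5'-end gap is
≤ 2000 bp (intergenic) or ≤ 4000 bp (intronic). The locus 5' end is used
as the TSS proxy for both classes; locating host-gene TSSs would need
annotation the pipeline does not require.

**Cascade and tiers.** Stages: (1) bound; (2) ∩ significant H/L DE;
(3) annotate cohort consistency; (4) distance rule; (5) drop entries on
an explicit known-miRNA exclusion list (`excluded_reason="known"`), which
makes otherwise-manual judgment calls reproducible. Tier 1 passes 1–4;
tier 2 passes 1, 2 and 4; tier 3 passes 1–2 only. Within a tier,
candidates sort by ascending DE FDR then ascending binding distance (a
deterministic tie-break; any other fixed order would be equally
defensible). Every record keeps all stage outcomes, so the final list is
an evidence trail, not just a ranking.

**Clinical association.** For tier-1 candidates the pipeline contrasts
GCNIS-present vs -absent, stage II vs I and stage III vs I (stage I as
reference) with the same DE machinery over all features, so the BH family
is the full feature set per contrast; a flag (`gcnis_assoc`,
`stage_assoc`) is set when the candidate's FDR < α in the corresponding
contrast. A level with fewer than two samples renders its contrast "not
evaluable" rather than failing.

**Downstream targets.** Predicted-target lists from several algorithms
are combined by vote counting (default `min_votes=2` of 4 — inclusive,
because prediction algorithms have low pairwise agreement; configurable).
Three-way overlaps of downregulated genes, predicted targets and a
cell-type signature identify "direct targets in signature" as the triple
intersection. Cytoband filtering selects genes whose band label starts
with a prefix such as `12p`. qPCR analysis uses the comparative-Ct
method: replicates averaged, ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt against the control-group mean, fold = 2^(−ΔΔCt) with amplification
efficiency fixed at 2.0. Endogenous-control candidates are ranked
ascending by the standard deviation of their Ct across samples (ties by
coefficient of variation, then name); SD is the core stability
descriptor — pairwise-correlation stability indices are out of scope. A
candidate missing in more than half the samples is excluded with a
reason.

## Synthetic data

The generator plants a known answer key so every stage is testable
without downloads. Defaults (the study conditions): 200 miRNA loci on one
synthetic chromosome (one locus per 50 kb slot, jittered, random strand,
30% intronic); 30 planted regulated miRNAs with signed log2 effects of
magnitude 2 (half repressed); ChIP peaks (200–500 bp wide, 3 replicates,
±50 bp replicate shift) planted so the consensus near edge sits at a true
distance drawn uniformly from 0–1800 bp for regulated loci and
3000–20000 bp for 30 decoy loci; negative-binomial counts (dispersion
0.3) for 90 samples (SEM 40, EC 30, TERA 10, YST 10) whose driver
expression is high in SEM/EC and low in TERA/YST, with each planted
miRNA's log2 mean coupled linearly to the sample's driver percentile;
two fold-change cohorts sharing each planted miRNA's direction (log2
effect magnitude 1–2, cohort noise SD 0.2); and GCNIS/stage labels whose
probabilities shift with the mean expression percentile of six planted
repressed candidates (lower expression → GCNIS more likely and higher
stage). Each artifact draws from its own seeded stream, so regenerating
one never perturbs another and every output is a pure function of the
config.

What the generator does **not** emulate: multi-chromosome genomes by
default, copy-number structure (e.g. 12p gain), microarray probe effects,
library-composition biases, per-feature dispersion variation, or
covariate confounding between subtype and clinical labels beyond the
planted coupling. Passing recovery tests therefore demonstrates that the
cascade's logic is correct and well-calibrated under its stated model,
not that real-cohort candidates are guaranteed true positives.

## Problem sizes and numerics

Tests and the acceptance script run the generator at its default sizes
(200 features × 90 samples), 10 seeds for recovery and 20 seeds for null
calibration — sizes at which the planted effects are comfortably
detectable and a full run takes seconds. Degenerate inputs are errors,
not silent answers: zero-length intervals, strand-less loci entering
binding, all-zero library sizes, overlapping DE groups, p-values outside
[0,1], non-positive fold changes, conflicting aliases, empty control
groups. Upstream windows clipped to nothing at the chromosome origin
yield "no window" (unbound) rather than an invalid interval. Reports
carry a config hash and no timestamps, so identical runs are
byte-identical.

## Known limitations

* The rank-sum DE stand-in has less power than count-model DE at small n
  and does not model dispersion; absolute p-values are not comparable to
  edgeR/DESeq2 output even when decisions agree.
* The 5'-end TSS proxy ignores distal or host-gene promoters; the
  intronic 4 kb allowance is a classification rule, not a TSS model.
* The alias table is a small static snapshot; unrecognized spellings pass
  through unchanged (and are reported) rather than resolved.
* Strict-intersection consensus is sensitive to one bad replicate; the
  coverage-fraction mode exists for that case but changes the meaning of
  "consensus" and is therefore off by default.
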