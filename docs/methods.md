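# Methods

## Promoter search space and motif counting

Coordinates are 0-based half-open (BED convention) everywhere; 1-based
inputs must be converted at the reader boundary. A gene's search space is
the intersection of a TSS-anchored window with the merged open-chromatin
track. The window defaults to ±10 kb (a 20 kb promoter neighbourhood); the
upstream/downstream split is configurable because a symmetric split is an
assumption, not a biological necessity. On the minus strand the flanks are
mirrored. Clipping at sequence boundaries shortens the window, never below
one base, and a TSS outside its chromosome is an error naming the gene.

Open-chromatin tracks (e.g. two replicate DNase accessibility tracks) are
merged by a sorted sweep that fuses overlapping and bookended intervals;
the result is the minimal disjoint representation of the base-pair union,
and tests verify it against a base-resolution boolean mask on toy
chromosomes.

Motif matching is exact IUPAC matching of the consensus `GACGTGKCMTWW`
(Hocomoco M00402 logo). Every window of motif length is tested on the plus
strand and against the reverse-complemented pattern; overlapping matches
and both orientations count as separate instances, because the quantity of
interest is how many binding opportunities a promoter offers. `N` bases
never match; sequences are uppercased on load. A hit counts toward a gene
only when fully contained in one accessible subregion — containment is the
strict, reproducible reading of "instances found in open chromatin"; a
motif instance straddling an accessibility boundary is not a credible
binding site call. Because counts here come from direct scanning of the
supplied genome, they will generally differ from counts derived from
precomputed motif databases on specific assemblies; the packaged panel's
motif counts are fixture data, not a recomputation target.

Homotypic clusters — runs of ≥ 2 instances whose consecutive starts lie
within `max_gap` — are tallied alongside raw counts. `max_gap` defaults to
500 bp, a typical cis-regulatory module scale; it is a CLI knob because no
canonical distance exists. The count-vs-response test is a Pearson
correlation of instance (or cluster) counts against log2 fold change, with
a two-sided p from the t distribution on n − 2 df; zero-variance input
raises an error rather than returning a number.

## 2^−ΔΔCt quantification

Replicate structure is E biological experiments × T technical replicates
(default 3 × 3, i.e. n = 9 wells). Technical replicates are averaged first
and never inflate n for testing. Per experiment,
ΔCt = Ct(target) − mean(Ct of references); the two references (*GAPDH*,
*RPLP0*) are combined by the arithmetic mean of their Cts, which is the
geometric mean in expression space. ΔΔCt is the difference of
cross-experiment mean ΔCt between condition and baseline, and the fold
change is 2^−ΔΔCt: amplification efficiency is fixed at 2.0 (no standard-
curve correction). The reported spread is the sd of per-experiment fold
changes, and the p-value defaults to Student's t on per-experiment ΔCt
values (Kruskal–Wallis available as `anova_on_ranks`); identical groups
return p = 1 with a zero-variance flag, and noise-free separated groups
return p = 0 with the same flag rather than dividing by zero.

Rebasing converts a vs-control fold change into a vs-stress fold change by
dividing by the stress-alone fold change — algebraically
2^−(ΔΔCt₁ − ΔΔCt₂). Table output rounds fold changes to two decimals; full
precision is kept internally. Mild-dose selection returns the smallest dose
at which *all* reporter genes (XBP1s, *HSPA5*, *DDIT3* by default) reach
the threshold fold (default 2.0), or an explicit no-qualifying-dose result.

## DE selection and the unspliced-isoform control

Selection keeps genes with |log2FC| ≥ 1 (twofold) and p < 0.05. Boundary
handling is fixed and tested: a fold change exactly at the threshold is
included, a p-value exactly at the threshold is excluded. Genes passing the
same thresholds in the XBP1u induction experiment are removed from the
XBP1s candidate sets **in both directions** — any sensitivity to the
induction system disqualifies a gene as a direct XBP1 candidate, which is
the conservative reading. The five Venn sets are disjoint by construction
(a gene listed in both directions of one experiment, possible only at
degenerate thresholds, counts as up). Motif filtering keeps candidates with
≥ 1 accessible instance, plus a force-include list for previously reported
targets (*HSPA5*, *DDIT3* — the latter carries no consensus instance).
DE input is a generic (gene, log2FC, p, q) table so upstream tools'
output maps in by column renaming; no expression model is re-fit here.

Heat-map ordering is the leaf order of average-linkage agglomeration
(euclidean or 1 − Pearson distance), with rows imputed by their own mean
and pre-sorted lexicographically so the result does not depend on input
order; the merge sequence is tested against a brute-force O(n³)
agglomeration oracle.

## Dependency classification

The profile matrix has seven fold-change columns per gene — XBP1s
induction, Tg and Tm vs control, silencing under each stress vs control,
and the two derived silencing-vs-stress ratios — plus a parallel boolean
significance matrix and a distinguished XBP1s reference row.

The three **experimental approaches** are: (1) the induction cell;
(2) the Tg-silencing arm; (3) the Tm-silencing arm. Under the default
`or` rule an arm fires when either of its two printed comparisons
(vs control, vs stress alone) is significant; single-column rules
(`vs_ctrl_only`, `vs_stress_only`) are available because no published rule
reproduces a panel's final membership under either single column alone.
A gene needs ≥ 2 firing approaches to be classified.

Correlation uses the five primary columns (induction and the four
vs-control responses); the derived ratio columns are excluded to avoid
counting the same measurements twice. Fold changes are correlated raw by
default, with a log2 option. Classified genes whose two silencing-vs-stress
ratios are both significant and point in opposite directions (one > 1, one
< 1) are demoted to `model_dependent` — their levels track the stress
model, not XBP1 alone. r exactly 0, or an undefined correlation, leaves a
gene unclassified. On the packaged panel this rule places *BBC3* and *ERN1*
(among others) in the repressed set, the classical targets *DNAJB9*,
*EDEM1* and *SEC23B* in the activated set, and *DDIT3*/*GADD34* in
`model_dependent`; *HSPA6*, with a single significant cell, stays
unclassified. The rule is deliberately not tuned to reproduce any
particular published set size.

## Synthetic data

The generators' defaults are the study's magnitudes: an 11-fold XBP1s
induction for ΔΔCt recovery, 0.1-cycle technical noise, 3 × 3 replicates,
345 up / 199 down planted genes among 12,000 for the DE screen, twofold
silencing ratios and 10% log-scale noise for the classifier matrices, and
4 accessible + 3 inaccessible planted motif instances per gene.

*Genomes.* One chromosome per gene, uniform ACGT background, TSS centred so
the strand-aware window is a fixed span, accessible blocks covering 20% of
the window in four segments. Planted instances are concrete realizations of
the degenerate consensus, half of them reverse-complemented, placed
disjointly fully inside (or fully outside) accessible blocks. Chromosomes
whose rescan does not reproduce the planted instance set exactly — a chance
background match anywhere, or a planted instance spawning an extra
overlapping match — are rejected and resampled, so manifests are exact, not
probabilistic. Every generator run ends by re-reading its output through
the scanning module and asserting manifest consistency.

*Ct tables.* Per well, Ct = gene baseline + planted ΔΔCt + N(0, sd);
reference genes carry no effect. Each gene is measured in its own sample
with its own reference wells, making genes statistically independent —
real array plates share reference wells within a plate, which would
correlate genes; independence is chosen so that binomial error bands apply
to rate checks. With sd = 0 the pipeline recovers planted effects exactly;
at sd = 0.1 and 3 × 3 replicates an 11-fold planted induction is recovered
within 10% and the planted-shift bias is below 0.05 cycles over 500 genes.

*DE tables.* Null genes: log2FC ~ N(0, 0.3), p ~ Uniform(0, 1). Planted
genes: log2FC ~ N(±2, 0.5), p ~ Beta(0.5, 20). In the default
margin-clearing mode, planted effects are resampled until they clear the
selection thresholds with margin (|log2FC| ≥ 1.1, p < 0.045) and null genes
near the fold boundary are kept clear of the p threshold, so set recovery
is exact by design; with margins off, recovery is governed by the raw
distributions (about 0.5 null genes among 12,000 are expected to pass both
thresholds by chance). A configurable subset of spliced-affected genes is
also planted in the unspliced table to exercise the control subtraction.

*Profile matrices.* Each cell is backed by three simulated log-scale
replicates (sd 0.1 natural log); the displayed fold change is the
exponentiated mean difference vs the matching control, and the significance
flag is a Student's t-test of those replicates — so null cells flag at the
test's ~5% false-positive rate rather than at an arbitrary rate. The three
approaches use independent control replicate sets, matching the design of
three independent experiments; within an arm the two comparisons share the
silencing replicates, as on a real plate. Planted repressed genes (silencing
ratio 2.0, induction ratio 0.5) are recovered essentially completely, and
the expected fraction of null genes classified is ≈ 1.6% (measured 1.45% on
a 10,000-null run), below the 2% design bound.

What the generators do **not** emulate: GC bias and nucleosome structure,
read-level RNA-seq noise and its dispersion structure, plate/batch effects,
amplification-efficiency variation, and cross-gene expression correlation.
Passing recovery tests therefore demonstrates correctness of the pipeline's
arithmetic and set logic under the stated noise models, not performance on
real sequencing or qPCR data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path with exact oracles: 200-gene genomes with 1 kb flanks for
planted-motif recovery, 100 random 2 kb sequences for brute-force scan
agreement, 500 genes for ΔΔCt recovery, 2,000 null genes for the t-test
size check (binomial band [4.0%, 6.1%] at α = 0.05), and the full
12,000-gene DE screen. Fold changes are positive by construction; all
rate comparisons use tolerances stated alongside the check. Degenerate
inputs (empty tables, single genes, zero-variance profiles, infeasible
motif packings) raise typed errors rather than returning silent defaults.

## Known limitations

Motif counts from direct scanning are assembly- and track-dependent and
not comparable across databases. The classification rule's exact published
counterpart is under-specified (membership rules reproducing any specific
published set size are not asserted). The 2^−ΔΔCt model assumes perfect
amplification efficiency. Cuffdiff/DESeq-style modelling, GO enrichment and
any protein-level readouts are out of scope; the pipeline consumes their
tabular outputs.
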