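# Methods

## Coordinate and overlap conventions

Every interval is 0-based half-open, the convention of all BED-family
formats the package reads and writes. Overlap means ≥ 1 shared base;
bookended intervals do not overlap. Distances between non-overlapping
features are edge-to-edge gaps with strand ignored — none of the windowing
operations here is strand-dependent. Ties in neighbor queries are broken
lexicographically by gene id so output order is deterministic.

One consequence worth noting: a bookended gene has gap 0 without sharing a
base, so a 0-bp window query returns overlapping *and* bookended genes.
The alternative (gap + 1 for non-overlapping features, as some interval
tools report) was rejected to keep "within *w* kb" meaning gap ≤ *w*.

## Super-enhancer calling

The caller follows the rank-ordering approach for super-enhancer
identification:

1. **TSS exclusion.** H3K27ac marks active promoters as well as enhancers,
   so peaks *fully contained* within ± `tss_exclusion` bp (default 250) of
   an annotated TSS are removed. Partial overlap retains the peak, and an
   exclusion of 0 disables the filter entirely rather than testing
   containment in a single base.
2. **Stitching.** Remaining peaks within `stitch_distance` bp (default
   12,500) on the same chromosome are merged transitively; the stitched
   region's signal is the sum of constituent signals.
3. **Ranking and thresholding.** Regions are ranked by signal (ties broken
   by genomic position for a stable permutation). Both the rank index and
   the signal are min–max scaled to [0, 1]; slopes are two-point finite
   differences (`numpy.gradient`, central differences with one-sided
   endpoints); the cutoff is the signal at the first index, scanning from
   the low-signal end, whose slope exceeds 1. Regions strictly above the
   cutoff are super. Because min–max scaling is invariant to positive
   scaling of the signal, uniformly rescaling all signals never changes the
   calls. Degenerate inputs are explicit: fewer than two regions is an
   error at the cutoff level (the pipeline returns a lone region as typical
   with a warning), and an all-equal curve returns the maximum, so nothing
   is called super.

Signal is depth-normalized: region signal = (per-base track sum over the
region) × (10⁶ / library size), i.e. per-million units. Fold changes
between stages over the merged SE universe use a pseudocount of one
normalized-signal unit in numerator and denominator so stages with zero
signal produce finite ratios.

## Progression dynamics

"Present at a stage" means ≥ 1 bp overlap with any SE of that stage —
stitched boundaries shift between samples, so coordinate identity is never
required, and presence is boolean (overlapping two SEs of a stage counts
once). Acquisition at stage *k* requires no overlap with any earlier
stage's SEs and is reported with stage-*k* coordinates; loss is always
measured against the baseline stage; an acquired region is retained iff it
is present at every later stage through the end of the series (a region
acquired at the final stage is trivially retained). Cohort representation
counts patients with ≥ 1 overlapping SE and is monotone under region
enlargement.

## The prioritization funnel

Fold-change cutoffs are applied as |log₂ FC| ≥ log₂ cutoff with the
boundary inclusive; nothing in the procedure motivates strict inequality,
and inclusivity makes the "fold change exactly 2" case unambiguous. Fold
changes are pseudocount-stabilized, log₂((b + ε)/(a + ε)) with ε = 1
intensity unit — appropriate for array-scale intensities in the hundreds,
and configurable. The first→last stage contrast is used for the
differential filter; neighbor mRNAs must pass the same cutoff over the same
contrast.

The 50 kb proximity window is measured between gene bodies (nearest
edges), not TSS-to-TSS, matching the convention used for SE
neighborhoods. Neighbor search defaults to mRNA biotypes only; a
`neighbor_biotypes` option admits miRNA or other biotypes where a
locus-specific analysis calls for it.

External-atlas membership is injected as a plain id list and patient
expression as a plain feature × patient matrix; the package never fetches
either. Pairs whose members are absent from the patient matrix cannot be
correlation-tested and fall through — together with pairs that fail
|r| ≥ 0.5 — to the trend-concordance branch, where the mRNA's
normal→tumor sign in patients must equal its first→last sign in the
series (sign agreement only; no effect-size threshold is imposed because
none is defined for this step, and zero never matches). Extreme responders
(|log₂ FC| ≥ log₂ 10 and annotated) are collected independently of
pairing. The shortlist is the union of the correlation, trend, and extreme
branches, so a feature is never double-counted.

## qPCR quantification

ΔCt = Ct(target) − mean Ct(references), with multiple reference genes
combined by arithmetic mean on the Ct scale — equivalent to a geometric
mean of relative quantities. ΔΔCt contrasts condition against control and
fold change = 2^(−ΔΔCt); the control against itself is exactly 1, and any
global Ct shift cancels. Per-replicate fold changes (each replicate's ΔCt
against the control mean) are returned for dispersion estimates. Any
constituent Ct at or above 40 cycles flags the result low-confidence.

Localization compares relative abundance 2^(−Ct) between nuclear and
cytoplasmic fractions of the same transcript; the nuclear share is
1/(1 + 2^(Ct_nuc − Ct_cyt)), so shares across the two fractions sum to 1.
Calls use share ≥ 0.6 → nuclear, ≤ 0.4 → cytoplasmic, else undetermined;
the thresholds are configurable because "primarily nuclear" has no
canonical numeric definition. Transcripts at the 40-cycle floor in both
fractions are undetermined outright. Group tests delegate to scipy:
`f_oneway` plus `tukey_hsd` (studentized-range adjustment) for series-wide
comparisons, classical equal-variance `ttest_ind` / `ttest_rel` for
two-group contrasts, with explicit errors on zero-variance input.

## Synthetic data

The generators are pure functions of a config whose seed fixes every draw;
repeated calls are byte-identical. Defaults describe the study conditions
the package targets: a 4-stage progression series, 25 planted SE clusters
among 400 decoy peaks on a 2 × 20 Mb genome, 8 planted cis pairs and 4
extreme responders among ~200 decoy lncRNAs, 50 patients, qPCR noise of
0.05 cycles.

*ChIP-seq series.* Features occupy 40 kb slots so nothing stitches across
features. Planted clusters are 3–8 peaks (300–900 bp, gaps 100–500 bp,
total span < 12.5 kb) with per-peak signal 20 + Exp(5) — well above 10× the
decoy median — active from their acquisition stage until their loss stage;
decoys are single Exp(1)-signal peaks present at every stage. The schedule
cycles through baseline-stable, acquired-retained, baseline-lost and
transient patterns so every dynamics class occurs. Tracks are emitted at
50 bp bin resolution with per-base values chosen so that quantifying a peak
against its track returns exactly the planted signal.

*Expression funnel.* Stage values follow monotone geometric ramps with ±3%
jitter. Planted cis pairs sit < 50 kb apart, change ≥ 2-fold, are
annotated, and share a latent patient factor with loading √r (r = 0.9
target), so their empirical correlation clears 0.5 with large margin at
n = 50; a quarter of the planted pairs are deliberately absent from the
patient matrix and concordant in trend, exercising the fall-through
branch. Decoys rotate through the funnel's failure modes: co-located but
uncorrelated *and* trend-discordant, co-located but unannotated, correlated
but distal, flat, and changing with only a flat neighbor. Extreme
responders are planted at high baselines so the pseudocount cannot pull a
16-fold change under the ±10 cutoff.

*qPCR.* A planted fold change *f* is a target Ct shift of −log₂ *f* in the
tumor condition; a planted nuclear share *s* is a fraction Ct difference of
−log₂(s/(1−s)); Gaussian noise of `noise_sd` cycles is added everywhere, and
the noiseless limit recovers truth exactly.

What the generators deliberately do not model: read-level artifacts
(mappability, GC, fragment-length effects, duplicate reads), input-chromatin
background, array normalization effects, patient-subtype structure, or qPCR
amplification-efficiency deviations from 2. Recovery tests passing on these
fixtures therefore validate the set logic, thresholds and estimators —
not robustness to those upstream artifacts.

## Problem sizes

The test suite and the acceptance script run on the default synthetic
conditions above (425 peak features × 4 stages, ~260 expression features ×
50 patients, 5 qPCR targets × 3 replicates) plus oracle sweeps of ~1,000
random instances per interval operation and 1,000 random rank curves for
the threshold oracle; the whole suite completes in a few seconds.

## Known limitations

- The hockey-stick threshold is sensitive to the extreme tail of the decoy
  signal distribution; an isolated strong typical enhancer can be called
  super (visible as one decoy above the cutoff at the baseline stage of the
  worked example). This mirrors the behavior of rank-based thresholding
  generally.
- No input-control subtraction or mappability correction is applied; the
  caller trusts the depth-normalized signal it is given.
- The unpaired t test is the classical equal-variance form, not Welch.
- Correlation filtering assumes patient expression rows are comparable
  across features (any monotone per-feature normalization is acceptable
  since Pearson r is location/scale invariant per feature).
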