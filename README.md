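# seprog

Super-enhancer calling, progression dynamics, and prioritization of
potentially *cis*-acting super-enhancer lncRNAs from H3K27ac ChIP-seq
peak/signal data.

## The problem

Super-enhancers (SEs) are clusters of enhancers whose aggregate
activating-histone signal (H3K27ac) places them far above typical enhancers
on a rank–signal curve. In progression models of breast cancer — a normal
mammary epithelial baseline followed by successively more malignant stages
(atypical hyperplasia, ductal carcinoma in situ, invasive carcinoma) — SEs
are gained and lost stage by stage, and the lncRNAs transcribed from SE
regions (SE-lncRNAs) are candidate local (*cis*) regulators of their
neighboring genes. `seprog` implements the computational chain that takes
per-stage enhancer peaks with signal and asks:

1. **Which stitched enhancer regions are super-enhancers?** Peaks within a
   stitch distance *d* (default 12,500 bp) are merged; peaks fully contained
   within ±250 bp of an annotated TSS are removed first; stitched regions
   are ranked by total depth-normalized signal *S*. After min–max scaling
   rank and signal to [0, 1], the super/typical threshold is the signal at
   the first point (scanning from the low end) where the slope of the scaled
   curve exceeds 1 — the tangent point of the "hockey stick". Regions with
   *S* strictly above the threshold are super.
2. **Which SEs are acquired, lost, or retained across the series?** An SE is
   *acquired* at stage *k* if it overlaps (≥ 1 bp) no SE of any earlier
   stage, *lost* at stage *k* if a baseline SE overlaps nothing at *k*, and
   *retained* if, once acquired, it stays present through the final stage.
   A region's representation in a patient cohort is the number of patients
   with ≥ 1 overlapping SE.
3. **Which SE-lncRNAs are plausibly cis-acting?** A filtering funnel:
   |log₂ FC| ≥ 1 between first and last stage → a neighboring mRNA within
   50 kb (gene body to gene body) passing the same cutoff → lncRNA annotated
   in an external patient atlas (id list supplied as input) → Pearson
   |r| ≥ 0.5 between lncRNA and mRNA across patients, with pairs that fail
   or cannot be tested re-examined for sign-concordant normal→tumor trends;
   extreme responders (|log₂ FC| ≥ log₂ 10, annotated) are kept on a
   separate branch. The shortlist is the union.
4. **Do candidate transcripts behave as expected in the wet lab?** ΔΔCt
   qPCR fold changes (fold = 2^(−ΔΔCt), references averaged on the Ct
   scale), nuclear/cytoplasmic localization calls from fraction Cts, and the
   standard group tests (one-way ANOVA with Tukey HSD, Student t tests).

All coordinates are 0-based half-open (BED convention). A seeded synthetic
data module generates every input with planted ground truth, so each stage
of the pipeline is verified by recovery tests.

## Worked example

```python
from seprog.synthdata import SynthConfig, gen_chipseq_series
from seprog.se_calling import call_super_enhancers, super_regions
from seprog.se_dynamics import StageSECollection, classify_dynamics

chip = gen_chipseq_series(SynthConfig(seed=1))
series = []
for i, stage in enumerate(chip.stage_names):
    calls = call_super_enhancers(chip.peaks[stage], chip.annotation)
    n_super = sum(c.is_super for c in calls)
    print(f"{stage}: {len(calls)} stitched regions, {n_super} super-enhancers")
    series.append(StageSECollection(stage, i, super_regions(calls)))

dynamics = classify_dynamics(series)
print(dynamics.status.value_counts().to_string())
```

prints

```
normal: 413 stitched regions, 14 super-enhancers
atypia: 416 stitched regions, 18 super-enhancers
dcis: 416 stitched regions, 17 super-enhancers
idc: 413 stitched regions, 13 super-enhancers
status
lost        21
retained     9
acquired     6
```

The synthetic genome plants 25 SE clusters (each 3–8 strong peaks inside a
12.5 kb span) among 400 weak decoy peaks. At the baseline 13 planted
clusters are active and 14 regions are called super (one decoy rides above
the threshold); the dynamics table then recovers the planted schedule: 9
acquisitions that persist to the end (*retained*), 6 transient or
final-stage acquisition events labeled *acquired* at their stage, and 21
stage-wise losses of baseline clusters (a cluster lost at stage 1 is also
counted as lost at stages 2 and 3, mirroring per-stage loss lists).

The same fixtures drive the expression funnel and qPCR modules; see
`seprog synth --help`, `seprog call-se --help`, `seprog cascade --help` and
`seprog qpcr --help` for the file-based command-line interface.

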