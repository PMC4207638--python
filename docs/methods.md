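# Methods

## Scope and model

`equicnv` reimplements a whole-genome aCGH CNV-discovery analysis for the
horse as a deterministic, fully tested pipeline. The observable is the
per-probe `log2(sample/reference)` ratio of a two-channel hybridization.
The generative model used throughout (simulator, caller, evaluation) is

    y_p = μ(p) + ε_p,   ε_p ~ N(0, σ²) i.i.d.,

where `μ(p) = log2(c/2)` for a probe inside a planted segment at copy
number `c` and 0 elsewhere. Heterozygous losses, single- and double-copy
gains therefore sit at −1, +0.585 and +1. A homozygous loss has no finite
log-ratio; it is represented by a floor of −4.0, between the deepest
segment means seen on real arrays (−2 to −3.5) and the dynamic range of
the assay. The reference channel is treated as copy-neutral; an optional
reference truth set can be supplied to `simulate_hybridization` callers by
planting inverse variants, but no assumption is made about reference
CNV content in any reported statistic.

## Simulator

Defaults are the study conditions of the cohort the pipeline models:

| parameter | default | why |
|---|---|---|
| probe spacing | 7.5 kb genome-wide, 4 kb in terminal 1 Mb sub-telomeres, 20 kb on chrY | the tiling design's median spacings |
| probe length | 60 bp | 60-mer oligo design |
| spacing jitter | ±20% uniform per step | breaks grid artifacts; keeps median gap within the design spec |
| CNVs per sample | Poisson(26.4) | observed mean calls per individual |
| CNV size | log-uniform 1 kb – 2.5 Mb | observed size range |
| loss fraction | 0.72 | 19.1 losses of 26.4 calls per individual |
| homozygous fraction | 0.017 | 16 of ~950 calls |
| shared fraction | 0.30 | order of the shared-CNVR fraction after consolidation |
| breed-restricted fraction | 0.01 | 2 of 258 CNVRs were breed-specific |
| noise sd | blood 0.14, hair 0.41, fibroblast 0.14 | observed DLRSD by tissue |

Placement is length-weighted across chromosomes (chrY excluded — no Y
CNVRs were observed and Y probes carry a 0 baseline), with rejection
sampling so one sample's truth CNVs never overlap; this keeps recall
scoring unambiguous. Shared events are copied into 1–2 extra random
samples, breed-restricted events only into breed-mates. Reproducibility:
`SeedSequence(seed)` spawns one child for truth planting and one per
sample, so any sample regenerates in isolation.

What the simulator does **not** model: GC/dye bias, spatial and wave
artifacts, probe-specific response, partial-overlap signal dilution at
segment boundaries (a probe overlapping a breakpoint takes the full
shift), and sequence-aware probe placement. Passing tests therefore
demonstrate correctness of the calling/merging/statistics machinery under
the stated noise model, not robustness to real-array artifacts.

## QC

DLRSD is the sd of consecutive same-chromosome probe differences divided
by √2; under the i.i.d. model it is an unbiased estimator of σ, which the
calibration tests verify to within 5% at ≥50k probes for σ ∈ {0.14, 0.41}.
The plain sample sd is the default; an IQR/1.349 robust variant is
available (`robust=True`) for profiles with heavy CNV load, since real
vendor implementations are believed to use a robust spread. Missing probes
are dropped before pairing; pairs never span chromosome boundaries.
Quality bands: <0.2 excellent, 0.2–0.3 good, >0.3 poor. The platform FDR
is 100 × (calls in a self-to-self hybridization) / (all calls across
experiments).

## Calling

One call per maximal run of ≥`min_probes` (default 5) consecutive probes
all strictly beyond ±`log2_threshold` (default 0.5) with a common sign;
call coordinates are the first probe's start through the last probe's end;
`mean_log2` is the run mean; runs never cross chromosomes; missing probes
are removed before adjacency. This per-probe exceedance rule is a
deliberate, deterministic divergence from the proprietary ADM-2 interval
score that produced the original calls — only the threshold-over-5-probes
contract is public, and the strict reading is exactly testable against a
brute-force run enumeration. Consequences worth knowing:

- it is conservative: one interior sub-threshold probe splits or destroys
  a run, so single-copy gains (+0.585, only ~0.6σ above threshold at
  blood noise) fragment into several calls, and per-sample call counts on
  simulated data run higher than segment counts;
- ties at exactly ±0.5 never call (strict inequality);
- at σ = 0.14 the per-probe false-exceedance rate is ~3.6×10⁻⁴, so five
  consecutive same-sign exceedances are vanishingly rare: 400k-probe null
  genomes are call-free in ≥95% of seeds.

Zygosity is flagged from the run mean (not single probes): putatively
homozygous iff |mean| > 2.0. Whether the original software's "5
neighboring probes" is per-probe or window-mean is not recoverable;
`min_probes`/threshold are configurable.

## CNVR consolidation and classification

Two calls merge iff they overlap by ≥1 base or the end coordinate of one
equals the start of the next (1-based inclusive: a shared boundary base).
Contiguous-but-not-touching (end+1 == start) does not merge. Merging is
transitive single-linkage, which can chain long composite regions —
consistent with multi-megabase CNVRs in real maps. Lengths are
end − start + 1. State: gain/loss if all member calls agree, complex
otherwise. Sharing: ≥2 distinct individuals. Breed-specific: ≥2 carriers,
one breed, no other-breed carriers. A brute-force union-find merge is the
test oracle; idempotence, order-invariance and base-coverage conservation
are property-tested.

## Recovery scoring

A planted CNV is *detectable* if it covers ≥5 probes and |expected log2|
≥ 1 (single-copy gains are deliberately excluded: at blood noise the rule
detects but fragments them, and their per-probe exceedance is not
near-certain). It is *recovered* when the union of the sample's
same-direction calls overlapping it has both boundaries within one
(jittered) probe spacing of the truth. The union is used because interior
fragmentation of long segments changes segmentation, not detection; the
boundary requirement still fails if either outermost probe run is lost.
At σ = 0.14 recall on detectable truth is ≥99% in a 10-sample genome-wide
cohort.

## Annotation and statistics

Genic = any-overlap (≥1 bp) with a gene interval — no minimum-overlap
fraction is imposed; alternative gene sets change the genic/intergenic
split and both modes are supported by swapping the input set.
Sub-telomeric = overlap with the terminal 1 Mb of either chromosome end
(single-end mode available for acrocentric karyotypes). Enrichment =
100 × CNVR bp / chromosome bp, reported to 2 decimals with the unrounded
value retained; genome enrichment uses the total assembly length including
chrUn. Call-count means are reported to 1 decimal. The blood-vs-hair
comparison is an equal-variance two-sample Student's t (two-sided);
fibroblast samples form a third class and are excluded.

## Cross-study integration

Records are normalized to 1-based inclusive coordinates with a per-file
convention declaration (published CNV tables mix BED and 1-based
conventions); out-of-bounds records are clipped with a warning. Merging is
purely positional (state kept as metadata, never blocking a merge) under
the same relation as consolidation. A study counts once per composite
region regardless of its record count; shared = ≥2 contributing studies.

## Numerical and engineering choices

- Internal coordinates are 1-based inclusive everywhere; BED conversion
  happens only at file boundaries and round-trips losslessly.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed; pipeline outputs are byte-identical across runs
  (fixed float formats, no timestamps in the run log).
- Degenerate inputs: chromosomes shorter than one probe spacing get zero
  probes (warning); truth CNVs covering zero probes are kept in the truth
  set but flagged undetectable (warning); empty profiles yield empty call
  sets; empty CNVR sets yield zero enrichment rows.
- Problem sizes in the shipped analyses: genome-wide simulations use the
  full 2.48 Gb build with ~339k probes and a 10-sample cohort, which keeps
  each analysis script and the acceptance run in the seconds-to-a-minute
  range while exercising every stage at realistic scale.

## Known limitations

Published headline counts that depend on the raw hybridizations (the
258-CNVR map itself, the 950-call tally, the 1.55% platform FDR, the
1476/301 composite dataset) cannot be reproduced without the external raw
data and the five prior studies' supplementary files; the package instead
recomputes every summary statistic derivable from the shipped tables and
validates the machinery by simulation at matched conditions. The caller is
not ADM-2; on real data it will call fewer, cleaner segments than a
score-based method and will fragment long moderate-amplitude events.
Allele-aware genotyping is out of scope — aCGH cannot distinguish allelic
configurations, which is why homozygosity flags are tentative.
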