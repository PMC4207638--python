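# equicnv

Copy-number variant (CNV) discovery from whole-genome array-CGH data in the
horse, built as a fully simulatable analysis pipeline. It is aimed at
researchers working with two-channel tiling-array comparative genomic
hybridization (aCGH) who need a transparent, testable reimplementation of
the classic discovery workflow: hybridization quality control, per-sample
CNV calling, consolidation of calls into copy-number variable regions
(CNVRs) across a cohort, annotation and enrichment statistics, and
positional integration of CNVR maps across studies.

## The method

An aCGH experiment reports, for each of ~400,000 tiled 60-mer probes, the
ratio `log2(sample/reference)` of competitive hybridization intensities.
Under copy-neutrality the expected value is 0; a segment at copy number *c*
against a diploid reference shifts it to `log2(c/2)` (−1 for a heterozygous
loss, +0.585 for a single-copy gain, +1 for a double gain; a homozygous
loss is unboundedly negative and in practice floors around −2 to −4).

The pipeline's core pieces:

- **QC — DLRSD.** The derivative log ratio standard deviation is the
  standard deviation of consecutive-probe log2 differences divided by √2,
  so it estimates the per-probe noise sd of a hybridization. Bands:
  `< 0.2` excellent, `0.2–0.3` good, `> 0.3` poor. Blood DNA typically
  hybridizes at ~0.14, hair DNA at ~0.41.
- **Calling.** A CNV is a maximal run of ≥ 5 consecutive probes whose
  values all exceed `+0.5` (gain) or fall below `−0.5` (loss). Run means
  beyond ±2.0 flag putative homozygosity. With 7.5 kb median probe
  spacing this detects variants from roughly 30 kb.
- **CNVR consolidation.** Calls from all samples merge when they overlap
  by ≥ 1 base or share a boundary coordinate, transitively. CNVRs are
  classified gain/loss/complex (complex = both directions among member
  calls), shared (≥ 2 individuals) vs private, and breed-specific
  (≥ 2 carriers, all of one breed, no carriers of any other breed).
- **Statistics.** Chromosome enrichment = 100 × (total CNVR length on the
  chromosome) / (chromosome length); cohort summaries of per-individual
  call counts and CNVR sizes; equal-variance Student's t for blood vs hair
  call counts.
- **Cross-study integration.** CNVR sets from multiple studies, after
  coordinate normalization, merge under the same positional relation into
  a composite dataset; composite regions reported by ≥ 2 studies are
  *shared*, the rest *novel*.
- **Simulation.** Because the raw hybridizations are external, the package
  ships a generator that emulates the platform: EquCab2 chromosome sizes,
  a jittered tiling design (7.5 kb genome-wide, 4 kb in the terminal 1 Mb
  sub-telomeres, 20 kb on chrY), planted CNV truth sets with shared and
  breed-restricted variants, and Gaussian per-probe noise at tissue-specific
  levels. Every downstream stage is validated against this ground truth.

The published cohort's summary tables (36 discovery horses; 258 CNVRs) are
shipped in `equicnv.published`, so the headline cohort statistics are
recomputable without the raw arrays.

## Worked example

```python
import equicnv as e

genome = e.build_genome(preset="equcab2_table2")      # 33 chromosomes, 2.48 Gb
probes = e.design_probe_map(genome, seed=1)           # ~339k tiled probes

samples = [e.SampleInfo(f"horse{i}", breed=f"breed{i%5}", tissue="blood")
           for i in range(10)]
hybs, truth = e.simulate_cohort(genome, probes, samples, e.SimParams(), seed=5)

print(round(e.compute_dlrsd(hybs[0], probes), 3))     # 0.14  (blood-like noise)

calls = [c for h in hybs for c in e.call_cnvs(h, probes)]
cnvrs = e.consolidate_calls(calls, genome=genome)
print(len(calls), len(cnvrs))                         # 475 345

summary = e.cohort_summary(calls, cnvrs, genome)
print(round(summary.genome_enrichment_percent, 2))    # 3.01
```

The DLRSD of 0.14 recovers the injected blood-like noise; 475 strict-rule
calls across 10 samples consolidate into 345 CNVRs covering 3.01% of the
simulated genome (planted density is higher than the real cohort's 1.15%
because every sample here is a CNV carrier against a clean reference).

The same stages are scriptable from the shell (`equicnv simulate / qc /
call / merge / annotate / stats / integrate / run`), and the numbered
drivers under `analysis/` walk through the full study: published-table
summaries, cohort simulation and QC, calling and consolidation with
recovery scoring, enrichment statistics, and cross-study integration.

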