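# epistate

Integrative analysis of epigenetic reprogramming in a two-condition cell
model (e.g. epithelial cells before and after an EMT-inducing
perturbation), combining three genome-wide layers:

1. **DNA methylation by DREAM** — digital restriction enzyme analysis of
   methylation.  Sequential digestion with the isoschizomers SmaI
   (blocked by CpG methylation, blunt cut `CCC^GGG`) and XmaI
   (methylation-insensitive, `C^CCGGG` with 5′ overhang) stamps each
   sequenced fragment end with an allele-specific signature: reads from
   methylated alleles begin `CCGGG`, reads from unmethylated alleles
   begin `GGG`.  Per CCCGGG site, the methylation fraction is
   `m / (m + u)` from the two signature counts, at a default minimum of
   100 tags per sample.
2. **Promoter chromatin state from H3K4me3 / H3K27me3 ChIP-seq peaks** —
   a gene is marked when a peak overlaps `[TSS−1 kb, TSS+0.5 kb)`;
   states are K4, K27, BIVALENT (both) or NONE, with 4×4 switch matrices
   between conditions, bivalency statistics and merged peak footprints.
3. **Expression from RNA tag counts** — between-sample scaling by the
   mode of the per-gene log₂ count-ratio histogram (assumes most genes
   unchanged), fold-change categories (default "highly altered" =
   ≥ 9-fold), and coupling of expression change to chromatin-state
   switches and to promoter methylation.

The integration layer builds strand-aware TSS meta-profiles (k-neighbor
averaged), couples promoter methylation gain to H3K27me3 gain with a
seeded permutation test, and stratifies everything by partially
methylated domains (PMDs, ~40% of the genome).

A first-class synthetic-data generator (`epistate.simulate`) emits
genomes, annotations, DREAM tags, peak sets and expression counts with
machine-readable ground truth, so every estimator in the package is
testable by parameter recovery.

## Differential-methylation rules

Promoter scope (promoter = mean methylation over CpG sites in
`[TSS−1 kb, TSS+1 kb)`):

- GAIN: baseline ≤ 1 % and comparison > 2 %
- LOSS: baseline > 1 % and comparison ≤ 1 %

Site scope (for the heavily methylated genome bulk):

- hypermethylation: baseline ≤ 10 % and gain ≥ 20 points
- hypomethylation: baseline ≥ 70 % and loss ≥ 20 points

The false-discovery rate of a call rule is estimated from a *null pair*
of biologically equivalent samples: every call between them is false,
and FDR = calls / eligible units.

## Worked example

```python
from epistate import chromatin, dream
from epistate.simulate import SimulationConfig, simulate_all

ds = simulate_all(SimulationConfig(), seed=20230)   # 2 x 5 Mb, 2,000 genes
ca, cb = ds.config.conditions                       # epithelial, mesenchymal

filt = dream.filter_by_coverage(ds.dream_counts, 100)
prom, _ = dream.aggregate_region_methylation(filt.sites, ds.genes, "promoter")
prom = prom.set_index("gene_id")
calls = dream.call_promoter_change(prom[ca], prom[cb])
print(calls.value_counts().to_dict())

k4 = chromatin.assign_promoter_marks(ds.genes, ds.peaks[("H3K4me3", ca)])
k27 = chromatin.assign_promoter_marks(ds.genes, ds.peaks[("H3K27me3", ca)])
states, _ = chromatin.classify_states(k4, k27)
print(states["state"].value_counts().to_dict())
```

prints

```
{'NONE': 1881, 'GAIN': 90, 'LOSS': 29}
{'K4': 1073, 'K27': 455, 'NONE': 416, 'BIVALENT': 56}
```

i.e. all 90 planted promoter gains are recovered at coverage ~200 (the
29 LOSS calls are sampling-noise artifacts of near-boundary promoters at
the 1 % threshold — exactly the error mode the null-pair FDR estimate
quantifies), and the promoter-state census matches the generator's
planted state fractions (55 % K4, 22 % K27, 3 % bivalent).

The same pipeline is scriptable from the shell via the `epistate`
command (`epistate simulate all`, `epistate dream aggregate`,
`epistate chromstate classify`, `epistate expr normalize`, …); every
output is a TSV with a `#`-commented provenance header.

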