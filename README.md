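# bsinc

Absolute quantitation of microbial genomes from multiplexed Nanopore-style
metagenomic sequencing, using a **barcoded spike-in calibration** strategy
with dynamic limits of detection and quantitation.

## Who this is for

Environmental microbiologists and water-sector practitioners who co-sequence
a DNA mock-community standard of known composition (the *spike-in*) alongside
their samples in one multiplexed long-read run, and want genome copy numbers
per library — not just relative abundances — for the taxa in their samples,
including taxa represented only by draft genomes or MAGs.

## The method

Spike-in standard and samples are barcoded separately, pooled, and sequenced
together. For each barcode *i* and genome *g* the package computes, from
primary read-to-genome alignments:

- mapped bases `M_g` (sum of aligned target spans) and covered bases `C_g`
  (interval-union size), with coverage fraction `f_g = C_g / L_g`;
- the **barcode effect factor** `BEF_i = B_i / (κ · m_i)`, the ratio of the
  barcode's observed bases `B_i` to its theoretical yield from `m_i` ng of
  input DNA (`κ` in bp/ng); this removes barcode ligation-efficiency batch
  effects, and final estimates are provably invariant to `κ`;
- the **observed genome copy number** `N_g = (M_g / BEF_i) / C_g` — dividing
  by *covered* rather than total genome length makes the statistic usable
  with incomplete assemblies;
- dynamic limits: a genome is **detected** when `f_g > 10%` (LOD) and
  **quantifiable** when the coefficient of variation of `N_g` across
  replicate barcodes is ≤ 10% (LOQ);
- an ordinary least-squares calibration over retained spike-in genomes,
  `log10(theoretical copies) = a + b · log10(N_g)`, applied to the sample
  genomes' observed copy numbers to give absolute estimates.

A first-class synthetic-data generator simulates the whole experiment —
genomes, log-distributed communities, per-barcode throughput differences,
lognormal read lengths, extraction bias — together with truth alignments,
so every stage is testable without sequencing data.

## Worked example

Simulate a 3+3-barcode run (three spike-in replicates, three sample
replicates) and run the analysis in memory:

```python
import numpy as np
from bsinc import (BarcodeSpec, RunSpec, TaxonSpec, CommunitySpec,
                   simulate_experiment, analyze_experiment)

spike  = CommunitySpec(taxa=[TaxonSpec(f"spk{i}", 5000, c)
                             for i, c in enumerate(np.logspace(2, 5, 8))],
                       distribution="log_distributed")
sample = CommunitySpec(taxa=[TaxonSpec(f"smp{i}", 5000, c)
                             for i, c in enumerate(np.logspace(3, 5, 5))])

def ng(c):  # input DNA mass implied by the community (1e6 bp per ng)
    return sum(t.theoretical_copies * t.genome_length for t in c.taxa) / 1e6

run = RunSpec(barcodes=[
    *(BarcodeSpec(f"bc0{i+1}", material="spike_in", input_dna_ng=ng(spike),
                  throughput_multiplier=m) for i, m in enumerate([0.6, 1.0, 1.8])),
    *(BarcodeSpec(f"bc0{i+4}", material="sample", input_dna_ng=ng(sample),
                  throughput_multiplier=m) for i, m in enumerate([1.2, 0.8, 1.5])),
], read_length_mu=np.log(250), read_length_sigma=0.3, seed=7)

exp = simulate_experiment(spike, sample, run, 16_000_000)
analysis = analyze_experiment(exp)
m = analysis.model
print(f"calibration: slope={m.slope:.4f} intercept={m.intercept:.4f} "
      f"R2={m.r_squared:.4f} n={m.n_points}")
for g, r in sorted(analysis.results.items()):
    print(f"{g}: detected={r.detected} est={r.estimated_copies and round(r.estimated_copies)}"
          f" truth={round(exp.sample_truth[g])}")
```

Output:

```
calibration: slope=1.0053 intercept=-1.0297 R2=1.0000 n=7
smp0: detected=True est=1013 truth=1000
smp1: detected=True est=3062 truth=3162
smp2: detected=True est=9870 truth=10000
smp3: detected=True est=31693 truth=31623
smp4: detected=True est=100564 truth=100000
```

The fitted slope near 1 and intercept near −1 say the observed copy
numbers are proportional to the theoretical ones up to a constant (here the
arbitrary κ/mass scale, which the intercept absorbs); the sample estimates
recover the true copy numbers within sampling noise despite the three-fold
throughput differences between barcodes.

The same chain runs from files (`FASTQ` + `PAF`/`SAM` + manifest TSVs) via
the CLI: `bsinc simulate`, `bsinc calibrate`, `bsinc quantify`, and
`bsinc run --config run.yaml`.

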