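# Methods

## Model and assumptions

The package implements absolute quantitation by internal calibration. A DNA
standard of known composition (the spike-in) and the samples are barcoded
separately and sequenced in one multiplexed long-read run. For barcode *i*
with observed bases `B_i` and input DNA mass `m_i` (ng), the barcode effect
factor is

    BEF_i = B_i / (κ · m_i)

with `κ` a run-level theoretical yield constant in bp/ng. The observed copy
number of genome *g* under barcode *i* is

    N_{g,i} = (M_{g,i} / BEF_i) / C_{g,i}

where `M` is the sum of primary-alignment target spans (mapped bases) and
`C` the interval-union size of those spans (covered bases). Dividing by
covered rather than assembled genome length makes `N` well-defined for
draft genomes; when `C = 0` the quantity is *undefined* and the genome is
flagged "no coverage", never reported as zero copies.

Calibration is ordinary least squares in log10 space,

    log10(theoretical copies) = a + b · log10(N)

over the spike-in genomes that pass both dynamic limits: coverage fraction
strictly > 10% in every replicate barcode (LOD), and replicate coefficient
of variation ≤ 10% (LOQ, sample standard deviation with n−1 over the mean).
Sample genomes passing the same limits get estimates
`10^(a + b · log10(N̄))` from their mean observed copies across replicates.

Key modelling assumptions: (i) mapped bases scale linearly with the number
of genome copies in the library within a barcode; (ii) barcode-to-barcode
differences are multiplicative (ligation efficiency), hence removable by
BEF; (iii) biases that are *shared* between spike-in and sample material
(systematic, organism-independent) are absorbed by the regression, while
organism-specific extraction bias is explicitly *not* corrected — it is a
documented limitation of the approach.

## Interpretation conventions

Where the method leaves details open, the package fixes them as follows:

- **Threshold semantics.** The read filters remove reads *strictly below*
  Q7 / 200 bp, so boundary reads are kept. The LOD is strict
  (`fraction > 0.10`), the LOQ inclusive (`CV ≤ 0.10`).
- **Mean read quality** is the Phred score of the mean per-base error
  probability, the basecaller convention, not the arithmetic mean of Q.
- **Mapped bases** are target-interval spans of primary alignments:
  deletions inside the aligned span count, soft-clips do not, secondary
  alignments never count, supplementary alignments are excluded by default
  (`count_supplementary` includes them). Depth is defined as
  `mapped_bases / genome_length`.
- **Coordinates** are 0-based half-open throughout (PAF-native); SAM input
  is converted on parse; multi-contig genomes use concatenated contig
  coordinates in manifest order.
- **Regression orientation**: response = log10(theoretical), predictor =
  log10(observed), so applying the fitted line to a sample observation
  directly yields the calibrated estimate. The replicate observations are
  averaged before fitting (one point per genome); `replicate_mode="pooled"`
  fits per-barcode points instead.
- **Detection across replicates** defaults to all-replicates (conservative)
  and can be relaxed to any-replicate.
- **Subsampling** to a base target is read-granular: seeded shuffle, take
  reads until the cumulative bases reach the target, include the crossing
  read. It is applied per barcode.
- **Degenerate configurations.** If fewer than two spike-in genomes survive
  filtering while at least one is detected, calibration is refused
  ("calibration underdetermined", CLI exit code 3). If *no* spike-in genome
  is detectable at the configured LOD (e.g. LOD = 1.0), the pipeline
  degrades gracefully: it reports detection flags with an empty quantified
  set instead of aborting, since there is nothing a calibration could add.
- `κ` defaults to 1e7 bp/ng and is cosmetic: every estimate is invariant to
  it because the induced log-shift in all observed copy numbers is absorbed
  exactly by the calibration intercept. This invariance is asserted
  numerically (≤ 1e-9 relative) in the tests.

## Tunable parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `min_q` / `min_len` | 7 / 200 | Phred / bp | real-time read QC removals |
| `lod` | 0.10 | fraction | detection: coverage fraction strictly above |
| `loq_cv` | 0.10 | fraction | quantitation: replicate CV at most |
| `kappa` | 1e7 | bp/ng | theoretical yield constant (cosmetic) |
| `detection` | `all` | — | replicate detection rule (`all`/`any`) |
| `seed` | 42 | — | all subsampling / simulation randomness |

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
genome-copy abundances per community (log-distributed over ≥ 3 decades,
even, or custom), per-barcode throughput multipliers standing in for
ligation-efficiency batch effects, lognormal read lengths (default
μ = ln 3800, σ = 0.6, echoing a run N50 near 3.8 kb), uniform read start
positions with truncation at the genome end, optional per-taxon extraction
bias shared across barcodes, optional per-(barcode, taxon) lognormal
abundance noise, and i.i.d. nucleotide genomes at specified GC. Read
sampling weight is copies × genome length × bias, so longer genomes
contribute proportionally more bases per copy — precisely the bias the
covered-bases division corrects, which makes that correction testable.
Each read carries a full-span truth alignment, so the pipeline can be
exercised without an aligner; an aligner's PAF/SAM output drops in through
the same parsers.

What it does **not** emulate: realistic nanopore error profiles
(substitution-only errors at a uniform rate are available), chimeras,
mapping ambiguity between related genomes, barcode cross-talk, or
contamination. Passing tests therefore demonstrate the correctness of the
computational chain under its own model, not robustness to alignment or
chemistry artifacts in real data.

A consistency convention ties simulations to reality: each barcode's
`input_dna_ng` is set proportional to its community's total DNA mass
(Σ copies × genome length) through one shared mass scale (1e6 base units
per ng in the benchmarks), exactly as a fluorometer reading of the extract
would be. This is what makes spike-in and sample observed copy numbers
commensurable after BEF normalization; the shared scale, like κ, is
absorbed by the intercept.

## Benchmark study conditions and problem sizes

The canonical benchmarks (`bsinc.benchmarks`, re-run by
`scripts/acceptance.py`) use scaled-down problem sizes — 5–60 kb genomes,
≈250 bp mean reads (σ = 0.3 lognormal), per-barcode targets of 1–40 Mb —
chosen so each benchmark completes in seconds while per-genome read counts
stay large enough (tens to thousands) for replicate-CV statistics to be
meaningful:

- **Calibration recovery**: 8 spike-in genomes log-spaced over 4 decades
  (1e2–1e5 copies), 3 spike + 3 sample barcodes with throughput
  multipliers drawn uniformly from [0.5, 2], per-taxon multiplicative
  lognormal bias with σ = 0.1 (natural log) shared across replicates — a
  per-genome perturbation of the observed–theoretical relation, as in an
  extraction bias. The rarest genome sits near depth 2, so the LOQ may
  drop it; the recovery regression runs on the quantified sample genomes.
- **BEF necessity**: spike barcodes carry multipliers {0.5, 1, 2}; sample
  barcodes draw independently from the same set each seed; both arms
  (BEF on/off) analyze identical data with the CV gate off so they score
  the same genomes. The comparison is the across-seed mean |log10 error|;
  the per-seed win fraction is also reported (ties in throughput means can
  make single seeds a wash).
- **Dynamic LOD**: a 60 kb genome at 10 copies among four abundant 10 kb
  genomes lands at ≈5% coverage at the base effort and ≈18% at 4× effort;
  the large genome size keeps its read count high enough that the
  detection flip is stable across seeds.
- **Multi- vs single-taxon spike-in**: the single-taxon arm calibrates on
  the *rarest* spike-in member (depth ≈ 1.3, strongly mismatched to the
  sample's abundance range). At such depths the observed copy number is
  compressed toward 1 read depth — mapped/covered cannot fall below the
  per-base depth of an isolated read — so a single rare taxon yields a
  systematically biased correction factor, while the multi-taxon
  regression is anchored by well-covered members. Deviations are computed
  on absolute copies; relative abundances would cancel a slope-1 intercept
  error identically across taxa and hide exactly the failure being
  measured.

## Numerical choices

- Interval unions use a sort-and-sweep over half-open intervals, validated
  against a per-base boolean-array oracle by property test and benchmark.
- OLS is `scipy.stats.linregress`; R² is reported as NaN for two-point
  fits (it is vacuously 1 there and carries no information).
- CV uses the n−1 standard deviation (triplicates are the expected case);
  a CV over < 2 defined values is undefined, not zero.
- All randomness flows from explicit seeds; per-barcode generator streams
  are derived via CRC32 of the barcode name so adding a barcode does not
  reshuffle the others.

## Known limitations

Organism-specific extraction bias is not corrected, only absorbed insofar
as it is shared between spike-in and sample — with cell-based sample
material against a DNA-based standard this remains the dominant error
source. Quantitation of rare taxa demands disproportionate sequencing
effort (coverage fraction must clear the LOD). Mapped bases from
low-coverage genomes are depth-compressed (observed copies cannot drop
below ≈1), which biases calibration points near the LOD; the LOQ filter
removes most, but calibration standards should span the sample's abundance
range at adequate depth. Reference-database completeness bounds what can
be detected at all.
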