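"""Canonical simulation benchmarks for the quantitation workflow.

Each benchmark builds a fully specified mock run with
:mod:`bsinc.synthetic_data`, executes the analysis chain, and measures one
property of the method:

* :func:`spikein_recovery` — parameter recovery of the log-log calibration
  on a spike-in spanning four decades with per-barcode throughput
  differences and per-taxon lognormal bias;
* :func:`kappa_invariance` — final estimates do not depend on the yield
  constant ``kappa``;
* :func:`bef_necessity` — dropping BEF normalization under unequal barcode
  throughputs inflates the estimation error;
* :func:`lod_flip` — a genome near the detection limit flips from
  not-detected to detected as its sequencing effort grows, without
  disturbing other genomes' estimates;
* :func:`multi_vs_single_spikein` — a multi-taxon spike-in regression beats
  a single mismatched-abundance spike-in correction factor.

A consistency convention ties the simulations together: each barcode's
``input_dna_ng`` is proportional to its community's total DNA mass
(Σ copies × genome_length), exactly as a measured extract concentration
would be. This is what makes spike-in and sample observed copy numbers
commensurable after BEF normalization; the shared mass-per-ng constant, like
``kappa``, is absorbed by the calibration intercept.

Problem sizes (5 kb genomes, ≈260 bp mean reads, per-barcode targets in the
1–40 Mb range) are scaled-down study conditions chosen so each benchmark
runs in seconds while keeping per-genome read counts large enough for the
replicate-CV machinery to be meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .bsinc_quant import DEFAULT_KAPPA, apply_lod, estimate_copies
from .metrics import deviation_pct, single_spikein_calibration
from .pipeline import AnalysisResult, analyze_experiment
from .read_processing import MATERIAL_SAMPLE, MATERIAL_SPIKE_IN
from .reference_db import SpikeInTruth
from .synthetic_data import (
    BarcodeSpec,
    CommunitySpec,
    RunSpec,
    SimulatedExperiment,
    TaxonSpec,
    simulate_experiment,
)

#: arbitrary bp-per-ng mass scale tying input_dna_ng to community DNA mass
MASS_SCALE = 1e6
BENCH_READ_MU = math.log(250.0)
BENCH_READ_SIGMA = 0.3
_MEAN_READ = math.exp(BENCH_READ_MU + BENCH_READ_SIGMA**2 / 2)


def community_dna_mass(community: CommunitySpec) -> float:
    """Total DNA 'mass' of a community in base units (Σ copies × length)."""
    return sum(t.theoretical_copies * t.genome_length for t in community.taxa)


def _input_ng(community: CommunitySpec) -> float:
    return community_dna_mass(community) / MASS_SCALE


def _target_for_min_depth(community: CommunitySpec, min_depth: float) -> int:
    """Per-barcode base target putting the rarest taxon at ``min_depth``."""
    mass = community_dna_mass(community)
    min_weight = min(t.theoretical_copies * t.genome_length for t in community.taxa)
    min_length = min(
        t.genome_length for t in community.taxa
        if t.theoretical_copies * t.genome_length == min_weight
    )
    return int(round(min_depth * min_length * mass / min_weight))


def _barcodes(
    spike_multipliers: Sequence[float],
    sample_multipliers: Sequence[float],
    spike_ng: float,
    sample_ng: float,
) -> list[BarcodeSpec]:
    specs = []
    for i, mult in enumerate(spike_multipliers):
        specs.append(BarcodeSpec(
            barcode=f"bc{i + 1:02d}", material=MATERIAL_SPIKE_IN,
            replicate_group="spike", input_dna_ng=spike_ng,
            throughput_multiplier=float(mult),
        ))
    offset = len(spike_multipliers)
    for i, mult in enumerate(sample_multipliers):
        specs.append(BarcodeSpec(
            barcode=f"bc{offset + i + 1:02d}", material=MATERIAL_SAMPLE,
            replicate_group="sample", input_dna_ng=sample_ng,
            throughput_multiplier=float(mult),
        ))
    return specs


def _log_community(
    copies: Sequence[float], genome_length: int | Sequence[int], prefix: str
) -> CommunitySpec:
    lengths = (
        [genome_length] * len(copies) if isinstance(genome_length, int) else list(genome_length)
    )
    taxa = [
        TaxonSpec(f"{prefix}{i:02d}", int(lengths[i]), float(copies[i]))
        for i in range(len(copies))
    ]
    span = math.log10(max(copies) / min(copies))
    return CommunitySpec(taxa=taxa, distribution="log_distributed" if span >= 3 else "custom")


# ---------------------------------------------------------------------------
# calibration parameter recovery (and kappa invariance on the same run)
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    slope: float
    intercept: float
    r_squared: float
    n_genomes: int
    analysis: AnalysisResult
    experiment: SimulatedExperiment


def _recovery_experiment(seed: int, bias_sigma: float = 0.1) -> SimulatedExperiment:
    """3+3-barcode run, 8-genome spike-in over 4 decades, throughputs in [0.5, 2]."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 2])
    copies = np.logspace(2, 5, 8)
    spike = _log_community(copies, 5000, "spk")
    sample = _log_community(copies, 5000, "smp")
    bias = {
        t.genome_id: float(f)
        for community in (spike, sample)
        for t, f in zip(
            community.taxa,
            np.exp(rng.normal(0.0, bias_sigma, size=len(community.taxa))),
        )
    }
    multipliers = rng.uniform(0.5, 2.0, size=6)
    run = RunSpec(
        barcodes=_barcodes(multipliers[:3], multipliers[3:],
                           _input_ng(spike), _input_ng(sample)),
        read_length_mu=BENCH_READ_MU, read_length_sigma=BENCH_READ_SIGMA,
        extraction_bias=bias, seed=seed,
    )
    target = _target_for_min_depth(spike, 2.0)
    return simulate_experiment(spike, sample, run, target)


def spikein_recovery(seed: int = 1, kappa: float = DEFAULT_KAPPA) -> RecoveryResult:
    """Fit the calibration on noisy spike-ins and regress estimates on truth.

    Returns the slope/intercept/R² of log10(estimated) vs log10(theoretical)
    over the quantified sample genomes.
    """
    experiment = _recovery_experiment(seed)
    analysis = analyze_experiment(experiment, kappa=kappa)
    truth = experiment.sample_truth
    pairs = [
        (math.log10(truth[g]), math.log10(r.estimated_copies))
        for g, r in analysis.results.items()
        if r.estimated_copies is not None
    ]
    if len(pairs) < 3:
        raise RuntimeError(f"too few quantified genomes ({len(pairs)}) for recovery fit")
    x, y = zip(*pairs)
    fit = _scipy_stats.linregress(x, y)
    return RecoveryResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), n_genomes=len(pairs),
        analysis=analysis, experiment=experiment,
    )


def kappa_invariance(seed: int = 1, factor: float = 1e3) -> float:
    """Max relative change of any sample estimate when kappa is scaled."""
    experiment = _recovery_experiment(seed)
    base = analyze_experiment(experiment, kappa=DEFAULT_KAPPA)
    scaled = analyze_experiment(experiment, kappa=DEFAULT_KAPPA * factor)
    max_rel = 0.0
    for genome_id, result in base.results.items():
        other = scaled.results[genome_id].estimated_copies
        if result.estimated_copies is None or other is None:
            if (result.estimated_copies is None) != (other is None):
                raise RuntimeError(f"kappa scaling changed the retained set ({genome_id})")
            continue
        max_rel = max(max_rel, abs(other - result.estimated_copies) / result.estimated_copies)
    return max_rel


# ---------------------------------------------------------------------------
# BEF necessity
# ---------------------------------------------------------------------------

@dataclass
class BefComparison:
    errors_with_bef: list[float] = field(default_factory=list)
    errors_without_bef: list[float] = field(default_factory=list)

    @property
    def mean_with(self) -> float:
        return float(np.mean(self.errors_with_bef))

    @property
    def mean_without(self) -> float:
        return float(np.mean(self.errors_without_bef))

    @property
    def win_fraction(self) -> float:
        wins = [w < wo for w, wo in zip(self.errors_with_bef, self.errors_without_bef)]
        return float(np.mean(wins))


def _mean_abs_log10_error(analysis: AnalysisResult, truth: dict[str, float]) -> float:
    errors = [
        abs(math.log10(r.estimated_copies / truth[g]))
        for g, r in analysis.results.items()
        if r.estimated_copies is not None
    ]
    if not errors:
        raise RuntimeError("no quantified genomes to score")
    return float(np.mean(errors))


def bef_necessity(
    n_seeds: int = 20, base_seed: int = 1,
    multipliers: Sequence[float] = (0.5, 1.0, 2.0),
) -> BefComparison:
    """Mean |log10 error| of sample estimates with vs without BEF.

    Spike-in barcodes carry the throughput multipliers in order; sample
    barcodes get an independent random assignment from the same set each
    seed. Both arms analyze identical simulated data; the CV gate is off so
    both arms score the same genomes.
    """
    comparison = BefComparison()
    for k in range(n_seeds):
        seed = base_seed + 7919 * k
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 4])
        spike = _log_community(np.logspace(3, 5, 5), 5000, "spk")
        sample = _log_community(np.logspace(3.5, 5, 5), 5000, "smp")
        sample_mults = rng.choice(multipliers, size=3, replace=True)
        run = RunSpec(
            barcodes=_barcodes(multipliers, sample_mults,
                               _input_ng(spike), _input_ng(sample)),
            read_length_mu=BENCH_READ_MU, read_length_sigma=BENCH_READ_SIGMA,
            seed=seed,
        )
        target = _target_for_min_depth(spike, 5.0)
        experiment = simulate_experiment(spike, sample, run, target)
        with_bef = analyze_experiment(experiment, loq_cv=None, sample_loq_cv=None)
        without_bef = analyze_experiment(
            experiment, loq_cv=None, sample_loq_cv=None, apply_bef=False
        )
        comparison.errors_with_bef.append(
            _mean_abs_log10_error(with_bef, experiment.sample_truth)
        )
        comparison.errors_without_bef.append(
            _mean_abs_log10_error(without_bef, experiment.sample_truth)
        )
    return comparison


# ---------------------------------------------------------------------------
# dynamic LOD behaviour
# ---------------------------------------------------------------------------

@dataclass
class LodFlipResult:
    coverage_low: float
    coverage_high: float
    detected_low: bool
    detected_high: bool
    max_other_shift_log10: float
    rare_genome: str = "rare"


def lod_flip(seed: int = 1, effort_ratio: float = 4.0) -> LodFlipResult:
    """A near-LOD genome flips detection as sample effort grows.

    The rare genome sits at ≈5% coverage fraction at the base effort and
    ≈18% at ``effort_ratio``× the effort; the other genomes' estimates are
    compared across efforts (max |log10 shift|). Noise-free simulation; the
    CV gate is off so estimates exist at both efforts for the comparison.
    """
    spike = _log_community([2e3, 5e3, 1e4, 2e4, 5e4], 10_000, "spk")
    abundant = [2e3, 3e3, 5e3, 8e3]
    sample = CommunitySpec(taxa=(
        [TaxonSpec(f"smp{i:02d}", 10_000, c) for i, c in enumerate(abundant)]
        + [TaxonSpec("rare", 60_000, 10.0)]
    ))
    run = RunSpec(
        barcodes=_barcodes([1.0] * 3, [1.0] * 3, _input_ng(spike), _input_ng(sample)),
        read_length_mu=BENCH_READ_MU, read_length_sigma=BENCH_READ_SIGMA,
        seed=seed,
    )
    # base sample effort: rare genome at depth ≈ 0.048 → coverage ≈ 4.7%
    mass = community_dna_mass(sample)
    low_target = int(round(0.048 * mass / 10.0))
    spike_target = _target_for_min_depth(spike, 10.0)

    def run_at(sample_target: int):
        experiment = simulate_experiment(
            spike, sample, run,
            {MATERIAL_SPIKE_IN: spike_target, MATERIAL_SAMPLE: sample_target},
        )
        analysis = analyze_experiment(experiment, sample_loq_cv=None)
        coverages = []
        for barcode in experiment.barcodes(MATERIAL_SAMPLE):
            from .alignment_summary import summarize_coverage

            summaries = summarize_coverage(
                experiment.alignments[barcode], sample.lengths, barcode
            )
            coverages.append(summaries["rare"].coverage_fraction)
        return analysis, float(np.mean(coverages))

    low, cov_low = run_at(low_target)
    high, cov_high = run_at(int(round(low_target * effort_ratio)))
    shifts = []
    for genome_id in sample.truth:
        if genome_id == "rare":
            continue
        a = low.results[genome_id].estimated_copies
        b = high.results[genome_id].estimated_copies
        if a is None or b is None:
            raise RuntimeError(f"abundant genome {genome_id} lost its estimate")
        shifts.append(abs(math.log10(b / a)))
    return LodFlipResult(
        coverage_low=cov_low, coverage_high=cov_high,
        detected_low=low.results["rare"].detected,
        detected_high=high.results["rare"].detected,
        max_other_shift_log10=float(max(shifts)),
    )


# ---------------------------------------------------------------------------
# multi-taxon vs single-taxon spike-in
# ---------------------------------------------------------------------------

@dataclass
class SpikeinComparison:
    median_dev_multi: list[float] = field(default_factory=list)
    median_dev_single: list[float] = field(default_factory=list)

    @property
    def win_fraction(self) -> float:
        """Fraction of seeds where the multi-taxon calibration is ≤ the single."""
        wins = [m <= s for m, s in zip(self.median_dev_multi, self.median_dev_single)]
        return float(np.mean(wins))


def multi_vs_single_spikein(n_seeds: int = 40, base_seed: int = 1) -> SpikeinComparison:
    """Median |deviation %| of absolute copies: full regression vs one rare taxon.

    The single-taxon arm calibrates with the rarest spike-in member (strongly
    mismatched in abundance to the sample taxa, near its detection limit), as
    a single log-space correction factor. Deviations are on absolute copy
    numbers; relative abundances would cancel a slope-1 intercept error by
    construction.
    """
    comparison = SpikeinComparison()
    for k in range(n_seeds):
        seed = base_seed + 104729 * k
        spike = _log_community(np.logspace(2, 5, 6), 5000, "spk")
        sample = _log_community(np.logspace(4, 6, 6), 5000, "smp")
        run = RunSpec(
            barcodes=_barcodes([1.0] * 3, [1.0] * 3,
                               _input_ng(spike), _input_ng(sample)),
            read_length_mu=BENCH_READ_MU, read_length_sigma=BENCH_READ_SIGMA,
            abundance_noise_sigma=0.05, seed=seed,
        )
        targets = {
            MATERIAL_SPIKE_IN: _target_for_min_depth(spike, 1.3),
            MATERIAL_SAMPLE: _target_for_min_depth(sample, 2.5),
        }
        experiment = simulate_experiment(spike, sample, run, targets)
        multi = analyze_experiment(experiment, sample_loq_cv=None)

        # single-taxon arm: correction factor from the rarest spike-in member
        rare_id = min(experiment.spike_truth, key=experiment.spike_truth.get)
        observations = [
            analysis_obs[rare_id] for analysis_obs in multi.spike_observed.values()
        ]
        single_model = single_spikein_calibration(
            SpikeInTruth(rare_id, experiment.spike_truth[rare_id]), observations
        )
        truth = experiment.sample_truth
        est_multi: dict[str, float] = {}
        est_single: dict[str, float] = {}
        for genome_id, result in multi.results.items():
            if result.mean_observed is None or not result.detected:
                continue
            est_multi[genome_id] = result.estimated_copies
            est_single[genome_id] = estimate_copies(result.mean_observed, single_model)
        comparison.median_dev_multi.append(
            deviation_pct(est_multi, truth).median_deviation_pct
        )
        comparison.median_dev_single.append(
            deviation_pct(est_single, truth).median_deviation_pct
        )
    return comparison
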