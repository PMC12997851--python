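"""Composition and accuracy metrics for quantitation benchmarks.

Covers relative abundance, percent deviation from theoretical composition,
the Simpson dominance index (Σp²), single-taxon spike-in calibration (one
correction factor instead of a regression), and sequencing-effort titration
(re-running subsample → coverage → calibrate → quantify at increasing base
targets to show convergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_summary import (
    AlignmentRecord,
    GenomeLengths,
    restrict_alignments,
    summarize_coverage,
)
from .bsinc_quant import (
    DEFAULT_KAPPA,
    DEFAULT_LOD,
    DEFAULT_LOQ_CV,
    CalibrationModel,
    ObservedCopyNumber,
    apply_lod,
    barcode_effect_factor,
    fit_calibration,
    observe_all,
    quantify_sample,
)
from .read_processing import MATERIAL_SAMPLE, MATERIAL_SPIKE_IN, BarcodeLibrary, subsample_to_bases
from .reference_db import SpikeInTruth, truth_as_mapping


def relative_abundance(copies: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-taxon copies to relative abundances summing to 1."""
    if any(v < 0 for v in copies.values()):
        raise ValueError("negative copy numbers")
    total = sum(copies.values())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero composition")
    return {taxon: value / total for taxon, value in copies.items()}


@dataclass(slots=True)
class DeviationReport:
    """Per-taxon percent deviations from theoretical values."""

    per_taxon: dict[str, float | None]
    median_deviation_pct: float

    def __iter__(self):
        return iter(self.per_taxon.items())


def deviation_pct(
    estimated: Mapping[str, float], theoretical: Mapping[str, float]
) -> DeviationReport:
    """Per-taxon 100·(estimated − theoretical)/theoretical, over shared taxa.

    ``median_deviation_pct`` is the median of the *absolute* deviations
    (deviation magnitudes are what matter for quantitation accuracy); taxa
    with theoretical 0 get a ``None`` deviation and are excluded from it.
    """
    shared = [t for t in theoretical if t in estimated]
    if not shared:
        raise ValueError("no shared taxa between estimated and theoretical")
    per_taxon: dict[str, float | None] = {}
    for taxon in shared:
        theo = theoretical[taxon]
        if theo == 0:
            per_taxon[taxon] = None
            continue
        per_taxon[taxon] = 100.0 * (estimated[taxon] - theo) / theo
    defined = [abs(v) for v in per_taxon.values() if v is not None]
    median = float(np.median(defined)) if defined else float("nan")
    return DeviationReport(per_taxon=per_taxon, median_deviation_pct=median)


def simpson_dominance(composition: Mapping[str, float]) -> float:
    """Simpson dominance index Σp² (1 = single taxon, 1/S = uniform).

    Accepts raw copies or relative abundances; values are normalized first.
    """
    p = np.asarray(list(composition.values()), dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("invalid composition")
    p = p / p.sum()
    return float(np.sum(p**2))


def simpson_diversity(composition: Mapping[str, float]) -> float:
    """Complement form 1 − Σp² (Gini–Simpson diversity)."""
    return 1.0 - simpson_dominance(composition)


def single_spikein_calibration(
    truth_single: SpikeInTruth,
    observed_single: ObservedCopyNumber | Iterable[ObservedCopyNumber],
    lod: float = DEFAULT_LOD,
) -> CalibrationModel:
    """One-taxon calibration: slope fixed at 1, intercept a single factor.

    ``intercept = log10(theoretical) − log10(observed)``, with observed the
    mean across replicates when several observations are given. The taxon
    must pass the LOD in every replicate. R² is undefined (NaN).
    """
    observations = (
        [observed_single]
        if isinstance(observed_single, ObservedCopyNumber)
        else list(observed_single)
    )
    values: list[float] = []
    for obs in observations:
        if obs.copies_observed is None or not apply_lod(obs.coverage_fraction, lod):
            raise ValueError(
                f"single spike-in taxon {truth_single.genome_id!r} below LOD"
            )
        values.append(obs.copies_observed)
    mean_observed = float(np.mean(values))
    return CalibrationModel(
        slope=1.0,
        intercept=math.log10(truth_single.theoretical_copies) - math.log10(mean_observed),
        r_squared=float("nan"),
        n_points=len(values),
        retained_genomes=[truth_single.genome_id],
        filters_applied={"lod_coverage_fraction": lod, "mode": "single_spikein"},
    )


def effort_titration(
    libraries: Mapping[str, BarcodeLibrary],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    db: GenomeLengths,
    spike_truth: Iterable[SpikeInTruth] | Mapping[str, float],
    sample_truth: Mapping[str, float],
    targets: Sequence[int],
    seed: int,
    kappa: float = DEFAULT_KAPPA,
    lod: float = DEFAULT_LOD,
    loq_cv: float | None = DEFAULT_LOQ_CV,
) -> pd.DataFrame:
    """Re-run subsample → coverage → calibrate → quantify per base target.

    ``libraries``/``alignments`` are keyed by barcode; spike-in and sample
    barcodes are told apart by ``BarcodeLibrary.material``. For each target
    (ascending) every barcode is subsampled to the target with a seed derived
    from ``seed`` and the target's rank, coverage and BEFs are recomputed on
    the subsample, the calibration refitted on spike-in barcodes, and sample
    deviations evaluated against the theoretical composition. Returns a tidy
    long-format table: columns ``target_bases, metric, taxon, value, seed``.
    """
    if list(targets) != sorted(targets):
        raise ValueError("targets must be ascending")
    spike_truth_map = truth_as_mapping(spike_truth)
    rows: list[dict] = []
    for rank, target in enumerate(targets):
        spike_observed: dict[str, dict[str, ObservedCopyNumber]] = {}
        sample_summaries: dict[str, dict] = {}
        sample_befs: dict[str, object] = {}
        for barcode, library in libraries.items():
            sub = subsample_to_bases(library, int(target), seed=seed + rank)
            kept_ids = {r.read_id for r in sub.reads}
            alns = restrict_alignments(alignments[barcode], kept_ids)
            summaries = summarize_coverage(alns, db, barcode)
            bef = barcode_effect_factor(
                max(sub.total_bases, 1), library.input_dna_ng, kappa, barcode
            )
            if library.material == MATERIAL_SPIKE_IN:
                spike_observed[barcode] = observe_all(summaries, bef)
            else:
                sample_summaries[barcode] = summaries
                sample_befs[barcode] = bef
        model = fit_calibration(spike_truth_map, spike_observed, lod=lod, loq_cv=loq_cv, kappa=kappa)
        for metric, value in (
            ("slope", model.slope),
            ("intercept", model.intercept),
            ("r_squared", model.r_squared),
            ("n_points", model.n_points),
        ):
            rows.append({"target_bases": target, "metric": metric,
                         "taxon": None, "value": value, "seed": seed})
        if sample_summaries:
            results = quantify_sample(sample_summaries, sample_befs, model,
                                      lod=lod, loq_cv=loq_cv)
            estimated = {g: r.estimated_copies for g, r in results.items()
                         if r.estimated_copies is not None}
            if estimated:
                theo = relative_abundance(
                    {g: sample_truth[g] for g in estimated if g in sample_truth}
                )
                est = relative_abundance(estimated)
                report = deviation_pct(est, theo)
                for taxon, dev in report:
                    rows.append({"target_bases": target, "metric": "deviation_pct",
                                 "taxon": taxon, "value": dev, "seed": seed})
                rows.append({"target_bases": target, "metric": "median_abs_deviation_pct",
                             "taxon": None, "value": report.median_deviation_pct,
                             "seed": seed})
    return pd.DataFrame(rows, columns=["target_bases", "metric", "taxon", "value", "seed"])
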