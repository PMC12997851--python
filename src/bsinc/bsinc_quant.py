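"""Barcoded spike-in calibration (BSINC): the absolute-quantitation core.

The method co-sequences a spike-in DNA standard of known composition with the
samples, each under its own barcodes, in one multiplexed long-read library.
Quantitation proceeds in four steps:

1. **Barcode effect factor (BEF).** Ligation efficiency differs between
   barcodes, so each barcode's realized sequencing effort is normalized by
   its theoretical output: ``BEF_i = observed_bases_i / (kappa · input_ng_i)``
   where ``kappa`` (bp/ng) is a run-level yield constant. Final estimates are
   provably invariant to the choice of ``kappa`` (the log-shift is absorbed
   by the calibration intercept), so its default is cosmetic.

2. **Observed genome copy number.** For each genome and barcode,
   ``copies_observed = (mapped_bases / BEF) / covered_bases`` — a genome-
   size-free copy estimate that works with draft genomes, since it divides
   by the bases actually covered rather than by an assumed genome size.
   Genomes with zero covered bases have *no* observed copy number (flagged,
   never reported as zero copies).

3. **Dynamic LOD/LOQ.** A genome is detected when its coverage fraction is
   strictly > 10% (LOD), and quantifiable when the coefficient of variation
   of its observed copies across replicate barcodes is ≤ 10% (LOQ). Both
   thresholds are dynamic: they move with sequencing effort rather than
   being fixed input concentrations.

4. **Calibration and estimation.** Ordinary least squares of
   ``log10(theoretical copies)`` on ``log10(observed copies)`` over the
   spike-in genomes that survive LOD/LOQ filtering yields slope, intercept
   and R²; sample estimates are ``10^(intercept + slope·log10(observed))``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .alignment_summary import CoverageSummary
from .reference_db import ReferenceDB, SpikeInTruth, truth_as_mapping

logger = logging.getLogger(__name__)

DEFAULT_KAPPA = 1e7  # bp per ng; cosmetic (estimates are kappa-invariant)
DEFAULT_LOD = 0.10  # coverage fraction must be strictly greater
DEFAULT_LOQ_CV = 0.10  # replicate CV must be less than or equal

DETECTION_ALL = "all"
DETECTION_ANY = "any"


class CalibrationError(RuntimeError):
    """Raised when too few spike-in genomes survive LOD/LOQ filtering."""


@dataclass(slots=True)
class BarcodeEffectFactor:
    """Observed-vs-theoretical sequencing effort ratio of one barcode."""

    barcode: str
    observed_bases: int
    input_dna_ng: float
    kappa: float
    bef: float = field(init=False)

    def __post_init__(self) -> None:
        if self.observed_bases <= 0:
            raise ValueError(f"barcode {self.barcode!r}: observed_bases must be > 0")
        if self.input_dna_ng <= 0:
            raise ValueError(f"barcode {self.barcode!r}: input_dna_ng must be > 0")
        if self.kappa <= 0:
            raise ValueError(f"barcode {self.barcode!r}: kappa must be > 0")
        self.bef = self.observed_bases / (self.kappa * self.input_dna_ng)


@dataclass(slots=True)
class ObservedCopyNumber:
    """BEF-normalized mapped bases over covered bases for one genome/barcode.

    ``copies_observed`` is ``None`` (with ``reason``) when the genome has no
    covered bases — absence of evidence, not zero copies.
    """

    genome_id: str
    barcode: str
    copies_observed: float | None
    coverage_fraction: float
    reason: str | None = None


@dataclass
class CalibrationModel:
    """Log10-space linear calibration fitted on spike-in controls."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    retained_genomes: list[str] = field(default_factory=list)
    filters_applied: dict = field(default_factory=dict)
    kappa: float = DEFAULT_KAPPA

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": None if math.isnan(self.r_squared) else self.r_squared,
            "n_points": self.n_points,
            "retained_genomes": self.retained_genomes,
            "filters_applied": self.filters_applied,
            "kappa": self.kappa,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        r2 = payload.get("r_squared")
        return cls(
            slope=payload["slope"],
            intercept=payload["intercept"],
            r_squared=float("nan") if r2 is None else r2,
            n_points=payload["n_points"],
            retained_genomes=list(payload.get("retained_genomes", [])),
            filters_applied=dict(payload.get("filters_applied", {})),
            kappa=payload.get("kappa", DEFAULT_KAPPA),
        )


@dataclass(slots=True)
class QuantResult:
    """Per-genome detection/quantitation outcome for a sample."""

    genome_id: str
    detected: bool
    quantifiable: bool
    estimated_copies: float | None = None
    cv: float | None = None
    mean_observed: float | None = None
    copies_per_ul_extract: float | None = None


def barcode_effect_factor(
    observed_bases: int,
    input_dna_ng: float,
    kappa: float = DEFAULT_KAPPA,
    barcode: str = "",
) -> BarcodeEffectFactor:
    """BEF of one barcode: observed bp over theoretical bp (``kappa``·ng)."""
    bef = BarcodeEffectFactor(
        barcode=barcode, observed_bases=int(observed_bases),
        input_dna_ng=input_dna_ng, kappa=kappa,
    )
    logger.info("barcode %s: BEF = %.4g (%d bp / %.3g ng)",
                barcode, bef.bef, bef.observed_bases, input_dna_ng)
    return bef


def observed_copy_number(
    summary: CoverageSummary, bef: BarcodeEffectFactor
) -> ObservedCopyNumber:
    """Observed copies = (mapped_bases / BEF) / covered_bases."""
    if summary.barcode != bef.barcode:
        raise ValueError(
            f"barcode mismatch: coverage is {summary.barcode!r}, BEF is {bef.barcode!r}"
        )
    if summary.covered_bases == 0:
        return ObservedCopyNumber(
            genome_id=summary.genome_id, barcode=summary.barcode,
            copies_observed=None,
            coverage_fraction=summary.coverage_fraction,
            reason="no coverage",
        )
    copies = (summary.mapped_bases / bef.bef) / summary.covered_bases
    return ObservedCopyNumber(
        genome_id=summary.genome_id, barcode=summary.barcode,
        copies_observed=copies, coverage_fraction=summary.coverage_fraction,
    )


def observe_all(
    summaries: Mapping[str, CoverageSummary], bef: BarcodeEffectFactor
) -> dict[str, ObservedCopyNumber]:
    """Observed copy numbers for every genome of one barcode."""
    return {gid: observed_copy_number(s, bef) for gid, s in summaries.items()}


def apply_lod(coverage_fraction: float, threshold: float = DEFAULT_LOD) -> bool:
    """Detection rule: coverage fraction strictly greater than the threshold."""
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError(f"coverage_fraction {coverage_fraction} outside [0, 1]")
    return coverage_fraction > threshold


def replicate_cv(values: Sequence[float]) -> float | None:
    """Sample CV (n−1 standard deviation over mean); None if undefined."""
    if len(values) < 2:
        return None
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=1) / mean)


def _retained_spikein_points(
    truth: Mapping[str, float],
    observed: Mapping[str, Mapping[str, ObservedCopyNumber]],
    lod: float,
    loq_cv: float | None,
) -> dict[str, list[float]]:
    """Spike-in genomes passing LOD in every replicate and the CV gate."""
    retained: dict[str, list[float]] = {}
    for genome_id in truth:
        values: list[float] = []
        ok = True
        for obs_map in observed.values():
            obs = obs_map.get(genome_id)
            if obs is None or obs.copies_observed is None:
                ok = False
                break
            if not apply_lod(obs.coverage_fraction, lod):
                ok = False
                break
            values.append(obs.copies_observed)
        if not ok:
            continue
        if loq_cv is not None:
            cv = replicate_cv(values)
            if cv is not None and cv > loq_cv:
                continue
        retained[genome_id] = values
    return retained


def fit_calibration(
    truth: Iterable[SpikeInTruth] | Mapping[str, float],
    observed: Mapping[str, Mapping[str, ObservedCopyNumber]],
    lod: float = DEFAULT_LOD,
    loq_cv: float | None = DEFAULT_LOQ_CV,
    replicate_mode: str = "mean",
    kappa: float = DEFAULT_KAPPA,
) -> CalibrationModel:
    """OLS of log10(theoretical copies) on log10(observed copies).

    ``observed`` maps replicate spike-in barcode -> genome -> observation.
    A genome enters the fit only if it passes the LOD in *all* replicates and
    its replicate CV is ≤ ``loq_cv`` (``loq_cv=None`` disables the CV gate).
    ``replicate_mode`` is ``"mean"`` (one point per genome, the mean of
    observed copies across replicates; the default) or ``"pooled"`` (one
    point per genome per barcode).
    """
    truth_map = truth_as_mapping(truth)
    if replicate_mode not in ("mean", "pooled"):
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    retained = _retained_spikein_points(truth_map, observed, lod, loq_cv)
    if len(retained) < 2:
        raise CalibrationError(
            f"calibration underdetermined: only {len(retained)} spike-in genome(s) "
            f"passed LOD/LOQ filtering (need ≥ 2)"
        )

    xs: list[float] = []
    ys: list[float] = []
    for genome_id, values in retained.items():
        y = math.log10(truth_map[genome_id])
        if replicate_mode == "mean":
            xs.append(math.log10(float(np.mean(values))))
            ys.append(y)
        else:
            for v in values:
                xs.append(math.log10(v))
                ys.append(y)

    fit = _scipy_stats.linregress(xs, ys)
    n_points = len(xs)
    r_squared = float(fit.rvalue**2) if n_points >= 3 else float("nan")
    model = CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        n_points=n_points,
        retained_genomes=sorted(retained),
        filters_applied={
            "lod_coverage_fraction": lod,
            "loq_cv": loq_cv,
            "replicate_mode": replicate_mode,
        },
        kappa=kappa,
    )
    logger.info(
        "calibration: slope=%.4f intercept=%.4f R²=%s on %d point(s) (%d genomes)",
        model.slope, model.intercept,
        "n/a" if math.isnan(r_squared) else f"{r_squared:.4f}",
        n_points, len(retained),
    )
    return model


def estimate_copies(
    observed: float | ObservedCopyNumber, model: CalibrationModel
) -> float | None:
    """Calibrated estimate: 10^(intercept + slope · log10(observed copies))."""
    value = observed.copies_observed if isinstance(observed, ObservedCopyNumber) else observed
    if value is None or value <= 0:
        return None
    if model.slope == 0:
        logger.warning("degenerate calibration model (slope 0): constant estimates")
    return float(10.0 ** (model.intercept + model.slope * math.log10(value)))


def copies_per_ul(estimated_copies: float, library_input_volume_ul: float) -> float:
    """Convert per-library copies to copies per µL of DNA extract."""
    if library_input_volume_ul <= 0:
        raise ValueError("library_input_volume_ul must be > 0")
    return estimated_copies / library_input_volume_ul


def quantify_sample(
    summaries: Mapping[str, Mapping[str, CoverageSummary]],
    befs: Mapping[str, BarcodeEffectFactor],
    model: CalibrationModel | None,
    lod: float = DEFAULT_LOD,
    loq_cv: float | None = DEFAULT_LOQ_CV,
    detection: str = DETECTION_ALL,
    volume_ul: float | None = None,
) -> dict[str, QuantResult]:
    """Detect and quantify every genome across replicate sample barcodes.

    ``summaries`` maps sample barcode -> genome -> coverage. A genome is
    detected when its coverage fraction passes the LOD in all replicates
    (``detection="all"``, the conservative default) or in at least one
    (``"any"``). It is quantifiable when detected and its replicate CV
    passes the LOQ gate (with ``loq_cv=None`` the gate is skipped; with
    < 2 defined replicate observations the CV is undefined and the genome is
    not quantifiable unless the gate is off). Undetected or unquantifiable
    genomes are reported with flags, never silently dropped. ``model=None``
    (calibration unavailable) reports detection flags only.
    """
    if detection not in (DETECTION_ALL, DETECTION_ANY):
        raise ValueError(f"unknown detection mode {detection!r}")
    barcodes = list(summaries)
    if not barcodes:
        return {}
    genome_ids = list(summaries[barcodes[0]])
    results: dict[str, QuantResult] = {}
    for genome_id in genome_ids:
        passes: list[bool] = []
        values: list[float] = []
        for barcode in barcodes:
            summary = summaries[barcode][genome_id]
            obs = observed_copy_number(summary, befs[barcode])
            passes.append(apply_lod(obs.coverage_fraction, lod))
            if obs.copies_observed is not None:
                values.append(obs.copies_observed)
        detected = all(passes) if detection == DETECTION_ALL else any(passes)
        cv = replicate_cv(values)
        if loq_cv is None:
            quantifiable = detected and bool(values)
        else:
            quantifiable = detected and cv is not None and cv <= loq_cv
        estimated = None
        mean_obs = float(np.mean(values)) if values else None
        if model is None:
            quantifiable = False
        elif detected and quantifiable and mean_obs is not None:
            estimated = estimate_copies(mean_obs, model)
        results[genome_id] = QuantResult(
            genome_id=genome_id,
            detected=detected,
            quantifiable=quantifiable,
            estimated_copies=estimated,
            cv=cv,
            mean_observed=mean_obs,
            copies_per_ul_extract=(
                copies_per_ul(estimated, volume_ul)
                if estimated is not None and volume_ul is not None else None
            ),
        )
    return results


def aggregate_rank(
    results: Mapping[str, QuantResult], db: ReferenceDB, rank: str
) -> tuple[dict[str, float], pd.DataFrame]:
    """Sum estimated copies of quantifiable genomes sharing a taxonomy rank.

    Returns ``(totals, report)``: ``totals`` holds per-taxon copy sums for
    taxa with ≥1 quantified genome; ``report`` covers every taxon with genome
    counts so that taxa entirely below LOD/LOQ remain visible.
    """
    from .reference_db import RANKS

    if rank not in RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r} (expected one of {RANKS})")
    rows: dict[str, dict] = {}
    for genome_id, result in results.items():
        label = db[genome_id].taxonomy.get(rank, "") or f"unclassified_{rank}"
        row = rows.setdefault(label, {
            rank: label, "n_genomes": 0, "n_detected": 0,
            "n_quantified": 0, "estimated_copies": 0.0,
        })
        row["n_genomes"] += 1
        row["n_detected"] += int(result.detected)
        if result.estimated_copies is not None:
            row["n_quantified"] += 1
            row["estimated_copies"] += result.estimated_copies
    report = pd.DataFrame(sorted(rows.values(), key=lambda r: r[rank]))
    totals = {
        r[rank]: r["estimated_copies"] for r in rows.values() if r["n_quantified"] > 0
    }
    return totals, report


def quant_to_dataframe(
    results: Mapping[str, QuantResult], db: ReferenceDB | None = None
) -> pd.DataFrame:
    from .reference_db import format_taxonomy

    rows = []
    for genome_id, r in results.items():
        rows.append({
            "genome_id": genome_id,
            "taxonomy": format_taxonomy(db[genome_id].taxonomy) if db else "",
            "detected": r.detected,
            "quantifiable": r.quantifiable,
            "cv": r.cv,
            "mean_observed": r.mean_observed,
            "estimated_copies": r.estimated_copies,
            "copies_per_ul": r.copies_per_ul_extract,
        })
    return pd.DataFrame(rows)
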