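import math

import numpy as np
import pytest

from bsinc.alignment_summary import CoverageSummary
from bsinc.bsinc_quant import (
    CalibrationError,
    CalibrationModel,
    aggregate_rank,
    apply_lod,
    barcode_effect_factor,
    copies_per_ul,
    estimate_copies,
    fit_calibration,
    observed_copy_number,
    quantify_sample,
    replicate_cv,
)
from bsinc.reference_db import GenomeRecord, ReferenceDB, parse_taxonomy


def make_observed(copies_by_genome, barcode="bc01", coverage=0.5, kappa=1e7, ng=100.0):
    """Build ObservedCopyNumber maps through the real coverage→BEF machinery."""
    bef = barcode_effect_factor(int(kappa * ng), ng, kappa, barcode)  # bef = 1
    out = {}
    for genome_id, copies in copies_by_genome.items():
        length = 10_000
        covered = int(coverage * length)
        summary = CoverageSummary(genome_id, barcode, int(copies * covered), covered, length)
        out[genome_id] = observed_copy_number(summary, bef)
    return out


class TestBarcodeEffectFactor:
    def test_definitional_identity(self):
        assert barcode_effect_factor(int(1e7 * 50), 50.0, 1e7).bef == pytest.approx(1.0)

    def test_arithmetic(self):
        assert barcode_effect_factor(2_000_000_000, 100.0, 1e7).bef == pytest.approx(2.0)

    @pytest.mark.parametrize("bases, ng", [(0, 10.0), (100, 0.0), (100, -1.0)])
    def test_nonpositive_inputs_rejected(self, bases, ng):
        with pytest.raises(ValueError):
            barcode_effect_factor(bases, ng, 1e7)


class TestObservedCopyNumber:
    def test_unit_bef(self):
        bef = barcode_effect_factor(int(1e9), 100.0, 1e7)  # bef = 1
        s = CoverageSummary("g", "", 1000, 100, 1000)
        assert observed_copy_number(s, bef).copies_observed == pytest.approx(10.0)

    def test_bef_halves_copies(self):
        bef = barcode_effect_factor(int(2e9), 100.0, 1e7)  # bef = 2
        s = CoverageSummary("g", "", 1000, 100, 1000)
        assert observed_copy_number(s, bef).copies_observed == pytest.approx(5.0)

    def test_no_coverage_flagged_not_zero(self):
        bef = barcode_effect_factor(int(1e9), 100.0, 1e7)
        obs = observed_copy_number(CoverageSummary("g", "", 0, 0, 1000), bef)
        assert obs.copies_observed is None
        assert obs.reason == "no coverage"

    def test_barcode_mismatch_rejected(self):
        bef = barcode_effect_factor(int(1e9), 100.0, 1e7, barcode="bc01")
        with pytest.raises(ValueError, match="mismatch"):
            observed_copy_number(CoverageSummary("g", "bc02", 10, 10, 1000), bef)


@pytest.mark.parametrize("fraction, expected", [(0.11, True), (0.10, False), (0.0, False)])
def test_lod_is_strictly_greater_than(fraction, expected):
    assert apply_lod(fraction) is expected


@pytest.mark.parametrize("values, expected", [
    ([10, 10, 10], 0.0),
    ([8, 10, 12], 0.2),  # sd (n−1) = 2, mean = 10
])
def test_replicate_cv_values(values, expected):
    assert replicate_cv(values) == pytest.approx(expected)


def test_replicate_cv_undefined_cases():
    assert replicate_cv([5.0]) is None
    assert replicate_cv([1.0, -1.0]) is None  # zero mean


class TestFitCalibration:
    def fit(self, truth, factor=1.0, **kwargs):
        observed = {
            bc: make_observed({g: c * factor for g, c in truth.items()}, barcode=bc)
            for bc in ("bc01", "bc02", "bc03")
        }
        return fit_calibration(truth, observed, **kwargs)

    def test_identity_data(self):
        truth = {f"g{i}": 10.0**i for i in range(1, 6)}
        model = self.fit(truth)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0)
        assert model.n_points == 5

    def test_constant_factor_shifts_intercept(self):
        truth = {f"g{i}": 10.0**i for i in range(1, 6)}
        model = self.fit(truth, factor=10.0)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(-1.0)

    def test_lognormal_noise_recovery_matches_ols_oracle(self):
        rng = np.random.default_rng(2024)
        truth = {f"g{i}": float(c) for i, c in enumerate(np.logspace(2, 6, 8))}
        noisy = {g: c * float(np.exp(rng.normal(0, 0.05))) for g, c in truth.items()}
        observed = {bc: make_observed(noisy, barcode=bc) for bc in ("b1", "b2", "b3")}
        model = fit_calibration(truth, observed)
        assert model.slope == pytest.approx(1.0, abs=0.1)
        # independent least-squares oracle on the same log10 pairs (the
        # integer base counts quantize the observed values slightly)
        x = np.log10([observed["b1"][g].copies_observed for g in truth])
        y = np.log10([truth[g] for g in truth])
        slope_oracle, intercept_oracle = np.polyfit(x, y, 1)
        assert model.slope == pytest.approx(slope_oracle, rel=1e-9)
        assert model.intercept == pytest.approx(intercept_oracle, rel=1e-9)

    def test_two_point_closed_form(self):
        truth = {"a": 100.0, "b": 10_000.0}
        observed = {bc: make_observed({"a": 50.0, "b": 2_000.0}, barcode=bc)
                    for bc in ("b1", "b2")}
        model = fit_calibration(truth, observed)
        x1, x2 = math.log10(50.0), math.log10(2_000.0)
        y1, y2 = 2.0, 4.0
        slope = (y2 - y1) / (x2 - x1)
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(y1 - slope * x1)
        assert math.isnan(model.r_squared)  # undefined below 3 points

    def test_underdetermined_raises(self):
        truth = {"a": 100.0, "b": 1_000.0, "c": 10_000.0}
        observed = {
            bc: make_observed({"a": 100.0}, barcode=bc, coverage=0.5)
            | make_observed({"b": 1_000.0, "c": 10_000.0}, barcode=bc, coverage=0.05)
            for bc in ("b1", "b2")
        }
        with pytest.raises(CalibrationError, match="underdetermined"):
            fit_calibration(truth, observed)

    def test_filtering_never_adds_points(self):
        truth = {f"g{i}": 10.0**i for i in range(1, 6)}
        with pytest.raises(CalibrationError):
            self.fit(truth, lod=0.6)  # coverage fixture is 0.5 → all filtered out

    def test_retained_subset_under_partial_lod(self):
        truth = {"lo": 10.0, "mid": 1_000.0, "hi": 100_000.0}
        observed = {
            bc: make_observed({"lo": 10.0}, barcode=bc, coverage=0.05)
            | make_observed({"mid": 1_000.0, "hi": 100_000.0}, barcode=bc)
            for bc in ("b1", "b2", "b3")
        }
        model = fit_calibration(truth, observed)
        assert model.retained_genomes == ["hi", "mid"]


class TestEstimateCopies:
    def test_identity_model(self):
        model = CalibrationModel(1.0, 0.0, 1.0, 5)
        assert estimate_copies(250.0, model) == pytest.approx(250.0)

    def test_log_shift(self):
        model = CalibrationModel(1.0, 0.3, 1.0, 5)
        assert estimate_copies(1000.0, model) == pytest.approx(1995.26, abs=0.01)

    def test_degenerate_slope_constant(self):
        model = CalibrationModel(0.0, 2.0, 0.0, 5)
        assert estimate_copies(123.0, model) == pytest.approx(100.0)

    def test_absent_observation(self):
        model = CalibrationModel(1.0, 0.0, 1.0, 5)
        assert estimate_copies(None, model) is None
        assert estimate_copies(0.0, model) is None


def test_copies_per_ul():
    assert copies_per_ul(1000.0, 2.0) == pytest.approx(500.0)
    assert copies_per_ul(0.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        copies_per_ul(10.0, 0.0)


def identity_model():
    return CalibrationModel(1.0, 0.0, 1.0, 5)


def befs_for(barcodes, kappa=1e7, ng=100.0):
    return {bc: barcode_effect_factor(int(kappa * ng), ng, kappa, bc) for bc in barcodes}


class TestQuantifySample:
    def summaries(self, copies, coverage=0.5, barcodes=("b1", "b2", "b3")):
        out = {}
        for bc in barcodes:
            out[bc] = {}
            for genome_id, c in copies.items():
                length = 10_000
                covered = int(coverage * length)
                out[bc][genome_id] = CoverageSummary(
                    genome_id, bc, int(c * covered), covered, length
                )
        return out

    def test_identity_recovery(self):
        copies = {"a": 100.0, "b": 5_000.0}
        results = quantify_sample(
            self.summaries(copies), befs_for(("b1", "b2", "b3")), identity_model()
        )
        for genome_id, c in copies.items():
            r = results[genome_id]
            assert r.detected and r.quantifiable
            assert r.estimated_copies == pytest.approx(c, rel=1e-3)

    def test_below_lod_never_estimated(self):
        results = quantify_sample(
            self.summaries({"a": 100.0}, coverage=0.05),
            befs_for(("b1", "b2", "b3")), identity_model(),
        )
        assert not results["a"].detected
        assert results["a"].estimated_copies is None

    def test_all_vs_any_detection(self):
        summaries = self.summaries({"a": 100.0}, coverage=0.5)
        summaries["b1"]["a"] = CoverageSummary("a", "b1", 5_000, 500, 10_000)  # 5%
        befs = befs_for(("b1", "b2", "b3"))
        strict = quantify_sample(summaries, befs, identity_model())
        loose = quantify_sample(summaries, befs, identity_model(), detection="any")
        assert not strict["a"].detected
        assert loose["a"].detected

    def test_volume_conversion(self):
        results = quantify_sample(
            self.summaries({"a": 1_000.0}, barcodes=("b1", "b2")),
            befs_for(("b1", "b2")), identity_model(), volume_ul=2.0,
        )
        assert results["a"].copies_per_ul_extract == pytest.approx(
            results["a"].estimated_copies / 2.0
        )


def test_kappa_invariance_of_estimates():
    """Scaling kappa rescales BEFs and observed copies but not final estimates."""
    truth = {f"g{i}": 10.0**i for i in range(2, 6)}
    sample = {"s1": 300.0, "s2": 40_000.0}

    def run(kappa):
        observed = {}
        for bc in ("b1", "b2"):
            bef = barcode_effect_factor(int(1e9), 100.0, kappa, bc)
            observed[bc] = {
                g: observed_copy_number(
                    CoverageSummary(g, bc, int(c * 5_000), 5_000, 10_000), bef
                )
                for g, c in truth.items()
            }
        model = fit_calibration(truth, observed, loq_cv=None)
        bef = barcode_effect_factor(int(1e9), 100.0, kappa, "s")
        return {
            g: estimate_copies(observed_copy_number(
                CoverageSummary(g, "s", int(c * 5_000), 5_000, 10_000), bef
            ), model)
            for g, c in sample.items()
        }

    base, scaled = run(1e7), run(1e10)
    for genome_id in sample:
        assert scaled[genome_id] == pytest.approx(base[genome_id], rel=1e-9)


def test_aggregate_rank_sums_and_reports():
    db = ReferenceDB([
        GenomeRecord("g1", 1000, parse_taxonomy("g__Nitrospira;s__Nitrospira a")),
        GenomeRecord("g2", 1000, parse_taxonomy("g__Nitrospira;s__Nitrospira b")),
        GenomeRecord("g3", 1000, parse_taxonomy("g__Gordonia;s__Gordonia c")),
    ])
    from bsinc.bsinc_quant import QuantResult

    results = {
        "g1": QuantResult("g1", True, True, estimated_copies=100.0),
        "g2": QuantResult("g2", True, True, estimated_copies=50.0),
        "g3": QuantResult("g3", False, False),  # below LOD
    }
    totals, report = aggregate_rank(results, db, "genus")
    assert totals == {"Nitrospira": pytest.approx(150.0)}
    gordonia = report[report["genus"] == "Gordonia"].iloc[0]
    assert gordonia["n_genomes"] == 1 and gordonia["n_quantified"] == 0
    with pytest.raises(ValueError, match="rank"):
        aggregate_rank(results, db, "clade")
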