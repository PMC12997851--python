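import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsinc.bsinc_quant import CalibrationModel, estimate_copies, observed_copy_number
from bsinc.alignment_summary import CoverageSummary
from bsinc.bsinc_quant import barcode_effect_factor
from bsinc.metrics import (
    deviation_pct,
    effort_titration,
    relative_abundance,
    simpson_diversity,
    simpson_dominance,
    single_spikein_calibration,
)
from bsinc.reference_db import SpikeInTruth
from bsinc.standards import gut_standard_copy_fractions, log_standard_copy_fractions
from bsinc.synthetic_data import (
    BarcodeSpec,
    RunSpec,
    log_distributed_community,
    simulate_experiment,
)


class TestRelativeAbundance:
    @pytest.mark.parametrize("copies, expected", [
        ({"a": 3.0, "b": 1.0}, {"a": 0.75, "b": 0.25}),
        ({"solo": 42.0}, {"solo": 1.0}),
        ({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}, dict.fromkeys("abcd", 0.25)),
    ])
    def test_examples(self, copies, expected):
        assert relative_abundance(copies) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance({"a": 0.0, "b": 0.0})


class TestDeviationPct:
    def test_identity_is_zero(self):
        comp = {"a": 0.5, "b": 0.3, "c": 0.2}
        report = deviation_pct(comp, comp)
        assert all(v == 0 for v in report.per_taxon.values())
        assert report.median_deviation_pct == 0.0

    def test_signed_deviation(self):
        report = deviation_pct({"a": 0.6}, {"a": 0.5})
        assert report.per_taxon["a"] == pytest.approx(20.0)

    def test_rare_taxon_blowup(self):
        report = deviation_pct({"a": 0.01}, {"a": 1e-4})
        assert report.per_taxon["a"] == pytest.approx(9_900.0)

    def test_zero_theoretical_excluded(self):
        report = deviation_pct({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.0})
        assert report.per_taxon["b"] is None
        assert report.median_deviation_pct == 0.0


class TestSimpson:
    @pytest.mark.parametrize("comp, expected", [
        (dict.fromkeys(range(10), 0.1), 0.10),
        ({"solo": 1.0}, 1.0),
        ({"a": 0.9, "b": 0.1}, 0.82),
    ])
    def test_examples(self, comp, expected):
        assert simpson_dominance(comp) == pytest.approx(expected)

    def test_mock_standard_dominances(self):
        # the log-distributed standard is dominated by one member; the gut
        # standard is comparatively even
        assert simpson_dominance(log_standard_copy_fractions()) == pytest.approx(0.90, abs=0.005)
        assert simpson_dominance(gut_standard_copy_fractions()) == pytest.approx(0.11, abs=0.005)

    def test_diversity_complement(self):
        comp = {"a": 0.7, "b": 0.3}
        assert simpson_diversity(comp) == pytest.approx(1 - simpson_dominance(comp))

    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_bounds(self, values):
        comp = {str(i): v for i, v in enumerate(values)}
        d = simpson_dominance(comp)
        assert 1.0 / len(values) - 1e-9 <= d <= 1.0 + 1e-9


def make_obs(copies, coverage=0.5, barcode="b1"):
    bef = barcode_effect_factor(int(1e9), 100.0, 1e7, barcode)
    length = 10_000
    covered = int(coverage * length)
    return observed_copy_number(
        CoverageSummary("tax", barcode, int(copies * covered), covered, length), bef
    )


class TestSingleSpikein:
    def test_identity(self):
        model = single_spikein_calibration(SpikeInTruth("tax", 100.0), make_obs(100.0))
        assert model.slope == 1.0
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(model.r_squared)

    def test_tenfold_observed_gives_minus_one_intercept(self):
        model = single_spikein_calibration(SpikeInTruth("tax", 100.0), make_obs(1000.0))
        assert model.intercept == pytest.approx(-1.0)

    def test_application_of_correction_factor(self):
        model = CalibrationModel(1.0, -1.0, float("nan"), 1)
        assert estimate_copies(100.0, model) == pytest.approx(10.0)

    def test_below_lod_rejected(self):
        with pytest.raises(ValueError, match="LOD"):
            single_spikein_calibration(
                SpikeInTruth("tax", 100.0), make_obs(100.0, coverage=0.05)
            )


@pytest.fixture(scope="module")
def titration_experiment():
    spike = log_distributed_community(5, decades=3.0, genome_length=5_000,
                                      top_copies=1e5, prefix="spk")
    sample = log_distributed_community(5, decades=2.0, genome_length=5_000,
                                       top_copies=1e5, prefix="smp")
    mass = {"spike_in": sum(t.theoretical_copies * t.genome_length for t in spike.taxa),
            "sample": sum(t.theoretical_copies * t.genome_length for t in sample.taxa)}
    barcodes = [
        BarcodeSpec(f"s{i}", material="spike_in", input_dna_ng=mass["spike_in"] / 1e6)
        for i in range(3)
    ] + [
        BarcodeSpec(f"m{i}", material="sample", input_dna_ng=mass["sample"] / 1e6)
        for i in range(3)
    ]
    run = RunSpec(barcodes=barcodes, read_length_mu=math.log(250.0),
                  read_length_sigma=0.3, seed=9)
    return simulate_experiment(spike, sample, run, 4_000_000)


class TestEffortTitration:
    def test_reproducible_and_target_at_full_data(self, titration_experiment):
        exp = titration_experiment
        targets = [500_000, 10_000_000]  # second target exceeds the full library
        kwargs = dict(
            libraries=exp.libraries, alignments=exp.alignments,
            db={**exp.spike_community.lengths, **exp.sample_community.lengths},
            spike_truth=exp.spike_truth, sample_truth=exp.sample_truth,
            targets=targets, seed=5, loq_cv=None,
        )
        table = effort_titration(**kwargs)
        again = effort_titration(**kwargs)
        assert table.equals(again)
        slopes = table[table.metric == "slope"].set_index("target_bases")["value"]
        assert set(slopes.index) == set(targets)
        # the largest target keeps every read, so it matches the unsubsampled fit
        full = effort_titration(**{**kwargs, "targets": [10_000_000]})
        assert slopes[10_000_000] == pytest.approx(
            full[full.metric == "slope"]["value"].iloc[0]
        )

    def test_deviation_shrinks_with_effort(self):
        """Median deviation decreases in expectation as effort grows."""
        lows, highs = [], []
        for seed in (1, 2, 3):
            spike = log_distributed_community(5, 3.0, 5_000, 1e5, "spk")
            sample = log_distributed_community(5, 2.0, 5_000, 1e5, "smp")
            mass_s = sum(t.theoretical_copies * t.genome_length for t in spike.taxa)
            mass_m = sum(t.theoretical_copies * t.genome_length for t in sample.taxa)
            barcodes = [
                BarcodeSpec(f"s{i}", material="spike_in", input_dna_ng=mass_s / 1e6)
                for i in range(3)
            ] + [
                BarcodeSpec(f"m{i}", material="sample", input_dna_ng=mass_m / 1e6)
                for i in range(3)
            ]
            run = RunSpec(barcodes=barcodes, read_length_mu=math.log(250.0),
                          read_length_sigma=0.3, seed=seed)
            exp = simulate_experiment(spike, sample, run, 4_000_000)
            table = effort_titration(
                exp.libraries, exp.alignments,
                {**spike.lengths, **sample.lengths},
                exp.spike_truth, exp.sample_truth,
                targets=[300_000, 4_000_000], seed=seed, loq_cv=None,
            )
            med = table[table.metric == "median_abs_deviation_pct"].set_index("target_bases")["value"]
            lows.append(med[300_000])
            highs.append(med[4_000_000])
        assert np.mean(highs) < np.mean(lows)
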