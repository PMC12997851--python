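import math

import numpy as np
import pytest

from bsinc.alignment_summary import summarize_coverage
from bsinc.metrics import simpson_dominance
from bsinc.synthetic_data import (
    BarcodeSpec,
    CommunitySpec,
    RunSpec,
    TaxonSpec,
    even_community,
    log_distributed_community,
    simulate_barcode_reads,
    simulate_genomes,
    write_truth_tables,
)


def two_taxon_community(copies_a=9_000.0, copies_b=1_000.0, length=10_000):
    return CommunitySpec(taxa=[
        TaxonSpec("A", length, copies_a),
        TaxonSpec("B", length, copies_b),
    ])


def simple_run(barcodes, seed=1, **kwargs):
    return RunSpec(barcodes=barcodes, read_length_mu=math.log(300.0),
                   read_length_sigma=0.3, seed=seed, **kwargs)


class TestSimulateGenomes:
    def test_lengths(self):
        community = even_community(3, genome_length=10_000)
        genomes = simulate_genomes(community, seed=1)
        assert all(len(seq) == 10_000 for seq in genomes.values())
        assert set(genomes) == {t.genome_id for t in community.taxa}

    def test_gc_content_within_binomial_tolerance(self):
        community = CommunitySpec(taxa=[TaxonSpec("g", 100_000, 1.0, gc_content=0.5)])
        seq = simulate_genomes(community, seed=3)["g"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.02)

    def test_seed_determinism(self):
        community = even_community(2, genome_length=5_000)
        assert simulate_genomes(community, seed=7) == simulate_genomes(community, seed=7)
        assert simulate_genomes(community, seed=7) != simulate_genomes(community, seed=8)


class TestSimulateBarcodeReads:
    def test_abundance_share_follows_copies(self):
        community = two_taxon_community()
        run = simple_run([BarcodeSpec("bc01")])
        library, alignments = simulate_barcode_reads(community, run, "bc01", 1_000_000)
        share_a = sum(a.genome_id == "A" for a in alignments) / len(alignments)
        assert share_a == pytest.approx(0.9, abs=0.02)

    def test_throughput_multiplier_scales_bases(self):
        community = two_taxon_community()
        run = simple_run([
            BarcodeSpec("bc01", throughput_multiplier=1.0),
            BarcodeSpec("bc02", throughput_multiplier=2.0),
        ])
        lib1, _ = simulate_barcode_reads(community, run, "bc01", 500_000)
        lib2, _ = simulate_barcode_reads(community, run, "bc02", 500_000)
        assert lib2.total_bases / lib1.total_bases == pytest.approx(2.0, rel=0.01)

    def test_seed_determinism_bytes(self, tmp_path):
        from bsinc.read_processing import write_fastq

        community = two_taxon_community(length=2_000)
        genomes = simulate_genomes(community, seed=5)
        run = simple_run([BarcodeSpec("bc01")], seed=5)
        paths = []
        for name in ("one", "two"):
            library, _ = simulate_barcode_reads(
                community, run, "bc01", 50_000, genomes=genomes, with_sequences=True
            )
            path = tmp_path / f"{name}.fastq"
            write_fastq(library, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_alignments_reproduce_read_lengths(self):
        """Summing mapped bases over truth alignments equals total read bases."""
        community = two_taxon_community()
        run = simple_run([BarcodeSpec("bc01")])
        library, alignments = simulate_barcode_reads(community, run, "bc01", 200_000)
        summaries = summarize_coverage(alignments, community.lengths, "bc01")
        total_mapped = sum(s.mapped_bases for s in summaries.values())
        assert total_mapped == library.total_bases
        per_genome = {g: 0 for g in community.lengths}
        for read, aln in zip(library.reads, alignments):
            per_genome[aln.genome_id] += read.length
        for genome_id, summary in summaries.items():
            assert summary.mapped_bases == per_genome[genome_id]

    def test_extraction_bias_shifts_share(self):
        community = two_taxon_community(5_000.0, 5_000.0)
        run = simple_run([BarcodeSpec("bc01")], extraction_bias={"A": 3.0})
        _, alignments = simulate_barcode_reads(community, run, "bc01", 1_000_000)
        share_a = sum(a.genome_id == "A" for a in alignments) / len(alignments)
        assert share_a == pytest.approx(0.75, abs=0.02)


class TestTruthTables:
    def test_log_distribution_spans_three_decades(self, tmp_path):
        community = log_distributed_community(10, decades=4.0, top_copies=1e6)
        run = simple_run([BarcodeSpec("bc01")])
        paths = write_truth_tables(community, run, tmp_path)
        lines = paths["truth"].read_text().strip().splitlines()[1:]
        rels = [float(line.split("\t")[2]) for line in lines]
        assert max(rels) / min(rels) >= 1e3
        assert sum(rels) == pytest.approx(1.0, abs=1e-9)

    def test_even_community_dominance(self, tmp_path):
        community = even_community(10)
        assert simpson_dominance(community.rel_abundances()) == pytest.approx(0.10)

    def test_custom_truth_echoed(self, tmp_path):
        community = two_taxon_community()
        run = simple_run([BarcodeSpec("bc01", input_dna_ng=55.0)])
        paths = write_truth_tables(community, run, tmp_path)
        truth_lines = paths["truth"].read_text().strip().splitlines()
        assert truth_lines[1].split("\t")[:2] == ["A", "9000.0"]
        meta = paths["barcodes"].read_text()
        assert "55.0" in meta

    def test_log_distributed_validation(self):
        with pytest.raises(ValueError, match="3 decades"):
            CommunitySpec(
                taxa=[TaxonSpec("a", 1000, 10.0), TaxonSpec("b", 1000, 100.0)],
                distribution="log_distributed",
            )
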