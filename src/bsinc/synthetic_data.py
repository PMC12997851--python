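"""Synthetic mock experiments with the statistical structure BSINC assumes.

The generator produces fully specified runs — reference genomes, spike-in
and sample communities, per-barcode reads, and *truth* alignments giving
each read's true source interval — so that every pipeline stage is testable
without sequencing data or an aligner.

What it emulates:

* log-distributed (or even / custom) genome-copy abundances per community;
* per-barcode ligation-efficiency differences as throughput multipliers
  (a barcode with multiplier 2 yields ≈2× the bases of the target), which
  is exactly the batch effect the BEF normalization corrects;
* lognormal read lengths (defaults echo a run N50 around 3.8 kb);
* read sampling weight ∝ copies × genome_length × bias — longer genomes
  yield proportionally more bases per copy, the bias the covered-bases
  division corrects, which makes that correction testable;
* optional per-taxon multiplicative extraction bias (shared across
  barcodes) and per-(barcode, taxon) lognormal abundance noise.

All outputs are deterministic functions of (specs, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .alignment_summary import AlignmentRecord
from .read_processing import (
    MATERIAL_SAMPLE,
    MATERIAL_SPIKE_IN,
    BarcodeLibrary,
    ReadRecord,
)

DEFAULT_READ_LENGTH_MU = math.log(3800.0)
DEFAULT_READ_LENGTH_SIGMA = 0.6


@dataclass(slots=True)
class TaxonSpec:
    """One community member: a genome and its theoretical copy number."""

    genome_id: str
    genome_length: int
    theoretical_copies: float
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError(f"{self.genome_id!r}: genome_length must be > 0")
        if self.theoretical_copies <= 0:
            raise ValueError(f"{self.genome_id!r}: theoretical_copies must be > 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"{self.genome_id!r}: gc_content must be in (0, 1)")


@dataclass
class CommunitySpec:
    """A mock community: taxa with genome lengths and copy abundances."""

    taxa: list[TaxonSpec]
    distribution: Literal["log_distributed", "even", "custom"] = "custom"

    def __post_init__(self) -> None:
        if self.distribution == "log_distributed":
            copies = [t.theoretical_copies for t in self.taxa]
            span = math.log10(max(copies) / min(copies))
            if span < 3:
                raise ValueError(
                    f"log_distributed community must span ≥ 3 decades (got {span:.2f})"
                )

    @property
    def truth(self) -> dict[str, float]:
        return {t.genome_id: t.theoretical_copies for t in self.taxa}

    @property
    def lengths(self) -> dict[str, int]:
        return {t.genome_id: t.genome_length for t in self.taxa}

    def rel_abundances(self) -> dict[str, float]:
        total = sum(t.theoretical_copies for t in self.taxa)
        return {t.genome_id: t.theoretical_copies / total for t in self.taxa}


def log_distributed_community(
    n_taxa: int,
    decades: float,
    genome_length: int | Sequence[int] = 10_000,
    top_copies: float = 1e5,
    prefix: str = "g",
) -> CommunitySpec:
    """Log-spaced copy abundances over ``decades`` decades (rarest first id)."""
    copies = np.logspace(math.log10(top_copies) - decades, math.log10(top_copies), n_taxa)
    lengths = (
        [int(genome_length)] * n_taxa
        if isinstance(genome_length, int)
        else [int(x) for x in genome_length]
    )
    taxa = [
        TaxonSpec(f"{prefix}{i:02d}", lengths[i], float(copies[i]))
        for i in range(n_taxa)
    ]
    return CommunitySpec(
        taxa=taxa, distribution="log_distributed" if decades >= 3 else "custom"
    )


def even_community(
    n_taxa: int, copies: float = 1e4, genome_length: int = 10_000, prefix: str = "e"
) -> CommunitySpec:
    taxa = [TaxonSpec(f"{prefix}{i:02d}", genome_length, copies) for i in range(n_taxa)]
    return CommunitySpec(taxa=taxa, distribution="even")


@dataclass(slots=True)
class BarcodeSpec:
    """One barcode library: material, replicates, DNA input, ligation proxy."""

    barcode: str
    material: str = MATERIAL_SAMPLE
    replicate_group: str = ""
    input_dna_ng: float = 100.0
    throughput_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.throughput_multiplier <= 0:
            raise ValueError(f"{self.barcode!r}: throughput_multiplier must be > 0")
        if self.input_dna_ng <= 0:
            raise ValueError(f"{self.barcode!r}: input_dna_ng must be > 0")


@dataclass
class RunSpec:
    """Run-level simulation parameters shared by all barcodes."""

    barcodes: list[BarcodeSpec]
    read_length_mu: float = DEFAULT_READ_LENGTH_MU
    read_length_sigma: float = DEFAULT_READ_LENGTH_SIGMA
    #: "error_free" or ("uniform_sub", substitution_rate)
    error_model: str | tuple[str, float] = "error_free"
    #: per-taxon multiplicative factor shared across barcodes (extraction bias)
    extraction_bias: dict[str, float] | None = None
    #: σ (natural log) of i.i.d. per-(barcode, taxon) lognormal weight noise
    abundance_noise_sigma: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.extraction_bias and any(v <= 0 for v in self.extraction_bias.values()):
            raise ValueError("extraction bias factors must be > 0")

    def barcode_spec(self, barcode: str) -> BarcodeSpec:
        for spec in self.barcodes:
            if spec.barcode == barcode:
                return spec
        raise KeyError(f"unknown barcode {barcode!r}")


def _barcode_rng(seed: int, barcode: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(barcode.encode()), salt])


def simulate_genomes(
    community: CommunitySpec, seed: int
) -> dict[str, str]:
    """I.i.d. nucleotide sequences at each taxon's GC content, per-seed stable."""
    genomes: dict[str, str] = {}
    for taxon in community.taxa:
        rng = _barcode_rng(seed, taxon.genome_id, salt=1)
        gc = taxon.gc_content
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        codes = rng.choice(4, size=taxon.genome_length, p=probs)
        genomes[taxon.genome_id] = (
            np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
        )
    return genomes


def _substitution_rate(error_model: str | tuple[str, float]) -> float:
    if error_model == "error_free":
        return 0.0
    if isinstance(error_model, tuple) and error_model[0] == "uniform_sub":
        return float(error_model[1])
    raise ValueError(f"unknown error model {error_model!r}")


def simulate_barcode_reads(
    community: CommunitySpec,
    run: RunSpec,
    barcode: str,
    target_bases: int,
    genomes: Mapping[str, str] | None = None,
    with_sequences: bool = False,
) -> tuple[BarcodeLibrary, list[AlignmentRecord]]:
    """Draw one barcode's reads and their truth alignments.

    Reads are drawn from taxa with probability ∝ copies × length × bias
    (× lognormal noise when configured); starts are uniform on the genome
    and lognormal lengths are truncated at the genome end. The total base
    count is ≈ ``target_bases × throughput_multiplier`` (the read crossing
    the total is included). Each read gets one primary full-span truth
    alignment. Sequence payloads are materialized only on request.
    """
    spec = run.barcode_spec(barcode)
    rng = _barcode_rng(run.seed, barcode)
    total = int(round(target_bases * spec.throughput_multiplier))

    n_taxa = len(community.taxa)
    lengths_by_taxon = np.array([t.genome_length for t in community.taxa], dtype=np.int64)
    weights = np.array(
        [t.theoretical_copies * t.genome_length for t in community.taxa], dtype=float
    )
    if run.extraction_bias:
        weights *= np.array(
            [run.extraction_bias.get(t.genome_id, 1.0) for t in community.taxa]
        )
    if run.abundance_noise_sigma > 0:
        weights *= np.exp(rng.normal(0.0, run.abundance_noise_sigma, size=n_taxa))
    weights /= weights.sum()

    # draw lognormal lengths until the cumulative total crosses the target
    mean_len = math.exp(run.read_length_mu + run.read_length_sigma**2 / 2)
    read_lengths = np.empty(0, dtype=np.int64)
    while read_lengths.sum() < total:
        deficit = total - int(read_lengths.sum())
        chunk = max(int(deficit / mean_len * 1.2) + 16, 16)
        drawn = rng.lognormal(run.read_length_mu, run.read_length_sigma, size=chunk)
        read_lengths = np.concatenate([
            read_lengths, np.maximum(np.round(drawn).astype(np.int64), 1)
        ])
    cutoff = int(np.searchsorted(np.cumsum(read_lengths), total)) + 1
    read_lengths = read_lengths[:cutoff]
    n_reads = read_lengths.size

    taxon_idx = rng.choice(n_taxa, size=n_reads, p=weights)
    genome_len = lengths_by_taxon[taxon_idx]
    starts = np.floor(rng.random(n_reads) * genome_len).astype(np.int64)
    ends = np.minimum(starts + read_lengths, genome_len)
    final_lengths = ends - starts

    sub_rate = _substitution_rate(run.error_model)
    quality = 20.0 if sub_rate == 0 else float(-10.0 * math.log10(sub_rate))

    genome_ids = [t.genome_id for t in community.taxa]
    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    for i in range(n_reads):
        gid = genome_ids[taxon_idx[i]]
        read_id = f"{barcode}_r{i:07d}"
        sequence = None
        if with_sequences:
            if genomes is None:
                raise ValueError("with_sequences requires simulated genome sequences")
            sequence = genomes[gid][starts[i]:ends[i]]
            if sub_rate > 0:
                seq = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(seq.size) < sub_rate)[0]
                if hits.size:
                    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
                    seq[hits] = alphabet[rng.choice(4, size=hits.size)]
                sequence = seq.tobytes().decode("ascii")
        reads.append(ReadRecord(
            read_id=read_id, length=int(final_lengths[i]), mean_quality=quality,
            barcode=barcode, sequence=sequence,
        ))
        alignments.append(AlignmentRecord(
            read_id=read_id, genome_id=gid,
            target_start=int(starts[i]), target_end=int(ends[i]),
            is_primary=True, barcode=barcode,
        ))
    library = BarcodeLibrary(
        barcode=barcode, material=spec.material,
        replicate_group=spec.replicate_group, input_dna_ng=spec.input_dna_ng,
        reads=reads,
    )
    return library, alignments


@dataclass
class SimulatedExperiment:
    """An in-memory mock run: libraries, truth alignments, and truth tables."""

    spike_community: CommunitySpec
    sample_community: CommunitySpec
    run: RunSpec
    libraries: dict[str, BarcodeLibrary]
    alignments: dict[str, list[AlignmentRecord]]

    @property
    def spike_truth(self) -> dict[str, float]:
        return self.spike_community.truth

    @property
    def sample_truth(self) -> dict[str, float]:
        return self.sample_community.truth

    def barcodes(self, material: str) -> list[str]:
        return [b.barcode for b in self.run.barcodes if b.material == material]

    def lengths(self, material: str) -> dict[str, int]:
        community = (
            self.spike_community if material == MATERIAL_SPIKE_IN else self.sample_community
        )
        return community.lengths


def simulate_experiment(
    spike_community: CommunitySpec,
    sample_community: CommunitySpec,
    run: RunSpec,
    target_bases: int | Mapping[str, int],
    genomes: Mapping[str, str] | None = None,
    with_sequences: bool = False,
) -> SimulatedExperiment:
    """Simulate every barcode of a run (spike-in and sample materials).

    ``target_bases`` may be a single int or a per-material mapping
    (``{"spike_in": ..., "sample": ...}``).
    """
    libraries: dict[str, BarcodeLibrary] = {}
    alignments: dict[str, list[AlignmentRecord]] = {}
    for spec in run.barcodes:
        community = spike_community if spec.material == MATERIAL_SPIKE_IN else sample_community
        target = (
            target_bases if isinstance(target_bases, int) else int(target_bases[spec.material])
        )
        library, alns = simulate_barcode_reads(
            community, run, spec.barcode, target, genomes=genomes,
            with_sequences=with_sequences,
        )
        libraries[spec.barcode] = library
        alignments[spec.barcode] = alns
    return SimulatedExperiment(
        spike_community=spike_community, sample_community=sample_community,
        run=run, libraries=libraries, alignments=alignments,
    )


# ---------------------------------------------------------------------------
# file emission (FASTA / FASTQ / truth PAF / truth tables)
# ---------------------------------------------------------------------------

def write_genomes_fasta(genomes: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for genome_id, seq in genomes.items():
            handle.write(f">{genome_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def write_manifest_for_communities(
    communities: Mapping[str, CommunitySpec], fasta_names: Mapping[str, str],
    path: str | Path,
) -> None:
    """Reference manifest TSV for simulated (single-contig) genomes.

    ``communities`` maps material ("spike_in"/"sample") to its community;
    ``fasta_names`` maps material to the FASTA filename written next to the
    manifest.
    """
    role = {MATERIAL_SPIKE_IN: "spike_in", MATERIAL_SAMPLE: "sample_reference"}
    with open(path, "w") as handle:
        handle.write("genome_id\tfasta_path\tcontig_ids\ttaxonomy\trole\n")
        for material, community in communities.items():
            for taxon in community.taxa:
                taxonomy = f"d__Bacteria;p__;c__;o__;f__;g__{taxon.genome_id};s__{taxon.genome_id}"
                handle.write(
                    f"{taxon.genome_id}\t{fasta_names[material]}\t{taxon.genome_id}\t"
                    f"{taxonomy}\t{role[material]}\n"
                )


def write_truth_paf(
    alignments: Sequence[AlignmentRecord],
    lengths: Mapping[str, int],
    read_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Truth alignments as minimap2-dialect PAF (primary, full-span)."""
    with open(path, "w") as handle:
        for aln in alignments:
            qlen = read_lengths[aln.read_id]
            span = aln.target_end - aln.target_start
            handle.write(
                f"{aln.read_id}\t{qlen}\t0\t{span}\t+\t{aln.genome_id}\t"
                f"{lengths[aln.genome_id]}\t{aln.target_start}\t{aln.target_end}\t"
                f"{span}\t{span}\t60\ttp:A:P\n"
            )


def write_truth_tables(
    community: CommunitySpec, run: RunSpec, outdir: str | Path, stem: str = "truth"
) -> dict[str, Path]:
    """Machine-readable truth: copies/abundances, barcode metadata, biases."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rel = community.rel_abundances()
    truth_path = outdir / f"{stem}.tsv"
    with open(truth_path, "w") as handle:
        handle.write("genome_id\ttheoretical_copies\ttheoretical_rel_abundance\n")
        for taxon in community.taxa:
            handle.write(
                f"{taxon.genome_id}\t{taxon.theoretical_copies!r}\t{rel[taxon.genome_id]!r}\n"
            )
    meta_path = outdir / "barcodes.tsv"
    with open(meta_path, "w") as handle:
        handle.write("barcode\tmaterial\treplicate_group\tinput_dna_ng\tthroughput_multiplier\n")
        for spec in run.barcodes:
            handle.write(
                f"{spec.barcode}\t{spec.material}\t{spec.replicate_group}\t"
                f"{spec.input_dna_ng!r}\t{spec.throughput_multiplier!r}\n"
            )
    bias_path = outdir / "bias.tsv"
    with open(bias_path, "w") as handle:
        handle.write("genome_id\textraction_bias\n")
        for taxon in community.taxa:
            factor = (run.extraction_bias or {}).get(taxon.genome_id, 1.0)
            handle.write(f"{taxon.genome_id}\t{factor!r}\n")
    return {"truth": truth_path, "barcodes": meta_path, "bias": bias_path}
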