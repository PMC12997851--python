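"""Per-barcode read QC filtering and seeded subsampling to a base target.

Long-read runs are filtered in real time on the instrument: reads with a mean
quality below Q7 or shorter than 200 bp are removed. Sequencing-effort
titrations then randomly subsample each barcode's reads down to a target
number of bases. Both operations are reproduced here with explicit semantics:

* thresholds are removals of *strictly* sub-threshold reads, so boundary
  values (exactly Q7, exactly 200 bp) are kept;
* mean read quality is the Phred score of the mean per-base error
  probability (the basecaller convention), not the arithmetic mean of Q;
* subsampling shuffles reads with a seeded RNG and takes them in order until
  the cumulative base count reaches the target, including the read that
  crosses it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUALITY = 7.0
DEFAULT_MIN_LENGTH = 200
DEFAULT_SEED = 42

MATERIAL_SPIKE_IN = "spike_in"
MATERIAL_SAMPLE = "sample"


@dataclass(slots=True)
class ReadRecord:
    """One long read; sequence/quality payloads are optional."""

    read_id: str
    length: int
    mean_quality: float
    barcode: str = ""
    sequence: str | None = None
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"read {self.read_id!r}: negative length")
        if self.mean_quality < 0:
            raise ValueError(f"read {self.read_id!r}: negative mean quality")


@dataclass
class BarcodeLibrary:
    """All reads of one barcode, plus the library-level metadata BEF needs."""

    barcode: str
    material: str = MATERIAL_SAMPLE
    replicate_group: str = ""
    input_dna_ng: float = 1.0
    reads: list[ReadRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.input_dna_ng <= 0:
            raise ValueError(f"barcode {self.barcode!r}: input_dna_ng must be > 0")

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(slots=True)
class FilterStats:
    """Read/base accounting of one filtering pass (conserved: in = kept + dropped)."""

    reads_in: int
    reads_kept: int
    bases_in: int
    bases_kept: int

    @property
    def reads_dropped(self) -> int:
        return self.reads_in - self.reads_kept

    @property
    def bases_dropped(self) -> int:
        return self.bases_in - self.bases_kept


def mean_read_quality(per_base_phred: Sequence[int] | np.ndarray) -> float:
    """Phred-scaled mean quality: −10·log10 of the mean per-base error rate."""
    q = np.asarray(per_base_phred, dtype=float)
    if q.size == 0:
        raise ValueError("cannot compute mean quality of an empty quality string")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    library: BarcodeLibrary,
    min_q: float = DEFAULT_MIN_QUALITY,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> tuple[BarcodeLibrary, FilterStats]:
    """Remove reads with mean quality < ``min_q`` or length < ``min_len``.

    Boundary reads (exactly at a threshold) are kept.
    """
    kept = [r for r in library.reads if r.mean_quality >= min_q and r.length >= min_len]
    stats = FilterStats(
        reads_in=len(library.reads),
        reads_kept=len(kept),
        bases_in=library.total_bases,
        bases_kept=sum(r.length for r in kept),
    )
    logger.info(
        "barcode %s: QC filter kept %d/%d reads (%d/%d bases)",
        library.barcode, stats.reads_kept, stats.reads_in,
        stats.bases_kept, stats.bases_in,
    )
    return replace(library, reads=kept), stats


def subsample_to_bases(
    library: BarcodeLibrary, target_bases: int, seed: int = DEFAULT_SEED
) -> BarcodeLibrary:
    """Random read-granular subsample to ≥ ``target_bases`` cumulative bases.

    Reads are shuffled by a seeded RNG and taken in order until the running
    base total reaches the target; the read crossing the target is included,
    so the output satisfies ``target ≤ bases < target + max read length``.
    If the library already holds ≤ target bases it is returned unchanged.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be > 0")
    if library.total_bases <= target_bases:
        return library
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(library.reads))
    lengths = np.fromiter((library.reads[i].length for i in order), dtype=np.int64)
    cutoff = int(np.searchsorted(np.cumsum(lengths), target_bases)) + 1
    kept = [library.reads[i] for i in order[:cutoff]]
    return replace(library, reads=kept)


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(
    path: str | Path,
    barcode: str,
    material: str = MATERIAL_SAMPLE,
    replicate_group: str = "",
    input_dna_ng: float = 1.0,
    keep_payload: bool = False,
) -> BarcodeLibrary:
    """Load one demultiplexed FASTQ (gz-transparent) into a BarcodeLibrary."""
    reads: list[ReadRecord] = []
    with _open_text(Path(path)) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            reads.append(ReadRecord(
                read_id=rec.id,
                length=len(rec.seq),
                mean_quality=mean_read_quality(quals) if quals else 0.0,
                barcode=barcode,
                sequence=str(rec.seq) if keep_payload else None,
                qualities=list(quals) if keep_payload else None,
            ))
    return BarcodeLibrary(
        barcode=barcode, material=material, replicate_group=replicate_group,
        input_dna_ng=input_dna_ng, reads=reads,
    )


def write_fastq(library: BarcodeLibrary, path: str | Path) -> None:
    """Write a library (reads must carry sequence payloads) as FASTQ."""
    with _open_text(Path(path), "wt") as handle:
        for read in library.reads:
            if read.sequence is None:
                raise ValueError(f"read {read.read_id!r} has no sequence payload")
            quals = read.qualities
            if quals is None:
                quals = [int(round(read.mean_quality))] * read.length
            qual_str = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual_str}\n")


def write_filter_summary(
    stats: dict[str, FilterStats], path: str | Path
) -> None:
    """Per-barcode read/base accounting TSV."""
    with open(path, "w") as handle:
        handle.write("barcode\treads_in\treads_out\tbases_in\tbases_out\n")
        for barcode, s in stats.items():
            handle.write(f"{barcode}\t{s.reads_in}\t{s.reads_kept}\t{s.bases_in}\t{s.bases_kept}\n")
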