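"""Genome-level coverage statistics from read-to-genome alignments.

Detection and quantitation both rest on three per-genome, per-barcode numbers
derived from primary alignments:

* **mapped bases** ``M_g`` — the sum of target-interval spans (includes
  deletions inside the aligned span, excludes soft-clips);
* **covered bases** ``C_g`` — the size of the union of target intervals,
  i.e. the number of distinct genome positions touched by ≥1 alignment;
* **coverage fraction** ``f_g = C_g / L_g`` — the detection (LOD) statistic.

``depth`` is defined as ``M_g / L_g``. Coordinates are 0-based half-open
everywhere (PAF-native); SAM input is converted on parse. Multi-contig
genomes use the concatenated contig coordinates defined by the reference
manifest. Secondary alignments are always excluded; supplementary alignments
are excluded by default (``count_supplementary`` includes them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .reference_db import ReferenceDB

#: Either a full ReferenceDB or a plain {genome_id: length} mapping.
GenomeLengths = Union[ReferenceDB, Mapping[str, int]]


@dataclass(slots=True)
class AlignmentRecord:
    """One read-to-genome alignment with its target interval (0-based, half-open)."""

    read_id: str
    genome_id: str
    target_start: int
    target_end: int
    is_primary: bool = True
    barcode: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"alignment {self.read_id!r} on {self.genome_id!r}: "
                f"invalid interval [{self.target_start}, {self.target_end})"
            )

    @property
    def span(self) -> int:
        return self.target_end - self.target_start


@dataclass(slots=True)
class CoverageSummary:
    """Per-genome per-barcode coverage statistics."""

    genome_id: str
    barcode: str
    mapped_bases: int
    covered_bases: int
    genome_length: int

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bases / self.genome_length

    @property
    def depth(self) -> float:
        return self.mapped_bases / self.genome_length


def _contig_resolver(db: GenomeLengths):
    """Return fn(contig) -> (genome_id, offset, genome_length)."""
    if isinstance(db, ReferenceDB):
        def resolve(contig: str) -> tuple[str, int, int]:
            genome_id, offset, _ = db.resolve_contig(contig)
            return genome_id, offset, db.genome_length(genome_id)
    else:
        def resolve(contig: str) -> tuple[str, int, int]:
            if contig not in db:
                raise KeyError(f"contig {contig!r} not present in reference manifest")
            return contig, 0, int(db[contig])
    return resolve


def parse_paf(
    source: str | Path | IO[str] | Iterable[str],
    db: GenomeLengths,
    barcode: str = "",
) -> list[AlignmentRecord]:
    """Parse a minimap2-style PAF stream into genome-coordinate alignments.

    Secondary alignments (``tp:A:S``) and inversion fragments (``tp:A:I``)
    are excluded; records without a ``tp`` tag count as primary. Target
    (contig) coordinates are offset into the genome's concatenated
    coordinates via the manifest. Malformed lines raise with a line number;
    unknown contigs are a hard error naming the contig.
    """
    resolve = _contig_resolver(db)
    close = False
    if isinstance(source, (str, Path)):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    records: list[AlignmentRecord] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"malformed PAF line {lineno}: expected ≥12 fields")
            try:
                contig = fields[5]
                t_start = int(fields[7])
                t_end = int(fields[8])
            except ValueError as exc:
                raise ValueError(f"malformed PAF line {lineno}: {exc}") from None
            tp = "P"
            for tag in fields[12:]:
                if tag.startswith("tp:A:"):
                    tp = tag[5:]
                    break
            if tp in ("S", "I", "i"):
                continue
            genome_id, offset, _ = resolve(contig)
            records.append(AlignmentRecord(
                read_id=fields[0],
                genome_id=genome_id,
                target_start=offset + t_start,
                target_end=offset + t_end,
                is_primary=True,
                barcode=barcode,
            ))
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return records


def parse_sam(
    path: str | Path,
    db: GenomeLengths,
    barcode: str = "",
    count_supplementary: bool = False,
) -> list[AlignmentRecord]:
    """Parse SAM/BAM alignments (via pysam) into genome-coordinate records.

    Unmapped and secondary (0x100) records are excluded; supplementary
    (0x800) records are excluded unless ``count_supplementary``.
    """
    import pysam

    resolve = _contig_resolver(db)
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.is_supplementary and not count_supplementary:
                continue
            genome_id, offset, _ = resolve(aln.reference_name)
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                genome_id=genome_id,
                target_start=offset + aln.reference_start,
                target_end=offset + aln.reference_end,
                is_primary=not aln.is_supplementary,
                barcode=barcode,
            ))
    return records


def interval_union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length of the union of half-open intervals (sort-and-sweep)."""
    if starts.size == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = ends[order]
    running_max = np.maximum.accumulate(e)
    prev_max = np.empty_like(running_max)
    prev_max[0] = s[0]  # first interval contributes fully
    prev_max[1:] = running_max[:-1]
    contrib = e - np.maximum(s, prev_max)
    return int(np.clip(contrib, 0, None).sum())


def summarize_coverage(
    alignments: Iterable[AlignmentRecord],
    db: GenomeLengths,
    barcode: str,
    include_supplementary: bool = True,
) -> dict[str, CoverageSummary]:
    """Aggregate alignments into one :class:`CoverageSummary` per genome.

    Every genome in the database gets a row, including zero rows for genomes
    with no alignments. Records flagged non-primary are skipped unless
    ``include_supplementary`` (parsers already drop secondaries).
    """
    lengths = db.lengths() if isinstance(db, ReferenceDB) else dict(db)
    by_genome: dict[str, list[tuple[int, int]]] = {gid: [] for gid in lengths}
    for aln in alignments:
        if not aln.is_primary and not include_supplementary:
            continue
        if aln.genome_id not in by_genome:
            raise KeyError(f"alignment targets unknown genome {aln.genome_id!r}")
        if aln.target_end > lengths[aln.genome_id]:
            raise ValueError(
                f"alignment on {aln.genome_id!r} ends at {aln.target_end} "
                f"beyond genome length {lengths[aln.genome_id]}"
            )
        by_genome[aln.genome_id].append((aln.target_start, aln.target_end))

    summaries: dict[str, CoverageSummary] = {}
    for genome_id, intervals in by_genome.items():
        if intervals:
            arr = np.asarray(intervals, dtype=np.int64)
            mapped = int((arr[:, 1] - arr[:, 0]).sum())
            covered = interval_union_length(arr[:, 0], arr[:, 1])
        else:
            mapped = covered = 0
        summaries[genome_id] = CoverageSummary(
            genome_id=genome_id,
            barcode=barcode,
            mapped_bases=mapped,
            covered_bases=covered,
            genome_length=lengths[genome_id],
        )
    return summaries


def restrict_alignments(
    alignments: Iterable[AlignmentRecord], read_ids: Iterable[str]
) -> list[AlignmentRecord]:
    """Keep only alignments whose read is in ``read_ids`` (post-subsampling)."""
    keep = set(read_ids)
    return [a for a in alignments if a.read_id in keep]


def coverage_to_dataframe(
    summaries: Iterable[CoverageSummary] | Mapping[str, CoverageSummary],
) -> pd.DataFrame:
    if isinstance(summaries, Mapping):
        summaries = summaries.values()
    rows = [
        {
            "genome_id": s.genome_id,
            "barcode": s.barcode,
            "mapped_bases": s.mapped_bases,
            "covered_bases": s.covered_bases,
            "genome_length": s.genome_length,
            "coverage_fraction": s.coverage_fraction,
            "depth": s.depth,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=[
        "genome_id", "barcode", "mapped_bases", "covered_bases",
        "genome_length", "coverage_fraction", "depth",
    ])


def write_coverage_tsv(
    summaries_by_barcode: Mapping[str, Mapping[str, CoverageSummary]],
    path: str | Path,
) -> None:
    frames = [coverage_to_dataframe(s) for s in summaries_by_barcode.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> dict[str, dict[str, CoverageSummary]]:
    """Inverse of :func:`write_coverage_tsv`: barcode -> genome -> summary."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, CoverageSummary]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.barcode), {})[str(row.genome_id)] = CoverageSummary(
            genome_id=str(row.genome_id),
            barcode=str(row.barcode),
            mapped_bases=int(row.mapped_bases),
            covered_bases=int(row.covered_bases),
            genome_length=int(row.genome_length),
        )
    return out
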