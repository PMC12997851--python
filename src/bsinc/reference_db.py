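"""Reference genome databases, taxonomy, and spike-in truth tables.

A reference database maps every alignment target (contig) to a genome-level
record. Genomes may be multi-contig (draft genomes / MAGs are first-class):
the manifest assigns contigs to a ``genome_id`` and the genome length is the
sum of its contig lengths. All coverage statistics downstream are genome-level
aggregates over the concatenated contig coordinate system defined by the
manifest's contig order.

Manifest format (TSV with header)::

    genome_id  fasta_path  contig_ids  taxonomy  role

``contig_ids`` is a comma-separated list in concatenation order, or ``*`` to
claim every sequence of the FASTA in file order. ``taxonomy`` is a 7-rank
semicolon string (GTDB-style ``d__...;p__...;...;s__...`` prefixes accepted);
unknown ranks may be empty. ``role`` is ``spike_in`` or ``sample_reference``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: GTDB-style single-letter rank prefixes, e.g. ``g__Nitrospira``.
_PREFIX_TO_RANK = {
    "d": "domain",
    "k": "domain",  # kingdom used interchangeably by some taxonomies
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

ROLE_SPIKE_IN = "spike_in"
ROLE_SAMPLE_REFERENCE = "sample_reference"
_VALID_ROLES = (ROLE_SPIKE_IN, ROLE_SAMPLE_REFERENCE)


def parse_taxonomy(text: str) -> dict[str, str]:
    """Parse a semicolon-separated taxonomy string into an ordered rank map.

    Accepts GTDB-style prefixed fields (``g__Gordonia``) or plain positional
    fields (domain..species order). Missing ranks are stored as ``""``.
    """
    taxonomy = {rank: "" for rank in RANKS}
    fields = [f.strip() for f in text.split(";")] if text else []
    positional = [f for f in fields if f and "__" not in f]
    for i, value in enumerate(fields):
        if not value:
            continue
        if "__" in value:
            prefix, _, name = value.partition("__")
            rank = _PREFIX_TO_RANK.get(prefix.lower())
            if rank is not None:
                taxonomy[rank] = name.strip()
            continue
        if i < len(RANKS) and positional:
            taxonomy[RANKS[i]] = value
    return taxonomy


def format_taxonomy(taxonomy: Mapping[str, str]) -> str:
    """Inverse of :func:`parse_taxonomy` (GTDB-style prefixes)."""
    inverse = {"domain": "d", "phylum": "p", "class": "c", "order": "o",
               "family": "f", "genus": "g", "species": "s"}
    return ";".join(f"{inverse[r]}__{taxonomy.get(r, '')}" for r in RANKS)


@dataclass(slots=True)
class GenomeRecord:
    """One reference genome (possibly multi-contig)."""

    genome_id: str
    length: int
    taxonomy: dict[str, str]
    role: str = ROLE_SAMPLE_REFERENCE
    #: (contig_id, contig_length) in concatenation order.
    contigs: tuple[tuple[str, int], ...] = ()
    fasta_path: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome {self.genome_id!r}: length must be > 0")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"genome {self.genome_id!r}: invalid role {self.role!r}")
        if self.contigs and sum(l for _, l in self.contigs) != self.length:
            raise ValueError(
                f"genome {self.genome_id!r}: contig lengths do not sum to genome length"
            )

    def contig_offsets(self) -> dict[str, int]:
        """Offset of each contig in the genome's concatenated coordinates."""
        offsets: dict[str, int] = {}
        pos = 0
        for contig_id, contig_len in self.contigs:
            offsets[contig_id] = pos
            pos += contig_len
        return offsets


@dataclass(slots=True)
class SpikeInTruth:
    """Theoretical genome copies of one spike-in genome per barcode library."""

    genome_id: str
    theoretical_copies: float
    theoretical_rel_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.theoretical_copies <= 0:
            raise ValueError(
                f"spike-in {self.genome_id!r}: theoretical_copies must be > 0"
            )


class ReferenceDB:
    """Collection of :class:`GenomeRecord` with contig-to-genome resolution."""

    def __init__(self, records: Iterable[GenomeRecord] = ()) -> None:
        self._records: dict[str, GenomeRecord] = {}
        #: contig_id -> (genome_id, offset_in_genome, contig_length)
        self.contig_map: dict[str, tuple[str, int, int]] = {}
        for record in records:
            self.add(record)

    def add(self, record: GenomeRecord) -> None:
        if record.genome_id in self._records:
            raise ValueError(f"duplicate genome_id {record.genome_id!r}")
        contigs = record.contigs or ((record.genome_id, record.length),)
        offsets = {}
        pos = 0
        for contig_id, contig_len in contigs:
            if contig_id in self.contig_map:
                raise ValueError(f"contig {contig_id!r} claimed by two genomes")
            offsets[contig_id] = (record.genome_id, pos, contig_len)
            pos += contig_len
        self._records[record.genome_id] = record
        self.contig_map.update(offsets)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self._records.values())

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._records

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._records[genome_id]

    @property
    def genome_ids(self) -> list[str]:
        return list(self._records)

    def genome_length(self, genome_id: str) -> int:
        return self._records[genome_id].length

    def lengths(self) -> dict[str, int]:
        return {gid: rec.length for gid, rec in self._records.items()}

    def by_role(self, role: str) -> list[GenomeRecord]:
        return [r for r in self._records.values() if r.role == role]

    def resolve_contig(self, contig_id: str) -> tuple[str, int, int]:
        """Return (genome_id, offset, contig_length) for a contig.

        Raises ``KeyError`` naming the contig if it is unknown.
        """
        try:
            return self.contig_map[contig_id]
        except KeyError:
            raise KeyError(f"contig {contig_id!r} not present in reference manifest") from None

    def write_manifest(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["genome_id", "fasta_path", "contig_ids", "taxonomy", "role"])
            for record in self:
                contig_ids = ",".join(c for c, _ in record.contigs) if record.contigs else "*"
                writer.writerow([
                    record.genome_id,
                    record.fasta_path,
                    contig_ids,
                    format_taxonomy(record.taxonomy),
                    record.role,
                ])


def _fasta_lengths(path: Path) -> dict[str, int]:
    """Sequence lengths of a FASTA file, in file order."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reference_manifest(manifest_path: str | Path) -> ReferenceDB:
    """Load a reference database from a manifest TSV.

    Genome lengths are read from the referenced FASTA files (relative paths
    resolve against the manifest's directory). Every sequence present in a
    referenced FASTA must be claimed by some manifest row; an unclaimed contig
    is a hard error naming the contig.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    fasta_cache: dict[Path, dict[str, int]] = {}
    claimed: dict[Path, set[str]] = {}
    db = ReferenceDB()

    with manifest_path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        rows = list(reader)

    if not rows:
        logger.warning("empty reference manifest %s: empty database", manifest_path)
        return db

    for row in rows:
        genome_id = row["genome_id"].strip()
        fasta_path = (base / row["fasta_path"]).resolve()
        if fasta_path not in fasta_cache:
            fasta_cache[fasta_path] = _fasta_lengths(fasta_path)
            claimed[fasta_path] = set()
        lengths = fasta_cache[fasta_path]
        spec = row.get("contig_ids", "*").strip() or "*"
        if spec == "*":
            contig_ids = list(lengths)
        else:
            contig_ids = [c.strip() for c in spec.split(",") if c.strip()]
        contigs = []
        for contig_id in contig_ids:
            if contig_id not in lengths:
                raise ValueError(
                    f"genome {genome_id!r}: contig {contig_id!r} not found in {fasta_path}"
                )
            contigs.append((contig_id, lengths[contig_id]))
        claimed[fasta_path].update(contig_ids)
        db.add(GenomeRecord(
            genome_id=genome_id,
            length=sum(l for _, l in contigs),
            taxonomy=parse_taxonomy(row.get("taxonomy", "")),
            role=row.get("role", ROLE_SAMPLE_REFERENCE).strip() or ROLE_SAMPLE_REFERENCE,
            contigs=tuple(contigs),
            fasta_path=row["fasta_path"],
        ))

    for fasta_path, lengths in fasta_cache.items():
        unclaimed = set(lengths) - claimed[fasta_path]
        if unclaimed:
            name = sorted(unclaimed)[0]
            raise ValueError(
                f"contig {name!r} present in {fasta_path} but absent from manifest"
            )
    return db


def load_spikein_truth(path: str | Path, db: ReferenceDB | None = None) -> list[SpikeInTruth]:
    """Load a spike-in truth table (TSV: genome_id, theoretical_copies).

    Relative abundances are computed as copies / Σ copies. If ``db`` is given,
    every genome_id must exist in it.
    """
    path = Path(path)
    entries: list[tuple[str, float]] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            genome_id = row["genome_id"].strip()
            copies = float(row["theoretical_copies"])
            if copies <= 0:
                raise ValueError(f"spike-in {genome_id!r}: nonpositive theoretical_copies")
            if db is not None and genome_id not in db:
                raise ValueError(f"spike-in {genome_id!r} not present in reference database")
            entries.append((genome_id, copies))
    total = sum(c for _, c in entries)
    return [
        SpikeInTruth(genome_id=g, theoretical_copies=c, theoretical_rel_abundance=c / total)
        for g, c in entries
    ]


def truth_as_mapping(truth: Iterable[SpikeInTruth] | Mapping[str, float]) -> dict[str, float]:
    """Normalize a truth table argument to ``{genome_id: theoretical_copies}``."""
    if isinstance(truth, Mapping):
        return dict(truth)
    return {t.genome_id: t.theoretical_copies for t in truth}
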