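"""Sequence and profile-database input/output.

Reference genomes arrive as FASTA — either one file per genome (the file
stem names the genome) or a multi-FASTA plus a two-column manifest mapping
record ids to genome ids, mirroring how archives of microbial genomes group
replicons (chromosome + plasmids) per strain. Reads arrive as FASTA or
FASTQ. All sequences are upper-cased on load; characters outside A/C/G/T
are retained so coordinates stay faithful, but they never contribute
motifs.

Simulated reads carry their genome of origin in the read id, using the
convention ``<genome_id>|<ordinal>|<start>|<strand>``; any id whose first
``|``-separated field names a genome is recognized as a truth label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "ReadRecord",
    "FormatError",
    "read_fasta",
    "read_genomes",
    "read_manifest",
    "read_reads",
    "write_fasta",
    "write_reads",
    "parse_truth_genome_id",
    "write_profile_db",
    "load_profile_db",
]


class FormatError(ValueError):
    """A sequence file does not parse in the expected format."""


@dataclass
class GenomeRecord:
    """One named reference genome: an ordered list of replicon sequences.

    ``total_length`` (the genome length L) is the sum of record lengths;
    the splitter addresses the genome through concatenated coordinates
    [0, L) in record order.
    """

    genome_id: str
    records: list[tuple[str, str]]  # (record_id, sequence)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)

    def concatenated(self) -> str:
        return "".join(s for _, s in self.records)

    @classmethod
    def from_sequence(cls, genome_id: str, sequence: str) -> "GenomeRecord":
        return cls(genome_id, [(genome_id, sequence.upper())])


@dataclass
class ReadRecord:
    """A sequenced read (DNA fragment), optionally with a truth label."""

    read_id: str
    sequence: str
    truth_genome_id: str | None = None
    qualities: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")


def parse_truth_genome_id(read_id: str) -> str | None:
    """Extract the source genome from a simulator-labelled read id."""
    if "|" in read_id:
        return read_id.split("|", 1)[0]
    return None


def _check_fasta_shape(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            return
    raise FormatError(f"{path}: empty FASTA file (no records)")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (record_id, upper-cased sequence) pairs.

    The record id is the header token before the first whitespace; record
    order is file order. Empty or malformed files raise :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    _check_fasta_shape(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a TSV manifest ``record_id <tab> genome_id``."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_genomes(
    paths: Sequence[str | Path] | str | Path,
    manifest: str | Path | dict[str, str] | None = None,
) -> list[GenomeRecord]:
    """Load reference genomes from one or more FASTA files.

    Without a manifest, each file is one genome named by its file stem.
    With a manifest (TSV record_id→genome_id, or an equivalent dict),
    records from all files are grouped by their mapped genome id; the
    manifest wins over file grouping. Records absent from the manifest
    raise an error rather than being silently dropped.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    mapping: dict[str, str] | None
    if manifest is None:
        mapping = None
    elif isinstance(manifest, dict):
        mapping = manifest
    else:
        mapping = read_manifest(manifest)

    genomes: dict[str, GenomeRecord] = {}
    for p in paths:
        p = Path(p)
        records = read_fasta(p)
        if mapping is None:
            gid = p.stem
            if gid in genomes:
                raise ValueError(f"duplicate genome_id {gid!r} (from {p})")
            genomes[gid] = GenomeRecord(gid, records)
        else:
            for rid, seq in records:
                if rid not in mapping:
                    raise ValueError(f"record {rid!r} in {p} is missing from the manifest")
                gid = mapping[rid]
                genomes.setdefault(gid, GenomeRecord(gid, [])).records.append((rid, seq))
    return list(genomes.values())


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise FormatError(f"{path}: cannot sniff format from leading character {line[0]!r}")
    return "empty"


def read_reads(path: str | Path, format: str = "auto") -> list[ReadRecord]:
    """Load sequenced reads from FASTA or FASTQ.

    Truth labels are populated from read ids that follow the simulator's
    labelling convention. An empty file yields an empty list with a
    warning rather than an error, so pipelines survive empty partitions.
    """
    path = Path(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "empty":
        logger.warning("%s: empty reads file", path)
        return []
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown reads format {format!r}")
    out: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            quals = None
            if format == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            out.append(
                ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    truth_genome_id=parse_truth_genome_id(rec.id),
                    qualities=quals,
                )
            )
    except ValueError as exc:  # biopython signals malformed records this way
        raise FormatError(f"{path}: {exc}") from exc
    if not out:
        logger.warning("%s: no records parsed", path)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads(reads: Iterable[ReadRecord], path: str | Path, format: str = "fasta") -> None:
    """Write reads as FASTA or FASTQ (constant Q40 when qualities absent)."""
    with open(path, "w") as fh:
        for r in reads:
            if format == "fasta":
                fh.write(f">{r.read_id}\n{r.sequence}\n")
            elif format == "fastq":
                if r.qualities is not None:
                    qual = "".join(chr(q + 33) for q in r.qualities)
                else:
                    qual = "I" * len(r.sequence)
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            else:
                raise ValueError(f"unknown reads format {format!r}")


def write_profile_db(db, path: str | Path) -> None:
    """Persist a profile database; see :func:`motifbayes.profiles.save_database`."""
    from .profiles import save_database

    save_database(db, path)


def load_profile_db(path: str | Path, k: int | None = None):
    """Load a profile database; see :func:`motifbayes.profiles.load_database`."""
    from .profiles import load_database

    return load_database(path, k=k)
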