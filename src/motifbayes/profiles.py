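"""Reference profile construction: size groups, genome splitting, motif counting.

A single motif-occurrence profile per genome (the classic naive Bayes
reference) favors large genomes: a longer sequence simply contains more
distinct motifs, so random matches accumulate in its favor. The
multi-profile scheme neutralizes this by splitting every genome above a
size threshold into ``n`` overlapping sub-sequences of similar length and
profiling each sub-sequence separately. With genome length ``L`` and
partition count ``n``, each sub-sequence has nominal length ``2L/(n+1)``
and adjacent sub-sequences overlap by ``L/(n+1)`` bases, so the slices
tile [0, L) with 2x coverage in the interior and no motif near a cut point
is lost from every profile.

The default size-group table bins genomes at 2, 4 and 6 Mb into partition
counts 1, 3, 5 and 7. Under it the largest bacterial genomes (~12.9 Mb)
yield ~3.2 Mb sub-sequences against a ~140 kb smallest genome — a ~23-fold
residual size ratio, down from ~93-fold before division.

Integer geometry: sub-sequence ``i`` starts at ``floor(i*L/(n+1))`` with
nominal length ``floor(2L/(n+1))``; the last slice is extended to end
exactly at ``L``. This reproduces the real-valued geometry wherever it is
exact (e.g. a 3 Mb genome in three 1.5 Mb slices overlapping by 750 kb)
and guarantees gap-free coverage otherwise.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kmers
from .io import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SizeGroupTable",
    "DEFAULT_GROUP_TABLE",
    "SINGLE_PROFILE_TABLE",
    "SubSequence",
    "MotifProfile",
    "ProfileDatabase",
    "ProfileDBError",
    "assign_group",
    "split_genome",
    "count_motifs",
    "build_database",
    "post_division_size_ratio",
    "save_database",
    "load_database",
]

DB_FORMAT = "motifbayes-profile-db"
DB_VERSION = 1

#: Largest supported motif length; packed codes stay within int64.
MAX_K = 31


class ProfileDBError(RuntimeError):
    """A profile-database file is unreadable or incompatible with a request."""


@dataclass(frozen=True)
class SizeGroupTable:
    """Genome-length bins mapping each genome to its partition count.

    ``rows`` are (lower_bound, upper_bound, partitions) with inclusive
    bounds in bases; ``upper_bound=None`` means unbounded. Bounds must be
    contiguous from 1 and partition counts non-decreasing, so every
    positive length maps to exactly one row.
    """

    rows: tuple[tuple[int, int | None, int], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("group table must have at least one row")
        expected_lo = 1
        prev_n = 0
        for i, (lo, hi, n) in enumerate(self.rows):
            if lo != expected_lo:
                raise ValueError(f"row {i}: lower bound {lo} != expected {expected_lo}")
            if n < prev_n:
                raise ValueError(f"row {i}: partition count {n} decreases")
            if n < 1:
                raise ValueError(f"row {i}: partition count must be >= 1")
            if hi is None:
                if i != len(self.rows) - 1:
                    raise ValueError(f"row {i}: only the last row may be unbounded")
            else:
                if hi < lo:
                    raise ValueError(f"row {i}: upper bound {hi} < lower bound {lo}")
                expected_lo = hi + 1
            prev_n = n
        if self.rows[-1][1] is not None:
            raise ValueError("last row must be unbounded (upper bound None)")

    def partitions(self, total_length: int) -> int:
        if total_length < 1:
            raise ValueError(f"genome length must be >= 1, got {total_length}")
        for lo, hi, n in self.rows:
            if hi is None or total_length <= hi:
                return n
        raise AssertionError("unreachable: table covers all lengths")

    def to_json(self) -> list[list[int | None]]:
        return [[lo, hi, n] for lo, hi, n in self.rows]

    @classmethod
    def from_json(cls, rows: Sequence[Sequence[int | None]]) -> "SizeGroupTable":
        return cls(tuple((int(lo), None if hi is None else int(hi), int(n)) for lo, hi, n in rows))


#: Four size groups: <=2 Mb undivided, then 3, 5 and 7 partitions.
DEFAULT_GROUP_TABLE = SizeGroupTable(
    (
        (1, 2_000_000, 1),
        (2_000_001, 4_000_000, 3),
        (4_000_001, 6_000_000, 5),
        (6_000_001, None, 7),
    )
)

#: Degenerate table that never divides; multi-profile mode under it
#: coincides with the single-profile classifier.
SINGLE_PROFILE_TABLE = SizeGroupTable(((1, None, 1),))


def assign_group(total_length: int, table: SizeGroupTable = DEFAULT_GROUP_TABLE) -> int:
    """Partition count for a genome of ``total_length`` bases."""
    return table.partitions(total_length)


@dataclass(frozen=True)
class SubSequence:
    """One overlapping slice of a genome in concatenated coordinates."""

    genome_id: str
    index: int
    start: int  # 0-based inclusive
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


def split_coordinates(total_length: int, n: int) -> list[tuple[int, int]]:
    """(start, end) intervals of the ``n`` overlapping sub-sequences.

    For ``n == 1`` the single interval is the whole genome. Requires
    ``total_length >= n + 1`` so every slice is non-empty.
    """
    L = total_length
    if n < 1:
        raise ValueError(f"partition count must be >= 1, got {n}")
    if n == 1:
        if L < 1:
            raise ValueError("genome length must be >= 1")
        return [(0, L)]
    if L < n + 1:
        raise ValueError(f"genome of length {L} is too short to split into {n} sub-sequences")
    nominal = (2 * L) // (n + 1)
    out = []
    for i in range(n):
        start = (i * L) // (n + 1)
        end = L if i == n - 1 else min(start + nominal, L)
        out.append((start, end))
    return out


def split_genome(genome: GenomeRecord, n: int) -> list[SubSequence]:
    """Split a genome into ``n`` overlapping sub-sequences (see module docs)."""
    coords = split_coordinates(genome.total_length, n)
    return [SubSequence(genome.genome_id, i, s, e) for i, (s, e) in enumerate(coords)]


@dataclass
class MotifProfile:
    """Sparse motif-occurrence profile of one (sub-)sequence.

    Counts are stored as a sorted array of packed motif codes with
    parallel occurrence counts. The smoothed probability of motif ``m``
    is ``(count(m) + alpha) / (total_motifs + alpha * 4**k)`` (Laplace
    add-alpha over the full motif space), so no motif ever scores -inf.
    """

    genome_id: str
    sub_index: int
    k: int
    codes: np.ndarray  # sorted, unique packed motif codes
    code_counts: np.ndarray  # parallel occurrence counts
    alpha: float = 1.0
    start: int = 0
    end: int = 0

    @property
    def total_motifs(self) -> int:
        return int(self.code_counts.sum())

    @property
    def owner(self) -> tuple[str, int]:
        return (self.genome_id, self.sub_index)

    def counts(self) -> dict[str, int]:
        """Materialize the motif->count map with string keys.

        Intended for inspection and small-k work; at genome scale this
        builds millions of strings.
        """
        return {
            _kmers.code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.code_counts)
        }

    def count_of(self, motif: str) -> int:
        code = _kmers.kmer_to_code(motif)
        i = int(np.searchsorted(self.codes, code))
        if i < self.codes.size and int(self.codes[i]) == code:
            return int(self.code_counts[i])
        return 0

    def log_probability(self, motif: str) -> float:
        """Smoothed log P(motif | this profile)."""
        denom = self.total_motifs + self.alpha * 4.0**self.k
        return float(np.log((self.count_of(motif) + self.alpha) / denom))


def count_motifs(sequence: str, k: int) -> dict[str, int]:
    """Count every length-``k`` window of ``sequence`` advancing by one base.

    Windows containing any non-ACGT character are skipped; a sequence
    shorter than ``k`` yields an empty map.
    """
    codes = _kmers.valid_window_codes(_kmers.encode_sequence(sequence.upper()), k)
    uniq, cnt = np.unique(codes, return_counts=True)
    return {_kmers.code_to_kmer(int(c), k): int(n) for c, n in zip(uniq, cnt)}


@dataclass
class ProfileDatabase:
    """The full reference: one profile per genome (single-profile mode) or
    per sub-sequence (multi-profile mode), plus the grouping metadata."""

    k: int
    mode: str  # "nbc" | "nbc-mp"
    group_table: SizeGroupTable
    profiles: list[MotifProfile]
    alpha: float = 1.0

    genome_index: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_index:
            idx: dict[str, list[int]] = {}
            for i, p in enumerate(self.profiles):
                idx.setdefault(p.genome_id, []).append(i)
            self.genome_index = idx

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genome_index)

    def __len__(self) -> int:
        return len(self.profiles)


def _record_window_codes(genome: GenomeRecord, k: int):
    """Per-record window codes with their concatenated start coordinates.

    Motif windows never span record junctions: a window must lie entirely
    within one replicon to be counted, so junction artifacts from
    concatenation cannot enter a profile.
    """
    offset = 0
    out = []  # (record_offset, record_length, valid window positions, codes)
    for _, seq in genome.records:
        base = _kmers.encode_sequence(seq)
        codes, valid = _kmers.window_codes(base, k)
        pos = np.flatnonzero(valid)
        out.append((offset, len(seq), pos, codes[pos] if pos.size else codes[:0]))
        offset += len(seq)
    return out


def _profile_for_interval(windows, k: int, start: int, end: int, dtype) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique codes and counts of windows fully inside [start, end)."""
    parts = []
    for off, reclen, pos, codes in windows:
        lo = max(start, off)
        hi = min(end, off + reclen)
        if hi - lo < k:
            continue
        # window local start positions in [lo-off, hi-off-k]
        a = np.searchsorted(pos, lo - off)
        b = np.searchsorted(pos, hi - off - k, side="right")
        if b > a:
            parts.append(codes[a:b])
    if not parts:
        return np.empty(0, dtype=dtype), np.empty(0, dtype=np.int64)
    uniq, cnt = np.unique(np.concatenate(parts), return_counts=True)
    return uniq.astype(dtype, copy=False), cnt


def build_database(
    genomes: Sequence[GenomeRecord],
    k: int,
    mode: str = "nbc-mp",
    table: SizeGroupTable = DEFAULT_GROUP_TABLE,
    alpha: float = 1.0,
) -> ProfileDatabase:
    """Build the reference profile database.

    In mode ``"nbc"`` every genome contributes a single profile over its
    whole (concatenated) sequence. In mode ``"nbc-mp"`` each genome is
    first assigned a partition count from the size-group table, split into
    that many overlapping sub-sequences, and one profile is built per
    sub-sequence. Genomes shorter than ``k`` keep an empty profile (with a
    warning) so the class set is stable.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    if mode not in ("nbc", "nbc-mp"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 1 <= k <= MAX_K:
        raise ValueError(f"motif length {k} outside supported range [1, {MAX_K}]")
    if alpha <= 0:
        raise ValueError(f"smoothing pseudocount must be > 0, got {alpha}")
    seen: set[str] = set()
    for g in genomes:
        if g.genome_id in seen:
            raise ValueError(f"duplicate genome_id {g.genome_id!r}")
        seen.add(g.genome_id)

    dtype = _kmers.code_dtype_for(k)
    profiles: list[MotifProfile] = []
    for g in genomes:
        L = g.total_length
        n = 1 if mode == "nbc" else assign_group(L, table)
        if L < k:
            logger.warning("genome %s (length %d) is shorter than k=%d; empty profile", g.genome_id, L, k)
        coords = split_coordinates(L, n) if L >= n + 1 or n == 1 else [(0, L)]
        windows = _record_window_codes(g, k)
        for i, (s, e) in enumerate(coords):
            codes, cnt = _profile_for_interval(windows, k, s, e, dtype)
            profiles.append(
                MotifProfile(g.genome_id, i, k, codes, cnt, alpha=alpha, start=s, end=e)
            )
        logger.debug("genome %s: L=%d partitions=%d", g.genome_id, L, n)
    return ProfileDatabase(k=k, mode=mode, group_table=table, profiles=profiles, alpha=alpha)


def post_division_size_ratio(
    db_or_table: ProfileDatabase | SizeGroupTable,
    min_genome_length: int | None = None,
    max_genome_length: int | None = None,
) -> float:
    """Max/min sub-sequence length after division.

    Given a built database, uses the actual sub-sequence lengths. Given a
    size-group table plus the genome-length extremes of a collection,
    evaluates the nominal post-division length ``2L/(n+1)`` (or ``L`` when
    undivided) at both extremes. This is the residual size spread the
    splitting leaves for the classifier to absorb.
    """
    if isinstance(db_or_table, ProfileDatabase):
        lengths = [p.end - p.start for p in db_or_table.profiles]
        if len(lengths) < 2:
            raise ValueError("need at least two sub-sequences")
        return max(lengths) / min(lengths)
    table = db_or_table
    if min_genome_length is None or max_genome_length is None:
        raise ValueError("genome length extremes are required with a bare group table")

    def after(L: int) -> float:
        n = table.partitions(L)
        return L if n == 1 else 2 * L / (n + 1)

    return after(max_genome_length) / after(min_genome_length)


# ---------------------------------------------------------------------------
# persistence: a single self-describing zip container (JSON metadata + one
# pair of .npy arrays per profile), versioned for forward compatibility

def save_database(db: ProfileDatabase, path: str | Path) -> None:
    meta = {
        "format": DB_FORMAT,
        "version": DB_VERSION,
        "k": db.k,
        "mode": db.mode,
        "alpha": db.alpha,
        "group_table": db.group_table.to_json(),
        "profiles": [
            {
                "genome_id": p.genome_id,
                "sub_index": p.sub_index,
                "start": p.start,
                "end": p.end,
                "alpha": p.alpha,
            }
            for p in db.profiles
        ],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for i, p in enumerate(db.profiles):
            for name, arr in (("codes", p.codes), ("counts", p.code_counts)):
                buf = _stdio.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"profile_{i}_{name}.npy", buf.getvalue())


def load_database(path: str | Path, k: int | None = None) -> ProfileDatabase:
    """Load a saved database; ``k`` asserts compatibility with a classify request."""
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, OSError) as exc:
        raise ProfileDBError(f"{path}: not a profile database ({exc})") from exc
    with zf:
        try:
            meta = json.loads(zf.read("meta.json"))
        except KeyError as exc:
            raise ProfileDBError(f"{path}: missing metadata") from exc
        if meta.get("format") != DB_FORMAT:
            raise ProfileDBError(f"{path}: unrecognized format {meta.get('format')!r}")
        if meta.get("version") != DB_VERSION:
            raise ProfileDBError(
                f"{path}: database version {meta.get('version')} != supported {DB_VERSION}"
            )
        if k is not None and meta["k"] != k:
            raise ProfileDBError(
                f"{path}: database was built with k={meta['k']} but k={k} was requested"
            )
        profiles = []
        for i, pm in enumerate(meta["profiles"]):
            codes = np.load(_stdio.BytesIO(zf.read(f"profile_{i}_codes.npy")))
            counts = np.load(_stdio.BytesIO(zf.read(f"profile_{i}_counts.npy")))
            profiles.append(
                MotifProfile(
                    genome_id=pm["genome_id"],
                    sub_index=pm["sub_index"],
                    k=meta["k"],
                    codes=codes,
                    code_counts=counts,
                    alpha=pm["alpha"],
                    start=pm["start"],
                    end=pm["end"],
                )
            )
    return ProfileDatabase(
        k=meta["k"],
        mode=meta["mode"],
        group_table=SizeGroupTable.from_json(meta["group_table"]),
        profiles=profiles,
        alpha=meta["alpha"],
    )
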