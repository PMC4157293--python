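"""Read scoring and assignment.

Each read is reduced to its feature vector — the multiset of overlapping
length-``k`` motifs d = {d_1 … d_K} obtained by sliding a window one base
at a time — and scored against every profile with the naive Bayes
log-likelihood

    score(read, profile) = sum_j log P(d_j | profile),

where P(d_j | profile) is the profile's Laplace-smoothed motif
probability. Class priors and the evidence term are constant across
profiles and are dropped from the argmax. The read is assigned to the
highest-scoring profile without any threshold; in multi-profile mode the
winning sub-sequence is mapped back to its source genome.

Reference profiles count the forward strand only, while sequencers sample
both strands, so by default each read is scored as given and as its
reverse complement and the better orientation wins (disable with
``forward_only`` for strict as-given scoring). Ties are broken
deterministically: forward orientation first, then database order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kmers
from .io import ReadRecord
from .profiles import MotifProfile, ProfileDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "Assignment",
    "AbundanceTable",
    "extract_features",
    "score_profile",
    "classify_read",
    "classify_all",
]


@dataclass
class FeatureVector:
    """The motif multiset of one read: d = {d_1 … d_K}, plus bookkeeping
    for windows dropped because they contained a non-ACGT character."""

    read_id: str
    k: int
    motifs: list[str]
    skipped_windows: int = 0

    @property
    def K(self) -> int:
        return len(self.motifs)


@dataclass
class Assignment:
    """Winning profile for one read, mapped to its owning genome."""

    read_id: str
    winner_genome_id: str
    winner_sub_index: int
    score: float
    orientation: str  # "forward" | "reverse"
    tie_count: int = 1
    no_features: bool = False  # no valid motif in either orientation


@dataclass
class AbundanceTable:
    """Per-genome assigned-fragment counts (sub-sequence hits combined
    into their source genome)."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_assignments(
        cls, assignments: list[Assignment], genome_ids: list[str] | None = None
    ) -> "AbundanceTable":
        counts = dict.fromkeys(genome_ids, 0) if genome_ids is not None else {}
        for a in assignments:
            counts[a.winner_genome_id] = counts.get(a.winner_genome_id, 0) + 1
        return cls(counts)

    def top(self, n: int) -> list[tuple[str, int]]:
        """Top ``n`` genomes by count; equal counts rank alphabetically."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def extract_features(read: ReadRecord | str, k: int) -> FeatureVector:
    """Sliding-window motif extraction (step 1; non-ACGT windows skipped).

    Reads shorter than ``k`` yield an empty feature vector.
    """
    if isinstance(read, str):
        read = ReadRecord("read", read)
    codes, valid = _kmers.window_codes(_kmers.encode_sequence(read.sequence.upper()), k)
    motifs = [_kmers.code_to_kmer(int(c), k) for c in codes[valid]]
    return FeatureVector(
        read_id=read.read_id,
        k=k,
        motifs=motifs,
        skipped_windows=int(valid.size - valid.sum()),
    )


def score_profile(features: FeatureVector, profile: MotifProfile) -> float:
    """Summed smoothed log-probability of the feature vector; 0 when K=0."""
    if features.k != profile.k:
        raise ValueError(f"feature k={features.k} does not match profile k={profile.k}")
    return float(sum(profile.log_probability(m) for m in features.motifs))


def _read_unit_codes(sequence: str, k: int, forward_only: bool) -> list[np.ndarray]:
    """Valid packed motif codes per orientation (forward [, reverse])."""
    seq = sequence.upper()
    units = [_kmers.valid_window_codes(_kmers.encode_sequence(seq), k)]
    if not forward_only:
        rc = _kmers.reverse_complement(seq)
        units.append(_kmers.valid_window_codes(_kmers.encode_sequence(rc), k))
    return units


def _batch_scores(units: list[np.ndarray], db: ProfileDatabase) -> np.ndarray:
    """Score matrix of shape (n_units, n_profiles).

    All units' codes are concatenated once; each profile is then scored
    with a single binary search over its sorted code array, and per-unit
    sums are recovered from a cumulative sum (robust to empty units,
    which score 0 against every profile).
    """
    n_units = len(units)
    P = len(db.profiles)
    S = np.zeros((n_units, P))
    if n_units == 0:
        return S
    lengths = np.array([u.size for u in units], dtype=np.int64)
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    allc = np.concatenate([u for u in units if u.size]) if lengths.sum() else None
    if allc is None:
        return S
    for pi, prof in enumerate(db.profiles):
        denom = prof.total_motifs + prof.alpha * 4.0**db.k
        if prof.codes.size:
            idx = np.searchsorted(prof.codes, allc)
            idxc = np.minimum(idx, prof.codes.size - 1)
            found = prof.codes[idxc] == allc
            cnt = np.where(found, prof.code_counts[idxc], 0)
        else:
            cnt = np.zeros(allc.size)
        lp = np.log((cnt + prof.alpha) / denom)
        cs = np.concatenate(([0.0], np.cumsum(lp)))
        S[:, pi] = cs[bounds[1:]] - cs[bounds[:-1]]
    return S


def classify_all(
    reads: list[ReadRecord],
    db: ProfileDatabase,
    forward_only: bool = False,
) -> tuple[list[Assignment], AbundanceTable]:
    """Assign every read to its best-scoring profile and tally per-genome
    fragment counts.

    Deterministic given the database and read order; a read with no valid
    motif in either orientation is flagged and assigned to the first
    profile with score 0 rather than dropped, keeping the accuracy
    denominator equal to the number of input reads.
    """
    if not db.profiles:
        raise ValueError("empty profile database")
    n_orient = 1 if forward_only else 2
    units: list[np.ndarray] = []
    for r in reads:
        units.extend(_read_unit_codes(r.sequence, db.k, forward_only))
    S = _batch_scores(units, db)
    S = S.reshape(len(reads), n_orient, len(db.profiles))
    has_motifs = np.array(
        [any(units[i * n_orient + j].size for j in range(n_orient)) for i in range(len(reads))]
    )

    assignments: list[Assignment] = []
    for i, r in enumerate(reads):
        if not has_motifs[i]:
            p0 = db.profiles[0]
            logger.warning("read %s has no valid motif; assigned to first profile", r.read_id)
            assignments.append(
                Assignment(r.read_id, p0.genome_id, p0.sub_index, 0.0,
                           "forward", tie_count=len(db.profiles), no_features=True)
            )
            continue
        fwd = S[i, 0]
        rev = S[i, 1] if n_orient == 2 else None
        best = fwd if rev is None else np.maximum(fwd, rev)
        m = best.max()
        winner = int(np.argmax(best))  # first profile in db order on ties
        tie_count = int((best == m).sum())
        orientation = "forward"
        if rev is not None and rev[winner] > fwd[winner]:
            orientation = "reverse"
        p = db.profiles[winner]
        assignments.append(
            Assignment(r.read_id, p.genome_id, p.sub_index, float(m), orientation, tie_count)
        )
    abundance = AbundanceTable.from_assignments(assignments, genome_ids=db.genome_ids)
    return assignments, abundance


def classify_read(read: ReadRecord, db: ProfileDatabase, forward_only: bool = False) -> Assignment:
    """Classify a single read (see :func:`classify_all`)."""
    assignments, _ = classify_all([read], db, forward_only=forward_only)
    return assignments[0]
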