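"""Synthetic reference genomes and error-bearing shotgun reads.

The genome generator emulates a skewed microbial reference collection:
each genome is drawn from its own order-1 Markov chain over A/C/G/T whose
transition rows are perturbed per genome, so genomes carry genuine
compositional (k-mer-frequency) signal that a composition-based
classifier can learn, at any specified length. The chains are
hierarchical: one ancestral transition matrix is drawn per community and
every genome perturbs it log-normally, with ``composition_divergence``
the relative spread of transition probabilities between genomes. 0 is
the no-signal limit (all genomes compositionally identical) and values
near 1 give strongly idiosyncratic compositions; real communities of
related taxa sit at small values.

The read simulator reproduces the classic wgsim single-end protocol with
substitution-only errors: a fixed number of reads per genome, fixed read
length, uniformly random start positions and strands, and each base
independently substituted with the given probability to a uniformly
random *different* base. No insertions, deletions, chimeras or coverage
bias. Reads never span replicon junctions. Every read id embeds its truth
label as ``<genome_id>|<ordinal>|<start>|<strand>`` with ``start`` the
forward-strand 0-based offset in the genome's concatenated coordinates
and strand ``f``/``r``. Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kmers import decode_codes, encode_sequence
from .io import GenomeRecord, ReadRecord

logger = logging.getLogger(__name__)

__all__ = ["SimulationSpec", "generate_genomes", "simulate_reads"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _markov_chain(cum: np.ndarray, u: np.ndarray, first: int) -> np.ndarray:
        n = u.size
        out = np.empty(n + 1, dtype=np.int8)
        out[0] = first
        for i in range(n):
            s = out[i]
            x = u[i]
            if x < cum[s, 0]:
                out[i + 1] = 0
            elif x < cum[s, 1]:
                out[i + 1] = 1
            elif x < cum[s, 2]:
                out[i + 1] = 2
            else:
                out[i + 1] = 3
        return out

except ImportError:  # pragma: no cover

    def _markov_chain(cum: np.ndarray, u: np.ndarray, first: int) -> np.ndarray:
        n = u.size
        out = np.empty(n + 1, dtype=np.int8)
        out[0] = first
        c = cum
        s = first
        for i in range(n):
            x = u[i]
            if x < c[s, 0]:
                s = 0
            elif x < c[s, 1]:
                s = 1
            elif x < c[s, 2]:
                s = 2
            else:
                s = 3
            out[i + 1] = s
        return out


@dataclass
class SimulationSpec:
    """Configuration of one synthetic community and its read set.

    genome_lengths may be an explicit list (one entry per genome) or a
    (low, high) range sampled uniformly for ``n_genomes`` genomes.
    """

    n_genomes: int = 20
    genome_lengths: Sequence[int] | tuple[int, int] | None = None
    length_range: tuple[int, int] = (500_000, 8_000_000)
    read_length: int = 100
    reads_per_genome: int = 100
    substitution_rate: float = 0.0
    composition_divergence: float = 0.1
    seed: int = 0
    forward_only: bool = False
    genome_id_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.reads_per_genome < 0:
            raise ValueError("reads_per_genome must be >= 0")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0.0 <= self.composition_divergence <= 1.0:
            raise ValueError("composition_divergence must be in [0, 1]")
        if self.genome_lengths is not None:
            lens = list(self.genome_lengths)
            if len(lens) == self.n_genomes and any(x <= 0 for x in lens):
                raise ValueError("genome lengths must be positive")

    def resolved_lengths(self, rng: np.random.Generator) -> list[int]:
        if self.genome_lengths is not None:
            lens = [int(x) for x in self.genome_lengths]
            if len(lens) == self.n_genomes:
                return lens
            if len(lens) == 2:
                lo, hi = lens
                return [int(x) for x in rng.integers(lo, hi + 1, size=self.n_genomes)]
            raise ValueError(
                f"genome_lengths has {len(lens)} entries for {self.n_genomes} genomes"
            )
        lo, hi = self.length_range
        return [int(x) for x in rng.integers(lo, hi + 1, size=self.n_genomes)]

    def with_(self, **kw) -> "SimulationSpec":
        return replace(self, **kw)


def _base_transition_matrix(rng: np.random.Generator) -> np.ndarray:
    """Community-wide ancestral transition rows (mild shared skew)."""
    rows = rng.dirichlet(np.full(4, 10.0), size=4)
    rows = np.maximum(rows, 1e-9)
    return rows / rows.sum(axis=1, keepdims=True)


def _transition_matrix(
    rng: np.random.Generator, base: np.ndarray, divergence: float
) -> np.ndarray:
    """Per-genome Markov transition rows P(next | prev), 4x4.

    Each genome perturbs the shared base rows log-normally:
    row ∝ base_row * exp(divergence * Z), Z ~ N(0, 1) per entry, so
    ``divergence`` is roughly the relative spread of transition
    probabilities between genomes — genomes share most of their
    composition (as related taxa do) and are identical in the limit
    divergence -> 0.
    """
    if divergence <= 0.0:
        return base.copy()
    rows = base * np.exp(divergence * rng.standard_normal((4, 4)))
    return rows / rows.sum(axis=1, keepdims=True)


def generate_genomes(spec: SimulationSpec) -> list[GenomeRecord]:
    """Draw the synthetic community: one order-1 Markov genome per class."""
    if spec.n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x67]))
    lengths = spec.resolved_lengths(rng)
    if any(L <= 0 for L in lengths):
        raise ValueError("genome lengths must be positive")
    base = _base_transition_matrix(rng)
    genomes = []
    for gi, L in enumerate(lengths):
        T = _transition_matrix(rng, base, spec.composition_divergence)
        cum = np.cumsum(T, axis=1)
        first = int(rng.integers(0, 4))
        u = rng.random(L - 1)
        codes = _markov_chain(cum, u, first)
        gid = f"{spec.genome_id_prefix}{gi:03d}"
        genomes.append(GenomeRecord(gid, [(gid, decode_codes(codes))]))
    return genomes


def simulate_reads(genomes: Sequence[GenomeRecord], spec: SimulationSpec) -> list[ReadRecord]:
    """Sample ``reads_per_genome`` single-end reads from every genome.

    Start positions are uniform over all windows that fit inside one
    replicon; strand is uniform unless ``forward_only``; substitutions
    are applied after orientation (i.e. to the read as sequenced).
    Genomes with no replicon long enough for a read are skipped with a
    warning.
    """
    L = spec.read_length
    rate = spec.substitution_rate
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x52]))
    reads: list[ReadRecord] = []
    for g in genomes:
        recs = [(off, seq) for off, seq in _with_offsets(g) if len(seq) >= L]
        if not recs:
            logger.warning("genome %s has no replicon of length >= %d; skipped", g.genome_id, L)
            continue
        weights = np.array([len(seq) - L + 1 for _, seq in recs], dtype=float)
        weights /= weights.sum()
        rec_choice = rng.choice(len(recs), size=spec.reads_per_genome, p=weights)
        rec_codes = [encode_sequence(seq) for _, seq in recs]
        for ordinal in range(spec.reads_per_genome):
            ri = int(rec_choice[ordinal])
            off, seq = recs[ri]
            start = int(rng.integers(0, len(seq) - L + 1))
            codes = rec_codes[ri][start : start + L].copy()
            strand = "f" if spec.forward_only else ("f", "r")[int(rng.integers(0, 2))]
            if strand == "r":
                codes = np.where(codes >= 0, 3 - codes, codes)[::-1]
            if rate > 0.0:
                mask = (rng.random(L) < rate) & (codes >= 0)
                if mask.any():
                    shift = rng.integers(1, 4, size=int(mask.sum()))
                    codes[mask] = (codes[mask] + shift) % 4
            rid = f"{g.genome_id}|{ordinal:06d}|{off + start}|{strand}"
            reads.append(ReadRecord(rid, decode_codes(codes), truth_genome_id=g.genome_id))
    return reads


def _with_offsets(genome: GenomeRecord):
    off = 0
    for _, seq in genome.records:
        yield off, seq
        off += len(seq)
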