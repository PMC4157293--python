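"""Evaluation: classification accuracy, abundance tables, rank agreement,
and the simulation benchmark grid.

Accuracy is fragment-level and strain-level:

    accuracy = (# fragments assigned to their true genome) / (# fragments),

with no partial credit for near taxa and with unscorable reads (no valid
motif) counted in the denominator as incorrect. Two classifiers' outputs
on the same read set are compared without truth labels via Spearman's
rank correlation between their per-genome abundance rankings, restricted
to the genomes common to both top-``n`` lists (average ranks on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import AbundanceTable, Assignment, classify_all
from .io import ReadRecord
from .profiles import DEFAULT_GROUP_TABLE, SizeGroupTable, build_database
from .simulate import SimulationSpec, generate_genomes, simulate_reads

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyReport",
    "compute_accuracy",
    "truth_from_reads",
    "spearman_abundance",
    "run_benchmark",
]


@dataclass
class AccuracyReport:
    n_total: int
    n_correct: int
    per_genome: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "per_genome": self.per_genome,
        }


def truth_from_reads(reads: Sequence[ReadRecord]) -> dict[str, str]:
    return {r.read_id: r.truth_genome_id for r in reads if r.truth_genome_id is not None}


def compute_accuracy(
    assignments: Sequence[Assignment],
    truth: Mapping[str, str] | Callable[[str], str | None],
) -> AccuracyReport:
    """Fraction of fragments assigned to their true genome.

    ``truth`` maps read ids to genome ids (or is a callable doing so).
    Every assignment must have a truth label; an empty assignment list is
    an error (0/0 is undefined, not zero).
    """
    if not assignments:
        raise ValueError("no assignments: accuracy is undefined on an empty set")
    lookup = truth if callable(truth) else truth.get
    missing = [a.read_id for a in assignments if lookup(a.read_id) is None]
    if missing:
        shown = ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
        raise ValueError(f"{len(missing)} assignment(s) lack truth labels: {shown}")
    per: dict[str, dict[str, int]] = {}
    n_correct = 0
    for a in assignments:
        true_gid = lookup(a.read_id)
        correct = (a.winner_genome_id == true_gid) and not a.no_features
        n_correct += correct
        for gid, key in ((true_gid, "n_true"), (a.winner_genome_id, "n_assigned")):
            per.setdefault(gid, {"n_true": 0, "n_assigned": 0, "n_correct": 0})[key] += 1
        if correct:
            per[true_gid]["n_correct"] += 1
    return AccuracyReport(n_total=len(assignments), n_correct=n_correct, per_genome=per)


def spearman_abundance(
    a: AbundanceTable | Mapping[str, int],
    b: AbundanceTable | Mapping[str, int],
    top_n: int = 30,
) -> tuple[float, int]:
    """Spearman's rho between two abundance rankings over their common top strains.

    Each table's ``top_n`` genomes by fragment count are intersected and
    the correlation is computed on the two count vectors over that
    intersection, with average ranks on ties. Returns (rho, intersection
    size); fewer than two common strains is an error since the
    coefficient is undefined.
    """
    ta = a if isinstance(a, AbundanceTable) else AbundanceTable(dict(a))
    tb = b if isinstance(b, AbundanceTable) else AbundanceTable(dict(b))
    if not ta.counts or not tb.counts:
        raise ValueError("abundance tables must be non-empty")
    top_a = {g for g, _ in ta.top(top_n)}
    top_b = {g for g, _ in tb.top(top_n)}
    common = sorted(top_a & top_b)
    if len(common) < 2:
        raise ValueError(
            f"only {len(common)} strain(s) common to the two top-{top_n} lists; "
            "rank correlation is undefined"
        )
    xs = [ta.counts[g] for g in common]
    ys = [tb.counts[g] for g in common]
    rho = float(stats.spearmanr(xs, ys).statistic)
    return rho, len(common)


def run_benchmark(
    spec: SimulationSpec,
    ks: Sequence[int],
    read_lengths: Sequence[int],
    error_rates: Sequence[float],
    modes: Sequence[str] = ("nbc", "nbc-mp"),
    seeds: Sequence[int] = (0,),
    table: SizeGroupTable = DEFAULT_GROUP_TABLE,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Full factorial simulation benchmark.

    For every (seed, k, mode, read length, error rate) cell: build the
    reference database from a fresh synthetic community, simulate reads,
    classify, and record accuracy. Genomes depend only on the seed and
    are shared across cells; databases are shared across read conditions.
    Cells with read length < k are recorded as not applicable rather than
    crashing the grid. The result is a tidy DataFrame, deterministic
    given the grid and seeds.
    """
    rows = []
    for seed in seeds:
        gspec = spec.with_(seed=int(seed))
        genomes = generate_genomes(gspec)
        reads_cache: dict[tuple[int, float], list[ReadRecord]] = {}
        for k in ks:
            for mode in modes:
                db = build_database(genomes, k=k, mode=mode, table=table, alpha=alpha)
                for rl in read_lengths:
                    for rate in error_rates:
                        row = {
                            "seed": seed, "k": k, "mode": mode,
                            "read_length": rl, "error_rate": rate,
                        }
                        if rl < k:
                            row.update(n_reads=0, accuracy=np.nan, status="not_applicable")
                            rows.append(row)
                            continue
                        key = (rl, rate)
                        if key not in reads_cache:
                            reads_cache[key] = simulate_reads(
                                genomes,
                                gspec.with_(read_length=rl, substitution_rate=rate),
                            )
                        reads = reads_cache[key]
                        assignments, _ = classify_all(reads, db)
                        rep = compute_accuracy(assignments, truth_from_reads(reads))
                        row.update(n_reads=rep.n_total, accuracy=rep.accuracy, status="ok")
                        rows.append(row)
                        logger.info(
                            "seed=%s k=%d mode=%s len=%d rate=%g accuracy=%.4f",
                            seed, k, mode, rl, rate, rep.accuracy,
                        )
                del db
    return pd.DataFrame(rows)
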