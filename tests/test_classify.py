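import math

import numpy as np
import pytest

from motifbayes import (
    GenomeRecord,
    MotifProfile,
    ReadRecord,
    build_database,
    classify_all,
    classify_read,
    extract_features,
    score_profile,
)
from motifbayes.profiles import SINGLE_PROFILE_TABLE, ProfileDatabase

from conftest import random_dna
from oracle import brute_classify, dense_profile, revcomp


def profile_from_counts(counts: dict[str, int], k: int, alpha: float = 1.0, gid="g", sub=0):
    from motifbayes._kmers import kmer_to_code

    items = sorted((kmer_to_code(m), c) for m, c in counts.items())
    codes = np.array([c for c, _ in items], dtype=np.int64)
    cnts = np.array([n for _, n in items], dtype=np.int64)
    return MotifProfile(gid, sub, k, codes, cnts, alpha=alpha)


class TestExtractFeatures:
    def test_sliding_windows(self):
        fv = extract_features("ACGTA", 4)
        assert fv.motifs == ["ACGT", "CGTA"] and fv.K == 2

    def test_read_shorter_than_k(self):
        assert extract_features("ACGT", 5).K == 0

    def test_25bp_read_15mer(self, rng):
        assert extract_features(random_dna(rng, 25), 15).K == 11

    def test_skipped_windows_accounting(self):
        fv = extract_features("ACGNACGT", 3)
        # 6 windows total, 3 touch the N
        assert fv.skipped_windows == 3
        assert fv.K == len("ACGNACGT") - 3 + 1 - fv.skipped_windows
        assert fv.motifs == ["ACG", "ACG", "CGT"]  # order preserved


class TestScoreProfile:
    def test_uniform_profile_closed_form(self):
        k = 2
        prof = profile_from_counts({m: 3 for m in ("AA", "AC", "AG", "AT")}, k)
        # not uniform over all 16; use a truly uniform dense profile instead:
        import itertools

        uniform = profile_from_counts(
            {"".join(m): 5 for m in itertools.product("ACGT", repeat=k)}, k
        )
        fv = extract_features("AAACC", k)  # K = 4
        assert score_profile(fv, uniform) == pytest.approx(4 * math.log(1 / 4**k), rel=1e-12)
        assert prof is not uniform

    def test_empty_feature_vector_scores_zero(self):
        prof = profile_from_counts({"AA": 1}, 2)
        assert score_profile(extract_features("A", 2), prof) == 0.0

    def test_hand_evaluated_smoothing(self):
        # counts {AA:3, AC:1}, k=2, total 4, alpha=1 -> denominator 4 + 16 = 20
        prof = profile_from_counts({"AA": 3, "AC": 1}, 2)
        fv = extract_features("AAC", 2)  # motifs AA, AC
        assert score_profile(fv, prof) == pytest.approx(
            math.log(4 / 20) + math.log(2 / 20), rel=1e-12
        )

    def test_k_mismatch_rejected(self):
        prof = profile_from_counts({"AA": 1}, 2)
        with pytest.raises(ValueError, match="k=3.*k=2"):
            score_profile(extract_features("ACGT", 3), prof)


class TestClassifyRead:
    def test_exact_substring_wins_on_toy_set(self, toy_genomes):
        db = build_database(toy_genomes, k=3, mode="nbc")
        dense = [dense_profile(g.records[0][1], 3, 1.0) for g in toy_genomes]
        for g in toy_genomes:
            seq = g.records[0][1][100:150]
            a = classify_read(ReadRecord("q", seq), db)
            bi, bs = brute_classify(seq, dense, 3)
            assert a.winner_genome_id == toy_genomes[bi].genome_id
            assert a.winner_genome_id == g.genome_id
            assert a.score == pytest.approx(bs, abs=1e-9)

    def test_singleton_database(self, toy_genomes):
        db = build_database(toy_genomes[:1], k=4, mode="nbc")
        a = classify_read(ReadRecord("q", "TTTTTTTT"), db)
        assert a.winner_genome_id == toy_genomes[0].genome_id

    def test_identical_profiles_tie_first_wins(self):
        seq = "ACGTACGTACGTACGT"
        g1 = GenomeRecord.from_sequence("first", seq)
        g2 = GenomeRecord.from_sequence("second", seq)
        db = build_database([g1, g2], k=4, mode="nbc")
        a = classify_read(ReadRecord("q", seq[:10]), db)
        assert a.winner_genome_id == "first"
        assert a.tie_count == 2

    def test_reverse_complement_orientation(self, toy_genomes):
        db = build_database(toy_genomes, k=3, mode="nbc")
        seq = toy_genomes[1].records[0][1][50:110]
        a = classify_read(ReadRecord("q", revcomp(seq)), db)
        assert a.winner_genome_id == toy_genomes[1].genome_id
        assert a.orientation == "reverse"
        # forward-only scoring must not see the reverse-strand signal
        af = classify_read(ReadRecord("q", revcomp(seq)), db, forward_only=True)
        assert af.orientation == "forward"

    def test_no_valid_motif_flagged_and_assigned_first(self, toy_genomes, caplog):
        db = build_database(toy_genomes, k=4, mode="nbc")
        with caplog.at_level("WARNING"):
            a = classify_read(ReadRecord("q", "NNNNNNNN"), db)
        assert a.no_features and a.score == 0.0
        assert a.winner_genome_id == toy_genomes[0].genome_id
        assert "q" in caplog.text


class TestClassifyAll:
    def test_all_reads_from_one_genome(self, toy_genomes, rng):
        db = build_database(toy_genomes, k=4, mode="nbc")
        src = toy_genomes[0]
        starts = rng.integers(0, 330, size=100)
        reads = [
            ReadRecord(f"{src.genome_id}|{i:06d}|{s}|f", src.records[0][1][s : s + 70])
            for i, s in enumerate(starts)
        ]
        _, abundance = classify_all(reads, db)
        assert abundance.counts[src.genome_id] == 100
        assert abundance.total == 100

    def test_empty_read_list(self, toy_genomes):
        db = build_database(toy_genomes, k=4, mode="nbc")
        assignments, abundance = classify_all([], db)
        assert assignments == []
        assert abundance.counts == {g.genome_id: 0 for g in toy_genomes}

    def test_mode_equivalence_under_forced_n1(self, rng):
        genomes = [
            GenomeRecord.from_sequence(f"g{i}", random_dna(rng, 2000)) for i in range(4)
        ]
        reads = [
            ReadRecord(f"q{i}", random_dna(rng, 60)) for i in range(50)
        ]
        db_nbc = build_database(genomes, k=5, mode="nbc")
        db_mp = build_database(genomes, k=5, mode="nbc-mp", table=SINGLE_PROFILE_TABLE)
        a1, t1 = classify_all(reads, db_nbc)
        a2, t2 = classify_all(reads, db_mp)
        assert a1 == a2
        assert t1.counts == t2.counts

    def test_determinism(self, toy_genomes, rng):
        db = build_database(toy_genomes, k=3, mode="nbc")
        reads = [ReadRecord(f"q{i}", random_dna(rng, 30)) for i in range(40)]
        r1 = classify_all(reads, db)
        r2 = classify_all(reads, db)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_empty_database_rejected(self):
        db = ProfileDatabase(k=3, mode="nbc", group_table=SINGLE_PROFILE_TABLE, profiles=[])
        with pytest.raises(ValueError):
            classify_all([ReadRecord("q", "ACGT")], db)


class TestOracleEquivalence:
    def test_scores_match_dense_brute_force(self, rng):
        """Vectorized sparse scoring equals dense enumeration of all 4**k motifs."""
        for k in (1, 2, 3):
            genomes = [
                GenomeRecord.from_sequence(f"g{i}", random_dna(rng, int(rng.integers(40, 100))))
                for i in range(4)
            ]
            alpha = 0.5
            db = build_database(genomes, k=k, mode="nbc", alpha=alpha)
            dense = [dense_profile(g.records[0][1], k, alpha) for g in genomes]
            for _ in range(25):
                seq = random_dna(rng, int(rng.integers(k, 35)))
                a = classify_read(ReadRecord("q", seq), db)
                bi, bs = brute_classify(seq, dense, k)
                assert a.score == pytest.approx(bs, abs=1e-9)
                assert a.winner_genome_id == genomes[bi].genome_id

    def test_count_scaling_with_alpha_preserves_argmax(self, rng):
        """Multiplying all counts and alpha by c preserves the ranking."""
        genomes = [
            GenomeRecord.from_sequence(f"g{i}", random_dna(rng, 300)) for i in range(5)
        ]
        db = build_database(genomes, k=4, mode="nbc", alpha=1.0)
        c = 7
        scaled = ProfileDatabase(
            k=db.k,
            mode=db.mode,
            group_table=db.group_table,
            profiles=[
                MotifProfile(p.genome_id, p.sub_index, p.k, p.codes, p.code_counts * c,
                             alpha=p.alpha * c, start=p.start, end=p.end)
                for p in db.profiles
            ],
            alpha=db.alpha * c,
        )
        reads = [ReadRecord(f"q{i}", random_dna(rng, 30)) for i in range(40)]
        a1, _ = classify_all(reads, db)
        a2, _ = classify_all(reads, scaled)
        assert [x.winner_genome_id for x in a1] == [x.winner_genome_id for x in a2]
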