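"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (string slicing, dict counting,
dense enumeration of the whole motif space) and shares no code with the
package's vectorized implementation.
"""

import itertools
import math

ACGT = set("ACGT")


def brute_count_motifs(sequence: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if set(w) <= ACGT:
            counts[w] = counts.get(w, 0) + 1
    return counts


def dense_profile(sequence: str, k: int, alpha: float) -> dict[str, float]:
    """Smoothed probability of every one of the 4**k motifs (dense)."""
    counts = brute_count_motifs(sequence, k)
    total = sum(counts.values())
    denom = total + alpha * 4**k
    return {
        "".join(m): (counts.get("".join(m), 0) + alpha) / denom
        for m in itertools.product("ACGT", repeat=k)
    }


def brute_score(read_sequence: str, dense: dict[str, float], k: int) -> float:
    s = 0.0
    for i in range(len(read_sequence) - k + 1):
        w = read_sequence[i : i + k]
        if set(w) <= ACGT:
            s += math.log(dense[w])
    return s


def revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


def brute_classify(read_sequence: str, dense_profiles: list[dict[str, float]], k: int):
    """(best profile index, best score), forward/reverse max, first-wins ties."""
    best_i, best_s = 0, -math.inf
    for i, d in enumerate(dense_profiles):
        s = max(brute_score(read_sequence, d, k), brute_score(revcomp(read_sequence), d, k))
        if s > best_s:
            best_i, best_s = i, s
    return best_i, best_s


def brute_spearman(xs: list[float], ys: list[float]) -> float:
    """Spearman's rho via explicit average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(xs), ranks(ys)
    n = len(xs)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
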