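"""Integer encoding of DNA and vectorized k-mer (motif) extraction.

Motifs are fixed-length DNA words over {A, C, G, T}. Internally every motif
of length ``k`` is packed into a single integer code in ``[0, 4**k)`` using
two bits per base (A=0, C=1, G=2, T=3, most significant base first), which
lets profiles store sorted code arrays and score reads with binary search
instead of string hashing. Positions holding any other character (N, IUPAC
ambiguity codes, gaps) encode to -1 and every window touching them is
dropped from motif extraction while remaining present in the sequence
coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode_sequence",
    "decode_codes",
    "window_codes",
    "kmer_to_code",
    "code_to_kmer",
    "reverse_complement",
    "code_dtype_for",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to an int8 array (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; negative codes decode to ``N``."""
    idx = np.where(codes >= 0, codes, 4).astype(np.intp)
    return _CODE_BASE[idx].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def code_dtype_for(k: int) -> np.dtype:
    # 4**15 < 2**31, so int32 suffices up to k=15; larger k needs int64.
    return np.dtype(np.int32) if 4**k < 2**31 else np.dtype(np.int64)


def window_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes of every length-``k`` window advancing by one base.

    Parameters
    ----------
    base_codes : per-base codes from :func:`encode_sequence`.
    k : motif length (>= 1).

    Returns
    -------
    codes : int64 array of length ``max(len - k + 1, 0)``; entries at
        invalid windows are meaningless and must be masked with ``valid``.
    valid : boolean array, True where the window contains only A/C/G/T.
    """
    if k < 1:
        raise ValueError(f"motif length must be >= 1, got {k}")
    n = base_codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=bool))
    bad = np.concatenate(([0], np.cumsum(base_codes < 0)))
    valid = (bad[k:] - bad[:-k]) == 0
    clipped = np.where(base_codes >= 0, base_codes, 0).astype(np.int64)
    codes = clipped[:n].copy()
    for j in range(1, k):
        codes *= 4
        codes += clipped[j : j + n]
    return codes, valid


def valid_window_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    codes, valid = window_codes(base_codes, k)
    return codes[valid]


def kmer_to_code(kmer: str) -> int:
    codes = encode_sequence(kmer)
    if (codes < 0).any():
        raise ValueError(f"motif {kmer!r} contains non-ACGT characters")
    code = 0
    for c in codes:
        code = code * 4 + int(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")
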