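"""Low-level sequence primitives shared across the package.

All coordinates are 0-based half-open on the plus strand. Sequences are
uppercase strings over ``ACGTN``; ``N`` is accepted on input but treated as
mismatching every base by every scanning operation.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Code value used for N: compares unequal to every ACGT code.
N_CODE = 4


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str, allow_n: bool = True) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4).

    Raises ``ValueError`` listing the offending symbols if the sequence
    contains characters outside the allowed alphabet.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for ch, code in _CODE.items():
        out[arr == ord(ch)] = code
    bad = out == 255
    if not allow_n:
        bad |= out == N_CODE
    if bad.any():
        symbols = sorted({seq[i] for i in np.flatnonzero(bad)[:20]})
        raise ValueError(f"sequence contains non-{'ACGTN' if allow_n else 'ACGT'} characters: {symbols}")
    return out


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in arr)


def hamming_scan(seq: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Mismatch count of ``pattern`` at every start position of ``seq``.

    ``seq`` may contain N (code 4), which mismatches every pattern base.
    Returns an int array of length ``len(seq) - len(pattern) + 1`` (empty if
    the pattern is longer than the sequence).
    """
    L, m = len(seq), len(pattern)
    n = L - m + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    mm = np.zeros(n, dtype=np.int64)
    for j in range(m):
        mm += seq[j : j + n] != pattern[j]
    return mm


def base_probs(gc: float) -> np.ndarray:
    """Per-base probabilities (A, C, G, T) for a given G+C fraction."""
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    return np.array([at, g, g, at])


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random iid DNA string with the given G+C fraction."""
    codes = rng.choice(4, size=length, p=base_probs(gc))
    return decode(codes)


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    gc: float,
    protected: np.ndarray | None = None,
) -> tuple[str, np.ndarray]:
    """Substitution-only mutation of ``seq`` at per-base ``rate``.

    Replacement bases are drawn from the background composition conditioned
    on differing from the original, so the stationary composition is
    preserved. ``protected`` is a boolean mask of positions never mutated.
    Returns the mutated string and the array of mutated positions.
    """
    if rate <= 0:
        return seq, np.zeros(0, dtype=np.int64)
    arr = encode(seq).copy()
    hit = rng.random(len(arr)) < rate
    if protected is not None:
        hit &= ~protected
    hit &= arr != N_CODE
    pos = np.flatnonzero(hit)
    probs = base_probs(gc)
    for i in pos:
        while True:
            b = rng.choice(4, p=probs)
            if b != arr[i]:
                arr[i] = b
                break
    return decode(arr), pos


def kmer_codes(seq: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes at every start of an encoded sequence.

    Returns ``(codes, valid)`` where ``valid`` marks windows free of N.
    Requires ``k <= 32`` (codes fit in uint64).
    """
    if k > 32:
        raise ValueError("k must be <= 32")
    L = len(seq)
    n = L - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    isn = seq == N_CODE
    nbad = np.zeros(n, dtype=np.int32)
    clean = np.where(isn, 0, seq).astype(np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | clean[j : j + n]
        nbad += isn[j : j + n]
    return codes, nbad == 0
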