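"""Time-delay embedding and ordinal symbolization.

Shared front end of every entropy in the package: overlapping
reconstruction windows, Bandt-Pompe ordinal patterns, signed variance
weights, and amplitude quantization for the improved permutation
entropy (IPE).

Conventions
-----------
Vectors (windows) and samples are numbered 1-based in all user-facing
output and documentation, matching the standard presentation of the
Bandt-Pompe symbolization; internal arrays are 0-based numpy arrays.
Ties between equal values are broken by original position (stable
sort), so the earlier index receives the lower rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "as_signal",
    "embed",
    "pattern_of",
    "ordinal_patterns",
    "signed_weights",
    "symbolize",
    "ipe_symbolize",
    "OrdinalPattern",
    "PatternSequence",
]

#: Largest embedding dimension for which the base-10 pattern code is
#: collision-free (each rank occupies one decimal digit).
MAX_CODED_DIMENSION = 9


def as_signal(x) -> np.ndarray:
    """Validate and coerce ``x`` to a 1-D float array.

    Raises
    ------
    ValueError
        If the series is empty or contains NaN/Inf.
    """
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 1:
        raise ValueError("invalid signal: series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("invalid signal: non-finite samples (NaN/Inf)")
    return arr


def embed(x, d: int) -> np.ndarray:
    """Return the N-d+1 overlapping reconstruction vectors of ``x``.

    Row ``i`` (0-based) is ``x[i:i+d]``, i.e. the window starting at
    sample i+1 in 1-based numbering. Unit delay only.
    """
    x = as_signal(x)
    if d < 2:
        raise ValueError(f"embedding dimension d={d} must be >= 2")
    if x.size < d:
        raise ValueError(f"series too short: N={x.size} < d={d}")
    return np.lib.stride_tricks.sliding_window_view(x, d)


@dataclass(frozen=True)
class OrdinalPattern:
    """An ordinal (Bandt-Pompe) pattern.

    ``ranks`` is the permutation of 1..d that sorts the vector into
    non-decreasing order: ranks[k] is the 1-based original position of
    the (k+1)-th smallest element. ``code`` renders the ranks as one
    base-10 integer (valid for d <= 9), e.g. ranks (1,3,2) -> 132.
    """

    ranks: tuple
    code: int


def _codes_from_ranks(ranks: np.ndarray) -> np.ndarray:
    d = ranks.shape[-1]
    if d > MAX_CODED_DIMENSION:
        raise ValueError(f"base-10 pattern codes require d <= {MAX_CODED_DIMENSION}")
    place = 10 ** np.arange(d - 1, -1, -1, dtype=np.int64)
    return ranks.astype(np.int64) @ place


def pattern_of(vector) -> OrdinalPattern:
    """Ordinal pattern of one d-vector (stable tie-break).

    Equal values keep their original order, so e.g. (4, 5, 4) maps to
    ranks (1, 3, 2) and code 132, and a constant vector maps to the
    identity pattern.
    """
    v = np.asarray(vector, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("pattern requires a vector of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("invalid vector: non-finite entries")
    ranks = np.argsort(v, kind="stable") + 1
    return OrdinalPattern(tuple(int(r) for r in ranks), int(_codes_from_ranks(ranks)))


def ordinal_patterns(x, d: int) -> np.ndarray:
    """Base-10 pattern codes of every reconstruction vector of ``x``.

    Vectorized equivalent of applying :func:`pattern_of` to each row of
    :func:`embed`; returns an int64 array of length N-d+1.
    """
    vectors = embed(x, d)
    ranks = np.argsort(vectors, axis=1, kind="stable") + 1
    return _codes_from_ranks(ranks)


def signed_weights(x, d: int) -> np.ndarray:
    """Signed variance weight of every reconstruction vector.

    The magnitude is the population variance of the vector (divisor d).
    The sign encodes where the vector's mass sits: it is positive iff
    the mean of the interior elements (positions 2..d-1, the single
    middle element when d=3) is at least the mean of the whole vector.
    A vector bulging upward in the middle gets a positive weight, one
    sagging in the middle a negative weight, so two same-pattern
    vectors of equal spread but opposite local shape do not compare as
    equal.
    """
    if d < 3:
        raise ValueError(f"flag undefined: signed weights need d >= 3, got d={d}")
    vectors = embed(x, d)
    w = vectors.var(axis=1)
    flag = vectors[:, 1 : d - 1].mean(axis=1) - vectors.mean(axis=1)
    return np.where(flag >= 0, w, -w)


@dataclass(frozen=True)
class PatternSequence:
    """Per-vector ordinal codes, signed weights and sign flags."""

    codes: np.ndarray
    weights: np.ndarray
    flags: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)


def symbolize(x, d: int) -> PatternSequence:
    """Ordinal codes plus signed weights for every vector of ``x``."""
    codes = ordinal_patterns(x, d)
    weights = signed_weights(x, d)
    return PatternSequence(codes=codes, weights=weights, flags=weights >= 0)


def ipe_symbolize(x, d: int, L: int) -> np.ndarray:
    """Integer symbol vectors for the improved permutation entropy.

    The signal range is split into L equal bins of width
    Delta = (xmax - xmin)/L, the top bin closed at xmax. The first
    element of each vector is quantized directly to its bin index; each
    remaining element k is symbolized relative to the first as
    ``S1 + floor((x_k - x_1)/Delta)``. Every symbol is clamped to
    [0, L-1], so each vector maps to one of L**d words.
    """
    x = as_signal(x)
    if L < 2:
        raise ValueError(f"quantization level count L={L} must be >= 2")
    xmin, xmax = float(x.min()), float(x.max())
    if xmax == xmin:
        raise ValueError("degenerate range: constant signal cannot be quantized")
    delta = (xmax - xmin) / L
    vectors = embed(x, d)
    first = np.minimum(np.floor((vectors[:, :1] - xmin) / delta), L - 1)
    rest = first + np.floor((vectors[:, 1:] - vectors[:, :1]) / delta)
    symbols = np.concatenate([first, rest], axis=1)
    return np.clip(symbols, 0, L - 1).astype(np.int64)
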