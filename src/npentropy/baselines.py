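"""Baseline ordinal entropies: PE, WPE and IPE.

All three are normalized Shannon entropies (natural log) over a
probability distribution derived from the ordinal symbolization of the
series:

* PE   - relative frequencies of the Bandt-Pompe patterns, normalized
  by ln(d!).
* WPE  - patterns weighted by each vector's variance instead of a unit
  count, normalized by ln(d!).
* IPE  - relative frequencies of the L-level quantized symbol words,
  normalized by ln(L**d).

Each value lies in [0, 1]; 0*ln 0 is taken as 0 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import ipe_symbolize, ordinal_patterns, signed_weights

__all__ = ["Distribution", "bandt_pompe_distribution", "pe", "wpe", "ipe"]

_D_RANGE = (3, 9)


def _check_dimension(d: int) -> None:
    lo, hi = _D_RANGE
    if not lo <= d <= hi:
        raise ValueError(f"embedding dimension d={d} outside supported range [{lo}, {hi}]")


@dataclass(frozen=True)
class Distribution:
    """A probability distribution over pattern identities.

    ``labels`` are base-10 pattern codes (PE/WPE) or symbol-word tuples
    (IPE); only observed patterns are listed. ``probs`` are the matching
    probabilities (sum to 1).
    """

    labels: tuple
    probs: np.ndarray

    def __post_init__(self):
        if np.any(self.probs < 0) or abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def as_dict(self) -> dict:
        return {label: float(p) for label, p in zip(self.labels, self.probs)}


def shannon_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*ln 0 := 0 convention."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(max(-(nz * np.log(nz)).sum(), 0.0))


def _normalized(entropy: float, log_states: float) -> float:
    return min(entropy / log_states, 1.0)


def bandt_pompe_distribution(x, d: int) -> Distribution:
    """Relative frequencies of the ordinal patterns of ``x``."""
    codes = ordinal_patterns(x, d)
    labels, counts = np.unique(codes, return_counts=True)
    return Distribution(tuple(int(c) for c in labels), counts / counts.sum())


def pe(x, d: int) -> float:
    """Normalized permutation entropy of ``x`` at dimension ``d``."""
    _check_dimension(d)
    dist = bandt_pompe_distribution(x, d)
    return _normalized(shannon_entropy(dist.probs), math.lgamma(d + 1))


def weighted_distribution(x, d: int) -> Distribution:
    """Variance-weighted pattern distribution used by WPE.

    Each vector contributes its (unsigned) population variance to its
    pattern's mass; the denominator is the total variance mass of all
    vectors.
    """
    codes = ordinal_patterns(x, d)
    weights = np.abs(signed_weights(x, d))
    total = weights.sum()
    if total == 0:
        raise ValueError("degenerate weights: every vector has zero variance")
    labels = np.unique(codes)
    mass = np.array([weights[codes == c].sum() for c in labels])
    return Distribution(tuple(int(c) for c in labels), mass / total)


def wpe(x, d: int) -> float:
    """Normalized weighted permutation entropy of ``x``."""
    _check_dimension(d)
    dist = weighted_distribution(x, d)
    return _normalized(shannon_entropy(dist.probs), math.lgamma(d + 1))


def ipe_distribution(x, d: int, L: int) -> Distribution:
    """Relative frequencies of the L-level quantized symbol words."""
    symbols = ipe_symbolize(x, d, L)
    words, counts = np.unique(symbols, axis=0, return_counts=True)
    labels = tuple(tuple(int(s) for s in row) for row in words)
    return Distribution(labels, counts / counts.sum())


def ipe(x, d: int, L: int) -> float:
    """Normalized improved permutation entropy of ``x``.

    Entropy of the symbol-word distribution over ln(L**d) (the number
    of possible words).
    """
    _check_dimension(d)
    dist = ipe_distribution(x, d, L)
    return _normalized(shannon_entropy(dist.probs), d * math.log(L))
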