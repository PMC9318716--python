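"""Ordinal pattern encoding and permutation entropy.

A window of ``m`` consecutive samples is encoded as its rank vector: entry
``j`` holds the rank (1 = smallest, ``m`` = largest) of sample ``j`` within
the window, with ties resolved in favour of the earlier index.  Permutation
entropy (PE) is the Shannon entropy, in nats, of the empirical distribution
of these patterns over all overlapping windows, plus the Miller--Madow
correction that compensates the negative bias of the plug-in estimator.

The rank-vector convention used here is *not* the argsort (inverse
permutation) convention used by some other packages; for the window
``(4, 7, 2)`` the pattern is ``(2, 3, 1)`` -- "the first sample is the
2nd smallest, the second the 3rd smallest, the third the smallest" --
whereas the argsort convention would give ``(2, 0, 1)``.  The two conventions
yield the same entropy but different pattern labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "OrdinalPattern",
    "OrdinalDistribution",
    "PEEstimate",
    "encode_window",
    "ordinal_distribution",
    "permutation_entropy",
    "lambda0",
    "sigma_memoryless",
    "sigma_harris",
]


class DimensionError(ValueError):
    """Pattern dimension is invalid (m < 2, or too large to enumerate)."""


class SeriesTooShortError(ValueError):
    """The time series has fewer samples than the operation requires."""


class OrdinalPattern(tuple):
    """An ordinal pattern: a permutation of ``1..m`` stored as a tuple.

    Immutable and hashable, so it can serve as a dictionary key.  Entry
    ``j`` is the rank of window sample ``j``, 1 being the smallest.
    """

    __slots__ = ()

    def __new__(cls, ranks: Iterable[int]) -> "OrdinalPattern":
        ranks = tuple(int(r) for r in ranks)
        m = len(ranks)
        if m < 2:
            raise DimensionError(f"pattern dimension must be >= 2, got {m}")
        if sorted(ranks) != list(range(1, m + 1)):
            raise ValueError(f"ranks {ranks} are not a permutation of 1..{m}")
        return super().__new__(cls, ranks)

    @property
    def m(self) -> int:
        return len(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OrdinalPattern{tuple(self)!r}"


@dataclass(frozen=True)
class OrdinalDistribution:
    """Empirical distribution of ordinal patterns over overlapping windows.

    ``window_count`` is ``N - m + 1`` for a series of length ``N``; only
    *visited* patterns are stored, so ``1 <= len(counts) <= m!``.
    """

    m: int
    window_count: int
    counts: Mapping[OrdinalPattern, int]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.window_count:
            raise ValueError(
                f"counts sum to {total}, expected window_count={self.window_count}"
            )

    @property
    def frequencies(self) -> dict[OrdinalPattern, float]:
        """Relative frequencies p̂_S of each visited pattern."""
        wc = self.window_count
        return {s: c / wc for s, c in self.counts.items()}

    @property
    def n_visited(self) -> int:
        """Number of distinct patterns observed (M̂ <= m!)."""
        return len(self.counts)

    @property
    def n(self) -> int:
        """Length of the originating series, N = window_count + m - 1."""
        return self.window_count + self.m - 1


@dataclass(frozen=True)
class PEEstimate:
    """A permutation-entropy value in nats, with provenance.

    ``h = plug_in + mm_correction``; ``h_normalized = h / log(m!)``.  An
    uncertainty may be attached (``sigma``), labelled by the estimator that
    produced it: ``"memoryless"``, ``"harris"`` or ``"surrogate"``.
    """

    h: float
    h_normalized: float
    m: int
    n: int
    plug_in: float
    mm_correction: float
    sigma: Optional[float] = None
    sigma_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("attached uncertainty must be non-negative")

    def with_sigma(self, sigma: float, label: str) -> "PEEstimate":
        """Return a copy with an uncertainty attached."""
        return PEEstimate(
            h=self.h,
            h_normalized=self.h_normalized,
            m=self.m,
            n=self.n,
            plug_in=self.plug_in,
            mm_correction=self.mm_correction,
            sigma=float(sigma),
            sigma_label=str(label),
        )


def _as_finite_array(values, name: str = "series") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = np.ravel(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _rank_windows(values: np.ndarray, m: int) -> np.ndarray:
    """Rank-encode all overlapping m-windows; rows are rank vectors in 1..m."""
    windows = np.lib.stride_tricks.sliding_window_view(values, m)
    # stable argsort implements the earlier-index-wins tie rule
    order = np.argsort(windows, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(windows.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, m + 1)
    return ranks


def encode_window(window: Sequence[float]) -> OrdinalPattern:
    """Encode one window of ``m`` samples as its ordinal pattern.

    Entry ``j`` of the result is the rank of ``window[j]`` (1 = smallest).
    Tied values receive ranks in index order, so the earlier sample gets
    the smaller rank; equality is exact floating-point comparison.

    >>> encode_window((4.0, 7.0, 2.0))
    OrdinalPattern(2, 3, 1)
    """
    arr = _as_finite_array(window, "window")
    m = arr.size
    if m < 2:
        raise DimensionError(f"window must hold at least 2 samples, got {m}")
    return OrdinalPattern(_rank_windows(arr, m)[0])


def ordinal_distribution(x, m: int) -> OrdinalDistribution:
    """Count ordinal patterns over all ``N - m + 1`` overlapping windows.

    Parameters
    ----------
    x : array-like or TimeSeries
        The scalar series; anything exposing ``values`` or castable to a
        1-d float array.
    m : int
        Pattern dimension, ``2 <= m``; the series must satisfy ``N >= m``.
    """
    values = _as_finite_array(getattr(x, "values", x))
    m = int(m)
    if m < 2:
        raise DimensionError(f"pattern dimension must be >= 2, got {m}")
    n = values.size
    if n < m:
        raise SeriesTooShortError(f"series of length {n} is shorter than m={m}")
    ranks = _rank_windows(values, m)
    # encode each rank vector in base m+1 to group identical rows quickly
    base = (m + 1) ** np.arange(m, dtype=np.int64)
    codes = ranks.astype(np.int64) @ base
    _, first_idx, cnt = np.unique(codes, return_index=True, return_counts=True)
    counts = {
        OrdinalPattern(ranks[i]): int(c) for i, c in zip(first_idx, cnt)
    }
    return OrdinalDistribution(m=m, window_count=n - m + 1, counts=counts)


def permutation_entropy(d: OrdinalDistribution) -> PEEstimate:
    """Miller--Madow-corrected permutation entropy of a pattern distribution.

    The plug-in term is ``-sum p̂_S log p̂_S`` over visited patterns; the
    correction adds ``(M̂ - 1) / (2 (N - m + 1))`` with ``M̂`` the number of
    visited patterns.  Both terms and their sum are returned, in nats,
    together with the normalisation ``h / log(m!)``.
    """
    p = np.array(list(d.frequencies.values()))
    plug_in = float(-np.sum(p * np.log(p)))
    mm = (d.n_visited - 1) / (2.0 * d.window_count)
    h = plug_in + mm
    return PEEstimate(
        h=h,
        h_normalized=h / math.log(math.factorial(d.m)),
        m=d.m,
        n=d.n,
        plug_in=plug_in,
        mm_correction=mm,
    )


def _lambda0_from_probs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    logp = np.log(p)
    return float(np.sum(p * logp**2) - np.sum(p * logp) ** 2)


def lambda0(d: OrdinalDistribution) -> float:
    """Plug-in estimate Λ̂₀ = Σ p̂ log²p̂ − (Σ p̂ log p̂)², the population
    variance of −log p̂; zero whenever the distribution is uniform."""
    return max(0.0, _lambda0_from_probs(np.array(list(d.frequencies.values()))))


def sigma_memoryless(d: OrdinalDistribution) -> float:
    """Leading-order PE standard deviation under a memoryless multinomial
    symbol source: sqrt(Λ̂₀ / (N − m + 1)).

    Vanishes for a uniform pattern distribution, where the leading term of
    the variance expansion is zero; callers should then fall back to
    :func:`sigma_harris`.
    """
    return math.sqrt(lambda0(d) / d.window_count)


def sigma_harris(m: int, n: int) -> float:
    """PE standard-deviation floor for a uniform multinomial over the m!
    patterns: sqrt((m! − 1) / 2) / n.

    This is the next-order term of the variance expansion, which dominates
    when all patterns are equiprobable (high-noise limit) and the
    leading-order term vanishes.
    """
    m = int(m)
    if m < 2:
        raise DimensionError(f"pattern dimension must be >= 2, got {m}")
    n = int(n)
    if n <= m:
        raise SeriesTooShortError(f"series length {n} must exceed m={m}")
    return math.sqrt((math.factorial(m) - 1) / 2.0) / n


def permutation_entropy_series(x, m: int) -> PEEstimate:
    """Convenience: pattern distribution and PE of a series in one call."""
    return permutation_entropy(ordinal_distribution(x, m))
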