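"""IAAFT surrogate generation with endpoint detrending.

The iterative amplitude-adjusted Fourier transform (IAAFT) produces
randomised replicas of a series that keep its amplitude distribution
exactly and its power spectrum (hence autocorrelation) approximately.
Because spectral methods assume periodicity, a mismatch between the first
and last sample produces artefacts; the series is therefore first detrended
by subtracting the straight line through its endpoints, which leaves the
endpoints equal without discarding data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ordinal import SeriesTooShortError

__all__ = [
    "TimeSeries",
    "SurrogateEnsemble",
    "detrend_endpoints",
    "iaaft",
    "make_ensemble",
    "CONVERGENCE_RTOL",
]

logger = logging.getLogger(__name__)

#: Relative threshold of the IAAFT stop rule: iteration ends when the squared
#: Euclidean distance between consecutive iterates falls below this fraction
#: of the iterate's squared norm.
CONVERGENCE_RTOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of finite real samples.

    ``seed`` and ``label`` are optional provenance metadata; they do not
    affect equality of the numerical content.
    """

    values: np.ndarray
    seed: Optional[int] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            arr = np.ravel(arr)
        if arr.size < 2:
            raise SeriesTooShortError(
                f"a time series needs at least 2 samples, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series contains non-finite values")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SurrogateEnsemble:
    """L IAAFT surrogates of one (detrended) original series.

    ``iterations`` and ``converged`` record, per surrogate, how many IAAFT
    cycles were run and whether the stop rule was met before the iteration
    cap.  Surrogates are stored after their own endpoint detrending, so
    their amplitude multiset matches the original's up to the (small)
    detrending shift.
    """

    original: TimeSeries
    surrogates: tuple[TimeSeries, ...]
    iterations: tuple[int, ...]
    converged: tuple[bool, ...]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = self.original.n
        if any(s.n != n for s in self.surrogates):
            raise ValueError("all surrogates must have the original's length")
        if not (len(self.surrogates) == len(self.iterations) == len(self.converged)):
            raise ValueError("per-surrogate diagnostics must match ensemble size")

    @property
    def l(self) -> int:
        return len(self.surrogates)


def detrend_endpoints(x: TimeSeries | Sequence[float]) -> TimeSeries:
    """Subtract the line through the first and last samples.

    Maps ``x_n -> x_n - (x_N - x_1)/(N - 1) * (n - 1)`` so that the output's
    first and last values both equal ``x_1``.  A series whose endpoints
    already coincide is returned unchanged in value.
    """
    ts = x if isinstance(x, TimeSeries) else TimeSeries(np.asarray(x, dtype=float))
    v = ts.values
    n = v.size
    slope = (v[-1] - v[0]) / (n - 1)
    out = v - slope * np.arange(n)
    return TimeSeries(out, seed=ts.seed, label=ts.label)


def _iaaft_core(
    values: np.ndarray, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, int, bool]:
    """Run the IAAFT iteration; returns (surrogate, iterations, converged).

    Each cycle takes the original's Fourier amplitudes with the current
    iterate's phases, inverse-transforms, and rank-remaps the result onto
    the original's sorted amplitudes, so every iterate carries exactly the
    original's amplitude multiset.  Stops when consecutive iterates are
    closer (squared Euclidean) than ``CONVERGENCE_RTOL`` times the squared
    norm, or when the rank ordering revisits a previous state (fixed point
    or 2-cycle, from which no further change is possible).
    """
    n = values.size
    sorted_x = np.sort(values)
    target_amp = np.abs(np.fft.rfft(values))
    y = rng.permutation(values)
    if not np.any(values):
        return y, 0, True  # all-zero input: any shuffle is already exact
    prev_orders: list[np.ndarray] = []
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        phases = np.angle(np.fft.rfft(y))
        z = np.fft.irfft(target_amp * np.exp(1j * phases), n=n)
        order = np.argsort(z, kind="stable")
        y_new = np.empty(n)
        y_new[order] = sorted_x
        dist2 = float(np.sum((y_new - y) ** 2))
        norm2 = float(np.sum(y_new**2))
        y = y_new
        if dist2 < CONVERGENCE_RTOL * norm2:
            converged = True
            break
        if any(np.array_equal(order, o) for o in prev_orders):
            # the iteration revisited a rank ordering: it is locked in a
            # cycle and cannot improve further; treat as terminal
            converged = True
            break
        prev_orders.append(order)
        if len(prev_orders) > 2:
            prev_orders.pop(0)
    return y, iterations, converged


def iaaft(
    x: TimeSeries | Sequence[float],
    seed: Optional[int] = None,
    max_iter: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> TimeSeries:
    """Generate one IAAFT surrogate of ``x``.

    The caller is responsible for detrending ``x`` first (see
    :func:`make_ensemble` for the full pipeline).  If the iteration cap is
    reached before convergence a warning is logged and the last iterate is
    returned; its amplitude multiset is still exact.
    """
    ts = x if isinstance(x, TimeSeries) else TimeSeries(np.asarray(x, dtype=float))
    if rng is None:
        rng = np.random.default_rng(seed)
    out, iterations, converged = _iaaft_core(ts.values, rng, max_iter)
    if not converged:
        logger.warning(
            "IAAFT did not converge within %d iterations (N=%d)", max_iter, ts.n
        )
    return TimeSeries(out, seed=seed, label=ts.label)


def make_ensemble(
    x: TimeSeries | Sequence[float],
    l: int = 100,
    seed: Optional[int] = None,
    max_iter: int = 1000,
) -> SurrogateEnsemble:
    """Detrend ``x`` and generate ``l`` independent IAAFT surrogates of it.

    Per-surrogate random streams are spawned from ``seed`` through
    ``numpy.random.SeedSequence``, so the ensemble is reproducible given
    ``(x, l, seed)`` while the surrogates remain mutually independent.
    Each surrogate is endpoint-detrended after generation, matching the
    pipeline the uncertainty procedure requires.
    """
    if l < 2:
        raise ValueError(f"ensemble size must be at least 2, got {l}")
    ts = x if isinstance(x, TimeSeries) else TimeSeries(np.asarray(x, dtype=float))
    original = detrend_endpoints(ts)
    children = np.random.SeedSequence(seed).spawn(l)
    surrogates = []
    iterations = []
    converged = []
    for child in children:
        out, its, ok = _iaaft_core(original.values, np.random.default_rng(child), max_iter)
        surrogates.append(detrend_endpoints(TimeSeries(out)))
        iterations.append(its)
        converged.append(ok)
    n_bad = sum(not ok for ok in converged)
    if n_bad:
        logger.warning(
            "%d of %d surrogates did not converge within %d iterations",
            n_bad, l, max_iter,
        )
    return SurrogateEnsemble(
        original=original,
        surrogates=tuple(surrogates),
        iterations=tuple(iterations),
        converged=tuple(converged),
        seed=seed,
    )
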