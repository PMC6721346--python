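"""Approximate entropy (ApEn) and sliding-window ApEn series.

ApEn(m, r) quantifies the regularity of a series: embed it as overlapping
m-dimensional template vectors, count templates within Chebyshev distance r
of each other, and compare the log match frequencies at dimensions m and
m + 1,

    ApEn(m, r) = phi^m(r) - phi^(m+1)(r),
    phi^m(r)   = mean_i ln C_i^m(r),
    C_i^m(r)   = #{j : max_k |x(i+k) - x(j+k)| <= r} / (N - m + 1).

Low values mean predictable, narrow-band signals; high values mean complex,
noise-like signals.  Conventions follow Pincus's original definition:
self-matches (j = i) are counted, so every C_i > 0 and the logarithm is
always defined; the match test is ``d <= r``; dimension m uses N - m + 1
templates and dimension m + 1 uses N - m.  With these conventions ApEn is
non-negative whenever matches are abundant, but for series where only
self-matches occur (e.g. a strict ramp with r below the step) the differing
normalizations make it slightly negative — ln((N-m)/(N-m+1)) at the extreme.

Defaults are m = 2 and r = 0.25 * SD of the series, a standard operating
point for short physiological records; in sliding mode r is resolved from
each window's own SD so the statistic stays amplitude-invariant per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

try:  # JIT-compiled sliding kernel; pure-NumPy path used when unavailable
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.25
DEFAULT_WINDOW = 500
DEFAULT_STEP = 1


@dataclass
class ApEnParams:
    """Embedding dimension and tolerance policy.

    ``r`` (absolute tolerance), when given, overrides ``r_factor``
    (tolerance as a fraction of the series' standard deviation).
    """

    m: int = DEFAULT_M
    r_factor: float = DEFAULT_R_FACTOR
    r: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r is None and not (0 < self.r_factor <= 1):
            raise ValueError(f"r_factor must be in (0, 1], got {self.r_factor}")
        if self.r is not None and self.r <= 0:
            raise ValueError(f"absolute tolerance r must be > 0, got {self.r}")

    def resolve_r(self, series: np.ndarray) -> float:
        """Absolute tolerance for one series (0 for a constant series).

        A standard deviation that is negligible relative to the data scale
        (float rounding on a constant series) counts as zero variance.
        """
        if self.r is not None:
            return float(self.r)
        x = np.asarray(series, dtype=float)
        sd = float(np.std(x))
        scale = float(np.max(np.abs(x), initial=0.0))
        if sd <= 1e-12 * max(1.0, scale):
            return 0.0
        return float(self.r_factor * sd)


@dataclass
class ApEnSeries:
    """Sliding-window ApEn values.

    Window w (1-based) covers samples ``[(w-1)*step, (w-1)*step + L)``; the
    number of windows is ``(N - L) // step`` — the final full-length window
    position at offset ``N - L`` is deliberately not emitted, matching the
    convention that a 2000-sample trial with L = 500, step 1 yields 1500
    values.
    """

    values: np.ndarray
    window_length: int
    step: int

    @property
    def count(self) -> int:
        return self.values.size


def _check_length(n: int, m: int) -> None:
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m} (need >= {m + 2})")


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """phi^m(r) from scratch: embed, Chebyshev distances, log match ratios."""
    n = x.size - m + 1
    d = np.abs(x[:n, None] - x[None, :n])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n, None] - x[None, k : k + n]), out=d)
    counts = np.count_nonzero(d <= r, axis=1)
    return float(np.mean(np.log(counts / n)))


def apen(series: np.ndarray, params: ApEnParams | None = None) -> float:
    """Approximate entropy by two independent passes (dimension m, then m+1)."""
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float).ravel()
    _check_length(x.size, params.m)
    r = params.resolve_r(x)
    if r == 0:
        warnings.warn(
            "zero-variance series with relative tolerance: ApEn defined as 0",
            stacklevel=2,
        )
        return 0.0
    return _phi(x, params.m, r) - _phi(x, params.m + 1, r)


def apen_fast(series: np.ndarray, params: ApEnParams | None = None) -> float:
    """Approximate entropy via one pass over a shared distance structure.

    Numerically equal to :func:`apen` (to ~1e-12): the dimension-(m+1)
    Chebyshev distances are the dimension-m distances extended by one lag, so
    both match counts come from a single incremental structure instead of two
    independent embeddings.
    """
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float).ravel()
    _check_length(x.size, params.m)
    r = params.resolve_r(x)
    if r == 0:
        warnings.warn(
            "zero-variance series with relative tolerance: ApEn defined as 0",
            stacklevel=2,
        )
        return 0.0
    m = params.m
    n1 = x.size - m + 1  # templates at dimension m
    n2 = x.size - m  # templates at dimension m + 1
    d = np.abs(x[:n1, None] - x[None, :n1])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n1, None] - x[None, k : k + n1]), out=d)
    counts_m = np.count_nonzero(d <= r, axis=1)
    np.maximum(
        d[:n2, :n2], np.abs(x[m : m + n2, None] - x[None, m : m + n2]), out=d[:n2, :n2]
    )
    counts_m1 = np.count_nonzero(d[:n2, :n2] <= r, axis=1)
    phi_m = float(np.mean(np.log(counts_m / n1)))
    phi_m1 = float(np.mean(np.log(counts_m1 / n2)))
    return phi_m - phi_m1


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _sliding_kernel(
        x: np.ndarray, L: int, step: int, m: int, r_factor: float, r_abs: float
    ) -> np.ndarray:  # pragma: no cover - exercised via sliding_apen
        count = (x.size - L) // step
        out = np.empty(count)
        n1 = L - m + 1
        n2 = L - m
        c1 = np.empty(n1, dtype=np.int64)
        c2 = np.empty(n2, dtype=np.int64)
        for w in range(count):
            win = x[w * step : w * step + L]
            r = r_factor * win.std() if r_abs <= 0 else r_abs
            if r == 0.0:
                out[w] = 0.0
                continue
            c1[:] = 1  # self-matches
            c2[:] = 1
            # Chebyshev distances are symmetric: visit each pair once
            for i in range(n1):
                for j in range(i + 1, n1):
                    d = 0.0
                    for k in range(m):
                        t = abs(win[i + k] - win[j + k])
                        if t > d:
                            d = t
                    if d <= r:
                        c1[i] += 1
                        c1[j] += 1
                        if j < n2:
                            t = abs(win[i + m] - win[j + m])
                            if t > d:
                                d = t
                            if d <= r:
                                c2[i] += 1
                                c2[j] += 1
            phi1 = 0.0
            for i in range(n1):
                phi1 += np.log(c1[i] / n1)
            phi2 = 0.0
            for i in range(n2):
                phi2 += np.log(c2[i] / n2)
            out[w] = phi1 / n1 - phi2 / n2
        return out


def sliding_apen(
    series: np.ndarray,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    params: ApEnParams | None = None,
) -> ApEnSeries:
    """ApEn of each sliding window of ``series``.

    When ``params.r`` is unset, the tolerance is resolved per window from
    that window's own standard deviation.
    """
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= window_length:
        raise ValueError(
            f"series length {x.size} must exceed window length {window_length}"
        )
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if _HAVE_NUMBA:
        r_abs = params.r if params.r is not None else -1.0
        values = _sliding_kernel(
            np.ascontiguousarray(x), window_length, step, params.m,
            params.r_factor, r_abs,
        )
    else:
        count = (x.size - window_length) // step
        values = np.empty(count)
        for w in range(count):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values[w] = apen_fast(
                    x[w * step : w * step + window_length], params
                )
    return ApEnSeries(values=values, window_length=window_length, step=step)
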