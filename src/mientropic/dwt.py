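"""Dyadic discrete wavelet decomposition and per-sub-band reconstruction.

An ``L``-level Mallat decomposition splits ``(0, fs/2)`` into ``L + 1``
contiguous sub-bands: an approximation band ``A_L`` covering
``(0, fs/2^(L+1))`` and detail bands ``D_L .. D_1`` each spanning one octave
up to Nyquist.  At ``fs = 250`` Hz with ``L = 4`` the detail band ``D4``
covers ~7.8-15.6 Hz (the mu rhythm) and ``D3`` ~15.6-31.2 Hz (the beta
rhythm), which is why those two bands feed the rest of the pipeline.

The transform uses PyWavelets with symmetric (half-sample mirror) signal
extension; the extension mode is fixed, not configurable, so coefficient
layouts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

_EXT_MODE = "symmetric"

#: Sub-bands the classification pipeline keeps by default.
DEFAULT_BANDS = ("D3", "D4")


@dataclass
class WaveletParams:
    """Wavelet basis and decomposition depth."""

    wavelet_name: str = "db4"
    levels: int = 4

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        self.wavelet = pywt.Wavelet(self.wavelet_name)


@dataclass
class SubBandDecomposition:
    """Coefficient pyramid plus frequency bookkeeping for one signal.

    ``coefficients`` maps band names (``"A{L}"``, ``"D{L}"`` .. ``"D1"``) to
    coefficient arrays; ``band_edges`` maps the same names to exact
    ``(low, high)`` dyadic edges in Hz.
    """

    coefficients: dict[str, np.ndarray]
    band_edges: dict[str, tuple[float, float]]
    fs: float
    wavelet_params: WaveletParams
    signal_length: int = 0
    _coeff_list: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def band_names(self) -> list[str]:
        return list(self.coefficients)


def subband_edges(fs: float, levels: int, rounding: str = "none") -> list[float]:
    """Boundaries of the ``levels + 1`` dyadic sub-bands, in Hz.

    With ``rounding="none"`` the exact edges ``fs / 2**k`` for
    ``k = levels+1 .. 1`` are returned (prepended with 0).  With
    ``rounding="paper"`` the lowest boundary ``fs / 2**(levels+1)`` is rounded
    to one decimal first and then doubled successively — the convention under
    which the customary printed table of 250 Hz sub-bands reads
    ``0-7.8, 7.8-15.6, 15.6-31.2, 31.2-62.4, 62.4-124.8``.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if rounding not in ("none", "paper"):
        raise ValueError(f"rounding must be 'none' or 'paper', got {rounding!r}")
    if rounding == "paper":
        b = round(fs / 2 ** (levels + 1), 1)
        edges = [0.0]
        for _ in range(levels + 1):
            edges.append(b)
            b *= 2
        return edges
    return [0.0] + [fs / 2**k for k in range(levels + 1, 0, -1)]


def band_edge_map(
    fs: float, levels: int, rounding: str = "none"
) -> dict[str, tuple[float, float]]:
    """Map band names ``A{L}, D{L} .. D1`` to ``(low, high)`` Hz."""
    edges = subband_edges(fs, levels, rounding)
    names = [f"A{levels}"] + [f"D{lvl}" for lvl in range(levels, 0, -1)]
    return {n: (edges[i], edges[i + 1]) for i, n in enumerate(names)}


def decompose(
    signal: np.ndarray, params: WaveletParams | None = None, fs: float = 250.0
) -> SubBandDecomposition:
    """Mallat pyramid decomposition of a single-channel series.

    Returns a :class:`SubBandDecomposition` with ``levels`` detail bands and
    one approximation band; the inverse transform of the full pyramid
    reproduces the input (perfect reconstruction).
    """
    params = params or WaveletParams()
    x = np.asarray(signal, dtype=float).ravel()
    min_len = 2**params.levels
    if x.size < min_len:
        raise ValueError(
            f"signal of length {x.size} too short for {params.levels}-level "
            f"decomposition (minimum {min_len} samples)"
        )
    coeff_list = pywt.wavedec(x, params.wavelet, mode=_EXT_MODE, level=params.levels)
    names = [f"A{params.levels}"] + [
        f"D{lvl}" for lvl in range(params.levels, 0, -1)
    ]
    return SubBandDecomposition(
        coefficients=dict(zip(names, coeff_list)),
        band_edges=band_edge_map(fs, params.levels),
        fs=fs,
        wavelet_params=params,
        signal_length=x.size,
        _coeff_list=list(coeff_list),
    )


def reconstruct_full(decomp: SubBandDecomposition) -> np.ndarray:
    """Inverse transform of the complete pyramid."""
    rec = pywt.waverec(decomp._coeff_list, decomp.wavelet_params.wavelet, mode=_EXT_MODE)
    return rec[: decomp.signal_length]


def reconstruct_band(decomp: SubBandDecomposition, band_id: str) -> np.ndarray:
    """Time-domain signal containing only one sub-band.

    All other coefficient arrays are zeroed before the inverse transform, so
    by linearity the per-band reconstructions sum to the original signal.
    """
    if band_id not in decomp.coefficients:
        raise KeyError(
            f"unknown band {band_id!r}; available bands: {decomp.band_names}"
        )
    masked = [
        c if name == band_id else np.zeros_like(c)
        for name, c in decomp.coefficients.items()
    ]
    rec = pywt.waverec(masked, decomp.wavelet_params.wavelet, mode=_EXT_MODE)
    return rec[: decomp.signal_length]
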