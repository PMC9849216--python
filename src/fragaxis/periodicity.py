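"""Detection of helical-pitch (10-bp) periodicity in positional signals.

A positional series (typically a nucleosome-relative end-frequency
profile) is first de-trended by subtracting a locally weighted
regression (loess) fit, then a plain FFT periodogram gives the spectral
density at the Fourier frequencies; the dominant period inside a band
(default 5–20 bp) summarises the oscillation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import periodogram as _scipy_periodogram
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["Periodogram", "detrend", "periodogram", "dominant_period"]


@dataclasses.dataclass
class Periodogram:
    """One-sided power spectrum at Fourier frequencies (cycles per bp)."""

    frequencies: np.ndarray
    density: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")
        if np.any((self.frequencies <= 0) | (self.frequencies > 0.5)):
            raise ValueError("frequencies must lie in (0, 0.5]")

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.frequencies


def detrend(signal: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Residuals after subtracting a loess (tricube, degree-1) fit.

    ``span`` is the loess fraction of the series used per local fit.
    Residuals are re-centred so their mean is exactly zero.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = len(signal)
    if n < 10:
        raise ValueError("signal too short to de-trend")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if span * n < 3:
        raise ValueError(f"span {span} covers fewer than 3 points for length {n}")
    x = np.arange(n, dtype=np.float64)
    fit = lowess(signal, x, frac=span, return_sorted=False)
    residual = signal - fit
    return residual - residual.mean()


def periodogram(signal: np.ndarray, pad_to: int | None = None) -> Periodogram:
    """Plain (untapered, boxcar) FFT periodogram of a de-trended series.

    With ``scaling='spectrum'`` the total one-sided density equals the
    mean square of the series (a Parseval identity), so spectral mass
    is directly comparable to residual variance.  ``pad_to`` zero-pads
    the series for a finer frequency grid.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = len(signal)
    if n < 4:
        raise ValueError("signal too short for a periodogram")
    nfft = max(pad_to or n, n)
    freqs, density = _scipy_periodogram(
        signal, window="boxcar", nfft=nfft, detrend=False, scaling="spectrum"
    )
    keep = freqs > 0
    return Periodogram(frequencies=freqs[keep], density=density[keep], n=n)


def dominant_period(
    pg: Periodogram, band: tuple[float, float] = (5.0, 20.0)
) -> float:
    """Period (bp) of maximal spectral density within a period band.

    Ties break toward the shorter period.
    """
    lo, hi = band
    if not (2.0 < lo < hi):
        raise ValueError("band must satisfy 2 < lo < hi")
    periods = pg.periods
    mask = (periods >= lo) & (periods <= hi)
    if not mask.any():
        raise ValueError(f"no Fourier frequency falls in the {band} bp band")
    dens = pg.density[mask]
    freqs = pg.frequencies[mask]
    best = dens.max()
    candidates = freqs[dens == best]
    return float(1.0 / candidates.max())
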