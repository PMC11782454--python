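"""Culture phenotype utilities: growth rates and absorption spectra.

Growth rate is the slope of ln(OD) versus time restricted to a fixed OD
window (default 0.1-0.3, the quasi-exponential range of a dilute bubbled
photobioreactor culture). Whole-cell absorption spectra are corrected
for light scatter by normalizing at 730 nm and subtracting the chord
between 560 and 730 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ODSeries",
    "Spectrum",
    "fit_growth_rate",
    "generation_time",
    "correct_spectrum_scatter",
]


@dataclass(frozen=True)
class ODSeries:
    """Optical density time course (time in h, OD dimensionless)."""

    time: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        od = np.asarray(self.od, float)
        if t.shape != od.shape:
            raise ValueError("time and od must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("od must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class Spectrum:
    """Absorption spectrum (wavelength in nm, absorbance in OD units)."""

    wavelength: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, float)
        ab = np.asarray(self.absorbance, float)
        if wl.shape != ab.shape:
            raise ValueError("wavelength and absorbance must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength must be strictly increasing")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)


def fit_growth_rate(series: ODSeries, window: tuple[float, float] = (0.1, 0.3)) -> float:
    """Specific growth rate (h^-1) from an exponential fit in an OD window.

    Ordinary least squares of ln(OD) on time over points with OD in the
    closed interval ``window``. Requires at least three in-window points.
    """
    lo, hi = window
    mask = (series.od >= lo) & (series.od <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points with OD in [{lo}, {hi}], found {int(mask.sum())}"
        )
    slope, _ = np.polyfit(series.time[mask], np.log(series.od[mask]), 1)
    return float(slope)


def generation_time(mu: float) -> float:
    """Generation (doubling) time T_gen = ln(2)/mu, in hours."""
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return float(np.log(2.0) / mu)


def correct_spectrum_scatter(spec: Spectrum, outside: str = "extrapolate") -> Spectrum:
    """Scatter-correct a whole-cell spectrum.

    The spectrum is scaled so absorbance at 730 nm is 1, then the straight
    line (chord) through the 560 nm and 730 nm points is subtracted — an
    estimate of the wavelength-dependent light scatter of the cells. The
    corrected spectrum is 0 at 560 and 730 nm by construction.

    ``outside`` controls treatment beyond [560, 730] nm: "extrapolate"
    subtracts the extended chord; "keep" leaves those points at their
    normalized values.
    """
    wl, ab = spec.wavelength, spec.absorbance
    if wl[0] > 560.0 or wl[-1] < 730.0:
        raise ValueError("spectrum must cover 560-730 nm")
    a730 = float(np.interp(730.0, wl, ab))
    if a730 == 0:
        raise ValueError("absorbance at 730 nm is zero; cannot normalize")
    norm = ab / a730
    a560 = float(np.interp(560.0, wl, norm))
    chord = a560 + (1.0 - a560) * (wl - 560.0) / (730.0 - 560.0)
    corrected = norm - chord
    if outside == "keep":
        inside = (wl >= 560.0) & (wl <= 730.0)
        corrected = np.where(inside, corrected, norm)
    elif outside != "extrapolate":
        raise ValueError("outside must be 'extrapolate' or 'keep'")
    return Spectrum(wavelength=wl.copy(), absorbance=corrected)
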