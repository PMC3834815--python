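"""Low-energy CD spectrum processing and exciton-coupling metrics.

Processing chain as used for the 2AP-dimer couplet band: scan averaging,
blank (no-DNA) baseline subtraction, Means-Movement smoothing (a centred
moving average, width counted in points), conversion of ellipticity to
molar CD per mol 2AP residue, and amplitude metrics on the red-shifted
exciton lobe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    IncompatibleGridError,
    UndefinedReferenceError,
)

__all__ = [
    "CDSpectrum",
    "ExcitonMetrics",
    "MDEG_PER_DELTA_EPS",
    "average_scans",
    "baseline_subtract",
    "smooth_means_movement",
    "to_delta_epsilon",
    "from_delta_epsilon",
    "exciton_metrics",
    "percent_signal_change",
]

#: Standard conversion between ellipticity in mdeg and molar CD:
#: theta[mdeg] = 32980 * delta_eps[M^-1 cm^-1] * c[M] * l[cm]
MDEG_PER_DELTA_EPS = 32980.0

UNITS = ("mdeg", "delta_epsilon")


@dataclass
class CDSpectrum:
    """Wavelength-resolved CD data with acquisition metadata."""

    wavelengths: np.ndarray
    values: np.ndarray
    units: str = "mdeg"
    n_scans: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ConfigurationError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ConfigurationError("wavelengths and values must match in length")
        if self.wavelengths.size < 2:
            raise ConfigurationError("a spectrum needs at least 2 points")
        dw = np.diff(self.wavelengths)
        if np.any(dw <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if not np.allclose(dw, dw[0], rtol=1e-6, atol=0.0):
            raise ConfigurationError("wavelength grid must be uniform")
        if self.units not in UNITS:
            raise ConfigurationError(f"units must be one of {UNITS}")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def same_grid(self, other: "CDSpectrum") -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.allclose(
            self.wavelengths, other.wavelengths, rtol=1e-9, atol=1e-9
        )

    def replace_values(self, values: np.ndarray, **meta) -> "CDSpectrum":
        md = dict(self.metadata)
        md.update(meta)
        return CDSpectrum(self.wavelengths.copy(), np.asarray(values, float),
                          units=self.units, n_scans=self.n_scans, metadata=md)


@dataclass
class ExcitonMetrics:
    """Amplitude metrics of the red-shifted exciton lobe."""

    amplitude_330: float
    band_mean_320_330: float
    peak_wavelength: float
    peak_defined: bool = True


def average_scans(spectra: list) -> CDSpectrum:
    """Pointwise mean of repeat scans; n_scans accumulates."""
    if not spectra:
        raise ConfigurationError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if not ref.same_grid(s):
            raise IncompatibleGridError("scan grids differ")
        if s.units != ref.units:
            raise ConfigurationError("scan units differ")
    mean = np.mean([s.values for s in spectra], axis=0)
    out = ref.replace_values(mean)
    out.n_scans = sum(s.n_scans for s in spectra)
    return out


def baseline_subtract(sample: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    """Pointwise sample - blank (blank recorded without DNA)."""
    if sample.units != blank.units:
        raise ConfigurationError("sample and blank units differ")
    if not sample.same_grid(blank):
        raise IncompatibleGridError("sample and blank grids differ")
    return sample.replace_values(sample.values - blank.values,
                                 baseline_corrected=True)


def smooth_means_movement(spectrum: CDSpectrum, width: int = 5) -> CDSpectrum:
    """Centred moving average over ``width`` points (Means-Movement style).

    At the edges the window shrinks symmetrically, so the first and last
    points pass through unchanged for width 5, the next use a 3-point
    window, and so on. Grid length is preserved.
    """
    if width % 2 == 0:
        raise ConfigurationError("smoothing width must be odd")
    if width < 3:
        raise ConfigurationError("smoothing width must be at least 3")
    v = spectrum.values
    n = v.size
    half = width // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return spectrum.replace_values(out, smoothed_width=width)


def to_delta_epsilon(spectrum: CDSpectrum, conc_2ap: float,
                     pathlength: float) -> CDSpectrum:
    """Convert mdeg ellipticity to molar CD per mol 2AP residue.

    ``conc_2ap`` is the 2AP-residue concentration in mol/L (strand
    concentration times residues per strand); ``pathlength`` in cm.
    """
    if spectrum.units != "mdeg":
        raise ConfigurationError("input spectrum must be in mdeg")
    if conc_2ap <= 0:
        raise ConfigurationError("2AP concentration must be positive")
    if pathlength <= 0:
        raise ConfigurationError("pathlength must be positive")
    out = spectrum.replace_values(
        spectrum.values / (MDEG_PER_DELTA_EPS * conc_2ap * pathlength),
        conc_2ap=conc_2ap, pathlength_cm=pathlength,
    )
    out.units = "delta_epsilon"
    return out


def from_delta_epsilon(spectrum: CDSpectrum, conc_2ap: float,
                       pathlength: float) -> CDSpectrum:
    """Inverse of :func:`to_delta_epsilon`."""
    if spectrum.units != "delta_epsilon":
        raise ConfigurationError("input spectrum must be in delta_epsilon")
    if conc_2ap <= 0 or pathlength <= 0:
        raise ConfigurationError("concentration and pathlength must be positive")
    out = spectrum.replace_values(
        spectrum.values * (MDEG_PER_DELTA_EPS * conc_2ap * pathlength)
    )
    out.units = "mdeg"
    return out


def exciton_metrics(spectrum: CDSpectrum, band: tuple = (300.0, 360.0)) -> ExcitonMetrics:
    """Amplitude at 330 nm, 320-330 nm band mean, and extremum position.

    The extremum is the sign-aware maximum of ``|value|`` within ``band``.
    A numerically all-zero band yields zero metrics and ``peak_defined=False``.
    """
    if spectrum.units != "delta_epsilon":
        raise ConfigurationError("metrics require delta_epsilon units")
    wl, v = spectrum.wavelengths, spectrum.values
    lo, hi = band
    if wl.min() > lo or wl.max() < hi:
        raise ConfigurationError(f"grid does not cover the {lo}-{hi} nm band")
    amp330 = float(np.interp(330.0, wl, v))
    sel_band = (wl >= 320.0) & (wl <= 330.0)
    band_mean = float(v[sel_band].mean())
    sel = (wl >= lo) & (wl <= hi)
    absmax = np.abs(v[sel]).max()
    if absmax <= 0.0 or not math.isfinite(absmax):
        return ExcitonMetrics(amp330, band_mean, float("nan"), peak_defined=False)
    peak = float(wl[sel][np.argmax(np.abs(v[sel]))])
    return ExcitonMetrics(amp330, band_mean, peak, peak_defined=True)


def percent_signal_change(sample: ExcitonMetrics, reference: ExcitonMetrics,
                          metric: str = "amplitude_330") -> float:
    """Percentage reduction of the couplet amplitude relative to a reference.

    100 * (1 - sample/reference); negative values indicate signal growth.
    """
    ref = getattr(reference, metric)
    sam = getattr(sample, metric)
    if ref == 0:
        raise UndefinedReferenceError("reference amplitude is zero")
    return 100.0 * (1.0 - sam / ref)
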