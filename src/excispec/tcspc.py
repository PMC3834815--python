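"""Global iterative-reconvolution fitting of multi-exponential TCSPC decays.

One or several decay histograms are fitted simultaneously with a
multi-exponential model convolved with the measured instrument response.
Lifetimes are shared (linked) across curves; fractional amplitudes,
background and a channel shift are free per curve.

The optimiser uses variable projection: for any trial set of lifetimes and
shifts, the per-curve amplitudes and background solve a weighted
non-negative linear least-squares problem exactly, so only the lifetimes
(in log-space) and shifts are iterated nonlinearly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.signal import fftconvolve

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    IncompatibleGridError,
    InvalidStateError,
)

__all__ = [
    "DecayCurve",
    "DecayModel",
    "GlobalFitResult",
    "reconvolve",
    "fit_global",
    "reduced_chisq",
    "residual_randomness",
    "select_model_order",
    "estimate_uncertainties",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """A single TCSPC histogram (also used for the instrument response).

    Parameters
    ----------
    times
        Bin-centre time grid in ns; must be uniform and increasing.
    counts
        Non-negative counts per bin (floats allowed, e.g. for a
        normalised IRF or a noiseless expectation).
    wavelength
        Emission wavelength in nm, if applicable.
    metadata
        Free-form key/value metadata carried through file round-trips.
    """

    times: np.ndarray
    counts: np.ndarray
    wavelength: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.counts.ndim != 1:
            raise ConfigurationError("times and counts must be 1-D arrays")
        if self.times.size != self.counts.size:
            raise ConfigurationError("times and counts must have equal length")
        if self.times.size < 2:
            raise ConfigurationError("a decay curve needs at least 2 channels")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ConfigurationError("time grid must be uniform")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ConfigurationError("counts must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.times.size

    @property
    def bin_width(self) -> float:
        """Channel width in ns."""
        return float(self.times[1] - self.times[0])

    def same_grid(self, other: "DecayCurve") -> bool:
        return self.times.size == other.times.size and np.allclose(
            self.times, other.times, rtol=1e-9, atol=1e-12
        )


@dataclass
class DecayModel:
    """Multi-exponential model with shared lifetimes.

    ``lifetimes`` (ns, ascending) are common to all curves; ``amplitudes``
    has one row of non-negative pre-exponential factors per curve;
    ``backgrounds`` (counts/bin) and ``shifts`` (channels, real-valued)
    are per curve.
    """

    lifetimes: np.ndarray
    amplitudes: np.ndarray
    backgrounds: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        self.backgrounds = np.atleast_1d(np.asarray(self.backgrounds, dtype=float))
        self.shifts = np.atleast_1d(np.asarray(self.shifts, dtype=float))
        if np.any(self.lifetimes <= 0):
            raise ConfigurationError("lifetimes must be positive")
        # ties allowed: an over-specified fit may converge to duplicates
        if np.any(np.diff(self.lifetimes) < 0):
            raise ConfigurationError("lifetimes must be ordered ascending")
        if self.amplitudes.shape[1] != self.lifetimes.size:
            raise ConfigurationError(
                "amplitudes must have one column per lifetime component"
            )
        if np.any(self.amplitudes < 0):
            raise ConfigurationError("amplitudes must be non-negative")
        n_curves = self.amplitudes.shape[0]
        if self.backgrounds.size != n_curves or self.shifts.size != n_curves:
            raise ConfigurationError("backgrounds/shifts must match curve count")

    @property
    def n_components(self) -> int:
        return self.lifetimes.size

    @property
    def n_curves(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def a_factors(self) -> np.ndarray:
        """Per-curve fractional amplitudes (rows sum to 1)."""
        tot = self.amplitudes.sum(axis=1, keepdims=True)
        tot = np.where(tot > 0, tot, 1.0)
        return self.amplitudes / tot

    def sorted(self) -> "DecayModel":
        """Copy with components reordered by ascending lifetime."""
        order = np.argsort(self.lifetimes, kind="stable")
        return DecayModel(
            lifetimes=self.lifetimes[order],
            amplitudes=self.amplitudes[:, order],
            backgrounds=self.backgrounds.copy(),
            shifts=self.shifts.copy(),
        )


@dataclass
class GlobalFitResult:
    """Converged linked-parameter fit with diagnostics."""

    model: DecayModel
    chisq_reduced_global: float
    chisq_reduced: np.ndarray              # per curve
    weighted_residuals: list               # per curve, fit range only
    residual_randomness: np.ndarray        # runs-test p per curve
    fit_range: tuple                       # (start, stop) channel interval
    n_iterations: int
    converged: bool
    curve_intensities: np.ndarray          # total counts per curve in range
    wavelengths: list
    uncertainties: dict | None = None      # filled by estimate_uncertainties

    @property
    def lifetimes(self) -> np.ndarray:
        return self.model.lifetimes

    @property
    def a_factors(self) -> np.ndarray:
        return self.model.a_factors

    @property
    def sample_a_factors(self) -> np.ndarray:
        """One A-factor set per sample: intensity-weighted mean over curves."""
        w = self.curve_intensities.astype(float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        return (self.model.a_factors * (w / w.sum())[:, None]).sum(axis=0)


# ---------------------------------------------------------------------------
# reconvolution core
# ---------------------------------------------------------------------------

def _normalized_irf(irf_counts: np.ndarray) -> np.ndarray:
    s = irf_counts.sum()
    if s <= 0:
        raise ConfigurationError("IRF has zero total intensity")
    return irf_counts / s


def _shift_channels(y: np.ndarray, shift: float) -> np.ndarray:
    """Shift a histogram by a real-valued number of channels.

    Linear interpolation; values shifted past the window edges are lost.
    """
    if shift == 0.0:
        return y
    n = y.size
    idx = np.arange(n, dtype=float) - shift
    return np.interp(idx, np.arange(n, dtype=float), y, left=0.0, right=0.0)


def decay_basis(
    times: np.ndarray,
    lifetimes: np.ndarray,
    irf_counts: np.ndarray,
    shift: float = 0.0,
) -> np.ndarray:
    """Convolution of each unit-amplitude exponential with the unit-area IRF.

    Returns an (n_channels, n_components) matrix whose columns are the
    causal discrete convolutions; the model expectation for a curve is
    ``basis @ amplitudes + background``.
    """
    irf = _shift_channels(_normalized_irf(np.asarray(irf_counts, float)), shift)
    t = times - times[0]
    n = times.size
    cols = np.empty((n, len(lifetimes)))
    for i, tau in enumerate(lifetimes):
        d = np.exp(-t / tau)
        conv = fftconvolve(irf, d)[:n]
        cols[:, i] = np.maximum(conv, 0.0)
    return cols


def reconvolve(model: DecayModel, irf: DecayCurve, curve_index: int = 0) -> np.ndarray:
    """Expected counts per bin for one curve of a :class:`DecayModel`."""
    if curve_index < 0 or curve_index >= model.n_curves:
        raise ConfigurationError(f"curve_index {curve_index} out of range")
    basis = decay_basis(
        irf.times, model.lifetimes, irf.counts, shift=float(model.shifts[curve_index])
    )
    return basis @ model.amplitudes[curve_index] + model.backgrounds[curve_index]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _weights(counts: np.ndarray, expectation: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "neyman":
        return 1.0 / np.maximum(counts, 1.0)
    if weighting == "pearson":
        return 1.0 / np.maximum(expectation, 1.0)
    raise ConfigurationError(f"unknown weighting {weighting!r}")


def reduced_chisq(
    curve,
    expectation: np.ndarray,
    n_free_params: int,
    weighting: str = "neyman",
) -> float:
    """Poisson-weighted reduced chi-square of an expectation against data."""
    counts = curve.counts if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    expectation = np.asarray(expectation, float)
    if counts.size == 0:
        raise ConfigurationError("empty fit range")
    dof = counts.size - n_free_params
    if dof <= 0:
        raise ConfigurationError(f"non-positive degrees of freedom ({dof})")
    w = _weights(counts, expectation, weighting)
    return float(np.sum(w * (counts - expectation) ** 2) / dof)


def residual_randomness(weighted_residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs-test p-value on residual signs.

    Normal approximation to the runs distribution. Residuals of a single
    sign give p ~ 0 (no randomness), not an error.
    """
    r = np.asarray(weighted_residuals, float)
    if r.size < 20:
        raise ConfigurationError("runs test needs at least 20 residuals")
    signs = r >= 0
    n1 = int(signs.sum())
    n2 = r.size - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 0.0
    z = (runs - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def _default_fit_range(curves: list, irf: DecayCurve) -> tuple:
    """Fit window: 10 channels before the IRF peak to the last informative bin.

    The background estimate is the median of the pre-peak channels (if at
    least 20 channels precede the peak); the window closes at the last
    channel whose counts exceed it in any curve.
    """
    peak = int(np.argmax(irf.counts))
    start = max(0, peak - 10)
    stop = start
    for c in curves:
        pre = c.counts[: max(peak - 20, 0)]
        bg = float(np.median(pre)) if pre.size else 0.0
        above = np.nonzero(c.counts > bg)[0]
        if above.size:
            stop = max(stop, int(above[-1]) + 1)
    if stop <= start:
        stop = len(irf.counts)
    return start, stop


def _solve_linear(basis, counts, weights):
    """Weighted NNLS for amplitudes + background of one curve."""
    sw = np.sqrt(weights)
    design = np.column_stack([basis, np.ones(len(counts))]) * sw[:, None]
    coef, _ = optimize.nnls(design, counts * sw)
    return coef[:-1], coef[-1]


def _check_inputs(curves, irf, n_components, free_tau=True):
    if not curves:
        raise ConfigurationError("at least one decay curve is required")
    # the 1..6 cap applies to free-lifetime fits; fixed-lifetime refits
    # (e.g. against a union of reference lifetimes) are linear and may be wider
    if free_tau and not 1 <= n_components <= 6:
        raise ConfigurationError("n_components must be in 1..6")
    if n_components < 1:
        raise ConfigurationError("n_components must be at least 1")
    for c in curves:
        if not c.same_grid(irf):
            raise IncompatibleGridError("decay curve and IRF grids differ")
        if c.counts.sum() <= 0:
            raise DegenerateDataError("curve has all-zero counts")


def _init_lifetimes(n_components: int, irf: DecayCurve) -> np.ndarray:
    window = irf.times[-1] - irf.times[0] + irf.bin_width
    lo, hi = 5.0 * irf.bin_width, window / 3.0
    if n_components == 1:
        return np.array([np.sqrt(lo * hi)])
    return np.geomspace(lo, hi, n_components)


def fit_global(
    curves: list,
    irf: DecayCurve,
    n_components: int,
    init: DecayModel | None = None,
    *,
    fix_lifetimes: np.ndarray | None = None,
    fit_shift: bool = True,
    weighting: str = "pearson",
    fit_range: tuple | None = None,
    ftol: float = 1e-10,
    max_nfev: int = 500 * 8,
) -> GlobalFitResult:
    """Fit decay curves globally with lifetimes linked across curves.

    Minimises the Poisson-weighted sum of squares over all curves and
    channels in the fit range. Lifetimes are iterated in log-space (shared);
    amplitudes and background are solved per curve by non-negative linear
    least squares at every step; an optional real-valued channel shift is
    free per curve. Returns ``converged=False`` instead of raising when the
    iteration cap is reached.

    ``weighting="pearson"`` (default) takes Poisson weights from the model
    expectation, 1/max(M, 1), which avoids the lifetime bias that data-based
    Neyman weights (1/max(C, 1), available via ``weighting="neyman"``)
    introduce in low-count tail channels.
    """
    if fix_lifetimes is not None:
        fix_lifetimes = np.sort(np.asarray(fix_lifetimes, float))
        n_components = fix_lifetimes.size
    _check_inputs(curves, irf, n_components, free_tau=fix_lifetimes is None)

    start, stop = fit_range if fit_range is not None else _default_fit_range(curves, irf)
    if stop - start <= n_components + 2:
        raise ConfigurationError("fit range too small for the model")
    sl = slice(start, stop)
    times = irf.times
    data = [c.counts[sl] for c in curves]
    wts = [1.0 / np.maximum(d, 1.0) if weighting == "neyman" else None for d in data]
    n_curves = len(curves)

    if init is not None:
        tau0 = np.asarray(init.lifetimes, float)
        shifts0 = np.asarray(init.shifts, float)
    else:
        tau0 = _init_lifetimes(n_components, irf)
        shifts0 = np.zeros(n_curves)

    free_tau = fix_lifetimes is None
    theta0 = []
    if free_tau:
        theta0.extend(np.log(tau0))
    if fit_shift:
        theta0.extend(shifts0)
    theta0 = np.asarray(theta0, float)

    # per-call scratch for the linear solutions of the last evaluation
    last = {}

    def unpack(theta):
        k = 0
        if free_tau:
            tau = np.exp(theta[:n_components])
            k = n_components
        else:
            tau = fix_lifetimes
        shifts = theta[k : k + n_curves] if fit_shift else np.zeros(n_curves)
        return tau, shifts

    def residuals(theta):
        tau, shifts = unpack(theta)
        res = []
        amps, bgs = [], []
        for j in range(n_curves):
            basis = decay_basis(times, tau, irf.counts, shift=float(shifts[j]))[sl]
            if weighting == "pearson":
                # one Neyman pre-solve to get an expectation for the weights
                w0 = 1.0 / np.maximum(data[j], 1.0)
                a0, b0 = _solve_linear(basis, data[j], w0)
                w = 1.0 / np.maximum(basis @ a0 + b0, 1.0)
            else:
                w = wts[j]
            a, b = _solve_linear(basis, data[j], w)
            amps.append(a)
            bgs.append(b)
            res.append(np.sqrt(w) * (basis @ a + b - data[j]))
        last["tau"], last["shifts"] = tau, shifts
        last["amps"], last["bgs"] = amps, bgs
        return np.concatenate(res)

    if theta0.size:
        lo, hi = [], []
        if free_tau:
            # keep lifetimes within a physically sensible window
            window = times[-1] - times[0] + irf.bin_width
            lo.extend([np.log(0.05 * irf.bin_width)] * n_components)
            hi.extend([np.log(10.0 * window)] * n_components)
        if fit_shift:
            lo.extend([-50.0] * n_curves)
            hi.extend([50.0] * n_curves)
        theta0 = np.clip(theta0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        sol = optimize.least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf",
            ftol=ftol, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
        )
        residuals(sol.x)
        converged = bool(sol.status > 0)
        nfev = int(sol.nfev)
    else:
        residuals(theta0)
        converged, nfev = True, 1

    order = np.argsort(last["tau"], kind="stable")
    model = DecayModel(
        lifetimes=np.asarray(last["tau"])[order],
        amplitudes=np.vstack(last["amps"])[:, order],
        backgrounds=np.asarray(last["bgs"]),
        shifts=np.asarray(last["shifts"]),
    )

    # diagnostics
    n_params_total = (n_components if free_tau else 0) + n_curves * (
        n_components + 1 + (1 if fit_shift else 0)
    )
    per_curve_params = n_components + 1 + (1 if fit_shift else 0) + (
        n_components if free_tau else 0
    )
    wres, chis, pruns, intens = [], [], [], []
    ss_total = 0.0
    bins_total = 0
    for j in range(n_curves):
        expect = reconvolve(model, irf, j)[sl]
        w = _weights(data[j], expect, weighting)
        r = np.sqrt(w) * (data[j] - expect)
        wres.append(r)
        ss_total += float(np.sum(r**2))
        bins_total += r.size
        dof_j = r.size - per_curve_params
        chis.append(float(np.sum(r**2) / dof_j) if dof_j > 0 else np.nan)
        pruns.append(residual_randomness(r) if r.size >= 20 else np.nan)
        intens.append(float(np.sum(data[j])))

    dof_g = bins_total - n_params_total
    return GlobalFitResult(
        model=model,
        chisq_reduced_global=ss_total / dof_g if dof_g > 0 else np.nan,
        chisq_reduced=np.asarray(chis),
        weighted_residuals=wres,
        residual_randomness=np.asarray(pruns),
        fit_range=(start, stop),
        n_iterations=nfev,
        converged=converged,
        curve_intensities=np.asarray(intens),
        wavelengths=[c.wavelength for c in curves],
    )


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------

def select_model_order(
    curves: list,
    irf: DecayCurve,
    max_components: int = 6,
    alpha: float = 0.05,
    min_afactor: float = 0.005,
    **fit_kwargs,
) -> int:
    """Smallest component count beyond which adding one is not justified.

    Fits n = 1..max sequentially; n+1 replaces n when the F-statistic of the
    chi-square decrease is significant at ``alpha`` and every component of
    the larger fit carries an A-factor of at least ``min_afactor`` in at
    least one curve.
    """
    prev = fit_global(curves, irf, 1, **fit_kwargs)
    n_curves = len(curves)

    def total_ss(res):
        return sum(float(np.sum(r**2)) for r in res.weighted_residuals)

    fshift = 1 if fit_kwargs.get("fit_shift", True) else 0

    def total_dof(res, n):
        bins = sum(r.size for r in res.weighted_residuals)
        return bins - (n + n_curves * (n + 1 + fshift))

    accepted = 1
    for n in range(2, max_components + 1):
        cur = fit_global(curves, irf, n, **fit_kwargs)
        ss_prev, ss_cur = total_ss(prev), total_ss(cur)
        dp = 1 + n_curves  # one lifetime + one amplitude per curve
        dof_cur = total_dof(cur, n)
        if ss_cur >= ss_prev or dof_cur <= 0:
            break
        fstat = ((ss_prev - ss_cur) / dp) / (ss_cur / dof_cur)
        pval = stats.f.sf(fstat, dp, dof_cur)
        carries = np.any(cur.model.a_factors >= min_afactor, axis=0).all()
        if pval < alpha and carries:
            accepted = n
            prev = cur
        else:
            break
    return accepted


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------

def estimate_uncertainties(
    result: GlobalFitResult,
    curves: list,
    irf: DecayCurve,
    n_boot: int = 50,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Parametric-bootstrap relative standard errors of lifetimes and A-factors.

    Simulates ``n_boot`` Poisson replicates from the fitted expectations,
    refits each (warm-started at the fitted model), and reports the relative
    standard deviation of every parameter. Deterministic given ``seed``.
    Also stored on ``result.uncertainties``.
    """
    if not result.converged:
        raise InvalidStateError("uncertainties require a converged fit")
    n_curves = len(curves)
    expectations = [np.maximum(reconvolve(result.model, irf, j), 0.0)
                    for j in range(n_curves)]
    rng_streams = np.random.SeedSequence(seed).spawn(n_boot)

    taus, afs, saf = [], [], []
    for b in range(n_boot):
        rng = np.random.default_rng(rng_streams[b])
        rep = [
            DecayCurve(irf.times, rng.poisson(expectations[j]).astype(float),
                       wavelength=curves[j].wavelength)
            for j in range(n_curves)
        ]
        fit = fit_global(rep, irf, result.model.n_components,
                         init=result.model, fit_range=result.fit_range,
                         **fit_kwargs)
        taus.append(fit.model.lifetimes)
        afs.append(fit.model.a_factors)
        saf.append(fit.sample_a_factors)

    taus = np.asarray(taus)
    afs = np.asarray(afs)
    saf = np.asarray(saf)

    def rel_sd(arr):
        m = np.mean(arr, axis=0)
        s = np.std(arr, axis=0, ddof=1)
        return s / np.where(np.abs(m) > 0, np.abs(m), 1.0)

    unc = {
        "lifetimes_rel": rel_sd(taus),
        "a_factors_rel": rel_sd(afs),
        "sample_a_factors_rel": rel_sd(saf),
        "n_boot": n_boot,
    }
    result.uncertainties = unc
    return unc
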