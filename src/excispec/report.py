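"""Conformational-population reporting from global decay fits.

Lifetime components are assigned to stacking classes (well stacked,
partially stacked fast/slow, extrahelical), fit parameters are compared
between conditions as percentage changes of rank-matched components, and a
two-state paired/unpaired mixture fraction is estimated against
double-strand and single-strand reference fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidStateError,
    UndefinedReferenceError,
    UnidentifiableMixtureError,
)
from .tcspc import DecayCurve, GlobalFitResult, fit_global

__all__ = [
    "CLASS_NAMES",
    "StateReport",
    "MixtureEstimate",
    "classify_components",
    "percent_param_change",
    "estimate_mixture_fraction",
    "parameter_distance",
]

CLASS_NAMES = (
    "stacked",
    "partially_stacked_fast",
    "partially_stacked_slow",
    "extrahelical",
)

#: Lifetime class boundaries in ns, anchored to the ~50 ps (well stacked)
#: and ~10 ns (extrahelical) landmark components; conventions, configurable.
DEFAULT_BOUNDARIES = {"stacked_max": 0.15, "partial_split": 1.0,
                      "extrahelical_min": 5.0}


@dataclass
class StateReport:
    """Per-component classes, class populations and optional comparisons."""

    component_classes: list
    populations: dict
    percent_changes: dict | None = None
    mixture_fraction: float | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class MixtureEstimate:
    fraction: float
    residual: float
    refit: GlobalFitResult
    union_lifetimes: np.ndarray


def _classify_lifetime(tau: float, bounds: dict) -> str:
    if tau <= bounds["stacked_max"]:
        return "stacked"
    if tau >= bounds["extrahelical_min"]:
        return "extrahelical"
    if tau < bounds["partial_split"]:
        return "partially_stacked_fast"
    return "partially_stacked_slow"


def classify_components(result: GlobalFitResult,
                        boundaries: dict | None = None) -> StateReport:
    """Assign each lifetime component to a stacking class.

    Class populations are the per-sample A-factors summed within each class;
    they sum to 1 because the A-factors do.
    """
    if not result.converged:
        raise InvalidStateError("classification requires a converged fit")
    bounds = dict(DEFAULT_BOUNDARIES)
    if boundaries:
        bounds.update(boundaries)
    classes = [_classify_lifetime(t, bounds) for t in result.lifetimes]
    a = result.sample_a_factors
    pops = {name: 0.0 for name in CLASS_NAMES}
    for cls, ai in zip(classes, a):
        pops[cls] += float(ai)
    return StateReport(component_classes=classes, populations=pops,
                       metadata={"boundaries": bounds})


def _params_of(x) -> tuple:
    """(lifetimes, per-sample A-factors) from a result or a raw pair."""
    if isinstance(x, GlobalFitResult):
        return np.asarray(x.lifetimes, float), np.asarray(x.sample_a_factors, float)
    tau, a = x
    return np.asarray(tau, float), np.asarray(a, float)


def percent_param_change(sample, reference, n_report: int = 3) -> dict:
    """Percentage change of lifetimes and A-factors vs a reference condition.

    Components are matched by ascending-lifetime rank; only the first
    ``n_report`` components are reported (the longest-lifetime component is
    conventionally omitted as a minor population). Values follow
    100 * (X_sample - X_ref) / X_ref.
    """
    tau_s, a_s = _params_of(sample)
    tau_r, a_r = _params_of(reference)
    if tau_s.size != tau_r.size:
        raise ConfigurationError("component counts differ between conditions")
    if tau_s.size < n_report:
        raise ConfigurationError(f"need at least {n_report} components")

    def pct(s, r, label):
        out = []
        for i in range(n_report):
            if r[i] == 0:
                raise UndefinedReferenceError(
                    f"reference {label}{i + 1} is zero; percent change undefined"
                )
            out.append(100.0 * (s[i] - r[i]) / r[i])
        return out

    return {"tau": pct(tau_s, tau_r, "tau"), "A": pct(a_s, a_r, "A")}


def parameter_distance(a, b, n_use: int = 3) -> float:
    """Euclidean distance between conditions in (A1..3, log tau1..3) space."""
    tau_a, aa = _params_of(a)
    tau_b, ab = _params_of(b)
    if tau_a.size != tau_b.size:
        raise ConfigurationError("component counts differ")
    if tau_a.size < n_use:
        raise ConfigurationError(f"need at least {n_use} components")
    va = np.concatenate([aa[:n_use], np.log(tau_a[:n_use])])
    vb = np.concatenate([ab[:n_use], np.log(tau_b[:n_use])])
    return float(np.linalg.norm(va - vb))


def _union_lifetimes(tau_a: np.ndarray, tau_b: np.ndarray,
                     rtol: float = 0.05) -> np.ndarray:
    merged = np.sort(np.concatenate([tau_a, tau_b]))
    out = [merged[0]]
    for t in merged[1:]:
        if (t - out[-1]) / out[-1] <= rtol:
            out[-1] = 0.5 * (out[-1] + t)
        else:
            out.append(t)
    return np.asarray(out)


def _map_to_union(tau: np.ndarray, a: np.ndarray, union: np.ndarray) -> np.ndarray:
    out = np.zeros(union.size)
    for t, ai in zip(tau, a):
        j = int(np.argmin(np.abs(union - t)))
        out[j] += ai
    return out


def estimate_mixture_fraction(
    complex_curves: list,
    ds_ref: GlobalFitResult,
    ss_ref: GlobalFitResult,
    irf: DecayCurve,
    **fit_kwargs,
) -> MixtureEstimate:
    """Two-state paired/unpaired fraction of a complex decay set.

    The complex curves are refitted with lifetimes fixed to the union of the
    double-strand and single-strand reference lifetimes; the fraction f in
    [0, 1] minimising || A_complex - (f*A_ss + (1-f)*A_ds) ||^2 is returned
    together with the residual distance. f = 1 means fully single-strand-like
    (unpaired).
    """
    for ref, name in ((ds_ref, "ds"), (ss_ref, "ss")):
        if not ref.converged:
            raise InvalidStateError(f"{name} reference fit not converged")
    union = _union_lifetimes(ds_ref.lifetimes, ss_ref.lifetimes)
    a_ds = _map_to_union(ds_ref.lifetimes, ds_ref.sample_a_factors, union)
    a_ss = _map_to_union(ss_ref.lifetimes, ss_ref.sample_a_factors, union)
    direction = a_ss - a_ds
    norm2 = float(direction @ direction)
    if norm2 < 1e-12:
        raise UnidentifiableMixtureError(
            "reference A-vectors are identical; mixture fraction unidentifiable"
        )
    fit_kwargs.setdefault("fit_shift", False)
    refit = fit_global(complex_curves, irf, n_components=union.size,
                       fix_lifetimes=union, **fit_kwargs)
    a_c = refit.sample_a_factors
    f = float(np.clip((a_c - a_ds) @ direction / norm2, 0.0, 1.0))
    resid = float(np.linalg.norm(a_c - (f * a_ss + (1 - f) * a_ds)))
    return MixtureEstimate(fraction=f, residual=resid, refit=refit,
                           union_lifetimes=union)
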