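"""Nernst sigmoid and three-state redox models for titration traces.

The CO-inhibited oxidase passes through three states as the electrode
potential is raised: the fully reduced CO-bound state (``R4CO``), the
mixed-valence CO-bound state (``R2CO``, binuclear center still reduced), and
the oxidized CO-free state (``O``).  Sequential one-step equilibria with
midpoints E_m1 < E_m2 govern the populations:

    x ∝ (1, a₁, a₁a₂),   aᵢ = exp(nᵢ F (E − E_m,i) / RT)

so the reduced fraction of a single couple is 1 / (1 + exp(n F (E − E_m)/RT)).
The apparent electron number n is kept as a free, bounded parameter: measured
traces often convolve multi-electron steps, so the fitted slope need not be
the physical electron count.

Band-area traces are fitted as amplitude × population + offset, either with a
single sigmoid (appearing/disappearing species) or with the transient
intermediate population of the two-transition model.  :func:`global_fit`
performs alternating least squares on a whole spectral series: species
spectra are the linear solution given populations, then midpoints are refit
given spectra, iterated to convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import constants as _const
from scipy.optimize import curve_fit, least_squares

from .errors import ConvergenceError, FitError, ValidationError
from .spectra import SpectralSeries

SPECIES = ("R4CO", "R2CO", "O")

#: conversion between Ag/AgCl (sat. KCl) and SHE scales, mV; applied only on request
AGCL_TO_SHE_MV = 210.0


def thermal_voltage_mV(temperature_K: float = 298.15) -> float:
    """RT/F in millivolts (25.693 mV at 298.15 K)."""
    return 1000.0 * _const.R * temperature_K / _const.physical_constants["Faraday constant"][0]


@dataclass(frozen=True)
class NernstTransition:
    """One redox couple: midpoint potential (mV) and apparent electron number."""

    midpoint_mV: float
    n_app: float = 1.0
    temperature_K: float = 298.15
    midpoint_se_mV: float | None = None
    n_app_se: float | None = None

    def __post_init__(self):
        if not self.n_app > 0:
            raise ValidationError("n_app must be > 0")
        if not abs(self.midpoint_mV) <= 2000:
            raise ValidationError("midpoint_mV outside the ±2000 mV sanity bound")
        if not self.temperature_K > 0:
            raise ValidationError("temperature_K must be > 0")

    def to_she(self, offset_mV: float = AGCL_TO_SHE_MV) -> "NernstTransition":
        """Shift the midpoint from the stored reference scale by ``offset_mV``."""
        return replace(self, midpoint_mV=self.midpoint_mV + offset_mV)


@dataclass(frozen=True)
class ThreeStateModel:
    """Two sequential transitions R4CO → R2CO → O with midpoint_1 < midpoint_2."""

    transition_1: NernstTransition
    transition_2: NernstTransition

    def __post_init__(self):
        if not self.transition_1.midpoint_mV < self.transition_2.midpoint_mV:
            raise ValidationError("transition_1.midpoint_mV must be < transition_2.midpoint_mV")


@dataclass(frozen=True)
class TitrationTrace:
    """A band-area trace vs electrode potential, with optional standard errors."""

    potentials_mV: np.ndarray
    values: np.ndarray
    standard_errors: np.ndarray | None = None

    def __post_init__(self):
        pot = np.asarray(self.potentials_mV, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "potentials_mV", pot)
        object.__setattr__(self, "values", val)
        if pot.shape != val.shape:
            raise ValidationError("potentials_mV and values lengths differ")
        d = np.diff(pot)
        if pot.size > 1 and not ((d > 0).all() or (d < 0).all()):
            raise ValidationError("potentials_mV must be strictly monotonic")
        if self.standard_errors is not None:
            se = np.asarray(self.standard_errors, dtype=float)
            object.__setattr__(self, "standard_errors", se)
            if se.shape != val.shape:
                raise ValidationError("standard_errors length differs from values")


def nernst_fraction(E, transition: NernstTransition):
    """Fraction reduced at potential(s) ``E`` (mV); 0.5 at the midpoint, → 1 as E → −∞."""
    kt = thermal_voltage_mV(transition.temperature_K)
    u = transition.n_app * (np.asarray(E, dtype=float) - transition.midpoint_mV) / kt
    return 1.0 / (1.0 + np.exp(np.clip(u, -700, 700)))


def three_state_populations(E, model: ThreeStateModel) -> np.ndarray:
    """Populations (x_R4, x_R2, x_O) at potential(s) ``E``; rows sum to 1 exactly.

    Boltzmann-weighted sequential equilibria evaluated as a log-domain softmax
    for numerical stability at extreme potentials.
    """
    E = np.asarray(E, dtype=float)
    t1, t2 = model.transition_1, model.transition_2
    u1 = t1.n_app * (E - t1.midpoint_mV) / thermal_voltage_mV(t1.temperature_K)
    u2 = t2.n_app * (E - t2.midpoint_mV) / thermal_voltage_mV(t2.temperature_K)
    logw = np.stack([np.zeros_like(u1), u1, u1 + u2])
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=0, keepdims=True)


def _weights(trace: TitrationTrace) -> np.ndarray | None:
    se = trace.standard_errors
    if se is None or not np.all(np.isfinite(se)) or np.any(se <= 0):
        return None
    return se


def fit_sigmoid_trace(trace: TitrationTrace, direction: str = "disappearing",
                      n_bounds: tuple[float, float] = (0.5, 4.0),
                      temperature_K: float = 298.15,
                      bootstrap: int = 0, rng_seed: int = 0):
    """Fit amplitude × population + offset to a band-area trace.

    ``direction``:

    * ``disappearing`` — species reduced below E_m (e.g. the R4CO band);
      model ``A·f(E) + c`` with f the reduced fraction.
    * ``appearing``   — species formed above E_m; model ``A·(1−f(E)) + c``.
    * ``transient``   — intermediate of two sequential transitions (the R2CO
      band); model ``A·x_R2(E) + c``.  Returns two transitions.

    Weighted least squares (inverse-variance when standard errors are present),
    asymptotic standard errors from the Jacobian covariance.  An optional
    seeded residual bootstrap (``bootstrap`` resamples) refines the midpoint
    uncertainty; its result replaces the asymptotic standard error.
    """
    E = trace.potentials_mV
    y = trace.values
    if E.size < 6:
        raise FitError("need at least 6 points spanning the transition")
    span = float(np.ptp(y))
    scale = float(np.max(np.abs(y))) if np.max(np.abs(y)) > 0 else 1.0
    if span <= 1e-12 * scale:
        raise FitError("trace is constant: no transition to fit")
    sigma = _weights(trace)
    kt = thermal_voltage_mV(temperature_K)
    lo_E, hi_E = float(E.min()), float(E.max())

    def _warn_outside(mid):
        if not (lo_E <= mid <= hi_E):
            warnings.warn(
                f"fitted midpoint {mid:.1f} mV lies outside the sampled range "
                f"[{lo_E:.0f}, {hi_E:.0f}] mV", stacklevel=3)

    if direction in ("disappearing", "appearing"):
        sgn = 1.0 if direction == "disappearing" else -1.0

        def model(E, mid, n, amp, off):
            f = 1.0 / (1.0 + np.exp(np.clip(n * (E - mid) / kt, -700, 700)))
            return amp * (f if sgn > 0 else 1.0 - f) + off

        # midpoint guess: potential where the trace crosses half range
        half = (y.max() + y.min()) / 2.0
        mid0 = float(E[np.argmin(np.abs(y - half))])
        p0 = [mid0, 1.0, span, float(y.min())]
        bounds = ([-2000.0, n_bounds[0], 0.0, -np.inf],
                  [2000.0, n_bounds[1], np.inf, np.inf])
        try:
            popt, pcov = curve_fit(model, E, y, p0=p0, sigma=sigma, bounds=bounds,
                                   maxfev=20000)
        except RuntimeError as e:
            raise FitError(f"sigmoid fit did not converge: {e}")
        perr = np.sqrt(np.diag(pcov))
        mid_se = float(perr[0])
        if bootstrap > 0:
            mid_se = _residual_bootstrap(model, E, y, popt, bounds, bootstrap, rng_seed)
        _warn_outside(popt[0])
        return NernstTransition(float(popt[0]), float(popt[1]), temperature_K,
                                midpoint_se_mV=mid_se, n_app_se=float(perr[1]))

    if direction == "transient":
        def model(E, m1, dm, n1, n2, amp, off):
            m = ThreeStateModel(NernstTransition(m1, n1, temperature_K),
                                NernstTransition(m1 + dm, n2, temperature_K))
            return amp * three_state_populations(E, m)[1] + off

        i_max = int(np.argmax(y))
        peak_E = float(E[i_max])
        p0 = [peak_E - 50.0, 100.0, 1.0, 1.0, span, float(y.min())]
        bounds = ([-2000.0, 1e-3, n_bounds[0], n_bounds[0], 0.0, -np.inf],
                  [2000.0, 4000.0, n_bounds[1], n_bounds[1], np.inf, np.inf])
        try:
            popt, pcov = curve_fit(model, E, y, p0=p0, sigma=sigma, bounds=bounds,
                                   maxfev=40000)
        except RuntimeError as e:
            raise FitError(f"transient fit did not converge: {e}")
        perr = np.sqrt(np.diag(pcov))
        m1, dm = float(popt[0]), float(popt[1])
        se1 = float(perr[0])
        se2 = float(np.sqrt(pcov[0, 0] + pcov[1, 1] + 2 * pcov[0, 1]))
        if bootstrap > 0:
            se1 = _residual_bootstrap(model, E, y, popt, bounds, bootstrap, rng_seed)
        _warn_outside(m1)
        _warn_outside(m1 + dm)
        t1 = NernstTransition(m1, float(popt[2]), temperature_K,
                              midpoint_se_mV=se1, n_app_se=float(perr[2]))
        t2 = NernstTransition(m1 + dm, float(popt[3]), temperature_K,
                              midpoint_se_mV=se2, n_app_se=float(perr[3]))
        return t1, t2

    raise ValueError(f"unknown direction {direction!r}")


def _residual_bootstrap(model, E, y, popt, bounds, n_boot, rng_seed) -> float:
    """Seeded residual bootstrap of the first fitted parameter (the midpoint)."""
    rng = np.random.default_rng(rng_seed)
    fitted = model(E, *popt)
    resid = y - fitted
    mids = []
    for _ in range(n_boot):
        y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            p_b, _ = curve_fit(model, E, y_b, p0=popt, bounds=bounds, maxfev=20000)
            mids.append(p_b[0])
        except RuntimeError:
            continue
    if len(mids) < max(10, n_boot // 10):
        return float("nan")
    return float(np.std(mids, ddof=1))


def _populations_for(E, params, n_species, temperature_K):
    if n_species == 3:
        m1, dm, n1, n2 = params
        model = ThreeStateModel(NernstTransition(m1, n1, temperature_K),
                                NernstTransition(m1 + dm, n2, temperature_K))
        return three_state_populations(E, model).T
    m1, n1 = params
    f = nernst_fraction(E, NernstTransition(m1, n1, temperature_K))
    return np.stack([f, 1.0 - f], axis=1)


def global_fit(series: SpectralSeries, model_init: ThreeStateModel | NernstTransition | None = None,
               n_species: int = 3, max_iter: int = 200, tol: float = 1e-8,
               n_bounds: tuple[float, float] = (0.5, 4.0)):
    """Alternating least squares over a whole spectral series.

    Given midpoints, the species spectra are the linear least-squares solution
    of ``data ≈ populations × spectra``; given spectra, the midpoints (and
    apparent electron numbers) are refit; iterated until the relative residual
    change drops below ``tol`` or ``max_iter`` iterations.  Deterministic for
    a given initialization; if ``model_init`` is None the midpoints are seeded
    at the 25th/75th percentile potentials of the series.

    Returns ``(model, species_spectra)`` where ``species_spectra`` has one row
    per species on the series' wavenumber grid.  For ``n_species == 2`` pass a
    single :class:`NernstTransition` (or None) and a transition is returned.
    """
    if n_species not in (2, 3):
        raise ValueError("n_species must be 2 or 3")
    Y = series.data
    E = series.potentials
    temperature_K = 298.15
    if model_init is None:
        q25, q75 = np.percentile(E, [25, 75])
        if n_species == 3:
            params = np.array([q25, q75 - q25, 1.0, 1.0])
        else:
            params = np.array([(q25 + q75) / 2.0, 1.0])
    elif n_species == 3:
        if not isinstance(model_init, ThreeStateModel):
            raise ValueError("model_init must be a ThreeStateModel when n_species=3")
        temperature_K = model_init.transition_1.temperature_K
        params = np.array([
            model_init.transition_1.midpoint_mV,
            model_init.transition_2.midpoint_mV - model_init.transition_1.midpoint_mV,
            model_init.transition_1.n_app, model_init.transition_2.n_app,
        ])
    else:
        if not isinstance(model_init, NernstTransition):
            raise ValueError("model_init must be a NernstTransition when n_species=2")
        temperature_K = model_init.temperature_K
        params = np.array([model_init.midpoint_mV, model_init.n_app])

    if n_species == 3:
        lb = np.array([-2000.0, 1e-3, n_bounds[0], n_bounds[0]])
        ub = np.array([2000.0, 4000.0, n_bounds[1], n_bounds[1]])
    else:
        lb = np.array([-2000.0, n_bounds[0]])
        ub = np.array([2000.0, n_bounds[1]])

    S = None
    r_prev = np.inf
    for _ in range(max_iter):
        P = _populations_for(E, params, n_species, temperature_K)
        cond = np.linalg.cond(P)
        if cond > 1e8:
            raise ConvergenceError(
                f"population matrix condition number {cond:.2e} > 1e8; "
                "widen the potential range so every species is represented")
        S, *_ = np.linalg.lstsq(P, Y, rcond=None)
        r_lin = float(np.linalg.norm(Y - P @ S))

        def resid(p):
            return (Y - _populations_for(E, p, n_species, temperature_K) @ S).ravel()

        sol = least_squares(resid, np.clip(params, lb, ub), bounds=(lb, ub),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        params = sol.x
        r = float(np.linalg.norm(sol.fun))
        if np.isfinite(r_prev) and abs(r_prev - r) <= tol * max(r_prev, 1e-30):
            r_prev = r
            break
        r_prev = r

    if n_species == 3:
        model = ThreeStateModel(
            NernstTransition(float(params[0]), float(params[2]), temperature_K),
            NernstTransition(float(params[0] + params[1]), float(params[3]), temperature_K))
    else:
        model = NernstTransition(float(params[0]), float(params[1]), temperature_K)
    return model, S
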