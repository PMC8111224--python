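"""Pseudo-Voigt band deconvolution with series-shared shapes.

The C≡O stretching region is modeled as a sum of pseudo-Voigt components —
η-weighted mixtures of a unit-area Lorentzian and a unit-area Gaussian of
equal FWHM (η = 0.2 by default, i.e. 20% Lorentzian / 80% Gaussian).  The fit
follows a two-phase protocol: phase 1 determines one shared (center, FWHM, η)
per band jointly over all spectra with free per-spectrum areas; phase 2
freezes those shapes and refits the non-negative areas spectrum by spectrum,
yielding area-vs-potential traces with standard errors.

With shapes frozen the model is linear in the areas, so phase 2 is a
non-negative linear least-squares problem solved exactly by NNLS; phase 1 is
a variable-projection fit (the areas are eliminated by NNLS inside the shape
optimization), which keeps the optimizer small and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import find_peaks, peak_widths

from .errors import FitError, ValidationError
from .spectra import SpectralSeries, Spectrum
from .titration import TitrationTrace

#: default fit window in the C≡O stretching region, cm⁻¹
DEFAULT_WINDOW = (1950.0, 1980.0)
#: default Lorentzian fraction of the pseudo-Voigt mixture
DEFAULT_ETA = 0.2

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class PseudoVoigtBand:
    """One spectral component: center and FWHM in cm⁻¹, Lorentzian fraction η,
    and (optionally) an area in AU·cm⁻¹."""

    center: float
    fwhm: float
    eta: float = DEFAULT_ETA
    area: float | None = None

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValidationError("fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValidationError("eta must lie in [0, 1]")
        if self.area is not None and self.area < 0:
            raise ValidationError("area must be ≥ 0")


def pseudo_voigt(wavenumber, center: float, fwhm: float, eta: float = DEFAULT_ETA):
    """Unit-area pseudo-Voigt profile evaluated at ``wavenumber`` (cm⁻¹).

    η-weighted sum of a unit-area Lorentzian and a unit-area Gaussian of the
    same FWHM: non-negative, symmetric about ``center``, integrates to 1 over
    the real line.  Peak value is 2/(π·fwhm) for η = 1 and
    (2/fwhm)·√(ln2/π) for η = 0.
    """
    if not fwhm > 0:
        raise ValidationError("fwhm must be > 0")
    if not 0.0 <= eta <= 1.0:
        raise ValidationError("eta must lie in [0, 1]")
    x = np.asarray(wavenumber, dtype=float) - center
    hw = fwhm / 2.0
    lorentz = (hw / np.pi) / (x * x + hw * hw)
    gauss = np.sqrt(_LN2 / np.pi) / hw * np.exp(-_LN2 * (x / hw) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def _pv_peak_height(fwhm: float, eta: float) -> float:
    return eta * 2.0 / (np.pi * fwhm) + (1.0 - eta) * 2.0 * np.sqrt(_LN2 / np.pi) / fwhm


def peak_pick(spectrum: Spectrum, window: tuple[float, float],
              eta: float = DEFAULT_ETA, prominence_sigmas: float = 3.0) -> list[PseudoVoigtBand]:
    """Seed bands from local maxima inside ``window``.

    The prominence threshold is ``prominence_sigmas`` times a robust noise
    estimate (scaled MAD of first differences).  Each peak seeds one band:
    center at the maximum, FWHM from the half-height crossing, η fixed.
    Returns an empty list when nothing exceeds the threshold — overlapping
    bands closer than the resolution limit may merge into one seed, in which
    case the caller should seed manually.
    """
    lo, hi = min(window), max(window)
    nu = spectrum.wavenumbers
    mask = (nu >= lo) & (nu <= hi)
    if mask.sum() < 3:
        raise ValidationError(f"window [{lo}, {hi}] lies outside the spectrum grid")
    y = spectrum.absorbance[mask]
    x = nu[mask]
    d = np.diff(y)
    noise_sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    prominence = prominence_sigmas * noise_sd
    idx, _ = find_peaks(y, prominence=max(prominence, 1e-15))
    if idx.size == 0:
        return []
    widths, _, _, _ = peak_widths(y, idx, rel_height=0.5)
    spacing = spectrum.spacing
    bands = []
    for i, w in zip(idx, widths):
        fwhm = max(float(w) * spacing, spacing)
        height = float(y[i])
        bands.append(PseudoVoigtBand(center=float(x[i]), fwhm=fwhm, eta=eta,
                                     area=max(height, 0.0) / _pv_peak_height(fwhm, eta)))
    return bands


@dataclass(frozen=True)
class SharedShapeFit:
    """Result of the two-phase shared-shape fit.

    ``bands`` hold the shared shapes; ``areas`` is the (potential × band)
    area matrix with ``area_se`` its covariance-derived standard errors.
    """

    bands: tuple[PseudoVoigtBand, ...]
    potentials_mV: np.ndarray
    areas: np.ndarray
    area_se: np.ndarray
    residual_norm: float
    window: tuple[float, float]
    collapsed: bool = False

    def __post_init__(self):
        if not np.isfinite(self.residual_norm):
            raise ValidationError("residual_norm must be finite")
        if (self.areas < 0).any():
            raise ValidationError("areas must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    @property
    def fwhms(self) -> np.ndarray:
        return np.array([b.fwhm for b in self.bands])

    def trace(self, band_index: int) -> TitrationTrace:
        """Area-vs-potential trace for one band."""
        return TitrationTrace(self.potentials_mV, self.areas[:, band_index],
                              self.area_se[:, band_index])


def _design_matrix(x: np.ndarray, centers, fwhms, etas) -> np.ndarray:
    return np.stack([pseudo_voigt(x, c, f, e) for c, f, e in zip(centers, fwhms, etas)],
                    axis=1)


def fit_shared_shape(series: SpectralSeries, initial_bands, window: tuple[float, float] = DEFAULT_WINDOW,
                     fit_baseline: bool = False, max_nfev: int = 2000) -> SharedShapeFit:
    """Two-phase pseudo-Voigt fit with shapes shared across the series.

    Phase 1: bounded trust-region least squares over the shared shape
    parameters (center and FWHM per band; η stays at the seeded value), with
    the per-spectrum areas eliminated at every step by non-negative linear
    least squares.  Phase 2: shapes frozen, areas refit per spectrum with
    asymptotic standard errors.  ``fit_baseline`` co-fits a per-spectrum
    linear baseline (offset + slope) inside the window; off by default since
    the Fourier baseline filter normally precedes fitting.

    Deterministic for given inputs.  Bands whose centers approach within
    0.1 × FWHM of each other flag the fit as ``collapsed`` (with a warning).
    """
    bands = list(initial_bands)
    if len(series) < 2:
        raise FitError("need at least 2 spectra")
    if not bands:
        raise FitError("need at least 1 initial band")
    lo, hi = min(window), max(window)
    nu = series.wavenumbers
    mask = (nu >= lo) & (nu <= hi)
    nb = len(bands)
    if mask.sum() < 2 * nb + 2:
        raise ValidationError(f"window [{lo}, {hi}] holds too few grid points for {nb} bands")
    x = nu[mask]
    Y = series.data[:, mask]
    spacing = series.spectra[0].spacing
    etas = np.array([b.eta for b in bands])

    def full_design(centers, fwhms):
        A = _design_matrix(x, centers, fwhms, etas)
        if fit_baseline:
            A = np.hstack([A, np.ones((x.size, 1)), (x - x.mean())[:, None]])
        return A

    def solve_areas(A):
        # non-negative areas; baseline columns (if any) unconstrained
        if fit_baseline:
            # alternate: NNLS on band columns after projecting out the baseline
            B = A[:, nb:]
            Qb, _ = np.linalg.qr(B)
            proj = np.eye(x.size) - Qb @ Qb.T
            Ab = proj @ A[:, :nb]
            areas = np.empty((Y.shape[0], nb))
            coefs = np.empty((Y.shape[0], A.shape[1]))
            for i, y in enumerate(Y):
                a, _ = nnls(Ab, proj @ y)
                b = np.linalg.lstsq(B, y - A[:, :nb] @ a, rcond=None)[0]
                areas[i] = a
                coefs[i] = np.concatenate([a, b])
            return areas, coefs
        areas = np.empty((Y.shape[0], nb))
        for i, y in enumerate(Y):
            areas[i], _ = nnls(A, y)
        return areas, areas

    def residuals(theta):
        centers, fwhms = theta[:nb], theta[nb:2 * nb]
        A = full_design(centers, fwhms)
        _, coefs = solve_areas(A)
        return (Y - coefs @ A.T).ravel()

    theta0 = np.concatenate([[b.center for b in bands], [b.fwhm for b in bands]])
    margin = 5.0
    lb = np.concatenate([np.full(nb, lo - margin), np.full(nb, spacing)])
    ub = np.concatenate([np.full(nb, hi + margin), np.full(nb, 4 * (hi - lo))])
    sol = least_squares(residuals, np.clip(theta0, lb, ub), bounds=(lb, ub),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=max_nfev)
    if not sol.success:
        raise FitError("shared-shape fit did not converge",
                       residual_norm=float(np.linalg.norm(sol.fun)))
    centers, fwhms = sol.x[:nb], sol.x[nb:2 * nb]

    collapsed = False
    for i in range(nb):
        for j in range(i + 1, nb):
            if abs(centers[i] - centers[j]) < 0.1 * max(fwhms[i], fwhms[j]):
                collapsed = True
                warnings.warn(
                    f"bands {i} and {j} collapsed (|Δcenter| < 0.1×FWHM)", stacklevel=2)

    # phase 2: shapes frozen, per-spectrum non-negative areas with SEs
    A = full_design(centers, fwhms)
    areas, coefs = solve_areas(A)
    resid = Y - coefs @ A.T
    dof = max(x.size - A.shape[1], 1)
    AtA_inv = np.linalg.pinv(A.T @ A)
    se = np.empty_like(areas)
    for i in range(Y.shape[0]):
        sigma2 = float(resid[i] @ resid[i]) / dof
        se[i] = np.sqrt(sigma2 * np.diag(AtA_inv)[:nb])

    fitted_bands = tuple(
        PseudoVoigtBand(float(c), float(f), float(e), area=float(areas[:, k].max()))
        for k, (c, f, e) in enumerate(zip(centers, fwhms, etas)))
    return SharedShapeFit(bands=fitted_bands, potentials_mV=series.potentials,
                          areas=areas, area_se=se,
                          residual_norm=float(np.linalg.norm(resid)),
                          window=(lo, hi), collapsed=collapsed)
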