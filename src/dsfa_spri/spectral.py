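"""Wavelength-domain forward model for dual-band SPR interrogation.

This module carries the optical core of the method: smooth-edged band-pass
filter transmittances, a Gaussian surface-plasmon-resonance (SPR) reflectance
dip with a linear refractive-index response, band-intensity integration, the
spectral-contrast statistic ``gamma``, dip localization, and Gaussian dip
fitting.

The physical picture: broadband light passes through one of two nested
band-pass filters (A: narrow, 583-598 nm; AB: wide, 562-598 nm), reflects off
an SPR chip whose reflectance carries a resonance dip, and is integrated by a
monochrome camera pixel.  The per-pixel contrast

    gamma = (I_A - I_B) / (I_A + I_B) = (2 I_A - I_AB) / I_AB

with ``I_B = I_AB - I_A`` tracks spectral shifts of the dip relative to the
two bands: its sign and magnitude change as the resonance red- or blue-shifts
with the refractive index at the chip surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "PassbandFilter",
    "DipModel",
    "BandIntensities",
    "DipLocation",
    "GaussianDipFit",
    "A_FILTER",
    "AB_FILTER",
    "DEFAULT_DIP",
    "default_grid",
    "make_passband",
    "spr_spectrum",
    "band_intensity",
    "gamma_value",
    "find_dip",
    "fit_gaussian_dip",
]

# Raised-cosine edge: fraction of the full 0->1 edge width spanned between the
# 50 % point and the 0.005 % point (the transition-width convention used for
# the fabricated filters).
_EDGE_SPAN_FRACTION = 0.5 - np.arccos(1.0 - 2.0 * 5e-5) / np.pi


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing wavelength axis in nanometres."""

    lambda_min: float = 550.0
    lambda_max: float = 610.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValueError(f"step must be > 0, got {self.step}")
        if not (self.lambda_max > self.lambda_min):
            raise ValueError("lambda_max must exceed lambda_min")
        n = round((self.lambda_max - self.lambda_min) / self.step)
        if n < 1:
            raise ValueError("grid must contain at least two samples")
        if abs(self.lambda_min + n * self.step - self.lambda_max) > 1e-9 * self.step:
            raise ValueError(
                "grid span must be an integer multiple of the step "
                f"({self.lambda_min}..{self.lambda_max} @ {self.step})"
            )

    @property
    def values(self) -> np.ndarray:
        n = round((self.lambda_max - self.lambda_min) / self.step)
        return self.lambda_min + self.step * np.arange(n + 1)

    def __len__(self) -> int:
        return round((self.lambda_max - self.lambda_min) / self.step) + 1


def default_grid() -> WavelengthGrid:
    """Default 550-610 nm axis at 0.1 nm, sub-resolving the 4-5 nm filter edges."""
    return WavelengthGrid(550.0, 610.0, 0.1)


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength (transmittance or relative intensity)."""

    grid: WavelengthGrid
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or len(samples) != len(self.grid):
            raise ValueError(
                f"samples length {samples.shape} does not match grid length {len(self.grid)}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def require_same_grid(self, other: "Spectrum") -> None:
        if self.grid != other.grid:
            raise ValueError(f"spectra are on different grids: {self.grid} vs {other.grid}")


@dataclass(frozen=True)
class PassbandFilter:
    """Band-pass filter described by its cut-on/cut-off and edge steepness.

    ``edge_width`` is the wavelength span of each edge between 50 % and
    0.005 % transmission (relative to the plateau), the steepness metric
    quoted for the fabricated filters (about 4-5 nm).
    """

    cut_on: float
    cut_off: float
    peak_transmittance: float = 0.85
    edge_width: float = 4.5

    def __post_init__(self) -> None:
        if not self.cut_on < self.cut_off:
            raise ValueError("cut_on must be below cut_off")
        if not (0.0 < self.peak_transmittance <= 1.0):
            raise ValueError("peak_transmittance must lie in (0, 1]")
        if not self.edge_width > 0:
            raise ValueError("edge_width must be > 0")

    @property
    def center(self) -> float:
        return 0.5 * (self.cut_on + self.cut_off)

    @property
    def width(self) -> float:
        return self.cut_off - self.cut_on

    def to_spectrum(self, grid: WavelengthGrid) -> Spectrum:
        return make_passband(self.cut_on, self.cut_off, self.peak_transmittance,
                             self.edge_width, grid)


#: Narrow filter: transmits band 1 only.
A_FILTER = PassbandFilter(583.0, 598.0, 0.85, 4.5)
#: Wide filter: transmits band 1 + band 2.
AB_FILTER = PassbandFilter(562.0, 598.0, 0.85, 4.5)


@dataclass(frozen=True)
class DipModel:
    """Gaussian SPR reflectance dip with a linear refractive-index response.

    R(lambda; n) = baseline - depth * exp(-(lambda - dip_center(n))^2 / (2 width^2))
    dip_center(n) = lambda0 + slope_s_lambda * (n - n0)

    The default center (593.5 nm) places the dip on the long-wavelength
    shoulder of the shared filter cut-off, the operating point at which a red
    shift of the resonance produces an increasing gamma, matching the sign of
    the measured response; see docs/methods.md for the geometry.
    """

    lambda0: float = 593.5
    n0: float = 1.333
    slope_s_lambda: float = 244.7
    width: float = 8.0
    depth: float = 0.5
    baseline: float = 0.9

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if not (0.0 <= self.depth <= self.baseline <= 1.0):
            raise ValueError(
                f"need 0 <= depth <= baseline <= 1, got depth={self.depth}, baseline={self.baseline}"
            )

    def dip_center(self, n: float) -> float:
        """Resonance wavelength at refractive index ``n`` (nm)."""
        return self.lambda0 + self.slope_s_lambda * (n - self.n0)

    def with_center(self, lambda0: float) -> "DipModel":
        return replace(self, lambda0=lambda0)


#: Default operating point used by the simulator and the demo scenario.
DEFAULT_DIP = DipModel()


class BandIntensities(NamedTuple):
    """Band-integrated intensities; ``i_b`` is derived as ``i_ab - i_a``."""

    i_a: float
    i_ab: float

    @property
    def i_b(self) -> float:
        return self.i_ab - self.i_a

    @property
    def gamma(self) -> float:
        return gamma_value(self.i_a, self.i_ab)


def make_passband(cut_on: float, cut_off: float, peak: float, edge_width: float,
                  grid: WavelengthGrid) -> Spectrum:
    """Smooth-edged rectangular transmittance with raised-cosine edges.

    The transmittance equals ``peak`` on the interior plateau, exactly
    ``peak / 2`` at ``cut_on`` and ``cut_off``, and each edge spans
    ``edge_width`` nm between its 50 % and 0.005 % points.
    """
    if not cut_on < cut_off:
        raise ValueError("cut_on must be below cut_off")
    if cut_on < grid.lambda_min or cut_off > grid.lambda_max:
        raise ValueError(
            f"passband [{cut_on}, {cut_off}] nm exceeds grid span "
            f"[{grid.lambda_min}, {grid.lambda_max}] nm"
        )
    if not (0.0 < peak <= 1.0):
        raise ValueError("peak must lie in (0, 1]")

    full_edge = edge_width / _EDGE_SPAN_FRACTION  # full 0 -> 1 span
    lam = grid.values

    u_on = np.clip((lam - (cut_on - 0.5 * full_edge)) / full_edge, 0.0, 1.0)
    rising = 0.5 * (1.0 - np.cos(np.pi * u_on))
    u_off = np.clip((lam - (cut_off - 0.5 * full_edge)) / full_edge, 0.0, 1.0)
    falling = 1.0 - 0.5 * (1.0 - np.cos(np.pi * u_off))

    return Spectrum(grid, peak * rising * falling)


def spr_spectrum(dip: DipModel, n: float, grid: WavelengthGrid,
                 n_bounds: tuple[float, float] = (1.30, 1.40)) -> Spectrum:
    """Reflectance spectrum of the SPR surface at refractive index ``n``."""
    lo, hi = n_bounds
    if not (lo <= n <= hi):
        raise ValueError(f"refractive index {n} outside sane aqueous range [{lo}, {hi}]")
    lam = grid.values
    center = dip.dip_center(n)
    samples = dip.baseline - dip.depth * np.exp(-((lam - center) ** 2) / (2.0 * dip.width**2))
    return Spectrum(grid, samples)


def band_intensity(reflectance: Spectrum, filt: Spectrum,
                   illumination: Spectrum | None = None) -> float:
    """Band-integrated detected intensity (trapezoid over the shared grid).

    Computes ``integral R(lambda) T(lambda) L(lambda) dlambda``.  A ``None``
    illumination means a flat (unit) source spectrum.
    """
    reflectance.require_same_grid(filt)
    product = reflectance.samples * filt.samples
    if illumination is not None:
        reflectance.require_same_grid(illumination)
        product = product * illumination.samples
    value = float(np.trapezoid(product, reflectance.wavelengths))
    return value


def gamma_value(i_a, i_ab):
    """Spectral contrast response gamma = (2 I_A - I_AB) / I_AB.

    Algebraically identical to ``(I_A - I_B) / (I_A + I_B)`` with
    ``I_B = I_AB - I_A``; bounded in [-1, 1] for 0 <= I_A <= I_AB.  Accepts
    scalars or arrays (elementwise).
    """
    i_a = np.asarray(i_a, dtype=float)
    i_ab = np.asarray(i_ab, dtype=float)
    if np.any(i_ab <= 0):
        raise ValueError("I_AB must be positive (mask dark pixels before calling)")
    out = (2.0 * i_a - i_ab) / i_ab
    if out.ndim == 0:
        return float(out)
    return out


class DipLocation(NamedTuple):
    """Result of resonance-dip localization within a search band."""

    wavelength: float
    on_boundary: bool
    index: int


def find_dip(spectrum: Spectrum, search_band: PassbandFilter,
             refine: bool = False) -> DipLocation:
    """Locate the resonance dip as the in-band intensity minimum.

    The dip is the wavelength of the minimum sample within
    ``[cut_on, cut_off]``.  With ``refine`` a three-point quadratic
    interpolation around the argmin sharpens the estimate below the grid
    step (off by default: the raw minimum is the conventional readout).
    A minimum landing on the band boundary is flagged via ``on_boundary``
    (the dip may have left the search window).
    """
    lam = spectrum.wavelengths
    in_band = (lam >= search_band.cut_on) & (lam <= search_band.cut_off)
    if in_band.sum() < 3:
        raise ValueError("search band overlaps fewer than three grid samples")
    vals = spectrum.samples[in_band]
    if np.ptp(vals) <= 1e-14 * max(1.0, abs(float(vals[0]))):
        raise ValueError("spectrum is constant within the search band; no dip to locate")

    band_idx = np.flatnonzero(in_band)
    local = int(np.argmin(vals))
    idx = int(band_idx[local])
    on_boundary = local == 0 or local == len(vals) - 1
    wavelength = float(lam[idx])

    if refine and not on_boundary:
        y0, y1, y2 = spectrum.samples[idx - 1], spectrum.samples[idx], spectrum.samples[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:  # curvature consistent with a minimum
            delta = 0.5 * (y0 - y2) / denom
            wavelength = float(lam[idx] + np.clip(delta, -1.0, 1.0) * spectrum.grid.step)

    return DipLocation(wavelength, on_boundary, idx)


@dataclass(frozen=True)
class GaussianDipFit:
    """Least-squares Gaussian dip fit: R = baseline - depth * exp(...)."""

    center: float
    width: float
    depth: float
    baseline: float
    residual_norm: float
    covariance: np.ndarray = field(repr=False)

    def as_dip_model(self, n0: float = 1.333, slope_s_lambda: float = 0.0) -> DipModel:
        return DipModel(lambda0=self.center, n0=n0, slope_s_lambda=slope_s_lambda,
                        width=self.width, depth=self.depth,
                        baseline=min(self.baseline, 1.0))


def _gaussian_dip(lam, center, width, depth, baseline):
    return baseline - depth * np.exp(-((lam - center) ** 2) / (2.0 * width**2))


def fit_gaussian_dip(spectrum: Spectrum,
                     initial: DipModel | None = None) -> GaussianDipFit:
    """Fit a Gaussian dip to a spectrum by nonlinear least squares.

    The starting point is taken from ``initial`` when given, otherwise
    auto-estimated from the spectrum (argmin for the center, extrema for
    depth/baseline, half-depth crossing for the width).  Raises on flat input,
    on input without an interior minimum, and on non-convergence.
    """
    lam = spectrum.wavelengths
    vals = spectrum.samples
    span = float(np.ptp(vals))
    if span <= 1e-12:
        raise ValueError("flat spectrum: nothing to fit")

    if initial is not None:
        p0 = [initial.lambda0, initial.width, initial.depth, initial.baseline]
    else:
        imin = int(np.argmin(vals))
        if imin == 0 or imin == len(vals) - 1:
            raise ValueError("no interior minimum in the spectrum (monotonic input?)")
        baseline0 = float(np.max(vals))
        depth0 = span
        center0 = float(lam[imin])
        # width from the half-depth crossing nearest the minimum
        half = baseline0 - 0.5 * depth0
        above = np.flatnonzero(vals[imin:] >= half)
        width0 = float(lam[imin + above[0]] - center0) / 1.1774 if above.size else 5.0
        width0 = max(width0, spectrum.grid.step)
        p0 = [center0, width0, depth0, baseline0]

    try:
        popt, pcov = curve_fit(
            _gaussian_dip, lam, vals, p0=p0,
            bounds=([lam[0] - 50.0, 1e-3, 0.0, -np.inf],
                    [lam[-1] + 50.0, 200.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Gaussian dip fit did not converge (start {p0}): {exc}") from exc

    center, width, depth, baseline = (float(v) for v in popt)
    residual = float(np.linalg.norm(vals - _gaussian_dip(lam, *popt)))
    return GaussianDipFit(center, width, depth, baseline, residual, pcov)
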