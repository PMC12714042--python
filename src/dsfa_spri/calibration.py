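"""Sensitivity, baseline noise, and limit-of-detection calibration.

Two interrogation modes share one arithmetic:

* spectral-shift mode — the resonance wavelength is tracked against the
  refractive index; sensitivity S_lambda is the OLS slope in nm/RIU;
* gamma mode — the ROI-averaged spectral contrast is tracked instead;
  sensitivity S_gamma is in a.u./RIU.

In both, the limit of detection is LOD = baseline_noise / |sensitivity|
(RIU): the refractive-index change resolvable at one baseline standard
deviation.  The module also provides the theoretical-sensitivity procedure
(red-shift a Gaussian-fitted dip through the measured filter curves and fit
gamma against n) and a 3-sigma concentration-LOD extrapolation for
dose-response end points.

Helpers at the end run the full synthetic staircase calibration for both
modes, from simulated spectrometer spectra and simulated image stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .demosaic import demosaic_frame
from .pipeline import (
    DEFAULT_INTENSITY_FLOOR,
    GammaSeries,
    gamma_map,
    interior_tile_mask,
)
from .simulate import FrameStack
from .spectral import (
    AB_FILTER,
    DipModel,
    PassbandFilter,
    Spectrum,
    WavelengthGrid,
    band_intensity,
    find_dip,
    fit_gaussian_dip,
    gamma_value,
    spr_spectrum,
)

__all__ = [
    "LinearFit",
    "CalibrationResult",
    "ConcentrationResponse",
    "ConcentrationLOD",
    "TheoreticalSensitivity",
    "fit_sensitivity",
    "baseline_noise",
    "detection_limit",
    "theoretical_gamma_sensitivity",
    "concentration_lod",
    "simulate_dip_spectra",
    "spectral_shift_calibration",
    "gamma_calibration",
]


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    stderr: float


def fit_sensitivity(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least-squares sensitivity fit (slope in y-units per RIU)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two (x, y) pairs of equal length")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: sensitivity is undefined")
    res = linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue) ** 2, float(res.stderr))


def baseline_noise(series, window: tuple[int, int] | None = None) -> float:
    """Sample standard deviation (n-1 denominator) over a series window.

    ``series`` is a plain sequence or a :class:`GammaSeries`; ``window`` is a
    half-open index range ``(start, stop)``, default the whole series.
    """
    values = series.values if isinstance(series, GammaSeries) else np.asarray(series, dtype=float)
    if window is not None:
        start, stop = window
        if start < 0 or stop > len(values) or stop - start < 2:
            raise ValueError(f"window {window} invalid for series of length {len(values)}")
        values = values[start:stop]
    if len(values) < 2:
        raise ValueError("need at least two samples to estimate noise")
    if np.any(~np.isfinite(values)):
        raise ValueError("series window contains gaps (NaN)")
    return float(np.std(values, ddof=1))


def detection_limit(noise: float, sensitivity: float) -> float:
    """Limit of detection in RIU: baseline noise divided by |sensitivity|."""
    if sensitivity == 0:
        raise ValueError("zero sensitivity: LOD undefined")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    return noise / abs(sensitivity)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted sensitivity, baseline noise, and detection limit with units."""

    mode: str  # "spectral_shift" or "gamma"
    sensitivity: float
    intercept: float
    r_squared: float
    baseline_noise: float
    lod: float
    sensitivity_units: str
    noise_units: str
    per_state: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        expected = detection_limit(self.baseline_noise, self.sensitivity)
        if not np.isclose(self.lod, expected, rtol=1e-12, atol=0):
            raise ValueError("lod must equal baseline_noise / |sensitivity|")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sensitivity": self.sensitivity,
            "sensitivity_units": self.sensitivity_units,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "baseline_noise": self.baseline_noise,
            "noise_units": self.noise_units,
            "lod_riu": self.lod,
        }


@dataclass(frozen=True)
class TheoreticalSensitivity:
    """Result of the Gaussian-redshift theoretical-sensitivity procedure."""

    slope: float
    intercept: float
    r_squared: float
    n_values: np.ndarray
    gamma_values: np.ndarray
    dip_exits_band: bool


def _half_max_band(filt: Spectrum) -> tuple[float, float]:
    lam = filt.wavelengths
    t = filt.samples
    above = lam[t >= 0.5 * t.max()]
    return float(above[0]), float(above[-1])


def theoretical_gamma_sensitivity(filter_a: Spectrum, filter_ab: Spectrum,
                                  fitted_dip: DipModel,
                                  s_lambda: float | None = None,
                                  n_range: tuple[float, float] = (1.333, 1.3495),
                                  n_points: int = 20,
                                  illumination: Spectrum | None = None) -> TheoreticalSensitivity:
    """Theoretical gamma sensitivity from a Gaussian-fitted dip.

    Red-shifts the fitted Gaussian dip by ``s_lambda * (n - n0)`` across
    ``n_range``, integrates it through the supplied filter curves, computes
    gamma at each step, and fits gamma against n by OLS.  ``dip_exits_band``
    flags configurations whose dip center leaves the AB half-maximum band
    within the scan (the slope is then dominated by edge effects).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    filter_a.require_same_grid(filter_ab)
    if s_lambda is None:
        s_lambda = fitted_dip.slope_s_lambda
    dip = DipModel(lambda0=fitted_dip.lambda0, n0=fitted_dip.n0,
                   slope_s_lambda=float(s_lambda), width=fitted_dip.width,
                   depth=fitted_dip.depth, baseline=fitted_dip.baseline)

    lo, hi = _half_max_band(filter_ab)
    ns = np.linspace(n_range[0], n_range[1], n_points)
    centers = np.array([dip.dip_center(v) for v in ns])
    exits = bool(np.any((centers < lo) | (centers > hi)))

    gammas = np.empty_like(ns)
    for k, n in enumerate(ns):
        refl = spr_spectrum(dip, float(n), filter_a.grid)
        i_a = band_intensity(refl, filter_a, illumination)
        i_ab = band_intensity(refl, filter_ab, illumination)
        gammas[k] = gamma_value(i_a, i_ab)

    if s_lambda == 0:
        # degenerate scan: gamma is constant, slope exactly zero
        return TheoreticalSensitivity(0.0, float(gammas.mean()), 1.0, ns, gammas, exits)
    fit = fit_sensitivity(ns, gammas)
    return TheoreticalSensitivity(fit.slope, fit.intercept, fit.r_squared,
                                  ns, gammas, exits)


@dataclass(frozen=True)
class ConcentrationResponse:
    """Post-wash gamma differences at a series of analyte concentrations."""

    concentrations: np.ndarray  # ug/mL, strictly increasing, positive
    delta_gamma: np.ndarray  # a.u.
    noise: float  # a.u., baseline gamma noise

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.delta_gamma, dtype=float)
        if c.shape != d.shape or c.size < 2:
            raise ValueError("need >= 2 matched concentration/response points")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "delta_gamma", d)


@dataclass(frozen=True)
class ConcentrationLOD:
    concentration: float  # ug/mL
    extrapolated: bool
    slope: float
    intercept: float
    k: float
    mode: str


def concentration_lod(response: ConcentrationResponse, k: float = 3.0,
                      mode: str = "log") -> ConcentrationLOD:
    """Concentration detectable at ``k`` times the baseline gamma noise.

    Fits ``delta_gamma = a log10(C) + b`` (default) or a through-origin
    linear response ``delta_gamma = a C`` and solves for the concentration at
    which the response equals ``k * noise``.  A result below the lowest
    measured concentration is flagged as extrapolated.
    """
    c, d = response.concentrations, response.delta_gamma
    threshold = k * response.noise
    if mode == "log":
        fit = fit_sensitivity(np.log10(c), d)
        if fit.slope <= 0:
            raise ValueError("non-increasing response with concentration")
        c_lod = float(10.0 ** ((threshold - fit.intercept) / fit.slope))
        slope, intercept = fit.slope, fit.intercept
    elif mode == "linear":
        if fit_sensitivity(c, d).slope <= 0:
            raise ValueError("non-increasing response with concentration")
        slope = float(np.dot(c, d) / np.dot(c, c))  # through-origin response
        intercept = 0.0
        c_lod = float(threshold / slope)
    else:
        raise ValueError("mode must be 'log' or 'linear'")
    return ConcentrationLOD(c_lod, c_lod < c[0], slope, intercept, k, mode)


# ---------------------------------------------------------------------------
# End-to-end synthetic staircase calibration
# ---------------------------------------------------------------------------

def simulate_dip_spectra(dip: DipModel, levels: Sequence[float],
                         spectra_per_state: int = 10,
                         grid: WavelengthGrid | None = None,
                         noise_sigma: float = 1e-3,
                         seed: int = 0) -> dict[float, list[Spectrum]]:
    """Simulated spectrometer channel: noisy SPR spectra per RI state.

    The spectrometer samples at 0.5 nm by default — coarse relative to the
    imaging channel — with additive Gaussian reflectance noise per sample.
    """
    if grid is None:
        grid = WavelengthGrid(550.0, 610.0, 0.5)
    rng = np.random.default_rng(seed)
    out: dict[float, list[Spectrum]] = {}
    for level in levels:
        clean = spr_spectrum(dip, float(level), grid)
        out[float(level)] = [
            Spectrum(grid, clean.samples + rng.normal(0.0, noise_sigma, len(grid)))
            for _ in range(spectra_per_state)
        ]
    return out


def spectral_shift_calibration(spectra_by_state: Mapping[float, Sequence[Spectrum]],
                               band: PassbandFilter = AB_FILTER,
                               localizer: str = "gauss",
                               noise_statistic: str = "max") -> CalibrationResult:
    """Spectral-shift-mode calibration from per-state spectrum ensembles.

    Per state, the stability series tracks the raw in-band minimum of each
    individual spectrum (the conventional spectrometer readout); the state
    wavelength used for the sensitivity fit comes from a Gaussian fit of the
    state-averaged spectrum (``localizer='gauss'``, robust on a coarse grid)
    or from the mean of the raw minima (``localizer='min'``).  Baseline noise
    is the max (default) or mean of the per-state standard deviations.
    """
    if localizer not in ("gauss", "min"):
        raise ValueError("localizer must be 'gauss' or 'min'")
    rows = []
    for n, spectra in sorted(spectra_by_state.items()):
        spectra = list(spectra)
        minima = np.array([find_dip(s, band).wavelength for s in spectra])
        if localizer == "gauss":
            mean_spectrum = Spectrum(spectra[0].grid,
                                     np.mean([s.samples for s in spectra], axis=0))
            center = fit_gaussian_dip(mean_spectrum).center
        else:
            center = float(minima.mean())
        rows.append({
            "n": float(n),
            "wavelength_nm": center,
            "wavelength_sd_nm": float(np.std(minima, ddof=1)) if len(minima) > 1 else 0.0,
            "n_spectra": len(spectra),
        })
    table = pd.DataFrame(rows)
    fit = fit_sensitivity(table["n"], table["wavelength_nm"])
    noise = _pool_noise(table["wavelength_sd_nm"].to_numpy(), noise_statistic)
    return CalibrationResult(
        mode="spectral_shift", sensitivity=fit.slope, intercept=fit.intercept,
        r_squared=fit.r_squared, baseline_noise=noise,
        lod=detection_limit(noise, fit.slope),
        sensitivity_units="nm/RIU", noise_units="nm", per_state=table)


def _pool_noise(per_state_sd: np.ndarray, statistic: str) -> float:
    if statistic == "max":
        return float(np.max(per_state_sd))
    if statistic == "mean":
        return float(np.mean(per_state_sd))
    if statistic == "pooled":
        return float(np.sqrt(np.mean(per_state_sd**2)))
    raise ValueError("noise_statistic must be 'max', 'mean', or 'pooled'")


def gamma_calibration(stack: FrameStack, state_n: Sequence[float],
                      state_windows: Sequence[tuple[int, int]],
                      intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
                      roi: str | np.ndarray = "interior",
                      interior_border_px: int = 1,
                      noise_statistic: str = "max",
                      demosaic_mode: str = "average") -> CalibrationResult:
    """Gamma-mode calibration from a DBSI frame stack.

    Each frame is demosaiced, converted to a gamma map, and averaged over the
    ROI ("interior" restricts to tile-interior pixels, keeping boundary grid
    artifacts out of the statistic; "full" uses every valid pixel; or pass a
    boolean mask on the cropped band-image shape).  Per state window
    ``(start, stop)`` the frame-mean series gives the state mean and its
    standard deviation; sensitivity, noise, and LOD follow as in
    spectral-shift mode.
    """
    if len(state_n) != len(state_windows):
        raise ValueError("state_n and state_windows must align")
    geometry = stack.geometry
    tp = geometry.tile_px

    means = np.empty(len(stack))
    for k in range(len(stack)):
        bands = demosaic_frame(stack.frame(k), mode=demosaic_mode)
        frame = gamma_map(bands, intensity_floor, timestamp=float(stack.times[k]))
        if isinstance(roi, str):
            if roi == "interior":
                mask = interior_tile_mask(frame.values.shape, tp, interior_border_px)
            elif roi == "full":
                mask = np.ones(frame.values.shape, dtype=bool)
            else:
                raise ValueError("roi must be 'interior', 'full', or a boolean mask")
        else:
            mask = np.asarray(roi, dtype=bool)
        means[k] = frame.mean(mask)

    rows = []
    for n, (start, stop) in zip(state_n, state_windows):
        window = means[start:stop]
        if len(window) < 2:
            raise ValueError(f"state window ({start}, {stop}) has fewer than two frames")
        rows.append({
            "n": float(n),
            "gamma_mean": float(np.mean(window)),
            "gamma_sd": float(np.std(window, ddof=1)),
            "n_frames": len(window),
        })
    table = pd.DataFrame(rows)
    fit = fit_sensitivity(table["n"], table["gamma_mean"])
    noise = _pool_noise(table["gamma_sd"].to_numpy(), noise_statistic)
    return CalibrationResult(
        mode="gamma", sensitivity=fit.slope, intercept=fit.intercept,
        r_squared=fit.r_squared, baseline_noise=noise,
        lod=detection_limit(noise, fit.slope),
        sensitivity_units="a.u./RIU", noise_units="a.u.", per_state=table)
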