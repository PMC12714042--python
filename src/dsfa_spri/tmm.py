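"""Transfer-matrix optics for multilayer dielectric filter stacks.

Standard 2x2 characteristic-matrix treatment of stratified media, used here
to model SiO2/Ta2O5 interference filters of the kind the dual-band filter
array is built from: quarter-wave reflectors, their transmittance spectra,
and the insensitivity of a buried stack's spectral feature to a thin SiO2
overlayer (the etch-stop argument).

Conventions: layers are listed incident-side first; indices may be complex
with a non-negative imaginary part (absorption); angles are in radians in the
incident medium; polarization is "TE" (s) or "TM" (p).  Material indices
default to non-dispersive SiO2 = 1.46 and Ta2O5 = 2.10.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectral import PassbandFilter, Spectrum, WavelengthGrid

__all__ = [
    "SIO2_INDEX",
    "TA2O5_INDEX",
    "Layer",
    "Stack",
    "characteristic_matrix",
    "stack_transmittance",
    "stack_reflectance",
    "overlayer_shift_scan",
    "quarter_wave_stack",
    "band_centroid",
]

SIO2_INDEX = 1.46
TA2O5_INDEX = 2.10


@dataclass(frozen=True)
class Layer:
    """A homogeneous film: complex refractive index and physical thickness (nm)."""

    index: complex
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if complex(self.index).imag < 0:
            raise ValueError("Im(index) must be >= 0 (lossless or absorbing)")


@dataclass(frozen=True)
class Stack:
    """Layer sequence between an incident medium and a substrate."""

    layers: tuple[Layer, ...] = ()
    n_incident: float = 1.0
    n_substrate: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        for n in (self.n_incident, self.n_substrate):
            if not (np.isreal(n) and n >= 1.0):
                raise ValueError("incident/substrate indices must be real and >= 1")

    def with_overlayer(self, layer: Layer) -> "Stack":
        """New stack with ``layer`` prepended on the incident side."""
        return replace(self, layers=(layer, *self.layers))

    def reversed(self) -> "Stack":
        return Stack(tuple(reversed(self.layers)), n_incident=self.n_substrate,
                     n_substrate=self.n_incident)


def _cos_theta(index, n_incident: float, angle: float):
    """Complex propagation cosine in a medium, from the Snell invariant."""
    kt = n_incident * np.sin(angle) / index
    return np.sqrt(1.0 - kt**2 + 0j)


def _admittance(index, cos_t, polarization: str):
    if polarization == "TE":
        return index * cos_t
    if polarization == "TM":
        return index / cos_t
    raise ValueError(f"polarization must be 'TE' or 'TM', got {polarization!r}")


def characteristic_matrix(layer: Layer, wavelength: float, angle: float = 0.0,
                          polarization: str = "TE",
                          n_incident: float = 1.0) -> np.ndarray:
    """2x2 characteristic matrix of a single film at one wavelength.

    Phase thickness ``delta = 2 pi n d cos(theta_layer) / lambda`` with the
    in-layer angle given by the Snell invariant from the incident medium.
    The matrix is unimodular for any lossless layer.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if abs(np.sin(angle)) >= 1.0:
        raise ValueError("evanescent incidence: |sin(angle)| must be < 1 in the entry medium")
    n = complex(layer.index)
    cos_t = _cos_theta(n, n_incident, angle)
    eta = _admittance(n, cos_t, polarization)
    delta = 2.0 * np.pi * n * layer.thickness * cos_t / wavelength
    c, s = np.cos(delta), np.sin(delta)
    return np.array([[c, 1j * s / eta], [1j * eta * s, c]], dtype=complex)


def _stack_amplitudes(stack: Stack, wavelengths: np.ndarray, angle: float,
                      polarization: str):
    """Vectorized reflection/transmission amplitudes over a wavelength axis."""
    if abs(np.sin(angle)) >= 1.0:
        raise ValueError("evanescent incidence: |sin(angle)| must be < 1 in the entry medium")
    lam = np.asarray(wavelengths, dtype=float)

    cos0 = _cos_theta(stack.n_incident, stack.n_incident, angle)
    eta0 = _admittance(stack.n_incident, cos0, polarization)
    cos_s = _cos_theta(stack.n_substrate, stack.n_incident, angle)
    eta_s = _admittance(stack.n_substrate, cos_s, polarization)

    b = np.ones_like(lam, dtype=complex)
    c = np.full_like(lam, eta_s, dtype=complex)
    for layer in reversed(stack.layers):
        n = complex(layer.index)
        cos_t = _cos_theta(n, stack.n_incident, angle)
        eta = _admittance(n, cos_t, polarization)
        delta = 2.0 * np.pi * n * layer.thickness * cos_t / lam
        cd, sd = np.cos(delta), np.sin(delta)
        b, c = cd * b + 1j * sd / eta * c, 1j * eta * sd * b + cd * c

    denom = eta0 * b + c
    r = (eta0 * b - c) / denom
    t_power = 4.0 * eta0.real * eta_s.real / np.abs(denom) ** 2
    return r, t_power


def stack_transmittance(stack: Stack, grid: WavelengthGrid, angle: float = 0.0,
                        polarization: str = "TE") -> Spectrum:
    """Power transmittance spectrum T(lambda) of the stack."""
    _, t = _stack_amplitudes(stack, grid.values, angle, polarization)
    return Spectrum(grid, t.real)


def stack_reflectance(stack: Stack, grid: WavelengthGrid, angle: float = 0.0,
                      polarization: str = "TE") -> Spectrum:
    """Power reflectance spectrum R(lambda); T + R = 1 for lossless stacks."""
    r, _ = _stack_amplitudes(stack, grid.values, angle, polarization)
    return Spectrum(grid, np.abs(r) ** 2)


def band_centroid(spectrum: Spectrum, band: PassbandFilter) -> float:
    """Transmittance-weighted spectral centroid within a band (nm).

    Robust to ripple, unlike a peak argmax; raises on a featureless
    (near-zero or flat beyond numerical noise) in-band spectrum.
    """
    lam = spectrum.wavelengths
    in_band = (lam >= band.cut_on) & (lam <= band.cut_off)
    if in_band.sum() < 3:
        raise ValueError("band overlaps fewer than three grid samples")
    t = spectrum.samples[in_band]
    total = float(np.trapezoid(t, lam[in_band]))
    if total <= 0 or not np.isfinite(total):
        raise ValueError("featureless (zero) spectrum within the band")
    return float(np.trapezoid(t * lam[in_band], lam[in_band]) / total)


def overlayer_shift_scan(stack: Stack, overlayer_index: float,
                         thicknesses, band: PassbandFilter,
                         grid: WavelengthGrid | None = None,
                         angle: float = 0.0,
                         polarization: str = "TE") -> list[tuple[float, float]]:
    """Spectral-centroid shift of a band feature versus overlayer thickness.

    For each thickness, an overlayer (e.g. an SiO2 etch-stop film) is
    prepended on the incident side and the shift of the band's
    transmittance-weighted centroid relative to the bare stack is reported.
    A well-designed buried filter shows negligible shift for overlayers up to
    a couple of hundred nanometres.
    """
    if grid is None:
        grid = WavelengthGrid(band.cut_on - 30.0, band.cut_off + 30.0, 0.2)
    base = band_centroid(stack_transmittance(stack, grid, angle, polarization), band)
    out: list[tuple[float, float]] = []
    for d in thicknesses:
        if d == 0:
            out.append((0.0, 0.0))
            continue
        shifted = stack.with_overlayer(Layer(overlayer_index, float(d)))
        centroid = band_centroid(stack_transmittance(shifted, grid, angle, polarization), band)
        out.append((float(d), centroid - base))
    return out


def quarter_wave_stack(center: float, pairs: int, n_high: float = TA2O5_INDEX,
                       n_low: float = SIO2_INDEX, n_incident: float = 1.0,
                       n_substrate: float = 1.5, first: str = "high") -> Stack:
    """Quarter-wave high/low Bragg reflector designed at ``center`` nm."""
    if pairs < 1:
        raise ValueError("pairs must be >= 1")
    d_high = center / (4.0 * n_high)
    d_low = center / (4.0 * n_low)
    if first == "high":
        pair = (Layer(n_high, d_high), Layer(n_low, d_low))
    elif first == "low":
        pair = (Layer(n_low, d_low), Layer(n_high, d_high))
    else:
        raise ValueError("first must be 'high' or 'low'")
    return Stack(pair * pairs, n_incident=n_incident, n_substrate=n_substrate)
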