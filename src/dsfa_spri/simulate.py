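"""Synthetic checkerboard dual-band spectral image (DBSI) generator.

Renders the raw sensor-side object the pipeline consumes: monochrome frames
in which 10x10 um filter units alternate checkerboard-fashion between the
narrow A filter and the wide AB filter.  Each tile's noiseless value is the
band-integrated intensity of the forward optical model (illumination x filter
x SPR reflectance) times a camera gain; grid-boundary artifacts and camera
noise (Gaussian read noise, optional Poisson shot noise) are applied on top.

Refractive-index protocols (step staircases and Langmuir-style binding
transients) drive time sequences, and every sequence carries a ground-truth
sidecar table for parameter-recovery tests.

The camera pixel pitch is folded into an integer ``tile_px`` (default 4
pixels per filter unit) so that pixel-shift demosaicing is exact; resampling
of real, non-integer-pitch sensor data is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import (
    A_FILTER,
    AB_FILTER,
    DEFAULT_DIP,
    BandIntensities,
    DipModel,
    PassbandFilter,
    Spectrum,
    WavelengthGrid,
    band_intensity,
    default_grid,
    spr_spectrum,
)

__all__ = [
    "MosaicGeometry",
    "Segment",
    "RIProtocol",
    "NoiseModel",
    "SceneOptics",
    "DBSIFrame",
    "FrameStack",
    "build_mosaic",
    "evaluate_protocol",
    "render_frame",
    "render_sequence",
    "staircase_protocol",
    "DEFAULT_RI_LEVELS",
]

#: Five-state refractive-index staircase covering the calibration range.
DEFAULT_RI_LEVELS = tuple(np.linspace(1.333, 1.3495, 5))


@dataclass(frozen=True)
class MosaicGeometry:
    """Checkerboard layout: tile (i, j) is filter A iff (i + j + parity) is even."""

    n_tiles_x: int
    n_tiles_y: int
    tile_px: int
    parity: int = 0

    def __post_init__(self) -> None:
        if self.tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        if self.n_tiles_x < 1 or self.n_tiles_y < 1:
            raise ValueError("tile counts must be >= 1")
        if self.parity not in (0, 1):
            raise ValueError("parity must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_tiles_y * self.tile_px, self.n_tiles_x * self.tile_px)

    def tile_class_map(self) -> np.ndarray:
        """Boolean per-tile map, True where the tile carries filter A."""
        i, j = np.meshgrid(np.arange(self.n_tiles_y), np.arange(self.n_tiles_x),
                           indexing="ij")
        return (i + j + self.parity) % 2 == 0

    def pixel_class_map(self) -> np.ndarray:
        """Boolean per-pixel map, True on filter-A pixels."""
        return np.kron(self.tile_class_map(),
                       np.ones((self.tile_px, self.tile_px), dtype=bool))


def build_mosaic(n_tiles_x: int, n_tiles_y: int, tile_px: int,
                 parity: int = 0) -> MosaicGeometry:
    """Construct and validate a checkerboard mosaic geometry."""
    return MosaicGeometry(n_tiles_x, n_tiles_y, tile_px, parity)


@dataclass(frozen=True)
class Segment:
    """One protocol segment.

    kind 'step':     hold ``n`` for ``duration`` seconds.
    kind 'langmuir': pseudo-first-order association,
                     n(t') = n_start + delta_n_max * (1 - exp(-k_obs t')).
    kind 'wash':     exponential relaxation toward
                     n_base + residual_fraction * (n_start - n_base).
    """

    kind: str
    duration: float
    n: float | None = None
    delta_n_max: float | None = None
    k_obs: float | None = None
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "langmuir", "wash"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("segment duration must be > 0")
        if self.kind == "step" and self.n is None:
            raise ValueError("step segment requires n")
        if self.kind == "langmuir" and (self.delta_n_max is None or self.k_obs is None):
            raise ValueError("langmuir segment requires delta_n_max and k_obs")
        if self.kind == "wash" and self.k_obs is None:
            raise ValueError("wash segment requires k_obs")


@dataclass(frozen=True)
class RIProtocol:
    """Ordered refractive-index program; all n(t) must stay within [1.30, 1.40]."""

    segments: tuple[Segment, ...]
    n_start: float = 1.333

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        extremes = [self.n_start]
        n_at = self.n_start
        for seg in self.segments:
            if seg.kind == "step":
                n_at = seg.n
                extremes.append(n_at)
            elif seg.kind == "langmuir":
                extremes.append(n_at + seg.delta_n_max)
                n_at = n_at + seg.delta_n_max * (1.0 - np.exp(-seg.k_obs * seg.duration))
            else:  # wash
                target = self.n_start + seg.residual_fraction * (n_at - self.n_start)
                extremes.append(target)
                n_at = target + (n_at - target) * np.exp(-seg.k_obs * seg.duration)
            extremes.append(n_at)
        if min(extremes) < 1.30 or max(extremes) > 1.40:
            raise ValueError("protocol drives n outside [1.30, 1.40]")

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    def evaluate(self, times) -> np.ndarray:
        return evaluate_protocol(self, times)


def staircase_protocol(levels=DEFAULT_RI_LEVELS, dwell_s: float = 30.0) -> RIProtocol:
    """Step staircase through the given refractive-index levels."""
    return RIProtocol(tuple(Segment("step", dwell_s, n=float(v)) for v in levels),
                      n_start=float(levels[0]))


def evaluate_protocol(protocol: RIProtocol, times) -> np.ndarray:
    """Refractive index n(t) at the requested times (seconds from start).

    Piecewise-constant for step segments; exponential association/relaxation
    for Langmuir segments.  At a segment boundary the later segment applies.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    total = protocol.total_duration
    if np.any(t < 0) or np.any(t > total + 1e-9):
        raise ValueError(f"times must lie within [0, {total}] s")

    starts = np.concatenate([[0.0], np.cumsum([s.duration for s in protocol.segments])])
    out = np.empty_like(t)

    n_at = protocol.n_start
    for k, seg in enumerate(protocol.segments):
        t0, t1 = starts[k], starts[k + 1]
        last = k == len(protocol.segments) - 1
        sel = (t >= t0) & ((t <= t1) if last else (t < t1))
        tp = t[sel] - t0
        if seg.kind == "step":
            out[sel] = seg.n
            n_end = seg.n
        elif seg.kind == "langmuir":
            out[sel] = n_at + seg.delta_n_max * (1.0 - np.exp(-seg.k_obs * tp))
            n_end = n_at + seg.delta_n_max * (1.0 - np.exp(-seg.k_obs * seg.duration))
        else:  # wash
            target = protocol.n_start + seg.residual_fraction * (n_at - protocol.n_start)
            out[sel] = target + (n_at - target) * np.exp(-seg.k_obs * tp)
            n_end = target + (n_at - target) * np.exp(-seg.k_obs * seg.duration)
        n_at = n_end

    if np.isscalar(times) or np.ndim(times) == 0:
        return float(out[0])
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Gaussian read noise (counts) plus optional Poisson shot noise."""

    read_noise_sigma: float = 10.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SceneOptics:
    """Bundle of the forward optical model shared by all frames of a scene.

    ``gain`` converts band-integrated intensity (nm-scaled units) to detector
    counts; by default it is chosen so the two tile classes average ~2000
    counts at the protocol start index, i.e. mid-scale on a 12-bit camera.
    """

    dip: DipModel = DEFAULT_DIP
    filter_a: PassbandFilter = A_FILTER
    filter_ab: PassbandFilter = AB_FILTER
    grid: WavelengthGrid = field(default_factory=default_grid)
    illumination: Spectrum | None = None
    gain: float | None = None
    mid_scale_counts: float = 2000.0

    def __post_init__(self) -> None:
        t_a = self.filter_a.to_spectrum(self.grid).samples
        t_ab = self.filter_ab.to_spectrum(self.grid).samples
        if np.any(t_a > t_ab + 1e-12):
            raise ValueError("filters must be nested: T_A <= T_AB pointwise")
        object.__setattr__(self, "_t_a", Spectrum(self.grid, t_a))
        object.__setattr__(self, "_t_ab", Spectrum(self.grid, t_ab))
        if self.gain is None:
            ba = self.band_values(self.dip.n0)
            object.__setattr__(
                self, "gain",
                float(self.mid_scale_counts / (0.5 * (ba.i_a + ba.i_ab))))

    def band_values(self, n: float) -> BandIntensities:
        """Unit-gain band intensities (I_A, I_AB) at refractive index n."""
        refl = spr_spectrum(self.dip, float(n), self.grid)
        i_a = band_intensity(refl, self._t_a, self.illumination)
        i_ab = band_intensity(refl, self._t_ab, self.illumination)
        return BandIntensities(i_a, i_ab)

    def gamma(self, n: float) -> float:
        """Noiseless forward-model gamma at refractive index n."""
        return self.band_values(n).gamma


@dataclass(frozen=True)
class DBSIFrame:
    """One monochrome checkerboard frame with its mosaic geometry."""

    data: np.ndarray
    geometry: MosaicGeometry
    timestamp: float = 0.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.geometry.shape:
            raise ValueError(f"frame shape {data.shape} != geometry shape {self.geometry.shape}")
        if data.min() < 0 or data.max() > 2**self.bit_depth - 1:
            raise ValueError("frame values outside [0, 2^bit_depth - 1]")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class FrameStack:
    """Time sequence of DBSI frames plus acquisition metadata."""

    data: np.ndarray  # (n_frames, H, W) float counts
    times: np.ndarray  # seconds
    geometry: MosaicGeometry
    bit_depth: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if data.ndim != 3 or data.shape[0] != times.shape[0]:
            raise ValueError("data must be (n_frames, H, W) matching times")
        if data.shape[1:] != self.geometry.shape:
            raise ValueError("frame shape does not match geometry")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, k: int) -> DBSIFrame:
        return DBSIFrame(self.data[k], self.geometry, float(self.times[k]),
                         self.bit_depth)


def _boundary_mask(geometry: MosaicGeometry, width: int) -> np.ndarray:
    """Pixels within ``width`` px of an internal tile boundary."""
    h, w = geometry.shape
    tp = geometry.tile_px
    mask = np.zeros((h, w), dtype=bool)
    if width <= 0 or tp <= 1:
        return mask
    ly = np.arange(h) % tp
    lx = np.arange(w) % tp
    ty = np.arange(h) // tp
    tx = np.arange(w) // tp
    near_y = ((ly < width) & (ty > 0)) | ((ly >= tp - width) & (ty < geometry.n_tiles_y - 1))
    near_x = ((lx < width) & (tx > 0)) | ((lx >= tp - width) & (tx < geometry.n_tiles_x - 1))
    mask |= near_y[:, None]
    mask |= near_x[None, :]
    return mask


def _tile_values(geometry: MosaicGeometry, n, optics: SceneOptics):
    """Per-pixel noiseless (value, other-class value) images for scalar or per-tile n."""
    class_map = geometry.pixel_class_map()
    n_arr = np.asarray(n, dtype=float)
    if n_arr.ndim == 0:
        ba = optics.band_values(float(n_arr))
        a_img = np.full(geometry.shape, optics.gain * ba.i_a)
        ab_img = np.full(geometry.shape, optics.gain * ba.i_ab)
    elif n_arr.shape == (geometry.n_tiles_y, geometry.n_tiles_x):
        a_tiles = np.empty_like(n_arr)
        ab_tiles = np.empty_like(n_arr)
        for value in np.unique(n_arr):
            ba = optics.band_values(float(value))
            sel = n_arr == value
            a_tiles[sel] = optics.gain * ba.i_a
            ab_tiles[sel] = optics.gain * ba.i_ab
        ones = np.ones((geometry.tile_px, geometry.tile_px))
        a_img = np.kron(a_tiles, ones)
        ab_img = np.kron(ab_tiles, ones)
    else:
        raise ValueError("n must be a scalar or a per-tile (n_tiles_y, n_tiles_x) array")
    own = np.where(class_map, a_img, ab_img)
    other = np.where(class_map, ab_img, a_img)
    return own, other


def render_frame(geometry: MosaicGeometry, n, optics: SceneOptics | None = None,
                 artifact_fraction: float = 0.5, artifact_width: int = 1,
                 noise: NoiseModel | None = None,
                 rng: np.random.Generator | None = None,
                 bit_depth: int = 12, timestamp: float = 0.0) -> DBSIFrame:
    """Render one noisy checkerboard frame at refractive index ``n``.

    ``n`` may be a scalar or a per-tile array (spatially structured scenes).
    Grid artifacts replace boundary pixels of ``artifact_width`` px with a
    fixed mixture ``(1 - f) * own + f * other`` of the two tile-class values
    (f = ``artifact_fraction``; 0.5 reproduces the mean-contaminated boundary
    grid).  Noise is applied last; with ``noise=None`` the frame is exact.
    An identical noise seed reproduces the frame bitwise.
    """
    if optics is None:
        optics = SceneOptics()
    own, other = _tile_values(geometry, n, optics)

    img = own.copy()
    if artifact_width > 0 and artifact_fraction != 0.0:
        mask = _boundary_mask(geometry, artifact_width)
        img[mask] = (1.0 - artifact_fraction) * own[mask] + artifact_fraction * other[mask]

    if noise is not None:
        if rng is None:
            rng = noise.rng()
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise.read_noise_sigma > 0:
            img = img + rng.normal(0.0, noise.read_noise_sigma, img.shape)

    img = np.clip(img, 0.0, 2**bit_depth - 1)
    return DBSIFrame(img, geometry, timestamp, bit_depth)


def render_sequence(geometry: MosaicGeometry, protocol: RIProtocol,
                    frame_rate: float = 1.0, optics: SceneOptics | None = None,
                    artifact_fraction: float = 0.5, artifact_width: int = 1,
                    noise: NoiseModel | None = None,
                    bit_depth: int = 12) -> tuple[FrameStack, pd.DataFrame]:
    """Render one frame per sample time over a refractive-index protocol.

    Returns the frame stack plus a ground-truth table with the per-frame
    time, refractive index, noiseless band intensities (in counts), and the
    forward-model gamma — the oracle for parameter-recovery tests.
    """
    if optics is None:
        optics = SceneOptics()
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    n_frames = int(np.floor(protocol.total_duration * frame_rate))
    if n_frames < 1:
        raise ValueError("protocol too short for the frame rate: zero frames requested")

    times = np.arange(n_frames) / frame_rate
    n_values = protocol.evaluate(times)
    rng = noise.rng() if noise is not None else None

    frames = np.empty((n_frames, *geometry.shape))
    truth_rows = []
    for k, (t, n) in enumerate(zip(times, n_values)):
        frame = render_frame(geometry, float(n), optics,
                             artifact_fraction=artifact_fraction,
                             artifact_width=artifact_width,
                             noise=noise, rng=rng, bit_depth=bit_depth,
                             timestamp=float(t))
        frames[k] = frame.data
        ba = optics.band_values(float(n))
        truth_rows.append({
            "time_s": float(t),
            "n": float(n),
            "i_a": optics.gain * ba.i_a,
            "i_ab": optics.gain * ba.i_ab,
            "gamma": ba.gamma,
        })

    stack = FrameStack(frames, times, geometry, bit_depth,
                       seed=noise.seed if noise is not None else None)
    return stack, pd.DataFrame(truth_rows)
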