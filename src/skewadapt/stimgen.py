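"""Stimulus generation: skewed image sequences, random-dot tests, and
parametric direction-statistics surrogates.

Skew distortion is the linear shear

    [x_d, y_d] = [x + tan(Ψ)·y, tan(Ψ)·x + y]

applied about the image center; it emulates the geometric distortion of
progressive-addition lenses and biases the motion-direction statistics of a
natural image sequence toward the skewing direction.  Because the original
12,000-frame movie is not redistributable, :func:`synth_movie` produces a
surrogate with the two properties the model actually consumes: broadband
(1/f) spatial content and piecewise-coherent local translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import DirectionGrid, DirectionSignal

__all__ = [
    "SkewTransform",
    "apply_skew",
    "skew_point",
    "hanning_weight",
    "hanning_window",
    "DotField",
    "update_dots",
    "MovieParams",
    "ImageSequence",
    "synth_movie",
    "DirectionStatsModel",
    "direction_stats_signal",
    "test_direction_signal",
]


# --------------------------------------------------------------------------
# skew distortion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SkewTransform:
    """Shear map (x, y) -> (x + tanΨ·y, tanΨ·x + y) about the image center."""

    psi: float  # shear angle Ψ in degrees

    def __post_init__(self) -> None:
        if abs(np.tan(np.radians(self.psi))) >= 1.0 - 1e-12:
            raise ValueError(
                f"|tan(Ψ)| >= 1 for Ψ = {self.psi}°: shear map is not invertible"
            )

    @property
    def matrix(self) -> np.ndarray:
        t = np.tan(np.radians(self.psi))
        return np.array([[1.0, t], [t, 1.0]])

    @property
    def determinant(self) -> float:
        t = np.tan(np.radians(self.psi))
        return 1.0 - t * t


def skew_point(x: float, y: float, psi: float) -> tuple[float, float]:
    """Forward shear map of a single point (degrees of shear angle)."""
    m = SkewTransform(psi).matrix
    xd, yd = m @ np.array([x, y], dtype=float)
    return float(xd), float(yd)


def apply_skew(
    image: np.ndarray,
    psi: float,
    crop: int | None = None,
    order: int = 1,
) -> np.ndarray:
    """Resample ``image`` under the shear map and crop the central square.

    The warp is implemented as an inverse-map resampling (bilinear by
    default) about the image center, so no holes are produced.  ``crop``
    gives the side of the central square kept after warping; by default 90%
    of the smaller image dimension (650 of 720 at the full scale).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("apply_skew expects a single 2-D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    tf = SkewTransform(psi)  # validates invertibility

    # scipy's affine_transform maps output coords to input coords; rows are y.
    # The shear matrix is symmetric under the (x, y) -> (row, col) swap.
    m_inv = np.linalg.inv(tf.matrix)
    center = (np.array(image.shape) - 1) / 2.0
    offset = center - m_inv @ center
    lo, hi = float(image.min()), float(image.max())
    warped = ndimage.affine_transform(
        image, m_inv, offset=offset, order=order, mode="constant", cval=lo
    )
    warped = np.clip(warped, lo, hi)

    if crop is None:
        crop = int(round(0.9 * min(image.shape)))
    crop = min(crop, *image.shape)
    r0 = (image.shape[0] - crop) // 2
    c0 = (image.shape[1] - crop) // 2
    return warped[r0 : r0 + crop, c0 : c0 + crop]


# --------------------------------------------------------------------------
# circular Hanning aperture
# --------------------------------------------------------------------------

def hanning_weight(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Radial aperture profile w(r) = cos²(π·r/N) for r ≤ N/2, else 0."""
    if n <= 0:
        raise ValueError("window extent N must be positive")
    r = np.asarray(r, dtype=float)
    w = np.where(r <= n / 2.0, np.cos(np.pi * r / n) ** 2, 0.0)
    return w if w.ndim else float(w)


def hanning_window(n: int) -> np.ndarray:
    """2-D circular Hanning aperture mask of size n×n (center weight 1)."""
    if n <= 0:
        raise ValueError("window extent N must be positive")
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    return np.asarray(hanning_weight(r, n))


# --------------------------------------------------------------------------
# random-dot test stimuli
# --------------------------------------------------------------------------

@dataclass
class DotField:
    """Coherently moving random dots inside a circular annulus.

    Positions are in degrees of visual angle relative to the annulus center.
    ``direction`` is the motion direction θ in degrees (positive = upward),
    ``speed`` in °/s.  The default aperture matches the experimental display:
    a 650-pixel diameter at 0.271 mm pixel pitch viewed from 57 cm, i.e.
    about 17.7° across.
    """

    positions: np.ndarray
    direction: float = 0.0
    speed: float = 3.0
    outer_radius: float = 8.85
    inner_radius: float = 0.0
    dot_diameter: float = 0.14

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (m, 2) array")
        self.positions = pos

    @property
    def dot_count(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def sample(
        cls,
        dot_count: int = 2000,
        direction: float = 0.0,
        speed: float = 3.0,
        outer_radius: float = 8.85,
        inner_radius: float = 0.0,
        rng_seed: int = 0,
        **kw,
    ) -> "DotField":
        rng = np.random.default_rng(rng_seed)
        pos = _uniform_annulus(rng, dot_count, inner_radius, outer_radius)
        return cls(pos, direction, speed, outer_radius, inner_radius, **kw)


def _uniform_annulus(rng, m: int, r_in: float, r_out: float) -> np.ndarray:
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, m))
    phi = rng.uniform(0.0, 2 * np.pi, m)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def update_dots(field: DotField, dt: float, rng_seed: int | np.random.Generator = 0) -> DotField:
    """Advance a dot field by ``dt`` seconds.

    Every dot translates by speed·dt along the motion direction (positive θ
    has an upward component); dots leaving the annulus are repositioned
    uniformly inside it with the seeded generator.  Dot count is conserved.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if field.dot_count == 0:
        raise ValueError("empty dot field")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    th = np.radians(field.direction)
    disp = field.speed * dt * np.array([np.cos(th), np.sin(th)])
    pos = field.positions + disp
    r = np.hypot(pos[:, 0], pos[:, 1])
    out = (r > field.outer_radius) | (r < field.inner_radius)
    if np.any(out):
        pos[out] = _uniform_annulus(
            rng, int(out.sum()), field.inner_radius, field.outer_radius
        )
    return replace(field, positions=pos)


# --------------------------------------------------------------------------
# surrogate naturalistic movies
# --------------------------------------------------------------------------

@dataclass
class ImageSequence:
    """Ordered grayscale frames in [0, 1] with display metadata."""

    frames: np.ndarray  # (t, h, w)
    frame_rate: float = 25.0
    pixel_pitch: float = 0.0272  # degrees per pixel at the experimental scale

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (t, h, w) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def map_frames(self, fn) -> "ImageSequence":
        mapped = np.stack([fn(f) for f in self.frames])
        return replace(self, frames=mapped)


@dataclass(frozen=True)
class MovieParams:
    """Texture / motion settings of the surrogate movie generator.

    The surrogate emulates the two statistics of the adapting movie the model
    consumes: a 1/f-like spatial amplitude spectrum (``spectral_slope``) and
    piecewise-coherent local translation.  Direction and speed are redrawn
    every ``segment_len`` frames: direction ~ N(direction_deg, direction_jitter),
    speed ~ |N(speed_px, speed_jitter)| pixels per frame.  The defaults give a
    horizontally dominated, broadband direction distribution, the desk-scale
    stand-in for natural-scene statistics.
    """

    size: int = 130
    spectral_slope: float = 1.0
    speed_px: float = 2.0
    speed_jitter: float = 0.3
    direction_deg: float = 0.0
    direction_jitter: float = 20.0
    segment_len: int = 12
    windowed: bool = True


def synth_movie(
    params: MovieParams | None = None,
    n_frames: int = 60,
    rng_seed: int = 0,
) -> ImageSequence:
    """Generate a deterministic surrogate naturalistic image sequence."""
    params = params or MovieParams()
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if params.size < 16:
        raise ValueError("frame size below filter support")
    rng = np.random.default_rng(rng_seed)

    # periodic 1/f texture on a larger canvas so the crop can drift
    canvas = 2 * params.size
    fy = np.fft.fftfreq(canvas)[:, None]
    fx = np.fft.fftfreq(canvas)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amp = f ** (-params.spectral_slope)
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, (canvas, canvas))
    texture_f = amp * np.exp(1j * phase)

    # piecewise-coherent velocity (pixels/frame), positive y = upward motion
    n_seg = int(np.ceil(n_frames / params.segment_len))
    dirs = np.radians(
        params.direction_deg + params.direction_jitter * rng.standard_normal(n_seg)
    )
    speeds = np.abs(params.speed_px + params.speed_jitter * rng.standard_normal(n_seg))
    vel = np.repeat(
        np.column_stack([speeds * np.cos(dirs), speeds * np.sin(dirs)]),
        params.segment_len,
        axis=0,
    )[:n_frames]

    shift = np.vstack([[0.0, 0.0], np.cumsum(vel[:-1], axis=0)])
    ky = 2j * np.pi * np.fft.fftfreq(canvas)[:, None]
    kx = 2j * np.pi * np.fft.fftfreq(canvas)[None, :]
    frames = np.empty((n_frames, params.size, params.size))
    mask = hanning_window(params.size) if params.windowed else None
    for i in range(n_frames):
        dx, dy = shift[i]
        # displacing the pattern by (+dx, +dy_up) moves rows by -dy
        ph = np.exp(-(kx * dx) - (ky * (-dy)))
        frame = np.fft.ifft2(texture_f * ph).real
        frame = frame[: params.size, : params.size]
        frames[i] = frame
    lo, hi = frames.min(), frames.max()
    frames = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)
    if mask is not None:
        frames = frames * mask
    return ImageSequence(frames)


# --------------------------------------------------------------------------
# parametric direction statistics (surrogate R_θ of the adapting movies)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionStatsModel:
    """Baseline + Gaussian-bump model of adapting-movie direction statistics.

    ``components`` is a list of (center°, SD°, amplitude) bumps on top of a
    uniform ``baseline``.  The built-in conditions emulate the qualitative
    statistics of windowed natural movies: un-skewed (UnSK) content is
    broadband but dominated by horizontal motion; ±25° skew shifts the
    dominant signal to about ±50°, leaving a weaker residual horizontal mode.

    Pooled motion energy has arbitrary units; the default amplitude scale
    (dominant bump 0.1) is calibrated so that the simulated psychometric
    functions have slopes in the human range (SD ≈ 2°), the observable the
    decision temperature was adjusted to reproduce.
    """

    baseline: float = 0.02
    components: tuple[tuple[float, float, float], ...] = ((0.0, 25.0, 0.1),)
    condition: str = "UnSK"

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        for c, w, a in self.components:
            if w <= 0 or a < 0:
                raise ValueError("bump widths must be > 0 and amplitudes >= 0")

    @classmethod
    def for_condition(cls, condition: str) -> "DirectionStatsModel":
        cond = condition.upper().replace("UNSK", "UnSK")
        if cond == "UnSK":
            return cls()
        if cond == "DSK":
            return cls(
                baseline=0.02,
                components=((-50.0, 20.0, 0.1), (0.0, 20.0, 0.06)),
                condition="DSK",
            )
        if cond == "USK":
            return cls.for_condition("DSK").mirrored("USK")
        raise ValueError(f"unknown condition {condition!r}")

    def mirrored(self, condition: str | None = None) -> "DirectionStatsModel":
        comps = tuple((-c, w, a) for c, w, a in self.components)
        return replace(
            self, components=comps, condition=condition or f"mirror({self.condition})"
        )


def direction_stats_signal(
    model: DirectionStatsModel, grid: DirectionGrid
) -> DirectionSignal:
    """Evaluate a :class:`DirectionStatsModel` on a direction grid."""
    th = grid.angles
    values = np.full(grid.n, float(model.baseline))
    for c, w, a in model.components:
        d = th - c
        if grid.circular:
            d = (d + 180.0) % 360.0 - 180.0
        values = values + a * np.exp(-(d**2) / (2.0 * w**2))
    return DirectionSignal(grid, values)


def test_direction_signal(
    theta: float,
    grid: DirectionGrid,
    width: float = 15.0,
    amplitude: float = 0.1,
) -> DirectionSignal:
    """Gaussian direction signal of a coherent random-dot test stimulus.

    ``width`` is the Gaussian SD (default 15°); the peak amplitude is the
    configured constant ``amplitude`` (default on the same calibrated scale
    as the adapting statistics, see :class:`DirectionStatsModel`).
    """
    if not grid.contains(theta):
        raise ValueError(f"test direction {theta}° outside grid range")
    if width <= 0 or amplitude < 0:
        raise ValueError("width must be > 0, amplitude >= 0")
    d = grid.angles - theta
    if grid.circular:
        d = (d + 180.0) % 360.0 - 180.0
    return DirectionSignal(grid, amplitude * np.exp(-(d**2) / (2.0 * width**2)))
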