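"""Local motion detection: elaborated-Reichardt / motion-energy front-end.

The stages mirror early visual processing: isotropic center-surround (DoG)
filtering ("LGN"), orientation-selective filtering by a steerable odd/even
quadrature pair, delayed cross-correlation between spatially shifted filter
outputs of consecutive frames (the Reichardt correlator), opponent
subtraction and half-wave rectification.  Detector directions live on the
full circle; when pooling onto a non-circular half-range grid the left and
right hemifields are folded onto the elevation axis (θ = angle from
horizontal, positive upward), the perceptual axis probed in the
experiments.  Pooling over space, time and speed yields the direction
signal R_θ consumed by the recurrent circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import DirectionGrid, DirectionSignal
from .stimgen import ImageSequence

__all__ = [
    "FilterBankSpec",
    "LocalMotionField",
    "erd_local_motion",
    "center_surround_normalize",
    "pool_to_direction_signal",
    "movie_direction_signal",
]


@dataclass(frozen=True)
class FilterBankSpec:
    """Parameters of the motion detector bank.

    ``delay`` is the temporal correlation delay in frames; ``shifts_px``
    lists the spatial correlation offsets (one per speed channel ρ);
    ``lgn_center_sigma``/``lgn_surround_sigma`` set the DoG radii and
    ``orient_sigma`` the scale of the steerable derivative filters (pixels).
    """

    delay: int = 1
    shifts_px: tuple[float, ...] = (1.0, 2.0)
    lgn_center_sigma: float = 1.0
    lgn_surround_sigma: float = 2.0
    orient_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("temporal delay must be at least one frame")
        if len(self.shifts_px) == 0 or min(self.shifts_px) <= 0:
            raise ValueError("need at least one positive spatial shift")


@dataclass
class LocalMotionField:
    """Rectified opponent motion energy R_{x,t,ρ,θ}.

    ``energy`` has shape (t, ρ, θ, h, w); ``directions`` are the half-circle
    elevation angles after left/right folding.
    """

    energy: np.ndarray
    directions: np.ndarray
    shifts_px: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.energy.ndim != 5:
            raise ValueError("energy must have shape (t, rho, theta, h, w)")
        if self.energy.shape[2] != len(self.directions):
            raise ValueError("direction axis mismatch")
        if self.energy.size and self.energy.min() < 0:
            raise ValueError("motion energy must be non-negative")


def _lgn(frame: np.ndarray, spec: FilterBankSpec) -> np.ndarray:
    return ndimage.gaussian_filter(frame, spec.lgn_center_sigma) - ndimage.gaussian_filter(
        frame, spec.lgn_surround_sigma
    )


def _derivatives(frame: np.ndarray, spec: FilterBankSpec):
    """Gaussian derivative basis (steerable) of one frame."""
    s = spec.orient_sigma
    gy = ndimage.gaussian_filter1d(frame, s, axis=0, order=1)
    gx = ndimage.gaussian_filter1d(frame, s, axis=1, order=1)
    gyy = ndimage.gaussian_filter1d(frame, s, axis=0, order=2)
    gxx = ndimage.gaussian_filter1d(frame, s, axis=1, order=2)
    gxy = ndimage.gaussian_filter1d(
        ndimage.gaussian_filter1d(frame, s, axis=1, order=1), s, axis=0, order=1
    )
    return gx, gy, gxx, gxy, gyy


def _steer(basis, phi: float):
    """Odd/even quadrature pair steered to image direction ``phi`` (radians).

    Image rows are y pointing down, so an upward motion component maps to a
    negative row direction.
    """
    gx, gy, gxx, gxy, gyy = basis
    c, si = np.cos(phi), -np.sin(phi)  # (col, row) direction of motion
    odd = c * gx + si * gy
    even = c * c * gxx + 2.0 * c * si * gxy + si * si * gyy
    return odd, even


def _shift(img: np.ndarray, dx: float, dy_up: float) -> np.ndarray:
    """Translate pattern by (+dx, +dy upward) with periodic bilinear warp."""
    return ndimage.shift(img, (-dy_up, dx), order=1, mode="grid-wrap", prefilter=False)


def erd_local_motion(seq: ImageSequence, spec: FilterBankSpec | None = None,
                     grid: DirectionGrid | None = None) -> LocalMotionField:
    """Detect local opponent motion energy from an image sequence.

    For each half-circle direction θ the full-circle image directions
    φ ∈ {θ, 180° − θ} are evaluated and summed (left/right fold).  For each
    φ the correlator multiplies the filtered frame at t with the filtered
    frame at t+Δ shifted backwards along φ, subtracts the anti-preferred
    (φ+180°) correlation, and half-wave rectifies.
    """
    spec = spec or FilterBankSpec()
    grid = grid or DirectionGrid.default()
    frames = seq.frames
    if frames.shape[0] <= spec.delay:
        raise ValueError("sequence shorter than the temporal delay")
    if min(frames.shape[1:]) < 8 * spec.orient_sigma:
        raise ValueError("frames smaller than the filter support")

    lgn = np.stack([_lgn(f, spec) for f in frames])
    bases = [_derivatives(f, spec) for f in lgn]
    n_t = frames.shape[0] - spec.delay
    n_rho = len(spec.shifts_px)
    energy = np.zeros((n_t, n_rho, grid.n, *frames.shape[1:]))

    for j, theta in enumerate(grid.angles):
        if grid.circular:
            phis = {theta % 360.0}
        else:
            phis = {theta % 360.0, (180.0 - theta) % 360.0}
        for phi_deg in phis:
            phi = np.radians(phi_deg)
            ux, uy = np.cos(phi), np.sin(phi)
            pairs = [_steer(b, phi) for b in bases]
            for rho, d in enumerate(spec.shifts_px):
                for t in range(n_t):
                    now = pairs[t]
                    nxt = pairs[t + spec.delay]
                    e = np.zeros(frames.shape[1:])
                    for ch in (0, 1):
                        # preferred arm: pattern moved by +d·u between frames;
                        # null arm swaps the delayed/undelayed taps, so a
                        # static sequence cancels exactly
                        fwd = now[ch] * _shift(nxt[ch], -d * ux, -d * uy)
                        bwd = nxt[ch] * _shift(now[ch], -d * ux, -d * uy)
                        e += fwd - bwd
                    energy[t, rho, j] += np.maximum(e, 0.0)
    return LocalMotionField(energy, grid.angles.copy(), tuple(spec.shifts_px))


def center_surround_normalize(
    field: LocalMotionField, surround: int = 9, eps_scale: float = 1e-3
) -> LocalMotionField:
    """Divisive normalization by a local spatial pool of responses.

    Each response is divided by (ε + mean response in a ``surround``-sized
    square window, pooled across directions and speeds at that location);
    ε = ``eps_scale`` times the field mean guards empty pools.
    """
    e = field.energy
    mean = float(e.mean())
    eps = eps_scale * mean if mean > 0 else eps_scale
    pooled = e.mean(axis=(1, 2))  # (t, h, w) pool across rho and theta
    pooled = np.stack(
        [ndimage.uniform_filter(p, size=surround, mode="nearest") for p in pooled]
    )
    norm = e / (eps + pooled[:, None, None, :, :])
    return replace(field, energy=norm)


def pool_to_direction_signal(
    field: LocalMotionField, grid: DirectionGrid | None = None
) -> DirectionSignal:
    """Average energy over space, time and speed per direction (R_θ)."""
    if field.energy.size == 0:
        raise ValueError("empty motion field")
    if grid is None:
        grid = DirectionGrid(field.directions.copy())
    elif not np.allclose(grid.angles, field.directions):
        raise ValueError("field directions do not match the grid")
    values = field.energy.mean(axis=(0, 1, 3, 4))
    return DirectionSignal(grid, values)


def movie_direction_signal(
    seq: ImageSequence,
    spec: FilterBankSpec | None = None,
    grid: DirectionGrid | None = None,
    normalize: bool = True,
) -> DirectionSignal:
    """Full front-end pipeline: ERD → normalization → direction pooling."""
    field = erd_local_motion(seq, spec, grid)
    if normalize:
        field = center_surround_normalize(field)
    return pool_to_direction_signal(field, grid)
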