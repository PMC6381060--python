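"""File I/O helpers: image stacks, direction signals, trial tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DirectionGrid, DirectionSignal
from .stimgen import ImageSequence

__all__ = [
    "save_image_sequence",
    "load_image_sequence",
    "save_direction_signal",
    "load_direction_signal",
    "save_dot_trajectory",
]


def save_image_sequence(seq: ImageSequence, path: str | Path) -> Path:
    """Write frames as a multi-page TIFF (.tif) or numbered PNGs (directory)."""
    path = Path(path)
    frames8 = (np.clip(seq.frames, 0, 1) * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, frames8)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames8):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    return path


def load_image_sequence(path: str | Path, frame_rate: float = 25.0) -> ImageSequence:
    """Read a grayscale stack written by :func:`save_image_sequence`."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files under {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        import tifffile

        frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageSequence(frames / 255.0, frame_rate=frame_rate)


def save_direction_signal(signal: DirectionSignal, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"direction_deg": signal.grid.angles, "energy": signal.values}
    ).to_csv(path, index=False)
    return path


def load_direction_signal(path: str | Path) -> DirectionSignal:
    df = pd.read_csv(path)
    grid = DirectionGrid(df["direction_deg"].to_numpy(dtype=float))
    return DirectionSignal(grid, df["energy"].to_numpy(dtype=float))


def save_dot_trajectory(frames: list, path: str | Path) -> Path:
    """Write dot positions per frame as CSV (frame, x, y)."""
    rows = []
    for i, field in enumerate(frames):
        for x, y in field.positions:
            rows.append({"frame": i, "x": x, "y": y})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
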