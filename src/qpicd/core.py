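"""Core containers for time-lapse quantitative phase images.

A quantitative phase image (QPI) records, per pixel, the optical phase delay
``dphi(x, y)`` in radians accumulated by light passing through a cell; it is
proportional to the dry-mass surface density integrated over the cell
thickness.  A :class:`PhaseImage` couples the 2-D phase map with the two
physical calibration constants every downstream feature needs: the pixel
size (assumed square) and the illumination wavelength, both in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["PhaseImage", "TimeLapseStack"]


@dataclass(frozen=True)
class PhaseImage:
    """One frame of a quantitative phase movie.

    Parameters
    ----------
    phase:
        2-D float array of phase values in radians.
    pixel_size:
        Pixel pitch in the object plane, micrometres (square pixels).
    wavelength:
        Illumination wavelength in micrometres.
    """

    phase: np.ndarray
    pixel_size: float
    wavelength: float

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        if phase.ndim != 2:
            raise ValueError(f"phase map must be 2-D, got shape {phase.shape}")
        if not (self.pixel_size > 0 and self.wavelength > 0):
            raise ValueError("pixel_size and wavelength must be positive")
        object.__setattr__(self, "phase", phase)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in square micrometres."""
        return self.pixel_size * self.pixel_size


@dataclass
class TimeLapseStack:
    """An ordered sequence of phase frames sampled at a fixed interval.

    ``interval`` is in minutes (6 min is the default acquisition cadence);
    frame ``i`` is at time ``i * interval / 60`` hours.
    """

    frames: list[PhaseImage]
    interval: float = 6.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.frames:
            first = self.frames[0]
            for fr in self.frames[1:]:
                if fr.shape != first.shape:
                    raise ValueError("all frames must share the same shape")
                if fr.pixel_size != first.pixel_size or fr.wavelength != first.wavelength:
                    raise ValueError("all frames must share pixel size and wavelength")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> PhaseImage:
        return self.frames[i]

    @property
    def times_h(self) -> np.ndarray:
        """Acquisition times of the frames in hours."""
        return np.arange(len(self.frames)) * self.interval / 60.0

    @property
    def duration_h(self) -> float:
        return 0.0 if not self.frames else float(self.times_h[-1])

    def as_array(self) -> np.ndarray:
        """Stack all frames into a (T, H, W) float array."""
        return np.stack([f.phase for f in self.frames])

    # -- TIFF round trip ----------------------------------------------------

    def write_tiff(self, path: str | Path) -> None:
        """Write the stack as a multi-page 32-bit float TIFF.

        Pixel size, wavelength and frame interval are stored as JSON in the
        image description so the stack round-trips without sidecar files.
        No timestamp tags are written, keeping output byte-reproducible.
        """
        first = self.frames[0]
        desc = json.dumps(
            {
                "pixel_size_um": first.pixel_size,
                "wavelength_um": first.wavelength,
                "interval_min": self.interval,
            },
            sort_keys=True,
        )
        tifffile.imwrite(
            path,
            self.as_array().astype(np.float32),
            description=desc,
            photometric="minisblack",
        )

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        pixel_size: float | None = None,
        wavelength: float | None = None,
        interval: float | None = None,
    ) -> "TimeLapseStack":
        """Read a stack written by :meth:`write_tiff`.

        Calibration values stored in the TIFF description are used unless
        overridden explicitly.
        """
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta: dict = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
        lam = wavelength if wavelength is not None else meta.get("wavelength_um")
        dt = interval if interval is not None else meta.get("interval_min", 6.0)
        if px is None or lam is None:
            raise ValueError(
                "pixel size / wavelength not found in TIFF metadata; "
                "pass them explicitly"
            )
        if data.ndim == 2:
            data = data[None]
        frames = [PhaseImage(fr.astype(float), px, lam) for fr in data]
        return cls(frames=frames, interval=float(dt))


def write_label_tiff(path: str | Path, labels: Sequence[np.ndarray]) -> None:
    """Write per-frame integer label maps as a 16-bit multi-page TIFF."""
    arr = np.stack([np.asarray(l) for l in labels]).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_label_tiff(path: str | Path) -> np.ndarray:
    """Read a (T, H, W) label-map stack written by :func:`write_label_tiff`."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data.astype(np.int32)
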