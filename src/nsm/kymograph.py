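"""Kymograph container and TIFF + JSON-sidecar I/O.

A kymograph is the central exchange format of the package: a 2-D array of
relative contrast, rows = frames (time), columns = pixels along the channel
axis, together with the calibration needed to interpret it (frame interval,
pixel pitch, coordinate origin).  On disk it is a 32-bit float TIFF next to
a small JSON sidecar carrying the calibration and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile


@dataclass
class Kymograph:
    """Relative-contrast kymograph with calibration metadata.

    Attributes
    ----------
    contrast : ndarray, shape (n_frames, n_pixels)
        Signed relative contrast (dimensionless); for raw intensity movies
        the same container is reused with intensity values (see
        :mod:`nsm.preprocess`).
    dt : float
        Frame interval in seconds.
    pixel_pitch : float
        Pixel size along the channel axis in nm.
    origin : float
        Coordinate (nm) of the center of pixel 0.
    metadata : dict
        Free-form provenance (channel area, noise level, seed, ...).
    """

    contrast: np.ndarray
    dt: float
    pixel_pitch: float
    origin: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast)
        if self.contrast.ndim != 2:
            raise ValueError("kymograph contrast must be 2-D (frames x pixels)")
        if not np.all(np.isfinite(self.contrast)):
            raise ValueError("kymograph contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.contrast.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.contrast.shape[1]

    def pixel_positions(self) -> np.ndarray:
        """Positions (nm) of pixel centers along the channel."""
        return self.origin + self.pixel_pitch * np.arange(self.n_pixels)

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return self.dt * np.arange(self.n_frames)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write a float32 TIFF and a ``.json`` sidecar next to it."""
        path = Path(path)
        tifffile.imwrite(path, self.contrast.astype(np.float32))
        sidecar = {
            "dt_s": self.dt,
            "pixel_pitch_nm": self.pixel_pitch,
            "origin_nm": self.origin,
            **self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Kymograph":
        """Read a TIFF written by :meth:`save` (sidecar required)."""
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing metadata sidecar {sidecar_path} (dt and pixel pitch "
                "are required to interpret a kymograph)"
            )
        meta = json.loads(sidecar_path.read_text())
        dt = meta.pop("dt_s")
        pitch = meta.pop("pixel_pitch_nm")
        origin = meta.pop("origin_nm", 0.0)
        return cls(np.asarray(data, dtype=np.float64), dt, pitch, origin, meta)
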