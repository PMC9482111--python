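"""Light-weight containers for micrographs and region masks.

A :class:`Micrograph` wraps a 2D plane or a 3D Z-stack together with its
pixel calibration and channel role; a :class:`RegionMask` is a binary pixel
set delimiting one cell or one nucleus.  Both validate the invariants the
measurement code relies on (finite non-negative intensities, a single
connected region) so downstream functions can stay simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = ["Micrograph", "RegionMask"]

ChannelRole = Literal["cytoskeleton", "nucleus"]


@dataclass
class Micrograph:
    """A single-channel fluorescence micrograph.

    Parameters
    ----------
    pixels : ndarray
        2D ``(rows, cols)`` plane or 3D ``(slices, rows, cols)`` Z-stack.
        Intensities must be finite and non-negative.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    channel_role : {"cytoskeleton", "nucleus"}
        Which label the channel carries.
    """

    pixels: np.ndarray
    pixel_size: float = 0.1
    channel_role: ChannelRole = "cytoskeleton"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2D or 3D, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("intensities must be finite")
        if np.any(np.asarray(self.pixels, dtype=np.float64) < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.channel_role not in ("cytoskeleton", "nucleus"):
            raise ValueError(f"unknown channel_role {self.channel_role!r}")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size: float = 0.1,
        channel_role: ChannelRole = "cytoskeleton",
    ) -> "Micrograph":
        return cls(tifffile.imread(str(path)), pixel_size, channel_role)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels)


@dataclass
class RegionMask:
    """Binary mask delimiting a single cell or nucleus region.

    Must contain at least one true pixel forming a single connected
    component (8-connectivity).
    """

    pixels: np.ndarray
    _n_true: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={self.pixels.ndim}")
        n = int(self.pixels.sum())
        if n == 0:
            raise ValueError("mask must contain at least one true pixel")
        _, n_comp = ndi.label(self.pixels, structure=np.ones((3, 3), dtype=int))
        if n_comp != 1:
            raise ValueError(f"mask must be a single connected component, got {n_comp}")
        self._n_true = n

    @property
    def n_pixels(self) -> int:
        return self._n_true

    @classmethod
    def from_tiff(cls, path: str | Path) -> "RegionMask":
        return cls(tifffile.imread(str(path)) > 0)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels.astype(np.uint8) * 255)
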