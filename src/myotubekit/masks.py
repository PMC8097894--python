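"""Calibrated 2-D label masks.

All morphometry in this package operates on integer label images
(0 = background, k > 0 = object k) together with a single isotropic
pixel-size calibration in micrometres per pixel.  Masks are exchanged
on disk as single-channel 16-bit TIFF.

Coordinate convention: 0-based pixel indices; ``x`` is the column
index, ``y`` the row index.  Physical coordinates are index ×
``pixel_size``.  Angles are measured from the +x axis, counterclockwise
positive with y pointing up (i.e. row index negated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage


class MaskError(ValueError):
    """Raised for malformed label masks or calibration."""


@dataclass(eq=False)
class LabeledMask:
    """A 2-D integer label image with a μm/px calibration.

    Parameters
    ----------
    labels:
        2-D integer array; 0 is background, positive values are object ids.
    pixel_size:
        Side length of one pixel in micrometres.  Pixels are assumed square.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskError(f"label image must be 2-D, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise MaskError("label image must have an integer dtype")
        if self.labels.size and self.labels.min() < 0:
            raise MaskError("labels must be non-negative")
        if not (self.pixel_size > 0):
            raise MaskError(f"pixel_size must be > 0, got {self.pixel_size}")

    # -- basic queries ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size**2

    def present_labels(self) -> np.ndarray:
        """Sorted array of object ids present in the mask."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def pixel_count(self, label: int) -> int:
        n = int(np.count_nonzero(self.labels == label))
        if n == 0:
            raise MaskError(f"label {label} absent from mask")
        return n

    def area_um2(self, label: int) -> float:
        """Rasterized object area: pixel count × pixel_size²."""
        return self.pixel_count(label) * self.pixel_area

    def boundary_pixels(self, label: int) -> np.ndarray:
        """(row, col) coordinates of the object's 8-connectivity boundary.

        A pixel is a boundary pixel if it belongs to the object and at
        least one of its 8 neighbours does not.
        """
        obj = self.labels == label
        if not obj.any():
            raise MaskError(f"label {label} absent from mask")
        interior = ndimage.binary_erosion(obj, structure=np.ones((3, 3), bool))
        return np.argwhere(obj & ~interior)

    def boundary_pixels_um(self, label: int) -> np.ndarray:
        """Boundary pixel centres in μm, as (row, col) × pixel_size."""
        return self.boundary_pixels(label).astype(float) * self.pixel_size

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tiff(cls, path, pixel_size: float) -> "LabeledMask":
        arr = tifffile.imread(path)
        return cls(labels=np.asarray(arr).astype(np.int64), pixel_size=pixel_size)

    def to_tiff(self, path) -> None:
        """Write as single-channel 16-bit TIFF (labels must fit uint16)."""
        if self.labels.size and self.labels.max() > np.iinfo(np.uint16).max:
            raise MaskError("more than 65535 labels: cannot write 16-bit TIFF")
        tifffile.imwrite(path, self.labels.astype(np.uint16))


def min_boundary_distance_um(
    mask: LabeledMask, label_a: int, label_b: int
) -> float:
    """Minimal border-to-border Euclidean distance between two objects, μm.

    Distance between boundary *pixel centres*; sub-pixel edge geometry is
    not recoverable from a raster.
    """
    from scipy.spatial.distance import cdist

    pa = mask.boundary_pixels_um(label_a)
    pb = mask.boundary_pixels_um(label_b)
    return float(cdist(pa, pb).min())
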