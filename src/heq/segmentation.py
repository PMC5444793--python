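"""Lung segmentation by thresholding and interior region growing.

A CT slice is an integer grid of Hounsfield units (HU).  Lung parenchyma is
far less attenuating than soft tissue, so candidate lung pixels are those
below -500 HU.  Air outside the patient is below -500 HU too, but it is
connected to the image border; the lung fields are the sub-threshold
components that are *not* border-connected.  The mask is the union of all
such interior components above a minimum area (small interior components are
discarded as airway cross-sections or noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: HU cutoff separating lung parenchyma from soft tissue.
LUNG_THRESHOLD_HU = -500

#: Components smaller than this (pixels) are dropped as airways/noise.
DEFAULT_MIN_AREA = 50


class NoLungFoundError(ValueError):
    """Raised when no interior sub-threshold component qualifies as lung."""


class MaskError(ValueError):
    """Raised when a supplied mask fails validation."""


@dataclass(frozen=True)
class CTSlice:
    """A single 2-D CT slice in Hounsfield units.

    Parameters
    ----------
    hu
        2-D integer array of HU values, row-major, origin top-left.
    patient_id, slice_id
        Opaque identifiers; slices of one patient share ``patient_id``.
    pixel_spacing_mm
        In-plane pixel size (row, column) in millimetres.
    """

    hu: np.ndarray
    patient_id: str
    slice_id: str
    pixel_spacing_mm: tuple[float, float] = (0.78, 0.78)

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu)
        if hu.ndim != 2 or hu.size == 0:
            raise ValueError("HU grid must be a non-empty 2-D array")
        if not np.issubdtype(hu.dtype, np.integer):
            if not np.all(np.isfinite(hu)) or np.any(hu != np.round(hu)):
                raise ValueError("HU values must be finite integers")
            hu = hu.astype(np.int16)
        object.__setattr__(self, "hu", hu)
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape


@dataclass(frozen=True)
class LungMask:
    """Boolean lung mask congruent with its slice."""

    mask: np.ndarray
    lung_pixel_count: int = field(init=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise MaskError("mask must be 2-D")
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise MaskError(f"mask values must be binary, got {vals}")
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "lung_pixel_count", int(mask.sum()))

    def check_congruent(self, ct: CTSlice) -> None:
        """Validate pairing with a slice (shape match)."""
        if self.mask.shape != ct.shape:
            raise MaskError(
                f"mask shape {self.mask.shape} does not match slice {ct.shape}"
            )


# 8-connectivity structuring element for candidate lung components.
_STRUCT8 = np.ones((3, 3), dtype=bool)


def segment_lungs(ct: CTSlice, min_area: int = DEFAULT_MIN_AREA) -> LungMask:
    """Segment the lung fields of a CT slice.

    Pixels below -500 HU are candidates; 8-connected candidate components
    touching the image border (outside-patient air) are excluded, as are
    interior components smaller than ``min_area`` pixels.

    Raises
    ------
    NoLungFoundError
        If no interior component of at least ``min_area`` pixels exists.
    """
    if min(ct.shape) < 16:
        raise ValueError("slice must be at least 16x16 pixels")
    below = ct.hu < LUNG_THRESHOLD_HU
    labels, n = ndimage.label(below, structure=_STRUCT8)
    if n == 0:
        raise NoLungFoundError("no pixels below -500 HU")
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[border_labels] = False
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep &= areas >= min_area
    if not keep.any():
        raise NoLungFoundError(
            f"no interior component below -500 HU with area >= {min_area}"
        )
    return LungMask(keep[labels])


def load_mask(path, ct: CTSlice | None = None) -> LungMask:
    """Load a lung mask from a NIfTI file, validating binary values.

    If ``ct`` is given, shape congruence is checked immediately.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise MaskError(f"expected a 2-D mask, got shape {data.shape}")
    mask = LungMask(data)
    if ct is not None:
        mask.check_congruent(ct)
    return mask
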