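"""Reading and writing slices, masks, curves and feature matrices.

Slices are NIfTI (int16 HU) or DICOM (rescale slope/intercept applied to
reach HU); masks are NIfTI uint8.  Quantification curves and feature
matrices round-trip through CSV.  All grids are row-major with origin
top-left and 0-based indices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import QuantCurve
from .segmentation import CTSlice, LungMask

MANIFEST_COLUMNS = ("patient_id", "slice_id", "score", "image_path", "mask_path")


def read_slice(
    path,
    patient_id: str,
    slice_id: str,
    slice_index: int = 0,
    pixel_spacing_mm: tuple[float, float] = (0.78, 0.78),
) -> CTSlice:
    """Read one 2-D HU slice from a NIfTI or DICOM file.

    Multi-slice NIfTI volumes are addressed by ``slice_index`` along the
    third axis.  DICOM pixel data is converted to HU via the stored rescale
    slope and intercept; non-integer HU after rescale are rounded with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
    else:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"cannot read a 2-D slice from shape {data.shape}")
        hu = np.asarray(data, dtype=np.float64)
    if np.any(hu != np.round(hu)):
        warnings.warn(f"{path.name}: non-integer HU after rescale; rounding")
        hu = np.round(hu)
    return CTSlice(
        hu=hu.astype(np.int16),
        patient_id=patient_id,
        slice_id=slice_id,
        pixel_spacing_mm=pixel_spacing_mm,
    )


def write_slice(ct: CTSlice, path) -> None:
    """Write a slice as int16 NIfTI."""
    img = nib.Nifti1Image(ct.hu.astype(np.int16), affine=np.eye(4))
    nib.save(img, str(path))


def write_mask(mask: LungMask, path) -> None:
    """Write a lung mask as uint8 NIfTI."""
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def write_curve(curve: QuantCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_curve(path) -> QuantCurve:
    return QuantCurve.from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_curves(curves, path) -> None:
    """Write many curves to one CSV (long format)."""
    pd.concat([c.to_frame() for c in curves]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_curves(path) -> list[QuantCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        QuantCurve.from_frame(g) for _, g in df.groupby("slice_id", sort=True)
    ]


def write_manifest(df: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return df
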