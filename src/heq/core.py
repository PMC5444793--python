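"""Threshold filtration of a masked CT slice: LAA% and Betti numbers.

For a threshold t, the low-attenuation area (LAA) is the set of lung pixels
with HU strictly below t.  As t rises the LAA sets are nested, forming a
filtration of the lung.  At each level we record:

- ``laa_pct``  : 100 x |LAA| / |lung|, the classic emphysema burden index;
- ``b0``       : number of connected LAA regions (zeroth Betti number);
- ``b1``       : number of normal-lung islands completely surrounded by LAA
  (first Betti number, i.e. holes of the LAA set);
- ``nb0, nb1`` : b0 and b1 divided by the lung pixel count, so slices with
  different lung areas are comparable.

Connectivity follows the standard dual pairing for binary images:
foreground (LAA) is 8-connected, background 4-connected.  With pixels read
as closed unit squares this pairing satisfies the Euler relation
chi = b0 - b1, which :func:`euler_characteristic` checks independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import CTSlice, LungMask

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

#: Plausible HU range for an LAA threshold (air floor to soft tissue).
THRESHOLD_RANGE_HU = (-1024, 500)


@dataclass(frozen=True)
class ThresholdGrid:
    """Evenly spaced HU thresholds over a half-open range [lower, upper).

    The half-open convention makes the canonical -1000..-700 HU sweep at
    5 HU steps contain exactly 60 levels.
    """

    lower_hu: int
    upper_hu: int
    step_hu: int = 5

    def __post_init__(self) -> None:
        if self.lower_hu >= self.upper_hu:
            raise ValueError("lower_hu must be < upper_hu")
        if self.step_hu <= 0:
            raise ValueError("step_hu must be positive")
        if (self.upper_hu - self.lower_hu) % self.step_hu:
            raise ValueError("range must be divisible by step_hu")

    @property
    def n_levels(self) -> int:
        return (self.upper_hu - self.lower_hu) // self.step_hu

    @property
    def levels(self) -> list[int]:
        return list(range(self.lower_hu, self.upper_hu, self.step_hu))


#: The study's full sweep: 60 levels from -1000 HU up to (excluding) -700 HU.
FULL_GRID = ThresholdGrid(-1000, -700, 5)


@dataclass(frozen=True)
class BinarizedSlice:
    """Partition of the lung at one threshold: normal lung vs LAA."""

    normal_lung: np.ndarray
    laa: np.ndarray
    threshold_hu: int

    def __post_init__(self) -> None:
        if self.normal_lung.shape != self.laa.shape:
            raise ValueError("grids must be congruent")
        if np.any(self.normal_lung & self.laa):
            raise ValueError("normal lung and LAA must be disjoint")


@dataclass(frozen=True)
class QuantRecord:
    """Quantification of one slice at one threshold."""

    threshold_hu: int
    laa_pct: float
    b0: int
    b1: int
    nb0: float
    nb1: float
    lung_pixels: int


@dataclass(frozen=True)
class QuantCurve:
    """Per-slice filtration profile: one record per threshold, ascending."""

    records: tuple[QuantRecord, ...]
    slice_id: str
    patient_id: str

    def __post_init__(self) -> None:
        ts = [r.threshold_hu for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def thresholds(self) -> list[int]:
        return [r.threshold_hu for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records])
        df["slice_id"] = self.slice_id
        df["patient_id"] = self.patient_id
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "QuantCurve":
        df = df.sort_values("threshold_hu")
        recs = tuple(
            QuantRecord(
                threshold_hu=int(r.threshold_hu),
                laa_pct=float(r.laa_pct),
                b0=int(r.b0),
                b1=int(r.b1),
                nb0=float(r.nb0),
                nb1=float(r.nb1),
                lung_pixels=int(r.lung_pixels),
            )
            for r in df.itertuples()
        )
        return cls(
            records=recs,
            slice_id=str(df["slice_id"].iloc[0]),
            patient_id=str(df["patient_id"].iloc[0]),
        )


def binarize(ct: CTSlice, mask: LungMask, threshold_hu: int) -> BinarizedSlice:
    """Split the lung into normal and low-attenuation pixels at a threshold.

    A lung pixel is LAA iff its HU is *strictly* below ``threshold_hu``;
    a pixel exactly at the threshold counts as normal lung.
    """
    mask.check_congruent(ct)
    lo, hi = THRESHOLD_RANGE_HU
    if not lo <= threshold_hu <= hi:
        raise ValueError(
            f"threshold {threshold_hu} HU outside plausible range [{lo}, {hi}]"
        )
    laa = mask.mask & (ct.hu < threshold_hu)
    return BinarizedSlice(
        normal_lung=mask.mask & ~laa, laa=laa, threshold_hu=threshold_hu
    )


def betti_numbers(laa: np.ndarray) -> tuple[int, int]:
    """Betti numbers of a binary image (foreground 8-connected).

    ``b0`` is the number of 8-connected foreground components.  ``b1`` is
    the number of 4-connected background components that touch no border
    pixel — the holes fully enclosed by foreground.
    """
    laa = np.asarray(laa, dtype=bool)
    if laa.ndim != 2:
        raise ValueError("expected a 2-D boolean grid")
    if laa.size == 0 or not laa.any():
        return 0, 0
    _, b0 = ndimage.label(laa, structure=_STRUCT8)
    holes, n_holes = ndimage.label(~laa, structure=_STRUCT4)
    border = np.unique(
        np.concatenate([holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]])
    )
    b1 = n_holes - np.count_nonzero(border)
    return int(b0), int(b1)


def euler_characteristic(laa: np.ndarray) -> int:
    """Euler characteristic of the cubical set spanned by the pixels.

    Each foreground pixel contributes a closed unit square; chi is counted
    as vertices - edges + faces of their union.  Independent of
    :func:`betti_numbers`, and equal to b0 - b1 under the 8/4 pairing.
    """
    laa = np.asarray(laa, dtype=bool)
    if laa.ndim != 2:
        raise ValueError("expected a 2-D boolean grid")
    if laa.size == 0:
        return 0
    p = np.zeros((laa.shape[0] + 2, laa.shape[1] + 2), dtype=bool)
    p[1:-1, 1:-1] = laa
    faces = int(laa.sum())
    # A lattice vertex exists iff any of its <=4 incident pixels is set.
    verts = int(
        (p[:-1, :-1] | p[:-1, 1:] | p[1:, :-1] | p[1:, 1:]).sum()
    )
    # A horizontal edge exists iff the pixel above or below is set;
    # vertical likewise for left/right.
    h_edges = int((p[:-1, 1:-1] | p[1:, 1:-1]).sum())
    v_edges = int((p[1:-1, :-1] | p[1:-1, 1:]).sum())
    return verts - h_edges - v_edges + faces


def quantify_slice(
    ct: CTSlice, mask: LungMask, thresholds: ThresholdGrid
) -> QuantCurve:
    """Run the full threshold sweep on one masked slice."""
    mask.check_congruent(ct)
    n_lung = mask.lung_pixel_count
    if n_lung == 0:
        raise ValueError("mask contains no lung pixels")
    records = []
    for t in thresholds.levels:
        b = binarize(ct, mask, t)
        n_laa = int(b.laa.sum())
        b0, b1 = betti_numbers(b.laa)
        records.append(
            QuantRecord(
                threshold_hu=t,
                laa_pct=100.0 * n_laa / n_lung,
                b0=b0,
                b1=b1,
                nb0=b0 / n_lung,
                nb1=b1 / n_lung,
                lung_pixels=n_lung,
            )
        )
    return QuantCurve(
        records=tuple(records), slice_id=ct.slice_id, patient_id=ct.patient_id
    )
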