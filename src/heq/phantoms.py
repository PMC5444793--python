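"""Synthetic chest-CT phantoms with ground-truth lung masks and topology.

Each phantom is a 2-D HU grid: air background, an elliptical body of soft
tissue, two elliptical lung fields of normal parenchyma, and low-attenuation
lesions inside the lungs.  Lesions are either solid disks (one LAA
component each) or annuli enclosing an island of normal lung (one component
plus one hole each), so the Betti numbers of the low-attenuation set are
known exactly for every threshold strictly between the lesion and lung HU.

A cohort emulates the structure of the kind of emphysema CT study this
package targets: a few dozen patients with a handful of slices each, an
ordinal visual score 0 (none) to 5 (very severe) per slice skewed toward
low scores, and a lesion burden that increases monotonically with score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _draw_disk

from .segmentation import CTSlice, LungMask


class PhantomPlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap."""


@dataclass(frozen=True)
class GroundTruthTopology:
    """Exact LAA topology for thresholds in (lesion_hu, lung_hu]."""

    laa_pixels: int
    b0: int
    b1: int
    lung_pixels: int


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU parameters of one phantom slice.

    HU defaults: body +40 (soft tissue), normal lung -780, lesions -980,
    outside air -1000.  ``ring_count`` annular lesions each enclose an
    island of normal lung.  ``noise_sd`` adds rounded Gaussian HU noise.
    """

    image_size: int = 256
    body_hu: int = 40
    lung_hu: int = -780
    lesion_hu: int = -980
    air_hu: int = -1000
    lesion_count: int = 0
    lesion_radius_px: int = 5
    ring_count: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lesion_hu < self.lung_hu < self.body_hu):
            raise ValueError("need lesion_hu < lung_hu < body_hu")
        if self.lesion_count < 0 or self.ring_count < 0:
            raise ValueError("lesion and ring counts must be >= 0")
        if self.lesion_radius_px < 1:
            raise ValueError("lesion radius must be >= 1 pixel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


_PLACEMENT_ATTEMPTS = 1000
#: Ring wall thickness (px) and clearance from the lung boundary (px).
_RING_WALL = 3
_MARGIN = 2


def _lung_fields(n: int) -> np.ndarray:
    """Two axis-aligned elliptical lung fields inside a body ellipse."""
    r, c = np.ogrid[:n, :n]
    cy = cx = n / 2
    lungs = np.zeros((n, n), dtype=bool)
    for side in (-1, 1):
        lcx = cx + side * 0.195 * n
        lungs |= ((r - cy) / (0.28 * n)) ** 2 + (
            (c - lcx) / (0.148 * n)
        ) ** 2 <= 1.0
    return lungs


def _body(n: int) -> np.ndarray:
    r, c = np.ogrid[:n, :n]
    cy = cx = n / 2
    return ((r - cy) / (0.39 * n)) ** 2 + ((c - cx) / (0.45 * n)) ** 2 <= 1.0


def _place_centers(
    dist: np.ndarray,
    radii: Sequence[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Rejection-sample lesion centers inside the eroded lung fields.

    ``dist`` is the distance transform of the lung mask; a lesion of
    radius r needs dist > r + margin at its center, and any two lesions
    keep a 2 px gap so they stay disjoint under 8-connectivity.
    """
    placed: list[tuple[int, int, int]] = []
    for i, r in enumerate(radii):
        cand = np.argwhere(dist > r + _MARGIN)
        if len(cand) == 0:
            raise PhantomPlacementError("no room for lesions inside the lungs")
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            y, x = cand[rng.integers(len(cand))]
            if all(
                (y - cy) ** 2 + (x - cx) ** 2 >= (r + cr + 2) ** 2
                for cy, cx, cr in placed
            ):
                placed.append((int(y), int(x), int(r)))
                break
        else:
            raise PhantomPlacementError(
                f"could not place lesion {i + 1} of {len(radii)} "
                f"after {_PLACEMENT_ATTEMPTS} attempts"
            )
    return [(y, x) for y, x, _ in placed]


def make_phantom(
    spec: PhantomSpec,
    patient_id: str = "P0",
    slice_id: str = "S0",
) -> tuple[CTSlice, LungMask, GroundTruthTopology]:
    """Render one phantom slice with its exact mask and LAA topology.

    The ground truth holds for any threshold t with lesion_hu < t <=
    lung_hu on a noise-free phantom: every lesion pixel is LAA, every other
    lung pixel is not, so b0 = lesion_count + ring_count and b1 =
    ring_count.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    lungs = _lung_fields(n)
    body = _body(n)

    hu = np.full((n, n), spec.air_hu, dtype=np.int16)
    hu[body] = spec.body_hu
    hu[lungs] = spec.lung_hu

    r_disk = spec.lesion_radius_px
    r_ring = spec.lesion_radius_px + _RING_WALL + 1

    lesions = np.zeros((n, n), dtype=bool)
    # Distance to the lung boundary keeps every lesion strictly interior.
    dist = ndimage.distance_transform_edt(lungs)
    radii = [r_ring] * spec.ring_count + [r_disk] * spec.lesion_count
    centers = _place_centers(dist, radii, rng)
    ring_centers = centers[: spec.ring_count]
    disk_centers = centers[spec.ring_count :]

    for y, x in disk_centers:
        rr, cc = _draw_disk((y, x), r_disk + 0.5, shape=(n, n))
        lesions[rr, cc] = True
    for y, x in ring_centers:
        rr, cc = _draw_disk((y, x), r_ring + 0.5, shape=(n, n))
        ring = np.zeros((n, n), dtype=bool)
        ring[rr, cc] = True
        rr, cc = _draw_disk((y, x), r_ring - _RING_WALL + 0.5, shape=(n, n))
        ring[rr, cc] = False
        lesions |= ring

    hu[lesions] = spec.lesion_hu
    if spec.noise_sd > 0:
        hu = (hu + rng.normal(0.0, spec.noise_sd, hu.shape)).round()
        hu = hu.astype(np.int16)

    truth = GroundTruthTopology(
        laa_pixels=int(lesions.sum()),
        b0=spec.lesion_count + spec.ring_count,
        b1=spec.ring_count,
        lung_pixels=int(lungs.sum()),
    )
    ct = CTSlice(hu=hu, patient_id=patient_id, slice_id=slice_id)
    return ct, LungMask(lungs), truth


def default_severity_to_score(lesion_count: int) -> int:
    """Monotone step map from lesion count to visual score 0-5."""
    return min(5, (lesion_count + 1) // 3)


def _score_lesions(score: int) -> int:
    """Central lesion count of a score band (inverse of the default map)."""
    return 0 if score == 0 else 3 * score


#: Default per-slice visual-score distribution, skewed toward low scores
#: as in the screening-type cohorts this generator emulates.
DEFAULT_SCORE_DISTRIBUTION: Mapping[int, float] = {
    0: 0.53,
    1: 0.23,
    2: 0.09,
    3: 0.10,
    4: 0.03,
    5: 0.02,
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: patients, slices per patient, score assignment."""

    n_patients: int = 39
    slices_per_patient: int = 3
    severity_to_score: Callable[[int], int] = default_severity_to_score
    score_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.slices_per_patient < 1:
            raise ValueError("need at least 1 slice per patient")
        if set(self.score_distribution) - set(range(6)):
            raise ValueError("scores must lie in 0..5")


@dataclass(frozen=True)
class CohortSlice:
    ct: CTSlice
    mask: LungMask
    truth: GroundTruthTopology
    score: int
    lesion_count: int


@dataclass(frozen=True)
class Cohort:
    slices: tuple[CohortSlice, ...]

    def __len__(self) -> int:
        return len(self.slices)

    def patient_ids(self) -> list[str]:
        return [s.ct.patient_id for s in self.slices]

    def scores(self) -> list[int]:
        return [s.score for s in self.slices]


def make_cohort(
    spec: CohortSpec, phantom_template: PhantomSpec
) -> Cohort:
    """Generate a full synthetic cohort, deterministic given the seeds.

    Each patient draws a severity (a visual score from the cohort score
    distribution, mapped to a central lesion count); each of the patient's
    slices jitters that lesion count by at most one, so all slices of one
    patient carry the same score band and patient grouping matters in
    grouped cross-validation.  Rings (annular lesions) appear at score >= 2
    so higher-grade slices carry nonzero b1.
    """
    rng = np.random.default_rng(spec.seed)
    scores = sorted(spec.score_distribution)
    probs = np.array([spec.score_distribution[s] for s in scores], float)
    probs /= probs.sum()

    out: list[CohortSlice] = []
    for p in range(spec.n_patients):
        patient_score = int(rng.choice(scores, p=probs))
        base = _score_lesions(patient_score)
        for k in range(spec.slices_per_patient):
            lesions = max(0, base + int(rng.integers(-1, 2)))
            rings = min(lesions, max(0, spec.severity_to_score(lesions) - 1))
            pspec = PhantomSpec(
                image_size=phantom_template.image_size,
                body_hu=phantom_template.body_hu,
                lung_hu=phantom_template.lung_hu,
                lesion_hu=phantom_template.lesion_hu,
                air_hu=phantom_template.air_hu,
                lesion_count=lesions - rings,
                lesion_radius_px=phantom_template.lesion_radius_px,
                ring_count=rings,
                noise_sd=phantom_template.noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            ct, mask, truth = make_phantom(
                pspec, patient_id=f"P{p:03d}", slice_id=f"P{p:03d}_S{k}"
            )
            out.append(
                CohortSlice(
                    ct=ct,
                    mask=mask,
                    truth=truth,
                    score=spec.severity_to_score(lesions),
                    lesion_count=lesions,
                )
            )
    return Cohort(slices=tuple(out))
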