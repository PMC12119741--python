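"""Lesion VOIs and quantitative PET metrics (SUV, CNR, liver COV).

The delineation protocol mirrors clinical practice for comparing two
reconstructions of the same scan fairly:

* lesions are segmented on the range-corrected image with a 50% isocontour of
  the regional maximum (no background correction), keeping the 26-connected
  component that contains the maximum voxel;
* the *same* VOI (identical voxel set) is mapped onto the non-corrected image,
  so metric differences reflect the reconstruction, not re-segmentation;
* per tissue type at most the 5 largest lesions per patient enter the
  analysis; lesions are classed small (<= 1 cm³), medium (1-10 cm³] or
  large (> 10 cm³);
* each lesion gets a same-tissue background shell VOI of >= 10 cm³ starting
  ~5 mm outside the lesion border;
* image noise is the coefficient of variation (COV = SD/mean · 100%) in a
  10 mm-radius sphere in a homogeneous, lesion-free part of the liver.

Metrics: SUVmax, SUVmean, SUVpeak (highest-mean 1 mL sphere), and
CNR = (lesion mean − background mean) / background SD.  Standard deviations
are sample SDs (n−1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import VoxelGrid, lesion_radius

__all__ = [
    "VOI",
    "delineate_isocontour",
    "map_voi",
    "classify_size",
    "select_lesions",
    "background_voi",
    "suv_stats",
    "cnr",
    "cov",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VOI:
    mask: np.ndarray  # boolean volume
    grid: VoxelGrid
    label: str = "lesion"  # 'lesion' | 'background' | 'liver_noise'

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 3:
            raise ValueError("VOI mask must be a 3-D boolean volume")
        if not self.mask.any():
            raise ValueError("VOI is empty")
        if self.mask.shape != self.grid.shape:
            raise ValueError("VOI mask shape does not match its grid")

    @property
    def volume(self) -> float:
        """VOI volume in cm³ (voxel count × voxel volume)."""
        return float(self.mask.sum()) * self.grid.voxel_volume_ml


def delineate_isocontour(image: np.ndarray, search_region: VOI,
                         threshold: float = 0.5) -> VOI:
    """50% isocontour VOI within a search region, no background correction.

    Keeps the 26-connected component of {value >= threshold × regional max}
    that contains the maximum voxel.
    """
    region = search_region.mask
    vals = np.where(region, image, -np.inf)
    mx = vals.max()
    if not np.isfinite(mx) or mx <= 0:
        raise ValueError("search region is empty or has no positive uptake")
    above = region & (image >= threshold * mx)
    comp, _ = ndimage.label(above, structure=_CONN26)
    max_idx = np.unravel_index(np.argmax(vals), vals.shape)
    return VOI(mask=comp == comp[max_idx], grid=search_region.grid, label="lesion")


def map_voi(voi: VOI, target_grid: VoxelGrid) -> VOI:
    """Reuse a VOI's voxel set on another reconstruction of the same grid."""
    if target_grid.shape != voi.grid.shape or not np.allclose(
            target_grid.spacing, voi.grid.spacing):
        raise ValueError("VOI can only be mapped between images on the same grid")
    return VOI(mask=voi.mask.copy(), grid=target_grid, label=voi.label)


def classify_size(volume_cm3: float) -> str:
    """Size class: small (<= 1 cm³), medium (1, 10] cm³, large (> 10 cm³)."""
    if volume_cm3 <= 0:
        raise ValueError("lesion volume must be positive")
    if volume_cm3 <= 1.0:
        return "small"
    if volume_cm3 <= 10.0:
        return "medium"
    return "large"


def select_lesions(records: list, max_per_tissue: int = 5) -> list:
    """Keep at most the N largest lesions per tissue type for one patient.

    ``records`` are objects with ``tissue``, ``volume`` and ``suv_max``
    attributes (or mappings with those keys).  Ties in volume are broken by
    higher SUVmax, then by lower original index.
    """
    def get(r, k):
        return r[k] if isinstance(r, dict) else getattr(r, k)

    by_tissue: dict[str, list[tuple[float, float, int]]] = {}
    for i, r in enumerate(records):
        by_tissue.setdefault(get(r, "tissue"), []).append(
            (-float(get(r, "volume")), -float(get(r, "suv_max")), i))
    keep: set[int] = set()
    for entries in by_tissue.values():
        for _, _, i in sorted(entries)[:max_per_tissue]:
            keep.add(i)
    return [r for i, r in enumerate(records) if i in keep]


def background_voi(lesion_voi: VOI, labels: np.ndarray, host_label: int,
                   lesion_label_base: int = 10,
                   min_volume_cm3: float = 10.0, offset_mm: float = 5.0) -> VOI:
    """Same-tissue background shell around a lesion.

    Takes host-tissue voxels (excluding all lesion labels) whose distance from
    the lesion border is at least ``offset_mm``, and grows the shell outward
    (nearest voxels first) until it reaches ``min_volume_cm3``.
    """
    grid = lesion_voi.grid
    dist = ndimage.distance_transform_edt(~lesion_voi.mask, sampling=grid.spacing)
    eligible = (labels == host_label) & (labels < lesion_label_base) & (dist >= offset_mm)
    n_needed = int(np.ceil(min_volume_cm3 / grid.voxel_volume_ml))
    if eligible.sum() < n_needed:
        achieved = eligible.sum() * grid.voxel_volume_ml
        raise ValueError(
            f"host tissue too small for background VOI: {achieved:.1f} cm³ "
            f"available, {min_volume_cm3:.1f} cm³ required")
    d_sel = np.where(eligible, dist, np.inf)
    cutoff = np.partition(d_sel.ravel(), n_needed - 1)[n_needed - 1]
    mask = eligible & (d_sel <= cutoff)
    return VOI(mask=mask, grid=grid, label="background")


def suv_stats(image_suv: np.ndarray, voi: VOI,
              peak_sphere_ml: float = 1.0) -> dict[str, float]:
    """SUVmax, SUVmean and SUVpeak over a VOI.

    SUVpeak is the highest mean over 1 mL spheres centered at VOI voxel
    centers; sphere membership is voxel-center-in-sphere and spheres may
    extend beyond the VOI (voxels outside the image grid are excluded from
    the sphere mean).
    """
    vals = image_suv[voi.mask]
    if vals.size == 0:
        raise ValueError("empty VOI")
    r = lesion_radius(peak_sphere_ml)
    sp = voi.grid.spacing
    half = [int(np.floor(r / s)) for s in sp]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, sp)]
    foot = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2) <= r * r
    foot = foot.astype(float)
    # sphere means with in-grid renormalization at the image border
    num = ndimage.convolve(image_suv, foot, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(image_suv), foot, mode="constant", cval=0.0)
    peak = float((num / den)[voi.mask].max())
    return {"suv_max": float(vals.max()), "suv_mean": float(vals.mean()),
            "suv_peak": peak}


def cnr(image: np.ndarray, lesion_voi: VOI, background_voi_: VOI) -> float:
    """Contrast-to-noise ratio (lesion mean − background mean) / background SD."""
    lesion = image[lesion_voi.mask]
    bg = image[background_voi_.mask]
    if lesion.size == 0 or bg.size == 0:
        raise ValueError("empty VOI")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ZeroDivisionError("background SD is zero; CNR undefined")
    return float((lesion.mean() - bg.mean()) / sd)


def cov(image: np.ndarray, liver_mask: np.ndarray) -> float:
    """Liver noise level: COV = SD/mean · 100% over the liver noise sphere."""
    vals = image[liver_mask]
    if vals.size == 0:
        raise ValueError("empty liver VOI")
    mean = float(vals.mean())
    if mean == 0:
        raise ZeroDivisionError("liver mean is zero; COV undefined")
    return float(vals.std(ddof=1) / mean * 100.0)
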