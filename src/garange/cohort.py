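"""Synthetic digital patients for the in-silico Ga-68 PET study.

Real whole-body PET data for this kind of study cannot be redistributed, so
the cohort generator builds stylized but quantitatively meaningful digital
patients: a soft-tissue body ellipsoid truncated by the axial field of view,
containing a high-uptake liver, a low-density lung region, a dense bone
structure, and spherical lesions placed in soft tissue, bone or lung.  Dosing
follows the clinical protocol the study emulates (1.5 MBq/kg, body weights
drawn from 51-118 kg), so voxel activity concentrations carry real SUV
meaning: activity [kBq/mL] = SUV × injected activity [kBq] / weight [g]
(assuming 1 g/mL tissue).

Arrays are indexed (x, y, z); the slice (axial) axis is the last one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "PatientMeta",
    "LesionSpec",
    "DigitalPatient",
    "CohortConfig",
    "LesionPlanEntry",
    "LABELS",
    "lesion_radius",
    "build_patient",
    "build_cohort",
    "default_lesion_plan",
    "activity_from_suv",
    "suv_from_activity",
]

#: integer codes of the tissue-label volume; lesion k gets LESION_BASE + k.
LABELS = {"air": 0, "soft": 1, "liver": 2, "lung": 3, "bone": 4}
LESION_BASE = 10

#: 511 keV linear attenuation of water, 1/mm
MU_WATER = 0.0096
#: mass density relative to water per tissue (used to scale attenuation)
DENSITY = {"air": 0.0, "soft": 1.0, "liver": 1.05, "lung": 0.3, "bone": 1.9}
#: background uptake (SUV) per tissue
SUV_LEVELS = {"air": 0.0, "soft": 1.0, "liver": 5.0, "lung": 0.3, "bone": 0.5}


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside its host tissue."""


@dataclass(frozen=True)
class VoxelGrid:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.73, 2.73, 2.80)  # mm
    origin: tuple[float, float, float] | None = None  # center of voxel (0,0,0)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacings must be positive")
        if self.origin is None:
            # default: grid centered on the physical origin
            o = tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))
            object.__setattr__(self, "origin", o)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm³)."""
        return float(np.prod(self.spacing)) / 1000.0

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates (mm) along each axis."""
        return tuple(self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                     for a in range(3))

    def half_extent(self) -> tuple[float, float, float]:
        return tuple(n * s / 2.0 for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    weight: float  # kg
    injected_activity: float  # MBq
    seed: int


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float, float]  # mm
    volume: float  # cm³
    tissue: str  # 'soft' | 'bone' | 'lung'
    uptake: float  # SUV


@dataclass
class DigitalPatient:
    grid: VoxelGrid
    activity: np.ndarray  # kBq/mL
    mu_map: np.ndarray  # 1/mm at 511 keV
    labels: np.ndarray  # int codes, lesions at LESION_BASE + k
    lesions: list[LesionSpec]
    meta: PatientMeta

    @property
    def suv(self) -> np.ndarray:
        """The activity volume converted back to SUV units."""
        return suv_from_activity(self.activity, self.meta)

    def lesion_mask(self, k: int) -> np.ndarray:
        return self.labels == LESION_BASE + k


@dataclass(frozen=True)
class LesionPlanEntry:
    tissue: str
    volume: float | None = None  # cm³; None -> sampled from the size class
    size_class: str | None = None  # 'small' | 'medium' | 'large'
    uptake: float | None = None  # SUV; None -> sampled


#: volume sampling windows (cm³) per size class.  The large window is sized
#: so that lesions remain in the large class (> 10 cm³) after 50% isocontour
#: delineation, which shrinks a sphere's measured volume by roughly one voxel
#: shell; only the lung region of the stylized torso has that much room.
SIZE_CLASS_VOLUMES = {"small": (0.3, 1.0), "medium": (2.0, 6.0), "large": (20.0, 26.0)}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 10
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((64, 64, 16)))
    weight_range: tuple[float, float] = (51.0, 118.0)  # kg
    dose_per_kg: float = 1.5  # MBq/kg
    suv_levels: dict = field(default_factory=lambda: dict(SUV_LEVELS))
    lesion_suv_range: tuple[float, float] = (4.0, 20.0)
    lesion_plan: tuple[LesionPlanEntry, ...] | None = None  # None -> per-patient default
    placement_margin_mm: float = 1.5  # clearance beyond the lesion radius
    max_placement_tries: int = 200


def lesion_radius(volume_cm3: float) -> float:
    """Radius (mm) of the sphere of the given volume (cm³): r = (3V/4π)^(1/3)."""
    if volume_cm3 <= 0:
        raise ValueError("lesion volume must be positive")
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def activity_from_suv(suv: np.ndarray, meta: PatientMeta) -> np.ndarray:
    """kBq/mL from SUV: SUV × injected[kBq] / weight[g], 1 g/mL tissue."""
    return suv * (meta.injected_activity * 1000.0) / (meta.weight * 1000.0)


def suv_from_activity(activity: np.ndarray, meta: PatientMeta) -> np.ndarray:
    return activity * (meta.weight * 1000.0) / (meta.injected_activity * 1000.0)


def _ellipsoid_mask(grid: VoxelGrid, center: tuple[float, float, float],
                    semi_axes: tuple[float, float, float]) -> np.ndarray:
    x, y, z = grid.coordinate_axes()
    dx = (x - center[0]) / semi_axes[0]
    dy = (y - center[1]) / semi_axes[1]
    dz = (z - center[2]) / semi_axes[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def _sphere_mask(grid: VoxelGrid, center: tuple[float, float, float],
                 radius: float) -> np.ndarray:
    # single-slice (2D) mode: lesions are disks through the slice
    rz = radius if grid.shape[2] > 1 else np.inf
    return _ellipsoid_mask(grid, center, (radius, radius, rz))


def _anatomy_labels(grid: VoxelGrid) -> np.ndarray:
    """Stylized torso: body ellipsoid with liver, lung and bone sub-regions.

    Proportions are expressed in fractions of the field of view so the same
    anatomy scales to small test grids; the body's axial semi-axis exceeds
    the grid (truncated whole-body ellipsoid), so every slice holds tissue.
    """
    hx, hy, hz = grid.half_extent()
    labels = np.zeros(grid.shape, dtype=np.int16)
    body = _ellipsoid_mask(grid, (0, 0, 0), (0.88 * hx, 0.66 * hy, 1.8 * hz))
    labels[body] = LABELS["soft"]
    liver = _ellipsoid_mask(grid, (-0.40 * hx, 0.0, 0.0),
                            (0.36 * hx, 0.40 * hy, 1.6 * hz))
    labels[body & liver] = LABELS["liver"]
    lung = _ellipsoid_mask(grid, (0.40 * hx, 0.0, 0.0),
                           (0.32 * hx, 0.38 * hy, 1.6 * hz))
    labels[body & lung] = LABELS["lung"]
    bone = _ellipsoid_mask(grid, (0.0, -0.44 * hy, 0.0),
                           (0.20 * hx, 0.20 * hy, 1.6 * hz))
    labels[body & bone] = LABELS["bone"]
    return labels


def default_lesion_plan(patient_index: int) -> tuple[LesionPlanEntry, ...]:
    """Three lesions per patient cycling through tissues and size classes.

    Soft tissue and bone alternate small/medium; every third patient carries
    a large lung lesion (only the lung region of the stylized torso can host
    a lesion that stays above 10 cm³ after isocontour delineation together
    with a >= 10 cm³ same-tissue background shell).  Large lesions are the
    rarest class, as in clinical cohorts.
    """
    i = patient_index
    lung_size = "large" if i % 3 == 2 else ("medium", "small")[i % 2]
    return (
        LesionPlanEntry("soft", size_class=("small", "medium")[i % 2]),
        LesionPlanEntry("bone", size_class=("medium", "small")[i % 2]),
        LesionPlanEntry("lung", size_class=lung_size),
    )


def _place_lesion(grid: VoxelGrid, host_mask: np.ndarray, radius: float,
                  margin: float, rng: np.random.Generator,
                  max_tries: int, name: str) -> tuple[float, float, float]:
    """Pick a voxel center such that a sphere of ``radius`` fits in the host.

    Feasibility uses the Euclidean distance transform of the host mask padded
    by one background voxel, so the sphere also stays inside the grid.
    """
    # pad with background so the distance transform respects the grid border;
    # in single-slice (2D) mode the axial direction is unconstrained
    pad = (1, 1, 1 if host_mask.shape[2] > 1 else 0)
    padded = np.pad(host_mask, [(p, p) for p in pad], constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=grid.spacing)
    dist = dist[1:-1, 1:-1, slice(1, -1) if pad[2] else slice(None)]
    feasible = np.argwhere(dist >= radius + margin)
    if feasible.size == 0:
        raise LesionPlacementError(
            f"lesion {name!r} (radius {radius:.1f} mm) does not fit inside its "
            f"host tissue")
    # bounded random choice among feasible voxel centers
    for _ in range(max_tries):
        idx = feasible[rng.integers(len(feasible))]
        return tuple(grid.origin[a] + grid.spacing[a] * idx[a] for a in range(3))
    raise LesionPlacementError(f"placement retries exhausted for lesion {name!r}")


def build_patient(config: CohortConfig, seed: int,
                  patient_index: int = 0) -> DigitalPatient:
    """Build one seeded digital patient.

    Deterministic: identical (config, seed, patient_index) gives bit-identical
    volumes.  Raises :class:`LesionPlacementError` naming the lesion when a
    requested lesion cannot fit inside its host tissue.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid
    weight = float(rng.uniform(*config.weight_range))
    meta = PatientMeta(patient_id=f"P{patient_index:03d}", weight=weight,
                       injected_activity=config.dose_per_kg * weight, seed=seed)

    labels = _anatomy_labels(grid)
    plan = (config.lesion_plan if config.lesion_plan is not None
            else default_lesion_plan(patient_index))

    lesions: list[LesionSpec] = []
    occupied = np.zeros(grid.shape, dtype=bool)
    for k, entry in enumerate(plan):
        if entry.tissue not in ("soft", "bone", "lung"):
            raise ValueError(f"unsupported lesion tissue {entry.tissue!r}")
        if entry.volume is not None:
            volume = float(entry.volume)
        else:
            lo, hi = SIZE_CLASS_VOLUMES[entry.size_class or "small"]
            volume = float(rng.uniform(lo, hi))
        uptake = (float(entry.uptake) if entry.uptake is not None
                  else float(rng.uniform(*config.lesion_suv_range)))
        radius = lesion_radius(volume)
        host = (labels == LABELS[entry.tissue]) & ~occupied
        center = _place_lesion(grid, host, radius, config.placement_margin_mm,
                               rng, config.max_placement_tries,
                               name=f"{meta.patient_id}/lesion{k}:{entry.tissue}")
        mask = _sphere_mask(grid, center, radius)
        labels[mask] = LESION_BASE + k
        # keep later lesions clear of this one (2-voxel guard band)
        guard = _sphere_mask(grid, center, radius + 2.0 * max(grid.spacing))
        occupied |= guard
        lesions.append(LesionSpec(center=center, volume=volume,
                                  tissue=entry.tissue, uptake=uptake))

    suv = np.zeros(grid.shape, dtype=float)
    density = np.zeros(grid.shape, dtype=float)
    for name, code in LABELS.items():
        sel = labels == code
        suv[sel] = config.suv_levels.get(name, 0.0)
        density[sel] = DENSITY[name]
    for k, les in enumerate(lesions):
        sel = labels == LESION_BASE + k
        suv[sel] = les.uptake
        density[sel] = DENSITY[les.tissue]

    activity = activity_from_suv(suv, meta)
    mu_map = MU_WATER * density
    return DigitalPatient(grid=grid, activity=activity, mu_map=mu_map,
                          labels=labels, lesions=lesions, meta=meta)


def build_cohort(config: CohortConfig, base_seed: int) -> list[DigitalPatient]:
    """Build ``config.n_patients`` patients with per-patient seeds base_seed+i."""
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return [build_patient(config, seed=base_seed + i, patient_index=i)
            for i in range(config.n_patients)]


def liver_noise_sphere(patient: DigitalPatient, radius_mm: float = 10.0) -> np.ndarray:
    """Mask of the liver noise-measurement sphere (10 mm radius by default).

    Centered at the deepest point (largest inscribed sphere) of the lesion-free
    liver label: deterministic and guaranteed to exclude and stay away from
    lesions.
    """
    liver = patient.labels == LABELS["liver"]
    if not liver.any():
        raise ValueError("patient has no liver region")
    padded = np.pad(liver, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=patient.grid.spacing)
    dist = dist[1:-1, 1:-1, 1:-1]
    idx = np.unravel_index(np.argmax(dist), dist.shape)
    if dist[idx] < radius_mm:
        raise ValueError("liver region cannot contain the noise sphere")
    center = tuple(patient.grid.origin[a] + patient.grid.spacing[a] * idx[a]
                   for a in range(3))
    return _sphere_mask(patient.grid, center, radius_mm)
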