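"""Positron-range kernels for PET resolution modelling.

A positron emitted by a beta-plus decay travels a few millimetres in tissue
before annihilating; the annihilation point, not the emission point, is what
the scanner sees.  This module generates the tissue-independent (water)
annihilation-displacement kernel for a radionuclide by Monte-Carlo:

1. sample positron kinetic energies from the allowed Fermi beta-plus spectrum,
2. convert each energy to a continuous-slowing-down (CSDA) path length in
   water with the empirical Katz-Penfold range-energy formula,
3. scale the path length by a detour factor (positron tracks are tortuous, so
   the net 3D displacement is shorter than the path length) and draw an
   isotropic direction,
4. histogram the displacement vectors onto the reconstruction voxel grid,
   symmetrize, and normalize to unit sum.

The resulting :class:`RangeKernel` is used as an image-space convolution
inside the forward/backward model of iterative reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetaSpectrum",
    "RangeKernel",
    "NUCLIDES",
    "fermi_factor",
    "allowed_spectrum",
    "default_spectrum",
    "sample_energies",
    "csda_range",
    "sample_displacements",
    "build_kernel",
    "delta_kernel",
    "make_kernel",
]

_MEC2_KEV = 511.0  # electron rest energy
_ALPHA = 1.0 / 137.035999084  # fine-structure constant

#: endpoint (maximum) beta+ energy in keV and atomic number of the *daughter*
#: nucleus for the supported radionuclides.
NUCLIDES: dict[str, tuple[float, int]] = {
    "Ga-68": (1899.0, 30),  # -> Zn-68
    "F-18": (635.0, 8),  # -> O-18
}


@dataclass(frozen=True)
class BetaSpectrum:
    """Tabulated beta-plus kinetic-energy spectrum of one radionuclide.

    ``energies`` (keV) and ``intensities`` (relative, unnormalized) define the
    emission density; intensity is zero at 0 and at the endpoint.
    """

    radionuclide: str
    endpoint_energy: float  # keV
    daughter_Z: int
    energies: np.ndarray = field(repr=False)
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.intensities, dtype=float)
        if self.endpoint_energy <= 0:
            raise ValueError("endpoint energy must be positive")
        if e.shape != w.shape or e.ndim != 1 or e.size < 2:
            raise ValueError("spectrum grid must be two matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("spectrum intensities must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", w)

    @property
    def mean_energy(self) -> float:
        """Mean emission energy (keV) of the tabulated density."""
        return float(np.trapezoid(self.intensities * self.energies, self.energies)
                     / np.trapezoid(self.intensities, self.energies))


@dataclass(frozen=True)
class RangeKernel:
    """Voxelized, unit-sum, centrally symmetric annihilation-displacement kernel."""

    radionuclide: str
    spacing: tuple[float, float, float]  # mm
    values: np.ndarray = field(repr=False)
    mean_range: float = 0.0  # mm, mean 3D displacement of the generating sample
    n_samples: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or any(s % 2 == 0 for s in v.shape):
            raise ValueError("kernel must be 3-D with odd extent per axis")
        if np.any(v < 0):
            raise ValueError("kernel values must be non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("kernel must sum to 1 within 1e-9")
        object.__setattr__(self, "values", v)

    @property
    def is_delta(self) -> bool:
        return self.values.shape == (1, 1, 1)


def fermi_factor(Z: int, energy_kev: np.ndarray) -> np.ndarray:
    """Nonrelativistic positron Fermi/Coulomb factor F(Z, E).

    F = 2*pi*eta / (1 - exp(-2*pi*eta)) with eta = -Z*alpha/beta (repulsive
    for positrons, so slow positrons are suppressed).
    """
    e = np.asarray(energy_kev, dtype=float)
    etot = e + _MEC2_KEV
    gamma = etot / _MEC2_KEV
    beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-30, None))
    x = 2.0 * np.pi * (-Z * _ALPHA / beta)
    # as beta -> 0, x -> -inf and F -> -x*exp(x) -> 0; clamp to avoid overflow
    f = np.where(x < -50.0, 0.0, x / (1.0 - np.exp(np.minimum(-x, 60.0))))
    return f


def allowed_spectrum(energy_kev: np.ndarray, endpoint_kev: float, daughter_Z: int) -> np.ndarray:
    """Allowed-transition beta+ shape N(E) ∝ F(Z,E)·p·E_tot·(Emax−E)²."""
    e = np.asarray(energy_kev, dtype=float)
    etot = e + _MEC2_KEV
    p = np.sqrt(np.clip(etot**2 - _MEC2_KEV**2, 0.0, None))
    n = fermi_factor(daughter_Z, e) * p * etot * np.clip(endpoint_kev - e, 0.0, None) ** 2
    return np.where((e <= 0) | (e >= endpoint_kev), 0.0, n)


def default_spectrum(radionuclide: str, n_grid: int = 4096) -> BetaSpectrum:
    """Tabulated allowed Fermi spectrum for a supported radionuclide."""
    try:
        emax, z = NUCLIDES[radionuclide]
    except KeyError:
        raise ValueError(f"unknown radionuclide {radionuclide!r}; "
                         f"known: {sorted(NUCLIDES)}") from None
    e = np.linspace(0.0, emax, n_grid)
    return BetaSpectrum(radionuclide, emax, z, e, allowed_spectrum(e, emax, z))


def sample_energies(spectrum: BetaSpectrum, n: int, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` positron energies (keV) by inverse-CDF from the tabulation."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    e, w = spectrum.energies, spectrum.intensities
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum has zero total intensity")
    if np.count_nonzero(w) == 1:
        # degenerate single-line spectrum
        return np.full(n, e[np.argmax(w)], dtype=float)
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, e)


# Katz-Penfold validity floor; below it the range is linearly interpolated to 0.
_KP_EMIN_MEV = 0.01


def csda_range(energy_kev: float | np.ndarray) -> np.ndarray:
    """CSDA path length (mm) of an electron/positron in water.

    Katz-Penfold empirical formula R[g/cm²] = 0.412·E^(1.265−0.0954·ln E)
    (E in MeV), divided by water density 1 g/cm³.  Monotone increasing, 0 at 0.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be non-negative")
    e_mev = e / 1000.0
    ec = np.maximum(e_mev, _KP_EMIN_MEV)
    r = 0.412 * ec ** (1.265 - 0.0954 * np.log(ec))
    # linear ramp below the formula's validity floor keeps R(0)=0 and monotone
    r = np.where(e_mev < _KP_EMIN_MEV, r * e_mev / _KP_EMIN_MEV, r)
    return r * 10.0  # g/cm² at unit density -> cm -> mm


def sample_displacements(spectrum: BetaSpectrum, n: int,
                         detour_factor: float = 0.65,
                         seed: int | None = None) -> np.ndarray:
    """Monte-Carlo annihilation displacement vectors (n × 3, mm) in water.

    Each sampled energy is converted to a CSDA path length, scaled by the
    detour factor (net displacement / path length), and given an isotropic
    direction.
    """
    if not 0.0 < detour_factor <= 1.0:
        raise ValueError("detour_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    # child streams keep the energy draw and the direction draw independent
    e_seed, d_seed = rng.integers(0, 2**31 - 1, size=2)
    energies = sample_energies(spectrum, n, seed=int(e_seed))
    radii = detour_factor * csda_range(energies)
    drng = np.random.default_rng(int(d_seed))
    cos_t = drng.uniform(-1.0, 1.0, n)
    phi = drng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    dirs = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    return radii[:, None] * dirs


def build_kernel(displacements: np.ndarray,
                 spacing: tuple[float, float, float],
                 truncation_radius: float = 10.0,
                 radionuclide: str = "",
                 n_samples: int | None = None,
                 seed: int | None = None) -> RangeKernel:
    """Histogram displacement vectors into a unit-sum symmetric voxel kernel.

    The kernel is centered at the origin with half-extent
    ``ceil(truncation_radius / spacing)`` voxels per axis, symmetrized by
    averaging with its point reflection, and normalized to sum 1.  A warning
    is logged if the truncation covers < 99.9% of the displacement mass.
    """
    d = np.asarray(displacements, dtype=float)
    if d.size == 0:
        raise ValueError("displacement list is empty")
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("displacements must be an (n, 3) array")
    sp = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in sp):
        raise ValueError("spacing must be positive")
    half = [int(np.ceil(truncation_radius / s)) for s in sp]
    mags = np.linalg.norm(d, axis=1)
    covered = np.mean(mags <= truncation_radius)
    if covered < 0.999:
        warnings.warn(
            f"kernel truncation radius {truncation_radius} mm covers only "
            f"{100 * covered:.2f}% of displacements", stacklevel=2)
    edges = [np.arange(-h - 0.5, h + 1.5) * s for h, s in zip(half, sp)]
    hist, _ = np.histogramdd(d, bins=edges)
    sym = 0.5 * (hist + hist[::-1, ::-1, ::-1])
    total = sym.sum()
    if total <= 0:
        raise ValueError("no displacements fall inside the truncation radius")
    return RangeKernel(
        radionuclide=radionuclide,
        spacing=sp,
        values=sym / total,
        mean_range=float(mags.mean()),
        n_samples=len(d) if n_samples is None else n_samples,
        seed=seed,
    )


def delta_kernel(spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> RangeKernel:
    """The 1×1×1 identity kernel (the "no range modelling" element)."""
    return RangeKernel(radionuclide="delta", spacing=tuple(float(s) for s in spacing),
                       values=np.ones((1, 1, 1)), mean_range=0.0, n_samples=0)


def make_kernel(radionuclide: str,
                spacing: tuple[float, float, float],
                n_samples: int = 1_000_000,
                detour_factor: float = 0.65,
                truncation_radius: float = 10.0,
                seed: int | None = None) -> RangeKernel:
    """End-to-end kernel generation for a supported radionuclide."""
    spec = default_spectrum(radionuclide)
    disp = sample_displacements(spec, n_samples, detour_factor=detour_factor, seed=seed)
    return build_kernel(disp, spacing, truncation_radius=truncation_radius,
                        radionuclide=radionuclide, n_samples=n_samples, seed=seed)
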