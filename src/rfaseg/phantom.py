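"""Synthetic CT-like phantoms with a known ablation-zone ground truth.

A phantom is a piecewise-constant volume — a dark ellipsoidal lesion (the
ablation zone) in a brighter background, optionally wrapped in a thin
hyper-enhancing rim and pierced by a bright umbrella-shaped needle (a
cylindrical shaft entering the lesion plus tines fanning out from a hub) —
plus seeded Gaussian noise.  Intensities are abstract HU-like units
(defaults: lesion 40, background 110, rim 160, needle 1000); no scanner
physics is simulated.

The ground-truth mask is the lesion ellipsoid; needle voxels are excluded
from the truth and the rim is excluded by default (it can be included to
study the over-segmentation that a rim-adapting boundary produces).

:func:`paper_case_suite` draws reproducible case collections whose lesion
volumes (~6–123 cm³), in-plane spacing (0.679–0.777 mm), slice spacing
(1–3 mm) and needle prevalence (half the cases) emulate routine
post-interventional RFA acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import PhantomSpecError
from .volume import ImageVolume, SegmentationMask

__all__ = ["NeedleSpec", "PhantomSpec", "generate_phantom", "paper_case_suite"]


@dataclass
class NeedleSpec:
    """Umbrella RFA electrode: shaft from entry point to a hub plus tines."""

    entry_point: tuple[float, float, float]  # world mm
    hub: tuple[float, float, float]  # world mm, tine origin (in the lesion)
    shaft_radius_mm: float = 1.2
    tine_count: int = 8
    tine_length_mm: float = 12.0
    tine_radius_mm: float = 0.6
    tine_angle_deg: float = 55.0  # opening angle of the umbrella
    intensity: float = 1000.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic volume (serializable to YAML)."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (0.7, 0.7, 2.0)
    background: float = 110.0
    lesion_center: tuple[float, float, float] | None = None  # world mm
    lesion_radii: tuple[float, float, float] = (15.0, 15.0, 15.0)
    lesion_intensity: float = 40.0
    rim_thickness_mm: float = 0.0  # 0 disables the rim
    rim_intensity: float = 160.0
    needle: NeedleSpec | None = None
    noise_sigma: float = 0.0
    rng_seed: int = 0
    bump_amplitude: float = 0.0  # relative radial perturbation (non-sphericity)
    rim_in_truth: bool = False

    def __post_init__(self) -> None:
        if self.lesion_center is None:
            self.lesion_center = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
            )
        if not self.lesion_intensity < self.background:
            raise PhantomSpecError(
                "intensity ordering violated: lesion must be darker than background"
            )
        if self.rim_thickness_mm > 0 and not self.background < self.rim_intensity:
            raise PhantomSpecError(
                "intensity ordering violated: rim must be brighter than background"
            )
        if self.needle is not None:
            top = self.rim_intensity if self.rim_thickness_mm > 0 else self.background
            if not top < self.needle.intensity:
                raise PhantomSpecError(
                    "intensity ordering violated: needle must be brightest"
                )
        extent_lo = np.asarray(self.lesion_center) - np.asarray(self.lesion_radii)
        extent_hi = np.asarray(self.lesion_center) + np.asarray(self.lesion_radii)
        grid_hi = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        if np.any(extent_lo < 0) or np.any(extent_hi > grid_hi):
            raise PhantomSpecError("lesion does not fit inside the grid")


def _ellipsoid_mask(coords, center, radii, bump_amplitude=0.0, rng_seed=0):
    """Boolean ellipsoid; optional smooth radial bump for non-sphericity."""
    X, Y, Z = coords
    d = np.stack(
        [
            (X - center[0]) / radii[0],
            (Y - center[1]) / radii[1],
            (Z - center[2]) / radii[2],
        ]
    )
    rho = np.sqrt((d**2).sum(axis=0))
    if bump_amplitude:
        # low-order spherical perturbation, deterministic in the seed
        rng = np.random.default_rng(rng_seed)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arctan2(d[1], d[0])
            cosphi = np.where(rho > 0, d[2] / np.maximum(rho, 1e-12), 0.0)
        wobble = 1.0 + bump_amplitude * (
            np.sin(2 * theta + phase[0]) * (1 - cosphi**2)
            + 0.5 * np.sin(3 * theta + phase[1]) * cosphi
        )
        return rho <= wobble
    return rho <= 1.0


def _capsule_mask(coords, p0, p1, radius):
    """Voxels within `radius` of the segment p0-p1 (a thick cylinder)."""
    X, Y, Z = coords
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    L2 = float(axis @ axis)
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 == 0:
        return dx**2 + dy**2 + dz**2 <= radius**2
    t = (dx * axis[0] + dy * axis[1] + dz * axis[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    qx = dx - t * axis[0]
    qy = dy - t * axis[1]
    qz = dz - t * axis[2]
    return qx**2 + qy**2 + qz**2 <= radius**2


def _needle_mask(coords, needle: NeedleSpec):
    entry = np.asarray(needle.entry_point, dtype=float)
    hub = np.asarray(needle.hub, dtype=float)
    mask = _capsule_mask(coords, entry, hub, needle.shaft_radius_mm)
    axis = hub - entry
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    # orthonormal frame around the shaft axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    alpha = math.radians(needle.tine_angle_deg)
    for i in range(needle.tine_count):
        phi = 2 * math.pi * i / needle.tine_count
        direction = math.cos(alpha) * axis + math.sin(alpha) * (
            math.cos(phi) * u + math.sin(phi) * v
        )
        tip = hub + needle.tine_length_mm * direction
        mask |= _capsule_mask(coords, hub, tip, needle.tine_radius_mm)
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegmentationMask]:
    """Render a phantom volume and its ground-truth lesion mask.

    Deterministic for a fixed ``rng_seed``; noise-free phantoms without rim
    and needle take exactly two intensity values.
    """
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = sx * np.arange(nx)
    y = sy * np.arange(ny)
    z = sz * np.arange(nz)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    coords = (X, Y, Z)

    lesion = _ellipsoid_mask(
        coords, spec.lesion_center, spec.lesion_radii,
        spec.bump_amplitude, spec.rng_seed,
    )
    values = np.full(spec.shape, float(spec.background))
    rim = None
    if spec.rim_thickness_mm > 0:
        outer_radii = tuple(
            r + spec.rim_thickness_mm for r in spec.lesion_radii
        )
        outer = _ellipsoid_mask(
            coords, spec.lesion_center, outer_radii,
            spec.bump_amplitude, spec.rng_seed,
        )
        rim = outer & ~lesion
        values[rim] = float(spec.rim_intensity)
    values[lesion] = float(spec.lesion_intensity)

    needle_vox = None
    if spec.needle is not None:
        needle_vox = _needle_mask(coords, spec.needle)
        values[needle_vox] = float(spec.needle.intensity)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    truth = lesion.copy()
    if spec.rim_in_truth and rim is not None:
        truth |= rim
    if needle_vox is not None:
        truth &= ~needle_vox

    volume = ImageVolume(values=values, spacing=spec.spacing)
    mask = SegmentationMask(truth, spec.spacing)
    return volume, mask


def paper_case_suite(n_cases: int, rng_seed: int) -> list[PhantomSpec]:
    """Draw a reproducible collection of realistic case specifications.

    Lesion volumes are log-uniform over 6.25–122.62 cm³, in-plane pixel
    spacing uniform over 0.679–0.777 mm, inter-slice spacing uniform over
    1–3 mm, with a 512×512 in-plane matrix and enough slices (52–232) to
    contain the lesion.  Every other case carries an umbrella needle, so
    half of an even-sized suite does.
    """
    if n_cases < 1:
        raise PhantomSpecError("n_cases must be >= 1")
    rng = np.random.default_rng(rng_seed)
    specs: list[PhantomSpec] = []
    for i in range(n_cases):
        vol_cm3 = math.exp(
            rng.uniform(math.log(6.25), math.log(122.62))
        )
        base_r = (3.0 * vol_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        # mild anisotropy with unit product so the volume is preserved
        f = rng.uniform(0.85, 1.18, size=2)
        factors = np.array([f[0], f[1], 1.0 / (f[0] * f[1])])
        radii = tuple(base_r * factors)
        sp_xy = float(rng.uniform(0.679, 0.777))
        sp_z = float(rng.uniform(1.0, 3.0))
        nz = int(np.clip(math.ceil(2 * radii[2] / sp_z) + 30, 52, 232))
        shape = (512, 512, nz)
        center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, (sp_xy, sp_xy, sp_z)))
        needle = None
        if i % 2 == 0:  # half of the cases keep the needle in place
            entry = (center[0], center[1] - (512 - 1) * sp_xy / 2.0, center[2])
            needle = NeedleSpec(
                entry_point=entry,
                hub=center,
                tine_length_mm=min(0.8 * min(radii), 20.0),
            )
        specs.append(
            PhantomSpec(
                shape=shape,
                spacing=(sp_xy, sp_xy, sp_z),
                lesion_center=center,
                lesion_radii=radii,
                rim_thickness_mm=2.0,
                needle=needle,
                noise_sigma=10.0,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
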