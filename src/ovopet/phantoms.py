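"""Synthetic phantom generation: egg, in ovo embryo, MRI hardware, MR/CT.

Everything the study needs is generated here with ground truth attached:

* a uniform saline-filled egg phantom (liquid ellipsoid + thin calcite-like
  shell) for the hardware-configuration experiments,
* fertilised-egg ("in ovo") phantoms with brain, liver and CAM-xenograft
  uptake plus injected-dose bookkeeping including unmeasured bleeding loss,
* parametric μ templates for the animal bed (arc shell) and cylindrical MRI
  coils (annulus),
* surrogate MR (piecewise-constant + Gaussian noise) and CT (HU) volumes
  from which the attenuation-correction maps are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .petsim import decay_factor
from .volume import MuMap, VoxelVolume, make_grid

# ground-truth linear attenuation coefficients at 511 keV (cm^-1)
MU_WATER_511 = 0.096
MU_SHELL_511 = 0.17

# label ids shared across the package
LABELS = {0: "air", 1: "liquid", 2: "shell", 3: "brain", 4: "liver", 5: "xenograft"}
LABEL_IDS = {v: k for k, v in LABELS.items()}

AXIS_NAMES = "xyz"


@dataclass(frozen=True)
class EggGeometry:
    """Ellipsoidal egg: liquid compartment semi-axes plus a thin shell.

    The long axis (semi-axis ``c``) is aligned with grid axis ``long_axis``
    (default z); ``a`` and ``b`` are the transverse semi-axes. Default size
    gives an egg of ~4.6 x 4.6 x 5.8 cm including shell, consistent with a
    standard hen's egg of roughly 5 cm.
    """

    semi_axes_mm: tuple[float, float, float] = (22.5, 22.5, 28.5)
    shell_thickness_mm: float = 0.35
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    long_axis: int = 2

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be > 0")
        if self.shell_thickness_mm < 0:
            raise ValueError("shell thickness must be >= 0")
        if self.long_axis not in (0, 1, 2):
            raise ValueError("long_axis must be 0, 1 or 2")

    def radii(self, include_shell: bool = False) -> np.ndarray:
        """Per-grid-axis semi-axes (mm); ``c`` mapped onto ``long_axis``."""
        a, b, c = self.semi_axes_mm
        r = np.empty(3)
        transverse = [ax for ax in range(3) if ax != self.long_axis]
        r[transverse[0]], r[transverse[1]] = a, b
        r[self.long_axis] = c
        if include_shell:
            r = r + self.shell_thickness_mm
        return r


@dataclass(frozen=True)
class BedSpec:
    """Animal-bed arc shell below the scanner axis."""

    radius_mm: float = 28.0
    angular_extent_deg: float = 120.0
    thickness_mm: float = 8.0
    mu: float = 0.065

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("bed radius and thickness must be > 0")
        if not 0 < self.angular_extent_deg <= 180:
            raise ValueError("bed angular extent must be in (0, 180] degrees")
        if self.mu < 0:
            raise ValueError("bed mu must be >= 0")


@dataclass(frozen=True)
class CoilSpec:
    """Cylindrical MRI coil modelled as a full annulus around the axis."""

    inner_diameter_mm: float = 86.0
    wall_thickness_mm: float = 4.0
    mu: float = 0.15

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("coil diameter and wall thickness must be > 0")
        if self.mu < 0:
            raise ValueError("coil mu must be >= 0")


@dataclass(frozen=True)
class HardwareSpec:
    """Which hardware parts sit in the PET field of view."""

    bed: BedSpec = field(default_factory=BedSpec)
    coil: CoilSpec = field(default_factory=CoilSpec)
    include_bed: bool = True
    include_coil: bool = True


@dataclass(frozen=True)
class OrganSpec:
    """An organ compartment carved into the egg's liquid background.

    ``size_mm`` is a radius for spheres, or three semi-axes for ellipsoids.
    ``uptake`` is the activity concentration relative to the liquid
    background (background = 1).
    """

    name: str
    center_mm: tuple[float, float, float]
    size_mm: float | tuple[float, float, float]
    uptake: float
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.name not in LABEL_IDS or self.name in ("air", "liquid", "shell"):
            raise ValueError(f"unknown organ name {self.name!r}")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError("shape must be 'sphere' or 'ellipsoid'")
        if self.uptake < 1.0:
            raise ValueError("organ uptake must be >= background (1.0)")

    def semi_axes(self) -> np.ndarray:
        if self.shape == "sphere":
            return np.full(3, float(self.size_mm))
        return np.asarray(self.size_mm, dtype=float)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injected-dose bookkeeping for one in ovo acquisition.

    The dose calibrator reports ``dispensed - residual`` as the injected
    activity; activity lost to bleeding and dabbed off the egg is *not*
    subtracted from that report, so the calibrator overestimates the
    activity actually inside the egg by ``lost_activity_kBq``.
    """

    nuclide: str = "F-18"
    dispensed_activity_kBq: float = 4890.0
    residual_activity_kBq: float = 250.0
    lost_activity_kBq: float = 0.0
    frame_start_min: float = 60.0
    frame_duration_min: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispensed_activity_kBq <= 0:
            raise ValueError("dispensed activity must be > 0")
        if not 0 <= self.residual_activity_kBq < self.dispensed_activity_kBq:
            raise ValueError("residual must be in [0, dispensed)")
        if not 0 <= self.lost_activity_kBq <= self.dispensed_activity_kBq - self.residual_activity_kBq:
            raise ValueError("lost activity must be in [0, dispensed - residual]")

    @property
    def calibrator_injected_kBq(self) -> float:
        """What the dose calibrator reports (loss not subtracted)."""
        return self.dispensed_activity_kBq - self.residual_activity_kBq

    @property
    def true_in_egg_kBq(self) -> float:
        """Activity actually inside the egg at injection time."""
        return self.calibrator_injected_kBq - self.lost_activity_kBq

    @property
    def half_life_min(self) -> float:
        from .petsim import HALF_LIFE_MIN

        return HALF_LIFE_MIN[self.nuclide]


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid_mask(grid: VoxelVolume, center_mm, radii_mm) -> np.ndarray:
    x, y, z = grid.meshgrid()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _check_fits(grid: VoxelVolume, center_mm, radii_mm, what: str) -> None:
    for ax in range(3):
        lo = center_mm[ax] - radii_mm[ax]
        hi = center_mm[ax] + radii_mm[ax]
        coords = grid.axis_coords(ax)
        if lo < coords[0] - grid.voxel_size_mm / 2 or hi > coords[-1] + grid.voxel_size_mm / 2:
            raise ValueError(f"{what} exceeds the grid along axis '{AXIS_NAMES[ax]}'")


# ---------------------------------------------------------------------------
# phantom builders


def make_egg_phantom(
    geometry: EggGeometry = EggGeometry(),
    fill_concentration: float = 117.0,
    grid: VoxelVolume | None = None,
    mu_liquid: float = MU_WATER_511,
    mu_shell: float = MU_SHELL_511,
) -> tuple[VoxelVolume, VoxelVolume, MuMap]:
    """Uniform saline-filled egg phantom.

    Returns ``(activity, labels, mu_truth)``: every liquid voxel carries
    ``fill_concentration`` kBq/cc, the thin shell is labelled separately
    with its own μ, outside is air.
    """
    if grid is None:
        grid = make_grid((96, 96, 96), 1.0)
    outer = geometry.radii(include_shell=True)
    _check_fits(grid, geometry.center_mm, outer, "egg")
    liquid = _ellipsoid_mask(grid, geometry.center_mm, geometry.radii())
    with_shell = _ellipsoid_mask(grid, geometry.center_mm, outer)
    shell = with_shell & ~liquid

    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[liquid] = LABEL_IDS["liquid"]
    labels[shell] = LABEL_IDS["shell"]

    activity = np.where(liquid, float(fill_concentration), 0.0)
    mu = np.where(liquid, mu_liquid, 0.0) + np.where(shell, mu_shell, 0.0)
    return (
        grid.like(activity, "kBq/cc"),
        grid.like(labels.astype(np.int32), "label"),
        grid.like(mu, "cm-1"),
    )


def default_organs(geometry: EggGeometry = EggGeometry()) -> list[OrganSpec]:
    """Brain, liver and CAM-xenograft specs scaled to the default egg.

    Uptake ratios relative to background: brain 2x, liver 3x, xenograft 4x.
    The xenograft sits near the shell on the chorioallantoic membrane; the
    brain towards the blunt pole; the liver mid-egg.
    """
    s = min(geometry.semi_axes_mm) / 22.5  # scale factor vs the default egg
    cx, cy, cz = geometry.center_mm
    return [
        OrganSpec("brain", (cx, cy, cz + 16 * s), 4.0 * s, 2.0, "sphere"),
        OrganSpec("liver", (cx + 5 * s, cy, cz - 6 * s), (7 * s, 6 * s, 9 * s), 3.0, "ellipsoid"),
        OrganSpec("xenograft", (cx, cy + 14 * s, cz + 6 * s), 4.0 * s, 4.0, "sphere"),
    ]


def make_inovo_phantom(
    geometry: EggGeometry,
    organs: list[OrganSpec],
    meta: AcquisitionMeta,
    grid: VoxelVolume,
    mu_liquid: float = MU_WATER_511,
    mu_shell: float = MU_SHELL_511,
) -> tuple[VoxelVolume, VoxelVolume, MuMap, AcquisitionMeta]:
    """Fertilised-egg phantom with organ uptake and dose bookkeeping.

    Organ compartments are carved into the liquid background with the given
    relative uptakes, then the whole image is scaled so that the total image
    activity equals the *true in-egg* activity decayed to the frame start
    (``meta.true_in_egg_kBq * exp(-λ t0)``).
    """
    activity_rel, labels, mu = make_egg_phantom(geometry, 1.0, grid, mu_liquid, mu_shell)
    liquid = labels.values == LABEL_IDS["liquid"]

    masks: dict[str, np.ndarray] = {}
    for organ in organs:
        m = _ellipsoid_mask(grid, organ.center_mm, organ.semi_axes())
        if not m.any():
            raise ValueError(f"organ '{organ.name}' contains no voxels on this grid")
        if np.any(m & ~liquid):
            raise ValueError(f"organ '{organ.name}' extends outside the liquid compartment")
        for other, om in masks.items():
            if np.any(m & om):
                raise ValueError(f"organs overlap: ('{other}', '{organ.name}')")
        masks[organ.name] = m

    rel = activity_rel.values.copy()
    lab = labels.values.copy()
    for organ in organs:
        m = masks[organ.name]
        rel[m] = organ.uptake
        lab[m] = LABEL_IDS[organ.name]

    target_kBq = meta.true_in_egg_kBq * decay_factor(meta.nuclide, meta.frame_start_min, 0.0)
    total_rel = rel.sum() * grid.voxel_volume_cc
    if total_rel <= 0:
        raise ValueError("phantom has no activity")
    activity = rel * (target_kBq / total_rel)
    return grid.like(activity, "kBq/cc"), grid.like(lab, "label"), mu, meta


def make_hardware_mumap(
    spec: HardwareSpec,
    grid: VoxelVolume,
    egg: EggGeometry | None = None,
) -> tuple[MuMap, MuMap]:
    """Rasterise the bed and coil μ templates on ``grid``.

    Returns ``(bed_mu, coil_mu)`` as separate maps (all-zero when the
    component is excluded); assignment is by voxel centre (no partial
    volume). Components are centred on the in-plane grid centre with the bed
    arc opening upward (+y), i.e. the bed lies below the axis.
    """
    cx, cy, _ = grid.center_mm
    if egg is not None and spec.include_coil:
        egg_extent = float(np.max(np.delete(egg.radii(include_shell=True), egg.long_axis)))
        if spec.coil.inner_diameter_mm / 2.0 <= egg_extent:
            raise ValueError(
                f"coil annulus (inner radius {spec.coil.inner_diameter_mm / 2:.1f} mm) "
                f"intersects the egg bounding box (extent {egg_extent:.1f} mm)"
            )
    x, y, _ = grid.meshgrid()
    rr = np.hypot(x - cx, y - cy)

    bed = np.zeros(grid.shape)
    if spec.include_bed:
        b = spec.bed
        phi = np.degrees(np.arctan2(x - cx, -(y - cy)))  # 0 at straight down
        in_arc = (rr >= b.radius_mm) & (rr < b.radius_mm + b.thickness_mm)
        in_arc &= np.abs(phi) <= b.angular_extent_deg / 2.0
        bed[in_arc] = b.mu

    coil = np.zeros(grid.shape)
    if spec.include_coil:
        c = spec.coil
        ri = c.inner_diameter_mm / 2.0
        coil[(rr >= ri) & (rr < ri + c.wall_thickness_mm)] = c.mu

    return grid.like(bed, "cm-1"), grid.like(coil, "cm-1")


# ---------------------------------------------------------------------------
# surrogate MR / CT

#: default MR mean intensities per label: liquid and embryonic tissue give
#: signal; air, shell and hardware are MR-invisible (air-like)
DEFAULT_MR_CONTRAST = {0: 2.0, 1: 100.0, 2: 2.0, 3: 95.0, 4: 105.0, 5: 98.0}


def simulate_mr_volume(
    labels: VoxelVolume,
    contrast: dict[int, float] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> VoxelVolume:
    """Piecewise-constant surrogate MR volume with Gaussian noise.

    No pulse-sequence physics: each label is assigned a mean intensity, the
    shell and hardware are MR-invisible, noise is additive Gaussian clipped
    at zero. Deterministic for a given seed.
    """
    contrast = DEFAULT_MR_CONTRAST if contrast is None else contrast
    present = np.unique(labels.values)
    missing = [int(l) for l in present if int(l) not in contrast]
    if missing:
        raise ValueError(f"contrast map is missing label(s) {missing}")
    lut = np.zeros(int(present.max()) + 1)
    for l in present:
        lut[int(l)] = contrast[int(l)]
    mr = lut[labels.values]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mr = mr + rng.normal(0.0, noise_sd, size=mr.shape)
    return labels.like(np.clip(mr, 0.0, None), "arbitrary-MR")


def simulate_ct_volume(hardware_mu: MuMap, params=None) -> VoxelVolume:
    """Surrogate CT of a hardware template, in Hounsfield units.

    Exact inverse of the bilinear 511 keV scaling so that
    ``hu_to_mu_511(simulate_ct_volume(mu)) == mu`` (air → −1000 HU, water-μ
    → 0 HU).
    """
    from .mumaps import BilinearScalingParams

    params = params or BilinearScalingParams()
    mu = np.asarray(hardware_mu.values)
    if np.any(mu < 0):
        raise ValueError("hardware mu must be nonnegative")
    mu_max = params.mu_water_511 + params.slope_high * (params.max_hu - params.breakpoint_hu)
    if np.any(mu > mu_max):
        raise ValueError(
            f"mu exceeds the invertible range of the bilinear model (max {mu_max:.4f} cm^-1)"
        )
    low = mu <= params.mu_water_511
    hu = np.where(
        low,
        params.breakpoint_hu + (mu - params.mu_water_511) / params.slope_low,
        params.breakpoint_hu + (mu - params.mu_water_511) / params.slope_high,
    )
    return hardware_mu.like(hu, "HU")
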