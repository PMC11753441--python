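"""Attenuation maps for the four AC configurations.

* NO-AC: no attenuation correction (all-zero μ-map).
* AC-1:  MR-based object map — air/tissue segmentation of the surrogate MR,
         tissue set to 0.1023 cm^-1 (the vendor's rodent value, deliberately
         slightly above water at 511 keV).
* AC-2:  AC-1 plus the animal-bed template (CT-derived, bilinear-scaled).
* AC-3:  AC-2 plus the MRI-coil template.

The eggshell gives no MR signal and is therefore absent from AC-1 maps, as
in a real MR-based workflow; this contributes a small residual bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import MuMap, VoxelVolume

#: linear attenuation coefficient assigned to MR "tissue" (cm^-1)
MU_TISSUE_AC = 0.1023


@dataclass(frozen=True)
class BilinearScalingParams:
    """Bilinear CT-HU → 511 keV μ scaling.

    Anchored so that −1000 HU (air) maps to 0 and the breakpoint (0 HU,
    water) maps to ``mu_water_511``. Above the breakpoint a shallower slope
    applies, chosen so 1000 HU maps to a cortical-bone-like ~0.17 cm^-1.
    """

    mu_water_511: float = 0.096
    breakpoint_hu: float = 0.0
    slope_low: float | None = None  # defaults to mu_water_511 / 1000
    slope_high: float = 7.4e-5
    max_hu: float = 3000.0  # upper edge of the invertible range

    def __post_init__(self) -> None:
        if self.slope_low is None:
            object.__setattr__(self, "slope_low", self.mu_water_511 / (self.breakpoint_hu + 1000.0))
        if self.slope_low < 0 or self.slope_high < 0:
            raise ValueError("slopes must be >= 0")
        if self.mu_water_511 <= 0:
            raise ValueError("mu_water_511 must be > 0")


class ACMode(str, Enum):
    NO_AC = "none"
    AC1 = "ac1"
    AC2 = "ac2"
    AC3 = "ac3"


@dataclass(frozen=True)
class ACConfig:
    """Which component μ templates enter the composite AC map."""

    mode: ACMode = ACMode.AC3

    @property
    def components(self) -> tuple[str, ...]:
        return {
            ACMode.NO_AC: (),
            ACMode.AC1: ("object",),
            ACMode.AC2: ("object", "bed"),
            ACMode.AC3: ("object", "bed", "coil"),
        }[self.mode]


def segment_mr_to_mumap(
    mr: VoxelVolume,
    threshold: float | str = "otsu",
    tissue_mu: float = MU_TISSUE_AC,
) -> MuMap:
    """Binary air/tissue segmentation of an MR volume into a μ-map.

    Voxels above the threshold (Otsu by default, or a fixed value) are
    tissue; the largest connected tissue component is kept and its interior
    holes filled; tissue is assigned ``tissue_mu`` exactly, air 0.
    """
    if np.any(mr.values < 0):
        raise ValueError("MR values must be nonnegative")
    vals = np.asarray(mr.values)
    thr = float(threshold_otsu(vals)) if threshold == "otsu" else float(threshold)
    tissue = vals > thr
    if not tissue.any():
        raise ValueError("empty tissue segment")
    comp, n = ndimage.label(tissue)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        tissue = comp == (1 + int(np.argmax(sizes)))
    tissue = ndimage.binary_fill_holes(tissue)
    return mr.like(np.where(tissue, tissue_mu, 0.0), "cm-1")


def hu_to_mu_511(ct: VoxelVolume, params: BilinearScalingParams | None = None) -> MuMap:
    """Bilinear HU → μ(511 keV) conversion, clamped to 0 below −1000 HU."""
    params = params or BilinearScalingParams()
    hu = np.asarray(ct.values)
    if np.any(hu < -1024):
        raise ValueError("HU below -1024: corrupt input")
    low = hu <= params.breakpoint_hu
    mu = np.where(
        low,
        params.mu_water_511 + params.slope_low * (hu - params.breakpoint_hu),
        params.mu_water_511 + params.slope_high * (hu - params.breakpoint_hu),
    )
    return ct.like(np.clip(mu, 0.0, None), "cm-1")


def compose_ac_map(
    config: ACConfig,
    object_mu: MuMap | None = None,
    bed_mu: MuMap | None = None,
    coil_mu: MuMap | None = None,
) -> MuMap:
    """Voxelwise sum of the component μ-maps selected by ``config``.

    NO-AC returns an all-zero map on the grid of whichever component was
    passed. All supplied maps must share the grid.
    """
    maps = {"object": object_mu, "bed": bed_mu, "coil": coil_mu}
    template = next((m for m in maps.values() if m is not None), None)
    if template is None:
        raise ValueError("at least one component map is required to define the grid")
    for name, m in maps.items():
        if m is not None and m.shape != template.shape:
            raise ValueError(f"grid mismatch: '{name}' has shape {m.shape}, expected {template.shape}")
    total = np.zeros(template.shape)
    for name in config.components:
        m = maps[name]
        if m is None:
            raise ValueError(f"AC config {config.mode.value!r} requires the '{name}' map")
        total = total + m.values
    return template.like(total, "cm-1")
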