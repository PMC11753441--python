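"""VOI analysis: deviations, %ID/cc, line profiles, difference images.

Two normalisations of %ID/cc are implemented side by side:

* image mode — tissue concentration divided by the total activity measured
  inside a whole-egg sphere on the image itself. Invariant under any global
  multiplicative reconstruction bias, which is exactly why it is robust to
  missing hardware attenuation templates.
* calibrator mode — divided by the dose-calibrator injected activity
  (dispensed − residual). Biased by any activity lost from the egg that the
  calibrator never saw (e.g. dabbed-off bleeding).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .petsim import FWHM_TO_SIGMA
from .volume import VoxelVolume


@dataclass(frozen=True)
class VOI:
    """Spherical (world-mm) or label-mask volume of interest."""

    name: str
    kind: str = "sphere"  # "sphere" | "label_mask"
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    label_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            if self.center_mm is None or self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("sphere VOI needs a center and a positive radius")
        elif self.kind == "label_mask":
            if self.label_id is None:
                raise ValueError("label_mask VOI needs a label_id")
        else:
            raise ValueError(f"unknown VOI kind {self.kind!r}")

    def mask(self, volume: VoxelVolume, labels: VoxelVolume | None = None) -> np.ndarray:
        if self.kind == "label_mask":
            if labels is None:
                raise ValueError("label_mask VOI requires a labels volume")
            return np.asarray(labels.values) == self.label_id
        x, y, z = volume.meshgrid()
        cx, cy, cz = self.center_mm  # type: ignore[misc]
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius_mm**2  # type: ignore[operator]


@dataclass
class QuantResult:
    """Per-VOI quantification record."""

    voi: str
    mean_concentration: float
    actual_concentration: float | None = None
    deviation_percent: float | None = None
    pid_cc_image: float | None = None
    pid_cc_calibrator: float | None = None
    extra: dict = field(default_factory=dict)


def voi_mean(volume: VoxelVolume, voi: VOI, labels: VoxelVolume | None = None) -> float:
    """Mean value over voxels whose centres fall inside the VOI."""
    m = voi.mask(volume, labels)
    if not m.any():
        raise ValueError(f"VOI '{voi.name}' contains no voxels on this grid")
    return float(np.mean(volume.values[m]))


def percent_deviation(measured: float, actual: float) -> float:
    """100·(measured − actual)/actual, rounded to one decimal.

    Rounding is half-away-from-zero, matching how tabulated deviations such
    as −51.0 and −20.2 are printed.
    """
    if actual <= 0:
        raise ValueError("actual concentration must be > 0")
    dev = 100.0 * (measured - actual) / actual
    return math.copysign(math.floor(abs(dev) * 10.0 + 0.5), dev) / 10.0


@dataclass
class TotalActivityResult:
    total_kBq: float
    truncated: bool = False  # object support extended beyond the sphere


def total_activity_image(
    volume: VoxelVolume,
    whole_egg_sphere: VOI,
    support: np.ndarray | None = None,
) -> TotalActivityResult:
    """Total activity (kBq) inside a whole-egg sphere VOI.

    ``support`` (optional boolean mask of the true object extent) triggers a
    recorded warning when it is not fully covered by the sphere.
    """
    m = whole_egg_sphere.mask(volume)
    if not m.any():
        raise ValueError("whole-egg sphere contains no voxels")
    truncated = False
    if support is not None and np.any(np.asarray(support) & ~m):
        truncated = True
        warnings.warn("object support extends beyond the whole-egg sphere", stacklevel=2)
    total = float(np.sum(volume.values[m]) * volume.voxel_volume_cc)
    return TotalActivityResult(total_kBq=total, truncated=truncated)


def pid_cc(concentration: float, normalizer_kBq: float, mode: str = "image") -> float:
    """Percent injected dose per cc: 100 · concentration / normalizer.

    ``mode`` records which normaliser is used ("image" = image-derived total
    activity, "calibrator" = dose-calibrator injected activity); the
    arithmetic is identical.
    """
    if mode not in ("image", "calibrator"):
        raise ValueError("mode must be 'image' or 'calibrator'")
    if normalizer_kBq <= 0:
        raise ValueError("normalizer must be > 0")
    return 100.0 * concentration / normalizer_kBq


def average_replicates(
    volumes: list[VoxelVolume],
    fwhm_mm: float = 2.0,
    scale_factors: list[float] | None = None,
) -> VoxelVolume:
    """Gaussian-filter each replicate (2 mm FWHM default) and average.

    ``scale_factors`` (e.g. reciprocal decay factors) rescale each replicate
    to a common reference time before averaging.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape or v.voxel_size_mm != ref.voxel_size_mm:
            raise ValueError(f"grid mismatch: {v.shape} vs {ref.shape}")
    if scale_factors is None:
        scale_factors = [1.0] * len(volumes)
    sigma = fwhm_mm * FWHM_TO_SIGMA / ref.voxel_size_mm
    acc = np.zeros(ref.shape)
    for v, c in zip(volumes, scale_factors):
        vals = v.values * c
        if fwhm_mm > 0:
            vals = gaussian_filter(vals, sigma, mode="constant")
        acc += vals
    return ref.like(acc / len(volumes))


def line_profile(
    volume: VoxelVolume,
    axis: int,
    actual_concentration: float,
    through_mm: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D profile along ``axis`` through a point, as % of the actual value.

    Returns ``(positions_mm, percent)``. Default line passes through the
    grid centre (where the egg is placed).
    """
    if actual_concentration <= 0:
        raise ValueError("actual concentration must be > 0")
    point = through_mm if through_mm is not None else volume.center_mm
    idx = [int(round(i)) for i in volume.world_to_index(point)]
    for a in range(3):
        if a != axis and not 0 <= idx[a] < volume.shape[a]:
            raise ValueError("profile line lies outside the grid")
    sel: list = list(idx)
    sel[axis] = slice(None)
    values = volume.values[tuple(sel)]
    return volume.axis_coords(axis), 100.0 * values / actual_concentration


def percent_difference_image(recon: VoxelVolume, truth: VoxelVolume, mask: np.ndarray | None = None) -> VoxelVolume:
    """Voxelwise 100·(recon − truth)/truth inside the object mask, NaN outside."""
    if recon.shape != truth.shape:
        raise ValueError(f"grid mismatch: {recon.shape} vs {truth.shape}")
    m = np.asarray(truth.values) > 0 if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty object mask")
    out = np.full(recon.shape, np.nan)
    t = np.asarray(truth.values)
    out[m] = 100.0 * (np.asarray(recon.values)[m] - t[m]) / t[m]
    return recon.like(out, "percent")
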