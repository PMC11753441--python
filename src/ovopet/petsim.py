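"""Forward PET simulation: attenuated line-integral projection and noise.

The scanner is modelled as a stack of independent 2-D parallel-beam slice
sinograms (in-plane lines of response only). A single sparse system matrix
``A`` maps one in-plane image slice to one slice sinogram; the same matrix is
reused for every axial slice and for the back-projection (its transpose), so
the projector/back-projector pair is exactly adjoint.

Units: images are kBq/cc; ``A`` weights samples by step length in mm, so raw
projections are kBq/cc·mm per line of response. Attenuation factors use
cm^-1 μ-maps with path lengths converted to cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d

from .volume import VoxelVolume

#: half-lives in minutes
HALF_LIFE_MIN = {"F-18": 109.77, "Ga-68": 67.71}

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # = 1/2.355


@dataclass(frozen=True)
class ScannerModel:
    """Slice-wise 2-D parallel-beam scanner.

    ``n_angles`` view angles uniformly over 180 degrees; ``n_radial_bins``
    radial positions of width ``radial_bin_size_mm`` centred on the grid
    centre. The energy window is metadata only (no energy-resolved physics).
    """

    n_angles: int = 120
    n_radial_bins: int = 160
    radial_bin_size_mm: float = 1.0
    sensitivity: float = 1.0
    step_fraction: float = 0.5  # ray sampling step, as a fraction of the voxel size
    energy_window_kev: tuple[float, float] = (358.0, 664.0)

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial_bins < 1:
            raise ValueError("n_angles and n_radial_bins must be >= 1")
        if self.radial_bin_size_mm <= 0 or self.sensitivity <= 0:
            raise ValueError("radial_bin_size_mm and sensitivity must be > 0")

    @property
    def radial_extent_mm(self) -> float:
        return self.n_radial_bins * self.radial_bin_size_mm

    @property
    def radial_coords_mm(self) -> np.ndarray:
        return (np.arange(self.n_radial_bins) - (self.n_radial_bins - 1) / 2.0) * self.radial_bin_size_mm

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * math.pi / self.n_angles

    @classmethod
    def for_grid(cls, grid: VoxelVolume, n_angles: int = 120, **kw) -> "ScannerModel":
        """Scanner whose radial field of view covers the grid diagonal."""
        nx, ny, _ = grid.shape
        diag = math.hypot(nx, ny) * grid.voxel_size_mm
        bin_mm = kw.pop("radial_bin_size_mm", grid.voxel_size_mm)
        n_bins = int(math.ceil(diag / bin_mm)) + 4
        return cls(n_angles=n_angles, n_radial_bins=n_bins, radial_bin_size_mm=bin_mm, **kw)


@dataclass
class Sinogram:
    """Per-slice sinograms, all arrays shaped (n_angles, n_radial_bins, nz).

    ``trues`` are unattenuated line integrals (kBq/cc·mm); ``acf`` the
    attenuation factor per LOR; ``scatter`` the mean scatter contribution in
    the same units as the attenuated trues; ``prompts`` and
    ``tail_window_counts`` are in counts once :func:`apply_poisson` has been
    applied (``counts_per_unit`` records the scale factor).
    """

    trues: np.ndarray
    acf: np.ndarray | None = None
    scatter: np.ndarray | None = None
    prompts: np.ndarray | None = None
    tail_window_counts: np.ndarray | None = None
    counts_per_unit: float = 1.0
    frame: dict = field(default_factory=dict)

    @property
    def attenuated_trues(self) -> np.ndarray:
        acf = self.acf if self.acf is not None else 1.0
        return self.trues * acf

    def save_npz(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        arrays = {
            k: getattr(self, k)
            for k in ("trues", "acf", "scatter", "prompts", "tail_window_counts")
            if getattr(self, k) is not None
        }
        np.savez_compressed(
            path,
            header=json.dumps({"counts_per_unit": self.counts_per_unit, "frame": self.frame}),
            **arrays,
        )
        return path

    @classmethod
    def load_npz(cls, path: str | Path) -> "Sinogram":
        import json

        with np.load(path, allow_pickle=False) as f:
            header = json.loads(str(f["header"]))
            kw = {k: f[k] for k in f.files if k != "header"}
        return cls(counts_per_unit=header["counts_per_unit"], frame=header["frame"], **kw)


# ---------------------------------------------------------------------------
# system matrix

_MATRIX_CACHE: dict[tuple, sp.csr_matrix] = {}


def system_matrix(scanner: ScannerModel, grid: VoxelVolume) -> sp.csr_matrix:
    """Sparse 2-D projection matrix (n_angles*n_bins) x (nx*ny).

    Ray-driven with bilinear interpolation at a fixed step of
    ``step_fraction`` voxels; entry weights carry the step length in mm, so
    ``A @ x`` is the mm-weighted line integral of the slice ``x`` (kBq/cc →
    kBq/cc·mm). Rotation centre is the in-plane grid centre. Matrices are
    cached per (scanner geometry, grid geometry).
    """
    nx, ny, _ = grid.shape
    vs = grid.voxel_size_mm
    key = (
        scanner.n_angles,
        scanner.n_radial_bins,
        scanner.radial_bin_size_mm,
        scanner.step_fraction,
        nx,
        ny,
        vs,
    )
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]

    step = scanner.step_fraction * vs
    half_len = scanner.radial_extent_mm / 2.0
    t = np.arange(-half_len, half_len + step / 2, step)  # sample positions along the ray
    r = scanner.radial_coords_mm

    blocks = []
    for theta in scanner.angles_rad:
        d = np.array([math.cos(theta), math.sin(theta)])  # ray direction
        p = np.array([-math.sin(theta), math.cos(theta)])  # radial offset direction
        # sample world coords relative to grid centre: (n_bins, n_t, 2)
        x = r[:, None] * p[0] + t[None, :] * d[0]
        y = r[:, None] * p[1] + t[None, :] * d[1]
        # continuous voxel indices
        fx = x / vs + (nx - 1) / 2.0
        fy = y / vs + (ny - 1) / 2.0
        ix0 = np.floor(fx).astype(np.int64)
        iy0 = np.floor(fy).astype(np.int64)
        wx = fx - ix0
        wy = fy - iy0
        rows = np.broadcast_to(np.arange(scanner.n_radial_bins)[:, None], fx.shape)

        data, ii, jj = [], [], []
        for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
            ix = ix0 + dx
            iy = iy0 + dy
            w = (wx if dx else 1 - wx) * (wy if dy else 1 - wy) * step
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (w > 0)
            data.append(w[ok])
            ii.append(rows[ok])
            jj.append(ix[ok] * ny + iy[ok])
        block = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(ii), np.concatenate(jj))),
            shape=(scanner.n_radial_bins, nx * ny),
        ).tocsr()
        blocks.append(block)
    A = sp.vstack(blocks, format="csr")
    _MATRIX_CACHE[key] = A
    return A


def _check_coverage(scanner: ScannerModel, grid: VoxelVolume) -> None:
    nx, ny, _ = grid.shape
    diag = math.hypot(nx, ny) * grid.voxel_size_mm
    if scanner.radial_extent_mm < diag:
        raise ValueError(
            f"grid diagonal {diag:.1f} mm exceeds scanner radial coverage "
            f"{scanner.radial_extent_mm:.1f} mm"
        )


def _project_flat(A: sp.csr_matrix, vol: VoxelVolume) -> np.ndarray:
    nx, ny, nz = vol.shape
    flat = np.asarray(vol.values, dtype=np.float64).reshape(nx * ny, nz)
    return A @ flat  # (n_angles*n_bins, nz)


def project(activity: VoxelVolume, scanner: ScannerModel) -> Sinogram:
    """Unattenuated line-integral projection of an activity volume."""
    if np.any(activity.values < 0):
        raise ValueError("activity must be nonnegative")
    _check_coverage(scanner, activity)
    A = system_matrix(scanner, activity)
    proj = _project_flat(A, activity)
    trues = proj.reshape(scanner.n_angles, scanner.n_radial_bins, activity.shape[2])
    return Sinogram(trues=trues)


def attenuation_factors(mu: VoxelVolume, scanner: ScannerModel) -> np.ndarray:
    """Per-LOR attenuation factor exp(-∫μ dl), μ in cm^-1, path in cm."""
    if np.any(mu.values < 0):
        raise ValueError("mu must be nonnegative")
    _check_coverage(scanner, mu)
    A = system_matrix(scanner, mu)
    line_mm = _project_flat(A, mu)  # cm^-1 · mm
    acf = np.exp(-line_mm / 10.0)
    return acf.reshape(scanner.n_angles, scanner.n_radial_bins, mu.shape[2])


# ---------------------------------------------------------------------------
# scatter and noise


def add_scatter(
    sino: Sinogram,
    scatter_fraction: float,
    kernel_fwhm_mm: float = 30.0,
    tail_window_ratio: float = 0.5,
    scanner: ScannerModel | None = None,
    radial_bin_size_mm: float | None = None,
) -> Sinogram:
    """Add a broad-Gaussian scatter channel and the tail-window link.

    The scatter sinogram is the attenuated trues smoothed radially with a
    Gaussian of ``kernel_fwhm_mm`` and globally scaled so that
    scatter/(attenuated trues + scatter) equals ``scatter_fraction``.
    ``tail_window_counts = tail_window_ratio * scatter`` is the noise-free
    dual-energy-window link used later by the scatter correction.
    """
    if not 0 <= scatter_fraction < 0.5:
        raise ValueError("scatter_fraction must be in [0, 0.5)")
    if tail_window_ratio <= 0:
        raise ValueError("tail_window_ratio must be > 0")
    bin_mm = radial_bin_size_mm or (scanner.radial_bin_size_mm if scanner else 1.0)
    n_bins = sino.trues.shape[1]
    if kernel_fwhm_mm > n_bins * bin_mm:
        raise ValueError("scatter kernel FWHM exceeds the radial field of view")
    att = sino.attenuated_trues
    if scatter_fraction == 0:
        scatter = np.zeros_like(att)
    else:
        sigma_bins = kernel_fwhm_mm * FWHM_TO_SIGMA / bin_mm
        smoothed = gaussian_filter1d(att, sigma_bins, axis=1, mode="constant")
        total = smoothed.sum()
        if total <= 0:
            scatter = np.zeros_like(att)
        else:
            scale = scatter_fraction / (1.0 - scatter_fraction) * att.sum() / total
            scatter = smoothed * scale
    prompts = att + scatter
    return replace(
        sino,
        scatter=scatter,
        prompts=prompts,
        tail_window_counts=tail_window_ratio * scatter,
        frame={**sino.frame, "scatter_fraction": scatter_fraction, "tail_window_ratio": tail_window_ratio},
    )


def apply_poisson(sino: Sinogram, total_count_budget: float, seed: int) -> Sinogram:
    """Replace prompts and tail window by Poisson draws at a count budget.

    The sinogram is scaled so the *expected attenuated-true* count total
    equals ``total_count_budget``; the applied scale is recorded in
    ``counts_per_unit`` so reconstruction can restore concentration units.
    """
    if total_count_budget <= 0:
        raise ValueError("total_count_budget must be > 0")
    att = sino.attenuated_trues
    total = att.sum()
    if total <= 0:
        raise ValueError("cannot scale an all-zero sinogram to a count budget")
    scale = total_count_budget / total
    prompts_mean = sino.prompts if sino.prompts is not None else att
    tail_mean = (
        sino.tail_window_counts if sino.tail_window_counts is not None else np.zeros_like(att)
    )
    rng = np.random.default_rng(seed)
    prompts = rng.poisson(prompts_mean * scale).astype(np.float64)
    tail = rng.poisson(tail_mean * scale).astype(np.float64)
    return replace(
        sino,
        prompts=prompts,
        tail_window_counts=tail,
        counts_per_unit=sino.counts_per_unit * scale,
        frame={**sino.frame, "count_budget": total_count_budget, "noise_seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# decay


def decay_factor(nuclide: str, frame_start_min: float, frame_duration_min: float = 0.0) -> float:
    """Frame-averaged decay factor relative to injection time.

    exp(-λ t0) · (1 - exp(-λ T)) / (λ T); the T → 0 limit is exp(-λ t0).
    """
    if nuclide not in HALF_LIFE_MIN:
        raise ValueError(f"unknown nuclide {nuclide!r}; known: {sorted(HALF_LIFE_MIN)}")
    lam = math.log(2.0) / HALF_LIFE_MIN[nuclide]
    f = math.exp(-lam * frame_start_min)
    if frame_duration_min > 0:
        x = lam * frame_duration_min
        f *= -math.expm1(-x) / x
    return f
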