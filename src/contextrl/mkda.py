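"""Multilevel kernel density analysis (MKDA) for coordinate-based meta-analysis.

Each study contributes a binary indicator map: the union of spheres
(default radius 10 mm) around its reported activation foci on an isotropic
voxel grid (default 2 mm). The group density map is the weighted proportion
of studies active at each voxel (weights default to the square root of the
study sample size, the convention that keeps large studies from dominating).
Family-wise-error thresholds come from a Monte-Carlo permutation test that
relocates every study's foci uniformly within the analysis mask and records
the maximum density. Unequal category sizes are handled by bootstrap
subsampling of the larger category, with a consistency threshold applied to
the across-iteration significance frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_RADIUS_MM = 10.0


@dataclass
class Grid:
    """Voxel grid with an affine mm <-> voxel mapping (nibabel convention)."""

    shape: tuple
    affine: np.ndarray

    def mm_to_vox(self, xyz_mm) -> np.ndarray:
        xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        vox = (inv[:3, :3] @ xyz_mm.T).T + inv[:3, 3]
        return np.rint(vox).astype(int)

    def vox_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    @property
    def voxel_size(self) -> float:
        sizes = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        if not np.allclose(sizes, sizes[0]):
            raise ValueError("only isotropic grids are supported")
        return float(sizes[0])


def make_synthetic_mask(shape=(24, 24, 24), voxel_size=2.0, axes_frac=(0.9, 0.8, 0.8)):
    """Ellipsoidal stand-in analysis mask for tests and simulations.

    Synthetic: an ellipsoid inscribed in the grid, centered so that mm
    coordinate (0, 0, 0) falls at the grid center. Returns ``(mask, grid)``.
    """
    shape = tuple(shape)
    affine = np.diag([voxel_size] * 3 + [1.0])
    center = (np.array(shape) - 1) / 2.0
    affine[:3, 3] = -center * voxel_size
    grid = Grid(shape, affine)
    ijk = np.indices(shape).reshape(3, -1).T
    semi = (np.array(shape) / 2.0) * np.asarray(axes_frac)
    d = ((ijk - center) / semi) ** 2
    mask = (d.sum(axis=1) <= 1.0).reshape(shape)
    return mask, grid


@dataclass
class FociStudy:
    """One study's activation foci (MNI mm), category, and sample size."""

    study_id: str
    category: str
    foci: np.ndarray              # (n_foci, 3) mm
    n_participants: int

    def __post_init__(self):
        self.foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if self.foci.shape[0] < 1 or self.foci.shape[1] != 3:
            raise ValueError("a study needs at least one 3D focus")

    @property
    def weight(self) -> float:
        return float(np.sqrt(self.n_participants))


@dataclass
class DensityMap:
    """Weighted study-density values on a grid, plus threshold metadata."""

    values: np.ndarray
    grid: Grid
    mask: np.ndarray
    meta: dict = field(default_factory=dict)


# --- kernels and maps --------------------------------------------------------

def _sphere_offsets(radius_mm: float, voxel_size: float) -> np.ndarray:
    r_vox = int(np.floor(radius_mm / voxel_size))
    rng = np.arange(-r_vox, r_vox + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = (ii**2 + jj**2 + kk**2) * voxel_size**2 <= radius_mm**2 + 1e-9
    return np.stack([ii[keep], jj[keep], kk[keep]], axis=1)


def _stamp(vox_centers: np.ndarray, offsets: np.ndarray, shape) -> np.ndarray:
    """Union of spheres around voxel centers as a boolean array."""
    out = np.zeros(shape, dtype=bool)
    pts = (vox_centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
    pts = pts[ok]
    out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return out


def indicator_map(study: FociStudy, grid: Grid, mask: np.ndarray,
                  radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Binary map: voxels within ``radius_mm`` of any focus, masked.

    Foci falling outside the mask are clipped to the nearest mask voxel
    (with a log warning).
    """
    if radius_mm <= 0:
        raise ValueError("kernel radius must be positive")
    vox = grid.mm_to_vox(study.foci)
    vox = np.clip(vox, 0, np.array(grid.shape) - 1)
    inside = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not inside.all():
        from scipy.spatial import cKDTree

        mask_vox = np.argwhere(mask)
        tree = cKDTree(mask_vox)
        _, nearest = tree.query(vox[~inside])
        vox[~inside] = mask_vox[nearest]
        log.warning("indicator_map: clipped %d foci of %s to the mask",
                    (~inside).sum(), study.study_id)
    offsets = _sphere_offsets(radius_mm, grid.voxel_size)
    return _stamp(vox, offsets, grid.shape) & mask


def study_weights(studies, scheme="sqrt_n") -> np.ndarray:
    """Per-study weights, normalized to sum to one."""
    if isinstance(scheme, (list, tuple, np.ndarray)):
        w = np.asarray(scheme, dtype=float)
    elif scheme == "sqrt_n":
        w = np.array([s.weight for s in studies])
    elif scheme == "uniform":
        w = np.ones(len(studies))
    else:
        raise ValueError(f"unknown weight scheme: {scheme!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w / total


def density_map(studies, grid: Grid, mask: np.ndarray,
                radius_mm: float = DEFAULT_RADIUS_MM,
                weights="sqrt_n") -> DensityMap:
    """Voxelwise weighted proportion of studies active (values in [0, 1])."""
    w = study_weights(studies, weights)
    values = np.zeros(grid.shape)
    for study, wi in zip(studies, w):
        values += wi * indicator_map(study, grid, mask, radius_mm)
    return DensityMap(values, grid, mask,
                      meta={"radius_mm": radius_mm, "n_studies": len(studies)})


# --- permutation inference ---------------------------------------------------

def _null_density_max(foci_counts, w, mask_vox, offsets, shape, mask, rng):
    values = np.zeros(shape)
    for n_foci, wi in zip(foci_counts, w):
        idx = rng.integers(0, len(mask_vox), size=n_foci)
        values += wi * (_stamp(mask_vox[idx], offsets, shape) & mask)
    return values.max()


def permutation_threshold(studies, grid: Grid, mask: np.ndarray,
                          radius_mm: float = DEFAULT_RADIUS_MM,
                          weights="sqrt_n", n_perm: int = 1000,
                          alpha: float = 0.05,
                          seed: int | np.random.Generator = 0) -> float:
    """FWE critical density from the permutation distribution of map maxima.

    Every permutation relocates each study's foci uniformly at random
    among mask voxels (keeping per-study focus counts), recomputes the
    weighted density map, and records its maximum. The critical value is
    the conservative (1 - alpha) quantile of the maxima; a voxel is
    FWE-significant when its observed density strictly exceeds it.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = study_weights(studies, weights)
    mask_vox = np.argwhere(mask)
    if len(mask_vox) < max(len(s.foci) for s in studies):
        raise ValueError("mask too small for the foci counts")
    offsets = _sphere_offsets(radius_mm, grid.voxel_size)
    counts = [len(s.foci) for s in studies]
    maxima = np.array([
        _null_density_max(counts, w, mask_vox, offsets, grid.shape, mask, rng)
        for _ in range(n_perm)
    ])
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def thresholded_map(studies, grid, mask, radius_mm=DEFAULT_RADIUS_MM,
                    weights="sqrt_n", n_perm=1000, alpha=0.05, seed=0):
    """Density map with FWE threshold metadata and its binary exceedance map."""
    dm = density_map(studies, grid, mask, radius_mm, weights)
    crit = permutation_threshold(studies, grid, mask, radius_mm, weights,
                                 n_perm, alpha, seed)
    dm.meta.update({"alpha": alpha, "n_perm": n_perm, "fwe_critical": crit})
    return dm, dm.values > crit


def bootstrap_contrast(mixed_studies, only_studies, grid: Grid, mask: np.ndarray,
                       radius_mm: float = DEFAULT_RADIUS_MM, weights="sqrt_n",
                       n_boot: int = 500, subset_size: int = 9,
                       consistency: float = 0.05, n_perm: int = 1000,
                       alpha: float = 0.05,
                       seed: int | np.random.Generator = 0):
    """Bootstrap-balanced mixed > only contrast map.

    Each iteration draws ``subset_size`` studies from the (larger) mixed
    category, FWE-thresholds both categories' density maps, and marks
    voxels significant for mixed but not for the only category. The final
    map keeps voxels whose across-iteration significance frequency reaches
    ``consistency``. Returns ``(final_map, frequency_map)``.
    """
    if not (0 < consistency <= 1):
        raise ValueError("consistency must lie in (0, 1]")
    if subset_size > len(mixed_studies):
        raise ValueError("subset_size exceeds the mixed category size")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freq = np.zeros(grid.shape)
    for _ in range(n_boot):
        idx = rng.choice(len(mixed_studies), size=subset_size, replace=False)
        subset = [mixed_studies[i] for i in idx]
        _, sig_mixed = thresholded_map(subset, grid, mask, radius_mm, weights,
                                       n_perm, alpha, seed=rng)
        _, sig_only = thresholded_map(only_studies, grid, mask, radius_mm,
                                      weights, n_perm, alpha, seed=rng)
        freq += sig_mixed & ~sig_only
    freq /= n_boot
    return freq >= consistency, freq


def overlap_fraction(map_a: np.ndarray, map_b: np.ndarray,
                     region_mask: np.ndarray) -> float:
    """Percentage of map_a voxels inside the region that are also in map_b."""
    if not (map_a.shape == map_b.shape == region_mask.shape):
        raise ValueError("grid mismatch between maps")
    a = map_a.astype(bool) & region_mask.astype(bool)
    denom = a.sum()
    if denom == 0:
        log.warning("overlap_fraction: map_a has no voxels in the region")
        return 0.0
    return 100.0 * float((a & map_b.astype(bool)).sum()) / float(denom)


# --- NIfTI I/O ---------------------------------------------------------------

def load_mask(path):
    """Read a binary mask NIfTI; returns (mask, Grid)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data > 0, Grid(tuple(data.shape), np.asarray(img.affine))


def save_map(values: np.ndarray, grid: Grid, path) -> None:
    """Write a map (density or binary) as NIfTI on the grid's affine."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine),
             str(path))


def read_foci_csv(path) -> list[FociStudy]:
    """Read a foci table (study_id, category, x, y, z, n) into studies."""
    df = pd.read_csv(path)
    studies = []
    for (sid, cat, n), grp in df.groupby(["study_id", "category", "n"], sort=False):
        studies.append(FociStudy(str(sid), str(cat),
                                 grp[["x", "y", "z"]].to_numpy(), int(n)))
    return studies


def write_foci_csv(studies, path) -> None:
    rows = [
        {"study_id": s.study_id, "category": s.category,
         "x": x, "y": y, "z": z, "n": s.n_participants}
        for s in studies for x, y, z in s.foci
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
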