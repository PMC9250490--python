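"""Phantom brain atlas: labeled 3-D grids with Braak-grouped cortical regions.

The atlas stands in for a template-space anatomical parcellation (AAL-style)
with regions grouped by Braak stage (I-II transentorhinal, III-IV limbic,
V-VI isocortical) plus a cerebellum-like reference region used for SUVr
normalization.  Cortical regions come in mirror-symmetric left/right pairs so
that hemispheric asymmetry can be planted and detected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib

BRAAK_GROUPS = ("I_II", "III_IV", "V_VI")
REFERENCE_GROUP = "REFERENCE"
HEMISPHERES = ("L", "R", "MID")

#: minimum voxels per region, below which smoothing destroys the ROI signal
MIN_REGION_VOXELS = 8


class AtlasSizingError(ValueError):
    """Raised when the requested regions cannot be placed on the grid."""


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    braak_group: str
    hemisphere: str

    def __post_init__(self):
        if self.braak_group not in BRAAK_GROUPS + (REFERENCE_GROUP,):
            raise ValueError(f"unknown braak_group {self.braak_group!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass
class PhantomAtlas:
    """Labeled integer grid plus region metadata.

    ``label_grid`` maps each voxel to a region id (0 = background).  Exactly
    one region is the reference region; every cortical region belongs to one
    of the three Braak groups and one hemisphere.
    """

    label_grid: np.ndarray
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label_grid must be 3-D")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.label_grid.shape)

    # -- lookups ----------------------------------------------------------
    def region_by_name(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        valid = ", ".join(r.name for r in self.regions)
        raise KeyError(f"unknown region {name!r}; valid regions: {valid}")

    def region_mask(self, name: str) -> np.ndarray:
        return self.label_grid == self.region_by_name(name).region_id

    @property
    def reference_region(self) -> Region:
        refs = [r for r in self.regions if r.braak_group == REFERENCE_GROUP]
        if len(refs) != 1:
            raise ValueError(f"atlas must have exactly one reference region, found {len(refs)}")
        return refs[0]

    @property
    def cortical_regions(self) -> list[Region]:
        return [r for r in self.regions if r.braak_group != REFERENCE_GROUP]

    def regions_in_group(self, group: str) -> list[Region]:
        return [r for r in self.regions if r.braak_group == group]

    def hemisphere_cortical_mask(self, side: str) -> np.ndarray:
        if side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {side!r}")
        ids = [r.region_id for r in self.cortical_regions if r.hemisphere == side]
        if not ids:
            raise ValueError(f"atlas has no cortical regions labeled hemisphere {side!r}")
        return np.isin(self.label_grid, ids)

    def voxel_count(self, name: str) -> int:
        return int(self.region_mask(name).sum())

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ids = {r.region_id for r in self.regions}
        if len(ids) != len(self.regions):
            raise ValueError("duplicate region ids")
        present = set(np.unique(self.label_grid)) - {0}
        if not present <= ids:
            raise ValueError("label grid contains ids without region metadata")
        self.reference_region  # exactly-one check
        for g in BRAAK_GROUPS:
            if not self.regions_in_group(g):
                raise ValueError(f"no regions in Braak group {g}")
        for r in self.regions:
            n = int((self.label_grid == r.region_id).sum())
            if n < MIN_REGION_VOXELS:
                raise ValueError(f"region {r.name} has only {n} voxels (< {MIN_REGION_VOXELS})")

    # -- I/O --------------------------------------------------------------
    def save(self, nifti_path: str | Path, regions_csv_path: str | Path) -> None:
        img = nib.Nifti1Image(self.label_grid.astype(np.int16), np.eye(4))
        nib.save(img, str(nifti_path))
        with open(regions_csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "name", "braak_group", "hemisphere"])
            for r in self.regions:
                w.writerow([r.region_id, r.name, r.braak_group, r.hemisphere])

    @classmethod
    def load(cls, nifti_path: str | Path, regions_csv_path: str | Path) -> "PhantomAtlas":
        grid = np.asanyarray(nib.load(str(nifti_path)).dataobj).astype(np.int32)
        regions = []
        with open(regions_csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                regions.append(Region(int(row["id"]), row["name"],
                                      row["braak_group"], row["hemisphere"]))
        atlas = cls(grid, regions)
        atlas.validate()
        return atlas


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def build_phantom_atlas(grid_shape: tuple[int, int, int] = (32, 32, 32),
                        n_regions_per_group: int = 1,
                        seed: int = 0) -> PhantomAtlas:
    """Place mirror-symmetric ellipsoidal cortical regions plus a midline reference.

    Axis 0 is treated as left-right; regions are laid out on a slot lattice in
    the (axis 1, axis 2) plane, one ellipsoid per slot per hemisphere, with the
    right-hemisphere copy the exact mirror image of the left.  The reference
    region sits on the midline, spatially separated from the cortical slots so
    that moderate Gaussian smoothing cannot bleed cortical signal into it.

    Raises :class:`AtlasSizingError` if the grid is too small for the requested
    number of regions.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 16 for s in grid_shape):
        raise ValueError("grid_shape must be 3 axes, each >= 16")
    if n_regions_per_group < 1:
        raise ValueError("n_regions_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    X, Y, Z = grid_shape

    n_slots = 3 * n_regions_per_group
    sy = int(np.ceil(np.sqrt(n_slots)))
    sz = int(np.ceil(n_slots / sy))
    # cortical slab occupies y in [0.06, 0.52]; reference lives at y ~ 0.84
    y_lo, y_hi = 0.06 * Y, 0.52 * Y
    z_lo, z_hi = 0.12 * Z, 0.88 * Z
    pitch_y = (y_hi - y_lo) / sy
    pitch_z = (z_hi - z_lo) / sz
    r_yz = 0.42 * min(pitch_y, pitch_z)
    cx_left = 0.26 * X
    r_x = min(0.16 * X, 0.22 * X - 1.0)  # keep clear of midline and edge

    label = np.zeros(grid_shape, dtype=np.int32)
    regions: list[Region] = []
    next_id = 1

    slot = 0
    for group in BRAAK_GROUPS:
        for j in range(n_regions_per_group):
            iy, iz = slot // sz, slot % sz
            slot += 1
            cy = y_lo + (iy + 0.5) * pitch_y + rng.uniform(-0.1, 0.1) * pitch_y
            cz = z_lo + (iz + 0.5) * pitch_z + rng.uniform(-0.1, 0.1) * pitch_z
            base = f"{group.lower()}_{j}"
            left = _ellipsoid_mask(grid_shape, (cx_left, cy, cz), (r_x, r_yz, r_yz))
            n_vox = int(left.sum())
            if n_vox < MIN_REGION_VOXELS:
                raise AtlasSizingError(
                    f"cannot place region {base}_L on grid {grid_shape}: ellipsoid of "
                    f"radii ({r_x:.2f}, {r_yz:.2f}, {r_yz:.2f}) voxels holds {n_vox} "
                    f"voxels (< {MIN_REGION_VOXELS}); use a larger grid or fewer regions")
            right = np.flip(left, axis=0)
            if np.any(left & right):
                raise AtlasSizingError(
                    f"cannot place region {base}: hemispheres overlap at the midline")
            for mask, hemi in ((left, "L"), (right, "R")):
                if np.any(label[mask]):
                    raise AtlasSizingError(f"cannot place region {base}_{hemi}: overlap")
                label[mask] = next_id
                regions.append(Region(next_id, f"{base}_{hemi}", group, hemi))
                next_id += 1

    # large midline reference: like the cerebellum, it dwarfs any single
    # cortical ROI, so the non-progressing compartment dominates image geometry
    ref_center = (X / 2 - 0.5, 0.84 * Y, 0.45 * Z)
    ref_radii = (0.40 * X, 0.11 * Y, 0.30 * Z)
    ref = _ellipsoid_mask(grid_shape, ref_center, ref_radii)
    if np.any(label[ref]):
        raise AtlasSizingError("cannot place reference region: overlaps cortical slots")
    if int(ref.sum()) < MIN_REGION_VOXELS:
        raise AtlasSizingError("cannot place reference region: too few voxels")
    label[ref] = next_id
    regions.append(Region(next_id, "cerebellum_ref", REFERENCE_GROUP, "MID"))

    atlas = PhantomAtlas(label, regions)
    atlas.validate()
    return atlas
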