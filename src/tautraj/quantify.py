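"""Intensity normalization and regional SUVr quantification.

Model inputs are normalized the way PET volumes are fed to the embedding
model: divide by the mean uptake of the reference (cerebellum-like) region,
then divide by the global maximum so the volume peaks at exactly 1.  Regional
reporting stays on the SUVr scale (reference-normalized only); the max
normalization applies to model inputs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import BRAAK_GROUPS, PhantomAtlas


class NormalizationError(ValueError):
    pass


def _reference_mean(volume: np.ndarray, atlas: PhantomAtlas) -> float:
    ref = atlas.reference_region
    m = float(volume[atlas.label_grid == ref.region_id].mean())
    if m <= 0:
        raise NormalizationError(
            f"reference region {ref.name!r} has non-positive mean uptake ({m})")
    return m


def normalize_intensity(volume: np.ndarray, atlas: PhantomAtlas) -> np.ndarray:
    """Reference-mean division followed by global-max division.

    Output maximum is exactly 1; the map is idempotent.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.grid_shape:
        raise ValueError(f"volume shape {volume.shape} != atlas grid {atlas.grid_shape}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite voxels")
    q = volume / _reference_mean(volume, atlas)
    m = float(q.max())
    if m <= 0:
        raise NormalizationError("volume maximum is non-positive after reference division")
    return q / m


def regional_suvr(volume: np.ndarray, atlas: PhantomAtlas, region_name: str) -> float:
    """Mean uptake in the region divided by mean uptake in the reference region."""
    volume = np.asarray(volume, dtype=float)
    mask = atlas.region_mask(region_name)  # raises KeyError listing valid names
    return float(volume[mask].mean()) / _reference_mean(volume, atlas)


@dataclass
class SUVrTable:
    """Long-format per-subject, per-region SUVr values."""

    frame: pd.DataFrame  # columns: subject_id, region, suvr
    reference_name: str

    def pivot(self) -> pd.DataFrame:
        return self.frame.pivot(index="subject_id", columns="region", values="suvr")

    def bilateral_mean(self) -> pd.DataFrame:
        """Average the _L/_R copies of each region; columns are base names."""
        wide = self.pivot()
        base = {c: c.rsplit("_", 1)[0] if c.rsplit("_", 1)[-1] in ("L", "R") else c
                for c in wide.columns}
        return wide.T.groupby(wide.columns.map(base)).mean().T


def suvr_table(volumes, atlas: PhantomAtlas, subject_ids=None,
               regions=None) -> SUVrTable:
    """Tabulate SUVr for every cortical region (or a named subset)."""
    if subject_ids is None:
        subject_ids = [f"sub{i:04d}" for i in range(len(volumes))]
    if regions is None:
        regions = [r.name for r in atlas.cortical_regions]
    ref_name = atlas.reference_region.name
    rows = []
    for sid, vol in zip(subject_ids, volumes):
        vol = np.asarray(vol, dtype=float)
        ref_mean = _reference_mean(vol, atlas)
        for name in regions:
            mask = atlas.region_mask(name)
            rows.append((sid, name, float(vol[mask].mean()) / ref_mean))
    return SUVrTable(pd.DataFrame(rows, columns=["subject_id", "region", "suvr"]),
                     reference_name=ref_name)


def braak_group_profile(frames, atlas: PhantomAtlas) -> pd.DataFrame:
    """Mean SUVr per Braak group for an ordered sequence of volumes.

    Regions within a group are weighted equally (not by voxel count).
    Returns a (n_frames x 3) DataFrame with columns I_II, III_IV, V_VI.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    group_masks = {g: [atlas.region_mask(r.name) for r in atlas.regions_in_group(g)]
                   for g in BRAAK_GROUPS}
    rows = []
    for vol in frames:
        vol = np.asarray(vol, dtype=float)
        ref_mean = _reference_mean(vol, atlas)
        rows.append([float(np.mean([vol[m].mean() / ref_mean for m in masks]))
                     for g, masks in group_masks.items()])
    return pd.DataFrame(rows, columns=list(BRAAK_GROUPS))
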