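"""Synthetic phantom PET cohorts with known progression structure.

Each subject carries a hidden progression value ``s`` in [0, 1].  Regional
tracer uptake follows a logistic onset curve b + a * sigmoid((s - tau) / w)
whose onsets are staggered in Braak order (transentorhinal before limbic
before isocortical), so that generated cohorts reproduce the qualitative
medial-temporal-first spreading pattern.  Nuisance structure mimics real
acquisition: per-subject global scale, additive Gaussian noise, and isotropic
Gaussian smoothing.  A minority of "atypical" subjects get one hemisphere's
cortical uptake multiplied by an asymmetry factor.

Covariates follow the canonical biomarker cascade: an amyloid-like marker
rises before any tau region, a cognition-like score (MMSE-like) declines
late, and a metabolism-like marker (FDG-like) is flat with a late decline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .atlas import BRAAK_GROUPS, PhantomAtlas

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DIAGNOSES = ("CN", "MCI", "AD")

COHORT_COLUMNS = ["subject_id", "true_s", "diagnosis", "atypical_true",
                  "mmse_like", "amyloid_like", "fdg_like", "age", "sex",
                  "apoe4", "volume_path"]


@dataclass(frozen=True)
class RegionOnsetParams:
    """Logistic onset parameters of one region's uptake curve."""

    baseline: float
    amplitude: float
    onset: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0.0 <= self.onset <= 1.0:
            raise ValueError(f"onset must lie in [0, 1], got {self.onset}")


def regional_uptake(s: float, params: RegionOnsetParams) -> float:
    """Expected uptake b + a * sigmoid((s - onset) / width) at progression s."""
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"progression s must lie in [0, 1], got {s}")
    return params.baseline + params.amplitude * expit((s - params.onset) / params.width)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    true_s: float
    diagnosis: str
    atypical_true: bool
    covariates: dict = field(default_factory=dict)
    volume_path: str = ""

    def __post_init__(self):
        if not 0.0 <= self.true_s <= 1.0:
            raise ValueError("true_s must lie in [0, 1]")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}")
        for k, v in self.covariates.items():
            if not np.isfinite(v):
                raise ValueError(f"covariate {k} is not finite")


@dataclass
class CohortConfig:
    """Generation parameters for a phantom cohort.

    Defaults describe the study conditions used throughout: a 200-subject
    cohort with uniform progression, mild voxel noise and scale nuisance,
    smoothing comparable to uniform 8-mm-FWHM resolution on the desk grid,
    and 5% strongly asymmetric atypical subjects.
    """

    n: int = 200
    noise_sd: float = 0.05
    scale_sd: float = 0.10
    smoothing_fwhm_vox: float = 2.0
    atypical_fraction: float = 0.05
    asymmetry_factor: float = 2.0
    # biomarker cascade: amyloid leads the earliest tau onset, with its
    # transition fully inside the observable window; cognition declines late,
    # metabolism latest
    amyloid_onset: float = 0.15
    amyloid_width: float = 0.06
    mmse_onset: float = 0.70
    mmse_width: float = 0.08
    fdg_onset: float = 0.85
    fdg_width: float = 0.06
    covariate_noise_sd: float = 0.02
    mmse_noise_sd: float = 0.5
    # diagnosis thresholds on true_s with label noise
    cn_threshold: float = 0.45
    ad_threshold: float = 0.80
    label_noise: float = 0.10
    #: optional list of (center, sd) stage regimes; true_s is then drawn from
    #: an equal mixture of truncated normals instead of Uniform(0, 1)
    stage_regimes: list | None = None

    def validate(self, onset_params: dict) -> None:
        if not 0.0 <= self.atypical_fraction < 0.5:
            raise ValueError(
                f"atypical_fraction must lie in [0, 0.5), got {self.atypical_fraction}")
        tau_onsets = [p.onset for p in onset_params.values() if p.amplitude > 0]
        if tau_onsets and self.amyloid_onset >= min(tau_onsets):
            raise ValueError(
                f"amyloid_onset ({self.amyloid_onset}) must precede the earliest tau "
                f"region onset ({min(tau_onsets)})")


def default_onset_params(atlas: PhantomAtlas) -> dict[str, RegionOnsetParams]:
    """Braak-ordered group onsets: I_II at 0.25, III_IV at 0.45, V_VI at 0.65.

    All regions of a Braak group (and the left/right copies of each region)
    share parameters: the staging model orders groups, not individual regions.
    Transitions are wide (width 0.10) so uptake keeps evolving across the
    whole course, as drawn in biomarker-cascade models; amplitudes shrink
    with stage (isocortical uptake rises least), mirroring the smallest
    late-stage SUVr increase seen in staged tau imaging.
    """
    group_onset = {"I_II": 0.25, "III_IV": 0.45, "V_VI": 0.65}
    group_amp = {"I_II": 1.2, "III_IV": 1.0, "V_VI": 0.7}
    params: dict[str, RegionOnsetParams] = {}
    for group in BRAAK_GROUPS:
        p = RegionOnsetParams(baseline=1.0, amplitude=group_amp[group],
                              onset=group_onset[group], width=0.10)
        for r in atlas.regions_in_group(group):
            params[r.name] = p
    ref = atlas.reference_region
    params[ref.name] = RegionOnsetParams(baseline=1.0, amplitude=0.0,
                                         onset=0.5, width=0.06)
    _check_braak_order(atlas, params)
    return params


def _check_braak_order(atlas: PhantomAtlas, params: dict[str, RegionOnsetParams]) -> None:
    onsets = {g: [params[r.name].onset for r in atlas.regions_in_group(g)]
              for g in BRAAK_GROUPS}
    if not (max(onsets["I_II"]) < min(onsets["III_IV"])
            and max(onsets["III_IV"]) < min(onsets["V_VI"])):
        raise ValueError("region onsets do not respect Braak-group ordering")


def plant_atypical(volume: np.ndarray, atlas: PhantomAtlas, factor: float,
                   side: str) -> np.ndarray:
    """Multiply one hemisphere's cortical uptake by an asymmetry factor.

    The reference region and the other hemisphere are untouched.
    """
    if factor <= 1.0:
        raise ValueError(f"asymmetry factor must be > 1, got {factor}")
    mask = atlas.hemisphere_cortical_mask(side)
    out = np.array(volume, dtype=float, copy=True)
    out[mask] *= factor
    return out


@dataclass
class SyntheticCohort:
    """A generated cohort: records, per-subject volumes, atlas and parameters."""

    records: list[SubjectRecord]
    volumes: list[np.ndarray]
    atlas: PhantomAtlas
    onset_params: dict[str, RegionOnsetParams]
    config: CohortConfig

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"subject_id": rec.subject_id,
                   "true_s": rec.true_s,
                   "diagnosis": rec.diagnosis,
                   "atypical_true": rec.atypical_true}
            row.update(rec.covariates)
            row["volume_path"] = rec.volume_path
            rows.append(row)
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @property
    def true_s(self) -> np.ndarray:
        return np.array([r.true_s for r in self.records])

    def write(self, out_dir: str | Path) -> Path:
        """Write cohort CSV, atlas, and one NIfTI volume per subject."""
        out_dir = Path(out_dir)
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
        self.atlas.save(out_dir / "atlas.nii.gz", out_dir / "atlas_regions.csv")
        new_records = []
        for rec, vol in zip(self.records, self.volumes):
            rel = f"volumes/{rec.subject_id}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                     str(out_dir / rel))
            new_records.append(dataclasses.replace(rec, volume_path=rel))
        self.records = new_records
        path = out_dir / "cohort.csv"
        self.table.to_csv(path, index=False)
        return path


def _draw_true_s(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    if config.stage_regimes is None:
        return rng.uniform(0.0, 1.0, size=config.n)
    regimes = list(config.stage_regimes)
    idx = rng.integers(0, len(regimes), size=config.n)
    s = np.empty(config.n)
    for i, k in enumerate(idx):
        c, sd = regimes[k]
        s[i] = np.clip(rng.normal(c, sd), 0.0, 1.0)
    return s


def generate_cohort(atlas: PhantomAtlas, config: CohortConfig | None = None,
                    seed: int = 0,
                    onset_params: dict[str, RegionOnsetParams] | None = None,
                    out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a phantom cohort; fully reproducible from ``seed``.

    Per subject: draw true_s, paint each region at its expected uptake,
    optionally plant hemispheric asymmetry, apply global scale, add voxel
    noise, smooth, and clip at zero.  If ``out_dir`` is given, volumes and the
    cohort table are also written to disk.
    """
    if config is None:
        config = CohortConfig()
    if onset_params is None:
        onset_params = default_onset_params(atlas)
    _check_braak_order(atlas, onset_params)
    config.validate(onset_params)
    rng = np.random.default_rng(seed)

    true_s = _draw_true_s(rng, config)
    n_atyp = int(round(config.atypical_fraction * config.n))
    atypical_idx = set(rng.choice(config.n, size=n_atyp, replace=False).tolist())

    region_masks = {r.name: atlas.region_mask(r.name) for r in atlas.regions}
    sigma = config.smoothing_fwhm_vox * FWHM_TO_SIGMA

    records, volumes = [], []
    width = max(4, len(str(config.n)))
    for i in range(config.n):
        s = float(true_s[i])
        vol = np.zeros(atlas.grid_shape, dtype=float)
        for name, mask in region_masks.items():
            vol[mask] = regional_uptake(s, onset_params[name])
        atypical = i in atypical_idx
        side = "L"
        if atypical:
            side = "L" if rng.uniform() < 0.5 else "R"
            vol = plant_atypical(vol, atlas, config.asymmetry_factor, side)
        scale = max(float(rng.normal(1.0, config.scale_sd)), 0.2) if config.scale_sd > 0 else 1.0
        vol = scale * vol
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
        if sigma > 0:
            vol = gaussian_filter(vol, sigma=sigma)
        vol = np.clip(vol, 0.0, None)

        # covariates: amyloid rises first, MMSE declines late, FDG flat-to-late-decline
        amyloid = 1.1 + 0.4 * expit((s - config.amyloid_onset) / config.amyloid_width)
        mmse = 29.0 - 8.0 * expit((s - config.mmse_onset) / config.mmse_width)
        fdg = 1.30 - 0.25 * expit((s - config.fdg_onset) / config.fdg_width)
        cov = {
            "mmse_like": float(np.clip(mmse + rng.normal(0, config.mmse_noise_sd), 0, 30)),
            "amyloid_like": float(amyloid + rng.normal(0, config.covariate_noise_sd)),
            "fdg_like": float(fdg + rng.normal(0, config.covariate_noise_sd)),
            "age": float(np.clip(rng.normal(74.0 + 2.0 * s, 7.0), 50, 95)),
            "sex": int(rng.uniform() < 0.52),
            "apoe4": int(rng.uniform() < 0.30 + 0.25 * s),
        }

        if s < config.cn_threshold:
            dx = "CN"
        elif s > config.ad_threshold:
            dx = "AD"
        else:
            dx = "MCI"
        if rng.uniform() < config.label_noise:
            dx = DIAGNOSES[rng.integers(0, 3)]

        records.append(SubjectRecord(subject_id=f"sub{i:0{width}d}", true_s=s,
                                     diagnosis=dx, atypical_true=atypical,
                                     covariates=cov))
        volumes.append(vol)

    cohort = SyntheticCohort(records, volumes, atlas, dict(onset_params), config)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
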