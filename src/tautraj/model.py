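"""Model/Results interface tying the pipeline stages together.

:class:`TauTrajectoryModel` is constructed from a cohort of volumes (plus an
atlas and optional covariates); ``fit()`` normalizes the volumes, trains the
VAE on a random half, embeds every subject, clusters the latent means, builds
and orients the MST, computes pseudo-times and atypicality flags, decodes the
trajectory image sequence, and fits biomarker onset curves.  The returned
:class:`TauTrajectoryResults` carries every intermediate product plus a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import PhantomAtlas
from .cohort import SyntheticCohort
from .cluster import (ClusterAssignment, KSelectionDiagnostics, cluster_latents,
                      select_k)
from .curves import CubicFit, LogisticFit, fit_cubic, fit_logistic_curve, onset_ordering
from .quantify import SUVrTable, braak_group_profile, normalize_intensity, suvr_table
from .trajectory import (ProgressionGraph, flag_atypical, pseudo_time,
                         records_to_frame, sample_trajectory)
from .vae import VAEConfig, encode_volumes, train_vae

#: covariates fitted with onset curves when present in the covariate table
CURVE_COVARIATES = ("amyloid_like", "mmse_like", "fdg_like")


class TauTrajectoryModel:
    """Image-level tau trajectory model for a cohort of PET-like volumes.

    Parameters
    ----------
    volumes : sequence of 3-D arrays
        Raw (un-normalized) volumes on the atlas grid.
    atlas : PhantomAtlas
        Labeled parcellation with Braak groups and a reference region.
    covariates : DataFrame, optional
        Per-subject covariates (row order must match ``volumes``).
    k : int or "auto"
        Number of clusters; "auto" selects k by the largest merge-gap rule.
    train_fraction : float
        Fraction of subjects used to train the VAE (the rest assess
        overfitting); the embedding is applied to the whole cohort.
    """

    def __init__(self, volumes, atlas: PhantomAtlas, covariates: pd.DataFrame | None = None,
                 subject_ids=None, vae_config: VAEConfig | None = None,
                 k="auto", k_range=(2, 8), linkage: str = "ward",
                 percentile: float = 95.0, n_frames: int = 20,
                 root_override: int | None = None, train_fraction: float = 0.5,
                 fit_curves: bool = True, seed: int = 0):
        self.volumes = [np.asarray(v, dtype=float) for v in volumes]
        self.atlas = atlas
        self.covariates = covariates
        n = len(self.volumes)
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"sub{i:04d}" for i in range(n)])
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match volumes")
        if covariates is not None and len(covariates) != n:
            raise ValueError("covariates must have one row per volume")
        self.vae_config = vae_config if vae_config is not None else VAEConfig(seed=seed)
        self.k = k
        self.k_range = tuple(k_range)
        self.linkage = linkage
        self.percentile = percentile
        self.n_frames = n_frames
        self.root_override = root_override
        self.train_fraction = train_fraction
        self.fit_curves = fit_curves
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kwargs) -> "TauTrajectoryModel":
        """Build the model from a generated phantom cohort."""
        table = cohort.table.set_index("subject_id")
        return cls(volumes=cohort.volumes, atlas=cohort.atlas,
                   covariates=table.reset_index(),
                   subject_ids=[r.subject_id for r in cohort.records], **kwargs)

    # -- stages ------------------------------------------------------------
    def _split(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x51]))
        n_train = int(round(self.train_fraction * n))
        n_train = max(n_train, min(n, 2 * self.vae_config.batch_size))
        return rng.permutation(n)[:n_train]

    def _cluster_anchor(self, suvr: SUVrTable, assignment: ClusterAssignment) -> np.ndarray:
        """Per-cluster mean SUVr over early-Braak (I_II) regions."""
        early = [r.name for r in self.atlas.regions_in_group("I_II")]
        wide = suvr.pivot().loc[self.subject_ids, early].mean(axis=1).to_numpy()
        return np.array([wide[assignment.members(c)].mean()
                         for c in range(assignment.k)])

    def fit(self) -> "TauTrajectoryResults":
        n = len(self.volumes)
        normalized = [normalize_intensity(v, self.atlas) for v in self.volumes]
        train_idx = self._split(n)
        state = train_vae([normalized[i] for i in train_idx], self.vae_config)

        means, logvars = encode_volumes(normalized, state)
        held_idx = np.setdiff1d(np.arange(n), train_idx)
        recon_train, recon_held = self._recon_errors(normalized, means, state,
                                                     train_idx, held_idx)

        override = None if self.k == "auto" else int(self.k)
        k, k_diag = select_k(means, self.k_range, self.linkage, override=override)
        assignment = cluster_latents(means, k, self.linkage)

        suvr = suvr_table(self.volumes, self.atlas, subject_ids=self.subject_ids)
        anchor = self._cluster_anchor(suvr, assignment)
        graph = build_oriented_graph(assignment, anchor, self.root_override)

        records = pseudo_time(means, assignment, graph, subject_ids=self.subject_ids)
        records = flag_atypical(records, self.percentile)

        frames = sample_trajectory(graph, self.n_frames, state)
        heatmap = braak_group_profile(frames, self.atlas)

        logistic_fits: dict[str, LogisticFit] = {}
        cubic_fits: dict[str, CubicFit] = {}
        if self.fit_curves:
            pt = np.array([r.pseudo_time for r in records])
            bilateral = suvr.bilateral_mean().loc[self.subject_ids]
            series = {name: bilateral[name].to_numpy() for name in bilateral.columns}
            if self.covariates is not None:
                for cov in CURVE_COVARIATES:
                    if cov in self.covariates.columns:
                        series[cov] = self.covariates[cov].to_numpy(dtype=float)
            for name, y in series.items():
                logistic_fits[name] = fit_logistic_curve(pt, y)
                cubic_fits[name] = fit_cubic(pt, y)

        return TauTrajectoryResults(
            model=self, state=state, latent_means=means, latent_logvars=logvars,
            train_indices=train_idx, recon_train=recon_train, recon_heldout=recon_held,
            assignment=assignment, k_diagnostics=k_diag, suvr=suvr,
            cluster_anchor=anchor, graph=graph, records=records,
            trajectory_frames=frames, braak_heatmap=heatmap,
            logistic_fits=logistic_fits, cubic_fits=cubic_fits)

    @staticmethod
    def _recon_errors(normalized, means, state, train_idx, held_idx):
        from .vae import generate

        def mean_err(idx):
            if len(idx) == 0:
                return float("nan")
            errs = [np.mean((normalized[i] - generate(means[i], state)) ** 2)
                    for i in idx]
            return float(np.mean(errs))

        return mean_err(train_idx), mean_err(held_idx)


def build_oriented_graph(assignment: ClusterAssignment, anchor,
                         root_override: int | None = None,
                         backbone: bool = False) -> ProgressionGraph:
    from .trajectory import build_mst, orient_path

    return orient_path(build_mst(assignment.centers), anchor,
                       root_override=root_override, backbone=backbone)


@dataclass
class TauTrajectoryResults:
    """Everything the fitted trajectory model produced."""

    model: TauTrajectoryModel
    state: object
    latent_means: np.ndarray
    latent_logvars: np.ndarray
    train_indices: np.ndarray
    recon_train: float
    recon_heldout: float
    assignment: ClusterAssignment
    k_diagnostics: KSelectionDiagnostics
    suvr: SUVrTable
    cluster_anchor: np.ndarray
    graph: ProgressionGraph
    records: list
    trajectory_frames: list
    braak_heatmap: pd.DataFrame
    logistic_fits: dict = field(default_factory=dict)
    cubic_fits: dict = field(default_factory=dict)

    @property
    def pseudotime_table(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    @property
    def pseudo_times(self) -> np.ndarray:
        return np.array([r.pseudo_time for r in self.records])

    @property
    def atypical_flags(self) -> np.ndarray:
        return np.array([r.atypical_flag for r in self.records])

    def spearman_vs(self, values) -> float:
        """Spearman correlation of pseudo-time against an external variable."""
        from scipy.stats import spearmanr

        return float(spearmanr(self.pseudo_times, np.asarray(values, dtype=float))[0])

    def curve_report(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.logistic_fits.items():
            rows.append({"series_name": name, "lower": fit.lower, "upper": fit.upper,
                         "midpoint": fit.midpoint, "rate": fit.rate,
                         "pseudo_r2": fit.pseudo_r2, "converged": fit.converged})
        return pd.DataFrame(rows, columns=["series_name", "lower", "upper",
                                           "midpoint", "rate", "pseudo_r2", "converged"])

    def summary(self) -> str:
        n = len(self.records)
        flagged = int(self.atypical_flags.sum())
        lines = [
            "Tau trajectory model results",
            "=" * 60,
            f"subjects: {n}    latent dim: {self.state.config.latent_dim}"
            f"    conv layers: {self.state.config.n_conv_layers}",
            f"VAE epochs: {self.state.config.epochs}"
            f"    train subjects: {len(self.train_indices)}",
            f"reconstruction MSE  train: {self.recon_train:.3e}"
            f"   held-out: {self.recon_heldout:.3e}",
            f"clusters (k): {self.assignment.k}  linkage: {self.assignment.linkage_name}",
            f"MST path: {' -> '.join(str(c) for c in self.graph.path)}"
            f"    total length: {self.graph.total_path_length:.3f}",
            f"pseudo-time range: [{self.pseudo_times.min():.1f},"
            f" {self.pseudo_times.max():.1f}]",
            f"atypical flagged: {flagged}/{n}"
            f" (>{self.model.percentile:g}th pct edge distance)",
        ]
        if self.logistic_fits:
            order = onset_ordering(self.logistic_fits)
            lines.append("-" * 60)
            lines.append("logistic onset fits (ordered by midpoint):")
            for name in order:
                f = self.logistic_fits[name]
                lines.append(f"  {name:<16s} midpoint={f.midpoint:7.2f}"
                             f"  rate={f.rate:7.3f}  pseudoR2={f.pseudo_r2:6.3f}")
        return "\n".join(lines)
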