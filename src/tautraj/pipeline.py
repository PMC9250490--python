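"""Declarative end-to-end pipeline: config, staged artifacts, manifest, replay.

A run directory accumulates one artifact set per stage, in DAG order:

    simulate    cohort.csv, atlas.nii.gz, atlas_regions.csv, volumes/
    preprocess  normalized/, suvr.csv
    train       model.npz, history.csv
    encode      latents.csv
    cluster     assignment.csv, k_diagnostics.json, contingency.csv,
                cluster_stats.csv
    trajectory  graph.json, pseudotime.csv, frames/, braak_heatmap.csv
    curves      curve_fits.csv
    (always)    manifest.json — config, per-stage seeds, versions, timings

Every source of randomness derives from the single global seed, so a
completed run is reproducible from its manifest alone (``replay``).
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
import yaml

from . import __version__
from .atlas import PhantomAtlas, build_phantom_atlas
from .cohort import CohortConfig, SyntheticCohort, SubjectRecord, generate_cohort
from .cluster import (cluster_contingency, cluster_latents,
                      compare_clusters_continuous, select_k, ClusterAssignment)
from .curves import fit_cubic, fit_logistic_curve
from .model import CURVE_COVARIATES, build_oriented_graph
from .quantify import braak_group_profile, normalize_intensity, suvr_table
from .trajectory import (ProgressionGraph, flag_atypical, pseudo_time,
                         records_to_frame, sample_trajectory)
from .vae import ModelState, VAEConfig, encode_volumes, train_vae

STAGES = ("simulate", "preprocess", "train", "encode", "cluster",
          "trajectory", "curves")


class SchemaError(ValueError):
    """Configuration does not match the expected schema."""


@dataclass
class SyntheticBlock:
    grid_shape: tuple = (32, 32, 32)
    n_regions_per_group: int = 2
    atlas_seed: int = 7
    cohort: CohortConfig = field(default_factory=CohortConfig)


@dataclass
class ClusteringBlock:
    k: object = "auto"          # integer or "auto"
    k_min: int = 2
    k_max: int = 8
    linkage: str = "ward"


@dataclass
class TrajectoryBlock:
    percentile: float = 95.0
    n_frames: int = 20
    root_override: int | None = None


@dataclass
class PipelineConfig:
    """Full declarative configuration of one pipeline run.

    ``input_dir`` may be the string "synthetic" (generate a phantom cohort)
    or a directory containing cohort.csv + atlas files + volumes.
    Every field has a default; a block provided in a config file must be
    complete (missing keys inside a provided block are a schema error).
    """

    input_dir: str = "synthetic"
    output_dir: str = "tautraj_run"
    seed: int = 0
    train_fraction: float = 0.5
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    vae: VAEConfig = field(default_factory=VAEConfig)
    clustering: ClusteringBlock = field(default_factory=ClusteringBlock)
    trajectory: TrajectoryBlock = field(default_factory=TrajectoryBlock)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["grid_shape"] = list(self.synthetic.grid_shape)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise SchemaError("config must be a mapping")
        blocks = {"synthetic": SyntheticBlock, "vae": VAEConfig,
                  "clustering": ClusteringBlock, "trajectory": TrajectoryBlock}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in data.items():
            if key not in blocks:
                kwargs[key] = value
                continue
            block_cls = blocks[key]
            if key == "synthetic":
                value = dict(value)
                cohort_part = value.pop("cohort", None)
                missing = _check_block("synthetic", value,
                                       {f.name for f in dataclasses.fields(SyntheticBlock)}
                                       - {"cohort"})
                value["grid_shape"] = tuple(value["grid_shape"])
                if cohort_part is not None:
                    _check_block("synthetic.cohort", cohort_part,
                                 {f.name for f in dataclasses.fields(CohortConfig)})
                    value["cohort"] = CohortConfig(**cohort_part)
                kwargs[key] = SyntheticBlock(**value)
            else:
                _check_block(key, value,
                             {f.name for f in dataclasses.fields(block_cls)})
                kwargs[key] = block_cls(**value)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2 ** 31))


def _check_block(name: str, value: dict, expected: set) -> None:
    if not isinstance(value, dict):
        raise SchemaError(f"config block {name!r} must be a mapping")
    unknown = set(value) - expected
    if unknown:
        raise SchemaError(f"unknown keys in {name}: {sorted(unknown)}")
    missing = expected - set(value)
    if missing:
        raise SchemaError(f"missing keys in {name}: {sorted(missing)}"
                          f" (a provided block must be complete)")


# ---------------------------------------------------------------------------
# run context

@dataclass
class RunContext:
    """Lazy artifact store backed by a run directory."""

    run_dir: Path
    config: PipelineConfig
    cache: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        return self.run_dir / name

    # -- loaders (disk-backed, memoized) ----------------------------------
    def atlas(self) -> PhantomAtlas:
        if "atlas" not in self.cache:
            self.cache["atlas"] = PhantomAtlas.load(self.path("atlas.nii.gz"),
                                                    self.path("atlas_regions.csv"))
        return self.cache["atlas"]

    def cohort_table(self) -> pd.DataFrame:
        if "cohort_table" not in self.cache:
            self.cache["cohort_table"] = pd.read_csv(self.path("cohort.csv"))
        return self.cache["cohort_table"]

    def subject_ids(self) -> list:
        return self.cohort_table()["subject_id"].tolist()

    def volumes(self) -> list:
        if "volumes" not in self.cache:
            table = self.cohort_table()
            self.cache["volumes"] = [
                np.asanyarray(nib.load(str(self.run_dir / p)).dataobj).astype(float)
                for p in table["volume_path"]]
        return self.cache["volumes"]

    def normalized(self) -> list:
        if "normalized" not in self.cache:
            ndir = self.path("normalized")
            table = self.cohort_table()
            self.cache["normalized"] = [
                np.asanyarray(nib.load(str(ndir / f"{sid}.nii.gz")).dataobj).astype(float)
                for sid in table["subject_id"]]
        return self.cache["normalized"]

    def model_state(self) -> ModelState:
        if "model_state" not in self.cache:
            self.cache["model_state"] = ModelState.load(self.path("model.npz"))
        return self.cache["model_state"]

    def latents(self) -> np.ndarray:
        if "latents" not in self.cache:
            df = pd.read_csv(self.path("latents.csv"))
            cols = [c for c in df.columns if c.startswith("mean_")]
            self.cache["latents"] = df[cols].to_numpy()
        return self.cache["latents"]

    def assignment(self) -> ClusterAssignment:
        if "assignment" not in self.cache:
            df = pd.read_csv(self.path("assignment.csv"))
            labels = df["cluster"].to_numpy()
            X = self.latents()
            k = int(labels.max()) + 1
            centers = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
            self.cache["assignment"] = ClusterAssignment(
                labels=labels, k=k,
                linkage_name=self.config.clustering.linkage, centers=centers)
        return self.cache["assignment"]

    def graph(self) -> ProgressionGraph:
        if "graph" not in self.cache:
            with open(self.path("graph.json")) as fh:
                self.cache["graph"] = ProgressionGraph.from_dict(json.load(fh))
        return self.cache["graph"]

    def pseudotime_table(self) -> pd.DataFrame:
        return pd.read_csv(self.path("pseudotime.csv"))


# ---------------------------------------------------------------------------
# stages

def stage_simulate(ctx: RunContext) -> list[str]:
    cfg = ctx.config
    if cfg.input_dir != "synthetic":
        src = Path(cfg.input_dir)
        for name in ("cohort.csv", "atlas.nii.gz", "atlas_regions.csv"):
            if not (src / name).exists():
                raise FileNotFoundError(f"input directory lacks {name}")
        table = pd.read_csv(src / "cohort.csv")
        ctx.run_dir.mkdir(parents=True, exist_ok=True)
        atlas = PhantomAtlas.load(src / "atlas.nii.gz", src / "atlas_regions.csv")
        atlas.save(ctx.path("atlas.nii.gz"), ctx.path("atlas_regions.csv"))
        (ctx.path("volumes")).mkdir(exist_ok=True)
        vols = []
        for sid, rel in zip(table["subject_id"], table["volume_path"]):
            vol = np.asanyarray(nib.load(str(src / rel)).dataobj).astype(float)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                     str(ctx.path("volumes") / f"{sid}.nii.gz"))
            vols.append(vol)
        table["volume_path"] = [f"volumes/{sid}.nii.gz" for sid in table["subject_id"]]
        table.to_csv(ctx.path("cohort.csv"), index=False)
        ctx.cache.update(volumes=vols, cohort_table=table, atlas=atlas)
        return ["cohort.csv", "atlas.nii.gz", "atlas_regions.csv", "volumes/"]
    blk = cfg.synthetic
    atlas = build_phantom_atlas(blk.grid_shape, blk.n_regions_per_group,
                                seed=blk.atlas_seed)
    cohort = generate_cohort(atlas, blk.cohort, seed=cfg.stage_seed("simulate"),
                             out_dir=ctx.run_dir)
    ctx.cache.update(volumes=cohort.volumes, cohort_table=cohort.table,
                     atlas=atlas, cohort=cohort)
    return ["cohort.csv", "atlas.nii.gz", "atlas_regions.csv", "volumes/"]


def stage_preprocess(ctx: RunContext) -> list[str]:
    atlas = ctx.atlas()
    vols = ctx.volumes()
    sids = ctx.subject_ids()
    ndir = ctx.path("normalized")
    ndir.mkdir(exist_ok=True)
    normalized = []
    for sid, vol in zip(sids, vols):
        nv = normalize_intensity(vol, atlas)
        nib.save(nib.Nifti1Image(nv.astype(np.float32), np.eye(4)),
                 str(ndir / f"{sid}.nii.gz"))
        normalized.append(nv)
    ctx.cache["normalized"] = normalized
    suvr = suvr_table(vols, atlas, subject_ids=sids)
    suvr.frame.to_csv(ctx.path("suvr.csv"), index=False)
    ctx.cache["suvr"] = suvr
    return ["normalized/", "suvr.csv"]


def stage_train(ctx: RunContext) -> list[str]:
    cfg = ctx.config
    normalized = ctx.normalized()
    n = len(normalized)
    rng = np.random.default_rng(cfg.stage_seed("train"))
    n_train = max(int(round(cfg.train_fraction * n)),
                  min(n, 2 * cfg.vae.batch_size))
    train_idx = rng.permutation(n)[:n_train]
    vcfg = dataclasses.replace(cfg.vae, seed=cfg.stage_seed("train"))
    state = train_vae([normalized[i] for i in train_idx], vcfg)
    state.save(ctx.path("model.npz"))
    state.history.to_csv(ctx.path("history.csv"), index=False)
    ctx.cache["model_state"] = state
    ctx.cache["train_idx"] = train_idx
    return ["model.npz", "history.csv"]


def stage_encode(ctx: RunContext) -> list[str]:
    state = ctx.model_state()
    means, logvars = encode_volumes(ctx.normalized(), state)
    cols = {f"mean_{d}": means[:, d] for d in range(means.shape[1])}
    cols.update({f"logvar_{d}": logvars[:, d] for d in range(logvars.shape[1])})
    df = pd.DataFrame({"subject_id": ctx.subject_ids(), **cols})
    df.to_csv(ctx.path("latents.csv"), index=False)
    ctx.cache["latents"] = means
    return ["latents.csv"]


def stage_cluster(ctx: RunContext) -> list[str]:
    cfg = ctx.config.clustering
    X = ctx.latents()
    override = None if cfg.k == "auto" else int(cfg.k)
    k, diag = select_k(X, (cfg.k_min, cfg.k_max), cfg.linkage, override=override)
    assignment = cluster_latents(X, k, cfg.linkage)
    pd.DataFrame({"subject_id": ctx.subject_ids(),
                  "cluster": assignment.labels}).to_csv(
        ctx.path("assignment.csv"), index=False)
    with open(ctx.path("k_diagnostics.json"), "w") as fh:
        json.dump({"selected_k": int(k), "overridden": diag.overridden,
                   "gap_by_k": {str(kk): v for kk, v in diag.gap_by_k.items()},
                   "merge_heights": diag.merge_heights[-12:].tolist()}, fh, indent=2)
    table = ctx.cohort_table()
    stats_rows = []
    if "diagnosis" in table.columns:
        cont = cluster_contingency(assignment, table["diagnosis"])
        cont.counts.to_csv(ctx.path("contingency.csv"))
        stats_rows.append({"covariate": "diagnosis", "test": "chi2",
                           "statistic": cont.statistic, "p_value": cont.p_value,
                           "significant_pairs": ""})
    for cov in ("age", "mmse_like", "amyloid_like", "fdg_like"):
        if cov in table.columns and min(np.bincount(assignment.labels)) >= 2:
            res = compare_clusters_continuous(table[cov].to_numpy(), assignment)
            stats_rows.append({"covariate": cov, "test": "anova_tukey",
                               "statistic": res.f_statistic, "p_value": res.p_value,
                               "significant_pairs": ";".join(
                                   f"{i}-{j}" for i, j in res.significant_pairs)})
    pd.DataFrame(stats_rows).to_csv(ctx.path("cluster_stats.csv"), index=False)
    ctx.cache["assignment"] = assignment
    return ["assignment.csv", "k_diagnostics.json", "contingency.csv",
            "cluster_stats.csv"]


def stage_trajectory(ctx: RunContext) -> list[str]:
    cfg = ctx.config.trajectory
    atlas = ctx.atlas()
    assignment = ctx.assignment()
    suvr = suvr_table(ctx.volumes(), atlas, subject_ids=ctx.subject_ids())
    early = [r.name for r in atlas.regions_in_group("I_II")]
    per_subject = suvr.pivot()[early].mean(axis=1).to_numpy()
    anchor = np.array([per_subject[assignment.members(c)].mean()
                       for c in range(assignment.k)])
    graph = build_oriented_graph(assignment, anchor,
                                 root_override=cfg.root_override)
    with open(ctx.path("graph.json"), "w") as fh:
        json.dump(graph.to_dict(), fh, indent=2)
    records = pseudo_time(ctx.latents(), assignment, graph,
                          subject_ids=ctx.subject_ids())
    records = flag_atypical(records, cfg.percentile)
    records_to_frame(records).to_csv(ctx.path("pseudotime.csv"), index=False)
    state = ctx.model_state()
    frames = sample_trajectory(graph, cfg.n_frames, state)
    fdir = ctx.path("frames")
    fdir.mkdir(exist_ok=True)
    for i, frame in enumerate(frames):
        nib.save(nib.Nifti1Image(frame.astype(np.float32), np.eye(4)),
                 str(fdir / f"frame_{i:03d}.nii.gz"))
    heat = braak_group_profile(frames, atlas)
    heat.insert(0, "frame_index", np.arange(len(frames)))
    heat.to_csv(ctx.path("braak_heatmap.csv"), index=False)
    ctx.cache["graph"] = graph
    ctx.cache["records"] = records
    return ["graph.json", "pseudotime.csv", "frames/", "braak_heatmap.csv"]


def stage_curves(ctx: RunContext) -> list[str]:
    atlas = ctx.atlas()
    pt_table = ctx.pseudotime_table()
    t = pt_table["pseudo_time"].to_numpy()
    suvr = suvr_table(ctx.volumes(), atlas, subject_ids=ctx.subject_ids())
    series = {name: suvr.bilateral_mean().loc[ctx.subject_ids(), name].to_numpy()
              for name in suvr.bilateral_mean().columns}
    table = ctx.cohort_table()
    for cov in CURVE_COVARIATES:
        if cov in table.columns:
            series[cov] = table[cov].to_numpy(dtype=float)
    rows = []
    for name, y in series.items():
        fit = fit_logistic_curve(t, y)
        cub = fit_cubic(t, y)
        rows.append({"series_name": name, "lower": fit.lower, "upper": fit.upper,
                     "midpoint": fit.midpoint, "rate": fit.rate,
                     "pseudo_r2": fit.pseudo_r2, "converged": fit.converged,
                     "cubic_rss": cub.rss, "note": fit.note})
    pd.DataFrame(rows).to_csv(ctx.path("curve_fits.csv"), index=False)
    return ["curve_fits.csv"]


_STAGE_FN = {"simulate": stage_simulate, "preprocess": stage_preprocess,
             "train": stage_train, "encode": stage_encode,
             "cluster": stage_cluster, "trajectory": stage_trajectory,
             "curves": stage_curves}


def run_stage(ctx: RunContext, stage: str) -> list[str]:
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    return _STAGE_FN[stage](ctx)


def run_pipeline(config: PipelineConfig,
                 stages=STAGES) -> RunContext:
    """Execute the pipeline stages in order, writing a manifest at the end.

    On a stage failure the already-produced artifacts are kept and the error
    names the failing stage.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    ctx = RunContext(run_dir=run_dir, config=config)
    manifest = {"package_version": __version__,
                "python": platform.python_version(),
                "config": config.to_dict(),
                "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
                "stages": []}
    for stage in stages:
        t0 = time.time()
        try:
            artifacts = run_stage(ctx, stage)
        except Exception as exc:
            manifest["stages"].append({"name": stage, "status": "failed",
                                       "error": str(exc)})
            with open(run_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, "status": "ok",
                                   "artifacts": artifacts,
                                   "seconds": round(time.time() - t0, 2)})
    config.save(run_dir / "config.yaml")
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return ctx


def replay(manifest_path: str | Path, output_dir: str | Path) -> RunContext:
    """Re-run a completed pipeline from its manifest into a new directory."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    config.output_dir = str(output_dir)
    return run_pipeline(config)


def plot_embedding(latents, labels, seed: int, out_csv: str | Path,
                   out_png: str | Path | None = None) -> pd.DataFrame:
    """2-D t-SNE display of the latent features (display-only utility)."""
    from sklearn.manifold import TSNE

    X = np.asarray(latents, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points for an embedding plot")
    perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
    emb = TSNE(n_components=2, random_state=int(seed),
               perplexity=perplexity, init="pca").fit_transform(X)
    df = pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1], "label": list(labels)})
    df.to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in sorted(set(df["label"])):
            sub = df[df["label"] == lab]
            ax.scatter(sub["x"], sub["y"], s=8, label=str(lab))
        ax.legend(markerscale=2, fontsize=7)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return df
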