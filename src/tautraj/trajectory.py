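"""Minimum-spanning-tree trajectory over cluster centers and per-subject
pseudo-time.

Cluster centers become nodes of a complete Euclidean graph; the MST connects
them with minimal total edge weight.  When the tree is a simple path it is
oriented from the low-uptake end to the high-uptake end, and each subject's
latent vector is projected onto the path to yield a scalar progression
position, rescaled to pseudo-time in [0, 100].  The residual distance from
the latent vector to its selected edge measures atypicality; subjects beyond
a cohort percentile of that distance are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import networkx as nx
import pandas as pd


class TopologyError(RuntimeError):
    """The MST is not a simple path (or the path is missing/invalid)."""


@dataclass
class ProgressionGraph:
    centers: np.ndarray                  # (k, d)
    edges: list                          # [(i, j, weight)], i < j
    path: list | None = None             # ordered node ids root -> terminal
    cumulative_length: np.ndarray | None = None  # arc length from root, per path node

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    @property
    def total_path_length(self) -> float:
        if self.cumulative_length is None:
            raise TopologyError("graph has no oriented path")
        return float(self.cumulative_length[-1])

    def node_position(self, node: int) -> float:
        """Arc-length position of a cluster center along the oriented path."""
        if self.path is None:
            raise TopologyError("graph has no oriented path")
        return float(self.cumulative_length[self.path.index(node)])

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist(),
                "edges": [[int(i), int(j), float(w)] for i, j, w in self.edges],
                "path": None if self.path is None else [int(i) for i in self.path],
                "cumulative_length": None if self.cumulative_length is None
                else [float(c) for c in self.cumulative_length]}

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionGraph":
        return cls(centers=np.asarray(d["centers"], dtype=float),
                   edges=[(int(i), int(j), float(w)) for i, j, w in d["edges"]],
                   path=None if d["path"] is None else list(d["path"]),
                   cumulative_length=None if d["cumulative_length"] is None
                   else np.asarray(d["cumulative_length"], dtype=float))


def build_mst(centers) -> ProgressionGraph:
    """Exact Euclidean MST over cluster centers (Kruskal, lexicographic ties)."""
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 1:
        centers = centers[:, None]
    k = centers.shape[0]
    if k < 2:
        raise ValueError("need at least 2 centers")
    dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if dists[i, j] == 0.0:
                raise ValueError(f"duplicate cluster centers {i} and {j}")
            g.add_edge(i, j, weight=dists[i, j])
    # Kruskal with a stable sort keeps insertion (lexicographic) order on ties
    mst_edges = sorted((min(u, v), max(u, v)) for u, v in
                       nx.minimum_spanning_edges(g, algorithm="kruskal", data=False))
    edges = [(i, j, float(dists[i, j])) for i, j in mst_edges]
    return ProgressionGraph(centers=centers, edges=edges)


def _path_from_tree(graph: ProgressionGraph) -> list:
    adj: dict[int, list[int]] = {i: [] for i in range(graph.k)}
    for i, j, _ in graph.edges:
        adj[i].append(j)
        adj[j].append(i)
    degrees = {n: len(v) for n, v in adj.items()}
    leaves = sorted(n for n, d in degrees.items() if d == 1)
    if len(leaves) != 2 or any(d > 2 for d in degrees.values()):
        raise TopologyError(
            "MST is a branching tree, not a simple path; reduce the number of "
            "clusters, pass root_override with backbone mode, or inspect the graph")
    path = [leaves[0]]
    prev = None
    while len(path) < graph.k:
        nxt = [n for n in adj[path[-1]] if n != prev]
        prev = path[-1]
        path.append(nxt[0])
    return path


def _longest_path(graph: ProgressionGraph) -> list:
    """Weighted-diameter backbone of a branching tree (experimental)."""
    g = nx.Graph()
    for i, j, w in graph.edges:
        g.add_edge(i, j, weight=w)

    def farthest(src):
        dist = nx.single_source_dijkstra_path_length(g, src)
        node = max(sorted(dist), key=lambda n: dist[n])
        return node, dist[node]

    a, _ = farthest(0)
    b, _ = farthest(a)
    return nx.shortest_path(g, a, b, weight="weight")


def orient_path(graph: ProgressionGraph, anchor, root_override: int | None = None,
                backbone: bool = False) -> ProgressionGraph:
    """Orient the MST into a progression path.

    ``anchor`` gives one scalar per cluster (by default the cluster-mean
    early-Braak SUVr, supplied by the caller); the endpoint with the smaller
    anchor becomes the root, so the path runs from low to high uptake.
    ``root_override`` forces the root endpoint.  ``backbone=True``
    (experimental) uses the weighted longest path of a branching tree instead
    of failing.
    """
    anchor = np.asarray(anchor, dtype=float)
    if anchor.shape != (graph.k,):
        raise ValueError(f"anchor must have one value per cluster ({graph.k})")
    try:
        path = _path_from_tree(graph)
    except TopologyError:
        if not backbone:
            raise
        path = _longest_path(graph)
    if root_override is not None:
        if root_override == path[-1]:
            path = path[::-1]
        elif root_override != path[0]:
            raise ValueError(f"root_override {root_override} is not a path endpoint "
                             f"({path[0]} or {path[-1]})")
    elif anchor[path[-1]] < anchor[path[0]]:
        path = path[::-1]
    cum = [0.0]
    for a, b in zip(path[:-1], path[1:]):
        cum.append(cum[-1] + float(np.linalg.norm(graph.centers[b] - graph.centers[a])))
    return replace(graph, path=path, cumulative_length=np.asarray(cum))


@dataclass(frozen=True)
class PseudoTimeRecord:
    subject_id: str
    cluster: int
    selected_edge: tuple
    raw_position: float
    pseudo_time: float
    edge_distance: float
    atypical_flag: bool = False


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "cluster": r.cluster,
          "raw_position": r.raw_position, "pseudo_time": r.pseudo_time,
          "edge_distance": r.edge_distance, "atypical_flag": r.atypical_flag}
         for r in records])


def pseudo_time(latents, assignment, graph: ProgressionGraph,
                subject_ids=None) -> list[PseudoTimeRecord]:
    """Project each subject onto the oriented MST path.

    For a subject with latent z in cluster c, v = z - center_c is projected
    onto the path edges incident to c; the edge with the largest scalar
    projection (pointing away from the center) is selected, and the signed
    projection moves the subject from the center's arc-length position toward
    the terminal or root.  If both incident projections are non-positive the
    subject sits at its center.  Positions are clamped to the path and
    min-max rescaled to [0, 100] over the cohort.
    """
    X = np.asarray(latents, dtype=float)
    if graph.path is None:
        raise TopologyError("graph has no oriented path; call orient_path first")
    labels = np.asarray(assignment.labels)
    if subject_ids is None:
        subject_ids = [f"sub{i:04d}" for i in range(len(labels))]
    on_path = set(graph.path)
    total = graph.total_path_length
    pos_in_path = {node: idx for idx, node in enumerate(graph.path)}

    raws, dists, edges_sel = [], [], []
    for z, c in zip(X, labels):
        c = int(c)
        if c not in on_path:
            raise TopologyError(f"cluster {c} is not on the oriented path")
        v = z - graph.centers[c]
        idx = pos_in_path[c]
        candidates = []  # (projection, direction_sign, neighbor, unit)
        if idx + 1 < len(graph.path):
            nxt = graph.path[idx + 1]
            u = graph.centers[nxt] - graph.centers[c]
            u = u / np.linalg.norm(u)
            candidates.append((float(v @ u), +1, nxt, u))
        if idx - 1 >= 0:
            prv = graph.path[idx - 1]
            u = graph.centers[prv] - graph.centers[c]
            u = u / np.linalg.norm(u)
            candidates.append((float(v @ u), -1, prv, u))
        proj, sign, neighbor, u = max(candidates, key=lambda t: t[0])
        base = graph.cumulative_length[idx]
        raw = base + sign * proj if proj > 0 else base
        raw = float(np.clip(raw, 0.0, total))
        resid = v - (v @ u) * u
        raws.append(raw)
        dists.append(float(np.linalg.norm(resid)))
        edges_sel.append((min(c, neighbor), max(c, neighbor)))

    raws = np.asarray(raws)
    lo, hi = raws.min(), raws.max()
    if hi == lo:
        warnings.warn("all raw positions identical; pseudo-time set to 0")
        pt = np.zeros_like(raws)
    else:
        # clip guards float round-off so the range is exactly [0, 100]
        pt = np.clip(100.0 * (raws - lo) / (hi - lo), 0.0, 100.0)
    return [PseudoTimeRecord(subject_id=str(sid), cluster=int(c),
                             selected_edge=e, raw_position=float(r),
                             pseudo_time=float(t), edge_distance=float(d))
            for sid, c, e, r, t, d in zip(subject_ids, labels, edges_sel, raws, pt, dists)]


def flag_atypical(records, percentile: float = 95.0) -> list[PseudoTimeRecord]:
    """Flag subjects whose edge distance strictly exceeds the cohort percentile.

    The threshold uses the linear-interpolation percentile definition, so at
    most (100 - percentile)% of subjects (plus at most one) are flagged.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    records = list(records)
    if len(records) < 20:
        raise ValueError("need at least 20 records for a meaningful percentile")
    dists = np.array([r.edge_distance for r in records])
    threshold = float(np.percentile(dists, percentile))
    return [replace(r, atypical_flag=bool(r.edge_distance > threshold))
            for r in records]


def sample_trajectory(graph: ProgressionGraph, n_frames: int, model) -> list[np.ndarray]:
    """Decode latent points at equal arc-length spacing along the oriented path."""
    from .vae import generate

    if graph.path is None:
        raise TopologyError("graph has no oriented path; call orient_path first")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    total = graph.total_path_length
    cum = graph.cumulative_length
    pts = np.linspace(0.0, total, n_frames)
    frames = []
    for t in pts:
        seg = int(np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(cum) - 2))
        a, b = graph.path[seg], graph.path[seg + 1]
        seg_len = cum[seg + 1] - cum[seg]
        frac = 0.0 if seg_len == 0 else (t - cum[seg]) / seg_len
        z = (1 - frac) * graph.centers[a] + frac * graph.centers[b]
        frames.append(generate(z, model))
    return frames
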