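"""MST construction, path orientation, pseudo-time projection, flagging."""

import itertools

import numpy as np
import pytest

from tautraj import (build_mst, flag_atypical, orient_path, pseudo_time,
                     sample_trajectory)
from tautraj.cluster import ClusterAssignment
from tautraj.trajectory import ProgressionGraph, TopologyError


# ---------------------------------------------------------------------------
# brute-force spanning-tree oracle

def brute_force_mst_weight(centers):
    """Minimum spanning-tree weight by exhaustive edge-subset enumeration."""
    k = len(centers)
    all_edges = [(i, j, float(np.linalg.norm(centers[i] - centers[j])))
                 for i in range(k) for j in range(i + 1, k)]
    best = np.inf
    for subset in itertools.combinations(all_edges, k - 1):
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


def test_collinear_centers_give_chain_tree():
    centers = np.array([[0.0], [1.0], [2.0], [4.0]])
    g = build_mst(centers)
    assert {(i, j) for i, j, _ in g.edges} == {(0, 1), (1, 2), (2, 3)}
    assert g.total_weight == pytest.approx(4.0)
    assert g.total_weight == pytest.approx(brute_force_mst_weight(centers))


def test_two_centers_give_single_edge():
    g = build_mst(np.array([[0.0, 0.0], [3.0, 4.0]]))
    assert g.edges == [(0, 1, pytest.approx(5.0))]


@pytest.mark.parametrize("k", [3, 4, 5, 6])
def test_mst_weight_matches_exhaustive_enumeration(k):
    rng = np.random.default_rng(k)
    for _ in range(25):
        centers = rng.normal(size=(k, 3))
        g = build_mst(centers)
        assert g.total_weight == pytest.approx(
            brute_force_mst_weight(centers), rel=1e-10)


def test_duplicate_centers_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_mst(np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]]))


# ---------------------------------------------------------------------------
# orientation

def _chain_graph():
    return build_mst(np.array([[0.0], [1.0], [2.5]]))


def test_orientation_puts_low_anchor_at_root():
    g = orient_path(_chain_graph(), anchor=[0.1, 0.5, 0.9])
    assert g.path == [0, 1, 2]
    np.testing.assert_allclose(g.cumulative_length, [0.0, 1.0, 2.5])


def test_root_override_reverses_path():
    g = orient_path(_chain_graph(), anchor=[0.1, 0.5, 0.9], root_override=2)
    assert g.path == [2, 1, 0]
    np.testing.assert_allclose(g.cumulative_length, [0.0, 1.5, 2.5])


def test_root_override_must_be_an_endpoint():
    with pytest.raises(ValueError, match="endpoint"):
        orient_path(_chain_graph(), anchor=[0.1, 0.5, 0.9], root_override=1)


def test_branching_tree_is_unsupported_by_default():
    centers = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [1.0, 1.0]])
    g = build_mst(centers)  # star-ish: node 1 has degree 3
    with pytest.raises(TopologyError, match="branching"):
        orient_path(g, anchor=[0.1, 0.2, 0.3, 0.4])


def test_backbone_mode_takes_weighted_diameter():
    centers = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [1.0, 0.8]])
    g = build_mst(centers)
    oriented = orient_path(g, anchor=[0.1, 0.2, 0.9, 0.5], backbone=True)
    assert oriented.path == [0, 1, 2]  # longest path skips the stub node


def test_cumulative_length_strictly_increasing_along_path():
    rng = np.random.default_rng(0)
    centers = np.cumsum(rng.uniform(0.5, 1.5, size=(5, 1)), axis=0)
    g = orient_path(build_mst(centers), anchor=np.arange(5))
    assert np.all(np.diff(g.cumulative_length) > 0)


# ---------------------------------------------------------------------------
# pseudo-time

def _line_setup():
    """Four collinear cluster centers at 0, 10, 20, 30 in 1-D."""
    centers = np.array([[0.0], [10.0], [20.0], [30.0]])
    graph = orient_path(build_mst(centers), anchor=[0, 1, 2, 3])
    return centers, graph


def _assignment(labels, centers):
    return ClusterAssignment(labels=np.asarray(labels), k=len(centers),
                             linkage_name="ward", centers=np.asarray(centers))


def test_scalar_projection_recovers_position_on_line():
    centers, graph = _line_setup()
    # subject of interest sits at 15 inside cluster 1, toward cluster 2;
    # the rest sit at their centers so every cluster is populated
    latents = np.array([[15.0], [0.0], [20.0], [30.0]])
    a = _assignment([1, 0, 2, 3], centers)
    recs = pseudo_time(latents, a, graph, subject_ids=list("abcd"))
    assert recs[0].raw_position == pytest.approx(15.0)
    assert recs[0].selected_edge == (1, 2)
    assert recs[0].edge_distance == pytest.approx(0.0)


def test_subject_at_center_sits_at_cumulative_length():
    centers, graph = _line_setup()
    latents = np.array([[20.0], [0.0], [10.0], [30.0]])
    a = _assignment([2, 0, 1, 3], centers)
    recs = pseudo_time(latents, a, graph, subject_ids=list("abcd"))
    assert recs[0].raw_position == pytest.approx(20.0)
    assert recs[0].edge_distance == pytest.approx(0.0)
    assert recs[1].raw_position == pytest.approx(0.0)


def test_positions_clamped_to_path():
    centers, graph = _line_setup()
    latents = np.array([[-7.0], [40.0], [10.0], [20.0]])  # first two beyond the ends
    a = _assignment([0, 3, 1, 2], centers)
    recs = pseudo_time(latents, a, graph, subject_ids=list("abcd"))
    assert recs[0].raw_position == pytest.approx(0.0)
    assert recs[1].raw_position == pytest.approx(30.0)


def test_pseudo_time_scaled_to_exact_unit_range():
    centers, graph = _line_setup()
    rng = np.random.default_rng(1)
    latents = rng.uniform(0, 30, size=(40, 1))
    labels = np.clip((latents[:, 0] / 10).round().astype(int), 0, 3)
    recs = pseudo_time(latents, _assignment(labels, centers), graph)
    pts = np.array([r.pseudo_time for r in recs])
    assert pts.min() == pytest.approx(0.0, abs=1e-12)
    assert pts.max() == pytest.approx(100.0, abs=1e-12)


def test_identical_positions_collapse_to_zero_with_warning():
    # two-cluster chain: both subjects sit exactly halfway, so both raw
    # positions equal 5 and min-max scaling degenerates
    centers = np.array([[0.0], [10.0]])
    graph = orient_path(build_mst(centers), anchor=[0, 1])
    latents = np.array([[5.0], [5.0]])
    a = _assignment([0, 1], centers)
    with pytest.warns(UserWarning, match="identical"):
        recs = pseudo_time(latents, a, graph)
    assert all(r.pseudo_time == 0.0 for r in recs)


def test_pseudo_time_invariant_under_rigid_motion():
    rng = np.random.default_rng(2)
    centers = np.cumsum(rng.uniform(1, 2, size=(4, 3)), axis=0)
    latents = centers[[0, 1, 1, 2, 3]] + rng.normal(scale=0.3, size=(5, 3))
    labels = [0, 1, 1, 2, 3]
    # random rotation (QR orthogonalization) + translation
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    shift = rng.normal(size=3)

    def run(C, Z):
        g = orient_path(build_mst(C), anchor=np.arange(4))
        return pseudo_time(Z, _assignment(labels, C), g)

    base = run(centers, latents)
    moved = run(centers @ Q.T + shift, latents @ Q.T + shift)
    for r1, r2 in zip(base, moved):
        assert r1.pseudo_time == pytest.approx(r2.pseudo_time, abs=1e-8)
        assert r1.edge_distance == pytest.approx(r2.edge_distance, abs=1e-8)


def test_cluster_centers_have_increasing_pseudo_time_along_path():
    centers, graph = _line_setup()
    latents = centers.copy()
    recs = pseudo_time(latents, _assignment([0, 1, 2, 3], centers), graph)
    pts = [r.pseudo_time for r in recs]
    assert pts == sorted(pts)
    assert np.all(np.diff(pts) > 0)


def test_off_path_cluster_is_a_topology_error():
    centers, graph = _line_setup()
    graph = ProgressionGraph(centers=centers, edges=graph.edges,
                             path=[0, 1, 2], cumulative_length=np.array([0.0, 10.0, 20.0]))
    latents = np.array([[0.0], [10.0], [20.0], [30.0]])
    with pytest.raises(TopologyError, match="not on the oriented path"):
        pseudo_time(latents, _assignment([0, 1, 2, 3], centers), graph)


# ---------------------------------------------------------------------------
# atypicality flagging

def _records_with_distances(dists):
    centers, graph = _line_setup()
    latents = np.array([[float(d)] for d in np.linspace(0, 30, len(dists))])
    labels = np.clip((latents[:, 0] / 10).round().astype(int), 0, 3)
    recs = pseudo_time(latents, _assignment(labels, centers), graph)
    from dataclasses import replace
    return [replace(r, edge_distance=float(d)) for r, d in zip(recs, dists)]


def test_flagging_distances_one_to_hundred_flags_exactly_five():
    recs = flag_atypical(_records_with_distances(np.arange(1, 101)), 95.0)
    assert sum(r.atypical_flag for r in recs) == 5
    flagged = {r.edge_distance for r in recs if r.atypical_flag}
    assert flagged == {96.0, 97.0, 98.0, 99.0, 100.0}


def test_flagging_equal_distances_flags_none():
    recs = flag_atypical(_records_with_distances(np.full(30, 2.5)), 95.0)
    assert not any(r.atypical_flag for r in recs)


def test_flagged_fraction_bounded_by_percentile():
    rng = np.random.default_rng(3)
    for trial in range(5):
        dists = rng.exponential(size=200)
        recs = flag_atypical(_records_with_distances(dists), 95.0)
        frac = np.mean([r.atypical_flag for r in recs])
        assert frac <= 0.05 + 1 / 200


def test_percentile_bounds_enforced():
    recs = _records_with_distances(np.arange(25))
    with pytest.raises(ValueError, match="percentile"):
        flag_atypical(recs, 100.0)


def test_flagging_needs_twenty_records():
    recs = _records_with_distances(np.arange(10))
    with pytest.raises(ValueError, match="20"):
        flag_atypical(recs, 95.0)


# ---------------------------------------------------------------------------
# trajectory sampling

def test_two_frames_decode_the_endpoints(tiny_trained):
    _, _, _, cfg, state = tiny_trained
    from tautraj import generate

    centers = np.zeros((3, cfg.latent_dim))
    centers[1, 0], centers[2, 0] = 1.0, 2.0
    graph = orient_path(build_mst(centers), anchor=[0, 1, 2])
    frames = sample_trajectory(graph, 2, state)
    assert np.allclose(frames[0], generate(centers[0], state))
    assert np.allclose(frames[1], generate(centers[2], state))


def test_equally_spaced_centers_are_hit_exactly(tiny_trained):
    _, _, _, cfg, state = tiny_trained
    from tautraj import generate

    centers = np.zeros((3, cfg.latent_dim))
    centers[1, 1], centers[2, 1] = 1.5, 3.0
    graph = orient_path(build_mst(centers), anchor=[0, 1, 2])
    frames = sample_trajectory(graph, 3, state)
    for j in range(3):
        assert np.allclose(frames[j], generate(centers[j], state), atol=1e-12)


def test_unoriented_graph_rejected(tiny_trained):
    _, _, _, cfg, state = tiny_trained
    graph = build_mst(np.arange(2 * cfg.latent_dim,
                                dtype=float).reshape(2, cfg.latent_dim))
    with pytest.raises(TopologyError, match="orient"):
        sample_trajectory(graph, 4, state)
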