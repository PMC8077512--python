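"""Axis estimation and territory assignment against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from tagtrace import geometry as g
from tagtrace import simulate
from tagtrace.config import EmbryoConfig


def brute_internuclear(xy):
    """All-pairs nearest-neighbour median, no spatial index."""
    n = len(xy)
    nn = []
    for i in range(n):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        nn.append(d.min())
    return float(np.median(nn))


def brute_nearest_nucleus(sxyz, nxyz, nid):
    out = np.empty(len(sxyz), dtype=int)
    for i, p in enumerate(sxyz):
        d = np.sqrt(((nxyz - p) ** 2).sum(axis=1))
        best = d.min()
        out[i] = nid[np.abs(d - best) <= 1e-9].min()
    return out


class TestInternuclearDistance:
    def test_square_lattice_spacing(self, nucleus_table):
        xs, ys = np.meshgrid(np.arange(5) * 10.0, np.arange(5) * 10.0)
        nuc = nucleus_table(np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)]))
        assert g.internuclear_distance(nuc) == pytest.approx(10.0)

    def test_two_nuclei(self, nucleus_table):
        nuc = nucleus_table([[0, 0, 0], [7, 0, 0]])
        assert g.internuclear_distance(nuc) == pytest.approx(7.0)

    def test_single_nucleus_raises(self, nucleus_table):
        with pytest.raises(ValueError):
            g.internuclear_distance(nucleus_table([[0, 0, 0]]))

    def test_matches_brute_force_on_jittered_lattice(self, nucleus_table):
        rng = np.random.default_rng(4)
        xs, ys = np.meshgrid(np.arange(8) * 9.0, np.arange(8) * 9.0)
        xy = np.column_stack([xs.ravel(), ys.ravel()]) + rng.normal(0, 1.0, (64, 2))
        nuc = nucleus_table(np.column_stack([xy, np.zeros(64)]))
        assert g.internuclear_distance(nuc) == pytest.approx(brute_internuclear(xy))


class TestEdgeTrimming:
    def test_margin_rule(self, nucleus_table):
        # row of nuclei spaced 10 µm: internuclear distance 10, margin 15
        xy = np.column_stack([np.arange(10) * 10.0 + 5, np.full(10, 50.0)])
        nuc = nucleus_table(np.column_stack([xy, np.zeros(10)]))
        kept = g.trim_frame_edge_nuclei(nuc, (0, 100, 0, 100), k=1.5)
        # nuclei at x=5 and x=15 are within 1.0-1.5 internuclear distances of x=0
        assert kept["x_um"].min() >= 15.0
        assert kept["x_um"].max() <= 85.0

    def test_k_zero_keeps_interior(self, nucleus_table):
        xy = np.column_stack([np.arange(10) * 10.0 + 5, np.full(10, 50.0)])
        nuc = nucleus_table(np.column_stack([xy, np.zeros(10)]))
        kept = g.trim_frame_edge_nuclei(nuc, (0, 100, 0, 100), k=0.0)
        assert len(kept) == len(nuc)

    def test_all_removed_raises(self, nucleus_table):
        nuc = nucleus_table([[1, 1, 0], [2, 2, 0]])
        with pytest.raises(ValueError):
            g.trim_frame_edge_nuclei(nuc, (0, 4, 0, 4), k=1.5)


class TestOpposingEdgesAndMidline:
    def test_parallel_rows_are_the_two_sides(self, nucleus_table):
        xs = np.arange(12) * 8.0
        pts = np.concatenate(
            [np.column_stack([xs, np.zeros(12)]), np.column_stack([xs, np.full(12, 10.0)])]
        )
        nuc = nucleus_table(np.column_stack([pts, np.zeros(24)]))
        side_a, side_b = g.find_opposing_edges(nuc)
        ys = {round(float(side_a["y_um"].iloc[0]), 6), round(float(side_b["y_um"].iloc[0]), 6)}
        assert ys == {0.0, 10.0}
        assert side_a["y_um"].nunique() == 1 and side_b["y_um"].nunique() == 1

    def test_collinear_cloud_raises(self, nucleus_table):
        xs = np.arange(10) * 5.0
        nuc = nucleus_table(np.column_stack([xs, np.zeros(10), np.zeros(10)]))
        with pytest.raises(ValueError):
            g.find_opposing_edges(nuc)

    def test_elliptical_cloud_sides_disjoint_arcs(self, nucleus_table):
        # filled elliptical cloud: boundary is the shell, sides its two arcs
        xs, ys = np.meshgrid(np.arange(-80, 81, 6.0), np.arange(-30, 31, 6.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        pts = pts[(pts[:, 0] / 80) ** 2 + (pts[:, 1] / 30) ** 2 <= 1.0] + (100, 50)
        nuc = nucleus_table(np.column_stack([pts, np.zeros(len(pts))]))
        side_a, side_b = g.find_opposing_edges(nuc)
        assert set(side_a["id"]).isdisjoint(set(side_b["id"]))
        assert min(len(side_a), len(side_b)) >= 8
        # the sides straddle the midline: mean lateral offsets have opposite sign
        assert (side_a["y_um"].mean() - 50) * (side_b["y_um"].mean() - 50) < 0

    def test_midline_of_symmetric_rows(self, nucleus_table):
        xs = np.arange(12) * 8.0
        a = nucleus_table(np.column_stack([xs, np.zeros(12), np.zeros(12)]))
        b = nucleus_table(np.column_stack([xs, np.full(12, 10.0), np.zeros(12)]))
        axis = g.fit_midline(a, b)
        assert axis.anchor[1] == pytest.approx(5.0)
        assert abs(axis.direction[0]) == pytest.approx(1.0, abs=1e-9)

    def test_midline_equivariant_under_rotation(self, nucleus_table):
        xs = np.arange(12) * 8.0
        pts_a = np.column_stack([xs, np.zeros(12)])
        pts_b = np.column_stack([xs, np.full(12, 10.0)])
        th = np.deg2rad(30)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = nucleus_table(np.column_stack([pts_a @ rot.T, np.zeros(12)]))
        b = nucleus_table(np.column_stack([pts_b @ rot.T, np.zeros(12)]))
        axis = g.fit_midline(a, b)
        expected_anchor = np.array([np.mean(xs), 5.0]) @ rot.T
        assert np.allclose(axis.anchor[:2], expected_anchor, atol=1e-6)
        expected_dir = rot @ np.array([1.0, 0.0])
        assert abs(axis.direction[:2] @ expected_dir) == pytest.approx(1.0, abs=1e-9)

    def test_single_midpoint_is_degenerate(self, nucleus_table):
        a = nucleus_table([[0, 0, 0]])
        b = nucleus_table([[0, 10, 0]])
        with pytest.raises(ValueError):
            g.fit_midline(a, b)


class TestOrientation:
    def _axis(self):
        return g.EmbryoAxis(anchor=np.zeros(3), direction=np.array([1.0, 0, 0]))

    def test_sparser_end_is_anterior(self, nucleus_table):
        rng = np.random.default_rng(0)
        # 3 nuclei in the first 60 µm, 30 in the last 60 µm of a 300 µm span
        x = np.concatenate([rng.uniform(0, 60, 3), rng.uniform(120, 240, 40), rng.uniform(240, 300, 30)])
        nuc = nucleus_table(np.column_stack([x, rng.uniform(0, 30, len(x)), np.zeros(len(x))]))
        axis = g.orient_anterior(self._axis(), nuc)
        assert axis.direction[0] == 1.0  # posterior points to +x
        assert axis.oriented

    def test_mirrored_dataset_flips(self, nucleus_table):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(0, 60, 3), rng.uniform(120, 240, 40), rng.uniform(240, 300, 30)])
        nuc = nucleus_table(np.column_stack([300 - x, rng.uniform(0, 30, len(x)), np.zeros(len(x))]))
        axis = g.orient_anterior(self._axis(), nuc)
        assert axis.direction[0] == -1.0

    def test_exact_tie_raises(self, nucleus_table):
        x = np.concatenate([np.linspace(0, 50, 5), np.full(10, 150.0), np.linspace(250, 300, 5)])
        nuc = nucleus_table(np.column_stack([x, np.zeros(len(x)), np.zeros(len(x))]))
        with pytest.raises(ValueError, match="tie"):
            g.orient_anterior(self._axis(), nuc)


class TestApPosition:
    def _oriented_axis(self):
        return g.EmbryoAxis(
            anchor=np.zeros(3),
            direction=np.array([1.0, 0, 0]),
            anterior_origin=0.0,
            oriented=True,
        )

    def test_projection_arithmetic(self):
        ap, el = g.ap_position(np.array([[130.0, 40.0, 3.0]]), self._oriented_axis())
        assert ap[0] == pytest.approx(130.0)
        assert el[0] == pytest.approx(26.0)

    def test_perpendicular_displacement_invariant(self):
        axis = self._oriented_axis()
        ap1, _ = g.ap_position(np.array([[50.0, 0.0, 0.0]]), axis)
        ap2, _ = g.ap_position(np.array([[50.0, 35.0, 7.0]]), axis)
        assert ap1[0] == pytest.approx(ap2[0])

    def test_unoriented_axis_refuses(self):
        axis = g.EmbryoAxis(anchor=np.zeros(3), direction=np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            g.ap_position(np.zeros((1, 3)), axis)


class TestTerritories:
    def test_nearest_and_tie_rule(self, nucleus_table, spot_table):
        nuc = nucleus_table([[0, 0, 0], [10, 0, 0]], ids=[7, 3])
        spots = spot_table([[1, 0, 0], [5, 0, 0]])
        out = g.assign_territories(spots, nuc)
        assert out["nucleus_id"].tolist() == [7, 3]  # nearest, then lowest id on the tie

    def test_matches_brute_force(self, nucleus_table, spot_table):
        rng = np.random.default_rng(9)
        nxyz = rng.uniform(0, 100, (40, 3))
        nuc = nucleus_table(nxyz, ids=rng.permutation(40))
        sxyz = rng.uniform(0, 100, (1000, 3))
        spots = spot_table(sxyz)
        out = g.assign_territories(spots, nuc)
        expected = brute_nearest_nucleus(sxyz, nxyz, nuc["id"].to_numpy())
        assert np.array_equal(out["nucleus_id"].to_numpy(), expected)

    def test_no_nuclei_raises(self, nucleus_table, spot_table):
        with pytest.raises(ValueError):
            g.assign_territories(spot_table([[0, 0, 0]]), nucleus_table(np.zeros((0, 3))))


class TestAxisRecovery:
    def test_rigid_motion_leaves_ap_unchanged(self):
        cfg = EmbryoConfig(rng_seed=21, orientation_deg=0.0)
        nuc, _ = simulate.generate_nuclei(cfg)
        axis, retained = g.estimate_axis(nuc, frame_size=cfg.frame_size)
        ap0, _ = g.ap_position(retained[["x_um", "y_um", "z_um"]].to_numpy(), axis)

        cfg_rot = EmbryoConfig(rng_seed=21, orientation_deg=9.0, midline_offset_um=6.0)
        nuc_r, truth_r = simulate.generate_nuclei(cfg_rot)
        axis_r, retained_r = g.estimate_axis(nuc_r, frame_size=cfg_rot.frame_size)
        # same generative axis position error bound in both orientations
        xy = retained_r[["x_um", "y_um"]].to_numpy()
        ap_est = axis_r.project(xy) - axis_r.anterior_origin
        ap_true = truth_r.ap_of(xy)
        ap_true -= ap_true.min()
        d = g.internuclear_distance(retained_r)
        assert np.mean(np.abs(ap_est - ap_true)) < d / 2

    def test_anterior_matches_truth_across_seeds(self):
        ok = 0
        rng = np.random.default_rng(5)
        for i in range(20):
            cfg = EmbryoConfig(
                rng_seed=300 + i,
                orientation_deg=rng.uniform(-15, 15) + 180 * (rng.random() < 0.5),
                midline_offset_um=rng.uniform(-10, 10),
            )
            nuc, truth = simulate.generate_nuclei(cfg)
            axis, _ = g.estimate_axis(nuc, frame_size=cfg.frame_size)
            ok += axis.direction[:2] @ truth.direction_xy > 0
        assert ok == 20
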