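"""Synthetic-embryo generator: determinism, structure and distributions."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from tagtrace import simulate
from tagtrace.config import ConstantProfile, EmbryoConfig, PlateauProfile
from tagtrace.io import make_spot_table


class TestNuclei:
    def test_zero_nuclei_axis_still_defined(self):
        cfg = EmbryoConfig(rng_seed=0, n_nuclei=0)
        nuclei, axis = simulate.generate_nuclei(cfg)
        assert len(nuclei) == 0
        assert np.isfinite(axis.tip_xy).all()
        assert np.linalg.norm(axis.direction_xy) == pytest.approx(1.0)

    def test_determinism_byte_identical(self):
        cfg = EmbryoConfig(rng_seed=42, orientation_deg=5.0)
        a, _ = simulate.generate_nuclei(cfg)
        b, _ = simulate.generate_nuclei(EmbryoConfig(rng_seed=42, orientation_deg=5.0))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_zero_jitter_gives_hexagonal_lattice_constant(self):
        cfg = EmbryoConfig(rng_seed=3, internuclear_jitter=0.0, z_jitter=0.0)
        nuclei, axis = simulate.generate_nuclei(cfg)
        xy = nuclei[["x_um", "y_um"]].to_numpy()
        d, _ = cKDTree(xy).query(xy, k=2)
        nn = d[:, 1]
        # hexagonal lattice: every nearest-neighbour distance is the constant
        assert nn.std() / nn.mean() < 1e-9
        # independent oracle: lattice constant from density over the visible area
        area = simulate._visible_area(cfg, axis, step=0.25)
        expected = np.sqrt(2.0 * area / (np.sqrt(3.0) * cfg.n_nuclei))
        assert nn.mean() == pytest.approx(expected, rel=0.01)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            simulate.generate_nuclei(EmbryoConfig(rng_seed=0, n_nuclei=5000))

    def test_nuclei_inside_frame_and_embryo(self):
        cfg = EmbryoConfig(rng_seed=8, orientation_deg=-12.0)
        nuclei, axis = simulate.generate_nuclei(cfg)
        xy = nuclei[["x_um", "y_um"]].to_numpy()
        fx, fy, _ = cfg.frame_size
        assert (xy >= 0).all() and (xy[:, 0] <= fx).all() and (xy[:, 1] <= fy).all()
        assert axis.inside(xy).all()


class TestSpots:
    def test_no_translation_no_sites(self):
        cfg = EmbryoConfig(rng_seed=1, translated_profile=ConstantProfile(0.0))
        gt = simulate.generate_embryo(cfg)
        assert gt.truth["translated"].sum() == 0
        # protein channel holds only free proteins / aggregates
        assert (gt.protein_kind != "site").all()

    def test_full_translation_every_mrna_paired(self):
        cfg = EmbryoConfig(
            rng_seed=2,
            translated_profile=ConstantProfile(1.0),
            aggregate_density=0.0,
            free_protein_density=0.0,
            nuclear_fraction=0.0,
        )
        gt = simulate.generate_embryo(cfg)
        assert gt.truth["translated"].all()
        site_pos = gt.spots["protein"][["x_um", "y_um", "z_um"]].to_numpy()
        mrna_pos = gt.truth[["x_um", "y_um", "z_um"]].to_numpy()
        d, _ = cKDTree(site_pos).query(mrna_pos)
        assert (d < 0.6).all()

    def test_translated_fraction_binomial(self):
        cfg = EmbryoConfig(
            rng_seed=5,
            translated_profile=ConstantProfile(0.5),
            expression_profile=PlateauProfile(amplitude=80.0),
        )
        gt = simulate.generate_embryo(cfg)
        n = len(gt.truth)
        assert n >= 10000
        frac = gt.truth["translated"].mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_territory_truth_counts_conserve(self, small_embryo):
        truth = small_embryo.truth
        per_nucleus = truth.groupby("nucleus_id").size()
        assert per_nucleus.sum() == len(truth)
        assert (truth[truth["translated"]]["ribosomes"] >= 1).all()
        assert (truth[~truth["translated"]]["ribosomes"] == 0).all()

    def test_site_intensity_encodes_ribosomes(self, small_embryo):
        cfg = small_embryo.config
        truth = small_embryo.truth
        sites = small_embryo.spots["protein"].iloc[: (truth["protein_id"] >= 0).sum()]
        c = simulate.correction_factor_of(cfg)
        tr = truth[truth["protein_id"] >= 0].sort_values("protein_id")
        expected = tr["ribosomes"].to_numpy() * cfg.single_protein_intensity * c
        ratio = sites["intensity"].to_numpy() / expected
        # multiplicative noise has median 1 at 10% cv
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)


class TestProbePairs:
    def test_point_mass_zero_coincides(self):
        cfg = EmbryoConfig(
            rng_seed=4,
            translating_compaction_median=0.0,
            nontranslating_compaction_median=0.0,
        )
        gt = simulate.generate_embryo(cfg)
        pp = simulate.generate_probe_pairs(cfg, gt)
        n = len(gt.truth)
        d = np.linalg.norm(
            pp.five[["x_um", "y_um", "z_um"]].to_numpy()
            - pp.three[["x_um", "y_um", "z_um"]].to_numpy()[:n],
            axis=1,
        )
        assert np.allclose(d, 0.0)

    def test_point_mass_exact_distance(self):
        cfg = EmbryoConfig(
            rng_seed=4,
            compaction_sigma=0.0,
            translating_compaction_median=0.3,
            nontranslating_compaction_median=0.3,
        )
        gt = simulate.generate_embryo(cfg)
        pp = simulate.generate_probe_pairs(cfg, gt)
        n = len(gt.truth)
        d = np.linalg.norm(
            pp.five[["x_um", "y_um", "z_um"]].to_numpy()
            - pp.three[["x_um", "y_um", "z_um"]].to_numpy()[:n],
            axis=1,
        )
        assert np.allclose(d, 0.3)

    def test_class_medians_ordered(self):
        cfg = EmbryoConfig(rng_seed=6, expression_profile=PlateauProfile(amplitude=10.0))
        gt = simulate.generate_embryo(cfg)
        pp = simulate.generate_probe_pairs(cfg, gt)
        tr = pp.pairs[pp.pairs["translating"]]["distance_um"]
        nt = pp.pairs[~pp.pairs["translating"]]["distance_um"]
        assert len(tr) > 200 and len(nt) > 200
        assert tr.median() > nt.median()


class TestRendering:
    def test_intensity_conservation_single_spot(self):
        spots = make_spot_table(np.array([[5.0, 5.0, 3.0]]), 1000.0, "mrna")
        img = simulate.render_spots(spots, (10, 10, 6), (0.12, 0.12, 0.3))
        assert img.sum() == pytest.approx(1000.0, rel=0.01)

    def test_zero_spots_pure_noise(self):
        spots = make_spot_table(np.zeros((0, 3)), np.zeros(0), "mrna")
        img = simulate.render_spots(
            spots, (5, 5, 3), (0.12, 0.12, 0.3),
            noise=simulate.NoiseModel(background=20.0, read_sigma=2.0, seed=0),
        )
        assert img.mean() == pytest.approx(20.0, abs=1.0)

    def test_grid_overflow_raises(self):
        spots = make_spot_table(np.array([[1.0, 1.0, 1.0]]), 1.0, "mrna")
        with pytest.raises(ValueError):
            simulate.render_spots(spots, (1000, 1000, 10), (0.01, 0.01, 0.3))


class TestTimelapse:
    def test_no_dropout_no_jitter_constant_positions(self):
        cfg = EmbryoConfig(
            rng_seed=9, n_frames=10, dropout_rate=0.0, site_jitter=0.0,
            free_protein_density=0.0, n_tethered_sites=15,
        )
        tl = simulate.generate_timelapse(cfg)
        assert tl.sites.groupby("track_id")["frame"].count().eq(10).all()
        assert tl.sites.groupby("track_id")["x_um"].std().fillna(0).max() == 0.0

    def test_dropout_rate_recovered(self):
        cfg = EmbryoConfig(
            rng_seed=10, n_frames=50, dropout_rate=0.2,
            free_protein_density=0.0, n_tethered_sites=100,
        )
        tl = simulate.generate_timelapse(cfg)
        n_expected = 50 * 100
        missing = 1.0 - len(tl.sites) / n_expected
        se = np.sqrt(0.2 * 0.8 / n_expected)
        assert abs(missing - 0.2) < 3 * se

    def test_determinism(self):
        cfg = EmbryoConfig(rng_seed=12, n_frames=5)
        a = simulate.generate_timelapse(cfg).sites
        b = simulate.generate_timelapse(EmbryoConfig(rng_seed=12, n_frames=5)).sites
        assert a.to_csv(index=False) == b.to_csv(index=False)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = EmbryoConfig(rng_seed=77, nuclear_cycle="nc14", orientation_deg=-9.5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = EmbryoConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            EmbryoConfig(nuclear_fraction=1.5)
        with pytest.raises(ValueError):
            EmbryoConfig(nucleus_radius=-1.0)
        with pytest.raises(ValueError):
            EmbryoConfig(nuclear_cycle="nc15")
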