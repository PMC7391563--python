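"""Landmark I/O, linear traits, jaw standardisation, GPA, PCA, projection."""

import math

import numpy as np
import pytest

from sandsift import morphshape as ms
from sandsift import simcross
from sandsift.morphshape import (LandmarkConfig, bending_energy,
                                 bending_energy_matrix, gpa, linear_distances,
                                 mouth_angle, procrustes_distance, project,
                                 read_tps, shape_pca, standardize_jaw, write_tps)


def config_from(base, **kwargs):
    return LandmarkConfig(id=kwargs.pop("id", "spec"), coords=base, **kwargs)


class TestTpsIO:
    def test_round_trip(self, tmp_path, base_shape):
        cfgs = [config_from(base_shape + i, id=f"s{i}") for i in range(3)]
        path = tmp_path / "shapes.tps"
        write_tps(cfgs, path)
        back = read_tps(path)
        assert [c.id for c in back] == ["s0", "s1", "s2"]
        for a, b in zip(cfgs, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_scale_applied(self, tmp_path, base_shape):
        path = tmp_path / "scaled.tps"
        lines = [f"LM={len(base_shape)}"]
        lines += [f"{x} {y}" for x, y in base_shape]
        lines += ["ID=sc", "SCALE=0.5"]
        path.write_text("\n".join(lines) + "\n")
        cfg = read_tps(path)[0]
        np.testing.assert_allclose(cfg.coords, base_shape * 0.5)

    def test_malformed_count_names_record(self, tmp_path, base_shape):
        path = tmp_path / "bad.tps"
        lines = ["LM=13"] + [f"{x} {y}" for x, y in base_shape[:5]] + ["ID=broken"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="broken"):
            read_tps(path)

    def test_hypural_point_gives_sl(self, tmp_path, base_shape):
        cfg = config_from(base_shape, hypural=np.array([30.0, 1.2]))
        path = tmp_path / "hyp.tps"
        write_tps([cfg], path)
        back = read_tps(path)[0]
        expected = float(np.linalg.norm(np.array([30.0, 1.2]) - base_shape[7]))
        assert back.sl == pytest.approx(expected)


class TestLinearTraits:
    def test_three_four_five_triangle(self, base_shape):
        coords = base_shape.copy()
        coords[0] = [0.0, 0.0]     # landmark 1
        coords[12] = [3.0, 4.0]    # landmark 15
        d = linear_distances(config_from(coords))
        assert d["EpD"] == pytest.approx(5.0)

    def test_coincident_points_zero(self, base_shape):
        coords = base_shape.copy()
        coords[2] = coords[3]      # landmarks 3, 4
        assert linear_distances(config_from(coords))["LJL"] == 0.0

    def test_fixture_hand_arithmetic(self, base_shape):
        cfg = config_from(base_shape)
        pairs = {"EpD": (0, 12), "LJL": (2, 3), "ML": (2, 7), "EyL": (4, 5)}
        d = linear_distances(cfg)
        for name, (i, j) in pairs.items():
            expected = math.hypot(*(base_shape[i] - base_shape[j]))
            assert d[name] == pytest.approx(expected, abs=1e-12)


class TestMouthAngle:
    def _with_vectors(self, base, eye, jaw):
        coords = base.copy()
        coords[4] = [0.0, 0.0]                 # landmark 5
        coords[5] = eye                        # landmark 6
        coords[7] = [5.0, 5.0]                 # landmark 10
        coords[2] = np.array([5.0, 5.0]) + jaw  # landmark 3
        return config_from(coords)

    def test_parallel_vectors_zero(self, base_shape):
        cfg = self._with_vectors(base_shape, [1.0, 0.0], [1.0, 0.0])
        assert mouth_angle(cfg) == pytest.approx(0.0, abs=1e-12)

    def test_downward_jaw_positive_45(self, base_shape):
        cfg = self._with_vectors(base_shape, [1.0, 0.0], [1.0, -1.0])
        assert mouth_angle(cfg) == pytest.approx(45.0, abs=1e-12)

    def test_common_rotation_invariant(self, base_shape):
        cfg = self._with_vectors(base_shape, [1.0, 0.2], [0.8, -0.5])
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        cfg2 = config_from(cfg.coords @ rot.T)
        assert mouth_angle(cfg2) == pytest.approx(mouth_angle(cfg), abs=1e-9)


class TestStandardizeJaw:
    def _with_angle(self, base, deg):
        coords = base.copy()
        coords[2] = [0.0, 0.0]                               # landmark 3
        coords[7] = [1.0, 0.0]                               # landmark 10
        rad = math.radians(deg)
        coords[3] = [0.8 * math.cos(rad), 0.8 * math.sin(rad)]  # landmark 4
        return config_from(coords)

    def test_two_specimens_meet_at_mean(self, base_shape):
        cfgs = [self._with_angle(base_shape, 20.0), self._with_angle(base_shape, 40.0)]
        out = standardize_jaw(cfgs)
        for cfg in out:
            ang = math.degrees(ms._signed_angle(cfg.point(10) - cfg.point(3),
                                                cfg.point(4) - cfg.point(3)))
            assert ang == pytest.approx(30.0, abs=1e-9)

    def test_jaw_length_preserved(self, base_shape):
        cfgs = [self._with_angle(base_shape, 10.0), self._with_angle(base_shape, 50.0)]
        out = standardize_jaw(cfgs)
        for before, after in zip(cfgs, out):
            assert np.linalg.norm(after.point(4) - after.point(3)) == \
                pytest.approx(np.linalg.norm(before.point(4) - before.point(3)))

    def test_already_at_mean_noop(self, base_shape):
        cfgs = [self._with_angle(base_shape, 30.0)] * 3
        out = standardize_jaw(cfgs)
        np.testing.assert_allclose(out[0].coords, cfgs[0].coords, atol=1e-12)


class TestGpa:
    def test_identical_shapes_zero_distance(self, base_shape):
        space = gpa([config_from(base_shape, id="a"),
                     config_from(base_shape, id="b")], slide=False)
        assert procrustes_distance(space.aligned[0], space.aligned[1]) < 1e-10

    def test_similarity_transform_invariance(self, base_shape, rng):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        other = 2.7 * base_shape @ rot.T + rng.normal(0, 10, size=2)
        space = gpa([config_from(base_shape, id="a"), config_from(other, id="b")],
                    slide=False)
        assert procrustes_distance(space.aligned[0], space.aligned[1]) <= 1e-8

    def test_degenerate_config_rejected(self):
        flat = np.zeros((13, 2))
        with pytest.raises(ValueError, match="degenerate"):
            gpa([config_from(flat, id="a"), config_from(flat, id="b")])

    def test_consensus_is_least_squares_optimum(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.05, (13, 2)), id=f"s{i}")
                for i in range(8)]
        space = gpa(cfgs, slide=False)
        # no further rotation of any specimen can reduce its distance
        for x in space.aligned:
            r = ms._optimal_rotation(x, space.consensus)
            np.testing.assert_allclose(r, np.eye(2), atol=1e-6)

    def test_sliding_reduces_bending_energy(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.08, (13, 2)), id=f"s{i}")
                for i in range(10)]
        no_slide = gpa(cfgs, slide=False)
        slid = gpa(cfgs, slide=True)
        be0 = bending_energy_matrix(no_slide.consensus)
        e0 = sum(bending_energy(x, no_slide.consensus, be0) for x in no_slide.aligned)
        be1 = bending_energy_matrix(slid.consensus)
        e1 = sum(bending_energy(x, slid.consensus, be1) for x in slid.aligned)
        assert e1 <= e0 + 1e-12

    def test_single_slide_pass_monotone(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.08, (13, 2)), id=f"s{i}")
                for i in range(6)]
        space = gpa(cfgs, slide=False)
        be = bending_energy_matrix(space.consensus)
        for x in space.aligned:
            e_before = bending_energy(x, space.consensus, be)
            e_after = bending_energy(ms._slide_pass(x, space.consensus, be),
                                     space.consensus, be)
            assert e_after <= e_before + 1e-12


class TestAllometryFree:
    def test_zero_allometry_unchanged(self, base_shape, rng):
        cfgs = simcross.simulate_landmarks({"A": 40}, {"A": base_shape},
                                           noise_sd=0.01, seed=61)
        space = gpa(cfgs, slide=False)
        log_sl = np.log10(space.meta["sl"].to_numpy(float))
        adj, report = ms.allometry_free(space, log_sl, n_perm=99, seed=1)
        assert report["p_perm"] > 0.05
        assert np.abs(adj.aligned - space.aligned).max() < 0.02

    def test_residuals_uncorrelated_with_size(self, base_shape):
        allo = np.zeros((13, 2))
        allo[12] = [0.0, 0.6]
        cfgs = simcross.simulate_landmarks({"A": 200}, {"A": base_shape},
                                           allometry=allo, log_sl_sd=0.15,
                                           noise_sd=0.003, seed=62)
        space = gpa(cfgs, slide=False)
        log_sl = np.log10(space.meta["sl"].to_numpy(float))
        adj, report = ms.allometry_free(space, log_sl, n_perm=99, seed=2)
        assert report["p_perm"] <= 0.01
        y = adj.aligned.reshape(len(cfgs), -1)
        corr = np.corrcoef(np.column_stack([log_sl[:, None], y]).T)[0, 1:]
        assert np.nanmax(np.abs(corr)) < 0.05

    def test_separate_group_regressions(self, base_shape):
        allo = np.zeros((13, 2))
        allo[12] = [0.0, 0.6]
        a = simcross.simulate_landmarks({"A": 60}, {"A": base_shape},
                                        allometry=allo, log_sl_mean=1.8,
                                        log_sl_sd=0.1, noise_sd=0.003, seed=63)
        b = simcross.simulate_landmarks({"B": 60}, {"B": base_shape},
                                        allometry=-allo, log_sl_mean=2.4,
                                        log_sl_sd=0.1, noise_sd=0.003, seed=64)
        space = gpa(a + b, slide=False)
        log_sl = np.log10(space.meta["sl"].to_numpy(float))
        groups = np.array(["A"] * 60 + ["B"] * 60)
        adj, _ = ms.allometry_free(space, log_sl, groups=groups, n_perm=49, seed=3)
        y = adj.aligned.reshape(120, -1)
        for sel in (groups == "A", groups == "B"):
            x = log_sl[sel] - log_sl[sel].mean()
            beta = x @ (y[sel] - y[sel].mean(0)) / (x @ x)
            assert np.abs(beta).max() < 0.05


class TestShapePcaAndProject:
    def test_known_direction_recovered(self, base_shape):
        rng = np.random.default_rng(65)
        direction = np.zeros((13, 2))
        direction[3] = [0.5, 0.0]
        cfgs = []
        for i in range(60):
            t = rng.normal(0, 0.2)
            cfgs.append(config_from(base_shape + t * direction +
                                    rng.normal(0, 0.003, (13, 2)), id=f"s{i}"))
        space = shape_pca(gpa(cfgs, slide=False))
        assert space.var_frac[0] > 0.7
        lo = config_from(base_shape - 0.2 * direction, id="lo")
        hi = config_from(base_shape + 0.2 * direction, id="hi")
        ref = gpa([lo, hi], slide=False)
        axis_true = (ref.aligned[1] - ref.aligned[0]).reshape(-1)
        cos = abs(space.axes[:, 0] @ axis_true) / np.linalg.norm(axis_true)
        assert cos > 0.99

    def test_scores_covariance_diagonal(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.05, (13, 2)), id=f"s{i}")
                for i in range(20)]
        space = shape_pca(gpa(cfgs, slide=False))
        cov = np.cov(space.scores[:, :5].T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10 * max(1.0, np.abs(cov).max() / 1e-4)

    def test_self_projection_identity(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.05, (13, 2)), id=f"s{i}")
                for i in range(15)]
        space = shape_pca(gpa(cfgs, slide=False))
        proj = project(cfgs[:5], space)
        assert np.abs(proj.to_numpy() - space.scores[:5]).max() <= 1e-8

    def test_consensus_projects_to_near_zero(self, base_shape, rng):
        cfgs = [config_from(base_shape + rng.normal(0, 0.05, (13, 2)), id=f"s{i}")
                for i in range(15)]
        space = shape_pca(gpa(cfgs, slide=False))
        proj = project([config_from(space.consensus, id="cons")], space)
        # consensus sits at the centroid up to the tiny mean/consensus gap
        assert np.abs(proj.to_numpy()).max() < 1e-3

    def test_held_out_specimens_cluster_with_class(self, base_shape):
        rng = np.random.default_rng(66)
        shift = np.zeros((13, 2))
        shift[0] = [0.4, 0.0]
        means = {"A": base_shape, "B": base_shape + shift}
        cfgs = simcross.simulate_landmarks({"A": 30, "B": 30}, means,
                                           noise_sd=0.01, seed=67)
        space = shape_pca(gpa(cfgs, slide=False))
        held = simcross.simulate_landmarks({"B": 10}, means, noise_sd=0.01, seed=68)
        proj = project(held, space)
        cls = space.meta["cls"].to_numpy()
        mean_a = space.scores[cls == "A", 0].mean()
        mean_b = space.scores[cls == "B", 0].mean()
        held_mean = proj["PC1"].mean()
        assert abs(held_mean - mean_b) < abs(held_mean - mean_a)
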