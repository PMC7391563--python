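"""Genotype-probability HMM, EM/nonparametric scans, permutations, intervals.

The HMM is checked against an exhaustive hidden-path enumeration oracle and
the EM scan against its closed-form reduction at a fully typed marker.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sandsift import linkmap, qtlscan, simcross
from sandsift.linkmap import kosambi_inverse
from sandsift.qtlscan import (F2_PRIOR, bayes_interval, calc_genoprob,
                              f2_transition_matrix, perm_threshold, pve,
                              scan_em, scan_np)


def toy_map(positions, name="LG01"):
    table = pd.DataFrame({
        "group": name,
        "marker": [f"m{i}" for i in range(len(positions))],
        "pos_cM": positions,
    })
    return linkmap.map_from_table(table)


def enumerate_posterior(obs, positions, error_prob):
    """Brute-force P(true genotype | observations) over all hidden paths."""
    k = len(positions)
    trans = [f2_transition_matrix(kosambi_inverse(d)) for d in np.diff(positions)]

    def emit(o, g):
        if o < 0:
            return 1.0
        return 1.0 - error_prob if o == g else error_prob / 2.0

    post = np.zeros((k, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=k):
        p = F2_PRIOR[path[0]] * emit(obs[0], path[0])
        for j in range(1, k):
            p *= trans[j - 1][path[j - 1], path[j]] * emit(obs[j], path[j])
        total += p
        for j in range(k):
            post[j, path[j]] += p
    return post / total


class TestCalcGenoprob:
    def test_zero_error_degenerate_at_typed_marker(self):
        lmap = toy_map([0.0, 10.0, 20.0])
        codes = pd.DataFrame([[0, 1, 2]], index=["i1"], columns=["m0", "m1", "m2"])
        grid = calc_genoprob(codes, lmap, step=1.0, error_prob=0.0)
        marker_idx = np.flatnonzero(grid.table["is_marker"].to_numpy())
        for j, g in zip(marker_idx, [0, 1, 2]):
            np.testing.assert_allclose(grid.probs[0, j], np.eye(3)[g], atol=1e-12)

    def test_single_marker_bayes_posterior(self):
        # prior (1/4, 1/2, 1/4), observation AA with error 0.05
        lmap = toy_map([0.0])
        codes = pd.DataFrame([[0]], index=["i1"], columns=["m0"])
        grid = calc_genoprob(codes, lmap, step=1.0, error_prob=0.05)
        expected = np.array([0.25 * 0.95, 0.5 * 0.025, 0.25 * 0.025])
        expected /= expected.sum()
        np.testing.assert_allclose(grid.probs[0, 0], expected, atol=1e-12)
        assert grid.probs[0, 0, 0] == pytest.approx(0.927, abs=5e-4)

    @pytest.mark.parametrize("obs", [
        [0, 1, 2], [1, -1, 2], [-1, -1, 0], [2, 2, 2],
    ])
    def test_forward_backward_equals_enumeration(self, obs):
        positions = [0.0, 7.5, 23.0]
        lmap = toy_map(positions)
        codes = pd.DataFrame([obs], index=["i1"],
                             columns=[f"m{i}" for i in range(3)])
        grid = calc_genoprob(codes, lmap, step=0.0, error_prob=0.05)
        oracle = enumerate_posterior(obs, np.array(positions), 0.05)
        np.testing.assert_allclose(grid.probs[0], oracle, atol=1e-10)

    def test_four_marker_chain_with_pseudomarkers(self):
        # the oracle enumerates over the full grid: interval transitions use
        # the map function gap by gap, so pseudomarkers are part of the chain
        positions = [0.0, 5.0, 11.0, 30.0]
        lmap = toy_map(positions)
        obs = [0, -1, 1, 2]
        codes = pd.DataFrame([obs], index=["i1"],
                             columns=[f"m{i}" for i in range(4)])
        grid = calc_genoprob(codes, lmap, step=10.0, error_prob=0.05)
        grid_pos = grid.table["pos_cM"].to_numpy()
        grid_obs = np.full(len(grid_pos), -1)
        for o, p in zip(obs, positions):
            grid_obs[np.abs(grid_pos - p).argmin()] = o
        oracle = enumerate_posterior(grid_obs, grid_pos, 0.05)
        np.testing.assert_allclose(grid.probs[0], oracle, atol=1e-10)

    def test_rows_sum_to_one(self, small_cross):
        smap, codes = small_cross
        lmap = linkmap.map_from_table(
            smap.marker_table().reset_index().rename(
                columns={"chrom": "group", "pos_cM": "pos_cM"}))
        grid = calc_genoprob(codes, lmap, step=2.0)
        np.testing.assert_allclose(grid.probs.sum(axis=2), 1.0, atol=1e-9)


def sim_grid_and_phen(seed, n=150, n_chr=2, qtl_effect=0.8, step=2.0,
                      sigma=1.0):
    smap = simcross.simulate_map(n_chr, 50.0, 6, seed=seed)
    codes = simcross.simulate_f2(smap, n, seed=seed + 1)
    arch = simcross.QtlArchitecture(
        qtl=(simcross.Qtl("chr01", 20.0, qtl_effect),), sigma_e=sigma)
    phen = simcross.simulate_phenotypes(codes, smap, arch, seed=seed + 2)
    y = phen.loc[phen["class"] == "F2", "value"].reindex(codes.index)
    lmap = linkmap.map_from_table(
        smap.marker_table().reset_index().rename(columns={"chrom": "group"}))
    grid = calc_genoprob(codes, lmap, step=step)
    return grid, y, codes


class TestScanEm:
    def test_reduction_at_typed_marker(self):
        grid, y, codes = sim_grid_and_phen(seed=71, step=0.0)
        grid0 = calc_genoprob(codes, linkmap.map_from_table(
            grid.table[grid.table["is_marker"]]
            .rename(columns={"marker": "marker"})
            .assign(marker=lambda d: d["marker"])[["group", "marker", "pos_cM"]]),
            step=0.0, error_prob=0.0)
        curve = scan_em(grid0, y, tol=1e-12)
        yv = y.to_numpy()
        n = len(yv)
        rss0 = np.sum((yv - yv.mean()) ** 2)
        for j, row in grid0.table.iterrows():
            g = codes[row["marker"]].to_numpy()
            rss1 = sum(np.sum((yv[g == k] - yv[g == k].mean()) ** 2)
                       for k in range(3) if (g == k).any())
            expected = (n / 2.0) * math.log10(rss0 / rss1)
            assert curve.table.loc[j, "lod"] == pytest.approx(expected, abs=1e-6)

    def test_affine_invariance(self):
        grid, y, _ = sim_grid_and_phen(seed=72)
        a = scan_em(grid, y)
        b = scan_em(grid, 3.5 * y - 11.0)
        np.testing.assert_allclose(a.lod, b.lod, atol=1e-5)

    def test_null_phenotype_small_peak(self):
        rng = np.random.default_rng(73)
        hits = 0
        for _ in range(20):
            grid, y, _ = sim_grid_and_phen(seed=int(rng.integers(2 ** 30)),
                                           qtl_effect=0.0, step=5.0, n=100)
            curve = scan_em(grid, y)
            hits += curve.max_lod > 3.0
        assert hits <= 2

    def test_qtl_peak_near_truth(self):
        grid, y, _ = sim_grid_and_phen(seed=74, n=250)
        curve = scan_em(grid, y)
        peak = curve.peak()
        assert peak["group"] == "chr01"
        assert abs(peak["pos_cM"] - 20.0) <= 10.0

    def test_additive_covariate_absorbs_shift(self):
        grid, y, _ = sim_grid_and_phen(seed=75, n=120)
        rng = np.random.default_rng(75)
        sex = rng.integers(0, 2, size=len(y)).astype(float)
        y_shifted = y + 5.0 * sex
        plain = scan_em(grid, y_shifted)
        adjusted = scan_em(grid, y_shifted, covariates=sex)
        base = scan_em(grid, y)
        # covariate model recovers the clean scan; the plain one is distorted
        assert np.abs(adjusted.lod - base.lod).max() < \
            np.abs(plain.lod - base.lod).max()
        assert np.abs(adjusted.lod - base.lod).mean() < 0.5

    def test_interactive_covariate_detects_sex_specific_qtl(self):
        rng = np.random.default_rng(76)
        smap = simcross.simulate_map(1, 50.0, 6, seed=77)
        codes = simcross.simulate_f2(smap, 300, seed=78)
        sex = rng.integers(0, 2, size=300).astype(float)
        g = codes["chr01_m003"].to_numpy()          # marker at 20 cM
        y = pd.Series((1.0 - g) * 1.2 * sex + rng.normal(0, 1, 300),
                      index=codes.index)
        lmap = linkmap.map_from_table(
            smap.marker_table().reset_index().rename(columns={"chrom": "group"}))
        grid = calc_genoprob(codes, lmap, step=5.0)
        add = scan_em(grid, y, covariates=sex, interactive=False)
        full = scan_em(grid, y, covariates=sex, interactive=True)
        assert full.max_lod > add.max_lod
        assert abs(full.peak()["pos_cM"] - 20.0) <= 10.0


class TestScanNp:
    def test_constant_phenotype_zero(self):
        grid, y, _ = sim_grid_and_phen(seed=81, n=60)
        curve = scan_np(grid, pd.Series(np.ones(len(y)), index=y.index))
        assert np.allclose(curve.lod, 0.0)

    def test_reduction_to_kruskal_wallis(self):
        grid, y, codes = sim_grid_and_phen(seed=82, step=0.0)
        grid0 = calc_genoprob(codes, linkmap.map_from_table(
            grid.table[grid.table["is_marker"]][["group", "marker", "pos_cM"]]),
            step=0.0, error_prob=0.0)
        curve = scan_np(grid0, y)
        yv = y.to_numpy()
        for j, row in grid0.table.iterrows():
            g = codes[row["marker"]].to_numpy()
            groups = [yv[g == k] for k in range(3) if (g == k).any()]
            h = stats.kruskal(*groups).statistic
            assert curve.table.loc[j, "lod"] == pytest.approx(h / (2 * math.log(10)),
                                                              abs=1e-8)

    def test_monotone_relation_positive_lod(self):
        grid, _, codes = sim_grid_and_phen(seed=83, n=200)
        g = codes["chr01_m003"].to_numpy().astype(float)
        y = pd.Series(g + np.random.default_rng(83).normal(0, 0.3, len(g)),
                      index=codes.index)
        curve = scan_np(grid, y)
        peak = curve.peak()
        assert peak["group"] == "chr01" and curve.max_lod > 3.0


class TestPermutationsAndIntervals:
    def test_threshold_monotone_and_p_bounds(self):
        grid, y, _ = sim_grid_and_phen(seed=91, n=100, step=5.0)
        perms = perm_threshold(grid, y, n_perm=50, seed=5,
                               alphas=(0.05, 0.10, 0.37))
        assert perms.thresholds[0.05] >= perms.thresholds[0.10] >= perms.thresholds[0.37]
        assert perms.genomewide_p(1e9) == 1 / 51
        assert perms.genomewide_p(-1.0) == 1.0

    def test_two_position_toy_interval(self):
        table = pd.DataFrame({
            "group": "LG01", "pos_cM": [0.0, 10.0], "is_marker": [True, True],
            "marker": ["m0", "m1"],
            "lod": np.log10([0.96, 0.04]),
        })
        curve = qtlscan.LodCurve(table=table, model="normal_em",
                                 covariates="none", n=100)
        ci = bayes_interval(curve, prob=0.95)
        assert ci["low_cM"] == ci["high_cM"] == 0.0

    def test_flat_curve_spans_group(self):
        table = pd.DataFrame({
            "group": "LG01", "pos_cM": np.linspace(0, 40, 9),
            "is_marker": [True] + [False] * 7 + [True],
            "marker": ["m0"] + [""] * 7 + ["m1"],
            "lod": np.zeros(9),
        })
        curve = qtlscan.LodCurve(table=table, model="normal_em",
                                 covariates="none", n=50)
        ci = bayes_interval(curve, prob=0.95)
        assert ci["high_cM"] - ci["low_cM"] >= 35.0

    def test_interval_widened_to_markers_and_contains_peak(self):
        grid, y, _ = sim_grid_and_phen(seed=92, n=200)
        curve = scan_em(grid, y)
        ci = bayes_interval(curve)
        assert ci["low_marker_cM"] <= ci["peak_cM"] <= ci["high_marker_cM"]
        assert ci["low_marker_cM"] <= ci["low_cM"]
        assert ci["high_marker_cM"] >= ci["high_cM"]


class TestPve:
    @pytest.mark.parametrize("lod,n,expected", [
        (4.23, 107, 16.64),
        (3.67, 107, 14.61),
        (7.79, 103, 29.41),
        (5.02, 103, 20.10),
        (2.60, 19, 46.75),
    ])
    def test_reported_values(self, lod, n, expected):
        assert round(pve(lod, n), 2) == expected

    def test_zero_lod(self):
        assert pve(0.0, 100) == 0.0

    def test_monotonicity_and_range(self):
        lods = np.linspace(0, 30, 50)
        vals = [pve(l, 107) for l in lods]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v < 100 for v in vals)
        assert pve(5.0, 50) > pve(5.0, 200)
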