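"""Design construction, permutation inference, ANOVA and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from connparc.connectivity import sphere_seed
from connparc.glm import (build_design, permutation_glm, cluster_extent_fwe,
                          network_strength, anova_table, cohens_d,
                          sphere_grid_effects, PermutationGLM)


def _cov(n_per_group=10, centres=("c1", "c2"), seed=0, mean_fd=True):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("A", "B"):
        for i in range(n_per_group):
            rows.append({"subject_id": f"{g}{i}", "group": g,
                         "age_years": rng.uniform(8, 30),
                         "fiq": rng.normal(108, 10),
                         "centre": centres[i % len(centres)]})
    cov = pd.DataFrame(rows)
    if mean_fd:
        cov["mean_fd"] = rng.uniform(0.05, 0.3, len(cov))
    return cov


class TestBuildDesign:
    def test_single_centre_has_no_dummies(self):
        X, names = build_design(_cov(centres=("c1",)))
        assert not any(n.startswith("centre_") for n in names)

    def test_group_column_sums_to_zero_with_equal_groups(self):
        X, names = build_design(_cov())
        assert X[:, names.index("group")].sum() == pytest.approx(0.0)

    def test_hand_built_toy_matrix(self):
        # ten subjects: enough rows for the nine-column voxel design
        fiq = np.array([96.0, 111.0, 120.0, 104.0, 99.0, 118.0, 102.0,
                        95.0, 125.0, 107.0])
        fd = np.array([0.10, 0.28, 0.15, 0.22, 0.09, 0.30, 0.18, 0.11,
                       0.26, 0.14])
        gm = np.array([0.52, 0.61, 0.70, 0.48, 0.66, 0.57, 0.73, 0.44,
                       0.59, 0.63])
        ages = np.array([10.0, 17.0, 30.0, 12.0, 21.0, 28.0, 9.0, 15.0,
                         24.0, 19.0])
        cov = pd.DataFrame({
            "subject_id": list("abcdefghij"),
            "group": ["A"] * 5 + ["B"] * 5,
            "age_years": ages,
            "fiq": fiq,
            "centre": ["c1", "c2"] * 5,
            "mean_fd": fd,
        })
        X, names = build_design(cov, gm_values=gm)
        la_c = np.log(ages) - np.log(ages).mean()
        grp = np.array([1.0] * 5 + [-1.0] * 5)
        expect = np.column_stack([
            np.ones(10),
            [0, 1] * 5,
            fd - fd.mean(),
            fiq - fiq.mean(),
            la_c,
            grp,
            grp * la_c,
            gm - gm.mean(),
            grp * (gm - gm.mean()),
        ])
        assert names == ["intercept", "centre_c2", "mean_fd", "fiq",
                         "log_age", "group", "group_x_age", "gm",
                         "group_x_gm"]
        assert np.allclose(X, expect, atol=1e-12)

    def test_constant_gm_columns_dropped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            X, names = build_design(_cov(), gm_values=np.full(20, 0.5))
        assert "gm" not in names and "group_x_gm" not in names

    def test_rank_deficiency_is_an_error(self):
        cov = _cov()
        cov["fiq"] = cov["age_years"]  # fiq collinear with age... not quite
        cov["fiq"] = np.log(cov["age_years"])  # exactly collinear with log_age
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(cov)


class TestPermutationGlm:
    def test_permutation_p_floor(self):
        cov = _cov(n_per_group=10, centres=("c1",), mean_fd=False)
        effect = np.where(cov["group"] == "A", 5.0, -5.0)
        maps = effect[:, None] + 0.01 * np.random.default_rng(0).normal(
            size=(20, 1))
        res = permutation_glm(maps, cov, contrast="group", n_perm=99, seed=1)
        assert res.p_fwe_voxel[0] == pytest.approx(1 / 100)

    def test_fixed_seed_is_deterministic(self, rng):
        cov = _cov()
        maps = rng.normal(size=(20, 15))
        a = permutation_glm(maps, cov, n_perm=120, seed=7)
        b = permutation_glm(maps, cov, n_perm=120, seed=7)
        assert np.array_equal(a.null_max_stat, b.null_max_stat)
        assert np.array_equal(a.p_fwe_voxel, b.p_fwe_voxel)

    def test_constant_gm_reduces_to_gm_free_model(self, rng):
        cov = _cov(n_per_group=8)
        maps = rng.normal(size=(16, 12))
        gm = np.full((16, 12), 0.6)
        with pytest.warns(RuntimeWarning):
            with_gm = permutation_glm(maps, cov, n_perm=60, seed=3, gm=gm)
        without = permutation_glm(maps, cov, n_perm=60, seed=3)
        assert np.allclose(with_gm.tmap, without.tmap, atol=1e-8)
        assert np.allclose(with_gm.p_fwe_voxel, without.p_fwe_voxel,
                           atol=1e-12)

    def test_voxel_dependent_gm_interaction_detected(self, rng):
        # connectivity depends on GM with opposite slopes per group at
        # half the voxels
        cov = _cov(n_per_group=25, mean_fd=False)
        n, v = len(cov), 20
        gm = rng.uniform(0.3, 0.9, size=(n, v))
        grp = np.where(cov["group"] == "A", 1.0, -1.0)
        maps = 0.05 * rng.normal(size=(n, v))
        maps[:, :10] += 0.8 * grp[:, None] * (gm[:, :10] - 0.6)
        res = permutation_glm(maps, cov, contrast="group_x_gm", n_perm=200,
                              seed=5, gm=gm)
        assert (res.p_fwe_voxel[:10] <= 0.05).all()
        assert (res.p_fwe_voxel[10:] > 0.05).all()

    def test_unknown_contrast_rejected(self, rng):
        with pytest.raises(ValueError, match="not estimable"):
            permutation_glm(rng.normal(size=(20, 3)), _cov(),
                            contrast="does_not_exist", n_perm=10)

    def test_estimator_wrapper_exposes_fitted_attributes(self, rng):
        est = PermutationGLM(contrast="group", n_perm=50, random_state=2)
        params = est.get_params()
        assert params["n_perm"] == 50
        est.set_params(n_perm=60)
        est.fit(rng.normal(size=(20, 6)), covariates=_cov())
        assert est.tmap_.shape == (6,)
        assert est.p_fwe_voxel_.min() > 0


class TestClusterExtent:
    GRID = (5, 5, 3)

    def _vox(self):
        return np.argwhere(np.ones(self.GRID, bool))

    def test_subthreshold_map_gives_empty_table(self):
        z = np.zeros(75)
        table = cluster_extent_fwe(z, self._vox(), self.GRID, forming_z=3.1)
        assert len(table) == 0

    def test_face_adjacent_voxels_form_one_cluster(self):
        z = np.zeros(self.GRID)
        z[1, 1, 1] = 4.0
        z[1, 2, 1] = 4.5
        table = cluster_extent_fwe(z.ravel(), self._vox(), self.GRID, 3.1)
        assert len(table) == 1
        assert table["size"].iloc[0] == 2
        assert table["peak_stat"].iloc[0] == 4.5

    def test_diagonal_voxels_are_separate_under_face_connectivity(self):
        z = np.zeros(self.GRID)
        z[1, 1, 1] = 4.0
        z[2, 2, 1] = 4.0
        table = cluster_extent_fwe(z.ravel(), self._vox(), self.GRID, 3.1)
        assert len(table) == 2
        table26 = cluster_extent_fwe(z.ravel(), self._vox(), self.GRID, 3.1,
                                     connectivity=26)
        assert len(table26) == 1

    def test_cluster_p_monotone_in_size(self):
        null = np.array([1, 2, 2, 3, 5, 8])
        z = np.zeros(self.GRID)
        z[0, 0:3, 0] = 4.0   # size 3
        z[3, 0:2, 2] = 4.0   # size 2
        table = cluster_extent_fwe(z.ravel(), self._vox(), self.GRID, 3.1,
                                   null_max_extents=null)
        table = table.sort_values("size")
        assert table["p_fwe"].iloc[0] >= table["p_fwe"].iloc[1]


class TestAnova:
    def test_identical_conditions_give_zero_f(self):
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 3),
            "seed_type": np.tile(["a", "b", "c"], 6),
            "strength": np.repeat(np.random.default_rng(0).normal(size=6), 3),
        })
        out = anova_table(df)
        assert out["seed_type"][0] == 0.0

    def test_matches_statsmodels_repeated_measures(self, rng):
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(5), 3),
            "seed_type": np.tile(["a", "b", "c"], 5),
            "strength": rng.normal(size=15),
        })
        out = anova_table(df)
        from statsmodels.stats.anova import AnovaRM
        sm = AnovaRM(df, depvar="strength", subject="subject",
                     within=["seed_type"]).fit()
        assert out["seed_type"][0] == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), rel=1e-8)

    def test_mixed_design_matches_pingouin(self, rng):
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "group": np.repeat(["A"] * 5 + ["B"] * 5, 3),
            "seed_type": np.tile(["a", "b", "c"], 10),
            "strength": rng.normal(size=30),
        })
        out = anova_table(df, between="group")
        import pingouin as pg
        pt = pg.mixed_anova(df, dv="strength", within="seed_type",
                            subject="subject", between="group")
        pt = pt.set_index("Source")
        assert out["group"][0] == pytest.approx(pt.loc["group", "F"],
                                                rel=1e-6)
        assert out["seed_type"][0] == pytest.approx(pt.loc["seed_type", "F"],
                                                    rel=1e-6)
        assert out["group_x_seed_type"][0] == pytest.approx(
            pt.loc["Interaction", "F"], rel=1e-6)

    def test_network_strength_table(self, rng):
        maps = {s: rng.normal(size=(8, 30)) for s in ("prob", "s4", "s8")}
        mask = np.zeros(30, bool)
        mask[:10] = True
        table, effects = network_strength(maps, mask,
                                          groups=["A"] * 4 + ["B"] * 4)
        assert len(table) == 24
        assert set(effects) == {"group", "seed_type", "group_x_seed_type"}
        expect = maps["prob"][0, :10].mean()
        got = table.query("subject == 0 and seed_type == 'prob'")
        assert got["strength"].iloc[0] == pytest.approx(expect)


class TestCohensD:
    def test_identical_groups(self, rng):
        a = rng.normal(size=10)
        assert cohens_d(a, a.copy()) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=9)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_spread_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestSphereGrid:
    def _setup(self, rng, gradient=True):
        grid = (9, 9, 5)
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        prob = np.zeros(grid)
        region = np.zeros(grid, bool)
        region[1:8, 1:4, 1:4] = True
        centre = np.array([4.0, 2.0, 2.0])
        for v in np.argwhere(region):
            prob[tuple(v)] = max(0.3, 1.0 - 0.12 * np.linalg.norm(v - centre))
        net = np.zeros(grid, bool)
        net[2:6, 6:8, 1:3] = True
        gm = np.ones(grid, bool)
        T = 150
        latent = rng.normal(size=T)
        groups = np.array(["A"] * 6 + ["B"] * 6)
        data = []
        for g in groups:
            vol = rng.normal(size=grid + (T,)) + 100
            sign = 1.0 if g == "A" else -1.0
            subj_jitter = 0.2 * rng.normal()  # between-subject variability
            for v in np.argwhere(region):
                w = prob[tuple(v)] if gradient else 0.6
                # group difference in coupling scales with probability
                wnorm = (w - 0.3) / 0.7 if gradient else 0.0
                gain = 1.0 + sign * 0.5 * wnorm + subj_jitter
                vol[tuple(v)] += (gain * w) * latent
            vol[net] += latent
            data.append(vol)
        return prob, aff, data, gm, net, groups

    def test_spheres_disjoint_and_centred_in_support(self, rng):
        prob, aff, data, gm, net, groups = self._setup(rng)
        table, corrs = sphere_grid_effects(prob, aff, data, gm, net, groups,
                                           radius_mm=4.0, threshold=0.25)
        seen = set()
        for _, row in table.iterrows():
            c = (int(row["centre_x"]), int(row["centre_y"]),
                 int(row["centre_z"]))
            assert prob[c] > 0.25
            world = aff[:3, :3] @ np.array(c) + aff[:3, 3]
            vox = {tuple(v)
                   for v in sphere_seed(world, 4.0, aff, prob.shape)}
            assert not (seen & vox)
            seen |= vox

    def test_gradient_phantom_positive_strength_probability_corr(self, rng):
        prob, aff, data, gm, net, groups = self._setup(rng, gradient=True)
        table, corrs = sphere_grid_effects(prob, aff, data, gm, net, groups)
        assert corrs["A"] > 0.5 and corrs["B"] > 0.5
        # group difference largest near the peak
        top = table.nlargest(3, "mean_prob")["cohens_d"].mean()
        bottom = table.nsmallest(3, "mean_prob")["cohens_d"].mean()
        assert top > bottom

    def test_flat_probability_flagged(self, rng):
        grid = (6, 6, 4)
        prob = np.full(grid, 0.5)
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        gm = np.ones(grid, bool)
        net = np.zeros(grid, bool)
        net[0, 0, 0] = True
        data = [rng.normal(size=grid + (50,)) + 100 for _ in range(4)]
        with pytest.warns(RuntimeWarning):
            table, corrs = sphere_grid_effects(
                prob, aff, data, gm, net, np.array(["A", "A", "B", "B"]),
                threshold=0.25)
        assert all(np.isnan(v) for v in corrs.values())

    def test_empty_support_rejected(self, rng):
        grid = (6, 6, 4)
        with pytest.raises(ValueError):
            sphere_grid_effects(np.zeros(grid), np.eye(4), [],
                                np.ones(grid, bool), np.ones(grid, bool),
                                np.array([]), threshold=0.25)
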