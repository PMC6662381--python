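import io

import numpy as np
import pandas as pd
import pytest

from phylomorph import morpho, simulate, tps
from phylomorph.morpho import LandmarkConfiguration


def similarity(coords, theta=0.0, scale=1.0, shift=(0.0, 0.0), reflect=False):
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    out = scale * coords @ R.T + np.asarray(shift)
    if reflect:
        out = out * np.array([1.0, -1.0])
    return out


# ---------------------------------------------------------------------------
# thin-plate splines and TPS files
# ---------------------------------------------------------------------------


class TestTps:
    def test_interpolates_exactly_at_anchors(self, foot_template):
        src = foot_template.coords
        rng = np.random.default_rng(0)
        dst = src + 0.1 * rng.standard_normal(src.shape)
        W, A = tps.tps_coefficients(src, dst)
        np.testing.assert_allclose(tps.tps_warp(src, W, A, src), dst, atol=1e-8)

    def test_reproduces_similarity_transform(self, foot_template):
        src = foot_template.coords
        dst = similarity(src, theta=0.6, scale=1.4, shift=(2, -1))
        W, A = tps.tps_coefficients(src, dst)
        probe = np.array([[0.3, 0.4], [-0.8, 0.9]])
        np.testing.assert_allclose(tps.tps_warp(src, W, A, probe),
                                   similarity(probe, 0.6, 1.4, (2, -1)), atol=1e-9)

    def test_collinear_source_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            tps.tps_coefficients(src, src + 1.0)

    def test_quadratic_warp_recovery_vs_grid_oracle(self, foot_template):
        """A masked point under a known smooth warp is recovered close to the
        spline's own dense-grid interpolation of that warp."""
        src = foot_template.coords

        def warp(p):
            return np.column_stack([p[:, 0] + 0.05 * p[:, 1] ** 2,
                                    p[:, 1] - 0.04 * p[:, 0] ** 2])

        dst = warp(src)
        miss = 7
        shared = np.ones(len(src), dtype=bool)
        shared[miss] = False
        W, A = tps.tps_coefficients(src[shared], dst[shared])
        est = tps.tps_warp(src[shared], W, A, src[miss][None, :])[0]
        # oracle: spline fit on a dense grid sampling of the same warp
        gx, gy = np.meshgrid(np.linspace(-1.3, 1.3, 9), np.linspace(-0.8, 1.5, 9))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        Wg, Ag = tps.tps_coefficients(grid, warp(grid))
        oracle = tps.tps_warp(grid, Wg, Ag, src[miss][None, :])[0]
        assert np.linalg.norm(est - oracle) < 0.05

    def test_file_round_trip(self, foot_template):
        specs = simulate.generate_landmark_dataset(n_species=3, n_per_species=2,
                                                   missing_fraction=0.1, seed=4)
        payload = [{"coords": c.coords, "id": c.specimen, "image": f"{c.specimen}.jpg"}
                   for c in specs]
        buf = io.StringIO()
        tps.write_tps(payload, buf)
        buf.seek(0)
        back = tps.read_tps(buf)
        assert len(back) == len(payload)
        for orig, rd in zip(payload, back):
            np.testing.assert_allclose(orig["coords"], rd["coords"], atol=1e-9,
                                       equal_nan=True)
            assert rd["id"] == orig["id"]

    def test_scale_record_applied(self):
        text = "LM=2\n1 2\n3 4\nSCALE=0.5\n"
        spec = tps.read_tps(io.StringIO(text))[0]
        np.testing.assert_allclose(spec["coords"], [[0.5, 1.0], [1.5, 2.0]])


# ---------------------------------------------------------------------------
# imputation and shape ratios
# ---------------------------------------------------------------------------


class TestImputation:
    def test_identity_when_complete(self):
        df = simulate.generate_measurement_table(n_species=5, n_per_species=3,
                                                 missing_fraction=0.0, seed=1)
        out, n = morpho.impute_missing_measurements(df)
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    def test_noiseless_allometry_recovered(self):
        """With exact proportionality the regression recovers masked values."""
        df = simulate.generate_measurement_table(n_species=8, n_per_species=4,
                                                 noise=0.0, missing_fraction=0.0,
                                                 seed=2)
        truth = df.loc[5, "TL"]
        df.loc[5, "TL"] = np.nan
        out, n = morpho.impute_missing_measurements(df)
        assert n == 1
        assert out.loc[5, "TL"] == pytest.approx(truth, abs=1e-6)

    def test_observed_entries_untouched(self):
        df = simulate.generate_measurement_table(n_species=10, n_per_species=5,
                                                 missing_fraction=0.05, seed=3)
        obs_mask = df[list(morpho.MEASUREMENT_VARS)].notna()
        out, _ = morpho.impute_missing_measurements(df)
        before = df[list(morpho.MEASUREMENT_VARS)].to_numpy()
        after = out[list(morpho.MEASUREMENT_VARS)].to_numpy()
        assert np.array_equal(before[obs_mask.to_numpy()], after[obs_mask.to_numpy()])
        assert not np.isnan(after).any()

    def test_deterministic(self):
        df = simulate.generate_measurement_table(n_species=10, n_per_species=5,
                                                 missing_fraction=0.05, seed=3)
        out1, _ = morpho.impute_missing_measurements(df)
        out2, _ = morpho.impute_missing_measurements(df)
        pd.testing.assert_frame_equal(out1, out2)

    def test_all_missing_specimen_rejected(self):
        df = simulate.generate_measurement_table(n_species=3, n_per_species=2,
                                                 missing_fraction=0.0, seed=4)
        df.loc[0, list(morpho.MEASUREMENT_VARS)] = np.nan
        with pytest.raises(ValueError, match="all measurements missing"):
            morpho.impute_missing_measurements(df)


class TestShapeRatios:
    def test_equal_variables_give_zero_vector(self):
        df = pd.DataFrame({
            "specimen": ["a", "b"], "species": ["sp1", "sp1"],
            **{v: [10.0, 10.0] for v in morpho.MEASUREMENT_VARS},
        })
        out = morpho.shape_ratios(df)
        np.testing.assert_allclose(
            out.loc["sp1", [c for c in out.columns if c.startswith("ln_")]], 0.0)

    def test_known_ratio(self):
        df = pd.DataFrame({
            "specimen": ["a"], "species": ["sp1"],
            **{v: [10.0] for v in morpho.MEASUREMENT_VARS},
        })
        df["TL"] = 20.0
        out = morpho.shape_ratios(df)
        assert out.loc["sp1", "ln_TL_SVL"] == pytest.approx(np.log(2))

    def test_scale_invariance(self):
        df = simulate.generate_measurement_table(n_species=4, n_per_species=3,
                                                 missing_fraction=0.0, seed=5)
        r1 = morpho.shape_ratios(df)
        df2 = df.copy()
        df2[list(morpho.MEASUREMENT_VARS)] *= 2.0
        r2 = morpho.shape_ratios(df2)
        cols = [c for c in r1.columns if c.startswith("ln_")]
        np.testing.assert_allclose(r1[cols], r2[cols], atol=1e-12)


# ---------------------------------------------------------------------------
# landmark completion and GPA
# ---------------------------------------------------------------------------


class TestInterpolation:
    def test_identical_config_recovered_exactly(self, foot_template):
        c = LandmarkConfiguration("s", "sp", foot_template.coords.copy(),
                                  foot_template.semilandmarks, foot_template.neighbors)
        c.coords[3] = np.nan
        filled = morpho.interpolate_missing_landmarks(c, foot_template)
        np.testing.assert_allclose(filled.coords[3], foot_template.coords[3], atol=1e-9)

    def test_similarity_transform_recovered(self, foot_template):
        warped = similarity(foot_template.coords, theta=0.7, scale=1.7, shift=(2, 3))
        c = LandmarkConfiguration("s", "sp", warped.copy(),
                                  foot_template.semilandmarks, foot_template.neighbors)
        c.coords[5] = np.nan
        filled = morpho.interpolate_missing_landmarks(c, foot_template)
        np.testing.assert_allclose(filled.coords[5], warped[5], atol=1e-9)

    def test_too_many_missing_rejected(self, foot_template):
        c = LandmarkConfiguration("s", "sp", foot_template.coords.copy(),
                                  foot_template.semilandmarks, foot_template.neighbors)
        c.coords[:8] = np.nan
        with pytest.raises(ValueError, match="missing points"):
            morpho.interpolate_missing_landmarks(c, foot_template)


class TestGPA:
    def test_similarity_copies_align_to_zero_distance(self, foot_template):
        rng = np.random.default_rng(6)
        X = np.stack([
            similarity(foot_template.coords, theta=rng.uniform(0, 6.28),
                       scale=np.exp(rng.normal(0, 0.5)), shift=rng.normal(0, 5, 2))
            for _ in range(6)
        ])
        res = morpho.gpa(X)
        assert res.procrustes_distances().max() < 1e-9

    def test_invariant_under_pre_applied_similarity(self, foot_template):
        """Shape relations (pairwise distances, consensus up to rotation) are
        unchanged by similarity-transforming every input."""
        specs = simulate.generate_landmark_dataset(n_species=5, n_per_species=2, seed=7)
        X = np.stack([c.coords for c in specs])
        res1 = morpho.gpa(X)
        X2 = np.stack([similarity(x, theta=1.1, scale=2.0, shift=(4, -2)) for x in X])
        res2 = morpho.gpa(X2)
        np.testing.assert_allclose(res1.procrustes_distances(),
                                   res2.procrustes_distances(), atol=1e-9)
        from phylomorph.morpho import _rotate_onto
        np.testing.assert_allclose(_rotate_onto(res2.consensus, res1.consensus),
                                   res1.consensus, atol=1e-7)

    def test_reflected_specimen_corrected(self, foot_template):
        rng = np.random.default_rng(8)
        base = foot_template.coords
        X = np.stack([
            base + 0.01 * rng.standard_normal(base.shape),
            similarity(base + 0.01 * rng.standard_normal(base.shape), reflect=True),
            base + 0.01 * rng.standard_normal(base.shape),
        ])
        res = morpho.gpa(X)
        assert res.reflected[1]
        assert res.procrustes_distances().max() < 0.1

    def test_two_shape_closed_form_oracle(self):
        """Pairwise alignment of triangles matches the SVD closed form."""
        A = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
        B = np.array([[0.1, -0.1], [1.2, 0.2], [0.2, 1.1]])

        def center_scale(x):
            c = x - x.mean(axis=0)
            return c / np.sqrt((c**2).sum())

        a, b = center_scale(A), center_scale(B)
        U, s, Vt = np.linalg.svd(b.T @ a)
        d = np.sign(np.linalg.det(U @ Vt))
        rot = U @ np.diag([1, d]) @ Vt
        closed = np.sqrt(((b @ rot - a) ** 2).sum())
        res = morpho.gpa(np.stack([A, B]))
        assert res.procrustes_distances()[0, 1] == pytest.approx(closed, abs=1e-6)

    def test_aligned_invariants(self, foot_template):
        specs = simulate.generate_landmark_dataset(n_species=6, n_per_species=2, seed=9)
        res = morpho.gpa(specs)
        for x in res.aligned:
            assert np.abs(x.mean(axis=0)).max() < 1e-9
            assert np.sqrt((x**2).sum()) == pytest.approx(1.0, abs=1e-9)
        # consensus = mean of aligned configurations, rescaled to unit size
        mean = res.aligned.mean(axis=0)
        mean = (mean - mean.mean(axis=0)) / np.sqrt(((mean - mean.mean(axis=0)) ** 2).sum())
        np.testing.assert_allclose(res.consensus, mean, atol=1e-6)

    def test_sliding_never_increases_bending_energy(self):
        specs = simulate.generate_landmark_dataset(n_species=8, n_per_species=3, seed=10)
        res = morpho.gpa(specs, slide=True)
        assert res.bending_energy_trace, "sliding produced no trace"
        for before, after in res.bending_energy_trace:
            assert after <= before + 1e-12

    def test_sliding_requires_metadata(self):
        X = np.stack([np.random.default_rng(0).standard_normal((21, 2))
                      for _ in range(3)])
        with pytest.raises(ValueError, match="sliding requires"):
            morpho.GeneralizedProcrustes(slide=True).fit(X)


class TestSpeciesMeans:
    def test_duplicated_specimens_mean_equals_member(self, foot_template):
        c = foot_template.coords
        specs = [LandmarkConfiguration(f"s{i}", "sp1", c.copy(),
                                       foot_template.semilandmarks,
                                       foot_template.neighbors) for i in range(3)]
        specs += [LandmarkConfiguration("t1", "sp2", c * 1.5 + 2.0,
                                        foot_template.semilandmarks,
                                        foot_template.neighbors)]
        means, species, sizes, _ = morpho.species_mean_shapes(specs)
        assert species == ["sp1", "sp2"]
        # both species reduce to the same shape after alignment
        assert np.sqrt(((means[0] - means[1]) ** 2).sum()) < 1e-6

    def test_counts(self):
        specs = simulate.generate_landmark_dataset(n_species=7, n_per_species=4, seed=11)
        means, species, sizes, _ = morpho.species_mean_shapes(specs)
        assert means.shape[0] == len(species) == len(sizes) == 7


class TestPhylomorphospace:
    def test_variance_fractions_sum_to_one(self):
        tree = simulate.simulate_yule_tree(12, seed=12, height=1.0)
        traits = simulate.simulate_multivariate_bm(tree, p=5, rate=1.0, seed=13)
        pms = morpho.phylomorphospace(tree, traits)
        assert pms["variance_fractions"].sum() == pytest.approx(1.0)

    def test_rank_one_data(self):
        tree = simulate.simulate_yule_tree(10, seed=14, height=1.0)
        base = simulate.simulate_multivariate_bm(tree, p=1, rate=1.0, seed=15)
        traits = pd.DataFrame(
            np.column_stack([base.to_numpy(), 2 * base.to_numpy(), -base.to_numpy()]),
            index=base.index)
        pms = morpho.phylomorphospace(tree, traits)
        assert pms["variance_fractions"][0] == pytest.approx(1.0, abs=1e-9)

    def test_ancestor_projection_shape(self):
        tree = simulate.simulate_yule_tree(9, seed=16, height=1.0)
        traits = simulate.simulate_multivariate_bm(tree, p=4, rate=1.0, seed=17)
        pms = morpho.phylomorphospace(tree, traits)
        assert pms["ancestor_scores"].shape == (tree.n_nodes - tree.n_tips, 4)
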