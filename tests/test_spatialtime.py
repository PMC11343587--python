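import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sptime.io import normalize_log_cpm, filter_genes
from sptime.spatialtime import (
    FracturePlane,
    assign_spatialtime,
    classify_trends,
    compare_genotypes,
    fit_gene_trends,
    natural_spline_basis,
    summarize_over_spatialtime,
)
from sptime.synthetic import SyntheticConfig, generate_section, _default_plane

from conftest import make_norm


def section_at(coords, **meta_cols):
    """Minimal section with given spot coordinates."""
    import scipy.sparse as sp
    from sptime.io import SpatialSection

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    meta = pd.DataFrame({"in_tissue": True, **meta_cols},
                        index=[f"P{i:03d}" for i in range(n)])
    return SpatialSection(
        spot_ids=[f"P{i:03d}" for i in range(n)],
        coords=coords,
        array_pos=np.zeros((n, 2), int),
        counts=sp.csr_matrix(np.ones((n, 1), int)),
        gene_ids=["G"],
        metadata=meta,
    )


class TestFracturePlane:
    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            FracturePlane(points=np.array([[0.0, 0.0]]))

    def test_consecutive_duplicates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            FracturePlane(points=np.array([[0, 0], [0, 0], [1, 1]], float))

    def test_csv_round_trip(self, tmp_path):
        plane = FracturePlane(points=np.array([[0.5, 1.5], [2.0, 3.0], [4.0, 1.0]]))
        plane.to_csv(tmp_path / "plane.csv")
        back = FracturePlane.from_csv(tmp_path / "plane.csv")
        np.testing.assert_allclose(back.points, plane.points)


class TestAssignSpatialtime:
    def test_hand_geometry_interior_and_endpoint(self):
        # plane is the segment (0,0)-(0,10)
        plane = FracturePlane(points=np.array([[0.0, 0.0], [0.0, 10.0]]))
        sec = section_at([[3.0, 4.0], [3.0, 15.0], [0.0, 5.0]])
        st = assign_spatialtime(sec, plane)
        assert st.distance[0] == pytest.approx(3.0, abs=1e-12)          # interior projection
        assert st.distance[1] == pytest.approx(np.sqrt(9 + 25), abs=1e-12)  # nearest endpoint
        assert st.distance[2] == 0.0

    def test_spot_on_polyline(self):
        plane = FracturePlane(points=np.array([[0.0, 0.0], [10.0, 0.0]]))
        st = assign_spatialtime(section_at([[4.0, 0.0], [5.0, 5.0]]), plane)
        assert st.distance[0] == 0.0
        assert st.s[0] == 0.0

    def test_minmax_normalization(self):
        plane = FracturePlane(points=np.array([[0.0, -1.0], [0.0, 1.0]]))
        st = assign_spatialtime(section_at([[1.0, 0.0], [2.0, 0.0], [5.0, 0.0]]), plane)
        assert st.s.min() == 0.0
        assert st.s.max() == 1.0
        assert np.all(np.diff(st.s[np.argsort(st.distance)]) >= 0)

    def test_all_equal_distances_give_zero(self):
        plane = FracturePlane(points=np.array([[0.0, -10.0], [0.0, 10.0]]))
        st = assign_spatialtime(section_at([[2.0, 0.0], [2.0, 1.0], [-2.0, 0.0]]), plane)
        assert np.all(st.s == 0.0)

    def test_rigid_motion_invariance(self, small_section):
        section, _ = small_section
        plane = _default_plane(section.coords)
        base = assign_spatialtime(section, plane)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.4, -56.7])
        moved = section_at(section.coords @ R.T + shift)
        moved_plane = FracturePlane(points=plane.points @ R.T + shift)
        got = assign_spatialtime(moved, moved_plane)
        np.testing.assert_allclose(got.s, base.s, atol=1e-9)

    def test_rescaling_invariance(self, small_section):
        section, _ = small_section
        plane = _default_plane(section.coords)
        base = assign_spatialtime(section, plane)
        scaled = section_at(section.coords * 3.7)
        got = assign_spatialtime(scaled, FracturePlane(points=plane.points * 3.7))
        np.testing.assert_allclose(got.s, base.s, atol=1e-9)

    def test_matches_generator_truth(self, small_section, small_st):
        _, truth = small_section
        rho = scipy.stats.spearmanr(
            small_st.series().loc[truth.true_spatialtime.index].to_numpy(),
            truth.true_spatialtime.to_numpy(),
        ).statistic
        assert rho >= 0.99

    def test_cluster_inclusion_mask(self):
        plane = FracturePlane(points=np.array([[0.0, -1.0], [0.0, 1.0]]))
        sec = section_at([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]], cluster=[1, 1, 2])
        st = assign_spatialtime(sec, plane, include_clusters=[1])
        assert st.included.sum() == 2
        assert np.isnan(st.s[2])
        assert st.s[1] == 1.0  # normalized over included spots only

    def test_empty_inclusion_errors(self):
        plane = FracturePlane(points=np.array([[0.0, -1.0], [0.0, 1.0]]))
        sec = section_at([[1.0, 0.0]], cluster=[1])
        with pytest.raises(ValueError):
            assign_spatialtime(sec, plane, include_clusters=[])
        with pytest.raises(ValueError, match="no included"):
            assign_spatialtime(sec, plane, include_clusters=[99])

    def test_plane_outside_bbox_warns(self):
        plane = FracturePlane(points=np.array([[100.0, 100.0], [101.0, 101.0]]))
        with pytest.warns(UserWarning, match="bounding box"):
            assign_spatialtime(section_at([[0.0, 0.0], [1.0, 1.0]]), plane)


class TestSplineBasis:
    def test_linear_beyond_boundaries(self):
        knots = np.array([0.2, 0.5, 0.8])
        x = np.array([-1.0, -0.5, 0.0, 1.0, 1.5, 2.0])
        B = natural_spline_basis(x, knots)
        # second differences vanish on each linear tail
        left = B[:3]
        d2 = np.diff(left, n=2, axis=0)
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)


class TestFitGeneTrends:
    def test_null_calibration_single_rep(self, rng):
        n, g = 400, 1000
        s_vals = rng.uniform(0, 1, n)
        Y = rng.normal(size=(n, g))
        norm = make_norm(Y)
        from sptime.spatialtime import SpatialTimeValues

        st = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                               s=s_vals, included=np.ones(n, bool))
        trends = fit_gene_trends(norm, st)
        frac = np.mean([t.p < 0.05 for t in trends])
        se = np.sqrt(0.05 * 0.95 / g)
        assert frac < 0.05 + 4 * se
        assert frac > 0.05 - 4 * se

    def test_planted_gene_detected_and_shuffle_destroys(self, rng):
        n = 500
        s_vals = rng.uniform(0, 1, n)
        Y = rng.normal(size=(n, 50))
        Y[:, 0] += 2.0 * np.exp(-((s_vals - 0.4) ** 2) / (2 * 0.12**2))
        norm = make_norm(Y)
        from sptime.spatialtime import SpatialTimeValues

        st = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                               s=s_vals, included=np.ones(n, bool))
        trends = fit_gene_trends(norm, st)
        assert trends[0].q < 0.05
        shuffled = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                                     s=rng.permutation(s_vals), included=np.ones(n, bool))
        t2 = fit_gene_trends(norm, shuffled)
        assert t2[0].p > 0.001  # signal gone; occasional small p is chance

    def test_constant_gene_p_one(self, rng):
        Y = rng.normal(size=(100, 3))
        Y[:, 1] = 7.0
        norm = make_norm(Y)
        from sptime.spatialtime import SpatialTimeValues

        s_vals = np.linspace(0, 1, 100)
        st = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                               s=s_vals, included=np.ones(100, bool))
        trends = fit_gene_trends(norm, st)
        assert trends[1].p == 1.0

    def test_too_few_spots(self, rng):
        norm = make_norm(rng.normal(size=(4, 3)))
        from sptime.spatialtime import SpatialTimeValues

        s_vals = np.linspace(0, 1, 4)
        st = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                               s=s_vals, included=np.ones(4, bool))
        with pytest.raises(ValueError):
            fit_gene_trends(norm, st, df=3)


class TestClassifyTrends:
    @pytest.fixture(scope="class")
    def classified(self, small_norm, small_st):
        trends = fit_gene_trends(small_norm, small_st)
        return classify_trends(trends, k=4)

    def test_recovery_on_synthetic(self, classified, small_section):
        _, truth = small_section
        labels = pd.Series({t.gene: t.class_label for t in classified})
        tc = truth.class_of_gene.reindex(labels.index).fillna("none")
        planted = tc != "none"
        acc = (labels[planted] == tc[planted]).mean()
        assert acc >= 0.9

    def test_class_requires_significance(self, classified):
        for t in classified:
            if t.class_label != "none":
                assert t.q < 0.05

    def test_k_one_single_label(self, small_norm, small_st):
        trends = fit_gene_trends(small_norm, small_st)
        out = classify_trends(trends, k=1)
        labels = {t.class_label for t in out if t.class_label != "none"}
        assert labels == {"early..late"}

    def test_monotone_increasing_is_late(self, rng):
        n = 300
        s_vals = np.linspace(0, 1, n)
        Y = rng.normal(size=(n, 10), scale=0.2)
        Y[:, 0] += 3.0 * s_vals  # monotone increasing
        norm = make_norm(Y)
        from sptime.spatialtime import SpatialTimeValues

        st = SpatialTimeValues(spot_ids=norm.spot_ids, distance=s_vals,
                               s=s_vals, included=np.ones(n, bool))
        trends = fit_gene_trends(norm, st)
        with pytest.warns(UserWarning):
            out = classify_trends(trends, k=4)  # fewer than 4 significant genes
        assert out[0].class_label == "late"


class TestSummarize:
    def make_st(self, s_vals):
        from sptime.spatialtime import SpatialTimeValues

        n = len(s_vals)
        return SpatialTimeValues(
            spot_ids=[f"s{i:04d}" for i in range(n)], distance=np.asarray(s_vals),
            s=np.asarray(s_vals, float), included=np.ones(n, bool),
        )

    def test_constant_values_flat(self, rng):
        s_vals = rng.uniform(0, 1, 2000)
        st = self.make_st(s_vals)
        vals = pd.Series(3.5, index=st.spot_ids)
        curve = summarize_over_spatialtime(vals, st, n_bins=10)
        np.testing.assert_allclose(curve.mean, 3.5)
        assert np.nanmax(curve.ci_hi - curve.ci_lo) < 1e-9

    def test_single_bin_is_global_mean(self, rng):
        s_vals = rng.uniform(0, 1, 100)
        st = self.make_st(s_vals)
        vals = pd.Series(rng.normal(size=100), index=st.spot_ids)
        curve = summarize_over_spatialtime(vals, st, n_bins=1)
        assert curve.mean[0] == pytest.approx(vals.mean())

    def test_empty_bins_nan(self):
        s_vals = np.array([0.05, 0.95])
        st = self.make_st(s_vals)
        vals = pd.Series([1.0, 2.0], index=st.spot_ids)
        curve = summarize_over_spatialtime(vals, st, n_bins=10)
        assert np.isnan(curve.mean[5])
        assert curve.n[5] == 0

    def test_planted_peak_recovered(self, rng):
        s_vals = rng.uniform(0, 1, 4000)
        st = self.make_st(s_vals)
        vals = pd.Series(np.exp(-((s_vals - 0.6) ** 2) / (2 * 0.12**2))
                         + rng.normal(scale=0.3, size=4000), index=st.spot_ids)
        curve = summarize_over_spatialtime(vals, st, n_bins=20)
        assert abs(curve.peak - 0.6) <= 0.05 + 1e-9  # within one bin


class TestCompareGenotypes:
    def make_inputs(self, rng, effect=0.0, n=800):
        from sptime.spatialtime import SpatialTimeValues

        out = []
        for tag in ("a", "b"):
            s_vals = rng.uniform(0, 1, n)
            ids = [f"{tag}{i:04d}" for i in range(n)]
            st = SpatialTimeValues(spot_ids=ids, distance=s_vals, s=s_vals,
                                   included=np.ones(n, bool))
            bump = effect if tag == "a" else 0.0
            vals = pd.Series(bump * np.exp(-((s_vals - 0.5) ** 2) / (2 * 0.12**2))
                             + rng.normal(size=n), index=ids)
            out.append((vals, st))
        return out

    def test_antisymmetry(self, rng):
        (va, sa), (vb, sb) = self.make_inputs(rng, effect=1.0)
        fwd = compare_genotypes(va, sa, vb, sb, n_perm=50, seed=3)
        rev = compare_genotypes(vb, sb, va, sa, n_perm=50, seed=3)
        assert fwd.delta_auc == pytest.approx(-rev.delta_auc, abs=1e-12)

    def test_null_not_significant(self, rng):
        (va, sa), (vb, sb) = self.make_inputs(rng, effect=0.0)
        cmp = compare_genotypes(va, sa, vb, sb, n_perm=200, seed=5)
        assert cmp.p_value > 0.05  # deterministic given seeds

    def test_effect_detected(self, rng):
        (va, sa), (vb, sb) = self.make_inputs(rng, effect=1.0)
        cmp = compare_genotypes(va, sa, vb, sb, n_perm=200, seed=5)
        assert cmp.delta_auc > 0
        assert cmp.p_value < 0.05
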