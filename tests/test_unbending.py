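import numpy as np
import pytest

from unbendfish import (
    AxisSpec,
    BendSpec,
    LandmarkConfiguration,
    bend,
    centroid_size,
    curvature_index,
    fit_axis_curve,
    gpa,
    procrustes_variance,
    regression_unbend,
    template,
    tps_unbend_dataset,
    tps_unbend_specimen,
)
from unbendfish.errors import (
    DegenerateConfigurationError,
    StructuralError,
    UnfittableAxisError,
)


class TestFitAxisCurve:
    def test_straight_chain_zero_curvature(self, axis):
        curve = fit_axis_curve(template("slender"), axis, degree=3)
        assert np.abs(curve.coefficients[1:]).max() < 1e-10
        assert curve.fit_rmse < 1e-12

    def test_recovers_exact_quadratic(self):
        # sampled symmetrically so the chord is horizontal and the
        # chord-aligned frame coincides with the sampling frame
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = 0.1 * x**2
        config = LandmarkConfiguration(
            specimen_id="q", coords=np.column_stack([x, y])
        )
        curve = fit_axis_curve(config, AxisSpec((1, 2, 3, 4, 5)), degree=2)
        assert curve.coefficients[2] == pytest.approx(0.1, abs=1e-9)

    def test_cubic_exact_through_four_points(self, rng):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = rng.normal(scale=0.1, size=4)
        y[0] = y[-1] = 0.0  # keep the chord horizontal for clarity
        config = LandmarkConfiguration(
            specimen_id="c", coords=np.column_stack([x, y])
        )
        curve = fit_axis_curve(config, AxisSpec((1, 2, 3, 4)), degree=3)
        assert curve.fit_rmse <= 1e-9

    def test_too_few_points(self):
        coords = np.array([(0.0, 0.0), (1.0, 0.5), (2.0, 0.0)])
        config = LandmarkConfiguration(specimen_id="t", coords=coords)
        with pytest.raises(UnfittableAxisError):
            fit_axis_curve(config, AxisSpec((1, 2, 3)), degree=3)

    def test_vertical_folding_rejected(self):
        coords = np.array(
            [(0.0, 0.0), (1.0, 0.3), (0.5, 0.6), (2.0, 0.9), (4.0, 0.0)]
        )
        config = LandmarkConfiguration(specimen_id="v", coords=coords)
        with pytest.raises(UnfittableAxisError, match="folding"):
            fit_axis_curve(config, AxisSpec((1, 2, 3, 4, 5)), degree=2)


class TestTpsUnbendSpecimen:
    def test_identity_on_straight(self, axis):
        tpl = template("slender")
        out = tps_unbend_specimen(tpl, axis, degree=3)
        assert np.abs(out.coords - tpl.coords).max() < 1e-8

    @pytest.mark.parametrize("degree", [2, 3])
    @pytest.mark.parametrize("amplitude", [0.01, 0.03, 0.06])
    def test_round_trip_recovers_template(self, axis, degree, amplitude):
        tpl = template("slender")
        bent = bend(tpl, BendSpec(degree=degree, amplitude=amplitude))
        flat = tps_unbend_specimen(bent, axis, degree=degree)
        rms = np.sqrt(
            np.mean(np.sum((flat.coords - tpl.coords) ** 2, axis=1))
        )
        assert rms < 1e-3 * centroid_size(tpl)

    def test_output_chain_is_straight(self, axis):
        tpl = template("deep")
        bent = bend(tpl, BendSpec(degree=3, amplitude=0.05, direction=-1))
        flat = tps_unbend_specimen(bent, axis, degree=3)
        assert curvature_index(flat, axis).ic < 1e-6

    def test_chain_extent_equals_curve_arc_length(self, axis):
        tpl = template("slender")
        bent = bend(tpl, BendSpec(degree=2, amplitude=0.05))
        curve = fit_axis_curve(bent, axis, degree=2)
        flat = tps_unbend_specimen(bent, axis, degree=2, curve=curve)
        idx = axis.indices(flat.n_landmarks)
        extent = np.linalg.norm(flat.coords[idx[-1]] - flat.coords[idx[0]])
        arc = curve.arc_length(0.0, curve.chord)
        assert extent == pytest.approx(arc, abs=10 * curve.fit_rmse + 1e-9)

    def test_deterministic(self, axis):
        tpl = template("slender")
        bent = bend(tpl, BendSpec(degree=3, amplitude=0.04))
        a = tps_unbend_specimen(bent, axis, degree=3)
        b = tps_unbend_specimen(bent, axis, degree=3)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestTpsUnbendDataset:
    def test_n_preserved_and_semilandmarks_dropped(self, synth_sample, axis):
        ds, _ = synth_sample
        result = tps_unbend_dataset(ds, axis, degree=3)
        assert result.corrected.n_specimens == ds.n_specimens
        assert result.corrected.n_landmarks == ds.n_landmarks - 4
        assert result.method == "tps"
        assert len(result.residual_ic) == ds.n_specimens
        assert np.all(result.residual_ic < 1e-2)

    def test_straight_dataset_equals_gpa_minus_dropped(self, rng, axis):
        from unbendfish import Dataset

        base = template("slender")
        configs = []
        for i in range(5):
            # random rigid motions of the straight template
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            coords = base.coords @ rot.T + rng.normal(size=2)
            configs.append(
                LandmarkConfiguration(specimen_id=f"s{i}", coords=coords)
            )
        ds = Dataset(configs)
        result = tps_unbend_dataset(ds, axis, degree=2)
        keep = [i for i in range(19) if i + 1 not in (16, 17, 18, 19)]
        pruned = Dataset(
            [c.with_coords(c.coords[keep]) for c in ds]
        )
        expected = gpa(pruned)
        from unbendfish.procrustes import _optimal_rotation

        rot = _optimal_rotation(expected.consensus, result.corrected.consensus)
        aligned = np.einsum("npk,kj->npj", result.corrected.coords, rot)
        np.testing.assert_allclose(aligned, expected.coords, atol=1e-8)

    def test_variance_reduction_on_bent_sample(self, synth_sample, axis):
        ds, _ = synth_sample
        original = gpa(ds)
        result = tps_unbend_dataset(ds, axis, degree=3)
        assert procrustes_variance(result.corrected) < procrustes_variance(
            original
        )

    def test_group_partitioning_changes_nothing_with_fixed_degree(
        self, synth_sample, axis
    ):
        ds, _ = synth_sample
        plain = tps_unbend_dataset(ds, axis, degree=3)
        grouped = tps_unbend_dataset(ds, axis, degree=3, groups=7)
        np.testing.assert_allclose(
            plain.corrected.coords, grouped.corrected.coords, atol=1e-12
        )

    def test_group_degree_selection(self, synth_sample, axis):
        ds, _ = synth_sample
        result = tps_unbend_dataset(ds, axis, degree=None, groups=3)
        degrees = result.diagnostics["degree"]
        assert set(degrees) <= {2, 3}
        assert result.diagnostics.groupby("group")["degree"].nunique().max() == 1

    def test_bad_drop_rejected(self, synth_sample, axis):
        ds, _ = synth_sample
        with pytest.raises(StructuralError):
            tps_unbend_dataset(ds, axis, drop=(12, 16))


class TestRegressionUnbend:
    def test_corrected_shapes_decoupled_from_ic(self, synth_sample, axis):
        # residual orthogonality is exact before the final re-superimposition
        # (next test); after re-GPA the association must stay negligible
        from unbendfish import regress_shape_on_covariate

        ds, _ = synth_sample
        sds = gpa(ds)
        ic = np.array([curvature_index(c, axis).ic for c in sds.coords])
        result = regression_unbend(sds, ic, axis=axis)
        fit = regress_shape_on_covariate(result.corrected, ic, n_perm=99, seed=0)
        assert fit.r_squared < 0.01

    def test_orthogonality_exact_before_regpa(self, synth_sample, axis):
        ds, _ = synth_sample
        sds = gpa(ds)
        ic = np.array([curvature_index(c, axis).ic for c in sds.coords])
        Y = sds.flattened()
        X = np.column_stack([np.ones(len(ic)), ic])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        cov = resid.T @ (ic - ic.mean()) / (len(ic) - 1)
        assert np.abs(cov).max() < 1e-10

    def test_noise_only_shapes_nearly_unchanged(self, rng):
        from unbendfish import Dataset
        from unbendfish.procrustes import _optimal_rotation

        base = template("slender").coords
        noise = 1e-3
        ds = Dataset(
            [
                LandmarkConfiguration(
                    specimen_id=f"s{i}",
                    coords=base + rng.normal(scale=noise, size=base.shape),
                )
                for i in range(40)
            ]
        )
        sds = gpa(ds)
        ic = rng.normal(size=40)  # covariate unrelated to the shapes
        result = regression_unbend(sds, ic)
        rot = _optimal_rotation(sds.consensus, result.corrected.consensus)
        aligned = np.einsum("npk,kj->npj", result.corrected.coords, rot)
        assert np.abs(aligned - sds.coords).max() < noise

    def test_constant_ic_rejected(self, synth_sample):
        ds, _ = synth_sample
        sds = gpa(ds)
        with pytest.raises(DegenerateConfigurationError):
            regression_unbend(sds, np.full(sds.n_specimens, 0.01))

    def test_length_mismatch(self, synth_sample):
        ds, _ = synth_sample
        sds = gpa(ds)
        with pytest.raises(StructuralError):
            regression_unbend(sds, np.arange(3))

    def test_variance_reduction(self, synth_sample, axis):
        ds, _ = synth_sample
        sds = gpa(ds)
        ic = np.array([curvature_index(c, axis).ic for c in sds.coords])
        result = regression_unbend(sds, ic, axis=axis)
        assert procrustes_variance(result.corrected) < procrustes_variance(sds)
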