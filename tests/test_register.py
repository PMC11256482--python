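"""Affine and diffeomorphic registration: self-consistency and parameter recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morphorad.imageio import Volume
from morphorad.morphometry import jacobian_determinant
from morphorad.phantom import (
    FocalDeformationSpec,
    add_rician_noise,
    invert_field,
    make_deformation,
    make_phantom,
    resample_through_map,
)
from morphorad.phantom import _interpolate_field
from morphorad.register import (
    AffineTransform,
    apply_transform,
    build_template,
    register_affine,
    register_nonlinear,
    resample_affine,
)

from conftest import make_volume


@pytest.fixture(scope="module")
def textured(small_spec_module):
    vol, lab = make_phantom(small_spec_module)
    return small_spec_module, vol, lab


@pytest.fixture(scope="module")
def small_spec_module():
    from morphorad.phantom import PhantomSpec

    return PhantomSpec(grid_shape=(32, 32, 24), spacing=(0.5, 0.5, 1.0),
                       noise_sigma=0.02, bias_amplitude=0.0, texture_amplitude=0.15)


def degraded(vol, sigma_abs, seed):
    return vol.copy_with(add_rician_noise(vol.data, sigma_abs, np.random.default_rng(seed)))


class TestAffine:
    def test_transform_validation(self):
        with pytest.raises(ValueError):
            AffineTransform(np.diag([2.0, 1.0, 1.0, 1.0]), kind="rigid")
        AffineTransform(np.diag([2.0, 1.0, 1.0, 1.0]), kind="affine")  # fine

    def test_self_registration_near_identity(self, textured):
        spec, vol, _ = textured
        noisy = degraded(vol, spec.noise_sigma_abs, 1)
        T = register_affine(noisy, noisy, kind="rigid")
        assert T.rotation_angle_deg() < 0.1
        assert np.linalg.norm(T.translation_at(np.zeros(3))) < 0.05

    def test_known_rotation_translation_recovered(self, textured):
        """5 degrees + 1 mm must be recovered within 0.5 degrees / 0.2 mm."""
        spec, vol, _ = textured
        M = np.eye(4)
        M[:3, :3] = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        M[:3, 3] = [1.0, 0.0, 0.0]
        Minv = np.linalg.inv(M)
        g = vol.world_grid()
        subj = vol.copy_with(resample_through_map(vol, g @ Minv[:3, :3].T + Minv[:3, 3]))
        subj = degraded(subj, spec.noise_sigma_abs, 2)
        tpl = degraded(vol, spec.noise_sigma_abs, 3)
        T = register_affine(subj, tpl, kind="rigid")
        residual = AffineTransform(T.matrix @ Minv, kind="affine")
        assert residual.rotation_angle_deg() < 0.5
        assert np.linalg.norm(residual.translation_at(np.zeros(3))) < 0.2

    def test_agrees_with_simpleitk_oracle(self, textured):
        """Our rigid estimate matches an independent registration toolkit's
        estimate of the same pair to within a fraction of a voxel."""
        import SimpleITK as sitk

        spec, vol, _ = textured
        M = np.eye(4)
        M[:3, :3] = Rotation.from_euler("xyz", [2.0, -1.5, 3.0], degrees=True).as_matrix()
        M[:3, 3] = [0.6, -0.4, 0.8]
        Minv = np.linalg.inv(M)
        g = vol.world_grid()
        subj = vol.copy_with(resample_through_map(vol, g @ Minv[:3, :3].T + Minv[:3, 3]))
        subj = degraded(subj, spec.noise_sigma_abs, 21)
        tpl = degraded(vol, spec.noise_sigma_abs, 22)

        ours = register_affine(subj, tpl, kind="rigid")

        def to_sitk(v):
            img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(v.data, np.float64).T))
            img.SetSpacing(tuple(float(s) for s in v.spacing))
            img.SetOrigin(tuple(float(o) for o in v.affine[:3, 3]))
            return img

        fixed_img, moving_img = to_sitk(tpl), to_sitk(subj)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(32)
        reg.SetOptimizerAsRegularStepGradientDescent(1.0, 1e-4, 200)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(sitk.CenteredTransformInitializer(
            fixed_img, moving_img, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY))
        reg.SetInterpolator(sitk.sitkLinear)
        tfm = reg.Execute(fixed_img, moving_img)
        tfm = sitk.Euler3DTransform(tfm)
        R_sitk = np.asarray(tfm.GetMatrix()).reshape(3, 3)
        c = np.asarray(tfm.GetCenter())
        t_sitk = np.asarray(tfm.GetTranslation())
        M_sitk = np.eye(4)
        M_sitk[:3, :3] = R_sitk
        M_sitk[:3, 3] = c - R_sitk @ c + t_sitk

        resid = AffineTransform(ours.matrix @ np.linalg.inv(M_sitk), kind="affine")
        assert resid.rotation_angle_deg() < 1.0
        assert np.linalg.norm(resid.translation_at(np.zeros(3))) < 0.5

    def test_mi_never_decreases_within_level(self, textured):
        spec, vol, _ = textured
        subj = degraded(vol, spec.noise_sigma_abs, 4)
        tpl = degraded(vol, spec.noise_sigma_abs, 5)
        T = register_affine(subj, tpl, kind="rigid")
        for entry in T.mi_trace:
            assert entry["final"] >= entry["initial"] - 1e-12


class TestNonlinear:
    def test_self_registration_null_field(self, textured):
        spec, vol, _ = textured
        noisy = degraded(vol, spec.noise_sigma_abs, 6)
        mask = np.asarray(vol.data) > 0.05 * vol.data.max()
        res = register_nonlinear(noisy, noisy, mask=mask, iterations=(30, 20, 10))
        mean_u = np.linalg.norm(res.field.data, axis=-1)[mask].mean()
        assert mean_u < 0.05

    def test_focal_deformation_landmark_recovery(self, textured):
        """Landmark error after demons is at least halved vs affine-only."""
        spec, vol, _ = textured
        g = vol.world_grid()
        blob = FocalDeformationSpec((0.0, 0.0, 1.9), 4.0, 0.9)
        fwd, _ = make_deformation([blob], vol)
        inv = invert_field(fwd)
        subj = vol.copy_with(resample_through_map(vol, g + inv.data))
        subj = degraded(subj, spec.noise_sigma_abs, 7)
        tpl = degraded(vol, spec.noise_sigma_abs, 8)
        mask = np.asarray(vol.data) > 0.05 * vol.data.max()
        res = register_nonlinear(subj, tpl, mask=mask, iterations=(80, 50, 30),
                                 sigma_total=1.0)
        lin = np.array([-1.0, 0.0, 1.0]) * blob.sigma
        lms = np.stack(np.meshgrid(lin, lin, lin, indexing="ij"), axis=-1).reshape(-1, 3)
        lms = lms + np.asarray(blob.center)
        true_mapped = lms + fwd.displacement_fn(lms)
        est_mapped = lms + _interpolate_field(res.field, lms)
        err_nl = np.linalg.norm(est_mapped - true_mapped, axis=1).mean()
        err_affine = np.linalg.norm(lms - true_mapped, axis=1).mean()
        assert err_nl <= 0.5 * err_affine

    def test_orientation_preserved(self, textured):
        spec, vol, _ = textured
        g = vol.world_grid()
        fwd, _ = make_deformation([FocalDeformationSpec((0.0, 0.0, 1.9), 2.0, 0.7)], vol)
        inv = invert_field(fwd)
        subj = vol.copy_with(resample_through_map(vol, g + inv.data))
        subj = degraded(subj, spec.noise_sigma_abs, 9)
        tpl = degraded(vol, spec.noise_sigma_abs, 10)
        mask = np.asarray(vol.data) > 0.05 * vol.data.max()
        res = register_nonlinear(subj, tpl, mask=mask, iterations=(40, 30, 15))
        det = jacobian_determinant(res.field)
        assert det.data[mask].min() > 0


class TestApplyTransform:
    def test_identity_result(self, textured):
        _, vol, _ = textured
        from morphorad.register import RegistrationResult
        from morphorad.imageio import DisplacementField

        res = RegistrationResult(
            affine=AffineTransform.identity(),
            field=DisplacementField(data=np.zeros(vol.shape3 + (3,)), affine=vol.affine),
        )
        out = apply_transform(vol, res)
        assert np.allclose(out.data, vol.data)

    def test_translation_on_ramp_shifts_values(self):
        shape = (16, 16, 16)
        aff = np.eye(4)
        vol = Volume(data=np.indices(shape, dtype=float)[0] * 2.0, affine=aff)
        T = AffineTransform(np.eye(4), kind="rigid")
        T.matrix[:3, 3] = [1.0, 0.0, 0.0]  # one voxel along the ramp
        out = resample_affine(vol, vol, T)
        assert np.allclose(out.data[2:-2], vol.data[2:-2] + 2.0)

    def test_nearest_neighbour_introduces_no_new_labels(self, textured):
        _, vol, lab = textured
        T = AffineTransform.from_params([2.0, -1.0, 3.0, 0.7, -0.4, 0.9], "rigid",
                                        np.zeros(3))
        from morphorad.register import RegistrationResult
        from morphorad.imageio import DisplacementField

        g = vol.world_grid()
        res = RegistrationResult(affine=T, field=DisplacementField(data=T(g) - g, affine=vol.affine))
        warped = apply_transform(lab, res, interpolation="nearest")
        assert set(np.unique(warped.data)) <= set(np.unique(lab.data))

    def test_unknown_interpolation_rejected(self, textured):
        _, vol, _ = textured
        with pytest.raises(ValueError, match="interpolation"):
            apply_transform(vol, AffineTransform.identity(), interpolation="cubic",
                            reference=vol)


class TestTemplate:
    def test_single_volume_returned(self, textured):
        _, vol, _ = textured
        assert build_template([vol]) is vol

    def test_identical_volumes_mean_is_same(self, textured):
        spec, vol, _ = textured
        tpl = build_template([vol, vol, vol], levels=(4, 2))
        # identical up to sub-voxel resampling of the (near-identity) transforms
        mask = np.asarray(vol.data) > 0
        assert np.corrcoef(tpl.data[mask], vol.data[mask])[0, 1] > 0.999
        assert np.abs(tpl.data - vol.data).mean() < 0.01 * vol.data.max()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_template([])

    def test_template_beats_individuals(self):
        """Averaging noise-jittered phantoms must track the clean phantom at
        least as well as any single one (shared pose, so the comparison is
        noise-dominated rather than interpolation-dominated)."""
        from morphorad.phantom import PhantomSpec

        spec = PhantomSpec(grid_shape=(32, 32, 24), spacing=(0.5, 0.5, 1.0),
                           noise_sigma=0.05, bias_amplitude=0.0, texture_amplitude=0.0)
        clean, _ = make_phantom(spec)
        vols = [degraded(clean, spec.noise_sigma_abs, 100 + i) for i in range(6)]
        tpl = build_template(vols, levels=(4, 2))
        mask = np.asarray(clean.data) > 0.05 * clean.data.max()
        corr = lambda v: np.corrcoef(np.asarray(v.data)[mask], np.asarray(clean.data)[mask])[0, 1]
        c_tpl = corr(tpl)
        assert all(c_tpl >= corr(v) - 1e-6 for v in vols)
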