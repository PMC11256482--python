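"""Phantom anatomy, Gaussian-blob deformations and MR signal models."""

import numpy as np
import pytest

from morphorad.imageio import DisplacementField
from morphorad.phantom import (
    CORPUS_CALLOSUM,
    CORTEX,
    LABEL_NAMES,
    ContrastProtocol,
    DWIProtocol,
    FocalDeformationSpec,
    PhantomSpec,
    add_rician_noise,
    default_dwi_protocol,
    fibonacci_directions,
    invert_field,
    make_bias_field,
    make_deformation,
    make_phantom,
    simulate_dwi,
    simulate_t2star,
    warp_and_degrade,
)
from morphorad.quantmaps import cbv_map, delta_r2star


def brute_force_labels(spec):
    """Independent voxel-by-voxel evaluation of the geometric predicates."""
    from morphorad.phantom import _GEOM, BACKGROUND, STRIATUM, VENTRICLES

    shape = spec.grid_shape
    aff = spec.affine
    fov = spec.fov
    s = spec.brain_scale
    out = np.zeros(shape, dtype=int)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                xyz = aff[:3, :3] @ [i, j, k] + aff[:3, 3]

                def inside(cf, sf):
                    c = np.asarray(cf) * fov
                    ax = np.asarray(sf) * fov * s
                    return (((xyz - c) / ax) ** 2).sum() <= 1.0

                if not inside((0, 0, 0), _GEOM["brain_semiaxes"]):
                    continue
                lab = CORTEX
                for side in (-1, 1):
                    if inside((side * _GEOM["striatum_centers_x"], 0, _GEOM["striatum_center_z"]),
                              _GEOM["striatum_semiaxes"]):
                        lab = STRIATUM
                ax, by = np.asarray(_GEOM["cc_semiaxes_xy"]) * fov[:2] * s
                zc = _GEOM["cc_z_center"] * fov[2]
                zh = _GEOM["cc_half_thickness"] * fov[2] * s
                if abs(xyz[2] - zc) <= zh and (xyz[0] / ax) ** 2 + (xyz[1] / by) ** 2 <= 1.0:
                    lab = CORPUS_CALLOSUM
                for side in (-1, 1):
                    if inside((side * _GEOM["ventricle_centers_x"], 0, _GEOM["ventricle_center_z"]),
                              _GEOM["ventricle_semiaxes"]):
                        lab = VENTRICLES
                out[i, j, k] = lab
    return out


def test_degenerate_geometry_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(brain_scale=0.0)
    with pytest.raises(ValueError):
        PhantomSpec(grid_shape=(4, 4, 4))


def test_class_means_exact(default_phantom):
    spec, vol, lab = default_phantom
    for code, name in LABEL_NAMES.items():
        sel = np.asarray(lab.data) == code
        assert sel.any(), name
        assert np.all(vol.data[sel] == spec.intensities[name])


def test_label_counts_match_brute_force_scan():
    spec = PhantomSpec(grid_shape=(16, 16, 12), spacing=(1.0, 1.0, 2.0))
    _, lab = make_phantom(spec)
    oracle = brute_force_labels(spec)
    assert np.array_equal(np.asarray(lab.data), oracle)


class TestDeformation:
    def test_empty_list_is_identity(self, default_phantom):
        _, vol, _ = default_phantom
        fld, jac = make_deformation([], vol)
        assert np.all(fld.data == 0)
        assert np.allclose(np.log(jac(vol.world_grid())), 0.0)

    def test_center_jacobian_closed_form(self, default_phantom):
        _, vol, _ = default_phantom
        c = (0.0, 0.0, 2.0)
        _, jac = make_deformation([FocalDeformationSpec(c, 2.0, 0.9)], vol)
        assert jac(np.array(c)) == pytest.approx(0.9, abs=1e-12)
        assert np.log(jac(np.array(c))) == pytest.approx(np.log(0.9), abs=1e-12)

    def test_analytic_matches_refined_finite_differences(self, default_phantom):
        """Central differences of Phi on a 10x refined 1D transect agree with
        the closed-form Jacobian to better than 1e-3."""
        _, vol, _ = default_phantom
        spec = FocalDeformationSpec((0.0, 0.0, 0.0), 2.0, 0.8)
        fld, jac = make_deformation([spec], vol)
        h = vol.spacing.min() / 10.0
        pts = np.stack(np.meshgrid(*[np.arange(-4, 4.01, h)] * 2, [0.0], indexing="ij"), axis=-1)
        grad = np.zeros(pts.shape[:-1] + (3, 3))
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            fp = pts + dp + fld.displacement_fn(pts + dp)
            fm = pts - dp + fld.displacement_fn(pts - dp)
            grad[..., :, ax] = (fp - fm) / (2 * h)
        num = np.linalg.det(grad)
        assert np.abs(num - jac(pts)).max() < 1e-3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FocalDeformationSpec((0, 0, 0), 2.0, -0.5)
        with pytest.raises(ValueError):
            FocalDeformationSpec((0, 0, 0), 0.0, 1.1)

    def test_overlapping_blobs_warn(self, default_phantom):
        _, vol, _ = default_phantom
        specs = [FocalDeformationSpec((0, 0, 0), 2.0, 0.9),
                 FocalDeformationSpec((1.0, 0, 0), 2.0, 1.1)]
        with pytest.warns(UserWarning, match="overlap"):
            make_deformation(specs, vol)

    def test_inversion_fixed_point(self, default_phantom):
        _, vol, _ = default_phantom
        fld, _ = make_deformation([FocalDeformationSpec((0, 0, 1.0), 2.0, 0.85)], vol)
        inv = invert_field(fld)
        g = vol.world_grid()
        residual = inv.data + fld.displacement_fn(g + inv.data)
        assert np.abs(residual).max() < 1e-9


class TestWarpAndDegrade:
    def test_identity_no_noise_no_bias(self, default_phantom):
        spec, vol, _ = default_phantom
        clean_spec = PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0)
        out = warp_and_degrade(vol, None, clean_spec)
        assert np.allclose(out.data, vol.data)

    def test_bias_ratio_recovered(self, default_phantom):
        spec, vol, _ = default_phantom
        rng = np.random.default_rng(5)
        bias = make_bias_field(vol, 0.3, rng)
        clean_spec = PhantomSpec(noise_sigma=0.0, bias_amplitude=0.3)
        out = warp_and_degrade(vol, None, clean_spec, rng=rng, bias=bias)
        pos = np.asarray(vol.data) > 0
        assert np.allclose(out.data[pos] / vol.data[pos], bias[pos])

    def test_rayleigh_floor_statistics(self, rng):
        """Zero-signal voxels follow the Rayleigh law: mean sigma*sqrt(pi/2)."""
        sigma = 4.0
        noisy = add_rician_noise(np.zeros(40000), sigma, rng)
        assert noisy.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)
        expected_var = (2 - np.pi / 2) * sigma**2
        assert noisy.var() == pytest.approx(expected_var, rel=0.05)


class TestDWI:
    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            DWIProtocol(bvals=np.zeros(3), bvecs=np.zeros((3, 3)))
        bad = fibonacci_directions(30) * 2.0
        with pytest.raises(ValueError):
            DWIProtocol(bvals=np.full(30, 1000.0), bvecs=bad)

    def test_b0_returns_s0(self):
        prot = default_dwi_protocol(s0=123.0)
        tensors = np.tile(np.eye(3) * 7e-4, (4, 4, 4, 1, 1))
        sig = simulate_dwi(tensors, prot, np.eye(4))
        assert np.allclose(sig.data[..., prot.bvals == 0], 123.0)

    def test_isotropic_signal_direction_independent(self):
        prot = default_dwi_protocol()
        d = 7e-4
        tensors = np.tile(np.eye(3) * d, (2, 2, 2, 1, 1))
        sig = simulate_dwi(tensors, prot, np.eye(4))
        dw = sig.data[0, 0, 0, prot.bvals > 0]
        assert np.allclose(dw, prot.s0 * np.exp(-1000 * d))

    def test_principal_axis_attenuation(self):
        """Signal along the principal eigenvector at b=1000 is s0*exp(-1.5)."""
        evals = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        g = np.array([[1.0, 0.0, 0.0]])
        prot = DWIProtocol(bvals=np.concatenate([[0.0], np.full(6, 1000.0), [1000.0]]),
                           bvecs=np.concatenate([np.zeros((1, 3)),
                                                 fibonacci_directions(6), g]))
        tensors = np.tile(evals, (1, 1, 1, 1, 1))
        sig = simulate_dwi(tensors, prot, np.eye(4))
        assert sig.data[0, 0, 0, -1] == pytest.approx(prot.s0 * np.exp(-1.5), rel=1e-12)

    def test_asymmetric_tensor_rejected(self):
        prot = default_dwi_protocol()
        t = np.zeros((2, 2, 2, 3, 3))
        t[..., 0, 1] = 1e-4
        with pytest.raises(ValueError):
            simulate_dwi(t, prot, np.eye(4))


class TestT2Star:
    def test_zero_cbv_no_signal_change(self, default_phantom):
        _, vol, _ = default_phantom
        cbv = vol.copy_with(np.zeros(vol.shape3), units="%")
        pre = vol.copy_with(np.full(vol.shape3, 50.0))
        p, q = simulate_t2star(cbv, ContrastProtocol(), pre)
        assert np.allclose(p.data, q.data)

    def test_dr2star_linear_in_cbv(self, default_phantom):
        _, vol, _ = default_phantom
        prot = ContrastProtocol()
        pre = vol.copy_with(np.full(vol.shape3, 50.0))
        for scale in (1.0, 2.0):
            cbv = vol.copy_with(np.full(vol.shape3, 3.0 * scale), units="%")
            p, q = simulate_t2star(cbv, prot, pre)
            lr = np.log(p.data / q.data)
            assert np.allclose(lr, scale * np.log(np.exp(
                (3.0 / 100) * (4 * np.pi / 3) * prot.gamma_dchi_b0 * prot.te)))

    def test_round_trip_recovers_cbv(self, default_phantom):
        _, vol, _ = default_phantom
        prot = ContrastProtocol()
        rng = np.random.default_rng(0)
        truth = vol.copy_with(rng.uniform(0.0, 8.0, vol.shape3), units="%")
        pre = vol.copy_with(np.full(vol.shape3, 80.0))
        p, q = simulate_t2star(truth, prot, pre)
        dr2s, _ = delta_r2star(p, q, te=prot.te)
        rec = cbv_map(dr2s, protocol=prot).cbv
        err = np.abs(rec.data - truth.data) / np.maximum(truth.data, 1e-12)
        assert err[truth.data > 0.1].max() < 1e-9

    def test_invalid_te_rejected(self):
        with pytest.raises(ValueError):
            ContrastProtocol(te=0.0)
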