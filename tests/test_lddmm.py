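"""Smoothing kernel, flow integration, geodesic energy, and image matching."""

import numpy as np
import pytest

from likefusion.lddmm import (
    Diffeomorphism,
    KernelParams,
    VelocityField,
    geodesic_energy,
    identity_map,
    integrate_flow,
    kernel_apply,
    lddmm_match,
    warp_image,
    warp_labels,
)
from likefusion.volumes import IntensityVolume, LabelVolume, VoxelGrid


def _dense_operator(field, params):
    """Oracle: apply (L'L) = (-alpha*laplacian + gamma)^(2p) by repeated
    7-point stencil application with periodic wrap."""
    out = field.astype(np.float64)
    for _ in range(2 * params.p):
        lap = -6.0 * out
        for ax in range(3):
            lap += np.roll(out, 1, axis=ax) + np.roll(out, -1, axis=ax)
        out = -params.alpha * lap + params.gamma * out
    return out


class TestKernel:
    def test_zero_field(self):
        z = np.zeros((3, 16, 16, 16), dtype=np.float32)
        assert np.array_equal(kernel_apply(z, KernelParams()), z)

    def test_constant_field_scaled_by_gamma_power(self):
        p = KernelParams(alpha=2.0, gamma=1.5, p=2)
        c = np.full((16, 16, 16), 3.0, dtype=np.float32)
        out = kernel_apply(c, p)
        assert np.allclose(out, 3.0 / 1.5 ** 4, rtol=1e-5)

    def test_sinusoid_eigenvalue(self):
        n, k = 16, 3
        params = KernelParams(alpha=1.0, gamma=0.7, p=2)
        x = np.arange(n)
        f = np.sin(2 * np.pi * k * x / n)[:, None, None] * np.ones((1, n, n))
        lam = 2.0 - 2.0 * np.cos(2 * np.pi * k / n)
        expected = f * (params.alpha * lam + params.gamma) ** (-2 * params.p)
        assert np.allclose(kernel_apply(f.astype(np.float32), params), expected, atol=1e-5)

    def test_inverts_dense_operator(self):
        rng = np.random.default_rng(0)
        params = KernelParams(alpha=0.8, gamma=1.2, p=1)
        f = rng.normal(size=(16, 16, 16))
        recovered = kernel_apply(_dense_operator(f, params).astype(np.float32), params)
        assert np.allclose(recovered, f, atol=1e-3)

    def test_linear_and_positive_definite(self):
        rng = np.random.default_rng(1)
        params = KernelParams()
        f = rng.normal(size=(16, 16, 16)).astype(np.float32)
        g = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lhs = kernel_apply(2.0 * f + g, params)
        rhs = 2.0 * kernel_apply(f, params) + kernel_apply(g, params)
        assert np.allclose(lhs, rhs, atol=1e-4)
        assert float(np.sum(kernel_apply(f, params) * f)) > 0

    def test_nonfinite_rejected(self):
        bad = np.full((8, 8, 8), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            kernel_apply(bad, KernelParams())


class TestGeodesicEnergy:
    def test_zero_and_quadratic_scaling(self):
        rng = np.random.default_rng(2)
        params = KernelParams()
        v = VelocityField(rng.normal(size=(2, 3, 16, 16, 16)).astype(np.float32) * 0.1)
        assert geodesic_energy(VelocityField.zeros((16, 16, 16), 2), params) == 0.0
        e1 = geodesic_energy(v, params)
        e2 = geodesic_energy(VelocityField(2.0 * v.v), params)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-4)

    def test_sinusoid_matches_dense_operator_oracle(self):
        n, k = 16, 2
        params = KernelParams(alpha=1.0, gamma=0.5, p=2)
        v = np.zeros((1, 3, n, n, n))
        v[0, 0] = 1.7 * np.sin(2 * np.pi * k * np.arange(n) / n)[:, None, None]
        expected = float(np.sum(_dense_operator(v[0, 0], params) * v[0, 0]))
        got = geodesic_energy(VelocityField(v.astype(np.float32)), params)
        assert got == pytest.approx(expected, rel=1e-4)
        # closed form: eigenvalue * amplitude^2 * N / 2
        lam = 2.0 - 2.0 * np.cos(2 * np.pi * k / n)
        closed = (params.alpha * lam + params.gamma) ** 4 * 1.7 ** 2 * n ** 3 / 2
        assert got == pytest.approx(closed, rel=1e-4)


class TestIntegrateFlow:
    def test_zero_velocity_identity(self):
        d = integrate_flow(VelocityField.zeros((16, 16, 16), 3))
        ident = identity_map((16, 16, 16))
        assert np.allclose(d.forward, ident) and np.allclose(d.inverse, ident)

    def test_constant_velocity_translation(self):
        u = np.array([1.5, -0.5, 0.75], dtype=np.float32)
        v = np.zeros((8, 3, 16, 16, 16), dtype=np.float32)
        v[:, 0], v[:, 1], v[:, 2] = u[0], u[1], u[2]
        d = integrate_flow(VelocityField(v))
        disp_f = d.forward - identity_map((16, 16, 16))
        disp_i = d.inverse - identity_map((16, 16, 16))
        for c in range(3):
            assert np.allclose(disp_f[c], u[c], atol=1e-4)
            assert np.allclose(disp_i[c], -u[c], atol=1e-4)

    def test_smooth_field_roundtrip(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        raw = rng.normal(size=(3, 32, 32, 32))
        smooth = np.stack([gaussian_filter(raw[c], 5.0, mode="wrap") for c in range(3)])
        smooth *= 1.5 / np.abs(smooth).max()
        v = np.repeat(smooth[None], 5, axis=0).astype(np.float32)
        d = integrate_flow(VelocityField(v))
        assert d.roundtrip_error() < 0.25

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            VelocityField(np.zeros((3, 16, 16, 16), dtype=np.float32))


@pytest.fixture(scope="module")
def label_vol():
    grid = VoxelGrid.from_spacing((16, 16, 16), (1, 1, 1))
    labels = np.zeros((16, 16, 16), dtype=np.int32)
    labels[4:9, 4:9, 4:9] = 1
    labels[10:13, 10:13, 10:13] = 2
    return LabelVolume(grid, labels, {1: "a", 2: "b"})


class TestWarp:

    def test_identity_map_no_change(self, label_vol):
        d = Diffeomorphism.identity((16, 16, 16))
        img = IntensityVolume(label_vol.grid,
                              np.random.default_rng(4).normal(size=(16, 16, 16)).astype(np.float32))
        assert np.allclose(warp_image(img, d).values, img.values)
        assert np.array_equal(warp_labels(label_vol, d, "nearest").labels, label_vol.labels)

    def test_prob_mode_interior_indicator_and_partition(self, label_vol):
        v = np.zeros((2, 3, 16, 16, 16), dtype=np.float32)
        v[:, 0] = 0.4  # small subvoxel shift so boundaries interpolate
        d = integrate_flow(VelocityField(v))
        prob = warp_labels(label_vol, d, "prob")
        assert np.allclose(prob.probs.sum(axis=0), 1.0, atol=1e-6)
        assert prob.prob_of(1)[6, 6, 6] == pytest.approx(1.0)  # deep interior voxel

    def test_unknown_mode(self, label_vol):
        with pytest.raises(ValueError, match="unknown"):
            warp_labels(label_vol, Diffeomorphism.identity((16, 16, 16)), "spline")


def _bump(center, dims=(32, 32, 32), sigma=4.0, amplitude=100.0):
    idx = np.indices(dims, dtype=np.float64)
    r2 = sum((idx[d] - center[d]) ** 2 for d in range(3))
    return amplitude * np.exp(-r2 / (2 * sigma ** 2))


class TestLddmmMatch:
    def test_self_match_stays_near_identity(self):
        grid = VoxelGrid.from_spacing((32, 32, 32), (1, 1, 1))
        img = IntensityVolume(grid, _bump((16, 16, 16)).astype(np.float32))
        diffeo, _, trace = lddmm_match(img, img)
        disp = np.abs(diffeo.forward - identity_map((32, 32, 32)))
        assert disp.max() < 0.1
        assert trace["data"].iloc[-1] <= trace["data"].iloc[0] + 1e-9

    def test_translation_recovery_of_shifted_bump(self):
        grid = VoxelGrid.from_spacing((32, 32, 32), (1, 1, 1))
        atlas = IntensityVolume(grid, _bump((15, 16, 16)).astype(np.float32))
        target = IntensityVolume(grid, _bump((17, 16, 16)).astype(np.float32))
        # translation oracle: integer shifts of the atlas; the best is +2
        errs = {s: float(np.sum((np.roll(atlas.values, s, axis=0) - target.values) ** 2))
                for s in range(-4, 5)}
        assert min(errs, key=errs.get) == 2
        diffeo, _, _ = lddmm_match(atlas, target)
        disp = diffeo.forward - identity_map((32, 32, 32))
        assert disp[0, 15, 16, 16] == pytest.approx(2.0, abs=0.5)
        assert abs(disp[1, 15, 16, 16]) < 0.5 and abs(disp[2, 15, 16, 16]) < 0.5

    def test_energy_trace_non_increasing_within_stage(self):
        grid = VoxelGrid.from_spacing((32, 32, 32), (1, 1, 1))
        atlas = IntensityVolume(grid, _bump((15, 15, 16)).astype(np.float32))
        target = IntensityVolume(grid, _bump((17, 16, 16)).astype(np.float32))
        _, _, trace = lddmm_match(atlas, target)
        for _, stage_rows in trace.groupby("stage"):
            total = stage_rows["total"].to_numpy()
            assert np.all(np.diff(total) <= 1e-9 * np.abs(total[:-1]))

    def test_grid_mismatch(self):
        g1 = VoxelGrid.from_spacing((16, 16, 16), (1, 1, 1))
        g2 = VoxelGrid.from_spacing((16, 16, 8), (1, 1, 1))
        a = IntensityVolume(g1, np.zeros((16, 16, 16), dtype=np.float32))
        b = IntensityVolume(g2, np.zeros((16, 16, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            lddmm_match(a, b)


def test_diffeomorphism_nifti_roundtrip(tmp_path):
    from likefusion.lddmm import load_diffeomorphism, save_diffeomorphism

    rng = np.random.default_rng(9)
    v = VelocityField((0.05 * rng.normal(size=(2, 3, 12, 12, 12))).astype(np.float32))
    d = integrate_flow(v)
    save_diffeomorphism(d, tmp_path / "fwd.nii.gz", tmp_path / "inv.nii.gz")
    back = load_diffeomorphism(tmp_path / "fwd.nii.gz", tmp_path / "inv.nii.gz")
    assert np.allclose(back.forward, d.forward, atol=1e-6)
    assert np.allclose(back.inverse, d.inverse, atol=1e-6)
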