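"""Trilinear sampling, maximum-gradient direction and SIG at wall points."""

import numpy as np
import pytest

from tofsig import (
    Volume,
    compute_sig,
    extract_wall,
    gradient_direction,
    trilinear_sample,
)
from tofsig.errors import OutOfBoundsError, ParameterError
from tofsig.sig_core import FLAG_FLAT, FLAG_OOB
from tofsig.volume_io import voxel_to_world


def _field_volume(fn, shape=(10, 11, 9), spacing=(0.8, 1.1, 0.7)):
    v = Volume(data=np.zeros(shape), spacing=spacing)
    xs, ys, zs = v.axes_world()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    return Volume(data=fn(gx, gy, gz), spacing=spacing)


def _interior_points(v, rng, n):
    lo, hi = v.world_bounds()
    return rng.uniform(lo + 1e-6, hi - 1e-6, size=(n, 3))


class TestTrilinearSample:
    def test_voxel_center_identity(self, random_volume, rng):
        idx = np.column_stack([rng.integers(0, s, 30) for s in random_volume.shape])
        pos = voxel_to_world(random_volume, idx)
        vals = trilinear_sample(random_volume, pos)
        assert np.allclose(vals, random_volume.data[idx[:, 0], idx[:, 1], idx[:, 2]],
                           atol=1e-12)

    def test_affine_field_reproduced_exactly(self, rng):
        v = _field_volume(lambda x, y, z: 3 * x + 2 * y - z + 5)
        pts = _interior_points(v, rng, 200)
        expected = 3 * pts[:, 0] + 2 * pts[:, 1] - pts[:, 2] + 5
        assert np.allclose(trilinear_sample(v, pts), expected, atol=1e-12)

    def test_matches_corner_weight_oracle(self, rng):
        """Brute-force oracle: explicit 8-corner weighted sum."""
        v = Volume(data=rng.normal(size=(4, 4, 4)), spacing=(0.9, 1.2, 0.6))
        pts = _interior_points(v, rng, 100)
        for p in pts:
            f = (p / np.asarray(v.spacing)) + v.center_index  # fractional index
            i0 = np.floor(f).astype(int)
            i0 = np.minimum(i0, np.array(v.shape) - 2)
            t = f - i0
            acc = 0.0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        w = (
                            (t[0] if di else 1 - t[0])
                            * (t[1] if dj else 1 - t[1])
                            * (t[2] if dk else 1 - t[2])
                        )
                        acc += w * v.data[i0[0] + di, i0[1] + dj, i0[2] + dk]
            assert trilinear_sample(v, p) == pytest.approx(acc, abs=1e-12)

    def test_out_of_bounds_rejected(self, random_volume):
        lo, hi = random_volume.world_bounds()
        with pytest.raises(OutOfBoundsError):
            trilinear_sample(random_volume, hi + 1.0)


class TestGradientDirection:
    def test_uniform_gradient(self, rng):
        v = _field_volume(lambda x, y, z: 5 * x)
        pts = _interior_points(v, rng, 50)
        n, flat = gradient_direction(v, pts)
        assert not flat.any()
        assert np.allclose(n, [1.0, 0.0, 0.0], atol=1e-12)

    def test_radial_hill_points_to_center(self):
        v = _field_volume(lambda x, y, z: -(x**2 + y**2 + z**2),
                          shape=(11, 11, 11), spacing=(1, 1, 1))
        n, flat = gradient_direction(v, (0.0, 2.0, 0.0))
        assert not flat
        assert np.allclose(n, [0.0, -1.0, 0.0], atol=1e-9)

    def test_smooth_field_matches_analytic_within_2_degrees(self, rng):
        """Sum-of-sinusoids field: interpolated central-difference direction
        vs the closed-form gradient."""
        k1, k2 = 0.25, 0.4

        def field(x, y, z):
            return np.sin(k1 * x) * np.cos(k2 * y) + 0.5 * np.sin(k2 * z)

        def grad(p):
            x, y, z = p.T
            return np.column_stack(
                [
                    k1 * np.cos(k1 * x) * np.cos(k2 * y),
                    -k2 * np.sin(k1 * x) * np.sin(k2 * y),
                    0.5 * k2 * np.cos(k2 * z),
                ]
            )

        v = _field_volume(field, shape=(32, 32, 32), spacing=(0.25, 0.25, 0.25))
        # stay 2 voxels off the border: there one-sided differences apply
        # and the O(h^2) central-difference accuracy claim does not
        lo, hi = v.world_bounds()
        pts = rng.uniform(lo + 0.5, hi - 0.5, size=(200, 3))
        n, flat = gradient_direction(v, pts)
        g = grad(pts)
        gnorm = np.linalg.norm(g, axis=1)
        # direction is ill-conditioned where the gradient vanishes; such
        # points are flagged/excluded by the method, so compare only where
        # a meaningful gradient exists
        ok = ~flat & (gnorm > 0.25 * np.median(gnorm))
        assert ok.sum() > 100
        g_unit = g[ok] / gnorm[ok, None]
        angles = np.degrees(
            np.arccos(np.clip(np.sum(n[ok] * g_unit, axis=1), -1, 1))
        )
        assert np.max(angles) < 2.0

    def test_flat_field_flagged(self):
        v = _field_volume(lambda x, y, z: np.ones_like(x) * 7.0)
        n, flat = gradient_direction(v, (0.0, 0.0, 0.0))
        assert flat
        assert np.all(np.isnan(n))


class TestComputeSig:
    @pytest.mark.parametrize("g", [1.0, 10.0, 100.0])
    def test_linear_field_exact(self, g):
        """Phi = g*x: SIG equals g at every vertex of any embedded iso surface."""
        v = _field_volume(lambda x, y, z: g * x, shape=(12, 12, 12),
                          spacing=(0.8, 1.1, 0.9))
        mesh = extract_wall(v, g * 0.37)
        wps = compute_sig(v, mesh, d=0.03)
        assert wps.valid.all()
        assert np.allclose(wps.sig_scalar, g, rtol=1e-9)
        assert np.allclose(wps.directions, [1.0, 0.0, 0.0], atol=1e-9)

    def test_point_set_contracts(self, gaussian_tube):
        """Unit directions, exact offset distance, vector/scalar consistency."""
        _, vol, _ = gaussian_tube
        mesh = extract_wall(vol, 55.0)
        wps = compute_sig(vol, mesh, d=0.03)
        ok = wps.valid
        assert ok.sum() > 500
        norms = np.linalg.norm(wps.directions[ok], axis=1)
        assert np.all(np.abs(norms - 1.0) <= 1e-9)
        dist = np.linalg.norm(wps.inner_positions[ok] - wps.positions[ok], axis=1)
        assert np.all(np.abs(dist - 0.03) <= 1e-9)
        assert np.allclose(wps.sig_vector[ok],
                           wps.sig_scalar[ok, None] * wps.directions[ok])
        assert np.allclose(np.linalg.norm(wps.sig_vector[ok], axis=1),
                           np.abs(wps.sig_scalar[ok]))

    def test_gaussian_tube_matches_analytic_derivative(self, gaussian_tube):
        """Median relative error vs |dPhi/dr| at the iso radius < 5% at
        spacing sigma/4."""
        _, vol, oracle = gaussian_tube
        iso = 55.0
        mesh = extract_wall(vol, iso)
        wps = compute_sig(vol, mesh, d=0.03)
        truth = oracle.wall_gradient_magnitude(iso)
        rel = np.abs(wps.sig_scalar[wps.valid] - truth) / truth
        assert np.median(rel) < 0.05

    def test_positive_on_enhancing_lumen(self, sigmoid_tube):
        """n points toward increasing SI, so SIG > 0 on a bright tube wall."""
        _, vol, _ = sigmoid_tube
        mesh = extract_wall(vol, 55.0)
        wps = compute_sig(vol, mesh)
        assert np.all(wps.sig_scalar[wps.valid] > 0)

    def test_linearity_in_intensity_scale(self, gaussian_tube):
        _, vol, _ = gaussian_tube
        mesh = extract_wall(vol, 55.0)
        a = compute_sig(vol, mesh)
        scaled = Volume(data=3.0 * vol.data, spacing=vol.spacing)
        b = compute_sig(scaled, mesh)
        ok = a.valid & b.valid
        assert np.allclose(b.sig_scalar[ok], 3.0 * a.sig_scalar[ok], rtol=1e-10)

    def test_offset_convergence_on_analytic_field(self, gaussian_tube):
        """The finite-offset quotient (Phi(X_a + d n) - Phi(X_a)) / d
        converges to ||grad Phi(X_a)|| as d -> 0: on the analytic field the
        error shrinks monotonically over d in {0.3, 0.1, 0.03} mm."""
        _, vol, oracle = gaussian_tube
        mesh = extract_wall(vol, 55.0)
        pts = mesh.vertices
        g = oracle.grad(pts)
        gnorm = np.linalg.norm(g, axis=1)
        n = g / gnorm[:, None]
        errors = []
        for d in (0.3, 0.1, 0.03):
            quotient = (oracle.phi(pts + d * n) - oracle.phi(pts)) / d
            errors.append(np.median(np.abs(quotient - gnorm)))
        assert errors[0] > errors[1] > errors[2]

    def test_offset_bias_visible_through_pipeline(self):
        """On the gridded volume the d = 0.3 mm offset is measurably worse
        than d = 0.03 mm (below that, spatial discretization dominates)."""
        from tofsig import PhantomSpec, generate_phantom

        spec = PhantomSpec(
            geometry="straight_tube", radius=4.0, profile="gaussian",
            sigma=4.0, amplitude=100.0, background=5.0, noise_sd=0.0,
            spacing=(0.5, 0.5, 0.5), shape=(40, 40, 26),
        )
        vol, oracle = generate_phantom(spec)
        mesh = extract_wall(vol, 80.5)
        truth = np.linalg.norm(oracle.grad(mesh.vertices), axis=1)
        errors = []
        for d in (0.3, 0.03):
            wps = compute_sig(vol, mesh, d=d)
            ok = wps.valid
            errors.append(np.median(np.abs(wps.sig_scalar[ok] - truth[ok])))
        assert errors[0] > errors[1]

    def test_invalid_offset_rejected(self, gaussian_tube):
        _, vol, _ = gaussian_tube
        with pytest.raises(ParameterError):
            compute_sig(vol, np.zeros((1, 3)), d=0.0)

    def test_border_points_flagged_not_fatal(self, gaussian_tube):
        _, vol, _ = gaussian_tube
        lo, hi = vol.world_bounds()
        outside = np.array([hi + 5.0])
        near_flat = np.array([[hi[0] - 0.01, 0.0, 0.0]])  # far tail: ~zero gradient
        wps = compute_sig(vol, np.vstack([outside, near_flat]))
        assert wps.flags[0] == FLAG_OOB
        assert wps.flags[1] in (FLAG_FLAT, 0)
        assert np.isnan(wps.sig_scalar[0])

    def test_rotation_about_tube_axis(self):
        """Rotating an azimuthally modulated tube 30 degrees about its axis
        changes the mean wall SIG by < 2%."""
        from tofsig import PhantomSpec, generate_phantom, normalize_volume

        means = []
        for phase_deg in (0.0, 30.0):
            th = np.deg2rad(phase_deg)
            spec = PhantomSpec(
                azimuthal_mod=0.5,
                azimuth_ref=(float(np.cos(th)), float(np.sin(th)), 0.0),
                noise_sd=0.0,
            )
            vol, _ = generate_phantom(spec)
            norm, stats = normalize_volume(vol)
            iso = float(stats.apply(30.0))
            mesh = extract_wall(norm, iso)
            wps = compute_sig(norm, mesh)
            means.append(wps.summary()["sig_mean"])
        assert abs(means[1] - means[0]) / means[0] < 0.02
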