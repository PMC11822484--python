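"""Gridded field container: sampling, gradients, IO round-trips."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from mstsim.field import TemperatureField2D, import_temperature_map
from mstsim.fixtures import FixtureSpec, make_fixture


class TestSampling:
    def test_nodal_values_exact(self, gaussian_field):
        f = gaussian_field
        ix, iy = 13, 57
        T, grad = f.sample((f.x[ix], f.y[iy]))
        assert T == pytest.approx(f.T[ix, iy], rel=1e-12)
        assert grad[0] == pytest.approx(f.grad_x[ix, iy], rel=1e-12)
        assert grad[1] == pytest.approx(f.grad_y[ix, iy], rel=1e-12)

    def test_cell_midpoint_is_corner_mean(self, gaussian_field):
        f = gaussian_field
        ix, iy = 20, 30
        mid = (0.5 * (f.x[ix] + f.x[ix + 1]), 0.5 * (f.y[iy] + f.y[iy + 1]))
        T, _ = f.sample(mid)
        corners = f.T[ix : ix + 2, iy : iy + 2]
        assert T == pytest.approx(corners.mean(), rel=1e-14)

    def test_linear_field_gradient_everywhere(self, linear_field):
        f = linear_field
        rng = np.random.default_rng(7)
        pts = rng.uniform(-50e-6, 50e-6, size=(100, 2))
        T, grad = f.sample(pts)
        c = 0.5 / 50e-6  # amplitude / length_scale
        assert np.allclose(grad[:, 0], c, rtol=1e-9)
        assert np.allclose(grad[:, 1], 0.0, atol=1e-12)
        assert np.allclose(T, f.ambient + c * pts[:, 0], rtol=1e-12)

    def test_matches_scipy_regular_grid_interpolator(self, gaussian_field):
        """Independent cross-check of the bilinear sampler."""
        f = gaussian_field
        rgi = RegularGridInterpolator((f.x, f.y), f.T, method="linear")
        rng = np.random.default_rng(11)
        pts = rng.uniform(-39e-6, 39e-6, size=(200, 2))
        T, _ = f.sample(pts)
        assert np.allclose(T, rgi(pts), rtol=1e-12, atol=1e-12)

    def test_out_of_bounds_rejected(self, gaussian_field):
        with pytest.raises(ValueError):
            gaussian_field.sample((1.0, 0.0))


class TestValidation:
    def test_nonuniform_axis_rejected(self):
        x = np.array([0.0, 1.0, 3.0]) * 1e-6
        y = np.array([0.0, 1.0, 2.0]) * 1e-6
        Z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            TemperatureField2D(x=x, y=y, T=Z, grad_x=Z, grad_y=Z)

    def test_shape_mismatch_rejected(self):
        ax = np.arange(4.0) * 1e-6
        with pytest.raises(ValueError):
            TemperatureField2D(
                x=ax, y=ax, T=np.zeros((4, 4)), grad_x=np.zeros((3, 4)), grad_y=np.zeros((4, 4))
            )


class TestIO:
    def test_npz_roundtrip_bitstable(self, gaussian_field, tmp_path):
        p = tmp_path / "field.npz"
        gaussian_field.save_npz(p)
        back = TemperatureField2D.load_npz(p)
        assert np.array_equal(back.T, gaussian_field.T)
        assert np.array_equal(back.grad_x, gaussian_field.grad_x)
        assert np.array_equal(back.x, gaussian_field.x)
        assert back.ambient == gaussian_field.ambient

    def test_csv_roundtrip(self, gaussian_field, tmp_path):
        p = tmp_path / "field.csv"
        gaussian_field.save_csv(p)
        back = TemperatureField2D.load_csv(p)
        assert np.allclose(back.T, gaussian_field.T, rtol=1e-12)
        assert np.allclose(back.grad_x, gaussian_field.grad_x, rtol=1e-12)
        assert back.ambient == pytest.approx(gaussian_field.ambient)

    def test_import_constant_map_zero_gradient(self, tmp_path):
        p = tmp_path / "const.csv"
        ax = np.arange(5) * 1.0  # um
        rows = ["x,y,T"] + [f"{x},{y},300.0" for x in ax for y in ax]
        p.write_text("\n".join(rows) + "\n")
        f = import_temperature_map(p, units="K", length_units="um")
        assert np.allclose(f.grad_x, 0.0) and np.allclose(f.grad_y, 0.0)
        assert f.x[1] - f.x[0] == pytest.approx(1e-6)

    def test_import_celsius_conversion(self, tmp_path):
        p = tmp_path / "c.csv"
        rows = ["x,y,T"] + [f"{x},{y},{24.0 + x}" for x in range(3) for y in range(3)]
        p.write_text("\n".join(rows) + "\n")
        f = import_temperature_map(p, units="C", length_units="um")
        assert f.T.min() == pytest.approx(297.15)
        assert f.T.max() == pytest.approx(299.15)

    def test_import_gaussian_hotspot_preserves_peak(self, tmp_path):
        amb, A, sig = 297.15, 2.0, 8e-6
        ax = np.linspace(-30e-6, 30e-6, 61)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        T = amb + A * np.exp(-(xx**2 + yy**2) / (2 * sig**2))
        rows = ["x,y,T"] + [
            f"{x:.17g},{y:.17g},{t:.17g}" for x, y, t in zip(xx.ravel(), yy.ravel(), T.ravel())
        ]
        p = tmp_path / "gauss.csv"
        p.write_text("\n".join(rows) + "\n")
        f = import_temperature_map(p, units="K", length_units="m", ambient=amb)
        i, j = np.unravel_index(np.argmax(f.T), f.T.shape)
        assert f.x[i] == pytest.approx(0.0, abs=1e-12)
        assert f.y[j] == pytest.approx(0.0, abs=1e-12)
        assert f.T[i, j] == pytest.approx(amb + A, rel=1e-12)
        # central-difference gradient approximates the analytic one
        T0, grad = f.sample((sig, 0.0))
        analytic = -A * sig / sig**2 * np.exp(-0.5)
        assert grad[0] == pytest.approx(analytic, rel=0.02)

    def test_ragged_grid_rejected(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("x,y,T\n0,0,300\n0,1,300\n1,0,300\n")
        with pytest.raises(ValueError):
            import_temperature_map(p, length_units="um")


class TestFixtures:
    def test_flat_fixture(self, flat_field):
        assert np.allclose(flat_field.T, flat_field.ambient)
        assert np.allclose(flat_field.grad_x, 0.0)

    def test_gaussian_fixture_matches_closed_form(self):
        spec = FixtureSpec("gaussian", amplitude=1.5, length_scale=12e-6, half_width=30e-6, spacing=1e-6)
        f = make_fixture(spec)
        xx, yy = np.meshgrid(f.x, f.y, indexing="ij")
        expected = spec.ambient + 1.5 * np.exp(-(xx**2 + yy**2) / (2 * 12e-6**2))
        assert np.array_equal(f.T, expected)

    def test_shell_fixture_gradient_inverse_square(self):
        spec = FixtureSpec("shell", amplitude=2.0, length_scale=10e-6, half_width=40e-6, spacing=1e-6)
        f = make_fixture(spec)
        xx, yy = np.meshgrid(f.x, f.y, indexing="ij")
        r = np.hypot(xx, yy)
        outside = r > 10e-6
        g = np.hypot(f.grad_x, f.grad_y)
        # |grad T| = A * L / r^2 on the 1/r tail, zero in the flat core
        assert np.allclose(g[outside], 2.0 * 10e-6 / r[outside] ** 2, rtol=1e-12)
        assert np.allclose(g[~outside], 0.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec("vortex")
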