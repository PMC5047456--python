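"""Dose-response mapping, volume-weighted statistics, SAR, paired stats."""

import numpy as np
import pytest

import craniofield as cf
from craniofield.conductivity import ConductivityField, TissueTable
from craniofield.constants import Tissue
from craniofield.mesh import box_mesh
from craniofield.metrics import (TERModel, paired_difference, r_squared,
                                 region_stats, sar, ter, weighted_quantile)
from craniofield.solver import FieldSolution


def make_solution(mesh, E, name="t", current=0.9):
    E = np.asarray(E, dtype=float)
    return FieldSolution(pair_name=name, current=current,
                         phi=np.zeros(mesh.n_nodes), E=E,
                         J=E.copy(), mesh_hash=mesh.geometry_hash())


@pytest.fixture(scope="module")
def cube():
    return box_mesh((2, 2, 2), (10.0, 10.0, 10.0), label=int(Tissue.WM))


class TestTERMapping:
    @pytest.mark.parametrize("x, expected, tol", [
        (100.0, 0.0, 0.0),          # below the measured range: no effect
        (109.9, 0.0, 0.0),
        (300.0, 1.245, 0.0),        # above the range: clamped
        (110.0, 0.175, 0.005),      # cubic at the lower threshold
        (225.0, 1.037, 0.005),      # growth-arrest point, TER ~ 1
    ])
    def test_pointwise_values(self, x, expected, tol):
        assert ter(x) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_nondecreasing_on_dense_grid(self):
        x = np.linspace(0.0, 500.0, 20001)
        y = ter(x)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0.0) & (y <= 1.245))

    def test_smallest_effective_field_on_integer_grid(self):
        x = np.arange(0, 301, dtype=float)
        y = ter(x)
        assert x[np.argmax(y > 0)] == 110.0

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            ter(-1.0)

    def test_vectorized_matches_scalar(self):
        xs = np.array([0.0, 110.0, 175.0, 240.0, 400.0])
        assert np.allclose(ter(xs), [ter(float(v)) for v in xs])


class TestWeightedQuantile:
    def test_equal_weights_median_matches_numpy(self, rng):
        v = rng.normal(size=101)
        assert weighted_quantile(v, 0.5) == pytest.approx(np.median(v))
        v = rng.normal(size=100)
        assert weighted_quantile(v, 0.5) == pytest.approx(np.median(v))

    def test_matches_midpoint_rule_oracle(self, rng):
        """Independent brute-force midpoint-rule implementation."""
        v = rng.normal(size=37)
        w = rng.uniform(0.5, 2.0, size=37)
        order = np.argsort(v)
        vs, ws = v[order], w[order]
        pos = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
        for q in (0.1, 0.25, 0.5, 0.75, 0.99):
            assert weighted_quantile(v, q, w) == pytest.approx(
                np.interp(q, pos, vs))

    def test_threshold_fractions_invariant_under_subdivision(self, rng):
        # halving every element (same value, half the volume each) must not
        # change any volume-fraction threshold statistic
        v = rng.uniform(0, 300, size=25)
        w = rng.uniform(0.5, 2.0, size=25)
        v2 = np.repeat(v, 2)
        w2 = np.repeat(w / 2.0, 2)
        for thr in (100.0, 225.0):
            f1 = w[v >= thr].sum() / w.sum()
            f2 = w2[v2 >= thr].sum() / w2.sum()
            assert f1 == pytest.approx(f2)


class TestRegionStats:
    def test_threshold_percentages(self, cube):
        # equal-volume elements at 100, 230, 250 V/m (and padding to fill
        # the cube mesh): P100 counts >= 100, P225 counts >= 225
        mesh = box_mesh((1, 1, 3), (1.0, 1.0, 3.0))
        E = np.zeros((mesh.n_elements, 3))
        vals = np.array([100.0, 230.0, 250.0])
        # each cube cell splits into 6 equal-volume tets
        E[:, 0] = np.repeat(vals, 6)
        sol = make_solution(mesh, E)
        stats = region_stats(sol, mesh, np.ones(mesh.n_elements, bool))
        assert stats["P100"] == pytest.approx(100.0)
        assert stats["P225"] == pytest.approx(66.667, rel=1e-3)

    def test_identical_field_degenerate_stats(self, cube):
        E = np.tile([123.0, 0, 0], (cube.n_elements, 1))
        stats = region_stats(make_solution(cube, E), cube,
                             np.ones(cube.n_elements, bool))
        assert stats["Q2"] == pytest.approx(123.0)
        assert stats["IQR"] == pytest.approx(0.0)

    def test_p225_never_exceeds_p100(self, cube, rng):
        E = np.zeros((cube.n_elements, 3))
        E[:, 0] = rng.uniform(0, 400, cube.n_elements)
        stats = region_stats(make_solution(cube, E), cube,
                             np.ones(cube.n_elements, bool))
        assert 0.0 <= stats["P225"] <= stats["P100"] <= 100.0

    def test_equal_volume_stats_match_sort_oracle(self, rng):
        mesh = box_mesh((2, 2, 2), (8.0, 8.0, 8.0))
        mag = rng.uniform(0, 300, mesh.n_elements)
        E = np.zeros((mesh.n_elements, 3))
        E[:, 1] = mag
        stats = region_stats(make_solution(mesh, E), mesh,
                             np.ones(mesh.n_elements, bool))
        assert stats["Q2"] == pytest.approx(np.median(mag))
        # IQR against the same midpoint definition, computed independently
        s = np.sort(mag)
        pos = (np.arange(len(s)) + 0.5) / len(s)
        iqr = np.interp(0.75, pos, s) - np.interp(0.25, pos, s)
        assert stats["IQR"] == pytest.approx(iqr)

    def test_empty_region_rejected(self, cube):
        E = np.zeros((cube.n_elements, 3))
        with pytest.raises(ValueError, match="nothing"):
            region_stats(make_solution(cube, E), cube,
                         np.zeros(cube.n_elements, bool),
                         region_name="nothing")


class TestSAR:
    def test_printed_formula_arithmetic(self, cube):
        # sigma = 0.465 S/m, |E| = 100 V/m, rho = 1000 kg/m^3 -> 4.65 W/kg
        M = cube.n_elements
        sigma = ConductivityField(0.465 * np.tile(np.eye(3), (M, 1, 1)),
                                  np.zeros(M, dtype=int))
        E = np.tile([100.0, 0, 0], (M, 1))
        table = TissueTable(density={Tissue.WM: 1000.0})
        out = sar(make_solution(cube, E), sigma, cube, table)
        assert np.allclose(out, 4.65)

    def test_zero_field_zero_sar(self, cube):
        M = cube.n_elements
        sigma = ConductivityField(np.tile(np.eye(3), (M, 1, 1)),
                                  np.zeros(M, dtype=int))
        out = sar(make_solution(cube, np.zeros((M, 3))), sigma, cube)
        assert np.all(out == 0.0)

    def test_anisotropic_eigen_aligned(self, cube, rng):
        """E along a principal axis with eigenvalue lam gives lam |E|^2 / rho."""
        M = cube.n_elements
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        lam = np.array([0.4, 0.2, 0.1])
        tensor = Q @ np.diag(lam) @ Q.T
        sigma = ConductivityField(np.tile(tensor, (M, 1, 1)),
                                  np.zeros(M, dtype=int))
        E = np.tile(Q[:, 0] * 150.0, (M, 1))
        table = TissueTable(density={Tissue.WM: 1045.0})
        out = sar(make_solution(cube, E), sigma, cube, table)
        assert np.allclose(out, 0.4 * 150.0 ** 2 / 1045.0)

    def test_missing_density_rejected(self, cube):
        M = cube.n_elements
        sigma = ConductivityField(np.tile(np.eye(3), (M, 1, 1)),
                                  np.zeros(M, dtype=int))
        table = TissueTable(density={Tissue.GM: 1045.0})
        with pytest.raises(ValueError, match="density"):
            sar(make_solution(cube, np.zeros((M, 3))), sigma, cube, table)

    def test_sar_quadratic_in_current(self, study, baseline):
        """Doubling the injected current quadruples SAR everywhere."""
        sol = baseline.solutions["LR"]
        doubled = FieldSolution(pair_name="LR", current=2 * sol.current,
                                phi=2 * sol.phi, E=2 * sol.E, J=2 * sol.J,
                                mesh_hash=sol.mesh_hash)
        s1 = sar(sol, baseline.sigma, baseline.mesh)
        s2 = sar(doubled, baseline.sigma, baseline.mesh)
        assert np.allclose(s2, 4.0 * s1)


class TestPairedStats:
    def test_identical_solutions_zero_delta_unit_r2(self, cube):
        E = np.random.default_rng(3).uniform(0, 200, (cube.n_elements, 3))
        a = make_solution(cube, E)
        b = make_solution(cube, E.copy())
        d = paired_difference(a, b, cube)
        assert np.all(d["delta"] == 0.0)
        assert r_squared(a, b, cube, np.ones(cube.n_elements, bool)) == \
            pytest.approx(1.0)

    def test_scaled_solution_delta_is_field_itself(self, cube):
        E = np.random.default_rng(4).uniform(10, 200, (cube.n_elements, 3))
        a = make_solution(cube, 2.0 * E)
        b = make_solution(cube, E)
        d = paired_difference(a, b, cube)
        assert np.allclose(d["delta"], b.magnitude)
        assert d["fraction_increased"] == pytest.approx(1.0)

    def test_affine_transform_r2_is_one(self, cube):
        mag = np.random.default_rng(5).uniform(10, 200, cube.n_elements)
        E = np.zeros((cube.n_elements, 3))
        E[:, 0] = mag
        E2 = np.zeros_like(E)
        E2[:, 0] = 3.0 * mag + 17.0
        assert r_squared(make_solution(cube, E), make_solution(cube, E2),
                         cube, np.ones(cube.n_elements, bool)) == \
            pytest.approx(1.0)

    def test_r2_matches_covariance_oracle(self, cube, rng):
        x = rng.uniform(0, 100, cube.n_elements)
        y = 0.4 * x + rng.normal(0, 10, cube.n_elements)
        Ex = np.zeros((cube.n_elements, 3))
        Ex[:, 2] = x
        Ey = np.zeros_like(Ex)
        Ey[:, 2] = np.abs(y)
        got = r_squared(make_solution(cube, Ex), make_solution(cube, Ey),
                        cube, np.ones(cube.n_elements, bool))
        w = cube.volumes / cube.volumes.sum()
        yy = np.abs(y)
        mx, my = w @ x, w @ yy
        cov = w @ ((x - mx) * (yy - my))
        expect = cov ** 2 / ((w @ ((x - mx) ** 2)) * (w @ ((yy - my) ** 2)))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_mesh_mismatch_rejected(self, cube):
        other = box_mesh((2, 2, 2), (9.0, 9.0, 9.0))
        a = make_solution(cube, np.zeros((cube.n_elements, 3)))
        b = make_solution(other, np.zeros((other.n_elements, 3)))
        with pytest.raises(ValueError, match="mesh"):
            paired_difference(a, b, cube)

    def test_zero_variance_r2_undefined(self, cube):
        E = np.tile([100.0, 0, 0], (cube.n_elements, 1))
        a = make_solution(cube, E)
        b = make_solution(cube, E.copy())
        with pytest.raises(ValueError, match="variance"):
            r_squared(a, b, cube, np.ones(cube.n_elements, bool))
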