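import numpy as np
import pytest

import laflow
from laflow import (FlowDataset, HemoParams, Mask3D, TimeSeries,
                    kinetic_energy, ke_vel_ratio, median_filter3,
                    q_criterion, velocity_gradient, viscous_energy_loss,
                    vorticity)
from laflow.synthetic import (lamb_oseen, poiseuille_tube, simple_shear,
                              solid_body_rotation)

from conftest import naive_gradient

MU = 0.0035


class TestVelocityGradient:
    def test_affine_field_exact(self):
        # v_x = a*x: d(v_x)/dx = a at every voxel, one-sided stencils included
        a = 7.0
        n = 10
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        vel = np.zeros((1, n, n, n, 3))
        vel[0, ..., 0] = a * xx * 2e-3   # x in m at 2 mm spacing
        ds = FlowDataset(vel, np.ones((1, n, n, n)), spacing=(2, 2, 2))
        mask = Mask3D(np.ones((n, n, n), dtype=np.int16), {"LA": 1},
                      (2, 2, 2))
        g = velocity_gradient(ds, mask, "LA")
        assert np.abs(g.tensor[..., 0, 0] - a).max() < 1e-10
        assert not g.reduced.any()

    def test_solid_body_antisymmetric(self):
        ds, mask = solid_body_rotation(3.0, shape=(10, 10, 10))
        g = velocity_gradient(ds, mask, "LA")
        sym = 0.5 * (g.tensor + np.swapaxes(g.tensor, -1, -2))
        interior = np.zeros(mask.labels.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.linalg.norm(sym[interior], axis=(-1, -2)).max() < 1e-8
        assert g.tensor[5, 5, 5, 0, 1] == pytest.approx(-3.0)
        assert g.tensor[5, 5, 5, 1, 0] == pytest.approx(3.0)

    def test_single_voxel_mask_flagged(self):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[2, 2, 2] = 1
        mask = Mask3D(labels, {"LA": 1}, (1, 1, 1))
        vel = np.random.default_rng(0).normal(size=(1, 5, 5, 5, 3))
        ds = FlowDataset(vel, np.ones((1, 5, 5, 5)), spacing=(1, 1, 1))
        g = velocity_gradient(ds, mask, "LA")
        assert np.all(g.tensor[2, 2, 2] == 0)
        assert g.reduced[2, 2, 2]

    def test_empty_label_error(self):
        mask = Mask3D(np.zeros((5, 5, 5), dtype=np.int16), {"LA": 1},
                      (1, 1, 1))
        ds = FlowDataset(np.zeros((1, 5, 5, 5, 3)), np.ones((1, 5, 5, 5)),
                         spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="no voxels"):
            velocity_gradient(ds, mask, "LA")

    def test_matches_naive_loop_oracle(self, tiny_random_ds):
        rng = np.random.default_rng(7)
        labels = (rng.uniform(size=(12, 12, 12)) < 0.7).astype(np.int16)
        mask = Mask3D(labels, {"LA": 1}, tiny_random_ds.spacing)
        g = velocity_gradient(tiny_random_ds, mask, "LA", phase=1)
        want = naive_gradient(tiny_random_ds.velocity[1], mask.region("LA"),
                              tiny_random_ds.spacing)
        assert np.abs(g.tensor - want).max() < 1e-10


class TestVorticity:
    def test_solid_body_curl(self):
        ds, mask = solid_body_rotation(1.0, shape=(40, 40, 40))
        omega, series = vorticity(ds, mask)
        mag = np.linalg.norm(omega[0], axis=-1)
        assert np.abs(mag[1:-1, 1:-1, 1:-1] - 2.0).max() < 1e-9
        assert series.values[0] == pytest.approx(2.0, rel=0.02)
        assert series.units == "1/s"

    def test_uniform_flow_irrotational(self):
        vel = np.zeros((2, 8, 8, 8, 3))
        vel[..., 1] = 0.7
        ds = FlowDataset(vel, np.ones((2, 8, 8, 8)), spacing=(2, 2, 2))
        mask = Mask3D(np.ones((8, 8, 8), dtype=np.int16), {"LA": 1},
                      (2, 2, 2))
        _, series = vorticity(ds, mask)
        assert np.all(series.values == 0)

    def test_lamb_oseen_peak(self):
        gamma_c, r_c = 0.01, 6.0
        ds, mask = lamb_oseen(gamma_c, r_c, shape=(8, 48, 48),
                              spacing=(1.0, 1.0, 1.0))
        omega, _ = vorticity(ds, mask)
        peak = np.abs(omega[0][..., 2]).max()
        analytic = gamma_c / (np.pi * (r_c * 1e-3) ** 2)
        assert peak == pytest.approx(analytic, rel=0.03)


class TestQCriterion:
    def test_rigid_rotation_value_and_ratio(self):
        ds, mask = solid_body_rotation(30.0, shape=(20, 20, 20))
        q, ratio = q_criterion(ds, mask, params=HemoParams(q_threshold=500))
        assert np.abs(q[0][1:-1, 1:-1, 1:-1] - 900.0).max() < 1e-6
        # linear field: one-sided boundary stencils are exact, so every
        # region voxel clears the threshold
        assert ratio.values[0] == 1.0

    def test_simple_shear_cancels(self):
        ds, mask = simple_shear(10.0)
        q, ratio = q_criterion(ds, mask)
        assert np.abs(q).max() < 1e-8
        assert np.all(ratio.values == 0)

    def test_uniform_flow_zero(self):
        vel = np.zeros((1, 8, 8, 8, 3))
        vel[..., 2] = 1.0
        ds = FlowDataset(vel, np.ones((1, 8, 8, 8)), spacing=(1, 1, 1))
        mask = Mask3D(np.ones((8, 8, 8), dtype=np.int16), {"LA": 1},
                      (1, 1, 1))
        q, ratio = q_criterion(ds, mask)
        assert np.all(q == 0) and np.all(ratio.values == 0)

    def test_matches_naive_oracle(self, tiny_random_ds):
        mask = Mask3D(np.ones((12, 12, 12), dtype=np.int16), {"LA": 1},
                      tiny_random_ds.spacing)
        q, _ = q_criterion(tiny_random_ds, mask)
        g = naive_gradient(tiny_random_ds.velocity[0], mask.region("LA"),
                           tiny_random_ds.spacing)
        om = 0.5 * (g - np.swapaxes(g, -1, -2))
        s = 0.5 * (g + np.swapaxes(g, -1, -2))
        want = 0.5 * (np.sum(om ** 2, axis=(-1, -2))
                      - np.sum(s ** 2, axis=(-1, -2)))
        assert np.abs(q[0] - want).max() < 1e-10


class TestKineticEnergy:
    def test_uniform_field_closed_form(self):
        # |v| = 0.5 m/s over 1e-4 m^3 at rho = 1060 -> 13.25 mJ
        n = 10
        h_mm = (1e-4 / n ** 3) ** (1 / 3) * 1e3
        vel = np.zeros((1, n, n, n, 3))
        vel[..., 0] = 0.5
        ds = FlowDataset(vel, np.ones((1, n, n, n)),
                         spacing=(h_mm, h_mm, h_mm))
        mask = Mask3D(np.ones((n, n, n), dtype=np.int16), {"LA": 1},
                      (h_mm, h_mm, h_mm))
        ke, ke_pv = kinetic_energy(ds, mask)
        assert ke.values[0] == pytest.approx(13.25, rel=1e-9)
        assert ke.units == "mJ"
        # KE / V = 0.5 * 1060 * 0.25 J/m^3 = 132.5 uJ/ml
        assert ke_pv.values[0] == pytest.approx(132.5, rel=1e-9)

    def test_zero_field(self):
        ds, mask = solid_body_rotation(0.0, shape=(6, 6, 6))
        ke, _ = kinetic_energy(ds, mask)
        assert np.all(ke.values == 0)

    def test_quadratic_scaling(self, tiny_random_ds):
        from dataclasses import replace
        mask = Mask3D(np.ones((12, 12, 12), dtype=np.int16), {"LA": 1},
                      tiny_random_ds.spacing)
        ke1, _ = kinetic_energy(tiny_random_ds, mask)
        ke2, _ = kinetic_energy(
            replace(tiny_random_ds, velocity=tiny_random_ds.velocity * 2),
            mask)
        assert np.allclose(ke2.values, 4 * ke1.values)


class TestViscousEnergyLoss:
    def test_rigid_rotation_dissipates_nothing(self):
        ds, mask = solid_body_rotation(10.0, shape=(16, 16, 16))
        vel, _ = viscous_energy_loss(ds, mask)
        interior_only = vel.values[0]
        # boundary one-sided stencils are exact for the linear field
        assert interior_only < 1e-12

    def test_simple_shear_closed_form(self):
        k, n, h = 10.0, 16, 1.5
        ds, mask = simple_shear(k, shape=(n, n, n), spacing=(h, h, h))
        vel, _ = viscous_energy_loss(ds, mask)
        v_m3 = n ** 3 * (h * 1e-3) ** 3
        assert vel.values[0] * 1e-3 == pytest.approx(MU * k ** 2 * v_m3,
                                                     rel=0.02)

    def test_poiseuille_closed_form(self):
        # wall shear dominates; needs the wall layer resolved
        h, nz, nxy = 0.3, 40, 96
        ds, mask = poiseuille_tube(radius_mm=5.0, v0=0.4, axis="z",
                                   shape=(nz, nxy, nxy), spacing=(h, h, h))
        vel, _ = viscous_energy_loss(ds, mask)
        el_w = vel.values[0] * 1e-3
        exact = 2 * np.pi * MU * (nz * h * 1e-3) * 0.4 ** 2
        assert el_w == pytest.approx(exact, rel=0.05)

    def test_poiseuille_grid_refinement_monotone(self):
        errs = []
        for h, nz, nxy in [(2.4, 10, 12), (1.2, 20, 24), (0.6, 40, 48)]:
            ds, mask = poiseuille_tube(radius_mm=5.0, v0=0.4, axis="z",
                                       shape=(nz, nxy, nxy),
                                       spacing=(h, h, h))
            vel, _ = viscous_energy_loss(ds, mask)
            exact = 2 * np.pi * MU * (nz * h * 1e-3) * 0.4 ** 2
            errs.append(abs(vel.values[0] * 1e-3 - exact) / exact)
        assert errs[0] > errs[1] > errs[2]

    def test_nonnegative_on_random_field(self, tiny_random_ds):
        mask = Mask3D((np.random.default_rng(3).uniform(size=(12, 12, 12))
                       < 0.6).astype(np.int16), {"LA": 1},
                      tiny_random_ds.spacing)
        vel, _ = viscous_energy_loss(tiny_random_ds, mask)
        assert np.all(vel.values >= 0)

    def test_matches_naive_oracle(self, tiny_random_ds):
        mask = Mask3D(np.ones((12, 12, 12), dtype=np.int16), {"LA": 1},
                      tiny_random_ds.spacing)
        vel, _ = viscous_energy_loss(tiny_random_ds, mask)
        g = naive_gradient(tiny_random_ds.velocity[0], mask.region("LA"),
                           tiny_random_ds.spacing)
        div = np.trace(g, axis1=-2, axis2=-1)
        br = g + np.swapaxes(g, -1, -2)
        for i in range(3):
            br[..., i, i] -= (2 / 3) * div
        phi = 0.5 * np.sum(br ** 2, axis=(-1, -2))
        want = MU * phi.sum() * tiny_random_ds.voxel_volume_m3 * 1e3
        assert vel.values[0] == pytest.approx(want, rel=1e-10)


class TestKeVelRatio:
    def test_elementwise_division(self):
        t = np.array([0.0, 0.5])
        r = ke_vel_ratio(TimeSeries("ke", t, [2.0, 4.0], "mJ"),
                         TimeSeries("vel", t, [1.0, 2.0], "mW"))
        assert np.allclose(r.values, [2.0, 2.0])

    def test_zero_vel_flagged_undefined(self):
        ds, mask = solid_body_rotation(5.0, shape=(10, 10, 10))
        ke, _ = kinetic_energy(ds, mask)
        vel, _ = viscous_energy_loss(ds, mask)
        r = ke_vel_ratio(ke, vel)
        assert np.all(np.isnan(r.values))

    def test_amplitude_invariance(self):
        from dataclasses import replace
        ds, mask = lamb_oseen(0.01, 6.0, shape=(8, 32, 32),
                              spacing=(1.5, 1.5, 1.5))
        ds2 = replace(ds, velocity=ds.velocity * 1.7)
        r1 = ke_vel_ratio(kinetic_energy(ds, mask)[0],
                          viscous_energy_loss(ds, mask)[0])
        r2 = ke_vel_ratio(kinetic_energy(ds2, mask)[0],
                          viscous_energy_loss(ds2, mask)[0])
        assert np.allclose(r1.values, r2.values)

    def test_time_base_mismatch_error(self):
        with pytest.raises(ValueError, match="time base"):
            ke_vel_ratio(TimeSeries("ke", [0.0, 0.5], [1, 1], "mJ"),
                         TimeSeries("vel", [0.0, 0.4], [1, 1], "mW"))


class TestMedianFilter:
    def test_constant_unchanged(self):
        f = np.full((6, 6, 6), 2.5)
        assert np.array_equal(median_filter3(f), f)

    def test_impulse_removed(self):
        f = np.zeros((7, 7, 7))
        f[3, 3, 3] = 100.0
        assert np.all(median_filter3(f) == 0)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=(6, 6, 6))
        got = median_filter3(f)
        pad = np.pad(f, 1, mode="edge")
        for k in range(6):
            for j in range(6):
                for i in range(6):
                    nb = pad[k:k + 3, j:j + 3, i:i + 3]
                    assert got[k, j, i] == np.median(nb)

    def test_ramp_interior_unchanged(self):
        zz, yy, xx = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
        f = (xx + 2 * yy + 3 * zz).astype(float)
        out = median_filter3(f)
        assert np.array_equal(out[1:-1, 1:-1, 1:-1], f[1:-1, 1:-1, 1:-1])


class TestHomogeneity:
    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_scaling_laws_on_lamb_oseen(self, alpha):
        from dataclasses import replace
        ds, mask = lamb_oseen(0.008, 6.0, shape=(8, 32, 32),
                              spacing=(1.5, 1.5, 1.5))
        ds_a = replace(ds, velocity=ds.velocity * alpha)
        _, w1 = vorticity(ds, mask)
        _, w2 = vorticity(ds_a, mask)
        assert np.allclose(w2.values, alpha * w1.values)
        q1, _ = q_criterion(ds, mask)
        q2, _ = q_criterion(ds_a, mask)
        assert np.allclose(q2, alpha ** 2 * q1)
        ke1, _ = kinetic_energy(ds, mask)
        ke2, _ = kinetic_energy(ds_a, mask)
        assert np.allclose(ke2.values, alpha ** 2 * ke1.values)
        vel1, _ = viscous_energy_loss(ds, mask)
        vel2, _ = viscous_energy_loss(ds_a, mask)
        assert np.allclose(vel2.values, alpha ** 2 * vel1.values)
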