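"""Deterministic analytic flow fields and a left-atrial phantom.

These generators make every pipeline stage testable without patient data:

* ``solid_body_rotation`` — rigid rotation; the calibration oracle for
  vorticity (|omega| = 2*Omega_z) and the Q-criterion (Q = Omega_z^2).
* ``poiseuille_tube`` — laminar tube flow; closed forms for flux
  (pi R^2 v0 / 2) and viscous dissipation (2 pi mu L v0^2).
* ``simple_shear`` — vx = k*y; zero Q, dissipation mu k^2 V.
* ``lamb_oseen`` — a viscous line vortex; analytic vorticity profile and
  the field used for amplitude-scaling (homogeneity) checks.
* ``la_phantom`` — an ellipsoidal atrium fed by four pulmonary-vein tubes
  and drained by a mitral tube, with prescribed triphasic venous (S/D/Ar)
  and biphasic mitral (E/A) flow waveforms and an interior decaying vortex.
  Ground-truth peak values and volumes are returned alongside.

Waveforms are sums of Gaussian pulses: amplitude, center and width per wave
are explicit, so true peaks and (analytic) pulse volumes are known exactly.
Steady analytic fields are replicated over all phases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .flowdata import FlowDataset, Mask3D, SphereSeed

logger = logging.getLogger("laflow")


# ---------------------------------------------------------------------------
# Shared grid helpers
# ---------------------------------------------------------------------------

def _world_grids(shape, spacing, origin=(0.0, 0.0, 0.0)):
    """World-coordinate (x, y, z) arrays, each shaped (z, y, x), in mm."""
    nz, ny, nx = shape
    z, y, x = np.meshgrid(
        origin[2] + np.arange(nz) * spacing[2],
        origin[1] + np.arange(ny) * spacing[1],
        origin[0] + np.arange(nx) * spacing[0],
        indexing="ij")
    return x, y, z


def _as_dataset(vel_single_phase, shape, spacing, n_phases, cycle_duration,
                magnitude=None):
    vel = np.repeat(vel_single_phase[None], n_phases, axis=0)
    if magnitude is None:
        magnitude = np.ones((n_phases,) + tuple(shape))
    return FlowDataset(velocity=vel, magnitude=magnitude, spacing=spacing,
                       cycle_duration=cycle_duration)


def _check_resolution(feature_mm: float, spacing, what: str) -> None:
    if feature_mm < 4 * min(spacing):
        warnings.warn(f"{what} ({feature_mm:g} mm) is resolved by fewer "
                      f"than 4 voxels at spacing {min(spacing):g} mm")


# ---------------------------------------------------------------------------
# Analytic oracle fields
# ---------------------------------------------------------------------------

def solid_body_rotation(omega_z: float, shape=(40, 40, 40),
                        spacing=(1.5, 1.5, 1.5), n_phases: int = 1,
                        cycle_duration: float = 1.0
                        ) -> tuple[FlowDataset, Mask3D]:
    """Rigid rotation about the grid-center vertical axis.

    v = Omega x r with Omega = (0, 0, omega_z); |curl v| = 2*omega_z and
    Q = omega_z^2 everywhere. omega_z in s^-1, velocities in m/s.
    """
    x, y, _ = _world_grids(shape, spacing)
    cx, cy = x.mean(), y.mean()
    vx = -omega_z * (y - cy) * 1e-3      # mm -> m
    vy = omega_z * (x - cx) * 1e-3
    vel = np.stack([vx, vy, np.zeros_like(vx)], axis=-1)
    ds = _as_dataset(vel, shape, spacing, n_phases, cycle_duration)
    mask = Mask3D(labels=np.ones(shape, dtype=np.int16),
                  label_map={"LA": 1}, spacing=spacing)
    return ds, mask


def simple_shear(k: float, shape=(24, 24, 24), spacing=(1.5, 1.5, 1.5),
                 n_phases: int = 1) -> tuple[FlowDataset, Mask3D]:
    """Plane shear vx = k*y (k in s^-1): Q = 0, dissipation mu*k^2 per volume."""
    _, y, _ = _world_grids(shape, spacing)
    vx = k * (y - y.mean()) * 1e-3
    vel = np.stack([vx, np.zeros_like(vx), np.zeros_like(vx)], axis=-1)
    ds = _as_dataset(vel, shape, spacing, n_phases, 1.0)
    mask = Mask3D(labels=np.ones(shape, dtype=np.int16),
                  label_map={"LA": 1}, spacing=spacing)
    return ds, mask


def poiseuille_tube(radius_mm: float = 5.0, v0: float = 0.4,
                    length_mm: float | None = None, axis: str = "z",
                    shape=(40, 24, 24), spacing=(1.5, 1.5, 1.5),
                    n_phases: int = 1) -> tuple[FlowDataset, Mask3D]:
    """Axis-aligned Poiseuille flow: v = v0 (1 - r^2/R^2) along ``axis``.

    The mask is the tube lumen (r <= R over the given length). Mean velocity
    is v0/2, flux pi R^2 v0 / 2, viscous dissipation 2 pi mu L v0^2.
    """
    _check_resolution(2 * radius_mm, spacing, "tube diameter")
    x, y, z = _world_grids(shape, spacing)
    axes = {"x": (x, y, z), "y": (y, x, z), "z": (z, x, y)}
    if axis not in axes:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    along, p, q = axes[axis]
    r2 = (p - p.mean()) ** 2 + (q - q.mean()) ** 2
    if length_mm is None:
        length_mm = along.max() - along.min()
    inside = (r2 <= radius_mm ** 2) & \
        (np.abs(along - along.mean()) <= length_mm / 2)
    speed = np.where(inside, v0 * (1.0 - r2 / radius_mm ** 2), 0.0)
    vel = np.zeros(speed.shape + (3,))
    vel[..., "xyz".index(axis)] = speed
    ds = _as_dataset(vel, shape, spacing, n_phases, 1.0)
    mask = Mask3D(labels=inside.astype(np.int16), label_map={"LA": 1},
                  spacing=spacing)
    return ds, mask


def lamb_oseen(circulation: float = 0.01, r_core_mm: float = 6.0,
               shape=(24, 48, 48), spacing=(1.5, 1.5, 1.5),
               n_phases: int = 1) -> tuple[FlowDataset, Mask3D]:
    """Lamb-Oseen vortex about the vertical grid-center axis.

    Tangential speed v_theta(r) = Gamma/(2 pi r) * (1 - exp(-r^2/r_c^2)),
    with Gamma (``circulation``) in m^2/s and r_c in mm. The axial vorticity
    is omega_z(r) = Gamma/(pi r_c^2) exp(-r^2/r_c^2) (r_c in meters inside
    the formula), peaking on the axis.
    """
    _check_resolution(2 * r_core_mm, spacing, "vortex core diameter")
    x, y, _ = _world_grids(shape, spacing)
    dx = (x - x.mean()) * 1e-3
    dy = (y - y.mean()) * 1e-3
    r = np.hypot(dx, dy)
    r_c = r_core_mm * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        v_theta = circulation / (2 * np.pi * r) * (1 - np.exp(-(r / r_c) ** 2))
    v_theta = np.where(r > 0, v_theta, 0.0)
    vx = np.where(r > 0, -v_theta * dy / r, 0.0)
    vy = np.where(r > 0, v_theta * dx / r, 0.0)
    vel = np.stack([vx, vy, np.zeros_like(vx)], axis=-1)
    ds = _as_dataset(vel, shape, spacing, n_phases, 1.0)
    mask = Mask3D(labels=np.ones(shape, dtype=np.int16),
                  label_map={"LA": 1}, spacing=spacing)
    return ds, mask


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

@dataclass
class GaussianPulse:
    amplitude: float    # ml/s (negative for reversal waves)
    center: float       # fraction of the cycle, in [0, 1)
    width: float        # Gaussian sigma, fraction of the cycle

    def __call__(self, t_frac: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((t_frac - self.center) / self.width) ** 2)

    def volume_ml(self, cycle_duration: float) -> float:
        """Analytic time integral of the pulse over (-inf, inf), in ml."""
        return self.amplitude * self.width * cycle_duration \
            * float(np.sqrt(2 * np.pi))


def waveform(pulses: list[GaussianPulse], t_frac: np.ndarray) -> np.ndarray:
    return np.sum([p(t_frac) for p in pulses], axis=0)


# ---------------------------------------------------------------------------
# LA phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, timing and waveform prescription for the LA phantom.

    Defaults emulate a clinical acquisition: ~2 mm isotropic voxels,
    30 phases over a 1 s cycle, velocities well under a 150 cm/s VENC,
    triphasic pulmonary-vein waveforms (S, D and a small negative Ar wave)
    and a biphasic mitral waveform (E, A) whose cycle volume balances the
    summed venous inflow by construction.
    """

    shape: tuple[int, int, int] = (64, 64, 64)        # (z, y, x)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    n_phases: int = 30
    cycle_duration: float = 1.0                        # s
    la_center: tuple[float, float, float] = (63.0, 63.0, 72.0)  # mm
    la_semiaxes: tuple[float, float, float] = (26.0, 24.0, 22.0)  # mm
    pv_radius: float = 6.0                             # mm
    pv_offsets: tuple = ((-15.0, -15.0), (-15.0, 15.0),
                         (15.0, -15.0), (15.0, 15.0))  # (dx, dy) mm
    mv_radius: float = 12.0                            # mm
    # per-vein pulmonary waveform (ml/s, cycle fractions); pulse centers sit
    # on the default 30-phase sampling grid so the prescribed peak amplitude
    # is observable at a sample instant
    pv_pulses: tuple = (GaussianPulse(50.0, 0.20, 0.06),
                        GaussianPulse(40.0, 0.60, 0.05),
                        GaussianPulse(-15.0, 0.90, 0.03))
    # mitral waveform before mass-balance scaling (ml/s)
    mv_pulses: tuple = (GaussianPulse(200.0, 0.60, 0.05),
                        GaussianPulse(120.0, 0.90, 0.035))
    # interior vortex: circulation m^2/s, core radius mm, S/D gating pulses
    vortex_circulation: float = 0.012
    vortex_core_mm: float = 8.0
    vortex_gates: tuple = (GaussianPulse(1.0, 0.22, 0.07),
                           GaussianPulse(0.8, 0.62, 0.06))
    noise_sigma: float = 0.0                           # m/s
    seed: int = 0

    PV_NAMES = ("RS", "RI", "LS", "LI")


def _tube_velocity(x, y, z, center_xy, radius, z_range, q_ml_s, t_frac):
    """Time-resolved Poiseuille velocity (m/s, along -z) inside one tube."""
    r2 = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2
    inside = (r2 <= radius ** 2) & (z >= z_range[0]) & (z <= z_range[1])
    area_mm2 = np.pi * radius ** 2
    # mean velocity mm/s = Q[ml/s]*1e3 / area; peak = 2x mean
    profile = np.where(inside, 2.0 * (1.0 - r2 / radius ** 2), 0.0)
    vz = -(q_ml_s[:, None, None, None] * 1e3 / area_mm2) \
        * profile[None] * 1e-3      # m/s
    return inside, vz


def la_phantom(spec: PhantomSpec | None = None
               ) -> tuple[FlowDataset, Mask3D, list[SphereSeed], dict]:
    """Build the phantom dataset, mask, sphere seeds and ground truth.

    Returns ``(ds, mask, seeds, truth)``. ``truth`` holds the prescribed
    per-vein S/D/Ar peak flow rates, mitral E/A peaks, analytic passive and
    active mitral volumes, per-vein and mitral cycle volumes, and the vortex
    parameters. Deterministic: the same spec yields bit-identical output.
    """
    spec = spec or PhantomSpec()
    if spec.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    shape, spacing = spec.shape, spec.spacing
    x, y, z = _world_grids(shape, spacing)
    t_frac = np.arange(spec.n_phases) / spec.n_phases

    cx, cy, cz = spec.la_center
    ax, ay, az = spec.la_semiaxes
    ellipsoid = (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                 + ((z - cz) / az) ** 2) <= 1.0

    # --- tubes -------------------------------------------------------------
    pv_centers = [(cx + ox, cy + oy) for ox, oy in spec.pv_offsets]
    for a in range(len(pv_centers)):
        for b in range(a + 1, len(pv_centers)):
            d = np.hypot(pv_centers[a][0] - pv_centers[b][0],
                         pv_centers[a][1] - pv_centers[b][1])
            if d < 2 * spec.pv_radius:
                raise ValueError(f"pulmonary-vein tubes {a} and {b} overlap")

    z_top = z.max()
    pv_z = (cz + 0.4 * az, z_top)       # tubes descend into the roof
    mv_z = (z.min(), cz - 0.8 * az)

    q_pv = waveform(list(spec.pv_pulses), t_frac)          # per vein, ml/s
    pv_cycle_vol = 4 * np.trapezoid(
        np.append(q_pv, q_pv[0]),
        dx=spec.cycle_duration / spec.n_phases)            # ml (cyclic)
    q_mv_raw = waveform(list(spec.mv_pulses), t_frac)
    mv_cycle_vol_raw = np.trapezoid(np.append(q_mv_raw, q_mv_raw[0]),
                                    dx=spec.cycle_duration / spec.n_phases)
    mv_scale = pv_cycle_vol / mv_cycle_vol_raw             # mass balance
    q_mv = q_mv_raw * mv_scale

    vel = np.zeros((spec.n_phases,) + tuple(shape) + (3,), dtype=np.float64)
    region = ellipsoid.copy()
    for cxy in pv_centers:
        inside, vz = _tube_velocity(x, y, z, cxy, spec.pv_radius, pv_z,
                                    q_pv, t_frac)
        region |= inside
        vel[..., 2] = np.where(inside[None], vz, vel[..., 2])
    inside_mv, vz_mv = _tube_velocity(x, y, z, (cx, cy), spec.mv_radius,
                                      mv_z, q_mv, t_frac)
    region |= inside_mv
    vel[..., 2] = np.where(inside_mv[None], vz_mv, vel[..., 2])

    # --- interior vortex (S and D windows) ---------------------------------
    in_tube = inside_mv.copy()
    for cxy in pv_centers:
        r2 = (x - cxy[0]) ** 2 + (y - cxy[1]) ** 2
        in_tube |= (r2 <= spec.pv_radius ** 2) & (z >= pv_z[0])
    chamber = ellipsoid & ~in_tube
    dx_m = (x - cx) * 1e-3
    dy_m = (y - cy) * 1e-3
    r = np.hypot(dx_m, dy_m)
    r_c = spec.vortex_core_mm * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        v_theta = spec.vortex_circulation / (2 * np.pi * r) \
            * (1 - np.exp(-(r / r_c) ** 2))
    v_theta = np.where((r > 0) & chamber, v_theta, 0.0)
    gate = waveform(list(spec.vortex_gates), t_frac)
    with np.errstate(invalid="ignore"):
        ex = np.where(r > 0, -dy_m / r, 0.0)
        ey = np.where(r > 0, dx_m / r, 0.0)
    vel[..., 0] += gate[:, None, None, None] * v_theta[None] * ex[None]
    vel[..., 1] += gate[:, None, None, None] * v_theta[None] * ey[None]

    magnitude = np.where(region, 1.0, 0.1)[None].repeat(spec.n_phases, axis=0)
    ds = FlowDataset(velocity=vel, magnitude=magnitude, spacing=spacing,
                     cycle_duration=spec.cycle_duration, venc=150.0)
    if spec.noise_sigma > 0:
        ds = add_noise(ds, spec.noise_sigma, spec.seed)

    mask = Mask3D(labels=region.astype(np.int16), label_map={"LA": 1},
                  spacing=spacing)

    seed_z_pv = 0.5 * (pv_z[0] + pv_z[1])
    seeds = [SphereSeed(name, (cxy[0], cxy[1], seed_z_pv), spec.pv_radius)
             for name, cxy in zip(PhantomSpec.PV_NAMES, pv_centers)]
    seeds.append(SphereSeed("MV", (cx, cy, 0.5 * (mv_z[0] + mv_z[1])),
                            spec.mv_radius))

    s_p, d_p, ar_p = spec.pv_pulses
    e_p, a_p = spec.mv_pulses
    truth = {
        "pv_s_peak_ml_s": s_p.amplitude,
        "pv_d_peak_ml_s": d_p.amplitude,
        "pv_ar_peak_ml_s": ar_p.amplitude,
        "pv_s_d_ratio": s_p.amplitude / d_p.amplitude,
        "mv_e_peak_ml_s": e_p.amplitude * mv_scale,
        "mv_a_peak_ml_s": a_p.amplitude * mv_scale,
        "mv_ea_peak_ratio": e_p.amplitude / a_p.amplitude,
        "mv_passive_volume_ml": e_p.volume_ml(spec.cycle_duration) * mv_scale,
        "mv_active_volume_ml": a_p.volume_ml(spec.cycle_duration) * mv_scale,
        "mv_ea_volume_ratio": e_p.volume_ml(1.0) / a_p.volume_ml(1.0),
        "pv_cycle_volume_ml": pv_cycle_vol,
        "mv_cycle_volume_ml": pv_cycle_vol,   # balanced by construction
        "vortex_circulation_m2_s": spec.vortex_circulation,
        "vortex_core_mm": spec.vortex_core_mm,
        "la_volume_ml": float(ellipsoid.sum()) * mask.voxel_volume_mm3 * 1e-3,
    }
    return ds, mask, seeds, truth


def add_noise(ds: FlowDataset, sigma: float, seed: int = 0) -> FlowDataset:
    """Add i.i.d. zero-mean Gaussian noise to every velocity component.

    The magnitude image is untouched. sigma in m/s; sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return ds
    rng = np.random.default_rng(seed)
    noisy = ds.velocity + rng.normal(0.0, sigma, size=ds.velocity.shape)
    return replace(ds, velocity=noisy)
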