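"""Velocity-gradient machinery and volumetric hemodynamic indices.

All indices operate on the masked left-atrial (or other labeled) region of a
:class:`~laflow.flowdata.FlowDataset`:

* kinetic energy       KE(t)  = 1/2 * rho * sum_i |v_i|^2 * Vol_i        [J]
* viscous energy loss  EL(t)  = mu * sum_i Phi_v,i * Vol_i               [W]
  with the dissipation function
  Phi_v = 1/2 * sum_ij [ (dv_i/dx_j + dv_j/dx_i) - (2/3)(div v) d_ij ]^2
* vorticity            omega = curl v;  |omega_LA|(t) is its magnitude
  volume-averaged over the region (normalization against LA dilation)  [1/s]
* Q-criterion          Q = 1/2 (||Omega||_F^2 - ||S||_F^2)              [1/s^2]
  with Omega/S the antisymmetric/symmetric velocity-gradient parts;
  q_crit_ratio(t) is the fraction of region voxels with Q above a
  threshold (default 500 s^-2), a volume-normalized vortex-core burden.

Spatial derivatives use central differences where both axis neighbors lie
inside the region, one-sided differences where only one does, and zero (with
a reduced-accuracy flag) where neither does — velocities outside the
segmented region are unreliable and never enter a stencil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flowdata import FlowDataset, Mask3D, TimeSeries

logger = logging.getLogger("laflow")


@dataclass
class HemoParams:
    rho: float = 1060.0        # blood density, kg/m^3
    mu: float = 0.0035         # dynamic viscosity, Pa*s
    q_threshold: float = 500.0  # vortex-core threshold, s^-2

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0 or self.q_threshold <= 0:
            raise ValueError("all hemodynamic parameters must be positive")


@dataclass
class GradientTensorField:
    """Per-voxel velocity-gradient tensor dv_i/dx_j (s^-1) on a masked grid."""

    tensor: np.ndarray          # (z, y, x, 3, 3)
    valid: np.ndarray           # (z, y, x) bool — in-region voxels
    reduced: np.ndarray         # (z, y, x) bool — some derivative had no stencil


def _masked_derivative(f: np.ndarray, region: np.ndarray, axis: int,
                       h_m: float) -> tuple[np.ndarray, np.ndarray]:
    """d(f)/dx along one array axis, restricted to in-region neighbors.

    Returns (derivative, no_stencil) where no_stencil marks in-region voxels
    with no in-region neighbor along this axis.
    """
    fp = np.zeros_like(f)
    fm = np.zeros_like(f)
    rp = np.zeros_like(region)
    rm = np.zeros_like(region)
    src_p = [slice(None)] * 3
    dst_p = [slice(None)] * 3
    src_p[axis] = slice(1, None)
    dst_p[axis] = slice(None, -1)
    fp[tuple(dst_p)] = f[tuple(src_p)]
    rp[tuple(dst_p)] = region[tuple(src_p)]
    fm[tuple(src_p)] = f[tuple(dst_p)]
    rm[tuple(src_p)] = region[tuple(dst_p)]

    central = rp & rm
    fwd = rp & ~rm
    bwd = rm & ~rp
    deriv = np.zeros_like(f)
    deriv[central] = (fp[central] - fm[central]) / (2.0 * h_m)
    deriv[fwd] = (fp[fwd] - f[fwd]) / h_m
    deriv[bwd] = (f[bwd] - fm[bwd]) / h_m
    no_stencil = region & ~(rp | rm)
    return deriv, no_stencil


def velocity_gradient(ds: FlowDataset, mask: Mask3D, label: str | int = "LA",
                      phase: int = 0) -> GradientTensorField:
    """Velocity-gradient tensor at one cardiac phase over one labeled region."""
    region = mask.region(label)
    if not region.any():
        raise ValueError(f"label {label!r} selects no voxels")
    vel = ds.velocity[phase]            # (z, y, x, 3) m/s
    # array axes (z, y, x) = axes (0, 1, 2); world x derivative = axis 2
    h = [ds.spacing[0] * 1e-3, ds.spacing[1] * 1e-3, ds.spacing[2] * 1e-3]
    world_to_array = {0: 2, 1: 1, 2: 0}     # d/dx_j -> array axis

    tensor = np.zeros(region.shape + (3, 3))
    reduced = np.zeros(region.shape, dtype=bool)
    for i in range(3):                  # velocity component
        for j in range(3):              # world derivative direction
            d, nos = _masked_derivative(vel[..., i], region,
                                        world_to_array[j], h[j])
            tensor[..., i, j] = np.where(region, d, 0.0)
            reduced |= nos
    frac = reduced.sum() / region.sum()
    if frac > 0:
        logger.info("velocity_gradient: %.2f%% of region voxels have a "
                    "missing stencil along some axis", 100 * frac)
    return GradientTensorField(tensor=tensor, valid=region, reduced=reduced)


def _phase_gradients(ds: FlowDataset, mask: Mask3D, label):
    for t in range(ds.n_phases):
        yield t, velocity_gradient(ds, mask, label, phase=t)


def vorticity(ds: FlowDataset, mask: Mask3D, label: str | int = "LA"
              ) -> tuple[np.ndarray, TimeSeries]:
    """Curl field per phase and the volume-averaged |omega| curve.

    Returns ``(omega, series)`` where ``omega`` has shape (t, z, y, x, 3)
    in s^-1 and ``series`` is |omega_LA|(t) = sum(|omega|*Vol_i) / V_region,
    i.e. the mean vorticity magnitude over the region.
    """
    region = mask.region(label)
    omega = np.zeros((ds.n_phases,) + region.shape + (3,))
    avg = np.zeros(ds.n_phases)
    for t, g in _phase_gradients(ds, mask, label):
        gt = g.tensor
        w = np.stack([gt[..., 2, 1] - gt[..., 1, 2],
                      gt[..., 0, 2] - gt[..., 2, 0],
                      gt[..., 1, 0] - gt[..., 0, 1]], axis=-1)
        omega[t] = np.where(region[..., None], w, 0.0)
        avg[t] = np.linalg.norm(omega[t][region], axis=-1).mean()
    return omega, TimeSeries("vorticity_la", ds.times, avg, "1/s")


def q_criterion(ds: FlowDataset, mask: Mask3D, label: str | int = "LA",
                params: HemoParams | None = None
                ) -> tuple[np.ndarray, TimeSeries]:
    """Q field per phase and the fraction of region voxels above threshold."""
    params = params or HemoParams()
    region = mask.region(label)
    n_region = region.sum()
    q = np.zeros((ds.n_phases,) + region.shape)
    ratio = np.zeros(ds.n_phases)
    for t, g in _phase_gradients(ds, mask, label):
        gt = g.tensor
        omega_t = 0.5 * (gt - np.swapaxes(gt, -1, -2))
        s_t = 0.5 * (gt + np.swapaxes(gt, -1, -2))
        qt = 0.5 * (np.sum(omega_t ** 2, axis=(-1, -2))
                    - np.sum(s_t ** 2, axis=(-1, -2)))
        q[t] = np.where(region, qt, 0.0)
        ratio[t] = np.sum(q[t][region] > params.q_threshold) / n_region
    return q, TimeSeries("q_crit_ratio", ds.times, ratio, "dimensionless")


def kinetic_energy(ds: FlowDataset, mask: Mask3D, label: str | int = "LA",
                   params: HemoParams | None = None
                   ) -> tuple[TimeSeries, TimeSeries]:
    """KE(t) in mJ and KE per unit region volume in uJ/ml.

    KE(t) = 1/2 * rho * sum_i |v_i(t)|^2 * Vol_i over region voxels.
    """
    params = params or HemoParams()
    region = mask.region(label)
    vol_m3 = ds.voxel_volume_m3
    v_region = ds.velocity[:, region, :]               # (t, n, 3)
    ke_j = 0.5 * params.rho * np.sum(v_region ** 2, axis=(1, 2)) * vol_m3
    v_tot = region.sum() * vol_m3
    ke = TimeSeries("ke", ds.times, ke_j * 1e3, "mJ")
    # J/m^3 is numerically uJ/ml
    ke_pv = TimeSeries("ke_per_volume", ds.times, ke_j / v_tot, "uJ/ml")
    return ke, ke_pv


def viscous_energy_loss(ds: FlowDataset, mask: Mask3D,
                        label: str | int = "LA",
                        params: HemoParams | None = None
                        ) -> tuple[TimeSeries, TimeSeries]:
    """Viscous dissipation rate EL(t) in mW and its volume-normalized curve.

    The full dissipation function is used, including the (2/3) div(v) term:
    MRI velocity fields are never discretely divergence-free even though
    blood is incompressible.
    """
    params = params or HemoParams()
    region = mask.region(label)
    vol_m3 = ds.voxel_volume_m3
    el_w = np.zeros(ds.n_phases)
    for t, g in _phase_gradients(ds, mask, label):
        gt = g.tensor[region]                      # (n, 3, 3)
        div = np.trace(gt, axis1=-2, axis2=-1)
        bracket = gt + np.swapaxes(gt, -1, -2)
        bracket[:, np.arange(3), np.arange(3)] -= (2.0 / 3.0) * div[:, None]
        phi = 0.5 * np.sum(bracket ** 2, axis=(-1, -2))   # s^-2
        el_w[t] = params.mu * phi.sum() * vol_m3
    v_tot = region.sum() * vol_m3
    vel_series = TimeSeries("vel", ds.times, el_w * 1e3, "mW")
    vel_pv = TimeSeries("vel_per_volume", ds.times, el_w / v_tot, "uW/ml")
    return vel_series, vel_pv


def ke_vel_ratio(ke: TimeSeries, vel: TimeSeries, eps: float = 1e-12
                 ) -> TimeSeries:
    """Elementwise KE/VEL flow-efficiency curve; NaN where VEL <= eps."""
    if ke.times.shape != vel.times.shape or not np.allclose(ke.times,
                                                            vel.times):
        raise ValueError("KE and VEL series are on different time bases")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vel.values > eps, ke.values / vel.values, np.nan)
    return TimeSeries("ke_vel_ratio", ke.times, ratio, "dimensionless")


def median_filter3(field: np.ndarray) -> np.ndarray:
    """3x3x3 median filter with nearest-edge replication at the borders.

    Used to suppress speckle in Q-criterion volumes before rendering.
    """
    return ndimage.median_filter(np.asarray(field, dtype=float), size=3,
                                 mode="nearest")
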