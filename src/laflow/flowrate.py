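"""Sphere-seeded vessel cross-sections, flow-rate curves and wave features.

A sample sphere placed in each pulmonary vein (RS/RI/LS/LI) and at the
mitral valve fixes where flow is measured. The cross-section normal is the
dominant flow direction: the per-phase mean velocity over in-sphere voxels
is ranked by magnitude and the top five phase means are averaged. A plane
through the sphere center is then sampled on a uniform in-plane grid and the
flow rate is the surface integral of v . n over the lumen.

Wave features follow clinical convention: pulmonary-vein curves yield the
systolic (S) and diastolic (D) inflow peaks, the atrial reversal (Ar) and
the S/D ratio; the mitral curve yields the early (E) and atrial (A) filling
peaks, their ratio by peak and by integrated volume, and an E/A-fusion flag.
The detection windows (mitral 10%-of-peak onset, Ar in the last 30% of the
cycle, 20%-of-E fusion trough) are configurable operational choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flowdata import FlowDataset, Mask3D, SphereSeed, TimeSeries


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class CrossSection:
    """A planar sampling of one vessel lumen."""

    name: str
    origin: np.ndarray            # mm, plane/seed center
    normal: np.ndarray            # unit, world axes
    points: np.ndarray            # (n, 3) lumen sample points, mm
    area_weight: float            # mm^2 per sample point
    lumen_area_mm2: float = 0.0   # partial-coverage (sub-sample) lumen area


def _index_coords(points_xyz: np.ndarray, spacing, origin) -> np.ndarray:
    """World mm -> fractional (z, y, x) index coordinates, shape (3, n)."""
    rel = (points_xyz - np.asarray(origin)) / np.asarray(spacing)
    return rel[:, ::-1].T


def _in_sphere_voxels(shape, spacing, origin, seed: SphereSeed) -> np.ndarray:
    nz, ny, nx = shape
    z, y, x = np.meshgrid(np.arange(nz) * spacing[2] + origin[2],
                          np.arange(ny) * spacing[1] + origin[1],
                          np.arange(nx) * spacing[0] + origin[0],
                          indexing="ij")
    cx, cy, cz = seed.center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= seed.radius ** 2


def plane_normal_from_flow(ds: FlowDataset, seed: SphereSeed,
                           n_top: int = 5) -> np.ndarray:
    """Dominant flow direction within the seed sphere (unit vector).

    Per phase, the mean velocity over voxels whose centers fall inside the
    sphere; phases are ranked by that mean's magnitude and the top
    ``min(n_top, N)`` phase means are summed and normalized.
    """
    inside = _in_sphere_voxels(ds.shape, ds.spacing, ds.origin, seed)
    if not inside.any():
        raise ValueError(f"seed {seed.name!r} does not intersect the grid")
    means = ds.velocity[:, inside, :].mean(axis=1)        # (t, 3)
    norms = np.linalg.norm(means, axis=1)
    if not np.any(norms > 0):
        raise ValueError(f"seed {seed.name!r} contains no nonzero-velocity "
                         "voxel at any phase")
    top = np.argsort(norms)[::-1][:min(n_top, ds.n_phases)]
    direction = means[top].sum(axis=0)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError(f"seed {seed.name!r}: top-phase velocities cancel")
    return direction / n


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def extract_cross_section(mask: Mask3D, label: str | int,
                          seed: SphereSeed, normal: np.ndarray,
                          extent_factor: float = 3.0) -> CrossSection:
    """Planar lumen sampling through the seed center, perpendicular to normal.

    The plane is sampled on a uniform grid with step = min(spacing)/2 over
    +- extent_factor * seed radius. A sample belongs to the lumen when the
    linearly interpolated binary label is >= 0.5; the lumen is restricted to
    the connected component containing the seed center.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    region = mask.region(label).astype(np.float32)
    step = min(mask.spacing) / 2.0
    half = extent_factor * seed.radius
    n_side = int(np.ceil(2 * half / step)) + 1
    u = np.linspace(-half, half, n_side)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    e1, e2 = _plane_basis(normal)
    pts = (np.asarray(seed.center)[None, None]
           + uu[..., None] * e1 + vv[..., None] * e2)     # (n, n, 3)
    flat = pts.reshape(-1, 3)
    vals = ndimage.map_coordinates(region,
                                   _index_coords(flat, mask.spacing,
                                                 mask.origin),
                                   order=1, mode="constant", cval=0.0)
    vals = vals.reshape(n_side, n_side)
    lumen = vals >= 0.5
    center_idx = (n_side // 2, n_side // 2)
    if not lumen[center_idx]:
        raise ValueError(
            f"seed {seed.name!r}: no lumen at the plane center — "
            "reposition the seed inside the vessel")
    comp, _ = ndimage.label(lumen, structure=np.ones((3, 3), dtype=int))
    lumen &= comp == comp[center_idx]
    # sub-sample lumen area: integrate the fractional label coverage over
    # the lumen plus a 2-sample ring (captures the partial-voxel boundary
    # without picking up neighboring structures)
    ring = ndimage.binary_dilation(lumen, iterations=2)
    lumen_area = float(vals[ring].sum() * step ** 2)
    return CrossSection(name=seed.name,
                        origin=np.asarray(seed.center, dtype=float),
                        normal=normal,
                        points=pts[lumen],
                        area_weight=float(step ** 2),
                        lumen_area_mm2=lumen_area)


def flow_rate(ds: FlowDataset, cs: CrossSection,
              orient_positive: bool = True) -> TimeSeries:
    """Flow rate Q(t) in ml/s through a cross-section.

    Q(t) = sum over lumen points of v(p, t) . n * dA with trilinear velocity
    interpolation. 1 (m/s)*mm^2 = 1 ml/s, so no further conversion is
    needed. When ``orient_positive`` the normal is flipped, if necessary, so
    the cycle-integrated flow is positive (curves plot inflow-dominant).
    """
    coords = _index_coords(cs.points, ds.spacing, ds.origin)
    q = np.empty(ds.n_phases)
    for t in range(ds.n_phases):
        v = np.stack([ndimage.map_coordinates(ds.velocity[t, ..., c], coords,
                                              order=1, mode="constant",
                                              cval=0.0)
                      for c in range(3)], axis=-1)
        q[t] = (v @ cs.normal).sum() * cs.area_weight
    if orient_positive and np.trapezoid(q, dx=1.0) < 0:
        q = -q
    return TimeSeries(f"flow_{cs.name}", ds.times, q, "ml/s")


# ---------------------------------------------------------------------------
# Wave features
# ---------------------------------------------------------------------------

@dataclass
class WaveFeatures:
    name: str
    # pulmonary-vein features
    s_peak: float | None = None
    s_time: float | None = None
    d_peak: float | None = None
    d_time: float | None = None
    ar_peak: float | None = None
    ar_time: float | None = None
    s_d_ratio: float | None = None
    no_reversal: bool = False
    # mitral features
    e_peak: float | None = None
    e_time: float | None = None
    a_peak: float | None = None
    a_time: float | None = None
    ea_peak_ratio: float | None = None
    passive_volume: float | None = None
    active_volume: float | None = None
    ea_volume_ratio: float | None = None
    fusion: bool = False
    a_absent: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def detect_pv_waves(q: TimeSeries, mv: TimeSeries,
                    onset_fraction: float = 0.10,
                    ar_window: float = 0.30) -> WaveFeatures:
    """S/D/Ar peaks and S/D ratio of one pulmonary-vein curve.

    The systolic window runs from the cycle start until the subject's mitral
    flow first exceeds ``onset_fraction`` of its maximum (valve opening);
    S is the maximum in that window, D the maximum after it, and Ar the
    minimum within the last ``ar_window`` fraction of the cycle.
    """
    if q.times.shape != mv.times.shape or not np.allclose(q.times, mv.times):
        raise ValueError("PV and MV curves are on different time bases")
    if np.all(mv.values == 0):
        raise ValueError("mitral curve is identically zero; "
                         "cannot phase the cycle")
    mv_max = mv.values.max()
    above = np.nonzero(mv.values > onset_fraction * mv_max)[0]
    onset = int(above[0]) if above.size else len(mv.values)
    onset = max(onset, 1)

    t, v = q.times, q.values
    cycle = t[-1] + (t[1] - t[0]) if t.size > 1 else 1.0
    i_s = int(np.argmax(v[:onset]))
    i_d = onset + int(np.argmax(v[onset:])) if onset < v.size else i_s
    late = t >= (1.0 - ar_window) * cycle
    i_ar = np.nonzero(late)[0][int(np.argmin(v[late]))]
    ar = float(v[i_ar])
    feats = WaveFeatures(
        name=q.name,
        s_peak=float(v[i_s]), s_time=float(t[i_s]),
        d_peak=float(v[i_d]), d_time=float(t[i_d]),
        ar_peak=ar, ar_time=float(t[i_ar]),
        s_d_ratio=float(v[i_s] / v[i_d]) if v[i_d] != 0 else None,
        no_reversal=ar >= 0)
    return feats


def detect_mv_waves(q: TimeSeries,
                    onset_fraction: float = 0.10,
                    fusion_fraction: float = 0.20) -> WaveFeatures:
    """E/A peaks, passive/active filling volumes and their ratios.

    E is the global maximum; A is the last local maximum after E. The E-A
    split is the flow minimum between the two peaks; passive volume
    integrates from E onset (last upward crossing of ``onset_fraction`` x
    E peak before E) to the split, active volume from the split to A offset
    (first downward crossing of ``onset_fraction`` x A peak after A, else
    cycle end). Negative lobes are clipped at zero. The fusion flag is set
    when the trough exceeds ``fusion_fraction`` of the E peak.
    """
    t, v = q.times, q.values
    if not np.any(v > 0):
        raise ValueError("mitral curve has no positive excursion")

    def local_maxima(lo, hi):
        idx = np.arange(max(lo, 1), min(hi, len(v) - 1))
        keep = [(v[i] >= v[i - 1]) and (v[i] >= v[i + 1]) and v[i] > 0
                for i in idx]
        return idx[np.asarray(keep, dtype=bool)] if idx.size \
            else np.array([], dtype=int)

    i_max = int(np.argmax(v))
    after = local_maxima(i_max + 1, len(v))
    if after.size:
        i_e, i_a = i_max, int(after[-1])
    else:
        # global max is the late (atrial) wave: take the last earlier local
        # max as E — advanced diastolic dysfunction reverses the amplitudes
        before = local_maxima(1, i_max)
        if before.size == 0:
            return WaveFeatures(name=q.name, e_peak=float(v[i_max]),
                                e_time=float(t[i_max]), a_absent=True,
                                fusion=True)
        i_e, i_a = int(before[-1]), i_max
    e_peak = float(v[i_e])
    a_peak = float(v[i_a])
    feats = WaveFeatures(name=q.name, e_peak=e_peak, e_time=float(t[i_e]))

    i_split = i_e + int(np.argmin(v[i_e:i_a + 1]))
    trough = float(v[i_split])
    feats.fusion = trough > fusion_fraction * e_peak

    onset_level = onset_fraction * e_peak
    below = np.nonzero(v[:i_e] <= onset_level)[0]
    i_onset = int(below[-1]) if below.size else 0
    offset_level = onset_fraction * a_peak
    after_a = np.nonzero(v[i_a:] <= offset_level)[0]
    i_offset = i_a + int(after_a[0]) if after_a.size else len(v) - 1

    pos = np.clip(v, 0.0, None)
    passive = float(np.trapezoid(pos[i_onset:i_split + 1],
                                 t[i_onset:i_split + 1]))
    active = float(np.trapezoid(pos[i_split:i_offset + 1],
                                t[i_split:i_offset + 1]))
    feats.a_peak = a_peak
    feats.a_time = float(t[i_a])
    feats.ea_peak_ratio = e_peak / a_peak if a_peak != 0 else None
    feats.passive_volume = passive
    feats.active_volume = active
    feats.ea_volume_ratio = passive / active if active > 0 else None
    return feats
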