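"""Particle pathline advection in the time-resolved velocity field.

Massless particles are advected with classical 4th-order Runge-Kutta,
trilinear interpolation in space and linear interpolation in time, cyclic
over the cardiac cycle (the last phase wraps to the first). Particles that
leave the labeled region (or the grid) terminate. Used to visualize how
pulmonary-vein inflow organizes into the atrial vortex; the exporter writes
legacy ASCII VTK polylines with a per-point speed scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .flowdata import FlowDataset, Mask3D


@dataclass
class Pathline:
    times: np.ndarray        # s
    positions: np.ndarray    # (n, 3) mm
    speeds: np.ndarray       # m/s
    terminated: bool = False


@dataclass
class PathlineSet:
    emitter: str
    trail: int
    particles: list[Pathline] = field(default_factory=list)


class _FieldSampler:
    """Trilinear-space / linear-time velocity sampling, cyclic in time."""

    def __init__(self, ds: FlowDataset):
        self.ds = ds
        self.dt_phase = ds.cycle_duration / ds.n_phases

    def __call__(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        ds = self.ds
        ft = (t / self.dt_phase) % ds.n_phases
        t0 = int(np.floor(ft)) % ds.n_phases
        t1 = (t0 + 1) % ds.n_phases
        w = ft - np.floor(ft)
        rel = (points_mm - np.asarray(ds.origin)) / np.asarray(ds.spacing)
        coords = rel[:, ::-1].T                     # (3, n) in (z, y, x)
        out = np.empty((len(points_mm), 3))
        for c in range(3):
            v0 = ndimage.map_coordinates(ds.velocity[t0, ..., c], coords,
                                         order=1, mode="constant", cval=0.0)
            if w > 0:
                v1 = ndimage.map_coordinates(ds.velocity[t1, ..., c], coords,
                                             order=1, mode="constant",
                                             cval=0.0)
                out[:, c] = (1 - w) * v0 + w * v1
            else:
                out[:, c] = v0
        return out


def _inside(points_mm: np.ndarray, ds: FlowDataset,
            region: np.ndarray | None) -> np.ndarray:
    rel = (points_mm - np.asarray(ds.origin)) / np.asarray(ds.spacing)
    nz, ny, nx = ds.shape
    ok = ((rel[:, 0] >= 0) & (rel[:, 0] <= nx - 1)
          & (rel[:, 1] >= 0) & (rel[:, 1] <= ny - 1)
          & (rel[:, 2] >= 0) & (rel[:, 2] <= nz - 1))
    if region is not None and ok.any():
        idx = np.round(rel[ok][:, ::-1]).astype(int)
        idx[:, 0] = np.clip(idx[:, 0], 0, nz - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
        idx[:, 2] = np.clip(idx[:, 2], 0, nx - 1)
        in_mask = region[idx[:, 0], idx[:, 1], idx[:, 2]]
        ok[np.nonzero(ok)[0][~in_mask]] = False
    return ok


def advect(ds: FlowDataset, emitters: np.ndarray, *,
           steps_per_phase: int = 4, n_cycles: float = 1.0,
           trail: int = 6, mask: Mask3D | None = None,
           label: str | int = "LA", t0: float = 0.0,
           emitter_name: str = "seed") -> PathlineSet:
    """Advect particles released at ``emitters`` (world mm, shape (n, 3)).

    Integration runs from ``t0`` for ``n_cycles`` cardiac cycles with
    ``steps_per_phase`` RK4 substeps per phase. Particles leaving the grid
    (or the ``mask`` region, if given) are terminated and flagged. An
    emitter region with zero velocity yields an empty set with a warning.
    """
    import warnings
    emitters = np.atleast_2d(np.asarray(emitters, dtype=float))
    sampler = _FieldSampler(ds)
    region = mask.region(label) if mask is not None else None
    v_emit = sampler(emitters, t0)
    if not np.any(np.linalg.norm(v_emit, axis=1) > 0):
        warnings.warn("emitter region has zero velocity; no pathlines")
        return PathlineSet(emitter=emitter_name, trail=trail)

    dt = sampler.dt_phase / steps_per_phase
    n_steps = int(round(n_cycles * ds.n_phases * steps_per_phase))
    mm_per_m = 1e3

    pos = emitters.copy()
    alive = np.ones(len(pos), dtype=bool)
    times = [t0]
    traj = [pos.copy()]
    speeds = [np.linalg.norm(v_emit, axis=1)]
    for s in range(n_steps):
        t = t0 + s * dt
        k1 = sampler(pos, t)
        k2 = sampler(pos + 0.5 * dt * k1 * mm_per_m, t + 0.5 * dt)
        k3 = sampler(pos + 0.5 * dt * k2 * mm_per_m, t + 0.5 * dt)
        k4 = sampler(pos + dt * k3 * mm_per_m, t + dt)
        step = (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4) * mm_per_m
        new_pos = np.where(alive[:, None], pos + step, pos)
        ok = _inside(new_pos, ds, region)
        alive &= ok
        pos = np.where(alive[:, None], new_pos, pos)
        times.append(t + dt)
        traj.append(pos.copy())
        speeds.append(np.linalg.norm(sampler(pos, t + dt), axis=1))

    traj = np.stack(traj)          # (steps+1, n, 3)
    speeds = np.stack(speeds)
    times = np.asarray(times)
    out = PathlineSet(emitter=emitter_name, trail=trail)
    for p in range(len(emitters)):
        out.particles.append(Pathline(times=times, positions=traj[:, p],
                                      speeds=speeds[:, p],
                                      terminated=not alive[p]))
    return out


def save_pathlines_vtk(ps: PathlineSet, path) -> None:
    """Legacy ASCII VTK polyline export with a per-point speed scalar."""
    from pathlib import Path
    pts, lines, spd = [], [], []
    for pl in ps.particles:
        start = len(pts)
        pts.extend(pl.positions.tolist())
        spd.extend(pl.speeds.tolist())
        lines.append(list(range(start, start + len(pl.positions))))
    out = ["# vtk DataFile Version 3.0", f"laflow pathlines {ps.emitter}",
           "ASCII", "DATASET POLYDATA", f"POINTS {len(pts)} float"]
    out += [f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}" for p in pts]
    total = sum(len(li) + 1 for li in lines)
    out.append(f"LINES {len(lines)} {total}")
    out += [f"{len(li)} " + " ".join(map(str, li)) for li in lines]
    out += [f"POINT_DATA {len(pts)}", "SCALARS speed float 1",
            "LOOKUP_TABLE default"]
    out += [f"{s:.6f}" for s in spd]
    Path(path).write_text("\n".join(out) + "\n")
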