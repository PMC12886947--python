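import numpy as np
import pytest

from laflow import FlowDataset, Mask3D


@pytest.fixture
def sphere_mask():
    """Digitized sphere R = 10 mm on a 1 mm grid (voxel-center test)."""
    n = 24
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2
    region = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= 10.0 ** 2
    return Mask3D(region.astype(np.int16), {"LA": 1}, (1.0, 1.0, 1.0))


@pytest.fixture
def tiny_random_ds():
    """Random 12^3, 3-phase dataset for dual-route (naive oracle) checks."""
    rng = np.random.default_rng(42)
    shape = (3, 12, 12, 12)
    return FlowDataset(velocity=rng.normal(0, 0.3, shape + (3,)),
                       magnitude=rng.uniform(0.5, 2.0, shape),
                       spacing=(1.5, 1.5, 1.5), cycle_duration=0.9)


def naive_gradient(vel, region, spacing_mm):
    """Loop-based masked velocity gradient, s^-1. Independent oracle."""
    nz, ny, nx = region.shape
    h = np.asarray(spacing_mm, dtype=float) * 1e-3   # (dx, dy, dz) m
    g = np.zeros((nz, ny, nx, 3, 3))
    steps = {0: (0, 0, 1), 1: (0, 1, 0), 2: (1, 0, 0)}  # world x, y, z
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if not region[k, j, i]:
                    continue
                for comp in range(3):
                    for ax in range(3):
                        dk, dj, di = steps[ax]
                        kp, jp, ip = k + dk, j + dj, i + di
                        km, jm, im = k - dk, j - dj, i - di
                        has_p = (0 <= kp < nz and 0 <= jp < ny
                                 and 0 <= ip < nx and region[kp, jp, ip])
                        has_m = (0 <= km < nz and 0 <= jm < ny
                                 and 0 <= im < nx and region[km, jm, im])
                        v0 = vel[k, j, i, comp]
                        if has_p and has_m:
                            d = (vel[kp, jp, ip, comp]
                                 - vel[km, jm, im, comp]) / (2 * h[ax])
                        elif has_p:
                            d = (vel[kp, jp, ip, comp] - v0) / h[ax]
                        elif has_m:
                            d = (v0 - vel[km, jm, im, comp]) / h[ax]
                        else:
                            d = 0.0
                        g[k, j, i, comp, ax] = d
    return g
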