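"""Data model and I/O for time-resolved 3-component velocity fields.

Conventions used throughout the package:

* velocity arrays are indexed ``(phase t, z, y, x, component)`` with the
  component axis ordered ``(vx, vy, vz)`` along the world x/y/z axes and
  stored internally in m/s;
* magnitude arrays are indexed ``(t, z, y, x)`` in arbitrary scanner units;
* ``spacing`` is ``(dx, dy, dz)`` in mm, ``origin`` is ``(x0, y0, z0)`` in mm,
  and the world position of voxel index ``(k, j, i)`` (z, y, x order) is
  ``origin + (i*dx, j*dy, k*dz)``;
* cardiac phases are uniformly spaced: phase ``k`` occurs at
  ``k * cycle_duration / n_phases`` seconds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger("laflow")

MM3_TO_ML = 1e-3
M3_TO_ML = 1e6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FlowDataset:
    """A 4D flow acquisition: velocity + magnitude volumes over one cycle."""

    velocity: np.ndarray          # (t, z, y, x, 3), m/s
    magnitude: np.ndarray         # (t, z, y, x)
    spacing: tuple[float, float, float]   # (dx, dy, dz) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    cycle_duration: float = 1.0   # s (RR interval)
    venc: float | None = None     # cm/s

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64) \
            if self.velocity.dtype != np.float32 else np.asarray(self.velocity)
        self.magnitude = np.asarray(self.magnitude)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (t, z, y, x, 3)")
        if self.magnitude.shape != self.velocity.shape[:4]:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} does not match "
                f"velocity grid {self.velocity.shape[:4]}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite values")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial grid shape (z, y, x)."""
        return self.velocity.shape[1:4]

    @property
    def times(self) -> np.ndarray:
        """Time of each phase in seconds (uniform over the RR interval)."""
        return np.arange(self.n_phases) * self.cycle_duration / self.n_phases

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9


@dataclass
class Mask3D:
    """Labeled integer segmentation volume congruent with a FlowDataset."""

    labels: np.ndarray            # (z, y, x) int
    label_map: dict[str, int] = field(
        default_factory=lambda: {"LA": 1, "LV": 2, "AscAorta": 3})
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def label_value(self, label: str | int) -> int:
        if isinstance(label, str):
            if label not in self.label_map:
                raise KeyError(f"unknown label {label!r}; "
                               f"known: {sorted(self.label_map)}")
            return self.label_map[label]
        return int(label)

    def region(self, label: str | int) -> np.ndarray:
        """Boolean voxel mask of one labeled structure."""
        return self.labels == self.label_value(label)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SphereSeed:
    """Named sample sphere marking a vessel (RS/RI/LS/LI pulmonary veins, MV)."""

    name: str
    center: tuple[float, float, float]   # world mm (x, y, z)
    radius: float                        # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class TimeSeries:
    """A named, unit-tagged curve sampled once per cardiac phase."""

    name: str
    times: np.ndarray    # s
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"time_s": self.times,
                      f"{self.name} [{self.units}]": self.values}
                     ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _nifti_array(ds_array: np.ndarray) -> np.ndarray:
    """(t, z, y, x) -> (x, y, z, t) as NIfTI expects."""
    return np.ascontiguousarray(np.transpose(ds_array, (3, 2, 1, 0)))


def _from_nifti_array(arr: np.ndarray) -> np.ndarray:
    """(x, y, z[, t]) -> (t, z, y, x)."""
    if arr.ndim == 3:
        arr = arr[..., None]
    return np.ascontiguousarray(np.transpose(arr, (3, 2, 1, 0)))


def save_flowdataset(ds: FlowDataset, outdir: str | Path) -> Path:
    """Write a dataset as per-component 4D NIfTI volumes + a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(ds.spacing, ds.origin)
    for ci, cname in enumerate("xyz"):
        img = nib.Nifti1Image(
            _nifti_array(ds.velocity[..., ci]).astype(np.float32), aff)
        nib.save(img, outdir / f"vel_{cname}.nii.gz")
    nib.save(nib.Nifti1Image(_nifti_array(ds.magnitude).astype(np.float32),
                             aff),
             outdir / "mag.nii.gz")
    meta = {"velocity_units": "m/s",
            "cycle_duration_s": ds.cycle_duration,
            "n_phases": ds.n_phases,
            "venc_cm_s": ds.venc,
            "spacing_mm": list(ds.spacing),
            "origin_mm": list(ds.origin)}
    (outdir / "flow.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_flowdataset(velocity_paths,
                     magnitude_path=None,
                     *,
                     velocity_units: str | None = None,
                     cycle_duration: float | None = None,
                     venc: float | None = None) -> FlowDataset:
    """Load a dataset from per-component NIfTI files (or a directory).

    ``velocity_paths`` is either a directory written by
    :func:`save_flowdataset` or a sequence of three 4D NIfTI paths ordered
    (vx, vy, vz). Declared input units must be 'cm/s' or 'm/s'; velocities
    are converted to m/s internally. Missing timing metadata with no
    ``cycle_duration`` argument is a hard error.
    """
    meta = {}
    if isinstance(velocity_paths, (str, Path)) and Path(velocity_paths).is_dir():
        d = Path(velocity_paths)
        sidecar = d / "flow.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        velocity_paths = [d / f"vel_{c}.nii.gz" for c in "xyz"]
        magnitude_path = magnitude_path or d / "mag.nii.gz"

    units = velocity_units or meta.get("velocity_units")
    if units not in ("cm/s", "m/s"):
        raise ValueError(f"velocity units must be 'cm/s' or 'm/s', got {units!r}")
    rr = cycle_duration if cycle_duration is not None \
        else meta.get("cycle_duration_s")
    if rr is None:
        raise ValueError("no cardiac timing metadata found and no "
                         "cycle_duration given")

    comps, shapes = [], []
    spacing = origin = None
    for p in velocity_paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        img = nib.load(str(p))
        arr = _from_nifti_array(np.asarray(img.dataobj, dtype=np.float64))
        shapes.append((p, arr.shape))
        if comps and arr.shape != comps[0].shape:
            raise ValueError(
                f"component shape mismatch: {shapes[0][0]} has "
                f"{shapes[0][1]} but {p} has {arr.shape}")
        comps.append(arr)
        if spacing is None:
            z = img.header.get_zooms()
            spacing = tuple(float(v) for v in z[:3])
            origin = tuple(float(v) for v in img.affine[:3, 3])
    velocity = np.stack(comps, axis=-1)

    mag_p = Path(magnitude_path)
    if not mag_p.exists():
        raise FileNotFoundError(mag_p)
    magnitude = _from_nifti_array(
        np.asarray(nib.load(str(mag_p)).dataobj, dtype=np.float64))
    if magnitude.shape != velocity.shape[:4]:
        raise ValueError(f"magnitude file {mag_p} shape {magnitude.shape} "
                         f"does not match velocity grid {velocity.shape[:4]}")

    if units == "cm/s":
        velocity = velocity / 100.0
    return FlowDataset(velocity=velocity, magnitude=magnitude,
                       spacing=spacing, origin=origin,
                       cycle_duration=float(rr),
                       venc=venc if venc is not None else meta.get("venc_cm_s"))


def save_mask(mask: Mask3D, path: str | Path) -> None:
    path = Path(path)
    aff = _affine(mask.spacing, mask.origin)
    arr = np.ascontiguousarray(np.transpose(mask.labels, (2, 1, 0)))
    nib.save(nib.Nifti1Image(arr.astype(np.int16), aff), str(path))
    Path(str(path) + ".labels.json").write_text(json.dumps(mask.label_map))


def load_mask(path: str | Path) -> Mask3D:
    img = nib.load(str(path))
    labels = np.ascontiguousarray(
        np.transpose(np.asarray(img.dataobj, dtype=np.int32), (2, 1, 0)))
    zooms = img.header.get_zooms()
    label_file = Path(str(path) + ".labels.json")
    label_map = json.loads(label_file.read_text()) if label_file.exists() \
        else {"LA": 1, "LV": 2, "AscAorta": 3}
    return Mask3D(labels=labels, label_map=label_map,
                  spacing=tuple(float(v) for v in zooms[:3]),
                  origin=tuple(float(v) for v in img.affine[:3, 3]))


def save_seeds(seeds: list[SphereSeed], path: str | Path) -> None:
    payload = [{"name": s.name, "center_mm": list(s.center),
                "radius_mm": s.radius} for s in seeds]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_seeds(path: str | Path) -> list[SphereSeed]:
    return [SphereSeed(name=d["name"], center=tuple(d["center_mm"]),
                       radius=d["radius_mm"])
            for d in json.loads(Path(path).read_text())]


def save_scalar_vtk(field: np.ndarray, spacing, origin,
                    path: str | Path) -> None:
    """Write a (z, y, x) scalar volume as a legacy VTK image via SimpleITK."""
    import SimpleITK as sitk
    img = sitk.GetImageFromArray(np.asarray(field, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def apply_mask(ds: FlowDataset, mask: Mask3D, label: str | int = "LA"
               ) -> FlowDataset:
    """Zero all velocities outside one labeled region, at every phase.

    Magnitude is left untouched. Idempotent.
    """
    region = mask.region(label)
    if region.shape != ds.shape:
        raise ValueError(f"mask grid {region.shape} does not match dataset "
                         f"grid {ds.shape}")
    if not region.any():
        warnings.warn(f"label {label!r} selects no voxels; "
                      "masked velocities are all zero")
    vel = np.where(region[None, :, :, :, None], ds.velocity, 0.0)
    return replace(ds, velocity=vel)


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def mask_to_surface_mesh(mask: Mask3D, label: str | int = "LA",
                         smooth: bool = False):
    """Closed triangular surface of one label, vertices in world mm.

    Marching cubes at the 0.5 iso-level of the binarized label. The binary
    volume is zero-padded by one voxel so surfaces touching the grid edge
    still close. Returns a ``trimesh.Trimesh``.
    """
    import trimesh
    region = mask.region(label)
    if not region.any():
        raise ValueError(f"label {label!r} selects no voxels")
    padded = np.pad(region.astype(np.float32), 1)
    dz, dy, dx = mask.spacing[2], mask.spacing[1], mask.spacing[0]
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(dz, dy, dx))
    # (z, y, x) mm -> world (x, y, z) mm, undoing the 1-voxel pad
    verts_xyz = verts[:, ::-1] - np.array([dx, dy, dz]) + np.array(mask.origin)
    mesh = trimesh.Trimesh(vertices=verts_xyz, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if smooth:
        trimesh.smoothing.filter_taubin(mesh)
    return mesh


_CUBE_TETS = np.array([
    [0, 1, 3, 7], [0, 1, 7, 5], [0, 5, 7, 4],
    [0, 3, 2, 7], [0, 2, 6, 7], [0, 6, 4, 7],
])  # 6-tet Kuhn split of a unit cube; corner c = (x, y, z) bits of its index


def mask_to_volume_mesh(mask: Mask3D, label: str | int = "LA"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Tetrahedralize the labeled voxels (6 tets per voxel).

    Returns ``(points, tets)`` with points in world mm. The summed tet
    volume equals voxel count x voxel volume exactly.
    """
    region = mask.region(label)
    if not region.any():
        raise ValueError(f"label {label!r} selects no voxels")
    kk, jj, ii = np.nonzero(region)
    dx, dy, dz = mask.spacing
    nz, ny, nx = region.shape

    def node_id(i, j, k):   # grid-corner lattice (nx+1, ny+1, nz+1)
        return (k * (ny + 1) + j) * (nx + 1) + i

    corner_bits = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1]
                            for c in range(8)])
    tets = []
    for tet in _CUBE_TETS:
        ids = [node_id(ii + corner_bits[c, 0], jj + corner_bits[c, 1],
                       kk + corner_bits[c, 2]) for c in tet]
        tets.append(np.stack(ids, axis=1))
    tets = np.concatenate(tets, axis=0)

    used, tets = np.unique(tets, return_inverse=True)
    tets = tets.reshape(-1, 4)
    k_n = used // ((ny + 1) * (nx + 1))
    j_n = (used // (nx + 1)) % (ny + 1)
    i_n = used % (nx + 1)
    points = np.stack([i_n * dx, j_n * dy, k_n * dz], axis=1) \
        + np.array(mask.origin)
    return points, tets


def tet_mesh_volume_mm3(points: np.ndarray, tets: np.ndarray) -> float:
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    vols = np.abs(np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))) / 6.0
    return float(vols.sum())


def save_volume_mesh_vtk(points: np.ndarray, tets: np.ndarray,
                         path: str | Path) -> None:
    """Legacy ASCII VTK unstructured-grid writer for tetrahedral meshes."""
    lines = ["# vtk DataFile Version 3.0", "laflow tetrahedral mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(points)} float"]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in points]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(int(v)) for v in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Upsampling
# ---------------------------------------------------------------------------

def upsample_scalar(field: np.ndarray, factor: int
                    ) -> np.ndarray:
    """Upsample the spatial axes of a (t, z, y, x) field by cubic interpolation.

    Tensor-product natural cubic splines, applied axis by axis; new sample
    ``m`` along an axis sits at old index ``m / factor``, so the effective
    spacing is divided by ``factor``, old samples are preserved, and affine
    fields are reproduced exactly. The time axis is untouched.
    """
    from scipy.interpolate import CubicSpline
    if int(factor) != factor or factor < 1:
        raise ValueError("upsampling factor must be an integer >= 1")
    factor = int(factor)
    field = np.asarray(field, dtype=np.float64)
    if factor == 1:
        return field.copy()
    squeeze = False
    if field.ndim == 3:
        field, squeeze = field[None], True
    out = field
    for ax in (1, 2, 3):
        n = out.shape[ax]
        if n < 2:
            out = np.repeat(out, factor, axis=ax)
            continue
        new_idx = np.arange(n * factor) / factor
        # natural spline extrapolates linearly past the last sample
        spline = CubicSpline(np.arange(n), out, axis=ax, bc_type="natural")
        out = spline(new_idx)
    return out[0] if squeeze else out
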