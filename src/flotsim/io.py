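"""Readers and writers: multi-page TIFF stacks with JSON sidecars, HDF5
containers for media / fields / sensitivity matrices / reconstructions,
and CSV curves.

All artifacts embed provenance (seeds, photon budgets, config hash) as
attributes or sidecar entries so a result can be traced back to the
generating command.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .acquisition import AcquisitionSpec, MeasurementStack
from .medium import FluorophoreMap, OpticalMedium, VoxelGrid
from .metrics import DecayCurve
from .reconstruction import ReconstructionVolume
from .sensitivity import SensitivityMatrix

AXIS_ORDER = "x,y,z"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# measurement stacks: TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def write_stack(stack: MeasurementStack, path) -> Path:
    """Multi-page grayscale TIFF (one page per stage position) + sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames, dtype=np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {
        "acquisition": dataclasses.asdict(stack.acq),
        "source_col": stack.source_col,
        "meta": _jsonable(stack.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return path


def read_stack(path) -> MeasurementStack:
    """Read a multi-page TIFF stack; sidecar missing -> defaults + warning flag."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            for i, p in enumerate(tf.pages):
                if p.shape != tf.pages[0].shape:
                    raise ValueError(
                        f"inconsistent page size at page {i}: "
                        f"{p.shape} != {tf.pages[0].shape}"
                    )
        frames = tf.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        acq = AcquisitionSpec(**sidecar["acquisition"])
        source_col = sidecar.get("source_col", 0)
        meta = sidecar.get("meta", {})
    else:
        acq = AcquisitionSpec(
            n_positions=frames.shape[0],
            n_offset_px=frames.shape[1],
            n_along_px=frames.shape[2],
        )
        source_col = 0
        meta = {"warning": "missing sidecar; acquisition defaults assumed"}
    return MeasurementStack(frames, acq, source_col=source_col, meta=meta)


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------


def write_medium(medium: OpticalMedium, path, fmap: FluorophoreMap | None = None):
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("mua", "mus", "g", "n"):
            f.create_dataset(name, data=getattr(medium, name))
        if fmap is not None:
            f.create_dataset("yield", data=fmap.yield_)
            f.attrs["fluoro_meta"] = json.dumps(_jsonable(fmap.meta))
        f.attrs["voxel_size_mm"] = medium.grid.voxel_size
        f.attrs["axis_order"] = AXIS_ORDER
    return path


def read_medium(path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        h = float(f.attrs["voxel_size_mm"])
        mua = f["mua"][...]
        grid = VoxelGrid(*mua.shape, h)
        medium = OpticalMedium(
            grid, mua, f["mus"][...], f["g"][...], f["n"][...],
            allow_zero_scatter=True,
        )
        fmap = None
        if "yield" in f:
            meta = json.loads(f.attrs.get("fluoro_meta", "{}"))
            fmap = FluorophoreMap(grid, f["yield"][...], meta)
    return medium, fmap


def write_sensitivity(W: SensitivityMatrix, path):
    """Sparse-triplet serialization (explicit backend only)."""
    if W.backend != "sparse":
        raise ValueError("HDF5 serialization covers the sparse backend; "
                         "conv-backend operators are rebuilt from kernels")
    path = Path(path)
    coo = W.matrix.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("row", data=coo.row)
        f.create_dataset("col", data=coo.col)
        f.create_dataset("val", data=coo.data)
        f.attrs["shape"] = W.shape
        f.attrs["grid"] = (W.grid.nx, W.grid.ny, W.grid.nz)
        f.attrs["voxel_size_mm"] = W.grid.voxel_size
        f.attrs["provenance"] = json.dumps(_jsonable(W.provenance))
        if W.row_index is not None:
            keys = np.array(list(W.row_index), dtype=np.int64)
            vals = np.array(list(W.row_index.values()), dtype=np.int64)
            f.create_dataset("row_index_keys", data=keys)
            f.create_dataset("row_index_vals", data=vals)
    return path


def read_sensitivity(path) -> SensitivityMatrix:
    import scipy.sparse as sp

    path = Path(path)
    with h5py.File(path, "r") as f:
        shape = tuple(f.attrs["shape"])
        nx, ny, nz = (int(v) for v in f.attrs["grid"])
        grid = VoxelGrid(nx, ny, nz, float(f.attrs["voxel_size_mm"]))
        mat = sp.csr_matrix(
            (f["val"][...], (f["row"][...], f["col"][...])), shape=shape
        )
        prov = json.loads(f.attrs.get("provenance", "{}"))
        row_index = None
        if "row_index_keys" in f:
            keys = f["row_index_keys"][...]
            vals = f["row_index_vals"][...]
            row_index = {tuple(int(x) for x in k): int(v) for k, v in zip(keys, vals)}
    return SensitivityMatrix(grid, "sparse", matrix=mat, row_index=row_index,
                             provenance=prov)


def write_reconstruction(recon: ReconstructionVolume, path):
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("recon", data=recon.values)
        f.attrs["voxel_size_mm"] = recon.grid.voxel_size
        f.attrs["lambda"] = recon.lam
        f.attrs["residual_norm"] = recon.residual_norm
        f.attrs["solution_norm"] = recon.solution_norm
        f.attrs["diagnostics"] = json.dumps(_jsonable(recon.diagnostics))
    return path


def read_reconstruction(path) -> ReconstructionVolume:
    path = Path(path)
    with h5py.File(path, "r") as f:
        vals = f["recon"][...]
        grid = VoxelGrid(*vals.shape, float(f.attrs["voxel_size_mm"]))
        return ReconstructionVolume(
            grid,
            vals,
            float(f.attrs["lambda"]),
            float(f.attrs["residual_norm"]),
            float(f.attrs["solution_norm"]),
            json.loads(f.attrs.get("diagnostics", "{}")),
        )


# ---------------------------------------------------------------------------
# curves and reports
# ---------------------------------------------------------------------------


def write_curve(curve: DecayCurve, path):
    path = Path(path)
    with path.open("w") as f:
        f.write("depth_um,intensity\n")
        for d, v in zip(curve.depth_um, curve.intensity):
            f.write(f"{d:.6g},{v:.8g}\n")
    return path


def read_curve(path) -> DecayCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return DecayCurve(data[:, 0], data[:, 1])


def write_report(report: dict, path):
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return path


def write_fields(path, phi=None, greens=None):
    """MC fields container: dataset ``phi`` and ``green/<pixel_id>``.

    Seed, photon budget, and source/detector geometry travel as attributes.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        if phi is not None:
            d = f.create_dataset("phi", data=phi.phi)
            d.attrs["meta"] = json.dumps(_jsonable(phi.meta))
            f.attrs["voxel_size_mm"] = phi.grid.voxel_size
        if greens:
            grp = f.create_group("green")
            for pixel_id, gf in greens.items():
                d = grp.create_dataset(str(pixel_id), data=gf.green)
                d.attrs["meta"] = json.dumps(_jsonable(gf.meta))
                if gf.detector is not None:
                    d.attrs["position"] = gf.detector.position
                f.attrs["voxel_size_mm"] = gf.grid.voxel_size
    return path


def read_fields(path):
    """Read back (phi, greens) written by :func:`write_fields`."""
    from .mc import DetectorSpec, FluenceField, GreenField

    path = Path(path)
    phi = None
    greens = {}
    with h5py.File(path, "r") as f:
        h = float(f.attrs["voxel_size_mm"])
        if "phi" in f:
            data = f["phi"][...]
            grid = VoxelGrid(*data.shape, h)
            phi = FluenceField(grid, data, json.loads(f["phi"].attrs["meta"]))
        if "green" in f:
            for key, d in f["green"].items():
                data = d[...]
                grid = VoxelGrid(*data.shape, h)
                det = None
                if "position" in d.attrs:
                    det = DetectorSpec(tuple(float(v) for v in d.attrs["position"]))
                greens[int(key)] = GreenField(
                    grid, data, det, json.loads(d.attrs["meta"])
                )
    return phi, greens


def write_reconstruction_tiff(recon: ReconstructionVolume, path):
    """Multi-page 16-bit TIFF, one page per depth layer, for viewing."""
    path = Path(path)
    vals = recon.values
    peak = float(vals.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    pages = np.transpose(np.rint(vals * scale).astype(np.uint16), (2, 0, 1))
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path
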