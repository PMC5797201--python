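"""Container I/O: NIfTI images, sinogram files, HU -> mu conversion.

Sinograms are stored as flat little-endian binary (plane-major, then angle,
then radial) with a JSON sidecar carrying the geometry hash, span, dtype and
shape; a hash mismatch on read is an explicit error.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import ScannerGeometry
from .projector import Image3D
from .sinogram import SinogramSet

__all__ = [
    "read_image", "write_image",
    "read_sinogram", "write_sinogram",
    "hu_to_mu", "DEFAULT_HU_BREAKPOINTS",
]


class ContainerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------

def write_image(img: Image3D, path) -> None:
    """NIfTI-1 with the affine carrying voxel size and corner origin.

    Internal axis order (z, y, x) is stored transposed so that on-disk the
    fastest axis is x, as NIfTI viewers expect.
    """
    data = np.ascontiguousarray(np.transpose(img.values, (2, 1, 0)))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)   # NIfTI-1 has no 64-bit int type
    else:
        data = data.astype(np.float64)
    dz, dy, dx = img.voxel_size
    z0, y0, x0 = img.origin
    affine = np.diag([dx, dy, dz, 1.0])
    # voxel-centre position of index (0,0,0)
    affine[:3, 3] = [x0 + dx / 2.0, y0 + dy / 2.0, z0 + dz / 2.0]
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_image(path) -> Image3D:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ContainerError("expected a 3-D NIfTI image")
    aff = ni.affine
    vox = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(aff[:3, :3], np.diag(vox), atol=1e-6):
        raise ContainerError("only axis-aligned affines are supported")
    dx, dy, dz = (float(v) for v in vox)
    x0 = float(aff[0, 3]) - dx / 2.0
    y0 = float(aff[1, 3]) - dy / 2.0
    z0 = float(aff[2, 3]) - dz / 2.0
    values = np.transpose(data, (2, 1, 0))
    return Image3D(values, (dz, dy, dx), (z0, y0, x0))


# ---------------------------------------------------------------------------
# sinogram container
# ---------------------------------------------------------------------------

def write_sinogram(sino: SinogramSet, path) -> None:
    path = Path(path)
    arr = np.ascontiguousarray(sino.data, dtype="<f8")
    path.write_bytes(arr.tobytes())
    sidecar = {
        "format": "petquant-sinogram",
        "version": 1,
        "span": sino.span,
        "shape": list(arr.shape),
        "dtype": "<f8",
        "plane_order": "segment-major",
        "geometry_hash": sino.geometry_hash,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_sinogram(path, geom: ScannerGeometry | None = None) -> SinogramSet:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta.get("format") != "petquant-sinogram":
        raise ContainerError("not a sinogram container")
    shape = tuple(meta["shape"])
    n = int(np.prod(shape))
    raw = path.read_bytes()
    if len(raw) != n * np.dtype(meta["dtype"]).itemsize:
        raise ContainerError("payload size does not match sidecar shape")
    data = np.frombuffer(raw, dtype=meta["dtype"], count=n).reshape(shape)
    if geom is not None and meta.get("geometry_hash") and \
            meta["geometry_hash"] != geom.content_hash():
        raise ContainerError("geometry hash mismatch")
    return SinogramSet(data.copy(), meta["span"], meta.get("geometry_hash", ""))


# ---------------------------------------------------------------------------
# HU -> mu piecewise-linear conversion
# ---------------------------------------------------------------------------

#: (HU, mu at 511 keV in 1/cm); air pinned to exactly 0
DEFAULT_HU_BREAKPOINTS = (
    (-1000.0, 0.0),
    (0.0, 0.096),
    (1000.0, 0.172),
    (3000.0, 0.262),
)


def hu_to_mu(ct_like: Image3D, breakpoints=DEFAULT_HU_BREAKPOINTS) -> Image3D:
    bp = np.asarray(breakpoints, dtype=float)
    hu = bp[:, 0]
    mu = bp[:, 1]
    if np.any(np.diff(hu) <= 0):
        raise ContainerError("breakpoints must be strictly increasing in HU")
    out = np.interp(ct_like.values, hu, mu)
    out = np.clip(out, 0.0, None)
    return ct_like.copy_with(out)
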