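"""Exact Siddon ray tracing between crystal pairs and image voxels.

The 3-D system matrix element ``p_ij`` is the exact intersection length (mm)
of the line between the two crystal-face centres with voxel ``j``.  Tracing
is decomposed into a precomputed transaxial part — 2-D Siddon intersections
per (angle, radial) bin, shared by every ring pair — and an on-the-fly axial
part: the 2-D intervals are parametrised by ``t`` along the chord, the axial
coordinate is linear in the same ``t``, and each transaxial interval is split
at the z-voxel crossings.  The combined sub-interval lengths are scaled by
the oblique chord length, which yields exactly the 3-D Siddon lengths.

Ray tracing is always performed in span-1; span-S outputs are formed by
summing span-1 planes.  ``p_ij`` carries no sensitivity terms — normalisation
and attenuation are separate factor sinograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import (ScannerGeometry, SinoBinMap, build_michelogram,
                       build_sino_bin_map)
from .sinogram import SinogramSet, empty_sinogram, reduce_span

__all__ = [
    "Image3D",
    "TransaxialLUT",
    "centred_image",
    "build_transaxial_lut",
    "forward_project",
    "back_project",
    "attenuation_factors",
]


@dataclass
class Image3D:
    """Voxel grid with axes (axial z, transaxial y, transaxial x).

    ``origin`` is the mm offset of the grid corner (voxel [0,0,0] low corner)
    from the scanner iso-centre; ``voxel_size`` is (dz, dy, dx) in mm.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("Image3D expects a 3-D array (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def grid_spec(self) -> tuple:
        return (self.shape, self.voxel_size, self.origin)

    def copy_with(self, values: np.ndarray) -> "Image3D":
        return Image3D(values, self.voxel_size, self.origin)

    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def voxel_centres(self):
        """Coordinate vectors (z, y, x) of voxel centres in mm."""
        out = []
        for n, d, o in zip(self.shape, self.voxel_size, self.origin):
            out.append(o + d * (np.arange(n) + 0.5))
        return tuple(out)


def centred_image(geom_or_none, shape, voxel_size,
                  values: np.ndarray | None = None) -> Image3D:
    """Grid centred on the iso-centre (geometry arg kept for symmetry)."""
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    origin = (-nz * dz / 2.0, -ny * dy / 2.0, -nx * dx / 2.0)
    if values is None:
        values = np.zeros(shape)
    return Image3D(values, voxel_size, origin)


# ---------------------------------------------------------------------------
# 2-D Siddon per transaxial bin
# ---------------------------------------------------------------------------

@njit(cache=True)
def _siddon2d(ax, ay, bx, by, x0, y0, dx, dy, nx, ny,
              out_ix, out_iy, out_t0, out_t1):
    """Exact 2-D voxel traversal from (ax,ay) to (bx,by), t in [0,1].

    Returns the number of entries written.  Ties at voxel boundaries are
    resolved by half-open voxel intervals [low, high).
    """
    ux = bx - ax
    uy = by - ay
    eps = 1e-12
    tmin = 0.0
    tmax = 1.0
    # clip to grid bounding box (slab method)
    for axis in range(2):
        if axis == 0:
            p0, u, lo, n, d = ax, ux, x0, nx, dx
        else:
            p0, u, lo, n, d = ay, uy, y0, ny, dy
        hi = lo + n * d
        if abs(u) < eps:
            if p0 < lo or p0 >= hi:
                return 0
        else:
            t_a = (lo - p0) / u
            t_b = (hi - p0) / u
            if t_a > t_b:
                t_a, t_b = t_b, t_a
            if t_a > tmin:
                tmin = t_a
            if t_b < tmax:
                tmax = t_b
    if tmin >= tmax:
        return 0
    # start voxel
    t = tmin
    px = ax + t * ux
    py = ay + t * uy
    ix = int(np.floor((px - x0) / dx))
    iy = int(np.floor((py - y0) / dy))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    sx = 1 if ux > 0 else -1
    sy = 1 if uy > 0 else -1
    # parametric distance to next x/y boundary
    if abs(ux) < eps:
        tx = 1e30
        dtx = 1e30
    else:
        nxt = x0 + (ix + (1 if sx > 0 else 0)) * dx
        tx = (nxt - ax) / ux
        dtx = dx / abs(ux)
    if abs(uy) < eps:
        ty = 1e30
        dty = 1e30
    else:
        nyt = y0 + (iy + (1 if sy > 0 else 0)) * dy
        ty = (nyt - ay) / uy
        dty = dy / abs(uy)
    n_out = 0
    while t < tmax - eps:
        if tx < ty:
            t_next = tx
        else:
            t_next = ty
        if t_next > tmax:
            t_next = tmax
        if t_next > t + eps:
            out_ix[n_out] = ix
            out_iy[n_out] = iy
            out_t0[n_out] = t
            out_t1[n_out] = t_next
            n_out += 1
        t = t_next
        if tx < ty:
            ix += sx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        else:
            iy += sy
            ty += dty
            if iy < 0 or iy >= ny:
                break
    return n_out


@dataclass
class TransaxialLUT:
    """Precomputed 2-D Siddon intersections for every transaxial bin.

    CSR layout over flattened (angle, radial) bins: bin ``b`` owns entries
    ``indptr[b]:indptr[b+1]``, each a voxel column ``(iy, ix)`` with the
    parametric interval ``[t0, t1]`` along the chord from crystal A to B.
    ``l2d[b]`` is the full 2-D chord length |AB| in mm.
    """

    grid: tuple                      # ((nz, ny, nx), voxel, origin)
    indptr: np.ndarray               # (n_bins+1,) int64
    entry_ix: np.ndarray             # int32
    entry_iy: np.ndarray             # int32
    entry_t0: np.ndarray             # float64
    entry_t1: np.ndarray             # float64
    l2d: np.ndarray                  # (n_bins,) float64
    binmap: SinoBinMap

    def entries(self, angle: int, radial: int):
        """(iy, ix, t0, t1) arrays of one bin, ordered from crystal A to B."""
        b = angle * self.binmap.n_radial + radial
        s, e = self.indptr[b], self.indptr[b + 1]
        return (self.entry_iy[s:e], self.entry_ix[s:e],
                self.entry_t0[s:e], self.entry_t1[s:e])

    def chord_lengths(self, angle: int, radial: int) -> np.ndarray:
        iy, ix, t0, t1 = self.entries(angle, radial)
        return (t1 - t0) * self.l2d[angle * self.binmap.n_radial + radial]


@njit(cache=True)
def _build_lut_kernel(xy_a, xy_b, x0, y0, dx, dy, nx, ny,
                      indptr, ent_ix, ent_iy, ent_t0, ent_t1):
    nb = xy_a.shape[0]
    buf_ix = np.empty(2 * (nx + ny) + 4, dtype=np.int32)
    buf_iy = np.empty(2 * (nx + ny) + 4, dtype=np.int32)
    buf_t0 = np.empty(2 * (nx + ny) + 4, dtype=np.float64)
    buf_t1 = np.empty(2 * (nx + ny) + 4, dtype=np.float64)
    pos = 0
    for b in range(nb):
        indptr[b] = pos
        n = _siddon2d(xy_a[b, 0], xy_a[b, 1], xy_b[b, 0], xy_b[b, 1],
                      x0, y0, dx, dy, nx, ny, buf_ix, buf_iy, buf_t0, buf_t1)
        for k in range(n):
            ent_ix[pos] = buf_ix[k]
            ent_iy[pos] = buf_iy[k]
            ent_t0[pos] = buf_t0[k]
            ent_t1[pos] = buf_t1[k]
            pos += 1
    indptr[nb] = pos
    return pos


def build_transaxial_lut(geom: ScannerGeometry, image_spec) -> TransaxialLUT:
    """Trace all transaxial bins through the (y, x) grid of ``image_spec``.

    ``image_spec`` is an :class:`Image3D` or a ``(shape, voxel, origin)``
    tuple; only the transaxial part of the grid is used.
    """
    if isinstance(image_spec, Image3D):
        grid = image_spec.grid_spec()
    else:
        grid = tuple(image_spec)
    (nz, ny, nx), (dz, dy, dx), (z0, y0, x0) = grid

    fov_radius = 0.5 * max(ny * dy, nx * dx) * np.sqrt(2.0)
    if fov_radius > 0.5 * geom.ring_diameter + 1e-9:
        # corners may poke outside the ring; only reject if the inscribed
        # circle does, which would put crystals inside the image
        if 0.5 * min(ny * dy, nx * dx) > 0.5 * geom.ring_diameter:
            raise ValueError("image FOV extends outside the detector ring")

    binmap = build_sino_bin_map(geom)
    xy = geom.tx_crystal_xy()
    xy_a = xy[binmap.pair_a.ravel()]
    xy_b = xy[binmap.pair_b.ravel()]
    nb = xy_a.shape[0]
    cap = nb * (nx + ny + 2)
    indptr = np.zeros(nb + 1, dtype=np.int64)
    ent_ix = np.empty(cap, dtype=np.int32)
    ent_iy = np.empty(cap, dtype=np.int32)
    ent_t0 = np.empty(cap, dtype=np.float64)
    ent_t1 = np.empty(cap, dtype=np.float64)
    used = _build_lut_kernel(xy_a, xy_b, x0, y0, dx, dy, nx, ny,
                             indptr, ent_ix, ent_iy, ent_t0, ent_t1)
    l2d = np.hypot(xy_b[:, 0] - xy_a[:, 0], xy_b[:, 1] - xy_a[:, 1])
    return TransaxialLUT(grid=grid, indptr=indptr,
                         entry_ix=ent_ix[:used].copy(),
                         entry_iy=ent_iy[:used].copy(),
                         entry_t0=ent_t0[:used].copy(),
                         entry_t1=ent_t1[:used].copy(),
                         l2d=l2d, binmap=binmap)


# ---------------------------------------------------------------------------
# forward / back projection kernels (span-1)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _project_kernel(values, sino, mode,
                    bins, plane_r0, plane_r1, ring_z,
                    indptr, ent_ix, ent_iy, ent_t0, ent_t1, l2d,
                    z0, dvz, nz, n_radial):
    """mode 0: forward (values -> sino); mode 1: back (sino -> values)."""
    n_planes = plane_r0.shape[0]
    eps = 1e-12
    for bi in range(bins.shape[0]):
        b = bins[bi]
        s = indptr[b]
        e = indptr[b + 1]
        if e == s:
            continue
        a = b // n_radial
        r = b - a * n_radial
        L2 = l2d[b]
        for p in range(n_planes):
            zA = ring_z[plane_r0[p]]
            zB = ring_z[plane_r1[p]]
            dz = zB - zA
            L3 = np.sqrt(L2 * L2 + dz * dz)
            acc = 0.0
            val = 0.0
            if mode == 1:
                val = sino[p, a, r]
                if val == 0.0:
                    continue
            for k in range(s, e):
                t0 = ent_t0[k]
                t1 = ent_t1[k]
                iy = ent_iy[k]
                ix = ent_ix[k]
                if dz == 0.0:
                    iz = int(np.floor((zA - z0) / dvz))
                    if 0 <= iz < nz:
                        seg = (t1 - t0) * L3
                        if mode == 0:
                            acc += values[iz, iy, ix] * seg
                        else:
                            values[iz, iy, ix] += val * seg
                    continue
                t = t0
                iz = int(np.floor((zA + t * dz - z0) / dvz))
                step = 1 if dz > 0 else -1
                while t < t1 - eps:
                    if step > 0:
                        z_next = z0 + (iz + 1) * dvz
                    else:
                        z_next = z0 + iz * dvz
                    t_next = (z_next - zA) / dz
                    if t_next > t1:
                        t_next = t1
                    if t_next > t:
                        if 0 <= iz < nz:
                            seg = (t_next - t) * L3
                            if mode == 0:
                                acc += values[iz, iy, ix] * seg
                            else:
                                values[iz, iy, ix] += val * seg
                        t = t_next
                    iz += step
            if mode == 0:
                sino[p, a, r] = acc


def _plane_rings(geom: ScannerGeometry):
    m1 = build_michelogram(geom, 1)
    r0 = np.array([p[0, 0] for p in m1.plane_pairs], dtype=np.int32)
    r1 = np.array([p[0, 1] for p in m1.plane_pairs], dtype=np.int32)
    return r0, r1


def _subset_bins(lut: TransaxialLUT, subset) -> np.ndarray:
    """Flattened active-bin ids, optionally restricted to an angle subset."""
    active = lut.binmap.active_mask
    nr = lut.binmap.n_radial
    if subset is None:
        angles = np.arange(lut.binmap.n_angles)
    else:
        angles = np.asarray(subset, dtype=np.int64)
    a_grid, r_grid = np.meshgrid(angles, np.arange(nr), indexing="ij")
    keep = active[a_grid, r_grid]
    return (a_grid[keep] * nr + r_grid[keep]).astype(np.int64)


def _check_grid(image: Image3D, lut: TransaxialLUT):
    if tuple(image.grid_spec()[0]) != tuple(lut.grid[0]) or \
       not np.allclose(image.grid_spec()[1], lut.grid[1]) or \
       not np.allclose(image.grid_spec()[2], lut.grid[2]):
        raise ValueError("image grid does not match the LUT grid")


def forward_project(image: Image3D, lut: TransaxialLUT,
                    geom: ScannerGeometry, subset=None,
                    span=1) -> SinogramSet:
    """q_i = sum_j p_ij n_j in span-1 (reduced to ``span`` if requested)."""
    _check_grid(image, lut)
    if np.any(np.isnan(image.values)):
        raise ValueError("NaN in input image")
    (nz, ny, nx), (dvz, dy, dx), (z0, y0, x0) = lut.grid
    r0, r1 = _plane_rings(geom)
    sino = empty_sinogram(geom, 1)
    bins = _subset_bins(lut, subset)
    _project_kernel(image.values, sino.data, 0, bins, r0, r1, geom.ring_z(),
                    lut.indptr, lut.entry_ix, lut.entry_iy,
                    lut.entry_t0, lut.entry_t1, lut.l2d,
                    z0, dvz, nz, lut.binmap.n_radial)
    if span != 1:
        sino = reduce_span(sino, geom, span)
    return sino


def back_project(sino: SinogramSet, lut: TransaxialLUT,
                 geom: ScannerGeometry, subset=None) -> Image3D:
    """Exact adjoint of :func:`forward_project` (span-1 input)."""
    if sino.span != 1:
        raise ValueError("back projection expects span-1 sinograms")
    (nz, ny, nx), voxel, origin = lut.grid
    r0, r1 = _plane_rings(geom)
    img = np.zeros((nz, ny, nx), dtype=np.float64)
    bins = _subset_bins(lut, subset)
    _project_kernel(img, np.ascontiguousarray(sino.data, dtype=np.float64),
                    1, bins, r0, r1, geom.ring_z(),
                    lut.indptr, lut.entry_ix, lut.entry_iy,
                    lut.entry_t0, lut.entry_t1, lut.l2d,
                    origin[0], voxel[0], nz, lut.binmap.n_radial)
    return Image3D(img, voxel, origin)


def attenuation_factors(mumap: Image3D, lut: TransaxialLUT,
                        geom: ScannerGeometry) -> SinogramSet:
    """AF_i = exp(-sum_j p_ij mu_j / 10); mu in 1/cm, lengths in mm."""
    if np.any(mumap.values < 0):
        raise ValueError("negative attenuation coefficients")
    line = forward_project(mumap, lut, geom)
    af = np.exp(-line.data / 10.0)
    return SinogramSet(af, 1, line.geometry_hash)
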