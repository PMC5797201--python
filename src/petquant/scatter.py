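"""Fully-3D voxel-driven single-scatter model (VSM).

Each emission voxel above a configurable activity threshold is treated
independently: the unscattered photon is scored at a sampled detector A, the
opposing photon is traced through the attenuation map where every high-mu
voxel along its path acts as a scattering patch, and the scattered photon is
scored at a sampled detector B with the Klein-Nishina differential
cross-section and the solid angle of B.  Summing over emission voxels gives
absolute per-LOR single-scatter probabilities on a sparse, regular node grid
(sampled ring pairs x sampled angles x sampled radial bins), which is then
interpolated to the full sinogram (bicubic transaxially, bilinear across the
Michelogram) and scaled to the prompt data by weighted least squares in the
scatter-and-randoms-only region outside the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import RectBivariateSpline

from .geometry import (ScannerGeometry, build_michelogram, build_sino_bin_map,
                       count_sinograms)
from .projector import Image3D
from .sinogram import SinogramSet, empty_sinogram, reduce_span

__all__ = [
    "R_E_CM",
    "ScatterConfig",
    "ScatterLUT",
    "SparseScatterSinogram",
    "build_scatter_lut",
    "kn_differential",
    "kn_total",
    "downsample_image",
    "vsm_single_scatter",
    "interpolate_scatter",
    "scale_scatter",
]

#: classical electron radius in cm
R_E_CM = 2.8179403e-13


class ScatterError(ValueError):
    pass


@dataclass
class ScatterConfig:
    emission_downsample: int = 1
    mumap_downsample: int = 1
    axial_detector_sampling: int = 8      # 1:N ring stride
    tx_detector_sampling: int = 7         # 1:N transaxial bin stride
    emission_threshold: float = 0.05      # fraction of image max
    scattering_patch_threshold: float = 0.02  # mu (1/cm)
    af_mask_threshold: float = 0.95
    energy_lld_keV: float = 0.0           # lower discriminator, 0 = off

    def __post_init__(self):
        if self.emission_downsample < 1 or self.mumap_downsample < 1:
            raise ScatterError("downsample factors must be >= 1")
        if not 0 <= self.emission_threshold < 1:
            raise ScatterError("emission_threshold must be in [0, 1)")


# ---------------------------------------------------------------------------
# Klein-Nishina
# ---------------------------------------------------------------------------

def kn_differential(cos_theta):
    """Differential K-N cross-section at 511 keV incident energy.

    Returns (d sigma_e / d Omega in cm^2/sr, scattered/incident energy
    ratio).  With alpha = E/m_e c^2 = 1 the energy ratio is
    P = 1/(2 - cos theta) and d sigma/d Omega =
    (r_e^2 / 2) P^2 (P + 1/P - sin^2 theta).
    """
    c = np.asarray(cos_theta, dtype=float)
    if np.any(c < -1 - 1e-12) or np.any(c > 1 + 1e-12):
        raise ScatterError("cos(theta) outside [-1, 1]")
    c = np.clip(c, -1.0, 1.0)
    P = 1.0 / (2.0 - c)
    sin2 = 1.0 - c * c
    dsdo = 0.5 * R_E_CM ** 2 * P * P * (P + 1.0 / P - sin2)
    if np.ndim(cos_theta) == 0:
        return float(dsdo), float(P)
    return dsdo, P


def kn_total(alpha: float = 1.0) -> float:
    """Total K-N electronic cross-section (cm^2) for photon energy
    alpha = E / (m_e c^2)."""
    a = float(alpha)
    t1 = (1 + a) / a ** 2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return float(2 * np.pi * R_E_CM ** 2 * (t1 + t2 - t3))


def mu_energy_scaling(energy_ratio) -> np.ndarray:
    """c_B: mu at the scattered energy relative to mu at 511 keV.

    Water-like medium where Compton scattering dominates, so the scaling
    follows the total K-N cross-section ratio at the downshifted energy.
    """
    er = np.asarray(energy_ratio, dtype=float)
    sigma511 = kn_total(1.0)
    out = np.vectorize(lambda e: kn_total(e) / sigma511)(er)
    return float(out) if np.ndim(energy_ratio) == 0 else out


# ---------------------------------------------------------------------------
# image downsampling
# ---------------------------------------------------------------------------

def downsample_image(img: Image3D, factor: int) -> Image3D:
    """Block-mean downsampling with a centred crop when not divisible.

    Means are preserved over the common support, so mu-maps keep their mean
    attenuation and emission keeps total activity up to the voxel-volume
    ratio (exactly, when the dimensions divide).
    """
    factor = int(factor)
    if factor < 1:
        raise ScatterError("factor must be >= 1")
    if factor == 1:
        return Image3D(img.values.copy(), img.voxel_size, img.origin)
    shape = img.shape
    if any(s < factor for s in shape):
        raise ScatterError("downsample factor larger than image dimension")
    new_shape = tuple(s // factor for s in shape)
    start = tuple((s - n * factor) // 2 for s, n in zip(shape, new_shape))
    sl = tuple(slice(st, st + n * factor)
               for st, n in zip(start, new_shape))
    v = img.values[sl]
    v = v.reshape(new_shape[0], factor, new_shape[1], factor,
                  new_shape[2], factor).mean(axis=(1, 3, 5))
    voxel = tuple(d * factor for d in img.voxel_size)
    origin = tuple(o + st * d
                   for o, st, d in zip(img.origin, start, img.voxel_size))
    return Image3D(v, voxel, origin)


# ---------------------------------------------------------------------------
# ray integrals through a voxel grid (exact traversal)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _line_integral_mm(mu, z0, y0, x0, dz, dy, dx, p0, p1):
    """Integral of mu along the segment p0 -> p1; lengths in mm."""
    nz, ny, nx = mu.shape
    u = p1 - p0
    L = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    if L == 0.0:
        return 0.0
    eps = 1e-12
    tmin, tmax = 0.0, 1.0
    lo = np.array([z0, y0, x0])
    d = np.array([dz, dy, dx])
    n = np.array([nz, ny, nx])
    for ax in range(3):
        hi = lo[ax] + n[ax] * d[ax]
        if abs(u[ax]) < eps:
            if p0[ax] < lo[ax] or p0[ax] >= hi:
                return 0.0
        else:
            ta = (lo[ax] - p0[ax]) / u[ax]
            tb = (hi - p0[ax]) / u[ax]
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
    if tmin >= tmax:
        return 0.0
    acc = 0.0
    t = tmin
    idx = np.empty(3, np.int64)
    for ax in range(3):
        idx[ax] = int(np.floor((p0[ax] + t * u[ax] - lo[ax]) / d[ax]))
        if idx[ax] < 0:
            idx[ax] = 0
        if idx[ax] > n[ax] - 1:
            idx[ax] = n[ax] - 1
    tnext = np.empty(3)
    dt = np.empty(3)
    stp = np.empty(3, np.int64)
    for ax in range(3):
        if abs(u[ax]) < eps:
            tnext[ax] = 1e30
            dt[ax] = 1e30
            stp[ax] = 1
        else:
            stp[ax] = 1 if u[ax] > 0 else -1
            bound = lo[ax] + (idx[ax] + (1 if u[ax] > 0 else 0)) * d[ax]
            tnext[ax] = (bound - p0[ax]) / u[ax]
            dt[ax] = d[ax] / abs(u[ax])
    while t < tmax - eps:
        ax_min = 0
        if tnext[1] < tnext[ax_min]:
            ax_min = 1
        if tnext[2] < tnext[ax_min]:
            ax_min = 2
        tn = tnext[ax_min]
        if tn > tmax:
            tn = tmax
        if tn > t:
            acc += mu[idx[0], idx[1], idx[2]] * (tn - t) * L
            t = tn
        idx[ax_min] += stp[ax_min]
        if idx[ax_min] < 0 or idx[ax_min] >= n[ax_min]:
            break
        tnext[ax_min] += dt[ax_min]
    return acc


@njit(cache=True)
def _collect_patches(mu, z0, y0, x0, dz, dy, dx, e, a_hat, thresh,
                     max_range, out_vox, out_len, out_depth):
    """Scattering patches along the ray e + l * a_hat, l > 0.

    Writes flat patch-voxel indices, chord lengths (mm) and the cumulative
    optical depth (mu * mm) from E to each patch entry; returns the count.
    """
    p0 = e
    p1 = e + a_hat * max_range
    nz, ny, nx = mu.shape
    u = p1 - p0
    L = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    eps = 1e-12
    tmin, tmax = 0.0, 1.0
    lo = np.array([z0, y0, x0])
    d = np.array([dz, dy, dx])
    n = np.array([nz, ny, nx])
    for ax in range(3):
        hi = lo[ax] + n[ax] * d[ax]
        if abs(u[ax]) < eps:
            if p0[ax] < lo[ax] or p0[ax] >= hi:
                return 0
        else:
            ta = (lo[ax] - p0[ax]) / u[ax]
            tb = (hi - p0[ax]) / u[ax]
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
    if tmin >= tmax:
        return 0
    t = tmin
    idx = np.empty(3, np.int64)
    for ax in range(3):
        idx[ax] = int(np.floor((p0[ax] + t * u[ax] - lo[ax]) / d[ax]))
        if idx[ax] < 0:
            idx[ax] = 0
        if idx[ax] > n[ax] - 1:
            idx[ax] = n[ax] - 1
    tnext = np.empty(3)
    dt = np.empty(3)
    stp = np.empty(3, np.int64)
    for ax in range(3):
        if abs(u[ax]) < eps:
            tnext[ax] = 1e30
            dt[ax] = 1e30
            stp[ax] = 1
        else:
            stp[ax] = 1 if u[ax] > 0 else -1
            bound = lo[ax] + (idx[ax] + (1 if u[ax] > 0 else 0)) * d[ax]
            tnext[ax] = (bound - p0[ax]) / u[ax]
            dt[ax] = d[ax] / abs(u[ax])
    count = 0
    depth = 0.0
    while t < tmax - eps:
        ax_min = 0
        if tnext[1] < tnext[ax_min]:
            ax_min = 1
        if tnext[2] < tnext[ax_min]:
            ax_min = 2
        tn = tnext[ax_min]
        if tn > tmax:
            tn = tmax
        if tn > t:
            seg = (tn - t) * L
            m = mu[idx[0], idx[1], idx[2]]
            if m > thresh and count < out_len.shape[0]:
                out_vox[count] = (idx[0] * mu.shape[1] + idx[1]) * \
                    mu.shape[2] + idx[2]
                out_len[count] = seg
                out_depth[count] = depth
                count += 1
            depth += m * seg
            t = tn
        idx[ax_min] += stp[ax_min]
        if idx[ax_min] < 0 or idx[ax_min] >= n[ax_min]:
            break
        tnext[ax_min] += dt[ax_min]
    return count


@njit(cache=True)
def _kn_diff_nb(c):
    P = 1.0 / (2.0 - c)
    return 0.5 * R_E_CM ** 2 * P * P * (P + 1.0 / P - (1.0 - c * c)), P


@njit(cache=True)
def _kn_total_nb(a):
    t1 = (1 + a) / a ** 2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E_CM ** 2 * (t1 + t2 - t3)


@njit(cache=True)
def _depth_table(mu, z0, y0, x0, dz, dy, dx, points, det_pos):
    """Optical depths (unitless) from each point to each detector."""
    out = np.empty((points.shape[0], det_pos.shape[0]))
    for i in range(points.shape[0]):
        for j in range(det_pos.shape[0]):
            out[i, j] = _line_integral_mm(mu, z0, y0, x0, dz, dy, dx,
                                          points[i], det_pos[j]) / 10.0
    return out


@njit(cache=True)
def _vsm_kernel(em_pts, em_vals, mu, z0, y0, x0, dz, dy, dx,
                det_pos, det_norm, tau_e, tau_p, patch_of_voxel, patch_pos,
                group_ptr, group_adet, node_bdet, node_out,
                face_area, patch_thresh, max_range, sigma_e, out):
    """Accumulate P_s(BSEA) per output node.

    Nodes are grouped by their unscattered-side detector A (``group_*``
    CSR arrays over ``node_bdet``/``node_out``); ``tau_e``/``tau_p`` are
    precomputed optical depths from emission points / patch centres to the
    sampled detectors.
    """
    max_patches = mu.shape[0] + mu.shape[1] + mu.shape[2] + 4
    pat_vox = np.empty(max_patches, np.int64)
    pat_len = np.empty(max_patches)
    pat_dep = np.empty(max_patches)
    n_groups = group_ptr.shape[0] - 1
    for gi in range(n_groups):
        a = group_adet[gi]
        ap = det_pos[a]
        an = det_norm[a]
        g0 = group_ptr[gi]
        g1 = group_ptr[gi + 1]
        if g1 == g0:
            continue
        for ei in range(em_pts.shape[0]):
            e = em_pts[ei]
            w = em_vals[ei]
            ea = ap - e
            r_a = np.sqrt(ea[0] ** 2 + ea[1] ** 2 + ea[2] ** 2)
            if r_a == 0.0:
                continue
            cos_a = -(ea[0] * an[0] + ea[1] * an[1] + ea[2] * an[2]) / r_a
            if cos_a <= 0.0:
                continue
            a_hat0 = -ea[0] / r_a       # opposing photon direction
            a_hat1 = -ea[1] / r_a
            a_hat2 = -ea[2] / r_a
            eps_a = face_area * cos_a / (4.0 * np.pi * r_a * r_a)
            tau_ae = tau_e[ei, a]
            a_hat = np.empty(3)
            a_hat[0] = a_hat0
            a_hat[1] = a_hat1
            a_hat[2] = a_hat2
            npat = _collect_patches(mu, z0, y0, x0, dz, dy, dx,
                                    e, a_hat, patch_thresh, max_range,
                                    pat_vox, pat_len, pat_dep)
            for si in range(npat):
                pid = patch_of_voxel[pat_vox[si]]
                if pid < 0:
                    continue
                flat = pat_vox[si]
                mu_s = mu.ravel()[flat]
                p_s = w * eps_a * np.exp(-(tau_ae + pat_dep[si] / 10.0)) * \
                    (1.0 - np.exp(-mu_s * pat_len[si] / 10.0))
                sz = patch_pos[pid, 0]
                sy = patch_pos[pid, 1]
                sx = patch_pos[pid, 2]
                for k in range(g0, g1):
                    b = node_bdet[k]
                    bp = det_pos[b]
                    bn = det_norm[b]
                    sb0 = bp[0] - sz
                    sb1 = bp[1] - sy
                    sb2 = bp[2] - sx
                    r_b = np.sqrt(sb0 * sb0 + sb1 * sb1 + sb2 * sb2)
                    if r_b == 0.0:
                        continue
                    s_hat0 = sb0 / r_b
                    s_hat1 = sb1 / r_b
                    s_hat2 = sb2 / r_b
                    cos_t = a_hat0 * s_hat0 + a_hat1 * s_hat1 + \
                        a_hat2 * s_hat2
                    if cos_t < -1.0:
                        cos_t = -1.0
                    if cos_t > 1.0:
                        cos_t = 1.0
                    cos_b = -(s_hat0 * bn[0] + s_hat1 * bn[1] +
                              s_hat2 * bn[2])
                    if cos_b <= 0.0:
                        continue
                    dsdo, eratio = _kn_diff_nb(cos_t)
                    omega_b = face_area * cos_b / (r_b * r_b)
                    c_b = _kn_total_nb(eratio) / sigma_e
                    out[node_out[k]] += p_s * (omega_b / sigma_e) * dsdo * \
                        np.exp(-c_b * tau_p[pid, b])


# ---------------------------------------------------------------------------
# sparse sinogram structure and the VSM driver
# ---------------------------------------------------------------------------

@dataclass
class SparseScatterSinogram:
    """Scatter values on a regular sparse node grid.

    ``values[i, j, k, l]`` is the scatter estimate for the plane with ring
    pair ``(ring_nodes[i], ring_nodes[j])`` at transaxial bin
    ``(angle_nodes[k], radial_nodes[l])``; ring pairs outside the
    ring-difference acceptance hold NaN.
    """

    ring_nodes: np.ndarray
    angle_nodes: np.ndarray
    radial_nodes: np.ndarray
    values: np.ndarray
    span: int = 1


def _strided_nodes(n: int, stride: int) -> np.ndarray:
    """Strided 0-based nodes always including the last index."""
    nodes = list(range(0, n, max(int(stride), 1)))
    if nodes[-1] != n - 1:
        nodes.append(n - 1)
    return np.array(nodes, dtype=np.int64)


@dataclass
class ScatterLUT:
    """Precomputed geometry/attenuation tables for one mu-map + sampling.

    ``tau_emission``/``tau_patch`` are unitless optical depths from every
    emission point / scattering-patch centre to every sampled detector;
    ``det_pos``/``det_norm`` give detector-face centres and inward normals
    (geometric efficiencies and solid angles derive from them).
    """

    det_pos: np.ndarray            # (n_det, 3) mm, (z, y, x)
    det_norm: np.ndarray           # (n_det, 3) unit inward normals
    det_tx: np.ndarray             # (n_det,) transaxial position
    det_ring: np.ndarray           # (n_det,) ring
    em_points: np.ndarray          # (n_em, 3)
    em_values: np.ndarray          # (n_em,)
    patch_pos: np.ndarray          # (n_patch, 3) voxel centres
    patch_of_voxel: np.ndarray     # flat mu-grid -> patch id or -1
    tau_emission: np.ndarray       # (n_em, n_det)
    tau_patch: np.ndarray          # (n_patch, n_det)


def build_scatter_lut(emission_ds: Image3D, mumap_ds: Image3D,
                      geom: ScannerGeometry, cfg: ScatterConfig,
                      rings: np.ndarray) -> ScatterLUT:
    """Assemble the detector tables and optical-depth LUTs."""
    mu = np.ascontiguousarray(mumap_ds.values, dtype=np.float64)
    if np.any(mu < 0):
        raise ScatterError("negative mu values")
    em = emission_ds.values
    thresh = cfg.emission_threshold * em.max() if em.max() > 0 else 0.0
    sel = np.argwhere(em > thresh)
    zc, yc, xc = emission_ds.voxel_centres()
    em_pts = np.stack([zc[sel[:, 0]], yc[sel[:, 1]], xc[sel[:, 2]]], axis=1) \
        if sel.size else np.zeros((0, 3))
    em_vals = em[sel[:, 0], sel[:, 1], sel[:, 2]].astype(np.float64) \
        if sel.size else np.zeros(0)

    # scattering patches: mu voxels above threshold, point = voxel centre
    patch_of_voxel = np.full(mu.size, -1, dtype=np.int64)
    pat_sel = np.argwhere(mu > cfg.scattering_patch_threshold)
    zm, ym, xm = mumap_ds.voxel_centres()
    patch_pos = np.stack([zm[pat_sel[:, 0]], ym[pat_sel[:, 1]],
                          xm[pat_sel[:, 2]]], axis=1) \
        if pat_sel.size else np.zeros((0, 3))
    flat = (pat_sel[:, 0] * mu.shape[1] + pat_sel[:, 1]) * mu.shape[2] + \
        pat_sel[:, 2] if pat_sel.size else np.zeros(0, dtype=np.int64)
    patch_of_voxel[flat] = np.arange(pat_sel.shape[0])

    # sampled detectors: all transaxial positions x sampled rings
    xy = geom.tx_crystal_xy()
    ring_z = geom.ring_z()
    D = geom.n_crystal_positions
    tx_idx = np.tile(np.arange(D), rings.size)
    ring_idx = np.repeat(rings, D)
    det_pos = np.empty((tx_idx.size, 3))
    det_pos[:, 0] = ring_z[ring_idx]
    det_pos[:, 1] = xy[tx_idx, 1]
    det_pos[:, 2] = xy[tx_idx, 0]
    det_norm = np.zeros_like(det_pos)
    rxy = np.hypot(xy[tx_idx, 0], xy[tx_idx, 1])
    det_norm[:, 1] = -xy[tx_idx, 1] / rxy
    det_norm[:, 2] = -xy[tx_idx, 0] / rxy

    (dzm, dym, dxm) = mumap_ds.voxel_size
    (z0m, y0m, x0m) = mumap_ds.origin
    tau_e = _depth_table(mu, z0m, y0m, x0m, dzm, dym, dxm, em_pts, det_pos)
    tau_p = _depth_table(mu, z0m, y0m, x0m, dzm, dym, dxm, patch_pos,
                         det_pos)
    return ScatterLUT(det_pos=det_pos, det_norm=det_norm, det_tx=tx_idx,
                      det_ring=ring_idx, em_points=em_pts, em_values=em_vals,
                      patch_pos=patch_pos, patch_of_voxel=patch_of_voxel,
                      tau_emission=tau_e, tau_patch=tau_p)


def vsm_single_scatter(emission_ds: Image3D, mumap_ds: Image3D,
                       geom: ScannerGeometry, cfg: ScatterConfig,
                       full_sampling: bool = False,
                       lut: ScatterLUT | None = None) -> SparseScatterSinogram:
    """Voxel-driven single-scatter estimate on the sparse node grid.

    ``full_sampling=True`` evaluates every ring pair and every transaxial
    bin (no interpolation needed afterwards) — intended for small
    geometries and validation.
    """
    if full_sampling:
        rings = np.arange(geom.n_rings)
        angles = np.arange(geom.n_angles)
        radials = np.arange(geom.n_radial_bins)
    else:
        rings = _strided_nodes(geom.n_rings, cfg.axial_detector_sampling)
        angles = _strided_nodes(geom.n_angles, cfg.tx_detector_sampling)
        radials = _strided_nodes(geom.n_radial_bins, cfg.tx_detector_sampling)

    values = np.full((rings.size, rings.size, angles.size, radials.size),
                     np.nan)
    mrd = geom.max_ring_diff
    ok_pairs = np.abs(rings[:, None] - rings[None, :]) <= mrd
    values[ok_pairs] = 0.0

    if lut is None:
        lut = build_scatter_lut(emission_ds, mumap_ds, geom, cfg, rings)
    if lut.em_points.shape[0] == 0:
        import warnings
        warnings.warn("no emission voxels above threshold; scatter is zero")
        return SparseScatterSinogram(rings, angles, radials, values)

    mu = np.ascontiguousarray(mumap_ds.values, dtype=np.float64)
    binmap = build_sino_bin_map(geom)
    face_area = geom.crystal_width_tx * geom.ring_pitch  # mm^2
    sigma_e = kn_total(1.0)
    (dzm, dym, dxm) = mumap_ds.voxel_size
    (z0m, y0m, x0m) = mumap_ds.origin
    max_range = 2.0 * geom.ring_diameter + geom.n_rings * geom.ring_pitch

    # node list: (plane(rA,rB), angle, radial); detector table index is
    # ring_slot * D + tx_position
    D = geom.n_crystal_positions
    ring_slot = {int(rv): s for s, rv in enumerate(rings)}
    a_grid, r_grid = np.meshgrid(angles, radials, indexing="ij")
    tx_a = binmap.pair_a[a_grid, r_grid].ravel()
    tx_b = binmap.pair_b[a_grid, r_grid].ravel()
    n_tx = tx_a.size

    node_adet = []
    node_bdet = []
    node_out = []
    out_flat_index = {}
    n_nodes = 0
    pair_list = []
    for i, rA in enumerate(rings):
        for j, rB in enumerate(rings):
            if abs(int(rA) - int(rB)) > mrd:
                continue
            base = n_nodes
            pair_list.append((i, j, base))
            n_nodes += n_tx
            a_det = ring_slot[int(rA)] * D + tx_a
            b_det = ring_slot[int(rB)] * D + tx_b
            outs = base + np.arange(n_tx)
            # both photon role assignments feed the same output node
            node_adet.append(a_det)
            node_bdet.append(b_det)
            node_out.append(outs)
            node_adet.append(b_det)
            node_bdet.append(a_det)
            node_out.append(outs)
    node_adet = np.concatenate(node_adet)
    node_bdet = np.concatenate(node_bdet)
    node_out = np.concatenate(node_out)

    order = np.argsort(node_adet, kind="stable")
    node_adet = node_adet[order]
    node_bdet = np.ascontiguousarray(node_bdet[order])
    node_out = np.ascontiguousarray(node_out[order])
    group_adet, group_start = np.unique(node_adet, return_index=True)
    group_ptr = np.append(group_start, node_adet.size).astype(np.int64)

    out = np.zeros(n_nodes)
    _vsm_kernel(lut.em_points, lut.em_values, mu, z0m, y0m, x0m,
                dzm, dym, dxm, lut.det_pos, lut.det_norm,
                lut.tau_emission, lut.tau_patch, lut.patch_of_voxel,
                lut.patch_pos, group_ptr, group_adet.astype(np.int64),
                node_bdet, node_out, face_area,
                cfg.scattering_patch_threshold, max_range, sigma_e, out)
    for i, j, base in pair_list:
        values[i, j] = out[base:base + n_tx].reshape(angles.size,
                                                     radials.size)
    return SparseScatterSinogram(rings, angles, radials, values)


def interpolate_scatter(sparse: SparseScatterSinogram,
                        geom: ScannerGeometry) -> SinogramSet:
    """Fill the full span-1 sinogram from the sparse node grid.

    Bicubic across (angle, radial) per sampled ring pair, then bilinear
    across the Michelogram (r0, r1); negative overshoot is clipped to 0 and
    node values are reproduced exactly.
    """
    an = sparse.angle_nodes.astype(float)
    rn = sparse.radial_nodes.astype(float)
    if an.size < 4 or rn.size < 4:
        raise ScatterError("need >= 4 transaxial nodes per axis for bicubic")
    na, nr = geom.n_angles, geom.n_radial_bins
    nrings = sparse.ring_nodes.size
    full_tx = np.full((nrings, nrings, na, nr), np.nan)
    aa = np.arange(na, dtype=float)
    rr = np.arange(nr, dtype=float)
    for i in range(nrings):
        for j in range(nrings):
            v = sparse.values[i, j]
            if np.any(np.isnan(v)):
                continue
            spl = RectBivariateSpline(an, rn, v, kx=3, ky=3)
            full_tx[i, j] = spl(aa, rr)

    m1 = build_michelogram(geom, 1)
    out = empty_sinogram(geom, 1)
    nodes = sparse.ring_nodes.astype(float)
    for p in range(m1.n_planes):
        r0, r1 = (float(v) for v in m1.plane_pairs[p][0])
        i1 = int(np.clip(np.searchsorted(nodes, r0, side="right") - 1,
                         0, nodes.size - 2))
        j1 = int(np.clip(np.searchsorted(nodes, r1, side="right") - 1,
                         0, nodes.size - 2))
        fi = (r0 - nodes[i1]) / (nodes[i1 + 1] - nodes[i1])
        fj = (r1 - nodes[j1]) / (nodes[j1 + 1] - nodes[j1])
        acc = np.zeros((na, nr))
        wsum = 0.0
        for di, wi in ((0, 1 - fi), (1, fi)):
            for dj, wj in ((0, 1 - fj), (1, fj)):
                w = wi * wj
                if w == 0.0:
                    continue
                tile = full_tx[i1 + di, j1 + dj]
                if np.any(np.isnan(tile)):
                    continue
                acc += w * tile
                wsum += w
        out.data[p] = acc / wsum if wsum > 0 else 0.0
    np.clip(out.data, 0.0, None, out=out.data)
    return out


def scale_scatter(scatter: SinogramSet, prompts: SinogramSet,
                  randoms: SinogramSet, af: SinogramSet,
                  geom: ScannerGeometry,
                  scatter_axial_norm: np.ndarray | None = None,
                  af_threshold: float = 0.95) -> tuple[SinogramSet, np.ndarray]:
    """WLS scaling of the scatter shape to the prompts, per SSR axial group.

    The mask keeps bins with attenuation factors above ``af_threshold`` —
    rays missing the object, where prompts contain only scatter tails and
    randoms.  One multiplicative factor k per SSR group minimises
    sum w (prompts - randoms - k * scatter)^2 with w = 1/max(prompts, 1),
    evaluated on reduced sinograms: planes of the group and all angles are
    summed first so each fitted bin is count-rich (fitting raw span-1 bins
    with sub-unity counts biases k low through the count-dependent weights).
    k is applied to all planes of the group, then the optional
    scatter-specific axial normalisation factors multiply per plane.

    Returns (scaled scatter sinogram, k per SSR group).
    """
    for s in (prompts, randoms, af):
        if s.span != scatter.span:
            raise ScatterError("span mismatch between scaling inputs")
    if scatter.span != 1:
        raise ScatterError("scaling operates on span-1 sinograms")
    m1 = build_michelogram(geom, 1)
    u_of_plane = np.array([int(p[0].sum()) for p in m1.plane_pairs])
    n_groups = 2 * geom.n_rings - 1
    binmap = build_sino_bin_map(geom)
    active = binmap.active_mask

    ks = np.ones(n_groups)
    out = scatter.copy()
    any_mask = False
    for u in range(n_groups):
        planes = np.flatnonzero(u_of_plane == u)
        if planes.size == 0:
            continue
        # reduce: sum the group's planes, then mask, then sum over angles
        mask2d = (af.data[planes].mean(axis=0) > af_threshold) & active
        if not np.any(mask2d):
            continue
        weight2d = mask2d.astype(float)
        p_red = (prompts.data[planes].sum(axis=0) * weight2d).sum(axis=0)
        r_red = (randoms.data[planes].sum(axis=0) * weight2d).sum(axis=0)
        s_red = (scatter.data[planes].sum(axis=0) * weight2d).sum(axis=0)
        keep = weight2d.sum(axis=0) > 0
        if not np.any(keep):
            continue
        any_mask = True
        if not np.any(s_red[keep] > 0):
            raise ScatterError(
                f"scatter is zero on the scaling mask of SSR group {u}")
        w = 1.0 / np.maximum(p_red[keep], 1.0)
        num = float(np.sum(w * s_red[keep] * (p_red[keep] - r_red[keep])))
        den = float(np.sum(w * s_red[keep] ** 2))
        ks[u] = num / den
        out.data[planes] *= ks[u]
    if not any_mask:
        raise ScatterError("empty scaling mask everywhere — lower the AF "
                           "threshold or check the attenuation factors")
    if scatter_axial_norm is not None:
        out.data *= np.asarray(scatter_axial_norm, dtype=float)[:, None, None]
    return out, ks
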