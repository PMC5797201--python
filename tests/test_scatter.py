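import numpy as np
import pytest

from petquant.geometry import build_michelogram, build_sino_bin_map, \
    toy_geometry
from petquant.projector import centred_image
from petquant.scatter import (R_E_CM, ScatterConfig, ScatterError,
                              SparseScatterSinogram, downsample_image,
                              interpolate_scatter, kn_differential, kn_total,
                              scale_scatter, vsm_single_scatter)
from petquant.sinogram import SinogramSet, empty_sinogram


# ---------------------------------------------------------------------------
# Klein-Nishina
# ---------------------------------------------------------------------------

def test_kn_forward_scatter():
    dsdo, er = kn_differential(1.0)
    assert np.isclose(dsdo, R_E_CM ** 2, rtol=1e-12)
    assert er == 1.0


def test_kn_backscatter():
    dsdo, er = kn_differential(-1.0)
    assert np.isclose(dsdo, (10.0 / 54.0) * R_E_CM ** 2, rtol=1e-12)
    assert np.isclose(er, 1.0 / 3.0)


def test_kn_shape():
    # decreasing from the forward peak to a shallow minimum near 115 deg,
    # then nearly flat (slight rise) towards backscatter
    theta = np.linspace(0, np.pi, 500)
    dsdo, _ = kn_differential(np.cos(theta))
    imin = int(np.argmin(dsdo))
    assert np.all(np.diff(dsdo[:imin]) < 0)
    assert 1.8 < theta[imin] < 2.2
    assert dsdo[-1] < 1.1 * dsdo[imin]
    assert dsdo[0] == dsdo.max()


def test_kn_energy_bookkeeping():
    # energy_ratio * (1 + alpha (1 - cos theta)) == 1 for alpha = 1
    c = np.linspace(-1, 1, 101)
    _, er = kn_differential(c)
    assert np.allclose(er * (1 + (1 - c)), 1.0, rtol=1e-12)


def test_kn_domain_error():
    with pytest.raises(ScatterError):
        kn_differential(1.5)


def test_kn_total_thomson_limit():
    # alpha -> 0 recovers the Thomson cross-section 8 pi r_e^2 / 3
    assert np.isclose(kn_total(1e-8), 8 * np.pi * R_E_CM ** 2 / 3, rtol=1e-6)


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def test_downsample_identity_and_uniform():
    img = centred_image(None, (4, 8, 8), (2.0, 2.0, 2.0))
    img.values[:] = 3.5
    assert np.array_equal(downsample_image(img, 1).values, img.values)
    ds = downsample_image(img, 2)
    assert ds.shape == (2, 4, 4)
    assert np.allclose(ds.values, 3.5)
    assert ds.voxel_size == (4.0, 4.0, 4.0)


def test_downsample_printed_dims():
    # 127 -> 63 axial and 344 -> 172 transaxial at factor 2
    img = centred_image(None, (127, 344, 344), (2.0, 2.0, 2.0))
    ds = downsample_image(img, 2)
    assert ds.shape == (63, 172, 172)
    assert ds.voxel_size == (4.0, 4.0, 4.0)


def test_downsample_preserves_mean_and_activity():
    rng = np.random.default_rng(0)
    img = centred_image(None, (4, 8, 8), (2.0, 2.0, 2.0))
    img.values[:] = rng.random(img.shape)
    ds = downsample_image(img, 2)
    assert np.isclose(ds.values.mean(), img.values.mean())
    assert np.isclose(ds.values.sum() * ds.voxel_volume(),
                      img.values.sum() * img.voxel_volume())


def test_downsample_factor_too_large():
    img = centred_image(None, (2, 8, 8), (2.0, 2.0, 2.0))
    with pytest.raises(ScatterError):
        downsample_image(img, 3)


# ---------------------------------------------------------------------------
# VSM vs brute-force evaluation of the three-equation chain
# ---------------------------------------------------------------------------

def _seg_in_box(p0, p1, lo, hi):
    u = np.asarray(p1, float) - np.asarray(p0, float)
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            if not (lo[ax] <= p0[ax] < hi[ax]):
                return 0.0
        else:
            ta = (lo[ax] - p0[ax]) / u[ax]
            tb = (hi[ax] - p0[ax]) / u[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            tmin = max(tmin, ta)
            tmax = min(tmax, tb)
    return max(0.0, tmax - tmin) * float(np.linalg.norm(u))


def _entry_t(p0, u, lo, hi):
    """Ray parameter at which p0 + t*u enters the box (inf if missed)."""
    tmin, tmax = 0.0, np.inf
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            if not (lo[ax] <= p0[ax] < hi[ax]):
                return np.inf
        else:
            ta = (lo[ax] - p0[ax]) / u[ax]
            tb = (hi[ax] - p0[ax]) / u[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            tmin = max(tmin, ta)
            tmax = min(tmax, tb)
    return tmin if tmin < tmax else np.inf


def _vsm_oracle(geom, emission, mumap, patch_thresh):
    """Direct nested-loop evaluation of the single-scatter chain.

    Integrals are evaluated as per-voxel box-clipped segment lengths —
    independent of the package's incremental voxel traversal.
    """
    mu = mumap.values
    zc, yc, xc = mumap.voxel_centres()
    dz, dy, dx = mumap.voxel_size
    z0, y0, x0 = mumap.origin
    mu_boxes = []
    for iz, iy, ix in np.argwhere(mu > 0):
        lo = np.array([z0 + iz * dz, y0 + iy * dy, x0 + ix * dx])
        mu_boxes.append((mu[iz, iy, ix], lo, lo + [dz, dy, dx],
                         np.array([zc[iz], yc[iy], xc[ix]]),
                         mu[iz, iy, ix] > patch_thresh))

    def depth(p0, p1):
        return sum(m * _seg_in_box(p0, p1, lo, hi)
                   for m, lo, hi, _, _ in mu_boxes) / 10.0

    xy = geom.tx_crystal_xy()
    rz = geom.ring_z()
    bm = build_sino_bin_map(geom)
    m1 = build_michelogram(geom, 1)
    face = geom.crystal_width_tx * geom.ring_pitch
    sig = kn_total(1.0)
    ezc, eyc, exc = emission.voxel_centres()
    em_pts = [(np.array([ezc[i], eyc[j], exc[k]]), emission.values[i, j, k])
              for i, j, k in np.argwhere(emission.values > 0)]

    out = np.zeros((m1.n_planes, geom.n_angles, geom.n_radial_bins))
    for p in range(m1.n_planes):
        r0, r1 = m1.plane_pairs[p][0]
        for a in range(geom.n_angles):
            for r in range(geom.n_radial_bins):
                txA, txB = bm.pair_a[a, r], bm.pair_b[a, r]
                tot = 0.0
                for (tA, rA), (tB, rB) in (((txA, r0), (txB, r1)),
                                           ((txB, r1), (txA, r0))):
                    A = np.array([rz[rA], xy[tA, 1], xy[tA, 0]])
                    B = np.array([rz[rB], xy[tB, 1], xy[tB, 0]])
                    nA = np.array([0.0, -xy[tA, 1], -xy[tA, 0]])
                    nA /= np.linalg.norm(nA)
                    nB = np.array([0.0, -xy[tB, 1], -xy[tB, 0]])
                    nB /= np.linalg.norm(nB)
                    for e_pt, w in em_pts:
                        ea = A - e_pt
                        r_a = np.linalg.norm(ea)
                        cos_a = -ea @ nA / r_a
                        if cos_a <= 0:
                            continue
                        a_hat = -ea / r_a
                        eps_a = face * cos_a / (4 * np.pi * r_a ** 2)
                        far = e_pt + a_hat * 4000.0
                        for mval, lo, hi, s_c, is_patch in mu_boxes:
                            if not is_patch:
                                continue
                            chord = _seg_in_box(e_pt, far, lo, hi)
                            if chord <= 0:
                                continue
                            t_in = _entry_t(e_pt, a_hat, lo, hi)
                            entry = e_pt + a_hat * t_in
                            tau_ae = depth(A, e_pt) + depth(e_pt, entry)
                            p_s = w * eps_a * np.exp(-tau_ae) * \
                                (1 - np.exp(-mval * chord / 10.0))
                            sb = B - s_c
                            r_b = np.linalg.norm(sb)
                            s_hat = sb / r_b
                            cos_t = float(np.clip(a_hat @ s_hat, -1, 1))
                            cos_b = -s_hat @ nB
                            if cos_b <= 0:
                                continue
                            dsdo, er = kn_differential(cos_t)
                            omega = face * cos_b / r_b ** 2
                            c_b = kn_total(er) / sig
                            tot += p_s * (omega / sig) * dsdo * \
                                np.exp(-c_b * depth(s_c, B))
                out[p, a, r] = tot
    return out


@pytest.fixture(scope="module")
def toy2():
    return toy_geometry(n_rings=2, n_blocks_tx=8, crystals_per_block=4)


def _sparse_to_planes(geom, sp):
    m1 = build_michelogram(geom, 1)
    out = np.zeros((m1.n_planes, geom.n_angles, geom.n_radial_bins))
    for i, rA in enumerate(sp.ring_nodes):
        for j, rB in enumerate(sp.ring_nodes):
            pl = m1.plane_index[rA, rB]
            if pl >= 0:
                out[pl] = sp.values[i, j]
    return out


def test_vsm_single_voxel_matches_oracle(toy2):
    em = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    mu = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    em.values[1, 4, 4] = 2.0
    mu.values[1, 4, 2] = 0.1
    cfg = ScatterConfig(emission_threshold=0.0,
                        scattering_patch_threshold=0.01)
    got = _sparse_to_planes(toy2, vsm_single_scatter(em, mu, toy2, cfg,
                                                     full_sampling=True))
    expect = _vsm_oracle(toy2, em, mu, 0.01)
    nz = expect > 0
    assert nz.sum() > 100
    assert np.max(np.abs(got[nz] - expect[nz]) / expect[nz]) < 1e-10
    assert np.all(got[~nz] == 0)
    assert got.max() <= 1.0


def test_vsm_multi_voxel_matches_oracle(toy2):
    em = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    mu = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    em.values[1, 4, 4] = 1.0
    em.values[1, 3, 5] = 0.5
    mu.values[1, 4, 2] = 0.1
    mu.values[1, 3, 3] = 0.08
    mu.values[0, 4, 3] = 0.05
    cfg = ScatterConfig(emission_threshold=0.0,
                        scattering_patch_threshold=0.01)
    got = _sparse_to_planes(toy2, vsm_single_scatter(em, mu, toy2, cfg,
                                                     full_sampling=True))
    expect = _vsm_oracle(toy2, em, mu, 0.01)
    nz = expect > 1e-300
    assert np.max(np.abs(got[nz] - expect[nz]) /
                  np.maximum(expect[nz], 1e-300)) < 1e-8


def test_vsm_zero_mu_gives_zero(toy2):
    em = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    em.values[1, 4, 4] = 1.0
    mu = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    sp = vsm_single_scatter(em, mu, toy2, ScatterConfig(
        emission_threshold=0.0), full_sampling=True)
    assert np.nansum(sp.values) == 0.0


def test_vsm_linear_in_emission(toy2):
    em = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    em.values[1, 4, 4] = 1.0
    mu = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    mu.values[1, 4, 2] = 0.1
    cfg = ScatterConfig(emission_threshold=0.0)
    sp1 = vsm_single_scatter(em, mu, toy2, cfg, full_sampling=True)
    em2 = em.copy_with(2.0 * em.values)
    sp2 = vsm_single_scatter(em2, mu, toy2, cfg, full_sampling=True)
    assert np.allclose(np.nan_to_num(sp2.values),
                       2.0 * np.nan_to_num(sp1.values), rtol=1e-12)


def test_vsm_empty_emission_warns(toy2):
    em = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    mu = centred_image(toy2, (3, 8, 8), (4.0, 4.0, 4.0))
    mu.values[1, 4, 2] = 0.1
    with pytest.warns(UserWarning, match="threshold"):
        sp = vsm_single_scatter(em, mu, toy2, ScatterConfig(),
                                full_sampling=True)
    assert np.nansum(sp.values) == 0.0


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _sparse_grid(geom, stride):
    def nodes(n):
        out = list(range(0, n, stride))
        if out[-1] != n - 1:
            out.append(n - 1)
        return np.array(out)
    return nodes(geom.n_rings), nodes(geom.n_angles), \
        nodes(geom.n_radial_bins)


def test_interpolate_constant(toy8):
    rn, an, radn = _sparse_grid(toy8, 2)
    vals = np.full((rn.size, rn.size, an.size, radn.size), 4.2)
    sp = SparseScatterSinogram(rn, an, radn, vals)
    full = interpolate_scatter(sp, toy8)
    assert np.allclose(full.data, 4.2, rtol=1e-9)


def test_interpolate_smooth_function_stride7(toy8):
    # smooth separable function sampled at stride 7: < 2% relative error
    na, nr, nrg = toy8.n_angles, toy8.n_radial_bins, toy8.n_rings

    def f(r0, r1, a, r):
        # half a period across each axis: smooth relative to the stride
        return (2 + np.sin(np.pi * a / na)) * \
            (2 + np.cos(np.pi * r / nr)) * (1 + 0.1 * (r0 + r1))

    rn, an, radn = _sparse_grid(toy8, 7)
    A, R = np.meshgrid(an, radn, indexing="ij")
    vals = np.empty((rn.size, rn.size, an.size, radn.size))
    for i, r0 in enumerate(rn):
        for j, r1 in enumerate(rn):
            vals[i, j] = f(r0, r1, A, R)
    sp = SparseScatterSinogram(rn, an, radn, vals)
    full = interpolate_scatter(sp, toy8)
    m1 = build_michelogram(toy8, 1)
    aa, rr = np.meshgrid(np.arange(na), np.arange(nr), indexing="ij")
    worst = 0.0
    for p in range(m1.n_planes):
        r0, r1 = m1.plane_pairs[p][0]
        expect = f(r0, r1, aa, rr)
        worst = max(worst, np.max(np.abs(full.data[p] - expect) / expect))
    assert worst < 0.02


def test_interpolate_exact_at_nodes(toy8):
    rng = np.random.default_rng(3)
    rn, an, radn = _sparse_grid(toy8, 3)
    vals = rng.uniform(1.0, 2.0, (rn.size, rn.size, an.size, radn.size))
    sp = SparseScatterSinogram(rn, an, radn, vals)
    full = interpolate_scatter(sp, toy8)
    m1 = build_michelogram(toy8, 1)
    for i, r0 in enumerate(rn):
        for j, r1 in enumerate(rn):
            p = m1.plane_index[r0, r1]
            got = full.data[p][np.ix_(an, radn)]
            assert np.allclose(got, vals[i, j], atol=1e-9)


def test_interpolate_too_sparse(toy8):
    rn = np.array([0, toy8.n_rings - 1])
    an = np.array([0, 10, toy8.n_angles - 1])
    radn = np.array([0, 10, 20, toy8.n_radial_bins - 1])
    vals = np.ones((2, 2, 3, 4))
    with pytest.raises(ScatterError, match="4 transaxial nodes"):
        interpolate_scatter(SparseScatterSinogram(rn, an, radn, vals), toy8)


def test_interpolate_clips_negative(toy8):
    rn, an, radn = _sparse_grid(toy8, 3)
    rng = np.random.default_rng(4)
    vals = rng.uniform(0.0, 1.0, (rn.size, rn.size, an.size, radn.size))
    vals[:, :, ::2, ::2] = 0.0   # force overshoot
    full = interpolate_scatter(SparseScatterSinogram(rn, an, radn, vals),
                               toy8)
    assert np.all(full.data >= 0.0)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def _af_mask_setup(geom, af_val=1.0):
    af = empty_sinogram(geom, 1)
    af.data += af_val
    return af


def test_scale_exact_recovery(toy8):
    rng = np.random.default_rng(5)
    shape = empty_sinogram(toy8, 1)
    shape.data += rng.uniform(0.5, 1.5, shape.data.shape)
    randoms = empty_sinogram(toy8, 1)
    randoms.data += 2.0
    prompts = SinogramSet(randoms.data + 3.0 * shape.data, 1)
    scaled, ks = scale_scatter(shape, prompts, randoms,
                               _af_mask_setup(toy8), toy8)
    assert np.allclose(ks, 3.0, atol=1e-9)
    assert np.allclose(scaled.data, 3.0 * shape.data)


def test_scale_zero_scatter_on_mask(toy8):
    shape = empty_sinogram(toy8, 1)
    prompts = empty_sinogram(toy8, 1)
    prompts.data += 1.0
    with pytest.raises(ScatterError, match="zero"):
        scale_scatter(shape, prompts, prompts, _af_mask_setup(toy8), toy8)


def test_scale_empty_mask(toy8):
    shape = empty_sinogram(toy8, 1)
    shape.data += 1.0
    prompts = shape.copy()
    with pytest.raises(ScatterError, match="mask"):
        scale_scatter(shape, prompts, prompts, _af_mask_setup(toy8, 0.5),
                      toy8)


def test_scale_poisson_recovery(toy8):
    # known k = 1.7 recovered within 0.1 at ~1e6 counts
    rng = np.random.default_rng(6)
    shape2 = empty_sinogram(toy8, 1)
    shape2.data += rng.uniform(2.0, 6.0, shape2.data.shape)
    rnd = empty_sinogram(toy8, 1)
    rnd.data += 3.0
    lam = rnd.data + 1.7 * shape2.data
    c = 1e6 / lam.sum()
    shape2.data *= c
    rnd.data *= c
    prompts = SinogramSet(
        rng.poisson(rnd.data + 1.7 * shape2.data).astype(float), 1)
    scaled, ks = scale_scatter(shape2, prompts, rnd, _af_mask_setup(toy8),
                               toy8)
    k_glob = scaled.total() / shape2.total()
    assert abs(k_glob - 1.7) < 0.1


def test_scale_applies_axial_norm(toy8):
    shape = empty_sinogram(toy8, 1)
    shape.data += 1.0
    randoms = empty_sinogram(toy8, 1)
    prompts = SinogramSet(2.0 * shape.data, 1)
    fac = np.linspace(1.0, 2.0, shape.n_planes)
    scaled, ks = scale_scatter(shape, prompts, randoms,
                               _af_mask_setup(toy8), toy8,
                               scatter_axial_norm=fac)
    assert np.allclose(scaled.data, 2.0 * fac[:, None, None])
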