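"""Per-bin normalisation factor sinograms from component tables.

Components are multiplicative detection-sensitivity factors applied on the
model side of the reconstruction (the forward model is multiplied by them),
so a dead crystal position carries efficiency 0 and the bins it touches get
factor 0.  Dead time enters as a rate-dependent factor >= 1 per bucket.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (SSR, ScannerGeometry, build_michelogram,
                       build_sino_bin_map, count_sinograms, span_group_map)
from .sinogram import SinogramSet, empty_sinogram, reduce_to_ssr

__all__ = [
    "NormComponents",
    "decode_span1_axial",
    "deadtime_factor",
    "build_norm_sinogram",
    "scatter_axial_factors",
    "read_norm_components",
    "write_norm_components",
]


class NormalisationError(ValueError):
    pass


@dataclass
class NormComponents:
    """Component tables for one scanner geometry.

    geometric              (n_radial,) — replicated over all angles
    crystal_interference   (n_radial, positions_per_block)
    crystal_efficiencies   (n_tx_positions, n_rings); dead positions = 0
    axial_factors_spanS    per span-S plane (vendor-style table); span in
                           ``axial_span``
    axial_factors_span1    per span-1 plane (decoded), optional
    scatter_axial_factors  per plane, optional
    deadtime_params        (n_buckets, 2): [tau_paralysable, tau_nonpar] (s)
    """

    geometric: np.ndarray | None = None
    crystal_interference: np.ndarray | None = None
    crystal_efficiencies: np.ndarray | None = None
    axial_factors_spanS: np.ndarray | None = None
    axial_span: int = 11
    axial_factors_span1: np.ndarray | None = None
    scatter_axial_factors: np.ndarray | None = None
    deadtime_params: np.ndarray | None = None

    def require(self, *names: str):
        for name in names:
            if getattr(self, name) is None:
                raise NormalisationError(f"missing component: {name}")
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise NormalisationError(
                    f"component {name} must be finite and >= 0")


# ---------------------------------------------------------------------------

def decode_span1_axial(eps_spanS: np.ndarray, prompts_span1: SinogramSet,
                       prompts_spanS: SinogramSet,
                       geom: ScannerGeometry, span: int = 11) -> np.ndarray:
    """Decode span-1 axial factors from span-S factors and phantom prompts.

    eps1[p] = N_p * epsS[group(p)] * P1[p] / PS[group(p)], with N_p the
    number of span-1 planes in the span-S group containing plane p and P the
    plane-summed prompt counts of a high-statistics uniform acquisition.
    """
    if prompts_span1.span != 1 or prompts_spanS.span != span:
        raise NormalisationError("prompt sinogram spans do not match request")
    gmap = span_group_map(geom, span)
    n1 = count_sinograms(geom, 1)
    eps_spanS = np.asarray(eps_spanS, dtype=float)
    if eps_spanS.shape[0] != count_sinograms(geom, span):
        raise NormalisationError("axial factor table length mismatch")
    p1 = prompts_span1.data.reshape(n1, -1).sum(axis=1)
    ps = prompts_spanS.data.reshape(eps_spanS.shape[0], -1).sum(axis=1)
    zero = np.flatnonzero(p1 <= 0)
    if zero.size:
        raise NormalisationError(
            f"zero-count span-1 plane(s) {zero[:8].tolist()} — "
            "need a higher-statistics acquisition")
    if np.any(ps[gmap] <= 0):
        raise NormalisationError("zero-count span-S group")
    n_uv = np.bincount(gmap, minlength=eps_spanS.shape[0]).astype(float)
    return n_uv[gmap] * eps_spanS[gmap] * p1 / ps[gmap]


def deadtime_factor(singles_rate, params) -> np.ndarray:
    """Combined paralysable/non-paralysable dead-time factor (>= 1).

    For measured rate n and bucket parameters (tau_p, tau_n) the live-time
    fractions are exp(-n*tau_p) and 1/(1 + n*tau_n); the correction factor is
    their inverse product: exp(n*tau_p) * (1 + n*tau_n).
    """
    n = np.asarray(singles_rate, dtype=float)
    if np.any(n < 0):
        raise NormalisationError("negative singles rate")
    params = np.asarray(params, dtype=float)
    tau_p = params[..., 0]
    tau_n = params[..., 1]
    return np.exp(n * tau_p) * (1.0 + n * tau_n)


def build_norm_sinogram(components: NormComponents,
                        bucket_singles: np.ndarray | None,
                        frame, geom: ScannerGeometry) -> SinogramSet:
    """Span-1 factor sinogram combining all components for one time frame.

    Per-bin factor = geometric(radial) x interference(radial, in-block pos
    of crystal A) x eff(A) x eff(B) x axial(plane) x deadtime(bucket A) x
    deadtime(bucket B); dead-time rates are frame-averaged.  Bins touching a
    dead position come out 0 through the zero efficiencies.
    """
    components.require("geometric", "crystal_interference",
                       "crystal_efficiencies")
    g = np.asarray(components.geometric, dtype=float)
    itf = np.asarray(components.crystal_interference, dtype=float)
    eff = np.asarray(components.crystal_efficiencies, dtype=float)
    if g.shape != (geom.n_radial_bins,):
        raise NormalisationError("geometric component shape mismatch")
    if itf.shape != (geom.n_radial_bins, geom.positions_per_block):
        raise NormalisationError("crystal_interference shape mismatch")
    if eff.shape != (geom.n_crystal_positions, geom.n_rings):
        raise NormalisationError("crystal_efficiencies shape mismatch")
    live = geom.live_mask_tx()
    if np.any(eff[~live, :] != 0):
        raise NormalisationError("dead positions must have efficiency 0")

    if components.axial_factors_span1 is not None:
        axial = np.asarray(components.axial_factors_span1, dtype=float)
    else:
        axial = np.ones(count_sinograms(geom, 1))
    if axial.shape[0] != count_sinograms(geom, 1):
        raise NormalisationError("axial factor length mismatch (span-1)")

    # frame-averaged dead-time factor per bucket
    if components.deadtime_params is not None and bucket_singles is not None:
        bs = np.asarray(bucket_singles, dtype=float)
        t0, t1 = frame
        s0, s1 = int(t0 // 1000), max(int(np.ceil(t1 / 1000.0)), 1)
        s1 = min(s1, bs.shape[0])
        rates = bs[s0:s1].mean(axis=0) if s1 > s0 else np.zeros(bs.shape[1])
        dt = deadtime_factor(rates, components.deadtime_params)
    else:
        dt = np.ones(geom.n_buckets)

    binmap = build_sino_bin_map(geom)
    m1 = build_michelogram(geom, 1)
    pa = binmap.pair_a
    pb = binmap.pair_b
    ppb = geom.positions_per_block
    tx_part = (g[None, :] * itf[np.arange(geom.n_radial_bins)[None, :],
                                (pa % ppb)])
    r0 = np.array([p[0, 0] for p in m1.plane_pairs])
    r1 = np.array([p[0, 1] for p in m1.plane_pairs])

    out = empty_sinogram(geom, 1)
    # bucket of each (position, ring) pair
    for p in range(m1.n_planes):
        eff_a = eff[pa, r0[p]]
        eff_b = eff[pb, r1[p]]
        dt_a = dt[geom.bucket_of(pa, np.full_like(pa, r0[p]))]
        dt_b = dt[geom.bucket_of(pb, np.full_like(pb, r1[p]))]
        out.data[p] = axial[p] * tx_part * eff_a * eff_b * dt_a * dt_b
    out.data[:, ~binmap.active_mask] = 0.0
    return out


def scatter_axial_factors(ssr_scatter_ref: SinogramSet,
                          spanS_scatter_ref: SinogramSet,
                          geom: ScannerGeometry) -> np.ndarray:
    """Per-plane factors aligning span data with its SSR axial profile.

    The SSR reference predicts each plane's share of its rebinned group; the
    factor is predicted / observed per plane so that factor-corrected data
    reproduce the SSR-consistent axial profile.
    """
    span = spanS_scatter_ref.span
    if ssr_scatter_ref.span != SSR:
        raise NormalisationError("first argument must be SSR data")
    m = build_michelogram(geom, span)
    ssr_tot = ssr_scatter_ref.data.reshape(2 * geom.n_rings - 1, -1).sum(axis=1)
    obs = spanS_scatter_ref.data.reshape(m.n_planes, -1).sum(axis=1)
    # SSR group of each plane and group multiplicities
    u_of_plane = np.array([int(round(np.mean(p.sum(axis=1))))
                           for p in m.plane_pairs])
    mult = np.bincount(u_of_plane, minlength=2 * geom.n_rings - 1).astype(float)
    pred = ssr_tot[u_of_plane] / mult[u_of_plane]
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise NormalisationError("zero plane totals in scatter reference")
    return pred / obs


# ---------------------------------------------------------------------------
# component container I/O: JSON manifest + flat binary arrays
# ---------------------------------------------------------------------------

_FIELDS = ("geometric", "crystal_interference", "crystal_efficiencies",
           "axial_factors_spanS", "axial_factors_span1",
           "scatter_axial_factors", "deadtime_params")


def write_norm_components(comp: NormComponents, path,
                          geometry_hash: str = "") -> None:
    path = Path(path)
    manifest = {"format": "petquant-norm", "version": 1,
                "geometry_hash": geometry_hash,
                "axial_span": comp.axial_span, "arrays": {}}
    payload = b""
    offset = 0
    for name in _FIELDS:
        arr = getattr(comp, name)
        if arr is None:
            continue
        arr = np.ascontiguousarray(np.asarray(arr, dtype="<f8"))
        manifest["arrays"][name] = {"shape": list(arr.shape),
                                    "dtype": "<f8", "offset": offset}
        payload += arr.tobytes()
        offset += arr.nbytes
    path.write_bytes(payload)
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=1))


def read_norm_components(path, expected_hash: str | None = None
                         ) -> NormComponents:
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".json").read_text())
    if manifest.get("format") != "petquant-norm":
        raise NormalisationError("not a normalisation component file")
    if expected_hash is not None and manifest.get("geometry_hash") and \
            manifest["geometry_hash"] != expected_hash:
        raise NormalisationError("geometry hash mismatch")
    raw = path.read_bytes()
    kwargs = {"axial_span": manifest.get("axial_span", 11)}
    for name, meta in manifest["arrays"].items():
        shape = tuple(meta["shape"])
        n = int(np.prod(shape))
        arr = np.frombuffer(raw, dtype=meta["dtype"], count=n,
                            offset=meta["offset"]).reshape(shape)
        kwargs[name] = arr.copy()
    return NormComponents(**kwargs)
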