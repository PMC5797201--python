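"""Reduced-variance random-event estimation.

Crystal singles rates are recovered from delayed-coincidence fan sums by a
fixed-point maximum-likelihood iteration; the expected randoms rate of a
crystal pair is then ``2 tau S_i S_j`` and the randoms sinogram follows by
mapping pairs to bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScannerGeometry, build_michelogram, build_sino_bin_map
from .sinogram import SinogramSet, empty_sinogram, reduce_span

__all__ = ["SinglesEstimate", "estimate_singles", "randoms_sinogram"]


class RandomsError(ValueError):
    pass


@dataclass
class SinglesEstimate:
    """Estimated singles rate per crystal (counts/s)."""

    S: np.ndarray                # (n_tx_positions, n_rings)
    tau: float
    iterations: int
    fansum_residual: float       # max relative fan-sum mismatch at the end
    note: str = ""


def _fan_structures(geom: ScannerGeometry):
    """Transaxial fan matrix and axial band for fan-sum evaluation.

    Crystal j is in the fan of i iff the transaxial pair falls inside the
    radial acceptance with both positions live, and |ring_i - ring_j| is
    within the maximum ring difference.
    """
    binmap = build_sino_bin_map(geom)
    D = geom.n_crystal_positions
    live = geom.live_mask_tx()
    tx_fan = binmap.pair_to_bin >= 0
    tx_fan &= live[:, None] & live[None, :]
    nr = geom.n_rings
    ax_band = np.zeros((nr, nr), dtype=bool)
    rr = np.arange(nr)
    ax_band[np.abs(rr[:, None] - rr[None, :]) <= geom.max_ring_diff] = True
    return tx_fan.astype(float), ax_band.astype(float)


def fan_sum_of_rates(S: np.ndarray, geom: ScannerGeometry) -> np.ndarray:
    """sum_{j in J_i} S_j for every crystal i, shape (n_tx, n_rings)."""
    tx_fan, ax_band = _fan_structures(geom)
    return tx_fan @ (S @ ax_band.T)


def estimate_singles(delayed_fansums: np.ndarray, geom: ScannerGeometry,
                     tau: float, acq_time: float, n_iter: int = 10,
                     init: np.ndarray | None = None,
                     tol: float = 1e-7) -> SinglesEstimate:
    """ML fixed point S_i <- S_i/2 + (sum_j d_ij) / (2 sum_j 2 tau S_j).

    ``delayed_fansums`` are per-crystal delayed counts over ``acq_time``
    seconds (each delayed event contributing to both its crystals); rates are
    handled per unit time internally.  Iterates until the relative update
    drops below ``tol`` or ``n_iter`` is reached.
    """
    d = np.asarray(delayed_fansums, dtype=float)
    if d.shape != (geom.n_crystal_positions, geom.n_rings):
        raise RandomsError("fan-sum array shape mismatch")
    if np.any(d < 0):
        raise RandomsError("negative fan sums")
    if tau <= 0 or acq_time <= 0:
        raise RandomsError("tau and acq_time must be positive")
    d_rate = d / acq_time

    tx_fan, ax_band = _fan_structures(geom)
    live = geom.live_mask_tx()
    fan_size = (tx_fan.sum(axis=1)[:, None] * ax_band.sum(axis=1)[None, :])

    if not np.any(d_rate > 0):
        return SinglesEstimate(np.zeros_like(d_rate), tau, 0, 0.0,
                               note="all-zero fan sums")

    if init is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.sqrt(d_rate / np.maximum(2.0 * tau * fan_size, 1e-300))
        S[fan_size == 0] = 0.0
        S[S == 0] = max(S.max() * 1e-3, 1e-12)
    else:
        S = np.asarray(init, dtype=float).copy()
    S[~live, :] = 0.0

    it = 0
    for it in range(1, n_iter + 1):
        denom = 2.0 * tau * (tx_fan @ (S @ ax_band.T))
        bad = (denom <= 0) & (d_rate > 0)
        if np.any(bad):
            raise RandomsError("zero fan-sum denominator with nonzero data")
        with np.errstate(divide="ignore", invalid="ignore"):
            upd = np.where(denom > 0, d_rate / np.maximum(denom, 1e-300), 0.0)
        S_new = 0.5 * S + 0.5 * upd
        S_new[~live, :] = 0.0
        delta = np.max(np.abs(S_new - S) / np.maximum(S, 1e-300))
        S = S_new
        if delta < tol:
            break

    model = 2.0 * tau * S * (tx_fan @ (S @ ax_band.T))
    mask = d_rate > 0
    resid = float(np.max(np.abs(model[mask] - d_rate[mask]) / d_rate[mask])) \
        if np.any(mask) else 0.0
    return SinglesEstimate(S, tau, it, resid)


def randoms_sinogram(est: SinglesEstimate, geom: ScannerGeometry,
                     frame_duration: float, span=1) -> SinogramSet:
    """Expected randoms counts per bin: 2 tau S_i S_j * duration (span-1)."""
    S = est.S
    binmap = build_sino_bin_map(geom)
    m1 = build_michelogram(geom, 1)
    pa, pb = binmap.pair_a, binmap.pair_b
    out = empty_sinogram(geom, 1)
    for p in range(m1.n_planes):
        r0, r1 = m1.plane_pairs[p][0]
        out.data[p] = 2.0 * est.tau * S[pa, r0] * S[pb, r1] * frame_duration
    out.data[:, ~binmap.active_mask] = 0.0
    if span != 1:
        out = reduce_span(out, geom, span)
    return out
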