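"""Cylindrical PET scanner geometry and sinogram index algebra.

All other modules consume the index mappings defined here:

* transaxial: crystal-position pairs <-> interleaved (angle, radial) sinogram
  bins, with dead (gap) positions tracked per detector block;
* axial: ring pairs <-> span-1 / span-S / SSR sinogram planes organised in a
  segment-major Michelogram ordering.

Conventions (fixed so that sinogram files are bit-reproducible):

* 0-based indices everywhere;
* plane ordering is segment-major (0, +1, -1, +2, -2, ...), within a segment
  ordered by ``r0 + r1``;
* the interleaved transaxial binning places the two crystal pairs of
  neighbouring parity into alternate radial rows of the same angle, with the
  radial window of ``n_radial_bins`` centred on the FOV;
* one dead crystal position per ``gaps_per_block`` sits at a fixed in-block
  offset (``gap_offset``, default: last position of the block).  The offset is
  a calibration choice: with the interleave above, the 64-ring full-size
  preset yields exactly 68516 live transaxial bins for any offset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np

__all__ = [
    "SSR",
    "ScannerGeometry",
    "MichelogramMap",
    "SinoBinMap",
    "Segment",
    "build_geometry",
    "mmr_preset",
    "mmr_reduced",
    "toy_geometry",
    "count_sinograms",
    "segment_table",
    "build_michelogram",
    "build_sino_bin_map",
    "ssr_plane",
]

#: sentinel for single-slice rebinning "span"
SSR = "ssr"


class GeometryError(ValueError):
    """Inconsistent or unsupported geometry description."""


def _parse_span(span) -> int | str:
    if isinstance(span, str):
        if span.lower() == SSR:
            return SSR
        span = int(span)
    span = int(span)
    if span < 1 or span % 2 == 0:
        raise GeometryError(f"span must be odd or 'ssr', got {span}")
    return span


@dataclass(frozen=True)
class ScannerGeometry:
    """Full combinatorial description of a cylindrical scanner.

    Units: distances in mm, ``coincidence_window_tau`` in seconds.
    """

    n_rings: int
    ring_pitch: float
    ring_diameter: float
    n_blocks_tx: int
    crystals_per_block: int
    gaps_per_block: int
    n_radial_bins: int
    max_ring_diff: int
    span: int | str = 1
    buckets_axial: int = 1
    buckets_tx: int = 1
    coincidence_window_tau: float = 2.93e-9
    gap_offset: int = -1  # -1 -> last position in block

    def __post_init__(self):
        for name in ("n_rings", "n_blocks_tx", "crystals_per_block",
                     "n_radial_bins", "buckets_axial", "buckets_tx"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.gaps_per_block < 0:
            raise GeometryError("gaps_per_block must be >= 0")
        if self.n_crystal_positions != self.n_angles * 2:
            raise GeometryError(
                "n_angles x 2 != n_crystal_positions "
                f"({self.n_angles * 2} != {self.n_crystal_positions})")
        if not (0 <= self.max_ring_diff <= self.n_rings - 1):
            raise GeometryError("max_ring_diff must be in [0, n_rings-1]")
        if self.n_radial_bins > self.n_crystal_positions:
            raise GeometryError("n_radial_bins exceeds crystal positions")
        object.__setattr__(self, "span", _parse_span(self.span))

    # -- derived counts -----------------------------------------------------
    @property
    def positions_per_block(self) -> int:
        return self.crystals_per_block + self.gaps_per_block

    @property
    def n_crystal_positions(self) -> int:
        return self.n_blocks_tx * self.positions_per_block

    @property
    def n_angles(self) -> int:
        return self.n_crystal_positions // 2

    @property
    def n_buckets(self) -> int:
        return self.buckets_axial * self.buckets_tx

    @property
    def n_crystals(self) -> int:
        """Total crystal positions over all rings (incl. dead positions)."""
        return self.n_crystal_positions * self.n_rings

    # -- dead-position layout ----------------------------------------------
    @property
    def dead_offsets(self) -> tuple[int, ...]:
        if self.gaps_per_block == 0:
            return ()
        base = self.gap_offset
        if base < 0:
            base = self.positions_per_block - self.gaps_per_block
        return tuple((base + i) % self.positions_per_block
                     for i in range(self.gaps_per_block))

    def live_mask_tx(self) -> np.ndarray:
        """Boolean (n_crystal_positions,) — True for live positions."""
        mask = np.ones(self.n_crystal_positions, dtype=bool)
        ppb = self.positions_per_block
        for off in self.dead_offsets:
            mask[np.arange(self.n_blocks_tx) * ppb + off] = False
        return mask

    # -- physical coordinates ----------------------------------------------
    def tx_crystal_xy(self) -> np.ndarray:
        """(n_crystal_positions, 2) crystal-face centres in mm (iso-centred)."""
        d = np.arange(self.n_crystal_positions)
        phi = 2.0 * np.pi * (d + 0.5) / self.n_crystal_positions
        r = 0.5 * self.ring_diameter
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)

    def ring_z(self) -> np.ndarray:
        """(n_rings,) axial centres in mm, centred on the iso-centre."""
        r = np.arange(self.n_rings)
        return (r - (self.n_rings - 1) / 2.0) * self.ring_pitch

    @property
    def crystal_width_tx(self) -> float:
        """Arc-length pitch of one crystal position (mm)."""
        return np.pi * self.ring_diameter / self.n_crystal_positions

    # -- buckets ------------------------------------------------------------
    def bucket_of(self, tx_pos: np.ndarray, ring: np.ndarray) -> np.ndarray:
        """Bucket id = axial_bucket * buckets_tx + transaxial_bucket."""
        blocks_per_bucket = max(1, self.n_blocks_tx // self.buckets_tx)
        rings_per_bucket = max(1, -(-self.n_rings // self.buckets_axial))
        btx = np.minimum(np.asarray(tx_pos) // self.positions_per_block
                         // blocks_per_bucket, self.buckets_tx - 1)
        bax = np.minimum(np.asarray(ring) // rings_per_bucket,
                         self.buckets_axial - 1)
        return bax * self.buckets_tx + btx

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# presets and construction
# ---------------------------------------------------------------------------

_MMR = dict(
    n_rings=64,
    ring_pitch=4.0625,
    ring_diameter=656.0,
    n_blocks_tx=56,
    crystals_per_block=8,
    gaps_per_block=1,
    n_radial_bins=344,
    max_ring_diff=60,
    buckets_axial=8,
    buckets_tx=28,
)


def mmr_preset(**overrides) -> ScannerGeometry:
    """64-ring full-size preset (504 positions, 252 angles, 344 radial)."""
    cfg = dict(_MMR)
    cfg.update(overrides)
    return ScannerGeometry(**cfg)


def mmr_reduced(n_rings: int, **overrides) -> ScannerGeometry:
    """Contiguous ring subset of the full-size preset."""
    if not 1 <= n_rings <= 64:
        raise GeometryError("reduced preset needs 1 <= n_rings <= 64")
    cfg = dict(_MMR)
    cfg["n_rings"] = n_rings
    cfg["max_ring_diff"] = min(60, n_rings - 1)
    cfg["buckets_axial"] = max(1, round(8 * n_rings / 64))
    cfg.update(overrides)
    return ScannerGeometry(**cfg)


def toy_geometry(n_rings: int = 4, n_blocks_tx: int = 16,
                 crystals_per_block: int = 4, gaps_per_block: int = 0,
                 **overrides) -> ScannerGeometry:
    """Small scanner for fast tests; FOV scaled with crystal count."""
    npos = n_blocks_tx * (crystals_per_block + gaps_per_block)
    cfg = dict(
        n_rings=n_rings,
        ring_pitch=4.0,
        ring_diameter=npos * 656.0 / 504.0,
        n_blocks_tx=n_blocks_tx,
        crystals_per_block=crystals_per_block,
        gaps_per_block=gaps_per_block,
        n_radial_bins=2 * ((npos * 344 // 504) // 2),
        max_ring_diff=n_rings - 1,
        buckets_axial=max(1, n_rings // 4),
        buckets_tx=max(1, n_blocks_tx // 2),
    )
    cfg.update(overrides)
    return ScannerGeometry(**cfg)


_PRESETS = {"mmr": mmr_preset, "toy": toy_geometry}


def build_geometry(config: dict | str | ScannerGeometry) -> ScannerGeometry:
    """Build and validate a geometry from a config dict or preset name.

    Preset names: ``"mmr"`` and ``"mmr-reduced:<n_rings>"``.
    """
    if isinstance(config, ScannerGeometry):
        return config
    if isinstance(config, str):
        name = config.lower()
        if name in _PRESETS:
            return _PRESETS[name]()
        if name.startswith("mmr-reduced:"):
            return mmr_reduced(int(name.split(":", 1)[1]))
        raise GeometryError(f"unknown geometry preset {config!r}")
    cfg = dict(config)
    preset = cfg.pop("preset", None)
    if preset is not None:
        return replace(build_geometry(preset), **cfg)
    return ScannerGeometry(**cfg)


# ---------------------------------------------------------------------------
# axial algebra: segments, Michelogram, spans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One signed band of ring differences."""
    seg_id: int       # 0, +1, -1, +2, -2, ...
    d_min: int        # smallest |ring difference| in the band
    d_max: int        # largest |ring difference| in the band
    n_planes: int


def segment_table(geom: ScannerGeometry, span=None) -> list[Segment]:
    """Ordered segments (0, +1, -1, ...) with per-segment plane counts.

    For span-S, segment 0 covers |RD| <= (S-1)/2 and segment +-k the next S
    ring differences, clipped at ``max_ring_diff``; the per-segment plane
    count is ``2*n_rings - 1 - 2*d_min`` (one plane per value of ``r0+r1``).
    When a segment holds a single ring difference (span-1, or a clipped last
    segment), ``r0+r1`` steps by 2 and the count is ``n_rings - d_min``.
    For SSR there is a single segment.
    """
    span = _parse_span(geom.span if span is None else span)
    n, mrd = geom.n_rings, geom.max_ring_diff

    def planes_in_band(d_min, d_max):
        if d_min == d_max:
            return n - d_min          # single RD: r0+r1 has one parity
        return 2 * n - 1 - 2 * d_min

    if span == SSR:
        return [Segment(0, 0, mrd, 2 * n - 1)]
    half = (span - 1) // 2
    segs = [Segment(0, 0, min(half, mrd), planes_in_band(0, min(half, mrd)))]
    k = 1
    while half + (k - 1) * span + 1 <= mrd:
        d_min = half + (k - 1) * span + 1
        d_max = min(half + k * span, mrd)
        n_pl = planes_in_band(d_min, d_max)
        if n_pl <= 0:
            break
        segs.append(Segment(+k, d_min, d_max, n_pl))
        segs.append(Segment(-k, d_min, d_max, n_pl))
        k += 1
    return segs


def count_sinograms(geom: ScannerGeometry, span=None) -> int:
    """Number of axial planes for the given span (span-1 / span-S / SSR)."""
    span = _parse_span(geom.span if span is None else span)
    if span == SSR:
        return 2 * geom.n_rings - 1
    if span == 1:
        # all (r0, r1) with |r1-r0| <= max_ring_diff
        n, d = geom.n_rings, geom.max_ring_diff
        return n + 2 * sum(n - k for k in range(1, d + 1))
    return sum(s.n_planes for s in segment_table(geom, span))


def ssr_plane(geom: ScannerGeometry, r0, r1):
    """SSR plane id = r0 + r1 (0-based, range 0 .. 2*n_rings-2)."""
    r0 = np.asarray(r0)
    r1 = np.asarray(r1)
    if np.any((r0 < 0) | (r0 >= geom.n_rings) | (r1 < 0) | (r1 >= geom.n_rings)):
        raise GeometryError("ring index out of range")
    if np.any(np.abs(r1 - r0) > geom.max_ring_diff):
        raise GeometryError("ring difference exceeds max_ring_diff")
    out = r0 + r1
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MichelogramMap:
    """Ring-pair <-> plane mappings for one span.

    ``plane_index[r0, r1]`` is the plane id (or -1 outside the ring-difference
    acceptance); ``plane_pairs[p]`` lists the contributing ``(r0, r1)`` ring
    pairs of plane ``p``; ``segment_of_plane[p]`` is the signed segment id.
    """
    span: int | str
    n_planes: int
    plane_index: np.ndarray           # (n_rings, n_rings) int32
    segment_of_plane: np.ndarray      # (n_planes,) int32
    plane_pairs: tuple                # tuple of (K,2) int arrays

    def group_sizes(self) -> np.ndarray:
        """Number of span-1 ring pairs per plane (N_uv of the span grouping)."""
        return np.array([len(p) for p in self.plane_pairs])


def build_michelogram(geom: ScannerGeometry, span=None) -> MichelogramMap:
    span = _parse_span(geom.span if span is None else span)
    n = geom.n_rings
    plane_index = np.full((n, n), -1, dtype=np.int32)
    seg_ids: list[int] = []
    pairs: list[list[tuple[int, int]]] = []

    if span == SSR:
        for u in range(2 * n - 1):
            seg_ids.append(0)
            pairs.append([])
        for r0 in range(n):
            for r1 in range(n):
                if abs(r1 - r0) <= geom.max_ring_diff:
                    plane_index[r0, r1] = r0 + r1
                    pairs[r0 + r1].append((r0, r1))
    else:
        plane = 0
        for seg in segment_table(geom, span):
            # signed ring-difference band of this segment
            if seg.seg_id == 0:
                rds = range(-seg.d_max, seg.d_max + 1)
            elif seg.seg_id > 0:
                rds = range(seg.d_min, seg.d_max + 1)
            else:
                rds = range(-seg.d_max, -seg.d_min + 1)
            u_min = seg.d_min
            u_step = 2 if seg.d_min == seg.d_max else 1
            for i in range(seg.n_planes):
                seg_ids.append(seg.seg_id)
                pairs.append([])
            for rd in rds:
                for r0 in range(n):
                    r1 = r0 + rd
                    if not (0 <= r1 < n):
                        continue
                    u = r0 + r1
                    pid = plane + (u - u_min) // u_step
                    plane_index[r0, r1] = pid
                    pairs[pid].append((r0, r1))
            plane += seg.n_planes

    plane_pairs = tuple(np.array(sorted(p), dtype=np.int32).reshape(-1, 2)
                        for p in pairs)
    return MichelogramMap(span=span, n_planes=len(seg_ids),
                          plane_index=plane_index,
                          segment_of_plane=np.array(seg_ids, dtype=np.int32),
                          plane_pairs=plane_pairs)


def span_group_map(geom: ScannerGeometry, span) -> np.ndarray:
    """(n_span1_planes,) span-S plane id for every span-1 plane."""
    m1 = build_michelogram(geom, 1)
    ms = build_michelogram(geom, span)
    out = np.empty(m1.n_planes, dtype=np.int32)
    for p in range(m1.n_planes):
        r0, r1 = m1.plane_pairs[p][0]
        out[p] = ms.plane_index[r0, r1]
    return out


# ---------------------------------------------------------------------------
# transaxial algebra: interleaved sinogram bin map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinoBinMap:
    """Transaxial crystal pair <-> (angle, radial) bin mappings.

    ``pair_a``/``pair_b`` give the two crystal positions of each bin
    (crystal A is the ray origin for the projector); ``pair_to_bin`` is the
    inverse, -1 for pairs outside the radial acceptance.  ``active_mask`` is
    True where both positions are live.
    """
    n_angles: int
    n_radial: int
    pair_a: np.ndarray        # (n_angles, n_radial) int32
    pair_b: np.ndarray        # (n_angles, n_radial) int32
    pair_to_bin: np.ndarray   # (D, D) int32, flattened bin id or -1
    active_mask: np.ndarray   # (n_angles, n_radial) bool

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def bin_to_pairs(self, angle: int, radial: int) -> set:
        """Unordered crystal pairs contributing to one bin."""
        a = int(self.pair_a[angle, radial])
        b = int(self.pair_b[angle, radial])
        return {(min(a, b), max(a, b))}


def build_sino_bin_map(geom: ScannerGeometry) -> SinoBinMap:
    D = geom.n_crystal_positions
    na, nr = geom.n_angles, geom.n_radial_bins
    a = np.arange(na)[:, None]
    t = np.arange(nr)[None, :] - (nr - 1) // 2       # centred radial offset
    pair_a = ((a + (t + 1) // 2) % D).astype(np.int32)
    pair_b = ((a - t // 2 + D // 2) % D).astype(np.int32)

    pair_to_bin = np.full((D, D), -1, dtype=np.int32)
    flat = np.arange(na * nr, dtype=np.int32).reshape(na, nr)
    pair_to_bin[pair_a, pair_b] = flat
    pair_to_bin[pair_b, pair_a] = flat

    live = geom.live_mask_tx()
    active = live[pair_a] & live[pair_b]
    return SinoBinMap(n_angles=na, n_radial=nr, pair_a=pair_a, pair_b=pair_b,
                      pair_to_bin=pair_to_bin, active_mask=active)
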