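"""List-mode coincidence streams: container, I/O, histogramming, bootstrap.

The on-disk container is a fixed-width little-endian record file with a JSON
sidecar (``<path>.json``) carrying the duration, geometry hash and record
counts.  Event records store the two crystals as (transaxial position, ring)
index pairs plus a delayed flag; bucket-singles records store per-bucket
singles rates reported at arbitrary times.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (ScannerGeometry, build_michelogram,
                       build_sino_bin_map, count_sinograms)
from .sinogram import SinogramSet, empty_sinogram

__all__ = [
    "EVENT_DTYPE",
    "SINGLES_DTYPE",
    "ListModeData",
    "HistogramOutput",
    "read_listmode",
    "write_listmode",
    "histogram",
    "bootstrap_resample",
]

EVENT_DTYPE = np.dtype([
    ("time_ms", "<u4"),
    ("tx_a", "<u2"), ("ring_a", "<u2"),
    ("tx_b", "<u2"), ("ring_b", "<u2"),
    ("delayed", "<u1"), ("_pad", "<u1"),
])

SINGLES_DTYPE = np.dtype([
    ("time_ms", "<u4"),
    ("bucket", "<u2"),
    ("rate", "<f4"),
])

_MAGIC = b"PQLM"
_VERSION = 1


class ListModeError(ValueError):
    """Malformed list-mode file or records."""


@dataclass
class ListModeData:
    """Timestamped prompt/delayed events plus bucket-singles records."""

    events: np.ndarray                 # EVENT_DTYPE
    singles_records: np.ndarray        # SINGLES_DTYPE
    duration_ms: int
    geometry_hash: str = ""

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=EVENT_DTYPE)
        self.singles_records = np.asarray(self.singles_records,
                                          dtype=SINGLES_DTYPE)
        if self.events.size and np.any(np.diff(
                self.events["time_ms"].astype(np.int64)) < 0):
            raise ListModeError("event times must be non-decreasing")

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    def validate_against(self, geom: ScannerGeometry):
        ev = self.events
        if ev.size == 0:
            return
        if int(max(ev["ring_a"].max(), ev["ring_b"].max())) >= geom.n_rings:
            raise ListModeError("event ring index outside geometry")
        if int(max(ev["tx_a"].max(), ev["tx_b"].max())) >= \
                geom.n_crystal_positions:
            raise ListModeError("event crystal position outside geometry")
        if self.singles_records.size and \
                int(self.singles_records["bucket"].max()) >= geom.n_buckets:
            raise ListModeError("singles bucket id outside geometry")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_listmode(lm: ListModeData, path) -> None:
    path = Path(path)
    header = struct.pack("<4sHxxQQQ", _MAGIC, _VERSION,
                         lm.n_events, lm.singles_records.size,
                         int(lm.duration_ms))
    with open(path, "wb") as f:
        f.write(header)
        f.write(lm.events.tobytes())
        f.write(lm.singles_records.tobytes())
    sidecar = {
        "format": "petquant-listmode",
        "version": _VERSION,
        "duration_ms": int(lm.duration_ms),
        "geometry_hash": lm.geometry_hash,
        "n_events": lm.n_events,
        "n_singles_records": int(lm.singles_records.size),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_listmode(path, geom: ScannerGeometry | None = None) -> ListModeData:
    path = Path(path)
    raw = path.read_bytes()
    hdr_size = struct.calcsize("<4sHxxQQQ")
    if len(raw) < hdr_size:
        raise ListModeError("file too short for header")
    magic, version, n_ev, n_sg, duration = struct.unpack("<4sHxxQQQ",
                                                         raw[:hdr_size])
    if magic != _MAGIC:
        raise ListModeError(f"bad magic {magic!r}")
    if version != _VERSION:
        raise ListModeError(f"unsupported version {version}")
    ev_bytes = n_ev * EVENT_DTYPE.itemsize
    sg_bytes = n_sg * SINGLES_DTYPE.itemsize
    if len(raw) != hdr_size + ev_bytes + sg_bytes:
        raise ListModeError("truncated or oversized record section")
    events = np.frombuffer(raw, dtype=EVENT_DTYPE, count=n_ev,
                           offset=hdr_size).copy()
    singles = np.frombuffer(raw, dtype=SINGLES_DTYPE, count=n_sg,
                            offset=hdr_size + ev_bytes).copy()
    gh = ""
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        gh = json.loads(sidecar.read_text()).get("geometry_hash", "")
    lm = ListModeData(events, singles, duration, geometry_hash=gh)
    if geom is not None:
        lm.validate_against(geom)
    return lm


# ---------------------------------------------------------------------------
# histogramming
# ---------------------------------------------------------------------------

@dataclass
class HistogramOutput:
    """Per-frame histogramming products."""

    prompts: SinogramSet
    delayeds: SinogramSet
    head_curve: dict                   # seconds / prompt_rate / delayed_rate
    com_trace: np.ndarray              # per-second axial centre of mass (mm)
    bucket_singles: np.ndarray         # (n_seconds, n_buckets) mean rates
    delayed_fansums: np.ndarray        # (n_tx_positions, n_rings)
    discarded_prompts: int
    discarded_delayeds: int
    frame: tuple


def _bin_events(ev, geom, binmap, plane_index):
    """Map events to (plane, angle, radial); returns indices + keep mask."""
    nr = geom.n_radial_bins
    txa = ev["tx_a"].astype(np.int64)
    txb = ev["tx_b"].astype(np.int64)
    flat = binmap.pair_to_bin[txa, txb].astype(np.int64)
    ok = flat >= 0
    ok &= binmap.active_mask.ravel()[np.clip(flat, 0, None)]
    a = flat // nr
    r = flat - a * nr
    # crystal A of the bin determines which event crystal carries ring0
    bin_a = binmap.pair_a[a, r]
    is_a = txa == bin_a
    r0 = np.where(is_a, ev["ring_a"], ev["ring_b"]).astype(np.int64)
    r1 = np.where(is_a, ev["ring_b"], ev["ring_a"]).astype(np.int64)
    plane = plane_index[r0, r1].astype(np.int64)
    ok &= plane >= 0
    return plane, a, r, ok


def histogram(lm: ListModeData, geom: ScannerGeometry,
              frames=None, span=None) -> list[HistogramOutput]:
    """Histogram events into prompt/delayed sinograms for each frame.

    ``frames`` is a list of (t0_ms, t1_ms) half-open intervals; ``None``
    histogram the whole stream as one frame.  Events on dead positions,
    outside the radial acceptance or beyond the ring-difference limit are
    counted into the per-frame discard tallies.
    """
    lm.validate_against(geom)
    span = geom.span if span is None else span
    if frames is None:
        frames = [(0, int(lm.duration_ms))]
    frames = [(int(t0), int(t1)) for t0, t1 in frames]
    for t0, t1 in frames:
        if not 0 <= t0 < t1 <= lm.duration_ms:
            raise ValueError(f"frame ({t0},{t1}) outside acquisition")
    for (a0, a1), (b0, b1) in zip(frames, frames[1:]):
        if b0 < a1:
            raise ValueError("overlapping frames")

    binmap = build_sino_bin_map(geom)
    plane_index = build_michelogram(geom, span).plane_index
    n_sec_total = int(np.ceil(lm.duration_ms / 1000.0))
    times = lm.events["time_ms"].astype(np.int64)
    ring_pitch = geom.ring_pitch

    out = []
    for t0, t1 in frames:
        sel = (times >= t0) & (times < t1)
        ev = lm.events[sel]
        is_del = ev["delayed"].astype(bool)
        prompts = empty_sinogram(geom, span)
        delayeds = empty_sinogram(geom, span)
        discard = [0, 0]
        plane, a, r, ok = _bin_events(ev, geom, binmap, plane_index)
        for which, sino in ((0, prompts), (1, delayeds)):
            m = ok & (is_del == bool(which))
            np.add.at(sino.data, (plane[m], a[m], r[m]), 1.0)
            discard[which] = int(((~ok) & (is_del == bool(which))).sum())

        # per-second head curve and axial-COM trace over the frame
        s0, s1 = t0 // 1000, int(np.ceil(t1 / 1000.0))
        n_sec = max(s1 - s0, 1)
        sec = np.minimum(ev["time_ms"] // 1000 - s0, n_sec - 1).astype(np.int64)
        prompt_rate = np.bincount(sec[~is_del], minlength=n_sec).astype(float)
        delayed_rate = np.bincount(sec[is_del], minlength=n_sec).astype(float)
        # SSR axial position of each prompt event, in mm
        u = ev["ring_a"].astype(np.int64) + ev["ring_b"].astype(np.int64)
        z = (u - (2 * geom.n_rings - 2) / 2.0) * ring_pitch / 2.0
        zsum = np.bincount(sec[~is_del], weights=z[~is_del], minlength=n_sec)
        with np.errstate(invalid="ignore"):
            com = np.where(prompt_rate > 0, zsum / np.maximum(prompt_rate, 1),
                           np.nan)

        # bucket singles: mean reported rate per second per bucket
        sg = lm.singles_records
        in_frame = (sg["time_ms"] >= t0) & (sg["time_ms"] < t1)
        sgf = sg[in_frame]
        bucket_singles = np.zeros((n_sec, geom.n_buckets))
        counts = np.zeros((n_sec, geom.n_buckets))
        ssec = np.minimum(sgf["time_ms"] // 1000 - s0, n_sec - 1).astype(np.int64)
        np.add.at(bucket_singles, (ssec, sgf["bucket"].astype(np.int64)),
                  sgf["rate"].astype(float))
        np.add.at(counts, (ssec, sgf["bucket"].astype(np.int64)), 1.0)
        with np.errstate(invalid="ignore"):
            bucket_singles = np.where(counts > 0, bucket_singles /
                                      np.maximum(counts, 1), 0.0)

        # delayed fan sums over active bins; each event feeds both crystals
        fansums = np.zeros((geom.n_crystal_positions, geom.n_rings))
        dm = ok & is_del
        np.add.at(fansums, (ev["tx_a"][dm].astype(np.int64),
                            ev["ring_a"][dm].astype(np.int64)), 1.0)
        np.add.at(fansums, (ev["tx_b"][dm].astype(np.int64),
                            ev["ring_b"][dm].astype(np.int64)), 1.0)

        out.append(HistogramOutput(
            prompts=prompts, delayeds=delayeds,
            head_curve={"seconds": np.arange(s0, s0 + n_sec),
                        "prompt_rate": prompt_rate,
                        "delayed_rate": delayed_rate},
            com_trace=com, bucket_singles=bucket_singles,
            delayed_fansums=fansums,
            discarded_prompts=discard[0], discarded_delayeds=discard[1],
            frame=(t0, t1)))
    return out


def bootstrap_resample(lm: ListModeData, seed: int) -> ListModeData:
    """Nonparametric event-level bootstrap replicate.

    Samples n events with replacement from the n originals — prompts and
    delayeds as one stream, each event keeping its type flag — then restores
    time order with a stable sort.  Singles records are copied unchanged.
    """
    if lm.n_events < 1:
        raise ListModeError("bootstrap needs at least one event")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, lm.n_events, size=lm.n_events)
    ev = lm.events[idx]
    ev = ev[np.argsort(ev["time_ms"], kind="stable")]
    return ListModeData(ev.copy(), lm.singles_records.copy(),
                        lm.duration_ms, lm.geometry_hash)
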