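"""Projection-data container with span reduction helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (SSR, ScannerGeometry, build_michelogram,
                       count_sinograms, span_group_map)

__all__ = ["SinogramSet", "empty_sinogram", "reduce_span", "reduce_to_ssr"]


@dataclass
class SinogramSet:
    """Stack of sinogram planes, shape ``(n_planes, n_angles, n_radial)``.

    Plane ordering is the segment-major Michelogram ordering of
    :func:`petquant.geometry.build_michelogram` for the stored span.
    """

    data: np.ndarray
    span: int | str
    geometry_hash: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("sinogram data must be (planes, angles, radial)")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "SinogramSet":
        return SinogramSet(self.data.copy(), self.span, self.geometry_hash)

    def total(self) -> float:
        return float(self.data.sum())


def empty_sinogram(geom: ScannerGeometry, span=None,
                   dtype=np.float64) -> SinogramSet:
    span = geom.span if span is None else span
    shape = (count_sinograms(geom, span), geom.n_angles, geom.n_radial_bins)
    return SinogramSet(np.zeros(shape, dtype=dtype), span,
                       geom.content_hash())


def reduce_span(sino: SinogramSet, geom: ScannerGeometry,
                span) -> SinogramSet:
    """Sum span-1 planes into span-S (or SSR) groups."""
    if sino.span != 1:
        raise ValueError("span reduction starts from span-1 data")
    gmap = (np.array([p[0].sum() for p in build_michelogram(geom, 1).plane_pairs])
            if span == SSR else span_group_map(geom, span))
    n_out = count_sinograms(geom, span)
    out = np.zeros((n_out,) + sino.data.shape[1:], dtype=sino.data.dtype)
    np.add.at(out, gmap, sino.data)
    return SinogramSet(out, span, sino.geometry_hash)


def reduce_to_ssr(sino: SinogramSet, geom: ScannerGeometry) -> SinogramSet:
    if sino.span == SSR:
        return sino.copy()
    if sino.span == 1:
        return reduce_span(sino, geom, SSR)
    # span-S planes collapse to the SSR plane of their mean axial position
    m = build_michelogram(geom, sino.span)
    gmap = np.array([int(round(np.mean(p.sum(axis=1)))) for p in m.plane_pairs])
    out = np.zeros((2 * geom.n_rings - 1,) + sino.data.shape[1:],
                   dtype=sino.data.dtype)
    np.add.at(out, gmap, sino.data)
    return SinogramSet(out, SSR, sino.geometry_hash)
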