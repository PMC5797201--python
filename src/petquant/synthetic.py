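"""Synthetic phantoms, normalisation components and a list-mode simulator.

The simulator draws per-bin Poisson realisations of an expected-counts model

    prompts_i ~ Poisson( trues_i + scatter_i + randoms_i ),
    trues_i   = eta_i * AF_i * (A emission)_i * duration,

converts them to timestamped coincidence events (uniform times), draws the
delayeds as an independent Poisson realisation of the randoms expectation,
and emits bucket-singles records consistent with the per-crystal singles
model that generated the randoms.  Everything is deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry, build_michelogram, build_sino_bin_map
from .listmode import EVENT_DTYPE, SINGLES_DTYPE, ListModeData
from .normalisation import NormComponents, build_norm_sinogram
from .projector import (Image3D, TransaxialLUT, attenuation_factors,
                        build_transaxial_lut, centred_image, forward_project)
from .pvc import Parcellation
from .scatter import ScatterConfig, interpolate_scatter, vsm_single_scatter
from .sinogram import SinogramSet

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "make_phantom",
    "make_norm_components",
    "simulate_listmode",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    phantom: dict = field(default_factory=lambda: {
        "type": "uniform_cylinder", "diameter_mm": 200.0, "activity": 1.0})
    mu_water: float = 0.096            # 1/cm at 511 keV
    duration_s: float = 600.0
    randoms_fraction: float = 0.0      # of total prompts
    scatter_fraction: float = 0.0      # of total prompts
    efficiency_cv: float = 0.0
    deadtime_tau_p: float = 0.0
    deadtime_tau_n: float = 0.0
    seed: int = 0
    target_prompts: float | None = None
    scatter_mode: str = "analytic"     # "analytic" | "vsm"
    scatter_emission_downsample: int = 4
    scatter_mumap_downsample: int = 3
    scatter_axial_sampling: int = 2
    scatter_tx_sampling: int = 7
    singles_report_interval_s: float = 2.0

    def __post_init__(self):
        if not (0 <= self.randoms_fraction < 1 and
                0 <= self.scatter_fraction < 1 and
                self.randoms_fraction + self.scatter_fraction < 1):
            raise SimulationError("fractions must be in [0, 1) and sum < 1")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def make_phantom(cfg: SimulationConfig, geom: ScannerGeometry,
                 shape=(15, 96, 96), voxel=None):
    """Voxelised phantom: (emission, mu-map, parcellation) on one grid."""
    if voxel is None:
        dz = geom.ring_pitch / 2.0
        fov = 0.85 * geom.ring_diameter
        voxel = (dz, fov / shape[1], fov / shape[2])
    emission = centred_image(geom, shape, voxel)
    mumap = centred_image(geom, shape, voxel)
    labels = centred_image(geom, shape, voxel)
    zc, yc, xc = emission.voxel_centres()
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    R = np.hypot(Y, X)

    ph = cfg.phantom
    kind = ph.get("type", "uniform_cylinder")
    if kind == "uniform_cylinder":
        radius = 0.5 * float(ph.get("diameter_mm", 200.0))
        if radius > 0.5 * geom.ring_diameter:
            raise SimulationError("phantom exceeds the detector ring")
        length = float(ph.get("length_mm", shape[0] * voxel[0]))
        inside = (R <= radius) & (np.abs(Z) <= length / 2.0)
        emission.values[inside] = float(ph.get("activity", 1.0))
        mumap.values[inside] = cfg.mu_water
        labels.values[inside] = 1
        region_map = {0: "background", 1: "cylinder"}
    elif kind == "brain_like":
        ratios = tuple(ph.get("ratios", (1.0, 1.4, 0.8)))
        radius = 0.5 * float(ph.get("diameter_mm", 180.0))
        if radius > 0.5 * geom.ring_diameter:
            raise SimulationError("phantom exceeds the detector ring")
        length = float(ph.get("length_mm", shape[0] * voxel[0]))
        inz = np.abs(Z) <= length / 2.0
        base = float(ph.get("activity", 1.0))
        shells = (radius, 0.66 * radius, 0.33 * radius)
        region_map = {0: "background", 1: "outer", 2: "mid", 3: "inner"}
        for i, (router, ratio) in enumerate(zip(shells, ratios)):
            m = (R <= router) & inz
            emission.values[m] = base * ratio
            labels.values[m] = i + 1
        mumap.values[(R <= radius) & inz] = cfg.mu_water
    else:
        raise SimulationError(f"unknown phantom type {kind!r}")
    labels.values = labels.values.astype(np.int64)
    return emission, mumap, Parcellation(labels, region_map)


def make_norm_components(geom: ScannerGeometry, efficiency_cv: float = 0.0,
                         seed: int = 0, with_geometric: bool = True,
                         deadtime_tau_p: float = 0.0,
                         deadtime_tau_n: float = 0.0) -> NormComponents:
    """Self-consistent synthetic component tables for a geometry."""
    rng = np.random.default_rng(seed)
    nr = geom.n_radial_bins
    ppb = geom.positions_per_block
    if with_geometric:
        x = (np.arange(nr) - (nr - 1) / 2.0) / (nr / 2.0)
        geometric = 1.0 + 0.15 * x ** 2
        interference = 1.0 + 0.05 * np.cos(
            2 * np.pi * np.arange(ppb)[None, :] / ppb +
            0.5 * x[:, None])
    else:
        geometric = np.ones(nr)
        interference = np.ones((nr, ppb))
    eff = np.ones((geom.n_crystal_positions, geom.n_rings))
    if efficiency_cv > 0:
        eff *= np.clip(1.0 + efficiency_cv *
                       rng.standard_normal(eff.shape), 0.05, None)
    eff[~geom.live_mask_tx(), :] = 0.0
    dt = np.zeros((geom.n_buckets, 2))
    dt[:, 0] = deadtime_tau_p
    dt[:, 1] = deadtime_tau_n
    return NormComponents(geometric=geometric,
                          crystal_interference=interference,
                          crystal_efficiencies=eff,
                          deadtime_params=dt)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

def _analytic_scatter_shape(geom: ScannerGeometry,
                            trues: np.ndarray) -> np.ndarray:
    """Smooth, wide scatter-like background following the trues' axial
    profile (stands in for multiple scatter / model mismatch)."""
    n_planes, na, nr = trues.shape
    r = np.arange(nr)
    c = (nr - 1) / 2.0
    w = 0.75 * nr
    radial = np.clip(1.0 - ((r - c) / w) ** 2, 0.0, None) ** 2
    axial = trues.reshape(n_planes, -1).sum(axis=1)
    axial = axial / max(axial.max(), 1e-300)
    shape = axial[:, None, None] * np.ones((1, na, 1)) * radial[None, None, :]
    return shape


@dataclass
class SimulationResult:
    listmode: ListModeData
    expected_trues: SinogramSet
    expected_scatter: SinogramSet
    expected_randoms: SinogramSet
    singles_rates: np.ndarray          # per-crystal S_i (counts/s)
    norm: SinogramSet
    af: SinogramSet


def simulate_listmode(emission: Image3D, mumap: Image3D,
                      components: NormComponents, cfg: SimulationConfig,
                      geom: ScannerGeometry,
                      lut: TransaxialLUT | None = None) -> SimulationResult:
    rng = np.random.default_rng(cfg.seed)
    if lut is None:
        lut = build_transaxial_lut(geom, emission)
    binmap = lut.binmap
    m1 = build_michelogram(geom, 1)
    duration = float(cfg.duration_s)

    af = attenuation_factors(mumap, lut, geom)
    eta = build_norm_sinogram(components, None, (0, duration * 1000), geom)
    if np.all(eta.data == 0):
        raise SimulationError("normalisation factors are zero everywhere")

    trues = forward_project(emission, lut, geom).data * af.data * \
        eta.data * duration
    t_total = trues.sum()
    if cfg.target_prompts is not None and t_total > 0:
        frac_t = 1.0 - cfg.randoms_fraction - cfg.scatter_fraction
        trues *= cfg.target_prompts * frac_t / t_total
        t_total = trues.sum()
    if not np.isfinite(t_total):
        raise SimulationError("expectation overflow")
    p_total = t_total / max(1.0 - cfg.randoms_fraction - cfg.scatter_fraction,
                            1e-12)

    # --- scatter expectation ---------------------------------------------
    s_target = cfg.scatter_fraction * p_total
    if s_target > 0:
        if cfg.scatter_mode == "vsm":
            from .scatter import downsample_image
            scfg = ScatterConfig(
                axial_detector_sampling=cfg.scatter_axial_sampling,
                tx_detector_sampling=cfg.scatter_tx_sampling)
            em_ds = downsample_image(emission,
                                     cfg.scatter_emission_downsample)
            mu_ds = downsample_image(mumap, cfg.scatter_mumap_downsample)
            sparse = vsm_single_scatter(em_ds, mu_ds, geom, scfg)
            shape = interpolate_scatter(sparse, geom).data
        else:
            shape = _analytic_scatter_shape(geom, trues)
        shape = shape * eta.data  # block effects apply to scatter too
        shape[:, ~binmap.active_mask] = 0.0
        if shape.sum() <= 0:
            raise SimulationError("scatter shape is empty")
        scatter = shape * (s_target / shape.sum())
    else:
        scatter = np.zeros_like(trues)

    # --- randoms from a per-crystal singles model -------------------------
    r_target = cfg.randoms_fraction * p_total
    eff = np.asarray(components.crystal_efficiencies, dtype=float)
    tau = geom.coincidence_window_tau
    pa, pb = binmap.pair_a, binmap.pair_b
    randoms_unit = np.zeros_like(trues)
    for p in range(m1.n_planes):
        r0, r1 = m1.plane_pairs[p][0]
        randoms_unit[p] = 2.0 * tau * eff[pa, r0] * eff[pb, r1] * duration
    randoms_unit[:, ~binmap.active_mask] = 0.0
    if r_target > 0:
        if randoms_unit.sum() <= 0:
            raise SimulationError("randoms model empty (no live crystals?)")
        s0 = np.sqrt(r_target / randoms_unit.sum())
        randoms = randoms_unit * s0 ** 2
        singles = s0 * eff              # S_i per crystal
    else:
        randoms = np.zeros_like(trues)
        singles = np.zeros_like(eff)

    # --- Poisson draws -> event stream ------------------------------------
    prompt_exp = trues + scatter + randoms
    prompt_counts = rng.poisson(prompt_exp).astype(np.int64)
    delayed_counts = rng.poisson(randoms).astype(np.int64)

    def counts_to_events(counts, delayed_flag):
        idx = np.flatnonzero(counts.ravel())
        reps = counts.ravel()[idx]
        n = int(reps.sum())
        if n == 0:
            return np.empty(0, dtype=EVENT_DTYPE)
        flat = np.repeat(idx, reps)
        na, nr = geom.n_angles, geom.n_radial_bins
        plane = flat // (na * nr)
        rest = flat - plane * (na * nr)
        a = rest // nr
        r = rest - a * nr
        ev = np.zeros(n, dtype=EVENT_DTYPE)
        r0 = np.array([p[0, 0] for p in m1.plane_pairs])[plane]
        r1 = np.array([p[0, 1] for p in m1.plane_pairs])[plane]
        ev["tx_a"] = pa[a, r]
        ev["ring_a"] = r0
        ev["tx_b"] = pb[a, r]
        ev["ring_b"] = r1
        ev["delayed"] = delayed_flag
        ev["time_ms"] = rng.integers(0, max(int(duration * 1000), 1), size=n)
        return ev

    events = np.concatenate([counts_to_events(prompt_counts, 0),
                             counts_to_events(delayed_counts, 1)])
    events = events[np.argsort(events["time_ms"], kind="stable")]

    # --- bucket singles records -------------------------------------------
    bucket_rate = np.zeros(geom.n_buckets)
    tx_idx, ring_idx = np.meshgrid(np.arange(geom.n_crystal_positions),
                                   np.arange(geom.n_rings), indexing="ij")
    np.add.at(bucket_rate, geom.bucket_of(tx_idx.ravel(), ring_idx.ravel()),
              singles.ravel())
    step_ms = max(int(cfg.singles_report_interval_s * 1000), 1)
    t_report = np.arange(0, int(duration * 1000), step_ms)
    sg = np.zeros(t_report.size * geom.n_buckets, dtype=SINGLES_DTYPE)
    sg["time_ms"] = np.repeat(t_report, geom.n_buckets)
    sg["bucket"] = np.tile(np.arange(geom.n_buckets), t_report.size)
    sg["rate"] = np.tile(bucket_rate, t_report.size)

    lm = ListModeData(events, sg, int(duration * 1000),
                      geometry_hash=geom.content_hash())
    gh = geom.content_hash()
    return SimulationResult(
        listmode=lm,
        expected_trues=SinogramSet(trues, 1, gh),
        expected_scatter=SinogramSet(scatter, 1, gh),
        expected_randoms=SinogramSet(randoms, 1, gh),
        singles_rates=singles,
        norm=eta, af=af)
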