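"""Bootstrap uncertainty estimation over the full processing chain.

Each replicate resamples the list-mode stream, then re-runs the identical
histogram -> randoms -> reconstruction (-> PVC) chain; voxel-wise mean and
standard-error images and per-replicate regional SUVr values are collected.
The SE is the across-replicate sample standard deviation (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .listmode import ListModeData, bootstrap_resample, histogram
from .normalisation import NormComponents, build_norm_sinogram
from .projector import Image3D, TransaxialLUT, attenuation_factors
from .pvc import Parcellation, PSFKernel, iterative_yang
from .randoms import estimate_singles, randoms_sinogram
from .recon import ReconConfig, osem
from .sinogram import SinogramSet

__all__ = ["StandardPipeline", "BootstrapResult", "run_bootstrap", "suvr"]


class UncertaintyError(ValueError):
    pass


@dataclass
class StandardPipeline:
    """histogram -> ML randoms -> OSEM (-> iterative Yang) for one frame.

    The attenuation factors, normalisation components and (optionally) the
    scatter estimate are fixed inputs; randoms fan sums are recomputed from
    each replicate's delayeds.
    """

    geom: ScannerGeometry
    lut: TransaxialLUT
    components: NormComponents
    af: SinogramSet
    recon_cfg: ReconConfig = field(default_factory=ReconConfig)
    scatter: SinogramSet | None = None
    parcellation: Parcellation | None = None
    psf: PSFKernel | None = None
    pvc_iterations: int = 10
    randoms_iterations: int = 10

    def run(self, lm: ListModeData) -> Image3D:
        geom = self.geom
        hist = histogram(lm, geom, span=1)[0]
        duration_s = lm.duration_ms / 1000.0
        norm = build_norm_sinogram(self.components, hist.bucket_singles,
                                   (0, lm.duration_ms), geom)
        est = estimate_singles(hist.delayed_fansums, geom,
                               tau=geom.coincidence_window_tau,
                               acq_time=duration_s,
                               n_iter=self.randoms_iterations)
        randoms = randoms_sinogram(est, geom, duration_s)
        img = osem(hist.prompts, norm, self.af, randoms,
                   self.scatter, self.lut, geom, self.recon_cfg)
        if self.psf is not None and self.parcellation is not None:
            img = iterative_yang(img, self.parcellation, self.psf,
                                 k_iter=self.pvc_iterations)
        return img


@dataclass
class BootstrapResult:
    n_replicates: int
    voxel_mean: Image3D
    voxel_se: Image3D
    regional: dict           # label -> array of per-replicate SUVr values
    seeds: list

    def regional_se(self) -> dict:
        return {k: float(np.std(v, ddof=1)) for k, v in self.regional.items()}


def run_bootstrap(lm: ListModeData, pipeline, n_replicates: int,
                  base_seed: int, parcellation: Parcellation | None = None,
                  reference_region=None) -> BootstrapResult:
    """Run the pipeline on ``n_replicates`` bootstrap resamples of ``lm``.

    ``pipeline`` is a :class:`StandardPipeline` or any object/callable with
    the same ``run(lm) -> Image3D`` contract.  Replicate r uses seed
    ``base_seed + r``; the result is deterministic in ``base_seed``.
    """
    runner = pipeline.run if hasattr(pipeline, "run") else pipeline
    if parcellation is None and hasattr(pipeline, "parcellation"):
        parcellation = pipeline.parcellation
    images = []
    regional: dict[int, list] = {}
    seeds = []
    for r in range(1, n_replicates + 1):
        seed = base_seed + r
        seeds.append(seed)
        try:
            rep = bootstrap_resample(lm, seed)
            img = runner(rep)
        except Exception as exc:   # noqa: BLE001 - annotate replicate id
            raise UncertaintyError(f"pipeline failed on replicate {r}: {exc}"
                                   ) from exc
        images.append(img.values)
        if parcellation is not None and reference_region is not None:
            for label, val in suvr(img, parcellation,
                                   reference_region).items():
                regional.setdefault(label, []).append(val)
    stack = np.stack(images)
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) if n_replicates > 1 \
        else np.zeros_like(mean)
    proto = img
    return BootstrapResult(
        n_replicates=n_replicates,
        voxel_mean=proto.copy_with(mean),
        voxel_se=proto.copy_with(se),
        regional={k: np.asarray(v) for k, v in regional.items()},
        seeds=seeds)


def suvr(img: Image3D, parcellation: Parcellation,
         reference_region) -> dict:
    """Region means normalised to the reference-region mean.

    ``reference_region`` is a label or set of labels; its own SUVr is 1 by
    construction (for a single-label reference).
    """
    if np.isscalar(reference_region):
        reference_region = {int(reference_region)}
    reference_region = {int(r) for r in reference_region}
    lab = parcellation.labels.values
    if lab.shape != img.shape:
        raise UncertaintyError("parcellation grid does not match image")
    ref_mask = np.isin(lab, list(reference_region))
    if not np.any(ref_mask):
        raise UncertaintyError("reference region is empty")
    ref = float(img.values[ref_mask].mean())
    if ref <= 0:
        raise UncertaintyError("reference region mean must be positive")
    out = {}
    for rid in parcellation.region_ids:
        m = lab == rid
        out[int(rid)] = float(img.values[m].mean()) / ref
    return out
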