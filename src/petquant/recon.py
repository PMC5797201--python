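"""OSEM reconstruction with multiplicative system factors and additive terms.

The forward model for measured prompts m_i is

    m_i ~ Poisson( eta_i * (A x)_i + r_i + s_i ),

where ``A`` is the span-1 Siddon projector, ``eta_i`` the product of the
normalisation-factor and attenuation-factor sinograms, and r/s the expected
randoms and scatter counts in data space (not pre-corrected).  The subset
update keeps the additive terms inside the model ("multiplicative factors on
the model" convention, applied consistently everywhere):

    x <- x / s_k * A_k^T[ eta * m / (eta * (A_k x) + r + s) ],
    s_k = A_k^T(eta)

which is algebraically identical to dividing the additive terms by eta and
weighting data-space ratios — the single documented algebra avoids the
classic normalisation-placement inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .projector import Image3D, TransaxialLUT, back_project, forward_project
from .sinogram import SinogramSet

__all__ = ["ReconConfig", "partition_subsets", "osem"]


class ReconError(ValueError):
    pass


@dataclass
class ReconConfig:
    n_subsets: int = 14
    n_iterations: int = 4
    update_scatter_each_iteration: bool = False
    epsilon: float = 1e-20
    track_likelihood: bool = False


def partition_subsets(geom: ScannerGeometry, n_subsets: int) -> list[np.ndarray]:
    """Interleaved balanced angle subsets (angle a -> subset a mod N)."""
    na = geom.n_angles
    if n_subsets < 1 or na % n_subsets != 0:
        divs = [d for d in range(1, na + 1) if na % d == 0]
        raise ReconError(
            f"{na} angles not divisible by {n_subsets} subsets; "
            f"valid counts include {divs[:12]}")
    return [np.arange(s, na, n_subsets) for s in range(n_subsets)]


def osem(prompts: SinogramSet, norm: SinogramSet, af: SinogramSet,
         randoms: SinogramSet, scatter_provider, lut: TransaxialLUT,
         geom: ScannerGeometry, cfg: ReconConfig,
         initial: Image3D | None = None) -> Image3D:
    """Ordered-subsets EM reconstruction (span-1 inputs throughout).

    ``scatter_provider`` is ``None``, a SinogramSet (fixed scatter), or a
    callable ``image -> SinogramSet`` invoked before each full iteration
    when ``cfg.update_scatter_each_iteration`` is set (once, otherwise).
    """
    for name, s in (("prompts", prompts), ("norm", norm), ("af", af),
                    ("randoms", randoms)):
        if s.span != 1:
            raise ReconError(f"{name} must be span-1")
        if s.data.shape != prompts.data.shape:
            raise ReconError(f"{name} shape mismatch")
        if np.any(np.isnan(s.data)):
            raise ReconError(f"NaN in {name}")
    if np.any(prompts.data < 0):
        raise ReconError("negative prompt counts")

    eps = cfg.epsilon
    eta = norm.data * af.data
    subsets = partition_subsets(geom, cfg.n_subsets)

    # per-subset sensitivity images s_k = A_k^T(eta)
    sens = []
    for sub in subsets:
        sens.append(back_project(SinogramSet(eta, 1, prompts.geometry_hash),
                                 lut, geom, subset=sub).values)
    sens_total = np.sum(sens, axis=0)

    (nz, ny, nx), voxel, origin = lut.grid
    if initial is not None:
        x = initial.values.copy()
    else:
        x = np.where(sens_total > 0, 1.0, 0.0)

    m = prompts.data

    def current_scatter(img_values):
        if scatter_provider is None:
            return np.zeros_like(m)
        if isinstance(scatter_provider, SinogramSet):
            return scatter_provider.data
        img = Image3D(img_values, voxel, origin)
        s = scatter_provider(img)
        return s.data if isinstance(s, SinogramSet) else np.asarray(s)

    s_data = current_scatter(x)
    log = []
    for it in range(cfg.n_iterations):
        if cfg.update_scatter_each_iteration and it > 0:
            s_data = current_scatter(x)
        for k, sub in enumerate(subsets):
            img = Image3D(x, voxel, origin)
            q = forward_project(img, lut, geom, subset=sub).data
            denom = eta * q + randoms.data + s_data
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(denom > eps, eta * m / np.maximum(denom, eps),
                                 0.0)
            upd = back_project(SinogramSet(ratio, 1, prompts.geometry_hash),
                               lut, geom, subset=sub).values
            # voxels unseen by this subset keep their value; voxels with no
            # sensitivity anywhere stay 0 through the initialisation
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.where(sens[k] > 0, x * upd / np.maximum(sens[k], eps),
                             x)
            if cfg.track_likelihood:
                qq = denom[:, sub, :]
                mm = m[:, sub, :]
                ok = qq > 0
                log.append(float(np.sum(mm[ok] * np.log(qq[ok]) - qq[ok])))
    out = Image3D(x, voxel, origin)
    out.log_likelihood = log  # attribute for run logs
    return out
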