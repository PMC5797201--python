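# petquant

Quantitative PET acquisition modelling, reconstruction and analysis for
cylindrical scanner geometries, implemented as a pure CPU library with a CLI.
The processing chain covers:

- **geometry** — parametrisable cylindrical scanners with the full sinogram
  index algebra: interleaved transaxial (angle, radial) binning with dead
  crystal positions per block, Michelogram plane ordering, span-1 / odd
  span-S / single-slice-rebinning (SSR) axial compression and segment tables.
  A full-size 64-ring preset (`"mmr"`) and ring-reduced variants
  (`"mmr-reduced:<n>"`) are built in.
- **listmode** — a documented binary list-mode container with JSON sidecar,
  histogramming to prompt/delayed sinograms at any span, head curve, axial
  centre-of-mass motion trace, bucket-singles matrices, delayed fan sums and
  a nonparametric event-level bootstrap resampler.
- **normalisation** — factor sinograms assembled from geometric, crystal
  interference, crystal efficiency, axial and dead-time (paralysable +
  non-paralysable) components; span-1 axial factor decoding from span-S
  factors and a high-statistics acquisition; scatter-specific axial factors.
- **projector** — exact Siddon ray tracing decomposed into a precomputed
  transaxial LUT and on-the-fly axial traversal (numba kernels); matched
  forward/back projectors (exact adjoints) and attenuation factor generation.
- **randoms** — maximum-likelihood singles-rate estimation from delayed fan
  sums and reduced-variance randoms sinogram synthesis.
- **scatter** — fully-3D voxel-driven single-scatter model with
  Klein–Nishina scoring over sampled detectors, optical-depth look-up
  tables, bicubic/bilinear interpolation to the full sinogram and weighted
  least-squares scaling to the prompts in the scatter-and-randoms-only
  region.
- **recon** — OSEM with multiplicative normalisation/attenuation factors and
  additive randoms/scatter terms; balanced interleaved angle subsets;
  optional scatter re-estimation each iteration.
- **pvc** — iterative-Yang partial volume correction with separable
  two-Gaussian PSF kernels and PSF fitting from point-source profiles.
- **uncertainty** — bootstrap orchestration of the whole chain: voxel
  mean/standard-error images and regional SUVr distributions.
- **synthetic** — digital phantoms, synthetic normalisation components and a
  Poisson list-mode acquisition simulator (trues + VSM or analytic scatter +
  singles-model randoms), used throughout the test suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end checks (projector exactness,
randoms/scatter recovery, uniform-cylinder flatness with all corrections,
bootstrap determinism and Poisson SE scaling); the whole suite runs in a few
minutes on one CPU.

## CLI

All stages are exposed under a single executable:

```sh
petquant simulate --config sim.json --geometry mmr-reduced:8 --out study/
petquant lm-hist  --listmode study/study.plm --geometry study/geometry.json --out study/h
petquant lm-boot  --listmode study/study.plm --seed 7 --out study/boot.plm
petquant randoms  --listmode study/study.plm --geometry study/geometry.json --out study/r.sino
petquant scatter  --emission em.nii --mumap mu.nii --geometry mmr-reduced:8 --out s.sino
petquant recon    --prompts study/h_prompts.sino --norm study/norm.bin \
                  --mumap study/mumap.nii --geometry study/geometry.json --out recon.nii
petquant pvc      --image recon.nii --labels labels.nii --psf psf.json --out pvc.nii
petquant bootstrap --listmode study/study.plm --geometry study/geometry.json \
                   --norm study/norm.bin --mumap study/mumap.nii --labels study/labels.nii \
                   --replicates 50 --seed 1 --out study/boot
petquant suvr     --image pvc.nii --labels labels.nii --reference-label 1
```

Commands are pure functions of (inputs, config, seed) and write a JSON run
log next to their primary output.

## File formats

- images: NIfTI-1 (axis order x fastest on disk; internal order z, y, x);
- sinograms: flat little-endian float64 binary (plane-major, angle, radial)
  plus a JSON sidecar with span, shape, plane-order id and geometry hash —
  a hash mismatch on read is an error;
- list-mode: fixed-width little-endian records (magic `PQLM`) plus a JSON
  sidecar with duration, geometry hash and record counts;
- normalisation components: flat binary arrays with a JSON manifest.

## Conventions

All indices are 0-based. Plane ordering is segment-major (0, +1, −1, +2,
−2, …), within a segment ordered by `r0 + r1`. Ray tracing is always span-1;
span-S data are formed by summing span-1 planes. Normalisation is applied as
multiplicative factors on the model (dead bins carry factor 0), and the OSEM
update keeps randoms/scatter as additive terms inside the forward model. The
dead-position offset within each detector block is a geometry config field;
the default (last position of the block) reproduces the printed live-bin
count of the 64-ring preset for any offset choice.
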