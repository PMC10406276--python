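# tractent

Entropy-based filtering of diffusion-MRI tractograms, with fiber-level
Sørensen–Dice evaluation and synthetic bundle phantoms.

## The problem

Probabilistic tractography of small fiber structures — cranial nerves in
particular, whose cisternal diameters (2–10 mm) barely exceed the 2 mm
acquisition voxel — is extremely sensitive to its parameters (seed-region
placement and size, FA cut-off). Poorly parameterized tracking produces
spurious fibers: false continuations into neighboring structures and
incoherent fibers where bundles mingle. Hand-tuning the parameters requires
expert neuroanatomical knowledge; *filtering* a permissively tracked
tractogram down to its plausible core is a route to automation.

`tractent` implements a filtering score based on the Shannon entropy of
local fiber orientations, an FA baseline, an import path for externally
computed per-fiber weights (e.g. SIFT2), and the evaluation machinery to
compare filtered tractograms against a reference.

## The method

1. **Orientation field.** The streamlines (sampled ~10× finer than the
   voxel) are rasterized into a fiber-density image (segment-length
   weighted). Its intensity gradient — normal to the fiber walls — is
   estimated per voxel over a 3×3×3 neighborhood and optionally regularized
   by gradient-vector-flow diffusion. Tangents are recovered as the
   sign-aligned average of cross products between each voxel's gradient and
   its 26 neighbors'.
2. **Entropy map.** The unit sphere is split into *n* regions of equal area
   (recursive zonal construction; default *n* = 32, matching a 32-direction
   acquisition). For each voxel, the tangents in a cubic neighborhood sized
   to the nerve diameter are binned into this spherical histogram, and

   *E(x, y, z) = −Σᵢ p(xᵢ) log₂ p(xᵢ)*,  *p(xᵢ) = C(xᵢ)/ΣⱼC(xⱼ)*

   is the voxel's orientation-disorder score in bits.
3. **Fiber score.** Each fiber gets *α* = the mean of *E* over the voxels it
   visits. Coherent fibers score low; filtering keeps the least entropic
   fraction.
4. **Evaluation.** A candidate tractogram *Y* is compared to a reference *X*
   by discretizing one onto the voxel grid and counting included fibers:
   *SD = 2|Z|/(|X|+|Y|)* with *Z* the fibers of *Y* inside *X*'s mask
   (penalizes spurious fibers), and *RSD = 2|RZ|/(|X|+|Y|)* with the roles
   swapped (penalizes truncation). Sweeping the keep-percentage 0–100 %
   yields *SD_init* (no filtering), *SD_max* (best reachable), and the
   filtering gain *SD_diff = SD_max − SD_init*.

Because real ground-truth tractograms require patient data, the `phantom`
module generates synthetic bundles with the same statistical structure:
curved bundles of preset nerve diameters plus false-continuation or
disordered contamination, and degradation suites mapping bad tracking
parameters onto their tractogram-level effects.

## Worked example

```python
from tractent import RunConfig, compute_entropy_scores, sd_score, threshold_sweep
from tractent.phantom import benchmark_phantom

gt, degraded, true_ids, cont_ids = benchmark_phantom("disordered", seed=7)
report = sd_score(gt, degraded)
print(f"before filtering: SD={report.sd:.3f} RSD={report.rsd:.3f} "
      f"(|X|={report.n_X}, |Y|={report.n_Y}, |Z|={report.n_Z})")

scores = compute_entropy_scores(degraded, RunConfig(diameter_mm=7.0))
sweep = threshold_sweep(gt, degraded, scores)
print(f"sweep: SD_init={sweep.sd_init:.3f} SD_max={sweep.sd_max:.3f} "
      f"at keep={sweep.best_percentage}% -> SD_diff={sweep.sd_diff:.3f}")
```

prints

```
before filtering: SD=0.764 RSD=0.748 (|X|=200, |Y|=300, |Z|=191)
sweep: SD_init=0.764 SD_max=0.953 at keep=67% -> SD_diff=0.189
```

The contaminated tractogram (200 true + 100 disordered fibers) starts at
SD = 0.764 against the reference bundle; keeping the 67 % least-entropic
fibers removes essentially all contaminants and lifts the overlap to 0.953,
a filtering gain of 0.189.

The same pipeline is available from the shell:

```sh
tractent phantom --preset V --contamination disordered:100 --seed 7 \
    -o gt.tck --degraded deg.tck --labels labels.tsv --reference ref.nii.gz
tractent pipeline --ground-truth gt.tck --candidate deg.tck \
    --reference ref.nii.gz --diameter 7 -o run/
```

plus stage-by-stage subcommands (`density`, `tangents`, `entropy`, `score`,
`filter`, `evaluate`, `sweep`).

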