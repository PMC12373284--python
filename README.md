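# tractokit

Along-tract analysis ("tractometry") quantifies tissue properties along
the length of white-matter tracts reconstructed from diffusion MRI.
`tractokit` implements the core of that workflow for researchers who
already have a tractogram and scalar maps (FA, MD, MK, ...) in subject
space:

* **recognition** — classify each streamline of a tractogram into named
  bundles using an ordered set of anatomical criteria (probability map,
  midline crossing, start/end regions, length range, primary travel
  axis, waypoint inclusion/exclusion ROIs with millimeter tolerances, an
  MDF shape prior), applied in a fixed order with per-criterion
  rejection tallies and first-in-dictionary tie-breaking;
* **cleaning** — set-level outlier removal: iterative Mahalanobis
  cleaning (length z-score > 4 or node-averaged Mahalanobis distance > 3,
  up to 5 rounds, never below 20 streamlines) and greedy
  QuickBundles-threshold cleaning under the minimum-direct-flip (MDF)
  distance;
* **profiles** — orient a bundle, resample every streamline to 100
  arc-length-uniform nodes, and extract the weighted mean profile of any
  scalar volume, with Gaussian-Mahalanobis streamline weights
  w = exp(−d²/2) normalized per node;
* **statistics** — per-node OLS group models (`value ~ group + age + sex`)
  with two-sided t-tests on the group term and Benjamini–Hochberg FDR
  across nodes; median imputation applied within train/test separately;
  the exponential learning-curve model
  R²(x) = α − (α−β)·e^−(x−x_min)/κ, whose rate κ is the number of
  training samples at which 1 − 1/e ≈ 63% of the α−β gap is closed;
  jitter / scaling / time-warp augmentation of profile tensors;
* **phantoms** — seeded synthetic generators for every input above
  (streamline bundles around parametric curves, painted scalar volumes,
  ROI masks, probability maps, distractors, group tables with planted
  node-localized effects, learning-curve data), so every stage is
  testable against known ground truth with no data download.

File formats go through nibabel: TRK/TCK tractograms, NIfTI-1 volumes,
and tidy long CSV profiles (`subject_id,tract_name,node_id,metric,value`).

## Worked example

```python
import numpy as np
from tractokit import phantom as ph
from tractokit import recognize, extract_profile, fit_learning_curve, pointwise_group_model

# A seeded phantom: two bundles (arc + helix, 60 streamlines each,
# planted FA profile 0.3 + 0.2 sin(pi t)) among 100 distractors.
result = ph.make_phantom(ph.default_phantom_spec(seed=7))
rec = recognize(result.tractogram, result.definitions)
print("assigned:", {t: len(ix) for t, ix in rec.kept_indices.items()})

prof = extract_profile(rec.bundles["left_arc"], result.scalars["FA"], tract_name="left_arc")
truth = result.truth.planted_profiles["left_arc"]["FA"]
err = float(np.max(np.abs(prof.values - truth)))
print("profile error (max, % of range):", round(err, 4), round(100 * err / np.ptp(truth), 1))

sizes, scores = ph.make_learning_data(0.62, 0.38, 413.0, 100.0, noise_sd=0.01, seed=7)
fit = fit_learning_curve(sizes, scores, alpha=0.62)
print(f"learning curve: beta={fit.beta:.3f} kappa={fit.kappa:.0f}")

tidy, cov = ph.make_group_dataset(effect_nodes=range(40, 61), effect_size_sd=2.0, seed=7)
res = pointwise_group_model(tidy, cov, "synthetic_tract", "FA")
print("FDR-rejected nodes:", np.flatnonzero(res.rejected))
```

prints

```
assigned: {'left_arc': 60, 'right_helix': 60}
profile error (max, % of range): 0.0044 2.2
learning curve: beta=0.384 kappa=456
FDR-rejected nodes: [40 41 42 43 44 45 46 47 48 49 50 51 52 53 54 55 56 57 58 59 60 92]
```

All 120 planted streamlines are recovered and no distractor is accepted;
the planted FA profile is reconstructed to ~2% of its range; the fitted
learning curve lands near the generating parameters (β = 0.38, κ = 413)
from six noisy scores; and the per-node model flags the 21 nodes carrying
the planted group effect (node 92 is a false discovery — at FDR level
0.05 a small number of these is the expected price of the procedure).

The same pipeline is available from the shell:

```bash
tractokit simulate phantom --seed 7 --out phantom/
tractokit recognize --tractogram phantom/tractogram.trk --config phantom/bundles.json --out bundles/
tractokit profile --bundles bundles/ --scalars phantom/FA.nii.gz --out profiles.csv
tractokit stats pointwise --profiles profiles.csv --covariates cov.csv \
    --tract left_arc --metric FA --out pointwise.csv
```

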