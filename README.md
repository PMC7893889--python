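# fidburn

Accuracy analysis of an MR-only prostate radiotherapy workflow with
semi-automatically burned-in gold fiducial markers, re-implemented as a
tested Python pipeline on synthetic phantoms.

In an MR-only workflow a synthetic CT (sCT) generated from a Dixon MR
acquisition replaces the planning CT. Implanted gold fiducial markers
(FMs) — the surrogate for prostate position during image-guided
radiotherapy — are invisible on the five-material sCT, so they are
*burned in*: each marker's signal void is delineated on three slices of
the water-Dixon image, expanded isotropically by 2 mm, the six
lowest-intensity voxels are selected, and those voxels are written into
the sCT at 3000 HU. The marker position estimate is the unweighted
center of mass (COM) of the selected voxels.

The package provides, for whoever needs to validate such a workflow:

* `fidburn.phantom` — synthetic pelvis phantoms: an MR-like volume with
  marker signal voids (plus optional calcification confounders), a
  co-registered five-material sCT, observer-perturbed delineations, and
  simulated registration cohorts with known error structure;
* `fidburn.burnin` — delineation expansion, k-lowest-voxel selection
  (deterministic raster-order tie-break), COM computation, burn-in, and
  inter-observer COM variability;
* `fidburn.rigid` — 6-DOF transforms (translations RL/CC/AP in mm,
  extrinsic rotations about those axes in degrees), closed-form rigid
  point-set registration of marker COMs, composition, per-axis RMS
  residuals, and the CT-frame correction of sCT-CBCT registrations;
* `fidburn.stats` — the population error decomposition
  (mean **M** = mean of per-patient means, systematic
  **Σ** = SD of per-patient means, random **σ** = RMS of per-patient
  SDs), inter-observer IQR / pooled-SD summaries, an exact-for-ties
  paired Wilcoxon signed-rank test and the Brown–Forsythe
  (non-parametric Levene) spread test;
* `fidburn.pipeline` / the `fidburn` CLI — seeded, hash-stamped
  end-to-end runs.

## Worked example

```python
import numpy as np
from fidburn import (PhantomConfig, generate_phantom,
                     generate_observer_delineations, expand_delineation,
                     select_lowest_voxels, burn_in_markers)

cfg = PhantomConfig(seed=7)            # 64x64x48 @ 1.7x1.7x2.5 mm, 4 markers
mr, sct, truth = generate_phantom(cfg)

obs = generate_observer_delineations(truth, mr, n_observers=1,
                                     jitter_sd=0.0, seed=999)
sels = [select_lowest_voxels(mr, expand_delineation(d, 2.0, mr), k=6)
        for d in obs[0]]
burned, report = burn_in_markers(sct, sels)
print(report)
for sel, m in zip(sels, truth):
    print(m.label, "COM error %.2f mm" % np.linalg.norm(sel.com - m.center))
```

prints

```
{'n_burned': 24, 'n_shared_voxels': 0}
FM1 COM error 0.40 mm
FM2 COM error 0.60 mm
FM3 COM error 0.46 mm
FM4 COM error 0.67 mm
```

— 4 markers × 6 voxels burned at 3000 HU, each recovered marker COM well
within half the largest voxel dimension (1.25 mm) of the true cylinder
center.

The numbered drivers under `analysis/` run the three sub-studies and
write their tables to `results/`:

```sh
python analysis/01_simulate_phantom.py        # phantom + ground truth
python analysis/02_burnin_com_variability.py  # 7-observer COM scatter, k=1..15
python analysis/03_interobserver_registration.py  # IQR / pooled-SD comparison
python analysis/04_position_verification.py   # corrected sCT-CBCT vs CT-CBCT
```

For example, `03` reports a ~3.5× smaller pooled inter-observer SD for
the MR-only workflow with Levene p ≪ 0.001 on every parameter, and `04`
decomposes a 26-patient × 24-fraction cohort into M / Σ / σ per
parameter and shows the per-fraction workflow differences sitting at the
scale of the CT-sCT marker registration residual (RMS < 0.3 mm here).

See `docs/methods.md` for the model conventions (angle convention,
tie-breaks, quantile rule, estimator definitions) and the phantom's
scope and limitations.

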