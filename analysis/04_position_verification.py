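#!/usr/bin/env python
"""Position-verification accuracy: corrected sCT-CBCT vs CT-CBCT.

Chains the marker-level position-verification comparison on one
synthetic patient geometry plus a simulated cohort:

1. shift the phantom's markers by a known CT<->sCT patient repositioning
   transform, add sub-mm marker localization noise, and recover the
   transform by rigid least squares (with the per-axis RMS residual);
2. simulate 26 patients x 24 CBCT registrations from clinically
   representative generating parameters, express them in the sCT frame, correct them
   back with the *fitted* CT-sCT transform, and decompose both cohorts
   into population mean M, systematic error Sigma and random error sigma;
3. decompose the per-fraction sCT-minus-CT differences the same way and
   test the per-patient mean differences against zero (Wilcoxon).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fidburn import (
    PhantomConfig,
    PointCorrespondence,
    RigidTransform6,
    StudyDesign,
    compose,
    correct_registration,
    fit_rigid,
    generate_phantom,
    invert,
    population_errors,
    registration_difference_stats,
    residual_rms,
    simulate_registration_study,
    transform_points,
)
from fidburn.stats import PARAM_COLUMNS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 7
MARKER_NOISE_MM = 0.4  # COM localization noise between CT and sCT modalities
CT_SCT_TRUE = (3.0, -2.0, 1.5, 1.0, -0.8, 0.5)  # patient repositioning
COHORT_MEAN = (-0.2, -0.7, -0.3, -0.5, 0.8, -0.6)
COHORT_SYS = (2.8, 3.8, 2.9, 4.6, 2.7, 2.4)
COHORT_RND = (3.3, 2.7, 2.9, 4.4, 2.2, 1.4)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    _, _, truth = generate_phantom(PhantomConfig(seed=SEED))
    pts_sct = np.array([m.center for m in truth])
    labels = [m.label for m in truth]
    center = pts_sct.mean(axis=0)

    ct_sct_true = RigidTransform6(*CT_SCT_TRUE, center=center)
    rng = np.random.default_rng(SEED)
    pts_ct = transform_points(ct_sct_true, pts_sct)
    pts_ct += rng.normal(0, MARKER_NOISE_MM, pts_ct.shape)
    pairs = PointCorrespondence(pts_ct, pts_sct, labels)
    fit = fit_rigid(pairs)
    rms = residual_rms(pairs, fit)
    print("marker-based CT-sCT registration residual RMS (mm): "
          f"RL={rms['RL']:.2f} CC={rms['CC']:.2f} AP={rms['AP']:.2f} "
          f"(overall {rms['overall']:.2f})")

    design = StudyDesign(
        n_patients=26, n_raters_or_fractions=24,
        population_mean=np.array(COHORT_MEAN),
        systematic_sd=np.array(COHORT_SYS),
        random_sd=np.array(COHORT_RND), seed=SEED + 100,
    )
    ct_cbct = simulate_registration_study(design, workflow="CT")
    inv_true = invert(ct_sct_true)
    corrected_rows = []
    for _, row in ct_cbct.iterrows():
        T_ct = RigidTransform6(
            row.tRL_mm, row.tCC_mm, row.tAP_mm,
            row.rRL_deg, row.rCC_deg, row.rAP_deg, center=center,
        )
        T_sct = compose(inv_true, T_ct)  # same fraction, sCT reference frame
        corr = correct_registration(T_sct, fit)
        rec = {"patient_id": row.patient_id,
               "rater_or_fraction_id": row.rater_or_fraction_id,
               "workflow": "MR-only"}
        rec.update(corr.params())
        corrected_rows.append(rec)
    both = pd.concat([pd.DataFrame(corrected_rows), ct_cbct], ignore_index=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    both.to_csv(SCRATCH / "position_verification_records.csv", index=False)

    print("\npopulation error decomposition (26 patients x 24 CBCTs):")
    for wf in ("CT", "MR-only"):
        t = population_errors(both[both.workflow == wf]).table
        t.to_csv(RESULTS / f"population_errors_{wf.replace('/', '')}.csv")
        print(f"  {wf}: RL mean {t.loc['tRL_mm', 'mean']:+.1f} mm, "
              f"Sigma {t.loc['tRL_mm', 'systematic']:.1f} mm, "
              f"sigma {t.loc['tRL_mm', 'random']:.1f} mm")

    diff = registration_difference_stats(both, workflows=("MR-only", "CT"))
    table = diff.table.copy()
    table["p_mean_vs_zero"] = diff.pvalues
    table.to_csv(RESULTS / "difference_stats.csv")
    print("\nper-fraction MR-only minus CT differences:")
    print(table.to_string(float_format=lambda v: f"{v:.3g}"))
    print("\ntranslation differences are on the scale of the CT-sCT marker "
          "residual; rotation differences reach ~1 deg because the fitted "
          "correction's angular error scales as residual / marker lever arm. "
          "Both are far below the cohort's setup errors.")


if __name__ == "__main__":
    main()
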