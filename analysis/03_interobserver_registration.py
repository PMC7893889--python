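#!/usr/bin/env python
"""Inter-observer error of target-delineation registrations, two workflows.

Simulates 20 patients x 7 observers registering for target delineation
under the conventional CT/MR workflow (large observer scatter: the
marker-based CT-MR match is manual) and the MR-only workflow (small
scatter: the sCT shares the Dixon frame, leaving only a soft-tissue
intra-MR registration).  The generating observer SDs per parameter are
clinically representative pooled group SDs per workflow.  Reports per-patient
mean IQR, pooled SD after per-patient mean subtraction, and the paired
Wilcoxon / non-parametric Levene comparisons.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fidburn import StudyDesign, ioe_summary, simulate_registration_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

N_PATIENTS = 20
N_OBSERVERS = 7
PATIENT_SD = 2.0  # between-patient spread of the true registration (mm / deg)
# observer scatter per parameter (tRL, tCC, tAP, rRL, rCC, rAP)
SD_CTMR = (0.87, 1.26, 1.32, 1.97, 1.17, 1.18)
SD_MRONLY = (0.25, 0.30, 0.40, 0.59, 0.42, 0.43)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    common = dict(
        n_patients=N_PATIENTS, n_raters_or_fractions=N_OBSERVERS,
        population_mean=np.zeros(6), systematic_sd=np.full(6, PATIENT_SD),
    )
    rec = pd.concat([
        simulate_registration_study(
            StudyDesign(**common, random_sd=np.array(SD_CTMR), seed=31),
            workflow="CT/MR"),
        simulate_registration_study(
            StudyDesign(**common, random_sd=np.array(SD_MRONLY), seed=32),
            workflow="MR-only"),
    ], ignore_index=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rec.to_csv(SCRATCH / "ioe_records.csv", index=False)

    res = ioe_summary(rec, workflows=("CT/MR", "MR-only"))
    res.table.to_csv(RESULTS / "ioe_table.csv")
    print(f"{N_PATIENTS} patients x {N_OBSERVERS} observers per workflow")
    print(res.table.to_string(float_format=lambda v: f"{v:.3g}"))
    ratio = (res.table["pooled_sd_CT/MR"] / res.table["pooled_sd_MR-only"]).mean()
    print(f"\nmean pooled-SD ratio CT/MR : MR-only = {ratio:.1f} "
          "(the MR-only workflow has the smaller inter-observer error)")
    sig = (res.table["p_group"] < 0.05).all() and (res.table["p_patient"] < 0.05).all()
    print("all parameters significant at the 5% level "
          f"(patient-level Wilcoxon and group-level Levene): {sig}")


if __name__ == "__main__":
    main()
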