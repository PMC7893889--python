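#!/usr/bin/env python
"""Burn-in accuracy and inter-observer variability of marker COMs.

Seven simulated observers delineate each marker's signal void on three
slices; each delineation is expanded by 2 mm, the k lowest-intensity
voxels are selected, and their center of mass (COM) is the marker
position.  This script sweeps k = 1..15, reports per-marker COM scatter
across observers (SD of the RL, CC, AP components) and the cumulative
fraction of markers below scatter thresholds, and burns the k = 6
selection into the sCT.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fidburn import (
    PhantomConfig,
    burn_in_markers,
    com_variability,
    expand_delineation,
    generate_observer_delineations,
    generate_phantom,
    select_lowest_voxels,
    write_volume,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "phantom"

SEED = 7
N_OBSERVERS = 7
JITTER_SD_MM = 0.5
MARGIN_MM = 2.0
K_BURN = 6
NOISE_SD = 25.0  # ~5% of the water-tissue MR intensity


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    # several phantoms to approach the cohort's ~78 markers (20 phantoms x 4)
    rows = []
    com_err_k6 = []
    for ph_seed in range(20):
        cfg = PhantomConfig(seed=SEED + ph_seed, noise_sd=NOISE_SD)
        mr, sct, truth = generate_phantom(cfg)
        centers = {m.label: m.center for m in truth}
        observers = generate_observer_delineations(
            truth, mr, n_observers=N_OBSERVERS, jitter_sd=JITTER_SD_MM,
            misid_prob=0.0, seed=1000 + ph_seed,
        )
        for delins in observers:
            for d in delins:
                roi = expand_delineation(d, MARGIN_MM, mr)
                for k in range(1, 16):
                    sel = select_lowest_voxels(mr, roi, k)
                    rows.append({
                        "phantom": ph_seed, "k": k,
                        "marker_label": f"p{ph_seed}_{sel.marker_label}",
                        "observer_id": sel.observer_id,
                        "x_RL_mm": sel.com[0], "y_AP_mm": sel.com[1],
                        "z_CC_mm": sel.com[2],
                    })
                    if k == K_BURN:
                        com_err_k6.append(
                            np.linalg.norm(sel.com - centers[sel.marker_label])
                        )
        if ph_seed == 0:  # burn the first phantom's reference selection
            ref = generate_observer_delineations(
                truth, mr, n_observers=1, jitter_sd=0.0, seed=999
            )
            sels = [
                select_lowest_voxels(mr, expand_delineation(d, MARGIN_MM, mr), K_BURN)
                for d in ref[0]
            ]
            burned, report = burn_in_markers(sct, sels)
            write_volume(burned, SCRATCH / "sct_burned.nii")
            print(f"burned {report['n_burned']} voxels at 3000 HU "
                  f"({len(truth)} markers x k={K_BURN}) into the sCT")

    coms = pd.DataFrame(rows)
    n_markers = coms["marker_label"].nunique()
    print(f"\n{n_markers} markers x {N_OBSERVERS} observers, k swept 1..15")
    print(f"k={K_BURN} COM error vs truth: mean {np.mean(com_err_k6):.2f} mm, "
          f"max {np.max(com_err_k6):.2f} mm")

    summary_rows = []
    for k in (1, 6, 12):
        var = com_variability(coms[coms.k == k])
        pm = var["per_marker"]
        for comp in ("RL", "AP", "CC"):
            col = f"sd_{comp}_mm"
            summary_rows.append({
                "k": k, "component": comp,
                "mean_sd_mm": pm[col].mean(), "max_sd_mm": pm[col].max(),
                "frac_below_0.5mm": float((pm[col] < 0.5).mean()),
            })
        var["cumulative"].assign(k=k).to_csv(
            RESULTS / f"com_variability_cumulative_k{k}.csv", index=False
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(RESULTS / "com_variability_summary.csv", index=False)

    # convenience figure: cumulative histograms of per-marker COM SDs
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharey=True)
    for ax, comp in zip(axes, ("RL", "CC", "AP")):
        for k, color in ((1, "tab:blue"), (6, "tab:green"), (12, "tab:red")):
            pm = com_variability(coms[coms.k == k])["per_marker"]
            sds = np.sort(pm[f"sd_{comp}_mm"])
            frac_above = 1.0 - np.arange(1, len(sds) + 1) / len(sds)
            ax.step(sds, 100 * frac_above, where="post", color=color,
                    label=f"k={k}")
        ax.set_title(comp)
        ax.set_xlabel("SD of COM component (mm)")
    axes[0].set_ylabel("% of markers with SD > x")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(SCRATCH.parent / "com_variability_cumulative.png", dpi=120)
    print("\nper-component COM scatter across observers:")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("\nCC scatter is the largest component (slice direction, 2.5 mm); "
          "RL/AP scatter stays sub-voxel. k=1 scatter is zero here because "
          "every observer's jittered ROI still contains the single deepest "
          "void voxel; larger k admits voxels near the ROI boundary, where "
          "observers differ.")


if __name__ == "__main__":
    main()
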