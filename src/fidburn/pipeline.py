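"""Run configuration and the end-to-end simulation pipeline.

``run_end_to_end`` chains the three sub-studies on one synthetic cohort:

  simulate phantom -> burn markers into the sCT -> inter-observer COM
  variability -> marker-based CT-sCT registration and correction of
  position-verification registrations -> population / inter-observer
  error statistics.

Every artifact is stamped with a hash of the run configuration and the
seeds in use; two runs with an identical config produce identical files.
All randomness derives from ``RunConfig.seed`` through a documented
sequence of child seeds (phantom, delineations, cohort, IOE cohorts,
marker noise), with no hidden global state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burnin, phantom, rigid, stats
from .volume import ImageVolume, read_volume, write_volume  # noqa: F401 (re-export)

__all__ = ["RunConfig", "StageError", "run_end_to_end", "observers_to_coms"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, reproducible from the seed."""

    seed: int = 0
    k: int = burnin.DEFAULT_K
    margin_mm: float = burnin.DEFAULT_MARGIN_MM
    burn_hu: float = burnin.DEFAULT_BURN_HU
    n_observers: int = 7
    jitter_sd_mm: float = 0.5
    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    # position-verification cohort (per-fraction CT-CBCT registrations)
    cohort_n_patients: int = 10
    cohort_n_fractions: int = 8
    cohort_mean: tuple = (-0.2, -0.7, -0.3, -0.5, 0.8, -0.6)
    cohort_systematic_sd: tuple = (2.8, 3.8, 2.9, 4.6, 2.7, 2.4)
    cohort_random_sd: tuple = (3.3, 2.7, 2.9, 4.4, 2.2, 1.4)
    # true CT<->sCT patient repositioning between the two scans
    ct_sct_params: tuple = (3.0, -2.0, 1.5, 1.0, -0.8, 0.5)
    marker_noise_mm: float = 0.0
    # inter-observer study: observer scatter per workflow
    ioe_n_patients: int = 20
    ioe_n_observers: int = 7
    ioe_random_sd_ct: tuple = (0.87, 1.26, 1.32, 1.97, 1.17, 1.18)
    ioe_random_sd_sct: tuple = (0.25, 0.30, 0.40, 0.59, 0.42, 0.43)
    ioe_patient_sd: float = 2.0

    def child_seeds(self) -> dict:
        """Named integer child seeds (fixed order, < 2**31)."""
        ss = np.random.SeedSequence(self.seed)
        names = ["phantom", "delineations", "cohort", "ioe_ct", "ioe_sct", "marker_noise"]
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = dataclasses.asdict(self.phantom)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        if isinstance(ph, dict):
            ph = {**ph}
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "spacing" in ph:
                ph["spacing"] = tuple(ph["spacing"])
            ph = phantom.PhantomConfig(**ph)
        return cls(phantom=ph, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def observers_to_coms(
    observer_delins, mr_volume: ImageVolume, margin_mm: float, k: int,
    burn_hu: float = burnin.DEFAULT_BURN_HU,
) -> tuple[pd.DataFrame, list]:
    """Run expand -> select -> COM for every observer delineation.

    Returns the COM table (marker_label, observer_id, k, COM components)
    and the list of voxel selections (for burn-in).
    """
    rows = []
    selections = []
    for delins in observer_delins:
        for d in delins:
            roi = burnin.expand_delineation(d, margin_mm, mr_volume)
            sel = burnin.select_lowest_voxels(mr_volume, roi, k, burn_hu=burn_hu)
            selections.append(sel)
            rows.append({
                "marker_label": sel.marker_label,
                "observer_id": sel.observer_id,
                "k": sel.k,
                "x_RL_mm": sel.com[0],
                "y_AP_mm": sel.com[1],
                "z_CC_mm": sel.com[2],
            })
    return pd.DataFrame(rows), selections


def write_delineations_csv(observer_delins, path) -> None:
    rows = []
    for delins in observer_delins:
        for d in delins:
            for v in d.voxels:
                rows.append({
                    "observer_id": d.observer_id,
                    "marker_label": d.marker_label,
                    "i_RL": v[0], "j_AP": v[1], "k_CC": v[2],
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_delineations_csv(path) -> list:
    """Delineations grouped per observer (inverse of the writer)."""
    df = pd.read_csv(path)
    observers = []
    for _, obs_grp in df.groupby("observer_id", sort=True):
        delins = []
        for label, grp in obs_grp.groupby("marker_label", sort=True, dropna=False):
            delins.append(burnin.Delineation(
                voxels=grp[["i_RL", "j_AP", "k_CC"]].to_numpy(),
                observer_id=str(grp["observer_id"].iloc[0]),
                marker_label=None if pd.isna(label) else str(label),
            ))
        observers.append(delins)
    return observers


def _record_to_transform(row, center) -> rigid.RigidTransform6:
    return rigid.RigidTransform6(
        t_rl=row["tRL_mm"], t_cc=row["tCC_mm"], t_ap=row["tAP_mm"],
        r_rl=row["rRL_deg"], r_cc=row["rCC_deg"], r_ap=row["rAP_deg"],
        center=center,
    )


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # propagate with the stage name
                raise StageError(name, exc) from exc
        return wrapped
    return decorate


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Run the full simulated workflow; returns a manifest of artifacts.

    Products, all under ``out_dir``: the phantom MR/sCT pair and the
    burned sCT (NIfTI), the ground-truth marker table, per-observer COM
    table and COM-variability report, the corrected position-verification
    comparison (difference decomposition), the inter-observer and
    population-error tables, and ``run_log.json`` recording the config
    hash, child seeds and every active numerical convention.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.child_seeds()
    manifest: dict = {"out_dir": str(out), "config_hash": config.config_hash()}

    @_stage("simulate")
    def stage_simulate():
        ph = dataclasses.replace(config.phantom, seed=seeds["phantom"])
        mr, sct, truth = phantom.generate_phantom(ph)
        write_volume(mr, out / "mr.nii")
        write_volume(sct, out / "sct.nii")
        phantom.truth_to_frame(truth).to_csv(out / "truth_markers.csv", index=False)
        return mr, sct, truth

    mr, sct, truth = stage_simulate()

    @_stage("burnin")
    def stage_burnin():
        delins = phantom.generate_observer_delineations(
            truth, mr, n_observers=1, jitter_sd=0.0, misid_prob=0.0,
            seed=seeds["delineations"],
        )
        write_delineations_csv(delins, out / "delineations_reference.csv")
        coms, selections = observers_to_coms(
            delins, mr, config.margin_mm, config.k, burn_hu=config.burn_hu
        )
        burned, report = burnin.burn_in_markers(sct, selections)
        write_volume(burned, out / "sct_burned.nii")
        coms.to_csv(out / "reference_coms.csv", index=False)
        return coms, burned, report

    ref_coms, burned, burn_report = stage_burnin()
    manifest["burn_report"] = burn_report

    @_stage("com_variability")
    def stage_comvar():
        delins = phantom.generate_observer_delineations(
            truth, mr, n_observers=config.n_observers,
            jitter_sd=config.jitter_sd_mm, misid_prob=0.0,
            seed=seeds["delineations"] + 1,
        )
        coms, _ = observers_to_coms(delins, mr, config.margin_mm, config.k)
        coms.to_csv(out / "observer_coms.csv", index=False)
        var = burnin.com_variability(coms)
        var["per_marker"].to_csv(out / "com_variability.csv", index=False)
        var["cumulative"].to_csv(out / "com_variability_cumulative.csv", index=False)
        return var

    comvar = stage_comvar()
    manifest["com_variability_excluded"] = comvar["n_excluded"]

    @_stage("registration_correction")
    def stage_correction():
        truth_pts = np.array([m.center for m in truth])
        labels = [m.label for m in truth]
        ct_sct_true = rigid.RigidTransform6(
            *config.ct_sct_params, center=truth_pts.mean(axis=0)
        )
        ct_pts = rigid.transform_points(ct_sct_true, truth_pts)
        if config.marker_noise_mm > 0:
            nrng = np.random.default_rng(seeds["marker_noise"])
            ct_pts = ct_pts + nrng.normal(0, config.marker_noise_mm, ct_pts.shape)
        pairs = rigid.match_markers(ct_pts, truth_pts, labels, labels)
        ct_sct_fit = rigid.fit_rigid(pairs)
        rms = rigid.residual_rms(pairs, ct_sct_fit)
        with open(out / "ct_sct_registration.json", "w") as fh:
            json.dump({"transform": ct_sct_fit.to_dict(), "residual_rms_mm": rms},
                      fh, indent=2)

        design = phantom.StudyDesign(
            n_patients=config.cohort_n_patients,
            n_raters_or_fractions=config.cohort_n_fractions,
            population_mean=np.array(config.cohort_mean),
            systematic_sd=np.array(config.cohort_systematic_sd),
            random_sd=np.array(config.cohort_random_sd),
            seed=seeds["cohort"],
        )
        ct_cbct = phantom.simulate_registration_study(design, workflow="CT")
        center = truth_pts.mean(axis=0)
        inv_true = rigid.invert(ct_sct_true)
        rows = []
        for _, row in ct_cbct.iterrows():
            T_ct = _record_to_transform(row, center)
            # the same fraction seen from the sCT frame, then corrected back
            T_sct = rigid.compose(inv_true, T_ct)
            corrected = rigid.correct_registration(T_sct, ct_sct_fit)
            rec = {
                "patient_id": row["patient_id"],
                "rater_or_fraction_id": row["rater_or_fraction_id"],
                "workflow": "MR-only",
            }
            rec.update(corrected.params())
            rows.append(rec)
        both = pd.concat([pd.DataFrame(rows), ct_cbct], ignore_index=True)
        both.to_csv(out / "position_verification_records.csv", index=False)
        diff = stats.registration_difference_stats(
            both, workflows=("MR-only", "CT")
        )
        diff_table = diff.table.copy()
        diff_table["p_mean_vs_zero"] = diff.pvalues
        diff_table.to_csv(out / "difference_stats.csv")
        pop = stats.population_errors(ct_cbct)
        pop.table.to_csv(out / "population_errors.csv")
        return rms, diff, pop

    rms, diff, pop = stage_correction()
    manifest["ct_sct_residual_rms_mm"] = rms

    @_stage("ioe")
    def stage_ioe():
        common = dict(
            n_patients=config.ioe_n_patients,
            n_raters_or_fractions=config.ioe_n_observers,
            population_mean=np.zeros(6),
            systematic_sd=np.full(6, config.ioe_patient_sd),
        )
        rec_ct = phantom.simulate_registration_study(
            phantom.StudyDesign(**common, random_sd=np.array(config.ioe_random_sd_ct),
                                seed=seeds["ioe_ct"]),
            workflow="CT/MR",
        )
        rec_sct = phantom.simulate_registration_study(
            phantom.StudyDesign(**common, random_sd=np.array(config.ioe_random_sd_sct),
                                seed=seeds["ioe_sct"]),
            workflow="MR-only",
        )
        both = pd.concat([rec_ct, rec_sct], ignore_index=True)
        both.to_csv(out / "ioe_records.csv", index=False)
        ioe = stats.ioe_summary(both, workflows=("CT/MR", "MR-only"))
        ioe.table.to_csv(out / "ioe_table.csv")
        return ioe

    ioe = stage_ioe()

    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "child_seeds": seeds,
        "settings": {
            "k": config.k,
            "margin_mm": config.margin_mm,
            "burn_hu": config.burn_hu,
            "quantile_rule": "linear interpolation (type 7)",
            "angle_convention": "extrinsic rotations about fixed RL, CC, AP axes, "
                                "in that order, degrees",
            "tie_break": "ascending raster order (CC-major, then AP, then RL)",
            "sigma_definition": "RMS of per-patient SDs",
            "wilcoxon_zeros": "dropped",
            "levene_variant": "Brown-Forsythe (median-centered)",
        },
        "burn_report": burn_report,
        "config": config.to_dict(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    manifest["ioe_unpaired"] = ioe.n_unpaired_patients
    manifest["files"] = sorted(p.name for p in out.iterdir())
    return manifest
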