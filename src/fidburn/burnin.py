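"""Semi-automatic fiducial-marker burn-in on a synthetic CT.

Gold fiducial markers (FMs) implanted in the prostate appear as signal
voids on the water-only Dixon MR image but are absent from the synthetic
CT (sCT), which contains only five tissue classes.  The burn-in procedure
makes FM-based position verification possible:

1. an observer delineates each signal void on three slices;
2. the delineation is isotropically expanded by a physical margin
   (default 2 mm, anisotropic voxel spacing respected);
3. the k lowest-intensity voxels inside the expanded region are selected
   (default k = 6);
4. their unweighted center of mass (COM) is the marker position estimate;
5. the selected voxels are written into the sCT at a fixed CT number
   (default 3000 HU).

Inter-observer variability of the resulting COM positions is summarized
per marker as the SD of the RL, CC and AP components, with a cumulative
fraction-below-threshold summary across markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .volume import ImageVolume, raster_order_key

DEFAULT_K = 6
DEFAULT_MARGIN_MM = 2.0
DEFAULT_BURN_HU = 3000.0

__all__ = [
    "Delineation",
    "MarkerVoxelSelection",
    "expand_delineation",
    "select_lowest_voxels",
    "compute_com",
    "burn_in_markers",
    "label_coms_by_truth",
    "com_variability",
]


@dataclass
class Delineation:
    """A set of voxel indices outlining one marker's signal void.

    ``voxels`` is an (N, 3) integer array of grid indices; ``marker_label``
    may be None for delineations not (yet) matched to a ground-truth
    marker, e.g. a misidentified structure.
    """

    voxels: np.ndarray
    observer_id: str = "obs0"
    marker_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError("delineation is empty")
        if self.voxels.shape[1] != 3:
            raise ValueError("voxels must be an (N, 3) index array")
        # deduplicate, keep deterministic order
        self.voxels = np.unique(self.voxels, axis=0)

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class MarkerVoxelSelection:
    """The k voxels chosen for burn-in, their COM, and the burn-in HU."""

    voxels: np.ndarray
    com: np.ndarray
    k: int
    burn_hu: float = DEFAULT_BURN_HU
    marker_label: Optional[str] = None
    observer_id: str = "obs0"

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        self.com = np.asarray(self.com, dtype=float)
        if self.k != len(self.voxels):
            raise ValueError(f"k={self.k} but {len(self.voxels)} voxels selected")
        if len(np.unique(self.voxels, axis=0)) != len(self.voxels):
            raise ValueError("selected voxels must be pairwise distinct")


def _ball_offsets(margin: float, spacing: np.ndarray) -> np.ndarray:
    """Integer voxel offsets whose physical length is <= margin (mm)."""
    reach = np.floor(margin / spacing).astype(int)
    rng = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    phys = grid * spacing
    return grid[np.einsum("ij,ij->i", phys, phys) <= margin**2 + 1e-12]


def expand_delineation(
    mask: Delineation, margin: float, geometry: ImageVolume
) -> Delineation:
    """Isotropic physical expansion of a delineation.

    Returns exactly the voxels whose center lies within Euclidean physical
    distance ``margin`` (mm) of some input voxel center.  Expansion is done
    in 3D physical space, so the anisotropic spacing (e.g. 2.5 mm slices vs
    1.7 mm in-plane) shrinks the reach in the slice direction.  The output
    is clipped to the grid and is always a superset of the input.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    offsets = _ball_offsets(margin, geometry.spacing)
    expanded = (mask.voxels[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    expanded = expanded[
        np.all(expanded >= 0, axis=1)
        & np.all(expanded < np.array(geometry.shape), axis=1)
    ]
    expanded = np.unique(expanded, axis=0)
    return Delineation(expanded, mask.observer_id, mask.marker_label)


def select_lowest_voxels(
    image: ImageVolume, roi: Delineation, k: int = DEFAULT_K,
    burn_hu: float = DEFAULT_BURN_HU,
) -> MarkerVoxelSelection:
    """Select the k lowest-intensity voxels within the ROI.

    Ties are broken by ascending raster order (CC-major, then AP, then RL)
    so the selection is deterministic across runs and platforms.  Voxels
    are returned in selection order (lowest first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(roi):
        raise ValueError(f"k={k} exceeds ROI size {len(roi)}")
    vox = roi.voxels
    intensities = image.values[vox[:, 0], vox[:, 1], vox[:, 2]]
    order = np.lexsort((raster_order_key(vox, image.shape), intensities))
    chosen = vox[order[:k]]
    return MarkerVoxelSelection(
        voxels=chosen,
        com=compute_com_indices(chosen, image),
        k=k,
        burn_hu=burn_hu,
        marker_label=roi.marker_label,
        observer_id=roi.observer_id,
    )


def compute_com_indices(voxels: np.ndarray, geometry: ImageVolume) -> np.ndarray:
    """Unweighted mean of the physical centers of the given voxels (mm)."""
    voxels = np.atleast_2d(np.asarray(voxels))
    if voxels.size == 0:
        raise ValueError("cannot compute COM of an empty selection")
    return geometry.voxel_to_physical(voxels).mean(axis=0)


def compute_com(selection: MarkerVoxelSelection, geometry: ImageVolume) -> np.ndarray:
    """COM of a voxel selection: unweighted mean of voxel centers (mm)."""
    return compute_com_indices(selection.voxels, geometry)


def burn_in_markers(
    sct: ImageVolume, selections: list[MarkerVoxelSelection]
) -> tuple[ImageVolume, dict]:
    """Write the selected voxels into the sCT at their burn-in HU.

    Returns the burned volume plus a small report: the number of modified
    voxels (a voxel claimed by two overlapping selections is burned once
    and counted once) and the count of such shared voxels.
    """
    out = sct.copy()
    seen: dict[tuple, int] = {}
    for sel in selections:
        if np.any(sel.voxels < 0) or np.any(sel.voxels >= np.array(sct.shape)):
            raise ValueError(
                f"selection for marker {sel.marker_label!r} has voxels outside "
                f"the {sct.shape} grid"
            )
        for v in map(tuple, sel.voxels):
            seen[v] = seen.get(v, 0) + 1
            out.values[v] = sel.burn_hu
    n_shared = sum(1 for c in seen.values() if c > 1)
    return out, {"n_burned": len(seen), "n_shared_voxels": n_shared}


def label_coms_by_truth(
    coms: pd.DataFrame, truth_positions: dict, gate_mm: float = 5.0
) -> pd.DataFrame:
    """Attach marker labels to COM rows by nearest ground-truth marker.

    ``coms`` needs columns observer_id, x_RL_mm, y_AP_mm, z_CC_mm;
    ``truth_positions`` maps label -> 3-vector (mm).  COMs farther than
    ``gate_mm`` from every truth marker stay unlabelled (NaN) — e.g. a
    delineation placed on a calcification.
    """
    labels = list(truth_positions)
    pos = np.array([truth_positions[lab] for lab in labels])
    pts = coms[["x_RL_mm", "y_AP_mm", "z_CC_mm"]].to_numpy()
    dist = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    nearest = dist.argmin(axis=1)
    out = coms.copy()
    out["marker_label"] = [
        labels[j] if dist[i, j] <= gate_mm else None
        for i, j in enumerate(nearest)
    ]
    return out


def _greedy_label_coms(coms: pd.DataFrame, gate_mm: float = 5.0) -> pd.DataFrame:
    """Cluster unlabelled COMs greedily by nearest existing cluster center."""
    out = coms.copy().reset_index(drop=True)
    centers: list[np.ndarray] = []
    members: list[list[int]] = []
    for i, p in enumerate(out[["x_RL_mm", "y_AP_mm", "z_CC_mm"]].to_numpy()):
        if centers:
            d = np.linalg.norm(np.array(centers) - p, axis=1)
            j = int(d.argmin())
            if d[j] <= gate_mm:
                members[j].append(i)
                pts = out.loc[members[j], ["x_RL_mm", "y_AP_mm", "z_CC_mm"]]
                centers[j] = pts.mean().to_numpy()
                continue
        centers.append(p.astype(float))
        members.append([i])
    lab = np.empty(len(out), dtype=object)
    for j, idx in enumerate(members):
        lab[idx] = f"cluster{j}"
    out["marker_label"] = lab
    return out


def com_variability(
    coms: pd.DataFrame,
    thresholds_mm=(0.5, 1.0, 1.5, 2.0, 2.5),
    gate_mm: float = 5.0,
) -> dict:
    """Inter-observer variability of marker COM positions.

    Parameters
    ----------
    coms : DataFrame
        One row per (marker, observer) COM with columns marker_label,
        observer_id, x_RL_mm, y_AP_mm, z_CC_mm.  Rows with missing labels
        are clustered by greedy nearest-COM matching within ``gate_mm``.
    thresholds_mm : sequence
        Thresholds for the cumulative summary.

    Returns
    -------
    dict with keys
        ``per_marker`` — DataFrame of sample SDs (n-1 denominator) of the
        RL, CC, AP components per marker, with observer counts;
        ``cumulative`` — DataFrame: per threshold and component, the
        fraction of markers whose SD is below the threshold;
        ``n_excluded`` — markers dropped for having < 2 observers.
    """
    if "marker_label" not in coms.columns or coms["marker_label"].isna().any():
        labelled = coms[coms.get("marker_label").notna()] if "marker_label" in coms else coms.iloc[0:0]
        unlabelled = coms[coms["marker_label"].isna()] if "marker_label" in coms else coms
        if len(unlabelled):
            unlabelled = _greedy_label_coms(unlabelled, gate_mm)
        coms = pd.concat([labelled, unlabelled], ignore_index=True)
    rows = []
    n_excluded = 0
    for label, grp in coms.groupby("marker_label", sort=True):
        if len(grp) < 2:
            n_excluded += 1
            continue
        rows.append({
            "marker_label": label,
            "n_observers": len(grp),
            "sd_RL_mm": grp["x_RL_mm"].std(ddof=1),
            "sd_AP_mm": grp["y_AP_mm"].std(ddof=1),
            "sd_CC_mm": grp["z_CC_mm"].std(ddof=1),
        })
    per_marker = pd.DataFrame(rows)
    cum_rows = []
    for thr in thresholds_mm:
        row = {"threshold_mm": thr}
        for comp in ("RL", "AP", "CC"):
            col = f"sd_{comp}_mm"
            frac = float((per_marker[col] < thr).mean()) if len(per_marker) else np.nan
            row[f"frac_below_{comp}"] = frac
        cum_rows.append(row)
    return {
        "per_marker": per_marker,
        "cumulative": pd.DataFrame(cum_rows),
        "n_excluded": n_excluded,
    }
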