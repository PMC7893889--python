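"""Synthetic pelvis phantom and registration-cohort simulation.

Patient data behind MR-only prostate radiotherapy studies are not
shareable, so every analysis here runs on simulated inputs with known
ground truth:

* a water-Dixon-like MR volume in which cylindrical gold fiducial markers
  (1 mm diameter, 5 mm length) appear as signal voids, with optional
  calcification confounders that look just like marker voids;
* a co-registered five-material synthetic CT (air, compact bone, spongy
  bone, fat, water-rich tissue) sharing the MR frame of reference;
* observer-perturbed three-slice delineations of the voids;
* cohorts of 6-parameter registration records drawn from a
  mean + per-patient systematic + per-fraction random Gaussian model, the
  generative inverse of the population-error decomposition.

All randomness flows from explicit seeds through
``numpy.random.SeedSequence`` children spawned in a fixed, documented
order (marker placement, calcifications, noise), so phantoms are
bit-identical across runs for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .burnin import Delineation
from .stats import PARAM_COLUMNS
from .volume import ImageVolume

MATERIALS = ("air", "compact_bone", "spongy_bone", "fat", "water")

DEFAULT_HU_MAP = {
    "air": -1000.0,
    "fat": -100.0,
    "water": 30.0,
    "spongy_bone": 200.0,
    "compact_bone": 700.0,
}

# MR base intensity per material (arbitrary units); only the rank ordering
# near the voids matters for the burn-in analyses
_MR_INTENSITY = {
    "air": 5.0,
    "compact_bone": 100.0,
    "spongy_bone": 300.0,
    "fat": 800.0,
    "water": 500.0,
}


class PlacementError(RuntimeError):
    """Marker placement failed after bounded retries (markers overlap)."""


@dataclass
class PhantomConfig:
    """Geometry and appearance of the synthetic pelvis phantom.

    Defaults follow the water-Dixon acquisition grid (1.7 x 1.7 mm
    in-plane, 2.5 mm slices) and the implanted-marker geometry (four gold
    cylinders, 1 mm diameter x 5 mm length).  ``void_contrast`` is the
    fractional MR intensity drop of a fully marker-occupied voxel relative
    to the local background; the true void contrast on mDIXON-w is not a
    well-characterized quantity, so it is a free parameter.
    """

    grid_shape: tuple = (64, 64, 48)
    spacing: tuple = (1.7, 1.7, 2.5)
    n_markers: int = 4
    marker_diameter: float = 1.0
    marker_length: float = 5.0
    void_contrast: float = 0.6
    void_dilation: float = 2.0
    noise_sd: float = 0.0
    n_calcifications: int = 0
    hu_map: dict = field(default_factory=lambda: dict(DEFAULT_HU_MAP))
    seed: int = 0
    max_axis_tilt_deg: float = 30.0
    min_separation_mm: float = 10.0
    supersample: int = 3

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.marker_diameter >= self.marker_length:
            raise ValueError("marker diameter must be smaller than its length")
        if set(self.hu_map) != set(MATERIALS):
            raise ValueError(f"hu_map must have exactly the five materials {MATERIALS}")
        if not 0 <= self.void_contrast <= 1:
            raise ValueError("void_contrast must be in [0, 1]")
        if self.void_dilation < 1.0:
            raise ValueError("void_dilation must be >= 1 (void covers the marker)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def void_halo_mm(self) -> float:
        """Radial growth of the signal void beyond the physical marker.

        Susceptibility dephasing around a gold cylinder darkens a region
        larger than the metal itself; the halo scales the void diameter by
        ``void_dilation`` and extends its length by the same absolute
        amount on each end.
        """
        return 0.5 * (self.void_dilation - 1.0) * self.marker_diameter


@dataclass
class GroundTruthMarker:
    """True marker cylinder: center (mm), unit axis, label."""

    center: np.ndarray
    axis: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError("marker axis must be a unit vector")


@dataclass
class StudyDesign:
    """Generative parameters of a simulated registration cohort.

    The six parameters follow :data:`PARAM_COLUMNS` order (translations
    RL, CC, AP in mm; rotations about RL, CC, AP in degrees).  Each patient
    draws one systematic offset from N(population_mean, systematic_sd^2);
    each fraction (or rater) adds independent N(0, random_sd^2) noise.
    """

    n_patients: int
    n_raters_or_fractions: int
    population_mean: np.ndarray = field(default_factory=lambda: np.zeros(6))
    systematic_sd: np.ndarray = field(default_factory=lambda: np.zeros(6))
    random_sd: np.ndarray = field(default_factory=lambda: np.zeros(6))
    seed: int = 0

    def __post_init__(self) -> None:
        self.population_mean = np.broadcast_to(
            np.asarray(self.population_mean, dtype=float), (6,)
        ).copy()
        self.systematic_sd = np.broadcast_to(
            np.asarray(self.systematic_sd, dtype=float), (6,)
        ).copy()
        self.random_sd = np.broadcast_to(
            np.asarray(self.random_sd, dtype=float), (6,)
        ).copy()
        if self.n_patients < 1 or self.n_raters_or_fractions < 1:
            raise ValueError("counts must be >= 1")
        if np.any(self.systematic_sd < 0) or np.any(self.random_sd < 0):
            raise ValueError("SDs must be >= 0")


def _phantom_geometry(config: PhantomConfig):
    """Material labels on the grid plus the prostate-region center/radius."""
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=float)
    extent = (np.array(shape) - 1) * spacing
    center = extent / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    phys = np.stack([ii * spacing[0], jj * spacing[1], kk * spacing[2]], axis=-1)
    # body: elliptical cylinder along CC
    a, b = 0.45 * extent[0], 0.42 * extent[1]
    rho = np.sqrt(
        ((phys[..., 0] - center[0]) / a) ** 2 + ((phys[..., 1] - center[1]) / b) ** 2
    )
    materials = np.full(shape, "air", dtype=object)
    materials[rho <= 1.0] = "fat"
    materials[rho <= 0.82] = "water"
    # femoral-head-like bone spheres, compact shell with spongy core
    bone_r = min(10.0, 0.18 * extent[0])
    for side in (-1.0, 1.0):
        bc = center + np.array([side * 0.30 * extent[0], 0.0, 0.0])
        d = np.linalg.norm(phys - bc, axis=-1)
        materials[d <= bone_r] = "compact_bone"
        materials[d <= 0.6 * bone_r] = "spongy_bone"
    prostate_r = min(16.0, 0.28 * min(a, b))
    return materials, phys, center, prostate_r


def _sample_cap_direction(rng: np.random.Generator, max_tilt_deg: float) -> np.ndarray:
    """Uniform unit vector within max_tilt_deg of the +CC axis."""
    cos_max = np.cos(np.deg2rad(max_tilt_deg))
    cos_t = 1.0 - rng.random() * (1.0 - cos_max)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
    phi = rng.random() * 2 * np.pi
    return np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _carve_cylinder_void(
    mr: np.ndarray, vol_geom: ImageVolume, center: np.ndarray, axis: np.ndarray,
    length: float, diameter: float, contrast: float, supersample: int,
) -> None:
    """Multiply MR intensities by (1 - contrast * occupancy) for a cylinder.

    Occupancy per voxel is estimated by supersampling each voxel into
    ``supersample**3`` points; a 1 mm cylinder is sub-voxel on this grid
    and naive center-in/out rasterization would drop it entirely.
    """
    spacing = vol_geom.spacing
    half = length / 2.0 + diameter / 2.0
    lo = vol_geom.physical_to_voxel(center - half - spacing)
    hi = vol_geom.physical_to_voxel(center + half + spacing)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(vol_geom.shape) - 1)
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    vox = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    ss = supersample
    offs1d = (np.arange(ss) + 0.5) / ss - 0.5
    sub = np.stack(np.meshgrid(offs1d, offs1d, offs1d, indexing="ij"), axis=-1)
    sub = sub.reshape(-1, 3) * spacing  # (ss^3, 3) physical offsets in a voxel
    pts = vol_geom.voxel_to_physical(vox)[:, None, :] + sub[None, :, :]
    rel = pts - center
    axial = rel @ axis
    radial = np.linalg.norm(rel - axial[..., None] * axis, axis=-1)
    inside = (np.abs(axial) <= length / 2.0) & (radial <= diameter / 2.0)
    occ = inside.mean(axis=1)
    hit = occ > 0
    v = vox[hit]
    mr[v[:, 0], v[:, 1], v[:, 2]] *= 1.0 - contrast * occ[hit]


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ImageVolume, ImageVolume, list[GroundTruthMarker]]:
    """Generate the paired MR-like and sCT-like volumes with ground truth.

    The MR volume shows each marker as a signal void (intensity reduced by
    ``void_contrast`` times the cylinder occupancy of the voxel); the sCT
    contains only the five configured HU values and shares the MR geometry
    exactly, emulating the intrinsic registration of a Dixon-derived
    synthetic CT.  Calcification confounders, if requested, are small
    spheres that are voids on MR but absent from the truth table.

    Raises
    ------
    PlacementError
        If non-overlapping marker placement fails after bounded retries.
    """
    spacing = np.asarray(config.spacing, dtype=float)
    materials, _, center, prostate_r = _phantom_geometry(config)
    mr_values = np.vectorize(_MR_INTENSITY.get, otypes=[float])(materials)
    sct_values = np.vectorize(config.hu_map.get, otypes=[float])(materials)
    vol_geom = ImageVolume(mr_values, spacing)

    ss_root = np.random.SeedSequence(config.seed)
    place_ss, calc_ss, noise_ss = ss_root.spawn(3)

    rng = np.random.default_rng(place_ss)
    centers: list[np.ndarray] = []
    max_tries = 200 * config.n_markers
    tries = 0
    while len(centers) < config.n_markers:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {config.n_markers} markers with "
                f">= {config.min_separation_mm} mm separation after {max_tries} tries"
            )
        tries += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = prostate_r * rng.random() ** (1 / 3)
        cand = center + r * u
        if all(
            np.linalg.norm(cand - c) >= config.min_separation_mm for c in centers
        ):
            centers.append(cand)
    truth = [
        GroundTruthMarker(
            center=c,
            axis=_sample_cap_direction(rng, config.max_axis_tilt_deg),
            label=f"FM{i + 1}",
        )
        for i, c in enumerate(centers)
    ]
    halo = config.void_halo_mm()
    for m in truth:
        _carve_cylinder_void(
            mr_values, vol_geom, m.center, m.axis,
            config.marker_length + 2 * halo, config.marker_diameter + 2 * halo,
            config.void_contrast, config.supersample,
        )

    if config.n_calcifications > 0:
        crng = np.random.default_rng(calc_ss)
        placed = 0
        tries = 0
        while placed < config.n_calcifications and tries < 200 * config.n_calcifications:
            tries += 1
            u = crng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = center + prostate_r * crng.random() ** (1 / 3) * u
            if all(np.linalg.norm(cand - m.center) >= 7.0 for m in truth):
                _carve_cylinder_void(
                    mr_values, vol_geom, cand, np.array([0.0, 0.0, 1.0]),
                    2.0, 2.0, config.void_contrast, config.supersample,
                )
                placed += 1

    if config.noise_sd > 0:
        nrng = np.random.default_rng(noise_ss)
        mr_values = mr_values + nrng.normal(0.0, config.noise_sd, mr_values.shape)

    mr_volume = ImageVolume(mr_values, spacing)
    sct_volume = ImageVolume(sct_values, spacing)
    return mr_volume, sct_volume, truth


def generate_observer_delineations(
    truth: list[GroundTruthMarker],
    mr_volume: ImageVolume,
    n_observers: int,
    jitter_sd: float = 0.5,
    misid_prob: float = 0.0,
    seed: int = 0,
    inplane_radius_mm: float = 2.5,
) -> list[list[Delineation]]:
    """Simulate manual three-slice delineations by several observers.

    Each delineation covers exactly three consecutive slices along CC,
    centered (after Gaussian jitter of ``jitter_sd`` mm) on the marker.
    With probability ``misid_prob`` the observer instead delineates a
    spurious void-like location (emulating a misidentified marker, e.g. a
    calcification); such delineations carry no marker label.

    Returns one list of delineations per observer, in marker order.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0.0 <= misid_prob <= 1.0:
        raise ValueError("misid_prob must be a probability")
    rng = np.random.default_rng(seed)
    shape = np.array(mr_volume.shape)
    extent_center = (shape - 1) * mr_volume.spacing / 2.0

    # in-plane neighborhood: voxel offsets within inplane_radius_mm
    sp = mr_volume.spacing
    reach = np.floor(inplane_radius_mm / sp[:2]).astype(int)
    inplane = [
        (di, dj)
        for di in range(-reach[0], reach[0] + 1)
        for dj in range(-reach[1], reach[1] + 1)
        if (di * sp[0]) ** 2 + (dj * sp[1]) ** 2 <= inplane_radius_mm**2 + 1e-12
    ]

    truth_centers = np.array([m.center for m in truth])

    def spurious_point() -> np.ndarray:
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = extent_center + 15.0 * rng.random() ** (1 / 3) * u
            if np.min(np.linalg.norm(truth_centers - cand, axis=1)) >= 6.0:
                return cand
        raise RuntimeError("could not place a spurious delineation")

    observers = []
    for o in range(n_observers):
        obs_id = f"obs{o + 1}"
        delins = []
        for m in truth:
            misidentified = rng.random() < misid_prob
            target = spurious_point() if misidentified else (
                m.center + rng.normal(0.0, jitter_sd, size=3)
            )
            cv = mr_volume.physical_to_voxel(target)
            # keep the full 3-slice, in-plane-disc footprint inside the grid
            pad = np.array([reach[0], reach[1], 1])
            cv = np.clip(cv, pad, shape - 1 - pad)
            voxels = np.array([
                (cv[0] + di, cv[1] + dj, cv[2] + dk)
                for dk in (-1, 0, 1)
                for di, dj in inplane
            ])
            delins.append(Delineation(
                voxels=voxels,
                observer_id=obs_id,
                marker_label=None if misidentified else m.label,
            ))
        observers.append(delins)
    return observers


def simulate_registration_study(design: StudyDesign, workflow: str = "MR-only") -> pd.DataFrame:
    """Draw a cohort of 6-parameter registration records.

    For patient p one systematic offset s_p ~ N(population_mean,
    systematic_sd^2) is drawn; each of the patient's records is
    s_p + N(0, random_sd^2), independently per parameter.  Column layout
    matches the registration-record CSV contract (patient_id,
    rater_or_fraction_id, workflow, six parameters).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    n = design.n_raters_or_fractions
    for p in range(design.n_patients):
        s_p = design.population_mean + rng.normal(0.0, 1.0, 6) * design.systematic_sd
        vals = s_p + rng.normal(0.0, 1.0, (n, 6)) * design.random_sd
        for f in range(n):
            row = {
                "patient_id": f"P{p + 1:03d}",
                "rater_or_fraction_id": f"F{f + 1:02d}",
                "workflow": workflow,
            }
            row.update(dict(zip(PARAM_COLUMNS, vals[f])))
            rows.append(row)
    return pd.DataFrame(rows)


def truth_to_frame(truth: list[GroundTruthMarker]) -> pd.DataFrame:
    """Ground-truth markers as the CSV-shaped table."""
    return pd.DataFrame([
        {
            "label": m.label,
            "x_RL_mm": m.center[0], "y_AP_mm": m.center[1], "z_CC_mm": m.center[2],
            "axis_RL": m.axis[0], "axis_AP": m.axis[1], "axis_CC": m.axis[2],
        }
        for m in truth
    ])


def frame_to_truth(df: pd.DataFrame) -> list[GroundTruthMarker]:
    return [
        GroundTruthMarker(
            center=np.array([r.x_RL_mm, r.y_AP_mm, r.z_CC_mm]),
            axis=np.array([r.axis_RL, r.axis_AP, r.axis_CC]),
            label=r.label,
        )
        for r in df.itertuples()
    ]
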