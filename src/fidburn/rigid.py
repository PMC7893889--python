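"""6-DOF rigid transforms and marker-based point-set registration.

Position-verification registrations in image-guided prostate radiotherapy
are reported as six parameters: translations along the right-left (RL),
cranio-caudal (CC) and anterior-posterior (AP) axes in mm, and rotation
angles about those axes in degrees.  This module represents such
transforms, fits them to matched marker center-of-mass (COM) point sets by
closed-form least squares (Kabsch), composes them, and computes
per-component RMS residuals.

Angle convention (documented prominently because reported rotation values
depend on it): *extrinsic* rotations about the fixed RL, CC and AP axes,
applied in that order, in degrees; the rotation center defaults to the
centroid of the moving point set.  Points are (N, 3) arrays in (RL, AP, CC)
coordinate order, mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

# point coordinate order is (RL, AP, CC) = (x, y, z); rotations are applied
# extrinsically RL then CC then AP, i.e. scipy euler sequence "xzy"
_EULER_SEQ = "xzy"

__all__ = [
    "RigidTransform6",
    "PointCorrespondence",
    "fit_rigid",
    "transform_points",
    "compose",
    "invert",
    "residual_rms",
    "correct_registration",
    "match_markers",
]


@dataclass
class RigidTransform6:
    """Rigid transform: translations (mm) and rotations (degrees).

    ``t_rl, t_ap, t_cc`` translate along the anatomical axes; ``r_rl, r_cc,
    r_ap`` rotate about them (extrinsic, applied RL then CC then AP) around
    ``center`` (mm, in (RL, AP, CC) order).  The action on a point p is
    ``R @ (p - center) + center + t``.
    """

    t_rl: float = 0.0
    t_cc: float = 0.0
    t_ap: float = 0.0
    r_rl: float = 0.0
    r_cc: float = 0.0
    r_ap: float = 0.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("rotation center must be a 3-vector")
        # orthonormality is guaranteed by construction; validate anyway
        R = self.rotation_matrix()
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix determinant is not +1")

    @property
    def translation(self) -> np.ndarray:
        """Translation vector in point (RL, AP, CC) order."""
        return np.array([self.t_rl, self.t_ap, self.t_cc])

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            _EULER_SEQ, [self.r_rl, self.r_cc, self.r_ap], degrees=True
        ).as_matrix()

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on (RL, AP, CC, 1) columns."""
        R = self.rotation_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation - R @ self.center
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform6":
        """Re-extract the six parameters from a homogeneous matrix.

        Raises
        ------
        ValueError
            If the rotation block is not special-orthogonal, or the CC
            rotation is gimbal-degenerate (|r_cc| -> 90 deg, far outside the
            clinical range).
        """
        M = np.asarray(M, dtype=float)
        R = M[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("matrix rotation block is not a proper rotation")
        import warnings

        with warnings.catch_warnings():
            # scipy warns at gimbal lock; we raise a hard error just below
            warnings.simplefilter("ignore", UserWarning)
            r_rl, r_cc, r_ap = Rotation.from_matrix(R).as_euler(
                _EULER_SEQ, degrees=True
            )
        if abs(abs(r_cc) - 90.0) < 1e-9:
            raise ValueError(
                "gimbal-degenerate extraction: |rotation about CC| = 90 deg"
            )
        center = np.asarray(center, dtype=float)
        t = M[:3, 3] - center + R @ center
        return cls(
            t_rl=t[0], t_ap=t[1], t_cc=t[2],
            r_rl=r_rl, r_cc=r_cc, r_ap=r_ap, center=center,
        )

    def params(self) -> dict:
        """Six parameters in the reporting order used throughout."""
        return {
            "tRL_mm": self.t_rl, "tCC_mm": self.t_cc, "tAP_mm": self.t_ap,
            "rRL_deg": self.r_rl, "rCC_deg": self.r_cc, "rAP_deg": self.r_ap,
        }

    def to_dict(self) -> dict:
        d = self.params()
        d.update(
            center_RL_mm=float(self.center[0]),
            center_AP_mm=float(self.center[1]),
            center_CC_mm=float(self.center[2]),
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform6":
        center = np.array([
            d.get("center_RL_mm", 0.0),
            d.get("center_AP_mm", 0.0),
            d.get("center_CC_mm", 0.0),
        ])
        return cls(
            t_rl=float(d["tRL_mm"]), t_cc=float(d["tCC_mm"]), t_ap=float(d["tAP_mm"]),
            r_rl=float(d["rRL_deg"]), r_cc=float(d["rCC_deg"]), r_ap=float(d["rAP_deg"]),
            center=center,
        )


@dataclass
class PointCorrespondence:
    """Matched marker positions in two frames, (N, 3) mm, labelled."""

    fixed: np.ndarray
    moving: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 3:
            raise ValueError("fixed and moving must be matching (N, 3) arrays")
        if len(self.labels) != len(self.fixed):
            raise ValueError("one label per point pair required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be pairwise distinct")


def transform_points(T: RigidTransform6, points: np.ndarray) -> np.ndarray:
    """Apply rotation (about T.center) then translation to (N, 3) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R = T.rotation_matrix()
    out = (pts - T.center) @ R.T + T.center + T.translation
    return out if np.asarray(points).ndim == 2 else out[0]


def fit_rigid(pairs: PointCorrespondence) -> RigidTransform6:
    """Least-squares rigid registration of moving onto fixed points (Kabsch).

    Minimizes sum_i ||fixed_i - T(moving_i)||^2 over rigid transforms via
    SVD of the cross-covariance of the centered point sets; reflection is
    excluded (det +1).  Rotation center is the centroid of the moving set,
    so the fitted translation is simply the centroid displacement.

    Raises
    ------
    ValueError
        For fewer than 3 pairs or (near-)collinear points, where the
        6-DOF problem is under-determined.
    """
    P, Q = pairs.moving, pairs.fixed
    if len(P) < 3:
        raise ValueError(f"need >= 3 point pairs for a 6-DOF fit, got {len(P)}")
    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    Pc = P - p_bar
    Qc = Q - q_bar
    # rank < 2 after centering means the markers lie on a line
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2:
        raise ValueError("moving points are collinear: rotation under-determined")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = q_bar - R @ p_bar
    return RigidTransform6.from_matrix(M, center=p_bar)


def compose(T2: RigidTransform6, T1: RigidTransform6) -> RigidTransform6:
    """The transform equivalent to applying T1 first, then T2.

    Parameters are re-extracted in the fixed extrinsic RL-CC-AP angle
    convention; the composed transform keeps T1's rotation center.
    """
    M = T2.as_matrix() @ T1.as_matrix()
    return RigidTransform6.from_matrix(M, center=T1.center)


def invert(T: RigidTransform6) -> RigidTransform6:
    """The inverse transform, parameterized about the same center."""
    return RigidTransform6.from_matrix(np.linalg.inv(T.as_matrix()), center=T.center)


def residual_rms(pairs: PointCorrespondence, T: RigidTransform6) -> dict:
    """Per-component and overall RMS of fixed - T(moving) residuals (mm).

    The component RMS of the marker COM difference vectors is the
    registration-quality figure reported per axis; ``overall`` is the root
    mean squared Euclidean residual norm.
    """
    d = pairs.fixed - transform_points(T, pairs.moving)
    comp = np.sqrt(np.mean(d**2, axis=0))
    return {
        "RL": float(comp[0]),
        "AP": float(comp[1]),
        "CC": float(comp[2]),
        "overall": float(np.sqrt(np.mean(np.sum(d**2, axis=1)))),
    }


def correct_registration(
    sct_cbct: RigidTransform6, ct_sct: RigidTransform6
) -> RigidTransform6:
    """Express an sCT-CBCT registration in the CT frame.

    The synthetic CT and the planning CT show the patient in different
    positions; a marker-based CT-sCT rigid registration accounts for that
    offset so the corrected parameters are comparable, parameter by
    parameter, to a CT-CBCT registration.  Equals ``compose(ct_sct,
    sct_cbct)``.
    """
    return compose(ct_sct, sct_cbct)


def match_markers(
    fixed: np.ndarray,
    moving: np.ndarray,
    fixed_labels=None,
    moving_labels=None,
    ambiguity_mm: float = 2.0,
) -> PointCorrespondence:
    """Build marker correspondences by label, else greedy mutual-nearest.

    With labels on both sides, points are paired by shared label.  Without,
    pairs are formed greedily by ascending distance, requiring mutual
    nearest neighbours; if a moving marker has two fixed candidates within
    ``ambiguity_mm`` of each other the match is ambiguous and an error is
    raised rather than guessing.
    """
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    if fixed_labels is not None and moving_labels is not None:
        shared = [lab for lab in fixed_labels if lab in set(moving_labels)]
        if len(shared) < 3:
            raise ValueError(f"only {len(shared)} shared labels; need >= 3")
        fi = {lab: i for i, lab in enumerate(fixed_labels)}
        mi = {lab: i for i, lab in enumerate(moving_labels)}
        return PointCorrespondence(
            fixed=fixed[[fi[lab] for lab in shared]],
            moving=moving[[mi[lab] for lab in shared]],
            labels=list(shared),
        )
    dist = np.linalg.norm(fixed[:, None, :] - moving[None, :, :], axis=2)
    pairs = []
    used_f: set = set()
    used_m: set = set()
    for f, m in sorted(
        ((f, m) for f in range(len(fixed)) for m in range(len(moving))),
        key=lambda fm: dist[fm],
    ):
        if f in used_f or m in used_m:
            continue
        rivals = [
            g for g in range(len(fixed))
            if g != f and g not in used_f and abs(dist[g, m] - dist[f, m]) < ambiguity_mm
        ]
        if rivals:
            raise ValueError(
                f"ambiguous marker match: two fixed markers within {ambiguity_mm} mm "
                f"of moving marker {m}"
            )
        pairs.append((f, m))
        used_f.add(f)
        used_m.add(m)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} unambiguous matches; need >= 3")
    fsel, msel = zip(*pairs)
    return PointCorrespondence(
        fixed=fixed[list(fsel)], moving=moving[list(msel)],
        labels=[f"pair{i}" for i in range(len(pairs))],
    )
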