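"""Landmark-based sagittal spino-pelvic geometry.

Global frame convention (used throughout the package): x anterior, y to
the patient's left, z superior; gravity acts along -z; angles are
measured in the sagittal (x-z) plane, in degrees.

The data model mirrors multi-view radiographic reconstructions: named 3D
points per anatomical structure (17 per vertebra, 11 per rib, 23 on the
pelvis).  Point-index conventions for the structures this module reads
are given by the module-level constants below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

# -- landmark index conventions -------------------------------------------
# Vertebra (17 points): endplate corner rings are ordered anterior-left,
# anterior-right, posterior-right, posterior-left.
VERT_SUP_PLATE = (0, 1, 2, 3)     # superior endplate corners AL, AR, PR, PL
VERT_SUP_CENTER = 4
VERT_INF_PLATE = (5, 6, 7, 8)     # inferior endplate corners AL, AR, PR, PL
VERT_INF_CENTER = 9
VERT_PEDICLE_L, VERT_PEDICLE_R = 10, 11
VERT_TRANSVERSE_L, VERT_TRANSVERSE_R = 12, 13
VERT_SPINOUS = 14
VERT_ARTICULAR_L, VERT_ARTICULAR_R = 15, 16
N_VERTEBRA_POINTS = 17

# Sacrum (9 points)
SACRUM_S1_PLATE = (0, 1, 2, 3)    # S1 superior endplate corners AL, AR, PR, PL
SACRUM_S1_CENTER = 4
SACRUM_DOME_APEX = 5
SACRUM_TIP = 6
SACRUM_ALA_L, SACRUM_ALA_R = 7, 8
N_SACRUM_POINTS = 9

# Pelvis (23 points): points 0 and 1 are the femoral head centers.
PELVIS_FEMORAL_HEAD_L, PELVIS_FEMORAL_HEAD_R = 0, 1
N_PELVIS_POINTS = 23
N_RIB_POINTS = 11

VERTEBRA_NAMES = tuple(f"T{i}" for i in range(1, 13)) + \
    tuple(f"L{i}" for i in range(1, 6))


class LandmarkError(ValueError):
    """Missing or malformed landmarks."""


class LandmarkSet:
    """Named 3D anatomical points, one row per (structure, index).

    Stored as a :class:`pandas.DataFrame` with columns
    ``structure, index, x_mm, y_mm, z_mm`` (the CSV interchange schema).
    """

    COLUMNS = ("structure", "index", "x_mm", "y_mm", "z_mm")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise LandmarkError(f"landmark table missing columns {missing}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise LandmarkError("landmark coordinates must be finite")
        self._df = df.sort_values(["structure", "index"]).reset_index(drop=True)

    @classmethod
    def from_dict(cls, points: dict[str, np.ndarray]) -> "LandmarkSet":
        rows = []
        for structure, arr in points.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            for i, p in enumerate(arr):
                rows.append((structure, i, p[0], p[1], p[2]))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def structures(self) -> list[str]:
        return sorted(self._df["structure"].unique())

    def points(self, structure: str) -> np.ndarray:
        sub = self._df[self._df["structure"] == structure]
        if sub.empty:
            raise LandmarkError(f"no landmarks for structure '{structure}'")
        sub = sub.sort_values("index")
        return sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def with_points(self, structure: str, pts: np.ndarray) -> "LandmarkSet":
        df = self._df.copy()
        mask = df["structure"] == structure
        sub = df.loc[mask].sort_values("index")
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if pts.shape[0] != mask.sum():
            raise LandmarkError("point count mismatch in with_points")
        df.loc[sub.index, ["x_mm", "y_mm", "z_mm"]] = pts
        return LandmarkSet(df)

    def transform_structures(self, structures, func) -> "LandmarkSet":
        """Apply ``func((k,3) array) -> (k,3)`` to the named structures."""
        out = self
        for s in structures:
            if s in self.structures:
                out = out.with_points(s, func(self.points(s)))
        return out

    # -- CSV interchange ------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        return cls(pd.read_csv(path))

    def counts(self) -> dict[str, int]:
        return self._df.groupby("structure").size().to_dict()

    def validate_reconstruction_counts(self) -> None:
        """Check the radiographic-reconstruction point-count invariants."""
        counts = self.counts()
        for name in VERTEBRA_NAMES:
            if counts.get(name, 0) != N_VERTEBRA_POINTS:
                raise LandmarkError(
                    f"{name}: expected {N_VERTEBRA_POINTS} points, "
                    f"got {counts.get(name, 0)}")
        if counts.get("pelvis", 0) != N_PELVIS_POINTS:
            raise LandmarkError("pelvis: expected 23 points")
        for name, k in counts.items():
            if name.startswith("rib_") and k != N_RIB_POINTS:
                raise LandmarkError(f"{name}: expected 11 points, got {k}")


@dataclass
class ClassificationCutoffs:
    """Cutoffs of the sagittal-balance classification (degrees)."""

    pi_shear: float = 60.0
    ss_shear: float = 50.0
    pt_retroverted: float = 25.0


@dataclass
class SpinoPelvicParams:
    """Sagittal pelvic morphology/orientation and slip severity."""

    pi_deg: float
    ss_deg: float
    pt_deg: float
    slip_pct: float | None = None
    grade: str | None = None
    config_type: str | None = None

    def __post_init__(self) -> None:
        if abs(self.pi_deg - self.ss_deg - self.pt_deg) > 1e-6:
            raise ValueError("PI must equal SS + PT")
        if self.slip_pct is not None and self.slip_pct < 0:
            raise ValueError("slip percentage must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


@dataclass
class PlateFrame:
    """Orthonormal local frame anchored on an endplate / growth plate."""

    origin: np.ndarray
    x_axis: np.ndarray   # lateral (to the patient's right)
    y_axis: np.ndarray   # in-plane sagittal anterior direction
    z_axis: np.ndarray   # plate normal, opposed to gravity

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("plate frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("plate frame must be right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Rows are (x', y', z') expressed in the global frame."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.rotation.T


# -- dual kriging free-form deformation -----------------------------------

class SingularControlError(ValueError):
    """Coplanar or duplicate kriging controls make the system singular."""


def krige_deform(template_points: np.ndarray, source_controls: np.ndarray,
                 target_controls: np.ndarray) -> np.ndarray:
    """Deform template points by dual kriging between two control nets.

    A vector-valued interpolant with a cubic radial kernel phi(r) = r^3
    and a linear (affine) drift is fitted so that every source control
    maps exactly onto its target; the template points are then pushed
    through the fitted map.  The linear drift guarantees that an affine
    relation between the control nets is reproduced exactly everywhere.
    """
    X = np.asarray(template_points, dtype=float).reshape(-1, 3)
    S = np.asarray(source_controls, dtype=float).reshape(-1, 3)
    T = np.asarray(target_controls, dtype=float).reshape(-1, 3)
    m = S.shape[0]
    if T.shape[0] != m:
        raise ValueError("source and target control counts differ")
    if m < 4:
        raise SingularControlError("need at least 4 non-coplanar controls")
    # normalize the control net to a unit box so the radial kernel and the
    # drift block are on comparable scales (pure conditioning; the fitted
    # map is unchanged)
    center = S.mean(axis=0)
    scale = float(np.abs(S - center).max())
    if scale == 0.0:
        raise SingularControlError("duplicate control points")
    Sn = (S - center) / scale
    Xn = (X - center) / scale
    r = np.linalg.norm(Sn[:, None, :] - Sn[None, :, :], axis=2)
    if np.any((r + np.eye(m)) < 1e-9):
        raise SingularControlError("duplicate control points")
    Phi = r**3
    P = np.hstack([np.ones((m, 1)), Sn])
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = Phi
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.vstack([T, np.zeros((4, 3))])
    if np.linalg.cond(A) > 1e10:
        raise SingularControlError(
            "kriging system is singular (coplanar or degenerate controls)")
    W = np.linalg.solve(A, rhs)
    w, a = W[:m], W[m:]
    rx = np.linalg.norm(Xn[:, None, :] - Sn[None, :, :], axis=2)
    return rx**3 @ w + np.hstack([np.ones((X.shape[0], 1)), Xn]) @ a


# -- spino-pelvic parameters ----------------------------------------------

def _sagittal(v: np.ndarray) -> np.ndarray:
    """Project a 3D vector onto the sagittal plane as (x, z)."""
    return np.array([v[0], v[2]])


def _plate_midpoints(plate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    plate = np.asarray(plate, dtype=float).reshape(4, 3)
    ant = 0.5 * (plate[0] + plate[1])
    post = 0.5 * (plate[2] + plate[3])
    return ant, post


def compute_spinopelvic_params(pelvis_landmarks: LandmarkSet,
                               sacrum_landmarks: LandmarkSet | None = None,
                               slip_pct: float | None = None,
                               cutoffs: ClassificationCutoffs | None = None
                               ) -> SpinoPelvicParams:
    """PI / SS / PT from the S1 endplate corners and femoral head centers.

    PI is the angle between the perpendicular to the S1 endplate at its
    midpoint and the line to the bicoxofemoral axis midpoint; SS is the
    endplate angle to the horizontal; PT = PI - SS.
    """
    if sacrum_landmarks is None:
        sacrum_landmarks = pelvis_landmarks
    pelvis = pelvis_landmarks.points("pelvis")
    sacrum = sacrum_landmarks.points("sacrum")
    if pelvis.shape[0] < 2:
        raise LandmarkError("pelvis must include both femoral head centers")
    if sacrum.shape[0] < 4:
        raise LandmarkError("sacrum must include the S1 endplate corners")
    plate = sacrum[list(SACRUM_S1_PLATE)]
    ant, post = _plate_midpoints(plate)
    u = _sagittal(ant - post)
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise LandmarkError("degenerate S1 endplate (zero sagittal extent)")
    u = u / nu
    ss = np.degrees(np.arctan2(-u[1], u[0]))
    # perpendicular to the plate, pointing superior-anterior
    n = np.array([-u[1], u[0]])
    M = _sagittal(plate.mean(axis=0))
    H = _sagittal(0.5 * (pelvis[PELVIS_FEMORAL_HEAD_L]
                         + pelvis[PELVIS_FEMORAL_HEAD_R]))
    v = H - M
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise LandmarkError("femoral head axis coincides with plate midpoint")
    v = v / nv
    pi = np.degrees(np.arccos(np.clip(-n @ v, -1.0, 1.0)))
    params = SpinoPelvicParams(pi_deg=float(pi), ss_deg=float(ss),
                               pt_deg=float(pi - ss), slip_pct=slip_pct,
                               grade=(meyerding_grade(slip_pct)
                                      if slip_pct is not None else None))
    if params.grade is not None:
        params.config_type = classify_configuration(params, cutoffs)
    return params


def compute_slip_percentage(l5_inferior_plate: np.ndarray,
                            s1_superior_plate: np.ndarray) -> float:
    """Taillard slip percentage of L5 over S1.

    Posteroanterior displacement of the L5 inferior endplate relative to
    the S1 superior endplate, projected on the S1 in-plane AP axis and
    normalized by the S1 endplate AP width, in percent.
    """
    l5_ant, l5_post = _plate_midpoints(l5_inferior_plate)
    s1_ant, s1_post = _plate_midpoints(s1_superior_plate)
    ap = s1_ant - s1_post
    width = np.linalg.norm(ap)
    if width < 1e-9:
        raise ValueError("S1 endplate has zero AP width")
    u = ap / width
    displacement = (l5_post - s1_post) @ u
    return float(displacement / width * 100.0)


def measure_slip(landmarks: LandmarkSet) -> float:
    """Slip percentage measured directly from a landmark set."""
    l5 = landmarks.points("L5")[list(VERT_INF_PLATE)]
    s1 = landmarks.points("sacrum")[list(SACRUM_S1_PLATE)]
    return compute_slip_percentage(l5, s1)


_PELVIC_RING = ("sacrum", "pelvis")


def apply_slip(landmarks: LandmarkSet, target_slip_pct: float) -> LandmarkSet:
    """Rigidly offset pelvis+sacrum to realize a target slip percentage.

    The offset acts along the in-plane posteroanterior axis of the L5
    inferior endplate (pelvis moves posteriorly, so L5 slips anteriorly
    relative to S1); its magnitude is solved in closed form so the
    measured Taillard slip equals the target even when the L5 and S1
    plates are wedged relative to each other.
    """
    if target_slip_pct < 0:
        raise ValueError("target slip percentage must be >= 0")
    l5 = landmarks.points("L5")[list(VERT_INF_PLATE)]
    s1 = landmarks.points("sacrum")[list(SACRUM_S1_PLATE)]
    current = compute_slip_percentage(l5, s1)
    l5_ant, l5_post = _plate_midpoints(l5)
    u5 = l5_ant - l5_post
    u5 = u5 / np.linalg.norm(u5)
    s1_ant, s1_post = _plate_midpoints(s1)
    u1 = (s1_ant - s1_post)
    width = np.linalg.norm(u1)
    u1 = u1 / width
    proj = u5 @ u1
    if proj < 0.1:
        raise ValueError("L5 and S1 plates are too misaligned to apply slip")
    delta = (target_slip_pct - current) / 100.0 * width / proj
    shift = -delta * u5
    return landmarks.transform_structures(_PELVIC_RING, lambda p: p + shift)


def _rotation_y(theta_deg: float) -> np.ndarray:
    """Sagittal rotation that increases the sacral slope by theta."""
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def apply_pelvic_rotation(landmarks: LandmarkSet, target_pi: float,
                          target_ss: float, tol: float = 0.1) -> LandmarkSet:
    """Retarget PI and SS by sagittal rotations about the S1 plate center.

    A rigid rotation of sacrum+pelvis about the S1 plate center changes
    the sacral slope but leaves PI (intrinsic to the pelvis) untouched,
    so two rotations about the same center are composed: sacrum+pelvis to
    set SS, then pelvis alone (femoral heads relative to the sacrum) to
    set PT = PI - SS.  Recomputed parameters are verified against the
    targets within ``tol`` degrees.
    """
    current = compute_spinopelvic_params(landmarks, landmarks)
    center = landmarks.points("sacrum")[list(SACRUM_S1_PLATE)].mean(axis=0)

    def rotate(structs, theta, lms):
        R = _rotation_y(theta)
        return lms.transform_structures(
            structs, lambda p: (p - center) @ R.T + center)

    out = rotate(_PELVIC_RING, target_ss - current.ss_deg, landmarks)
    mid = compute_spinopelvic_params(out, out)
    target_pt = target_pi - target_ss
    out = rotate(("pelvis",), mid.pt_deg - target_pt, out)
    final = compute_spinopelvic_params(out, out)
    if abs(final.pi_deg - target_pi) > tol or abs(final.ss_deg - target_ss) > tol:
        raise RuntimeError(
            f"pelvic rotation missed targets: got PI={final.pi_deg:.3f}, "
            f"SS={final.ss_deg:.3f}")
    return out


def meyerding_grade(slip_pct: float) -> str:
    """Meyerding severity grade from the slip percentage."""
    if slip_pct < 0:
        raise ValueError("slip percentage must be >= 0")
    if slip_pct == 0:
        return "none"
    if slip_pct <= 25:
        return "I"
    if slip_pct <= 50:
        return "II"
    if slip_pct <= 75:
        return "III"
    if slip_pct <= 100:
        return "IV"
    return "V"


LOW_GRADES = ("none", "I", "II")


def classify_configuration(params: SpinoPelvicParams,
                           cutoffs: ClassificationCutoffs | None = None
                           ) -> str:
    """Sagittal-balance class: nutcracker/shear (low grade) or
    balanced/retroverted pelvis (high grade)."""
    c = cutoffs or ClassificationCutoffs()
    grade = params.grade or (meyerding_grade(params.slip_pct)
                             if params.slip_pct is not None else "none")
    if grade in LOW_GRADES:
        if params.pi_deg >= c.pi_shear and params.ss_deg >= c.ss_shear:
            return "shear"
        return "nutcracker"
    if params.pt_deg >= c.pt_retroverted:
        return "retroverted"
    return "balanced"
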