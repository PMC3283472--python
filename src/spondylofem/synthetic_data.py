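"""Synthetic stand-in for the multi-view radiographic reconstruction.

Builds a parametric adolescent thoracolumbar/pelvic template whose
sagittal spino-pelvic parameters (PI, SS, slip percentage) can be dialed
exactly, emits the reconstruction-style landmark sets (17 points per
vertebra, 11 per rib, 23 on the pelvis, with configurable Gaussian
reconstruction noise), and meshes the L4-pelvis segment into a hybrid
model: hexahedral solids with anatomical material regions (cortical
shell, trabecular core, annulus/nucleus, three-zone growth plates,
sacral dome), a beam chain for T1-L3 plus an optional simplified rib
cage, the posterior arch of L5 with removable bilateral pars elements,
and tension-only ligament springs.

Default patient scalars: age 14 y, height 157.2 cm, weight 45.5 kg,
PI 61 deg, SS 52 deg, Grade II slip (30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem.elements import BeamElement, BeamSection, SpringElement
from .fem.mesh import SpineModel
from .geometry import (
    LandmarkSet,
    SpinoPelvicParams,
    VERTEBRA_NAMES,
    VERT_INF_CENTER,
    VERT_INF_PLATE,
    VERT_SUP_CENTER,
    VERT_SUP_PLATE,
    SACRUM_S1_PLATE,
    apply_slip,
    compute_spinopelvic_params,
    measure_slip,
    meyerding_grade,
    classify_configuration,
)

REFERENCE_HEIGHT_CM = 157.2

LUMBAR_NAMES = ("L1", "L2", "L3", "L4", "L5")
THORACIC_NAMES = tuple(f"T{i}" for i in range(1, 13))


@dataclass
class PatientScalars:
    age_yr: float = 14.0
    height_cm: float = 157.2
    weight_kg: float = 45.5


@dataclass
class CurveAngles:
    """Sagittal curvature of the template spine (degrees).

    Defaults sit in adolescent normative ranges; the source geometry's
    own curvature is not part of the published parameter set, so these
    are exposed rather than hard-coded deeper down.
    """

    lumbar_lordosis_deg: float = 65.0
    thoracic_kyphosis_deg: float = 40.0


# share of the total lumbar lordosis taken up at each junction, caudal to
# cranial (S1-L5 ... L2-L1); most sagittal curvature sits at L4-S1
_LORDOSIS_WEIGHTS = (0.30, 0.25, 0.20, 0.15, 0.10)


@dataclass
class TemplateModel:
    """Parametric geometry realizing a requested spino-pelvic state."""

    landmarks: LandmarkSet
    params: SpinoPelvicParams
    patient: PatientScalars
    curve: CurveAngles
    dome_height_mm: float = 3.0

    def vertebral_centroids(self) -> dict[str, np.ndarray]:
        out = {}
        for name in VERTEBRA_NAMES:
            pts = self.landmarks.points(name)
            out[name] = 0.5 * (pts[VERT_SUP_CENTER] + pts[VERT_INF_CENTER])
        return out


class UnrealizableTargetError(ValueError):
    """Requested spino-pelvic targets outside the constructible range."""


def _dims(scale: float) -> dict:
    """Per-level vertebral body dimensions (mm), scaled by stature."""
    lum = {"width": 42.0, "depth": 33.0, "height": 24.0, "disc": 10.0}
    tho = {"width": 32.0, "depth": 26.0, "height": 19.0, "disc": 5.0}
    return {name: {k: v * scale for k, v in (lum if name.startswith("L")
                                             else tho).items()}
            for name in VERTEBRA_NAMES} | {
        "s1_width": 46.0 * scale, "s1_depth": 34.0 * scale,
        "gp_thickness": 3.0 * scale, "l5s1_disc": 8.0 * scale,
        "sacrum_depth": 38.0 * scale, "hip_halfspan": 60.0 * scale,
        "hip_offset": 70.0 * scale,
    }


def _direction(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(superior, anterior) unit vectors of an axis tilted anteriorly."""
    t = np.radians(theta_deg)
    d = np.array([np.sin(t), 0.0, np.cos(t)])
    a = np.array([np.cos(t), 0.0, -np.sin(t)])
    return d, a


_Y = np.array([0.0, 1.0, 0.0])


def _vertebra_landmarks(center: np.ndarray, theta_deg: float,
                        dims: dict) -> np.ndarray:
    d, a = _direction(theta_deg)
    h, w, dp = dims["height"], dims["width"], dims["depth"]
    pts = np.zeros((17, 3))
    for plate, sgn in ((VERT_SUP_PLATE, +1), (VERT_INF_PLATE, -1)):
        pc = center + sgn * (h / 2) * d
        ring = [pc + (dp / 2) * a + (w / 2) * _Y,
                pc + (dp / 2) * a - (w / 2) * _Y,
                pc - (dp / 2) * a - (w / 2) * _Y,
                pc - (dp / 2) * a + (w / 2) * _Y]
        for idx, p in zip(plate, ring):
            pts[idx] = p
    pts[VERT_SUP_CENTER] = center + (h / 2) * d
    pts[VERT_INF_CENTER] = center - (h / 2) * d
    pts[10] = center - (dp / 2 + 5) * a + 0.33 * w * _Y   # pedicles
    pts[11] = center - (dp / 2 + 5) * a - 0.33 * w * _Y
    pts[12] = center - (dp / 2 + 10) * a + 0.75 * w * _Y  # transverse tips
    pts[13] = center - (dp / 2 + 10) * a - 0.75 * w * _Y
    pts[14] = center - (dp / 2 + 1.0 * w) * a - 0.3 * h * d  # spinous tip
    pts[15] = center - (dp / 2 + 12) * a + 0.4 * w * _Y - 0.5 * h * d
    pts[16] = center - (dp / 2 + 12) * a - 0.4 * w * _Y - 0.5 * h * d
    return pts


def _pelvis_landmarks(hip_mid: np.ndarray, plate_center: np.ndarray,
                      halfspan: float, scale: float) -> np.ndarray:
    """23 pelvis points; indices 0/1 are the femoral head centers."""
    pts = [hip_mid + halfspan * _Y, hip_mid - halfspan * _Y]
    for side in (+1, -1):  # iliac wing arcs, 8 points each
        for k in range(8):
            t = k / 7.0
            ang = np.pi * (0.15 + 0.7 * t)
            p = plate_center + np.array([
                35.0 * scale * np.cos(ang),
                side * (30.0 + 35.0 * t) * scale,
                (25.0 * np.sin(ang) + 5.0) * scale,
            ])
            pts.append(p)
    pts.append(hip_mid + np.array([25.0, 0.0, -60.0]) * scale)   # pubis
    pts.append(hip_mid + np.array([-15.0, 45.0, -80.0]) * scale)  # ischium L
    pts.append(hip_mid + np.array([-15.0, -45.0, -80.0]) * scale)
    pts.append(plate_center + np.array([-20.0, 35.0, -15.0]) * scale)  # SI
    pts.append(plate_center + np.array([-20.0, -35.0, -15.0]) * scale)
    return np.array(pts)


def generate_template_geometry(
        targets: SpinoPelvicParams | tuple[float, float, float] | None = None,
        patient: PatientScalars | None = None,
        curve: CurveAngles | None = None,
        dome_height_mm: float = 3.0) -> TemplateModel:
    """Build the parametric template at requested (PI, SS, slip%).

    Defaults reproduce the reference patient: PI 61, SS 52, Grade II
    slip at 30%.  The construction realizes PI and SS exactly (plate
    placed at SS, femoral heads at PT = PI - SS) and then applies the
    slip operator, so the geometry module measures the targets back
    within 0.1 deg / 0.1%.
    """
    if targets is None:
        pi, ss, slip = 61.0, 52.0, 30.0
    elif isinstance(targets, SpinoPelvicParams):
        pi, ss = targets.pi_deg, targets.ss_deg
        slip = targets.slip_pct if targets.slip_pct is not None else 30.0
    else:
        pi, ss, slip = targets
    patient = patient or PatientScalars()
    curve = curve or CurveAngles()
    pt = pi - ss
    if not (-25.0 <= pt <= 60.0) or not (10.0 <= ss <= 80.0) or slip < 0:
        raise UnrealizableTargetError(
            f"targets PI={pi}, SS={ss} (PT={pt}), slip={slip} are outside "
            "the constructible range")

    scale = patient.height_cm / REFERENCE_HEIGHT_CM
    dims = _dims(scale)
    M = np.zeros(3)  # S1 superior endplate center
    d1, u1 = _direction(ss)  # plate normal / AP direction at sacral slope

    structures: dict[str, np.ndarray] = {}

    # sacrum
    w1, dp1 = dims["s1_width"], dims["s1_depth"]
    plate = np.array([M + (dp1 / 2) * u1 + (w1 / 2) * _Y,
                      M + (dp1 / 2) * u1 - (w1 / 2) * _Y,
                      M - (dp1 / 2) * u1 - (w1 / 2) * _Y,
                      M - (dp1 / 2) * u1 + (w1 / 2) * _Y])
    sacrum = np.vstack([
        plate, M[None],
        (M + dome_height_mm * d1)[None],
        (M - 100.0 * scale * d1 - 15.0 * scale * u1)[None],
        (M + 40.0 * scale * _Y - 10.0 * scale * d1)[None],
        (M - 40.0 * scale * _Y - 10.0 * scale * d1)[None],
    ])
    structures["sacrum"] = sacrum

    # pelvis (femoral heads realize PT about the plate center)
    tp = np.radians(pt)
    hip_mid = M + dims["hip_offset"] * np.array([np.sin(tp), 0.0, -np.cos(tp)])
    structures["pelvis"] = _pelvis_landmarks(hip_mid, M,
                                             dims["hip_halfspan"], scale)

    # vertebral column, stacked caudo-cranially from the S1 plate
    kyphosis_step = curve.thoracic_kyphosis_deg / 12.0
    gap5 = 2 * dims["gp_thickness"] + dims["l5s1_disc"]
    theta = ss
    top = M  # running superior endplate center
    centroids: dict[str, np.ndarray] = {}
    for k, name in enumerate(("L5", "L4", "L3", "L2", "L1") + tuple(
            f"T{i}" for i in range(12, 0, -1))):
        if name.startswith("L"):
            theta -= _LORDOSIS_WEIGHTS[k] * curve.lumbar_lordosis_deg
        else:
            theta += kyphosis_step
        d, _ = _direction(theta)
        disc = gap5 if name == "L5" else dims[name]["disc"]
        center = top + (disc + dims[name]["height"] / 2) * d
        structures[name] = _vertebra_landmarks(center, theta, dims[name])
        centroids[name] = center
        top = center + (dims[name]["height"] / 2) * d

    # ribs: 11 points per rib, smooth axial arcs anchored at each thoracic level
    for i, name in enumerate(THORACIC_NAMES):
        c = centroids[name]
        k = min(i, 11 - i)  # cage widens to mid-thorax
        rx = (45.0 + 12.0 * k) * scale
        ry = (50.0 + 10.0 * k) * scale
        _, a = _direction(0.0)
        for side, tag in ((+1, "left"), (-1, "right")):
            beta = np.radians(np.linspace(172.0, 15.0, 11))
            arc = (c[None] + rx * np.cos(beta)[:, None] * a[None]
                   + side * ry * np.sin(beta)[:, None] * _Y[None]
                   - 18.0 * scale * np.linspace(0, 1, 11)[:, None]
                   * np.array([0.0, 0.0, 1.0])[None])
            structures[f"rib_{tag}_{i + 1:02d}"] = arc

    landmarks = LandmarkSet.from_dict(structures)
    landmarks = apply_slip(landmarks, slip)
    params = compute_spinopelvic_params(landmarks, landmarks,
                                        slip_pct=measure_slip(landmarks))
    params.config_type = classify_configuration(params)
    if abs(params.pi_deg - pi) > 0.1 or abs(params.ss_deg - ss) > 0.1 \
            or abs(params.slip_pct - slip) > 0.1:
        raise UnrealizableTargetError(
            f"template missed targets: measured PI={params.pi_deg:.2f}, "
            f"SS={params.ss_deg:.2f}, slip={params.slip_pct:.2f}")
    return TemplateModel(landmarks=landmarks, params=params, patient=patient,
                         curve=curve, dome_height_mm=dome_height_mm)


def generate_patient_landmarks(template: TemplateModel,
                               noise_sd_mm: float = 3.3,
                               seed: int | None = None) -> LandmarkSet:
    """Landmarks as a radiographic reconstruction would deliver them.

    Adds isotropic Gaussian noise with the technique's average 3.3 mm
    accuracy by default; reproducible through ``seed``.
    """
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    df = template.landmarks.frame
    rng = np.random.default_rng(seed)
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    df[["x_mm", "y_mm", "z_mm"]] = coords + rng.normal(
        0.0, noise_sd_mm, size=coords.shape)
    return LandmarkSet(df)


# -- material library ------------------------------------------------------

@dataclass
class Material:
    E: float   # MPa
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")


@dataclass
class MaterialLibrary:
    """Complete material map over the region labels the mesher emits."""

    solids: dict[str, Material]
    springs: dict[str, float]           # N/mm
    beam_sections: dict[str, BeamSection]

    def solid_for_region(self, label: str) -> Material:
        key = region_material_key(label)
        if key not in self.solids:
            raise KeyError(f"no material for region '{label}' (key '{key}')")
        return self.solids[key]

    def override(self, updates: dict) -> "MaterialLibrary":
        """New library with nested overrides from a config mapping."""
        solids = dict(self.solids)
        for name, vals in (updates.get("solids") or {}).items():
            base = solids.get(name, Material(1.0, 0.3))
            solids[name] = replace(base, **vals)
        springs = dict(self.springs) | dict(updates.get("springs") or {})
        beams = dict(self.beam_sections)
        for name, vals in (updates.get("beam_sections") or {}).items():
            beams[name] = replace(beams[name], **vals)
        return MaterialLibrary(solids, springs, beams)


def region_material_key(label: str) -> str:
    """Map a mesh region label (e.g. 'cortical_L4') to a material key."""
    if label.startswith("gp_"):
        return "gp_" + label.rsplit("_", 1)[1]
    if label == "pelvis_bone":
        return label
    return label.split("_", 1)[0]


def default_material_library() -> MaterialLibrary:
    """Literature-range linear-elastic defaults (MPa), all overridable."""
    solids = {
        "cortical": Material(12000.0, 0.30),
        "trabecular": Material(100.0, 0.20),
        "annulus": Material(4.2, 0.45),
        "nucleus": Material(1.0, 0.499),
        "gp_sensitive": Material(12.0, 0.45),
        "gp_transition": Material(50.0, 0.40),
        "gp_newbone": Material(350.0, 0.30),
        "pelvis_bone": Material(5000.0, 0.30),
    }
    springs = {"ligament": 20.0, "interspinous": 10.0}
    beam_sections = {
        "facet": BeamSection(E=500.0, G=200.0, A=50.0,
                             Iy=200.0, Iz=200.0, J=400.0),
        "spine_chain": BeamSection(E=5000.0, G=2000.0, A=600.0,
                                   Iy=3.0e4, Iz=3.0e4, J=6.0e4),
        "rib": BeamSection(E=5000.0, G=2000.0, A=40.0,
                           Iy=500.0, Iz=500.0, J=1000.0),
        "arch": BeamSection(E=12000.0, G=4600.0, A=60.0,
                            Iy=300.0, Iz=300.0, J=600.0),
        "connector": BeamSection(E=15000.0, G=6000.0, A=800.0,
                                 Iy=1.0e5, Iz=1.0e5, J=2.0e5),
    }
    return MaterialLibrary(solids, springs, beam_sections)


# -- detailed hex mesh ------------------------------------------------------

def _bilinear(quad: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Points on a bilinear patch; quad ring order AL, AR, PR, PL.

    ``s`` runs anterior (0) to posterior (1); ``t`` left (0) to right (1).
    """
    AL, AR, PR, PL = quad
    return ((1 - s)[..., None] * ((1 - t)[..., None] * AL + t[..., None] * AR)
            + s[..., None] * ((1 - t)[..., None] * PL + t[..., None] * PR))


def build_detailed_mesh(template: TemplateModel, resolution: int = 12,
                        materials: MaterialLibrary | None = None,
                        include_ribcage: bool = True,
                        pars_lysis: bool = True) -> SpineModel:
    """Mesh the L4-pelvis segment and attach chain / arch / ligaments.

    ``resolution`` is the in-plane element count across a vertebral
    body (>= 2).  The through-thickness layer counts are fixed per
    structure (3 per vertebral body, >= 2 per disc, 3 per growth plate
    as its three histological zones).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    lib = materials or default_material_library()
    lm = template.landmarks
    scale = template.patient.height_cm / REFERENCE_HEIGHT_CM
    dims = _dims(scale)
    n = resolution

    l4 = lm.points("L4")
    l5 = lm.points("L5")
    sac = lm.points("sacrum")
    qL4s = l4[list(VERT_SUP_PLATE)]
    qL4i = l4[list(VERT_INF_PLATE)]
    qL5s = l5[list(VERT_SUP_PLATE)]
    qL5i = l5[list(VERT_INF_PLATE)]
    qS1 = sac[list(SACRUM_S1_PLATE)]
    M1 = qS1.mean(axis=0)
    n1 = np.cross(qS1[1] - qS1[0], qS1[3] - qS1[0])
    n1 /= np.linalg.norm(n1)
    if n1[2] < 0:
        n1 = -n1
    qSacB = (qS1 - M1) * 0.75 + M1 - dims["sacrum_depth"] * n1
    center_b = qSacB.mean(axis=0)
    # pelvis attachment block: widen laterally, keep extruding along the
    # sacral axis so the loft cannot fold over the tilted sacrum
    qPelB = (qSacB - center_b) * np.array([1.2, 1.8, 1.2]) + center_b \
        - 24.0 * scale * n1

    gp = dims["gp_thickness"]
    disc5 = dims["l5s1_disc"]
    tot = 2 * gp + disc5
    f1, f2 = gp / tot, (gp + disc5) / tot

    # (top quad, bottom quad, layer fractions, [(nlayers, labeller), ...])
    def vert_label(level):
        def lab(layer, nlay, i, j):
            edge = i in (0, n - 1) or j in (0, n - 1) \
                or layer in (0, nlay - 1)
            return f"{'cortical' if edge else 'trabecular'}_{level}"
        return lab

    def disc_label(level):
        def lab(layer, nlay, i, j):
            si = (i + 0.5) / n - 0.5
            tj = (j + 0.5) / n - 0.5
            core = (si * si + tj * tj) < 0.45 ** 2
            return f"{'nucleus' if core else 'annulus'}_{level}"
        return lab

    def zone_label(prefix, order):
        def lab(layer, nlay, i, j):
            return f"{prefix}_{order[layer]}"
        return lab

    # Decompose the L5-S1 gap per corner into a through-thickness part
    # (along the mean plate normal) and a tangential part (slip offset +
    # disc wedge).  The growth plates are bonded to their vertebrae, so
    # each growth-plate block is a clean extrusion of its own endplate;
    # the disc block absorbs the entire tangential offset.
    n5 = np.cross(qL5i[1] - qL5i[0], qL5i[3] - qL5i[0])
    n5 /= np.linalg.norm(n5)
    if n5[2] < 0:
        n5 = -n5
    nbar = n5 + n1
    nbar /= np.linalg.norm(nbar)
    delta = qS1 - qL5i
    dn = (delta @ nbar)[:, None] * nbar[None]
    dt = delta - dn
    qA = qL5i + f1 * dn
    qB = qL5i + f2 * dn + dt
    segments = [
        (qL4s, qL4i, 3, vert_label("L4")),
        (qL4i, qL5s, 2, disc_label("L4L5")),
        (qL5s, qL5i, 3, vert_label("L5")),
        # growth plates: newly formed bone against the metaphysis,
        # sensitive zone in the middle, transition zone toward the disc
        (qL5i, qA, 3,
         zone_label("gp_l5", ("newbone", "sensitive", "transition"))),
        (qA, qB, 3, disc_label("L5S1")),
        (qB, qS1, 3,
         zone_label("gp_s1", ("transition", "sensitive", "newbone"))),
        (qS1, qSacB, 4, vert_label("S1")),
        (qSacB, qPelB, 2, lambda layer, nlay, i, j: "pelvis_bone"),
    ]

    s_grid, t_grid = np.meshgrid(np.linspace(0, 1, n + 1),
                                 np.linspace(0, 1, n + 1), indexing="ij")
    level_quads: list[np.ndarray] = [segments[0][0]]
    seg_bounds: list[tuple[int, int]] = []
    for qtop, qbot, nlay, _ in segments:
        start = len(level_quads) - 1   # the segment's top interface level
        for k in range(1, nlay + 1):
            level_quads.append(qtop + (k / nlay) * (qbot - qtop))
        seg_bounds.append((start, len(level_quads) - 1))

    n_levels = len(level_quads)
    npl = (n + 1) ** 2  # nodes per level
    positions = np.empty((n_levels * npl, 3))
    for li, quad in enumerate(level_quads):
        positions[li * npl:(li + 1) * npl] = _bilinear(
            quad, s_grid, t_grid).reshape(npl, 3)

    # sacral dome: bulge the S1 interface along the plate normal, decaying
    # cranially through the disc and caudally into the sacrum
    l5i_level = seg_bounds[2][1]
    s1_level = seg_bounds[5][1]
    h_dome = template.dome_height_mm
    if h_dome > 0:
        rho2 = (((s_grid - 0.5) / 0.5) ** 2
                + ((t_grid - 0.5) / 0.5) ** 2).reshape(npl)
        radial = np.clip(1.0 - rho2, 0.0, None)
        for li in range(l5i_level, min(s1_level + 3, n_levels)):
            if li <= s1_level:
                w = (li - l5i_level) / (s1_level - l5i_level)
            else:
                w = 1.0 - 0.5 * (li - s1_level)
            positions[li * npl:(li + 1) * npl] += (
                h_dome * w * radial[:, None] * n1[None])

    def nid(level, i, j):
        return level * npl + i * (n + 1) + j

    hex_conn = []
    hex_region = []
    for (qtop, qbot, nlay, labeller), (lo, hi) in zip(segments, seg_bounds):
        for layer in range(nlay):
            top_level = lo + layer
            bot_level = lo + layer + 1
            for i in range(n):
                for j in range(n):
                    hex_conn.append([
                        nid(bot_level, i, j), nid(bot_level, i + 1, j),
                        nid(bot_level, i + 1, j + 1), nid(bot_level, i, j + 1),
                        nid(top_level, i, j), nid(top_level, i + 1, j),
                        nid(top_level, i + 1, j + 1), nid(top_level, i, j + 1),
                    ])
                    hex_region.append(labeller(layer, nlay, i, j))
    hex_conn = np.array(hex_conn, dtype=int)
    hex_E = np.empty(len(hex_region))
    hex_nu = np.empty(len(hex_region))
    for k, label in enumerate(hex_region):
        m = lib.solid_for_region(label)
        hex_E[k] = m.E
        hex_nu[k] = m.nu

    positions = list(positions)
    beams: list[BeamElement] = []
    springs: list[SpringElement] = []
    node_groups: dict[str, np.ndarray] = {}

    def add_node(p) -> int:
        positions.append(np.asarray(p, dtype=float))
        return len(positions) - 1

    def level_nodes(level) -> np.ndarray:
        return np.arange(level * npl, (level + 1) * npl)

    def nearest_node(point, candidates) -> int:
        pts = np.array([positions[i] for i in candidates])
        return int(candidates[np.argmin(np.linalg.norm(pts - point, axis=1))])

    def tie_beams(node, candidates, section, region):
        """Attach a beam-borne node to the solid with a non-collinear,
        symmetry-preserving fan of beams.

        Solid nodes carry no rotational stiffness, so an attached beam
        assembly is free to spin about any axis passing through all of
        its anchor points; anchors spanning a triangle leave no such
        axis.  Anchors are the k nearest candidates including all
        distance ties (so mirror-symmetric geometry yields a mirror-
        symmetric tie), with k grown until the anchor set is
        non-collinear.
        """
        pts = np.array([positions[i] for i in candidates])
        dist = np.linalg.norm(pts - positions[node], axis=1)
        order = np.argsort(dist)
        k = 4
        while True:
            cut = dist[order[min(k, len(order)) - 1]] * (1 + 1e-9) + 1e-9
            sel = np.nonzero(dist <= cut)[0]
            anchor_pts = pts[sel]
            centered = anchor_pts - anchor_pts.mean(axis=0)
            s = np.linalg.svd(centered, compute_uv=False)
            if len(sel) >= 3 and s[1] > 1e-6 * max(s[0], 1.0):
                break
            if k >= len(order):
                raise ValueError("cannot find non-collinear tie anchors")
            k += 1
        for idx in sel:
            beams.append(BeamElement((int(candidates[idx]), node), section,
                                     region=region))

    # named node groups over the solid mesh
    node_groups["plate_l5_inferior"] = level_nodes(l5i_level)
    node_groups["l5_growth_plate"] = np.concatenate(
        [level_nodes(l) for l in range(seg_bounds[3][0], seg_bounds[3][1] + 1)])
    node_groups["disc_l5s1"] = np.concatenate(
        [level_nodes(l) for l in range(seg_bounds[4][0], seg_bounds[4][1] + 1)])
    node_groups["s1_growth_plate"] = np.concatenate(
        [level_nodes(l) for l in range(seg_bounds[5][0], seg_bounds[5][1] + 1)])
    sacrum_nodes = np.concatenate(
        [level_nodes(l) for l in range(seg_bounds[6][0], seg_bounds[6][1] + 1)])
    pelvis_block = np.concatenate(
        [level_nodes(l) for l in range(seg_bounds[7][0], seg_bounds[7][1] + 1)])
    node_groups["sacrum"] = sacrum_nodes
    node_groups["s1_plate_center"] = np.array(
        [nearest_node(M1, level_nodes(s1_level))])

    # acetabulum nodes at the femoral head centers, tied to the pelvis block
    pel = lm.points("pelvis")
    connector = lib.beam_sections["connector"]
    acet = {}
    for tag, head in (("left", pel[0]), ("right", pel[1])):
        a = add_node(head)
        tie_beams(a, pelvis_block, connector, "connector")
        acet[tag] = a
        node_groups[f"acetabulum_{tag}"] = np.array([a])
    node_groups["pelvis"] = np.concatenate(
        [pelvis_block, [acet["left"], acet["right"]]])

    # posterior arch of L5 with bilateral pars elements
    l5_mid_level = seg_bounds[2][0] + 1  # interior level of the L5 body
    post_face = [nid(l5_mid_level, n, j) for j in range(n + 1)]
    l5_pts = lm.points("L5")
    arch_sec = lib.beam_sections["arch"]
    ped_l = nearest_node(l5_pts[10], post_face)
    ped_r = nearest_node(l5_pts[11], post_face)
    art_l = add_node(l5_pts[15])
    art_r = add_node(l5_pts[16])
    spin = add_node(l5_pts[14])
    pars_beams = [BeamElement((ped_l, art_l), arch_sec, region="pars"),
                  BeamElement((ped_r, art_r), arch_sec, region="pars")]
    if not pars_lysis:
        beams.extend(pars_beams)
    beams.append(BeamElement((art_l, spin), arch_sec, region="lamina"))
    beams.append(BeamElement((art_r, spin), arch_sec, region="lamina"))
    node_groups["l5_posterior_arch"] = np.array([art_l, art_r, spin])
    # facet joints: short beams, since the articulation transmits shear
    # and compression (not just an axial line of action) and must
    # stabilize the arch when the pars is lysed.  Anchored two levels
    # below the S1 endplate (the articular process roots in the sacrum
    # body), keeping concentrated tie forces away from the growth plate
    # whose stresses are the analysis target.
    sac_top = level_nodes(s1_level)
    sac_anchor = level_nodes(min(s1_level + 2, n_levels - 1))
    facet_sec = lib.beam_sections["facet"]
    for art in (art_l, art_r):
        tie_beams(art, sac_anchor, facet_sec, "facet")

    # thoracolumbar beam chain T1..L3 and the centroid chain for loading
    chain_sec = lib.beam_sections["spine_chain"]
    centroids = template.vertebral_centroids()
    chain_nodes: list[int] = []
    chain_levels: list[str] = []
    for name in THORACIC_NAMES + ("L1", "L2", "L3"):
        chain_nodes.append(add_node(centroids[name]))
        chain_levels.append(name)
    for a, b in zip(chain_nodes[:-1], chain_nodes[1:]):
        beams.append(BeamElement((a, b), chain_sec, region="spine_chain"))
    tie_beams(chain_nodes[-1], level_nodes(0), chain_sec, "spine_chain")
    # L4/L5 follower forces are spread over the interior mid-body
    # cross-section (registered as load groups) rather than injected at
    # a single node, which would spike the nearby growth-plate stresses
    for name, seg in (("L4", 0), ("L5", 2)):
        mid = seg_bounds[seg][0] + 1
        interior = np.array([nid(mid, i, j)
                             for i in range(1, n) for j in range(1, n)])
        node_groups[f"load_{name}"] = interior
        chain_nodes.append(nearest_node(centroids[name], level_nodes(mid)))
        chain_levels.append(name)
    centroid_chain = chain_nodes
    node_groups["T1"] = np.array([chain_nodes[0]])

    # simplified rib cage: beam arcs per thoracic level, closed anteriorly
    if include_ribcage:
        rib_sec = lib.beam_sections["rib"]
        for i, name in enumerate(THORACIC_NAMES):
            tips = {}
            for tag, chain_node in (("left", chain_nodes[i]),
                                    ("right", chain_nodes[i])):
                arc = lm.points(f"rib_{tag}_{i + 1:02d}")
                ids = [add_node(p) for p in arc]
                beams.append(BeamElement((chain_node, ids[0]), rib_sec,
                                         region="rib"))
                for a, b in zip(ids[:-1], ids[1:]):
                    beams.append(BeamElement((a, b), rib_sec, region="rib"))
                tips[tag] = ids[-1]
            beams.append(BeamElement((tips["left"], tips["right"]), rib_sec,
                                     region="sternum"))

    # tension-only ligament springs (anterior/posterior longitudinal,
    # interspinous)
    k_lig = lib.springs["ligament"]
    lig_pairs = []
    for top_level, bot_level in ((seg_bounds[0][1], seg_bounds[2][0]),
                                 (seg_bounds[2][1], seg_bounds[6][0])):
        for (i, j) in ((0, n // 2), (n, n // 2)):  # anterior / posterior
            lig_pairs.append((nid(top_level, i, j), nid(bot_level, i, j)))
    for a, b in lig_pairs:
        springs.append(SpringElement((a, b), k_lig, tension_only=True,
                                     region="ligament"))
    sac_post = nearest_node(_bilinear(qS1, np.array(1.0), np.array(0.5)),
                            sac_top)
    springs.append(SpringElement((spin, sac_post),
                                 lib.springs["interspinous"],
                                 tension_only=True, region="interspinous"))

    model = SpineModel(
        positions=np.array(positions),
        hex_conn=hex_conn,
        hex_E=hex_E,
        hex_nu=hex_nu,
        hex_region=hex_region,
        beams=beams,
        springs=springs,
        node_groups=node_groups,
        centroid_chain=centroid_chain,
        chain_levels=chain_levels,
    )
    from .fem.elements import hex_jacobians, InvertedElementError
    det = hex_jacobians(model.hex_coords())
    if np.any(det <= 0):
        bad = np.unique(np.nonzero(det <= 0)[0])
        raise InvertedElementError(
            f"mesh build produced degenerate hexahedra {bad.tolist()}")
    return model
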