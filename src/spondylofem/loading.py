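"""Physiological loading: body-weight distribution and follower load.

The trunk weight is distributed over the vertebral bodies as fractions
of total body weight; the follower-load scheme then redirects each
segmental force along the local tangent of the (deformed) centroid
chain, so the resultant internal force "follows" the kyphotic and
lordotic curvature of the spine, and the standing posture is anchored
by fixed/torsion-sprung acetabula with T1 blocked transversally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem.mesh import DofMap, SpineModel
from .fem.solve import BoundaryConditions, resolve_tension_only

G_M_S2 = 9.81

#: Default per-vertebra body-weight fractions for an upright trunk
#: (head/neck/shoulder girdle lumped at T1); sum ~= 0.57 of body weight
#: carried above the lumbosacral junction.  Fully overridable.
DEFAULT_BW_FRACTIONS: dict[str, float] = (
    {"T1": 0.161}
    | {f"T{i}": 0.023 for i in range(2, 13)}
    | {f"L{i}": 0.031 for i in range(1, 6)}
)


@dataclass
class LoadDistribution:
    """Per-vertebra body-weight fractions plus the body weight itself."""

    body_weight_kg: float
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BW_FRACTIONS))
    gravity_m_s2: float = G_M_S2

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("body-weight fractions must be >= 0")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("body-weight fractions sum to more than 1")


def body_weight_distribution(body_weight_kg: float,
                             fraction_table: dict[str, float] | None = None,
                             gravity_m_s2: float = G_M_S2
                             ) -> dict[str, np.ndarray]:
    """Gravity force vector (N, direction -z) applied at each vertebra."""
    dist = LoadDistribution(body_weight_kg,
                            dict(fraction_table or DEFAULT_BW_FRACTIONS),
                            gravity_m_s2)
    return {level: np.array([0.0, 0.0, -f * body_weight_kg * gravity_m_s2])
            for level, f in dist.fractions.items()}


@dataclass
class FollowerLoadState:
    """Segmental follower forces along the centroid chain."""

    centroids: np.ndarray    # (m, 3) ordered cranio-caudal
    magnitudes: np.ndarray   # (m,) N
    directions: np.ndarray   # (m, 3) unit tangents, pointing caudally

    def forces(self) -> np.ndarray:
        return self.magnitudes[:, None] * self.directions


def follower_load_vectors(centroid_chain: np.ndarray,
                          magnitudes: np.ndarray) -> FollowerLoadState:
    """Unit tangents of the centroid polyline scaled by the magnitudes.

    Tangents use central finite differences (one-sided at the ends) and
    point in the cranio-caudal direction of the ordered chain; the force
    magnitudes are preserved exactly.
    """
    pts = np.asarray(centroid_chain, dtype=float).reshape(-1, 3)
    mags = np.asarray(magnitudes, dtype=float).reshape(-1)
    m = pts.shape[0]
    if m < 3:
        raise ValueError("need at least 3 centroids for tangent estimation")
    if mags.shape[0] != m:
        raise ValueError("one magnitude per centroid required")
    seg = np.diff(pts, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) < 1e-9):
        raise ValueError("duplicate consecutive centroids in the chain")
    tang = np.empty_like(pts)
    tang[0] = pts[1] - pts[0]
    tang[-1] = pts[-1] - pts[-2]
    tang[1:-1] = pts[2:] - pts[:-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return FollowerLoadState(centroids=pts, magnitudes=mags, directions=tang)


def standing_boundary_conditions(model: SpineModel,
                                 torsion_stiffness: float = 5.0e6
                                 ) -> BoundaryConditions:
    """Standing posture: acetabula fixed in translation with rotational
    torsion springs (N*mm/rad); T1 blocked transversally (x, y free in z)."""
    bcs = BoundaryConditions()
    for tag in ("acetabulum_left", "acetabulum_right"):
        for node in model.group(tag):
            bcs.fix_node(int(node), dofs=(0, 1, 2))
            for rot in (3, 4, 5):
                bcs.ground_springs.append((int(node), rot, torsion_stiffness))
    for node in model.group("T1"):
        bcs.fix_node(int(node), dofs=(0, 1))
    return bcs


@dataclass
class FollowerDiagnostics:
    converged: bool
    iterations: int
    residual_rad: float
    active_springs: np.ndarray | None = None


def _chain_magnitudes(model: SpineModel,
                      distribution: LoadDistribution) -> np.ndarray:
    mags = []
    for level in model.chain_levels:
        f = distribution.fractions.get(level, 0.0)
        mags.append(f * distribution.body_weight_kg * distribution.gravity_m_s2)
    return np.array(mags)


def follower_equilibrium_iteration(model: SpineModel,
                                   bcs: BoundaryConditions,
                                   distribution: LoadDistribution,
                                   tol: float = 1e-3,
                                   max_iter: int = 25,
                                   single_pass: bool = False
                                   ) -> tuple[np.ndarray, FollowerLoadState,
                                              FollowerDiagnostics]:
    """Fixed-point follower-load solve.

    Each pass applies the segmental forces tangent to the current
    (deformed) centroid chain, re-solves the model (honouring
    tension-only ligaments), and re-estimates the tangents; iteration
    stops when the largest direction change drops below ``tol`` (rad).
    """
    if not model.centroid_chain:
        raise ValueError("model has no centroid chain to load")
    dofmap = DofMap(model, extra_rotation_nodes=bcs.rotation_nodes())
    nodes = list(model.centroid_chain)
    mags = _chain_magnitudes(model, distribution)
    tdofs = dofmap.translation_dofs(np.array(nodes))
    # per-level force application: a registered load group (e.g. the
    # mid-body cross-section of a solid vertebra) if present, else the
    # chain node itself
    load_dofs = []
    for level, node in zip(model.chain_levels, nodes):
        grp = model.node_groups.get(f"load_{level}")
        grp = np.array([node]) if grp is None or not len(grp) else grp
        load_dofs.append(dofmap.translation_dofs(np.asarray(grp, dtype=int)))

    def chain_positions(u: np.ndarray) -> np.ndarray:
        return model.positions[nodes] + u[tdofs]

    u = np.zeros(dofmap.ndof)
    state = follower_load_vectors(chain_positions(u), mags)
    active = None
    residual = np.inf
    for it in range(1, max_iter + 1):
        f = np.zeros(dofmap.ndof)
        forces = state.forces()
        for row, d in zip(forces, load_dofs):
            f[d.reshape(-1, 3)] += row / d.shape[0]
        u, active = resolve_tension_only(model, bcs, f, dofmap=dofmap,
                                         active0=active)
        new_state = follower_load_vectors(chain_positions(u), mags)
        cosang = np.clip(np.sum(new_state.directions * state.directions,
                                axis=1), -1.0, 1.0)
        residual = float(np.max(np.arccos(cosang)))
        state = new_state
        if single_pass or residual < tol:
            return u, state, FollowerDiagnostics(True, it, residual, active)
    raise RuntimeError(
        f"follower load did not converge in {max_iter} iterations "
        f"(last direction change {residual:.2e} rad)")
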