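"""Assembly, boundary conditions, sparse direct solve, tension-only loop."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import (
    beam_element_stiffness,
    hex_stiffness_batch,
    spring_stiffness,
)
from .mesh import DofMap, SpineModel


class SingularSystemError(RuntimeError):
    """Raised when the constrained stiffness matrix cannot be factorized.

    Usually means the model has unconstrained rigid-body modes or an
    internal mechanism; check that the boundary conditions remove all six
    rigid modes and that every node is connected to stiffness.
    """


class ActiveSetError(RuntimeError):
    """Tension-only active set failed to stabilize within max_iter."""


@dataclass
class BoundaryConditions:
    """Fixed DOFs and grounded (boundary) springs.

    ``fixed`` holds (node, local_dof) pairs with local_dof 0-2 translation
    and 3-5 rotation; ``ground_springs`` holds (node, local_dof, stiffness)
    triples added to the matching diagonal entries.
    """

    fixed: list[tuple[int, int]] = field(default_factory=list)
    ground_springs: list[tuple[int, int, float]] = field(default_factory=list)

    def fix_node(self, node: int, dofs=(0, 1, 2, 3, 4, 5)) -> None:
        for d in dofs:
            self.fixed.append((node, d))

    def rotation_nodes(self) -> set[int]:
        out = {n for n, d in self.fixed if d >= 3}
        out |= {n for n, d, _ in self.ground_springs if d >= 3}
        return out


@dataclass
class FESystem:
    """Assembled (unconstrained) global system."""

    K: sp.csr_matrix
    dofmap: DofMap
    model: SpineModel
    active_springs: np.ndarray  # bool per spring element


def assemble_global_stiffness(model: SpineModel,
                              dofmap: DofMap | None = None,
                              active_springs: np.ndarray | None = None
                              ) -> FESystem:
    """Assemble the global sparse stiffness matrix.

    ``active_springs`` masks spring elements (used by the tension-only
    iteration); by default every spring participates.
    """
    if dofmap is None:
        dofmap = DofMap(model)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    if model.n_hex:
        Kel = hex_stiffness_batch(model.hex_coords(), model.hex_E, model.hex_nu)
        dofs = dofmap.translation_dofs(model.hex_conn.reshape(-1)).reshape(
            model.n_hex, 24)
        r = np.repeat(dofs, 24, axis=1).ravel()
        c = np.tile(dofs, (1, 24)).ravel()
        rows.append(r)
        cols.append(c)
        vals.append(Kel.ravel())

    for b in model.beams:
        i, j = b.nodes
        Ke = beam_element_stiffness(b, model.positions[i], model.positions[j])
        d = np.array(dofmap.node_dofs(i) + dofmap.node_dofs(j))
        rows.append(np.repeat(d, 12))
        cols.append(np.tile(d, 12))
        vals.append(Ke.ravel())

    if active_springs is None:
        active_springs = np.ones(len(model.springs), dtype=bool)
    for s, act in zip(model.springs, active_springs):
        if not act:
            continue
        i, j = s.nodes
        Ke, _ = spring_stiffness(s, model.positions[i], model.positions[j])
        d = np.concatenate([dofmap.translation_dofs(np.array([i]))[0],
                            dofmap.translation_dofs(np.array([j]))[0]])
        rows.append(np.repeat(d, 6))
        cols.append(np.tile(d, 6))
        vals.append(Ke.ravel())

    n = dofmap.ndof
    if rows:
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)).tocsr()
    else:
        K = sp.csr_matrix((n, n))
    return FESystem(K=K, dofmap=dofmap, model=model,
                    active_springs=np.asarray(active_springs, dtype=bool))


@dataclass
class ConstrainedSystem:
    system: FESystem
    bcs: BoundaryConditions
    free: np.ndarray       # bool mask over global DOFs
    K_mod: sp.csr_matrix   # full matrix with grounded springs added


def apply_boundary_conditions(system: FESystem,
                              bcs: BoundaryConditions) -> ConstrainedSystem:
    """Mark fixed DOFs for elimination and add grounded-spring stiffness."""
    dm = system.dofmap
    free = np.ones(dm.ndof, dtype=bool)
    for node, local in bcs.fixed:
        free[dm.dof(node, local)] = False   # KeyError if DOF absent
    K = system.K
    if bcs.ground_springs:
        diag_idx = [dm.dof(n, d) for n, d, _ in bcs.ground_springs]
        diag_val = [k for _, _, k in bcs.ground_springs]
        D = sp.coo_matrix((diag_val, (diag_idx, diag_idx)),
                          shape=K.shape).tocsr()
        K = (K + D).tocsr()
    return ConstrainedSystem(system=system, bcs=bcs, free=free, K_mod=K)


def solve_static(constrained: ConstrainedSystem, load_vector: np.ndarray,
                 _factor_cache: dict | None = None) -> np.ndarray:
    """Solve K u = f on the free DOFs by sparse LU; returns the full u.

    Residual is checked to 1e-8 relative; an unconstrained or mechanism-
    bearing model raises :class:`SingularSystemError` with advice.
    """
    free = constrained.free
    f = np.asarray(load_vector, dtype=float)[free]
    if _factor_cache is not None and "lu" in _factor_cache:
        lu, s = _factor_cache["lu"]
    else:
        Kff = constrained.K_mod[free][:, free].tocsr()
        # symmetric Jacobi scaling: the model mixes rotational and
        # translational DOFs and very soft with very stiff materials
        d = Kff.diagonal()
        if np.any(d <= 0):
            raise SingularSystemError(
                "zero or negative diagonal stiffness on a free DOF; a node "
                "or rotation is unsupported — check constraints")
        s = 1.0 / np.sqrt(d)
        Ks = sp.diags(s) @ Kff @ sp.diags(s)
        try:
            lu = spla.splu(Ks.tocsc())
        except RuntimeError as exc:  # pragma: no cover - message passthrough
            raise SingularSystemError(
                "stiffness matrix is singular; add boundary conditions that "
                "suppress all rigid-body modes") from exc
        if _factor_cache is not None:
            _factor_cache["lu"] = (lu, s)
    Kff = constrained.K_mod[free][:, free].tocsr()
    uf = s * lu.solve(s * f)
    # one step of iterative refinement for the remaining conditioning
    uf += s * lu.solve(s * (f - Kff @ uf))
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError(
            "solver produced non-finite displacements; the system is "
            "singular or ill-conditioned — check for missing constraints")
    fn = np.linalg.norm(f)
    if fn > 0:
        res = np.linalg.norm(Kff @ uf - f) / fn
        if res > 1e-8:
            raise SingularSystemError(
                f"linear solve residual {res:.2e} exceeds 1e-8; the system "
                "is ill-conditioned — check for missing constraints")
    u = np.zeros(constrained.system.dofmap.ndof)
    u[free] = uf
    return u


def spring_elongations(model: SpineModel, dofmap: DofMap,
                       u: np.ndarray) -> np.ndarray:
    """Axial elongation of every spring (positive = tension)."""
    out = np.empty(len(model.springs))
    for k, s in enumerate(model.springs):
        i, j = s.nodes
        d = model.positions[j] - model.positions[i]
        n = d / np.linalg.norm(d)
        ui = u[dofmap.translation_dofs(np.array([i]))[0]]
        uj = u[dofmap.translation_dofs(np.array([j]))[0]]
        out[k] = (uj - ui) @ n
    return out


def resolve_tension_only(model: SpineModel, bcs: BoundaryConditions,
                         load_vector: np.ndarray, max_iter: int = 20,
                         dofmap: DofMap | None = None,
                         active0: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Active-set solve honouring tension-only springs.

    Springs flagged ``tension_only`` are removed while their axial
    elongation is negative and re-solved until the active set is stable.
    Returns (displacements, final active mask).
    """
    if dofmap is None:
        dofmap = DofMap(model, extra_rotation_nodes=bcs.rotation_nodes())
    n_springs = len(model.springs)
    tension_only = np.array([s.tension_only for s in model.springs],
                            dtype=bool)
    active = (np.ones(n_springs, dtype=bool) if active0 is None
              else np.asarray(active0, dtype=bool).copy())
    active[~tension_only] = True
    if not tension_only.any():
        sys_ = assemble_global_stiffness(model, dofmap, active)
        con = apply_boundary_conditions(sys_, bcs)
        return solve_static(con, load_vector), active

    seen: set[tuple] = set()
    forced_off = np.zeros(n_springs, dtype=bool)
    for _ in range(max_iter + 1):
        sys_ = assemble_global_stiffness(model, dofmap, active)
        con = apply_boundary_conditions(sys_, bcs)
        u = solve_static(con, load_vector)
        elong = spring_elongations(model, dofmap, u)
        new_active = active.copy()
        new_active[tension_only] = elong[tension_only] >= -1e-12
        new_active[forced_off] = False
        if np.array_equal(new_active, active):
            return u, active
        state = tuple(new_active.tolist())
        if state in seen:
            # a cycling spring sits at zero force; drop it for good (the
            # conservative unilateral resolution) and continue
            cyclers = tension_only & (new_active != active)
            forced_off |= cyclers
            new_active[cyclers] = False
        seen.add(tuple(active.tolist()))
        active = new_active
    raise ActiveSetError(
        f"tension-only active set did not stabilize in {max_iter} iterations")
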