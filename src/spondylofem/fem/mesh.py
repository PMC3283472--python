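"""Hybrid mesh container and degree-of-freedom bookkeeping.

A :class:`SpineModel` mixes three element technologies: hexahedral solids
for the detailed L4-pelvis segment, beams for the thoracolumbar chain /
rib cage / posterior arch, and axial springs for ligaments and facets.
Solid-only nodes carry 3 translational DOFs; nodes touched by a beam or a
rotational boundary condition additionally carry 3 rotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elements import BeamElement, BeamSection, HexElement, SpringElement


@dataclass
class SpineModel:
    """Nodes, elements, materials and named node groups of one model."""

    positions: np.ndarray                     # (n_nodes, 3) mm
    hex_conn: np.ndarray                      # (n_hex, 8) int, VTK ordering
    hex_E: np.ndarray                         # (n_hex,) MPa
    hex_nu: np.ndarray                        # (n_hex,)
    hex_region: list[str]                     # per-element region label
    beams: list[BeamElement] = field(default_factory=list)
    springs: list[SpringElement] = field(default_factory=list)
    node_groups: dict[str, np.ndarray] = field(default_factory=dict)
    centroid_chain: list[int] = field(default_factory=list)  # T1..L5 node ids
    chain_levels: list[str] = field(default_factory=list)    # names for chain

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("node coordinates must be finite")
        self.hex_conn = np.asarray(self.hex_conn, dtype=int).reshape(-1, 8)
        self.hex_E = np.asarray(self.hex_E, dtype=float)
        self.hex_nu = np.asarray(self.hex_nu, dtype=float)
        n = self.n_nodes
        refs = [self.hex_conn.ravel()] if self.hex_conn.size else []
        refs += [np.asarray(b.nodes) for b in self.beams]
        refs += [np.asarray(s.nodes) for s in self.springs]
        if refs:
            allref = np.concatenate(refs)
            if allref.size and (allref.min() < 0 or allref.max() >= n):
                raise ValueError("element references a nonexistent node")

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_hex(self) -> int:
        return self.hex_conn.shape[0]

    def hex_coords(self) -> np.ndarray:
        """(n_hex, 8, 3) corner coordinates."""
        return self.positions[self.hex_conn]

    def hex_centroids(self) -> np.ndarray:
        return self.hex_coords().mean(axis=1)

    def group(self, name: str) -> np.ndarray:
        if name not in self.node_groups:
            raise KeyError(f"model has no node group '{name}'")
        return np.asarray(self.node_groups[name], dtype=int)

    def elements_in_regions(self, prefixes: tuple[str, ...] | str) -> np.ndarray:
        """Indices of hexahedra whose region label starts with any prefix."""
        if isinstance(prefixes, str):
            prefixes = (prefixes,)
        return np.array([i for i, r in enumerate(self.hex_region)
                         if r.startswith(tuple(prefixes))], dtype=int)

    # -- plain-text round trip (mesh description JSON) ------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "positions": self.positions.tolist(),
            "hex_conn": self.hex_conn.tolist(),
            "hex_E": self.hex_E.tolist(),
            "hex_nu": self.hex_nu.tolist(),
            "hex_region": self.hex_region,
            "beams": [
                {"nodes": list(b.nodes), "region": b.region,
                 "orientation": list(b.orientation) if b.orientation else None,
                 "section": vars(b.section)} for b in self.beams
            ],
            "springs": [
                {"nodes": list(s.nodes), "stiffness": s.stiffness,
                 "tension_only": s.tension_only, "region": s.region}
                for s in self.springs
            ],
            "node_groups": {k: np.asarray(v).tolist()
                            for k, v in self.node_groups.items()},
            "centroid_chain": list(self.centroid_chain),
            "chain_levels": list(self.chain_levels),
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpineModel":
        data = json.loads(Path(path).read_text())
        beams = [BeamElement(tuple(b["nodes"]), BeamSection(**b["section"]),
                             tuple(b["orientation"]) if b["orientation"] else None,
                             b["region"]) for b in data["beams"]]
        springs = [SpringElement(tuple(s["nodes"]), s["stiffness"],
                                 s["tension_only"], s["region"])
                   for s in data["springs"]]
        return cls(
            positions=np.array(data["positions"], dtype=float),
            hex_conn=np.array(data["hex_conn"], dtype=int).reshape(-1, 8),
            hex_E=np.array(data["hex_E"], dtype=float),
            hex_nu=np.array(data["hex_nu"], dtype=float),
            hex_region=list(data["hex_region"]),
            beams=beams,
            springs=springs,
            node_groups={k: np.array(v, dtype=int)
                         for k, v in data["node_groups"].items()},
            centroid_chain=list(data["centroid_chain"]),
            chain_levels=list(data.get("chain_levels", [])),
        )


class DofMap:
    """Node -> global DOF numbering with per-node 3 or 6 DOFs.

    Rotational DOFs are allocated only at nodes referenced by a beam
    element or listed in ``extra_rotation_nodes`` (e.g. nodes carrying a
    torsion-spring boundary condition), which keeps the assembled system
    free of zero-stiffness rotational equations at solid-only nodes.
    """

    def __init__(self, model: SpineModel,
                 extra_rotation_nodes: set[int] | None = None) -> None:
        n = model.n_nodes
        has_rot = np.zeros(n, dtype=bool)
        for b in model.beams:
            has_rot[list(b.nodes)] = True
        if extra_rotation_nodes:
            has_rot[list(extra_rotation_nodes)] = True
        counts = np.where(has_rot, 6, 3)
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.has_rot = has_rot
        self.ndof = int(self.offsets[-1])

    def dof(self, node: int, local: int) -> int:
        """Global index of DOF ``local`` (0-2 translation, 3-5 rotation)."""
        if local >= 3 and not self.has_rot[node]:
            raise KeyError(f"node {node} carries no rotational DOFs")
        return int(self.offsets[node]) + local

    def translation_dofs(self, nodes: np.ndarray) -> np.ndarray:
        """(k, 3) translational DOF indices for the given nodes."""
        nodes = np.asarray(nodes, dtype=int)
        return self.offsets[nodes][:, None] + np.arange(3)[None, :]

    def node_dofs(self, node: int) -> list[int]:
        k = 6 if self.has_rot[node] else 3
        return [int(self.offsets[node]) + i for i in range(k)]
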