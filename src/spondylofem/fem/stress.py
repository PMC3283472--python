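"""Stress recovery for hexahedral solids.

Strains are evaluated at the 2x2x2 Gauss points, averaged to the element
centroid, and mapped through isotropic Hooke's law; the result is one
symmetric 3x3 stress tensor (MPa, global frame) per element.
"""

from __future__ import annotations

import numpy as np

from .elements import hex_centroid_strain, isotropic_elasticity_matrix
from .mesh import DofMap, SpineModel


def recover_hex_stresses(model: SpineModel, displacements: np.ndarray,
                         dofmap: DofMap | None = None) -> np.ndarray:
    """Element-centroid stress tensors (n_hex, 3, 3) from a solved field."""
    if model.n_hex == 0:
        return np.zeros((0, 3, 3))
    if dofmap is None:
        dofmap = DofMap(model)
    u = np.asarray(displacements, dtype=float)
    dofs = dofmap.translation_dofs(model.hex_conn.reshape(-1)).reshape(
        model.n_hex, 24)
    ue = u[dofs]
    eps = hex_centroid_strain(model.hex_coords(), ue)  # (nel, 6) Voigt
    sig = np.empty_like(eps)
    # group by (E, nu) to reuse the constitutive matrix
    mats = np.column_stack([model.hex_E, model.hex_nu])
    for row in np.unique(mats, axis=0):
        mask = np.all(mats == row, axis=1)
        D = isotropic_elasticity_matrix(row[0], row[1])
        sig[mask] = eps[mask] @ D.T
    out = np.empty((model.n_hex, 3, 3))
    out[:, 0, 0] = sig[:, 0]
    out[:, 1, 1] = sig[:, 1]
    out[:, 2, 2] = sig[:, 2]
    out[:, 0, 1] = out[:, 1, 0] = sig[:, 3]
    out[:, 1, 2] = out[:, 2, 1] = sig[:, 4]
    out[:, 0, 2] = out[:, 2, 0] = sig[:, 5]
    return out
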