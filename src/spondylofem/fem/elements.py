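"""Element stiffness formulations.

Beam: classical 3D Euler-Bernoulli two-node beam, 12x12, local DOF order
(ux, uy, uz, rx, ry, rz) per node, transformed to the global frame by the
element triad.  Hexahedron: standard trilinear isoparametric brick with
2x2x2 Gauss quadrature and isotropic Hooke's law in Voigt order
(xx, yy, zz, xy, yz, zx) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ZeroLengthElementError(ValueError):
    """Beam or spring with coincident end nodes."""


class InvertedElementError(ValueError):
    """Hexahedron with a non-positive Jacobian at a Gauss point."""


@dataclass
class BeamSection:
    """Cross-section and material of a beam element (MPa, mm units)."""

    E: float
    G: float
    A: float
    Iy: float
    Iz: float
    J: float

    def __post_init__(self) -> None:
        for name in ("E", "G", "A", "Iy", "Iz", "J"):
            if getattr(self, name) <= 0:
                raise ValueError(f"beam section property {name} must be positive")


@dataclass
class BeamElement:
    nodes: tuple[int, int]
    section: BeamSection
    orientation: tuple[float, float, float] | None = None
    region: str = "beam"


@dataclass
class SpringElement:
    nodes: tuple[int, int]
    stiffness: float
    tension_only: bool = False
    region: str = "spring"

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise ValueError("spring stiffness must be >= 0")


@dataclass
class HexElement:
    """One 8-node brick; connectivity uses VTK hexahedron node ordering."""

    nodes: tuple[int, ...]
    E: float
    nu: float
    region: str = "solid"

    def __post_init__(self) -> None:
        if len(self.nodes) != 8:
            raise ValueError("hexahedron needs exactly 8 nodes")
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


def beam_triad(xi: np.ndarray, xj: np.ndarray,
               orientation: tuple[float, float, float] | None) -> tuple[np.ndarray, float]:
    """Local axes (rows ex, ey, ez) and length of a beam element."""
    d = np.asarray(xj, dtype=float) - np.asarray(xi, dtype=float)
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        raise ZeroLengthElementError("zero-length beam element")
    ex = d / L
    if orientation is not None:
        ref = np.asarray(orientation, dtype=float)
    else:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(ex @ ref) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
    ey = ref - (ref @ ex) * ex
    ny = np.linalg.norm(ey)
    if ny < 1e-10:
        raise ValueError("beam orientation vector parallel to element axis")
    ey /= ny
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez]), L


def _beam_local_stiffness(sec: BeamSection, L: float) -> np.ndarray:
    E, G = sec.E, sec.G
    a = E * sec.A / L
    t = G * sec.J / L
    K = np.zeros((12, 12))
    K[0, 0] = K[6, 6] = a
    K[0, 6] = K[6, 0] = -a
    K[3, 3] = K[9, 9] = t
    K[3, 9] = K[9, 3] = -t
    # bending in local x-y plane: v (1, 7) and theta_z (5, 11), inertia Iz
    c = E * sec.Iz / L**3
    idx = [1, 5, 7, 11]
    kb = c * np.array([
        [12, 6 * L, -12, 6 * L],
        [6 * L, 4 * L**2, -6 * L, 2 * L**2],
        [-12, -6 * L, 12, -6 * L],
        [6 * L, 2 * L**2, -6 * L, 4 * L**2],
    ])
    K[np.ix_(idx, idx)] += kb
    # bending in local x-z plane: w (2, 8) and theta_y (4, 10), inertia Iy
    c = E * sec.Iy / L**3
    idx = [2, 4, 8, 10]
    kb = c * np.array([
        [12, -6 * L, -12, -6 * L],
        [-6 * L, 4 * L**2, 6 * L, 2 * L**2],
        [-12, 6 * L, 12, 6 * L],
        [-6 * L, 2 * L**2, 6 * L, 4 * L**2],
    ])
    K[np.ix_(idx, idx)] += kb
    return K


def beam_element_stiffness(element: BeamElement, xi: np.ndarray,
                           xj: np.ndarray) -> np.ndarray:
    """12x12 global-frame stiffness of a two-node Euler-Bernoulli beam."""
    R, L = beam_triad(xi, xj, element.orientation)
    Kl = _beam_local_stiffness(element.section, L)
    T = np.zeros((12, 12))
    for b in range(4):
        T[3 * b:3 * b + 3, 3 * b:3 * b + 3] = R
    return T.T @ Kl @ T


def spring_stiffness(element: SpringElement, xi: np.ndarray,
                     xj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """6x6 translational stiffness of an axial spring and its unit axis."""
    d = np.asarray(xj, dtype=float) - np.asarray(xi, dtype=float)
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        raise ZeroLengthElementError("zero-length spring element")
    n = d / L
    k = element.stiffness * np.outer(n, n)
    K = np.block([[k, -k], [-k, k]])
    return K, n


def isotropic_elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic Hooke matrix, Voigt order (xx,yy,zz,xy,yz,zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


# trilinear shape functions on [-1,1]^3, VTK hexahedron corner ordering
_XI_NODES = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_GP = np.array(np.meshgrid(*([[-1, 1]] * 3), indexing="ij"),
               dtype=float).reshape(3, 8).T / np.sqrt(3.0)


def _shape_gradients(points: np.ndarray) -> np.ndarray:
    """dN/dxi at the given natural-coordinate points: (npts, 8, 3)."""
    pts = np.atleast_2d(points)
    g = np.empty((pts.shape[0], 8, 3))
    for a in range(8):
        s = _XI_NODES[a]
        f = (1 + s * pts) / 2.0  # (npts, 3) one-dimensional factors
        g[:, a, 0] = (s[0] / 2.0) * f[:, 1] * f[:, 2]
        g[:, a, 1] = (s[1] / 2.0) * f[:, 0] * f[:, 2]
        g[:, a, 2] = (s[2] / 2.0) * f[:, 0] * f[:, 1]
    return g


_DN_GP = _shape_gradients(_GP)  # (8 gp, 8 nodes, 3)


def hex_jacobians(coords: np.ndarray) -> np.ndarray:
    """Gauss-point Jacobian determinants, coords (nel, 8, 3) -> (nel, 8)."""
    c = np.asarray(coords, dtype=float)
    single = c.ndim == 2
    if single:
        c = c[None]
    J = np.einsum("gia,nib->ngab", _DN_GP, c)
    det = np.linalg.det(J)
    return det[0] if single else det


def hex_stiffness_batch(coords: np.ndarray, E: np.ndarray,
                        nu: np.ndarray) -> np.ndarray:
    """Stiffness matrices for a batch of hexahedra.

    Parameters
    ----------
    coords : (nel, 8, 3) node coordinates in VTK ordering.
    E, nu : (nel,) material per element.

    Returns
    -------
    (nel, 24, 24) element stiffness matrices (DOF = 3 translations/node).

    Raises
    ------
    InvertedElementError
        naming the offending elements if any Gauss-point Jacobian is <= 0.
    """
    c = np.asarray(coords, dtype=float)
    nel = c.shape[0]
    J = np.einsum("gia,nib->ngab", _DN_GP, c)  # (nel, 8gp, 3, 3)
    det = np.linalg.det(J)
    if np.any(det <= 0):
        bad = np.unique(np.nonzero(det <= 0)[0])
        raise InvertedElementError(
            f"non-positive Jacobian in hexahedra {bad.tolist()}")
    Jinv = np.linalg.inv(J)
    # dN/dx[n,g,i,b] = dN/dxi[g,i,a] * (J^-T)[n,g,a,b]
    dNdx = np.einsum("gia,ngba->ngib", _DN_GP, Jinv)
    D = np.array([isotropic_elasticity_matrix(e, v) for e, v in
                  zip(np.broadcast_to(E, (nel,)), np.broadcast_to(nu, (nel,)))])
    K = np.zeros((nel, 24, 24))
    for g in range(8):
        B = _strain_displacement(dNdx[:, g])  # (nel, 6, 24)
        DB = D @ B
        K += np.swapaxes(B, 1, 2) @ DB * det[:, g, None, None]
    K = 0.5 * (K + np.swapaxes(K, 1, 2))
    return K


def _strain_displacement(dNdx: np.ndarray) -> np.ndarray:
    """B matrices (nel, 6, 24) from shape gradients (nel, 8, 3)."""
    nel = dNdx.shape[0]
    B = np.zeros((nel, 6, 24))
    dx, dy, dz = dNdx[:, :, 0], dNdx[:, :, 1], dNdx[:, :, 2]
    B[:, 0, 0::3] = dx
    B[:, 1, 1::3] = dy
    B[:, 2, 2::3] = dz
    B[:, 3, 0::3] = dy
    B[:, 3, 1::3] = dx
    B[:, 4, 1::3] = dz
    B[:, 4, 2::3] = dy
    B[:, 5, 0::3] = dz
    B[:, 5, 2::3] = dx
    return B


def hex_element_stiffness(element: HexElement,
                          node_positions: np.ndarray) -> np.ndarray:
    """24x24 stiffness of one trilinear hexahedron.

    ``node_positions`` are the 8 corner coordinates (in VTK ordering) of
    this element.
    """
    coords = np.asarray(node_positions, dtype=float).reshape(1, 8, 3)
    return hex_stiffness_batch(coords, np.array([element.E]),
                               np.array([element.nu]))[0]


def hex_centroid_strain(coords: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Gauss-averaged (centroid) strain, Voigt order, for a batch.

    coords (nel, 8, 3); u (nel, 24) element displacement vectors.
    """
    c = np.asarray(coords, dtype=float)
    J = np.einsum("gia,nib->ngab", _DN_GP, c)
    Jinv = np.linalg.inv(J)
    dNdx = np.einsum("gia,ngba->ngib", _DN_GP, Jinv)
    eps = np.zeros((c.shape[0], 6))
    for g in range(8):
        B = _strain_displacement(dNdx[:, g])
        eps += np.einsum("nij,nj->ni", B, u)
    return eps / 8.0
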