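"""Structured hexahedral linear-elastic FEM with mixed boundary conditions.

The substrate (a polyacrylamide gel slab bonded to glass) is modelled as a
rectangular block of isotropic linear-elastic material, discretized into
8-node trilinear hexahedra on a structured lattice.  Displacements or forces
may be prescribed independently per node and per axis (a mixed boundary
value problem); the solver returns displacements at force-prescribed DOFs
and reaction forces at displacement-prescribed DOFs.

Unit system: kPa (stress / modulus), µm (length), nN (force).  These are
consistent: 1 kPa × 1 µm² = 1 nN, so no conversion factors appear anywhere.

Node ordering is lexicographic, i (x) fastest, then j (y), then k (z);
DOFs are (x, y, z) per node.  Layer k = 0 is the glass-bonded bottom,
k = nz−1 the free top surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    GeometryError,
    InputError,
    MaterialError,
    RankDeficiencyError,
    SolverError,
)

__all__ = [
    "SubstrateModel",
    "HexMesh",
    "MixedBCSet",
    "FemSolution",
    "BarModel1D",
    "hex8_stiffness",
    "assemble_global",
    "MbvpFactorization",
    "solve_mbvp",
    "bar_stiffness_1d",
    "bar_solve_mbvp",
]

#: free DOFs above this count switch from sparse LU to preconditioned CG
DIRECT_SOLVE_LIMIT = 200_000


@dataclass(frozen=True)
class SubstrateModel:
    """Material and geometry of the gel slab.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E in kPa.
    poissons_ratio : float
        Poisson's ratio ν, in [0, 0.5).  Exactly 0.5 is rejected: the
        incompressible limit is singular for a pure-displacement
        formulation.  Polyacrylamide gels measure around ν ≈ 0.47.
    thickness : float
        Gel thickness in µm (distance from glass to free surface).
    lateral_size_x, lateral_size_y : float
        Lateral extent of the modelled block in µm.
    """

    youngs_modulus: float
    poissons_ratio: float
    thickness: float
    lateral_size_x: float
    lateral_size_y: float

    def __post_init__(self):
        if not self.youngs_modulus > 0:
            raise MaterialError(f"Young's modulus must be > 0, got {self.youngs_modulus}")
        if not (0.0 <= self.poissons_ratio < 0.5):
            raise MaterialError(
                f"Poisson's ratio must lie in [0, 0.5); got {self.poissons_ratio}. "
                "The incompressible limit 0.5 is singular for displacement FEM."
            )
        for name in ("thickness", "lateral_size_x", "lateral_size_y"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class HexMesh:
    """Structured node lattice for the slab.

    ``nx, ny, nz`` are node counts; node (i, j, k) sits at
    ``origin + (i·sx, j·sy, k·sz)`` with k = 0 at the bottom (bonded) face
    and k = nz−1 at the free top surface.
    """

    nx: int
    ny: int
    nz: int
    spacing_x: float
    spacing_y: float
    spacing_z: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 2:
            raise GeometryError("all node counts must be >= 2")
        if min(self.spacing_x, self.spacing_y, self.spacing_z) <= 0:
            raise GeometryError("all spacings must be > 0")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def node_index(self, i, j, k):
        return i + self.nx * (j + self.ny * k)

    def top_surface_nodes(self) -> np.ndarray:
        """Node ids of the top (k = nz−1) surface, shape (ny, nx)."""
        i, j = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="xy")
        return self.node_index(i, j, self.nz - 1)

    def fixed_boundary_nodes(self) -> np.ndarray:
        """Node ids of the bottom face and the four vertical walls."""
        i, j, k = np.meshgrid(
            np.arange(self.nx), np.arange(self.ny), np.arange(self.nz), indexing="ij"
        )
        on = (k == 0) | (i == 0) | (i == self.nx - 1) | (j == 0) | (j == self.ny - 1)
        return self.node_index(i[on], j[on], k[on])

    def surface_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of top-surface nodes, each (ny, nx)."""
        x = self.origin[0] + np.arange(self.nx) * self.spacing_x
        y = self.origin[1] + np.arange(self.ny) * self.spacing_y
        return np.meshgrid(x, y, indexing="xy")


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6×6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, xz)."""
    if not (0.0 <= nu < 0.5):
        raise MaterialError(f"Poisson's ratio must be in [0, 0.5), got {nu}")
    if E <= 0:
        raise MaterialError(f"Young's modulus must be > 0, got {E}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


# local corner offsets, lexicographic (x fastest)
_CORNERS = np.array(
    [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)], dtype=float
)
_XI = 2.0 * _CORNERS - 1.0  # natural coordinates of the corners


def _b_matrix(dNdx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (Voigt xx,yy,zz,xy,yz,xz) from dN/dx (8×3)."""
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        gx, gy, gz = dNdx[a]
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


@lru_cache(maxsize=32)
def hex8_stiffness(E: float, nu: float, hx: float, hy: float, hz: float) -> np.ndarray:
    """Element stiffness of an 8-node trilinear hexahedron (mean-dilatation).

    Deviatoric response is integrated with the full 2×2×2 Gauss rule; the
    volumetric strain-displacement operator is replaced by its element
    average (the B-bar / mean-dilatation treatment).  The fully integrated
    trilinear brick locks volumetrically as ν → 0.5, which would wreck
    traction recovery on nearly incompressible gels (ν ≈ 0.47); B-bar
    removes the locking while preserving the patch test and the six
    rigid-body modes.

    Returns the 24×24 symmetric matrix in nN/µm for a box element of edge
    lengths (hx, hy, hz) µm.  Node order is lexicographic (x fastest); DOF
    order is (x, y, z) per node.
    """
    if min(hx, hy, hz) <= 0:
        raise GeometryError("element dimensions must be > 0")
    D = elasticity_matrix(E, nu)
    half = np.array([hx, hy, hz]) / 2.0  # d(x)/d(xi), diagonal Jacobian
    detJ = half.prod()
    g = 1.0 / np.sqrt(3.0)
    gauss = [np.array([p, q, r]) for p in (-g, g) for q in (-g, g) for r in (-g, g)]

    def dndx(xi):
        dN = np.empty((8, 3))
        for a in range(8):
            s = _XI[a]
            dN[a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8
            dN[a, 1] = (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) / 8
            dN[a, 2] = (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] / 8
        return dN / half  # box element: J is diagonal

    Bs = [_b_matrix(dndx(xi)) for xi in gauss]
    # element-average volumetric operator (equal weights, constant detJ)
    g_mean = np.mean([B[0] + B[1] + B[2] for B in Bs], axis=0)
    K = np.zeros((24, 24))
    for B in Bs:
        Bbar = B.copy()
        corr = (g_mean - (B[0] + B[1] + B[2])) / 3.0
        Bbar[0] += corr
        Bbar[1] += corr
        Bbar[2] += corr
        K += Bbar.T @ D @ Bbar * detJ
    K = 0.5 * (K + K.T)
    K.setflags(write=False)
    return K


def assemble_global(mesh: HexMesh, substrate: SubstrateModel) -> sp.csr_matrix:
    """Assemble the global stiffness matrix over 3·nx·ny·nz DOFs.

    The mesh must span the substrate block: (n−1)·spacing must equal the
    corresponding substrate dimension (to 1e-6 relative).
    """
    spans = (
        ((mesh.nx - 1) * mesh.spacing_x, substrate.lateral_size_x, "x"),
        ((mesh.ny - 1) * mesh.spacing_y, substrate.lateral_size_y, "y"),
        ((mesh.nz - 1) * mesh.spacing_z, substrate.thickness, "z"),
    )
    for got, want, ax in spans:
        if abs(got - want) > 1e-6 * max(want, 1.0):
            raise GeometryError(
                f"mesh span {got:g} µm along {ax} does not match substrate {want:g} µm"
            )
    Ke = hex8_stiffness(
        substrate.youngs_modulus,
        substrate.poissons_ratio,
        mesh.spacing_x,
        mesh.spacing_y,
        mesh.spacing_z,
    )
    nx, ny, nz = mesh.nx, mesh.ny, mesh.nz
    ii, jj, kk = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    n0 = (ii + nx * (jj + ny * kk)).ravel()
    corner_off = np.array(
        [a + nx * (b + ny * c) for (a, b, c) in _CORNERS.astype(int)], dtype=np.int64
    )
    enodes = n0[:, None] + corner_off[None, :]  # (E, 8)
    edofs = (3 * enodes[:, :, None] + np.arange(3)).reshape(-1, 24).astype(np.int32)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = np.tile(Ke.ravel(), edofs.shape[0])
    K = sp.coo_matrix((data, (rows, cols)), shape=(mesh.n_dofs, mesh.n_dofs)).tocsr()
    return K


class MixedBCSet:
    """Per-DOF boundary prescription: displacement (µm) or force (nN).

    Every DOF carries exactly one prescription.  The default is a prescribed
    force of zero (a natural, traction-free condition); calling
    :meth:`prescribe_displacement` switches DOFs to Dirichlet.
    """

    def __init__(self, n_dofs: int):
        self.n_dofs = int(n_dofs)
        self.is_dirichlet = np.zeros(self.n_dofs, dtype=bool)
        self.value = np.zeros(self.n_dofs, dtype=float)

    @staticmethod
    def dofs(node_ids, axis: int) -> np.ndarray:
        """DOF indices for the given node ids along axis 0 (x), 1 (y) or 2 (z)."""
        return 3 * np.asarray(node_ids, dtype=np.int64).ravel() + axis

    def prescribe_displacement(self, dof_ids, values) -> None:
        dof_ids = np.asarray(dof_ids, dtype=np.int64).ravel()
        values = np.broadcast_to(np.asarray(values, dtype=float).ravel(), dof_ids.shape)
        if not np.all(np.isfinite(values)):
            raise InputError("non-finite displacement prescription")
        self.is_dirichlet[dof_ids] = True
        self.value[dof_ids] = values

    def prescribe_force(self, dof_ids, values) -> None:
        dof_ids = np.asarray(dof_ids, dtype=np.int64).ravel()
        values = np.broadcast_to(np.asarray(values, dtype=float).ravel(), dof_ids.shape)
        if not np.all(np.isfinite(values)):
            raise InputError("non-finite force prescription")
        self.is_dirichlet[dof_ids] = False
        self.value[dof_ids] = values

    def scaled(self, c: float) -> "MixedBCSet":
        out = MixedBCSet(self.n_dofs)
        out.is_dirichlet = self.is_dirichlet.copy()
        out.value = c * self.value
        return out


@dataclass
class FemSolution:
    """Solution of one mixed boundary value problem.

    ``displacements`` holds every nodal DOF in µm.  ``reactions`` holds the
    reaction force in nN at displacement-prescribed DOFs and zero elsewhere
    (at force-prescribed DOFs the internal force equals the applied force by
    equilibrium, up to the solver residual).
    """

    displacements: np.ndarray
    reactions: np.ndarray
    is_dirichlet: np.ndarray
    residual: float


class MbvpFactorization:
    """Reusable solver for a fixed stiffness matrix and Dirichlet pattern.

    Factorizes the free-free block once; :meth:`solve` may then be called
    with many different prescribed values (same partition).  This is what
    makes the iterative whole-field scheme cheap: each cycle reuses two
    factorizations.
    """

    def __init__(
        self,
        K: sp.spmatrix,
        is_dirichlet: np.ndarray,
        *,
        direct_limit: int = DIRECT_SOLVE_LIMIT,
        tol: float = 1e-8,
    ):
        self.K = K.tocsr()
        self.is_dirichlet = np.asarray(is_dirichlet, dtype=bool)
        if self.is_dirichlet.shape != (K.shape[0],):
            raise InputError("Dirichlet mask length does not match matrix size")
        if not self.is_dirichlet.any():
            raise RankDeficiencyError(
                "no displacement prescribed anywhere: all six rigid-body modes "
                "(3 translations + 3 rotations) are unconstrained"
            )
        self.tol = tol
        self.free = np.flatnonzero(~self.is_dirichlet)
        self.diri = np.flatnonzero(self.is_dirichlet)
        Kf = self.K[self.free]
        self.Kff = Kf[:, self.free].tocsc()
        self.Kfd = Kf[:, self.diri].tocsr()
        self._lu = None
        self._precond = None
        if self.free.size == 0:
            return
        if self.free.size <= direct_limit:
            try:
                self._lu = spla.splu(self.Kff)
            except RuntimeError as exc:  # SuperLU reports exactly singular
                raise RankDeficiencyError(
                    f"reduced stiffness matrix is singular ({exc}); a rigid-body "
                    "mode is likely unconstrained"
                ) from exc
        else:
            d = self.Kff.diagonal()
            if np.any(d <= 0):
                raise RankDeficiencyError("non-positive diagonal in reduced system")
            inv_d = 1.0 / d
            self._precond = spla.LinearOperator(
                self.Kff.shape, matvec=lambda v: inv_d * v
            )

    def _solve_reduced(self, rhs: np.ndarray) -> np.ndarray:
        if self._lu is not None:
            x = self._lu.solve(rhs)
        else:
            x, info = spla.cg(
                self.Kff, rhs, rtol=self.tol, atol=0.0, maxiter=20000, M=self._precond
            )
            if info != 0:
                res = float(np.linalg.norm(self.Kff @ x - rhs))
                raise SolverError(
                    f"conjugate gradients did not converge (info={info})", residual=res
                )
        if not np.all(np.isfinite(x)):
            raise RankDeficiencyError(
                "solver produced non-finite displacements; the reduced system is "
                "singular or extremely ill-conditioned"
            )
        return x

    def solve(self, values: np.ndarray) -> FemSolution:
        """Solve for the given per-DOF prescribed values.

        ``values[d]`` is the prescribed displacement (µm) at Dirichlet DOFs
        and the prescribed force (nN) at the rest.
        """
        values = np.asarray(values, dtype=float)
        u = values.copy()
        f_free = values[self.free]
        rhs = f_free - self.Kfd @ values[self.diri]
        if self.free.size:
            u[self.free] = self._solve_reduced(rhs)
        internal = self.K @ u
        scale = max(np.linalg.norm(rhs), np.linalg.norm(internal), 1e-30)
        residual = float(np.linalg.norm(internal[self.free] - f_free) / scale)
        if residual > 100 * max(self.tol, 1e-12):
            raise SolverError(
                f"equilibrium residual {residual:.3e} exceeds tolerance", residual=residual
            )
        reactions = np.zeros_like(u)
        reactions[self.diri] = internal[self.diri]
        return FemSolution(
            displacements=u,
            reactions=reactions,
            is_dirichlet=self.is_dirichlet.copy(),
            residual=residual,
        )


def solve_mbvp(
    K: sp.spmatrix,
    bc: MixedBCSet,
    *,
    direct_limit: int = DIRECT_SOLVE_LIMIT,
    tol: float = 1e-8,
) -> FemSolution:
    """One-shot mixed boundary value solve; see :class:`MbvpFactorization`."""
    fact = MbvpFactorization(K, bc.is_dirichlet, direct_limit=direct_limit, tol=tol)
    return fact.solve(bc.value)


# ---------------------------------------------------------------------------
# 1D elastic bar: the minimal system in which a mixed boundary value problem
# shows that zero displacement does not imply zero force and vice versa.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarModel1D:
    """Chain of linear springs with one scalar DOF per node.

    ``element_stiffnesses`` are the n element (spring) constants in nN/µm;
    ``bc`` gives one prescription per node: ``("u", value)`` for a
    displacement (µm) or ``("f", value)`` for a force (nN).
    """

    element_stiffnesses: tuple[float, ...]
    bc: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self):
        if len(self.element_stiffnesses) == 0:
            raise InputError("need at least one element stiffness")
        if any(k <= 0 for k in self.element_stiffnesses):
            raise InputError("element stiffnesses must all be > 0")
        n_nodes = len(self.element_stiffnesses) + 1
        if self.bc and len(self.bc) != n_nodes:
            raise InputError(f"need one boundary prescription per node ({n_nodes})")
        for kind, _ in self.bc:
            if kind not in ("u", "f"):
                raise InputError(f"unknown prescription kind {kind!r}")


def bar_stiffness_1d(stiffnesses) -> np.ndarray:
    """Symmetric tridiagonal stiffness matrix of a spring chain.

    For stiffnesses (k1, k2) this is
    [[k1, −k1, 0], [−k1, k1+k2, −k2], [0, −k2, k2]]; every row sums to zero
    (a rigid translation costs no energy).
    """
    stiffnesses = tuple(float(k) for k in stiffnesses)
    if len(stiffnesses) == 0 or any(k <= 0 for k in stiffnesses):
        raise InputError("stiffnesses must be a non-empty list of positive values")
    n = len(stiffnesses)
    K = np.zeros((n + 1, n + 1))
    for e, k in enumerate(stiffnesses):
        K[e : e + 2, e : e + 2] += k * np.array([[1.0, -1.0], [-1.0, 1.0]])
    return K


def bar_solve_mbvp(bar: BarModel1D) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 1D bar MBVP; returns (displacements, nodal forces).

    The returned forces satisfy ΣF = 0 (global equilibrium): the reaction
    forces at displacement-prescribed nodes balance the applied ones.
    """
    if not bar.bc:
        raise InputError("bar has no boundary prescriptions")
    K = bar_stiffness_1d(bar.element_stiffnesses)
    n = K.shape[0]
    kinds = np.array([kind for kind, _ in bar.bc])
    vals = np.array([v for _, v in bar.bc], dtype=float)
    diri = kinds == "u"
    if not diri.any():
        raise RankDeficiencyError(
            "all-force prescriptions leave the rigid translation mode free"
        )
    free = ~diri
    u = np.zeros(n)
    u[diri] = vals[diri]
    if free.any():
        Kff = K[np.ix_(free, free)]
        rhs = vals[free] - K[np.ix_(free, diri)] @ vals[diri]
        u[free] = np.linalg.solve(Kff, rhs)
    F = K @ u
    return u, F
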