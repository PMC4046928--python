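"""Bridge between a surface grid and the 3D FEM block underneath it.

The displacement/mask grid coincides node-for-node with the top surface of
the hexahedral mesh.  The vertical discretization is controlled separately:
traction varies laterally on the cell scale but the through-thickness
response is smooth, so elements are allowed a vertical aspect ratio
(``z_aspect`` × in-plane spacing, default 2) that roughly halves the number
of unknowns without measurable effect on recovered tractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .errors import GeometryError
from .fields import ClusterMask, SurfaceGrid
from .mesh_fem import HexMesh, SubstrateModel, assemble_global

__all__ = ["Domain", "domain_for_grid", "required_margin", "check_mask_margin"]

DEFAULT_Z_ASPECT = 2.0


def _n_layers(thickness: float, spacing: float, z_aspect: float, spacing_z) -> int:
    if spacing_z is not None:
        n = max(2, round(thickness / spacing_z))
    else:
        n = max(4, int(np.ceil(thickness / (z_aspect * spacing))))
    return n


@dataclass(frozen=True)
class Domain:
    """A substrate block, its mesh, and the surface grid on top of it."""

    substrate: SubstrateModel
    mesh: HexMesh
    grid: SurfaceGrid

    @property
    def stiffness(self) -> sp.csr_matrix:
        return _assembled(self.mesh, self.substrate)

    def top_interior_nodes(self) -> np.ndarray:
        """Top-surface node ids excluding the wall ring, shape (ny−2, nx−2)."""
        return self.mesh.top_surface_nodes()[1:-1, 1:-1]


@lru_cache(maxsize=6)
def _assembled(mesh: HexMesh, substrate: SubstrateModel) -> sp.csr_matrix:
    return assemble_global(mesh, substrate)


def domain_for_grid(
    grid: SurfaceGrid,
    substrate: SubstrateModel,
    *,
    z_aspect: float = DEFAULT_Z_ASPECT,
    spacing_z: float | None = None,
) -> Domain:
    """Build the FEM block whose top surface is exactly ``grid``.

    The grid extent must match the substrate's lateral size; the number of
    element layers through the thickness follows the ``z_aspect`` rule (or
    an explicit ``spacing_z``).
    """
    for got, want, ax in (
        (grid.size_x, substrate.lateral_size_x, "x"),
        (grid.size_y, substrate.lateral_size_y, "y"),
    ):
        if abs(got - want) > 1e-6 * max(want, 1.0):
            raise GeometryError(
                f"surface grid spans {got:g} µm along {ax} but the substrate "
                f"is {want:g} µm"
            )
    spacing = min(grid.spacing_x, grid.spacing_y)
    nlayers = _n_layers(substrate.thickness, spacing, z_aspect, spacing_z)
    mesh = HexMesh(
        nx=grid.nx,
        ny=grid.ny,
        nz=nlayers + 1,
        spacing_x=grid.spacing_x,
        spacing_y=grid.spacing_y,
        spacing_z=substrate.thickness / nlayers,
        origin=grid.origin,
    )
    return Domain(substrate=substrate, mesh=mesh, grid=grid)


def required_margin(mask: ClusterMask, thickness: float) -> float:
    """Minimum distance the lateral walls must keep from any labeled node.

    The walls carry zero displacement; placed too close they would clamp
    the very deformation the recovery needs.  The rule is
    max(thickness, 0.75 × mask bounding-box diagonal, 30 µm).
    """
    lab = mask.labels > 0
    if not lab.any():
        return 0.0
    jj, ii = np.nonzero(lab)
    wx = (ii.max() - ii.min()) * mask.grid.spacing_x
    wy = (jj.max() - jj.min()) * mask.grid.spacing_y
    diag = float(np.hypot(wx, wy))
    return max(thickness, 0.75 * diag, 30.0)


def check_mask_margin(
    mask: ClusterMask, substrate: SubstrateModel, min_margin: float | None = None
) -> None:
    """Raise GeometryError if labeled nodes sit too close to the lateral walls."""
    lab = mask.labels > 0
    if not lab.any():
        return
    need = required_margin(mask, substrate.thickness) if min_margin is None else min_margin
    g = mask.grid
    jj, ii = np.nonzero(lab)
    x = g.origin[0] + ii * g.spacing_x
    y = g.origin[1] + jj * g.spacing_y
    dist = min(
        (x - g.origin[0]).min(),
        (g.origin[0] + g.size_x - x).min(),
        (y - g.origin[1]).min(),
        (g.origin[1] + g.size_y - y).min(),
    )
    if dist < need - 1e-9:
        raise GeometryError(
            f"labeled nodes come within {dist:.1f} µm of the lateral walls; "
            f"at least {need:.1f} µm of traction-free margin is required "
            "(enlarge the modelled domain or pass min_margin explicitly)"
        )
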