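"""Synthetic ground truth: prescribed traction fields and the forward model.

Validation of an inverse method needs inputs whose answer is known.  The
generators here prescribe self-equilibrated nodal force fields mimicking
contractile cells (the canonical case: two 20 µm circular "cells" 10 µm
apart on a 1 kPa, 70 µm gel), the forward FEM turns them into the surface
displacement field a microscope would see, and Gaussian noise can be added
to emulate bead-tracking error.  The classical half-space (Cerruti) surface
Green's function for a tangential point load is provided as an independent
analytic oracle for the deep-substrate limit.
"""

from __future__ import annotations

import numpy as np

from .domain import DEFAULT_Z_ASPECT, domain_for_grid
from .errors import GeometryError, InputError
from .fields import (
    PrescribedForceField,
    SurfaceDisplacementField,
    SurfaceGrid,
    tributary_areas,
)
from .mesh_fem import MixedBCSet, SubstrateModel, solve_mbvp

__all__ = [
    "make_two_cell_fixture",
    "make_contractile_disk",
    "make_point_force_fixture",
    "forward_surface_displacements",
    "add_displacement_noise",
    "cerruti_surface_displacement",
    "cerruti_displacement_field",
    "deep_substrate_point_force_profile",
    "two_cell_mask_labels",
]

DEFAULT_MARGIN_FLOOR = 30.0  # µm


def _fixture_margin(thickness: float, bbox_diag: float, margin) -> float:
    if margin is not None:
        return float(margin)
    return max(thickness, 0.75 * bbox_diag, DEFAULT_MARGIN_FLOOR)


def _centered_grid(half_x: float, half_y: float, spacing: float) -> SurfaceGrid:
    """Symmetric grid about (0, 0) with a node exactly at the origin."""
    nhx = int(np.ceil(half_x / spacing - 1e-9))
    nhy = int(np.ceil(half_y / spacing - 1e-9))
    return SurfaceGrid(
        nx=2 * nhx + 1,
        ny=2 * nhy + 1,
        spacing_x=spacing,
        spacing_y=spacing,
        origin=(-nhx * spacing, -nhy * spacing),
    )


def _substrate_for(grid: SurfaceGrid, E, nu, thickness) -> SubstrateModel:
    return SubstrateModel(
        youngs_modulus=E,
        poissons_ratio=nu,
        thickness=thickness,
        lateral_size_x=grid.size_x,
        lateral_size_y=grid.size_y,
    )


def _balance_cluster(f: np.ndarray, sel: np.ndarray) -> None:
    """Remove the (rasterization-induced) net force of a cluster in place."""
    n = int(sel.sum())
    if n:
        f[sel] -= f[sel].sum() / n


def two_cell_mask_labels(
    grid: SurfaceGrid, diameter: float = 20.0, gap: float = 10.0
) -> np.ndarray:
    """Labels 1 and 2 for two circles of given diameter with edge-to-edge gap."""
    R = diameter / 2.0
    cx = gap / 2.0 + R
    X, Y = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[(X + cx) ** 2 + Y**2 <= R**2 + 1e-9] = 1
    labels[(X - cx) ** 2 + Y**2 <= R**2 + 1e-9] = 2
    return labels


def make_two_cell_fixture(
    *,
    diameter: float = 20.0,
    gap: float = 10.0,
    youngs_modulus: float = 1.0,
    poissons_ratio: float = 0.45,
    thickness: float = 70.0,
    spacing: float = 4.84,
    peak_force: float = 0.5,
    pattern: str = "contractile_pair",
    fz_ratio: float = 0.0,
    margin: float | None = None,
    seed: int | None = None,
) -> PrescribedForceField:
    """Two circular "cells", each carrying a self-equilibrated force field.

    Default geometry: 20 µm diameter circles separated by a 10 µm
    (half-cell) gap on a 1 kPa, 70 µm-thick gel.  ``pattern`` selects how
    forces are laid out inside each circle:

    - ``contractile_pair``: the two halves of each circle (split across the
      inter-cell axis) pull toward each other with equal and opposite nodal
      forces of magnitude ``peak_force`` nN.
    - ``ring``: every node pulls radially toward its circle's center.
    - ``tapered_pair``: like ``contractile_pair`` but with a smooth
      amplitude ∝ (dx/R)(1 − (r/R)²) that vanishes at the rim; the force
      field is continuous at the mesh scale, which matters when comparing
      against continuum limits.

    ``fz_ratio`` = k adds an out-of-plane component of magnitude
    k·|in-plane| at every loaded node (sign following the in-plane sign, so
    each cluster stays self-equilibrated in z as well).
    """
    if gap <= 0:
        raise GeometryError("circles overlap or touch: gap must be > 0")
    if pattern not in ("contractile_pair", "ring", "tapered_pair"):
        raise InputError(f"unknown pattern {pattern!r}")
    R = diameter / 2.0
    cx = gap / 2.0 + R
    bbox_diag = float(np.hypot(2 * cx + diameter, diameter))
    m = _fixture_margin(thickness, bbox_diag, margin)
    grid = _centered_grid(cx + R + m, R + m, spacing)
    labels = two_cell_mask_labels(grid, diameter, gap)
    X, Y = grid.meshgrid()
    fx = np.zeros(grid.shape)
    fy = np.zeros(grid.shape)
    for c, x0 in ((1, -cx), (2, cx)):
        sel = labels == c
        if pattern == "contractile_pair":
            dx = X - x0
            left = sel & (dx < 0)
            right = sel & (dx > 0)
            n_l, n_r = int(left.sum()), int(right.sum())
            if n_l == 0 or n_r == 0:
                raise GeometryError("disk too small for the grid spacing")
            # the halves pull toward each other; when rasterization leaves
            # the halves with unequal node counts, the larger-count half is
            # scaled down so the cluster stays exactly self-equilibrated
            # while the peak nodal force remains `peak_force`
            a, b = 1.0, n_l / n_r
            s = peak_force / max(a, b)
            fx[left] = a * s
            fx[right] = -b * s
        elif pattern == "tapered_pair":
            dx, dy = X - x0, Y
            r2 = (dx**2 + dy**2) / R**2
            amp = -(dx / R) * np.maximum(1.0 - r2, 0.0)
            # normalize so the peak nodal force equals peak_force
            amp = amp / (2.0 / (3.0 * np.sqrt(3.0)))  # max of x(1-x^2) on [0,1]
            fx[sel] = (peak_force * amp)[sel]
            _balance_cluster(fx, sel)
        else:  # ring
            dx, dy = X - x0, Y
            r = np.hypot(dx, dy)
            rs = np.where(r > 0, r, 1.0)
            fx[sel] = (-peak_force * dx / rs)[sel]
            fy[sel] = (-peak_force * dy / rs)[sel]
        _balance_cluster(fx, sel)
        _balance_cluster(fy, sel)
    fz = fz_ratio * np.sign(fx + np.where(fx == 0, fy, 0)) * np.hypot(fx, fy)
    substrate = _substrate_for(grid, youngs_modulus, poissons_ratio, thickness)
    return PrescribedForceField(
        grid=grid,
        fx=fx,
        fy=fy,
        fz=fz,
        labels=labels,
        metadata={
            "generator": "two_cell",
            "diameter_um": diameter,
            "gap_um": gap,
            "peak_force_nN": peak_force,
            "pattern": pattern,
            "fz_ratio": fz_ratio,
            "seed": seed,
        },
        substrate=substrate,
    )


def make_contractile_disk(
    *,
    radius: float = 15.0,
    center: tuple[float, float] = (0.0, 0.0),
    peak_traction: float = 0.1,
    youngs_modulus: float = 1.0,
    poissons_ratio: float = 0.45,
    thickness: float = 70.0,
    spacing: float = 4.84,
    margin: float | None = None,
    seed: int | None = None,
) -> PrescribedForceField:
    """A single circular cluster pulling radially inward, traction ∝ r/R.

    Peak traction (kPa) occurs at the rim; nodal forces are traction times
    the tributary area, then balanced exactly.
    """
    m = _fixture_margin(thickness, 2 * np.sqrt(2.0) * radius, margin)
    half_x = abs(center[0]) + radius + m
    half_y = abs(center[1]) + radius + m
    grid = _centered_grid(half_x, half_y, spacing)
    X, Y = grid.meshgrid()
    dx, dy = X - center[0], Y - center[1]
    r = np.hypot(dx, dy)
    sel = r <= radius + 1e-9
    area = tributary_areas(grid)
    mag = peak_traction * r / radius
    fx = np.where(sel & (r > 0), -mag * dx / np.where(r > 0, r, 1.0) * area, 0.0)
    fy = np.where(sel & (r > 0), -mag * dy / np.where(r > 0, r, 1.0) * area, 0.0)
    _balance_cluster(fx, sel)
    _balance_cluster(fy, sel)
    labels = np.where(sel, 1, 0).astype(np.int32)
    substrate = _substrate_for(grid, youngs_modulus, poissons_ratio, thickness)
    return PrescribedForceField(
        grid=grid,
        fx=fx,
        fy=fy,
        fz=np.zeros(grid.shape),
        labels=labels,
        metadata={
            "generator": "contractile_disk",
            "radius_um": radius,
            "peak_traction_kPa": peak_traction,
            "seed": seed,
        },
        substrate=substrate,
    )


def make_point_force_fixture(
    *,
    force: float = 1.0,
    youngs_modulus: float = 1.0,
    poissons_ratio: float = 0.45,
    thickness: float = 240.0,
    spacing: float = 4.0,
    lateral_half_size: float = 100.0,
) -> PrescribedForceField:
    """A single tangential point force at the domain center (micro-needle analogue).

    Not self-equilibrated: the probe force is reacted by the glass and walls.
    """
    grid = _centered_grid(lateral_half_size, lateral_half_size, spacing)
    fx = np.zeros(grid.shape)
    j0, i0 = grid.ny // 2, grid.nx // 2
    fx[j0, i0] = force
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[j0, i0] = 1
    substrate = _substrate_for(grid, youngs_modulus, poissons_ratio, thickness)
    return PrescribedForceField(
        grid=grid,
        fx=fx,
        fy=np.zeros(grid.shape),
        fz=np.zeros(grid.shape),
        labels=labels,
        metadata={"generator": "point_force", "force_nN": force},
        substrate=substrate,
        self_equilibrated=False,
    )


def forward_surface_displacements(
    field: PrescribedForceField,
    substrate: SubstrateModel | None = None,
    *,
    with_z: bool = True,
    z_aspect: float = DEFAULT_Z_ASPECT,
    spacing_z: float | None = None,
    tol: float = 1e-8,
) -> SurfaceDisplacementField:
    """Forward-solve the slab under the prescribed surface forces.

    The bottom face and the four walls are fixed; every interior top node
    carries its prescribed nodal force (zero outside the clusters).  Returns
    the top-surface displacements — exactly what bead imaging would measure,
    minus noise.
    """
    substrate = substrate if substrate is not None else field.substrate
    if substrate is None:
        raise InputError("no substrate given and the force field carries none")
    dom = domain_for_grid(field.grid, substrate, z_aspect=z_aspect, spacing_z=spacing_z)
    ring = np.ones(field.grid.shape, dtype=bool)
    ring[1:-1, 1:-1] = False
    for comp in (field.fx, field.fy, field.fz):
        if np.any(comp[ring] != 0):
            raise GeometryError("prescribed forces touch the wall ring; enlarge domain")
    bc = MixedBCSet(dom.mesh.n_dofs)
    fixed = dom.mesh.fixed_boundary_nodes()
    for ax in range(3):
        bc.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
    top = dom.top_interior_nodes()
    inner = (slice(1, -1), slice(1, -1))
    bc.prescribe_force(MixedBCSet.dofs(top, 0), field.fx[inner].ravel())
    bc.prescribe_force(MixedBCSet.dofs(top, 1), field.fy[inner].ravel())
    bc.prescribe_force(MixedBCSet.dofs(top, 2), field.fz[inner].ravel())
    sol = solve_mbvp(dom.stiffness, bc, tol=tol)
    u = sol.displacements
    top_all = dom.mesh.top_surface_nodes()
    ux = u[3 * top_all]
    uy = u[3 * top_all + 1]
    uz = u[3 * top_all + 2] if with_z else None
    return SurfaceDisplacementField(field.grid, ux, uy, uz)


def add_displacement_noise(
    disp: SurfaceDisplacementField, sigma: float, seed: int
) -> SurfaceDisplacementField:
    """Add i.i.d. zero-mean Gaussian noise (std ``sigma`` µm) per node and axis."""
    if sigma < 0:
        raise InputError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ux = disp.ux + rng.normal(0.0, sigma, disp.grid.shape) if sigma else disp.ux.copy()
    uy = disp.uy + rng.normal(0.0, sigma, disp.grid.shape) if sigma else disp.uy.copy()
    uz = None
    if disp.uz is not None:
        uz = disp.uz + rng.normal(0.0, sigma, disp.grid.shape) if sigma else disp.uz.copy()
    return SurfaceDisplacementField(disp.grid, ux, uy, uz, disp.valid.copy())


def deep_substrate_point_force_profile(
    *,
    force: float = 1.0,
    youngs_modulus: float = 1.0,
    poissons_ratio: float = 0.45,
    spacing: float = 4.0,
    thickness: float = 400.0,
    wall_distance_x: float = 240.0,
    wall_distance_y: float = 200.0,
    spacing_y: float = 10.0,
    spacing_z: float = 20.0,
    tol: float = 1e-8,
) -> dict:
    """Surface displacement profile under a tangential point load, deep substrate.

    Solves a quarter-symmetry model of a very thick slab (default 400 µm —
    more than 10× the largest observation radius of 6 grid spacings)
    loaded by a single tangential nodal force at the center of the top
    surface, and returns the FEM ``ux`` profile along the force axis
    together with the half-space (Cerruti) closed-form values.  The fixed
    far walls sit 10× the observation radius away along the measurement
    axis; the domain is stretched (coarser spacing) along y and z, where
    the solution varies slowly, to keep the solve tractable.  The two
    symmetry planes carry the standard conditions (x = 0, the
    antisymmetry plane: uy = uz = 0; y = 0, the mirror plane: uy = 0) and
    the shared corner node takes F/4.

    Returns a dict with keys ``r_um``, ``ux_parallel``, ``cerruti_parallel``.
    """
    from .mesh_fem import HexMesh, MbvpFactorization, MixedBCSet, assemble_global

    nx = int(round(wall_distance_x / spacing)) + 1
    ny = int(round(wall_distance_y / spacing_y)) + 1
    nz = int(round(thickness / spacing_z)) + 1
    mesh = HexMesh(
        nx=nx, ny=ny, nz=nz,
        spacing_x=spacing, spacing_y=spacing_y,
        spacing_z=thickness / (nz - 1),
    )
    substrate = SubstrateModel(
        youngs_modulus=youngs_modulus,
        poissons_ratio=poissons_ratio,
        thickness=thickness,
        lateral_size_x=(nx - 1) * spacing,
        lateral_size_y=(ny - 1) * spacing_y,
    )
    K = assemble_global(mesh, substrate)
    bc = MixedBCSet(mesh.n_dofs)
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    nodes = mesh.node_index(i, j, k)
    fixed = nodes[(k == 0) | (i == nx - 1) | (j == ny - 1)]
    for ax in range(3):
        bc.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
    sym_x = nodes[i == 0]  # x = 0 plane: uy, uz vanish by antisymmetry
    bc.prescribe_displacement(MixedBCSet.dofs(sym_x, 1), 0.0)
    bc.prescribe_displacement(MixedBCSet.dofs(sym_x, 2), 0.0)
    sym_y = nodes[j == 0]  # y = 0 plane: uy vanishes by mirror symmetry
    bc.prescribe_displacement(MixedBCSet.dofs(sym_y, 1), 0.0)
    corner = mesh.node_index(0, 0, nz - 1)
    bc.prescribe_force(MixedBCSet.dofs([corner], 0), force / 4.0)
    sol = MbvpFactorization(K, bc.is_dirichlet, tol=tol).solve(bc.value)
    u = sol.displacements
    r = np.arange(1, nx - 1) * spacing
    ux_par = np.array(
        [u[3 * mesh.node_index(ii, 0, nz - 1)] for ii in range(1, nx - 1)]
    )
    return {
        "r_um": r,
        "ux_parallel": ux_par,
        "cerruti_parallel": np.array(
            [cerruti_surface_displacement(force, youngs_modulus, poissons_ratio, rr)
             for rr in r]
        ),
    }


def cerruti_surface_displacement(
    force: float, E: float, nu: float, r: float, direction: str = "parallel"
) -> float:
    """Half-space surface displacement along the force axis at distance r.

    For a tangential point force F on the surface of an elastic half space,
    the surface displacement parallel to the force is
    u = F(1+ν)/(πEr) on the force axis and u = F(1+ν)(1−ν)/(πEr) on the
    perpendicular axis.  Used as the deep-substrate oracle: a finite slab
    much thicker than the observation radius must approach these values.
    """
    if r <= 0:
        raise InputError("the point-load solution is singular at r = 0")
    base = force * (1 + nu) / (np.pi * E * r)
    if direction == "parallel":
        return base
    if direction == "perpendicular":
        return base * (1 - nu)
    raise InputError(f"direction must be 'parallel' or 'perpendicular', got {direction!r}")


def cerruti_displacement_field(force, E, nu, x, y):
    """Full surface (ux, uy) of the tangential point-load half-space solution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    if np.any(r <= 0):
        raise InputError("the point-load solution is singular at r = 0")
    A = force * (1 + nu) / (np.pi * E)
    ux = A * ((1 - nu) / r + nu * x**2 / r**3)
    uy = A * nu * x * y / r**3
    return ux, uy
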