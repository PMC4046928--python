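"""Traction recovery from measured surface displacements.

Two schemes are implemented.

**Mixed boundary conditions** (the method of choice): displacements are
prescribed only at nodes under the cells, the exact traction-free condition
(F = 0) is prescribed everywhere else on the free surface, and the walls
and bottom are fixed.  One linear solve returns the reaction forces at the
displacement-prescribed nodes — these are the cell tractions.  Because the
extracellular boundary condition is exact, no displacement data outside the
cells and no regularization are needed, and the solution is unique.

**Iterative whole-field displacements**: the traditional alternative that
prescribes the measured (ux, uy) over the entire surface, then alternates
between (i) zeroing the spurious extracellular forces, (ii) forward-solving
for an updated displacement field, and (iii) restoring the measured
displacements under the cells, until the RMS of surface nodal forces
changes by less than ``rms_tol`` (default 5%) between cycles.

Out-of-plane handling: if the field carries no uz, a zero out-of-plane
force (Fz = 0) is prescribed under the cells.  For nearly incompressible
gels (ν ≥ 0.4, e.g. polyacrylamide at ν ≈ 0.47) the in-plane problem
decouples from Fz and the in-plane traction error stays small; for lower ν
the coupling is strong and the recovery refuses to run without uz unless
explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .domain import DEFAULT_Z_ASPECT, Domain, check_mask_margin, domain_for_grid
from .errors import AlignmentError, InputError, NonConvergenceError
from .fields import ClusterMask, SurfaceDisplacementField, TractionField
from .mesh_fem import MbvpFactorization, MixedBCSet, SubstrateModel

__all__ = [
    "RecoveryReport",
    "recover_mixed",
    "recover_whole_field_iterative",
    "error_ratio",
    "rms_difference",
    "cluster_net_force",
]

NU_DECOUPLING_THRESHOLD = 0.4


@dataclass
class RecoveryReport:
    """Summary of one recovery run.

    ``error_ratios`` maps cluster id → ε = ‖net in-plane force‖ / Σ‖force‖,
    the self-equilibration measure (0 for an exact solution; NaN when a
    cluster carries no force at all).  ``residual_history`` holds the
    relative RMS force change per cycle (iterative mode only).
    """

    error_ratios: dict[int, float] = field(default_factory=dict)
    net_forces: dict[int, np.ndarray] = field(default_factory=dict)
    rms_traction: float = 0.0
    iterations: int = 1
    residual_history: list[float] = field(default_factory=list)
    solver_residual: float = 0.0


def _smooth(disp: SurfaceDisplacementField, sigma: float) -> SurfaceDisplacementField:
    def g(a):
        return ndimage.gaussian_filter(a, sigma, mode="nearest")

    return SurfaceDisplacementField(
        disp.grid,
        g(disp.ux),
        g(disp.uy),
        None if disp.uz is None else g(disp.uz),
        disp.valid.copy(),
    )


def _align(disp: SurfaceDisplacementField, mask: ClusterMask) -> SurfaceDisplacementField:
    if disp.grid.same_geometry(mask.grid):
        return disp
    return disp.resample_to(mask.grid)


def _check_labeled_valid(disp, mask):
    bad = (mask.labels > 0) & ~disp.valid
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise InputError(
            f"labeled node (i={i}, j={j}) at x={mask.grid.x()[i]:.2f}, "
            f"y={mask.grid.y()[j]:.2f} µm has no valid displacement data"
        )


def _z_mode(disp: SurfaceDisplacementField, nu: float, allow_low_poisson: bool) -> str:
    if disp.has_z:
        return "dirichlet"
    if nu >= NU_DECOUPLING_THRESHOLD or allow_low_poisson:
        return "zero_force"
    raise InputError(
        f"no uz data and Poisson's ratio {nu} < {NU_DECOUPLING_THRESHOLD}: the "
        "in-plane problem does not decouple from the out-of-plane traction at "
        "low ν, so all three displacement components must be prescribed "
        "(pass allow_low_poisson=True to override)"
    )


def _report_for(tf: TractionField, iterations=1, history=None, residual=0.0) -> RecoveryReport:
    rep = RecoveryReport(
        iterations=iterations,
        residual_history=list(history or []),
        solver_residual=residual,
    )
    labeled = tf.labels > 0
    rep.rms_traction = (
        float(np.sqrt(np.mean(tf.traction_magnitude()[labeled] ** 2))) if labeled.any() else 0.0
    )
    for c in sorted(int(v) for v in np.unique(tf.labels) if v != 0):
        rep.error_ratios[c] = error_ratio(tf, c)
        rep.net_forces[c] = cluster_net_force(tf, c)
    return rep


def recover_mixed(
    disp: SurfaceDisplacementField,
    mask: ClusterMask,
    substrate: SubstrateModel,
    *,
    smooth_sigma: float | None = None,
    min_margin: float | None = None,
    allow_low_poisson: bool = False,
    z_aspect: float = DEFAULT_Z_ASPECT,
    spacing_z: float | None = None,
    tol: float = 1e-8,
) -> tuple[TractionField, RecoveryReport]:
    """Mixed-boundary-condition recovery (single solve, no regularization).

    Under the labeled nodes the measured displacements are prescribed
    (ux, uy, and uz when available, else Fz = 0); every other free-surface
    node is exactly traction-free; walls and bottom are fixed.  Traction
    outside the labels is zero by construction; inside it comes from the
    Dirichlet reactions divided by the nodal tributary area.
    """
    disp = _align(disp, mask)
    if smooth_sigma:
        disp = _smooth(disp, smooth_sigma)
    _check_labeled_valid(disp, mask)
    check_mask_margin(mask, substrate, min_margin)
    zmode = _z_mode(disp, substrate.poissons_ratio, allow_low_poisson)
    dom = domain_for_grid(mask.grid, substrate, z_aspect=z_aspect, spacing_z=spacing_z)

    bc = MixedBCSet(dom.mesh.n_dofs)
    fixed = dom.mesh.fixed_boundary_nodes()
    for ax in range(3):
        bc.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
    inner = (slice(1, -1), slice(1, -1))
    lab_in = mask.labels[inner] > 0
    top = dom.top_interior_nodes()[lab_in]
    bc.prescribe_displacement(MixedBCSet.dofs(top, 0), disp.ux[inner][lab_in])
    bc.prescribe_displacement(MixedBCSet.dofs(top, 1), disp.uy[inner][lab_in])
    if zmode == "dirichlet":
        bc.prescribe_displacement(MixedBCSet.dofs(top, 2), disp.uz[inner][lab_in])
    # else: the default prescription at those DOFs is already Fz = 0

    fact = MbvpFactorization(dom.stiffness, bc.is_dirichlet, tol=tol)
    sol = fact.solve(bc.value)

    fx = np.zeros(mask.grid.shape)
    fy = np.zeros(mask.grid.shape)
    fz = np.zeros(mask.grid.shape)
    labeled = mask.labels > 0
    top_all = dom.mesh.top_surface_nodes()
    fx[labeled] = sol.reactions[3 * top_all[labeled]]
    fy[labeled] = sol.reactions[3 * top_all[labeled] + 1]
    if zmode == "dirichlet":
        fz[labeled] = sol.reactions[3 * top_all[labeled] + 2]
    tf = TractionField.from_nodal_forces(mask.grid, fx, fy, fz, mask.labels)
    return tf, _report_for(tf, iterations=1, residual=sol.residual)


def recover_whole_field_iterative(
    disp: SurfaceDisplacementField,
    mask: ClusterMask,
    substrate: SubstrateModel,
    *,
    rms_tol: float = 0.05,
    max_iter: int = 50,
    smooth_sigma: float | None = None,
    min_margin: float | None = None,
    z_aspect: float = DEFAULT_Z_ASPECT,
    spacing_z: float | None = None,
    tol: float = 1e-8,
) -> tuple[TractionField, RecoveryReport]:
    """Iterative whole-field displacement recovery.

    Requires valid (ux, uy) on the whole surface grid, inside and outside
    the clusters.  Each cycle performs two solves on cached factorizations:
    a traction solve with the current full-field displacements prescribed
    (Fz = 0 on the surface), then — after zeroing extracellular forces — a
    forward solve that refreshes the extracellular displacements while the
    measured intracellular ones are restored.  Converged when the RMS of
    surface nodal-force magnitudes changes by less than ``rms_tol``
    (relative) between consecutive cycles.
    """
    disp = _align(disp, mask)
    if smooth_sigma:
        disp = _smooth(disp, smooth_sigma)
    if not disp.valid.all():
        j, i = np.argwhere(~disp.valid)[0]
        raise InputError(
            "the whole-field method needs valid displacement data on the entire "
            f"surface grid; node (i={i}, j={j}) is invalid"
        )
    check_mask_margin(mask, substrate, min_margin)
    dom = domain_for_grid(mask.grid, substrate, z_aspect=z_aspect, spacing_z=spacing_z)
    K = dom.stiffness
    ndof = dom.mesh.n_dofs
    fixed = dom.mesh.fixed_boundary_nodes()
    top = dom.top_interior_nodes()
    inner = (slice(1, -1), slice(1, -1))
    lab_in = mask.labels[inner] > 0

    # phase A: full-field (ux, uy) Dirichlet on the surface, Fz = 0
    bcA = MixedBCSet(ndof)
    for ax in range(3):
        bcA.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
    bcA.prescribe_displacement(MixedBCSet.dofs(top, 0), disp.ux[inner].ravel())
    bcA.prescribe_displacement(MixedBCSet.dofs(top, 1), disp.uy[inner].ravel())
    factA = MbvpFactorization(K, bcA.is_dirichlet, tol=tol)

    # phase B: forces prescribed on the whole surface (forward problem)
    bcB = MixedBCSet(ndof)
    for ax in range(3):
        bcB.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
    factB = MbvpFactorization(K, bcB.is_dirichlet, tol=tol)

    ux = disp.ux[inner].ravel().copy()
    uy = disp.uy[inner].ravel().copy()
    history: list[float] = []
    rms_prev = None
    lab_flat = lab_in.ravel()
    fx_in = fy_in = None
    resid = 0.0
    for cycle in range(1, max_iter + 1):
        valsA = bcA.value.copy()
        valsA[MixedBCSet.dofs(top, 0)] = ux
        valsA[MixedBCSet.dofs(top, 1)] = uy
        solA = factA.solve(valsA)
        resid = solA.residual
        fx_all = solA.reactions[3 * top.ravel()]
        fy_all = solA.reactions[3 * top.ravel() + 1]
        # traction-free condition: extracellular forces are discarded
        fx_in = np.where(lab_flat, fx_all, 0.0)
        fy_in = np.where(lab_flat, fy_all, 0.0)

        rms = float(np.sqrt(np.mean(fx_in**2 + fy_in**2)))
        if rms_prev is not None:
            change = abs(rms - rms_prev) / max(rms_prev, 1e-30)
            history.append(change)
            if change < rms_tol or (rms_prev == 0.0 and rms == 0.0):
                break
        elif rms == 0.0:
            history.append(0.0)
            break
        rms_prev = rms

        valsB = bcB.value.copy()
        valsB[MixedBCSet.dofs(top, 0)] = fx_in
        valsB[MixedBCSet.dofs(top, 1)] = fy_in
        solB = factB.solve(valsB)
        unew_x = solB.displacements[3 * top.ravel()]
        unew_y = solB.displacements[3 * top.ravel() + 1]
        # measured displacements are restored under the clusters; the
        # computed extracellular field replaces the measured one outside
        ux = np.where(lab_flat, disp.ux[inner].ravel(), unew_x)
        uy = np.where(lab_flat, disp.uy[inner].ravel(), unew_y)
    else:
        raise NonConvergenceError(
            f"whole-field iteration did not reach {rms_tol:.0%} RMS change "
            f"within {max_iter} cycles",
            history=history,
        )

    fx = np.zeros(mask.grid.shape)
    fy = np.zeros(mask.grid.shape)
    fx[inner] = fx_in.reshape(top.shape)
    fy[inner] = fy_in.reshape(top.shape)
    tf = TractionField.from_nodal_forces(mask.grid, fx, fy, None, mask.labels)
    return tf, _report_for(tf, iterations=cycle, history=history, residual=resid)


def error_ratio(tf: TractionField, cluster_id: int) -> float:
    """Self-equilibration error ε of one cluster.

    ε = ‖Σᵢ(F_xi, F_yi)‖ / Σᵢ‖(F_xi, F_yi)‖ over the cluster's nodes; 0 for
    an exactly balanced traction field, 1 for a single unbalanced force.
    Returns NaN when the cluster carries no in-plane force at all.
    """
    sel = tf.labels == cluster_id
    if not sel.any():
        raise InputError(f"cluster id {cluster_id} not present in the field")
    mags = np.hypot(tf.fx[sel], tf.fy[sel])
    denom = mags.sum()
    if denom == 0.0:
        return float("nan")
    net = np.hypot(tf.fx[sel].sum(), tf.fy[sel].sum())
    return float(net / denom)


def rms_difference(
    tf_a: TractionField, tf_b: TractionField, region: ClusterMask | None = None
) -> tuple[float, float]:
    """Node-by-node RMS of the vector difference between two traction fields.

    Returns (ΔRMS traction in kPa, ΔRMS nodal force in nN), evaluated over
    the labeled nodes of ``region`` (whole grid when omitted).
    """
    if not tf_a.grid.same_geometry(tf_b.grid):
        raise AlignmentError("traction fields live on different grids")
    if region is not None:
        if not region.grid.same_geometry(tf_a.grid):
            raise AlignmentError("region mask does not match the traction grid")
        sel = region.labels > 0
    else:
        sel = np.ones(tf_a.grid.shape, dtype=bool)
    dt2 = (
        (tf_a.tx - tf_b.tx) ** 2
        + (tf_a.ty - tf_b.ty) ** 2
        + (tf_a.tz - tf_b.tz) ** 2
    )
    df2 = (
        (tf_a.fx - tf_b.fx) ** 2
        + (tf_a.fy - tf_b.fy) ** 2
        + (tf_a.fz - tf_b.fz) ** 2
    )
    return (
        float(np.sqrt(np.mean(dt2[sel]))),
        float(np.sqrt(np.mean(df2[sel]))),
    )


def cluster_net_force(tf: TractionField, cluster_id: int) -> np.ndarray:
    """Vector sum (fx, fy, fz) in nN of the nodal forces of one cluster."""
    sel = tf.labels == cluster_id
    if not sel.any():
        raise InputError(f"cluster id {cluster_id} not present in the field")
    return np.array([tf.fx[sel].sum(), tf.fy[sel].sum(), tf.fz[sel].sum()])
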