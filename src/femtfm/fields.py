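"""Gridded surface fields: displacements, cluster masks, tractions, forces.

All fields live on a regular lattice of top-surface nodes.  Arrays are
stored with shape (ny, nx); element [j, i] belongs to the node at physical
position ``origin + (i·spacing_x, j·spacing_y)``, so the row index increases
with y ("lower-left" origin).  File readers are responsible for flipping
image rows into this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import AlignmentError, GeometryError, InputError

__all__ = [
    "SurfaceGrid",
    "SurfaceDisplacementField",
    "ClusterMask",
    "TractionField",
    "PrescribedForceField",
    "tributary_areas",
]


@dataclass(frozen=True)
class SurfaceGrid:
    """Geometry of a regular surface lattice (nx × ny nodes, spacings in µm)."""

    nx: int
    ny: int
    spacing_x: float
    spacing_y: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise GeometryError("grid needs at least 2 nodes per axis")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise GeometryError("grid spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def size_x(self) -> float:
        return (self.nx - 1) * self.spacing_x

    @property
    def size_y(self) -> float:
        return (self.ny - 1) * self.spacing_y

    def x(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.nx) * self.spacing_x

    def y(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.ny) * self.spacing_y

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x(), self.y(), indexing="xy")

    def same_geometry(self, other: "SurfaceGrid", tol: float = 1e-6) -> bool:
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and abs(self.spacing_x - other.spacing_x) <= tol * self.spacing_x
            and abs(self.spacing_y - other.spacing_y) <= tol * self.spacing_y
            and abs(self.origin[0] - other.origin[0]) <= tol * max(1.0, self.spacing_x)
            and abs(self.origin[1] - other.origin[1]) <= tol * max(1.0, self.spacing_y)
        )


def tributary_areas(grid: SurfaceGrid) -> np.ndarray:
    """Tributary surface area per node in µm².

    Interior nodes own a full cell sx·sy, edges half, corners a quarter, so
    the areas tile the surface exactly: Σ areas = size_x · size_y.
    """
    wx = np.full(grid.nx, grid.spacing_x)
    wx[[0, -1]] = grid.spacing_x / 2
    wy = np.full(grid.ny, grid.spacing_y)
    wy[[0, -1]] = grid.spacing_y / 2
    return np.outer(wy, wx)


def _check_shape(grid: SurfaceGrid, arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise AlignmentError(f"{name} has shape {arr.shape}, expected {grid.shape}")
    return arr


@dataclass
class SurfaceDisplacementField:
    """Measured or simulated top-surface displacements (µm) on a grid.

    ``uz`` is optional: plain 2D bead imaging yields only the in-plane
    components.  ``valid`` flags nodes with trustworthy data; non-finite
    entries are only permitted where ``valid`` is False.
    """

    grid: SurfaceGrid
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.ux = _check_shape(self.grid, self.ux, "ux")
        self.uy = _check_shape(self.grid, self.uy, "uy")
        if self.uz is not None:
            self.uz = _check_shape(self.grid, self.uz, "uz")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise AlignmentError("validity mask shape mismatch")
        comps = [self.ux, self.uy] + ([self.uz] if self.uz is not None else [])
        for c in comps:
            if not np.all(np.isfinite(c[self.valid])):
                raise InputError("non-finite displacement at a node marked valid")

    @property
    def has_z(self) -> bool:
        return self.uz is not None

    def in_plane(self) -> "SurfaceDisplacementField":
        """A view of the same field with the out-of-plane component dropped."""
        return SurfaceDisplacementField(
            self.grid, self.ux, self.uy, None, self.valid.copy()
        )

    def scaled(self, c: float) -> "SurfaceDisplacementField":
        return SurfaceDisplacementField(
            self.grid,
            c * self.ux,
            c * self.uy,
            None if self.uz is None else c * self.uz,
            self.valid.copy(),
        )

    def resample_to(self, grid: SurfaceGrid) -> "SurfaceDisplacementField":
        """Bilinear resampling onto another grid.

        Target nodes outside the source extent get zero displacement and are
        marked invalid.
        """
        if self.grid.same_geometry(grid):
            return SurfaceDisplacementField(
                grid,
                self.ux.copy(),
                self.uy.copy(),
                None if self.uz is None else self.uz.copy(),
                self.valid.copy(),
            )
        xs, ys = self.grid.x(), self.grid.y()
        xt, yt = grid.meshgrid()
        pts = np.stack([yt.ravel(), xt.ravel()], axis=1)
        eps_x = 1e-9 * self.grid.spacing_x
        eps_y = 1e-9 * self.grid.spacing_y
        inside = (
            (pts[:, 1] >= xs[0] - eps_x)
            & (pts[:, 1] <= xs[-1] + eps_x)
            & (pts[:, 0] >= ys[0] - eps_y)
            & (pts[:, 0] <= ys[-1] + eps_y)
        )
        pts[:, 1] = np.clip(pts[:, 1], xs[0], xs[-1])
        pts[:, 0] = np.clip(pts[:, 0], ys[0], ys[-1])

        def interp(values):
            f = RegularGridInterpolator((ys, xs), values, method="linear")
            out = f(pts)
            out[~inside] = 0.0
            return out.reshape(grid.shape)

        ux = interp(self.ux)
        uy = interp(self.uy)
        uz = interp(self.uz) if self.uz is not None else None
        vsrc = interp(self.valid.astype(float)) >= 1.0 - 1e-9
        valid = vsrc & inside.reshape(grid.shape)
        return SurfaceDisplacementField(grid, ux, uy, uz, valid)


@dataclass
class ClusterMask:
    """Integer cluster labels per surface node: 0 = extracellular, 1..M = cluster."""

    grid: SurfaceGrid
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise AlignmentError(
                f"label array shape {labels.shape} does not match grid {self.grid.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise InputError("cluster labels must be integers")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise InputError("cluster labels must be >= 0")
        self.labels = labels.astype(np.int32)

    def cluster_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def node_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.cluster_ids()}

    def contains(self, other: "ClusterMask") -> bool:
        """True if every labeled node of ``other`` is labeled here."""
        if not self.grid.same_geometry(other.grid):
            raise AlignmentError("masks live on different grids")
        return bool(np.all(self.labels[other.labels > 0] > 0))


@dataclass
class TractionField:
    """Recovered traction (kPa) and nodal force (nN) per top-surface node.

    ``force = traction × tributary area`` holds per node and per component.
    """

    grid: SurfaceGrid
    tx: np.ndarray
    ty: np.ndarray
    tz: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    area: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_nodal_forces(
        cls, grid: SurfaceGrid, fx, fy, fz=None, labels=None
    ) -> "TractionField":
        fx = _check_shape(grid, fx, "fx")
        fy = _check_shape(grid, fy, "fy")
        fz = np.zeros(grid.shape) if fz is None else _check_shape(grid, fz, "fz")
        if labels is None:
            labels = np.zeros(grid.shape, dtype=np.int32)
        area = tributary_areas(grid)
        return cls(
            grid=grid,
            tx=fx / area,
            ty=fy / area,
            tz=fz / area,
            fx=fx,
            fy=fy,
            fz=fz,
            area=area,
            labels=np.asarray(labels, dtype=np.int32),
        )

    def force_magnitude(self) -> np.ndarray:
        return np.sqrt(self.fx**2 + self.fy**2 + self.fz**2)

    def traction_magnitude(self) -> np.ndarray:
        return np.sqrt(self.tx**2 + self.ty**2 + self.tz**2)

    def scaled(self, c: float) -> "TractionField":
        return replace(
            self,
            tx=c * self.tx,
            ty=c * self.ty,
            tz=c * self.tz,
            fx=c * self.fx,
            fy=c * self.fy,
            fz=c * self.fz,
            area=self.area.copy(),
            labels=self.labels.copy(),
        )


@dataclass
class PrescribedForceField:
    """Known surface nodal forces (nN) used to drive the forward model.

    Generators of self-equilibrated fields balance each cluster's net force
    at construction (fp residue below 1e-9 nN is tolerated and verified).
    ``substrate`` carries the slab the fixture was built for, so the forward
    model and the recovery run on exactly the same geometry.
    """

    grid: SurfaceGrid
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)
    substrate: object | None = None
    self_equilibrated: bool = True

    def __post_init__(self):
        self.fx = _check_shape(self.grid, self.fx, "fx")
        self.fy = _check_shape(self.grid, self.fy, "fy")
        self.fz = _check_shape(self.grid, self.fz, "fz")
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise AlignmentError("label array shape mismatch")
        if self.self_equilibrated:
            scale = max(np.abs(self.fx).max(), np.abs(self.fy).max(), 1e-30)
            for c in sorted(int(v) for v in np.unique(self.labels) if v != 0):
                sel = self.labels == c
                net = np.hypot(self.fx[sel].sum(), self.fy[sel].sum())
                if net > 1e-9 + 1e-12 * scale:
                    raise InputError(
                        f"cluster {c} net in-plane force {net:.3e} nN is not zero"
                    )

    def cluster_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def mask(self) -> ClusterMask:
        return ClusterMask(self.grid, self.labels.copy())

    def scaled(self, c: float) -> "PrescribedForceField":
        return PrescribedForceField(
            self.grid,
            c * self.fx,
            c * self.fy,
            c * self.fz,
            self.labels.copy(),
            dict(self.metadata, scaled_by=c),
            self.substrate,
            self.self_equilibrated,
        )
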