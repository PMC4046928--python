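"""Readers and writers for the toolkit's plain-text formats.

Displacement and traction tables are CSV with a fixed header and row-major,
x-fastest node ordering; floats are written with 9 significant digits so
reruns produce byte-identical files.  Metadata (tool version, config hash,
seed, input digests) rides in leading ``#`` comment lines.

Mask images (TIFF/PNG, integer labels) are flipped on load so that image
row 0 — conventionally the top of the frame — maps to the largest y of the
physical grid: the package's arrays put y increasing with row index,
origin at the lower-left.  Misaligned y conventions are the single most
common TFM bug, hence the explicit flip here and nowhere else.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import AlignmentError, FormatError, InputError
from .fields import ClusterMask, SurfaceDisplacementField, SurfaceGrid, TractionField

__all__ = [
    "read_displacement_csv",
    "write_displacement_csv",
    "read_traction_csv",
    "write_traction_csv",
    "read_mask_image",
    "write_mask_image",
    "write_vtk",
    "file_digest",
]

_FLOAT = "%.9g"


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _metadata_lines(metadata: dict | None) -> list[str]:
    lines = [f"# femtfm {__version__}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _grid_from_columns(x: np.ndarray, y: np.ndarray) -> SurfaceGrid:
    xs = np.unique(x)
    ys = np.unique(y)
    for name, vals in (("x", xs), ("y", ys)):
        if vals.size < 2:
            raise FormatError(f"need at least two distinct {name} coordinates")
        d = np.diff(vals)
        if np.any(np.abs(d - d[0]) > 1e-6 * abs(d[0])):
            raise FormatError(f"non-uniform {name} grid spacing")
    return SurfaceGrid(
        nx=xs.size,
        ny=ys.size,
        spacing_x=float(np.diff(xs)[0]),
        spacing_y=float(np.diff(ys)[0]),
        origin=(float(xs[0]), float(ys[0])),
    )


def read_displacement_csv(path) -> SurfaceDisplacementField:
    """Read `x_um,y_um,ux_um,uy_um[,uz_um]`; absent grid nodes become invalid."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty displacement file") from exc
    want = ["x_um", "y_um", "ux_um", "uy_um"]
    if list(df.columns[:4]) != want or df.columns.size > 5:
        raise FormatError(
            f"{path}: header must be x_um,y_um,ux_um,uy_um[,uz_um], got {list(df.columns)}"
        )
    has_z = df.columns.size == 5
    if has_z and df.columns[4] != "uz_um":
        raise FormatError(f"{path}: fifth column must be uz_um, got {df.columns[4]}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    grid = _grid_from_columns(df["x_um"].to_numpy(), df["y_um"].to_numpy())
    i = np.rint((df["x_um"].to_numpy() - grid.origin[0]) / grid.spacing_x).astype(int)
    j = np.rint((df["y_um"].to_numpy() - grid.origin[1]) / grid.spacing_y).astype(int)
    flat = j * grid.nx + i
    if np.unique(flat).size != flat.size:
        raise FormatError(f"{path}: duplicate grid nodes")
    shape = grid.shape

    def scatter(col):
        a = np.full(shape, np.nan)
        a[j, i] = df[col].to_numpy()
        return a

    ux = scatter("ux_um")
    uy = scatter("uy_um")
    uz = scatter("uz_um") if has_z else None
    valid = np.isfinite(ux) & np.isfinite(uy)
    if has_z:
        valid &= np.isfinite(uz)
    ux[~valid] = 0.0
    uy[~valid] = 0.0
    if has_z:
        uz[~valid] = 0.0
    return SurfaceDisplacementField(grid, ux, uy, uz, valid)


def write_displacement_csv(
    disp: SurfaceDisplacementField, path, metadata: dict | None = None
) -> None:
    """Write valid nodes only, row-major with x fastest."""
    g = disp.grid
    X, Y = g.meshgrid()
    sel = disp.valid
    cols = {"x_um": X[sel], "y_um": Y[sel], "ux_um": disp.ux[sel], "uy_um": disp.uy[sel]}
    if disp.has_z:
        cols["uz_um"] = disp.uz[sel]
    order = np.lexsort((cols["x_um"], cols["y_um"]))
    lines = _metadata_lines(metadata)
    lines.append(",".join(cols))
    for r in order:
        lines.append(",".join(_FLOAT % cols[c][r] for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


_TRACTION_COLS = [
    "x_um", "y_um", "label",
    "tx_kPa", "ty_kPa", "tz_kPa",
    "fx_nN", "fy_nN", "fz_nN",
    "area_um2",
]


def write_traction_csv(tf: TractionField, path, metadata: dict | None = None) -> None:
    g = tf.grid
    X, Y = g.meshgrid()
    lines = _metadata_lines(metadata)
    lines.append(",".join(_TRACTION_COLS))
    for j in range(g.ny):
        for i in range(g.nx):
            vals = [
                _FLOAT % X[j, i],
                _FLOAT % Y[j, i],
                str(int(tf.labels[j, i])),
                _FLOAT % tf.tx[j, i],
                _FLOAT % tf.ty[j, i],
                _FLOAT % tf.tz[j, i],
                _FLOAT % tf.fx[j, i],
                _FLOAT % tf.fy[j, i],
                _FLOAT % tf.fz[j, i],
                _FLOAT % tf.area[j, i],
            ]
            lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_traction_csv(path) -> TractionField:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty traction file") from exc
    if list(df.columns) != _TRACTION_COLS:
        raise FormatError(f"{path}: unexpected traction header {list(df.columns)}")
    grid = _grid_from_columns(df["x_um"].to_numpy(), df["y_um"].to_numpy())
    if len(df) != grid.nx * grid.ny:
        raise FormatError(f"{path}: expected {grid.nx * grid.ny} rows, got {len(df)}")
    i = np.rint((df["x_um"].to_numpy() - grid.origin[0]) / grid.spacing_x).astype(int)
    j = np.rint((df["y_um"].to_numpy() - grid.origin[1]) / grid.spacing_y).astype(int)

    def scatter(col, dtype=float):
        a = np.zeros(grid.shape, dtype=dtype)
        a[j, i] = df[col].to_numpy()
        return a

    return TractionField(
        grid=grid,
        tx=scatter("tx_kPa"),
        ty=scatter("ty_kPa"),
        tz=scatter("tz_kPa"),
        fx=scatter("fx_nN"),
        fy=scatter("fy_nN"),
        fz=scatter("fz_nN"),
        area=scatter("area_um2"),
        labels=scatter("label", dtype=np.int32),
    )


def read_mask_image(path, grid: SurfaceGrid) -> ClusterMask:
    """Load an integer-label image and rasterize it onto the node grid.

    The image is assumed to cover the same physical extent as the grid.
    Each node takes the label of the pixel containing its position (ties
    on pixel borders resolve toward the lower-index pixel).  Image rows
    are flipped so row 0 (top of frame) maps to the largest y.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if img.ndim == 3:
        if img.shape[2] > 1 and not np.all(img[..., 1:] == img[..., :1]):
            raise InputError(f"{path}: mask image must be single-channel")
        img = img[..., 0]
    if not np.issubdtype(img.dtype, np.integer):
        if not np.allclose(img, np.round(img)):
            raise InputError(f"{path}: mask image must hold integer labels")
        img = np.round(img).astype(np.int32)
    img = np.flipud(img)
    h, w = img.shape
    if (h, w) == grid.shape:
        labels = img.astype(np.int32)
    else:
        # rescale: pixel (r, c) spans [c·px, (c+1)·px) × [r·py, (r+1)·py)
        px = grid.size_x / w
        py = grid.size_y / h
        xi = np.clip(((grid.x() - grid.origin[0]) / px).astype(int), 0, w - 1)
        yj = np.clip(((grid.y() - grid.origin[1]) / py).astype(int), 0, h - 1)
        labels = img[np.ix_(yj, xi)].astype(np.int32)
        if labels.shape != grid.shape:
            raise AlignmentError(f"{path}: cannot align mask image to grid")
    return ClusterMask(grid, labels)


def write_mask_image(mask: ClusterMask, path) -> None:
    img = np.flipud(mask.labels.astype(np.uint16))
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def write_vtk(
    disp: SurfaceDisplacementField | None,
    tf: TractionField | None,
    path,
    metadata: dict | None = None,
) -> None:
    """Legacy-VTK structured grid of the surface with vector point data."""
    ref = disp if disp is not None else tf
    if ref is None:
        raise InputError("nothing to write")
    g = ref.grid
    if tf is not None and disp is not None and not tf.grid.same_geometry(disp.grid):
        raise AlignmentError("displacement and traction grids differ")
    X, Y = g.meshgrid()
    lines = [
        "# vtk DataFile Version 3.0",
        f"femtfm {__version__} " + " ".join(f"{k}={v}" for k, v in (metadata or {}).items()),
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {g.nx} {g.ny} 1",
        f"POINTS {g.nx * g.ny} double",
    ]
    for j in range(g.ny):
        for i in range(g.nx):
            lines.append(f"{X[j, i]:.9g} {Y[j, i]:.9g} 0")
    lines.append(f"POINT_DATA {g.nx * g.ny}")
    if disp is not None:
        lines.append("VECTORS displacement_um double")
        uz = disp.uz if disp.has_z else np.zeros(g.shape)
        for j in range(g.ny):
            for i in range(g.nx):
                lines.append(
                    f"{disp.ux[j, i]:.9g} {disp.uy[j, i]:.9g} {uz[j, i]:.9g}"
                )
    if tf is not None:
        lines.append("VECTORS traction_kPa double")
        for j in range(g.ny):
            for i in range(g.nx):
                lines.append(f"{tf.tx[j, i]:.9g} {tf.ty[j, i]:.9g} {tf.tz[j, i]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")
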