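"""Digital image correlation on bead image pairs.

The displacement field that feeds traction recovery comes from comparing
two fluorescent-bead images: one with cells attached (deformed) and one
after the cells are enzymatically released (the stress-free reference).
This module provides a minimal, self-contained DIC: windowed normalized
cross-correlation with quadratic sub-pixel peak refinement, plus a
synthetic bead-image generator and warper so the whole chain can be tested
without any microscope data.

Image convention: arrays are indexed [row, col] with the row index
increasing along +y and the column index along +x, i.e. pixel (0, 0) is
the lower-left corner of the physical field of view.  File I/O flips
conventional top-origin images into this layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .errors import InputError
from .fields import SurfaceDisplacementField, SurfaceGrid

__all__ = [
    "BeadImagePair",
    "generate_bead_image",
    "warp_image",
    "dic_displacement_field",
]

PEAK_QUALITY_THRESHOLD = 0.5


@dataclass
class BeadImagePair:
    """Reference (cell-free) and deformed (with cells) grayscale images."""

    reference: np.ndarray
    deformed: np.ndarray
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.deformed = np.asarray(self.deformed, dtype=float)
        if self.reference.shape != self.deformed.shape:
            raise InputError("reference and deformed images differ in shape")
        if self.reference.ndim != 2:
            raise InputError("images must be 2D grayscale arrays")
        if self.pixel_size <= 0:
            raise InputError("pixel size must be > 0")


def generate_bead_image(
    shape: tuple[int, int] = (256, 256),
    n_beads: int = 400,
    bead_sigma: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic fluorescent-bead image: Gaussian spots at random positions.

    Bead centers are uniform over the frame (continuous coordinates);
    intensities are summed and normalized to peak 1.  Deterministic given
    the seed.
    """
    if n_beads < 0:
        raise InputError("n_beads must be >= 0")
    h, w = shape
    img = np.zeros((h, w))
    if n_beads == 0:
        return img
    rng = np.random.default_rng(seed)
    ys = rng.uniform(0, h - 1, n_beads)
    xs = rng.uniform(0, w - 1, n_beads)
    half = max(3, int(np.ceil(4 * bead_sigma)))
    for yc, xc in zip(ys, xs):
        y0, y1 = int(max(0, np.floor(yc) - half)), int(min(h, np.floor(yc) + half + 1))
        x0, x1 = int(max(0, np.floor(xc) - half)), int(min(w, np.floor(xc) + half + 1))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += np.exp(
            -((yy - yc) ** 2 + (xx - xc) ** 2) / (2 * bead_sigma**2)
        )
    m = img.max()
    return img / m if m > 0 else img


def warp_image(
    img: np.ndarray, displacement_fn, pixel_size: float = 1.0
) -> np.ndarray:
    """Deform an image under a continuous displacement field (backward map).

    ``displacement_fn(x_um, y_um) -> (ux_um, uy_um)`` is the material
    displacement; the deformed image at x is sampled from the reference at
    x − u(x) by bilinear interpolation (valid for fields smooth at the
    pixel scale).  Samples falling outside the frame read as 0.
    """
    from scipy.ndimage import map_coordinates

    img = np.asarray(img, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ux, uy = displacement_fn(xx * pixel_size, yy * pixel_size)
    src_x = xx - np.asarray(ux) / pixel_size
    src_y = yy - np.asarray(uy) / pixel_size
    return map_coordinates(img, [src_y, src_x], order=1, mode="constant", cval=0.0)


def _subpixel_offset(c: np.ndarray, j: int, i: int) -> tuple[float, float]:
    """Quadratic 1D fits through the 3×3 neighborhood of a correlation peak."""

    def fit(m, z, p):
        denom = m - 2 * z + p
        if denom >= 0:  # not a maximum; skip refinement
            return 0.0
        return float(np.clip(0.5 * (m - p) / denom, -0.5, 0.5))

    dy = fit(c[j - 1, i], c[j, i], c[j + 1, i]) if 0 < j < c.shape[0] - 1 else 0.0
    dx = fit(c[j, i - 1], c[j, i], c[j, i + 1]) if 0 < i < c.shape[1] - 1 else 0.0
    return dy, dx


def dic_displacement_field(
    pair: BeadImagePair,
    window: int = 32,
    step: int = 16,
    search: int = 10,
) -> SurfaceDisplacementField:
    """Windowed normalized cross-correlation between the image pair.

    A ``window``×``window`` template around each output grid point of the
    reference image is correlated against the deformed image over a
    ±``search`` px range; the correlation peak, refined to sub-pixel
    precision by a quadratic fit to its 3×3 neighborhood, gives the local
    displacement.  Windows whose normalized correlation peak falls below
    0.5, or whose peak sits on the search border, are flagged invalid.
    Output is in µm on a grid with spacing ``step`` × pixel size.
    """
    h, w = pair.reference.shape
    if window > min(h, w):
        raise InputError(f"window {window} px exceeds image size {pair.reference.shape}")
    if window < 4 or step < 1 or search < 1:
        raise InputError("window >= 4, step >= 1 and search >= 1 required")
    half = window // 2
    lo = half + search
    cx = np.arange(lo, w - lo - (window - 2 * half), step)
    cy = np.arange(lo, h - lo - (window - 2 * half), step)
    if cx.size == 0 or cy.size == 0:
        raise InputError("image too small for the requested window/search")
    ux = np.zeros((cy.size, cx.size))
    uy = np.zeros((cy.size, cx.size))
    valid = np.zeros((cy.size, cx.size), dtype=bool)
    for jj, yc in enumerate(cy):
        for ii, xc in enumerate(cx):
            tmpl = pair.reference[yc - half : yc + half, xc - half : xc + half]
            if tmpl.std() == 0:
                continue
            region = pair.deformed[
                yc - half - search : yc + half + search,
                xc - half - search : xc + half + search,
            ]
            corr = match_template(region, tmpl)  # (2*search+1)² map
            j, i = np.unravel_index(np.argmax(corr), corr.shape)
            peak = corr[j, i]
            on_border = j in (0, corr.shape[0] - 1) or i in (0, corr.shape[1] - 1)
            if peak < PEAK_QUALITY_THRESHOLD or on_border:
                continue
            dy, dx = _subpixel_offset(corr, j, i)
            ux[jj, ii] = (i + dx - search) * pair.pixel_size
            uy[jj, ii] = (j + dy - search) * pair.pixel_size
            valid[jj, ii] = True
    grid = SurfaceGrid(
        nx=cx.size,
        ny=cy.size,
        spacing_x=step * pair.pixel_size,
        spacing_y=step * pair.pixel_size,
        origin=(cx[0] * pair.pixel_size, cy[0] * pair.pixel_size),
    )
    return SurfaceDisplacementField(grid, ux, uy, None, valid)
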