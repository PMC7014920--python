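"""Grey Level Index (GLI) images.

The GLI of a square measuring field is the areal fraction of pixels darker
than a gray-value threshold — a robust estimate of the local volume density
of cell bodies in a cell-stained section.  Fields are adjacent,
non-overlapping squares; the conventional field edge is 17 μm at a scan
resolution of 1.02 μm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GLIImage",
    "estimate_gray_threshold",
    "compute_gli_image",
    "gli_at",
]

DEFAULT_FIELD_SIZE_UM = 17.0
DEFAULT_RESOLUTION_UM_PER_PX = 1.02


@dataclass(frozen=True)
class GLIImage:
    """A grid of cell-body area fractions, one value per measuring field.

    Attributes
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Fraction of sub-threshold ("dark") pixels per field, each in [0, 1].
    field_size_um : float
        Nominal field edge length in micrometres.
    field_px : int
        Effective field edge in pixels (nominal size rounded to whole pixels).
    resolution_um_per_px : float
        Resolution of the source image.
    threshold : float
        Gray-value threshold used; pixels strictly below it count as cellular.
    origin : tuple of int
        Pixel coordinate (row, col) of the top-left corner of field (0, 0).
    """

    values: np.ndarray
    field_size_um: float
    field_px: int
    resolution_um_per_px: float
    threshold: float
    origin: tuple = (0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("GLI grid must be 2-D")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("GLI values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def effective_field_size_um(self) -> float:
        return self.field_px * self.resolution_um_per_px

    @property
    def shape(self):
        return self.values.shape


def estimate_gray_threshold(gray_image: np.ndarray) -> float:
    """Estimate the gray threshold separating dark cellular elements from
    bright background by analysing the image's gray-value histogram.

    The threshold maximizes the between-class variance of the two resulting
    pixel classes (Otsu's criterion) over all 256 8-bit levels.  Pixels
    strictly below the returned value belong to the dark class.

    Parameters
    ----------
    gray_image : ndarray
        Grayscale image; values are binned into 256 levels over their range
        if not already 8-bit integers.

    Returns
    -------
    float
        Threshold t; the dark class is ``pixel < t``.

    Raises
    ------
    ValueError
        If the image is constant (no threshold can separate two classes).
    """
    img = np.asarray(gray_image)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise ValueError("constant image: gray threshold is undecidable")

    if np.issubdtype(img.dtype, np.integer) and lo >= 0 and hi <= 255:
        levels = np.arange(257, dtype=float)  # candidate cuts 0..256
        hist = np.bincount(img.ravel().astype(np.intp), minlength=256).astype(float)
        centers = np.arange(256, dtype=float)
    else:
        hist, edges = np.histogram(img.ravel(), bins=256, range=(lo, hi))
        hist = hist.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        levels = edges

    # between-class variance for every cut position k: classes [<k] vs [>=k]
    w0 = np.cumsum(hist)
    total = w0[-1]
    m_cum = np.cumsum(hist * centers)
    m_tot = m_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m_cum / w0
        mu1 = (m_tot - m_cum) / (total - w0)
        sigma_b = w0 * (total - w0) * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    k = int(np.argmax(sigma_b))  # class 0 = bins 0..k, class 1 = bins k+1..
    return float(levels[k + 1])


def compute_gli_image(
    gray_image: np.ndarray,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    field_size_um: float = DEFAULT_FIELD_SIZE_UM,
    threshold: float | None = None,
    *,
    origin: tuple = (0, 0),
) -> GLIImage:
    """Compute a GLI image from a grayscale section image.

    Each value is the fraction of pixels strictly darker than ``threshold``
    within an adjacent, non-overlapping square field.  Trailing partial
    fields (right and bottom edges) are dropped, not padded.

    Parameters
    ----------
    gray_image : ndarray
        2-D grayscale section image.
    resolution_um_per_px : float
        In-plane scan resolution.
    field_size_um : float
        Nominal measuring-field edge; converted to whole pixels by rounding.
    threshold : float, optional
        Gray threshold; estimated from the histogram when omitted.
    origin : (row, col)
        Pixel offset of the field grid within the image.

    Returns
    -------
    GLIImage
    """
    img = np.asarray(gray_image)
    if img.ndim != 2:
        raise ValueError("gray_image must be 2-D")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    field_px = int(round(field_size_um / resolution_um_per_px))
    if field_px < 2:
        raise ValueError(f"field of {field_px} px is too small (need >= 2 px)")
    r0, c0 = origin
    sub = img[r0:, c0:]
    nr, nc = sub.shape[0] // field_px, sub.shape[1] // field_px
    if nr < 1 or nc < 1:
        raise ValueError("measuring field is larger than the image")
    if threshold is None:
        threshold = estimate_gray_threshold(img)

    dark = (sub[: nr * field_px, : nc * field_px] < threshold).astype(np.float64)
    vals = dark.reshape(nr, field_px, nc, field_px).mean(axis=(1, 3))
    return GLIImage(
        values=vals,
        field_size_um=float(field_size_um),
        field_px=field_px,
        resolution_um_per_px=float(resolution_um_per_px),
        threshold=float(threshold),
        origin=(int(r0), int(c0)),
        meta={"effective_field_size_um": field_px * resolution_um_per_px},
    )


def gli_at(gli_image: GLIImage, image_xy) -> np.ndarray | float:
    """Bilinearly interpolated GLI at image pixel coordinates.

    Coordinates are (x, y) = (col, row) in source-image pixels.  Field
    (i, j) is anchored at its centre, pixel ``origin + (i + 0.5) * field_px``.
    Points outside the span of field centres raise.

    Parameters
    ----------
    gli_image : GLIImage
    image_xy : array-like, shape (2,) or (n, 2)

    Returns
    -------
    float or ndarray
        Interpolated fraction(s), each within the [min, max] of the four
        surrounding fields.
    """
    pts = np.atleast_2d(np.asarray(image_xy, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("image_xy must be (x, y) pairs")
    f = gli_image.field_px
    r0, c0 = gli_image.origin
    # fractional field-grid coordinates (row, col)
    gr = (pts[:, 1] - r0) / f - 0.5
    gc = (pts[:, 0] - c0) / f - 0.5
    nr, nc = gli_image.values.shape
    eps = 1e-9
    if (gr < -eps).any() or (gr > nr - 1 + eps).any() or (gc < -eps).any() or (gc > nc - 1 + eps).any():
        raise ValueError("point outside the GLI grid extent")
    gr = np.clip(gr, 0, nr - 1)
    gc = np.clip(gc, 0, nc - 1)
    i0 = np.clip(np.floor(gr).astype(int), 0, nr - 2) if nr > 1 else np.zeros(len(gr), int)
    j0 = np.clip(np.floor(gc).astype(int), 0, nc - 2) if nc > 1 else np.zeros(len(gc), int)
    i1 = np.minimum(i0 + 1, nr - 1)
    j1 = np.minimum(j0 + 1, nc - 1)
    fr = gr - i0
    fc = gc - j0
    v = gli_image.values
    out = (
        v[i0, j0] * (1 - fr) * (1 - fc)
        + v[i1, j0] * fr * (1 - fc)
        + v[i0, j1] * (1 - fr) * fc
        + v[i1, j1] * fr * fc
    )
    return float(out[0]) if np.asarray(image_xy).ndim == 1 else out
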