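"""Actin orientation estimation and cell-type-specific organization metrics.

The organizational state of a cell population is summarized by the
orientational order parameter (OOP) and the director of the distribution of
per-pixel actin orientation axes.  Orientations are axial quantities
(defined modulo 180 degrees): a fiber pointing "left" and "right" is the
same fiber.  All statistics here therefore go through the mean dyadic
(structure) tensor

    T = < r r^T >,   r = (cos(theta), sin(theta)),

whose eigen-decomposition is insensitive to the sign of each r.  For unit
axial vectors T is symmetric with trace 1; its largest eigenvalue lies in
[1/2, 1].  The reported OOP is by default normalized to [0, 1],

    oop = 2 * lambda_max(T) - 1,

so that 0 means isotropy and 1 perfect alignment; the raw eigenvalue is
available through ``oop_convention="raw_eigenvalue"``.  The director is the
eigenvector of lambda_max, reported as an angle in [0, 180).

Coordinate convention: arrays are indexed (row, col); an angle theta in
degrees denotes the axis (cos theta, sin theta) in (x=col, y=row)
components, i.e. theta is measured from the +x (column) axis toward the
+y (row) axis.  The convention is used consistently by every module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class OrientationField:
    """Per-pixel axial orientation with a validity mask.

    ``angles_deg`` holds the orientation axis in [0, 180) degrees;
    ``valid`` marks pixels where the estimate is trustworthy (sufficient
    gradient coherence, or exact by construction for synthetic truth).
    Values at invalid pixels are meaningless and must not be consumed.
    """

    angles_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.angles_deg.shape != self.valid.shape:
            raise ValueError("angles and validity mask must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.angles_deg.shape

    def unit_vectors(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return (n, 2) unit axial vectors at valid (optionally masked) pixels."""
        sel = self.valid if mask is None else (self.valid & mask)
        ang = np.deg2rad(self.angles_deg[sel])
        return np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass
class OrganizationMetrics:
    """OOP, director and bookkeeping for one cell type in one field of view."""

    cell_type: str
    oop: float
    director_deg: float | None
    angle_to_stretch_deg: float | None
    n_vectors: int
    actin_fraction: float

    def as_record(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "oop": self.oop,
            "director_deg": self.director_deg,
            "angle_to_stretch_deg": self.angle_to_stretch_deg,
            "n_vectors": self.n_vectors,
            "actin_fraction": self.actin_fraction,
        }


def estimate_orientation_field(
    actin_image: np.ndarray,
    sigma_smooth: float = 2.0,
    block_size: int = 8,
    coherence_cutoff: float = 0.2,
) -> OrientationField:
    """Least-mean-square ridge orientation estimation on an actin image.

    The image is Gaussian-smoothed, standardized to zero mean / unit
    standard deviation, and Sobel gradients are accumulated over sliding
    ``block_size`` windows.  The dominant gradient direction of a window is
    ``0.5 * atan2(2*sum(GxGy), sum(Gx^2 - Gy^2))``; the ridge (fiber) axis is
    perpendicular to it, hence the 90-degree offset.  A pixel is valid when
    the window's gradient coherence

        ||(sum(Gx^2-Gy^2), sum(2GxGy))|| / sum(Gx^2+Gy^2)

    reaches ``coherence_cutoff``; a constant image yields an empty mask.
    """
    img = np.asarray(actin_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    smoothed = ndimage.gaussian_filter(img, sigma=sigma_smooth, mode="reflect")
    sd = smoothed.std()
    if sd == 0:
        return OrientationField(np.zeros_like(img), np.zeros(img.shape, dtype=bool))
    z = (smoothed - smoothed.mean()) / sd

    # x = columns (axis 1), y = rows (axis 0)
    gx = ndimage.sobel(z, axis=1, mode="reflect")
    gy = ndimage.sobel(z, axis=0, mode="reflect")

    jxx = ndimage.uniform_filter(gx * gx, size=block_size, mode="reflect")
    jyy = ndimage.uniform_filter(gy * gy, size=block_size, mode="reflect")
    jxy = ndimage.uniform_filter(gx * gy, size=block_size, mode="reflect")

    diff = jxx - jyy
    cross = 2.0 * jxy
    energy = jxx + jyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, np.hypot(diff, cross) / np.maximum(energy, 1e-300), 0.0)

    angles = (90.0 + 0.5 * np.degrees(np.arctan2(cross, diff))) % 180.0
    valid = (energy > 1e-12) & (coherence >= coherence_cutoff)

    # reflection padding mirrors orientations across the border, so estimates
    # within the filter support of an edge are systematically wrong: mask them
    margin = int(np.ceil(block_size / 2 + 3.0 * sigma_smooth + 1))
    if 2 * margin < min(img.shape):
        border = np.zeros(img.shape, dtype=bool)
        border[margin:-margin, margin:-margin] = True
        valid &= border
    return OrientationField(angles, valid)


def select_class_vectors(
    field: OrientationField,
    semantic_map: np.ndarray,
    actin_foreground: np.ndarray,
    cell_type: str,
    *,
    codes: dict | None = None,
) -> np.ndarray:
    """Split valid actin orientation vectors by cell type.

    Cardiomyocyte vectors live at StriatedMyocyte pixels of the alpha-actinin
    class map.  Fibroblast vectors live at actin-foreground pixels whose
    alpha-actinin class is Background (a fibroblast has actin fibrils but no
    alpha-actinin).  Pixels classified Other carry actin that belongs to
    neither set and are excluded from both.
    """
    from . import imaging_io  # local import to avoid a cycle

    if codes is None:
        codes = {
            "striated_myocyte": imaging_io.CLASS_STRIATED,
            "background": imaging_io.CLASS_BACKGROUND,
            "other": imaging_io.CLASS_OTHER,
        }
    semantic_map = np.asarray(semantic_map)
    actin_foreground = np.asarray(actin_foreground, dtype=bool)
    if semantic_map.shape != field.shape or actin_foreground.shape != field.shape:
        raise ValueError("semantic map, actin mask and field shapes must match")

    if cell_type in ("cardiomyocyte", "striated_myocyte"):
        mask = semantic_map == codes["striated_myocyte"]
    elif cell_type == "fibroblast":
        mask = semantic_map == codes["background"]
    elif cell_type == "other":
        mask = semantic_map == codes["other"]
    else:
        raise ValueError(f"unknown cell type tag: {cell_type!r}")
    # an actin orientation vector exists only where actin is present: the
    # actin-foreground requirement applies to every cell type alike
    return field.unit_vectors(mask & actin_foreground)


def structure_tensor_metrics(
    vectors: np.ndarray,
    oop_convention: str = "normalized",
    unit_tol: float = 1e-6,
) -> tuple[float, float]:
    """OOP and director of a multiset of unit axial vectors.

    Returns ``(oop, director_deg)`` from the eigen-decomposition of the mean
    dyadic tensor.  ``oop_convention`` selects the normalized order parameter
    in [0, 1] (default) or the raw maximum eigenvalue in [0.5, 1].
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] == 0:
        raise ValueError("expected a nonempty (n, 2) array of vectors")
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(np.abs(norms - 1.0) > unit_tol):
        raise ValueError("orientation vectors must be unit length")

    txx = float(np.mean(v[:, 0] * v[:, 0]))
    txy = float(np.mean(v[:, 0] * v[:, 1]))
    tyy = float(np.mean(v[:, 1] * v[:, 1]))
    tensor = np.array([[txx, txy], [txy, tyy]])
    evals, evecs = np.linalg.eigh(tensor)
    lam = float(evals[-1])
    director = evecs[:, -1]
    director_deg = float(np.degrees(np.arctan2(director[1], director[0])) % 180.0)

    if oop_convention == "normalized":
        oop = 2.0 * lam - 1.0
    elif oop_convention == "raw_eigenvalue":
        oop = lam
    else:
        raise ValueError(f"unknown oop_convention: {oop_convention!r}")
    return float(np.clip(oop, 0.0, 1.0)), director_deg


def angle_between_axes(p: np.ndarray, q: np.ndarray) -> float:
    """Acute angle in degrees between two axes (unit vectors mod 180).

    Folding through the absolute dot product keeps the result in [0, 90]:
    antiparallel vectors describe the same axis and give 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("zero vector has no direction")
    cosang = abs(float(np.dot(p, q))) / (np_ * nq)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def axis_vector(angle_deg: float) -> np.ndarray:
    """Unit axial vector for an angle in degrees ((x, y) components)."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def actin_fraction(cm_count: int, fb_count: int, other_count: int = 0) -> float:
    """Cardiomyocyte actin fraction: CM vectors over all actin vectors."""
    total = cm_count + fb_count + other_count
    if min(cm_count, fb_count, other_count) < 0:
        raise ValueError("counts must be nonnegative")
    if total == 0:
        raise ValueError("no actin vectors: fraction undefined")
    return cm_count / total


def actin_foreground_mask(
    actin_image: np.ndarray, sigma: float = 2.0, method: str = "otsu"
) -> np.ndarray:
    """Binary mask of actin-positive pixels (simple threshold mode).

    Smooths the actin channel and applies an Otsu threshold.  This is the
    lightweight alternative to running the texture classifier on the actin
    channel; adequate whenever actin foreground is well separated from
    background in intensity.
    """
    from skimage.filters import threshold_otsu

    img = ndimage.gaussian_filter(np.asarray(actin_image, dtype=float), sigma)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    if method != "otsu":
        raise ValueError(f"unknown method: {method!r}")
    return img > threshold_otsu(img)


def organization_metrics(
    field: OrientationField,
    semantic_map: np.ndarray,
    actin_foreground: np.ndarray,
    stretch_angle_deg: float = 0.0,
    oop_convention: str = "normalized",
) -> list[OrganizationMetrics]:
    """Per-cell-type organization summary for one field of view.

    Produces one row per cell type (cardiomyocyte, fibroblast) with OOP,
    director, angle to the stretch axis, vector count and actin fraction.
    Cell types with no vectors get oop 0 and undefined angles.
    """
    counts: dict[str, np.ndarray] = {}
    for tag in ("cardiomyocyte", "fibroblast", "other"):
        counts[tag] = select_class_vectors(field, semantic_map, actin_foreground, tag)
    total = sum(len(v) for v in counts.values())
    stretch = axis_vector(stretch_angle_deg)

    rows = []
    for tag in ("cardiomyocyte", "fibroblast"):
        vecs = counts[tag]
        n = len(vecs)
        frac = (n / total) if total > 0 else 0.0
        if n == 0:
            rows.append(OrganizationMetrics(tag, 0.0, None, None, 0, frac))
            continue
        oop, director_deg = structure_tensor_metrics(vecs, oop_convention)
        theta = angle_between_axes(stretch, axis_vector(director_deg)) if oop > 0 else None
        rows.append(
            OrganizationMetrics(tag, oop, director_deg if oop > 0 else None, theta, n, frac)
        )
    return rows
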