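"""Cross-sectional geometry of a single diaphyseal bone section.

Given a grayscale micro-CT cross-section the routines here segment bone from
background with a minimum (histogram-valley) threshold, trace the subperiosteal
(outer) contour, approximate the endocortical (inner) border with a fitted
ellipse, and quantify the standard cross-sectional geometry of long-bone
biomechanics: total subperiosteal area (TA), medullary area (MA), cortical
area (CA = TA - MA), cortical porosity area (CPA), second moments of area
about the anatomical mediolateral / anteroposterior axes (Ix, Iy) and about
the principal axes (Imax, Imin), and the two size-independent indices
MA/TA (medullary index) and CPA/CA (porosity index).

Axis convention: x = mediolateral (image columns), y = anteroposterior
(image rows, increasing toward anterior).  All physical quantities are in mm
units; pixels are square with side ``pixel_size_mm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when a section cannot be segmented (no bimodal histogram,
    empty foreground, or an ellipse fit escaping the cortex)."""


@dataclass(frozen=True)
class CrossSectionImage:
    """A 2D grayscale slice with isotropic pixel size.

    ``intensities[row, col]`` with x = mediolateral = columns and
    y = anteroposterior = rows.
    """

    intensities: np.ndarray
    pixel_size_mm: float
    provenance: str = ""

    def __post_init__(self):
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if np.asarray(self.intensities).ndim != 2:
            raise ValueError("section intensities must be a 2D array")


@dataclass(frozen=True)
class PeriostealContour:
    """Closed outer (subperiosteal) outline of the section.

    ``polygon`` is an ordered (N, 2) array of (x, y) vertices in mm traced at
    the pixel-edge (0.5) level; ``mask`` is the hole-filled foreground of the
    largest component, which is the region actually used for area and moment
    computation.
    """

    polygon: np.ndarray
    enclosed_area_mm2: float
    mask: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class EndocortealEllipse:
    """Ellipse approximating the endocortical (medullary-cavity) border."""

    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    orientation_deg: float

    @property
    def area_mm2(self) -> float:
        a, b = self.semi_axes_mm
        return math.pi * a * b

    @property
    def is_degenerate(self) -> bool:
        return min(self.semi_axes_mm) <= 0


@dataclass(frozen=True)
class SectionGeometry:
    """Complete per-section measurement record (mm / mm^2 / mm^4)."""

    TA_mm2: float
    CA_mm2: float
    MA_mm2: float
    CPA_mm2: float
    Ix_mm4: float
    Iy_mm4: float
    Ixy_mm4: float
    Imax_mm4: float
    Imin_mm4: float
    theta_deg: float
    imax_imin_ratio: float
    ix_iy_ratio: float
    medullary_index: float
    porosity_index: float
    threshold: float = float("nan")
    provenance: str = ""

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "TA_mm2", "CA_mm2", "MA_mm2", "CPA_mm2",
                "Ix_mm4", "Iy_mm4", "Ixy_mm4", "Imax_mm4", "Imin_mm4",
                "theta_deg", "imax_imin_ratio", "ix_iy_ratio",
                "medullary_index", "porosity_index",
            )
        }


# ---------------------------------------------------------------------------
# thresholding


def minimum_threshold(histogram: np.ndarray, max_iter: int = 10_000) -> int:
    """Histogram-valley threshold for a bimodal intensity histogram.

    The histogram is repeatedly smoothed with a 3-bin running mean until
    exactly two local maxima remain; the threshold is the minimum-count bin
    strictly between the two modes, ties broken toward the lower intensity.
    Foreground (bone) is conventionally ``intensity > threshold``.

    Raises
    ------
    SegmentationError
        If no bimodal structure emerges within ``max_iter`` smoothing passes.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 3:
        raise ValueError("histogram must be a 1D array of at least 3 bins")
    if h.sum() <= 0:
        raise SegmentationError("empty histogram")

    kernel = np.full(3, 1.0 / 3.0)
    for _ in range(max_iter):
        peaks = _plateau_local_maxima(h)
        if len(peaks) == 2:
            lo, hi = peaks
            if hi - lo < 2:
                raise SegmentationError("no bimodal structure: adjacent modes")
            interior = h[lo + 1 : hi]
            return lo + 1 + int(np.argmin(interior))
        smoothed = np.convolve(np.r_[h[0], h, h[-1]], kernel, mode="valid")
        if len(peaks) < 2 and np.allclose(smoothed, h):
            break  # fixed point, will never become bimodal
        h = smoothed
    raise SegmentationError("no bimodal structure in histogram")


def _plateau_local_maxima(h: np.ndarray) -> list[int]:
    """Indices (first bin of each plateau) of strict local maxima."""
    # collapse runs of equal values so plateaus count once
    keep = np.r_[True, np.diff(h) != 0]
    vals = h[keep]
    idx = np.flatnonzero(keep)
    peaks = []
    for i in range(len(vals)):
        left = vals[i - 1] if i > 0 else -np.inf
        right = vals[i + 1] if i < len(vals) - 1 else -np.inf
        if vals[i] > left and vals[i] > right:
            peaks.append(int(idx[i]))
    return peaks


def histogram_256(intensities: np.ndarray) -> np.ndarray:
    """256-bin histogram over the 8-bit range (values clipped into [0, 255])."""
    return np.bincount(
        np.clip(np.asarray(intensities).ravel(), 0, 255).astype(np.int64),
        minlength=256,
    )[:256]


def _resolve_threshold(section: CrossSectionImage, threshold) -> float:
    if threshold == "auto" or threshold is None:
        return float(minimum_threshold(histogram_256(section.intensities)))
    return float(threshold)


# ---------------------------------------------------------------------------
# contours and regions


def periosteal_contour(section: CrossSectionImage, threshold="auto") -> PeriostealContour:
    """Outer subperiosteal outline: largest 8-connected bone component with
    interior holes (medullary cavity, pores) filled."""
    thr = _resolve_threshold(section, threshold)
    fg = np.asarray(section.intensities) > thr
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=_EIGHT)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)

    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len)  # (row, col) vertices
    p = section.pixel_size_mm
    polygon = np.column_stack([boundary[:, 1] * p, boundary[:, 0] * p])  # (x, y) mm
    x, y = polygon[:, 0], polygon[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return PeriostealContour(polygon=polygon, enclosed_area_mm2=float(area), mask=mask)


def _medullary_region(section, contour, thr) -> np.ndarray | None:
    """Connected non-bone region inside the contour holding the centroid
    (fallback: the largest enclosed non-bone region), or None if there is no
    enclosed cavity."""
    non_bone = contour.mask & ~(np.asarray(section.intensities) > thr)
    if not non_bone.any():
        return None
    labels, n = ndimage.label(non_bone)  # 4-connected: keeps cavity and pores apart
    rc = ndimage.center_of_mass(contour.mask)
    centroid = (int(round(rc[0])), int(round(rc[1])))
    lab = labels[centroid] if contour.mask[centroid] else 0
    if lab == 0:
        sizes = ndimage.sum_labels(non_bone, labels, index=np.arange(1, n + 1))
        lab = int(np.argmax(sizes)) + 1
    region = labels == lab
    return region


def endocortical_ellipse(
    section: CrossSectionImage,
    contour: PeriostealContour,
    threshold="auto",
) -> EndocortealEllipse:
    """Fit an ellipse to the medullary-cavity boundary.

    The cavity is the connected non-bone region inside the periosteal contour
    that contains the section centroid.  Its traced boundary is fitted by
    direct least-squares conic fitting; if the conic fit fails the cavity's
    second-moment-equivalent ellipse is used instead.  A section with no
    enclosed cavity yields a degenerate zero-area ellipse (MA = 0) with a
    logged warning, not an error.
    """
    thr = _resolve_threshold(section, threshold)
    region = _medullary_region(section, contour, thr)
    p = section.pixel_size_mm
    if region is None or region.sum() < 4:
        logger.warning("no enclosed medullary cavity; degenerate ellipse (MA = 0)")
        rc = ndimage.center_of_mass(contour.mask)
        return EndocortealEllipse((rc[1] * p, rc[0] * p), (0.0, 0.0), 0.0)

    boundary = max(measure.find_contours(region.astype(float), 0.5), key=len)
    xy = np.column_stack([boundary[:, 1], boundary[:, 0]]) * p  # (x, y) mm
    model = measure.EllipseModel.from_estimate(xy)
    if model and np.all(np.isfinite(model.axis_lengths)) and min(model.axis_lengths) > 0:
        (xc, yc), (a, b), phi = model.center, model.axis_lengths, model.theta
        if a < b:  # normalise: first semi-axis is the major one
            a, b = b, a
            phi += math.pi / 2
        phi_deg = math.degrees(phi) % 180.0
        return EndocortealEllipse((float(xc), float(yc)), (float(a), float(b)), phi_deg)

    # fallback: moment-equivalent ellipse of the cavity region
    logger.warning("conic ellipse fit degenerate; using moment-equivalent ellipse")
    rows, cols = np.nonzero(region)
    x, y = cols * p, rows * p
    cov = np.cov(np.vstack([x, y])) + (p**2 / 12.0) * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    a, b = 2.0 * np.sqrt(evals[::-1])
    ang = math.degrees(math.atan2(evecs[1, 1], evecs[0, 1])) % 180.0
    return EndocortealEllipse((float(x.mean()), float(y.mean())), (float(a), float(b)), ang)


def _ellipse_mask(ellipse: EndocortealEllipse, shape, pixel_size: float) -> np.ndarray:
    if ellipse.is_degenerate:
        return np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols * pixel_size - ellipse.center_mm[0]
    y = rows * pixel_size - ellipse.center_mm[1]
    t = math.radians(ellipse.orientation_deg)
    u = x * math.cos(t) + y * math.sin(t)
    v = -x * math.sin(t) + y * math.cos(t)
    a, b = ellipse.semi_axes_mm
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# areas, moments, porosity


def compute_areas(
    contour: PeriostealContour,
    ellipse: EndocortealEllipse,
    pixel_size_mm: float,
) -> tuple[float, float, float]:
    """(TA, MA, CA) in mm^2.

    TA is the pixel-count area of the hole-filled outer region (consistent
    with how pores and the cavity are handled downstream); MA is the analytic
    area pi*a*b of the fitted endocortical ellipse; CA = TA - MA.
    """
    ta = float(contour.mask.sum()) * pixel_size_mm**2
    ma = float(ellipse.area_mm2)
    if ma >= ta:
        raise SegmentationError(
            f"endocortical ellipse area {ma:.3f} mm^2 >= total area {ta:.3f} mm^2: "
            "ellipse fit escaped the cortex"
        )
    return ta, ma, ta - ma


def second_moments(region: np.ndarray, pixel_size_mm: float):
    """Centroidal second moments of area of a solid pixel region.

    Pixel summation with the per-pixel self-moment p^4/12 included, so a
    square region is exact at any resolution:

        Ix = sum[(y - ybar)^2 + p^2/12] * p^2   (bending rigidity in the AP plane)
        Iy = sum[(x - xbar)^2 + p^2/12] * p^2
        Ixy = sum[(x - xbar)(y - ybar)] * p^2

    Principal values Imax/Imin = (Ix+Iy)/2 +/- sqrt(((Ix-Iy)/2)^2 + Ixy^2);
    theta = 0.5 * atan2(2 Ixy, Iy - Ix), mapped to (-90, 90], is the angle of
    the Imax axis from x (mediolateral).

    Returns (Ix, Iy, Ixy, Imax, Imin, theta_deg), all mm^4 / degrees.
    """
    rows, cols = np.nonzero(region)
    n = rows.size
    if n < 2:
        raise SegmentationError("region too small for second moments")
    p = pixel_size_mm
    x = cols * p
    y = rows * p
    xb, yb = x.mean(), y.mean()
    a_px = p * p
    self_term = n * p**4 / 12.0
    ix = float(np.sum((y - yb) ** 2) * a_px + self_term)
    iy = float(np.sum((x - xb) ** 2) * a_px + self_term)
    ixy = float(np.sum((x - xb) * (y - yb)) * a_px)
    mean = 0.5 * (ix + iy)
    half = math.hypot(0.5 * (ix - iy), ixy)
    imax, imin = mean + half, mean - half
    theta = 0.5 * math.degrees(math.atan2(2.0 * ixy, iy - ix))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return ix, iy, ixy, imax, imin, theta


def cortical_porosity(
    section: CrossSectionImage,
    contour: PeriostealContour,
    ellipse: EndocortealEllipse,
    threshold="auto",
) -> float:
    """Cortical porosity area: sub-threshold pixel area between the periosteal
    contour and the endocortical ellipse, in mm^2."""
    thr = _resolve_threshold(section, threshold)
    cortex = contour.mask & ~_ellipse_mask(ellipse, contour.mask.shape, section.pixel_size_mm)
    pores = cortex & ~(np.asarray(section.intensities) > thr)
    cavity = _medullary_region(section, contour, thr)
    if cavity is not None:
        # air connected to the medullary cavity is cavity, not intracortical
        # porosity; without this the sliver between the fitted ellipse and
        # the true endocortical border would be miscounted as pore area
        pores &= ~cavity
    return float(pores.sum()) * section.pixel_size_mm**2


# ---------------------------------------------------------------------------
# orchestration


def section_geometry(
    section: CrossSectionImage,
    threshold="auto",
    endocortical: str = "ellipse",
    porosity_denominator: str = "outline",
) -> SectionGeometry:
    """Full per-section workflow: threshold -> periosteal contour ->
    endocortical ellipse -> areas -> second moments -> porosity.

    Parameters
    ----------
    threshold : "auto" or numeric
        "auto" applies the minimum (histogram-valley) threshold.
    endocortical : {"ellipse", "trace"}
        "ellipse" (default) approximates the endocortical border by the fitted
        ellipse; "trace" uses the traced cavity region itself (sensitivity
        option).
    porosity_denominator : {"outline", "bone"}
        Denominator of the porosity index: outline-derived cortical area
        CA = TA - MA (default, pores included), or bone-only area CA - CPA.
    """
    thr = _resolve_threshold(section, threshold)
    contour = periosteal_contour(section, thr)
    ellipse = endocortical_ellipse(section, contour, thr)
    p = section.pixel_size_mm

    region_cavity = _medullary_region(section, contour, thr)
    cavity_mask = (
        np.zeros_like(contour.mask) if region_cavity is None else region_cavity
    )
    if endocortical == "trace":
        ma = float(cavity_mask.sum()) * p * p
        ta = float(contour.mask.sum()) * p * p
        ca = ta - ma
        cortex_solid = contour.mask & ~cavity_mask
    elif endocortical == "ellipse":
        ta, ma, ca = compute_areas(contour, ellipse, p)
        cortex_solid = contour.mask & ~_ellipse_mask(ellipse, contour.mask.shape, p)
    else:
        raise ValueError(f"unknown endocortical mode {endocortical!r}")

    ix, iy, ixy, imax, imin, theta = second_moments(cortex_solid, p)
    # intracortical pores only: air connected to the medullary cavity is
    # cavity, not porosity (the fitted ellipse rarely matches it to the pixel)
    pores = cortex_solid & ~(np.asarray(section.intensities) > thr) & ~cavity_mask
    cpa = float(pores.sum()) * p * p
    denom = ca if porosity_denominator == "outline" else ca - cpa
    porosity = cpa / denom if denom > 0 else 0.0

    return SectionGeometry(
        TA_mm2=ta, CA_mm2=ca, MA_mm2=ma, CPA_mm2=cpa,
        Ix_mm4=ix, Iy_mm4=iy, Ixy_mm4=ixy, Imax_mm4=imax, Imin_mm4=imin,
        theta_deg=theta,
        imax_imin_ratio=imax / imin if imin > 0 else float("inf"),
        ix_iy_ratio=ix / iy if iy > 0 else float("inf"),
        medullary_index=ma / ta if ta > 0 else 0.0,
        porosity_index=porosity,
        threshold=thr,
        provenance=section.provenance,
    )
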