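"""Synthetic bone phantoms with exact closed-form ground truth.

Real input to the analysis is a micro-CT scan of an epiphysis-free immature
femur; those scans are not publicly deposited, so every pipeline stage here
is exercised against generated phantoms instead.  A phantom diaphysis is a
tapered elliptical annulus: outer (periosteal) semi-axes a(z), b(z) and
inner (endocortical) semi-axes a_i(z), b_i(z) are piecewise-linear in z,
with circular intracortical pores planted wholly inside the cortex.  Because
the geometry is analytic, every measurand has an exact closed form:

    TA = pi a b            MA = pi a_i b_i           CA = TA - MA
    Ix = pi (a b^3 - a_i b_i^3) / 4                  (about the ML axis)
    Iy = pi (b a^3 - b_i a_i^3) / 4                  (about the AP axis)

Truth second moments ignore the planted pores (at <= 10% porosity they
perturb the measured moments by well under the tolerances used downstream),
so the closed forms stay exact.

Cohort generation maps an age to a phantom through three ontogenetic
trajectories modelled on growing wild chimpanzees: a rise-then-fall medullary
index (cavity expansion in infancy, then cortical infilling), an
exponentially declining porosity index (high intracortical porosity in the
first 1-2 years, stabilizing around 3-4 years), and an Ix/Iy shape ratio
declining from circular toward mediolaterally reinforced.  With a similar
inner ellipse a_i = rho*a, b_i = rho*b the targets decouple exactly:
medullary index = rho^2 and Ix/Iy = (b/a)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._transform import euler_matrix_xyz, rotate_volume, to_index_space
from .growth import GrowthCurve
from .section import CrossSectionImage
from .volume import VoxelVolume


class PorePackingError(RuntimeError):
    """Planted pore area cannot reach the requested fraction (pores too
    large for the cortical thickness, or packing saturated)."""


# ---------------------------------------------------------------------------
# specs and truth


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one epiphysis-free bone volume.

    Semi-axis profiles are piecewise-linear over ``profile_z`` (fractions of
    length from the distal end, which sits at low z).  The default profile
    flares at both metaphyses with a mid-shaft waist — so the 35/50/65%
    sections differ measurably — and flares more distally, which is what the
    automatic distal-end detection keys on.
    """

    length_mm: float = 60.0
    profile_z: tuple = (0.0, 0.15, 0.5, 0.85, 1.0)
    outer_a_mm: tuple = (10.8, 8.8, 8.0, 8.6, 10.0)
    outer_b_mm: tuple = (8.1, 6.6, 6.0, 6.5, 7.5)
    inner_a_mm: tuple = (5.4, 4.4, 4.0, 4.3, 5.0)
    inner_b_mm: tuple = (4.1, 3.3, 3.0, 3.2, 3.8)
    pore_fraction: float = 0.0
    pore_radius_mm: float = 0.3
    tilt_euler_deg: tuple = (0.0, 0.0, 0.0)
    voxel_size_mm: float = 0.15
    background_intensity: int = 20
    bone_intensity: int = 200
    noise_sd: float = 5.0
    side: str = "R"
    seed: int = 0

    def __post_init__(self):
        n = len(self.profile_z)
        for name in ("outer_a_mm", "outer_b_mm", "inner_a_mm", "inner_b_mm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must match profile_z in length")
        oa, ob = np.asarray(self.outer_a_mm), np.asarray(self.outer_b_mm)
        ia, ib = np.asarray(self.inner_a_mm), np.asarray(self.inner_b_mm)
        if not (np.all(ia < oa) and np.all(ib < ob)):
            raise ValueError("inner semi-axes must be strictly inside outer semi-axes")
        if np.any(ia < 0) or np.any(ib < 0):
            raise ValueError("inner semi-axes must be non-negative")
        if not 0.0 <= self.pore_fraction <= 0.4:
            raise ValueError("pore_fraction must lie in [0, 0.4]")
        if self.voxel_size_mm <= 0 or self.length_mm <= 0:
            raise ValueError("length_mm and voxel_size_mm must be positive")
        if self.bone_intensity <= self.background_intensity:
            raise ValueError("bone_intensity must exceed background_intensity")

    def semi_axes_at(self, frac: float) -> tuple[float, float, float, float]:
        """(a, b, a_i, b_i) in mm at a fraction of length from the distal end."""
        z = np.asarray(self.profile_z)
        return tuple(
            float(np.interp(frac, z, np.asarray(p)))
            for p in (self.outer_a_mm, self.outer_b_mm, self.inner_a_mm, self.inner_b_mm)
        )


@dataclass(frozen=True)
class SectionTruth:
    """Closed-form ground truth for one cross-section."""

    TA_mm2: float
    CA_mm2: float
    MA_mm2: float
    CPA_mm2: float
    Ix_mm4: float
    Iy_mm4: float
    Imax_mm4: float
    Imin_mm4: float
    medullary_index: float
    porosity_index: float

    @classmethod
    def from_annulus(cls, a, b, a_i, b_i, cpa_mm2=0.0) -> "SectionTruth":
        ta = math.pi * a * b
        ma = math.pi * a_i * b_i
        ca = ta - ma
        ix = math.pi * (a * b**3 - a_i * b_i**3) / 4.0
        iy = math.pi * (b * a**3 - b_i * a_i**3) / 4.0
        return cls(
            TA_mm2=ta, CA_mm2=ca, MA_mm2=ma, CPA_mm2=cpa_mm2,
            Ix_mm4=ix, Iy_mm4=iy,
            Imax_mm4=max(ix, iy), Imin_mm4=min(ix, iy),
            medullary_index=ma / ta,
            porosity_index=cpa_mm2 / ca if ca > 0 else 0.0,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def scaled_phantom_spec(length_mm: float, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` whose cross-sectional profile scales with
    length (keeping femur-like proportions), so short test phantoms remain
    elongated enough to have an unambiguous long axis."""
    s = length_mm / PhantomSpec.length_mm
    fields = {}
    for name in ("outer_a_mm", "outer_b_mm", "inner_a_mm", "inner_b_mm"):
        default = PhantomSpec.__dataclass_fields__[name].default
        fields[name] = tuple(s * v for v in default)
    fields.update(overrides)
    return PhantomSpec(length_mm=length_mm, **fields)


def section_truth_at(spec: PhantomSpec, fraction: float, cpa_mm2: float = 0.0) -> SectionTruth:
    """Closed-form truth of a spec at a fractional location (pore area given
    separately, since it is realized stochastically)."""
    a, b, a_i, b_i = spec.semi_axes_at(fraction)
    return SectionTruth.from_annulus(a, b, a_i, b_i, cpa_mm2)


# ---------------------------------------------------------------------------
# rasterization and pore planting

_PORE_TOL = 0.005  # planted fraction must be within 0.5 percentage points


def _grid_coords(shape, pixel):
    """Pixel-centre physical coordinates (x, y) with the origin at the image centre."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x = (cols - (shape[1] - 1) / 2.0) * pixel
    y = (rows - (shape[0] - 1) / 2.0) * pixel
    return x, y


def _annulus_masks(shape, pixel, a, b, a_i, b_i, rotation_deg=0.0):
    x, y = _grid_coords(shape, pixel)
    if rotation_deg:
        t = math.radians(rotation_deg)
        x, y = x * math.cos(t) + y * math.sin(t), -x * math.sin(t) + y * math.cos(t)
    outer = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    if a_i > 0 and b_i > 0:
        inner = (x / a_i) ** 2 + (y / b_i) ** 2 <= 1.0
    else:
        inner = np.zeros(shape, dtype=bool)
    return outer, inner


def _plant_pores(
    cortex_mask: np.ndarray,
    cortex_area_mm2: float,
    pore_fraction: float,
    pore_radius_mm: float,
    pixel: float,
    rng: np.random.Generator,
    max_attempts: int = 20_000,
):
    """Place non-overlapping circular pores wholly inside the cortex mask
    until the planted (continuous) pore area is within 0.5 percentage points
    of ``pore_fraction`` of the cortex area.

    Returns a list of (row, col, radius_mm) pore records.  Raises
    :class:`PorePackingError` when the target is unreachable.
    """
    if pore_fraction <= 0:
        return []
    target = pore_fraction * cortex_area_mm2
    gap = pixel  # clearance to the cortex boundary and between pores
    dt = ndimage.distance_transform_edt(cortex_mask) * pixel
    r_max = 1.25 * pore_radius_mm
    cand = np.column_stack(np.nonzero(dt > pore_radius_mm * 0.75 + gap))
    if cand.size == 0:
        raise PorePackingError(
            f"pore radius {pore_radius_mm} mm too large for the cortical thickness"
        )
    min_r = max(1.5 * pixel, 0.2 * pore_radius_mm)
    pores: list[tuple[int, int, float]] = []
    planted = 0.0
    attempts = 0
    while planted < target - 0.9 * _PORE_TOL * cortex_area_mm2:
        if attempts >= max_attempts:
            raise PorePackingError(
                f"pore packing saturated at fraction {planted / cortex_area_mm2:.4f} "
                f"(target {pore_fraction:.4f})"
            )
        attempts += 1
        r = float(rng.uniform(0.75, 1.25) * pore_radius_mm)
        # shrink the last pore so the total lands inside the tolerance band
        if planted + math.pi * r * r > target + _PORE_TOL * cortex_area_mm2:
            r = math.sqrt(max(target - planted, 0.0) / math.pi)
            if r < min_r:
                break  # close enough: the residual deficit is < pi*min_r^2
        row, col = cand[rng.integers(len(cand))]
        if dt[row, col] <= r + gap:
            continue
        if any(
            (row - r0) ** 2 + (col - c0) ** 2 <= ((r + rr + gap) / pixel) ** 2
            for r0, c0, rr in pores
        ):
            continue
        pores.append((int(row), int(col), r))
        planted += math.pi * r * r
    if abs(planted / cortex_area_mm2 - pore_fraction) > _PORE_TOL:
        raise PorePackingError(
            f"planted fraction {planted / cortex_area_mm2:.4f} misses target "
            f"{pore_fraction:.4f} by more than {_PORE_TOL}"
        )
    return pores


def _stamp_pores(image: np.ndarray, pores, pixel: float, value) -> None:
    for row, col, r in pores:
        rr = int(math.ceil(r / pixel)) + 1
        r0, r1 = max(row - rr, 0), min(row + rr + 1, image.shape[0])
        c0, c1 = max(col - rr, 0), min(col + rr + 1, image.shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - row) ** 2 + (xx - col) ** 2 <= (r / pixel) ** 2
        image[r0:r1, c0:c1][disk] = value


def _pore_area(pores) -> float:
    return sum(math.pi * r * r for _, _, r in pores)


def _crop_to_foreground(vol: np.ndarray, fg: np.ndarray, margin: int, fill) -> np.ndarray:
    if not fg.any():
        return vol
    sl = []
    for ax in range(3):
        proj = np.flatnonzero(fg.any(axis=tuple(i for i in range(3) if i != ax)))
        sl.append(slice(max(proj[0] - margin, 0), min(proj[-1] + margin + 1, vol.shape[ax])))
    return np.ascontiguousarray(vol[tuple(sl)])


# ---------------------------------------------------------------------------
# 2D section phantom


def make_section_phantom(
    outer_semi_axes: tuple[float, float],
    inner_semi_axes: tuple[float, float] = (0.0, 0.0),
    pore_fraction: float = 0.0,
    pixel_size_mm: float = 0.05,
    seed: int = 0,
    pore_radius_mm: float = 0.3,
    rotation_deg: float = 0.0,
    bone_intensity: int = 200,
    background_intensity: int = 20,
    noise_sd: float = 0.0,
) -> tuple[CrossSectionImage, SectionTruth]:
    """Rasterize a single elliptical-annulus cross-section with planted pores.

    The 2D analogue of :func:`make_phantom_volume`, for fast unit-level
    checks; ``rotation_deg`` rotates the annulus (and its pore field) in
    plane.  Returns the grayscale section and its closed-form truth.
    """
    a, b = outer_semi_axes
    a_i, b_i = inner_semi_axes
    if a <= 0 or b <= 0 or a_i < 0 or b_i < 0 or a_i >= a or b_i >= b:
        raise ValueError("need 0 <= inner semi-axes < outer semi-axes")
    rng = np.random.default_rng(seed)
    pad = 4 * pixel_size_mm + 0.05 * max(a, b)
    half = max(a, b) + pad
    n = 2 * int(math.ceil(half / pixel_size_mm)) + 1
    outer, inner = _annulus_masks((n, n), pixel_size_mm, a, b, a_i, b_i, rotation_deg)
    cortex = outer & ~inner

    cortex_area = math.pi * (a * b - a_i * b_i)
    pores = _plant_pores(cortex, cortex_area, pore_fraction, pore_radius_mm,
                         pixel_size_mm, rng)
    image = np.full((n, n), float(background_intensity))
    image[cortex] = bone_intensity
    _stamp_pores(image, pores, pixel_size_mm, background_intensity)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    truth = SectionTruth.from_annulus(a, b, a_i, b_i, _pore_area(pores))
    return (
        CrossSectionImage(image, pixel_size_mm, provenance=f"section-phantom(seed={seed})"),
        truth,
    )


# ---------------------------------------------------------------------------
# 3D volume phantom


def make_phantom_volume(
    spec: PhantomSpec,
    truth_fractions: tuple = (0.35, 0.5, 0.65),
) -> tuple[VoxelVolume, dict[float, SectionTruth]]:
    """Voxelize a full tapered-annulus bone volume with planted pores.

    Pores are short longitudinal canals (circular cross-section, a few slices
    tall) planted per z-segment against the segment's narrowest cortex, so
    every slice's planted pore area stays within 0.5 percentage points of
    ``spec.pore_fraction``.  The finished volume is mirrored for left-side
    specimens, rotated by ``spec.tilt_euler_deg``, degraded with additive
    Gaussian noise, and clipped to 8-bit.

    Returns the volume and closed-form truth at each requested fraction of
    length (distal end at low z).
    """
    rng = np.random.default_rng(spec.seed)
    vx = spec.voxel_size_mm
    n_z = int(round(spec.length_mm / vx))
    if n_z < 3:
        raise ValueError("volume must span at least 3 slices")

    a_max = max(spec.outer_a_mm)
    b_max = max(spec.outer_b_mm)
    pad = 3 * vx
    nx = 2 * int(math.ceil((a_max + pad) / vx)) + 1
    ny = 2 * int(math.ceil((b_max + pad) / vx)) + 1
    pad_z = 3
    vol = np.full((n_z + 2 * pad_z, ny, nx), float(spec.background_intensity))

    # canal height: pores are longitudinal canals spanning a slab of slices,
    # tall enough that a slightly oblique resampled section still samples a
    # single canal population
    slice_cpa = np.zeros(n_z)
    canals: list[list] = []  # active: [row, col, radius_mm, end_slice]
    gap = vx
    min_len = max(3, int(round(2.0 / vx)))
    max_len = max(min_len + 1, int(round(6.0 / vx)))
    # per-slice tracking band, kept an order of magnitude tighter than the
    # 0.5-percentage-point contract so neighbouring slices agree closely
    lower_tol, upper_tol = 0.1 * _PORE_TOL, 0.2 * _PORE_TOL

    for k in range(n_z):
        frac = k / (n_z - 1)
        a, b, a_i, b_i = spec.semi_axes_at(frac)
        outer, inner = _annulus_masks((ny, nx), vx, a, b, a_i, b_i)
        cortex = outer & ~inner
        plane = vol[pad_z + k]
        plane[cortex] = spec.bone_intensity
        if spec.pore_fraction > 0:
            cortex_area = math.pi * (a * b - a_i * b_i)
            dt = ndimage.distance_transform_edt(cortex) * vx
            # retire canals that reached their planned end or that the
            # tapering cortex can no longer contain
            canals = [
                c for c in canals if c[3] > k and dt[c[0], c[1]] > c[2] + gap
            ]
            target = spec.pore_fraction * cortex_area
            planted = _pore_area([(c[0], c[1], c[2]) for c in canals])
            while planted > target + upper_tol * cortex_area and canals:
                # cortex narrowed: end the youngest canal early
                victim = max(range(len(canals)), key=lambda i: canals[i][3])
                planted -= math.pi * canals[victim][2] ** 2
                canals.pop(victim)
            attempts = 0
            while planted < target - lower_tol * cortex_area:
                if attempts > 5000:
                    raise PorePackingError(
                        f"pore packing saturated at slice {k}: fraction "
                        f"{planted / cortex_area:.4f} (target {spec.pore_fraction:.4f})"
                    )
                attempts += 1
                r = float(rng.uniform(0.85, 1.15) * spec.pore_radius_mm)
                if planted + math.pi * r * r > target + upper_tol * cortex_area:
                    r = math.sqrt(max(target - planted, 0.0) / math.pi)
                    if r < 1.5 * vx:
                        break
                row = int(rng.integers(ny))
                col = int(rng.integers(nx))
                if dt[row, col] <= r + gap:
                    continue
                if any(
                    (row - c[0]) ** 2 + (col - c[1]) ** 2 <= ((r + c[2] + gap) / vx) ** 2
                    for c in canals
                ):
                    continue
                canals.append([row, col, r, k + int(rng.integers(min_len, max_len))])
                planted += math.pi * r * r
            _stamp_pores(plane, [(c[0], c[1], c[2]) for c in canals], vx,
                         spec.background_intensity)
            slice_cpa[k] = planted

    if spec.side.upper() == "L":
        vol = vol[:, :, ::-1].copy()

    if any(abs(t) > 1e-9 for t in spec.tilt_euler_deg):
        r_idx = to_index_space(euler_matrix_xyz(spec.tilt_euler_deg))
        vol = rotate_volume(vol, r_idx, cval=spec.background_intensity)
        vol = _crop_to_foreground(vol, vol > spec.background_intensity, margin=3,
                                  fill=spec.background_intensity)

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    truths = {}
    for frac in truth_fractions:
        k = int(math.floor(frac * (n_z - 1) + 0.5))
        truths[frac] = section_truth_at(spec, frac, cpa_mm2=slice_cpa[k])
    volume = VoxelVolume(vol, vx, provenance=f"phantom(seed={spec.seed})")
    return volume, truths


# ---------------------------------------------------------------------------
# ontogenetic trajectories and cohorts


@dataclass(frozen=True)
class MedullaryTrajectory:
    """Rise-then-fall medullary index (MA/TA) over age.

    A gamma-shaped bump over a baseline: the index starts at ``baseline`` at
    birth (thick neonatal cortex around a narrow cavity), peaks at
    ``baseline + rise_amplitude`` at ``peak_age`` (cavity expansion in early
    infancy), then relaxes back as the cortex infills; ``fall_rate`` sets how
    sharply the bump decays.
    """

    baseline: float = 0.30
    rise_amplitude: float = 0.12
    peak_age: float = 1.5
    fall_rate: float = 1.0

    def __call__(self, age):
        t = np.asarray(age, dtype=float)
        k = self.fall_rate
        bump = np.where(
            t > 0, (t / self.peak_age) ** k * np.exp(k * (1.0 - t / self.peak_age)), 0.0
        )
        return self.baseline + self.rise_amplitude * bump


@dataclass(frozen=True)
class PorosityTrajectory:
    """Exponentially declining porosity index (CPA/CA) over age.

    High intracortical porosity near birth declines toward a low adult
    plateau: value = plateau + (initial_level - plateau) exp(-decline_rate t).
    """

    initial_level: float = 0.12
    decline_rate: float = 1.2
    plateau: float = 0.01

    def __call__(self, age):
        t = np.asarray(age, dtype=float)
        return self.plateau + (self.initial_level - self.plateau) * np.exp(
            -self.decline_rate * t
        )

    def plateau_onset_age(self, residual: float = 0.05) -> float:
        """Age by which the decaying component has fallen to ``residual`` of
        its initial amplitude."""
        return math.log(1.0 / residual) / self.decline_rate


@dataclass(frozen=True)
class ShapeTrajectory:
    """Monotone decline of Ix/Iy from circular toward the adult value
    (progressive mediolateral reinforcement)."""

    initial_ratio: float = 1.0
    adult_ratio: float = 0.45
    rate: float = 0.4

    def __call__(self, age):
        t = np.asarray(age, dtype=float)
        return self.adult_ratio + (self.initial_ratio - self.adult_ratio) * np.exp(
            -self.rate * t
        )


_DEFAULT_GROWTH = GrowthCurve(
    # cubic fitted to the bundled wild-chimpanzee reference sample
    coefficients=(67.748, 34.576, -3.2116, 0.13300),
    valid_age_range=(0.0, 13.0),
    valid_length_range=(60.0, 270.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of an ontogenetic cohort.

    Each individual's age is drawn uniformly over ``age_range_years``; femur
    length follows ``growth_curve`` plus Gaussian noise; the three
    trajectories (plus per-individual scatter ``noise_sds``) set that
    individual's phantom geometry, from which all section truth follows in
    closed form.
    """

    n_individuals: int = 20
    age_range_years: tuple[float, float] = (0.0, 13.0)
    medullary_trajectory: MedullaryTrajectory = field(default_factory=MedullaryTrajectory)
    porosity_trajectory: PorosityTrajectory = field(default_factory=PorosityTrajectory)
    shape_trajectory: ShapeTrajectory = field(default_factory=ShapeTrajectory)
    growth_curve: GrowthCurve = _DEFAULT_GROWTH
    noise_sds: dict = field(
        default_factory=lambda: {
            "medullary": 0.02, "porosity": 0.01, "shape": 0.03, "length": 5.0,
        }
    )
    voxel_size_mm: float = 0.15
    pore_radius_mm: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("a cohort needs at least 2 individuals")
        lo, hi = self.age_range_years
        if not 0.0 <= lo < hi:
            raise ValueError("invalid age range")


# flare multipliers giving metaphyseal ends and a mid-shaft waist; the distal
# end (z=0) flares most, which the auto distal-end rule keys on
_FLARE_Z = (0.0, 0.15, 0.5, 0.85, 1.0)
_FLARE = (1.35, 1.10, 1.0, 1.08, 1.25)


def phantom_spec_for_individual(
    age: float,
    femur_length_mm: float,
    medullary_index: float,
    porosity_index: float,
    ix_iy_ratio: float,
    cohort: CohortSpec,
    seed: int,
    side: str = "R",
    tilt_euler_deg: tuple = (0.0, 0.0, 0.0),
) -> PhantomSpec:
    """Translate ontogenetic targets into an exact phantom geometry.

    The inner ellipse is similar to the outer one (a_i = rho a, b_i = rho b),
    so medullary index = rho^2 and Ix/Iy = (b/a)^2 hold exactly at every
    cross-section regardless of taper.
    """
    m = float(np.clip(medullary_index, 0.05, 0.60))
    q = float(np.clip(porosity_index, 0.0, 0.35))
    s = float(np.clip(ix_iy_ratio, 0.20, 1.0))
    rho = math.sqrt(m)
    a_mid = 0.045 * femur_length_mm  # mid-shaft ML semi-axis scales with length
    b_over_a = math.sqrt(s)
    a_prof = tuple(a_mid * f for f in _FLARE)
    b_prof = tuple(a_mid * b_over_a * f for f in _FLARE)
    return PhantomSpec(
        length_mm=femur_length_mm,
        profile_z=_FLARE_Z,
        outer_a_mm=a_prof,
        outer_b_mm=b_prof,
        inner_a_mm=tuple(rho * v for v in a_prof),
        inner_b_mm=tuple(rho * v for v in b_prof),
        pore_fraction=q,
        pore_radius_mm=cohort.pore_radius_mm,
        voxel_size_mm=cohort.voxel_size_mm,
        side=side,
        tilt_euler_deg=tilt_euler_deg,
        seed=seed,
    )


@dataclass(frozen=True)
class CohortData:
    """Generated cohort: metadata table, per-individual phantom specs,
    per-(individual, fraction) truth table, and (optionally) voxel volumes."""

    metadata: pd.DataFrame
    phantom_specs: list
    truth: pd.DataFrame
    volumes: list | None = None


def make_cohort(
    spec: CohortSpec,
    realize_volumes: bool = False,
    truth_fractions: tuple = (0.35, 0.5, 0.65),
) -> CohortData:
    """Draw an ontogenetic cohort of phantom individuals.

    ``realize_volumes=False`` (default) returns metadata, phantom specs and
    closed-form truth only — sufficient for trajectory-level analyses and far
    cheaper than voxelizing each individual.  With ``realize_volumes=True``
    the full voxel volume of every individual is generated as well.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range_years
    ages = rng.uniform(lo, hi, size=spec.n_individuals)
    sexes = rng.choice(["M", "F"], size=spec.n_individuals)
    sides = rng.choice(["R", "L"], size=spec.n_individuals, p=[0.7, 0.3])

    meta_rows, truth_rows, specs = [], [], []
    for i in range(spec.n_individuals):
        age = float(ages[i])
        length = float(spec.growth_curve(age) + rng.normal(0.0, spec.noise_sds["length"]))
        length = max(length, 30.0)
        m = float(spec.medullary_trajectory(age) + rng.normal(0.0, spec.noise_sds["medullary"]))
        q = float(spec.porosity_trajectory(age) + rng.normal(0.0, spec.noise_sds["porosity"]))
        s = float(spec.shape_trajectory(age) + rng.normal(0.0, spec.noise_sds["shape"]))
        ind_seed = int(rng.integers(0, 2**31 - 1))
        pspec = phantom_spec_for_individual(
            age, length, m, q, s, spec, seed=ind_seed, side=str(sides[i])
        )
        specs.append(pspec)
        sid = f"SYN_{spec.seed:04d}_{i:03d}"
        meta_rows.append(
            {
                "specimen_id": sid,
                "sex": str(sexes[i]),
                "age_years": age,
                "side": str(sides[i]),
                "femur_length_mm": length,
                "voxel_size_mm": spec.voxel_size_mm,
            }
        )
        for frac in truth_fractions:
            t = section_truth_at(pspec, frac)
            row = t.as_dict()
            # pores are realized only when the volume is; record the target
            row["CPA_mm2"] = pspec.pore_fraction * row["CA_mm2"]
            row["porosity_index"] = pspec.pore_fraction
            row["ix_iy_ratio"] = row["Ix_mm4"] / row["Iy_mm4"]
            row["imax_imin_ratio"] = row["Imax_mm4"] / row["Imin_mm4"]
            row.update(specimen_id=sid, fraction=frac, age_years=age)
            truth_rows.append(row)

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    volumes = None
    if realize_volumes:
        volumes = [make_phantom_volume(ps, truth_fractions)[0] for ps in specs]
    return CohortData(metadata=metadata, phantom_specs=specs, truth=truth, volumes=volumes)


def simulate_growth_pairs(
    curve: GrowthCurve, n: int, noise_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Sample (age, femur length) pairs from a growth curve with Gaussian
    length noise; at least 4 pairs (a cubic must be identifiable)."""
    if n < 4:
        raise ValueError("need n >= 4 pairs to identify a cubic")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*curve.valid_age_range, size=n)
    lengths = np.asarray(curve(ages)) + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "id": [f"GP_{i:03d}" for i in range(n)],
            "age_years": ages,
            "femur_length_mm": lengths,
        }
    )
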