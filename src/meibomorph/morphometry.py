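"""Per-gland geometry extraction and the deformation coefficient.

The deformation coefficient D scores how far a single gland departs from a
straight band of uniform width.  It combines the arc-chord (arc-string)
tortuosity of the two gland boundaries with a width-variation term:

    ratio   = pa * pb / L_central**2
    sigma_w = sqrt( sum_i (w_i - w_avg)**2 / (n + 1) )

where ``pa`` and ``pb`` are the arc lengths of the left and right gland
boundaries, ``L_central`` is the length of the central axis segment (the
"string" of the arc-string model: the straight segment joining the first
and last midpoints), ``w_i`` are the per-row gland widths ("diameters",
one per sampling step), ``w_avg`` their mean and ``n`` their count.

Three combiners are available (see :func:`deformation_coefficient`); the
default multiplies the arc-chord ratio by ``1 + sigma_w / w_avg``, which is
dimensionless and attains its minimum of exactly 1.0 on a straight gland of
constant width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter
from skimage import measure

__all__ = [
    "VARIANTS",
    "DEFAULT_VARIANT",
    "MorphometryError",
    "GlandGeometry",
    "DeformationRecord",
    "EyeRecord",
    "GlandComponent",
    "width_variation",
    "polyline_length",
    "label_glands",
    "extract_geometry",
    "deformation_coefficient",
    "analyze_eye",
]

#: Formula variants for the deformation coefficient.
VARIANTS = ("as_printed", "normalized", "normalized_plus_one")
DEFAULT_VARIANT = "normalized_plus_one"

#: Below this principal-axis tilt (radians) the component is treated as
#: already axis-aligned and no rotation is applied, so axis-aligned masks
#: are measured exactly.
_ROTATION_EPS = 0.01

#: Boundary sequences are smoothed with a quadratic Savitzky-Golay filter
#: before arc lengths are measured; raw pixel-quantised boundaries form a
#: staircase whose polyline length is biased upward, worst for shallow
#: slopes.  At steep slopes quantisation noise is negligible relative to
#: the per-row excursion and wide windows clip curvature extrema instead,
#: so the window shrinks with the measured boundary slope.  Widths get a
#: short moving average against the same quantisation jitter.
_BOUNDARY_SMOOTH = 11
_WIDTH_SMOOTH = 3


def _slope_adaptive_window(x: np.ndarray, max_window: int) -> int:
    slope = np.median(np.abs(np.diff(x)))
    if slope >= 1.5:
        win = 5
    elif slope >= 0.75:
        win = 7
    else:
        win = max_window
    n = x.size
    return min(win, n if n % 2 else n - 1)


class MorphometryError(ValueError):
    """Raised for degenerate glands or invalid morphometry inputs."""


def width_variation(widths: Sequence[float], denominator: str = "n_plus_1") -> float:
    """Width-variation term sigma_w = sqrt(sum (w_i - w_avg)^2 / d).

    ``denominator`` selects d: ``"n_plus_1"`` (the model's convention, the
    default), ``"n"`` or ``"n_minus_1"``.
    """
    w = np.asarray(widths, dtype=float)
    n = w.size
    if n < 2:
        raise MorphometryError("need at least 2 width samples")
    d = {"n_plus_1": n + 1, "n": n, "n_minus_1": n - 1}[denominator]
    return float(np.sqrt(np.sum((w - w.mean()) ** 2) / d))


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (N, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise MorphometryError("polyline needs at least 2 points")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class GlandGeometry:
    """Geometry of one gland sampled once per step along its axis.

    Point arrays are (n, 2) in (axis, across-axis) coordinates; for an
    unrotated gland these are (row, column) pixel coordinates.
    """

    centerline_pts: np.ndarray
    left_boundary_pts: np.ndarray
    right_boundary_pts: np.ndarray
    widths: np.ndarray
    w_avg: float
    sigma_w: float
    pa: float
    pb: float
    L_central: float
    n: int

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.n != len(self.widths) or self.n < 2:
            raise MorphometryError("n must equal len(widths) and be >= 2")
        if np.any(self.widths <= 0):
            raise MorphometryError("degenerate width")
        if self.L_central <= 0:
            raise MorphometryError("degenerate central line")

    @classmethod
    def from_profile(
        cls,
        axis_pos: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        widths: np.ndarray | None = None,
        sigma_denominator: str = "n_plus_1",
    ) -> "GlandGeometry":
        """Build a geometry from per-step left/right boundary positions.

        ``axis_pos`` are the sampling positions along the gland axis,
        ``left``/``right`` the across-axis boundary coordinates.  ``widths``
        defaults to ``right - left``; raster extraction passes its own
        pixel-count widths instead.
        """
        axis_pos = np.asarray(axis_pos, dtype=float)
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if widths is None:
            widths = right - left
        widths = np.asarray(widths, dtype=float)
        center = (left + right) / 2.0
        left_pts = np.column_stack([axis_pos, left])
        right_pts = np.column_stack([axis_pos, right])
        center_pts = np.column_stack([axis_pos, center])
        # The central line is the straight axis segment (the "string"):
        # its length is the distance between the first and last midpoints.
        l_central = float(
            np.hypot(axis_pos[-1] - axis_pos[0], center[-1] - center[0])
        )
        return cls(
            centerline_pts=center_pts,
            left_boundary_pts=left_pts,
            right_boundary_pts=right_pts,
            widths=widths,
            w_avg=float(widths.mean()),
            sigma_w=width_variation(widths, sigma_denominator),
            pa=polyline_length(left_pts),
            pb=polyline_length(right_pts),
            L_central=l_central,
            n=len(widths),
        )


@dataclass
class DeformationRecord:
    """Deformation coefficient for one gland of one eye.

    ``gland_index`` runs 1..10 from the temporal to the nasal side.
    """

    gland_index: int
    D: float
    variant: str = DEFAULT_VARIANT
    geometry_ref: GlandGeometry | None = None


@dataclass
class EyeRecord:
    """Per-eye analysis result: subject, laterality, group, gland records."""

    subject_id: str
    laterality: str  # "OD" | "OS"
    group: str  # "treatment" | "control"
    mask_ref: str | None = None
    records: list[DeformationRecord] = field(default_factory=list)


@dataclass
class GlandComponent:
    """One connected component of a gland mask."""

    label: int
    coords: np.ndarray  # (N, 2) integer (row, col) pixel coordinates
    area: int
    centroid_row: float
    centroid_col: float
    touches_border: bool

    @property
    def topmost_row(self) -> int:
        return int(self.coords[:, 0].min())


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MorphometryError("mask must be 2-D")
    return mask > 0


def label_glands(mask: np.ndarray, min_area: int = 64) -> list[GlandComponent]:
    """Label gland components and order them left-to-right by centroid column.

    Components are 8-connected; those below ``min_area`` pixels are
    discarded.  Ties in centroid column are broken by topmost row.
    """
    bmask = _as_bool_mask(mask)
    lab = measure.label(bmask, connectivity=2)
    comps: list[GlandComponent] = []
    nrows, ncols = bmask.shape
    for region in measure.regionprops(lab):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        comps.append(
            GlandComponent(
                label=region.label,
                coords=np.asarray(region.coords),
                area=int(region.area),
                centroid_row=float(region.centroid[0]),
                centroid_col=float(region.centroid[1]),
                touches_border=(r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols),
            )
        )
    comps.sort(key=lambda c: (c.centroid_col, c.topmost_row))
    return comps


def _bin_profile(
    axis_pos: np.ndarray, across_pos: np.ndarray, step_px: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row (left, right) across-axis extrema binned along the axis."""
    rel = np.rint((axis_pos - axis_pos.min()) / step_px).astype(int)
    nbins = int(rel.max()) + 1
    if nbins < 2:
        raise MorphometryError("gland too short")
    counts = np.bincount(rel, minlength=nbins)
    if np.any(counts == 0):
        raise MorphometryError("fragmented gland: internal empty row")
    left = np.full(nbins, np.inf)
    right = np.full(nbins, -np.inf)
    np.minimum.at(left, rel, across_pos)
    np.maximum.at(right, rel, across_pos)
    rows = axis_pos.min() + np.arange(nbins, dtype=float) * step_px
    return rows, left, right


def _axis_frame(coords: np.ndarray, step_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotate pixel coordinates so the central gland axis is the first axis.

    The rotation acts on the coordinate set, not the raster, so no
    resampling occurs.  A second-moment (principal-axis) estimate gives the
    coarse orientation; it is then refined so that the central chord — the
    segment joining the first and last row midpoints, i.e. the "string" of
    the arc-string model — is vertical.  The refinement matters for sinuous
    glands, whose lateral excursions bias the raw second moments.
    Near-vertical components (tilt below _ROTATION_EPS) skip rotation, so
    axis-aligned masks are measured exactly.
    """
    pts = coords.astype(float)
    if pts.shape[0] < 3:
        return pts[:, 0], pts[:, 1]
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] < 0:  # orient top-to-bottom
        major = -major
    tilt = np.arctan2(major[1], major[0])
    if abs(tilt) > np.pi / 4:
        # Closer to horizontal than vertical: bring the major axis upright
        # before any row binning makes sense.
        minor = np.array([-major[1], major[0]])
        axis_pos, across_pos = centered @ major, centered @ minor
    else:
        # Near-vertical glands keep the image frame; the second moments of
        # a sinuous gland are biased by its lateral excursions, so the
        # chord refinement below, not the PCA tilt, decides the rotation.
        axis_pos, across_pos = pts[:, 0], pts[:, 1]
    for _ in range(3):
        rows, left, right = _bin_profile(axis_pos, across_pos, step_px)
        mid = (left + right) / 2.0
        chord_tilt = np.arctan2(mid[-1] - mid[0], rows[-1] - rows[0])
        if abs(chord_tilt) < _ROTATION_EPS / 10.0:
            break
        c, s = np.cos(chord_tilt), np.sin(chord_tilt)
        axis_pos, across_pos = c * axis_pos + s * across_pos, -s * axis_pos + c * across_pos
    return axis_pos, across_pos


def extract_geometry(
    component: GlandComponent | np.ndarray,
    step_px: int = 1,
    sigma_denominator: str = "n_plus_1",
    smooth_window: int = _BOUNDARY_SMOOTH,
) -> GlandGeometry:
    """Extract a :class:`GlandGeometry` from one connected component.

    The component is rotated (in coordinate space) so its principal axis is
    vertical; every ``step_px`` rows the leftmost and rightmost foreground
    positions give the boundary samples, width ``w_i = right - left + 1``
    and the midpoint.  Boundary sequences are smoothed (quadratic
    Savitzky-Golay) before polyline arc lengths ``pa``/``pb`` are measured;
    ``L_central`` is the length of the straight central axis segment.
    """
    if isinstance(component, GlandComponent):
        coords = component.coords
    else:
        bmask = _as_bool_mask(component)
        coords = np.argwhere(bmask)
        if coords.size == 0:
            raise MorphometryError("empty component")
    axis_pos, across_pos = _axis_frame(coords, step_px)
    rows, left, right = _bin_profile(axis_pos, across_pos, step_px)
    nbins = rows.size
    widths = right - left + 1.0

    def _smooth_boundary(x: np.ndarray) -> np.ndarray:
        win = _slope_adaptive_window(x, smooth_window)
        if win < 5:
            return x
        return savgol_filter(x, win, 2, mode="nearest")

    left_s = _smooth_boundary(left)
    right_s = _smooth_boundary(right)
    wwin = max(1, min(_WIDTH_SMOOTH, nbins))
    widths_s = uniform_filter1d(widths, size=wwin, mode="nearest")
    return GlandGeometry.from_profile(
        rows, left_s, right_s, widths=widths_s, sigma_denominator=sigma_denominator
    )


def deformation_coefficient(geom: GlandGeometry, variant: str = DEFAULT_VARIANT) -> float:
    """Deformation coefficient D of one gland geometry.

    Variants:

    ``"as_printed"``
        ``(pa*pb/L^2) * sigma_w`` — the literal reading of the published
        formula.  It carries pixel units and is 0, not 1, on a straight
        uniform gland; kept for fidelity.
    ``"normalized"``
        ``(pa*pb/L^2) * (sigma_w/w_avg)`` — dimensionless but still 0 on a
        uniform gland.
    ``"normalized_plus_one"`` (default)
        ``(pa*pb/L^2) * (1 + sigma_w/w_avg)`` — dimensionless with minimum
        exactly 1 on a straight uniform gland, matching the stated
        properties of the score.
    """
    if variant not in VARIANTS:
        raise MorphometryError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if geom.L_central <= 0:
        raise MorphometryError("L_central must be positive")
    if geom.w_avg <= 0:
        raise MorphometryError("w_avg must be positive")
    ratio = geom.pa * geom.pb / geom.L_central**2
    if variant == "as_printed":
        return ratio * geom.sigma_w
    if variant == "normalized":
        return ratio * (geom.sigma_w / geom.w_avg)
    return ratio * (1.0 + geom.sigma_w / geom.w_avg)


def analyze_eye(
    mask: np.ndarray,
    laterality: str,
    group: str,
    subject_id: str = "",
    variant: str = DEFAULT_VARIANT,
    min_area: int = 64,
    step_px: int = 1,
    temporal_side: str | None = None,
    sigma_denominator: str = "n_plus_1",
    exclude_border: bool = True,
    mask_ref: str | None = None,
) -> EyeRecord:
    """Analyze one eye mask: label, select the 10 central glands, score each.

    Glands touching the image border are excluded (their geometry is
    incomplete).  Raises :class:`MorphometryError` if fewer than 10
    analyzable glands remain.
    """
    from .selection import find_midline, select_central_10, temporal_side_for

    comps = label_glands(mask, min_area=min_area)
    if exclude_border:
        comps = [c for c in comps if not c.touches_border]
    if len(comps) < 10:
        raise MorphometryError(f"insufficient glands ({len(comps)} < 10)")
    if temporal_side is None:
        temporal_side = temporal_side_for(laterality)
    midline = find_midline(comps)
    index_map = select_central_10(comps, midline, laterality, temporal_side)
    records = []
    for idx, comp in index_map.items():
        geom = extract_geometry(
            comp, step_px=step_px, sigma_denominator=sigma_denominator
        )
        records.append(
            DeformationRecord(
                gland_index=idx,
                D=deformation_coefficient(geom, variant),
                variant=variant,
                geometry_ref=geom,
            )
        )
    return EyeRecord(
        subject_id=subject_id,
        laterality=laterality,
        group=group,
        mask_ref=mask_ref,
        records=records,
    )
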