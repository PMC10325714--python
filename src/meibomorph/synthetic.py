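"""Synthetic meibography scenes and paired two-eye cohorts.

Glands are modelled as vertical bands: the centerline is a sinusoid in the
column direction, the width tapers linearly along the axis, and a pixel is
foreground when its column lies within half the local width of the
centerline column ("horizontal offset" rasterization).  This family spans
straight to heavily distorted glands while keeping the two ingredients of
the deformation coefficient — boundary arc length and width variance —
under independent control: the sinusoid amplitude drives the arc-chord
ratio, the width taper drives ``sigma_w``, and neither contaminates the
other.

Coordinates are 0-based, rows run down the image, and the gland axis is
the row direction.

Cohorts emulate a paired ocular design: each subject contributes a treated
eye and the untreated contralateral eye.  Per gland, the control eye draws
its deformation target from a baseline profile plus subject-level noise
shared between the eyes (inducing between-eye correlation) plus eye-level
noise; the treated eye adds a per-gland additive effect.  Shape parameters
are then solved (1-D inversion on the sinusoid amplitude) so the analytic
deformation coefficient of the generated gland matches its target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .morphometry import (
    DEFAULT_VARIANT,
    DeformationRecord,
    EyeRecord,
    GlandGeometry,
    deformation_coefficient,
    width_variation,
)

__all__ = [
    "SyntheticError",
    "GlandShapeParams",
    "EyelidScene",
    "CohortSpec",
    "SyntheticEye",
    "CohortSubject",
    "truth_geometry",
    "analytic_deformation",
    "generate_gland_mask",
    "render_image",
    "scene_from_params",
    "generate_eyelid_scene",
    "solve_amplitude_for_d",
    "generate_cohort",
    "render_eye_scene",
    "COHORT_LENGTH_PX",
    "COHORT_WAVELENGTH_PX",
    "COHORT_BASE_WIDTH_PX",
]


class SyntheticError(ValueError):
    """Raised for invalid shape parameters or infeasible scenes."""


# Canonical cohort gland: 361 rows spanning exactly three sinusoid periods,
# so arc-length integrals over the axis are phase-invariant and the central
# chord is exactly vertical.
COHORT_LENGTH_PX = 361
COHORT_WAVELENGTH_PX = 120.0
COHORT_BASE_WIDTH_PX = 11.0
#: Absolute width-taper slopes sampled for cohort glands (px per row).
COHORT_TAPER_SLOPES = (0.008, 0.012, 0.016, 0.020)

_DENSE_N = 20001  # dense-integration grid for analytic arc lengths


@dataclass
class GlandShapeParams:
    """Continuous parameterization of one synthetic gland.

    ``length_px`` is the number of rasterized rows; the centerline column at
    row offset y (0 <= y <= length_px - 1) is
    ``axis_col + amplitude_px * sin(2*pi*y/wavelength_px + phase_rad)`` and
    the local width is ``base_width_px + width_slope * y``.
    """

    length_px: int
    base_width_px: float
    amplitude_px: float = 0.0
    wavelength_px: float = 100.0
    width_slope: float = 0.0
    phase_rad: float = 0.0
    axis_col: float = 0.0

    def __post_init__(self) -> None:
        if self.length_px < 2:
            raise SyntheticError("length_px must be >= 2")
        if self.base_width_px <= 0:
            raise SyntheticError("base_width_px must be > 0")
        if self.amplitude_px < 0:
            raise SyntheticError("amplitude_px must be >= 0")
        if self.wavelength_px <= 0:
            raise SyntheticError("wavelength_px must be > 0")
        if min(self.base_width_px, self.base_width_px + self.width_slope * (self.length_px - 1)) <= 0:
            raise SyntheticError("degenerate width")

    # -- continuous model ------------------------------------------------
    def centerline(self, y: np.ndarray) -> np.ndarray:
        k = 2.0 * np.pi / self.wavelength_px
        return self.axis_col + self.amplitude_px * np.sin(k * np.asarray(y, float) + self.phase_rad)

    def centerline_slope(self, y: np.ndarray) -> np.ndarray:
        k = 2.0 * np.pi / self.wavelength_px
        return self.amplitude_px * k * np.cos(k * np.asarray(y, float) + self.phase_rad)

    def width(self, y: np.ndarray) -> np.ndarray:
        return self.base_width_px + self.width_slope * np.asarray(y, float)


def truth_geometry(
    params: GlandShapeParams,
    row0: int = 0,
    sigma_denominator: str = "n_plus_1",
) -> GlandGeometry:
    """Analytic ground-truth geometry of ``params``.

    Boundary arc lengths come from dense trapezoid integration of the
    continuous boundary curves ``centerline(y) -/+ width(y)/2``; width
    samples are taken once per row; the central-line length is the straight
    distance between the first and last centerline points.  Independent of
    any rasterization.
    """
    span = params.length_px - 1
    y_rows = np.arange(params.length_px, dtype=float)
    widths = params.width(y_rows)
    if np.any(widths <= 0):
        raise SyntheticError("degenerate width")

    t = np.linspace(0.0, span, _DENSE_N)
    cs = params.centerline_slope(t)
    half = params.width_slope / 2.0
    pa = float(np.trapezoid(np.sqrt(1.0 + (cs - half) ** 2), t))
    pb = float(np.trapezoid(np.sqrt(1.0 + (cs + half) ** 2), t))

    center = params.centerline(y_rows)
    left = center - widths / 2.0
    right = center + widths / 2.0
    axis_pos = row0 + y_rows
    l_central = float(np.hypot(span, center[-1] - center[0]))
    return GlandGeometry(
        centerline_pts=np.column_stack([axis_pos, center]),
        left_boundary_pts=np.column_stack([axis_pos, left]),
        right_boundary_pts=np.column_stack([axis_pos, right]),
        widths=widths,
        w_avg=float(widths.mean()),
        sigma_w=width_variation(widths, sigma_denominator),
        pa=pa,
        pb=pb,
        L_central=l_central,
        n=len(widths),
    )


def analytic_deformation(params: GlandShapeParams, variant: str = DEFAULT_VARIANT) -> float:
    """Deformation coefficient of the continuous gland model."""
    return deformation_coefficient(truth_geometry(params), variant)


def generate_gland_mask(
    params: GlandShapeParams,
    canvas_rows: int,
    canvas_cols: int,
    row0: int | None = None,
) -> tuple[np.ndarray, GlandGeometry]:
    """Rasterize one gland and return (mask, analytic ground truth).

    A pixel is foreground when its column is within half the local width of
    the centerline column of its row.  The gland occupies rows
    ``row0 .. row0 + length_px - 1`` (vertically centered by default).
    Raises ``SyntheticError("out of canvas")`` if it does not fit.
    """
    if row0 is None:
        row0 = (canvas_rows - params.length_px) // 2
    if row0 < 0 or row0 + params.length_px > canvas_rows:
        raise SyntheticError("out of canvas")
    y = np.arange(params.length_px, dtype=float)
    center = params.centerline(y)
    w = params.width(y)
    if np.any(w <= 0):
        raise SyntheticError("degenerate width")
    lo = np.ceil(center - w / 2.0).astype(int)
    hi = np.floor(center + w / 2.0).astype(int)
    if lo.min() < 0 or hi.max() >= canvas_cols:
        raise SyntheticError("out of canvas")
    mask = np.zeros((canvas_rows, canvas_cols), dtype=bool)
    for i in range(params.length_px):
        mask[row0 + i, lo[i] : hi[i] + 1] = True
    return mask, truth_geometry(params, row0=row0)


def render_image(
    mask: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    fg_level: float = 200.0,
    bg_level: float = 20.0,
    blur_sigma: float = 1.2,
) -> np.ndarray:
    """Render an 8-bit grayscale image from a gland mask.

    Foreground intensity smoothed into the background plus additive
    Gaussian noise, clipped to [0, 255].
    """
    base = bg_level + (fg_level - bg_level) * gaussian_filter(
        mask.astype(float), blur_sigma
    )
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return np.clip(base, 0, 255).astype(np.uint8)


@dataclass
class EyelidScene:
    """A rendered eyelid: image, mask, per-gland params and ground truth."""

    image: np.ndarray
    mask: np.ndarray
    gland_params: list[GlandShapeParams]
    truth_geometries: list[GlandGeometry]

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise SyntheticError("image and mask dims must match")

    def params_json(self) -> str:
        return json.dumps([asdict(p) for p in self.gland_params], indent=1)


def scene_from_params(
    gland_params: list[GlandShapeParams],
    canvas_rows: int,
    canvas_cols: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EyelidScene:
    """Rasterize a list of glands onto one canvas and render the image.

    Glands must not overlap ("infeasible packing").  Gland order must be
    left-to-right; ground-truth geometries align index-wise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    order = sorted(range(len(gland_params)), key=lambda i: gland_params[i].axis_col)
    if order != list(range(len(gland_params))):
        raise SyntheticError("gland_params must be ordered left-to-right")
    mask = np.zeros((canvas_rows, canvas_cols), dtype=bool)
    truths: list[GlandGeometry] = []
    for p in gland_params:
        gmask, truth = generate_gland_mask(p, canvas_rows, canvas_cols)
        if np.any(mask & gmask):
            raise SyntheticError("infeasible packing: glands overlap")
        mask |= gmask
        truths.append(truth)
    image = render_image(mask, noise_sd, rng)
    return EyelidScene(image=image, mask=mask, gland_params=gland_params, truth_geometries=truths)


_DEFAULT_SHAPE_RANGES: dict[str, tuple[float, float]] = {
    "length_px": (260, 320),
    "base_width_px": (8.0, 14.0),
    "amplitude_px": (0.0, 14.0),
    "wavelength_px": (90.0, 140.0),
    "width_slope": (-0.015, 0.015),
    "phase_rad": (0.0, 2.0 * np.pi),
}


def generate_eyelid_scene(
    n_glands: int,
    spacing_px: float = 60.0,
    shape_ranges: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 4.0,
    seed: int = 0,
    margin_rows: int = 40,
    margin_cols: float | None = None,
) -> EyelidScene:
    """Sample ``n_glands`` gland shapes and render one eyelid scene.

    Deterministic for a fixed seed.  Shape fields are drawn uniformly from
    ``shape_ranges`` (defaults above); gland axes sit on an even grid of
    pitch ``spacing_px``.
    """
    if n_glands < 1:
        raise SyntheticError("n_glands must be >= 1")
    ranges = dict(_DEFAULT_SHAPE_RANGES)
    if shape_ranges:
        ranges.update(shape_ranges)
    rng = np.random.default_rng(seed)
    if margin_cols is None:
        margin_cols = spacing_px
    params: list[GlandShapeParams] = []
    for i in range(n_glands):
        draw = {k: rng.uniform(*ranges[k]) for k in ranges}
        params.append(
            GlandShapeParams(
                length_px=int(round(draw["length_px"])),
                base_width_px=draw["base_width_px"],
                amplitude_px=draw["amplitude_px"],
                wavelength_px=draw["wavelength_px"],
                width_slope=draw["width_slope"],
                phase_rad=draw["phase_rad"],
                axis_col=margin_cols + i * spacing_px + 0.25,
            )
        )
    canvas_rows = int(max(p.length_px for p in params)) + 2 * margin_rows
    canvas_cols = int(np.ceil(2 * margin_cols + (n_glands - 1) * spacing_px))
    return scene_from_params(params, canvas_rows, canvas_cols, noise_sd=noise_sd, rng=rng)


# ---------------------------------------------------------------------------
# Amplitude <-> deformation inversion
# ---------------------------------------------------------------------------

def solve_amplitude_for_d(
    target_d: float,
    params: GlandShapeParams,
    variant: str = DEFAULT_VARIANT,
    tol: float = 1e-4,
    max_amplitude: float | None = None,
) -> float:
    """Amplitude at which the analytic D of ``params`` equals ``target_d``.

    All fields of ``params`` except the amplitude are kept.  D is strictly
    increasing in amplitude, so the solution is unique.  Raises
    ``SyntheticError`` when the target lies below the gland's floor (its D
    at zero amplitude) or above the search cap.
    """
    def d_of(a: float) -> float:
        p = GlandShapeParams(
            length_px=params.length_px,
            base_width_px=params.base_width_px,
            amplitude_px=a,
            wavelength_px=params.wavelength_px,
            width_slope=params.width_slope,
            phase_rad=params.phase_rad,
            axis_col=params.axis_col,
        )
        return analytic_deformation(p, variant)

    floor = d_of(0.0)
    if target_d < floor - 1e-9:
        raise SyntheticError(
            f"unreachable target D={target_d:.4f}: below variant minimum {floor:.4f}"
        )
    if target_d <= floor:
        return 0.0
    if max_amplitude is None:
        max_amplitude = 4.0 * params.wavelength_px
    hi = params.wavelength_px / 4.0
    while d_of(hi) < target_d:
        hi *= 2.0
        if hi > max_amplitude:
            raise SyntheticError(
                f"unreachable target D={target_d:.4f}: exceeds search cap"
            )
    return float(brentq(lambda a: d_of(a) - target_d, 0.0, hi, xtol=tol))


@lru_cache(maxsize=32)
def _arc_ratio_table(half_slope: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate G(beta) = (pa/span)*(pb/span) for full-period sinusoids.

    ``beta`` is the peak centerline slope (amplitude * 2*pi/wavelength).
    Over whole periods the mean boundary slope factor is phase-invariant,
    so a single phase-averaged table serves every gland with the same
    absolute taper slope.
    """
    beta = np.linspace(0.0, 12.0, 2401)
    theta = np.linspace(0.0, 2.0 * np.pi, 2049)
    c = np.cos(theta)[None, :]
    b = beta[:, None]
    ga = np.trapezoid(np.sqrt(1.0 + (b * c - half_slope) ** 2), theta, axis=1) / (2.0 * np.pi)
    gb = np.trapezoid(np.sqrt(1.0 + (b * c + half_slope) ** 2), theta, axis=1) / (2.0 * np.pi)
    return beta, ga * gb


def _width_term(base_width: float, slope: float, length: int, denominator: str = "n_plus_1") -> float:
    """C = 1 + sigma_w/w_avg of the linear width program on the row grid."""
    w = base_width + slope * np.arange(length, dtype=float)
    return 1.0 + width_variation(w, denominator) / float(w.mean())


# ---------------------------------------------------------------------------
# Paired cohorts
# ---------------------------------------------------------------------------

def _reference_profiles() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(baseline means, treatment effects, paired-difference SDs) per gland."""
    from .reference import load_reference_tables

    ref = load_reference_tables()
    baseline = np.array([row["mean"] for row in ref["site_anova"]["control"]["rows"]])
    effects = np.array([row["mean"] for row in ref["paired_differences"]["rows"]])
    diff_sd = np.array([row["sd"] for row in ref["paired_differences"]["rows"]])
    return baseline, effects, diff_sd


@dataclass
class CohortSpec:
    """Study conditions for a paired two-eye cohort.

    Defaults emulate the reference clinical cohort the pipeline was built
    around: 36 analyzable subjects per table row, control-eye baselines at
    the control-group site profile, treatment effects at the paired
    between-eye difference profile, and per-gland noise scaled so the
    generated paired-difference SD per gland matches the same profile.
    """

    n_subjects: int = 36
    per_gland_effect: np.ndarray | None = None  # 10 additive treatment shifts
    baseline_d: np.ndarray | None = None  # 10 control-eye means
    between_eye_corr: float = 0.5
    noise_sd: float | np.ndarray | None = None  # scalar or per-gland total eye SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SyntheticError("n_subjects must be >= 2")
        if not (0.0 <= self.between_eye_corr < 1.0):
            raise SyntheticError("between_eye_corr must be in [0, 1)")
        baseline, effects, diff_sd = _reference_profiles()
        if self.per_gland_effect is None:
            self.per_gland_effect = effects.copy()
        self.per_gland_effect = np.asarray(self.per_gland_effect, dtype=float)
        if self.per_gland_effect.shape != (10,):
            raise SyntheticError("per_gland_effect must have 10 entries")
        if self.baseline_d is None:
            self.baseline_d = baseline.copy()
        self.baseline_d = np.asarray(self.baseline_d, dtype=float)
        if self.baseline_d.shape != (10,):
            raise SyntheticError("baseline_d must have 10 entries")
        if self.noise_sd is None:
            # total per-eye SD such that sd(diff) = sqrt(2(1-rho))*sd
            # reproduces the reference paired-difference SD per gland
            self.noise_sd = diff_sd / np.sqrt(2.0 * (1.0 - self.between_eye_corr))
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (10,)
        ).copy()
        if np.any(self.noise_sd < 0):
            raise SyntheticError("noise_sd must be >= 0")


@dataclass
class SyntheticEye:
    """One generated eye: analysis record plus renderable shape params."""

    record: EyeRecord
    gland_params: list[GlandShapeParams]  # left-to-right, incl. 2 flankers
    index_by_position: list[int | None]  # gland index per position, None=flanker
    target_d: dict[int, float]
    realized_d: dict[int, float]


@dataclass
class CohortSubject:
    subject_id: str
    treatment: SyntheticEye
    control: SyntheticEye


def generate_cohort(spec: CohortSpec, variant: str = DEFAULT_VARIANT) -> list[CohortSubject]:
    """Generate a paired cohort of (treatment eye, control eye) subjects.

    Per subject and gland g the control deformation target is
    ``baseline_g + u_sg + e_sg`` and the treatment target adds
    ``effect_g``, where ``u`` is subject-level noise shared by both eyes
    (variance ``rho * sd_g^2``) and ``e`` is eye-level
    (variance ``(1-rho) * sd_g^2``).  Targets below a gland's geometric
    floor (its D at zero amplitude) are truncated to the floor.  Sinusoid
    amplitudes are solved so the analytic D of each generated gland equals
    its (truncated) target.

    Each eye carries 12 glands: the 10 indexed central glands plus one
    baseline flanker on each side, so central-region selection has margin.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    rho = spec.between_eye_corr
    sd = spec.noise_sd  # (10,)

    # Targets: axis order (subject, eye[T,C], gland 1..10)
    u = rng.normal(size=(n, 1, 10)) * np.sqrt(rho) * sd
    e = rng.normal(size=(n, 2, 10)) * np.sqrt(1.0 - rho) * sd
    targets = spec.baseline_d + u + e
    targets[:, 0, :] += spec.per_gland_effect

    # Flanker targets: baseline of the adjacent edge gland, same noise law.
    edge_sd = sd[[0, 9]]
    uf = rng.normal(size=(n, 1, 2)) * np.sqrt(rho) * edge_sd
    ef = rng.normal(size=(n, 2, 2)) * np.sqrt(1.0 - rho) * edge_sd
    flank_targets = spec.baseline_d[[0, 9]] + uf + ef

    # Width programs and phases per gland instance (12 per eye).
    slope_mag = rng.choice(COHORT_TAPER_SLOPES, size=(n, 2, 12))
    slope_sign = rng.choice([-1.0, 1.0], size=(n, 2, 12))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, 2, 12))
    lateralities = rng.choice(["OD", "OS"], size=n)

    k = 2.0 * np.pi / COHORT_WAVELENGTH_PX
    y = np.arange(COHORT_LENGTH_PX, dtype=float)

    # Width term C and base width per instance.  Negative tapers start wide
    # so widths stay positive and comparable.
    base_w = np.where(
        slope_sign < 0,
        COHORT_BASE_WIDTH_PX + slope_mag * (COHORT_LENGTH_PX - 1),
        COHORT_BASE_WIDTH_PX,
    )
    slope = slope_sign * slope_mag
    w = base_w[..., None] + slope[..., None] * y  # (n,2,12,L)
    w_avg = w.mean(axis=-1)
    sig = np.sqrt(np.sum((w - w_avg[..., None]) ** 2, axis=-1) / (COHORT_LENGTH_PX + 1))
    cterm = 1.0 + sig / w_avg  # (n,2,12)

    # Solve beta per instance from the phase-averaged arc-ratio table.
    betas = np.empty((n, 2, 12))
    realized = np.empty((n, 2, 12))
    all_targets = np.concatenate([flank_targets[..., :1], targets, flank_targets[..., 1:]], axis=2)
    for mag in COHORT_TAPER_SLOPES:
        sel = slope_mag == mag
        beta_grid, g_grid = _arc_ratio_table(mag / 2.0)
        ratio_needed = all_targets[sel] / cterm[sel]
        ratio_needed = np.clip(ratio_needed, g_grid[0], g_grid[-1])  # floor truncation
        b = np.interp(ratio_needed, g_grid, beta_grid)
        betas[sel] = b
        realized[sel] = np.interp(b, beta_grid, g_grid) * cterm[sel]
    amplitudes = betas / k

    subjects: list[CohortSubject] = []
    for s in range(n):
        lat_t = str(lateralities[s])
        lat_c = "OS" if lat_t == "OD" else "OD"
        sid = f"S{s + 1:03d}"
        eyes = []
        for eye_i, (lat, grp) in enumerate([(lat_t, "treatment"), (lat_c, "control")]):
            # Position -> gland index: index 1 sits at the temporal extreme.
            temporal_left = lat == "OD"
            index_by_position: list[int | None] = [None] * 12
            for pos in range(1, 11):
                index_by_position[pos] = pos if temporal_left else 11 - pos
            # all_targets columns are ordered [temporal flanker, g1..g10,
            # nasal flanker] in INDEX order; map to image positions.
            col_of_position = (
                [0 if temporal_left else 11]
                + [index_by_position[p] for p in range(1, 11)]
                + [11 if temporal_left else 0]
            )

            params_list = []
            amp_by_pos = []
            for pos in range(12):
                col = col_of_position[pos]
                amp_by_pos.append(amplitudes[s, eye_i, col])
            ext = 2.0 * np.asarray(amp_by_pos) + (base_w[s, eye_i].max() + slope_mag[s, eye_i].max() * COHORT_LENGTH_PX)
            pitch = float(ext.max()) + 8.0
            margin_c = pitch / 2.0 + 20.0
            for pos in range(12):
                col = col_of_position[pos]
                params_list.append(
                    GlandShapeParams(
                        length_px=COHORT_LENGTH_PX,
                        base_width_px=float(base_w[s, eye_i, col]),
                        amplitude_px=float(amplitudes[s, eye_i, col]),
                        wavelength_px=COHORT_WAVELENGTH_PX,
                        width_slope=float(slope[s, eye_i, col]),
                        phase_rad=float(phases[s, eye_i, col]),
                        axis_col=margin_c + pos * pitch + 0.25,
                    )
                )
            target_d = {g: float(all_targets[s, eye_i, g]) for g in range(1, 11)}
            realized_d = {g: float(realized[s, eye_i, g]) for g in range(1, 11)}
            records = [
                DeformationRecord(gland_index=g, D=realized_d[g], variant=variant)
                for g in range(1, 11)
            ]
            eyes.append(
                SyntheticEye(
                    record=EyeRecord(subject_id=sid, laterality=lat, group=grp, records=records),
                    gland_params=params_list,
                    index_by_position=index_by_position,
                    target_d=target_d,
                    realized_d=realized_d,
                )
            )
        subjects.append(CohortSubject(subject_id=sid, treatment=eyes[0], control=eyes[1]))
    return subjects


def render_eye_scene(
    eye: SyntheticEye,
    noise_sd: float = 4.0,
    seed: int = 0,
    margin_rows: int = 40,
) -> EyelidScene:
    """Rasterize and render the 12-gland scene of one generated eye."""
    rng = np.random.default_rng(seed)
    params = eye.gland_params
    canvas_rows = max(p.length_px for p in params) + 2 * margin_rows
    right_edge = max(
        p.axis_col + p.amplitude_px + p.width(np.arange(p.length_px)).max() for p in params
    )
    canvas_cols = int(np.ceil(right_edge + 20))
    return scene_from_params(params, canvas_rows, canvas_cols, noise_sd=noise_sd, rng=rng)
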