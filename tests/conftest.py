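import numpy as np
import pytest

from meibomorph.synthetic import GlandShapeParams, generate_gland_mask


@pytest.fixture
def rect_mask():
    """Axis-aligned 10-px-wide, 100-row rectangle gland."""
    mask = np.zeros((120, 40), dtype=bool)
    mask[10:110, 15:25] = True
    return mask


def dense_arc_oracle(params: GlandShapeParams, n_points: int = 20001):
    """Independent dense-integration oracle for (pa, pb, L_central).

    Samples the continuous boundary curves on a fine grid and sums segment
    lengths by finite differences — no shared code with the package's
    analytic-geometry path, which integrates derivative formulas.
    """
    y = np.linspace(0.0, params.length_px - 1, n_points)
    c = params.centerline(y)
    w = params.width(y)
    left = c - w / 2.0
    right = c + w / 2.0

    def arclen(x):
        return float(np.sum(np.hypot(np.diff(y), np.diff(x))))

    chord = float(np.hypot(y[-1] - y[0], (left[-1] + right[-1]) / 2 - (left[0] + right[0]) / 2))
    return arclen(left), arclen(right), chord


@pytest.fixture
def sinusoid_gland():
    """Single-period sinusoidal gland (amplitude 10, wavelength 100, width 10)."""
    params = GlandShapeParams(
        length_px=100, base_width_px=10.0, amplitude_px=10.0,
        wavelength_px=100.0, axis_col=60.25,
    )
    mask, truth = generate_gland_mask(params, 140, 120)
    return params, mask, truth
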