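import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from octavti.ridge import RidgeParams, steger_thresholds


@pytest.fixture(scope="session")
def ridge_params() -> RidgeParams:
    """Detection parameters matched to the default rendered vessels:
    detection scale = vessel profile sigma, thresholds from a minimum
    line contrast of 0.3."""
    up, lo = steger_thresholds(0.3, 2.0, 2.0)
    return RidgeParams(sigma=2.0, upper_threshold=up, lower_threshold=lo, min_component_px=20)


@pytest.fixture
def y_skeleton() -> np.ndarray:
    """Y-shaped 1-px skeleton: three straight branches meeting at (30, 30)."""
    sk = np.zeros((64, 64), dtype=bool)
    for i in range(31):
        sk[i, 30] = True  # vertical stem from the top
    for i in range(1, 25):
        sk[30 + i, 30 - i] = True  # lower-left branch
        sk[30 + i, 30 + i] = True  # lower-right branch
    return sk


def render_single_sine(amplitude, period, n_periods, seed=0, noise_sigma=0.0, size=1024):
    """One sine vessel centered on the canvas, plus its ground truth."""
    from octavti.synthetic import RenderConfig, make_curve, render_image

    curve = make_curve(
        "sine", {"amplitude": amplitude, "period": period, "n_periods": n_periods}, 3000
    )
    length = n_periods * period
    curve = curve.translated((size - length) / 2, size / 2)
    cfg = RenderConfig(
        image_size=size,
        vessel_profile_sigma=2.0,
        peak_intensity=0.8,
        background_level=0.05,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return render_image([curve], cfg)
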