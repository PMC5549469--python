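import numpy as np
import pytest

from fbcine import localize, lvcenter, phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: geometry checks need exact intensities."""
    cfg = phantom.PhantomConfig(seed=2, noise_sd=0.0)
    slc, truth = phantom.generate_cine(cfg)
    return cfg, slc, truth


@pytest.fixture(scope="session")
def default_phantom():
    """Phantom at the default (mildly noisy) study conditions."""
    cfg = phantom.PhantomConfig(seed=1)
    slc, truth = phantom.generate_cine(cfg)
    return cfg, slc, truth


@pytest.fixture(scope="session")
def clean_fits(clean_phantom):
    """Per-frame ellipse fits of the noise-free phantom via the full chain."""
    cfg, slc, truth = clean_phantom
    fits = []
    for t in range(1, cfg.n_frames + 1):
        pred = localize.fallback_localize(slc.frames[t - 1])
        assert pred is not None
        fit = lvcenter.locate_center(slc.frames[t - 1], pred.center)
        assert isinstance(fit, lvcenter.EllipseFit), (t, fit)
        fits.append(fit)
    return fits


def ellipse_points(center, a, b, angle, n=100, rng=None, noise_sd=0.0):
    """Exact (row, col) samples of an ellipse, optionally jittered."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = center[1] + a * np.cos(th) * np.cos(angle) - b * np.sin(th) * np.sin(angle)
    y = center[0] + a * np.cos(th) * np.sin(angle) + b * np.sin(th) * np.cos(angle)
    pts = np.column_stack([y, x])
    if noise_sd > 0:
        pts = pts + rng.normal(0, noise_sd, pts.shape)
    return pts
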