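import numpy as np
import pytest

from gastruquant import synth


def linear_profile(lo: float = 0.0, hi: float = 6000.0):
    return lambda s: lo + (hi - lo) * np.asarray(s, dtype=float)


def make_sample(seed: int, noise_sd: float = 0.0, frame=(360, 360), **shape_kwargs):
    """One synthetic gastruloid with a posterior-increasing T gradient."""
    rng = np.random.default_rng(seed)
    defaults = dict(
        length_px=float(rng.uniform(150, 210)),
        width_px=float(rng.uniform(55, 85)),
        bend_curvature=float(rng.uniform(0, 1 / 300)),
        orientation_deg=float(rng.uniform(0, 180)),
    )
    defaults.update(shape_kwargs)
    spec = synth.ShapeSpec(**defaults)
    pol = synth.PolarizationSpec("T", linear_profile(), noise_sd=noise_sd,
                                 background_level=500.0)
    return synth.make_gastruloid_image(spec, [pol], seed=seed, frame_shape=frame)


@pytest.fixture(scope="session")
def straight_sample():
    return make_sample(7, length_px=200.0, width_px=70.0, bend_curvature=0.0,
                       orientation_deg=0.0)


@pytest.fixture(scope="session")
def bent_sample():
    return make_sample(
        11, frame=(420, 480), length_px=300.0, width_px=60.0,
        bend_curvature=1 / 150, orientation_deg=0.0)


def disk_mask(radius: int = 50, pad: int = 20) -> np.ndarray:
    n = 2 * (radius + pad)
    rr, cc = np.ogrid[:n, :n]
    c = n / 2 - 0.5
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def ellipse_mask(a: float = 100, b: float = 60, pad: int = 25) -> np.ndarray:
    h, w = int(2 * (a + pad)), int(2 * (b + pad))
    rr, cc = np.ogrid[:h, :w]
    cr, cw = h / 2 - 0.5, w / 2 - 0.5
    return ((rr - cr) / a) ** 2 + ((cc - cw) / b) ** 2 <= 1


def rect_mask(length: int = 200, width: int = 40, pad: int = 30) -> np.ndarray:
    m = np.zeros((width + 2 * pad, length + 2 * pad), dtype=bool)
    m[pad: pad + width, pad: pad + length] = True
    return m


def raster_moment_eccentricity(mask: np.ndarray, supersample: int = 4) -> float:
    """Independent oracle: eccentricity of the second-moment-equivalent
    ellipse computed directly from (supersampled) raster moments."""
    m = np.kron(mask, np.ones((supersample, supersample), dtype=bool))
    rr, cc = np.nonzero(m)
    rr = rr.astype(float) - rr.mean()
    cc = cc.astype(float) - cc.mean()
    cov = np.cov(np.vstack([rr, cc]))
    lam = np.linalg.eigvalsh(cov)
    return float(np.sqrt(1.0 - lam[0] / lam[1]))
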