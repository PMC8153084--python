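import numpy as np
import pytest

from mammofractal import (
    GrayImage,
    PhantomRegion,
    PhantomSpec,
    ScaleFamily,
    generate_fbm_surface,
    generate_phantom_mammogram,
)


@pytest.fixture(scope="session")
def fbm_half():
    """One fixed H=0.5 surface reused by several tests."""
    return generate_fbm_surface(256, 0.5, seed=7)


@pytest.fixture(scope="session")
def small_scales():
    return ScaleFamily.log_spaced(2.0, 8.0, 10)


@pytest.fixture(scope="session")
def noise_field(small_scales):
    """64x64 white-noise field transformed at small scales (oracle tests)."""
    from mammofractal.wtmm import gradient_wavelet_transform

    rng = np.random.default_rng(42)
    values = rng.standard_normal((64, 64))
    return gradient_wavelet_transform(values, small_scales)


@pytest.fixture(scope="session")
def uniform_phantom():
    """448-px phantom textured with a single dense-class (H=0.65) region."""
    spec = PhantomSpec(
        image_side=448, regions=[PhantomRegion({"kind": "full"}, target_h=0.65)]
    )
    return generate_phantom_mammogram(spec, seed=5)


def periodogram_hurst(values) -> float:
    """Independent H oracle: Hann-windowed radially averaged periodogram.

    The spectral density of an isotropic H-rough surface falls as
    |k|^-(2H+2); the slope of the binned log-periodogram against log |k|
    recovers H without touching any wavelet machinery.
    """
    v = np.asarray(values, float)
    v = v - v.mean()
    n = v.shape[0]
    w = np.hanning(n)
    p = np.abs(np.fft.fft2(v * np.outer(w, w))) ** 2
    k = np.hypot(np.fft.fftfreq(n)[None, :], np.fft.fftfreq(n)[:, None]).ravel()
    p = p.ravel()
    bins = np.geomspace(3.0 / n, 0.25, 16)
    lk, lp = [], []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (k >= lo) & (k < hi)
        if sel.sum() >= 8:
            lk.append(np.log(np.sqrt(lo * hi)))
            lp.append(np.log(p[sel].mean()))
    slope = np.polyfit(lk, lp, 1)[0]
    return (-slope - 2.0) / 2.0


def structure_function_slope(values, lags) -> float:
    """Independent roughness oracle: log-log slope of E[(f(r+e)-f(r))^2]."""
    v = np.asarray(values, float)
    s2 = []
    for e in lags:
        d1 = v[e:, :] - v[:-e, :]
        d2 = v[:, e:] - v[:, :-e]
        s2.append(0.5 * (np.mean(d1**2) + np.mean(d2**2)))
    return np.polyfit(np.log(lags), np.log(s2), 1)[0]
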