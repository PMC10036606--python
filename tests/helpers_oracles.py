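"""Independent numerical oracles shared by the test modules.

These deliberately avoid the code paths of the package under test:
convolution is done by explicit FFT with a hand-built kernel, percentiles by
explicit sorting and linear interpolation between order statistics.
"""

import numpy as np
from scipy.signal import fftconvolve


def oracle_blur_bin(field: np.ndarray, sigma_nm: float, res_nm: float, factor: int) -> np.ndarray:
    """Dense-convolution + mean-binning oracle: explicit normalized Gaussian
    kernel, FFT convolution on a reflect-padded field."""
    r = int(np.ceil(5 * sigma_nm / res_nm))
    x = np.arange(-r, r + 1) * res_nm
    k1 = np.exp(-(x**2) / (2 * sigma_nm**2))
    k1 /= k1.sum()
    kern = np.outer(k1, k1)
    padded = np.pad(field, r, mode="reflect")
    blurred = fftconvolve(padded, kern, mode="same")[r:-r, r:-r]
    ny, nx = blurred.shape
    ny_c, nx_c = ny // factor, nx // factor
    return blurred[: ny_c * factor, : nx_c * factor].reshape(
        ny_c, factor, nx_c, factor
    ).mean(axis=(1, 3))


def sort_percentile(values: np.ndarray, q: float) -> float:
    """Percentile by sorting and linear interpolation between order
    statistics (the 'linear' convention, implemented from scratch)."""
    v = np.sort(np.asarray(values, float).ravel())
    if len(v) == 1:
        return float(v[0])
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
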