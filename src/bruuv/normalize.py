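"""Signal transformations shared by the callers.

Four steps: quantile normalization across TSS windows (puts every window on a
common reference distribution so one emission model is meaningful across
genes), a gamma-equivalent z-score (probability-integral transform through a
method-of-moments gamma fit, mapped to standard-normal quantiles), scaling of
a mock/UV sample pair to a common sequencing depth, and wavelet denoising of
binned coverage.

The gamma-equivalent z-score is implemented as: fit Gamma(k, theta) by
moments to the (pseudocounted) values, evaluate its CDF, clamp to
[1e-6, 1 - 1e-6], and return the standard-normal quantile.  Because the
moment fit rescales with the data, the transform is invariant (up to
clamping) under uniform positive scaling of the input.  A plain z-score mode
is available where a rank-free alternative is wanted.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import special

from .annotations_io import BinnedTrack


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows to their per-rank mean reference.

    Every output row's multiset of values equals the reference distribution
    (the mean across rows of row-sorted values); within-row order is kept and
    tied input values receive the mean of the reference values they span.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    reference = np.sort(m, axis=1).mean(axis=0)
    out = np.empty_like(m)
    for i, row in enumerate(m):
        order = np.argsort(row, kind="stable")
        assigned = np.empty_like(row)
        assigned[order] = reference
        # ties: average the reference values spanned by each tied group
        sorted_vals = row[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        groups = np.split(order, boundaries)
        for g in groups:
            if len(g) > 1:
                assigned[g] = assigned[g].mean()
        out[i] = assigned
    return out


def fit_gamma_moments(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments gamma fit: k = m^2/v, theta = v/m."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    var = v.var(ddof=1)
    if var <= 0 or m <= 0:
        raise ValueError("degenerate window: non-positive mean or variance")
    return m * m / var, var / m


def gamma_z_transform(values: np.ndarray, mode: str = "gamma_z") -> np.ndarray:
    """Map non-negative values to z-scores via a fitted gamma CDF.

    A pseudocount (half the smallest positive value; 1e-6 if none exists)
    makes zeros admissible for the gamma fit.  The CDF is clamped to
    [1e-6, 1 - 1e-6] before taking standard-normal quantiles, so outputs lie
    within about +-4.75.  Strictly increasing in the input (up to clamping).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if mode == "plain_z":
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError("degenerate window: zero variance")
        return (x - x.mean()) / sd
    if mode != "gamma_z":
        raise ValueError(f"unknown mode {mode!r}")
    positive = x[x > 0]
    eps = positive.min() / 2.0 if positive.size else 1e-6
    shifted = x + eps
    if shifted.var(ddof=1) <= 0:
        raise ValueError("degenerate window: zero variance")
    k, theta = fit_gamma_moments(shifted)
    cdf = special.gammainc(k, shifted / theta)
    cdf = np.clip(cdf, 1e-6, 1.0 - 1e-6)
    return special.ndtri(cdf)


def scale_pair_to_common_depth(
    mock: BinnedTrack, uv: BinnedTrack
) -> tuple[BinnedTrack, BinnedTrack, float]:
    """Scale both tracks to the smaller library total.

    Returns the scaled pair and the baseline probability p0 that a read in a
    bin came from the UV sample, which is 0.5 by construction after scaling.
    """
    if mock.total_reads <= 0 or uv.total_reads <= 0:
        raise ValueError("both tracks need positive total_reads")
    target = min(mock.total_reads, uv.total_reads)
    mock_s = mock.scaled(target / mock.total_reads)
    uv_s = uv.scaled(target / uv.total_reads)
    p0 = uv_s.total_reads / (uv_s.total_reads + mock_s.total_reads)
    return mock_s, uv_s, p0


def wavelet_smooth(
    series: np.ndarray,
    wavelet: str = "db4",
    level: int | None = None,
    mode: str = "soft",
) -> np.ndarray:
    """Universal-threshold wavelet denoising, clamped at zero.

    Decomposes with the named wavelet (symmetric boundary), soft-thresholds
    the detail coefficients at sigma * sqrt(2 ln n) with sigma estimated from
    the median absolute deviation of the finest-level details, reconstructs,
    and clips negatives (coverage cannot be negative).  Length preserved.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(x.size, w.dec_len)
    if level is not None and level > max_level:
        raise ValueError(f"level {level} exceeds maximum decomposition depth {max_level}")
    lvl = level if level is not None else max_level
    if lvl < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, w, level=lvl, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(x.size))
    if thresh > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thresh, mode=mode) for c in coeffs[1:]
        ]
    rec = pywt.waverec(coeffs, w, mode="symmetric")[: x.size]
    return np.clip(rec, 0.0, None)


def smooth_track(track: BinnedTrack, wavelet: str = "db4") -> BinnedTrack:
    """Apply wavelet_smooth per chromosome (chromosomes of length 1 pass through)."""
    data = {
        c: (wavelet_smooth(v, wavelet=wavelet) if v.size >= 2 else v.copy())
        for c, v in track.data.items()
    }
    return BinnedTrack(track.bin_width, data, track.total_reads, track.strand_mode)
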