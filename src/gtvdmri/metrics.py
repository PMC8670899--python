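"""Full-reference image quality metrics: PSNR, SSIM, RMSE maps, residual maps.

Conventions (MRI intensities have no fixed dynamic range, so these must be
stated): PSNR uses the maximum of the reference image as the peak; SSIM uses
the standard windowed computation with stabilizing constants derived from the
joint dynamic range of the two inputs, which keeps the metric symmetric. For
4-D data SSIM is computed volume-by-volume on the 3-D images and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "rmse_map", "residual_map", "metric_report"]


@dataclass(frozen=True)
class MetricReport:
    """Scalar PSNR/SSIM plus the per-volume breakdown for 4-D inputs."""

    psnr: float
    ssim: float
    psnr_per_volume: np.ndarray
    ssim_per_volume: np.ndarray


def _check_shapes(ref: np.ndarray, test: np.ndarray) -> tuple:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio 20 log10(peak / rmse), peak = max(ref), in dB.

    Identical images yield +inf (an explicit sentinel, so sweeps stay total).
    """
    ref, test = _check_shapes(ref, test)
    rmse = float(np.sqrt(np.mean((ref - test) ** 2)))
    if rmse == 0:
        return np.inf
    peak = float(ref.max())
    return float(20.0 * np.log10(peak / rmse))


def _ssim_3d(a: np.ndarray, b: np.ndarray) -> float:
    rng = max(a.max(), b.max()) - min(a.min(), b.min())
    if rng == 0:
        return 1.0  # both constant and equal
    return float(structural_similarity(a, b, data_range=rng))


def ssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity; symmetric in its arguments.

    3-D inputs use one windowed pass; 4-D inputs are scored volume-by-volume
    and averaged.
    """
    ref, test = _check_shapes(ref, test)
    if ref.ndim == 3:
        return _ssim_3d(ref, test)
    if ref.ndim == 4:
        vals = [_ssim_3d(ref[..., j], test[..., j]) for j in range(ref.shape[3])]
        return float(np.mean(vals))
    raise ValueError("ssim expects a 3-D or 4-D array")


def rmse_map(ref: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Per-voxel root mean square error across the volume (4th) dimension."""
    ref, test = _check_shapes(ref, test)
    if ref.ndim != 4:
        raise ValueError("rmse_map expects 4-D arrays")
    return np.sqrt(np.mean((ref - test) ** 2, axis=3))


def residual_map(noisy: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """Elementwise noisy - denoised; structure here means structure was removed."""
    noisy, denoised = _check_shapes(noisy, denoised)
    return noisy - denoised


def metric_report(ref: np.ndarray, test: np.ndarray) -> MetricReport:
    """PSNR and SSIM overall plus per volume for 4-D reference/test pairs."""
    ref, test = _check_shapes(ref, test)
    if ref.ndim != 4:
        raise ValueError("metric_report expects 4-D arrays")
    p = np.array([psnr(ref[..., j], test[..., j]) for j in range(ref.shape[3])])
    s = np.array([_ssim_3d(ref[..., j], test[..., j]) for j in range(ref.shape[3])])
    return MetricReport(
        psnr=psnr(ref, test),
        ssim=float(np.mean(s)),
        psnr_per_volume=p,
        ssim_per_volume=s,
    )
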