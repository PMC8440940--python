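"""Image-quality and overlap metrics: SSIM, interpolation error, Dice.

SSIM uses the canonical published settings (11x11 Gaussian window with
sigma = 1.5, K1 = 0.01, K2 = 0.03) and is aggregated as the mean of the
local SSIM map over a region of interest, so scores reflect the cardiac
chamber rather than background.  Interpolation error (IE) is the root mean
square intensity difference over the ROI, on the nominal 0-255 scale.  Dice
is the standard 2TP / (2TP + FP + FN) overlap of two binary masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .core import ChamberMask, ImageSeries
from .synth import SynthesisParams, _synthesize_pair


@dataclass
class MetricResult:
    """Per-frame metric values and their mean over an evaluation."""

    name: str
    values: np.ndarray
    roi: ChamberMask | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _check_pair(a: np.ndarray, b: np.ndarray, roi: ChamberMask) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if a.shape != roi.pixels.shape:
        raise ValueError("ROI must match the frame shape")
    roi.require_nonempty()
    return a, b


def ssim(a: np.ndarray, b: np.ndarray, roi: ChamberMask,
         data_range: float = 255.0) -> float:
    """Mean of the local SSIM map over the ROI pixels."""
    a, b = _check_pair(a, b, roi)
    _, ssim_map = structural_similarity(
        a, b, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
        data_range=data_range, full=True,
    )
    return float(ssim_map[roi.pixels].mean())


def interpolation_error(predicted: np.ndarray, truth: np.ndarray, roi: ChamberMask) -> float:
    """Root-mean-square intensity difference over the ROI."""
    predicted, truth = _check_pair(predicted, truth, roi)
    diff = predicted[roi.pixels] - truth[roi.pixels]
    return float(np.sqrt(np.mean(diff**2)))


def dice(a: ChamberMask, b: ChamberMask) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN); 1 if both empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("masks must share a shape")
    tp = int((a.pixels & b.pixels).sum())
    fp = int((~a.pixels & b.pixels).sum())
    fn = int((a.pixels & ~b.pixels).sum())
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def leave_out_evaluation(series: ImageSeries, k_skip: int, method: str,
                         roi: ChamberMask,
                         params: SynthesisParams | None = None) -> tuple[MetricResult, MetricResult]:
    """Leave-some-out reconstruction quality of a synthesis method.

    For every window of ``k_skip`` consecutive interior frames, those frames
    are dropped and resynthesized from the two flanking frames (at fractions
    j / (k_skip + 1)), then scored against the held-out originals.  Returns
    (IE, SSIM) results with one value per dropped frame.
    """
    if k_skip < 1:
        raise ValueError("k_skip must be >= 1")
    if len(series) <= k_skip + 1:
        raise ValueError("series too short for this k_skip")
    params = params or SynthesisParams(method=method)
    if params.method != method:
        params = SynthesisParams(factor=params.factor, method=method, hs=params.hs)
    data_range = series.intensity_range[1] - series.intensity_range[0]
    ts = np.arange(1, k_skip + 1) / (k_skip + 1)
    ie_vals: list[float] = []
    ssim_vals: list[float] = []
    for start in range(0, len(series) - k_skip - 1):
        i0 = series.frames[start]
        i1 = series.frames[start + k_skip + 1]
        predictions = _synthesize_pair(i0, i1, ts, params)
        for j, pred in enumerate(predictions):
            truth = series.frames[start + 1 + j]
            ie_vals.append(interpolation_error(pred, truth, roi))
            ssim_vals.append(ssim(pred, truth, roi, data_range=data_range))
    return (
        MetricResult(name=f"IE[{method}, skip={k_skip}]", values=np.array(ie_vals), roi=roi),
        MetricResult(name=f"SSIM[{method}, skip={k_skip}]", values=np.array(ssim_vals), roi=roi),
    )
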