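"""Forecast evaluation: RMSE, MAE, and dynamic time warping.

RMSE and MAE are the usual pointwise deviations. DTW is the minimum
cumulative absolute difference over monotone alignments of the two sequences
(steps down, right, or diagonal on the cost matrix), computed by dynamic
programming with no warping-window constraint. Metrics are reported on the
normalized scale per window and averaged across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ForecastEval", "rmse", "mae", "dtw", "evaluate_forecast"]


@dataclass(frozen=True)
class ForecastEval:
    rmse: float
    mae: float
    dtw: float
    n_points: int


def _pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean square error sqrt(mean((y - y_hat)^2))."""
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    """Mean absolute error mean(|y - y_hat|)."""
    y, y_hat = _pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def dtw(y, y_hat) -> float:
    """Dynamic time warping distance with |.| local cost.

    Minimum over monotone warping paths from (0, 0) to (T1-1, T2-1) of the
    summed element-wise absolute differences along the path.
    """
    a = np.asarray(y, dtype=np.float64).ravel()
    b = np.asarray(y_hat, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        ci = cost[i - 1]
        row = acc[i]
        prev = acc[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[n, m])


def evaluate_forecast(y, y_hat) -> ForecastEval:
    """Bundle RMSE, MAE and DTW for one pair of sequences."""
    y, y_hat = _pair(y, y_hat)
    return ForecastEval(rmse(y, y_hat), mae(y, y_hat), dtw(y, y_hat),
                        int(y.size))
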