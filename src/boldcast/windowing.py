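"""Max-min normalization, sliding windows, and chronological splits.

A forecasting task on a ``m x T`` block is cut into windows of length
``L = D + H``: the first D timepoints of every region form the input, the
following H timepoints of the target region form the output. Windows are
ordered by start index; the train/validation/test split is chronological so
that the test windows are strictly the latest — random window assignment
would leak future values into training and is available only behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationParams",
    "WindowSpec",
    "WindowSet",
    "normalize",
    "denormalize",
    "make_windows",
    "split_windows",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Range of the original series: y_bar = (y - y_min)/(y_max - y_min)."""

    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise ValueError("y_max must exceed y_min")


def normalize(y: np.ndarray,
              params: NormalizationParams | None = None
              ) -> tuple[np.ndarray, NormalizationParams]:
    """Max-min normalize to [0, 1]; returns the params for inversion.

    When ``params`` is given (e.g. fitted on the training portion) it is
    applied as-is and outputs may leave [0, 1].
    """
    y = np.asarray(y, dtype=np.float64)
    if params is None:
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi == lo:
            raise ValueError("degenerate range: series is constant")
        params = NormalizationParams(lo, hi)
    return (y - params.y_min) / (params.y_max - params.y_min), params


def denormalize(y_bar: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert max-min normalization: y = y_bar * (y_max - y_min) + y_min."""
    return np.asarray(y_bar, dtype=np.float64) * (params.y_max - params.y_min) \
        + params.y_min


@dataclass(frozen=True)
class WindowSpec:
    """History length D, horizon H, and stride of the sliding window."""

    D: int
    H: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.D < 1 or self.H < 1 or self.stride < 1:
            raise ValueError("D, H and stride must all be >= 1")

    @property
    def L(self) -> int:
        return self.D + self.H


@dataclass
class WindowSet:
    """Sliding windows of one (subject, target region, IMF) task.

    inputs : (n_windows, m, D) — all regions' history.
    targets : (n_windows, H) — the target region's future.
    last_step_index : per-window index N of the last historical timepoint.
    """

    inputs: np.ndarray
    targets: np.ndarray
    target_region_index: int
    last_step_index: np.ndarray
    spec: WindowSpec

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_windows(series_block: np.ndarray, target_region_index: int,
                 spec: WindowSpec) -> WindowSet:
    """Cut a ``m x T`` block into a WindowSet for one target region."""
    block = np.asarray(series_block, dtype=np.float64)
    if block.ndim != 2:
        raise ValueError("series_block must be m x T")
    m, T = block.shape
    if not 0 <= target_region_index < m:
        raise ValueError(f"target_region_index {target_region_index} out of "
                         f"range for m={m}")
    L = spec.L
    if T < L:
        raise ValueError(
            f"series too short: T={T} < D+H={L} (need at least {L} timepoints)")
    n_windows = (T - L) // spec.stride + 1
    starts = np.arange(n_windows) * spec.stride
    inputs = np.stack([block[:, s: s + spec.D] for s in starts])
    targets = np.stack(
        [block[target_region_index, s + spec.D: s + L] for s in starts])
    return WindowSet(inputs, targets, target_region_index,
                     starts + spec.D - 1, spec)


def split_windows(ws: WindowSet, fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  shuffle: bool = False, seed: int = 0
                  ) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Split into train/validation/test, chronological by default (7:2:1)."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ws)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n} windows by {fractions} leaves an empty part")
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)

    def take(idx: np.ndarray) -> WindowSet:
        return WindowSet(ws.inputs[idx], ws.targets[idx],
                         ws.target_region_index, ws.last_step_index[idx], ws.spec)

    return (take(order[:n_train]),
            take(order[n_train: n_train + n_val]),
            take(order[n_train + n_val:]))
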