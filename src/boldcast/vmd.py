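"""Variational mode decomposition (VMD) of 1-D signals.

VMD decomposes a signal x(t) into K band-limited intrinsic mode functions
(IMFs) u_k with center frequencies omega_k by minimizing the summed bandwidth
of the analytic, baseband-shifted modes subject to sum_k u_k = x. The saddle
point of the augmented Lagrangian is found by ADMM: each sweep updates every
mode spectrum by Wiener filtering around its current center frequency,

    u_k(w) <- (x(w) - sum_{i != k} u_i(w) + lambda(w)/2) / (1 + alpha (w - w_k)^2),

re-centers w_k at the spectral center of mass of |u_k|^2 over positive
frequencies, and (when tau > 0) ascends the Lagrange multiplier lambda by
tau * (sum_k u_k - x). Iteration stops when the summed relative change of the
mode spectra drops below ``tol``.

Center frequencies are stored in cycles/sample; multiply by 1/TR only at
reporting boundaries to obtain Hz. The low-frequency BOLD pipeline keeps the
modes below 0.05 Hz (typically IMF 1 and IMF 2 of K=4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Cohort

__all__ = [
    "VmdConfig",
    "VmdResult",
    "vmd_decompose",
    "reconstruct",
    "select_low_modes",
    "decompose_cohort",
    "CohortDecomposition",
]


@dataclass
class VmdConfig:
    """Decomposition settings.

    K : number of modes (the BOLD pipeline default is 4).
    alpha : quadratic bandwidth penalty; larger -> narrower modes.
    tau : dual-ascent step for the reconstruction multiplier; 0 relaxes the
        exact-reconstruction constraint (more robust to noise).
    tol : relative convergence tolerance on the summed mode change.
    init_mode : 'uniform' spaces initial center frequencies over [0, 0.5),
        'zero' starts all at 0, 'random' draws them from a seeded RNG.
    """

    K: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.init_mode not in {"uniform", "zero", "random"}:
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class VmdResult:
    """Modes (K x T, time domain) sorted by non-decreasing center frequency."""

    modes: np.ndarray
    center_freqs: np.ndarray  # cycles/sample, in [0, 0.5]
    n_iter: int
    converged: bool

    def center_freqs_hz(self, tr_seconds: float) -> np.ndarray:
        return self.center_freqs / tr_seconds


def vmd_decompose(x: np.ndarray, config: VmdConfig) -> VmdResult:
    """Decompose a 1-D series into ``config.K`` modes.

    The series is mirror-extended by half its length at each end before the
    frequency-domain iteration and trimmed afterwards, which suppresses edge
    ringing of the Wiener filters.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    T0 = x.size
    if T0 < 8:
        raise ValueError(f"series too short for VMD: T={T0} < 8")

    # mirror extension by T0//2 on each side
    ell = T0 // 2
    ext = np.concatenate([x[:ell][::-1], x, x[-ell:][::-1]])
    T = ext.size

    freqs = np.arange(T) / T - 0.5 - 1.0 / T  # cycles/sample, fftshift order
    f_hat = np.fft.fftshift(np.fft.fft(ext))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0.0

    K = config.K
    if config.init_mode == "uniform":
        omega = 0.5 * np.arange(K) / K
    elif config.init_mode == "zero":
        omega = np.zeros(K)
    else:
        rng = np.random.default_rng(config.seed)
        omega = np.sort(rng.uniform(0.0, 0.5, size=K))

    u_hat = np.zeros((K, T), dtype=np.complex128)
    lam_hat = np.zeros(T, dtype=np.complex128)
    half = T // 2
    pos_freqs = freqs[half:]

    n_iter = 0
    converged = False
    eps = np.finfo(np.float64).eps
    for n_iter in range(1, config.max_iter + 1):
        u_prev = u_hat.copy()
        total = u_hat.sum(axis=0)
        for k in range(K):
            others = total - u_hat[k]
            new_k = (f_hat_plus - others - lam_hat / 2.0) / (
                1.0 + config.alpha * (freqs - omega[k]) ** 2)
            total = others + new_k
            u_hat[k] = new_k
            power = np.abs(u_hat[k, half:]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float((pos_freqs * power).sum() / denom)
        if config.tau > 0:
            lam_hat = lam_hat + config.tau * (total - f_hat_plus)
        diff = np.abs(u_hat - u_prev) ** 2
        norm = np.abs(u_prev) ** 2
        u_diff = float((diff.sum(axis=1) / (norm.sum(axis=1) + eps)).sum())
        if u_diff < config.tol:
            converged = True
            break

    # back to time domain: hermitian-complete the positive-half spectra
    u_full = np.zeros((K, T), dtype=np.complex128)
    u_full[:, half:] = u_hat[:, half:]
    u_full[:, 1: half + 1] = np.conj(u_hat[:, -1: half - 1: -1])
    u_full[:, 0] = np.conj(u_full[:, -1])
    u_time = np.real(np.fft.ifft(np.fft.ifftshift(u_full, axes=1), axis=1))
    modes = u_time[:, ell: ell + T0]

    order = np.argsort(omega, kind="stable")
    return VmdResult(
        modes=np.ascontiguousarray(modes[order]),
        center_freqs=np.clip(omega[order], 0.0, 0.5),
        n_iter=n_iter,
        converged=converged,
    )


def reconstruct(result: VmdResult) -> np.ndarray:
    """Sum of all modes (the reconstruction sum_k u_k ~ x)."""
    return result.modes.sum(axis=0)


def select_low_modes(result: VmdResult, tr_seconds: float,
                     f_max_hz: float) -> list[int]:
    """Indices of modes with center frequency below ``f_max_hz`` (ascending)."""
    if f_max_hz <= 0:
        raise ValueError("f_max_hz must be positive")
    hz = result.center_freqs_hz(tr_seconds)
    return [int(i) for i in np.nonzero(hz < f_max_hz)[0]]


@dataclass
class CohortDecomposition:
    """Per-(subject, region) VMD results with the retained low-band modes."""

    results: dict[str, dict[str, VmdResult]]
    selected: dict[str, dict[str, list[int]]]
    f_max_hz: float
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)

    def selected_modes(self, subject_id: str, region: str) -> np.ndarray:
        """The retained modes of one region, shape (n_selected, T)."""
        res = self.results[subject_id][region]
        idx = self.selected[subject_id][region]
        return res.modes[idx]

    def imf_block(self, subject_id: str, imf_index: int) -> np.ndarray:
        """m x T matrix of one selected-IMF rank across all regions.

        ``imf_index`` indexes into each region's selected-mode list (0 is the
        lowest retained band). Raises if any region retained fewer modes.
        """
        rows = []
        for region in self.region_labels:
            idx = self.selected[subject_id][region]
            if imf_index >= len(idx):
                raise ValueError(
                    f"region {region!r} of subject {subject_id!r} has only "
                    f"{len(idx)} selected modes (asked for index {imf_index})")
            rows.append(self.results[subject_id][region].modes[idx[imf_index]])
        return np.vstack(rows)

    def n_selected(self, subject_id: str) -> int:
        return min(len(self.selected[subject_id][r]) for r in self.region_labels)


def decompose_cohort(cohort: Cohort, config: VmdConfig,
                     f_max_hz: float = 0.05) -> CohortDecomposition:
    """Run VMD on every region series of every subject; keep low modes."""
    results: dict[str, dict[str, VmdResult]] = {}
    selected: dict[str, dict[str, list[int]]] = {}
    for subj in cohort:
        results[subj.subject_id] = {}
        selected[subj.subject_id] = {}
        for r, label in enumerate(subj.region_labels):
            try:
                res = vmd_decompose(subj.data[r], config)
            except ValueError as e:
                raise ValueError(
                    f"VMD failed for subject {subj.subject_id!r}, "
                    f"region {label!r}: {e}") from e
            results[subj.subject_id][label] = res
            selected[subj.subject_id][label] = select_low_modes(
                res, subj.tr_seconds, f_max_hz)
    return CohortDecomposition(results, selected, f_max_hz,
                               cohort.tr_seconds, list(cohort.region_labels))
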