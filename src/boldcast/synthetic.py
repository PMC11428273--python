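"""Synthetic cohorts with the statistical structure of resting-state BOLD.

Each region's signal is a sum of band-limited oscillatory components —
frequency and phase drawn per (subject, region, component) from configured
bands — mixed across regions through a coupling matrix (so a target region
is partially predictable from the auxiliary regions, as functional
connectivity implies) plus AR(1) noise emulating the temporal autocorrelation
of BOLD. The default bands sit in the low-frequency ranges where the
functional connectome is stable (roughly 0.008-0.016 Hz and 0.03-0.05 Hz),
so the < 0.05 Hz mode-selection rule of the pipeline retains both.

Per-subject frequency/phase jitter creates the between-subject variance that
a meaningful ICC analysis requires. The whole cohort is a pure function of
(config, seed). What the generator does *not* emulate: hemodynamic
nonlinearity, scanner drift, motion or physiological artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, RoiTimeSeries

__all__ = [
    "SyntheticConfig",
    "coupled_mixing",
    "generate_subject",
    "generate_cohort",
    "ground_truth_components",
]


def coupled_mixing(m: int, strength: float = 0.4) -> np.ndarray:
    """Identity plus uniform cross-region coupling of the given strength.

    Every region receives ``strength`` times the average of the other
    regions, making each partially predictable from the rest.
    """
    c = np.eye(m)
    if m > 1:
        off = strength / (m - 1)
        c += off * (np.ones((m, m)) - np.eye(m))
    return c


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation settings.

    band_freqs_hz : per-component (low, high) frequency bands in Hz.
    amplitudes : per-component oscillation amplitudes.
    coupling : m x m mixing matrix applied to the stacked region signals;
        None means ``coupled_mixing(m, 0.4)``.
    noise_sigma : innovation s.d. of the AR(1) noise.
    ar_coeff : AR(1) coefficient in [0, 1).
    """

    n_subjects: int = 10
    m: int = 6
    T: int = 600
    tr_seconds: float = 0.72
    band_freqs_hz: tuple[tuple[float, float], ...] = ((0.008, 0.016),
                                                      (0.03, 0.05))
    amplitudes: tuple[float, ...] = (1.0, 0.6)
    coupling: np.ndarray | None = None
    noise_sigma: float = 0.2
    ar_coeff: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.m < 1 or self.T < 2:
            raise ValueError("n_subjects, m >= 1 and T >= 2 required")
        if len(self.band_freqs_hz) != len(self.amplitudes):
            raise ValueError("one amplitude per frequency band required")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        for lo, hi in self.band_freqs_hz:
            if not (0 < lo < hi):
                raise ValueError(f"invalid frequency band ({lo}, {hi})")
            if hi >= nyquist:
                raise ValueError(
                    f"band edge {hi} Hz >= Nyquist {nyquist:.4f} Hz")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")

    def mixing(self) -> np.ndarray:
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=np.float64)
            if c.shape != (self.m, self.m):
                raise ValueError("coupling must be m x m")
            return c
        return coupled_mixing(self.m, 0.4)


def _subject_rng(config: SyntheticConfig, subject_index: int
                 ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, subject_index)))


def ground_truth_components(config: SyntheticConfig, subject_index: int
                            ) -> np.ndarray:
    """Noiseless mixed band components, shape (n_components, m, T).

    Summing over the first axis and adding the same-seed AR(1) noise
    reproduces :func:`generate_subject` exactly.
    """
    rng = _subject_rng(config, subject_index)
    t = np.arange(config.T) * config.tr_seconds
    mix = config.mixing()
    comps = np.zeros((len(config.band_freqs_hz), config.m, config.T))
    for c, ((lo, hi), amp) in enumerate(zip(config.band_freqs_hz,
                                            config.amplitudes)):
        freqs = rng.uniform(lo, hi, size=config.m)
        phases = rng.uniform(0, 2 * np.pi, size=config.m)
        raw = amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                           + phases[:, None])
        comps[c] = mix @ raw
    return comps


def _ar1_noise(rng: np.random.Generator, m: int, T: int, sigma: float,
               rho: float) -> np.ndarray:
    innov = rng.standard_normal((m, T)) * sigma
    if rho == 0 or sigma == 0:
        return innov if sigma > 0 else np.zeros((m, T))
    noise = np.empty((m, T))
    noise[:, 0] = innov[:, 0] / np.sqrt(1 - rho ** 2)  # stationary start
    for t in range(1, T):
        noise[:, t] = rho * noise[:, t - 1] + innov[:, t]
    return noise


def generate_subject(config: SyntheticConfig, subject_index: int
                     ) -> RoiTimeSeries:
    """One subject: mixed band components + AR(1) noise; seeded."""
    comps = ground_truth_components(config, subject_index)
    # independent child stream for the noise, so components and noise are
    # each reproducible on their own
    noise_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, subject_index, 1)))
    noise = _ar1_noise(noise_rng, config.m, config.T, config.noise_sigma,
                       config.ar_coeff)
    labels = [f"ROI{i + 1}" for i in range(config.m)]
    return RoiTimeSeries(f"sub-{subject_index:03d}", labels,
                         comps.sum(axis=0) + noise, config.tr_seconds)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """n_subjects independent subjects with shared labels and TR."""
    return Cohort([generate_subject(config, i)
                   for i in range(config.n_subjects)])
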