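"""Run configuration: nested, validated, with the published defaults.

Defaults bundle the printed training recipe: K=4 modes with the < 0.05 Hz
selection rule, loss weights (50, 3, 1, 1), initial learning rate 0.01 with
inverse time decay, batch size 128, hidden/fully connected width 96, and a
chronological 7:2:1 train/validation/test split. Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "load_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VmdSection(_Section):
    K: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init_mode: str = "uniform"
    f_max_hz: float = 0.05


class WindowSection(_Section):
    D: int = 24
    H: int = 12
    stride: int = 1


class SplitSection(_Section):
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    shuffle: bool = False


class ModelSection(_Section):
    gru_hidden: int = 96
    fc_nodes: int = 96
    cbam_reduction: int = 8
    spatial_kernel: int = 7
    disc_gru_hidden: int = 96


class LossSection(_Section):
    lambda_ae: float = 50.0
    lambda_t: float = 3.0
    lambda_dis: float = 1.0
    lambda_g: float = 1.0
    trend_epsilon: float = 0.01


class TrainSection(_Section):
    lr_init: float = 0.01
    decay_rate: float = 1.0
    decay_steps: int = 200
    batch_size: int = 128
    supervised_epochs: int = 50
    joint_epochs: int = 50
    d_steps_per_g_step: int = 1
    grad_clip: float | None = 5.0
    early_stop_patience: int = 0


class SimulateSection(_Section):
    n_subjects: int = 2
    m: int = 4
    T: int = 300
    tr_seconds: float = 0.72
    band_freqs_hz: tuple[tuple[float, float], ...] = ((0.008, 0.016),
                                                      (0.03, 0.05))
    amplitudes: tuple[float, ...] = (1.0, 0.6)
    coupling_strength: float = 0.4
    noise_sigma: float = 0.2
    ar_coeff: float = 0.3


class PipelineSection(_Section):
    extension_length: int = 24
    target_regions: list[str] | None = None


class RunConfig(_Section):
    """Top-level configuration for the end-to-end pipeline."""

    vmd: VmdSection = VmdSection()
    window: WindowSection = WindowSection()
    split: SplitSection = SplitSection()
    model: ModelSection = ModelSection()
    loss: LossSection = LossSection()
    train: TrainSection = TrainSection()
    simulate: SimulateSection = SimulateSection()
    pipeline: PipelineSection = PipelineSection()
    seed: int = 0


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unknown keys raise with the offending key named."""
    data: dict = {}
    if path is not None:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
    if overrides:
        for key, val in overrides.items():
            section, _, leaf = key.partition(".")
            data.setdefault(section, {})[leaf] = val
    return RunConfig(**data)
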