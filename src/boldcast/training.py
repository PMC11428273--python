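"""Two-phase adversarial training, prediction, and series prolongation.

Training of one (subject, target region, IMF) task runs in two phases:

1. a supervised phase minimizing the supervised loss
   ``L_s = lambda_ae L_ae + lambda_t L_t + lambda_dis L_dis`` with Adam;
2. a joint phase alternating discriminator steps (cross-entropy on real vs
   generated horizon windows) with generator steps on the full objective
   ``L_G = L_s + lambda_g L_g``.

The learning rate follows inverse time decay,
``lr(step) = lr_init / (1 + decay_rate * step / decay_steps)``, and the
parameters with the best validation RMSE are retained. The sign function in
the trend loss has zero gradient almost everywhere, so optimization uses the
smooth surrogate ``tanh(delta / eps)`` for the predicted increments while the
reported trend loss keeps the exact sign form.

Series prolongation feeds each trained model the last D observed points of
its normalized IMF block, predicts H steps for every region, autoregressively
rolls forward until the requested extension is covered, denormalizes, sums
the per-IMF forecasts and concatenates them to the original series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import RoiTimeSeries
from .losses import LossWeights
from .model import (DiscriminatorSpec, GeneratorSpec, ModelState,
                    discriminator_core, generator_core, init_model)
from .vmd import CohortDecomposition
from .windowing import (NormalizationParams, WindowSet, WindowSpec,
                        make_windows, normalize, split_windows)

__all__ = [
    "TrainConfig",
    "fit",
    "predict",
    "persistence_forecast",
    "TaskModel",
    "prepare_task",
    "train_subject_models",
    "extend_series",
    "save_task",
    "load_task",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, inverse-time-decay learning rate)."""

    lr_init: float = 0.01
    decay_rate: float = 1.0
    decay_steps: int = 200
    batch_size: int = 128
    supervised_epochs: int = 50
    joint_epochs: int = 50
    d_steps_per_g_step: int = 1
    grad_clip: float | None = 5.0
    seed: int = 0
    early_stop_patience: int = 0
    trend_epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.supervised_epochs < 0 or self.joint_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr(self, step: int) -> float:
        return self.lr_init / (1.0 + self.decay_rate * step / self.decay_steps)


class _Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place)."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float,
             clip: float | None) -> None:
        self.t += 1
        if clip is not None:
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if gnorm > clip:
                grads = {k: g * (clip / gnorm) for k, g in grads.items()}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---- differentiable loss terms -------------------------------------------

def _t_ae(y: Tensor, y_hat: Tensor) -> Tensor:
    diff = y - y_hat
    return (((diff * diff).sum(axis=1) + 1e-12) ** 0.5).mean()


def _t_trend(y_true: np.ndarray, y_hat: Tensor, anchor: np.ndarray,
             eps: float) -> Tensor:
    """Soft trend loss: |tanh(pred increment / eps) - sign(true increment)|."""
    y_ext = np.concatenate([anchor[:, None], y_true], axis=1)
    s_true = np.sign(np.diff(y_ext, axis=1))
    yh_ext = ad.concat([Tensor(anchor[:, None]), y_hat], axis=1)
    d_pred = yh_ext[:, 1:] - yh_ext[:, :-1]
    return (ad.tanh(d_pred * (1.0 / eps)) - Tensor(s_true)).abs().mean()


def _t_dist(y: Tensor, y_hat: Tensor) -> Tensor:
    return (y.mean(axis=1) - y_hat.mean(axis=1)).abs().mean()


def _sce_mean(logits: Tensor, target_ones: bool) -> Tensor:
    # mean over windows of the stable sigmoid cross-entropy
    from .autodiff import softplus
    return softplus(-logits).mean() if target_ones else softplus(logits).mean()


def _supervised(y_np: np.ndarray, y_hat: Tensor, anchor: np.ndarray,
                w: LossWeights, eps: float) -> Tensor:
    y = Tensor(y_np)
    return (_t_ae(y, y_hat) * w.lambda_ae
            + _t_trend(y_np, y_hat, anchor, eps) * w.lambda_t
            + _t_dist(y, y_hat) * w.lambda_dis)


def _lift_params(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


def _grads(tensors: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: t.grad for k, t in tensors.items() if t.grad is not None}


def _val_rmse(params: dict[str, np.ndarray], spec: GeneratorSpec,
              ws: WindowSet) -> float:
    y_hat, _ = generator_core(params, spec, Tensor(ws.inputs))
    return float(np.sqrt(np.mean((y_hat.data - ws.targets) ** 2)))


def fit(train: WindowSet, val: WindowSet,
        gen_spec: GeneratorSpec | None = None,
        disc_spec: DiscriminatorSpec | None = None,
        weights: LossWeights = LossWeights(),
        config: TrainConfig = TrainConfig()) -> ModelState:
    """Train generator + discriminator on one windowed task.

    Returns the model state whose parameters achieved the best validation
    RMSE over both phases; ``state.history`` holds one record per epoch.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    m, D = train.inputs.shape[1], train.inputs.shape[2]
    H = train.targets.shape[1]
    if gen_spec is None:
        gen_spec = GeneratorSpec(m=m, D=D, H=H,
                                 target_index=train.target_region_index)
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(H=H, gru_hidden=gen_spec.gru_hidden)
    state = init_model(gen_spec, disc_spec, seed=config.seed)
    if config.supervised_epochs == 0 and config.joint_epochs == 0:
        return state

    rng = np.random.default_rng(config.seed)
    opt_g = _Adam(state.gen_params)
    opt_d = _Adam(state.disc_params)
    anchors_all = train.inputs[:, train.target_region_index, -1]

    best_rmse = np.inf
    best_params = {k: v.copy() for k, v in state.gen_params.items()}
    step = 0
    no_improve = 0

    def run_epoch(phase: str, epoch: int) -> None:
        nonlocal step, best_rmse, best_params, no_improve
        order = rng.permutation(len(train))
        comps = {"ae": [], "trend": [], "dist": [], "adv": [], "d": []}
        for start in range(0, len(order), config.batch_size):
            idx = order[start: start + config.batch_size]
            xb = train.inputs[idx]
            yb = train.targets[idx]
            ab = anchors_all[idx]
            lr = config.lr(step)

            if phase == "joint":
                for _ in range(config.d_steps_per_g_step):
                    gp = {k: Tensor(v) for k, v in state.gen_params.items()}
                    y_fake, _ = generator_core(gp, state.gen_spec, Tensor(xb))
                    dp = _lift_params(state.disc_params)
                    lf = discriminator_core(dp, state.disc_spec,
                                            Tensor(y_fake.data))
                    lr_ = discriminator_core(dp, state.disc_spec, Tensor(yb))
                    d_loss = _sce_mean(lf, False) + _sce_mean(lr_, True)
                    d_loss.backward()
                    if not np.isfinite(d_loss.data):
                        raise RuntimeError(
                            f"discriminator loss diverged (NaN/inf) at "
                            f"phase={phase} epoch={epoch} step={step}")
                    opt_d.step(_grads(dp), lr, config.grad_clip)
                    comps["d"].append(float(d_loss.data))

            gp = _lift_params(state.gen_params)
            y_hat, _ = generator_core(gp, state.gen_spec, Tensor(xb))
            loss = _supervised(yb, y_hat, ab, weights, config.trend_epsilon)
            if phase == "joint":
                dpc = {k: Tensor(v) for k, v in state.disc_params.items()}
                logits = discriminator_core(dpc, state.disc_spec, y_hat)
                adv = _sce_mean(logits, True)
                loss = loss + adv * weights.lambda_g
                comps["adv"].append(float(adv.data))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"generator loss diverged (NaN/inf) at phase={phase} "
                    f"epoch={epoch} step={step}")
            loss.backward()
            opt_g.step(_grads(gp), lr, config.grad_clip)
            step += 1
            comps["ae"].append(float(_t_ae(Tensor(yb), y_hat.detach()).data))
            comps["trend"].append(float(_t_trend(
                yb, y_hat.detach(), ab, config.trend_epsilon).data))
            comps["dist"].append(float(_t_dist(Tensor(yb), y_hat.detach()).data))

        rmse = _val_rmse(state.gen_params, state.gen_spec, val)
        state.history.append({
            "phase": phase, "epoch": epoch, "lr": config.lr(step),
            "val_rmse": rmse,
            **{f"loss_{k}": float(np.mean(v)) for k, v in comps.items() if v},
        })
        if rmse < best_rmse:
            best_rmse = rmse
            best_params = {k: v.copy() for k, v in state.gen_params.items()}
            no_improve = 0
        else:
            no_improve += 1

    stopped = False
    for epoch in range(config.supervised_epochs):
        run_epoch("supervised", epoch)
        if config.early_stop_patience and no_improve >= config.early_stop_patience:
            stopped = True
            break
    if not stopped:
        no_improve = 0
        for epoch in range(config.joint_epochs):
            run_epoch("joint", epoch)
            if (config.early_stop_patience
                    and no_improve >= config.early_stop_patience):
                break

    state.gen_params = best_params
    return state


def predict(state: ModelState, X: np.ndarray) -> np.ndarray:
    """Forecast H steps (normalized scale) for one (m, D) history block."""
    from .model import generator_forward
    return generator_forward(state, X)


def persistence_forecast(X: np.ndarray, target_region_index: int,
                         H: int) -> np.ndarray:
    """Repeat-last-value baseline; X is (m, D) or (batch, m, D)."""
    X = np.asarray(X, dtype=np.float64)
    last = X[..., target_region_index, -1]
    return np.repeat(np.asarray(last)[..., None], H, axis=-1)


# ---------------------------------------------------------------------------
# per-(subject, target region, IMF) task plumbing

@dataclass
class TaskModel:
    """A trained model for one (target region, IMF) task plus its scalers."""

    state: ModelState
    target_region: str
    imf_index: int
    norm_params: list[NormalizationParams]
    region_labels: list[str] = field(default_factory=list)

    @property
    def target_index(self) -> int:
        return self.region_labels.index(self.target_region)


def prepare_task(block: np.ndarray, target_index: int, spec: WindowSpec,
                 fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                 shuffle: bool = False, seed: int = 0,
                 ) -> tuple[WindowSet, WindowSet, WindowSet,
                            list[NormalizationParams]]:
    """Normalize an m x T IMF block and window it into train/val/test.

    Normalization parameters are fitted per region on the first
    ``fractions[0]`` share of timepoints (the training era) and applied to
    the full series, so later splits never leak their range into training.
    """
    block = np.asarray(block, dtype=np.float64)
    m, T = block.shape
    n_train_t = max(int(np.floor(fractions[0] * T)), 2)
    params: list[NormalizationParams] = []
    normed = np.empty_like(block)
    for r in range(m):
        _, p = normalize(block[r, :n_train_t])
        normed[r], _ = normalize(block[r], p)
        params.append(p)
    ws = make_windows(normed, target_index, spec)
    train, val, test = split_windows(ws, fractions, shuffle=shuffle, seed=seed)
    return train, val, test, params


def train_subject_models(decomp: CohortDecomposition, subject_id: str,
                         window_spec: WindowSpec,
                         gen_spec_kw: dict | None = None,
                         weights: LossWeights = LossWeights(),
                         config: TrainConfig = TrainConfig(),
                         fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                         target_regions: list[str] | None = None,
                         ) -> dict[tuple[str, int], TaskModel]:
    """Fit one model per (target region, selected IMF) for one subject."""
    labels = decomp.region_labels
    targets = target_regions if target_regions is not None else labels
    n_imfs = decomp.n_selected(subject_id)
    models: dict[tuple[str, int], TaskModel] = {}
    for imf in range(n_imfs):
        block = decomp.imf_block(subject_id, imf)
        for region in targets:
            tidx = labels.index(region)
            train, val, _, nparams = prepare_task(
                block, tidx, window_spec, fractions, seed=config.seed)
            kw = dict(m=len(labels), D=window_spec.D, H=window_spec.H,
                      target_index=tidx)
            kw.update(gen_spec_kw or {})
            state = fit(train, val, GeneratorSpec(**kw),
                        weights=weights, config=config)
            models[(region, imf)] = TaskModel(state, region, imf,
                                              nparams, list(labels))
    return models


def extend_series(cohort_models: dict[tuple[str, int], TaskModel],
                  subject: RoiTimeSeries, decomp: CohortDecomposition,
                  extension_length: int,
                  history_end: int | None = None) -> RoiTimeSeries:
    """Prolong a subject's series by ``extension_length`` timepoints.

    For every selected IMF, each region's model forecasts its next H points
    from the last D points of the normalized IMF block; forecasts are
    appended and the rollout repeats until the extension is covered. The
    per-IMF forecasts are denormalized, superimposed, and concatenated to
    the original series.

    ``history_end`` truncates the observed history to its first
    ``history_end`` timepoints before rolling out (used to compare a
    predicted segment against the observed continuation).
    """
    if extension_length <= 0:
        raise ValueError("extension_length must be positive")
    labels = subject.region_labels
    n_imfs = decomp.n_selected(subject.subject_id)
    if n_imfs == 0:
        raise ValueError(
            f"no selected IMFs for subject {subject.subject_id!r}")
    for region in labels:
        for imf in range(n_imfs):
            if (region, imf) not in cohort_models:
                raise ValueError(
                    f"missing trained model for region {region!r}, "
                    f"IMF index {imf}")

    extension = np.zeros((len(labels), extension_length))
    for imf in range(n_imfs):
        block = decomp.imf_block(subject.subject_id, imf)
        nparams = {r: cohort_models[(r, imf)].norm_params[i]
                   for i, r in enumerate(labels)}
        normed = np.vstack([normalize(block[i], nparams[r])[0]
                            for i, r in enumerate(labels)])
        if history_end is not None:
            normed = normed[:, :history_end]
        D = cohort_models[(labels[0], imf)].state.gen_spec.D
        H = cohort_models[(labels[0], imf)].state.gen_spec.H
        produced = 0
        rolled = normed
        preds: list[np.ndarray] = []
        while produced < extension_length:
            hist = rolled[:, -D:]
            step_pred = np.vstack([
                predict(cohort_models[(r, imf)].state, hist)
                for r in labels])
            rolled = np.concatenate([rolled, step_pred], axis=1)
            preds.append(step_pred)
            produced += H
        pred_block = np.concatenate(preds, axis=1)[:, :extension_length]
        for i, r in enumerate(labels):
            p = nparams[r]
            extension[i] += pred_block[i] * (p.y_max - p.y_min) + p.y_min
    observed = subject.data if history_end is None \
        else subject.data[:, :history_end]
    data = np.concatenate([observed, extension], axis=1)
    return replace(subject, data=data)


def save_task(task: TaskModel, path) -> None:
    """Write one trained task (model + scalers + metadata) to HDF5."""
    import json

    import h5py

    from .model import save_model
    save_model(task.state, path)
    with h5py.File(path, "a") as f:
        f.attrs["target_region"] = task.target_region
        f.attrs["imf_index"] = task.imf_index
        f.attrs["norm_params"] = json.dumps(
            [[p.y_min, p.y_max] for p in task.norm_params])
        f.attrs["region_labels"] = json.dumps(task.region_labels)


def load_task(path) -> TaskModel:
    import json

    import h5py

    from .model import load_model
    state = load_model(path)
    with h5py.File(path, "r") as f:
        target = str(f.attrs["target_region"])
        imf = int(f.attrs["imf_index"])
        nparams = [NormalizationParams(lo, hi)
                   for lo, hi in json.loads(f.attrs["norm_params"])]
        labels = json.loads(f.attrs["region_labels"])
    return TaskModel(state, target, imf, nparams, labels)
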