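"""Generator and discriminator networks for adversarial BOLD forecasting.

The generator maps a normalized ``batch x m x D`` history block (all m regions
of the network, D timepoints) to a ``batch x H`` forecast of the target
region:

    temporal attention -> spatial attention -> region-mixing conv ->
    2-layer GRU encoder -> fully connected bridge -> 2-layer GRU decoder
    unrolled H steps -> per-step linear head.

Each attention layer is a one-dimensional convolution followed by a
convolutional block attention module (CBAM). The temporal layer's convolution
mixes regions at every timestep (kernel 1 x m) and its CBAM spatial gate
provides per-timestep weights; the spatial layer's convolution mixes time
within every region (kernel D x 1) and its CBAM channel gate is the
per-region attention vector used for physiological interpretation.

The discriminator is a 3-layer GRU over the H-length window with a sigmoid
head scoring realness in (0, 1).

All forward passes run on the package's autodiff tensors so the same code
serves training (with gradients) and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "ModelState",
    "init_model",
    "cbam_attention",
    "temporal_attention_layer",
    "spatial_attention_layer",
    "generator_forward",
    "discriminator_forward",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the generator.

    m, D, H : regions, history length, horizon.
    gru_hidden : GRU state size (default 96, the published network width).
    fc_nodes : width of the fully connected encoder-decoder bridge (default 96).
    cbam_reduction : channel-attention bottleneck ratio; must be < m.
    spatial_kernel : width of the CBAM spatial convolution (odd).
    """

    m: int
    D: int
    H: int
    gru_hidden: int = 96
    gru_layers: int = 2
    fc_nodes: int = 96
    cbam_reduction: int = 8
    spatial_kernel: int = 7
    target_index: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.D < 1 or self.H < 1:
            raise ValueError("m, D, H must be >= 1")
        if self.gru_layers != 2:
            raise ValueError("the generator uses exactly 2 GRU layers")
        if self.cbam_reduction >= self.m:
            raise ValueError(
                f"cbam_reduction={self.cbam_reduction} must be smaller than "
                f"the channel count m={self.m}")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the window-level discriminator (3 GRU layers)."""

    H: int
    gru_hidden: int = 96
    gru_layers: int = 3

    def __post_init__(self) -> None:
        if self.gru_layers != 3:
            raise ValueError("the discriminator uses exactly 3 GRU layers")


@dataclass
class ModelState:
    """Trained (or freshly initialized) parameters plus their specs."""

    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    gen_params: dict[str, np.ndarray]
    disc_params: dict[str, np.ndarray]
    seed: int
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter initialization

def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    lim = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-lim, lim, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _init_gru(p: dict, prefix: str, rng, n_layers: int, in_dim: int, hidden: int):
    for layer in range(n_layers):
        d = in_dim if layer == 0 else hidden
        for gate in ("z", "r", "n"):
            p[f"{prefix}/l{layer}/W{gate}"] = _uniform(rng, d, (d, hidden))
            p[f"{prefix}/l{layer}/U{gate}"] = _orthogonal(rng, hidden)
            p[f"{prefix}/l{layer}/b{gate}"] = np.zeros(hidden)


def _init_cbam(p: dict, prefix: str, rng, channels: int, reduction: int, k: int):
    mid = max(channels // reduction, 1)
    p[f"{prefix}/mlp_w1"] = _uniform(rng, channels, (channels, mid))
    p[f"{prefix}/mlp_b1"] = np.zeros(mid)
    p[f"{prefix}/mlp_w2"] = _uniform(rng, mid, (mid, channels))
    p[f"{prefix}/mlp_b2"] = np.zeros(channels)
    p[f"{prefix}/sconv_w"] = _uniform(rng, 2 * k, (1, 2, k))
    p[f"{prefix}/sconv_b"] = np.zeros(1)


def init_model(gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
               seed: int = 0) -> ModelState:
    """Build seeded initial parameters for both networks."""
    rng = np.random.default_rng(seed)
    g: dict[str, np.ndarray] = {}
    m, D, h = gen_spec.m, gen_spec.D, gen_spec.gru_hidden
    # temporal attention: 1 x m conv (region mixing) + CBAM over (C=m, L=D)
    g["tatt/conv_w"] = _uniform(rng, m, (m, m))
    g["tatt/conv_b"] = np.zeros(m)
    _init_cbam(g, "tatt/cbam", rng, m, gen_spec.cbam_reduction,
               gen_spec.spatial_kernel)
    # spatial attention: D x 1 conv (time mixing) + CBAM
    g["satt/conv_w"] = _uniform(rng, D, (D, D))
    g["satt/conv_b"] = np.zeros(D)
    _init_cbam(g, "satt/cbam", rng, m, gen_spec.cbam_reduction,
               gen_spec.spatial_kernel)
    # encoder head conv (1 x m region mixing) + 2-layer GRU + FC bridge
    g["enc/conv_w"] = _uniform(rng, m, (m, m))
    g["enc/conv_b"] = np.zeros(m)
    _init_gru(g, "enc/gru", rng, 2, m, h)
    g["bridge/w1"] = _uniform(rng, h, (h, gen_spec.fc_nodes))
    g["bridge/b1"] = np.zeros(gen_spec.fc_nodes)
    g["bridge/w2"] = _uniform(rng, gen_spec.fc_nodes, (gen_spec.fc_nodes, h))
    g["bridge/b2"] = np.zeros(h)
    # decoder: 2-layer GRU on scalar input + linear head
    _init_gru(g, "dec/gru", rng, 2, 1, h)
    g["dec/head_w"] = _uniform(rng, h, (h, 1))
    g["dec/head_b"] = np.zeros(1)

    d: dict[str, np.ndarray] = {}
    hd = disc_spec.gru_hidden
    _init_gru(d, "gru", rng, 3, 1, hd)
    d["head_w"] = _uniform(rng, hd, (hd, 1))
    d["head_b"] = np.zeros(1)
    return ModelState(gen_spec, disc_spec, g, d, seed)


# ---------------------------------------------------------------------------
# building blocks (all operate on Tensors)

def _linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return x @ w + b


def _conv1d(x: Tensor, w: Tensor, b: Tensor, k: int) -> Tensor:
    """Same-padded 1-D convolution; x (batch, Cin, L), w (Cout, Cin, k)."""
    batch, cin, L = x.shape
    pad = k // 2
    zeros = Tensor(np.zeros((batch, cin, pad)))
    xp = ad.concat([zeros, x, zeros], axis=2)
    out = None
    for j in range(k):
        xj = xp[:, :, j: j + L].transpose(0, 2, 1)          # (b, L, Cin)
        wj = w[:, :, j].transpose(1, 0)                      # (Cin, Cout)
        term = (xj @ wj).transpose(0, 2, 1)                  # (b, Cout, L)
        out = term if out is None else out + term
    return out + b.reshape(1, -1, 1)


def cbam_attention(F: Tensor, params: dict[str, np.ndarray] | dict[str, Tensor],
                   prefix: str = "", k: int = 7,
                   ) -> tuple[Tensor, Tensor, Tensor]:
    """CBAM over a (batch, C, L) block.

    Channel attention: average- and max-pooled channel descriptors through a
    shared two-layer MLP, summed, sigmoid -> per-channel gate. Spatial
    attention: channel-wise average/max maps concatenated and convolved
    (width ``k``), sigmoid -> per-position gate. Both gates multiply into the
    features.

    Returns (attended block, channel gate (batch, C), spatial gate (batch, L)).
    """
    p = {key: (v if isinstance(v, Tensor) else Tensor(v))
         for key, v in params.items() if key.startswith(prefix)}
    w1, b1 = p[f"{prefix}mlp_w1"], p[f"{prefix}mlp_b1"]
    w2, b2 = p[f"{prefix}mlp_w2"], p[f"{prefix}mlp_b2"]

    avg = F.mean(axis=2)                                     # (b, C)
    mx = F.max(axis=2)
    mlp = (ad.relu(_linear(avg, w1, b1)) @ w2 + b2) \
        + (ad.relu(_linear(mx, w1, b1)) @ w2 + b2)
    ch_gate = ad.sigmoid(mlp)                                # (b, C)
    f1 = F * ch_gate.reshape(ch_gate.shape[0], ch_gate.shape[1], 1)

    sp_avg = f1.mean(axis=1, keepdims=True)                  # (b, 1, L)
    sp_max = f1.max(axis=1, keepdims=True)
    sp = ad.concat([sp_avg, sp_max], axis=1)                 # (b, 2, L)
    conv = _conv1d(sp, p[f"{prefix}sconv_w"], p[f"{prefix}sconv_b"], k)
    sp_gate = ad.sigmoid(conv)                               # (b, 1, L)
    out = f1 * sp_gate
    return out, ch_gate, sp_gate.reshape(sp_gate.shape[0], sp_gate.shape[2])


def temporal_attention_layer(X: Tensor, params, spec: GeneratorSpec
                             ) -> tuple[Tensor, Tensor]:
    """1 x m region-mixing convolution + CBAM; returns (block, time weights)."""
    w = Tensor._lift(params["tatt/conv_w"])
    b = Tensor._lift(params["tatt/conv_b"])
    mixed = ad.relu((X.transpose(0, 2, 1) @ w + b).transpose(0, 2, 1))
    out, _, t_weights = cbam_attention(mixed, params, "tatt/cbam/",
                                       spec.spatial_kernel)
    return out, t_weights


def spatial_attention_layer(X: Tensor, params, spec: GeneratorSpec
                            ) -> tuple[Tensor, Tensor]:
    """D x 1 time-mixing convolution + CBAM; returns (block, region attention)."""
    w = Tensor._lift(params["satt/conv_w"])
    b = Tensor._lift(params["satt/conv_b"])
    mixed = ad.relu(X @ w + b)                               # mixes the time axis
    out, region_att, _ = cbam_attention(mixed, params, "satt/cbam/",
                                        spec.spatial_kernel)
    return out, region_att


def _gru_stack(params, prefix: str, steps: list[Tensor], n_layers: int,
               hidden: int, h0: list[Tensor] | None = None
               ) -> tuple[list[Tensor], list[Tensor]]:
    """Run a GRU stack over a list of (batch, in) steps.

    Returns (top-layer outputs per step, final hidden per layer).
    """
    batch = steps[0].shape[0]
    hs = h0 if h0 is not None else [
        Tensor(np.zeros((batch, hidden))) for _ in range(n_layers)]
    hs = list(hs)
    outs: list[Tensor] = []
    P = {k: Tensor._lift(v) for k, v in params.items() if k.startswith(prefix)}
    for x in steps:
        inp = x
        for layer in range(n_layers):
            pre = f"{prefix}/l{layer}"
            h = hs[layer]
            z = ad.sigmoid(inp @ P[f"{pre}/Wz"] + h @ P[f"{pre}/Uz"] + P[f"{pre}/bz"])
            r = ad.sigmoid(inp @ P[f"{pre}/Wr"] + h @ P[f"{pre}/Ur"] + P[f"{pre}/br"])
            n = ad.tanh(inp @ P[f"{pre}/Wn"] + (r * h) @ P[f"{pre}/Un"] + P[f"{pre}/bn"])
            h_new = z * h + (1.0 - z) * n
            hs[layer] = h_new
            inp = h_new
        outs.append(inp)
    return outs, hs


def generator_core(params, spec: GeneratorSpec, X: Tensor
                   ) -> tuple[Tensor, dict[str, Tensor]]:
    """Differentiable generator pass; X (batch, m, D) -> (batch, H).

    Also returns the attention diagnostics (time weights, region attention).
    """
    if X.shape[1:] != (spec.m, spec.D):
        raise ValueError(f"input shape {X.shape[1:]} != (m, D)="
                         f"{(spec.m, spec.D)}")
    P = {k: Tensor._lift(v) for k, v in params.items()}
    a1, t_weights = temporal_attention_layer(X, P, spec)
    a2, region_att = spatial_attention_layer(a1, P, spec)
    # encoder head: 1 x m region-mixing conv
    enc_in = ad.relu((a2.transpose(0, 2, 1) @ P["enc/conv_w"] + P["enc/conv_b"]))
    steps = [enc_in[:, t, :] for t in range(spec.D)]
    _, enc_h = _gru_stack(P, "enc/gru", steps, 2, spec.gru_hidden)
    # fully connected bridge on the top-layer state
    bridged = ad.relu(enc_h[-1] @ P["bridge/w1"] + P["bridge/b1"]) \
        @ P["bridge/w2"] + P["bridge/b2"]
    dec_h = [enc_h[0], bridged]
    # decoder: autoregressive scalar rollout for H steps, seeded with the
    # target region's last observed value when the target is known
    batch = X.shape[0]
    if spec.target_index is not None:
        y_prev = X[:, spec.target_index, -1].reshape(batch, 1)
    else:
        y_prev = Tensor(np.zeros((batch, 1)))
    outs: list[Tensor] = []
    for _ in range(spec.H):
        top, dec_h = _gru_stack(P, "dec/gru", [y_prev], 2, spec.gru_hidden,
                                h0=dec_h)
        y_prev = top[0] @ P["dec/head_w"] + P["dec/head_b"]
        outs.append(y_prev)
    y_hat = ad.concat(outs, axis=1)                          # (batch, H)
    return y_hat, {"time_weights": t_weights, "region_attention": region_att}


def discriminator_core(params, spec: DiscriminatorSpec, W: Tensor) -> Tensor:
    """Differentiable discriminator pass; W (batch, H) -> logits (batch,)."""
    if W.shape[1] != spec.H:
        raise ValueError(f"window length {W.shape[1]} != H={spec.H}")
    P = {k: Tensor._lift(v) for k, v in params.items()}
    steps = [W[:, t].reshape(-1, 1) for t in range(spec.H)]
    outs, _ = _gru_stack(P, "gru", steps, 3, spec.gru_hidden)
    logits = ad.relu(outs[-1]) @ P["head_w"] + P["head_b"]
    return logits.reshape(-1)


# ---------------------------------------------------------------------------
# inference wrappers (plain numpy in, plain numpy out)

def generator_forward(state: ModelState, X: np.ndarray,
                      return_attention: bool = False):
    """Forecast H steps for a batch of (m, D) history blocks."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    y, att = generator_core(state.gen_params, state.gen_spec, Tensor(X))
    out = y.data[0] if single else y.data
    if return_attention:
        att_np = {k: (v.data[0] if single else v.data) for k, v in att.items()}
        return out, att_np
    return out


def discriminator_forward(state: ModelState, W: np.ndarray,
                          return_logits: bool = False) -> np.ndarray:
    """Score H-length windows; returns probabilities in (0,1) by default."""
    W = np.asarray(W, dtype=np.float64)
    single = W.ndim == 1
    if single:
        W = W[None]
    logits = discriminator_core(state.disc_params, state.disc_spec,
                                Tensor(W)).data
    out = logits if return_logits else 1.0 / (1.0 + np.exp(-logits))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# serialization

def save_model(state: ModelState, path: str | Path) -> None:
    """Write specs + parameters + seed to one HDF5 archive (bit-exact)."""
    with h5py.File(path, "w") as f:
        f.attrs["gen_spec"] = json.dumps(asdict(state.gen_spec))
        f.attrs["disc_spec"] = json.dumps(asdict(state.disc_spec))
        f.attrs["seed"] = state.seed
        f.attrs["history"] = json.dumps(state.history)
        for name, arr in state.gen_params.items():
            f.create_dataset(f"gen/{name}", data=arr)
        for name, arr in state.disc_params.items():
            f.create_dataset(f"disc/{name}", data=arr)


def load_model(path: str | Path) -> ModelState:
    with h5py.File(path, "r") as f:
        gen_spec = GeneratorSpec(**json.loads(f.attrs["gen_spec"]))
        disc_spec = DiscriminatorSpec(**json.loads(f.attrs["disc_spec"]))
        seed = int(f.attrs["seed"])
        history = json.loads(f.attrs["history"])
        gp = {k[len("gen/"):]: f[k][()] for k in _walk(f, "gen")}
        dp = {k[len("disc/"):]: f[k][()] for k in _walk(f, "disc")}
    return ModelState(gen_spec, disc_spec, gp, dp, seed, history)


def _walk(f: h5py.File, root: str) -> list[str]:
    names: list[str] = []
    f[root].visititems(
        lambda name, obj: names.append(f"{root}/{name}")
        if isinstance(obj, h5py.Dataset) else None)
    return names
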