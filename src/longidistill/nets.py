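"""Temporal network cores: LSTM, 1-D CNN, CNN-LSTM, RNN, sparse autoencoder.

All modules are written against the in-package autodiff engine and follow
the gate algebra exactly:

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)          (forget gate)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)          (input gate)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)          (output gate)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    h_t = o_t * squash(c_t)

where ``squash`` defaults to tanh (the canonical LSTM).  A ``sigmoid``
variant of the cell-state squashing is retained behind ``state_squash``
because one published description of this architecture prints the hidden
state as o_t * sigmoid(c_t); the tanh default follows the same source's own
description of the cell-state nonlinearity.

The CNN is a 1-D valid cross-correlation over the taxon axis within each
time point, with kernel weights shared across time.  Masked forward passes
carry the recurrent state through unobserved slots, so a padded run equals
an unpadded run on the compacted observed subsequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "Linear", "Conv1d", "LSTMCell", "RNNCell", "MLPHead", "Branch",
    "LSTMState", "lstm_step", "lstm_forward", "rnn_step", "conv_extract",
    "SequenceClassifier", "build_model", "cnn_lstm_forward",
    "SparseAutoencoder", "AutoencoderConfig", "autoencoder_loss",
    "save_model", "load_model", "rebuild_head",
]


# ---------------------------------------------------------------------------
# module plumbing
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container: named tensors + named submodules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}: "
                                 f"{p.data.shape} vs {state[n].shape}")
            p.data = state[n].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return ad.tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.W = _uniform_fan_in(rng, (n_out, n_in), n_in)
        self.b = _uniform_fan_in(rng, (n_out,), n_in)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W.transpose() + self.b


class Conv1d(Module):
    """Valid (no input padding) 1-D cross-correlation along the last axis.

    Input (..., in_channels, length) -> output (..., out_channels, L_out)
    with L_out = (length - kernel_size)//stride + 1:

        O[d, e] = sum_i sum_j w[d, i, j] * x[i, e*stride + j] + b[d]
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride = kernel_size, stride
        fan_in = in_channels * kernel_size
        self.W = _uniform_fan_in(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.b = _uniform_fan_in(rng, (out_channels,), fan_in)

    def out_length(self, length: int) -> int:
        if length < self.kernel_size:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel_size}")
        return (length - self.kernel_size) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        self.out_length(x.shape[-1])
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        out = ad.conv1d(x, self.W, self.b, self.stride)
        return out.reshape(out.shape[1:]) if squeeze else out


def conv_extract(conv: Conv1d, x: np.ndarray | Tensor) -> Tensor:
    """Functional feature extraction for a single per-time-point vector.

    Accepts (length,) or (channels, length); single-channel input is
    promoted to one channel.
    """
    t = x if isinstance(x, Tensor) else ad.Tensor(x)
    if t.ndim == 1:
        t = t.reshape(1, t.shape[0])
    return conv(t)


# ---------------------------------------------------------------------------
# recurrent cells
# ---------------------------------------------------------------------------

@dataclass
class LSTMState:
    h: Tensor
    c: Tensor
    t: int = 0


class LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 state_squash: str = "tanh"):
        super().__init__()
        if state_squash not in ("tanh", "sigmoid"):
            raise ValueError("state_squash must be 'tanh' or 'sigmoid'")
        self.n_in, self.n_hidden = n_in, n_hidden
        self.state_squash = state_squash
        for gate in ("f", "i", "o", "c"):
            setattr(self, f"W_{gate}", _uniform_fan_in(rng, (n_hidden, n_in), n_in))
            setattr(self, f"U_{gate}", _uniform_fan_in(rng, (n_hidden, n_hidden), n_hidden))
            setattr(self, f"b_{gate}", _uniform_fan_in(rng, (n_hidden,), n_in))

    def initial_state(self, batch: int) -> LSTMState:
        zeros = ad.Tensor(np.zeros((batch, self.n_hidden)))
        return LSTMState(h=zeros, c=ad.Tensor(np.zeros((batch, self.n_hidden))), t=0)

    def step(self, x_t: Tensor, state: LSTMState) -> LSTMState:
        if x_t.shape[-1] != self.n_in:
            raise ValueError(f"input dim {x_t.shape[-1]} != expected {self.n_in}")
        h_prev, c_prev = state.h, state.c
        f = ad.sigmoid(x_t @ self.W_f.transpose() + h_prev @ self.U_f.transpose() + self.b_f)
        i = ad.sigmoid(x_t @ self.W_i.transpose() + h_prev @ self.U_i.transpose() + self.b_i)
        o = ad.sigmoid(x_t @ self.W_o.transpose() + h_prev @ self.U_o.transpose() + self.b_o)
        g = ad.tanh(x_t @ self.W_c.transpose() + h_prev @ self.U_c.transpose() + self.b_c)
        c = f * c_prev + i * g
        squash = ad.tanh if self.state_squash == "tanh" else ad.sigmoid
        h = o * squash(c)
        return LSTMState(h=h, c=c, t=state.t + 1)

    def gate_cat(self):
        """Concatenated gate weights for the fused step (one matmul per
        transform instead of four); ordering f, i, o, c."""
        w = ad.concatenate([self.W_f, self.W_i, self.W_o, self.W_c], axis=0)
        u = ad.concatenate([self.U_f, self.U_i, self.U_o, self.U_c], axis=0)
        b = ad.concatenate([self.b_f, self.b_i, self.b_o, self.b_c], axis=0)
        return w.transpose(), u.transpose(), b

    def step_fused(self, x_t: Tensor, state: LSTMState, cat) -> LSTMState:
        """Identical algebra to ``step`` through concatenated gate blocks."""
        wt, ut, b = cat
        z = x_t @ wt + state.h @ ut + b
        zf, zi, zo, zc = ad.split(z, 4, axis=-1)
        f, i, o = ad.sigmoid(zf), ad.sigmoid(zi), ad.sigmoid(zo)
        c = f * state.c + i * ad.tanh(zc)
        squash = ad.tanh if self.state_squash == "tanh" else ad.sigmoid
        return LSTMState(h=o * squash(c), c=c, t=state.t + 1)


def lstm_step(cell: LSTMCell, x_t, state: LSTMState | None = None) -> LSTMState:
    """One gate update; ``state=None`` starts from h=c=0 at t=0."""
    x = x_t if isinstance(x_t, Tensor) else ad.Tensor(np.atleast_2d(x_t))
    if x.ndim == 1:
        x = x.reshape(1, x.shape[0])
    if state is None:
        state = cell.initial_state(x.shape[0])
    return cell.step(x, state)


def lstm_forward(cell: LSTMCell, values: Tensor | np.ndarray,
                 mask: np.ndarray | None = None,
                 use_mask: bool = True) -> tuple[Tensor, Tensor]:
    """Run the cell over a (B, T, F) batch.

    With ``use_mask`` the state update at mask==0 slots is skipped (carried
    through) and the returned "last" hidden state is each subject's final
    observed slot; without it every slot updates and the final slot's hidden
    state is returned.
    """
    x = values if isinstance(values, Tensor) else ad.Tensor(values)
    batch, t_slots, _ = x.shape
    if use_mask:
        if mask is None:
            raise ValueError("use_mask requires an observation mask")
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            bad = int(np.argmax(mask.sum(axis=1) == 0))
            raise ValueError(f"subject at batch index {bad} has an all-zero mask")
    state = cell.initial_state(batch)
    cat = cell.gate_cat()
    hs = []
    for t in range(t_slots):
        new = cell.step_fused(x[:, t, :], state, cat)
        if use_mask:
            m = ad.Tensor(mask[:, t:t + 1])
            keep = ad.Tensor(1.0 - mask[:, t:t + 1])
            state = LSTMState(h=m * new.h + keep * state.h,
                              c=m * new.c + keep * state.c, t=t + 1)
        else:
            state = new
        hs.append(state.h)
    hidden = ad.stack(hs, axis=1)  # (B, T, H)
    if use_mask:
        last_idx = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
        last = hidden[np.arange(batch), last_idx.astype(int)]
    else:
        last = hs[-1]
    return hidden, last


class RNNCell(Module):
    """Plain recurrence h_t = tanh(W_x x_t + W_h h_{t-1} + b)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        self.W_x = _uniform_fan_in(rng, (n_hidden, n_in), n_in)
        self.W_h = _uniform_fan_in(rng, (n_hidden, n_hidden), n_hidden)
        self.b = _uniform_fan_in(rng, (n_hidden,), n_in)

    def initial_state(self, batch: int) -> LSTMState:
        z = ad.Tensor(np.zeros((batch, self.n_hidden)))
        return LSTMState(h=z, c=z, t=0)

    def step(self, x_t: Tensor, state: LSTMState) -> LSTMState:
        a = x_t @ self.W_x.transpose() + state.h @ self.W_h.transpose() + self.b
        return LSTMState(h=ad.tanh(a), c=state.c, t=state.t + 1)


def rnn_step(cell: RNNCell, x_t, h_prev=None) -> Tensor:
    x = x_t if isinstance(x_t, Tensor) else ad.Tensor(np.atleast_2d(x_t))
    if x.ndim == 1:
        x = x.reshape(1, x.shape[0])
    state = cell.initial_state(x.shape[0]) if h_prev is None else LSTMState(
        h=h_prev if isinstance(h_prev, Tensor) else ad.Tensor(np.atleast_2d(h_prev)),
        c=ad.Tensor(np.zeros((x.shape[0], cell.n_hidden))), t=0)
    return cell.step(x, state).h


# ---------------------------------------------------------------------------
# heads and branches
# ---------------------------------------------------------------------------

class MLPHead(Module):
    """Penultimate layer + output layer; softmax for mutually exclusive
    classes, per-label sigmoid in multi-label mode."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 hidden: int = 64, multi_label: bool = False):
        super().__init__()
        self.n_in, self.n_out, self.hidden = n_in, n_out, hidden
        self.multi_label = multi_label
        self.penultimate = Linear(n_in, hidden, rng)
        self.out = Linear(hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        z = self.out(ad.tanh(self.penultimate(x)))
        return ad.sigmoid(z) if self.multi_label else ad.softmax(z, axis=-1)

    @property
    def penultimate_weights(self) -> Tensor:
        return self.penultimate.W


class Branch(Module):
    """Shallow auxiliary classifier branched from an intermediate layer.

    An adapter maps the attachment-point features to the main head's input
    dimension so the penultimate layer's weight matrix has exactly the main
    head's shape (required by the weight-matching loss).
    """

    def __init__(self, n_in: int, main_in: int, n_out: int,
                 rng: np.random.Generator, hidden: int = 64,
                 multi_label: bool = False, name: str = ""):
        super().__init__()
        self.attachment = name
        self.adapter = Linear(n_in, main_in, rng)
        self.head = MLPHead(main_in, n_out, rng, hidden=hidden,
                            multi_label=multi_label)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(ad.tanh(self.adapter(x)))

    @property
    def penultimate_weights(self) -> Tensor:
        return self.head.penultimate.W


# ---------------------------------------------------------------------------
# sequence classifiers
# ---------------------------------------------------------------------------

@dataclass
class ModelOutput:
    probs: Tensor                       # (B, n_outputs)
    hidden: Tensor                      # (B, T, H)
    branch_probs: list[Tensor] = field(default_factory=list)


class SequenceClassifier(Module):
    """CNN-LSTM family classifier over padded longitudinal batches.

    ``arch`` selects the temporal core: "lstm", "cnnlstm" (conv stack shared
    across time feeding the LSTM) or "rnn".  Optional shallow branches
    support the branch-distillation training scheme; an optional concat-pool
    head (mean ++ max ++ last hidden) supports transfer fine-tuning.
    """

    def __init__(self, n_features: int, n_outputs: int, arch: str = "cnnlstm",
                 hidden: int = 128, head_hidden: int = 64,
                 conv_channels: tuple[int, ...] = (32, 32), kernel_size: int = 5,
                 stride: int = 2, multi_label: bool = False,
                 state_squash: str = "tanh", n_branches: int = 0,
                 use_concat_pool: bool = False, seed: int = 0):
        super().__init__()
        if arch not in ("lstm", "cnnlstm", "rnn"):
            raise ValueError(f"unknown arch {arch!r}")
        self.config = dict(
            n_features=n_features, n_outputs=n_outputs, arch=arch, hidden=hidden,
            head_hidden=head_hidden, conv_channels=tuple(conv_channels),
            kernel_size=kernel_size, stride=stride, multi_label=multi_label,
            state_squash=state_squash, n_branches=n_branches,
            use_concat_pool=use_concat_pool, seed=seed,
        )
        self.n_features, self.n_outputs = n_features, n_outputs
        self.arch, self.multi_label = arch, multi_label
        self.use_concat_pool = use_concat_pool
        rng = np.random.default_rng(seed)

        core_in = n_features
        self.convs: list[Conv1d] = []
        if arch == "cnnlstm":
            length, in_ch = n_features, 1
            for ci, out_ch in enumerate(conv_channels):
                conv = Conv1d(in_ch, out_ch, kernel_size, stride, rng)
                setattr(self, f"conv{ci}", conv)
                self.convs.append(conv)
                length = conv.out_length(length)
                in_ch = out_ch
            core_in = in_ch * length
        self._conv_out_dim = core_in

        if arch == "rnn":
            self.core = RNNCell(core_in, hidden, rng)
        else:
            self.core = LSTMCell(core_in, hidden, rng, state_squash=state_squash)
        head_in = 3 * hidden if use_concat_pool else hidden
        self.head = MLPHead(head_in, n_outputs, rng, hidden=head_hidden,
                            multi_label=multi_label)

        self.branches: list[Branch] = []
        if n_branches:
            points = self._branch_points()[:n_branches]
            for bi, (name, dim) in enumerate(points):
                br = Branch(dim, head_in, n_outputs, rng, hidden=head_hidden,
                            multi_label=multi_label, name=name)
                setattr(self, f"branch{bi}", br)
                self.branches.append(br)

    def _branch_points(self) -> list[tuple[str, int]]:
        # ordered shallow -> deep
        pts = []
        if self.arch == "cnnlstm":
            pts.append(("post_conv", self._conv_out_dim))
        pts.append(("post_recurrent", self.core.n_hidden))
        return pts

    # -- forward ----------------------------------------------------------
    def _conv_features(self, x: Tensor) -> Tensor:
        """(B, T, F) -> (B, T, conv_out_dim), kernel weights shared across time.

        tanh sits between conv layers (same nonlinearity family as the rest
        of the body, and unlike ReLU it cannot silence a unit permanently);
        the last conv layer feeds the recurrent core linearly, whose gates
        supply the nonlinearity.
        """
        b, t, f = x.shape
        z = x.reshape(b * t, 1, f)
        for li, conv in enumerate(self.convs):
            if li > 0:
                z = ad.tanh(z)
            z = conv(z)
        return z.reshape(b, t, self._conv_out_dim)

    def forward(self, values: np.ndarray | Tensor, mask: np.ndarray,
                use_mask: bool = True, with_branches: bool = False) -> ModelOutput:
        x = values if isinstance(values, Tensor) else ad.Tensor(values)
        feats = self._conv_features(x) if self.arch == "cnnlstm" else x
        if self.arch == "rnn":
            hidden, last = _rnn_forward(self.core, feats, mask, use_mask)
        else:
            hidden, last = lstm_forward(self.core, feats, mask, use_mask=use_mask)
        if self.use_concat_pool:
            from .transfer import concat_pool
            pool_mask = np.asarray(mask) if use_mask else np.ones(
                (hidden.shape[0], hidden.shape[1]), dtype=np.int8)
            head_in = concat_pool(hidden, pool_mask)
        else:
            head_in = last
        probs = self.head(head_in)
        branch_probs = []
        if with_branches and self.branches:
            for br in self.branches:
                if br.attachment == "post_conv":
                    m = np.asarray(mask, dtype=np.float64)
                    mm = ad.Tensor(m[:, :, None])
                    cnt = ad.Tensor(m.sum(axis=1, keepdims=True))
                    b_in = (feats * mm).sum(axis=1) / cnt
                else:
                    b_in = last
                branch_probs.append(br(b_in))
        return ModelOutput(probs=probs, hidden=hidden, branch_probs=branch_probs)

    def predict_proba(self, values, mask, use_mask: bool = True) -> np.ndarray:
        with ad.no_grad():
            return self.forward(values, mask, use_mask=use_mask).probs.data

    # -- structure for transfer ------------------------------------------
    def layer_blocks(self) -> list[list[Tensor]]:
        """Parameter blocks ordered first -> last for unfreezing/lr decay."""
        blocks = []
        if self.convs:
            blocks.append([p for c in self.convs for p in c.parameters()])
        blocks.append(self.core.parameters())
        blocks.append(self.head.parameters())
        return blocks


def _rnn_forward(cell: RNNCell, values: Tensor, mask, use_mask: bool):
    x = values if isinstance(values, Tensor) else ad.Tensor(values)
    batch, t_slots, _ = x.shape
    if use_mask:
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("subject with all-zero mask")
    state = cell.initial_state(batch)
    hs = []
    for t in range(t_slots):
        new = cell.step(x[:, t, :], state)
        if use_mask:
            m = ad.Tensor(mask[:, t:t + 1])
            keep = ad.Tensor(1.0 - mask[:, t:t + 1])
            state = LSTMState(h=m * new.h + keep * state.h, c=state.c, t=t + 1)
        else:
            state = new
        hs.append(state.h)
    hidden = ad.stack(hs, axis=1)
    if use_mask:
        last_idx = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
        last = hidden[np.arange(batch), last_idx.astype(int)]
    else:
        last = hs[-1]
    return hidden, last


def build_model(arch: str, n_features: int, n_outputs: int, **kw) -> SequenceClassifier:
    return SequenceClassifier(n_features, n_outputs, arch=arch, **kw)


def cnn_lstm_forward(model: SequenceClassifier, values, mask,
                     use_mask: bool = True) -> Tensor:
    """Class scores of the full conv -> recurrent -> head pipeline."""
    return model.forward(values, mask, use_mask=use_mask).probs


# ---------------------------------------------------------------------------
# sparse autoencoder (feature-extraction baseline)
# ---------------------------------------------------------------------------

class SparseAutoencoder(Module):
    """Symmetric autoencoder with ReLU hidden layers and a sigmoid latent.

    The latent layer uses a sigmoid so its average activation lies in (0, 1)
    as the Bernoulli-KL sparsity penalty requires; all other hidden layers
    are ReLU.
    """

    def __init__(self, n_in: int, latent: int, hidden: tuple[int, ...] = (128,),
                 seed: int = 0):
        super().__init__()
        if latent >= n_in:
            raise ValueError(f"latent size {latent} must be < input size {n_in}")
        rng = np.random.default_rng(seed)
        widths = [n_in, *hidden, latent]
        self.encoder_layers: list[Linear] = []
        for li, (a, b) in enumerate(zip(widths, widths[1:])):
            lay = Linear(a, b, rng)
            setattr(self, f"enc{li}", lay)
            self.encoder_layers.append(lay)
        widths_dec = [latent, *reversed(hidden), n_in]
        self.decoder_layers: list[Linear] = []
        for li, (a, b) in enumerate(zip(widths_dec, widths_dec[1:])):
            lay = Linear(a, b, rng)
            setattr(self, f"dec{li}", lay)
            self.decoder_layers.append(lay)
        self.latent = latent

    def encode(self, x: Tensor) -> Tensor:
        z = x if isinstance(x, Tensor) else ad.Tensor(x)
        for lay in self.encoder_layers[:-1]:
            z = ad.relu(lay(z))
        return ad.sigmoid(self.encoder_layers[-1](z))

    def decode(self, z: Tensor) -> Tensor:
        for lay in self.decoder_layers[:-1]:
            z = ad.relu(lay(z))
        return self.decoder_layers[-1](z)

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        z = self.encode(x)
        return self.decode(z), z

    def weight_tensors(self) -> list[Tensor]:
        return [lay.W for lay in self.encoder_layers + self.decoder_layers]


@dataclass
class AutoencoderConfig:
    """Sparse-autoencoder loss weights.

    lam scales the squared-weight (L2) regularizer, beta the Bernoulli-KL
    sparsity penalty toward target activation p.
    """

    lam: float = 0.0
    beta: float = 0.0
    p: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("sparsity parameter p must be in (0, 1)")
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be >= 0")


def autoencoder_loss(config: AutoencoderConfig, x: np.ndarray, x_hat: Tensor,
                     weights: list[Tensor], latent: Tensor) -> Tensor:
    """Reconstruction MSE + lam * sum |W|^2 + beta * sum_n KL(p || p'_n).

    p'_n is the batch-average activation of latent neuron n; values outside
    (0, 1) are clamped to [1e-7, 1 - 1e-7] with a warning (the Bernoulli KL
    is undefined at the boundary).
    """
    import warnings

    x_arr = np.asarray(x, dtype=np.float64)
    m = x_arr.shape[0]
    diff = x_hat - ad.Tensor(x_arr)
    recon = (diff * diff).sum() / m
    loss = recon
    if config.lam:
        for w in weights:
            loss = loss + config.lam * (w * w).sum()
    if config.beta:
        eps = 1e-7
        p_hat = latent.mean(axis=0)  # average activation per latent neuron
        if (p_hat.data <= 0).any() or (p_hat.data >= 1).any():
            warnings.warn("average latent activation outside (0,1); clamping",
                          stacklevel=2)
        p_hat = p_hat.clip(eps, 1.0 - eps)
        p = config.p
        kl = (p * (ad.Tensor(np.full_like(p_hat.data, p)) / p_hat).log()
              + (1 - p) * (ad.Tensor(np.full_like(p_hat.data, 1 - p)) / (1.0 - p_hat)).log()).sum()
        loss = loss + config.beta * kl
    return loss


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: SequenceClassifier, path: str | Path) -> None:
    """Checkpoint = architecture metadata (JSON attr) + parameter arrays."""
    arrays = {n.replace(".", "/"): a for n, a in model.state_dict().items()}
    meta = json.dumps(model.config)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> SequenceClassifier:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        state = {k.replace("/", "."): f[k] for k in f.files if k != "__meta__"}
    meta["conv_channels"] = tuple(meta["conv_channels"])
    model = SequenceClassifier(**meta)
    model.load_state_dict(state)
    return model


def rebuild_head(model: SequenceClassifier, n_outputs: int,
                 multi_label: bool = False, use_concat_pool: bool = True,
                 seed: int = 0) -> None:
    """Reinitialize only the classifier head (body weights untouched)."""
    rng = np.random.default_rng(seed)
    head_in = 3 * model.core.n_hidden if use_concat_pool else model.core.n_hidden
    model.use_concat_pool = use_concat_pool
    model.multi_label = multi_label
    model.n_outputs = n_outputs
    model.head = MLPHead(head_in, n_outputs, rng,
                         hidden=model.config["head_hidden"],
                         multi_label=multi_label)
    model.config.update(n_outputs=n_outputs, multi_label=multi_label,
                        use_concat_pool=use_concat_pool)
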