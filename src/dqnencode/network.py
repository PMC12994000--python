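"""Layered value-network feature extractors.

Three architectures act as fixed (already-trained) nonlinear feature maps
from stacked game frames to unit activations:

* ``feedforward``       — conv x3 -> fully connected (512) -> Q-values
* ``dueling``           — conv x3 -> value & advantage streams (512 each)
                          -> Q = V + A - mean(A)
* ``recurrent_dueling`` — conv x3 -> LSTM cell (512) -> dueling streams -> Q

All convolutions use valid padding and ReLU; on 84x84 input the spatial
sizes are forced to 20 -> 9 -> 7 by the printed unit counts (20x20x32,
9x9x64, 7x7x64). The forward pass records every unit's activation per time
step as the raw material for encoding-model predictors. The LSTM hidden and
cell state are zeroed immediately after any time step flagged as an episode
terminal, so features never leak across episodes.

The forward pass is plain NumPy: inputs here are short toy streams, and the
explicit recurrence makes the terminal-reset contract easy to audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

LAYER_ORDER = ("conv1", "conv2", "conv3", "lstm", "layer4", "output")
HIDDEN_LAYERS = ("conv1", "conv2", "conv3", "lstm", "layer4")

VARIANTS = ("feedforward", "dueling", "recurrent_dueling")

DEFAULT_CONV_LAYERS = ((32, 8, 4), (64, 4, 2), (64, 3, 1))


def conv_output_size(input_size: int, kernel: int, stride: int) -> int:
    """Spatial output size of a valid (unpadded) strided convolution."""
    if kernel > input_size:
        raise ValueError(f"kernel {kernel} exceeds input size {input_size}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return (input_size - kernel) // stride + 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for one of the three variants."""

    variant: str = "feedforward"
    conv_layers: tuple = DEFAULT_CONV_LAYERS
    fc_units: int = 512
    lstm_units: int = 512
    n_actions: int = 4
    input_frames: int = 4
    input_size: int = 84

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_actions < 1:
            raise ValueError("n_actions must be positive")

    @property
    def conv_spatial_sizes(self) -> tuple:
        sizes = []
        s = self.input_size
        for _, kernel, stride in self.conv_layers:
            s = conv_output_size(s, kernel, stride)
            sizes.append(s)
        return tuple(sizes)

    @property
    def conv_flat_size(self) -> int:
        s = self.conv_spatial_sizes[-1]
        return s * s * self.conv_layers[-1][0]

    @property
    def has_lstm(self) -> bool:
        return self.variant == "recurrent_dueling"

    @property
    def has_dueling(self) -> bool:
        return self.variant in ("dueling", "recurrent_dueling")

    def unit_counts(self) -> dict:
        """Units recorded per layer label."""
        counts = {}
        s = self.input_size
        for i, (ch, kernel, stride) in enumerate(self.conv_layers, start=1):
            s = conv_output_size(s, kernel, stride)
            counts[f"conv{i}"] = s * s * ch
        if self.has_lstm:
            counts["lstm"] = self.lstm_units
        # layer4: one fc for feedforward, two 512-unit streams for dueling
        counts["layer4"] = self.fc_units * (2 if self.has_dueling else 1)
        counts["output"] = self.n_actions
        return counts


@dataclass
class NetworkWeights:
    """Parameter arrays for a NetworkSpec, keyed by name.

    conv{i}_w: (out_ch, in_ch, k, k); conv{i}_b: (out_ch,)
    fc_w/fc_b (feedforward); value_w/value_b, adv_w/adv_b and their heads
    (dueling); lstm_w_x: (4H, D), lstm_w_h: (4H, H), lstm_b: (4H,) with gate
    order (input, forget, cell, output).
    """

    spec: NetworkSpec
    params: dict

    def __getitem__(self, key: str) -> np.ndarray:
        return self.params[key]


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_weights(spec: NetworkSpec, seed: int = 0, scale: float = 1.0) -> NetworkWeights:
    """Variance-scaled random weights, deterministic given the seed.

    ``scale=0`` yields all-zero parameters (useful for degenerate-path
    checks: every ReLU unit then outputs exactly 0).
    """
    rng = np.random.default_rng(seed)
    p: dict = {}
    in_ch = spec.input_frames
    for i, (ch, k, _) in enumerate(spec.conv_layers, start=1):
        fan = in_ch * k * k
        p[f"conv{i}_w"] = scale * _he(rng, (ch, in_ch, k, k), fan)
        p[f"conv{i}_b"] = np.zeros(ch)
        in_ch = ch
    flat = spec.conv_flat_size
    if spec.has_lstm:
        h = spec.lstm_units
        p["lstm_w_x"] = scale * _he(rng, (4 * h, flat), flat)
        p["lstm_w_h"] = scale * _he(rng, (4 * h, h), h)
        p["lstm_b"] = np.zeros(4 * h)
        head_in = h
    else:
        head_in = flat
    if spec.has_dueling:
        p["value_w"] = scale * _he(rng, (spec.fc_units, head_in), head_in)
        p["value_b"] = np.zeros(spec.fc_units)
        p["adv_w"] = scale * _he(rng, (spec.fc_units, head_in), head_in)
        p["adv_b"] = np.zeros(spec.fc_units)
        p["value_head_w"] = scale * _he(rng, (1, spec.fc_units), spec.fc_units)
        p["value_head_b"] = np.zeros(1)
        p["adv_head_w"] = scale * _he(rng, (spec.n_actions, spec.fc_units), spec.fc_units)
        p["adv_head_b"] = np.zeros(spec.n_actions)
    else:
        p["fc_w"] = scale * _he(rng, (spec.fc_units, head_in), head_in)
        p["fc_b"] = np.zeros(spec.fc_units)
        p["q_w"] = scale * _he(rng, (spec.n_actions, spec.fc_units), spec.fc_units)
        p["q_b"] = np.zeros(spec.n_actions)
    return NetworkWeights(spec=spec, params=p)


def _check_weights(spec: NetworkSpec, weights: NetworkWeights) -> None:
    ref = init_weights(spec, seed=0)
    for key, arr in ref.params.items():
        if key not in weights.params:
            raise ValueError(f"weights missing parameter {key!r}")
        if weights.params[key].shape != arr.shape:
            raise ValueError(
                f"weight {key!r} has shape {weights.params[key].shape}, "
                f"spec requires {arr.shape}"
            )


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Valid strided convolution of a (T, C, H, W) batch with (O, C, k, k)."""
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (T, C, oh, ow, k, k)
    out = np.einsum("ocij,tcxyij->toxy", w, win, optimize=True)
    return out + b[None, :, None, None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class FeatureTimeSeries:
    """Per-unit activation time courses at the stimulus rate.

    values     : (U, T) activations
    unit_layer : (U,) layer labels from LAYER_ORDER
    rate_hz    : sampling rate of the columns
    """

    values: np.ndarray
    unit_layer: np.ndarray
    rate_hz: float = 45.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.unit_layer = np.asarray(self.unit_layer, dtype=object).astype(str)
        if self.values.ndim != 2:
            raise ValueError("values must be U x T")
        if self.unit_layer.shape[0] != self.values.shape[0]:
            raise ValueError("one layer label per unit required")
        unknown = set(self.unit_layer) - set(LAYER_ORDER)
        if unknown:
            raise ValueError(f"unknown layer labels {sorted(unknown)}")

    @property
    def n_units(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[1])

    def select_layers(self, layers) -> "FeatureTimeSeries":
        if isinstance(layers, str):
            layers = LAYER_ORDER if layers == "all" else (layers,)
        mask = np.isin(self.unit_layer, list(layers))
        if not mask.any():
            raise ValueError(f"no units in layers {layers}")
        return FeatureTimeSeries(self.values[mask], self.unit_layer[mask], self.rate_hz)


def forward_features(
    spec: NetworkSpec,
    weights: NetworkWeights,
    stacks: np.ndarray,
    terminal_flags: np.ndarray,
    chunk: int = 256,
    include_output: bool = True,
) -> FeatureTimeSeries:
    """Run stacked states through the network, recording every unit.

    stacks         : (T, depth, H, W) state stacks (scaled to [0,1] internally)
    terminal_flags : (T,) bool; LSTM state is reset to zero *after* each
                     flagged step, reproducing the fresh-episode condition.

    Returns a FeatureTimeSeries with U = sum of the spec's unit counts
    (conv layers post-ReLU, LSTM hidden output, fc/dueling-stream
    activations, and Q-values when ``include_output``).
    """
    _check_weights(spec, weights)
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim != 4:
        raise ValueError("stacks must be (T, depth, H, W)")
    t_total = stacks.shape[0]
    terminal_flags = np.asarray(terminal_flags, dtype=bool)
    if terminal_flags.shape != (t_total,):
        raise ValueError("terminal_flags must align with stacks")
    if stacks.shape[1] != spec.input_frames:
        raise ValueError(
            f"stack depth {stacks.shape[1]} != spec input_frames {spec.input_frames}"
        )

    x = stacks / 255.0
    conv_out: dict = {i: [] for i in range(1, len(spec.conv_layers) + 1)}
    for start in range(0, t_total, chunk):
        xi = x[start:start + chunk]
        for i, (_, _, stride) in enumerate(spec.conv_layers, start=1):
            xi = np.maximum(
                _conv2d(xi, weights[f"conv{i}_w"], weights[f"conv{i}_b"], stride), 0.0
            )
            conv_out[i].append(xi.astype(np.float32))
    conv_act = {i: np.concatenate(v) for i, v in conv_out.items()}
    flat = conv_act[len(spec.conv_layers)].reshape(t_total, -1)

    blocks: list = []
    labels: list = []

    for i in range(1, len(spec.conv_layers) + 1):
        a = conv_act[i].reshape(t_total, -1)
        blocks.append(a.T)
        labels += [f"conv{i}"] * a.shape[1]

    if spec.has_lstm:
        h_units = spec.lstm_units
        wx, wh, b = weights["lstm_w_x"], weights["lstm_w_h"], weights["lstm_b"]
        h = np.zeros(h_units)
        c = np.zeros(h_units)
        hs = np.empty((t_total, h_units), dtype=np.float32)
        for t in range(t_total):
            gates = wx @ flat[t] + wh @ h + b
            i_g = _sigmoid(gates[:h_units])
            f_g = _sigmoid(gates[h_units:2 * h_units])
            g_g = np.tanh(gates[2 * h_units:3 * h_units])
            o_g = _sigmoid(gates[3 * h_units:])
            c = f_g * c + i_g * g_g
            h = o_g * np.tanh(c)
            hs[t] = h
            if terminal_flags[t]:  # episode boundary: next step starts fresh
                h = np.zeros(h_units)
                c = np.zeros(h_units)
        blocks.append(hs.T)
        labels += ["lstm"] * h_units
        head_in = hs.astype(float)
    else:
        head_in = flat

    if spec.has_dueling:
        v_s = np.maximum(head_in @ weights["value_w"].T + weights["value_b"], 0.0)
        a_s = np.maximum(head_in @ weights["adv_w"].T + weights["adv_b"], 0.0)
        blocks.append(v_s.T.astype(np.float32))
        labels += ["layer4"] * spec.fc_units
        blocks.append(a_s.T.astype(np.float32))
        labels += ["layer4"] * spec.fc_units
        value = v_s @ weights["value_head_w"].T + weights["value_head_b"]
        adv = a_s @ weights["adv_head_w"].T + weights["adv_head_b"]
        q = value + adv - adv.mean(axis=1, keepdims=True)
    else:
        fc = np.maximum(head_in @ weights["fc_w"].T + weights["fc_b"], 0.0)
        blocks.append(fc.T.astype(np.float32))
        labels += ["layer4"] * spec.fc_units
        q = fc @ weights["q_w"].T + weights["q_b"]

    if include_output:
        blocks.append(q.T.astype(np.float32))
        labels += ["output"] * spec.n_actions

    values = np.concatenate(blocks, axis=0)
    return FeatureTimeSeries(values=values, unit_layer=np.array(labels), rate_hz=45.0)
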