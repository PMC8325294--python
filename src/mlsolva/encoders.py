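"""Per-atom feature encoders: skip-connected GCN and bidirectional RNN (BiLM).

Both encoders map an embedded molecule (M × D) to a feature tensor
(M × N) while preserving the atom rows.  The GCN layer is

    GCN(H, A) = tanh(D^{-1/2} A D^{-1/2} H W1 + H W2 + b)

with the skip term ``H W2`` and degree-normalized adjacency; isolated atoms
(degree 0) get a zero normalized-adjacency row, so a single-atom solvent
such as water is well defined.  The BiLM runs stacked forward and backward
recurrences (vanilla RNN, GRU or LSTM cells); per level the two directions
are summed.  Either encoder's output is a trainable weighted sum over the
stacked layer outputs, including the (projected) input as level 0:

    P = Σ_i c_i H^(i)

The encoders are written on the package's autodiff tensors so the same
forward code serves inference and gradient-based training; the public
functions accept and return plain NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .embedding import EmbeddedMolecule
from .molgraph import MolGraph

CELL_TYPES = ("rnn", "gru", "lstm")
_GATES = {"rnn": 1, "gru": 3, "lstm": 4}


@dataclass
class FeatureTensor:
    """Encoded per-atom features P or Q, one row per heavy atom."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GCNParams:
    """Weights of a stacked skip-connected GCN encoder.

    ``layers[i]`` holds (W1, W2, b); ``layer_weights`` are the trainable
    scalars c_i over [projected input, layer 1, ..., layer L].
    ``input_proj`` bridges embedding dim D to hidden width N when D != N.
    """

    layers: list = field(default_factory=list)     # [(W1, W2, b), ...]
    layer_weights: np.ndarray = None               # (L+1,)
    input_proj: np.ndarray | None = None           # (D, N) or None
    include_input: bool = True

    @property
    def width(self) -> int:
        return self.layers[0][0].shape[1]

    def n_parameters(self) -> int:
        n = sum(w1.size + w2.size + b.size for w1, w2, b in self.layers)
        n += self.layer_weights.size
        if self.input_proj is not None:
            n += self.input_proj.size
        return n


@dataclass
class BiLMParams:
    """Weights of a stacked bidirectional recurrent encoder.

    Forward and backward stacks are independent (unshared) parameter sets;
    every level shares the hidden width N so the per-level sums and the
    final weighted sum are well defined.
    """

    cell_type: str = "gru"
    forward_layers: list = field(default_factory=list)   # [(Wx, Wh, b), ...]
    backward_layers: list = field(default_factory=list)
    layer_weights: np.ndarray = None
    input_proj: np.ndarray | None = None
    include_input: bool = True

    @property
    def width(self) -> int:
        return self.forward_layers[0][1].shape[0]

    def n_parameters(self) -> int:
        n = self.layer_weights.size
        for layers in (self.forward_layers, self.backward_layers):
            n += sum(wx.size + wh.size + b.size for wx, wh, b in layers)
        if self.input_proj is not None:
            n += self.input_proj.size
        return n


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_gcn_params(d_in: int, width: int = 128, depth: int = 3,
                    rng=None, seed: int | None = None) -> GCNParams:
    """Glorot-initialized GCN encoder; c_i start at 1/(L+1)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    layers = []
    for _ in range(depth):
        layers.append((_glorot(rng, (width, width)),
                       _glorot(rng, (width, width)),
                       np.zeros(width)))
    proj = None if d_in == width else _glorot(rng, (d_in, width))
    c = np.full(depth + 1, 1.0 / (depth + 1))
    return GCNParams(layers=layers, layer_weights=c, input_proj=proj)


def init_bilm_params(d_in: int, width: int = 128, depth: int = 2,
                     cell_type: str = "gru", rng=None,
                     seed: int | None = None) -> BiLMParams:
    """Glorot-initialized BiLM encoder with unshared direction weights."""
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}")
    rng = np.random.default_rng(seed) if seed is not None or rng is None else rng
    g = _GATES[cell_type]

    def make_stack():
        return [(_glorot(rng, (width, g * width)),
                 _glorot(rng, (width, g * width)),
                 np.zeros(g * width))
                for _ in range(depth)]

    fwd, bwd = make_stack(), make_stack()
    proj = None if d_in == width else _glorot(rng, (d_in, width))
    c = np.full(depth + 1, 1.0 / (depth + 1))
    return BiLMParams(cell_type=cell_type, forward_layers=fwd,
                      backward_layers=bwd, layer_weights=c, input_proj=proj)


# ---------------------------------------------------------------------------
# Tensor-space forward passes (shared by inference and training)
# ---------------------------------------------------------------------------

def params_to_tensors(params, requires_grad: bool = False) -> dict:
    """Wrap a params dataclass in autodiff tensors that SHARE its buffers.

    In-place optimizer updates on the tensors therefore mutate the params
    object directly; saving the dataclass saves the trained weights.
    """

    def t(arr):
        arr = np.ascontiguousarray(arr, dtype=np.float64)
        return Tensor(arr, requires_grad=requires_grad)

    tree: dict = {"c": t(params.layer_weights),
                  "proj": t(params.input_proj) if params.input_proj is not None else None,
                  "include_input": params.include_input}
    if isinstance(params, GCNParams):
        tree["kind"] = "gcn"
        tree["layers"] = [tuple(t(a) for a in layer) for layer in params.layers]
    elif isinstance(params, BiLMParams):
        tree["kind"] = "bilm"
        tree["cell_type"] = params.cell_type
        tree["forward_layers"] = [tuple(t(a) for a in layer)
                                  for layer in params.forward_layers]
        tree["backward_layers"] = [tuple(t(a) for a in layer)
                                   for layer in params.backward_layers]
    else:
        raise TypeError(f"unknown params type: {type(params)}")
    return tree


def iter_param_tensors(tree: dict):
    yield tree["c"]
    if tree["proj"] is not None:
        yield tree["proj"]
    for key in ("layers", "forward_layers", "backward_layers"):
        for layer in tree.get(key, ()):
            yield from layer


def _weighted_layer_sum(levels: list, c: Tensor, include_input: bool) -> Tensor:
    start = 0 if include_input else 1
    total = None
    for i in range(start, len(levels)):
        term = c[i:i + 1] * levels[i]
        total = term if total is None else total + term
    return total


def gcn_forward(x: Tensor, abar: np.ndarray, tree: dict) -> Tensor:
    """Batched GCN encode: x (B, M, D), abar (B, M, M) -> (B, M, N)."""
    h = x if tree["proj"] is None else x @ tree["proj"]
    abar_t = Tensor(abar)
    levels = [h]
    for w1, w2, b in tree["layers"]:
        h = ((abar_t @ h) @ w1 + h @ w2 + b).tanh()
        levels.append(h)
    return _weighted_layer_sum(levels, tree["c"], tree["include_input"])


def _cell_step(cell_type: str, x_t: Tensor, h: Tensor, c_state, wx, wh, b, n: int):
    """One recurrent step on a (B, N) slice; returns (h', c_state')."""
    if cell_type == "rnn":
        return (x_t @ wx + h @ wh + b).tanh(), None
    pre_x = x_t @ wx + b
    pre_h = h @ wh
    if cell_type == "gru":
        r = (pre_x[:, :n] + pre_h[:, :n]).sigmoid()
        z = (pre_x[:, n:2 * n] + pre_h[:, n:2 * n]).sigmoid()
        cand = (pre_x[:, 2 * n:] + r * pre_h[:, 2 * n:]).tanh()
        one = Tensor(np.ones(1))
        return (one - z) * h + z * cand, None
    # lstm
    gates = pre_x + pre_h
    i = gates[:, :n].sigmoid()
    f = gates[:, n:2 * n].sigmoid()
    g = gates[:, 2 * n:3 * n].tanh()
    o = gates[:, 3 * n:].sigmoid()
    c_new = f * c_state + i * g
    return o * c_new.tanh(), c_new


def _run_direction(h_in: Tensor, layers, cell_type: str) -> list:
    """Run a stacked unidirectional recurrence over (B, T, N); list of levels."""
    b_sz, t_len, n = h_in.shape
    levels = []
    current = h_in
    for wx, wh, b in layers:
        h = Tensor(np.zeros((b_sz, n)))
        c_state = Tensor(np.zeros((b_sz, n))) if cell_type == "lstm" else None
        outs = []
        for t in range(t_len):
            x_t = current[:, t, :]
            h, c_state = _cell_step(cell_type, x_t, h, c_state, wx, wh, b, n)
            outs.append(h)
        current = stack(outs, axis=1)
        levels.append(current)
    return levels


def _reversal_indices(lengths: np.ndarray, t_len: int) -> np.ndarray:
    """Per-row index arrays that reverse the first `length` positions."""
    idx = np.tile(np.arange(t_len), (len(lengths), 1))
    for b, m in enumerate(lengths):
        idx[b, :m] = np.arange(m - 1, -1, -1)
    return idx


def bilm_forward(x: Tensor, lengths: np.ndarray, tree: dict) -> Tensor:
    """Batched BiLM encode: x (B, T, D), per-row valid lengths -> (B, T, N).

    Sequences shorter than T are padded on the right; the backward
    direction reverses each row individually so real positions never see
    padding.  Rows at padded positions are unspecified and must be masked
    by the caller.
    """
    h0 = x if tree["proj"] is None else x @ tree["proj"]
    t_len = h0.shape[1]
    rev_idx = _reversal_indices(np.asarray(lengths), t_len)
    cell_type = tree["cell_type"]

    fwd_levels = _run_direction(h0, tree["forward_layers"], cell_type)
    h0_rev = h0.gather_axis1(rev_idx)
    bwd_levels_rev = _run_direction(h0_rev, tree["backward_layers"], cell_type)
    # un-reverse (the per-row reversal is an involution)
    bwd_levels = [lvl.gather_axis1(rev_idx) for lvl in bwd_levels_rev]

    levels = [h0]
    for fwd, bwd in zip(fwd_levels, bwd_levels):
        levels.append(fwd + bwd)
    return _weighted_layer_sum(levels, tree["c"], tree["include_input"])


# ---------------------------------------------------------------------------
# Public single-molecule API
# ---------------------------------------------------------------------------

def gcn_layer(h: np.ndarray, graph: MolGraph, w1: np.ndarray,
              w2: np.ndarray, b: np.ndarray) -> np.ndarray:
    """One skip-connected GCN layer: tanh(Ā H W1 + H W2 + 1 bᵀ)."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[0] != graph.size:
        raise ValueError("H row count must equal graph size")
    if h.shape[1] != np.shape(w1)[0] or h.shape[1] != np.shape(w2)[0]:
        raise ValueError("weight shapes incompatible with H")
    abar = graph.normalized_adjacency()
    return np.tanh(abar @ h @ w1 + h @ w2 + np.asarray(b))


def gcn_encode(x: EmbeddedMolecule, params: GCNParams) -> FeatureTensor:
    """Encode one molecule with the stacked GCN; rows follow atom order."""
    tree = params_to_tensors(params)
    abar = x.graph.normalized_adjacency()[None, :, :]
    out = gcn_forward(Tensor(x.matrix[None, :, :]), abar, tree)
    return FeatureTensor(matrix=out.data[0])


def bilm_encode(x: EmbeddedMolecule, params: BiLMParams) -> FeatureTensor:
    """Encode one molecule with the BiLM; sequence order = canonical order."""
    tree = params_to_tensors(params)
    lengths = np.array([x.graph.size])
    out = bilm_forward(Tensor(x.matrix[None, :, :]), lengths, tree)
    return FeatureTensor(matrix=out.data[0])
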