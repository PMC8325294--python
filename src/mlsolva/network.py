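"""The assembled solvation network: embeddings, two encoders, interaction map.

A :class:`SolvationNet` owns an embedding matrix over a fixed token
vocabulary (plus one shared ``unk`` row), a solvent-side encoder and a
solute-side encoder (independent weights by default, optionally shared).
Its forward pass pads a mini-batch of molecule pairs to a common size,
encodes both sides, and reduces the pairwise interaction map to predicted
solvation free energies.  Because padded atom rows are masked out of the
molecular sums, batched predictions agree with unbatched ones to machine
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .embedding import EmbeddingTable
from .encoders import (BiLMParams, FeatureTensor, GCNParams, bilm_forward,
                       gcn_forward, init_bilm_params, init_gcn_params,
                       iter_param_tensors, params_to_tensors)
from .interaction import InteractionMap, interaction_map
from .molgraph import MolGraph


@dataclass
class PreparedGraph:
    """Index/mask arrays for one molecule, reusable across epochs."""

    idx_main: np.ndarray       # (M,) row into embedding matrix
    idx_aux: np.ndarray        # (M,) radius-0 row (unk row where inactive)
    aux_mask: np.ndarray       # (M,) 1.0 where the radius-0 vector is added
    abar: np.ndarray           # (M, M) normalized adjacency
    size: int


class SolvationNet:
    """Embedding + paired encoders + dot-product interaction read-out."""

    def __init__(self, vocab, embed_dim: int = 128, encoder_kind: str = "gcn",
                 width: int = 128, depth: int = 3, cell_type: str = "gru",
                 share_encoders: bool = False, combine_radii: bool = True,
                 table: EmbeddingTable | None = None,
                 trainable_embeddings: bool | None = None,
                 seed: int = 0):
        if encoder_kind not in ("gcn", "bilm"):
            raise ValueError("encoder_kind must be 'gcn' or 'bilm'")
        self.encoder_kind = encoder_kind
        self.cell_type = cell_type
        self.share_encoders = share_encoders
        self.combine_radii = combine_radii
        self.embed_dim = int(table.dim if table is not None else embed_dim)
        self.width = width
        self.depth = depth

        self.vocab = sorted(int(t) for t in vocab)
        self.token_index = {t: i for i, t in enumerate(self.vocab)}
        self.unk_index = len(self.vocab)

        rng = np.random.default_rng(seed)
        self.embeddings = np.empty((len(self.vocab) + 1, self.embed_dim))
        if table is not None:
            for tok, i in self.token_index.items():
                self.embeddings[i] = (table.vectors[tok] if tok in table
                                      else table.unk_vector)
            self.embeddings[self.unk_index] = table.unk_vector
            self.trainable_embeddings = (table.trainable
                                         if trainable_embeddings is None
                                         else trainable_embeddings)
            # tokens absent from a frozen table must hit the unk row exactly
            self._known = {tok for tok in self.vocab if tok in table}
        else:
            scale = 1.0 / np.sqrt(self.embed_dim)
            self.embeddings[:] = rng.normal(0.0, scale, self.embeddings.shape)
            self.trainable_embeddings = (True if trainable_embeddings is None
                                         else trainable_embeddings)
            self._known = set(self.vocab)

        if encoder_kind == "gcn":
            self.solvent_params = init_gcn_params(self.embed_dim, width, depth,
                                                  rng=rng)
            self.solute_params = (self.solvent_params if share_encoders else
                                  init_gcn_params(self.embed_dim, width, depth,
                                                  rng=rng))
        else:
            self.solvent_params = init_bilm_params(self.embed_dim, width, depth,
                                                   cell_type, rng=rng)
            self.solute_params = (self.solvent_params if share_encoders else
                                  init_bilm_params(self.embed_dim, width, depth,
                                                   cell_type, rng=rng))
        self._cache: dict[int, PreparedGraph] = {}

    # -- parameters ----------------------------------------------------------
    def parameter_tensors(self) -> tuple[Tensor, dict, dict]:
        """(embedding tensor, solvent tree, solute tree) sharing net buffers."""
        emb = Tensor(self.embeddings, requires_grad=self.trainable_embeddings)
        tree_a = params_to_tensors(self.solvent_params, requires_grad=True)
        tree_b = (tree_a if self.share_encoders else
                  params_to_tensors(self.solute_params, requires_grad=True))
        return emb, tree_a, tree_b

    def trainable_parameters(self, emb: Tensor, tree_a: dict, tree_b: dict):
        params = list(iter_param_tensors(tree_a))
        if not self.share_encoders:
            params += list(iter_param_tensors(tree_b))
        if self.trainable_embeddings:
            params.append(emb)
        return params

    def n_parameters(self) -> int:
        n = self.solvent_params.n_parameters()
        if not self.share_encoders:
            n += self.solute_params.n_parameters()
        if self.trainable_embeddings:
            n += self.embeddings.size
        return n

    # -- graph preparation ---------------------------------------------------
    def prepare(self, graph: MolGraph) -> PreparedGraph:
        # keyed by id() with a strong reference to the graph, so a freed
        # address can never alias a stale entry
        cached = self._cache.get(id(graph))
        if cached is not None and cached[0] is graph:
            return cached[1]
        m = graph.size
        idx_main = np.empty(m, dtype=np.intp)
        idx_aux = np.full(m, self.unk_index, dtype=np.intp)
        aux_mask = np.zeros(m)
        for i, tok in enumerate(graph.tokens):
            tok = int(tok)
            if tok in self._known:
                idx_main[i] = self.token_index[tok]
                if (self.combine_radii and graph.aux_tokens is not None):
                    aux = int(graph.aux_tokens[i])
                    if aux != tok and aux in self._known:
                        idx_aux[i] = self.token_index[aux]
                        aux_mask[i] = 1.0
            else:
                idx_main[i] = self.unk_index
        prepared = PreparedGraph(idx_main=idx_main, idx_aux=idx_aux,
                                 aux_mask=aux_mask,
                                 abar=graph.normalized_adjacency(), size=m)
        self._cache[id(graph)] = (graph, prepared)
        return prepared

    # -- forward -------------------------------------------------------------
    def _encode_side(self, emb: Tensor, tree: dict,
                     prepared: list[PreparedGraph]) -> tuple[Tensor, np.ndarray]:
        """Returns (P (B, M, N), pad mask (B, M)) for one side of a batch."""
        b = len(prepared)
        m_max = max(p.size for p in prepared)
        idx_main = np.full((b, m_max), self.unk_index, dtype=np.intp)
        idx_aux = np.full((b, m_max), self.unk_index, dtype=np.intp)
        aux_mask = np.zeros((b, m_max))
        pad_mask = np.zeros((b, m_max))
        abar = np.zeros((b, m_max, m_max))
        lengths = np.empty(b, dtype=np.intp)
        for k, p in enumerate(prepared):
            idx_main[k, :p.size] = p.idx_main
            idx_aux[k, :p.size] = p.idx_aux
            aux_mask[k, :p.size] = p.aux_mask
            pad_mask[k, :p.size] = 1.0
            abar[k, :p.size, :p.size] = p.abar
            lengths[k] = p.size
        x = emb.take_rows(idx_main) + aux_mask[:, :, None] * emb.take_rows(idx_aux)
        if self.encoder_kind == "gcn":
            feats = gcn_forward(x, abar, tree)
        else:
            feats = bilm_forward(x, lengths, tree)
        return feats, pad_mask

    def forward_batch(self, pairs, emb: Tensor, tree_a: dict,
                      tree_b: dict) -> Tensor:
        """Predicted ΔG°_sol for a batch of (solvent graph, solute graph)."""
        prep_a = [self.prepare(a) for a, _ in pairs]
        prep_b = [self.prepare(b) for _, b in pairs]
        feats_a, mask_a = self._encode_side(emb, tree_a, prep_a)
        feats_b, mask_b = self._encode_side(emb, tree_b, prep_b)
        u = (feats_a * mask_a[:, :, None]).sum(axis=1)
        v = (feats_b * mask_b[:, :, None]).sum(axis=1)
        return -(u * v).sum(axis=1)

    # -- inference -----------------------------------------------------------
    def predict_pairs(self, pairs, batch_size: int = 256) -> np.ndarray:
        emb, tree_a, tree_b = self.parameter_tensors()
        out = []
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            out.append(self.forward_batch(chunk, emb, tree_a, tree_b).data)
        return np.concatenate(out) if out else np.empty(0)

    def encode(self, graph: MolGraph, side: str = "solute") -> FeatureTensor:
        """Per-atom feature tensor of one molecule (P or Q)."""
        emb, tree_a, tree_b = self.parameter_tensors()
        tree = tree_a if side == "solvent" else tree_b
        feats, _ = self._encode_side(emb, tree, [self.prepare(graph)])
        return FeatureTensor(matrix=feats.data[0])

    def pair_interaction_map(self, solvent: MolGraph,
                             solute: MolGraph) -> InteractionMap:
        p = self.encode(solvent, side="solvent")
        q = self.encode(solute, side="solute")
        return interaction_map(p, q)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint to .npz; round-trips bit-exactly."""
        arrays = {"vocab": np.asarray(self.vocab, dtype=np.int64),
                  "embeddings": self.embeddings,
                  "known": np.asarray(sorted(self._known), dtype=np.int64)}
        config = {"encoder_kind": self.encoder_kind,
                  "cell_type": self.cell_type,
                  "share_encoders": self.share_encoders,
                  "combine_radii": self.combine_radii,
                  "embed_dim": self.embed_dim, "width": self.width,
                  "depth": self.depth,
                  "trainable_embeddings": self.trainable_embeddings}
        for prefix, params in (("a", self.solvent_params),
                               ("b", self.solute_params)):
            arrays[f"{prefix}_c"] = params.layer_weights
            if params.input_proj is not None:
                arrays[f"{prefix}_proj"] = params.input_proj
            layer_lists = ([("l", params.layers)]
                           if isinstance(params, GCNParams) else
                           [("f", params.forward_layers),
                            ("r", params.backward_layers)])
            for tag, layers in layer_lists:
                for i, triple in enumerate(layers):
                    for j, arr in enumerate(triple):
                        arrays[f"{prefix}_{tag}{i}_{j}"] = arr
        arrays["config_json"] = np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SolvationNet":
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        config = json.loads(bytes(arrays["config_json"]).decode())
        net = cls.__new__(cls)
        net.encoder_kind = config["encoder_kind"]
        net.cell_type = config["cell_type"]
        net.share_encoders = config["share_encoders"]
        net.combine_radii = config["combine_radii"]
        net.embed_dim = config["embed_dim"]
        net.width = config["width"]
        net.depth = config["depth"]
        net.trainable_embeddings = config["trainable_embeddings"]
        net.vocab = [int(t) for t in arrays["vocab"]]
        net.token_index = {t: i for i, t in enumerate(net.vocab)}
        net.unk_index = len(net.vocab)
        net.embeddings = arrays["embeddings"]
        net._known = {int(t) for t in arrays["known"]}
        net._cache = {}

        def load_params(prefix):
            c = arrays[f"{prefix}_c"]
            proj = arrays.get(f"{prefix}_proj")
            if config["encoder_kind"] == "gcn":
                layers = []
                i = 0
                while f"{prefix}_l{i}_0" in arrays:
                    layers.append(tuple(arrays[f"{prefix}_l{i}_{j}"]
                                        for j in range(3)))
                    i += 1
                return GCNParams(layers=layers, layer_weights=c,
                                 input_proj=proj)
            stacks = {}
            for tag in ("f", "r"):
                layers = []
                i = 0
                while f"{prefix}_{tag}{i}_0" in arrays:
                    layers.append(tuple(arrays[f"{prefix}_{tag}{i}_{j}"]
                                        for j in range(3)))
                    i += 1
                stacks[tag] = layers
            return BiLMParams(cell_type=config["cell_type"],
                              forward_layers=stacks["f"],
                              backward_layers=stacks["r"],
                              layer_weights=c, input_proj=proj)

        net.solvent_params = load_params("a")
        net.solute_params = (net.solvent_params if net.share_encoders
                             else load_params("b"))
        return net
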