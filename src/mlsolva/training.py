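"""Supervised training, RMSprop, cross-validation and metrics.

Training minimizes mean squared error plus an L2 penalty with RMSprop:

    G_t = ρ G_{t-1} + (1 − ρ) (∇_w L_t)²
    w_t = w_{t-1} − η ∇_w L_t / sqrt(G_t + ε)

Model assessment uses the mean unsigned error (MUE) and RMSE in kcal/mol.
Fold construction supports uniform random splits and scaffold-based splits
(K-means on MACCS substructure fingerprints of the distinct compounds on
one side, so no compound ever straddles folds).  Nested cross-validation
runs an inner hyperparameter-selection loop inside every outer fold and is
structurally leakage-free; it can be repeated from shifted seeds and
aggregated, re-randomizing both fold membership and weight initialization
per repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit.Chem import MACCSkeys
from sklearn.cluster import KMeans

from .embedding import EmbeddingTable
from .molgraph import Molecule, _rdkit_mol, record_graphs
from .network import SolvationNet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of one supervised training run."""

    learning_rate: float = 0.01
    lr_decay: float = 1.0      # multiplicative per-epoch decay (1.0 = none)
    rmsprop_rho: float = 0.9
    rmsprop_epsilon: float = 1e-8
    l2_lambda: float = 0.0
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    encoder_kind: str = "gcn"
    cell_type: str = "gru"
    width: int = 128
    depth: int = 3
    embed_dim: int = 128
    share_encoders: bool = False
    combine_radii: bool = True
    radius: int = 1
    early_stopping_patience: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must be in (0, 1]")
        if not (0.0 <= self.rmsprop_rho < 1.0):
            raise ValueError("rmsprop_rho must be in [0, 1)")
        if self.rmsprop_epsilon <= 0:
            raise ValueError("rmsprop_epsilon must be > 0")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass
class OptimizerState:
    """Per-parameter RMSprop state: moving average of squared gradients."""

    avg_sq: np.ndarray
    t: int = 0


def loss(predictions, targets, params=(), l2_lambda: float = 0.0) -> float:
    """MSE over the batch plus l2_lambda · Σ params²."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    if predictions.size == 0:
        raise ValueError("empty batch")
    mse = float(np.mean((predictions - targets) ** 2))
    penalty = l2_lambda * sum(float(np.sum(np.asarray(p) ** 2)) for p in params)
    return mse + penalty


def rmsprop_step(w: np.ndarray, grad: np.ndarray, state: OptimizerState,
                 cfg: TrainConfig) -> tuple[np.ndarray, OptimizerState]:
    """One RMSprop descent update; returns the new weights and state."""
    w = np.asarray(w, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    if w.shape != grad.shape or w.shape != state.avg_sq.shape:
        raise ValueError("weight/gradient/state shapes must match")
    rho = cfg.rmsprop_rho
    avg_sq = rho * state.avg_sq + (1.0 - rho) * grad ** 2
    w_new = w - cfg.learning_rate * grad / np.sqrt(avg_sq + cfg.rmsprop_epsilon)
    return w_new, OptimizerState(avg_sq=avg_sq, t=state.t + 1)


class _RMSprop:
    """Applies rmsprop_step in place to a list of autodiff tensors."""

    def __init__(self, tensors, cfg: TrainConfig):
        self.tensors = list(tensors)
        self.cfg = cfg
        self.states = [OptimizerState(avg_sq=np.zeros_like(t.data))
                       for t in self.tensors]

    def step(self):
        for i, tensor in enumerate(self.tensors):
            new_w, self.states[i] = rmsprop_step(tensor.data, tensor.grad,
                                                 self.states[i], self.cfg)
            tensor.data[...] = new_w
            tensor.grad = None


@dataclass
class TrainResult:
    """A trained network plus its training trace and configuration."""

    net: SolvationNet
    config: TrainConfig
    loss_trace: list
    final_train_mue: float
    final_train_rmse: float

    def predict(self, records) -> np.ndarray:
        pairs = [record_graphs(r, self.config.radius) for r in records]
        return self.net.predict_pairs(pairs)


def train(records, config: TrainConfig,
          table: EmbeddingTable | None = None,
          validation_records=None) -> TrainResult:
    """Train a solvation network on records; deterministic per config.seed."""
    records = list(records)
    if not records:
        raise ValueError("need at least one training record")
    pairs = [record_graphs(r, config.radius) for r in records]
    targets = np.array([r.dg_sol for r in records])

    vocab: set[int] = set()
    for a, b in pairs:
        vocab.update(int(t) for t in a.tokens)
        vocab.update(int(t) for t in b.tokens)
        for g in (a, b):
            if g.aux_tokens is not None:
                vocab.update(int(t) for t in g.aux_tokens)
    if table is not None:
        vocab.update(table.vectors.keys())

    net = SolvationNet(vocab=vocab, embed_dim=config.embed_dim,
                       encoder_kind=config.encoder_kind, width=config.width,
                       depth=config.depth, cell_type=config.cell_type,
                       share_encoders=config.share_encoders,
                       combine_radii=config.combine_radii, table=table,
                       seed=config.seed)

    emb, tree_a, tree_b = net.parameter_tensors()
    trainables = net.trainable_parameters(emb, tree_a, tree_b)
    optimizer = _RMSprop(trainables, config)
    rng = np.random.default_rng(config.seed + 1)

    n = len(records)
    loss_trace: list[float] = []
    best_val, patience_left = np.inf, config.early_stopping_patience
    for epoch in range(config.epochs):
        if config.lr_decay < 1.0:
            optimizer.cfg = replace(
                config,
                learning_rate=config.learning_rate * config.lr_decay ** epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            preds = net.forward_batch([pairs[i] for i in idx],
                                      emb, tree_a, tree_b)
            err = preds - targets[idx]
            batch_loss = (err * err).mean()
            if config.l2_lambda > 0:
                for p in trainables:
                    batch_loss = batch_loss + config.l2_lambda * (p * p).sum()
            value = float(batch_loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {value}; "
                    f"lr={config.learning_rate}, width={config.width}")
            batch_loss.backward()
            optimizer.step()
            epoch_loss += value * len(idx)
        loss_trace.append(epoch_loss / n)
        if validation_records is not None and config.early_stopping_patience:
            val_pairs = [record_graphs(r, config.radius)
                         for r in validation_records]
            val_pred = net.predict_pairs(val_pairs)
            val_mue = float(np.mean(np.abs(
                val_pred - np.array([r.dg_sol for r in validation_records]))))
            if val_mue < best_val - 1e-12:
                best_val, patience_left = val_mue, config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stop at epoch %d (val MUE %.4f)",
                                epoch, best_val)
                    break

    if table is not None and net.trainable_embeddings:
        for tok, i in net.token_index.items():
            table.vectors[tok] = net.embeddings[i].copy()
        table.unk_vector = net.embeddings[net.unk_index].copy()

    final_pred = net.predict_pairs(pairs)
    residuals = final_pred - targets
    return TrainResult(net=net, config=config, loss_trace=loss_trace,
                       final_train_mue=float(np.mean(np.abs(residuals))),
                       final_train_rmse=float(np.sqrt(np.mean(residuals ** 2))))


def evaluate(model, records) -> dict:
    """MUE/RMSE (kcal/mol) and per-record residuals of a trained model."""
    records = list(records)
    if not records:
        raise ValueError("cannot evaluate on an empty record set")
    if isinstance(model, TrainResult):
        preds = model.predict(records)
    else:
        pairs = [record_graphs(r) for r in records]
        preds = model.predict_pairs(pairs)
    targets = np.array([r.dg_sol for r in records])
    residuals = preds - targets
    return {"mue": float(np.mean(np.abs(residuals))),
            "rmse": float(np.sqrt(np.mean(residuals ** 2))),
            "residuals": residuals}


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    mode: str
    labels: np.ndarray
    k: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if np.any(self.labels < 0) or np.any(self.labels >= self.k):
            raise ValueError("fold labels out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.labels == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.labels != fold)[0]


def random_folds(records, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition into k folds with sizes differing by ≤ 1."""
    n = len(records)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.intp)
    labels[rng.permutation(n)] = np.arange(n) % k
    return FoldAssignment(mode="random-uniform", labels=labels, k=k)


def maccs_fingerprint(mol: Molecule) -> np.ndarray:
    """166-bit MACCS substructure key vector (0/1)."""
    keys = MACCSkeys.GenMACCSKeys(_rdkit_mol(mol))
    bits = np.zeros(167, dtype=np.float64)
    bits[list(keys.GetOnBits())] = 1.0
    return bits[1:]  # bit 0 of the RDKit vector is unused padding


def scaffold_folds(records, k: int, on: str = "solute",
                   seed: int = 0) -> FoldAssignment:
    """K-means clusters on MACCS fingerprints of distinct compounds.

    Every record follows its compound's cluster, so all measurements of one
    compound share a fold and test folds contain unseen chemotypes.
    """
    if on not in ("solvent", "solute"):
        raise ValueError("on must be 'solvent' or 'solute'")
    side = [getattr(r, on) for r in records]
    distinct: dict[str, Molecule] = {}
    for mol in side:
        distinct.setdefault(mol.smiles, mol)
    if len(distinct) < k:
        raise ValueError(
            f"only {len(distinct)} distinct {on} compounds for k={k}")
    smiles_list = sorted(distinct)
    fps = np.array([maccs_fingerprint(distinct[s]) for s in smiles_list])
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    clusters = km.fit_predict(fps)
    cluster_of = dict(zip(smiles_list, clusters))
    labels = np.array([cluster_of[mol.smiles] for mol in side], dtype=np.intp)
    return FoldAssignment(mode=f"scaffold-{on}", labels=labels, k=k)


def make_folds(records, k: int, mode: str, seed: int) -> FoldAssignment:
    if mode == "random":
        return random_folds(records, k, seed)
    if mode in ("scaffold-solvent", "scaffold-solute"):
        return scaffold_folds(records, k, on=mode.split("-")[1], seed=seed)
    raise ValueError(f"unknown split mode: {mode!r}")


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    repeat: int
    outer_fold: int
    mue: float
    rmse: float
    selected: dict
    n_test: int
    test_indices: list = field(default_factory=list)
    residuals: np.ndarray | None = None


@dataclass
class CVReport:
    """Per-fold and aggregate metrics of repeated nested cross-validation."""

    folds: list
    outer_k: int
    inner_k: int
    repeats: int
    mode: str

    def _per_repeat(self, attr: str) -> np.ndarray:
        out = []
        for r in range(self.repeats):
            vals = [f for f in self.folds if f.repeat == r]
            out.append(float(np.mean([getattr(f, attr) for f in vals])))
        return np.array(out)

    def _pooled_mue_per_repeat(self) -> np.ndarray:
        out = []
        for r in range(self.repeats):
            res = np.concatenate([f.residuals for f in self.folds
                                  if f.repeat == r])
            out.append(float(np.mean(np.abs(res))))
        return np.array(out)

    def aggregates(self) -> dict:
        mue = self._per_repeat("mue")
        rmse = self._per_repeat("rmse")
        pooled = self._pooled_mue_per_repeat()
        return {"mue_mean": float(mue.mean()), "mue_sd": float(mue.std()),
                "rmse_mean": float(rmse.mean()), "rmse_sd": float(rmse.std()),
                "pooled_mue_mean": float(pooled.mean()),
                "pooled_mue_sd": float(pooled.std())}

    def to_dict(self) -> dict:
        return {"outer_k": self.outer_k, "inner_k": self.inner_k,
                "repeats": self.repeats, "mode": self.mode,
                "aggregates": self.aggregates(),
                "folds": [{"repeat": f.repeat, "outer_fold": f.outer_fold,
                           "mue": f.mue, "rmse": f.rmse,
                           "selected": f.selected, "n_test": f.n_test}
                          for f in self.folds]}


def _candidate_size(base: TrainConfig, candidate: dict, n_tokens: int) -> int:
    """Rough trainable-parameter count used only for tie-breaking."""
    cfg = replace(base, **candidate)
    w, d = cfg.width, cfg.depth
    per_layer = 2 * w * w + w
    if cfg.encoder_kind == "bilm":
        gates = {"rnn": 1, "gru": 3, "lstm": 4}[cfg.cell_type]
        per_layer = 2 * (gates * (2 * w * w + w))
    encoders = 1 if cfg.share_encoders else 2
    n = encoders * (d * per_layer + d + 1)
    if cfg.embed_dim != w:
        n += encoders * cfg.embed_dim * w
    return n + n_tokens * cfg.embed_dim


def _assert_leakage_free(train_idx, test_idx, n: int):
    train_set, test_set = set(train_idx.tolist()), set(test_idx.tolist())
    if train_set & test_set:
        raise AssertionError("outer train/test overlap detected")
    if train_set | test_set != set(range(n)):
        raise AssertionError("outer folds do not cover the dataset")


def nested_cv(records, outer_k: int = 5, inner_k: int = 4, repeats: int = 1,
              hyper_space=None, folds_mode: str = "random",
              base_seed: int = 0, base_config: TrainConfig | None = None,
              table: EmbeddingTable | None = None) -> CVReport:
    """Repeated nested CV: inner loop selects hyperparameters, outer evaluates.

    ``hyper_space`` is a list of dicts of TrainConfig overrides; selection
    is by mean inner-validation MUE, with ties broken by smaller model then
    lower candidate index.  Each repeat r reseeds both the folds and the
    weight initialization from ``base_seed + r``.
    """
    records = list(records)
    if not hyper_space:
        raise ValueError("hyper_space must contain at least one candidate")
    if base_config is None:
        base_config = TrainConfig()
    n = len(records)
    folds_results: list[FoldResult] = []

    for r in range(repeats):
        seed_r = base_seed + r
        outer = make_folds(records, outer_k, folds_mode, seed_r)
        for ofold in range(outer_k):
            test_idx = outer.test_indices(ofold)
            train_idx = outer.train_indices(ofold)
            _assert_leakage_free(train_idx, test_idx, n)
            if len(test_idx) == 0:
                continue
            outer_train = [records[i] for i in train_idx]
            # inner loop: plain random k-fold over the outer-training split
            inner = random_folds(outer_train, min(inner_k, len(outer_train)),
                                 seed=seed_r * 1000 + ofold)
            scores = []
            for cand_idx, candidate in enumerate(hyper_space):
                cfg = replace(base_config, **candidate,
                              seed=seed_r * 100 + ofold)
                inner_mues = []
                for ifold in range(inner.k):
                    it_idx = inner.train_indices(ifold)
                    iv_idx = inner.test_indices(ifold)
                    assert not (set(it_idx.tolist()) & set(iv_idx.tolist()))
                    result = train([outer_train[i] for i in it_idx], cfg,
                                   table=table)
                    metrics = evaluate(result, [outer_train[i] for i in iv_idx])
                    inner_mues.append(metrics["mue"])
                size = _candidate_size(base_config, candidate, n_tokens=50)
                scores.append((float(np.mean(inner_mues)), size, cand_idx))
            best_mue, _, best_idx = min(scores)
            winner = hyper_space[best_idx]
            cfg = replace(base_config, **winner, seed=seed_r * 100 + ofold)
            final = train(outer_train, cfg, table=table)
            test_records = [records[i] for i in test_idx]
            metrics = evaluate(final, test_records)
            folds_results.append(FoldResult(
                repeat=r, outer_fold=ofold, mue=metrics["mue"],
                rmse=metrics["rmse"],
                selected={"candidate_index": best_idx,
                          "inner_mue": best_mue, **winner},
                n_test=len(test_idx), test_indices=test_idx.tolist(),
                residuals=metrics["residuals"]))
    return CVReport(folds=folds_results, outer_k=outer_k, inner_k=inner_k,
                    repeats=repeats, mode=folds_mode)
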