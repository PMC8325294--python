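"""High-level modelling interface: SolvationModel.fit() -> SolvationResults.

This mirrors the fit/results split of mainstream statistical packages: the
model object holds data and configuration, ``fit`` trains the network and
returns a results object carrying the learned weights, the training trace,
goodness-of-fit metrics, and interpretation helpers (interaction maps and
per-atom group contributions).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import interaction, molgraph
from .embedding import EmbeddingTable
from .molgraph import Molecule, SolvationRecord, build_graph
from .network import SolvationNet
from .training import TrainConfig, evaluate, train


def _as_molecule(obj) -> Molecule:
    if isinstance(obj, Molecule):
        return obj
    if isinstance(obj, str):
        return molgraph.parse_smiles(obj)
    raise TypeError(f"expected SMILES or Molecule, got {type(obj)}")


def records_from_dataframe(df: pd.DataFrame) -> list:
    """Build records from a DataFrame with the generic dataset columns."""
    required = {"solute_smiles", "dg_kcal_mol"}
    if not required <= set(df.columns):
        raise ValueError(f"dataframe must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        solvent = getattr(row, "solvent_smiles", "O")
        records.append(SolvationRecord(
            solvent=molgraph.parse_smiles(str(solvent)),
            solute=molgraph.parse_smiles(str(row.solute_smiles)),
            dg_sol=float(row.dg_kcal_mol)))
    return records


class SolvationModel:
    """A pairwise-interaction solvation free energy model over records.

    Parameters
    ----------
    records : list of SolvationRecord
        Supervised (solvent, solute, ΔG°_sol) examples.
    encoder : {"gcn", "bilm"}
        Architecture of both encoders.
    config : TrainConfig, optional
        Full hyperparameter set; keyword overrides win over it.
    embedding_table : EmbeddingTable, optional
        Pretrained token embeddings (frozen unless marked trainable);
        by default a trainable randomly initialized table is used.
    """

    def __init__(self, records, encoder: str = "gcn",
                 config: TrainConfig | None = None,
                 embedding_table: EmbeddingTable | None = None,
                 **overrides):
        self.records = list(records)
        if not self.records:
            raise ValueError("need at least one record")
        base = config if config is not None else TrainConfig()
        self.config = replace(base, encoder_kind=encoder, **overrides)
        self.embedding_table = embedding_table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SolvationModel":
        return cls(records_from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, dialect: str = "generic",
                 **kwargs) -> "SolvationModel":
        return cls(molgraph.read_dataset(path, dialect=dialect), **kwargs)

    def fit(self, seed: int | None = None, **overrides) -> "SolvationResults":
        cfg = self.config
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            cfg = replace(cfg, **overrides)
        result = train(self.records, cfg, table=self.embedding_table)
        return SolvationResults(self, result)


class SolvationResults:
    """Fitted solvation model: weights, fit diagnostics, interpretation."""

    def __init__(self, model: SolvationModel, train_result):
        self.model = model
        self._train_result = train_result
        self.net: SolvationNet = train_result.net
        self.config: TrainConfig = train_result.config
        self.loss_trace = np.asarray(train_result.loss_trace)
        self.mue = train_result.final_train_mue
        self.rmse = train_result.final_train_rmse

    # -- prediction ----------------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.records)

    @property
    def resid(self) -> np.ndarray:
        targets = np.array([r.dg_sol for r in self.model.records])
        return self.fittedvalues - targets

    def predict(self, data) -> np.ndarray:
        """Predict ΔG°_sol (kcal/mol) for records, a DataFrame, or pairs."""
        if isinstance(data, pd.DataFrame):
            pairs = [(str(getattr(row, "solvent_smiles", "O")),
                      str(row.solute_smiles))
                     for row in data.itertuples(index=False)]
            data = [SolvationRecord(solvent=_as_molecule(a),
                                    solute=_as_molecule(b), dg_sol=0.0)
                    for a, b in pairs]
        return self._train_result.predict(list(data))

    def predict_pair(self, solvent, solute) -> float:
        imap = self.interaction_map(solvent, solute)
        return interaction.solvation_energy(imap)

    def evaluate(self, records) -> dict:
        """MUE/RMSE/residuals on held-out records."""
        return evaluate(self._train_result, records)

    # -- interpretation ------------------------------------------------------
    def _pair_graphs(self, solvent, solute):
        radius = self.config.radius
        if isinstance(solvent, molgraph.MolGraph):
            graph_a = solvent
        else:
            graph_a = build_graph(_as_molecule(solvent), radius)
        if isinstance(solute, molgraph.MolGraph):
            graph_b = solute
        else:
            graph_b = build_graph(_as_molecule(solute), radius)
        return graph_a, graph_b

    def interaction_map(self, solvent, solute) -> interaction.InteractionMap:
        """Full M_a × M_b pairwise interaction map of one pair."""
        graph_a, graph_b = self._pair_graphs(solvent, solute)
        return self.net.pair_interaction_map(graph_a, graph_b)

    def group_contributions(self, solvent, solute) -> pd.DataFrame:
        """Per-solute-atom contributions (canonical order, kcal/mol)."""
        graph_a, graph_b = self._pair_graphs(solvent, solute)
        imap = self.net.pair_interaction_map(graph_a, graph_b)
        contrib = interaction.group_contributions(imap)
        elements = (list(graph_b.elements) if graph_b.elements
                    else [""] * graph_b.size)
        return pd.DataFrame({
            "atom_index": np.arange(graph_b.size),
            "element": elements,
            "token": graph_b.tokens,
            "contribution_kcal_mol": contrib,
        })

    def molecular_features(self, solvent, solute) -> interaction.MolecularFeatures:
        graph_a, graph_b = self._pair_graphs(solvent, solute)
        p = self.net.encode(graph_a, side="solvent")
        q = self.net.encode(graph_b, side="solute")
        return interaction.molecular_features(p, q)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Solvation interaction model",
            "=" * 47,
            f"{'Encoder:':<28}{cfg.encoder_kind}"
            + (f" ({cfg.cell_type})" if cfg.encoder_kind == "bilm" else ""),
            f"{'Hidden width / depth:':<28}{cfg.width} / {cfg.depth}",
            f"{'Embedding dim:':<28}{cfg.embed_dim}",
            f"{'Trainable parameters:':<28}{self.net.n_parameters()}",
            f"{'Records:':<28}{len(self.model.records)}",
            f"{'Epochs:':<28}{len(self.loss_trace)}",
            f"{'Final train loss (MSE):':<28}{self.loss_trace[-1]:.6f}",
            f"{'Train MUE (kcal/mol):':<28}{self.mue:.4f}",
            f"{'Train RMSE (kcal/mol):':<28}{self.rmse:.4f}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.net.save(path)
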