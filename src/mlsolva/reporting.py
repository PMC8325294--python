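"""Exports for interpretation: 2-D projections of molecular feature vectors.

For a list of solutes, computes the encoded molecular feature vector v
(column sum of Q) and the pre-encoder embedding sum Σ_β y_β, projects each
set to two dimensions with seeded t-SNE, and attaches the predicted
hydration free energy.  A strong organisation of the v-projection by ΔG —
absent from the raw-embedding projection — is the signature that the
encoder, not the input embedding, carries the solvation-relevant features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .interaction import molecular_features
from .model import SolvationResults, _as_molecule
from .molgraph import build_graph


def tsne_project(matrix: np.ndarray, seed: int = 0, perplexity: float = 30.0,
                 n_iter: int = 1000) -> np.ndarray:
    """Seeded 2-D t-SNE; perplexity is clipped to the sample count."""
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 molecules to project")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
                random_state=seed, init="pca")
    return tsne.fit_transform(matrix)


def feature_projections(results: SolvationResults, molecules,
                        solvent="O", seed: int = 0,
                        perplexity: float = 30.0,
                        n_iter: int = 1000) -> pd.DataFrame:
    """Projections of encoded (v) and pre-encoder (Σ y_β) molecular vectors.

    Returns one row per molecule: 2-D coordinates of both projections plus
    the predicted solvation free energy in the given solvent.
    """
    mols = [_as_molecule(m) for m in molecules]
    if len(mols) < 3:
        raise ValueError("need at least 3 molecules to project")
    radius = results.config.radius
    graphs = [build_graph(m, radius) for m in mols]
    solvent_graph = build_graph(_as_molecule(solvent), radius)
    p_solvent = results.net.encode(solvent_graph, side="solvent")

    encoded, raw, dg = [], [], []
    for graph in graphs:
        q = results.net.encode(graph, side="solute")
        feats = molecular_features(p_solvent, q)
        encoded.append(feats.v)
        dg.append(feats.energy_from_features)
        # pre-encoder sum: embedding rows straight from the lookup matrix
        prep = results.net.prepare(graph)
        emb = results.net.embeddings
        rows = emb[prep.idx_main] + prep.aux_mask[:, None] * emb[prep.idx_aux]
        raw.append(rows.sum(axis=0))

    coords_v = tsne_project(np.array(encoded), seed=seed,
                            perplexity=perplexity, n_iter=n_iter)
    coords_y = tsne_project(np.array(raw), seed=seed,
                            perplexity=perplexity, n_iter=n_iter)
    return pd.DataFrame({
        "smiles": [m.smiles for m in mols],
        "v_tsne_x": coords_v[:, 0], "v_tsne_y": coords_v[:, 1],
        "y_tsne_x": coords_y[:, 0], "y_tsne_y": coords_y[:, 1],
        "dg_pred_kcal_mol": dg,
    })
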