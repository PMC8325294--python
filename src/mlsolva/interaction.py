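"""Pairwise interaction map, solvation energy, and group contributions.

The model writes the solvation free energy of a solvent–solute pair as a
sum of pairwise atomistic terms obtained from unnormalized dot-product
attention between encoded atom features:

    I[α, β] = −p_α · q_β          (kcal/mol per atom pair)
    ΔG°_sol = Σ_α Σ_β I[α, β]

Column sums of the map give per-solute-atom group contributions; row sums
give the solvent-side mirror.  The same energy is available from molecular
feature vectors u = Σ_α p_α and v = Σ_β q_β as ΔG = −u·v.

Sign convention: the per-pair terms carry the minus sign, and the
feature-vector route uses −u·v so that both routes agree identically; the
global sign is absorbable into learned encoder weights, so training is
indifferent to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import FeatureTensor


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, FeatureTensor):
        return x.matrix
    return np.asarray(x, dtype=np.float64)


@dataclass
class InteractionMap:
    """M_a × M_b matrix of pairwise solvent-atom/solute-atom terms."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("interaction map must be 2-D")

    @property
    def solvent_size(self) -> int:
        return self.matrix.shape[0]

    @property
    def solute_size(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MolecularFeatures:
    """Molecular feature vectors: u (solvent) and v (solute) column sums."""

    u: np.ndarray
    v: np.ndarray

    @property
    def energy_from_features(self) -> float:
        """ΔG°_sol computed on the molecular-feature route, −u·v."""
        return float(-np.dot(self.u, self.v))


def interaction_map(P, Q) -> InteractionMap:
    """I = −P Qᵀ, the pairwise interaction (unnormalized attention) map."""
    P, Q = _as_matrix(P), _as_matrix(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError(
            f"feature widths differ: solvent {P.shape[1]} vs solute {Q.shape[1]}")
    return InteractionMap(matrix=-(P @ Q.T))


def solvation_energy(imap: InteractionMap) -> float:
    """ΔG°_sol = Σ_α Σ_β I[α, β], kcal/mol."""
    return float(imap.matrix.sum())


def molecular_features(P, Q) -> MolecularFeatures:
    """Column sums u = Σ_α p_α and v = Σ_β q_β."""
    P, Q = _as_matrix(P), _as_matrix(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError("feature widths differ")
    return MolecularFeatures(u=P.sum(axis=0), v=Q.sum(axis=0))


def group_contributions(imap: InteractionMap) -> np.ndarray:
    """Per-solute-atom contributions I_β = Σ_α I[α, β]; sums to ΔG°_sol."""
    return imap.matrix.sum(axis=0)


def solvent_side_contributions(imap: InteractionMap) -> np.ndarray:
    """Per-solvent-atom row sums; the interpretability mirror of I_β."""
    return imap.matrix.sum(axis=1)
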