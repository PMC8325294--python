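"""Synthetic solvation datasets with a known pairwise-additive ground truth.

Each latent atom type t carries a solvent-role vector φ_t and a solute-role
vector ψ_t; the noiseless energy of a solvent–solute pair is the double sum
of −φ·ψ over atom pairs, i.e. exactly the additive structure the model
expresses through its interaction map.  A sufficiently wide GCN therefore
must drive the noiseless training error toward zero, and the stored true
per-solute-atom contributions let tests check that learned group
contributions recover the planted ones.

Molecules are connected graphs (paths, cycles or random trees) whose atom
tokens are the latent type ids directly; in ``smiles_mode`` each type maps
to an element of a fixed fragment alphabet instead and records carry valid
SMILES, which exercises the full RDKit pipeline (at the price of exact
representability, since Morgan tokens are finer than the latent types).

In ``hard_mode``, an atom's effective latent vectors are shifted by the
mean of a second per-type table over its bonded neighbours, making true
contributions environment-dependent: a model that ignores connectivity
cannot represent them, whereas one GCN message-passing hop can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molgraph import (ELEMENT_VALENCE, MolGraph, Molecule, SolvationRecord,
                       parse_smiles)

DEFAULT_ALPHABET = ("C", "N", "O", "S", "P", "F")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic data-generating process.

    The per-type latent tables (phi, psi and the hard-mode neighbour
    tables) are drawn once from ``seed`` and are part of the spec's
    identity; redrawing them would define a different ground truth.
    """

    n_atom_types: int = 6
    latent_dim: int = 8
    molecule_size_range: tuple = (1, 9)
    topology: str = "mixed"          # {path, cycle, random-tree, mixed}
    noise_sd: float = 0.0            # kcal/mol
    seed: int = 0
    smiles_mode: bool = False
    element_alphabet: tuple = DEFAULT_ALPHABET
    hard_mode: bool = False
    neighbor_coupling: float = 0.5   # strength of hard-mode environment term
    phi: np.ndarray | None = field(default=None, repr=False)
    psi: np.ndarray | None = field(default=None, repr=False)
    phi_nb: np.ndarray | None = field(default=None, repr=False)
    psi_nb: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        lo, hi = self.molecule_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid molecule_size_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.topology not in ("path", "cycle", "random-tree", "mixed"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.smiles_mode and self.n_atom_types > len(self.element_alphabet):
            raise ValueError("smiles_mode needs one element per atom type")
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(self.latent_dim)
        shape = (self.n_atom_types, self.latent_dim)
        for name in ("phi", "psi", "phi_nb", "psi_nb"):
            if getattr(self, name) is None:
                setattr(self, name, rng.normal(0.0, scale, shape))
            else:
                arr = np.asarray(getattr(self, name), dtype=np.float64)
                if arr.shape != shape:
                    raise ValueError(f"{name} must have shape {shape}")
                setattr(self, name, arr)


def _sample_topology(spec: SyntheticSpec, size: int, rng) -> np.ndarray:
    """Connected adjacency matrix of the requested family."""
    topology = spec.topology
    if topology == "mixed":
        topology = rng.choice(["path", "cycle", "random-tree"])
    adjacency = np.zeros((size, size))
    if size == 1:
        return adjacency
    if topology == "cycle" and size >= 3:
        for i in range(size):
            j = (i + 1) % size
            adjacency[i, j] = adjacency[j, i] = 1.0
        return adjacency
    if topology == "random-tree" and size > 2:
        # random attachment with a degree cap so smiles_mode stays valid
        cap = 4
        for i in range(1, size):
            choices = [j for j in range(i)
                       if adjacency[j].sum() < cap]
            parent = int(rng.choice(choices))
            adjacency[i, parent] = adjacency[parent, i] = 1.0
        return adjacency
    # path (also the fallback for tiny cycles/trees)
    for i in range(size - 1):
        adjacency[i, i + 1] = adjacency[i + 1, i] = 1.0
    return adjacency


def _sample_types(spec: SyntheticSpec, adjacency: np.ndarray, rng,
                  type_subset=None) -> np.ndarray:
    allowed = np.arange(spec.n_atom_types) if type_subset is None \
        else np.asarray(sorted(type_subset))
    size = adjacency.shape[0]
    if not spec.smiles_mode:
        return rng.choice(allowed, size=size)
    degrees = adjacency.sum(axis=1)
    types = np.empty(size, dtype=np.int64)
    for i in range(size):
        ok = [t for t in allowed
              if ELEMENT_VALENCE[spec.element_alphabet[t]] >= degrees[i]]
        if not ok:  # pragma: no cover - degree cap keeps carbon available
            ok = [t for t in allowed
                  if spec.element_alphabet[t] == "C"]
        types[i] = rng.choice(ok)
    return types


def sample_molecule(spec: SyntheticSpec, rng, type_subset=None) -> MolGraph:
    """Sample one connected molecule; tokens are the latent type ids."""
    lo, hi = spec.molecule_size_range
    size = int(rng.integers(lo, hi + 1))
    adjacency = _sample_topology(spec, size, rng)
    types = _sample_types(spec, adjacency, rng, type_subset)
    elements = tuple(spec.element_alphabet[t % len(spec.element_alphabet)]
                     for t in types)
    return MolGraph(tokens=types, adjacency=adjacency, elements=elements)


def _effective_latents(graph: MolGraph, table: np.ndarray,
                       nb_table: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Per-atom latent vectors, with hard-mode neighbour shifts if enabled."""
    types = graph.tokens
    vectors = table[types].astype(np.float64)
    if spec.hard_mode:
        adjacency = graph.adjacency
        degrees = adjacency.sum(axis=1)
        nb_mean = adjacency @ nb_table[types]
        nz = degrees > 0
        nb_mean[nz] /= degrees[nz, None]
        vectors = vectors + spec.neighbor_coupling * nb_mean
    return vectors


def pair_energy_matrix(solvent: MolGraph, solute: MolGraph,
                       spec: SyntheticSpec) -> np.ndarray:
    """Noiseless per-pair energy terms, −φ_eff[α]·ψ_eff[β] (M_a × M_b)."""
    for g in (solvent, solute):
        if np.any(g.tokens < 0) or np.any(g.tokens >= spec.n_atom_types):
            raise ValueError("atom type outside the spec's type set")
    phi_eff = _effective_latents(solvent, spec.phi, spec.phi_nb, spec)
    psi_eff = _effective_latents(solute, spec.psi, spec.psi_nb, spec)
    return -(phi_eff @ psi_eff.T)


def ground_truth_energy(solvent: MolGraph, solute: MolGraph,
                        spec: SyntheticSpec, rng=None) -> float:
    """ΔG = Σ_αβ −φ·ψ plus Gaussian noise of spec.noise_sd (if rng given)."""
    value = float(pair_energy_matrix(solvent, solute, spec).sum())
    if rng is not None and spec.noise_sd > 0:
        value += float(rng.normal(0.0, spec.noise_sd))
    return value


def true_solute_contributions(solvent: MolGraph, solute: MolGraph,
                              spec: SyntheticSpec) -> np.ndarray:
    """Planted per-solute-atom contributions (column sums; sum = noiseless ΔG)."""
    return pair_energy_matrix(solvent, solute, spec).sum(axis=0)


def _graph_to_molecule(graph: MolGraph) -> tuple[Molecule, np.ndarray]:
    """smiles_mode: build an RDKit molecule, canonicalize, re-map the types."""
    rw = Chem.RWMol()
    for element in graph.elements:
        rw.AddAtom(Chem.Atom(element))
    m = graph.size
    for i in range(m):
        for j in range(i + 1, m):
            if graph.adjacency[i, j]:
                rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    smiles = Chem.MolToSmiles(mol)
    order = list(map(int, mol.GetProp("_smilesAtomOutputOrder")
                     .strip("[],").split(",")))
    types_canonical = graph.tokens[np.asarray(order)]
    return parse_smiles(smiles), types_canonical


@dataclass
class SyntheticDataset:
    """Records plus the generating truth needed by recovery tests."""

    records: list
    noiseless_dg: np.ndarray
    solute_contributions: list        # per record, (M_b,) planted truth
    spec: SyntheticSpec


def generate_dataset(n_records: int, spec: SyntheticSpec,
                     solvent_type_subset=None,
                     solute_type_subset=None) -> SyntheticDataset:
    """Deterministically generate records from spec.seed.

    Token-mode records carry their graphs directly (``solvent_graph`` /
    ``solute_graph``); smiles_mode records are ordinary SMILES records and
    the stored truth is re-indexed to canonical atom order.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(spec.seed)
    records, noiseless, contributions = [], [], []
    for _ in range(n_records):
        solvent = sample_molecule(spec, rng, solvent_type_subset)
        solute = sample_molecule(spec, rng, solute_type_subset)
        dg0 = ground_truth_energy(solvent, solute, spec)
        dg = dg0 + (float(rng.normal(0.0, spec.noise_sd))
                    if spec.noise_sd > 0 else 0.0)
        contrib = true_solute_contributions(solvent, solute, spec)
        if spec.smiles_mode:
            solvent_mol, _ = _graph_to_molecule(solvent)
            solute_mol, solute_types = _graph_to_molecule(solute)
            # contributions depend only on (type, neighbourhood), both of
            # which the canonical re-indexing permutes consistently
            reindexed = true_solute_contributions(
                solvent, MolGraph(tokens=solute_types,
                                  adjacency=_canonical_adjacency(solute_mol),
                                  elements=solute_mol.elements), spec)
            records.append(SolvationRecord(solvent=solvent_mol,
                                           solute=solute_mol, dg_sol=dg))
            contributions.append(reindexed)
        else:
            placeholder_a = Molecule(smiles="*", elements=solvent.elements,
                                     bonds=_bond_list(solvent.adjacency))
            placeholder_b = Molecule(smiles="*", elements=solute.elements,
                                     bonds=_bond_list(solute.adjacency))
            records.append(SolvationRecord(
                solvent=placeholder_a, solute=placeholder_b, dg_sol=dg,
                solvent_graph=solvent, solute_graph=solute))
            contributions.append(contrib)
        noiseless.append(dg0)
    return SyntheticDataset(records=records,
                            noiseless_dg=np.array(noiseless),
                            solute_contributions=contributions, spec=spec)


def _bond_list(adjacency: np.ndarray) -> tuple:
    m = adjacency.shape[0]
    return tuple((i, j) for i in range(m) for j in range(i + 1, m)
                 if adjacency[i, j])


def _canonical_adjacency(molecule: Molecule) -> np.ndarray:
    m = molecule.n_atoms
    adjacency = np.zeros((m, m))
    for i, j in molecule.bonds:
        adjacency[i, j] = adjacency[j, i] = 1.0
    return adjacency
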