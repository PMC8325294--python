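"""SMILES parsing, heavy-atom molecular graphs, and solvation dataset IO.

Molecules are represented by their heavy atoms only (hydrogens stay
implicit), in the canonical atom order produced by RDKit's SMILES
canonicalization, so that downstream sequence encoders see a reproducible
atom ordering.  Each atom carries a Morgan (circular-substructure)
identifier as its token: the radius-1 identifier when the atom has
neighbours, falling back to the radius-0 identifier for isolated heavy
atoms such as the oxygen of water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

#: Heavy elements accepted in molecules (hydrogen is implicit only).
SUPPORTED_ELEMENTS = frozenset({"C", "O", "S", "N", "P", "F", "Cl", "Br", "I"})

#: Conventional maximum connectivity used by the synthetic generator's
#: SMILES mode; shared here so both modules agree.
ELEMENT_VALENCE = {"C": 4, "N": 3, "P": 3, "O": 2, "S": 2,
                   "F": 1, "Cl": 1, "Br": 1, "I": 1}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class UnsupportedElementError(ValueError):
    """Raised when a molecule contains a heavy atom outside the supported set."""


@dataclass(frozen=True)
class Molecule:
    """A heavy-atom molecule in canonical atom order.

    Attributes
    ----------
    smiles : str
        Canonical SMILES.
    elements : tuple of str
        Element symbol per heavy atom, canonical order.
    bonds : tuple of (int, int)
        Undirected heavy-atom bonds, ``i < j``, no duplicates.
    """

    smiles: str
    elements: tuple
    bonds: tuple

    def __post_init__(self):
        m = len(self.elements)
        if m < 1:
            raise ValueError("molecule needs at least one heavy atom")
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < m and 0 <= j < m) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {m} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class MolGraph:
    """Graph view of a molecule: per-atom tokens plus adjacency/degree.

    ``tokens`` holds one atom-environment identifier per heavy atom; for
    SMILES-derived molecules these are Morgan identifiers, for synthetic
    molecules they are latent atom-type ids.  ``aux_tokens`` optionally
    carries the radius-0 identifiers, used additively by the embedding
    layer when both radii are present in a lookup table.
    """

    tokens: np.ndarray                    # (M,) int64
    adjacency: np.ndarray                 # (M, M) float, symmetric, 0 diagonal
    elements: tuple = ()
    aux_tokens: np.ndarray | None = None  # (M,) int64 radius-0 identifiers

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        m = self.tokens.shape[0]
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency shape does not match token count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def size(self) -> int:
        return int(self.tokens.shape[0])

    @property
    def degree(self) -> np.ndarray:
        """Diagonal degree matrix D (row sums of adjacency)."""
        return np.diag(self.adjacency.sum(axis=1))

    def normalized_adjacency(self) -> np.ndarray:
        """D^{-1/2} A D^{-1/2}; rows/columns of isolated atoms are zero."""
        deg = self.adjacency.sum(axis=1)
        inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
        inv_sqrt = np.where(deg > 0, inv_sqrt, 0.0)
        return inv_sqrt[:, None] * self.adjacency * inv_sqrt[None, :]


@dataclass
class SolvationRecord:
    """One supervised example: (solvent, solute, ΔG°_sol in kcal/mol)."""

    solvent: Molecule
    solute: Molecule
    dg_sol: float
    # Graphs may be attached directly (synthetic data bypasses SMILES).
    solvent_graph: MolGraph | None = field(default=None, repr=False)
    solute_graph: MolGraph | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.dg_sol):
            raise ValueError("dg_sol must be finite")


def parse_smiles(smiles: str) -> Molecule:
    """Parse and canonicalize a SMILES string into a heavy-atom Molecule.

    Raises
    ------
    SmilesParseError
        If RDKit cannot parse or sanitize the input.
    UnsupportedElementError
        If any heavy atom falls outside the supported element set.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # Re-parse the canonical SMILES: the new atom order IS the canonical order.
    mol = Chem.MolFromSmiles(canonical)
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bad = sorted(set(elements) - SUPPORTED_ELEMENTS)
    if bad:
        raise UnsupportedElementError(
            f"unsupported element(s) {bad} in SMILES {smiles!r}")
    bonds = tuple(sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                          max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                         for b in mol.GetBonds()))
    return Molecule(smiles=canonical, elements=elements, bonds=bonds)


def _rdkit_mol(molecule: Molecule) -> Chem.Mol:
    mol = Chem.MolFromSmiles(molecule.smiles)
    if mol is None:  # pragma: no cover - Molecule always built from valid SMILES
        raise SmilesParseError(f"stored SMILES failed to re-parse: {molecule.smiles!r}")
    return mol


def morgan_atom_identifiers(molecule: Molecule, radius: int = 1
                            ) -> dict[int, dict[int, int]]:
    """Per-atom Morgan identifiers: {atom index: {radius: identifier}}."""
    mol = _rdkit_mol(molecule)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=extra)
    per_atom: dict[int, dict[int, int]] = {i: {} for i in range(mol.GetNumAtoms())}
    for ident, hits in extra.GetBitInfoMap().items():
        for atom_idx, r in hits:
            per_atom[atom_idx][r] = ident
    return per_atom


def build_graph(molecule: Molecule, radius: int = 1) -> MolGraph:
    """Build the MolGraph of a Molecule with Morgan-identifier tokens.

    The token of atom i is its Morgan identifier at ``radius``; atoms whose
    largest available environment is smaller (isolated heavy atoms) fall
    back to the identifier at the largest radius present, so water's single
    oxygen keeps its distinctive radius-0 identifier.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    ids = morgan_atom_identifiers(molecule, radius=radius)
    m = molecule.n_atoms
    tokens = np.empty(m, dtype=np.int64)
    aux = np.empty(m, dtype=np.int64)
    for i in range(m):
        per_radius = ids[i]
        tokens[i] = per_radius.get(radius, per_radius[max(per_radius)])
        aux[i] = per_radius[0]
    adjacency = np.zeros((m, m))
    for i, j in molecule.bonds:
        adjacency[i, j] = adjacency[j, i] = 1.0
    return MolGraph(tokens=tokens, adjacency=adjacency,
                    elements=molecule.elements, aux_tokens=aux)


def graph_for(record_side: Molecule | MolGraph, radius: int = 1) -> MolGraph:
    """Return a MolGraph for either representation of a record side."""
    if isinstance(record_side, MolGraph):
        return record_side
    return build_graph(record_side, radius=radius)


def record_graphs(record: SolvationRecord, radius: int = 1
                  ) -> tuple[MolGraph, MolGraph]:
    """Graphs for (solvent, solute), honouring any attached synthetic graphs."""
    solvent = record.solvent_graph or build_graph(record.solvent, radius)
    solute = record.solute_graph or build_graph(record.solute, radius)
    return solvent, solute


# ---------------------------------------------------------------------------
# Dataset IO
# ---------------------------------------------------------------------------

GENERIC_COLUMNS = ("solvent_smiles", "solute_smiles", "dg_kcal_mol")

#: Published FreeSolv export column names mapped onto the generic schema.
#: Hydration data: the solvent column is absent and defaults to water.
_FREESOLV_SOLUTE_COLS = ("smiles", "SMILES", "solute_smiles")
_FREESOLV_DG_COLS = ("expt", "experimental value (kcal/mol)", "dg_kcal_mol")


class DatasetSchemaError(ValueError):
    """Raised when a dataset file lacks required columns or is empty."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise DatasetSchemaError(f"empty dataset file: {path}") from None
    if df.empty:
        raise DatasetSchemaError(f"dataset file has no rows: {path}")
    return df


def _pick(df: pd.DataFrame, candidates) -> str | None:
    for c in candidates:
        if c in df.columns:
            return c
    return None


def read_dataset(path, dialect: str = "generic", deduplicate: bool = False
                 ) -> list[SolvationRecord]:
    """Read solvation records from CSV/TSV.

    Parameters
    ----------
    path : path-like
        File with a header row.
    dialect : {"generic", "freesolv"}
        ``generic`` expects columns ``solvent_smiles``, ``solute_smiles``,
        ``dg_kcal_mol`` (a missing solvent column defaults to water).
        ``freesolv`` maps a FreeSolv-style export (``smiles``, ``expt``)
        onto the same schema with water as solvent.
    deduplicate : bool
        Drop exact duplicate (solvent, solute) pairs, keeping the first.
        Off by default.

    Rows whose SMILES fail to parse are dropped with a logged warning.
    """
    df = _read_table(path)
    if dialect == "generic":
        solute_col, dg_col = "solute_smiles", "dg_kcal_mol"
        solvent_col = "solvent_smiles" if "solvent_smiles" in df.columns else None
    elif dialect == "freesolv":
        solute_col = _pick(df, _FREESOLV_SOLUTE_COLS)
        dg_col = _pick(df, _FREESOLV_DG_COLS)
        solvent_col = _pick(df, ("solvent_smiles",))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = [name for name, col in
               (("solute SMILES", solute_col), ("dg (kcal/mol)", dg_col))
               if col is None or col not in df.columns]
    if missing:
        raise DatasetSchemaError(
            f"missing required column(s) {missing} in {path}")

    records: list[SolvationRecord] = []
    molecule_cache: dict[str, Molecule] = {}
    dropped = 0
    seen_pairs: set[tuple[str, str]] = set()

    def cached_parse(smiles: str) -> Molecule:
        if smiles not in molecule_cache:
            molecule_cache[smiles] = parse_smiles(smiles)
        return molecule_cache[smiles]

    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            solvent_smiles = str(row[solvent_col]) if solvent_col else "O"
            solvent = cached_parse(solvent_smiles)
            solute = cached_parse(str(row[solute_col]))
            dg = float(row[dg_col])
            record = SolvationRecord(solvent=solvent, solute=solute, dg_sol=dg)
        except (SmilesParseError, UnsupportedElementError, ValueError) as exc:
            dropped += 1
            logger.warning("dropping row: %s", exc)
            continue
        if deduplicate:
            key = (record.solvent.smiles, record.solute.smiles)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
        records.append(record)
    if dropped:
        logger.warning("dropped %d unparseable row(s) from %s", dropped, path)
    if not records:
        raise DatasetSchemaError(f"no valid records in {path}")
    return records


def write_dataset(records, path) -> None:
    """Write records in the generic CSV schema (UTF-8, '.' decimals)."""
    df = pd.DataFrame({
        "solvent_smiles": [r.solvent.smiles for r in records],
        "solute_smiles": [r.solute.smiles for r in records],
        "dg_kcal_mol": [r.dg_sol for r in records],
    })
    df.to_csv(path, index=False, encoding="utf-8")
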