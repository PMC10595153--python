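"""Loading, cleaning and featurization of SMILES + logS tables.

Molecules are represented as heavy-atom graphs: hydrogens stay implicit and
enter only through the attached-hydrogens count block of the atom feature
vector.  Each atom carries a 40-dimensional feature vector and each bond a
10-dimensional one; the blocks and their order are fixed by
:class:`FeatureConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SchemaError(ValueError):
    """A table is missing a required column."""


class InvalidSMILESError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class UnsupportedElementError(ValueError):
    """A molecule contains an element outside the 15-symbol vocabulary."""


class EncodingOverflowError(ValueError):
    """An atom property exceeds the range its one-hot block can encode."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One row of a solubility table: a SMILES string and its logS label."""

    smiles: str
    logS: float
    id: Optional[str] = None


@dataclass(frozen=True)
class FeatureConfig:
    """Vocabularies and block sizes of the atom/bond featurization.

    The atom vector concatenates, in order: element one-hot (15), heavy-atom
    degree one-hot (8, degrees 0-7), formal charge scalar, radical-electron
    scalar, hybridization one-hot (6), aromaticity flag, attached-hydrogens
    one-hot (5, counts 0-4), chiral-centre flag, chirality-type one-hot
    (2: R, S; all-zero for achiral atoms).  Total width 40.

    The bond vector concatenates: bond-type one-hot (4), conjugation flag,
    ring flag, stereo one-hot (4).  Total width 10.
    """

    element_vocab: tuple = (
        "B", "C", "N", "O", "F", "Si", "P", "S",
        "Cl", "As", "Se", "Br", "Te", "I", "At",
    )
    degree_slots: int = 8
    hybridization_vocab: tuple = ("SP", "SP2", "SP3", "SP3D", "SP3D2", "other")
    hydrogen_slots: int = 5
    chirality_type_vocab: tuple = ("R", "S")
    bond_type_vocab: tuple = ("single", "double", "triple", "aromatic")
    stereo_vocab: tuple = ("STEREOZ", "STEREONONE", "STEREOE", "STEREOANY")

    @property
    def atom_width(self) -> int:
        return (
            len(self.element_vocab)
            + self.degree_slots
            + 1  # formal charge
            + 1  # radical electrons
            + len(self.hybridization_vocab)
            + 1  # aromatic flag
            + self.hydrogen_slots
            + 1  # chiral-centre flag
            + len(self.chirality_type_vocab)
        )

    @property
    def bond_width(self) -> int:
        return len(self.bond_type_vocab) + 1 + 1 + len(self.stereo_vocab)

    def digest(self) -> str:
        """Stable hash of the featurization scheme, stored in checkpoints."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_FEATURES = FeatureConfig()


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with per-atom and per-bond feature vectors.

    ``bonds`` is an undirected edge list of 0-based atom index pairs; every
    pair appears once with ``u < v``.  ``bond_order`` holds the categorical
    bond type (``single``/``double``/``triple``/``aromatic``) and
    ``ring_membership`` whether the bond lies in a ring — together these
    decide which bonds are breakable during fragmentation.
    """

    n_atoms: int
    atom_features: np.ndarray  # (N, 40) float32
    bonds: list  # list[(u, v)] with u < v
    bond_features: np.ndarray  # (B, 10) float32
    ring_membership: np.ndarray  # (B,) bool
    bond_order: list  # list[str]
    smiles: Optional[str] = None

    def neighbors(self, i: int) -> list:
        out = []
        for u, v in self.bonds:
            if u == i:
                out.append(v)
            elif v == i:
                out.append(u)
        return out


# ---------------------------------------------------------------------------
# table I/O


def load_dataset(
    path,
    smiles_column: str = "smiles",
    label_column: str = "logS",
    id_column: Optional[str] = None,
    sep: str = ",",
) -> list:
    """Read a delimited SMILES+logS table into :class:`MoleculeRecord` rows.

    No chemistry is parsed here; rows come back in file order, one record per
    row.  Raises :class:`SchemaError` when a required column is absent.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (smiles_column, label_column) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; file has columns {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        raw = row[smiles_column]
        smiles = "" if pd.isna(raw) else str(raw)
        label = float(row[label_column]) if not pd.isna(row[label_column]) else math.nan
        rid = None
        if id_column is not None and id_column in df.columns and not pd.isna(row[id_column]):
            rid = str(row[id_column])
        records.append(MoleculeRecord(smiles=smiles, logS=label, id=rid))
    return records


def write_dataset(records: Sequence[MoleculeRecord], path, sep: str = ",") -> None:
    """Write records back out in the same table dialect ``load_dataset`` reads."""
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "logS": [r.logS for r in records],
        }
    )
    if any(r.id is not None for r in records):
        df.insert(0, "id", [r.id for r in records])
    df.to_csv(path, sep=sep, index=False)


def canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical form of a SMILES, or None when it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def clean_dataset(records: Sequence[MoleculeRecord]) -> list:
    """Drop records with missing structure or label, then structural duplicates.

    Duplicates are detected by canonical-structure equality (two SMILES
    spellings of one molecule count as one record); the first occurrence is
    kept and order is otherwise preserved.  Cleaning never raises on content:
    strings that fail to canonicalize are deduplicated by raw text instead.
    """
    seen = set()
    out = []
    for rec in records:
        if not rec.smiles or not rec.smiles.strip():
            continue
        if rec.logS is None or not math.isfinite(rec.logS):
            continue
        key = canonical_smiles(rec.smiles)
        if key is None:
            key = "raw:" + rec.smiles
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# featurization

_HYBRIDIZATION_MAP = {
    Chem.HybridizationType.SP: "SP",
    Chem.HybridizationType.SP2: "SP2",
    Chem.HybridizationType.SP3: "SP3",
    Chem.HybridizationType.SP3D: "SP3D",
    Chem.HybridizationType.SP3D2: "SP3D2",
}

_BOND_TYPE_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_STEREO_MAP = {
    Chem.BondStereo.STEREOZ: "STEREOZ",
    Chem.BondStereo.STEREOCIS: "STEREOZ",
    Chem.BondStereo.STEREONONE: "STEREONONE",
    Chem.BondStereo.STEREOE: "STEREOE",
    Chem.BondStereo.STEREOTRANS: "STEREOE",
    Chem.BondStereo.STEREOANY: "STEREOANY",
}


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size, dtype=np.float32)
    v[index] = 1.0
    return v


def featurize_atom(atom: Chem.Atom, cfg: FeatureConfig = DEFAULT_FEATURES) -> np.ndarray:
    """Encode one RDKit atom as the 40-dimensional feature vector."""
    symbol = atom.GetSymbol()
    if symbol not in cfg.element_vocab:
        raise UnsupportedElementError(
            f"element {symbol!r} is outside the supported vocabulary {cfg.element_vocab}"
        )
    degree = atom.GetDegree()  # heavy-atom degree (implicit Hs excluded)
    if degree >= cfg.degree_slots:
        raise EncodingOverflowError(f"heavy-atom degree {degree} exceeds {cfg.degree_slots - 1}")
    n_h = atom.GetTotalNumHs()
    if n_h >= cfg.hydrogen_slots:
        raise EncodingOverflowError(f"hydrogen count {n_h} exceeds {cfg.hydrogen_slots - 1}")

    hyb = _HYBRIDIZATION_MAP.get(atom.GetHybridization(), "other")
    chiral = atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED

    chirality_type = np.zeros(len(cfg.chirality_type_vocab), dtype=np.float32)
    if atom.HasProp("_CIPCode"):
        cip = atom.GetProp("_CIPCode")
        if cip in cfg.chirality_type_vocab:
            chirality_type[cfg.chirality_type_vocab.index(cip)] = 1.0

    return np.concatenate(
        [
            _one_hot(cfg.element_vocab.index(symbol), len(cfg.element_vocab)),
            _one_hot(degree, cfg.degree_slots),
            np.array([atom.GetFormalCharge()], dtype=np.float32),
            np.array([atom.GetNumRadicalElectrons()], dtype=np.float32),
            _one_hot(cfg.hybridization_vocab.index(hyb), len(cfg.hybridization_vocab)),
            np.array([1.0 if atom.GetIsAromatic() else 0.0], dtype=np.float32),
            _one_hot(n_h, cfg.hydrogen_slots),
            np.array([1.0 if chiral else 0.0], dtype=np.float32),
            chirality_type,
        ]
    )


def featurize_bond(bond: Chem.Bond, cfg: FeatureConfig = DEFAULT_FEATURES) -> np.ndarray:
    """Encode one RDKit bond as the 10-dimensional feature vector."""
    btype = _BOND_TYPE_MAP.get(bond.GetBondType())
    if btype is None:
        # exotic orders (dative etc.) fall back to single for encoding purposes
        btype = "single"
    stereo = _STEREO_MAP.get(bond.GetStereo(), "STEREONONE")
    return np.concatenate(
        [
            _one_hot(cfg.bond_type_vocab.index(btype), len(cfg.bond_type_vocab)),
            np.array([1.0 if bond.GetIsConjugated() else 0.0], dtype=np.float32),
            np.array([1.0 if bond.IsInRing() else 0.0], dtype=np.float32),
            _one_hot(cfg.stereo_vocab.index(stereo), len(cfg.stereo_vocab)),
        ]
    )


def smiles_to_graph(smiles: str, cfg: FeatureConfig = DEFAULT_FEATURES) -> MolecularGraph:
    """Parse a SMILES, check validity and build the featurized heavy-atom graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"invalid SMILES: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    atom_features = np.stack(
        [featurize_atom(a, cfg) for a in mol.GetAtoms()]
    ) if mol.GetNumAtoms() else np.zeros((0, cfg.atom_width), dtype=np.float32)

    bonds, bond_feats, ring, order = [], [], [], []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(u, v), max(u, v)))
        bond_feats.append(featurize_bond(b, cfg))
        ring.append(b.IsInRing())
        order.append(_BOND_TYPE_MAP.get(b.GetBondType(), "single"))

    bond_features = (
        np.stack(bond_feats) if bond_feats else np.zeros((0, cfg.bond_width), dtype=np.float32)
    )
    return MolecularGraph(
        n_atoms=mol.GetNumAtoms(),
        atom_features=atom_features.astype(np.float32),
        bonds=bonds,
        bond_features=bond_features.astype(np.float32),
        ring_membership=np.array(ring, dtype=bool),
        bond_order=order,
        smiles=smiles,
    )


def graph_to_json(g: MolecularGraph) -> str:
    """One-molecule JSON line for debugging dumps."""
    return json.dumps(
        {
            "smiles": g.smiles,
            "n_atoms": g.n_atoms,
            "bonds": [list(b) for b in g.bonds],
            "bond_order": g.bond_order,
            "ring": g.ring_membership.astype(int).tolist(),
            "atom_features": g.atom_features.tolist(),
            "bond_features": g.bond_features.tolist(),
        }
    )
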