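"""SMILES to molecular-graph featurization.

A molecule is represented by a padded one-hot node-feature matrix ``H``
(one row per heavy atom; hydrogens stay implicit) together with five binary
adjacency matrices: ``A_full`` covering bonds of every kind, plus one matrix
per bond class (single, double, triple, aromatic) describing the
corresponding substructure.  Self-loops follow a participation rule: in
``A_full`` every real atom carries a self-loop, while in a substructure
matrix atom *i* has ``A[i, i] = 1`` only if it is incident to at least one
bond of that class — the diagonal thereby doubles as the substructure
membership mask used by the masked-sum fusion layer.

Atom features are six fixed one-hot blocks (atomic number 1–101, formal
charge −3…3 plus an "extreme" bucket, hybridization, ring membership,
aromaticity, chirality tag), giving a feature width of 124.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; failures are raised as SmilesParseError

BOND_CLASSES = ("single", "double", "triple", "aromatic")

_BOND_TYPE_TO_CLASS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_HYBRIDIZATIONS = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "Other")
_CHIRALITY = ("Unspecified", "Clockwise", "Counter-clockwise", "Other")

_RDKIT_HYB = {
    Chem.HybridizationType.S: "S",
    Chem.HybridizationType.SP: "SP",
    Chem.HybridizationType.SP2: "SP2",
    Chem.HybridizationType.SP3: "SP3",
    Chem.HybridizationType.SP3D: "SP3D",
    Chem.HybridizationType.SP3D2: "SP3D2",
}

_RDKIT_CHI = {
    Chem.ChiralType.CHI_UNSPECIFIED: "Unspecified",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "Clockwise",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "Counter-clockwise",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


class UnsupportedElementError(ValueError):
    """Raised for atomic numbers outside the supported 1–101 range."""


class CapacityExceededError(ValueError):
    """Raised when a molecule has more heavy atoms than the padding allows."""


@dataclass(frozen=True)
class FeatureVocabulary:
    """Fixed category orderings for the six one-hot atom-feature blocks."""

    atomic_numbers: tuple[int, ...] = tuple(range(1, 102))
    formal_charges: tuple = (-3, -2, -1, 0, 1, 2, 3, "Extreme")
    hybridizations: tuple[str, ...] = _HYBRIDIZATIONS
    in_ring: tuple[str, ...] = ("No", "Yes")
    aromatic: tuple[str, ...] = ("No", "Yes")
    chirality: tuple[str, ...] = _CHIRALITY

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return (len(self.atomic_numbers), len(self.formal_charges),
                len(self.hybridizations), len(self.in_ring),
                len(self.aromatic), len(self.chirality))

    @property
    def feature_length(self) -> int:
        return sum(self.block_sizes)

    def to_json(self) -> str:
        return json.dumps({
            "atomic_numbers": list(self.atomic_numbers),
            "formal_charges": [str(c) for c in self.formal_charges],
            "hybridizations": list(self.hybridizations),
            "in_ring": list(self.in_ring),
            "aromatic": list(self.aromatic),
            "chirality": list(self.chirality),
        })


@dataclass(frozen=True)
class AtomRecord:
    atomic_number: int
    formal_charge: int
    hybridization: str
    in_ring: bool
    aromatic: bool
    chirality: str


@dataclass(frozen=True)
class ParsedMolecule:
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, str], ...]
    source_smiles: str

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class MolecularGraph:
    """Padded featurization of one molecule."""

    H: np.ndarray                      # (n_max, D) one-hot rows, zero padding
    A_full: np.ndarray                 # (n_max, n_max) all bond classes + self-loops
    A_sub: dict[str, np.ndarray]       # bond class -> (n_max, n_max)
    n_atoms: int
    source_smiles: str = ""


def parse_smiles(text: str) -> ParsedMolecule:
    """Parse a SMILES string into a heavy-atom graph with perceived aromaticity.

    Raises :class:`SmilesParseError` on malformed input.
    """
    if not text:
        raise SmilesParseError(text)
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(text)
    atoms = tuple(
        AtomRecord(
            atomic_number=a.GetAtomicNum(),
            formal_charge=a.GetFormalCharge(),
            hybridization=_RDKIT_HYB.get(a.GetHybridization(), "Other"),
            in_ring=a.IsInRing(),
            aromatic=a.GetIsAromatic(),
            chirality=_RDKIT_CHI.get(a.GetChiralTag(), "Other"),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         _BOND_TYPE_TO_CLASS.get(b.GetBondType(), "single"))
        for b in mol.GetBonds()
    )
    return ParsedMolecule(atoms=atoms, bonds=bonds, source_smiles=text)


def encode_atom(atom: AtomRecord, vocab: FeatureVocabulary | None = None) -> np.ndarray:
    """One-hot encode an atom as the concatenation of the six feature blocks.

    Out-of-list charges map to the "Extreme" slot; unknown hybridization or
    chirality to "Other".  Atomic numbers outside the vocabulary raise
    :class:`UnsupportedElementError` — the element list has no catch-all.
    """
    vocab = vocab or FeatureVocabulary()
    if atom.atomic_number not in vocab.atomic_numbers:
        raise UnsupportedElementError(
            f"atomic number {atom.atomic_number} outside supported range "
            f"{vocab.atomic_numbers[0]}-{vocab.atomic_numbers[-1]}")
    charge = atom.formal_charge if atom.formal_charge in vocab.formal_charges else "Extreme"
    hyb = atom.hybridization if atom.hybridization in vocab.hybridizations else "Other"
    chi = atom.chirality if atom.chirality in vocab.chirality else "Other"
    blocks = (
        (vocab.atomic_numbers, atom.atomic_number),
        (vocab.formal_charges, charge),
        (vocab.hybridizations, hyb),
        (vocab.in_ring, "Yes" if atom.in_ring else "No"),
        (vocab.aromatic, "Yes" if atom.aromatic else "No"),
        (vocab.chirality, chi),
    )
    vec = np.zeros(vocab.feature_length, dtype=np.float32)
    offset = 0
    for categories, value in blocks:
        vec[offset + list(categories).index(value)] = 1.0
        offset += len(categories)
    return vec


def build_adjacency_set(mol: ParsedMolecule, n_max: int
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Build the full-molecule and per-bond-class adjacency matrices.

    ``A_full`` holds every bond plus a self-loop on each real atom.  Each
    ``A_sub[k]`` holds only class-*k* bonds, with a self-loop on atom *i*
    exactly when *i* participates in at least one class-*k* bond.
    """
    n = mol.n_atoms
    if n > n_max:
        raise CapacityExceededError(
            f"molecule {mol.source_smiles!r} has {n} atoms > n_max={n_max}")
    A_full = np.zeros((n_max, n_max), dtype=np.float32)
    A_sub = {k: np.zeros((n_max, n_max), dtype=np.float32) for k in BOND_CLASSES}
    A_full[np.arange(n), np.arange(n)] = 1.0
    for i, j, cls in mol.bonds:
        A_full[i, j] = A_full[j, i] = 1.0
        A_sub[cls][i, j] = A_sub[cls][j, i] = 1.0
        A_sub[cls][i, i] = A_sub[cls][j, j] = 1.0
    return A_full, A_sub


def featurize(text: str, vocab: FeatureVocabulary | None = None,
              n_max: int | None = None) -> MolecularGraph:
    """Full SMILES → :class:`MolecularGraph` pipeline with zero padding."""
    vocab = vocab or FeatureVocabulary()
    mol = parse_smiles(text)
    n_max = mol.n_atoms if n_max is None else n_max
    H = np.zeros((n_max, vocab.feature_length), dtype=np.float32)
    for i, atom in enumerate(mol.atoms):
        H[i] = encode_atom(atom, vocab)
    A_full, A_sub = build_adjacency_set(mol, n_max)
    return MolecularGraph(H=H, A_full=A_full, A_sub=A_sub,
                          n_atoms=mol.n_atoms, source_smiles=text)


@dataclass
class GraphBatch:
    """A stack of molecular graphs sharing one vocabulary and padding size."""

    H: np.ndarray                       # (B, n_max, D)
    A_full: np.ndarray                  # (B, n_max, n_max)
    A_sub: dict[str, np.ndarray]        # class -> (B, n_max, n_max)
    n_atoms: np.ndarray                 # (B,)
    vocab: FeatureVocabulary = field(default_factory=FeatureVocabulary)
    smiles: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.H.shape[0]

    @property
    def n_max(self) -> int:
        return self.H.shape[1]

    @property
    def node_mask(self) -> np.ndarray:
        """(B, n_max) indicator of real (non-padding) atoms."""
        return (np.arange(self.n_max)[None, :] < self.n_atoms[:, None]).astype(np.float32)

    def subset(self, idx) -> "GraphBatch":
        idx = np.asarray(idx)
        return GraphBatch(H=self.H[idx], A_full=self.A_full[idx],
                          A_sub={k: v[idx] for k, v in self.A_sub.items()},
                          n_atoms=self.n_atoms[idx], vocab=self.vocab,
                          smiles=tuple(self.smiles[i] for i in idx) if self.smiles else ())

    @classmethod
    def from_smiles(cls, smiles_list, vocab: FeatureVocabulary | None = None,
                    n_max: int | None = None) -> "GraphBatch":
        vocab = vocab or FeatureVocabulary()
        parsed = [parse_smiles(s) for s in smiles_list]
        if n_max is None:
            n_max = max(m.n_atoms for m in parsed)
        graphs = [featurize(s, vocab, n_max) for s in smiles_list]
        return cls(
            H=np.stack([g.H for g in graphs]),
            A_full=np.stack([g.A_full for g in graphs]),
            A_sub={k: np.stack([g.A_sub[k] for g in graphs]) for k in BOND_CLASSES},
            n_atoms=np.array([g.n_atoms for g in graphs], dtype=np.int64),
            vocab=vocab,
            smiles=tuple(smiles_list),
        )

    def save(self, path) -> None:
        """Serialize to an ``.npz`` container with the vocabulary embedded."""
        arrays = {"H": self.H, "A_full": self.A_full, "n_atoms": self.n_atoms}
        for k in BOND_CLASSES:
            arrays[f"A_{k}"] = self.A_sub[k]
        arrays["vocab_json"] = np.array(self.vocab.to_json())
        arrays["smiles"] = np.array(list(self.smiles))
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "GraphBatch":
        with np.load(path, allow_pickle=False) as z:
            return cls(H=z["H"], A_full=z["A_full"],
                       A_sub={k: z[f"A_{k}"] for k in BOND_CLASSES},
                       n_atoms=z["n_atoms"],
                       smiles=tuple(str(s) for s in z["smiles"]))
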