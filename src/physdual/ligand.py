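"""Ligand featurization: SMILES to molecular graphs.

A ligand is represented as a heavy-atom graph: atoms are nodes carrying a
fixed-length feature vector (the node label), chemical bonds are edges.
Hydrogens are added internally for Gasteiger charge assignment and for 3D
conformer embedding, then folded back onto their heavy neighbours, so the
graph seen by the network stays small while charges remain conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import ComputationError, InputError

__all__ = [
    "LigandRecord",
    "AtomNode",
    "BondEdge",
    "LigandGraph",
    "parse_smiles",
    "assign_gasteiger_charges",
    "embed_conformer",
    "featurize_atoms_bonds",
    "ATOM_FEATURE_SCHEMES",
    "BOND_ORDER_NAMES",
]

# Element vocabulary for the default one-hot block; anything else maps to "other".
_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_MAX_DEGREE = 5

BOND_ORDER_NAMES = ("single", "double", "triple", "aromatic")

_BOND_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class LigandRecord:
    """A named SMILES entry, the unit of a ligand dataset."""

    id: str
    smiles: str

    def __post_init__(self):
        if not self.id:
            raise InputError("ligand record id must be non-empty")


@dataclass
class AtomNode:
    index: int
    element: str
    degree: int
    formal_charge: int
    is_aromatic: bool
    partial_charge: float | None = None
    features: np.ndarray | None = None


@dataclass
class BondEdge:
    i: int
    j: int
    bond_order: str
    in_ring: bool
    features: np.ndarray | None = None


@dataclass
class LigandGraph:
    """Heavy-atom molecular graph with optional charges and 3D coordinates."""

    record: LigandRecord
    atoms: list[AtomNode]
    bonds: list[BondEdge]
    coords: np.ndarray | None = None  # (n_atoms, 3), angstrom
    feature_scheme: str | None = None
    _mol: Chem.Mol = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency over heavy atoms."""
        a = np.zeros((self.n_atoms, self.n_atoms))
        for b in self.bonds:
            a[b.i, b.j] = a[b.j, b.i] = 1.0
        return a

    def atom_feature_matrix(self) -> np.ndarray:
        if any(at.features is None for at in self.atoms):
            raise InputError(
                f"ligand {self.record.id!r}: atoms are not featurized; "
                "call featurize_atoms_bonds first"
            )
        return np.stack([at.features for at in self.atoms])

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {(min(b.i, b.j), max(b.i, b.j)) for b in self.bonds}


def _mol_from_smiles(record: LigandRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles, sanitize=True)
    if mol is not None and mol.GetNumAtoms() == 0:
        mol = None  # empty SMILES parses to an atomless molecule
    if mol is None:
        raise InputError(
            f"ligand {record.id!r}: SMILES {record.smiles!r} could not be parsed"
        )
    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags > 1:
        raise InputError(
            f"ligand {record.id!r}: multi-fragment SMILES ({n_frags} fragments) "
            "is rejected; supply a single connected molecule"
        )
    return mol


def parse_smiles(record: LigandRecord) -> LigandGraph:
    """Parse a SMILES string into a heavy-atom :class:`LigandGraph`.

    Raises
    ------
    InputError
        If the SMILES is unparseable or encodes more than one fragment.
    """
    mol = _mol_from_smiles(record)
    atoms = [
        AtomNode(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            is_aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondEdge(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            bond_order=_BOND_ORDER_FROM_RDKIT.get(b.GetBondType(), "single"),
            in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    return LigandGraph(record=record, atoms=atoms, bonds=bonds, _mol=mol)


def _require_mol(graph: LigandGraph) -> Chem.Mol:
    if graph._mol is None:
        graph._mol = _mol_from_smiles(graph.record)
    return graph._mol


def assign_gasteiger_charges(graph: LigandGraph) -> LigandGraph:
    """Populate per-atom Gasteiger partial charges (elementary-charge units).

    Charges are computed on the explicit-hydrogen molecule; each hydrogen's
    charge is folded into its heavy neighbour, so the heavy-atom charges sum
    to the molecular net formal charge.
    """
    mol_h = Chem.AddHs(_require_mol(graph))
    Chem.rdPartialCharges.ComputeGasteigerCharges(mol_h, throwOnParamFailure=False)
    heavy = [a for a in mol_h.GetAtoms() if a.GetAtomicNum() > 1]
    bad = [
        f"{a.GetSymbol()}{a.GetIdx()}"
        for a in mol_h.GetAtoms()
        if not math.isfinite(a.GetDoubleProp("_GasteigerCharge"))
    ]
    if bad:
        raise InputError(
            f"ligand {graph.record.id!r}: Gasteiger parameters unavailable for "
            f"atoms {', '.join(bad)}"
        )
    for node, atom in zip(graph.atoms, heavy):
        q = atom.GetDoubleProp("_GasteigerCharge")
        q += sum(
            nb.GetDoubleProp("_GasteigerCharge")
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 1
        )
        node.partial_charge = q
    return graph


def embed_conformer(graph: LigandGraph, seed: int, n_trials: int = 10) -> LigandGraph:
    """Attach deterministic 3D coordinates to the heavy atoms.

    Generates ``n_trials`` distance-geometry embeddings (ETKDG) with seeds
    derived from ``seed``, relaxes each with MMFF94 (UFF fallback), and keeps
    the lowest-energy relaxed conformer. Identical seeds give identical
    coordinates.
    """
    mol_h = Chem.AddHs(_require_mol(graph))
    best = None
    for trial in range(n_trials):
        m = Chem.Mol(mol_h)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) * 1009 + trial
        if AllChem.EmbedMolecule(m, params) != 0:
            continue
        try:
            if AllChem.MMFFHasAllMoleculeParams(m):
                ff = AllChem.MMFFGetMoleculeForceField(
                    m, AllChem.MMFFGetMoleculeProperties(m)
                )
            else:
                ff = AllChem.UFFGetMoleculeForceField(m)
            ff.Minimize(maxIts=500)
            energy = ff.CalcEnergy()
        except Exception:  # pragma: no cover - rare FF setup failure
            continue
        if best is None or energy < best[0]:
            best = (energy, m)
    if best is None:
        raise ComputationError(
            f"ligand {graph.record.id!r}: conformer embedding failed for all "
            f"{n_trials} trials at seed {seed}; retry with another seed"
        )
    conf = best[1].GetConformer()
    heavy_idx = [a.GetIdx() for a in best[1].GetAtoms() if a.GetAtomicNum() > 1]
    graph.coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy_idx])
    return graph


def _default_atom_features(atom: AtomNode) -> np.ndarray:
    el = np.zeros(len(_ELEMENTS) + 1)
    el[_ELEMENTS.index(atom.element) if atom.element in _ELEMENTS else -1] = 1.0
    deg = np.zeros(_MAX_DEGREE + 1)
    deg[min(atom.degree, _MAX_DEGREE)] = 1.0
    if atom.partial_charge is None:
        raise InputError("assign_gasteiger_charges must run before featurization")
    return np.concatenate(
        [el, deg, [float(atom.formal_charge), float(atom.is_aromatic), atom.partial_charge]]
    )


def _default_bond_features(bond: BondEdge) -> np.ndarray:
    order = np.zeros(len(BOND_ORDER_NAMES))
    order[BOND_ORDER_NAMES.index(bond.bond_order)] = 1.0
    return np.concatenate([order, [float(bond.in_ring)]])


ATOM_FEATURE_SCHEMES = {"default": (_default_atom_features, _default_bond_features)}


def featurize_atoms_bonds(graph: LigandGraph, scheme: str = "default") -> LigandGraph:
    """Fill atom and bond feature vectors according to a named scheme.

    The default scheme is element one-hot (C,N,O,S,F,Cl,Br,I,P,other) +
    degree one-hot (0-5) + formal charge + aromatic flag + Gasteiger charge
    for atoms; bond-order one-hot + ring flag for bonds.
    """
    if scheme not in ATOM_FEATURE_SCHEMES:
        raise InputError(
            f"unknown feature scheme {scheme!r}; available: "
            f"{sorted(ATOM_FEATURE_SCHEMES)}"
        )
    atom_fn, bond_fn = ATOM_FEATURE_SCHEMES[scheme]
    for atom in graph.atoms:
        atom.features = atom_fn(atom)
    for bond in graph.bonds:
        bond.features = bond_fn(bond)
    graph.feature_scheme = scheme
    return graph


def prepare_ligand(record: LigandRecord, seed: int = 0, scheme: str = "default") -> LigandGraph:
    """Full ligand pipeline: parse, charge, embed a conformer, featurize."""
    graph = parse_smiles(record)
    assign_gasteiger_charges(graph)
    embed_conformer(graph, seed=seed)
    return featurize_atoms_bonds(graph, scheme=scheme)
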