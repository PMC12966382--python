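"""Readers and writers for the pipeline's on-disk formats.

Formats: FASTA for the protein, PDB for coordinates, CSV for ligand lists
(`id,smiles`), labels and predictions (`ligand_id,score_kcal_mol[,method]`),
JSON for ligand graph bundles, energy breakdowns and metrics reports.
Every writer's output round-trips through its paired reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import InputError
from .ligand import AtomNode, BondEdge, LigandGraph, LigandRecord
from .protein import ProteinRecord

__all__ = [
    "read_fasta",
    "read_sdf",
    "read_ligand_csv",
    "write_ligand_csv",
    "read_pdb_coords",
    "read_score_csv",
    "write_score_csv",
    "write_graph_bundle",
    "read_graph_bundle",
]


def read_fasta(path) -> ProteinRecord:
    """First record of a FASTA file (a warning is issued if there are more)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records; using the first "
            f"({records[0].id}) — this is a single-target tool",
            stacklevel=2,
        )
    rec = records[0]
    return ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())


def read_sdf(path) -> list[LigandRecord]:
    """Ligand records from an SDF file (ids from molecule titles)."""
    from rdkit import Chem

    records = []
    for k, mol in enumerate(Chem.SDMolSupplier(str(path), sanitize=True)):
        if mol is None:
            raise InputError(f"{path}: molecule {k + 1} could not be parsed")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k + 1}"
        records.append(LigandRecord(name, Chem.MolToSmiles(mol)))
    if not records:
        raise InputError(f"{path}: no molecules found")
    return records


def read_ligand_csv(path) -> list[LigandRecord]:
    """CSV/TSV with header ``id,smiles``; duplicate ids are rejected."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["id", "smiles"]:
        raise InputError(
            f"{path}: expected header 'id,smiles', got {list(df.columns)!r}"
        )
    df.columns = cols
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate ligand id {dup!r}")
    out = []
    for row in df.itertuples(index=True):
        if pd.isna(row.id) or pd.isna(row.smiles):
            raise InputError(f"{path}: missing id or smiles on data line {row.Index + 2}")
        out.append(LigandRecord(str(row.id), str(row.smiles)))
    return out


def write_ligand_csv(records: list[LigandRecord], path) -> None:
    pd.DataFrame(
        {"id": [r.id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, index=False)


def read_pdb_coords(path, chain: str | None = None) -> np.ndarray:
    """C-alpha coordinates (N, 3) in file order from the first model."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    coords = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if "CA" in residue:
                coords.append(residue["CA"].coord)
    if not coords:
        raise InputError(f"{path}: no C-alpha atoms found")
    return np.array(coords, dtype=float)


def read_score_csv(path) -> dict[str, dict[str, float]]:
    """Scores keyed method -> ligand -> kcal/mol.

    Header ``ligand_id,score_kcal_mol`` (single method, key "scores") or
    ``ligand_id,score_kcal_mol,method``.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["ligand_id", "score_kcal_mol"]:
        raise InputError(
            f"{path}: expected header 'ligand_id,score_kcal_mol[,method]', "
            f"got {list(df.columns)!r}"
        )
    df.columns = cols
    out: dict[str, dict[str, float]] = {}
    has_method = "method" in cols
    for row in df.itertuples(index=True):
        method = str(row.method) if has_method else "scores"
        score = float(row.score_kcal_mol)
        if not np.isfinite(score):
            raise InputError(f"{path}: non-finite score on data line {row.Index + 2}")
        out.setdefault(method, {})[str(row.ligand_id)] = score
    return out


def write_score_csv(scores: dict[str, dict[str, float]], path) -> None:
    rows = [
        {"ligand_id": lid, "score_kcal_mol": val, "method": method}
        for method, per in scores.items()
        for lid, val in per.items()
    ]
    df = pd.DataFrame(rows, columns=["ligand_id", "score_kcal_mol", "method"])
    if df["method"].nunique() <= 1:
        df = df.drop(columns=["method"])
    df.to_csv(path, index=False)


def write_graph_bundle(graph: LigandGraph, path) -> None:
    """Serialize a ligand graph (atoms, bonds, features, charges, coords)."""
    doc = {
        "id": graph.record.id,
        "smiles": graph.record.smiles,
        "feature_scheme": graph.feature_scheme,
        "atoms": [
            {
                "index": a.index,
                "element": a.element,
                "degree": a.degree,
                "formal_charge": a.formal_charge,
                "is_aromatic": a.is_aromatic,
                "partial_charge": a.partial_charge,
                "features": None if a.features is None else a.features.tolist(),
            }
            for a in graph.atoms
        ],
        "bonds": [
            {
                "i": b.i,
                "j": b.j,
                "bond_order": b.bond_order,
                "in_ring": b.in_ring,
                "features": None if b.features is None else b.features.tolist(),
            }
            for b in graph.bonds
        ],
        "coords": None if graph.coords is None else graph.coords.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_graph_bundle(path) -> LigandGraph:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON ({exc})") from None
    for key in ("id", "smiles", "atoms", "bonds"):
        if key not in doc:
            raise InputError(f"{path}: graph bundle missing key {key!r}")
    atoms = [
        AtomNode(
            index=a["index"],
            element=a["element"],
            degree=a["degree"],
            formal_charge=a["formal_charge"],
            is_aromatic=a["is_aromatic"],
            partial_charge=a["partial_charge"],
            features=None if a["features"] is None else np.array(a["features"]),
        )
        for a in doc["atoms"]
    ]
    bonds = [
        BondEdge(
            i=b["i"],
            j=b["j"],
            bond_order=b["bond_order"],
            in_ring=b["in_ring"],
            features=None if b["features"] is None else np.array(b["features"]),
        )
        for b in doc["bonds"]
    ]
    coords = None if doc.get("coords") is None else np.array(doc["coords"])
    return LigandGraph(
        record=LigandRecord(doc["id"], doc["smiles"]),
        atoms=atoms,
        bonds=bonds,
        coords=coords,
        feature_scheme=doc.get("feature_scheme"),
    )
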