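"""Built-in study fixtures: the four ligands, the target, reference labels.

The study system is the kinase DYRK2 (dual-specificity tyrosine-
phosphorylation-regulated kinase 2) against four FDA-approved Alzheimer's
drugs. The construct sequence (His-tag + TEV linker + kinase domain) and
the per-tool reference binding scores ship verbatim as fixtures so the
whole pipeline runs offline.

The SMILES strings are canonical structures for the four drugs (DrugBank
DB09128 brexpiprazole, DB00843 donepezil, DB00674 galantamine, DB00989
rivastigmine); they are declared package fixtures keyed to those database
identifiers, not transcriptions from the study tables, which print only
the identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .ligand import LigandRecord
from .protein import ProteinRecord

__all__ = [
    "DRUG_SMILES",
    "DYRK2_SEQUENCE",
    "REFERENCE_SCORES",
    "REFERENCE_TOOL",
    "MODEL_REPORTED_SCORES",
    "FixtureSet",
    "load_paper_fixtures",
]

DRUG_SMILES = {
    "brexpiprazole": "O=c1ccc2ccc(OCCCCN3CCN(c4cccc5sccc45)CC3)cc2[nH]1",
    "donepezil": "COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2",
    "galantamine": "COc1ccc2c3c1OC1CC(O)C=CC31CCN(C)C2",
    "rivastigmine": "CCN(C)C(=O)Oc1cccc(C(C)N(C)C)c1",
}

_DRUG_ORDER = ("brexpiprazole", "donepezil", "galantamine", "rivastigmine")

#: DYRK2 expression-construct sequence (His6 tag + TEV linker + kinase domain).
DYRK2_SEQUENCE = (
    "MHHHHHHSSGVDLGTENLYFQSMGKVKATPMTPEQAMKQYMQKLTAFEHHEIFSYPEIYFLGLNAKKRQGM"
    "TGGPNNGGYDDDQGSYVQVPHDHVAYRYEVLKVIGKGSFGQVVKAYDHKVHQHVALKMVRNEKRFHRQAAE"
    "EIRILEHLRKQDKDNTMNVIHMLENFTFRNHICMTFELLSMNLYELIKKNKFQGFSLPLVRKFAHSILQCL"
    "DALHKNRIIHCDLKPENILLKQQGRSGIKVIDFGSSCYEHQRVYTYIQSRFYRAPEVILGARYGMPIDMWS"
    "LGCILAELLTGYPLLPGEDEGDQLACMIELLGMPSQKLLDASKRAKNFVSSKGYPRYCTVTTLSDGSVVLN"
    "GGRSRRGKLRGPPESREWGNALKGCDDPLFLDFLKQCLEWDPAVRMTPGQALRHPWLRRRLP"
)

#: His-tag/linker prefix removed when trimming is requested (TEV cleavage
#: convention leaves the serine of ENLYFQ/S on the mature protein).
_HIS_TAG_PREFIX = "MHHHHHHSSGVDLGTENLYFQ"

#: Per-tool reference binding scores, kcal/mol (more negative = stronger).
REFERENCE_SCORES: dict[str, dict[str, float]] = {
    "SeamDock": {
        "brexpiprazole": -8.56,
        "donepezil": -8.35,
        "galantamine": -5.56,
        "rivastigmine": -5.57,
    },
    "Vina": {
        "brexpiprazole": -9.9,
        "donepezil": -10.6,
        "galantamine": -7.4,
        "rivastigmine": -7.0,
    },
    "Smina": {
        "brexpiprazole": -10.1,
        "donepezil": -10.6,
        "galantamine": -7.4,
        "rivastigmine": -6.8,
    },
    "QVina": {
        "brexpiprazole": -9.9,
        "donepezil": -10.6,
        "galantamine": -7.4,
        "rivastigmine": -7.0,
    },
    "CB-DOCK": {
        "brexpiprazole": -9.9,
        "donepezil": -10.9,
        "galantamine": -8.1,
        "rivastigmine": -7.3,
    },
    "DeepPurpose": {
        "brexpiprazole": -9.6,
        "donepezil": -9.1,
        "galantamine": -8.2,
        "rivastigmine": -7.7,
    },
}

#: The designated reference column for label generation and evaluation.
REFERENCE_TOOL = "Vina"

#: Scores the reference study's own model reported, for report comparison.
MODEL_REPORTED_SCORES: dict[str, float] = {
    "brexpiprazole": -10.00,
    "donepezil": -10.80,
    "galantamine": -7.6,
    "rivastigmine": -6.9,
}


@dataclass(frozen=True)
class FixtureSet:
    drugs: tuple[LigandRecord, ...]
    protein: ProteinRecord
    reference_scores: dict[str, dict[str, float]]
    predicted_scores: dict[str, float]

    @property
    def reference_labels(self) -> dict[str, float]:
        """The reference-tool row used as training/evaluation labels."""
        return dict(self.reference_scores[REFERENCE_TOOL])


def load_paper_fixtures(trim_his_tag: bool = False) -> FixtureSet:
    """The embedded study fixtures; never touches the network.

    ``trim_his_tag=True`` removes the His-tag/TEV-linker prefix from the
    construct sequence; the default keeps the printed sequence verbatim.
    """
    seq = DYRK2_SEQUENCE
    if trim_his_tag:
        if not seq.startswith(_HIS_TAG_PREFIX):
            raise InputError("construct sequence lost its expected tag prefix")
        seq = seq[len(_HIS_TAG_PREFIX):]
    return FixtureSet(
        drugs=tuple(LigandRecord(name, DRUG_SMILES[name]) for name in _DRUG_ORDER),
        protein=ProteinRecord("DYRK2", seq),
        reference_scores={k: dict(v) for k, v in REFERENCE_SCORES.items()},
        predicted_scores=dict(MODEL_REPORTED_SCORES),
    )
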