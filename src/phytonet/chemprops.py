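"""Physicochemical descriptors and physiological availability flags.

Each phytochemical carries five descriptors (molecular weight, AlogP,
H-bond donors, H-bond acceptors, rotatable bonds) and tri-state
physiological flags: human intestinal absorption (HIA), Caco-2
permeability and blood-brain-barrier (BBB) permeability.  Lipinski's
rule of five (RO5) is evaluated from the descriptors; a compound
"satisfies" RO5 when it has at most one violation among
{MW > 500, AlogP > 5, HBD > 5, HBA > 10} (Lipinski's own convention).

Descriptor computation is pluggable: an RDKit backend computes from
SMILES, and a precomputed-table backend serves externally calculated
values verbatim.  HIA/Caco-2/BBB predictors are *not* retrained here;
flags normally arrive precomputed, and a clearly-labelled naive
surrogate predictor exists so the pipeline can run end to end on
synthetic inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PROPERTIES = ("RO5", "HIA", "Caco-2", "BBB")

__all__ = [
    "ChemicalRecord",
    "DescriptorBackend",
    "RDKitBackend",
    "TableBackend",
    "SurrogateAvailabilityModel",
    "compute_descriptors",
    "ro5_violations",
    "ro5_compliant",
    "cosatisfaction_table",
    "load_chemical_table",
    "PROPERTIES",
]


@dataclass
class ChemicalRecord:
    """Descriptors and physiological flags for one phytochemical.

    Flags are tri-state: True / False / None (unknown).  Unknown flags
    are never counted as satisfied or unsatisfied.
    """

    phytochemical_id: str
    smiles: Optional[str] = None
    mw: Optional[float] = None
    alogp: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    rotatable_bonds: Optional[int] = None
    hia: Optional[bool] = None
    caco2: Optional[bool] = None
    bbb: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.phytochemical_id}: mw must be positive")
        for name in ("hbd", "hba", "rotatable_bonds"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise ValueError(
                    f"{self.phytochemical_id}: {name} must be a non-negative integer"
                )


class DescriptorBackend(Protocol):
    """Anything that can produce the five descriptors for a compound."""

    name: str

    def descriptors(
        self, phytochemical_id: str, smiles: Optional[str]
    ) -> dict[str, float]: ...


class RDKitBackend:
    """Descriptor computation from SMILES via RDKit.

    HBD follows RDKit's Lipinski donor count (water "O" -> hbd = 1);
    AlogP is the Crippen estimate.  The backend records its name and
    library version for output provenance.
    """

    def __init__(self) -> None:
        from rdkit import Chem  # deferred: optional dependency
        from rdkit.Chem import Crippen, Descriptors, Lipinski
        import rdkit

        self._chem = Chem
        self._crippen = Crippen
        self._descriptors = Descriptors
        self._lipinski = Lipinski
        self.name = f"rdkit-{rdkit.__version__}"

    def descriptors(
        self, phytochemical_id: str, smiles: Optional[str]
    ) -> dict[str, float]:
        if not smiles:
            raise ValueError(f"{phytochemical_id}: no SMILES available")
        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"{phytochemical_id}: unparseable SMILES {smiles!r}")
        return {
            "mw": float(self._descriptors.MolWt(mol)),
            "alogp": float(self._crippen.MolLogP(mol)),
            "hbd": int(self._lipinski.NumHDonors(mol)),
            "hba": int(self._lipinski.NumHAcceptors(mol)),
            "rotatable_bonds": int(self._lipinski.NumRotatableBonds(mol)),
        }


class TableBackend:
    """Serve precomputed descriptors verbatim from a table keyed by ID."""

    name = "precomputed-table"

    def __init__(self, table: Mapping[str, Mapping[str, float]]):
        self._table = dict(table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableBackend":
        records = load_chemical_table(path)
        return cls(
            {
                r.phytochemical_id: {
                    "mw": r.mw,
                    "alogp": r.alogp,
                    "hbd": r.hbd,
                    "hba": r.hba,
                    "rotatable_bonds": r.rotatable_bonds,
                }
                for r in records
            }
        )

    def descriptors(
        self, phytochemical_id: str, smiles: Optional[str] = None
    ) -> dict[str, float]:
        if phytochemical_id not in self._table:
            raise KeyError(f"no precomputed descriptors for {phytochemical_id}")
        return dict(self._table[phytochemical_id])


def compute_descriptors(
    smiles: str, backend: DescriptorBackend, phytochemical_id: str = ""
) -> dict[str, float]:
    """Compute mw/alogp/hbd/hba/rotatable_bonds with the given backend."""
    return backend.descriptors(phytochemical_id, smiles)


class SurrogateAvailabilityModel:
    """Naive logistic surrogate for HIA/Caco-2/BBB flags.

    This is a toy heuristic on molecular weight and AlogP, provided only
    so the pipeline can run end to end when no precomputed flags exist.
    It is NOT a validated absorption or permeability model and its
    outputs must not be interpreted as such.
    """

    name = "surrogate-logistic-v1"

    @staticmethod
    def _sigmoid(z: float) -> float:
        return 1.0 / (1.0 + math.exp(-z))

    def predict(self, record: ChemicalRecord) -> dict[str, Optional[bool]]:
        if record.mw is None or record.alogp is None:
            return {"hia": None, "caco2": None, "bbb": None}
        mw, alogp = record.mw, record.alogp
        hia = self._sigmoid(4.0 - 0.008 * mw + 0.3 * alogp) > 0.5
        caco2 = self._sigmoid(3.0 - 0.007 * mw + 0.4 * alogp) > 0.5
        bbb = self._sigmoid(2.0 - 0.009 * mw + 0.6 * alogp) > 0.5
        return {"hia": hia, "caco2": caco2, "bbb": bbb}


def ro5_violations(record: ChemicalRecord) -> Optional[int]:
    """Count Lipinski violations, or None when a descriptor is missing."""
    if None in (record.mw, record.alogp, record.hbd, record.hba):
        return None
    return (
        int(record.mw > 500)
        + int(record.alogp > 5)
        + int(record.hbd > 5)
        + int(record.hba > 10)
    )


def ro5_compliant(record: ChemicalRecord) -> Optional[bool]:
    """RO5 satisfaction: at most one violation; None if not assessable."""
    v = ro5_violations(record)
    return None if v is None else v <= 1


def _satisfies(record: ChemicalRecord, prop: str) -> Optional[bool]:
    if prop == "RO5":
        return ro5_compliant(record)
    if prop == "HIA":
        return record.hia
    if prop == "Caco-2":
        return record.caco2
    if prop == "BBB":
        return record.bbb
    raise KeyError(prop)


def cosatisfaction_table(records: Sequence[ChemicalRecord]) -> pd.DataFrame:
    """Symmetric count matrix over {RO5, HIA, Caco-2, BBB}.

    Diagonal cells count compounds satisfying each property; off-diagonal
    cells count compounds satisfying both.  Unknown (None) flags never
    count.
    """
    if not records:
        raise ValueError("no chemical records")
    flags = {
        prop: [_satisfies(r, prop) is True for r in records] for prop in PROPERTIES
    }
    table = pd.DataFrame(0, index=PROPERTIES, columns=PROPERTIES, dtype=int)
    for i, p in enumerate(PROPERTIES):
        for q in PROPERTIES[i:]:
            count = sum(a and b for a, b in zip(flags[p], flags[q]))
            table.loc[p, q] = count
            table.loc[q, p] = count
    return table


_NA = {"", "NA", "NaN", "nan", "None"}


def _opt(value: str, cast):
    return None if value in _NA else cast(value)


def _opt_bool(value: str) -> Optional[bool]:
    if value in _NA:
        return None
    if value.lower() in {"1", "true", "yes"}:
        return True
    if value.lower() in {"0", "false", "no"}:
        return False
    raise ValueError(f"cannot parse flag value {value!r}")


def load_chemical_table(path: str | Path) -> list[ChemicalRecord]:
    """Read the chemical TSV; any descriptor/flag column may be NA.

    Columns: phytochemical_id, smiles, mw, alogp, hbd, hba, rotb, hia,
    caco2, bbb (header row required).  Records that fail validation are
    skipped with a logged error rather than aborting the whole load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"phytochemical_id", "mw", "alogp", "hbd", "hba"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                ChemicalRecord(
                    phytochemical_id=row["phytochemical_id"],
                    smiles=_opt(row.get("smiles", ""), str),
                    mw=_opt(row["mw"], float),
                    alogp=_opt(row["alogp"], float),
                    hbd=_opt(row["hbd"], lambda v: int(float(v))),
                    hba=_opt(row["hba"], lambda v: int(float(v))),
                    rotatable_bonds=_opt(row.get("rotb", ""), lambda v: int(float(v))),
                    hia=_opt_bool(row.get("hia", "")),
                    caco2=_opt_bool(row.get("caco2", "")),
                    bbb=_opt_bool(row.get("bbb", "")),
                )
            )
        except ValueError as exc:
            logger.error("skipping chemical record: %s", exc)
    return records
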