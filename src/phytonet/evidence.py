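"""Ethnopharmacological evidence matching.

A predicted health effect of a phytochemical gains support when a plant
that contains the compound has a traditional (ethnopharmacological) use
whose concept is semantically close to the predicted phenotype.  A
plant supports a phenotype when the best Wu-Palmer similarity between
the phenotype and any of the plant's use concepts exceeds a threshold
(0.8 by default, strict).  The per-phenotype support count n_e ranks
the surviving effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .netprop import PVP
from .ontosim import PhenotypeOntology

logger = logging.getLogger(__name__)

__all__ = [
    "PlantRecord",
    "SupportingPlant",
    "EvidenceResult",
    "load_plant_records",
    "plants_of",
    "match_evidence",
    "filter_by_evidence",
]


@dataclass(frozen=True)
class PlantRecord:
    """A plant, its constituent phytochemicals and its recorded uses."""

    plant_id: str
    phytochemical_ids: frozenset[str]
    use_concepts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.phytochemical_ids:
            raise ValueError(f"plant {self.plant_id} lists no phytochemicals")


@dataclass(frozen=True)
class SupportingPlant:
    plant_id: str
    use_concept: str
    similarity: float


@dataclass(frozen=True)
class EvidenceResult:
    """Per-phenotype supporting plants for one phytochemical."""

    phytochemical_id: str
    support: dict[str, tuple[SupportingPlant, ...]]
    threshold: float

    def n_e(self, phenotype: str) -> int:
        """Number of plants supporting the phenotype (Table-style n_e)."""
        return len(self.support.get(phenotype, ()))


def load_plant_records(
    compounds_path: str | Path,
    uses_path: str | Path,
    ontology: PhenotypeOntology | None = None,
) -> list[PlantRecord]:
    """Assemble plant records from two TSVs.

    ``compounds_path``: (plant_id, phytochemical_id) rows;
    ``uses_path``: (plant_id, use_concept_id) rows.  Use concepts absent
    from the ontology (when one is given) are dropped with a logged
    count.  Plants without any phytochemical row are skipped.
    """
    compounds: dict[str, set[str]] = {}
    for plant, item in _read_pairs(compounds_path):
        compounds.setdefault(plant, set()).add(item)
    uses: dict[str, set[str]] = {}
    n_unknown = 0
    for plant, concept in _read_pairs(uses_path):
        if ontology is not None and concept not in ontology:
            n_unknown += 1
            continue
        uses.setdefault(plant, set()).add(concept)
    if n_unknown:
        logger.info("dropped %d use concept(s) not in the ontology", n_unknown)
    return [
        PlantRecord(p, frozenset(compounds[p]), frozenset(uses.get(p, ())))
        for p in sorted(compounds)
    ]


def _read_pairs(path: str | Path) -> Iterable[tuple[str, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            yield parts[0], parts[1]


def plants_of(
    phytochemical_id: str, plant_records: Sequence[PlantRecord]
) -> list[PlantRecord]:
    """Plants containing the phytochemical (may be empty)."""
    return [r for r in plant_records if phytochemical_id in r.phytochemical_ids]


def match_evidence(
    pvp: PVP,
    plant_records: Sequence[PlantRecord],
    ontology: PhenotypeOntology,
    threshold: float = 0.8,
) -> EvidenceResult:
    """Find plants whose uses semantically match each predicted effect.

    A plant supports phenotype ``phi`` iff the maximum Wu-Palmer
    similarity between ``phi`` and any of its use concepts is strictly
    greater than ``threshold``; the best-matching concept is recorded
    (lexicographic tie-break).  Predicted phenotypes absent from the
    ontology are skipped with a warning.
    """
    containing = plants_of(pvp.phytochemical_id, plant_records)
    support: dict[str, tuple[SupportingPlant, ...]] = {}
    for phen in sorted(pvp.selected()):
        if phen not in ontology:
            logger.warning(
                "%s: predicted phenotype %s not in ontology, skipped",
                pvp.phytochemical_id,
                phen,
            )
            continue
        rows = []
        for plant in containing:
            best_sim, best_use = -1.0, None
            for use in sorted(plant.use_concepts):
                if use not in ontology:
                    continue
                s = ontology.wup_similarity(phen, use)
                if s > best_sim:
                    best_sim, best_use = s, use
            if best_use is not None and best_sim > threshold:
                rows.append(SupportingPlant(plant.plant_id, best_use, best_sim))
        support[phen] = tuple(rows)
    return EvidenceResult(pvp.phytochemical_id, support, threshold)


def filter_by_evidence(
    pvp: PVP, evidence: EvidenceResult
) -> list[tuple[str, int, int]]:
    """Keep predicted phenotypes with at least one supporting plant.

    Returns (phenotype_id, n_e, rank) sorted by descending n_e, dense
    ranking with lexicographic tie-break within equal counts.
    """
    if evidence.phytochemical_id != pvp.phytochemical_id:
        raise ValueError("evidence was computed for a different phytochemical")
    kept = [
        (phen, evidence.n_e(phen))
        for phen in sorted(pvp.selected())
        if evidence.n_e(phen) >= 1
    ]
    kept.sort(key=lambda t: (-t[1], t[0]))
    out = []
    rank = 0
    prev_count = None
    for phen, count in kept:
        if count != prev_count:
            rank += 1
            prev_count = count
        out.append((phen, count, rank))
    return out
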