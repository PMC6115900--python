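"""End-to-end orchestration of the three-stage prediction pipeline.

Stage 1 infers statistically significant phenotype effects per
phytochemical by network propagation with a permutation null
(:mod:`phytonet.netprop`).  Stage 2 computes chemical-property flags
and the property co-satisfaction matrix (:mod:`phytonet.chemprops`).
Stage 3 matches predicted effects against the ethnopharmacological
uses of plants containing each compound (:mod:`phytonet.evidence`).

Every stage is a pure function of (inputs, config, seed); a run
directory receives all stage outputs, a resolved-config snapshot and a
manifest with input hashes for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as sps

from . import __version__
from .chemprops import ChemicalRecord, cosatisfaction_table, load_chemical_table, ro5_compliant
from .evidence import (
    EvidenceResult,
    filter_by_evidence,
    load_plant_records,
    match_evidence,
)
from .netprop import (
    PVP,
    build_transition,
    derive_compound_seed,
    load_gene_phenotype_map,
    load_network,
    load_target_profiles,
    predict_pvp,
)
from .ontosim import build_ontology, load_triples

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "SummaryReport", "run_pipeline", "summarize"]


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths and numeric parameters of one pipeline run.

    Parameter defaults: restart 0.7, tolerance 1e-8, seed weights
    1.0/0.3, 1000 random profiles, alpha 0.01, Wu-Palmer threshold 0.8,
    skews {1:1, 1:10, all}, 10 evaluation repeats.
    """

    network: str
    targets: str
    gene_phenotype: str
    ontology: str
    plant_compounds: str
    plant_uses: str
    chemicals: str
    corpus: str | None = None
    output_dir: str = "phytonet_run"
    restart: float = 0.7
    tol: float = 1e-8
    direct_weight: float = 1.0
    indirect_weight: float = 0.3
    n_random: int = 1000
    alpha: float = 0.01
    wup_threshold: float = 0.8
    skews: tuple[str, ...] = ("1:1", "1:10", "all")
    repeats: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "skews" in raw:
            raw["skews"] = tuple(raw["skews"])
        return cls(**raw)


@dataclass(frozen=True)
class SummaryReport:
    """Across-compound summary of predicted and supported effect counts."""

    n_compounds: int
    mean_predicted: float
    ci_low: float
    ci_high: float
    ci_level: float
    mean_supported: float
    supported_fraction: float


@dataclass
class PipelineResult:
    pvps: dict[str, PVP] = field(default_factory=dict)
    evidence: dict[str, EvidenceResult] = field(default_factory=dict)
    filtered: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    chemical_records: list[ChemicalRecord] = field(default_factory=list)
    cosatisfaction: object = None
    summary: SummaryReport | None = None


def summarize(
    pvps: dict[str, PVP],
    filtered: dict[str, list[tuple[str, int, int]]],
    ci_level: float = 0.95,
) -> SummaryReport:
    """Mean predicted-effect count with a Student-t confidence interval,
    mean evidence-supported count, and the overall supported fraction."""
    if not pvps:
        raise ValueError("no PVPs to summarise")
    predicted = np.array([len(p.selected()) for p in pvps.values()], dtype=float)
    supported = np.array(
        [len(filtered.get(pid, [])) for pid in pvps], dtype=float
    )
    mean = float(predicted.mean())
    n = predicted.size
    if n > 1 and predicted.std(ddof=1) > 0:
        half = float(
            sps.t.ppf(0.5 + ci_level / 2, n - 1) * predicted.std(ddof=1) / np.sqrt(n)
        )
    else:
        half = 0.0
    total_pred = predicted.sum()
    fraction = float(supported.sum() / total_pred) if total_pred else 0.0
    return SummaryReport(
        n_compounds=n,
        mean_predicted=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        ci_level=ci_level,
        mean_supported=float(supported.mean()),
        supported_fraction=fraction,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all three stages and write outputs under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    stage = "load-inputs"
    try:
        network = load_network(config.network)
        profiles = load_target_profiles(config.targets)
        gpmap = load_gene_phenotype_map(config.gene_phenotype)
        ontology = build_ontology(load_triples(config.ontology))
        plants = load_plant_records(
            config.plant_compounds, config.plant_uses, ontology
        )
        chem_records = load_chemical_table(config.chemicals)

        stage = "netprop"
        W = build_transition(network)
        for pid in sorted(profiles):
            pvp = predict_pvp(
                profiles[pid],
                network,
                gpmap,
                n_random=config.n_random,
                alpha=config.alpha,
                rng_seed=derive_compound_seed(config.seed, pid),
                restart=config.restart,
                tol=config.tol,
                direct_weight=config.direct_weight,
                indirect_weight=config.indirect_weight,
                W=W,
            )
            result.pvps[pid] = pvp

        stage = "chemprops"
        result.chemical_records = chem_records
        result.cosatisfaction = cosatisfaction_table(chem_records)

        stage = "evidence"
        for pid, pvp in result.pvps.items():
            ev = match_evidence(pvp, plants, ontology, config.wup_threshold)
            result.evidence[pid] = ev
            result.filtered[pid] = filter_by_evidence(pvp, ev)

        stage = "summary"
        result.summary = summarize(result.pvps, result.filtered)

        stage = "write-outputs"
        _write_outputs(config, result)
    except Exception:
        logger.error("pipeline failed during stage %r", stage)
        raise
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.output_dir)
    with open(out / "pvp.tsv", "w") as fh:
        fh.write("phytochemical_id\tphenotype_id\traw_score\tempirical_p\tselected\n")
        for pid in sorted(result.pvps):
            pvp = result.pvps[pid]
            for phen in sorted(pvp.raw_scores):
                fh.write(
                    f"{pid}\t{phen}\t{pvp.raw_scores[phen]:.10g}"
                    f"\t{pvp.empirical_p[phen]:.10g}\t{pvp.binary[phen]}\n"
                )
    with open(out / "evidence.tsv", "w") as fh:
        fh.write("phytochemical_id\tphenotype_id\tn_e\trank\tsupporting_plants\n")
        for pid in sorted(result.filtered):
            ev = result.evidence[pid]
            for phen, n_e, rank in result.filtered[pid]:
                plants = ";".join(sp.plant_id for sp in ev.support[phen])
                fh.write(f"{pid}\t{phen}\t{n_e}\t{rank}\t{plants}\n")
    with open(out / "chem_flags.tsv", "w") as fh:
        fh.write("phytochemical_id\tro5\thia\tcaco2\tbbb\n")
        fmt = lambda v: "NA" if v is None else str(v).lower()
        for rec in result.chemical_records:
            fh.write(
                f"{rec.phytochemical_id}\t{fmt(ro5_compliant(rec))}"
                f"\t{fmt(rec.hia)}\t{fmt(rec.caco2)}\t{fmt(rec.bbb)}\n"
            )
    result.cosatisfaction.to_csv(out / "cosatisfaction.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(dataclasses.asdict(result.summary), fh, indent=2)
        fh.write("\n")
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            fh,
        )
    inputs = {
        name: getattr(config, name)
        for name in (
            "network",
            "targets",
            "gene_phenotype",
            "ontology",
            "plant_compounds",
            "plant_uses",
            "chemicals",
            "corpus",
        )
        if getattr(config, name)
    }
    manifest = {
        "phytonet_version": __version__,
        "inputs": {name: {"path": p, "sha256": _sha256(p)} for name, p in inputs.items()},
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
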