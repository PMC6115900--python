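"""Deterministic synthetic inputs for the whole pipeline.

Generates all seven input kinds -- molecular network, target profiles,
gene-phenotype associations, phenotype ontology triples, plant records,
chemical descriptor table and an annotated abstract corpus -- with
controlled structure and planted ground truth, so every pipeline stage
can be exercised and its signal recovered without any external
database.

Planted structure:

* each phytochemical is assigned ``true_pairs_per_compound`` true
  phenotypes; its direct targets are drawn from those phenotypes' own
  gene sets (and indirect targets from the targets' network
  neighbours), so the propagation signal exists by construction;
* plants containing a compound list use concepts matching the
  compound's true phenotypes (exactly, or their ontology parent) with
  probability ``use_match_rate``;
* in the corpus, sentence co-occurrence of a true pair happens at
  ``background_cooccurrence * enrichment_strength`` per abstract versus
  ``background_cooccurrence`` for any other pair.

All sampling flows through one ``numpy.random.default_rng(rng_seed)``
stream in a fixed order, so the same spec and seed reproduce
byte-identical files.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "FixtureData", "build_fixture", "generate_all", "planted_truth"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    rng_seed: int = 7
    n_nodes: int = 300
    edge_density: float = 0.02
    n_phytochemicals: int = 20
    targets_direct: int = 9
    targets_indirect: int = 6
    n_phenotypes: int = 40
    genes_per_phenotype: int = 8
    ontology_depth: int = 4
    branching: int = 3
    n_plants: int = 40
    compounds_per_plant: int = 3
    uses_per_plant: int = 4
    n_abstracts: int = 2000
    true_pairs_per_compound: int = 3
    use_match_rate: float = 0.8
    background_cooccurrence: float = 5e-4
    solo_mention_rate: float = 5e-3
    enrichment_strength: float = 20.0

    def __post_init__(self) -> None:
        counts = (
            self.n_nodes,
            self.n_phytochemicals,
            self.targets_direct,
            self.targets_indirect,
            self.n_phenotypes,
            self.genes_per_phenotype,
            self.ontology_depth,
            self.branching,
            self.n_plants,
            self.compounds_per_plant,
            self.uses_per_plant,
            self.n_abstracts,
            self.true_pairs_per_compound,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for rate in (self.edge_density, self.use_match_rate,
                     self.background_cooccurrence, self.solo_mention_rate):
            if not (0.0 < rate <= 1.0):
                raise ValueError("densities and rates must lie in (0, 1]")
        if self.background_cooccurrence * self.enrichment_strength > 1.0:
            raise ValueError("background_cooccurrence * enrichment_strength exceeds 1")
        if self.n_phenotypes > self.n_ontology_concepts:
            raise ValueError("ontology too small for the requested phenotype count")
        if self.true_pairs_per_compound > self.n_phenotypes:
            raise ValueError("true_pairs_per_compound exceeds n_phenotypes")

    @property
    def n_ontology_concepts(self) -> int:
        b, d = self.branching, self.ontology_depth
        return (b ** (d + 1) - 1) // (b - 1)


@dataclass(frozen=True)
class FixtureData:
    """In-memory counterpart of the generated file set."""

    spec: FixtureSpec
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    gene_sets: dict[str, tuple[str, ...]]  # phenotype concept -> genes
    ontology_triples: tuple[tuple[str, str, str], ...]
    profiles: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]  # pid -> (direct, indirect)
    true_phenotypes: dict[str, tuple[str, ...]]
    chemicals: tuple[dict, ...]
    plant_compounds: tuple[tuple[str, str], ...]
    plant_uses: tuple[tuple[str, str], ...]
    abstracts: tuple[tuple[str, tuple[tuple[str, ...], ...]], ...]
    truth: frozenset[tuple[str, str]]


def _concept_names(spec: FixtureSpec) -> list[str]:
    return [f"C{k:04d}" for k in range(spec.n_ontology_concepts)]


@functools.lru_cache(maxsize=4)
def build_fixture(spec: FixtureSpec) -> FixtureData:
    """Generate the full synthetic data set in memory."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_nodes
    nodes = tuple(f"G{i:04d}" for i in range(n))

    # --- molecular network: Chung-Lu style degree-heterogeneous graph
    w = (np.arange(n) + 1.0) ** -0.4
    target_edges = spec.edge_density * n * (n - 1) / 2.0
    pair_mass = (w.sum() ** 2 - (w**2).sum()) / 2.0
    theta = target_edges / pair_mass
    prob = np.minimum(theta * np.outer(w, w), 1.0)
    draw = rng.random((n, n))
    iu, ju = np.triu_indices(n, 1)
    keep = draw[iu, ju] < prob[iu, ju]
    edges = tuple((nodes[i], nodes[j]) for i, j in zip(iu[keep], ju[keep]))
    neighbours: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        neighbours[a].add(b)
        neighbours[b].add(a)

    # --- phenotype concepts: full b-ary tree; the deepest concepts (leaves)
    # are the phenotypes carrying gene associations
    concepts = _concept_names(spec)
    triples = [
        (concepts[k], concepts[(k - 1) // spec.branching], "RB")
        for k in range(1, len(concepts))
    ]
    phenotypes = tuple(concepts[-spec.n_phenotypes:])
    parent_of = {
        concepts[k]: concepts[(k - 1) // spec.branching]
        for k in range(1, len(concepts))
    }
    gene_sets = {
        phen: tuple(sorted(rng.choice(n, size=spec.genes_per_phenotype, replace=False)))
        for phen in phenotypes
    }
    gene_sets = {p: tuple(nodes[i] for i in idx) for p, idx in gene_sets.items()}
    # a few non-hierarchical RO side links (exercised only by neighbourhood queries)
    ro_pairs = rng.choice(len(concepts), size=(10, 2), replace=True)
    for a, b in ro_pairs:
        if a != b:
            triples.append((concepts[a], concepts[b], "RO"))

    # --- target profiles planted on the true phenotypes' genes
    compounds = tuple(f"PC{i:03d}" for i in range(spec.n_phytochemicals))
    profiles: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    true_phens: dict[str, tuple[str, ...]] = {}
    all_nodes = list(nodes)
    for pid in compounds:
        chosen = rng.choice(
            spec.n_phenotypes, size=spec.true_pairs_per_compound, replace=False
        )
        phens = tuple(phenotypes[i] for i in chosen)
        true_phens[pid] = phens
        base, rem = divmod(spec.targets_direct, len(phens))
        direct: set[str] = set()
        for k, phen in enumerate(phens):
            quota = base + (1 if k < rem else 0)
            pool = list(gene_sets[phen])
            take = min(quota, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False)
            direct |= {pool[i] for i in idx}
        while len(direct) < spec.targets_direct:  # top up after cross-phenotype overlap
            direct.add(all_nodes[int(rng.integers(n))])
        hood = sorted(set().union(*(neighbours[g] for g in direct)) - direct)
        indirect: set[str] = set()
        if hood:
            take = min(spec.targets_indirect, len(hood))
            idx = rng.choice(len(hood), size=take, replace=False)
            indirect = {hood[i] for i in idx}
        while len(indirect) < spec.targets_indirect:
            cand = all_nodes[int(rng.integers(n))]
            if cand not in direct:
                indirect.add(cand)
        profiles[pid] = (tuple(sorted(direct)), tuple(sorted(indirect)))

    # --- chemical descriptor table with planted RO5 pass/fail patterns
    chemicals = []
    for pid in compounds:
        compliant = rng.random() < 0.7
        if compliant:
            row = {
                "mw": round(float(rng.uniform(150, 480)), 1),
                "alogp": round(float(rng.uniform(-1.0, 4.5)), 2),
                "hbd": int(rng.integers(0, 5)),
                "hba": int(rng.integers(0, 9)),
                "rotb": int(rng.integers(0, 10)),
            }
        else:  # at least two violations: heavy and lipophilic
            row = {
                "mw": round(float(rng.uniform(520, 900)), 1),
                "alogp": round(float(rng.uniform(5.2, 9.0)), 2),
                "hbd": int(rng.integers(6, 12)),
                "hba": int(rng.integers(11, 18)),
                "rotb": int(rng.integers(5, 20)),
            }
        flags = {}
        for name in ("hia", "caco2", "bbb"):
            u = rng.random()
            flags[name] = "true" if u < 0.5 else ("false" if u < 0.8 else "NA")
        chemicals.append({"phytochemical_id": pid, "smiles": "NA", **row, **flags})

    # --- plants: contained compounds plus matching + noise use concepts
    plant_compounds: list[tuple[str, str]] = []
    plant_uses: list[tuple[str, str]] = []
    for j in range(spec.n_plants):
        plant = f"PL{j:03d}"
        idx = rng.choice(spec.n_phytochemicals, size=spec.compounds_per_plant,
                         replace=False)
        members = [compounds[i] for i in idx]
        uses: set[str] = set()
        for pid in members:
            plant_compounds.append((plant, pid))
            for phen in true_phens[pid]:
                if rng.random() < spec.use_match_rate:
                    if rng.random() < 0.7:
                        uses.add(phen)
                    else:
                        uses.add(parent_of.get(phen, phen))
        noise = rng.choice(len(concepts), size=spec.uses_per_plant, replace=False)
        uses |= {concepts[i] for i in noise}
        plant_uses.extend((plant, u) for u in sorted(uses))

    # --- corpus with planted sentence-level co-occurrence enrichment
    truth = frozenset(
        (pid, phen) for pid in compounds for phen in true_phens[pid]
    )
    pairs = [(pid, phen) for pid in compounds for phen in phenotypes]
    rates = np.full(len(pairs), spec.background_cooccurrence)
    for k, pair in enumerate(pairs):
        if pair in truth:
            rates[k] = spec.background_cooccurrence * spec.enrichment_strength
    co_hits = rng.random((spec.n_abstracts, len(pairs))) < rates[None, :]
    terms = list(compounds) + list(phenotypes)
    solo_hits = rng.random((spec.n_abstracts, len(terms))) < spec.solo_mention_rate
    abstracts = []
    for i in range(spec.n_abstracts):
        sentences: list[tuple[str, ...]] = []
        for k in np.flatnonzero(co_hits[i]):
            sentences.append(pairs[k])
        for t in np.flatnonzero(solo_hits[i]):
            sentences.append((terms[t],))
        abstracts.append((f"A{i:06d}", tuple(sentences)))

    return FixtureData(
        spec=spec,
        nodes=nodes,
        edges=edges,
        gene_sets=gene_sets,
        ontology_triples=tuple(triples),
        profiles=profiles,
        true_phenotypes=true_phens,
        chemicals=tuple(chemicals),
        plant_compounds=tuple(plant_compounds),
        plant_uses=tuple(plant_uses),
        abstracts=tuple(abstracts),
        truth=truth,
    )


def generate_all(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic file set; returns {kind: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = build_fixture(spec)
    paths = {
        "network": out / "network.tsv",
        "targets": out / "targets.tsv",
        "gene_phenotype": out / "gene_phenotype.tsv",
        "ontology": out / "ontology.tsv",
        "plant_compounds": out / "plant_compounds.tsv",
        "plant_uses": out / "plant_uses.tsv",
        "chemicals": out / "chemicals.tsv",
        "corpus": out / "corpus.jsonl",
        "truth": out / "truth.tsv",
    }
    with open(paths["network"], "w") as fh:
        for a, b in data.edges:
            fh.write(f"{a}\t{b}\n")
    with open(paths["targets"], "w") as fh:
        for pid in sorted(data.profiles):
            direct, indirect = data.profiles[pid]
            for t in direct:
                fh.write(f"{pid}\t{t}\tdirect\n")
            for t in indirect:
                fh.write(f"{pid}\t{t}\tindirect\n")
    with open(paths["gene_phenotype"], "w") as fh:
        for phen in sorted(data.gene_sets):
            for g in data.gene_sets[phen]:
                fh.write(f"{phen}\t{g}\n")
    with open(paths["ontology"], "w") as fh:
        for c1, c2, rel in data.ontology_triples:
            fh.write(f"{c1}\t{c2}\t{rel}\n")
    with open(paths["plant_compounds"], "w") as fh:
        for plant, pid in data.plant_compounds:
            fh.write(f"{plant}\t{pid}\n")
    with open(paths["plant_uses"], "w") as fh:
        for plant, use in data.plant_uses:
            fh.write(f"{plant}\t{use}\n")
    with open(paths["chemicals"], "w") as fh:
        cols = ["phytochemical_id", "smiles", "mw", "alogp", "hbd", "hba",
                "rotb", "hia", "caco2", "bbb"]
        fh.write("\t".join(cols) + "\n")
        for row in data.chemicals:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(paths["corpus"], "w") as fh:
        for aid, sentences in data.abstracts:
            fh.write(
                json.dumps(
                    {"id": aid, "sentences": [list(s) for s in sentences]},
                    sort_keys=True,
                )
                + "\n"
            )
    with open(paths["truth"], "w") as fh:
        for pid, phen in sorted(data.truth):
            fh.write(f"{pid}\t{phen}\n")
    return paths


def planted_truth(spec: FixtureSpec) -> frozenset[tuple[str, str]]:
    """Ground-truth (phytochemical, phenotype) pairs of the fixture."""
    return build_fixture(spec).truth
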