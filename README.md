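# phytonet

Phytochemicals — the non-nutritive secondary metabolites of plants — act
on many proteins at once, so their potential health effects are best
read off a molecular interaction network rather than one target at a
time. `phytonet` predicts the systemic health effects of phytochemicals
by combining three independent lines of evidence:

1. **Network propagation.** A compound's protein targets (direct
   binders, weight 1.0; indirectly affected proteins, weight 0.3) seed a
   random walk with restart on a protein–protein interaction network,
   `p(t+1) = (1 − r)·Wᵀp(t) + r·p₀` with restart `r = 0.7`, iterated to
   an L1 tolerance of 10⁻⁸ (W is the degree-normalised adjacency
   matrix). Steady-state node scores are summed over each phenotype's
   associated genes, and each phenotype score is tested against an
   empirical null built from random target profiles of the same size:
   `p = (n_exceed + 1)/(n_random + 1)`. Phenotypes with `p < 0.01` form
   the compound's binary phenotype vector (PVP).
2. **Chemical availability.** Molecular weight, AlogP, H-bond
   donors/acceptors and rotatable bonds give Lipinski rule-of-five
   compliance (≤ 1 violation); tri-state HIA, Caco-2 and blood–brain
   barrier flags support oral-availability and tissue filters, and a
   co-satisfaction matrix summarises how the four properties overlap.
3. **Ethnopharmacological evidence.** A predicted effect is supported
   when a plant containing the compound has a traditional use whose
   concept is semantically close to the predicted phenotype on a rooted
   concept hierarchy: Wu–Palmer similarity
   `sim(c₁,c₂) = 2·depth(lcs) / (path(c₁,lcs) + path(c₂,lcs) + 2·depth(lcs))`
   must exceed 0.8. The number of supporting plants `n_e` ranks the
   surviving effects.

A literature-validation module scores any association list against an
annotated abstract corpus (sentence-level co-occurrence `n_c`, Jaccard
index `n_c/n_o`, one-sided Fisher exact enrichment, BH q-values,
Mann–Whitney comparisons) and evaluates precision/recall under
controlled class skew. A deterministic generator (`phytonet.fixtures`)
produces all seven input kinds with planted ground truth, so the whole
pipeline is testable end to end without any external database.

## Worked example

```sh
phytonet fixtures --out inputs --seed 7     # synthetic inputs, 300-node network
phytonet run --config config.yaml           # config lists the input paths, seed 1
```

prints

```
20 compounds: 3.6 predicted effects (95% CI 3.3-4.0), 3.5 with ethnopharmacological support (95%)
```

i.e. across the 20 synthetic compounds the propagation null keeps on
average 3.6 phenotypes per compound (Student-t 95% CI of the mean), and
95% of those predictions are supported by at least one plant whose
traditional use matches the phenotype at Wu–Palmer similarity > 0.8.
The run directory contains per-pair scores and the ranked, evidence-
filtered effects:

```
phytochemical_id  phenotype_id  n_e  rank  supporting_plants
PC000             C0088         7    1     PL006;PL009;PL010;PL019;PL021;PL036;PL039
PC000             C0086         6    2     PL006;PL010;PL019;PL021;PL036;PL039
PC000             C0115         4    3     PL009;PL010;PL036;PL039
```

together with `pvp.tsv` (raw propagation scores and empirical
p-values), `chem_flags.tsv`, the property co-satisfaction matrix, a
summary, a resolved-config snapshot and a manifest with input hashes.
Single similarity queries work directly:

```sh
$ phytonet ontosim sim C0100 C0101 --ontology inputs/ontology.tsv
0.800000
```

(two sibling leaf concepts whose common parent sits at depth 4:
2·4/(1+1+8) = 0.8).

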