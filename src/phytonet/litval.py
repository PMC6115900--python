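"""Literature co-occurrence validation and skew-controlled evaluation.

Predicted phytochemical-phenotype associations are validated against an
annotated abstract corpus: for each pair, n_c counts abstracts with a
sentence mentioning both terms, n_o counts abstracts mentioning either
or both anywhere, the Jaccard index is n_c / n_o, and a one-sided
Fisher exact test measures abstract-level enrichment.  Benjamini-
Hochberg q-values control the FDR over each association list, and
Mann-Whitney U tests compare statistic distributions between a
predicted and a random association set.

Precision/recall evaluation controls class skew by sampling negative
pairs from the prediction universe at a chosen positive:negative ratio,
repeated with fresh negative draws and averaged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

__all__ = [
    "LiteratureCorpus",
    "AssociationStats",
    "EvaluationReport",
    "ComparisonResult",
    "load_corpus",
    "cooccurrence",
    "jaccard",
    "fisher_enrichment",
    "bh_fdr",
    "mann_whitney",
    "association_stats",
    "evaluate",
    "compare_sets",
]


@dataclass(frozen=True)
class LiteratureCorpus:
    """Abstracts as lists of sentences; sentences are term-mention sets."""

    abstracts: tuple[tuple[str, tuple[frozenset[str], ...]], ...]

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.abstracts]
        if len(ids) != len(set(ids)):
            raise ValueError("abstract ids are not unique")

    def __len__(self) -> int:
        return len(self.abstracts)


@dataclass(frozen=True)
class AssociationStats:
    """Literature statistics for one phytochemical-phenotype pair."""

    phytochemical_id: str
    phenotype_id: str
    n_c: int
    n_o: int
    ji: float
    fisher_p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_c > self.n_o:
            raise ValueError("n_c cannot exceed n_o")


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/recall at one class skew, averaged over negative draws."""

    skew: str
    precision_mean: float
    precision_sd: float
    recall: float
    repeats: int
    rng_seed: int


@dataclass(frozen=True)
class ComparisonResult:
    """Summary table plus Mann-Whitney p-values per statistic column."""

    summary: pd.DataFrame
    mw_p: dict[str, float]


def load_corpus(path: str | Path) -> LiteratureCorpus:
    """Read a JSONL corpus: {"id": ..., "sentences": [[term, ...], ...]}."""
    abstracts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                abstracts.append(
                    (
                        str(obj["id"]),
                        tuple(frozenset(s) for s in obj["sentences"]),
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: bad record ({exc})")
    return LiteratureCorpus(tuple(abstracts))


def cooccurrence(
    corpus: LiteratureCorpus, chem_id: str, pheno_id: str
) -> tuple[int, int]:
    """(n_c, n_o): sentence-level co-mention vs any-mention abstract counts."""
    n_c = n_o = 0
    for _, sentences in corpus.abstracts:
        both_in_sentence = False
        chem_any = pheno_any = False
        for s in sentences:
            has_c = chem_id in s
            has_p = pheno_id in s
            chem_any |= has_c
            pheno_any |= has_p
            both_in_sentence |= has_c and has_p
        if both_in_sentence:
            n_c += 1
        if chem_any or pheno_any:
            n_o += 1
    return n_c, n_o


def jaccard(n_c: int, n_o: int) -> float:
    """n_c / n_o, with the 0/0 convention = 0."""
    if n_c > n_o:
        raise ValueError("n_c cannot exceed n_o")
    return 0.0 if n_o == 0 else n_c / n_o


def fisher_enrichment(
    corpus: LiteratureCorpus, chem_id: str, pheno_id: str
) -> float:
    """One-sided Fisher exact p for abstract-level co-mention enrichment.

    The 2x2 table classifies every abstract by whether it mentions the
    phytochemical and whether it mentions the phenotype (anywhere).  The
    p-value is the exact hypergeometric upper tail, P(X >= a); a table
    with a zero margin returns 1.
    """
    a = b = c = d = 0
    for _, sentences in corpus.abstracts:
        has_c = any(chem_id in s for s in sentences)
        has_p = any(pheno_id in s for s in sentences)
        if has_c and has_p:
            a += 1
        elif has_c:
            b += 1
        elif has_p:
            c += 1
        else:
            d += 1
    return _hypergeom_sf(a, b, c, d)


def _hypergeom_sf(a: int, b: int, c: int, d: int) -> float:
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0
    # P(X >= a) for X ~ Hypergeom(N=n_total, K=col1, n=row1)
    return float(stats.hypergeom.sf(a - 1, n_total, col1, row1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact permutation distribution of the rank-sum statistic
    (tie-aware, computed by dynamic programming over midranks) when
    len(x) * len(y) <= 400, otherwise the tie-corrected normal
    approximation with continuity correction.  The mode used is logged.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size * y.size <= 400:
        logger.debug("mann_whitney: exact mode (n*m=%d)", x.size * y.size)
        return _mann_whitney_exact(x, y)
    logger.debug("mann_whitney: asymptotic mode (n*m=%d)", x.size * y.size)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p via the permutation distribution of U.

    Under exchangeability the distribution of U is symmetric about
    n*m/2 (also with ties), so the two-sided p-value is
    P(|U - nm/2| >= |u_obs - nm/2|).  Doubled midranks keep all sums
    integral; subset counts are accumulated by dynamic programming.
    """
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)  # doubled midranks
    w2_obs = int(ranks2[:n].sum())
    u2_obs = w2_obs - n * (n + 1)  # doubled U statistic
    total2 = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets of processed items with doubled
    # rank-sum s; float64 is exact for counts below 2^53.
    dp = np.zeros((n + 1, total2 + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n, 0, -1):  # descending so each item counts once
            dp[k, r:] += dp[k - 1, : total2 + 1 - r]
    counts = dp[n]
    sums2 = np.arange(total2 + 1)
    u2 = sums2 - n * (n + 1)
    center = n * m  # doubled n*m/2
    extreme = np.abs(u2 - center) >= abs(u2_obs - center) - 1e-9
    return float(counts[extreme].sum() / counts.sum())


def association_stats(
    corpus: LiteratureCorpus, pairs: Iterable[Pair]
) -> list[AssociationStats]:
    """Compute n_c, n_o, JI, Fisher p and BH q for a list of pairs.

    The BH correction treats the given list as one family.
    """
    base = []
    for chem, phen in pairs:
        n_c, n_o = cooccurrence(corpus, chem, phen)
        base.append(
            (chem, phen, n_c, n_o, jaccard(n_c, n_o), fisher_enrichment(corpus, chem, phen))
        )
    if not base:
        return []
    qvals = bh_fdr([row[5] for row in base])
    return [
        AssociationStats(chem, phen, n_c, n_o, ji, p, float(q))
        for (chem, phen, n_c, n_o, ji, p), q in zip(base, qvals)
    ]


_SKEW_RATIOS = {"1:1": 1, "1:10": 10, "all": None}


def evaluate(
    predictions: set[Pair],
    positives: set[Pair],
    universe: set[Pair],
    skew: str = "1:1",
    repeats: int = 10,
    rng_seed: int = 0,
) -> EvaluationReport:
    """Precision/recall with a skew-controlled sampled negative set.

    Per repeat, ``ratio * |positives|`` negatives are sampled without
    replacement from ``universe - positives`` ("all" uses the entire
    complement); precision is TP / (TP + FP) restricted to positives
    plus sampled negatives, recall is TP / |positives| and does not
    depend on the skew.
    """
    if skew not in _SKEW_RATIOS:
        raise ValueError(f"skew must be one of {sorted(_SKEW_RATIOS)}")
    if not positives <= universe:
        raise ValueError("positives must be a subset of the universe")
    if not positives:
        raise ValueError("empty positive set")
    ratio = _SKEW_RATIOS[skew]
    candidates = sorted(universe - positives)
    tp = len(predictions & positives)
    recall = tp / len(positives)
    rng = np.random.default_rng(rng_seed)
    precisions = []
    for _ in range(repeats):
        if ratio is None:
            negatives = candidates
        else:
            n_neg = ratio * len(positives)
            if n_neg > len(candidates):
                raise ValueError(
                    f"cannot sample {n_neg} negatives from {len(candidates)} candidates"
                )
            idx = rng.choice(len(candidates), size=n_neg, replace=False)
            negatives = [candidates[i] for i in idx]
        fp = len(predictions & set(negatives))
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
    prec = np.array(precisions)
    sd = float(prec.std(ddof=1)) if repeats > 1 else 0.0
    return EvaluationReport(
        skew, float(prec.mean()), sd, recall, repeats, rng_seed
    )


def compare_sets(
    predicted_stats: Sequence[AssociationStats],
    random_stats: Sequence[AssociationStats],
    p_threshold: float = 0.001,
    q_threshold: float = 0.05,
) -> ComparisonResult:
    """Compare literature statistics of predicted vs random pair sets.

    Reports mean co-occurrence and Jaccard, the number of pairs passing
    the Fisher p threshold (n_p) and the BH q threshold (n_q) per set,
    and two-sided Mann-Whitney p-values per statistic column.
    """
    if not predicted_stats or not random_stats:
        raise ValueError("both association lists must be non-empty")

    def cols(rows):
        return {
            "n_c": [r.n_c for r in rows],
            "ji": [r.ji for r in rows],
            "fisher_p": [r.fisher_p for r in rows],
            "q": [r.q for r in rows],
        }

    pred, rand = cols(predicted_stats), cols(random_stats)
    summary = pd.DataFrame(
        {
            "mean_cooccurrence": [np.mean(pred["n_c"]), np.mean(rand["n_c"])],
            "mean_jaccard": [np.mean(pred["ji"]), np.mean(rand["ji"])],
            "n_p": [
                sum(p < p_threshold for p in pred["fisher_p"]),
                sum(p < p_threshold for p in rand["fisher_p"]),
            ],
            "n_q": [
                sum(q < q_threshold for q in pred["q"]),
                sum(q < q_threshold for q in rand["q"]),
            ],
        },
        index=["predicted", "random"],
    )
    mw_p = {
        name: mann_whitney(pred[name], rand[name])
        for name in ("n_c", "ji", "fisher_p", "q")
    }
    return ComparisonResult(summary, mw_p)
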