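"""Network propagation of phytochemical target effects.

A phytochemical is represented by its protein targets (direct binding
partners, weighted 1.0, and indirectly affected proteins, weighted 0.3).
These seed a random walk with restart (RWR) on an undirected molecular
interaction network,

    p(t+1) = (1 - r) * W^T p(t) + r * p0,        r = 0.7 by default,

whose steady state scores every node by its network proximity to the
seeds.  Node scores are summed over the genes associated with each
phenotype; significance of a phenotype score is assessed against an
empirical null obtained by redrawing the same numbers of direct and
indirect targets uniformly at random from the network.  Phenotypes with
empirical p < alpha form the binary phenotype vector of the
phytochemical (PVP).

W is the degree (row-) normalised adjacency matrix, so W^T is
column-stochastic and the iteration conserves probability mass.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParseError",
    "MolecularNetwork",
    "TargetProfile",
    "PropagationResult",
    "GenePhenotypeMap",
    "PVP",
    "load_network",
    "load_target_profiles",
    "load_gene_phenotype_map",
    "build_transition",
    "make_seed_vector",
    "run_rwr",
    "map_to_phenotypes",
    "empirical_null",
    "build_pvp",
    "predict_pvp",
    "derive_compound_seed",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass
class MolecularNetwork:
    """Undirected gene/protein interaction graph.

    Nodes are ordered lexicographically so that all derived matrices and
    vectors are reproducible.  The adjacency matrix is symmetric with a
    zero diagonal (self-loops are dropped at load time).
    """

    nodes: tuple[str, ...]
    adjacency: sp.csr_matrix
    n_self_loops_dropped: int = 0
    n_duplicate_edges: int = 0
    index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def __contains__(self, node: str) -> bool:
        return node in self.index

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[tuple[str, str], float],
        n_self_loops_dropped: int = 0,
        n_duplicate_edges: int = 0,
    ) -> "MolecularNetwork":
        """Build a network from {(a, b): weight} with a != b."""
        nodes = tuple(sorted({n for pair in edges for n in pair}))
        index = {n: i for i, n in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for (a, b), w in edges.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        adj = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(nodes), len(nodes)), dtype=float
        )
        return cls(nodes, adj, n_self_loops_dropped, n_duplicate_edges, index)


@dataclass(frozen=True)
class TargetProfile:
    """Direct and indirect protein targets of one phytochemical.

    A target listed both as direct and indirect is kept as direct (the
    stronger association wins); the constructor enforces disjointness.
    """

    phytochemical_id: str
    direct_targets: frozenset[str]
    indirect_targets: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.direct_targets & self.indirect_targets
        if overlap:
            logger.info(
                "%s: %d target(s) listed as both direct and indirect; kept as direct",
                self.phytochemical_id,
                len(overlap),
            )
            object.__setattr__(
                self, "indirect_targets", self.indirect_targets - overlap
            )
        if not (self.direct_targets | self.indirect_targets):
            raise ValueError(
                f"{self.phytochemical_id}: profile has no targets at all"
            )


@dataclass(frozen=True)
class PropagationResult:
    """Steady-state RWR node scores aligned to the network node order."""

    phytochemical_id: str
    node_scores: np.ndarray
    iterations: int
    converged: bool
    nodes: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenePhenotypeMap:
    """phenotype_id -> set of associated gene IDs (network namespace)."""

    genes_by_phenotype: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for phen, genes in self.genes_by_phenotype.items():
            if not genes:
                raise ValueError(f"phenotype {phen} has no associated genes")

    def __len__(self) -> int:
        return len(self.genes_by_phenotype)

    def items(self):
        return self.genes_by_phenotype.items()

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes_by_phenotype))


@dataclass(frozen=True)
class PVP:
    """Binary phenotype vector of a phytochemical, with provenance.

    ``binary[phen] == 1`` iff ``empirical_p[phen] < alpha`` (strict).
    """

    phytochemical_id: str
    raw_scores: Mapping[str, float]
    empirical_p: Mapping[str, float]
    binary: Mapping[str, int]
    n_random: int
    alpha: float
    rng_seed: int

    def selected(self) -> frozenset[str]:
        """Phenotypes predicted as effects of this phytochemical."""
        return frozenset(p for p, b in self.binary.items() if b)


# ---------------------------------------------------------------------------
# Loading


def _parse_edge_line(parts: list[str], lineno: int) -> list[tuple[str, str, float]]:
    if len(parts) < 2:
        raise NetworkParseError(
            f"line {lineno}: expected at least two columns, got {len(parts)}"
        )
    if len(parts) == 2:
        return [(parts[0], parts[1], 1.0)]
    # three or more columns: TSV with a numeric weight, or SIF
    # (source, interaction, target...)
    try:
        weight = float(parts[2])
    except ValueError:
        return [(parts[0], t, 1.0) for t in parts[2:]]
    if len(parts) > 3:
        raise NetworkParseError(f"line {lineno}: too many columns for weighted TSV")
    return [(parts[0], parts[1], weight)]


def load_network(edge_list_path: str | Path) -> MolecularNetwork:
    """Load an undirected network from a 2/3-column TSV or a SIF file.

    Self-loops are dropped and duplicate edges collapsed (first weight
    wins); both counts are logged and recorded on the returned network.
    """
    path = Path(edge_list_path)
    edges: dict[tuple[str, str], float] = {}
    n_self, n_dup = 0, 0
    with open(path) as fh:
        any_line = False
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            any_line = True
            parts = line.split("\t") if "\t" in line else line.split()
            for a, b, w in _parse_edge_line(parts, lineno):
                if a == b:
                    n_self += 1
                    continue
                key = (a, b) if a < b else (b, a)
                if key in edges:
                    n_dup += 1
                else:
                    edges[key] = w
    if not any_line:
        raise NetworkParseError(f"{path}: empty edge list")
    if not edges:
        raise NetworkParseError(f"{path}: no usable edges (all self-loops?)")
    net = MolecularNetwork.from_edges(edges, n_self, n_dup)
    logger.info(
        "loaded network %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates)",
        path.name,
        net.n_nodes,
        net.n_edges,
        n_self,
        n_dup,
    )
    return net


def load_target_profiles(path: str | Path) -> dict[str, TargetProfile]:
    """Read a TSV of (phytochemical_id, target_id, direct|indirect)."""
    direct: dict[str, set[str]] = {}
    indirect: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 columns")
            pid, tid, assoc = parts
            if assoc == "direct":
                direct.setdefault(pid, set()).add(tid)
                indirect.setdefault(pid, set())
            elif assoc == "indirect":
                indirect.setdefault(pid, set()).add(tid)
                direct.setdefault(pid, set())
            else:
                raise ValueError(
                    f"{path}, line {lineno}: association must be direct/indirect"
                )
    return {
        pid: TargetProfile(pid, frozenset(direct[pid]), frozenset(indirect[pid]))
        for pid in sorted(direct)
    }


def load_gene_phenotype_map(path: str | Path) -> GenePhenotypeMap:
    """Read a TSV of (phenotype_id, gene_id) pairs."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return GenePhenotypeMap({p: frozenset(g) for p, g in mapping.items()})


# ---------------------------------------------------------------------------
# Propagation


def build_transition(network: MolecularNetwork) -> sp.csr_matrix:
    """Row-stochastic transition matrix W = D^-1 A.

    Isolated nodes receive a self-transition of 1 so that no probability
    mass leaks during the iteration.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    adj = network.adjacency.tocsr().astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    W = sp.diags(inv) @ adj
    if (~nz).any():
        W = W.tolil()
        for i in np.flatnonzero(~nz):
            W[i, i] = 1.0
        W = W.tocsr()
    return W.tocsr()


def make_seed_vector(
    profile: TargetProfile,
    network: MolecularNetwork,
    direct_weight: float = 1.0,
    indirect_weight: float = 0.3,
) -> np.ndarray:
    """Initial probability vector p0 for a target profile.

    Direct targets receive ``direct_weight``, indirect targets
    ``indirect_weight``; the vector is then normalised to sum to one so
    the RWR iteration stays a probability iteration (the 1 : 0.3
    relative weighting is preserved).  Targets absent from the network
    are dropped with a logged count.
    """
    p0 = np.zeros(network.n_nodes)
    dropped = 0
    for t in profile.direct_targets:
        if t in network.index:
            p0[network.index[t]] = direct_weight
        else:
            dropped += 1
    for t in profile.indirect_targets:
        if t in network.index:
            p0[network.index[t]] = indirect_weight
        else:
            dropped += 1
    if dropped:
        logger.info(
            "%s: %d target(s) not in network, dropped",
            profile.phytochemical_id,
            dropped,
        )
    total = p0.sum()
    if total == 0:
        raise ValueError(
            f"{profile.phytochemical_id}: no targets present in the network"
        )
    return p0 / total


def _iterate(
    WT: sp.csr_matrix,
    P0: np.ndarray,
    restart: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Run the RWR iteration on one or many seed columns simultaneously.

    Convergence is the maximum L1 change over columns.
    """
    P = P0.copy()
    for it in range(1, max_iter + 1):
        P_next = (1.0 - restart) * (WT @ P) + restart * P0
        delta = np.abs(P_next - P).sum(axis=0)
        P = P_next
        if np.max(delta) < tol:
            return P, it, True
    return P, max_iter, False


def run_rwr(
    W: sp.csr_matrix,
    p0: np.ndarray,
    restart: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 10000,
    *,
    phytochemical_id: str = "",
    nodes: tuple[str, ...] = (),
) -> PropagationResult:
    """Iterate p(t+1) = (1-r) W^T p(t) + r p0 to the steady state.

    Stops when the L1 difference between successive iterates falls below
    ``tol``; a run that hits ``max_iter`` first is returned with
    ``converged=False`` and a logged warning.
    """
    if not (0.0 < restart <= 1.0):
        raise ValueError("restart must be in (0, 1]")
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError("p0 must sum to 1")
    WT = W.T.tocsr()
    scores, iterations, converged = _iterate(WT, p0[:, None], restart, tol, max_iter)
    if not converged:
        logger.warning(
            "%s: RWR did not converge in %d iterations", phytochemical_id, max_iter
        )
    return PropagationResult(
        phytochemical_id, scores.ravel(), iterations, converged, tuple(nodes)
    )


def map_to_phenotypes(
    result: PropagationResult, gpmap: GenePhenotypeMap
) -> dict[str, float]:
    """Sum steady-state node scores over each phenotype's gene set.

    Genes absent from the network contribute zero; a phenotype whose
    genes are all off-network scores zero.
    """
    if len(gpmap) == 0:
        raise ValueError("empty gene-phenotype map")
    if not result.nodes:
        raise ValueError("PropagationResult carries no node ordering")
    index = {n: i for i, n in enumerate(result.nodes)}
    out: dict[str, float] = {}
    for phen, genes in gpmap.items():
        out[phen] = float(
            sum(result.node_scores[index[g]] for g in genes if g in index)
        )
    return out


def _phenotype_gene_indices(
    gpmap: GenePhenotypeMap, network: MolecularNetwork
) -> dict[str, np.ndarray]:
    return {
        phen: np.array(
            sorted(network.index[g] for g in genes if g in network.index), dtype=int
        )
        for phen, genes in gpmap.items()
    }


def _null_scores(
    profile: TargetProfile,
    network: MolecularNetwork,
    gpmap: GenePhenotypeMap,
    n_random: int,
    rng_seed: int,
    restart: float,
    tol: float,
    max_iter: int,
    direct_weight: float,
    indirect_weight: float,
    W: sp.csr_matrix | None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Observed phenotype scores and empirical p-values in one pass.

    The random profiles preserve the in-network direct and indirect
    target counts of the observed profile.  The RNG stream is
    documented and stable: with ``rng = numpy.random.default_rng(rng_seed)``,
    the j-th random profile is ``rng.choice(n_nodes, size=nd+ni,
    replace=False)`` whose first ``nd`` entries are the direct targets.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if W is None:
        W = build_transition(network)
    WT = W.T.tocsr()
    p0_obs = make_seed_vector(profile, network, direct_weight, indirect_weight)
    nd = sum(1 for t in profile.direct_targets if t in network.index)
    ni = sum(1 for t in profile.indirect_targets if t in network.index)
    n = network.n_nodes
    if nd + ni > n:
        raise ValueError("more targets than network nodes")
    rng = np.random.default_rng(rng_seed)
    P0 = np.zeros((n, n_random + 1))
    P0[:, 0] = p0_obs
    for j in range(n_random):
        pick = rng.choice(n, size=nd + ni, replace=False)
        v = np.zeros(n)
        v[pick[:nd]] = direct_weight
        v[pick[nd:]] = indirect_weight
        P0[:, j + 1] = v / v.sum()
    P, _, converged = _iterate(WT, P0, restart, tol, max_iter)
    if not converged:
        logger.warning(
            "%s: null propagation did not converge", profile.phytochemical_id
        )
    gene_idx = _phenotype_gene_indices(gpmap, network)
    raw: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for phen, idx in gene_idx.items():
        if idx.size:
            col = P[idx, :].sum(axis=0)
        else:
            col = np.zeros(n_random + 1)
        raw[phen] = float(col[0])
        n_exceed = int(np.count_nonzero(col[1:] > col[0]))
        pvals[phen] = (n_exceed + 1) / (n_random + 1)
    return raw, pvals


def empirical_null(
    profile: TargetProfile,
    network: MolecularNetwork,
    gpmap: GenePhenotypeMap,
    n_random: int = 1000,
    rng_seed: int = 0,
    *,
    restart: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 10000,
    direct_weight: float = 1.0,
    indirect_weight: float = 0.3,
    W: sp.csr_matrix | None = None,
) -> dict[str, float]:
    """Empirical p-value per phenotype against random target profiles.

    p(phen) = (n_exceed + 1) / (n_random + 1), where ``n_exceed`` counts
    random profiles whose phenotype score is *strictly* greater than the
    observed score (ties do not count, the conservative reading).
    """
    _, pvals = _null_scores(
        profile,
        network,
        gpmap,
        n_random,
        rng_seed,
        restart,
        tol,
        max_iter,
        direct_weight,
        indirect_weight,
        W,
    )
    return pvals


def build_pvp(
    raw_scores: Mapping[str, float],
    empirical_p: Mapping[str, float],
    alpha: float = 0.01,
    *,
    phytochemical_id: str = "",
    n_random: int = 0,
    rng_seed: int = 0,
) -> PVP:
    """Binarise empirical p-values into a PVP (1 iff p < alpha, strict)."""
    if set(raw_scores) != set(empirical_p):
        diff = sorted(set(raw_scores) ^ set(empirical_p))
        raise ValueError(f"mismatched phenotype keys: {diff}")
    binary = {p: int(empirical_p[p] < alpha) for p in empirical_p}
    return PVP(
        phytochemical_id=phytochemical_id,
        raw_scores=dict(raw_scores),
        empirical_p=dict(empirical_p),
        binary=binary,
        n_random=n_random,
        alpha=alpha,
        rng_seed=rng_seed,
    )


def predict_pvp(
    profile: TargetProfile,
    network: MolecularNetwork,
    gpmap: GenePhenotypeMap,
    *,
    n_random: int = 1000,
    alpha: float = 0.01,
    rng_seed: int = 0,
    restart: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 10000,
    direct_weight: float = 1.0,
    indirect_weight: float = 0.3,
    W: sp.csr_matrix | None = None,
) -> PVP:
    """Full per-compound pipeline: propagate, map, null-filter, binarise."""
    raw, pvals = _null_scores(
        profile,
        network,
        gpmap,
        n_random,
        rng_seed,
        restart,
        tol,
        max_iter,
        direct_weight,
        indirect_weight,
        W,
    )
    return build_pvp(
        raw,
        pvals,
        alpha,
        phytochemical_id=profile.phytochemical_id,
        n_random=n_random,
        rng_seed=rng_seed,
    )


def derive_compound_seed(master_seed: int, phytochemical_id: str) -> int:
    """Deterministic per-compound RNG seed from a master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{phytochemical_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
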