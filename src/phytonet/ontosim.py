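"""Phenotype concept hierarchy and Wu-Palmer semantic similarity.

Concepts (CUI-like identifiers) are connected by typed relations:
RB (broader), RN (narrower) and RO (other-related).  RB/RN edges define
the hierarchy used for depth, lowest-common-subsumer and path queries;
RO edges are kept only for neighbourhood lookups and never contribute
to the similarity computation.

The Wu-Palmer similarity of two concepts is

    sim(c1, c2) = 2*d / (path(c1, lcs) + path(c2, lcs) + 2*d),

where ``lcs`` is their deepest common ancestor, ``d = depth(lcs)`` and
``path`` is the shortest path length along hierarchical edges.  A
virtual root ties the (typically many) hierarchy roots together; two
concepts whose only common ancestor is the virtual root have
similarity 0.
"""

from __future__ import annotations

import logging
from collections import deque
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

ROOT = "__ROOT__"

__all__ = ["ROOT", "PhenotypeOntology", "build_ontology", "load_triples",
           "depth", "lcs", "wup_similarity"]


class PhenotypeOntology:
    """Rooted concept hierarchy with RO side-links.

    ``parents``/``children`` hold the hierarchical (RB/RN-derived) DAG,
    rooted at the virtual concept :data:`ROOT` at depth 0.  Depth of a
    multi-parent concept is the length of its *shortest* ancestor chain.
    """

    def __init__(
        self,
        parents: dict[str, set[str]],
        ro_edges: set[frozenset[str]] | None = None,
        n_cycle_edges_dropped: int = 0,
    ):
        self.parents: dict[str, set[str]] = {c: set(p) for c, p in parents.items()}
        self.children: dict[str, set[str]] = {ROOT: set()}
        self.n_cycle_edges_dropped = n_cycle_edges_dropped
        concepts = set(self.parents)
        for ps in parents.values():
            concepts |= ps
        for e in ro_edges or ():
            concepts |= set(e)  # RO-only concepts become hierarchy roots
        concepts.discard(ROOT)
        # attach parentless concepts to the virtual root
        for c in concepts:
            if not self.parents.get(c):
                self.parents[c] = {ROOT}
        self.parents[ROOT] = set()
        for c, ps in self.parents.items():
            for p in ps:
                self.children.setdefault(p, set()).add(c)
            self.children.setdefault(c, set())
        self.concepts: frozenset[str] = frozenset(concepts)
        self.ro_edges: set[frozenset[str]] = set(ro_edges or ())
        self._depth = self._bfs_depths()

    def _bfs_depths(self) -> dict[str, int]:
        depths = {ROOT: 0}
        queue = deque([ROOT])
        while queue:
            u = queue.popleft()
            for v in self.children[u]:
                if v not in depths:
                    depths[v] = depths[u] + 1
                    queue.append(v)
        return depths

    def __contains__(self, concept: str) -> bool:
        return concept == ROOT or concept in self.concepts

    def _require(self, concept: str) -> None:
        if concept not in self:
            raise KeyError(f"unknown concept: {concept}")

    def depth(self, concept: str) -> int:
        """Shortest ancestor-chain length from the virtual root."""
        self._require(concept)
        return self._depth[concept]

    def ancestors(self, concept: str) -> set[str]:
        """All hierarchical ancestors of ``concept``, including itself."""
        self._require(concept)
        seen = {concept}
        queue = deque([concept])
        while queue:
            u = queue.popleft()
            for p in self.parents[u]:
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        return seen

    def lcs(self, c1: str, c2: str) -> str:
        """Deepest common ancestor; depth ties broken lexicographically."""
        common = self.ancestors(c1) & self.ancestors(c2)
        best_depth = max(self._depth[c] for c in common)
        candidates = sorted(c for c in common if self._depth[c] == best_depth)
        if len(candidates) > 1:
            logger.debug("lcs(%s, %s): tie among %s", c1, c2, candidates)
        return candidates[0]

    def path_length(self, c1: str, c2: str) -> int:
        """Shortest path length along hierarchical edges (undirected)."""
        self._require(c1)
        self._require(c2)
        if c1 == c2:
            return 0
        dist = {c1: 0}
        queue = deque([c1])
        while queue:
            u = queue.popleft()
            for v in self.parents[u] | self.children[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if v == c2:
                        return dist[v]
                    queue.append(v)
        raise RuntimeError(f"no hierarchical path between {c1} and {c2}")

    def wup_similarity(self, c1: str, c2: str) -> float:
        """Wu-Palmer similarity in [0, 1]; 0 when only the root subsumes."""
        self._require(c1)
        self._require(c2)
        sub = self.lcs(c1, c2)
        d = self._depth[sub]
        if d == 0:
            return 0.0
        p1 = self.path_length(c1, sub)
        p2 = self.path_length(c2, sub)
        return 2.0 * d / (p1 + p2 + 2.0 * d)

    def related(self, concept: str) -> set[str]:
        """Concepts linked by non-hierarchical (RO) edges."""
        self._require(concept)
        out = set()
        for e in self.ro_edges:
            if concept in e:
                out |= set(e) - {concept}
        return out


def load_triples(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (cui1, cui2, rel) triples from a TSV file."""
    triples = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 columns")
            triples.append((parts[0], parts[1], parts[2]))
    return triples


def build_ontology(
    triples: Iterable[tuple[str, str, str]],
    rb_points_to_broader: bool = True,
    allowed_concepts: set[str] | None = None,
) -> PhenotypeOntology:
    """Build a rooted hierarchy from (c1, c2, rel) triples.

    With the default polarity, RB(a, b) means "b is broader than a" so b
    becomes a parent of a; RN(a, b) is the inverse.  Dumps with the
    opposite polarity can set ``rb_points_to_broader=False``.  Edges
    that would close a cycle in the hierarchy are dropped
    deterministically (lexicographic processing order) with a warning.
    ``allowed_concepts`` optionally restricts the load to an allowlist
    (e.g. concepts of selected semantic types).
    """
    hier_edges: set[tuple[str, str]] = set()  # (child, parent)
    ro_edges: set[frozenset[str]] = set()
    for c1, c2, rel in triples:
        if allowed_concepts is not None and (
            c1 not in allowed_concepts or c2 not in allowed_concepts
        ):
            continue
        if c1 == c2:
            continue
        if rel == "RB":
            child, parent = (c1, c2) if rb_points_to_broader else (c2, c1)
            hier_edges.add((child, parent))
        elif rel == "RN":
            child, parent = (c2, c1) if rb_points_to_broader else (c1, c2)
            hier_edges.add((child, parent))
        elif rel == "RO":
            ro_edges.add(frozenset((c1, c2)))
        else:
            raise ValueError(f"unknown relation code: {rel!r}")

    parents: dict[str, set[str]] = {}
    dropped = 0
    for child, parent in sorted(hier_edges):
        if _reachable(parents, start=parent, goal=child):
            dropped += 1
            logger.warning(
                "dropping hierarchical edge %s -> %s: would create a cycle",
                child,
                parent,
            )
            continue
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return PhenotypeOntology(parents, ro_edges, dropped)


def _reachable(parents: dict[str, set[str]], start: str, goal: str) -> bool:
    """Is ``goal`` an ancestor of ``start`` under the current parent map?"""
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for p in parents.get(u, ()):
            if p == goal:
                return True
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return False


# Module-level conveniences mirroring the class API.

def depth(ontology: PhenotypeOntology, concept: str) -> int:
    return ontology.depth(concept)


def lcs(ontology: PhenotypeOntology, c1: str, c2: str) -> str:
    return ontology.lcs(c1, c2)


def wup_similarity(ontology: PhenotypeOntology, c1: str, c2: str) -> float:
    return ontology.wup_similarity(c1, c2)
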