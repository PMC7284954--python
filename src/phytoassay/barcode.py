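"""Identification-hit screening and threshold clustering on precomputed data.

No alignment happens here: the module consumes identity/coverage tables and
fractional distance matrices produced elsewhere, screens hits by coverage
and identity cutoffs, builds WPGMA trees, extracts monospecific clades, and
groups sequences into species-hypothesis-style clusters by single linkage at
a fixed threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


__all__ = [
    "IdentificationHit",
    "Clade",
    "screen_hits",
    "wpgma",
    "monospecific_clades",
    "sh_cluster",
    "read_fasta_lengths",
]


@dataclass(frozen=True)
class IdentificationHit:
    query_id: str
    subject_name: str
    percent_identity: float
    query_coverage: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity outside [0, 100]: {self.percent_identity}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"query coverage outside [0, 1]: {self.query_coverage}")


def screen_hits(
    hits: Sequence[IdentificationHit],
    min_coverage: float = 0.95,
    min_identity: float = 99.0,
    top_n: int = 50,
) -> list[IdentificationHit]:
    """Retain the top hits by score, then apply coverage/identity cutoffs.

    Input order is preserved among retained hits.  Hits without scores are
    kept in the top-n selection only when fewer than ``top_n`` scored hits
    exist before them.
    """
    if top_n is not None and len(hits) > top_n:
        scored = sorted(
            range(len(hits)),
            key=lambda i: (-(hits[i].score if hits[i].score is not None else float("-inf")), i),
        )
        top = set(scored[:top_n])
    else:
        top = set(range(len(hits)))
    return [
        h
        for i, h in enumerate(hits)
        if i in top and h.query_coverage >= min_coverage and h.percent_identity >= min_identity
    ]


@dataclass(frozen=True)
class Clade:
    """Rooted (sub)tree node with an ultrametric merge height."""

    height: float
    name: str | None = None
    children: tuple["Clade", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=None) + ";"

    def _newick_inner(self, parent_height: float | None) -> str:
        length = "" if parent_height is None else f":{parent_height - self.height:g}"
        if self.is_leaf:
            return f"{self.name}{length}"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner}){length}"


def _check_square(labels: Sequence[str], matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match the label count")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (matrix < 0).any():
        raise ValueError("distances must be non-negative")
    return matrix


def wpgma(labels: Sequence[str], matrix) -> Clade:
    """Weighted pair-group agglomeration with arithmetic-mean updates.

    The closest pair of clusters merges at half its distance; the merged
    cluster's distance to any other is the plain average of its two
    children's distances.  Ties break on the lexicographically smallest
    (representative, representative) label pair, so the tree is
    deterministic and invariant to input order up to isomorphism.
    """
    matrix = _check_square(labels, matrix)
    if len(labels) < 2:
        raise ValueError("need at least two labels to cluster")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")

    # representative = lexicographically smallest leaf in the cluster
    clusters: dict[str, Clade] = {lab: Clade(height=0.0, name=lab) for lab in labels}
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(matrix[i, j])

    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        pair, d = best
        a, b = sorted(pair)
        merged = Clade(height=d / 2.0, children=(clusters[a], clusters[b]))
        others = [r for r in clusters if r not in (a, b)]
        for c in others:
            dist[frozenset((a, c))] = (
                dist.pop(frozenset((a, c))) + dist.pop(frozenset((b, c)))
            ) / 2.0
        del dist[pair]
        del clusters[b]
        clusters[a] = merged
    return next(iter(clusters.values()))


def monospecific_clades(tree: Clade, labels_to_species: Mapping[str, str]) -> list[Clade]:
    """Maximal clades whose leaves all carry the same species name."""
    species = {leaf: labels_to_species[leaf] for leaf in tree.leaves()}

    out: list[Clade] = []

    def visit(node: Clade) -> None:
        kinds = {species[leaf] for leaf in node.leaves()}
        if len(kinds) == 1:
            out.append(node)
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return out


def sh_cluster(labels: Sequence[str], matrix, threshold: float = 0.015) -> dict[str, int]:
    """Single-linkage clusters at a fixed fractional-dissimilarity cutoff.

    Connected components of the graph joining pairs at distance <=
    ``threshold``; an approximation of species-hypothesis-style reference
    clustering.  Cluster ids are assigned in order of first label.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    matrix = _check_square(labels, matrix)
    n = len(labels)
    assignment: dict[str, int] = {}
    next_id = 0
    visited = [False] * n
    for start in range(n):
        if visited[start]:
            continue
        queue = deque([start])
        visited[start] = True
        while queue:
            i = queue.popleft()
            assignment[labels[i]] = next_id
            for j in range(n):
                if not visited[j] and matrix[i, j] <= threshold:
                    visited[j] = True
                    queue.append(j)
        next_id += 1
    return assignment


def read_fasta_lengths(path) -> dict[str, int]:
    """Sequence ids and lengths from a FASTA file (bookkeeping only)."""
    from Bio import SeqIO

    return {record.id: len(record.seq) for record in SeqIO.parse(str(path), "fasta")}
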