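"""Homolog-group calling: all-vs-all local alignment, Markov clustering,
and typed gene-pair tallies (paralog / ortholog / coortholog).

Pair semantics (the package's operational contract, in the spirit of the
classic ortholog-group pipelines): within each homolog cluster,

* same-species pairs are paralogs,
* cross-species reciprocal-best-hit pairs are orthologs,
* the remaining cross-species pairs are coorthologs.

BLAST is replaced by exact Smith-Waterman since family collections at desk
scale hold at most a few hundred proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import local_score
from .errors import FormatError
from .io_formats import ProteinRecord, Table2Fixture

DEFAULT_INFLATION = 1.5
DEFAULT_CUTOFF = 0.3


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def local_align_score(a: str, b: str) -> float:
    """Smith-Waterman score (BLOSUM62, affine gaps)."""
    return local_score(a, b)


def all_vs_all_scores(records: list[ProteinRecord]) -> pd.DataFrame:
    """Symmetric matrix of local alignment scores (diagonal = self-scores)."""
    ids = [r.id for r in records]
    n = len(records)
    scores = np.zeros((n, n))
    for i in range(n):
        scores[i, i] = local_score(records[i].sequence, records[i].sequence)
        for j in range(i + 1, n):
            s = local_score(records[i].sequence, records[j].sequence)
            scores[i, j] = scores[j, i] = s
    return pd.DataFrame(scores, index=ids, columns=ids)


def build_similarity_graph(records: list[ProteinRecord],
                           cutoff: float = DEFAULT_CUTOFF,
                           scores: pd.DataFrame | None = None) -> nx.Graph:
    """Weighted similarity graph with normalized edge weights.

    weight(a, b) = score(a, b) / max(self-score(a), self-score(b)), kept when
    >= ``cutoff``.  Nodes carry a ``species`` attribute.
    """
    if scores is None:
        scores = all_vs_all_scores(records)
    graph = nx.Graph()
    for rec in records:
        graph.add_node(rec.id, species=rec.species)
    ids = list(scores.index)
    mat = scores.to_numpy()
    for i, j in itertools.combinations(range(len(ids)), 2):
        denom = max(mat[i, i], mat[j, j])
        if denom <= 0:
            continue
        weight = mat[i, j] / denom
        if weight >= cutoff and weight > 0:
            graph.add_edge(ids[i], ids[j], weight=min(weight, 1.0))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl(graph: nx.Graph, inflation: float = DEFAULT_INFLATION,
        prune_eps: float = 1e-5, max_iter: int = 100) -> list[set[str]]:
    """Markov clustering of a weighted graph.

    Column-stochastic flow matrix with unit self-loops; iterate expansion
    (matrix square) then inflation (elementwise power, renormalize),
    pruning entries below ``prune_eps``, until idempotence (max |delta|
    < 1e-6) or ``max_iter``.  Clusters are the connected systems of the
    converged flow; singletons are allowed.
    """
    if inflation <= 1:
        raise FormatError("MCL inflation must be > 1")
    if prune_eps < 0:
        raise FormatError("prune_eps must be >= 0")
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = M[index[v], index[u]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated[inflated < prune_eps] = 0.0
        cols = inflated.sum(axis=0, keepdims=True)
        cols[cols == 0] = 1.0
        inflated /= cols
        if np.max(np.abs(inflated - M)) < 1e-6:
            M = inflated
            break
        M = inflated
    support = (M > 1e-8) | (M.T > 1e-8)
    flow = nx.from_numpy_array(support.astype(float))
    clusters = []
    for component in nx.connected_components(flow):
        clusters.append({nodes[i] for i in component})
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters


# ---------------------------------------------------------------------------
# pair typing
# ---------------------------------------------------------------------------

def reciprocal_best_hits(scores: pd.DataFrame, species_map: dict[str, str],
                         species_a: str, species_b: str
                         ) -> set[tuple[str, str]]:
    """Reciprocal best hits between two species.

    (a, b) qualifies iff b attains the maximum of score(a, .) over species B
    and a attains the maximum of score(b, .) over species A; all tied
    partners qualify.
    """
    genes_a = [g for g in scores.index if species_map.get(g) == species_a]
    genes_b = [g for g in scores.index if species_map.get(g) == species_b]
    if not genes_a or not genes_b:
        return set()
    best_in_b: dict[str, set[str]] = {}
    for a in genes_a:
        row = scores.loc[a, genes_b]
        top = row.max()
        best_in_b[a] = set(row.index[row == top]) if top > 0 else set()
    best_in_a: dict[str, set[str]] = {}
    for b in genes_b:
        row = scores.loc[b, genes_a]
        top = row.max()
        best_in_a[b] = set(row.index[row == top]) if top > 0 else set()
    pairs = set()
    for a in genes_a:
        for b in best_in_b[a]:
            if a in best_in_a[b]:
                pairs.add((a, b))
    return pairs


@dataclass(frozen=True)
class TypedPair:
    a: str
    b: str
    type: str  # paralog | ortholog | coortholog


def call_pair_types(clusters: list[set[str]], species_map: dict[str, str],
                    rbh: set[tuple[str, str]]) -> list[TypedPair]:
    """Type every within-cluster unordered pair exactly once."""
    rbh_norm = {frozenset(p) for p in rbh}
    pairs = []
    for cluster in clusters:
        for a, b in itertools.combinations(sorted(cluster), 2):
            if species_map.get(a) == species_map.get(b):
                ptype = "paralog"
            elif frozenset((a, b)) in rbh_norm:
                ptype = "ortholog"
            else:
                ptype = "coortholog"
            pairs.append(TypedPair(a, b, ptype))
    return pairs


@dataclass(frozen=True)
class PairTable:
    """Species-by-species pair counts, lower-triangular content.

    ``diagonal[sp]`` = paralog pairs within ``sp``; ``cells[(i, j)]`` with i
    after j in ``species_order`` = (ortholog, coortholog) counts.
    """

    species_order: tuple[str, ...]
    diagonal: dict[str, int]
    cells: dict[tuple[str, str], tuple[int, int]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for i, sp in enumerate(self.species_order):
            row = {}
            for j, other in enumerate(self.species_order):
                if j > i:
                    row[other] = ""
                elif j == i:
                    row[other] = str(self.diagonal.get(sp, 0))
                else:
                    o, c = self.cells.get((sp, other), (0, 0))
                    row[other] = f"{o}/{c}"
            rows[sp] = row
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(self.species_order))


def pair_count_table(typed_pairs: list[TypedPair], species_map: dict[str, str],
                     species_order: tuple[str, ...]) -> PairTable:
    order = {sp: i for i, sp in enumerate(species_order)}
    diagonal = {sp: 0 for sp in species_order}
    cells = {}
    for p in typed_pairs:
        sa, sb = species_map[p.a], species_map[p.b]
        if sa not in order or sb not in order:
            raise FormatError(f"species {sa!r}/{sb!r} not in species_order")
        if p.type == "paralog":
            diagonal[sa] += 1
        else:
            lo, hi = sorted((sa, sb), key=order.get)
            key = (hi, lo)  # row = later species, column = earlier
            o, c = cells.get(key, (0, 0))
            if p.type == "ortholog":
                cells[key] = (o + 1, c)
            else:
                cells[key] = (o, c + 1)
    return PairTable(species_order=tuple(species_order), diagonal=diagonal,
                     cells=cells)


def aggregate_pair_totals(table: PairTable | Table2Fixture
                          ) -> tuple[int, int, int]:
    """(paralog, ortholog, coortholog) totals over the whole table."""
    paralog = sum(table.diagonal.values())
    ortholog = sum(o for o, _ in table.cells.values())
    coortholog = sum(c for _, c in table.cells.values())
    return paralog, ortholog, coortholog


def wrky_density(count: int, genome_size_mb: float) -> float:
    """Family members per megabase, reported to 4 decimals."""
    if genome_size_mb <= 0:
        raise FormatError("genome size must be positive")
    return round(count / genome_size_mb, 4)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyResult:
    clusters: list[set[str]]
    typed_pairs: list[TypedPair]
    pair_table: PairTable


def homolog_groups(records: list[ProteinRecord],
                   inflation: float = DEFAULT_INFLATION,
                   cutoff: float = DEFAULT_CUTOFF) -> HomologyResult:
    """Full pipeline: scores -> graph -> MCL -> RBH -> typed pairs -> table."""
    species_map = {r.id: r.species for r in records}
    species_order = tuple(dict.fromkeys(r.species for r in records))
    scores = all_vs_all_scores(records)
    graph = build_similarity_graph(records, cutoff=cutoff, scores=scores)
    clusters = mcl(graph, inflation=inflation)
    rbh: set[tuple[str, str]] = set()
    for sa, sb in itertools.combinations(species_order, 2):
        rbh |= reciprocal_best_hits(scores, species_map, sa, sb)
    typed = call_pair_types(clusters, species_map, rbh)
    table = pair_count_table(typed, species_map, species_order)
    return HomologyResult(clusters=clusters, typed_pairs=typed, pair_table=table)
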