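"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementation paths (Biopython's
PairwiseAligner, the bisection pI solver, vectorized p-distances) and
recompute the same quantities from first principles.
"""

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11
GAP_EXTEND = 1

NEG = float("-inf")


def _sub(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def gotoh_global(a: str, b: str) -> float:
    """Affine-gap global alignment score (gap of length k costs open + k*ext)."""
    n, m = len(a), len(b)
    open_cost = GAP_OPEN + GAP_EXTEND
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + i * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + j * GAP_EXTEND)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - GAP_EXTEND)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def gotoh_local(a: str, b: str) -> float:
    """Affine-gap Smith-Waterman score (0 when nothing scores positive)."""
    n, m = len(a), len(b)
    open_cost = GAP_OPEN + GAP_EXTEND
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = max(0.0, max(M[i - 1, j - 1], X[i - 1, j - 1],
                                   Y[i - 1, j - 1]) + s)
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - GAP_EXTEND)
            best = max(best, M[i, j])
    return best


def pdistance_pair(row_a: str, row_b: str) -> float:
    """Direct column count over comparable (both non-gap) positions."""
    total = diff = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            total += 1
            if x != y:
                diff += 1
    if total == 0:
        raise ValueError("no comparable columns")
    return diff / total


def pi_grid_search(sequences, pka: dict, step: float = 1e-4) -> np.ndarray:
    """Vectorized dense-grid isoelectric points for many peptides at once.

    ``pka`` maps group -> (pKa, sign); returns the grid pH minimizing the
    absolute net charge for each peptide.
    """
    grid = np.arange(0.0, 14.0 + step, step)
    groups = sorted(pka)
    curves = np.empty((len(grid), len(groups)))
    for k, name in enumerate(groups):
        value, sign = pka[name]
        if sign > 0:
            curves[:, k] = 1.0 / (1.0 + 10.0 ** (grid - value))
        else:
            curves[:, k] = -1.0 / (1.0 + 10.0 ** (value - grid))
    counts = np.zeros((len(groups), len(sequences)))
    for s, seq in enumerate(sequences):
        for k, name in enumerate(groups):
            if name == "n_terminus" or name == "c_terminus":
                counts[k, s] = 1
            else:
                counts[k, s] = seq.count(name)
    charge = curves @ counts  # grid x peptides
    return grid[np.argmin(np.abs(charge), axis=0)]


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies over ``taxa`` as edge lists.

    Nodes: taxon names (leaves) and integers (internal).  Built by
    sequential insertion of each taxon into every edge.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    base = [(taxa[0], 0), (taxa[1], 0), (taxa[2], 0)]
    trees = [base]
    next_internal = 1
    for leaf in taxa[3:]:
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                node = next_internal
                rest = edges[:k] + edges[k + 1:]
                new_trees.append(rest + [(u, node), (v, node), (leaf, node)])
        trees = new_trees
        next_internal += 1
    return trees


def topology_fits_additively(edges, dist, taxa, tol=1e-8) -> bool:
    """Least-squares branch-length fit: zero residual == additive topology."""
    import networkx as nx
    g = nx.Graph()
    for i, (u, v) in enumerate(edges):
        g.add_edge(u, v, idx=i)
    pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1:]]
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        path = nx.shortest_path(g, a, b)
        for u, v in zip(path, path[1:]):
            A[r, g.edges[u, v]["idx"]] = 1.0
        y[r] = dist.loc[a, b]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return bool(np.max(np.abs(A @ x - y)) < tol)


def topology_splits(edges, taxa):
    """Canonical internal bipartitions of an edge-list topology."""
    import networkx as nx
    g = nx.Graph(edges)
    taxa_set = set(taxa)
    anchor = min(taxa)
    splits = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in taxa_set}
        if anchor in side:
            side = taxa_set - side
        if 2 <= len(side) <= len(taxa_set) - 2:
            splits.add(frozenset(side))
    return splits
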