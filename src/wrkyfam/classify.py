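"""Family classification: structural group rules plus reference-guided
neighbor-joining placement for group-II subgroups.

Group assignment follows the structural convention for this family:

* two (or more) WRKY domains with C2H2 fingers  -> group I
* one domain with a C2H2 finger                 -> group II
* one domain with a C2HC finger                 -> group III

Group II subdivides into IIa-IIe only by phylogeny, so subgroups are called
by placing each query domain in a neighbor-joining tree together with a
labeled reference set and reading off the nearest reference by tree-path
(patristic) distance.  Rule-vs-phylogeny disagreements are flagged, never
silently overridden.
"""

from __future__ import annotations

import io as _io
import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Phylo

from . import alignment
from .domain_scan import (DEFAULT_VARIANTS, PatternSpace, WRKYDomain,
                          assemble_domains, spacing_signature)
from .errors import FormatError, InternalError
from .io_formats import ProteinRecord, Table1Fixture

GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")
II_SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted tree over named leaves, backed by a networkx graph.

    Edges carry ``length`` (>= 0) and optionally ``support``.  Internal nodes
    are anonymous integers; leaf nodes are their taxon names.
    """

    def __init__(self, graph: nx.Graph, leaves: tuple[str, ...]):
        self.graph = graph
        self.leaves = tuple(leaves)

    def distances_from(self, node) -> dict:
        """Patristic distances from ``node`` to every other node."""
        return nx.single_source_dijkstra_path_length(
            self.graph, node, weight="length")

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions induced by internal edges.

        Each split is canonicalized as the side NOT containing the
        lexicographically smallest leaf.
        """
        anchor = min(self.leaves)
        splits = set()
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side_u = {n for n in nx.node_connected_component(g, u)
                      if n in set(self.leaves)}
            side = frozenset(side_u if anchor not in side_u
                             else set(self.leaves) - side_u)
            if 2 <= len(side) <= len(self.leaves) - 2:
                splits.add(side)
        return splits

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        internal = [n for n in self.graph.nodes if n not in set(self.leaves)]
        root = internal[0] if internal else next(iter(self.graph.nodes))

        def render(node, parent) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                name = str(node)
            else:
                name = "(" + ",".join(render(c, node) for c in children) + ")"
                support = None
                if parent is not None:
                    support = self.graph.edges[node, parent].get("support")
                if support is not None:
                    name += f"{support:.6g}"
            if parent is not None:
                length = self.graph.edges[node, parent].get("length", 0.0)
                name += f":{length:.6g}"
            return name

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        tree = Phylo.read(_io.StringIO(text), "newick")
        graph = nx.Graph()
        leaves = []
        counter = itertools.count()

        def walk(clade):
            if clade.is_terminal():
                leaves.append(clade.name)
                return clade.name
            node = next(counter)
            for child in clade.clades:
                cid = walk(child)
                graph.add_edge(node, cid,
                               length=float(child.branch_length or 0.0))
                if child.confidence is not None:
                    graph.edges[node, cid]["support"] = float(child.confidence)
            return node

        walk(tree.root)
        if not graph.nodes:  # single-leaf degenerate newick
            graph.add_node(tree.root.name)
            leaves.append(tree.root.name)
        return cls(graph, tuple(leaves))


# ---------------------------------------------------------------------------
# rule classification
# ---------------------------------------------------------------------------

def classify_by_rule(domains: list[WRKYDomain]) -> tuple[str, bool]:
    """Structural group from domain count and finger types.

    Returns ``(group, conflict_flag)``.  Multi-domain proteins containing a
    C2HC finger violate the group-I definition and are flagged.
    """
    if not domains:
        return "unclassified", False
    types = [d.finger.finger_type for d in domains]
    if len(domains) >= 2:
        return "I", "C2HC" in types
    return ("II", False) if types[0] == "C2H2" else ("III", False)


# ---------------------------------------------------------------------------
# alignment-based machinery
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two domain sequences, in [0, 1]."""
    if not a or not b:
        raise FormatError("pairwise_identity: empty sequence")
    return alignment.aligned_identity(a, b)


@dataclass(frozen=True)
class MSA:
    """A rectangular multiple alignment (rows of equal length)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InternalError("MSA rows of unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


def center_star_msa(domain_sequences: dict[str, str], anchor_id: str) -> MSA:
    """Center-star multiple alignment: every sequence is globally aligned to
    the anchor and columns are merged on anchor coordinates.
    """
    if anchor_id not in domain_sequences:
        raise FormatError(f"anchor {anchor_id!r} not among the input sequences")
    anchor = domain_sequences[anchor_id]
    others = [sid for sid in domain_sequences if sid != anchor_id]

    # per-sequence: insertion length after each anchor position (slot 0 = before
    # position 1), plus the gapped pair rows
    inserts: dict[str, list[int]] = {}
    pair_rows: dict[str, tuple[str, str]] = {}
    max_insert = [0] * (len(anchor) + 1)
    for sid in others:
        aln = alignment.global_align(anchor, domain_sequences[sid])
        row_a, row_b = str(aln[0]), str(aln[1])
        ins = [0] * (len(anchor) + 1)
        apos = 0
        for ca in row_a:
            if ca == "-":
                ins[apos] += 1
            else:
                apos += 1
        inserts[sid] = ins
        pair_rows[sid] = (row_a, row_b)
        for slot, n in enumerate(ins):
            max_insert[slot] = max(max_insert[slot], n)

    rows: dict[str, str] = {}
    anchor_row = []
    for slot in range(len(anchor) + 1):
        anchor_row.append("-" * max_insert[slot])
        if slot < len(anchor):
            anchor_row.append(anchor[slot])
    rows[anchor_id] = "".join(anchor_row)

    for sid in others:
        row_a, row_b = pair_rows[sid]
        out = []
        apos = 0
        slot_chars: list[str] = []
        for ca, cb in zip(row_a, row_b):
            if ca == "-":
                slot_chars.append(cb)
            else:
                out.append("-" * (max_insert[apos] - len(slot_chars)))
                out.append("".join(slot_chars))
                slot_chars = []
                out.append(cb)
                apos += 1
        out.append("-" * (max_insert[apos] - len(slot_chars)))
        out.append("".join(slot_chars))
        rows[sid] = "".join(out)

    ids = tuple(domain_sequences)
    msa = MSA(ids=ids, rows=tuple(rows[sid] for sid in ids))
    if msa.n_columns < len(anchor):
        raise InternalError("center-star MSA narrower than its anchor")
    return msa


def pdistance_matrix(msa: MSA) -> pd.DataFrame:
    """p-distances: fraction of differing residues over columns where both
    rows are non-gap.  A pair with zero comparable columns is an error.
    """
    arr = np.array([list(r) for r in msa.rows])
    n = len(msa.ids)
    dist = np.zeros((n, n))
    nongap = arr != "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            total = int(both.sum())
            if total == 0:
                raise FormatError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}")
            diff = int((arr[i][both] != arr[j][both]).sum())
            dist[i, j] = dist[j, i] = diff / total
    return pd.DataFrame(dist, index=msa.ids, columns=msa.ids)


# ---------------------------------------------------------------------------
# neighbor joining + bootstrap
# ---------------------------------------------------------------------------

def neighbor_joining(distance_matrix: pd.DataFrame) -> Tree:
    """Saitou-Nei neighbor joining with deterministic lowest-index tie-break.

    Negative branch lengths are clamped to zero.  Requires a symmetric
    matrix with a zero diagonal and at least 3 taxa.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distance_matrix, dtype=float).copy()
        labels = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise FormatError("neighbor joining requires at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise FormatError("distance matrix must be symmetric with zero diagonal")

    graph = nx.Graph()
    active: list = list(labels)
    next_internal = itertools.count()

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # row-major scan = lowest (i, j) on ties
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new = ("_nj", next(next_internal))
        graph.add_edge(active[i], new, length=max(li, 0.0))
        graph.add_edge(active[j], new, length=max(lj, 0.0))
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)],
                       d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        active = [active[x] for x in keep] + [new]

    # final 3-taxon star
    center = ("_nj", next(next_internal))
    (a, b, c) = active
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    graph.add_edge(a, center, length=max(la, 0.0))
    graph.add_edge(b, center, length=max(lb, 0.0))
    graph.add_edge(c, center, length=max(lc, 0.0))
    return Tree(graph, tuple(labels))


def bootstrap_support(msa: MSA, n_replicates: int = 1000, seed: int = 0
                      ) -> dict[frozenset, float]:
    """Column-resampling bootstrap supports for the NJ tree of ``msa``.

    Returns support (fraction of replicate trees containing the split) for
    every internal bipartition of the tree built from the full alignment.
    Degenerate alignments (all pairwise distances zero) yield all-zero
    supports with a warning.
    """
    if n_replicates < 1:
        raise FormatError("n_replicates must be >= 1")
    dist = pdistance_matrix(msa)
    tree = neighbor_joining(dist)
    splits = tree.bipartitions()
    if float(dist.to_numpy().max()) == 0.0:
        warnings.warn("degenerate alignment (identical rows): supports set to 0")
        return {s: 0.0 for s in splits}
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in splits}
    ncol = msa.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(r[c] for c in cols) for r in msa.rows)
        try:
            rep_dist = pdistance_matrix(MSA(ids=msa.ids, rows=rows))
        except FormatError:
            continue  # a pair lost all comparable columns in this resample
        rep_splits = neighbor_joining(rep_dist).bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: counts[s] / n_replicates for s in splits}


# ---------------------------------------------------------------------------
# subgroup placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSet:
    """Labeled reference domain sequences guiding subgroup placement."""

    entries: tuple[tuple[str, str, str], ...]  # (id, label, sequence)

    def __post_init__(self):
        for rid, label, seq in self.entries:
            if label not in GROUP_LABELS:
                raise FormatError(f"reference {rid!r}: unknown label {label!r}")
            if not seq:
                raise FormatError(f"reference {rid!r}: empty sequence")

    @property
    def labels(self) -> dict[str, str]:
        return {rid: label for rid, label, _ in self.entries}

    @property
    def sequences(self) -> dict[str, str]:
        return {rid: seq for rid, _, seq in self.entries}


def assign_subgroup(tree_or_distances, query_id: str,
                    reference_set: ReferenceSet) -> str:
    """Label of the nearest labeled reference by patristic distance.

    Ties are broken by majority vote among the 3 nearest references, then
    by lexicographic label order.
    """
    labels = reference_set.labels
    if not labels:
        raise FormatError("empty reference set")
    if isinstance(tree_or_distances, Tree):
        dist = tree_or_distances.distances_from(query_id)
        ref_dist = {rid: dist[rid] for rid in labels}
    else:
        ref_dist = {rid: float(tree_or_distances.loc[query_id, rid])
                    for rid in labels}
    best = min(ref_dist.values())
    tied = sorted(rid for rid, d in ref_dist.items() if d == best)
    tied_labels = {labels[r] for r in tied}
    if len(tied_labels) == 1:
        return tied_labels.pop()
    nearest3 = sorted(ref_dist, key=lambda r: (ref_dist[r], r))[:3]
    votes: dict[str, int] = {}
    for rid in nearest3:
        votes[labels[rid]] = votes.get(labels[rid], 0) + 1
    top = max(votes.values())
    return sorted(l for l, v in votes.items() if v == top)[0]


# ---------------------------------------------------------------------------
# whole-family classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCall:
    gene_id: str
    provisional_group: str          # I, II, III or unclassified
    subgroup: str | None = None     # IIa..IIe, set for group II / conflicts
    conflict_flag: bool = False
    support: float = 0.0            # bootstrap agreement of the placement
    n_domains: int = 0
    signatures: tuple[str, ...] = ()
    variant: str = ""
    length: int = 0

    @property
    def group(self) -> str:
        """Full label: subgroup when placed, otherwise the provisional group."""
        if self.provisional_group == "II" and self.subgroup:
            return self.subgroup
        return self.provisional_group


@dataclass(frozen=True)
class FamilyTable:
    calls: tuple[GroupCall, ...]

    def __len__(self) -> int:
        return len(self.calls)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gene_id": c.gene_id, "group": c.group,
            "provisional_group": c.provisional_group,
            "subgroup": c.subgroup or "", "conflict": c.conflict_flag,
            "support": c.support, "n_domains": c.n_domains,
            "signatures": ";".join(c.signatures), "variant": c.variant,
            "length": c.length,
        } for c in self.calls])


def _placement_domain(domains: list[WRKYDomain]) -> WRKYDomain:
    # multi-domain (group I) proteins are placed by their C-terminal domain
    return domains[-1]


def classify_family(records: list[ProteinRecord], reference_set: ReferenceSet,
                    pattern_space: PatternSpace | None = None,
                    variant_set=DEFAULT_VARIANTS,
                    n_bootstrap: int = 100, seed: int = 0) -> FamilyTable:
    """Classify every protein: structural rules, then tree placement of
    single-domain proteins against the labeled references.

    ``support`` is the fraction of bootstrap column-resamples in which the
    nearest reference carries the same label as the point assignment.
    """
    space = pattern_space or PatternSpace()
    per_record = []
    for rec in records:
        domains = assemble_domains(rec.sequence, variant_set, space)
        group, conflict = classify_by_rule(domains)
        per_record.append((rec, domains, group, conflict))

    # tree placement for single-domain proteins (II for subgroups, III for
    # conflict detection)
    queries = {}
    for rec, domains, group, _ in per_record:
        if group in {"II", "III"} and domains:
            d = _placement_domain(domains)
            queries[rec.id] = rec.sequence[d.start - 1:d.end]

    placements: dict[str, tuple[str, float]] = {}
    if queries:
        ref_seqs = reference_set.sequences
        clash = set(queries) & set(ref_seqs)
        if clash:
            raise FormatError(f"query ids collide with reference ids: {sorted(clash)}")
        anchor = reference_set.entries[0][0]
        seqs = {**ref_seqs, **queries}
        msa = center_star_msa(seqs, anchor)
        dist = pdistance_matrix(msa)
        tree = neighbor_joining(dist)
        point = {qid: assign_subgroup(tree, qid, reference_set)
                 for qid in queries}
        agree = {qid: 0 for qid in queries}
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            ncol = msa.n_columns
            arr = np.array([list(r) for r in msa.rows])
            for _ in range(n_bootstrap):
                cols = rng.integers(0, ncol, size=ncol)
                rep = MSA(ids=msa.ids,
                          rows=tuple("".join(row) for row in arr[:, cols]))
                try:
                    rep_dist = pdistance_matrix(rep)
                except FormatError:
                    continue
                for qid in queries:
                    if assign_subgroup(rep_dist, qid, reference_set) == point[qid]:
                        agree[qid] += 1
        for qid in queries:
            support = agree[qid] / n_bootstrap if n_bootstrap > 0 else 0.0
            placements[qid] = (point[qid], support)

    calls = []
    for rec, domains, group, conflict in per_record:
        subgroup = None
        support = 0.0
        if rec.id in placements:
            label, support = placements[rec.id]
            if group == "II":
                if label in II_SUBGROUPS:
                    subgroup = label
                else:  # nearest reference is I or III: rule vs phylogeny clash
                    conflict = True
            elif group == "III" and label in II_SUBGROUPS:
                conflict = True
                subgroup = label
        variant = domains[0].heptapeptide.variant if domains else ""
        calls.append(GroupCall(
            gene_id=rec.id, provisional_group=group, subgroup=subgroup,
            conflict_flag=conflict, support=support, n_domains=len(domains),
            signatures=tuple(spacing_signature(d) for d in domains),
            variant=variant, length=len(rec.sequence)))
    return FamilyTable(calls=tuple(calls))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyMember:
    """Minimal per-gene record for summaries (also built from fixtures)."""

    gene_id: str
    group: str
    variant: str
    length: int


def members_from_table1(fixture: Table1Fixture) -> list[FamilyMember]:
    return [FamilyMember(gene_id=r.gene_name, group=r.group,
                         variant=r.conserved_motif, length=r.orf_len_aa)
            for r in fixture.rows]


@dataclass(frozen=True)
class FamilySummary:
    n_members: int
    group_counts: dict[str, int]      # per full label, plus aggregate "II"
    variant_counts: dict[str, int]
    length_min: int
    length_max: int
    length_mean: float                # unrounded
    length_mean_1dp: float


def summarize_family(family) -> FamilySummary:
    """Aggregate counts over a :class:`FamilyTable` or FamilyMember list."""
    if isinstance(family, FamilyTable):
        members = [FamilyMember(c.gene_id, c.group, c.variant, c.length)
                   for c in family.calls]
    else:
        members = list(family)
    group_counts: dict[str, int] = {}
    variant_counts: dict[str, int] = {}
    for m in members:
        group_counts[m.group] = group_counts.get(m.group, 0) + 1
        if m.variant:
            variant_counts[m.variant] = variant_counts.get(m.variant, 0) + 1
    group_counts["II"] = (group_counts.get("II", 0)
                          + sum(group_counts.get(s, 0) for s in II_SUBGROUPS))
    lengths = [m.length for m in members if m.length > 0]
    mean = float(np.mean(lengths)) if lengths else 0.0
    return FamilySummary(
        n_members=len(members),
        group_counts=group_counts,
        variant_counts=variant_counts,
        length_min=min(lengths) if lengths else 0,
        length_max=max(lengths) if lengths else 0,
        length_mean=mean,
        length_mean_1dp=round(mean, 1),
    )
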