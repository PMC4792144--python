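"""Readers/writers for the standard formats the pipeline touches, plus the
packaged literature-table fixtures.

Conventions
-----------
* GFF3 coordinates are 1-based inclusive and kept as written; protein residue
  positions are 1-based inclusive throughout the package.
* TSV with a header row is the exchange format for matrices and edge lists.
* The two packaged fixtures (``table1.tsv``, ``table2.tsv``) are verbatim
  transcriptions of printed gene-family tables (including printed anomalies);
  loaders verify a SHA-256 checksum before parsing.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import FixtureError, FormatError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

_FIXTURE_SHA256 = {
    "table1.tsv": "41b4c193794b34fc16ab8b63634273052d3f4b4ff6ed2b87e1c21065623ccf9b",
    "table2.tsv": "f7af14ebb03623801368e214cdd821844f89d2193ed1a11082134d6ea6c54764",
}


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a species tag.

    ``sequence`` is upper-case over the 20 standard residues plus ``X``.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene model as an ordered list of exons (1-based inclusive)."""

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start > end:
                raise FormatError(f"{self.gene_id}: exon {start}-{end} reversed")
            if prev_end is not None and start <= prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons")
            prev_end = end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated; record order is preserved.
    The first whitespace-delimited token of each header is the id.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(recs, handle, "fasta")


def read_species_map(path) -> dict[str, str]:
    """Read a two-column TSV ``gene_id <tab> species`` into a dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return mapping
        for row in reader:
            if len(row) < 2:
                raise FormatError(f"{path}: malformed species-map row {row!r}")
            mapping[row[0]] = row[1]
    return mapping


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3_gene_models(path) -> list[GeneModel]:
    """Parse exon features from a GFF3 file into gene models.

    Exons are grouped by their ``Parent`` attribute (falling back to ``ID``);
    mRNA features map their parents through to genes when present.
    """
    path = Path(path)
    parent_of: dict[str, str] = {}
    strands: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            ftype, start, end, strand, attrs = (
                fields[2], fields[3], fields[4], fields[6], fields[8])
            attributes = _gff3_attributes(attrs)
            if ftype in {"gene", "mRNA"}:
                fid = attributes.get("ID")
                if fid is not None:
                    parent_of[fid] = attributes.get("Parent", fid)
                    strands.setdefault(fid, strand)
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent is None:
                    raise FormatError(
                        f"{path}:{lineno}: exon without Parent attribute: {line!r}")
                root = parent
                while root in parent_of and parent_of[root] != root:
                    root = parent_of[root]
                if root not in exons:
                    order.append(root)
                exons.setdefault(root, []).append((int(start), int(end)))
                strands.setdefault(root, strand)
    models = []
    for gene_id in order:
        models.append(GeneModel(gene_id=gene_id, strand=strands[gene_id],
                                exons=tuple(exons[gene_id])))
    return models


def write_gff3_gene_models(models: Iterable[GeneModel], path,
                           seqid: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(f"{seqid}\twrkyfam\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(f"{seqid}\twrkyfam\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n")


# ---------------------------------------------------------------------------
# packaged table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    gene_name: str
    orf_len_aa: int
    group: str
    conserved_motif: str
    domain_pattern: str
    best_hit_at_name: str
    best_hit_locus: str
    stress: str = ""


@dataclass(frozen=True)
class Table1Fixture:
    """Per-gene family classification table (95 carrot WRKY genes)."""

    rows: tuple[Table1Row, ...]

    def row(self, gene_name: str) -> Table1Row:
        for r in self.rows:
            if r.gene_name == gene_name:
                return r
        raise KeyError(gene_name)

    def __len__(self) -> int:
        return len(self.rows)


SPECIES_ORDER = ("Cre", "Ppa", "Smo", "Pab", "Ath", "Dca", "Vvi", "Mdo", "Osa")


@dataclass(frozen=True)
class Table2Fixture:
    """Cross-species homolog pair-count table.

    ``diagonal[sp]`` holds the paralog-pair count for species ``sp``;
    ``cells[(a, b)]`` (lower-triangular, a after b in ``species_order``) holds
    ``(ortholog_count, coortholog_count)``.
    """

    species_order: tuple[str, ...]
    diagonal: dict[str, int]
    cells: dict[tuple[str, str], tuple[int, int]]


def _fixture_text(name: str) -> str:
    ref = resources.files("wrkyfam.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"packaged fixture {name} missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(
            f"fixture {name} corrupted: sha256 {digest} != {_FIXTURE_SHA256[name]}")
    return raw.decode("utf-8")


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 95-gene family table, verbatim as printed."""
    text = _fixture_text("table1.tsv")
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    rows = []
    for rec in reader:
        rows.append(Table1Row(
            gene_name=rec["gene_name"],
            orf_len_aa=int(rec["orf_aa"]),
            group=rec["group"],
            conserved_motif=rec["conserved_motif"],
            domain_pattern=rec["domain_pattern"],
            best_hit_at_name=rec["best_hit_at_name"],
            best_hit_locus=rec["best_hit_locus"],
            stress=rec.get("stress", "") or "",
        ))
    if len(rows) != 95:
        raise FixtureError(f"table1 fixture has {len(rows)} rows, expected 95")
    return Table1Fixture(rows=tuple(rows))


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged 9-species paralog/ortholog/coortholog pair table."""
    text = _fixture_text("table2.tsv")
    lines = [l for l in text.splitlines() if l.strip()]
    header = tuple(lines[0].split("\t")[1:])
    if header != SPECIES_ORDER:
        raise FixtureError(f"unexpected species order {header}")
    diagonal: dict[str, int] = {}
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        sp = parts[0]
        i = SPECIES_ORDER.index(sp)
        values = parts[1:]
        if len(values) != i + 1:
            raise FixtureError(f"row {sp}: expected {i + 1} cells, got {len(values)}")
        for j, cell in enumerate(values):
            other = SPECIES_ORDER[j]
            if other == sp:
                diagonal[sp] = int(cell)
            else:
                ortho, co = cell.split("/")
                cells[(sp, other)] = (int(ortho), int(co))
    if any(v < 0 for v in diagonal.values()):
        raise FixtureError("negative paralog count")
    return Table2Fixture(species_order=SPECIES_ORDER, diagonal=diagonal, cells=cells)


# ---------------------------------------------------------------------------
# Newick / edge lists / matrices
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if not math.isfinite(x):
        raise FormatError(f"non-finite value {x!r} cannot be serialized")
    return f"{x:.6g}"


def write_newick(tree, path) -> None:
    """Serialize an unrooted :class:`~wrkyfam.classify.Tree` as Newick.

    The tree is rooted for output at an arbitrary internal node; bootstrap
    supports (when present) are written as internal node labels.
    """
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path):
    from .classify import Tree  # local import: classify depends on io_formats
    with open(path) as fh:
        text = fh.read().strip()
    return Tree.from_newick(text)


def write_edge_list(edges: Sequence[tuple[str, str, float]], path) -> None:
    """Write weighted edges as TSV (``source  target  weight``)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{_fmt(w)}\n")


def read_edge_list(path) -> list[tuple[str, str, float]]:
    edges = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return edges
        for row in reader:
            edges.append((row[0], row[1], float(row[2])))
    return edges


def write_tsv_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labeled matrix as TSV with 6-significant-digit floats."""
    for value in matrix.to_numpy().ravel():
        if isinstance(value, float) and not math.isfinite(value):
            raise FormatError("non-finite value in matrix")
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
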