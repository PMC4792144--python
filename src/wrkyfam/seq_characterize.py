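"""Protein physicochemical descriptors, exon-intron summaries, and promoter
cis-element scanning.

The isoelectric point is computed from the Henderson-Hasselbalch net-charge
model with the Bjellqvist pKa set (below): net charge at a given pH is

    z(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH))

over the free termini plus the ionizable side chains (K, R, H basic;
D, E, C, Y acidic), and pI is the zero crossing located by bisection on
[0, 14].  GRAVY is the mean Kyte-Doolittle hydropathy; the instability
index is the standard length-normalized dipeptide-weight sum (stable < 40);
the aliphatic index is X(A) + 2.9 X(V) + 3.9 (X(I) + X(L)) in mole percent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData

from .errors import FormatError
from .io_formats import GeneModel

#: Bjellqvist pKa values. Termini first, then side chains; sign marks
#: acidic (-) vs basic (+) groups.
PKA = {
    "n_terminus": (9.094, +1),
    "c_terminus": (3.100, -1),
    "K": (10.00, +1),
    "R": (12.00, +1),
    "H": (5.98, +1),
    "D": (4.05, -1),
    "E": (4.45, -1),
    "C": (9.00, -1),
    "Y": (10.00, -1),
}

RESIDUE_CLASSES = {
    "positive": set("KRH"),
    "negative": set("DE"),
    "aliphatic": set("AVIL"),
    "aromatic": set("FWY"),
}


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of the peptide at the given pH under the bundled pKa set."""
    if not sequence:
        raise FormatError("empty sequence")
    groups = [PKA["n_terminus"], PKA["c_terminus"]]
    groups += [PKA[res] for res in sequence if res in PKA]
    charge = 0.0
    for pka, sign in groups:
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Always defined: the termini alone make the charge curve strictly
    decreasing from positive to negative.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity (mean Kyte-Doolittle value)."""
    if not sequence:
        raise FormatError("empty sequence")
    clean = sequence.replace("X", "")
    if not clean:
        raise FormatError("sequence contains only ambiguous residues")
    return ProteinAnalysis(clean).gravy()


def instability_index(sequence: str) -> float:
    """Dipeptide-weight instability index; < 40 classifies as stable.

    A length-1 sequence has no dipeptides and scores 0.
    """
    if not sequence:
        raise FormatError("empty sequence")
    clean = sequence.replace("X", "")
    if len(clean) < 2:
        return 0.0
    return ProteinAnalysis(clean).instability_index()


def is_stable(sequence: str) -> bool:
    return instability_index(sequence) < 40.0


def aliphatic_index(sequence: str) -> float:
    """Relative volume of aliphatic side chains, in mole percent units."""
    if not sequence:
        raise FormatError("empty sequence")
    n = len(sequence)
    x = {res: 100.0 * sequence.count(res) / n for res in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def residue_class_percentages(sequence: str,
                              aliphatic_includes_g: bool = False
                              ) -> dict[str, float]:
    """Percentages of positive/negative/aliphatic/aromatic residues.

    The aliphatic class is {A, V, I, L} by default; glycine can be included
    since the membership of that class is convention-dependent.
    """
    if not sequence:
        raise FormatError("empty sequence")
    classes = {k: set(v) for k, v in RESIDUE_CLASSES.items()}
    if aliphatic_includes_g:
        classes["aliphatic"] = classes["aliphatic"] | {"G"}
    n = len(sequence)
    return {name: 100.0 * sum(1 for r in sequence if r in members) / n
            for name, members in classes.items()}


@dataclass(frozen=True)
class PhysChemProfile:
    length: int
    pI: float
    gravy: float
    instability_index: float
    aliphatic_index: float
    percent_positive: float
    percent_negative: float
    percent_aliphatic: float
    percent_aromatic: float


def physchem_profile(sequence: str) -> PhysChemProfile:
    pct = residue_class_percentages(sequence)
    return PhysChemProfile(
        length=len(sequence),
        pI=isoelectric_point(sequence),
        gravy=gravy(sequence),
        instability_index=instability_index(sequence),
        aliphatic_index=aliphatic_index(sequence),
        percent_positive=pct["positive"],
        percent_negative=pct["negative"],
        percent_aliphatic=pct["aliphatic"],
        percent_aromatic=pct["aromatic"],
    )


# ---------------------------------------------------------------------------
# exon-intron structure
# ---------------------------------------------------------------------------

def count_introns(gene_model: GeneModel) -> int:
    return len(gene_model.exons) - 1


def exon_intron_summary(models) -> dict[int, int]:
    """Histogram mapping intron count -> number of genes."""
    hist: dict[int, int] = {}
    for m in models:
        k = count_introns(m)
        hist[k] = hist.get(k, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# promoter cis elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str  # IUPAC nucleotide codes
    description: str = ""

    def __post_init__(self):
        bad = set(self.consensus.upper()) - set(ambiguous_dna_values)
        if bad:
            raise FormatError(
                f"element {self.name}: non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class ElementHit:
    element: str
    start: int       # 1-based on the forward promoter strand
    strand: str      # "+" or "-"
    matched: str     # substring of the + strand at [start, start+len)


#: Bundled dictionary of the ten promoter elements most often reported for
#: this family's promoters.  Consensi are compact IUPAC approximations of
#: the corresponding plant cis-element definitions; users may supply their
#: own dictionary via TSV.
DEFAULT_ELEMENTS = (
    CisElement("W-box", "YTGACY", "WRKY binding site"),
    CisElement("G-box", "CACGTG", "light responsiveness"),
    CisElement("Sp1", "GGGCGG", "light responsiveness"),
    CisElement("CGTCA-motif", "CGTCA", "MeJA responsiveness"),
    CisElement("ERF", "GCCGCC", "ethylene responsiveness"),
    CisElement("ABRE", "TACGTG", "abscisic acid responsiveness"),
    CisElement("Skn-1", "GTCAT", "endosperm expression"),
    CisElement("TC-rich", "ATTTTCTTCA", "defense and stress responsiveness"),
    CisElement("MBS", "CAACTG", "MYB binding site, drought inducibility"),
    CisElement("HSE", "AAAAAATTTC", "heat stress responsiveness"),
)


def load_element_dictionary(path) -> tuple[CisElement, ...]:
    """Read a TSV element dictionary: name, consensus[, description]."""
    elements = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"malformed element row: {line!r}")
            desc = parts[2] if len(parts) > 2 else ""
            elements.append(CisElement(parts[0], parts[1], desc))
    return tuple(elements)


_IUPAC_CLASS = {code: values for code, values in ambiguous_dna_values.items()}


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for code in consensus.upper():
        values = _IUPAC_CLASS[code]
        parts.append(values if len(values) == 1 else f"[{values}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_cis_elements(promoter: str, dictionary=DEFAULT_ELEMENTS
                      ) -> list[ElementHit]:
    """All matches of each element on both strands, sorted by + position.

    ``N`` in the promoter matches nothing; minus-strand hits are reported in
    forward-strand coordinates with the forward-strand substring.
    """
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise FormatError(f"non-nucleotide characters in promoter: {sorted(bad)}")
    hits = []
    for element in dictionary:
        pattern = _consensus_regex(element.consensus)
        width = len(element.consensus)
        for m in pattern.finditer(promoter):
            hits.append(ElementHit(element.name, m.start() + 1, "+", m.group(1)))
        rc = str(Seq(element.consensus).reverse_complement())
        for m in _consensus_regex(rc).finditer(promoter):
            hits.append(ElementHit(element.name, m.start() + 1, "-", m.group(1)))
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits
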