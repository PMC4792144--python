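"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator is a pure function of its seed and specification, so the
whole test suite runs with no downloads: proteins carry implanted
heptapeptide + zinc-finger architectures, multi-species families follow a
simulated duplication/speciation history, promoters carry implanted cis
elements, count matrices hide planted correlated modules, and Ct tables
encode known fold changes.

Background amino-acid composition is uniform over the 18 residues other
than C and H: keeping cysteine and histidine out of the random background
guarantees that the only zinc-finger-competent motifs in a generated
protein are the implanted ones, so implant coordinates are exact truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_scan import DEFAULT_VARIANTS, PatternSpace
from .errors import ConfigError
from .io_formats import GeneModel, ProteinRecord
from .seq_characterize import DEFAULT_ELEMENTS, CisElement, ElementHit

BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVWY"  # 20 minus C, H


def _background(rng: np.random.Generator, n: int,
                alphabet: str = BACKGROUND_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# single proteins with implanted domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainTruth:
    hepta_start: int                  # 1-based
    variant: str
    finger_positions: tuple[int, int, int, int]
    finger_type: str
    spacings: tuple[int, int, int]


@dataclass(frozen=True)
class ProteinTruth:
    group: str
    subgroup: str | None
    domains: tuple[DomainTruth, ...]
    seed: int


def _domain_segment(rng: np.random.Generator, variant: str, finger_type: str,
                    spacings: tuple[int, int, int], linker: int
                    ) -> tuple[str, int, tuple[int, int, int, int]]:
    """Build hepta + linker + finger; returns (segment, hepta offset 0-based,
    finger positions relative to segment start, 0-based)."""
    n1, n2, n3 = spacings
    last = "H" if finger_type == "C2H2" else "C"
    segment = (variant + _background(rng, linker)
               + "C" + _background(rng, n1)
               + "C" + _background(rng, n2)
               + "H" + _background(rng, n3)
               + last)
    c1 = 7 + linker
    positions = (c1, c1 + 1 + n1, c1 + 2 + n1 + n2, c1 + 3 + n1 + n2 + n3)
    return segment, positions


def gen_wrky_protein(group: str, seed: int, *, subgroup: str | None = None,
                     variant: str = "WRKYGQK",
                     spacing_choice: tuple[int, int, int] | None = None,
                     linker: int = 5, flank: int = 30,
                     record_id: str | None = None, species: str = ""
                     ) -> tuple[ProteinRecord, ProteinTruth]:
    """Generate one protein of the requested group with implanted domains.

    Group I gets two C2H2 domains, II one C2H2, III one C2HC.  Spacings
    default to the canonical motif for the group; truth records implant
    coordinates.
    """
    if group not in {"I", "II", "III"}:
        raise ConfigError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    finger_type = "C2HC" if group == "III" else "C2H2"
    if spacing_choice is None:
        spacing_choice = (7, 23, 1) if group == "III" else (4, 23, 1)
    n_domains = 2 if group == "I" else 1
    parts = [_background(rng, flank)]
    truths = []
    offset = flank
    for k in range(n_domains):
        seg, positions = _domain_segment(rng, variant, finger_type,
                                         spacing_choice, linker)
        truths.append(DomainTruth(
            hepta_start=offset + 1, variant=variant,
            finger_positions=tuple(offset + 1 + p for p in positions),
            finger_type=finger_type, spacings=spacing_choice))
        parts.append(seg)
        offset += len(seg)
        spacer = _background(rng, flank)
        parts.append(spacer)
        offset += flank
    sequence = "".join(parts)
    rid = record_id or f"syn_{group}_{seed}"
    record = ProteinRecord(id=rid, sequence=sequence, species=species)
    truth = ProteinTruth(group=group, subgroup=subgroup,
                         domains=tuple(truths), seed=seed)
    return record, truth


def mutate_sequence(sequence: str, sub_prob: float, rng: np.random.Generator,
                    protect: tuple[tuple[int, int], ...] = ()) -> str:
    """Per-site substitution with probability ``sub_prob``.

    ``protect`` lists 1-based inclusive windows (e.g. implanted domains)
    that are never mutated, so structural truth labels survive mutation.
    """
    protected = np.zeros(len(sequence), dtype=bool)
    for lo, hi in protect:
        protected[lo - 1:hi] = True
    chars = list(sequence)
    hits = rng.random(len(chars)) < sub_prob
    for i in np.nonzero(hits & ~protected)[0]:
        choices = [c for c in BACKGROUND_ALPHABET if c != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# subgroup templates for classifier tests
# ---------------------------------------------------------------------------

def make_reference_templates(seed: int = 2016) -> dict[str, str]:
    """Synthetic domain templates for labels I, IIa-IIe, III.

    These are NOT real reference proteins; they are randomized domain
    sequences with the right architecture, used to exercise the placement
    machinery without bundling third-party data.
    """
    rng = np.random.default_rng(seed)
    templates = {}
    for label in ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III"):
        finger_type = "C2HC" if label == "III" else "C2H2"
        spacings = (7, 23, 1) if label == "III" else (4, 23, 1)
        seg, _ = _domain_segment(rng, "WRKYGQK", finger_type, spacings, 5)
        templates[label] = seg
    return templates


def gen_subgroup_queries(n_per_subgroup: int, sub_prob: float, seed: int,
                         templates: dict[str, str] | None = None
                         ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Group-II query proteins derived from subgroup templates by per-site
    substitution noise (anchor and coordinating residues protected).

    Returns the records and the truth map id -> subgroup.
    """
    templates = templates or make_reference_templates()
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for label in ("IIa", "IIb", "IIc", "IId", "IIe"):
        base = templates[label]
        # protect the anchor and the four coordinating residues so mutated
        # queries keep the implanted architecture; spacers are free to mutate
        # (the mutation alphabet contains no C/H, so spacings cannot shift)
        c1 = 13  # templates use linker 5 after the 7-residue anchor
        n1, n2, n3 = (4, 23, 1)
        coords = (c1, c1 + 1 + n1, c1 + 2 + n1 + n2, c1 + 3 + n1 + n2 + n3)
        protect = ((1, 7),) + tuple((p, p) for p in coords)
        for k in range(n_per_subgroup):
            seq = mutate_sequence(base, sub_prob, rng, protect=protect)
            rid = f"q_{label}_{k}"
            records.append(ProteinRecord(id=rid, sequence=seq))
            truth[rid] = label
    return records, truth


# ---------------------------------------------------------------------------
# family evolution along a species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTruth:
    pair_types: dict[frozenset, str]   # {a, b} -> paralog|ortholog|coortholog
    families: dict[str, int]           # gene id -> root-family index
    seed: int


def simulate_family_evolution(n_families: int = 25,
                              species: tuple[str, ...] = ("A", "B", "C"),
                              birth_rate: float = 0.03,
                              loss_rate: float = 0.02,
                              sub_prob: float = 0.03,
                              seq_length: int = 120,
                              seed: int = 0
                              ) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Evolve gene families along a fixed 3-species tree ((A,B),C).

    Each family starts from one random ancestral protein.  Along every
    branch each gene lineage is lost with ``loss_rate``, duplicates with
    probability ``birth_rate`` (at most one duplication per branch per
    lineage), and accumulates per-site substitutions with ``sub_prob``.

    Truth pair types follow the duplication/speciation history: same-species
    pairs are paralogs; cross-species pairs whose paths contain no
    duplication after their last common speciation are orthologs; remaining
    cross-species pairs are coorthologs.
    """
    if species != ("A", "B", "C"):
        raise ConfigError("the bundled species tree is the 3-taxon ((A,B),C)")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    pair_types: dict[frozenset, str] = {}
    families: dict[str, int] = {}
    counter = itertools.count()

    # lineage = (sequence, dup_tags) where dup_tags is the set of duplication
    # event ids on the lineage's path from the family root
    def branch(lineages, dup_offset):
        """Evolve a list of lineages along one branch; returns survivors."""
        out = []
        for seq, tags in lineages:
            if rng.random() < loss_rate and len(lineages) > 1:
                continue
            seq = mutate_sequence(seq, sub_prob, rng)
            if rng.random() < birth_rate:
                event = f"dup{next(counter)}"
                out.append((mutate_sequence(seq, sub_prob, rng),
                            tags | {event}))
                out.append((seq, tags | {event + "b"}))
            else:
                out.append((seq, tags))
        return out

    for fam in range(n_families):
        root_seq = _background(rng, seq_length)
        root = [(root_seq, frozenset())]
        # first speciation: (AB) ancestor vs C
        ab_anc = branch(root, fam)
        c_lin = branch(root, fam)
        # second speciation: A vs B
        a_lin = branch(ab_anc, fam)
        b_lin = branch(ab_anc, fam)
        genes: dict[str, tuple[str, frozenset, str]] = {}
        for sp, lineages in (("A", a_lin), ("B", b_lin), ("C", c_lin)):
            for i, (seq, tags) in enumerate(lineages):
                gid = f"{sp}_f{fam}_g{i}"
                genes[gid] = (seq, tags, sp)
                records.append(ProteinRecord(id=gid, sequence=seq, species=sp))
                families[gid] = fam
        ids = sorted(genes)
        for x, y in itertools.combinations(ids, 2):
            _, tx, sx = genes[x]
            _, ty, sy = genes[y]
            if sx == sy:
                ptype = "paralog"
            else:
                # duplications not shared by both paths happened after the
                # last common ancestor; the speciation split A/B vs C (or
                # A vs B) always separates the paths, so any unshared
                # duplication is post-speciation
                if tx.symmetric_difference(ty):
                    ptype = "coortholog"
                else:
                    ptype = "ortholog"
            pair_types[frozenset((x, y))] = ptype
    return records, FamilyTruth(pair_types=pair_types, families=families,
                                seed=seed)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def gen_gene_models(intron_count_spec: dict[int, int], seed: int = 0,
                    exon_length: tuple[int, int] = (80, 400),
                    intron_length: tuple[int, int] = (60, 800)
                    ) -> tuple[list[GeneModel], dict[str, int]]:
    """Gene models with a planted intron-count histogram.

    ``intron_count_spec`` maps intron count -> number of genes; truth maps
    gene id -> intron count.
    """
    rng = np.random.default_rng(seed)
    models, truth = [], {}
    gid = itertools.count(1)
    for introns in sorted(intron_count_spec):
        for _ in range(intron_count_spec[introns]):
            name = f"gene{next(gid)}"
            pos = int(rng.integers(1, 10000))
            exons = []
            for k in range(introns + 1):
                length = int(rng.integers(*exon_length))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(*intron_length))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gene_id=name, strand=strand,
                                    exons=tuple(exons)))
            truth[name] = introns
    return models, truth


# ---------------------------------------------------------------------------
# promoters with implanted elements
# ---------------------------------------------------------------------------

def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values
    return "".join(
        rng.choice(list(ambiguous_dna_values[c])) for c in consensus.upper())


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def gen_promoters(n: int, implant_spec: dict[str, int], seed: int = 0,
                  length: int = 1500,
                  dictionary: tuple[CisElement, ...] = DEFAULT_ELEMENTS,
                  scrub_spurious: bool = True
                  ) -> tuple[dict[str, str], dict[str, list[ElementHit]]]:
    """Promoters of fixed length with non-overlapping implanted elements.

    ``implant_spec`` maps element name -> implants per promoter; implants
    are placed on a random strand.  Backgrounds are uniform ACGT; because
    the short consensi match uniform DNA by chance, ``scrub_spurious``
    re-randomizes background positions until the implanted hits are the only
    dictionary matches, making truth exhaustive (precision AND recall 1).
    """
    by_name = {e.name: e for e in dictionary}
    unknown = set(implant_spec) - set(by_name)
    if unknown:
        raise ConfigError(f"unknown elements in implant spec: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    promoters, truth = {}, {}
    for i in range(n):
        seq = list(_background(rng, length, alphabet="ACGT"))
        occupied = np.zeros(length, dtype=bool)
        hits = []
        for name, count in sorted(implant_spec.items()):
            element = by_name[name]
            width = len(element.consensus)
            for _ in range(count):
                for _attempt in range(200):
                    start = int(rng.integers(0, length - width + 1))
                    if not occupied[start:start + width].any():
                        break
                else:
                    raise ConfigError("could not place implants without overlap")
                realized = _realize_consensus(element.consensus, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                forward = realized if strand == "+" else _revcomp(realized)
                seq[start:start + width] = list(forward)
                occupied[start:start + width] = True
                hits.append(ElementHit(element=name, start=start + 1,
                                       strand=strand, matched=forward))
        if scrub_spurious:
            from .seq_characterize import scan_cis_elements
            planted = {(h.element, h.start) for h in hits}
            for _round in range(100):
                spurious = [h for h in scan_cis_elements("".join(seq), dictionary)
                            if (h.element, h.start) not in planted]
                if not spurious:
                    break
                progress = False
                for h in spurious:
                    span = range(h.start - 1, h.start - 1 + len(h.matched))
                    free = [p for p in span if not occupied[p]]
                    if free:
                        p = free[int(rng.integers(len(free)))]
                        seq[p] = str(rng.choice([c for c in "ACGT"
                                                 if c != seq[p]]))
                        progress = True
                if not progress:
                    raise ConfigError(
                        "cannot scrub a chance motif overlapping implants")
            else:
                raise ConfigError("background scrubbing did not converge")
        pid = f"prom{i + 1}"
        promoters[pid] = "".join(seq)
        truth[pid] = sorted(hits, key=lambda h: h.start)
    return promoters, truth


# ---------------------------------------------------------------------------
# expression matrices with planted modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    modules: dict[str, int]        # gene -> module index (-1 = background)
    loadings: dict[str, float]     # gene -> latent-factor loading
    seed: int


def gen_expression(n_genes: int = 200, n_samples: int = 8,
                   module_spec: tuple[tuple[int, float], ...] = ((20, 0.9), (20, -0.9)),
                   nb_dispersion: float = 0.1, base_mean: float = 200.0,
                   seed: int = 0):
    """Negative-binomial count matrix with planted correlated modules.

    Each module's genes share a per-sample latent factor with the given
    loading (negative loadings plant anti-correlation).  Returns an
    :class:`~wrkyfam.expression.ExpressionMatrix` plus truth.
    """
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    modules: dict[str, int] = {g: -1 for g in genes}
    loadings: dict[str, float] = {g: 0.0 for g in genes}
    cursor = 0
    for mi, (size, loading) in enumerate(module_spec):
        if cursor + size > n_genes:
            raise ConfigError("module spec exceeds gene count")
        for g in genes[cursor:cursor + size]:
            modules[g] = mi
            loadings[g] = loading
        cursor += size
    latent = rng.normal(size=(len(module_spec), n_samples))
    counts = np.zeros((n_genes, n_samples))
    for i, g in enumerate(genes):
        base = base_mean * float(rng.lognormal(0.0, 0.5))
        mi = modules[g]
        log_shift = loadings[g] * latent[mi] if mi >= 0 else np.zeros(n_samples)
        mean = base * np.exp(log_shift)
        # NB via gamma-Poisson: shape r = 1/dispersion
        r = 1.0 / nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts[i] = rng.poisson(lam)
    lengths = pd.Series(rng.integers(500, 5000, size=n_genes), index=genes,
                        name="length")
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=lengths)
    return matrix, ExpressionTruth(modules=modules, loadings=loadings, seed=seed)


# ---------------------------------------------------------------------------
# Ct tables with planted folds
# ---------------------------------------------------------------------------

def gen_ct_table(true_folds: dict[tuple[str, str], float],
                 calibrator: str = "control", reference_gene: str = "TUB",
                 noise_sd: float = 0.0, n_replicates: int = 3, seed: int = 0
                 ) -> pd.DataFrame:
    """Ct table consistent with planted fold changes under the ddCt model.

    ``true_folds`` maps (gene, condition) -> fold relative to the
    calibrator condition; replicate rows get Gaussian Ct noise.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for g, _ in true_folds})
    conditions = sorted({c for _, c in true_folds})
    rows = []
    base_ct = {g: 22.0 + 2.0 * rng.random() for g in genes}
    for gene in genes:
        for condition in [calibrator] + [c for c in conditions if c != calibrator]:
            fold = 1.0 if condition == calibrator else true_folds.get(
                (gene, condition), 1.0)
            target = base_ct[gene] - np.log2(fold)
            for rep in range(n_replicates):
                rows.append({
                    "gene": gene, "condition": condition, "timepoint": 0,
                    "replicate": rep + 1,
                    "ct_target": target + rng.normal(0.0, noise_sd),
                    "ct_reference": 18.0 + rng.normal(0.0, noise_sd),
                    "reference_gene": reference_gene,
                })
    return pd.DataFrame(rows)
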