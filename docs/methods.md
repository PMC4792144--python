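# Methods

This note documents the models, algorithmic contracts and numerical
choices behind `wrkyfam`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Domain model and scanning

A WRKY domain is an anchor heptapeptide followed by a zinc finger. The
scanner is pattern-based, not profile-based: anchors are exact matches
against a configurable variant set (default `WRKYGQK, WRKYGKK, WRKYDQK,
WRKYDHK, WKKYDHK, WKKYDQK` — both the WRKY- and WKKY-initial spellings of
the DHK/DQK variants circulate in published family tables, and the package
accepts both), and fingers are quadruples `C...C...H...(H|C)` whose
spacer-run lengths fall in a `PatternSpace`. The default space accepts
C2H2 spacings n1 ∈ [4,5], n2 ∈ [22,24], n3 = 1 and C2HC 7/[22,23]/1; the
`strict` profile narrows n2 to the textbook [22,23] (C2H2) and 23 (C2HC).
The default is wider because curated family tables contain observed X22
and X24 group-II entries. The anchor-to-finger gap is bounded at 60
residues, the canonical domain span; search is left-most-first with C2H2
preferred over C2HC at equal start. The ambiguous residue `X` never
matches an anchor or coordinating position. Assembly is greedy left to
right, each finger consumed by at most one anchor; in multi-domain
proteins the last domain is tagged `C` and the others `N`.

Trade-off: pattern scanning cannot score partial or degenerate domains the
way a profile HMM would; proteins whose spacings fall outside the
configured ranges are simply not called. The synthetic generators implant
spacings inside the range, so recovery tests certify the scanner's
contract, not its sensitivity on divergent real sequences.

## Group rules and subgroup placement

Group assignment is a pure function of domain count and finger type
(two C2H2 domains → I; one C2H2 → II; one C2HC → III; none →
unclassified). Multi-domain proteins containing a C2HC finger are called I
with a conflict flag. Subgroups IIa–IIe are phylogenetic: query domains
(the C-terminal domain for multi-domain proteins) are aligned together
with labeled reference domains by center-star alignment anchored at the
first reference, p-distances are computed over mutually non-gap columns,
a neighbor-joining tree is built, and each query takes the label of its
nearest reference by patristic distance (ties: majority among the three
nearest, then lexicographic label order). Rule-vs-tree disagreements
(a structural III landing next to a II reference, or vice versa) set the
conflict flag and are never silently overridden — printed family tables
contain exactly such rows, and the package surfaces rather than resolves
them.

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
matrix with a deterministic lowest-index tie-break; negative branch
lengths are clamped to zero. Correctness is tested against exhaustive
topology enumeration with least-squares additivity fits, and
cross-checked against scikit-bio's independent implementation.

Bootstrap support for trees resamples alignment columns with replacement
(single seeded generator) and reports, per internal bipartition of the
full-data tree, the fraction of replicate trees containing it. An
alignment with all-zero distances is degenerate; supports are reported as
0 with a warning. The per-query `support` reported by `classify_family`
is cheaper by design: the fraction of column resamples in which the
nearest reference (by raw p-distance, not a re-built tree) carries the
point-estimate label. It measures placement stability, not clade support.

All alignments use BLOSUM62 with affine gaps costing `11 + k` for a gap of
length k (open 11, extend 1), the conventional protein-search defaults;
identity is matches over residue-residue columns of one optimal global
alignment, with the input pair canonically ordered so ties cannot break
symmetry.

## Physicochemical descriptors

The isoelectric point solves `charge(pH) = 0` by bisection on [0, 14] to
|ΔpH| < 1e-3, with charge summed over free termini plus K, R, H (basic)
and D, E, C, Y (acidic) using the Bjellqvist pKa set bundled in
`seq_characterize.PKA`. GRAVY is the mean Kyte–Doolittle hydropathy and
the instability index the standard length-normalized dipeptide-weight sum
(both delegated to Biopython's ProtParam, which uses the same published
tables; `X` residues are excluded). The aliphatic index is
`X(A) + 2.9·X(V) + 3.9·(X(I)+X(L))` in mole percent. Residue classes are
positive {K,R,H}, negative {D,E}, aromatic {F,W,Y} and aliphatic {A,V,I,L}
with glycine optionally included, since the membership of the "aliphatic"
composition statistic is convention-dependent. The stability threshold
(< 40) belongs to the instability index, and the package applies it there.
All descriptors are verified against independent brute-force oracles
(dense grid search for pI, direct sums for the rest); no attempt is made
to reproduce any particular published cohort average, which would require
the original sequences.

## Promoter elements

Elements are IUPAC consensi compiled to regular expressions and scanned on
both strands with overlapping matches allowed; minus-strand hits are
reported in forward coordinates. `N` in a promoter matches nothing. The
bundled ten-element dictionary (W-box, G-box, Sp1, CGTCA-motif, ERF, ABRE,
Skn-1, TC-rich, MBS, HSE) uses compact approximations of the standard
plant cis-element definitions; only the W-box consensus `YTGACY` is
treated as authoritative. Users can load their own TSV dictionary.

## Homology calling

All-vs-all Smith–Waterman (exact, affordable at desk scale) feeds a
similarity graph with weights `score(a,b)/max(self a, self b)` kept at
≥ 0.3. Markov clustering uses unit self-loops, column-stochastic flow,
expansion/inflation (default inflation 1.5) with pruning at 1e-5 and an
idempotence stop at max |Δ| < 1e-6. Pair typing inside each cluster:
same-species = paralog, cross-species reciprocal best hits (all tied
partners qualify) = ortholog, remaining cross-species = coortholog. These
operational definitions are this package's contract; they follow the
caption semantics of published paralog/ortholog/coortholog tables but are
not byte-compatible with any external pipeline.

A known, inherent limit: when a post-speciation duplication makes a
one-to-many family, RBH promotes exactly one of the co-orthologous pairs
to "ortholog". On simulated histories this caps ortholog precision
below 1 in proportion to the duplication rate (measured 0.83–0.97 across
seeds at the default rates; recall stays ~1.0).

## Expression

RPKM is `10^9·C/(N·L)`; the heatmap export is `log2(x+1)`. ΔΔCt averages
replicate ΔCt values per gene × condition before subtracting the
calibrator ΔCt; the calibrator fold is identically 1. Pearson
correlations with zero-variance inputs are "not calculable", mirrored as
network sign `na` with the cause (`zero_variance` vs `missing`) reported
separately. Network signs follow the zero crossing (r > 0 positive,
r < 0 negative) with an optional |r| filter, off by default, because no
significance threshold is part of the method's definition.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of seed and spec. Protein backgrounds are
uniform over the 18 residues other than C and H so that implanted fingers
are provably the only finger-competent motifs and implant coordinates are
exact truth; real proteins of course contain background C/H, so these
tests certify bookkeeping, not discrimination against decoy fingers.
Family evolution runs on a fixed ((A,B),C) species tree with per-branch
loss (default 0.02), at most one duplication per lineage per branch
(default probability 0.03 — duplication fixation is rare on short
timescales), and per-site substitution (default 0.03, no indels; test
conditions use 0.05). Truth typing follows the history: cross-species
pairs are orthologs iff no duplication separates them after their last
common speciation. Promoter backgrounds are uniform ACGT with implanted,
non-overlapping, optionally reverse-complemented elements; because short
consensi match uniform DNA by chance, the generator re-randomizes
background positions until implanted hits are the only dictionary matches,
making precision/recall tests exact. Expression counts are gamma-Poisson
(negative binomial, dispersion 0.1) around lognormal base means, with
module genes sharing a per-sample latent factor through a configurable
loading; Ct tables invert the ΔΔCt model exactly before adding Gaussian
noise.

Problem sizes in the test and acceptance runs (300 proteins for group
recovery, 100 queries for subgroup recovery, 25 families / ~80 genes for
homology, 20 matrices at 4–8 taxa for tree recovery, 1000 random
instances per oracle comparison) are chosen so the full suite completes
in well under a minute while keeping binomial noise on the measured rates
small relative to the thresholds tested.

## Degenerate inputs and tie-breaks

Empty FASTA → empty results, exit 0. Fewer than 3 taxa → error. A
sequence pair with no mutually non-gap columns → error naming the pair.
Zero-variance expression vectors → `na`, never NaN propagation. NJ ties →
lowest index pair; RBH ties → all tied partners; subgroup ties → 3-nearest
majority, then lexicographic. MCL on an empty graph → empty clustering;
singletons are legitimate clusters. Fixture loaders verify SHA-256
checksums and refuse to parse corrupted tables. The packaged family table
preserves printed inconsistencies verbatim (rows whose finger pattern
contradicts their group label, and best-hit name/locus pairs that disagree
with each other); loaders and summaries never "correct" them.
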