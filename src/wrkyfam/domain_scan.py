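"""Detection of WRKY domains: heptapeptide anchors plus downstream zinc fingers.

A WRKY domain is modelled as a conserved seven-residue anchor (WRKYGQK or a
known variant) followed, within a bounded linker, by a zinc-finger motif whose
four metal-coordinating residues are two cysteines and then either two
histidines (C2H2) or a histidine and a cysteine (C2HC).  Spacer-run lengths
between coordinating residues are constrained by a :class:`PatternSpace`;
the compact rendering of those lengths (e.g. ``C-X7-C-X23-H-X1-C``) is the
domain's spacing signature.

Pattern scanning here replaces profile-HMM search: the anchor plus finger
definition is explicit, deterministic, and directly testable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormatError

#: Heptapeptide anchor variants recognised by default.  Both the
#: WRKY-initial and the WKKY-initial spellings of the DHK/DQK variants are
#: included because published family tables use both interchangeably.
DEFAULT_VARIANTS = frozenset({
    "WRKYGQK", "WRKYGKK", "WRKYDQK", "WRKYDHK", "WKKYDHK", "WKKYDQK",
})

#: Heptapeptide-to-finger gap bound: the whole domain spans roughly 60
#: residues, so the finger's first cysteine must start within this many
#: residues after the anchor.
DEFAULT_MAX_GAP = 60


@dataclass(frozen=True)
class HeptapeptideHit:
    """An occurrence of a heptapeptide anchor (1-based start)."""

    start: int
    variant: str

    @property
    def end(self) -> int:
        return self.start + 6


@dataclass(frozen=True)
class ZincFingerHit:
    """Four coordinating residues of a zinc finger (1-based positions)."""

    positions: tuple[int, int, int, int]
    finger_type: str  # "C2H2" or "C2HC"

    def __post_init__(self):
        p = self.positions
        if not (p[0] < p[1] < p[2] < p[3]):
            raise FormatError("zinc-finger positions must be strictly increasing")
        if self.finger_type not in {"C2H2", "C2HC"}:
            raise FormatError(f"unknown finger type {self.finger_type!r}")

    @property
    def spacings(self) -> tuple[int, int, int]:
        p = self.positions
        return (p[1] - p[0] - 1, p[2] - p[1] - 1, p[3] - p[2] - 1)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[3]


@dataclass(frozen=True)
class WRKYDomain:
    """A complete WRKY domain: anchor plus downstream zinc finger."""

    heptapeptide: HeptapeptideHit
    finger: ZincFingerHit
    terminus_tag: str = "only"  # "N", "C" or "only"

    @property
    def start(self) -> int:
        return self.heptapeptide.start

    @property
    def end(self) -> int:
        return self.finger.end


@dataclass(frozen=True)
class PatternSpace:
    """Allowed spacer-run lengths per finger type, plus the anchor-finger gap.

    Defaults accept the spacings observed across published family tables
    (C2H2 second run up to 24); ``strict()`` narrows to the textbook motif
    definitions.
    """

    c2h2_n1: tuple[int, int] = (4, 5)
    c2h2_n2: tuple[int, int] = (22, 24)
    c2h2_n3: tuple[int, int] = (1, 1)
    c2hc_n1: tuple[int, int] = (7, 7)
    c2hc_n2: tuple[int, int] = (22, 23)
    c2hc_n3: tuple[int, int] = (1, 1)
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self):
        for lo, hi in (self.c2h2_n1, self.c2h2_n2, self.c2h2_n3,
                       self.c2hc_n1, self.c2hc_n2, self.c2hc_n3):
            if lo > hi:
                raise FormatError("empty spacing range in PatternSpace")
        if self.max_gap <= 0:
            raise FormatError("max_gap must be positive")

    @classmethod
    def strict(cls) -> "PatternSpace":
        return cls(c2h2_n2=(22, 23), c2hc_n2=(23, 23))

    def ranges(self, finger_type: str):
        if finger_type == "C2H2":
            return self.c2h2_n1, self.c2h2_n2, self.c2h2_n3
        return self.c2hc_n1, self.c2hc_n2, self.c2hc_n3

    def allows(self, finger_type: str, spacings: tuple[int, int, int]) -> bool:
        return all(lo <= n <= hi
                   for (lo, hi), n in zip(self.ranges(finger_type), spacings))


def find_heptapeptides(sequence: str, variant_set=DEFAULT_VARIANTS
                       ) -> list[HeptapeptideHit]:
    """All occurrences of any anchor variant, sorted by position.

    Overlapping occurrences are all reported.  The ambiguous residue ``X``
    never matches an anchor position.
    """
    hits = []
    n = len(sequence)
    for i in range(n - 6):
        window = sequence[i:i + 7]
        if window in variant_set:
            hits.append(HeptapeptideHit(start=i + 1, variant=window))
    return hits


def _finger_at(sequence: str, c1_idx: int, finger_type: str,
               space: PatternSpace) -> ZincFingerHit | None:
    """Best (smallest-spacing) finger of the given type anchored at c1 (0-based)."""
    n = len(sequence)
    last = "H" if finger_type == "C2H2" else "C"
    r1, r2, r3 = space.ranges(finger_type)
    for n1 in range(r1[0], r1[1] + 1):
        c2 = c1_idx + 1 + n1
        if c2 >= n or sequence[c2] != "C":
            continue
        for n2 in range(r2[0], r2[1] + 1):
            h1 = c2 + 1 + n2
            if h1 >= n or sequence[h1] != "H":
                continue
            for n3 in range(r3[0], r3[1] + 1):
                h2 = h1 + 1 + n3
                if h2 >= n or sequence[h2] != last:
                    continue
                return ZincFingerHit(
                    positions=(c1_idx + 1, c2 + 1, h1 + 1, h2 + 1),
                    finger_type=finger_type)
    return None


def find_zinc_finger(sequence: str, search_from: int,
                     pattern_space: PatternSpace | None = None
                     ) -> ZincFingerHit | None:
    """Left-most zinc finger starting at/after ``search_from`` (1-based).

    The first cysteine must lie within ``max_gap`` residues of
    ``search_from``.  At equal start position C2H2 is preferred over C2HC.
    """
    space = pattern_space or PatternSpace()
    if search_from < 1:
        search_from = 1
    limit = min(len(sequence), search_from - 1 + space.max_gap)
    for i in range(search_from - 1, limit):
        if sequence[i] != "C":
            continue
        for finger_type in ("C2H2", "C2HC"):
            hit = _finger_at(sequence, i, finger_type, space)
            if hit is not None:
                return hit
    return None


def assemble_domains(sequence: str, variant_set=DEFAULT_VARIANTS,
                     pattern_space: PatternSpace | None = None
                     ) -> list[WRKYDomain]:
    """Pair each anchor with its nearest downstream finger (greedy, left to
    right); anchors without a reachable finger are dropped and each finger is
    consumed by at most one anchor.
    """
    space = pattern_space or PatternSpace()
    domains: list[WRKYDomain] = []
    next_free = 1
    for hepta in find_heptapeptides(sequence, variant_set):
        search_from = max(hepta.end + 1, next_free)
        hit = find_zinc_finger(sequence, search_from, space)
        if hit is None:
            continue
        if hit.start - hepta.end - 1 > space.max_gap:
            continue
        domains.append(WRKYDomain(heptapeptide=hepta, finger=hit))
        next_free = hit.end + 1
    if len(domains) == 1:
        return domains
    tagged = []
    for i, d in enumerate(domains):
        tag = "C" if i == len(domains) - 1 else "N"
        tagged.append(WRKYDomain(heptapeptide=d.heptapeptide, finger=d.finger,
                                 terminus_tag=tag))
    return tagged


def spacing_signature(domain: WRKYDomain) -> str:
    """Canonical spacing signature, e.g. ``C-X7-C-X23-H-X1-C``."""
    n1, n2, n3 = domain.finger.spacings
    last = "H" if domain.finger.finger_type == "C2H2" else "C"
    return f"C-X{n1}-C-X{n2}-H-X{n3}-{last}"


_SIG_RE = re.compile(r"^CX(\d+)CX(\d+)H(?:X(\d+)|([A-WYZ0-9]))([HC])$")


def _parse_one(fragment: str) -> tuple[str, tuple[int, int, int]]:
    normalized = re.sub(r"[-_\s]", "", fragment)
    m = _SIG_RE.match(normalized)
    if m is None:
        # "HXH" tail: the X is a single spacer character, not a run length
        m = re.match(r"^CX(\d+)CX(\d+)H([A-Z])([HC])$", normalized)
        if m is None:
            raise FormatError(f"unparseable spacing signature: {fragment!r}")
        n1, n2 = int(m.group(1)), int(m.group(2))
        n3 = 1
        last = m.group(4)
    else:
        n1, n2 = int(m.group(1)), int(m.group(2))
        n3 = int(m.group(3)) if m.group(3) is not None else 1
        last = m.group(5)
    finger_type = "C2H2" if last == "H" else "C2HC"
    return finger_type, (n1, n2, n3)


def parse_signature(text: str) -> list[tuple[str, tuple[int, int, int]]]:
    """Parse a spacing signature in canonical or table dialect.

    The table dialect writes the final spacer as a literal character
    (``HXH`` == ``H-X1-H``; a concrete residue such as the T of ``HTC``
    counts as one spacer position) and may join two per-terminus patterns
    with ``/`` plus ``(N)``/``(C)`` tags; such dual patterns yield two parses.
    """
    parts = [p for p in re.split(r"/", text) if p.strip()]
    parses = []
    for part in parts:
        fragment = re.sub(r"\((N|C)\)", "", part).strip()
        parses.append(_parse_one(fragment))
    if not parses:
        raise FormatError(f"unparseable spacing signature: {text!r}")
    return parses
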