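"""Core plastome records: annotated genomes, gene features, and region classification.

A chloroplast genome is modelled as a circular DNA sequence plus a flat list
of typed gene features (CDS, tRNA, rRNA).  Coordinates are 0-based, half-open
throughout; GenBank's 1-based inclusive convention is converted at the I/O
boundary.  Features that cross the origin of the linearized circle are stored
with their parts split at the origin and flagged ``wraps_origin``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")

#: Region-class labels used when classifying an interval against the annotation.
#: "CDS" means fully inside the exonic parts of an annotated gene (of any kind),
#: "intron" fully inside an intron, "IGS" fully intergenic, and "CDS-IGS" an
#: interval that straddles an exon boundary.
REGION_CLASSES = ("CDS", "intron", "IGS", "CDS-IGS")

_SUFFIX_RE = re.compile(r"[._-]\d+$")


def canonical_symbol(name: str) -> str:
    """Canonical gene identity for cross-genome matching.

    Lower-cased symbol with trailing transcript/copy suffixes (``_1``, ``.2``)
    stripped.  tRNA anticodon suffixes (e.g. ``trnH-GUG``) are kept: they
    distinguish genuinely different genes.
    """
    sym = name.strip()
    if not sym.lower().startswith("trn"):
        sym = _SUFFIX_RE.sub("", sym)
    return sym.lower()


@dataclass
class GeneFeature:
    """A gene with one or more exonic parts on a plastome.

    ``parts`` is an ordered list of 0-based half-open intervals; a feature with
    k parts has k-1 introns.  For a feature flagged ``wraps_origin`` the parts
    are stored split at the origin (last part ends at genome length, first
    begins at 0 conceptually continuing it).
    """

    name: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    pseudo: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name} has no parts")
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"feature {self.name} has empty part ({s}, {e})")

    @property
    def intron_count(self) -> int:
        return len(self.parts) - 1

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def symbol(self) -> str:
        return canonical_symbol(self.name)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive parts, in coordinate order."""
        ordered = sorted(self.parts)
        return [(ordered[i][1], ordered[i + 1][0]) for i in range(len(ordered) - 1)]


@dataclass
class AnnotatedPlastome:
    """A circular annotated chloroplast genome: the universal input record."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"plastome {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"plastome {self.id}: ambiguity codes other than N are not "
                f"supported (found {sorted(bad)})"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.end > n or f.start < 0:
                raise ValueError(
                    f"plastome {self.id}: feature {f.name} at [{f.start}, {f.end}) "
                    f"lies outside the sequence of length {n}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Exonic sequence of a feature, strand-corrected (5'->3')."""
        chunks = [self.sequence[s:e] for s, e in sorted(feat.parts)]
        seq = "".join(chunks)
        if feat.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T), with N excluded from both numerator and denominator.

    Raises ``ValueError`` on an empty or all-N sequence, where the content is
    undefined.
    """
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise ValueError("gc_content undefined: sequence contains no A/C/G/T")
    return gc / (gc + at)


def classify_interval(
    plastome: AnnotatedPlastome, interval: tuple[int, int]
) -> str:
    """Classify a half-open interval against the annotation.

    Returns one of ``REGION_CLASSES``.  The interval may wrap the circular
    origin (start > end means it runs through the origin).
    """
    start, end = interval
    n = plastome.length
    if start == end:
        raise ValueError("cannot classify a zero-length interval")
    if start < end:
        positions = [(start, end)]
    else:  # wraps origin
        positions = [(start, n), (0, end)]

    overlaps_exon = fully_exonic = False
    overlaps_intron = fully_intronic = False
    for seg in positions:
        for f in plastome.features:
            for p in sorted(f.parts):
                if _overlap(seg, p):
                    overlaps_exon = True
                    if _contained(seg, p):
                        fully_exonic = True
            for iv in f.introns():
                if _overlap(seg, iv):
                    overlaps_intron = True
                    if _contained(seg, iv):
                        fully_intronic = True

    if overlaps_exon:
        if fully_exonic and len(positions) == 1:
            return "CDS"
        return "CDS-IGS"
    if overlaps_intron:
        if fully_intronic and len(positions) == 1:
            return "intron"
        return "CDS-IGS"
    return "IGS"


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contained(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return b[0] <= a[0] and a[1] <= b[1]


def summarize_features(plastome: AnnotatedPlastome, partition=None) -> dict:
    """Feature-count summary in the style of a genome-features table.

    Each gene symbol is counted once; genes present as two copies inside the
    inverted repeats are additionally tallied as IR-duplicated.  When a
    quadripartite ``partition`` is supplied the IR-duplicated tally only counts
    symbols with copies in both IR regions; without one, symbols occurring
    more than once are tallied as duplicated.
    """
    by_kind: dict[str, dict[str, int]] = {k: {} for k in FEATURE_KINDS}
    for f in plastome.features:
        if f.pseudo:
            continue
        by_kind[f.kind][f.symbol] = by_kind[f.kind].get(f.symbol, 0) + 1

    def in_ir(feat: GeneFeature) -> bool:
        if partition is None:
            return False
        mid = (feat.start + feat.end) // 2
        return _point_in(mid, partition.irb) or _point_in(mid, partition.ira)

    summary = {}
    total_unique = total_dup = 0
    for kind in FEATURE_KINDS:
        unique = len(by_kind[kind])
        dup = 0
        for sym, count in by_kind[kind].items():
            if count < 2:
                continue
            if partition is None:
                dup += 1
            else:
                copies = [
                    f for f in plastome.features
                    if f.kind == kind and f.symbol == sym and in_ir(f)
                ]
                if len(copies) >= 2:
                    dup += 1
        summary[kind] = {"unique": unique, "ir_duplicated": dup}
        total_unique += unique
        total_dup += dup
    summary["genes"] = {"unique": total_unique, "ir_duplicated": total_dup}
    return summary


def _point_in(pos: int, interval: tuple[int, int]) -> bool:
    return interval[0] <= pos < interval[1]


def region_label(partition, interval: tuple[int, int]) -> str:
    """Assign an interval to LSC/SSC/IR by its midpoint."""
    mid = (interval[0] + interval[1]) // 2
    if _point_in(mid, partition.lsc):
        return "LSC"
    if _point_in(mid, partition.ssc):
        return "SSC"
    return "IR"
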