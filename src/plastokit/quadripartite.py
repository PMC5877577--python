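"""Quadripartite structure: inverted-repeat detection, LSC/IRb/SSC/IRa
partitioning, and IR/SC junction reports.

The canonical plastome layout is LSC - IRb - SSC - IRa on the circle.  IR
detection is seed-and-extend: exact 25-mer matches between the sequence and
its reverse complement seed candidate diagonals, which are extended with an
X-drop scheme and trimmed back to the highest-scoring endpoints, so exact
planted repeats are recovered at exact coordinates.  The longest qualifying
pair wins; ties break towards the smaller start coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import AnnotatedPlastome, GeneFeature, reverse_complement

logger = logging.getLogger(__name__)

SEED_K = 25
BOUNDARIES = ("J(LSC/IRb)", "J(IRb/SSC)", "J(SSC/IRa)", "J(IRa/LSC)")


class NoInvertedRepeatError(ValueError):
    """Raised when no qualifying inverted-repeat pair exists."""


class DegeneratePartitionError(ValueError):
    """Raised when an IR pair leaves a zero-length single-copy arc."""


@dataclass
class IRPair:
    """The two occurrences of the inverted repeat, as linear intervals.

    ``first``/``second`` are ordered by start coordinate on the given
    linearization; which is IRa and which IRb is only decided during
    partitioning (it depends on which single-copy arc is larger).
    """

    first: tuple[int, int]
    second: tuple[int, int]
    identity: float

    @property
    def length(self) -> int:
        return self.first[1] - self.first[0]


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical rotation (LSC starts at 0).

    ``offset`` is the position in the *input* linearization that became
    coordinate 0 of the canonical rotation.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    offset: int = 0

    def lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc[1] - self.lsc[0],
            "IRb": self.irb[1] - self.irb[0],
            "SSC": self.ssc[1] - self.ssc[0],
            "IRa": self.ira[1] - self.ira[0],
        }

    @property
    def genome_length(self) -> int:
        return self.ira[1]


def detect_inverted_repeats(
    sequence: str, min_len: int = 10_000, max_mismatch_frac: float = 0.01
) -> IRPair:
    """Find the longest pair (s, reverse-complement(s)) of disjoint occurrences
    on the circle.

    The linear scan is run at three phase offsets (0, n/3, 2n/3): an IR copy
    shorter than a third of the genome can cover at most one of these cut
    points, so at least one linearization leaves both copies intact and the
    result is rotation-invariant.  Returned intervals are in input
    coordinates; an interval crossing the origin has end > n.

    Raises :class:`NoInvertedRepeatError` when nothing of at least ``min_len``
    with identity >= 1 - ``max_mismatch_frac`` exists; callers may treat such
    genomes as IR-lacking.
    """
    n = len(sequence)
    if n <= 2 * min_len:
        raise NoInvertedRepeatError(
            f"sequence of {n} bp cannot hold two copies of a {min_len} bp repeat"
        )
    best = None
    for off in (0, n // 3, (2 * n) // 3):
        rotated = sequence[off:] + sequence[:off]
        found = _detect_linear(rotated, min_len, max_mismatch_frac)
        if found is None:
            continue
        (a1, a2), (b1, b2), identity = found
        first = ((a1 + off) % n, (a1 + off) % n + (a2 - a1))
        second = ((b1 + off) % n, (b1 + off) % n + (b2 - b1))
        first, second = sorted([first, second])
        length = a2 - a1
        cand = (-length, first, second, identity)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise NoInvertedRepeatError("no IR found")
    _, first, second, identity = best
    if second[0] < first[1] and second[1] > first[0]:
        raise NoInvertedRepeatError("only a self-overlapping palindrome found")
    return IRPair(first=first, second=second, identity=identity)


def _detect_linear(sequence: str, min_len: int, max_mismatch_frac: float):
    """Best disjoint (s, revcomp(s)) pair on this linearization, or None."""
    n = len(sequence)
    rc = reverse_complement(sequence)

    # Seed: exact SEED_K-mer matches between sequence and its reverse
    # complement.  Sample query positions with a stride; an IR of min_len
    # guarantees many seeds regardless of phase.
    index: dict[str, list[int]] = {}
    stride = max(1, SEED_K // 2)
    for i in range(0, n - SEED_K + 1, stride):
        index.setdefault(sequence[i : i + SEED_K], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for j in range(0, n - SEED_K + 1):
        hits = index.get(rc[j : j + SEED_K])
        if hits:
            for i in hits:
                diagonals.setdefault(j - i, []).append(i)

    best: tuple[int, int, int, int] | None = None  # (-len, start, end, mism)
    for d, seed_starts in sorted(diagonals.items()):
        # both IR copies sit on the same diagonal of the seq-vs-revcomp
        # comparison, so cluster seeds by gap and extend each cluster
        for lo_seed, hi_seed in _cluster(sorted(seed_starts), gap=500):
            start, end, mism = _xdrop_extend(sequence, rc, d, lo_seed, hi_seed + SEED_K)
            length = end - start
            if length < min_len:
                continue
            if mism > max_mismatch_frac * length:
                continue
            cand = (-length, start, end, mism)
            if best is None or cand < best:
                best = cand

    if best is None:
        return None
    _, start, end, mism = best
    length = end - start
    d = _best_diag(diagonals, sequence, rc, start, end)
    # run [start, end) in sequence matches rc[start+d, end+d), i.e. the
    # reverse complement of sequence[n-end-d : n-start-d).
    other = (n - end - d, n - start - d)
    a, b = sorted([(start, end), other])
    if a[1] > b[0]:
        return None  # self-overlapping palindrome, not two copies
    return a, b, 1 - mism / length


def _cluster(sorted_positions: list[int], gap: int) -> list[tuple[int, int]]:
    """Group sorted positions into (first, last) clusters split at gaps."""
    clusters = []
    first = last = sorted_positions[0]
    for p in sorted_positions[1:]:
        if p - last > gap:
            clusters.append((first, last))
            first = p
        last = p
    clusters.append((first, last))
    return clusters


def _xdrop_extend(
    seq: str, rc: str, d: int, lo: int, hi: int, xdrop: int = 50
) -> tuple[int, int, int]:
    """Extend a seeded run on diagonal d of seq vs rc in both directions.

    Scoring +1 per match, -3 per mismatch; extension stops once the running
    score falls ``xdrop`` below its maximum, and the run is trimmed back to
    the maximum-scoring endpoints.  Returns (start, end, mismatches) in seq
    coordinates.
    """
    n = len(seq)
    # right extension
    end = hi
    score = best_score = 0
    best_end = hi
    i = hi
    while i < n and i + d < n:
        score += 1 if seq[i] == rc[i + d] and seq[i] != "N" else -3
        i += 1
        if score > best_score:
            best_score, best_end = score, i
        elif best_score - score > xdrop:
            break
    end = best_end
    # left extension
    score = best_score = 0
    best_start = lo
    i = lo - 1
    while i >= 0 and i + d >= 0:
        score += 1 if seq[i] == rc[i + d] and seq[i] != "N" else -3
        if score > best_score:
            best_score, best_start = score, i
        elif best_score - score > xdrop:
            break
        i -= 1
    start = best_start
    mism = sum(1 for k in range(start, end) if seq[k] != rc[k + d] or seq[k] == "N")
    return start, end, mism


def _best_diag(diagonals, seq, rc, start, end) -> int:
    for d, seeds in sorted(diagonals.items()):
        if any(start <= s < end for s in seeds):
            for lo, hi in _cluster(sorted(seeds), gap=500):
                s2, e2, _ = _xdrop_extend(seq, rc, d, lo, hi + SEED_K)
                if s2 <= start and end <= e2:
                    return d
    raise NoInvertedRepeatError("internal: lost the winning diagonal")


def partition(sequence: str, ir: IRPair) -> QuadripartitePartition:
    """Assign the two single-copy arcs to LSC (longer) and SSC (shorter).

    The canonical rotation places the LSC start at coordinate 0, followed by
    IRb, SSC, IRa; region lengths always sum to the genome length.
    """
    n = len(sequence)
    (a1, a2), (b1, b2) = ir.first, ir.second
    arc_x = (b1 - a2) % n      # arc from end of first copy to start of second
    arc_y = (a1 - b2) % n      # arc from end of second copy back to first
    if arc_x == 0 or arc_y == 0:
        raise DegeneratePartitionError(
            "IR copies are adjacent: a single-copy arc has zero length"
        )
    len_first = a2 - a1
    len_second = b2 - b1
    if arc_x >= arc_y:
        # LSC is the arc after the first copy: rotate so it starts at a2.
        offset = a2 % n
        lsc = (0, arc_x)
        irb = (arc_x, arc_x + len_second)
        ssc = (irb[1], irb[1] + arc_y)
        ira = (ssc[1], ssc[1] + len_first)
    else:
        # LSC is the arc after the second copy: rotate so it starts at b2.
        offset = b2 % n
        lsc = (0, arc_y)
        irb = (arc_y, arc_y + len_first)
        ssc = (irb[1], irb[1] + arc_x)
        ira = (ssc[1], ssc[1] + len_second)
    if ira[1] != n:
        raise DegeneratePartitionError(
            f"IR pair does not tile the circle: regions sum to {ira[1]}, not {n}"
        )
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, offset=offset)


def rotate_plastome(plastome: AnnotatedPlastome, offset: int) -> AnnotatedPlastome:
    """Rotate the circular genome so input coordinate ``offset`` becomes 0.

    Features crossing the new origin are split into two parts and flagged.
    """
    n = plastome.length
    offset %= n
    seq = plastome.sequence[offset:] + plastome.sequence[:offset]
    feats = []
    for f in plastome.features:
        parts = []
        wraps = False
        for s, e in f.parts:
            s2, e2 = (s - offset) % n, (e - offset) % n
            if e2 == 0:
                e2 = n
            if s2 < e2:
                parts.append((s2, e2))
            else:  # part now crosses the origin: split
                parts.extend([(s2, n), (0, e2)])
                wraps = True
        feats.append(
            GeneFeature(
                name=f.name,
                kind=f.kind,
                strand=f.strand,
                parts=sorted(parts),
                pseudo=f.pseudo,
                wraps_origin=wraps or f.wraps_origin,
            )
        )
    return AnnotatedPlastome(
        id=plastome.id, sequence=seq, circular=plastome.circular, features=feats
    )


def canonicalize(
    plastome: AnnotatedPlastome,
    min_len: int = 10_000,
    max_mismatch_frac: float = 0.01,
) -> tuple[AnnotatedPlastome, QuadripartitePartition]:
    """Detect the IR, partition, and return the canonically rotated genome."""
    ir = detect_inverted_repeats(plastome.sequence, min_len, max_mismatch_frac)
    part = partition(plastome.sequence, ir)
    rotated = rotate_plastome(plastome, part.offset)
    part.offset = 0
    return rotated, part


@dataclass
class JunctionGene:
    gene: str
    relation: str            # spans | inside-left | inside-right
    bp: int                  # distance to boundary, or overlap into far side
    detail: dict = field(default_factory=dict)


@dataclass
class JunctionReport:
    genome: str
    entries: dict[str, list[JunctionGene]] = field(default_factory=dict)

    def signature(self) -> tuple:
        """(boundary -> gene, relation) fingerprint used for classification."""
        sig = []
        for b in BOUNDARIES:
            genes = self.entries.get(b, [])
            spanning = [g for g in genes if g.relation == "spans"]
            pick = spanning[0] if spanning else (genes[0] if genes else None)
            sig.append((b, pick.gene if pick else None, pick.relation if pick else None))
        return tuple(sig)


def junction_report(
    plastome: AnnotatedPlastome,
    part: QuadripartitePartition,
    window: int = 2000,
) -> JunctionReport:
    """Genes spanning or flanking each of the four IR/SC boundaries.

    For each boundary the report lists any gene spanning it (with the overlap
    it carries into each side) and otherwise the nearest gene within
    ``window`` bp on each side.  Coordinates must be on the canonical
    rotation (``part.offset == 0``).
    """
    n = part.genome_length
    boundary_pos = {
        "J(LSC/IRb)": part.irb[0],
        "J(IRb/SSC)": part.ssc[0],
        "J(SSC/IRa)": part.ira[0],
        "J(IRa/LSC)": n,  # == 0 on the circle
    }
    report = JunctionReport(genome=plastome.id)
    for bname, bpos in boundary_pos.items():
        entries: list[JunctionGene] = []
        for f in plastome.features:
            s, e = _circular_span(f, n)
            # View the span against the boundary at bpos and bpos +/- n so
            # genes and boundaries near the origin see each other; each
            # feature contributes at most one entry per boundary.
            found = None
            for shift in (0, n, -n):
                s2, e2 = s + shift, e + shift
                if s2 < bpos < e2:
                    found = JunctionGene(
                        gene=f.name,
                        relation="spans",
                        bp=min(bpos - s2, e2 - bpos),
                        detail={"left_bp": bpos - s2, "right_bp": e2 - bpos},
                    )
                    break
                if bpos - window <= e2 <= bpos:
                    found = JunctionGene(
                        gene=f.name, relation="inside-left", bp=bpos - e2
                    )
                    break
                if bpos <= s2 <= bpos + window:
                    found = JunctionGene(
                        gene=f.name, relation="inside-right", bp=s2 - bpos
                    )
                    break
            if found is not None:
                entries.append(found)
        spans = [g for g in entries if g.relation == "spans"]
        flank = sorted(
            (g for g in entries if g.relation != "spans"), key=lambda g: g.bp
        )
        nearest = []
        for side in ("inside-left", "inside-right"):
            side_genes = [g for g in flank if g.relation == side]
            if side_genes:
                nearest.append(side_genes[0])
        report.entries[bname] = spans + nearest
    return report


def _circular_span(f: GeneFeature, n: int) -> tuple[int, int]:
    """Feature span as (start, end) with end > n when the feature wraps."""
    if not f.wraps_origin:
        return f.start, f.end
    head = [p for p in f.parts if p[0] == 0]
    tail = [p for p in f.parts if p[1] == n]
    if not head or not tail:
        return f.start, f.end
    return tail[0][0], head[-1][1] + n


def compare_junctions(reports: list[JunctionReport]) -> dict[tuple, list[str]]:
    """Group genomes by their junction signature (boundary -> gene, relation)."""
    if len(reports) < 2:
        raise ValueError("junction comparison needs at least two genomes")
    classes: dict[tuple, list[str]] = {}
    for r in reports:
        classes.setdefault(r.signature(), []).append(r.genome)
    return classes


def junction_table(reports: list[JunctionReport]) -> list[dict]:
    rows = []
    for r in reports:
        for boundary in BOUNDARIES:
            for g in r.entries.get(boundary, []):
                rows.append(
                    {
                        "genome": r.genome,
                        "boundary": boundary,
                        "gene": g.gene,
                        "relation": g.relation,
                        "bp": g.bp,
                    }
                )
    return rows
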