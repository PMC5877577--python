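"""Per-locus sequence variability and mutational-hotspot classification.

The variability percentage of an aligned homologous locus is

    percent = (substitutions + indel events)
              / (aligned length - indel length + indel events) * 100

where *substitutions* counts gap-free columns holding at least two distinct
bases, an *indel event* is a maximal run of columns containing at least one
gap, and *indel length* is the total number of such columns.  A locus is a
mutational hotspot when its percentage exceeds 80 (non-coding loci: introns
and intergenic spacers) or 50 (coding loci); both cuts are strict.

Alignment is a deterministic center-star multiple alignment built from
Biopython pairwise global alignments (match +1, mismatch -1, gap open -4,
gap extend -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .records import AnnotatedPlastome

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class LocusAlignment:
    locus: str
    locus_class: str  # "coding" | "non-coding"
    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"locus {self.locus}: an alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.locus}: unequal row lengths {lengths}")
        ncols = len(self.rows[0])
        for j in range(ncols):
            if all(r[j] == GAP for r in self.rows):
                raise ValueError(f"locus {self.locus}: all-gap column {j}")

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class VariabilityRecord:
    locus: str
    locus_class: str
    substitutions: int
    indel_events: int
    indel_length: int
    aligned_length: int
    percent: float
    hotspot: bool = False


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Global affine-gap aligner; a gap of length g costs gap_open + g*gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_locus(
    seqs: list[str],
    names: list[str] | None = None,
    locus: str = "locus",
    locus_class: str = "non-coding",
    aligner: Align.PairwiseAligner | None = None,
) -> LocusAlignment:
    """Deterministic multiple alignment of 2-60 homologous sequences.

    Center-star strategy: the center is the sequence with the highest total
    pairwise alignment score against the others; every other sequence is
    aligned to the center and the pairwise gaps are merged ("once a gap,
    always a gap").  Sequences are merged in decreasing order of similarity
    to the center, ties broken by input order, so the result is deterministic
    for a fixed input order.
    """
    if any(not s for s in seqs):
        raise ValueError("empty sequence in alignment input")
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    names = names or [f"seq{i}" for i in range(len(seqs))]
    aligner = aligner or make_aligner()

    if len(seqs) == 2:
        a, b = _pairwise(aligner, seqs[0], seqs[1])
        return LocusAlignment(locus, locus_class, list(names), [a, b])

    scores = [[0.0] * len(seqs) for _ in seqs]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            s = aligner.score(seqs[i], seqs[j])
            scores[i][j] = scores[j][i] = s
    totals = [sum(row) for row in scores]
    center = max(range(len(seqs)), key=lambda i: (totals[i], -i))

    order = sorted(
        (i for i in range(len(seqs)) if i != center),
        key=lambda i: (-scores[center][i], i),
    )
    # master holds the center row with accumulated gaps; others maps index ->
    # aligned row in master coordinates
    master = seqs[center]
    aligned: dict[int, str] = {center: master}
    for idx in order:
        a_center, a_new = _pairwise(aligner, _degap(master), seqs[idx])
        # merge the new center gapping into the master coordinates
        merged_master, merged_new, remap_old = _merge(master, a_center, a_new)
        for k in list(aligned):
            aligned[k] = _apply_remap(aligned[k], remap_old, len(merged_master))
        aligned[idx] = merged_new
        master = merged_master
    rows = [aligned[i] for i in range(len(seqs))]
    return LocusAlignment(locus, locus_class, list(names), rows)


def _pairwise(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return _format_alignment(aln, a, b)


def _format_alignment(aln, a: str, b: str) -> tuple[str, str]:
    ra, rb = [], []
    pa = pb = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        if s1 > pa:
            ra.append(a[pa:s1])
            rb.append(GAP * (s1 - pa))
        if s2 > pb:
            ra.append(GAP * (s2 - pb))
            rb.append(b[pb:s2])
        ra.append(a[s1:e1])
        rb.append(b[s2:e2])
        pa, pb = e1, e2
    if pa < len(a):
        ra.append(a[pa:])
        rb.append(GAP * (len(a) - pa))
    if pb < len(b):
        ra.append(GAP * (len(b) - pb))
        rb.append(b[pb:])
    return "".join(ra), "".join(rb)


def _degap(row: str) -> str:
    return row.replace(GAP, "")


def _merge(master: str, a_center: str, a_new: str):
    """Merge a fresh center/new pairwise alignment into master coordinates.

    ``master`` is the center with previously accumulated gaps; ``a_center``
    is the same (ungapped) center re-aligned against the new sequence.
    Returns the merged master row, the new row in merged coordinates, and a
    remap (list of old master column -> merged column) for existing rows.
    """
    mi = ci = 0
    merged_master = []
    merged_new = []
    remap: list[int] = []  # for each merged column, old master column or -1
    while mi < len(master) or ci < len(a_center):
        m_gap = mi < len(master) and master[mi] == GAP
        c_gap = ci < len(a_center) and a_center[ci] == GAP
        if mi < len(master) and m_gap:
            # a gap already present in master: keep, new row gets a gap
            merged_master.append(GAP)
            merged_new.append(GAP)
            remap.append(mi)
            mi += 1
        elif ci < len(a_center) and c_gap:
            # new alignment inserts a gap into the center
            merged_master.append(GAP)
            merged_new.append(a_new[ci])
            remap.append(-1)
            ci += 1
        else:
            merged_master.append(master[mi])
            merged_new.append(a_new[ci])
            remap.append(mi)
            mi += 1
            ci += 1
    return "".join(merged_master), "".join(merged_new), remap


def _apply_remap(row: str, remap: list[int], ncols: int) -> str:
    out = []
    for old in remap:
        out.append(GAP if old == -1 else row[old])
    return "".join(out)


def variability(alignment: LocusAlignment) -> VariabilityRecord:
    """Variability percentage of an aligned locus.

    Columns containing any gap are charged to indel runs only; in gap-free
    columns N matches everything and never counts as a substitution.
    """
    rows = alignment.rows
    ncols = alignment.length
    substitutions = 0
    indel_cols = 0
    indel_events = 0
    in_gap_run = False
    for j in range(ncols):
        col = [r[j] for r in rows]
        if GAP in col:
            indel_cols += 1
            if not in_gap_run:
                indel_events += 1
                in_gap_run = True
            continue
        in_gap_run = False
        bases = {c for c in col if c != "N"}
        if len(bases) >= 2:
            substitutions += 1
    denom = ncols - indel_cols + indel_events
    percent = 100.0 * (substitutions + indel_events) / denom if denom else 0.0
    return VariabilityRecord(
        locus=alignment.locus,
        locus_class=alignment.locus_class,
        substitutions=substitutions,
        indel_events=indel_events,
        indel_length=indel_cols,
        aligned_length=ncols,
        percent=percent,
    )


def classify_hotspots(
    records: list[VariabilityRecord],
    coding_cut: float = 50.0,
    noncoding_cut: float = 80.0,
) -> list[VariabilityRecord]:
    """Flag hotspots: percent strictly above the cut for the locus class."""
    out = []
    for r in records:
        cut = coding_cut if r.locus_class == "coding" else noncoding_cut
        out.append(
            VariabilityRecord(
                locus=r.locus,
                locus_class=r.locus_class,
                substitutions=r.substitutions,
                indel_events=r.indel_events,
                indel_length=r.indel_length,
                aligned_length=r.aligned_length,
                percent=r.percent,
                hotspot=r.percent > cut,
            )
        )
    return out


@dataclass
class LocusSet:
    """Named homologous locus sequences across genomes."""

    name: str
    locus_class: str
    seqs: dict[str, str] = field(default_factory=dict)
    kind: str = ""  # CDS / tRNA / rRNA for gene loci, "" otherwise


def extract_homologous_loci(
    plastomes: list[AnnotatedPlastome],
    classes: tuple[str, ...] = ("gene", "intron", "spacer"),
) -> list[LocusSet]:
    """Homologous loci shared by all genomes: exonic gene sequences, introns,
    and intergenic spacers between consecutive shared genes.

    Spacers are named ``geneA-geneB`` after the flanking shared genes in
    genome order; a spacer whose flanking adjacency differs between genomes
    (e.g. a local inversion) is skipped with a logged note, as is any locus
    absent from at least one genome.
    """
    if len(plastomes) < 2:
        raise ValueError("need at least two genomes")
    symbol_maps = []
    for p in plastomes:
        m: dict[str, object] = {}
        for f in p.features:
            if f.pseudo:
                continue
            m.setdefault(f.symbol, f)  # first copy wins (IR duplicates)
        symbol_maps.append(m)
    shared = set(symbol_maps[0])
    for m in symbol_maps[1:]:
        shared &= set(m)
    if not shared:
        logger.warning("no shared gene symbols across genomes")
        return []

    loci: list[LocusSet] = []
    if "gene" in classes:
        for sym in sorted(shared):
            ls = LocusSet(
                name=sym, locus_class="coding", kind=symbol_maps[0][sym].kind
            )
            for p, m in zip(plastomes, symbol_maps):
                ls.seqs[p.id] = p.feature_sequence(m[sym])
            loci.append(ls)
    if "intron" in classes:
        for sym in sorted(shared):
            n_introns = {m[sym].intron_count for m in symbol_maps}
            if len(n_introns) != 1 or n_introns == {0}:
                continue
            for k in range(n_introns.pop()):
                ls = LocusSet(name=f"{sym}-intron{k + 1}", locus_class="non-coding")
                for p, m in zip(plastomes, symbol_maps):
                    s, e = m[sym].introns()[k]
                    ls.seqs[p.id] = p.sequence[s:e]
                if all(ls.seqs.values()):
                    loci.append(ls)
    if "spacer" in classes:
        orders = []
        for p, m in zip(plastomes, symbol_maps):
            order = sorted(shared, key=lambda sym: m[sym].start)
            orders.append(order)
        ref_adj = list(zip(orders[0], orders[0][1:]))
        for a, b in ref_adj:
            ok = True
            for order in orders[1:]:
                pairs = set(zip(order, order[1:]))
                if (a, b) not in pairs:
                    ok = False
                    break
            if not ok:
                logger.info("spacer %s-%s skipped: adjacency differs", a, b)
                continue
            ls = LocusSet(name=f"{a}-{b}", locus_class="non-coding")
            usable = True
            for p, m in zip(plastomes, symbol_maps):
                s = m[a].end
                e = m[b].start
                if e <= s:
                    usable = False
                    break
                ls.seqs[p.id] = p.sequence[s:e]
            if usable and all(ls.seqs.values()):
                loci.append(ls)
    return loci


def variability_table(
    loci: list[LocusSet],
    coding_cut: float = 50.0,
    noncoding_cut: float = 80.0,
) -> list[VariabilityRecord]:
    """Align each locus, compute variability, and flag hotspots."""
    records = []
    for ls in loci:
        names = sorted(ls.seqs)
        aln = align_locus(
            [ls.seqs[n] for n in names],
            names=names,
            locus=ls.name,
            locus_class=ls.locus_class,
        )
        records.append(variability(aln))
    return classify_hotspots(records, coding_cut, noncoding_cut)
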