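"""Positive-selection screening via pairwise NG86 dN/dS.

The Nei-Gojobori (1986) counting method: per codon, each of the nine
one-step neighbours is classified as synonymous or nonsynonymous (changes to
a stop codon count as nonsynonymous), giving site fractions that sum to 3
per codon; observed differences between codon pairs are averaged over all
mutational pathways (equal weights, pathways through stop codons excluded
and the weights renormalised); proportions are corrected with the
Jukes-Cantor formula d = -3/4 ln(1 - 4/3 p).

This is a rapid gene-level screen for elevated nonsynonymous substitution.
It is not a site-model test: it reports ratios per gene pair, not per-site
posterior identification of selected positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # universal code (= plastid here)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when a substitution proportion reaches 3/4 and the Jukes-Cantor
    correction diverges."""


@dataclass
class CodonAlignment:
    """Aligned coding sequences: length divisible by 3, gaps in whole codons."""

    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.taxa):
            raise ValueError(f"{self.gene}: taxa/rows mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: unequal aligned lengths")
        if lengths.pop() % 3:
            raise ValueError(f"{self.gene}: aligned length not divisible by 3")
        for taxon, row in zip(self.taxa, self.rows):
            for c in self.codons(row):
                if c in _STOPS:
                    raise ValueError(f"{self.gene}/{taxon}: internal stop codon {c}")

    @staticmethod
    def codons(row: str) -> list[str]:
        return [row[i : i + 3] for i in range(0, len(row), 3)]


@dataclass
class DnDsResult:
    gene: str
    pair: tuple[str, str]
    dN: float
    dS: float
    omega: float | None  # None when dN = dS = 0; inf when dS = 0 < dN


def build_codon_alignment(
    gene: str,
    seqs: dict[str, str],
    exclude_prefixes: tuple[str, ...] = ("ndh",),
) -> CodonAlignment | None:
    """Codon-aware alignment of a gene's coding sequences.

    Sequences are trimmed to frame (a trailing partial codon dropped, the
    terminal stop removed), their translations aligned, and the nucleotides
    threaded back so gaps come in whole codons.  Genes matching
    ``exclude_prefixes`` (by default the ndh family, frequently lost in the
    taxa this screen is aimed at) and genes with internal stops after framing
    are skipped with a logged reason, returning None.
    """
    if gene.lower().startswith(tuple(p.lower() for p in exclude_prefixes)):
        logger.info("%s: excluded by prefix rule", gene)
        return None
    framed: dict[str, str] = {}
    for taxon, seq in seqs.items():
        s = seq.upper()
        s = s[: len(s) - len(s) % 3]
        if s[-3:] in _STOPS:
            s = s[:-3]
        codons = CodonAlignment.codons(s)
        if any(c in _STOPS for c in codons):
            logger.warning("%s/%s: internal stop after framing; gene skipped", gene, taxon)
            return None
        framed[taxon] = s
    taxa = sorted(framed)
    if len(taxa) < 2:
        return None

    proteins = {t: str(Seq(framed[t]).translate()) for t in taxa}
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    # center-star on protein sequences, center = first taxon alphabetically
    center = taxa[0]
    master_prot = proteins[center]
    aligned_prot: dict[str, str] = {center: master_prot}
    for taxon in taxa[1:]:
        a_center, a_new = _protein_pair(aligner, master_prot.replace("-", ""), proteins[taxon])
        master_prot, merged_new, remap = _merge_rows(master_prot, a_center, a_new)
        for k in list(aligned_prot):
            if k != taxon:
                aligned_prot[k] = "".join(
                    "-" if old == -1 else aligned_prot[k][old] for old in remap
                )
        aligned_prot[taxon] = merged_new

    rows = []
    for t in taxa:
        codons = CodonAlignment.codons(framed[t])
        out = []
        ci = 0
        for aa in aligned_prot[t]:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[ci])
                ci += 1
        rows.append("".join(out))
    return CodonAlignment(gene=gene, taxa=taxa, rows=rows)


def _protein_pair(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    ra, rb = [], []
    pa = pb = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        if s1 > pa:
            ra.append(a[pa:s1])
            rb.append("-" * (s1 - pa))
        if s2 > pb:
            ra.append("-" * (s2 - pb))
            rb.append(b[pb:s2])
        ra.append(a[s1:e1])
        rb.append(b[s2:e2])
        pa, pb = e1, e2
    if pa < len(a):
        ra.append(a[pa:])
        rb.append("-" * (len(a) - pa))
    if pb < len(b):
        ra.append("-" * (len(b) - pb))
        rb.append(b[pb:])
    return "".join(ra), "".join(rb)


def _merge_rows(master: str, a_center: str, a_new: str):
    mi = ci = 0
    mm, mn, remap = [], [], []
    while mi < len(master) or ci < len(a_center):
        if mi < len(master) and master[mi] == "-":
            mm.append("-")
            mn.append("-")
            remap.append(mi)
            mi += 1
        elif ci < len(a_center) and a_center[ci] == "-":
            mm.append("-")
            mn.append(a_new[ci])
            remap.append(-1)
            ci += 1
        else:
            mm.append(master[mi])
            mn.append(a_new[ci])
            remap.append(mi)
            mi += 1
            ci += 1
    return "".join(mm), "".join(mn), remap


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon; sums to 3.

    Changes producing a stop codon are nonsynonymous.
    """
    aa = _TABLE.forward_table[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1 :]
            if neighbor not in _STOPS and _TABLE.forward_table[neighbor] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _TABLE.forward_table[codon]


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts between two codons, averaged over all
    mutational pathways; pathways passing through a stop codon are excluded
    and the remaining pathways reweighted equally.  If every pathway passes
    through a stop, stops are tolerated as intermediates (their steps counted
    as nonsynonymous) so the differences are still scored.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return (1.0, 0.0) if _aa(c1) == _aa(c2) else (0.0, 1.0)

    def walk(order, allow_stops):
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops and nxt != c2:
                return None
            if _aa(cur) is not None and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(permutations(diff))
    results = [walk(o, allow_stops=False) for o in orders]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = [walk(o, allow_stops=True) for o in orders]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: correction diverges")
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def ng86_dnds(aln: CodonAlignment, pair: tuple[str, str]) -> DnDsResult:
    """Pairwise NG86 dN/dS for two taxa of a codon alignment.

    Codons containing a gap or N in either row are skipped; at least 10
    overlapping codons are required.  ``omega`` is None when both rates are
    zero and +inf when dS = 0 < dN.  Symmetric in the pair by construction.
    """
    t1, t2 = pair
    row1 = aln.rows[aln.taxa.index(t1)]
    row2 = aln.rows[aln.taxa.index(t2)]
    codons1 = CodonAlignment.codons(row1)
    codons2 = CodonAlignment.codons(row2)

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    used = 0
    for c1, c2 in zip(codons1, codons2):
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        used += 1
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        dsd, dnd = _pathway_counts(c1, c2)
        sd += dsd
        nd += dnd
    if used < 10:
        raise ValueError(f"{aln.gene}: only {used} overlapping codons (< 10)")

    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    dS = _jukes_cantor(ps)
    dN = _jukes_cantor(pn)
    if dS == 0.0 and dN == 0.0:
        omega: float | None = None
    elif dS == 0.0:
        omega = math.inf
    else:
        omega = dN / dS
    return DnDsResult(gene=aln.gene, pair=(t1, t2), dN=dN, dS=dS, omega=omega)


def all_pairs_dnds(aln: CodonAlignment) -> list[DnDsResult]:
    out = []
    for i in range(len(aln.taxa)):
        for j in range(i + 1, len(aln.taxa)):
            try:
                out.append(ng86_dnds(aln, (aln.taxa[i], aln.taxa[j])))
            except (SaturationError, ValueError) as exc:
                logger.warning("%s %s-%s: %s", aln.gene, aln.taxa[i], aln.taxa[j], exc)
    return out


def screen_positive_genes(
    results: list[DnDsResult], omega_cut: float = 1.0
) -> list[tuple[str, float]]:
    """Genes whose maximum defined pairwise omega exceeds ``omega_cut``,
    sorted by that maximum, descending (ties by gene name)."""
    best: dict[str, float] = {}
    for r in results:
        if r.omega is None or math.isinf(r.omega):
            continue
        best[r.gene] = max(best.get(r.gene, 0.0), r.omega)
    flagged = [(g, w) for g, w in best.items() if w > omega_cut]
    return sorted(flagged, key=lambda t: (-t[1], t[0]))
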