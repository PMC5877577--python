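"""Synthetic annotated plastomes and evolved genome sets with full ground
truth, so every pipeline stage can be exercised without downloads.

The generator builds a circular genome with the canonical LSC-IRb-SSC-IRa
layout: IRa is the exact reverse complement of IRb, genes (CDS with optional
introns, tRNA, rRNA) are placed in both single-copy and IR regions, and SSRs
and dispersed repeats are planted at recorded coordinates.  Default
dimensions follow a typical orchid plastome: LSC 87 kb, IR 26 kb, SSC 15 kb
(about 154 kb in total) at GC ~0.37.

Evolution along a guide tree applies per-region substitution rates, indels
outside genes and planted repeats (so planted ground truth stays exact), and
codon-aware CDS evolution in which nonsynonymous proposals are accepted with
probability min(1, omega), giving genes with a controlled dN/dS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .records import AnnotatedPlastome, GeneFeature, reverse_complement

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PlantedSSR:
    motif: str
    repeats: int
    region: str  # LSC | SSC | IR


@dataclass
class PlantedRepeat:
    length: int
    type: str = "F"       # F | P | R | C
    mismatches: int = 0


@dataclass
class PlastomeSpec:
    lsc_len: int = 87_000
    ir_len: int = 26_000
    ssc_len: int = 15_000
    n_genes: int = 30
    gene_len: tuple[int, int] = (300, 1500)   # CDS length range (codons*3)
    intron_frac: float = 0.3
    gc: float = 0.37
    ssrs: list[PlantedSSR] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    seed: int = 0


@dataclass
class GroundTruth:
    ir_first: tuple[int, int] = (0, 0)   # IRb in canonical coordinates
    ir_second: tuple[int, int] = (0, 0)  # IRa
    region_bounds: dict = field(default_factory=dict)
    ssr_coords: list = field(default_factory=list)      # (motif, repeats, start)
    repeat_coords: list = field(default_factory=list)   # (type, pos1, pos2, length, mism)
    gene_coords: dict = field(default_factory=dict)
    gene_omega: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)        # per-branch / per-locus counts


class SpecError(ValueError):
    pass


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c in sorted(_TABLE.forward_table) if "U" not in c]
    idx = rng.integers(0, len(codons), size=n_codons - 2)
    body = "".join(codons[i] for i in idx)
    return "ATG" + body + "TAA"


def generate_plastome(spec: PlastomeSpec) -> tuple[AnnotatedPlastome, GroundTruth]:
    """Build a synthetic annotated plastome with exact planted ground truth.

    The same seed always yields byte-identical output.  Raises
    :class:`SpecError` when planted features collide.
    """
    rng = np.random.default_rng(spec.seed)
    lsc = _random_dna(rng, spec.lsc_len, spec.gc)
    irb = _random_dna(rng, spec.ir_len, spec.gc)
    ssc = _random_dna(rng, spec.ssc_len, spec.gc)

    truth = GroundTruth()
    n_total = spec.lsc_len + 2 * spec.ir_len + spec.ssc_len
    lsc_off = 0
    irb_off = spec.lsc_len
    ssc_off = irb_off + spec.ir_len
    ira_off = ssc_off + spec.ssc_len
    truth.region_bounds = {
        "LSC": (lsc_off, irb_off),
        "IRb": (irb_off, ssc_off),
        "SSC": (ssc_off, ira_off),
        "IRa": (ira_off, n_total),
    }
    truth.ir_first = truth.region_bounds["IRb"]
    truth.ir_second = truth.region_bounds["IRa"]

    regions = {"LSC": lsc, "IR": irb, "SSC": ssc}
    offsets = {"LSC": lsc_off, "IR": irb_off, "SSC": ssc_off}
    claimed: dict[str, list[tuple[int, int]]] = {"LSC": [], "IR": [], "SSC": []}

    features: list[GeneFeature] = []

    def claim(region: str, length: int, what: str) -> int:
        buf = regions[region]
        if len(buf) - length - 50 <= 50:
            raise SpecError(f"cannot place {what} of {length} bp in {region}")

        def free(start: int) -> bool:
            return all(
                start + length + 10 <= s or e + 10 <= start
                for s, e in claimed[region]
            )

        for _ in range(200):
            start = int(rng.integers(50, len(buf) - length - 50))
            if free(start):
                claimed[region].append((start, start + length))
                return start
        # deterministic fallback scan for crowded regions
        for start in range(50, len(buf) - length - 49, 10):
            if free(start):
                claimed[region].append((start, start + length))
                return start
        raise SpecError(f"cannot place {what} of {length} bp in {region}")

    # --- genes -------------------------------------------------------------
    # Payloads are drawn first, then laid out sequentially per region with
    # the slack distributed into random inter-gene gaps: placement succeeds
    # whenever the total fits, regardless of seed.
    n_ir_genes = max(1, spec.n_genes // 10)
    n_ssc_genes = max(1, spec.n_genes // 6)
    n_lsc_genes = spec.n_genes - n_ir_genes - n_ssc_genes
    gene_plan = (
        [("LSC", "CDS")] * n_lsc_genes
        + [("SSC", "CDS")] * n_ssc_genes
        + [("IR", "CDS")] * n_ir_genes
    )

    payloads: dict[str, list[dict]] = {"LSC": [], "SSC": [], "IR": []}
    gene_id = 0
    for region, _ in gene_plan:
        lo, hi = spec.gene_len
        n_codons = int(rng.integers(lo // 3, hi // 3))
        cds = _random_cds(rng, n_codons)
        intron = ""
        if rng.random() < spec.intron_frac:
            intron = bytes(
                _random_dna(rng, int(rng.integers(80, 300)), spec.gc)
            ).decode()
        strand = "+" if rng.random() < 0.5 else "-"
        payloads[region].append(
            {
                "name": f"gen{gene_id:02d}",
                "kind": "CDS",
                "strand": strand,
                "cds": cds,
                "intron": intron,
            }
        )
        gene_id += 1
    # a tRNA and an rRNA inside the IR (duplicated with it), one tRNA in LSC
    for name, kind, region, length in (
        ("trnX-AAA", "tRNA", "IR", 75),
        ("rrnS", "rRNA", "IR", 1500),
        ("trnY-CCC", "tRNA", "LSC", 80),
    ):
        payloads[region].append(
            {
                "name": name,
                "kind": kind,
                "strand": "+",
                "cds": bytes(_random_dna(rng, length, spec.gc)).decode(),
                "intron": "",
            }
        )

    margin, spacing = 50, 10
    for region, items in payloads.items():
        if not items:
            continue
        buf = regions[region]
        lengths = [len(p["cds"]) + len(p["intron"]) for p in items]
        slack = len(buf) - 2 * margin - sum(lengths) - spacing * (len(items) - 1)
        if slack < 0:
            raise SpecError(
                f"{region}: {len(items)} features need {-slack} bp more space"
            )
        cuts = sorted(int(rng.integers(0, slack + 1)) for _ in range(len(items)))
        pos = margin
        prev_cut = 0
        for p, length, cut in zip(items, lengths, cuts):
            pos += cut - prev_cut
            prev_cut = cut
            start = pos
            cds, intron, strand = p["cds"], p["intron"], p["strand"]
            minus = p["kind"] == "CDS" and strand == "-"
            if intron:
                split = 3 * (len(cds) // 6)
                insert = cds[:split] + intron + cds[split:]
                # on the minus strand the genome holds revcomp(insert), so
                # the downstream exon comes first and the part lengths swap
                first_exon = (len(cds) - split) if minus else split
                parts = [
                    (start, start + first_exon),
                    (start + first_exon + len(intron), start + length),
                ]
            else:
                insert = cds
                parts = [(start, start + length)]
            if minus:
                insert = reverse_complement(insert)
            buf[start : start + length] = np.frombuffer(insert.encode(), dtype="S1")
            claimed[region].append((start, start + length))
            off = offsets[region]
            features.append(
                GeneFeature(
                    name=p["name"],
                    kind=p["kind"],
                    strand=strand,
                    parts=[(s + off, e + off) for s, e in parts],
                )
            )
            truth.gene_coords[p["name"]] = (start + off, start + off + length, region)
            pos += length + spacing

    # --- planted SSRs -------------------------------------------------------
    for planted in spec.ssrs:
        run = planted.motif * planted.repeats
        start = claim(planted.region, len(run) + 2, f"SSR {planted.motif}")
        buf = regions[planted.region]
        payload = np.frombuffer(run.encode(), dtype="S1")
        buf[start : start + len(run)] = payload
        # break the run at both ends so the planted locus is maximal
        for pos, nb in ((start - 1, planted.motif[-1]), (start + len(run), planted.motif[0])):
            if 0 <= pos < len(buf) and bytes(buf[pos : pos + 1]).decode() == nb:
                alt = next(b for b in "ACGT" if b != nb)
                buf[pos] = alt.encode()
        truth.ssr_coords.append(
            (planted.motif, planted.repeats, start + offsets[planted.region])
        )

    # --- planted dispersed repeats (both occurrences in the LSC) ------------
    for planted in spec.repeats:
        block = _random_dna(rng, planted.length, spec.gc)
        s1 = claim("LSC", planted.length, "repeat occurrence 1")
        s2 = claim("LSC", planted.length, "repeat occurrence 2")
        copy = block.copy()
        if planted.mismatches:
            pos = rng.choice(planted.length, size=planted.mismatches, replace=False)
            for p in pos:
                cur = bytes(copy[p : p + 1]).decode()
                alt = next(b for b in "ACGT" if b != cur)
                copy[p] = alt.encode()
        occ2 = {
            "F": copy,
            "P": np.frombuffer(
                reverse_complement(bytes(copy).decode()).encode(), dtype="S1"
            ),
            "R": copy[::-1],
            "C": np.frombuffer(
                bytes(copy).decode().translate(str.maketrans("ACGT", "TGCA")).encode(),
                dtype="S1",
            ),
        }[planted.type]
        lsc[s1 : s1 + planted.length] = block
        lsc[s2 : s2 + planted.length] = occ2
        a, b = sorted((s1, s2))
        truth.repeat_coords.append(
            (planted.type, a + lsc_off, b + lsc_off, planted.length, planted.mismatches)
        )

    # Make the planted IR pair strictly maximal on the circle: force the
    # first 12 single-copy pairings beyond each boundary to mismatch (a base
    # never pairs with itself under the inverted-repeat relation), so no
    # extension of the detected repeat can score above the planted boundary.
    guard = 12
    for t in range(guard):
        ssc[t] = ssc[len(ssc) - 1 - t]          # breaks extension into SSC
        lsc[len(lsc) - 1 - t] = lsc[t]          # breaks extension across origin

    ira = np.frombuffer(
        reverse_complement(bytes(irb).decode()).encode(), dtype="S1"
    )
    genome = bytes(np.concatenate([lsc, irb, ssc, ira])).decode()

    # mirror IR genes into IRa (they are duplicated with the repeat)
    mirrored = []
    for f in features:
        if f.start >= irb_off and f.end <= ssc_off:
            parts = []
            for s, e in f.parts:
                s2 = ira_off + (ssc_off - e)
                e2 = ira_off + (ssc_off - s)
                parts.append((s2, e2))
            mirrored.append(
                GeneFeature(
                    name=f.name,
                    kind=f.kind,
                    strand="-" if f.strand == "+" else "+",
                    parts=sorted(parts),
                )
            )
    features.extend(mirrored)

    plastome = AnnotatedPlastome(
        id=f"synthetic-{spec.seed}",
        sequence=genome,
        circular=True,
        features=sorted(features, key=lambda f: f.start),
    )
    return plastome, truth


# ---------------------------------------------------------------------------
# evolution along a guide tree
# ---------------------------------------------------------------------------

@dataclass
class EvolutionSpec:
    """Guide tree (newick with branch lengths) plus per-region rates.

    Substitution rates are expected substitutions per site per unit branch
    length; ``gene_omega`` maps gene names to the dN/dS with which their CDS
    evolves (default 1 = neutral).  Indels are placed only outside genes and
    planted repeats so planted ground truth stays exact.
    """

    tree: str = "(a:0.01,b:0.01);"
    coding_rate: float = 0.01
    noncoding_rate: float = 0.03
    ir_rate_factor: float = 0.3
    indel_rate: float = 0.0
    indel_len: tuple[int, int] = (1, 10)
    gene_omega: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _parse_newick(s: str):
    """Minimal newick parser -> nested (children, name, length) tuples."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        children = []
        name = ""
        length = 0.0
        if s[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if s[pos] == ",":
                    pos += 1
                else:
                    break
            assert s[pos] == ")", f"bad newick near {pos}"
            pos += 1
        while pos < len(s) and s[pos] not in ",():;":
            name += s[pos]
            pos += 1
        if ":" in name:
            name, _, bl = name.partition(":")
            length = float(bl)
        elif pos < len(s) and s[pos] == ":":
            pos += 1
            bl = ""
            while pos < len(s) and s[pos] not in ",()":
                bl += s[pos]
                pos += 1
            length = float(bl)
        return (children, name, length)

    return parse()


@dataclass
class _Lineage:
    """Mutable per-lineage state carried down the guide tree."""

    seq: np.ndarray            # S1 array
    region: np.ndarray         # U3 array: LSC / IR / SSC
    indel_ok: np.ndarray       # bool: positions where indels may occur
    parts: list[list[tuple[int, int]]]  # feature parts, parallel to features

    def copy(self) -> "_Lineage":
        return _Lineage(
            self.seq.copy(),
            self.region.copy(),
            self.indel_ok.copy(),
            [list(p) for p in self.parts],
        )


def evolve_genomes(
    ancestor: AnnotatedPlastome,
    truth: GroundTruth,
    evo: EvolutionSpec,
) -> tuple[dict[str, AnnotatedPlastome], GroundTruth]:
    """Evolve the ancestor along the guide tree; returns leaf genomes.

    Each branch applies per-site substitutions at the configured region rates
    (IR positions damped by ``ir_rate_factor``) and, when ``indel_rate`` > 0,
    indel events at positions outside genes and planted repeats; feature
    coordinates are shifted through indels so leaf annotations stay exact.
    CDS positions mutate codon-aware: an amino-acid-changing proposal is
    accepted with probability min(1, omega) for its gene and proposals
    creating stops are rejected.  Realized counts are recorded per branch.
    """
    rng = np.random.default_rng(evo.seed)
    tree = _parse_newick(evo.tree)

    region0 = np.empty(ancestor.length, dtype="U3")
    for name, (s, e) in truth.region_bounds.items():
        region0[s:e] = "IR" if name in ("IRa", "IRb") else name

    indel_ok0 = np.ones(ancestor.length, dtype=bool)
    for _, _, start in truth.ssr_coords:
        indel_ok0[max(0, start - 2) : start + 80] = False
    for _, p1, p2, length, _ in truth.repeat_coords:
        indel_ok0[p1 : p1 + length] = False
        indel_ok0[p2 : p2 + length] = False
    for f in ancestor.features:
        indel_ok0[f.start : f.end] = False
    # no indels inside the IR: the two copies are kept in sync by
    # copy-correction (below), which substitution mirroring handles but
    # coordinate shifts would not
    indel_ok0[region0 == "IR"] = False

    genomes: dict[str, AnnotatedPlastome] = {}
    realized: dict[str, dict] = {}

    def coding_map(lineage: _Lineage) -> dict[int, tuple]:
        cmap: dict[int, tuple] = {}
        for f, parts in zip(ancestor.features, lineage.parts):
            if f.kind != "CDS":
                continue
            positions: list[int] = []
            for s, e in sorted(parts):
                positions.extend(range(s, e))
            if f.strand == "-":
                positions = positions[::-1]
            ptup = tuple(positions)
            for idx, pos in enumerate(ptup):
                cmap[pos] = (f.name, f.strand, idx, ptup)
        return cmap

    def mutate_branch(lineage: _Lineage, blen: float) -> dict:
        counts = {
            "coding": 0,
            "noncoding": 0,
            "per_gene": {},
            "indel_events": 0,
            "indel_bp": 0,
        }
        cmap = coding_map(lineage)
        n = len(lineage.seq)
        is_coding = np.zeros(n, dtype=bool)
        is_coding[list(cmap)] = True
        # tRNA/rRNA exons evolve at the conservative coding rate too (without
        # codon-aware acceptance); only spacers and introns are "non-coding"
        for f, parts in zip(ancestor.features, lineage.parts):
            if f.kind in ("tRNA", "rRNA"):
                for s, e in parts:
                    is_coding[s:e] = True
        rates = np.where(is_coding, evo.coding_rate, evo.noncoding_rate)
        rates = rates * np.where(lineage.region == "IR", evo.ir_rate_factor, 1.0)
        hits = np.nonzero(rng.random(n) < 1 - np.exp(-rates * blen))[0]
        for pos in hits:
            cur = lineage.seq[pos]
            alts = [b for b in _BASES if b != cur]
            new = alts[int(rng.integers(0, 3))]
            if pos in cmap:
                gene, strand, idx, positions = cmap[pos]
                omega = evo.gene_omega.get(gene, 1.0)
                if not _accept_coding(
                    lineage.seq, int(pos), new, strand, idx, positions, omega, rng
                ):
                    continue
                counts["coding"] += 1
                counts["per_gene"][gene] = counts["per_gene"].get(gene, 0) + 1
            else:
                counts["noncoding"] += 1
            lineage.seq[pos] = new

        if evo.indel_rate > 0:
            eligible = np.nonzero(lineage.indel_ok)[0]
            expect = evo.indel_rate * blen * len(eligible)
            n_events = int(rng.poisson(expect))
            sites = sorted(
                (int(x) for x in rng.choice(eligible, size=n_events, replace=False)),
                reverse=True,
            )
            for site in sites:
                length = int(rng.integers(evo.indel_len[0], evo.indel_len[1] + 1))
                if rng.random() < 0.5:  # deletion, truncated at protected bases
                    run = lineage.indel_ok[site : site + length]
                    if not run.all():
                        length = int(np.argmin(run))
                    if length < 1:
                        continue
                    _apply_indel(lineage, site, -length, rng, evo)
                else:
                    _apply_indel(lineage, site, length, rng, evo)
                counts["indel_events"] += 1
                counts["indel_bp"] += length

        _sync_ir_copies(lineage)
        return counts

    def _sync_ir_copies(lineage: _Lineage) -> None:
        """Copy-correct IRa from IRb (reverse complement) after mutation,
        emulating the gene conversion that keeps real plastome IRs
        near-identical."""
        ir_pos = np.nonzero(lineage.region == "IR")[0]
        if ir_pos.size == 0:
            return
        breaks = np.nonzero(np.diff(ir_pos) > 1)[0]
        if breaks.size != 1:
            return
        first = ir_pos[: breaks[0] + 1]
        second = ir_pos[breaks[0] + 1 :]
        if first.size != second.size:
            return
        seg = bytes(lineage.seq[first]).decode()
        lineage.seq[second] = np.frombuffer(
            reverse_complement(seg).encode(), dtype="S1"
        )

    def _accept_coding(seq, pos, new, strand, idx, positions, omega, rng) -> bool:
        codon_idx = idx // 3
        cpos = sorted(positions[codon_idx * 3 : codon_idx * 3 + 3])
        old_plus = b"".join(bytes(seq[p]) for p in cpos).decode()
        new_plus = "".join(
            new.decode() if p == pos else old_plus[k] for k, p in enumerate(cpos)
        )
        if strand == "-":
            oc, nc = reverse_complement(old_plus), reverse_complement(new_plus)
        else:
            oc, nc = old_plus, new_plus
        if oc in _STOPS or nc in _STOPS:
            return False
        # relative fixation: synonymous damped by 1/omega above 1 so omega > 1
        # manifests as an excess of nonsynonymous over synonymous changes
        if _TABLE.forward_table[oc] == _TABLE.forward_table[nc]:
            return bool(rng.random() < min(1.0, 1.0 / max(omega, 1e-9)))
        return bool(rng.random() < min(1.0, omega))

    def _apply_indel(lineage: _Lineage, site: int, delta: int, rng, evo) -> None:
        if delta < 0:
            sl = slice(site, site - delta)
            lineage.seq = np.delete(lineage.seq, sl)
            lineage.region = np.delete(lineage.region, sl)
            lineage.indel_ok = np.delete(lineage.indel_ok, sl)
        else:
            insert = _random_dna(rng, delta, 0.37)
            lineage.seq = np.insert(lineage.seq, site, insert)
            lineage.region = np.insert(
                lineage.region, site, [lineage.region[site]] * delta
            )
            lineage.indel_ok = np.insert(
                lineage.indel_ok, site, np.ones(delta, dtype=bool)
            )
        shift = delta
        for parts in lineage.parts:
            for k, (s, e) in enumerate(parts):
                if s >= site:
                    parts[k] = (s + shift, e + shift)

    def descend(node, lineage: _Lineage):
        children, name, length = node
        if length > 0:
            lineage = lineage.copy()
            key = name or f"node{len(realized)}"
            realized[key] = mutate_branch(lineage, length)
        if not children:
            feats = [
                GeneFeature(
                    name=f.name,
                    kind=f.kind,
                    strand=f.strand,
                    parts=sorted(parts),
                    pseudo=f.pseudo,
                )
                for f, parts in zip(ancestor.features, lineage.parts)
            ]
            genomes[name] = AnnotatedPlastome(
                id=name,
                sequence=bytes(lineage.seq).decode(),
                circular=ancestor.circular,
                features=feats,
            )
        for child in children:
            descend(child, lineage)

    root_lineage = _Lineage(
        seq=np.frombuffer(ancestor.sequence.encode(), dtype="S1").copy(),
        region=region0,
        indel_ok=indel_ok0,
        parts=[list(f.parts) for f in ancestor.features],
    )
    descend(tree, root_lineage)

    out_truth = GroundTruth(
        ir_first=truth.ir_first,
        ir_second=truth.ir_second,
        region_bounds=dict(truth.region_bounds),
        ssr_coords=list(truth.ssr_coords),
        repeat_coords=list(truth.repeat_coords),
        gene_coords=dict(truth.gene_coords),
        gene_omega=dict(evo.gene_omega),
        realized=realized,
    )
    return genomes, out_truth
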