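"""Repeat scans: dispersed repeats, microsatellites (SSRs), and a simplified
tandem-repeat finder.

Dispersed repeats come in four orientation types relating the two
occurrences: forward (F, same strand), palindromic (P, reverse complement),
reverse (R, reversed) and complement (C, complemented).  A hit is a *maximal*
pair: it cannot be extended at either end without exceeding the Hamming
budget.  Defaults follow the conventional plastome analysis parameters:
minimum length 30 bp, Hamming distance at most 3, the 50 longest hits kept
per type.

SSR detection follows MISA semantics: maximal runs of a primitive 1-6 bp
motif, with minimum repeat numbers 10/5/4/3/3/3 for mono- through
hexanucleotides.  The tandem-repeat finder is an explicitly simplified,
deterministic variant of the classic period-scoring heuristic (+2 match, -7
mismatch, -7 indel, minimum score 80, maximum period 500): candidate periods
come from k-mer recurrence and runs are scored against their per-phase
consensus without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    AnnotatedPlastome,
    classify_interval,
    complement,
    region_label,
    reverse_complement,
)

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
SEED_K = 7  # pigeonhole: a 30 bp window with <= 3 mismatches holds an exact 7-mer

REPEAT_TYPES = ("F", "P", "R", "C")


@dataclass(frozen=True)
class RepeatHit:
    """A maximal dispersed-repeat pair.

    ``pos1``/``pos2`` are the start coordinates of the two occurrences
    (pos1 <= pos2); both occurrences have the same ``length``.
    """

    type: str
    pos1: int
    pos2: int
    length: int
    mismatches: int


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    unit_len: int
    repeats: int
    start: int
    region: str = ""        # LSC / SSC / IR
    region_class: str = ""  # CDS / intron / IGS / CDS-IGS

    @property
    def end(self) -> int:
        return self.start + self.unit_len * self.repeats


@dataclass
class CompoundSSR:
    members: list[SSRLocus]
    gaps: list[int]


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    span: tuple[int, int]
    copy_number: float
    score: int
    consensus: str


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

def find_dispersed_repeats(
    sequence: str,
    min_len: int = 30,
    max_hamming: int = 3,
    cap_per_type: int = 50,
) -> list[RepeatHit]:
    """Maximal dispersed-repeat pairs of the four orientation types.

    Seed-and-extend: exact ``SEED_K``-mer matches between the sequence and
    each orientation transform nominate diagonals; around every seed all
    maximal windows within the Hamming budget are enumerated from the
    neighbouring mismatch positions.  Per type the ``cap_per_type`` longest
    hits are kept, ties resolved by (length desc, pos1 asc, pos2 asc).

    Self-overlapping palindromic/reverse hits (a site matching its own
    reverse complement or reverse) are kept only when the two occurrences
    overlap by less than half their length.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 makes exact seeding impossible")
    n = len(sequence)
    if n < 2 * min_len:
        return []

    targets = {
        "F": sequence,
        "C": complement(sequence),
        "R": sequence[::-1],
        "P": reverse_complement(sequence),
    }
    out: list[RepeatHit] = []
    for rtype, target in targets.items():
        windows = _maximal_windows(sequence, target, min_len, max_hamming)
        hits: set[RepeatHit] = set()
        for start, end, d, mism in windows:
            length = end - start
            p1 = start
            if rtype == "F":
                p2 = start + d
                if d == 0:
                    continue  # trivial self-identity
            elif rtype == "C":
                p2 = start + d
                if d == 0:
                    continue
            else:  # R and P relate occurrences by reversal
                p2 = n - (start + d) - length
            a, b = sorted((p1, p2))
            if rtype in ("R", "P"):
                overlap = max(0, (a + length) - b)
                if overlap * 2 >= length:
                    continue  # self-hit: occurrences mostly coincide
            elif a + length > b:
                # F/C occurrences overlapping => tandem-like; keep only if
                # offset is at least one full position (always true) but drop
                # full self-identity handled above.
                pass
            hits.add(RepeatHit(rtype, a, b, length, mism))
        ranked = sorted(hits, key=lambda h: (-h.length, h.pos1, h.pos2))
        out.extend(ranked[:cap_per_type])
    return out


def _maximal_windows(seq: str, target: str, min_len: int, budget: int):
    """All maximal (<= budget mismatches, >= min_len) windows on seeded
    diagonals of seq vs target.

    Returns tuples (start, end, diag, mismatches) in seq coordinates where
    seq[start:end] pairs with target[start+diag : end+diag].  'N' never
    matches anything.
    """
    n = len(seq)
    k = SEED_K
    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        kmer = target[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)

    diag_seeds: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            diag_seeds.setdefault(j - i, []).append(i)

    results: set[tuple[int, int, int, int]] = set()
    for d, seeds in diag_seeds.items():
        lo_bound = max(0, -d)
        hi_bound = min(n, n - d)
        # seeds sorted; skip seeds inside the exact stretch already processed
        done_until = lo_bound - 1
        for i in sorted(set(seeds)):
            if i + k <= done_until:
                continue
            left = _walk_mismatches(seq, target, d, i - 1, -1, lo_bound - 1, budget + 1)
            right = _walk_mismatches(seq, target, d, i + k, +1, hi_bound, budget + 1)
            done_until = (right[0] if right else hi_bound)
            # windows run between a left slot and a right slot; pad with
            # sentinels so boundary-limited windows appear once each
            L = ([lo_bound - 1] * (budget + 2 - len(left))) + sorted(left)
            R = sorted(right) + ([hi_bound] * (budget + 2 - len(right)))
            for q in range(budget + 1):
                lo_m = L[len(L) - 1 - q]          # (q+1)-th mismatch to the left
                hi_m = R[budget - q]              # (budget-q+1)-th to the right
                start, end = lo_m + 1, hi_m
                if end - start < min_len:
                    continue
                mism = sum(1 for x in L if start <= x) + sum(
                    1 for x in R if x < end
                )
                results.add((start, end, d, mism))
    return results


def _walk_mismatches(seq, target, d, start, step, bound, count):
    """Positions of the next ``count`` mismatches on diagonal d, walking from
    ``start`` (inclusive) in direction ``step`` until ``bound`` (exclusive)."""
    out = []
    i = start
    while i != bound and len(out) < count:
        a, b = seq[i], target[i + d]
        if a != b or a == "N":
            out.append(i)
        i += step
    return out


def brute_force_dispersed(
    sequence: str, min_len: int = 30, max_hamming: int = 3
) -> set[RepeatHit]:
    """Independent all-pairs enumeration of maximal dispersed repeats.

    Quadratic reference used for validation on short sequences: scans every
    diagonal of every orientation in full and reduces to maximal windows.
    """
    n = len(sequence)
    targets = {
        "F": sequence,
        "C": complement(sequence),
        "R": sequence[::-1],
        "P": reverse_complement(sequence),
    }
    import numpy as np

    arr = np.frombuffer(sequence.encode(), dtype="S1")
    hits: set[RepeatHit] = set()
    for rtype, target in targets.items():
        tarr = np.frombuffer(target.encode(), dtype="S1")
        for d in range(-(n - 1), n):
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            a = arr[lo:hi]
            b = tarr[lo + d : hi + d]
            mism_arr = np.nonzero((a != b) | (a == b"N"))[0] + lo
            # Sentinel-padded mismatch slots: every window between slot i and
            # slot i + budget + 1 (exclusive) holds <= budget mismatches and
            # is maximal: each end abuts a budget-breaking mismatch or the
            # diagonal boundary.
            B = max_hamming + 1
            slots = np.concatenate(
                [np.full(B, lo - 1), mism_arr, np.full(B, hi)]
            )
            starts = np.maximum(slots[:-B] + 1, lo)
            ends = np.minimum(slots[B:], hi)
            keep = np.nonzero(ends - starts >= min_len)[0]
            for i in keep:
                start, end = int(starts[i]), int(ends[i])
                count = int(
                    np.searchsorted(mism_arr, end) - np.searchsorted(mism_arr, start)
                )
                length = end - start
                p1 = start
                if rtype in ("F", "C"):
                    if d == 0:
                        continue
                    p2 = start + d
                else:
                    p2 = n - (start + d) - length
                a, b = sorted((p1, p2))
                if rtype in ("R", "P"):
                    overlap = max(0, (a + length) - b)
                    if overlap * 2 >= length:
                        continue
                hits.add(RepeatHit(rtype, a, b, length, count))
    return hits


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for q in range(1, p):
        if p % q == 0 and motif == motif[:q] * (p // q):
            return False
    return True


def find_ssrs(
    sequence: str, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """Microsatellite loci: maximal runs of a primitive 1-6 bp motif.

    Every maximal run whose full-unit count meets the threshold for its unit
    length is reported exactly once, described by its shortest (primitive)
    unit.  Runs containing N are broken at the N.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    n = len(sequence)
    out: list[SSRLocus] = []
    for p, min_rep in sorted(thresholds.items()):
        if p < 1 or p > 6:
            raise ValueError("SSR unit lengths must be 1..6")
        i = 0
        while i + p < n + 1:
            # maximal stretch with period p starting at i
            if "N" in sequence[i : i + p]:
                i += 1
                continue
            j = i + p
            while j < n and sequence[j] == sequence[j - p] and sequence[j] != "N":
                j += 1
            stretch = j - i
            reps = stretch // p
            if reps >= min_rep:
                motif = sequence[i : i + p]
                if _is_primitive(motif):
                    # maximality to the left is guaranteed by the scan order:
                    # i is the first position of this period-p stretch
                    out.append(
                        SSRLocus(motif=motif, unit_len=p, repeats=reps, start=i)
                    )
                i = j  # nothing with the same period can start inside
            else:
                i += 1
    out.sort(key=lambda s: (s.start, s.unit_len))
    return out


def merge_compound_ssrs(
    ssrs: list[SSRLocus], max_gap: int = 100
) -> list[CompoundSSR]:
    """Chain SSRs whose gaps are at most ``max_gap`` bp into compound loci."""
    ordered = sorted(ssrs, key=lambda s: s.start)
    compounds: list[CompoundSSR] = []
    group: list[SSRLocus] = []
    for s in ordered:
        if group and s.start - group[-1].end <= max_gap:
            group.append(s)
        else:
            if len(group) >= 2:
                compounds.append(_make_compound(group))
            group = [s]
    if len(group) >= 2:
        compounds.append(_make_compound(group))
    return compounds


def _make_compound(group: list[SSRLocus]) -> CompoundSSR:
    gaps = [b.start - a.end for a, b in zip(group, group[1:])]
    return CompoundSSR(members=list(group), gaps=gaps)


# ---------------------------------------------------------------------------
# tandem repeats (simplified)
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    sequence: str,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
    min_score: int = 80,
    max_period: int = 500,
) -> list[TandemRepeat]:
    """Deterministic simplified tandem-repeat finder.

    Candidate (start, period) pairs come from recurring 5-mers at distances
    up to ``max_period``; each candidate run is extended while its running
    period-match score stays near its maximum and then scored against the
    per-phase consensus of the run (+match per agreement, -mismatch
    otherwise; the gap penalty is unused because this variant does not model
    indels).  Runs scoring at least ``min_score`` and spanning at least two
    periods are reported.  This is a simplified variant of the classic
    heuristic and is not expected to be output-identical to it.
    """
    n = len(sequence)
    k = 5
    last_seen: dict[str, list[int]] = {}
    candidates: set[tuple[int, int]] = set()
    for i in range(n - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer:
            continue
        occ = last_seen.setdefault(kmer, [])
        for j in reversed(occ):
            d = i - j
            if d > max_period:
                break
            candidates.add((j, d))
        occ.append(i)

    reported: list[TandemRepeat] = []
    claimed: list[tuple[int, tuple[int, int]]] = []
    for start, period in sorted(candidates, key=lambda c: (c[1], c[0])):
        a0, b0 = _extend_periodic(sequence, start, period, mismatch)
        if b0 - a0 < 2 * period:
            continue
        # trim the greedy span to its best-scoring subsegment against the
        # consensus (the extension may run into a neighbouring region that
        # shares the period, e.g. a homopolymer)
        consensus0 = _consensus(sequence, a0, b0, period)
        a, b = _best_subsegment(sequence, a0, b0, period, consensus0, match, mismatch)
        if b - a < 2 * period:
            continue
        if any(p == period and a >= s[0] and b <= s[1] for p, s in claimed):
            continue
        consensus = _consensus(sequence, a, b, period)
        score = 0
        for idx in range(a, b):
            if sequence[idx] == consensus[(idx - a) % period]:
                score += match
            else:
                score -= mismatch
        if score >= min_score:
            tr = TandemRepeat(
                period=period,
                span=(a, b),
                copy_number=round((b - a) / period, 1),
                score=score,
                consensus=consensus,
            )
            reported.append(tr)
            claimed.append((period, (a, b)))
    # drop non-primitive reports that duplicate a shorter-period repeat
    final = []
    for tr in sorted(reported, key=lambda t: (t.span[0], t.period)):
        redundant = any(
            tr.period % other.period == 0
            and other.period < tr.period
            and other.span[0] <= tr.span[0]
            and tr.span[1] <= other.span[1]
            for other in reported
        )
        if not redundant:
            final.append(tr)
    return final


def _extend_periodic(seq: str, start: int, period: int, mismatch_penalty: int):
    """Greedy two-sided extension of a periodic run; extension stops strictly
    before three consecutive mismatches so a run never bridges into an
    adjacent region that happens to share the period (e.g. a homopolymer)."""
    n = len(seq)
    xdrop = 3 * mismatch_penalty - 1
    # right
    b = start + period
    score = best = 0
    best_b = b
    i = b
    while i < n:
        score += 2 if (seq[i] == seq[i - period] and seq[i] != "N") else -mismatch_penalty
        i += 1
        if score > best:
            best, best_b = score, i
        elif best - score > xdrop:
            break
    # left
    a = start
    score = best = 0
    best_a = a
    i = a - 1
    while i >= 0 and i + period < n:
        score += 2 if (seq[i] == seq[i + period] and seq[i] != "N") else -mismatch_penalty
        if score > best:
            best, best_a = score, i
        elif best - score > xdrop:
            break
        i -= 1
    return best_a, best_b


def _best_subsegment(
    seq: str, a: int, b: int, period: int, consensus: str, match: int, mismatch: int
) -> tuple[int, int]:
    """Maximum-scoring contiguous subsegment of [a, b) scored against the
    period consensus (Kadane), with ties to the leftmost-longest segment."""
    best_score = cur = 0
    best = (a, a)
    cur_start = a
    for idx in range(a, b):
        pt = match if seq[idx] == consensus[(idx - a) % period] else -mismatch
        if cur <= 0:
            cur = pt
            cur_start = idx
        else:
            cur += pt
        if cur > best_score:
            best_score = cur
            best = (cur_start, idx + 1)
    return best


def _consensus(seq: str, a: int, b: int, period: int) -> str:
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for idx in range(a, b):
        c = cols[(idx - a) % period]
        c[seq[idx]] = c.get(seq[idx], 0) + 1
    return "".join(
        max(sorted(c), key=lambda base: c[base]) if c else "N" for c in cols
    )


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def classify_repeats(
    items: list,
    plastome: AnnotatedPlastome,
    part,
    length_bins: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90),
) -> dict:
    """Counts of repeat hits / SSR loci by {LSC,SSC,IR} x region class and by
    length bin.

    Accepts ``RepeatHit`` (classified at its first occurrence) and
    ``SSRLocus`` items.  Length bins are half-open [b, next_b) with a final
    open-ended ``90+`` bin.
    """
    by_region: dict[tuple[str, str], int] = {}
    by_bin: dict[str, int] = {}
    annotated = []
    for item in items:
        if isinstance(item, RepeatHit):
            interval = (item.pos1, item.pos1 + item.length)
        else:
            interval = (item.start, item.end)
        length = interval[1] - interval[0]
        rclass = classify_interval(plastome, interval)
        region = region_label(part, interval)
        key = (region, rclass)
        by_region[key] = by_region.get(key, 0) + 1
        label = _bin_label(length, length_bins)
        by_bin[label] = by_bin.get(label, 0) + 1
        if isinstance(item, SSRLocus):
            annotated.append(
                SSRLocus(
                    motif=item.motif,
                    unit_len=item.unit_len,
                    repeats=item.repeats,
                    start=item.start,
                    region=region,
                    region_class=rclass,
                )
            )
        else:
            annotated.append(item)
    return {"by_region": by_region, "by_length": by_bin, "items": annotated}


def _bin_label(length: int, bins: tuple[int, ...]) -> str:
    for lo, hi in zip(bins, bins[1:]):
        if lo <= length < hi:
            return f"{lo}-{hi - 1}"
    if length >= bins[-1]:
        return f"{bins[-1]}+"
    return f"<{bins[0]}"


def mask_second_ir(sequence: str, part) -> str:
    """Replace the IRa copy with N so repeat scans see one IR copy only."""
    s, e = part.ira
    return sequence[:s] + "N" * (e - s) + sequence[e:]
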