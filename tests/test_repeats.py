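"""Dispersed repeats, SSRs, compound SSRs, tandem repeats, classification."""

import random

import pytest

from plastokit.records import complement, reverse_complement
from plastokit.repeats import (
    SSRLocus,
    brute_force_dispersed,
    classify_repeats,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    mask_second_ir,
    merge_compound_ssrs,
)


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _plant(s, pos, block):
    return s[:pos] + block + s[pos + len(block):]


class TestDispersed:
    def test_forward_pair_found(self):
        rng = random.Random(0)
        block = _random_seq(rng, 30)
        s = _plant(_plant(_random_seq(rng, 600), 50, block), 400, block)
        hits = find_dispersed_repeats(s)
        f = [h for h in hits if h.type == "F"]
        assert any(
            h.pos1 <= 50 and h.pos2 <= 400 and h.pos1 + h.length >= 80 for h in f
        )
        # the same offset pair: occurrence offsets agree with the planting
        best = max(f, key=lambda h: h.length)
        assert best.pos2 - best.pos1 == 350

    def test_palindromic_pair_found(self):
        rng = random.Random(1)
        block = _random_seq(rng, 30)
        s = _plant(
            _plant(_random_seq(rng, 600), 50, block), 400, reverse_complement(block)
        )
        assert any(h.type == "P" for h in find_dispersed_repeats(s))

    def test_hamming_budget_boundary(self):
        rng = random.Random(2)
        background = _random_seq(rng, 600)
        block = _random_seq(rng, 30)

        def with_mismatches(k):
            mutated = list(block)
            for pos in [3, 11, 19, 27][:k]:
                mutated[pos] = next(b for b in "ACGT" if b != mutated[pos])
            s = _plant(_plant(background, 20, block), 400, "".join(mutated))
            return [
                h
                for h in find_dispersed_repeats(s)
                if h.type == "F" and 380 <= h.pos2 <= 420
            ]

        hits3 = with_mismatches(3)
        covering = [h for h in hits3 if h.pos1 <= 20 and h.pos1 + h.length >= 50]
        assert covering and all(h.mismatches <= 3 for h in covering)
        # 4 mismatches: no single hit covers the whole planted block
        hits4 = with_mismatches(4)
        assert not [h for h in hits4 if h.pos1 <= 20 and h.pos1 + h.length >= 50]

    def test_min_len_below_seed_rejected(self):
        with pytest.raises(ValueError):
            find_dispersed_repeats("ACGT" * 100, min_len=7)

    def test_oracle_equivalence_sample(self):
        """Seeded scan equals brute-force enumeration on planted sequences."""
        rng = random.Random(3)
        for _ in range(10):
            n = rng.randrange(300, 900)
            s = _random_seq(rng, n)
            block = _random_seq(rng, rng.randrange(30, 50))
            i1, i2 = sorted(rng.sample(range(0, n - 60), 2))
            if i2 - i1 > len(block) + 5:
                s = _plant(_plant(s, i1, block), i2, reverse_complement(block))
            assert set(find_dispersed_repeats(s, cap_per_type=10**9)) == (
                brute_force_dispersed(s)
            )

    def test_min_len_monotonicity(self):
        rng = random.Random(4)
        s = _random_seq(rng, 1500)
        block = _random_seq(rng, 60)
        s = _plant(_plant(s, 100, block), 900, block)
        counts = [
            len(find_dispersed_repeats(s, min_len=m, cap_per_type=10**9))
            for m in (30, 40, 50, 61)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_determinism(self):
        rng = random.Random(5)
        s = _random_seq(rng, 2000)
        block = _random_seq(rng, 40)
        s = _plant(_plant(s, 100, block), 1500, block)
        assert find_dispersed_repeats(s) == find_dispersed_repeats(s)


class TestSSR:
    @pytest.mark.parametrize(
        "seq,motif,repeats,found",
        [
            ("G" * 20 + "A" * 10 + "C" * 20, "A", 10, True),
            ("G" * 20 + "A" * 9 + "C" * 20, "A", 9, False),
            ("G" * 20 + "AT" * 5 + "C" * 20, "AT", 5, True),
            ("G" * 20 + "AT" * 4 + "C" * 20, "AT", 4, False),
            ("G" * 20 + "ACT" * 4 + "G" * 20, "ACT", 4, True),
            ("T" * 20 + "ACGT" * 3 + "G" * 20, "ACGT", 3, True),
            ("G" * 20 + "ACGTA" * 3 + "C" * 20, "ACGTA", 3, True),
            ("G" * 20 + "ACGTAT" * 3 + "C" * 20, "ACGTAT", 3, True),
        ],
    )
    def test_threshold_boundaries(self, seq, motif, repeats, found):
        loci = [s for s in find_ssrs(seq) if s.motif == motif]
        if found:
            assert len(loci) == 1 and loci[0].repeats == repeats
        else:
            assert not loci

    def test_non_primitive_motif_reported_as_shortest_unit(self):
        seq = "G" * 5 + "AT" * 6 + "C" * 5  # flanks below the mono threshold
        loci = find_ssrs(seq)
        assert [(s.motif, s.repeats) for s in loci] == [("AT", 6)]

    def test_runs_broken_at_n(self):
        seq = "C" * 20 + "A" * 6 + "N" + "A" * 6 + "C" * 20
        assert not [s for s in find_ssrs(seq) if s.motif == "A"]

    def test_maximality_and_primitivity_against_enumerator(self):
        """Every reported locus is maximal and primitive; enumeration of all
        unit lengths on random sequences finds no missed locus."""
        rng = random.Random(6)
        thresholds = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
        for _ in range(20):
            # AT-rich composition so runs actually occur
            seq = "".join(rng.choice("AATTACGT") for _ in range(2000))
            found = {(s.motif, s.repeats, s.start) for s in find_ssrs(seq)}
            expected = set()
            for p, minrep in thresholds.items():
                for start in range(len(seq) - p * minrep + 1):
                    motif = seq[start : start + p]
                    if "N" in motif:
                        continue
                    # primitive?
                    if any(
                        p % q == 0 and motif == motif[:q] * (p // q)
                        for q in range(1, p)
                    ):
                        continue
                    # maximal run at this start?
                    if start >= p and seq[start - p : start] == motif:
                        continue  # not leftmost
                    if start >= 1 and seq[start - 1] == seq[start + p - 1]:
                        continue  # period extends left by one base
                    reps = 1
                    while seq[
                        start + reps * p : start + (reps + 1) * p
                    ] == motif:
                        reps += 1
                    if reps >= minrep:
                        expected.add((motif, reps, start))
            assert found == expected

    def test_threshold_monotonicity(self):
        rng = random.Random(7)
        seq = "".join(rng.choice("AATTACGT") for _ in range(3000))
        base = len(find_ssrs(seq))
        stricter = len(find_ssrs(seq, thresholds={1: 11, 2: 6, 3: 5, 4: 4, 5: 4, 6: 4}))
        assert stricter <= base


class TestCompound:
    def _mk(self, starts_units):
        return [
            SSRLocus(motif=m, unit_len=len(m), repeats=r, start=s)
            for s, m, r in starts_units
        ]

    def test_gap_at_limit_merges(self):
        a = self._mk([(0, "A", 10), (110, "AT", 5)])  # gap = 110 - 10 = 100
        comps = merge_compound_ssrs(a, max_gap=100)
        assert len(comps) == 1 and len(comps[0].members) == 2
        assert comps[0].gaps == [100]

    def test_gap_over_limit_does_not_merge(self):
        a = self._mk([(0, "A", 10), (111, "AT", 5)])  # gap = 101
        assert merge_compound_ssrs(a, max_gap=100) == []

    def test_six_member_chain(self):
        starts = [(i * 60, "A", 10) for i in range(6)]  # gaps of 50
        comps = merge_compound_ssrs(self._mk(starts), max_gap=100)
        assert len(comps) == 1 and len(comps[0].members) == 6


class TestTandem:
    def test_pure_run_scores_two_per_base(self):
        s = "T" * 60 + "ACG" * 30 + "G" * 60
        reps = [t for t in find_tandem_repeats(s) if t.period == 3]
        assert reps
        assert max(t.score for t in reps) == 180

    def test_just_under_score_cut_not_reported(self):
        s = "T" * 60 + "ACG" * 13 + "G" * 60
        assert not [t for t in find_tandem_repeats(s) if t.period == 3]

    def test_random_sequences_have_no_long_period_repeats(self):
        for seed in range(20):
            rng = random.Random(100 + seed)
            s = _random_seq(rng, 10_000)
            hits = [t for t in find_tandem_repeats(s) if t.period >= 3]
            assert hits == []


class TestClassification:
    def test_planted_region_counts(self, small_plastome):
        from plastokit.quadripartite import canonicalize

        plastome, truth = small_plastome
        rotated, part = canonicalize(plastome, min_len=4000)
        # the generator plants SSRs between genes (IGS) in LSC/SSC
        loci = find_ssrs(mask_second_ir(rotated.sequence, part))
        annotated = classify_repeats(loci, rotated, part)
        items = annotated["items"]
        planted = {(m, r) for m, r, _ in truth.ssr_coords}
        got = {(s.motif, s.repeats): s for s in items}
        for m, r in planted:
            assert (m, r) in got
            assert got[(m, r)].region in ("LSC", "SSC")
            assert got[(m, r)].region_class == "IGS"

    def test_masking_silences_ira_copy(self, small_plastome):
        from plastokit.quadripartite import canonicalize

        plastome, _ = small_plastome
        rotated, part = canonicalize(plastome, min_len=4000)
        masked = mask_second_ir(rotated.sequence, part)
        s, e = part.ira
        assert set(masked[s:e]) == {"N"}
        assert masked[:s] == rotated.sequence[:s]
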