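"""Locus extraction, alignment, the variability statistic, and hotspot calls."""

import random

import pytest

from plastokit.hotspots import (
    LocusAlignment,
    align_locus,
    classify_hotspots,
    extract_homologous_loci,
    variability,
    variability_table,
)
from plastokit.records import AnnotatedPlastome, GeneFeature


def _score_alignment(rows, match=1, mismatch=-1, gap_open=4, gap_extend=1):
    """Score a pairwise alignment under the module's affine-gap model."""
    a, b = rows
    score = 0.0
    in_gap = False
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            score -= gap_extend
            if not in_gap:
                score -= gap_open
            in_gap = True
        else:
            in_gap = False
            score += match if ca == cb else mismatch
    return score


def _optimal_score(a, b, match=1, mismatch=-1, gap_open=4, gap_extend=1):
    """Exhaustive affine-gap global alignment score by DP over (i, j, state)."""
    from functools import lru_cache
    import math

    @lru_cache(maxsize=None)
    def f(i, j, state):  # state: 0 diagonal, 1 gap in b, 2 gap in a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + f(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend + (gap_open if state != 1 else 0)
            options.append(-cost + f(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend + (gap_open if state != 2 else 0)
            options.append(-cost + f(i, j + 1, 2))
        return max(options) if options else -math.inf

    return f(0, 0, 0)


class TestAlign:
    def test_identical_sequences_align_gapless(self):
        aln = align_locus(["ACGTACGT", "ACGTACGT", "ACGTACGT"])
        assert aln.rows == ["ACGTACGT"] * 3

    def test_pairwise_matches_exhaustive_dp_oracle(self):
        rng = random.Random(0)
        for _ in range(15):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randrange(5, 14)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randrange(5, 14)))
            aln = align_locus([a, b])
            assert _score_alignment(aln.rows) == pytest.approx(_optimal_score(a, b))

    def test_single_gap_run_example(self):
        aln = align_locus(["ACGTACGT", "ACGCGA"])
        gaps = [c for c in range(aln.length) if "-" in {r[c] for r in aln.rows}]
        # exactly one run of 2 gap columns under the default penalties
        assert len(gaps) == 2 and gaps[1] == gaps[0] + 1

    def test_three_sequences_one_deletion(self):
        base = "ACGTTGCAACGT"
        aln = align_locus([base, base, base[:4] + base[6:]])
        assert aln.length == len(base)
        assert aln.rows[0] == base and aln.rows[1] == base
        assert aln.rows[2].count("-") == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_locus(["ACGT", ""])


class TestVariability:
    def test_identical_rows_zero(self):
        aln = LocusAlignment("x", "coding", ["a", "b"], ["ACGT", "ACGT"])
        assert variability(aln).percent == 0.0

    def test_hand_derived_example(self):
        # 8 columns, 1 substitution column, one 2-column gap run:
        # (1 + 1) / (8 - 2 + 1) * 100 = 28.5714...
        aln = LocusAlignment("x", "coding", ["a", "b"], ["ACGTACGT", "ACCT--GT"])
        r = variability(aln)
        assert r.substitutions == 1
        assert r.indel_events == 1
        assert r.indel_length == 2
        assert r.percent == pytest.approx(200 / 7)

    def test_all_polymorphic_gapless_is_100(self):
        aln = LocusAlignment("x", "coding", ["a", "b"], ["AAAA", "CCCC"])
        assert variability(aln).percent == 100.0

    def test_gap_column_with_mismatch_not_double_counted(self):
        # column 2 has a gap in one row and differing bases in the others:
        # charged to the indel run only
        aln = LocusAlignment(
            "x", "coding", ["a", "b", "c"], ["ACGT", "AC-T", "AGGT"]
        )
        r = variability(aln)
        assert r.indel_events == 1 and r.indel_length == 1
        assert r.substitutions == 1  # column 1 (C vs C vs G)

    def test_n_matches_everything(self):
        aln = LocusAlignment("x", "coding", ["a", "b"], ["ANGT", "ACGT"])
        assert variability(aln).substitutions == 0

    def test_row_reordering_and_duplication_invariance(self):
        rows = ["ACGTAC-T", "ACCTAAGT", "AC-TAAGT"]
        base = variability(
            LocusAlignment("x", "coding", ["a", "b", "c"], rows)
        ).percent
        shuffled = variability(
            LocusAlignment("x", "coding", ["c", "a", "b"], rows[::-1])
        ).percent
        duplicated = variability(
            LocusAlignment("x", "coding", list("abcd"), rows + [rows[0]])
        ).percent
        assert base == shuffled == duplicated

    def test_no_gap_reduces_to_substitution_fraction(self):
        rows = ["ACGTACGT", "ACATACGA"]
        r = variability(LocusAlignment("x", "coding", ["a", "b"], rows))
        assert r.percent == pytest.approx(100 * 2 / 8)

    def test_binomial_recovery_no_indels(self):
        """Pairs diverged at per-site rate p give percent near 100p."""
        rng = random.Random(42)
        p = 0.1
        L = 2000
        percents = []
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(L))
            b = "".join(
                (rng.choice([x for x in "ACGT" if x != c]) if rng.random() < p else c)
                for c in a
            )
            r = variability(LocusAlignment("x", "coding", ["a", "b"], [a, b]))
            percents.append(r.percent)
        mean = sum(percents) / len(percents)
        se = (p * (1 - p) / L) ** 0.5 * 100 / len(percents) ** 0.5
        assert abs(mean - 100 * p) < 3 * max(se, 0.05)


class TestHotspots:
    @pytest.mark.parametrize(
        "locus_class,percent,expected",
        [
            ("coding", 50.0, False),   # strict inequality at the cut
            ("coding", 55.0, True),
            ("non-coding", 80.0, False),
            ("non-coding", 100.0, True),
        ],
    )
    def test_cutoffs(self, locus_class, percent, expected):
        from plastokit.hotspots import VariabilityRecord

        rec = VariabilityRecord("x", locus_class, 0, 0, 0, 100, percent)
        assert classify_hotspots([rec])[0].hotspot is expected


def _mini_genomes():
    """Two tiny genomes sharing genes X and Y with a spacer between."""
    rng = random.Random(9)
    gene_x = "ATGGCTGCTGCTGCAGCAGCTGCTTAA"
    gene_y = "ATGTTTGGGCCCAAATTTGGGTAA"
    spacer1 = "".join(rng.choice("ACGT") for _ in range(60))
    spacer2 = spacer1[:20] + "TT" + spacer1[25:]  # small planted indel + edit
    head = "".join(rng.choice("ACGT") for _ in range(30))
    tail = "".join(rng.choice("ACGT") for _ in range(30))

    def build(name, spacer):
        seq = head + gene_x + spacer + gene_y + tail
        feats = [
            GeneFeature("geneX", "CDS", "+", [(30, 30 + len(gene_x))]),
            GeneFeature(
                "geneY",
                "CDS",
                "+",
                [(30 + len(gene_x) + len(spacer), 30 + len(gene_x) + len(spacer) + len(gene_y))],
            ),
        ]
        return AnnotatedPlastome(id=name, sequence=seq, features=feats)

    return build("g1", spacer1), build("g2", spacer2)


class TestExtraction:
    def test_shared_genes_and_spacer(self):
        g1, g2 = _mini_genomes()
        loci = extract_homologous_loci([g1, g2])
        names = {l.name for l in loci}
        assert {"genex", "geney", "genex-geney"} <= names
        spacer = next(l for l in loci if l.name == "genex-geney")
        assert spacer.locus_class == "non-coding"
        assert len(spacer.seqs) == 2

    def test_no_shared_genes_warns_empty(self):
        g1, _ = _mini_genomes()
        other = AnnotatedPlastome(
            id="o",
            sequence="ACGT" * 50,
            features=[GeneFeature("zzz", "CDS", "+", [(0, 30)])],
        )
        assert extract_homologous_loci([g1, other]) == []

    def test_inverted_adjacency_spacer_skipped(self):
        g1, g2 = _mini_genomes()
        # swap gene order in g2's annotation: adjacency (X, Y) no longer holds
        f1, f2 = g2.features
        g2.features = [
            GeneFeature("geneY", "CDS", "+", f1.parts),
            GeneFeature("geneX", "CDS", "+", f2.parts),
        ]
        loci = extract_homologous_loci([g1, g2])
        assert "genex-geney" not in {l.name for l in loci}

    def test_variability_table_end_to_end(self):
        g1, g2 = _mini_genomes()
        records = variability_table(extract_homologous_loci([g1, g2]))
        by_name = {r.locus: r for r in records}
        assert by_name["genex"].percent == 0.0
        assert by_name["genex-geney"].percent > 0.0


class TestSignRecovery:
    def test_noncoding_exceeds_coding_on_asymmetric_rates(self, evolved_pair):
        """Spacers evolved 5x faster than genes show higher mean variability."""
        genomes, _ = evolved_pair
        plastomes = list(genomes.values())
        records = variability_table(extract_homologous_loci(plastomes))
        coding = [r.percent for r in records if r.locus_class == "coding"]
        noncoding = [r.percent for r in records if r.locus_class == "non-coding"]
        assert coding and noncoding
        assert sum(noncoding) / len(noncoding) > sum(coding) / len(coding)
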