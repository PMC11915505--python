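import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmrna_curator.core import GeneForm, RejectReason, Thresholds, revcomp
from tmrna_curator.hits import (
    CandidateHit,
    ParseError,
    ToolKind,
    TrnaHit,
    designate_strength,
    extract_region,
    filter_contig_end_truncation,
    filter_intron_phase3,
    filter_trna_overlap,
    parse_hits,
    phase2_candidates,
)


def _hit(tool=ToolKind.ARAGORN, score=110.0, start=1000, end=1400, **kw):
    kw.setdefault("contig", "c1")
    kw.setdefault("strand", "+")
    return CandidateHit(tool=tool, score=score, start=start, end=end, **kw)


class TestParsers:
    def test_tblout_reversed_coordinates(self):
        row = "c9 - tmRNA RF00023 cm 1 350 300 120 - no 1 0.50 0.0 151.2 1e-12 ! -"
        (hit,) = parse_hits(row, "infernal_tblout")
        assert (hit.start, hit.end, hit.strand) == (120, 300, "-")
        assert hit.score == pytest.approx(151.2)
        assert hit.tool is ToolKind.INFERNAL

    def test_blast6_bitscore_column(self):
        row = "q1\tc2\t97.0\t350\t10\t0\t1\t350\t5000\t5349\t1e-80\t312.4"
        (hit,) = parse_hits(row, "blast_tab6")
        assert hit.tool is ToolKind.RFIND_BLAST
        assert hit.score == pytest.approx(312.4)
        assert (hit.start, hit.end, hit.strand) == (5000, 5349, "+")

    def test_blast6_minus_strand(self):
        row = "q1\tc2\t97.0\t350\t10\t0\t1\t350\t5349\t5000\t1e-80\t300"
        (hit,) = parse_hits(row, "blast_tab6")
        assert (hit.start, hit.end, hit.strand) == (5000, 5349, "-")

    def test_trnascan_header_skipped(self):
        text = (
            "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
            "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
            "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\n"
            "c1\t1\t900\t828\tAla\tTGC\t0\t0\t77.3\n"
        )
        (trna,) = parse_hits(text, "trnascan_tab")
        assert isinstance(trna, TrnaHit)
        assert (trna.start, trna.end, trna.strand) == (828, 900, "-")

    def test_empty_file(self):
        assert parse_hits("", "infernal_tblout") == []

    def test_comments_skipped(self):
        assert parse_hits("# a comment\n\n", "aragorn") == []

    def test_unknown_dialect(self):
        with pytest.raises(ParseError, match="dialect"):
            parse_hits("", "glimmer")

    def test_unparseable_row_reports_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_hits("# ok\nnot a row\n", "blast_tab6")


class TestStrength:
    @pytest.mark.parametrize(
        "tool,score,expect",
        [
            (ToolKind.ARAGORN, 104, "S"),
            (ToolKind.ARAGORN, 103, "W"),
            (ToolKind.INFERNAL, 140.0, "W"),
            (ToolKind.INFERNAL, 140.1, "S"),
            (ToolKind.RFIND_BLAST, 90.5, "S"),
            (ToolKind.RFIND_BLAST, 90.0, "W"),
        ],
    )
    def test_boundaries(self, tool, score, expect, thresholds):
        hit = _hit(tool=tool, score=score)
        assert designate_strength(hit, thresholds) == expect
        assert hit.strength == expect

    @given(st.floats(0, 500, allow_nan=False), st.floats(0, 500, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_score(self, a, b):
        lo, hi = sorted((a, b))
        s_lo = designate_strength(_hit(score=lo))
        s_hi = designate_strength(_hit(score=hi))
        assert not (s_lo == "S" and s_hi == "W")


class TestExtractRegion:
    GENOME = {"c1": "".join("ACGT"[(i * 7) % 4] for i in range(10000))}

    def test_flanked_interval(self):
        hit = _hit(start=1000, end=1500)
        region = extract_region(hit, self.GENOME, flank_bp=250)
        assert (region.start, region.end) == (749, 1750)
        assert region.sequence == self.GENOME["c1"][749:1750]

    def test_left_clip(self):
        hit = _hit(start=100, end=400)
        region = extract_region(hit, self.GENOME, flank_bp=250)
        assert region.start == 0

    def test_minus_strand_revcomp(self):
        hit = _hit(start=1000, end=1500, strand="-")
        region = extract_region(hit, self.GENOME, flank_bp=250)
        assert region.sequence == revcomp(self.GENOME["c1"][749:1750])

    def test_missing_contig(self):
        with pytest.raises(KeyError):
            extract_region(_hit(contig="nope"), self.GENOME)

    @pytest.mark.parametrize("strand", "+-")
    def test_backmapping_identity(self, strand):
        hit = _hit(start=1000, end=1500, strand=strand)
        region = extract_region(hit, self.GENOME, flank_bp=100)
        contig = self.GENOME["c1"]
        for pos in range(0, region.end - region.start, 37):
            c = region.to_contig(pos)
            base = contig[c - 1]
            expect = region.sequence[pos] if strand == "+" else revcomp(region.sequence[pos])
            assert base == expect


class TestTrnaOverlap:
    def _trna(self, start, end, score, contig="c1"):
        return TrnaHit(contig=contig, start=start, end=end, strand="+", score=score)

    def test_reject_over_both_cutoffs(self, thresholds):
        hit = _hit(start=100, end=200, form_guess=GeneForm.STANDARD)
        trna = self._trna(195, 260, 43.0)  # overlap 6
        assert filter_trna_overlap(hit, [trna], thresholds) is RejectReason.TRNA_OVERLAP

    def test_overlap_exactly_five_kept(self, thresholds):
        hit = _hit(start=100, end=200)
        trna = self._trna(196, 260, 100.0)  # overlap 5
        assert filter_trna_overlap(hit, [trna], thresholds) is None

    def test_score_exactly_42_kept(self, thresholds):
        hit = _hit(start=100, end=200)
        trna = self._trna(100, 200, 42.0)
        assert filter_trna_overlap(hit, [trna], thresholds) is None

    def test_permuted_strong_exception(self, thresholds):
        hit = _hit(start=100, end=200, form_guess=GeneForm.PERMUTED, score=120)
        designate_strength(hit, thresholds)
        assert hit.strength == "S"
        trna = self._trna(141, 260, 80.0)  # overlap 60
        assert filter_trna_overlap(hit, [trna], thresholds) is None

    def test_permuted_weak_not_exempt(self, thresholds):
        hit = _hit(start=100, end=200, form_guess=GeneForm.PERMUTED, score=50)
        designate_strength(hit, thresholds)
        trna = self._trna(141, 260, 80.0)
        assert filter_trna_overlap(hit, [trna], thresholds) is RejectReason.TRNA_OVERLAP

    def test_other_contig_ignored(self, thresholds):
        hit = _hit(start=100, end=200)
        trna = self._trna(100, 200, 99.0, contig="elsewhere")
        assert filter_trna_overlap(hit, [trna], thresholds) is None

    def test_invariant_under_trna_reordering(self, thresholds):
        hit = _hit(start=100, end=200)
        trnas = [self._trna(10, 90, 99.0), self._trna(190, 260, 50.0), self._trna(150, 160, 30.0)]
        a = filter_trna_overlap(hit, trnas, thresholds)
        b = filter_trna_overlap(hit, list(reversed(trnas)), thresholds)
        assert a == b == RejectReason.TRNA_OVERLAP


class TestTruncation:
    def test_rfind_only_truncated_rejected(self):
        hit = _hit(tool=ToolKind.RFIND_BLAST, start=9000, end=9500, contig_length=9500)
        out = filter_contig_end_truncation(hit, (9000, 9530))
        assert out is RejectReason.CONTIG_END_TRUNCATION

    def test_corroborated_by_aragorn_kept(self):
        hits = [
            _hit(tool=ToolKind.RFIND_BLAST, start=9000, end=9500, contig_length=9500),
            _hit(tool=ToolKind.ARAGORN, start=9000, end=9500, contig_length=9500),
        ]
        assert filter_contig_end_truncation(hits, (9000, 9530)) is None

    def test_internal_rfind_only_kept(self):
        hit = _hit(tool=ToolKind.RFIND_BLAST, start=1000, end=1400, contig_length=9500)
        assert filter_contig_end_truncation(hit, (1000, 1400)) is None

    def test_truncated_at_contig_start(self):
        hit = _hit(tool=ToolKind.RFIND_BLAST, start=1, end=300, contig_length=9500)
        out = filter_contig_end_truncation(hit, (-20, 300))
        assert out is RejectReason.CONTIG_END_TRUNCATION


class TestIntronPhase3:
    @pytest.mark.parametrize(
        "length,bits,keep",
        [
            (545, 225.3, True),
            (500, 150.0, True),  # inclusive boundaries
            (499, 300.0, False),
            (600, 149.0, False),
            (499, 149.0, False),
        ],
    )
    def test_cutoffs(self, length, bits, keep, thresholds):
        hit = _hit(tool=ToolKind.INFERNAL, score=bits, start=1000, end=1000 + length - 1)
        out = filter_intron_phase3(hit, thresholds)
        assert (out is None) == keep


class TestPhase2:
    NESTING = {"genusA": "familyF", "genusB": "familyF", "familyF": "phylumP"}

    def test_selection_rule(self):
        stats = {"t40": (40, 10), "t25": (25, 13)}
        out = phase2_candidates(
            stats, {}, {"g1": "t40", "g2": "t25"}, set(),
            {"g1": [_hit(score=10)], "g2": [_hit(score=10)]},
        )
        assert "g1" in out and "g2" not in out  # 75% vs 48% failed

    def test_nested_taxon_suppressed(self):
        stats = {"genusA": (30, 5), "familyF": (60, 10)}
        genome_taxon = {f"g{i}": "genusA" for i in range(3)}
        hits = {g: [_hit(score=i)] for i, g in enumerate(genome_taxon)}
        out = phase2_candidates(stats, self.NESTING, genome_taxon, set(), hits)
        # genomes selected through familyF (genusA is nested inside it)
        assert set(out) == set(genome_taxon)

    def test_one_hit_per_genome_is_best(self):
        stats = {"t": (40, 0)}
        hits = {"g": [_hit(score=5.0), _hit(score=50.0), _hit(score=20.0)]}
        out = phase2_candidates(stats, {}, {"g": "t"}, set(), hits)
        assert out["g"].score == 50.0

    def test_identified_genomes_skipped(self):
        stats = {"t": (40, 0)}
        out = phase2_candidates(
            stats, {}, {"g": "t"}, {"g"}, {"g": [_hit(score=5.0)]}
        )
        assert out == {}

    def test_cyclic_nesting_errors(self):
        stats = {"a": (40, 0)}
        with pytest.raises(ValueError, match="cyclic"):
            phase2_candidates(
                stats, {"a": "b", "b": "a"}, {"g": "a"}, set(), {"g": [_hit()]}
            )

    def test_alternate_interpretation_config(self):
        # 22 genomes, 12 failed (54.5%): fails the 20-failed rule,
        # passes the 20-total rule
        stats = {"t": (22, 10)}
        args = (stats, {}, {"g": "t"}, set(), {"g": [_hit(score=5.0)]})
        assert phase2_candidates(*args) == {}
        assert "g" in phase2_candidates(*args, count_total_genomes=True)
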