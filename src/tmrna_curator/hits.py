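"""Hit-table ingestion and phase 1-3 rejection rules.

Parses candidate tables (minimal Aragorn-style tab, Infernal tblout, BLAST
tabular outfmt 6) and tRNAscan-SE v2 tabular files, designates strong/weak
hits, extracts flanked genomic regions, and applies the overlap/truncation/
intron-screen filters.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .core import GeneForm, RejectReason, Thresholds, revcomp


class ToolKind(enum.Enum):
    ARAGORN = "ARAGORN"
    INFERNAL = "INFERNAL"
    RFIND_BLAST = "RFIND_BLAST"


@dataclass
class CandidateHit:
    """One tool hit; coordinates 1-based inclusive with start <= end."""

    tool: ToolKind
    score: float
    contig: str
    start: int
    end: int
    strand: str
    form_guess: GeneForm | None = None
    strength: str | None = None  # 'S' or 'W', set by designate_strength
    contig_length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"hit {self.contig}:{self.start}-{self.end}: start > end")
        if not math.isfinite(self.score):
            raise ValueError("hit score must be finite")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TrnaHit:
    contig: str
    start: int
    end: int
    strand: str
    score: float
    isotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"tRNA hit {self.contig}: start > end")


class ParseError(ValueError):
    pass


_FORM_TOKENS = {
    "standard": GeneForm.STANDARD,
    "permuted": GeneForm.PERMUTED,
    "intron": GeneForm.INTRON,
    "standard_no_cds": GeneForm.STANDARD_NO_CDS,
    "permuted_no_cds": GeneForm.PERMUTED_NO_CDS,
}

DIALECTS = ("aragorn", "infernal_tblout", "blast_tab6", "trnascan_tab")


def _orient(a: int, b: int) -> tuple[int, int, str]:
    return (a, b, "+") if a <= b else (b, a, "-")


def parse_hits(stream, dialect: str):
    """Parse a hit table in one of the supported dialects.

    `stream` may be a string or an iterable of lines. Returns CandidateHit
    lists for the candidate dialects and TrnaHit lists for `trnascan_tab`.
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}")
    lines = stream.splitlines() if isinstance(stream, str) else list(stream)
    out: list = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if dialect == "aragorn":
                out.append(_parse_aragorn_row(line))
            elif dialect == "infernal_tblout":
                out.append(_parse_tblout_row(line))
            elif dialect == "blast_tab6":
                out.append(_parse_blast6_row(line))
            else:
                hit = _parse_trnascan_row(line)
                if hit is not None:
                    out.append(hit)
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{dialect} line {lineno}: {exc}") from exc
    return out


def _parse_aragorn_row(line: str) -> CandidateHit:
    # minimal tab dialect: contig  start  end  strand  score  form
    fields = line.split("\t")
    if len(fields) < 6:
        raise ValueError(f"expected 6 tab-separated fields, got {len(fields)}")
    contig, start, end, strand, score, form = fields[:6]
    lo, hi, _ = _orient(int(start), int(end))
    return CandidateHit(
        tool=ToolKind.ARAGORN,
        score=float(score),
        contig=contig,
        start=lo,
        end=hi,
        strand=strand,
        form_guess=_FORM_TOKENS.get(form.lower()),
    )


def _parse_tblout_row(line: str) -> CandidateHit:
    fields = line.split()
    if len(fields) < 17:
        raise ValueError(f"expected >=17 whitespace fields, got {len(fields)}")
    contig = fields[0]
    seq_from, seq_to = int(fields[7]), int(fields[8])
    lo, hi, implied = _orient(seq_from, seq_to)
    strand = fields[9] if fields[9] in "+-" else implied
    return CandidateHit(
        tool=ToolKind.INFERNAL,
        score=float(fields[14]),
        contig=contig,
        start=lo,
        end=hi,
        strand=strand,
    )


def _parse_blast6_row(line: str) -> CandidateHit:
    fields = line.split("\t")
    if len(fields) < 12:
        raise ValueError(f"expected 12 tab-separated fields, got {len(fields)}")
    sstart, send = int(fields[8]), int(fields[9])
    lo, hi, strand = _orient(sstart, send)
    return CandidateHit(
        tool=ToolKind.RFIND_BLAST,
        score=float(fields[11]),
        contig=fields[1],
        start=lo,
        end=hi,
        strand=strand,
    )


def _parse_trnascan_row(line: str) -> TrnaHit | None:
    fields = [f.strip() for f in line.split("\t")]
    # Skip the three-line header block of tRNAscan-SE tabular output.
    if len(fields) < 2 or not fields[1].strip().isdigit():
        return None
    if len(fields) < 9:
        raise ValueError(f"expected >=9 tab-separated fields, got {len(fields)}")
    begin, end = int(fields[2]), int(fields[3])
    lo, hi, strand = _orient(begin, end)
    return TrnaHit(
        contig=fields[0].strip(),
        start=lo,
        end=hi,
        strand=strand,
        score=float(fields[8]),
        isotype=fields[4],
    )


# ---------------------------------------------------------------------------
# Strength designation and region extraction

_STRONG_CUTOFF = {
    ToolKind.ARAGORN: "aragorn_strong",
    ToolKind.INFERNAL: "infernal_strong",
    ToolKind.RFIND_BLAST: "rfind_strong",
}


def designate_strength(hit: CandidateHit, t: Thresholds | None = None) -> str:
    """'S' iff the score strictly exceeds the tool's cutoff, else 'W'."""
    t = t or Thresholds()
    cutoff = getattr(t, _STRONG_CUTOFF[hit.tool])
    hit.strength = "S" if hit.score > cutoff else "W"
    return hit.strength


@dataclass
class Region:
    """Extracted (flanked, strand-oriented) genomic region."""

    sequence: str
    contig: str
    start: int  # 0-based half-open on the plus strand of the contig
    end: int
    strand: str

    def to_contig(self, pos: int) -> int:
        """Map a 0-based position in the extracted sequence to a 1-based
        contig coordinate."""
        if not 0 <= pos < self.end - self.start:
            raise IndexError(f"position {pos} outside extracted region")
        if self.strand == "+":
            return self.start + pos + 1
        return self.end - pos


def extract_region(
    hit: CandidateHit, genome: Mapping[str, str], flank_bp: int | None = None
) -> Region:
    """Extract the hit interval plus flanks, clipped at contig ends.

    Minus-strand hits are reverse-complemented so the returned sequence reads
    5'->3' along the gene.
    """
    if flank_bp is None:
        flank_bp = Thresholds().flank_bp
    if hit.contig not in genome:
        raise KeyError(f"contig {hit.contig!r} not in genome")
    contig_seq = genome[hit.contig]
    lo = max(0, hit.start - 1 - flank_bp)
    hi = min(len(contig_seq), hit.end + flank_bp)
    plus = contig_seq[lo:hi]
    seq = plus if hit.strand == "+" else revcomp(plus)
    return Region(sequence=seq, contig=hit.contig, start=lo, end=hi, strand=hit.strand)


# ---------------------------------------------------------------------------
# Rejection filters


def filter_trna_overlap(
    hit: CandidateHit, trnas: Sequence[TrnaHit], t: Thresholds | None = None
) -> RejectReason | None:
    """Reject a candidate overlapped >trna_overlap_bp by a tRNA scoring
    >trna_score, unless the form is permuted and the hit is strong.

    Overlap is computed strand-blind on contig coordinates.
    """
    t = t or Thresholds()
    permuted = hit.form_guess in (GeneForm.PERMUTED, GeneForm.PERMUTED_NO_CDS)
    if permuted and hit.strength == "S":
        return None
    for trna in trnas:
        if trna.contig != hit.contig:
            continue
        overlap = min(hit.end, trna.end) - max(hit.start, trna.start) + 1
        if overlap > t.trna_overlap_bp and trna.score > t.trna_score:
            return RejectReason.TRNA_OVERLAP
    return None


def filter_contig_end_truncation(
    hits: CandidateHit | Sequence[CandidateHit],
    mature_span: tuple[int, int] | None,
    contig_length: int | None = None,
) -> RejectReason | None:
    """Reject loci supported only by a database-BLAST hit whose expected
    mature sequence runs off a contig end.

    `mature_span` is the expected mature-sequence interval on the contig
    (1-based inclusive) from reference mapping; may extend past contig ends.
    """
    if mature_span is None:
        return None
    hit_list = [hits] if isinstance(hits, CandidateHit) else list(hits)
    if not hit_list:
        return None
    tools = {h.tool for h in hit_list}
    if tools != {ToolKind.RFIND_BLAST}:
        return None
    if contig_length is None:
        contig_length = next(
            (h.contig_length for h in hit_list if h.contig_length is not None), None
        )
    lo, hi = mature_span
    truncated = lo < 1 or (contig_length is not None and hi > contig_length)
    return RejectReason.CONTIG_END_TRUNCATION if truncated else None


def filter_intron_phase3(
    hit: CandidateHit, t: Thresholds | None = None
) -> RejectReason | None:
    """Intron-screen cutoffs: keep iff length >= intron_min_len and score
    >= intron_min_bits (both inclusive)."""
    t = t or Thresholds()
    if hit.length >= t.intron_min_len and hit.score >= t.intron_min_bits:
        return None
    return RejectReason.SIZE_SCORE_CUTOFF


# ---------------------------------------------------------------------------
# Phase 2: taxon selection and best-hit-per-genome


def _ancestors(taxon: str, nesting: Mapping[str, str]) -> list[str]:
    chain = []
    seen = {taxon}
    cur = taxon
    while cur in nesting:
        cur = nesting[cur]
        if cur in seen:
            raise ValueError(f"cyclic taxon nesting at {cur!r}")
        seen.add(cur)
        chain.append(cur)
    return chain


def phase2_candidates(
    taxon_stats: Mapping[str, tuple[int, int]],
    taxon_nesting: Mapping[str, str],
    genome_taxon: Mapping[str, str],
    identified_genomes: set[str],
    hits_per_genome: Mapping[str, Sequence[CandidateHit]],
    min_failed: int = 20,
    min_failed_fraction: float = 0.5,
    count_total_genomes: bool = False,
) -> dict[str, CandidateHit]:
    """Select under-represented taxa and return one top CM hit per genome
    still lacking an identified gene.

    `taxon_stats` maps taxon -> (genomes_total, genomes_with_gene);
    `taxon_nesting` maps each taxon to its parent. A taxon is selected when
    it has >= min_failed failed genomes (or total genomes when
    `count_total_genomes`) and a failure fraction strictly >
    `min_failed_fraction`; selected taxa nested inside other selected taxa
    are dropped.
    """
    selected = set()
    for taxon, (total, with_gene) in taxon_stats.items():
        if total <= 0:
            continue
        failed = total - with_gene
        size_ok = (total if count_total_genomes else failed) >= min_failed
        if size_ok and failed / total > min_failed_fraction:
            selected.add(taxon)
    non_nested = {
        t for t in selected if not any(a in selected for a in _ancestors(t, taxon_nesting))
    }

    out: dict[str, CandidateHit] = {}
    for genome, taxon in genome_taxon.items():
        if genome in identified_genomes:
            continue
        lineage = {taxon, *_ancestors(taxon, taxon_nesting)}
        if not (lineage & non_nested):
            continue
        genome_hits = list(hits_per_genome.get(genome, ()))
        if not genome_hits:
            continue
        out[genome] = max(genome_hits, key=lambda h: h.score)
    return out
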