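"""Core domain model.

Gene records with named segment maps, deduplication, the ``species.serial``
naming scheme, the curation funnel, and the tab-separated flat-file dialect.

Coordinate conventions: all in-memory intervals are 0-based half-open; every
serialized or parsed coordinate (flat file, hit tables, provenance) is
1-based inclusive.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

AMBIG_DNA = "RYSWKMBDHVN"
IUPAC_DNA = frozenset("ACGT" + AMBIG_DNA)
_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Segment name vocabulary
TRNA5 = "TRNA5"
TRNA3 = "TRNA3"
CDS = "CDS"
CCA = "CCA"
IVS = "IVS"
INTRON = "INTRON"
SPACER1 = "SPACER1"
SPACER2 = "SPACER2"


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and fold U onto T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet, IUPAC-aware)."""
    return normalize(seq).translate(_RC)[::-1]


class GeneForm(enum.Enum):
    STANDARD = "standard"
    PERMUTED = "permuted"
    INTRON = "intron"
    STANDARD_NO_CDS = "standard_no_cds"
    PERMUTED_NO_CDS = "permuted_no_cds"

    @property
    def has_cds(self) -> bool:
        return self in (GeneForm.STANDARD, GeneForm.PERMUTED, GeneForm.INTRON)


#: Per-form segment order. Kept as data so the (figure-derived) permuted
#: layout can be adjusted without touching code. The INTRON form splits the
#: tRNA-like-3' segment around the intron, hence TRNA3 appears twice.
FORM_SEGMENT_ORDER: dict[GeneForm, tuple[str, ...]] = {
    GeneForm.STANDARD: (TRNA5, SPACER1, CDS, SPACER2, TRNA3, CCA),
    GeneForm.INTRON: (TRNA5, SPACER1, CDS, SPACER2, TRNA3, INTRON, TRNA3, CCA),
    GeneForm.PERMUTED: (TRNA3, CCA, IVS, TRNA5, SPACER1, CDS),
    GeneForm.STANDARD_NO_CDS: (TRNA5, SPACER1, TRNA3, CCA),
    GeneForm.PERMUTED_NO_CDS: (TRNA3, CCA, IVS, TRNA5),
}


class RejectReason(enum.Enum):
    TRNA_OVERLAP = "TRNA_OVERLAP"
    CONTIG_END_TRUNCATION = "CONTIG_END_TRUNCATION"
    AMBIGUOUS_BLOCK = "AMBIGUOUS_BLOCK"
    ACCEPTOR_STEM = "ACCEPTOR_STEM"
    MISSING_CCA = "MISSING_CCA"
    TAG_ORF = "TAG_ORF"
    INTERNAL_DELETION = "INTERNAL_DELETION"
    DUPLICATE = "DUPLICATE"
    SIZE_SCORE_CUTOFF = "SIZE_SCORE_CUTOFF"


class Status(enum.Enum):
    CANDIDATE = "CANDIDATE"
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


@dataclass(frozen=True)
class Thresholds:
    """Numeric cutoffs of the curation protocol.

    Strength cutoffs are exclusive (score must strictly exceed); the intron
    screen cutoffs are inclusive.
    """

    aragorn_strong: float = 103.0
    infernal_strong: float = 140.0
    rfind_strong: float = 90.0
    trna_overlap_bp: int = 5
    trna_score: float = 42.0
    flank_bp: int = 250
    intron_min_len: int = 500
    intron_min_bits: float = 150.0
    max_ambig_block: int = 1
    max_stem_mismatch: int = 1

    def __post_init__(self) -> None:
        for name in (
            "aragorn_strong",
            "infernal_strong",
            "rfind_strong",
            "trna_overlap_bp",
            "trna_score",
            "flank_bp",
            "intron_min_len",
            "intron_min_bits",
            "max_ambig_block",
            "max_stem_mismatch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")


@dataclass(frozen=True)
class Provenance:
    """Source location of one gene instance (1-based inclusive, on contig)."""

    assembly: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}-{self.end}")

    def serialize(self) -> str:
        return f"{self.assembly}:{self.contig}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "Provenance":
        assembly, contig, span, strand = text.rsplit(":", 3)
        lo, hi = span.split("-")
        return cls(assembly, contig, int(lo), int(hi), strand)


@dataclass(frozen=True)
class Segment:
    """Named interval on a gene sequence, 0-based half-open."""

    name: str
    start: int
    end: int
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad segment interval {self.name} {self.start}:{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentMap:
    """Ordered, non-overlapping named intervals over a gene sequence."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        prev_end = 0
        for seg in self.segments:
            if seg.start < prev_end:
                raise ValueError(f"segments overlap or are out of order at {seg.name}")
            prev_end = seg.end
        for seg in self.segments:
            if seg.name == CCA and not seg.provisional and len(seg) != 3:
                raise ValueError("CCA segment must be exactly 3 positions")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def first(self, name: str) -> Segment | None:
        for seg in self.segments:
            if seg.name == name:
                return seg
        return None

    def all(self, name: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.name == name)

    def total_length(self, name: str) -> int:
        return sum(len(s) for s in self.all(name))

    @property
    def span_end(self) -> int:
        return max((s.end for s in self.segments), default=0)

    def covers_fully(self, seq_len: int) -> bool:
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                return False
            pos = seg.end
        return pos == seq_len

    def with_insertion(self, pos: int, length: int) -> "SegmentMap":
        """Shift boundaries to account for inserting `length` bases at `pos`.

        A segment strictly containing `pos` grows; segments at/after `pos`
        shift right.
        """
        if length == 0:
            return self
        out = []
        for seg in self.segments:
            if seg.end <= pos:
                out.append(seg)
            elif seg.start >= pos:
                out.append(replace(seg, start=seg.start + length, end=seg.end + length))
            else:
                out.append(replace(seg, end=seg.end + length))
        return SegmentMap(tuple(out))

    def serialize(self) -> str:
        if not self.segments:
            return "."
        parts = []
        for seg in self.segments:
            flag = "?" if seg.provisional else ""
            parts.append(f"{seg.name}:{seg.start + 1}-{seg.end}{flag}")
        return ",".join(parts)

    @classmethod
    def parse(cls, text: str) -> "SegmentMap":
        if text == ".":
            return cls(())
        segs = []
        for token in text.split(","):
            name, span = token.split(":")
            provisional = span.endswith("?")
            span = span.rstrip("?")
            lo, hi = span.split("-")
            segs.append(Segment(name, int(lo) - 1, int(hi), provisional))
        return cls(tuple(segs))


@dataclass
class GeneRecord:
    """A candidate or accepted tmRNA gene."""

    id: str
    sequence: str
    form: GeneForm
    segments: SegmentMap = field(default_factory=lambda: SegmentMap(()))
    species: str = ""
    instance_count: int = 1
    status: Status = Status.CANDIDATE
    reject_reasons: tuple[RejectReason, ...] = ()
    provenance: tuple[Provenance, ...] = ()
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.instance_count < 1:
            raise ValueError(f"record {self.id}: instance_count must be positive")
        if self.segments.span_end > len(self.sequence):
            raise ValueError(f"record {self.id}: segments exceed sequence length")
        self.reject_reasons = tuple(self.reject_reasons)
        self.provenance = tuple(self.provenance)
        if (self.status is Status.REJECTED) != bool(self.reject_reasons):
            raise ValueError(
                f"record {self.id}: REJECTED status iff reject_reasons non-empty"
            )

    @property
    def norm_sequence(self) -> str:
        return normalize(self.sequence)

    def rejected(self, *reasons: RejectReason) -> "GeneRecord":
        merged = tuple(dict.fromkeys(self.reject_reasons + reasons))
        return replace(self, status=Status.REJECTED, reject_reasons=merged)

    def accepted(self) -> "GeneRecord":
        return replace(self, status=Status.ACCEPTED, reject_reasons=())


# ---------------------------------------------------------------------------
# Deduplication and naming


def deduplicate(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Collapse records with identical (case/U-T-insensitive) sequences.

    Instance counts are summed and provenance concatenated; output is sorted
    by sequence so the result is independent of input order.
    """
    by_seq: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.norm_sequence, []).append(rec)
    out = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        first = group[0]
        merged = replace(
            first,
            instance_count=sum(r.instance_count for r in group),
            provenance=tuple(p for r in group for p in r.provenance),
        )
        out.append(merged)
    return out


def assign_names(
    records: Sequence[GeneRecord],
    species_of_instance: Mapping[Provenance, str],
) -> dict[str, str]:
    """Name each unique sequence ``<species>.<k>``.

    The species is the one contributing the most instances of the sequence;
    ``k`` ranks sequences within that species by descending instance count.
    Ties are broken by lexicographic sequence, then species label.
    """
    chosen: dict[str, tuple[str, int, str]] = {}  # record id -> (species, count, seq)
    for rec in records:
        if not rec.provenance:
            raise ValueError(f"record {rec.id}: no instances to derive species from")
        counts: Counter[str] = Counter()
        for prov in rec.provenance:
            if prov not in species_of_instance:
                raise ValueError(
                    f"record {rec.id}: instance {prov.serialize()} has no species label"
                )
            counts[species_of_instance[prov]] += 1
        # most frequent species; tie -> lexicographically smallest label
        top = max(counts.values())
        species = min(s for s, c in counts.items() if c == top)
        chosen[rec.id] = (species, rec.instance_count, rec.norm_sequence)

    per_species: dict[str, list[tuple[int, str, str]]] = {}
    for rid, (species, count, seq) in chosen.items():
        per_species.setdefault(species, []).append((count, seq, rid))
    names: dict[str, str] = {}
    for species, entries in per_species.items():
        entries.sort(key=lambda t: (-t[0], t[1], t[2]))
        for k, (_, _, rid) in enumerate(entries, start=1):
            names[rid] = f"{species}.{k}"
    return names


# ---------------------------------------------------------------------------
# Curation funnel


@dataclass
class CandidateBundle:
    """One candidate locus: its hits, extracted record and contig context."""

    record: GeneRecord
    hits: list = field(default_factory=list)  # list[hits.CandidateHit]
    mature_span: tuple[int, int] | None = None  # 1-based inclusive, contig coords
    contig_length: int | None = None


FUNNEL_STAGES = (
    "hits",
    "after_skip_identical",
    "after_trna_rejection",
    "after_deduplication",
    "after_truncation_rejection",
    "after_qc",
)


@dataclass
class FunnelReport:
    stages: tuple[tuple[str, int], ...]
    accepted: list[GeneRecord]
    rejected: list[GeneRecord]

    def counts(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.stages)


def curate_funnel(
    bundles: Sequence[CandidateBundle],
    trna_annotations: Sequence,
    references: Sequence[GeneRecord],
    config: Thresholds | None = None,
) -> FunnelReport:
    """Run the batch curation funnel and report per-stage survivor counts.

    Stages, in order: all hits; skipping candidates identical to existing
    reference sequences; rejecting likely tRNAs; deduplication; rejecting
    contig-end truncations; automated QC.
    """
    from . import hits as hits_mod
    from . import qc as qc_mod

    config = config or Thresholds()
    counts: list[tuple[str, int]] = [("hits", len(bundles))]
    rejected: list[GeneRecord] = []

    ref_seqs = {r.norm_sequence for r in references}
    live: list[CandidateBundle] = []
    for b in bundles:
        if b.record.norm_sequence in ref_seqs:
            rejected.append(b.record.rejected(RejectReason.DUPLICATE))
        else:
            live.append(b)
    counts.append(("after_skip_identical", len(live)))

    survivors = []
    for b in live:
        dropped = False
        for hit in b.hits:
            if hits_mod.filter_trna_overlap(hit, trna_annotations, config) is not None:
                dropped = True
                break
        if dropped:
            rejected.append(b.record.rejected(RejectReason.TRNA_OVERLAP))
        else:
            survivors.append(b)
    live = survivors
    counts.append(("after_trna_rejection", len(live)))

    # Deduplicate records while carrying bundle context along.
    by_seq: dict[str, list[CandidateBundle]] = {}
    for b in live:
        by_seq.setdefault(b.record.norm_sequence, []).append(b)
    merged: list[CandidateBundle] = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        rec = deduplicate([b.record for b in group])[0]
        merged.append(
            CandidateBundle(
                record=rec,
                hits=[h for b in group for h in b.hits],
                mature_span=group[0].mature_span,
                contig_length=group[0].contig_length,
            )
        )
    live = merged
    counts.append(("after_deduplication", len(live)))

    survivors = []
    for b in live:
        reason = hits_mod.filter_contig_end_truncation(
            b.hits, b.mature_span, contig_length=b.contig_length
        )
        if reason is not None:
            rejected.append(b.record.rejected(reason))
        else:
            survivors.append(b)
    live = survivors
    counts.append(("after_truncation_rejection", len(live)))

    accepted: list[GeneRecord] = []
    for b in live:
        relatives = [r for r in references if r.form is b.record.form]
        report, rec = qc_mod.run_qc(b.record, relatives)
        if rec.status is Status.REJECTED:
            rejected.append(rec)
        else:
            accepted.append(rec.accepted())
    counts.append(("after_qc", len(accepted)))

    return FunnelReport(tuple(counts), accepted, rejected)


# ---------------------------------------------------------------------------
# Flat-file dialect

_FLATFILE_HEADER = (
    "#id\tform\tspecies\tsequence\tsegments\tinstance_count\t"
    "status\treject_reasons\tprovenance\tannotations"
)


class FlatfileError(ValueError):
    pass


def write_flatfile(records: Iterable[GeneRecord]) -> str:
    """Serialize records to the tab-separated flat-file dialect."""
    lines = [_FLATFILE_HEADER]
    for rec in records:
        reasons = ",".join(r.value for r in rec.reject_reasons) or "."
        prov = ";".join(p.serialize() for p in rec.provenance) or "."
        ann = (
            json.dumps(rec.annotations, sort_keys=True, separators=(",", ":"))
            if rec.annotations
            else "."
        )
        lines.append(
            "\t".join(
                [
                    rec.id,
                    rec.form.value,
                    rec.species or ".",
                    rec.sequence,
                    rec.segments.serialize(),
                    str(rec.instance_count),
                    rec.status.value,
                    reasons,
                    prov,
                    ann,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_flatfile(text: str) -> list[GeneRecord]:
    """Parse the flat-file dialect; errors carry 1-based line numbers."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise FlatfileError(f"line {lineno}: expected 10 fields, got {len(fields)}")
        (rid, form_tok, species, seq, segs, count, status_tok, reasons, prov, ann) = fields
        try:
            form = GeneForm(form_tok)
        except ValueError:
            raise FlatfileError(f"line {lineno}: unknown form {form_tok!r}") from None
        try:
            status = Status(status_tok)
            reject = (
                tuple(RejectReason(r) for r in reasons.split(","))
                if reasons != "."
                else ()
            )
            record = GeneRecord(
                id=rid,
                sequence=seq,
                form=form,
                segments=SegmentMap.parse(segs),
                species="" if species == "." else species,
                instance_count=int(count),
                status=status,
                reject_reasons=reject,
                provenance=(
                    tuple(Provenance.parse(p) for p in prov.split(";"))
                    if prov != "."
                    else ()
                ),
                annotations={} if ann == "." else json.loads(ann),
            )
        except (ValueError, KeyError) as exc:
            raise FlatfileError(f"line {lineno}: {exc}") from exc
        records.append(record)
    return records
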