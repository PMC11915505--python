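"""Seeded synthetic gene fixtures.

Generates tmRNA gene records of every form with exact ground-truth segment
maps, plants targeted defects, emits tRNA decoys, and writes emulated
tool-output files, so that every pipeline stage can be exercised offline.
All randomness flows through explicitly seeded ``random.Random`` instances;
identical configuration implies byte-identical output.
"""

from __future__ import annotations

import random
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

from .core import (
    CCA,
    CDS,
    INTRON,
    IVS,
    SPACER1,
    SPACER2,
    TRNA3,
    TRNA5,
    CandidateBundle,
    GeneForm,
    GeneRecord,
    Provenance,
    RejectReason,
    Segment,
    SegmentMap,
    revcomp,
)
from .hits import CandidateHit, ToolKind, TrnaHit
from .introns import DEFAULT_TLOOP, TLoopModel, find_intron_boundaries

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenConfig:
    """Parameters for one synthetic gene."""

    seed: int
    form: GeneForm = GeneForm.STANDARD
    tag_len_aa: int = 10
    tloop: TLoopModel = DEFAULT_TLOOP
    intron_subsite: int | None = None
    intron_len: int | None = None
    intron_rule: str = "UG"  # or "CA" for the C(-1)/A(P1) variant
    heg_len: int = 0
    flank_bp: int = 250
    species: str = "Synthetica exempli"

    def __post_init__(self) -> None:
        if self.form is GeneForm.INTRON:
            subsite = self.intron_subsite if self.intron_subsite is not None else 7
            length = self.intron_len if self.intron_len is not None else 300
            if not 1 <= subsite <= 8:
                raise ValueError("intron_subsite must be in 1-8")
            if length < 40:
                raise ValueError("intron_len must be >= 40")
            if self.heg_len and self.heg_len + 30 > length:
                raise ValueError("heg_len too large for intron_len")
        elif self.intron_subsite is not None or self.intron_len is not None:
            raise ValueError("intron parameters require the INTRON form")
        if self.intron_rule not in ("UG", "CA"):
            raise ValueError("intron_rule must be 'UG' or 'CA'")
        if self.tag_len_aa < 2:
            raise ValueError("tag_len_aa must be >= 2")
        if self.heg_len < 0 or self.flank_bp < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class GroundTruth:
    """Exact construction facts for one generated gene."""

    segments: SegmentMap
    tloop: TLoopModel
    tag: str
    exon: str  # spliced (intron-free) gene sequence
    intron_start: int | None = None
    intron_end: int | None = None
    intron_subsite: int | None = None
    minus1_base: str | None = None
    p1_partner: str | None = None
    heg_sites: dict[str, int] = field(default_factory=dict)


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _tag_codons(rng: random.Random, tag_len_aa: int) -> tuple[str, str]:
    """CDS (resume codon through stop) and its tag peptide."""
    from Bio.Seq import Seq

    if tag_len_aa == 2:
        codons = ["GCA", "GCA"]  # the minimal Ala-Ala tag
    else:
        codons = ["GCA"] + [rng.choice(_NONSTOP_CODONS) for _ in range(tag_len_aa - 1)]
    cds = "".join(codons) + "TAA"
    tag = str(Seq("".join(codons)).translate(table=11))
    return cds, tag


def _adjusted_tloop(cfg: GenConfig) -> TLoopModel:
    """Force the loop base at the intron subsite to supply the -1 base."""
    if cfg.form is not GeneForm.INTRON:
        return cfg.tloop
    k = cfg.intron_subsite if cfg.intron_subsite is not None else 7
    want = "T" if cfg.intron_rule == "UG" else "C"
    loop = cfg.tloop.loop
    if loop[k - 1] != want:
        loop = loop[: k - 1] + want + loop[k:]
    return TLoopModel(cfg.tloop.stem5, loop, cfg.tloop.stem3)


def _build_intron(
    rng: random.Random, cfg: GenConfig, length: int
) -> tuple[str, int | None]:
    """Intron sequence: P1-partner base, interior (optional HEG ORF), ω=G.

    Returns the sequence and the ORF start offset within the intron (or
    None).
    """
    partner = "G" if cfg.intron_rule == "UG" else "A"
    interior = list(_rand_seq(rng, length - 2))
    orf_at = None
    if cfg.heg_len:
        n_codons = max(2, cfg.heg_len // 3)
        orf = "ATG" + "".join(
            rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)
        ) + "TAA"
        at = max(16, (len(interior) - len(orf)) // 2)
        interior[at : at + len(orf)] = orf
        orf_at = at + 1
    return partner + "".join(interior) + "G", orf_at


def gen_gene(cfg: GenConfig) -> tuple[GeneRecord, GroundTruth]:
    """Generate one gene with an exact segment map and ground truth.

    Clean output passes the full QC suite; INTRON-form output is verified at
    build time to be exactly recoverable by the boundary finder (the whole
    gene is regenerated if chance motifs make the boundaries ambiguous).
    """
    last_error = None
    for attempt in range(64):
        rng = random.Random((cfg.seed, attempt).__repr__())
        try:
            return _build_gene(cfg, rng)
        except GenerationError as exc:
            last_error = exc
    raise GenerationError(
        f"could not build an unambiguous gene (seed {cfg.seed}): {last_error}"
    )


def _build_gene(cfg: GenConfig, rng: random.Random) -> tuple[GeneRecord, GroundTruth]:
    tloop = _adjusted_tloop(cfg)

    stem7 = _rand_seq(rng, 7)
    trna5 = stem7 + _rand_seq(rng, rng.randint(9, 12))
    spacer1 = _rand_seq(rng, rng.randint(4, 7))
    cds, tag = ("", "")
    if cfg.form.has_cds:
        cds, tag = _tag_codons(rng, cfg.tag_len_aa)
    spacer2 = _rand_seq(rng, rng.randint(6, 9))
    t_pre = _rand_seq(rng, rng.randint(4, 6))
    t_post = _rand_seq(rng, rng.randint(3, 5))
    trna3 = t_pre + tloop.stem5 + tloop.loop + tloop.stem3 + t_post + revcomp(stem7)
    ivs = _rand_seq(rng, rng.randint(20, 30))

    if cfg.form in (GeneForm.STANDARD, GeneForm.INTRON):
        pieces = [(TRNA5, trna5), (SPACER1, spacer1), (CDS, cds), (SPACER2, spacer2), (TRNA3, trna3), (CCA, "CCA")]
    elif cfg.form is GeneForm.STANDARD_NO_CDS:
        pieces = [(TRNA5, trna5), (SPACER1, spacer1), (TRNA3, trna3), (CCA, "CCA")]
    elif cfg.form is GeneForm.PERMUTED:
        pieces = [(TRNA3, trna3), (CCA, "CCA"), (IVS, ivs), (TRNA5, trna5), (SPACER1, spacer1), (CDS, cds)]
    else:  # PERMUTED_NO_CDS
        pieces = [(TRNA3, trna3), (CCA, "CCA"), (IVS, ivs), (TRNA5, trna5)]

    segs = []
    pos = 0
    for name, seq_part in pieces:
        segs.append(Segment(name, pos, pos + len(seq_part)))
        pos += len(seq_part)
    exon = "".join(p for _, p in pieces)
    seg_map = SegmentMap(tuple(segs))

    annotations: dict = {}
    truth = GroundTruth(segments=seg_map, tloop=tloop, tag=tag, exon=exon)
    sequence = exon

    if cfg.form is GeneForm.INTRON:
        k = cfg.intron_subsite if cfg.intron_subsite is not None else 7
        intron_len = cfg.intron_len if cfg.intron_len is not None else 300
        trna3_seg = seg_map.first(TRNA3)
        insert_at = trna3_seg.start + len(t_pre) + 5 + k  # inside the loop
        allow_ca = cfg.intron_rule == "CA"
        for _ in range(8):
            intron_seq, _ = _build_intron(random.Random(rng.random()), cfg, intron_len)
            candidate = exon[:insert_at] + intron_seq + exon[insert_at:]
            call = find_intron_boundaries(candidate, tloop, allow_CA=allow_ca)
            if (
                call is not None
                and call.intron_start == insert_at
                and call.intron_end == insert_at + intron_len
                and call.spliced_exon == exon
            ):
                break
        else:
            raise GenerationError(
                f"could not place an unambiguous intron (seed {cfg.seed})"
            )
        sequence = candidate
        # split TRNA3 around the intron
        new_segs = []
        for seg in segs:
            if seg.name == TRNA3 and seg.start < insert_at < seg.end:
                new_segs.append(Segment(TRNA3, seg.start, insert_at))
                new_segs.append(Segment(INTRON, insert_at, insert_at + intron_len))
                new_segs.append(
                    Segment(TRNA3, insert_at + intron_len, seg.end + intron_len)
                )
            elif seg.start >= insert_at:
                new_segs.append(
                    Segment(seg.name, seg.start + intron_len, seg.end + intron_len)
                )
            else:
                new_segs.append(seg)
        seg_map = SegmentMap(tuple(new_segs))
        heg_sites = {
            "in_P7.1": insert_at + intron_len // 2,
            "after_P9": insert_at + intron_len - 6,
        }
        annotations = {
            "heg_sites": heg_sites,
            "intron": {"start": insert_at, "end": insert_at + intron_len, "subsite": k},
        }
        truth = replace(
            truth,
            segments=seg_map,
            intron_start=insert_at,
            intron_end=insert_at + intron_len,
            intron_subsite=k,
            minus1_base="T" if cfg.intron_rule == "UG" else "C",
            p1_partner="G" if cfg.intron_rule == "UG" else "A",
            heg_sites=heg_sites,
        )

    offset = 1000
    record = GeneRecord(
        id=f"syn{cfg.seed}",
        sequence=sequence,
        form=cfg.form,
        segments=seg_map,
        species=cfg.species,
        provenance=(
            Provenance(
                assembly=f"ASM_{cfg.seed}",
                contig=f"ctg_{cfg.seed}",
                start=offset + 1,
                end=offset + len(sequence),
                strand="+",
            ),
        ),
        annotations=annotations,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Defect planting


def _shift_point(p: int, a: int, b: int) -> int:
    if p <= a:
        return p
    if p >= b:
        return p - (b - a)
    return a


def delete_slice(record: GeneRecord, a: int, b: int) -> GeneRecord:
    """Remove sequence slice [a, b); segments shrink/shift, empty ones drop."""
    seq = record.sequence[:a] + record.sequence[b:]
    segs = []
    for seg in record.segments:
        lo, hi = _shift_point(seg.start, a, b), _shift_point(seg.end, a, b)
        if hi > lo:
            segs.append(replace(seg, start=lo, end=hi))
    ann = dict(record.annotations)
    if "heg_sites" in ann:
        ann["heg_sites"] = {k: _shift_point(v, a, b) for k, v in ann["heg_sites"].items()}
    if "intron" in ann:
        iv = dict(ann["intron"])
        iv["start"] = _shift_point(iv["start"], a, b)
        iv["end"] = _shift_point(iv["end"], a, b)
        ann["intron"] = iv
    return replace(record, sequence=seq, segments=SegmentMap(tuple(segs)), annotations=ann)


_PLANTABLE = (
    RejectReason.AMBIGUOUS_BLOCK,
    RejectReason.ACCEPTOR_STEM,
    RejectReason.MISSING_CCA,
    RejectReason.TAG_ORF,
    RejectReason.INTERNAL_DELETION,
)


def plant_defect(record: GeneRecord, reason: RejectReason, seed: int = 0) -> GeneRecord:
    """Minimally mutate a clean record so exactly the targeted check fails."""
    from . import qc as qc_mod

    rng = random.Random(seed)
    if reason is RejectReason.AMBIGUOUS_BLOCK:
        target = next(
            (record.segments.first(n) for n in (SPACER2, SPACER1, IVS) if record.segments.first(n)),
            None,
        )
        if target is None or len(target) < 2:
            raise ValueError("no spacer segment to host an ambiguous block")
        at = target.start
        seq = record.sequence[:at] + "NN" + record.sequence[at + 2 :]
        return replace(record, sequence=seq)

    if reason is RejectReason.ACCEPTOR_STEM:
        trna5 = record.segments.first(TRNA5)
        if trna5 is None:
            raise ValueError("record lacks a TRNA5 segment")
        for _ in range(400):
            i, j = rng.sample(range(7), 2)
            seq = list(record.sequence)
            for p in (i, j):
                seq[trna5.start + p] = rng.choice(
                    [b for b in "ACGT" if b != record.sequence[trna5.start + p]]
                )
            mutated = replace(record, sequence="".join(seq))
            res = qc_mod.check_acceptor_stem(mutated)
            if res.outcome is qc_mod.Outcome.FLAG and not res.details["rescuing_shifts"]:
                return mutated
        raise GenerationError(f"could not break the acceptor stem (seed {seed})")

    if reason is RejectReason.MISSING_CCA:
        cca = record.segments.first(CCA)
        if cca is None:
            raise ValueError("record lacks a CCA segment")
        return delete_slice(record, cca.start, cca.end)

    if reason is RejectReason.TAG_ORF:
        cds = record.segments.first(CDS)
        if cds is None or len(cds) < 12:
            raise ValueError("record lacks a plantable CDS")
        n_codons = len(cds) // 3
        codon_idx = max(1, (n_codons - 1) // 2)  # internal, not resume or stop
        at = cds.start + 3 * codon_idx
        seq = record.sequence[:at] + "TAA" + record.sequence[at + 3 :]
        return replace(record, sequence=seq)

    if reason is RejectReason.INTERNAL_DELETION:
        cds = record.segments.first(CDS)
        if cds is None or len(cds) < 12:
            raise ValueError("record lacks a deletable CDS")
        # keep resume codon + stop codon: a valid but drastically short frame
        return delete_slice(record, cds.start + 3, cds.end - 3)

    raise ValueError(
        f"{reason.value} is not plantable on a record; "
        f"plantable reasons: {[r.value for r in _PLANTABLE]}"
    )


# ---------------------------------------------------------------------------
# Decoys and batch fixtures


def gen_trna_decoy(
    hit: CandidateHit, seed: int = 0, score: float = 80.0, overlap: int = 20
) -> TrnaHit:
    """A tRNA annotation overlapping `hit` by exactly `overlap` bases."""
    rng = random.Random(seed)
    trna_len = rng.randint(70, 90)
    start = hit.end - overlap + 1
    if start < 1:
        start = 1
    return TrnaHit(
        contig=hit.contig,
        start=start,
        end=start + trna_len - 1,
        strand=rng.choice("+-"),
        score=score,
        isotype="Ala",
    )


def _bundle_for(record: GeneRecord, tool: ToolKind, score: float) -> CandidateBundle:
    prov = record.provenance[0]
    contig_length = prov.end + 500
    hit = CandidateHit(
        tool=tool,
        score=score,
        contig=prov.contig,
        start=prov.start,
        end=prov.end,
        strand=prov.strand,
        form_guess=record.form,
        contig_length=contig_length,
    )
    return CandidateBundle(
        record=record,
        hits=[hit],
        mature_span=(prov.start, prov.end),
        contig_length=contig_length,
    )


def gen_funnel_batch(
    seed: int,
    n_clean: int = 10,
    n_trna_decoys: int = 3,
    n_truncated: int = 2,
    n_duplicates: int = 0,
    references: Sequence[GeneRecord] = (),
) -> tuple[list[CandidateBundle], list[TrnaHit]]:
    """A funnel batch with planted per-stage casualties.

    Clean genes survive every stage; decoy loci are overlapped by strong
    tRNAs; truncated loci carry a database-BLAST hit only, with a mature
    span running off the contig end; duplicates copy reference sequences.
    """
    bundles: list[CandidateBundle] = []
    trnas: list[TrnaHit] = []
    sub = random.Random(seed)

    for i in range(n_clean):
        rec, _ = gen_gene(GenConfig(seed=seed * 1000 + i))
        bundles.append(_bundle_for(rec, ToolKind.ARAGORN, 110.0 + i))

    for i in range(n_trna_decoys):
        rec, _ = gen_gene(GenConfig(seed=seed * 1000 + 500 + i))
        bundle = _bundle_for(rec, ToolKind.ARAGORN, 90.0)
        trnas.append(gen_trna_decoy(bundle.hits[0], seed=sub.randrange(2**31)))
        bundles.append(bundle)

    for i in range(n_truncated):
        rec, _ = gen_gene(GenConfig(seed=seed * 1000 + 700 + i))
        bundle = _bundle_for(rec, ToolKind.RFIND_BLAST, 95.0)
        # expected mature span extends past the contig end
        bundle.mature_span = (bundle.mature_span[0], bundle.contig_length + 30)
        bundles.append(bundle)

    for i in range(n_duplicates):
        ref = references[i % len(references)]
        dup = replace(ref, id=f"dup{i}", status=ref.status, reject_reasons=ref.reject_reasons)
        bundles.append(_bundle_for(dup, ToolKind.ARAGORN, 120.0))

    return bundles, trnas


# ---------------------------------------------------------------------------
# Emulated tool-output files

_TBLOUT_HEADER = (
    "#target name         accession query name           accession mdl mdl from"
    "   mdl to seq from   seq to strand trunc pass   gc  bias  score   E-value inc description of target"
)


def emit_tool_files(items: Sequence, dialect: str) -> str:
    """Write a syntactically valid hit table describing `items`.

    Candidate dialects take CandidateHit lists; ``trnascan_tab`` takes
    TrnaHit lists. Round-tripping through ``parse_hits`` preserves the
    fields both sides carry.
    """
    if dialect == "aragorn":
        lines = ["#contig\tstart\tend\tstrand\tscore\tform"]
        for h in items:
            form = h.form_guess.value if h.form_guess else "unknown"
            lines.append(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:g}\t{form}"
            )
        return "\n".join(lines) + "\n"

    if dialect == "infernal_tblout":
        lines = [_TBLOUT_HEADER]
        for h in items:
            sfrom, sto = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            lines.append(
                f"{h.contig} - tmRNA RF00023 cm 1 350 {sfrom} {sto} {h.strand}"
                f" no 1 0.50 0.0 {h.score:g} 1e-12 ! -"
            )
        return "\n".join(lines) + "\n"

    if dialect == "blast_tab6":
        lines = []
        for h in items:
            sstart, send = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            lines.append(
                "\t".join(
                    [
                        "dbref.1",
                        h.contig,
                        "98.500",
                        str(h.length),
                        "3",
                        "0",
                        "1",
                        str(h.length),
                        str(sstart),
                        str(send),
                        "1e-50",
                        f"{h.score:g}",
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    if dialect == "trnascan_tab":
        lines = [
            "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf",
            "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore",
            "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----",
        ]
        for i, t in enumerate(items, start=1):
            begin, end = (t.start, t.end) if t.strand == "+" else (t.end, t.start)
            lines.append(
                f"{t.contig}\t{i}\t{begin}\t{end}\t{t.isotype or 'Ala'}\tTGC\t0\t0\t{t.score:g}"
            )
        return "\n".join(lines) + "\n"

    raise ValueError(f"unknown dialect {dialect!r}")
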