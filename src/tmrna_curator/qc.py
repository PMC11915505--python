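"""Automated sanity checks applied to curated gene sequences.

These replace the manual inspection steps with testable rules: ambiguous
base blocks, acceptor-stem pairing, CCA positions, tag reading frame, and
comparative internal-deletion detection.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .core import (
    CCA,
    CDS,
    TRNA3,
    TRNA5,
    GeneForm,
    GeneRecord,
    RejectReason,
    Status,
    normalize,
)


class Outcome(enum.Enum):
    PASS = "PASS"
    FLAG = "FLAG"
    REJECT = "REJECT"
    UNEVALUATED = "UNEVALUATED"


@dataclass
class CheckResult:
    outcome: Outcome
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class QcConfig:
    deletion_fraction: float = 0.5
    genetic_code: int = 11  # NCBI translation table (bacterial default)
    stem_shift_range: int = 3
    stem_flag_mismatches: int = 2


#: base pairs accepted in the acceptor stem: Watson-Crick plus G.U wobble
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def check_ambiguous_blocks(seq: str) -> CheckResult:
    """REJECT any run of two or more consecutive non-ACGT bases."""
    if not seq:
        raise ValueError("empty sequence")
    s = normalize(seq)
    spans = []
    i = 0
    while i < len(s):
        if s[i] not in "ACGT":
            j = i
            while j < len(s) and s[j] not in "ACGT":
                j += 1
            if j - i >= 2:
                spans.append((i + 1, j))  # 1-based inclusive
            i = j
        else:
            i += 1
    outcome = Outcome.REJECT if spans else Outcome.PASS
    return CheckResult(outcome, {"spans": spans})


def _stem_mismatches(side5: str, side3: str) -> int:
    return sum(1 for i in range(7) if (side5[i], side3[6 - i]) not in _PAIRS)


def check_acceptor_stem(record: GeneRecord, config: QcConfig | None = None) -> CheckResult:
    """Count non-pairing positions in the 7-bp acceptor stem.

    The stem pairs the first 7 bases of the tRNA-like-5' segment against the
    7 bases immediately preceding the CCA positions, antiparallel. FLAG at
    >=2 mismatches; shifts of the 5' segment within +-stem_shift_range are
    tried and any shift reaching <=1 mismatch reported as a rescue.
    """
    config = config or QcConfig()
    trna5 = record.segments.first(TRNA5)
    cca = record.segments.first(CCA)
    if trna5 is None or cca is None:
        raise ValueError(f"record {record.id}: TRNA5/CCA segments required for stem check")
    seq = record.norm_sequence
    if len(trna5) < 7 or cca.start < 7:
        raise ValueError(f"record {record.id}: sequence too short for 7-bp stem")
    side3 = seq[cca.start - 7 : cca.start]
    mism = _stem_mismatches(seq[trna5.start : trna5.start + 7], side3)
    shifts = {}
    for d in range(-config.stem_shift_range, config.stem_shift_range + 1):
        if d == 0:
            continue
        lo = trna5.start + d
        if lo < 0 or lo + 7 > len(seq):
            continue
        shifts[d] = _stem_mismatches(seq[lo : lo + 7], side3)
    rescues = sorted(d for d, m in shifts.items() if m <= 1)
    outcome = Outcome.FLAG if mism >= config.stem_flag_mismatches else Outcome.PASS
    return CheckResult(
        outcome,
        {"mismatches": mism, "shift_mismatches": shifts, "rescuing_shifts": rescues},
    )


def check_cca_positions(record: GeneRecord) -> CheckResult:
    """All three positions equivalent to the tRNA CCA tail must be present
    (the bases need not literally read CCA)."""
    cca = record.segments.first(CCA)
    if cca is None or len(cca) < 3:
        return CheckResult(
            Outcome.REJECT, {"present": 0 if cca is None else len(cca)}
        )
    return CheckResult(Outcome.PASS, {"present": len(cca)})


def check_tag_orf(record: GeneRecord, config: QcConfig | None = None) -> CheckResult:
    """Translate the tag CDS (resume codon through stop, inclusive).

    FLAG on any internal stop or a missing terminal stop. A declared
    frameshift annotation ``{"position": p, "offset": o}`` (0-based within
    the CDS) splits the frame; the flag is suppressed when the adjusted
    frame is clean.
    """
    config = config or QcConfig()
    if not record.form.has_cds:
        return CheckResult(Outcome.UNEVALUATED, {"reason": "form has no CDS"})
    cds_segs = record.segments.all(CDS)
    if not cds_segs:
        raise ValueError(f"record {record.id}: no CDS segment")
    seq = record.norm_sequence
    cds = "".join(seq[s.start : s.end] for s in cds_segs)
    if len(cds) < 6:
        raise ValueError(f"record {record.id}: CDS shorter than 6 nt")
    frameshift = record.annotations.get("frameshift")
    shifted = False
    if frameshift:
        p, o = int(frameshift["position"]), int(frameshift["offset"])
        if not 0 <= p <= len(cds) or not 0 <= p + o <= len(cds):
            raise ValueError(f"record {record.id}: frameshift annotation out of range")
        cds = cds[:p] + cds[p + o :]
        shifted = True
    if len(cds) % 3:
        return CheckResult(Outcome.FLAG, {"reason": "CDS length not a multiple of 3"})
    aa = str(Seq(cds).translate(table=config.genetic_code))
    internal_stops = [i + 1 for i, ch in enumerate(aa[:-1]) if ch == "*"]
    terminal_stop = aa.endswith("*")
    clean = not internal_stops and terminal_stop
    outcome = Outcome.PASS if clean else Outcome.FLAG
    tag = aa[:-1] if terminal_stop else aa
    return CheckResult(
        outcome,
        {
            "tag": tag,
            "tag_length": len(tag),
            "internal_stop_codons": internal_stops,
            "terminal_stop": terminal_stop,
            "frameshift_applied": shifted,
        },
    )


def check_internal_deletion(
    record: GeneRecord,
    relatives: Sequence[GeneRecord],
    config: QcConfig | None = None,
) -> CheckResult:
    """FLAG when a core segment is drastically shorter than in relatives.

    A segment among {TRNA5, TRNA3, CDS} is suspicious when shorter than
    ``deletion_fraction`` of the minimum length of that segment among
    same-form relatives.
    """
    config = config or QcConfig()
    rels = [r for r in relatives if r.form is record.form and r.segments.segments]
    if not rels:
        return CheckResult(Outcome.UNEVALUATED, {"reason": "no relatives"})
    short = {}
    for name in (TRNA5, TRNA3, CDS):
        mine = record.segments.total_length(name)
        if mine == 0:
            continue
        lengths = [r.segments.total_length(name) for r in rels]
        lengths = [x for x in lengths if x > 0]
        if not lengths:
            continue
        floor = config.deletion_fraction * min(lengths)
        if mine < floor:
            short[name] = {"length": mine, "relatives_min": min(lengths)}
    outcome = Outcome.FLAG if short else Outcome.PASS
    return CheckResult(outcome, {"short_segments": short})


@dataclass
class QcReport:
    record_id: str
    checks: dict[str, CheckResult]
    status: Status
    reasons: tuple[RejectReason, ...]

    def serialize(self) -> str:
        rows = []
        for name, res in self.checks.items():
            rows.append(f"{self.record_id}\t{name}\t{res.outcome.value}\t{res.details}")
        return "\n".join(rows) + "\n"


_CHECK_REASON = {
    "ambiguous_blocks": RejectReason.AMBIGUOUS_BLOCK,
    "acceptor_stem": RejectReason.ACCEPTOR_STEM,
    "cca_positions": RejectReason.MISSING_CCA,
    "tag_orf": RejectReason.TAG_ORF,
    "internal_deletion": RejectReason.INTERNAL_DELETION,
}


def run_qc(
    record: GeneRecord,
    relatives: Sequence[GeneRecord] = (),
    config: QcConfig | None = None,
) -> tuple[QcReport, GeneRecord]:
    """Run every check, aggregate outcomes, and set the record status.

    A FLAG escalates to a rejection unless the check itself found a repair
    (a rescuing stem shift, or a validated frameshift); per-check errors are
    reported as UNEVALUATED.
    """
    config = config or QcConfig()
    checks: dict[str, CheckResult] = {}

    def safe(name, fn, *args):
        try:
            checks[name] = fn(*args)
        except ValueError as exc:
            checks[name] = CheckResult(Outcome.UNEVALUATED, {"error": str(exc)})

    safe("ambiguous_blocks", check_ambiguous_blocks, record.sequence)
    safe("acceptor_stem", check_acceptor_stem, record, config)
    safe("cca_positions", check_cca_positions, record)
    safe("tag_orf", check_tag_orf, record, config)
    safe("internal_deletion", check_internal_deletion, record, relatives, config)

    reasons = []
    for name, res in checks.items():
        if res.outcome is Outcome.REJECT:
            reasons.append(_CHECK_REASON[name])
        elif res.outcome is Outcome.FLAG:
            if name == "acceptor_stem" and res.details.get("rescuing_shifts"):
                continue  # correctable by shifting the tRNA-like-5' segment
            reasons.append(_CHECK_REASON[name])

    if reasons:
        new_record = record.rejected(*reasons)
    else:
        new_record = replace(record, status=Status.ACCEPTED, reject_reasons=())
    report = QcReport(record.id, checks, new_record.status, tuple(reasons))
    return report, new_record
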