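"""Segment mapping and the center-padded chunk alignment.

A chunk alignment anchors records of one gene form at their named segment
boundaries: each segment is padded with dashes inserted contiguously at its
center until it reaches the length of the longest instance of that segment.
No base-level alignment optimization is performed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

from .core import IUPAC_DNA, GeneRecord, Segment, SegmentMap

PAD = "-"

#: symbols used to tag alignment columns with their segment block
_BLOCK_CODES = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# Reference-based segment transfer


def map_segments_by_reference(
    candidate: str,
    ref: GeneRecord,
    match: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> SegmentMap:
    """Transfer the reference's segment boundaries onto a candidate.

    `match` is a list of collinear aligned block pairs
    ``((cand_start, cand_end), (ref_start, ref_end))`` in 0-based half-open
    coordinates (e.g. BLAST HSP blocks). Boundaries falling outside all
    blocks are extrapolated linearly from the nearest matched position and
    flagged provisional.
    """
    if not ref.segments.segments:
        raise ValueError(f"reference {ref.id} lacks a segment map")
    if not match:
        raise ValueError("empty match")
    blocks = sorted(match, key=lambda b: b[1][0])

    def transfer(r: int) -> tuple[int, bool]:
        for (cs, ce), (rs, re) in blocks:
            if rs <= r <= re:
                return cs + (r - rs), False
        # outside every block: extrapolate from the nearest block edge
        best = None
        for (cs, ce), (rs, re) in blocks:
            for c_edge, r_edge in ((cs, rs), (ce, re)):
                d = abs(r - r_edge)
                if best is None or d < best[0]:
                    best = (d, c_edge + (r - r_edge))
        return best[1], True

    segs = []
    n = len(candidate)
    for seg in ref.segments:
        c_start, p1 = transfer(seg.start)
        c_end, p2 = transfer(seg.end)
        c_start = max(0, min(n, c_start))
        c_end = max(0, min(n, c_end))
        if c_end <= c_start:
            continue
        segs.append(Segment(seg.name, c_start, c_end, provisional=p1 or p2))
    return SegmentMap(tuple(segs))


# ---------------------------------------------------------------------------
# Chunk alignment


@dataclass
class ChunkAlignment:
    """Rows padded so that segment blocks line up column-wise."""

    rows: list[tuple[str, str]]  # (label, padded sequence)
    blocks: tuple[tuple[str, int, int], ...]  # (segment name, col start, col end)
    meta: dict[str, GeneRecord] = field(default_factory=dict)  # label -> source record

    @property
    def width(self) -> int:
        return self.rows[0][1].__len__() if self.rows else 0

    def block_widths(self) -> dict[int, int]:
        return {i: e - s for i, (_, s, e) in enumerate(self.blocks)}


def center_pad(seq: str, width: int) -> str:
    """Pad `seq` to `width` with dashes inserted contiguously at its center.

    The insertion point is ceil(L/2): for odd lengths the extra residue stays
    on the left side of the pad.
    """
    if len(seq) > width:
        raise ValueError("segment longer than block width")
    cut = (len(seq) + 1) // 2
    return seq[:cut] + PAD * (width - len(seq)) + seq[cut:]


def _strength_prefix(rec: GeneRecord, strength: Mapping[str, str] | None) -> str:
    if strength and rec.id in strength:
        return f"{strength[rec.id]} "
    return ""


def chunk_align(
    records: Sequence[GeneRecord],
    taxonomy: Mapping[str, str] | None = None,
    strength: Mapping[str, str] | None = None,
) -> ChunkAlignment:
    """Build a chunk alignment from same-form records with complete maps.

    Rows are sorted by the taxonomic lineage string (stable for ties); labels
    carry the record id, prefixed with "S " or "W " when strength is known.
    """
    if not records:
        return ChunkAlignment([], ())
    taxonomy = taxonomy or {}
    forms = {r.form for r in records}
    if len(forms) > 1:
        raise ValueError(f"mixed gene forms in chunk alignment: {sorted(f.value for f in forms)}")
    name_seq = records[0].segments.names()
    for rec in records:
        if PAD in rec.sequence:
            raise ValueError(f"record {rec.id}: sequence contains reserved pad character")
        if not rec.segments.covers_fully(len(rec.sequence)):
            raise ValueError(f"record {rec.id}: segment map does not cover the sequence")
        if rec.segments.names() != name_seq:
            missing = set(name_seq) ^ set(rec.segments.names())
            which = ",".join(sorted(missing)) or "segment order"
            raise ValueError(f"record {rec.id}: segment mismatch ({which})")

    widths = [
        max(len(rec.segments.segments[i]) for rec in records)
        for i in range(len(name_seq))
    ]
    blocks = []
    col = 0
    for name, w in zip(name_seq, widths):
        blocks.append((name, col, col + w))
        col += w

    ordered = sorted(records, key=lambda r: taxonomy.get(r.id, ""))
    rows = []
    meta = {}
    for rec in ordered:
        parts = []
        for i, seg in enumerate(rec.segments.segments):
            parts.append(center_pad(rec.sequence[seg.start : seg.end], widths[i]))
        label = _strength_prefix(rec, strength) + rec.id
        rows.append((label, "".join(parts)))
        meta[label] = rec
    return ChunkAlignment(rows, tuple(blocks), meta)


def unchunk(aln: ChunkAlignment) -> list[GeneRecord]:
    """Strip padding and rebuild records with segment maps taken from the
    (possibly hand-edited) block boundaries."""
    if not aln.rows:
        return []
    width = len(aln.rows[0][1])
    out = []
    for label, padded in aln.rows:
        if len(padded) != width:
            raise ValueError(f"row {label!r}: unequal row lengths")
        bases = padded.replace(PAD, "")
        bad = set(bases) - IUPAC_DNA - set("acgtun")
        if bad:
            raise ValueError(f"row {label!r}: non-IUPAC characters {sorted(bad)}")
        segs = []
        pos = 0
        for name, cs, ce in aln.blocks:
            n = sum(1 for ch in padded[cs:ce] if ch != PAD)
            if n:
                segs.append(Segment(name, pos, pos + n))
            pos += n
        seg_map = SegmentMap(tuple(segs))
        base = aln.meta.get(label)
        rid = label[2:] if label[:2] in ("S ", "W ") else label
        if base is not None:
            out.append(replace(base, sequence=bases, segments=seg_map))
        else:
            from .core import GeneForm

            out.append(GeneRecord(id=rid, sequence=bases, form=GeneForm.STANDARD, segments=seg_map))
    return out


# ---------------------------------------------------------------------------
# Stockholm serialization (with a per-column segment annotation line)


def chunk_to_stockholm(aln: ChunkAlignment) -> str:
    """Serialize as Stockholm with a #=GC SEGMENTS column annotation; the
    block-code legend goes in a #=GF line so editors can round-trip it."""
    legend = ",".join(
        f"{_BLOCK_CODES[i]}:{name}" for i, (name, _, _) in enumerate(aln.blocks)
    )
    cols = []
    for i, (_, s, e) in enumerate(aln.blocks):
        cols.append(_BLOCK_CODES[i] * (e - s))
    seg_line = "".join(cols)
    lines = ["# STOCKHOLM 1.0", f"#=GF SEGMENTS {legend}"]
    label_w = max((len(lbl) for lbl, _ in aln.rows), default=0)
    label_w = max(label_w, len("#=GC SEGMENTS"))
    for label, seq in aln.rows:
        lines.append(f"{label.replace(' ', '_'):<{label_w}} {seq}")
    lines.append(f"{'#=GC SEGMENTS':<{label_w}} {seg_line}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def chunk_from_stockholm(text: str) -> ChunkAlignment:
    legend: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    seg_line = ""
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line == "//" or line.startswith("# STOCKHOLM"):
            continue
        if line.startswith("#=GF SEGMENTS"):
            for tok in line.split(None, 2)[2].split(","):
                code, name = tok.split(":")
                legend[code] = name
        elif line.startswith("#=GC SEGMENTS"):
            seg_line = line.split()[2]
        elif not line.startswith("#"):
            label, seq = line.split()
            rows.append((label.replace("_", " ", 1) if label[:2] in ("S_", "W_") else label, seq))
    blocks = []
    i = 0
    while i < len(seg_line):
        code = seg_line[i]
        j = i
        while j < len(seg_line) and seg_line[j] == code:
            j += 1
        blocks.append((legend[code], i, j))
        i = j
    return ChunkAlignment(rows, tuple(blocks))
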