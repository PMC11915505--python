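"""Seed-alignment preparation: pairwise identity, greedy identity filtering
and flagged-row add-back, with Stockholm read/write that preserves
column annotations such as ``#=GC SS_cons``."""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

GAP_CHARS = set("-.~")

IDENTITY_MODES = ("mutual", "min_ungapped", "alignment")


@dataclass
class Alignment:
    """Ordered aligned rows plus preserved annotation lines."""

    rows: list[tuple[str, str]]
    gf: list[str] = field(default_factory=list)  # file-level annotations
    gc: dict[str, str] = field(default_factory=dict)  # per-column annotations
    gs: list[str] = field(default_factory=list)
    gr: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            raise ValueError("unequal row lengths")

    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


def pairwise_identity(a: str, b: str, mode: str = "mutual") -> float:
    """Fractional identity between two aligned rows.

    The numerator counts columns where both rows carry the same (non-gap,
    case-folded) residue. The denominator depends on `mode`:
    ``mutual`` (default) counts columns where both rows are non-gap,
    ``min_ungapped`` uses the shorter ungapped length, and ``alignment``
    uses the full column count. Returns 0.0 when the denominator is 0.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    if mode not in IDENTITY_MODES:
        raise ValueError(f"unknown identity mode {mode!r}")
    a, b = a.upper(), b.upper()
    matches = 0
    mutual = 0
    for x, y in zip(a, b):
        xg, yg = x in GAP_CHARS, y in GAP_CHARS
        if not xg and not yg:
            mutual += 1
            if x == y:
                matches += 1
    if mode == "mutual":
        denom = mutual
    elif mode == "min_ungapped":
        denom = min(
            sum(1 for x in a if x not in GAP_CHARS),
            sum(1 for y in b if y not in GAP_CHARS),
        )
    else:
        denom = len(a)
    return matches / denom if denom else 0.0


def greedy_identity_filter(
    aln: Alignment, threshold: float, mode: str = "mutual"
) -> Alignment:
    """Keep rows, in input order, whose identity to every already-kept row
    is strictly below `threshold`."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    kept: list[tuple[str, str]] = []
    for rid, seq in aln.rows:
        if all(pairwise_identity(seq, k, mode) < threshold for _, k in kept):
            kept.append((rid, seq))
    return Alignment(kept, gf=list(aln.gf), gc=dict(aln.gc), gs=list(aln.gs), gr=list(aln.gr))


def add_back_flagged(
    original: Alignment, filtered: Alignment, flagged_ids: Iterable[str]
) -> Alignment:
    """Reinstate flagged rows removed by filtering, restoring original order."""
    flagged = set(flagged_ids)
    orig_ids = set(original.ids())
    unknown = flagged - orig_ids
    if unknown:
        raise ValueError(f"unknown flagged ids: {sorted(unknown)}")
    keep = set(filtered.ids()) | flagged
    rows = [(rid, seq) for rid, seq in original.rows if rid in keep]
    return Alignment(
        rows, gf=list(original.gf), gc=dict(original.gc), gs=list(original.gs), gr=list(original.gr)
    )


# ---------------------------------------------------------------------------
# Stockholm I/O


def read_stockholm(text: str) -> Alignment:
    """Read single-block or interleaved Stockholm, preserving annotations."""
    seqs: dict[str, list[str]] = {}
    order: list[str] = []
    gf: list[str] = []
    gc: dict[str, list[str]] = {}
    gs: list[str] = []
    gr: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("# STOCKHOLM") or line == "//":
            continue
        if line.startswith("#=GF"):
            gf.append(line[5:].strip())
        elif line.startswith("#=GC"):
            _, tag, chunk = line.split(None, 2)
            gc.setdefault(tag, []).append(chunk)
        elif line.startswith("#=GS"):
            gs.append(line[5:].strip())
        elif line.startswith("#=GR"):
            gr.append(line[5:].strip())
        elif line.startswith("#"):
            continue
        else:
            rid, chunk = line.split(None, 1)
            if rid not in seqs:
                seqs[rid] = []
                order.append(rid)
            seqs[rid].append(chunk.replace(" ", ""))
    rows = [(rid, "".join(seqs[rid])) for rid in order]
    return Alignment(rows, gf=gf, gc={t: "".join(c) for t, c in gc.items()}, gs=gs, gr=gr)


def write_stockholm(aln: Alignment) -> str:
    lines = ["# STOCKHOLM 1.0"]
    for item in aln.gf:
        lines.append(f"#=GF {item}")
    for item in aln.gs:
        lines.append(f"#=GS {item}")
    label_w = max(
        [len(r) for r, _ in aln.rows] + [len(f"#=GC {t}") for t in aln.gc] + [1]
    )
    for rid, seq in aln.rows:
        lines.append(f"{rid:<{label_w}} {seq}")
    for item in aln.gr:
        lines.append(f"#=GR {item}")
    for tag, chunk in aln.gc.items():
        lines.append(f"{f'#=GC {tag}':<{label_w}} {chunk}")
    lines.append("//")
    return "\n".join(lines) + "\n"
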