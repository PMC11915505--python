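"""Group I intron boundary determination within the TψC-loop.

Boundary rules: the exon base preceding the intron (-1 position) is a U
pairing an internal G near the intron 5' end (P1 proxy), the intron's
3'-terminal (ω) base is a G, and excising the intron must reconstitute the
expected TψC stem/loop. The loop's eight internucleotide positions number
the possible insertion subsites 1-8. A C(-1)/A(P1) variant is allowed when
requested.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GeneForm, GeneRecord, normalize

HEG_SITES = ("after_P9", "in_P7.1")


@dataclass(frozen=True)
class TLoopModel:
    """Expected post-splicing TψC stem/loop: 5-bp stem, 8-base loop, 5-bp stem."""

    stem5: str
    loop: str
    stem3: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "stem5", normalize(self.stem5))
        object.__setattr__(self, "loop", normalize(self.loop))
        object.__setattr__(self, "stem3", normalize(self.stem3))
        if len(self.stem5) != 5 or len(self.stem3) != 5:
            raise ValueError("TψC stems must be 5 bp")
        if len(self.loop) != 8:
            raise ValueError("TψC loop must be exactly 8 bases for subsite numbering")
        pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
        mism = sum(
            1 for i in range(5) if (self.stem5[i], self.stem3[4 - i]) not in pairs
        )
        if mism > 1:
            raise ValueError("TψC stems do not pair (>1 mismatch)")


DEFAULT_TLOOP = TLoopModel("GGGGC", "ATTCGATT", "GCCCC")


@dataclass
class IntronCall:
    """A called group I intron on a gene sequence (0-based half-open)."""

    intron_start: int
    intron_end: int
    minus1_base: str
    omega_base: str
    p1_partner: str
    subsite: int
    spliced_exon: str
    loop_start: int  # position of loop base 1 in the spliced exon
    heg: str = "none"
    stem_mismatches: int = 0

    def __post_init__(self) -> None:
        if (self.minus1_base, self.p1_partner) not in {("T", "G"), ("U", "G"), ("C", "A")}:
            raise ValueError(
                f"invalid -1/P1 pairing {self.minus1_base}/{self.p1_partner}"
            )
        if not 1 <= self.subsite <= 8:
            raise ValueError(f"subsite {self.subsite} outside 1-8")
        if self.heg not in ("none",) + HEG_SITES:
            raise ValueError(f"unknown HEG site {self.heg!r}")

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_intron_boundaries(
    gene: str,
    tloop: TLoopModel | None = None,
    allow_CA: bool = False,
    max_stem_mismatch: int = 1,
    p1_window: int = 15,
    min_len: int = 40,
    omega_override: str | None = None,
) -> IntronCall | None:
    """Locate group I intron boundaries that reconstitute the TψC-loop.

    Enumerates (start, end) pairs obeying the -1/P1 and ω rules whose
    excision restores `tloop` with the loop matched exactly and at most
    `max_stem_mismatch` total stem mismatches and length >= `min_len`
    (an intact TψC region would otherwise admit a tiny spurious excision);
    returns the best-matching
    call, or None. Ties are broken by longest intron first, then smallest
    start: chance motifs inside the intron can mimic a boundary, and such
    mimics always delimit a shorter intron than the outermost consistent
    call.
    """
    tloop = tloop or DEFAULT_TLOOP
    seq = normalize(gene)
    omega = normalize(omega_override) if omega_override else "G"
    rules = {"T": "G"}
    if allow_CA:
        rules["C"] = "A"

    best: tuple[int, int, int] | None = None  # (-score, start, end)
    best_call = None
    for k in range(1, 9):
        minus1 = tloop.loop[k - 1]
        if minus1 not in rules:
            continue
        partner = rules[minus1]
        prefix = tloop.loop[:k]  # must immediately precede the intron
        suffix = tloop.loop[k:]  # must immediately follow it
        for i in _find_all(seq, prefix):
            start = i + k  # intron start candidate
            if i - 5 < 0:
                continue
            m5 = _mismatches(seq[i - 5 : i], tloop.stem5)
            if m5 > max_stem_mismatch:
                continue
            if partner not in seq[start : start + p1_window]:
                continue
            # candidate intron ends: ω base, then loop remainder, then stem3
            for j in _find_all(seq[start:], omega + suffix):
                end = start + j + 1
                if end - start < min_len:
                    continue
                tail = seq[end + len(suffix) : end + len(suffix) + 5]
                if len(tail) < 5:
                    continue
                m3 = _mismatches(tail, tloop.stem3)
                if m5 + m3 > max_stem_mismatch:
                    continue
                score = 18 - (m5 + m3)
                key = (-score, -(end - start), start)
                if best is None or key < best:
                    best = key
                    exon = seq[:start] + seq[end:]
                    best_call = IntronCall(
                        intron_start=start,
                        intron_end=end,
                        minus1_base=minus1,
                        omega_base=seq[end - 1],
                        p1_partner=partner,
                        subsite=k,
                        spliced_exon=exon,
                        loop_start=i,
                        stem_mismatches=m5 + m3,
                    )
    return best_call


def assign_subsite(call: IntronCall, tloop: TLoopModel | None = None) -> int:
    """Internucleotide loop position (1-8) at which the intron interrupts
    the reconstituted loop."""
    tloop = tloop or DEFAULT_TLOOP
    k = call.intron_start - call.loop_start
    if not 1 <= k <= 8:
        raise ValueError("intron not in TψC-loop")
    if call.spliced_exon[call.loop_start : call.loop_start + 8] != tloop.loop:
        raise ValueError("reconstituted loop does not match the TψC-loop model")
    return k


# ---------------------------------------------------------------------------
# Subsite logo


@dataclass
class LogoMatrix:
    alphabet: str
    frequencies: np.ndarray  # shape (columns, len(alphabet))
    information: np.ndarray  # bits per column

    def column(self, i: int) -> dict[str, float]:
        return {b: float(self.frequencies[i, j]) for j, b in enumerate(self.alphabet)}


def subsite_logo(loops: Sequence[str], alphabet: str = "ACGT") -> LogoMatrix:
    """Per-column base frequencies over equally weighted unique sequences.

    Information content per column is log2(|alphabet|) - H (bits).
    """
    if not loops:
        raise ValueError("no sequences")
    uniq = list(dict.fromkeys(normalize(s) for s in loops))
    lengths = {len(s) for s in uniq}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)}")
    (width,) = lengths
    index = {b: i for i, b in enumerate(alphabet)}
    freq = np.zeros((width, len(alphabet)))
    for s in uniq:
        for i, ch in enumerate(s):
            if ch not in index:
                raise ValueError(f"character {ch!r} outside alphabet {alphabet!r}")
            freq[i, index[ch]] += 1.0
    freq /= len(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.log2(len(alphabet)) - entropy
    return LogoMatrix(alphabet, freq, info)


# ---------------------------------------------------------------------------
# HEG detection


@dataclass(frozen=True)
class DomTblRow:
    target: str
    query: str
    query_accession: str
    i_evalue: float
    score: float
    description: str


def parse_domtbl(stream) -> list[DomTblRow]:
    """Parse HMMER domtblout (whitespace-aligned, '#' comments)."""
    lines = stream.splitlines() if isinstance(stream, str) else list(stream)
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(maxsplit=22)
        if len(fields) < 23:
            raise ValueError(f"domtblout line {lineno}: expected >=23 fields")
        rows.append(
            DomTblRow(
                target=fields[0],
                query=fields[3],
                query_accession=fields[4],
                i_evalue=float(fields[12]),
                score=float(fields[13]),
                description=fields[22],
            )
        )
    return rows


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest forward-frame ORF (ATG..stop inclusive) as (start, codons)."""
    best = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOP_CODONS:
                if start is not None:
                    codons = (i + 3 - start) // 3
                    if best is None or codons > best[1]:
                        best = (start, codons)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def flag_heg(
    intron_seq: str,
    domtbl: Sequence[DomTblRow] | None = None,
    intron_id: str | None = None,
    site_positions: Mapping[str, int] | None = None,
    min_orf_codons: int = 150,
    max_i_evalue: float = 0.01,
) -> str:
    """Flag a homing endonuclease gene within an intron.

    With domain-table evidence, any LAGLIDADG-family hit under the inclusion
    e-value flags the intron; the insertion site is taken from the row
    description when it names one. Without evidence, a fallback heuristic
    flags introns containing an ORF of >= `min_orf_codons` codons and picks
    the configured site nearest the ORF.
    """
    seq = normalize(intron_seq)
    if domtbl:
        for row in domtbl:
            if intron_id is not None and row.target != intron_id:
                continue
            named = f"{row.query} {row.query_accession} {row.description}"
            if "LAGLIDADG" in named.upper() and row.i_evalue <= max_i_evalue:
                for site in HEG_SITES:
                    if site in row.description:
                        return site
                return _site_near_orf(seq, site_positions)
        return "none"
    orf = _longest_orf(seq)
    if orf is not None and orf[1] >= min_orf_codons:
        return _site_near_orf(seq, site_positions, orf_start=orf[0])
    return "none"


def _site_near_orf(
    seq: str, site_positions: Mapping[str, int] | None, orf_start: int | None = None
) -> str:
    if orf_start is None:
        orf = _longest_orf(seq)
        orf_start = orf[0] if orf else len(seq) // 2
    if site_positions:
        return min(site_positions, key=lambda s: abs(site_positions[s] - orf_start))
    # without annotated sites: late ORFs sit after P9, earlier ones in P7.1
    return "after_P9" if orf_start > (2 * len(seq)) // 3 else "in_P7.1"


# ---------------------------------------------------------------------------
# HEG insertion robustness simulation


def insert_heg_sim(
    intron_gene: GeneRecord, site: str, length: int, seed: int
) -> GeneRecord:
    """Insert `length` uniform-random ACGT bases at an annotated HEG site.

    The segment map and stored annotations shift accordingly; bases outside
    the insertion point are untouched and the result is deterministic under
    a fixed seed.
    """
    import random

    if site not in HEG_SITES:
        raise ValueError(f"unknown HEG site {site!r}")
    if intron_gene.form is not GeneForm.INTRON:
        raise ValueError(f"record {intron_gene.id} is not of INTRON form")
    sites = intron_gene.annotations.get("heg_sites")
    if not sites or site not in sites:
        raise ValueError(f"record {intron_gene.id} lacks annotated site {site!r}")
    if length < 0:
        raise ValueError("insertion length must be non-negative")
    if length == 0:
        return intron_gene
    pos = int(sites[site])
    rng = random.Random(seed)
    insert = "".join(rng.choice("ACGT") for _ in range(length))
    seq = intron_gene.sequence[:pos] + insert + intron_gene.sequence[pos:]

    ann = dict(intron_gene.annotations)
    ann["heg_sites"] = {
        name: (p + length if p > pos else p) for name, p in sites.items()
    }
    if "intron" in ann:
        iv = dict(ann["intron"])
        if iv.get("start", 0) >= pos:
            iv["start"] = iv["start"] + length
        if iv.get("end", 0) > pos:
            iv["end"] = iv["end"] + length
        ann["intron"] = iv
    return replace(
        intron_gene,
        sequence=seq,
        segments=intron_gene.segments.with_insertion(pos, length),
        annotations=ann,
    )
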