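"""Anatomy annotation of a single IS element copy.

Given one element sequence (ungapped, in the orientation it occupies in the
locus) and its immediate flanks, this module locates the four diagnostic
features of a canonical IS5-family element:

* the terminal inverted repeats (TIRs), reported as a pair of "inward reads"
  (each TIR read 5'->3' from the element's outer edge toward its interior)
  together with the catalogue of positions where the two reads differ;
* the transposase open reading frame (longest ORF on either strand);
* the target-site duplication (TSD), i.e. the flanking direct repeats created
  upon insertion;
* sigma-70 promoter candidates (-35/-10 hexamer pairs) near the element's
  5' end.

Coordinates follow the np convention: 1-based, counted from the element's
first nucleotide (= the outer end of the left TIR).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._dna import START_CODONS, STOP_CODONS, revcomp
from .errors import MalformedElementError, MalformedInputError

TARGET_SITE_RE = re.compile(r"^T[TA]A$")

MINUS35_CONSENSUS = "TTGACA"
MINUS35_CONSERVED = (0, 1, 2)  # T*T*G*ACA: position preceding each asterisk
MINUS10_CONSENSUS = "TATAAT"
MINUS10_CONSERVED = (0, 1, 5)  # T*A*TAAT*


@dataclass(frozen=True)
class TIRPair:
    """The two terminal inverted repeats of one element copy.

    ``left_inward`` is the element's first ``length`` nt on the top strand;
    ``right_inward`` is the reverse complement of its last ``length`` nt, so
    both strings read from the element's outer edges toward the interior and
    are directly comparable.  ``mismatch_positions`` lists the 1-based np
    positions at which the two inward reads differ.
    """

    length: int
    left_inward: str
    right_inward: str
    mismatch_positions: tuple[int, ...]

    @classmethod
    def from_element(cls, element: str, length: int) -> "TIRPair":
        if len(element) < 2 * length:
            raise MalformedElementError(
                f"element of {len(element)} nt cannot carry two {length}-nt TIRs"
            )
        left = element[:length]
        right = revcomp(element[-length:])
        mism = tuple(i + 1 for i in range(length) if left[i] != right[i])
        return cls(length, left, right, mism)


@dataclass(frozen=True)
class PromoterHit:
    """One -35/-10 hexamer pair.  Intervals are 1-based inclusive np."""

    minus35_interval: tuple[int, int]
    minus10_interval: tuple[int, int]
    minus35_seq: str
    minus10_seq: str
    spacer: int
    score: int


@dataclass
class AnnotatedElement:
    """Full anatomy of one strain's element copy (ungapped coordinates)."""

    strain_id: str
    element_interval: tuple[int, int]
    tirs: TIRPair | None
    orf: tuple[tuple[int, int], str] | None
    tsd: tuple[tuple[int, int], tuple[int, int], str] | None
    promoters: list[PromoterHit] = field(default_factory=list)

    @property
    def orf_strand(self) -> str:
        return self.orf[1] if self.orf else "none"


def detect_tirs(
    element: str, k_min: int = 10, k_max: int = 50, d_max: int = 2
) -> TIRPair | None:
    """De novo detection of terminal inverted repeats.

    Returns the largest length ``k`` in ``[k_min, min(k_max, len/2)]`` such
    that the element's first ``k`` nt and the reverse complement of its last
    ``k`` nt differ at no more than ``d_max`` positions *and* match at the
    innermost position ``k``: a repeat is delimited by its last matching
    column, so it is never extended onto a mismatch.  Returns ``None`` when no
    length qualifies (distinct from the error below).

    Raises
    ------
    MalformedElementError
        If the element is shorter than ``2 * k_min``.
    """
    n = len(element)
    if n < 2 * k_min:
        raise MalformedElementError(
            f"element of {n} nt is shorter than 2*k_min={2 * k_min}"
        )
    best: TIRPair | None = None
    for k in range(k_min, min(k_max, n // 2) + 1):
        pair = TIRPair.from_element(element, k)
        if len(pair.mismatch_positions) <= d_max and pair.left_inward[-1] == pair.right_inward[-1]:
            best = pair
    return best


def _orf_scan_frame(seq: str, frame: int):
    """Yield (start0, end0) inclusive 0-based intervals of ORFs in one frame.

    An ORF runs from the first start codon after the previous stop to the
    next in-frame stop codon (interval includes the stop codon).
    """
    start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                yield (start, i + 2)
            start = None
        elif start is None and codon in START_CODONS:
            start = i


def find_transposase_orf(
    element: str, min_len: int = 300
) -> tuple[tuple[int, int], str] | None:
    """Longest open reading frame on either strand, or ``None``.

    Start codons ATG/GTG/TTG (bacterial); the ORF ends at, and includes, its
    stop codon; its length (stop included) must be >= ``min_len``.  Ties are
    broken in favour of the + strand, then the leftmost interval.  Intervals
    are 1-based inclusive on the top strand regardless of the ORF's strand.
    """
    n = len(element)
    candidates: list[tuple[int, int, tuple[int, int], str]] = []
    for frame in range(3):
        for s0, e0 in _orf_scan_frame(element, frame):
            candidates.append((e0 - s0 + 1, 0, (s0 + 1, e0 + 1), "+"))
    rc = revcomp(element)
    for frame in range(3):
        for s0, e0 in _orf_scan_frame(rc, frame):
            candidates.append((e0 - s0 + 1, 1, (n - e0, n - s0), "-"))
    candidates = [c for c in candidates if c[0] >= min_len]
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (-c[0], c[1], c[2][0]))
    return best[2], best[3]


def detect_tsd(
    left_flank: str, right_flank: str, n_min: int = 2, n_max: int = 10
) -> tuple[str, bool] | None:
    """Flanking direct repeat (target-site duplication) detection.

    Compares the terminal ``n``-mer of the left flank with the initial
    ``n``-mer of the right flank and returns the longest exact match with
    ``n`` in ``[n_min, n_max]``, plus whether it matches the T(T/A)A target
    site (which requires n == 3).  ``None`` when no repeat is found.
    """
    if len(left_flank) < n_min or len(right_flank) < n_min:
        raise MalformedInputError(
            f"flanks must be at least n_min={n_min} nt long"
        )
    hi = min(n_max, len(left_flank), len(right_flank))
    for n in range(hi, n_min - 1, -1):
        if left_flank[-n:] == right_flank[:n]:
            seq = right_flank[:n]
            return seq, bool(n == 3 and TARGET_SITE_RE.match(seq))
    return None


def _hexamer_matches(hexamer: str, consensus: str, conserved: tuple[int, ...],
                     max_soft_mismatches: int) -> int | None:
    """Matched-position count, or None if the hexamer fails the constraints."""
    matches = 0
    soft_mismatches = 0
    for i in range(6):
        if hexamer[i] == consensus[i]:
            matches += 1
        elif i in conserved:
            return None
        else:
            soft_mismatches += 1
    if soft_mismatches > max_soft_mismatches:
        return None
    return matches


def scan_promoters(
    element: str,
    search_window: int = 60,
    spacer_range: tuple[int, int] = (15, 19),
    max_soft_mismatches: int = 2,
) -> list[PromoterHit]:
    """Scan the element's 5' end for sigma-70 -35/-10 promoter pairs.

    Both hexamers must lie entirely within the first ``search_window`` nt.
    The -35 box is matched against T*T*G*ACA (conserved positions 1,2,3 exact,
    at most ``max_soft_mismatches`` mismatches elsewhere), the -10 box against
    T*A*TAAT* (conserved positions 1,2,6 exact), and the spacer between them
    must fall in ``spacer_range``.  Hits are ranked by total matched consensus
    positions (0-12) descending, then by |spacer - 17| ascending, then by the
    leftmost -35 start.
    """
    if len(element) < search_window:
        raise MalformedInputError(
            f"element of {len(element)} nt is shorter than the "
            f"{search_window}-nt search window"
        )
    window = element[:search_window]
    m35_hits = []
    m10_hits = []
    for p in range(search_window - 5):
        hexamer = window[p : p + 6]
        s35 = _hexamer_matches(hexamer, MINUS35_CONSENSUS, MINUS35_CONSERVED,
                               max_soft_mismatches)
        if s35 is not None:
            m35_hits.append((p, hexamer, s35))
        s10 = _hexamer_matches(hexamer, MINUS10_CONSENSUS, MINUS10_CONSERVED,
                               max_soft_mismatches)
        if s10 is not None:
            m10_hits.append((p, hexamer, s10))
    hits = []
    lo, hi = spacer_range
    for p35, h35, s35 in m35_hits:
        for p10, h10, s10 in m10_hits:
            spacer = p10 - (p35 + 6)
            if lo <= spacer <= hi:
                hits.append(
                    PromoterHit(
                        minus35_interval=(p35 + 1, p35 + 6),
                        minus10_interval=(p10 + 1, p10 + 6),
                        minus35_seq=h35,
                        minus10_seq=h10,
                        spacer=spacer,
                        score=s35 + s10,
                    )
                )
    hits.sort(
        key=lambda h: (-h.score, abs(h.spacer - 17), h.minus35_interval[0],
                       h.minus10_interval[0])
    )
    return hits


def annotate_element(
    strain_id: str,
    sequence: str,
    element_interval: tuple[int, int],
    tir_k_min: int = 10,
    tir_k_max: int = 50,
    tir_d_max: int = 2,
    orf_min_len: int = 300,
    tsd_n_min: int = 2,
    tsd_n_max: int = 10,
) -> AnnotatedElement:
    """Annotate one element copy inside an ungapped strain sequence.

    ``element_interval`` is 1-based inclusive in ``sequence`` coordinates.
    TSD detection is attempted only when both flanks are long enough.
    """
    a, b = element_interval
    element = sequence[a - 1 : b]
    left_flank = sequence[: a - 1]
    right_flank = sequence[b:]
    tirs = detect_tirs(element, tir_k_min, tir_k_max, tir_d_max)
    orf = find_transposase_orf(element, orf_min_len)
    tsd = None
    if len(left_flank) >= tsd_n_min and len(right_flank) >= tsd_n_min:
        found = detect_tsd(left_flank, right_flank, tsd_n_min, tsd_n_max)
        if found is not None:
            seq, _ = found
            n = len(seq)
            tsd = ((a - n, a - 1), (b + 1, b + n), seq)
    promoters = scan_promoters(element) if len(element) >= 60 else []
    return AnnotatedElement(
        strain_id=strain_id,
        element_interval=(a, b),
        tirs=tirs,
        orf=orf,
        tsd=tsd,
        promoters=promoters,
    )


def to_gff3(ann: AnnotatedElement, seqid: str, source: str = "isinv") -> list[str]:
    """Render an annotated element as GFF3 feature lines (ungapped coords)."""
    rows = []

    def row(ftype, start, end, strand=".", attrs=""):
        rows.append(
            "\t".join(
                [seqid, source, ftype, str(start), str(end), ".", strand, ".",
                 attrs or f"ID={ftype}_{start}_{end}"]
            )
        )

    a, b = ann.element_interval
    row("mobile_genetic_element", a, b, "+", f"ID=element;strain={ann.strain_id}")
    if ann.tirs:
        t = ann.tirs.length
        row("terminal_inverted_repeat", a, a + t - 1, "+", "ID=tir_left")
        row("terminal_inverted_repeat", b - t + 1, b, "-", "ID=tir_right")
    if ann.orf:
        (s, e), strand = ann.orf
        row("CDS", a + s - 1, a + e - 1, strand, "ID=transposase")
    if ann.tsd:
        (l1, l2), (r1, r2), seq = ann.tsd
        row("direct_repeat", l1, l2, "+", f"ID=tsd_left;seq={seq}")
        row("direct_repeat", r1, r2, "+", f"ID=tsd_right;seq={seq}")
    for i, p in enumerate(ann.promoters[:1]):
        row("minus_35_signal", a + p.minus35_interval[0] - 1,
            a + p.minus35_interval[1] - 1, "+", f"ID=minus35_{i}")
        row("minus_10_signal", a + p.minus10_interval[0] - 1,
            a + p.minus10_interval[1] - 1, "+", f"ID=minus10_{i}")
    return rows
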