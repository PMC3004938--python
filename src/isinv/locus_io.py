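"""Per-locus alignment parsing and presence/orientation calling.

A locus is a multi-strain nucleotide alignment containing an IS insertion
plus flanking genomic anchor sequence; one strain is designated the
canonical reference and the element's column interval is annotated on it.
Orientation of each strain's copy is decided by the strand of its
transposase ORF relative to the reference (not by TIR order, because an
internal inversion flips the transposase while leaving the TIR
configuration canonical).

Coordinate systems: alignment columns and ungapped strain positions are both
1-based inclusive, but are distinct systems and never mixed in one field.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._dna import revcomp
from .annotate import AnnotatedElement, find_transposase_orf
from .errors import FormatError, UnknownStrainError

PRESENCE_ABSENT_MAX = 0.10
PRESENCE_PRESENT_MIN = 0.50


@dataclass
class LocusAlignment:
    locus_id: str
    strains: list  # ordered [(strain_id, aligned sequence), ...]
    reference_strain: str
    reference_element_interval: tuple[int, int]  # 1-based alignment columns

    def row(self, strain_id: str) -> str:
        for sid, seq in self.strains:
            if sid == strain_id:
                return seq
        raise UnknownStrainError(strain_id)

    def validate(self) -> None:
        if not self.strains:
            raise FormatError("alignment contains no sequences")
        lengths = {len(seq) for _, seq in self.strains}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        width = lengths.pop()
        ids = [sid for sid, _ in self.strains]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate strain ids in alignment")
        if self.reference_strain not in ids:
            raise UnknownStrainError(
                f"reference strain {self.reference_strain!r} not in alignment"
            )
        a, b = self.reference_element_interval
        if not (1 < a <= b < width):
            raise FormatError(
                "element interval must lie strictly inside the alignment"
            )
        ref = self.row(self.reference_strain)
        if ref[a - 1] == "-" or ref[b - 1] == "-":
            raise FormatError(
                "reference strain is gapped at an element boundary column"
            )


@dataclass(frozen=True)
class OrientationCall:
    strain_id: str
    state: str  # absent | canonical | inverted | ambiguous
    non_gap_fraction: float
    orf_strand: str  # + | - | none


def read_locus_alignment(path, reference_strain: str | None = None,
                         element_interval: tuple[int, int] | None = None,
                         locus_id: str | None = None) -> LocusAlignment:
    """Read an aligned multi-FASTA locus.

    When ``reference_strain`` or ``element_interval`` is omitted it is taken
    from the JSON sidecar ``<path>.json`` (as written by the simulator).
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if reference_strain is None or element_interval is None:
        sidecar = Path(f"{path}.json")
        if not sidecar.exists():
            raise FormatError(
                f"{path}: no annotation sidecar and no explicit interval given"
            )
        meta = json.loads(sidecar.read_text())
        reference_strain = reference_strain or meta["reference_strain"]
        element_interval = element_interval or tuple(
            meta["element_interval_alignment"]
        )
    aln = LocusAlignment(
        locus_id=locus_id or path.stem,
        strains=records,
        reference_strain=reference_strain,
        reference_element_interval=tuple(element_interval),
    )
    aln.validate()
    return aln


def extract_ungapped(aln: LocusAlignment, strain_id: str,
                     column_interval: tuple[int, int]) -> tuple[str, dict]:
    """Ungapped subsequence of one strain over an alignment-column interval.

    Returns the gap-free sequence and a map {alignment column -> 1-based
    ungapped position within the extracted sequence} with entries only for
    non-gap columns; the map round-trips exactly.
    """
    row = aln.row(strain_id)
    a, b = column_interval
    if not (1 <= a <= b <= len(row)):
        raise FormatError(f"column interval {column_interval} outside alignment")
    seq = []
    col_to_pos = {}
    for col in range(a, b + 1):
        ch = row[col - 1]
        if ch != "-":
            seq.append(ch)
            col_to_pos[col] = len(seq)
    return "".join(seq), col_to_pos


def call_presence_orientation(aln: LocusAlignment,
                              canonical: AnnotatedElement) -> list[OrientationCall]:
    """Call IS presence and orientation for every strain of a locus.

    Presence is the non-gap fraction over the element columns: absent at
    <= 0.10, present at >= 0.50, ambiguous between.  For present strains the
    ungapped element region is extracted and its longest transposase ORF
    strand compared with the reference's: same strand -> canonical, opposite
    -> inverted, no ORF -> ambiguous.
    """
    interval = aln.reference_element_interval
    n_cols = interval[1] - interval[0] + 1
    ref_strand = canonical.orf_strand
    calls = []
    for strain_id, _ in aln.strains:
        seq, _map = extract_ungapped(aln, strain_id, interval)
        frac = len(seq) / n_cols
        if frac <= PRESENCE_ABSENT_MAX:
            calls.append(OrientationCall(strain_id, "absent", frac, "none"))
            continue
        if frac < PRESENCE_PRESENT_MIN:
            calls.append(OrientationCall(strain_id, "ambiguous", frac, "none"))
            continue
        orf = find_transposase_orf(seq)
        if orf is None or ref_strand == "none":
            calls.append(OrientationCall(strain_id, "ambiguous", frac, "none"))
            continue
        strand = orf[1]
        state = "canonical" if strand == ref_strand else "inverted"
        calls.append(OrientationCall(strain_id, state, frac, strand))
    return calls


def reverse_complement_alignment(aln: LocusAlignment) -> LocusAlignment:
    """The same locus read on the opposite strand (rows revcomped, element
    interval reflected).  Presence/orientation calls are invariant under
    this transformation."""
    width = len(aln.strains[0][1])
    a, b = aln.reference_element_interval
    return LocusAlignment(
        locus_id=aln.locus_id,
        strains=[(sid, revcomp(seq)) for sid, seq in aln.strains],
        reference_strain=aln.reference_strain,
        reference_element_interval=(width - b + 1, width - a + 1),
    )
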