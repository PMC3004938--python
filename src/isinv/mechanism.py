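"""Mechanism classification of observed IS inversions.

The two TIR inward reads of the canonical element are identical except for a
single diagnostic mismatch (np 17 by default: L carries one base, R the
other).  Because the five possible inversion processes leave different TIR
configurations behind, the pair (left-read identity, right-read identity) at
the diagnostic position, combined with the orientation call, identifies the
mechanism:

=============  ==========  ===========  =======================================
orientation    left read   right read   class
=============  ==========  ===========  =======================================
canonical      —           —            not_inverted
inverted       R           L            full_inversion_ab (whole-element flip:
                                        excision/re-integration and an
                                        upstream conversion tract are
                                        sequence-indistinguishable)
inverted       L           R            internal_inversion_c (tract downstream
                                        of the mismatch: transposase only)
inverted       L           L            conversion_left_d (tract covers the
                                        mismatch, left TIR as template)
inverted       R           R            conversion_right_e
inverted       neither     any          unclassified (likewise any/neither)
=============  ==========  ===========  =======================================

Only the diagnostic position decides the class; mismatches elsewhere in the
23-mers (point mutations) are reported in the evidence trail but do not
change the call.
"""
from __future__ import annotations

from dataclasses import dataclass

from .annotate import TIRPair
from .errors import NoDiagnosticAsymmetryError
from .locus_io import OrientationCall

CLASSES = ("not_inverted", "full_inversion_ab", "internal_inversion_c",
           "conversion_left_d", "conversion_right_e", "unclassified")

_TABLE = {
    ("R", "L"): "full_inversion_ab",
    ("L", "R"): "internal_inversion_c",
    ("L", "L"): "conversion_left_d",
    ("R", "R"): "conversion_right_e",
}

SCENARIO_TO_CLASS = {
    "full_ab": "full_inversion_ab",
    "internal_c": "internal_inversion_c",
    "conversion_left_d": "conversion_left_d",
    "conversion_right_e": "conversion_right_e",
}


@dataclass(frozen=True)
class MechanismCall:
    strain_id: str
    mechanism_class: str
    left_match: str  # L | R | neither
    right_match: str
    mismatch_np_used: int
    evidence: str


def _match_at(observed_read: str, canonical: TIRPair, np_: int) -> str:
    ch = observed_read[np_ - 1]
    if ch == canonical.left_inward[np_ - 1]:
        return "L"
    if ch == canonical.right_inward[np_ - 1]:
        return "R"
    return "neither"


def classify_mechanism(observed: TIRPair, canonical: TIRPair,
                       orientation: OrientationCall) -> MechanismCall:
    """Classify one strain's element into an inversion-mechanism class.

    Raises :class:`NoDiagnosticAsymmetryError` when the canonical TIR pair
    does not carry exactly one mismatch — the test hinges on that asymmetry.
    """
    if len(canonical.mismatch_positions) != 1:
        raise NoDiagnosticAsymmetryError(
            "canonical TIRs must differ at exactly one position, found "
            f"{list(canonical.mismatch_positions)}"
        )
    if observed.length != canonical.length:
        raise NoDiagnosticAsymmetryError(
            "observed and canonical TIR lengths differ "
            f"({observed.length} vs {canonical.length})"
        )
    np_ = canonical.mismatch_positions[0]
    left = _match_at(observed.left_inward, canonical, np_)
    right = _match_at(observed.right_inward, canonical, np_)

    notes = [f"diagnostic np {np_}: left={left}, right={right}"]
    full_left = ("L" if observed.left_inward == canonical.left_inward
                 else "R" if observed.left_inward == canonical.right_inward
                 else "neither")
    full_right = ("L" if observed.right_inward == canonical.left_inward
                  else "R" if observed.right_inward == canonical.right_inward
                  else "neither")
    if (full_left, full_right) != (left, right):
        notes.append(
            "full 23-mer comparison disagrees with the diagnostic position "
            f"(left={full_left}, right={full_right}): point mutations present, "
            "confidence reduced"
        )

    if orientation.state == "canonical":
        cls = "not_inverted"
    elif orientation.state == "inverted":
        cls = _TABLE.get((left, right), "unclassified")
        if cls == "full_inversion_ab":
            notes.append(
                "excision/re-integration and upstream-tract recombination are "
                "indistinguishable at the sequence level"
            )
    else:
        cls = "unclassified"
        notes.append(f"orientation call is {orientation.state}")
    return MechanismCall(
        strain_id=orientation.strain_id,
        mechanism_class=cls,
        left_match=left,
        right_match=right,
        mismatch_np_used=np_,
        evidence="; ".join(notes),
    )


def predict_pair_outcome(orientation_1: str, orientation_2: str) -> str:
    """Outcome of ectopic recombination between two co-linear IS copies.

    Copies in the same relative orientation delete the intervening sequence;
    copies in opposite orientations invert it.
    """
    if orientation_1 not in "+-" or orientation_2 not in "+-":
        raise ValueError("orientations must be '+' or '-'")
    return "deletion" if orientation_1 == orientation_2 else "inversion"
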