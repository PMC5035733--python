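"""In-silico terminal restriction fragment (T-RF) prediction.

A T-RF is the fragment between the 5' end of the labeled PCR primer and the
first restriction cut downstream; its length (bp) is what a capillary
sequencer sizes in T-RFLP fingerprinting. Predicting T-RFs from reference
or contig sequences lets labeling calls made from amplicon reads be
cross-validated against fragments observed to shift between heavy and
light gradient fractions.

Only the forward (labeled-primer) strand fragment is reported, matching
single-labeled-primer T-RFLP. Recognition sites may contain IUPAC
degeneracy codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "IUPAC",
    "ENZYME_REGISTRY",
    "EnzymeSpec",
    "TrfPrediction",
    "find_first_cut",
    "predict_trf",
    "match_trf",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme as recognition sequence plus cut offset.

    ``cut_offset`` counts bases from the 5' end of the recognition site to
    the cut on the top strand, e.g. MspI (C^CGG) has recognition ``CCGG``
    and offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if not rec or any(b not in IUPAC for b in rec):
            raise ValueError(f"recognition sequence {self.recognition!r} not IUPAC nucleotides")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset must lie within the recognition site")

    def site_regex(self) -> re.Pattern[str]:
        pattern = "".join(
            b if len(IUPAC[b]) == 1 else "[" + "".join(sorted(IUPAC[b])) + "]"
            for b in self.recognition
        )
        return re.compile(pattern)


# Common T-RFLP enzymes, examples only — any EnzymeSpec is accepted.
ENZYME_REGISTRY: dict[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("MspI", "CCGG", 1),
        EnzymeSpec("HaeIII", "GGCC", 2),
        EnzymeSpec("AluI", "AGCT", 2),
        EnzymeSpec("RsaI", "GTAC", 2),
        EnzymeSpec("HhaI", "GCGC", 3),
        EnzymeSpec("Bsh1236I", "CGCG", 2),
    )
}


@dataclass(frozen=True)
class TrfPrediction:
    """Predicted terminal fragment for one sequence and enzyme."""

    sequence_id: str
    enzyme: str
    trf_length: int
    status: str  # "cut" | "uncut" | "unanchored"


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    return seq


def find_first_cut(sequence: str, enzyme: EnzymeSpec) -> int | None:
    """0-based position of the first cut, or None if the site never occurs.

    The cut position equals the index of the first IUPAC-compatible
    occurrence of the recognition site plus the enzyme's cut offset; it is
    also the length of the 5' fragment.
    """
    seq = _check_sequence(sequence)
    m = enzyme.site_regex().search(seq)
    if m is None:
        return None
    return m.start() + enzyme.cut_offset


def _anchor_primer(seq: str, primer: str, max_mismatch: int) -> int | None:
    """5'-most position where the primer aligns with <= max_mismatch mismatches."""
    if not primer:
        return 0
    k = len(primer)
    for start in range(len(seq) - k + 1):
        mm = sum(1 for a, b in zip(primer, seq[start:start + k]) if a != b)
        if mm <= max_mismatch:
            return start
    return None


def predict_trf(
    sequence: str,
    primer: str,
    enzyme: EnzymeSpec,
    max_primer_mismatch: int = 0,
    sequence_id: str = "",
) -> TrfPrediction:
    """Predict the T-RF of a sequence for one labeled primer and enzyme.

    The sequence is truncated at the primer's 5'-most anchoring (allowing up
    to ``max_primer_mismatch`` mismatches); the T-RF length is the distance
    from the primer's 5' end to the first cut. Sequences without an
    acceptable primer match get status ``unanchored``; sequences with no
    recognition site downstream are ``uncut`` with the full remaining length.
    """
    seq = _check_sequence(sequence)
    primer = primer.upper()
    if len(primer) >= len(seq):
        raise ValueError("primer must be shorter than the sequence")
    start = _anchor_primer(seq, primer, max_primer_mismatch)
    if start is None:
        return TrfPrediction(sequence_id, enzyme.name, 0, "unanchored")
    trimmed = seq[start:]
    cut = find_first_cut(trimmed, enzyme)
    if cut is None:
        return TrfPrediction(sequence_id, enzyme.name, len(trimmed), "uncut")
    return TrfPrediction(sequence_id, enzyme.name, cut, "cut")


def match_trf(predicted: float, observed: Sequence[float], tolerance: float = 2.0) -> list[float]:
    """Observed T-RF sizes within +/- tolerance bp of the predicted length.

    The default +/-2 bp tolerance reflects typical capillary sizing error.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return [o for o in observed if abs(o - predicted) <= tolerance]
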