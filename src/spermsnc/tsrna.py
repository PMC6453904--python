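"""Positional typing of tRNA-derived small RNAs (tsRNAs).

A fragment aligned to a mature tRNA is typed by where its ends fall
relative to the tRNA's two ends and the anticodon loop:

* 5'-tRNA half  — starts at/near the 5' end, ends inside the anticodon loop
* 5'-tRF        — starts at/near the 5' end, ends before the loop
* 3'-tRNA half  — ends at/near the 3' end, starts inside the loop
* 3'-tRF        — ends at/near the 3' end, starts after the loop
* i-tRF         — anchored at neither end (or spanning past the loop)

"near" is controlled by an anchor tolerance ``anchor_tol`` (nt from the
tRNA end) and the loop window extends ``loop_pad`` nt on each side of the
3-nt anticodon. A read anchored at both ends is an intact tRNA, not a
fragment, and is rejected (returns None).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ParseError, ValidationError
from .io import ReferenceRecord

TSRNA_SUBTYPES = ("5p_half", "3p_half", "5p_tRF", "3p_tRF", "i_tRF")

FIVE_PRIME_SUBTYPES = ("5p_half", "5p_tRF")


@dataclass(frozen=True)
class TypingParams:
    """Window parameters for positional tsRNA typing (nt)."""

    loop_pad: int = 2
    anchor_tol: int = 3


DEFAULT_TYPING = TypingParams()


def classify_tsrna(
    interval: tuple[int, int],
    trna: ReferenceRecord,
    params: TypingParams = DEFAULT_TYPING,
) -> Optional[str]:
    """Type a fragment interval (0-based, half-open) on a mature tRNA.

    Returns one of TSRNA_SUBTYPES, or None for a near-full-length read
    (both ends anchored), which is not counted as a tsRNA.
    """
    if trna.anticodon_interval is None:
        raise ValidationError(f"reference {trna.id!r} is not an annotated tRNA")
    start, end = interval
    length = len(trna.sequence)
    if not (0 <= start < end <= length):
        raise ValidationError(
            f"interval ({start}, {end}) outside tRNA {trna.id!r} of length {length}"
        )
    a0, a1 = trna.anticodon_interval
    w0, w1 = a0 - params.loop_pad, a1 + params.loop_pad
    t = params.anchor_tol
    five_anchored = start < t
    three_anchored = end > length - t
    if five_anchored and three_anchored:
        return None
    if five_anchored:
        if w0 <= end < w1:
            return "5p_half"
        if end < w0:
            return "5p_tRF"
        return "i_tRF"
    if three_anchored:
        if w0 <= start < w1:
            return "3p_half"
        if start >= w1:
            return "3p_tRF"
        return "i_tRF"
    return "i_tRF"


# ---------------------------------------------------------------------------
# Canonical naming: <AminoAcidAnticodon>-<length>-<isoform>
# ---------------------------------------------------------------------------

_TSRNA_ID = re.compile(r"^([A-Za-z]{3}[ACGTacgt]{3})-(\d+)-(\d+)$")


def name_tsrna(
    features: Sequence[tuple[str, int, str, float]],
) -> list[str]:
    """Assign canonical identifiers to tsRNA features.

    ``features`` are tuples (trna_subtype_label, length, sequence, abundance),
    e.g. ("GlyGCC", 30, "GCATT...", 5421.0). Within each (subtype, length)
    group the isoform index is assigned by descending mean abundance, ties
    broken by sequence lexicographic order, so naming is stable under sample
    reordering. The isoform suffix is always emitted ("ThrTGT-38-1") so that
    identifiers stay injective even for singleton groups.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (label, length, seq, _ab) in enumerate(features):
        groups.setdefault((label, length), []).append(i)
    names = [""] * len(features)
    for (label, length), idxs in groups.items():
        seqs = {features[i][2] for i in idxs}
        if len(seqs) != len(idxs):
            raise ValidationError(
                f"duplicate sequences in tsRNA group ({label}, {length})"
            )
        ordered = sorted(idxs, key=lambda i: (-features[i][3], features[i][2]))
        for iso, i in enumerate(ordered, start=1):
            names[i] = f"{label}-{length}-{iso}"
    return names


def parse_tsrna_id(identifier: str) -> tuple[str, int, int]:
    """Parse "GlyGCC-30-1" -> ("GlyGCC", 30, 1)."""
    m = _TSRNA_ID.match(identifier)
    if not m:
        raise ParseError(f"malformed tsRNA identifier: {identifier!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))
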