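"""Typing and naming of rRNA-derived small RNAs (rsRNAs).

rsRNAs are typed solely by the rRNA precursor they derive from (5S, 5.8S,
18S, 28S or 45S) and named "<subtype>-<length>"; an abundance-ranked
isoform suffix is added only when distinct sequences collide on the same
(subtype, length) pair, which keeps the printed singleton names intact
while identifiers stay injective.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .errors import ParseError, ValidationError
from .io import RRNA_SUBTYPES, ReferenceRecord


def classify_rsrna(
    interval: tuple[int, int], rrna: ReferenceRecord
) -> tuple[str, int]:
    """Return (precursor subtype, fragment length) for an rRNA-aligned read."""
    if rrna.class_label != "rRNA":
        raise ValidationError(f"reference {rrna.id!r} is not an rRNA precursor")
    if rrna.subtype_label not in RRNA_SUBTYPES:
        raise ValidationError(
            f"rRNA {rrna.id!r}: invalid precursor subtype {rrna.subtype_label!r}"
        )
    start, end = interval
    if not (0 <= start < end <= len(rrna.sequence)):
        raise ValidationError(
            f"interval ({start}, {end}) outside rRNA {rrna.id!r}"
        )
    return rrna.subtype_label, end - start


_RSRNA_ID = re.compile(r"^(5S|5\.8S|18S|28S|45S)-(\d+)(?:-(\d+))?$")


def name_rsrna(
    features: Sequence[tuple[str, int, str, float]],
) -> list[str]:
    """Assign identifiers to rsRNA features.

    ``features`` are tuples (subtype, length, sequence, abundance). A
    singleton (subtype, length) group keeps the bare "28S-58" form;
    collisions get "-1", "-2", ... by descending abundance (ties by
    sequence).
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (subtype, length, seq, _ab) in enumerate(features):
        if subtype not in RRNA_SUBTYPES:
            raise ValidationError(f"invalid rRNA precursor subtype {subtype!r}")
        groups.setdefault((subtype, length), []).append(i)
    names = [""] * len(features)
    for (subtype, length), idxs in groups.items():
        seqs = {features[i][2] for i in idxs}
        if len(seqs) != len(idxs):
            raise ValidationError(
                f"duplicate sequences in rsRNA group ({subtype}, {length})"
            )
        if len(idxs) == 1:
            names[idxs[0]] = f"{subtype}-{length}"
            continue
        ordered = sorted(idxs, key=lambda i: (-features[i][3], features[i][2]))
        for iso, i in enumerate(ordered, start=1):
            names[i] = f"{subtype}-{length}-{iso}"
    return names


def parse_rsrna_id(identifier: str) -> tuple[str, int, int]:
    """Parse "28S-58" -> ("28S", 58, 1); "28S-20-2" -> ("28S", 20, 2)."""
    m = _RSRNA_ID.match(identifier)
    if not m:
        raise ParseError(f"malformed rsRNA identifier: {identifier!r}")
    return m.group(1), int(m.group(2)), int(m.group(3) or 1)
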