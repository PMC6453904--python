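"""Hierarchical exact-match annotation of reads to sncRNA classes.

Each read is matched, full-length and without mismatches, against the
references of one class at a time in a configurable hierarchy (default
miRNA -> tRNA -> rRNA -> piRNA); the first class with a hit wins. Matching
uses a k-mer anchor index (k = minimum read length): the read's first k-mer
nominates candidate (reference, offset) placements which are then verified
by direct comparison, so hits are exactly the substring occurrences a naive
scan would find.

Within the winning class, reads hitting both a mature rRNA subunit and the
45S precursor (which physically contains the subunits) are assigned to the
mature subunit. Remaining ties are broken by observed support (reads
assigned to each reference in the batch), then lexicographic reference id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .io import ReadBatch, ReferenceSet

DEFAULT_HIERARCHY = ("miRNA", "tRNA", "rRNA", "piRNA")


@dataclass(frozen=True, slots=True)
class ReadAnnotation:
    """One read's class assignment and placement on its reference."""

    read: str
    class_label: str                      # one of the four classes or "unannotated"
    reference_id: Optional[str] = None
    start: int = 0
    end: int = 0
    n_equivalent_hits: int = 0


class AnnotationIndex:
    """k-mer anchor index over a ReferenceSet, organized per class."""

    def __init__(
        self,
        refset: ReferenceSet,
        hierarchy: Sequence[str] = DEFAULT_HIERARCHY,
        k: int = 15,
        mismatch_budget: int = 0,
    ):
        if len(refset) == 0:
            raise ValidationError("cannot index an empty ReferenceSet")
        if sorted(hierarchy) != sorted(DEFAULT_HIERARCHY):
            raise ValidationError(
                f"hierarchy must be a permutation of {DEFAULT_HIERARCHY}"
            )
        if mismatch_budget != 0:
            raise NotImplementedError(
                "only exact matching (mismatch_budget=0) is implemented"
            )
        self.refset = refset
        self.hierarchy = tuple(hierarchy)
        self.k = k
        # kmer -> class -> list of (reference_id, offset); one lookup per
        # read resolves every class, so unannotatable reads fail fast
        self._index: dict[str, dict[str, list[tuple[str, int]]]] = {}
        for rec in refset.records.values():
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                entry = self._index.setdefault(seq[pos : pos + k], {})
                entry.setdefault(rec.class_label, []).append((rec.id, pos))

    def hits(self, read: str, class_label: str) -> list[tuple[str, int]]:
        """All exact full-length placements of ``read`` in one class."""
        if len(read) < self.k:
            return []
        entry = self._index.get(read[: self.k])
        if not entry:
            return []
        return self._verify(read, entry.get(class_label, ()))

    def _verify(self, read: str, candidates) -> list[tuple[str, int]]:
        out = []
        for rid, pos in candidates:
            if self.refset[rid].sequence[pos : pos + len(read)] == read:
                out.append((rid, pos))
        return out

    def first_hits(self, read: str) -> tuple[Optional[str], list[tuple[str, int]]]:
        """(winning class, its hits) in hierarchy order, or (None, [])."""
        if len(read) < self.k:
            return None, []
        entry = self._index.get(read[: self.k])
        if not entry:
            return None, []
        for class_label in self.hierarchy:
            cands = entry.get(class_label)
            if cands:
                hits = self._verify(read, cands)
                if hits:
                    return class_label, hits
        return None, []


def build_index(
    refset: ReferenceSet,
    hierarchy: Sequence[str] = DEFAULT_HIERARCHY,
    k: int = 15,
) -> AnnotationIndex:
    return AnnotationIndex(refset, hierarchy, k=k)


def _select_hits(
    index: AnnotationIndex,
    class_label: str,
    hits: list[tuple[str, int]],
    support: Optional[Mapping[str, int]],
) -> tuple[str, int, int]:
    """Pick (reference_id, start, n_equivalent_hits) among same-class hits."""
    if class_label == "rRNA":
        mature = [
            h for h in hits if index.refset[h[0]].subtype_label != "45S"
        ]
        if mature:
            hits = mature
    support = support or {}
    best_ref = min({rid for rid, _ in hits}, key=lambda r: (-support.get(r, 0), r))
    start = min(pos for rid, pos in hits if rid == best_ref)
    return best_ref, start, len(hits)


def annotate_read(
    read: str,
    index: AnnotationIndex,
    support: Optional[Mapping[str, int]] = None,
) -> ReadAnnotation:
    """Annotate one read by trying classes in hierarchy order."""
    class_label, hits = index.first_hits(read)
    if class_label is None:
        return ReadAnnotation(read=read, class_label="unannotated")
    rid, start, n_eq = _select_hits(index, class_label, hits, support)
    return ReadAnnotation(
        read=read,
        class_label=class_label,
        reference_id=rid,
        start=start,
        end=start + len(read),
        n_equivalent_hits=n_eq,
    )


@dataclass
class BatchAnnotation:
    """Annotations of a batch, collapsed over identical read sequences."""

    sample_id: str
    annotations: list[ReadAnnotation]
    multiplicities: list[int]
    class_counts: dict[str, int]
    surviving: int

    def iter_weighted(self) -> Iterable[tuple[ReadAnnotation, int]]:
        return zip(self.annotations, self.multiplicities)


def annotate_batch(batch: ReadBatch, index: AnnotationIndex) -> BatchAnnotation:
    """Annotate all reads of a batch.

    Two passes over the collapsed read sequences: the first tallies
    per-reference support (each candidate reference in a read's winning
    class receives the read's multiplicity), the second resolves
    multi-mapping reads toward the best-supported reference. Each read
    counts exactly once.
    """
    counts = Counter(batch.reads)
    uniq = sorted(counts)  # deterministic order
    winning: list[tuple[str, Optional[str], list[tuple[str, int]]]] = []
    support: dict[str, int] = {}
    for seq in uniq:
        hit_class, hits = index.first_hits(seq)
        winning.append((seq, hit_class, hits))
        if hit_class is not None:
            for rid in {r for r, _ in hits}:
                support[rid] = support.get(rid, 0) + counts[seq]

    annotations: list[ReadAnnotation] = []
    mults: list[int] = []
    class_counts: Counter = Counter({c: 0 for c in index.hierarchy})
    class_counts["unannotated"] = 0
    for seq, hit_class, hits in winning:
        if hit_class is None:
            ann = ReadAnnotation(read=seq, class_label="unannotated")
        else:
            rid, start, n_eq = _select_hits(index, hit_class, hits, support)
            ann = ReadAnnotation(
                read=seq,
                class_label=hit_class,
                reference_id=rid,
                start=start,
                end=start + len(seq),
                n_equivalent_hits=n_eq,
            )
        annotations.append(ann)
        mults.append(counts[seq])
        class_counts[ann.class_label] += counts[seq]
    return BatchAnnotation(
        sample_id=batch.sample_id,
        annotations=annotations,
        multiplicities=mults,
        class_counts=dict(class_counts),
        surviving=len(batch.reads),
    )
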