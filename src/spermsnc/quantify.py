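"""Count matrices, RPM normalization, expression floor, composition, grouping.

Feature identity: miRNA and piRNA reads are counted per reference (exact
mature sequences); tRNA- and rRNA-derived reads are counted per distinct
(reference, start, end) fragment, typed by the tsrna/rsrna modules and
named with their canonical identifiers across the whole cohort. Reads
annotated to a tRNA but rejected as near-full-length (intact tRNAs, not
fragments) are kept in a separate per-sample bucket so read bookkeeping
still balances.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import BatchAnnotation
from .errors import ValidationError
from .io import ReferenceSet
from .rsrna import classify_rsrna, name_rsrna
from .tsrna import DEFAULT_TYPING, FIVE_PRIME_SUBTYPES, TypingParams, classify_tsrna, name_tsrna

GROUP_HIGH = "H-GQE"
GROUP_LOW = "L-GQE"
GROUP_EXCLUDED = "excluded"

CLASS_TO_FEATURE_CLASS = {"tRNA": "tsRNA", "rRNA": "rsRNA", "miRNA": "miRNA", "piRNA": "piRNA"}


def assign_group(gqe_rate: float) -> str:
    """Map a good-quality-embryo rate to its cohort group.

    >= 0.75 -> H-GQE; <= 0.25 -> L-GQE; in between -> excluded (both
    boundaries inclusive).
    """
    if not (0.0 <= gqe_rate <= 1.0):
        raise ValidationError(f"gqe_rate {gqe_rate} outside [0, 1]")
    if gqe_rate >= 0.75:
        return GROUP_HIGH
    if gqe_rate <= 0.25:
        return GROUP_LOW
    return GROUP_EXCLUDED


@dataclass
class CountMatrix:
    """Features x samples raw counts with feature metadata.

    ``feature_meta`` is indexed by feature id with columns: class (tsRNA /
    rsRNA / miRNA / piRNA), subtype, reference_id, start, end, sequence.
    ``full_length_excluded`` counts tRNA-annotated reads rejected as intact
    tRNAs, per sample.
    """

    counts: pd.DataFrame
    feature_meta: pd.DataFrame
    full_length_excluded: pd.Series = None
    surviving: pd.Series = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.full_length_excluded is None:
            self.full_length_excluded = pd.Series(0, index=self.counts.columns)
        if not self.counts.index.is_unique:
            raise ValidationError("duplicate feature ids in count matrix")

    @property
    def denominators(self) -> pd.Series:
        """Annotated sncRNA reads per sample (sum of feature counts)."""
        return self.counts.sum(axis=0)


def aggregate_counts(
    batch_annotations: Mapping[str, BatchAnnotation],
    refset: ReferenceSet,
    typing_params: TypingParams = DEFAULT_TYPING,
) -> CountMatrix:
    """Build the cohort count matrix from per-sample annotations.

    All samples must be annotated against the same ReferenceSet. Canonical
    feature names are assigned on the full cohort (isoform indices ordered
    by cohort-mean relative abundance) so they are stable under sample
    reordering.
    """
    samples = list(batch_annotations)
    # key -> {sample: count}; key identifies the feature pre-naming
    counts: dict[tuple, dict[str, int]] = defaultdict(dict)
    meta: dict[tuple, dict] = {}
    full_length = pd.Series(0, index=samples, dtype=int)
    surviving = pd.Series(0, index=samples, dtype=int)

    for sample, ba in batch_annotations.items():
        surviving[sample] = ba.surviving
        for ann, mult in ba.iter_weighted():
            if ann.class_label == "unannotated":
                continue
            rec = refset[ann.reference_id]
            interval = (ann.start, ann.end)
            if ann.class_label == "tRNA":
                subtype = classify_tsrna(interval, rec, typing_params)
                if subtype is None:
                    full_length[sample] += mult
                    continue
                key = ("tsRNA", rec.id, ann.start, ann.end)
                meta[key] = {
                    "class": "tsRNA",
                    "subtype": subtype,
                    "group_label": rec.subtype_label,
                    "reference_id": rec.id,
                    "start": ann.start,
                    "end": ann.end,
                    "sequence": ann.read,
                }
            elif ann.class_label == "rRNA":
                rsub, _length = classify_rsrna(interval, rec)
                key = ("rsRNA", rec.id, ann.start, ann.end)
                meta[key] = {
                    "class": "rsRNA",
                    "subtype": rsub,
                    "group_label": rsub,
                    "reference_id": rec.id,
                    "start": ann.start,
                    "end": ann.end,
                    "sequence": ann.read,
                }
            else:  # miRNA / piRNA counted per mature reference
                fclass = CLASS_TO_FEATURE_CLASS[ann.class_label]
                key = (fclass, rec.id, 0, len(rec.sequence))
                meta[key] = {
                    "class": fclass,
                    "subtype": "",
                    "group_label": rec.id,
                    "reference_id": rec.id,
                    "start": ann.start,
                    "end": ann.end,
                    "sequence": ann.read,
                }
            counts[key][sample] = counts[key].get(sample, 0) + mult

    keys = sorted(counts)
    raw = pd.DataFrame(
        [[counts[k].get(s, 0) for s in samples] for k in keys],
        columns=samples,
        dtype=int,
    )
    # cohort-mean relative abundance drives isoform ordering
    denom = raw.sum(axis=0).replace(0, 1)
    mean_rel = (raw / denom).mean(axis=1).to_numpy()

    names = [""] * len(keys)
    for fclass, namer in (("tsRNA", name_tsrna), ("rsRNA", name_rsrna)):
        idxs = [i for i, k in enumerate(keys) if k[0] == fclass]
        feats = [
            (
                meta[keys[i]]["group_label"],
                meta[keys[i]]["end"] - meta[keys[i]]["start"],
                meta[keys[i]]["sequence"],
                float(mean_rel[i]),
            )
            for i in idxs
        ]
        for i, nm in zip(idxs, namer(feats)):
            names[i] = nm
    for i, k in enumerate(keys):
        if k[0] in ("miRNA", "piRNA"):
            names[i] = meta[k]["reference_id"]
    if len(set(names)) != len(names):
        raise ValidationError("feature naming produced duplicate identifiers")

    raw.index = pd.Index(names, name="feature")
    meta_df = pd.DataFrame(
        [meta[k] for k in keys], index=raw.index
    )[["class", "subtype", "reference_id", "start", "end", "sequence"]]
    order = raw.index.sort_values()
    return CountMatrix(
        counts=raw.loc[order],
        feature_meta=meta_df.loc[order],
        full_length_excluded=full_length,
        surviving=surviving,
    )


def rpm_normalize(
    matrix: CountMatrix, denominator_policy: str = "annotated"
) -> pd.DataFrame:
    """Reads-per-million view of a count matrix.

    Policies: "annotated" (default; denominator = annotated sncRNA reads in
    the sample, so columns sum to 1e6) or "surviving" (all reads that
    passed preprocessing).
    """
    if denominator_policy == "annotated":
        denom = matrix.denominators
    elif denominator_policy == "surviving":
        if matrix.surviving is None:
            raise ValidationError("surviving read counts not recorded")
        denom = matrix.surviving
    else:
        raise ValidationError(f"unknown denominator policy {denominator_policy!r}")
    zero = denom[denom <= 0]
    if len(zero):
        raise ValidationError(
            f"zero normalization denominator for sample(s) {list(zero.index)}"
        )
    return matrix.counts / denom * 1e6


def filter_by_mean_rpm(
    rpm: pd.DataFrame,
    threshold: float = 10.0,
    feature_meta: Optional[pd.DataFrame] = None,
    class_label: Optional[str] = None,
) -> pd.Index:
    """Features whose mean RPM across samples is strictly above threshold."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    sub = rpm
    if class_label is not None:
        if feature_meta is None:
            raise ValidationError("class restriction requires feature_meta")
        sub = rpm.loc[feature_meta["class"] == class_label]
    return sub.index[sub.mean(axis=1) > threshold]


def composition_summary(
    ba: BatchAnnotation,
    refset: ReferenceSet,
    typing_params: TypingParams = DEFAULT_TYPING,
) -> dict:
    """Per-sample class composition and subtype breakdowns (percent).

    Class percentages are taken over annotated reads and sum to 100;
    tsRNA-subtype and rsRNA-precursor shares sum to 100 within their class.
    A sample with zero annotated reads yields None percentages.
    """
    class_counts = {
        c: n for c, n in ba.class_counts.items() if c != "unannotated"
    }
    annotated = sum(class_counts.values())
    out = {
        "sample_id": ba.sample_id,
        "annotated": annotated,
        "unannotated": ba.class_counts.get("unannotated", 0),
    }
    if annotated == 0:
        out["class_pct"] = None
        return out
    out["class_pct"] = {
        CLASS_TO_FEATURE_CLASS[c]: 100.0 * n / annotated
        for c, n in class_counts.items()
    }
    # share of ALL reads (annotated + unannotated) — the convention behind
    # statements like "~56% of the sncRNAs annotated to tsRNAs"
    total = annotated + out["unannotated"]
    out["class_pct_total"] = {
        CLASS_TO_FEATURE_CLASS[c]: 100.0 * n / total for c, n in class_counts.items()
    }
    ts_sub: Counter = Counter()
    rs_sub: Counter = Counter()
    for ann, mult in ba.iter_weighted():
        if ann.class_label == "tRNA":
            sub = classify_tsrna((ann.start, ann.end), refset[ann.reference_id], typing_params)
            if sub is not None:
                ts_sub[sub] += mult
        elif ann.class_label == "rRNA":
            rsub, _ = classify_rsrna((ann.start, ann.end), refset[ann.reference_id])
            rs_sub[rsub] += mult
    ts_total = sum(ts_sub.values())
    rs_total = sum(rs_sub.values())
    out["tsrna_subtype_pct"] = (
        {k: 100.0 * v / ts_total for k, v in ts_sub.items()} if ts_total else {}
    )
    out["five_prime_tsrna_pct"] = (
        sum(out["tsrna_subtype_pct"].get(s, 0.0) for s in FIVE_PRIME_SUBTYPES)
        if ts_total
        else None
    )
    out["rsrna_subtype_pct"] = (
        {k: 100.0 * v / rs_total for k, v in rs_sub.items()} if rs_total else {}
    )
    return out


def length_distribution(ba: BatchAnnotation, class_label: str) -> dict[int, int]:
    """Histogram of read lengths for one annotated class of a sample."""
    internal = {v: k for k, v in CLASS_TO_FEATURE_CLASS.items()}.get(
        class_label, class_label
    )
    hist: Counter = Counter()
    for ann, mult in ba.iter_weighted():
        if ann.class_label == internal:
            hist[len(ann.read)] += mult
    return dict(hist)
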