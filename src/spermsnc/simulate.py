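"""Synthetic sperm small-RNA cohorts with known ground truth.

The generator emulates the structure the analysis assumes in a cohort of
two groups defined by good-quality-embryo (GQE) rate: H-GQE (rate >= 0.75,
n = 23) and L-GQE (rate <= 0.25, n = 64). Per sample, reads are drawn so
that on average ~56% annotate to tsRNAs, 18% to rsRNAs, 6% to miRNAs and
4% to piRNAs (the remainder is unannotatable random sequence), 5'-anchored
fragments dominate the tsRNAs, and the 28S precursor dominates the rsRNAs.

Count model: the per-sample read depth is split across classes by a
multinomial at the design composition; within a class, each feature's
relative weight is perturbed by a Gamma(1/dispersion, weight*dispersion)
draw (the mixing distribution of a negative binomial) and counts are drawn
multinomially from the perturbed weights. Features therefore show
gamma-Poisson-style overdispersion across samples while the per-sample
class composition stays binomially tight around the design values.

Group-differential "spiked" features have their weight multiplied by
2^(+-effect) in the L-GQE group; the truth table records the signed
log2 fold change (L over H) and per-group expected RPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import ReadBatch, ReferenceRecord, ReferenceSet, write_fastq, write_table
from .quantify import assign_group
from .tsrna import DEFAULT_TYPING, classify_tsrna

FEATURE_CLASSES = ("tsRNA", "rsRNA", "miRNA", "piRNA")

# anticodon labels; the first seven appear among the cohort's differential
# tsRNA features and are cycled through first
AA_ANTICODONS = (
    "GlyGCC", "ThrTGT", "GluTTC", "ProAGG", "ProTGG", "AsnATT", "ArgCCG",
    "AlaAGC", "AspGTC", "CysGCA", "GlnCTG", "GluCTC", "HisGTG", "IleAAT",
    "LeuCAG", "LysCTT", "MetCAT", "PheGAA", "SerGCT", "TrpCCA", "ValAAC",
    "TyrGTA", "ArgTCT", "SerAGA",
)

# desk-scale precursor lengths, ordered 5S < 5.8S < 18S < 28S (< 45S)
RRNA_LENGTHS = {"5S": 120, "5.8S": 155, "18S": 600, "28S": 1500}

# tsRNA fragment subtype mix: 5'-anchored mass 0.82 (halves 0.68), matching
# the dominance of 5' halves among sperm tsRNAs
TSRNA_SUBTYPE_PROBS = {
    "5p_half": 0.68,
    "5p_tRF": 0.14,
    "3p_half": 0.07,
    "3p_tRF": 0.05,
    "i_tRF": 0.06,
}

# rsRNA precursor mix: 28S carries >= 60% of rsRNA reads
RSRNA_SUBTYPE_PROBS = {"28S": 0.62, "18S": 0.18, "5.8S": 0.08, "5S": 0.07, "45S": 0.05}

_MIN_FRAG = 16


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_seq_block(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Batch of random reads with the given lengths (vectorized draw)."""
    if len(lengths) == 0:
        return []
    m = int(lengths.max())
    block = rng.integers(0, 4, size=(len(lengths), m), dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    chars = lut[block]
    return [chars[i, : lengths[i]].tobytes().decode() for i in range(len(lengths))]


# ---------------------------------------------------------------------------
# Toy references
# ---------------------------------------------------------------------------

def build_toy_references(
    n_trna: int = 21,
    n_mirna: int = 40,
    n_pirna: int = 30,
    seed: int = 0,
) -> ReferenceSet:
    """Deterministic toy reference set covering all four sncRNA classes.

    tRNAs are 70-90 nt with a 3-nt anticodon starting 32-38 nt from the 5'
    end (the triplet spelled into the sequence) and a 3' CCA; rRNA
    precursors are five records with 5S < 5.8S < 18S < 28S < 45S, the 45S
    built as spacers with the 18S/5.8S/28S sequences embedded (so reads
    from mature subunits also occur inside 45S, as in vivo); miRNAs are
    20-23 nt and piRNAs 26-31 nt mature sequences.
    """
    if min(n_trna, n_mirna, n_pirna) < 1:
        raise ValidationError("reference counts must be >= 1")
    rng = np.random.default_rng(seed)
    refset = ReferenceSet()
    for i in range(n_trna):
        label = AA_ANTICODONS[i % len(AA_ANTICODONS)]
        rid = f"tRNA-{label}" if i < len(AA_ANTICODONS) else f"tRNA-{label}-{i}"
        length = int(rng.integers(70, 91))
        seq = list(_random_seq(rng, length))
        a0 = int(rng.integers(32, 39))
        seq[a0 : a0 + 3] = list(label[3:].replace("U", "T"))
        seq[-3:] = list("CCA")
        refset.add(
            ReferenceRecord(
                id=rid,
                sequence="".join(seq),
                class_label="tRNA",
                subtype_label=label,
                anticodon_interval=(a0, a0 + 3),
            )
        )
    mature = {}
    for sub, length in RRNA_LENGTHS.items():
        mature[sub] = _random_seq(rng, length)
        refset.add(
            ReferenceRecord(
                id=f"rRNA-{sub}", sequence=mature[sub], class_label="rRNA",
                subtype_label=sub,
            )
        )
    spacers = [_random_seq(rng, 80) for _ in range(4)]
    seq_45s = (
        spacers[0] + mature["18S"] + spacers[1] + mature["5.8S"]
        + spacers[2] + mature["28S"] + spacers[3]
    )
    refset.add(
        ReferenceRecord(
            id="rRNA-45S", sequence=seq_45s, class_label="rRNA", subtype_label="45S"
        )
    )
    for i in range(n_mirna):
        refset.add(
            ReferenceRecord(
                id=f"miR-{i + 1}",
                sequence=_random_seq(rng, int(rng.integers(20, 24))),
                class_label="miRNA",
            )
        )
    for i in range(n_pirna):
        refset.add(
            ReferenceRecord(
                id=f"piR-{i + 1}",
                sequence=_random_seq(rng, int(rng.integers(26, 32))),
                class_label="piRNA",
            )
        )
    return refset


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikedFeature:
    feature_id: str
    class_label: str
    log2_effect: float      # magnitude, > 0
    direction: str          # "up" / "down" in the L-GQE group


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a simulated two-group cohort."""

    n_high: int = 23
    n_low: int = 64
    gqe_high_range: tuple[float, float] = (0.75, 1.0)
    gqe_low_range: tuple[float, float] = (0.02, 0.25)
    composition: tuple[tuple[str, float], ...] = (
        ("tsRNA", 0.56), ("rsRNA", 0.18), ("miRNA", 0.06), ("piRNA", 0.04),
    )
    spiked_features: tuple[SpikedFeature, ...] = ()
    dispersion: float = 0.1
    depth_range: tuple[int, int] = (100_000, 300_000)
    seed: int = 0

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if any(f < 0 for f in comp.values()) or sum(comp.values()) > 1 + 1e-12:
            raise ValidationError("composition fractions must be >= 0 and sum <= 1")
        lo, hi = self.gqe_high_range
        if not (0.75 <= lo <= hi <= 1.0):
            raise ValidationError("gqe_high_range must lie within [0.75, 1]")
        lo, hi = self.gqe_low_range
        if not (0.0 <= lo <= hi <= 0.25):
            raise ValidationError("gqe_low_range must lie within [0, 0.25]")
        if min(self.n_high, self.n_low) < 2:
            raise ValidationError("need at least 2 samples per group")

    @property
    def composition_dict(self) -> dict[str, float]:
        return dict(self.composition)


# ---------------------------------------------------------------------------
# Feature catalog (the latent features reads are drawn from)
# ---------------------------------------------------------------------------

def _draw_ts_interval(
    rng: np.random.Generator, subtype: str, trna: ReferenceRecord
) -> Optional[tuple[int, int]]:
    """One fragment interval that types as ``subtype`` under default windows."""
    L = len(trna.sequence)
    a0, a1 = trna.anticodon_interval
    pad, t = DEFAULT_TYPING.loop_pad, DEFAULT_TYPING.anchor_tol
    w0, w1 = a0 - pad, a1 + pad
    if subtype == "5p_half":
        start = int(rng.integers(0, t))
        end = int(rng.integers(max(w0, start + _MIN_FRAG), w1))
    elif subtype == "5p_tRF":
        start = int(rng.integers(0, t))
        end = int(rng.integers(start + _MIN_FRAG, w0))
    elif subtype == "3p_half":
        end = L - int(rng.integers(0, t))
        start = int(rng.integers(w0, w1))
    elif subtype == "3p_tRF":
        end = L - int(rng.integers(0, t))
        start = int(rng.integers(w1, end - _MIN_FRAG + 1))
    else:  # i_tRF
        start = int(rng.integers(t, L - t - _MIN_FRAG - 12))
        end = start + int(rng.integers(_MIN_FRAG + 2, _MIN_FRAG + 14))
    if not (0 <= start < end <= L):
        return None
    if classify_tsrna((start, end), trna) != subtype:
        return None
    return start, end


def build_feature_catalog(
    refset: ReferenceSet,
    seed: int,
    n_tsrna_per_trna: int = 6,
    n_rsrna: int = 60,
) -> pd.DataFrame:
    """Latent feature table: id, class, reference, interval, subtype, weight.

    Within-class weights are log-normal (sigma = 1) and normalized to sum
    to one; tsRNA fragment subtypes follow TSRNA_SUBTYPE_PROBS, rsRNA
    precursors follow RSRNA_SUBTYPE_PROBS. Deterministic given
    (refset, seed).
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    seen_seqs: set[str] = set()

    def push(fid, fclass, rec, start, end, subtype) -> bool:
        seq = rec.sequence[start:end]
        if seq in seen_seqs:
            return False
        seen_seqs.add(seq)
        rows.append(
            {
                "feature_id": fid, "class": fclass, "reference_id": rec.id,
                "subtype": subtype, "start": start, "end": end, "sequence": seq,
                "weight": float(rng.lognormal(0.0, 1.0)),
            }
        )
        return True

    subs, probs = zip(*TSRNA_SUBTYPE_PROBS.items())
    for rec in refset.by_class("tRNA"):
        made = 0
        attempts = 0
        while made < n_tsrna_per_trna and attempts < 50 * n_tsrna_per_trna:
            attempts += 1
            sub = subs[rng.choice(len(subs), p=probs)]
            iv = _draw_ts_interval(rng, sub, rec)
            if iv is None:
                continue
            if push(f"ts:{rec.id}:{iv[0]}-{iv[1]}", "tsRNA", rec, iv[0], iv[1], sub):
                made += 1

    rsubs, rprobs = zip(*RSRNA_SUBTYPE_PROBS.items())
    by_sub = {r.subtype_label: r for r in refset.by_class("rRNA")}
    missing = set(rsubs) - set(by_sub)
    if missing:
        raise ConfigError(f"reference set lacks rRNA precursors: {sorted(missing)}")
    made = 0
    attempts = 0
    while made < n_rsrna and attempts < 50 * n_rsrna:
        attempts += 1
        sub = rsubs[rng.choice(len(rsubs), p=rprobs)]
        rec = by_sub[sub]
        length = int(rng.integers(17, 41))
        if sub == "45S":
            # spacer region only: fragments unique to the 45S precursor
            start = int(rng.integers(0, 80 - length))
        else:
            start = int(rng.integers(0, len(rec.sequence) - length + 1))
        if push(f"rs:{rec.id}:{start}-{start + length}", "rsRNA", rec,
                start, start + length, sub):
            made += 1

    for rec in refset.by_class("miRNA"):
        push(rec.id, "miRNA", rec, 0, len(rec.sequence), "")
    for rec in refset.by_class("piRNA"):
        push(rec.id, "piRNA", rec, 0, len(rec.sequence), "")

    cat = pd.DataFrame(rows).set_index("feature_id")
    for fclass in FEATURE_CLASSES:
        mask = cat["class"] == fclass
        cat.loc[mask, "weight"] /= cat.loc[mask, "weight"].sum()
    # weights drawn per class above but reads per class also scale with the
    # rsRNA precursor / tsRNA subtype mixes; fold those in so expected shares
    # match the stated probabilities
    for fclass, mix in (("tsRNA", TSRNA_SUBTYPE_PROBS), ("rsRNA", RSRNA_SUBTYPE_PROBS)):
        cls = cat["class"] == fclass
        for sub, p in mix.items():
            m = cls & (cat["subtype"] == sub)
            tot = cat.loc[m, "weight"].sum()
            if tot > 0:
                cat.loc[m, "weight"] *= p / tot
        cat.loc[cls, "weight"] /= cat.loc[cls, "weight"].sum()
    return cat


def default_spikes(
    catalog: pd.DataFrame,
    log2_effect: float = 2.0,
) -> tuple[SpikedFeature, ...]:
    """Default group-differential features, mirroring the cohort's structure:
    10 tsRNAs (5 down / 5 up in L-GQE), 7 rsRNAs (6 down / 1 up) and
    5 miRNAs (3 down / 2 up), all at |log2FC| = log2_effect.

    Spikes are taken from mid-abundance ranks so that their combined weight
    share stays small and within-class renormalization barely biases the
    realized fold changes.
    """
    plan = {"tsRNA": (30, 10, 5), "rsRNA": (15, 7, 6), "miRNA": (10, 5, 3)}
    spikes: list[SpikedFeature] = []
    for fclass, (rank0, n, n_down) in plan.items():
        sub = catalog[catalog["class"] == fclass].sort_values(
            "weight", ascending=False
        )
        rank0 = min(rank0, max(0, len(sub) - n))
        chosen = sub.index[rank0 : rank0 + n]
        for i, fid in enumerate(chosen):
            spikes.append(
                SpikedFeature(
                    feature_id=fid,
                    class_label=fclass,
                    log2_effect=log2_effect,
                    direction="down" if i < n_down else "up",
                )
            )
    return tuple(spikes)


def default_design(refset: ReferenceSet, seed: int = 0, **overrides) -> CohortDesign:
    """The study-condition design (23 vs 64 samples) with default spikes."""
    base = CohortDesign(seed=seed)
    catalog = build_feature_catalog(refset, seed)
    design = replace(base, spiked_features=default_spikes(catalog), **overrides)
    return design


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _group_weights(
    catalog: pd.DataFrame, design: CohortDesign, group: str
) -> pd.Series:
    """Per-feature weights with spike multipliers applied (un-normalized)."""
    w = catalog["weight"].copy()
    if group == "L-GQE":
        for sp in design.spiked_features:
            if sp.feature_id not in w.index:
                raise ConfigError(f"spiked feature {sp.feature_id!r} not in catalog")
            mult = 2.0 ** (sp.log2_effect if sp.direction == "up" else -sp.log2_effect)
            w[sp.feature_id] *= mult
    return w


def simulate_sample(
    refset: ReferenceSet,
    design: CohortDesign,
    gqe_rate: float,
    group: str,
    sample_seed: int,
    sample_id: str = "sample",
    catalog: Optional[pd.DataFrame] = None,
    emit_reads: bool = True,
) -> tuple[Optional[ReadBatch], pd.Series]:
    """Draw one sample's reads and per-feature true counts.

    Deterministic given (refset, design, sample_seed). With
    ``emit_reads=False`` only the true counts are returned (fast path).
    """
    if catalog is None:
        catalog = build_feature_catalog(refset, design.seed)
    comp = design.composition_dict
    missing = [c for c in comp if not (catalog["class"] == c).any()]
    if missing:
        raise ConfigError(f"composition classes missing from references: {missing}")
    rng = np.random.default_rng(sample_seed)
    depth = int(rng.integers(design.depth_range[0], design.depth_range[1] + 1))
    classes = list(comp)
    fracs = np.array([comp[c] for c in classes] + [1.0 - sum(comp.values())])
    n_per = rng.multinomial(depth, fracs)

    w_all = _group_weights(catalog, design, group)
    counts = pd.Series(0, index=catalog.index, dtype=int)
    for c, n_c in zip(classes, n_per[: len(classes)]):
        idx = catalog.index[catalog["class"] == c]
        w = w_all[idx].to_numpy()
        if design.dispersion > 0:
            # Gamma(1/disp, scale=w*disp): mean w, variance disp*w^2
            shape = 1.0 / design.dispersion
            g = rng.gamma(shape, w * design.dispersion)
        else:
            g = w
        counts[idx] = rng.multinomial(int(n_c), g / g.sum())

    batch = None
    if emit_reads:
        reads: list[str] = []
        seqs = catalog["sequence"]
        for fid, n in counts.items():
            if n:
                reads.extend([seqs[fid]] * int(n))
        n_un = int(n_per[-1])
        reads.extend(_random_seq_block(rng, rng.integers(18, 41, size=n_un)))
        batch = ReadBatch(sample_id=sample_id, reads=reads)
        batch.log.input = len(reads)
        batch.log.surviving = len(reads)
    return batch, counts


@dataclass
class CohortData:
    """In-memory result of a cohort simulation."""

    batches: dict[str, Optional[ReadBatch]]
    true_counts: pd.DataFrame            # features x samples
    metadata: pd.DataFrame               # sample_id, gqe_rate, group
    truth: pd.DataFrame                  # per-feature truth table
    catalog: pd.DataFrame


def _truth_table(catalog: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    comp = design.composition_dict
    annotated_frac = sum(comp.values())
    truth = catalog.copy()
    spiked = {sp.feature_id: sp for sp in design.spiked_features}
    truth["spiked"] = truth.index.map(lambda f: f in spiked)
    truth["log2fc"] = truth.index.map(
        lambda f: (
            spiked[f].log2_effect if spiked[f].direction == "up" else -spiked[f].log2_effect
        )
        if f in spiked
        else 0.0
    )
    for group, col in (("H-GQE", "expected_rpm_H"), ("L-GQE", "expected_rpm_L")):
        w = _group_weights(catalog, design, group)
        vals = pd.Series(0.0, index=truth.index)
        for c, frac in comp.items():
            idx = catalog.index[catalog["class"] == c]
            vals[idx] = frac * (w[idx] / w[idx].sum()) / annotated_frac * 1e6
        truth[col] = vals
    return truth


def simulate_cohort(
    refset: ReferenceSet,
    design: CohortDesign,
    out_dir: Optional[str | Path] = None,
    emit_reads: bool = True,
) -> CohortData:
    """Simulate the full two-group cohort.

    Sample ids are H01.. / L01..; GQE rates are uniform in the group's
    range and group labels are re-derived from the rate via assign_group
    (consistent by construction). With ``out_dir`` set, per-sample
    FASTQ.gz files plus metadata and truth TSVs are written.
    """
    catalog = build_feature_catalog(refset, design.seed)
    rng = np.random.default_rng(design.seed)
    plan: list[tuple[str, float, str]] = []
    for i in range(design.n_high):
        plan.append((f"H{i + 1:02d}", float(rng.uniform(*design.gqe_high_range)), "H-GQE"))
    for i in range(design.n_low):
        plan.append((f"L{i + 1:02d}", float(rng.uniform(*design.gqe_low_range)), "L-GQE"))
    sample_seeds = rng.integers(0, 2**31, size=len(plan))

    batches: dict[str, Optional[ReadBatch]] = {}
    count_cols: dict[str, pd.Series] = {}
    meta_rows = []
    for (sid, gqe, group), sseed in zip(plan, sample_seeds):
        batch, counts = simulate_sample(
            refset, design, gqe, group, int(sseed), sample_id=sid,
            catalog=catalog, emit_reads=emit_reads,
        )
        batches[sid] = batch
        count_cols[sid] = counts
        derived = assign_group(gqe)
        if derived != group:
            raise ValidationError(f"sample {sid}: group {group} != derived {derived}")
        meta_rows.append({"sample_id": sid, "gqe_rate": gqe, "group": group})

    true_counts = pd.DataFrame(count_cols)
    metadata = pd.DataFrame(meta_rows)
    truth = _truth_table(catalog, design)
    data = CohortData(
        batches=batches, true_counts=true_counts, metadata=metadata,
        truth=truth, catalog=catalog,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if emit_reads:
            for sid, batch in batches.items():
                write_fastq(batch, out / f"{sid}.fastq.gz")
        write_table(metadata, out / "metadata.tsv")
        write_table(truth.reset_index(), out / "truth.tsv")
    return data
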