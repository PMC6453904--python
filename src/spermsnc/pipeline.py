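"""Stage orchestration: file-based stages with manifests, plus an
in-memory end-to-end analysis used programmatically.

Run-directory layout (all TSV/JSON/FASTA/FASTQ.gz, reproducible bytes):

    references/             refs_<class>.fasta (+ trna_anticodons.tsv)
    reads/                  <sample>.fastq.gz, metadata.tsv, truth.tsv
    preprocessed/           <sample>.fastq.gz, preprocess_log.tsv
    annotations/            <sample>.tsv, class_counts.tsv
    quantified/             counts.tsv, feature_meta.tsv, rpm.tsv, composition.tsv
    diffexp/                de_<class>.tsv
    multivariate/           pca_scores_<class>.tsv, variance_<class>.tsv,
                            roc_<class>.tsv, auc_summary.tsv
    manifests/              <stage>.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from .annotate import BatchAnnotation, ReadAnnotation, build_index, annotate_batch
from .config import PipelineConfig
from .diffexp import differential_features
from .errors import PipelineError, ValidationError
from .multivariate import evaluate_panel
from .quantify import (
    CountMatrix,
    aggregate_counts,
    assign_group,
    composition_summary,
    filter_by_mean_rpm,
    rpm_normalize,
)
from .simulate import CohortDesign, build_toy_references, default_spikes, build_feature_catalog, simulate_cohort
from .tsrna import TypingParams

logger = logging.getLogger("spermsnc")

PANEL_CLASSES = ("tsRNA", "rsRNA", "miRNA")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, params: dict, inputs: list[Path],
                    outputs: list[Path]) -> None:
    mdir = out / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {str(p.relative_to(out)): _sha256(p) for p in inputs},
        "outputs": [str(p.relative_to(out)) for p in outputs],
    }
    with open(mdir / f"{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(paths: list[Path], stage: str) -> None:
    for p in paths:
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r}: missing upstream output {p} — run the "
                "preceding stage first"
            )


def _design_from_config(cfg: PipelineConfig, refset) -> CohortDesign:
    base = CohortDesign(
        n_high=cfg.cohort.n_high,
        n_low=cfg.cohort.n_low,
        dispersion=cfg.cohort.dispersion,
        depth_range=(cfg.cohort.depth_min, cfg.cohort.depth_max),
        seed=cfg.seed,
    )
    catalog = build_feature_catalog(refset, cfg.seed)
    import dataclasses
    return dataclasses.replace(
        base, spiked_features=default_spikes(catalog, cfg.cohort.spike_log2fc)
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    t0 = time.time()
    refset = build_toy_references(
        cfg.references.n_trna, cfg.references.n_mirna, cfg.references.n_pirna,
        seed=cfg.seed,
    )
    design = _design_from_config(cfg, refset)
    rdir = out / "references"
    rdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for class_label, fname in (("tRNA", "refs_trna.fasta"), ("rRNA", "refs_rrna.fasta"),
                               ("miRNA", "refs_mirna.fasta"), ("piRNA", "refs_pirna.fasta")):
        sub = sio.ReferenceSet()
        for rec in refset.by_class(class_label):
            sub.add(rec)
        sio.write_fasta(sub, rdir / fname)
        outputs.append(rdir / fname)
    ac = pd.DataFrame(
        [
            {
                "id": r.id,
                "anticodon_start": r.anticodon_interval[0],
                "anticodon_end": r.anticodon_interval[1],
                "subtype_label": r.subtype_label,
            }
            for r in refset.by_class("tRNA")
        ]
    )
    sio.write_table(ac, rdir / "trna_anticodons.tsv")
    outputs.append(rdir / "trna_anticodons.tsv")

    reads_dir = out / "reads"
    simulate_cohort(refset, design, out_dir=reads_dir)
    outputs += sorted(reads_dir.glob("*.fastq.gz"))
    outputs += [reads_dir / "metadata.tsv", reads_dir / "truth.tsv"]
    _write_manifest(out, "simulate", {"seed": cfg.seed, "design": str(design)},
                    [], outputs)
    logger.info("simulate: %d files in %.1fs", len(outputs), time.time() - t0)


def _load_references(out: Path) -> sio.ReferenceSet:
    rdir = out / "references"
    _require([rdir / "refs_trna.fasta", rdir / "trna_anticodons.tsv"], "annotate")
    refset = sio.ReferenceSet()
    refset.update(
        sio.read_fasta(rdir / "refs_trna.fasta", "tRNA",
                       anticodon_table=sio.read_anticodon_table(rdir / "trna_anticodons.tsv"))
    )
    refset.update(
        sio.read_fasta(rdir / "refs_rrna.fasta", "rRNA",
                       subtype_parser=lambda rid: rid.split("-", 1)[1])
    )
    refset.update(sio.read_fasta(rdir / "refs_mirna.fasta", "miRNA"))
    refset.update(sio.read_fasta(rdir / "refs_pirna.fasta", "piRNA"))
    return refset


def run_preprocess(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    reads_dir = out / "reads"
    _require([reads_dir / "metadata.tsv"], "preprocess")
    pdir = out / "preprocessed"
    pdir.mkdir(parents=True, exist_ok=True)
    p = cfg.preprocess
    log_rows = []
    outputs = []
    inputs = sorted(reads_dir.glob("*.fastq.gz"))
    for fq in inputs:
        sid = fq.name.removesuffix(".fastq.gz")
        batch = sio.read_fastq(fq, sid)
        pre = sio.preprocess_reads(
            batch, adapter=p.adapter or None, min_len=p.min_len, max_len=p.max_len,
            min_mean_qual=p.min_mean_qual, seed_len=p.seed_len,
            max_mismatch=p.max_mismatch,
        )
        sio.write_fastq(pre, pdir / fq.name)
        outputs.append(pdir / fq.name)
        log_rows.append({"sample_id": sid, **pre.log.__dict__})
    sio.write_table(pd.DataFrame(log_rows), pdir / "preprocess_log.tsv")
    outputs.append(pdir / "preprocess_log.tsv")
    _write_manifest(out, "preprocess", {"preprocess": cfg.preprocess.__dict__},
                    inputs, outputs)


def run_annotate(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    pdir = out / "preprocessed"
    _require([pdir / "preprocess_log.tsv"], "annotate")
    refset = _load_references(out)
    index = build_index(refset, tuple(cfg.annotation.hierarchy), k=cfg.annotation.kmer)
    adir = out / "annotations"
    adir.mkdir(parents=True, exist_ok=True)
    inputs = sorted(pdir.glob("*.fastq.gz"))
    outputs = []
    cc_rows = []
    for fq in inputs:
        sid = fq.name.removesuffix(".fastq.gz")
        batch = sio.read_fastq(fq, sid)
        ba = annotate_batch(batch, index)
        df = pd.DataFrame(
            [
                {
                    "sequence": ann.read,
                    "count": mult,
                    "class": ann.class_label,
                    "reference_id": ann.reference_id or "",
                    "start": ann.start,
                    "end": ann.end,
                    "n_equivalent_hits": ann.n_equivalent_hits,
                }
                for ann, mult in ba.iter_weighted()
            ]
        )
        sio.write_table(df, adir / f"{sid}.tsv")
        outputs.append(adir / f"{sid}.tsv")
        cc_rows.append({"sample_id": sid, "surviving": ba.surviving, **ba.class_counts})
    sio.write_table(pd.DataFrame(cc_rows), adir / "class_counts.tsv")
    outputs.append(adir / "class_counts.tsv")
    _write_manifest(out, "annotate", {"annotation": cfg.annotation.__dict__},
                    inputs, outputs)


def _load_batch_annotations(out: Path) -> dict[str, BatchAnnotation]:
    adir = out / "annotations"
    _require([adir / "class_counts.tsv"], "quantify")
    cc = sio.read_table(adir / "class_counts.tsv", required=("sample_id", "surviving"))
    result = {}
    for _, row in cc.iterrows():
        sid = row["sample_id"]
        df = sio.read_table(adir / f"{sid}.tsv",
                            required=("sequence", "count", "class"))
        anns, mults = [], []
        for _, r in df.iterrows():
            anns.append(
                ReadAnnotation(
                    read=r["sequence"], class_label=r["class"],
                    reference_id=r["reference_id"] or None,
                    start=int(r["start"]), end=int(r["end"]),
                    n_equivalent_hits=int(r["n_equivalent_hits"]),
                )
            )
            mults.append(int(r["count"]))
        class_counts = {
            c: int(row[c]) for c in ("miRNA", "tRNA", "rRNA", "piRNA", "unannotated")
            if c in row
        }
        result[sid] = BatchAnnotation(
            sample_id=sid, annotations=anns, multiplicities=mults,
            class_counts=class_counts, surviving=int(row["surviving"]),
        )
    return result


def run_type(cfg: PipelineConfig) -> None:
    """Type tRNA/rRNA fragments, name features, build the raw count matrix."""
    out = Path(cfg.output_dir)
    refset = _load_references(out)
    bas = _load_batch_annotations(out)
    tp = TypingParams(cfg.typing.loop_pad, cfg.typing.anchor_tol)
    cm = aggregate_counts(bas, refset, tp)
    qdir = out / "quantified"
    qdir.mkdir(parents=True, exist_ok=True)
    sio.write_matrix(cm.counts, qdir / "counts.tsv")
    meta = cm.feature_meta.copy()
    meta.index.name = "feature"
    meta.to_csv(qdir / "feature_meta.tsv", sep="\t")
    extras = pd.DataFrame(
        {
            "sample_id": cm.counts.columns,
            "full_length_excluded": cm.full_length_excluded.values,
            "surviving": cm.surviving.values,
        }
    )
    sio.write_table(extras, qdir / "sample_bookkeeping.tsv")
    _write_manifest(out, "type", {"typing": cfg.typing.__dict__},
                    sorted((out / "annotations").glob("*.tsv")),
                    [qdir / "counts.tsv", qdir / "feature_meta.tsv",
                     qdir / "sample_bookkeeping.tsv"])


def run_quantify(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    qdir = out / "quantified"
    _require([qdir / "counts.tsv", qdir / "feature_meta.tsv"], "quantify")
    counts = sio.read_matrix(qdir / "counts.tsv")
    meta = pd.read_csv(qdir / "feature_meta.tsv", sep="\t", index_col=0)
    book = sio.read_table(qdir / "sample_bookkeeping.tsv",
                          required=("sample_id", "surviving"))
    cm = CountMatrix(
        counts=counts, feature_meta=meta,
        full_length_excluded=pd.Series(
            book["full_length_excluded"].values, index=book["sample_id"]),
        surviving=pd.Series(book["surviving"].values, index=book["sample_id"]),
    )
    rpm = rpm_normalize(cm, cfg.quantify.denominator)
    sio.write_matrix(rpm, qdir / "rpm.tsv")

    refset = _load_references(out)
    bas = _load_batch_annotations(out)
    tp = TypingParams(cfg.typing.loop_pad, cfg.typing.anchor_tol)
    comp_rows = []
    for sid, ba in bas.items():
        s = composition_summary(ba, refset, tp)
        row = {"sample_id": sid, "annotated": s["annotated"],
               "unannotated": s["unannotated"]}
        if s["class_pct"]:
            for c, v in s["class_pct"].items():
                row[f"pct_{c}"] = v
            row["pct_five_prime_tsrna"] = s["five_prime_tsrna_pct"]
            for c, v in s["rsrna_subtype_pct"].items():
                row[f"pct_rsrna_{c}"] = v
        comp_rows.append(row)
    sio.write_table(pd.DataFrame(comp_rows), qdir / "composition.tsv")

    meta_path = out / "reads" / "metadata.tsv"
    md = sio.read_table(meta_path, required=("sample_id", "gqe_rate"))
    md["group"] = md["gqe_rate"].map(assign_group)
    sio.write_table(md, qdir / "groups.tsv")
    _write_manifest(out, "quantify", {"quantify": cfg.quantify.__dict__},
                    [qdir / "counts.tsv"],
                    [qdir / "rpm.tsv", qdir / "composition.tsv", qdir / "groups.tsv"])


def run_diffexp(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    qdir = out / "quantified"
    _require([qdir / "rpm.tsv", qdir / "groups.tsv"], "diffexp")
    rpm = sio.read_matrix(qdir / "rpm.tsv")
    meta = pd.read_csv(qdir / "feature_meta.tsv", sep="\t", index_col=0)
    md = sio.read_table(qdir / "groups.tsv", required=("sample_id", "group"))
    groups = pd.Series(md["group"].values, index=md["sample_id"])
    n_h = (groups == "H-GQE").sum()
    n_l = (groups == "L-GQE").sum()
    if min(n_h, n_l) < 5:
        logger.warning(
            "diffexp: small group sizes (%d vs %d) — low statistical power",
            n_h, n_l,
        )
    ddir = out / "diffexp"
    ddir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for fclass in PANEL_CLASSES:
        kept = filter_by_mean_rpm(rpm, cfg.quantify.rpm_floor, meta, fclass)
        de = differential_features(
            rpm.loc[kept], groups, class_labels=meta["class"],
            fdr=cfg.diffexp.fdr, min_abs_log2fc=cfg.diffexp.min_abs_log2fc,
            pseudocount=cfg.diffexp.pseudocount, test=cfg.diffexp.test,
        )
        sio.write_table(de, ddir / f"de_{fclass}.tsv")
        outputs.append(ddir / f"de_{fclass}.tsv")
    _write_manifest(out, "diffexp", {"diffexp": cfg.diffexp.__dict__},
                    [qdir / "rpm.tsv"], outputs)


def select_panel(de: pd.DataFrame, max_panel: int = 10) -> list[str]:
    """Biomarker panel = significant DE features (top max_panel by adjusted p)."""
    sig = de[de["significant"]]
    return list(sig["feature"].head(max_panel))


def run_multivariate(cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    qdir, ddir = out / "quantified", out / "diffexp"
    _require([qdir / "rpm.tsv", ddir / "de_tsRNA.tsv"], "multivariate")
    rpm = sio.read_matrix(qdir / "rpm.tsv")
    md = sio.read_table(qdir / "groups.tsv", required=("sample_id", "group"))
    groups = pd.Series(md["group"].values, index=md["sample_id"])
    mdir = out / "multivariate"
    mdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    auc_rows = []
    for fclass in PANEL_CLASSES:
        de = sio.read_table(ddir / f"de_{fclass}.tsv")
        panel = select_panel(de, cfg.multivariate.max_panel)
        if len(panel) < 1:
            logger.warning("multivariate: no significant %s features — skipped", fclass)
            continue
        res = evaluate_panel(rpm, panel, groups, C=cfg.multivariate.C,
                             scale=cfg.multivariate.scale)
        scores = pd.DataFrame(
            res["pca"].scores[:, :2], columns=["PC1", "PC2"],
            index=res["panel"].samples,
        )
        scores["group"] = res["panel"].labels
        scores.index.name = "sample_id"
        scores.to_csv(mdir / f"pca_scores_{fclass}.tsv", sep="\t",
                      float_format="%.12g")
        var = pd.DataFrame(
            {
                "component": np.arange(1, len(res["pca"].variance_explained) + 1),
                "variance_explained_pct": res["pca"].variance_explained,
            }
        )
        sio.write_table(var, mdir / f"variance_{fclass}.tsv")
        roc = res["roc_loo"]
        sio.write_table(
            pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}),
            mdir / f"roc_{fclass}.tsv",
        )
        auc_rows.append(
            {
                "class": fclass,
                "panel_size": len(panel),
                "auc_loo": res["roc_loo"].auc,
                "auc_resubstitution": res["roc_resub"].auc,
                "pc1_variance_pct": res["pca"].variance_explained[0],
                "pc2_variance_pct": (
                    res["pca"].variance_explained[1]
                    if len(res["pca"].variance_explained) > 1 else float("nan")
                ),
            }
        )
        outputs += [mdir / f"pca_scores_{fclass}.tsv", mdir / f"variance_{fclass}.tsv",
                    mdir / f"roc_{fclass}.tsv"]
    auc_df = pd.DataFrame(
        auc_rows,
        columns=["class", "panel_size", "auc_loo", "auc_resubstitution",
                 "pc1_variance_pct", "pc2_variance_pct"],
    )
    sio.write_table(auc_df, mdir / "auc_summary.tsv")
    outputs.append(mdir / "auc_summary.tsv")
    _write_manifest(out, "multivariate", {"multivariate": cfg.multivariate.__dict__},
                    [qdir / "rpm.tsv"], outputs)


def run_report(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    _require([out / "multivariate" / "auc_summary.tsv"], "report")
    comp = sio.read_table(out / "quantified" / "composition.tsv")
    auc = sio.read_table(out / "multivariate" / "auc_summary.tsv")
    de_counts = {}
    for fclass in PANEL_CLASSES:
        path = out / "diffexp" / f"de_{fclass}.tsv"
        try:
            de = sio.read_table(path)
        except pd.errors.EmptyDataError:
            de = pd.DataFrame()
        de_counts[fclass] = int(de["significant"].sum()) if len(de) else 0
    report = {
        "n_samples": int(len(comp)),
        "mean_composition_pct": {
            c: float(comp[f"pct_{c}"].mean())
            for c in ("tsRNA", "rsRNA", "miRNA", "piRNA")
            if f"pct_{c}" in comp
        },
        "mean_five_prime_tsrna_pct": (
            float(comp["pct_five_prime_tsrna"].mean())
            if "pct_five_prime_tsrna" in comp else None
        ),
        "n_differential": de_counts,
        "panels": auc.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(out, "report", {}, [], [out / "report.json"])
    return report


STAGES = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "annotate": run_annotate,
    "type": run_type,
    "quantify": run_quantify,
    "diffexp": run_diffexp,
    "multivariate": run_multivariate,
    "report": run_report,
}


def run_all(cfg: PipelineConfig) -> dict:
    for name, fn in STAGES.items():
        logger.info("stage: %s", name)
        result = fn(cfg)
    return result


# ---------------------------------------------------------------------------
# In-memory end-to-end analysis
# ---------------------------------------------------------------------------

def analyze_cohort(
    refset,
    design: CohortDesign,
    rpm_floor: float = 10.0,
    fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    C: float = 1.0,
    max_panel: int = 10,
    typing_params: TypingParams = TypingParams(),
) -> dict:
    """Simulate -> annotate -> type -> quantify -> DE -> panel evaluation,
    entirely in memory. Returns intermediate objects and per-class results.
    """
    cohort = simulate_cohort(refset, design)
    index = build_index(refset)
    bas = {sid: annotate_batch(b, index) for sid, b in cohort.batches.items()}
    cm = aggregate_counts(bas, refset, typing_params)
    rpm = rpm_normalize(cm)
    groups = pd.Series(
        cohort.metadata["group"].values, index=cohort.metadata["sample_id"]
    )
    compositions = [composition_summary(ba, refset, typing_params) for ba in bas.values()]
    results = {
        "cohort": cohort,
        "annotations": bas,
        "count_matrix": cm,
        "rpm": rpm,
        "groups": groups,
        "compositions": compositions,
        "classes": {},
    }
    for fclass in PANEL_CLASSES:
        kept = filter_by_mean_rpm(rpm, rpm_floor, cm.feature_meta, fclass)
        de = differential_features(
            rpm.loc[kept], groups, class_labels=cm.feature_meta["class"],
            fdr=fdr, min_abs_log2fc=min_abs_log2fc,
        )
        panel = select_panel(de, max_panel)
        entry = {"n_floor": len(kept), "de": de, "panel": panel}
        if panel:
            entry["eval"] = evaluate_panel(rpm, panel, groups, C=C)
        results["classes"][fclass] = entry
    return results
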