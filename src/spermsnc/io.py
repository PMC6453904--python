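"""Reference/read ingestion, read preprocessing, and TSV table round-trips.

Sequence handling conventions
-----------------------------
* All sequences are normalized to the DNA alphabet (U -> T) at ingestion.
* Coordinates are 0-based, half-open everywhere internally.
* Mature tRNA references get a 3' CCA appended when absent (3' fragments
  end in CCA in vivo); the record is flagged when this happened.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("spermsnc")

SNCRNA_CLASSES = ("miRNA", "tRNA", "rRNA", "piRNA")
RRNA_SUBTYPES = ("5S", "5.8S", "18S", "28S", "45S")

_ALLOWED = set("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); reject other letters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALLOWED
    if bad:
        raise ValidationError(f"sequence contains invalid characters: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated reference sequence (mature miRNA/tRNA, rRNA precursor, piRNA)."""

    id: str
    sequence: str
    class_label: str
    subtype_label: str = ""
    anticodon_interval: Optional[tuple[int, int]] = None
    cca_added: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"reference {self.id!r}: empty sequence")
        if self.class_label not in SNCRNA_CLASSES:
            raise ValidationError(
                f"reference {self.id!r}: unknown class {self.class_label!r}"
            )
        has_ac = self.anticodon_interval is not None
        if has_ac != (self.class_label == "tRNA"):
            raise ValidationError(
                f"reference {self.id!r}: anticodon_interval must be present "
                "iff class is tRNA"
            )
        if has_ac:
            a0, a1 = self.anticodon_interval
            if a1 - a0 != 3 or a0 <= 0 or a1 >= len(self.sequence):
                raise ValidationError(
                    f"tRNA {self.id!r}: anticodon interval ({a0}, {a1}) must be "
                    "3 nt and lie strictly inside the sequence"
                )
        if self.class_label == "rRNA" and self.subtype_label not in RRNA_SUBTYPES:
            raise ValidationError(
                f"rRNA {self.id!r}: subtype {self.subtype_label!r} not one of "
                f"{RRNA_SUBTYPES}"
            )


@dataclass
class ReferenceSet:
    """A collection of ReferenceRecords with a per-class index."""

    records: dict[str, ReferenceRecord] = field(default_factory=dict)

    def add(self, record: ReferenceRecord) -> None:
        if record.id in self.records:
            raise ValidationError(f"duplicate reference id {record.id!r}")
        self.records[record.id] = record

    def update(self, other: "ReferenceSet") -> None:
        for rec in other.records.values():
            self.add(rec)

    @property
    def class_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {c: [] for c in SNCRNA_CLASSES}
        for rid, rec in self.records.items():
            idx[rec.class_label].append(rid)
        return idx

    def by_class(self, class_label: str) -> list[ReferenceRecord]:
        return [r for r in self.records.values() if r.class_label == class_label]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> ReferenceRecord:
        return self.records[rid]


@dataclass
class PreprocessLog:
    input: int = 0
    adapter_trimmed: int = 0
    length_filtered: int = 0
    quality_filtered: int = 0
    surviving: int = 0

    def check_conservation(self) -> None:
        if self.input != self.surviving + self.length_filtered + self.quality_filtered:
            raise ValidationError("preprocessing bookkeeping does not balance")


@dataclass
class ReadBatch:
    """All reads of one sample, with optional per-base Phred qualities."""

    sample_id: str
    reads: list[str]
    qualities: Optional[list[str]] = None
    log: PreprocessLog = field(default_factory=PreprocessLog)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_anticodon_table(path: str | Path) -> pd.DataFrame:
    """Sidecar tRNA annotation: id, anticodon_start, anticodon_end, subtype_label."""
    df = read_table(
        path, required=("id", "anticodon_start", "anticodon_end", "subtype_label")
    )
    return df.set_index("id")


def read_fasta(
    path: str | Path,
    class_label: str,
    subtype_parser: Optional[Callable[[str], str]] = None,
    anticodon_table: Optional[pd.DataFrame] = None,
    append_cca: bool = True,
) -> ReferenceSet:
    """Parse one FASTA file into a ReferenceSet fragment of a single class.

    tRNA entries require an anticodon annotation, supplied either via
    ``anticodon_table`` (indexed by record id) or unavailable -> error.
    ``subtype_parser`` maps a record id to its subtype label (e.g. "28S"
    from an rRNA header); for tRNAs the sidecar table wins.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    text = path.read_text()
    if text.strip() == "":
        logger.warning("FASTA file %s is empty", path)
        return ReferenceSet()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected '>' header line")
            break
    refset = ReferenceSet()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq))
        subtype = subtype_parser(entry.id) if subtype_parser else ""
        anticodon = None
        cca_added = False
        if class_label == "tRNA":
            if anticodon_table is None or entry.id not in anticodon_table.index:
                raise ValidationError(
                    f"tRNA entry {entry.id!r} lacks an anticodon annotation"
                )
            row = anticodon_table.loc[entry.id]
            anticodon = (int(row["anticodon_start"]), int(row["anticodon_end"]))
            subtype = str(row["subtype_label"])
            if append_cca and not seq.endswith("CCA"):
                seq += "CCA"
                cca_added = True
        refset.add(
            ReferenceRecord(
                id=entry.id,
                sequence=seq,
                class_label=class_label,
                subtype_label=subtype,
                anticodon_interval=anticodon,
                cca_added=cca_added,
            )
        )
    return refset


def write_fasta(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in refset.records.values():
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, sample_id: str) -> ReadBatch:
    """Read a (possibly gzipped) 4-line-record FASTQ file into a ReadBatch."""
    path = Path(path)
    reads: list[str] = []
    quals: list[str] = []
    with _open_maybe_gzip(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"{path}: truncated FASTQ (record {len(lines) // 4}, "
            f"{len(lines)} lines is not a multiple of 4)"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ParseError(f"{path}: malformed FASTQ record {i // 4}")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: record {i // 4}: sequence/quality length mismatch"
            )
        reads.append(normalize_sequence(seq))
        quals.append(qual)
    batch = ReadBatch(sample_id=sample_id, reads=reads, qualities=quals)
    batch.log.input = len(reads)
    batch.log.surviving = len(reads)
    return batch


def write_fastq(batch: ReadBatch, path: str | Path) -> None:
    """Write a batch as FASTQ(.gz); gzip mtime pinned to 0 for reproducibility."""
    path = Path(path)
    quals = batch.qualities
    if str(path).endswith(".gz"):
        fh = gzip.GzipFile(filename=str(path), mode="wb", mtime=0)
    else:
        fh = open(path, "wb")
    with fh:
        for i, seq in enumerate(batch.reads):
            q = quals[i] if quals else "I" * len(seq)
            fh.write(f"@{batch.sample_id}_{i}\n{seq}\n+\n{q}\n".encode())


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def trim_adapter(
    read: str, adapter: str, seed_len: int = 8, max_mismatch: int = 1
) -> int:
    """Return the cut position of the leftmost 3' adapter occurrence.

    A prefix of ``adapter`` of length >= seed_len must match the read from
    some position through the read's 3' end with <= max_mismatch mismatches.
    Returns len(read) when no adapter is found.
    """
    n = len(read)
    for i in range(0, n - seed_len + 1):
        span = min(n - i, len(adapter))
        if span < seed_len:
            break
        mism = sum(1 for a, b in zip(read[i : i + span], adapter[:span]) if a != b)
        if mism <= max_mismatch:
            return i
    return n


def preprocess_reads(
    batch: ReadBatch,
    adapter: Optional[str] = None,
    min_len: int = 15,
    max_len: int = 45,
    min_mean_qual: float = 20.0,
    seed_len: int = 8,
    max_mismatch: int = 1,
) -> ReadBatch:
    """Adapter-trim, length-filter and quality-filter a read batch."""
    if min_len > max_len:
        raise ValidationError("min_len must be <= max_len")
    adapter = normalize_sequence(adapter) if adapter else None
    log = PreprocessLog(input=len(batch.reads))
    out_reads: list[str] = []
    out_quals: list[str] = [] if batch.qualities is not None else None
    for i, read in enumerate(batch.reads):
        qual = batch.qualities[i] if batch.qualities is not None else None
        if adapter:
            cut = trim_adapter(read, adapter, seed_len, max_mismatch)
            if cut < len(read):
                log.adapter_trimmed += 1
                read = read[:cut]
                qual = qual[:cut] if qual is not None else None
        if not (min_len <= len(read) <= max_len):
            log.length_filtered += 1
            continue
        if qual is not None and _mean_phred(qual) < min_mean_qual:
            log.quality_filtered += 1
            continue
        out_reads.append(read)
        if out_quals is not None:
            out_quals.append(qual)
    log.surviving = len(out_reads)
    log.check_conservation()
    return ReadBatch(
        sample_id=batch.sample_id, reads=out_reads, qualities=out_quals, log=log
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """TSV writer; floats carry 12 significant digits so round-trips are lossless."""
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path, id_name: str = "feature") -> None:
    """Feature x sample matrix writer: first column is the feature id."""
    out = matrix.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
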