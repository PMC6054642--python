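"""Canonical tag data model and I/O.

A :class:`TagSet` wraps an ordered collection of sequenced molecules
(:class:`~exoprof.simulate.TagRecord`) plus bookkeeping metadata, and
offers the library-level transformations: PCR-duplicate removal, 5'-end
and insert-size extraction, and Bernoulli subsampling (used to emulate
cell titrations).

Duplicates follow the sequence definition (identical Read_1 and Read_2
sequences); a coordinate mode (identical 5' coordinate/strand pairs) is
provided because heterogeneous Read_2 sonication ends make the two
equivalent in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import TagRecord

_TSV_COLS = [
    "molecule_id",
    "chrom",
    "r1_pos5",
    "r1_strand",
    "r2_pos5",
    "r2_strand",
    "r1_seq",
    "r2_seq",
    "shoulder",
    "carryover",
    "duplicate_of",
    "barcode_trim_k",
]


@dataclass
class TagSet:
    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.metadata.setdefault("n_input", len(self.records))

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def read_len(self) -> int:
        if self.records and self.records[0].r1_seq:
            return len(self.records[0].r1_seq)
        return int(self.metadata.get("read_len", 40))

    @classmethod
    def from_records(cls, records, **metadata) -> "TagSet":
        ts = cls(records=list(records))
        ts.metadata.update(metadata)
        return ts


def dedupe(tags: TagSet, mode: str = "sequence") -> TagSet:
    """Keep the first representative of every duplicate class.

    mode="sequence": identical (Read_1, Read_2) sequences.
    mode="coordinate": identical 5' coordinates and strands of both reads.
    Input order is otherwise preserved; the operation is idempotent.
    """
    if mode not in ("sequence", "coordinate"):
        raise ValueError(f"unknown dedupe mode {mode!r}")
    seen = set()
    kept = []
    for rec in tags.records:
        if mode == "sequence":
            if not rec.r1_seq or not rec.r2_seq:
                raise ValueError("sequence mode requires both read sequences")
            key = (rec.r1_seq, rec.r2_seq)
        else:
            key = (rec.chrom, rec.r1_pos5, rec.r1_strand, rec.r2_pos5, rec.r2_strand)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    meta = dict(tags.metadata)
    meta["n_input"] = len(tags.records)
    meta["n_after_dedupe"] = len(kept)
    meta["dedupe_mode"] = mode
    return TagSet(records=kept, metadata=meta)


def five_prime_ends(tags: TagSet, which: str = "read1") -> list[tuple[str, int, str]]:
    """(chrom, pos, strand) of the chosen read's 5'-most base, per record."""
    if which not in ("read1", "read2"):
        raise ValueError(f"which must be read1 or read2, got {which!r}")
    if which == "read1":
        return [(r.chrom, r.r1_pos5, r.r1_strand) for r in tags.records]
    return [(r.chrom, r.r2_pos5, r.r2_strand) for r in tags.records]


def _span(rec: TagRecord, read_len: int) -> int:
    def interval(pos, strand):
        # a minus-strand read's 5' end is its rightmost base (half-open maths)
        return (pos, pos + read_len) if strand == "+" else (pos - read_len + 1, pos + 1)

    a1, b1 = interval(rec.r1_pos5, rec.r1_strand)
    a2, b2 = interval(rec.r2_pos5, rec.r2_strand)
    return max(b1, b2) - min(a1, a2)


def insert_sizes(tags: TagSet, read_len: int | None = None) -> list[int]:
    """Outer-coordinate span of each pair (rightmost exclusive - leftmost)."""
    rl = read_len if read_len is not None else tags.read_len
    out = []
    for rec in tags.records:
        size = _span(rec, rl)
        if size <= 0:
            raise ValueError(f"non-positive insert for {rec.molecule_id}")
        out.append(size)
    return out


def subsample(tags: TagSet, fraction: float, seed: int = 0) -> TagSet:
    """Bernoulli thinning at ``fraction``, deterministic under ``seed``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(tags.records)) < fraction if fraction < 1.0 else None
    kept = tags.records if keep is None else [r for r, k in zip(tags.records, keep) if k]
    meta = dict(tags.metadata)
    meta["subsample_fraction"] = fraction
    meta["n_input"] = len(tags.records)
    return TagSet(records=list(kept), metadata=meta)


# ---------------------------------------------------------------------------
# I/O: 12-column paired TSV, per-read BED6, paired FASTQ


def write_tags_tsv(tags: TagSet, path) -> None:
    df = pd.DataFrame(
        [
            (
                r.molecule_id,
                r.chrom,
                r.r1_pos5,
                r.r1_strand,
                r.r2_pos5,
                r.r2_strand,
                r.r1_seq,
                r.r2_seq,
                int(r.shoulder),
                int(r.carryover),
                r.duplicate_of or ".",
                r.barcode_trim_k,
            )
            for r in tags.records
        ],
        columns=_TSV_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_tags_tsv(path, **metadata) -> TagSet:
    df = pd.read_csv(path, sep="\t", dtype={"r1_seq": str, "r2_seq": str})
    records = [
        TagRecord(
            molecule_id=str(row.molecule_id),
            chrom=str(row.chrom),
            r1_pos5=int(row.r1_pos5),
            r1_strand=str(row.r1_strand),
            r2_pos5=int(row.r2_pos5),
            r2_strand=str(row.r2_strand),
            r1_seq="" if pd.isna(row.r1_seq) else str(row.r1_seq),
            r2_seq="" if pd.isna(row.r2_seq) else str(row.r2_seq),
            shoulder=bool(row.shoulder),
            carryover=bool(row.carryover),
            duplicate_of=None if str(row.duplicate_of) == "." else str(row.duplicate_of),
            barcode_trim_k=int(row.barcode_trim_k),
        )
        for row in df.itertuples(index=False)
    ]
    return TagSet.from_records(records, source=str(path), **metadata)


def write_reads_bed(tags: TagSet, path, which: str = "read1") -> None:
    """Per-read BED6 of the occupied interval (strand column 6)."""
    rl = tags.read_len
    rows = []
    for r in tags.records:
        pos, strand = (r.r1_pos5, r.r1_strand) if which == "read1" else (r.r2_pos5, r.r2_strand)
        start, end = (pos, pos + rl) if strand == "+" else (pos - rl + 1, pos + 1)
        rows.append((r.chrom, start, end, f"{r.molecule_id}/{which}", 0, strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_ends_bed(path) -> list[tuple[str, int, str]]:
    """Read per-read BED6 into 5'-end tuples.

    An optional 7th column is treated as a mappability flag: rows with a
    non-zero flag are dropped (the hook for real-data multi-mapper
    filtering; simulated truth never sets it).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 7:
        df = df[df.iloc[:, 6].astype(int) == 0]
    ends = []
    for row in df.itertuples(index=False):
        chrom, start, end, strand = str(row[0]), int(row[1]), int(row[2]), str(row[5])
        pos = start if strand == "+" else end - 1
        ends.append((chrom, pos, strand))
    return ends


def write_fastq_pair(tags: TagSet, r1_path, r2_path) -> None:
    """Paired FASTQ, Phred+33, constant Q40 qualities."""
    for path, which in ((r1_path, "r1_seq"), (r2_path, "r2_seq")):
        recs = []
        for r in tags.records:
            seq = getattr(r, which)
            sr = SeqRecord(Seq(seq), id=r.molecule_id, description="")
            sr.letter_annotations["phred_quality"] = [40] * len(seq)
            recs.append(sr)
        SeqIO.write(recs, str(path), "fastq")


def read_fastq_pair(r1_path, r2_path) -> TagSet:
    """Sequences-only import (coordinates unavailable from FASTQ)."""
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files differ in record count")
    records = [
        TagRecord(
            molecule_id=a.id,
            chrom=".",
            r1_pos5=-1,
            r1_strand="+",
            r2_pos5=-1,
            r2_strand="-",
            r1_seq=str(a.seq),
            r2_seq=str(b.seq),
        )
        for a, b in zip(r1, r2)
    ]
    return TagSet.from_records(records, source=str(r1_path))


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
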