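"""Library-level diagnostics.

5'-end nucleotide-frequency profiling, sequence-bias calling with IUPAC
summarization, ChIP-nexus barcode filtering with failure-mode profiling,
insert-size mode +/- SD, and duplicate-rate reporting.

The bias rule is relative: a nucleotide is flagged at a position when its
frequency strictly exceeds background * (1 + margin).  With the default
10% margin this puts the displayed thresholds at A/T > 34% and
G/C > 21% on the yeast-like 31/19 background (display rounds to the
nearest integer percent; the rule itself never rounds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import STATIC_BARCODE

_NUCS = ("A", "C", "G", "T")

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class NtFreqProfile:
    """Per-position nucleotide frequencies over read 5' ends.

    ``freq`` is a (n_positions x 4) DataFrame with columns A, C, G, T;
    rows with zero coverage hold NaN.  ``coverage`` counts reads covering
    each position.
    """

    n_positions: int
    freq: pd.DataFrame
    n_reads: int
    coverage: np.ndarray = field(default=None, repr=False)


@dataclass
class BiasCall:
    background: dict
    margin: float
    flagged: list  # per-position set of nucleotides
    iupac: str
    thresholds_pct: dict  # displayed integer-percent thresholds


@dataclass
class BarcodeQC:
    n_pass: int
    n_fail: int
    pass_profile: NtFreqProfile | None
    fail_profile: NtFreqProfile | None
    #: presence frequency of the expected static-barcode base at each
    #: barcode position (1-based read position -> frequency), among fails
    fail_barcode_presence: dict = field(default_factory=dict)


def nt_freq(reads: list[str], n_positions: int) -> NtFreqProfile:
    """Column-wise base frequencies over the first ``n_positions`` of each read.

    Reads shorter than ``n_positions`` contribute to the positions they
    cover; frequencies are normalized per position by coverage.
    """
    if not reads:
        raise ValueError("empty read list")
    if n_positions < 1:
        raise ValueError(f"n_positions must be >= 1, got {n_positions}")
    counts = np.zeros((n_positions, 4), dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    for read in reads:
        arr = lut[np.frombuffer(read[:n_positions].upper().encode("ascii"), dtype=np.uint8)]
        valid = arr >= 0
        pos = np.flatnonzero(valid)
        np.add.at(counts, (pos, arr[valid]), 1)
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = counts / np.where(coverage > 0, coverage, 1)[:, None]
    freq[coverage == 0] = np.nan
    df = pd.DataFrame(freq, columns=list(_NUCS))
    df.index = pd.RangeIndex(1, n_positions + 1, name="position")
    return NtFreqProfile(n_positions=n_positions, freq=df, n_reads=len(reads), coverage=coverage)


def iupac_symbol(flagged: set) -> str:
    """Standard IUPAC degenerate code for a set of nucleotides; empty -> '-'."""
    flagged = frozenset(flagged)
    if not flagged:
        return "-"
    if not flagged <= frozenset("ACGT"):
        raise ValueError(f"not a nucleotide set: {flagged}")
    return IUPAC_CODES[flagged]


def call_bias(profile: NtFreqProfile, background: dict, margin: float = 0.10) -> BiasCall:
    """Flag nucleotides whose frequency strictly exceeds background*(1+margin)."""
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    total = sum(background.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"background frequencies must sum to 1, got {total}")
    flagged = []
    for _, row in profile.freq.iterrows():
        hit = {
            n
            for n in _NUCS
            if not np.isnan(row[n]) and row[n] > background[n] * (1.0 + margin)
        }
        flagged.append(hit)
    iupac = "".join(iupac_symbol(s) for s in flagged)
    thresholds = {n: int(round(background[n] * (1.0 + margin) * 100)) for n in _NUCS}
    return BiasCall(
        background=dict(background),
        margin=margin,
        flagged=flagged,
        iupac=iupac,
        thresholds_pct=thresholds,
    )


def nexus_filter(read: str) -> tuple[bool, str | None]:
    """ChIP-nexus barcode filter: pass iff 1-based positions 6-9 are CTGA.

    Returns (passed, reason); reads shorter than 9 nt fail with "short".
    """
    if len(read) < 9:
        return False, "short"
    if read[5:9].upper() == STATIC_BARCODE:
        return True, None
    return False, "barcode"


def barcode_qc(reads: list[str], n_positions: int = 15) -> BarcodeQC:
    """Partition reads by the CTGA filter and profile both partitions.

    The failure partition additionally reports the presence frequency of
    the expected static-barcode base at each barcode position (read
    positions 6-9), which makes the sequential A>G>T>C loss signature of
    polymerase over-trimming a one-line check.
    """
    if not reads:
        raise ValueError("empty read list")
    passed, failed = [], []
    for r in reads:
        (passed if nexus_filter(r)[0] else failed).append(r)
    presence = {}
    if failed:
        for i, base in enumerate(STATIC_BARCODE):  # read positions 6..9
            pos = 5 + i
            hits = sum(1 for r in failed if len(r) > pos and r[pos].upper() == base)
            presence[pos + 1] = hits / len(failed)
    return BarcodeQC(
        n_pass=len(passed),
        n_fail=len(failed),
        pass_profile=nt_freq(passed, n_positions) if passed else None,
        fail_profile=nt_freq(failed, n_positions) if failed else None,
        fail_barcode_presence=presence,
    )


def insert_mode_sd(sizes: list[int]) -> tuple[int, float]:
    """Most frequent integer size (smallest on ties) and population SD."""
    if len(sizes) == 0:
        raise ValueError("empty size list")
    arr = np.asarray(sizes, dtype=int)
    values, counts = np.unique(arr, return_counts=True)
    mode = int(values[np.argmax(counts)])  # np.unique sorts: ties pick smallest
    return mode, float(arr.std(ddof=0))


def duplicate_rate(n_before: int, n_after: int) -> float:
    """Fraction of records removed as duplicates: 1 - after/before."""
    if n_before == 0:
        raise ValueError("empty input: duplicate rate undefined")
    if n_after > n_before:
        raise ValueError("more records after dedupe than before")
    return 1.0 - n_after / n_before


# ---------------------------------------------------------------------------
# Reporting


def profile_to_tsv(profile: NtFreqProfile, path) -> None:
    profile.freq.to_csv(path, sep="\t")


def qc_report_text(report: dict) -> str:
    """Human-readable rendering of a QC report dictionary."""
    lines = ["exoprof QC report", "=" * 40]
    for key, val in report.items():
        if isinstance(val, dict):
            lines.append(f"{key}:")
            for k, v in val.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines) + "\n"


def write_qc_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(qc_report_text(report))
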