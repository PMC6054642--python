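"""Synthetic genome construction, motif planting, and FASTA/BED I/O.

Generates reproducible single-chromosome genomes with controlled base
composition (defaults mirror the budding-yeast-like 31/19/19/31 percent
A/C/G/T split) and plants oriented transcription-factor motif sites that
anchor all downstream stop-site profiling.  Coordinates are 0-based,
half-open throughout; BED emission is native and conversion to 1-based
happens only at display time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Base composition used throughout as the yeast-like background.
DEFAULT_BASE_PROBS = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}

#: Fixed 10-mer used as the default planted motif in tests and examples
#: (the URS1-like element bound by Ume6).
DEFAULT_MOTIF = "TAGCCGCCGA"

DEFAULT_CHROM = "chrS"

_NUCS = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeSpec:
    """Parameters of a synthetic chromosome.

    Parameters
    ----------
    length : int
        Chromosome length in bp (>= 0).
    base_probs : dict
        Mapping nucleotide -> sampling frequency; must cover A, C, G, T
        and sum to 1 within 1e-9.
    seed : int
        Seed of the generator; identical specs give byte-identical output.
    """

    length: int
    base_probs: dict = field(default_factory=lambda: dict(DEFAULT_BASE_PROBS))
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self):
        if self.length < 0:
            raise ValueError(f"length must be >= 0, got {self.length}")
        if set(self.base_probs) != set(_NUCS):
            raise ValueError("base_probs must have exactly the keys A, C, G, T")
        total = sum(self.base_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"base_probs must sum to 1, got {total!r}")
        if any(p < 0 for p in self.base_probs.values()):
            raise ValueError("base_probs must be non-negative")


@dataclass(frozen=True)
class MotifSite:
    """An oriented genomic interval anchoring profile analysis.

    ``start``/``end`` always store the forward-strand interval; orientation
    is applied downstream, never by coordinate mutation.
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_id: str
    rank_score: float = 0.0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        # Right-of-center for even widths; documented convention.
        return self.start + (self.end - self.start) // 2


def generate_genome(spec: GenomeSpec) -> str:
    """Draw a sequence of ``spec.length`` i.i.d. bases from ``base_probs``."""
    if spec.length == 0:
        return ""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = np.array([spec.base_probs[n] for n in _NUCS], dtype=float)
    probs = probs / probs.sum()  # guard 1e-9 slack
    draws = rng.choice(alphabet, size=spec.length, p=probs)
    return draws.tobytes().decode("ascii")


def plant_motifs(
    sequence: str,
    motif: str = DEFAULT_MOTIF,
    n_sites: int = 0,
    min_spacing: int = 100,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
) -> tuple[str, list[MotifSite]]:
    """Substitute ``motif`` at ``n_sites`` non-overlapping positions.

    Positions are at least ``min_spacing`` bp apart (edge to edge); strands
    are drawn uniformly and the reverse complement is written for minus
    sites.  Returns the modified sequence and sites sorted by coordinate.
    """
    motif = motif.upper()
    if set(motif) - set(_NUCS):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if n_sites == 0:
        return sequence, []
    m = len(motif)
    if n_sites * (m + min_spacing) > len(sequence):
        raise ValueError(
            f"cannot place {n_sites} sites of width {m} with spacing "
            f"{min_spacing} in a {len(sequence)} bp sequence"
        )
    rng = np.random.default_rng(seed)
    # Uniform placement of non-overlapping spaced intervals: draw sorted
    # positions in the slack space, then re-inflate by one pitch per site.
    pitch = m + min_spacing
    slack = len(sequence) - m - (n_sites - 1) * pitch
    if slack < 0:
        raise ValueError(
            f"cannot place {n_sites} sites of width {m} with spacing "
            f"{min_spacing} in a {len(sequence)} bp sequence"
        )
    x = np.sort(rng.integers(0, slack + 1, size=n_sites))
    starts = [int(x[i] + i * pitch) for i in range(n_sites)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in starts]
    scores = rng.uniform(1.0, 1000.0, size=n_sites)

    seq = bytearray(sequence, "ascii")
    placed = sorted(zip(starts, strands, scores), key=lambda t: t[0])
    sites = []
    for i, (start, strand, score) in enumerate(placed):
        text = motif if strand == "+" else reverse_complement(motif)
        seq[start : start + m] = text.encode("ascii")
        sites.append(
            MotifSite(
                chrom=chrom,
                start=start,
                end=start + m,
                strand=strand,
                site_id=f"site_{i:04d}",
                rank_score=round(float(score), 2),
            )
        )
    return seq.decode("ascii"), sites


# ---------------------------------------------------------------------------
# Standard-format I/O


def write_fasta(path, sequences: dict[str, str]) -> None:
    """Write ``{name: sequence}`` as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_sites_bed(sites: list[MotifSite], path) -> None:
    """Write motif sites as BED6 (name=site_id, score=rank_score)."""
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.site_id, s.rank_score, s.strand) for s in sites],
        columns=_BED6_COLS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> list[MotifSite]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED6_COLS, comment="#")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            MotifSite(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                site_id=str(row.name),
                rank_score=float(row.score),
            )
        )
    return sites
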