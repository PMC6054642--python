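"""Mechanistic paired-end library simulator for ChIP protocol variants.

Simulates library construction for ChIP-seq, ChIPmentation, the ChIP-exo
series (1.1, 3.1, 4.0, 4.1, 5.0) and ChIP-nexus over a synthetic genome
with planted binding sites.  Each sequenced molecule is emitted as a
:class:`TagRecord` carrying true genomic coordinates (alignment is
simulated away: records hold truth, which makes downstream tests exact)
together with ground-truth provenance flags.

The generative model, per molecule:

1. Sonication draws fragment sizes from a truncated lognormal
   (mode/sd parameterization, clipped to [min, max]); fragment placement is
   enriched at binding sites.  Site fragments carry a pair of
   protein-DNA crosslinks at midpoint +/- ``crosslink_offset`` (one per
   strand).
2. For tagmentation protocols (ChIPmentation, exo 3.1) Tn5 converts a
   fragment to a library molecule with probability 1-(1-p)^L, a
   length-weighted selection gate; the cut position is drawn proportional
   to a 19-bp position-weight-matrix match score.  Spent Tn5 holds the cut
   pieces together (the carryover model), so the amplified molecule keeps
   the sonication span while the interior cut ends leak into the read pool
   as carryover records with probability ``p_carry``.
3. Lambda exonuclease digests the 5' strand to ``stop_offset`` bp 5' of
   the crosslink; with probability ``p_shoulder`` digestion fails and the
   read starts at the sonication end (ChIP-seq-like shouldering).  A
   fraction ``p_inner_site`` of site molecules instead stop at the
   secondary midpoint stop on the motif-complementary strand, emitted only
   with probability ``p_inner_ligation`` (models the missing inner peak of
   the 4.x chemistry).
4. Version-specific barcoding: ChIP-nexus prepends a 5-nt random barcode
   plus the fixed CTGA spacer (eroded by T4-polymerase over-trimming with
   probability ``p_overtrim`` per base, A then G then T then C); version
   4.0 prepends a random pentamer that displaces the mapped stop site 5 bp
   in the 5' direction of the read strand.
5. PCR duplicates a molecule 1 + Poisson(dup_mean - 1) times, byte
   identical in both reads.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .genome import MotifSite, reverse_complement

VERSIONS = ("seq", "mentation", "exo1.1", "exo3.1", "exo4.0", "exo4.1", "exo5.0", "nexus")
EXO_VERSIONS = frozenset({"exo1.1", "exo3.1", "exo4.0", "exo4.1", "exo5.0", "nexus"})
TAGMENT_VERSIONS = frozenset({"mentation", "exo3.1"})

#: ChIP-nexus fixed spacer, read positions 6-9 (1-based) of Read_1.
STATIC_BARCODE = "CTGA"
#: Random-barcode length shared by nexus and the 4.0 pentamer.
RANDOM_BARCODE_LEN = 5

TN5_PWM_WIDTH = 19

_BG = (0.31, 0.19, 0.19, 0.31)  # A, C, G, T


def _pwm_default() -> np.ndarray:
    """Default Tn5 target-preference matrix over the 19 bp recognition window.

    Palindromic about the central cut position (column 9): column j mirrors
    column 18-j through base complementation, as Tn5 engages its target as
    a dimer.  Flanks sit at the genomic background.
    """
    pwm = np.tile(np.array(_BG), (TN5_PWM_WIDTH, 1))
    # columns 9..14 (A, C, G, T); left half filled by complement symmetry
    right = {
        9: (0.40, 0.10, 0.10, 0.40),
        10: (0.60, 0.14, 0.13, 0.13),
        11: (0.15, 0.12, 0.55, 0.18),
        12: (0.18, 0.50, 0.17, 0.15),
        13: (0.55, 0.15, 0.15, 0.15),
        14: (0.22, 0.13, 0.45, 0.20),
    }
    for j, row in right.items():
        pwm[j] = row
        a, c, g, t = row
        pwm[18 - j] = (t, g, c, a)  # complement: A<->T, C<->G
    return pwm


TN5_PWM = _pwm_default()


class ConfigError(ValueError):
    """Raised when a SimConfig field is out of contract."""


def _version_defaults(version: str) -> dict:
    d: dict = {}
    d["p_shoulder"] = {
        "exo1.1": 0.05,
        "exo3.1": 0.35,
        "exo4.0": 0.30,
        "exo4.1": 0.30,
        "exo5.0": 0.10,
        "nexus": 0.05,
    }.get(version, 1.0)
    d["p_inner_ligation"] = 0.1 if version in ("exo4.0", "exo4.1") else 1.0
    d["p_carry"] = 0.4 if version in TAGMENT_VERSIONS else 0.0
    d["p_overtrim"] = 0.3 if version == "nexus" else 0.0
    return d


@dataclass
class SimConfig:
    """All simulator parameters in one validated record.

    Defaults are the study conditions: 100-500 bp sonication fragments
    (mode 180, sd 80), 2 x 40 bp reads, crosslinks 8 bp from the motif
    midpoint, exonuclease stops 6 bp 5' of the crosslink.  Per-version
    shoulder/ligation/carryover/trimming rates are filled in by
    :meth:`for_version`.
    """

    version: str
    n_fragments: int = 50_000
    frag_size_mode: int = 180
    frag_size_sd: float = 80.0
    frag_size_min: int = 100
    frag_size_max: int = 500
    enrichment: float = 25.0
    background_frac: float = 0.10
    crosslink_offset: int = 8
    stop_offset: int = 6
    p_shoulder: float = 0.10
    p_inner_site: float = 0.25
    p_inner_ligation: float = 1.0
    tn5_pwm: np.ndarray = field(default_factory=lambda: TN5_PWM.copy())
    p_tagment_per_bp: float = 0.005
    p_carry: float = 0.0
    p_overtrim: float = 0.0
    dup_mean: float = 1.5
    read_len: int = 40
    seed: int = 0

    @classmethod
    def for_version(cls, version: str, seed: int = 0, **overrides) -> "SimConfig":
        """Config with the per-version default rates applied."""
        params = _version_defaults(version)
        params.update(overrides)
        cfg = cls(version=version, seed=seed, **params)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.version not in VERSIONS:
            raise ConfigError(f"version: unknown protocol {self.version!r}")
        for name in (
            "background_frac",
            "p_shoulder",
            "p_inner_site",
            "p_inner_ligation",
            "p_tagment_per_bp",
            "p_carry",
            "p_overtrim",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        if self.n_fragments < 0:
            raise ConfigError(f"n_fragments: must be >= 0, got {self.n_fragments}")
        if self.enrichment < 1:
            raise ConfigError(f"enrichment: must be >= 1, got {self.enrichment}")
        if self.dup_mean < 1:
            raise ConfigError(f"dup_mean: must be >= 1, got {self.dup_mean}")
        if self.read_len < 10:
            raise ConfigError(f"read_len: must be >= 10, got {self.read_len}")
        if self.frag_size_min < self.read_len:
            raise ConfigError(
                f"frag_size_min: must be >= read_len ({self.read_len}), "
                f"got {self.frag_size_min}"
            )
        if not self.frag_size_min <= self.frag_size_mode <= self.frag_size_max:
            raise ConfigError("frag_size_mode: must lie within [frag_size_min, frag_size_max]")
        if self.frag_size_sd <= 0:
            raise ConfigError(f"frag_size_sd: must be > 0, got {self.frag_size_sd}")
        pwm = np.asarray(self.tn5_pwm, dtype=float)
        if pwm.shape != (TN5_PWM_WIDTH, 4):
            raise ConfigError(
                f"tn5_pwm: must have shape ({TN5_PWM_WIDTH}, 4), got {pwm.shape}"
            )
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigError("tn5_pwm: rows must sum to 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tn5_pwm"] = np.asarray(self.tn5_pwm).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "tn5_pwm" in d:
            d["tn5_pwm"] = np.asarray(d["tn5_pwm"], dtype=float)
        if "version" not in d:
            raise ConfigError("version: missing")
        version = d.pop("version")
        seed = d.pop("seed", 0)
        return cls.for_version(version, seed=seed, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a config from YAML (JSON being a YAML subset is accepted)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


@dataclass
class Fragment:
    """One sonication fragment with its crosslink and tagmentation state."""

    chrom: str
    start: int
    end: int
    origin_site: str = "background"
    origin_strand: str = "+"
    site_mid: Optional[int] = None
    crosslinks: list = field(default_factory=list)  # [(pos, strand), ...]
    cut_site: Optional[int] = None
    carry_piece: Optional[tuple] = None  # (start, end, cut_on_right: bool)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment start must precede end: [{self.start}, {self.end})")
        for pos, _ in self.crosslinks:
            if not self.start <= pos < self.end:
                raise ValueError(f"crosslink {pos} outside fragment [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class TagRecord:
    """One sequenced molecule: coordinates, strands, sequences, truth flags."""

    molecule_id: str
    chrom: str
    r1_pos5: int
    r1_strand: str
    r2_pos5: int
    r2_strand: str
    r1_seq: str = ""
    r2_seq: str = ""
    shoulder: bool = False
    carryover: bool = False
    duplicate_of: Optional[str] = None
    barcode_trim_k: int = 0
    origin_site: str = "background"


# ---------------------------------------------------------------------------
# Sonication


def lognormal_params(mode: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the requested mode and standard deviation.

    mode = exp(mu - sigma^2) pins mu once sigma is known; sd is strictly
    increasing in sigma, solved by bracketed root finding.
    """

    def sd_of(sigma: float) -> float:
        mu = math.log(mode) + sigma * sigma
        return math.sqrt(math.expm1(sigma * sigma)) * math.exp(mu + sigma * sigma / 2)

    sigma = brentq(lambda s: sd_of(s) - sd, 1e-9, 3.0)
    return math.log(mode) + sigma * sigma, sigma


def _merged_overlap_intervals(
    sites: list[MotifSite], size: int, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Start-position intervals [a, b) whose fragment of ``size`` overlaps a site,
    clipped to the eligible start range [lo, hi)."""
    raw = sorted((max(lo, s.start - size + 1), min(hi, s.end)) for s in sites)
    merged: list[list[int]] = []
    for a, b in raw:
        if a >= b:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _sample_positions(rng, intervals, total_len, k) -> np.ndarray:
    """k uniform draws from a union of disjoint intervals."""
    lens = np.array([b - a for a, b in intervals])
    starts = np.array([a for a, _ in intervals])
    cum = np.cumsum(lens)
    u = rng.integers(0, total_len, size=k)
    idx = np.searchsorted(cum, u, side="right")
    offset = u - (cum[idx] - lens[idx])
    return starts[idx] + offset


def _sample_complement(rng, intervals, lo, hi, total_complement, k) -> np.ndarray:
    """k uniform draws from [lo, hi) minus the union of ``intervals``."""
    gaps = []
    cursor = lo
    for a, b in intervals:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < hi:
        gaps.append((cursor, hi))
    return _sample_positions(rng, gaps, total_complement, k)


def simulate_fragments(
    genome: str, sites: list[MotifSite], config: SimConfig, rng=None
) -> list[Fragment]:
    """Draw sonication fragments with site enrichment and crosslink placement."""
    if not genome:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = len(genome)
    margin = config.read_len + config.stop_offset + 4  # keep reads inside the chromosome
    mu, sigma = lognormal_params(config.frag_size_mode, config.frag_size_sd)
    # truncated lognormal: out-of-range molecules are removed by size
    # selection, not clamped, so the interior mode is preserved
    sizes = np.empty(0, dtype=int)
    while sizes.size < config.n_fragments:
        draw = np.rint(rng.lognormal(mu, sigma, size=2 * config.n_fragments + 16))
        ok = draw[(draw >= config.frag_size_min) & (draw <= config.frag_size_max)]
        sizes = np.concatenate([sizes, ok.astype(int)])
    sizes = sizes[: config.n_fragments]
    if sizes.size and margin + sizes.max() + margin > L:
        raise ValueError("fragment window exceeds genome length")
    want_bg = rng.random(config.n_fragments) < config.background_frac

    site_starts = np.array([s.start for s in sites]) if sites else np.empty(0, int)
    chrom = sites[0].chrom if sites else "chrS"

    starts = np.empty(config.n_fragments, dtype=int)
    for size in np.unique(sizes):
        sel = np.flatnonzero(sizes == size)
        lo, hi = margin, L - size - margin
        n_total = hi - lo
        if sites:
            ov = _merged_overlap_intervals(sites, int(size), lo, hi)
            n_over = sum(b - a for a, b in ov)
        else:
            ov, n_over = [], 0
        n_non = n_total - n_over
        bg_sel = sel[want_bg[sel]]
        en_sel = sel[~want_bg[sel]]
        if bg_sel.size:
            starts[bg_sel] = _sample_complement(rng, ov, lo, hi, n_non, bg_sel.size)
        if en_sel.size:
            w_over = config.enrichment * n_over
            q = w_over / (w_over + n_non) if (w_over + n_non) > 0 else 0.0
            hit = rng.random(en_sel.size) < q
            if ov and hit.any():
                starts[en_sel[hit]] = _sample_positions(rng, ov, n_over, int(hit.sum()))
            if (~hit).any():
                starts[en_sel[~hit]] = _sample_complement(
                    rng, ov, lo, hi, n_non, int((~hit).sum())
                )

    fragments = []
    for i in range(config.n_fragments):
        s, e = int(starts[i]), int(starts[i] + sizes[i])
        frag = Fragment(chrom=chrom, start=s, end=e)
        if sites:
            j = int(np.searchsorted(site_starts, e) - 1)
            hit_site = None
            for cand in (j, j + 1):
                if 0 <= cand < len(sites):
                    st = sites[cand]
                    if st.start < e and st.end > s:
                        hit_site = st
                        break
            if hit_site is not None:
                mid = hit_site.midpoint
                xl = []
                for pos, strand in (
                    (mid - config.crosslink_offset, "+"),
                    (mid + config.crosslink_offset, "-"),
                ):
                    # stop coordinate must stay inside the fragment
                    if s + config.stop_offset <= pos < e - config.stop_offset:
                        xl.append((pos, strand))
                frag.origin_site = hit_site.site_id
                frag.origin_strand = hit_site.strand
                frag.site_mid = mid
                frag.crosslinks = xl
        fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# Tagmentation


def pwm_score_track(genome: str, pwm: np.ndarray) -> np.ndarray:
    """Match weight of the PWM window starting at each genomic position."""
    pwm = np.asarray(pwm, dtype=float)
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    gi = lut[g]
    L = len(genome)
    w = pwm.shape[0]
    if L < w:
        return np.empty(0)
    logp = np.log(np.maximum(pwm, 1e-12))
    score = np.zeros(L - w + 1)
    for j in range(w):
        score += logp[j, gi[j : L - w + 1 + j]]
    return np.exp(score - score.max())


def tagment(
    fragments: list[Fragment], genome: str, config: SimConfig, rng=None
) -> list[Fragment]:
    """Tn5 selection gate plus PWM-weighted cut placement and carryover.

    A fragment enters the library with probability 1-(1-p)^L (length-
    weighted selection; unreacted molecules carry no adapter and are
    lost).  One cut is drawn proportional to the PWM match score across
    the fragment; spent Tn5 bridges the cut so the amplified molecule
    keeps its sonication span, while with probability ``p_carry`` the
    crosslink-distal piece's ends also enter the read pool (carryover).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pwm = np.asarray(config.tn5_pwm, dtype=float)
    if pwm.shape[0] != TN5_PWM_WIDTH:
        raise ConfigError(f"tn5_pwm: width must be {TN5_PWM_WIDTH}, got {pwm.shape[0]}")
    track = pwm_score_track(genome, pwm)
    half = TN5_PWM_WIDTH // 2  # cut at the window center
    p = config.p_tagment_per_bp
    out = []
    for frag in fragments:
        if frag.size < TN5_PWM_WIDTH:
            raise ValueError(f"fragment of {frag.size} bp shorter than the Tn5 window")
        p_tag = 1.0 - (1.0 - p) ** frag.size
        if rng.random() >= p_tag:
            continue  # unreacted: no adapter, lost at amplification
        w = track[frag.start : frag.end - TN5_PWM_WIDTH + 1]
        tot = w.sum()
        if tot <= 0:
            ws = int(rng.integers(frag.start, frag.end - TN5_PWM_WIDTH + 1))
        else:
            ws = frag.start + int(rng.choice(len(w), p=w / tot))
        cut = ws + half
        frag.cut_site = cut
        if config.p_carry > 0 and rng.random() < config.p_carry:
            ref = frag.site_mid if frag.site_mid is not None else (frag.start + frag.end) // 2
            if cut <= ref:
                frag.carry_piece = (frag.start, cut, True)  # cut on the right edge
            else:
                frag.carry_piece = (cut, frag.end, False)
        out.append(frag)
    return out


# ---------------------------------------------------------------------------
# Exonuclease digestion / end selection


@dataclass
class _Geometry:
    r1_pos5: int
    r1_strand: str
    r2_pos5: int
    r2_strand: str
    shoulder: bool = False
    carryover: bool = False


def exo_process(fragment: Fragment, config: SimConfig, rng=None) -> Optional[_Geometry]:
    """5' end geometry of the main molecule for exonuclease protocols.

    Returns ``None`` when the molecule is lost (failed inner-stop
    ligation).  Background fragments (no crosslink) behave like shoulder
    molecules: the read starts at a sonication end.
    """
    if config.version not in EXO_VERSIONS:
        raise ValueError(f"exo_process does not apply to version {config.version!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    def sonication_end(strand: str) -> _Geometry:
        if strand == "+":
            return _Geometry(fragment.start, "+", fragment.end - 1, "-", shoulder=True)
        return _Geometry(fragment.end - 1, "-", fragment.start, "+", shoulder=True)

    if not fragment.crosslinks:
        return sonication_end("+" if rng.random() < 0.5 else "-")
    if rng.random() < config.p_shoulder:
        return sonication_end("+" if rng.random() < 0.5 else "-")

    inner_ok = (
        fragment.site_mid is not None
        and fragment.start + config.read_len <= fragment.site_mid < fragment.end
    )
    if inner_ok and rng.random() < config.p_inner_site:
        if rng.random() >= config.p_inner_ligation:
            return None  # inner stop made, ligation failed: molecule lost
        strand = "-" if fragment.origin_strand == "+" else "+"
        if strand == "+":
            return _Geometry(fragment.site_mid, "+", fragment.end - 1, "-")
        return _Geometry(fragment.site_mid, "-", fragment.start, "+")

    pos, strand = fragment.crosslinks[int(rng.integers(len(fragment.crosslinks)))]
    if strand == "+":
        stop = pos - config.stop_offset
        if stop < fragment.start:
            raise ValueError("stop coordinate outside fragment")
        return _Geometry(stop, "+", fragment.end - 1, "-")
    stop = pos + config.stop_offset
    if stop >= fragment.end:
        raise ValueError("stop coordinate outside fragment")
    return _Geometry(stop, "-", fragment.start, "+")


def _sonication_geometry(fragment: Fragment, rng) -> _Geometry:
    """ChIP-seq / ChIPmentation main molecule: both ends are fragment ends."""
    if rng.random() < 0.5:
        return _Geometry(fragment.start, "+", fragment.end - 1, "-")
    return _Geometry(fragment.end - 1, "-", fragment.start, "+")


def _carry_geometry(fragment: Fragment, config: SimConfig, rng) -> _Geometry:
    """Read geometry of the carryover (crosslink-distal) piece.

    The cut end carries the Tn5 adapter: always the Read_2 adapter in
    exo 3.1, either adapter (coin flip) in ChIPmentation.
    """
    a, b, cut_on_right = fragment.carry_piece
    if cut_on_right:
        cut_end = (b - 1, "-")
        son_end = (a, "+")
    else:
        cut_end = (a, "+")  # cut is the left edge
        son_end = (b - 1, "-")
    cut_is_r1 = config.version == "mentation" and rng.random() < 0.5
    if cut_is_r1:
        (r1, s1), (r2, s2) = cut_end, son_end
    else:
        (r1, s1), (r2, s2) = son_end, cut_end
    return _Geometry(r1, s1, r2, s2, shoulder=True, carryover=True)


# ---------------------------------------------------------------------------
# Barcoding and sequence synthesis


def read_sequence(genome: str, pos5: int, strand: str, length: int) -> str:
    """Genomic sequence of a read whose 5'-most base sits at ``pos5``."""
    if strand == "+":
        if pos5 < 0 or pos5 + length > len(genome):
            raise ValueError("read runs off the chromosome edge")
        return genome[pos5 : pos5 + length]
    if pos5 - length + 1 < 0 or pos5 + 1 > len(genome):
        raise ValueError("read runs off the chromosome edge")
    return reverse_complement(genome[pos5 - length + 1 : pos5 + 1])


def _overtrim_depth(config: SimConfig, rng) -> int:
    """Markov erosion of the static barcode: each base removed w.p. p_overtrim."""
    k = 0
    while k < len(STATIC_BARCODE) and rng.random() < config.p_overtrim:
        k += 1
    return k


def apply_barcode_scheme(
    geom: _Geometry,
    genome: str,
    config: SimConfig,
    rng,
    molecule_id: str,
    chrom: str,
    origin_site: str = "background",
) -> TagRecord:
    """Attach version-specific barcodes and synthesize both read sequences."""
    rl = config.read_len
    trim_k = 0
    r1_pos5 = geom.r1_pos5
    if config.version == "nexus":
        pentamer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=RANDOM_BARCODE_LEN))
        trim_k = _overtrim_depth(config, rng)
        static = STATIC_BARCODE[: len(STATIC_BARCODE) - trim_k]
        genomic_len = rl - RANDOM_BARCODE_LEN - len(static)
        r1_seq = pentamer + static + read_sequence(genome, geom.r1_pos5, geom.r1_strand, genomic_len)
    elif config.version == "exo4.0":
        pentamer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=RANDOM_BARCODE_LEN))
        r1_seq = pentamer + read_sequence(
            genome, geom.r1_pos5, geom.r1_strand, rl - RANDOM_BARCODE_LEN
        )
        # the pentamer is read as genomic by the aligner: the mapped stop
        # site appears 5 bp more 5' along the read strand
        r1_pos5 = geom.r1_pos5 - RANDOM_BARCODE_LEN if geom.r1_strand == "+" else geom.r1_pos5 + RANDOM_BARCODE_LEN
    else:
        r1_seq = read_sequence(genome, geom.r1_pos5, geom.r1_strand, rl)
    r2_seq = read_sequence(genome, geom.r2_pos5, geom.r2_strand, rl)
    return TagRecord(
        molecule_id=molecule_id,
        chrom=chrom,
        r1_pos5=r1_pos5,
        r1_strand=geom.r1_strand,
        r2_pos5=geom.r2_pos5,
        r2_strand=geom.r2_strand,
        r1_seq=r1_seq,
        r2_seq=r2_seq,
        shoulder=geom.shoulder,
        carryover=geom.carryover,
        barcode_trim_k=trim_k,
        origin_site=origin_site,
    )


# ---------------------------------------------------------------------------
# PCR and orchestration


def pcr_duplicate(records: list[TagRecord], config: SimConfig, rng=None) -> list[TagRecord]:
    """Amplify each molecule 1 + Poisson(dup_mean - 1) times.

    Copies are byte-identical in both sequences and flagged with the
    originating molecule id.  dup_mean = 1 reproduces the input exactly.
    """
    if config.dup_mean < 1:
        raise ConfigError(f"dup_mean: must be >= 1, got {config.dup_mean}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.dup_mean == 1:
        return list(records)
    out = []
    counts = rng.poisson(config.dup_mean - 1, size=len(records)) + 1
    for rec, c in zip(records, counts):
        out.append(rec)
        for j in range(1, int(c)):
            out.append(
                dataclasses.replace(
                    rec,
                    molecule_id=f"{rec.molecule_id}.dup{j}",
                    duplicate_of=rec.molecule_id,
                )
            )
    return out


def simulate_library(
    genome: str, sites: list[MotifSite], config: SimConfig
) -> tuple[list[TagRecord], pd.DataFrame]:
    """Full pipeline: fragments -> (tagmentation) -> digestion -> barcodes -> PCR.

    Returns the amplified record list and a truth table mapping each
    molecule to its origin site and provenance flags.  Deterministic under
    ``config.seed``: all draws flow from one generator in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = sites[0].chrom if sites else "chrS"
    fragments = simulate_fragments(genome, sites, config, rng)
    if config.version in TAGMENT_VERSIONS:
        fragments = tagment(fragments, genome, config, rng)

    records: list[TagRecord] = []
    n = 0
    for frag in fragments:
        if config.version in EXO_VERSIONS:
            geom = exo_process(frag, config, rng)
        else:
            geom = _sonication_geometry(frag, rng)
        geoms = [] if geom is None else [geom]
        if frag.carry_piece is not None:
            geoms.append(_carry_geometry(frag, config, rng))
        for g in geoms:
            n += 1
            records.append(
                apply_barcode_scheme(
                    g, genome, config, rng, f"m{n:07d}", chrom, frag.origin_site
                )
            )
    records = pcr_duplicate(records, config, rng)
    truth = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "origin_site": [r.origin_site for r in records],
            "shoulder": [r.shoulder for r in records],
            "carryover": [r.carryover for r in records],
            "duplicate_of": [r.duplicate_of or "" for r in records],
            "barcode_trim_k": [r.barcode_trim_k for r in records],
        }
    )
    return records, truth
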