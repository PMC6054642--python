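# Methods

## The generative model

`exoprof` simulates one sequenced molecule at a time through five stages.
All randomness flows from a single `numpy` generator seeded by
`SimConfig.seed`, drawn in a fixed documented order (sonication →
tagmentation → digestion → barcoding → PCR), so a run is reproducible
bit-for-bit across platforms.

### Sonication and enrichment

Fragment sizes follow a lognormal parameterized by its **mode** and
**standard deviation** (mode pins μ = ln(mode) + σ²; σ is solved from the
sd by bracketed root finding), truncated to `[frag_size_min,
frag_size_max]` by resampling. Truncation, not clamping: size selection
(gel or bead cleanup) removes out-of-range molecules rather than piling
them at the boundary, and resampling preserves the interior mode that the
insert-size diagnostics recover.

Placement is a two-stage draw. With probability `background_frac` the
fragment start is uniform over positions whose fragment avoids every
binding site (the input-chromatin component). Otherwise starts are
weighted: positions whose fragment would overlap a site carry weight
`enrichment`, all others weight 1, giving the closed-form overlap
probability (1 − background_frac) · E·n_over / (E·n_over + n_non) used by
the statistical tests. Site-overlapping fragments carry a crosslink pair
at motif midpoint ± `crosslink_offset` (one per strand, default 8 bp),
kept only where the downstream stop coordinate stays inside the fragment.

### Tagmentation (ChIPmentation, ChIP-exo 3.1)

A fragment of length L is tagmented with probability 1 − (1 − p)^L
(`p_tagment_per_bp`, default 0.005); unreacted molecules receive no
adapter and are lost. This is a length-weighted selection gate — the
mechanism behind the observed abundance increase of larger fragments in
tagmentation libraries ("more opportunities for Tn5 binding"), and the
package's tests verify the resulting upward shift of the mean emitted
insert against the input sonication distribution.

The cut position is drawn proportional to the match score of a 19-bp
position-weight matrix (the Tn5 recognition-sequence width) along the
fragment; the default PWM is palindromic about the central cut position
through base complementation, as Tn5 engages DNA as a dimer, with its
information concentrated in the six central columns. Scores are
precomputed once per genome as a log-sum track, so per-fragment sampling
is a slice.

**Carryover.** The model treats spent Tn5 as bridging the cut
(noncovalently holding both pieces through library prep): the amplified
main molecule keeps its sonication span, while with probability `p_carry`
the crosslink-distal piece's ends additionally enter the read pool as a
flagged carryover record. The cut end of a carryover record carries the
Tn5 adapter: it is always the Read_2 end in exo 3.1 (the Read_1 adapter
is added at the digested end), and either read end with equal probability
in ChIPmentation (Tn5 loads both adapters). This one mechanism produces
the three tagmentation fingerprints at once: PWM sequence bias at
non-digested read ends, mixed-strand interior 5′ ends (the "purple"
heatmap look, i.e. a falling strand-segregation score as p_carry grows),
and extra apparent shouldering. An alternative family of models in which
the sequenced insert is bounded by the interior cut was rejected: under
any such model the cut-truncation (≈25% mean loss) outweighs the maximum
lift of length-weighted selection (a factor 1 + cv² ≈ 1.14 on this size
distribution), making the observed insert-size increase unattainable.

### Exonuclease digestion

For a molecule with a crosslink, with probability 1 − `p_shoulder` the 5′
strand is resected to `stop_offset` bp (default 6) 5′ of the crosslink:
Read_1 starts at midpoint − 14 on the motif strand (or +14 on the other),
and Read_2 is always the opposite sonication end. With probability
`p_shoulder` digestion fails and Read_1 starts at the sonication end — a
ChIP-seq-like tag. Crosslink-free (background) molecules behave as
shoulder molecules. A fraction `p_inner_site` (default 0.25) of site
molecules instead stop at a secondary site at the motif midpoint on the
motif-complementary strand; these are emitted only with probability
`p_inner_ligation`, which models the near-absence of the inner peak in
the 4.x chemistry (default 0.1 for 4.0/4.1, 1.0 elsewhere) as a per-stop
ligation efficiency — the mechanism is left open, only the yield effect
is modeled.

Per-version default rates (shoulder / inner ligation / carryover /
over-trim): exo1.1 0.05/1.0/–/–, exo3.1 0.35/1.0/0.4/–, exo4.x
0.30/0.1/–/–, exo5.0 0.10/1.0/–/–, nexus 0.05/1.0/–/0.3; ChIP-seq and
ChIPmentation skip digestion entirely. These encode the qualitative
ordering reported for the protocols (5.0 ≈ 1.1 ≪ 3.1/4.x shouldering);
no quantitative rates are published, so they are free parameters.

### Barcoding

ChIP-nexus Read_1 is 5 random nt + the fixed `CTGA` spacer + genomic
sequence from the stop site; the mapped coordinate is the true stop (the
barcode is clipped before alignment). T4-polymerase **over-trimming** is a
Markov erosion of the spacer's terminal bases: trimming starts with
probability `p_overtrim` and each further base is removed with the same
probability, capped at 4, i.e. P(k ≥ j+1 | k ≥ j) = p_overtrim. Bases
leave in adapter order A, then G, then T, then C, and the read
frame-shifts (genomic bases fill in), so among filter-failing reads the
expected-base presence decreases strictly along C(6) ≥ T(7) ≥ G(8) ≥ A(9)
for p ∈ (0, 1). Note a trimmed read can still pass the CTGA filter when
the first genomic base happens to complete the spacer (probability ≈ 0.31
for k = 1) — exactly as in real data, so "filter pass" and "untrimmed
truth" agree in one direction only.

Version 4.0's Read_1 begins with a random pentamer that the aligner reads
as genomic, so the record's mapped 5′ coordinate is displaced 5 bp in the
5′ direction of the read strand (− 5 for +, +5 for −). All other versions
read genomic sequence directly from the 5′ coordinate. Read_2 is always
genomic from its sonication (or carryover) end — consistent with the
observed lack of bias at A-tailed/ligated Read_2 ends in non-tagmentation
protocols.

### PCR

Each molecule is emitted 1 + Poisson(`dup_mean` − 1) times (shifted
Poisson; no duplication model is published). Copies are byte-identical in
both reads and flagged with the original molecule id, so sequence-level
deduplication inverts amplification exactly whenever originals are
distinct.

## Diagnostics

- **Bias rule**: "more than 10% above background" is relative
  (f > b·(1+m)), never additive: both printed thresholds then agree
  (0.31 → 34.1% displayed ">34%", 0.19 → 20.9% displayed ">21%"). Display
  rounds to the nearest integer percent; the rule never rounds.
- **Profiles**: offsets are measured from the motif midpoint
  (start + ⌊width/2⌋, right-of-center for even widths — this convention
  moves stripes by 1 bp, hence documented) in motif orientation; a tag in
  range of two sites counts at each (pileup semantics). Row sorting is
  linked across matrices, descending by central-window totals of a
  reference dataset or by mean per-matrix rank; ties break on site_id.
- **Peaks**: per-stratum argmax after optional moving-average smoothing;
  ties break toward smaller |offset|, then negative; an all-zero stratum
  reports an absent peak rather than a fake one.
- **Insert size** is the outer-coordinate span of the read pair (the
  standard paired-end definition); whether published distributions are
  outer-to-outer or 5′-to-5′ is not stated, so users comparing against
  published histograms should mind the one-read-length difference.
- **Dedupe** defaults to the sequence definition (identical Read_1 and
  Read_2); coordinate mode exists because heterogeneous Read_2 sonication
  ends make the two equivalent in practice — except at stop-site pileups
  without a random barcode, where distinct molecules can share both
  coordinates and collapse (visible as duplicate rates slightly above the
  PCR expectation for exo 1.1/5.0; the UMI-bearing nexus library recovers
  the PCR rate exactly).

## What the synthetic data does and does not emulate

The generator reproduces base composition (A/T 31%, G/C 19%), oriented
planted sites of one fixed 10-mer, sonication size structure, per-version
5′-end geometry, Tn5 bias/carryover, barcode erosion and PCR duplication.
It does **not** emulate chromatin context, mappability, repeats, base-call
errors, adapter dimers, motif-sequence heterogeneity, or crosslinking
heterogeneity across sites (stops are deterministic given the site).
Consequences drawn in the tests are therefore about the *machinery* —
geometry recovery, filter behavior, estimator calibration — not about
biological variability. One artifact matters for QC: because ~90% of
enriched-library reads start at copies of a single planted motif, the
motif text itself imprints on Read_1 nucleotide profiles; composition QC
is a genome-wide property, so bias-call checks use site-free
(`background_frac = 1`) companion libraries.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; BED is native; a
  minus-strand read's 5′ end is its interval's last base (end − 1).
- Crosslink/stop offsets default to (8, 6) bp — figures show stop stripes
  but print no offsets; both are configurable and all geometry tests
  recover whatever is configured.
- Default problem sizes (300 kb genome, 200 sites, 50,000 molecules) were
  chosen so that stop peaks are recovered with ±1 bp margin and 3-SE
  statistical checks have comfortable power; they run in a few seconds per
  library.
- The insert-mode recovery test uses a tight size selection (sd 15 bp):
  with the default broad sd the integer-size histogram is flat within
  sampling noise over ±10 bp around the mode, so the most-frequent-integer
  estimator wanders that plateau and no n makes a ±5 bp assertion
  meaningful. The estimator itself is unchanged.
- Validation failures name the offending config field; CLI exit codes are
  0 (success, including empty-result warnings), 2 (validation), 3 (I/O).

## Known limitations

Single chromosome per genome record (multi-chromosome via repeated
specs); no real-aligner path in tests (a FASTQ exporter exists for users
who want to run one); heatmap rendering is presentational and untested
beyond execution; the ChIP-nexus filter implements only the positional
CTGA match, not any additional quality criteria of upstream pipelines.
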