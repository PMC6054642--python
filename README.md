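# exoprof

Simulation and stop-site diagnostics for ChIP-exo-family sequencing
protocols.

ChIP-exo resolves protein–DNA binding to near base-pair resolution by
digesting immunoprecipitated chromatin with lambda exonuclease until the
enzyme stalls at a formaldehyde crosslink; the 5′ end of Read_1 then marks
the exonuclease stop site. The family of protocol variants around this idea
— ChIP-seq, ChIPmentation, the ChIP-exo 1.1/3.1/4.0/4.1/5.0 series, and
ChIP-nexus — differ in how adapters are attached (ligation, Tn5
tagmentation, single-stranded splint ligation) and each choice leaves a
characteristic fingerprint in the sequenced reads: shouldering from
undigested molecules, Tn5 sequence bias at non-digested read ends, barcode
erosion by T4-polymerase over-trimming, and bp-scale displacements of the
apparent stop site.

`exoprof` is for methods developers and analysts who want those
fingerprints as *testable, quantitative* objects. It provides:

- **a mechanistic paired-end library simulator** (`exoprof.simulate`):
  sonication fragments with binding-site enrichment and per-strand
  crosslinks, Tn5 tagmentation with a 19-bp position-weight-matrix cut
  preference and carryover, exonuclease digestion with shouldering and
  inner-stop ligation efficiency, version-specific barcoding (ChIP-nexus
  5-nt random barcode + CTGA spacer, version-4.0 random pentamer), and PCR
  duplication. Records carry true genomic coordinates and provenance flags,
  so every downstream analysis is testable without alignment or downloads.
- **the comparison diagnostics** used to tell protocols apart
  (`exoprof.qc`, `exoprof.profiles`): 5′-end nucleotide-frequency profiles
  and relative-margin bias calls with IUPAC summaries, the CTGA barcode
  filter with failure-mode profiling, insert-size mode ± SD, duplicate-rate
  reporting, and strand-separated motif-anchored profiling (heatmap
  matrices with linked row sorting, composites, stop-site peaks and shifts,
  shoulder fraction, strand-segregation score).

## The core statistics

For tag 5′ ends accumulated around oriented motif sites (offset measured
from the motif midpoint in motif orientation; "same" stratum = tag strand
equals motif strand):

- **bias call**: nucleotide *n* at read position *i* is flagged when
  f_i(n) > b(n)·(1 + m) with margin m = 0.10; on the yeast-like background
  (A/T 31%, G/C 19%) the displayed thresholds are A/T > 34% and G/C > 21%.
- **shoulder fraction**: tags with 50 < |offset| ≤ 500 over tags with
  |offset| ≤ 500, both strata pooled — the ChIP-seq-like halo around the
  stop-site stripes.
- **strand-segregation score**: S = f_same(offset<0) + f_opp(offset>0) − 1
  ∈ [−1, 1]; 1 is the perfectly segregated blue/red exo pattern, 0 is
  strand-independent scatter (the "purple" look of Tn5 carryover).
- **peak shift**: signed difference of per-stratum composite argmax
  offsets between two libraries; the version-4.0 chemistry reads a random
  pentamer before genomic bases, displacing its mapped stop peaks 5 bp away
  from the motif midpoint.

## Worked example

```python
import exoprof as xp

g = xp.generate_genome(xp.GenomeSpec(length=300_000, seed=1))
g, sites = xp.plant_motifs(g, n_sites=200, min_spacing=1200, seed=2)

for version in ("exo5.0", "exo4.0", "seq"):
    cfg = xp.SimConfig.for_version(version, seed=11, n_fragments=50_000)
    records, truth = xp.simulate_library(g, sites, cfg)
    tags = xp.dedupe(xp.TagSet.from_records(records))
    mat = xp.anchor_matrix(xp.five_prime_ends(tags), sites, window=500)
    comp = xp.composite(mat)
    print(version, xp.peak_offsets(comp),
          round(xp.shoulder_fraction(mat), 3),
          round(xp.strand_segregation_score(mat), 3))
```

prints

```
exo5.0 (-14, 14) 0.268 0.585
exo4.0 (-19, 19) 0.405 0.733
seq (-11, 6) 0.776 0.724
```

Version 5.0 stops at −14/+14 bp: the configured crosslink geometry
(crosslink 8 bp from the midpoint, stop 6 bp 5′ of the crosslink) recovered
exactly, with about 27% of in-window signal in the shoulder. Version 4.0
shows the same stops displaced 5 bp outward by its pentamer prefix and more
shouldering; the ChIP-seq control has no meaningful stop stripe (its argmax
wanders the broad fragment-end distribution) and ~78% of its signal lies
beyond ±50 bp.

The same pipeline is scripted end to end in `analysis/01...04`
(simulate all eight protocols, barcode QC, insert/bias table, stop-site
metrics), writing small summary tables under `results/`, and is available
as a CLI: `exoprof simulate | qc | profile | report` (each run writes a
manifest with the effective config and seed for byte-identical reruns).

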