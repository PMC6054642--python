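#!/usr/bin/env python
"""Simulate matched libraries for every protocol variant.

Builds one shared 300 kb genome with 200 planted binding sites, then
simulates ChIP-seq, ChIPmentation, ChIP-exo 1.1/3.1/4.0/4.1/5.0 and
ChIP-nexus libraries (50,000 molecules each) over it, writing tag tables,
truth tables and the site BED under scratch/libraries/ for the later
analysis steps.
"""

from pathlib import Path

import exoprof as xp

OUT = Path(__file__).resolve().parent.parent / "scratch" / "libraries"
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    genome = xp.generate_genome(xp.GenomeSpec(length=300_000, seed=1))
    genome, sites = xp.plant_motifs(genome, n_sites=200, min_spacing=1200, seed=2)
    xp.write_fasta(OUT / "genome.fa", {"chrS": genome})
    xp.write_sites_bed(sites, OUT / "sites.bed")

    for version in xp.VERSIONS:
        cfg = xp.SimConfig.for_version(version, seed=SEED, n_fragments=50_000)
        records, truth = xp.simulate_library(genome, sites, cfg)
        tagset = xp.TagSet.from_records(records, version=version, read_len=cfg.read_len)
        stem = version.replace(".", "")
        xp.write_tags_tsv(tagset, OUT / f"{stem}_tags.tsv")
        xp.tags.write_truth_tsv(truth, OUT / f"{stem}_truth.tsv")
        cfg.to_yaml(OUT / f"{stem}_config.yaml")
        print(f"{version:10s}: {len(records):6d} records "
              f"({truth['duplicate_of'].ne('').sum()} PCR duplicates)")
    print(f"libraries written to {OUT}")


if __name__ == "__main__":
    main()
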