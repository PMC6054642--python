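#!/usr/bin/env python
"""ChIP-nexus barcode QC and the over-trimming failure signature.

Every untrimmed Read_1 carries CTGA at positions 6-9; reads eroded by
T4-polymerase over-trimming lose the static barcode terminal-base first,
so among failing reads the expected-base presence decreases along
C (pos 6) >= T (7) >= G (8) >= A (9).  This script simulates nexus
libraries across a range of over-trimming rates and tabulates pass/fail
counts and the presence ordering.
"""

from pathlib import Path

import pandas as pd

import exoprof as xp
from exoprof import qc

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 13


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    genome = xp.generate_genome(xp.GenomeSpec(length=300_000, seed=1))
    genome, sites = xp.plant_motifs(genome, n_sites=200, min_spacing=1200, seed=2)
    rows = []
    for p_overtrim in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        cfg = xp.SimConfig.for_version(
            "nexus", seed=SEED, n_fragments=20_000, p_overtrim=p_overtrim
        )
        records, _ = xp.simulate_library(genome, sites, cfg)
        bq = qc.barcode_qc([r.r1_seq for r in records])
        row = {
            "p_overtrim": p_overtrim,
            "n_pass": bq.n_pass,
            "n_fail": bq.n_fail,
            "fail_fraction": round(bq.n_fail / (bq.n_pass + bq.n_fail), 4),
        }
        for pos, base in zip((6, 7, 8, 9), "CTGA"):
            row[f"presence_{base}_pos{pos}"] = round(
                bq.fail_barcode_presence.get(pos, float("nan")), 4
            )
        rows.append(row)
        print(row)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "barcode_qc.tsv", sep="\t", index=False)
    ordered = df.dropna().apply(
        lambda r: r["presence_C_pos6"] >= r["presence_T_pos7"]
        >= r["presence_G_pos8"] >= r["presence_A_pos9"],
        axis=1,
    )
    print(f"\npresence ordering C>=T>=G>=A holds in {int(ordered.sum())}/{len(ordered)} "
          f"trimmed conditions; table -> {OUT / 'barcode_qc.tsv'}")


if __name__ == "__main__":
    main()
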