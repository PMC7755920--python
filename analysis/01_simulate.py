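#!/usr/bin/env python
"""Generate the synthetic two-condition CAGE study.

Writes the genome (FASTA), the ground-truth promoter table and the two
per-condition CTSS tables under results/study/.  The composition follows
the standard study conditions: 500 sharp W-box promoters expressed in WT
only, 500 broad mutant-dominated promoters, 100 dual-code shifting
promoters, 10^6 tags per condition.
"""

import os

from promarch.io import write_ctss, write_fasta
from promarch.synthetic import simulate_study

SEED = 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    genome, truth, datasets = simulate_study(seed=SEED)
    write_fasta(genome, os.path.join(OUT, "genome.fa"))
    truth.to_csv(os.path.join(OUT, "truth.tsv"), sep="\t", index=False)
    for name, ds in datasets.items():
        write_ctss(ds, os.path.join(OUT, f"{name}.ctss.tsv"))
    print(f"planted {len(truth)} promoters "
          f"({truth['promoter_class'].value_counts().to_dict()})")
    for name, ds in datasets.items():
        print(f"{name}: {ds.total_raw:,} tags at {len(ds):,} CTSS positions")
    print(f"outputs in {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
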