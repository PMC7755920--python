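#!/usr/bin/env python
"""Run the full promoter-architecture pipeline on the simulated study.

Reads the outputs of 01_simulate.py and produces, under results/pipeline/:
the subtracted dependent CTSS set, normalized tables, tag clusters with
interquantile widths, consensus clusters, the expression matrix, SOM
assignments, shift results and motif tables, plus a manifest with
checksums.
"""

import os

from promarch.config import PipelineConfig
from promarch.pipeline import run_pipeline

HERE = os.path.dirname(__file__)
STUDY = os.path.join(HERE, "..", "results", "study")
OUT = os.path.join(HERE, "..", "results", "pipeline")
SEED = 1


def main() -> None:
    import logging

    logging.basicConfig(level=logging.INFO)
    _, manifest = run_pipeline(
        PipelineConfig(),
        os.path.join(STUDY, "wt.ctss.tsv"),
        os.path.join(STUDY, "mutant.ctss.tsv"),
        os.path.join(STUDY, "genome.fa"),
        OUT,
        seed=SEED,
    )
    print(f"{len(manifest.outputs)} output files in {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
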