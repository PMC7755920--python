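"""End-to-end promoter-architecture analysis.

Fixed stage order: position-level subtraction (WT minus mutant positions
gives the factor-dependent set; the mutant set passes through as the
independent set), per-set power-law normalization, distance clustering with
interquantile widths, consensus aggregation, the expression matrix, SOM
expression profiling, KS shifting-promoter detection, and core-promoter
motif analysis.  Every stage writes a TSV (plus BED for clusters) and the
run manifest records config, seeds and output checksums, so deterministic
stages are bit-reproducible and stochastic ones reproducible from the
recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .clustering import cluster_ctss, subtract_ctss
from .consensus import aggregate_clusters, expression_matrix
from .io import CtssDataset, clusters_to_bed, read_ctss, read_fasta, write_ctss
from .motifs import best_tata_match, information_content_logo, load_tbp_pwm, ww_density
from .normalization import normalize_power_law
from .shifting import get_shifting_promoters, score_all_shifts
from .som import label_condition_nodes, som_profiles
from .io import fetch_window

log = logging.getLogger("promarch")

__all__ = ["run_pipeline", "RunManifest"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]
    seeds: dict[str, int]
    outputs: dict[str, dict] = field(default_factory=dict)
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    failed_stage: str | None = None

    def record(self, stage: str, path: str) -> None:
        self.outputs[path] = {"stage": stage, "sha256": _sha256(path)}

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def run_pipeline(
    config: PipelineConfig,
    wt_ctss: str | CtssDataset,
    mutant_ctss: str | CtssDataset,
    genome: str | dict,
    outdir: str,
    seed: int = 0,
) -> tuple[str, RunManifest]:
    """Run the full analysis; returns (outdir, manifest).

    Any stage failure is re-raised with the stage name after writing the
    partial manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    inputs = {}
    if isinstance(wt_ctss, str):
        inputs["wt_ctss"] = _sha256(wt_ctss)
        wt_ctss = read_ctss(wt_ctss, sample_id="wt")
    if isinstance(mutant_ctss, str):
        inputs["mutant_ctss"] = _sha256(mutant_ctss)
        mutant_ctss = read_ctss(mutant_ctss, sample_id="mutant")
    if isinstance(genome, str):
        inputs["genome"] = _sha256(genome)
        genome = read_fasta(genome)
    manifest = RunManifest(
        config=config.to_dict(), inputs=inputs,
        seeds={"som": int(config.som.seed if config.som.seed else seed)},
        started=time.time(),
    )
    stage = "init"
    try:
        # ---- subtraction -------------------------------------------------
        stage = "subtract"
        dep = subtract_ctss(wt_ctss, mutant_ctss, min_mutant_count=config.clustering.min_mutant_count)
        dep.sample_id = "dependent"
        indep = CtssDataset(mutant_ctss.df.copy(), sample_id="independent")
        log.info("subtract: %d WT CTSS -> %d dependent (removed %d shared positions)",
                 len(wt_ctss), len(dep), len(wt_ctss) - len(dep))
        p = os.path.join(outdir, "dependent.ctss.tsv")
        write_ctss(dep, p); manifest.record(stage, p)

        # ---- normalization ----------------------------------------------
        stage = "normalize"
        ncfg = config.normalization
        samples: dict[str, CtssDataset] = {}
        fits = []
        for ds in (dep, indep):
            if len(ds) == 0:  # degenerate input: keep the sample, no signal
                empty = ds.df.copy()
                empty["tpm"] = pd.Series(dtype=float)
                samples[ds.sample_id] = CtssDataset(empty, sample_id=ds.sample_id)
                log.warning("normalize[%s]: empty dataset, passing through", ds.sample_id)
                continue
            norm, fit = normalize_power_law(ds, fit_range=tuple(ncfg.fit_range),
                                            alpha=ncfg.alpha, total=ncfg.total)
            samples[ds.sample_id] = norm
            if fit is not None:
                fits.append(fit.to_frame().assign(sample=ds.sample_id))
            p = os.path.join(outdir, f"{ds.sample_id}.ctss.norm.tsv")
            write_ctss(norm, p, include_tpm=True); manifest.record(stage, p)
            log.info("normalize[%s]: %d positions, %d raw tags", ds.sample_id, len(norm), norm.total_raw)
        if fits:
            p = os.path.join(outdir, "powerlaw_fits.tsv")
            pd.concat(fits, ignore_index=True).to_csv(p, sep="\t", index=False)
            manifest.record(stage, p)

        # ---- clustering --------------------------------------------------
        stage = "cluster"
        ccfg = config.clustering
        cluster_tables: dict[str, pd.DataFrame] = {}
        for name, ds in samples.items():
            tc = cluster_ctss(ds, threshold=ccfg.threshold, max_dist=ccfg.max_dist,
                              keep_singletons_above=ccfg.keep_singletons_above,
                              q_low=ccfg.q_low, q_up=ccfg.q_up)
            cluster_tables[name] = tc
            log.info("cluster[%s]: %d tag clusters", name, len(tc))
            p = os.path.join(outdir, f"{name}.clusters.tsv")
            tc.to_csv(p, sep="\t", index=False); manifest.record(stage, p)
            p = os.path.join(outdir, f"{name}.clusters.bed")
            clusters_to_bed(tc, p); manifest.record(stage, p)

        # ---- consensus + expression -------------------------------------
        stage = "consensus"
        cons = aggregate_clusters(cluster_tables, tpm_threshold=config.consensus.tpm_threshold,
                                  max_dist=config.consensus.max_dist)
        log.info("consensus: %d regions", len(cons))
        p = os.path.join(outdir, "consensus.tsv")
        cons.to_csv(p, sep="\t", index=False); manifest.record(stage, p)
        expr, dominants = expression_matrix(cons, samples)
        p = os.path.join(outdir, "expression.tsv")
        expr.to_csv(p, sep="\t"); manifest.record(stage, p)

        # ---- SOM ---------------------------------------------------------
        stage = "som"
        try:
            som = som_profiles(expr, tpm_threshold=config.som.tpm_threshold,
                               xdim=config.som.xdim, ydim=config.som.ydim,
                               seed=manifest.seeds["som"])
            labels = label_condition_nodes(som, "dependent", "independent")
            assign = som.assignments.to_frame()
            assign["dependent_specific"] = assign["som_node"] == labels["dependent"]
            assign["independent_specific"] = assign["som_node"] == labels["independent"]
            p = os.path.join(outdir, "som_assignments.tsv")
            assign.to_csv(p, sep="\t"); manifest.record(stage, p)
            log.info("som: %d profiles on %dx%d grid; condition nodes %s",
                     len(som.assignments), som.xdim, som.ydim, labels)
        except ValueError as exc:
            log.warning("som skipped: %s", exc)

        # ---- shifting ----------------------------------------------------
        stage = "shift"
        scfg = config.shifting
        shifts = score_all_shifts(cons, samples["dependent"], samples["independent"],
                                  min_tpm=scfg.min_tpm, use_raw_counts=scfg.use_raw_counts)
        selected = get_shifting_promoters(shifts, fdr_threshold=scfg.fdr_threshold,
                                          score_threshold=scfg.score_threshold)
        log.info("shift: %d scored, %d selected at FDR <= %g", len(shifts), len(selected), scfg.fdr_threshold)
        p = os.path.join(outdir, "shift_results.tsv")
        shifts.to_csv(p, sep="\t", index=False); manifest.record(stage, p)
        p = os.path.join(outdir, "shifting_promoters.tsv")
        selected.to_csv(p, sep="\t", index=False); manifest.record(stage, p)

        # ---- motifs -------------------------------------------------------
        stage = "motifs"
        mcfg = config.motifs
        pwm = load_tbp_pwm(pseudocount=mcfg.pseudocount, background=mcfg.background)
        up, down = -mcfg.density_window[0], mcfg.density_window[1]
        lup, ldown = -mcfg.logo_window[0], mcfg.logo_window[1]
        for name, tc in cluster_tables.items():
            if len(tc) == 0:
                continue
            tata = best_tata_match(tc, genome, pwm, window=tuple(mcfg.tata_window))
            p = os.path.join(outdir, f"{name}.tata_best_match.tsv")
            tata.to_frame().assign(iq_width=tc["iq_width"].to_numpy()).to_csv(p, sep="\t")
            manifest.record(stage, p)
            log.info("motifs[%s]: median best TATA match %.1f%%", name, tata.median())
            seqs = [fetch_window(genome, r.chrom, int(r.dominant_pos), r.strand, up, down)
                    for r in tc.itertuples()]
            prof = ww_density(seqs, tc["iq_width"].to_numpy())
            p = os.path.join(outdir, f"{name}.ww_positional_mean.tsv")
            pd.DataFrame({"offset_index": np.arange(prof.occurrence.shape[1]),
                          "ww_fraction": prof.positional_mean}).to_csv(p, sep="\t", index=False)
            manifest.record(stage, p)
            logo_seqs = [fetch_window(genome, r.chrom, int(r.dominant_pos), r.strand, lup, ldown)
                         for r in tc.itertuples()]
            p = os.path.join(outdir, f"{name}.logo_matrix.tsv")
            information_content_logo(logo_seqs).to_csv(p, sep="\t", index=False)
            manifest.record(stage, p)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        manifest.write(os.path.join(outdir, "manifest.json"))
        log.error("pipeline failed at stage %r", stage)
        raise
    manifest.finished = time.time()
    manifest.write(os.path.join(outdir, "manifest.json"))
    return outdir, manifest
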