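"""End-to-end pipeline: simulate -> observe -> call -> landscape / interference.

Every stage writes its artifact under the configured output directory and a
manifest records the package version, seed and a parameter hash, so a rerun
with the same config is byte-identical (timestamps excluded by design: the
manifest carries none).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import CallerParams, call_population, count_per_individual
from .genome import RegionAnnotation, arabidopsis_like_genome
from .interference import extract_cis_dco
from .io import PipelineConfig, write_crossover_calls, write_genotype_matrix, write_sim_truth
from .landscape import bin_fixed, scale_tel_cen
from .simulate import (
    MeiosisParams,
    ObservationParams,
    observe_genotypes,
    simulate_f2_population,
)

__all__ = ["run_pipeline", "make_marker_scaffold"]

log = logging.getLogger("xomap")


def make_marker_scaffold(genome, spacing_bp: int) -> pd.DataFrame:
    """Evenly spaced markers per chromosome, anchored at both chromosome ends."""
    rows = []
    for chrom in genome:
        pos = list(range(1, chrom.length_bp, spacing_bp))
        if pos[-1] != chrom.length_bp:
            pos.append(chrom.length_bp)
        rows.extend((chrom.name, p) for p in pos)
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def _stage(name: str):
    log.info("[%s] starting", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full simulation + analysis pipeline; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    rng = np.random.default_rng(config.seed)
    genome = arabidopsis_like_genome(**config.genome)
    meiosis = MeiosisParams(**config.meiosis)
    obs = ObservationParams(**config.observation)
    caller = CallerParams(**config.caller)
    annotation = RegionAnnotation.from_genome(genome)

    try:
        _stage("simulate")
        markers = make_marker_scaffold(genome, config.marker_spacing_bp)
        truth_geno, truth = simulate_f2_population(
            genome, meiosis, config.n_individuals, markers, rng
        )
        write_genotype_matrix(truth_geno, out / "genotypes_true.tsv", seed=config.seed)
        write_sim_truth(truth, out / "sim_truth.tsv", seed=config.seed)

        _stage("observe")
        observed, _depths = observe_genotypes(truth_geno, obs, rng)
        write_genotype_matrix(observed, out / "genotypes_observed.tsv", seed=config.seed)

        _stage("call")
        segments, calls = call_population(observed, caller)
        write_crossover_calls(calls, out / "crossovers.tsv", dialect="native",
                              seed=config.seed)
        write_crossover_calls(calls, out / "crossovers.bed.tsv", dialect="bed",
                              seed=config.seed)
        _totals, mean = count_per_individual(calls, config.n_individuals)

        _stage("landscape")
        lengths = {c.name: c.length_bp for c in genome}
        profile = bin_fixed(calls, lengths, config.window_bp,
                            config.n_individuals, annotation)
        profile.to_csv(out / "landscape_fixed.tsv", sep="\t", index=False)
        scaled = scale_tel_cen(calls, annotation, config.n_bins, config.n_individuals)
        scaled.to_csv(out / "landscape_scaled.tsv", sep="\t", index=False)

        _stage("interference")
        dco = extract_cis_dco(segments, calls)
        dco.to_csv(out / "cis_dco.tsv", sep="\t", index=False)
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {err}") from err

    params_blob = json.dumps(
        {
            "genome": config.genome,
            "meiosis": asdict(meiosis),
            "observation": asdict(obs),
            "caller": asdict(caller),
            "n_individuals": config.n_individuals,
            "marker_spacing_bp": config.marker_spacing_bp,
            "window_bp": config.window_bp,
            "n_bins": config.n_bins,
        },
        sort_keys=True,
    )
    with open(out / "manifest.txt", "w") as fh:
        fh.write(f"xomap_version={__version__}\n")
        fh.write(f"seed={config.seed}\n")
        fh.write(f"n_individuals={config.n_individuals}\n")
        fh.write(f"mean_crossovers_per_f2={mean:.4f}\n")
        fh.write(f"param_hash={hashlib.sha256(params_blob.encode()).hexdigest()}\n")
    return out
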