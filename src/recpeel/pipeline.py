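"""End-to-end orchestration: simulate -> peel -> map -> QC -> summaries.

A run is driven by a :class:`RunConfig`; every run writes a manifest
(config, seed, package version) so identical config + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .core import PeelingParams
from .io import (
    read_genotypes,
    read_marker_map,
    read_pedigree,
    write_estimates,
    write_genetic_map,
    write_genotypes,
    write_marker_map,
    write_pedigree,
)
from .qc import gametes_to_parent_phenotypes
from .segregation import estimate_recombination
from .simulate import SimConfig, config_to_dict, simulate
from .summaries import accuracy_metrics

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    out_dir: str
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    marker_map_path: str | None = None
    sim: SimConfig | None = None
    params: PeelingParams = dataclasses.field(default_factory=PeelingParams)
    n_map_iterations: int = 4
    init_length_cm: float = 100.0
    seed: int = 1


def _write_manifest(out: Path, config: RunConfig) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "n_map_iterations": config.n_map_iterations,
        "init_length_cm": config.init_length_cm,
        "sim": config_to_dict(config.sim) if config.sim else None,
        "inputs": {
            "pedigree": config.pedigree_path,
            "genotypes": config.genotypes_path,
            "marker_map": config.marker_map_path,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulation(config: RunConfig) -> Path:
    """Simulate a dataset and write it in the primary dialects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimConfig(seed=config.seed)
    result = simulate(sim)
    write_pedigree(result.pedigree, out / "pedigree.txt")
    write_genotypes(result.genotypes, out / "genotypes.txt")
    write_marker_map(result.marker_map, out / "markers.txt")
    write_genetic_map(result.map_female, out / "true_map_female.tsv")
    write_genetic_map(result.map_male, out / "true_map_male.tsv")
    result.truth.to_frame(result.pedigree).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    _write_manifest(out, config)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Full run: load or simulate data, estimate, QC, write outputs.

    In simulation mode (``config.sim`` set and no input paths) accuracy
    metrics against the recorded truth are written as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.pedigree_path:
        for name, p in (
            ("pedigree", config.pedigree_path),
            ("genotypes", config.genotypes_path),
            ("marker map", config.marker_map_path),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        logger.info("reading inputs")
        pedigree = read_pedigree(config.pedigree_path)
        marker_map = read_marker_map(config.marker_map_path)
        genotypes = read_genotypes(config.genotypes_path, marker_map, pedigree)
    else:
        sim_cfg = config.sim or SimConfig(seed=config.seed)
        logger.info("simulating data (seed %d)", sim_cfg.seed)
        sim = simulate(sim_cfg)
        pedigree, genotypes, marker_map = sim.pedigree, sim.genotypes, sim.marker_map
        truth = sim
        write_pedigree(pedigree, out / "pedigree.txt")
        write_genotypes(genotypes, out / "genotypes.txt")
        write_marker_map(marker_map, out / "markers.txt")

    logger.info("estimating recombination (%d map iterations)", config.n_map_iterations)
    est = estimate_recombination(
        pedigree,
        genotypes,
        marker_map,
        params=config.params,
        n_map_iterations=config.n_map_iterations,
        init_length_cm=config.init_length_cm,
    )
    write_genetic_map(est.map_female, out / "map_female.tsv")
    write_genetic_map(est.map_male, out / "map_male.tsv")
    write_estimates(est.estimates_frame(), out / "estimates.tsv")
    pheno = gametes_to_parent_phenotypes(
        pedigree, est.total_crossovers, est.genome_mb, keep=est.qc_keep
    )
    write_estimates(pheno, out / "phenotypes.tsv")

    if truth is not None:
        metrics = _score_against_truth(est, truth)
        (out / "accuracy.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _write_manifest(out, config)
    return out


def _score_against_truth(est, sim) -> dict[str, float]:
    """Accuracy of the estimates on the QC-passing gametes."""
    ped = sim.pedigree
    keep = est.qc_keep & sim.truth.has_gamete.all(axis=1)
    true_tot = sim.truth.n_crossovers[keep]
    est_tot = est.total_crossovers[keep]
    parent_sex = np.stack(
        [ped.sex[ped.sire[keep]], ped.sex[ped.dam[keep]]], axis=1
    )
    true_land = sim.truth.crossovers[keep].sum(axis=(0, 1)).astype(float)
    est_land = est.peel.crossover_expectation[keep].sum(axis=(0, 1))
    metrics = accuracy_metrics(
        true_tot.reshape(-1),
        est_tot.reshape(-1),
        parent_sex.reshape(-1),
        true_land,
        est_land,
    )
    metrics["n_gametes"] = int(keep.sum()) * 2
    metrics["true_total_female_cm"] = float(sim.map_female.total_cm)
    metrics["true_total_male_cm"] = float(sim.map_male.total_cm)
    metrics["est_total_female_cm"] = float(est.map_female.total_cm)
    metrics["est_total_male_cm"] = float(est.map_male.total_cm)
    return metrics
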