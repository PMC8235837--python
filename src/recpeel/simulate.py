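"""Validation simulator: pedigree, founder haplotypes, meioses, genotyping.

The generator emulates the kind of data the estimator targets: a
multi-generation livestock pedigree with few sires and many dams, one
chromosome with a designed sex-specific recombination landscape (constant
in the middle 30-70% of the map, quadratically elevated ends, female map
1.3x the male map), and mixed-density SNP-array genotyping (39% high
density, 51% low density, 10% ungenotyped).  Founder haplotypes come from a
seeded Markov linkage-disequilibrium model: each allele copies its
left neighbour with probability ``ld_decay``, otherwise it is drawn from
the locus allele frequency.  Every meiosis's crossovers are recorded so
estimates can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeMatrix, MarkerMap, MISSING, Pedigree


@dataclass
class SimConfig:
    """Study conditions for the validation simulation.

    Defaults are a desk-scale analogue of a commercial pig line: a
    5-generation pedigree of ~3000 individuals (600 per generation, 30
    sires and 300 dams selected per generation), 1522 SNPs on a 100-Mb
    chromosome, a male map of 85 cM (~0.85 cM/Mb) with the female map 1.3x
    longer, and panel fractions matching the observed genotyping mix.
    """

    n_founders: int = 600
    n_generations: int = 5
    n_per_generation: int = 600
    n_sires: int = 30
    n_dams: int = 300
    n_loci: int = 1522
    chrom_length_bp: int = 100_000_000
    total_length_male_cm: float = 85.0
    female_ratio: float = 1.3
    mid_lo: float = 0.30
    mid_hi: float = 0.70
    end_elevation: float = 3.0
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    ld_decay: float = 0.8
    panel_fractions: tuple[float, float, float] = (0.39, 0.51, 0.10)
    low_panel_fraction_of_loci: float = 0.25
    genotype_error: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.panel_fractions) - 1.0) > 1e-9:
            raise ValueError("panel fractions must sum to 1")
        if not 0.0 < self.mid_lo < self.mid_hi < 1.0:
            raise ValueError("need 0 < mid_lo < mid_hi < 1")


@dataclass
class SimulationTruth:
    """True crossovers per meiosis and true haplotypes.

    ``crossovers`` is (N, 2, L-1) uint8: number of crossovers realised in
    each marker interval of each gamete (paternal side 0); founder rows are
    zero and flagged invalid via ``has_gamete``.
    """

    crossovers: np.ndarray
    has_gamete: np.ndarray  # (N, 2) bool
    haplotypes: np.ndarray  # (N, 2, L) uint8

    @property
    def n_crossovers(self) -> np.ndarray:
        """(N, 2) total crossover count per gamete."""
        return self.crossovers.sum(axis=-1)

    def to_frame(self, pedigree: Pedigree) -> pd.DataFrame:
        rows = []
        totals = self.n_crossovers
        for side, name, parents in (
            (0, "pat", pedigree.sire),
            (1, "mat", pedigree.dam),
        ):
            for i in np.flatnonzero(self.has_gamete[:, side]):
                rows.append(
                    {
                        "offspring_id": pedigree.ids[i],
                        "parent_id": pedigree.ids[parents[i]] if parents[i] >= 0 else "0",
                        "side": name,
                        "n_crossovers": int(totals[i, side]),
                        "intervals": ",".join(
                            str(j) for j in np.flatnonzero(self.crossovers[i, side])
                        ),
                    }
                )
        return pd.DataFrame(rows)


def build_landscape(
    total_length_cm: float,
    n_loci: int,
    mid_lo: float = 0.30,
    mid_hi: float = 0.70,
    end_elevation: float = 3.0,
    chromosome: str = "1",
    sex: str = "averaged",
    positions: np.ndarray | None = None,
) -> GeneticMap:
    """Designed landscape: constant middle, quadratically elevated ends.

    Interval rates are constant ``c`` on the middle ``[mid_lo, mid_hi)`` of
    the map, and rise on each end segment as a second-degree polynomial in
    relative position, continuous (value and slope) at the junction and
    reaching ``end_elevation * c`` at the terminal interval; the whole map
    is rescaled to ``total_length_cm``.
    """
    if n_loci < 3:
        raise ValueError("need at least 3 loci")
    L1 = n_loci - 1
    x = (np.arange(L1) + 0.5) / L1  # interval midpoints in map fraction
    d = np.ones(L1)
    left = x < mid_lo
    right = x >= mid_hi
    # t runs 0 at the junction -> 1 at the chromosome end
    t_left = (mid_lo - x[left]) / mid_lo
    t_right = (x[right] - mid_hi) / (1.0 - mid_hi)
    d[left] = 1.0 + (end_elevation - 1.0) * t_left**2
    d[right] = 1.0 + (end_elevation - 1.0) * t_right**2
    d *= total_length_cm / d.sum()
    return GeneticMap(
        chromosome=chromosome, interval_cm=d, sex=sex, positions=positions
    )


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Random-mating multi-generation pedigree with few sires, many dams."""
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    gen_members: list[np.ndarray] = []
    counter = 0
    for g in range(config.n_generations):
        size = config.n_founders if g == 0 else config.n_per_generation
        start = counter
        for _ in range(size):
            ids.append(f"G{g}_{counter}")
            s = "M" if rng.random() < 0.5 else "F"
            sex.append(s)
            if g == 0:
                sire.append(-1)
                dam.append(-1)
            counter += 1
        members = np.arange(start, counter)
        if g > 0:
            prev = gen_members[g - 1]
            males = prev[np.array([sex[i] == "M" for i in prev])]
            females = prev[np.array([sex[i] == "F" for i in prev])]
            n_sires = min(config.n_sires, len(males))
            n_dams = min(config.n_dams, len(females))
            if n_sires == 0 or n_dams == 0:
                raise ValueError("previous generation lacks one sex entirely")
            sires = rng.choice(males, size=n_sires, replace=False)
            dams = rng.choice(females, size=n_dams, replace=False)
            sire.extend(rng.choice(sires, size=size).tolist())
            dam.extend(rng.choice(dams, size=size).tolist())
        gen_members.append(members)
    line = np.full(len(ids), "sim", dtype=object)
    return Pedigree(
        ids=ids,
        sire=np.array(sire),
        dam=np.array(dam),
        sex=np.array(sex),
        line=line,
    )


def simulate_founders(
    n_founders: int,
    n_loci: int,
    allele_freq_range: tuple[float, float],
    ld_decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(2 * n_founders, L) founder haplotypes under the Markov LD model."""
    lo, hi = allele_freq_range
    freqs = rng.uniform(lo, hi, size=n_loci)
    n_hap = 2 * n_founders
    haps = np.empty((n_hap, n_loci), dtype=np.uint8)
    haps[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, n_loci):
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.uint8)
        copy = rng.random(n_hap) < ld_decay
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return haps


def drop_gametes(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    map_female: GeneticMap,
    map_male: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SimulationTruth]:
    """Transmit haplotypes through every meiosis of the pedigree.

    Each gamete starts on a random parental haplotype and switches in
    interval j with probability ``r_j`` (independent across intervals,
    consistent with Haldane's no-interference model).  Returns the full
    (N, 2, L) haplotype array and the recorded truth.
    """
    n = len(pedigree)
    L = map_female.n_loci
    r = {0: map_male.rec_fractions, 1: map_female.rec_fractions}
    haps = np.zeros((n, 2, L), dtype=np.uint8)
    crossovers = np.zeros((n, 2, L - 1), dtype=np.uint8)
    has_gamete = np.zeros((n, 2), dtype=bool)
    founder_idx = np.flatnonzero(pedigree.founders)
    haps[founder_idx] = founder_haplotypes[: 2 * len(founder_idx)].reshape(
        len(founder_idx), 2, L
    )
    max_gen = int(pedigree.generation.max())
    for g in range(1, max_gen + 1):
        idx = np.flatnonzero(pedigree.generation == g)
        for side, parents in ((0, pedigree.sire[idx]), (1, pedigree.dam[idx])):
            known = parents >= 0
            sub = idx[known]
            if len(sub) == 0:
                continue
            p = parents[known]
            switches = rng.random((len(sub), L - 1)) < r[side]
            start = rng.integers(0, 2, size=len(sub))
            hap_idx = np.empty((len(sub), L), dtype=np.int64)
            hap_idx[:, 0] = start
            hap_idx[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
            gamete = np.take_along_axis(
                haps[p], hap_idx[:, None, :], axis=1
            )[:, 0, :]
            # indexing trick above picks haps[p, hap_idx] locus-wise
            haps[sub, side] = gamete
            crossovers[sub, side] = switches
            has_gamete[sub, side] = True
    truth = SimulationTruth(
        crossovers=crossovers, has_gamete=has_gamete, haplotypes=haps
    )
    return haps, truth


def apply_genotyping(
    true_genotypes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Observe true dosages through mixed-density panels with call errors.

    High-density individuals are observed at every locus, low-density ones
    at an evenly spaced subset, ungenotyped ones not at all; each observed
    call is flipped to one of the two wrong dosages with probability
    ``genotype_error``.
    """
    n, L = true_genotypes.shape
    ids = ids if ids is not None else [str(i) for i in range(n)]
    labels = np.array(["high", "low", "ungenotyped"], dtype=object)
    panel = rng.choice(labels, size=n, p=list(config.panel_fractions))
    n_low = max(2, int(round(config.low_panel_fraction_of_loci * L)))
    low_loci = np.unique(np.round(np.linspace(0, L - 1, n_low)).astype(np.int64))
    observed = np.zeros((n, L), dtype=bool)
    observed[panel == "high"] = True
    low_rows = panel == "low"
    observed[np.ix_(low_rows, low_loci)] = True
    calls = np.full((n, L), MISSING, dtype=np.uint8)
    calls[observed] = true_genotypes[observed]
    flip = observed & (rng.random((n, L)) < config.genotype_error)
    # replace with one of the two wrong dosages, uniformly
    offset = rng.integers(1, 3, size=int(flip.sum()))
    calls[flip] = (calls[flip] + offset) % 3
    return GenotypeMatrix(ids=list(ids), calls=calls, panel=panel)


@dataclass
class SimResult:
    """Everything produced by one simulation run."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    map_female: GeneticMap
    map_male: GeneticMap
    truth: SimulationTruth
    true_genotypes: np.ndarray = field(repr=False, default=None)  # type: ignore


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Run the full generator: pedigree, founders, meioses, genotyping."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    positions = np.round(
        np.linspace(1, config.chrom_length_bp, config.n_loci)
    ).astype(np.int64)
    marker_map = MarkerMap(
        ids=[f"snp{j}" for j in range(config.n_loci)],
        chromosome=np.full(config.n_loci, "1", dtype=object),
        position=positions,
    )
    map_male = build_landscape(
        config.total_length_male_cm,
        config.n_loci,
        config.mid_lo,
        config.mid_hi,
        config.end_elevation,
        sex="M",
        positions=positions,
    )
    map_female = GeneticMap(
        chromosome=map_male.chromosome,
        interval_cm=map_male.interval_cm * config.female_ratio,
        sex="F",
        positions=positions,
    )
    pedigree = simulate_pedigree(config, rng)
    founder_haps = simulate_founders(
        int(pedigree.founders.sum()),
        config.n_loci,
        config.allele_freq_range,
        config.ld_decay,
        rng,
    )
    haps, truth = drop_gametes(pedigree, founder_haps, map_female, map_male, rng)
    true_genotypes = haps.sum(axis=1).astype(np.uint8)
    genotypes = apply_genotyping(true_genotypes, config, rng, ids=list(pedigree.ids))
    return SimResult(
        config=config,
        pedigree=pedigree,
        genotypes=genotypes,
        marker_map=marker_map,
        map_female=map_female,
        map_male=map_male,
        truth=truth,
        true_genotypes=true_genotypes,
    )


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
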