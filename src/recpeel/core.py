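"""Core data containers: pedigree, genotypes, marker map, genetic map, parameters.

Conventions used throughout the package:

* Genotype calls are dosage codes ``{0, 1, 2}`` (count of the ``A`` allele)
  with ``9`` meaning missing.
* Phased (ordered) genotype states are indexed ``0..3`` in the order
  ``(a,a), (a,A), (A,a), (A,A)`` where the pair is (paternal allele,
  maternal allele).
* Physical positions are 1-based bp as given; intervals and windows are
  half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 9

#: paternal allele of each ordered genotype state
STATE_PAT_ALLELE = np.array([0, 0, 1, 1], dtype=np.int8)
#: maternal allele of each ordered genotype state
STATE_MAT_ALLELE = np.array([0, 1, 0, 1], dtype=np.int8)
#: allele dosage of each ordered genotype state
STATE_DOSAGE = np.array([0, 1, 1, 2], dtype=np.int8)

PAT, MAT = 0, 1  # parent-side indices


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


@dataclass
class Pedigree:
    """Directed acyclic family structure.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, unique, in storage order.
    sire, dam : ndarray of int
        Index of the sire/dam within ``ids``; ``-1`` if unknown.
    sex : ndarray of str
        One of ``"F"``, ``"M"``, ``"U"``.
    line : ndarray of object
        Population/line label per individual.
    generation : ndarray of int
        0 for founders, ``1 + max(parent generations)`` otherwise.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    line: np.ndarray
    generation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id: {i!r}")
                seen.add(i)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype="U1")
        self.line = np.asarray(self.line, dtype=object)
        if self.generation is None:
            self.generation = self._compute_generations()
        self._index = {ident: k for k, ident in enumerate(self.ids)}

    def _compute_generations(self) -> np.ndarray:
        """Topological depth of every individual; raises on cycles."""
        n = len(self.ids)
        gen = np.full(n, -1, dtype=np.int64)
        # Kahn's algorithm on the parent->child DAG
        n_parents = (self.sire >= 0).astype(np.int64) + (self.dam >= 0)
        children: list[list[int]] = [[] for _ in range(n)]
        for c in range(n):
            for p in (self.sire[c], self.dam[c]):
                if p >= 0:
                    children[p].append(c)
        queue = [i for i in range(n) if n_parents[i] == 0]
        for i in queue:
            gen[i] = 0
        remaining = n_parents.copy()
        head = 0
        while head < len(queue):
            i = queue[head]
            head += 1
            pg = gen[i]
            for c in children[i]:
                gen[c] = max(gen[c], pg + 1)
                remaining[c] -= 1
                if remaining[c] == 0:
                    queue.append(c)
        if head != n:
            stuck = [self.ids[i] for i in range(n) if remaining[i] > 0]
            raise PedigreeError(
                f"pedigree contains a cycle involving individual {stuck[0]!r}"
            )
        return gen

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ident: str) -> int:
        return self._index[ident]

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of individuals with both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    def offspring_lists(self) -> tuple[list[list[int]], list[list[int]]]:
        """Lists of offspring indices per individual, as (sire-side, dam-side)."""
        as_sire: list[list[int]] = [[] for _ in range(len(self))]
        as_dam: list[list[int]] = [[] for _ in range(len(self))]
        for c in range(len(self)):
            if self.sire[c] >= 0:
                as_sire[self.sire[c]].append(c)
            if self.dam[c] >= 0:
                as_dam[self.dam[c]].append(c)
        return as_sire, as_dam


@dataclass
class MarkerMap:
    """Ordered markers on (one or more) chromosomes with bp positions."""

    ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        for chrom in self.chromosomes:
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def chromosomes(self) -> list:
        seen: list = []
        for c in self.chromosome:
            if c not in seen:
                seen.append(c)
        return seen

    def split_by_chromosome(self) -> dict:
        """One single-chromosome MarkerMap per chromosome, with locus indices."""
        out = {}
        for chrom in self.chromosomes:
            mask = self.chromosome == chrom
            idx = np.flatnonzero(mask)
            sub = MarkerMap(
                ids=[self.ids[i] for i in idx],
                chromosome=self.chromosome[idx],
                position=self.position[idx],
            )
            out[chrom] = (sub, idx)
        return out

    @property
    def span_mb(self) -> float:
        """bp span (last − first marker) summed over chromosomes, in Mb."""
        total = 0
        for chrom in self.chromosomes:
            pos = self.position[self.chromosome == chrom]
            total += int(pos[-1] - pos[0])
        return total / 1e6


@dataclass
class GenotypeMatrix:
    """Per-individual per-locus dosage calls with missingness.

    ``calls`` is an (n_individuals, n_loci) uint8 array over {0,1,2,9};
    ``panel`` labels each individual "high", "low" or "ungenotyped".
    """

    ids: list[str]
    calls: np.ndarray
    panel: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        self.panel = np.asarray(self.panel, dtype=object)
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[i, j]} for individual "
                f"{self.ids[i]!r} at locus {j}"
            )
        all_missing = (self.calls == MISSING).all(axis=1)
        for k in np.flatnonzero(all_missing):
            self.panel[k] = "ungenotyped"

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def genotyped(self) -> np.ndarray:
        """Boolean mask: has at least one non-missing call."""
        return (self.calls != MISSING).any(axis=1)

    def aligned_to(self, pedigree: Pedigree) -> "GenotypeMatrix":
        """Reorder rows to pedigree order; absent individuals become all-missing."""
        n, L = len(pedigree), self.n_loci
        calls = np.full((n, L), MISSING, dtype=np.uint8)
        panel = np.full(n, "ungenotyped", dtype=object)
        index = {ident: k for k, ident in enumerate(self.ids)}
        for i, ident in enumerate(pedigree.ids):
            k = index.get(ident)
            if k is not None:
                calls[i] = self.calls[k]
                panel[i] = self.panel[k]
        return GenotypeMatrix(ids=list(pedigree.ids), calls=calls, panel=panel)


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Inverse Haldane: recombination fraction -> cM distance."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * np.clip(r, 0.0, 0.5 - 1e-12))


@dataclass
class GeneticMap:
    """Per-interval genetic distances for one chromosome, for one sex.

    ``interval_cm`` has length ``n_loci - 1``.  ``positions`` (optional)
    carries marker bp positions for rate reporting and windowing.
    """

    chromosome: str
    interval_cm: np.ndarray
    sex: str = "averaged"
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.interval_cm = np.asarray(self.interval_cm, dtype=float)
        if np.any(self.interval_cm < 0):
            raise ValueError("negative interval length")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.positions) != len(self.interval_cm) + 1:
                raise ValueError("positions must have n_intervals + 1 entries")

    @property
    def n_loci(self) -> int:
        return len(self.interval_cm) + 1

    @property
    def total_cm(self) -> float:
        return float(self.interval_cm.sum())

    @property
    def rec_fractions(self) -> np.ndarray:
        return haldane_r(self.interval_cm)

    @classmethod
    def uniform(
        cls,
        chromosome: str,
        n_loci: int,
        total_cm: float = 100.0,
        sex: str = "averaged",
        positions: np.ndarray | None = None,
    ) -> "GeneticMap":
        d = np.full(n_loci - 1, total_cm / (n_loci - 1), dtype=float)
        return cls(chromosome=chromosome, interval_cm=d, sex=sex, positions=positions)


@dataclass
class PeelingParams:
    """Tunables of the peeling estimator.

    genotype_error
        Symmetric genotyping error rate ε used in the penetrance and in the
        called-offspring posterior factors.
    seg_call_threshold, geno_call_threshold
        Probabilities above which segregation / genotype states are called
        (taken as certain); below, they are treated as missing.
    n_outer_cycles, convergence_tol
        Peeling cycles per map iteration and early-stop criterion on the
        largest absolute genotype-probability change.
    """

    genotype_error: float = 0.01
    seg_call_threshold: float = 0.99
    geno_call_threshold: float = 0.90
    n_outer_cycles: int = 5
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.genotype_error < 0.5:
            raise ValueError("genotype_error must be in (0, 0.5)")
        for name in ("seg_call_threshold", "geno_call_threshold"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ValueError(f"{name} must be in (0.5, 1]")
        if self.n_outer_cycles < 1:
            raise ValueError("n_outer_cycles must be >= 1")
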