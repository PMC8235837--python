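"""Multilocus iterative peeling over a genotyped pedigree.

Every individual's phased-genotype distribution (4 ordered states per locus)
is the normalised product of three factors:

* **penetrance** — likelihood of its own dosage call under a symmetric
  genotyping-error model with rate ε;
* **anterior** — transmission from its parents' distributions weighted by
  the segregation probabilities of the inheritance HMM (the two parent
  sides are factorised rather than modelled jointly);
* **posterior** — evidence from its offspring, where each offspring's
  genotype and segregation are first *called* (taken as certain above the
  calling thresholds, missing otherwise) so that its contribution reduces
  to a small set of per-locus factor patterns.

Two details tighten the message passing: (1) when a parent's distribution
is used to peel a given child, that child's own posterior factor is divided
out first, and (2) the anterior uses leave-one-out segregation marginals
(all evidence except the locus itself) so a locus's data is not counted
twice.  Peeling sweeps the pedigree in generation order; calling and the
posterior factors are refreshed after every sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    MAT,
    MISSING,
    PAT,
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    PeelingParams,
    STATE_MAT_ALLELE,
    STATE_PAT_ALLELE,
)
from .segregation import (
    _normalize,
    expected_crossovers,
    forward_backward,
    leave_one_out_gamma,
)

logger = logging.getLogger(__name__)

_PAT_A = STATE_PAT_ALLELE.astype(float)  # allele on haplotype 0 of each state
_MAT_A = STATE_MAT_ALLELE.astype(float)  # allele on haplotype 1

CODE_MISSING = 4  # offspring factor code when either call is missing


def penetrance(call: int, eps: float) -> np.ndarray:
    """Likelihood of a dosage call given each ordered genotype state.

    States consistent with the call get ``1 - eps``; inconsistent states
    share ``eps`` equally.  A missing call (9) is uninformative.
    """
    if call == MISSING:
        return np.ones(4)
    if call not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {call!r}")
    consistent = np.array([0, 1, 1, 2]) == call
    k = (~consistent).sum()
    return np.where(consistent, 1.0 - eps, eps / k)


def _penetrance_table(eps: float) -> np.ndarray:
    """(10, 4) lookup indexed by dosage code (rows 3..8 unused)."""
    table = np.ones((10, 4))
    for call in (0, 1, 2):
        table[call] = penetrance(call, eps)
    return table


def _code_patterns(eps: float) -> np.ndarray:
    """(5, 4) offspring-factor patterns over parent states.

    Code ``2*allele + seg`` means: offspring's called transmitted allele
    ``allele`` arrived via parent haplotype ``seg``.  Parent states whose
    haplotype-``seg`` allele matches get ``1 - eps``, others ``eps``;
    code 4 (missing) contributes nothing.
    """
    pat = np.empty((5, 4))
    hap_allele = np.stack([_PAT_A, _MAT_A])  # [seg, state]
    for allele in (0, 1):
        for seg in (0, 1):
            match = hap_allele[seg] == allele
            pat[2 * allele + seg] = np.where(match, 1.0 - eps, eps)
    pat[CODE_MISSING] = 1.0
    return pat


def anterior(
    father_dist: np.ndarray,
    mother_dist: np.ndarray,
    seg_pat: np.ndarray,
    seg_mat: np.ndarray,
) -> np.ndarray:
    """Child ordered-genotype distribution implied by its parents.

    Per the factorised-parents simplification, the paternal and maternal
    allele distributions are computed independently: segregation state s
    selects the parent's haplotype-s allele.
    """
    f, m = np.asarray(father_dist, float), np.asarray(mother_dist, float)
    sp, sm = np.asarray(seg_pat, float), np.asarray(seg_mat, float)
    p_pat_A = sp[0] * (f @ _PAT_A) + sp[1] * (f @ _MAT_A)
    p_mat_A = sm[0] * (m @ _PAT_A) + sm[1] * (m @ _MAT_A)
    pat = np.array([1 - p_pat_A, p_pat_A])
    mat = np.array([1 - p_mat_A, p_mat_A])
    return np.outer(pat, mat).ravel()


def call_probabilities(dist: np.ndarray, tau: float) -> int | None:
    """Argmax state if its probability reaches tau, else None (missing)."""
    dist = np.asarray(dist, float)
    k = int(np.argmax(dist))
    return k if dist[k] >= tau else None


def segregation_evidence(
    child_locus_data: np.ndarray,
    parent_dist: np.ndarray,
    other_side_allele_dist: np.ndarray,
    side: int = PAT,
) -> np.ndarray:
    """p(child's data at a locus | focal parent transmits haplotype s).

    ``child_locus_data`` is the child's own likelihood over its 4 ordered
    states (penetrance x posterior); the focal parent fills the paternal or
    maternal slot according to ``side``; the other parent is marginalised
    through ``other_side_allele_dist``.  Uninformative inputs give [c, c].
    """
    cl = np.asarray(child_locus_data, float)
    p = np.asarray(parent_dist, float)
    q = np.asarray(other_side_allele_dist, float)
    if side == PAT:
        m0 = q[0] * cl[0] + q[1] * cl[1]
        m1 = q[0] * cl[2] + q[1] * cl[3]
    else:
        m0 = q[0] * cl[0] + q[1] * cl[2]
        m1 = q[0] * cl[1] + q[1] * cl[3]
    m = np.array([m0, m1])
    e0 = p @ m[STATE_PAT_ALLELE]
    e1 = p @ m[STATE_MAT_ALLELE]
    e = np.array([e0, e1])
    s = e.sum()
    return e / s if s > 0 else np.array([0.5, 0.5])


def posterior_from_offspring(
    parent_side: int,
    offspring_called: list[tuple[np.ndarray, np.ndarray]],
    eps: float,
    n_loci: int | None = None,
) -> np.ndarray:
    """Parent genotype evidence from called offspring states.

    Each element of ``offspring_called`` is ``(called_genotype,
    called_seg)`` for one offspring: integer arrays of length L with -1 for
    missing.  Offspring with either call missing at a locus contribute a
    flat factor there.  Returns an (L, 4) normalised product; with no
    offspring the result is uniform (no evidence).
    """
    if not offspring_called:
        if n_loci is None:
            raise ValueError("n_loci is required when there are no offspring")
        return np.full((n_loci, 4), 0.25)
    L = len(offspring_called[0][0])
    patterns = _code_patterns(eps)
    log_total = np.zeros((L, 4))
    allele_of = STATE_PAT_ALLELE if parent_side == PAT else STATE_MAT_ALLELE
    for geno, seg in offspring_called:
        geno = np.asarray(geno)
        seg = np.asarray(seg)
        code = np.full(L, CODE_MISSING, dtype=np.int64)
        ok = (geno >= 0) & (seg >= 0)
        code[ok] = 2 * allele_of[geno[ok]] + seg[ok]
        log_total += np.log(patterns[code])
    log_total -= log_total.max(axis=1, keepdims=True)
    return _normalize(np.exp(log_total))


def peel_individual(
    anterior_probs: np.ndarray,
    penetrance_probs: np.ndarray,
    posterior_probs: np.ndarray,
) -> np.ndarray:
    """Combine the three peeling factors into genotype distributions.

    Inputs are (..., 4) arrays (per locus); the result is the normalised
    elementwise product.  Loci where the product is identically zero carry
    conflicting evidence: they fall back to the penetrance alone with a
    logged warning rather than aborting.
    """
    a = np.asarray(anterior_probs, float)
    p = np.asarray(penetrance_probs, float)
    q = np.asarray(posterior_probs, float)
    prod = a * p * q
    zero = prod.sum(axis=-1) <= 0
    if np.any(zero):
        logger.warning(
            "%d loci had conflicting evidence; using own-data likelihood",
            int(np.count_nonzero(zero)),
        )
        prod = np.where(zero[..., None], p, prod)
    return _normalize(prod)


@dataclass
class PeelResult:
    """Output of the peeling cycles for one chromosome.

    Arrays are indexed in pedigree order.  ``seg_gamma`` and
    ``crossover_expectation`` have a parent-side axis (0 = paternal gamete,
    i.e. the sire's meiosis; 1 = maternal).
    """

    ids: list[str]
    genotype_probs: np.ndarray  # (N, L, 4)
    seg_gamma: np.ndarray  # (N, 2, L, 2)
    called_genotype: np.ndarray  # (N, L) int8, -1 missing
    called_seg: np.ndarray  # (N, 2, L) int8, -1 missing
    crossover_expectation: np.ndarray  # (N, 2, L-1)
    n_cycles: int
    converged: bool

    @property
    def dosages(self) -> np.ndarray:
        """Expected allele dosage per individual per locus."""
        from .core import STATE_DOSAGE

        return self.genotype_probs @ STATE_DOSAGE.astype(float)

    @property
    def total_crossovers(self) -> np.ndarray:
        """(N, 2) expected crossover count per gamete."""
        return self.crossover_expectation.sum(axis=-1)


class Peeler:
    """Stateful peeling engine for one chromosome.

    Construct once, then alternate :meth:`set_maps` / :meth:`run` when
    iterating the genetic-map estimate; state warm-starts between runs.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix,
        params: PeelingParams,
        map_female: GeneticMap,
        map_male: GeneticMap,
    ) -> None:
        if len(genotypes) != len(pedigree) or genotypes.ids != list(pedigree.ids):
            genotypes = genotypes.aligned_to(pedigree)
        self.ped = pedigree
        self.params = params
        n, L = len(pedigree), genotypes.n_loci
        self.n, self.L = n, L
        eps = params.genotype_error
        self.pen = _penetrance_table(eps)[genotypes.calls]  # (N,L,4)
        self.patterns = _code_patterns(eps)
        self.log_patterns = np.log(self.patterns)
        self.geno = _normalize(self.pen.copy())
        self.logpost = np.zeros((n, L, 4))
        self.gamma = np.full((n, 2, L, 2), 0.5)
        self.loo_gamma = np.full((n, 2, L, 2), 0.5)
        self.xo = np.zeros((n, 2, L - 1))
        self.code = np.full((n, 2, L), CODE_MISSING, dtype=np.uint8)
        self.called_geno = np.full((n, L), -1, dtype=np.int8)
        self.called_seg = np.full((n, 2, L), -1, dtype=np.int8)
        self.n_conflicts = 0
        max_gen = int(pedigree.generation.max()) if n else 0
        self.gens = [
            np.flatnonzero(pedigree.generation == g) for g in range(max_gen + 1)
        ]
        self.as_sire, self.as_dam = pedigree.offspring_lists()
        self.set_maps(map_female, map_male)

    def set_maps(self, map_female: GeneticMap, map_male: GeneticMap) -> None:
        if map_female.n_loci != self.L or map_male.n_loci != self.L:
            raise ValueError("genetic map does not match the number of loci")
        # paternal gametes arise in the sire's meiosis -> male map
        self.r = np.stack([map_male.rec_fractions, map_female.rec_fractions])

    # -- message helpers -------------------------------------------------

    def _parent_minus_child(self, parents: np.ndarray, children: np.ndarray,
                            side: int) -> np.ndarray:
        """Parent distributions with each focal child's factor divided out."""
        out = np.full((len(parents), self.L, 4), 0.25)
        known = parents >= 0
        if known.any():
            p = parents[known]
            codes = self.code[children[known], side]  # (k, L)
            out[known] = _normalize(self.geno[p] / self.patterns[codes])
        return out

    @staticmethod
    def _allele_prob(parent_dist: np.ndarray, seg: np.ndarray) -> np.ndarray:
        """p(transmitted allele = A) given parent dist and seg distribution."""
        pA_h0 = parent_dist @ _PAT_A
        pA_h1 = parent_dist @ _MAT_A
        # rounding can push the dot products a few ulp outside [0, 1]
        return np.clip(seg[..., 0] * pA_h0 + seg[..., 1] * pA_h1, 0.0, 1.0)

    # -- one peeling cycle ----------------------------------------------

    def cycle(self) -> float:
        """One downward sweep + calling + posterior refresh; returns max
        absolute change in genotype probabilities."""
        prev = self.geno.copy()
        for g, idx in enumerate(self.gens):
            if g == 0:
                self._update_founders(idx)
            else:
                self._peel_generation(idx)
        self._call_states()
        self._rebuild_posterior()
        return float(np.abs(self.geno - prev).max())

    def _update_founders(self, idx: np.ndarray) -> None:
        post = np.exp(self.logpost[idx] - self.logpost[idx].max(axis=-1, keepdims=True))
        self.geno[idx] = _normalize(self.pen[idx] * post)

    def _peel_generation(self, idx: np.ndarray) -> None:
        post = np.exp(self.logpost[idx] - self.logpost[idx].max(axis=-1, keepdims=True))
        childlik = _normalize(self.pen[idx] * post)  # (n,L,4)
        parents = (self.ped.sire[idx], self.ped.dam[idx])
        pdist = [
            self._parent_minus_child(parents[s], idx, s) for s in (PAT, MAT)
        ]
        allele_A = np.empty((2, len(idx), self.L))
        for side in (PAT, MAT):
            other = 1 - side
            # other parent's transmitted-allele dist under last cycle's
            # leave-one-out segregation
            qA = self._allele_prob(pdist[other], self.loo_gamma[idx, other])
            if side == PAT:
                m0 = (1 - qA) * childlik[..., 0] + qA * childlik[..., 1]
                m1 = (1 - qA) * childlik[..., 2] + qA * childlik[..., 3]
            else:
                m0 = (1 - qA) * childlik[..., 0] + qA * childlik[..., 2]
                m1 = (1 - qA) * childlik[..., 1] + qA * childlik[..., 3]
            p = pdist[side]
            pA_h0 = p @ _PAT_A
            pA_h1 = p @ _MAT_A
            e0 = (1 - pA_h0) * m0 + pA_h0 * m1
            e1 = (1 - pA_h1) * m0 + pA_h1 * m1
            evidence = _normalize(np.stack([e0, e1], axis=-1))
            r = self.r[side]
            alpha, beta, gam = forward_backward(evidence, r)
            loo = leave_one_out_gamma(alpha, beta, r)
            self.gamma[idx, side] = gam
            self.loo_gamma[idx, side] = loo
            self.xo[idx, side] = expected_crossovers(alpha, beta, evidence, r)
            allele_A[side] = self._allele_prob(p, loo)
        ant = np.empty((len(idx), self.L, 4))
        ant[..., 0] = (1 - allele_A[PAT]) * (1 - allele_A[MAT])
        ant[..., 1] = (1 - allele_A[PAT]) * allele_A[MAT]
        ant[..., 2] = allele_A[PAT] * (1 - allele_A[MAT])
        ant[..., 3] = allele_A[PAT] * allele_A[MAT]
        prod = ant * childlik
        zero = prod.sum(axis=-1) <= 0
        if zero.any():
            self.n_conflicts += int(zero.sum())
            prod[zero] = childlik[zero]  # conflicting evidence: keep own data
        self.geno[idx] = _normalize(prod)

    def _call_states(self) -> None:
        tau_g, tau_s = self.params.geno_call_threshold, self.params.seg_call_threshold
        best = self.geno.argmax(axis=-1)
        ok = np.take_along_axis(self.geno, best[..., None], axis=-1)[..., 0] >= tau_g
        self.called_geno = np.where(ok, best, -1).astype(np.int8)
        sbest = self.gamma.argmax(axis=-1)
        sok = np.take_along_axis(self.gamma, sbest[..., None], axis=-1)[..., 0] >= tau_s
        self.called_seg = np.where(sok, sbest, -1).astype(np.int8)
        allele = np.stack([STATE_PAT_ALLELE, STATE_MAT_ALLELE])  # [side, state]
        for side in (PAT, MAT):
            cg = self.called_geno
            cs = self.called_seg[:, side]
            code = np.full((self.n, self.L), CODE_MISSING, dtype=np.uint8)
            both = (cg >= 0) & (cs >= 0)
            code[both] = (2 * allele[side][cg[both]] + cs[both]).astype(np.uint8)
            self.code[:, side] = code

    def _rebuild_posterior(self) -> None:
        self.logpost.fill(0.0)
        logpat = self.log_patterns[:4]  # (4, 4) over parent states
        for side, off_lists in ((PAT, self.as_sire), (MAT, self.as_dam)):
            for parent, children in enumerate(off_lists):
                if not children:
                    continue
                codes = self.code[children, side]  # (k, L)
                counts = np.stack([(codes == c).sum(axis=0) for c in range(4)])
                self.logpost[parent] += counts.T @ logpat

    def run(self, n_cycles: int | None = None, tol: float | None = None) -> tuple[int, bool]:
        """Run peeling cycles until convergence or the cycle budget."""
        n_cycles = self.params.n_outer_cycles if n_cycles is None else n_cycles
        tol = self.params.convergence_tol if tol is None else tol
        delta = np.inf
        for c in range(1, n_cycles + 1):
            delta = self.cycle()
            if delta < tol:
                return c, True
        if delta >= tol:
            logger.warning(
                "peeling did not converge after %d cycles (max change %.2e)",
                n_cycles, delta,
            )
        return n_cycles, False

    def result(self, n_cycles: int, converged: bool) -> PeelResult:
        return PeelResult(
            ids=list(self.ped.ids),
            genotype_probs=self.geno,
            seg_gamma=self.gamma,
            called_genotype=self.called_geno,
            called_seg=self.called_seg,
            crossover_expectation=self.xo,
            n_cycles=n_cycles,
            converged=converged,
        )


def run_peeling_cycles(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    map_est: GeneticMap | tuple[GeneticMap, GeneticMap],
    params: PeelingParams | None = None,
) -> PeelResult:
    """Peel one chromosome with a fixed genetic map.

    ``map_est`` may be a single map (used for both sexes) or a
    ``(female, male)`` pair.
    """
    params = params or PeelingParams()
    if isinstance(map_est, GeneticMap):
        map_female = map_male = map_est
    else:
        map_female, map_male = map_est
    peeler = Peeler(pedigree, genotypes, params, map_female, map_male)
    n, conv = peeler.run()
    if peeler.n_conflicts:
        logger.warning(
            "%d locus-individual combinations had conflicting evidence; "
            "fell back to own-data likelihood", peeler.n_conflicts,
        )
    return peeler.result(n, conv)
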