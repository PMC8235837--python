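"""Two-state inheritance HMM along a chromosome.

For each gamete (one individual x one parent side) the inherited parental
haplotype at each locus is a hidden state in {0, 1}.  Transitions between
neighbouring loci occur with the interval's recombination fraction
``r_j = 0.5 (1 - exp(-2 d_j / 100))`` (Haldane, no interference), matching
the memoryless chain.  Per-locus evidence vectors come from the peeling
module; this module supplies exact smoothed marginals (forward-backward),
pairwise switch expectations (the expected crossover count per interval),
and the genetic-map update that converts population-average expectations
back into interval lengths.

All public functions are vectorised over arbitrary leading axes, so a whole
generation of gametes is smoothed in one call.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import GeneticMap, haldane_cm

logger = logging.getLogger(__name__)

_TINY = 1e-300


def _normalize(v: np.ndarray) -> np.ndarray:
    """Normalise the last axis to sum 1; all-zero rows become uniform."""
    s = v.sum(axis=-1, keepdims=True)
    bad = s <= 0
    if np.any(bad):
        v = np.where(bad, 1.0, v)
        s = np.where(bad, v.shape[-1], s)
    return v / s


def forward_backward(
    evidence: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for the two-state inheritance chain.

    Parameters
    ----------
    evidence : ndarray, shape (..., L, 2)
        Per-locus likelihoods p(data at locus | haplotype s).  Scale per
        locus is irrelevant.
    r : ndarray, shape (L-1,)
        Recombination fraction per interval.

    Returns
    -------
    alpha, beta, gamma : ndarrays, shape (..., L, 2)
        Per-locus normalised forward / backward vectors and smoothed
        marginals (gamma sums to 1 over the state axis).  The initial
        distribution is uniform.
    """
    e = np.asarray(evidence, dtype=float)
    L = e.shape[-2]
    if len(r) != L - 1:
        raise ValueError("need one recombination fraction per marker interval")
    alpha = np.empty_like(e)
    beta = np.empty_like(e)
    alpha[..., 0, :] = _normalize(0.5 * e[..., 0, :])
    for j in range(1, L):
        rj = r[j - 1]
        prev = alpha[..., j - 1, :]
        trans0 = (1 - rj) * prev[..., 0] + rj * prev[..., 1]
        trans1 = rj * prev[..., 0] + (1 - rj) * prev[..., 1]
        alpha[..., j, :] = _normalize(
            np.stack([trans0, trans1], axis=-1) * e[..., j, :]
        )
    beta[..., L - 1, :] = 0.5
    for j in range(L - 2, -1, -1):
        rj = r[j]
        nxt = beta[..., j + 1, :] * e[..., j + 1, :]
        b0 = (1 - rj) * nxt[..., 0] + rj * nxt[..., 1]
        b1 = rj * nxt[..., 0] + (1 - rj) * nxt[..., 1]
        beta[..., j, :] = _normalize(np.stack([b0, b1], axis=-1))
    gamma = _normalize(alpha * beta)
    return alpha, beta, gamma


def leave_one_out_gamma(alpha: np.ndarray, beta: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Smoothed marginals excluding each locus's own evidence.

    ``gamma_tilde[..., j, s]`` is proportional to p(s_j | all evidence except
    locus j): the forward prediction from locus j-1 times the backward
    message (which by construction excludes locus j's evidence).  Used for
    transmitting parental alleles without double-counting the locus.
    """
    L = alpha.shape[-2]
    pred = np.empty_like(alpha)
    pred[..., 0, :] = 0.5
    prev = alpha[..., :-1, :]
    r_col = np.asarray(r, dtype=float).reshape((1,) * (alpha.ndim - 2) + (L - 1, 1))
    p0 = (1 - r_col[..., 0]) * prev[..., 0] + r_col[..., 0] * prev[..., 1]
    pred[..., 1:, 0] = p0
    pred[..., 1:, 1] = r_col[..., 0] * prev[..., 0] + (1 - r_col[..., 0]) * prev[..., 1]
    return _normalize(pred * beta)


def expected_crossovers(
    alpha: np.ndarray, beta: np.ndarray, evidence: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Expected number of haplotype switches per marker interval.

    For interval j the pairwise posterior is
    ``xi_j(a, b) ∝ alpha_j(a) T_ab(r_j) e_{j+1}(b) beta_{j+1}(b)``;
    the expectation is the normalised off-diagonal mass.  Shape of the
    result: ``(..., L-1)``, each entry in [0, 1].
    """
    e = np.asarray(evidence, dtype=float)
    L = e.shape[-2]
    r_arr = np.asarray(r, dtype=float)
    a = alpha[..., :-1, :]  # (..., L-1, 2)
    nb = beta[..., 1:, :] * e[..., 1:, :]
    rj = r_arr.reshape((1,) * (alpha.ndim - 2) + (L - 1,))
    stay = (1 - rj) * (a[..., 0] * nb[..., 0] + a[..., 1] * nb[..., 1])
    switch = rj * (a[..., 0] * nb[..., 1] + a[..., 1] * nb[..., 0])
    total = stay + switch
    total = np.where(total <= 0, 1.0, total)
    return switch / total


def update_map(
    expectations: np.ndarray,
    template: GeneticMap,
    sex: str | None = None,
    rule: str = "linear",
    mode: str = "per_interval",
) -> GeneticMap:
    """Re-estimate interval lengths from population-average crossover counts.

    Parameters
    ----------
    expectations : ndarray, shape (n_gametes, L-1)
        Expected crossover count per gamete per interval.
    template : GeneticMap
        Supplies chromosome, positions, and (for ``mode="total_only"``) the
        relative interval spacing to preserve.
    rule : {"linear", "inverse_haldane"}
        ``linear``: d_j = 100 x mean expectation.  ``inverse_haldane``:
        treat the mean expectation as a recombination fraction and invert
        the Haldane map.
    mode : {"per_interval", "total_only"}
        ``total_only`` rescales the template's intervals to the new total
        length instead of updating each interval.
    """
    x = np.asarray(expectations, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("empty gamete set in map update")
    mean = x.mean(axis=0)
    if rule == "linear":
        d = 100.0 * mean
    elif rule == "inverse_haldane":
        d = haldane_cm(mean)
    else:
        raise ValueError(f"unknown map update rule {rule!r}")
    if mode == "total_only":
        rel = template.interval_cm / max(template.total_cm, _TINY)
        d = rel * d.sum()
    elif mode != "per_interval":
        raise ValueError(f"unknown map update mode {mode!r}")
    return GeneticMap(
        chromosome=template.chromosome,
        interval_cm=d,
        sex=sex or template.sex,
        positions=template.positions,
    )


def estimate_recombination(
    pedigree,
    genotypes,
    marker_map,
    params=None,
    n_map_iterations: int = 4,
    init_length_cm: float = 100.0,
    update_rule: str = "linear",
    update_mode: str = "per_interval",
    outlier_threshold: float = 5.0,
    require_all_grandparents: bool = True,
):
    """Jointly peel a chromosome and refine its sex-specific genetic maps.

    Starting from uniform 100-cM maps (about one expected crossover), the
    routine alternates peeling cycles with a map update: after each run the
    female map is re-estimated from the maternal gametes and the male map
    from the paternal gametes of QC-passing individuals (genotyped parents
    and grandparents, average rate below ``outlier_threshold`` cM/Mb).
    Repeated ``n_map_iterations`` times (chromosome-length estimates
    converge in about four).  If no gamete passes QC the prior map is
    returned unchanged.

    Returns an :class:`EstimationResult`.
    """
    from .core import GeneticMap as _GM, PeelingParams
    from .peeling import Peeler
    from .qc import filter_informative, filter_outliers, gamete_rates

    params = params or PeelingParams()
    chroms = marker_map.chromosomes
    if len(chroms) != 1:
        raise ValueError(
            "estimate_recombination works on a single chromosome; "
            "split the marker map first"
        )
    if genotypes.ids != list(pedigree.ids):
        genotypes = genotypes.aligned_to(pedigree)
    L = genotypes.n_loci
    if L != len(marker_map):
        raise ValueError("genotype matrix does not match the marker map")
    chrom = str(chroms[0])
    positions = marker_map.position
    span_mb = marker_map.span_mb
    map_f = _GM.uniform(chrom, L, init_length_cm, "F", positions)
    map_m = _GM.uniform(chrom, L, init_length_cm, "M", positions)

    peeler = Peeler(pedigree, genotypes, params, map_f, map_m)
    informative = filter_informative(
        pedigree, genotypes.genotyped, require_all_grandparents
    )
    n_cycles = 0
    converged = False
    keep = informative.copy()
    for _ in range(n_map_iterations):
        peeler.set_maps(map_f, map_m)
        n_cycles, converged = peeler.run()
        totals = peeler.xo.sum(axis=-1)  # (N, 2)
        rates = gamete_rates(totals, span_mb)
        keep = informative & filter_outliers(rates.mean(axis=1), outlier_threshold)
        if not keep.any():
            logger.warning(
                "no gametes passed QC on chromosome %s; keeping the prior map",
                chrom,
            )
            break
        map_f = update_map(peeler.xo[keep, 1], map_f, "F", update_rule, update_mode)
        map_m = update_map(peeler.xo[keep, 0], map_m, "M", update_rule, update_mode)
    result = peeler.result(n_cycles, converged)
    return EstimationResult(
        map_female=map_f,
        map_male=map_m,
        peel=result,
        qc_keep=keep,
        informative=informative,
        genome_mb=span_mb,
    )


class EstimationResult:
    """Maps and per-gamete estimates from :func:`estimate_recombination`."""

    def __init__(self, map_female, map_male, peel, qc_keep, informative, genome_mb):
        self.map_female = map_female
        self.map_male = map_male
        self.peel = peel
        self.qc_keep = np.asarray(qc_keep, dtype=bool)
        self.informative = np.asarray(informative, dtype=bool)
        self.genome_mb = float(genome_mb)

    @property
    def total_crossovers(self) -> np.ndarray:
        return self.peel.total_crossovers

    def estimates_frame(self):
        """Per-gamete TSV-ready table: id, parent_side, expected crossovers, rate."""
        import pandas as pd

        ids = self.peel.ids
        totals = self.total_crossovers
        rows = []
        for side, name in ((0, "pat"), (1, "mat")):
            for i, ident in enumerate(ids):
                rows.append(
                    {
                        "id": ident,
                        "parent_side": name,
                        "total_expected_crossovers": totals[i, side],
                        "rate_cM_per_Mb": 100.0 * totals[i, side] / self.genome_mb,
                        "qc_pass": bool(self.qc_keep[i]),
                    }
                )
        return pd.DataFrame(rows)
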