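"""Post-estimation filters and the gamete -> parent phenotype mapping.

Recombination estimates are only trusted for individuals whose ancestry is
well genotyped: the default keeps individuals whose two parents and four
grandparents are all present and genotyped (a relaxed mode needs only one
genotyped grandparent per parental side).  Individuals with implausibly
high average rates (> 5 cM/Mb) are screened out afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Pedigree


def filter_informative(
    pedigree: Pedigree,
    genotyped: np.ndarray,
    require_all_grandparents: bool = True,
) -> np.ndarray:
    """Boolean mask of individuals with genotyped parents and grandparents.

    ``genotyped`` is a per-individual boolean (e.g.
    ``GenotypeMatrix.genotyped``).  Strict mode requires both parents and
    all four grandparents known and genotyped; relaxed mode requires both
    parents and at least one genotyped grandparent on each side.
    """
    genotyped = np.asarray(genotyped, dtype=bool)
    sire, dam = pedigree.sire, pedigree.dam

    def _parent_ok(p: np.ndarray) -> np.ndarray:
        ok = (p >= 0) & genotyped[np.clip(p, 0, None)]
        gp_sire = np.where(p >= 0, sire[np.clip(p, 0, None)], -1)
        gp_dam = np.where(p >= 0, dam[np.clip(p, 0, None)], -1)
        gs_ok = (gp_sire >= 0) & genotyped[np.clip(gp_sire, 0, None)]
        gd_ok = (gp_dam >= 0) & genotyped[np.clip(gp_dam, 0, None)]
        if require_all_grandparents:
            return ok & gs_ok & gd_ok
        return ok & (gs_ok | gd_ok)

    return _parent_ok(sire) & _parent_ok(dam)


def filter_outliers(rates: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Keep-mask over per-individual average rates; removes strictly > threshold."""
    return np.asarray(rates, dtype=float) <= threshold


def gamete_rates(total_crossovers: np.ndarray, genome_mb: float) -> np.ndarray:
    """Convert expected crossover counts to cM/Mb over the covered span."""
    return 100.0 * np.asarray(total_crossovers, dtype=float) / genome_mb


def gametes_to_parent_phenotypes(
    pedigree: Pedigree,
    total_crossovers: np.ndarray,
    genome_mb: float,
    keep: np.ndarray | None = None,
) -> pd.DataFrame:
    """One phenotype record per retained gamete, attributed to its parent.

    Each retained offspring contributes a paternal record to its sire and a
    maternal record to its dam (records with an unknown parent are
    omitted).  ``total_crossovers`` is (N, 2) with the paternal gamete in
    column 0.  Rates are cM/Mb over ``genome_mb``.
    """
    n = len(pedigree)
    keep = np.ones(n, dtype=bool) if keep is None else np.asarray(keep, dtype=bool)
    rates = gamete_rates(total_crossovers, genome_mb)
    rows = []
    for side, parents in ((0, pedigree.sire), (1, pedigree.dam)):
        for c in np.flatnonzero(keep):
            p = parents[c]
            if p < 0:
                continue
            rows.append(
                {
                    "parent_id": pedigree.ids[p],
                    "sex": pedigree.sex[p],
                    "line": pedigree.line[p],
                    "offspring_id": pedigree.ids[c],
                    "rate": rates[c, side],
                }
            )
    return pd.DataFrame(rows, columns=["parent_id", "sex", "line", "offspring_id", "rate"])
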