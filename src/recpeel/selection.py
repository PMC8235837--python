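"""Selection-response projections for recombination rate as a trait.

Implements truncation selection arithmetic via the breeders' equation
R = h^2 * S, with S the selection differential (mean of the selected group
minus the population mean), and the expected gain from fixing the
favourable allele at a QTL of additive effect ``a`` segregating at
frequency ``p``: a * (1 - p).
"""

from __future__ import annotations

import math

import numpy as np


def selected_mean(values: np.ndarray, proportion: float) -> float:
    """Mean of the top ``ceil(n * proportion)`` values.

    Values are sorted descending; ties at the cut are broken by value
    order (the stable descending sort keeps earlier entries first).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value collection")
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must be in (0, 1]")
    k = math.ceil(v.size * proportion)
    top = np.sort(v, kind="stable")[::-1][:k]
    return float(top.mean())


def breeders_response(
    mu: float, mu_selected: float, h2: float
) -> tuple[float, float]:
    """Response to one round of truncation selection.

    Returns ``(R, R / mu)``: the absolute response ``h2 * (mu_selected -
    mu)`` in the trait's units (here cM/Mb) and the response relative to
    the population mean.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("heritability must be in [0, 1]")
    r = h2 * (mu_selected - mu)
    return r, r / mu


def qtl_fixation_gain(a: float, p: float, mu: float | None = None) -> tuple[float, float | None]:
    """Trait gain from fixing a QTL's favourable allele.

    ``a`` is the additive allele effect, ``p`` the current favourable
    allele frequency; the gain is ``a * (1 - p)``.  If ``mu`` is given the
    relative gain is returned as well, else None.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    gain = a * (1.0 - p)
    return gain, (gain / mu if mu is not None else None)
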