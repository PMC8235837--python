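"""Descriptive analyses of estimated recombination landscapes.

Windowed landscapes (interval cM apportioned pro-rata into fixed-width bp
windows), correlations of landscapes between groups (lines, sexes),
fixed-effects comparison of map lengths, 50-SNP smoothing, and the
accuracy metrics used to score the estimator against simulation truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import GeneticMap, MarkerMap


def windowed_landscape(
    map_est: GeneticMap,
    marker_map: MarkerMap | None = None,
    width_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Apportion interval cM into fixed-width windows; rate is cM/Mb.

    Intervals straddling a window boundary are split pro-rata by bp
    overlap, so the total cM is conserved exactly.  Returns a DataFrame
    with chromosome, start_bp, end_bp (half-open), cM and rate columns.
    """
    positions = map_est.positions
    if positions is None:
        if marker_map is None:
            raise ValueError("need bp positions (on the map or a marker map)")
        positions = marker_map.position
    starts = positions[:-1].astype(float)
    ends = positions[1:].astype(float)
    cm = map_est.interval_cm
    first = int(positions[0] // width_bp) * width_bp
    last = int((positions[-1] - 1) // width_bp + 1) * width_bp
    edges = np.arange(first, last + width_bp, width_bp, dtype=float)
    n_win = len(edges) - 1
    win_cm = np.zeros(n_win)
    for w in range(n_win):
        lo, hi = edges[w], edges[w + 1]
        overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)
        width = ends - starts
        frac = np.divide(overlap, width, out=np.zeros_like(width), where=width > 0)
        win_cm[w] = (cm * frac).sum()
    return pd.DataFrame(
        {
            "chromosome": map_est.chromosome,
            "start_bp": edges[:-1].astype(np.int64),
            "end_bp": edges[1:].astype(np.int64),
            "cM": win_cm,
            "rate_cM_per_Mb": win_cm / (width_bp / 1e6),
            "sex": map_est.sex,
        }
    )


def landscape_correlations(
    landscapes: dict[tuple[str, str], np.ndarray],
    min_windows: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Pearson correlations between (line, sex) landscapes.

    All landscapes must share a common grid (equal length).  Returns the
    full correlation matrix (DataFrame indexed by "line:sex") and summary
    means: between-line within each sex, and between-sex within line.
    Pairs with fewer than ``min_windows`` shared finite values, or zero
    variance, are reported as NaN.
    """
    keys = list(landscapes.keys())
    names = [f"{line}:{sex}" for line, sex in keys]
    k = len(keys)
    corr = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            a = np.asarray(landscapes[keys[i]], dtype=float)
            b = np.asarray(landscapes[keys[j]], dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_windows:
                continue
            aa, bb = a[ok], b[ok]
            if aa.std() == 0 or bb.std() == 0:
                continue
            corr[i, j] = corr[j, i] = float(np.corrcoef(aa, bb)[0, 1])
    mat = pd.DataFrame(corr, index=names, columns=names)
    summary: dict[str, list[float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            (line_i, sex_i), (line_j, sex_j) = keys[i], keys[j]
            if not np.isfinite(corr[i, j]):
                continue
            if sex_i == sex_j and line_i != line_j:
                summary.setdefault(f"between_line_{sex_i}", []).append(corr[i, j])
            elif line_i == line_j and sex_i != sex_j:
                summary.setdefault("between_sex", []).append(corr[i, j])
    means = {k_: float(np.mean(v)) for k_, v in summary.items()}
    return mat, means


def map_length_model(
    counts: pd.DataFrame,
    response: str = "n_crossovers",
) -> pd.DataFrame:
    """Fixed-effects comparison of genetic map length between lines.

    ``counts`` must have columns ``line``, ``chromosome`` and the response
    (crossover count per gamete per chromosome), for one sex.  Fits an OLS
    with line and chromosome fixed effects and returns, per line, the total
    map length in Morgan (sum over chromosomes of fitted cell means) with a
    normal-theory 95% confidence interval.
    """
    df = counts.copy()
    df["line"] = df["line"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    lines = sorted(df["line"].unique())
    chroms = sorted(df["chromosome"].unique())
    X = pd.get_dummies(df[["line", "chromosome"]], drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    y = df[response].astype(float)
    model = sm.OLS(y, X)
    try:
        fit = model.fit()
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"map length model failed: {exc}") from exc
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient design: line and chromosome effects are confounded"
        )
    # per-line total: sum over chromosomes of the fitted cell mean
    rows = []
    cols = list(X.columns)
    for line in lines:
        contrast = np.zeros(len(cols))
        contrast[cols.index("const")] = len(chroms)
        name = f"line_{line}"
        if name in cols:
            contrast[cols.index(name)] = len(chroms)
        for chrom in chroms:
            cname = f"chromosome_{chrom}"
            if cname in cols:
                contrast[cols.index(cname)] += 1.0
        est = float(contrast @ fit.params.to_numpy())
        se = float(np.sqrt(contrast @ fit.cov_params().to_numpy() @ contrast))
        # a crossover count per meiosis is a genetic length in Morgan
        rows.append(
            {
                "line": line,
                "total_morgan": est,
                "lower": est - 1.96 * se,
                "upper": est + 1.96 * se,
            }
        )
    return pd.DataFrame(rows)


def smooth_landscape(
    values: np.ndarray,
    window: int = 50,
    mode: str = "non_overlapping",
) -> np.ndarray:
    """Average a per-marker series in 50-SNP windows.

    ``non_overlapping`` returns one block mean per full window (trailing
    remainder dropped); ``rolling`` returns a centred rolling mean of the
    same length as the input (shrinking windows at the edges).
    """
    v = np.asarray(values, dtype=float)
    if mode == "non_overlapping":
        n_blocks = len(v) // window
        if n_blocks == 0:
            raise ValueError("series shorter than the window")
        return v[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    if mode == "rolling":
        return (
            pd.Series(v).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
    raise ValueError(f"unknown smoothing mode {mode!r}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def accuracy_metrics(
    true_counts: np.ndarray,
    est_counts: np.ndarray,
    parent_sex: np.ndarray,
    true_landscape: np.ndarray,
    est_landscape: np.ndarray,
    smooth_window: int = 50,
) -> dict[str, float]:
    """Score estimates against simulation truth.

    Per-gamete totals are correlated within parent groups (gametes from
    dams vs from sires); the per-interval landscapes are correlated raw and
    after non-overlapping ``smooth_window``-SNP averaging.  Zero-variance
    comparisons come back NaN.
    """
    parent_sex = np.asarray(parent_sex)
    out = {
        "r_individual_dams": _pearson(
            true_counts[parent_sex == "F"], est_counts[parent_sex == "F"]
        ),
        "r_individual_sires": _pearson(
            true_counts[parent_sex == "M"], est_counts[parent_sex == "M"]
        ),
        "r_landscape": _pearson(true_landscape, est_landscape),
    }
    if len(true_landscape) >= smooth_window:
        out["r_landscape_smoothed"] = _pearson(
            smooth_landscape(true_landscape, smooth_window),
            smooth_landscape(est_landscape, smooth_window),
        )
    else:
        out["r_landscape_smoothed"] = float("nan")
    return out
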