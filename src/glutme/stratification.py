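"""Immune-rich / immune-poor stratification and correlation analyses.

The cohort's ImmuneScore distribution is typically bimodal: a large mode of
immune-poor tumors and a smaller mode of heavily infiltrated immune-rich
tumors.  The split threshold is taken from a Gaussian kernel density estimate
of the score distribution — the valley (local density minimum) between the two
highest modes — after which Pearson correlations of glucose-uptake readouts
(TLRmax from FDG PET) with transporter expression and immune enrichment are
computed overall and conditionally within each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, NoValleyError, ParameterError

logger = logging.getLogger(__name__)

IMMUNE_POOR = "immune-poor"
IMMUNE_RICH = "immune-rich"

_GRID_POINTS = 512
_GRID_CUT = 3.0  # grid extends bandwidth * cut beyond the data range


@dataclass
class DensityCurve:
    """Kernel density estimate on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class ClusterAssignment:
    """Two-way immune cluster labels derived from a score threshold.

    A sample is immune-rich iff its score is strictly greater than the
    threshold; a score exactly at the threshold is immune-poor.
    """

    threshold: float
    labels: pd.Series

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    r: float
    p: float
    n: int


def _silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    This is the default of R's ``density`` (``bw.nrd0``), including its
    fallbacks when the IQR or the standard deviation vanishes.
    """
    n = len(values)
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = abs(float(values[0])) or 1.0
    return 0.9 * spread * n ** (-0.2)


def kde_density(
    values,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
) -> DensityCurve:
    """Gaussian-kernel density estimate on a 512-point regular grid.

    The grid spans ``[min - 3*bw, max + 3*bw]``, mirroring the convention of
    R's ``density`` function that the original analysis used.

    Raises
    ------
    DegenerateInputError
        If all values are identical (no spread to estimate a density from).
    ParameterError
        On fewer than 4 observations or an unknown bandwidth rule.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ParameterError("kde_density needs a 1-d vector of at least 4 values")
    if not np.all(np.isfinite(x)):
        raise ParameterError("kde_density requires finite values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; density is degenerate")
    if bandwidth_rule == "silverman":
        bw = _silverman_bandwidth(x)
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ParameterError("fixed bandwidth rule requires a positive bandwidth")
        bw = float(bandwidth)
    else:
        raise ParameterError(f"unknown bandwidth rule {bandwidth_rule!r}")
    grid = np.linspace(x.min() - _GRID_CUT * bw, x.max() + _GRID_CUT * bw, _GRID_POINTS)
    # mean of Gaussian kernels centred on the observations
    z = (grid[:, None] - x[None, :]) / bw
    density = stats.norm.pdf(z).mean(axis=1) / bw
    return DensityCurve(grid=grid, density=density, bandwidth=bw)


def _local_maxima(density: np.ndarray) -> np.ndarray:
    d = density
    idx = [i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    if len(d) >= 2:
        if d[0] > d[1]:
            idx.insert(0, 0)
        if d[-1] > d[-2]:
            idx.append(len(d) - 1)
    return np.asarray(idx, dtype=int)


def find_split_threshold(curve: DensityCurve) -> float:
    """Valley of a bimodal density: the split point between the two clusters.

    Locates the two highest local maxima of the curve and returns the grid
    point of the lowest density between them (ties resolved toward the smaller
    grid value).  More than two modes are tolerated: only the two highest are
    considered, and any interior minimum between them can win.

    Raises
    ------
    NoValleyError
        If the curve has fewer than two local maxima; callers may fall back to
        a fixed threshold.
    """
    maxima = _local_maxima(curve.density)
    if len(maxima) < 2:
        raise NoValleyError("density curve is unimodal; no valley to split on")
    top_two = maxima[np.argsort(curve.density[maxima], kind="stable")[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    interior = np.arange(lo + 1, hi)
    if len(interior) == 0:
        raise NoValleyError("the two highest modes are adjacent grid points")
    valley = interior[np.argmin(curve.density[interior])]  # argmin ties -> smaller index
    return float(curve.grid[valley])


def assign_clusters(scores: pd.Series, threshold: float) -> ClusterAssignment:
    """Label samples immune-rich iff score > threshold (strict inequality)."""
    scores = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(scores.to_numpy())):
        raise ParameterError("scores must be finite")
    labels = pd.Series(
        np.where(scores.to_numpy() > threshold, IMMUNE_RICH, IMMUNE_POOR),
        index=scores.index,
        name="cluster",
    )
    assignment = ClusterAssignment(threshold=float(threshold), labels=labels)
    logger.info("cluster sizes at threshold %.4g: %s", threshold, assignment.counts())
    return assignment


def stratify_scores(scores: pd.Series, bandwidth_rule: str = "silverman") -> ClusterAssignment:
    """KDE -> valley threshold -> cluster labels, in one call."""
    curve = kde_density(scores, bandwidth_rule=bandwidth_rule)
    return assign_clusters(scores, find_split_threshold(curve))


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson requires two equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ParameterError("pearson requires at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def correlation_panel(scores: pd.DataFrame, features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cross-correlate every enrichment score with every metabolic feature.

    Parameters
    ----------
    scores
        Samples x signatures enrichment table (including ImmuneScore).
    features
        Samples x features table, e.g. GLUT1, GLUT3, glycolysis score, TLRmax.

    Returns
    -------
    dict with ``"r"``, ``"p"`` and ``"n"`` DataFrames (signatures x features),
    ready to be drawn as a heatmap.
    """
    shared = scores.index.intersection(features.index)
    if len(shared) < 3:
        raise ParameterError("correlation panel requires at least 3 shared samples")
    scores = scores.loc[shared].sort_index()
    features = features.loc[shared].sort_index()
    r = pd.DataFrame(index=scores.columns, columns=features.columns, dtype=float)
    p = r.copy()
    for sig in scores.columns:
        for feat in features.columns:
            res = pearson(scores[sig], features[feat])
            r.loc[sig, feat] = res.r
            p.loc[sig, feat] = res.p
    return {"r": r, "p": p, "n": len(shared)}


def conditional_correlations(
    tlr: pd.Series,
    features: pd.DataFrame,
    clusters: ClusterAssignment,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Per-cluster Pearson correlation of TLRmax with each feature.

    Clusters with fewer than ``min_cluster_size`` samples are skipped with a
    logged warning rather than raising.

    Returns
    -------
    pandas.DataFrame
        Long table with columns cluster, feature, r, p, n.
    """
    rows = []
    for label in sorted(clusters.labels.unique()):
        members = clusters.labels.index[clusters.labels == label]
        members = members.intersection(tlr.index).intersection(features.index)
        if len(members) < min_cluster_size:
            logger.warning("cluster %s has %d samples (<%d); skipped", label, len(members), min_cluster_size)
            continue
        for feat in features.columns:
            res = pearson(tlr.loc[members], features.loc[members, feat])
            rows.append({"cluster": label, "feature": feat, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["cluster", "feature", "r", "p", "n"])
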