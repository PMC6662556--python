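"""Summary metrics of telomere-length distributions and their PCA reduction.

Each individual's TRF smear yields a weighted distribution of fragment sizes.
Twelve metrics summarize it: the weighted mean, skewness and kurtosis, and
the nine deciles P10-P90.  Because the metrics are strongly mutually
correlated, a principal component analysis reduces them to a single telomere
length score (PC1), oriented so that high scores mean long telomeres.

Weights are treated as molecule counts: every statistic is the one you would
get by replicating each fragment size in proportion to its weight.  Weighted
moments use the population (weights-normalized) form and kurtosis is reported
non-excess (a Gaussian scores 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import TLDistribution

METRIC_NAMES: tuple[str, ...] = (
    "mean_kb",
    "skew",
    "kurtosis",
    "p10",
    "p20",
    "p30",
    "p40",
    "p50",
    "p60",
    "p70",
    "p80",
    "p90",
)


@dataclass
class TLMetricSet:
    """The 12 summary metrics of one telomere-length distribution."""

    individual_id: str
    mean_kb: float
    skew: float
    kurtosis: float
    p10: float
    p20: float
    p30: float
    p40: float
    p50: float
    p60: float
    p70: float
    p80: float
    p90: float

    def __post_init__(self) -> None:
        dec = self.deciles()
        if np.any(np.diff(dec) < -1e-9):
            raise ValueError("deciles must be nondecreasing")

    def deciles(self) -> np.ndarray:
        return np.array(
            [getattr(self, f"p{q}") for q in range(10, 100, 10)], dtype=float
        )

    def as_row(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PCResult:
    """PCA of the 12-metric table.

    ``loadings`` has one unit-norm column per component, rows ordered as
    :data:`METRIC_NAMES`; ``scores`` holds per-individual component scores
    (PC1 is the telomere-length score).  The sign convention fixes the
    ``mean_kb`` loading of each component to be non-negative, so high PC1
    means long mean telomere length.
    """

    loadings: np.ndarray
    explained_fraction: np.ndarray
    scores: pd.DataFrame
    mode: str

    def pc1_scores(self) -> pd.Series:
        return self.scores["PC1"]


def _wsum(dist: TLDistribution) -> tuple[np.ndarray, np.ndarray, float]:
    w = dist.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    return dist.positions_kb, w, float(total)


def weighted_mean(dist: TLDistribution) -> float:
    """Weighted mean fragment size: sum(w*kb)/sum(w)."""
    x, w, total = _wsum(dist)
    return float(np.dot(w, x) / total)


def weighted_moments(dist: TLDistribution) -> tuple[float, float]:
    """Weighted skewness and (non-excess) kurtosis.

    Population form: with weights normalized to sum 1, the k-th central
    moment is m_k = sum(w*(x-mean)^k); skew = m3/m2^1.5, kurtosis = m4/m2^2.
    """
    x, w, total = _wsum(dist)
    if len(np.unique(x[w > 0])) < 2:
        raise ValueError("degenerate distribution: a single support point")
    p = w / total
    mu = np.dot(p, x)
    d = x - mu
    m2 = np.dot(p, d**2)
    if m2 <= 0:
        raise ValueError("degenerate distribution: zero weighted variance")
    m3 = np.dot(p, d**3)
    m4 = np.dot(p, d**4)
    return float(m3 / m2**1.5), float(m4 / m2**2)


def weighted_quantile(dist: TLDistribution, q: float | np.ndarray) -> float | np.ndarray:
    """Inverse of the weighted empirical CDF with linear interpolation.

    Support points get CDF ordinates at the midpoints of their cumulative
    weight blocks ((c_i - w_i/2)/W); quantiles interpolate linearly between
    adjacent support points and clamp at the extremes.  With two equal
    weights at 5 and 10 kb the median is therefore 7.5 kb.
    """
    qa = np.asarray(q, dtype=float)
    if np.any((qa <= 0) | (qa >= 1)):
        raise ValueError("quantile level must be strictly inside (0, 1)")
    x, w, total = _wsum(dist)
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    keep = w > 0
    x, w = x[keep], w[keep]
    cdf = (np.cumsum(w) - 0.5 * w) / total
    out = np.interp(qa, cdf, x)
    return float(out) if np.isscalar(q) else out


def compute_metric_set(dist: TLDistribution) -> TLMetricSet:
    """Assemble all 12 metrics for one individual."""
    skew, kurt = weighted_moments(dist)
    deciles = weighted_quantile(dist, np.arange(0.1, 0.95, 0.1))
    return TLMetricSet(
        individual_id=dist.individual_id,
        mean_kb=weighted_mean(dist),
        skew=skew,
        kurtosis=kurt,
        **{f"p{10 * (i + 1)}": float(v) for i, v in enumerate(deciles)},
    )


def metrics_table(metric_sets: list[TLMetricSet]) -> pd.DataFrame:
    """Stack metric sets into a DataFrame indexed by individual."""
    df = pd.DataFrame([m.as_row() for m in metric_sets])
    return df.set_index("individual_id")


def metric_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of the 12 metrics with two-sided p-values.

    Constant columns have undefined correlations; those entries are NaN and a
    warning is raised.
    """
    cols = list(METRIC_NAMES)
    data = table[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for correlations")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant metric column: correlations undefined (NaN)")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if sd[i] == 0 or sd[j] == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(data[:, i], data[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def pca_scores(table: pd.DataFrame, mode: str = "covariance") -> PCResult:
    """Eigendecomposition of the metric table; PC1 is the TL score.

    ``mode`` selects the covariance (default) or correlation matrix.  Zero
    eigenvalues are allowed (rank-deficient tables).  Component signs follow
    the convention that the ``mean_kb`` loading is non-negative, so high PC1
    scores represent longer telomeres; when the ``mean_kb`` loading of a
    component is exactly zero the first nonzero loading is made positive.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    cols = [c for c in METRIC_NAMES if c in table.columns]
    data = table[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n <= len(cols):
        warnings.warn(
            f"only {n} individuals for {len(cols)} metrics: PCA will be rank-deficient"
        )
    centered = data - data.mean(axis=0)
    if mode == "correlation":
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column: correlation-mode PCA undefined")
        centered = centered / sd
    cov = (centered.T @ centered) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    mean_idx = cols.index("mean_kb")
    for j in range(evecs.shape[1]):
        pivot = evecs[mean_idx, j]
        if pivot == 0:
            nz = np.nonzero(evecs[:, j])[0]
            pivot = evecs[nz[0], j] if len(nz) else 1.0
        if pivot < 0:
            evecs[:, j] = -evecs[:, j]
    scores = centered @ evecs
    names = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    return PCResult(
        loadings=evecs,
        explained_fraction=evals / evals.sum() if evals.sum() > 0 else evals,
        scores=pd.DataFrame(scores, index=table.index, columns=names),
        mode=mode,
    )


def standards_cv(table: pd.DataFrame, standard_ids: dict[str, list[str]]) -> dict[str, float]:
    """Coefficient of variation of mean TL across repeated runs of each standard.

    ``standard_ids`` maps a standard's name to the lane ids of its repeated
    runs (e.g. the same control blood run twice per gel).  Reported for QC
    only; no correction is applied.
    """
    out = {}
    for name, ids in standard_ids.items():
        vals = table.loc[[i for i in ids if i in table.index], "mean_kb"]
        if len(vals) < 2:
            raise ValueError(f"standard {name!r}: need >= 2 repeated runs")
        out[name] = float(vals.std(ddof=1) / vals.mean())
    return out
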