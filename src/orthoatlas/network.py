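"""Ortholog correlations, thresholded co-expression networks and their
degree distributions.

Cross-species conservation of tissue regulation is measured as the Pearson
correlation, across tissue categories, between the meta-profiles of the two
members of a 1:1 ortholog pair.  Within a species, a co-expression network
is the graph whose nodes are genes and whose edges join gene pairs whose
profiles correlate beyond a threshold (strictly ``r > threshold``).  Degree
distributions P(k) = n_k / n of these graphs follow a power law
``P(k) ~ k^-gamma``; the exponent is estimated either by a least-squares fit
on the log-log table or by discrete maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise ortholog correlations


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two equal-shape matrices.

    Rows with zero variance on either side yield NaN.
    """
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def ortholog_pair_correlations(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    species_pair: str = "",
) -> pd.DataFrame:
    """Per-cluster Pearson r across tissues between two aligned matrices.

    Both matrices must be indexed by the same 1:1 ortholog cluster ids and
    share identical tissue columns in identical order.  Constant profiles
    give an undefined r: the record is kept with ``r = NaN`` and
    ``constant = True`` rather than silently dropped.
    """
    if not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("tissue categories differ between the two matrices")
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("cluster indices differ between the two matrices")
    r = _rowwise_pearson(
        matrix_a.to_numpy(dtype=float), matrix_b.to_numpy(dtype=float)
    )
    return pd.DataFrame(
        {
            "cluster_id": matrix_a.index,
            "species_pair": species_pair,
            "r": r,
            "constant": np.isnan(r),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# thresholded networks


def correlation_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Gene x gene Pearson correlations across tissues.

    Constant genes (undefined correlation) are excluded from the network's
    node set, with a logged count.
    """
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0.0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d constant genes from the network", n_dropped)
    r = np.corrcoef(x[keep])
    if r.ndim == 0:  # single gene
        r = np.array([[1.0]])
    return r, matrix.index[keep]


def build_threshold_network(
    matrix: pd.DataFrame,
    threshold: float,
    include_self: bool = False,
) -> pd.DataFrame:
    """Boolean adjacency: edge iff r > threshold (strict), no self-loops.

    ``include_self`` keeps the diagonal 1s (every gene correlates perfectly
    with itself), which shifts every degree by exactly one; the default
    follows the standard simple-graph convention.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (-1, 1)")
    r, nodes = correlation_matrix(matrix)
    adj = r > threshold
    np.fill_diagonal(adj, include_self)
    return pd.DataFrame(adj, index=nodes, columns=nodes)


@dataclass
class DegreeDistribution:
    """(k, n_k, P(k)) table for one threshold or a threshold range."""

    label: str
    n: int
    table: pd.DataFrame  # columns: k, n_k, p_k

    def __post_init__(self) -> None:
        t = self.table
        if abs(float(t["p_k"].sum()) - 1.0) > 1e-12:
            raise ValueError("P(k) must sum to 1")

    def degrees(self) -> np.ndarray:
        """Expand the table back into one degree per node (exact tables only)."""
        return np.repeat(
            self.table["k"].to_numpy(),
            self.table["n_k"].round().astype(int).to_numpy(),
        )


def degree_distribution(adjacency: pd.DataFrame | np.ndarray,
                        label: str = "") -> DegreeDistribution:
    """Exact degree table of a symmetric adjacency matrix.

    Degrees are row sums of the discretized matrix (diagonal excluded by
    construction upstream); k = 0 appears if isolated nodes exist.
    """
    a = adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency)
    a = a.astype(bool)
    if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    deg = a.sum(axis=1).astype(int)
    k, n_k = np.unique(deg, return_counts=True)
    n = int(a.shape[0])
    table = pd.DataFrame({"k": k, "n_k": n_k, "p_k": n_k / n})
    return DegreeDistribution(label=label, n=n, table=table)


def average_degree_distribution(
    matrix: pd.DataFrame,
    low: float,
    high: float,
    step: float = 0.01,
) -> DegreeDistribution:
    """Range-averaged degree distribution over thresholds [low, high].

    A degree distribution is computed at every ``step`` (default one percent)
    increment within the closed range, and P(k) is averaged across those
    thresholds over the union of observed degrees (absent k contributes 0).
    The canonical ranges are 0.85-0.89, 0.90-0.94 and 0.95-0.99, each five
    thresholds at one-percent increments.
    """
    m = int(round((high - low) / step)) + 1
    if high < low or m < 1:
        raise ValueError("threshold range must span >= 1 threshold")
    thresholds = [round(low + i * step, 10) for i in range(m)]
    r, nodes = correlation_matrix(matrix)
    n = len(nodes)
    acc: dict[int, float] = {}
    for thr in thresholds:
        adj = r > thr
        np.fill_diagonal(adj, False)
        deg = adj.sum(axis=1).astype(int)
        k, n_k = np.unique(deg, return_counts=True)
        for ki, ni in zip(k.tolist(), n_k.tolist()):
            acc[ki] = acc.get(ki, 0.0) + ni / n
    ks = sorted(acc)
    p = np.array([acc[k] / m for k in ks])
    table = pd.DataFrame({"k": ks, "n_k": np.array([acc[k] for k in ks]) * n / m,
                          "p_k": p})
    return DegreeDistribution(label=f"{low:.2f}-{high:.2f}", n=n, table=table)


# ---------------------------------------------------------------------------
# power-law fits


@dataclass
class PowerLawFit:
    gamma: float
    method: str
    k_range: tuple[int, int]
    diagnostic: float  # R^2 for loglog; mean log-likelihood for mle

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")


def fit_power_law(
    dist: DegreeDistribution,
    method: str = "mle",
    k_min: int | None = None,
) -> PowerLawFit:
    """Estimate the exponent gamma of P(k) ~ k^-gamma.

    method "loglog": least-squares slope of log P(k) vs log k over k >= k_min
    with P(k) > 0; gamma = -slope.  method "mle": discrete maximum-likelihood
    exponent for the zeta distribution truncated at k_min (Hurwitz-zeta
    normalization), fitted on the (k, n_k) table.

    ``k_min`` defaults to the smallest positive degree with n_k > 0.
    """
    t = dist.table[dist.table["n_k"] > 0]
    t = t[t["k"] >= 1]
    if k_min is None:
        k_min = int(t["k"].min()) if len(t) else 1
    t = t[t["k"] >= k_min]
    if t["k"].nunique() < 3:
        raise ValueError("need >= 3 distinct positive degrees to fit")
    k = t["k"].to_numpy(dtype=float)
    k_range = (int(k.min()), int(k.max()))

    if method == "loglog":
        p = t["p_k"].to_numpy(dtype=float)
        res = stats.linregress(np.log(k), np.log(p))
        return PowerLawFit(
            gamma=float(-res.slope), method="loglog",
            k_range=k_range, diagnostic=float(res.rvalue**2),
        )
    if method == "mle":
        w = t["n_k"].to_numpy(dtype=float)
        n = w.sum()
        sum_log_k = float((w * np.log(k)).sum())

        def nll(g: float) -> float:
            return g * sum_log_k + n * np.log(special.zeta(g, k_min))

        res = optimize.minimize_scalar(nll, bounds=(1.0001, 25.0), method="bounded")
        gamma = float(res.x)
        return PowerLawFit(
            gamma=gamma, method="mle", k_range=k_range,
            diagnostic=float(-res.fun / n),
        )
    raise ValueError(f"unknown fit method {method!r}")


def sample_power_law_degrees(
    gamma: float,
    k_min: int,
    size: int,
    rng: np.random.Generator,
    k_max: int = 100_000,
) -> np.ndarray:
    """Sample degrees from the discrete power law p(k) ~ k^-gamma, k >= k_min.

    The support is truncated at ``k_max``; for gamma near 3 the truncated
    tail mass is ~k_max^-2 and negligible for estimation purposes.
    """
    ks = np.arange(k_min, k_max + 1, dtype=float)
    p = ks**-gamma
    p /= p.sum()
    return rng.choice(ks.astype(int), size=size, p=p)


def distribution_from_degrees(degrees: np.ndarray, label: str = "") -> DegreeDistribution:
    """(k, n_k, P(k)) table from an explicit degree sample."""
    deg = np.asarray(degrees, dtype=int)
    k, n_k = np.unique(deg, return_counts=True)
    n = int(deg.size)
    return DegreeDistribution(
        label=label, n=n,
        table=pd.DataFrame({"k": k, "n_k": n_k, "p_k": n_k / n}),
    )


def edge_list(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Undirected edge list (each pair once) for TSV export."""
    a = adjacency.to_numpy(dtype=bool)
    iu = np.triu_indices(a.shape[0], k=1)
    mask = a[iu]
    return pd.DataFrame(
        {
            "gene_a": adjacency.index[iu[0][mask]],
            "gene_b": adjacency.columns[iu[1][mask]],
        }
    )
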