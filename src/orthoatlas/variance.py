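"""Variance spectrum of expression log-ratios: tissue vs perturbation.

For every category (a tissue, or a perturbation experiment) the sample
variance across genes of its log-ratio vector measures how much of the
transcriptome the category moves.  Sorting those variances in decreasing
order against percent rank gives the spectrum on which tissue affiliation
dominates perturbation response by roughly an order of magnitude, with a
head of exceptions (cancer-like, potent-drug-like perturbations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CategoryVariance:
    category_id: str
    kind: str  # "tissue" | "perturbation"
    variance: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.kind not in ("tissue", "perturbation"):
            raise ValueError(f"unknown category kind {self.kind!r}")
        if self.n_genes < 2:
            raise ValueError("variance needs >= 2 genes")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


def variance_per_category(
    logratios: Iterable[float], category_id: str, kind: str
) -> CategoryVariance:
    """Sample variance (ddof=1) across genes of one category's log-ratios."""
    x = np.asarray(list(logratios), dtype=float)
    if x.size < 2:
        raise ValueError("log-ratio vector must have length >= 2")
    if np.isnan(x).any():
        raise ValueError("log-ratio vector contains missing values")
    return CategoryVariance(
        category_id=category_id, kind=kind,
        variance=float(x.var(ddof=1)), n_genes=int(x.size),
    )


def variances_from_frame(logratios: pd.DataFrame, kind: str) -> list[CategoryVariance]:
    """One CategoryVariance per column of a genes x categories table."""
    return [
        variance_per_category(logratios[c].to_numpy(), str(c), kind)
        for c in logratios.columns
    ]


def rank_percent_curve(
    variances: Iterable[CategoryVariance] | Mapping[str, float],
) -> pd.DataFrame:
    """Decreasing-order variance against percent rank (100*i/N, 1-based).

    Ties are ordered by category id so the curve is deterministic.
    """
    if isinstance(variances, Mapping):
        items = [(str(k), float(v)) for k, v in variances.items()]
    else:
        items = [(cv.category_id, cv.variance) for cv in variances]
    if not items:
        raise ValueError("need >= 1 category")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    return pd.DataFrame(
        {
            "percent_rank": [100.0 * (i + 1) / n for i in range(n)],
            "variance": [v for _, v in items],
            "category_id": [k for k, _ in items],
        }
    )


@dataclass(frozen=True)
class VarianceSummary:
    """Median tissue/perturbation variance ratio plus the exception head.

    ``exceedance_fraction``: fraction of perturbation categories whose
    variance strictly exceeds the median tissue variance (the cancers and
    potent drugs of the spectrum's head).
    """

    median_ratio: float
    exceedance_fraction: float
    n_tissue: int
    n_perturbation: int


def tissue_vs_perturbation_summary(
    tissue_variances: Iterable[float],
    perturbation_variances: Iterable[float],
) -> VarianceSummary:
    tv = np.asarray(list(tissue_variances), dtype=float)
    pv = np.asarray(list(perturbation_variances), dtype=float)
    if tv.size == 0 or pv.size == 0:
        raise ValueError("both variance lists must be nonempty")
    med_t = float(np.median(tv))
    med_p = float(np.median(pv))
    ratio = math.inf if med_p == 0.0 else med_t / med_p
    exceed = float(np.mean(pv > med_t))
    return VarianceSummary(
        median_ratio=ratio,
        exceedance_fraction=exceed,
        n_tissue=int(tv.size),
        n_perturbation=int(pv.size),
    )
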