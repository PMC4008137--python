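"""Hypergeometric GO over-representation analysis of correlation-selected
gene sets.

The study set is built by a conjunction rule over the two platform sets
(a cluster must pass the correlation cutoff in both independent compendia),
and each GO term is tested one-sided for over-representation of the study
set within the universe of all analyzed ortholog clusters:

    p = P[X >= Count],  X ~ Hypergeometric(N, Size, n)

with N the universe size, Size the term size within the universe, n the
study size and Count the observed study/term overlap.  No multiple-testing
correction is applied by default (raw p cutoffs of 0.001 for the
positively correlated set and 0.05 for the negatively correlated set);
a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def select_correlated_genes(
    records_set1: pd.DataFrame,
    records_set2: pd.DataFrame,
    cutoff: float,
    direction: str = "above",
) -> list:
    """Clusters passing the correlation cutoff in BOTH record sets.

    ``records_*`` carry columns ``cluster_id`` and ``r`` (one row per
    cluster).  direction "above": r > cutoff in both; "below": r < cutoff in
    both.  Clusters present in only one set are excluded and counted.
    """
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    a = records_set1.set_index("cluster_id")["r"]
    b = records_set2.set_index("cluster_id")["r"]
    common = a.index.intersection(b.index)
    n_only = (len(a) - len(common)) + (len(b) - len(common))
    if n_only:
        logger.info("excluded %d cluster records present in only one set", n_only)
    a, b = a.loc[common], b.loc[common]
    if direction == "above":
        mask = (a > cutoff) & (b > cutoff)
    else:
        mask = (a < cutoff) & (b < cutoff)
    mask &= a.notna() & b.notna()
    return sorted(common[mask])


def read_term_mapping(path) -> dict[str, set]:
    """Flat two-column TSV (term_id, gene_id) -> term -> gene set."""
    frame = pd.read_csv(path, sep="\t")
    return {
        term: set(group["gene_id"])
        for term, group in frame.groupby("term_id", sort=True)
    }


def term_mapping_from_frame(frame: pd.DataFrame) -> dict[str, set]:
    return {
        term: set(group["gene_id"])
        for term, group in frame.groupby("term_id", sort=True)
    }


def hypergeometric_pvalue(
    count: int, universe_size: int, term_size: int, study_size: int
) -> float:
    """One-sided over-representation tail P[X >= count]."""
    p = float(stats.hypergeom.sf(count - 1, universe_size, term_size, study_size))
    return min(p, 1.0)


def hypergeometric_enrichment(
    study: Iterable,
    term_map: Mapping[str, set],
    universe: Iterable,
    term_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided over-representation test per term.

    Returns columns term_id, pvalue, odds_ratio, exp_count, count, size,
    term (label), sorted by p-value then term id.  The odds ratio is from
    the 2x2 study/term table; Size == Count gives an infinite odds ratio.
    """
    study_set = set(study)
    universe_set = set(universe)
    if not study_set or not universe_set:
        raise ValueError("study and universe must be nonempty")
    if not study_set <= universe_set:
        raise ValueError("study set must be a subset of the universe")
    n_univ = len(universe_set)
    n_study = len(study_set)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe_set
        size = len(members)
        if size == 0:
            continue
        count = len(members & study_set)
        p = hypergeometric_pvalue(count, n_univ, size, n_study)
        a, b_ = count, size - count
        c, d = n_study - count, n_univ - size - n_study + count
        odds = (a * d) / (b_ * c) if b_ * c > 0 else math.inf
        rows.append(
            {
                "term_id": term,
                "pvalue": p,
                "odds_ratio": odds,
                "exp_count": size * n_study / n_univ,
                "count": count,
                "size": size,
                "term": (term_labels or {}).get(term, ""),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def significance_filter(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Retain results with p <= alpha (boundary inclusive).

    Conventional cutoffs: 0.001 for the positively correlated study set,
    0.05 for the negatively correlated one.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if len(results) == 0:
        return results
    return results[results["pvalue"] <= alpha].reset_index(drop=True)


def benjamini_hochberg(results: pd.DataFrame) -> pd.DataFrame:
    """Optional BH-adjusted p-values, added as column ``pvalue_bh``.

    Off the default path: the canonical analysis uses raw p cutoffs.
    """
    out = results.copy()
    if len(out) == 0:
        out["pvalue_bh"] = pd.Series(dtype=float)
        return out
    m = len(out)
    order = out["pvalue"].rank(method="first").astype(int)
    adj = (out["pvalue"] * m / order).to_numpy()
    # enforce monotonicity from the largest p downwards
    idx = order.sort_values(ascending=False).index
    running = 1.0
    for i in idx:
        running = min(running, adj[out.index.get_loc(i)])
        adj[out.index.get_loc(i)] = running
    out["pvalue_bh"] = adj.clip(max=1.0)
    return out
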