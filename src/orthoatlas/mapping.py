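"""Functional ortholog assignment inside m:n homolog clusters.

Lineage-specific duplication leaves clusters with several genes per species
(m:n:p, here capped at four per species).  Within such a cluster, for each
species pair, every cross-species gene pair is correlated across tissue
meta-profiles and the pairs are ranked from highest (rank 1) downwards.  A
large drop from rank 1 to rank 2 indicates one "best pair" — the putative
functional orthologs — while within-species duplicate pairs whose
correlation falls below the Blanc-Wolfe cutoff (0.52) are flagged as
regulatorily divergent paralogs.  Expression dendrograms (complete linkage
on 1 - r) visualize the cluster, and assignments can be checked for
concordance against sequence-similarity-based top pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .architecture import linkage_to_newick

logger = logging.getLogger(__name__)

MAX_GENES_PER_SPECIES = 4
DIVERGENCE_CUTOFF = 0.52  # Blanc-Wolfe duplicate-divergence threshold


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RankedPairList:
    """All m_A x m_B cross-species pairs of one cluster, ranked by r.

    Rank 1 is the highest correlation; ties are broken by (gene_a, gene_b)
    id order; pairs with an undefined r (constant profile) are flagged and
    placed last.
    """

    cluster_id: str
    species_pair: str
    pairs: pd.DataFrame  # columns: gene_a, gene_b, r, rank, flagged

    def __post_init__(self) -> None:
        ranks = self.pairs["rank"].to_numpy()
        if list(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive from 1")

    def best_pair(self) -> tuple[str, str]:
        row = self.pairs.iloc[0]
        return (row["gene_a"], row["gene_b"])


def rank_pair_correlations(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    cluster_id: str = "",
    species_pair: str = "",
) -> RankedPairList:
    """Correlate and rank every cross-species gene pair of a cluster.

    ``matrix_*`` are gene x tissue meta-profile matrices (tissue columns in
    identical order) holding the cluster members' profiles.
    """
    if len(genes_a) > MAX_GENES_PER_SPECIES or len(genes_b) > MAX_GENES_PER_SPECIES:
        raise ValueError(
            f"clusters admitted to ranking have <= {MAX_GENES_PER_SPECIES} genes per species"
        )
    if not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("tissue categories differ between the two matrices")
    rows = []
    for ga in genes_a:
        for gb in genes_b:
            r = _pearson(
                matrix_a.loc[ga].to_numpy(dtype=float),
                matrix_b.loc[gb].to_numpy(dtype=float),
            )
            rows.append({"gene_a": ga, "gene_b": gb, "r": r, "flagged": np.isnan(r)})
    frame = pd.DataFrame(rows)
    frame["_sort_r"] = frame["r"].fillna(-np.inf)
    frame = frame.sort_values(
        ["_sort_r", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_sort_r").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return RankedPairList(cluster_id=cluster_id, species_pair=species_pair, pairs=frame)


def rank_profile_summary(ranked_lists: Iterable[RankedPairList]) -> pd.DataFrame:
    """Per-rank distribution of correlations across clusters.

    Rows are ranks (1-based); ranks beyond a cluster's pair count simply
    contribute nothing to that row.  Columns: median, q1, q3, n.
    """
    by_rank: dict[int, list[float]] = {}
    n_lists = 0
    for rl in ranked_lists:
        n_lists += 1
        for rank, r in zip(rl.pairs["rank"], rl.pairs["r"]):
            if not np.isnan(r):
                by_rank.setdefault(int(rank), []).append(float(r))
    if n_lists == 0:
        raise ValueError("need >= 1 ranked cluster")
    rows = []
    for rank in sorted(by_rank):
        vals = np.array(by_rank[rank])
        rows.append(
            {
                "rank": rank,
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


def best_pair_assignment(
    ranked: RankedPairList, method: str = "greedy"
) -> list[tuple[str, str, float]]:
    """Match genes across the species pair, best correlations first.

    "greedy" repeatedly takes the highest-ranked pair whose genes are both
    still unmatched (mirrors the best-pair narrative; deterministic, but not
    guaranteed to maximize the summed correlation).  "optimal" maximizes the
    summed r over all matchings (Hungarian algorithm).  Both return
    min(m_A, m_B) pairs.
    """
    pairs = ranked.pairs
    genes_a = list(dict.fromkeys(pairs["gene_a"]))
    genes_b = list(dict.fromkeys(pairs["gene_b"]))
    n_match = min(len(genes_a), len(genes_b))
    if method == "greedy":
        used_a: set = set()
        used_b: set = set()
        out: list[tuple[str, str, float]] = []
        for row in pairs.itertuples(index=False):
            if row.gene_a in used_a or row.gene_b in used_b:
                continue
            out.append((row.gene_a, row.gene_b, float(row.r)))
            used_a.add(row.gene_a)
            used_b.add(row.gene_b)
            if len(out) == n_match:
                break
        return out
    if method == "optimal":
        score = np.full((len(genes_a), len(genes_b)), -2.0)
        for row in pairs.itertuples(index=False):
            r = -2.0 if np.isnan(row.r) else float(row.r)
            score[genes_a.index(row.gene_a), genes_b.index(row.gene_b)] = r
        ri, ci = linear_sum_assignment(-score)
        out = [
            (genes_a[i], genes_b[j], float(score[i, j]))
            for i, j in zip(ri, ci)
        ]
        out.sort(key=lambda t: -t[2])
        return out[:n_match]
    raise ValueError(f"unknown matching method {method!r}")


def flag_divergent_paralogs(
    matrix: pd.DataFrame,
    duplicate_pairs: Iterable[tuple[str, str]] | None = None,
    cutoff: float = DIVERGENCE_CUTOFF,
) -> pd.DataFrame:
    """Within-species duplicate pairs with r strictly below the cutoff.

    ``matrix`` holds the duplicates' tissue profiles (genes x tissues).  If
    ``duplicate_pairs`` is omitted, all gene pairs in the matrix are tested.
    Returns all pairs with their r and a boolean ``divergent`` flag
    (strict ``r < cutoff``; an r of exactly the cutoff is not flagged).
    """
    if duplicate_pairs is None:
        duplicate_pairs = combinations(list(matrix.index), 2)
    rows = []
    for g1, g2 in duplicate_pairs:
        r = _pearson(
            matrix.loc[g1].to_numpy(dtype=float), matrix.loc[g2].to_numpy(dtype=float)
        )
        rows.append(
            {"gene_1": g1, "gene_2": g2, "r": r,
             "divergent": bool(r < cutoff) if not np.isnan(r) else False}
        )
    return pd.DataFrame(rows, columns=["gene_1", "gene_2", "r", "divergent"])


@dataclass
class HomologTree:
    labels: list
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.labels)


def homolog_dendrogram(profiles: pd.DataFrame) -> HomologTree:
    """Complete-linkage tree over all cluster members (1 - r distances).

    ``profiles``: genes x tissues, with species-suffixed gene labels
    (e.g. ``21_2_h``, ``21_4_m``, ``21_5_r``).  A constant profile has no
    defined correlation; its leaf is attached at the maximal distance (2)
    with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("dendrogram needs >= 2 genes")
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "constant profiles attached at maximal distance: %s",
            list(profiles.index[constant]),
        )
        x = x.copy()
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    d[np.isnan(d)] = 2.0
    d[constant, :] = 2.0
    d[:, constant] = 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    z = linkage(squareform(d, checks=False), method="complete")
    return HomologTree(labels=list(profiles.index), linkage_matrix=z)


def concordance_with_sequence(
    expression_top: Mapping[str, tuple[str, str]],
    sequence_scores: pd.DataFrame,
    species_pair: str | None = None,
) -> tuple[float, list[str]]:
    """Fraction of clusters where expression and sequence agree on the top pair.

    ``expression_top``: cluster id -> rank-1 expression pair.
    ``sequence_scores``: long table (cluster_id, species_pair, gene_a,
    gene_b, similarity).  Clusters without sequence scores are excluded with
    a log line.  Returns (agreement fraction, discordant cluster ids).
    """
    scores = sequence_scores
    if species_pair is not None:
        scores = scores[scores["species_pair"] == species_pair]
    top_seq: dict[str, tuple[str, str]] = {}
    for cid, group in scores.groupby("cluster_id"):
        best = group.sort_values(
            ["similarity", "gene_a", "gene_b"], ascending=[False, True, True]
        ).iloc[0]
        top_seq[cid] = (best["gene_a"], best["gene_b"])
    missing = [c for c in expression_top if c not in top_seq]
    if missing:
        logger.info("excluding %d clusters without sequence scores", len(missing))
    shared = [c for c in expression_top if c in top_seq]
    if not shared:
        raise ValueError("no clusters with both expression and sequence assignments")
    discordant = [c for c in shared if expression_top[c] != top_seq[c]]
    agreement = 1.0 - len(discordant) / len(shared)
    return agreement, sorted(discordant)
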