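"""Compendium preparation: from probe-level matrices to ortholog meta-profiles.

The preparation chain mirrors how curated Affymetrix compendia are reduced to
one analysis-ready matrix per species:

1. keep only specific probe sets (suffix ``_at`` or ``_s_at``; multi-target
   suffixes ``_x_at``, ``_g_at``, ``_f_at``, ``_r_at``, ``_b_at``, ``_l_at``,
   ``_i_at`` are removed),
2. where a gene has several surviving probe sets, keep the one with the
   maximum present-call percentage (ties: lexicographically smallest id),
3. keep only ortholog clusters with a surviving probe in all three species
   ("complete triplets"; 1:1:1 clusters feed the per-cluster analyses),
4. average all samples of a tissue category into one meta-profile column,
5. optionally standardize each gene across tissues (z-score, ddof=1),
6. derive log-ratios: tissue column minus the per-gene mean over tissues,
   and perturbation experiment minus its matched control samples.

All expression values are log2 scale throughout, so differences are
log-ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import (
    SPECIES,
    ExpressionCompendium,
    OrthologClusterSet,
)

logger = logging.getLogger(__name__)

#: All recognized suffixes, longest-match-first ("_s_at" itself ends in "_at",
#: so matching must try the specific multi-character suffixes before "_at").
RECOGNIZED_SUFFIXES = (
    "_s_at", "_x_at", "_g_at", "_f_at", "_r_at", "_b_at", "_l_at", "_i_at", "_at",
)
KEPT_SUFFIXES = frozenset({"_at", "_s_at"})


def probe_suffix(probe_id: str) -> str | None:
    """Longest recognized suffix of ``probe_id``, or None."""
    for s in RECOGNIZED_SUFFIXES:
        if probe_id.endswith(s):
            return s
    return None


def filter_probe_sets(probes: pd.DataFrame) -> pd.DataFrame:
    """Keep only probe sets with a specific suffix (``_at`` or ``_s_at``).

    Probe ids without a recognizable suffix are dropped with a warning
    rather than raising — a curated table may carry stray control probes.
    """
    suffixes = probes.index.to_series().map(probe_suffix)
    unrecognized = suffixes.isna()
    if unrecognized.any():
        logger.warning(
            "dropping %d probe ids with unrecognized suffix (e.g. %s)",
            int(unrecognized.sum()), probes.index[unrecognized][0],
        )
    keep = suffixes.isin(KEPT_SUFFIXES)
    return probes.loc[keep.to_numpy()]


def select_best_probe(candidates: pd.DataFrame) -> str:
    """Probe id with maximum present-call %; ties go to the smallest id."""
    if len(candidates) == 0:
        raise ValueError("no candidate probes")
    best = candidates["present_call"].max()
    at_best = candidates.index[candidates["present_call"] == best]
    return sorted(at_best)[0]


def select_probes(probes: pd.DataFrame) -> pd.Series:
    """gene_id -> selected probe id over an already suffix-filtered table."""
    # sort on (gene, -present_call, probe id) so ties go to the smallest id
    ordered = (
        probes.assign(_pid=probes.index)
        .sort_values(["gene_id", "present_call", "_pid"],
                     ascending=[True, False, True], kind="mergesort")
    )
    first = ordered.groupby("gene_id", sort=True).head(1)
    return pd.Series(first.index, index=first["gene_id"], name="probe_id")


@dataclass
class TripletIndex:
    """Clusters surviving probe selection in all three species.

    ``complete``: every retained cluster with, per species, the surviving
    (gene, probe) assignments of all its members. ``one_to_one``: the strict
    1:1:1 subset as a flat table (index = cluster id).
    """

    complete: dict[str, dict[str, list[tuple[str, str]]]]
    one_to_one: pd.DataFrame

    def complete_ids(self) -> list[str]:
        return list(self.complete)


def assemble_triplets(
    clusters: OrthologClusterSet,
    probe_maps: Mapping[str, pd.Series],
) -> TripletIndex:
    """Retain clusters with >= 1 surviving probe per species.

    A gene with no surviving probe is dropped from its cluster; a cluster
    that loses a whole species is dropped with an accounting log line.
    The 1:1:1 table keeps only clusters with exactly one gene per species
    (counted before probe loss: a 2:1:1 cluster reduced to 1:1:1 by probe
    filtering stays out of the strict subset).
    """
    complete: dict[str, dict[str, list[tuple[str, str]]]] = {}
    dropped = 0
    rows: dict[str, dict[str, str]] = {}
    for cid, by_sp in clusters.clusters.items():
        surv: dict[str, list[tuple[str, str]]] = {}
        for sp in SPECIES:
            pm = probe_maps[sp]
            surv[sp] = [(g, pm[g]) for g in by_sp[sp] if g in pm.index]
        if all(surv[sp] for sp in SPECIES):
            complete[cid] = surv
            if all(len(by_sp[sp]) == 1 for sp in SPECIES):
                row: dict[str, str] = {}
                for sp in SPECIES:
                    row[f"{sp}_gene"], row[f"{sp}_probe"] = surv[sp][0]
                rows[cid] = row
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d incomplete clusters (missing probes in >=1 species)",
                    dropped)
    one = pd.DataFrame.from_dict(rows, orient="index")
    one.index.name = "cluster_id"
    return TripletIndex(complete=complete, one_to_one=one)


@dataclass
class TissueMetaProfileMatrix:
    """Genes (or probes) x tissue categories, one column per tissue.

    ``row_probe`` maps each row label back to its source probe set so that
    per-sample data (perturbation log-ratios) can be pulled for the same
    rows.  ``constant_rows`` lists rows flagged constant by standardization.
    """

    species: str
    values: pd.DataFrame
    standardized: bool = False
    constant_rows: list = field(default_factory=list)
    row_probe: pd.Series | None = None

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, species: str, standardized: bool = False
    ) -> "TissueMetaProfileMatrix":
        # round_trip parsing: exported floats must re-read bit-identically
        values = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )
        values.columns.name = "tissue"
        return cls(species=species, values=values, standardized=standardized)


def aggregate_tissue_profiles(
    compendium: ExpressionCompendium,
) -> TissueMetaProfileMatrix:
    """One representative vector per tissue: the mean over *all* samples
    annotated with that tissue, irrespective of sample class."""
    tissue_of = compendium.samples["tissue"]
    counts = tissue_of.value_counts()
    empty = [t for t in tissue_of.unique() if counts.get(t, 0) == 0]
    if empty:
        logger.warning("excluding tissues with zero samples: %s", empty)
    means = (
        compendium.values.T.groupby(tissue_of, sort=True).mean().T
    )
    means.columns.name = "tissue"
    return TissueMetaProfileMatrix(
        species=compendium.species,
        values=means,
        standardized=False,
        row_probe=pd.Series(means.index, index=means.index, name="probe_id"),
    )


def select_rows(
    meta: TissueMetaProfileMatrix,
    row_to_probe: Mapping[str, str] | pd.Series,
) -> TissueMetaProfileMatrix:
    """Re-index a probe-level meta-profile to analysis rows (genes/clusters).

    ``row_to_probe`` maps new row labels (e.g. ortholog cluster ids) to the
    selected probe set.
    """
    mapping = pd.Series(dict(row_to_probe))
    values = meta.values.loc[mapping.to_numpy()]
    values.index = pd.Index(mapping.index, name="row_id")
    return TissueMetaProfileMatrix(
        species=meta.species,
        values=values,
        standardized=meta.standardized,
        row_probe=pd.Series(mapping.to_numpy(), index=mapping.index, name="probe_id"),
    )


def standardize_per_gene(meta: TissueMetaProfileMatrix) -> TissueMetaProfileMatrix:
    """Per-row z-score across tissues (sample sd, ddof=1).

    Constant rows cannot be scaled; they are set to all-zero and flagged.
    """
    if meta.values.shape[1] < 2:
        raise ValueError("standardization needs >= 2 tissues")
    x = meta.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    z = (x - mean) / sd
    z[constant] = 0.0
    return TissueMetaProfileMatrix(
        species=meta.species,
        values=pd.DataFrame(z, index=meta.values.index, columns=meta.values.columns),
        standardized=True,
        constant_rows=list(meta.values.index[constant]),
        row_probe=meta.row_probe,
    )


@dataclass
class PerturbationLogratioSet:
    """Per-gene log-ratios for tissues and perturbation experiments.

    ``tissue``: rows x tissues, tissue column minus the per-row mean over all
    tissue columns.  ``perturbation``: rows x experiments, mean of
    perturbation samples minus mean of matched control samples (values are
    log2, so the difference is a log-ratio).
    """

    species: str
    tissue: pd.DataFrame
    perturbation: pd.DataFrame
    skipped_experiments: list = field(default_factory=list)


def compute_logratios(
    meta: TissueMetaProfileMatrix,
    compendium: ExpressionCompendium,
) -> PerturbationLogratioSet:
    """Tissue and perturbation log-ratios on the rows of ``meta``.

    ``meta`` must be unstandardized (log2 expression, not z-scores).
    Perturbation experiments lacking a control arm are skipped with a
    warning.
    """
    if meta.standardized:
        raise ValueError("log-ratios require an unstandardized meta-profile matrix")
    tissue_lr = meta.values.sub(meta.values.mean(axis=1), axis=0)

    if meta.row_probe is None:
        raise ValueError("meta-profile lacks row->probe mapping")
    probe_vals = compendium.values.loc[meta.row_probe.to_numpy()]
    probe_vals.index = meta.values.index

    samples = compendium.samples
    pert_cols: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    exp_ids = sorted(samples.loc[samples["sample_class"] == "perturbation",
                                 "experiment_id"].unique())
    for eid in exp_ids:
        in_exp = samples["experiment_id"] == eid
        pert_ids = samples.index[in_exp & (samples["sample_class"] == "perturbation")]
        ctrl_ids = samples.index[in_exp & (samples["sample_class"] == "control")]
        if len(ctrl_ids) == 0:
            logger.warning("experiment %s has no control samples; skipped", eid)
            skipped.append(eid)
            continue
        pert_cols[eid] = (
            probe_vals[pert_ids].mean(axis=1) - probe_vals[ctrl_ids].mean(axis=1)
        ).to_numpy()
    pert_lr = pd.DataFrame(pert_cols, index=meta.values.index)
    pert_lr.columns.name = "experiment_id"
    return PerturbationLogratioSet(
        species=meta.species,
        tissue=tissue_lr,
        perturbation=pert_lr,
        skipped_experiments=skipped,
    )


# ---------------------------------------------------------------------------
# end-to-end convenience


def prepare_species_matrices(
    compendia: Mapping[str, ExpressionCompendium],
    clusters: OrthologClusterSet,
    standardize: bool = False,
) -> tuple[dict[str, TissueMetaProfileMatrix], TripletIndex]:
    """Full prep chain for one platform set.

    Returns per-species meta-profile matrices indexed by 1:1:1 ortholog
    cluster id (so rows align across species), plus the triplet index with
    the complete m:n:p clusters for the functional-mapping stage.
    """
    probe_maps = {
        sp: select_probes(filter_probe_sets(compendia[sp].probes)) for sp in SPECIES
    }
    triplets = assemble_triplets(clusters, probe_maps)
    matrices: dict[str, TissueMetaProfileMatrix] = {}
    for sp in SPECIES:
        meta = aggregate_tissue_profiles(compendia[sp])
        mapping = triplets.one_to_one[f"{sp}_probe"]
        m = select_rows(meta, mapping)
        matrices[sp] = standardize_per_gene(m) if standardize else m
    return matrices, triplets


def gene_meta_profiles(
    compendium: ExpressionCompendium,
    probe_map: pd.Series,
    standardize: bool = False,
) -> TissueMetaProfileMatrix:
    """Meta-profiles for every surviving gene of one species (gene-id rows)."""
    meta = aggregate_tissue_profiles(compendium)
    m = select_rows(meta, probe_map)
    return standardize_per_gene(m) if standardize else m
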