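"""Synthetic multi-species expression compendium generator.

Emulates a curated microarray tissue compendium for human, mouse and rat:
log2-scale expression with per-gene baselines, tissue effects whose
cross-species correlation is controlled per species pair, perturbation /
control experiment pairs, a cell-culture shift signature, an Affymetrix-style
multi-probe-per-gene probe model, and ortholog clusters that are mostly
1:1:1 with a small m:n:p fraction (2-4 genes per species).

The generative model for gene ``g`` in a sample ``s`` of tissue ``t`` is::

    x = mu_g + T[g, t] + P[g, e] * 1[s perturbed in experiment e] + eps

with ``eps ~ Normal(0, noise_sd^2)``.  Tissue-effect vectors ``T`` of
orthologous genes in a species pair (A, B) are drawn jointly normal with
correlation ``rho_AB``, so conservation of tissue regulation is a dial.
All randomness derives from ``GeneratorConfig.seed``; identical seed and
config reproduce byte-identical output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse", "rat")
SPECIES_SUFFIX = {"human": "h", "mouse": "m", "rat": "r"}
SPECIES_PAIRS = (("human", "mouse"), ("human", "rat"), ("mouse", "rat"))

#: Multi-target probe-set suffixes (filtered out downstream) and the two
#: specific ones that survive the suffix filter.
MULTI_TARGET_SUFFIXES = ("_x_at", "_g_at", "_f_at", "_r_at", "_b_at", "_l_at", "_i_at")
SPECIFIC_SUFFIXES = ("_at", "_s_at")

CELL_CULTURE = "cell_culture"

# Default tissue catalogue, grouped by organ system.  The CNS block carries
# the dominant shared signature that separates on PC1.
_ORGAN_SYSTEMS: dict[str, tuple[str, ...]] = {
    "cns": (
        "cerebral_cortex", "cerebellum", "hippocampus", "hypothalamus",
        "amygdala", "thalamus", "spinal_cord", "brain_stem", "caudate_nucleus",
        "pituitary_gland",
    ),
    "cardiovascular": ("heart", "heart_atrium", "heart_ventricle", "aorta", "artery"),
    "musculoskeletal": ("skeletal_muscle", "smooth_muscle", "tongue", "bone", "cartilage"),
    "digestive": ("liver", "stomach", "small_intestine", "colon", "pancreas", "esophagus"),
    "respiratory": ("lung", "trachea", "bronchus"),
    "renal": ("kidney", "kidney_cortex", "kidney_medulla", "bladder"),
    "haemolymphoid": ("spleen", "thymus", "bone_marrow", "blood", "lymph_node"),
    "endocrine": ("adrenal_gland", "thyroid_gland", "parathyroid", "pineal_gland"),
    "reproductive": ("testis", "ovary", "uterus", "prostate", "placenta", "mammary_gland"),
    "integumentary": ("skin", "adipose_tissue", "eye", "retina", "salivary_gland"),
    "in_vitro": (CELL_CULTURE,),
}


def default_organ_system_map(n_tissues: int) -> dict[str, str]:
    """Tissue -> organ-system labels for the first ``n_tissues`` tissues.

    ``cell_culture`` is always included; the remaining slots are filled
    round-robin across organ systems so that small compendia still contain a
    mixture of systems (including a CNS block).
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    mapping = {CELL_CULTURE: "in_vitro"}
    pools = {
        sys: list(tissues)
        for sys, tissues in _ORGAN_SYSTEMS.items()
        if sys != "in_vitro"
    }
    order = itertools.cycle(pools)
    while len(mapping) < n_tissues:
        sys = next(order)
        if pools[sys]:
            tissue = pools[sys].pop(0)
            mapping[tissue] = sys
        elif all(not p for p in pools.values()):
            # more tissues requested than names in the catalogue
            i = len(mapping)
            mapping[f"tissue_{i:02d}"] = "other"
    return mapping


@dataclass(frozen=True)
class ProbeModel:
    """Per-gene probe-set instantiation model.

    Each gene gets one ``_at`` probe plus 0..``extra_probe_max`` extra probes
    whose suffixes are drawn from the multi-target set plus ``_s_at``;
    present-call percentages are Uniform(0, 100); probe-level measurement
    noise is iid Normal(0, probe_noise_sd^2) on top of the gene profile.
    """

    extra_probe_max: int = 2
    s_at_weight: float = 0.3
    probe_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.extra_probe_max < 0 or not 0 <= self.s_at_weight <= 1:
            raise ValueError("invalid probe model parameters")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic compendium.

    Defaults mirror the scale of the lower-coverage platform set of a
    three-species tissue compendium: 2127 ortholog clusters of which ~2% are
    m:n:p, 56 tissue categories, tissue effects an order of magnitude more
    variable than perturbation effects, and a mouse-rat conservation higher
    than either pair with human.
    """

    n_clusters: int = 2127
    mnp_fraction: float = 0.02
    n_tissues: int = 56
    organ_system_map: Mapping[str, str] | None = None
    n_samples_per_tissue: int = 3
    conservation: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("human", "mouse"): 0.6,
            ("human", "rat"): 0.6,
            ("mouse", "rat"): 0.9,
        }
    )
    negative_frac: float = 0.05
    tissue_effect_sd: float = 2.0
    perturbation_effect_sd: float = 0.6325  # ~2/sqrt(10): x10 variance gap
    noise_sd: float = 0.5
    n_perturbations: int = 50
    n_replicates: int = 2  # per arm of each perturbation experiment
    cellculture_signature_size: int = 177
    cellculture_effect: float = 4.0
    dominant_group: str = "cns"
    dominant_group_frac: float = 0.2
    dominant_group_effect: float = 3.0
    seq_discordance_frac: float = 0.1
    probe_model: ProbeModel = field(default_factory=ProbeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2 (tissue mean undefined otherwise)")
        for name in ("mnp_fraction", "negative_frac", "dominant_group_frac",
                     "seq_discordance_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tissue_effect_sd", "perturbation_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples_per_tissue < 1 or self.n_replicates < 1:
            raise ValueError("sample counts must be >= 1")
        if self.n_perturbations < 0 or self.cellculture_signature_size < 0:
            raise ValueError("counts must be >= 0")
        for pair, rho in self.conservation.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"conservation[{pair}] must be in [-1, 1]")

    # -- derived helpers -------------------------------------------------

    def tissues(self) -> list[str]:
        return list(self.organ_systems())

    def organ_systems(self) -> dict[str, str]:
        if self.organ_system_map is not None:
            return dict(self.organ_system_map)
        return default_organ_system_map(self.n_tissues)

    def rho(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.conservation else (b, a)
        return float(self.conservation[key])

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class OrthologClusterSet:
    """Ortholog clusters: cluster id -> per-species gene id lists."""

    clusters: dict[str, dict[str, list[str]]]

    def __len__(self) -> int:
        return len(self.clusters)

    def ids(self) -> list[str]:
        return list(self.clusters)

    def is_one_to_one(self, cid: str) -> bool:
        return all(len(g) == 1 for g in self.clusters[cid].values())

    def one_to_one_ids(self) -> list[str]:
        return [c for c in self.clusters if self.is_one_to_one(c)]

    def mnp_ids(self) -> list[str]:
        return [c for c in self.clusters if not self.is_one_to_one(c)]

    def genes(self, species: str) -> list[str]:
        return [g for c in self.clusters.values() for g in c[species]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, sp, g)
            for cid, by_sp in self.clusters.items()
            for sp in SPECIES
            for g in by_sp[sp]
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "species", "gene_id"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologClusterSet":
        clusters: dict[str, dict[str, list[str]]] = {}
        for cid, sp, g in frame[["cluster_id", "species", "gene_id"]].itertuples(index=False):
            clusters.setdefault(cid, {s: [] for s in SPECIES})[sp].append(g)
        return cls(clusters)


@dataclass
class ExpressionCompendium:
    """One species' expression compendium on one platform set.

    ``values``: probe sets x samples, log2 scale. ``samples``: per-sample
    tissue category, sample class (normal/perturbation/control) and
    experiment id. ``probes``: probe id -> gene id, present-call %.
    ``truth`` carries generator ground truth (gene-level profiles and which
    clusters/genes carry which signature) for testing; it is not written to
    disk as part of the compendium tables.
    """

    species: str
    platform_set: str
    values: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample annotation does not match matrix columns")
        if not self.values.index.equals(self.probes.index):
            raise ValueError("probe annotation does not match matrix rows")


@dataclass
class GroundTruth:
    """Gene-level generator truth shared by both platform sets of a species."""

    profiles: dict[str, pd.DataFrame]  # species -> genes x tissues of mu + T
    perturbation_effects: dict[str, pd.DataFrame]  # species -> genes x experiments
    cellculture_clusters: list[str]
    dominant_clusters: list[str]
    negative_clusters: list[str]
    primary_genes: dict[str, dict[str, str]]  # cluster -> species -> planted gene


# ---------------------------------------------------------------------------
# cluster generation


def generate_ortholog_clusters(config: GeneratorConfig) -> OrthologClusterSet:
    """Draw ortholog clusters; a ``mnp_fraction`` of them are m:n:p.

    m:n:p clusters have 2-4 genes in every species (never more than 4); the
    rest are strict 1:1:1.  Gene ids are globally unique per species and
    carry a species suffix (``..._h``, ``..._m``, ``..._r``).
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_clusters
    n_mnp = int(round(n * config.mnp_fraction))
    mnp_idx = set(rng.choice(n, size=n_mnp, replace=False).tolist()) if n_mnp else set()
    clusters: dict[str, dict[str, list[str]]] = {}
    for i in range(n):
        cid = f"OG{i + 1:05d}"
        counts = (
            rng.integers(2, 5, size=len(SPECIES)) if i in mnp_idx
            else np.ones(len(SPECIES), dtype=int)
        )
        clusters[cid] = {
            sp: [f"{i + 1}_{j + 1}_{SPECIES_SUFFIX[sp]}" for j in range(counts[k])]
            for k, sp in enumerate(SPECIES)
        }
    return OrthologClusterSet(clusters)


# ---------------------------------------------------------------------------
# ground truth (gene-level biology, shared across platform sets)


def _pair_correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    corr = np.eye(len(SPECIES))
    for i, a in enumerate(SPECIES):
        for j, b in enumerate(SPECIES):
            if i < j:
                corr[i, j] = corr[j, i] = config.rho(a, b)
    return corr


def generate_ground_truth(
    config: GeneratorConfig, clusters: OrthologClusterSet
) -> GroundTruth:
    """Draw the gene-level biology: baselines, tissue and perturbation effects.

    The first gene of each species in a cluster (the "planted" functional
    ortholog) carries the cluster's cross-species correlated tissue-effect
    vector; additional duplicates draw independent effects, emulating
    regulatory divergence after lineage-specific duplication.
    """
    rng = np.random.default_rng([config.seed, 23])
    tissues = config.tissues()
    n_t = len(tissues)
    cids = clusters.ids()
    n_c = len(cids)

    corr = _pair_correlation_matrix(config)
    # nearest-PSD safeguard: clip tiny negative eigenvalues from user rho maps
    w, v = np.linalg.eigh(corr)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_c, n_t, len(SPECIES)))
    conserved = config.tissue_effect_sd * (z @ chol.T)  # (cluster, tissue, species)

    n_neg = int(round(n_c * config.negative_frac))
    neg_idx = rng.choice(n_c, size=n_neg, replace=False) if n_neg else np.array([], int)
    conserved[neg_idx, :, 0] *= -1.0  # anti-correlate the human member
    negative_clusters = [cids[i] for i in sorted(neg_idx.tolist())]

    one_to_one = [i for i, c in enumerate(cids) if clusters.is_one_to_one(c)]
    n_cc = min(config.cellculture_signature_size, len(one_to_one))
    if n_cc < config.cellculture_signature_size:
        logger.warning(
            "cell-culture signature truncated to %d (only %d 1:1:1 clusters)",
            n_cc, len(one_to_one),
        )
    cc_idx = rng.choice(one_to_one, size=n_cc, replace=False) if n_cc else np.array([], int)
    cc_set = set(cc_idx.tolist())
    cc_clusters = [cids[i] for i in sorted(cc_set)]

    dominant_pool = [i for i in range(n_c) if i not in cc_set]
    n_dom = int(round(n_c * config.dominant_group_frac))
    n_dom = min(n_dom, len(dominant_pool))
    dom_idx = (
        rng.choice(dominant_pool, size=n_dom, replace=False) if n_dom else np.array([], int)
    )
    dom_set = set(dom_idx.tolist())
    dominant_clusters = [cids[i] for i in sorted(dom_set)]
    dom_tissues = np.array(
        [config.organ_systems()[t] == config.dominant_group for t in tissues]
    )
    cc_col = tissues.index(CELL_CULTURE) if CELL_CULTURE in tissues else None

    profiles: dict[str, pd.DataFrame] = {}
    pert: dict[str, pd.DataFrame] = {}
    primary: dict[str, dict[str, str]] = {cid: {} for cid in cids}
    exp_ids = [f"pert{e + 1:03d}" for e in range(config.n_perturbations)]

    for k, sp in enumerate(SPECIES):
        genes = clusters.genes(sp)
        idx = pd.Index(genes, name="gene_id")
        mu = rng.normal(8.0, 2.0, size=len(genes))
        effects = np.empty((len(genes), n_t))
        row = 0
        for i, cid in enumerate(cids):
            members = clusters.clusters[cid][sp]
            primary[cid][sp] = members[0]
            for j in range(len(members)):
                if i in cc_set:
                    # cell-culture signature: silent in tissues, spiked in culture
                    vec = np.zeros(n_t)
                    if cc_col is not None:
                        vec[cc_col] = config.cellculture_effect
                elif j == 0:
                    vec = conserved[i, :, k].copy()
                else:
                    vec = rng.normal(0.0, config.tissue_effect_sd, size=n_t)
                if i in dom_set:
                    vec = vec + config.dominant_group_effect * dom_tissues
                effects[row] = vec
                row += 1
        profiles[sp] = pd.DataFrame(
            mu[:, None] + effects, index=idx, columns=pd.Index(tissues, name="tissue")
        )
        pert[sp] = pd.DataFrame(
            rng.normal(0.0, config.perturbation_effect_sd, size=(len(genes), len(exp_ids))),
            index=idx,
            columns=pd.Index(exp_ids, name="experiment_id"),
        )

    return GroundTruth(
        profiles=profiles,
        perturbation_effects=pert,
        cellculture_clusters=cc_clusters,
        dominant_clusters=dominant_clusters,
        negative_clusters=negative_clusters,
        primary_genes=primary,
    )


# ---------------------------------------------------------------------------
# compendium instantiation (per platform set)


def _sample_design(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    tissues = config.tissues()
    records: list[tuple[str, str, str]] = []
    for t in tissues:
        for _ in range(config.n_samples_per_tissue):
            records.append((t, "normal", f"obs_{t}"))
    pert_tissues = [t for t in tissues if t != CELL_CULTURE] or tissues
    for e in range(config.n_perturbations):
        eid = f"pert{e + 1:03d}"
        t = pert_tissues[e % len(pert_tissues)]
        for _ in range(config.n_replicates):
            records.append((t, "control", eid))
        for _ in range(config.n_replicates):
            records.append((t, "perturbation", eid))
    frame = pd.DataFrame(records, columns=["tissue", "sample_class", "experiment_id"])
    frame.index = pd.Index(
        [f"s{i + 1:05d}" for i in range(len(frame))], name="sample_id"
    )
    return frame


def _instantiate_probes(
    genes: Sequence[str], pm: ProbeModel, rng: np.random.Generator
) -> pd.DataFrame:
    extra_pool = list(MULTI_TARGET_SUFFIXES) + ["_s_at"]
    w = np.full(len(extra_pool), (1.0 - pm.s_at_weight) / len(MULTI_TARGET_SUFFIXES))
    w[-1] = pm.s_at_weight
    rows: list[tuple[str, str]] = []
    n_extra = rng.integers(0, pm.extra_probe_max + 1, size=len(genes))
    for g, k in zip(genes, n_extra):
        rows.append((f"{g}.p1_at", g))
        for j in range(k):
            suffix = extra_pool[rng.choice(len(extra_pool), p=w)]
            rows.append((f"{g}.p{j + 2}{suffix}", g))
    probes = pd.DataFrame(rows, columns=["probe_id", "gene_id"]).set_index("probe_id")
    probes["present_call"] = rng.uniform(0.0, 100.0, size=len(probes))
    return probes


def generate_compendium(
    config: GeneratorConfig,
    clusters: OrthologClusterSet,
    platform_set: str = "SET1",
    truth: GroundTruth | None = None,
) -> dict[str, ExpressionCompendium]:
    """Instantiate one platform set: species -> ExpressionCompendium.

    The gene-level biology (baselines, tissue and perturbation effects) is a
    deterministic function of the config seed and is shared across platform
    sets, so SET1 and SET2 behave as independent measurements of the same
    underlying regulation — only sample noise, probe complements and
    present calls differ between sets.
    """
    if truth is None:
        truth = generate_ground_truth(config, clusters)
    set_tag = abs(hash_str(platform_set)) % (2**31)
    out: dict[str, ExpressionCompendium] = {}
    for k, sp in enumerate(SPECIES):
        rng = np.random.default_rng([config.seed, 57, set_tag, k])
        samples = _sample_design(config, rng)
        prof = truth.profiles[sp]
        pert = truth.perturbation_effects[sp]
        tissues = list(prof.columns)
        t_idx = np.array([tissues.index(t) for t in samples["tissue"]])
        gene_vals = prof.to_numpy()[:, t_idx]
        is_pert = (samples["sample_class"] == "perturbation").to_numpy()
        if is_pert.any():
            e_idx = pd.Index(pert.columns).get_indexer(
                samples.loc[is_pert, "experiment_id"]
            )
            gene_vals = gene_vals.copy()
            gene_vals[:, is_pert] += pert.to_numpy()[:, e_idx]
        gene_vals = gene_vals + rng.normal(
            0.0, config.noise_sd, size=gene_vals.shape
        )
        probes = _instantiate_probes(list(prof.index), config.probe_model, rng)
        gi = pd.Index(prof.index).get_indexer(probes["gene_id"])
        values = gene_vals[gi] + rng.normal(
            0.0, config.probe_model.probe_noise_sd, size=(len(probes), len(samples))
        )
        out[sp] = ExpressionCompendium(
            species=sp,
            platform_set=platform_set,
            values=pd.DataFrame(values, index=probes.index, columns=samples.index),
            samples=samples,
            probes=probes,
            truth={
                "profiles": prof,
                "perturbation_effects": pert,
                "cellculture_clusters": truth.cellculture_clusters,
                "dominant_clusters": truth.dominant_clusters,
                "negative_clusters": truth.negative_clusters,
                "primary_genes": truth.primary_genes,
            },
        )
    return out


def hash_str(s: str) -> int:
    """Stable (process-independent) string hash for seed derivation."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# GO mapping and sequence-similarity scores


def generate_go_mapping(
    config: GeneratorConfig,
    clusters: OrthologClusterSet,
    n_terms: int = 40,
    n_conserved_terms: int = 5,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Flat GO term -> gene mapping over ortholog cluster ids.

    Most terms draw members uniformly; ``n_conserved_terms`` draw only from
    clusters whose tissue regulation is conserved (not anti-correlated), so
    that an enrichment analysis of highly correlated orthologs has signal.
    """
    rng = np.random.default_rng([config.seed, 91])
    cids = clusters.ids()
    if truth is None:
        truth = generate_ground_truth(config, clusters)
    neg = set(truth.negative_clusters)
    conserved_pool = [c for c in cids if c not in neg] or cids
    rows: list[tuple[str, str]] = []
    for i in range(n_terms):
        pool = conserved_pool if i < n_conserved_terms else cids
        size = int(rng.integers(5, min(61, len(pool) + 1)))
        members = rng.choice(len(pool), size=size, replace=False)
        term = f"GO:{i + 1:07d}"
        rows.extend((term, pool[j]) for j in sorted(members.tolist()))
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def generate_sequence_scores(
    config: GeneratorConfig,
    clusters: OrthologClusterSet,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Pairwise sequence-similarity scores for m:n:p clusters.

    For a fraction ``1 - seq_discordance_frac`` of clusters the top-scoring
    pair per species pair is the planted functional ortholog pair; for the
    rest it is a random other pair, emulating cases where sequence similarity
    and expression conservation disagree.
    """
    rng = np.random.default_rng([config.seed, 131])
    if truth is None:
        truth = generate_ground_truth(config, clusters)
    rows: list[tuple[str, str, str, str, float]] = []
    for cid in clusters.mnp_ids():
        by_sp = clusters.clusters[cid]
        for a, b in SPECIES_PAIRS:
            pairs = [(ga, gb) for ga in by_sp[a] for gb in by_sp[b]]
            planted = (truth.primary_genes[cid][a], truth.primary_genes[cid][b])
            if len(pairs) > 1 and rng.random() < config.seq_discordance_frac:
                others = [p for p in pairs if p != planted]
                top = others[rng.integers(len(others))]
            else:
                top = planted
            base = rng.uniform(40.0, 70.0, size=len(pairs))
            for (ga, gb), s in zip(pairs, base):
                # boost larger than the base spread so `top` is the argmax
                score = s + (40.0 if (ga, gb) == top else 0.0)
                rows.append((cid, f"{a}-{b}", ga, gb, float(score)))
    return pd.DataFrame(
        rows, columns=["cluster_id", "species_pair", "gene_a", "gene_b", "similarity"]
    )


# ---------------------------------------------------------------------------
# TSV export (the dialect the prep module reads)


def write_compendium(compendium: ExpressionCompendium, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{compendium.species}_{compendium.platform_set}"
    compendium.values.to_csv(out / f"{tag}_matrix.tsv", sep="\t")
    compendium.samples.to_csv(out / f"{tag}_samples.tsv", sep="\t")
    compendium.probes.to_csv(out / f"{tag}_probes.tsv", sep="\t")


def read_compendium(
    in_dir: str | Path, species: str, platform_set: str
) -> ExpressionCompendium:
    d = Path(in_dir)
    tag = f"{species}_{platform_set}"
    values = pd.read_csv(
        d / f"{tag}_matrix.tsv", sep="\t", index_col=0, float_precision="round_trip"
    )
    values.columns.name = "sample_id"
    samples = pd.read_csv(d / f"{tag}_samples.tsv", sep="\t", index_col=0)
    probes = pd.read_csv(d / f"{tag}_probes.tsv", sep="\t", index_col=0)
    return ExpressionCompendium(
        species=species, platform_set=platform_set,
        values=values, samples=samples, probes=probes,
    )


def write_clusters(clusters: OrthologClusterSet, path: str | Path) -> None:
    clusters.to_frame().to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> OrthologClusterSet:
    return OrthologClusterSet.from_frame(pd.read_csv(path, sep="\t"))
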