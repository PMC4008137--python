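"""End-to-end orchestration: synthesize -> validate -> prep -> architecture
-> variance -> network -> enrich -> map, with every intermediate written as
plain TSV/JSON and a manifest of checksums for reproducibility.

Stages can be run individually (each reloads what it needs from the output
directory of earlier stages) or all at once; a fixed seed and config give
byte-identical outputs and therefore identical manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture, enrichment, mapping, network, prep, synthetic, variance
from .synthetic import SPECIES, SPECIES_PAIRS, GeneratorConfig

logger = logging.getLogger(__name__)

PLATFORM_SETS = ("SET1", "SET2")
ALL_STAGES = (
    "synthesize", "validate", "prep", "architecture",
    "variance", "network", "enrich", "map",
)
DEFAULT_NETWORK_RANGES = ((0.85, 0.89), (0.90, 0.94), (0.95, 0.99))


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``synthesize`` holds a generator config, or ``input_dir`` points
    at a directory with the five input table families in the generator's
    TSV dialect (per-species/set matrix+samples+probes, clusters.tsv,
    go_mapping.tsv, optional sequence_scores.tsv).
    """

    out_dir: str = "orthoatlas_out"
    seed: int = 0
    synthesize: GeneratorConfig | None = None
    input_dir: str | None = None
    stages: tuple = ALL_STAGES
    correlation_cutoff_pos: float = 0.7
    correlation_cutoff_neg: float = -0.2
    alpha_pos: float = 0.001
    alpha_neg: float = 0.05
    network_ranges: tuple = DEFAULT_NETWORK_RANGES
    category_target: str = synthetic.CELL_CULTURE
    category_on_threshold: float = 2.0  # log2-ratio units
    category_off_threshold: float = 1.0
    divergence_cutoff: float = mapping.DIVERGENCE_CUTOFF
    n_dendrograms: int = 3

    def __post_init__(self) -> None:
        if self.synthesize is None and self.input_dir is None:
            self.synthesize = GeneratorConfig(seed=self.seed)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.category_on_threshold <= self.category_off_threshold:
            raise ValueError("category on-threshold must exceed off-threshold")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthesize is not None:
            syn = dataclasses.asdict(self.synthesize)
            syn["conservation"] = {
                f"{a}-{b}": v for (a, b), v in self.synthesize.conservation.items()
            }
            d["synthesize"] = syn
        d["stages"] = list(self.stages)
        d["network_ranges"] = [list(r) for r in self.network_ranges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthesize", None)
        if syn is not None:
            syn = dict(syn)
            cons = syn.pop("conservation", None)
            if cons is not None:
                syn["conservation"] = {
                    tuple(k.split("-")): float(v) for k, v in cons.items()
                }
            pm = syn.pop("probe_model", None)
            if pm is not None:
                syn["probe_model"] = synthetic.ProbeModel(**pm)
            d["synthesize"] = GeneratorConfig(**syn)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "network_ranges" in d:
            d["network_ranges"] = tuple(tuple(r) for r in d["network_ranges"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_inputs(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    probes: pd.DataFrame,
    clusters: synthetic.OrthologClusterSet | None = None,
    go_mapping: pd.DataFrame | None = None,
    species: str | None = None,
) -> ValidationReport:
    """Schema and cross-reference checks with line-level diagnostics."""
    findings: list[str] = []

    for col in ("tissue", "sample_class", "experiment_id"):
        if col not in samples.columns:
            findings.append(f"samples table lacks column {col!r}")
    for col in ("gene_id", "present_call"):
        if col not in probes.columns:
            findings.append(f"probes table lacks column {col!r}")

    dup = probes.index[probes.index.duplicated(keep=False)]
    for pid in dup.unique():
        rows = [i + 2 for i, x in enumerate(probes.index) if x == pid]  # 1-based + header
        findings.append(f"duplicated probe id {pid!r} at rows {rows}")
    dup_s = samples.index[samples.index.duplicated(keep=False)].unique()
    for sid in dup_s:
        findings.append(f"duplicated sample id {sid!r}")

    missing_ann = [c for c in values.columns if c not in samples.index]
    for c in missing_ann:
        findings.append(f"matrix column {c!r} lacks a sample annotation")
    extra_ann = [s for s in samples.index if s not in set(values.columns)]
    for s in extra_ann:
        findings.append(f"annotated sample {s!r} missing from matrix")
    missing_probe = [p for p in values.index if p not in set(probes.index)]
    for p in missing_probe[:20]:
        findings.append(f"matrix row {p!r} lacks a probe annotation")

    if values.isna().any().any():
        n = int(values.isna().sum().sum())
        findings.append(f"matrix contains {n} missing values")

    if "sample_class" in samples.columns:
        bad = samples[~samples["sample_class"].isin(["normal", "perturbation", "control"])]
        for sid in bad.index:
            findings.append(f"sample {sid!r} has invalid class {bad.loc[sid, 'sample_class']!r}")

    if clusters is not None and species is not None:
        known = set(probes["gene_id"])
        for cid, by_sp in clusters.clusters.items():
            for g in by_sp.get(species, []):
                if g not in known:
                    findings.append(
                        f"cluster {cid} gene {g!r} absent from {species} probe table"
                    )
    if go_mapping is not None and clusters is not None:
        cids = set(clusters.ids())
        unknown = sorted(set(go_mapping["gene_id"]) - cids)
        for g in unknown[:20]:
            findings.append(f"GO mapping references unknown gene/cluster {g!r}")
    return ValidationReport(findings=findings)


# ---------------------------------------------------------------------------
# stage runner


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineReport:
    out_dir: Path
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the configured stages in canonical order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        fn = globals()[f"_stage_{stage}"]
        try:
            fn(config, ctx, out)
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise PipelineError(stage, exc) from exc
    manifest = _write_manifest(config, out)
    return PipelineReport(out_dir=out, manifest=manifest)


def _inputs_dir(config: PipelineConfig, out: Path) -> Path:
    if config.input_dir is not None:
        return Path(config.input_dir)
    return out / "inputs"


def _load_inputs(config: PipelineConfig, ctx: dict, out: Path) -> None:
    if "clusters" in ctx:
        return
    d = _inputs_dir(config, out)
    ctx["clusters"] = synthetic.read_clusters(d / "clusters.tsv")
    ctx["compendia"] = {
        ps: {sp: synthetic.read_compendium(d, sp, ps) for sp in SPECIES}
        for ps in PLATFORM_SETS
    }
    ctx["go_mapping"] = pd.read_csv(d / "go_mapping.tsv", sep="\t")
    seq = d / "sequence_scores.tsv"
    ctx["seq_scores"] = pd.read_csv(seq, sep="\t") if seq.exists() else None


def _stage_synthesize(config: PipelineConfig, ctx: dict, out: Path) -> None:
    gen = config.synthesize
    if gen is None:
        raise ValueError("synthesize stage requested but no generator config given")
    d = out / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    clusters = synthetic.generate_ortholog_clusters(gen)
    truth = synthetic.generate_ground_truth(gen, clusters)
    compendia = {
        ps: synthetic.generate_compendium(gen, clusters, ps, truth=truth)
        for ps in PLATFORM_SETS
    }
    go = synthetic.generate_go_mapping(gen, clusters, truth=truth)
    seq = synthetic.generate_sequence_scores(gen, clusters, truth=truth)
    synthetic.write_clusters(clusters, d / "clusters.tsv")
    go.to_csv(d / "go_mapping.tsv", sep="\t", index=False)
    seq.to_csv(d / "sequence_scores.tsv", sep="\t", index=False)
    for ps in PLATFORM_SETS:
        for sp in SPECIES:
            synthetic.write_compendium(compendia[ps][sp], d)
    ctx.update(clusters=clusters, compendia=compendia, go_mapping=go, seq_scores=seq)
    logger.info("synthesize: %d clusters, %d tissues, 2 platform sets x 3 species",
                len(clusters), gen.n_tissues)


def _stage_validate(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _load_inputs(config, ctx, out)
    findings: list[str] = []
    for ps in PLATFORM_SETS:
        for sp in SPECIES:
            comp = ctx["compendia"][ps][sp]
            rep = validate_inputs(
                comp.values, comp.samples, comp.probes,
                clusters=ctx["clusters"], go_mapping=ctx["go_mapping"], species=sp,
            )
            findings.extend(f"{ps}/{sp}: {f}" for f in rep.findings)
    (out / "validation.txt").write_text(
        "\n".join(findings) + "\n" if findings else "OK: zero findings\n"
    )
    if findings:
        raise ValueError(f"{len(findings)} validation findings (see validation.txt)")


def _stage_prep(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _load_inputs(config, ctx, out)
    d = out / "prep"
    d.mkdir(parents=True, exist_ok=True)
    ctx["meta"] = {}
    ctx["meta_std"] = {}
    ctx["logratios"] = {}
    ctx["triplets"] = {}
    for ps in PLATFORM_SETS:
        matrices, triplets = prep.prepare_species_matrices(
            ctx["compendia"][ps], ctx["clusters"], standardize=False
        )
        ctx["triplets"][ps] = triplets
        ctx["meta"][ps] = matrices
        ctx["meta_std"][ps] = {
            sp: prep.standardize_per_gene(m) for sp, m in matrices.items()
        }
        ctx["logratios"][ps] = {
            sp: prep.compute_logratios(matrices[sp], ctx["compendia"][ps][sp])
            for sp in SPECIES
        }
        triplets.one_to_one.to_csv(d / f"{ps}_triplets.tsv", sep="\t")
        for sp in SPECIES:
            matrices[sp].write_tsv(d / f"{ps}_{sp}_meta.tsv")
            ctx["meta_std"][ps][sp].write_tsv(d / f"{ps}_{sp}_meta_std.tsv")
            lr = ctx["logratios"][ps][sp]
            lr.tissue.to_csv(d / f"{ps}_{sp}_tissue_logratio.tsv", sep="\t")
            lr.perturbation.to_csv(d / f"{ps}_{sp}_pert_logratio.tsv", sep="\t")
        logger.info(
            "prep %s: %d complete clusters, %d strict 1:1:1",
            ps, len(triplets.complete), len(triplets.one_to_one),
        )


def _ensure_prep(config: PipelineConfig, ctx: dict, out: Path) -> None:
    if "meta" in ctx:
        return
    d = out / "prep"
    if not d.exists():
        _stage_prep(config, ctx, out)
        return
    ctx["meta"] = {}
    ctx["meta_std"] = {}
    ctx["logratios"] = {}
    for ps in PLATFORM_SETS:
        ctx["meta"][ps] = {}
        ctx["meta_std"][ps] = {}
        ctx["logratios"][ps] = {}
        for sp in SPECIES:
            ctx["meta"][ps][sp] = prep.TissueMetaProfileMatrix.read_tsv(
                d / f"{ps}_{sp}_meta.tsv", species=sp
            )
            ctx["meta_std"][ps][sp] = prep.standardize_per_gene(ctx["meta"][ps][sp])
            lr_t = pd.read_csv(d / f"{ps}_{sp}_tissue_logratio.tsv", sep="\t",
                               index_col=0, float_precision="round_trip")
            lr_p = pd.read_csv(d / f"{ps}_{sp}_pert_logratio.tsv", sep="\t",
                               index_col=0, float_precision="round_trip")
            ctx["logratios"][ps][sp] = prep.PerturbationLogratioSet(
                species=sp, tissue=lr_t, perturbation=lr_p
            )


def _stage_architecture(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _ensure_prep(config, ctx, out)
    d = out / "architecture"
    d.mkdir(parents=True, exist_ok=True)
    ctx["pca"] = {}
    for ps in PLATFORM_SETS:
        ctx["pca"][ps] = {}
        for sp in SPECIES:
            std = ctx["meta_std"][ps][sp]
            proj = architecture.run_pca(std)
            ctx["pca"][ps][sp] = proj
            proj.scores.to_csv(d / f"{ps}_{sp}_pca_scores.tsv", sep="\t")
            proj.loadings.to_csv(d / f"{ps}_{sp}_pca_loadings.tsv", sep="\t")
            pd.Series(
                proj.explained_variance_ratio,
                index=proj.scores.columns, name="explained_variance_ratio",
            ).to_csv(d / f"{ps}_{sp}_pca_evr.tsv", sep="\t")
            tree = architecture.cluster_tissues(std)
            (d / f"{ps}_{sp}_tissue_tree.nwk").write_text(tree.to_newick() + "\n")
            lr = ctx["logratios"][ps][sp]
            lr_meta = prep.TissueMetaProfileMatrix(
                species=sp, values=lr.tissue, standardized=False
            )
            if config.category_target in lr.tissue.columns:
                genes = architecture.find_category_specific_genes(
                    lr_meta, config.category_target,
                    config.category_on_threshold, config.category_off_threshold,
                )
                pd.Series(genes, name="gene_id").to_csv(
                    d / f"{ps}_{sp}_{config.category_target}_specific.tsv",
                    sep="\t", index=False,
                )
        for a, b in SPECIES_PAIRS:
            sim = architecture.architecture_correlation(
                ctx["pca"][ps][a].scores, ctx["pca"][ps][b].scores
            )
            logger.info("architecture %s %s-%s score correlation %.3f", ps, a, b, sim)


def _stage_variance(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _ensure_prep(config, ctx, out)
    d = out / "variance"
    d.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for ps in PLATFORM_SETS:
        for sp in SPECIES:
            lr = ctx["logratios"][ps][sp]
            tv = variance.variances_from_frame(lr.tissue, "tissue")
            pv = variance.variances_from_frame(lr.perturbation, "perturbation")
            rows = [dataclasses.asdict(v) for v in tv + pv]
            pd.DataFrame(rows).to_csv(d / f"{ps}_{sp}_variances.tsv", sep="\t", index=False)
            variance.rank_percent_curve(tv).to_csv(
                d / f"{ps}_{sp}_tissue_curve.tsv", sep="\t", index=False)
            variance.rank_percent_curve(pv).to_csv(
                d / f"{ps}_{sp}_perturbation_curve.tsv", sep="\t", index=False)
            s = variance.tissue_vs_perturbation_summary(
                [v.variance for v in tv], [v.variance for v in pv]
            )
            summaries[f"{ps}_{sp}"] = dataclasses.asdict(s)
    (d / "summary.json").write_text(json.dumps(summaries, indent=2, default=str))
    ctx["variance_summaries"] = summaries


def _stage_network(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _ensure_prep(config, ctx, out)
    d = out / "network"
    d.mkdir(parents=True, exist_ok=True)
    ctx["correlations"] = {}
    fits = {}
    for ps in PLATFORM_SETS:
        recs = []
        for a, b in SPECIES_PAIRS:
            rec = network.ortholog_pair_correlations(
                ctx["meta_std"][ps][a].values,
                ctx["meta_std"][ps][b].values,
                species_pair=f"{a}-{b}",
            )
            recs.append(rec)
        all_recs = pd.concat(recs, ignore_index=True)
        all_recs.to_csv(d / f"{ps}_ortholog_correlations.tsv", sep="\t", index=False)
        ctx["correlations"][ps] = all_recs
        for sp in SPECIES:
            for low, high in config.network_ranges:
                dist = network.average_degree_distribution(
                    ctx["meta_std"][ps][sp].values, low, high
                )
                dist.table.to_csv(
                    d / f"{ps}_{sp}_degree_{dist.label}.tsv", sep="\t", index=False
                )
                try:
                    for method in ("mle", "loglog"):
                        fit = network.fit_power_law(dist, method=method)
                        fits[f"{ps}_{sp}_{dist.label}_{method}"] = {
                            "gamma": fit.gamma, "k_range": list(fit.k_range),
                            "diagnostic": fit.diagnostic,
                        }
                except ValueError as exc:
                    logger.warning("power-law fit skipped (%s %s %s): %s",
                                   ps, sp, dist.label, exc)
    (d / "power_law_fits.json").write_text(json.dumps(fits, indent=2))
    ctx["power_law_fits"] = fits


def _ensure_correlations(config: PipelineConfig, ctx: dict, out: Path) -> None:
    if "correlations" in ctx:
        return
    d = out / "network"
    if d.exists():
        ctx["correlations"] = {
            ps: pd.read_csv(d / f"{ps}_ortholog_correlations.tsv", sep="\t")
            for ps in PLATFORM_SETS
        }
    else:
        _stage_network(config, ctx, out)


def _stage_enrich(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _load_inputs(config, ctx, out)
    _ensure_correlations(config, ctx, out)
    d = out / "enrichment"
    d.mkdir(parents=True, exist_ok=True)
    # per cluster, mean r across the three species pairs, per platform set
    mean_r = {
        ps: (
            ctx["correlations"][ps]
            .groupby("cluster_id", as_index=False)["r"].mean()
        )
        for ps in PLATFORM_SETS
    }
    universe = sorted(
        set(mean_r["SET1"]["cluster_id"]) & set(mean_r["SET2"]["cluster_id"])
    )
    term_map = enrichment.term_mapping_from_frame(ctx["go_mapping"])
    for direction, cutoff, alpha, tag in (
        ("above", config.correlation_cutoff_pos, config.alpha_pos, "positive"),
        ("below", config.correlation_cutoff_neg, config.alpha_neg, "negative"),
    ):
        study = enrichment.select_correlated_genes(
            mean_r["SET1"], mean_r["SET2"], cutoff, direction
        )
        if not study:
            logger.warning("empty %s study set at cutoff %s", tag, cutoff)
            pd.DataFrame().to_csv(d / f"{tag}_enrichment.tsv", sep="\t", index=False)
            continue
        res = enrichment.hypergeometric_enrichment(study, term_map, universe)
        res.to_csv(d / f"{tag}_enrichment.tsv", sep="\t", index=False)
        sig = enrichment.significance_filter(res, alpha)
        sig.to_csv(d / f"{tag}_significant.tsv", sep="\t", index=False)
        logger.info("enrich %s: study %d, %d significant terms at alpha %g",
                    tag, len(study), len(sig), alpha)


def _stage_map(config: PipelineConfig, ctx: dict, out: Path) -> None:
    _load_inputs(config, ctx, out)
    _ensure_prep(config, ctx, out)
    d = out / "mapping"
    d.mkdir(parents=True, exist_ok=True)
    clusters = ctx["clusters"]
    for ps in PLATFORM_SETS:
        compendia = ctx["compendia"][ps]
        probe_maps = {
            sp: prep.select_probes(prep.filter_probe_sets(compendia[sp].probes))
            for sp in SPECIES
        }
        gene_mats = {
            sp: prep.gene_meta_profiles(compendia[sp], probe_maps[sp], standardize=True)
            for sp in SPECIES
        }
        mnp = [
            cid for cid in clusters.mnp_ids()
            if all(
                any(g in probe_maps[sp].index for g in clusters.clusters[cid][sp])
                for sp in SPECIES
            )
        ]
        assign_rows, ranked_by_pair = [], {}
        for a, b in SPECIES_PAIRS:
            pair = f"{a}-{b}"
            ranked_by_pair[pair] = []
            for cid in mnp:
                ga = [g for g in clusters.clusters[cid][a] if g in probe_maps[a].index]
                gb = [g for g in clusters.clusters[cid][b] if g in probe_maps[b].index]
                rl = mapping.rank_pair_correlations(
                    ga, gb, gene_mats[a].values, gene_mats[b].values,
                    cluster_id=cid, species_pair=pair,
                )
                ranked_by_pair[pair].append(rl)
                for ga_, gb_, r in mapping.best_pair_assignment(rl):
                    assign_rows.append(
                        {"cluster_id": cid, "species_pair": pair,
                         "gene_a": ga_, "gene_b": gb_, "r": r}
                    )
            if ranked_by_pair[pair]:
                mapping.rank_profile_summary(ranked_by_pair[pair]).to_csv(
                    d / f"{ps}_{pair}_rank_summary.tsv", sep="\t")
        pd.DataFrame(assign_rows).to_csv(
            d / f"{ps}_assignments.tsv", sep="\t", index=False)

        div_rows = []
        for sp in SPECIES:
            for cid in mnp:
                dups = [g for g in clusters.clusters[cid][sp] if g in probe_maps[sp].index]
                if len(dups) < 2:
                    continue
                flags = mapping.flag_divergent_paralogs(
                    gene_mats[sp].values.loc[dups], cutoff=config.divergence_cutoff
                )
                flags.insert(0, "species", sp)
                flags.insert(0, "cluster_id", cid)
                div_rows.append(flags)
        if div_rows:
            pd.concat(div_rows, ignore_index=True).to_csv(
                d / f"{ps}_divergent_paralogs.tsv", sep="\t", index=False)

        for cid in mnp[: config.n_dendrograms]:
            members = [
                (sp, g) for sp in SPECIES
                for g in clusters.clusters[cid][sp] if g in probe_maps[sp].index
            ]
            profiles = pd.concat(
                [gene_mats[sp].values.loc[[g]] for sp, g in members]
            )
            tree = mapping.homolog_dendrogram(profiles)
            (d / f"{ps}_{cid}_dendrogram.nwk").write_text(tree.to_newick() + "\n")

        if ctx.get("seq_scores") is not None and mnp:
            conc = {}
            for a, b in SPECIES_PAIRS:
                pair = f"{a}-{b}"
                expr_top = {
                    rl.cluster_id: rl.best_pair() for rl in ranked_by_pair[pair]
                }
                if expr_top:
                    agree, discordant = mapping.concordance_with_sequence(
                        expr_top, ctx["seq_scores"], species_pair=pair
                    )
                    conc[pair] = {"agreement": agree, "discordant": discordant}
            (d / f"{ps}_sequence_concordance.json").write_text(
                json.dumps(conc, indent=2))


def _write_manifest(config: PipelineConfig, out: Path) -> dict:
    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
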