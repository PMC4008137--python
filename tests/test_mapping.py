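"""Functional ortholog assignment: ranking, matching, paralog divergence,
dendrograms, sequence concordance."""

import numpy as np
import pandas as pd
import pytest

from orthoatlas import mapping, prep, synthetic
from orthoatlas.synthetic import GeneratorConfig, ProbeModel


def profiles_with_correlations(rng, corr_to_base, n_tissues=40):
    """Profiles with (approximately) prescribed correlation to a base vector."""
    base = rng.normal(size=n_tissues)
    base = (base - base.mean()) / base.std()
    out = {"base": base}
    for name, rho in corr_to_base.items():
        z = rng.normal(size=n_tissues)
        z = z - z.mean()
        z -= base * (z @ base) / (base @ base)  # orthogonalize
        z /= z.std()
        out[name] = rho * base + np.sqrt(1 - rho**2) * z
    return out


def frame(d, tissues=None):
    mat = pd.DataFrame(d).T
    mat.columns = tissues or [f"t{j}" for j in range(mat.shape[1])]
    return mat


class TestRanking:
    def test_pairs_sorted_descending(self):
        rng = np.random.default_rng(0)
        profs = profiles_with_correlations(rng, {"a1": 0.9, "b1": 0.5, "b2": 0.7})
        ma = frame({"a1": profs["a1"], "a0": profs["base"]})
        mb = frame({"b1": profs["b1"], "b2": profs["b2"]})
        rl = mapping.rank_pair_correlations(["a0"], ["b1", "b2"], ma, mb)
        assert rl.pairs["rank"].tolist() == [1, 2]
        assert rl.pairs.loc[0, "r"] > rl.pairs.loc[1, "r"]
        assert rl.pairs.loc[0, "gene_b"] == "b2"

    def test_two_by_two_has_four_pairs(self):
        rng = np.random.default_rng(1)
        ma = frame({"a1": rng.normal(size=10), "a2": rng.normal(size=10)})
        mb = frame({"b1": rng.normal(size=10), "b2": rng.normal(size=10)})
        rl = mapping.rank_pair_correlations(["a1", "a2"], ["b1", "b2"], ma, mb)
        assert len(rl.pairs) == 4
        assert rl.pairs["rank"].tolist() == [1, 2, 3, 4]

    def test_one_to_one_degenerate(self):
        rng = np.random.default_rng(2)
        ma = frame({"a1": rng.normal(size=8)})
        mb = frame({"b1": rng.normal(size=8)})
        rl = mapping.rank_pair_correlations(["a1"], ["b1"], ma, mb)
        assert len(rl.pairs) == 1 and rl.pairs.loc[0, "rank"] == 1

    def test_constant_profile_flagged_last(self):
        ma = frame({"a1": np.arange(6.0)})
        mb = frame({"b1": np.arange(6.0) * 2, "b2": np.full(6, 3.0)})
        rl = mapping.rank_pair_correlations(["a1"], ["b1", "b2"], ma, mb)
        assert rl.pairs.iloc[-1]["gene_b"] == "b2"
        assert bool(rl.pairs.iloc[-1]["flagged"])

    def test_cluster_size_cap_enforced(self):
        genes = [f"a{i}" for i in range(5)]
        m = frame({g: np.random.default_rng(3).normal(size=6) for g in genes})
        with pytest.raises(ValueError):
            mapping.rank_pair_correlations(genes, ["b"], m, m)


class TestRankSummary:
    def test_one_to_one_clusters_populate_rank_one_only(self):
        rng = np.random.default_rng(4)
        lists = []
        for i in range(3):
            ma = frame({f"a{i}": rng.normal(size=8)})
            mb = frame({f"b{i}": rng.normal(size=8)})
            lists.append(
                mapping.rank_pair_correlations([f"a{i}"], [f"b{i}"], ma, mb)
            )
        summary = mapping.rank_profile_summary(lists)
        assert list(summary.index) == [1]
        assert summary.loc[1, "n"] == 3

    def test_hand_set_medians(self):
        def fake(cid, rs):
            pairs = pd.DataFrame(
                {"gene_a": [f"a{i}" for i in range(len(rs))],
                 "gene_b": [f"b{i}" for i in range(len(rs))],
                 "r": sorted(rs, reverse=True),
                 "flagged": False}
            )
            pairs["rank"] = range(1, len(rs) + 1)
            return mapping.RankedPairList(cid, "h-m", pairs)

        summary = mapping.rank_profile_summary(
            [fake("c1", [0.9, 0.3]), fake("c2", [0.7, 0.5])]
        )
        assert summary.loc[1, "median"] == pytest.approx(0.8)
        assert summary.loc[2, "median"] == pytest.approx(0.4)

    def test_planted_pair_drop_dominates(self):
        # clusters with one conserved pair: rank1 -> rank2 is the big drop
        cfg = GeneratorConfig(
            n_clusters=60, n_tissues=30, mnp_fraction=1.0, noise_sd=0.1,
            n_perturbations=0, cellculture_signature_size=0,
            dominant_group_frac=0.0, negative_frac=0.0,
            probe_model=ProbeModel(probe_noise_sd=0.05), seed=31,
        )
        cl = synthetic.generate_ortholog_clusters(cfg)
        truth = synthetic.generate_ground_truth(cfg, cl)
        comp = synthetic.generate_compendium(cfg, cl, truth=truth)
        pm = {sp: prep.select_probes(prep.filter_probe_sets(comp[sp].probes))
              for sp in synthetic.SPECIES}
        mats = {sp: prep.gene_meta_profiles(comp[sp], pm[sp], standardize=True)
                for sp in synthetic.SPECIES}
        lists = [
            mapping.rank_pair_correlations(
                cl.clusters[cid]["mouse"], cl.clusters[cid]["rat"],
                mats["mouse"].values, mats["rat"].values,
                cluster_id=cid, species_pair="mouse-rat",
            )
            for cid in cl.ids()
        ]
        summary = mapping.rank_profile_summary(lists)
        drops = -np.diff(summary["median"].to_numpy())
        assert drops[0] == max(drops)
        assert drops[0] > 0.2


class TestAssignment:
    def _ranked(self, r_matrix, genes_a, genes_b):
        rows = []
        for i, ga in enumerate(genes_a):
            for j, gb in enumerate(genes_b):
                rows.append({"gene_a": ga, "gene_b": gb, "r": r_matrix[i][j],
                             "flagged": False})
        pairs = pd.DataFrame(rows).sort_values(
            ["r", "gene_a", "gene_b"], ascending=[False, True, True]
        ).reset_index(drop=True)
        pairs["rank"] = range(1, len(pairs) + 1)
        return mapping.RankedPairList("c", "h-m", pairs)

    def test_greedy_clean_case(self):
        rl = self._ranked([[0.9, 0.2], [0.3, 0.8]], ["a1", "a2"], ["b1", "b2"])
        out = mapping.best_pair_assignment(rl)
        assert [(a, b) for a, b, _ in out] == [("a1", "b1"), ("a2", "b2")]

    def test_greedy_vs_optimal_documented_divergence(self):
        rl = self._ranked([[0.9, 0.8], [0.85, 0.1]], ["a1", "a2"], ["b1", "b2"])
        greedy = mapping.best_pair_assignment(rl, "greedy")
        assert [(a, b) for a, b, _ in greedy] == [("a1", "b1"), ("a2", "b2")]
        assert sum(r for *_, r in greedy) == pytest.approx(1.0)
        optimal = mapping.best_pair_assignment(rl, "optimal")
        assert sum(r for *_, r in optimal) == pytest.approx(1.65)
        assert {(a, b) for a, b, _ in optimal} == {("a1", "b2"), ("a2", "b1")}

    def test_one_to_n_returns_rank_one_pair(self):
        rl = self._ranked([[0.4, 0.9, 0.1]], ["a1"], ["b1", "b2", "b3"])
        out = mapping.best_pair_assignment(rl)
        assert out == [("a1", "b2", 0.9)]

    def test_no_gene_matched_twice(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(-1, 1, size=(4, 3)).tolist()
        rl = self._ranked(r, [f"a{i}" for i in range(4)], [f"b{j}" for j in range(3)])
        out = mapping.best_pair_assignment(rl)
        assert len(out) == 3
        assert len({a for a, *_ in out}) == 3
        assert len({b for _, b, _ in out}) == 3


class TestDivergentParalogs:
    def test_low_correlation_flagged(self):
        rng = np.random.default_rng(8)
        profs = profiles_with_correlations(rng, {"dup": 0.14})
        out = mapping.flag_divergent_paralogs(
            frame({"g": profs["base"], "dup": profs["dup"]})
        )
        assert out.loc[0, "r"] == pytest.approx(0.14, abs=1e-9)
        assert bool(out.loc[0, "divergent"])

    @pytest.mark.parametrize(
        "r,expected", [(0.5199, True), (0.5201, False), (0.60, False)]
    )
    def test_strictly_below_cutoff_rule(self, r, expected):
        rng = np.random.default_rng(9)
        profs = profiles_with_correlations(rng, {"dup": r})
        out = mapping.flag_divergent_paralogs(
            frame({"g": profs["base"], "dup": profs["dup"]})
        )
        assert bool(out.loc[0, "divergent"]) is expected


class TestDendrogram:
    def test_most_correlated_pair_merges_first(self):
        rng = np.random.default_rng(10)
        profs = profiles_with_correlations(rng, {"g2": 0.95, "g3": 0.1})
        tree = mapping.homolog_dendrogram(
            frame({"g1": profs["base"], "g2": profs["g2"], "g3": profs["g3"]})
        )
        first = tree.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # g1, g2

    def test_identical_profiles_merge_at_zero(self):
        x = np.arange(8.0)
        tree = mapping.homolog_dendrogram(frame({"g1": x, "g2": x.copy()}))
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_attached_at_max_distance(self, caplog):
        with caplog.at_level("WARNING"):
            tree = mapping.homolog_dendrogram(
                frame({"g1": np.arange(6.0), "g2": np.full(6, 2.0),
                       "g3": np.arange(6.0) * 3})
            )
        assert "constant" in caplog.text
        assert tree.linkage_matrix[-1, 2] == pytest.approx(2.0)

    def test_conserved_members_form_a_clade(self):
        # three conserved genes + two rewired duplicates
        rng = np.random.default_rng(11)
        profs = profiles_with_correlations(
            rng, {"m": 0.95, "r": 0.9, "h2": 0.0, "m2": -0.1}
        )
        tree = mapping.homolog_dendrogram(
            frame({"21_1_h": profs["h2"], "21_2_h": profs["base"],
                   "21_3_m": profs["m2"], "21_4_m": profs["m"],
                   "21_5_r": profs["r"]})
        )
        nwk = tree.to_newick()
        conserved = {"21_2_h", "21_4_m", "21_5_r"}
        # the conserved trio merges before any rewired member joins them
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(tree.linkage_matrix, t=3, criterion="maxclust")
        by_cluster = {}
        for lab, gene in zip(labels, tree.labels):
            by_cluster.setdefault(lab, set()).add(gene)
        assert conserved in by_cluster.values()
        assert all(g in nwk for g in conserved)


class TestSequenceConcordance:
    def test_identical_assignments(self):
        seq = pd.DataFrame(
            {"cluster_id": ["c1", "c1"], "species_pair": ["h-m", "h-m"],
             "gene_a": ["a1", "a1"], "gene_b": ["b1", "b2"],
             "similarity": [90.0, 50.0]}
        )
        agree, disc = mapping.concordance_with_sequence(
            {"c1": ("a1", "b1")}, seq, "h-m"
        )
        assert agree == 1.0 and disc == []

    def test_swapped_assignments(self):
        seq = pd.DataFrame(
            {"cluster_id": ["c1", "c1"], "species_pair": ["h-m", "h-m"],
             "gene_a": ["a1", "a1"], "gene_b": ["b1", "b2"],
             "similarity": [90.0, 50.0]}
        )
        agree, disc = mapping.concordance_with_sequence(
            {"c1": ("a1", "b2")}, seq, "h-m"
        )
        assert agree == 0.0 and disc == ["c1"]

    def test_generator_discordance_fraction_recovered(self):
        q = 0.2
        cfg = GeneratorConfig(
            n_clusters=500, n_tissues=30, mnp_fraction=1.0, noise_sd=0.05,
            n_perturbations=0, cellculture_signature_size=0,
            dominant_group_frac=0.0, negative_frac=0.0,
            seq_discordance_frac=q,
            probe_model=ProbeModel(probe_noise_sd=0.0, extra_probe_max=0),
            seed=41,
        )
        cl = synthetic.generate_ortholog_clusters(cfg)
        truth = synthetic.generate_ground_truth(cfg, cl)
        seq = synthetic.generate_sequence_scores(cfg, cl, truth=truth)
        comp = synthetic.generate_compendium(cfg, cl, truth=truth)
        pm = {sp: prep.select_probes(prep.filter_probe_sets(comp[sp].probes))
              for sp in synthetic.SPECIES}
        mats = {sp: prep.gene_meta_profiles(comp[sp], pm[sp], standardize=True)
                for sp in synthetic.SPECIES}
        expr_top = {}
        for cid in cl.ids():
            rl = mapping.rank_pair_correlations(
                cl.clusters[cid]["mouse"], cl.clusters[cid]["rat"],
                mats["mouse"].values, mats["rat"].values,
                cluster_id=cid, species_pair="mouse-rat",
            )
            expr_top[cid] = rl.best_pair()
        agree, _ = mapping.concordance_with_sequence(expr_top, seq, "mouse-rat")
        assert abs(agree - (1 - q)) < 0.05
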