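"""Signature-matrix construction pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from svrdeconv import (
    EnrichmentScoreTable,
    ExpressionMatrix,
    RankedMarkerTable,
    SignatureBuildConfig,
    assemble_signature,
    compute_enrichment_scores,
    filter_tumor_expressed,
    hematopoietic_gene_set,
    optimize_signature,
    rank_marker_genes,
)


def _panel(rng, group_means, n_per_group=4, sd=0.1, prefix="g"):
    """Log2-scale panel from a genes x groups matrix of means."""
    group_means = np.asarray(group_means, dtype=float)
    n_genes, n_groups = group_means.shape
    cols, labels = {}, {}
    for g in range(n_groups):
        for r in range(n_per_group):
            name = f"grp{g}_r{r}"
            cols[name] = group_means[:, g] + rng.normal(0, sd, n_genes)
            labels[name] = f"grp{g}"
    data = pd.DataFrame(cols, index=[f"{prefix}{i}" for i in range(n_genes)])
    return ExpressionMatrix(data, scale="log2"), pd.Series(labels)


class TestRankMarkerGenes:
    @pytest.mark.parametrize("method", ["moderated", "ttest"])
    def test_planted_marker_tops_its_type(self, rng, method):
        # gene 0 is 8 log2 units higher in grp0 than everywhere else
        means = np.full((30, 3), 5.0)
        means[0, 0] = 13.0
        means[1, 1] = 9.0  # a weaker marker of grp1
        ref, labels = _panel(rng, means)
        cfg = SignatureBuildConfig(de_method=method)
        markers = rank_marker_genes(ref, labels, cfg)
        assert markers.tables["grp0"].iloc[0]["gene"] == "g0"
        assert markers.tables["grp0"].iloc[0]["log2_fc"] == pytest.approx(8.0, abs=0.3)
        # cross-check with an independent plain two-sample t per gene
        in_g = (labels.reindex(ref.sample_ids) == "grp0").to_numpy()
        values = ref.data.to_numpy()
        p = np.array(
            [
                stats.ttest_ind(values[i, in_g], values[i, ~in_g]).pvalue
                for i in range(len(values))
            ]
        )
        adj = multipletests(p, method="fdr_bh")[1]
        lfc = values[:, in_g].mean(axis=1) - values[:, ~in_g].mean(axis=1)
        oracle = {ref.gene_ids[i] for i in range(len(p)) if adj[i] < 0.05 and lfc[i] > 0}
        assert "g0" in oracle
        assert set(markers.tables["grp0"]["gene"]) <= set(ref.gene_ids)
        if method == "ttest":
            assert set(markers.tables["grp0"]["gene"]) == oracle

    def test_constant_gene_is_never_a_marker(self, rng):
        means = np.full((10, 3), 5.0)
        means[2, 2] = 11.0
        ref, labels = _panel(rng, means, sd=0.0)
        markers = rank_marker_genes(ref, labels)
        for table in markers.tables.values():
            assert "g0" not in set(table["gene"])  # constant everywhere

    def test_markers_ordered_by_decreasing_fold_change(self, rng):
        means = np.full((20, 3), 5.0)
        means[0, 0] = 10.0  # fc 5
        means[1, 0] = 8.0  # fc 3
        ref, labels = _panel(rng, means, sd=0.05)
        markers = rank_marker_genes(ref, labels)
        genes = markers.tables["grp0"]["gene"].tolist()
        assert genes[:2] == ["g0", "g1"]
        fc = markers.tables["grp0"]["log2_fc"].to_numpy()
        assert (np.diff(fc) <= 1e-12).all()

    def test_small_group_is_an_error(self, rng):
        means = np.full((5, 2), 5.0)
        ref, labels = _panel(rng, means, n_per_group=2)
        labels = labels.copy()
        labels[labels.index[0]] = "grp1"  # leaves grp0 with one sample
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_marker_genes(ref, labels)

    def test_down_regulated_genes_excluded(self, rng):
        means = np.full((10, 2), 8.0)
        means[0, 0] = 2.0  # strongly DOWN in grp0
        ref, labels = _panel(rng, means)
        markers = rank_marker_genes(ref, labels)
        assert "g0" not in set(markers.tables["grp0"]["gene"])
        assert "g0" in set(markers.tables["grp1"]["gene"])


class TestEnrichmentScores:
    def _brute_force_es(self, panel, labels, groups):
        """Independent oracle: per-pair per-gene OLS fits via statsmodels."""
        import statsmodels.api as sm

        values = panel.data.to_numpy()
        es = {g: np.zeros(len(values)) for g in groups}
        for g in groups:
            for h in groups:
                if h == g:
                    continue
                mask = labels.isin([g, h]).to_numpy()
                x = sm.add_constant((labels[mask] == g).astype(float).to_numpy())
                coefs, pvals = [], []
                for i in range(len(values)):
                    fit = sm.OLS(values[i, mask], x).fit()
                    coefs.append(fit.params[1])
                    pvals.append(fit.pvalues[1])
                q = multipletests(pvals, method="fdr_bh")[1]
                sig = q < 0.05
                es[g][sig] += np.asarray(coefs)[sig]
        return es

    def test_matches_brute_force_pairwise_fits(self, rng):
        means = np.full((25, 3), 6.0)
        means[0, 0] = 12.0  # high only in grp0
        means[3, 1] = 10.0
        means[4, :] = 6.0  # flat
        panel, labels = _panel(rng, means)
        labels = labels.reindex(panel.sample_ids)
        es = compute_enrichment_scores(panel, labels, hematopoietic_groups={"grp0"})
        oracle = self._brute_force_es(panel, labels, ["grp0", "grp1", "grp2"])
        for g in oracle:
            np.testing.assert_allclose(es.scores[g].to_numpy(), oracle[g], atol=1e-10)
        assert es.scores.loc["g0", "grp0"] > 0
        # two significant pairwise coefficients of ~6 each
        assert es.scores.loc["g0", "grp0"] == pytest.approx(12.0, abs=1.0)

    def test_flat_gene_scores_zero_everywhere(self, rng):
        means = np.full((30, 3), 6.0)
        means[5, 1] = 11.0  # one real signal so BH has structure
        panel, labels = _panel(rng, means)
        es = compute_enrichment_scores(panel, labels, hematopoietic_groups=set())
        assert (es.scores.loc["g0"] == 0).all()

    def test_single_group_is_an_error(self, rng):
        means = np.full((5, 1), 6.0)
        panel, labels = _panel(rng, means)
        with pytest.raises(ValueError, match="2 tissue groups"):
            compute_enrichment_scores(panel, labels, hematopoietic_groups=set())


class TestHematopoieticFilter:
    def _table(self, scores, hemato):
        return EnrichmentScoreTable(
            scores=pd.DataFrame(scores).T.rename_axis("gene"),
            hematopoietic=hemato,
        )

    def test_immune_only_gene_kept(self):
        es = self._table(
            {"g1": {"blood": 5.0, "liver": 0.0}},
            {"blood": True, "liver": False},
        )
        assert hematopoietic_gene_set(es) == {"g1"}

    def test_fraction_just_above_threshold_removed(self):
        es = self._table(
            {"ok": {"blood": 95.0, "liver": 5.0}, "bad": {"blood": 94.0, "liver": 6.0}},
            {"blood": True, "liver": False},
        )
        assert hematopoietic_gene_set(es) == {"ok"}

    def test_all_zero_es_gene_excluded(self):
        es = self._table(
            {"g1": {"blood": 0.0, "liver": 0.0}}, {"blood": True, "liver": False}
        )
        assert hematopoietic_gene_set(es) == set()

    def test_matches_brute_force_fraction_computation(self, rng):
        genes = [f"g{i}" for i in range(40)]
        groups = ["blood", "thymus", "liver", "brain"]
        hemato = {"blood": True, "thymus": True, "liver": False, "brain": False}
        scores = pd.DataFrame(
            rng.normal(0, 3, size=(40, 4)), index=genes, columns=groups
        )
        es = EnrichmentScoreTable(scores=scores, hematopoietic=hemato)
        kept = hematopoietic_gene_set(es)
        for g in genes:
            pos = scores.loc[g].clip(lower=0)
            if pos.sum() <= 0:
                assert g not in kept
                continue
            frac = (pos["liver"] + pos["brain"]) / pos.sum()
            assert (g in kept) == (frac <= 0.05)


class TestTumorFilter:
    def _tumor_panel(self, means):
        data = pd.DataFrame(
            {f"t{j}": means for j in range(3)},
            index=[f"g{i}" for i in range(len(means))],
        )
        return ExpressionMatrix(data, scale="log2")

    def test_threshold_behaviour(self):
        panel = self._tumor_panel([7.5, 6.9, 7.0])
        kept = filter_tumor_expressed({"g0", "g1", "g2"}, panel)
        # mean > 7 removed; exactly 7 kept (strict inequality)
        assert kept == {"g1", "g2"}

    def test_absent_candidate_kept(self):
        panel = self._tumor_panel([8.0])
        assert filter_tumor_expressed({"g0", "missing"}, panel) == {"missing"}

    def test_matches_brute_force_scan(self, rng):
        means = rng.uniform(4, 10, size=25)
        panel = self._tumor_panel(means)
        candidates = {f"g{i}" for i in range(25)}
        kept = filter_tumor_expressed(candidates, panel)
        oracle = {f"g{i}" for i in range(25) if means[i] <= 7.0}
        assert kept == oracle


def _marker_table(lists):
    tables = {}
    for cell_type, genes in lists.items():
        tables[cell_type] = pd.DataFrame(
            {
                "gene": genes,
                "log2_fc": np.linspace(8, 2, len(genes)),
                "adj_p": np.full(len(genes), 1e-4),
            }
        )
    return RankedMarkerTable(tables)


class TestAssembleAndOptimize:
    def _ref(self, rng, genes, types, elevated):
        cols, labels = {}, {}
        for c, t in enumerate(types):
            for r in range(3):
                name = f"{t}_r{r}"
                v = np.full(len(genes), 10.0)
                for g in elevated.get(t, []):
                    v[genes.index(g)] = 200.0
                cols[name] = v * np.exp(rng.normal(0, 0.05, len(genes)))
                labels[name] = t
        ref = ExpressionMatrix(pd.DataFrame(cols, index=genes), scale="linear")
        return ref, pd.Series(labels)

    def test_disjoint_top1_lists_give_one_gene_per_type(self, rng):
        genes = [f"g{i}" for i in range(9)]
        types = ["a", "b", "c"]
        lists = {"a": genes[0:3], "b": genes[3:6], "c": genes[6:9]}
        ref, labels = self._ref(rng, genes, types, lists)
        sig = assemble_signature(_marker_table(lists), 1, ref, labels)
        assert list(sig.gene_ids) == ["g0", "g3", "g6"]

    def test_shared_top_gene_enters_once(self, rng):
        genes = [f"g{i}" for i in range(6)]
        lists = {"a": ["g0", "g1"], "b": ["g0", "g2"], "c": ["g3", "g4"]}
        ref, labels = self._ref(rng, genes, ["a", "b", "c"], lists)
        sig = assemble_signature(_marker_table(lists), 1, ref, labels)
        assert list(sig.gene_ids) == ["g0", "g3"]

    def test_union_matches_set_oracle_and_is_monotone_in_n(self, rng):
        genes = [f"g{i}" for i in range(30)]
        lists = {
            "a": [genes[i] for i in rng.choice(30, 8, replace=False)],
            "b": [genes[i] for i in rng.choice(30, 8, replace=False)],
            "c": [genes[i] for i in rng.choice(30, 8, replace=False)],
        }
        ref, labels = self._ref(rng, genes, ["a", "b", "c"], lists)
        table = _marker_table(lists)
        prev = set()
        for n in range(1, 9):
            sig = assemble_signature(table, n, ref, labels)
            union = set(sig.gene_ids)
            oracle = set().union(*(set(lists[t][:n]) for t in lists))
            assert union == oracle
            assert prev <= union
            prev = union

    def test_matrix_entries_are_per_type_linear_means(self, rng):
        genes = [f"g{i}" for i in range(6)]
        lists = {"a": ["g0", "g1"], "b": ["g2", "g3"], "c": ["g4", "g5"]}
        ref, labels = self._ref(rng, genes, ["a", "b", "c"], lists)
        sig = assemble_signature(_marker_table(lists), 2, ref, labels)
        mask = (labels.reindex(ref.sample_ids) == "a").to_numpy()
        expected = ref.data.loc["g0", mask].mean()
        assert sig.data.loc["g0", "a"] == pytest.approx(expected)

    def test_singleton_range_returns_that_n(self, rng):
        genes = [f"g{i}" for i in range(30)]
        lists = {
            "a": genes[0:10],
            "b": genes[10:20],
            "c": genes[20:30],
        }
        ref, labels = self._ref(rng, genes, ["a", "b", "c"], lists)
        cfg = SignatureBuildConfig(n_range=range(5, 6))
        best_n, sig, profile = optimize_signature(_marker_table(lists), ref, labels, cfg)
        assert best_n == 5
        assert len(profile) == 1
        assert len(sig.gene_ids) == 15

    def test_optimizer_matches_exhaustive_scan(self, rng):
        genes = [f"g{i}" for i in range(30)]
        lists = {"a": genes[0:10], "b": genes[10:20], "c": genes[20:30]}
        ref, labels = self._ref(rng, genes, ["a", "b", "c"], lists)
        table = _marker_table(lists)
        cfg = SignatureBuildConfig(n_range=range(2, 11))
        best_n, sig, profile = optimize_signature(table, ref, labels, cfg)
        # exhaustive oracle over the same range
        conds = {
            n: assemble_signature(table, n, ref, labels).condition_number
            for n in range(2, 11)
        }
        oracle_n = min(conds, key=lambda n: (conds[n], n))
        assert best_n == oracle_n
        assert sig.condition_number == pytest.approx(conds[oracle_n])
        assert len(profile) == len(conds)
        assert set(profile["n"]) == set(conds)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SignatureBuildConfig(n_range=range(0))
        with pytest.raises(ValueError):
            SignatureBuildConfig(significance=1.5)
        with pytest.raises(ValueError):
            SignatureBuildConfig(de_method="anova")
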