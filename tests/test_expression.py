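"""DEG thresholds, PCA on log counts, loading selection, DEG-mark crosstab."""

import numpy as np
import pandas as pd
import pytest

from diffmark.expression import (call_degs, crosstab_deg_mark, pca_counts,
                                 select_high_loading_genes, separating_component)
from diffmark.simulate import simulate_counts_matrix


def deg_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2FC", "FDR"])


class TestCallDegs:
    def test_passing_gene_is_up_deg(self):
        out = call_degs(deg_table([("g1", 1.5, 0.005)]))
        assert len(out) == 1 and out.iloc[0]["direction"] == "up"

    @pytest.mark.parametrize("log2fc,fdr", [(1.0, 0.005),   # |log2FC| boundary: strict
                                            (-2.0, 0.02),   # FDR fails
                                            (0.5, 0.001),   # effect too small
                                            (3.0, 0.01)])   # FDR boundary: strict
    def test_boundary_and_failing_genes_excluded(self, log2fc, fdr):
        assert len(call_degs(deg_table([("g1", log2fc, fdr)]))) == 0

    def test_down_direction_from_sign(self):
        out = call_degs(deg_table([("g1", -1.5, 0.001)]))
        assert out.iloc[0]["direction"] == "down"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            call_degs(pd.DataFrame({"gene_id": ["g1"], "log2FC": [2.0]}))

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            call_degs(deg_table([("g1", 2.0, 0.001), ("g1", 2.0, 0.001)]))

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(4)
        table = deg_table([(f"g{i}", lf, fd) for i, (lf, fd) in enumerate(
            zip(rng.normal(0, 2, 300), rng.uniform(0, 1, 300)))])
        counts_by_lfc = [len(call_degs(table, min_abs_log2fc=t))
                         for t in (0.5, 1.0, 1.5, 2.0)]
        assert counts_by_lfc == sorted(counts_by_lfc, reverse=True)
        counts_by_fdr = [len(call_degs(table, fdr_max=t))
                         for t in (0.001, 0.01, 0.1, 0.5)]
        assert counts_by_fdr == sorted(counts_by_fdr)


class TestPCA:
    def test_identical_samples_zero_scores(self):
        counts = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2]},
                              index=["g1", "g2", "g3"])
        pca = pca_counts(counts)
        np.testing.assert_allclose(pca.scores.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(pca.variance_explained, 0.0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        """Scores/loadings agree with a brute-force eigensolver on the covariance."""
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 500, size=(6, 5)).astype(float),
                              index=[f"g{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(5)])
        pca = pca_counts(counts)
        x = np.log(counts.to_numpy().T + 1.0)
        xc = x - x.mean(axis=0, keepdims=True)
        cov = xc.T @ xc / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = min(x.shape) - 1  # components with non-trivial variance
        np.testing.assert_allclose(pca.variance_explained[:k], evals[:k], atol=1e-8)
        for j in range(k):
            a = pca.loadings.iloc[:, j].to_numpy()
            b = evecs[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
            s = pca.scores.iloc[:, j].to_numpy()
            proj = xc @ a
            np.testing.assert_allclose(s, proj, atol=1e-8)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 300, size=(8, 6)).astype(float))
        pca = pca_counts(counts)
        x = np.log(counts.to_numpy().T + 1.0)
        xc = x - x.mean(axis=0, keepdims=True)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, xc, atol=1e-8)

    def test_loadings_orthonormal_variance_nonincreasing(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 300, size=(10, 7)).astype(float))
        pca = pca_counts(counts)
        l = pca.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-10)
        assert np.all(np.diff(pca.variance_explained) <= 1e-10)

    def test_sample_reordering_leaves_loadings_invariant(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 300, size=(6, 5)).astype(float),
                              columns=[f"s{i}" for i in range(5)])
        pca1 = pca_counts(counts)
        shuffled = counts[["s3", "s0", "s4", "s1", "s2"]]
        pca2 = pca_counts(shuffled)
        k = 4  # components with non-zero variance; the null-space one is arbitrary
        np.testing.assert_allclose(pca1.loadings.to_numpy()[:, :k],
                                   pca2.loadings.to_numpy()[:, :k], atol=1e-8)
        np.testing.assert_allclose(
            pca1.scores.loc[["s3", "s0", "s4", "s1", "s2"]].to_numpy()[:, :k],
            pca2.scores.to_numpy()[:, :k], atol=1e-8)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_counts(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestLoadingSelection:
    def _pca_with_loadings(self, loadings):
        loadings = np.asarray(loadings, dtype=float)
        pca = pca_counts(pd.DataFrame(np.ones((len(loadings), 2)) + 1.0))
        pca.loadings = pd.DataFrame({"PC1": loadings},
                                    index=[f"g{i}" for i in range(len(loadings))])
        pca.gene_ids = list(pca.loadings.index)
        return pca

    def test_single_high_loading_gene_selected(self):
        # loadings (1, 0 x9): mean 0.1, sample SD sqrt(0.1) ~ 0.3162, 3SD ~ 0.9487
        pca = self._pca_with_loadings([1.0] + [0.0] * 9)
        assert select_high_loading_genes(pca, "PC1") == {"g0"}

    def test_all_zero_loadings_empty_with_warning(self):
        pca = self._pca_with_loadings([0.0] * 5)
        with pytest.warns(UserWarning, match="zero loading SD"):
            assert select_high_loading_genes(pca, "PC1") == set()

    def test_equal_nonzero_loadings_degenerate_empty(self):
        pca = self._pca_with_loadings([0.4] * 5)
        with pytest.warns(UserWarning):
            assert select_high_loading_genes(pca, "PC1") == set()

    def test_sign_symmetric_selection(self):
        pca = self._pca_with_loadings([-1.0] + [0.0] * 9)
        assert select_high_loading_genes(pca, "PC1") == {"g0"}

    def test_unknown_component_rejected(self):
        pca = self._pca_with_loadings([1.0, 0.0, 0.0])
        with pytest.raises(KeyError):
            select_high_loading_genes(pca, "PC9")


class TestSimulatedRecovery:
    def test_perturbed_genotype_separates_and_de_genes_selected(self, sim_config, toy):
        """>= 80% of planted DE genes sit in the 3xSD selection of the
        component separating the perturbed genotype."""
        counts, de = simulate_counts_matrix(sim_config, toy.truth)
        pca = pca_counts(counts)
        groups = {s: s.rsplit("_rna_r", 1)[0] for s in pca.sample_ids}
        comp = separating_component(pca, groups, sim_config.de_genotype)
        scores = pca.scores[comp]
        mut = [s for s, g in groups.items() if g == sim_config.de_genotype]
        rest = [s for s, g in groups.items() if g != sim_config.de_genotype]
        gap = abs(scores[mut].mean() - scores[rest].mean())
        spread = max(scores[mut].std(), scores[rest].std())
        assert gap > 2 * spread  # clear genotype separation on the component
        selected = select_high_loading_genes(pca, comp)
        assert len(selected & set(de)) / len(de) >= 0.8


class TestCrosstab:
    def test_planted_loss_up_construction(self):
        """When loss-mark genes are exactly the up-DEGs, that cell holds all
        DEGs and is strongly enriched."""
        universe = [f"g{i}" for i in range(50)]
        marks = pd.Series("unchanged", index=universe)
        marks.iloc[:10] = "loss"
        degs = call_degs(deg_table([(g, 2.0, 1e-6) for g in universe[:10]]))
        out = crosstab_deg_mark(degs, marks)
        cell = out[(out["direction"] == "up") & (out["mark_call"] == "loss")].iloc[0]
        assert cell["overlap"] == 10 == len(degs)
        assert cell["p_adjusted"] < 0.01
        assert out["overlap"].sum() == len(degs)

    def test_zero_degs_all_cells_empty(self):
        marks = pd.Series("gain", index=["g1", "g2"])
        out = crosstab_deg_mark(call_degs(deg_table([("g1", 0.1, 0.9)])), marks)
        assert (out["overlap"] == 0).all()

    def test_counts_sum_to_degs_with_mark_info(self):
        universe = [f"g{i}" for i in range(30)]
        marks = pd.Series(["gain", "loss", "unchanged"] * 10, index=universe)
        rows = [(g, 3.0, 1e-9) for g in universe[:5]]
        rows += [("outside_universe", 3.0, 1e-9)]
        out = crosstab_deg_mark(call_degs(deg_table(rows)), marks)
        assert out["overlap"].sum() == 5  # the gene without mark info is excluded

    def test_independent_labels_fold_enrichment_near_one(self):
        rng = np.random.default_rng(77)
        universe = [f"g{i}" for i in range(60)]
        values = []
        for _ in range(500):
            marks = pd.Series(rng.choice(["gain", "loss", "unchanged"], 60),
                              index=universe)
            chosen = rng.choice(universe, 12, replace=False)
            degs = call_degs(deg_table(
                [(g, float(rng.choice([-2.0, 2.0])), 1e-6) for g in chosen]))
            out = crosstab_deg_mark(degs, marks)
            sub = out[(out["n_deg"] > 0) & (out["n_mark"] > 0)]
            values.extend(sub["fold_enrichment"].tolist())
        assert np.nanmean(values) == pytest.approx(1.0, abs=0.1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            crosstab_deg_mark(call_degs(deg_table([])), pd.Series(dtype=object))
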