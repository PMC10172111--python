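import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import pulsekinetics as pk
from pulsekinetics import analysis as an


def _toy_pm(seed=0, n=30):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, 4)),
        index=[f"G{i}" for i in range(n)],
        columns=["alpha", "beta", "lam", "gamma"],
    )


class TestZscore:
    def test_columns_standardized(self):
        z = an.zscore_parameters(_toy_pm())
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_rows_with_missing_dropped_with_warning(self):
        pm = _toy_pm()
        pm.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="dropping 1"):
            z = an.zscore_parameters(pm)
        assert len(z) == len(pm) - 1


class TestParameterCorrelation:
    def test_self_and_negation(self):
        pm = _toy_pm()
        pm["neg"] = -pm["alpha"]
        corr = an.pairwise_parameter_correlation(pm)
        assert corr.loc["alpha", "alpha"] == pytest.approx(1.0)
        assert corr.loc["alpha", "neg"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)

    def test_hand_covariance_oracle_five_genes(self):
        # textbook Pearson r computed by hand on a 5-gene table
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        pm = pd.DataFrame({"a": x, "b": y})
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        corr = an.pairwise_parameter_correlation(pm)
        assert corr.loc["a", "b"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_column_warns_nan(self):
        pm = _toy_pm()
        pm["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = an.pairwise_parameter_correlation(pm)
        assert np.isnan(corr.loc["flat", "flat"])

    def test_positive_semidefinite(self):
        corr = an.pairwise_parameter_correlation(_toy_pm(seed=3))
        eigs = np.linalg.eigvalsh(corr.values)
        assert eigs.min() > -1e-10


class TestClusterKinetics:
    def test_two_blob_recovery_across_seeds(self):
        pm, blobs = pk.synth.make_blob_parameters(seed=0)
        for seed in range(10):
            labels = an.cluster_kinetics(pm, k_neighbors=20, seed=seed)
            assert labels.nunique() == 2
            # agreement up to label permutation
            tab = pd.crosstab(labels, blobs)
            agree = tab.max(axis=1).sum() / len(labels)
            assert agree >= 0.99

    def test_identical_rows_single_cluster(self):
        pm = pd.DataFrame(np.ones((30, 4)), index=[f"G{i}" for i in range(30)])
        labels = an.cluster_kinetics(pm, k_neighbors=5, seed=0, zscore=False)
        assert labels.nunique() == 1

    def test_partition_invariant_to_gene_order(self):
        pm, _ = pk.synth.make_blob_parameters(seed=1)
        l1 = an.cluster_kinetics(pm, k_neighbors=10, seed=0)
        perm = pm.sample(frac=1.0, random_state=4)
        l2 = an.cluster_kinetics(perm, k_neighbors=10, seed=0)
        # same partition: co-membership must agree for every pair
        joined = pd.DataFrame({"a": l1, "b": l2.reindex(l1.index)})
        for series in ("a", "b"):
            assert joined[series].notna().all()
        same_a = joined["a"].to_numpy()[:, None] == joined["a"].to_numpy()[None, :]
        same_b = joined["b"].to_numpy()[:, None] == joined["b"].to_numpy()[None, :]
        assert (same_a == same_b).all()

    def test_k_too_large_raises(self):
        pm = _toy_pm(n=10)
        with pytest.raises(ValueError, match="k_neighbors"):
            an.cluster_kinetics(pm, k_neighbors=10)


class TestCovariation:
    @staticmethod
    def _correlated_expr(seed=0, n_cells=200, shared=True):
        rng = np.random.default_rng(seed)
        out = {}
        for t in (0.0, 2.0, 4.0, 6.0):
            factor = rng.gamma(4.0, 0.5, size=n_cells)
            rows = {}
            for g in ("A", "B"):
                lam = 5.0 * factor if shared else rng.gamma(4.0, 0.5, size=n_cells) * 5
                rows[g] = rng.poisson(lam)
            for i in range(8):
                rows[f"BG{i}"] = rng.poisson(5.0, size=n_cells)
            out[t] = pd.DataFrame(rows).T
        return out

    def test_shared_factor_genes_correlate(self):
        combined, _ = an.covariation_over_time(self._correlated_expr(shared=True))
        assert combined.loc["A", "B"] > 0.5

    def test_independent_genes_do_not(self):
        expr = self._correlated_expr(seed=1, n_cells=500, shared=False)
        combined, _ = an.covariation_over_time(expr)
        off = combined.values[~np.eye(len(combined), dtype=bool)]
        assert np.nanmean(np.abs(off)) < 0.1

    def test_per_timepoint_matrices_share_ordering(self):
        combined, per_tp = an.covariation_over_time(self._correlated_expr())
        for mat in per_tp.values():
            assert list(mat.index) == list(combined.index)
            assert list(mat.columns) == list(combined.columns)

    def test_symmetric_unit_diagonal(self):
        combined, _ = an.covariation_over_time(self._correlated_expr(seed=2))
        np.testing.assert_allclose(combined.values, combined.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(combined.values), 1.0, atol=1e-12)


class TestNucleocytoplasmicMatrix:
    @staticmethod
    def _cm():
        genes = ["A", "B"]
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "timepoint_h": 0.0, "volume_voxels": 10,
             "phase": [None, None], "batch": 0}
        )
        counts = {
            "nucleus": sparse.csr_matrix(np.array([[3, 0], [1, 2]])),
            "middle": sparse.csr_matrix(np.array([[0, 1], [0, 0]])),
            "periphery": sparse.csr_matrix(np.array([[0, 1], [0, 3]])),
        }
        return pk.CompartmentMatrix(genes=genes, cells=cells, counts=counts)

    def test_shape_and_row_sums(self):
        cm = self._cm()
        nc = an.build_nucleocytoplasmic_matrix(cm)
        assert nc.shape == (2, 4)
        totals = np.asarray(cm.total.todense()).sum(axis=0)
        np.testing.assert_allclose(nc.sum(axis=1).to_numpy(), totals)

    def test_fully_nuclear_gene_has_zero_cyto(self):
        nc = an.build_nucleocytoplasmic_matrix(self._cm())
        assert nc.loc[0, "A_cyto"] == 0  # cell 0: gene A entirely nuclear


class TestCompareGeneGroups:
    @staticmethod
    def _est(values_a, values_b):
        genes_a = [f"A{i}" for i in range(len(values_a))]
        genes_b = [f"B{i}" for i in range(len(values_b))]
        est = pd.DataFrame(
            {
                "gene": genes_a + genes_b,
                "phase": "all",
                "qc_pass": True,
                "beta": list(values_a) + list(values_b),
            }
        )
        labels = {g: "m6a" for g in genes_a} | {g: "non_m6a" for g in genes_b}
        return est, labels

    def test_exact_enumeration_example(self):
        # C(6,3)=20 equally likely rank splits; {1,2,3} vs {4,5,6} is one
        # of the two extremes -> two-sided p = 2/20 = 0.1
        est, labels = self._est([1, 2, 3], [4, 5, 6])
        res = an.compare_gene_groups(est, labels, "beta")
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_label_swap_symmetry(self):
        est, labels = self._est([1, 5, 3], [4, 2, 6])
        res1 = an.compare_gene_groups(est, labels, "beta")
        flipped = {g: ("non_m6a" if v == "m6a" else "m6a") for g, v in labels.items()}
        res2 = an.compare_gene_groups(est, flipped, "beta")
        assert res1["p_value"] == pytest.approx(res2["p_value"], abs=1e-12)

    def test_empty_group_raises(self):
        est, labels = self._est([1, 2, 3], [4, 5, 6])
        labels = {g: "m6a" for g in labels}
        with pytest.raises(ValueError, match="empty group"):
            an.compare_gene_groups(est, labels, "beta")


class TestPivotPhaseParameters:
    def test_twelve_columns_for_three_phases(self):
        rows = []
        for g in ("G1", "G2", "G3"):
            for ph in ("G1", "G1/S", "G2/M"):
                rows.append(
                    {"gene": g, "phase": ph, "alpha": 1.0, "beta": 0.5, "lam": 0.1,
                     "gamma": 0.01, "qc_pass": True}
                )
        wide = an.pivot_phase_parameters(pd.DataFrame(rows))
        assert wide.shape == (3, 12)
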