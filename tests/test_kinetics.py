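import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import pulsekinetics as pk
from pulsekinetics import kinetics as kin


def _two_timepoint_matrix():
    """2 genes (REF + A), 2 cells per timepoint, reference means 10 and 5."""
    genes = ["REF", "A"]
    cells = pd.DataFrame(
        {
            "cell_id": [1, 2, 1, 2],
            "timepoint_h": [0.0, 0.0, 2.0, 2.0],
            "volume_voxels": [100, 100, 100, 100],
            "phase": [None] * 4,
            "batch": 0,
        }
    )
    nucleus = np.array([[10, 10, 5, 5], [2, 2, 4, 4]])
    zeros = np.zeros_like(nucleus)
    counts = {
        "nucleus": sparse.csr_matrix(nucleus),
        "middle": sparse.csr_matrix(zeros),
        "periphery": sparse.csr_matrix(zeros),
    }
    return pk.CompartmentMatrix(genes=genes, cells=cells, counts=counts)


class TestNormalizeCounts:
    def test_hand_computed_scales(self):
        # reference means (10, 5), grand mean 7.5 -> scales (0.75, 1.5);
        # a count of 4 at t=2 becomes 6
        cm = _two_timepoint_matrix()
        out = kin.normalize_counts(cm, ["REF"])
        a = np.asarray(out.counts["nucleus"].todense())[1]
        np.testing.assert_allclose(a, [1.5, 1.5, 6.0, 6.0])

    def test_reference_means_equal_after(self):
        cm = _two_timepoint_matrix()
        out = kin.normalize_counts(cm, ["REF"])
        ref = np.asarray(out.total.todense())[0]
        m0 = ref[:2].mean()
        m2 = ref[2:].mean()
        assert abs(m0 - m2) < 1e-9

    def test_idempotent(self):
        cm = _two_timepoint_matrix()
        once = kin.normalize_counts(cm, ["REF"])
        twice = kin.normalize_counts(once, ["REF"])
        for comp in pk.COMPARTMENTS:
            np.testing.assert_allclose(
                np.asarray(once.counts[comp].todense()),
                np.asarray(twice.counts[comp].todense()),
                atol=1e-12,
            )

    def test_identity_when_means_equal(self):
        cm = _two_timepoint_matrix()
        m = np.array([[7, 7, 7, 7], [2, 2, 4, 4]])
        cm.counts["nucleus"] = sparse.csr_matrix(m)
        out = kin.normalize_counts(cm, ["REF"])
        np.testing.assert_allclose(np.asarray(out.counts["nucleus"].todense()), m)

    def test_zero_reference_signal_raises(self):
        cm = _two_timepoint_matrix()
        m = np.asarray(cm.counts["nucleus"].todense())
        m[0, 2:] = 0
        cm.counts["nucleus"] = sparse.csr_matrix(m)
        with pytest.raises(ValueError, match="zero reference"):
            kin.normalize_counts(cm, ["REF"])

    def test_missing_reference_gene_raises(self):
        with pytest.raises(ValueError, match="no reference genes"):
            kin.normalize_counts(_two_timepoint_matrix(), ["NOPE"])


class TestToConcentration:
    def test_division_by_volume(self):
        cm = _two_timepoint_matrix()
        conc = kin.to_concentration(cm)
        assert conc.loc["REF"].iloc[0] == pytest.approx(10 / 100)

    def test_doubling_volume_halves_concentration(self):
        cm = _two_timepoint_matrix()
        c1 = kin.to_concentration(cm)
        c2 = kin.to_concentration(cm, volumes=2 * cm.cells["volume_voxels"].to_numpy())
        np.testing.assert_allclose(c2.to_numpy(), c1.to_numpy() / 2)

    def test_zero_volume_raises(self):
        cm = _two_timepoint_matrix()
        with pytest.raises(ValueError, match="positive"):
            kin.to_concentration(cm, volumes=np.zeros(4))


class TestFitBeta:
    def test_exact_exponential(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        X = 2 * np.exp(-0.5 * t)
        beta, r2 = kin.fit_beta(t, X)
        assert beta == pytest.approx(0.5, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_flat(self):
        beta, r2 = kin.fit_beta([0, 2, 4, 6], [1.0, 1.0, 1.0, 1.0])
        assert beta == 0.0 and np.isnan(r2)

    def test_hand_ols_oracle(self):
        # independent closed-form OLS of ln X on t
        t = np.array([0.0, 2.0, 4.0, 6.0])
        X = np.array([1.0, 0.9, 0.5, 0.2])
        ln = np.log(X)
        slope = np.sum((t - t.mean()) * (ln - ln.mean())) / np.sum((t - t.mean()) ** 2)
        beta, _ = kin.fit_beta(t, X)
        assert beta == pytest.approx(-slope, abs=1e-12)

    def test_too_few_positive_points(self):
        beta, r2 = kin.fit_beta([0, 2, 4, 6], [1.0, 0.0, 0.0, 0.5])
        assert np.isnan(beta) and np.isnan(r2)

    def test_nls_mode_agrees_on_exact_data(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        X = 3 * np.exp(-0.3 * t)
        beta, r2 = kin.fit_beta(t, X, mode="nls")
        assert beta == pytest.approx(0.3, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)


class TestEstimateAlpha:
    def test_closed_form_inversion(self):
        # alpha = beta X0 / (1 - e^{-beta tau}) = 1/(1 - e^{-0.5})
        assert kin.estimate_alpha(2.0, 0.5, 1.0) == pytest.approx(2.5415, abs=1e-4)

    def test_zero_beta_limit(self):
        # L'Hopital: alpha -> X0/tau as beta -> 0
        assert kin.estimate_alpha(2.0, 1e-9, 1.0) == pytest.approx(2.0, rel=1e-6)
        assert kin.estimate_alpha(2.0, 0.0, 1.0) == 2.0

    def test_zero_initial_concentration(self):
        assert kin.estimate_alpha(0.0, 0.5, 1.0) == 0.0


class TestFitLambda:
    def test_exact_line(self):
        lam, f0, r2 = kin.fit_lambda([0, 2, 4, 6], [0.8, 0.6, 0.4, 0.2])
        assert lam == pytest.approx(0.1, abs=1e-12)
        assert f0 == pytest.approx(0.8, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_fraction(self):
        lam, _, _ = kin.fit_lambda([0, 2, 4, 6], [0.5] * 4)
        assert lam == 0.0

    def test_hand_ols_oracle(self):
        # sum (t-3)(y-0.6) / sum (t-3)^2 = -2.04/20
        lam, _, _ = kin.fit_lambda([0, 2, 4, 6], [0.9, 0.7, 0.52, 0.28])
        assert lam == pytest.approx(0.102, abs=1e-12)


class TestFitGamma:
    @pytest.mark.parametrize(
        "dr, expected",
        [
            ([0.30, 0.34, 0.38, 0.42], 0.02),
            ([0.50, 0.44, 0.38, 0.32], -0.03),  # inward translocation keeps sign
            ([0.4, 0.4, 0.4, 0.4], 0.0),
        ],
    )
    def test_known_slopes(self, dr, expected):
        gamma, _ = kin.fit_gamma([0, 2, 4, 6], dr)
        assert gamma == pytest.approx(expected, abs=1e-12)


class TestEstimateAll:
    def test_qc_gate_on_r2(self, small_matrix):
        cm, reads, design = small_matrix
        gs = pk.GeneSets(reference_genes=("REF00", "REF01"))
        norm = kin.normalize_counts(cm, gs.reference_genes)
        est = kin.estimate_all(norm, design, genesets=gs, reads=reads)
        assert set(est.columns) >= {
            "gene", "phase", "alpha", "beta", "lam", "gamma", "r2_beta", "qc_pass",
        }
        # the explicit QC rule: positives with r2 >= 0.5 pass
        good = est[(est.alpha > 0) & (est.beta > 0) & (est.r2_beta >= 0.5)]
        assert good["qc_pass"].all()
        bad = est[~((est.alpha > 0) & (est.beta > 0) & (est.r2_beta >= 0.5))]
        assert (~bad["qc_pass"]).all()

    def test_reference_genes_skipped(self, small_matrix):
        cm, reads, design = small_matrix
        gs = pk.GeneSets(reference_genes=("REF00", "REF01"))
        norm = kin.normalize_counts(cm, gs.reference_genes)
        est = kin.estimate_all(norm, design, genesets=gs, reads=reads)
        assert not set(est["gene"]) & set(gs.reference_genes)

    def test_phase_partition_bookkeeping(self, small_matrix):
        cm, reads, design = small_matrix
        gs = pk.GeneSets(reference_genes=("REF00", "REF01"))
        norm = kin.normalize_counts(cm, gs.reference_genes)
        rng = np.random.default_rng(0)
        phases = pd.Series(rng.choice(["G1", "G1/S", "G2/M"], size=len(cm.cells)))
        est = kin.estimate_all(norm, design, genesets=gs, reads=reads, phase_partition=phases)
        per_gene = est.groupby("gene")["phase"].nunique()
        assert (per_gene <= 4).all()  # 'all' + at most 3 phases
        assert set(est["phase"]) <= {"all", "G1", "G1/S", "G2/M"}

    def test_missing_phase_raises(self, small_matrix):
        cm, reads, design = small_matrix
        gs = pk.GeneSets(reference_genes=("REF00", "REF01"))
        phases = pd.Series([None] * len(cm.cells))
        with pytest.raises(ValueError, match="phase"):
            kin.estimate_all(cm, design, genesets=gs, reads=reads, phase_partition=phases)

    def test_exclusion_protects_beta_from_inflated_timepoint(
        self, small_geometry, small_fields
    ):
        # inject a residual-label artifact at the 1 h chase; excluding
        # that timepoint must shift beta less than including it does
        g = pk.synth.GeneTruth(gene="G", alpha=0.08, beta=0.4, lam=0.03, gamma=0.0)
        ref = pk.synth.GeneTruth(gene="R", alpha=0.02, beta=0.0, is_reference=True)
        cfg = pk.SimConfig(
            n_cells=4, genes=(g, ref), detection_efficiency=1.0, seed=13,
            chase_inflation={1.0: 2.0},
        )
        reads, _ = pk.synth.simulate_experiment(cfg, small_geometry, fields=small_fields)
        assigned = pk.subcellular.assign_and_partition(reads, small_geometry, fields=small_fields)
        gs = pk.GeneSets(reference_genes=("R",))
        betas = {}
        for excluded in (frozenset({1.0}), frozenset()):
            design = pk.PulseChaseDesign(excluded_chase_hours=excluded)
            cm = pk.subcellular.count_matrix(assigned, small_geometry, design=design)
            norm = kin.normalize_counts(cm, gs.reference_genes)
            est = kin.estimate_all(norm, design, genesets=gs, reads=assigned)
            betas[excluded] = float(est.set_index("gene").loc["G", "beta"])
        assert abs(betas[frozenset({1.0})] - 0.4) < abs(betas[frozenset()] - 0.4)
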