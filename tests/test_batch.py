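import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methex import InputError, SimulationConfig, generate_methylation_cohort
from methex.batch import (
    BatchANOVA,
    batch_purity_clustering,
    batch_vs_batch_dm_corruption,
    probe_batch_anova,
)


def _sheet(groups, batches, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(groups))]
    return pd.DataFrame(
        {"sample_id": ids, "group": groups, "batch": batches}
    ).set_index("sample_id")


class TestBatchANOVA:
    def test_equal_group_means_give_f_zero(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        est = BatchANOVA().fit(X, y)
        assert est.fstat_[0] == pytest.approx(0.0)
        assert est.pvalue_[0] == pytest.approx(1.0)

    def test_zero_within_variance_gives_p_zero(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        est = BatchANOVA().fit(X, y)
        assert np.isinf(est.fstat_[0])
        assert est.pvalue_[0] == 0.0

    def test_constant_probe_skipped(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.array(["a"] * 3 + ["b"] * 3)
        est = BatchANOVA().fit(X, y)
        assert not est.tested_[0] and est.tested_[1]
        assert est.n_skipped_ == 1

    def test_f_equals_t_squared_for_two_groups(self, rng):
        # algebraic identity against an independent pooled-variance t test
        X = rng.normal(size=(6, 40))
        y = np.array(["b1"] * 3 + ["b2"] * 3)
        est = BatchANOVA().fit(X, y)
        t, p = stats.ttest_ind(X[:3], X[3:], axis=0, equal_var=True)
        assert np.allclose(est.fstat_, t**2)
        assert np.allclose(est.pvalue_, p)

    def test_sample_order_permutation_invariant(self, rng):
        X = rng.normal(size=(9, 20))
        y = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        est = BatchANOVA().fit(X, y)
        perm = rng.permutation(9)
        est2 = BatchANOVA().fit(X[perm], y[perm])
        assert np.allclose(est.fstat_, est2.fstat_)
        assert np.allclose(est.qvalue_, est2.qvalue_)

    def test_single_sample_group_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "lonely"])
        with pytest.raises(InputError, match="lonely"):
            BatchANOVA().fit(X, y)

    def test_all_constant_matrix_rejected(self):
        X = np.ones((4, 3))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(InputError, match="constant"):
            BatchANOVA().fit(X, y)


class TestProbeBatchAnova:
    def test_susceptible_fraction_definition(self, small_cohort):
        beta, sheet, _ = small_cohort
        qc = probe_batch_anova(beta, sheet, fdr=0.05)
        tested = qc.table[qc.table["tested"]]
        assert qc.susceptible_fraction == pytest.approx(
            (tested["q"] < 0.05).mean()
        )
        assert (tested["q"] >= tested["p"] - 1e-12).all()

    def test_null_susceptibility_calibrated(self):
        # batch_sd = 0: batch labels carry no signal, so the fraction of
        # batch-susceptible probes stays near the FDR level on average
        fracs = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_probes=100, n_genes=100, n_pairs_per_batch=(6, 6),
                batch_sd=0.0, seed=seed,
            )
            beta, sheet, _ = generate_methylation_cohort(cfg)
            qc = probe_batch_anova(beta, sheet, fdr=0.05)
            fracs.append(qc.susceptible_fraction)
        mean = np.mean(fracs)
        mc = 1.96 * np.std(fracs) / np.sqrt(len(fracs))
        assert mean <= 0.05 + mc + 1e-9

    def test_laboratory_label_usable(self, small_cohort):
        beta, sheet, _ = small_cohort
        qc = probe_batch_anova(beta, sheet, label="laboratory")
        assert qc.label == "laboratory"

    def test_missing_label_column_rejected(self, small_cohort):
        beta, sheet, _ = small_cohort
        with pytest.raises(InputError, match="site"):
            probe_batch_anova(beta, sheet, label="site")


class TestPurityClustering:
    def test_dominant_batch_effect_clusters_by_batch(self):
        cfg = SimulationConfig(
            n_probes=150, n_genes=150, n_pairs_per_batch=(8, 8),
            batch_sd=2.0, noise_sd=0.1, seed=3,
        )
        beta, sheet, _ = generate_methylation_cohort(cfg)
        rep = batch_purity_clustering(beta, sheet)
        assert rep.perfect_split is True
        assert rep.agreement == pytest.approx(1.0)

    def test_no_batch_effect_agreement_near_zero(self):
        scores = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_probes=100, n_genes=100, n_pairs_per_batch=(6, 6),
                batch_sd=0.0, seed=seed,
            )
            beta, sheet, _ = generate_methylation_cohort(cfg)
            scores.append(batch_purity_clustering(beta, sheet).agreement)
        assert abs(np.mean(scores)) < 0.2

    def test_duplicated_samples_cannot_split(self):
        values = np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 6))
        beta = pd.DataFrame(values, index=[f"p{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        sheet = _sheet(["tumour"] * 6, ["b1", "b2"] * 3)
        rep = batch_purity_clustering(beta, sheet)
        assert rep.perfect_split is False

    def test_single_batch_not_applicable(self, rng):
        beta = pd.DataFrame(rng.random((10, 4)), columns=[f"s{i}" for i in range(4)])
        sheet = _sheet(["tumour"] * 4, ["b"] * 4)
        rep = batch_purity_clustering(beta, sheet)
        assert rep.perfect_split is None
        assert np.isnan(rep.agreement)


class TestDmCorruption:
    def _three_batch_cohort(self, offsets, frac_dm=0.0, seed=0):
        cfg = SimulationConfig(
            n_probes=300, n_genes=300, n_pairs_per_batch=(12, 12, 12),
            n_batches=3, frac_dm=frac_dm, batch_offsets=offsets, seed=seed,
        )
        return generate_methylation_cohort(cfg)

    def test_opposing_offsets_destroy_consistency(self):
        beta, sheet, _ = self._three_batch_cohort((0.8, -0.8, 0.0))
        normals = sheet[(sheet["group"] == "normal") & (sheet["batch"] == "batch2")]
        rep = batch_vs_batch_dm_corruption(
            beta, sheet, "batch0", "batch1", normal_samples=list(normals.index)
        )
        assert rep.k > 50
        assert rep.consistency < 0.5

    def test_same_batch_distribution_consistent(self):
        beta, sheet, _ = self._three_batch_cohort((0.5, 0.5, 0.0), frac_dm=0.2, seed=4)
        normals = sheet[(sheet["group"] == "normal") & (sheet["batch"] == "batch2")]
        rep = batch_vs_batch_dm_corruption(
            beta, sheet, "batch0", "batch1", normal_samples=list(normals.index)
        )
        assert rep.k > 0
        assert rep.consistency > 0.95

    def test_identical_batches_fully_consistent(self):
        beta, sheet, _ = self._three_batch_cohort((0.6, -0.6, 0.0), frac_dm=0.1, seed=5)
        normals = sheet[(sheet["group"] == "normal") & (sheet["batch"] == "batch2")]
        rep = batch_vs_batch_dm_corruption(
            beta, sheet, "batch0", "batch0", normal_samples=list(normals.index)
        )
        if rep.k:
            assert rep.consistency == 1.0

    def test_overlapping_sets_rejected(self, small_cohort):
        beta, sheet, _ = small_cohort
        tum = sheet[sheet["group"] == "tumour"].index[:3]
        with pytest.raises(InputError, match="disjoint"):
            batch_vs_batch_dm_corruption(
                beta, sheet, "batch0", "batch1", normal_samples=list(tum)
            )
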