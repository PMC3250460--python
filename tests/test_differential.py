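import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methex import (
    InputError,
    SAM,
    SimulationConfig,
    apply_effect_filters,
    dm_ttest,
    generate_expression_cohort,
    generate_methylation_cohort,
    sam_de,
)
from methex.differential import GroupTTest, benjamini_hochberg

from oracles import bh_stepup, sam_brute_force


class TestBenjaminiHochberg:
    def test_analytic_stepup(self):
        # four evenly spaced p values all collapse to the largest ratio
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_textbook_definition(self, pvals):
        assert np.allclose(benjamini_hochberg(pvals), bh_stepup(pvals))

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=30)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        p = np.asarray(pvals)
        q = benjamini_hochberg(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestGroupTTest:
    def test_identical_groups_not_significant(self):
        X = np.tile([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]], 1)
        y = np.array(["tumour", "tumour", "normal", "normal"])
        est = GroupTTest(positive_label="tumour").fit(X, y)
        assert np.allclose(est.pvalue_, 1.0)
        assert not est.significant_.any()
        assert (est.direction_ == "none").all()

    def test_direction_antisymmetric_under_label_swap(self, rng):
        X = rng.normal(size=(10, 25))
        y = np.array(["tumour"] * 5 + ["normal"] * 5)
        a = GroupTTest(positive_label="tumour").fit(X, y)
        b = GroupTTest(positive_label="normal").fit(X, y)
        assert np.allclose(a.effect_, -b.effect_)
        swap = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
        assert all(swap[d1] == d2 for d1, d2 in zip(a.direction_, b.direction_))
        assert np.allclose(a.pvalue_, b.pvalue_)

    def test_paired_beats_unpaired_with_patient_effects(self, rng):
        # strong per-patient baselines: the paired test removes them
        n = 12
        patient = rng.normal(0, 3, size=(n, 1))
        shift = 0.8
        X = np.vstack([patient + shift + rng.normal(0, 0.5, (n, 1)),
                       patient + rng.normal(0, 0.5, (n, 1))])
        y = np.array(["tumour"] * n + ["normal"] * n)
        pairs = np.concatenate([np.arange(n), np.arange(n)])
        paired = GroupTTest(paired=True, positive_label="tumour").fit(X, y, pairs=pairs)
        unpaired = GroupTTest(positive_label="tumour").fit(X, y)
        assert paired.pvalue_[0] < unpaired.pvalue_[0]

    def test_small_group_rejected(self):
        X = np.zeros((3, 4))
        y = np.array(["tumour", "normal", "normal"])
        with pytest.raises(InputError, match="2 samples"):
            GroupTTest().fit(X, y)

    def test_sklearn_params_round_trip(self):
        est = GroupTTest(alpha=0.01, paired=True)
        clone = GroupTTest(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestDmTtest:
    def test_recovers_true_dm(self):
        cfg = SimulationConfig(
            n_probes=500, n_genes=500, n_pairs_per_batch=(30,), n_batches=1,
            frac_dm=0.1, delta_beta_effect=0.3, seed=2,
        )
        beta, sheet, truth = generate_methylation_cohort(cfg)
        res = dm_ttest(beta, sheet, fdr=0.05, paired=True)
        called = res.index[res["significant"]]
        true_set = set(truth.probes.index[truth.probes["true_dm"]])
        recall = len(set(called) & true_set) / len(true_set)
        fdp = len(set(called) - true_set) / max(len(called), 1)
        assert recall >= 0.9
        assert fdp <= 0.10  # single realisation; the FDR average is checked below

    def test_direction_matches_truth_for_called_genes(self):
        cfg = SimulationConfig(
            n_probes=400, n_genes=400, n_pairs_per_batch=(25,), n_batches=1, seed=9
        )
        beta, sheet, truth = generate_methylation_cohort(cfg)
        res = dm_ttest(beta, sheet, fdr=0.05, paired=True)
        sig_true = res[res["significant"]].index.intersection(
            truth.probes.index[truth.probes["true_dm"]]
        )
        assert (
            res.loc[sig_true, "direction"] == truth.probes.loc[sig_true, "direction"]
        ).mean() > 0.99

    def test_null_fdr_controlled(self):
        # global null: empirical FDR stays at or below the nominal level
        fdps = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_probes=200, n_genes=200, n_pairs_per_batch=(10,), n_batches=1,
                frac_dm=0.0, batch_sd=0.0, seed=seed,
            )
            beta, sheet, _ = generate_methylation_cohort(cfg)
            res = dm_ttest(beta, sheet, fdr=0.05, paired=True)
            n_called = int(res["significant"].sum())
            fdps.append(1.0 if n_called else 0.0)
        mean_fdp = np.mean(fdps)
        mc = 1.96 * np.std(fdps) / np.sqrt(len(fdps))
        assert mean_fdp <= 0.05 + mc + 1e-9


class TestSAM:
    def test_matches_brute_force_on_enumerable_case(self, rng):
        X = rng.normal(size=(5, 8))
        X[:2, 0] += 4.0  # one strongly separated gene
        y = np.array(["tumour", "tumour", "normal", "normal", "normal"])
        est = SAM(fdr=0.1, n_permutations=100, s0=0.2, positive_label="tumour",
                  random_state=0).fit(X, y)
        d, called, delta = sam_brute_force(X, y, "tumour", s0=0.2, fdr=0.1)
        assert np.allclose(est.statistic_, d)
        assert est.n_permutations_used_ == 10  # C(5,2) enumerated
        assert np.array_equal(est.significant_, called)
        assert est.delta_ == pytest.approx(delta)

    def test_dominant_gene_called_with_correct_direction(self, rng):
        X = rng.normal(size=(12, 30))
        X[:6, 0] += 6.0
        y = np.array(["tumour"] * 6 + ["normal"] * 6)
        est = SAM(fdr=0.05, n_permutations=200, positive_label="tumour",
                  random_state=1).fit(X, y)
        assert est.significant_[0]
        assert est.direction_[0] == "up"

    def test_deterministic_given_seed(self, small_expression):
        expr, sheet = small_expression
        r1 = sam_de(expr, sheet, fdr=0.01, n_permutations=60, seed=4)
        r2 = sam_de(expr, sheet, fdr=0.01, n_permutations=60, seed=4)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_calibration(self):
        # no signal at all: significant calls are rare at FDR 0.01
        fdps = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_probes=200, n_genes=200, n_pairs_per_batch=(10,), n_batches=1,
                frac_dm=0.0, frac_de_background=0.0, batch_sd=0.0, seed=seed,
            )
            _, _, truth = generate_methylation_cohort(cfg)
            expr, esheet = generate_expression_cohort(cfg, truth)
            res = sam_de(expr, esheet, fdr=0.01, n_permutations=100, seed=seed)
            fdps.append(1.0 if res["significant"].any() else 0.0)
        mean_fdp = np.mean(fdps)
        mc = 1.96 * np.std(fdps) / np.sqrt(len(fdps))
        assert mean_fdp <= 0.01 + mc + 0.05  # small-replicate slack

    def test_recovers_true_de_directions(self, small_config, small_cohort, small_expression):
        _, _, truth = small_cohort
        expr, sheet = small_expression
        res = sam_de(expr, sheet, fdr=0.01, n_permutations=150, seed=3)
        called = res[res["significant"]]
        true_de = truth.genes[truth.genes["true_de"]]
        hits = called.index.intersection(true_de.index)
        assert len(hits) / len(true_de) > 0.8
        assert (res.loc[hits, "direction"] == true_de.loc[hits, "de_direction"]).all()


class TestEffectFilters:
    def _res(self, effects, kind="dm"):
        return pd.DataFrame(
            {
                "p": 0.01,
                "q": 0.01,
                "direction": ["hyper" if e > 0 else "hypo" for e in effects],
                "effect": effects,
                "significant": True,
            },
            index=[f"g{i}" for i in range(len(effects))],
        )

    def test_zero_threshold_is_identity(self):
        res = self._res([0.1, -0.2, 0.3])
        out = apply_effect_filters(res, min_abs_delta_beta=0.0)
        pd.testing.assert_frame_equal(out, res)

    def test_delta_beta_threshold_inclusive(self):
        res = self._res([0.10, 0.15, 0.30])
        out = apply_effect_filters(res, min_abs_delta_beta=0.15)
        assert len(out) == 2

    def test_fold_change_threshold_inclusive_on_log2(self):
        res = self._res([0.9, 1.0, 1.1])
        out = apply_effect_filters(res, min_fold_change=2.0)
        assert len(out) == 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(InputError, match="min_abs_delta_beta"):
            apply_effect_filters(self._res([0.1]), min_abs_delta_beta=-1)
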