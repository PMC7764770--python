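import math

import numpy as np
import pandas as pd
import pytest

from stockid import assignment_cv as acv
from stockid import synthetic_data as sd
from stockid.genotype_io import MISSING, GenotypeMatrix, SampleTable
from stockid.popgen_core import FreqTable, group_allele_frequencies
from wc_oracle import naive_assignment_loglik

from conftest import random_dataset


def freq_table(freqs, counts, groups=("A", "B")):
    freqs = np.asarray(freqs, dtype=float)
    counts = np.asarray(counts)
    loci = [f"L{j}" for j in range(freqs.shape[1])]
    return FreqTable(loci, list(groups), freqs, counts)


class TestAssignmentLoglik:
    def test_one_locus_hand_computation(self):
        # group A: 2 alt alleles out of 4 -> smoothed 2.5/5 = 0.5;
        # dosage 2 -> log(0.5^2) = ln 0.25
        f = freq_table([[0.5], [0.25]], [[4], [4]])
        res = acv.assignment_loglik(np.array([2]), f)
        assert res.log_likelihoods["A"] == pytest.approx(math.log(0.25),
                                                         abs=1e-12)

    def test_all_missing_unassignable_with_equal_posteriors(self):
        f = freq_table([[0.5, 0.2], [0.25, 0.8]], [[4, 4], [4, 4]])
        res = acv.assignment_loglik(np.array([MISSING, MISSING]), f)
        assert res.unassignable
        assert res.posteriors["A"] == pytest.approx(0.5)
        assert res.n_loci_used == 0

    def test_monotone_frequency_dominance(self):
        # A has the higher alt frequency everywhere; an all-alt sample
        # must land in A
        f = freq_table([[0.9, 0.8], [0.1, 0.2]], [[20, 20], [20, 20]])
        res = acv.assignment_loglik(np.array([2, 2]), f)
        assert res.assigned_group == "A"

    def test_posteriors_sum_to_one(self):
        f = freq_table([[0.7, 0.3], [0.2, 0.9]], [[10, 10], [10, 10]])
        res = acv.assignment_loglik(np.array([1, 2]), f)
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        """Randomised multi-locus cases against a looped product-of-
        genotype-probabilities oracle."""
        rng = np.random.default_rng(seed)
        n_loci = rng.integers(1, 20)
        n_groups = rng.integers(2, 4)
        counts = rng.integers(2, 40, size=(n_groups, n_loci)) * 2
        x = rng.integers(0, counts + 1)
        f = FreqTable([f"L{j}" for j in range(n_loci)],
                      [f"G{k}" for k in range(n_groups)],
                      x / counts, counts)
        dosages = rng.integers(-1, 3, size=n_loci).astype(np.int8)
        res = acv.assignment_loglik(dosages, f)
        expect = naive_assignment_loglik(
            dosages.tolist(),
            [[(int(x[k, j]), int(counts[k, j])) for j in range(n_loci)]
             for k in range(n_groups)])
        for k, grp in enumerate(f.group_labels):
            assert res.log_likelihoods[grp] == pytest.approx(expect[k],
                                                             abs=1e-12)


class TestAssignHoldout:
    def fixed_difference_data(self):
        calls = np.array([[0], [0], [2], [2]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b", "c", "d"], ["L1"], calls)
        s = SampleTable(pd.DataFrame({
            "sample_id": g.sample_ids, "cluster": ["N", "N", "S", "S"],
            "site_id": ["1"] * 4}))
        return g, s

    def test_fixed_difference_assigns_back(self):
        g, s = self.fixed_difference_data()
        freqs = group_allele_frequencies(g, s)
        results = acv.assign_holdout(g, freqs, ["L1"],
                                     s.labels_for(g.sample_ids))
        assert [r.assigned_group for r in results] == ["N", "N", "S", "S"]

    def test_empty_panel_rejected(self):
        g, s = self.fixed_difference_data()
        freqs = group_allele_frequencies(g, s)
        with pytest.raises(ValueError):
            acv.assign_holdout(g, freqs, [])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        g, s = random_dataset(rng, n_groups=2, n_samples=12, n_loci=8)
        freqs = group_allele_frequencies(g, s)
        panel = list(g.locus_ids)
        res = {r.sample_id: r for r in acv.assign_holdout(g, freqs, panel)}
        perm = rng.permutation(g.n_samples)
        g2 = g.subset_samples(perm)
        res2 = {r.sample_id: r for r in acv.assign_holdout(g2, freqs, panel)}
        for sid in res:
            assert res[sid].log_likelihoods == res2[sid].log_likelihoods
            assert res[sid].assigned_group == res2[sid].assigned_group


@pytest.fixture(scope="module")
def small_cv_data():
    cfg = sd.GenotypeSimConfig(samples_per_cluster=40, n_loci=200,
                               fst=0.10, seed=21)
    return sd.simulate_genotypes(cfg)


class TestRunCv:
    def test_record_shape(self, small_cv_data):
        g, s = small_cv_data
        cfg = acv.CVConfig(ladder=[2, 8, 200], n_iterations=4,
                           n_replicates=2, seed=0)
        summ = acv.run_cv(g, s, cfg)
        # replicates x iterations x panels x groups
        assert len(summ.records) == 2 * 4 * 3 * 2
        assert (summ.records.n_correct <= summ.records.n_total).all()

    def test_deterministic_given_seed(self, small_cv_data):
        g, s = small_cv_data
        cfg = acv.CVConfig(ladder=[2, 200], n_iterations=3, n_replicates=2,
                           seed=4)
        a = acv.run_cv(g, s, cfg)
        b = acv.run_cv(g, s, cfg)
        assert a.records_bytes() == b.records_bytes()
        assert a.confusion.equals(b.confusion)

    def test_perfect_separation_limit(self):
        """A fixed-difference locus with no missingness gives exactly 1."""
        rng = np.random.default_rng(3)
        n = 20
        calls = rng.integers(0, 3, size=(2 * n, 10)).astype(np.int8)
        calls[:n, 0] = 0
        calls[n:, 0] = 2
        g = GenotypeMatrix([f"s{i}" for i in range(2 * n)],
                           [f"L{j}" for j in range(10)], calls)
        s = SampleTable(pd.DataFrame({
            "sample_id": g.sample_ids,
            "cluster": ["N"] * n + ["S"] * n,
            "site_id": ["1"] * (2 * n)}))
        summ = acv.run_cv(g, s, acv.CVConfig(ladder=[1], n_iterations=5,
                                             n_replicates=1, seed=0))
        acc = acv.accuracy_by_panel(summ)
        assert (acc["accuracy_mean"] == 1.0).all()

    def test_no_leakage_canary(self, small_cv_data):
        """Corrupting holdout genotypes leaves every training-derived
        quantity (marker ranking, allele frequencies) unchanged."""
        g, s = small_cv_data
        groups = sorted(set(s.df["cluster"]))
        members = {grp: np.flatnonzero(
            s.labels_for(g.sample_ids) == grp) for grp in groups}
        ladder = [2, 50, 200]
        base = acv._run_iteration(g, s, "cluster", groups, members, ladder,
                                  seed=7, rep=0, it=0)
        corrupted = g.copy()
        rng = np.random.default_rng(0)
        corrupted.calls[base.hold_idx, :] = rng.integers(
            0, 3, size=(len(base.hold_idx), g.n_loci)).astype(np.int8)
        alt = acv._run_iteration(corrupted, s, "cluster", groups, members,
                                 ladder, seed=7, rep=0, it=0)
        assert np.array_equal(base.train_idx, alt.train_idx)
        assert base.ranked_locus_ids == alt.ranked_locus_ids
        np.testing.assert_array_equal(base.training_freqs.freq,
                                      alt.training_freqs.freq)
        # and the corruption did reach the holdout likelihoods
        assert not np.allclose(base.loglik, alt.loglik)

    def test_train_holdout_disjoint(self, small_cv_data):
        g, s = small_cv_data
        groups = sorted(set(s.df["cluster"]))
        members = {grp: np.flatnonzero(
            s.labels_for(g.sample_ids) == grp) for grp in groups}
        res = acv._run_iteration(g, s, "cluster", groups, members, [200],
                                 seed=1, rep=0, it=0)
        assert not set(res.train_idx) & set(res.hold_idx)
        # odd counts favour training
        assert len(res.train_idx) >= len(res.hold_idx)

    def test_site_mode_single_replicate_no_equalization(self):
        cfg = sd.GenotypeSimConfig(samples_per_cluster=30, n_loci=100,
                                   fst=0.05, sites_per_cluster=3,
                                   site_fst=0.01, seed=8)
        g, s = sd.simulate_genotypes(cfg)
        cv = acv.CVConfig(mode="site", ladder=[2, 100], n_iterations=2,
                          n_replicates=5, seed=0)
        assert cv.n_replicates == 1 and cv.equalize is False
        summ = acv.run_cv(g, s, cv)
        assert summ.records["replicate"].max() == 0
        assert set(summ.group_labels) == set(s.df["site_id"])

    def test_population_mode_requires_labels(self, small_cv_data):
        g, _ = small_cv_data
        s = SampleTable(pd.DataFrame({
            "sample_id": g.sample_ids,
            "cluster": [np.nan] * g.n_samples,
            "site_id": ["1"] * g.n_samples}))
        with pytest.raises(ValueError, match="label"):
            acv.run_cv(g, s, acv.CVConfig(n_iterations=1, seed=0))


@pytest.fixture(scope="module")
def summary(small_cv_data):
    g, s = small_cv_data
    return acv.run_cv(g, s, acv.CVConfig(ladder=[2, 32, 200],
                                         n_iterations=5,
                                         n_replicates=2, seed=2))


class TestSummaries:

    def test_confusion_conserves_totals(self, summary):
        for k in summary.ladder:
            mat = acv.summarize_assignment_matrix(summary, k)
            rec = summary.records[summary.records.panel_size == k]
            assert mat.to_numpy().sum() == rec["n_total"].sum()
            # row sums equal per-true-group assignable totals
            for grp in summary.group_labels:
                assert (mat.loc[grp].sum()
                        == rec.loc[rec.group == grp, "n_total"].sum())

    def test_unknown_panel_rejected(self, summary):
        with pytest.raises(ValueError):
            acv.summarize_assignment_matrix(summary, 999)

    def test_accuracy_table_matches_raw_records(self, summary):
        """Aggregates recompute from the raw records by brute force."""
        acc = acv.accuracy_by_panel(summary)
        rec = summary.records
        for _, row in acc.iterrows():
            k = row["panel_size"]
            if row["group"] == "overall":
                per_iter = (rec[rec.panel_size == k]
                            .groupby(["replicate", "iteration"])
                            .apply(lambda d: d.n_correct.sum()
                                   / d.n_total.sum(), include_groups=False))
            else:
                sub = rec[(rec.panel_size == k) & (rec.group == row["group"])]
                per_iter = sub.n_correct / sub.n_total
            assert row["accuracy_mean"] == pytest.approx(per_iter.mean())
            expect_sd = per_iter.std(ddof=1)
            if np.isnan(expect_sd):
                expect_sd = 0.0
            assert row["accuracy_sd"] == pytest.approx(expect_sd)

    def test_single_iteration_sd_zero(self, small_cv_data):
        g, s = small_cv_data
        summ = acv.run_cv(g, s, acv.CVConfig(ladder=[200], n_iterations=1,
                                             n_replicates=1, seed=0))
        acc = acv.accuracy_by_panel(summ)
        assert (acc["accuracy_sd"] == 0.0).all()
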