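"""EM fitting, component selection, thresholds, classification and core QC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import metscreen as ms
from metscreen.mixture import MixtureModel1D, majority_vote


def two_cluster_sample(rng, m1=0.0, m2=10.0, sd=0.1, n=200):
    return np.r_[rng.normal(m1, sd, n), rng.normal(m2, sd, n)]


class TestFitGmm1d:
    def test_k1_closed_form(self, rng):
        x = rng.normal(3.0, 2.0, 500)
        m = ms.fit_gmm_1d(x, K=1)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-12)
        assert m.sds[0] == pytest.approx(x.std(), abs=1e-12)  # ML divisor n
        assert m.weights[0] == 1.0

    def test_two_separated_clusters_recovered(self, rng):
        x = two_cluster_sample(rng)
        m = ms.fit_gmm_1d(x, K=2, seed=0)
        # oracle: per-cluster sample means after a midpoint split
        lo, hi = x[x < 5].mean(), x[x >= 5].mean()
        assert m.means[0] == pytest.approx(lo, abs=0.1)
        assert m.means[1] == pytest.approx(hi, abs=0.1)
        assert m.converged

    def test_n_below_k_raises(self):
        with pytest.raises(ms.InsufficientDataError):
            ms.fit_gmm_1d([1.0], K=2)

    def test_identical_values_with_k2_raise(self):
        with pytest.raises(ms.DegenerateDataError):
            ms.fit_gmm_1d([2.0] * 50, K=2)

    def test_loglik_trace_nondecreasing(self, rng):
        for K in (2, 3):
            x = rng.normal(0, 1, 150) if K == 2 else two_cluster_sample(rng, n=75)
            m = ms.fit_gmm_1d(x, K=K, seed=1)
            assert np.all(np.diff(m.loglik_trace) >= -1e-7)

    def test_weights_sum_to_one_and_means_ascending(self, rng):
        x = two_cluster_sample(rng, sd=1.0)
        m = ms.fit_gmm_1d(x, K=3, seed=2)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(m.means) >= 0)

    def test_agrees_with_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.r_[rng.normal(0, 0.5, 300), rng.normal(3, 0.7, 200)]
        ours = ms.fit_gmm_1d(x, K=2, seed=0)
        ref = sklearn.GaussianMixture(2, n_init=5, random_state=0, tol=1e-6).fit(
            x[:, None]
        )
        ref_means = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref_means, atol=0.05)
        assert ours.loglik == pytest.approx(ref.score(x[:, None]) * len(x), abs=1.0)


class TestThresholds:
    def test_symmetric_equal_weight_threshold_is_midpoint(self):
        m = MixtureModel1D(
            np.array([0.5, 0.5]), np.array([0.0, 4.0]), np.array([1.0, 1.0]),
            0.0, True, 1,
        )
        assert ms.thresholds_from_mixture(m)[0] == pytest.approx(2.0, abs=1e-9)

    def test_weighted_threshold_closed_form(self):
        # equal sds: w1*phi(t-m1) = w2*phi(t-m2) solves to
        # t = midpoint + sd^2 * ln(w1/w2) / (m2 - m1)
        m = MixtureModel1D(
            np.array([0.8, 0.2]), np.array([0.0, 4.0]), np.array([1.0, 1.0]),
            0.0, True, 1,
        )
        assert ms.thresholds_from_mixture(m)[0] == pytest.approx(
            2.0 + np.log(4.0) / 4.0, abs=1e-9
        )

    def test_k1_yields_no_thresholds(self, rng):
        m = ms.fit_gmm_1d(rng.normal(0, 1, 50), K=1)
        assert ms.thresholds_from_mixture(m) == []

    def test_threshold_is_posterior_half_point(self, rng):
        x = two_cluster_sample(rng, 0, 4, sd=1.0)
        m = ms.fit_gmm_1d(x, K=2, seed=0)
        t = ms.thresholds_from_mixture(m)[0]
        resp = m.responsibilities(np.array([t]))
        assert resp[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_no_crossing_reports_minimum_ratio_point_with_warning(self):
        m = MixtureModel1D(
            np.array([0.99, 0.01]), np.array([0.0, 0.5]), np.array([1.0, 1.0]),
            0.0, True, 1,
        )
        with pytest.warns(RuntimeWarning, match="crossing"):
            t = ms.thresholds_from_mixture(m)
        assert 0.0 <= t[0] <= 0.5


class TestSelectComponents:
    def test_single_gaussian_votes_k1(self, rng):
        x = rng.normal(0, 1, 300)
        sel = ms.select_components(x, K_candidates=(1, 2, 3), n_iterations=50, seed=0)
        assert sel.chosen_K == 1
        assert sel.votes[1] / sum(sel.votes.values()) > 0.9
        assert sel.consensus_thresholds == []

    def test_three_separated_components_recovered(self, rng):
        x = np.r_[rng.normal(0, 1, 120), rng.normal(4, 1, 120), rng.normal(8, 1, 120)]
        sel = ms.select_components(x, K_candidates=(1, 2, 3, 4), n_iterations=50, seed=1)
        assert sel.chosen_K == 3
        assert sel.votes[3] / sum(sel.votes.values()) >= 0.8
        t = sel.threshold_means()
        assert len(t) == 2 and t[0] < t[1]
        # consensus over qualifying subsample fits should agree with the
        # thresholds of the full-data K=3 fit
        full = ms.thresholds_from_mixture(ms.fit_gmm_1d(x, 3, seed=0))
        assert t[0] == pytest.approx(full[0], abs=0.2)
        assert t[1] == pytest.approx(full[1], abs=0.2)

    def test_tie_break_prefers_smaller_k(self):
        assert majority_vote({2: 100, 3: 100}) == 2
        assert majority_vote({1: 10, 2: 50, 5: 50}) == 2

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ms.ValidationError):
            ms.select_components(rng.normal(0, 1, 50), K_candidates=(), n_iterations=5)

    def test_vote_share_monotone_in_separation(self, rng):
        # as the two components separate, the K=2 vote share cannot drop
        shares = []
        for sep in (0.5, 2.0, 5.0):
            x = np.r_[rng.normal(0, 1, 120), rng.normal(sep, 1, 120)]
            sel = ms.select_components(
                x, K_candidates=(1, 2), n_iterations=40, seed=3
            )
            shares.append(sel.votes.get(2, 0) / sum(sel.votes.values()))
        # non-decreasing up to the one-vote resolution of the share
        for a, b in zip(shares, shares[1:]):
            assert b >= a - 1.0 / 40
        assert shares[-1] > shares[0]

    def test_deterministic_given_seed(self, rng):
        x = two_cluster_sample(rng, 0, 4, sd=1.0, n=100)
        a = ms.select_components(x, K_candidates=(1, 2, 3), n_iterations=20, seed=9)
        b = ms.select_components(x, K_candidates=(1, 2, 3), n_iterations=20, seed=9)
        assert a.votes == b.votes
        assert a.consensus_thresholds == b.consensus_thresholds


class TestClassify:
    def test_three_strata_examples(self):
        a = ms.classify([0.1, 0.45, 0.9], [0.3, 0.6])
        assert list(a.categories) == ["low", "intermediate", "high"]

    def test_boundary_value_goes_to_upper_category(self):
        a = ms.classify([0.3, 0.6], [0.3, 0.6])
        assert list(a.categories) == ["intermediate", "high"]

    def test_empty_thresholds_single_category(self):
        a = ms.classify([0.1, 0.9], [])
        assert list(a.categories) == ["all", "all"]

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.classify([0.5], [0.6, 0.3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=1, max_size=30
        ),
        t1=st.floats(min_value=-5, max_value=0),
        gap=st.floats(min_value=1e-3, max_value=5),
    )
    def test_classification_exhaustive_and_idempotent(self, values, t1, gap):
        thresholds = [t1, t1 + gap]
        a = ms.classify(values, thresholds)
        # every value gets exactly one of the declared labels
        assert a.categories.notna().all()
        assert set(a.categories) <= set(a.labels)
        # reclassifying the same values reproduces the same calls
        b = ms.classify(values, thresholds)
        assert list(a.categories) == list(b.categories)
        # label agrees with direct interval membership
        for v, lab in zip(values, a.categories):
            if v < thresholds[0]:
                assert lab == "low"
            elif v < thresholds[1]:
                assert lab == "intermediate"
            else:
                assert lab == "high"


def brute_force_qc(table, t_art, t_tum):
    """Independent row-by-row application of the three QC rules."""
    keep = []
    for _, row in table.iterrows():
        if not row["artifact_area_fraction"] < t_art:
            continue
        if not row["tumor_area_fraction"] > t_tum:
            continue
        if not row["tumor_area_fraction"] > row["artifact_area_fraction"]:
            continue
        keep.append(row["core_id"])
    return keep


class TestQcFilterCores:
    toy = pd.DataFrame(
        {
            "core_id": [f"c{i}" for i in range(1, 7)],
            "artifact_area_fraction": [0.01, 0.2, 0.05, 0.05, 0.06, 0.0],
            "tumor_area_fraction": [0.5, 0.6, 0.2, 0.4, 0.05, 0.31],
        }
    )

    def test_fixed_thresholds_on_toy_table(self):
        out, rep = ms.qc_filter_cores(
            self.toy, mode="fixed", fixed_thresholds=(0.07, 0.3)
        )
        assert list(out["core_id"]) == ["c1", "c4", "c6"]
        assert rep.n_input == 6 and rep.n_after_ratio == 3

    def test_empty_table_gives_zero_report(self):
        empty = self.toy.iloc[0:0]
        out, rep = ms.qc_filter_cores(empty, mode="fixed", fixed_thresholds=(0.07, 0.3))
        assert len(out) == 0
        assert rep.n_input == rep.n_after_ratio == 0

    def test_step3_removes_tumor_below_artifact(self):
        t = pd.DataFrame(
            {
                "core_id": ["x"],
                "artifact_area_fraction": [0.05],
                "tumor_area_fraction": [0.04],
            }
        )
        # passes step 1 (<0.07); step 2 threshold 0.03 keeps it; step 3 drops it
        out, rep = ms.qc_filter_cores(t, mode="fixed", fixed_thresholds=(0.07, 0.03))
        assert len(out) == 0
        assert rep.n_after_tumor == 1 and rep.n_after_ratio == 0

    def test_fixed_mode_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 30))
            t = pd.DataFrame(
                {
                    "core_id": [f"c{i}" for i in range(n)],
                    "artifact_area_fraction": rng.random(n),
                    "tumor_area_fraction": rng.random(n),
                }
            )
            t_art, t_tum = rng.random(), rng.random()
            out, _ = ms.qc_filter_cores(t, mode="fixed", fixed_thresholds=(t_art, t_tum))
            assert list(out["core_id"]) == brute_force_qc(t, t_art, t_tum)

    def test_fit_mode_recovers_planted_thresholds(self, rng):
        # artifact: clean cores ~0.03, artifact-heavy ~0.3; tumor: low ~0.15 high ~0.6
        n = 400
        art = np.where(rng.random(n) < 0.7, rng.normal(0.03, 0.01, n), rng.normal(0.3, 0.05, n))
        tum = np.where(rng.random(n) < 0.3, rng.normal(0.15, 0.03, n), rng.normal(0.6, 0.08, n))
        t = pd.DataFrame(
            {
                "core_id": [f"c{i}" for i in range(n)],
                "artifact_area_fraction": np.clip(art, 0, 1),
                "tumor_area_fraction": np.clip(tum, 0, 1),
            }
        )
        out, rep = ms.qc_filter_cores(t, mode="fit", seed=0)
        assert 0.05 < rep.artifact_threshold < 0.25
        assert 0.2 < rep.tumor_threshold < 0.5
        assert (out["tumor_area_fraction"] > out["artifact_area_fraction"]).all()

    def test_degenerate_data_directs_to_fixed_mode(self):
        t = pd.DataFrame(
            {
                "core_id": ["a", "b", "c"],
                "artifact_area_fraction": [0.1, 0.1, 0.1],
                "tumor_area_fraction": [0.5, 0.6, 0.7],
            }
        )
        with pytest.raises(ms.DegenerateDataError, match="fixed"):
            ms.qc_filter_cores(t, mode="fit")
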