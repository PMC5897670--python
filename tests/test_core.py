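"""Unit and property tests for the dependency-analysis core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import depna
from depna.core import (
    CorrelationMatrix,
    SubjectTimeSeries,
    dependency_matrix,
    fisher_z,
    influence_d,
    influencing_degree,
    inter_network_influence_between,
    inter_network_influence_within,
    intra_network_influence,
    partial_correlation,
    pearson_correlations,
    total_inter_network_influence,
)
from depna.roi import RoiSet, default_roiset

from conftest import (
    oracle_d,
    oracle_dependency,
    oracle_inter_between,
    oracle_inter_within,
    oracle_intra,
    oracle_pc,
    random_corr,
)


def ts(data, tr=3.0, roiset=None, sid="s1"):
    return SubjectTimeSeries(sid, np.asarray(data, float), tr, roiset)


class TestPearsonCorrelations:
    def test_identical_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        c = pearson_correlations(ts(np.column_stack([x, x, -x])))
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c.values), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((10000, 2))
        c = pearson_correlations(ts(x))
        assert abs(c.values[0, 1]) < 0.05  # sampling bound ~ 2/sqrt(T)

    def test_constant_column_names_roi(self, small_roiset):
        data = np.random.default_rng(0).standard_normal((30, 6))
        data[:, 2] = 5.0
        with pytest.raises(ValueError, match="a3"):
            pearson_correlations(ts(data, roiset=small_roiset))

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 time points"):
            with pytest.warns(UserWarning):
                pearson_correlations(ts(np.ones((2, 3)) + np.eye(2, 3)))


class TestFisherZ:
    def test_values_and_diagonal(self):
        c = CorrelationMatrix(np.array([[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1.0]]))
        z = fisher_z(c)
        assert z.transform == "fisher_z"
        assert z.values[0, 1] == pytest.approx(0.5 * np.log(3))  # atanh(0.5)
        assert z.values[0, 2] == 0.0
        assert np.allclose(np.diag(z.values), 1.0)  # diagonal untouched

    def test_clip_guard_keeps_z_finite(self):
        c = CorrelationMatrix(
            np.array([[1, 0.9999999], [0.9999999, 1.0]])
        )
        z = fisher_z(c)
        assert np.isfinite(z.values[0, 1])

    def test_double_transform_rejected(self):
        c = fisher_z(random_corr(np.random.default_rng(0), 4))
        with pytest.raises(ValueError, match="already"):
            fisher_z(c)


class TestPartialCorrelation:
    def test_direct_arithmetic(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.6   # C(i,k)
        c[0, 2] = c[2, 0] = 0.5   # C(i,j)
        c[1, 2] = c[2, 1] = 0.5   # C(k,j)
        pc = partial_correlation(CorrelationMatrix(c), 0, 1, 2)
        assert pc == pytest.approx(0.35 / 0.75)
        assert influence_d(CorrelationMatrix(c), 0, 1, 2) == pytest.approx(
            0.6 - 0.35 / 0.75
        )

    def test_reduces_to_correlation_when_conditioner_uncorrelated(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.4
        cm = CorrelationMatrix(c)
        assert partial_correlation(cm, 0, 1, 2) == pytest.approx(0.4)
        assert influence_d(cm, 0, 1, 2) == pytest.approx(0.0)

    def test_common_cause_removed(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(5000)
        x = np.column_stack([s + rng.standard_normal(5000),
                             s + rng.standard_normal(5000), s])
        cm = pearson_correlations(ts(x))
        assert abs(partial_correlation(cm, 0, 1, 2)) < 0.05

    def test_matches_residual_regression(self, rng):
        for _ in range(20):
            x = rng.standard_normal((80, 4))
            cm = pearson_correlations(ts(x))
            i, k, j = 0, 1, 2
            # independent oracle: correlate least-squares residuals
            def resid(col):
                beta = np.linalg.lstsq(
                    np.column_stack([x[:, j], np.ones(80)]), x[:, col], rcond=None
                )[0]
                return x[:, col] - beta[0] * x[:, j] - beta[1]
            expected = np.corrcoef(resid(i), resid(k))[0, 1]
            assert partial_correlation(cm, i, k, j) == pytest.approx(
                expected, abs=1e-10
            )

    def test_degenerate_conditioning_is_an_error(self):
        c = np.eye(3)
        c[0, 2] = c[2, 0] = 1.0
        c[0, 1] = c[1, 0] = 0.3
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(CorrelationMatrix(c), 0, 1, 2)

    def test_distinct_indices_required(self):
        cm = random_corr(np.random.default_rng(1), 4)
        with pytest.raises(ValueError, match="distinct"):
            partial_correlation(cm, 1, 1, 2)


class TestInfluenceD:
    def test_floored_at_zero(self):
        # PC > C(i,k): strong shared conditioner, weak direct correlation
        c = np.eye(3)
        c[0, 1] = c[1, 0] = -0.5
        c[0, 2] = c[2, 0] = 0.1
        c[1, 2] = c[2, 1] = 0.1
        cm = CorrelationMatrix(c)
        assert partial_correlation(cm, 0, 1, 2) < c[0, 1]  # sanity: d would be > 0
        c2 = np.eye(3)
        c2[0, 1] = c2[1, 0] = 0.0
        c2[0, 2] = c2[2, 0] = 0.6
        c2[1, 2] = c2[2, 1] = -0.6
        cm2 = CorrelationMatrix(c2)
        assert partial_correlation(cm2, 0, 1, 2) > 0  # C - PC negative
        assert influence_d(cm2, 0, 1, 2) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_in_i_k(self, seed):
        cm = random_corr(np.random.default_rng(seed), 5)
        assert influence_d(cm, 0, 3, 1) == influence_d(cm, 3, 0, 1)


class TestDependencyMatrix:
    def test_matches_literal_loop_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            cm = random_corr(rng, n)
            got = dependency_matrix(cm).values
            assert np.abs(got - oracle_dependency(cm.values)).max() < 1e-12

    def test_independent_signals_near_zero(self):
        rng = np.random.default_rng(11)
        cm = pearson_correlations(ts(rng.standard_normal((20000, 3))))
        assert dependency_matrix(cm).values.max() < 0.02

    def test_hub_column_dominates(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(2000)
        cols = [0.8 * s + rng.standard_normal(2000) for _ in range(4)] + [s]
        cm = pearson_correlations(ts(np.column_stack(cols)))
        dep = dependency_matrix(cm).values
        hub_col = dep[:, 4]
        for j in range(4):
            other = dep[:, j]
            assert hub_col[hub_col > 0].min() > other.max()

    def test_small_network_rejected(self):
        with pytest.raises(ValueError, match="N >= 3"):
            dependency_matrix(CorrelationMatrix(np.array([[1, 0.2], [0.2, 1.0]])))

    def test_non_negative_zero_diagonal(self, rng):
        dep = dependency_matrix(random_corr(rng, 7)).values
        assert dep.min() >= 0
        assert np.all(np.diag(dep) == 0)


class TestInfluencingDegree:
    def test_zero_and_single_edge(self):
        z = depna.DependencyMatrix(np.zeros((3, 3)), labels=("a", "b", "c"))
        assert all(v == 0 for v in influencing_degree(z).scores.values())
        m = np.zeros((3, 3))
        m[2, 1] = 0.3
        prof = influencing_degree(depna.DependencyMatrix(m, labels=("a", "b", "c")))
        assert prof.scores == {"a": 0.0, "b": pytest.approx(0.3), "c": 0.0}

    def test_hub_recovery_rate(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            s = rng.standard_normal(120)
            cols = [0.8 * s + rng.standard_normal(120) for _ in range(5)]
            cols.insert(2, s)  # hub at index 2
            cm = pearson_correlations(ts(np.column_stack(cols)))
            prof = influencing_degree(dependency_matrix(cm))
            scores = list(prof.scores.values())
            hits += int(np.argmax(scores) == 2)
        assert hits >= 0.95 * n_rep

    def test_noise_free_hub_degree_monotone_in_coupling(self):
        # expected correlation matrix of the hub model, no sampling noise:
        # corr(x_i, hub) = a/sqrt(a^2+1), corr(x_i, x_l) = a^2/(a^2+1)
        degrees = []
        for a in (0.2, 0.4, 0.6, 0.8):
            n = 6
            c = np.full((n, n), a**2 / (a**2 + 1))
            c[:, -1] = c[-1, :] = a / np.sqrt(a**2 + 1)
            np.fill_diagonal(c, 1.0)
            prof = influencing_degree(dependency_matrix(CorrelationMatrix(c)))
            degrees.append(list(prof.scores.values())[-1])
        assert all(b >= a for a, b in zip(degrees, degrees[1:]))


class TestNetworkVariants:
    def test_intra_equals_pipeline_on_submatrix(self, rng, small_roiset):
        cm = random_corr(rng, 6)
        cm.labels = small_roiset.labels
        prof = intra_network_influence(cm, small_roiset, "regulation")
        idx = list(small_roiset.member_indices("regulation"))
        expected = oracle_intra(cm.values, idx)
        assert np.allclose(prof.as_array(small_roiset.members("regulation")),
                           expected, atol=1e-12)

    def test_intra_null_near_zero(self, small_roiset):
        rng = np.random.default_rng(2)
        cm = pearson_correlations(
            ts(rng.standard_normal((20000, 6)), roiset=small_roiset)
        )
        prof = intra_network_influence(cm, small_roiset, "regulation")
        assert max(prof.scores.values()) < 0.02

    def test_intra_hub_recovery(self, small_roiset):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(3000)
        noise = rng.standard_normal((3000, 6))
        data = noise.copy()
        data[:, 3] = s                      # hub inside regulation
        data[:, 4] = 0.8 * s + noise[:, 4]
        data[:, 5] = 0.8 * s + noise[:, 5]
        cm = pearson_correlations(ts(data, roiset=small_roiset))
        prof = intra_network_influence(cm, small_roiset, "regulation")
        assert max(prof.scores, key=prof.scores.get) == "b1"

    def test_intra_masked_full_mode_differs_but_nonnegative(self, rng, small_roiset):
        cm = random_corr(rng, 6)
        prof = intra_network_influence(cm, small_roiset, "regulation",
                                       mode="masked_full")
        assert all(v >= 0 for v in prof.scores.values())

    def test_intra_needs_three_members(self):
        rs = RoiSet(("a", "b", "c", "d"),
                    {"a": "reactivity", "b": "reactivity",
                     "c": "reactivity", "d": "regulation"})
        cm = random_corr(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="need >= 3"):
            intra_network_influence(cm, rs, "regulation")

    def test_inter_within_matches_pair_loop(self, rng, small_roiset):
        cm = random_corr(rng, 6)
        prof = inter_network_influence_within(cm, small_roiset,
                                              "regulation", "reactivity")
        src = list(small_roiset.member_indices("regulation"))
        tgt = list(small_roiset.member_indices("reactivity"))
        expected = oracle_inter_within(cm.values, src, tgt)
        assert np.allclose(prof.as_array(small_roiset.members("regulation")),
                           expected, atol=1e-12)

    def test_inter_between_matches_loop(self, rng, small_roiset):
        cm = random_corr(rng, 6)
        prof = inter_network_influence_between(cm, small_roiset,
                                               "regulation", "reactivity")
        src = list(small_roiset.member_indices("regulation"))
        tgt = list(small_roiset.member_indices("reactivity"))
        expected = oracle_inter_between(cm.values, src, tgt)
        assert np.allclose(prof.as_array(small_roiset.members("regulation")),
                           expected, atol=1e-12)

    def test_inter_common_cause_approaches_mean_target_correlation(self, small_roiset):
        # b1 drives every reactivity node: removing it kills their pairwise r
        rng = np.random.default_rng(4)
        s = rng.standard_normal(20000)
        data = rng.standard_normal((20000, 6)) * 0.4
        for i in (0, 1, 2):
            data[:, i] += s
        data[:, 3] = s
        cm = pearson_correlations(ts(data, roiset=small_roiset))
        prof = inter_network_influence_within(cm, small_roiset,
                                              "regulation", "reactivity")
        tgt = [0, 1, 2]
        mean_c = np.mean([cm.values[i, k] for i in tgt for k in tgt if k > i])
        assert prof.scores["b1"] == pytest.approx(mean_c, abs=0.02)

    def test_total_inter_sums_scores(self, rng, small_roiset):
        cm = random_corr(rng, 6)
        prof = inter_network_influence_within(cm, small_roiset,
                                              "regulation", "reactivity")
        assert total_inter_network_influence(prof) == pytest.approx(
            sum(prof.scores.values())
        )

    def test_total_inter_rejects_wrong_scheme(self, rng):
        prof = influencing_degree(dependency_matrix(random_corr(rng, 5)))
        with pytest.raises(ValueError, match="scheme"):
            total_inter_network_influence(prof)


class TestPermutationInvariance:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_relabeling_permutes_outputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        cm = random_corr(rng, n)
        perm = rng.permutation(n)
        cmp_ = CorrelationMatrix(cm.values[np.ix_(perm, perm)])
        dep = dependency_matrix(cm).values
        depp = dependency_matrix(cmp_).values
        assert np.allclose(depp, dep[np.ix_(perm, perm)], atol=1e-12)
        deg = np.array(list(influencing_degree(dependency_matrix(cm)).scores.values()))
        degp = np.array(
            list(influencing_degree(dependency_matrix(cmp_)).scores.values())
        )
        assert np.allclose(degp, deg[perm], atol=1e-12)


def test_null_hub_contrast_centered_at_zero():
    """i.i.d. Gaussian networks: degrees are positive on average but no node
    is preferred — the hub-vs-rest contrast is within 2 MC standard errors."""
    rng = np.random.default_rng(99)
    contrasts = []
    means = []
    n_rep = 300
    for _ in range(n_rep):
        x = rng.standard_normal((44, 14))
        deg = dependency_matrix(pearson_correlations(ts(x))).values.sum(axis=0)
        means.append(deg.mean())
        contrasts.append(deg[-1] - deg[:-1].mean())
    contrasts = np.asarray(contrasts)
    assert np.mean(means) > 0
    se = contrasts.std(ddof=1) / np.sqrt(n_rep)
    assert abs(contrasts.mean()) < 2 * se
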