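"""FNI, likelihood-ratio comparisons, AUC/DeLong, Holm, contributions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacpih.added_value import (
    auc,
    comparison_p,
    delong_compare,
    explained_variance_contributions,
    fni,
    fni_compose,
    holm_adjust,
)
from vacpih.errors import DomainError, NestingError
from vacpih.models import ModelSpec


class TestFni:
    def test_reproduces_published_ratio(self):
        # model-level chi-squares solved from the published sequential
        # deviances (34.36 + 15.27 = 49.63) and total FNI 0.46
        assert fni(58.26, 92.62) == pytest.approx(0.371, abs=5e-4)

    def test_no_new_information(self):
        assert fni(7.3, 7.3) == 0.0

    def test_all_information_new(self):
        assert fni(0.0, 12.5) == 1.0

    def test_nesting_violation_rejected(self):
        with pytest.raises(NestingError):
            fni(10.0, 5.0)

    def test_zero_full_lr_rejected(self):
        with pytest.raises(DomainError):
            fni(0.0, 0.0)

    def test_composition_identity(self):
        # adequacies multiply along a nested chain: exact identity
        lr0, lre, lrf = 40.0, 66.7, 90.1
        total = fni(lr0, lrf)
        assert fni_compose(fni(lr0, lre), fni(lre, lrf)) == pytest.approx(
            total, abs=1e-15)

    def test_published_composition(self):
        assert round(100 * fni_compose(0.37, 0.14)) == 46


class TestComparisonP:
    def test_published_roundings(self):
        assert round(comparison_p(49.63, 29.05), 2) == 0.01
        assert round(comparison_p(34.36, 24.97), 1) == 0.1

    def test_zero_deviance(self):
        assert comparison_p(0.0, 4.09) == 1.0

    def test_bad_df_rejected(self):
        with pytest.raises(DomainError):
            comparison_p(5.0, 0.0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [1, 1, 1, 0, 0, 0]) == 1.0

    def test_pure_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_pairs(self):
        assert auc([0.9, 0.4, 0.5, 0.3], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_enumeration(self, rng):
        # brute-force oracle: count wins + half-ties over all pos/neg pairs
        for _ in range(20):
            n = rng.integers(6, 50)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(2, n - 2)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.uniform(0, 1, n), 2)  # force some ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            ])
            assert auc(scores, labels) == pytest.approx(brute, abs=1e-12)


class TestDeLong:
    def test_identical_scores_convention(self):
        s = np.array([0.8, 0.6, 0.4, 0.3])
        r = delong_compare(s, s, np.array([1, 1, 0, 0]))
        assert r.delta == 0.0 and r.p == 1.0

    def test_antisymmetry(self, rng):
        labels = rng.binomial(1, 0.4, 100)
        labels[:2] = [0, 1]
        a = rng.normal(size=100) + labels
        b = rng.normal(size=100) + 0.5 * labels
        r1 = delong_compare(a, b, labels)
        r2 = delong_compare(b, a, labels)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-15)
        assert r1.p == pytest.approx(r2.p, abs=1e-15)

    def test_se_close_to_bootstrap(self):
        # paired scores on 200 patients; the analytic DeLong SE of the AUC
        # difference should agree with a 2000-replicate bootstrap SE
        rng = np.random.default_rng(2024)
        n = 200
        labels = rng.binomial(1, 0.4, n)
        labels[:2] = [0, 1]
        base = rng.normal(size=n)
        a = base + 1.0 * labels + 0.5 * rng.normal(size=n)
        b = base + 0.6 * labels + 0.5 * rng.normal(size=n)
        analytic = delong_compare(a, b, labels).se
        boot = np.empty(2000)
        for i in range(2000):
            idx = rng.integers(0, n, n)
            while labels[idx].min() == labels[idx].max():
                idx = rng.integers(0, n, n)
            boot[i] = auc(a[idx], labels[idx]) - auc(b[idx], labels[idx])
        assert analytic == pytest.approx(boot.std(ddof=1), rel=0.15)


class TestHolm:
    def test_hand_stepdown(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06], atol=1e-12)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_published_six_test_family(self):
        family = [
            0.0036, 0.0003, 0.1166,  # AUC-difference tests
            comparison_p(34.36, 24.97),
            comparison_p(49.63, 29.05),
            comparison_p(15.27, 4.09),
        ]
        adjusted = [round(v, 3) for v in holm_adjust(family)]
        assert adjusted == [0.018, 0.002, 0.199, 0.199, 0.030, 0.018]

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotonicity_properties(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            holm_adjust([0.5, 1.2])


class TestContributions:
    def test_single_predictor_takes_all(self, cohort405):
        spec = ModelSpec("one", parametric_terms=["asa34"])
        tab = explained_variance_contributions(cohort405, spec, B=5, seed=0)
        assert tab.table["percent"].iloc[0] == pytest.approx(100.0)

    def test_symmetric_predictors_split_evenly(self):
        rng = np.random.default_rng(99)
        n = 20_000
        a = rng.binomial(1, 0.5, n).astype(float)
        b = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.8 + 1.0 * a + 1.0 * b))))
        df = pd.DataFrame({"a": a, "b": b, "pih": y})
        spec = ModelSpec("sym", parametric_terms=["a", "b"])
        tab = explained_variance_contributions(df, spec, B=10, seed=1)
        shares = dict(zip(tab.table["term"], tab.table["percent"]))
        assert shares["a"] == pytest.approx(50.0, abs=5.0)
        assert shares["b"] == pytest.approx(50.0, abs=5.0)

    def test_point_estimate_sums_to_100(self, cohort405):
        spec = ModelSpec("m", parametric_terms=["asa34", "ccb"],
                         smooth_terms=["map_t0"])
        tab = explained_variance_contributions(cohort405, spec, B=5, seed=0)
        assert tab.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_bootstrap_ci_brackets_point_estimate(self, cohort405):
        spec = ModelSpec("m", parametric_terms=["asa34", "ccb"])
        tab = explained_variance_contributions(cohort405, spec, B=50, seed=2)
        inside = ((tab.table["ci_low"] <= tab.table["percent"])
                  & (tab.table["percent"] <= tab.table["ci_high"]))
        assert inside.all()
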