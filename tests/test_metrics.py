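"""Metric definitions against brute-force oracles and analytic limits."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitphys import (
    Cohort,
    GaitCycle,
    SubjectRecord,
    bds_statistic,
    compute_features,
    correlation_integral,
    permutation_entropy,
    shannon_entropy,
    weighted_permutation_entropy,
)
from gaitphys.metrics import UndefinedMetricError, ordinal_patterns


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_shannon(x):
    x = np.asarray(x, float)
    n = x.size
    b = int(round(math.sqrt(n)))
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    width = (hi - lo) / b
    counts = [0] * b
    for v in x:
        idx = min(int((v - lo) / width), b - 1)
        counts[idx] += 1
    return -sum(c / n * math.log(c / n) for c in counts if c)


def oracle_pattern(window):
    # permutation sorting the window ascending, ties to the earlier sample
    return tuple(sorted(range(len(window)), key=lambda i: (window[i], i)))


def oracle_ordinal_counts(x, D, tau=1):
    counts, weights = Counter(), Counter()
    span = (D - 1) * tau
    for i in range(len(x) - span):
        w = [x[i + j * tau] for j in range(D)]
        sym = oracle_pattern(w)
        counts[sym] += 1
        mean = sum(w) / D
        weights[sym] += sum((v - mean) ** 2 for v in w) / D
    return counts, weights


def oracle_pe(x, D=4, tau=1):
    counts, _ = oracle_ordinal_counts(x, D, tau)
    n = sum(counts.values())
    return -sum(c / n * math.log(c / n) for c in counts.values())


def oracle_wpe(x, D=4, tau=1):
    _, weights = oracle_ordinal_counts(x, D, tau)
    tot = sum(weights.values())
    return -sum(w / tot * math.log(w / tot) for w in weights.values() if w > 0)


def oracle_corr_integral(x, m, eps):
    vecs = [x[i : i + m] for i in range(len(x) - m + 1)]
    close = total = 0
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            total += 1
            if max(abs(a - b) for a, b in zip(vecs[i], vecs[j])) < eps:
                close += 1
    return close / total


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

class TestShannonEntropy:
    def test_constant_series_has_zero_uncertainty(self):
        assert shannon_entropy(np.full(57, 3.14)) == 0.0

    def test_uniform_occupancy_attains_log_bins(self):
        vals = np.concatenate(
            [base + np.array([0.0, 0.1, 0.2, 0.3]) for base in (0, 1, 2, 3)]
        )
        assert shannon_entropy(vals) == pytest.approx(math.log(4), abs=1e-12)

    def test_matches_histogram_oracle(self, rng):
        x = rng.uniform(size=200)
        assert shannon_entropy(x) == pytest.approx(oracle_shannon(x), abs=1e-12)


# ---------------------------------------------------------------------------
# ordinal patterns / permutation entropies
# ---------------------------------------------------------------------------

class TestOrdinalPatterns:
    def test_monotone_series_single_symbol(self):
        dist = ordinal_patterns(np.arange(30.0), D=4)
        assert dist.counts == {(0, 1, 2, 3): 27}

    def test_single_window(self):
        dist = ordinal_patterns([1, 3, 2, 4, 5, 0, 7, 9][:8], D=4)
        # first window [1,3,2,4] sorts as positions (0,2,1,3)
        assert dist.counts[(0, 2, 1, 3)] >= 1

    def test_enumeration_oracle_small_series(self):
        x = [6, 9, 11, 12, 8, 13, 5, 2]
        dist = ordinal_patterns(x, D=3)
        counts, weights = oracle_ordinal_counts(x, 3)
        assert dist.counts == dict(counts)
        for sym, w in weights.items():
            assert dist.weights[sym] == pytest.approx(w, abs=1e-12)

    def test_symbol_count_conservation(self, rng):
        x = rng.normal(size=123)
        for tau in (1, 2, 3):
            dist = ordinal_patterns(x, D=4, tau=tau)
            assert dist.n_windows == 123 - 3 * tau
            assert len(dist.counts) <= math.factorial(4)


class TestPermutationEntropies:
    def test_monotone_is_zero(self):
        assert permutation_entropy(np.arange(50.0)) == 0.0
        assert weighted_permutation_entropy(np.arange(50.0)) == 0.0

    def test_equal_count_patterns_attain_log_count(self):
        # periodic 0,1,2,3 ramp: 4 distinct patterns, equal counts and
        # equal window variances -> PE = WPE = ln 4
        x = np.tile([0.0, 1.0, 2.0, 3.0], 11)[:43]
        assert permutation_entropy(x) == pytest.approx(math.log(4), abs=1e-12)
        assert weighted_permutation_entropy(x) == pytest.approx(
            permutation_entropy(x), abs=1e-12
        )

    def test_matches_enumeration_oracle_on_noise(self, rng):
        x = rng.normal(size=200)
        assert permutation_entropy(x) == pytest.approx(oracle_pe(x), abs=1e-12)
        assert weighted_permutation_entropy(x) == pytest.approx(
            oracle_wpe(x), abs=1e-12
        )

    def test_wpe_undefined_for_constant(self):
        with pytest.raises(UndefinedMetricError):
            weighted_permutation_entropy(np.zeros(30))

    def test_wpe_tracks_high_amplitude_segment(self, rng):
        quiet = 1e-3 * rng.normal(size=150)
        loud = 10.0 * np.tile([0.0, 1.0, 2.0, 3.0], 40)[:150]
        x = np.concatenate([quiet, loud])
        pe_loud = permutation_entropy(loud)
        assert abs(weighted_permutation_entropy(x) - pe_loud) < abs(
            permutation_entropy(x) - pe_loud
        )

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50),
           shift=st.floats(-20, 20))
    def test_affine_invariance(self, seed, scale, shift):
        x = np.random.default_rng(seed).normal(size=80)
        y = scale * x + shift
        assert permutation_entropy(y) == pytest.approx(
            permutation_entropy(x), abs=1e-10
        )
        assert weighted_permutation_entropy(y) == pytest.approx(
            weighted_permutation_entropy(x), abs=1e-10
        )
        assert shannon_entropy(y) == pytest.approx(shannon_entropy(x), abs=1e-10)

    def test_oracle_equivalence_battery(self):
        """SE/PE/WPE match brute force to 1e-10 on 100 random series."""
        rng = np.random.default_rng(77)
        for i in range(100):
            n = 50 if i % 2 else 200
            x = rng.normal(size=n) if i % 3 else rng.uniform(size=n)
            assert shannon_entropy(x) == pytest.approx(oracle_shannon(x), abs=1e-10)
            assert permutation_entropy(x) == pytest.approx(oracle_pe(x), abs=1e-10)
            assert weighted_permutation_entropy(x) == pytest.approx(
                oracle_wpe(x), abs=1e-10
            )

    def test_entropy_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 300))
            x = rng.normal(size=n)
            assert 0 <= shannon_entropy(x) <= math.log(round(math.sqrt(n))) + 1e-12
            assert 0 <= permutation_entropy(x) <= math.log(24) + 1e-12
            assert 0 <= weighted_permutation_entropy(x) <= math.log(24) + 1e-12


# ---------------------------------------------------------------------------
# correlation integral / BDS
# ---------------------------------------------------------------------------

class TestCorrelationIntegral:
    def test_everything_close_when_eps_exceeds_range(self, rng):
        x = rng.normal(size=40)
        assert correlation_integral(x, 3, eps=10 * np.ptp(x)) == 1.0

    def test_nothing_close_for_tiny_eps(self):
        x = np.arange(30.0)
        assert correlation_integral(x, 1, eps=1e-12) == 0.0

    def test_exhaustive_pair_count_oracle(self, rng):
        for _ in range(5):
            x = rng.integers(0, 6, size=12).astype(float)
            got = correlation_integral(x, 2, eps=1.5)
            assert got == pytest.approx(oracle_corr_integral(list(x), 2, 1.5))

    def test_exhaustive_oracle_larger_integer_series(self, rng):
        x = rng.integers(-4, 5, size=50).astype(float)
        for m, eps in [(1, 2.0), (2, 1.5), (3, 2.5)]:
            assert correlation_integral(x, m, eps) == pytest.approx(
                oracle_corr_integral(list(x), m, eps)
            )


class TestBDS:
    def test_exact_time_reversal_invariance(self, rng):
        for _ in range(5):
            x = rng.normal(size=150)
            assert bds_statistic(x) == pytest.approx(
                bds_statistic(x[::-1]), abs=1e-12
            )

    def test_logistic_map_strongly_rejects_iid(self):
        x = np.empty(500)
        x[0] = 0.3
        for i in range(1, 500):
            x[i] = 4 * x[i - 1] * (1 - x[i - 1])
        assert abs(bds_statistic(x)) > 3

    def test_agrees_with_independent_implementation(self):
        from statsmodels.tsa.stattools import bds as sm_bds

        rng = np.random.default_rng(5)
        for maker in (
            lambda: rng.normal(size=500),
            lambda: np.convolve(rng.normal(size=520), np.ones(4) / 4, "valid")[:500],
        ):
            x = maker()
            eps = 0.5 * x.std(ddof=1)
            ours = bds_statistic(x, m=2, eps=eps)
            theirs = float(np.asarray(sm_bds(x, max_dim=2, epsilon=eps)[0]))
            # conventions differ only in the finite-sample estimate of C_1
            assert abs(ours - theirs) <= 0.05 * abs(theirs) + 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            bds_statistic(np.ones(50))


# ---------------------------------------------------------------------------
# cohort-level feature extraction
# ---------------------------------------------------------------------------

def tiny_cohort(samples_by_cycle):
    cycles = [
        GaitCycle("s1", "left", i, "hip_sagittal", s)
        for i, s in enumerate(samples_by_cycle)
    ]
    return Cohort(cycles=cycles,
                  subjects={"s1": SubjectRecord("s1", "control", 8.0, 1.0)})


class TestComputeFeatures:
    def test_one_row_per_cycle_series(self, small_null_cohort):
        feats = compute_features(small_null_cohort)
        assert len(feats) == len(small_null_cohort)
        assert set(feats.columns) >= {"SE", "PE", "WPE", "BDS"}

    def test_identical_cycles_identical_features(self, rng):
        s = rng.normal(size=120)
        feats = compute_features(tiny_cohort([s, s.copy()]))
        a, b = feats.iloc[0], feats.iloc[1]
        for m in ("SE", "PE", "WPE", "BDS"):
            assert a[m] == b[m]

    def test_constant_cycle_yields_missing_not_crash(self, rng):
        feats = compute_features(
            tiny_cohort([rng.normal(size=100), np.full(100, 2.0)])
        )
        const_row = feats.iloc[1]
        assert const_row["SE"] == 0.0
        assert const_row["PE"] == 0.0
        assert np.isnan(const_row["WPE"])
        assert np.isnan(const_row["BDS"])

    def test_increments_mode_changes_bds_only(self, rng):
        cohort = tiny_cohort([rng.normal(size=150)])
        raw = compute_features(cohort)
        inc = compute_features(cohort, bds_increments=True)
        assert raw.loc[0, "PE"] == inc.loc[0, "PE"]
        assert raw.loc[0, "BDS"] != inc.loc[0, "BDS"]
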