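"""Tukey-fence outlier calling, checked against an independent brute-force
quantile oracle, plus the two-level OMP procedure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methylomp as M
from methylomp.data_io import DataValidationError
from methylomp.omp import QUANTILE_METHODS, tukey_limits


# ---------------------------------------------------------------------------
# Independent oracle: hand-rolled order-statistic quantiles + cell scan
# ---------------------------------------------------------------------------


def manual_quantile(values, q, method):
    xs = sorted(values)
    h = (len(xs) - 1) * q
    f, c = math.floor(h), math.ceil(h)
    if method == "linear":
        return xs[f] + (h - f) * (xs[c] - xs[f])
    if method == "lower":
        return xs[f]
    if method == "higher":
        return xs[c]
    if method == "midpoint":
        return (xs[f] + xs[c]) / 2.0
    raise AssertionError(method)


def brute_force_outliers(m, method):
    """Cell-by-cell scan against fences recomputed with manual quantiles."""
    out = {s: {} for s in m.sample_ids}
    for pid in m.probe_ids:
        row = m.df.loc[pid]
        vals = [v for v in row if not np.isnan(v)]
        if len(vals) < 4:
            continue
        q1 = manual_quantile(vals, 0.25, method)
        q3 = manual_quantile(vals, 0.75, method)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for s in m.sample_ids:
            v = row[s]
            if np.isnan(v):
                continue
            if v > hi:
                out[s][pid] = "hyper"
            elif v < lo:
                out[s][pid] = "hypo"
    return out


# ---------------------------------------------------------------------------
# compute_fences
# ---------------------------------------------------------------------------


class TestComputeFences:
    def test_hand_computed_linear_example(self):
        m = M.BetaMatrix.from_arrays(
            ["p"], list("abcd"), np.array([[0.1, 0.2, 0.3, 0.4]])
        )
        f = M.compute_fences(m, "linear")
        assert f.q1[0] == pytest.approx(0.175)
        assert f.q3[0] == pytest.approx(0.325)
        assert f.lower[0] == pytest.approx(-0.05)
        assert f.upper[0] == pytest.approx(0.55)

    def test_constant_probe_degenerate_fences(self):
        m = M.BetaMatrix.from_arrays(["p"], list("abcde"), np.full((1, 5), 0.5))
        f = M.compute_fences(m)
        assert f.lower[0] == f.upper[0] == 0.5

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=4, max_size=30),
        st.sampled_from(QUANTILE_METHODS),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_fence_identity_any_sample(self, values, method):
        """upper - q3 == 1.5 (q3 - q1) == q1 - lower, and ordering holds."""
        q1, q3, lo, hi = tukey_limits(np.array(values), method)
        assert hi - q3 == pytest.approx(1.5 * (q3 - q1))
        assert q1 - lo == pytest.approx(1.5 * (q3 - q1))
        assert lo <= q1 <= q3 <= hi

    def test_matches_manual_quantiles_all_methods(self):
        rng = np.random.default_rng(0)
        vals = rng.random((50, 9))
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(50)], [f"s{j}" for j in range(9)], vals
        )
        for method in QUANTILE_METHODS:
            f = M.compute_fences(m, method)
            for i in range(50):
                assert f.q1[i] == pytest.approx(manual_quantile(vals[i], 0.25, method))
                assert f.q3[i] == pytest.approx(manual_quantile(vals[i], 0.75, method))

    def test_too_few_samples_is_error(self):
        m = M.BetaMatrix.from_arrays(["p"], ["a", "b", "c"], np.full((1, 3), 0.5))
        with pytest.raises(DataValidationError, match=">= 4"):
            M.compute_fences(m)

    def test_sparse_probe_flagged_and_excluded(self):
        vals = np.full((2, 5), 0.5)
        vals[1, :3] = np.nan  # only 2 non-missing
        m = M.BetaMatrix.from_arrays(["good", "sparse"], list("abcde"), vals)
        f = M.compute_fences(m)
        assert list(f.probe_ids) == ["good"]
        assert f.excluded_probes == ["sparse"]

    def test_unknown_quantile_method_rejected(self):
        m = M.BetaMatrix.from_arrays(["p"], list("abcd"), np.full((1, 4), 0.5))
        with pytest.raises(DataValidationError, match="quantile method"):
            M.compute_fences(m, "nearest")


# ---------------------------------------------------------------------------
# call_outliers
# ---------------------------------------------------------------------------


class TestCallOutliers:
    @pytest.mark.parametrize("method", QUANTILE_METHODS)
    def test_matches_brute_force_oracle(self, method):
        """Cell-for-cell agreement with the independent scan, with missing."""
        rng = np.random.default_rng(7)
        vals = rng.random((200, 10))
        vals[rng.random((200, 10)) < 0.05] = np.nan
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(200)], [f"s{j}" for j in range(10)], vals
        )
        fences = M.compute_fences(m, method)
        profiles = M.call_outliers(m.select_probes(fences.probe_ids), fences)
        expected = brute_force_outliers(m, method)
        for prof in profiles:
            assert prof.outlier_probes == expected[prof.individual_id]

    def test_degenerate_fence_strict_inequality(self):
        vals = np.full((1, 6), 0.5)
        m = M.BetaMatrix.from_arrays(["p"], list("abcdef"), vals)
        fences = M.compute_fences(m)
        # at the fence: not an outlier
        assert M.call_outliers(m, fences)[0].n_outliers == 0
        vals2 = vals.copy()
        vals2[0, 0] = 0.5 + 1e-9  # epsilon above the degenerate fence
        m2 = M.BetaMatrix.from_arrays(["p"], list("abcdef"), vals2)
        prof = M.call_outliers(m2, fences)
        assert prof[0].outlier_probes == {"p": "hyper"}

    def test_all_inside_fences_empty_profiles(self, null_cohort):
        cord = null_cohort["cord"].select_probes(null_cohort["cord"].probe_ids[:50])
        fences = M.compute_fences(cord)
        wide = M.FenceTable(
            probe_ids=fences.probe_ids,
            q1=fences.q1, q3=fences.q3,
            lower=np.full_like(fences.lower, -1.0),
            upper=np.full_like(fences.upper, 2.0),
            n_used=fences.n_used,
        )
        assert all(p.n_outliers == 0 for p in M.call_outliers(cord, wide))

    def test_missing_beta_never_outlier_and_counted(self):
        vals = np.array([[0.1, 0.11, 0.12, 0.13, np.nan]])
        m = M.BetaMatrix.from_arrays(["p"], list("abcde"), vals)
        fences = M.compute_fences(m)
        prof = {p.individual_id: p for p in M.call_outliers(m, fences)}
        assert prof["e"].n_outliers == 0
        assert prof["e"].n_missing == 1

    def test_probe_without_fence_is_error(self):
        m = M.BetaMatrix.from_arrays(
            ["p", "q"], list("abcd"), np.full((2, 4), 0.5)
        )
        fences = M.compute_fences(m.select_probes(["p"]))
        with pytest.raises(DataValidationError, match="no fences"):
            M.call_outliers(m, fences)

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_monotonicity_raising_beta_never_lowers_count(self, data):
        """Against fixed fences, increasing one beta value cannot decrease
        that sample's outlier count."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        vals = rng.random((20, 6))
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(20)], list("abcdef"), vals
        )
        fences = M.compute_fences(m)
        base = {p.individual_id: p.n_outliers for p in M.call_outliers(m, fences)}
        i = data.draw(st.integers(0, 19))
        j = data.draw(st.integers(0, 5))
        bumped = vals.copy()
        bumped[i, j] = min(1.0, bumped[i, j] + data.draw(st.floats(0, 1)))
        m2 = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(20)], list("abcdef"), bumped
        )
        after = {p.individual_id: p.n_outliers for p in M.call_outliers(m2, fences)}
        sample = "abcdef"[j]
        assert after[sample] >= base[sample] - 1  # can lose at most the hypo status
        # strictly: the bumped cell can only move toward/over the upper fence
        assert after[sample] >= base[sample] - (
            1 if vals[i, j] < fences.lower[i] else 0
        )


# ---------------------------------------------------------------------------
# call_omp (count level)
# ---------------------------------------------------------------------------


def _profiles_from_counts(counts):
    return [
        M.OutlierProfile(
            individual_id=f"i{k}",
            hyper_probes=frozenset(f"p{j}" for j in range(c)),
            hypo_probes=frozenset(),
        )
        for k, c in enumerate(counts)
    ]


class TestCallOmp:
    def test_hand_computed_count_fence(self):
        result = M.call_omp(_profiles_from_counts([10, 11, 12, 100]), "linear")
        assert result.count_upper_limit == pytest.approx(68.875)
        assert result.omp_calls == {"i3"}

    def test_identical_counts_no_calls(self):
        result = M.call_omp(_profiles_from_counts([5, 5, 5, 5, 5]))
        assert result.count_upper_limit == 5
        assert result.omp_calls == set()

    def test_fewer_than_four_profiles_is_error(self):
        with pytest.raises(DataValidationError, match=">= 4"):
            M.call_omp(_profiles_from_counts([1, 2, 3]))

    def test_planted_cohort_recovered_exactly(self, small_cohort):
        cord, sheet, truth = (
            small_cohort["cord"], small_cohort["sheet"], small_cohort["truth"]
        )
        fences = M.compute_fences(cord)
        profiles = M.call_outliers(
            cord.select_probes(fences.probe_ids), fences, sheet.sample_to_individual()
        )
        result = M.call_omp(profiles)
        assert result.omp_calls == truth.planted_omp

    def test_leave_one_out_mode_on_planted_cohort(self, small_cohort):
        cord, sheet, truth = (
            small_cohort["cord"], small_cohort["sheet"], small_cohort["truth"]
        )
        fences = M.compute_fences(cord)
        profiles = M.call_outliers(
            cord.select_probes(fences.probe_ids), fences, sheet.sample_to_individual()
        )
        result = M.call_omp(profiles, leave_one_out=True)
        assert result.omp_calls == truth.planted_omp


# ---------------------------------------------------------------------------
# call_omp_external
# ---------------------------------------------------------------------------


class TestCallOmpExternal:
    def test_planted_individuals_confirmed_against_external(self, small_cohort):
        spec, truth = small_cohort["spec"], small_cohort["truth"]
        ref = M.simulate_external_reference(spec, truth, 7)
        ext = M.call_omp_external(
            small_cohort["cord"], ref,
            individual_ids=small_cohort["sheet"].sample_to_individual(),
        )
        assert truth.planted_omp <= ext.omp_calls
        assert ext.n_shared_probes == spec.n_probes

    def test_self_reference_matches_internal_calls(self, small_cohort):
        cord, sheet = small_cohort["cord"], small_cohort["sheet"]
        s2i = sheet.sample_to_individual()
        fences = M.compute_fences(cord)
        internal = M.call_omp(
            M.call_outliers(cord.select_probes(fences.probe_ids), fences, s2i)
        )
        ext = M.call_omp_external(cord, cord, individual_ids=s2i)
        assert ext.omp_calls == internal.omp_calls

    def test_reference_too_small_is_error(self, small_cohort):
        ref = M.simulate_external_reference(
            small_cohort["spec"], small_cohort["truth"], 3
        )
        with pytest.raises(DataValidationError, match=">= 4"):
            M.call_omp_external(small_cohort["cord"], ref)

    def test_shared_probe_floor_enforced(self, small_cohort):
        spec, truth = small_cohort["spec"], small_cohort["truth"]
        ref = M.simulate_external_reference(spec, truth, 7)
        tiny = ref.select_probes(ref.probe_ids[:50])
        with pytest.raises(DataValidationError, match="shared"):
            M.call_omp_external(small_cohort["cord"], tiny, min_shared_probes=100)
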