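"""Validation-metric oracles: matching, classification scores, timing
errors, FN imputation, stride-error propagation and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitevents import (agreement_stats, classification_scores, icc21,
                        impute_fn_errors, match_events, stride_param_errors,
                        summarize_stride_errors, timing_error_stats)


# ----------------------------------------------------------------------
# matching
# ----------------------------------------------------------------------

class TestMatching:
    def test_window_arithmetic_example(self):
        m = match_events(detected=[1.1, 2.3], reference=[1.0, 2.0], tw=0.5)
        assert m.pairs == [(1.0, 1.1)]
        assert m.fn_times == [2.0] and m.fp_times == [2.3]  # 0.3 > 0.25

    def test_identical_sets_all_tp(self):
        t = [1.0, 2.0, 3.0]
        m = match_events(t, t)
        assert m.tp == 3 and m.fn == m.fp == 0
        np.testing.assert_array_equal(m.errors, 0.0)

    def test_empty_detected_all_fn(self):
        m = match_events([], [1.0, 2.0])
        assert m.fn == 2 and m.tp == m.fp == 0

    def test_occlusion_exclusion_removes_reference_events(self):
        m = match_events([1.0], [1.0, 2.0], reference_excluded=[2.0])
        assert m.tp == 1 and m.fn == 0

    def test_counts_partition_always(self, rng):
        for _ in range(50):
            ref = np.sort(rng.uniform(0, 30, rng.integers(0, 15)))
            det = np.sort(rng.uniform(0, 30, rng.integers(0, 15)))
            m = match_events(det, ref)
            assert m.tp + m.fn == ref.size
            assert m.tp + m.fp == det.size
            assert all(abs(d - r) <= 0.25 + 1e-9 for r, d in m.pairs)

    def test_greedy_equals_optimal_in_gait_regime(self, rng):
        """When same-type events are spaced by more than the tolerance
        window (as in gait, where strides last ~1 s and TW = 0.5 s), each
        detection is feasible for at most one reference and greedy
        matching is provably optimal."""
        for _ in range(100):
            n = rng.integers(2, 12)
            ref = np.cumsum(rng.uniform(0.6, 1.5, n)) + 5
            jitter = rng.uniform(-0.2, 0.2, n)
            keep = rng.random(n) > 0.2
            det = np.sort(np.concatenate(
                [(ref + jitter)[keep], rng.uniform(0, 5, rng.integers(0, 3))]))
            m = match_events(det, ref)
            assert m.tp == _optimal_tp(det, ref, 0.5)

    def test_greedy_can_drop_one_pair_in_adversarial_overlap(self):
        """Documented divergence: with reference events exactly at the
        window spacing, greedy-nearest can sacrifice one pair relative to
        the exhaustive optimum — never more than one per overlap cluster."""
        ref = np.array([0.0, 0.9])
        det = np.array([-0.45, 0.4])
        m = match_events(det, ref, tw=1.0)  # tw/2 = 0.5
        assert m.tp == 1
        assert _optimal_tp(det, ref, 1.0) == 2

    def test_greedy_never_beats_optimal_dense(self, rng):
        for _ in range(100):
            ref = np.sort(rng.uniform(0, 4, rng.integers(1, 10)))
            det = np.sort(rng.uniform(0, 4, rng.integers(1, 10)))
            m = match_events(det, ref)
            opt = _optimal_tp(det, ref, 0.5)
            assert m.tp <= opt
            assert m.tp >= opt - max(1, opt // 2)


def _optimal_tp(detected, reference, tw):
    """Exhaustive maximum one-to-one matching inside the window
    (independent oracle via maximum bipartite matching)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching
    detected, reference = np.asarray(detected), np.asarray(reference)
    if detected.size == 0 or reference.size == 0:
        return 0
    ok = np.abs(reference[:, None] - detected[None, :]) <= tw / 2 + 1e-12
    if not ok.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(ok), perm_type="column")
    return int((match >= 0).sum())


# ----------------------------------------------------------------------
# scores
# ----------------------------------------------------------------------

class TestScores:
    def test_arithmetic_example(self):
        s, ppv, f1 = classification_scores((9, 1, 0))
        assert s == pytest.approx(0.9)
        assert ppv == 1.0
        assert f1 == pytest.approx(2 * 1.0 * 0.9 / 1.9)

    def test_perfect_detector(self):
        assert classification_scores((7, 0, 0)) == (1.0, 1.0, 1.0)

    def test_undefined_conventions(self):
        s, ppv, f1 = classification_scores((0, 0, 3))
        assert s is None and f1 is None and ppv == 0.0
        s, ppv, f1 = classification_scores((0, 3, 0))
        assert ppv is None and f1 is None and s == 0.0

    def test_random_triples_match_direct_formula(self, rng):
        for _ in range(1000):
            tp, fn, fp = rng.integers(0, 20, 3)
            s, ppv, f1 = classification_scores((int(tp), int(fn), int(fp)))
            if tp + fn:
                assert s == tp / (tp + fn)
            if tp + fp:
                assert ppv == tp / (tp + fp)
            if s is not None and ppv is not None and s + ppv > 0:
                assert f1 == pytest.approx(2 * s * ppv / (s + ppv))
                assert min(s, ppv) - 1e-12 <= f1 <= max(s, ppv) + 1e-12


# ----------------------------------------------------------------------
# timing errors
# ----------------------------------------------------------------------

class TestTimingErrors:
    def test_hand_computed_quantiles(self):
        me, iqre, mae = timing_error_stats(np.array([-20, -10, 0, 10, 20]) / 1e3)
        assert me == 0.0
        assert iqre == pytest.approx(0.020)
        assert mae == pytest.approx(0.010)

    def test_all_zero(self):
        assert timing_error_stats(np.zeros(5)) == (0.0, 0.0, 0.0)

    @given(st.lists(st.floats(-0.25, 0.25), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sign_flip_negates_bias_preserves_spread(self, errors):
        errors = np.asarray(errors)
        me, iqre, mae = timing_error_stats(errors)
        me2, iqre2, mae2 = timing_error_stats(-errors)
        assert me2 == pytest.approx(-me, abs=1e-12)
        assert iqre2 == pytest.approx(iqre, abs=1e-12)
        assert mae2 == pytest.approx(mae, abs=1e-12)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            timing_error_stats(np.array([]))


class TestImputation:
    def test_over_five_percent_missing_gets_worst_error(self):
        errors = np.full(9, 0.01)
        pool = np.array([0.01, -0.04, 0.02])
        out = impute_fn_errors(errors, 1, pool)  # 10% missing
        assert out.size == 10 and out[-1] == -0.04  # max magnitude, signed

    def test_under_five_percent_gets_mean(self):
        errors = np.full(98, 0.01)
        pool = np.array([0.03, 0.01])
        out = impute_fn_errors(errors, 2, pool)  # 2% missing
        assert out[-1] == pytest.approx(0.02)

    def test_no_fn_unchanged_and_empty_pool_fatal(self):
        e = np.array([0.01])
        assert impute_fn_errors(e, 0, np.array([])) is e
        with pytest.raises(ValueError):
            impute_fn_errors(e, 1, np.array([]))


# ----------------------------------------------------------------------
# stride errors
# ----------------------------------------------------------------------

def _table(ics, fcs, lengths, side="R"):
    import pandas as pd
    rows = []
    for k in range(len(ics) - 1):
        dur = ics[k + 1] - ics[k]
        rows.append({
            "side": side, "t_ic_start": ics[k], "t_fc": fcs[k],
            "t_ic_end": ics[k + 1], "duration_s": dur,
            "stance_s": fcs[k] - ics[k], "swing_s": ics[k + 1] - fcs[k],
            "length_m": lengths[k], "speed_mps": lengths[k] / dur,
            "condition": "SW",
        })
    return pd.DataFrame(rows)


class TestStrideErrors:
    def test_identical_tables_zero_errors(self):
        ref = _table([1.0, 2.1, 3.2], [1.7, 2.8], [1.3, 1.3])
        out = stride_param_errors(ref.copy(), ref)
        assert out["matched"].all()
        assert np.allclose(out["duration_err"], 0)
        summary = summarize_stride_errors(out)
        assert (summary["MAE"] == 0).all()
        assert (summary["frac_within_resolution"] == 1.0).all()

    def test_known_offset_propagates(self):
        ref = _table([1.0, 2.1, 3.2], [1.7, 2.8], [1.3, 1.3])
        det = _table([1.0, 2.11, 3.2], [1.7, 2.8], [1.3, 1.3])
        out = stride_param_errors(det, ref)
        errs = out["duration_err"].to_numpy()
        assert errs[0] == pytest.approx(0.01)   # first stride longer
        assert errs[1] == pytest.approx(-0.01)  # second shorter
        rel = out["duration_rel_err_pct"].to_numpy()
        assert rel[0] == pytest.approx(100 * 0.01 / 1.1)

    def test_missing_detection_counts_stride_missing(self):
        ref = _table([1.0, 2.1, 3.2], [1.7, 2.8], [1.3, 1.3])
        det = _table([1.0, 2.1], [1.7], [1.3])
        out = stride_param_errors(det, ref)
        assert out["matched"].tolist() == [True, False]

    def test_uniform_ic_shift_keeps_duration_moves_stance(self):
        ref = _table([1.0, 2.1, 3.2], [1.7, 2.8], [1.3, 1.3])
        det = _table([1.01, 2.11, 3.21], [1.7, 2.8], [1.3, 1.3])
        out = stride_param_errors(det, ref)
        assert np.allclose(out["duration_err"], 0, atol=1e-12)
        assert np.allclose(out["stance_err"], -0.01)
        assert np.allclose(out["swing_err"], +0.01)


# ----------------------------------------------------------------------
# agreement
# ----------------------------------------------------------------------

class TestAgreement:
    def test_identical_columns(self):
        x = np.array([1.0, 1.2, 1.4, 1.1, 1.3])
        rep = agreement_stats(x, x)
        assert rep.icc21 == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.bias == 0.0 and rep.rmse == 0.0
        assert rep.loa == (0.0, 0.0)

    def test_constant_offset(self):
        ref = np.array([1.0, 1.2, 1.4, 1.1])
        rep = agreement_stats(ref + 0.05, ref)
        assert rep.bias == pytest.approx(0.05)
        assert rep.rmse == pytest.approx(0.05)
        assert rep.loa[0] == pytest.approx(0.05) and rep.loa[1] == pytest.approx(0.05)

    def test_rmse_decomposition_identity(self, rng):
        for _ in range(30):
            d = rng.normal(size=rng.integers(3, 40))
            rep = agreement_stats(d, np.zeros_like(d))
            n = d.size
            lhs = rep.rmse ** 2
            sd = np.std(d, ddof=1)
            rhs = rep.bias ** 2 + sd ** 2 * (n - 1) / n
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_loa_bracket_bias_and_rho_bounds(self, rng):
        det = rng.normal(1.3, 0.1, 50)
        ref = det + rng.normal(0, 0.02, 50)
        rep = agreement_stats(det, ref)
        assert rep.loa[0] <= rep.bias <= rep.loa[1]
        assert -1 <= rep.spearman_rho <= 1
        assert rep.rmse >= abs(rep.bias)

    def test_icc_matches_pingouin_oracle(self, rng):
        """ICC(2,1) and its 95% CI against the independent ANOVA
        implementation in pingouin, on 50 random 30x2 tables."""
        import pandas as pd
        import pingouin as pg
        for _ in range(50):
            base = rng.normal(1.0, 0.3, 30)
            data = np.column_stack([base + rng.normal(0, 0.05, 30),
                                    base + rng.normal(0.02, 0.05, 30)])
            icc, ci = icc21(data)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile([0, 1], 30),
                "ratings": data.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings")
            row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-10)
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            # pingouin prints the CI rounded to two decimals
            assert ci[0] == pytest.approx(row[ci_col][0], abs=6e-3)
            assert ci[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_zero_variance_flagged(self):
        rep = agreement_stats(np.ones(5), np.ones(5))
        assert rep.icc21 is None
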