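"""Risk scores, percentile thresholds, Kaplan-Meier and log-rank oracles."""

import numpy as np
import pytest
from scipy import stats

from mfrsig.discovery import Signature
from mfrsig.evaluation import (
    evaluate_split,
    km_estimate,
    logrank_test,
    percentile_threshold,
    risk_scores,
    stratify,
)

from conftest import make_clinical, make_profile


def km_oracle(times, events):
    """Hand product-limit estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def logrank_oracle(t1, e1, t2, e2):
    """Observed-minus-expected tabulation over all event times (group 1)."""
    t1, t2 = np.asarray(t1, float), np.asarray(t2, float)
    e1, e2 = np.asarray(e1, bool), np.asarray(e2, bool)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(all_t[all_e]):
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        n = n1 + n2
        d = np.sum((all_t == t) & all_e)
        d1 = np.sum((t1 == t) & e1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return stat, float(stats.chi2.sf(stat, 1))


class TestRiskScores:
    def test_linear_predictor_definition(self):
        sig = Signature(("G000",), (float(np.log(2)),))
        prof = make_profile([[1.0], [0.0]])
        scores = risk_scores(sig, prof)
        assert scores["P000"] == pytest.approx(0.6931, abs=1e-4)
        assert scores["P001"] == 0.0

    def test_linearity_in_coefficients(self):
        rng = np.random.default_rng(0)
        prof = make_profile(rng.normal(size=(5, 3)))
        sig = Signature(tuple(prof.genes), (0.5, -1.0, 2.0))
        doubled = Signature(tuple(prof.genes), (1.0, -2.0, 4.0))
        s1 = risk_scores(sig, prof)
        s2 = risk_scores(doubled, prof)
        for p in prof.patients:
            assert s2[p] == pytest.approx(2 * s1[p])

    def test_missing_gene_rejected(self):
        sig = Signature(("NOPE",), (1.0,))
        with pytest.raises(ValueError):
            risk_scores(sig, make_profile(np.zeros((2, 1))))


class TestPercentileThreshold:
    def test_linear_interpolation_75th(self):
        assert percentile_threshold([1, 2, 3, 4], 75) == pytest.approx(3.25)

    def test_degenerate_and_boundary(self):
        assert percentile_threshold([5, 5, 5, 5], 75) == 5
        assert percentile_threshold([1, 2, 3, 9], 100) == 9

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([1, 2, 3], 75)


class TestStratify:
    def test_strict_threshold_and_tie_goes_low(self):
        groups = stratify({"A": 1.0, "B": 10.0, "C": 5.0}, 5.0)
        assert groups == {"A": "low", "B": "high", "C": "low"}

    def test_all_low_is_allowed(self):
        groups = stratify({"A": 1.0, "B": 2.0}, 5.0)
        assert set(groups.values()) == {"low"}

    def test_training_high_fraction_bounded(self):
        rng = np.random.default_rng(4)
        scores = {f"P{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        thr = percentile_threshold(scores.values(), 75)
        groups = stratify(scores, thr)
        n_high = sum(g == "high" for g in groups.values())
        assert n_high <= 50  # at most 25% above a strict 75th-percentile cut


class TestKaplanMeier:
    def test_two_subject_no_censoring(self):
        clin = make_clinical([1, 2], [True, True], ["A", "B"])
        curve = km_estimate({"A", "B"}, clin)
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_censor_shrinks_risk_set_without_step(self):
        # 5 subjects: censored at t=1, death at t=2 -> S(2) = 1 - 1/4
        clin = make_clinical([1, 2, 3, 3, 3], [False, True, False, False, False])
        curve = km_estimate(set(c.patient_id for c in clin), clin)
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(1.0)
        assert s[2.0] == pytest.approx(0.75)

    def test_all_censored_flat_curve(self):
        clin = make_clinical([3, 5, 8], [False] * 3)
        curve = km_estimate(set(c.patient_id for c in clin), clin)
        assert (curve.survival == 1.0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(set(), make_clinical([1], [True]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hand_product_limit_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        times = rng.integers(1, 8, size=n).astype(float)
        events = rng.random(n) < 0.7
        if not events.any():
            events[0] = True
        clin = make_clinical(times, events)
        curve = km_estimate({c.patient_id for c in clin}, clin)
        expected = km_oracle(times, events)
        got = dict(zip(curve.times, curve.survival))
        for t, s in expected.items():
            assert got[t] == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = [1, 2, 3, 4.0]
        events = [True, True, False, True]
        clin = make_clinical(times + times, events + events,
                             [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)])
        groups = {f"A{i}": "high" for i in range(4)} | {f"B{i}": "low" for i in range(4)}
        stat, p = logrank_test(groups, clin)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        # group A deaths at 1, 2; group B deaths at 3, 4
        clin = make_clinical([1, 2, 3, 4], [True] * 4, ["A1", "A2", "B1", "B2"])
        groups = {"A1": "high", "A2": "high", "B1": "low", "B2": "low"}
        stat, p = logrank_test(groups, clin)
        exp_stat, exp_p = logrank_oracle([1, 2], [True, True], [3, 4], [True, True])
        assert stat == pytest.approx(exp_stat, rel=1e-10)
        assert p == pytest.approx(exp_p, rel=1e-10)
        assert stat == pytest.approx(2.8824, abs=1e-4)  # frozen hand value

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(2)
        clin = make_clinical(rng.exponential(5, 20), rng.random(20) < 0.8)
        pats = [c.patient_id for c in clin]
        groups = {p: ("high" if i < 9 else "low") for i, p in enumerate(pats)}
        flipped = {p: ("low" if g == "high" else "high") for p, g in groups.items()}
        assert logrank_test(groups, clin)[0] == pytest.approx(logrank_test(flipped, clin)[0])

    def test_empty_group_rejected(self):
        clin = make_clinical([1, 2], [True, True], ["A", "B"])
        with pytest.raises(ValueError):
            logrank_test({"A": "high", "B": "high"}, clin)


def test_evaluate_split_end_to_end():
    rng = np.random.default_rng(5)
    n = 120
    x = rng.normal(size=(n, 1))
    h = 0.02 * np.exp(1.2 * x[:, 0])
    t = rng.exponential(1 / h)
    clin = make_clinical(t, np.ones(n, bool))
    prof = make_profile(x, log2_applied=True)
    sig = Signature(tuple(prof.genes), (1.2,))
    thr = percentile_threshold(risk_scores(sig, prof).values(), 75)
    strat = evaluate_split(sig, prof, clin, thr, "training")
    assert strat.n_high <= 30
    assert strat.logrank_p < 0.01  # strong planted effect separates groups
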