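"""Recurrence model, lifetime tree, and discounting."""

import numpy as np
import pytest

import uticea
from uticea.horizons import (EpisodeOutcomes, annuity_pv, discount_stream,
                             initial_state, prs_probability, run_long_term,
                             run_medium_term)

EP = EpisodeOutcomes(cost_uti=50.0, cost_no_uti=40.0,
                     qaly_loss_uti=0.01, qaly_loss_no_uti=0.005)


class TestDiscounting:
    def test_zero_rate_is_arithmetic_sum(self):
        assert discount_stream([1.0, 2.0, 3.0], 0.0) == 6.0

    def test_single_year_factor(self):
        assert discount_stream([0.0, 1.0], 0.035) \
            == pytest.approx(1 / 1.035)

    def test_constant_stream_matches_geometric_series(self):
        values = np.ones(25)
        rate = 0.035
        d = 1 / (1 + rate)
        expected = (1 - d ** 25) / (1 - d)
        assert discount_stream(values, rate) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_stream([1.0], -0.1)

    def test_annuity_fractional_years(self):
        rate = 0.035
        assert annuity_pv(3.0, rate) == pytest.approx(
            discount_stream([1, 1, 1], rate))
        assert annuity_pv(2.5, rate) == pytest.approx(
            discount_stream([1, 1, 0.5], rate))
        assert annuity_pv(4.0, 0.0) == 4.0


class TestScarringStep:
    @pytest.mark.parametrize("count,expected", [
        (0, 0.050), (1, 0.087), (2, 0.161), (3, 0.343), (4, 0.583),
        (7, 0.583),        # counts above four clamp to the four-attack row
    ])
    def test_published_step_function(self, point_params, count, expected):
        assert prs_probability(count, point_params) \
            == pytest.approx(expected, abs=1e-3)

    def test_negative_count_rejected(self, point_params):
        with pytest.raises(ValueError):
            prs_probability(-1, point_params)

    def test_non_decreasing_in_attack_count(self, point_params):
        probs = [prs_probability(k, point_params) for k in range(5)]
        assert probs == sorted(probs)


def _enumerate_paths(params, episodes, p_vur_treated, years=3):
    """Independent exhaustive enumeration of every annual outcome path.

    Walks the full branching tree (recurrence yes/no x attack yes/no x VUR
    destination) with plain recursion; no shared code with the cohort
    recursion it checks.
    """
    pa = float(params["pa_given_uti"])
    vur = float(params["vur_given_uti"])
    p_tgv = float(p_vur_treated) / vur if vur > 0 else 0.0
    c_hist = float(params["consult_uti_history"])
    rr = float(params["vur_treatment_effect"])
    rate = params.econ.discount_rate
    risk = {("none", 0): float(params["consult_uti_no_history"]),
            ("none", 1): c_hist, ("treated", 1): c_hist,
            ("untreated", 1): c_hist / rr}
    c_non = float(params["consult_no_uti"])
    proph = params.econ.costs["prophylaxis_annual"]

    totals = {"recurrences": 0.0, "cost": 0.0, "qaly_dec": 0.0,
              "pa_dist": np.zeros(5)}

    def walk(year, prob, hist, vur_state, k):
        if year > years:
            totals["pa_dist"][min(k, 4)] += prob
            return
        disc = (1 + rate) ** (-year)
        base = c_non * float(episodes.cost_no_uti) \
            + (proph if vur_state == "treated" else 0.0)
        totals["cost"] += prob * disc * base
        totals["qaly_dec"] += prob * disc * c_non * float(
            episodes.qaly_loss_no_uti)
        r = risk[(vur_state, hist)]
        # no recurrence this year
        walk(year + 1, prob * (1 - r), hist, vur_state, k)
        # recurrence: cost, possible attack, possible VUR detection
        totals["recurrences"] += prob * r
        totals["cost"] += prob * r * disc * float(episodes.cost_uti)
        totals["qaly_dec"] += prob * r * disc * float(episodes.qaly_loss_uti)
        if hist == 0:
            dests = [("none", 1 - vur), ("treated", vur * p_tgv),
                     ("untreated", vur * (1 - p_tgv))]
        elif vur_state == "untreated":
            dests = [("treated", p_tgv), ("untreated", 1 - p_tgv)]
        else:
            dests = [(vur_state, 1.0)]
        for dest, p_dest in dests:
            if p_dest == 0:
                continue
            walk(year + 1, prob * r * p_dest * pa, 1, dest, min(k + 1, 4))
            walk(year + 1, prob * r * p_dest * (1 - pa), 1, dest, k)

    init = initial_state(params, p_vur_treated)
    for hist in (0, 1):
        for vi, name in enumerate(("none", "untreated", "treated")):
            for k in range(5):
                p0 = float(init[hist, vi, k])
                if p0 > 0:
                    walk(1, p0, hist, name, k)
    return totals


def test_cohort_recursion_equals_exhaustive_enumeration(point_params):
    """The Markov cohort computation agrees exactly with brute-force path
    enumeration over the 3-year state space."""
    p_vur_treated = 0.003
    out = run_medium_term(point_params, EP, p_vur_treated)
    oracle = _enumerate_paths(point_params, EP, p_vur_treated)
    assert float(out.expected_recurrences) \
        == pytest.approx(oracle["recurrences"], rel=1e-12)
    assert float(out.cost) == pytest.approx(oracle["cost"], rel=1e-12)
    assert float(out.qaly_decrement) \
        == pytest.approx(oracle["qaly_dec"], rel=1e-12)
    assert np.allclose(out.pa_distribution, oracle["pa_dist"], rtol=1e-12)


def test_constant_risk_no_feedback_gives_three_p(point_params):
    """With one constant annual probability and no state feedback, the
    expected number of recurrences over 3 years is exactly 3p."""
    p = 0.05
    params = point_params.replace(consult_uti_no_history=p,
                                  consult_uti_history=p, vur_given_uti=0.0)
    out = run_medium_term(params, EP, p_vur_treated=0.0)
    assert float(out.expected_recurrences) == pytest.approx(3 * p, rel=1e-12)


def test_zero_recurrence_probability(point_params):
    params = point_params.replace(consult_uti_no_history=0.0,
                                  consult_uti_history=0.0, vur_given_uti=0.0)
    out = run_medium_term(params, EP, p_vur_treated=0.0)
    assert float(out.expected_recurrences) == 0.0


def test_recurrence_risks_by_vur_status(point_params):
    """History with no (or treated) VUR carries the published 0.080 annual
    risk; untreated VUR divides it by the prophylaxis relative risk."""
    from uticea.horizons import _recurrence_probs, _VUR_NONE, _VUR_TREATED, \
        _VUR_UNTREATED
    probs = _recurrence_probs(point_params)
    assert probs[(1, _VUR_NONE)] == pytest.approx(0.080, abs=1e-3)
    assert probs[(1, _VUR_TREATED)] == pytest.approx(0.080, abs=1e-3)
    assert probs[(1, _VUR_UNTREATED)] == pytest.approx(0.080 / 0.68, abs=2e-3)


def test_pa_distribution_sums_to_one(point_params):
    out = run_medium_term(point_params, EP, p_vur_treated=0.002)
    assert float(out.pa_distribution.sum()) == pytest.approx(1.0)


class TestLongTerm:
    def test_years_lived_closed_form(self, point_params):
        """Undiscounted expectation: (1-p) x 73 + p x (onset + mixture of
        dialysis/transplant survival)."""
        pa_dist = np.array([1.0, 0, 0, 0, 0])
        out = run_long_term(pa_dist, point_params)
        p = float(prs_probability(0, point_params)) * 0.050
        expected = (1 - p) * 73.0 + p * (13.67 + 0.5 * 12.25 + 0.5 * 21.6)
        assert float(out.years_lived) == pytest.approx(expected)
        assert float(out.p_esrd) == pytest.approx(p)

    def test_no_esrd_limit(self, point_params):
        params = point_params.replace(esrd_given_prs=0.0)
        out = run_long_term(np.array([1.0, 0, 0, 0, 0]), params)
        assert float(out.p_esrd) == 0.0
        assert float(out.years_lived) == pytest.approx(73.0)
        assert float(out.cost) == 0.0

    def test_zero_discount_full_utility_gives_years_lived(self, point_params):
        params = point_params.replace()
        params.econ.discount_rate = 0.0
        for key in ("baseline", "dialysis", "transplant"):
            params.econ.utilities[key] = 1.0
        out = run_long_term(np.array([0.8, 0.2, 0, 0, 0]), params)
        assert float(out.qaly) == pytest.approx(float(out.years_lived))

    def test_monotone_in_attack_count_mass(self, point_params):
        low = run_long_term(np.array([1.0, 0, 0, 0, 0]), point_params)
        high = run_long_term(np.array([0.0, 0, 0, 0, 1.0]), point_params)
        assert float(high.p_prs) > float(low.p_prs)
        assert float(high.cost) > float(low.cost)
        assert float(high.years_lived) < float(low.years_lived)
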