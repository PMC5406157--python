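"""NMB arithmetic, PSA behaviour, deterministic scenarios, population scaling."""

import numpy as np
import pandas as pd
import pytest

import uticea
from uticea.economics import (apply_scenario, evaluate_strategies,
                              intermediate_comparison, nmb, population_inmb,
                              run_deterministic_sa, run_psa, summarize)
from uticea.stratification import StratificationTable, post_lab_accuracy, \
    sampling_sensitivity


class TestNmb:
    def test_zero_everything(self):
        assert nmb(0.0, 0.0, 20000) == 0.0

    def test_direct_arithmetic(self):
        effect = 20.73 / 365.25
        assert nmb(44.06, effect, 20000) \
            == pytest.approx(effect * 20000 - 44.06)

    def test_nonpositive_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(1.0, 1.0, 0.0)

    def test_translation_invariance(self, point_params, table):
        """Adding a constant cost to every strategy leaves iNMB unchanged."""
        res = evaluate_strategies(point_params, table,
                                  ("clinical_judgment", "duty_5pct"))
        base = float(res["duty_5pct"].nmb_lifetime
                     - res["clinical_judgment"].nmb_lifetime)
        shifted = {s: float(r.nmb_lifetime) - 7.0 for s, r in res.items()}
        assert shifted["duty_5pct"] - shifted["clinical_judgment"] \
            == pytest.approx(base)


class TestPopulationScaling:
    def test_zero(self):
        assert population_inmb(0.0, 4_654_000) == 0.0

    def test_published_pairing(self):
        """£2.31 per child over the annual cohort is about £10.75M."""
        assert population_inmb(2.31, 4_654_000) / 1e6 \
            == pytest.approx(10.75, abs=0.01)

    def test_linearity(self):
        assert population_inmb(1.5, 2_000_000) \
            == 2 * population_inmb(1.5, 1_000_000)

    def test_bad_cohort_size(self):
        with pytest.raises(ValueError):
            population_inmb(1.0, 0)


class TestPsa:
    def test_same_seed_reproduces_bitwise(self, evidence, table):
        a = run_psa(("clinical_judgment", "duty_5pct"), 200, 9, evidence, table)
        b = run_psa(("clinical_judgment", "duty_5pct"), 200, 9, evidence, table)
        for s in a:
            assert np.array_equal(a[s].nmb_lifetime, b[s].nmb_lifetime)
            assert np.array_equal(a[s].short_cost, b[s].short_cost)

    def test_draw_count_validated(self, evidence, table):
        with pytest.raises(ValueError):
            run_psa(("clinical_judgment",), 0, 1, evidence, table)

    def test_reference_inmb_identically_zero(self, evidence, table):
        res = run_psa(("clinical_judgment", "duty_ge6"), 100, 4,
                      evidence, table)
        ref = res["clinical_judgment"]
        assert np.all(ref.nmb_lifetime - ref.nmb_lifetime == 0.0)
        frame = summarize(res)
        assert frame.loc["clinical_judgment", "inmb_lifetime"] == 0.0

    def test_psa_mean_of_linear_quantity_matches_closed_form(self, evidence,
                                                             table):
        """The sample-request probability is a product of independent
        draws, so its PSA mean equals the same formula evaluated at the
        posterior means (Beta and Dirichlet flat-prior means)."""
        from uticea.stratification import p_urine_sample_requested
        rng = np.random.default_rng(12)
        draws = evidence.sample(rng, size=20_000)
        strata = table.sample_stratum_probs(rng, size=20_000)
        p = p_urine_sample_requested("duty_5pct", draws, table, strata)
        # closed form at posterior means
        prev, vu = 61 / 2678, 134 / 2678
        m_u = (np.array([23, 12, 20]) + 1) / 58
        m_n = (np.array([2393, 52, 43]) + 1) / 2491
        expected = (1 - vu) * (prev * m_u[1:].sum()
                               + (1 - prev) * m_n[1:].sum())
        se = p.std(ddof=1) / np.sqrt(p.size)
        assert abs(p.mean() - expected) < 4 * se

    def test_identical_tables_give_zero_inmb(self, evidence, point_params):
        """If every strategy stratifies children identically, no strategy
        can differ from the reference."""
        rows = []
        base = StratificationTable.default()
        for s in uticea.STRATEGIES:
            for status in ("uti", "no_uti"):
                c = base.counts("clinical_judgment", status)
                rows.append({"strategy": s, "uti_status": status,
                             "lower": c[0], "intermediate": c[1],
                             "higher": c[2]})
        clone = StratificationTable(pd.DataFrame(rows))
        res = evaluate_strategies(point_params, clone)
        ref = res["clinical_judgment"]
        for s, r in res.items():
            assert float(r.nmb_lifetime) == pytest.approx(
                float(ref.nmb_lifetime), abs=1e-9)


class TestDeterministicScenarios:
    def test_unknown_scenario_rejected(self, point_params):
        with pytest.raises(KeyError):
            apply_scenario(8, point_params)

    def test_perfect_lab_collapses_cascade(self, point_params, table):
        """Scenario 2: post-laboratory sensitivity becomes sampling
        sensitivity x P(sample obtained) exactly."""
        p2 = apply_scenario(2, point_params)
        for s in uticea.STRATEGIES:
            sens, spec = post_lab_accuracy(s, p2, table)
            assert float(sens) == pytest.approx(
                float(sampling_sensitivity(s, table))
                * float(p2["urine_sample_obtained"]))
            assert float(spec) == pytest.approx(1.0)

    def test_prevalence_scenario_only_moves_mixture_weight(self, point_params,
                                                           table):
        """Scenario 1: the sample-request probability changes only through
        the prevalence weight in the status mixture."""
        p1 = apply_scenario(1, point_params)
        from uticea.stratification import p_urine_sample_requested
        got = float(p_urine_sample_requested("duty_5pct", p1, table))
        sens = float(sampling_sensitivity("duty_5pct", table))
        fpr = 1 - float(table.stratum_probs("duty_5pct", "no_uti")[0])
        expected = (1 - float(p1["very_unwell"])) * (
            0.10 * sens + 0.90 * fpr)
        assert got == pytest.approx(expected)

    def test_structural_ablation_removes_vur_and_attacks(self, evidence,
                                                         table):
        """Scenario 5: no VUR work-up, no pyelonephritis; every strategy has
        the same renal-sequelae profile."""
        p5 = apply_scenario(5, evidence.point_estimates())
        res = evaluate_strategies(p5, table,
                                  ("clinical_judgment", "duty_20pct"))
        for r in res.values():
            assert float(r.p_vur_treated) == 0.0
        assert float(res["duty_20pct"].p_esrd) == pytest.approx(
            float(res["clinical_judgment"].p_esrd))

    def test_doubled_esrd_cost_only_touches_long_term(self, evidence, table):
        frame = run_deterministic_sa(7, evidence, table,
                                     ("clinical_judgment",))
        assert frame.attrs["scenario"] == 7
        # short-term identical to an unmodified run; lifetime cost higher
        plain = summarize(evaluate_strategies(evidence.point_estimates(),
                                              table, ("clinical_judgment",)))
        assert frame.loc["clinical_judgment", "short_cost"] \
            == pytest.approx(plain.loc["clinical_judgment", "short_cost"])
        assert frame.loc["clinical_judgment", "lifetime_cost"] \
            > plain.loc["clinical_judgment", "lifetime_cost"]


class TestIntermediateComparison:
    def test_uti_share_of_intermediate_stratum(self, point_params, table):
        """18.8% of intermediate-risk children have UTI in the shipped
        high-specificity coefficient strategy."""
        m_u = table.stratum_probs("duty_5pct", "uti")[1]
        m_n = table.stratum_probs("duty_5pct", "no_uti")[1]
        prev = float(point_params["uti_prevalence"])
        share = prev * m_u / (prev * m_u + (1 - prev) * m_n)
        # the published 18.8% conditions prevalence on non-referral
        # (55/2543); the canonical composition here treats referral as
        # independent of status, hence the slightly higher share
        assert share == pytest.approx(0.188, abs=8e-3)

    def test_lab_arm_is_reference(self, point_params, table):
        out = intermediate_comparison(point_params, table)
        assert float(out["lab"]["inmb_vs_lab"]) == 0.0
        assert set(out) == set(uticea.ARMS)

    def test_dipstick_fraction_matches_obtain_probability(self, point_params,
                                                          table):
        out = intermediate_comparison(point_params, table)
        assert float(out["dipstick_land"]["p_dipsticked"]) \
            == pytest.approx(0.9567, abs=1e-4)
        assert float(out["lab"]["p_dipsticked"]) == 0.0
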