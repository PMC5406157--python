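"""Economic assembly: costs, QALYs, net monetary benefit, and sensitivity
analyses.

Per strategy the full pipeline is: decision tree (+ VUR work-up) -> acute
21-day model -> 3-year recurrence model -> lifetime tree.  Net monetary
benefit is ``effect x willingness-to-pay - cost``; incremental NMB compares
each strategy with clinical judgment on the same parameter draw (common
random numbers), so credible intervals reflect the paired design.
Probabilistic sensitivity analysis is fully vectorised: a draw axis runs
through every downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acute import AcuteStateSpace, ResolutionModel, run_acute
from .evidence import EvidenceBase, ParameterSet, load_parameters
from .horizons import EpisodeOutcomes, run_long_term, run_medium_term
from .pathway import ARMS, IntermediateArm, evaluate
from .stratification import STRATEGIES, StratificationTable

__all__ = [
    "REFERENCE_STRATEGY",
    "SCENARIOS",
    "StrategyResult",
    "nmb",
    "population_inmb",
    "evaluate_full",
    "evaluate_strategies",
    "run_psa",
    "summarize",
    "apply_scenario",
    "run_deterministic_sa",
    "intermediate_comparison",
]

REFERENCE_STRATEGY = "clinical_judgment"

#: Deterministic sensitivity-analysis scenarios.
SCENARIOS: dict[int, str] = {
    1: "UTI prevalence increased to 10%",
    2: "perfectly accurate NHS laboratory cultures",
    3: "doubled antibiotic treatment effect",
    4: "doubled disutility from UTI infection",
    5: "simpler model excluding VUR and pyelonephritis",
    6: "doubled probability of progressive renal scarring",
    7: "doubled cost of ESRD",
}


def nmb(cost, effect, wtp):
    """Net monetary benefit: effect (QALY) x willingness-to-pay - cost."""
    if np.any(np.asarray(wtp) <= 0):
        raise ValueError("willingness-to-pay must be > 0")
    return np.asarray(effect) * wtp - np.asarray(cost)


def population_inmb(per_child_inmb, annual_cohort_size: int):
    """Scale a per-child iNMB to the annual population figure (GBP)."""
    if annual_cohort_size <= 0:
        raise ValueError("cohort size must be > 0")
    return np.asarray(per_child_inmb) * annual_cohort_size


@dataclass
class StrategyResult:
    """Per-strategy outcomes at every horizon (scalars or draw arrays)."""

    strategy: str
    arm: str
    process_cost: np.ndarray        # diagnostic pathway cost per child
    short_cost: np.ndarray          # total 21-day health-service cost
    short_qald: np.ndarray
    asymptomatic_days: np.ndarray
    expected_recurrences: np.ndarray
    p_vur_treated: np.ndarray
    p_esrd: np.ndarray
    years_lived: np.ndarray
    lifetime_cost: np.ndarray
    lifetime_qaly: np.ndarray
    nmb_short: np.ndarray
    nmb_lifetime: np.ndarray
    categories: dict = field(default_factory=dict)
    antibiotic_for_uti_no_uti: np.ndarray | float = 0.0


def evaluate_full(strategy: str, params: ParameterSet,
                  table: StratificationTable, arm: str | IntermediateArm = "lab",
                  strata_draws=None) -> StrategyResult:
    """Run one strategy through every submodel for one parameter draw."""
    econ = params.econ
    u_asym = econ.utilities["asymptomatic"]
    gp = econ.costs["gp_consultation"]
    hospital = econ.costs["hospital_episode"]
    prev = params["uti_prevalence"]
    p_vu = params["very_unwell"]
    dpy = econ.days_per_year

    model = ResolutionModel.from_params(params)
    states = AcuteStateSpace.from_params(params)

    pw = evaluate(strategy, arm, params, table, strata_draws, model)
    acute = run_acute(pw, model, states, params)

    proc = (1 - p_vu) * (prev * pw.process_cost["uti"]
                         + (1 - prev) * pw.process_cost["no_uti"])
    short_cost = gp + acute.cost + proc + p_vu * hospital
    horizon = model.horizon_days

    # repeat presentations are costed identically to the index consultation
    ep = EpisodeOutcomes(
        cost_uti=gp + acute.by_status["uti"]["cost"]
        + (1 - p_vu) * pw.process_cost["uti"] + p_vu * hospital,
        cost_no_uti=gp + acute.by_status["no_uti"]["cost"]
        + (1 - p_vu) * pw.process_cost["no_uti"] + p_vu * hospital,
        qaly_loss_uti=(horizon * u_asym
                       - acute.by_status["uti"]["qald"]) / dpy,
        qaly_loss_no_uti=(horizon * u_asym
                          - acute.by_status["no_uti"]["qald"]) / dpy,
    )

    p_vur_treated = (1 - p_vu) * pw.p_vur_treated
    medium = run_medium_term(params, ep, p_vur_treated)
    lifetime = run_long_term(medium.pa_distribution, params)

    index_decrement = (horizon * u_asym - acute.qald) / dpy
    lifetime_cost = short_cost + medium.cost + lifetime.cost
    lifetime_qaly = lifetime.qaly - index_decrement - medium.qaly_decrement

    wtp = econ.willingness_to_pay
    return StrategyResult(
        strategy=strategy,
        arm=arm.mode if isinstance(arm, IntermediateArm) else arm,
        process_cost=proc,
        short_cost=short_cost,
        short_qald=acute.qald,
        asymptomatic_days=acute.asymptomatic_days,
        expected_recurrences=medium.expected_recurrences,
        p_vur_treated=p_vur_treated,
        p_esrd=lifetime.p_esrd,
        years_lived=lifetime.years_lived,
        lifetime_cost=lifetime_cost,
        lifetime_qaly=lifetime_qaly,
        nmb_short=nmb(short_cost, acute.qald / dpy, wtp),
        nmb_lifetime=nmb(lifetime_cost, lifetime_qaly, wtp),
        categories=pw.categories,
        antibiotic_for_uti_no_uti=pw.antibiotic_for_uti["no_uti"],
    )


def evaluate_strategies(params: ParameterSet, table: StratificationTable,
                        strategies=STRATEGIES, arm="lab", strata_draws=None
                        ) -> dict[str, StrategyResult]:
    return {s: evaluate_full(s, params, table, arm, strata_draws)
            for s in strategies}


def run_psa(strategies, draws: int, seed: int, evidence: EvidenceBase | None = None,
            table: StratificationTable | None = None, arm="lab"
            ) -> dict[str, StrategyResult]:
    """Probabilistic sensitivity analysis with common random numbers.

    One vectorised parameter draw of shape ``(draws,)`` is shared by every
    strategy, so per-draw iNMBs are paired differences.  Reproducible given
    ``seed``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    evidence = evidence or load_parameters()
    table = table or StratificationTable.default()
    rng = np.random.default_rng(seed)
    params = evidence.sample(rng, size=draws)
    strata_draws = table.sample_stratum_probs(rng, size=draws)
    return evaluate_strategies(params, table, strategies, arm, strata_draws)


def summarize(results: dict[str, StrategyResult],
              annual_cohort_size: int | None = None,
              reference: str = REFERENCE_STRATEGY) -> pd.DataFrame:
    """Mean outcomes and iNMB (with 95% credible intervals under PSA).

    iNMB is computed per draw against the reference strategy and then
    summarised; the reference row's iNMB is identically zero.
    """
    rows = []
    ref = results.get(reference)
    for name, res in results.items():
        row = {
            "strategy": name,
            "urine_sample_requested_pct": np.nan,
            "process_cost": float(np.mean(res.process_cost)),
            "short_cost": float(np.mean(res.short_cost)),
            "asymptomatic_days": float(np.mean(res.asymptomatic_days)),
            "short_qald": float(np.mean(res.short_qald)),
            "recurrences_per_10000_3yr": 1e4 * float(
                np.mean(res.expected_recurrences)),
            "pct_esrd": 100 * float(np.mean(res.p_esrd)),
            "years_lived": float(np.mean(res.years_lived)),
            "lifetime_cost": float(np.mean(res.lifetime_cost)),
            "lifetime_qaly": float(np.mean(res.lifetime_qaly)),
        }
        if ref is not None:
            for label, a, b in (("inmb_short", res.nmb_short, ref.nmb_short),
                                ("inmb_lifetime", res.nmb_lifetime,
                                 ref.nmb_lifetime)):
                diff = np.asarray(a) - np.asarray(b)
                row[label] = float(np.mean(diff))
                if diff.ndim and diff.size > 1:
                    # posterior (parameter-uncertainty) interval ...
                    row[f"{label}_lo"] = float(np.percentile(diff, 2.5))
                    row[f"{label}_hi"] = float(np.percentile(diff, 97.5))
                    # ... and the Monte-Carlo 95% CI of the mean, which is
                    # what shrinks ~1/sqrt(draws)
                    se = float(np.std(diff, ddof=1) / np.sqrt(diff.size))
                    row[f"{label}_se"] = se
                    row[f"{label}_mc_lo"] = row[label] - 1.96 * se
                    row[f"{label}_mc_hi"] = row[label] + 1.96 * se
                else:
                    row[f"{label}_lo"] = row[f"{label}_hi"] = row[label]
                    row[f"{label}_se"] = 0.0
                    row[f"{label}_mc_lo"] = row[f"{label}_mc_hi"] = row[label]
            if annual_cohort_size:
                row["inmb_annual_uk_m"] = float(population_inmb(
                    row["inmb_lifetime"], annual_cohort_size)) / 1e6
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("strategy")
    return frame.drop(columns=["urine_sample_requested_pct"])


def apply_scenario(scenario: int, params: ParameterSet) -> ParameterSet:
    """Return a copy of ``params`` with exactly one scenario modification."""
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; valid: 1..7")
    p = params.replace()
    if scenario == 1:
        p = p.replace(uti_prevalence=0.10)
    elif scenario == 2:
        p = p.replace(lab_sensitivity=1.0, lab_specificity=1.0)
    elif scenario == 3:
        p = p.replace(treatment_effect=params["treatment_effect"] / 2.0)
    elif scenario == 4:
        for key in ("symptomatic_uti", "pyelonephritis"):
            u = p.econ.utilities[key]
            p.econ.utilities[key] = max(0.0, 1.0 - 2.0 * (1.0 - u))
    elif scenario == 5:
        p = p.replace(referred_for_us=0.0, pa_given_uti=0.0,
                      vur_given_uti=0.0)
    elif scenario == 6:
        for k in range(5):
            name = f"prs_{k}pa"
            p = p.replace(**{name: min(1.0, 2.0 * float(params[name]))})
    elif scenario == 7:
        p.econ.costs["dialysis_annual"] *= 2.0
        p.econ.costs["transplant"] *= 2.0
    return p


def run_deterministic_sa(scenario: int, evidence: EvidenceBase | None = None,
                         table: StratificationTable | None = None,
                         strategies=STRATEGIES, arm="lab") -> pd.DataFrame:
    """Rerun all strategies at point estimates under one scenario."""
    evidence = evidence or load_parameters()
    table = table or StratificationTable.default()
    params = apply_scenario(scenario, evidence.point_estimates())
    results = evaluate_strategies(params, table, strategies, arm)
    frame = summarize(results, evidence.econ.annual_cohort_size)
    frame.attrs["scenario"] = scenario
    frame.attrs["description"] = SCENARIOS[scenario]
    return frame


def intermediate_comparison(params: ParameterSet, table: StratificationTable,
                            strategy: str = "duty_5pct", arms=ARMS
                            ) -> dict[str, dict]:
    """Compare treatment arms within one strategy's intermediate stratum.

    The cohort is restricted to intermediate-risk children (prevalence
    re-weighted accordingly, no hospital referrals), and each arm —
    laboratory-based delayed treatment or immediate dipstick-guided
    treatment — is run through the short-term pipeline.  iNMB is reported
    against the laboratory arm.
    """
    m_u = table.stratum_probs(strategy, "uti")[1]
    m_n = table.stratum_probs(strategy, "no_uti")[1]
    prev = params["uti_prevalence"]
    p_uti = prev * m_u / (prev * m_u + (1 - prev) * m_n)
    p_int = params.replace(uti_prevalence=p_uti,
                           very_unwell=0.0 * np.asarray(prev, dtype=float))
    pure_mid = {(strategy, "uti"): np.array([0.0, 1.0, 0.0]),
                (strategy, "no_uti"): np.array([0.0, 1.0, 0.0])}

    out: dict[str, dict] = {}
    model = ResolutionModel.from_params(p_int)
    states = AcuteStateSpace.from_params(p_int)
    gp = p_int.econ.costs["gp_consultation"]
    dpy = p_int.econ.days_per_year
    wtp = p_int.econ.willingness_to_pay
    for arm in arms:
        pw = evaluate(strategy, arm, p_int, table, pure_mid, model)
        acute = run_acute(pw, model, states, p_int)
        proc = (p_uti * pw.process_cost["uti"]
                + (1 - p_uti) * pw.process_cost["no_uti"])
        short_cost = gp + acute.cost + proc
        out[arm] = {
            "process_cost": proc,
            "short_cost": short_cost,
            "qald": acute.qald,
            "asymptomatic_days": acute.asymptomatic_days,
            "p_dipsticked": (p_uti * pw.p_dipsticked["uti"]
                             + (1 - p_uti) * pw.p_dipsticked["no_uti"]),
            "categories_uti": pw.categories["uti"],
            "antibiotic_for_uti_no_uti": pw.antibiotic_for_uti["no_uti"],
            "nmb_short": nmb(short_cost, acute.qald / dpy, wtp),
        }
    for arm in arms:
        out[arm]["inmb_vs_lab"] = out[arm]["nmb_short"] - out["lab"]["nmb_short"]
    return out
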