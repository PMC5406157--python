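"""Medium-term recurrence model and lifetime renal-sequelae tree.

The medium-term model is an annual-cycle cohort Markov model over the 3
years after the index consultation.  Each year a child may present with a
recurrent UTI (probability depending on UTI history and vesicoureteral
reflux status; prophylactic treatment of detected VUR multiplies the risk
by a relative risk < 1) and, independently, with a non-UTI acute illness.
Repeat presentations re-enter the diagnostic pathway at the same costs and
outcomes as the index consultation.  Each UTI episode carries a
pyelonephritic-attack risk; the cumulative attack count (capped at 4)
drives the probability of progressive renal scarring.

The lifetime tree converts the attack-count distribution into probabilities
of progressive renal scarring and end-stage renal disease, expected years
lived, and discounted lifetime cost and QALYs.  ESRD onsets at a triangular
age; half of cases are treated by dialysis (annual cost until death) and
half by transplant (one-off cost), with distinct survivals and utilities.
Scarring without ESRD carries no extra cost and no quality-of-life
decrement.  Costs and outcomes beyond the first year are discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import ParameterSet

__all__ = [
    "EpisodeOutcomes",
    "MediumTermOutcome",
    "LifetimeOutcome",
    "discount_stream",
    "annuity_pv",
    "prs_probability",
    "initial_state",
    "run_medium_term",
    "run_long_term",
]

_MAX_PA = 4          # attack counts above 4 use the 4-attack scarring row
_N_VUR = 3           # none / untreated / treated
_VUR_NONE, _VUR_UNTREATED, _VUR_TREATED = range(_N_VUR)


def discount_stream(values, rate: float):
    """Present value of a yearly stream; year 0 is undiscounted.

    ``PV = sum_t values[t] / (1+rate)**t``.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[-1])
    return (values / (1.0 + rate) ** t).sum(axis=-1)


def annuity_pv(years, rate: float):
    """PV of 1 per year paid at the start of years 0..years (fractional OK)."""
    years = np.asarray(years, dtype=float)
    if rate == 0:
        return years
    d = 1.0 / (1.0 + rate)
    n = np.floor(years)
    whole = (1.0 - d ** n) / (1.0 - d)
    return whole + (years - n) * d ** n


def prs_probability(pa_count: int, params: ParameterSet):
    """Probability of progressive renal scarring given an attack count."""
    if pa_count < 0:
        raise ValueError("pyelonephritic-attack count must be >= 0")
    k = min(int(pa_count), _MAX_PA)
    return params[f"prs_{k}pa"]


@dataclass
class EpisodeOutcomes:
    """Per-presentation cost and QALY loss of re-entering the pathway,
    identical to the index consultation for the same strategy."""

    cost_uti: float | np.ndarray
    cost_no_uti: float | np.ndarray
    qaly_loss_uti: float | np.ndarray
    qaly_loss_no_uti: float | np.ndarray


@dataclass
class MediumTermOutcome:
    expected_recurrences: float | np.ndarray
    pa_distribution: np.ndarray          # (..., 5) over 0..4+ attacks
    cost: float | np.ndarray             # discounted, years 1..3
    qaly_decrement: float | np.ndarray   # discounted, years 1..3
    p_vur_treated_final: float | np.ndarray


@dataclass
class LifetimeOutcome:
    p_prs: float | np.ndarray
    p_esrd: float | np.ndarray
    years_lived: float | np.ndarray
    cost: float | np.ndarray             # discounted ESRD treatment cost
    qaly: float | np.ndarray             # discounted lifetime QALY (baseline stream)


def _recurrence_probs(params: ParameterSet):
    """Annual UTI-presentation probability by (history, VUR status).

    Children with history and no VUR — or treated VUR — share the published
    risk; untreated VUR divides it by the prophylaxis relative risk.
    """
    c_hist = params["consult_uti_history"]
    rr = params["vur_treatment_effect"]
    return {
        (0, _VUR_NONE): params["consult_uti_no_history"],
        (1, _VUR_NONE): c_hist,
        (1, _VUR_UNTREATED): c_hist / rr,
        (1, _VUR_TREATED): c_hist,
    }


def initial_state(params: ParameterSet, p_vur_treated) -> np.ndarray:
    """Cohort distribution over (history, VUR, attack count) after year 0.

    Index UTI children carry history, a VUR assignment (treated when the
    index work-up confirmed it), and an index attack with the published
    probability; children without UTI start with no history.
    """
    prev = np.asarray(params["uti_prevalence"], dtype=float)
    pa = np.asarray(params["pa_given_uti"], dtype=float)
    vur = np.asarray(params["vur_given_uti"], dtype=float)
    p_tr = np.asarray(p_vur_treated, dtype=float)
    shape = np.broadcast_shapes(prev.shape, pa.shape, vur.shape, p_tr.shape)
    w = np.zeros(shape + (2, _N_VUR, _MAX_PA + 1))

    w[..., 0, _VUR_NONE, 0] = 1.0 - prev
    p_untr = np.clip(vur - p_tr, 0.0, None)
    p_none = 1.0 - vur
    for vi, pv in ((_VUR_NONE, p_none), (_VUR_UNTREATED, p_untr),
                   (_VUR_TREATED, p_tr)):
        w[..., 1, vi, 0] = prev * pv * (1.0 - pa)
        w[..., 1, vi, 1] = prev * pv * pa
    return w


def run_medium_term(params: ParameterSet, episodes: EpisodeOutcomes,
                    p_vur_treated, years: int | None = None
                    ) -> MediumTermOutcome:
    """Run the annual-cycle recurrence model over the medium-term horizon.

    Cycle ordering within a year: the recurrence event is resolved first,
    then the attack draw, then the state update (history gained, VUR
    assigned/detected).  At most one recurrence per child per year.
    """
    if years is None:
        years = params.medium_term_years
    pa = params["pa_given_uti"]
    vur = params["vur_given_uti"]
    p_tgv = np.where(np.asarray(vur) > 0,
                     np.asarray(p_vur_treated) / np.where(
                         np.asarray(vur) > 0, vur, 1.0), 0.0)
    rec = _recurrence_probs(params)
    rate = params.econ.discount_rate
    c_non = params["consult_no_uti"]
    prophylaxis = params.econ.costs["prophylaxis_annual"]

    w = initial_state(params, p_vur_treated)
    total_rec = np.zeros(w.shape[:-3])
    cost = np.zeros(w.shape[:-3])
    qaly_dec = np.zeros(w.shape[:-3])

    for year in range(1, years + 1):
        disc = (1.0 + rate) ** (-year)
        new_w = np.zeros_like(w)
        year_rec = np.zeros(w.shape[:-3])
        p_treated_now = w[..., :, _VUR_TREATED, :].sum(axis=(-2, -1))
        for hist in (0, 1):
            for vi in range(_N_VUR):
                r = rec.get((hist, vi))
                if r is None:          # no-history children have no VUR yet
                    continue
                for k in range(_MAX_PA + 1):
                    w0 = w[..., hist, vi, k]
                    new_w[..., hist, vi, k] += w0 * (1.0 - r)
                    ev = w0 * r
                    year_rec = year_rec + ev
                    k_up = min(k + 1, _MAX_PA)
                    # VUR assignment / detection during the episode
                    if hist == 0:
                        dest = ((_VUR_NONE, 1.0 - vur),
                                (_VUR_TREATED, vur * p_tgv),
                                (_VUR_UNTREATED, vur * (1.0 - p_tgv)))
                    elif vi == _VUR_UNTREATED:
                        dest = ((_VUR_TREATED, p_tgv),
                                (_VUR_UNTREATED, 1.0 - p_tgv))
                    else:
                        dest = ((vi, 1.0),)
                    for vj, pv in dest:
                        new_w[..., 1, vj, k_up] += ev * pv * pa
                        new_w[..., 1, vj, k] += ev * pv * (1.0 - pa)
        w = new_w
        total_rec = total_rec + year_rec
        year_cost = (year_rec * episodes.cost_uti
                     + c_non * episodes.cost_no_uti
                     + p_treated_now * prophylaxis)
        year_dec = (year_rec * episodes.qaly_loss_uti
                    + c_non * episodes.qaly_loss_no_uti)
        cost = cost + disc * year_cost
        qaly_dec = qaly_dec + disc * year_dec

    pa_dist = w.sum(axis=(-3, -2))
    return MediumTermOutcome(
        expected_recurrences=total_rec, pa_distribution=pa_dist,
        cost=cost, qaly_decrement=qaly_dec,
        p_vur_treated_final=w[..., :, _VUR_TREATED, :].sum(axis=(-2, -1)),
    )


def run_long_term(pa_distribution: np.ndarray,
                  params: ParameterSet) -> LifetimeOutcome:
    """Evaluate the lifetime tree from an attack-count distribution."""
    p_prs = sum(pa_distribution[..., k] * params[f"prs_{k}pa"]
                for k in range(_MAX_PA + 1))
    p_esrd = p_prs * params["esrd_given_prs"]

    onset = np.asarray(params["esrd_onset_age"], dtype=float)
    s_no = np.asarray(params["survival_no_esrd"], dtype=float)
    s_dial = np.asarray(params["survival_dialysis"], dtype=float)
    s_tx = np.asarray(params["survival_transplant"], dtype=float)
    f_tx = np.asarray(params["transplant_fraction"], dtype=float)

    rate = params.econ.discount_rate
    u = params.econ.utilities
    costs = params.econ.costs

    years_esrd = onset + (1.0 - f_tx) * s_dial + f_tx * s_tx
    years_lived = (1.0 - p_esrd) * s_no + p_esrd * years_esrd

    disc_onset = (1.0 + rate) ** (-onset)
    qaly_no = u["baseline"] * annuity_pv(s_no, rate)
    qaly_esrd = (u["baseline"] * annuity_pv(onset, rate)
                 + disc_onset * ((1.0 - f_tx) * u["dialysis"]
                                 * annuity_pv(s_dial, rate)
                                 + f_tx * u["transplant"]
                                 * annuity_pv(s_tx, rate)))
    qaly = (1.0 - p_esrd) * qaly_no + p_esrd * qaly_esrd

    cost_esrd = disc_onset * (
        (1.0 - f_tx) * costs["dialysis_annual"] * annuity_pv(s_dial, rate)
        + f_tx * costs["transplant"])
    cost = p_esrd * cost_esrd
    return LifetimeOutcome(p_prs=p_prs, p_esrd=p_esrd,
                           years_lived=years_lived, cost=cost, qaly=qaly)
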