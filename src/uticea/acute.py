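"""Acute illness: nine-state, single-day-cycle Markov model over 21 days.

Symptom resolution follows discrete hazards derived from Weibull survival
curves.  The treated-UTI hazard equals the untreated hazard divided by the
antibiotic treatment effect (a relative risk < 1, so treatment speeds
resolution) while the effect window is active; after the 7-day persistence
window treated and untreated probabilities coincide.  Resistant uropathogens
reduce the daily resolution probability by a multiplier; children whose
treatment is delayed pending a laboratory result follow the untreated hazard
for the first 2 days.  All symptoms resolve by day 21.

The cycle convention: state is evaluated at the end of each day; a child
resolving during day ``d`` is asymptomatic from day ``d+1`` onwards, so
resolution on day 1 yields 20 asymptomatic days within the 21-day horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import ParameterSet, ResolutionSettings

__all__ = [
    "ACUTE_GROUPS",
    "ResolutionModel",
    "AcuteStateSpace",
    "AcuteOutcome",
    "daily_resolution_probability",
    "resolution_schedule",
    "survival_curve",
    "group_outcome",
    "run_acute",
]

#: Resolution groups a child can occupy for the 21 acute days.
ACUTE_GROUPS: tuple[str, ...] = (
    "non_uti",              # symptomatic non-UTI illness
    "untreated",            # UTI, never treated
    "treated",              # UTI, appropriate antibiotic from day 1
    "resistant_uncorrected",  # UTI, resistant antibiotic, never corrected
    "resistant_corrected",  # UTI, resistant antibiotic corrected after culture
    "delayed",              # UTI, antibiotic started after laboratory result
)

#: Acute state occupied by each (group, phase); used for utility lookup.
_GROUP_STATE = {
    "non_uti": "symptomatic_non_uti",
    "untreated": "uti_untreated",
    "treated": "uti_treated_sensitive",
    "resistant_uncorrected": "uti_treated_resistant",
    "resistant_corrected": "uti_treated_resistant",
    "delayed": "uti_delayed_window",
}

_STATE_UTILITY_KEY = {
    "asymptomatic": "asymptomatic",
    "symptomatic_non_uti": "symptomatic_non_uti",
    "uti_untreated": "symptomatic_uti",
    "uti_treated_sensitive": "symptomatic_uti",
    "uti_treated_resistant": "symptomatic_uti",
    "uti_delayed_window": "symptomatic_uti",
    "pyelonephritis_untreated": "pyelonephritis",
    "pyelonephritis_treated": "pyelonephritis",
    "hospital": "hospital",
}


@dataclass
class ResolutionModel:
    """Daily resolution hazards for the acute phase.

    ``treatment_effect`` is the relative risk of remaining-symptomatic
    resolution for untreated versus treated children (< 1 means antibiotics
    accelerate recovery); ``resistant_multiplier`` scales the treated hazard
    down when the uropathogen is resistant to the prescribed antibiotic.
    Either may be a scalar or an array of PSA draws.
    """

    non_uti_shape: float
    non_uti_scale: float
    untreated_shape: float
    untreated_scale: float
    treatment_effect: float | np.ndarray = 0.55
    resistant_multiplier: float | np.ndarray = 0.70
    pyelonephritis_multiplier: float = 0.6
    delayed_window_days: int = 2
    effect_persistence_days: int = 7
    horizon_days: int = 21

    @classmethod
    def from_params(cls, params: ParameterSet) -> "ResolutionModel":
        r: ResolutionSettings = params.resolution
        return cls(
            non_uti_shape=r.non_uti_shape,
            non_uti_scale=r.non_uti_scale,
            untreated_shape=r.untreated_uti_shape,
            untreated_scale=r.untreated_uti_scale,
            treatment_effect=params["treatment_effect"],
            resistant_multiplier=params["resistant_effect_multiplier"],
            pyelonephritis_multiplier=r.pyelonephritis_hazard_multiplier,
            delayed_window_days=r.delayed_window_days,
            effect_persistence_days=r.effect_persistence_days,
            horizon_days=r.horizon_days,
        )

    # -- base discrete hazards --------------------------------------------
    def _weibull_hazard(self, shape: float, scale: float,
                        days: np.ndarray) -> np.ndarray:
        s_prev = np.exp(-((days - 1.0) / scale) ** shape)
        s_now = np.exp(-(days / scale) ** shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            h = 1.0 - s_now / s_prev
        # survival underflow: resolution is certain once S has vanished
        return np.where(s_prev > 0.0, h, 1.0)

    def _schedules(self):
        """Per-day resolution probabilities for every group.

        Returns a dict group -> array of shape ``(..., horizon)`` where the
        leading axes broadcast over PSA draws.
        """
        days = np.arange(1, self.horizon_days + 1, dtype=float)
        h_non = self._weibull_hazard(self.non_uti_shape, self.non_uti_scale, days)
        h_untr = self._weibull_hazard(self.untreated_shape,
                                      self.untreated_scale, days)

        rr = np.asarray(self.treatment_effect)[..., None]
        mult = np.asarray(self.resistant_multiplier)[..., None]
        in_window = days <= self.effect_persistence_days
        in_delay = days <= self.delayed_window_days

        h_treated = np.where(in_window, np.minimum(h_untr / rr, 1.0), h_untr)
        h_resistant = np.where(in_window,
                               np.minimum(mult * h_untr / rr, 1.0), h_untr)
        h_delayed = np.where(in_delay, h_untr * np.ones_like(h_treated),
                             h_treated)
        h_corrected = np.where(in_delay, h_resistant, h_treated)

        sched = {
            "non_uti": np.broadcast_to(
                h_non, np.broadcast_shapes(h_non.shape, h_treated.shape)).copy(),
            "untreated": np.broadcast_to(
                h_untr, np.broadcast_shapes(h_untr.shape, h_treated.shape)).copy(),
            "treated": h_treated,
            "resistant_uncorrected": h_resistant,
            "resistant_corrected": h_corrected,
            "delayed": h_delayed,
        }
        for g in sched:
            sched[g][..., -1] = 1.0  # all symptoms resolve by day 21
        return sched


def resolution_schedule(model: ResolutionModel, group: str,
                        pyelonephritis: bool = False) -> np.ndarray:
    """Daily resolution probabilities, shape ``(..., horizon_days)``."""
    if group not in ACUTE_GROUPS:
        raise KeyError(f"unknown acute group {group!r}")
    sched = model._schedules()[group]
    if pyelonephritis:
        sched = sched * model.pyelonephritis_multiplier
        sched[..., -1] = 1.0
    return sched


def daily_resolution_probability(model: ResolutionModel, group: str,
                                 day: int, pyelonephritis: bool = False):
    """P(resolve during `day` | unresolved at its start); day in 1..horizon."""
    if not 1 <= day <= model.horizon_days:
        raise ValueError(f"day must be in 1..{model.horizon_days}, got {day}")
    sched = resolution_schedule(model, group, pyelonephritis)
    out = sched[..., day - 1]
    return float(out) if np.ndim(out) == 0 else out


def survival_curve(model: ResolutionModel, group: str,
                   pyelonephritis: bool = False) -> np.ndarray:
    """P(still symptomatic at end of day d), d = 0..horizon; S(horizon)=0."""
    sched = resolution_schedule(model, group, pyelonephritis)
    surv = np.cumprod(1.0 - sched, axis=-1)
    s0 = np.ones_like(surv[..., :1])
    return np.concatenate([s0, surv], axis=-1)


class AcuteStateSpace:
    """The ordered nine acute health states with utilities and daily costs."""

    def __init__(self, names: tuple[str, ...], utilities: dict[str, float],
                 daily_costs: dict[str, float] | None = None):
        if len(names) != 9:
            raise ValueError("acute state space must have exactly nine states")
        self.names = tuple(names)
        self.utilities = {
            s: utilities[_STATE_UTILITY_KEY[s]] for s in self.names
        }
        self.daily_costs = {s: (daily_costs or {}).get(s, 0.0)
                            for s in self.names}
        u_asym = self.utilities["asymptomatic"]
        for s, u in self.utilities.items():
            if u > u_asym:
                raise ValueError(
                    f"state {s!r} utility exceeds asymptomatic utility")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "AcuteStateSpace":
        return cls(params.acute_states, params.econ.utilities)


@dataclass
class AcuteOutcome:
    """Cohort-average acute results over the 21-day horizon."""

    asymptomatic_days: float | np.ndarray
    qald: float | np.ndarray
    cost: float | np.ndarray
    by_status: dict


def group_outcome(model: ResolutionModel, group: str, states: AcuteStateSpace,
                  pyelonephritis: bool = False, hospital: bool = False):
    """(asymptomatic days, QALD, expected symptomatic days) for one group."""
    surv = survival_curve(model, group, pyelonephritis)  # (..., horizon+1)
    s_start = surv[..., :-1]                             # S at start of day d
    sympt_days = s_start.sum(axis=-1)
    asympt_days = model.horizon_days - sympt_days
    if hospital:
        state = "hospital"
    elif pyelonephritis:
        state = ("pyelonephritis_treated"
                 if group in ("treated", "resistant_uncorrected",
                              "resistant_corrected")
                 else "pyelonephritis_untreated")
    else:
        state = _GROUP_STATE[group]
    u_sym = states.utilities[state]
    u_asym = states.utilities["asymptomatic"]
    qald = asympt_days * u_asym + sympt_days * u_sym
    daily_cost = states.daily_costs[state]
    cost = sympt_days * daily_cost
    return asympt_days, qald, cost


def occupancy(model: ResolutionModel, group_weights: dict[str, float],
              states: AcuteStateSpace, pyelonephritis_fraction=0.0
              ) -> np.ndarray:
    """Start-of-day occupancy over the nine states, shape (horizon, 9).

    Aggregates the per-group survival curves onto the configured state
    space; each row sums to 1 (the Markov row-stochastic invariant).
    Scalar weights only (reporting/diagnostic use).
    """
    occ = np.zeros((model.horizon_days, len(states.names)))
    idx = {s: i for i, s in enumerate(states.names)}
    pa = pyelonephritis_fraction
    for group, w in group_weights.items():
        if w == 0:
            continue
        for is_pa, w_pa in ((False, w * (1 - pa)), (True, w * pa)):
            surv = survival_curve(model, group, is_pa)[: model.horizon_days]
            if is_pa and group != "non_uti":
                state = ("pyelonephritis_treated"
                         if group in ("treated", "resistant_uncorrected",
                                      "resistant_corrected")
                         else "pyelonephritis_untreated")
            else:
                state = _GROUP_STATE[group]
            # delayed-window children move to the treated state after day 2
            for d in range(model.horizon_days):
                st = state
                if group == "delayed" and not is_pa \
                        and d >= model.delayed_window_days:
                    st = "uti_treated_sensitive"
                if group == "resistant_corrected" and not is_pa \
                        and d >= model.delayed_window_days:
                    st = "uti_treated_sensitive"
                occ[d, idx[st]] += w_pa * surv[d]
                occ[d, idx["asymptomatic"]] += w_pa * (1.0 - surv[d])
    return occ


def run_acute(pathway, model: ResolutionModel, states: AcuteStateSpace,
              params: ParameterSet) -> AcuteOutcome:
    """Convert a pathway allocation into acute outcomes and costs.

    ``pathway`` supplies per-status acute-group fractions (conditional on
    not being referred very unwell).  Very unwell children occupy the
    hospital state with the treated (UTI) or non-UTI resolution curve.
    The acute cost comprises reconsultations plus any per-state daily costs;
    diagnostic process costs live on the pathway itself.
    """
    prev = params["uti_prevalence"]
    p_vu = params["very_unwell"]
    pa = params["pa_given_uti"]
    u = params.econ.utilities
    gp_cost = params.econ.costs["gp_consultation"]
    p_recon = params["reconsultation"]

    horizon = model.horizon_days
    by_status: dict[str, dict] = {}

    # UTI children not referred: mixture over acute groups, PA split
    a_uti = q_uti = c_uti = 0.0
    for group, w in pathway.acute_groups["uti"].items():
        a0, q0, c0 = group_outcome(model, group, states, pyelonephritis=False)
        a1, q1, c1 = group_outcome(model, group, states, pyelonephritis=True)
        a_uti = a_uti + w * ((1 - pa) * a0 + pa * a1)
        q_uti = q_uti + w * ((1 - pa) * q0 + pa * q1)
        c_uti = c_uti + w * ((1 - pa) * c0 + pa * c1)

    # non-UTI children not referred
    a_no, q_no, c_no = group_outcome(model, "non_uti", states)

    # very unwell children: hospital state, immediate treatment
    a_vu_uti, q_vu_uti, c_vu_uti = group_outcome(
        model, "treated", states, hospital=True)
    a_vu_no, q_vu_no, c_vu_no = group_outcome(
        model, "non_uti", states, hospital=True)

    recon_cost = p_recon * gp_cost
    a_u = (1 - p_vu) * a_uti + p_vu * a_vu_uti
    q_u = (1 - p_vu) * q_uti + p_vu * q_vu_uti
    c_u = (1 - p_vu) * c_uti + p_vu * c_vu_uti + recon_cost
    a_n = (1 - p_vu) * a_no + p_vu * a_vu_no
    q_n = (1 - p_vu) * q_no + p_vu * q_vu_no
    c_n = (1 - p_vu) * c_no + p_vu * c_vu_no + recon_cost

    by_status["uti"] = {"asymptomatic_days": a_u, "qald": q_u, "cost": c_u,
                        "asymptomatic_days_not_referred": a_uti,
                        "qald_not_referred": q_uti}
    by_status["no_uti"] = {"asymptomatic_days": a_n, "qald": q_n, "cost": c_n,
                           "asymptomatic_days_not_referred": a_no,
                           "qald_not_referred": q_no}

    asympt = prev * a_u + (1 - prev) * a_n
    qald = prev * q_u + (1 - prev) * q_n
    cost = prev * c_u + (1 - prev) * c_n
    return AcuteOutcome(asymptomatic_days=asympt, qald=qald, cost=cost,
                        by_status=by_status)
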