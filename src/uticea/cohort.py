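"""Synthetic patient-level data and the microsimulation oracle.

Generates children with the statistical structure the cohort model assumes
— UTI status at the configured prevalence, per-strategy risk strata drawn
from status-conditional multinomials, binary dipstick/laboratory results at
the configured accuracies, resistance and reflux flags, and latent uniform
draws for every downstream branch — then walks each child through exactly
the same branch logic as the cohort decision tree.  Empirical category
fractions and acute outcomes converge to the analytic cohort values, which
is what makes the microsimulation an independent oracle.

Also provides symptom-diary generation (daily resolved/unresolved records
right-censored at 14 days) and a censoring-aware Weibull fit used to
recover resolution parameters from such diaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acute import ResolutionModel, survival_curve
from .evidence import ParameterSet
from .pathway import CATEGORIES, IntermediateArm
from .stratification import StratificationTable

__all__ = [
    "MicrosimResult",
    "WeibullFit",
    "generate_cohort",
    "simulate_patients",
    "generate_diaries",
    "fit_weibull",
]


def _fingerprint(params: ParameterSet) -> tuple:
    keys = ("uti_prevalence", "very_unwell", "urine_sample_obtained",
            "contamination", "lab_sensitivity", "lab_specificity")
    return tuple(float(np.asarray(params[k]).ravel()[0]) for k in keys)


def generate_cohort(n: int, params: ParameterSet, table: StratificationTable,
                    seed: int) -> pd.DataFrame:
    """Generate ``n`` synthetic children; reproducible given ``seed``.

    Dipstick and laboratory results are conditionally independent given UTI
    status (only marginal accuracies are configured).  Latent uniforms
    (``u_*`` columns) drive the serendipitous-antibiotic, stop-call and
    symptom-resolution branches so the same child follows a coherent path
    under every strategy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prev = float(params["uti_prevalence"])
    uti = rng.random(n) < prev
    cohort = pd.DataFrame({
        "child": np.arange(n),
        "uti": uti,
        "very_unwell": rng.random(n) < float(params["very_unwell"]),
        "pa": uti & (rng.random(n) < float(params["pa_given_uti"])),
        "vur": uti & (rng.random(n) < float(params["vur_given_uti"])),
        "first_obtained": rng.random(n) < float(params["urine_sample_obtained"]),
        "first_contaminated": rng.random(n) < float(params["contamination"]),
        "repeat_obtained": rng.random(n) < float(params["urine_sample_obtained"]),
        "repeat_contaminated": rng.random(n) < float(params["contamination"]),
        "resistant_trimethoprim": uti & (
            rng.random(n) < float(params["resistance_trimethoprim"])),
        "resistant_amoxicillin": uti & (
            rng.random(n) < float(params["resistance_amoxicillin"])),
    })
    for test, se, sp in (
            ("lab_pos", "lab_sensitivity", "lab_specificity"),
            ("dip_lorn_pos", "dipstick_lorn_sensitivity",
             "dipstick_lorn_specificity"),
            ("dip_land_pos", "dipstick_land_sensitivity",
             "dipstick_land_specificity")):
        p = np.where(uti, float(params[se]), 1.0 - float(params[sp]))
        cohort[test] = rng.random(n) < p
    for stratgy in table.strategies:
        probs_u = table.stratum_probs(stratgy, "uti")
        probs_n = table.stratum_probs(stratgy, "no_uti")
        u = rng.random(n)
        cum_u, cum_n = np.cumsum(probs_u), np.cumsum(probs_n)
        stratum = np.where(uti,
                           np.searchsorted(cum_u, u),
                           np.searchsorted(cum_n, u)).clip(0, 2)
        cohort[f"stratum_{stratgy}"] = stratum.astype(np.int8)
    for name in ("u_serendip", "u_stop", "u_refer_us", "u_us", "u_resolve"):
        cohort[name] = rng.random(n)
    cohort.attrs["seed"] = seed
    cohort.attrs["param_fingerprint"] = _fingerprint(params)
    return cohort


@dataclass
class MicrosimResult:
    """Empirical pathway fractions and acute outcomes from patient walks."""

    strategy: str
    arm: str
    n: int
    n_uti: int
    categories: dict            # status -> {category: empirical fraction}
    p_sample_requested: float
    antibiotic_for_uti_no_uti: float
    asymptomatic_days: float
    qald: float
    by_status: dict
    sem_asymptomatic_days: float
    sem_qald: float


def simulate_patients(cohort: pd.DataFrame, strategy: str,
                      arm: IntermediateArm | str,
                      params: ParameterSet) -> MicrosimResult:
    """Walk every child through the branch logic of one strategy/arm.

    Mirrors the cohort decision tree exactly: higher risk treated
    immediately with culture-based correction/stop, intermediate risk per
    arm with a 2-day review for children without a sample, lower risk
    serendipitously.  Returns empirical category fractions (conditional on
    not being referred very unwell) and acute outcomes including referred
    children.
    """
    if isinstance(arm, str):
        arm = IntermediateArm(arm)
    if cohort.attrs.get("param_fingerprint") != _fingerprint(params):
        warnings.warn("cohort was generated under different parameters",
                      stacklevel=2)
    model = ResolutionModel.from_params(params)
    p_ab = float(params["antibiotics_for_non_uti"])
    p_stop = float(params["stop_antibiotic_no_uti"])

    n = len(cohort)
    uti = cohort["uti"].to_numpy()
    vu = cohort["very_unwell"].to_numpy()
    stratum = cohort[f"stratum_{strategy}"].to_numpy()
    first_ok = cohort["first_obtained"].to_numpy()
    usable = (first_ok & ~cohort["first_contaminated"].to_numpy()) | (
        first_ok & cohort["first_contaminated"].to_numpy()
        & cohort["repeat_obtained"].to_numpy()
        & ~cohort["repeat_contaminated"].to_numpy())
    lab_pos = cohort["lab_pos"].to_numpy()
    r_tri = cohort["resistant_trimethoprim"].to_numpy()
    r_amox = cohort["resistant_amoxicillin"].to_numpy()
    serendip = cohort["u_serendip"].to_numpy() < p_ab
    u_resolve = cohort["u_resolve"].to_numpy()

    s_untr2 = float(survival_curve(model, "untreated")[..., 2])
    s_non2 = float(survival_curve(model, "non_uti")[..., 2])
    # resolved by end of day d  <=>  u_resolve >= S(d)
    unresolved_day2 = np.where(uti, u_resolve < s_untr2, u_resolve < s_non2)

    group = np.full(n, "untreated", dtype=object)
    group[~uti] = "non_uti"
    category = np.full(n, "no_antibiotic", dtype=object)
    treated_for_uti = np.zeros(n, dtype=bool)
    nvu = ~vu

    confirmed = usable & lab_pos

    # ---- higher risk -----------------------------------------------------
    hi = nvu & (stratum == 2)
    m = hi & uti & ~r_tri
    group[m], category[m] = "treated", "immediate_appropriate"
    m = hi & uti & r_tri
    category[m] = "inappropriate"
    group[m & confirmed] = "resistant_corrected"
    group[m & ~confirmed] = "resistant_uncorrected"
    m = hi & ~uti
    category[m] = "inappropriate"
    stopped = usable & ~lab_pos & (cohort["u_stop"].to_numpy() < p_stop)
    treated_for_uti[m] = ~stopped[m]

    # ---- intermediate risk ----------------------------------------------
    mid = nvu & (stratum == 1)
    if arm.uses_dipstick:
        col = "dip_lorn_pos" if arm.mode == "dipstick_lorn" else "dip_land_pos"
        dip_pos = cohort[col].to_numpy()
        tested = mid & first_ok
        pos = tested & dip_pos
        m = pos & uti & ~r_tri
        group[m], category[m] = "treated", "immediate_appropriate"
        m = pos & uti & r_tri
        category[m] = "inappropriate"
        group[m & confirmed] = "resistant_corrected"
        group[m & ~confirmed] = "resistant_uncorrected"
        m = pos & ~uti
        category[m] = "inappropriate"
        treated_for_uti[m] = ~stopped[m]
        neg = tested & ~dip_pos
        m = neg & confirmed & uti
        group[m], category[m] = "delayed", "lab_informed_appropriate"
        m = neg & confirmed & ~uti
        category[m] = "lab_informed_appropriate"
        treated_for_uti[m] = True
        review = mid & ~first_ok
    else:
        m = mid & confirmed & uti
        group[m], category[m] = "delayed", "lab_informed_appropriate"
        m = mid & confirmed & ~uti
        category[m] = "lab_informed_appropriate"
        treated_for_uti[m] = True
        review = mid & ~usable
    started = review & unresolved_day2 & serendip
    m = started & uti & ~r_amox
    group[m], category[m] = "delayed", "immediate_appropriate"
    m = started & uti & r_amox
    group[m], category[m] = "resistant_uncorrected", "inappropriate"
    m = started & ~uti
    category[m] = "immediate_appropriate"

    # ---- lower risk ------------------------------------------------------
    lo = nvu & (stratum == 0)
    m = lo & serendip & uti & ~r_amox
    group[m], category[m] = "treated", "immediate_appropriate"
    m = lo & serendip & uti & r_amox
    group[m], category[m] = "resistant_uncorrected", "inappropriate"
    m = lo & serendip & ~uti
    category[m] = "immediate_appropriate"

    # very unwell children: hospital treatment (appropriate, immediate)
    group[vu & uti] = "treated"
    group[vu & ~uti] = "non_uti"

    # ---- acute outcomes --------------------------------------------------
    horizon = model.horizon_days
    u = params.econ.utilities
    day = np.zeros(n, dtype=int)
    pa = cohort["pa"].to_numpy()
    pa_eff = pa & ~vu      # hospital-treated children use the plain curve
    for g in np.unique(group):
        for is_pa in (False, True):
            m = (group == g) & (pa_eff == is_pa) if g != "non_uti" \
                else (group == g)
            if g == "non_uti" and is_pa:
                continue
            if not m.any():
                continue
            surv = np.asarray(survival_curve(model, str(g),
                                             pyelonephritis=is_pa and g != "non_uti"))
            day[m] = 1 + (u_resolve[m, None] < surv[None, 1:horizon]).sum(axis=1)
    asympt = (horizon - day).astype(float)

    u_state = np.where(vu, u["hospital"],
                       np.where(~uti, u["symptomatic_non_uti"],
                                np.where(pa, u["pyelonephritis"],
                                         u["symptomatic_uti"])))
    qald = asympt * u["asymptomatic"] + day * u_state

    categories = {}
    for status, m_status in (("uti", uti), ("no_uti", ~uti)):
        base = m_status & nvu
        denom = max(int(base.sum()), 1)
        categories[status] = {
            c: float((base & (category == c)).sum()) / denom
            for c in CATEGORIES}
    sample_req = nvu & (stratum >= 1)

    by_status = {}
    for status, m_status in (("uti", uti), ("no_uti", ~uti)):
        if m_status.any():
            by_status[status] = {
                "asymptomatic_days": float(asympt[m_status].mean()),
                "qald": float(qald[m_status].mean()),
            }
        else:
            by_status[status] = {"asymptomatic_days": np.nan, "qald": np.nan}
    n_nouti_nvu = max(int((~uti & nvu).sum()), 1)
    return MicrosimResult(
        strategy=strategy, arm=arm.mode, n=n, n_uti=int(uti.sum()),
        categories=categories,
        p_sample_requested=float(sample_req.mean()),
        antibiotic_for_uti_no_uti=float(
            (treated_for_uti & ~uti & nvu).sum()) / n_nouti_nvu,
        asymptomatic_days=float(asympt.mean()),
        qald=float(qald.mean()),
        by_status=by_status,
        sem_asymptomatic_days=float(asympt.std(ddof=1) / np.sqrt(n)),
        sem_qald=float(qald.std(ddof=1) / np.sqrt(n)),
    )


def generate_diaries(n: int, shape: float, scale: float, seed: int,
                     diary_days: int = 14) -> pd.DataFrame:
    """Daily symptom-resolution diaries, right-censored at ``diary_days``.

    Resolution times are continuous Weibull draws recorded at day
    granularity (a child resolving during day ``d`` has ``day == d``);
    children unresolved when the diary window closes are censored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = scale * rng.weibull(shape, size=n)
    day = np.ceil(np.maximum(t, 1e-12)).astype(int)
    resolved = day <= diary_days
    frame = pd.DataFrame({
        "child": np.arange(n),
        "resolved": resolved,
        "day": np.where(resolved, day, diary_days),
    })
    frame.attrs["seed"] = seed
    frame.attrs["diary_days"] = diary_days
    return frame


@dataclass
class WeibullFit:
    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]

    def survival(self, t):
        return np.exp(-(np.asarray(t, dtype=float) / self.scale) ** self.shape)


def fit_weibull(diaries: pd.DataFrame,
                diary_days: int | None = None) -> WeibullFit:
    """Maximum-likelihood Weibull fit honouring the diary censoring.

    A resolution recorded on day ``d`` is an interval-censored event in
    ``(d-1, d]``; unresolved diaries are right-censored at the diary window.
    Extrapolation beyond the window uses the fitted survival function.
    """
    from lifelines import WeibullFitter

    if diary_days is None:
        diary_days = int(diaries.attrs.get("diary_days", 14))
    resolved = diaries["resolved"].to_numpy()
    day = diaries["day"].to_numpy().astype(float)
    if not resolved.any():
        raise ValueError("degenerate diaries: every child is censored")
    if np.unique(day[resolved]).size < 2:
        raise ValueError("degenerate diaries: need >= 2 distinct resolution days")

    lower = np.where(resolved, np.maximum(day - 1.0, 1e-9), diary_days)
    upper = np.where(resolved, day, np.inf)
    wf = WeibullFitter()
    wf.fit_interval_censoring(lower, upper)
    summary = wf.summary
    lam = summary.loc["lambda_"]
    rho = summary.loc["rho_"]
    return WeibullFit(
        shape=float(rho["coef"]),
        scale=float(lam["coef"]),
        shape_ci=(float(rho["coef lower 95%"]), float(rho["coef upper 95%"])),
        scale_ci=(float(lam["coef lower 95%"]), float(lam["coef upper 95%"])),
    )
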