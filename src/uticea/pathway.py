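"""Short-term decision tree: testing and treatment at the index consultation.

For one diagnostic strategy the tree allocates the UTI and non-UTI
subcohorts (conditional on not being referred to hospital as very unwell)
across four treatment categories and the associated acute resolution
groups, and accumulates the diagnostic process cost per child:

* higher risk — urine sample requested and an antibiotic (trimethoprim)
  started immediately; a resistant culture triggers a prescription change,
  a negative culture may trigger a stop call, a contaminated sample is
  repeated once, and a child without an obtainable sample is reviewed at
  2 days and referred to hospital if unresolved;
* intermediate risk — urine sampling attempted and treatment delayed until
  a positive laboratory result (the laboratory-based arm), or determined
  immediately by a point-of-care dipstick (leukocyte-or-nitrite or
  leukocyte-and-nitrite arms) with negative dipsticks falling back to the
  laboratory result;
* lower risk — no sample; antibiotics (amoxicillin) only serendipitously
  when the working diagnosis is a non-UTI microbial infection.

Treatment categories record the appropriateness of the *initial*
prescription: a resistant immediate antibiotic counts as inappropriate even
though the prescription is later changed (the change still costs a revision
call and improves resolution from the day the culture returns).
"Appropriate" means the cultured uropathogen is sensitive to the antibiotic
given, whether UTI-directed or serendipitous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acute import ResolutionModel, survival_curve
from .evidence import ConfigurationError, ParameterSet
from .stratification import StratificationTable

__all__ = [
    "ARMS",
    "CATEGORIES",
    "IntermediateArm",
    "PathwayDistribution",
    "evaluate_strategy",
    "vur_workup",
    "evaluate",
]

#: Intermediate-risk treatment arms.
ARMS: tuple[str, ...] = ("lab", "dipstick_lorn", "dipstick_land")

#: Treatment categories; fractions sum to 1 within each UTI status.
CATEGORIES: tuple[str, ...] = (
    "immediate_appropriate", "lab_informed_appropriate",
    "inappropriate", "no_antibiotic",
)


@dataclass(frozen=True)
class IntermediateArm:
    """How intermediate-risk children are treated: laboratory-based delayed
    treatment, or immediate treatment on a positive dipstick."""

    mode: str = "lab"

    def __post_init__(self) -> None:
        if self.mode not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.mode!r}")

    @property
    def uses_dipstick(self) -> bool:
        return self.mode != "lab"


@dataclass
class PathwayDistribution:
    """Fractional allocation of each subcohort after the short-term tree.

    All fractions are conditional on not being referred as very unwell;
    ``p_very_unwell`` carries the referred fraction separately.  Process
    cost is the expected diagnostic cost per (not-referred) child of each
    status: sampling time, cultures, result interpretation, prescription
    calls, antibiotic courses, 2-day review visits and referrals, and (after
    :func:`vur_workup`) imaging.
    """

    strategy: str
    arm: IntermediateArm
    categories: dict            # status -> {category: fraction}
    acute_groups: dict          # status -> {acute group: fraction}
    p_very_unwell: float | np.ndarray
    p_sample_requested: float | np.ndarray
    p_sampled: dict             # status -> fraction attempting a sample
    p_dipsticked: dict          # status -> fraction receiving a dipstick
    p_usable: dict              # status -> fraction with a usable culture
    p_repeat: dict              # status -> fraction with a contaminated, repeated sample
    p_lab_confirmed: dict       # status -> fraction with a positive usable culture
    antibiotic_for_uti: dict    # status -> fraction on a UTI-directed antibiotic (not stopped)
    process_cost: dict          # status -> expected cost per child (GBP)
    p_us_referred: dict = field(default_factory=dict)
    p_vur_treated: float | np.ndarray = 0.0

    def validate(self) -> None:
        for status, cats in self.categories.items():
            total = sum(cats.values())
            if not np.allclose(total, 1.0, atol=1e-9):
                raise AssertionError(
                    f"{status} treatment categories sum to {total}, not 1")
            g = sum(self.acute_groups[status].values())
            if not np.allclose(g, 1.0, atol=1e-9):
                raise AssertionError(
                    f"{status} acute groups sum to {g}, not 1")


def _zeros_like(*values):
    """A zero broadcast to the common PSA shape of the given values."""
    out = 0.0
    for v in values:
        out = out + 0.0 * np.asarray(v, dtype=float)
    return out


def evaluate_strategy(strategy: str, arm: IntermediateArm | str,
                      params: ParameterSet, table: StratificationTable,
                      strata_draws=None,
                      model: ResolutionModel | None = None
                      ) -> PathwayDistribution:
    """Evaluate the decision tree for one strategy and one parameter draw.

    All arithmetic broadcasts over a leading PSA axis when ``params`` holds
    arrays.  ``model`` (daily resolution hazards) is needed for the
    review-at-2-days branches; it is built from ``params`` when omitted.
    """
    if isinstance(arm, str):
        arm = IntermediateArm(arm)
    if model is None:
        model = ResolutionModel.from_params(params)

    for name in ("urine_sample_obtained", "contamination", "lab_sensitivity",
                 "lab_specificity", "antibiotics_for_non_uti",
                 "stop_antibiotic_no_uti"):
        v = np.asarray(params[name], dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ConfigurationError(f"{name} outside [0, 1]")

    costs = params.econ.costs
    p_obt = params["urine_sample_obtained"]
    contam = params["contamination"]
    se_lab, sp_lab = params["lab_sensitivity"], params["lab_specificity"]
    r_tri = params["resistance_trimethoprim"]
    r_amox = params["resistance_amoxicillin"]
    p_ab = params["antibiotics_for_non_uti"]
    p_stop = params["stop_antibiotic_no_uti"]

    if arm.mode == "dipstick_lorn":
        dip_se = params["dipstick_lorn_sensitivity"]
        dip_sp = params["dipstick_lorn_specificity"]
    elif arm.mode == "dipstick_land":
        dip_se = params["dipstick_land_sensitivity"]
        dip_sp = params["dipstick_land_specificity"]

    # sampling cascade: a contaminated sample is repeated exactly once
    p_usable = p_obt * (1 - contam) * (1 + p_obt * contam)
    attempts = 1 + p_obt * contam           # expected attempts per sampler
    cultures = p_obt * (1 + contam * p_obt)  # contaminated samples are cultured too
    p_repeat_once = p_obt * contam
    usable_given_obt = p_usable / p_obt     # usable culture | first sample obtained

    # unresolved-at-2-days probabilities for the review branches
    s_untr2 = survival_curve(model, "untreated")[..., 2]
    s_non2 = survival_curve(model, "non_uti")[..., 2]
    s_tr2 = survival_curve(model, "treated")[..., 2]
    s_res2 = survival_curve(model, "resistant_uncorrected")[..., 2]

    sample_cost = costs["urine_sample"]
    dip_sample_cost = costs["urine_sample_dipstick"]
    culture_cost = costs["lab_culture"]
    interp_cost = costs["lab_interpretation"]
    call_cost = costs["revision_call"]
    trimeth = costs["antibiotic_trimethoprim"]
    amox = costs["antibiotic_amoxicillin"]
    gp = costs["gp_consultation"]
    hospital = costs["hospital_episode"]

    categories: dict = {}
    acute_groups: dict = {}
    p_sampled: dict = {}
    p_dip: dict = {}
    p_us: dict = {}
    p_rep: dict = {}
    p_conf: dict = {}
    ab_uti: dict = {}
    proc_cost: dict = {}

    for status in ("uti", "no_uti"):
        if strata_draws is not None:
            strata = np.asarray(strata_draws[(strategy, status)])
        else:
            strata = table.stratum_probs(strategy, status)
        low, mid, high = strata[..., 0], strata[..., 1], strata[..., 2]
        is_uti = status == "uti"

        cat = {c: _zeros_like(low, p_obt, se_lab) for c in CATEGORIES}
        grp = {g: _zeros_like(low, p_obt, se_lab)
               for g in ("untreated", "treated", "resistant_uncorrected",
                         "resistant_corrected", "delayed")}
        cost = _zeros_like(low, p_obt, se_lab)
        treated_for_uti = _zeros_like(low, p_obt, se_lab)
        p_pos = se_lab if is_uti else (1 - sp_lab)

        def review(weight, cost, start_group="delayed"):
            """Review-at-2-days for children without an obtainable sample:
            serendipitous amoxicillin only if unresolved and the working
            diagnosis is a non-UTI microbial infection."""
            nonlocal treated_for_uti
            cost = cost + weight * gp
            unres = s_untr2 if is_uti else s_non2
            started = unres * p_ab
            if is_uti:
                cat["immediate_appropriate"] += weight * started * (1 - r_amox)
                cat["inappropriate"] += weight * started * r_amox
                grp[start_group] += weight * started * (1 - r_amox)
                grp["resistant_uncorrected"] += weight * started * r_amox
                cat["no_antibiotic"] += weight * (1 - started)
                grp["untreated"] += weight * (1 - started)
            else:
                cat["immediate_appropriate"] += weight * started
                cat["no_antibiotic"] += weight * (1 - started)
            return cost + weight * started * amox

        # ---- higher risk: immediate UTI-directed antibiotic --------------
        cost = cost + high * (attempts * sample_cost + cultures * culture_cost
                              + p_usable * interp_cost + trimeth)
        if is_uti:
            sens = 1 - r_tri
            corrected = r_tri * p_usable * se_lab
            cat["immediate_appropriate"] += high * sens
            cat["inappropriate"] += high * r_tri
            grp["treated"] += high * sens
            grp["resistant_corrected"] += high * corrected
            grp["resistant_uncorrected"] += high * (r_tri - corrected)
            # prescription change: revision call + replacement course
            cost = cost + high * corrected * (call_cost + trimeth)
            # false-negative culture may trigger a stop call
            cost = cost + high * p_usable * (1 - se_lab) * p_stop * call_cost
            # no usable sample: review at 2 d, refer to hospital if unresolved
            s2 = (1 - r_tri) * s_tr2 + r_tri * s_res2
            cost = cost + high * (1 - p_usable) * (gp + s2 * hospital)
        else:
            stopped = p_usable * sp_lab * p_stop
            treated_for_uti += high * (1 - stopped)
            cat["inappropriate"] += high    # unnecessary UTI-directed course
            cost = cost + high * stopped * call_cost
            cost = cost + high * (1 - p_usable) * (gp + s_non2 * hospital)

        # ---- intermediate risk --------------------------------------------
        if arm.uses_dipstick:
            # dipstick on the first obtained sample; any repeat after
            # contamination uses a plain sample
            cost = cost + mid * (p_obt * dip_sample_cost
                                 + p_repeat_once * sample_cost
                                 + cultures * culture_cost
                                 + p_usable * interp_cost)
            p_dip_pos = dip_se if is_uti else (1 - dip_sp)
            dip_pos = p_obt * p_dip_pos
            dip_neg = p_obt * (1 - p_dip_pos)
            cost = cost + mid * dip_pos * trimeth
            if is_uti:
                sens = 1 - r_tri
                corrected = r_tri * usable_given_obt * se_lab
                cat["immediate_appropriate"] += mid * dip_pos * sens
                cat["inappropriate"] += mid * dip_pos * r_tri
                grp["treated"] += mid * dip_pos * sens
                grp["resistant_corrected"] += mid * dip_pos * corrected
                grp["resistant_uncorrected"] += mid * dip_pos * (r_tri - corrected)
                cost = cost + mid * dip_pos * corrected * (call_cost + trimeth)
                delayed = dip_neg * usable_given_obt * se_lab
                cat["lab_informed_appropriate"] += mid * delayed
                grp["delayed"] += mid * delayed
                cat["no_antibiotic"] += mid * (dip_neg - delayed)
                grp["untreated"] += mid * (dip_neg - delayed)
                cost = cost + mid * delayed * trimeth
            else:
                stopped = usable_given_obt * sp_lab * p_stop
                treated_for_uti += mid * dip_pos * (1 - stopped)
                cat["inappropriate"] += mid * dip_pos
                cost = cost + mid * dip_pos * stopped * call_cost
                delayed = dip_neg * usable_given_obt * (1 - sp_lab)
                treated_for_uti += mid * delayed
                cat["lab_informed_appropriate"] += mid * delayed
                cat["no_antibiotic"] += mid * (dip_neg - delayed)
                cost = cost + mid * delayed * trimeth
            cost = review(mid * (1 - p_obt), cost)
            p_dip[status] = mid * p_obt
        else:
            cost = cost + mid * (attempts * sample_cost
                                 + cultures * culture_cost
                                 + p_usable * interp_cost)
            delayed = p_usable * p_pos
            if is_uti:
                cat["lab_informed_appropriate"] += mid * delayed
                grp["delayed"] += mid * delayed
                cat["no_antibiotic"] += mid * p_usable * (1 - p_pos)
                grp["untreated"] += mid * p_usable * (1 - p_pos)
            else:
                treated_for_uti += mid * delayed
                cat["lab_informed_appropriate"] += mid * delayed
                cat["no_antibiotic"] += mid * p_usable * (1 - p_pos)
            # positive culture: the delayed course (initiation is part of
            # routine result handling; the revision call is charged only for
            # changing or stopping a prescription)
            cost = cost + mid * delayed * trimeth
            cost = review(mid * (1 - p_usable), cost)
            p_dip[status] = _zeros_like(mid, p_obt)

        # ---- lower risk: serendipitous antibiotics only -------------------
        if is_uti:
            cat["immediate_appropriate"] += low * p_ab * (1 - r_amox)
            cat["inappropriate"] += low * p_ab * r_amox
            grp["treated"] += low * p_ab * (1 - r_amox)
            grp["resistant_uncorrected"] += low * p_ab * r_amox
            cat["no_antibiotic"] += low * (1 - p_ab)
            grp["untreated"] += low * (1 - p_ab)
        else:
            cat["immediate_appropriate"] += low * p_ab
            cat["no_antibiotic"] += low * (1 - p_ab)
        cost = cost + low * p_ab * amox

        if not is_uti:
            grp = {"non_uti": 1.0 + _zeros_like(low, p_obt)}

        categories[status] = cat
        acute_groups[status] = grp
        p_sampled[status] = (mid + high) + _zeros_like(p_obt)
        p_us[status] = (mid + high) * p_usable
        p_rep[status] = (mid + high) * p_repeat_once
        p_conf[status] = (mid + high) * p_usable * p_pos
        ab_uti[status] = treated_for_uti
        proc_cost[status] = cost

    prev = params["uti_prevalence"]
    p_req = (1 - params["very_unwell"]) * (
        prev * p_sampled["uti"] + (1 - prev) * p_sampled["no_uti"])

    return PathwayDistribution(
        strategy=strategy, arm=arm, categories=categories,
        acute_groups=acute_groups, p_very_unwell=params["very_unwell"],
        p_sample_requested=p_req, p_sampled=p_sampled, p_dipsticked=p_dip,
        p_usable=p_us, p_repeat=p_rep, p_lab_confirmed=p_conf,
        antibiotic_for_uti=ab_uti, process_cost=proc_cost,
    )


def vur_workup(pathway: PathwayDistribution,
               params: ParameterSet) -> PathwayDistribution:
    """Apply the vesicoureteral-reflux work-up to laboratory-confirmed UTI.

    A fraction of confirmed cases is referred for ultrasound; positive scans
    proceed to micturating cystourethrogram (perfect accuracy by
    assumption), and confirmed VUR is flagged for prophylactic treatment.
    Falsely confirmed children without UTI can be referred and scanned but,
    having no VUR, cannot receive a true-positive diagnosis.
    """
    p_refer = params["referred_for_us"]
    vur = params["vur_given_uti"]
    us_se, us_sp = params["us_sensitivity"], params["us_specificity"]
    mcug_se = params["mcug_sensitivity"]
    c_us, c_mcug = params.econ.costs["ultrasound"], params.econ.costs["mcug"]

    referred_uti = pathway.p_lab_confirmed["uti"] * p_refer
    referred_no = pathway.p_lab_confirmed["no_uti"] * p_refer
    p_us_pos_uti = vur * us_se + (1 - vur) * (1 - us_sp)
    pathway.p_us_referred = {"uti": referred_uti, "no_uti": referred_no}
    pathway.p_vur_treated = referred_uti * vur * us_se * mcug_se
    pathway.process_cost["uti"] = pathway.process_cost["uti"] \
        + referred_uti * (c_us + p_us_pos_uti * c_mcug)
    pathway.process_cost["no_uti"] = pathway.process_cost["no_uti"] \
        + referred_no * (c_us + (1 - us_sp) * c_mcug)
    return pathway


def evaluate(strategy: str, arm: IntermediateArm | str, params: ParameterSet,
             table: StratificationTable, strata_draws=None,
             model: ResolutionModel | None = None) -> PathwayDistribution:
    """Decision tree plus VUR work-up in one call."""
    pw = evaluate_strategy(strategy, arm, params, table, strata_draws, model)
    return vur_workup(pw, params)
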