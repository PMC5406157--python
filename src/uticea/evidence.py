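"""Evidence base: named parameter distributions and economic settings.

Every quantity entering the model is a :class:`ParameterDistribution` — a
named sampling law with a deterministic point estimate (used for the
base-case analysis) and a random draw (used for probabilistic sensitivity
analysis).  Binomial evidence is propagated as a flat-prior conjugate
posterior, Beta(successes+1, failures+1); odds and relative risks are
sampled on the log scale; structural assumptions are fixed values.

The shipped default configuration encodes the full published evidence table
for the model: prevalence, risk-stratification inputs, diagnostic-test
accuracies, antibiotic resistance, recurrence and renal-sequelae risks, and
the unit costs and utilities of the economic evaluation.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "ParameterDistribution",
    "EconomicSettings",
    "ResolutionSettings",
    "ParameterSet",
    "EvidenceBase",
    "load_parameters",
    "MANDATORY_PARAMETERS",
]


class ConfigurationError(ValueError):
    """Raised when a parameter file is incomplete or malformed."""


#: Parameter names that every configuration must define.
MANDATORY_PARAMETERS: tuple[str, ...] = (
    "uti_prevalence",
    "pa_given_uti",
    "vur_given_uti",
    "very_unwell",
    "urine_sample_obtained",
    "contamination",
    "resistance_amoxicillin",
    "resistance_trimethoprim",
    "reconsultation",
    "antibiotics_for_non_uti",
    "stop_antibiotic_no_uti",
    "referred_for_us",
    "dipstick_lorn_sensitivity",
    "dipstick_lorn_specificity",
    "dipstick_land_sensitivity",
    "dipstick_land_specificity",
    "lab_sensitivity",
    "lab_specificity",
    "us_sensitivity",
    "us_specificity",
    "mcug_sensitivity",
    "mcug_specificity",
    "treatment_effect",
    "resistant_effect_multiplier",
    "consult_no_uti",
    "consult_uti_no_history",
    "consult_uti_history",
    "vur_treatment_effect",
    "prs_0pa",
    "prs_1pa",
    "prs_2pa",
    "prs_3pa",
    "prs_4pa",
    "esrd_given_prs",
    "esrd_onset_age",
    "transplant_fraction",
    "survival_no_esrd",
    "survival_dialysis",
    "survival_transplant",
)

_LAWS = (
    "binomial-proportion",
    "lognormal-odds",
    "lognormal-rr",
    "uniform",
    "triangle",
    "fixed",
)

# Parameters that are probabilities: sampled and point values must lie in [0,1].
_PROBABILITY_LAWS = ("binomial-proportion", "lognormal-odds")


@dataclass(frozen=True)
class ParameterDistribution:
    """One evidence-table row: a named quantity plus its sampling law.

    Parameters
    ----------
    name
        Identifier used throughout the model.
    law
        One of ``binomial-proportion``, ``lognormal-odds``, ``lognormal-rr``,
        ``uniform``, ``triangle``, ``fixed``.
    params
        Law-specific numbers (``successes``/``trials``, ``log_mean``/
        ``log_sd``, ``lower``/``mode``/``upper``, ``value``).
    estimate
        Optional explicit point estimate, used when the published rounding
        convention differs from the value implied by the law's parameters.
    """

    name: str
    law: str
    params: dict[str, float]
    estimate: float | None = None

    def __post_init__(self) -> None:
        if self.law not in _LAWS:
            raise ConfigurationError(
                f"parameter {self.name!r}: unknown law {self.law!r}"
            )
        p = self.params
        if self.law == "binomial-proportion":
            s, n = p["successes"], p["trials"]
            if n <= 0 or not (0 <= s <= n):
                raise ConfigurationError(
                    f"parameter {self.name!r}: need 0 <= successes <= trials, "
                    f"trials > 0; got ({s}, {n})"
                )
        elif self.law in ("lognormal-odds", "lognormal-rr"):
            if p["log_sd"] < 0:
                raise ConfigurationError(
                    f"parameter {self.name!r}: log_sd must be >= 0"
                )
        elif self.law == "uniform":
            if p["lower"] > p["upper"]:
                raise ConfigurationError(
                    f"parameter {self.name!r}: lower > upper"
                )
        elif self.law == "triangle":
            if not (p["lower"] <= p["mode"] <= p["upper"]):
                raise ConfigurationError(
                    f"parameter {self.name!r}: need lower <= mode <= upper"
                )

    # -- point estimate ----------------------------------------------------
    def point_estimate(self) -> float:
        """Deterministic base-case value of this parameter."""
        if self.estimate is not None:
            return float(self.estimate)
        p = self.params
        if self.law == "binomial-proportion":
            return p["successes"] / p["trials"]
        if self.law == "lognormal-odds":
            odds = np.exp(p["log_mean"])
            return float(odds / (1.0 + odds))
        if self.law == "lognormal-rr":
            return float(np.exp(p["log_mean"]))
        if self.law == "uniform":
            return 0.5 * (p["lower"] + p["upper"])
        if self.law == "triangle":
            return (p["lower"] + p["mode"] + p["upper"]) / 3.0
        return float(p["value"])

    # -- random draw -------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the PSA law (flat-prior posterior for binomial rows)."""
        p = self.params
        if self.law == "binomial-proportion":
            s, n = p["successes"], p["trials"]
            return rng.beta(s + 1.0, n - s + 1.0, size=size)
        if self.law == "lognormal-odds":
            odds = np.exp(rng.normal(p["log_mean"], p["log_sd"], size=size))
            return odds / (1.0 + odds)
        if self.law == "lognormal-rr":
            return np.exp(rng.normal(p["log_mean"], p["log_sd"], size=size))
        if self.law == "uniform":
            return rng.uniform(p["lower"], p["upper"], size=size)
        if self.law == "triangle":
            return rng.triangular(p["lower"], p["mode"], p["upper"], size=size)
        value = float(p["value"])
        return value if size is None else np.full(size, value)

    @property
    def is_probability(self) -> bool:
        return self.law in _PROBABILITY_LAWS


@dataclass
class EconomicSettings:
    """Willingness-to-pay, discounting, unit costs and utilities (GBP 2014/15)."""

    willingness_to_pay: float
    discount_rate: float
    days_per_year: float
    annual_cohort_size: int
    costs: dict[str, float]
    utilities: dict[str, float]
    price_year: str = "2014/15"

    def __post_init__(self) -> None:
        if self.willingness_to_pay <= 0:
            raise ConfigurationError("willingness_to_pay must be > 0")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        for k, v in self.costs.items():
            if v < 0:
                raise ConfigurationError(f"cost {k!r} must be >= 0")
        for k, v in self.utilities.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"utility {k!r} must lie in [0, 1]")

    def copy(self) -> "EconomicSettings":
        return EconomicSettings(
            willingness_to_pay=self.willingness_to_pay,
            discount_rate=self.discount_rate,
            days_per_year=self.days_per_year,
            annual_cohort_size=self.annual_cohort_size,
            costs=dict(self.costs),
            utilities=dict(self.utilities),
            price_year=self.price_year,
        )


@dataclass
class ResolutionSettings:
    """Weibull time-to-resolution settings for the acute-illness model."""

    non_uti_shape: float
    non_uti_scale: float
    untreated_uti_shape: float
    untreated_uti_scale: float
    pyelonephritis_hazard_multiplier: float = 0.6
    delayed_window_days: int = 2
    effect_persistence_days: int = 7
    horizon_days: int = 21
    diary_days: int = 14

    def __post_init__(self) -> None:
        for v in (self.non_uti_shape, self.non_uti_scale,
                  self.untreated_uti_shape, self.untreated_uti_scale):
            if v <= 0:
                raise ConfigurationError("Weibull shape/scale must be > 0")

    def copy(self) -> "ResolutionSettings":
        return ResolutionSettings(**self.__dict__)


class ParameterSet(Mapping):
    """One complete realisation of all model parameters.

    Behaves as a read-only mapping from parameter name to value.  Values are
    scalars for the base case, or ``numpy`` arrays of shape ``(draws,)`` for
    a vectorised PSA, and the whole downstream pipeline broadcasts over that
    axis.  Economic constants and resolution settings ride along unsampled.
    """

    def __init__(self, values: dict[str, Any], econ: EconomicSettings,
                 resolution: ResolutionSettings,
                 acute_states: tuple[str, ...],
                 medium_term_years: int = 3):
        self._values = dict(values)
        self.econ = econ
        self.resolution = resolution
        self.acute_states = tuple(acute_states)
        self.medium_term_years = int(medium_term_years)

    def __getitem__(self, key: str):
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with some parameter values replaced."""
        values = dict(self._values)
        values.update(overrides)
        return ParameterSet(values, self.econ.copy(), self.resolution.copy(),
                            self.acute_states, self.medium_term_years)

    def validate(self) -> None:
        """Check every probability lies in [0, 1]; raise on violation."""
        for name in MANDATORY_PARAMETERS:
            v = np.asarray(self._values[name], dtype=float)
            if name.startswith(("survival_", "esrd_onset")):
                continue
            if name in ("treatment_effect", "vur_treatment_effect"):
                if np.any(v <= 0):
                    raise ConfigurationError(f"{name} must be > 0")
                continue
            if np.any(v < 0) or np.any(v > 1):
                raise ConfigurationError(f"{name} outside [0, 1]")


class EvidenceBase:
    """The full evidence base: distributions plus economic settings."""

    def __init__(self, distributions: dict[str, ParameterDistribution],
                 econ: EconomicSettings, resolution: ResolutionSettings,
                 acute_states: tuple[str, ...], medium_term_years: int = 3):
        self.distributions = distributions
        self.econ = econ
        self.resolution = resolution
        self.acute_states = tuple(acute_states)
        self.medium_term_years = int(medium_term_years)

    def __getitem__(self, name: str) -> ParameterDistribution:
        return self.distributions[name]

    def __iter__(self):
        return iter(self.distributions.values())

    def point_estimates(self) -> ParameterSet:
        values = {d.name: d.point_estimate() for d in self}
        ps = ParameterSet(values, self.econ.copy(), self.resolution.copy(),
                          self.acute_states, self.medium_term_years)
        ps.validate()
        return ps

    def sample(self, rng: np.random.Generator,
               size: int | None = None) -> ParameterSet:
        """Draw a (possibly vectorised) ParameterSet; reproducible given rng."""
        values = {d.name: d.sample(rng, size=size) for d in self}
        return ParameterSet(values, self.econ.copy(), self.resolution.copy(),
                            self.acute_states, self.medium_term_years)


def _default_config_path() -> Path:
    return Path(str(resources.files("uticea").joinpath("data/default_config.yaml")))


def load_parameters(path: str | Path | None = None) -> EvidenceBase:
    """Load an evidence base from a YAML configuration file.

    With ``path=None`` the shipped default configuration is used.  Raises
    :class:`ConfigurationError` naming the offending parameter when a
    mandatory row is missing or a law is malformed; unknown parameter names
    are rejected.
    """
    cfg_path = _default_config_path() if path is None else Path(path)
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ConfigurationError(f"{cfg_path}: no 'parameters' section")

    known = set(MANDATORY_PARAMETERS)
    dists: dict[str, ParameterDistribution] = {}
    for name, spec in raw["parameters"].items():
        if name not in known:
            raise ConfigurationError(f"unknown parameter {name!r}")
        if not isinstance(spec, dict) or "law" not in spec:
            raise ConfigurationError(f"parameter {name!r}: malformed entry")
        spec = dict(spec)
        law = spec.pop("law")
        estimate = spec.pop("estimate", None)
        dists[name] = ParameterDistribution(name, law, spec, estimate)
    missing = [n for n in MANDATORY_PARAMETERS if n not in dists]
    if missing:
        raise ConfigurationError(f"missing mandatory parameter(s): {missing}")

    econ_raw = raw.get("economics", {})
    econ = EconomicSettings(
        willingness_to_pay=float(econ_raw["willingness_to_pay"]),
        discount_rate=float(econ_raw["discount_rate"]),
        days_per_year=float(econ_raw.get("days_per_year", 365.25)),
        annual_cohort_size=int(econ_raw["annual_cohort_size"]),
        costs={k: float(v) for k, v in econ_raw["costs"].items()},
        utilities={k: float(v) for k, v in econ_raw["utilities"].items()},
        price_year=str(raw.get("price_year", "2014/15")),
    )

    res_raw = raw.get("resolution", {})
    resolution = ResolutionSettings(
        non_uti_shape=float(res_raw["non_uti"]["shape"]),
        non_uti_scale=float(res_raw["non_uti"]["scale"]),
        untreated_uti_shape=float(res_raw["untreated_uti"]["shape"]),
        untreated_uti_scale=float(res_raw["untreated_uti"]["scale"]),
        pyelonephritis_hazard_multiplier=float(
            res_raw.get("pyelonephritis_hazard_multiplier", 0.6)),
        delayed_window_days=int(res_raw.get("delayed_window_days", 2)),
        effect_persistence_days=int(res_raw.get("effect_persistence_days", 7)),
        horizon_days=int(res_raw.get("horizon_days", 21)),
        diary_days=int(res_raw.get("diary_days", 14)),
    )

    acute_states = tuple(raw.get("acute_states", ()))
    if len(acute_states) != 9:
        raise ConfigurationError("acute_states must list exactly nine states")
    years = int(raw.get("horizons", {}).get("medium_term_years", 3))
    return EvidenceBase(dists, econ, resolution, acute_states, years)
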