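"""Risk-stratification tables and the diagnostic-accuracy cascade.

Each diagnostic strategy assigns every child (not referred to hospital as
very unwell) to a lower / intermediate / higher risk stratum, separately by
true UTI status.  Stratum counts are carried as a table; probabilities are
count / row-total at point estimates and Dirichlet(counts + 1) draws under
PSA.  Urine sampling is attempted in the intermediate and higher strata, so
the stratum probabilities fully determine the sampling sensitivity and
specificity of a strategy; composing them with the probability of obtaining
a sample and the NHS laboratory accuracy gives the post-laboratory cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import ParameterSet

__all__ = [
    "STRATEGIES",
    "STRATA",
    "StratificationTable",
    "AccuracySummary",
    "p_urine_sample_requested",
    "sampling_sensitivity",
    "sampling_specificity",
    "post_lab_accuracy",
    "accuracy_summary",
]

#: Canonical strategy identifiers, in publication order.
STRATEGIES: tuple[str, ...] = (
    "clinical_judgment", "duty_5pct", "duty_10pct", "duty_20pct",
    "duty_ge6", "duty_ge5", "duty_ge4", "duty_ge3",
)

STRATA: tuple[str, ...] = ("lower", "intermediate", "higher")
_STATUSES: tuple[str, ...] = ("uti", "no_uti")


class StratificationTable:
    """Counts of children by strategy x UTI status x risk stratum."""

    def __init__(self, frame: pd.DataFrame):
        required = {"strategy", "uti_status", *STRATA}
        if not required.issubset(frame.columns):
            raise ValueError(f"stratification table needs columns {sorted(required)}")
        counts = frame[list(STRATA)].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("stratum counts must be non-negative integers")
        self.frame = frame.set_index(["strategy", "uti_status"]).sort_index()

    @classmethod
    def default(cls) -> "StratificationTable":
        """The shipped table for the eight published strategies."""
        path = resources.files("uticea").joinpath("data/duty_stratification.tsv")
        return cls.from_tsv(str(path))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StratificationTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.reset_index().to_csv(path, sep="\t", index=False)

    @property
    def strategies(self) -> tuple[str, ...]:
        return tuple(self.frame.index.get_level_values("strategy").unique())

    def counts(self, strategy: str, uti_status: str) -> np.ndarray:
        """Raw (lower, intermediate, higher) counts for one table row."""
        try:
            row = self.frame.loc[(strategy, uti_status)]
        except KeyError as exc:
            raise KeyError(
                f"no stratification row for ({strategy!r}, {uti_status!r})"
            ) from exc
        return row[list(STRATA)].to_numpy(dtype=float)

    def stratum_probs(self, strategy: str, uti_status: str) -> np.ndarray:
        """Point-estimate stratum probabilities; sum to 1 exactly."""
        c = self.counts(strategy, uti_status)
        return c / c.sum()

    def sample_stratum_probs(self, rng: np.random.Generator,
                             size: int | None = None
                             ) -> dict[tuple[str, str], np.ndarray]:
        """Dirichlet(counts + 1) draws per (strategy, status) row.

        The flat-prior multinomial analogue of the Beta sampling used for
        binomial evidence.  Returns arrays of shape ``(3,)`` or ``(size, 3)``.
        """
        out: dict[tuple[str, str], np.ndarray] = {}
        for strategy in self.strategies:
            for status in _STATUSES:
                alpha = self.counts(strategy, status) + 1.0
                g = rng.gamma(alpha, size=None if size is None else (size, 3))
                out[(strategy, status)] = g / g.sum(axis=-1, keepdims=True)
        return out


@dataclass
class AccuracySummary:
    """Diagnostic-pathway summary for one strategy (the top block of the
    published short-term results table)."""

    strategy: str
    p_sample_requested: float
    sensitivity_sampling: float
    specificity_sampling: float
    sensitivity_post_lab: float
    specificity_post_lab: float


def _probs(table: StratificationTable, strategy: str, uti_status: str,
           strata_draws=None) -> np.ndarray:
    if strata_draws is not None:
        return np.asarray(strata_draws[(strategy, uti_status)])
    return table.stratum_probs(strategy, uti_status)


def p_urine_sample_requested(strategy: str, params: ParameterSet,
                             table: StratificationTable, strata_draws=None):
    """P(urine sample requested) among all presenting children.

    Very unwell children are referred to hospital before any sampling
    decision, so the status mixture of the intermediate-or-higher stratum
    probability is weighted by (1 - P(very unwell)).
    """
    prev = params["uti_prevalence"]
    p_vu = params["very_unwell"]
    p_uti = _probs(table, strategy, "uti", strata_draws)[..., 1:].sum(axis=-1)
    p_no = _probs(table, strategy, "no_uti", strata_draws)[..., 1:].sum(axis=-1)
    return (1.0 - p_vu) * (prev * p_uti + (1.0 - prev) * p_no)


def sampling_sensitivity(strategy: str, table: StratificationTable,
                         strata_draws=None):
    """P(intermediate or higher stratum | UTI), conditional on non-referral."""
    return _probs(table, strategy, "uti", strata_draws)[..., 1:].sum(axis=-1)


def sampling_specificity(strategy: str, table: StratificationTable,
                         strata_draws=None):
    """P(lower stratum | no UTI), conditional on non-referral."""
    return _probs(table, strategy, "no_uti", strata_draws)[..., 0]


def post_lab_accuracy(strategy: str, params: ParameterSet,
                      table: StratificationTable, strata_draws=None):
    """(sensitivity, specificity) after the obtain-sample/culture cascade.

    A child with UTI is laboratory-confirmed only if selected for sampling,
    a sample is obtained, and the culture is positive; a child without UTI is
    falsely confirmed only if selected, sampled, and the culture is falsely
    positive.
    """
    p_obt = params["urine_sample_obtained"]
    sens = sampling_sensitivity(strategy, table, strata_draws)
    spec = sampling_specificity(strategy, table, strata_draws)
    sens_post = sens * p_obt * params["lab_sensitivity"]
    spec_post = 1.0 - (1.0 - spec) * p_obt * (1.0 - params["lab_specificity"])
    return sens_post, spec_post


def accuracy_summary(strategy: str, params: ParameterSet,
                     table: StratificationTable) -> AccuracySummary:
    """Point-estimate diagnostic-pathway summary for one strategy."""
    sens_post, spec_post = post_lab_accuracy(strategy, params, table)
    return AccuracySummary(
        strategy=strategy,
        p_sample_requested=float(p_urine_sample_requested(strategy, params, table)),
        sensitivity_sampling=float(sampling_sensitivity(strategy, table)),
        specificity_sampling=float(sampling_specificity(strategy, table)),
        sensitivity_post_lab=float(sens_post),
        specificity_post_lab=float(spec_post),
    )
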