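"""Cohort simulation, outcome aggregation and between-strategy comparison.

One "Monte Carlo experiment" is one virtual patient whose stage
probabilities and unit costs are freshly drawn at every use — a
probabilistic sensitivity analysis in which parameter uncertainty and
patient-level pathway variability are propagated together. The default
cohort size of 100,000 patients per arm reflects the annual scale of the
Italian ART program.

Dispersion conventions:

* ``sd_cost`` is the standard deviation of per-patient total cost.
* ``pregnancy_rate`` is binary per patient, so its patient-level SD is
  uninformative; ``sd_rate`` is the SD of pregnancy fractions over
  consecutive disjoint sub-cohorts (default 150 patients each — a declared
  reporting convention, see docs/methods.md).
* ``cost_per_pregnancy`` is mean cost divided by the unrounded pregnancy
  rate; its dispersion is ``sd_cost / pregnancy_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats

from .parameters import (
    ParameterValidationError,
    Strategy,
    StudyParameters,
    validate,
)
from .pathway import PatientOutcome, SequencingMode, simulate_patient

__all__ = [
    "CohortResult",
    "SimulationSummary",
    "ComparisonResult",
    "Verdict",
    "run_cohort",
    "summarize",
    "compare_strategies",
    "format_p",
]

_ARM_INDEX = {Strategy.RFSH_MYOINS: 0, Strategy.RFSH: 1}

DEFAULT_N = 100_000
DEFAULT_SUBCOHORT_SIZE = 150


@dataclass(frozen=True)
class CohortResult:
    """Per-patient outcomes of one simulated cohort under one strategy."""

    strategy: Strategy
    n: int
    seed: int
    mode: SequencingMode
    costs: np.ndarray  # float64, per-patient total cost (euros)
    pregnant: np.ndarray  # bool
    cycles_used: np.ndarray  # int8, in {1,2,3}
    subcohort_size: int = DEFAULT_SUBCOHORT_SIZE
    outcomes: Optional[tuple[PatientOutcome, ...]] = None  # kept on request


@dataclass(frozen=True)
class SimulationSummary:
    """Headline outcomes of one cohort with dispersions.

    Dispersions are ``None`` when undefined (fewer than 2 patients, or
    fewer than 2 complete sub-cohorts for ``sd_rate``);
    ``cost_per_pregnancy`` is ``None`` when no pregnancy occurred.
    """

    strategy: Strategy
    n: int
    mean_cost: float
    sd_cost: Optional[float]
    pregnancy_rate: float
    sd_rate: Optional[float]
    cost_per_pregnancy: Optional[float]
    sd_cost_per_pregnancy: Optional[float]
    cycles_histogram: dict[int, int]
    subcohort_size: int

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "n": self.n,
            "mean_cost": self.mean_cost,
            "sd_cost": self.sd_cost,
            "pregnancy_rate": self.pregnancy_rate,
            "sd_rate": self.sd_rate,
            "cost_per_pregnancy": self.cost_per_pregnancy,
            "sd_cost_per_pregnancy": self.sd_cost_per_pregnancy,
            "cycles_histogram": {str(k): v for k, v in self.cycles_histogram.items()},
            "subcohort_size": self.subcohort_size,
        }


class Verdict(str, Enum):
    """Dominance verdict: dominant = cheaper AND more effective."""

    A_DOMINATES = "a_dominates"
    B_DOMINATES = "b_dominates"
    TRADEOFF = "tradeoff"


@dataclass(frozen=True)
class ComparisonResult:
    """Between-strategy deltas (a − b), test statistics and verdict."""

    strategy_a: Strategy
    strategy_b: Strategy
    delta_cost: float
    delta_rate: float
    delta_cost_per_pregnancy: Optional[float]
    z_cost: Optional[float]
    p_cost: Optional[float]
    z_rate: Optional[float]
    p_rate: Optional[float]
    verdict: Verdict

    def to_dict(self) -> dict:
        return {
            "strategy_a": self.strategy_a.value,
            "strategy_b": self.strategy_b.value,
            "delta_cost": self.delta_cost,
            "delta_rate": self.delta_rate,
            "delta_cost_per_pregnancy": self.delta_cost_per_pregnancy,
            "z_cost": self.z_cost,
            "p_cost": self.p_cost,
            "z_rate": self.z_rate,
            "p_rate": self.p_rate,
            "verdict": self.verdict.value,
        }


def run_cohort(
    params: StudyParameters,
    strategy: Strategy,
    n: int = DEFAULT_N,
    seed: int = 0,
    mode: SequencingMode = SequencingMode.TABLE_FAITHFUL,
    *,
    ohss_prob: float = 0.0,
    subcohort_size: int = DEFAULT_SUBCOHORT_SIZE,
    keep_trajectories: bool = False,
) -> CohortResult:
    """Simulate ``n`` independent patients on non-overlapping substreams.

    Each patient receives a child stream spawned from
    ``SeedSequence([seed, arm])``, so the two arms are driven by disjoint
    randomness for the same ``seed`` and results are reproducible and
    order-independent.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    violations = validate(params)
    if violations:
        raise ParameterValidationError(violations)
    strategy = Strategy(strategy)
    mode = SequencingMode(mode)

    root = np.random.SeedSequence([int(seed), _ARM_INDEX[strategy]])
    children = root.spawn(n)

    costs = np.empty(n, dtype=np.float64)
    pregnant = np.empty(n, dtype=bool)
    cycles_used = np.empty(n, dtype=np.int8)
    kept: list[PatientOutcome] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        out = simulate_patient(
            params, strategy, rng, mode, ohss_prob=ohss_prob, _validated=True
        )
        costs[i] = out.total_cost
        pregnant[i] = out.pregnant
        cycles_used[i] = out.cycles_used
        if keep_trajectories:
            kept.append(out)

    return CohortResult(
        strategy=strategy,
        n=n,
        seed=int(seed),
        mode=mode,
        costs=costs,
        pregnant=pregnant,
        cycles_used=cycles_used,
        subcohort_size=subcohort_size,
        outcomes=tuple(kept) if keep_trajectories else None,
    )


def summarize(cohort: CohortResult) -> SimulationSummary:
    """Aggregate a cohort into the three headline outcomes + dispersions."""
    n = cohort.n
    if n < 1:
        raise ValueError("empty cohort")
    mean_cost = float(np.mean(cohort.costs))
    sd_cost = float(np.std(cohort.costs, ddof=1)) if n >= 2 else None
    rate = float(np.mean(cohort.pregnant))

    m = cohort.subcohort_size
    groups = n // m
    if groups >= 2:
        frac = (
            cohort.pregnant[: groups * m]
            .reshape(groups, m)
            .mean(axis=1)
        )
        sd_rate = float(np.std(frac, ddof=1))
    else:
        sd_rate = None

    if rate > 0:
        cpp = mean_cost / rate
        sd_cpp = sd_cost / rate if sd_cost is not None else None
    else:
        cpp = None
        sd_cpp = None

    hist = {
        k: int(np.sum(cohort.cycles_used == k)) for k in (1, 2, 3)
    }
    return SimulationSummary(
        strategy=cohort.strategy,
        n=n,
        mean_cost=mean_cost,
        sd_cost=sd_cost,
        pregnancy_rate=rate,
        sd_rate=sd_rate,
        cost_per_pregnancy=cpp,
        sd_cost_per_pregnancy=sd_cpp,
        cycles_histogram=hist,
        subcohort_size=m,
    )


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_strategies(a: CohortResult, b: CohortResult) -> ComparisonResult:
    """Compare two cohorts: deltas (a − b), z tests, dominance verdict.

    Costs: two-sample z test with unequal variances (Welch form; the normal
    reference is appropriate at these cohort sizes). Pregnancy: two-proportion
    z test with pooled variance. A zero standard error yields z = 0, p = 1.
    """
    sa, sb = summarize(a), summarize(b)
    delta_cost = sa.mean_cost - sb.mean_cost
    delta_rate = sa.pregnancy_rate - sb.pregnancy_rate
    if sa.cost_per_pregnancy is not None and sb.cost_per_pregnancy is not None:
        delta_cpp = sa.cost_per_pregnancy - sb.cost_per_pregnancy
    else:
        delta_cpp = None

    if a.n >= 2 and b.n >= 2:
        va = np.var(a.costs, ddof=1)
        vb = np.var(b.costs, ddof=1)
        se = float(np.sqrt(va / a.n + vb / b.n))
        z_cost = delta_cost / se if se > 0 else 0.0
        p_cost = _two_sided_p(z_cost)
    else:
        z_cost = p_cost = None

    pool = (np.sum(a.pregnant) + np.sum(b.pregnant)) / (a.n + b.n)
    se_rate = float(np.sqrt(pool * (1.0 - pool) * (1.0 / a.n + 1.0 / b.n)))
    if se_rate > 0:
        z_rate = delta_rate / se_rate
        p_rate = _two_sided_p(z_rate)
    else:
        z_rate, p_rate = 0.0, 1.0

    if delta_cost < 0 and delta_rate > 0:
        verdict = Verdict.A_DOMINATES
    elif delta_cost > 0 and delta_rate < 0:
        verdict = Verdict.B_DOMINATES
    else:
        verdict = Verdict.TRADEOFF

    return ComparisonResult(
        strategy_a=a.strategy,
        strategy_b=b.strategy,
        delta_cost=float(delta_cost),
        delta_rate=float(delta_rate),
        delta_cost_per_pregnancy=delta_cpp,
        z_cost=float(z_cost) if z_cost is not None else None,
        p_cost=p_cost,
        z_rate=float(z_rate) if z_rate is not None else None,
        p_rate=p_rate,
        verdict=verdict,
    )


def format_p(p: Optional[float], floor: float = 1e-4) -> str:
    """Display convention for p-values: values below the floor print as
    '< 0.0001'."""
    if p is None:
        return "undefined"
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.4g}"
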