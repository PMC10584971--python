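"""Synthetic parameter scenarios and one-way deterministic sensitivity scans.

Scenarios make every stage of the package testable without external data:
random tables with controlled interval widths, degenerate tables that force
known outcomes, and named override sets. ``sensitivity_scan`` extends the
probabilistic sensitivity analysis with one-way scans evaluated by the
closed-form model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analytic
from .parameters import (
    ParameterRange,
    ParameterValidationError,
    Strategy,
    StudyParameters,
    map_ranges,
    reference_parameters,
    set_parameter,
    validate,
)

__all__ = [
    "ScenarioSpec",
    "random_scenario",
    "degenerate_scenario",
    "sensitivity_scan",
    "DEGENERATE_KINDS",
]

# random cost magnitudes span the reference cost table's orders of magnitude
_COST_LO, _COST_HI = 10.0, 5000.0

DEGENERATE_KINDS = ("certain_success", "certain_failure", "single_cycle_only")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named base table plus a list of (path, range) overrides."""

    name: str
    base: StudyParameters
    overrides: tuple[tuple[str, ParameterRange], ...] = ()
    seed: int | None = None

    def realize(self) -> StudyParameters:
        """Apply overrides; raise if the result breaks any invariant."""
        params = self.base
        for path, r in self.overrides:
            params = set_parameter(params, path, r)
        violations = validate(params)
        if violations:
            raise ParameterValidationError(violations)
        return params


def random_scenario(
    seed: int, width_bounds: tuple[float, float] = (0.0, 0.3)
) -> StudyParameters:
    """Random valid parameter table with interval widths in ``width_bounds``.

    Probability ranges: width drawn uniformly from ``width_bounds``, lower
    bound uniform on ``[0, 1 - width]``. Cost ranges: lower bound drawn
    log-uniformly between €10 and €5,000, relative width from
    ``width_bounds``. ``width_bounds=(0, 0)`` yields a fully degenerate
    (point) table. Deterministic in ``seed``.
    """
    w_lo, w_hi = width_bounds
    if not (0.0 <= w_lo <= w_hi <= 1.0):
        raise ValueError("width_bounds must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)

    def draw(path: str, _r: ParameterRange) -> ParameterRange:
        w = rng.uniform(w_lo, w_hi)
        if path.startswith("cost."):
            lo = math.exp(rng.uniform(math.log(_COST_LO), math.log(_COST_HI)))
            return ParameterRange(lo, lo * (1.0 + w))
        lo = rng.uniform(0.0, 1.0 - w)
        return ParameterRange(lo, lo + w)

    params = map_ranges(reference_parameters(), draw)
    assert not validate(params)
    return params


def degenerate_scenario(kind: str) -> StudyParameters:
    """Reference table forced into a structurally trivial regime.

    ``certain_success``: every probability is 1 and the ICSI share 0, so the
    first fresh cycle is always an IVF pregnancy. ``certain_failure``: all
    three pregnancy probabilities are 0. ``single_cycle_only``: both
    continuation gates are 0, so the program is exactly one fresh cycle.
    """
    base = reference_parameters()
    one = ParameterRange.fixed(1.0)
    zero = ParameterRange.fixed(0.0)
    if kind == "certain_success":
        params = map_ranges(
            base,
            lambda path, r: one if not path.startswith("cost.") else r,
        )
        return set_parameter(params, "fresh.icsi_share", zero)
    if kind == "certain_failure":
        for path in (
            "fresh.ivf_pregnancy",
            "fresh.icsi_pregnancy",
            "frozen.pregnancy_after_survival",
        ):
            base = set_parameter(base, path, zero)
        return base
    if kind == "single_cycle_only":
        for path in (
            "sequence.start_cycle2_after_failure",
            "sequence.start_cycle3_after_failure",
        ):
            base = set_parameter(base, path, zero)
        return base
    raise ValueError(
        f"unknown degenerate scenario {kind!r}; choose from {DEGENERATE_KINDS}"
    )


def sensitivity_scan(
    base: StudyParameters,
    parameter_path: str,
    grid: list[float],
    strategy: Strategy,
    *,
    ohss_prob: float = 0.0,
) -> pd.DataFrame:
    """One-way deterministic sensitivity scan evaluated analytically.

    All parameters are held at the midpoints of ``base`` except the one at
    ``parameter_path``, which takes each grid value in turn (as a fixed
    point). Returns one row per grid value with columns ``value``,
    ``pregnancy``, ``cost`` and ``cost_per_pregnancy``.
    """
    point = analytic.midpoint(base)
    rows = []
    for v in grid:
        p = set_parameter(point, parameter_path, ParameterRange.fixed(v))
        violations = validate(p)
        if violations:
            raise ParameterValidationError(violations)
        exp = analytic.expected_program_outcomes(
            p, strategy, ohss_prob=ohss_prob
        )
        rows.append(
            {
                "value": v,
                "pregnancy": exp.pregnancy,
                "cost": exp.cost,
                "cost_per_pregnancy": exp.cost_per_pregnancy,
            }
        )
    return pd.DataFrame(rows, columns=["value", "pregnancy", "cost", "cost_per_pregnancy"])
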