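"""Closed-form expected-value evaluation of the treatment program.

Because every probability and cost is drawn independently and uniformly at
each use, the program's expected pregnancy probability and expected total
cost are multilinear functions of the individual draw means — i.e. of the
range midpoints. The functions here evaluate that decision tree exactly,
serving as the deterministic oracle against which the stochastic engine in
:mod:`ivfsim.pathway` is cross-validated.

``midpoint(params)`` collapses every range to its midpoint. Point
parameterizations are represented as ordinary :class:`StudyParameters`
whose ranges are all degenerate, so they can be validated and simulated
with the same machinery. Evaluation at an arbitrary (non-degenerate)
parameter table is also exact: only the midpoints enter the expectation.

Covers the default ``table_faithful`` sequencing; the embryo-gated variant
is history-dependent and has no closed form here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    ParameterRange,
    Strategy,
    StudyParameters,
    map_ranges,
)

__all__ = [
    "ProgramExpectation",
    "midpoint",
    "expected_fresh_pregnancy",
    "expected_fresh_cost",
    "expected_frozen_pregnancy",
    "expected_frozen_cost",
    "expected_program_outcomes",
]


@dataclass(frozen=True)
class ProgramExpectation:
    """Exact program-level expectations for one strategy."""

    pregnancy: float
    cost: float

    @property
    def cost_per_pregnancy(self) -> float | None:
        """Expected cost divided by pregnancy probability (None if 0)."""
        if self.pregnancy == 0:
            return None
        return self.cost / self.pregnancy


def midpoint(params: StudyParameters) -> StudyParameters:
    """Collapse every range ``[lo, hi]`` to the degenerate ``[(lo+hi)/2]``."""
    return map_ranges(
        params, lambda _path, r: ParameterRange.fixed(r.midpoint)
    )


def _m(r: ParameterRange) -> float:
    return r.midpoint


def expected_fresh_pregnancy(p: StudyParameters, strategy: Strategy) -> float:
    """Probability that a single fresh cycle ends in ongoing pregnancy.

    pickup · usable · [(1−s)·fert_ivf·et_ivf·preg_ivf
                       + s·fert_icsi·et_icsi·preg_icsi]
    with s the ICSI share.
    """
    f = p.fresh(Strategy(strategy))
    s = _m(f.icsi_share)
    ivf = _m(f.ivf_fertilization) * _m(f.ivf_transfer) * _m(f.ivf_pregnancy)
    icsi = _m(f.icsi_fertilization) * _m(f.icsi_transfer) * _m(f.icsi_pregnancy)
    return (
        _m(f.oocyte_pickup)
        * _m(f.usable_oocytes)
        * ((1.0 - s) * ivf + s * icsi)
    )


def expected_fresh_cost(
    p: StudyParameters, strategy: Strategy, *, ohss_prob: float = 0.0
) -> float:
    """Expected cost of one fresh cycle, each item weighted by the
    probability that its stage is reached."""
    strategy = Strategy(strategy)
    f = p.fresh(strategy)
    c = p.costs
    stim = c.stim_rfsh_myoins if strategy is Strategy.RFSH_MYOINS else c.stim_rfsh
    cost = (
        _m(stim)
        + _m(c.other_hormones)
        + _m(c.monitoring_ultrasounds)
        + _m(c.consultations)
        + ohss_prob * _m(c.ohss_treatment)
    )
    p_pick = _m(f.oocyte_pickup)
    cost += p_pick * (_m(c.oocyte_pickup) + _m(c.pickup_ultrasound))
    p_lab = p_pick * _m(f.usable_oocytes)
    s = _m(f.icsi_share)
    cost += p_lab * (
        (1.0 - s) * _m(c.ivf_lab) + s * (_m(c.icsi_procedure) + _m(c.icsi_lab))
    )
    # catheter billed when a transfer is performed
    p_et_ivf = _m(f.ivf_fertilization) * _m(f.ivf_transfer)
    p_et_icsi = _m(f.icsi_fertilization) * _m(f.icsi_transfer)
    cost += p_lab * (
        (1.0 - s) * p_et_ivf * _m(c.fresh_et_ivf_catheter)
        + s * p_et_icsi * _m(c.icsi_et_catheter)
    )
    return cost


def expected_frozen_pregnancy(p: StudyParameters) -> float:
    """survival · pregnancy_after_survival."""
    return _m(p.frozen.embryo_survival) * _m(p.frozen.pregnancy_after_survival)


def expected_frozen_cost(p: StudyParameters) -> float:
    return _m(p.costs.freeze_and_thaw) + _m(p.frozen.embryo_survival) * _m(
        p.costs.frozen_et_catheter
    )


def expected_program_outcomes(
    p: StudyParameters, strategy: Strategy, *, ohss_prob: float = 0.0
) -> ProgramExpectation:
    """Exact expectation over the full up-to-3-cycle decision tree.

    Cycle 1 is fresh. After any failure the cycle-2 continuation gate is
    drawn; a patient still not pregnant after the cycle-2 stage — whether
    the cycle was run and failed, or declined — draws the cycle-3 gate.
    Later cycles mix fresh and frozen pathways with the per-cycle shares.
    Equals the true mean of the stochastic engine because the tree value is
    multilinear in the independent draws.
    """
    pf = expected_fresh_pregnancy(p, strategy)
    cf = expected_fresh_cost(p, strategy, ohss_prob=ohss_prob)
    pz = expected_frozen_pregnancy(p)
    cz = expected_frozen_cost(p)
    seq = p.sequence
    c2, s2 = _m(seq.start_cycle2_after_failure), _m(seq.fresh_share_cycle2)
    c3, s3 = _m(seq.start_cycle3_after_failure), _m(seq.fresh_share_cycle3)

    p2 = s2 * pf + (1.0 - s2) * pz  # pregnancy prob of a run cycle 2
    e2 = s2 * cf + (1.0 - s2) * cz
    p3 = s3 * pf + (1.0 - s3) * pz
    e3 = s3 * cf + (1.0 - s3) * cz

    # conditional on cycle-1 failure
    preg_tail = c2 * p2 + (1.0 - c2 * p2) * c3 * p3
    cost_tail = c2 * e2 + (1.0 - c2 * p2) * c3 * e3

    return ProgramExpectation(
        pregnancy=pf + (1.0 - pf) * preg_tail,
        cost=cf + (1.0 - pf) * cost_tail,
    )
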