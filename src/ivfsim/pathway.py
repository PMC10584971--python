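"""Patient-level treatment-pathway engine.

One virtual PCOS patient runs through up to three IVF cycles. The first
cycle is, by definition, fresh: stimulation, oocyte pickup, laboratory
fertilization (conventional IVF or ICSI), embryo transfer, and an
ongoing-pregnancy check at 12 gestational weeks. After any failed cycle the
patient may start another cycle, which is fresh or frozen-thawed according
to the sequencing shares; a frozen cycle is thaw + transfer only. The
program stops at the first ongoing pregnancy, at a refusal to continue, or
after the third cycle.

Every stage probability and every unit cost is redrawn uniformly from its
range at each use, and each stage event is a Bernoulli trial on the drawn
probability. Because draws are independent, every program-level expectation
is multilinear in the range midpoints, which is what makes the closed-form
evaluation in :mod:`ivfsim.analytic` exact.

Cost accrual is stage-conditional: an item is billed only when its stage is
reached (e.g. the pickup fee only on successful pickup, the catheter only
when a transfer is performed). Ovarian-hyperstimulation-syndrome (OHSS)
treatment is not billed by default; ``ohss_prob`` bills it per fresh cycle
with the given probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .parameters import (
    ParameterValidationError,
    Strategy,
    StudyParameters,
    validate,
)

__all__ = [
    "CycleKind",
    "Technique",
    "TerminalStage",
    "SequencingMode",
    "CycleRealization",
    "PatientOutcome",
    "simulate_fresh_cycle",
    "simulate_frozen_cycle",
    "simulate_patient",
    "outcomes_to_records",
]


class CycleKind(str, Enum):
    FRESH = "fresh"
    FROZEN = "frozen"


class Technique(str, Enum):
    IVF = "ivf"
    ICSI = "icsi"
    NONE = "none"


class TerminalStage(str, Enum):
    """First failed stage of a cycle, or ``pregnant``.

    Fresh cycles can end at any of the first six values; frozen cycles only
    at ``thaw_failed``, ``transfer_failed`` or ``pregnant``.
    ``transfer_not_reached`` means fertilization succeeded but no transfer
    was performed; ``transfer_failed`` means a transfer was performed and no
    ongoing pregnancy followed.
    """

    PICKUP_FAILED = "pickup_failed"
    NO_USABLE_OOCYTES = "no_usable_oocytes"
    FERTILIZATION_FAILED = "fertilization_failed"
    TRANSFER_NOT_REACHED = "transfer_not_reached"
    TRANSFER_FAILED = "transfer_failed"
    PREGNANT = "pregnant"
    THAW_FAILED = "thaw_failed"


class SequencingMode(str, Enum):
    """How cycles 2–3 are made available.

    ``table_faithful`` (default): frozen cycles are available unconditionally
    with the tabulated fresh/frozen shares. ``strict_embryo_gating``: a
    frozen cycle requires a prior fresh cycle that reached successful
    fertilization (so a cryopreserved embryo can exist); otherwise the cycle
    falls back to fresh.
    """

    TABLE_FAITHFUL = "table_faithful"
    STRICT_EMBRYO_GATING = "strict_embryo_gating"


# stages at which fertilization had succeeded in a fresh cycle
_FERTILIZED_STAGES = frozenset(
    {
        TerminalStage.TRANSFER_NOT_REACHED,
        TerminalStage.TRANSFER_FAILED,
        TerminalStage.PREGNANT,
    }
)


@dataclass(frozen=True)
class CycleRealization:
    """One simulated treatment cycle: terminal stage and itemized cost."""

    kind: CycleKind
    technique: Technique
    terminal_stage: TerminalStage
    pregnant: bool
    cost: float
    cost_items: Mapping[str, float]

    @property
    def reached_fertilization(self) -> bool:
        """True when a fresh cycle produced at least one fertilized embryo."""
        return self.kind is CycleKind.FRESH and self.terminal_stage in _FERTILIZED_STAGES


@dataclass(frozen=True)
class PatientOutcome:
    """One patient's full program: 1–3 cycles, pregnancy flag, total cost."""

    strategy: Strategy
    cycles: tuple[CycleRealization, ...]
    pregnant: bool
    total_cost: float
    cycles_used: int


def _require_valid(params: StudyParameters) -> None:
    violations = validate(params)
    if violations:
        raise ParameterValidationError(violations)


def _event(r, rng: np.random.Generator) -> bool:
    """Bernoulli trial with success probability freshly drawn from ``r``."""
    return rng.random() < r.sample(rng)


def simulate_fresh_cycle(
    params: StudyParameters,
    strategy: Strategy,
    rng: np.random.Generator,
    *,
    ohss_prob: float = 0.0,
    _validated: bool = False,
) -> CycleRealization:
    """Simulate one fresh cycle: stimulation through ongoing-pregnancy check.

    Costs billed unconditionally: the arm's stimulation drug, adjunct
    hormones (GnRH agonist, hCG), monitoring ultrasounds and consultations.
    Everything downstream is billed only when its stage is reached.
    """
    if not _validated:
        _require_valid(params)
    strategy = Strategy(strategy)
    fresh = params.fresh(strategy)
    costs = params.costs
    items: dict[str, float] = {}

    stim_name = (
        "stim_rfsh_myoins" if strategy is Strategy.RFSH_MYOINS else "stim_rfsh"
    )
    items[stim_name] = getattr(costs, stim_name).sample(rng)
    items["other_hormones"] = costs.other_hormones.sample(rng)
    items["monitoring_ultrasounds"] = costs.monitoring_ultrasounds.sample(rng)
    items["consultations"] = costs.consultations.sample(rng)
    if ohss_prob > 0.0 and rng.random() < ohss_prob:
        items["ohss_treatment"] = costs.ohss_treatment.sample(rng)

    def finish(stage: TerminalStage, technique: Technique) -> CycleRealization:
        return CycleRealization(
            kind=CycleKind.FRESH,
            technique=technique,
            terminal_stage=stage,
            pregnant=stage is TerminalStage.PREGNANT,
            cost=sum(items.values()),
            cost_items=items,
        )

    if not _event(fresh.oocyte_pickup, rng):
        return finish(TerminalStage.PICKUP_FAILED, Technique.NONE)
    items["oocyte_pickup"] = costs.oocyte_pickup.sample(rng)
    items["pickup_ultrasound"] = costs.pickup_ultrasound.sample(rng)

    if not _event(fresh.usable_oocytes, rng):
        return finish(TerminalStage.NO_USABLE_OOCYTES, Technique.NONE)

    use_icsi = rng.random() < fresh.icsi_share.sample(rng)
    if use_icsi:
        technique = Technique.ICSI
        items["icsi_procedure"] = costs.icsi_procedure.sample(rng)
        items["icsi_lab"] = costs.icsi_lab.sample(rng)
        fert, transfer, pregnancy = (
            fresh.icsi_fertilization,
            fresh.icsi_transfer,
            fresh.icsi_pregnancy,
        )
        catheter_name = "icsi_et_catheter"
    else:
        technique = Technique.IVF
        items["ivf_lab"] = costs.ivf_lab.sample(rng)
        fert, transfer, pregnancy = (
            fresh.ivf_fertilization,
            fresh.ivf_transfer,
            fresh.ivf_pregnancy,
        )
        catheter_name = "fresh_et_ivf_catheter"

    if not _event(fert, rng):
        return finish(TerminalStage.FERTILIZATION_FAILED, technique)
    if not _event(transfer, rng):
        return finish(TerminalStage.TRANSFER_NOT_REACHED, technique)
    items[catheter_name] = getattr(costs, catheter_name).sample(rng)
    if not _event(pregnancy, rng):
        return finish(TerminalStage.TRANSFER_FAILED, technique)
    return finish(TerminalStage.PREGNANT, technique)


def simulate_frozen_cycle(
    params: StudyParameters,
    rng: np.random.Generator,
    *,
    _validated: bool = False,
) -> CycleRealization:
    """Simulate one frozen-thawed cycle: thaw, transfer, pregnancy check."""
    if not _validated:
        _require_valid(params)
    items: dict[str, float] = {
        "freeze_and_thaw": params.costs.freeze_and_thaw.sample(rng)
    }

    def finish(stage: TerminalStage) -> CycleRealization:
        return CycleRealization(
            kind=CycleKind.FROZEN,
            technique=Technique.NONE,
            terminal_stage=stage,
            pregnant=stage is TerminalStage.PREGNANT,
            cost=sum(items.values()),
            cost_items=items,
        )

    if not _event(params.frozen.embryo_survival, rng):
        return finish(TerminalStage.THAW_FAILED)
    items["frozen_et_catheter"] = params.costs.frozen_et_catheter.sample(rng)
    if not _event(params.frozen.pregnancy_after_survival, rng):
        return finish(TerminalStage.TRANSFER_FAILED)
    return finish(TerminalStage.PREGNANT)


def simulate_patient(
    params: StudyParameters,
    strategy: Strategy,
    rng: np.random.Generator,
    mode: SequencingMode = SequencingMode.TABLE_FAITHFUL,
    *,
    ohss_prob: float = 0.0,
    _validated: bool = False,
) -> PatientOutcome:
    """Simulate a full program of up to three cycles for one patient.

    Cycle 1 is always fresh. A patient who is not pregnant draws the
    cycle-2 continuation gate; whether or not cycle 2 was started, a patient
    who is still not pregnant then draws the cycle-3 gate. Cycles 2 and 3
    are fresh or frozen according to the per-cycle fresh shares.
    """
    if not _validated:
        _require_valid(params)
    strategy = Strategy(strategy)
    mode = SequencingMode(mode)
    seq = params.sequence
    cycles: list[CycleRealization] = [
        simulate_fresh_cycle(
            params, strategy, rng, ohss_prob=ohss_prob, _validated=True
        )
    ]

    def next_cycle(share_fresh) -> CycleRealization:
        fresh_chosen = rng.random() < share_fresh.sample(rng)
        if not fresh_chosen and mode is SequencingMode.STRICT_EMBRYO_GATING:
            if not any(c.reached_fertilization for c in cycles):
                fresh_chosen = True  # no embryo ever frozen: fall back to fresh
        if fresh_chosen:
            return simulate_fresh_cycle(
                params, strategy, rng, ohss_prob=ohss_prob, _validated=True
            )
        return simulate_frozen_cycle(params, rng, _validated=True)

    if not cycles[-1].pregnant and _event(seq.start_cycle2_after_failure, rng):
        cycles.append(next_cycle(seq.fresh_share_cycle2))
    if not cycles[-1].pregnant and _event(seq.start_cycle3_after_failure, rng):
        cycles.append(next_cycle(seq.fresh_share_cycle3))

    return PatientOutcome(
        strategy=strategy,
        cycles=tuple(cycles),
        pregnant=cycles[-1].pregnant,
        total_cost=sum(c.cost for c in cycles),
        cycles_used=len(cycles),
    )


def outcomes_to_records(outcomes: Sequence[PatientOutcome]) -> list[dict]:
    """Flatten trajectories to one dict per cycle (for CSV audit export)."""
    records = []
    for pid, out in enumerate(outcomes):
        for cno, cyc in enumerate(out.cycles, start=1):
            records.append(
                {
                    "patient": pid,
                    "strategy": out.strategy.value,
                    "cycle": cno,
                    "kind": cyc.kind.value,
                    "technique": cyc.technique.value,
                    "terminal_stage": cyc.terminal_stage.value,
                    "pregnant": cyc.pregnant,
                    "cost": cyc.cost,
                }
            )
    return records
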