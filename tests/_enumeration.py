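"""Test-only oracle: flat exhaustive enumeration of the decision tree.

Enumerates every terminal path of one fresh cycle, one frozen cycle, and
the full up-to-3-cycle program at range midpoints, summing probability-
weighted costs directly. Built independently of the recursive evaluation in
``ivfsim.analytic``; mutual agreement to machine precision guards against
structural transcription errors of the pathway diagram.

Covers the default ``table_faithful`` sequencing.
"""

from __future__ import annotations

from ivfsim.parameters import Strategy, StudyParameters


def _m(r):
    return r.midpoint


def enumerate_fresh_outcomes(
    params: StudyParameters, strategy: Strategy, ohss_prob: float = 0.0
) -> list[tuple[float, float, str]]:
    """All (probability, expected cost, terminal stage) of one fresh cycle."""
    f = params.fresh(strategy)
    c = params.costs
    stim = (
        c.stim_rfsh_myoins if Strategy(strategy) is Strategy.RFSH_MYOINS else c.stim_rfsh
    )
    base = (
        _m(stim)
        + _m(c.other_hormones)
        + _m(c.monitoring_ultrasounds)
        + _m(c.consultations)
        + ohss_prob * _m(c.ohss_treatment)
    )
    out: list[tuple[float, float, str]] = []
    pu = _m(f.oocyte_pickup)
    out.append((1.0 - pu, base, "pickup_failed"))
    cost_picked = base + _m(c.oocyte_pickup) + _m(c.pickup_ultrasound)
    us = _m(f.usable_oocytes)
    out.append((pu * (1.0 - us), cost_picked, "no_usable_oocytes"))
    s = _m(f.icsi_share)
    branches = (
        (
            1.0 - s,
            _m(c.ivf_lab),
            _m(f.ivf_fertilization),
            _m(f.ivf_transfer),
            _m(f.ivf_pregnancy),
            _m(c.fresh_et_ivf_catheter),
        ),
        (
            s,
            _m(c.icsi_procedure) + _m(c.icsi_lab),
            _m(f.icsi_fertilization),
            _m(f.icsi_transfer),
            _m(f.icsi_pregnancy),
            _m(c.icsi_et_catheter),
        ),
    )
    for share, lab, fert, et, preg, cath in branches:
        p0 = pu * us * share
        c0 = cost_picked + lab
        out.append((p0 * (1.0 - fert), c0, "fertilization_failed"))
        out.append((p0 * fert * (1.0 - et), c0, "transfer_not_reached"))
        c1 = c0 + cath
        out.append((p0 * fert * et * (1.0 - preg), c1, "transfer_failed"))
        out.append((p0 * fert * et * preg, c1, "pregnant"))
    return out


def enumerate_frozen_outcomes(
    params: StudyParameters,
) -> list[tuple[float, float, str]]:
    c = params.costs
    surv = _m(params.frozen.embryo_survival)
    preg = _m(params.frozen.pregnancy_after_survival)
    thaw = _m(c.freeze_and_thaw)
    cath = _m(c.frozen_et_catheter)
    return [
        (1.0 - surv, thaw, "thaw_failed"),
        (surv * (1.0 - preg), thaw + cath, "transfer_failed"),
        (surv * preg, thaw + cath, "pregnant"),
    ]


def enumerate_program_paths(
    params: StudyParameters, strategy: Strategy, ohss_prob: float = 0.0
) -> list[tuple[float, float, bool]]:
    """All (probability, expected cost, pregnant) paths of the full program."""
    fresh = enumerate_fresh_outcomes(params, strategy, ohss_prob)
    frozen = enumerate_frozen_outcomes(params)
    seq = params.sequence
    c2, s2 = _m(seq.start_cycle2_after_failure), _m(seq.fresh_share_cycle2)
    c3, s3 = _m(seq.start_cycle3_after_failure), _m(seq.fresh_share_cycle3)

    def stage(start_prob: float, fresh_share: float):
        """Options at a continuation stage: skip, or run a fresh/frozen cycle."""
        opts = [(1.0 - start_prob, 0.0, None)]
        for q, cost, st in fresh:
            opts.append((start_prob * fresh_share * q, cost, st == "pregnant"))
        for q, cost, st in frozen:
            opts.append((start_prob * (1.0 - fresh_share) * q, cost, st == "pregnant"))
        return opts

    paths: list[tuple[float, float, bool]] = []
    for p1, cost1, st1 in fresh:
        if st1 == "pregnant":
            paths.append((p1, cost1, True))
            continue
        for p2, cost2, preg2 in stage(c2, s2):
            if preg2:
                paths.append((p1 * p2, cost1 + cost2, True))
                continue
            for p3, cost3, preg3 in stage(c3, s3):
                paths.append(
                    (p1 * p2 * p3, cost1 + cost2 + cost3, bool(preg3))
                )
    return paths


def enumerated_program_expectation(
    params: StudyParameters, strategy: Strategy, ohss_prob: float = 0.0
) -> tuple[float, float]:
    """(pregnancy probability, expected total cost) from the flat paths."""
    paths = enumerate_program_paths(params, strategy, ohss_prob)
    total = sum(p for p, _c, _g in paths)
    assert abs(total - 1.0) < 1e-9, f"path probabilities sum to {total}"
    preg = sum(p for p, _c, g in paths if g)
    cost = sum(p * c for p, c, _g in paths)
    return preg, cost
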