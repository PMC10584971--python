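"""Model parameter tables: transition-probability ranges and unit-cost ranges.

The simulation is parameterized entirely by closed intervals ``[lo, hi]``.
Probabilities are stored as fractions in ``[0, 1]``; unit costs are stored in
euros. Every interval is sampled uniformly at each use, so the interval
midpoint is the exact expected value of each draw.

The built-in :func:`reference_parameters` fixture encodes the Italian
reference setting for IVF programs in PCOS patients: per-arm fresh-cycle
transition probabilities (rFSH + myo-inositol versus rFSH only), shared
frozen-cycle and cycle-sequencing probabilities, and the cost table of the
Italian Health System. The same tables can be loaded from, and written to, a
plain CSV dialect in which probabilities appear in percent — visually
checkable against the published source tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterator, Mapping, Union

import numpy as np

__all__ = [
    "Strategy",
    "ParameterRange",
    "FreshCycleProbabilities",
    "FrozenCycleProbabilities",
    "SequenceProbabilities",
    "CostTable",
    "StudyParameters",
    "Violation",
    "ParameterLoadError",
    "ParameterValidationError",
    "ParameterPathError",
    "reference_parameters",
    "validate",
    "load_parameter_tables",
    "write_parameter_tables",
    "parameter_paths",
    "set_parameter",
    "get_parameter",
    "map_ranges",
    "parameter_dictionary",
]


class Strategy(str, Enum):
    """Ovarian-stimulation arm: rFSH alone or rFSH plus oral myo-inositol."""

    RFSH = "rfsh"
    RFSH_MYOINS = "rfsh_myoins"


@dataclass(frozen=True)
class ParameterRange:
    """Closed interval ``[lo, hi]`` for one probability or unit cost.

    A degenerate range ``lo == hi`` represents a fixed value. Sampling is
    uniform; the mean of each draw is therefore :attr:`midpoint`.
    """

    lo: float
    hi: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def is_degenerate(self) -> bool:
        return self.lo == self.hi

    def sample(self, rng: np.random.Generator) -> float:
        """One uniform draw from the interval."""
        if self.lo == self.hi:
            return self.lo
        return rng.uniform(self.lo, self.hi)

    @classmethod
    def fixed(cls, value: float) -> "ParameterRange":
        return cls(value, value)


@dataclass(frozen=True)
class FreshCycleProbabilities:
    """Stage-transition probability ranges of one fresh IVF/ICSI cycle.

    ``icsi_share`` is the probability that the laboratory performs ICSI
    rather than conventional IVF insemination.
    """

    oocyte_pickup: ParameterRange
    usable_oocytes: ParameterRange
    icsi_share: ParameterRange
    ivf_fertilization: ParameterRange
    ivf_transfer: ParameterRange
    ivf_pregnancy: ParameterRange
    icsi_fertilization: ParameterRange
    icsi_transfer: ParameterRange
    icsi_pregnancy: ParameterRange


@dataclass(frozen=True)
class FrozenCycleProbabilities:
    """Transition probabilities of a frozen-thawed embryo-transfer cycle."""

    embryo_survival: ParameterRange
    pregnancy_after_survival: ParameterRange


@dataclass(frozen=True)
class SequenceProbabilities:
    """Continuation and fresh-versus-frozen shares for cycles 2 and 3."""

    start_cycle2_after_failure: ParameterRange
    fresh_share_cycle2: ParameterRange
    start_cycle3_after_failure: ParameterRange
    fresh_share_cycle3: ParameterRange


@dataclass(frozen=True)
class CostTable:
    """Unit-cost ranges in euros for every billable step of the program."""

    stim_rfsh: ParameterRange
    stim_rfsh_myoins: ParameterRange
    other_hormones: ParameterRange
    monitoring_ultrasounds: ParameterRange
    consultations: ParameterRange
    oocyte_pickup: ParameterRange
    pickup_ultrasound: ParameterRange
    ivf_lab: ParameterRange
    fresh_et_ivf_catheter: ParameterRange
    ohss_treatment: ParameterRange
    icsi_procedure: ParameterRange
    icsi_lab: ParameterRange
    icsi_et_catheter: ParameterRange
    freeze_and_thaw: ParameterRange
    frozen_et_catheter: ParameterRange


@dataclass(frozen=True)
class StudyParameters:
    """Complete model parameterization.

    Fresh-cycle probabilities are arm-specific; frozen-cycle probabilities,
    cycle sequencing and all cost items other than the stimulation drug are
    shared between the two arms.
    """

    fresh_by_arm: Mapping[Strategy, FreshCycleProbabilities]
    frozen: FrozenCycleProbabilities
    sequence: SequenceProbabilities
    costs: CostTable

    def fresh(self, strategy: Strategy) -> FreshCycleProbabilities:
        return self.fresh_by_arm[Strategy(strategy)]


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the parameter path and the rule it breaks."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class ParameterLoadError(ValueError):
    """A parameter file is missing rows or contains malformed numbers."""


class ParameterValidationError(ValueError):
    """Raised by loaders when a table fails :func:`validate`."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid parameters: " + "; ".join(str(v) for v in violations)
        )


class ParameterPathError(KeyError):
    """An unknown dotted parameter path; the message lists valid paths."""


# ---------------------------------------------------------------------------
# Built-in reference fixture
# ---------------------------------------------------------------------------

_PCT = 0.01


def _pr(lo_pct: float, hi_pct: float) -> ParameterRange:
    """Probability range from percent bounds."""
    return ParameterRange(lo_pct * _PCT, hi_pct * _PCT)


def reference_parameters() -> StudyParameters:
    """Built-in reference parameterization (Italian setting, PCOS patients).

    Probability ranges are stored as fractions; the printed sources quote
    them in percent. Cost ranges are euros per item. The single-valued
    pickup ultrasound fee is the degenerate range ``[30, 30]``.
    """
    fresh_myoins = FreshCycleProbabilities(
        oocyte_pickup=_pr(70, 80),
        usable_oocytes=_pr(85, 95),
        icsi_share=_pr(10, 50),
        ivf_fertilization=_pr(35, 75),
        ivf_transfer=_pr(75, 95),
        ivf_pregnancy=_pr(20, 45),
        icsi_fertilization=_pr(85, 100),
        icsi_transfer=_pr(85, 100),
        icsi_pregnancy=_pr(20, 45),
    )
    fresh_rfsh = FreshCycleProbabilities(
        oocyte_pickup=_pr(70, 80),
        usable_oocytes=_pr(80, 90),
        icsi_share=_pr(10, 50),
        ivf_fertilization=_pr(30, 70),
        ivf_transfer=_pr(70, 90),
        ivf_pregnancy=_pr(20, 45),
        icsi_fertilization=_pr(80, 100),
        icsi_transfer=_pr(80, 100),
        icsi_pregnancy=_pr(20, 45),
    )
    frozen = FrozenCycleProbabilities(
        embryo_survival=_pr(90, 100),
        pregnancy_after_survival=_pr(20, 45),
    )
    sequence = SequenceProbabilities(
        start_cycle2_after_failure=_pr(70, 100),
        fresh_share_cycle2=_pr(40, 60),
        start_cycle3_after_failure=_pr(30, 60),
        fresh_share_cycle3=_pr(20, 30),
    )
    costs = CostTable(
        stim_rfsh=ParameterRange(1000, 2000),
        stim_rfsh_myoins=ParameterRange(900, 1900),
        other_hormones=ParameterRange(40, 360),
        monitoring_ultrasounds=ParameterRange(90, 200),
        consultations=ParameterRange(60, 200),
        oocyte_pickup=ParameterRange(1000, 1000),
        pickup_ultrasound=ParameterRange(30, 30),
        ivf_lab=ParameterRange(300, 600),
        fresh_et_ivf_catheter=ParameterRange(100, 200),
        ohss_treatment=ParameterRange(90, 150),
        icsi_procedure=ParameterRange(500, 700),
        icsi_lab=ParameterRange(300, 700),
        icsi_et_catheter=ParameterRange(100, 200),
        freeze_and_thaw=ParameterRange(150, 500),
        frozen_et_catheter=ParameterRange(100, 200),
    )
    return StudyParameters(
        fresh_by_arm={
            Strategy.RFSH_MYOINS: fresh_myoins,
            Strategy.RFSH: fresh_rfsh,
        },
        frozen=frozen,
        sequence=sequence,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_FRESH_FIELDS = [f.name for f in dataclasses.fields(FreshCycleProbabilities)]
_FROZEN_FIELDS = [f.name for f in dataclasses.fields(FrozenCycleProbabilities)]
_SEQUENCE_FIELDS = [f.name for f in dataclasses.fields(SequenceProbabilities)]
_COST_FIELDS = [f.name for f in dataclasses.fields(CostTable)]


def _check_probability(path: str, r: ParameterRange, out: list[Violation]) -> None:
    if not (r.lo <= r.hi):
        out.append(Violation(path, f"lo > hi ({r.lo} > {r.hi})"))
    if r.lo < 0 or r.hi > 1:
        out.append(Violation(path, f"probability out of [0,1] ([{r.lo}, {r.hi}])"))


def _check_cost(path: str, r: ParameterRange, out: list[Violation]) -> None:
    if not (r.lo <= r.hi):
        out.append(Violation(path, f"lo > hi ({r.lo} > {r.hi})"))
    if r.lo < 0:
        out.append(Violation(path, f"cost negative (lo = {r.lo})"))


def validate(params: StudyParameters) -> list[Violation]:
    """Check every structural invariant; return violations (never raise).

    An empty list means the parameterization is valid: both arms present,
    every probability range inside ``[0, 1]`` with ``lo <= hi``, every cost
    range non-negative with ``lo <= hi``.
    """
    out: list[Violation] = []
    arms = set(params.fresh_by_arm)
    expected = {Strategy.RFSH, Strategy.RFSH_MYOINS}
    if arms != expected:
        out.append(
            Violation(
                "fresh_by_arm",
                f"arms must be exactly {sorted(s.value for s in expected)}, "
                f"got {sorted(s.value for s in arms)}",
            )
        )
    for arm, fresh in params.fresh_by_arm.items():
        for name in _FRESH_FIELDS:
            _check_probability(
                f"fresh.{Strategy(arm).value}.{name}", getattr(fresh, name), out
            )
    for name in _FROZEN_FIELDS:
        _check_probability(f"frozen.{name}", getattr(params.frozen, name), out)
    for name in _SEQUENCE_FIELDS:
        _check_probability(f"sequence.{name}", getattr(params.sequence, name), out)
    for name in _COST_FIELDS:
        _check_cost(f"cost.{name}", getattr(params.costs, name), out)
    return out


# ---------------------------------------------------------------------------
# Functional updates and dotted parameter paths
# ---------------------------------------------------------------------------


def map_ranges(
    params: StudyParameters, fn: Callable[[str, ParameterRange], ParameterRange]
) -> StudyParameters:
    """Return a copy with ``fn(path, range)`` applied to every range."""

    def _block(obj, prefix: str):
        return type(obj)(
            **{
                f.name: fn(f"{prefix}.{f.name}", getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        )

    return StudyParameters(
        fresh_by_arm={
            arm: _block(fresh, f"fresh.{Strategy(arm).value}")
            for arm, fresh in params.fresh_by_arm.items()
        },
        frozen=_block(params.frozen, "frozen"),
        sequence=_block(params.sequence, "sequence"),
        costs=_block(params.costs, "cost"),
    )


def parameter_paths() -> list[str]:
    """All dotted paths accepted by :func:`set_parameter`.

    ``fresh.<name>`` addresses both arms at once; ``fresh.<arm>.<name>``
    addresses a single arm. Frozen, sequence and cost parameters are shared.
    """
    paths = [f"fresh.{n}" for n in _FRESH_FIELDS]
    paths += [
        f"fresh.{arm.value}.{n}" for arm in Strategy for n in _FRESH_FIELDS
    ]
    paths += [f"frozen.{n}" for n in _FROZEN_FIELDS]
    paths += [f"sequence.{n}" for n in _SEQUENCE_FIELDS]
    paths += [f"cost.{n}" for n in _COST_FIELDS]
    return paths


def _path_error(path: str) -> ParameterPathError:
    return ParameterPathError(
        f"unknown parameter path {path!r}; valid paths: "
        + ", ".join(parameter_paths())
    )


def _resolve(path: str):
    """-> (block, arm or None, field name); raises on unknown paths."""
    parts = path.split(".")
    if len(parts) == 2:
        block, name = parts
        arm = None
    elif len(parts) == 3 and parts[0] == "fresh":
        block, name = parts[0], parts[2]
        try:
            arm = Strategy(parts[1])
        except ValueError:
            raise _path_error(path) from None
    else:
        raise _path_error(path)
    fields = {
        "fresh": _FRESH_FIELDS,
        "frozen": _FROZEN_FIELDS,
        "sequence": _SEQUENCE_FIELDS,
        "cost": _COST_FIELDS,
    }.get(block)
    if fields is None or name not in fields:
        raise _path_error(path)
    return block, arm, name


def set_parameter(
    params: StudyParameters, path: str, new_range: ParameterRange
) -> StudyParameters:
    """Return a copy with the range at ``path`` replaced.

    ``fresh.<name>`` (no arm segment) replaces the range in both arms.
    """
    block, arm, name = _resolve(path)
    if block == "fresh":
        new_by_arm = {}
        for a, fresh in params.fresh_by_arm.items():
            if arm is None or a == arm:
                fresh = dataclasses.replace(fresh, **{name: new_range})
            new_by_arm[a] = fresh
        return dataclasses.replace(params, fresh_by_arm=new_by_arm)
    if block == "frozen":
        return dataclasses.replace(
            params, frozen=dataclasses.replace(params.frozen, **{name: new_range})
        )
    if block == "sequence":
        return dataclasses.replace(
            params,
            sequence=dataclasses.replace(params.sequence, **{name: new_range}),
        )
    return dataclasses.replace(
        params, costs=dataclasses.replace(params.costs, **{name: new_range})
    )


def get_parameter(params: StudyParameters, path: str) -> ParameterRange:
    """Range at ``path``; for arm-less fresh paths both arms must agree."""
    block, arm, name = _resolve(path)
    if block == "fresh":
        if arm is not None:
            return getattr(params.fresh(arm), name)
        values = {getattr(f, name) for f in params.fresh_by_arm.values()}
        if len(values) > 1:
            raise ParameterPathError(
                f"{path!r} differs between arms; use fresh.<arm>.{name}"
            )
        return next(iter(values))
    obj = {
        "frozen": params.frozen,
        "sequence": params.sequence,
        "cost": params.costs,
    }[block]
    return getattr(obj, name)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
#
# One row per parameter: block,name,arm,min,max,units
#   block ∈ {fresh, frozen, sequence, cost}; arm ∈ {rfsh, rfsh_myoins, shared}
#   units ∈ {pct, eur}: probabilities are stored in percent in files (exactly
#   as printed in the source tables) and converted to fractions on load.

_CSV_COLUMNS = ["block", "name", "arm", "min", "max", "units"]


def _expected_rows() -> list[tuple[str, str, str, str]]:
    rows = [
        ("fresh", name, arm.value, "pct")
        for arm in (Strategy.RFSH_MYOINS, Strategy.RFSH)
        for name in _FRESH_FIELDS
    ]
    rows += [("frozen", name, "shared", "pct") for name in _FROZEN_FIELDS]
    rows += [("sequence", name, "shared", "pct") for name in _SEQUENCE_FIELDS]
    rows += [("cost", name, "shared", "eur") for name in _COST_FIELDS]
    return rows


def _fmt_number(x: float) -> str:
    """Format trimming float noise: 70.00000000000001 -> '70'."""
    r = round(x, 9)
    if r == int(r):
        return str(int(r))
    return repr(r)


def write_parameter_tables(params: StudyParameters, path: Union[str, Path]) -> None:
    """Write the CSV representation (probabilities in percent)."""
    lines = [",".join(_CSV_COLUMNS)]
    for block, name, arm, units in _expected_rows():
        if block == "fresh":
            r = getattr(params.fresh(Strategy(arm)), name)
        elif block == "frozen":
            r = getattr(params.frozen, name)
        elif block == "sequence":
            r = getattr(params.sequence, name)
        else:
            r = getattr(params.costs, name)
        scale = 100.0 if units == "pct" else 1.0
        lines.append(
            ",".join(
                [
                    block,
                    name,
                    arm,
                    _fmt_number(r.lo * scale),
                    _fmt_number(r.hi * scale),
                    units,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _iter_csv_rows(path: Path) -> Iterator[tuple[int, dict]]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != _CSV_COLUMNS:
            raise ParameterLoadError(
                f"{path}: header must be {','.join(_CSV_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def load_parameter_tables(
    source: Union[str, Path], *, check: bool = True
) -> StudyParameters:
    """Load a :class:`StudyParameters` from the documented CSV layout.

    Percent values in the file are converted to fractions. Raises
    :class:`ParameterLoadError` on missing rows or malformed numbers and
    :class:`ParameterValidationError` (listing every violation) when the
    loaded table fails :func:`validate` — unless ``check=False``.
    """
    path = Path(source)
    if not path.exists():
        raise ParameterLoadError(f"parameter file not found: {path}")
    seen: dict[tuple[str, str, str], ParameterRange] = {}
    for lineno, row in _iter_csv_rows(path):
        key = (row["block"].strip(), row["name"].strip(), row["arm"].strip())
        units = row["units"].strip()
        try:
            lo = float(row["min"])
            hi = float(row["max"])
        except (TypeError, ValueError):
            raise ParameterLoadError(
                f"{path}:{lineno}: malformed number in row "
                f"{key[0]}/{key[1]} (min={row['min']!r}, max={row['max']!r})"
            ) from None
        scale = 0.01 if units == "pct" else 1.0
        seen[key] = ParameterRange(lo * scale, hi * scale)

    missing = [
        f"{b}/{n}/{a}"
        for (b, n, a, _u) in _expected_rows()
        if (b, n, a) not in seen
    ]
    if missing:
        raise ParameterLoadError(
            f"{path}: missing required rows: " + ", ".join(missing)
        )

    def fresh_for(arm: Strategy) -> FreshCycleProbabilities:
        return FreshCycleProbabilities(
            **{n: seen[("fresh", n, arm.value)] for n in _FRESH_FIELDS}
        )

    params = StudyParameters(
        fresh_by_arm={
            Strategy.RFSH_MYOINS: fresh_for(Strategy.RFSH_MYOINS),
            Strategy.RFSH: fresh_for(Strategy.RFSH),
        },
        frozen=FrozenCycleProbabilities(
            **{n: seen[("frozen", n, "shared")] for n in _FROZEN_FIELDS}
        ),
        sequence=SequenceProbabilities(
            **{n: seen[("sequence", n, "shared")] for n in _SEQUENCE_FIELDS}
        ),
        costs=CostTable(**{n: seen[("cost", n, "shared")] for n in _COST_FIELDS}),
    )
    if check:
        violations = validate(params)
        if violations:
            raise ParameterValidationError(violations)
    return params


def reference_csv_path() -> Path:
    """Path of the shipped reference-parameter CSV."""
    return Path(str(resources.files("ivfsim").joinpath("data/reference_parameters.csv")))


def parameter_dictionary() -> dict:
    """Machine-readable dictionary: canonical name -> source-table row label."""
    text = resources.files("ivfsim").joinpath("data/parameter_dictionary.json").read_text()
    return json.loads(text)
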