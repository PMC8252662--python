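"""Irradiation conditions, the energy measure E, and pulse schedules.

An irradiation condition is the triple (η, δ, τ):

* η — irradiance of the stimulation laser, W/cm²
* δ — irradiation time per unit area per single irradiation, µs/pixel
* τ — interval between successive irradiations, min

The energy delivered per unit area per unit time is ``E ∝ η·δ/τ``.  The
published condition table prints E in unstated absolute units (×10⁻¹⁴); only
ratios of E are physically anchored, so this module always reports the raw
rate η·δ/τ and, separately, a calibrated prediction of the printed column via
a single multiplicative constant C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "IrradiationCondition",
    "PulseSchedule",
    "UndefinedScheduleError",
    "condition_table",
    "get_condition",
    "relative_energy",
    "calibrate_energy_constant",
    "fit_energy_constant",
    "predict_printed_energy",
    "make_schedule",
    "read_conditions_csv",
    "write_conditions_csv",
]


class UndefinedScheduleError(ValueError):
    """Raised when a condition implies light delivery but no pulse timing."""


@dataclass(frozen=True)
class IrradiationCondition:
    """One row of the irradiation-condition table.

    The all-zero condition (label ``"0"``) is the unirradiated control.
    """

    label: str
    eta: float  # irradiance, W/cm²
    delta: float  # irradiation time per unit area, µs/pixel
    tau: float  # irradiation interval, min
    n_domains: int = 1  # replicate regions measured under this condition

    def __post_init__(self) -> None:
        if self.eta < 0 or self.delta < 0 or self.tau < 0:
            raise ValueError(f"condition {self.label!r}: η, δ, τ must be ≥ 0")
        if self.pulse_energy > 0 and self.tau <= 0:
            raise UndefinedScheduleError(
                f"condition {self.label!r}: η·δ > 0 requires an interval τ > 0"
            )

    @property
    def pulse_energy(self) -> float:
        """Per-pulse dose, proportional to η·δ (a.u.)."""
        return self.eta * self.delta

    @property
    def is_control(self) -> bool:
        """True for the unirradiated (η·δ = 0) control."""
        return self.pulse_energy == 0


@dataclass(frozen=True)
class PulseSchedule:
    """Deterministic pulse train expanded from a condition.

    ``pulse_times`` are minutes from experiment start, strictly increasing
    with consecutive differences equal to τ; ``pulse_energy`` is the per-pulse
    dose ∝ η·δ.
    """

    pulse_times: tuple[float, ...]
    pulse_energy: float
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times, dtype=float)
        if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0 or times[-1] >= self.duration):
            raise ValueError("pulse_times must be strictly increasing within [0, duration)")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)


#: Published irradiation conditions: label, η (W/cm²), δ (µs/px), τ (min),
#: printed E (×10⁻¹⁴, absolute unit unstated), N replicate domains.
_TABLE_ROWS = [
    ("0", 0.0, 0.0, 0.0, 0.0, 16),
    ("1", 0.022, 8.0, 20.0, 0.143, 4),
    ("2", 0.0077, 24.0, 20.0, 0.154, 3),
    ("3", 0.022, 24.0, 60.0, 0.143, 3),
    ("4", 0.071, 8.0, 60.0, 0.158, 3),
    ("5", 0.0077, 72.0, 60.0, 0.154, 3),
    ("6", 0.022, 8.0, 60.0, 0.0478, 4),
    ("7", 0.022, 8.0, 10.0, 0.287, 4),
    ("8", 0.0077, 8.0, 20.0, 0.0513, 6),
    ("9", 0.0077, 24.0, 60.0, 0.0513, 3),
]


def condition_table() -> pd.DataFrame:
    """The built-in condition table as a DataFrame.

    Columns: ``label, eta, delta, tau, printed_E, n_domains``.  ``printed_E``
    is the published energy column in its ×10⁻¹⁴ units (0 for the control).
    """
    return pd.DataFrame(
        _TABLE_ROWS, columns=["label", "eta", "delta", "tau", "printed_E", "n_domains"]
    )


def get_condition(label: str | int) -> IrradiationCondition:
    """Look up a built-in condition by its label."""
    label = str(label)
    for row in _TABLE_ROWS:
        if row[0] == label:
            return IrradiationCondition(row[0], row[1], row[2], row[3], row[5])
    raise KeyError(f"no built-in irradiation condition labelled {label!r}")


def relative_energy(cond: IrradiationCondition) -> float:
    """Energy per unit area per unit time, η·δ/τ, in raw units.

    Returns 0 for the unirradiated control.  Raises
    :class:`UndefinedScheduleError` if τ = 0 while η·δ > 0 (that combination
    cannot arise from a validated :class:`IrradiationCondition` but is guarded
    for raw inputs).
    """
    if cond.is_control:
        return 0.0
    if cond.tau <= 0:
        raise UndefinedScheduleError(f"condition {cond.label!r}: τ must be > 0")
    return cond.eta * cond.delta / cond.tau


def calibrate_energy_constant(cond: IrradiationCondition, printed_E: float) -> float:
    """Unit constant C such that ``C · η·δ/τ`` reproduces the printed E.

    The absolute unit of the published E column is unstated, so C is an
    artifact of the table's unit system; calibrated on any one irradiated
    condition it predicts every other row's printed value to within printed
    rounding.
    """
    rate = relative_energy(cond)
    if rate <= 0:
        raise ZeroDivisionError("cannot calibrate on the unirradiated control")
    return printed_E / rate


def fit_energy_constant(table: pd.DataFrame | None = None) -> float:
    """Single shared C minimizing proportional error across irradiated rows.

    Least-squares in log space, i.e. the geometric mean of per-row ratios
    printed_E / (η·δ/τ).
    """
    if table is None:
        table = condition_table()
    rates = table["eta"] * table["delta"] / table["tau"].where(table["tau"] > 0, np.nan)
    mask = rates > 0
    ratios = table.loc[mask, "printed_E"] / rates[mask]
    return float(np.exp(np.mean(np.log(ratios))))


def predict_printed_energy(cond: IrradiationCondition, constant: float, decimals: int = 3) -> float:
    """Predict the table's E column for ``cond`` using a calibrated C."""
    return round(constant * relative_energy(cond), decimals)


def make_schedule(cond: IrradiationCondition, duration: float) -> PulseSchedule:
    """Expand a condition into the pulse train over ``[0, duration)`` minutes.

    Pulses fall at 0, τ, 2τ, … strictly below ``duration`` (half-open
    convention; the first pulse coincides with experiment start).  The
    unirradiated control yields an empty train.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if cond.is_control:
        return PulseSchedule((), 0.0, float(duration))
    n = math.ceil(duration / cond.tau)
    times = tuple(k * cond.tau for k in range(n) if k * cond.tau < duration)
    return PulseSchedule(times, cond.pulse_energy, float(duration))


def read_conditions_csv(path) -> list[IrradiationCondition]:
    """Read conditions from CSV with columns label,eta,delta,tau,n_domains."""
    df = pd.read_csv(path, dtype={"label": str})
    return [
        IrradiationCondition(r.label, float(r.eta), float(r.delta), float(r.tau), int(r.n_domains))
        for r in df.itertuples()
    ]


def write_conditions_csv(conds: Iterable[IrradiationCondition], path) -> None:
    pd.DataFrame(
        [(c.label, c.eta, c.delta, c.tau, c.n_domains) for c in conds],
        columns=["label", "eta", "delta", "tau", "n_domains"],
    ).to_csv(path, index=False)
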