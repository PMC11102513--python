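"""Montage representation, validity checks, polarity inversion and current
density arithmetic.

A montage assigns a direct current to each labeled scalp electrode.
Positive currents are conducted into the scalp ("anodes"), negative
currents are return paths ("cathodes"); Kirchhoff's law requires the
currents to sum to zero.  Safety limits for multichannel stimulation are
expressed as a cap on the current at any single electrode and a cap on the
total injected (positive) current.  The published hypothalamus-network
montage uses pi cm^2 Ag/AgCl contacts, a +/-2.0 mA per-electrode limit and
a 4.0 mA total-injection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

__all__ = [
    "Montage",
    "StimProtocol",
    "ValidationReport",
    "current_density",
    "validate_montage",
    "invert_polarity",
    "table1_frame",
    "table1_montage",
]

#: Contact area of a Pistim-style circular electrode, cm^2.
DEFAULT_ELECTRODE_AREA_CM2 = math.pi

#: Tolerance on the zero-sum (Kirchhoff) condition, in uA.
NET_CURRENT_TOL_UA = 1e-6


@dataclass(frozen=True)
class Montage:
    """Per-electrode direct currents in microamperes.

    Parameters
    ----------
    currents_uA:
        Mapping electrode label -> current in uA.  Positive = current
        conducted into the scalp, negative = return.
    electrode_area_cm2:
        Contact area used for current-density arithmetic (default pi cm^2).
    polarity:
        Protocol tag: ``"anodal"``, ``"cathodal"`` or ``"sham"``.
    """

    currents_uA: dict[str, float]
    electrode_area_cm2: float = DEFAULT_ELECTRODE_AREA_CM2
    polarity: str = "anodal"

    def __post_init__(self):
        seen = set()
        for lab in self.currents_uA:
            key = lab.lower()
            if key in seen:
                raise ValueError(f"duplicate electrode label {lab!r} (labels are case-insensitive)")
            seen.add(key)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.currents_uA)

    def net_current_uA(self) -> float:
        return float(sum(self.currents_uA.values()))

    def total_injected_uA(self) -> float:
        """Sum of positive currents — the 'total injected current'."""
        return float(sum(c for c in self.currents_uA.values() if c > 0))

    def max_abs_uA(self) -> float:
        return float(max((abs(c) for c in self.currents_uA.values()), default=0.0))


@dataclass(frozen=True)
class StimProtocol:
    """Session timing: total duration plus linear current ramps.

    In a sham protocol current flows only during the ramps, mimicking the
    skin sensation of active stimulation without a sustained field.
    """

    duration_s: float = 1500.0  # 25 min
    ramp_up_s: float = 15.0
    ramp_down_s: float = 60.0
    sham: bool = False

    def __post_init__(self):
        if self.ramp_up_s < 0 or self.ramp_down_s < 0:
            raise ValueError("ramps must be nonnegative")
        if self.ramp_up_s + self.ramp_down_s > self.duration_s:
            raise ValueError("ramp-up + ramp-down exceeds session duration")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of montage safety/consistency checks; empty flags = valid."""

    flags: tuple[str, ...] = ()
    details: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.flags


def current_density(montage: Montage) -> dict[str, float]:
    """Per-electrode current density in mA/cm^2, sign preserved.

    density = current [uA] / 1000 / area [cm^2].
    """
    area = montage.electrode_area_cm2
    if area <= 0:
        raise ValueError(f"electrode area must be positive, got {area}")
    return {lab: c / 1000.0 / area for lab, c in montage.currents_uA.items()}


def validate_montage(montage: Montage, constraints=None, positions=None) -> ValidationReport:
    """Check a montage against Kirchhoff and safety constraints.

    Parameters
    ----------
    montage:
        The montage to check.
    constraints:
        Any object with ``per_electrode_mA`` and ``total_injected_mA``
        attributes (e.g. :class:`nettdcs.optimizer.ConstraintConfig`).
        ``None`` checks only the zero-sum condition.
    positions:
        Optional :class:`~nettdcs.positions.ElectrodePositionTable`; labels
        absent from it are flagged.

    Returns
    -------
    ValidationReport
        One flag per violated constraint; ``report.valid`` iff none.
    """
    flags: list[str] = []
    details: dict = {}

    net = montage.net_current_uA()
    details["net_current_uA"] = net
    if abs(net) > NET_CURRENT_TOL_UA:
        flags.append("net-current")

    if constraints is not None:
        imax_uA = constraints.per_electrode_mA * 1000.0
        itot_uA = constraints.total_injected_mA * 1000.0
        details["max_abs_uA"] = montage.max_abs_uA()
        details["total_injected_uA"] = montage.total_injected_uA()
        if montage.max_abs_uA() > imax_uA + 1e-9:
            flags.append("per-electrode-cap")
        if montage.total_injected_uA() > itot_uA + 1e-9:
            flags.append("total-injected-cap")

    if positions is not None:
        missing = tuple(l for l in montage.labels if l not in positions)
        if missing:
            flags.append("unknown-label")
            details["unknown_labels"] = missing

    return ValidationReport(tuple(flags), details)


def invert_polarity(montage: Montage) -> Montage:
    """Negate every current and swap the polarity tag.

    Sign inversion swaps excited and inhibited cortex, turning the montage
    built to excite the positively connected network into its inhibitory
    counterpart; validity (zero sum, caps) is preserved because the
    constraint set is sign-symmetric.
    """
    swapped = {"anodal": "cathodal", "cathodal": "anodal"}.get(montage.polarity, montage.polarity)
    return replace(
        montage,
        currents_uA={lab: -c for lab, c in montage.currents_uA.items()},
        polarity=swapped,
    )


def table1_frame() -> pd.DataFrame:
    """The published 12-electrode montage table (currents and densities)."""
    with resources.files("nettdcs.data").joinpath("table1_montage.csv").open() as fh:
        return pd.read_csv(fh)


def table1_montage(polarity: str = "anodal") -> Montage:
    """Build a :class:`Montage` from the published montage table."""
    if polarity not in ("anodal", "cathodal"):
        raise ValueError("polarity must be 'anodal' or 'cathodal'")
    df = table1_frame()
    currents = dict(zip(df["electrode_label"], df[f"{polarity}_current_uA"].astype(float)))
    return Montage(currents_uA=currents, polarity=polarity)


def sham_montage(montage: Montage) -> Montage:
    """Zero-current montage on the same electrodes.

    Represents the sustained state of a sham protocol; the ramp-only
    current delivery is timing, captured by :class:`StimProtocol`.
    """
    return replace(montage, currents_uA={l: 0.0 for l in montage.labels}, polarity="sham")
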