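"""Aeromechanic quantities of hovering flight from individual bird records.

The stroke-averaged vertical force balance for a hovering hummingbird is

    F_V = W = 1/2 * rho * Ubar**2 * S * C_V,

with air density ``rho``, mean wing velocity at the radius of gyration
``Ubar = 4 * Phi * f * R2`` (``Phi`` the cosine amplitude, i.e. half the
pronation-to-supination stroke amplitude), combined wing area ``S`` and a
dimensionless stroke-averaged vertical force coefficient ``C_V`` absorbing
wing posture and shape. Induced (wake) power follows actuator-disc theory:
``v_ind = sqrt(F / (2 * rho * A))`` with swept disc area ``A = Phi_p2s * R**2``,
and the specific induced power is ``P* = n * v_ind * (1 + tau + sigma)``
(load factor ``n``, Ellington-style temporal/spatial correction factors
``tau``/``sigma`` accepted as plain numbers).

Conventions used throughout:

* ``wing_area_S`` is the combined area of both wings; ``wing_length_R`` and
  ``R2 = r2_hat * R`` refer to a single wing. This keeps ``C_V`` in the
  conventional O(1) range.
* Records store the pronation-to-supination stroke amplitude (what wingbeat
  digitisation yields). ``mean_wing_velocity`` halves it internally to get
  the cosine amplitude; the swept-disc calculation uses it unhalved.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .constants import ISA, STANDARD_GRAVITY, TROPOSPHERE_TOP, Atmosphere

log = logging.getLogger(__name__)

#: plausible range for a vertical force coefficient; values outside it are
#: almost always a unit mix-up (g vs kg, cm^2 vs m^2).
FORCE_COEFFICIENT_RANGE = (0.1, 20.0)

AMPLITUDE_CONVENTIONS = ("p2s", "cosine")


class UnitSanityWarning(UserWarning):
    """A derived quantity landed outside its physically plausible range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IndividualRecord:
    """One bird: identity, environment, wing morphology, kinematics, burst force.

    SI units throughout: kilograms, metres, newtons, hertz, radians.
    ``hover_amplitude_Phi`` (and ``burst_amplitude``) follow the amplitude
    convention of the data set, pronation-to-supination by default.
    """

    id: str
    species: str
    clade: str = ""
    collector: str = ""
    elevation: float = 0.0
    body_mass: float = float("nan")
    weight: float = float("nan")
    wing_area_S: float = float("nan")
    wing_length_R: float = float("nan")
    r2_hat: float = float("nan")
    r3_hat: float = float("nan")
    aspect_ratio: float = float("nan")
    hover_frequency_f: float = float("nan")
    hover_amplitude_Phi: float = float("nan")
    burst_frequency: Optional[float] = None
    burst_amplitude: Optional[float] = None
    burst_force: Optional[float] = None

    def __post_init__(self) -> None:
        if math.isnan(self.weight) and not math.isnan(self.body_mass):
            self.weight = self.body_mass * STANDARD_GRAVITY

    def validate(self) -> None:
        """Check field invariants; raise ``ValueError`` naming the field."""
        for name in ("body_mass", "wing_area_S", "wing_length_R"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"record {self.id}: {name} must be > 0, got {v}")
        if not math.isnan(self.r2_hat) and not (0 < self.r2_hat < 1):
            raise ValueError(
                f"record {self.id}: r2_hat must lie in (0, 1), got {self.r2_hat}")
        if (not math.isnan(self.aspect_ratio)
                and not math.isnan(self.wing_length_R)
                and not math.isnan(self.wing_area_S)):
            ar = 4.0 * self.wing_length_R ** 2 / self.wing_area_S
            if abs(ar - self.aspect_ratio) > 1e-9 * max(1.0, abs(ar)):
                raise ValueError(
                    f"record {self.id}: aspect_ratio {self.aspect_ratio} "
                    f"inconsistent with 4R^2/S = {ar}")
        if self.burst_force is not None and not math.isnan(self.weight):
            if self.burst_force < self.weight:
                warnings.warn(
                    f"record {self.id}: burst force {self.burst_force} N below "
                    f"body weight {self.weight} N", UnitSanityWarning)


@dataclass
class DerivedAero:
    """Per-record aerodynamic quantities derived from an IndividualRecord."""

    air_density_rho: float = float("nan")      # kg m^-3
    R2: float = float("nan")                   # m, radius of gyration
    mean_wing_velocity_U: float = float("nan")  # m s^-1
    hover_force_coefficient: float = float("nan")
    burst_force_coefficient: Optional[float] = None
    load_factor_n: Optional[float] = None
    disc_area_A: float = float("nan")          # m^2
    induced_velocity: float = float("nan")     # m s^-1, weight support
    specific_induced_power_hover: float = float("nan")  # W N^-1
    specific_induced_power_burst: Optional[float] = None
    inflow_ratio: float = float("nan")


DERIVED_COLUMNS = [f.name for f in fields(DerivedAero)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def air_density_from_elevation(elevation: float,
                               reference: Atmosphere = ISA) -> float:
    """ISA troposphere air density (kg m^-3) at ``elevation`` metres a.s.l."""
    elevation = float(elevation)
    if not (0.0 <= elevation < TROPOSPHERE_TOP):
        raise ValueError(
            f"elevation {elevation} m outside the ISA troposphere [0, 11000)")
    t_ratio = 1.0 - reference.lapse_rate * elevation / reference.T0
    return reference.rho0 * t_ratio ** reference.exponent


def elevation_from_air_density(rho: float, reference: Atmosphere = ISA) -> float:
    """Inverse of :func:`air_density_from_elevation` (troposphere only)."""
    if not (0 < rho <= reference.rho0):
        raise ValueError(f"density {rho} outside (0, {reference.rho0}]")
    t_ratio = (rho / reference.rho0) ** (1.0 / reference.exponent)
    return (1.0 - t_ratio) * reference.T0 / reference.lapse_rate


def mean_wing_velocity(f: float, Phi: float, R2: float,
                       convention: str = "p2s") -> float:
    """Stroke-averaged wing velocity Ubar = 4 * Phi_cos * f * R2 (m s^-1).

    ``Phi`` is interpreted per ``convention``: with ``"p2s"`` (default) the
    stored pronation-to-supination amplitude is halved to the cosine
    amplitude before the formula is applied.
    """
    if f < 0 or Phi < 0 or R2 < 0:
        raise ValueError("f, Phi and R2 must be non-negative")
    if convention not in AMPLITUDE_CONVENTIONS:
        raise ValueError(f"unknown amplitude convention {convention!r}")
    phi_cos = Phi / 2.0 if convention == "p2s" else Phi
    return 4.0 * phi_cos * f * R2


def vertical_force_coefficient(F_V: float, rho: float, U: float,
                               S: float) -> float:
    """Stroke-averaged vertical force coefficient C_V = 2 F_V / (rho U^2 S)."""
    if rho <= 0 or S <= 0:
        raise ValueError("rho and S must be > 0")
    if U == 0:
        raise ValueError(
            "cannot form a force coefficient at zero wing velocity "
            "(division by rho * U^2 * S)")
    return 2.0 * F_V / (rho * U * U * S)


def load_factor(F_burst: float, W: float) -> float:
    """Burst load factor n = F_burst / W; warns (not fatal) when n < 1."""
    if W <= 0:
        raise ValueError("weight must be > 0")
    if F_burst < W:
        warnings.warn(
            f"burst force {F_burst} N below weight {W} N: recorded burst "
            "does not support body weight", UnitSanityWarning)
    return F_burst / W


def rf_induced_velocity(F: float, rho: float, Phi: float, R: float) -> float:
    """Rankine-Froude induced velocity sqrt(F / (2 rho A)), A = Phi * R^2.

    ``Phi`` is the pronation-to-supination stroke amplitude (the full angle
    swept by the wing defines the actuator disc sector).
    """
    if F <= 0 or rho <= 0 or Phi <= 0 or R <= 0:
        raise ValueError("F, rho, Phi and R must all be > 0")
    return math.sqrt(F / (2.0 * rho * Phi * R * R))


def specific_induced_power(n: float, v_ind: Optional[float] = None,
                           tau: float = 0.0, sigma: float = 0.0,
                           mode: str = "rankine_froude",
                           lambda_inflow: Optional[float] = None,
                           U: Optional[float] = None) -> float:
    """Specific induced power P* = P_ind / W in W N^-1.

    ``rankine_froude`` mode: ``n * v_ind * (1 + tau + sigma)``.
    ``inflow_ratio`` mode: ``n * lambda_inflow * U`` (correction factors are
    part of the inflow ratio there and are not applied twice).
    """
    if n < 1:
        raise ValueError("load factor n must be >= 1")
    if tau < 0 or sigma < 0:
        raise ValueError("correction factors tau, sigma must be >= 0")
    if mode == "rankine_froude":
        if v_ind is None:
            raise ValueError("rankine_froude mode requires v_ind")
        return n * v_ind * (1.0 + tau + sigma)
    if mode == "inflow_ratio":
        if lambda_inflow is None or U is None:
            raise ValueError("inflow_ratio mode requires lambda_inflow and U")
        return n * lambda_inflow * U
    raise ValueError(f"unknown induced-power mode {mode!r}")


def derive_all(record: IndividualRecord, convention: str = "p2s",
               tau: float = 0.0, sigma: float = 0.0,
               reference: Atmosphere = ISA) -> DerivedAero:
    """Populate every derived quantity computable from ``record``.

    Burst fields stay ``None`` when the record carries no burst force. Burst
    kinematics fall back to the hovering values when absent. Idempotent and
    side-effect free.
    """
    record.validate()
    for name in ("body_mass", "wing_area_S", "wing_length_R",
                 "hover_frequency_f", "hover_amplitude_Phi"):
        if math.isnan(getattr(record, name)):
            raise ValueError(f"record {record.id}: missing mandatory field {name}")

    r2 = record.r2_hat
    if math.isnan(r2):
        r2 = 0.5
        log.warning("record %s: r2_hat missing, defaulting to 0.5", record.id)

    out = DerivedAero()
    out.air_density_rho = air_density_from_elevation(record.elevation, reference)
    out.R2 = r2 * record.wing_length_R
    out.mean_wing_velocity_U = mean_wing_velocity(
        record.hover_frequency_f, record.hover_amplitude_Phi, out.R2, convention)
    out.hover_force_coefficient = vertical_force_coefficient(
        record.weight, out.air_density_rho, out.mean_wing_velocity_U,
        record.wing_area_S)
    if not (FORCE_COEFFICIENT_RANGE[0] <= out.hover_force_coefficient
            <= FORCE_COEFFICIENT_RANGE[1]):
        warnings.warn(
            f"record {record.id}: hover force coefficient "
            f"{out.hover_force_coefficient:.3g} outside "
            f"{FORCE_COEFFICIENT_RANGE}; probable unit error", UnitSanityWarning)

    # swept-disc sector uses the pronation-to-supination amplitude
    phi_p2s = (record.hover_amplitude_Phi if convention == "p2s"
               else 2.0 * record.hover_amplitude_Phi)
    out.disc_area_A = phi_p2s * record.wing_length_R ** 2
    out.induced_velocity = rf_induced_velocity(
        record.weight, out.air_density_rho, phi_p2s, record.wing_length_R)
    out.inflow_ratio = out.induced_velocity / out.mean_wing_velocity_U
    out.specific_induced_power_hover = specific_induced_power(
        1.0, out.induced_velocity, tau, sigma)

    if record.burst_force is not None and not math.isnan(record.burst_force):
        out.load_factor_n = load_factor(record.burst_force, record.weight)
        f_b = record.burst_frequency
        phi_b = record.burst_amplitude
        if f_b is None or math.isnan(f_b):
            f_b = record.hover_frequency_f
        if phi_b is None or math.isnan(phi_b):
            phi_b = record.hover_amplitude_Phi
        u_b = mean_wing_velocity(f_b, phi_b, out.R2, convention)
        out.burst_force_coefficient = vertical_force_coefficient(
            record.burst_force, out.air_density_rho, u_b, record.wing_area_S)
        phi_b_p2s = phi_b if convention == "p2s" else 2.0 * phi_b
        v_ind_b = rf_induced_velocity(
            record.burst_force, out.air_density_rho, phi_b_p2s,
            record.wing_length_R)
        out.specific_induced_power_burst = specific_induced_power(
            max(out.load_factor_n, 1.0), v_ind_b, tau, sigma)
    return out


# ---------------------------------------------------------------------------
# tabular interface
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [f.name for f in fields(IndividualRecord)]


def records_from_frame(df: pd.DataFrame) -> list[IndividualRecord]:
    """Build validated records from a DataFrame (empty cell = missing)."""
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in RECORD_COLUMNS:
            if name not in df.columns:
                continue
            v = row[name]
            if name in ("id", "species", "clade", "collector"):
                kwargs[name] = "" if pd.isna(v) else str(v)
            elif name in ("burst_frequency", "burst_amplitude", "burst_force"):
                kwargs[name] = None if pd.isna(v) else float(v)
            else:
                kwargs[name] = float("nan") if pd.isna(v) else float(v)
        out.append(IndividualRecord(**kwargs))
    return out


def read_records(path) -> list[IndividualRecord]:
    """Read an individual-record CSV (UTF-8, header = field names)."""
    return records_from_frame(pd.read_csv(path))


def derive_table(df: pd.DataFrame, convention: str = "p2s",
                 tau: float = 0.0, sigma: float = 0.0) -> pd.DataFrame:
    """Append DerivedAero columns to a record table."""
    derived = [derive_all(r, convention=convention, tau=tau, sigma=sigma)
               for r in records_from_frame(df)]
    cols = {name: [getattr(d, name) for d in derived] for name in DERIVED_COLUMNS}
    out = df.copy()
    for name, values in cols.items():
        out[name] = [np.nan if v is None else v for v in values]
    return out
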