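"""Deterministic disposition kinetics of D2O in a linked mother-infant system.

The mother is a one-compartment pool of total body water receiving an oral
D2O dose at t = 0; a fraction of her water output flows to the infant through
breastmilk, and the infant is a second one-compartment pool that grows over
the study. Because D2O traces water, its rate constants equal the water
turnover rate constants, so the fitted clearances are water clearances:

    dA_m/dt = -k_mm * A_m            A_m(0) = dose
    dA_b/dt =  k_mb * A_m - k_bo * A_b    A_b(0) = 0

with k_mb = CL_mb / V_m and k_bo = CL_bo / V_b. Saliva enrichment above the
pre-dose baseline (mg/kg) is the measured quantity: amount divided by the
water pool, with dilute heavy water taken at density 1.0 kg/L so L == kg.

All amounts are kg, volumes L, clearances L/day, rate constants 1/day, times
days since dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairParameters",
    "InfantPool",
    "Dose",
    "mother_amount",
    "infant_amount",
    "infant_volume",
    "predict_enrichment",
    "EQUAL_RATE_RTOL",
]

#: Relative closeness of k_mm and k_bo below which the equal-rate limit of the
#: biexponential infant solution is used (avoids catastrophic cancellation).
EQUAL_RATE_RTOL = 1e-8

ENRICH_SCALE = 1e6  # kg D2O per kg water -> mg/kg


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its physical constraint."""


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not np.all(np.asarray(value) > 0):
            raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Dose:
    """Oral D2O dose to the mother at t = 0, in kg (~0.030 kg in the field design)."""

    amount: float

    def __post_init__(self) -> None:
        _require_positive(dose=self.amount)


@dataclass(frozen=True)
class InfantPool:
    """The infant's body-water pool, growing linearly over the study window.

    water_fraction is kg water per kg body weight; 0.60 reproduces the
    ~3 kg total water content of a 5 kg infant. Density is fixed at
    1.0 kg/L so the pool in litres equals the water mass in kg.
    """

    weight_start: float
    weight_end: float
    water_fraction: float = 0.60
    density: float = 1.0
    duration: float = 14.0

    def __post_init__(self) -> None:
        _require_positive(
            weight_start=self.weight_start,
            weight_end=self.weight_end,
            duration=self.duration,
        )
        if not 0 < self.water_fraction < 1:
            raise InvalidParameterError(
                f"water_fraction must lie in (0, 1), got {self.water_fraction}"
            )

    def volume(self, t):
        """V_b(t) in L, linear in t between the start and end weights."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration):
            raise ValueError(f"t must lie in [0, {self.duration}] days")
        weight = self.weight_start + (self.weight_end - self.weight_start) * t / self.duration
        return self.water_fraction * weight / self.density

    @property
    def midpoint_volume(self) -> float:
        """V_b at mid-study; the single value used for the rate constant k_bo."""
        return float(self.volume(self.duration / 2.0))

    @property
    def growth_rate(self) -> float:
        """Net pool accretion dV_b/dt in L/day."""
        return (
            self.water_fraction
            * (self.weight_end - self.weight_start)
            / (self.density * self.duration)
        )


@dataclass(frozen=True)
class PairParameters:
    """Kinetic parameters of one mother-infant pair.

    Primary parameters are the mother's total elimination rate constant k_mm,
    her distribution volume V_m, the mother-to-infant water clearance CL_mb
    and the infant output clearance CL_bo. The mother-to-out clearance
    CL_mo = k_mm * V_m - CL_mb must be nonnegative: the milk route cannot
    exceed her total water output.
    """

    k_mm: float
    V_m: float
    CL_mb: float
    CL_bo: float
    V_b: float = field(default=3.0)  # infant pool used for the rate constant, L

    def __post_init__(self) -> None:
        _require_positive(
            k_mm=self.k_mm, V_m=self.V_m, CL_mb=self.CL_mb, CL_bo=self.CL_bo, V_b=self.V_b
        )
        if self.CL_mo < 0:
            raise InvalidParameterError(
                f"CL_mo = k_mm*V_m - CL_mb = {self.CL_mo:.4g} must be nonnegative"
            )

    @property
    def k_mb(self) -> float:
        return self.CL_mb / self.V_m

    @property
    def k_bo(self) -> float:
        return self.CL_bo / self.V_b

    @property
    def CL_mo(self) -> float:
        return self.k_mm * self.V_m - self.CL_mb

    @classmethod
    def from_pool(cls, k_mm, V_m, CL_mb, CL_bo, pool: InfantPool) -> "PairParameters":
        return cls(k_mm=k_mm, V_m=V_m, CL_mb=CL_mb, CL_bo=CL_bo, V_b=pool.midpoint_volume)


def mother_amount(dose, k_mm, t):
    """Mass of D2O in the mother (kg) at time t: monoexponential decay."""
    _require_positive(dose=dose, k_mm=k_mm)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be nonnegative")
    return dose * np.exp(-k_mm * t)


def infant_amount(dose, k_mm, k_mb, k_bo, t):
    """Mass of D2O in the infant (kg) at time t.

    Biexponential flip-flop solution

        A_b(t) = dose * k_mb / (k_mm - k_bo) * (exp(-k_bo t) - exp(-k_mm t))

    with the L'Hopital limit dose * k_mb * t * exp(-k t) when k_mm and k_bo
    coincide to within ``EQUAL_RATE_RTOL`` (the generic form suffers
    catastrophic cancellation there).
    """
    _require_positive(dose=dose, k_mm=k_mm, k_mb=k_mb, k_bo=k_bo)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be nonnegative")
    k_mm = np.asarray(k_mm, dtype=float)
    k_bo = np.asarray(k_bo, dtype=float)
    diff = k_mm - k_bo
    degenerate = np.abs(diff) < EQUAL_RATE_RTOL * np.abs(k_mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = dose * k_mb / diff * (np.exp(-k_bo * t) - np.exp(-k_mm * t))
    limit = dose * k_mb * t * np.exp(-k_mm * t)
    return np.where(degenerate, limit, generic)


def infant_volume(pool: InfantPool, t):
    """Infant distribution volume V_b(t) in L (see :meth:`InfantPool.volume`)."""
    return pool.volume(t)


def predict_enrichment(pair: PairParameters, pool: InfantPool, dose: Dose, role: str, t):
    """Predicted saliva enrichment above baseline (mg/kg) for mother or infant.

    Concentration is amount over the relevant water pool; the mother's pool is
    constant over the study while the infant's grows, so the infant prediction
    divides by V_b(t) pointwise.
    """
    if role == "mother":
        return ENRICH_SCALE * mother_amount(dose.amount, pair.k_mm, t) / pair.V_m
    if role == "infant":
        amt = infant_amount(dose.amount, pair.k_mm, pair.k_mb, pair.k_bo, t)
        return ENRICH_SCALE * amt / pool.volume(t)
    raise ValueError(f"role must be 'mother' or 'infant', got {role!r}")
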