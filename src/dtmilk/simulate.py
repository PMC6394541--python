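"""Synthetic calibration cohorts for the dose-to-mother deuterium design.

The generator reproduces the statistical structure the analysis assumes: a
~30 g oral D2O dose to the mother, saliva sampling of both subjects on days
0 (pre-dose), 1, 2, 5, 6, 13 and 14 with duplicate samples on day 0, day
5-or-6 and day 14, individual kinetic parameters drawn from a multivariate
log-normal population with weight covariates on V_m and CL_bo, and combined
(additive + proportional) residual noise on the enrichments.

Default population values are the reported covariate-model posterior means
(ln V_m intercept 3.49 at the 70 kg reference with slope 0.62 on
ln(MWT/70); ln CL_bo intercept -0.16 at the 5 kg reference with slope 0.17
on ln(BWT/5)); covariate distributions are centred on the calibration
cohort's medians (mother 53.1 kg, infant 5.9 kg at entry) with ranges
clipped to the cohort extremes.

When per-pair true non-milk intake ``rs_per_pair`` is specified, CL_mb is
derived from the infant water balance

    CL_mb = (1 - f_a) * (CL_bo + pool growth) - Rs / 1000

so a pair with Rs = 0 is a *perfect exclusively-breastfeeding* pair by
construction. Otherwise all four parameters are drawn freely and the implied
true Rs of each pair is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EnrichmentRecord, PairDataset
from .kinetics import InfantPool, infant_amount

__all__ = [
    "PARAM_NAMES",
    "SimulationTruth",
    "CohortDesign",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_perfect_ebf_pair",
]

#: Canonical parameter order used throughout the package.
PARAM_NAMES = ("CL_mb", "CL_bo", "k_mm", "V_m")

LOQ_MGKG = 20.0  # FTIR limit of quantitation for saliva


def _default_mu_log() -> np.ndarray:
    # intercepts at the reference covariates (70 kg mother, 5 kg infant):
    # CL_mb ~ 0.80 L/day, CL_bo = exp(-0.16), k_mm ~ 0.10 /day, V_m = exp(3.49)
    return np.array([np.log(0.80), -0.16, np.log(0.10), 3.49])


def _default_omega() -> np.ndarray:
    return np.diag(np.full(4, 0.2**2))


@dataclass
class SimulationTruth:
    """Generating population values for a synthetic cohort."""

    mu_log: np.ndarray = field(default_factory=_default_mu_log)
    slope_vm: float = 0.62  # ln V_m vs ln(MWT / 70 kg)
    slope_clbo: float = 0.17  # ln CL_bo vs ln(BWT / 5 kg)
    omega: np.ndarray = field(default_factory=_default_omega)
    sigma_add: float = 2.0  # mg/kg
    sigma_prop: float = 0.02  # fraction of the prediction
    f_a: float = 0.063  # atmospheric fraction of infant water input
    water_fraction: float = 0.60
    rs_per_pair: float | Sequence[float] | None = None  # g/day; None = free draw

    def __post_init__(self) -> None:
        self.mu_log = np.asarray(self.mu_log, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.mu_log.shape != (4,):
            raise ValueError("mu_log must have shape (4,) ordered as " + str(PARAM_NAMES))
        if self.omega.shape != (4, 4) or not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be a symmetric 4x4 matrix")
        if np.any(np.linalg.eigvalsh(self.omega) < -1e-12):
            raise ValueError("omega must be positive semi-definite")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("sigma components must be nonnegative")
        if not 0 <= self.f_a < 1:
            raise ValueError("f_a must lie in [0, 1)")


@dataclass
class CohortDesign:
    """Field sampling design and covariate distributions."""

    n_pairs: int = 20
    sampling_days: tuple = (0.0, 1.0, 2.0, 5.0, 6.0, 13.0, 14.0)
    duplicate_days: tuple = (0.0, 5.0, 14.0)
    randomize_day56_duplicate: bool = True  # duplicate falls on day 5 or 6
    dose: float = 0.030  # kg
    duration: float = 14.0
    mwt_median: float = 53.1
    mwt_log_sd: float = 0.25
    mwt_range: tuple = (34.5, 93.1)
    bwt_median: float = 5.9
    bwt_log_sd: float = 0.19
    bwt_range: tuple = (3.9, 8.4)
    growth_mean: float = 0.3  # kg gained over the study
    growth_sd: float = 0.1
    age_range_months: tuple = (2.0, 5.4)
    duplicate_jitter: float = 15.0 / (60.0 * 24.0)  # +/- 15 min, in days
    censor_below_loq: bool = False

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not set(self.duplicate_days) <= set(self.sampling_days):
            raise ValueError("duplicate days must be a subset of sampling days")
        if 0.0 not in self.sampling_days:
            raise ValueError("day 0 (pre-dose baseline) must be part of the design")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the per-pair generating truth."""

    pairs: list[PairDataset]
    truth: SimulationTruth
    individual: pd.DataFrame  # one row per pair: true parameters, covariates, true Rs

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _truncated_lognormal(rng, median, log_sd, lo, hi, size):
    draws = np.exp(rng.normal(np.log(median), log_sd, size=size))
    return np.clip(draws, lo, hi)


def simulate_cohort(
    truth: SimulationTruth,
    design: CohortDesign,
    seed: int | np.random.Generator = 0,
) -> SimulatedCohort:
    """Generate a seeded synthetic cohort of mother-infant pairs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = design.n_pairs
    mwt = _truncated_lognormal(rng, design.mwt_median, design.mwt_log_sd, *design.mwt_range, n)
    bwt0 = _truncated_lognormal(rng, design.bwt_median, design.bwt_log_sd, *design.bwt_range, n)
    growth = np.clip(rng.normal(design.growth_mean, design.growth_sd, size=n), 0.0, None)
    bwt1 = bwt0 + growth
    age = rng.uniform(*design.age_range_months, size=n)

    mean = np.tile(truth.mu_log, (n, 1))
    mean[:, 3] += truth.slope_vm * np.log(mwt / 70.0)
    mean[:, 1] += truth.slope_clbo * np.log(bwt0 / 5.0)
    try:
        chol = np.linalg.cholesky(truth.omega + 1e-12 * np.eye(4))
    except np.linalg.LinAlgError as err:
        raise ValueError("omega is not positive definite") from err
    eta = mean + rng.standard_normal((n, 4)) @ chol.T
    theta = np.exp(eta)  # columns: CL_mb, CL_bo, k_mm, V_m

    pools = [
        InfantPool(
            weight_start=bwt0[i],
            weight_end=bwt1[i],
            water_fraction=truth.water_fraction,
            duration=design.duration,
        )
        for i in range(n)
    ]
    growth_rate = np.array([p.growth_rate for p in pools])

    def balance_clmb(th):
        # milk inflow implied by the water balance at the requested true Rs
        rs = np.broadcast_to(np.asarray(truth.rs_per_pair, dtype=float), (n,))
        return (1.0 - truth.f_a) * (th[:, 1] + growth_rate) - rs / 1000.0

    # the population is truncated to the model's support (CL_mb < k_mm * V_m,
    # and CL_mb > 0 when derived from the balance): redraw violating pairs
    for _ in range(200):
        th = theta.copy()
        if truth.rs_per_pair is not None:
            th[:, 0] = balance_clmb(th)
        bad = (th[:, 0] <= 0) | (th[:, 0] >= th[:, 2] * th[:, 3])
        if not bad.any():
            break
        k = int(bad.sum())
        eta[bad] = mean[bad] + rng.standard_normal((k, 4)) @ chol.T
        theta = np.exp(eta)
    else:
        raise ValueError(
            "could not draw pairs satisfying CL_mb < k_mm*V_m; "
            "the requested truth is incompatible with the disposition model"
        )

    if truth.rs_per_pair is not None:
        rs_true = np.broadcast_to(
            np.asarray(truth.rs_per_pair, dtype=float), (n,)
        ).astype(float).copy()
        theta[:, 0] = balance_clmb(theta)
    else:
        rs_true = ((1.0 - truth.f_a) * (theta[:, 1] + growth_rate) - theta[:, 0]) * 1000.0

    pairs = []
    for i in range(n):
        pairs.append(
            _simulate_pair(
                pair_id=f"P{i + 1:03d}",
                cl_mb=theta[i, 0],
                cl_bo=theta[i, 1],
                k_mm=theta[i, 2],
                v_m=theta[i, 3],
                pool=pools[i],
                mwt=mwt[i],
                age=age[i],
                truth=truth,
                design=design,
                rng=rng,
            )
        )

    individual = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "CL_mb": theta[:, 0],
            "CL_bo": theta[:, 1],
            "k_mm": theta[:, 2],
            "V_m": theta[:, 3],
            "mother_wt_kg": mwt,
            "infant_wt_start_kg": bwt0,
            "infant_wt_end_kg": bwt1,
            "rs_true_g_day": rs_true,
        }
    )
    return SimulatedCohort(pairs=pairs, truth=truth, individual=individual)


def _simulate_pair(
    pair_id, cl_mb, cl_bo, k_mm, v_m, pool, mwt, age, truth, design, rng
) -> PairDataset:
    k_mb = cl_mb / v_m
    k_bo = cl_bo / pool.midpoint_volume
    records: list[EnrichmentRecord] = []

    dup_days = list(design.duplicate_days)
    if design.randomize_day56_duplicate and 5.0 in dup_days and 6.0 in design.sampling_days:
        if rng.random() < 0.5:
            dup_days[dup_days.index(5.0)] = 6.0

    def predict(role, t):
        t = np.asarray(t, dtype=float)
        if role == "mother":
            return 1e6 * design.dose * np.exp(-k_mm * t) / v_m
        amt = infant_amount(design.dose, k_mm, k_mb, k_bo, t)
        return 1e6 * amt / pool.volume(np.clip(t, 0.0, design.duration))

    def noisy(f):
        sd = np.sqrt(truth.sigma_add**2 + (truth.sigma_prop * f) ** 2)
        return f + rng.normal(0.0, 1.0, size=np.shape(f)) * sd

    for role in ("mother", "infant"):
        for day in design.sampling_days:
            duplicated = day in dup_days
            if day == 0.0:
                # pre-dose baseline: above-baseline enrichment is zero by
                # definition, observed with additive assay noise only
                n_rep = 2 if duplicated else 1
                for k in range(n_rep):
                    records.append(
                        EnrichmentRecord(
                            pair_id=pair_id,
                            role=role,
                            time=0.0,
                            enrichment=float(rng.normal(0.0, truth.sigma_add))
                            if truth.sigma_add > 0
                            else 0.0,
                            duplicate_group=f"{role}-d0" if duplicated else None,
                            is_baseline=True,
                        )
                    )
                continue
            if duplicated:
                times = day + rng.uniform(
                    -design.duplicate_jitter, design.duplicate_jitter, size=2
                )
                times = np.clip(times, 0.0, design.duration)  # stay in the study window
                group = f"{role}-d{day:g}"
            else:
                times = np.array([float(day)])
                group = None
            f = predict(role, times)
            y = noisy(f) if (truth.sigma_add > 0 or truth.sigma_prop > 0) else f
            for t_k, y_k, f_k in zip(times, np.atleast_1d(y), np.atleast_1d(f)):
                if design.censor_below_loq and f_k < LOQ_MGKG:
                    continue
                records.append(
                    EnrichmentRecord(
                        pair_id=pair_id,
                        role=role,
                        time=float(t_k),
                        enrichment=float(y_k),
                        duplicate_group=group,
                        is_baseline=False,
                        below_loq=bool(f_k < LOQ_MGKG),
                    )
                )

    return PairDataset(
        pair_id=pair_id,
        dose=design.dose,
        mother_weight=float(mwt),
        infant_weight_start=pool.weight_start,
        infant_weight_end=pool.weight_end,
        infant_age=float(age),
        records=records,
    )


def simulate_perfect_ebf_pair(
    truth: SimulationTruth,
    design: CohortDesign,
    seed: int | np.random.Generator = 0,
) -> PairDataset:
    """One pair whose generating water balance has zero non-milk intake."""
    truth0 = replace(truth, rs_per_pair=0.0)
    cohort = simulate_cohort(truth0, replace(design, n_pairs=1), seed)
    return cohort.pairs[0]
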