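"""Reading, writing and preprocessing of saliva-enrichment panels.

The on-disk dialect is two UTF-8 CSVs:

* records: ``pair_id, role, time_day, enrichment_mgkg, duplicate_group,
  field_excluded`` — one row per saliva sample, time in decimal days since
  dose (``time_unit="hour"`` converts on read), enrichment in mg/kg above the
  pre-dose baseline. Day-0 pre-dose rows (time 0) are baseline rows.
* covariates: ``pair_id, dose_g, mother_wt_kg, infant_wt_start_kg,
  infant_wt_end_kg, infant_age_mo`` — exactly one row per pair.

Preprocessing implements the field-protocol rules: duplicate samples (two
taken within an hour on designated days) are replaced by a single record at
the mean time with the mean enrichment, and pairs whose fitted infant output
clearance exceeds 40% of infant body weight per day are flagged as
biologically implausible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentRecord",
    "PairDataset",
    "SchemaError",
    "PanelParseError",
    "read_panel",
    "write_panel",
    "average_duplicates",
    "plausibility_filter",
]

RECORD_COLUMNS = [
    "pair_id",
    "role",
    "time_day",
    "enrichment_mgkg",
    "duplicate_group",
    "field_excluded",
]
COVARIATE_COLUMNS = [
    "pair_id",
    "dose_g",
    "mother_wt_kg",
    "infant_wt_start_kg",
    "infant_wt_end_kg",
    "infant_age_mo",
]

#: Duplicate samples farther apart than this (days) are rejected: the
#: protocol takes the two within one hour.
DEFAULT_DUPLICATE_WINDOW = 1.0 / 24.0

#: Implausibility rule: CL_bo strictly greater than this fraction of infant
#: body weight per day (kg/day == L/day at density 1.0) is incompatible with
#: life — 2.0 kg/day for a 5 kg infant.
CLBO_WEIGHT_FRACTION = 0.40


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class PanelParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


@dataclass(frozen=True)
class EnrichmentRecord:
    pair_id: str
    role: str  # "mother" | "infant"
    time: float  # days since dose
    enrichment: float  # mg/kg above baseline
    duplicate_group: str | None = None
    is_baseline: bool = False
    below_loq: bool = False  # noiseless prediction under the 20 mg/kg LOQ

    def __post_init__(self) -> None:
        if self.role not in ("mother", "infant"):
            raise ValueError(f"role must be mother|infant, got {self.role!r}")
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        if not math.isfinite(self.enrichment):
            raise ValueError("enrichment must be finite")


@dataclass
class PairDataset:
    """One mother-infant pair: dose, covariates and the full sample panel."""

    pair_id: str
    dose: float  # kg
    mother_weight: float  # kg
    infant_weight_start: float  # kg
    infant_weight_end: float  # kg
    infant_age: float  # months
    records: list[EnrichmentRecord] = field(default_factory=list)
    field_excluded: bool = False

    def __post_init__(self) -> None:
        for name in ("dose", "mother_weight", "infant_weight_start", "infant_weight_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def postdose_records(self, role: str | None = None) -> list[EnrichmentRecord]:
        out = [r for r in self.records if not r.is_baseline]
        if role is not None:
            out = [r for r in out if r.role == role]
        return out

    def validate(self, min_postdose: int = 2) -> None:
        for role in ("mother", "infant"):
            n = len(self.postdose_records(role))
            if n < min_postdose:
                raise ValueError(
                    f"pair {self.pair_id}: {n} post-dose {role} records, need >= {min_postdose}"
                )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelParseError(f"non-numeric {column} in {what} file at row {idx}")
    return coerced


def read_panel(
    records_path,
    covariates_path,
    *,
    time_unit: str = "day",
) -> list[PairDataset]:
    """Read the two-CSV panel dialect into validated :class:`PairDataset` objects.

    ``time_unit="hour"`` converts sample clock offsets to decimal days.
    Rows with time exactly 0 are flagged as pre-dose baseline rows.
    """
    if time_unit not in ("day", "hour"):
        raise ValueError(f"time_unit must be 'day' or 'hour', got {time_unit!r}")
    rec = pd.read_csv(records_path, dtype={"pair_id": str, "duplicate_group": str})
    cov = pd.read_csv(covariates_path, dtype={"pair_id": str})
    _require_columns(rec, RECORD_COLUMNS[:4], "records")
    _require_columns(cov, COVARIATE_COLUMNS, "covariates")

    times = _numeric(rec, "time_day", "records").to_numpy(dtype=float)
    if time_unit == "hour":
        times = times / 24.0
    enrich = _numeric(rec, "enrichment_mgkg", "records").to_numpy(dtype=float)
    dup = rec.get("duplicate_group")
    excl = rec.get("field_excluded")

    excluded_pairs: set[str] = set()
    if excl is not None:
        flags = excl.fillna(0).astype(bool)
        excluded_pairs = set(rec.loc[flags, "pair_id"])

    by_pair: dict[str, list[EnrichmentRecord]] = {}
    for i in range(len(rec)):
        pid = str(rec["pair_id"].iloc[i])
        group = None
        if dup is not None and pd.notna(dup.iloc[i]) and str(dup.iloc[i]).strip():
            group = str(dup.iloc[i]).strip()
        by_pair.setdefault(pid, []).append(
            EnrichmentRecord(
                pair_id=pid,
                role=str(rec["role"].iloc[i]),
                time=float(times[i]),
                enrichment=float(enrich[i]),
                duplicate_group=group,
                is_baseline=times[i] == 0.0,
            )
        )

    pairs: list[PairDataset] = []
    for _, row in cov.iterrows():
        pid = str(row["pair_id"])
        if pid not in by_pair:
            raise PanelParseError(f"pair {pid} has covariates but no records")
        pairs.append(
            PairDataset(
                pair_id=pid,
                dose=float(row["dose_g"]) / 1000.0,
                mother_weight=float(row["mother_wt_kg"]),
                infant_weight_start=float(row["infant_wt_start_kg"]),
                infant_weight_end=float(row["infant_wt_end_kg"]),
                infant_age=float(row["infant_age_mo"]),
                records=by_pair[pid],
                field_excluded=pid in excluded_pairs,
            )
        )
    known = {p.pair_id for p in pairs}
    orphan = set(by_pair) - known
    if orphan:
        raise PanelParseError(f"records without covariates for pair(s): {sorted(orphan)}")
    return pairs


def write_panel(pairs: Iterable[PairDataset], records_path, covariates_path) -> None:
    """Write pairs back to the two-CSV dialect (inverse of :func:`read_panel`)."""
    rec_rows, cov_rows = [], []
    for p in pairs:
        cov_rows.append(
            {
                "pair_id": p.pair_id,
                "dose_g": p.dose * 1000.0,
                "mother_wt_kg": p.mother_weight,
                "infant_wt_start_kg": p.infant_weight_start,
                "infant_wt_end_kg": p.infant_weight_end,
                "infant_age_mo": p.infant_age,
            }
        )
        for r in p.records:
            rec_rows.append(
                {
                    "pair_id": p.pair_id,
                    "role": r.role,
                    "time_day": r.time,
                    "enrichment_mgkg": r.enrichment,
                    "duplicate_group": r.duplicate_group or "",
                    "field_excluded": int(p.field_excluded),
                }
            )
    pd.DataFrame(rec_rows, columns=RECORD_COLUMNS).to_csv(records_path, index=False)
    pd.DataFrame(cov_rows, columns=COVARIATE_COLUMNS).to_csv(covariates_path, index=False)


def average_duplicates(
    records: Sequence[EnrichmentRecord],
    *,
    window: float = DEFAULT_DUPLICATE_WINDOW,
) -> list[EnrichmentRecord]:
    """Collapse each linked duplicate pair to its mean time and mean enrichment.

    Duplicates are linked by ``duplicate_group`` (same pair, role and group
    label). The two samples must lie within ``window`` days of each other
    (default one hour); anything else is a protocol violation. Records
    without a group label pass through unchanged, so the operation is
    idempotent.
    """
    groups: dict[tuple, list[EnrichmentRecord]] = {}
    out: list[EnrichmentRecord] = []
    for r in records:
        if r.duplicate_group is None:
            out.append(r)
        else:
            groups.setdefault((r.pair_id, r.role, r.duplicate_group), []).append(r)
    for key, members in groups.items():
        if len(members) != 2:
            raise ValueError(
                f"duplicate group {key} has {len(members)} member(s); expected exactly 2"
            )
        a, b = members
        if abs(a.time - b.time) > window:
            raise ValueError(
                f"duplicate group {key}: samples {abs(a.time - b.time) * 24:.1f} h apart "
                f"exceed the {window * 24:.0f}-h window"
            )
        out.append(
            EnrichmentRecord(
                pair_id=a.pair_id,
                role=a.role,
                time=(a.time + b.time) / 2.0,
                enrichment=(a.enrichment + b.enrichment) / 2.0,
                duplicate_group=None,
                is_baseline=a.is_baseline and b.is_baseline,
                below_loq=a.below_loq and b.below_loq,
            )
        )
    out.sort(key=lambda r: (r.role, r.time))
    return out


def preprocess_pair(pair: PairDataset, *, window: float = DEFAULT_DUPLICATE_WINDOW) -> PairDataset:
    """Duplicate-averaged copy of a pair (records replaced, covariates kept)."""
    return PairDataset(
        pair_id=pair.pair_id,
        dose=pair.dose,
        mother_weight=pair.mother_weight,
        infant_weight_start=pair.infant_weight_start,
        infant_weight_end=pair.infant_weight_end,
        infant_age=pair.infant_age,
        records=average_duplicates(pair.records, window=window),
        field_excluded=pair.field_excluded,
    )


def plausibility_filter(
    pair: PairDataset,
    clbo_estimate: float,
    *,
    weight_fraction: float = CLBO_WEIGHT_FRACTION,
) -> tuple[bool, str]:
    """Keep/exclude decision for the biological-plausibility rule on CL_bo.

    A pair is excluded iff the posterior summary of CL_bo (L/day) is strictly
    greater than ``weight_fraction`` of infant starting body weight (kg/day;
    the two scales coincide at density 1.0). Returns ``(keep, reason)``.
    """
    threshold = weight_fraction * pair.infant_weight_start
    if clbo_estimate > threshold:
        return False, (
            f"CL_bo {clbo_estimate:.3g} L/day exceeds {weight_fraction:.0%} of infant "
            f"body weight ({threshold:.3g} kg/day): biologically implausible"
        )
    return True, f"CL_bo {clbo_estimate:.3g} L/day within plausible range (<= {threshold:.3g})"
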