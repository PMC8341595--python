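"""Canonical data model and I/O for WHO cone-bioassay campaigns.

A campaign is a collection of cone observations: each record is one cone on one
wall of one house at one monthly visit, holding the number of mosquitoes exposed
and the cumulative number dead at each post-exposure reading hour (24-120 h).
Visits run on a half-month grid (1.5, 2.5, ... months post-spray); visits that
slipped more than half a month past their scheduled slot are regrouped into the
subsequent month. Cone heights are aggregated per house visit before analysis,
since height has no detectable effect on mortality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CampaignValidationError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

WALL_TYPES = ("cement", "mud")
TREATMENTS = ("sprayed", "control")
AGE_GROUPS = ("young", "old")
CONE_HEIGHTS = ("bottom", "middle", "upper")
#: Post-exposure reading hours; mortality at 48-120 h is "delayed" mortality.
HOURS = (24, 48, 72, 96, 120)

#: Monthly visit grid, months post-spray.
DEFAULT_MONTH_GRID = tuple(np.arange(1.5, 13.0, 1.0))

#: Canonical campaign CSV columns (one row per cone per visit).
CSV_COLUMNS = (
    "house_id",
    "wall_type",
    "treatment",
    "age_group",
    "visit_month",
    "cone_height",
    "n_exposed",
    "dead_24",
    "dead_48",
    "dead_72",
    "dead_96",
    "dead_120",
)


@dataclass(frozen=True)
class BioassayRecord:
    """One cone observation series.

    Parameters
    ----------
    house_id : str
        Opaque house identifier.
    wall_type : {"cement", "mud"}
    treatment : {"sprayed", "control"}
    age_group : {"young", "old"}
        Young = 2-5 day old unfed females; old = 13-26 day old, previously
        blood-fed — the cohort old enough to transmit malaria.
    visit_month : float
        Months post-spray, positive; on the half-month grid after regrouping.
    cone_height : {"bottom", "middle", "upper"}
        Cone position on the wall (~0.4, 1.0, 1.6 m).
    n_exposed : int
        Mosquitoes introduced into the cone (> 0).
    n_dead : mapping of int -> int
        Cumulative dead count per post-exposure hour. Missing reading hours are
        absent keys, never zeros. Counts are non-decreasing in hour.
    """

    house_id: str
    wall_type: str
    treatment: str
    age_group: str
    visit_month: float
    cone_height: str
    n_exposed: int
    n_dead: Mapping[int, int]

    def __post_init__(self):
        object.__setattr__(self, "n_dead", MappingProxyType(dict(self.n_dead)))
        self.validate()

    def validate(self) -> None:
        if self.wall_type not in WALL_TYPES:
            raise ValidationError(f"unknown wall_type {self.wall_type!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.cone_height not in CONE_HEIGHTS:
            raise ValidationError(f"unknown cone_height {self.cone_height!r}")
        if not self.visit_month > 0:
            raise ValidationError(f"visit_month must be > 0, got {self.visit_month}")
        if not self.n_exposed > 0:
            raise ValidationError(f"n_exposed must be > 0, got {self.n_exposed}")
        prev_hour, prev_dead = None, None
        for hour in sorted(self.n_dead):
            if hour not in HOURS:
                raise ValidationError(f"unknown observation hour {hour}")
            dead = self.n_dead[hour]
            if not 0 <= dead <= self.n_exposed:
                raise ValidationError(
                    f"n_dead[{hour}]={dead} outside [0, n_exposed={self.n_exposed}]"
                )
            if prev_dead is not None and dead < prev_dead:
                raise ValidationError(
                    f"n_dead decreasing: {prev_dead} at {prev_hour} h "
                    f"but {dead} at {hour} h"
                )
            prev_hour, prev_dead = hour, dead

    @property
    def hours(self) -> tuple[int, ...]:
        return tuple(sorted(self.n_dead))

    def mortality(self, hour: int) -> float:
        """Observed mortality fraction at ``hour``."""
        return self.n_dead[hour] / self.n_exposed


@dataclass(frozen=True)
class HouseVisit:
    """All cones of one house at one visit for one mosquito age group.

    Totals are conserved sums over the member cones; per-hour totals only sum
    cones that recorded that hour.
    """

    house_id: str
    wall_type: str
    treatment: str
    age_group: str
    visit_month: float
    records: tuple[BioassayRecord, ...]
    n_exposed_total: int = field(init=False)
    n_dead_total: Mapping[int, int] = field(init=False)
    n_exposed_by_hour: Mapping[int, int] = field(init=False)

    def __post_init__(self):
        for r in self.records:
            for attr in ("house_id", "wall_type", "treatment", "age_group", "visit_month"):
                if getattr(r, attr) != getattr(self, attr):
                    raise ValidationError(
                        f"member record disagrees on {attr}: "
                        f"{getattr(r, attr)!r} != {getattr(self, attr)!r}"
                    )
        dead: dict[int, int] = {}
        exposed: dict[int, int] = {}
        for r in self.records:
            for h, d in r.n_dead.items():
                dead[h] = dead.get(h, 0) + d
                exposed[h] = exposed.get(h, 0) + r.n_exposed
        object.__setattr__(self, "n_exposed_total", sum(r.n_exposed for r in self.records))
        object.__setattr__(self, "n_dead_total", MappingProxyType(dict(sorted(dead.items()))))
        object.__setattr__(self, "n_exposed_by_hour", MappingProxyType(dict(sorted(exposed.items()))))

    def mortality(self, hour: int) -> float:
        return self.n_dead_total[hour] / self.n_exposed_by_hour[hour]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _row_to_record(row: pd.Series) -> BioassayRecord:
    n_dead = {}
    for hour in HOURS:
        value = row.get(f"dead_{hour}")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        fval = float(value)
        if fval < 0 or fval != int(fval):
            raise ValidationError(f"dead_{hour} must be a non-negative integer, got {value!r}")
        n_dead[hour] = int(fval)
    n_exposed = float(row["n_exposed"])
    if n_exposed != int(n_exposed):
        raise ValidationError(f"n_exposed must be an integer, got {row['n_exposed']!r}")
    return BioassayRecord(
        house_id=str(row["house_id"]),
        wall_type=str(row["wall_type"]).strip().lower(),
        treatment=str(row["treatment"]).strip().lower(),
        age_group=str(row["age_group"]).strip().lower(),
        visit_month=float(row["visit_month"]),
        cone_height=str(row["cone_height"]).strip().lower(),
        n_exposed=int(n_exposed),
        n_dead=n_dead,
    )


def read_campaign(
    path,
    schema_map: Mapping[str, str] | None = None,
) -> list[BioassayRecord]:
    """Read a campaign CSV into validated :class:`BioassayRecord` objects.

    Parameters
    ----------
    path : path-like
        CSV file, UTF-8, header row, ``#`` comment lines allowed.
    schema_map : mapping, optional
        Maps canonical column names (see :data:`CSV_COLUMNS`) to the file's
        actual headers, for ingesting externally produced files whose layout
        differs from the canonical schema.

    Raises
    ------
    ConfigurationError
        If a required column is missing after applying ``schema_map``.
    CampaignValidationError
        Listing every row that violates a record invariant (decreasing dead
        counts, unknown labels, out-of-range counts). Bad rows are reported
        with their row numbers, never silently dropped.
    """
    frame = pd.read_csv(path, comment="#")
    if schema_map:
        rename = {src: canonical for canonical, src in schema_map.items()}
        missing_src = [src for src in rename if src not in frame.columns]
        if missing_src:
            raise ConfigurationError(
                f"schema_map refers to absent column(s): {missing_src}"
            )
        frame = frame.rename(columns=rename)
    required = [c for c in CSV_COLUMNS if not c.startswith("dead_")]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"campaign file missing column(s): {missing}")

    records, row_errors = [], []
    for idx, row in frame.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValidationError, ValueError, KeyError) as exc:
            # +2: header line plus 1-based indexing, matching what a user sees
            row_errors.append((int(idx) + 2, str(exc)))
    if row_errors:
        raise CampaignValidationError(row_errors)
    return records


def write_campaign(records: Iterable[BioassayRecord], path, header_comment: str | None = None) -> None:
    """Write records to the canonical campaign CSV; round-trips bit-exactly."""
    rows = []
    for r in records:
        row = {
            "house_id": r.house_id,
            "wall_type": r.wall_type,
            "treatment": r.treatment,
            "age_group": r.age_group,
            "visit_month": r.visit_month,
            "cone_height": r.cone_height,
            "n_exposed": r.n_exposed,
        }
        for hour in HOURS:
            row[f"dead_{hour}"] = r.n_dead.get(hour, "")
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def to_frame(records: Iterable[BioassayRecord]) -> pd.DataFrame:
    """Tidy per-cone DataFrame (wide dead_* columns, NaN for absent hours)."""
    rows = []
    for r in records:
        row = dict(
            house_id=r.house_id, wall_type=r.wall_type, treatment=r.treatment,
            age_group=r.age_group, visit_month=r.visit_month,
            cone_height=r.cone_height, n_exposed=r.n_exposed,
        )
        for hour in HOURS:
            row[f"dead_{hour}"] = r.n_dead.get(hour, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


# ---------------------------------------------------------------------------
# Month regrouping and height aggregation
# ---------------------------------------------------------------------------

def regroup_months(
    records: Iterable[BioassayRecord],
    grid: Sequence[float] = DEFAULT_MONTH_GRID,
    lateness_cutoff: float = 0.5,
) -> list[BioassayRecord]:
    """Snap raw visit months onto the half-month grid.

    A visit more than ``lateness_cutoff`` months past its scheduled grid slot
    (the largest grid month not exceeding it) is assigned to the subsequent
    grid month; otherwise it keeps its scheduled slot. The mapping is
    deterministic, idempotent on already-gridded data, and logged per record.

    Raises
    ------
    ValidationError
        For a visit at or before the spray date (visit_month <= 0) or before
        the first grid month minus one full interval.
    """
    grid = sorted(grid)
    if not grid:
        raise ConfigurationError("empty month grid")
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    out = []
    for r in records:
        m = r.visit_month
        if m <= 0:
            raise ValidationError(f"visit before spray date: visit_month={m}")
        # scheduled slot: largest grid month <= m (first slot for early visits)
        scheduled = grid[0]
        for g in grid:
            if g <= m + 1e-9:
                scheduled = g
            else:
                break
        if m < grid[0] - step + 1e-9:
            raise ValidationError(
                f"visit_month={m} precedes the campaign grid starting at {grid[0]}"
            )
        lateness = m - scheduled
        snapped = scheduled + step if lateness > lateness_cutoff + 1e-9 else scheduled
        if snapped != m:
            logger.info(
                "regroup: house %s month %.2f -> %.1f (lateness %.2f)",
                r.house_id, m, snapped, lateness,
            )
        out.append(replace(r, visit_month=snapped) if snapped != m else r)
    return out


def aggregate_heights(records: Iterable[BioassayRecord]) -> list[HouseVisit]:
    """Group cones into one :class:`HouseVisit` per (house, month, age group).

    Totals are conserved. Duplicate (house, month, age, height) combinations
    indicate a data error and raise.
    """
    groups: dict[tuple, list[BioassayRecord]] = {}
    for r in records:
        key = (r.house_id, r.visit_month, r.age_group)
        groups.setdefault(key, []).append(r)
    visits = []
    for (house_id, month, age), members in sorted(groups.items()):
        seen = set()
        for r in members:
            if r.cone_height in seen:
                raise ValidationError(
                    f"duplicate cone height {r.cone_height!r} for house {house_id} "
                    f"month {month} age {age}"
                )
            seen.add(r.cone_height)
        members = sorted(members, key=lambda r: CONE_HEIGHTS.index(r.cone_height))
        visits.append(
            HouseVisit(
                house_id=house_id,
                wall_type=members[0].wall_type,
                treatment=members[0].treatment,
                age_group=members[0].age_group,
                visit_month=month,
                records=tuple(members),
            )
        )
    return visits
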