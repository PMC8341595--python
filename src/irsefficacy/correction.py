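"""Control-mortality gating and Abbott's correction.

WHO practice for cone bioassays: when control mortality at 24 h exceeds 20%
(three cones combined) the bioassay is discarded; when control mortality is 5%
or more, exposed mortality (at 24 h and every delayed reading) is corrected with
Abbott's formula

    corrected = (observed - control) / (1 - control),

clamped below at zero. The formula is undefined at 100% control mortality; such
points are reported uncorrected and flagged. Controls are pooled across the
unsprayed houses of the same wall type, month and age group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bioassay import BioassayRecord, HOURS, aggregate_heights
from .errors import EmptySeriesError, FitError

logger = logging.getLogger(__name__)

#: Correction gate: control mortality at/above which Abbott's formula applies.
CORRECT_GATE = 0.05
#: Discard gate: 24 h control mortality above which the bioassay is discarded.
DISCARD_GATE = 0.20


class Gate(str, Enum):
    """Disposition of one arm-month point; every point receives exactly one."""

    RAW = "raw"
    ABBOTT = "abbott_corrected"
    DISCARDED = "discarded"
    UNCORRECTABLE_100 = "uncorrectable_100"


def abbott(observed: float, control: float) -> float:
    """Abbott's control-mortality correction, clamped below at zero.

    Parameters
    ----------
    observed, control : float
        Mortality fractions in [0, 1]; ``control`` must be < 1.

    Raises
    ------
    FitError
        If control == 1 (formula undefined; callers route such points to the
        ``uncorrectable_100`` gate instead).
    """
    if not 0.0 <= observed <= 1.0:
        raise ValueError(f"observed mortality {observed} outside [0, 1]")
    if not 0.0 <= control <= 1.0:
        raise ValueError(f"control mortality {control} outside [0, 1]")
    if control == 1.0:
        raise FitError("Abbott's formula undefined at 100% control mortality")
    return max(0.0, (observed - control) / (1.0 - control))


def gate_visit(
    control_mortality_24: float,
    control_mortality_hour: float | None = None,
    *,
    correct_gate: float = CORRECT_GATE,
    discard_gate: float = DISCARD_GATE,
) -> Gate:
    """Gate decision for one arm-month at one observation hour.

    The discard decision uses control mortality at 24 h only (three cones
    combined); the correction decision uses the observation hour's own control
    mortality, which grows with holding time. With ``control_mortality_hour``
    omitted, the 24 h value gates both decisions.
    """
    if control_mortality_hour is None:
        control_mortality_hour = control_mortality_24
    if control_mortality_24 > discard_gate:
        return Gate.DISCARDED
    if control_mortality_hour >= correct_gate:
        if control_mortality_hour == 1.0:
            return Gate.UNCORRECTABLE_100
        return Gate.ABBOTT
    return Gate.RAW


@dataclass(frozen=True)
class CorrectedPoint:
    """One month of one corrected series."""

    visit_month: float
    observed_mortality: float
    corrected_mortality: float
    control_mortality: float
    n_exposed_total: int
    n_houses: int
    gate: Gate

    @property
    def active(self) -> bool:
        """Whether the point enters downstream fitting."""
        return self.gate is not Gate.DISCARDED


@dataclass(frozen=True)
class CorrectedSeries:
    """Month-indexed corrected mortality for one (wall, age, hour) stratum."""

    wall_type: str
    age_group: str
    hour: int
    points: tuple[CorrectedPoint, ...]

    def active_points(self) -> tuple[CorrectedPoint, ...]:
        return tuple(p for p in self.points if p.active)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                wall_type=self.wall_type,
                age_group=self.age_group,
                hour=self.hour,
                visit_month=p.visit_month,
                n_houses=p.n_houses,
                n_exposed=p.n_exposed_total,
                observed_mortality=p.observed_mortality,
                control_mortality=p.control_mortality,
                corrected_mortality=p.corrected_mortality,
                corrected_mortality_pct=round(100 * p.corrected_mortality, 1),
                gate=p.gate.value,
            )
            for p in self.points
        ]
        return pd.DataFrame(rows)


def _pool(visits, hour):
    """Pooled (dead, exposed) across house visits recording ``hour``."""
    dead = sum(v.n_dead_total.get(hour, 0) for v in visits if hour in v.n_dead_total)
    exposed = sum(v.n_exposed_by_hour.get(hour, 0) for v in visits)
    return dead, exposed


def build_corrected_series(
    records: Iterable[BioassayRecord],
    wall_type: str,
    age_group: str,
    hour: int,
    *,
    correct_gate: float = CORRECT_GATE,
    discard_gate: float = DISCARD_GATE,
    control_hour_mode: str = "per_hour",
) -> CorrectedSeries:
    """Build the corrected mortality series for one stratum.

    Per month, exposed mortality is pooled across the sprayed houses of the
    arm and gated/corrected against the pooled matched-control mortality of
    the same wall type, age group and month.

    Parameters
    ----------
    control_hour_mode : {"per_hour", "h24"}
        Whether Abbott's correction at a delayed hour uses that hour's own
        control mortality (default) or the 24 h control mortality.

    Raises
    ------
    EmptySeriesError
        If the arm has no sprayed observations at this hour.
    """
    if control_hour_mode not in ("per_hour", "h24"):
        raise ValueError(f"unknown control_hour_mode {control_hour_mode!r}")
    records = [r for r in records if r.wall_type == wall_type and r.age_group == age_group]
    visits = aggregate_heights(records)
    sprayed = [v for v in visits if v.treatment == "sprayed"]
    controls = [v for v in visits if v.treatment == "control"]
    months = sorted({v.visit_month for v in sprayed if hour in v.n_dead_total})
    if not months:
        raise EmptySeriesError(
            f"no sprayed observations for {wall_type}/{age_group} at {hour} h"
        )

    points = []
    for month in months:
        sp = [v for v in sprayed if v.visit_month == month]
        ct = [v for v in controls if v.visit_month == month]
        dead, exposed = _pool(sp, hour)
        if exposed == 0:
            continue
        observed = dead / exposed
        n_houses = len({v.house_id for v in sp})

        ct_dead24, ct_exp24 = _pool(ct, 24)
        ct_deadh, ct_exph = _pool(ct, hour)
        if ct_exp24 == 0 or ct_exph == 0:
            logger.warning(
                "no matched control for %s/%s month %.1f at %d h: point excluded",
                wall_type, age_group, month, hour,
            )
            points.append(CorrectedPoint(month, observed, np.nan, np.nan,
                                         exposed, n_houses, Gate.DISCARDED))
            continue
        control24 = ct_dead24 / ct_exp24
        controlh = ct_deadh / ct_exph
        gating_control = controlh if control_hour_mode == "per_hour" else control24
        gate = gate_visit(control24, gating_control,
                          correct_gate=correct_gate, discard_gate=discard_gate)
        if gate is Gate.DISCARDED:
            logger.info(
                "discard %s/%s month %.1f: control 24 h mortality %.0f%% > %.0f%%",
                wall_type, age_group, month, 100 * control24, 100 * discard_gate,
            )
            corrected = np.nan
        elif gate is Gate.ABBOTT:
            corrected = abbott(observed, gating_control)
        else:  # RAW or UNCORRECTABLE_100: report uncorrected
            corrected = observed
        points.append(CorrectedPoint(month, observed, corrected, gating_control,
                                     exposed, n_houses, gate))
    return CorrectedSeries(wall_type, age_group, hour, tuple(points))


def corrected_table(
    records: Iterable[BioassayRecord],
    hours: Sequence[int] = HOURS,
    **kwargs,
) -> pd.DataFrame:
    """Tidy corrected-mortality table across every stratum present in the data.

    Mirrors the per-month percent-mortality report layout: one row per
    (wall_type, age_group, hour, visit_month) with pooled totals and gate.
    """
    records = list(records)
    frames = []
    strata = sorted({(r.wall_type, r.age_group) for r in records if r.treatment == "sprayed"})
    for wall, age in strata:
        for hour in hours:
            try:
                series = build_corrected_series(records, wall, age, hour, **kwargs)
            except EmptySeriesError:
                continue
            frames.append(series.to_frame())
    if not frames:
        raise EmptySeriesError("no sprayed observations in campaign")
    return pd.concat(frames, ignore_index=True)
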