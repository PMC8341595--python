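"""End-to-end campaign analysis: regroup, correct, duration, fit, compare."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .bioassay import BioassayRecord, HOURS, regroup_months
from .comparison import adjusted_monthly_counts, comparison_table, poisson_compare
from .correction import CorrectedSeries, build_corrected_series
from .efficacy import WHO_THRESHOLD, duration_table
from .errors import EmptySeriesError, FitError
from .time_mortality import TimeMortalityModel

logger = logging.getLogger(__name__)


def corrected_series_by_stratum(
    records: Iterable[BioassayRecord],
    hours: Sequence[int] = HOURS,
    *,
    regroup: bool = True,
    **correction_kwargs,
) -> list[CorrectedSeries]:
    """Corrected series for every (wall, age, hour) stratum in the campaign."""
    records = list(records)
    if regroup:
        records = regroup_months(records)
    strata = sorted({(r.wall_type, r.age_group) for r in records
                     if r.treatment == "sprayed"})
    out = []
    for wall, age in strata:
        for hour in hours:
            try:
                out.append(build_corrected_series(records, wall, age, hour,
                                                  **correction_kwargs))
            except EmptySeriesError:
                continue
    return out


def analyse_campaign(
    records: Iterable[BioassayRecord],
    *,
    threshold: float = WHO_THRESHOLD,
    hours: Sequence[int] = HOURS,
    fit_hours: Sequence[int] = (),
    chains: int = 4,
    iterations: int = 1000,
    burn_in: int = 500,
    seed: int | None = None,
) -> dict:
    """Full analysis of one campaign.

    Returns a dict with the corrected-mortality table, the residual-efficacy
    duration report, Bayesian fits with lethal times for the strata at
    ``fit_hours``, and the wall-surface Poisson comparison per hour.
    """
    records = regroup_months(list(records))
    series = corrected_series_by_stratum(records, hours, regroup=False)
    corrected = pd.concat([s.to_frame() for s in series], ignore_index=True)
    durations = duration_table(series, threshold)

    fits = {}
    for s in series:
        if s.hour not in fit_hours:
            continue
        try:
            model = TimeMortalityModel.from_corrected_series(s)
            res = model.fit(chains=chains, iterations=iterations,
                            burn_in=burn_in, seed=seed)
        except FitError as exc:
            logger.warning("fit failed for %s/%s %dh: %s",
                           s.wall_type, s.age_group, s.hour, exc)
            continue
        fits[f"{s.wall_type}|{s.age_group}|{s.hour}"] = res

    comparisons = {}
    for hour in hours:
        try:
            table = adjusted_monthly_counts(records, hour)
        except EmptySeriesError:
            continue
        if table.empty or table["wall_type"].nunique() < 2:
            continue
        comparisons[hour] = comparison_table(
            poisson_compare(table, ["wall_type"]))

    return dict(corrected=corrected, durations=durations, fits=fits,
                comparisons=comparisons)
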