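"""Synthetic cone-bioassay campaigns with the study's design geometry.

The generator runs the analysis model forward: per stratum (wall type, age
group, reading hour) the insecticide kill probability at month ``t`` is the
logistic curve m(t) = expit(beta1 + beta2 t), composed with an age- and
hour-dependent control background c_h as independent competing sources of
death, so a cone mosquito dies by hour h with probability

    P_h(t) = 1 - (1 - m_h(t)) * (1 - c_h).

This composition makes Abbott's correction exactly unbiased in expectation,
so the correction module's recovery is testable. Delayed mortality is drawn as
cumulative thinning of survivors — survivors of hour h face the incremental
hazard to h+24 — which guarantees monotone dead counts by construction.

The default configuration mirrors the emulated campaign: per wall type six
sprayed and two unsprayed (control) houses, three cones of ten females per
house visit, monthly visits on the 1.5-12.5 month grid (old mosquitoes from
month 4.5), occasional late visits that slip toward the next month, and a
missed-visit rate that reproduces the ~54 house-visit / ~1.6 thousand mosquito
per-arm totals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bioassay import AGE_GROUPS, DEFAULT_MONTH_GRID, HOURS, WALL_TYPES, BioassayRecord
from .errors import ConfigurationError
from .time_mortality import mortality_curve


def _default_strata() -> dict[tuple[str, str, int], tuple[float, float]]:
    # Per (wall, age): a common monthly depreciation slope and per-hour
    # intercepts rising with holding time (delayed mortality). Chosen so 24 h
    # mortality stays below the 80% threshold throughout while 72 h efficacy
    # lasts roughly 7-10 months depending on wall and age.
    slopes = {
        ("cement", "young"): -0.55,
        ("mud", "young"): -0.55,
        ("cement", "old"): -0.50,
        ("mud", "old"): -0.45,
    }
    intercepts = {
        ("cement", "young"): {24: 1.45, 48: 2.49, 72: 5.24, 96: 6.61, 120: 6.89},
        ("mud", "young"): {24: 1.30, 48: 2.60, 72: 5.68, 96: 6.78, 120: 7.00},
        ("cement", "old"): {24: 1.60, 48: 4.14, 72: 5.29, 96: 6.29, 120: 6.50},
        ("mud", "old"): {24: 1.50, 48: 2.60, 72: 5.80, 96: 6.25, 120: 7.24},
    }
    return {
        (wall, age, hour): (b1, slopes[(wall, age)])
        for (wall, age), per_hour in intercepts.items()
        for hour, b1 in per_hour.items()
    }


def _default_control_background() -> dict[tuple[str, int], float]:
    # Background mortality grows with holding time and is higher for old,
    # previously blood-fed females (senescence).
    young = {24: 0.02, 48: 0.03, 72: 0.05, 96: 0.08, 120: 0.10}
    old = {24: 0.05, 48: 0.08, 72: 0.12, 96: 0.18, 120: 0.25}
    return {("young", h): v for h, v in young.items()} | \
           {("old", h): v for h, v in old.items()}


@dataclass(frozen=True)
class SyntheticConfig:
    """True parameters and design geometry of a simulated campaign.

    Attributes
    ----------
    strata : mapping (wall_type, age_group, hour) -> (beta1, beta2)
        True logistic decay parameters per stratum; beta2 <= 0 (decaying).
    control_background : mapping (age_group, hour) -> float
        Background kill probability in control houses; non-decreasing in hour.
    sprayed_houses, control_houses : int
        Houses per wall type (6 sprayed + 2 unsprayed controls).
    cones_per_house, mosquitoes_per_cone : int
        Three cones (bottom/middle/upper) of ten females per visit.
    month_grid : tuple of float
        Scheduled visit months post-spray (half-month convention).
    old_start_month : float
        First month old mosquitoes are tested (colony logistics).
    missed_visit_prob : float
        Chance a sprayed house-visit does not happen in a given month.
    late_visit_prob, late_shift_range : float, (float, float)
        Chance a visit slips, and the uniform range (months) of the slip.
    seed : int
        Seed for full reproducibility.
    """

    strata: Mapping[tuple[str, str, int], tuple[float, float]] = field(
        default_factory=_default_strata)
    control_background: Mapping[tuple[str, int], float] = field(
        default_factory=_default_control_background)
    walls: Sequence[str] = WALL_TYPES
    ages: Sequence[str] = AGE_GROUPS
    hours: Sequence[int] = HOURS
    sprayed_houses: int = 6
    control_houses: int = 2
    cones_per_house: int = 3
    mosquitoes_per_cone: int = 10
    month_grid: Sequence[float] = DEFAULT_MONTH_GRID
    old_start_month: float = 4.5
    missed_visit_prob: float = 0.18
    late_visit_prob: float = 0.15
    late_shift_range: tuple[float, float] = (0.25, 0.9)
    seed: int = 0

    def validate(self) -> None:
        for count in (self.sprayed_houses, self.control_houses,
                      self.cones_per_house, self.mosquitoes_per_cone):
            if count <= 0:
                raise ConfigurationError("design counts must be positive")
        for (wall, age, hour), (b1, b2) in self.strata.items():
            if b2 > 0:
                raise ConfigurationError(
                    f"beta2 must be <= 0 (decaying efficacy), got {b2} for "
                    f"{wall}/{age}/{hour}h"
                )
        for (age, hour), c in self.control_background.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(f"control background {c} outside [0,1]")
        for age in self.ages:
            cs = [self.control_background[(age, h)] for h in self.hours]
            if any(b < a for a, b in zip(cs, cs[1:])):
                raise ConfigurationError(
                    f"control background must be non-decreasing in hour for {age}"
                )
        # combined kill probability must be non-decreasing in hour at every
        # grid month, otherwise cumulative thinning is impossible
        for wall in self.walls:
            for age in self.ages:
                for t in self.month_grid:
                    ps = [self._combined_kill(wall, age, h, t) for h in self.hours]
                    if any(b < a - 1e-12 for a, b in zip(ps, ps[1:])):
                        raise ConfigurationError(
                            f"kill probability decreasing in hour for "
                            f"{wall}/{age} at month {t}"
                        )
        if not 0 <= self.missed_visit_prob < 1 or not 0 <= self.late_visit_prob <= 1:
            raise ConfigurationError("probabilities must lie in [0, 1)")

    def _combined_kill(self, wall: str, age: str, hour: int, t: float) -> float:
        b1, b2 = self.strata[(wall, age, hour)]
        m = float(mortality_curve(t, b1, b2))
        c = self.control_background[(age, hour)]
        return 1.0 - (1.0 - m) * (1.0 - c)

    def manifest(self) -> dict:
        """JSON-ready record of the true parameters, for recovery scoring."""
        return {
            "strata": {
                f"{wall}|{age}|{hour}": [float(b1), float(b2)]
                for (wall, age, hour), (b1, b2) in sorted(self.strata.items())
            },
            "control_background": {
                f"{age}|{hour}": float(c)
                for (age, hour), c in sorted(self.control_background.items())
            },
            "design": {
                "sprayed_houses": self.sprayed_houses,
                "control_houses": self.control_houses,
                "cones_per_house": self.cones_per_house,
                "mosquitoes_per_cone": self.mosquitoes_per_cone,
                "month_grid": [float(m) for m in self.month_grid],
                "old_start_month": self.old_start_month,
                "missed_visit_prob": self.missed_visit_prob,
                "late_visit_prob": self.late_visit_prob,
                "late_shift_range": list(self.late_shift_range),
            },
            "seed": self.seed,
        }


_HEIGHTS = ("bottom", "middle", "upper")


def _simulate_cone(rng, kill_probs: Sequence[float], hours: Sequence[int],
                   n: int) -> dict[int, int]:
    """Cumulative thinning of survivors across holding hours."""
    survivors, cum_dead, prev_p = n, 0, 0.0
    n_dead = {}
    for hour, p in zip(hours, kill_probs):
        q = 0.0 if prev_p >= 1.0 else (p - prev_p) / (1.0 - prev_p)
        new_dead = int(rng.binomial(survivors, q))
        cum_dead += new_dead
        survivors -= new_dead
        n_dead[hour] = cum_dead
        prev_p = p
    return n_dead


def simulate_campaign(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[BioassayRecord], dict]:
    """Simulate a full campaign; returns records and the true-parameter manifest.

    Control houses follow the monthly schedule exactly (so matched controls
    exist every month); sprayed house-visits may be missed or slip late by the
    configured amounts. Bit-identical output for equal seeds.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    grid_max = max(config.month_grid)
    records = []
    for wall in config.walls:
        houses = (
            [(f"{wall[0].upper()}S{i + 1}", "sprayed") for i in range(config.sprayed_houses)]
            + [(f"{wall[0].upper()}C{i + 1}", "control") for i in range(config.control_houses)]
        )
        for age in config.ages:
            months = [m for m in config.month_grid
                      if age == "young" or m >= config.old_start_month]
            for house_id, treatment in houses:
                skip_next = False
                for month in months:
                    if skip_next:
                        # previous visit slipped into this month's slot
                        skip_next = False
                        continue
                    if treatment == "sprayed" and rng.random() < config.missed_visit_prob:
                        continue
                    visit_month = month
                    if (treatment == "sprayed" and month < grid_max
                            and rng.random() < config.late_visit_prob):
                        visit_month = month + rng.uniform(*config.late_shift_range)
                        # a slip past the regrouping cutoff replaces the next
                        # scheduled visit of this house
                        skip_next = visit_month - month > 0.5
                    if treatment == "sprayed":
                        kill = [config._combined_kill(wall, age, h, visit_month)
                                for h in config.hours]
                    else:
                        kill = [config.control_background[(age, h)]
                                for h in config.hours]
                    for ci in range(config.cones_per_house):
                        n_dead = _simulate_cone(rng, kill, config.hours,
                                                config.mosquitoes_per_cone)
                        records.append(BioassayRecord(
                            house_id=house_id,
                            wall_type=wall,
                            treatment=treatment,
                            age_group=age,
                            visit_month=round(visit_month, 3),
                            cone_height=_HEIGHTS[ci % 3],
                            n_exposed=config.mosquitoes_per_cone,
                            n_dead=n_dead,
                        ))
    return records, config.manifest()


def single_stratum_config(
    beta1: float,
    beta2: float,
    *,
    control_background: float = 0.02,
    n_months: int = 10,
    houses: int = 6,
    cones: int = 3,
    mosquitoes: int = 10,
    seed: int = 0,
) -> SyntheticConfig:
    """Minimal one-stratum design (cement/young, 24 h) for recovery studies."""
    grid = tuple(np.arange(1.5, 1.5 + n_months, 1.0))
    return SyntheticConfig(
        strata={("cement", "young", 24): (beta1, beta2)},
        control_background={("young", 24): control_background},
        walls=("cement",),
        ages=("young",),
        hours=(24,),
        sprayed_houses=houses,
        cones_per_house=cones,
        mosquitoes_per_cone=mosquitoes,
        month_grid=grid,
        missed_visit_prob=0.0,
        late_visit_prob=0.0,
        seed=seed,
    )


def parameter_recovery_study(
    n_campaigns: int = 100,
    beta1: float = 5.2,
    beta2: float = -0.55,
    *,
    seed: int = 0,
    level: float = 0.90,
    chains: int = 4,
    iterations: int = 1000,
    burn_in: int = 500,
    **design_kwargs,
):
    """Simulate-correct-fit closure: repeated campaigns at the study design size.

    For each replicate, a single-stratum campaign is generated from known
    (beta1, beta2), run through control gating/Abbott correction, and fitted;
    the replicate records whether each central credible interval covers the
    truth and the posterior-median LT50.

    Returns a DataFrame with one row per replicate (columns ``cover_beta1``,
    ``cover_beta2``, ``lt50_median``, ``converged``).
    """
    import pandas as pd

    from .correction import build_corrected_series
    from .time_mortality import TimeMortalityModel, lethal_time_point

    seed_rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_campaigns):
        sim_seed, fit_seed = seed_rng.integers(2 ** 31, size=2)
        config = single_stratum_config(beta1, beta2, seed=int(sim_seed), **design_kwargs)
        records, _ = simulate_campaign(config)
        series = build_corrected_series(records, "cement", "young", 24)
        model = TimeMortalityModel.from_corrected_series(series)
        res = model.fit(chains=chains, iterations=iterations, burn_in=burn_in,
                        seed=int(fit_seed))
        ci = res.credible_interval(level)
        lt50 = res.lethal_time(0.5)
        rows.append(dict(
            rep=rep,
            beta1_median=res.params[0],
            beta2_median=res.params[1],
            cover_beta1=bool(ci[0, 0] <= beta1 <= ci[0, 1]),
            cover_beta2=bool(ci[1, 0] <= beta2 <= ci[1, 1]),
            lt50_median=lt50.median_months,
            converged=res.converged,
        ))
    out = pd.DataFrame(rows)
    out.attrs["true_beta1"] = beta1
    out.attrs["true_beta2"] = beta2
    out.attrs["true_lt50"] = float(lethal_time_point(0.5, beta1, beta2))
    return out
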