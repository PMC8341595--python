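"""Poisson-regression comparison of monthly mortality counts between groups.

Observed (Abbott-adjusted) monthly dead counts are compared across cone
heights, wall surfaces and mosquito age groups with a log-link Poisson GLM
using the number of contributing houses as the exposure offset:

    log E[deaths_i] = log(houses_i) + X_i beta,

so exp(beta) is a mortality rate ratio per house-visit. Fitting is by
iteratively reweighted least squares (statsmodels GLM) to the maximum
likelihood; Wald tests give per-contrast confidence intervals and p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .bioassay import BioassayRecord, aggregate_heights
from .correction import CORRECT_GATE, DISCARD_GATE, Gate, abbott, gate_visit, _pool
from .errors import EmptySeriesError, FitError


@dataclass(frozen=True)
class RateComparison:
    """One covariate contrast from the Poisson model."""

    term: str
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int

    def __post_init__(self):
        if self.rate_ratio <= 0:
            raise ValueError("rate ratio must be positive")


def adjusted_monthly_counts(
    records: Iterable[BioassayRecord],
    hour: int,
    by: Sequence[str] = (),
    *,
    use_abbott: bool = True,
    correct_gate: float = CORRECT_GATE,
    discard_gate: float = DISCARD_GATE,
) -> pd.DataFrame:
    """Monthly Abbott-adjusted dead counts for sprayed houses, per group.

    Rows are (wall_type, age_group, visit_month) cells, further split by the
    record-level keys in ``by`` (e.g. ``("cone_height",)``). Dead counts are
    pooled, gated against the matched pooled control of the same wall type,
    age group and month, corrected where the gate requires, and rounded back
    to integer counts; discarded arm-months are dropped. ``n_houses`` counts
    the sprayed houses contributing to the cell (the Poisson offset).
    """
    records = list(records)
    visits = aggregate_heights(records)
    sprayed_records = [r for r in records if r.treatment == "sprayed" and hour in r.n_dead]
    controls = [v for v in visits if v.treatment == "control"]
    if not sprayed_records:
        raise EmptySeriesError(f"no sprayed observations at {hour} h")

    def cell_key(r):
        return (r.wall_type, r.age_group, r.visit_month) + tuple(getattr(r, k) for k in by)

    cells: dict[tuple, list[BioassayRecord]] = {}
    for r in sprayed_records:
        cells.setdefault(cell_key(r), []).append(r)

    rows = []
    for key in sorted(cells):
        wall, age, month = key[:3]
        members = cells[key]
        ct = [v for v in controls
              if v.wall_type == wall and v.age_group == age and v.visit_month == month]
        ct_dead24, ct_exp24 = _pool(ct, 24)
        ct_deadh, ct_exph = _pool(ct, hour)
        if ct_exp24 == 0 or ct_exph == 0:
            continue  # no matched control: cell cannot be gated
        control24 = ct_dead24 / ct_exp24
        controlh = ct_deadh / ct_exph
        gate = gate_visit(control24, controlh,
                          correct_gate=correct_gate, discard_gate=discard_gate)
        if gate is Gate.DISCARDED:
            continue
        dead = sum(r.n_dead[hour] for r in members)
        exposed = sum(r.n_exposed for r in members)
        observed = dead / exposed
        if use_abbott and gate is Gate.ABBOTT:
            dead_adj = int(np.rint(abbott(observed, controlh) * exposed))
        else:
            dead_adj = dead
        row = dict(wall_type=wall, age_group=age, visit_month=month)
        row.update({k: v for k, v in zip(by, key[3:])})
        row.update(n_dead=dead_adj, n_exposed=exposed,
                   n_houses=len({r.house_id for r in members}))
        rows.append(row)
    return pd.DataFrame(rows)


def poisson_compare(
    table: pd.DataFrame,
    covariates: Sequence[str],
    *,
    count_col: str = "n_dead",
    offset_col: str = "n_houses",
) -> list[RateComparison]:
    """Fit the offset Poisson GLM and return one rate ratio per contrast.

    Parameters
    ----------
    table : DataFrame
        One row per month per group with integer counts and positive offsets
        (see :func:`adjusted_monthly_counts`).
    covariates : sequence of str
        Categorical columns entering the model additively, e.g.
        ``("cone_height",)`` or ``("wall_type", "age_group")``.

    Raises
    ------
    FitError
        For a singular design, naming the collinear terms.
    """
    if (table[offset_col] <= 0).any():
        raise ValueError("offsets must be positive")
    if (table[count_col] < 0).any():
        raise ValueError("counts must be non-negative")
    for cov in covariates:
        totals = table.groupby(cov)[count_col].sum()
        if (totals == 0).any():
            warnings.warn(
                f"group(s) {list(totals[totals == 0].index)} of {cov!r} have "
                "all-zero counts; the contrast is separable",
                RuntimeWarning, stacklevel=2,
            )
    formula = f"{count_col} ~ " + " + ".join(f"C({c})" for c in covariates)
    model = smf.glm(formula, data=table, family=sm.families.Poisson(),
                    offset=np.log(table[offset_col].to_numpy(dtype=float)))
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise FitError(
            f"singular design matrix: {model.exog_names} span rank {rank} "
            f"< {model.exog.shape[1]} columns (collinear terms)"
        )
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    out = []
    with np.errstate(over="ignore"):  # separable contrasts give infinite CI ends
        for name in res.params.index:
            if name == "Intercept":
                continue
            out.append(RateComparison(
                term=name,
                rate_ratio=float(np.exp(res.params[name])),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                p_value=float(res.pvalues[name]),
                n_obs=int(res.nobs),
            ))
    return out


def comparison_table(comparisons: Iterable[RateComparison]) -> pd.DataFrame:
    """Tidy report of rate-ratio contrasts."""
    return pd.DataFrame([
        dict(term=c.term, rate_ratio=c.rate_ratio, ci_low=c.ci_low,
             ci_high=c.ci_high, p_value=c.p_value, n_obs=c.n_obs)
        for c in comparisons
    ])
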