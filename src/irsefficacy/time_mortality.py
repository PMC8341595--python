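"""Bayesian binomial-logistic time-mortality model with lethal-time estimation.

The probability that an exposed mosquito dies, as a function of months ``t``
since spraying, is modelled as a logistic curve

    m(t) = 1 / (1 + exp(-(beta1 + beta2 * t))),

with dead counts per pooled sample binomial, Ndead_i ~ Binomial(Ntotal_i,
m(t_i)). ``beta1`` sets the initial kill level (logit scale) and ``beta2`` the
per-month depreciation; a decaying product has ``beta2 < 0``. The posterior of
(beta1, beta2) under weakly-informative normal priors is sampled by multi-chain
adaptive random-walk Metropolis initialised at the posterior mode, and lethal
times LT_p — months post-spray at which the curve equals mortality ``p`` — are
obtained by inverting the curve draw by draw:

    LT_p = (logit(p) - beta1) / beta2.

Model/Results layout follows statsmodels: ``TimeMortalityModel(...).fit()``
returns a :class:`TimeMortalityResults` carrying draws, convergence
diagnostics, ``summary()``, ``lethal_time()`` and plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, special

from .correction import CorrectedSeries
from .errors import FitError

logger = logging.getLogger(__name__)

#: Weakly-informative prior scales (normal, zero mean) on the logit/month scale.
PRIOR_SCALE_INTERCEPT = 10.0
PRIOR_SCALE_SLOPE = 2.0

#: Convergence tolerance on the rank-normalised split R-hat statistic.
RHAT_TOLERANCE = 1.05


def mortality_curve(t, beta1: float, beta2: float):
    """Logistic kill probability m(t) = expit(beta1 + beta2 * t).

    Saturates numerically at the extremes; accepts scalars or arrays.
    """
    return special.expit(beta1 + beta2 * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class FitDataset:
    """Pooled observations for one (wall type, age group, hour) stratum.

    ``n_dead`` holds Abbott-adjusted dead counts rounded to integers where the
    correction applied; each row is one arm-month (or any pooled sample).
    """

    months: np.ndarray
    n_dead: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "months", np.asarray(self.months, dtype=float))
        object.__setattr__(self, "n_dead", np.asarray(self.n_dead, dtype=int))
        object.__setattr__(self, "n_total", np.asarray(self.n_total, dtype=int))
        if not (len(self.months) == len(self.n_dead) == len(self.n_total)):
            raise ValueError("months, n_dead, n_total must have equal length")
        if len(self.months) == 0:
            raise ValueError("empty dataset")
        if np.any(self.months <= 0):
            raise ValueError("months must be positive")
        if np.any(self.n_total <= 0):
            raise ValueError("n_total must be positive")
        if np.any((self.n_dead < 0) | (self.n_dead > self.n_total)):
            raise ValueError("n_dead must lie in [0, n_total]")

    def __len__(self) -> int:
        return len(self.months)

    @classmethod
    def from_corrected_series(cls, series: CorrectedSeries) -> "FitDataset":
        """Build from a corrected series, excluding discarded points.

        Corrected (possibly fractional) mortality is converted back to a dead
        count against the pooled total and rounded to the nearest integer.
        """
        pts = series.active_points()
        if not pts:
            raise FitError("corrected series has no active points")
        months = [p.visit_month for p in pts]
        totals = [p.n_exposed_total for p in pts]
        dead = [int(np.rint(p.corrected_mortality * p.n_exposed_total)) for p in pts]
        return cls(np.array(months), np.array(dead), np.array(totals))


def log_likelihood(data: FitDataset, beta1: float, beta2: float) -> float:
    """Binomial log-likelihood of the dataset under the logistic curve.

    Sum over observations of log C(n, d) + d log m + (n - d) log(1 - m);
    finite for all finite parameters.
    """
    eta = beta1 + beta2 * data.months
    d, n = data.n_dead, data.n_total
    const = special.gammaln(n + 1) - special.gammaln(d + 1) - special.gammaln(n - d + 1)
    return float(np.sum(const + d * special.log_expit(eta)
                        + (n - d) * special.log_expit(-eta)))


def lethal_time_point(p: float, beta1, beta2):
    """Invert the logistic curve: months at which m(t) = p, (logit(p)-b1)/b2."""
    return (special.logit(p) - np.asarray(beta1)) / np.asarray(beta2)


@dataclass(frozen=True)
class LethalTimeEstimate:
    """Posterior lethal-time summary for one target mortality ``p``.

    ``defined`` is False when the posterior-median curve never attains ``p``
    within [0, horizon] or when more than half of the draws give no
    non-negative lethal time (non-decaying or out-of-range draws, whose
    fraction is reported in ``excluded_fraction``).
    """

    p: float
    median_months: float
    ci_low: float
    ci_high: float
    defined: bool
    excluded_fraction: float


class TimeMortalityModel:
    """Binomial-logistic decay of cone-bioassay mortality over months post-spray.

    Parameters
    ----------
    data : FitDataset
        Pooled (month, dead, total) observations for one stratum.
    prior_scales : (float, float)
        Standard deviations of the zero-mean normal priors on
        (intercept beta1, slope beta2).
    """

    def __init__(self, data: FitDataset,
                 prior_scales=(PRIOR_SCALE_INTERCEPT, PRIOR_SCALE_SLOPE)):
        self.data = data
        self.prior_scales = tuple(float(s) for s in prior_scales)
        total_dead = int(data.n_dead.sum())
        self.separable = total_dead == 0 or total_dead == int(data.n_total.sum())
        if self.separable:
            warnings.warn(
                "degenerate (separable) data: all mosquitoes dead or all alive "
                "at every time point; likelihood has no interior maximum",
                RuntimeWarning, stacklevel=2,
            )

    @classmethod
    def from_corrected_series(cls, series: CorrectedSeries, **kwargs) -> "TimeMortalityModel":
        return cls(FitDataset.from_corrected_series(series), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, *, month_col="visit_month",
                       dead_col="n_dead", total_col="n_total", **kwargs) -> "TimeMortalityModel":
        return cls(FitDataset(frame[month_col].to_numpy(),
                              frame[dead_col].to_numpy(),
                              frame[total_col].to_numpy()), **kwargs)

    # -- likelihood / posterior -------------------------------------------

    def loglike(self, params) -> float:
        beta1, beta2 = params
        return log_likelihood(self.data, beta1, beta2)

    def logprior(self, params) -> float:
        s1, s2 = self.prior_scales
        beta1, beta2 = params
        return float(-0.5 * (beta1 / s1) ** 2 - 0.5 * (beta2 / s2) ** 2
                     - np.log(2 * np.pi * s1 * s2))

    def logposterior(self, params) -> float:
        return self.loglike(params) + self.logprior(params)

    # -- point estimation --------------------------------------------------

    def fit_mle(self) -> tuple[np.ndarray, np.ndarray]:
        """Maximum-likelihood (beta1, beta2) by direct numerical optimisation.

        Returns the estimate and the inverse observed-information covariance.

        Raises
        ------
        FitError
            For a non-identifiable design (fewer than two distinct months) or
            a diverging (separable) likelihood.
        """
        if len(np.unique(self.data.months)) < 2:
            raise FitError(
                "non-identifiable: two parameters but a single distinct time point"
            )
        if self.separable:
            raise FitError("maximum-likelihood estimate diverges on separable data")
        x0 = self._initial_guess()
        res = optimize.minimize(lambda x: -self.loglike(x), x0, method="BFGS")
        if np.linalg.norm(res.x) > 1e3:
            raise FitError("maximum-likelihood estimate diverged")
        return res.x, self._laplace_cov(res.x, self.loglike)

    def _initial_guess(self) -> np.ndarray:
        # empirical-logit least squares on the observed fractions
        frac = (self.data.n_dead + 0.5) / (self.data.n_total + 1.0)
        y = special.logit(frac)
        X = np.column_stack([np.ones_like(self.data.months), self.data.months])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    @staticmethod
    def _laplace_cov(x, logf, h: float = 1e-4) -> np.ndarray:
        """Covariance from the negative inverse Hessian of ``logf`` at ``x``."""
        k = len(x)
        H = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                e_i = np.zeros(k); e_i[i] = h
                e_j = np.zeros(k); e_j[j] = h
                H[i, j] = (logf(x + e_i + e_j) - logf(x + e_i - e_j)
                           - logf(x - e_i + e_j) + logf(x - e_i - e_j)) / (4 * h * h)
        cov = np.linalg.inv(-H)
        # guard against a non-PD numerical Hessian
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = np.clip(eigval, 1e-10, None)
        return (eigvec * eigval) @ eigvec.T

    # -- posterior sampling ------------------------------------------------

    def fit(self, chains: int = 4, iterations: int = 1000, burn_in: int = 500,
            seed: int | None = None) -> "TimeMortalityResults":
        """Sample the posterior of (beta1, beta2) by adaptive random-walk Metropolis.

        Chains are initialised overdispersed around the posterior mode with a
        Laplace-approximation proposal covariance; the proposal scale adapts
        toward ~30% acceptance during burn-in and is then frozen. Retained
        draws number ``chains * (iterations - burn_in)``. Fully reproducible
        given ``seed``.

        Raises
        ------
        FitError
            If fewer than three distinct time points are available.
        """
        if len(np.unique(self.data.months)) < 3:
            raise FitError("need at least 3 distinct time points to fit the decay curve")
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")

        mode = self._posterior_mode()
        cov = self._laplace_cov(mode, self.logposterior)
        chol = np.linalg.cholesky(cov * (2.38 ** 2 / 2.0) + 1e-12 * np.eye(2))

        ss = np.random.SeedSequence(seed)
        child_seeds = ss.spawn(chains)
        kept = iterations - burn_in
        draws = np.empty((chains, kept, 2))
        accept = np.zeros(chains)
        for c in range(chains):
            rng = np.random.default_rng(child_seeds[c])
            x = mode + chol @ rng.standard_normal(2) * 2.0  # overdispersed start
            lp = self.logposterior(x)
            log_scale, acc_block, n_block = 0.0, 0, 0
            for it in range(iterations):
                prop = x + np.exp(log_scale) * (chol @ rng.standard_normal(2))
                lp_prop = self.logposterior(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc_block += 1
                    if it >= burn_in:
                        accept[c] += 1
                n_block += 1
                if it < burn_in and n_block == 25:
                    log_scale += (acc_block / n_block - 0.3)
                    acc_block, n_block = 0, 0
                if it >= burn_in:
                    draws[c, it - burn_in] = x
        accept /= kept

        idata = az.from_dict(posterior={
            "beta1": draws[:, :, 0], "beta2": draws[:, :, 1],
        })
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        diagnostics = {
            "rhat": {"beta1": float(rhat["beta1"]), "beta2": float(rhat["beta2"])},
            "ess": {"beta1": float(ess["beta1"]), "beta2": float(ess["beta2"])},
            "acceptance": accept.tolist(),
        }
        converged = max(diagnostics["rhat"].values()) <= RHAT_TOLERANCE
        if not converged:
            warnings.warn(
                f"chains not converged: max R-hat = {max(diagnostics['rhat'].values()):.3f}",
                RuntimeWarning, stacklevel=2,
            )
        return TimeMortalityResults(
            model=self, draws=draws, diagnostics=diagnostics, converged=converged,
            chains=chains, iterations=iterations, burn_in=burn_in, seed=seed,
        )

    def _posterior_mode(self) -> np.ndarray:
        res = optimize.minimize(lambda x: -self.logposterior(x),
                                self._initial_guess(), method="BFGS")
        return res.x


class TimeMortalityResults:
    """Posterior sample and diagnostics of a fitted time-mortality model."""

    def __init__(self, model, draws, diagnostics, converged,
                 chains, iterations, burn_in, seed):
        self.model = model
        self.draws = draws                       # (chains, kept, 2)
        self.diagnostics = diagnostics
        self.converged = converged
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed

    @property
    def flat_draws(self) -> np.ndarray:
        """Pooled posterior draws, shape (chains * kept, 2)."""
        return self.draws.reshape(-1, 2)

    @property
    def params(self) -> np.ndarray:
        """Posterior medians (beta1, beta2)."""
        return np.median(self.flat_draws, axis=0)

    def credible_interval(self, level: float = 0.90) -> np.ndarray:
        """Central equal-tailed posterior intervals, shape (2 params, 2 bounds)."""
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return np.quantile(self.flat_draws, [lo, hi], axis=0).T

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        """Parameter table: posterior median, central interval, R-hat, ESS."""
        ci = self.credible_interval(level)
        med = self.params
        rows = []
        for i, name in enumerate(("beta1", "beta2")):
            rows.append(dict(
                parameter=name, median=med[i],
                ci_low=ci[i, 0], ci_high=ci[i, 1],
                rhat=self.diagnostics["rhat"][name],
                ess=self.diagnostics["ess"][name],
            ))
        return pd.DataFrame(rows).set_index("parameter")

    def lethal_time(self, p: float, horizon: float = 36.0,
                    level: float = 0.90) -> LethalTimeEstimate:
        """Posterior lethal time LT_p: months at which the curve equals ``p``.

        Draws with a non-decaying curve (beta2 >= 0) or a negative lethal time
        are excluded from the summary and their fraction reported; the estimate
        is flagged undefined when they exceed half the posterior mass or when
        the posterior-median curve never attains ``p`` within [0, horizon].
        """
        if not 0.0 < p < 1.0:
            raise ValueError(f"target mortality p={p} outside (0, 1)")
        b1, b2 = self.flat_draws[:, 0], self.flat_draws[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            lt = lethal_time_point(p, b1, b2)
        valid = (b2 < 0) & (lt >= 0) & np.isfinite(lt)
        excluded = 1.0 - valid.mean()

        med_b1, med_b2 = self.params
        if med_b2 != 0:
            lt_med_curve = lethal_time_point(p, med_b1, med_b2)
            attained = 0.0 <= lt_med_curve <= horizon
        else:
            attained = False
        defined = bool(attained) and excluded <= 0.5

        if valid.any():
            lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
            median = float(np.median(lt[valid]))
            ci_low, ci_high = np.quantile(lt[valid], [lo, hi])
        else:
            median = ci_low = ci_high = float("nan")
        return LethalTimeEstimate(p, median, float(ci_low), float(ci_high),
                                  defined, float(excluded))

    def curve_frame(self, t_grid=None, level: float = 0.90) -> pd.DataFrame:
        """Posterior mortality curve: median and central band on a time grid."""
        if t_grid is None:
            t_grid = np.linspace(0.5, max(24.0, self.model.data.months.max() + 6), 100)
        t_grid = np.asarray(t_grid, dtype=float)
        b = self.flat_draws
        # (draws, t): each row one posterior curve
        m = mortality_curve(t_grid[None, :], b[:, 0][:, None], b[:, 1][:, None])
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return pd.DataFrame({
            "t": t_grid,
            "mortality_median": np.median(m, axis=0),
            "mortality_low": np.quantile(m, lo, axis=0),
            "mortality_high": np.quantile(m, hi, axis=0),
        })

    def plot(self, ax=None, level: float = 0.90):
        """Observed mortality fractions with the posterior curve and band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.scatter(d.months, d.n_dead / d.n_total, color="k", zorder=3,
                   label="observed")
        cf = self.curve_frame(level=level)
        ax.plot(cf["t"], cf["mortality_median"], color="C0", label="posterior median")
        ax.fill_between(cf["t"], cf["mortality_low"], cf["mortality_high"],
                        color="C0", alpha=0.25,
                        label=f"{int(level * 100)}% credible band")
        ax.axhline(0.8, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("months post-spray")
        ax.set_ylabel("mortality")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        """JSON-ready fit summary with lethal times at 90/50/10% mortality."""
        summ = self.summary()
        out = {
            "n_obs": int(len(self.model.data)),
            "converged": bool(self.converged),
            "diagnostics": self.diagnostics,
            "chains": self.chains,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "params": {},
            "lethal_times": {},
        }
        for name, row in summ.iterrows():
            out["params"][name] = {
                "median": float(row["median"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
            }
        for p in (0.9, 0.5, 0.1):
            lt = self.lethal_time(p)
            out["lethal_times"][f"LT{int(p * 100)}"] = {
                "median_months": lt.median_months,
                "ci_low": lt.ci_low,
                "ci_high": lt.ci_high,
                "defined": bool(lt.defined),
                "excluded_fraction": lt.excluded_fraction,
            }
        return out
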