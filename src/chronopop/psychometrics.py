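"""Cumulative-Gaussian psychometric fitting for 2AFC duration judgements.

Each cell of the experiment (participant x condition x standard duration)
yields binary "comparison judged longer" responses at seven comparison
levels, expressed as signed % difference from the standard.  A cumulative
Gaussian ``P(longer) = lapse/2 + (1 - lapse) * Phi((x - mu) / sigma)`` is fit
by maximum likelihood on the raw Bernoulli trials; ``mu`` is the point of
subjective equality (PSE, the 50% point) and ``Phi^{-1}(0.75) * sigma`` the
just-noticeable difference (JND, half the 75%-25% distance).

A least-squares-on-pooled-proportions mode is provided for sensitivity
analysis, since published fits of this kind do not always state the
objective used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

PROBIT_75 = float(norm.ppf(0.75))  # 0.674490: JND = PROBIT_75 * sigma

SIGMA_BOUNDS = (0.5, 200.0)
"""Bounds on sigma in % of the standard; hits are flagged, not hidden."""


class DegenerateDataError(ValueError):
    """Raised when a cell cannot constrain a psychometric function."""


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted cumulative-Gaussian psychometric function.

    ``mu_pct`` and ``sigma_pct`` are in % of the standard duration;
    ``flags`` records boundary hits or convergence problems (empty tuple for
    a clean fit).
    """

    mu_pct: float
    sigma_pct: float
    loglik: float
    n_trials: int
    converged: bool
    lapse: float = 0.0
    flags: tuple[str, ...] = ()
    participant: str | None = None
    standard_ms: float | None = None

    @property
    def pse_pct(self) -> float:
        return self.mu_pct

    @property
    def jnd_pct(self) -> float:
        return PROBIT_75 * self.sigma_pct


def _aggregate(x: np.ndarray, y: np.ndarray):
    """Collapse raw trials to (level, n_longer, n_total) for fast likelihoods."""
    levels, inv = np.unique(x, return_inverse=True)
    n_tot = np.bincount(inv, minlength=len(levels)).astype(float)
    n_yes = np.bincount(inv, weights=y, minlength=len(levels))
    return levels, n_yes, n_tot


def _nll(params, levels, n_yes, n_tot, lapse):
    mu, sigma = params
    p = lapse / 2.0 + (1.0 - lapse) * norm.cdf((levels - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(n_yes * np.log(p) + (n_tot - n_yes) * np.log(1.0 - p)))


def _nll_grad(params, levels, n_yes, n_tot, lapse):
    """Analytic (d/dmu, d/dsigma) of the Bernoulli negative log-likelihood."""
    mu, sigma = params
    u = (levels - mu) / sigma
    p = np.clip(lapse / 2.0 + (1.0 - lapse) * norm.cdf(u), 1e-12, 1.0 - 1e-12)
    dl_dp = n_yes / p - (n_tot - n_yes) / (1.0 - p)
    common = dl_dp * (1.0 - lapse) * norm.pdf(u)
    return np.array(
        [float(np.sum(common) / sigma), float(np.sum(common * u) / sigma)]
    )


def _moment_start(levels, n_yes, n_tot):
    """Moment-based initial values from the pooled proportions.

    Treats the observed psychometric function as the CDF of the latent
    Gaussian: mean and sd of the distribution whose mass at each level is the
    increment in proportion correct.
    """
    props = n_yes / n_tot
    span = levels[-1] - levels[0] if levels[-1] > levels[0] else 1.0
    # crude quantile matching: interpolate the 50% crossing for mu
    if np.any(props <= 0.5) and np.any(props >= 0.5):
        mu0 = float(np.interp(0.5, np.sort(props), levels[np.argsort(props)]))
    else:
        mu0 = float(levels[np.argmin(np.abs(props - 0.5))])
    slope = (props[-1] - props[0]) / span
    sigma0 = 0.4 / max(slope, 1e-3)
    sigma0 = float(np.clip(sigma0, *SIGMA_BOUNDS))
    return mu0, sigma0


class CumulativeGaussianPsychometric(BaseEstimator):
    """sklearn-style cumulative-Gaussian psychometric estimator.

    ``fit(x, y)`` takes comparison levels ``x`` (signed % of the standard)
    and binary responses ``y`` (1 = comparison judged longer) and estimates
    ``mu_`` and ``sigma_`` by Bernoulli maximum likelihood (``method="mle"``,
    default) or least squares on pooled proportions (``method="ls"``).
    The lapse rate is a fixed, not fitted, parameter (default 0).

    Fitted attributes: ``mu_``, ``sigma_``, ``loglik_``, ``converged_``,
    ``flags_``, ``n_trials_``; convenience properties ``pse_`` and ``jnd_``.
    """

    def __init__(self, lapse: float = 0.0, method: str = "mle", n_starts: int = 3):
        self.lapse = lapse
        self.method = method
        self.n_starts = n_starts

    def fit(self, x, y) -> "CumulativeGaussianPsychometric":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("responses must be binary (0/1)")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must lie in [0, 1)")
        if self.method not in ("mle", "ls"):
            raise ValueError(f"unknown fitting method {self.method!r}")
        levels, n_yes, n_tot = _aggregate(x, y)
        if len(levels) < 2:
            raise DegenerateDataError(
                "need >= 2 distinct comparison levels to constrain a fit"
            )
        if n_yes.sum() == 0 or n_yes.sum() == n_tot.sum():
            raise DegenerateDataError(
                "all responses identical: psychometric function unconstrained"
            )
        mu0, sigma0 = _moment_start(levels, n_yes, n_tot)
        start_ll = -_nll((mu0, sigma0), levels, n_yes, n_tot, self.lapse)

        span = levels[-1] - levels[0]
        mu_bounds = (levels[0] - 2.0 * span, levels[-1] + 2.0 * span)
        starts = [(mu0, sigma0)]
        for f in (0.5, 2.0, 4.0):
            starts.append((mu0, float(np.clip(sigma0 * f, *SIGMA_BOUNDS))))
        starts = starts[: max(1, self.n_starts)]

        jac = None
        if self.method == "mle":
            objective = lambda th: _nll(th, levels, n_yes, n_tot, self.lapse)
            jac = lambda th: _nll_grad(th, levels, n_yes, n_tot, self.lapse)
        else:
            props = n_yes / n_tot

            def objective(th):
                mu, sigma = th
                p = self.lapse / 2.0 + (1.0 - self.lapse) * norm.cdf(
                    (levels - mu) / sigma
                )
                return float(np.sum(n_tot * (props - p) ** 2))

        best = None
        for s in starts:
            res = minimize(
                objective,
                s,
                jac=jac,
                method="L-BFGS-B",
                bounds=[mu_bounds, SIGMA_BOUNDS],
            )
            if best is None or res.fun < best.fun:
                best = res
        mu, sigma = best.x
        flags = []
        if not best.success:
            flags.append(f"optimizer: {best.message}")
        if sigma <= SIGMA_BOUNDS[0] * (1 + 1e-9):
            flags.append("sigma at lower bound")
        if sigma >= SIGMA_BOUNDS[1] * (1 - 1e-9):
            flags.append("sigma at upper bound")
        loglik = -_nll((mu, sigma), levels, n_yes, n_tot, self.lapse)
        if self.method == "mle" and loglik < start_ll - 1e-9:
            flags.append("likelihood below initializer")

        self.mu_ = float(mu)
        self.sigma_ = float(sigma)
        self.loglik_ = float(loglik)
        self.n_trials_ = int(n_tot.sum())
        self.converged_ = bool(best.success) and not flags
        self.flags_ = tuple(flags)
        return self

    def predict_proba(self, x):
        """P(comparison judged longer) at the given levels."""
        if not hasattr(self, "mu_"):
            raise RuntimeError("estimator is not fitted")
        x = np.asarray(x, dtype=float)
        return self.lapse / 2.0 + (1.0 - self.lapse) * norm.cdf(
            (x - self.mu_) / self.sigma_
        )

    @property
    def pse_(self) -> float:
        return self.mu_

    @property
    def jnd_(self) -> float:
        return PROBIT_75 * self.sigma_

    def to_fit(self) -> PsychometricFit:
        return PsychometricFit(
            mu_pct=self.mu_,
            sigma_pct=self.sigma_,
            loglik=self.loglik_,
            n_trials=self.n_trials_,
            converged=self.converged_,
            lapse=self.lapse,
            flags=self.flags_,
        )


def fit_cumulative_gaussian(
    trials: pd.DataFrame,
    lapse: float = 0.0,
    method: str = "mle",
) -> PsychometricFit:
    """Fit one cell's trials (columns ``comparison_pct``, ``response``).

    The input is expected to come from a single participant x condition x
    standard cell; pass slices of a trial table.  If ``participant`` /
    ``standard_ms`` columns are present and single-valued they are recorded
    on the fit so mispaired comparisons can be caught later.
    """
    est = CumulativeGaussianPsychometric(lapse=lapse, method=method)
    est.fit(trials["comparison_pct"].to_numpy(), trials["response"].to_numpy())
    fit = est.to_fit()
    meta = {}
    for col in ("participant", "standard_ms"):
        if col in trials.columns:
            vals = trials[col].unique()
            if len(vals) > 1:
                raise ValueError(
                    f"trials span multiple {col} values {vals!r}; "
                    "fit one cell at a time"
                )
            meta[col] = vals[0]
    if meta:
        from dataclasses import replace as _replace

        fit = _replace(
            fit,
            participant=str(meta["participant"]) if "participant" in meta else None,
            standard_ms=float(meta["standard_ms"]) if "standard_ms" in meta else None,
        )
    return fit


def derive_pse_jnd(fit: PsychometricFit) -> tuple[float, float]:
    """(PSE, JND) in % of the standard: the 50% point and half the 75-25% span."""
    return fit.pse_pct, fit.jnd_pct


def adaptation_effect(fit_adapt: PsychometricFit, fit_baseline: PsychometricFit) -> float:
    """PSE(adaptation) - PSE(baseline), in % of the standard duration.

    Negative values indicate duration compression after adaptation.  Both
    fits must come from the same participant and standard (checked when the
    fits carry that metadata).
    """
    for attr in ("standard_ms", "participant"):
        a, b = getattr(fit_adapt, attr), getattr(fit_baseline, attr)
        if a is not None and b is not None and a != b:
            raise ValueError(f"mismatched {attr}: {a!r} vs {b!r}")
    return fit_adapt.pse_pct - fit_baseline.pse_pct
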