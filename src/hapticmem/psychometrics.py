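"""Psychometric-function fitting and JND extraction for 2IFC data.

Responses ("comparison has the higher spatial period") are modelled as a
cumulative Gaussian of the comparison period: ``p(x) = lapse/2 +
(1-lapse) * Phi((x - mu) / sigma)``.  ``mu`` is the point of subjective
equality (PSE); the JND is defined as the period difference between the 50%
and 84% points, i.e. ``sigma`` of the underlying Gaussian.

Data from the two standards of a condition are pooled by aligning each
standard's trials at its own fitted PSE and refitting the merged set; the
pooled ``sigma`` is the condition's JND.  Participants whose mean JND lies
more than 2.5 between-participant standard deviations above the group mean
are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "fit_cumulative_gaussian",
    "pse",
    "jnd",
    "align_and_pool",
    "build_jnd_table",
    "exclude_outliers",
]

_SIGMA_MIN = 1e-4


@dataclass
class PsychometricFit:
    """A fitted cumulative Gaussian: mu (PSE, mm), sigma (JND, mm)."""

    mu: float
    sigma: float
    lapse: float
    n_trials: int
    converged: bool
    loglik: float


def _binned(levels, successes, totals):
    levels = np.asarray(levels, dtype=float)
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if not (levels.shape == successes.shape == totals.shape):
        raise ValueError("levels, successes and totals must have equal length")
    keep = totals > 0
    levels, successes, totals = levels[keep], successes[keep], totals[keep]
    order = np.argsort(levels)
    return levels[order], successes[order], totals[order]


def fit_cumulative_gaussian(
    levels,
    successes,
    totals,
    lapse: float = 0.0,
    fit_lapse: bool = False,
    max_lapse: float = 0.05,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to binomial response counts.

    Parameters
    ----------
    levels, successes, totals
        Comparison periods (mm), count of "higher" responses and trial count
        per level.  At least three distinct levels with trials are required.
    lapse, fit_lapse, max_lapse
        The lapse rate is fixed at ``lapse`` (default 0) unless ``fit_lapse``
        is set, in which case it is estimated within ``[0, max_lapse]``.

    Degenerate data (e.g. all responses identical) never raise; the fit is
    returned with ``converged=False`` when the optimiser fails or a parameter
    sits at its bound.
    """
    x, k, n = _binned(levels, successes, totals)
    if np.unique(x).size < 3:
        raise ValueError("need responses at >= 3 distinct comparison levels")
    span = float(x[-1] - x[0])
    sigma_hi = 10.0 * span

    def nll(theta):
        mu, sigma = theta[0], theta[1]
        lam = theta[2] if fit_lapse else lapse
        p = lam / 2.0 + (1.0 - lam) * norm.cdf((x - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    props = k / n
    # crude initialisers: level nearest p=.5, and slope-based spread
    mu0 = float(x[np.argmin(np.abs(props - 0.5))])
    inits = [
        (mu0, span / 4.0),
        (float(np.mean(x)), span / 2.0),
        (mu0, span / 10.0),
    ]
    bounds = [
        (x[0] - 2 * span, x[-1] + 2 * span),
        (_SIGMA_MIN, sigma_hi),
    ]
    if fit_lapse:
        bounds.append((0.0, max_lapse))
    best = None
    for mu_i, sg_i in inits:
        theta0 = [mu_i, sg_i] + ([min(0.01, max_lapse)] if fit_lapse else [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        # a clean success away from the sigma bounds needs no restarts
        if res.success and _SIGMA_MIN * (1 + 1e-6) < res.x[1] < sigma_hi * (1 - 1e-6):
            break
    mu, sigma = float(best.x[0]), float(best.x[1])
    lam = float(best.x[2]) if fit_lapse else lapse
    at_bound = (
        sigma <= _SIGMA_MIN * (1 + 1e-6)
        or sigma >= sigma_hi * (1 - 1e-6)
        or mu <= bounds[0][0] + 1e-9
        or mu >= bounds[0][1] - 1e-9
    )
    return PsychometricFit(
        mu=mu,
        sigma=sigma,
        lapse=lam,
        n_trials=int(n.sum()),
        converged=bool(best.success) and not at_bound,
        loglik=-float(best.fun),
    )


def pse(fit: PsychometricFit) -> float:
    """PSE in mm: the 50% point of the underlying Gaussian (``mu``)."""
    if not fit.converged:
        raise ValueError("cannot read PSE from an unconverged fit")
    return fit.mu


def jnd(fit: PsychometricFit) -> float:
    """JND in mm: 84% point minus 50% point, i.e. ``sigma`` (Phi(1) ~ 0.8413)."""
    if not fit.converged:
        raise ValueError("cannot read JND from an unconverged fit")
    return fit.sigma


def _counts(trials: pd.DataFrame, x_col: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = trials.groupby(x_col)["response"]
    agg = g.agg(["sum", "count"])
    return agg.index.to_numpy(float), agg["sum"].to_numpy(float), agg["count"].to_numpy(float)


@dataclass
class PooledFit:
    """Alignment-and-pooling result for one participant x condition."""

    pse_by_standard: dict[float, float]
    standard_fits: dict[float, PsychometricFit]
    pooled: PsychometricFit
    aligned_ok: bool


def align_and_pool(trials: pd.DataFrame, **fit_kwargs) -> PooledFit:
    """Pool the two standards' data of one condition at their fitted PSEs.

    Per-standard cumulative Gaussians are fitted first; each trial's
    comparison period is then re-expressed relative to its standard's PSE and
    the merged data refit.  The pooled ``mu`` is re-estimated freely and
    should land within one comparison step of 0; larger residuals set
    ``aligned_ok=False``.  A single-standard input degenerates to that
    standard's (aligned) fit.
    """
    fits: dict[float, PsychometricFit] = {}
    pses: dict[float, float] = {}
    pieces = []
    converged = True
    for std, sub in trials.groupby("standard_period_mm"):
        x, k, n = _counts(sub, "comparison_period_mm")
        fit = fit_cumulative_gaussian(x, k, n, **fit_kwargs)
        fits[float(std)] = fit
        converged &= fit.converged
        pses[float(std)] = fit.mu
        shifted = sub.copy()
        shifted["aligned_period_mm"] = shifted["comparison_period_mm"] - fit.mu
        pieces.append(shifted)
    merged = pd.concat(pieces)
    x, k, n = _counts(merged, "aligned_period_mm")
    pooled = fit_cumulative_gaussian(x, k, n, **fit_kwargs)
    pooled.converged = pooled.converged and converged
    steps = [
        np.median(np.diff(np.unique(sub["comparison_period_mm"])))
        for _, sub in trials.groupby("standard_period_mm")
    ]
    step = float(np.median(steps))
    aligned_ok = bool(abs(pooled.mu) <= step) and pooled.converged
    return PooledFit(
        pse_by_standard=pses, standard_fits=fits, pooled=pooled, aligned_ok=aligned_ok
    )


def build_jnd_table(trials: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """Per participant x condition JNDs and per-standard PSEs from raw trials.

    Returns a frame with columns participant, condition, n1, masked,
    pse_std1_mm, pse_std2_mm (ordered by standard period), jnd_mm, converged.
    """
    rows = []
    for (p, cond), sub in trials.groupby(["participant", "condition"], sort=True):
        pooled = align_and_pool(sub, **fit_kwargs)
        stds = sorted(pooled.pse_by_standard)
        row = {
            "participant": p,
            "condition": cond,
            "n1": int(sub["n1"].iloc[0]),
            "masked": bool(sub["masked"].iloc[0]),
            "pse_std1_mm": pooled.pse_by_standard[stds[0]],
            "pse_std2_mm": pooled.pse_by_standard[stds[-1]] if len(stds) > 1 else np.nan,
            "jnd_mm": pooled.pooled.sigma,
            "converged": pooled.pooled.converged,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def exclude_outliers(jnd_table: pd.DataFrame, z: float = 2.5) -> pd.DataFrame:
    """Flag participants with outlying bad precision.

    A participant is excluded iff their mean JND across conditions exceeds
    the grand mean by more than ``z`` between-participant standard deviations
    (single pass, statistics over all participants, upper tail only).  With
    fewer than three participants the rule is not applied.
    """
    out = jnd_table.copy()
    means = out.groupby("participant")["jnd_mm"].mean()
    if len(means) < 3:
        warnings.warn("fewer than 3 participants; exclusion rule not applied")
        out["excluded"] = False
        return out
    cutoff = means.mean() + z * means.std(ddof=1)
    bad = set(means.index[means > cutoff])
    out["excluded"] = out["participant"].isin(bad)
    return out
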