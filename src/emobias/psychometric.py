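"""Binomial maximum-likelihood fitting of cumulative-normal psychometric
functions, with PSE and slope-at-PSE derivation.

The model is F(x) = gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma)
fit by maximizing the binomial log-likelihood of per-level happy counts
over (mu, sigma), with the asymptote parameters fixed by options
(default gamma = lambda = 0) or a small shared lapse fitted.  The
optimizer is a deterministic coarse grid over (mu, sigma) followed by
bounded Nelder-Mead refinement, so fits are reproducible and the
refined likelihood can be checked against an exhaustive grid oracle.

PSE is the stimulus solving F(x) = 0.5 (equal to mu when the asymptotes
are symmetric); slope-at-PSE is the derivative of F there, equal to
(1 - gamma - lambda) / (sigma * sqrt(2*pi)) in the symmetric case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from emobias.errors import DegenerateDataError, InsufficientDataError
from emobias.io import DESIGN_LEVELS, VALID_RESPONSES

_P_CLIP = 1e-9  # F is clipped to [_P_CLIP, 1 - _P_CLIP] inside the likelihood


@dataclass(frozen=True)
class LevelCounts:
    """Per-level trial and happy-response counts, levels ascending."""

    levels: tuple[float, ...]
    n_valid: tuple[int, ...]
    k_happy: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.n_valid) == len(self.k_happy)):
            raise ValueError("levels, n_valid and k_happy lengths differ")
        if any(k < 0 or k > n for k, n in zip(self.k_happy, self.n_valid)):
            raise ValueError("need 0 <= k_happy <= n_valid at every level")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_valid))

    @property
    def k_total(self) -> int:
        return int(sum(self.k_happy))


@dataclass(frozen=True)
class FitOptions:
    """Fitting options; defaults give the plain 2-parameter model."""

    guess: float = 0.0
    lapse: float = 0.0
    fit_lapse: bool = False          # fit a shared lapse in [0, lapse_max]
    lapse_max: float = 0.05
    mu_bounds: tuple[float, float] = (-100.0, 100.0)
    sigma_bounds: tuple[float, float] = (0.05, 200.0)
    grid_mu_points: int = 21
    grid_sigma_range: tuple[float, float] = (0.1, 100.0)
    grid_sigma_points: int = 25


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    guess: float
    lapse: float
    loglik: float
    deviance: float
    converged: bool
    n_valid_trials: int
    pse: float
    slope_at_pse: float

    def to_dict(self) -> dict:
        return {
            "mu": self.mu, "sigma": self.sigma, "guess": self.guess,
            "lapse": self.lapse, "loglik": self.loglik,
            "deviance": self.deviance, "converged": self.converged,
            "n_valid_trials": self.n_valid_trials, "pse": self.pse,
            "slope_at_pse": self.slope_at_pse,
        }


def aggregate_levels(trials: pd.DataFrame,
                     levels: Sequence[int] = DESIGN_LEVELS) -> LevelCounts:
    """Collapse one participant's trials to per-level (n, k) counts.

    Omitted trials are dropped from both numerator and denominator; all
    design levels are present in the output even with zero counts.
    """
    valid = trials[trials["response"].isin(VALID_RESPONSES)]
    if len(valid) == 0:
        raise DegenerateDataError("no valid trials to aggregate")
    ordered = sorted(int(x) for x in levels)
    n_valid, k_happy = [], []
    for level in ordered:
        at = valid[valid["morph_level"] == level]
        n_valid.append(int(len(at)))
        k_happy.append(int((at["response"] == "happy").sum()))
    return LevelCounts(levels=tuple(float(x) for x in ordered),
                       n_valid=tuple(n_valid), k_happy=tuple(k_happy))


def _model_prob(x: np.ndarray, mu: float, sigma: float,
                guess: float, lapse: float) -> np.ndarray:
    return guess + (1.0 - guess - lapse) * norm.cdf((x - mu) / sigma)


def _neg_loglik(x: np.ndarray, n: np.ndarray, k: np.ndarray,
                mu, sigma, guess: float, lapse) -> np.ndarray:
    """Negative binomial log-likelihood; broadcasts over parameter arrays."""
    p = guess + (1.0 - guess - lapse) * norm.cdf((x - mu) / sigma)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=-1)


def _grid_nll(counts: LevelCounts, mu_grid: np.ndarray,
              sigma_grid: np.ndarray, guess: float, lapse: float) -> np.ndarray:
    x = np.asarray(counts.levels)
    n = np.asarray(counts.n_valid, dtype=float)
    k = np.asarray(counts.k_happy, dtype=float)
    mu = mu_grid[:, None, None]
    sigma = sigma_grid[None, :, None]
    return _neg_loglik(x[None, None, :], n, k, mu, sigma, guess, lapse)


def grid_search(counts: LevelCounts,
                mu_grid: np.ndarray, sigma_grid: np.ndarray,
                guess: float = 0.0, lapse: float = 0.0,
                ) -> tuple[float, float, float]:
    """Exhaustive likelihood evaluation on a (mu, sigma) grid.

    Returns (mu, sigma, loglik) of the best grid point; ties broken in
    favour of the lowest sigma.  Also serves as the independent oracle
    the refined fit is validated against.
    """
    nll = _grid_nll(counts, mu_grid, sigma_grid, guess, lapse)
    # lexsort-style tie break: minimal nll, then minimal sigma
    best = np.min(nll)
    ties = np.argwhere(nll <= best + 1e-12)
    i, j = min(ties.tolist(), key=lambda ij: (sigma_grid[ij[1]], mu_grid[ij[0]]))
    return float(mu_grid[i]), float(sigma_grid[j]), float(-nll[i, j])


def _grid_starts(counts: LevelCounts, mu_grid: np.ndarray,
                 sigma_grid: np.ndarray, guess: float, lapse: float,
                 n_starts: int = 3) -> list[tuple[float, float]]:
    """Best ``n_starts`` grid points, ordered by likelihood then sigma."""
    nll = _grid_nll(counts, mu_grid, sigma_grid, guess, lapse)
    flat = nll.ravel()
    order = np.lexsort((np.tile(sigma_grid, len(mu_grid)), flat))
    starts = []
    for idx in order[:n_starts]:
        i, j = divmod(int(idx), len(sigma_grid))
        starts.append((float(mu_grid[i]), float(sigma_grid[j])))
    return starts


def fit_psychometric(counts: LevelCounts,
                     options: FitOptions | None = None) -> PsychometricFit:
    """Maximum-likelihood fit of the cumulative-normal model.

    Requires at least 2 levels with responses.  Degenerate data (every
    response identical) never raise: the fit is returned with
    ``converged=False`` and mu pushed toward a bound, so cohort runs
    complete and downstream stages can drop the flagged row.
    """
    options = options or FitOptions()
    x = np.asarray(counts.levels)
    n = np.asarray(counts.n_valid, dtype=float)
    k = np.asarray(counts.k_happy, dtype=float)
    informative = n > 0
    if informative.sum() < 2:
        raise InsufficientDataError(
            "need >= 2 morph levels with valid trials to fit")
    degenerate = counts.k_total == 0 or counts.k_total == counts.n_total

    lo = float(x[informative].min())
    hi = float(x[informative].max())
    mu_grid = np.linspace(lo, hi, options.grid_mu_points)
    sigma_grid = np.geomspace(*options.grid_sigma_range,
                              options.grid_sigma_points)
    lapse_values = ([0.0, options.lapse_max / 2, options.lapse_max]
                    if options.fit_lapse else [options.lapse])

    best = None
    for lapse0 in lapse_values:
        starts = _grid_starts(counts, mu_grid, sigma_grid,
                              guess=options.guess, lapse=lapse0)
        if options.fit_lapse:
            bounds = [options.mu_bounds, options.sigma_bounds,
                      (0.0, options.lapse_max)]

            def objective(theta, lapse0=lapse0):
                return _neg_loglik(x, n, k, theta[0], theta[1],
                                   options.guess, theta[2])
        else:
            bounds = [options.mu_bounds, options.sigma_bounds]

            def objective(theta, lapse0=lapse0):
                return _neg_loglik(x, n, k, theta[0], theta[1],
                                   options.guess, lapse0)

        for mu0, sigma0 in starts:
            theta0 = (np.array([mu0, sigma0, lapse0]) if options.fit_lapse
                      else np.array([mu0, sigma0]))
            res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                    bounds=bounds,
                                    options={"xatol": 1e-6, "fatol": 1e-9,
                                             "maxiter": 2000})
            if best is None or res.fun < best[0]:
                best = (float(res.fun), res.x, res.success, lapse0)

    nll_opt, theta, success, lapse0 = best
    mu_hat, sigma_hat = float(theta[0]), float(theta[1])
    lapse_hat = float(theta[2]) if options.fit_lapse else float(lapse0)
    converged = bool(success) and not degenerate

    fit = PsychometricFit(
        mu=mu_hat, sigma=sigma_hat, guess=options.guess, lapse=lapse_hat,
        loglik=-nll_opt, deviance=float("nan"), converged=converged,
        n_valid_trials=counts.n_total,
        pse=_pse(mu_hat, sigma_hat, options.guess, lapse_hat),
        slope_at_pse=_slope_at_pse(mu_hat, sigma_hat, options.guess, lapse_hat))
    deviance, _ = deviance_gof(fit, counts)
    return PsychometricFit(**{**fit.to_dict(), "deviance": deviance})


def _pse(mu: float, sigma: float, guess: float, lapse: float) -> float:
    # x with F(x) = 0.5:  Phi((x - mu)/sigma) = (0.5 - guess)/(1 - guess - lapse)
    target = (0.5 - guess) / (1.0 - guess - lapse)
    return mu + sigma * float(norm.ppf(target))


def _slope_at_pse(mu: float, sigma: float, guess: float, lapse: float) -> float:
    target = (0.5 - guess) / (1.0 - guess - lapse)
    z = float(norm.ppf(target))
    return (1.0 - guess - lapse) * float(norm.pdf(z)) / sigma


def pse_of(fit: PsychometricFit) -> float:
    """Morph level supporting 50% happy judgments (positive => negative
    perceptual bias)."""
    return _pse(fit.mu, fit.sigma, fit.guess, fit.lapse)


def slope_at_pse(fit: PsychometricFit) -> float:
    """Derivative of the fitted function at the PSE, in probability per
    morph-%; larger values mean a more categorical judgment boundary."""
    return _slope_at_pse(fit.mu, fit.sigma, fit.guess, fit.lapse)


def deviance_gof(fit: PsychometricFit,
                 counts: LevelCounts) -> tuple[float, np.ndarray]:
    """Deviance against the saturated model, plus signed residuals.

    deviance = 2 * sum[ k log(k/(n F)) + (n-k) log((n-k)/(n (1-F))) ]
    with the convention 0 * log 0 = 0.  Residuals are signed square
    roots of the per-level deviance contributions.
    """
    x = np.asarray(counts.levels)
    n = np.asarray(counts.n_valid, dtype=float)
    k = np.asarray(counts.k_happy, dtype=float)
    mask = n > 0
    x, n, k = x[mask], n[mask], k[mask]
    f = np.clip(_model_prob(x, fit.mu, fit.sigma, fit.guess, fit.lapse),
                _P_CLIP, 1.0 - _P_CLIP)

    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log(k / (n * f)), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - f))), 0.0)
    per_level = 2.0 * (term1 + term2)
    per_level = np.maximum(per_level, 0.0)  # guard tiny negative round-off
    sign = np.sign(k / n - f)
    residuals = sign * np.sqrt(per_level)
    return float(per_level.sum()), residuals


def bootstrap_pse_ci(counts: LevelCounts, fit: PsychometricFit,
                     n_boot: int = 200, level: float = 0.95,
                     seed: int = 0,
                     options: FitOptions | None = None) -> dict:
    """Parametric-bootstrap percentile CI for PSE and slope.

    Optional diagnostic; not part of the core analysis path.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(counts.levels)
    n = np.asarray(counts.n_valid)
    p = _model_prob(x, fit.mu, fit.sigma, fit.guess, fit.lapse)
    pses, slopes = [], []
    for _ in range(n_boot):
        k_boot = rng.binomial(n, p)
        boot_counts = LevelCounts(levels=counts.levels,
                                  n_valid=tuple(int(v) for v in n),
                                  k_happy=tuple(int(v) for v in k_boot))
        try:
            boot_fit = fit_psychometric(boot_counts, options)
        except (DegenerateDataError, InsufficientDataError):
            continue
        if boot_fit.converged:
            pses.append(boot_fit.pse)
            slopes.append(boot_fit.slope_at_pse)
    alpha = (1.0 - level) / 2.0
    quantiles = [100 * alpha, 100 * (1 - alpha)]
    return {
        "pse_ci": tuple(np.percentile(pses, quantiles)) if pses else None,
        "slope_ci": tuple(np.percentile(slopes, quantiles)) if slopes else None,
        "n_boot_used": len(pses),
    }
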