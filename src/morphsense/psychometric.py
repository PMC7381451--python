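"""Logistic psychometric function for 2IFC expression-discrimination data.

The observer discriminates a morph-diluted emotional face from the neutral
face of the same identity in a temporal two-interval forced-choice (2IFC)
task.  Stimulus strength is parameterised by *dilution*: the percentage of
the neutral face morphed into the expressive face (0 % = full expression,
100 % = neutral).  Fitting happens in *intensity* space, ``x = 100 −
dilution``, so that performance increases with ``x`` and the slope is
positive; thresholds are reported back on the dilution scale, where a
larger value means the observer tolerates more dilution, i.e. is more
sensitive to the expression.

The performance model is the standard guess/lapse wrapper around a
logistic,

    ψ(x) = γ + (1 − γ − λ) · F(x; α, β),   F(x) = 1 / (1 + exp(−β(x − α))),

with γ = 0.5 (2IFC chance) and λ = 0 by default, so that ψ(α) = 0.75: α is
the intensity at the 75 %-correct criterion.  Maximum-likelihood estimates
of (α, β) are obtained from the exact binomial likelihood with a
multi-start quasi-Newton search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "GUESS_2IFC",
    "DEFAULT_CRITERION",
    "StimulusLevel",
    "BinnedData",
    "PsychometricParams",
    "FitResult",
    "InvalidParameterError",
    "UnattainableCriterionError",
    "UnfittableError",
    "eval_logistic",
    "eval_performance",
    "predict_percent_correct",
    "neg_log_likelihood",
    "fit_pf",
    "threshold_dilution",
    "threshold_from_params",
    "bootstrap_threshold_ci",
    "PsychometricCurve",
]

GUESS_2IFC = 0.5
DEFAULT_CRITERION = 0.75

#: Performance probabilities are clipped to this band inside logarithms so
#: the binomial negative log-likelihood stays finite with λ = 0.
_PSI_EPS = 1e-10

#: Optimiser box for (alpha, beta) in intensity units.
ALPHA_BOUNDS = (-50.0, 150.0)
BETA_BOUNDS = (1e-3, 10.0)


class InvalidParameterError(ValueError):
    """A psychometric parameter violates its domain (e.g. beta <= 0)."""


class UnattainableCriterionError(ValueError):
    """The requested criterion lies outside (gamma, 1 - lapse)."""


class UnfittableError(RuntimeError):
    """Threshold extraction was requested from an unfittable fit."""


def intensity_from_dilution(dilution_pct):
    """Map dilution (% neutral) to expression intensity, ``100 - dilution``."""
    return 100.0 - np.asarray(dilution_pct, dtype=float)


def dilution_from_intensity(intensity_pct):
    return 100.0 - np.asarray(intensity_pct, dtype=float)


@dataclass(frozen=True)
class StimulusLevel:
    """One morph level: ``intensity_pct`` is derived as ``100 - dilution_pct``."""

    dilution_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dilution_pct <= 100.0:
            raise ValueError(
                f"dilution_pct must lie in [0, 100], got {self.dilution_pct}"
            )

    @property
    def intensity_pct(self) -> float:
        return 100.0 - self.dilution_pct


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the 2IFC performance function.

    alpha
        Threshold location in intensity percent: ψ(alpha) sits halfway
        between the guess and lapse asymptotes (75 % for γ=0.5, λ=0).
    beta
        Logistic slope per percent intensity, > 0.
    gamma
        Guess rate (lower asymptote); 0.5 for 2IFC.
    lapse
        Lapse rate; the upper asymptote is 1 − lapse.
    """

    alpha: float
    beta: float
    gamma: float = GUESS_2IFC
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise InvalidParameterError(f"alpha must be finite, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.gamma < 1.0:
            raise InvalidParameterError(f"gamma must be in [0, 1), got {self.gamma}")
        if not 0.0 <= self.lapse < 1.0:
            raise InvalidParameterError(f"lapse must be in [0, 1), got {self.lapse}")
        if self.gamma + self.lapse >= 1.0:
            raise InvalidParameterError(
                f"gamma + lapse must be < 1, got {self.gamma + self.lapse}"
            )

    @property
    def threshold_dilution(self) -> float:
        """Dilution at which ψ crosses the midpoint criterion; ``100 - alpha``."""
        return 100.0 - self.alpha


@dataclass(frozen=True)
class BinnedData:
    """Per-dilution trial and correct counts for one fitting unit.

    Levels are stored sorted by ascending dilution so that fitting is
    invariant to input order.  Counts are normally integers; nonnegative
    reals are accepted so expected-count (noiseless) data can be fit.
    """

    dilution_pct: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.dilution_pct, dtype=float))
        n = np.atleast_1d(np.asarray(self.n_trials, dtype=float))
        k = np.atleast_1d(np.asarray(self.n_correct, dtype=float))
        if not (d.shape == n.shape == k.shape) or d.ndim != 1:
            raise ValueError("dilution_pct, n_trials, n_correct must be 1-D, equal length")
        if d.size == 0:
            raise ValueError("at least one level is required")
        if np.any((d < 0) | (d > 100)):
            raise ValueError("dilution_pct must lie in [0, 100]")
        if np.unique(d).size != d.size:
            raise ValueError("levels must be distinct")
        if np.any(n < 0) or np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= n_correct <= n_trials")
        if not np.any(n > 0):
            raise ValueError("at least one level must have trials")
        order = np.argsort(d)
        object.__setattr__(self, "dilution_pct", d[order])
        object.__setattr__(self, "n_trials", n[order])
        object.__setattr__(self, "n_correct", k[order])

    @property
    def intensity_pct(self) -> np.ndarray:
        return intensity_from_dilution(self.dilution_pct)

    @property
    def proportion_correct(self) -> np.ndarray:
        """Observed proportion correct per level (NaN where no trials)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_trials > 0, self.n_correct / self.n_trials, np.nan)

    @property
    def n_levels_used(self) -> int:
        return int(np.count_nonzero(self.n_trials > 0))

    @property
    def total_trials(self) -> float:
        return float(self.n_trials.sum())


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the performance function to one dataset.

    When ``fittable`` is false the parameters are the optimiser's best
    point but carry no threshold interpretation; threshold extraction
    refuses them.  ``log_likelihood`` is the exact binomial log-likelihood
    at ``params`` (<= 0 for integer counts).
    """

    params: PsychometricParams
    log_likelihood: float
    free_mask: tuple[str, ...] = ("alpha", "beta")
    converged: bool = True
    fittable: bool = True
    n_levels_used: int = 0
    reason: str | None = None


def eval_logistic(x, alpha: float, beta: float):
    """Plain logistic ``F(x) = 1 / (1 + exp(-beta * (x - alpha)))``.

    Strictly increasing in ``x`` with ``F(alpha) = 0.5``; ``beta`` must be
    positive.
    """
    if not beta > 0:
        raise InvalidParameterError(f"beta must be > 0, got {beta}")
    x = np.asarray(x, dtype=float)
    out = expit(beta * (x - alpha))
    return out if out.ndim else float(out)


def eval_performance(x, params: PsychometricParams):
    """2IFC performance ψ(x) = γ + (1 − γ − λ)·F(x; α, β), in [γ, 1 − λ]."""
    f = eval_logistic(x, params.alpha, params.beta)
    out = params.gamma + (1.0 - params.gamma - params.lapse) * np.asarray(f)
    return out if out.ndim else float(out)


def predict_percent_correct(dilution_pct, params: PsychometricParams):
    """Predicted percent correct at given dilution levels (convenience)."""
    return 100.0 * eval_performance(intensity_from_dilution(dilution_pct), params)


def neg_log_likelihood(data: BinnedData, params: PsychometricParams) -> float:
    """Exact binomial negative log-likelihood of ``data`` under ``params``.

    ψ is clipped away from 0 and 1 inside the logarithms, so the result is
    finite even when λ = 0 and an error occurs at very high intensity.
    Additive over disjoint level sets.
    """
    psi = eval_performance(data.intensity_pct, params)
    psi = np.clip(psi, _PSI_EPS, 1.0 - _PSI_EPS)
    n, k = data.n_trials, data.n_correct
    return float(-(k * np.log(psi) + (n - k) * np.log(1.0 - psi)).sum())


# ---------------------------------------------------------------------------
# ML fitting machinery (shared with the model-comparison bootstrap)
# ---------------------------------------------------------------------------


def _nll_and_grad(theta, x, n, k, gamma, lapse):
    """Binomial NLL and its analytic gradient w.r.t. (alpha, beta).

    Gradients ignore the clipping of ψ (flat where clipped); with counts
    concordant at the asymptotes this does not perturb the optimum.
    """
    alpha, beta = theta
    f = expit(beta * (x - alpha))
    span = 1.0 - gamma - lapse
    psi = np.clip(gamma + span * f, _PSI_EPS, 1.0 - _PSI_EPS)
    nll = -(k * np.log(psi) + (n - k) * np.log(1.0 - psi)).sum()
    # dNLL/dψ, then chain through ψ = γ + span·F
    dpsi = -(k / psi - (n - k) / (1.0 - psi))
    ff = f * (1.0 - f)
    ga = float((dpsi * span * ff * (-beta)).sum())
    gb = float((dpsi * span * ff * (x - alpha)).sum())
    return float(nll), np.array([ga, gb])


def _fisher_fit(x, n, k, gamma, lapse, start, max_iter=60, tol=1e-7):
    """Damped Fisher-scoring minimisation of the binomial NLL from one start.

    The expected information matrix is positive semi-definite, so the
    scoring direction is a descent direction; a halving line search keeps
    the iteration monotone.  Much faster than the multi-start quasi-Newton
    path and used for the bootstrap refits, which begin at the generating
    (null) parameters.  Returns ``(alpha, beta, nll, converged)``.
    """
    span = 1.0 - gamma - lapse
    a = float(np.clip(start[0], *ALPHA_BOUNDS))
    b = float(np.clip(start[1], *BETA_BOUNDS))

    def evaluate(a, b):
        f = expit(b * (x - a))
        psi = np.clip(gamma + span * f, _PSI_EPS, 1.0 - _PSI_EPS)
        nll = -(k * np.log(psi) + (n - k) * np.log(1.0 - psi)).sum()
        return f, psi, float(nll)

    f, psi, nll = evaluate(a, b)
    converged = False
    for _ in range(max_iter):
        dpsi = -(k / psi - (n - k) / (1.0 - psi))
        ff = span * f * (1.0 - f)
        ga = float((dpsi * ff * (-b)).sum())
        gb = float((dpsi * ff * (x - a)).sum())
        gnorm = max(abs(ga), abs(gb))
        if gnorm < tol * (1.0 + abs(nll)):
            converged = True
            break
        w = n * ff * ff / (psi * (1.0 - psi))
        iaa = float((w * b * b).sum())
        iab = float((w * (-b) * (x - a)).sum())
        ibb = float((w * (x - a) ** 2).sum())
        ridge = 1e-10 * (iaa + ibb) + 1e-12
        det = (iaa + ridge) * (ibb + ridge) - iab * iab
        if det <= 0:
            break
        da = -((ibb + ridge) * ga - iab * gb) / det
        db = -((iaa + ridge) * gb - iab * ga) / det
        step = 1.0
        improved = False
        for _ in range(25):
            a_new = float(np.clip(a + step * da, *ALPHA_BOUNDS))
            b_new = float(np.clip(b + step * db, *BETA_BOUNDS))
            if a_new == a and b_new == b:
                break
            f_new, psi_new, nll_new = evaluate(a_new, b_new)
            if nll_new < nll - 1e-12:
                a, b, f, psi, nll = a_new, b_new, f_new, psi_new, nll_new
                improved = True
                break
            step *= 0.5
        if not improved:
            # no descent possible: at the optimum (or a bound) to line-search
            converged = gnorm < 1e-3 * (1.0 + abs(nll))
            break
    return a, b, nll, converged


def _alpha_starts(x, n, k, gamma, lapse):
    """Candidate alpha starts: mid-performance crossing plus range anchors."""
    mask = n > 0
    xs, ps = x[mask], k[mask] / n[mask]
    order = np.argsort(xs)
    xs, ps = xs[order], ps[order]
    mid = gamma + (1.0 - gamma - lapse) / 2.0
    starts = []
    above = ps >= mid
    # first crossing from below to above, linearly interpolated
    for i in range(len(xs) - 1):
        if not above[i] and above[i + 1]:
            p0, p1 = ps[i], ps[i + 1]
            t = (mid - p0) / (p1 - p0) if p1 != p0 else 0.5
            starts.append(xs[i] + t * (xs[i + 1] - xs[i]))
            break
    starts += [float(np.median(xs)), float(xs[0]), float(xs[-1])]
    return starts


def _ml_fit(x, n, k, gamma, lapse, n_starts=7, rng=None, start_hint=None):
    """Multi-start L-BFGS-B minimisation of the binomial NLL.

    Returns ``(alpha, beta, nll, converged, at_bound)``.  ``start_hint``
    (alpha, beta) is tried first; with ``rng`` additional jittered starts
    are appended (used by bootstrap retries).
    """
    alphas = _alpha_starts(x, n, k, gamma, lapse)
    betas = [0.05, 0.15, 0.4, 1.0]
    starts: list[tuple[float, float]] = []
    if start_hint is not None:
        starts.append(start_hint)
    for a in alphas:
        for b in betas:
            starts.append((a, b))
    starts = starts[: max(n_starts, 1 + (start_hint is not None))]
    if rng is not None:
        lo, hi = float(np.min(x)), float(np.max(x))
        for _ in range(3):
            starts.append(
                (rng.uniform(lo, hi), float(np.exp(rng.uniform(np.log(0.02), np.log(2.0)))))
            )
    best = None
    bounds = [ALPHA_BOUNDS, BETA_BOUNDS]
    for a0, b0 in starts:
        a0 = float(np.clip(a0, *ALPHA_BOUNDS))
        b0 = float(np.clip(b0, *BETA_BOUNDS))
        res = minimize(
            _nll_and_grad,
            np.array([a0, b0]),
            args=(x, n, k, gamma, lapse),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = best.x
    at_bound = (
        abs(alpha - ALPHA_BOUNDS[0]) < 1e-6
        or abs(alpha - ALPHA_BOUNDS[1]) < 1e-6
        or abs(beta - BETA_BOUNDS[0]) < 1e-9
        or abs(beta - BETA_BOUNDS[1]) < 1e-6
    )
    return float(alpha), float(beta), float(best.fun), bool(best.success), at_bound


def fit_pf(
    data: BinnedData,
    gamma: float = GUESS_2IFC,
    lapse: float = 0.0,
    criterion: float = DEFAULT_CRITERION,
    n_starts: int = 7,
) -> FitResult:
    """Fit threshold and slope by maximum likelihood, guess/lapse fixed.

    The fit is declared unfittable (``fittable=False``, no exception) when
    fewer than two levels carry trials, when observed performance never
    reaches the criterion at any level (the function cannot be pinned to
    the criterion, as happens for overly strong fear morph sets), or when
    the optimiser terminates on a parameter bound.
    """
    x, n, k = data.intensity_pct, data.n_trials, data.n_correct
    reason = None
    if data.n_levels_used < 2:
        reason = "fewer than 2 levels with trials"
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        if np.nanmax(props) < criterion:
            reason = (
                f"observed performance never reaches the {criterion:.0%} criterion"
            )
    alpha, beta, nll, converged, at_bound = _ml_fit(
        x, n, k, gamma, lapse, n_starts=n_starts
    )
    if reason is None and at_bound:
        reason = "optimizer terminated at a parameter bound"
    params = PsychometricParams(alpha=alpha, beta=beta, gamma=gamma, lapse=lapse)
    return FitResult(
        params=params,
        log_likelihood=-nll,
        free_mask=("alpha", "beta"),
        converged=converged,
        fittable=reason is None and converged,
        n_levels_used=data.n_levels_used,
        reason=reason if reason is not None else (None if converged else "optimizer failed"),
    )


def threshold_from_params(
    params: PsychometricParams, criterion: float = DEFAULT_CRITERION
) -> float:
    """Dilution at which ψ equals ``criterion``; inverse of the fitted curve.

    With γ = 0.5, λ = 0 and the default 0.75 criterion this is exactly
    ``100 − alpha``.  Raises :class:`UnattainableCriterionError` when the
    criterion lies outside the open interval (γ, 1 − λ).
    """
    if not params.gamma < criterion < 1.0 - params.lapse:
        raise UnattainableCriterionError(
            f"criterion {criterion} outside attainable range "
            f"({params.gamma}, {1.0 - params.lapse})"
        )
    q = (criterion - params.gamma) / (1.0 - params.gamma - params.lapse)
    x_star = params.alpha + math.log(q / (1.0 - q)) / params.beta
    return 100.0 - x_star


def threshold_dilution(fit: FitResult, criterion: float = DEFAULT_CRITERION) -> float:
    """Threshold on the dilution scale from a fitted result.

    Larger values mean the observer tolerates more neutral dilution at
    criterion, i.e. greater sensitivity.  Refuses unfittable fits.
    """
    if not fit.fittable:
        raise UnfittableError(
            f"cannot extract a threshold from an unfittable fit ({fit.reason})"
        )
    return threshold_from_params(fit.params, criterion)


# ---------------------------------------------------------------------------
# Estimator interface
# ---------------------------------------------------------------------------


class PsychometricCurve(BaseEstimator):
    """Scikit-learn style estimator for the 2IFC psychometric curve.

    Parameters
    ----------
    guess : float, default 0.5
        Fixed guess rate γ (2IFC chance).
    lapse : float, default 0.0
        Fixed lapse rate λ.
    criterion : float, default 0.75
        Performance criterion defining the threshold.
    n_starts : int, default 7
        Number of optimiser starts.

    Attributes
    ----------
    alpha_, beta_ : float
        ML estimates in intensity units.
    threshold_ : float
        Criterion threshold on the dilution scale (NaN when unfittable).
    log_likelihood_ : float
        Binomial log-likelihood at the estimate.
    fittable_, converged_ : bool
    result_ : FitResult

    Examples
    --------
    >>> curve = PsychometricCurve().fit([[96.], [90.], [80.]], [0.55, 0.76, 0.97],
    ...                                 sample_weight=[240, 240, 240])
    >>> round(curve.threshold_, 1)  # doctest: +SKIP
    90.2
    """

    def __init__(
        self,
        guess: float = GUESS_2IFC,
        lapse: float = 0.0,
        criterion: float = DEFAULT_CRITERION,
        n_starts: int = 7,
    ):
        self.guess = guess
        self.lapse = lapse
        self.criterion = criterion
        self.n_starts = n_starts

    def fit(self, X, y, sample_weight=None):
        """Fit from per-trial or per-level data.

        ``X`` holds dilution percentages, shape ``(n, 1)`` or ``(n,)``.
        ``y`` is 0/1 correctness per trial, or a proportion correct per
        level when ``sample_weight`` carries the trial counts.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have exactly one feature (dilution_pct)")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        levels, inv = np.unique(X, return_inverse=True)
        n = np.bincount(inv, weights=w, minlength=levels.size)
        k = np.bincount(inv, weights=w * y, minlength=levels.size)
        data = BinnedData(levels, n, k)
        self.result_ = fit_pf(
            data,
            gamma=self.guess,
            lapse=self.lapse,
            criterion=self.criterion,
            n_starts=self.n_starts,
        )
        self.alpha_ = self.result_.params.alpha
        self.beta_ = self.result_.params.beta
        self.log_likelihood_ = self.result_.log_likelihood
        self.fittable_ = self.result_.fittable
        self.converged_ = self.result_.converged
        self.n_levels_ = self.result_.n_levels_used
        self.threshold_ = (
            threshold_dilution(self.result_, self.criterion)
            if self.fittable_
            else float("nan")
        )
        return self

    def predict(self, X):
        """Predicted probability correct at the given dilution levels."""
        if not hasattr(self, "result_"):
            raise RuntimeError("PsychometricCurve is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray(
            eval_performance(intensity_from_dilution(X), self.result_.params)
        )


def bootstrap_threshold_ci(
    data: BinnedData,
    fit: FitResult,
    n_boot: int = 999,
    level: float = 0.95,
    seed: int | None = None,
    criterion: float = DEFAULT_CRITERION,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile CI for the dilution threshold.

    Simulates binomial responses from the fitted performance function at
    the observed levels and trial counts, refits each replicate (Fisher
    scoring from the fitted values), and returns the percentile interval
    of the refitted thresholds.
    """
    if not fit.fittable:
        raise UnfittableError("cannot bootstrap an unfittable fit")
    rng = np.random.default_rng(seed)
    p = fit.params
    psi = eval_performance(data.intensity_pct, p)
    n = np.round(data.n_trials).astype(np.int64)
    hint = (p.alpha, p.beta)
    thresholds = np.empty(n_boot)
    for i in range(n_boot):
        k = rng.binomial(n, psi).astype(float)
        a, b, _, conv = _fisher_fit(
            data.intensity_pct, n.astype(float), k, p.gamma, p.lapse, hint
        )
        if not conv:
            a, b, _, _, _ = _ml_fit(
                data.intensity_pct, n.astype(float), k, p.gamma, p.lapse,
                start_hint=hint,
            )
        thresholds[i] = threshold_from_params(
            PsychometricParams(a, b, p.gamma, p.lapse), criterion
        )
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(thresholds, lo)),
        float(np.quantile(thresholds, 1.0 - lo)),
    )


def combine_binned(parts: Iterable[BinnedData]) -> BinnedData:
    """Merge several binned datasets, summing counts at shared levels."""
    d: dict[float, list[float]] = {}
    for part in parts:
        for lvl, n, k in zip(part.dilution_pct, part.n_trials, part.n_correct):
            acc = d.setdefault(float(lvl), [0.0, 0.0])
            acc[0] += n
            acc[1] += k
    levels = sorted(d)
    return BinnedData(
        np.array(levels),
        np.array([d[l][0] for l in levels]),
        np.array([d[l][1] for l in levels]),
    )
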