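"""Within-individual model comparison for two psychometric conditions.

Given one observer's binned 2IFC data in two conditions (e.g. happy and
fear morphs), the question is whether one psychometric function explains
both (null, "1PF") or each condition needs its own (alternative, "2PF").
Both models are fit by maximum likelihood with guess and lapse rates
fixed; the likelihood ratio LR = L(1PF) / L(2PF) <= 1 measures how much
worse the single function does.

Because the asymptotic chi-square reference is unreliable at psychophysical
sample sizes, the null distribution of LR is built by parametric bootstrap:
responses for both conditions are simulated from the fitted 1PF at the
observed levels and trial counts, both models are refit to each simulated
pair, and the p value is the fraction of simulated LRs strictly smaller
than the observed one (ties favour the null).  With B = 10,000 simulations,
fewer than 500 below the observed LR means p < .05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .psychometric import (
    DEFAULT_CRITERION,
    GUESS_2IFC,
    BinnedData,
    FitResult,
    PsychometricParams,
    _fisher_fit,
    _ml_fit,
    fit_pf,
    neg_log_likelihood,
)

__all__ = [
    "ConditionPair",
    "ModelComparisonResult",
    "InternalConsistencyError",
    "fit_1pf",
    "likelihood_ratio",
    "count_to_p",
    "pf_lr_test",
    "PsychometricLRTest",
]

_NESTING_TOL = 1e-9


class InternalConsistencyError(RuntimeError):
    """The constrained (1PF) fit beat the free (2PF) fit beyond tolerance."""


@dataclass(frozen=True)
class ConditionPair:
    """One observer's binned data in two conditions with distinct labels."""

    data_a: BinnedData
    data_b: BinnedData
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.labels[0] == self.labels[1]:
            raise ValueError(f"condition labels must be distinct, got {self.labels}")


@dataclass(frozen=True)
class ModelComparisonResult:
    """Outcome of the 1PF-vs-2PF parametric-bootstrap likelihood-ratio test."""

    fit_1pf: FitResult
    fits_2pf: tuple[FitResult, FitResult]
    lr: float
    tlr: float
    n_sims: int
    n_smaller: int
    p_value: float
    seed: int | None
    labels: tuple[str, str] = ("A", "B")
    n_redraws: int = 0

    def summary(self) -> str:
        p_txt = (
            f"p = {self.p_value:.4g}"
            if self.n_smaller > 0
            else f"p < {1.0 / self.n_sims:g}"
        )
        return (
            f"1PF vs 2PF ({self.labels[0]} / {self.labels[1]}): "
            f"LR = {self.lr:.4g}, TLR = {self.tlr:.4g}, "
            f"{self.n_smaller}/{self.n_sims} simulated LRs smaller, {p_txt}"
        )


def fit_1pf(
    pair: ConditionPair,
    gamma: float = GUESS_2IFC,
    lapse: float = 0.0,
    criterion: float = DEFAULT_CRITERION,
    n_starts: int = 7,
) -> FitResult:
    """Fit one shared (alpha, beta) to both conditions' data jointly.

    Maximises the summed binomial log-likelihood over both datasets with
    guess and lapse fixed.  The unfittable screening rule is applied to
    the pooled data: if observed performance never reaches the criterion
    anywhere, the result is flagged ``fittable=False``.
    """
    x = np.concatenate([pair.data_a.intensity_pct, pair.data_b.intensity_pct])
    n = np.concatenate([pair.data_a.n_trials, pair.data_b.n_trials])
    k = np.concatenate([pair.data_a.n_correct, pair.data_b.n_correct])
    reason = None
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    if np.count_nonzero(n > 0) < 2:
        reason = "fewer than 2 levels with trials"
    elif np.nanmax(props) < criterion:
        reason = f"observed performance never reaches the {criterion:.0%} criterion"
    alpha, beta, nll, converged, at_bound = _ml_fit(
        x, n, k, gamma, lapse, n_starts=n_starts
    )
    if reason is None and at_bound:
        reason = "optimizer terminated at a parameter bound"
    return FitResult(
        params=PsychometricParams(alpha=alpha, beta=beta, gamma=gamma, lapse=lapse),
        log_likelihood=-nll,
        free_mask=("alpha", "beta"),
        converged=converged,
        fittable=reason is None and converged,
        n_levels_used=int(np.count_nonzero(n > 0)),
        reason=reason,
    )


def likelihood_ratio(ll_1pf: float, ll_2pf: float) -> tuple[float, float]:
    """Likelihood ratio and its -2 log transform from the two fits.

    ``lr = exp(ll_1pf - ll_2pf)`` lies in (0, 1] by nesting;
    ``tlr = -2 (ll_1pf - ll_2pf) >= 0``.
    """
    if ll_1pf > ll_2pf + _NESTING_TOL:
        raise InternalConsistencyError(
            f"1PF log-likelihood {ll_1pf} exceeds 2PF {ll_2pf}; "
            "the free model must fit at least as well"
        )
    diff = min(ll_1pf - ll_2pf, 0.0)
    return float(np.exp(diff)), float(-2.0 * diff)


def count_to_p(n_smaller: int, n_sims: int) -> float:
    """Bootstrap p value ``n_smaller / n_sims`` (no continuity correction)."""
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if not 0 <= n_smaller <= n_sims:
        raise ValueError(
            f"n_smaller must lie in [0, n_sims] = [0, {n_sims}], got {n_smaller}"
        )
    return n_smaller / n_sims


def _fit_one(x, n, k, gamma, lapse, hint, fast, n_starts, rng):
    """One refit: fast Fisher scoring from the hint, or the multi-start path."""
    if fast:
        a, b, nll, conv = _fisher_fit(x, n, k, gamma, lapse, hint)
        if conv:
            return nll, True
    _, _, nll, conv, _ = _ml_fit(
        x, n, k, gamma, lapse, n_starts=n_starts, start_hint=hint, rng=rng
    )
    return nll, conv


def _joint_refit(xa, na, ka, xb, nb, kb, gamma, lapse, hint, fast=True,
                 n_starts=2, rng=None):
    """Refit 2PF and 1PF to one (possibly simulated) pair; return (ll2, ll1, ok)."""
    nlla, conv_a = _fit_one(xa, na, ka, gamma, lapse, hint, fast, n_starts, rng)
    nllb, conv_b = _fit_one(xb, nb, kb, gamma, lapse, hint, fast, n_starts, rng)
    x = np.concatenate([xa, xb])
    n = np.concatenate([na, nb])
    k = np.concatenate([ka, kb])
    nll1, conv_1 = _fit_one(x, n, k, gamma, lapse, hint, fast, n_starts, rng)
    ll2 = -(nlla + nllb)
    ll1 = -nll1
    ok = conv_a and conv_b and conv_1 and ll1 <= ll2 + _NESTING_TOL
    return ll2, ll1, ok


def pf_lr_test(
    pair: ConditionPair,
    n_sims: int = 10_000,
    seed: int | None = None,
    gamma: float = GUESS_2IFC,
    lapse: float = 0.0,
    n_starts: int = 7,
) -> ModelComparisonResult:
    """Parametric-bootstrap likelihood-ratio test between two conditions.

    1. Fit 2PF (separate functions) and 1PF (shared function) to the
       observed pair and compute the observed LR.
    2. ``n_sims`` times: simulate both conditions as binomial draws from
       the 1PF performance function at each condition's observed levels
       and trial counts; refit both models to the simulated pair with the
       same fixed guess and lapse; record the simulated LR.
    3. ``n_smaller`` counts simulated LRs *strictly* below the observed
       LR; ``p = n_smaller / n_sims``.

    A simulated replicate whose refit fails (non-convergence or a nesting
    violation) is retried with extra jittered starts; after three failures
    the dataset is redrawn.  More than 1 % redraws triggers a warning.
    Deterministic for a fixed seed.
    """
    fit_a = fit_pf(pair.data_a, gamma=gamma, lapse=lapse, n_starts=n_starts)
    fit_b = fit_pf(pair.data_b, gamma=gamma, lapse=lapse, n_starts=n_starts)
    if not (fit_a.fittable and fit_b.fittable):
        bad = pair.labels[0] if not fit_a.fittable else pair.labels[1]
        reason = fit_a.reason if not fit_a.fittable else fit_b.reason
        raise ValueError(
            f"condition {bad!r} is unfittable ({reason}); "
            "the model comparison requires both 2PF fits"
        )
    null_fit = fit_1pf(pair, gamma=gamma, lapse=lapse, n_starts=n_starts)
    ll2 = fit_a.log_likelihood + fit_b.log_likelihood
    ll1 = null_fit.log_likelihood
    if ll1 > ll2 + _NESTING_TOL:
        # optimisation noise: retry the free fits with a larger start grid
        fit_a = fit_pf(pair.data_a, gamma=gamma, lapse=lapse, n_starts=16)
        fit_b = fit_pf(pair.data_b, gamma=gamma, lapse=lapse, n_starts=16)
        ll2 = fit_a.log_likelihood + fit_b.log_likelihood
    lr_obs, tlr_obs = likelihood_ratio(ll1, ll2)

    rng = np.random.default_rng(seed)
    xa, xb = pair.data_a.intensity_pct, pair.data_b.intensity_pct
    na = np.round(pair.data_a.n_trials).astype(np.int64)
    nb = np.round(pair.data_b.n_trials).astype(np.int64)
    psi_a = _performance(xa, null_fit.params)
    psi_b = _performance(xb, null_fit.params)
    hint = (null_fit.params.alpha, null_fit.params.beta)

    n_smaller = 0
    n_redraws = 0
    done = 0
    while done < n_sims:
        ka = rng.binomial(na, psi_a).astype(float)
        kb = rng.binomial(nb, psi_b).astype(float)
        ok = False
        for attempt in range(3):
            ll2_s, ll1_s, ok = _joint_refit(
                xa, na.astype(float), ka, xb, nb.astype(float), kb,
                gamma, lapse, hint,
                fast=attempt == 0,
                n_starts=4 if attempt == 1 else 10,
                rng=None if attempt == 0 else rng,
            )
            if ok:
                break
        if not ok:
            n_redraws += 1
            continue
        lr_sim = float(np.exp(min(ll1_s - ll2_s, 0.0)))
        if lr_sim < lr_obs:
            n_smaller += 1
        done += 1
    if n_redraws > 0.01 * n_sims:
        warnings.warn(
            f"{n_redraws} of {n_sims} bootstrap replicates were redrawn after "
            "repeated refit failures",
            RuntimeWarning,
            stacklevel=2,
        )
    return ModelComparisonResult(
        fit_1pf=null_fit,
        fits_2pf=(fit_a, fit_b),
        lr=lr_obs,
        tlr=tlr_obs,
        n_sims=n_sims,
        n_smaller=n_smaller,
        p_value=count_to_p(n_smaller, n_sims),
        seed=seed,
        labels=pair.labels,
        n_redraws=n_redraws,
    )


def _performance(x, params: PsychometricParams):
    f = 1.0 / (1.0 + np.exp(-params.beta * (x - params.alpha)))
    return params.gamma + (1.0 - params.gamma - params.lapse) * f


class PsychometricLRTest(BaseEstimator):
    """Fit-shaped interface to :func:`pf_lr_test`.

    Parameters mirror the function; ``fit`` accepts the two conditions'
    :class:`~morphsense.psychometric.BinnedData` (paired-data signature).

    Attributes
    ----------
    result_ : ModelComparisonResult
    p_value_, lr_, tlr_ : float
    n_smaller_ : int
    """

    def __init__(
        self,
        n_sims: int = 10_000,
        random_state: int | None = None,
        guess: float = GUESS_2IFC,
        lapse: float = 0.0,
        n_starts: int = 7,
    ):
        self.n_sims = n_sims
        self.random_state = random_state
        self.guess = guess
        self.lapse = lapse
        self.n_starts = n_starts

    def fit(self, data_a: BinnedData, data_b: BinnedData, labels=("A", "B")):
        pair = ConditionPair(data_a, data_b, tuple(labels))
        self.result_ = pf_lr_test(
            pair,
            n_sims=self.n_sims,
            seed=self.random_state,
            gamma=self.guess,
            lapse=self.lapse,
            n_starts=self.n_starts,
        )
        self.p_value_ = self.result_.p_value
        self.lr_ = self.result_.lr
        self.tlr_ = self.result_.tlr
        self.n_smaller_ = self.result_.n_smaller
        return self
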