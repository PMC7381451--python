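"""End-to-end analysis of a trial table.

Reproduces the full measurement pipeline for a study: bin trials per
participant/condition (optionally per unique face or session), fit each
unit's psychometric function, extract 75 %-correct dilution thresholds,
run the within-individual bootstrap model comparison between the two
conditions (and between sessions when a retest exists), and aggregate a
group report: threshold means +/- SEM, a group curve of predicted percent
correct at a fixed dilution set, and a paired t test with effect size r.

The group curve follows the fixed-dilution convention: each participant's
*fitted* performance function is evaluated at the shared dilution set
(68, 80, 86, 90, 94, 96, 98) so that observers measured on tailored,
individually different ladders can be averaged on a common axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import ConditionPair, ModelComparisonResult, pf_lr_test
from .psychometric import (
    DEFAULT_CRITERION,
    GUESS_2IFC,
    BinnedData,
    FitResult,
    fit_pf,
    predict_percent_correct,
    threshold_dilution,
)
from .simulate import FIXED_DILUTIONS, TrialRecord

__all__ = [
    "AnalysisSettings",
    "ParticipantReport",
    "GroupReport",
    "StudyReport",
    "PairedTestResult",
    "bin_trials",
    "analyze_participant",
    "analyze_study",
    "group_curve",
    "paired_threshold_test",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """Knobs of the analysis pipeline.

    ``compare`` names the two conditions entering the individual-level
    test (default: the first two in order of appearance).  ``per_face``
    toggles per-unique-face fits; by default they run whenever every
    (condition, face) unit has at least ``per_face_min_trials`` trials per
    level, i.e. the 240-observation sub-design.
    """

    guess: float = GUESS_2IFC
    lapse: float = 0.0
    criterion: float = DEFAULT_CRITERION
    n_sims: int = 10_000
    seed: int | None = None
    compare: tuple[str, str] | None = None
    per_face: bool | None = None
    per_face_min_trials: int = 40
    n_starts: int = 7


@dataclass(frozen=True)
class PairedTestResult:
    """Paired-samples t test with the r effect size, df = n - 1."""

    t: float
    df: int
    p: float
    r: float
    n: int


@dataclass
class ParticipantReport:
    participant_id: str
    condition_fits: dict[str, FitResult] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    comparison: ModelComparisonResult | None = None
    comparison_skipped: str | None = None
    face_fits: dict[tuple[str, str], FitResult] = field(default_factory=dict)
    face_thresholds: dict[tuple[str, str], float] = field(default_factory=dict)
    session_comparisons: dict[str, ModelComparisonResult] = field(default_factory=dict)
    unfittable: dict[str, str] = field(default_factory=dict)


@dataclass
class GroupReport:
    thresholds: pd.DataFrame  # participants x conditions, dilution scale
    means: dict[str, float]
    sems: dict[str, float]
    curve: pd.DataFrame  # condition, dilution_pct, mean_pct, sem_pct, n
    paired: PairedTestResult | None
    excluded: dict[str, str]


@dataclass
class StudyReport:
    participants: list[ParticipantReport]
    group: GroupReport

    def summary(self) -> str:
        return report_text(self)


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .io import records_to_frame

    return records_to_frame(list(trials))


def bin_trials(
    trials: pd.DataFrame | Sequence[TrialRecord],
    by: Sequence[str] = ("participant_id", "condition"),
) -> dict[tuple, BinnedData]:
    """Bin trials into per-dilution counts for each grouping key.

    ``by`` may be any subset of the table's identifying columns; counts
    partition the input exactly.  Empty input yields an empty mapping.
    """
    df = _as_frame(trials)
    if len(df) == 0:
        return {}
    by = list(by)
    out: dict[tuple, BinnedData] = {}
    agg = (
        df.groupby(by + ["dilution_pct"], sort=True, observed=True)["correct"]
        .agg(["count", "sum"])
        .reset_index()
    )
    group_key = by[0] if len(by) == 1 else by
    for key, sub in agg.groupby(group_key, sort=False):
        key_t = key if isinstance(key, tuple) else (key,)
        out[key_t] = BinnedData(
            sub["dilution_pct"].to_numpy(dtype=float),
            sub["count"].to_numpy(dtype=float),
            sub["sum"].to_numpy(dtype=float),
        )
    return out


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def analyze_participant(
    trials: pd.DataFrame | Sequence[TrialRecord],
    settings: AnalysisSettings = AnalysisSettings(),
) -> ParticipantReport:
    """Full individual-level analysis for one participant's trials.

    Fits each condition (pooled over faces and sessions), extracts
    thresholds, runs the bootstrap model comparison between the two
    conditions of interest, optionally fits each condition x face unit,
    and, when exactly two sessions exist, tests session 1 vs session 2
    within each condition.  Unfittable units are flagged with a reason
    rather than raising.
    """
    df = _as_frame(trials)
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected trials from one participant, got {list(pids)}")
    conditions = list(dict.fromkeys(df["condition"]))
    if len(conditions) < 2:
        raise ValueError("participant-level analysis needs at least 2 conditions")
    report = ParticipantReport(participant_id=str(pids[0]))
    rng = np.random.default_rng(settings.seed)

    binned = bin_trials(df, by=["condition"])
    for cond in conditions:
        fit = fit_pf(
            binned[(cond,)],
            gamma=settings.guess,
            lapse=settings.lapse,
            criterion=settings.criterion,
            n_starts=settings.n_starts,
        )
        report.condition_fits[cond] = fit
        if fit.fittable:
            report.thresholds[cond] = threshold_dilution(fit, settings.criterion)
        else:
            report.unfittable[cond] = fit.reason or "unfittable"

    pair_labels = settings.compare or (conditions[0], conditions[1])
    comp_seed = _derive_seed(rng)
    if all((c,) in binned for c in pair_labels) and all(
        report.condition_fits[c].fittable for c in pair_labels
    ):
        report.comparison = pf_lr_test(
            ConditionPair(
                binned[(pair_labels[0],)], binned[(pair_labels[1],)], tuple(pair_labels)
            ),
            n_sims=settings.n_sims,
            seed=comp_seed,
            gamma=settings.guess,
            lapse=settings.lapse,
            n_starts=settings.n_starts,
        )
    else:
        bad = [c for c in pair_labels if not report.condition_fits.get(c, None) or not report.condition_fits[c].fittable]
        report.comparison_skipped = (
            f"condition(s) {bad} unfittable; model comparison skipped"
        )

    # per-unique-face fits, when the sub-design is rich enough
    face_binned = bin_trials(df, by=["condition", "face_id"])
    min_per_level = min(
        (float(b.n_trials.min()) for b in face_binned.values()), default=0.0
    )
    run_faces = (
        settings.per_face
        if settings.per_face is not None
        else min_per_level >= settings.per_face_min_trials
    )
    if run_faces:
        for (cond, face), data in face_binned.items():
            fit = fit_pf(
                data,
                gamma=settings.guess,
                lapse=settings.lapse,
                criterion=settings.criterion,
                n_starts=settings.n_starts,
            )
            report.face_fits[(cond, face)] = fit
            if fit.fittable:
                report.face_thresholds[(cond, face)] = threshold_dilution(
                    fit, settings.criterion
                )
            else:
                report.unfittable[f"{cond}/{face}"] = fit.reason or "unfittable"

    # test-retest: compare the two sessions within each condition
    sessions = list(dict.fromkeys(df["session_id"]))
    if len(sessions) == 2:
        sess_binned = bin_trials(df, by=["condition", "session_id"])
        for cond in conditions:
            key_a, key_b = (cond, sessions[0]), (cond, sessions[1])
            if key_a not in sess_binned or key_b not in sess_binned:
                continue
            fits_ok = all(
                fit_pf(sess_binned[k], gamma=settings.guess, lapse=settings.lapse).fittable
                for k in (key_a, key_b)
            )
            sess_seed = _derive_seed(rng)
            if not fits_ok:
                report.unfittable[f"{cond}/retest"] = "a session fit is unfittable"
                continue
            report.session_comparisons[cond] = pf_lr_test(
                ConditionPair(
                    sess_binned[key_a],
                    sess_binned[key_b],
                    (f"{sessions[0]}", f"{sessions[1]}"),
                ),
                n_sims=settings.n_sims,
                seed=sess_seed,
                gamma=settings.guess,
                lapse=settings.lapse,
                n_starts=settings.n_starts,
            )
    return report


def group_curve(
    fits: Mapping[str, FitResult],
    dilutions: Sequence[float] = FIXED_DILUTIONS,
) -> pd.DataFrame:
    """Across-participant mean +/- SEM of predicted percent correct.

    Each fittable participant's fitted performance function is evaluated
    at the shared dilution set; unfittable fits are excluded.  SEM is the
    sample SD (ddof=1) over sqrt(n); 0 when n = 1.
    """
    usable = {pid: f for pid, f in fits.items() if f.fittable}
    if not usable:
        raise ValueError("group curve needs at least one fittable fit")
    d = np.asarray(dilutions, dtype=float)
    preds = np.vstack(
        [predict_percent_correct(d, f.params) for f in usable.values()]
    )
    n = preds.shape[0]
    sem = preds.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(d.size)
    return pd.DataFrame(
        {
            "dilution_pct": d,
            "mean_pct": preds.mean(axis=0),
            "sem_pct": sem,
            "n": n,
        }
    )


def paired_threshold_test(
    thresholds_a: Sequence[float], thresholds_b: Sequence[float]
) -> PairedTestResult:
    """Paired-samples t test on per-participant thresholds, with effect size.

    df = n - 1; two-sided p; r = sqrt(t^2 / (t^2 + df)).
    """
    a = np.asarray(thresholds_a, dtype=float)
    b = np.asarray(thresholds_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError(f"paired test needs n >= 2, got n = {a.size}")
    df = a.size - 1
    diff = a - b
    if float(diff.std(ddof=1)) == 0.0:
        # zero-variance differences: t is 0/0; define the null-difference case
        t = 0.0 if float(diff.mean()) == 0.0 else math.copysign(math.inf, diff.mean())
        p = 1.0 if t == 0.0 else 0.0
        r = 0.0 if t == 0.0 else 1.0
        return PairedTestResult(t=t, df=df, p=p, r=r, n=a.size)
    res = stats.ttest_rel(a, b)
    t = float(res.statistic)
    r = math.sqrt(t * t / (t * t + df))
    return PairedTestResult(t=t, df=df, p=float(res.pvalue), r=r, n=a.size)


def analyze_study(
    trials: pd.DataFrame | Sequence[TrialRecord],
    settings: AnalysisSettings = AnalysisSettings(),
    dilutions: Sequence[float] = FIXED_DILUTIONS,
) -> StudyReport:
    """Per-participant analyses plus the group aggregate.

    Participants whose fits fail in either compared condition are excluded
    from the paired test and the group curve, with reasons enumerated in
    ``group.excluded``.
    """
    df = _as_frame(trials)
    participants = list(dict.fromkeys(df["participant_id"]))
    rng = np.random.default_rng(settings.seed)
    reports: list[ParticipantReport] = []
    for pid in participants:
        sub = df[df["participant_id"] == pid]
        p_settings = AnalysisSettings(
            **{**settings.__dict__, "seed": _derive_seed(rng)}
        )
        reports.append(analyze_participant(sub, p_settings))

    conditions = list(dict.fromkeys(df["condition"]))
    pair_labels = settings.compare or (conditions[0], conditions[1])
    rows = {}
    excluded: dict[str, str] = {}
    for rep in reports:
        if all(c in rep.thresholds for c in pair_labels):
            rows[rep.participant_id] = {c: rep.thresholds[c] for c in pair_labels}
        else:
            bad = [c for c in pair_labels if c not in rep.thresholds]
            excluded[rep.participant_id] = (
                f"unfittable in {', '.join(bad)}: "
                + "; ".join(rep.unfittable.get(c, "?") for c in bad)
            )
    thr = pd.DataFrame.from_dict(rows, orient="index")
    means = {c: float(thr[c].mean()) for c in thr.columns} if len(thr) else {}
    sems = (
        {c: float(thr[c].std(ddof=1) / math.sqrt(len(thr))) for c in thr.columns}
        if len(thr) > 1
        else {c: 0.0 for c in thr.columns}
    )
    curves = []
    for cond in pair_labels:
        fits = {
            rep.participant_id: rep.condition_fits[cond]
            for rep in reports
            if rep.participant_id in rows and cond in rep.condition_fits
        }
        if fits:
            c = group_curve(fits, dilutions)
            c.insert(0, "condition", cond)
            curves.append(c)
    curve = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    paired = (
        paired_threshold_test(thr[pair_labels[0]], thr[pair_labels[1]])
        if len(thr) >= 2
        else None
    )
    group = GroupReport(
        thresholds=thr, means=means, sems=sems, curve=curve, paired=paired,
        excluded=excluded,
    )
    return StudyReport(participants=reports, group=group)


def report_text(study: StudyReport) -> str:
    """Human-readable summary of a study report."""
    lines = []
    g = study.group
    lines.append(f"Participants analysed: {len(study.participants)}")
    if g.excluded:
        lines.append("Excluded from group statistics:")
        for pid, why in g.excluded.items():
            lines.append(f"  {pid}: {why}")
    for cond in g.means:
        lines.append(
            f"Group threshold [{cond}]: M = {g.means[cond]:.1f} % dilution "
            f"(SE = {g.sems[cond]:.2f}, n = {len(g.thresholds)})"
        )
    if g.paired is not None:
        p = g.paired
        lines.append(
            f"Paired t test: t({p.df}) = {p.t:.2f}, p = {p.p:.2g}, r = {p.r:.2f}"
        )
    for rep in study.participants:
        lines.append(f"-- {rep.participant_id}")
        for cond, fit in rep.condition_fits.items():
            if fit.fittable:
                lines.append(
                    f"   {cond}: threshold = {rep.thresholds[cond]:.1f} % dilution, "
                    f"slope = {fit.params.beta:.3f}"
                )
            else:
                lines.append(f"   {cond}: unfittable ({fit.reason})")
        if rep.comparison is not None:
            lines.append(f"   {rep.comparison.summary()}")
        elif rep.comparison_skipped:
            lines.append(f"   {rep.comparison_skipped}")
        for cond, comp in rep.session_comparisons.items():
            lines.append(f"   retest [{cond}]: {comp.summary()}")
    return "\n".join(lines) + "\n"
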