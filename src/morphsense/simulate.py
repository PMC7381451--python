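"""Synthetic 2IFC observers and method-of-constant-stimuli schedules.

No behavioural data ship with this package, so every analysis is exercised
against simulated observers whose responses are Bernoulli draws from a
known guess-0.5 logistic performance function of morph dilution.  The
default study design mirrors the measurement protocol the package targets:
seven dilution levels, six unique face identities, 40 repeats per face per
level (240 observations per level), trials organised as complete shuffled
passes over the level x face set, and the test stimulus appearing in the
first interval with probability 0.5.

``make_synthetic_study`` ships named presets emulating the canonical
experiments: a main group study (``exp1``: 11 observers, happy + fear,
generating thresholds centred on dilution 92 and 86), a two-session
test-retest variant, a per-face-heterogeneity variant, duration / image
size metadata variants, and a second-morphing-software replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .psychometric import PsychometricParams

__all__ = [
    "FIXED_DILUTIONS",
    "DEFAULT_FACES",
    "DILUTION_LADDERS",
    "ScheduleSpec",
    "ObserverSpec",
    "TrialSlot",
    "TrialRecord",
    "generate_schedule",
    "simulate_observer",
    "make_synthetic_study",
    "preset_config",
    "tailored_levels",
    "STUDY_PRESETS",
]

#: Fixed dilution set used for the group curve (and the default schedule).
FIXED_DILUTIONS = (68.0, 80.0, 86.0, 90.0, 94.0, 96.0, 98.0)

#: Six unique face identities: three female, three male.
DEFAULT_FACES = ("FF1", "FF2", "FF3", "MF1", "MF2", "MF3")

#: Available morph ladders: every dilution the two morphing pipelines render.
DILUTION_LADDERS = {
    "norrkross": tuple(float(v) for v in range(2, 99, 2)),
    "psychomorph": tuple(float(v) for v in range(1, 100)),
}


@dataclass(frozen=True)
class ScheduleSpec:
    """Design of one condition's method-of-constant-stimuli run."""

    dilution_levels: tuple[float, ...] = FIXED_DILUTIONS
    face_ids: tuple[str, ...] = DEFAULT_FACES
    repeats_per_face: int = 40
    condition_label: str = "happy"
    test_first_prob: float = 0.5
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.dilution_levels)
        if len(levels) == 0 or len(self.face_ids) == 0:
            raise ValueError("dilution_levels and face_ids must be non-empty")
        if len(set(levels)) != len(levels):
            raise ValueError("dilution levels must be distinct")
        if any(not 0.0 <= v <= 100.0 for v in levels):
            raise ValueError("dilution levels must lie in [0, 100]")
        if self.repeats_per_face < 1:
            raise ValueError("repeats_per_face must be >= 1")
        if self.test_first_prob != 0.5:
            raise ValueError("the test stimulus must be equally likely in either interval")
        object.__setattr__(self, "dilution_levels", levels)
        object.__setattr__(self, "face_ids", tuple(self.face_ids))

    @property
    def n_trials(self) -> int:
        return len(self.dilution_levels) * len(self.face_ids) * self.repeats_per_face


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled presentation before the observer responds."""

    face_id: str
    dilution_pct: float
    test_interval: int  # 1 or 2


@dataclass(frozen=True)
class ObserverSpec:
    """Generating truth for a synthetic observer.

    ``params`` maps condition label to the true performance parameters.
    ``face_offsets`` shift the threshold per unique face, in dilution
    points (positive = more sensitive to that face); they must average to
    ~zero so the pooled function stays centred.  ``session_shift`` moves
    the threshold by that many dilution points per session beyond the
    first (0 = perfectly stable observer).
    """

    params: Mapping[str, PsychometricParams]
    face_offsets: Mapping[str, float] = field(default_factory=dict)
    session_shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.params:
            raise ValueError("observer must define parameters for at least one condition")
        if self.face_offsets:
            mean_off = float(np.mean(list(self.face_offsets.values())))
            if abs(mean_off) > 1e-6:
                raise ValueError(
                    f"face offsets must average to ~0, got mean {mean_off:g}"
                )

    def condition_params(
        self, condition: str, face_id: str | None = None, session_index: int = 0
    ) -> PsychometricParams:
        """Effective parameters for one condition/face/session combination."""
        try:
            base = self.params[condition]
        except KeyError:
            raise KeyError(
                f"observer defines no parameters for condition {condition!r}"
            ) from None
        shift_dil = self.face_offsets.get(face_id, 0.0) + self.session_shift * session_index
        # a +1 dilution-point shift in threshold is a -1 shift of alpha (intensity)
        if shift_dil == 0.0:
            return base
        return PsychometricParams(
            alpha=base.alpha - shift_dil,
            beta=base.beta,
            gamma=base.gamma,
            lapse=base.lapse,
        )


@dataclass(frozen=True)
class TrialRecord:
    """One completed 2IFC trial."""

    participant_id: str
    session_id: str
    condition: str
    face_id: str
    dilution_pct: float
    test_interval: int
    response_interval: int
    correct: bool
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test_interval not in (1, 2) or self.response_interval not in (1, 2):
            raise ValueError("intervals must be 1 or 2")
        if self.correct != (self.response_interval == self.test_interval):
            raise ValueError("correct flag contradicts the interval columns")


def generate_schedule(spec: ScheduleSpec, seed: int | None = None) -> list[TrialSlot]:
    """Build the randomised trial order for one condition.

    Trials are organised as ``repeats_per_face`` complete shuffled passes
    over the level x face set, so every (level, face) pair appears exactly
    once per pass — no pair is shown an (n+1)-th time before the whole set
    has been shown n times.  The test interval is an independent fair coin
    per trial.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pairs = [
        (lvl, face) for lvl in spec.dilution_levels for face in spec.face_ids
    ]
    slots: list[TrialSlot] = []
    coins = rng.random(spec.n_trials) < spec.test_first_prob
    i = 0
    for _ in range(spec.repeats_per_face):
        for idx in rng.permutation(len(pairs)):
            lvl, face = pairs[idx]
            slots.append(
                TrialSlot(
                    face_id=face,
                    dilution_pct=lvl,
                    test_interval=1 if coins[i] else 2,
                )
            )
            i += 1
    return slots


def simulate_observer(
    schedule: Sequence[TrialSlot],
    observer: ObserverSpec,
    seed: int | None = None,
    condition: str | None = None,
    participant_id: str = "P01",
    session_id: str = "S1",
    session_index: int = 0,
    metadata: Mapping[str, Any] | None = None,
) -> list[TrialRecord]:
    """Run a synthetic observer through a schedule.

    Each trial is correct with probability ψ(dilution) under the
    observer's (face- and session-adjusted) parameters; the response
    interval equals the test interval on correct trials and the other
    interval otherwise.  At dilution 100 the test and comparison stimuli
    are identical, so the trial is a pure guess: p(correct) is exactly the
    2IFC chance level 0.5, whatever the fitted curve would extrapolate.
    Deterministic for a fixed seed.
    """
    if condition is None:
        if len(observer.params) != 1:
            raise ValueError(
                "condition must be given when the observer defines several conditions"
            )
        condition = next(iter(observer.params))
    rng = np.random.default_rng(seed)
    u = rng.random(len(schedule))
    records: list[TrialRecord] = []
    meta = dict(metadata or {})
    for slot, ui in zip(schedule, u):
        p = observer.condition_params(condition, slot.face_id, session_index)
        if slot.dilution_pct >= 100.0:
            psi = 0.5
        else:
            x = 100.0 - slot.dilution_pct
            f = float(expit(p.beta * (x - p.alpha)))
            psi = p.gamma + (1.0 - p.gamma - p.lapse) * f
        correct = bool(ui < psi)
        response = slot.test_interval if correct else 3 - slot.test_interval
        records.append(
            TrialRecord(
                participant_id=participant_id,
                session_id=session_id,
                condition=condition,
                face_id=slot.face_id,
                dilution_pct=slot.dilution_pct,
                test_interval=slot.test_interval,
                response_interval=response,
                correct=correct,
                metadata=meta,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

#: Offsets (dilution points, relative to the rounded true threshold) of the
#: seven tailored levels; even values so they sit on the 2 %-step ladder.
_TAILOR_OFFSETS = (-12, -8, -4, 0, 2, 4, 6)


def tailored_levels(
    threshold_dilution: float, step: float = 2.0, lo: float = 2.0, hi: float = 98.0
) -> tuple[float, ...]:
    """Seven ladder dilutions spanning an observer's threshold.

    Mimics tailoring the presented dilutions to the individual so that
    performance runs from near-ceiling to near-chance across the set: four
    levels at or below the threshold dilution (easier) and three above
    (harder), snapped to the morph ladder and shifted as a block to stay
    within [lo, hi].
    """
    base = round(threshold_dilution / step) * step
    levels = np.array([base + o for o in _TAILOR_OFFSETS], dtype=float)
    if levels[-1] > hi:
        levels -= levels[-1] - hi
    if levels[0] < lo:
        levels += lo - levels[0]
    levels = np.clip(levels, lo, hi)
    if np.unique(levels).size != levels.size:
        raise ValueError(
            f"cannot place 7 distinct levels in [{lo}, {hi}] with step {step}"
        )
    return tuple(float(v) for v in levels)


# Group-level generating truths: threshold means and standard errors on the
# dilution scale, slope per percent intensity.  The between-subject SD is
# SE * sqrt(n).
_EXP1 = {
    "n": 11,
    "happy": {"mean": 92.0, "se": 0.57},
    "fear": {"mean": 86.0, "se": 1.23},
    "beta": 0.3,
}
_EXP5 = {
    "n": 9,
    "happy": {"mean": 93.0, "se": 0.91},
    "fear": {"mean": 86.0, "se": 1.21},
    "beta": 0.3,
}


def _condition_block(mean, se, n, beta=0.3):
    return {"threshold_mean": mean, "threshold_sd": se * float(np.sqrt(n)), "beta": beta}


def preset_config(name: str) -> dict:
    """Return the study configuration dict for a named preset."""
    base = {
        "participants": _EXP1["n"],
        "sessions": 1,
        "conditions": {
            "happy": _condition_block(**{"mean": _EXP1["happy"]["mean"], "se": _EXP1["happy"]["se"], "n": _EXP1["n"]}),
            "fear": _condition_block(**{"mean": _EXP1["fear"]["mean"], "se": _EXP1["fear"]["se"], "n": _EXP1["n"]}),
        },
        "repeats_per_face": 40,
        "face_ids": list(DEFAULT_FACES),
        "levels": "tailored",
        "ladder_step": 2.0,
        "face_offset_sd": 0.0,
        "session_shift": 0.0,
        "metadata": {"duration_ms": 200, "image_size_deg": "19x27", "software": "norrkross"},
        "variants": None,
    }
    if name == "exp1":
        return base
    if name == "retest":
        cfg = dict(base)
        cfg["participants"] = 3
        cfg["sessions"] = 2
        return cfg
    if name == "faces":
        cfg = dict(base)
        cfg["participants"] = 6
        cfg["face_offset_sd"] = 2.0
        return cfg
    if name == "durations":
        cfg = dict(base)
        cfg["participants"] = 3
        cfg["variants"] = [
            {"metadata": {"duration_ms": 8}, "threshold_shift": -3.0},
            {"metadata": {"duration_ms": 83}, "threshold_shift": -1.0},
            {"metadata": {"duration_ms": 200}, "threshold_shift": 0.0},
        ]
        return cfg
    if name == "sizes":
        cfg = dict(base)
        cfg["participants"] = 3
        cfg["variants"] = [
            {"metadata": {"image_size_deg": "19x27"}, "threshold_shift": 0.0},
            {"metadata": {"image_size_deg": "5x7"}, "threshold_shift": -2.0},
            {"metadata": {"image_size_deg": "2.5x3.5"}, "threshold_shift": -3.0},
        ]
        return cfg
    if name == "software":
        cfg = dict(base)
        cfg["participants"] = _EXP5["n"]
        cfg["conditions"] = {
            "happy": _condition_block(_EXP5["happy"]["mean"], _EXP5["happy"]["se"], _EXP5["n"]),
            "fear": _condition_block(_EXP5["fear"]["mean"], _EXP5["fear"]["se"], _EXP5["n"]),
        }
        cfg["ladder_step"] = 1.0
        cfg["metadata"] = {"duration_ms": 200, "image_size_deg": "17.6x24.5", "software": "psychomorph"}
        return cfg
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(STUDY_PRESETS)}")


STUDY_PRESETS = ("exp1", "retest", "faces", "durations", "sizes", "software")


def _validate_config(config: Mapping[str, Any]) -> dict:
    cfg = dict(config)
    if not isinstance(cfg.get("participants"), int) or cfg["participants"] < 1:
        raise ValueError("config.participants must be a positive integer")
    conds = cfg.get("conditions")
    if not isinstance(conds, Mapping) or not conds:
        raise ValueError("config.conditions must be a non-empty mapping")
    for label, spec in conds.items():
        for key in ("threshold_mean", "threshold_sd", "beta"):
            if key not in spec:
                raise ValueError(f"config.conditions.{label}.{key} is missing")
            if not np.isfinite(spec[key]):
                raise ValueError(f"config.conditions.{label}.{key} must be finite")
        if spec["beta"] <= 0:
            raise ValueError(f"config.conditions.{label}.beta must be > 0")
        if spec["threshold_sd"] < 0:
            raise ValueError(f"config.conditions.{label}.threshold_sd must be >= 0")
    cfg.setdefault("sessions", 1)
    cfg.setdefault("repeats_per_face", 40)
    cfg.setdefault("face_ids", list(DEFAULT_FACES))
    cfg.setdefault("levels", "tailored")
    cfg.setdefault("ladder_step", 2.0)
    cfg.setdefault("face_offset_sd", 0.0)
    cfg.setdefault("session_shift", 0.0)
    cfg.setdefault("metadata", {})
    if cfg.get("variants") is None:
        cfg["variants"] = [{"metadata": dict(cfg["metadata"]), "threshold_shift": 0.0}]
    if cfg["sessions"] < 1:
        raise ValueError("config.sessions must be >= 1")
    return cfg


def make_synthetic_study(
    config: Mapping[str, Any] | str, seed: int | None = None
) -> list[TrialRecord]:
    """Generate a full synthetic study as a flat list of trial records.

    ``config`` is either a preset name (see :data:`STUDY_PRESETS`) or a
    mapping with the same shape as :func:`preset_config` returns.  Each
    participant gets their own RNG stream derived from ``seed`` and their
    index, so adding participants never perturbs existing ones.  True
    thresholds are drawn per participant and condition from a normal
    distribution with the configured mean and between-subject SD; the
    presented levels are tailored per participant around the drawn truth
    unless an explicit level list is configured.
    """
    if isinstance(config, str):
        config = preset_config(config)
    cfg = _validate_config(config)
    records: list[TrialRecord] = []
    faces = tuple(cfg["face_ids"])
    for p_idx in range(cfg["participants"]):
        pid = f"P{p_idx + 1:02d}"
        rng = np.random.default_rng([0 if seed is None else seed, p_idx])
        # generating truths for this participant
        true_thresholds = {
            label: float(
                rng.normal(spec["threshold_mean"], spec["threshold_sd"])
            )
            for label, spec in cfg["conditions"].items()
        }
        if cfg["face_offset_sd"] > 0:
            raw = rng.normal(0.0, cfg["face_offset_sd"], size=len(faces))
            raw -= raw.mean()
            face_offsets = dict(zip(faces, raw.tolist()))
        else:
            face_offsets = {}
        for s_idx in range(cfg["sessions"]):
            sid = f"S{s_idx + 1}"
            for variant in cfg["variants"]:
                v_meta = dict(cfg["metadata"])
                v_meta.update(variant.get("metadata", {}))
                v_shift = float(variant.get("threshold_shift", 0.0))
                for label, spec in cfg["conditions"].items():
                    thr = true_thresholds[label] + v_shift
                    params = PsychometricParams(
                        alpha=100.0 - thr, beta=float(spec["beta"])
                    )
                    observer = ObserverSpec(
                        params={label: params},
                        face_offsets=face_offsets,
                        session_shift=cfg["session_shift"],
                    )
                    if cfg["levels"] == "tailored":
                        levels = tailored_levels(thr, step=float(cfg["ladder_step"]))
                    else:
                        levels = tuple(float(v) for v in cfg["levels"])
                    sched_spec = ScheduleSpec(
                        dilution_levels=levels,
                        face_ids=faces,
                        repeats_per_face=int(cfg["repeats_per_face"]),
                        condition_label=label,
                        metadata=v_meta,
                    )
                    sched_seed = int(rng.integers(0, 2**31 - 1))
                    sim_seed = int(rng.integers(0, 2**31 - 1))
                    schedule = generate_schedule(sched_spec, seed=sched_seed)
                    records.extend(
                        simulate_observer(
                            schedule,
                            observer,
                            seed=sim_seed,
                            condition=label,
                            participant_id=pid,
                            session_id=sid,
                            session_index=s_idx,
                            metadata=v_meta,
                        )
                    )
    return records
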