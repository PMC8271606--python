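"""Stochastic per-fly scheduling model of circadian eclosion gating.

Adult emergence (eclosion) in *Drosophila* is restricted by the circadian
clock to recurring permitted windows ("gates").  Two mechanisms can produce
a gated population record:

``developmental``
    The clock sets the time at which each animal *initiates* the final steps
    of metamorphosis (head roughening), so that metamorphosis completes
    inside an open gate; the animal emerges the moment it is ready.

``permissive``
    Development free-runs; animals that complete metamorphosis while the
    gate is closed are held back and emerge at the next gate opening.

``arrhythmic``
    No functional clock: emergence follows completion directly, at any
    circadian phase.

Both gated models produce identical emergence-time distributions when the
roughening duration is deterministic; they differ in the distribution of
roughening *onsets* and in the fraction of "ready but unemerged" animals a
hypothetical ETH (ecdysis-triggering hormone) probe would reveal before a
gate opens.  :func:`compare_models` exposes exactly those discriminating
observables.

Times are decimal hours on the recording axis, with t=0 the start of
constant darkness (DD).  Circadian time of a clock with free-running period
``tau_h`` is ``ct(t) = (t + ct0_offset_h) mod tau_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GatingParams",
    "FlySchedule",
    "simulate_cohort",
    "ready_fraction",
    "compare_models",
    "wild_type_preset",
    "short_period_preset",
    "arrhythmic_preset",
    "schedules_to_frame",
    "write_schedules_csv",
    "read_schedules_csv",
]

_MODELS = ("developmental", "permissive", "arrhythmic")

#: maximum rejected draws per fly when truncating the duration distribution
_MAX_TRUNC_REJECTS = 1000


@dataclass(frozen=True)
class GatingParams:
    """Parameters of the gated-emergence scheduling model.

    Parameters
    ----------
    model
        One of ``developmental``, ``permissive``, ``arrhythmic``.
    tau_h
        Free-running clock period in hours (>0).
    gate_open_ct
        Circadian time at which the emergence gate opens, in ``[0, tau_h)``.
    gate_width_h
        Duration the gate stays open, hours, in ``(0, tau_h)``.  The gate
        interval is half-open ``[open, open + width)``: a completion falling
        exactly at gate close is deferred.
    commit_mean_h, commit_sd_h
        Mean / SD of the clock-independent development time from pupariation
        to the commitment point, hours.
    rough_mean_h, rough_sd_h
        Mean / SD of the roughening (final-steps-of-metamorphosis) duration,
        hours; the draw is truncated at zero.
    ct0_offset_h
        Circadian time at recording time t=0 (start of DD).
    gate_dependent_duration
        Off by default, encoding the observation that roughening duration is
        independent of the chosen gate.  When on, flies deferred to a later
        gate draw a duration stretched by ``gate_dependent_factor`` — a
        falsification switch for testing the constancy analysis, not a
        biological claim.
    """

    model: str = "developmental"
    tau_h: float = 24.0
    gate_open_ct: float = 0.0
    gate_width_h: float = 10.0
    commit_mean_h: float = 96.0
    commit_sd_h: float = 2.0
    rough_mean_h: float = 13.0
    rough_sd_h: float = 1.0
    ct0_offset_h: float = 12.0
    gate_dependent_duration: bool = False
    gate_dependent_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(
                f"unknown gating model {self.model!r}; expected one of {_MODELS}"
            )
        if not self.tau_h > 0:
            raise ValueError("tau_h must be positive")
        if not 0 <= self.gate_open_ct < self.tau_h:
            raise ValueError("gate_open_ct must lie in [0, tau_h)")
        if not 0 < self.gate_width_h < self.tau_h:
            raise ValueError("gate_width_h must lie in (0, tau_h)")
        if self.commit_sd_h < 0 or self.rough_sd_h < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.rough_mean_h > 0:
            raise ValueError("rough_mean_h must be positive")

    # -- circadian geometry -------------------------------------------------
    def ct(self, t_h: float) -> float:
        """Circadian time of recording time ``t_h``."""
        return (t_h + self.ct0_offset_h) % self.tau_h

    def in_gate(self, t_h: float) -> bool:
        """True iff ``t_h`` falls inside an open gate (half-open interval)."""
        phase = (self.ct(t_h) - self.gate_open_ct) % self.tau_h
        return phase < self.gate_width_h

    def next_gate_open(self, t_h: float) -> float:
        """Earliest time ``>= t_h`` at which a gate is open.

        Returns ``t_h`` itself when already inside a gate, otherwise the next
        gate-opening instant.
        """
        if self.in_gate(t_h):
            return t_h
        phase = (self.ct(t_h) - self.gate_open_ct) % self.tau_h
        return t_h + (self.tau_h - phase)


@dataclass
class FlySchedule:
    """Ground-truth (or inferred) event times for one animal, hours since DD start."""

    fly_id: str
    pupariation_zt_h: float
    commitment_t_h: float
    onset_t_h: float
    completion_t_h: float
    emergence_t_h: float
    rough_duration_h: float

    def __post_init__(self) -> None:
        if self.onset_t_h < self.commitment_t_h - 1e-9:
            raise ValueError("onset cannot precede commitment")
        if self.emergence_t_h < self.completion_t_h - 1e-9:
            raise ValueError("emergence cannot precede completion")
        if not self.rough_duration_h > 0:
            raise ValueError("rough_duration_h must be positive")


# -- presets -----------------------------------------------------------------
# The paper anchors these only qualitatively (morning emergence, ~24 h vs
# ~20 h free-running periods, clock-less arrhythmicity); gate phase and width
# are nominal reconstructions.

def wild_type_preset(**overrides) -> GatingParams:
    """per+ -like preset: 24-h clock, 10-h morning gate, developmental gating."""
    return replace(GatingParams(), **overrides)


def short_period_preset(**overrides) -> GatingParams:
    """perS-like preset: ~20-h free-running clock."""
    return replace(GatingParams(tau_h=20.0), **overrides)


def arrhythmic_preset(**overrides) -> GatingParams:
    """per01-like preset: no gate, emergence tracks completion."""
    return replace(GatingParams(model="arrhythmic"), **overrides)


# -- simulation ---------------------------------------------------------------

def _fly_rng(seed: int, index: int) -> np.random.Generator:
    # per-fly substream: growing the cohort never reshuffles earlier flies
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, fly_id: str
) -> float:
    if sd == 0:
        if mean <= 0:
            raise ValueError(f"fly {fly_id}: degenerate duration {mean} <= 0")
        return mean
    for _ in range(_MAX_TRUNC_REJECTS):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError(
        f"fly {fly_id}: truncated-normal rejection failed after "
        f"{_MAX_TRUNC_REJECTS} draws (mean={mean}, sd={sd})"
    )


def _schedule_one(
    params: GatingParams, fly_id: str, pupariation_offset_h: float,
    rng: np.random.Generator,
) -> FlySchedule:
    commitment = pupariation_offset_h + rng.normal(
        params.commit_mean_h, params.commit_sd_h
    )
    duration = _draw_truncated_normal(
        rng, params.rough_mean_h, params.rough_sd_h, fly_id
    )

    if params.model == "arrhythmic":
        onset = commitment
        completion = onset + duration
        emergence = completion
    elif params.model == "developmental":
        # smallest onset >= commitment such that onset + duration is in a gate
        naive = commitment + duration
        emergence = params.next_gate_open(naive)
        onset = emergence - duration
        if params.gate_dependent_duration and emergence > naive:
            duration = duration * params.gate_dependent_factor
            emergence = onset + duration
        completion = emergence
    else:  # permissive
        onset = commitment
        completion = onset + duration
        emergence = params.next_gate_open(completion)

    return FlySchedule(
        fly_id=fly_id,
        pupariation_zt_h=pupariation_offset_h,
        commitment_t_h=commitment,
        onset_t_h=onset,
        completion_t_h=completion,
        emergence_t_h=emergence,
        rough_duration_h=duration,
    )


def simulate_cohort(
    params: GatingParams,
    pupariation_zts: Sequence[float],
    n_per_group: int,
    seed: int,
) -> list[FlySchedule]:
    """Simulate ``n_per_group`` flies for each pupariation offset.

    ``pupariation_zts`` entries are time offsets on the recording axis (the
    stagger between synchronized collection cohorts); the mean development
    time from pupariation to commitment is added on top.  Deterministic for a
    fixed seed, and per-fly random substreams guarantee that enlarging the
    cohort does not change earlier flies.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if len(pupariation_zts) == 0:
        raise ValueError("pupariation_zts must be non-empty")
    schedules: list[FlySchedule] = []
    index = 0
    for g, zt in enumerate(pupariation_zts):
        for j in range(n_per_group):
            rng = _fly_rng(seed, index)
            fly_id = f"g{g}_f{j}"
            schedules.append(_schedule_one(params, fly_id, float(zt), rng))
            index += 1
    return schedules


def ready_fraction(schedules: Iterable[FlySchedule], probe_t_h: float) -> float:
    """Predicted responder fraction of an ETH probe at ``probe_t_h``.

    Among flies that have not yet emerged at the probe time, the fraction
    that have already completed metamorphosis (and would therefore eclose
    within ~2 h of an ETH injection).
    """
    schedules = list(schedules)
    unemerged = [s for s in schedules if s.emergence_t_h > probe_t_h]
    if not unemerged:
        raise ValueError(
            f"no unemerged flies at probe time {probe_t_h} h: "
            "responder fraction undefined (empty denominator)"
        )
    ready = sum(1 for s in unemerged if s.completion_t_h <= probe_t_h)
    return ready / len(unemerged)


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
    }


def compare_models(
    params_dev: GatingParams,
    params_perm: GatingParams,
    pupariation_zts: Sequence[float],
    n_per_group: int,
    seed: int,
    probe_step_h: float = 1.0,
) -> dict:
    """Contrast the developmental and permissive gating hypotheses.

    Both parameter sets must share the clock and cohort geometry (tau, gate,
    development-time distributions); only the gating model may differ.
    Returns per-model distribution summaries of onsets per collection group,
    roughening durations and emergence times, plus the predicted ETH-probe
    responder fraction sampled on a regular grid — the two observables that
    discriminate the hypotheses.
    """
    shared = ("tau_h", "gate_open_ct", "gate_width_h", "commit_mean_h",
              "commit_sd_h", "rough_mean_h", "rough_sd_h", "ct0_offset_h")
    for f_ in shared:
        if getattr(params_dev, f_) != getattr(params_perm, f_):
            raise ValueError(f"cohort specs differ in {f_!r}; models not comparable")
    if params_dev.model != "developmental" or params_perm.model != "permissive":
        raise ValueError("expected a developmental and a permissive parameter set")

    out: dict = {"models": {}}
    cohorts = {}
    for name, p in (("developmental", params_dev), ("permissive", params_perm)):
        scheds = simulate_cohort(p, pupariation_zts, n_per_group, seed)
        cohorts[name] = scheds
        onsets = np.array([s.onset_t_h for s in scheds])
        emerg = np.array([s.emergence_t_h for s in scheds])
        groups = {}
        per_group = n_per_group
        for g, zt in enumerate(pupariation_zts):
            sl = slice(g * per_group, (g + 1) * per_group)
            groups[float(zt)] = _summary(onsets[sl])
        t_lo = float(np.floor(min(s.commitment_t_h for s in scheds)))
        t_hi = float(np.ceil(emerg.max()))
        probe_ts = np.arange(t_lo, t_hi, probe_step_h)
        fractions = []
        for t in probe_ts:
            try:
                fractions.append(ready_fraction(scheds, float(t)))
            except ValueError:
                fractions.append(np.nan)
        out["models"][name] = {
            "onset_by_group": groups,
            "duration": _summary(np.array([s.rough_duration_h for s in scheds])),
            "emergence": _summary(emerg),
            "probe_t_h": probe_ts.tolist(),
            "ready_fraction": fractions,
        }

    dev_on = np.array([s.onset_t_h for s in cohorts["developmental"]])
    perm_on = np.array([s.onset_t_h for s in cohorts["permissive"]])
    dev_rf = np.nanmax(np.array(out["models"]["developmental"]["ready_fraction"][:-1],
                                dtype=float)) if len(probe_ts) > 1 else 0.0
    perm_rf = np.nanmax(np.array(out["models"]["permissive"]["ready_fraction"][:-1],
                                 dtype=float)) if len(probe_ts) > 1 else 0.0
    out["discriminators"] = {
        "onset_shift_h": float(np.mean(dev_on) - np.mean(perm_on)),
        "max_pre_emergence_ready_fraction": {
            "developmental": float(dev_rf),
            "permissive": float(perm_rf),
        },
        "onset_discriminates": bool(abs(np.mean(dev_on) - np.mean(perm_on)) > 1e-9),
    }
    return out


# -- CSV round trip ----------------------------------------------------------

_SCHEDULE_COLUMNS = [
    "fly_id", "group_zt", "commitment_t_h", "onset_t_h",
    "completion_t_h", "emergence_t_h", "rough_duration_h",
]


def schedules_to_frame(schedules: Iterable[FlySchedule]) -> pd.DataFrame:
    rows = [
        {
            "fly_id": s.fly_id,
            "group_zt": s.pupariation_zt_h,
            "commitment_t_h": s.commitment_t_h,
            "onset_t_h": s.onset_t_h,
            "completion_t_h": s.completion_t_h,
            "emergence_t_h": s.emergence_t_h,
            "rough_duration_h": s.rough_duration_h,
        }
        for s in schedules
    ]
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def write_schedules_csv(schedules: Iterable[FlySchedule], path) -> None:
    schedules_to_frame(schedules).to_csv(path, index=False)


def read_schedules_csv(path) -> list[FlySchedule]:
    df = pd.read_csv(path)
    return [
        FlySchedule(
            fly_id=str(r.fly_id),
            pupariation_zt_h=float(r.group_zt),
            commitment_t_h=float(r.commitment_t_h),
            onset_t_h=float(r.onset_t_h),
            completion_t_h=float(r.completion_t_h),
            emergence_t_h=float(r.emergence_t_h),
            rough_duration_h=float(r.rough_duration_h),
        )
        for r in df.itertuples()
    ]
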