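"""Synthetic incentivized-task cohorts with a controllable choking mechanism.

The generator emulates the structure of an incentivized motor-task study:
participants play alternating blocks of baseline and reappraisal trials
over three runs, each trial offering one of five monetary incentives
($0, $25, $50, $75, $100).  Success is Bernoulli with a probability that
rises with incentive up to a saturation point ($75 by default) and drops
by a participant-specific ``choke_depth`` at the maximum incentive — the
choking mechanism — with the drop attenuated under reappraisal.  Each
participant also carries a loss-aversion coefficient (lambda) that both
drives their choices in a mixed-gamble task and, via a configurable slope,
deepens their choking.

Skin-conductance traces are synthesised from the same trial schedule with
the shared canonical response kernel: every event (incentive presentation,
motor task, intertrial interval) emits a sudomotor burst whose amplitude
scales with incentive, and failed high-incentive baseline trials emit an
exaggerated burst (sympathetic hyperarousal), abolished or attenuated
under reappraisal.

Everything is a pure function of (config, seed); per-participant random
streams are derived by stable hashing of (seed, participant id) so that
adding a participant never perturbs another's data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (AmplitudeConfig, CohortConfig, EffectConfig,
                     FACILITATION_PEAK, INCENTIVE_LEVELS)
from .errors import DomainError
from .scr import SCRFBasis, SCRRecording, canonical_scrf, convolve_events

__all__ = [
    "Participant",
    "generate_cohort",
    "sample_performance_prob",
    "generate_scr_trace",
    "event_amplitude",
    "generate_gamble_choices",
    "default_gamble_grid",
    "ControllerParams",
    "SpringParams",
    "simulate_spring_mass_trial",
    "participant_rng",
]

CONDITIONS = ("baseline", "reappraisal")


@dataclass
class Participant:
    """Latent traits of one simulated participant.

    loss_aversion: lambda > 0, weighting of losses relative to gains.
    base_skill: peak success probability, in (0, 1).
    choke_depth: drop in success probability at the maximum incentive
        (baseline condition), in probability units, >= 0.
    facilitation: performance gain from the lowest to the moderate
        (saturation) incentive, in probability units.
    scr_gain: multiplicative electrodermal responsiveness (1 = average).
    """

    id: str
    loss_aversion: float
    base_skill: float
    choke_depth: float
    facilitation: float
    scr_gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_skill < 1.0:
            raise DomainError("base_skill must lie in (0, 1)")
        if self.choke_depth < 0:
            raise DomainError("choke_depth must be >= 0")
        if self.loss_aversion <= 0:
            raise DomainError("loss_aversion must be positive")


def participant_rng(seed: int, participant_id: str, stream: str = "") -> np.random.Generator:
    """Deterministic per-participant random stream.

    The stream key is a stable hash of (seed, participant id, stream
    label), so streams are independent across participants and across
    uses (outcomes vs traces vs choices) but fully reproducible.
    """
    digest = hashlib.sha256(
        f"{seed}|{participant_id}|{stream}".encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# performance model


def _facilitation_ramp(incentive: float) -> float:
    """Saturating ramp over normalised incentive, peaking at $75.

    Returns a value in [-1, 0]: -1 at $0, rising linearly to 0 at the
    saturation incentive and flat thereafter.  Coding the ramp as a
    deficit below the peak keeps ``base_skill`` equal to the peak success
    probability for any facilitation value.
    """
    return min(incentive, FACILITATION_PEAK) / FACILITATION_PEAK - 1.0


def sample_performance_prob(
    incentive: float,
    condition: str,
    p: Participant,
    effect: EffectConfig | None = None,
) -> float:
    """Success probability for one trial.

    ``clip(base_skill + facilitation * g(incentive) - choke, 0, 1)`` where
    g is the saturating ramp and the choke term equals ``choke_depth`` at
    the $100 incentive in the baseline condition, ``choke_depth *
    reappraisal_attenuation`` at $100 under reappraisal, and 0 otherwise.
    """
    if effect is None:
        effect = EffectConfig()
    if incentive not in INCENTIVE_LEVELS:
        raise DomainError(
            f"incentive {incentive!r} not on the grid {INCENTIVE_LEVELS}")
    if condition not in CONDITIONS:
        raise DomainError(f"condition must be one of {CONDITIONS}")
    choke = 0.0
    if incentive == max(INCENTIVE_LEVELS):
        choke = p.choke_depth
        if condition == "reappraisal":
            choke *= effect.reappraisal_attenuation
    prob = p.base_skill + p.facilitation * _facilitation_ramp(incentive) - choke
    return float(np.clip(prob, 0.0, 1.0))


# ---------------------------------------------------------------------------
# cohort and schedule


def _draw_participant(config: CohortConfig, seed: int, index: int) -> Participant:
    pid = f"P{index + 1:02d}"
    rng = participant_rng(seed, pid, "traits")
    lo, hi = config.base_skill_range
    base_skill = rng.uniform(lo, hi)
    lam = float(np.exp(rng.normal(config.loss_aversion_log_mean,
                                  config.loss_aversion_log_sd)))
    # never emit the sentinel values 0 and 10 that mark exclusions
    lam = float(np.clip(lam, 0.1, 9.5))
    lam_median = float(np.exp(config.loss_aversion_log_mean))
    depth = rng.normal(
        config.choke_depth_mean
        + config.effect.choke_lambda_slope * (lam - lam_median),
        config.choke_depth_sd)
    depth = float(np.clip(depth, 0.0, base_skill))  # keep skill - depth >= 0
    flo, fhi = config.facilitation_range
    facilitation = rng.uniform(flo, fhi)
    scr_gain = 1.0
    return Participant(id=pid, loss_aversion=lam, base_skill=base_skill,
                       choke_depth=depth, facilitation=facilitation,
                       scr_gain=scr_gain)


def _participant_schedule(p: Participant, config: CohortConfig,
                          seed: int) -> pd.DataFrame:
    """Blocked, alternating-condition trial schedule on a continuous clock."""
    rng = participant_rng(seed, p.id, "schedule")
    per_cond: dict[str, list[int]] = {}
    for cond in CONDITIONS:
        incs = np.repeat(INCENTIVE_LEVELS, config.trials_per_cell)
        rng.shuffle(incs)
        per_cond[cond] = [int(v) for v in incs]

    # chunk each condition into blocks, then interleave conditions
    blocks: list[tuple[str, list[int]]] = []
    n_per_cond = len(per_cond["baseline"])
    n_blocks_cond = int(np.ceil(n_per_cond / config.block_length))
    start = int(rng.integers(2))  # which condition opens the session
    order = (CONDITIONS[start], CONDITIONS[1 - start])
    for b in range(n_blocks_cond):
        for cond in order:
            chunk = per_cond[cond][b * config.block_length:(b + 1) * config.block_length]
            if chunk:
                blocks.append((cond, chunk))

    # spread blocks over runs (first runs take the extra block)
    n_runs = config.n_runs
    per_run = [len(blocks) // n_runs + (1 if r < len(blocks) % n_runs else 0)
               for r in range(n_runs)]

    rows = []
    outcome_rng = participant_rng(seed, p.id, "outcomes")
    t = 0.0
    block_index = 0
    bi = 0
    for run_idx, nb in enumerate(per_run, start=1):
        for _ in range(nb):
            cond, incs = blocks[bi]
            bi += 1
            for inc in incs:
                # round timings at draw so stored times are exactly consistent
                inc_dur = round(float(
                    outcome_rng.uniform(*config.incentive_duration_range)), 3)
                iti = round(float(outcome_rng.uniform(*config.iti_range)), 3)
                prob = sample_performance_prob(inc, cond, p, config.effect)
                outcome = "success" if outcome_rng.random() < prob else "failure"
                rows.append({
                    "participant_id": p.id,
                    "run": run_idx,
                    "block_index": block_index,
                    "condition": cond,
                    "incentive": inc,
                    "incentive_onset": round(t, 3),
                    "incentive_duration": inc_dur,
                    "task_onset": round(t + inc_dur, 3),
                    "task_duration": config.task_duration,
                    "iti_duration": iti,
                    "outcome": outcome,
                })
                t = round(t + inc_dur + config.task_duration + iti, 3)
            block_index += 1
        t += config.inter_run_gap
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[Participant], pd.DataFrame]:
    """Generate a full cohort: participants and their trial tables.

    Deterministic for a fixed (config, seed); every participant has every
    (condition x incentive) cell populated with ``trials_per_cell`` trials
    and outcomes drawn Bernoulli from :func:`sample_performance_prob`.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    participants = [_draw_participant(config, seed, i)
                    for i in range(config.n_participants)]
    tables = [_participant_schedule(p, config, seed) for p in participants]
    trials = pd.concat(tables, ignore_index=True)
    return participants, trials


# ---------------------------------------------------------------------------
# skin conductance generation


def event_amplitude(
    amp: AmplitudeConfig,
    event_type: str,
    incentive: float,
    condition: str,
    outcome: str,
    arousal_scale: float = 1.0,
) -> float:
    """Sudomotor burst amplitude for one event, in microsiemens.

    Incentive and task responses grow linearly with normalised incentive.
    Failed trials at or above ``arousal_threshold`` dollars add the
    hyperarousal term ``arousal_gain * arousal_scale`` in the baseline
    condition, scaled down by ``arousal_attenuation`` under reappraisal —
    selective to high-incentive failures, so low-incentive failure cells
    stay null.  ``arousal_scale`` lets callers tie the hyperarousal to a
    participant trait (the pipeline uses their relative choke depth).
    """
    m = incentive / 100.0
    if event_type == "incentive":
        return amp.incentive_base + amp.incentive_slope * m
    if event_type == "task":
        a = amp.task_base + amp.task_slope * m
        if outcome == "failure" and incentive >= amp.arousal_threshold:
            scale = 1.0 if condition == "baseline" else amp.arousal_attenuation
            a += amp.arousal_gain * arousal_scale * scale
        return a
    if event_type == "iti":
        return amp.iti_amp
    raise DomainError(f"unknown event type {event_type!r}")


def generate_scr_trace(
    schedule: pd.DataFrame,
    amp: AmplitudeConfig | None = None,
    noise_sd: float = 0.10,
    drift: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 100.0,
    basis: SCRFBasis | None = None,
    gain: float = 1.0,
    arousal_scale: float = 1.0,
    participant_id: str | None = None,
) -> SCRRecording:
    """Synthesise a conductance trace from a trial schedule.

    trace = sum over events of amplitude x SCRF(t - onset; boxcar driver)
            + drift * t + Gaussian white noise(sd = noise_sd),
    using the same canonical kernel and convolution convention as the
    analysis design matrix, so a noiseless trace is exactly reproducible
    by the GLM.  ``gain`` scales all event amplitudes (per-participant
    electrodermal responsiveness); ``arousal_scale`` scales only the
    hyperarousal term on failed high-incentive trials.
    """
    if amp is None:
        amp = AmplitudeConfig()
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if len(schedule) == 0:
        raise DomainError("empty schedule")
    if basis is None:
        basis = canonical_scrf(sampling_rate)
    elif basis.sampling_rate != sampling_rate:
        raise DomainError("basis must be sampled at the recording rate")
    if participant_id is None:
        pid = str(schedule["participant_id"].iloc[0]) if "participant_id" in schedule else "?"
    else:
        pid = participant_id

    end = (schedule["task_onset"] + schedule["task_duration"]
           + schedule["iti_duration"]).max()
    n = int(np.ceil((end + basis.duration) * sampling_rate))

    events: list[tuple[float, float, float]] = []
    for row in schedule.itertuples(index=False):
        a_inc = event_amplitude(amp, "incentive", row.incentive,
                                row.condition, row.outcome, arousal_scale)
        a_task = event_amplitude(amp, "task", row.incentive,
                                 row.condition, row.outcome, arousal_scale)
        a_iti = event_amplitude(amp, "iti", row.incentive,
                                row.condition, row.outcome, arousal_scale)
        events.append((row.incentive_onset, row.incentive_duration, gain * a_inc))
        events.append((row.task_onset, row.task_duration, gain * a_task))
        events.append((row.task_onset + row.task_duration, row.iti_duration,
                       gain * a_iti))

    trace = convolve_events(events, n, sampling_rate, basis.kernel)
    t = np.arange(n) / sampling_rate
    trace = trace + drift * t
    if noise_sd > 0:
        rng = participant_rng(seed, pid, "scr_noise")
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return SCRRecording(participant_id=pid, sampling_rate=sampling_rate,
                        samples=trace, schedule=schedule)


def participant_scr_gain(amp: AmplitudeConfig, seed: int,
                         participant_id: str) -> float:
    """Lognormal per-participant responsiveness multiplier (median 1)."""
    if amp.participant_gain_sd == 0:
        return 1.0
    rng = participant_rng(seed, participant_id, "scr_gain")
    return float(np.exp(rng.normal(0.0, amp.participant_gain_sd)))


# ---------------------------------------------------------------------------
# gamble choices (loss-aversion task)


def default_gamble_grid() -> list[tuple[float, float]]:
    """Mixed 50/50 gambles spanning gain/loss ratios from ~0.3 to ~10."""
    gains = np.arange(4.0, 44.0, 4.0)        # $4 ... $40
    losses = np.arange(2.0, 30.0, 2.0)       # $2 ... $28
    return [(float(g), float(l)) for g in gains for l in losses]


def generate_gamble_choices(
    p: Participant,
    gambles: list[tuple[float, float]] | None = None,
    choice_noise: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate accept/reject choices on mixed 50/50 gambles.

    Acceptance probability is a logistic function of the prospect value
    ``0.5 * (gain - lambda * loss)`` with temperature ``choice_noise``
    (dollars); choices are Bernoulli and seed-deterministic.
    """
    if gambles is None:
        gambles = default_gamble_grid()
    if len(gambles) == 0:
        raise DomainError("empty gamble list")
    if choice_noise <= 0:
        raise DomainError("choice_noise must be positive")
    gains = np.array([g for g, _ in gambles], dtype=float)
    losses = np.array([l for _, l in gambles], dtype=float)
    if np.any(gains <= 0) or np.any(losses <= 0):
        raise DomainError("mixed gambles require gain > 0 and loss > 0")
    pv = 0.5 * (gains - p.loss_aversion * losses)
    prob = expit(pv / choice_noise)
    rng = participant_rng(seed, p.id, "gambles")
    accepted = rng.random(len(gambles)) < prob
    return pd.DataFrame({
        "participant_id": p.id,
        "gain": gains,
        "loss": losses,
        "accepted": accepted,
    })


# ---------------------------------------------------------------------------
# optional spring-mass trial simulator


@dataclass
class ControllerParams:
    """Noisy proportional-derivative controller for the finger cursor."""

    kp: float = 40.0           # proportional gain, s^-2
    kd: float = 12.0           # derivative gain, s^-1
    motor_noise: float = 0.0   # accel noise SD per sqrt(step)


@dataclass
class SpringParams:
    """Damped mass-spring coupling of the mass cursor to the finger."""

    mass: float = 1.0
    stiffness: float = 39.478   # (2*pi)^2: ~1 Hz natural frequency at mass 1
    damping_ratio: float = 0.2
    dt: float = 0.01            # integration step, s
    horizon: float = 2.0        # trial duration, s


def simulate_spring_mass_trial(
    ctrl: ControllerParams | None = None,
    dyn: SpringParams | None = None,
    target_halfwidth: float = 0.1,
    seed: int = 0,
    velocity_threshold: float = 0.5,
    target: float = 1.0,
) -> bool:
    """Optional mechanistic trial simulator (not used for outcomes by default).

    The finger cursor is a unit point mass driven by a noisy PD controller
    toward the target; the mass cursor obeys damped mass-spring dynamics
    relative to the finger.  Success requires both cursors inside the
    target and below the velocity threshold at the 2 s horizon.  Bernoulli
    sampling from :func:`sample_performance_prob` remains the default
    outcome mechanism because the downstream analyses consume only
    success/failure.
    """
    if ctrl is None:
        ctrl = ControllerParams()
    if dyn is None:
        dyn = SpringParams()
    if dyn.mass <= 0 or dyn.stiffness <= 0 or dyn.dt <= 0:
        raise DomainError("mass, stiffness and timestep must be positive")
    if target_halfwidth <= 0:
        raise DomainError("target_halfwidth must be positive")
    rng = np.random.default_rng(seed)
    c = 2.0 * dyn.damping_ratio * np.sqrt(dyn.stiffness * dyn.mass)
    x_f = v_f = x_m = v_m = 0.0
    n_steps = int(round(dyn.horizon / dyn.dt))
    sqdt = np.sqrt(dyn.dt)
    for _ in range(n_steps):
        u = ctrl.kp * (target - x_f) - ctrl.kd * v_f
        if ctrl.motor_noise > 0:
            u += ctrl.motor_noise * rng.normal() / sqdt
        a_m = (dyn.stiffness * (x_f - x_m) + c * (v_f - v_m)) / dyn.mass
        v_f += u * dyn.dt
        x_f += v_f * dyn.dt
        v_m += a_m * dyn.dt
        x_m += v_m * dyn.dt
    inside = (abs(x_f - target) < target_halfwidth
              and abs(x_m - target) < target_halfwidth)
    slow = abs(v_f) < velocity_threshold and abs(v_m) < velocity_threshold
    return bool(inside and slow)
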