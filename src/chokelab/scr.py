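"""Model-based skin-conductance analysis.

The analysis treats the measured conductance trace as the output of a
linear time-invariant system: discrete sudomotor bursts, time-locked to
task events, are convolved with a stereotyped response kernel (the
canonical skin-conductance response function, SCRF) and superimposed on
slow tonic drift and noise.  Preprocessing is a causal (single-pass)
Butterworth band-pass at the acquisition rate followed by integer-stride
downsampling; the per-participant model is an ordinary least-squares GLM
whose regressors are event boxcars and parametric modulators convolved
with the SCRF and its first temporal derivative.

Conventions
-----------
* The kernel is a gamma-family density, time-shifted by an onset latency
  and rescaled to unit peak, so fitted amplitudes read directly as
  response sizes in microsiemens.
* Boxcar drivers have height 1 and the convolution carries the dt factor
  (integral convention); an event whose duration is below one sample is
  treated as a unit-area impulse.  Amplitudes are therefore invariant to
  the sampling rate, and an amplitude-1 impulse produces a response whose
  maximum equals the kernel peak (i.e. 1).
* Parametric modulators are mean-centered within participant before
  interaction products are formed; incentive is coded in dollars/100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DesignError, DomainError, FitError

__all__ = [
    "SCRFBasis",
    "SCRRecording",
    "DesignMatrix",
    "GLMFit",
    "canonical_scrf",
    "convolve_events",
    "bandpass_filter",
    "downsample",
    "build_design_matrix",
    "indicator_recoding",
    "fit_scr_glm",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SCRRecording:
    """A sampled skin-conductance trace with its event schedule.

    samples are in microsiemens; the schedule is the trial table
    (one row per trial) whose onsets refer to the same clock as the
    first sample (t = 0).
    """

    participant_id: str
    sampling_rate: float
    samples: np.ndarray
    schedule: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DomainError("conductance trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class SCRFBasis:
    """Canonical SCRF kernel and its first temporal derivative.

    Both are sampled on the same grid; ``kernel`` has unit peak and the
    derivative is scaled by the same normalisation constant so that the
    pair forms a consistent first-order Taylor basis for small latency
    shifts of the response.
    """

    kernel: np.ndarray
    derivative: np.ndarray
    sampling_rate: float
    params: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.kernel) / self.sampling_rate

    @property
    def time_to_peak(self) -> float:
        return float(np.argmax(self.kernel)) / self.sampling_rate


@dataclass
class DesignMatrix:
    """Convolved GLM design with named columns.

    ``X`` holds one column per (driver x basis-function); ``unconvolved``
    retains the raw driver signals for diagnostics.
    """

    X: np.ndarray
    names: list[str]
    sampling_rate: float
    unconvolved: np.ndarray | None = None
    driver_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


@dataclass
class GLMFit:
    """Per-participant least-squares amplitude estimates."""

    participant_id: str
    betas: pd.Series            # microsiemens per unit driver, incl. 'const'
    residual_variance: float
    dof: int
    design_names: list[str]

    def __getitem__(self, name: str) -> float:
        return float(self.betas[name])


# ---------------------------------------------------------------------------
# canonical response function


def canonical_scrf(
    sampling_rate: float,
    shape: float = 3.0,
    scale: float = 1.7,
    latency: float = 0.5,
    duration: float = 30.0,
) -> SCRFBasis:
    """Sample the canonical skin-conductance response function.

    The kernel is a gamma density in shifted time, ``h(t) proportional to
    ((t-L)/theta)^(k-1) exp(-(t-L)/theta)`` for t > L, normalised to unit
    peak.  The defaults (k = 3, theta = 1.7 s, L = 0.5 s) put the mode at
    L + (k-1) theta = 3.9 s after event onset, the stereotyped
    time-to-peak of event-related electrodermal responses, with a decay
    back to < 0.1% of peak well inside the 30 s support.

    The first temporal derivative is obtained analytically and sampled on
    the same grid; including it in a design matrix absorbs small
    participant-level latency shifts of the response.
    """
    if sampling_rate <= 0:
        raise DomainError("sampling_rate must be positive")
    if shape <= 1 or scale <= 0:
        raise DomainError("SCRF requires shape > 1 and scale > 0")
    if latency < 0 or duration <= latency:
        raise DomainError("SCRF requires 0 <= latency < duration")
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, duration, dt)
    s = np.maximum(t - latency, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(s > 0, (s / scale) ** (shape - 1) * np.exp(-s / scale), 0.0)
        # h'(t) = h(t) * ((k-1)/s - 1/scale)
        dh = np.where(s > 0, h * ((shape - 1) / np.where(s > 0, s, 1.0) - 1.0 / scale), 0.0)
    peak = h.max()
    if peak <= 0:
        raise DomainError("SCRF kernel degenerate on this grid")
    return SCRFBasis(
        kernel=h / peak,
        derivative=dh / peak,
        sampling_rate=sampling_rate,
        params={"shape": shape, "scale": scale, "latency": latency,
                "duration": duration},
    )


# ---------------------------------------------------------------------------
# event convolution (shared by the generator and the design builder)


def convolve_events(
    events: Iterable[tuple[float, float, float]],
    n_samples: int,
    sampling_rate: float,
    kernel: np.ndarray,
) -> np.ndarray:
    """Convolve amplitude-weighted event boxcars with a response kernel.

    ``events`` is an iterable of (onset_s, duration_s, amplitude).  Each
    event contributes a boxcar of its amplitude over [onset, onset+duration)
    sampled at ``sampling_rate``; the convolution is scaled by dt so the
    result approximates the continuous integral and is invariant to the
    sampling rate.  Events shorter than one sample are unit-area impulses
    (height amplitude/dt), so an amplitude-1 impulse yields exactly the
    kernel.
    """
    dt = 1.0 / sampling_rate
    driver = np.zeros(n_samples)
    for onset, dur, amp in events:
        if amp == 0.0:
            continue
        if onset < 0:
            raise DomainError(f"event onset {onset} is negative")
        start = int(np.ceil(onset * sampling_rate - 1e-9))
        stop = int(np.ceil((onset + dur) * sampling_rate - 1e-9))
        if start >= n_samples:
            continue
        if stop <= start:            # sub-sample event -> unit-area impulse
            driver[start] += amp / dt
        else:
            driver[start:min(stop, n_samples)] += amp
    return sps.fftconvolve(driver, kernel)[:n_samples] * dt


def _driver_signal(events, n_samples, sampling_rate):
    """Unconvolved driver (for diagnostics): same sampling as convolve_events."""
    dt = 1.0 / sampling_rate
    driver = np.zeros(n_samples)
    for onset, dur, amp in events:
        start = int(np.ceil(onset * sampling_rate - 1e-9))
        stop = int(np.ceil((onset + dur) * sampling_rate - 1e-9))
        if start >= n_samples:
            continue
        if stop <= start:
            driver[start] += amp / dt
        else:
            driver[start:min(stop, n_samples)] += amp
    return driver


# ---------------------------------------------------------------------------
# preprocessing


def bandpass_filter(
    rec: SCRRecording,
    low: float = 0.05,
    high: float = 5.0,
    order: int = 1,
) -> SCRRecording:
    """Causal (unidirectional, single-pass) Butterworth band-pass.

    Applied at the acquisition rate, before downsampling; the default
    first-order design gives the gentle roll-off conventional for
    skin-conductance preprocessing.  The 0.05 Hz high-pass removes tonic
    level and drift (DC gain is zero).
    """
    fs = rec.sampling_rate
    if not 0 < low < high:
        raise DomainError("cutoffs must satisfy 0 < low < high")
    if high >= fs / 2:
        raise DomainError(
            f"upper cutoff {high} Hz is not below the Nyquist rate {fs / 2} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def downsample(rec: SCRRecording, target_rate: float = 5.0) -> SCRRecording:
    """Decimate by keeping every (rate ratio)-th sample, first sample kept.

    The acquisition rate must be an integer multiple of ``target_rate``;
    no interpolation or anti-alias filtering is performed here because
    the band-pass has already limited the signal to the new Nyquist band.
    """
    if target_rate <= 0:
        raise DomainError("target_rate must be positive")
    ratio = rec.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise DomainError(
            f"sampling rate {rec.sampling_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz")
    ratio = int(round(ratio))
    return replace(rec, samples=rec.samples[::ratio].copy(),
                   sampling_rate=target_rate)


# ---------------------------------------------------------------------------
# design construction

_EPOCHS = ("incentive", "task")
_MODULATORS = ("perf", "cond", "inc")
_INTERACTIONS = (("perf", "cond"), ("perf", "inc"), ("cond", "inc"),
                 ("perf", "cond", "inc"))


def _schedule_columns(schedule: pd.DataFrame) -> None:
    required = {"incentive", "condition", "outcome", "incentive_onset",
                "incentive_duration", "task_onset", "task_duration",
                "iti_duration"}
    missing = required - set(schedule.columns)
    if missing:
        raise DesignError(f"schedule is missing columns: {sorted(missing)}")
    if schedule["outcome"].isna().any():
        raise DesignError("schedule contains trials with missing outcome")


def _modulator_values(schedule: pd.DataFrame, center: bool) -> dict[str, np.ndarray]:
    """Per-trial modulator codes: success=1/failure=0, reappraisal=1/baseline=0,
    incentive in dollars/100; centered within participant when requested."""
    perf = (schedule["outcome"].to_numpy() == "success").astype(float)
    cond = (schedule["condition"].to_numpy() == "reappraisal").astype(float)
    inc = schedule["incentive"].to_numpy(dtype=float) / 100.0
    vals = {"perf": perf, "cond": cond, "inc": inc}
    if center:
        vals = {k: v - v.mean() for k, v in vals.items()}
    return vals


def _design_length(schedule: pd.DataFrame, basis: SCRFBasis,
                   analysis_rate: float) -> int:
    end = (schedule["task_onset"] + schedule["task_duration"]
           + schedule["iti_duration"]).max()
    return int(np.ceil((end + basis.duration) * analysis_rate))


def build_design_matrix(
    schedule: pd.DataFrame,
    basis: SCRFBasis,
    analysis_rate: float = 5.0,
    center_modulators: bool = True,
    n_samples: int | None = None,
) -> DesignMatrix:
    """Build the full convolutional design for one participant.

    Drivers (17 when both conditions and both outcomes are present):

    * three onset boxcars — incentive presentation (its per-trial 2–5 s
      duration), motor task (2 s) and intertrial interval (1–7 s);
    * at the incentive and task epochs, parametric modulators for
      performance, condition and incentive, their three two-way products
      and the three-way product (7 modulators x 2 epochs).

    Every driver is convolved with the SCRF kernel and with its first
    temporal derivative, giving two columns per driver.  Modulators are
    mean-centered within participant before products are formed; a
    modulator that is constant within the schedule (e.g. a single-condition
    run) yields an all-zero centered driver and is dropped with a warning.
    """
    if basis.sampling_rate != analysis_rate:
        raise DesignError("basis must be sampled at the analysis rate")
    _schedule_columns(schedule)
    if len(schedule) == 0:
        raise DomainError("empty schedule")
    if n_samples is None:
        n_samples = _design_length(schedule, basis, analysis_rate)

    mods = _modulator_values(schedule, center_modulators)
    inc_events = list(zip(schedule["incentive_onset"],
                          schedule["incentive_duration"]))
    task_events = list(zip(schedule["task_onset"], schedule["task_duration"]))
    iti_events = list(zip(schedule["task_onset"] + schedule["task_duration"],
                          schedule["iti_duration"]))
    epoch_events = {"incentive": inc_events, "task": task_events}

    drivers: list[tuple[str, list[tuple[float, float, float]]]] = [
        ("incentive", [(o, d, 1.0) for o, d in inc_events]),
        ("task", [(o, d, 1.0) for o, d in task_events]),
        ("iti", [(o, d, 1.0) for o, d in iti_events]),
    ]
    for epoch in _EPOCHS:
        base_events = epoch_events[epoch]
        for m in _MODULATORS:
            amps = mods[m]
            drivers.append((f"{epoch}_x_{m}",
                            [(o, d, a) for (o, d), a in zip(base_events, amps)]))
        for combo in _INTERACTIONS:
            amps = np.prod([mods[m] for m in combo], axis=0)
            name = f"{epoch}_x_" + "_".join(combo)
            drivers.append((name,
                            [(o, d, a) for (o, d), a in zip(base_events, amps)]))

    return _convolve_drivers(drivers, basis, analysis_rate, n_samples)


def _convolve_drivers(drivers, basis: SCRFBasis, analysis_rate: float,
                      n_samples: int) -> DesignMatrix:
    cols, names, raw, kept = [], [], [], []
    for name, events in drivers:
        amps = np.array([a for _, _, a in events])
        if len(events) == 0 or np.allclose(amps, 0.0):
            warnings.warn(
                f"driver '{name}' is identically zero and was dropped "
                "(constant modulator within participant)", stacklevel=3)
            continue
        raw.append(_driver_signal(events, n_samples, analysis_rate))
        cols.append(convolve_events(events, n_samples, analysis_rate, basis.kernel))
        names.append(f"{name}:scrf")
        cols.append(convolve_events(events, n_samples, analysis_rate,
                                    basis.derivative))
        names.append(f"{name}:dscrf")
        kept.append(name)
    if not cols:
        raise DesignError("no usable drivers in schedule")
    return DesignMatrix(X=np.column_stack(cols), names=names,
                        sampling_rate=analysis_rate,
                        unconvolved=np.column_stack(raw), driver_names=kept)


def indicator_recoding(
    schedule: pd.DataFrame,
    basis: SCRFBasis,
    analysis_rate: float = 5.0,
    high_set: Sequence[int] = (100,),
    include_nuisance: bool = False,
    n_samples: int | None = None,
) -> DesignMatrix:
    """Cell-indicator design for the follow-up contrast analysis.

    Trials are partitioned into the 8 cells of condition (baseline /
    reappraisal) x performance (success / failure) x incentive level
    (high = ``high_set``, low = the rest), and each cell gets its own
    0/1 indicator driver at the motor-task epoch, convolved with the
    basis kernel and derivative.  ``high_set=(75, 100)`` reproduces the
    robustness variant in which high incentive means playing for $75 or
    $100.  Cells with no trials are dropped with a warning.

    With ``include_nuisance`` the incentive-presentation and ITI boxcars
    are prepended so that incentive-epoch responses do not leak into the
    cell estimates (the task boxcar is omitted: the 8 cells partition the
    task trials, so it would be collinear with their sum).
    """
    _schedule_columns(schedule)
    if len(schedule) == 0:
        raise DomainError("empty schedule")
    high = set(int(h) for h in high_set)
    if n_samples is None:
        n_samples = _design_length(schedule, basis, analysis_rate)

    drivers = []
    if include_nuisance:
        drivers += [
            ("incentive", [(o, d, 1.0) for o, d in
                           zip(schedule["incentive_onset"],
                               schedule["incentive_duration"])]),
            ("iti", [(o, d, 1.0) for o, d in
                     zip(schedule["task_onset"] + schedule["task_duration"],
                         schedule["iti_duration"])]),
        ]
    for cond in ("baseline", "reappraisal"):
        for outcome in ("success", "failure"):
            for level, sel in (("high", True), ("low", False)):
                mask = ((schedule["condition"] == cond)
                        & (schedule["outcome"] == outcome)
                        & (schedule["incentive"].astype(int).isin(high) == sel))
                name = f"cell_{cond}_{outcome}_{level}"
                rows = schedule[mask]
                events = [(o, d, 1.0) for o, d in
                          zip(rows["task_onset"], rows["task_duration"])]
                drivers.append((name, events))
    return _convolve_drivers(drivers, basis, analysis_rate, n_samples)


def cell_membership_counts(schedule: pd.DataFrame,
                           high_set: Sequence[int] = (100,)) -> pd.Series:
    """Trial counts in the 8 condition x outcome x high/low cells."""
    high = set(int(h) for h in high_set)
    level = np.where(schedule["incentive"].astype(int).isin(high), "high", "low")
    return schedule.groupby(
        [schedule["condition"], schedule["outcome"], pd.Series(level, index=schedule.index, name="level")]
    ).size()


# ---------------------------------------------------------------------------
# GLM fitting


def fit_scr_glm(rec: SCRRecording, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares of the trace on the convolved design.

    An intercept column is appended automatically.  The trace and design
    must share a sampling rate; if their lengths differ by no more than
    the kernel support (the design extends past the last event to let
    responses decay) both are truncated to the common length, otherwise
    the mismatch is an error.
    """
    if rec.sampling_rate != design.sampling_rate:
        raise FitError(
            f"trace at {rec.sampling_rate} Hz but design at "
            f"{design.sampling_rate} Hz")
    n = min(len(rec.samples), design.n_samples)
    if max(len(rec.samples), design.n_samples) - n > 60 * design.sampling_rate:
        raise FitError(
            f"trace length {len(rec.samples)} and design length "
            f"{design.n_samples} differ by more than the kernel support")
    y = rec.samples[:n]
    X = np.column_stack([np.ones(n), design.X[:n]])
    names = ["const"] + list(design.names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise FitError(f"design is rank deficient; collinear columns: {collinear}")
    beta, rss, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        raise FitError("no residual degrees of freedom")
    return GLMFit(
        participant_id=rec.participant_id,
        betas=pd.Series(beta, index=names),
        residual_variance=float(resid @ resid / dof),
        dof=dof,
        design_names=list(design.names),
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in np.where(diag < tol)[0]]
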