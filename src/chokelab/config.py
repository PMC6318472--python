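"""Configuration objects for cohort simulation and the analysis pipeline.

Every object is a plain dataclass with defaults that reproduce the study
conditions the package emulates: 38 participants, five incentive levels
($0–$100), alternating baseline/reappraisal blocks over three runs, 20
trials per (condition x incentive) cell, skin conductance acquired at
100 Hz and analysed at 5 Hz.  All configs serialise to/from JSON; unknown
keys are rejected so a typo in a config file fails loudly rather than
silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from .errors import ConfigurationError

INCENTIVE_LEVELS = (0, 25, 50, 75, 100)
#: Incentive (dollars) at which the facilitation ramp saturates; performance
#: can therefore peak below the maximum incentive, which is what makes a
#: positive choking score possible.
FACILITATION_PEAK = 75.0

DEFAULT_SEED = 20181127


@dataclass
class EffectConfig:
    """Behavioural effect parameters of the simulated cohort.

    reappraisal_attenuation: multiplier in [0, 1] applied to each
        participant's choke depth on reappraisal trials (0 = reappraisal
        abolishes choking, 1 = no effect).  The default 0.25 mirrors a
        roughly four-fold reduction of expected choking under reappraisal.
    choke_lambda_slope: increase in choke depth per unit loss aversion
        above the population mean, in probability units; links individual
        loss aversion to behavioural choking.
    """

    reappraisal_attenuation: float = 0.25
    choke_lambda_slope: float = 0.03

    def validate(self) -> None:
        if not 0.0 <= self.reappraisal_attenuation <= 1.0:
            raise ConfigurationError(
                "effect.reappraisal_attenuation must lie in [0, 1], got "
                f"{self.reappraisal_attenuation}"
            )


@dataclass
class AmplitudeConfig:
    """Sudomotor amplitude model for the skin-conductance generator.

    Amplitudes are in microsiemens per unit driver (unit-peak response
    kernel, integral boxcar convention).  Event responses scale linearly
    with normalised incentive (dollars/100); on failed trials at or above
    ``arousal_threshold`` dollars the task response gains ``arousal_gain``
    extra amplitude in the baseline condition — the selective hyperarousal
    signature of choking — reduced by ``arousal_attenuation`` under
    reappraisal (0 = abolished).
    """

    incentive_base: float = 0.30
    incentive_slope: float = 0.30
    task_base: float = 0.20
    task_slope: float = 0.20
    iti_amp: float = 0.05
    arousal_gain: float = 0.40
    arousal_threshold: float = 100.0
    arousal_attenuation: float = 0.0
    #: lognormal sigma of the per-participant multiplicative response gain;
    #: electrodermal responsiveness varies a lot between people (many
    #: near non-responders), so the default heterogeneity is large.
    participant_gain_sd: float = 0.8

    def validate(self) -> None:
        for name in ("incentive_base", "incentive_slope", "task_base",
                     "task_slope", "iti_amp", "arousal_gain"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"amplitude.{name} must be >= 0")
        if not 0.0 <= self.arousal_attenuation <= 1.0:
            raise ConfigurationError(
                "amplitude.arousal_attenuation must lie in [0, 1]")
        if self.participant_gain_sd < 0:
            raise ConfigurationError("amplitude.participant_gain_sd must be >= 0")


@dataclass
class CohortConfig:
    """Cohort composition, trial schedule timing and participant traits."""

    n_participants: int = 38
    trials_per_cell: int = 20
    n_runs: int = 3
    block_length: int = 10

    # timing, seconds
    incentive_duration_range: tuple[float, float] = (2.0, 5.0)
    task_duration: float = 2.0
    iti_range: tuple[float, float] = (1.0, 7.0)
    inter_run_gap: float = 20.0

    # participant trait distributions
    base_skill_range: tuple[float, float] = (0.55, 0.85)
    facilitation_range: tuple[float, float] = (0.05, 0.15)
    choke_depth_mean: float = 0.15
    choke_depth_sd: float = 0.05
    loss_aversion_log_mean: float = 0.693  # median lambda = 2
    loss_aversion_log_sd: float = 0.4

    effect: EffectConfig = field(default_factory=EffectConfig)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.trials_per_cell <= 0:
            raise ConfigurationError("trials_per_cell must be positive")
        if self.n_runs <= 0:
            raise ConfigurationError("n_runs must be positive")
        if self.block_length <= 0:
            raise ConfigurationError("block_length must be positive")
        lo, hi = self.incentive_duration_range
        if not (0 < lo <= hi):
            raise ConfigurationError("incentive_duration_range must be 0 < lo <= hi")
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ConfigurationError("iti_range must be 0 < lo <= hi")
        if self.task_duration <= 0:
            raise ConfigurationError("task_duration must be positive")
        lo, hi = self.base_skill_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("base_skill_range must lie inside (0, 1)")
        if self.choke_depth_mean < 0 or self.choke_depth_sd < 0:
            raise ConfigurationError("choke depth parameters must be >= 0")
        self.effect.validate()


@dataclass
class SCRConfig:
    """Skin-conductance acquisition and analysis settings."""

    sampling_rate: float = 100.0      # acquisition, Hz
    analysis_rate: float = 5.0        # post-downsampling, Hz
    noise_sd: float = 0.10            # microsiemens, white at acquisition rate
    drift: float = 0.001              # microsiemens per second, tonic slope
    filter_low: float = 0.05          # Hz
    filter_high: float = 5.0          # Hz
    filter_order: int = 1
    amplitude: AmplitudeConfig = field(default_factory=AmplitudeConfig)

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.analysis_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 < self.filter_low < self.filter_high:
            raise ConfigurationError("filter cutoffs must satisfy 0 < low < high")
        if self.filter_high >= self.sampling_rate / 2:
            raise ConfigurationError("filter_high must be below Nyquist")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        self.amplitude.validate()


@dataclass
class AnalysisConfig:
    """Statistical analysis options."""

    n_quad: int = 32                  # Gauss-Hermite nodes for the random intercept
    include_interaction: bool = True  # condition x centered-lambda term in the Tobit
    random_intercept: bool = True
    high_set: tuple[int, ...] = (100,)  # 'high incentive' cells for the indicator GLM
    center_modulators: bool = True
    lambda_bounds: tuple[float, float] = (0.05, 10.0)
    n_gambles: int = 140
    choice_noise: float = 5.0         # softmax temperature, dollars

    def validate(self) -> None:
        if self.n_quad < 2:
            raise ConfigurationError("n_quad must be >= 2")
        if not set(self.high_set) <= set(INCENTIVE_LEVELS):
            raise ConfigurationError("high_set must be a subset of the incentive grid")
        lo, hi = self.lambda_bounds
        if not 0 < lo < hi:
            raise ConfigurationError("lambda_bounds must satisfy 0 < lo < hi")
        if self.choice_noise <= 0:
            raise ConfigurationError("choice_noise must be positive")


@dataclass
class RunConfig:
    """One JSON-serialisable document configuring an end-to-end run."""

    seed: int = DEFAULT_SEED
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scr: SCRConfig = field(default_factory=SCRConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "chokelab_out"

    def validate(self) -> None:
        self.cohort.validate()
        self.scr.validate()
        self.analysis.validate()

    # -- JSON (de)serialisation ------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        cfg = _build(cls, data, "")
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _build(cls, data: dict[str, Any], prefix: str):
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"expected an object for '{prefix or cls.__name__}'")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = prefix or "config"
        raise ConfigurationError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _NESTED.get((cls.__name__, name))
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{prefix}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


_NESTED = {
    ("RunConfig", "cohort"): CohortConfig,
    ("RunConfig", "scr"): SCRConfig,
    ("RunConfig", "analysis"): AnalysisConfig,
    ("CohortConfig", "effect"): EffectConfig,
    ("SCRConfig", "amplitude"): AmplitudeConfig,
}
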