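"""Experiment configuration: tank geometry, trial schedule, analysis windows.

All spatial quantities are in centimetres, times in seconds. The coordinate
frame has its origin at the front-bottom-left corner of the fish compartment:
x runs along the long axis of the tank, y along the short axis, z upward.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "TankGeometry",
    "Trial",
    "TrialSchedule",
    "WindowSpec",
    "ResponseGains",
    "BehaviorModel",
    "AnalysisParams",
    "ScheduleSpec",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "ScheduleError",
    "CS_PLUS",
    "CS_MINUS",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"


class ScheduleError(ValueError):
    """Raised when a trial schedule is inconsistent with the analysis windows."""


@dataclass
class TankGeometry:
    """Physical coordinate frame of the fish compartment.

    Defaults describe the front compartment of the training tank: a
    20 x 9.5 cm footprint with a ~6 cm water column, a floating feeding
    ring (diameter ~4.5 cm) in the front corner, a water inflow tube at
    half-height of the water column near the front wall, and a rectangular
    reward zone bounding the feeding ring that spans the short axis and
    covers about one third of the footprint.
    """

    length_cm: float = 20.0
    width_cm: float = 9.5
    water_height_cm: float = 6.0
    ring_center: tuple[float, float] = (2.5, 2.4)
    ring_radius_cm: float = 2.25
    inflow_pos: tuple[float, float, float] = (0.3, 4.75, 3.0)
    # (x_min, y_min, x_max, y_max); default set in __post_init__ from footprint
    reward_zone: tuple[float, float, float, float] | None = None
    surface_threshold_frac: float = 0.70

    def __post_init__(self) -> None:
        if min(self.length_cm, self.width_cm, self.water_height_cm) <= 0:
            raise ValueError("tank dimensions must be positive")
        if self.reward_zone is None:
            self.reward_zone = (0.0, 0.0, self.length_cm / 3.0, self.width_cm)
        if not (0.0 < self.surface_threshold_frac < 1.0):
            raise ValueError("surface_threshold_frac must lie in (0, 1)")
        cx, cy = self.ring_center
        if not (0 <= cx <= self.length_cm and 0 <= cy <= self.width_cm):
            raise ValueError("ring_center must lie inside the tank footprint")
        ix, iy, iz = self.inflow_pos
        if not (0 <= ix <= self.length_cm and 0 <= iy <= self.width_cm and 0 <= iz <= self.water_height_cm):
            raise ValueError("inflow_pos must lie inside the tank")
        x0, y0, x1, y1 = self.reward_zone
        if not (x1 > x0 and y1 > y0):
            raise ValueError("reward_zone must have positive extent")
        # the reward zone spans the short axis and covers roughly 1/3 of
        # the footprint; enforce loosely so nonstandard tanks still load
        area_frac = (x1 - x0) * (y1 - y0) / (self.length_cm * self.width_cm)
        if not (0.15 <= area_frac <= 0.60):
            raise ValueError(
                f"reward_zone covers {area_frac:.2f} of the footprint; expected roughly one third"
            )

    @property
    def surface_threshold_cm(self) -> float:
        """Absolute z of the surface-sampling threshold."""
        return self.surface_threshold_frac * self.water_height_cm


@dataclass
class Trial:
    index: int
    day: int
    label: str  # CS+ / CS- (conditioned schedules) or odor id (unpaired)
    onset_s: float
    food_delay_s: float = 30.0
    odor: str | None = None
    rewarded: bool = False


@dataclass
class TrialSchedule:
    """Ordered odor-presentation trials.

    The default protocol delivers nine rewarded (CS+) and nine unrewarded
    (CS-) odor presentations per day in alternating order, at 20-min
    inter-trial intervals, with food arriving 30 s after CS+ onset.
    """

    trials: list[Trial]
    iti_s: float = 1200.0
    trials_per_day_per_stimulus: int = 9

    def __post_init__(self) -> None:
        onsets = [tr.onset_s for tr in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ScheduleError("trial onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> list[str]:
        return [tr.label for tr in self.trials]

    @property
    def onsets(self) -> list[float]:
        return [tr.onset_s for tr in self.trials]

    def with_labels(self, labels: Sequence[str]) -> "TrialSchedule":
        """Return a copy with trial labels replaced (e.g. odor -> CS assignment)."""
        if len(labels) != len(self.trials):
            raise ValueError("label sequence length must match trial count")
        trials = [dataclasses.replace(tr, label=lab) for tr, lab in zip(self.trials, labels)]
        return TrialSchedule(trials, self.iti_s, self.trials_per_day_per_stimulus)

    @classmethod
    def alternating(
        cls,
        n_days: int = 9,
        trials_per_day_per_stimulus: int = 9,
        iti_s: float = 1200.0,
        first_onset_s: float | None = None,
        food_delay_s: float = 30.0,
        first_label: str = CS_PLUS,
        labels: tuple[str, str] = (CS_PLUS, CS_MINUS),
    ) -> "TrialSchedule":
        """Build the standard alternating CS+/CS- protocol.

        Consecutive onsets are separated by ``iti_s``; the first onset
        defaults to one inter-trial interval after recording start so the
        pre-stimulus analysis windows are always covered.
        """
        if first_onset_s is None:
            first_onset_s = iti_s
        a, b = labels
        if first_label not in labels:
            raise ValueError("first_label must be one of labels")
        order = (a, b) if first_label == a else (b, a)
        trials: list[Trial] = []
        k = 0
        for day in range(1, n_days + 1):
            for j in range(2 * trials_per_day_per_stimulus):
                lab = order[j % 2]
                trials.append(
                    Trial(
                        index=k,
                        day=day,
                        label=lab,
                        onset_s=first_onset_s + k * iti_s,
                        food_delay_s=food_delay_s,
                        rewarded=(lab == CS_PLUS),
                    )
                )
                k += 1
        return cls(trials, iti_s=iti_s, trials_per_day_per_stimulus=trials_per_day_per_stimulus)


@dataclass
class WindowSpec:
    """The three peri-stimulus analysis windows.

    ``baseline_s`` ends at odor onset; the response window runs from onset
    to food delivery; the reference window immediately precedes the baseline
    window and has the same length as the response window, so reference and
    response are equidistant from the baseline window.
    """

    baseline_s: float = 30.0
    response_s: float = 30.0
    reference_s: float | None = None

    def __post_init__(self) -> None:
        if self.reference_s is None:
            self.reference_s = self.response_s
        if abs(self.reference_s - self.response_s) > 1e-9:
            raise ValueError("reference window must have the same length as the response window")
        if min(self.baseline_s, self.response_s) <= 0:
            raise ValueError("window lengths must be positive")

    @property
    def span_before_s(self) -> float:
        """Coverage required before odor onset (reference + baseline)."""
        return self.baseline_s + self.reference_s

    @property
    def preodor_shift_s(self) -> float:
        """Offset that moves the response window fully in front of odor onset."""
        return -(self.baseline_s + self.response_s)


@dataclass
class ResponseGains:
    """Full-strength (saturated) magnitudes of the six appetitive components.

    speed_cms     additive increase of mean swimming speed (cm/s)
    zlevel_cm     upward shift of mean position in the water column (cm)
    area          attraction weight toward the feeding ring (0..1)
    surface_hz    surface-sampling event rate during the response (events/s)
    inflow        attraction weight toward the inflow tube (0..1)
    circling      fractional suppression of stereotyped circling (0..1)
    """

    speed_cms: float = 0.20
    zlevel_cm: float = 0.15
    area: float = 0.08
    surface_hz: float = 0.020
    inflow: float = 0.035
    circling: float = 0.15

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"response gain {f.name} must be >= 0")

    @classmethod
    def zero(cls) -> "ResponseGains":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "ResponseGains":
        return ResponseGains(*(getattr(self, f.name) * factor for f in dataclasses.fields(self)))


@dataclass
class BehaviorModel:
    """Generative model of single-fish swimming during conditioning.

    Spontaneous behavior is wall-following circling at
    ``baseline_circle_freq_hz`` (the locomotor rhythm sits in the
    0.029-0.146 Hz band) with stochastic speed and amplitude perturbations.
    During response windows the six appetitive components are expressed with
    strength ``g(k) = 1 - exp(-learning_rate * k)`` on the k-th trial of a
    stimulus class, scaled by ``cs_minus_gain_frac`` for the unrewarded odor.
    The contribution of the components varies strongly between trials:
    each trial's response is scaled by a random gamma amplitude with mean 1
    and coefficient of variation ``trial_amplitude_cv``. Surface sampling
    also occurs spontaneously at the low rate ``spont_surface_hz``.
    """

    baseline_circle_freq_hz: float = 0.05
    baseline_speed_cms: float = 2.0
    response_gains: ResponseGains = field(default_factory=ResponseGains)
    learning_rate: float = 0.125
    cs_minus_gain_frac: float = 0.10
    noise_sd: float = 0.15
    spont_surface_hz: float = 0.015
    trial_amplitude_cv: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_circle_freq_hz <= 0:
            raise ValueError("baseline_circle_freq_hz must be positive")
        if not (0.0 <= self.cs_minus_gain_frac <= 1.0):
            raise ValueError("cs_minus_gain_frac must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spont_surface_hz < 0:
            raise ValueError("spont_surface_hz must be >= 0")
        if self.trial_amplitude_cv < 0:
            raise ValueError("trial_amplitude_cv must be >= 0")


@dataclass
class AnalysisParams:
    """Constants of the quantitative behavior analysis."""

    fps: float = 30.0
    band_hz: tuple[float, float] = (0.029, 0.146)
    circling_window_s: float = 30.0
    tukey_alpha: float = 0.25
    median_window: int = 5
    n_last: int = 12
    max_gap_frames: int = 10
    x_consistency_cm: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band_hz must be an increasing pair of positive frequencies")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be a positive odd integer")


@dataclass
class ScheduleSpec:
    """Protocol-level description of the trial schedule (serializable)."""

    n_days: int = 9
    trials_per_day_per_stimulus: int = 9
    iti_s: float = 1200.0
    first_onset_s: float | None = None
    food_delay_s: float = 30.0

    def build(self, first_label: str = CS_PLUS) -> TrialSchedule:
        return TrialSchedule.alternating(
            n_days=self.n_days,
            trials_per_day_per_stimulus=self.trials_per_day_per_stimulus,
            iti_s=self.iti_s,
            first_onset_s=self.first_onset_s,
            food_delay_s=self.food_delay_s,
            first_label=first_label,
        )


@dataclass
class ExperimentConfig:
    """Bundle of all configuration needed to run the pipeline end to end."""

    geometry: TankGeometry = field(default_factory=TankGeometry)
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    windows: WindowSpec = field(default_factory=WindowSpec)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    model: BehaviorModel = field(default_factory=BehaviorModel)


_TUPLE_FIELDS = {
    "ring_center": 2,
    "inflow_pos": 3,
    "reward_zone": 4,
    "band_hz": 2,
}


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            v = _to_dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def _from_dict(cls, data: dict, path: str = ""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section '{path or cls.__name__}' must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key '{path + key}'")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        v = data[name]
        sub = _NESTED.get((cls, name))
        if sub is not None:
            v = _from_dict(sub, v, path=f"{path}{name}.")
        elif name in _TUPLE_FIELDS and v is not None:
            v = tuple(v)
            if len(v) != _TUPLE_FIELDS[name]:
                raise ValueError(f"config key '{path + name}' must have {_TUPLE_FIELDS[name]} entries")
        kwargs[name] = v
    return cls(**kwargs)


_NESTED = {
    (ExperimentConfig, "geometry"): TankGeometry,
    (ExperimentConfig, "schedule"): ScheduleSpec,
    (ExperimentConfig, "windows"): WindowSpec,
    (ExperimentConfig, "analysis"): AnalysisParams,
    (ExperimentConfig, "model"): BehaviorModel,
    (BehaviorModel, "response_gains"): ResponseGains,
}


def config_to_dict(config: ExperimentConfig) -> dict:
    return _to_dict(config)


def config_from_dict(data: dict | None) -> ExperimentConfig:
    return _from_dict(ExperimentConfig, data or {})


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file.

    An empty file yields the full set of protocol defaults (e.g. circling
    band 0.029-0.146 Hz, surface threshold 0.70, ITI 1200 s). Unknown keys
    are rejected with an error naming the key.
    """
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
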