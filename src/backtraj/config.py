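"""Configuration types for the cohort model, simulator and pipeline.

Defaults encode the study conditions of a two-center large-MCA-stroke
cohort followed through 192 hours from admission: per-variable sampling
cadences, outcome definitions (midline shift >=5 mm, pineal gland shift
>4 mm, decompressive hemicraniectomy), and the event-anchored biomarker
signatures used to parameterize the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Any

import yaml

HORIZON_H = 192.0
WINDOW_H = 72.0

MLS5 = "mls5"
PGS4 = "pgs4"
DHC = "dhc"
OUTCOMES = (MLS5, PGS4, DHC)

#: variables whose between-scan change is legitimately large; the 25%-change
#: outlier rule is never applied to these.
RADIOGRAPHIC_VARIABLES = frozenset({"mls", "pgs"})


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class VariableSpec:
    """A longitudinal variable and how it is gridded.

    Parameters
    ----------
    name : str
        Lowercase variable identifier used in the measurements table.
    kind : {"continuous", "dichotomous"}
        Continuous variables are linearly interpolated; dichotomous ones
        switch value at the midpoint between differing nodes.
    units : str
        Display units.
    grid_step_h : int
        Width of the regularization bins in hours; must divide 24.
    plausible_range : tuple of float
        (lo, hi) physiologic bounds, used for simulation clipping.
    """

    name: str
    kind: Literal["continuous", "dichotomous"] = "continuous"
    units: str = ""
    grid_step_h: int = 1
    plausible_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.grid_step_h not in (1, 2, 6, 12, 24):
            raise ConfigError(
                f"VariableSpec.grid_step_h for {self.name!r}: {self.grid_step_h} "
                "not in {1, 2, 6, 12, 24}"
            )
        lo, hi = self.plausible_range
        if not lo < hi:
            raise ConfigError(f"VariableSpec.plausible_range for {self.name!r}: lo >= hi")
        if self.kind not in ("continuous", "dichotomous"):
            raise ConfigError(f"VariableSpec.kind for {self.name!r}: {self.kind!r}")


@dataclass(frozen=True)
class GapSpec:
    """Log-normal inter-measurement gap distribution, given as the gap
    median and quartiles in hours (the scale the cadence tables report)."""

    median_h: float
    q25_h: float
    q75_h: float

    def __post_init__(self) -> None:
        if not (0 < self.q25_h <= self.median_h <= self.q75_h):
            raise ConfigError(f"GapSpec: need 0 < q25 <= median <= q75, got {self}")


@dataclass(frozen=True)
class Signature:
    """Event-anchored pre-outcome drift of a marker.

    The marker sits at a patient-level baseline and ramps linearly by
    ``net_change`` over the ``onset_lag_h`` hours preceding the latent
    event time, i.e. Y(t) = b_i + net_change * clip((t - (T* - L)) / L, 0, 1)
    plus measurement noise.
    """

    baseline_mean: float
    baseline_sd_between_patients: float
    onset_lag_h: float
    net_change: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not 0 < self.onset_lag_h <= 72:
            raise ConfigError(f"Signature.onset_lag_h must be in (0, 72], got {self.onset_lag_h}")
        if self.noise_sd < 0:
            raise ConfigError("Signature.noise_sd must be >= 0")
        if self.baseline_sd_between_patients < 0:
            raise ConfigError("Signature.baseline_sd_between_patients must be >= 0")


def default_variable_specs() -> dict[str, VariableSpec]:
    """Grid steps: hourly for blood pressure / heart rate, 2 h temperature,
    6 h glucose and sodium, 12 h creatinine and the radiographic shifts,
    24 h white blood cell count."""
    specs = [
        VariableSpec("glucose", units="mg/dL", grid_step_h=6, plausible_range=(20, 800)),
        VariableSpec("sodium", units="mEq/L", grid_step_h=6, plausible_range=(110, 180)),
        VariableSpec("creatinine", units="mg/dL", grid_step_h=12, plausible_range=(0.1, 15)),
        VariableSpec("wbc", units="K/uL", grid_step_h=24, plausible_range=(0.5, 50)),
        VariableSpec("sbp", units="mmHg", grid_step_h=1, plausible_range=(50, 260)),
        VariableSpec("hr", units="bpm", grid_step_h=1, plausible_range=(20, 200)),
        VariableSpec("temp", units="degF", grid_step_h=2, plausible_range=(92, 107)),
        VariableSpec("mls", units="mm", grid_step_h=12, plausible_range=(0, 30)),
        VariableSpec("pgs", units="mm", grid_step_h=12, plausible_range=(0, 20)),
    ]
    return {s.name: s for s in specs}


def default_gaps() -> dict[str, GapSpec]:
    """Median [q25, q75] inter-measurement gaps: labs from the cohort's
    cadence table (glucose 5.4, sodium 8.9, creatinine 11.3, WBC 20.9 h);
    vitals roughly hourly, temperature two-hourly, imaging 14.5 h."""
    return {
        "glucose": GapSpec(5.4, 2.3, 8.3),
        "sodium": GapSpec(8.9, 6.0, 19.6),
        "creatinine": GapSpec(11.3, 6.6, 22.9),
        "wbc": GapSpec(20.9, 9.3, 24.4),
        "sbp": GapSpec(1.0, 0.8, 1.4),
        "hr": GapSpec(1.0, 0.8, 1.4),
        "temp": GapSpec(2.0, 1.5, 2.8),
        "imaging": GapSpec(14.5, 5.7, 23.9),
    }


def default_signatures() -> dict[str, Signature]:
    """Signature amplitudes mirror the observed pre-outcome drifts:
    WBC +1 K/uL over 72 h, temperature +0.5 degF over 24 h, sodium
    +2 mEq/L over 24 h, heart rate -7 bpm over 24 h; glucose, creatinine
    and SBP flat."""
    return {
        "wbc": Signature(10.0, 2.5, 72.0, 1.0, 0.8),
        "temp": Signature(98.5, 0.4, 24.0, 0.5, 0.3),
        "sodium": Signature(138.0, 3.0, 24.0, 2.0, 1.5),
        "hr": Signature(75.0, 10.0, 24.0, -7.0, 5.0),
        "glucose": Signature(146.0, 40.0, 24.0, 0.0, 22.0),
        "creatinine": Signature(1.0, 0.3, 24.0, 0.0, 0.1),
        "sbp": Signature(135.0, 15.0, 24.0, 0.0, 10.0),
    }


def _check_dist(dist: Mapping[str, Any], field_name: str) -> None:
    fam = dist.get("family")
    if fam == "weibull":
        if not (dist.get("shape", 0) > 0 and dist.get("scale", 0) > 0):
            raise ConfigError(f"{field_name}: weibull needs positive shape and scale")
    elif fam == "exponential":
        if not dist.get("scale", 0) > 0:
            raise ConfigError(f"{field_name}: exponential needs positive scale")
    elif fam == "lognormal":
        if "median" in dist:
            if not (0 < dist.get("q25", 0) <= dist["median"] <= dist.get("q75", 0)):
                raise ConfigError(f"{field_name}: lognormal needs 0 < q25 <= median <= q75")
        elif not dist.get("sigma", -1) >= 0:
            raise ConfigError(f"{field_name}: lognormal needs mu/sigma or median/q25/q75")
    elif fam == "degenerate":
        if "value" not in dist:
            raise ConfigError(f"{field_name}: degenerate needs a value")
    elif fam == "uniform":
        if not dist.get("low", 0) < dist.get("high", 0):
            raise ConfigError(f"{field_name}: uniform needs low < high")
    else:
        raise ConfigError(f"{field_name}: unknown family {fam!r}")


@dataclass
class SimConfig:
    """Parameters of the joint longitudinal-survival generator.

    Event, death and discharge times are drawn independently; the observed
    patient state is the earliest of the three truncated at ``horizon_h``.
    Distribution dictionaries take ``{"family": ..., ...}`` with families
    weibull(shape, scale), exponential(scale), lognormal(median, q25, q75)
    or (mu, sigma), degenerate(value), uniform(low, high); times in hours.
    """

    n_patients: int = 635
    horizon_h: float = HORIZON_H
    event_time_dist: dict = field(
        default_factory=lambda: {"family": "weibull", "shape": 0.75, "scale": 280.0}
    )
    death_time_dist: dict = field(
        default_factory=lambda: {"family": "weibull", "shape": 1.1, "scale": 520.0}
    )
    discharge_time_dist: dict = field(
        default_factory=lambda: {"family": "lognormal", "median": 240.0, "q25": 150.0, "q75": 380.0}
    )
    variable_specs: dict[str, VariableSpec] = field(default_factory=default_variable_specs)
    signatures: dict[str, Signature] = field(default_factory=default_signatures)
    sampling_gap_dist: dict[str, GapSpec] = field(default_factory=default_gaps)
    # radiographic / procedural structure
    pgs_delay_factor: float = 1.35   # latent PGS>4 crossing at factor * T*
    scan_noise_sd_mm: float = 0.25
    dhc_fraction: float = 0.24       # of patients whose latent MLS crossing is in-horizon
    dhc_lag_dist: dict = field(
        default_factory=lambda: {"family": "lognormal", "median": 10.0, "q25": 5.0, "q75": 20.0}
    )
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("SimConfig.n_patients must be >= 1")
        if self.horizon_h <= 0:
            raise ConfigError("SimConfig.horizon_h must be > 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError("SimConfig.artifact_rate must be in [0, 1]")
        if not 0.0 <= self.dhc_fraction <= 1.0:
            raise ConfigError("SimConfig.dhc_fraction must be in [0, 1]")
        _check_dist(self.event_time_dist, "SimConfig.event_time_dist")
        _check_dist(self.death_time_dist, "SimConfig.death_time_dist")
        _check_dist(self.discharge_time_dist, "SimConfig.discharge_time_dist")
        _check_dist(self.dhc_lag_dist, "SimConfig.dhc_lag_dist")
        for name in self.signatures:
            if name not in self.variable_specs:
                raise ConfigError(f"SimConfig.signatures: no VariableSpec for {name!r}")
        for name in self.signatures:
            if name not in self.sampling_gap_dist:
                raise ConfigError(f"SimConfig.sampling_gap_dist: missing gap spec for {name!r}")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> clean -> adjudicate ->
    regularize -> incidence -> backward -> figures)."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None          # read cohort CSVs instead of simulating
    outcomes: tuple[str, ...] = OUTCOMES
    horizon_h: float = HORIZON_H
    window_h: float = WINDOW_H
    flag_policy: Literal["flag_only", "drop_flagged"] = "flag_only"
    min_n: int = 5
    death_as_censoring: bool = True       # convention for the censoring KM used by IPCW
    variables: tuple[str, ...] = ("wbc", "temp", "sodium", "hr", "glucose", "creatinine", "sbp")
    outdir: str = "backtraj_out"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ConfigError(f"PipelineConfig.outcomes: unknown {sorted(unknown)}")
        if self.flag_policy not in ("flag_only", "drop_flagged"):
            raise ConfigError(
                f"PipelineConfig.flag_policy: {self.flag_policy!r} is not "
                "'flag_only' or 'drop_flagged'"
            )
        for v in self.variables:
            if v not in self.sim.variable_specs:
                raise ConfigError(f"PipelineConfig.variables: no spec for {v!r}")


def _dataclass_from(cls, data: Mapping[str, Any]):
    return cls(**data)


def load_sim_config(path: str) -> SimConfig:
    """Load a SimConfig from YAML/JSON; nested variable/gap/signature maps
    are rebuilt into their dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "variable_specs" in raw:
        raw["variable_specs"] = {
            k: VariableSpec(name=k, **{kk: (tuple(vv) if kk == "plausible_range" else vv)
                                       for kk, vv in v.items() if kk != "name"})
            for k, v in raw["variable_specs"].items()
        }
    if "signatures" in raw:
        raw["signatures"] = {k: Signature(**v) for k, v in raw["signatures"].items()}
    if "sampling_gap_dist" in raw:
        raw["sampling_gap_dist"] = {k: GapSpec(**v) for k, v in raw["sampling_gap_dist"].items()}
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
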