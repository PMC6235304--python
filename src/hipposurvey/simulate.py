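"""Synthetic drone-survey generator for hippo school counting experiments.

Generates complete surveys with the statistical structure the downstream
analysis assumes: a set of flights over one resident school, photos
stratified across flight-height classes with sun/cloud/wind covariates,
a panel of observers of mixed experience, per-unit counts drawn from
crossed-random-intercept binomial logistic models, and time-stamped ground
positions of surfacing individuals for the frame-overlay abundance stage.

Default parameter values reproduce the design of an eight-flight survey of
a ~60-animal school: 252 photos (42 per height class in 40..140 m), eight
observers (three experienced, five novice), 2016 photo-by-observer
experimental units, and generating logistic coefficients equal to the
fitted detection-rate and level-of-certainty models of that survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .glmm import encode_covariates

__all__ = [
    "GlmmTruth",
    "FlightPlanRow",
    "SimulationConfig",
    "FramePointSet",
    "generate_design",
    "generate_counts",
    "generate_frames",
    "simulate_survey",
]

# Fitted survey models used as default generating truth.  Coefficients act on
# the encoded covariates (standardized height/wind, regrouped binary cloud and
# sun, raw 0/1 experience where 0 = experienced, 1 = novice).  Wind is 0: it
# was dropped from both fitted models.
DR_TRUTH = {
    "intercept": 2.36659,
    "height": -0.07145,
    "wind": 0.0,
    "cloud": -0.74768,
    "sun": -0.61517,
    "experience": -0.51469,
}
DR_RANDOM_SD = {"flight": 0.4414, "photo": 0.3142, "observer": 0.2101}

LC_TRUTH = {
    "intercept": 2.79614,
    "height": -0.11748,
    "wind": 0.0,
    "cloud": -0.48934,
    "sun": -0.27579,
    "experience": -0.93356,
}
LC_RANDOM_SD = {"flight": 0.1833, "photo": 0.2618, "observer": 0.5618}


@dataclass(frozen=True)
class GlmmTruth:
    """Generating coefficients and random-effect SDs for one logistic model."""

    coefficients: dict = field(default_factory=dict)
    random_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.random_sd.items():
            if v < 0:
                raise ValueError(f"random-effect SD for {k} must be >= 0")


@dataclass(frozen=True)
class FlightPlanRow:
    """Flight-level design: covariates constant within the flight.

    ``n_photos`` is how many of the selected photos come from this flight;
    ``true_total`` the number of hippos present during the flight.
    """

    wind_ms: int
    cloud_class: int
    n_photos: int
    true_total: int
    takeoff_min: float  # minutes after the earliest takeoff of the survey

    def __post_init__(self):
        if not 1 <= self.wind_ms <= 5:
            raise ValueError("wind_ms must be an integer in [1, 5]")
        if self.cloud_class not in (0, 1, 2):
            raise ValueError("cloud_class must be in {0, 1, 2}")
        if self.true_total <= 0:
            raise ValueError("true_total must be > 0")


# Default flight plan.  Photo counts per flight are chosen so that the
# photo-level wind marginal is {1: 32, 2: 101, 3: 36, 4: 18, 5: 65} and the
# cloud marginal {0: 18, 1: 169, 2: 65} exactly, while wind and cloud stay
# constant within a flight.  True totals are the per-flight school estimates
# of the reference survey (population max 61).
DEFAULT_FLIGHTS = (
    FlightPlanRow(1, 1, 32, 57, 205.0),
    FlightPlanRow(2, 0, 18, 60, 70.0),
    FlightPlanRow(2, 1, 41, 58, 285.0),
    FlightPlanRow(2, 1, 42, 61, 5.0),
    FlightPlanRow(3, 1, 36, 59, 75.0),
    FlightPlanRow(4, 1, 18, 55, 35.0),
    FlightPlanRow(5, 2, 33, 57, 120.0),
    FlightPlanRow(5, 2, 32, 57, 0.0),
)


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic survey.

    The defaults are the reference-survey conditions; randomness is entirely
    driven by the ``seed`` (or an externally supplied Generator), so a fixed
    config + seed reproduces the survey byte-for-byte.
    """

    flights: tuple = DEFAULT_FLIGHTS
    height_classes: tuple = (40, 60, 80, 100, 120, 140)
    photos_per_height: int = 42
    n_observers: int = 8
    n_experienced: int = 3
    # photo-level sun-reflection marginal: counts of classes 0, 1, 2
    sun_counts: tuple = (187, 54, 11)
    # SD (minutes) of the noise added to acquisition time when ranking photos
    # for sun-class assignment; smaller = stronger sun/time correlation
    sun_time_noise_min: float = 60.0
    flight_duration_min: float = 75.0
    dr: GlmmTruth = field(
        default_factory=lambda: GlmmTruth(dict(DR_TRUTH), dict(DR_RANDOM_SD))
    )
    lc: GlmmTruth = field(
        default_factory=lambda: GlmmTruth(dict(LC_TRUTH), dict(LC_RANDOM_SD))
    )
    # rate of spurious extra detections per unit (emulates over-counting,
    # which lets the detection rate exceed 1); off by default
    false_positive_rate: float = 0.0
    # frame-overlay stage
    n_frames: int = 15
    # 15 frames at this spacing span ~25 min, beyond the longest dive
    frame_interval_s: float = 107.5
    dive_duration_s: tuple = (180.0, 300.0)
    surface_duration_s: tuple = (120.0, 240.0)
    max_speed_ms: float = 0.002
    min_separation_m: float = 12.0
    pool_extent_m: tuple = (250.0, 80.0)
    seed: int = 0

    # -- derived ---------------------------------------------------------
    @property
    def n_flights(self) -> int:
        return len(self.flights)

    @property
    def n_photos(self) -> int:
        return self.photos_per_height * len(self.height_classes)

    @property
    def population_total(self) -> int:
        """School size: the maximum of the per-flight totals."""
        return max(f.true_total for f in self.flights)

    def validate(self) -> None:
        if self.n_observers <= 0:
            raise ValueError("n_observers must be > 0")
        if not 0 <= self.n_experienced <= self.n_observers:
            raise ValueError("n_experienced must be in [0, n_observers]")
        if self.photos_per_height <= 0:
            raise ValueError("photos_per_height must be > 0")
        flight_total = sum(f.n_photos for f in self.flights)
        if flight_total != self.n_photos:
            raise ValueError(
                f"flight plan assigns {flight_total} photos but the height "
                f"stratification requires {self.n_photos} "
                f"({self.photos_per_height} x {len(self.height_classes)})"
            )
        if sum(self.sun_counts) != self.n_photos:
            raise ValueError("sun_counts must sum to the total photo count")
        if not 0 <= self.false_positive_rate:
            raise ValueError("false_positive_rate must be >= 0")
        if self.dive_duration_s[0] > self.dive_duration_s[1]:
            raise ValueError("dive_duration_s bounds out of order")
        if self.surface_duration_s[0] <= 0:
            raise ValueError("surfaced durations must be positive")
        if self.max_speed_ms < 0:
            raise ValueError("max_speed_ms must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flights"] = [asdict(f) for f in self.flights]
        return d


@dataclass
class FramePointSet:
    """Ground positions of surfaced animals in one geo-referenced frame."""

    frame_index: int
    timestamp: float  # seconds since first frame
    points: np.ndarray  # (n, 2) metres, common ground frame
    ids: np.ndarray | None = None  # synthetic truth only

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("frame points must be finite")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.points):
                raise ValueError("ids and points length mismatch")


def _rng(config: SimulationConfig, rng: np.random.Generator | None, stream: int):
    """Per-stage generator: independent streams derived from one seed."""
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_design(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the flight, photo and observer tables of one survey.

    Photos are stratified exactly equally across height classes.  Within the
    stratification, photos are dealt to flights by shuffling the multiset of
    flight labels (each flight appearing ``n_photos`` times), so per-flight
    photo counts — and hence the photo-level wind and cloud marginals — are
    exact.  Sun classes are the configured multiset assigned by noisy
    acquisition-time rank: later photos get the higher classes, which
    reproduces the positive sun/time correlation of real morning surveys.

    Returns ``(flights, photos, observers)`` DataFrames.
    """
    config = config or SimulationConfig()
    config.validate()
    gen = _rng(config, rng, stream=1)

    flights = pd.DataFrame(
        {
            "flight_id": np.arange(1, config.n_flights + 1),
            "takeoff_min": [f.takeoff_min for f in config.flights],
            "wind_ms": [f.wind_ms for f in config.flights],
            "cloud_class": [f.cloud_class for f in config.flights],
            "true_total": [f.true_total for f in config.flights],
        }
    )

    # deal flight labels to height classes: exact stratification both ways
    labels = np.repeat(flights["flight_id"].to_numpy(),
                       [f.n_photos for f in config.flights])
    gen.shuffle(labels)
    heights = np.repeat(config.height_classes, config.photos_per_height)

    takeoff = flights.set_index("flight_id")["takeoff_min"]
    # acquisition time: minutes after the survey's first takeoff
    within = gen.uniform(0.0, config.flight_duration_min, size=config.n_photos)
    time_min = takeoff.loc[labels].to_numpy() + within

    photos = pd.DataFrame(
        {
            "photo_id": np.arange(1, config.n_photos + 1),
            "flight_id": labels,
            "time_min": time_min,
            "height_m": heights,
        }
    )

    # sun classes: exact multiset, ordered by noisy time rank
    noisy = time_min + gen.normal(0.0, config.sun_time_noise_min, config.n_photos)
    order = np.argsort(noisy, kind="stable")
    sun = np.empty(config.n_photos, dtype=int)
    multiset = np.repeat([0, 1, 2], config.sun_counts)
    sun[order] = multiset
    photos["sun_class"] = sun

    observers = pd.DataFrame(
        {
            "observer_id": np.arange(1, config.n_observers + 1),
            # 0 = experienced, 1 = novice
            "experienced": [
                0 if i < config.n_experienced else 1
                for i in range(config.n_observers)
            ],
        }
    )
    return flights, photos, observers


def _linear_predictor(units: pd.DataFrame, truth: GlmmTruth, response: str,
                      effects: dict) -> np.ndarray:
    """Logit-scale mean + random intercepts for each unit."""
    X, names = encode_covariates(units, response=response)
    beta = np.array([truth.coefficients.get(n, 0.0) for n in names])
    eta = X @ beta
    for factor, col in (("flight", "flight_id"), ("photo", "photo_id"),
                        ("observer", "observer_id")):
        eta += units[col].map(effects[factor]).to_numpy()
    return eta


def _draw_effects(levels: np.ndarray, sd: float, gen: np.random.Generator) -> dict:
    return dict(zip(levels, gen.normal(0.0, sd, size=len(levels))))


def generate_counts(
    design: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-unit counts for every photo x observer experimental unit.

    For each unit the number of animals detected is Binomial(true_total,
    p_DR) and the number marked "definite" is Binomial(detected, p_LC),
    where p_DR and p_LC come through the logistic link from the configured
    coefficients plus flight/photo/observer Gaussian random intercepts
    (drawn once per entity and per response).  ``est_pop`` carries the
    per-flight school total, i.e. the denominator the frame-overlay stage
    would supply.

    Returns the unit table with one row per photo x observer.
    """
    config = config or SimulationConfig()
    config.validate()
    gen = _rng(config, rng, stream=2)
    flights, photos, observers = design

    units = (
        photos.merge(flights, on="flight_id")
        .merge(observers, how="cross")
        .sort_values(["photo_id", "observer_id"], ignore_index=True)
    )

    out = units[
        ["photo_id", "flight_id", "observer_id", "height_m", "wind_ms",
         "cloud_class", "sun_class", "experienced", "time_min"]
    ].copy()
    out["est_pop"] = units["true_total"].to_numpy()

    eta = {}
    for name, truth in (("dr", config.dr), ("lc", config.lc)):
        effects = {
            "flight": _draw_effects(flights["flight_id"].to_numpy(),
                                    truth.random_sd.get("flight", 0.0), gen),
            "photo": _draw_effects(photos["photo_id"].to_numpy(),
                                   truth.random_sd.get("photo", 0.0), gen),
            "observer": _draw_effects(observers["observer_id"].to_numpy(),
                                      truth.random_sd.get("observer", 0.0), gen),
        }
        eta[name] = _linear_predictor(out, truth, name, effects)

    from scipy.special import expit

    p_dr = expit(eta["dr"])
    p_lc = expit(eta["lc"])
    detected = gen.binomial(out["est_pop"].to_numpy(), p_dr)
    if config.false_positive_rate > 0:
        detected = detected + gen.poisson(config.false_positive_rate, len(out))
    definite = gen.binomial(detected, p_lc)
    out["n_definite"] = definite
    out["n_possible"] = detected - definite
    return out


def _place_individuals(n: int, config: SimulationConfig,
                       gen: np.random.Generator) -> np.ndarray:
    """Initial positions with minimum pairwise separation (dart throwing)."""
    lx, ly = config.pool_extent_m
    sep2 = config.min_separation_m**2
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        cand = gen.uniform((0, 0), (lx, ly))
        if all(np.sum((cand - p) ** 2) >= sep2 for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 2000 * max(n, 1):
            raise RuntimeError(
                "could not place individuals at the requested separation; "
                "enlarge pool_extent_m or reduce min_separation_m"
            )
    return np.array(pts).reshape(n, 2)


def _surface_schedule(horizon: float, config: SimulationConfig,
                      gen: np.random.Generator) -> list[tuple[float, float]]:
    """Alternating surfaced intervals [(start, end), ...] covering [0, horizon]."""
    lo_s, hi_s = config.surface_duration_s
    lo_d, hi_d = config.dive_duration_s
    # random phase: start somewhere inside a cycle
    t = -gen.uniform(0.0, hi_s + hi_d)
    surfaced = []
    up = gen.random() < 0.5
    while t < horizon:
        dur = gen.uniform(lo_s, hi_s) if up else gen.uniform(lo_d, hi_d)
        if up:
            surfaced.append((t, t + dur))
        t += dur
        up = not up
    return surfaced


def generate_frames(
    true_total: int,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[FramePointSet]:
    """Simulate the frame-overlay stage for one flight.

    Individuals alternate surfaced and dived intervals (dives bounded by
    ``dive_duration_s``) and drift slowly (piecewise-constant velocity,
    speed <= ``max_speed_ms``).  Frames are sampled every
    ``frame_interval_s`` seconds; each contains the ground positions of the
    individuals surfaced at that instant, tagged with true identities.

    With the defaults every animal is surfaced at >= 1 frame instant: the
    minimum surfaced duration exceeds the frame interval and the frame span
    exceeds the maximum dive, which is the coverage guarantee the 15-photo /
    25-minute protocol is designed around.
    """
    config = config or SimulationConfig()
    config.validate()
    if true_total < 0:
        raise ValueError("true_total must be >= 0")
    gen = _rng(config, rng, stream=3)

    span = config.frame_interval_s * (config.n_frames - 1)
    if config.frame_interval_s > config.surface_duration_s[0]:
        import warnings

        warnings.warn(
            "frame interval exceeds the minimum surfaced duration; an animal "
            "may surface and dive entirely between frames (coverage no longer "
            "guaranteed)",
            stacklevel=2,
        )

    pos0 = _place_individuals(true_total, config, gen)
    schedules = [_surface_schedule(span, config, gen) for _ in range(true_total)]
    # one constant velocity per individual; speeds are so low relative to the
    # school spacing that direction changes within a flight are immaterial
    angle = gen.uniform(0, 2 * math.pi, size=max(true_total, 1))
    speed = gen.uniform(0, config.max_speed_ms, size=max(true_total, 1))
    vel = np.column_stack([np.cos(angle), np.sin(angle)]) * speed[:, None]

    frames = []
    for k in range(config.n_frames):
        t = k * config.frame_interval_s
        up = [
            i
            for i in range(true_total)
            if any(a <= t < b for a, b in schedules[i])
        ]
        pts = pos0[up] + vel[up] * t if up else np.empty((0, 2))
        frames.append(
            FramePointSet(frame_index=k, timestamp=t, points=pts,
                          ids=np.array(up, dtype=int))
        )
    return frames


def simulate_survey(
    config: SimulationConfig | None = None,
) -> dict:
    """Run the full generator: design, counts, and per-flight frame stacks.

    Returns a dict with keys ``flights``, ``photos``, ``observers``,
    ``units`` (DataFrames) and ``frames`` (dict flight_id -> list of
    FramePointSet).  All randomness derives from ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    flights, photos, observers = generate_design(config)
    units = generate_counts((flights, photos, observers), config)
    frames = {}
    for i, row in flights.iterrows():
        frng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, int(row["flight_id"])])
        )
        frames[int(row["flight_id"])] = generate_frames(
            int(row["true_total"]), config, rng=frng
        )
    return {
        "flights": flights,
        "photos": photos,
        "observers": observers,
        "units": units,
        "frames": frames,
    }
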