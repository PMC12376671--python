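"""Synthetic cohort and sensor-stream generator.

Generates defecation events with known ground truth so that every
downstream stage — timeline extraction, optical conversion, statistics,
biometric ranking — can be exercised and validated without access to
real recordings.  The generator emulates the statistical structure the
analysis expects of real data:

* stool-dropping durations are log-normal (log-mean 0.694, log-SD 0.932,
  i.e. median about 2 s with a long tail), split into a stable
  per-participant component and within-participant noise at a 3:1
  variance ratio;
* stool thickness is coupled to dropping duration
  (``T = intercept + slope * SDD + noise``, slope 6.68 mm/s), and the
  Bristol stool form group follows from the event's mean thickness
  (thicker stool, lower Bristol score);
* eu-tenesmus durations are log-normal truncated to [3.6, 301.7] s with
  a gender-specific location (female mean ≈ 115 s, male ≈ 48 s before
  truncation);
* cleansing posture is roughly 50/50 seated/standing and, like the
  urination order, follows a stable per-participant probability;
* every participant keeps habitual values (typical hour of day, first
  stool delay, cleanup time, ...) so that biometric clustering has a
  signal to find.

Each simulated event yields a frame stream (toilet-state labels plus
pixel-level stool detections placed with the package's own optical
calibration), a seat-pressure stream, and an :class:`EventTruth` whose
anchor times satisfy the duration identities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, exp

import numpy as np
import pandas as pd

from .geometry import (
    CalibrationModel,
    calibration_x_for_distance,
    row_from_x,
    transform_coefficient,
    x_from_row,
)
from .records import DROPPED, DROPPING, FrameRecord, PressureRecord, StoolDetection
from .timeline import EventTimeline

__all__ = [
    "HabitProfile",
    "Participant",
    "GeneratorConfig",
    "BiomarkerTruth",
    "DropRecord",
    "EventTruth",
    "SimulatedEvent",
    "CohortDataset",
    "generate_cohort",
    "simulate_event",
    "simulate_dataset",
    "sample_sdd_population",
    "sample_etd_population",
    "BSFS_GROUPS",
    "BSFS_GROUP_STATS",
]

#: Bristol form groups, thickest first.
BSFS_GROUPS: tuple[tuple[int, ...], ...] = ((1, 2), (3,), (4,), (5,), (6, 7))

#: Calibrated per-group thickness (mean_mm, sd_mm) used by the forced-group
#: sampling mode.
BSFS_GROUP_STATS: dict[tuple[int, ...], tuple[float, float]] = {
    (1, 2): (38.5, 6.4),
    (3,): (31.6, 8.7),
    (4,): (23.9, 10.0),
    (5,): (19.5, 7.7),
    (6, 7): (15.8, 3.7),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the generator (defaults = the study conditions)."""

    frame_interval_s: float = 0.1
    pressure_interval_s: float = 0.1
    calibration: CalibrationModel = field(default_factory=CalibrationModel)

    # stool-dropping duration (log scale).  The between-participant log-SD
    # of 0.40 keeps per-participant average dropping durations in the 1-5 s
    # range while the marginal stays log-normal(0.694, 0.932); the stool
    # shape chain (thickness, Bristol group) inherits this moderate person
    # component and so varies day to day within a participant.
    sdd_log_mu: float = 0.694
    sdd_log_sigma: float = 0.932
    sdd_between_log_sd: float = 0.40
    habit_variance_ratio: float = 3.0  # between:within ratio of habit traits

    # thickness coupling T = intercept + slope * SDD + N(0, noise)
    thickness_slope_mm_per_s: float = 6.68
    thickness_intercept_mm: float = 5.1
    thickness_noise_sd_mm: float = 5.0
    thickness_min_mm: float = 2.0

    # Bristol banding on event mean thickness (mm, descending edges);
    # >= edges[0] -> group {1,2}, ..., < edges[3] -> group {6,7}
    bsfs_band_edges_mm: tuple[float, float, float, float] = (35.05, 27.75, 21.7, 17.65)
    force_bsfs_group: tuple[int, ...] | None = None

    # eu-tenesmus: truncated log-normal, gender-specific location
    etd_log_mu_female: float = 4.4558
    etd_log_sigma_female: float = 0.7558
    etd_log_mu_male: float = 3.6890
    etd_log_sigma_male: float = 0.6107
    etd_bounds_s: tuple[float, float] = (3.6, 301.7)

    # stool count and active-phase spread
    sc_poisson_lambda: float = 2.0
    add_gamma_shape: float = 1.66
    add_gamma_scale_s: float = 12.84
    drop_min_gap_s: float = 1.2

    # first-stool delay and cleanup tail (population means / spreads)
    fsd_mean_s: float = 25.0
    fsd_between_sd_s: float = 10.0
    fsd_within_log_sd: float = 0.4
    cleanup_mean_s: float = 29.0
    cleanup_between_sd_s: float = 10.0
    cleanup_within_log_sd: float = 0.3

    # event timing
    hour_range: tuple[int, int] = (6, 22)
    hour_within_sd_h: float = 1.5
    dropping_row_range: tuple[int, int] = (600, 1250)
    dropped_tail_s: float = 0.4
    sit_lead_range_s: tuple[float, float] = (2.0, 8.0)
    max_days: int = 22

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.pressure_interval_s <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.habit_variance_ratio < 0:
            raise ValueError("habit variance ratio must be >= 0")

    @property
    def sdd_between_sd(self) -> float:
        return min(self.sdd_between_log_sd, self.sdd_log_sigma)

    @property
    def sdd_within_sd(self) -> float:
        return (self.sdd_log_sigma**2 - self.sdd_between_sd**2) ** 0.5

    def etd_log_params(self, gender: str) -> tuple[float, float]:
        if gender == "female":
            return self.etd_log_mu_female, self.etd_log_sigma_female
        return self.etd_log_mu_male, self.etd_log_sigma_male

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class HabitProfile:
    """Stable per-participant habits driving the biometric signal."""

    log_sdd_mean: float
    log_sdd_sd: float
    typical_hour: int
    etd_scale: float  # person's median eu-tenesmus, seconds
    seated_cleansing_prob: float
    urination_first_prob: float
    bsfs_weights: tuple[float, ...]
    thickness_noise_sd: float
    fsd_mean: float
    sit_lead: float
    cleanup_tail: float

    def __post_init__(self) -> None:
        if self.log_sdd_sd < 0 or self.thickness_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0 <= self.typical_hour <= 23:
            raise ValueError("typical_hour must lie in 0..23")
        if self.etd_scale <= 0 or self.fsd_mean <= 0:
            raise ValueError("duration scales must be positive")
        for p in (self.seated_cleansing_prob, self.urination_first_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.bsfs_weights) != 7 or any(w < 0 for w in self.bsfs_weights):
            raise ValueError("bsfs_weights must be 7 non-negative weights")
        if abs(sum(self.bsfs_weights) - 1.0) > 1e-9:
            raise ValueError("bsfs_weights must sum to 1")
        if self.sit_lead < 0 or self.cleanup_tail < 0:
            raise ValueError("lead/tail times must be >= 0")


@dataclass(frozen=True)
class Participant:
    participant_id: int
    gender: str
    habit: HabitProfile

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError("gender must be 'male' or 'female'")


@dataclass(frozen=True)
class BiomarkerTruth:
    """Ground-truth values of the 11 biomarkers for one event."""

    DT: int
    SDD: float
    FSD: float
    ADD: float
    TDD: float
    ETD: float
    ST: float
    BSFS: int
    SC: int
    CT: int
    U: int
    participant: int

    def __post_init__(self) -> None:
        if not 0 <= self.DT <= 23:
            raise ValueError("DT must be an hour of day")
        if not 1 <= self.BSFS <= 7:
            raise ValueError("BSFS must lie in 1..7")
        if self.CT not in (0, 1) or self.U not in (0, 1):
            raise ValueError("CT and U are binary")
        if self.ADD > self.TDD + 1e-9 or self.FSD > self.TDD + 1e-9:
            raise ValueError("ADD and FSD cannot exceed TDD")

    def as_dict(self) -> dict:
        return {
            "DT": self.DT, "SDD": self.SDD, "FSD": self.FSD, "ADD": self.ADD,
            "TDD": self.TDD, "ETD": self.ETD, "ST": self.ST, "BSFS": self.BSFS,
            "SC": self.SC, "CT": self.CT, "U": self.U,
            "participant": self.participant,
        }


@dataclass(frozen=True)
class DropRecord:
    start_time: float
    splash_time: float
    pixel_width: int
    pixel_row: int
    drop_location: str


@dataclass(frozen=True)
class EventTruth:
    timeline: EventTimeline
    row: BiomarkerTruth
    per_drop: tuple[DropRecord, ...]


@dataclass(frozen=True)
class SimulatedEvent:
    participant_id: int
    day_index: int
    frames: list[FrameRecord]
    pressures: list[PressureRecord]
    truth: EventTruth


@dataclass
class CohortDataset:
    participants: list[Participant]
    events: list[SimulatedEvent]
    config: GeneratorConfig

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth biomarker table, one row per event."""
        rows = []
        genders = {p.participant_id: p.gender for p in self.participants}
        for ev in self.events:
            d = ev.truth.row.as_dict()
            d["day_index"] = ev.day_index
            d["gender"] = genders[ev.participant_id]
            rows.append(d)
        return pd.DataFrame(rows)


# -- cohort ----------------------------------------------------------------


def _draw_habit(rng: np.random.Generator, gender: str, cfg: GeneratorConfig) -> HabitProfile:
    mu_e, sig_e = cfg.etd_log_params(gender)
    r = cfg.habit_variance_ratio
    between = (r / (1.0 + r)) ** 0.5
    weights = rng.dirichlet(np.full(7, 2.0))
    weights = tuple(float(w) for w in (weights / weights.sum()))
    return HabitProfile(
        log_sdd_mean=cfg.sdd_log_mu + rng.normal(0.0, cfg.sdd_between_sd),
        log_sdd_sd=cfg.sdd_within_sd,
        typical_hour=int(rng.integers(cfg.hour_range[0], cfg.hour_range[1] + 1)),
        etd_scale=exp(mu_e + rng.normal(0.0, sig_e * between)),
        seated_cleansing_prob=float(rng.beta(2.0, 2.0)),
        urination_first_prob=float(rng.beta(2.0, 2.0)),
        bsfs_weights=weights,
        thickness_noise_sd=float(abs(rng.normal(cfg.thickness_noise_sd_mm, 1.0))),
        fsd_mean=float(max(3.0, rng.normal(cfg.fsd_mean_s, cfg.fsd_between_sd_s))),
        sit_lead=float(rng.uniform(*cfg.sit_lead_range_s)),
        cleanup_tail=float(max(5.0, rng.normal(cfg.cleanup_mean_s, cfg.cleanup_between_sd_s))),
    )


def generate_cohort(
    n_participants: int,
    n_female: int,
    seed: int,
    overrides: GeneratorConfig | dict | None = None,
) -> list[Participant]:
    """Draw a cohort of participants with stable habit profiles.

    The first ``n_female`` participant ids are female, the rest male.
    Identical arguments yield identical cohorts.
    """
    if n_participants < 0 or n_female < 0 or n_female > n_participants:
        raise ValueError("need 0 <= n_female <= n_participants")
    cfg = _resolve_config(overrides)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC047]))
    cohort = []
    for pid in range(1, n_participants + 1):
        gender = "female" if pid <= n_female else "male"
        cohort.append(Participant(pid, gender, _draw_habit(rng, gender, cfg)))
    return cohort


def _resolve_config(overrides: GeneratorConfig | dict | None) -> GeneratorConfig:
    if overrides is None:
        return GeneratorConfig()
    if isinstance(overrides, GeneratorConfig):
        return overrides
    return GeneratorConfig(**overrides)


# -- event synthesis -------------------------------------------------------


def _sample_etd(rng, habit: HabitProfile, gender: str, cfg: GeneratorConfig) -> float:
    _, sigma = cfg.etd_log_params(gender)
    within = sigma * (1.0 / (1.0 + cfg.habit_variance_ratio)) ** 0.5
    lo, hi = cfg.etd_bounds_s
    for _ in range(200):
        v = habit.etd_scale * exp(rng.normal(0.0, within))
        if lo <= v <= hi:
            return v
    return float(np.clip(habit.etd_scale, lo, hi))


def _bsfs_from_thickness(
    rng, mean_thickness: float, habit: HabitProfile, cfg: GeneratorConfig
) -> int:
    edges = cfg.bsfs_band_edges_mm
    if mean_thickness >= edges[0]:
        group = (1, 2)
    elif mean_thickness >= edges[1]:
        group = (3,)
    elif mean_thickness >= edges[2]:
        group = (4,)
    elif mean_thickness >= edges[3]:
        group = (5,)
    else:
        group = (6, 7)
    return _pick_within_group(rng, group, habit)


def _pick_within_group(rng, group: tuple[int, ...], habit: HabitProfile) -> int:
    if len(group) == 1:
        return group[0]
    w = np.array([habit.bsfs_weights[g - 1] for g in group], dtype=float)
    w = w / w.sum() if w.sum() > 0 else np.full(len(group), 1.0 / len(group))
    return int(rng.choice(group, p=w))


def simulate_event(
    participant: Participant,
    day_index: int,
    seed: int,
    config: GeneratorConfig | dict | None = None,
) -> tuple[list[FrameRecord], list[PressureRecord], EventTruth]:
    """Synthesize one defecation event: streams plus ground truth.

    Deterministic in ``(participant, day_index, seed, config)``.  The
    truth's anchor times satisfy ADD = tf - t1, TDD = te - t0 and
    ETD = tt - tf exactly; the emitted detection stream reproduces each
    drawn stool-dropping duration to within one frame interval.
    """
    cfg = _resolve_config(config)
    habit = participant.habit
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), participant.participant_id, int(day_index)])
    )

    # --- anchor times ----------------------------------------------------
    hour = float(np.clip(
        habit.typical_hour + rng.normal(0.0, cfg.hour_within_sd_h), 0.05, 22.5
    ))
    t0 = hour * 3600.0
    sit_lead = habit.sit_lead * rng.uniform(0.8, 1.2)

    urination_first = bool(rng.random() < habit.urination_first_prob)
    fsd = max(
        2.0,
        habit.fsd_mean
        * exp(rng.normal(0.0, cfg.fsd_within_log_sd) - cfg.fsd_within_log_sd**2 / 2),
    )
    t1 = t0 + fsd

    sc = 1 + int(rng.poisson(cfg.sc_poisson_lambda))

    # --- stool properties -------------------------------------------------
    if cfg.force_bsfs_group is not None:
        group = tuple(sorted(cfg.force_bsfs_group))
        mean_mm, sd_mm = BSFS_GROUP_STATS[group]
        t_event = max(cfg.thickness_min_mm, rng.normal(mean_mm, sd_mm))
        thickness = np.maximum(
            cfg.thickness_min_mm, t_event + rng.normal(0.0, 1.0, sc)
        )
        sdd = np.maximum(
            0.05,
            (thickness - cfg.thickness_intercept_mm) / cfg.thickness_slope_mm_per_s
            + rng.normal(0.0, 0.15, sc),
        )
        bsfs = _pick_within_group(rng, group, habit)
    else:
        sdd = np.exp(habit.log_sdd_mean + rng.normal(0.0, habit.log_sdd_sd, sc))
        thickness = np.maximum(
            cfg.thickness_min_mm,
            cfg.thickness_intercept_mm
            + cfg.thickness_slope_mm_per_s * sdd
            + rng.normal(0.0, habit.thickness_noise_sd, sc),
        )
        bsfs = _bsfs_from_thickness(rng, float(thickness.mean()), habit, cfg)

    # --- drop placement ---------------------------------------------------
    if sc == 1:
        starts = np.array([t1])
        add = 0.0
    else:
        min_gaps = sdd[:-1] + cfg.drop_min_gap_s
        required = float(min_gaps.sum())
        add = max(float(rng.gamma(cfg.add_gamma_shape, cfg.add_gamma_scale_s)), required)
        extra = (add - required) * rng.dirichlet(np.ones(sc - 1))
        gaps = min_gaps + extra
        starts = t1 + np.concatenate([[0.0], np.cumsum(gaps)])
    tf = float(starts[-1])
    last_splash = tf + float(sdd[-1])

    etd = max(_sample_etd(rng, habit, participant.gender, cfg), float(sdd[-1]) + 1.0)
    tt = tf + etd
    cleanup = max(
        2.0,
        habit.cleanup_tail
        * exp(rng.normal(0.0, cfg.cleanup_within_log_sd) - cfg.cleanup_within_log_sd**2 / 2),
    )
    te = tt + cleanup

    # keep the whole event inside the day
    overshoot = te + 2.0 - 86400.0
    if overshoot > 0:
        t0, t1, tf, tt, te = (v - overshoot for v in (t0, t1, tf, tt, te))
        starts = starts - overshoot
        last_splash -= overshoot

    seated_cleansing = bool(rng.random() < habit.seated_cleansing_prob)
    if seated_cleansing:
        release = rng.uniform(tt + 0.2, te - 0.2)
    else:
        release = rng.uniform(last_splash + 0.3, tt - 0.15)

    # --- pixel-level drop records ----------------------------------------
    cal = cfg.calibration
    locations = list(cal.distances_mm)
    per_drop = []
    drop_pixels = []
    for k in range(sc):
        loc = str(rng.choice(locations))
        x_loc = calibration_x_for_distance(cal.distances_mm[loc], cal)
        row_loc = row_from_x(x_loc, cal)
        coeff_loc = transform_coefficient(x_from_row(row_loc, cal), cal.coeff, cal.variant)
        width_loc = max(1, int(round(thickness[k] / coeff_loc)))
        row_drop = int(rng.integers(*cfg.dropping_row_range))
        coeff_drop = transform_coefficient(x_from_row(row_drop, cal), cal.coeff, cal.variant)
        width_drop = max(1, int(round(thickness[k] / coeff_drop)))
        per_drop.append(
            DropRecord(
                start_time=float(starts[k]),
                splash_time=float(starts[k] + sdd[k]),
                pixel_width=width_loc,
                pixel_row=row_loc,
                drop_location=loc,
            )
        )
        drop_pixels.append((row_drop, width_drop, row_loc, width_loc))

    # --- streams ----------------------------------------------------------
    dt = cfg.frame_interval_s
    t_start = t0 - sit_lead
    n_frames = int(ceil((te + 1.0 - t_start) / dt)) + 1
    urine_start = t0 + 0.3 * fsd if urination_first else None

    detmap: dict[int, list[StoolDetection]] = {}
    for k, rec in enumerate(per_drop):
        row_drop, width_drop, row_loc, width_loc = drop_pixels[k]
        i_start = max(0, ceil((rec.start_time - t_start) / dt - 1e-9))
        i_splash = max(i_start, ceil((rec.splash_time - t_start) / dt - 1e-9))
        for i in range(i_start, max(i_start + 1, i_splash)):
            detmap.setdefault(i, []).append(
                StoolDetection(row_drop, width_drop, DROPPING)
            )
        n_tail = max(1, int(round(cfg.dropped_tail_s / dt)))
        for i in range(i_splash, i_splash + n_tail):
            detmap.setdefault(i, []).append(
                StoolDetection(row_loc, width_loc, DROPPED)
            )

    frames = []
    for i in range(n_frames):
        t = t_start + i * dt
        if t < (urine_start if urine_start is not None else t1):
            state = "clean"
        elif t < t1:
            state = "urine"
        elif t < tt:
            state = "stool"
        elif t < te:
            state = "toilet_paper"
        else:
            state = "clean"
        frames.append(
            FrameRecord(
                time_s=round(t, 4),
                state=state,
                detections=tuple(detmap.get(i, ())),
            )
        )

    dp = cfg.pressure_interval_s
    n_press = int(ceil((te + 2.0 - t_start) / dp)) + 1
    pressures = [
        PressureRecord(
            time_s=round(t_start + i * dp, 4),
            seated=bool(t0 <= t_start + i * dp < release),
        )
        for i in range(n_press)
    ]

    # --- truth ------------------------------------------------------------
    timeline = EventTimeline(
        t0=t0, t1=t1, tf=tf, tt=tt, te=te,
        stool_count=sc,
        urination_first=urination_first,
        cleansing_seated=seated_cleansing,
        urination_observed=urination_first,
    )
    row = BiomarkerTruth(
        DT=int(t0 // 3600),
        SDD=float(np.mean(sdd)),
        FSD=fsd,
        ADD=tf - t1,
        TDD=te - t0,
        ETD=tt - tf,
        ST=float(np.mean(thickness)),
        BSFS=bsfs,
        SC=sc,
        CT=0 if seated_cleansing else 1,
        U=1 if urination_first else 0,
        participant=participant.participant_id,
    )
    truth = EventTruth(timeline=timeline, row=row, per_drop=tuple(per_drop))
    return frames, pressures, truth


def simulate_dataset(
    cohort: list[Participant],
    events_per_participant: int,
    seed: int,
    config: GeneratorConfig | dict | None = None,
) -> CohortDataset:
    """Simulate ``|cohort| x events_per_participant`` events with distinct
    day indices per participant; deterministic under a fixed seed."""
    if events_per_participant < 0:
        raise ValueError("events_per_participant must be >= 0")
    cfg = _resolve_config(config)
    events: list[SimulatedEvent] = []
    for participant in cohort:
        k = events_per_participant
        if k <= cfg.max_days:
            day_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), participant.participant_id, 0xDA75])
            )
            days = sorted(day_rng.choice(cfg.max_days, size=k, replace=False).tolist())
        else:
            days = list(range(k))
        for day in days:
            frames, pressures, truth = simulate_event(participant, day, seed, cfg)
            events.append(
                SimulatedEvent(participant.participant_id, int(day), frames, pressures, truth)
            )
    return CohortDataset(participants=list(cohort), events=events, config=cfg)


# -- lightweight population samplers (no stream synthesis) ------------------


def sample_sdd_population(
    n_draws: int,
    seed: int,
    config: GeneratorConfig | dict | None = None,
    n_participants: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal stool-dropping-duration draws across a fresh cohort.

    Returns ``(values, participant_ids)`` so that callers can account for
    the within-participant clustering when computing standard errors.
    """
    cfg = _resolve_config(config)
    cohort = generate_cohort(
        n_participants, n_participants // 2, seed, overrides=cfg
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5DD]))
    per = int(ceil(n_draws / n_participants))
    values, ids = [], []
    for p in cohort:
        draws = np.exp(p.habit.log_sdd_mean + rng.normal(0.0, p.habit.log_sdd_sd, per))
        values.append(draws)
        ids.append(np.full(per, p.participant_id))
    values = np.concatenate(values)[:n_draws]
    ids = np.concatenate(ids)[:n_draws]
    return values, ids


def sample_etd_population(
    n_per_gender: int,
    seed: int,
    config: GeneratorConfig | dict | None = None,
    n_participants_per_gender: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Eu-tenesmus draws ``(female_values, male_values)`` across fresh cohorts."""
    cfg = _resolve_config(config)
    total = 2 * n_participants_per_gender
    cohort = generate_cohort(total, n_participants_per_gender, seed, overrides=cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE7D]))
    per = int(ceil(n_per_gender / n_participants_per_gender))
    out = {"female": [], "male": []}
    for p in cohort:
        out[p.gender].append(
            [_sample_etd(rng, p.habit, p.gender, cfg) for _ in range(per)]
        )
    female = np.concatenate(out["female"])[:n_per_gender]
    male = np.concatenate(out["male"])[:n_per_gender]
    return female, male
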