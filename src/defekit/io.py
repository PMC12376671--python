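"""File formats, pipeline configuration and the end-to-end analysis run.

One CSV dialect everywhere: comma-separated, UTF-8, header row, ``.``
decimal.  Times are serialized as seconds-of-day floats with four
decimal places (the precision of the hhmmss.ssss frame-name convention).
Frame streams are written as a plain-text listing of hhmmss.ssss frame
names plus a CSV sidecar with one row per detection; pressure streams
and biomarker tables as CSV; truth, reports and the manifest as JSON;
configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biometric, stats
from .geometry import CalibrationModel, format_timestamp
from .records import FrameRecord, PressureRecord, StoolDetection, tag_for_row
from .synthetic import (
    BiomarkerTruth,
    CohortDataset,
    DropRecord,
    EventTruth,
    GeneratorConfig,
    SimulatedEvent,
    generate_cohort,
    simulate_dataset,
)
from .timeline import EventTimeline, extract_event

__all__ = [
    "PipelineConfig",
    "LongitudinalSeries",
    "write_frame_stream",
    "read_frame_stream",
    "write_pressure_stream",
    "read_pressure_stream",
    "write_truth",
    "read_truth",
    "write_dataset",
    "run_pipeline",
    "export_longitudinal",
]

_T4 = "%.4f"


# -- stream formats --------------------------------------------------------


def write_frame_stream(frames: list[FrameRecord], directory: str | Path) -> None:
    """Write a frame stream: ``frame_names.txt`` (hhmmss.ssss listing) and
    the ``frames.csv`` sidecar (time_s, state, n_detections, pixel_row,
    pixel_width), one CSV row per detection (one empty-detection row for
    frames without any)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = [format_timestamp(f.time_s, ".jpeg") for f in frames]
    (directory / "frame_names.txt").write_text("\n".join(names) + "\n")
    rows = []
    for f in frames:
        if f.detections:
            for det in f.detections:
                rows.append(
                    (_T4 % f.time_s, f.state, len(f.detections),
                     det.pixel_row, det.pixel_width)
                )
        else:
            rows.append((_T4 % f.time_s, f.state, 0, "", ""))
    pd.DataFrame(
        rows, columns=["time_s", "state", "n_detections", "pixel_row", "pixel_width"]
    ).to_csv(directory / "frames.csv", index=False)


def read_frame_stream(
    directory: str | Path, waterline_row: int = 1300
) -> list[FrameRecord]:
    df = pd.read_csv(Path(directory) / "frames.csv")
    frames: list[FrameRecord] = []
    for time_s, group in df.groupby("time_s", sort=True):
        dets = []
        for _, r in group.iterrows():
            if int(r["n_detections"]) > 0 and not pd.isna(r["pixel_row"]):
                row = int(r["pixel_row"])
                dets.append(
                    StoolDetection(row, int(r["pixel_width"]), tag_for_row(row, waterline_row))
                )
        state = str(group["state"].iloc[0])
        frames.append(FrameRecord(float(time_s), state, tuple(dets)))
    frames.sort(key=lambda f: f.time_s)
    return frames


def write_pressure_stream(pressures: list[PressureRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(_T4 % p.time_s, int(p.seated)) for p in pressures],
        columns=["time_s", "seated"],
    ).to_csv(path, index=False)


def read_pressure_stream(path: str | Path) -> list[PressureRecord]:
    df = pd.read_csv(path)
    return [
        PressureRecord(float(t), bool(int(s)))
        for t, s in zip(df["time_s"], df["seated"])
    ]


def write_truth(truth: EventTruth, path: str | Path) -> None:
    data = {
        "timeline": asdict(truth.timeline),
        "row": truth.row.as_dict(),
        "per_drop": [asdict(d) for d in truth.per_drop],
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> EventTruth:
    data = json.loads(Path(path).read_text())
    return EventTruth(
        timeline=EventTimeline(**data["timeline"]),
        row=BiomarkerTruth(**data["row"]),
        per_drop=tuple(DropRecord(**d) for d in data["per_drop"]),
    )


def write_dataset(dataset: CohortDataset, directory: str | Path) -> list[str]:
    """Write every event's streams and truth under ``directory``; returns
    the relative paths written."""
    directory = Path(directory)
    written = []
    for ev in dataset.events:
        sub = directory / f"event_p{ev.participant_id:03d}_d{ev.day_index:03d}"
        write_frame_stream(ev.frames, sub)
        write_pressure_stream(ev.pressures, sub / "pressure.csv")
        write_truth(ev.truth, sub / "truth.json")
        written += [
            str((sub / n).relative_to(directory))
            for n in ("frames.csv", "frame_names.txt", "pressure.csv", "truth.json")
        ]
    participants = [
        {"participant_id": p.participant_id, "gender": p.gender, "habit": asdict(p.habit)}
        for p in dataset.participants
    ]
    (directory / "participants.json").write_text(
        json.dumps(participants, indent=2, sort_keys=True)
    )
    written.append("participants.json")
    return written


# -- configuration ---------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce an end-to-end run."""

    seed: int = 0
    n_participants: int = 11
    n_female: int = 5
    events_per_participant: int = 5
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha: float = 0.05
    iqr_multiplier: float = 1.5
    quartile_method: str = "linear"
    perplexity: float | None = None
    min_subset_size: int = 3
    tsne_max_iter: int = 500
    biometric_groupings: tuple[str, ...] = ("time+behavior", "shape+behavior")
    write_streams: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["calibration"] = self.generator.calibration.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        gen = dict(data.pop("generator", {}))
        if "calibration" in gen:
            gen["calibration"] = CalibrationModel.from_dict(gen["calibration"])
        for tup in ("bsfs_band_edges_mm", "etd_bounds_s", "hour_range",
                    "dropping_row_range", "sit_lead_range_s", "force_bsfs_group"):
            if tup in gen and gen[tup] is not None:
                gen[tup] = tuple(gen[tup])
        data["generator"] = GeneratorConfig(**gen)
        if "biometric_groupings" in data:
            data["biometric_groupings"] = tuple(data["biometric_groupings"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# -- longitudinal export ---------------------------------------------------


@dataclass(frozen=True)
class LongitudinalSeries:
    """Per-participant Bristol-score diary over the monitoring window."""

    participant_label: int
    records: tuple[tuple[int, int], ...]  # (day_index, BSFS), days increasing
    bsfs_min: int
    bsfs_max: int
    bsfs_mode: int
    fraction_constipation: float  # BSFS {1,2}
    fraction_normal: float        # BSFS {3,4,5}
    fraction_diarrhea: float      # BSFS {6,7}

    def to_dict(self) -> dict:
        return {
            "participant": self.participant_label,
            "records": [list(r) for r in self.records],
            "summary": {
                "min": self.bsfs_min,
                "max": self.bsfs_max,
                "mode": self.bsfs_mode,
                "fraction_constipation": self.fraction_constipation,
                "fraction_normal": self.fraction_normal,
                "fraction_diarrhea": self.fraction_diarrhea,
            },
        }


def export_longitudinal(dataset: CohortDataset) -> list[LongitudinalSeries]:
    """One Bristol-score series per participant, days strictly increasing."""
    series = []
    by_pid: dict[int, list[tuple[int, int]]] = {}
    for ev in dataset.events:
        by_pid.setdefault(ev.participant_id, []).append(
            (ev.day_index, ev.truth.row.BSFS)
        )
    for pid in sorted(by_pid):
        recs = sorted(by_pid[pid])
        scores = np.array([b for _, b in recs])
        values, counts = np.unique(scores, return_counts=True)
        mode = int(values[np.argmax(counts)])
        n = len(scores)
        series.append(
            LongitudinalSeries(
                participant_label=pid,
                records=tuple(recs),
                bsfs_min=int(scores.min()),
                bsfs_max=int(scores.max()),
                bsfs_mode=mode,
                fraction_constipation=float(np.isin(scores, (1, 2)).sum() / n),
                fraction_normal=float(np.isin(scores, (3, 4, 5)).sum() / n),
                fraction_diarrhea=float(np.isin(scores, (6, 7)).sum() / n),
            )
        )
    return series


# -- end-to-end run --------------------------------------------------------


def _stats_report(table: pd.DataFrame, dataset: CohortDataset, cfg: PipelineConfig) -> dict:
    report: dict = {"n_events": int(len(table))}

    # pooled drop-level dropping durations for the log-normal fit
    drop_sdds = []
    for ev in dataset.events:
        try:
            _, episodes = extract_event(
                ev.frames, ev.pressures,
                waterline_row=cfg.generator.calibration.waterline_row,
            )
        except Exception:
            continue
        drop_sdds += [ep.sdd for ep in episodes if ep.sdd is not None and ep.sdd > 0]
    if len(drop_sdds) >= 2:
        fit = stats.fit_lognormal(drop_sdds)
        report["sdd_lognormal"] = {
            "mu_hat": fit.mu_hat, "sigma_hat": fit.sigma_hat,
            "arith_mean": fit.arith_mean, "arith_sd": fit.arith_sd, "n": fit.n,
        }

    # gender contrast of eu-tenesmus (per-variable IQR fencing)
    fem = table.loc[table["gender"] == "female", "ETD"].to_numpy()
    mal = table.loc[table["gender"] == "male", "ETD"].to_numpy()
    fem = stats.iqr_filter(fem, cfg.iqr_multiplier, cfg.quartile_method)
    mal = stats.iqr_filter(mal, cfg.iqr_multiplier, cfg.quartile_method)
    if len(fem) >= 3 and len(mal) >= 3:
        report["etd_by_gender"] = stats.compare_groups(
            fem, mal, labels=("female", "male"), alpha=cfg.alpha
        ).to_dict()

    # Bristol contrasts for thickness and eu-tenesmus
    for response in ("ST", "ETD"):
        report[f"bsfs_contrasts_{response}"] = [
            {"label": c.label, "note": c.note,
             **({} if c.result is None else c.result.to_dict())}
            for c in stats.bsfs_contrasts(
                table, response, alpha=cfg.alpha,
                multiplier=cfg.iqr_multiplier,
            )
        ]

    # thickness vs dropping duration
    try:
        reg = stats.linear_fit(table["SDD"], table["ST"])
        report["thickness_vs_sdd"] = {
            "slope_mm_per_s": reg.slope, "intercept_mm": reg.intercept,
            "r_squared": reg.r_squared, "n": reg.n,
        }
    except Exception as exc:
        report["thickness_vs_sdd"] = {"error": str(exc)}
    return report


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Simulate -> extract -> features -> statistics -> biometrics.

    Writes every intermediate table under ``output_dir`` and returns the
    manifest (also written as ``manifest.json``).  Identical configs give
    byte-identical outputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    cohort = generate_cohort(
        cfg.n_participants, cfg.n_female, cfg.seed, overrides=cfg.generator
    )
    dataset = simulate_dataset(cohort, cfg.events_per_participant, cfg.seed, cfg.generator)

    artifacts = []

    truth = dataset.truth_table()
    truth.to_csv(out / "events.csv", index=False, float_format="%.4f")
    artifacts.append("events.csv")

    if cfg.write_streams:
        artifacts += [f"streams/{p}" for p in write_dataset(dataset, out / "streams")]

    table = biometric.assemble_features(dataset)
    table.to_csv(out / "biomarkers.csv", index=False, float_format="%.4f")
    artifacts.append("biomarkers.csv")

    report = _stats_report(table, dataset, cfg)
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    artifacts.append("stats_report.json")

    ranked_frames = []
    for grouping in cfg.biometric_groupings:
        results = biometric.rank_subsets(
            table, grouping=grouping, seed=cfg.seed,
            perplexity=cfg.perplexity, min_size=cfg.min_subset_size,
            max_iter=cfg.tsne_max_iter,
        )
        frame = biometric.results_frame(results)
        frame["rank"] = np.arange(1, len(frame) + 1)
        ranked_frames.append(frame)
    if ranked_frames:
        pd.concat(ranked_frames, ignore_index=True).to_csv(
            out / "silhouette_rankings.csv", index=False, float_format="%.6f"
        )
        artifacts.append("silhouette_rankings.csv")

    longitudinal = [s.to_dict() for s in export_longitudinal(dataset)]
    (out / "longitudinal.json").write_text(
        json.dumps(longitudinal, indent=2, sort_keys=True)
    )
    artifacts.append("longitudinal.json")

    cfg.save(out / "config.yaml")
    artifacts.append("config.yaml")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": sorted(artifacts),
        "n_events_simulated": len(dataset.events),
        "n_events_extracted": int(len(table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
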