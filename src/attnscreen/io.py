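"""File formats: session-log CSV, cohort directories, YAML configuration.

Session logs are plain UTF-8 CSV with the fixed header
``second,attention,meditation,level,level_score,event``; a missing
meditation meter is an empty field.  A cohort is a directory of one
session CSV per subject plus ``manifest.csv``
(``subject_id,group,completed,seed``), from which every session can be
regenerated.  Configuration is YAML; every key is optional and missing
keys fall back to the reference game (five-level schedule, threshold 50,
300 s cap, 1 Hz) and the default cohort profiles.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AttentionProfile,
    CohortSpec,
    DEFAULT_ADHD_PROFILE,
    DEFAULT_CONTROL_PROFILE,
    SubjectRecord,
)
from .engine import (
    per_level_mean_attention,
    EVENT_FINISHED,
    EVENT_LEVEL_UP,
    EVENT_TICK,
    EVENT_TIMEOUT,
    METER_MAX,
    METER_MIN,
    GameConfig,
    LevelParams,
    SessionLog,
    default_config,
)

__all__ = [
    "ConfigError",
    "SessionParseError",
    "Settings",
    "RunManifest",
    "write_session_csv",
    "read_session_csv",
    "write_cohort",
    "read_cohort",
    "load_config",
    "default_settings",
]

SESSION_HEADER = ["second", "attention", "meditation", "level", "level_score", "event"]
_VALID_EVENTS = {EVENT_TICK, EVENT_LEVEL_UP, EVENT_FINISHED, EVENT_TIMEOUT}


class SessionParseError(ValueError):
    """Malformed or invalid session CSV; message names the offending line."""


class ConfigError(ValueError):
    """Type-invalid configuration values; message lists the offending keys."""


def write_session_csv(log: SessionLog, path: str | Path) -> None:
    """Write one session log; round-trips bit-exactly with the reader."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(SESSION_HEADER)
        med = log.meditation
        for i in range(len(log)):
            m = ""
            if med is not None and not np.isnan(med[i]):
                m = str(int(med[i]))
            w.writerow(
                [
                    int(log.second[i]),
                    int(log.attention[i]),
                    m,
                    int(log.level[i]),
                    int(log.level_score[i]),
                    log.event[i],
                ]
            )


def read_session_csv(path: str | Path) -> SessionLog:
    """Read and validate one session log.

    Accepts LF or CRLF newlines.  Raises :class:`SessionParseError` naming
    the 1-based line number on a malformed row, an out-of-range meter
    value, non-monotone seconds or a decreasing level column.
    """
    path = Path(path)
    seconds: list[int] = []
    attention: list[int] = []
    meditation: list[float] = []
    level: list[int] = []
    score: list[int] = []
    event: list[str] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SessionParseError(f"{path}: empty file")
        if header != SESSION_HEADER:
            raise SessionParseError(
                f"{path}: line 1: bad header {header!r}, expected {SESSION_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SESSION_HEADER):
                raise SessionParseError(
                    f"{path}: line {lineno}: expected {len(SESSION_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                sec = int(row[0])
                att = int(row[1])
                med = float(row[2]) if row[2] != "" else float("nan")
                lvl = int(row[3])
                sc = int(row[4])
            except ValueError as exc:
                raise SessionParseError(f"{path}: line {lineno}: {exc}") from None
            if not (METER_MIN <= att <= METER_MAX):
                raise SessionParseError(
                    f"{path}: line {lineno}: attention {att} outside "
                    f"[{METER_MIN}, {METER_MAX}]"
                )
            if row[5] not in _VALID_EVENTS:
                raise SessionParseError(
                    f"{path}: line {lineno}: unknown event {row[5]!r}"
                )
            if seconds and sec != seconds[-1] + 1:
                raise SessionParseError(
                    f"{path}: line {lineno}: seconds must increase by one "
                    f"(got {sec} after {seconds[-1]})"
                )
            if level and lvl < level[-1]:
                raise SessionParseError(
                    f"{path}: line {lineno}: level decreased from {level[-1]} to {lvl}"
                )
            seconds.append(sec)
            attention.append(att)
            meditation.append(med)
            level.append(lvl)
            score.append(sc)
            event.append(row[5])
    if not seconds:
        raise SessionParseError(f"{path}: no data rows")
    med_arr = np.asarray(meditation)
    return SessionLog(
        second=np.asarray(seconds, dtype=np.int64),
        attention=np.asarray(attention, dtype=np.int64),
        level=np.asarray(level, dtype=np.int64),
        level_score=np.asarray(score, dtype=np.int64),
        event=np.asarray(event, dtype=object),
        meditation=None if np.all(np.isnan(med_arr)) else med_arr,
    )


def write_cohort(records: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write one session CSV per subject plus the cohort manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        write_session_csv(r.log, outdir / f"{r.subject_id}.csv")
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "completed": r.completed,
                "seed": "" if r.seed is None else r.seed,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=["subject_id", "group", "completed", "seed"]).to_csv(
        manifest, index=False, lineterminator="\n"
    )
    return manifest


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    """Load a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    records: list[SubjectRecord] = []
    for row in manifest.itertuples(index=False):
        log = read_session_csv(indir / f"{row.subject_id}.csv")
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                log=log,
                completed=log.completed,
                level_means=per_level_mean_attention(log),
                seed=None if pd.isna(row.seed) else int(row.seed),
            )
        )
    return records


@dataclass(frozen=True)
class Settings:
    """Bundle of game, cohort and analysis configuration."""

    game: GameConfig
    cohort: CohortSpec
    alpha: float = 0.05


def default_settings(seed: int = 0) -> Settings:
    game = default_config()
    return Settings(game=game, cohort=CohortSpec(seed=seed, config=game), alpha=0.05)


def _profile_from_mapping(m: dict, label: str, errors: list[str]) -> AttentionProfile:
    base = DEFAULT_CONTROL_PROFILE if label == "control" else DEFAULT_ADHD_PROFILE
    kwargs = {"mean": base.mean, "sd": base.sd, "autocorr": base.autocorr}
    for k in ("mean", "sd", "autocorr"):
        if k in m:
            try:
                kwargs[k] = float(m[k])
            except (TypeError, ValueError):
                errors.append(f"cohort.{label}.{k}")
    return AttentionProfile(label=label, **kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> Settings:
    """Parse a YAML config; missing keys take the reference defaults.

    Unknown keys produce a warning, never a failure; type-invalid values
    raise :class:`ConfigError` listing every offending key at once.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded

    known_top = {"game", "cohort", "analysis"}
    for k in raw:
        if k not in known_top:
            warnings.warn(f"unknown configuration key ignored: {k!r}", stacklevel=2)

    errors: list[str] = []

    game_raw = raw.get("game", {}) or {}
    if not isinstance(game_raw, dict):
        raise ConfigError("game: must be a mapping")
    known_game = {"levels", "attentive_threshold", "tick_seconds", "max_session_seconds"}
    for k in game_raw:
        if k not in known_game:
            warnings.warn(f"unknown configuration key ignored: game.{k!r}", stacklevel=2)
    defaults = default_config()
    levels = defaults.levels
    if "levels" in game_raw:
        lv_raw = game_raw["levels"]
        if not isinstance(lv_raw, list) or not lv_raw:
            raise ConfigError("game.levels: must be a non-empty list of mappings")
        parsed = []
        for i, item in enumerate(lv_raw):
            if not isinstance(item, dict):
                errors.append(f"game.levels[{i}]")
                continue
            try:
                parsed.append(
                    LevelParams(
                        gain=int(item["gain"]),
                        penalty=int(item["penalty"]),
                        target=int(item["target"]),
                    )
                )
            except (KeyError, TypeError, ValueError):
                errors.append(f"game.levels[{i}]")
        levels = tuple(parsed)
    game_kwargs = {}
    for k, cast in (
        ("attentive_threshold", int),
        ("tick_seconds", int),
        ("max_session_seconds", int),
    ):
        if k in game_raw:
            try:
                game_kwargs[k] = cast(game_raw[k])
            except (TypeError, ValueError):
                errors.append(f"game.{k}")
    cohort_raw = raw.get("cohort", {}) or {}
    if not isinstance(cohort_raw, dict):
        raise ConfigError("cohort: must be a mapping")
    known_cohort = {"n_control", "n_adhd", "seed", "control", "adhd"}
    for k in cohort_raw:
        if k not in known_cohort:
            warnings.warn(
                f"unknown configuration key ignored: cohort.{k!r}", stacklevel=2
            )
    ctrl = _profile_from_mapping(cohort_raw.get("control", {}) or {}, "control", errors)
    adhd = _profile_from_mapping(cohort_raw.get("adhd", {}) or {}, "adhd", errors)
    cohort_kwargs = {}
    for k in ("n_control", "n_adhd", "seed"):
        if k in cohort_raw:
            try:
                cohort_kwargs[k] = int(cohort_raw[k])
            except (TypeError, ValueError):
                errors.append(f"cohort.{k}")
    if errors:
        raise ConfigError(f"invalid configuration values for: {', '.join(errors)}")
    game = GameConfig(levels=levels, **game_kwargs)
    if seed is not None:
        cohort_kwargs["seed"] = seed
    cohort = CohortSpec(
        control_profile=ctrl, adhd_profile=adhd, config=game, **cohort_kwargs
    )

    analysis_raw = raw.get("analysis", {}) or {}
    if not isinstance(analysis_raw, dict):
        raise ConfigError("analysis: must be a mapping")
    alpha = 0.05
    if "alpha" in analysis_raw:
        try:
            alpha = float(analysis_raw["alpha"])
        except (TypeError, ValueError):
            raise ConfigError("invalid configuration values for: analysis.alpha")
    for k in analysis_raw:
        if k != "alpha":
            warnings.warn(
                f"unknown configuration key ignored: analysis.{k!r}", stacklevel=2
            )

    return Settings(game=game, cohort=cohort, alpha=alpha)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every analysis output."""

    tool_version: str
    command: str
    seed: int | None
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    config: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n",
            encoding="utf-8",
        )

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        data["inputs"] = tuple(data.get("inputs", ()))
        data["outputs"] = tuple(data.get("outputs", ()))
        return RunManifest(**data)


def config_snapshot(settings: Settings) -> dict:
    """JSON-serialisable snapshot of the settings for run manifests."""
    return {
        "game": {
            "levels": [
                {"gain": lp.gain, "penalty": lp.penalty, "target": lp.target}
                for lp in settings.game.levels
            ],
            "attentive_threshold": settings.game.attentive_threshold,
            "tick_seconds": settings.game.tick_seconds,
            "max_session_seconds": settings.game.max_session_seconds,
        },
        "cohort": {
            "n_control": settings.cohort.n_control,
            "n_adhd": settings.cohort.n_adhd,
            "seed": settings.cohort.seed,
            "control": dataclasses.asdict(settings.cohort.control_profile),
            "adhd": dataclasses.asdict(settings.cohort.adhd_profile),
        },
        "analysis": {"alpha": settings.alpha},
    }
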