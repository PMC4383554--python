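"""CSV/JSON schemas, run configuration and reproducibility plumbing.

All tabular artifacts are plain CSV with a short ``#``-prefixed header that
records the package version, the RNG seed and a hash of the configuration
that produced the file, so any output can be traced to its exact settings.
Streams are small (tens of thousands of rows at most), so text formats are
the right trade-off.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acoustics import InvalidInputError, SizedBubble, mebr_from_intensities
from .dissolution import GasParams
from .events import PatientRecord, PatientSummary
from .tree import ObstructionSeries, SimParams

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_events_csv",
    "read_patient_json",
    "write_patient_json",
    "write_sized_events_csv",
    "read_sized_events_csv",
    "write_obstruction_csv",
    "write_table1_csv",
    "write_cohort_json",
    "write_outputs",
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with physical defaults built in."""

    seed: int = 0
    protocol_kind: str = "CABG"
    tree_generations: int = 19
    ensemble_size: int = 30
    time_step: float = 0.1
    stiction_coefficient: float = 10.0
    radius_noise_rel_sd: float = 0.40
    detection_threshold_db: float = 7.0
    gas: dict = field(default_factory=lambda: asdict(GasParams()))
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_params(self) -> SimParams:
        return SimParams(
            stiction_coefficient=self.stiction_coefficient,
            time_step=self.time_step,
            ensemble_size=self.ensemble_size,
            radius_noise_rel_sd=self.radius_noise_rel_sd,
            rng_seed=self.seed,
        )

    def gas_params(self) -> GasParams:
        return GasParams(**self.gas)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"# airemboli v{__version__}",
            f"# seed={self.seed} config_hash={self.config_hash}",
        ]


def _write_csv_with_header(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    buf = _io.StringIO()
    for line in config.header_lines():
        buf.write(line + "\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw detected-signal table.

    Requires columns ``time_s`` and ``side`` plus either ``mebr_db`` or the
    linear-intensity pair ``i_eb``/``i_b`` (converted on read); an optional
    ``phase`` column is carried through.  Times must be sorted.  Errors name
    the offending column or row.
    """
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    if "side" not in df.columns:
        raise SchemaError(f"{path}: missing column 'side'")
    if "mebr_db" not in df.columns:
        if {"i_eb", "i_b"}.issubset(df.columns):
            try:
                df["mebr_db"] = mebr_from_intensities(df["i_eb"], df["i_b"])
            except InvalidInputError as exc:
                bad = df.index[(df["i_eb"] <= 0) | (df["i_b"] <= 0)].tolist()
                raise SchemaError(f"{path}: non-positive intensity at rows {bad}") from exc
        else:
            raise SchemaError(f"{path}: need column 'mebr_db' or columns 'i_eb'+'i_b'")
    if df["time_s"].isna().any() or df["mebr_db"].isna().any():
        bad = df.index[df["time_s"].isna() | df["mebr_db"].isna()].tolist()
        raise SchemaError(f"{path}: unparseable values at rows {bad}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and (t[1:] < t[:-1]).any():
        row = int((t[1:] < t[:-1]).argmax()) + 1
        raise SchemaError(f"{path}: times not sorted at row {row}")
    bad_side = ~df["side"].isin(["left", "right"])
    if bad_side.any():
        raise SchemaError(f"{path}: invalid side at rows {df.index[bad_side].tolist()}")
    return df


def write_patient_json(patient: PatientRecord, curtains: dict, path: str | Path,
                       config: RunConfig) -> None:
    payload = {
        "_meta": {"version": __version__, "seed": config.seed,
                  "config_hash": config.config_hash},
        "id": patient.id,
        "mca_diameter_left": patient.mca_diameter_left,
        "mca_diameter_right": patient.mca_diameter_right,
        "procedure": patient.procedure,
        "haematocrit_samples": patient.haematocrit_samples,
        "bp_trace": patient.bp_trace,
        "signal_loss_intervals": patient.signal_loss_intervals,
        "monitoring_duration": patient.monitoring_duration,
        "curtain_intervals": curtains,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_patient_json(path: str | Path) -> tuple[PatientRecord, dict]:
    data = json.loads(Path(path).read_text())
    curtains = {
        side: [tuple(iv) for iv in ivs]
        for side, ivs in data.get("curtain_intervals", {}).items()
    }
    patient = PatientRecord(
        id=data["id"],
        mca_diameter_left=data["mca_diameter_left"],
        mca_diameter_right=data["mca_diameter_right"],
        procedure=data["procedure"],
        haematocrit_samples=[tuple(s) for s in data["haematocrit_samples"]],
        bp_trace=[tuple(s) for s in data.get("bp_trace", [])],
        signal_loss_intervals={
            side: [tuple(iv) for iv in ivs]
            for side, ivs in data.get("signal_loss_intervals", {}).items()
        },
        monitoring_duration=data.get("monitoring_duration", 0.0),
    )
    return patient, curtains


def write_sized_events_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Persist sized events: time_s, side, mebr_db, diameter_um,
    rel_uncertainty, volume_ml, phase, flags."""
    _write_csv_with_header(df, Path(path), config)


def read_sized_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    needed = {"time_s", "side", "mebr_db", "diameter_um", "rel_uncertainty", "volume_ml"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col in ("phase", "flags"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def sized_events_frame(events, sized: list[SizedBubble | None]) -> pd.DataFrame:
    """Tabulate a sized stream (one side) for writing."""
    rows = []
    for e, b in zip(events, sized):
        rows.append(
            {
                "time_s": e.time,
                "side": e.side,
                "mebr_db": e.mebr,
                "diameter_um": b.diameter if b else float("nan"),
                "rel_uncertainty": b.rel_uncertainty if b else float("nan"),
                "volume_ml": b.volume if b else float("nan"),
                "phase": e.phase or "",
                "flags": ";".join(b.flags) if b else "sizing_failed",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["time_s", "side", "mebr_db", "diameter_um", "rel_uncertainty",
                 "volume_ml", "phase", "flags"],
    )


def write_obstruction_csv(series_by_side: dict[str, ObstructionSeries],
                          path: str | Path, config: RunConfig) -> None:
    frames = []
    for side, series in series_by_side.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": series.times,
                    "side": side,
                    "mean_pct": series.mean_percent,
                    "ci_low": series.ci_low,
                    "ci_high": series.ci_high,
                }
            )
        )
    _write_csv_with_header(pd.concat(frames, ignore_index=True), Path(path), config)


def write_table1_csv(summaries: list[PatientSummary], path: str | Path,
                     config: RunConfig) -> None:
    """Table-1-shaped CSV: one row per field, one column per patient."""
    cols = {s.id: s for s in summaries}
    rows = {
        "procedure": {k: s.procedure for k, s in cols.items()},
        "n_emboli_left": {k: s.n_emboli_left for k, s in cols.items()},
        "n_emboli_right": {k: s.n_emboli_right for k, s in cols.items()},
        "total_volume_ml": {k: round(s.total_volume, 6) for k, s in cols.items()},
        "curtain_left_s": {k: s.curtain_duration_left for k, s in cols.items()},
        "curtain_right_s": {k: s.curtain_duration_right for k, s in cols.items()},
        "signal_loss_left_min": {k: s.signal_loss_left for k, s in cols.items()},
        "signal_loss_right_min": {k: s.signal_loss_right for k, s in cols.items()},
        "peak_affected_left_pct": {k: s.peak_affected_left for k, s in cols.items()},
        "peak_affected_right_pct": {k: s.peak_affected_right for k, s in cols.items()},
    }
    df = pd.DataFrame(rows).T
    df.index.name = "field"
    buf = _io.StringIO()
    for line in config.header_lines():
        buf.write(line + "\n")
    df.to_csv(buf, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def write_cohort_json(report: dict, path: str | Path, config: RunConfig) -> None:
    payload = {
        "_meta": {"version": __version__, "seed": config.seed,
                  "config_hash": config.config_hash},
        **report,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_outputs(
    out_dir: str | Path,
    config: RunConfig,
    sized_frames: dict[str, pd.DataFrame] | None = None,
    obstruction: dict[str, ObstructionSeries] | None = None,
    summaries: list[PatientSummary] | None = None,
    cohort: dict | None = None,
) -> list[Path]:
    """Write whichever result artifacts are present; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if sized_frames is not None:
        non_empty = [f for f in sized_frames.values() if len(f)]
        if non_empty:
            df = pd.concat(non_empty, ignore_index=True).sort_values(
                ["time_s", "side"], kind="stable"
            )
        else:
            df = next(iter(sized_frames.values()))
        p = out / "sized_events.csv"
        write_sized_events_csv(df, p, config)
        written.append(p)
    if obstruction is not None:
        p = out / "obstruction.csv"
        write_obstruction_csv(obstruction, p, config)
        written.append(p)
    if summaries is not None:
        p = out / "table1.csv"
        write_table1_csv(summaries, p, config)
        written.append(p)
    if cohort is not None:
        p = out / "cohort.json"
        write_cohort_json(cohort, p, config)
        written.append(p)
    return written
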