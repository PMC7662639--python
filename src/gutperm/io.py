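"""Tidy-CSV observation/result formats, config loading and run logs.

The exchange dialect is plain UTF-8 CSV with comma separators and dot
decimals.  Numeric output is serialized with 12 significant digits so a
round-trip through disk does not perturb downstream fits.  Times are stored
in minutes; all unit conversions live in :mod:`gutperm.units`.
"""

from __future__ import annotations

import datetime as _dt
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .egs import EGSTimeSeries
from .models import SegmentGeometry
from .perfusion import PerfusionTimeSeries
from .simulate import SimulatedRun
from .study import StudyConfig

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

OBSERVATION_COLUMNS = [
    "run_id",
    "experiment_type",
    "segment",
    "time_min",
    "analyte",
    "concentration_uM",
]


class ObservationSchemaError(ValueError):
    """Observation table violates the tidy schema; rows are reported 1-based
    relative to the data (header excluded)."""


def observations_frame(
    runs: Iterable[SimulatedRun],
    marker_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy observation table for a collection of simulated runs.

    For perfusion runs the analyte column distinguishes marker and drug by
    their solute names (taken from the truth ledger: the marker is the
    solute whose concentration series has one extra point).
    """
    rows: list[tuple] = []
    for run in runs:
        obs = run.observations
        segment = obs.geometry.segment_name
        if run.experiment_type == "perfusion":
            marker_name, drug_name = _perfusion_solute_names(run)
            for t, c in zip(obs.times_min, obs.marker_concentrations_uM):
                rows.append((run.run_id, "perfusion", segment, t, marker_name, c))
            for t, c in zip(obs.drug_times_min, obs.drug_concentrations_uM):
                rows.append((run.run_id, "perfusion", segment, t, drug_name, c))
        else:
            (solute_name,) = run.truth.permeabilities_cm_per_s.keys()
            for t, c in zip(obs.times_min, obs.receiver_concentrations_uM):
                rows.append((run.run_id, "egs", segment, t, solute_name, c))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def _perfusion_solute_names(run: SimulatedRun) -> tuple[str, str]:
    names = list(run.truth.permeabilities_cm_per_s.keys())
    if len(names) != 2:
        raise ValueError("perfusion run must carry exactly two solutes")
    return names[0], names[1]  # insertion order: marker first, then drug


def truth_frame(runs: Iterable[SimulatedRun]) -> pd.DataFrame:
    """Parallel tidy table of per-run ground truth, keyed by run_id."""
    rows: list[tuple] = []
    for run in runs:
        rows.append(
            (run.run_id, "jwater_uL_per_cm_per_h", run.truth.jwater_uL_per_cm_per_h)
        )
        for name, p in run.truth.permeabilities_cm_per_s.items():
            rows.append((run.run_id, f"permeability_cm_per_s:{name}", p))
    return pd.DataFrame(rows, columns=["run_id", "parameter", "value"])


def write_observations(runs_or_frame, path: str | Path) -> None:
    frame = (
        runs_or_frame
        if isinstance(runs_or_frame, pd.DataFrame)
        else observations_frame(runs_or_frame)
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy observation table.

    Violations (wrong header, negative times/concentrations, duplicate
    (run_id, time, analyte) keys, non-numeric values) raise
    :class:`ObservationSchemaError` naming the offending columns/rows.
    """
    frame = pd.read_csv(path, dtype={"run_id": str, "analyte": str})
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ObservationSchemaError(f"missing columns: {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in OBSERVATION_COLUMNS]
    if extra:
        raise ObservationSchemaError(f"unexpected columns: {', '.join(extra)}")
    problems: list[str] = []
    for col in ("time_min", "concentration_uM"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna()]
        if len(bad):
            problems.append(f"non-numeric {col} in rows {_rows(bad)}")
        frame[col] = values.astype(float)
    neg_t = frame.index[frame["time_min"] < 0]
    if len(neg_t):
        problems.append(f"negative time_min in rows {_rows(neg_t)}")
    neg_c = frame.index[frame["concentration_uM"] < 0]
    if len(neg_c):
        problems.append(f"negative concentration_uM in rows {_rows(neg_c)}")
    dup = frame.index[frame.duplicated(["run_id", "time_min", "analyte"], keep=False)]
    if len(dup):
        problems.append(f"duplicate (run_id, time_min, analyte) in rows {_rows(dup)}")
    if problems:
        raise ObservationSchemaError("; ".join(problems))
    return frame


def _rows(index) -> str:
    return ", ".join(str(i + 1) for i in list(index)[:20])


def perfusion_series_from_frame(
    frame: pd.DataFrame,
    run_id: str,
    marker_name: str,
    drug_name: str,
    nominal_marker_concentration_uM: float,
    nominal_volume_mL: float,
    nominal_drug_concentration_uM: float,
    sample_volume_mL: float,
    geometry: SegmentGeometry,
) -> PerfusionTimeSeries:
    """Assemble one run's perfusion time series from a tidy table."""
    sub = frame[frame["run_id"] == run_id]
    if sub.empty:
        raise ValueError(f"run {run_id!r} not present in observations")
    marker = sub[sub["analyte"] == marker_name].sort_values("time_min")
    drug = sub[sub["analyte"] == drug_name].sort_values("time_min")
    if marker.empty:
        raise ValueError(f"run {run_id!r} has no rows for marker {marker_name!r}")
    if drug.empty:
        raise ValueError(f"run {run_id!r} has no rows for drug {drug_name!r}")
    return PerfusionTimeSeries(
        times_min=marker["time_min"].to_numpy(),
        marker_concentrations_uM=marker["concentration_uM"].to_numpy(),
        drug_concentrations_uM=drug["concentration_uM"].to_numpy(),
        nominal_marker_concentration_uM=nominal_marker_concentration_uM,
        nominal_volume_mL=nominal_volume_mL,
        nominal_drug_concentration_uM=nominal_drug_concentration_uM,
        sample_volume_mL=sample_volume_mL,
        geometry=geometry,
    )


def egs_series_from_frame(
    frame: pd.DataFrame,
    run_id: str,
    solute_name: str,
    sac_volume_mL: float,
    sample_volume_mL: float,
    donor_concentration_uM: float,
    geometry: SegmentGeometry,
) -> EGSTimeSeries:
    sub = frame[(frame["run_id"] == run_id) & (frame["analyte"] == solute_name)]
    if sub.empty:
        raise ValueError(f"run {run_id!r} has no rows for analyte {solute_name!r}")
    sub = sub.sort_values("time_min")
    return EGSTimeSeries(
        times_min=sub["time_min"].to_numpy(),
        receiver_concentrations_uM=sub["concentration_uM"].to_numpy(),
        sac_volume_mL=sac_volume_mL,
        sample_volume_mL=sample_volume_mL,
        donor_concentration_uM=donor_concentration_uM,
        geometry=geometry,
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return StudyConfig.model_validate(raw)


def default_study_config() -> StudyConfig:
    """The packaged default scenario (see ``gutperm/data/default_scenario.yaml``)."""
    resource = importlib.resources.files("gutperm").joinpath(
        "data/default_scenario.yaml"
    )
    raw = yaml.safe_load(resource.read_text(encoding="utf-8"))
    return StudyConfig.model_validate(raw)


@dataclass
class RunLog:
    """Traceability record written next to every analysis output."""

    seed: int
    config_echo: dict
    software_version: str
    warnings: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
        logger.info("seed %d echoed to run log %s", self.seed, path)
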