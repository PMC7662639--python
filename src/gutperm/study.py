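"""Simulated comparative studies and group statistics.

Two designs are orchestrated on synthetic cohorts:

* marker comparison — the same true water flux estimated through markers of
  different permeability (classic phenol red vs PEGylated phenol red
  surrogates), quantifying how marker self-absorption drags the Jwater
  estimate down;
* effective-permeability study — a full factorial of model drugs x
  intestinal segments x markers, quantifying how the marker bias propagates
  into Peff and why it hits poorly permeable drugs hardest.

Group summaries are mean +/- sample SD; normality is checked per group with
the Shapiro-Wilk test and two groups are compared with the t-test (Welch by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .models import (
    EGSDesign,
    NoiseModel,
    PerfusionDesign,
    SegmentGeometry,
    SoluteSpec,
)
from .perfusion import analyze_perfusion
from .simulate import PerfusionScenario, SimulatedRun, generate_cohort


class ScenarioSolute(BaseModel):
    """A named solute scenario with per-segment true permeability."""

    name: str
    role: Literal["marker", "drug"]
    concentration_uM: float = Field(gt=0)
    permeability_cm_per_s: dict[str, float]

    model_config = {"frozen": True}

    def spec_for(self, segment_name: str) -> SoluteSpec:
        if segment_name not in self.permeability_cm_per_s:
            raise KeyError(
                f"solute scenario {self.name!r} has no permeability for "
                f"segment {segment_name!r}"
            )
        return SoluteSpec(
            name=self.name,
            role=self.role,
            permeability_cm_per_s=self.permeability_cm_per_s[segment_name],
            initial_concentration_uM=self.concentration_uM,
        )


class AnalysisOptions(BaseModel):
    variant: Literal["literal", "recursive"] = "recursive"
    fit_window: tuple[float, float] | None = None
    welch: bool = True
    holm: bool = False

    model_config = {"frozen": True}


class StudyConfig(BaseModel):
    """Configuration of the simulated comparative study."""

    segments: list[SegmentGeometry]
    markers: list[ScenarioSolute]
    drugs: list[ScenarioSolute]
    perfusion_design: PerfusionDesign = PerfusionDesign()
    egs_design: EGSDesign = EGSDesign()
    n_animals_per_group: int = Field(default=6, ge=2)
    noise: NoiseModel = NoiseModel()
    analysis: AnalysisOptions = AnalysisOptions()
    reference_marker: str | None = None
    reference_drug: str | None = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "StudyConfig":
        if not self.markers or not self.drugs:
            raise ValueError("at least one marker and one drug scenario required")
        for sol, role in [(m, "marker") for m in self.markers] + [
            (d, "drug") for d in self.drugs
        ]:
            if sol.role != role:
                raise ValueError(f"solute {sol.name!r} must have role {role!r}")
        names = [m.name for m in self.markers]
        if self.reference_marker is not None and self.reference_marker not in names:
            raise ValueError(f"reference marker {self.reference_marker!r} unknown")
        drug_names = [d.name for d in self.drugs]
        if self.reference_drug is not None and self.reference_drug not in drug_names:
            raise ValueError(f"reference drug {self.reference_drug!r} unknown")
        return self

    @property
    def reference_marker_name(self) -> str:
        return self.reference_marker or self.markers[0].name

    @property
    def reference_drug_name(self) -> str:
        return self.reference_drug or self.drugs[0].name


@dataclass(frozen=True)
class Summary:
    """Mean +/- sample SD (n-1 denominator) of one group."""

    mean: float
    sd: float | None
    n: int


def summarize(values: Sequence[float]) -> Summary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return Summary(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: normality per group, then a t-test."""

    label_a: str
    label_b: str
    summary_a: Summary
    summary_b: Summary
    shapiro_p_a: float
    shapiro_p_b: float
    t_p: float
    welch: bool
    evaluable: bool

    @property
    def significant_at_05(self) -> bool:
        return self.evaluable and self.t_p < 0.05

    @property
    def significant_at_01(self) -> bool:
        return self.evaluable and self.t_p < 0.01


def _shapiro_p(values: np.ndarray) -> float:
    if len(values) < 3 or np.ptp(values) == 0.0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = True,
) -> GroupComparison:
    """Shapiro-Wilk per group and a two-sample t-test (Welch by default).

    Groups with zero variance in both arms make the t statistic undefined;
    the comparison is then flagged not evaluable instead of raising.
    """
    arr_a = np.asarray(list(a), dtype=float)
    arr_b = np.asarray(list(b), dtype=float)
    degenerate = np.ptp(arr_a) == 0.0 and np.ptp(arr_b) == 0.0
    if degenerate:
        t_p, evaluable = float("nan"), False
    else:
        t_p = float(stats.ttest_ind(arr_a, arr_b, equal_var=not welch).pvalue)
        evaluable = not math.isnan(t_p)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        summary_a=summarize(arr_a),
        summary_b=summarize(arr_b),
        shapiro_p_a=_shapiro_p(arr_a),
        shapiro_p_b=_shapiro_p(arr_b),
        t_p=t_p,
        welch=welch,
        evaluable=evaluable,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def _group_seed(base_seed: int, index: int) -> int:
    """Deterministic per-group seed below 2**31."""
    child = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(child.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class StudyTables:
    """Per-run estimates plus group comparisons from one study."""

    estimates: pd.DataFrame
    comparisons: pd.DataFrame
    runs: list[SimulatedRun] = field(repr=False, default_factory=list)
    failures: pd.DataFrame | None = None


def _comparison_row(comp: GroupComparison, **keys: str) -> dict:
    return {
        **keys,
        "group_a": comp.label_a,
        "group_b": comp.label_b,
        "mean_a": comp.summary_a.mean,
        "sd_a": comp.summary_a.sd,
        "n_a": comp.summary_a.n,
        "mean_b": comp.summary_b.mean,
        "sd_b": comp.summary_b.sd,
        "n_b": comp.summary_b.n,
        "shapiro_p_a": comp.shapiro_p_a,
        "shapiro_p_b": comp.shapiro_p_b,
        "t_p": comp.t_p,
        "welch": comp.welch,
        "evaluable": comp.evaluable,
        "significant_0.05": comp.significant_at_05,
        "significant_0.01": comp.significant_at_01,
    }


def run_marker_comparison(
    config: StudyConfig, segment_name: str | None = None
) -> StudyTables:
    """Estimate the same true water flux through each marker scenario.

    One cohort is simulated per marker (parallel groups of
    ``n_animals_per_group`` animals) on the chosen segment (default: the
    first configured one), the perfusion chain estimates Jwater per animal,
    and every non-reference marker group is compared against the reference
    (classic-marker) group.  Runs whose simulation or estimation fails are
    recorded and skipped; the study continues.
    """
    segment = _find_segment(config, segment_name)
    drug = next(
        d for d in config.drugs if d.name == config.reference_drug_name
    ).spec_for(segment.segment_name)
    rows: list[dict] = []
    fail_rows: list[dict] = []
    all_runs: list[SimulatedRun] = []
    for g, marker_scenario in enumerate(config.markers):
        marker = marker_scenario.spec_for(segment.segment_name)
        scenario = PerfusionScenario(
            geometry=segment, design=config.perfusion_design, marker=marker, drug=drug
        )
        group_noise = config.noise.model_copy(
            update={"seed": _group_seed(config.noise.seed, g)}
        )
        runs = generate_cohort(
            scenario,
            config.n_animals_per_group,
            group_noise,
            run_id_prefix=f"jw-{marker.name}",
        )
        all_runs.extend(runs)
        for run in runs:
            try:
                result = analyze_perfusion(
                    run.observations,
                    variant=config.analysis.variant,
                    fit_window=config.analysis.fit_window,
                )
            except (ValueError, RuntimeError) as exc:
                fail_rows.append(
                    {"run_id": run.run_id, "marker": marker.name, "error": str(exc)}
                )
                continue
            rows.append(
                {
                    "marker": marker.name,
                    "run_id": run.run_id,
                    "segment": segment.segment_name,
                    "jwater_est_uL_per_cm_per_h": result.jwater_uL_per_cm_per_h,
                    "jwater_r2": result.water_flux.r_squared,
                    "jwater_true_uL_per_cm_per_h": run.truth.jwater_uL_per_cm_per_h,
                }
            )
    estimates = pd.DataFrame(rows)
    reference = config.reference_marker_name
    comp_rows = []
    ref_values = estimates.loc[
        estimates["marker"] == reference, "jwater_est_uL_per_cm_per_h"
    ].to_numpy()
    for marker_scenario in config.markers:
        if marker_scenario.name == reference:
            continue
        values = estimates.loc[
            estimates["marker"] == marker_scenario.name, "jwater_est_uL_per_cm_per_h"
        ].to_numpy()
        if len(ref_values) == 0 or len(values) == 0:
            continue
        comp = compare_groups(
            ref_values,
            values,
            label_a=reference,
            label_b=marker_scenario.name,
            welch=config.analysis.welch,
        )
        comp_rows.append(_comparison_row(comp, quantity="jwater", segment=segment.segment_name))
    comparisons = pd.DataFrame(comp_rows)
    if config.analysis.holm and len(comparisons):
        comparisons["t_p_holm"] = holm_adjust(comparisons["t_p"].fillna(1.0))
    failures = pd.DataFrame(fail_rows) if fail_rows else None
    return StudyTables(
        estimates=estimates, comparisons=comparisons, runs=all_runs, failures=failures
    )


def run_peff_study(config: StudyConfig) -> StudyTables:
    """Full factorial drug x segment x marker effective-permeability study.

    For each cell a cohort is simulated and analyzed; comparisons pit each
    non-reference marker against the reference marker per (drug, segment).
    """
    rows: list[dict] = []
    fail_rows: list[dict] = []
    all_runs: list[SimulatedRun] = []
    group_index = 0
    for drug_scenario in config.drugs:
        for segment in config.segments:
            for marker_scenario in config.markers:
                marker = marker_scenario.spec_for(segment.segment_name)
                drug = drug_scenario.spec_for(segment.segment_name)
                scenario = PerfusionScenario(
                    geometry=segment,
                    design=config.perfusion_design,
                    marker=marker,
                    drug=drug,
                )
                group_noise = config.noise.model_copy(
                    update={"seed": _group_seed(config.noise.seed, 1000 + group_index)}
                )
                group_index += 1
                runs = generate_cohort(
                    scenario,
                    config.n_animals_per_group,
                    group_noise,
                    run_id_prefix=f"peff-{drug.name}-{segment.segment_name}-{marker.name}",
                )
                all_runs.extend(runs)
                for run in runs:
                    try:
                        result = analyze_perfusion(
                            run.observations,
                            variant=config.analysis.variant,
                            fit_window=config.analysis.fit_window,
                        )
                    except (ValueError, RuntimeError) as exc:
                        fail_rows.append(
                            {
                                "run_id": run.run_id,
                                "drug": drug.name,
                                "segment": segment.segment_name,
                                "marker": marker.name,
                                "error": str(exc),
                            }
                        )
                        continue
                    rows.append(
                        {
                            "drug": drug.name,
                            "segment": segment.segment_name,
                            "marker": marker.name,
                            "run_id": run.run_id,
                            "peff_est_cm_per_s": result.peff_cm_per_s,
                            "ka_per_min": result.ka_fit.ka_per_min,
                            "ka_r2": result.ka_fit.r_squared,
                            "peff_true_cm_per_s": run.truth.permeabilities_cm_per_s[
                                drug.name
                            ],
                        }
                    )
    estimates = pd.DataFrame(rows)
    reference = config.reference_marker_name
    comp_rows = []
    for drug_scenario in config.drugs:
        for segment in config.segments:
            cell = estimates[
                (estimates["drug"] == drug_scenario.name)
                & (estimates["segment"] == segment.segment_name)
            ]
            ref_values = cell.loc[
                cell["marker"] == reference, "peff_est_cm_per_s"
            ].to_numpy()
            if len(ref_values) == 0:
                continue
            for marker_scenario in config.markers:
                if marker_scenario.name == reference:
                    continue
                values = cell.loc[
                    cell["marker"] == marker_scenario.name, "peff_est_cm_per_s"
                ].to_numpy()
                if len(values) == 0:
                    continue
                comp = compare_groups(
                    ref_values,
                    values,
                    label_a=reference,
                    label_b=marker_scenario.name,
                    welch=config.analysis.welch,
                )
                comp_rows.append(
                    _comparison_row(
                        comp,
                        quantity="peff",
                        drug=drug_scenario.name,
                        segment=segment.segment_name,
                    )
                )
    comparisons = pd.DataFrame(comp_rows)
    if config.analysis.holm and len(comparisons):
        comparisons["t_p_holm"] = holm_adjust(comparisons["t_p"].fillna(1.0))
    failures = pd.DataFrame(fail_rows) if fail_rows else None
    return StudyTables(
        estimates=estimates, comparisons=comparisons, runs=all_runs, failures=failures
    )


def _find_segment(config: StudyConfig, segment_name: str | None) -> SegmentGeometry:
    if segment_name is None:
        return config.segments[0]
    for seg in config.segments:
        if seg.segment_name == segment_name:
            return seg
    raise KeyError(f"segment {segment_name!r} not in study config")
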