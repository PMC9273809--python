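"""End-to-end meaningful-change-threshold analysis pipeline.

Stages: validate → changes → qualify → group → estimate → triangulate →
cdf.  Any stage failure aborts with the stage name and the underlying
cause.  Outputs are tidy CSV/JSON tables; a run with an identical config
and input is byte-identical (the run log carries seeds and versions but no
timestamps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .instruments import builtin_criteria, validate_records
from .changes import (
    AnchorSpec,
    QualificationDecision,
    TARGET_CHANGE,
    compute_changes,
    group_by_anchor_change,
    qualify_anchor,
    spearman_rho,
    ChangeError,
)
from .estimation import (
    GroupChangeSummary,
    MCTCandidate,
    TriangulationResult,
    anchor_mean_candidate,
    fit_change_regression,
    half_sd_mct,
    project_regression_mct,
    summarize_group,
    triangulate,
)
from .cdf import CdfError, EcdfCurve, KsSeparation, stratified_cdfs

__all__ = [
    "AnalysisConfig",
    "PipelineStageError",
    "PipelineReport",
    "default_anchors",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration of the anchor-based threshold analysis.

    The default anchor set is the canonical one: the depression severity
    scale under all three built-in bandings (primary anchor), the two CGI
    point-change scales, and the EQ-VAS as a continuous anchor with its
    published 7-point individual-level threshold.
    """

    criteria_names: tuple[str, ...] = ("criteria_1", "criteria_2", "criteria_3")
    rho_threshold: float = 0.40
    min_group_n: int = 25
    eq_vas_mct: float = 7.0
    include_half_sd: bool = True
    include_regression: bool = True
    improvement_category: int = 1
    target: str = TARGET_CHANGE
    target_improvement_sign: int = -1
    baseline_visit: str = "baseline"
    endpoint_visit: str = "endpoint"
    seed: Optional[int] = None  # recorded in the run log; analysis is deterministic

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        kwargs = dict(data)
        if "criteria_names" in kwargs:
            kwargs["criteria_names"] = tuple(kwargs["criteria_names"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "criteria_names": list(self.criteria_names),
            "rho_threshold": self.rho_threshold,
            "min_group_n": self.min_group_n,
            "eq_vas_mct": self.eq_vas_mct,
            "include_half_sd": self.include_half_sd,
            "include_regression": self.include_regression,
            "improvement_category": self.improvement_category,
            "target": self.target,
            "target_improvement_sign": self.target_improvement_sign,
            "baseline_visit": self.baseline_visit,
            "endpoint_visit": self.endpoint_visit,
            "seed": self.seed,
        }


def default_anchors(config: AnalysisConfig) -> list[AnchorSpec]:
    """The configured anchor set: MADRS per criteria, CGIs, EQ-VAS."""
    anchors = [
        AnchorSpec(
            instrument="madrs_total",
            anchor_type="severity_categorical",
            criteria=builtin_criteria(name),
            qualification_threshold=config.rho_threshold,
        )
        for name in config.criteria_names
    ]
    for cgi in ("cgi_ss_r", "cgi_sr_i"):
        anchors.append(
            AnchorSpec(
                instrument=cgi,
                anchor_type="ordinal_point",
                qualification_threshold=config.rho_threshold,
            )
        )
    anchors.append(
        AnchorSpec(
            instrument="eq_vas",
            anchor_type="continuous",
            qualification_threshold=config.rho_threshold,
            external_mct=config.eq_vas_mct,
        )
    )
    return anchors


@dataclass
class PipelineReport:
    changes: pd.DataFrame
    dropped_log: dict
    qualification: list[QualificationDecision]
    group_summaries: list[GroupChangeSummary]
    candidates: list[MCTCandidate]
    triangulation: TriangulationResult
    cdf_curves: list[tuple[str, EcdfCurve]]  # (anchor name, curve)
    cdf_separations: list[tuple[str, KsSeparation]]
    warnings: list[str] = field(default_factory=list)
    run_log: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------

    def group_summaries_frame(self) -> pd.DataFrame:
        cols = ["anchor", "category", "n", "mean", "sd", "median",
                "ci_low", "ci_high", "srm", "ses", "flagged_small"]
        return pd.DataFrame([s.to_dict() for s in self.group_summaries], columns=cols)

    def candidates_frame(self) -> pd.DataFrame:
        cols = ["source", "anchor", "value", "n"]
        return pd.DataFrame([c.to_dict() for c in self.candidates], columns=cols)

    def cdf_frame(self) -> pd.DataFrame:
        frames = []
        for anchor, curve in self.cdf_curves:
            f = curve.to_frame()
            f.insert(0, "anchor", anchor)
            frames.append(f)
        cols = ["anchor", "group", "value", "cumulative_proportion"]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)[cols]

    def separation_frame(self) -> pd.DataFrame:
        rows = [{"anchor": a, **s.to_dict()} for a, s in self.cdf_separations]
        return pd.DataFrame(rows, columns=["anchor", "group_a", "group_b", "distance"])

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "qualification.json",
                    [q.to_dict() for q in self.qualification])
        self.group_summaries_frame().to_csv(out / "group_summaries.csv", index=False)
        self.candidates_frame().to_csv(out / "mct_candidates.csv", index=False)
        _write_json(out / "triangulation.json", self.triangulation.to_dict())
        self.cdf_frame().to_csv(out / "cdf_curves.csv", index=False)
        self.separation_frame().to_csv(out / "cdf_separation.csv", index=False)
        _write_json(out / "run_log.json", self.run_log)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    records: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    anchors: Optional[Sequence[AnchorSpec]] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> PipelineReport:
    """Run validate → ... → cdf on a visit-record table.

    ``records`` is a long-format table as produced by
    :func:`mct_kit.instruments.read_visit_records` or the synthetic
    generators.  If ``out_dir`` is given, all report tables are written
    there.
    """
    config = config or AnalysisConfig()
    anchors = list(anchors) if anchors is not None else default_anchors(config)
    warnings_log: list[str] = []

    with _stage("validate"):
        records = validate_records(records)

    with _stage("changes"):
        criteria = [builtin_criteria(n) for n in config.criteria_names]
        changes, dropped_log = compute_changes(
            records,
            criteria=criteria,
            baseline_visit=config.baseline_visit,
            endpoint_visit=config.endpoint_visit,
        )

    with _stage("qualify"):
        qualification: list[QualificationDecision] = []
        decisions_by_spec: dict[str, QualificationDecision] = {}
        for spec in anchors:
            col = spec.raw_change_column()
            try:
                result = spearman_rho(changes[config.target], changes[col])
                decision = qualify_anchor(result, spec)
            except ChangeError as err:
                warnings_log.append(
                    f"anchor {spec.name}: correlation undefined ({err}); "
                    "treated as unqualified"
                )
                decision = QualificationDecision(
                    anchor=spec.name, rho=float("nan"), pvalue=None,
                    threshold=spec.qualification_threshold, qualified=False,
                )
            qualification.append(decision)
            decisions_by_spec[spec.name] = decision

    target_baseline = config.target.replace("_change", "_baseline")
    baseline_sd = None
    if target_baseline in changes.columns:
        vals = changes[target_baseline].astype(float).dropna()
        if len(vals) > 1:
            baseline_sd = float(np.std(vals, ddof=1))

    with _stage("group"):
        group_summaries: list[GroupChangeSummary] = []
        grouped_by_anchor: dict[str, dict[int, np.ndarray]] = {}
        for spec in anchors:
            if spec.anchor_type == "continuous":
                continue
            if not decisions_by_spec[spec.name].qualified:
                warnings_log.append(
                    f"anchor {spec.name} unqualified "
                    f"(|rho| < {spec.qualification_threshold}); skipped"
                )
                continue
            groups = group_by_anchor_change(
                changes, spec, target=config.target,
                min_group_n=config.min_group_n,
            )
            grouped_by_anchor[spec.name] = groups.groups
            for k in sorted(groups.groups):
                group_summaries.append(
                    summarize_group(
                        groups.groups[k],
                        baseline_sd=baseline_sd,
                        anchor=spec.name,
                        category=k,
                        flagged_small=k in groups.flagged_small,
                    )
                )

    with _stage("estimate"):
        candidates: list[MCTCandidate] = []
        for summary in group_summaries:
            if summary.category == config.improvement_category:
                candidates.append(anchor_mean_candidate(summary))
        if config.include_regression:
            for spec in anchors:
                if spec.anchor_type != "continuous":
                    continue
                if not decisions_by_spec[spec.name].qualified:
                    warnings_log.append(
                        f"continuous anchor {spec.name} unqualified; "
                        "regression projection skipped"
                    )
                    continue
                fit = fit_change_regression(
                    changes[spec.raw_change_column()], changes[config.target]
                )
                candidates.append(
                    project_regression_mct(fit, spec.external_mct, anchor=spec.name)
                )
        if config.include_half_sd:
            target_change = changes[config.target].astype(float).dropna()
            if len(target_change) > 1:
                candidates.append(
                    half_sd_mct(
                        float(np.std(target_change, ddof=1)),
                        improvement_sign=config.target_improvement_sign,
                        n=len(target_change),
                    )
                )
        if not any(c.source != "half_sd" for c in candidates):
            warnings_log.append(
                "no anchor-based candidates available; triangulation uses "
                "the distribution-based (half-SD) candidate only"
            )

    with _stage("triangulate"):
        triangulation = triangulate(candidates)

    with _stage("cdf"):
        cdf_curves: list[tuple[str, EcdfCurve]] = []
        cdf_separations: list[tuple[str, KsSeparation]] = []
        for anchor_name, groups in grouped_by_anchor.items():
            try:
                curves, seps = stratified_cdfs(groups)
            except CdfError as err:
                warnings_log.append(f"anchor {anchor_name}: no CDF report ({err})")
                continue
            cdf_curves.extend((anchor_name, c) for c in curves)
            cdf_separations.extend((anchor_name, s) for s in seps)

    n_patients = int(records["patient_id"].nunique())
    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_patients": n_patients,
        "n_complete_cases": int(len(changes)),
        "dropped": dropped_log,
        "warnings": warnings_log,
    }
    report = PipelineReport(
        changes=changes,
        dropped_log=dropped_log,
        qualification=qualification,
        group_summaries=group_summaries,
        candidates=candidates,
        triangulation=triangulation,
        cdf_curves=cdf_curves,
        cdf_separations=cdf_separations,
        warnings=warnings_log,
        run_log=run_log,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
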