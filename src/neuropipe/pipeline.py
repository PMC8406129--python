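"""End-to-end orchestration: cohort directory -> QC -> features -> filter
-> PCA/PLS-DA -> importance -> leave-one-out -> survey tables.

The pipeline is a pure function of (cohort files, config): repeated runs
produce byte-identical outputs.  Every exclusion and imputation decision
is logged with the participant id, and the run report asserts the
sample-size accounting (excluded + analysed = enrolled) per data type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import gait_features as gf
from . import hand_features as hf
from . import multivariate_stats as mv
from . import surveys
from .session_io import SensorSession, read_session

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    availability: float = 0.70
    ncomp_importance: int = 2   # components used for VIP / loading flags
    ncomp_loo: int = 6          # components reported by leave-one-out
    vip_threshold: float = 2.0
    loading_threshold: float = 0.2
    impute: str = "mean"        # or "complete-case"
    label_column: str = "group"
    equal_var: bool = False     # pooled t test if True
    chisq_correction: bool = False
    gait: gf.GaitConfig = field(default_factory=gf.GaitConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gait_raw = raw.pop("gait", {})
        cfg = cls(**raw)
        cfg.gait = gf.GaitConfig(**gait_raw)
        return cfg


@dataclass
class RunReport:
    cohort: dict
    qc: dict
    features: dict
    pca: dict
    plsda: dict
    validation: dict
    univariate: dict
    surveys: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "cohort": self.cohort,
                "qc": self.qc,
                "features": self.features,
                "pca": self.pca,
                "plsda": self.plsda,
                "validation": self.validation,
                "univariate": self.univariate,
                "surveys": self.surveys,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_cohort(cohort_dir: str | Path) -> tuple[list[SensorSession], pd.DataFrame]:
    """Read manifest.csv and every listed session file."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest.csv in {cohort_dir}")
    manifest = pd.read_csv(manifest_path)
    if "participant_id" not in manifest or "file" not in manifest:
        raise PipelineError("manifest must have participant_id and file columns")
    if manifest["participant_id"].duplicated().any():
        raise PipelineError("duplicate participant ids in manifest")
    sessions = [read_session(cohort_dir / f) for f in manifest["file"]]
    return sessions, manifest


def resolve_labels(
    sessions: list[SensorSession],
    manifest: pd.DataFrame,
    label_column: str = "group",
) -> pd.Series:
    """Case/control label per participant.

    Priority: the manifest's label column (the screening analogue, used for
    participants without a completed survey) is the fallback; a completed
    survey's classification rule takes precedence.
    """
    labels: dict[str, Optional[bool]] = {}
    override = (
        manifest.set_index("participant_id")[label_column]
        if label_column in manifest
        else None
    )
    for s in sessions:
        lab: Optional[bool] = None
        if s.survey is not None:
            lab = surveys.classify(s.survey).is_case
        if lab is None and override is not None:
            raw = override.get(s.participant_id)
            if isinstance(raw, str):
                lab = raw.strip().lower() == "case"
                logger.info("%s: label from manifest override (%s)", s.participant_id, raw)
        labels[s.participant_id] = lab
    return pd.Series(labels, name="is_case")


def build_feature_matrix(
    sessions: list[SensorSession], gait_config: gf.GaitConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the participants x features matrix and the QC log."""
    rows: dict[str, dict] = {}
    qc_rows: list[dict] = []
    for s in sessions:
        gait, qcs = gf.extract_gait_features(s, gait_config)
        hand = hf.extract_hand_features(s)
        rows[s.participant_id] = {**gait, **hand}
        for i, qc in enumerate(qcs):
            qc_rows.append(
                {
                    "participant_id": s.participant_id,
                    "walk": i,
                    "excluded": qc.excluded,
                    "reason": qc.reason.value,
                    "duration_s": qc.duration_s,
                }
            )
            if qc.excluded:
                logger.info(
                    "%s walk %d excluded: %s", s.participant_id, i, qc.reason.value
                )
    M = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    M.index.name = "participant_id"
    M = M[[*gf.GAIT_FEATURE_NAMES, *hf.HAND_FEATURE_NAMES]]
    return M, pd.DataFrame(qc_rows)


def score_surveys(sessions: list[SensorSession]) -> pd.DataFrame:
    """Per-participant scale scores, case labels, PRO-CTCAE and falls."""
    rows = []
    for s in sessions:
        row: dict = {"participant_id": s.participant_id}
        if s.survey is not None:
            row.update(surveys.score_all(s.survey).as_dict())
            lab = surveys.classify(s.survey)
            row.update(
                is_case=lab.is_case,
                is_feet_case=lab.is_feet_case,
                is_hands_case=lab.is_hands_case,
            )
            row["proctcae_severity"] = s.survey.proctcae_severity
            row["proctcae_interference"] = s.survey.proctcae_interference
            row["fell_since_last_chemo"] = s.survey.fell_since_last_chemo
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def make_group_table(labels: pd.Series, scores: pd.DataFrame) -> pd.DataFrame:
    """Survey comparison table: median and SD per group for each scale plus
    PRO-CTCAE, and the falls count per group."""
    scales = ["cipn20", "cipn8", "cipn4", "cipn2feet", "cipn2hands", "cipnm",
              "proctcae_severity", "proctcae_interference"]
    rows = []
    joined = scores.join(labels.rename("label"))
    for scale in scales:
        if scale not in joined:
            continue
        row: dict = {"measure": scale}
        for name, grp in (("case", True), ("control", False)):
            vals = joined.loc[joined["label"] == grp, scale].dropna().astype(float)
            row[f"{name}_median"] = float(vals.median()) if len(vals) else np.nan
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
            row[f"{name}_n"] = int(len(vals))
        rows.append(row)
    if "fell_since_last_chemo" in joined:
        row = {"measure": "fell_since_last_chemo"}
        for name, grp in (("case", True), ("control", False)):
            vals = joined.loc[joined["label"] == grp, "fell_since_last_chemo"].dropna()
            row[f"{name}_median"] = float(vals.astype(float).sum())  # count of falls
            row[f"{name}_sd"] = np.nan
            row[f"{name}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the full analysis on a cohort directory.

    Writes (when ``out_dir`` is given): report.json, features_wide.csv,
    features_long.csv, vip_table.csv, loo.csv, qc_log.csv, group_table.csv,
    survey_scores.csv.
    """
    config = config or PipelineConfig()
    sessions, manifest = load_cohort(cohort_dir)
    n_enrolled = len(sessions)

    labels = resolve_labels(sessions, manifest, config.label_column)
    unlabeled = labels[labels.isna()].index.tolist()
    if unlabeled:
        raise PipelineError(f"unlabelable participants: {', '.join(unlabeled)}")
    labels = labels.astype(bool)
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if min(n_cases, n_controls) < 2:
        raise PipelineError(
            f"one group (near-)empty: {n_cases} cases / {n_controls} controls"
        )

    M, qc_log = build_feature_matrix(sessions, config.gait)
    scores = score_surveys(sessions)

    # availability filter + imputation/scaling
    n_before = M.shape[1]
    M_filt = mv.drop_constant_features(mv.availability_filter(M, config.availability))
    if config.impute == "complete-case":
        M_filt = M_filt.dropna(axis=0)
        if min(labels[M_filt.index].sum(), (~labels[M_filt.index]).sum()) < 2:
            raise PipelineError("complete-case imputation left a group (near-)empty")
    scaled = mv.autoscale(M_filt)
    y = labels.loc[scaled.X.index].astype(float).to_numpy()

    pca = mv.fit_pca(scaled)
    max_comp = min(len(y) - 2, scaled.X.shape[1])  # n-2: LOO folds drop a row
    ncomp_fit = min(max(config.ncomp_importance, config.ncomp_loo), max_comp)
    model = mv.fit_plsda(scaled.X, y, ncomp=ncomp_fit, scale=False)
    ncomp_imp = min(config.ncomp_importance, ncomp_fit)
    report_imp = mv.important_features(
        model,
        ncomp=ncomp_imp,
        vip_threshold=config.vip_threshold,
        loading_threshold=config.loading_threshold,
        M=M_filt,
        labels=labels.loc[M_filt.index].to_numpy(),
        equal_var=config.equal_var,
    )
    loo = mv.loo_validate(scaled.X, y, ncomp=min(config.ncomp_loo, ncomp_fit), scale=False)

    # univariate: step length (pedometer pathway, analysed separately since
    # its availability tracks pedometer permission)
    univariate: dict = {}
    if "step_length_m" in M:
        sl = M["step_length_m"]
        case_vals = sl[labels & sl.notna()]
        ctrl_vals = sl[(~labels) & sl.notna()]
        res = mv.ttest_unpaired(case_vals, ctrl_vals, equal_var=config.equal_var)
        univariate["step_length_m"] = {
            "case_median": float(case_vals.median()) if len(case_vals) else None,
            "control_median": float(ctrl_vals.median()) if len(ctrl_vals) else None,
            "case_n": int(len(case_vals)),
            "control_n": int(len(ctrl_vals)),
            **(res or {}),
        }

    group_table = make_group_table(labels, scores)

    # falls chi-square where both groups reported
    if "fell_since_last_chemo" in scores:
        falls = scores["fell_since_last_chemo"].dropna()
        lab = labels.loc[falls.index]
        tab = [
            [int((falls[lab]).sum()), int((~falls[lab].astype(bool)).sum())],
            [int((falls[~lab]).sum()), int((~falls[~lab].astype(bool)).sum())],
        ]
        univariate["falls_chisq"] = mv.chisq_test(tab, correction=config.chisq_correction)

    # QC accounting (participant counted excluded if every walk excluded)
    per_part = qc_log.groupby("participant_id")["excluded"].all() if len(qc_log) else pd.Series(dtype=bool)
    n_gait_excluded = int(per_part.sum())
    n_gait_analysed = n_enrolled - n_gait_excluded
    assert n_gait_excluded + n_gait_analysed == n_enrolled
    reason_counts = (
        qc_log.loc[qc_log["excluded"], "reason"].value_counts().to_dict()
        if len(qc_log)
        else {}
    )

    vip_all = mv.vip(model, ncomp_imp)
    report = RunReport(
        cohort={
            "n_enrolled": n_enrolled,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "n_pedometer_permission": int(sum(s.pedometer_permission for s in sessions)),
            "n_survey_completed": int(sum(s.survey is not None for s in sessions)),
        },
        qc={
            "walks_total": int(len(qc_log)),
            "walks_excluded": int(qc_log["excluded"].sum()) if len(qc_log) else 0,
            "participants_gait_excluded": n_gait_excluded,
            "participants_gait_analysed": n_gait_analysed,
            "exclusion_reasons": reason_counts,
        },
        features={
            "n_before_filter": n_before,
            "n_after_filter": int(M_filt.shape[1]),
            "n_imputed_cells": int(scaled.imputed.values.sum()),
        },
        pca={
            "explained_var_pct": pca.explained_var_pct[: ncomp_fit].tolist(),
            "explained_var_pct_first2": float(pca.explained_var_pct[:2].sum()),
        },
        plsda={
            "ncomp": model.ncomp,
            "ncomp_importance": ncomp_imp,
            "explained_x_var_pct": model.explained_x_var_pct.tolist(),
            "explained_y_var_pct": model.explained_y_var_pct.tolist(),
            "n_vip_ge_1": int((vip_all >= 1).sum()),
            "n_vip_ge_2": int((vip_all >= config.vip_threshold).sum()),
            "important_features": report_imp.table.index[
                report_imp.table["important"]
            ].tolist(),
        },
        validation={
            "ncomp": loo.ncomp,
            "r2": loo.table["r2"].tolist(),
            "rmsep": loo.table["rmsep"].tolist(),
        },
        univariate=univariate,
        surveys={"group_table": group_table.to_dict(orient="records")},
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        M.to_csv(out / "features_wide.csv")
        M.reset_index().melt(
            id_vars="participant_id", var_name="feature_name", value_name="value"
        ).to_csv(out / "features_long.csv", index=False)
        report_imp.table.rename_axis("feature").to_csv(out / "vip_table.csv")
        loo.table.to_csv(out / "loo.csv", index=False)
        qc_log.to_csv(out / "qc_log.csv", index=False)
        group_table.to_csv(out / "group_table.csv", index=False)
        scores.join(labels.rename("label_resolved")).to_csv(out / "survey_scores.csv")
    return report
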