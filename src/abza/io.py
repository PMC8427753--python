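"""File formats, the analysis report, and the measure→grade→analyze pipeline.

Landmark files are CSV (one row per patient-measurement, columns
``patient_id, side, t_x, t_y, mid_base_x, mid_base_y, mid_apex_x,
mid_apex_y, occlusion, a1_status, acoa_patent, contralateral`` plus
repeated ``term_x_i, term_y_i`` pairs and an optional ``rater``) or the
equivalent JSON with a ``terminal_candidates`` array.  Cohort tables are
plain CSV with the documented patient-record columns.  All writers
serialize at full precision; rounding happens only in human-readable
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    ContingencyResult,
    LogisticModelResult,
    ROCResult,
    UnivariateResult,
    contingency_analysis,
    fit_logistic,
    interrater_reliability,
    roc_analysis,
    univariate_compare,
)
from .errors import DegenerateTestError, ParseError
from .geometry import AngioLandmarks, measure_abza
from .grading import GOOD, GradingScheme, grade_angle

logger = logging.getLogger("abza")

_REQUIRED_LANDMARK_COLUMNS = [
    "patient_id", "side", "t_x", "t_y", "mid_base_x", "mid_base_y",
    "mid_apex_x", "mid_apex_y", "occlusion", "a1_status", "acoa_patent",
    "contralateral",
]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}

#: default variable list for the univariate screen (used when present)
DEFAULT_UNIVARIATE_VARIABLES = [
    "age", "sex", "hospital", "hypertension", "diabetes", "hyperlipidemia",
    "chd", "prior_stroke", "smoking", "drinking", "sbp_gt_140", "dbp_gt_90",
    "glucose_gt_7", "nihss_baseline", "aspects_baseline", "toast",
    "anesthesia", "bridging", "onset_to_puncture_min",
    "puncture_to_recanalization_min", "onset_to_recanalization_min",
    "mtici_2b3", "good_collateral",
]


def _parse_bool(value: object, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse boolean {column}={value!r}")


def _parse_float(value: object, column: str, row: int) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row}: non-numeric coordinate {column}={value!r}"
        ) from exc
    if math.isnan(x):
        raise ParseError(f"row {row}: missing coordinate {column}")
    return x


def _record_from_mapping(obj: dict, row: int) -> AngioLandmarks:
    for col in ("patient_id", "side", "t", "midline", "occlusion",
                "a1_status", "acoa_patent", "measured_from_contralateral"):
        if col not in obj:
            raise ParseError(f"row {row}: missing required field {col!r}")
    cands = tuple(
        (_parse_float(p[0], "terminal_candidates.x", row),
         _parse_float(p[1], "terminal_candidates.y", row))
        for p in obj.get("terminal_candidates", [])
    )
    lm = AngioLandmarks(
        patient_id=str(obj["patient_id"]),
        side=str(obj["side"]),
        t=(_parse_float(obj["t"][0], "t.x", row),
           _parse_float(obj["t"][1], "t.y", row)),
        terminal_candidates=cands,
        midline=(
            (_parse_float(obj["midline"][0][0], "midline.base.x", row),
             _parse_float(obj["midline"][0][1], "midline.base.y", row)),
            (_parse_float(obj["midline"][1][0], "midline.apex.x", row),
             _parse_float(obj["midline"][1][1], "midline.apex.y", row)),
        ),
        occlusion=str(obj["occlusion"]),
        a1_status=str(obj["a1_status"]),
        acoa_patent=_parse_bool(obj["acoa_patent"], "acoa_patent", row),
        measured_from_contralateral=_parse_bool(
            obj["measured_from_contralateral"], "measured_from_contralateral",
            row),
        rater=obj.get("rater"),
    )
    lm.validate()
    return lm


def read_landmarks(path: Union[str, Path]) -> List[AngioLandmarks]:
    """Read landmark records from CSV or JSON; schema violations raise
    :class:`ParseError` naming the field and row."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ParseError("landmark JSON must be a list of records")
        return [_record_from_mapping(obj, i) for i, obj in enumerate(data)]

    df = pd.read_csv(path, dtype=str)
    for col in _REQUIRED_LANDMARK_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"landmark CSV is missing required column {col!r}")
    term_idx = sorted(
        int(c[len("term_x_"):]) for c in df.columns if c.startswith("term_x_")
    )
    for i in term_idx:
        if f"term_y_{i}" not in df.columns:
            raise ParseError(f"landmark CSV has term_x_{i} without term_y_{i}")

    records: List[AngioLandmarks] = []
    for row, rec in df.iterrows():
        cands: List[Tuple[float, float]] = []
        for i in term_idx:
            x, y = rec.get(f"term_x_{i}"), rec.get(f"term_y_{i}")
            if pd.isna(x) and pd.isna(y):
                continue
            cands.append((_parse_float(x, f"term_x_{i}", row),
                          _parse_float(y, f"term_y_{i}", row)))
        lm = AngioLandmarks(
            patient_id=str(rec["patient_id"]),
            side=str(rec["side"]),
            t=(_parse_float(rec["t_x"], "t_x", row),
               _parse_float(rec["t_y"], "t_y", row)),
            midline=(
                (_parse_float(rec["mid_base_x"], "mid_base_x", row),
                 _parse_float(rec["mid_base_y"], "mid_base_y", row)),
                (_parse_float(rec["mid_apex_x"], "mid_apex_x", row),
                 _parse_float(rec["mid_apex_y"], "mid_apex_y", row)),
            ),
            terminal_candidates=tuple(cands),
            occlusion=str(rec["occlusion"]),
            a1_status=str(rec["a1_status"]),
            acoa_patent=_parse_bool(rec["acoa_patent"], "acoa_patent", row),
            measured_from_contralateral=_parse_bool(
                rec["contralateral"], "contralateral", row),
            rater=(None if "rater" not in df.columns or pd.isna(rec["rater"])
                   else str(rec["rater"])),
        )
        lm.validate()
        records.append(lm)
    return records


def write_landmarks(records: Sequence[AngioLandmarks],
                    path: Union[str, Path]) -> None:
    """Write landmark records to CSV or JSON (by extension); lossless
    round-trip with :func:`read_landmarks`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = [
            {
                "patient_id": lm.patient_id,
                "side": lm.side,
                "t": list(lm.t),
                "midline": [list(lm.midline[0]), list(lm.midline[1])],
                "terminal_candidates": [list(p) for p in lm.terminal_candidates],
                "occlusion": lm.occlusion,
                "a1_status": lm.a1_status,
                "acoa_patent": lm.acoa_patent,
                "measured_from_contralateral": lm.measured_from_contralateral,
                "rater": lm.rater,
            }
            for lm in records
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
        return

    max_terms = max((len(lm.terminal_candidates) for lm in records), default=0)
    rows = []
    for lm in records:
        row = {
            "patient_id": lm.patient_id,
            "side": lm.side,
            "t_x": repr(lm.t[0]), "t_y": repr(lm.t[1]),
            "mid_base_x": repr(lm.midline[0][0]),
            "mid_base_y": repr(lm.midline[0][1]),
            "mid_apex_x": repr(lm.midline[1][0]),
            "mid_apex_y": repr(lm.midline[1][1]),
            "occlusion": lm.occlusion,
            "a1_status": lm.a1_status,
            "acoa_patent": lm.acoa_patent,
            "contralateral": lm.measured_from_contralateral,
            "rater": lm.rater if lm.rater is not None else "",
        }
        for i, (x, y) in enumerate(lm.terminal_candidates, start=1):
            row[f"term_x_{i}"] = repr(x)
            row[f"term_y_{i}"] = repr(y)
        rows.append(row)
    cols = _REQUIRED_LANDMARK_COLUMNS + ["rater"] + [
        c for i in range(1, max_terms + 1) for c in (f"term_x_{i}", f"term_y_{i}")
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV; booleans are normalized, numerics coerced."""
    df = pd.read_csv(path)
    for col in df.columns:
        if df[col].dtype == object:
            lowered = df[col].astype(str).str.strip().str.lower()
            if lowered.isin(_TRUE | _FALSE).all():
                df[col] = lowered.isin(_TRUE)
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort_path: Optional[Union[str, Path]] = None
    landmarks_path: Optional[Union[str, Path]] = None
    out_dir: Union[str, Path] = "abza_out"
    seed: int = 0
    scheme: GradingScheme = field(default_factory=GradingScheme)
    favorable_cutoff: int = 2
    univariate_variables: Optional[List[str]] = None
    models: Optional[List[Tuple[str, List[str]]]] = None
    roc_score_column: str = "abza_deg"


@dataclass
class AnalysisReport:
    """Everything the analysis stage produces, JSON-serializable."""

    univariate: List[UnivariateResult]
    models: List[LogisticModelResult]
    roc: Optional[ROCResult]
    contingency: Dict[str, ContingencyResult]
    irr: Dict[str, float]
    metadata: Dict[str, object]

    def to_dict(self) -> dict:
        return {
            "univariate": [dataclasses.asdict(u) for u in self.univariate],
            "models": [dataclasses.asdict(m) for m in self.models],
            "roc": None if self.roc is None else dataclasses.asdict(self.roc),
            "contingency": {k: dataclasses.asdict(v)
                            for k, v in self.contingency.items()},
            "irr": self.irr,
            "metadata": self.metadata,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _default_models(df: pd.DataFrame) -> List[Tuple[str, List[str]]]:
    models: List[Tuple[str, List[str]]] = []
    base = ["age", "toast", "mtici_2b3"]
    if "good_collateral" in df.columns:
        models.append(("Model 1", base + ["good_collateral"]))
    if "asitn_good" in df.columns:
        models.append(("Model 2", base + ["asitn_good"]))
    return models


def analyze_cohort(df: pd.DataFrame, config: RunConfig) -> AnalysisReport:
    """Run the full statistics pipeline on a graded cohort table."""
    df = df.copy()
    scheme = config.scheme
    if "abza_grade" not in df.columns and "abza_deg" in df.columns:
        graded = [grade_angle(a, scheme) for a in df["abza_deg"]]
        df["abza_grade"] = [g.grade for g in graded]
    if "good_collateral" not in df.columns and "abza_grade" in df.columns:
        df["good_collateral"] = df["abza_grade"] > scheme.dichotomy_threshold_grade
    if "asitn_good" not in df.columns and "asitn_grade" in df.columns:
        df["asitn_good"] = df["asitn_grade"] > scheme.dichotomy_threshold_grade

    if df.empty:
        raise ValueError("empty cohort: nothing to analyze")

    fav = df["mrs_90"] <= config.favorable_cutoff

    variables = config.univariate_variables
    if variables is None:
        variables = [v for v in DEFAULT_UNIVARIATE_VARIABLES if v in df.columns]
    univariate = []
    for var in variables:
        try:
            univariate.append(
                univariate_compare(df, var, favorable_cutoff=config.favorable_cutoff)
            )
        except DegenerateTestError as exc:
            logger.warning("univariate %s skipped: %s", var, exc)

    models = []
    for label, covs in (config.models if config.models is not None
                        else _default_models(df)):
        models.append(fit_logistic(df, covs, favorable_cutoff=config.favorable_cutoff,
                                   model_label=label))

    roc = None
    if config.roc_score_column in df.columns:
        roc = roc_analysis(df[config.roc_score_column].to_numpy(),
                           fav.to_numpy().astype(int))

    contingency: Dict[str, ContingencyResult] = {}
    if "good_collateral" in df.columns:
        tab = pd.crosstab(fav, df["good_collateral"]).to_numpy()
        contingency["mrs_by_collateral"] = contingency_analysis(tab)
        ce_laa = df[df["toast"].isin(["CE", "LAA"])] if "toast" in df.columns else None
        if ce_laa is not None and not ce_laa.empty:
            tab2 = pd.crosstab(ce_laa["toast"], ce_laa["good_collateral"]).to_numpy()
            contingency["toast_by_collateral"] = contingency_analysis(tab2)

    irr: Dict[str, float] = {}
    for col_a, col_b, mode, key in (
        ("abza_deg_rater_a", "abza_deg_rater_b", "continuous_angle", "icc_angle"),
        ("abza_grade_rater_a", "abza_grade_rater_b", "ordinal_grade",
         "weighted_kappa_grade"),
    ):
        if col_a in df.columns and col_b in df.columns:
            irr[key] = interrater_reliability(df[col_a], df[col_b], mode=mode)

    # hash of the analytic configuration only, so two runs that differ just
    # in output location hash identically
    config_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(config).items()
             if k != "out_dir"},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    metadata = {
        "tool_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "n_patients": int(len(df)),
        "n_favorable": int(fav.sum()),
    }
    return AnalysisReport(univariate=univariate, models=models, roc=roc,
                          contingency=contingency, irr=irr, metadata=metadata)


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """measure → grade → analyze, persisting every stage's output.

    Reads the cohort table (and optionally a landmark file whose measured
    angles are merged in by patient id), grades the angles, runs the
    statistics, and writes the per-patient score CSV, the report JSON and
    human-readable tables into ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_path is None:
        raise ValueError("run_pipeline requires a cohort_path")
    df = read_cohort(config.cohort_path)
    if df.empty:
        raise ValueError("empty cohort: nothing to analyze")

    if config.landmarks_path is not None:
        measured = {
            lm.patient_id: measure_abza(lm)
            for lm in read_landmarks(config.landmarks_path)
        }
        df["abza_deg"] = df["patient_id"].map(
            {pid: m.abza_deg for pid, m in measured.items()}
        )

    scheme = config.scheme
    if "abza_deg" in df.columns:
        graded = [grade_angle(a, scheme) for a in df["abza_deg"]]
        df["abza_trans"] = [g.abza_trans for g in graded]
        df["abza_grade"] = [g.grade for g in graded]
        df["collateral_class"] = [g.collateral_class for g in graded]
        df["good_collateral"] = df["collateral_class"] == GOOD

    report = analyze_cohort(df, config)

    score_cols = [c for c in ("patient_id", "abza_deg", "abza_trans",
                              "abza_grade", "collateral_class", "mrs_90")
                  if c in df.columns]
    df[score_cols].to_csv(out / "patient_scores.csv", index=False)
    report.to_json(out / "report.json")
    pd.DataFrame([dataclasses.asdict(u) for u in report.univariate]).to_csv(
        out / "univariate.csv", index=False)
    model_rows = [
        {"model": m.label, **dataclasses.asdict(t)}
        for m in report.models for t in m.terms
    ]
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
    logger.info("pipeline complete: %s (seed=%d, config=%s)", out,
                config.seed, report.metadata["config_hash"])
    return report
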