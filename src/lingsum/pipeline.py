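"""Cohort I/O, configuration and the end-to-end summarization pipeline.

Flow: read (or simulate) the per-child cohort table -> drop children without
a Bayley assessment -> induce linguistic variables per feature with fuzzy
c-means -> fuzzify records -> enumerate type-I/II sentences per group scope ->
evaluate truth degrees (probabilistic fuzzification mechanism by default) ->
reduce for interpretability -> render and serialize.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    BAYLEY_AGE_EQUIVALENTS,
    BAYLEY_COMPOSITES,
    CohortSpec,
    generate_cohort,
)
from .fuzzification import (
    AGE_RELATIVE_LABELS,
    THREE_LEVEL_LABELS,
    LinguisticVariable,
    build_age_relative_variable,
    fit_fcm,
    variable_from_centers,
)
from .fuzzy_core import DiscreteFuzzySet
from .interpretability import SummaryReport, reduce_summary
from .protoform import (
    QuantifiedSentence,
    Quantifier,
    default_quantifiers,
    enumerate_sentences,
    render_sentence,
    sentence_record,
)
from .truth import (
    EvaluationConfig,
    FiResult,
    evaluate_all,
    fi_evaluate_details,
    semi_fuzzy_almost_all,
)

logger = logging.getLogger("lingsum")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_cohort",
    "write_cohort",
    "build_variables",
    "run_pipeline",
    "worked_example",
    "worked_example_table",
    "validate_sentence_record",
    "DEFAULT_ET_FEATURES",
]

# the study's discriminative attention features, per AOI
_ET_STEMS = ("net_dwell_ms", "dwell_ms", "glance_duration_ms",
             "diversion_duration_ms", "first_fixation_duration_ms",
             "fixation_count", "fixation_time_ms")
DEFAULT_ET_FEATURES = tuple(f"{aoi}_{stem}" for aoi in ("si", "anim")
                            for stem in _ET_STEMS)

MANDATORY_COLUMNS = ("group", "chron_age_months")


@dataclass
class PipelineConfig:
    """Everything a summarization run needs, round-trippable through YAML."""

    input: Optional[str] = None  # cohort CSV; None -> simulate cohort_spec
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    et_features: tuple[str, ...] = DEFAULT_ET_FEATURES
    composite_features: tuple[str, ...] = BAYLEY_COMPOSITES
    age_relative_features: tuple[str, ...] = BAYLEY_AGE_EQUIVALENTS
    quantifier_names: tuple[str, ...] = ("few", "about half", "most")
    scopes: tuple[str, ...] = ("ASD", "TD")
    method: str = "fi"
    t_norm: str = "min"
    tau: float = 0.90
    seed: int = 0
    mc_samples: int = 100_000
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")

    def quantifiers(self) -> tuple[Quantifier, ...]:
        by_name = {q.name: q for q in default_quantifiers()}
        missing = [n for n in self.quantifier_names if n not in by_name]
        if missing:
            raise ValueError(f"unknown quantifiers: {missing}")
        return tuple(by_name[n] for n in self.quantifier_names)

    def evaluation(self) -> EvaluationConfig:
        return EvaluationConfig(method=self.method, t_norm=self.t_norm,
                                mc_samples=self.mc_samples, seed=self.seed)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        spec_data = data.pop("cohort_spec", None)
        cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in data.items()})
        if spec_data:
            spec_data.pop("asd", None), spec_data.pop("td", None)
            cfg.cohort_spec = CohortSpec(**spec_data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cohort_spec"] = {
            k: v for k, v in asdict(self.cohort_spec).items()
            if k not in ("asd", "td")}
        for k, v in list(data.items()):
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def _known_columns() -> set[str]:
    from .cohort import AOIS, ET_FEATURES
    cols = {"child_id", *MANDATORY_COLUMNS}
    cols.update(f"{aoi}_{stem}" for aoi in AOIS for stem in ET_FEATURES)
    cols.update(BAYLEY_COMPOSITES)
    cols.update(BAYLEY_AGE_EQUIVALENTS)
    return cols


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty Bayley cells become NaN (flagged absent).

    Missing mandatory columns or non-numeric cells raise with the offending
    name/location; unknown extra columns are preserved with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    extra = [c for c in df.columns if c not in _known_columns()]
    if extra:
        logger.warning("ignoring unknown columns: %s", ", ".join(extra))
    for col in df.columns:
        if col in ("child_id", "group") or col in extra:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {df[col][row]!r} in column {col!r}, "
                f"row {row + 2} (1-based, incl. header)")
        df[col] = coerced
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Variable induction and fuzzification
# ---------------------------------------------------------------------------

def display_name(column: str) -> str:
    """Human phrase for a cohort column ("anim_net_dwell_ms" -> "animation
    net dwell time", "cognitive_age_months" -> "cognitive age")."""
    name = column
    for suffix in ("_ms", "_months"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    name = name.replace("_", " ")
    if name.startswith("si "):
        name = "SI " + name[3:]
    elif name.startswith("anim "):
        name = "animation " + name[5:]
    if name.endswith("dwell"):
        name += " time"
    return name


def build_variables(df: pd.DataFrame, config: PipelineConfig
                    ) -> tuple[dict[str, LinguisticVariable], pd.DataFrame]:
    """Induce one linguistic variable per configured feature.

    Returns the variables keyed by feature name and the working value table
    (age-equivalent subscales replaced by their difference to chronological
    age, in months).
    """
    values = df.copy()
    variables: dict[str, LinguisticVariable] = {}
    for col in tuple(config.et_features) + tuple(config.composite_features):
        x = values[col].to_numpy(dtype=float)
        fit = fit_fcm(x, k=3, seed=config.seed)
        variables[col] = variable_from_centers(
            fit.centers, THREE_LEVEL_LABELS,
            (float(x.min()), float(x.max())),
            feature_name=col, display_name=display_name(col))
    for col in config.age_relative_features:
        diff = (values[col] - values["chron_age_months"]).to_numpy(dtype=float)
        values[col] = diff
        variables[col] = build_age_relative_variable(
            diff, seed=config.seed, feature_name=col,
            display_name=display_name(col))
    return variables, values


def fuzzify_table(values: pd.DataFrame,
                  variables: dict[str, LinguisticVariable]) -> dict:
    """Vectorized degrees: (feature, label) -> array aligned with the table."""
    from .fuzzy_core import evaluate_membership_array

    degrees = {}
    for feat, var in variables.items():
        x = values[feat].to_numpy(dtype=float)
        for label in var.labels:
            degrees[(feat, label)] = evaluate_membership_array(
                var.functions[label], x)
    return degrees


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    usable: pd.DataFrame
    excluded: int
    variables: dict
    sentences: list
    report: SummaryReport


def _make_evaluate_fn(degrees, groups, evaluation: EvaluationConfig):
    def evaluate_one(sentence: QuantifiedSentence) -> Optional[float]:
        evaluate_all([sentence], degrees, groups, evaluation)
        return sentence.truth

    return evaluate_one


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full summarization pipeline from a config."""
    if config.input is not None:
        cohort = read_cohort(config.input)
    else:
        cohort = generate_cohort(config.cohort_spec, seed=config.seed)

    bayley_cols = [c for c in (*config.composite_features,
                               *config.age_relative_features)
                   if c in cohort.columns]
    usable = cohort.dropna(subset=bayley_cols).reset_index(drop=True)
    excluded = len(cohort) - len(usable)
    if excluded:
        logger.info("excluded %d children without a Bayley assessment",
                    excluded)
    if usable.empty:
        raise ValueError("no usable records: every child lacks Bayley data")

    variables, values = build_variables(usable, config)
    degrees = fuzzify_table(values, variables)
    groups = usable["group"].to_numpy()

    sentences: list[QuantifiedSentence] = []
    quantifiers = config.quantifiers()
    for scope in config.scopes:
        sentences.extend(enumerate_sentences(
            list(variables.values()), quantifiers, scope=scope))
    evaluation = config.evaluation()
    evaluate_all(sentences, degrees, groups, evaluation)
    undefined = sum(s.undefined for s in sentences)
    if undefined:
        logger.info("%d sentences with vacuous pre-summarizer flagged "
                    "undefined", undefined)

    evaluate_fn = _make_evaluate_fn(degrees, groups, evaluation)
    report = reduce_summary(sentences, variables, evaluate_fn, tau=config.tau)
    for s in sentences + report.merged:
        s.text = render_sentence(s, variables)

    if config.output_dir:
        _write_outputs(Path(config.output_dir), config, variables, report)
    return PipelineResult(cohort, usable, excluded, variables, sentences,
                          report)


def _write_outputs(outdir: Path, config: PipelineConfig, variables,
                   report: SummaryReport) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    final = sorted(report.retained + report.merged,
                   key=lambda s: (s.scope, -(s.truth or 0.0)))
    (outdir / "sentences.json").write_text(json.dumps(
        [sentence_record(s) for s in final], indent=2))
    lines = ["Linguistic summaries", "=" * 60]
    for s in final:
        lines.append(f"{s.text} [{s.truth:.2f}]")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    fuzz = {
        feat: {
            "display_name": var.display_name,
            "labels": list(var.labels),
            "functions": {lbl: {"shape": mf.shape,
                                "breakpoints": list(mf.breakpoints)}
                          for lbl, mf in var.functions.items()},
        }
        for feat, var in variables.items()
    }
    (outdir / "fuzzification_report.json").write_text(json.dumps(fuzz, indent=2))


# ---------------------------------------------------------------------------
# Worked example: 'almost all' on the printed four-element fuzzy sets
# ---------------------------------------------------------------------------

def worked_example() -> FiResult:
    """Fuzzification of the semi-fuzzy 'almost all' on the reference sets.

    A = {0.8/e1, 0.9/e2, 1/e3, 0.2/e4} (behind by age) and
    B = {1/e1, 0.8/e2, 0.3/e3, 0.1/e4} (high animation net dwell time).
    """
    universe = ("e1", "e2", "e3", "e4")
    A = DiscreteFuzzySet.from_degrees(universe, (0.8, 0.9, 1.0, 0.2))
    B = DiscreteFuzzySet.from_degrees(universe, (1.0, 0.8, 0.3, 0.1))
    return fi_evaluate_details(semi_fuzzy_almost_all, [A, B])


def worked_example_table(result: Optional[FiResult] = None) -> str:
    """Plain-text rectangle table (interval widths x quantifier values)."""
    res = result or worked_example()
    rows_a, cols_b = res.intervals
    q = {idx: (w, v) for idx, w, v in res.cells}
    header = ["alpha1 \\ alpha2"] + [f"({lo:.2g},{hi:.2g}]" for lo, hi in cols_b]
    lines = ["  ".join(f"{h:>16}" for h in header)]
    for i, (lo, hi) in enumerate(rows_a):
        cells = [f"({lo:.2g},{hi:.2g}]".rjust(16)]
        for j in range(len(cols_b)):
            w, v = q[(i, j)]
            cells.append(f"{w:.2f}:{v:.2f}".rjust(16))
        lines.append("  ".join(cells))
    lines.append(f"evaluation result = {res.value:.4f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Sentence-record schema (mirrored in docs/sentence_schema.json)
# ---------------------------------------------------------------------------

def validate_sentence_record(rec: dict) -> None:
    """Structural validation of one serialized sentence record."""
    required = {"form": str, "quantifier": str, "scope": str,
                "summarizer": list, "summ_connective": str,
                "undefined": bool, "text": str}
    for key, typ in required.items():
        if key not in rec:
            raise ValueError(f"sentence record missing key {key!r}")
        if not isinstance(rec[key], typ):
            raise ValueError(f"sentence record key {key!r} has wrong type")
    if rec["form"] not in ("type1", "type2"):
        raise ValueError("form must be type1 or type2")
    if rec["form"] == "type2" and not rec.get("pre_summarizer"):
        raise ValueError("type2 record needs a pre_summarizer")
    truth = rec.get("truth")
    if truth is not None and not (0.0 <= truth <= 1.0):
        raise ValueError("truth outside [0, 1]")
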