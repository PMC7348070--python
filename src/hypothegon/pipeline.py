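"""End-to-end orchestration: file formats, run manifests, and study reports.

Judgment files are delimited text (comma-separated, UTF-8, header row) with
columns ``subject_id, condition, case_id, p_WN, p_ID, p_SL`` — one row per
subject × case.  Hand-entered triples are cleaned with a 1e-6 normalization
tolerance and renormalized exactly.  Study runs write per-subject
classifications, the certainty cross-table, the condition × label count
table, contingency Bayes factors against a reference condition, a JSON run
summary, and a manifest recording configs, seeds, input digests and package
version; all outputs except the manifest timestamp are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import (
    ClassifierConfig,
    CohortReport,
    SubjectJudgments,
    classify_cohort,
)
from .comparison import ComparisonConfig, ContingencyTable, compare_conditions
from .exceptions import DataError, MalformedJudgmentError
from .geometry import INPUT_CLEANUP_TOL, validate_probability_vector
from .strategies import STRATEGIES, StudyDesign
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger("hypothegon")

JUDGMENT_COLUMNS = ["subject_id", "condition", "case_id", "p_WN", "p_ID", "p_SL"]


# ---------------------------------------------------------------------------
# file formats


def read_judgments(path) -> list[SubjectJudgments]:
    """Parse a judgments CSV into per-subject records.

    Raises :class:`DataError` with file/row context on malformed input.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: cannot parse judgments file: {exc}") from exc
    missing = [c for c in JUDGMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")

    subjects: dict[tuple[str, str], list] = {}
    for idx, row in frame.iterrows():
        key = (str(row["subject_id"]), str(row["condition"]))
        triple = (row["p_WN"], row["p_ID"], row["p_SL"])
        try:
            vec = validate_probability_vector(triple, tolerance=INPUT_CLEANUP_TOL)
        except MalformedJudgmentError as exc:
            raise DataError(
                f"{path}, row {idx + 2} (subject {key[0]!r}, case "
                f"{row['case_id']!r}): {exc}"
            ) from exc
        subjects.setdefault(key, []).append(
            (str(row["case_id"]), tuple(float(v) for v in vec))
        )
    return [
        SubjectJudgments(subject_id=sid, condition=cond, judgments=tuple(js))
        for (sid, cond), js in subjects.items()
    ]


def write_judgments(subjects, path) -> None:
    """Write subjects in the exact dialect :func:`read_judgments` consumes."""
    rows = [
        {
            "subject_id": s.subject_id,
            "condition": s.condition,
            "case_id": cid,
            "p_WN": p[0],
            "p_ID": p[1],
            "p_SL": p[2],
        }
        for s in subjects
        for cid, p in s.judgments
    ]
    pd.DataFrame(rows, columns=JUDGMENT_COLUMNS).to_csv(path, index=False)


def read_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def configs_from_dict(cfg: dict):
    """Split one configuration mapping into the four component configs."""
    design = StudyDesign.from_config(cfg.get("design", {}))
    clf = ClassifierConfig(**(cfg.get("classifier") or {}))
    cmp_cfg = ComparisonConfig(**(cfg.get("comparison") or {}))
    gen = (
        GeneratorConfig.from_config({**cfg["generator"], "design": cfg.get("design", {})})
        if cfg.get("generator")
        else None
    )
    return design, clf, cmp_cfg, gen


# ---------------------------------------------------------------------------
# manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_manifest(configs: dict, inputs: dict, seeds: dict, events: list) -> dict:
    return {
        "artifact": {"name": "hypothegon", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": configs,
        "inputs": {str(k): _sha256(v) for k, v in inputs.items()},
        "seeds": seeds,
        "events": events,
    }


# ---------------------------------------------------------------------------
# study run


def run_study(
    judgments_file,
    design: StudyDesign | None = None,
    clf_cfg: ClassifierConfig | None = None,
    cmp_cfg: ComparisonConfig | None = None,
    out_dir=None,
    reference_condition: str | None = None,
) -> dict:
    """Classify a judgments file and compare conditions against a reference.

    Returns the run summary; when ``out_dir`` is given, also writes
    ``classifications.csv``, ``certainty_table.csv``, ``condition_table.csv``,
    ``run_summary.json`` and ``manifest.json`` there.  Partial outputs are
    removed if the run fails midway.
    """
    design = design or StudyDesign()
    clf_cfg = clf_cfg or ClassifierConfig()
    cmp_cfg = cmp_cfg or ComparisonConfig()
    events: list[str] = []

    subjects = read_judgments(judgments_file)
    events.append(f"read {len(subjects)} subjects from {judgments_file}")
    logger.info("classifying %d subjects", len(subjects))
    if clf_cfg.d_outside_robustness_band:
        events.append(
            f"warning: d={clf_cfg.d} outside the checked robustness band 0.05-0.20"
        )
        logger.warning("d=%s outside checked robustness band", clf_cfg.d)

    report = classify_cohort(subjects, design, clf_cfg)

    conditions = list(report.condition_table.index)
    comparisons = {}
    if len(conditions) < 2:
        events.append("single condition: contingency comparison skipped")
        logger.info("single condition: comparison skipped")
    else:
        ref = reference_condition or conditions[0]
        if ref not in conditions:
            raise DataError(f"reference condition {ref!r} not present in data")
        strat_cols = [c for c in report.condition_table.columns if c in STRATEGIES]
        for cond in conditions:
            if cond == ref:
                continue
            counts = report.condition_table.loc[[ref, cond], strat_cols]
            table = ContingencyTable(
                counts=tuple(tuple(int(v) for v in row) for row in counts.values),
                row_labels=(ref, cond),
                col_labels=tuple(strat_cols),
            )
            comparisons[f"{ref} vs {cond}"] = compare_conditions(
                table, cmp_cfg
            ).as_dict()
            events.append(f"compared {ref!r} vs {cond!r}")

    summary = {
        "n_subjects": len(subjects),
        "conditions": conditions,
        "config": {
            "design": design.to_config(),
            "classifier": asdict(clf_cfg),
            "comparison": asdict(cmp_cfg),
        },
        "certainty_table": {
            str(k): {str(c): int(x) for c, x in row.items()}
            for k, row in report.certainty_table.to_dict(orient="index").items()
        },
        "condition_table": {
            str(k): {str(c): int(x) for c, x in row.items()}
            for k, row in report.condition_table.to_dict(orient="index").items()
        },
        "comparisons": comparisons,
    }

    if out_dir is not None:
        _write_study_outputs(out_dir, judgments_file, report, summary, events)
    return summary


def _write_study_outputs(out_dir, judgments_file, report: CohortReport,
                         summary: dict, events: list) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _write(name: str, writer) -> None:
            target = out / name
            writer(target)
            written.append(target)

        _write("classifications.csv",
               lambda p: report.to_frame().to_csv(p, index=False))
        _write("certainty_table.csv",
               lambda p: report.certainty_table.to_csv(p))
        _write("condition_table.csv",
               lambda p: report.condition_table.to_csv(p))
        _write("run_summary.json",
               lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)))
        manifest = build_manifest(
            configs=summary["config"],
            inputs={"judgments": judgments_file},
            seeds={},
            events=events,
        )
        _write("manifest.json",
               lambda p: p.write_text(json.dumps(manifest, indent=2)))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def simulate_to_files(
    gen_cfg: GeneratorConfig, judgments_path, truth_path=None
) -> None:
    """Generate a cohort and write it in the classifier's input dialect."""
    cohort = generate_cohort(gen_cfg)
    write_judgments(cohort.subjects, judgments_path)
    if truth_path is not None:
        pd.DataFrame(
            sorted(cohort.truth.items()), columns=["subject_id", "strategy"]
        ).to_csv(truth_path, index=False)
    logger.info(
        "simulated %d subjects (seed %d) -> %s",
        len(cohort.subjects),
        gen_cfg.seed,
        judgments_path,
    )
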