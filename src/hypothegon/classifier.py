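"""Naive-Bayes classification of a subject's updating strategy.

Each subject supplies one judged simplex position per battery case.  Under the
hypothesis that the subject consistently follows strategy S, a judgment Ê for
a case with predicted position Ê_S is modelled with the isotropic Gaussian
kernel

    p(Ê | Ĥ_S) = (1/N) · exp(−|Ê − Ê_S|² / d),

with the bandwidth d (default 0.1) expressed in squared simplex-distance
units: the density falls to 1/e of its maximum when the squared distance
equals d.  The normalization N is identical across strategies for a fixed d
and cancels from every posterior and Bayes-factor ratio, so it is never
computed.  Judgments are combined naively (independently) across the battery:

    p_post(Ĥ_S) ∝ p(Ê_1|Ĥ_S) ··· p(Ê_6|Ĥ_S) · p_prior(Ĥ_S).

All products are sums of logs; posteriors come from a log-space softmax.
Classification certainty is reported as the Bayes factor of the dominant
strategy hypothesis over the runner-up (BF_1:2) and as the maximal posterior
under equal strategy priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import ConfigurationError, DataError, MalformedJudgmentError
from .geometry import (
    NORMALIZATION_TOL,
    generate_lattice,
    snap_to_lattice,
    validate_probability_vector,
)
from .strategies import STRATEGIES, StudyDesign, battery_predictions

#: Bandwidth range the original robustness check covered; values outside are
#: flagged in reports, not rejected.
D_ROBUSTNESS_BAND = (0.05, 0.20)

#: Per-subject evidence categories over BF_1:2 (lower edge of the first bin is
#: inclusive; the >100 and >1000 bins share the label "extreme" but are kept
#: separate as columns of the certainty table).
EVIDENCE_BINS = (
    (1.0, 3.0, "weak"),
    (3.0, 10.0, "moderate"),
    (10.0, 30.0, "strong"),
    (30.0, 100.0, "very strong"),
    (100.0, 1000.0, "extreme"),
    (1000.0, math.inf, "extreme"),
)

#: Column headers of the certainty cross-table, in ascending-evidence order.
BF_BIN_LABELS = (">1", ">3", ">10", ">30", ">100", ">1000")

#: Label reported when the top two strategies score exactly equally.
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SubjectJudgments:
    """A subject's ordered judged positions over the battery."""

    subject_id: str
    condition: str
    judgments: tuple[tuple[str, tuple[float, float, float]], ...]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {cid: np.asarray(p, dtype=float) for cid, p in self.judgments}


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of the strategy classifier.

    ``d`` is the Gaussian kernel scale in squared simplex-distance units.
    ``lattice_resolution``, when set, snaps judgments and predictions to the
    triangular lattice of that subdivision level before computing distances
    (continuum mode when ``None``).  ``radius_mode`` switches the exponent to
    exp(−r²/d²) — the bandwidth read as a literal radius — for sensitivity
    analysis only.
    """

    d: float = 0.1
    strategy_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    lattice_resolution: int | None = None
    tie_rule: str = "spread"
    radius_mode: bool = False

    def __post_init__(self):
        if not self.d > 0:
            raise ConfigurationError(f"kernel scale d must be positive, got {self.d!r}")
        prior = validate_probability_vector(self.strategy_prior, tolerance=1e-6)
        object.__setattr__(self, "strategy_prior", tuple(prior))

    @property
    def d_outside_robustness_band(self) -> bool:
        lo, hi = D_ROBUSTNESS_BAND
        return not lo <= self.d <= hi


@dataclass(frozen=True)
class ClassificationResult:
    """Per-subject classification with certainty metrics."""

    subject_id: str
    condition: str
    log_scores: dict[str, float]
    posterior: dict[str, float]
    bf: pd.DataFrame
    label: str
    bf_1_2: float
    log10_bf_1_2: float
    p_post_max: float
    evidence_category: str


def kernel_log_likelihood(
    judgment, predicted, d: float, radius_mode: bool = False
) -> float:
    """Log kernel density of a judgment around a predicted position.

    Up to the additive constant −log N, which is shared by all strategies for
    a fixed ``d`` and therefore droppable.
    """
    if not d > 0:
        raise ConfigurationError(f"kernel scale d must be positive, got {d!r}")
    diff = np.asarray(judgment, dtype=float) - np.asarray(predicted, dtype=float)
    sq = float(diff @ diff)
    return -sq / (d * d) if radius_mode else -sq / d


def evidence_category(bf_1_2: float) -> str:
    """Evidence label for a dominant-vs-runner-up Bayes factor (>= 1)."""
    if not bf_1_2 >= 1.0:
        raise ConfigurationError(
            f"BF_1:2 is dominant over runner-up and must be >= 1, got {bf_1_2!r}"
        )
    for lo, hi, label in EVIDENCE_BINS:
        if bf_1_2 <= hi:
            return label
    return "extreme"


def bf_bin(bf_1_2: float) -> str:
    """Certainty-table column for a BF_1:2 value (lower edges exclusive above 1)."""
    if not bf_1_2 >= 1.0:
        raise ConfigurationError(f"BF_1:2 must be >= 1, got {bf_1_2!r}")
    edges = (1.0, 3.0, 10.0, 30.0, 100.0, 1000.0)
    idx = 0
    for i, e in enumerate(edges):
        if bf_1_2 > e or (i == 0 and bf_1_2 >= e):
            idx = i
    return BF_BIN_LABELS[idx]


def _subject_log_scores(
    subject: SubjectJudgments,
    predictions: dict[str, dict[str, np.ndarray]],
    cfg: ClassifierConfig,
    lattice=None,
) -> np.ndarray:
    scores = np.zeros(len(STRATEGIES))
    if not subject.judgments:
        raise DataError(f"subject {subject.subject_id!r} has no judgments")
    for case_id, raw in subject.judgments:
        if case_id not in predictions:
            raise DataError(
                f"subject {subject.subject_id!r}: case {case_id!r} does not "
                f"resolve to a battery case"
            )
        try:
            judgment = validate_probability_vector(raw, tolerance=NORMALIZATION_TOL)
        except MalformedJudgmentError as exc:
            raise MalformedJudgmentError(
                f"subject {subject.subject_id!r}, case {case_id!r}: {exc}"
            ) from exc
        if lattice is not None:
            judgment = snap_to_lattice(judgment, lattice)
        for s_idx, strategy in enumerate(STRATEGIES):
            predicted = predictions[case_id][strategy]
            if lattice is not None:
                predicted = snap_to_lattice(predicted, lattice)
            scores[s_idx] += kernel_log_likelihood(
                judgment, predicted, cfg.d, radius_mode=cfg.radius_mode
            )
    return scores


def classify_subject(
    subject: SubjectJudgments,
    design: StudyDesign,
    cfg: ClassifierConfig | None = None,
    _predictions: dict[str, dict[str, np.ndarray]] | None = None,
) -> ClassificationResult:
    """Assign a subject's judgments to BUS, CES or SES.

    ``_predictions`` lets cohort-level callers reuse precomputed battery
    predictions; it must come from :func:`battery_predictions` with the same
    design and tie rule.
    """
    cfg = cfg or ClassifierConfig()
    predictions = _predictions or battery_predictions(design, tie_rule=cfg.tie_rule)
    lattice = (
        generate_lattice(cfg.lattice_resolution)
        if cfg.lattice_resolution is not None
        else None
    )
    scores = _subject_log_scores(subject, predictions, cfg, lattice=lattice)

    log_prior = np.log(np.asarray(cfg.strategy_prior, dtype=float))
    log_post = scores + log_prior
    posterior = np.exp(log_post - logsumexp(log_post))

    bf = np.exp(log_post[:, None] - log_post[None, :])
    bf_frame = pd.DataFrame(bf, index=list(STRATEGIES), columns=list(STRATEGIES))

    order = np.argsort(log_post)[::-1]
    top, runner = order[0], order[1]
    log_bf12 = log_post[top] - log_post[runner]
    if log_bf12 <= 1e-12:  # exactly tied top scores: do not break silently
        label = INDETERMINATE
        bf_1_2 = 1.0
        log_bf12 = 0.0
    else:
        label = STRATEGIES[top]
        bf_1_2 = float(np.exp(log_bf12))
    return ClassificationResult(
        subject_id=subject.subject_id,
        condition=subject.condition,
        log_scores={s: float(scores[i]) for i, s in enumerate(STRATEGIES)},
        posterior={s: float(posterior[i]) for i, s in enumerate(STRATEGIES)},
        bf=bf_frame,
        label=label,
        bf_1_2=bf_1_2,
        log10_bf_1_2=float(log_bf12 / math.log(10.0)),
        p_post_max=float(posterior[top]),
        evidence_category=evidence_category(bf_1_2),
    )


@dataclass
class CohortReport:
    """Cohort-level classification output."""

    results: list[ClassificationResult]
    certainty_table: pd.DataFrame
    condition_table: pd.DataFrame
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "subject_id": r.subject_id,
                "condition": r.condition,
                "label": r.label,
                "bf_1_2": r.bf_1_2,
                "log10_bf_1_2": r.log10_bf_1_2,
                "p_post_max": r.p_post_max,
                "evidence_category": r.evidence_category,
            }
            row.update({f"posterior_{s}": r.posterior[s] for s in STRATEGIES})
            rows.append(row)
        return pd.DataFrame(rows)


def classify_cohort(
    subjects: list[SubjectJudgments],
    design: StudyDesign,
    cfg: ClassifierConfig | None = None,
) -> CohortReport:
    """Classify every subject and tabulate certainty and condition counts."""
    if not subjects:
        raise DataError("empty cohort: no subjects to classify")
    cfg = cfg or ClassifierConfig()
    predictions = battery_predictions(design, tie_rule=cfg.tie_rule)
    results = [
        classify_subject(s, design, cfg, _predictions=predictions) for s in subjects
    ]

    labels = sorted({r.label for r in results} | set(STRATEGIES),
                    key=lambda s: (list(STRATEGIES) + [INDETERMINATE]).index(s)
                    if s in list(STRATEGIES) + [INDETERMINATE] else 99)
    certainty = pd.DataFrame(
        0, index=labels, columns=list(BF_BIN_LABELS), dtype=int
    )
    for r in results:
        certainty.loc[r.label, bf_bin(r.bf_1_2)] += 1

    conditions = list(dict.fromkeys(s.condition for s in subjects))
    condition_table = pd.DataFrame(
        0, index=conditions, columns=labels, dtype=int
    )
    for r in results:
        condition_table.loc[r.condition, r.label] += 1

    return CohortReport(
        results=results,
        certainty_table=certainty,
        condition_table=condition_table,
        config=cfg,
    )
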