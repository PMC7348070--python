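"""Diagnostic situation and judgment-update strategy models.

The diagnostic scenario: a teacher observes a student's response (right or
wrong) to one of three decimal-comparison tasks and judges the probability of
three mutually exclusive misconceptions — whole-number (WN),
ignore-decimal-point (ID), and shorter-is-larger (SL).  Each task elicits its
misconception-consistent response pattern with a fixed sensitivity
(default 80%); base rates default to 60/30/10.

Three update strategies map evidence to a posterior position on the simplex:

* BUS — Bayesian update strategy: posterior_i ∝ prior_i · L_i.
* CES — combined evidence strategy (base-rate neglect): posterior_i ∝ L_i.
* SES — single evidence strategy (base-rate neglect + inverse fallacy): the
  maximal likelihood is taken directly as that hypothesis's probability; the
  remaining mass is spread over the other hypotheses.

Each case is a different student, so priors reset to the design base rates for
every case; there is no chaining of posteriors across the battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DegenerateEvidenceError
from .geometry import validate_probability_vector

#: Strategy labels, in canonical order.
STRATEGIES = ("BUS", "CES", "SES")

#: Supported tie-breaking rules for SES on cases with several maximal likelihoods.
SES_TIE_RULES = ("spread", "max_normalize")

# Most-likely response (True = correct) per task under each misconception,
# in (WN, ID, SL) order.  Task 1 compares 4.8 vs 4.63, task 2 compares
# 3.7 vs 3.02, task 3 compares 3.49 vs 3.4.
TASK_RESPONSE_PATTERN = {
    "task1": (False, False, True),
    "task2": (True, False, True),
    "task3": (True, True, False),
}

TASK_DESCRIPTIONS = {
    "task1": "4.8 vs 4.63",
    "task2": "3.7 vs 3.02",
    "task3": "3.49 vs 3.4",
}


@dataclass(frozen=True)
class DiagnosticCase:
    """One task–response stimulus with its likelihood triple P(E|H_i).

    Likelihoods are conditional on *different* hypotheses and need not sum
    to 1.
    """

    case_id: str
    task_id: str | None
    response_correct: bool | None
    likelihoods: tuple[float, float, float]

    def __post_init__(self):
        L = np.asarray(self.likelihoods, dtype=float)
        if L.shape != (3,) or np.any(L < 0) or np.any(L > 1):
            raise ConfigurationError(
                f"case {self.case_id!r}: likelihoods must be three "
                f"probabilities, got {self.likelihoods!r}"
            )
        object.__setattr__(self, "likelihoods", tuple(float(x) for x in L))


def response_likelihoods(
    task_id: str, response_correct: bool, sensitivity: float
) -> np.ndarray:
    """Likelihood triple P(E|H_i) for an observed response to a task.

    Each hypothesis whose misconception-consistent response matches the
    observed one contributes ``sensitivity``; the others ``1 - sensitivity``.
    """
    if task_id not in TASK_RESPONSE_PATTERN:
        raise ConfigurationError(
            f"unknown task {task_id!r}; known: {sorted(TASK_RESPONSE_PATTERN)}"
        )
    if not 0.5 < sensitivity <= 1.0:
        raise ConfigurationError(
            f"sensitivity must be in (0.5, 1], got {sensitivity!r}"
        )
    pattern = TASK_RESPONSE_PATTERN[task_id]
    return np.array(
        [
            sensitivity if likely == bool(response_correct) else 1.0 - sensitivity
            for likely in pattern
        ]
    )


def default_battery(sensitivity: float = 0.8) -> list[DiagnosticCase]:
    """The six analyzed cases, in presentation order.

    Three cases have a high likelihood under exactly one misconception and
    three under exactly two, which is what makes the strategies separable.
    """
    rows = [
        ("case1", "task2", True),
        ("case2", "task1", False),
        ("case3", "task3", True),
        ("case4", "task2", False),
        ("case5", "task1", True),
        ("case6", "task3", False),
    ]
    return [
        DiagnosticCase(
            case_id=cid,
            task_id=tid,
            response_correct=correct,
            likelihoods=tuple(response_likelihoods(tid, correct, sensitivity)),
        )
        for cid, tid, correct in rows
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Base rates, task sensitivity, and the ordered case battery."""

    priors: tuple[float, float, float] = (0.60, 0.30, 0.10)
    sensitivity: float = 0.80
    battery: tuple[DiagnosticCase, ...] = ()

    def __post_init__(self):
        priors = validate_probability_vector(self.priors, tolerance=INPUT_TOL)
        object.__setattr__(self, "priors", tuple(priors))
        if not 0.5 < self.sensitivity <= 1.0:
            raise ConfigurationError(
                f"sensitivity must be in (0.5, 1], got {self.sensitivity!r}"
            )
        if not self.battery:
            object.__setattr__(
                self, "battery", tuple(default_battery(self.sensitivity))
            )
        ids = [c.case_id for c in self.battery]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate case ids in battery: {ids}")

    @property
    def prior_vector(self) -> np.ndarray:
        return np.asarray(self.priors, dtype=float)

    def case(self, case_id: str) -> DiagnosticCase:
        for c in self.battery:
            if c.case_id == case_id:
                return c
        raise ConfigurationError(f"unknown case id {case_id!r}")

    # -- (de)serialization -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "priors": list(self.priors),
            "sensitivity": self.sensitivity,
            "battery": [
                {
                    "case_id": c.case_id,
                    "task": c.task_id,
                    "response_correct": c.response_correct,
                    "likelihoods": list(c.likelihoods),
                }
                for c in self.battery
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "StudyDesign":
        cfg = dict(cfg or {})
        sensitivity = float(cfg.get("sensitivity", 0.80))
        priors = tuple(cfg.get("priors", (0.60, 0.30, 0.10)))
        battery = []
        for row in cfg.get("battery", []):
            if "likelihoods" in row and row["likelihoods"] is not None:
                L = tuple(float(x) for x in row["likelihoods"])
                task = row.get("task")
                correct = row.get("response_correct")
            else:
                task = row["task"]
                correct = bool(row["response_correct"])
                L = tuple(response_likelihoods(task, correct, sensitivity))
            battery.append(
                DiagnosticCase(
                    case_id=str(row["case_id"]),
                    task_id=task,
                    response_correct=correct,
                    likelihoods=L,
                )
            )
        return cls(priors=priors, sensitivity=sensitivity, battery=tuple(battery))


INPUT_TOL = 1e-6  # hand-entered priors rarely sum exactly to 1


def _check_likelihoods(likelihoods) -> np.ndarray:
    L = np.asarray(likelihoods, dtype=float)
    if L.shape != (3,) or np.any(L < 0):
        raise ConfigurationError(f"invalid likelihood triple {likelihoods!r}")
    if L.sum() == 0:
        raise DegenerateEvidenceError(
            "all-zero likelihoods: no hypothesis admits the observation"
        )
    return L


def bus_posterior(priors, likelihoods) -> np.ndarray:
    """Bayes' rule: posterior_i = prior_i L_i / sum_j prior_j L_j."""
    p = validate_probability_vector(priors, tolerance=INPUT_TOL)
    L = _check_likelihoods(likelihoods)
    joint = p * L
    total = joint.sum()
    if total == 0:
        raise DegenerateEvidenceError(
            f"evidence annihilates every hypothesis with positive prior: "
            f"priors {tuple(p)!r}, likelihoods {tuple(L)!r}"
        )
    return joint / total


def ces_posterior(likelihoods) -> np.ndarray:
    """Likelihoods renormalized to sum 1 (priors ignored)."""
    L = _check_likelihoods(likelihoods)
    return L / L.sum()


def ses_posterior(likelihoods, tie_rule: str = "spread") -> np.ndarray:
    """Maximal likelihood taken as that hypothesis's probability.

    With a unique maximum m the winner gets L_m and the remaining 1 - L_m is
    split equally over the other two hypotheses.  With k > 1 tied maxima the
    default ``spread`` rule gives each non-maximal hypothesis 1 - L_max and
    the tied maxima split the remainder equally (two maxima at 0.8 yield
    (0.4, 0.4, 0.2)).  The alternative ``max_normalize`` rule renormalizes the
    indicator of the maxima (two maxima yield (0.5, 0.5, 0)).
    """
    if tie_rule not in SES_TIE_RULES:
        raise ConfigurationError(
            f"unknown SES tie rule {tie_rule!r}; known: {SES_TIE_RULES}"
        )
    L = _check_likelihoods(likelihoods)
    m = L.max()
    is_max = np.isclose(L, m, rtol=0.0, atol=1e-12)
    k = int(is_max.sum())
    out = np.empty(3)
    if k == 1:
        out[is_max] = m
        out[~is_max] = (1.0 - m) / 2.0
    elif tie_rule == "max_normalize":
        out = is_max / k
    else:
        # each non-maximal hypothesis receives 1 - L_max (scaled down if the
        # total would exceed 1); tied maxima split the remainder equally
        loser_mass = (3 - k) * (1.0 - m)
        if loser_mass > 1.0:
            loser_mass = 1.0
        out[~is_max] = loser_mass / (3 - k) if k < 3 else 0.0
        out[is_max] = (1.0 - loser_mass) / k
    return out


def predict_strategy_positions(
    case: DiagnosticCase, design: StudyDesign, tie_rule: str = "spread"
) -> dict[str, np.ndarray]:
    """Predicted posterior position on the simplex for each strategy.

    Priors reset to the design base rates for every case (each case is a
    different student).
    """
    L = np.asarray(case.likelihoods, dtype=float)
    return {
        "BUS": bus_posterior(design.prior_vector, L),
        "CES": ces_posterior(L),
        "SES": ses_posterior(L, tie_rule=tie_rule),
    }


def battery_predictions(
    design: StudyDesign, tie_rule: str = "spread"
) -> dict[str, dict[str, np.ndarray]]:
    """case_id -> strategy -> predicted position, for the whole battery."""
    return {
        c.case_id: predict_strategy_positions(c, design, tie_rule=tie_rule)
        for c in design.battery
    }
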