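"""Synthetic cohorts with the statistical structure the classifier assumes.

Each simulated subject is committed to one update strategy; their judgment on
every battery case is the strategy's predicted simplex position perturbed by
isotropic Gaussian noise truncated to the simplex — exactly the kernel density
the classifier assumes, so parameter-recovery experiments exercise the
pipeline rather than model mismatch.  A logistic-normal noise mode with
matched scale is available for robustness experiments.

Sampling is by rejection: propose an isotropic Gaussian with per-component
variance d_gen/2 in an orthonormal (isometric) coordinate frame of the simplex
plane, so the accepted draws follow the density ∝ exp(−|x − center|²/d_gen)
restricted to the simplex, with |·| the 3-component Euclidean norm used by
the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, SubjectJudgments, classify_cohort
from .exceptions import ConfigurationError, GeneratorError
from .geometry import SIMPLEX_PLANE_BASIS, validate_probability_vector
from .strategies import STRATEGIES, StudyDesign, battery_predictions

#: Below this acceptance rate the rejection sampler aborts.
MIN_ACCEPTANCE_RATE = 1e-4


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic-cohort generator.

    ``d_gen`` is the noise scale in the same squared-distance units as the
    classifier's ``d`` (default 0.1, anchored to the classifier convention —
    the empirical noise magnitude of human subjects is not identifiable from
    published summaries).
    """

    n_per_strategy: dict = field(
        default_factory=lambda: {"BUS": 10, "CES": 10, "SES": 10}
    )
    d_gen: float = 0.1
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 0
    condition_label: str = "synthetic"
    tie_rule: str = "spread"
    noise_model: str = "kernel"

    def __post_init__(self):
        if not self.d_gen > 0:
            raise ConfigurationError(f"d_gen must be positive, got {self.d_gen!r}")
        for s, n in self.n_per_strategy.items():
            if s not in STRATEGIES:
                raise ConfigurationError(f"unknown strategy {s!r} in n_per_strategy")
            if n < 0:
                raise ConfigurationError(f"negative count for strategy {s!r}")
        if self.noise_model not in ("kernel", "logistic-normal"):
            raise ConfigurationError(
                f"unknown noise model {self.noise_model!r}"
            )

    def to_config(self) -> dict:
        return {
            "n_per_strategy": dict(self.n_per_strategy),
            "d_gen": self.d_gen,
            "seed": self.seed,
            "condition_label": self.condition_label,
            "tie_rule": self.tie_rule,
            "noise_model": self.noise_model,
            "design": self.design.to_config(),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "GeneratorConfig":
        cfg = dict(cfg or {})
        design = StudyDesign.from_config(cfg.pop("design", {}))
        known = {
            k: cfg[k]
            for k in (
                "n_per_strategy",
                "d_gen",
                "seed",
                "condition_label",
                "tie_rule",
                "noise_model",
            )
            if k in cfg
        }
        return cls(design=design, **known)


@dataclass(frozen=True)
class LabelledCohort:
    """Synthetic subjects plus their generating-strategy ground truth."""

    subjects: tuple[SubjectJudgments, ...]
    truth: dict


def _sample_kernel_batch(
    center: np.ndarray, d_gen: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n draws from exp(−|x − center|²/d_gen) truncated to the simplex."""
    out = np.empty((n, 3))
    got = 0
    proposed = 0
    sigma = np.sqrt(d_gen / 2.0)
    while got < n:
        batch = max(4 * (n - got), 64)
        z = rng.normal(0.0, sigma, size=(batch, 2))
        x = center + z @ SIMPLEX_PLANE_BASIS.T
        ok = np.all(x >= 0.0, axis=1)
        accepted = x[ok]
        proposed += batch
        take = min(len(accepted), n - got)
        out[got : got + take] = accepted[:take]
        got += take
        if proposed >= 64 and (got + 1) / proposed < MIN_ACCEPTANCE_RATE:
            raise GeneratorError(
                f"rejection acceptance rate below {MIN_ACCEPTANCE_RATE:g} for "
                f"center {tuple(center)!r}, d_gen {d_gen!r}"
            )
    # renormalize away accumulated floating error; components are >= 0 by
    # construction (rejection, not clipping)
    return out / out.sum(axis=1, keepdims=True)


def _sample_logistic_normal_batch(
    center: np.ndarray, d_gen: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian noise of matched scale in centered-log-ratio space."""
    eps = 1e-12
    clr = np.log(np.clip(center, eps, None))
    clr = clr - clr.mean()
    z = rng.normal(0.0, np.sqrt(d_gen / 2.0), size=(n, 2))
    logits = clr + z @ SIMPLEX_PLANE_BASIS.T
    x = np.exp(logits - logits.max(axis=1, keepdims=True))
    return x / x.sum(axis=1, keepdims=True)


def sample_judgment(
    predicted, d_gen: float, rng: np.random.Generator, noise_model: str = "kernel"
) -> np.ndarray:
    """One noisy judgment around a predicted position."""
    center = validate_probability_vector(predicted, tolerance=1e-6)
    if not d_gen > 0:
        raise ConfigurationError(f"d_gen must be positive, got {d_gen!r}")
    if noise_model == "kernel":
        return _sample_kernel_batch(center, d_gen, 1, rng)[0]
    return _sample_logistic_normal_batch(center, d_gen, 1, rng)[0]


def generate_cohort(cfg: GeneratorConfig) -> LabelledCohort:
    """A cohort of strategy-committed subjects, reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    predictions = battery_predictions(cfg.design, tie_rule=cfg.tie_rule)
    case_ids = [c.case_id for c in cfg.design.battery]
    sampler = (
        _sample_kernel_batch
        if cfg.noise_model == "kernel"
        else _sample_logistic_normal_batch
    )

    subjects: list[SubjectJudgments] = []
    truth: dict[str, str] = {}
    for strategy in STRATEGIES:
        n = int(cfg.n_per_strategy.get(strategy, 0))
        if n == 0:
            continue
        # draw per case for all subjects of this strategy at once
        draws = {
            cid: sampler(predictions[cid][strategy], cfg.d_gen, n, rng)
            for cid in case_ids
        }
        for i in range(n):
            sid = f"{cfg.condition_label}_{strategy}_{i + 1:03d}"
            judgments = tuple(
                (cid, tuple(float(v) for v in draws[cid][i])) for cid in case_ids
            )
            subjects.append(
                SubjectJudgments(
                    subject_id=sid,
                    condition=cfg.condition_label,
                    judgments=judgments,
                )
            )
            truth[sid] = strategy
    return LabelledCohort(subjects=tuple(subjects), truth=truth)


@dataclass
class RecoveryReport:
    """Aggregated truth-vs-assigned results over replicated synthetic cohorts."""

    confusion: pd.DataFrame
    recovery_rate: dict
    recovery_se: dict
    bf_1_2_by_truth: dict
    p_post_max_by_truth: dict
    replicates: int
    gen_config: GeneratorConfig
    clf_config: ClassifierConfig

    def as_dict(self) -> dict:
        return {
            "confusion": {
                t: {str(c): int(v) for c, v in row.items()}
                for t, row in self.confusion.to_dict(orient="index").items()
            },
            "recovery_rate": dict(self.recovery_rate),
            "recovery_se": dict(self.recovery_se),
            "replicates": self.replicates,
            "bf_1_2_mean_by_truth": {
                s: float(np.mean(v)) for s, v in self.bf_1_2_by_truth.items()
            },
            "p_post_max_mean_by_truth": {
                s: float(np.mean(v)) for s, v in self.p_post_max_by_truth.items()
            },
        }


def recovery_experiment(
    gen_cfg: GeneratorConfig,
    clf_cfg: ClassifierConfig | None = None,
    replicates: int = 100,
) -> RecoveryReport:
    """Generate, classify, and score ``replicates`` independent cohorts.

    Per-strategy recovery rates are averaged over replicates; the reported
    standard error is the Monte-Carlo SE of that mean across replicates.
    """
    if replicates < 1:
        raise ConfigurationError(f"replicates must be >= 1, got {replicates!r}")
    clf_cfg = clf_cfg or ClassifierConfig(tie_rule=gen_cfg.tie_rule)
    # independent child seeds, kept below 2**31 for portability
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(gen_cfg.seed).generate_state(replicates)
    ]

    labels = list(STRATEGIES) + ["indeterminate"]
    confusion = pd.DataFrame(0, index=list(STRATEGIES), columns=labels, dtype=int)
    per_rep_rates: dict[str, list[float]] = {s: [] for s in STRATEGIES}
    bf_by_truth: dict[str, list[float]] = {s: [] for s in STRATEGIES}
    pmax_by_truth: dict[str, list[float]] = {s: [] for s in STRATEGIES}

    for seed in child_seeds:
        cohort = generate_cohort(replace(gen_cfg, seed=seed))
        report = classify_cohort(list(cohort.subjects), gen_cfg.design, clf_cfg)
        hits: dict[str, int] = {s: 0 for s in STRATEGIES}
        totals: dict[str, int] = {s: 0 for s in STRATEGIES}
        for res in report.results:
            t = cohort.truth[res.subject_id]
            confusion.loc[t, res.label] += 1
            totals[t] += 1
            hits[t] += int(res.label == t)
            bf_by_truth[t].append(res.bf_1_2)
            pmax_by_truth[t].append(res.p_post_max)
        for s in STRATEGIES:
            if totals[s]:
                per_rep_rates[s].append(hits[s] / totals[s])

    rate = {
        s: float(np.mean(v)) for s, v in per_rep_rates.items() if v
    }
    se = {
        s: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for s, v in per_rep_rates.items()
        if v
    }
    return RecoveryReport(
        confusion=confusion,
        recovery_rate=rate,
        recovery_se=se,
        bf_1_2_by_truth={s: np.asarray(v) for s, v in bf_by_truth.items()},
        p_post_max_by_truth={s: np.asarray(v) for s, v in pmax_by_truth.items()},
        replicates=replicates,
        gen_config=gen_cfg,
        clf_config=clf_cfg,
    )
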