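"""Bayesian contingency-table test for strategy-by-condition dependence.

The distribution of assigned strategy labels across experimental conditions
is compared with the Gunel–Dickey Bayes factor under joint-multinomial
sampling: under the dependence model H1 the cell counts follow a single
multinomial with a symmetric Dirichlet(a) prior on the cell probabilities;
under the independence model H0 the cell probabilities factor into row and
column marginal probabilities, each with its own symmetric Dirichlet(a)
prior.  Both marginal likelihoods are Dirichlet-multinomial and the Bayes
factor is available in closed form,

    BF10 = [B(y + a) / B(a)] / ( [B(y_r + a) / B(a_r)] · [B(y_c + a) / B(a_c)] ),

where B is the multivariate beta function, y the cell counts, y_r / y_c the
row / column margins, and every concentration vector is constant a.  All
gamma-function arithmetic is done in log space.

Evidence strength for BF10 is reported on the Lee–Wagenmakers scale
(anecdotal / moderate / strong / very strong / extreme), with reciprocal bins
for BF10 < 1 read as evidence for independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import ConfigurationError, DataError

#: Lee–Wagenmakers evidence bins on BF10 (upper edges inclusive).
LW_BINS = (
    (1.0, 3.0, "anecdotal"),
    (3.0, 10.0, "moderate"),
    (10.0, 30.0, "strong"),
    (30.0, 100.0, "very strong"),
    (100.0, np.inf, "extreme"),
)

#: Default sensitivity sweep over the Dirichlet concentration.
SENSITIVITY_SWEEP = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Strategy-label counts by condition (rows: conditions, columns: labels)."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise DataError(f"expected a 2-D count table, got {self.counts!r}")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise DataError(f"counts must be nonnegative integers: {self.counts!r}")
        if arr.sum() == 0:
            raise DataError("contingency table has grand total 0")
        r, c = arr.shape
        object.__setattr__(
            self, "counts", tuple(tuple(int(x) for x in row) for row in arr)
        )
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"row{i + 1}" for i in range(r))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"col{j + 1}" for j in range(c))
            )
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise DataError("label lengths do not match the count table shape")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def grand_total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class ComparisonConfig:
    """Prior settings of the contingency-table test."""

    prior_concentration: float = 1.0
    sampling_model: str = "joint-multinomial"

    def __post_init__(self):
        if not self.prior_concentration > 0:
            raise ConfigurationError(
                f"prior concentration must be positive, got {self.prior_concentration!r}"
            )
        if self.sampling_model != "joint-multinomial":
            raise ConfigurationError(
                f"unsupported sampling model {self.sampling_model!r}; only "
                f"'joint-multinomial' is implemented"
            )


def _log_multivariate_beta(alpha: np.ndarray) -> float:
    return float(np.sum(gammaln(alpha)) - gammaln(np.sum(alpha)))


def log_gunel_dickey_bf(table: ContingencyTable, a: float = 1.0) -> float:
    """Natural-log BF10 for dependence under joint-multinomial sampling."""
    if not a > 0:
        raise ConfigurationError(f"prior concentration must be positive, got {a!r}")
    y = table.array
    r, c = y.shape
    yr, yc = y.sum(axis=1), y.sum(axis=0)
    log_m1 = _log_multivariate_beta(y.ravel() + a) - _log_multivariate_beta(
        np.full(r * c, a)
    )
    log_m0 = (
        _log_multivariate_beta(yr + a)
        - _log_multivariate_beta(np.full(r, a))
        + _log_multivariate_beta(yc + a)
        - _log_multivariate_beta(np.full(c, a))
    )
    return log_m1 - log_m0


def gunel_dickey_bf(
    table: ContingencyTable, cfg: ComparisonConfig | float | None = None
) -> float:
    """BF10 for dependence over independence.

    ``cfg`` may be a :class:`ComparisonConfig` or a bare concentration value.
    """
    if cfg is None:
        a = 1.0
    elif isinstance(cfg, ComparisonConfig):
        a = cfg.prior_concentration
    else:
        a = float(cfg)
    return float(np.exp(log_gunel_dickey_bf(table, a)))


def lw_evidence_label(bf10: float) -> str:
    """Lee–Wagenmakers evidence label for a BF10 (either direction)."""
    if not bf10 > 0:
        raise ConfigurationError(f"BF10 must be positive, got {bf10!r}")
    if bf10 == 1.0:
        return "no evidence"
    direction = "dependence" if bf10 > 1.0 else "independence"
    magnitude = bf10 if bf10 > 1.0 else 1.0 / bf10
    for lo, hi, label in LW_BINS:
        if magnitude <= hi:
            return f"{label} evidence for {direction}"
    return f"extreme evidence for {direction}"


@dataclass(frozen=True)
class ComparisonResult:
    """Full output of one contingency-table comparison."""

    table: ContingencyTable
    bf10: float
    bf01: float
    log10_bf10: float
    label: str
    prior_concentration: float
    sensitivity: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "counts": [list(r) for r in self.table.counts],
            "row_labels": list(self.table.row_labels),
            "col_labels": list(self.table.col_labels),
            "bf10": self.bf10,
            "bf01": self.bf01,
            "log10_bf10": self.log10_bf10,
            "label": self.label,
            "prior_concentration": self.prior_concentration,
            "sensitivity": dict(self.sensitivity),
        }


def compare_conditions(
    table: ContingencyTable,
    cfg: ComparisonConfig | None = None,
    sweep: tuple[float, ...] = SENSITIVITY_SWEEP,
) -> ComparisonResult:
    """Run the test at the configured concentration plus a sensitivity sweep."""
    cfg = cfg or ComparisonConfig()
    log_bf = log_gunel_dickey_bf(table, cfg.prior_concentration)
    bf10 = float(np.exp(log_bf))
    return ComparisonResult(
        table=table,
        bf10=bf10,
        bf01=float(np.exp(-log_bf)),
        log10_bf10=float(log_bf / np.log(10.0)),
        label=lw_evidence_label(bf10),
        prior_concentration=cfg.prior_concentration,
        sensitivity={a: gunel_dickey_bf(table, a) for a in sweep},
    )
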