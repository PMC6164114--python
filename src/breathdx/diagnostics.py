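"""Diagnostic-accuracy arithmetic.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV, false-positive
and false-negative rates, accuracy), ROC AUC with a DeLong 95% confidence
interval, the standard-error-based sample-size formula

    SE = sqrt( C (100 - C) / n )     =>     n = ceil( C (100 - C) / SE^2 )

with C the expected percent correctly classified, and forensic reconstruction
of integer confusion matrices from rounded published percentages.

The false-positive rate is defined as the complement of specificity,
100*fp/(fp+tn), and the false-negative rate as the complement of
sensitivity, 100*fn/(tp+fn).  Display rounding is half-up to one decimal,
matching the precision of published diagnostic tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ConfigurationError, DataError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "ReconstructionResult",
    "METRIC_NAMES",
    "round_half_up",
    "compute_metrics",
    "roc_auc",
    "sample_size",
    "reconstruct_confusion",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "fp_rate",
    "fn_rate",
    "accuracy",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 classification counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"{name} must be a non-negative integer")
        if self.total < 1:
            raise DataError("confusion matrix must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass
class DiagnosticReport:
    """The seven table metrics (percent) plus optional AUC with 95% CI.

    Metrics are stored unrounded; :meth:`rounded` applies the half-up
    one-decimal display convention.  Undefined metrics (zero denominator)
    are NaN.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fp_rate: float
    fn_rate: float
    accuracy: float
    n_cases: int
    n_controls: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    confusion: ConfusionMatrix | None = None

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {m: round_half_up(getattr(self, m), ndigits) for m in METRIC_NAMES}

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d.update(n_cases=self.n_cases, n_controls=self.n_controls)
        if self.auc is not None:
            d["auc"] = self.auc
            d["auc_ci"] = list(self.auc_ci) if self.auc_ci is not None else None
        if self.confusion is not None:
            c = self.confusion
            d["confusion"] = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
        return d


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> DiagnosticReport:
    """All seven metrics of a confusion matrix, as percentages."""
    if cm.n_cases < 1 or cm.n_controls < 1:
        raise DataError("need at least one case and one control")
    return DiagnosticReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fp_rate=_ratio(cm.fp, cm.fp + cm.tn),
        fn_rate=_ratio(cm.fn, cm.tp + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        n_cases=cm.n_cases,
        n_controls=cm.n_controls,
        confusion=cm,
    )


def roc_auc(scores, labels) -> tuple[float, float, float]:
    """AUC with a DeLong 95% confidence interval.

    AUC is the Mann-Whitney probability that a random case scores above a
    random control, ties counted half.  The variance is DeLong's structural
    components estimator; the normal-approximation CI is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be matching 1-D arrays")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise DataError("both classes must be present")

    # midranks give the tie-corrected Mann-Whitney statistic
    all_ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = all_ranks[:m]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components: V10 for cases, V01 for controls
    v10 = (r_pos - rankdata(pos)) / n
    r_neg = all_ranks[m:]
    v01 = 1.0 - (r_neg - rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), float(lo), float(hi)


def sample_size(C: float, SE: float) -> int:
    """Minimum n so the standard error of a C% accuracy stays below SE."""
    if not 0 < C < 100:
        raise ConfigurationError("C must be strictly between 0 and 100")
    if SE <= 0:
        raise ConfigurationError("SE must be positive")
    return math.ceil(C * (100.0 - C) / SE**2)


@dataclass
class ReconstructionResult:
    """Outcome of inverting rounded published metrics to integer counts."""

    solutions: list[ConfusionMatrix]
    consistent: bool
    #: when inconsistent: a largest subset of the supplied metrics that does
    #: admit a solution, with the metrics it had to drop
    max_consistent_subset: tuple[str, ...] = ()
    dropped_metrics: tuple[str, ...] = ()
    subset_solutions: list[ConfusionMatrix] = field(default_factory=list)
    #: all maximal consistent subsets (there may be several when a single
    #: erratum can be blamed on more than one printed value)
    maximal_subsets: list[tuple[str, ...]] = field(default_factory=list)


def _matches(cm: ConfusionMatrix, printed: dict[str, float], ndigits: int) -> bool:
    rep = compute_metrics(cm)
    for name, want in printed.items():
        got = round_half_up(getattr(rep, name), ndigits)
        if math.isnan(got) or abs(got - want) > 1e-9:
            return False
    return True


def _candidate_matrices(n_cases, n_controls, total):
    if n_cases is not None and n_controls is not None:
        for tp in range(n_cases + 1):
            for tn in range(n_controls + 1):
                yield ConfusionMatrix(tp=tp, fp=n_controls - tn, tn=tn, fn=n_cases - tp)
    else:
        for nc in range(1, total):
            for tp in range(nc + 1):
                for tn in range(total - nc + 1):
                    yield ConfusionMatrix(tp=tp, fp=total - nc - tn, tn=tn, fn=nc - tp)


def reconstruct_confusion(
    printed: dict[str, float],
    n_cases: int | None = None,
    n_controls: int | None = None,
    total: int | None = None,
    ndigits: int = 1,
) -> ReconstructionResult:
    """Recover the integer confusion matrices behind rounded printed metrics.

    Exhaustively searches non-negative integer (tp, fn, fp, tn) consistent
    with the size constraints and keeps matrices whose metrics round
    (half-up, ``ndigits`` decimals) to every supplied printed value.  When no
    matrix fits, the result is flagged inconsistent and a maximal subset of
    the printed metrics that does admit a solution is reported.
    """
    unknown = set(printed) - set(METRIC_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown metric names: {sorted(unknown)}")
    if len(printed) < 2:
        raise ConfigurationError("need at least two independent printed metrics")
    if (n_cases is None or n_controls is None) and total is None:
        raise ConfigurationError(
            "refusing unbounded search: supply n_cases+n_controls or total"
        )
    if n_cases is not None and n_controls is not None and total is not None:
        if n_cases + n_controls != total:
            raise ConfigurationError("n_cases + n_controls must equal total")

    candidates = [
        cm
        for cm in _candidate_matrices(n_cases, n_controls, total)
        if cm.n_cases >= 1 and cm.n_controls >= 1
    ]
    solutions = [cm for cm in candidates if _matches(cm, printed, ndigits)]
    if solutions:
        return ReconstructionResult(solutions=solutions, consistent=True)

    # find a largest consistent subset of the printed metrics
    names = sorted(printed)
    for size in range(len(names) - 1, 1, -1):
        best = []
        for subset in itertools.combinations(names, size):
            sub = {k: printed[k] for k in subset}
            sols = [cm for cm in candidates if _matches(cm, sub, ndigits)]
            if sols:
                best.append((subset, sols))
        if best:
            subset, sols = best[0]
            return ReconstructionResult(
                solutions=[],
                consistent=False,
                max_consistent_subset=subset,
                dropped_metrics=tuple(k for k in names if k not in subset),
                subset_solutions=sols,
                maximal_subsets=[s for s, _ in best],
            )
    return ReconstructionResult(solutions=[], consistent=False)
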