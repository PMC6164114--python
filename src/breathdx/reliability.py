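"""Sensor repeatability: intraclass correlation and coefficients of variation.

Repeatability of the 10 replicate measurements per breath bag is assessed
per sensor with the two-way fixed (consistency) average-measures intraclass
correlation, ICC(3,k), comparing each later measurement against the 2nd
(the 1st being deleted as contaminated), and with the within-subject
coefficient of variation in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["ReliabilityReport", "icc_3k", "icc_vs_reference", "cv_percent"]


@dataclass
class ReliabilityReport:
    """Per-sensor repeatability summary.

    ``icc_per_sensor`` is the minimum ICC(3,k) over the evaluated
    measurement pairs (conservative summary); ``worst_pair_per_sensor``
    records which pair attains it.
    """

    icc_per_sensor: np.ndarray
    cv_per_sensor: np.ndarray
    pairs_evaluated: list[tuple[int, int]]
    worst_pair_per_sensor: list[tuple[int, int]]


def icc_3k(data: np.ndarray) -> float:
    """Two-way fixed, consistency, average-measures ICC.

    From the two-way ANOVA decomposition of a subjects x measurements table:
    ICC(3,k) = (MS_subjects - MS_error) / MS_subjects, where MS_error is the
    residual (subject x measurement interaction) mean square.  Returns NaN
    when between-subject variance is zero (the coefficient is undefined).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise DataError("data must be a 2-D subjects x measurements table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 subjects and 2 measurement columns")
    if not np.all(np.isfinite(X)):
        raise DataError("missing or non-finite cells are not supported")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        return float("nan")
    return float((ms_rows - ms_err) / ms_rows)


def _as_subject_replicate_sensor(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 3:
        raise DataError("features must be (n_subjects, n_replicates, n_sensors)")
    return X


def icc_vs_reference(
    features: np.ndarray,
    replicate_numbers: list[int] | None = None,
    reference_replicate: int = 2,
    joint: bool = False,
) -> ReliabilityReport:
    """Per-sensor ICC of each measurement against the reference measurement.

    ``features`` is (n_subjects, n_replicates, n_sensors); ``replicate_numbers``
    gives the 1-based measurement index of each replicate axis entry (default
    2..n+1, i.e. the post-deletion replicates).  For each sensor and each
    measurement j != reference, ICC(3,k) is computed on the subjects x 2 table
    (reference, j); the per-sensor summary is the minimum over pairs.  With
    ``joint=True`` a single ICC(3,k) over all columns is computed instead.
    """
    X = _as_subject_replicate_sensor(features)
    n_subj, n_rep, n_sens = X.shape
    if replicate_numbers is None:
        replicate_numbers = list(range(2, n_rep + 2))
    if len(replicate_numbers) != n_rep:
        raise DataError("replicate_numbers length mismatch")
    if reference_replicate not in replicate_numbers:
        raise DataError(f"reference replicate {reference_replicate} missing")
    ref_idx = replicate_numbers.index(reference_replicate)

    if joint:
        iccs = np.array([icc_3k(X[:, :, s]) for s in range(n_sens)])
        pair = (reference_replicate, -1)
        return ReliabilityReport(
            icc_per_sensor=iccs,
            cv_per_sensor=cv_percent(X),
            pairs_evaluated=[pair],
            worst_pair_per_sensor=[pair] * n_sens,
        )

    pairs = [
        (reference_replicate, j) for j in replicate_numbers if j != reference_replicate
    ]
    icc_min = np.full(n_sens, np.inf)
    worst: list[tuple[int, int]] = [(-1, -1)] * n_sens
    for ref, j in pairs:
        j_idx = replicate_numbers.index(j)
        for s in range(n_sens):
            val = icc_3k(X[:, [ref_idx, j_idx], s])
            if val < icc_min[s]:
                icc_min[s] = val
                worst[s] = (ref, j)
    return ReliabilityReport(
        icc_per_sensor=icc_min,
        cv_per_sensor=cv_percent(X),
        pairs_evaluated=pairs,
        worst_pair_per_sensor=worst,
    )


def cv_percent(features: np.ndarray) -> np.ndarray:
    """Within-subject coefficient of variation per sensor, in percent.

    Per subject and sensor: sample SD across replicates divided by the
    replicate mean, x100; then averaged over subjects.  Sensors whose mean
    response is zero for some subject get NaN (undefined, not fabricated).
    """
    X = _as_subject_replicate_sensor(features)
    means = X.mean(axis=1)  # (n_subjects, n_sensors)
    sds = X.std(axis=1, ddof=1)
    out = np.empty(X.shape[2])
    for s in range(X.shape[2]):
        m = means[:, s]
        if np.any(m == 0):
            out[s] = math.nan
        else:
            out[s] = float(np.mean(sds[:, s] / np.abs(m)) * 100.0)
    return out
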