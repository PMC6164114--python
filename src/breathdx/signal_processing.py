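"""Raw sweep to feature-vector processing.

A measurement ("sweep") of the 32-channel chemiresistive array has three
phases: a clean-air baseline purge, a sample purge during which the polymers
swell and resistance rises toward a plateau, and a washout during which the
sensors relax back to baseline.  The per-channel feature is the fractional
resistance change

    dR/R0 = (Rmax - R0) / R0

where R0 is the baseline resistance and Rmax the peak resistance during the
sample purge.  Each breath bag is measured 10 times; the first measurement is
contaminated by residual air in the connecting tubing and is always deleted,
measurements whose baseline fails to return are treated as drifted and
deleted, and the retained replicates are averaged into one 32-element feature
vector per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, QualityError

__all__ = [
    "SensorSweep",
    "ReplicateFeature",
    "SubjectFeature",
    "extract_baseline",
    "extract_response",
    "compute_replicate_feature",
    "flag_drift",
    "aggregate_replicates",
]

#: fraction of the baseline-purge phase (its tail) averaged to estimate R0
BASELINE_WINDOW_FRACTION = 0.5
#: fraction of the washout tail averaged to estimate the terminal baseline
WASHOUT_TAIL_FRACTION = 0.1
#: default relative tolerance on baseline return before a replicate is
#: declared drifted
DEFAULT_DRIFT_TOLERANCE = 0.01


@dataclass
class SensorSweep:
    """One measurement: resistance traces for all channels over one sweep.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    replicate : int
        1-based replicate index within the subject's bag (1..10).
    times : ndarray, shape (n_times,)
        Sample times in seconds, strictly increasing, starting at the
        beginning of the baseline purge.
    resistances : ndarray, shape (n_channels, n_times)
        Strictly positive resistance readings (arbitrary ohm-scale units).
    phase_bounds : tuple of float
        ``(baseline_end_s, sample_end_s, washout_end_s)``.
    label : str or None
        Optional class label ("case"/"control") carried through the pipeline.
    drifted : bool or None
        Simulation ground truth only; ``None`` for real data.
    """

    subject_id: str
    replicate: int
    times: np.ndarray
    resistances: np.ndarray
    phase_bounds: tuple[float, float, float]
    label: str | None = None
    drifted: bool | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistances = np.asarray(self.resistances, dtype=float)
        if self.times.ndim != 1:
            raise DataError("times must be one-dimensional")
        if self.resistances.ndim != 2 or self.resistances.shape[1] != self.times.size:
            raise DataError("resistances must be (n_channels, n_times)")
        if not np.all(np.isfinite(self.resistances)):
            raise DataError(f"non-finite resistance in sweep {self.subject_id}/{self.replicate}")
        if np.any(self.resistances <= 0):
            raise DataError(
                f"non-positive resistance in sweep {self.subject_id}/{self.replicate}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        b, s, w = self.phase_bounds
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 < b < s < w <= t1 + 1e-9):
            raise DataError("phase bounds must be increasing and inside the time range")
        for lo, hi, name in ((t0 - 1e-9, b, "baseline"), (b, s, "sample"), (s, w, "washout")):
            n = int(np.count_nonzero((self.times > lo) & (self.times <= hi + 1e-9)))
            if n < 5:
                raise DataError(f"fewer than 5 samples in the {name} phase")

    @property
    def n_channels(self) -> int:
        return self.resistances.shape[0]


@dataclass
class ReplicateFeature:
    """dR/R0 responses and baseline-return diagnostics for one replicate."""

    subject_id: str
    replicate: int
    response: np.ndarray
    baseline_return_gap: np.ndarray
    drift_flag: bool
    label: str | None = None


@dataclass
class SubjectFeature:
    """Mean dR/R0 vector over a subject's retained replicates."""

    subject_id: str
    label: str | None
    response: np.ndarray
    n_used: int
    replicates_used: list[int] = field(default_factory=list)


def extract_baseline(sweep: SensorSweep) -> np.ndarray:
    """Estimate the per-channel baseline resistance R0.

    R0 is the mean resistance over the final half of the baseline-purge
    phase, which avoids transients at purge onset.
    """
    b_end = sweep.phase_bounds[0]
    t0 = sweep.times[0]
    window_start = t0 + (1.0 - BASELINE_WINDOW_FRACTION) * (b_end - t0)
    mask = (sweep.times >= window_start - 1e-9) & (sweep.times <= b_end + 1e-9)
    if not mask.any():
        raise DataError("empty baseline window")
    r0 = sweep.resistances[:, mask].mean(axis=1)
    if np.any(r0 <= 0):
        raise DataError("non-positive baseline resistance")
    return r0


def extract_response(sweep: SensorSweep, r0: np.ndarray) -> np.ndarray:
    """Per-channel fractional response (Rmax - R0)/R0.

    Rmax is the maximum resistance within the sample-purge phase.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise DataError("r0 must be strictly positive")
    b_end, s_end, _ = sweep.phase_bounds
    mask = (sweep.times > b_end) & (sweep.times <= s_end + 1e-9)
    if not mask.any():
        raise DataError("empty sample-purge window")
    rmax = sweep.resistances[:, mask].max(axis=1)
    return (rmax - r0) / r0


def _terminal_baseline(sweep: SensorSweep) -> np.ndarray:
    """Mean resistance over the tail of the washout phase."""
    _, s_end, w_end = sweep.phase_bounds
    tail_start = w_end - WASHOUT_TAIL_FRACTION * (w_end - s_end)
    mask = (sweep.times >= tail_start - 1e-9) & (sweep.times <= w_end + 1e-9)
    if not mask.any():
        raise DataError("empty washout tail window")
    return sweep.resistances[:, mask].mean(axis=1)


def compute_replicate_feature(
    sweep: SensorSweep, drift_tolerance: float = DEFAULT_DRIFT_TOLERANCE
) -> ReplicateFeature:
    """Extract the feature vector and drift diagnostics for one sweep."""
    r0 = extract_baseline(sweep)
    response = extract_response(sweep, r0)
    gap = (_terminal_baseline(sweep) - r0) / r0
    feat = ReplicateFeature(
        subject_id=sweep.subject_id,
        replicate=sweep.replicate,
        response=response,
        baseline_return_gap=gap,
        drift_flag=False,
        label=sweep.label,
    )
    feat.drift_flag = flag_drift(feat, drift_tolerance)
    return feat


def flag_drift(
    feature: ReplicateFeature, tolerance: float = DEFAULT_DRIFT_TOLERANCE
) -> bool:
    """A replicate is drifted when any channel's baseline fails to return.

    Automated surrogate for visual drift screening: true iff the absolute
    relative gap between terminal and initial baseline exceeds ``tolerance``
    on any channel.
    """
    return bool(np.any(np.abs(feature.baseline_return_gap) > tolerance))


def aggregate_replicates(features: list[ReplicateFeature]) -> SubjectFeature:
    """Average a subject's retained replicates into one feature vector.

    Replicate 1 is always discarded (residual-air contamination); replicates
    with ``drift_flag`` set are discarded; the channel-wise arithmetic mean
    of the rest is returned.  At least 2 replicates must survive.
    """
    if len(features) < 3:
        raise QualityError("need at least 3 replicates per subject")
    subject_ids = {f.subject_id for f in features}
    if len(subject_ids) != 1:
        raise QualityError(f"replicates from multiple subjects: {sorted(subject_ids)}")
    subject_id = features[0].subject_id

    discarded: list[str] = []
    retained: list[ReplicateFeature] = []
    for f in sorted(features, key=lambda f: f.replicate):
        if f.replicate == 1:
            discarded.append("replicate 1 deleted (first-measurement contamination)")
        elif f.drift_flag:
            discarded.append(f"replicate {f.replicate} deleted (drift)")
        else:
            retained.append(f)
    if len(retained) < 2:
        raise QualityError(
            f"subject {subject_id} rejected: fewer than 2 retained replicates "
            f"({'; '.join(discarded)})"
        )
    response = np.mean([f.response for f in retained], axis=0)
    return SubjectFeature(
        subject_id=subject_id,
        label=features[0].label,
        response=response,
        n_used=len(retained),
        replicates_used=[f.replicate for f in retained],
    )
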