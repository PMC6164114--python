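"""Sample-vector normalization and per-sensor autoscaling.

Preprocessing follows the standard chemometric order: each sample's
32-element response vector is first scaled to a constant sum of squares
(vector normalization), then each sensor column is autoscaled to zero mean
and unit standard deviation.  Autoscaling state (per-sensor means and SDs)
is fitted on a training set and applied unchanged to validation sets, so
held-out data never leak into the scaling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, DegenerateFeatureError, NormalizationError

__all__ = [
    "AutoscalerState",
    "ScaledMatrix",
    "normalize_samples",
    "fit_autoscaler",
    "apply_autoscaler",
]


@dataclass
class AutoscalerState:
    """Per-sensor means and sample standard deviations fitted on training data.

    SDs use the (n-1)-denominator convention.
    """

    means: np.ndarray
    sds: np.ndarray
    n_fit: int

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise DataError("means and sds must be matching 1-D vectors")
        if np.any(self.sds <= 0):
            raise DegenerateFeatureError("all sds must be strictly positive")
        if self.n_fit < 2:
            raise DataError("autoscaler must be fitted on at least 2 samples")

    def digest(self) -> str:
        """SHA-256 over the state's bytes; used as a leakage sentinel."""
        h = hashlib.sha256()
        h.update(self.means.tobytes())
        h.update(self.sds.tobytes())
        h.update(str(self.n_fit).encode())
        return h.hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "n_fit": int(self.n_fit),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AutoscalerState":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["means"]), np.array(d["sds"]), int(d["n_fit"]))


@dataclass
class ScaledMatrix:
    """An autoscaled samples x sensors matrix with scaling provenance."""

    values: np.ndarray
    provenance: str  # "fitted_here" | "applied_from_state"
    sample_ids: list[str] | None = None


def normalize_samples(
    matrix: np.ndarray,
    target_norm: float = 1.0,
    sample_ids: list[str] | None = None,
) -> np.ndarray:
    """Scale each row so its sum of squares equals ``target_norm``.

    Row directions are preserved; an all-zero row cannot be normalized and
    raises, naming the sample.
    """
    X = np.asarray(matrix, dtype=float)
    if target_norm <= 0:
        raise DataError("target_norm must be positive")
    ss = np.einsum("ij,ij->i", X, X)
    zero = np.where(ss == 0)[0]
    if zero.size:
        i = int(zero[0])
        name = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise NormalizationError(f"cannot normalize all-zero sample {name}")
    return X * np.sqrt(target_norm / ss)[:, None]


def fit_autoscaler(matrix: np.ndarray) -> AutoscalerState:
    """Fit per-column means and (n-1)-denominator SDs."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least 2 samples to fit")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.where(sds == 0)[0]
    if dead.size:
        raise DegenerateFeatureError(
            f"sensor column {int(dead[0])} has zero variance and cannot be autoscaled"
        )
    return AutoscalerState(means=means, sds=sds, n_fit=X.shape[0])


def apply_autoscaler(
    matrix: np.ndarray,
    state: AutoscalerState,
    sample_ids: list[str] | None = None,
    provenance: str = "applied_from_state",
) -> ScaledMatrix:
    """Center and scale columns by the fitted state: x' = (x - mean) / sd."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.means.size:
        raise DataError(
            f"matrix has {X.shape[-1]} columns but state was fitted on {state.means.size}"
        )
    return ScaledMatrix(
        values=(X - state.means) / state.sds,
        provenance=provenance,
        sample_ids=sample_ids,
    )
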