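"""Simulated electronic-nose cohorts with known ground truth.

The generator emulates the structure of a breath-test study: two cohorts
(cases and controls), each subject measured 10 times from one breath bag on a
32-channel chemiresistive array, each measurement a three-phase sweep (10 s
baseline purge, 40 s sample purge, 10 s washout).

The data-generating model per subject j and channel k:

    a_jk  = mu_k + delta_k * 1[case] + u_jk,        u_jk ~ N(0, sigma_subject^2)

and per replicate r:

    a_jkr = a_jk + e_jkr,                           e_jkr ~ N(0, sigma_replicate^2)

The resistance trace follows first-order kinetics around a per-channel
baseline B_k: flat during the baseline purge, exponential rise toward
B_k * (1 + a_jkr) with time constant tau_rise during the sample purge, and
exponential relaxation back toward baseline during the washout.  Replicate 1
of every subject carries an additive response bias (residual air in the
tubing); every later replicate independently drifts with probability
``drift_prob``, modelled as a linear multiplicative baseline ramp
d(t) = 1 + drift_magnitude * t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .signal_processing import SensorSweep

__all__ = [
    "SimulationConfig",
    "SubjectProfile",
    "generate_cohort",
    "generate_sweep",
    "write_sweeps_csv",
    "read_sweeps_csv",
    "write_truth_json",
]


def _per_channel(value, n_channels: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_channels,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Scalars given for per-channel fields are broadcast to all channels.
    Defaults produce a cohort whose replicate noise sits near a 0.2%
    within-subject coefficient of variation and near-unity repeatability,
    typical of a well-maintained conducting-polymer array.
    """

    n_cases: int = 20
    n_controls: int = 20
    n_channels: int = 32
    n_replicates: int = 10
    baseline_resistance: float | np.ndarray = None  # type: ignore[assignment]
    mu_control: float | np.ndarray = 0.05
    delta_mu: float | np.ndarray = None  # type: ignore[assignment]
    sigma_subject: float = 0.01
    sigma_replicate: float = 1e-4
    subject_covariance: np.ndarray | None = None
    tau_rise: float = 4.0
    drift_prob: float = 0.05
    drift_magnitude: float = 0.002
    first_replicate_bias: float = 0.01
    phase_durations: tuple[float, float, float] = (10.0, 40.0, 10.0)
    sample_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_channels", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.baseline_resistance is None:
            # spread of ohm-scale baselines across the array
            self.baseline_resistance = np.linspace(1000.0, 4100.0, self.n_channels)
        self.baseline_resistance = _per_channel(
            self.baseline_resistance, self.n_channels, "baseline_resistance"
        )
        if np.any(self.baseline_resistance <= 0):
            raise ConfigurationError("baseline_resistance must be positive")
        self.mu_control = _per_channel(self.mu_control, self.n_channels, "mu_control")
        if self.delta_mu is None:
            # a disease signature is a pattern change across polymers, not a
            # uniform scale change (which sample-vector normalization would
            # cancel): alternate the sign of the shift across channels
            signs = np.where(np.arange(self.n_channels) % 2 == 0, 1.0, -1.0)
            self.delta_mu = 0.004 * signs
        self.delta_mu = _per_channel(self.delta_mu, self.n_channels, "delta_mu")
        for name in ("sigma_subject", "sigma_replicate"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be a finite SD >= 0")
        if not 0.0 <= float(self.drift_prob) <= 1.0:
            raise ConfigurationError("drift_prob must be in [0, 1]")
        if not np.isfinite(self.drift_magnitude):
            raise ConfigurationError("drift_magnitude must be finite")
        if not np.isfinite(self.first_replicate_bias):
            raise ConfigurationError("first_replicate_bias must be finite")
        if any(d <= 0 for d in self.phase_durations):
            raise ConfigurationError("phase durations must be positive")
        if self.tau_rise <= 0 or self.sample_rate <= 0:
            raise ConfigurationError("tau_rise and sample_rate must be positive")
        if self.subject_covariance is not None:
            cov = np.asarray(self.subject_covariance, dtype=float)
            if cov.shape != (self.n_channels, self.n_channels):
                raise ConfigurationError("subject_covariance must be n_channels square")
            self.subject_covariance = cov

    @property
    def phase_bounds(self) -> tuple[float, float, float]:
        b, s, w = self.phase_durations
        return (b, b + s, b + s + w)


@dataclass
class SubjectProfile:
    """Ground truth for one simulated subject."""

    subject_id: str
    label: str  # "case" or "control"
    true_response: np.ndarray = field(repr=False)
    drifted_replicates: list[int] = field(default_factory=list)


def generate_sweep(
    profile: SubjectProfile,
    replicate_index: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SensorSweep:
    """Simulate one three-phase resistance sweep for one replicate.

    Replicate 1 receives the additive first-measurement bias; replicates 2..n
    drift with probability ``drift_prob``.  The drift decision and the
    replicate noise are drawn from ``rng`` in a fixed order, so identical
    generator state yields identical sweeps.
    """
    if not 1 <= replicate_index <= config.n_replicates:
        raise ConfigurationError(
            f"replicate_index {replicate_index} outside [1, {config.n_replicates}]"
        )
    a = profile.true_response + rng.normal(0.0, config.sigma_replicate, config.n_channels)
    if replicate_index == 1:
        a = a + config.first_replicate_bias
        drifted = False
    else:
        drifted = bool(rng.random() < config.drift_prob)

    b_end, s_end, w_end = config.phase_bounds
    dt = 1.0 / config.sample_rate
    times = np.arange(0.0, w_end + dt / 2, dt)
    d = 1.0 + config.drift_magnitude * times if drifted else np.ones_like(times)

    resist = np.empty((config.n_channels, times.size))
    base = np.where(times <= b_end)[0]
    sample = np.where((times > b_end) & (times <= s_end))[0]
    wash = np.where(times > s_end)[0]
    B = config.baseline_resistance[:, None]
    a_col = a[:, None]
    resist[:, base] = B * d[base]
    rise = 1.0 - np.exp(-(times[sample] - b_end) / config.tau_rise)
    resist[:, sample] = B * d[sample] * (1.0 + a_col * rise)
    plateau = a_col * (1.0 - np.exp(-(s_end - b_end) / config.tau_rise))
    decay = np.exp(-(times[wash] - s_end) / config.tau_rise)
    resist[:, wash] = B * d[wash] * (1.0 + plateau * decay)

    return SensorSweep(
        subject_id=profile.subject_id,
        replicate=replicate_index,
        times=times,
        resistances=resist,
        phase_bounds=(b_end, s_end, w_end),
        label=profile.label,
        drifted=drifted,
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectProfile], list[SensorSweep]]:
    """Simulate a full case/control cohort of sweeps.

    Returns one :class:`SubjectProfile` per subject (ground truth) and
    ``n_replicates`` sweeps per subject.  Deterministic for a fixed config
    (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[SubjectProfile] = []
    sweeps: list[SensorSweep] = []
    labels = ["case"] * config.n_cases + ["control"] * config.n_controls
    width = len(str(len(labels)))
    for idx, label in enumerate(labels, start=1):
        mean = config.mu_control + (config.delta_mu if label == "case" else 0.0)
        if config.subject_covariance is not None:
            effect = rng.multivariate_normal(
                np.zeros(config.n_channels), config.subject_covariance
            )
        else:
            effect = rng.normal(0.0, config.sigma_subject, config.n_channels)
        profile = SubjectProfile(
            subject_id=f"S{idx:0{width}d}",
            label=label,
            true_response=mean + effect,
        )
        for r in range(1, config.n_replicates + 1):
            sweep = generate_sweep(profile, r, config, rng)
            if sweep.drifted:
                profile.drifted_replicates.append(r)
            sweeps.append(sweep)
        profiles.append(profile)
    return profiles, sweeps


def write_sweeps_csv(sweeps: list[SensorSweep], path: str | Path) -> None:
    """Write sweeps as long-format CSV: one row per (replicate, channel, time)."""
    frames = []
    for sw in sweeps:
        n_ch, n_t = sw.resistances.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sw.subject_id,
                    "label": sw.label if sw.label is not None else "",
                    "replicate": sw.replicate,
                    "channel": np.repeat(np.arange(1, n_ch + 1), n_t),
                    "time_s": np.tile(sw.times, n_ch),
                    "resistance": sw.resistances.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sweeps_csv(
    path: str | Path, phase_bounds: tuple[float, float, float] = (10.0, 50.0, 60.0)
) -> list[SensorSweep]:
    """Read long-format sweep CSV back into :class:`SensorSweep` objects."""
    df = pd.read_csv(path)
    required = {"subject_id", "replicate", "channel", "time_s", "resistance"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"sweep CSV missing columns: {sorted(missing)}")
    sweeps = []
    for (sid, rep), grp in df.groupby(["subject_id", "replicate"], sort=True):
        wide = grp.pivot_table(index="channel", columns="time_s", values="resistance")
        label = None
        if "label" in grp.columns:
            lab = grp["label"].iloc[0]
            label = None if pd.isna(lab) or lab == "" else str(lab)
        sweeps.append(
            SensorSweep(
                subject_id=str(sid),
                replicate=int(rep),
                times=wide.columns.to_numpy(dtype=float),
                resistances=wide.to_numpy(dtype=float),
                phase_bounds=phase_bounds,
                label=label,
            )
        )
    return sweeps


def write_truth_json(profiles: list[SubjectProfile], path: str | Path) -> None:
    """Ground-truth sidecar: per-subject true responses and drift flags."""
    payload = {
        p.subject_id: {
            "label": p.label,
            "true_response": [float(x) for x in p.true_response],
            "drifted_replicates": list(p.drifted_replicates),
        }
        for p in profiles
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
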