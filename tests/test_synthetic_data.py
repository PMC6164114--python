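"""Generator contracts: ground-truth encoding, cohort shape, seeding, drift."""

import numpy as np
import pytest

from breathdx import (
    SimulationConfig,
    compute_replicate_feature,
    extract_baseline,
    extract_response,
    generate_cohort,
    generate_sweep,
)
from breathdx.errors import ConfigurationError


def test_noiseless_cohort_encodes_exact_class_means(noiseless_config):
    """With zero noise/drift/bias every sweep of a subject encodes the class mean."""
    cfg = noiseless_config
    profiles, sweeps = generate_cohort(cfg)
    kinetic = 1.0 - np.exp(-40.0 / cfg.tau_rise)
    by_id = {p.subject_id: p for p in profiles}
    for sw in sweeps:
        p = by_id[sw.subject_id]
        expected = cfg.mu_control + (cfg.delta_mu if p.label == "case" else 0.0)
        np.testing.assert_allclose(p.true_response, expected)
        resp = extract_response(sw, extract_baseline(sw))
        tol = np.abs(p.true_response) * np.exp(-40.0 / cfg.tau_rise) + 1e-12
        assert np.all(np.abs(resp - p.true_response * kinetic) < 1e-12)
        assert np.all(np.abs(resp - p.true_response) <= tol)


def test_cohort_shape_matches_study_structure():
    """56 cases + 188 controls, 10 measurements per bag: 244 profiles, 2440 sweeps."""
    cfg = SimulationConfig(n_cases=56, n_controls=188, n_replicates=10, sample_rate=0.5, seed=3)
    profiles, sweeps = generate_cohort(cfg)
    assert len(profiles) == 244
    assert len(sweeps) == 2440
    assert sum(p.label == "case" for p in profiles) == 56
    per_subject = {}
    for sw in sweeps:
        per_subject[sw.subject_id] = per_subject.get(sw.subject_id, 0) + 1
    assert set(per_subject.values()) == {10}


def test_seeding_contract():
    cfg7a = SimulationConfig(n_cases=2, n_controls=2, seed=7, sample_rate=1.0)
    cfg7b = SimulationConfig(n_cases=2, n_controls=2, seed=7, sample_rate=1.0)
    cfg8 = SimulationConfig(n_cases=2, n_controls=2, seed=8, sample_rate=1.0)
    _, sw_a = generate_cohort(cfg7a)
    _, sw_b = generate_cohort(cfg7b)
    _, sw_c = generate_cohort(cfg8)
    for a, b in zip(sw_a, sw_b):
        np.testing.assert_array_equal(a.resistances, b.resistances)
    assert any(
        not np.array_equal(a.resistances, c.resistances) for a, c in zip(sw_a, sw_c)
    )


def test_drifting_replicate_has_predictable_terminal_gap(noiseless_config):
    """A linear multiplicative ramp d(t)=1+0.002t moves the terminal baseline

    by about 0.002*(t_washout_tail - t_baseline_window) relative, far beyond
    the 1% drift tolerance.
    """
    cfg = SimulationConfig(
        n_cases=1,
        n_controls=1,
        sigma_subject=0.0,
        sigma_replicate=0.0,
        drift_prob=1.0,
        drift_magnitude=0.002,
        first_replicate_bias=0.0,
        seed=5,
    )
    _, sweeps = generate_cohort(cfg)
    drifted = [sw for sw in sweeps if sw.replicate >= 2]
    assert all(sw.drifted for sw in drifted)
    feat = compute_replicate_feature(drifted[0])
    # R0 window is t in [5, 10] (mean 7.5); washout tail is t in [59, 60]
    # (mean 59.5); the pure-drift prediction for the relative gap is
    # 0.002 * (59.5 - 7.5) = 0.104, plus a small residual-response term.
    assert feat.drift_flag
    assert np.all(np.abs(feat.baseline_return_gap - 0.104) < 0.012)


def test_zero_response_gives_flat_trace(noiseless_config):
    cfg = SimulationConfig(
        n_cases=1, n_controls=1, mu_control=0.0, delta_mu=0.0,
        sigma_subject=0.0, sigma_replicate=0.0, drift_prob=0.0,
        first_replicate_bias=0.0, seed=2,
    )
    _, sweeps = generate_cohort(cfg)
    sw = sweeps[1]
    assert np.ptp(sw.resistances, axis=1).max() == 0.0
    resp = extract_response(sw, extract_baseline(sw))
    np.testing.assert_allclose(resp, 0.0, atol=1e-14)


def test_first_replicate_carries_bias(noiseless_config):
    _, sweeps = generate_cohort(noiseless_config)
    first = next(sw for sw in sweeps if sw.replicate == 1)
    second = next(
        sw for sw in sweeps if sw.replicate == 2 and sw.subject_id == first.subject_id
    )
    r1 = extract_response(first, extract_baseline(first))
    r2 = extract_response(second, extract_baseline(second))
    kinetic = 1.0 - np.exp(-40.0 / noiseless_config.tau_rise)
    np.testing.assert_allclose(
        r1 - r2, noiseless_config.first_replicate_bias * kinetic, rtol=1e-9
    )


def test_class_means_converge_to_programmed_shift():
    """Law of large numbers: extracted case-control feature difference -> delta_mu."""
    n = 500
    cfg = SimulationConfig(
        n_cases=n, n_controls=n, n_replicates=4, sample_rate=0.5,
        drift_prob=0.0, seed=11,
    )
    profiles, sweeps = generate_cohort(cfg)
    from breathdx.pipeline import extract_features

    subjects, _, rejected = extract_features(sweeps)
    assert not rejected
    X = np.array([s.response for s in subjects])
    y = np.array([s.label == "case" for s in subjects])
    diff = X[y].mean(axis=0) - X[~y].mean(axis=0)
    # per-channel SD of the difference of means: sqrt(2 (s_subj^2 + s_rep^2/3) / n);
    # averaging over 32 independent channels divides it by sqrt(32)
    se_channel = np.sqrt(2 * (cfg.sigma_subject**2 + cfg.sigma_replicate**2 / 3) / n)
    mean_gap = diff.mean() - cfg.delta_mu.mean()
    assert abs(mean_gap) < 3 * se_channel / np.sqrt(cfg.n_channels)
    assert np.all(np.abs(diff - cfg.delta_mu) < 5 * se_channel)


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_replicates=0),
        dict(sigma_subject=-1.0),
        dict(sigma_replicate=float("nan")),
        dict(drift_prob=1.5),
        dict(phase_durations=(10.0, -1.0, 10.0)),
        dict(baseline_resistance=-5.0),
        dict(mu_control=float("inf")),
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_cases=2, n_controls=2, **bad)


def test_replicate_index_out_of_range(noiseless_config):
    profiles, _ = generate_cohort(noiseless_config)
    rng = np.random.default_rng(0)
    with pytest.raises(ConfigurationError):
        generate_sweep(profiles[0], 0, noiseless_config, rng)
    with pytest.raises(ConfigurationError):
        generate_sweep(profiles[0], 11, noiseless_config, rng)


def test_sweep_csv_roundtrip(tmp_path):
    from breathdx.synthetic_data import read_sweeps_csv, write_sweeps_csv

    cfg = SimulationConfig(n_cases=1, n_controls=1, n_replicates=3, sample_rate=0.5, seed=4)
    _, sweeps = generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_sweeps_csv(sweeps, path)
    back = read_sweeps_csv(path, phase_bounds=cfg.phase_bounds)
    assert len(back) == len(sweeps)
    orig = {(s.subject_id, s.replicate): s for s in sweeps}
    for sw in back:
        ref = orig[(sw.subject_id, sw.replicate)]
        np.testing.assert_allclose(sw.resistances, ref.resistances)
        assert sw.label == ref.label
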