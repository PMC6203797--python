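import itertools

import numpy as np
import pytest
from scipy import stats

from iticoder import GeneratorConfig, generate_null_unit, generate_session
from iticoder import itimod
from iticoder.itimod import (bin_iti_rates, cs_evoked_test,
                             compare_reinforced_unreinforced,
                             detect_modulation, shuffle_counts, shuffle_null,
                             stage_rms)
from iticoder.sessionio import Unit


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_single_spike_lands_in_first_bin(make_session, make_unit):
    session = make_session([36.0, 36.0, 36.0])
    delta = 36.0 / 6
    start = session.iti_intervals().loc[0, "start_s"]
    unit = make_unit([start + delta / 2])
    m = bin_iti_rates(session, unit, 6)
    assert m.counts[0, 0] == 1 and m.counts.sum() == 1
    assert m.rates[0, 0] == pytest.approx(1 / delta)


def test_spike_on_bin_edge_belongs_to_upper_bin(make_session, make_unit):
    """Half-open [k*w, (k+1)*w) convention: a spike exactly on an edge is
    counted in the higher bin."""
    session = make_session([36.0, 36.0, 36.0])
    delta = 36.0 / 6
    start = session.iti_intervals().loc[1, "start_s"]
    unit = make_unit([start + delta])
    m = bin_iti_rates(session, unit, 6)
    assert m.counts[1, 1] == 1 and m.counts[1, 0] == 0


def test_binning_matches_brute_force_histogram(make_session, make_unit):
    rng = np.random.default_rng(8)
    itis = [30.0, 42.0, 38.0]
    session = make_session(itis)
    mean_iti = session.mean_iti_s
    spikes = np.sort(rng.uniform(0, session.trials[-1].trial_offset_s, 400))
    unit = make_unit(spikes)
    m = bin_iti_rates(session, unit, 6)
    edges = np.linspace(0, mean_iti, 7)
    for row, (_, iti) in enumerate(session.iti_intervals().iterrows()):
        phases = spikes[(spikes >= iti.start_s) &
                        (spikes < iti.start_s + min(iti.duration_s,
                                                    mean_iti))] - iti.start_s
        expected = np.histogram(phases, bins=edges)[0].astype(float)
        expected[edges[1:] > iti.duration_s + 1e-9] = 0.0
        np.testing.assert_array_equal(m.counts[row], expected)


def test_validity_mask_tracks_short_itis(make_session, make_unit):
    session = make_session([20.0, 40.0, 45.0])  # mean 35
    m = bin_iti_rates(session, make_unit([]), 6)
    # trial with 20-s ITI: only bins ending before 20 s are valid
    delta = session.mean_iti_s / 6
    assert list(m.valid[0]) == [
        (k + 1) * delta <= 20.0 for k in range(6)]
    assert m.valid[1].all() and m.valid[2].all()


def test_unknown_binning_rejected(make_session, make_unit):
    session = make_session([36.0, 36.0])
    with pytest.raises(ValueError, match="n_bins"):
        bin_iti_rates(session, make_unit([]), 7)


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def test_shuffle_conserves_per_trial_totals(make_session, make_unit):
    rng = np.random.default_rng(3)
    session = make_session([25.0, 40.0, 38.0, 44.0])
    spikes = np.sort(rng.uniform(0, session.trials[-1].trial_offset_s, 300))
    m = bin_iti_rates(session, make_unit(spikes), 12)
    sh = shuffle_counts(m, 50, np.random.default_rng(0))
    np.testing.assert_allclose(sh.sum(axis=2),
                               np.broadcast_to(m.rates.sum(1), (50, 4)))


def test_single_valid_bin_shuffle_is_identity(make_session, make_unit):
    session = make_session([8.0, 60.0, 60.0])  # mean ~42.7; trial 0 short
    start = session.iti_intervals().loc[0, "start_s"]
    m = bin_iti_rates(session, make_unit([start + 1.0]), 6)
    assert m.valid[0].sum() == 1
    sh = shuffle_counts(m, 30, np.random.default_rng(1))
    np.testing.assert_array_equal(
        sh[:, 0, :], np.broadcast_to(m.rates[0], (30, 6)))


def test_null_sd_matches_exhaustive_permutation_oracle(make_session,
                                                       make_unit):
    """Monte-Carlo null s.d. converges to the exact value enumerated over
    all distinct within-trial permutations (3 trials x 6 bins, 6 spikes)."""
    session = make_session([40.0, 40.0, 40.0], resp_rate_hz=5.0)
    starts = session.iti_intervals()["start_s"].to_numpy()
    # counts per trial: t0 [2,1,0,...], t1 [1,1,1,0,...], t2 all zero
    delta = session.mean_iti_s / 6
    spikes = np.sort(np.concatenate([
        starts[0] + np.array([0.1, 0.2, delta + 0.1]),
        starts[1] + np.array([0.1, delta + 0.1, 2 * delta + 0.1]),
    ]))
    m4 = bin_iti_rates(session, make_unit(spikes), 6)

    # exhaustive oracle on the 6-bin matrix (distinct permutations only)
    per_trial_perms = [sorted(set(itertools.permutations(m4.counts[t])))
                       for t in range(3)]
    means = []
    for combo in itertools.product(*per_trial_perms):
        means.append(np.mean(combo, axis=0))
    exact_sd = np.array(means).std(axis=0)
    exact_mean = np.array(means).mean(axis=0)

    null = shuffle_null(m4, n_shuffles=4000, seed=12)
    width = session.mean_iti_s / 6
    np.testing.assert_allclose(null.mean * width, exact_mean, atol=0.02)
    np.testing.assert_allclose(null.sd * width, exact_sd, atol=0.02)


def test_forced_burst_detected_up(make_session, make_unit):
    session = make_session([36.0] * 12)
    itis = session.iti_intervals()
    delta = session.mean_iti_s / 6
    spikes = []
    rng = np.random.default_rng(5)
    for _, row in itis.iterrows():
        # background spikes everywhere, strong burst in bin 3
        spikes.extend(rng.uniform(row.start_s, row.start_s + 36.0, 10))
        spikes.extend(rng.uniform(row.start_s + 3 * delta,
                                  row.start_s + 4 * delta - 1e-6, 30))
    m = bin_iti_rates(session, make_unit(np.sort(spikes)), 6)
    null = shuffle_null(m, 100, seed=2)
    res = detect_modulation(m, null)
    assert res.significant[3] and res.direction[3] == 1
    assert res.direction[res.significant].max() == 1


def test_null_population_flag_rate_near_chance():
    """Per-bin |z|>2 flag rate on homogeneous Poisson units sits near the
    Gaussian two-sided level (~4.6%)."""
    cfg = GeneratorConfig(n_habituation=0, n_acquisition=30, n_extinction=0,
                          n_units=0, seed=31)
    session, _ = generate_session(cfg)
    span = session.trials[-1].trial_offset_s + 5
    rng = np.random.default_rng(9)
    props = []
    for i in range(60):
        u = generate_null_unit(cfg, 5.0, duration_s=span, rng=rng)
        m = bin_iti_rates(session, u, 20)
        null = shuffle_null(m, 100, seed=rng)
        props.append(detect_modulation(m, null).proportion_significant)
    assert 0.02 < np.mean(props) < 0.08


def test_prevalence_survival_curve_monotone_and_tail():
    cfg = GeneratorConfig(n_habituation=0, n_acquisition=25, n_extinction=0,
                          seed=32)
    session, _ = generate_session(cfg)
    span = session.trials[-1].trial_offset_s + 5
    rng = np.random.default_rng(10)
    results = []
    for i in range(40):
        u = generate_null_unit(cfg, 5.0, duration_s=span, rng=rng)
        m = bin_iti_rates(session, u, 40)
        results.append(detect_modulation(m, shuffle_null(m, 100, seed=rng)))
    prev = itimod.modulation_prevalence(results)
    assert (np.diff(prev["survival"]) <= 1e-12).all()
    # null population: the fraction above 20% should be tiny
    assert prev["fraction_above_threshold"] <= 0.1


# ---------------------------------------------------------------------------
# CS-evoked test
# ---------------------------------------------------------------------------

def test_cs_evoked_identical_rates_untestable(make_session, make_unit):
    session = make_session([30.0] * 5,
                           phases=["acquisition"] * 6)
    # one spike exactly 0.2 s before and after every CS
    spikes = []
    for tr in session.trials:
        spikes += [tr.cs_onset_s - 0.2, tr.cs_onset_s + 0.2]
    res = cs_evoked_test(session, make_unit(np.sort(spikes)), window_s=0.5)
    assert not res["testable"] and not res["flagged"]


def test_cs_evoked_window_outside_span_errors(make_session, make_unit):
    session = make_session([30.0] * 3, phases=["acquisition"] * 4)
    with pytest.raises(ValueError, match="window"):
        cs_evoked_test(session, make_unit([1.0]), window_s=10.0)


def test_cs_evoked_power_and_size():
    flagged_pos = 0
    for seed in range(10):
        cfg = GeneratorConfig(n_units=1, tuned_fraction=0.0,
                              cs_evoked_fraction=1.0, seed=70 + seed)
        session, _ = generate_session(cfg)
        res = cs_evoked_test(session, session.units[0])
        flagged_pos += res["flagged"]
    assert flagged_pos >= 8
    flagged_null = 0
    for seed in range(20):
        cfg = GeneratorConfig(n_units=1, tuned_fraction=0.0,
                              cs_evoked_fraction=0.0, seed=90 + seed)
        session, _ = generate_session(cfg)
        flagged_null += cs_evoked_test(session, session.units[0])["flagged"]
    assert flagged_null <= 4


# ---------------------------------------------------------------------------
# learning stages
# ---------------------------------------------------------------------------

def test_stationary_unit_not_classified_responsive():
    classified = 0
    for seed in range(8):
        cfg = GeneratorConfig(n_units=1, tuned_fraction=0.0,
                              seed=110 + seed)
        session, _ = generate_session(cfg)
        r = stage_rms(session, session.units[0], n_shuffles=60, seed=seed)
        classified += r.acquisition_responsive
    assert classified <= 2


def test_gated_unit_classified_and_extinction_intermediate():
    classified = 0
    ext_between = 0
    for seed in range(10):
        cfg = GeneratorConfig(n_units=1, tuned_fraction=1.0,
                              acquisition_gated_fraction=1.0,
                              tuning_gain=2.0, seed=130 + seed)
        session, _ = generate_session(cfg)
        r = stage_rms(session, session.units[0], n_shuffles=60, seed=seed)
        classified += r.acquisition_responsive
        hab = r.rms["habituation"]
        acq = np.mean([r.rms[s]
                       for s in ("acq_early", "acq_mid", "acq_late")])
        ext = np.mean([r.rms[s] for s in ("ext_early", "ext_late")])
        ext_between += hab - 0.3 < ext < acq + 0.3
    assert classified >= 8
    assert ext_between >= 7


def test_baseline_drift_without_tuning_not_responsive(make_session,
                                                      make_unit):
    """Stage-wise shuffle normalization removes global rate drift: a unit
    whose baseline doubles in acquisition but stays flat within the ITI
    is not classified."""
    classified = 0
    for seed in range(6):
        cfg = GeneratorConfig(n_units=0, seed=150 + seed)
        session, _ = generate_session(cfg)
        rng = np.random.default_rng(seed)
        spikes = []
        for _, row in session.iti_intervals().iterrows():
            rate = 10.0 if session.trials[int(row.name)].phase == \
                "acquisition" else 5.0
            n = rng.poisson(rate * row.duration_s)
            spikes.append(rng.uniform(row.start_s,
                                      row.start_s + row.duration_s, n))
        unit = Unit("drift", "amygdala", np.sort(np.concatenate(spikes)))
        r = stage_rms(session, unit, n_shuffles=60, seed=seed)
        classified += r.acquisition_responsive
    assert classified <= 1


def test_missing_phase_errors(make_session, make_unit):
    session = make_session([30.0] * 5, phases=["acquisition"] * 6)
    with pytest.raises(ValueError, match="habituation"):
        stage_rms(session, make_unit([10.0]))


# ---------------------------------------------------------------------------
# reinforced vs un-reinforced
# ---------------------------------------------------------------------------

def test_reinforcement_independent_tuning_similar():
    different = 0
    for seed in range(8):
        cfg = GeneratorConfig(n_units=1, tuned_fraction=1.0,
                              acquisition_gated_fraction=0.0,
                              catch_fraction=0.33, seed=170 + seed)
        session, _ = generate_session(cfg)
        out = compare_reinforced_unreinforced(session, session.units[0],
                                              n_shuffles=60, seed=seed)
        different += out["catch_vs_reinforced"]["different"]
    assert different <= 2


def test_no_catch_trials_errors():
    session, _ = generate_session(
        GeneratorConfig(n_units=1, catch_fraction=0.0, seed=1))
    with pytest.raises(ValueError, match="catch"):
        compare_reinforced_unreinforced(session, session.units[0])


def test_forced_reinforcement_dependence_detected():
    """A unit firing a burst only in ITIs after reinforced trials is
    flagged as different between trial classes."""
    cfg = GeneratorConfig(n_units=0, catch_fraction=0.33, seed=190)
    session, _ = generate_session(cfg)
    rng = np.random.default_rng(0)
    spikes = []
    for _, row in session.iti_intervals().iterrows():
        tr = session.trials[int(row.name)]
        n = rng.poisson(4.0 * row.duration_s)
        spikes.append(rng.uniform(row.start_s,
                                  row.start_s + row.duration_s, n))
        if tr.phase == "acquisition" and tr.reinforced:
            spikes.append(rng.uniform(row.start_s + 10, row.start_s + 14,
                                      rng.poisson(60)))
    unit = Unit("forced", "amygdala", np.sort(np.concatenate(spikes)))
    out = compare_reinforced_unreinforced(session, unit, n_shuffles=60,
                                          seed=3)
    assert out["catch_vs_reinforced"]["different"]
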