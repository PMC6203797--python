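import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from iticoder import (GeneratorConfig, generate_session,
                      generate_synchronous_pair)
from iticoder import synchrony
from iticoder.synchrony import (CCWindowMap, GateError, LAG_MAX_S, LAG_BIN_S,
                                N_LAGS, _count_map, classify_pair_significance,
                                cluster_cc_shapes, compute_pair,
                                sliding_crosscorr, window_grid)


def _session_with_pair(make_session, a_phases, b_phases, itis=(36.0, 36.0,
                                                               36.0)):
    session = make_session(list(itis))
    iti = session.iti_intervals()
    a, b = [], []
    for _, row in iti.iterrows():
        a.append(np.asarray(a_phases) + row.start_s)
        b.append(np.asarray(b_phases) + row.start_s)
    from iticoder.sessionio import Unit
    ua = Unit("a", "amygdala", np.concatenate(a))
    ub = Unit("b", "dACC", np.concatenate(b))
    session.units = [ua, ub]
    return session, ua, ub


def test_identical_trains_put_all_mass_at_zero_lag(make_session):
    phases = np.arange(0.5, 35.5, 0.9)      # >1 Hz, spacing > max lag
    session, ua, ub = _session_with_pair(make_session, phases, phases)
    cc = sliding_crosscorr(session, ua, ub)
    assert cc.counts.sum() > 0
    zero_bin = N_LAGS // 2
    assert cc.counts[:, zero_bin].sum() == cc.counts.sum()


def test_shifted_train_peaks_at_shift_lag(make_session):
    phases = np.arange(0.5, 34.5, 0.86)
    session, ua, ub = _session_with_pair(make_session, phases, phases + 0.1)
    cc = sliding_crosscorr(session, ua, ub)
    expected_bin = int((0.1 + LAG_MAX_S) / LAG_BIN_S)
    assert cc.counts[:, expected_bin].sum() == cc.counts.sum()


def test_rate_gate_enforced(make_session):
    phases = np.arange(0.5, 35.5, 5.0)      # ~0.2 Hz
    session, ua, ub = _session_with_pair(make_session, phases, phases)
    with pytest.raises(GateError, match="1"):
        sliding_crosscorr(session, ua, ub)


def _brute_force(a_ph, d_ph, durs, windows):
    counts = np.zeros((windows.size, N_LAGS))
    for a, d, dur in zip(a_ph, d_ph, durs):
        for w_i, w in enumerate(windows):
            if w + 3.0 > dur:
                continue
            for p in a:
                if not (w <= p < w + 3.0):
                    continue
                for q in d:
                    lag = q - p
                    if -LAG_MAX_S <= lag < LAG_MAX_S:
                        counts[w_i, int((lag + LAG_MAX_S) // LAG_BIN_S)] += 1
    return counts


def test_counts_match_exhaustive_double_loop():
    rng = np.random.default_rng(5)
    durs = np.array([36.0, 29.0, 41.0])
    a_ph = [np.sort(rng.uniform(0, d, 15)) for d in durs]
    d_ph = [np.sort(rng.uniform(0, d, 18)) for d in durs]
    windows = window_grid(36.0)
    ours = _count_map(a_ph, d_ph, durs, windows)
    np.testing.assert_array_equal(ours, _brute_force(a_ph, d_ph, durs,
                                                     windows))


def test_symmetry_under_unit_swap_with_lag_negation():
    """With all spikes interior to shared windows, swapping the reference
    unit mirrors the lag axis exactly."""
    a_ph = [np.array([10.3, 14.2, 18.7])]
    d_ph = [np.array([10.345, 14.155, 18.745])]
    durs = np.array([36.0])
    windows = window_grid(36.0)
    fwd = _count_map(a_ph, d_ph, durs, windows)
    rev = _count_map(d_ph, a_ph, durs, windows)
    np.testing.assert_array_equal(fwd, rev[:, ::-1])


# ---------------------------------------------------------------------------
# nulls and significance
# ---------------------------------------------------------------------------

def _cfg(seed, n_trials=20):
    return GeneratorConfig(n_habituation=0, n_acquisition=n_trials,
                           n_extinction=1, baseline_rate_hz=5.0, seed=seed)


def test_injected_coincidences_exceed_both_nulls(make_session):
    cfg = _cfg(50)
    session, _ = generate_session(cfg)
    ua, ub, _ = generate_synchronous_pair(cfg, "early", 2.0,
                                          trials=session.trials,
                                          rng=np.random.default_rng(1))
    cc = compute_pair(session, ua, ub, n_shuffles=50, seed=0)
    assert cc.pair_significant
    # significance concentrates where the coincidences were injected
    prof = cc.sig_mask.mean(axis=1)
    n = len(prof)
    assert prof[:n // 3].sum() > prof[2 * n // 3:].sum()
    # and at near-zero lags
    zero = N_LAGS // 2
    assert cc.sig_mask[:, zero - 2:zero + 3].sum() >= \
        0.5 * cc.sig_mask.sum()


def test_rate_comodulation_absorbed_by_within_null():
    """Two units whose firing rates rise and fall together across trials,
    with independent spike times, are not called synchronous."""
    cfg = _cfg(51)
    session, _ = generate_session(cfg)
    rng = np.random.default_rng(2)
    from iticoder.sessionio import Unit
    spikes = {"a": [], "b": []}
    for _, row in session.iti_intervals().iterrows():
        rate = rng.uniform(2.0, 10.0)       # shared slow rate, per trial
        for k in spikes:
            n = rng.poisson(rate * row.duration_s)
            spikes[k].append(rng.uniform(row.start_s,
                                         row.start_s + row.duration_s, n))
    ua = Unit("a", "amygdala", np.sort(np.concatenate(spikes["a"])))
    ub = Unit("b", "dACC", np.sort(np.concatenate(spikes["b"])))
    cc = compute_pair(session, ua, ub, n_shuffles=50, seed=3)
    assert not cc.pair_significant


def test_shared_tuning_absorbed_by_across_null():
    """Two independently tuned units with the same temporal profile (no
    trial-locked coincidences) are not called synchronous."""
    cfg = GeneratorConfig(n_habituation=0, n_acquisition=20, n_extinction=1,
                          n_units=2, tuned_fraction=1.0,
                          acquisition_gated_fraction=0.0, tuning_peak_s=10.0,
                          tuning_gain=3.0, tuning_width_s=8.0,
                          tuning_width_jitter_s=0.0, seed=52)
    session, _ = generate_session(cfg)
    ua = session.units[0]
    ub = session.units[1]
    ub.region = "dACC"
    cc = compute_pair(session, ua, ub, n_shuffles=50, seed=4)
    assert not cc.pair_significant


def test_across_null_undefined_for_single_iti(make_session, make_unit):
    phases = np.arange(0.5, 35.5, 0.5)
    session, ua, ub = _session_with_pair(make_session, phases, phases,
                                         itis=(36.0,))
    with pytest.raises(ValueError, match="single ITI"):
        synchrony.across_iti_null(session, ua, ub, n_shuffles=10, seed=0)


def _manual_map(n_windows=30, hot_windows=()):
    counts = np.zeros((n_windows, N_LAGS))
    q = np.full((n_windows, N_LAGS), 5.0)
    for w in hot_windows:
        counts[w, 36:39] = 10.0             # contiguous 3-bin run
    null = {"mean": q * 0.5, "sd": q * 0.1,
            "quantiles": {0.99: q}, "n_shuffles": 100}
    return CCWindowMap(pair_id=("a", "b"),
                       window_starts_s=np.arange(n_windows, dtype=float),
                       counts=counts, null_within=null,
                       null_across={k: (v.copy() if hasattr(v, "copy")
                                        else dict(v) if isinstance(v, dict)
                                        else v) for k, v in null.items()})


def test_persistence_rule_one_window_insufficient():
    cc = classify_pair_significance(_manual_map(hot_windows=(4,)))
    assert cc.window_significant.sum() == 1
    assert not cc.pair_significant


def test_persistence_rule_five_of_thirty_sufficient():
    cc = classify_pair_significance(_manual_map(hot_windows=(2, 7, 12, 20,
                                                             27)))
    assert cc.pair_significant


def test_single_significant_bin_is_speckle():
    cc = _manual_map()
    cc.counts[3, 37] = 10.0                 # isolated cell, no 2-bin run
    cc = classify_pair_significance(cc)
    assert cc.sig_mask[3, 37]
    assert not cc.window_significant[3]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _family_maps(seed0=60, per_family=3, n_shuffles=40):
    maps, labels = [], []
    for fam_idx, epoch in enumerate(("early", "late", "diffuse")):
        for k in range(per_family):
            cfg = _cfg(seed0 + 10 * fam_idx + k)
            session, _ = generate_session(cfg)
            ua, ub, _ = generate_synchronous_pair(
                cfg, epoch, 2.5, trials=session.trials,
                rng=np.random.default_rng(seed0 + 10 * fam_idx + k))
            cc = compute_pair(session, ua, ub, n_shuffles=n_shuffles,
                              seed=fam_idx * 7 + k)
            maps.append(cc)
            labels.append(fam_idx)
    return maps, np.array(labels)


@pytest.fixture(scope="module")
def family_maps():
    return _family_maps()


def test_cluster_recovery_of_pair_families(family_maps):
    maps, truth = family_maps
    clust = cluster_cc_shapes(maps, k=3, seed=0)
    assert adjusted_rand_score(truth, clust.labels) >= 0.8
    # cluster 0 is the earliest-peaking profile by construction
    peaks = [np.nanargmax(p) for p in clust.cluster_profiles]
    assert peaks[0] == min(peaks)


def test_cluster_labels_invariant_under_input_order(family_maps):
    maps, _ = family_maps
    clust = cluster_cc_shapes(maps, k=3, seed=0)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(maps))
    clust_p = cluster_cc_shapes([maps[i] for i in perm], k=3, seed=0)
    np.testing.assert_array_equal(clust.labels[perm], clust_p.labels)


def test_identical_profiles_flagged_degenerate():
    cc = classify_pair_significance(_manual_map(hot_windows=(2, 7, 12, 20,
                                                             27)))
    maps = [cc, cc, cc]
    clust = cluster_cc_shapes(maps, k=3, seed=0)
    assert clust.degenerate


def test_fewer_pairs_than_k_rejected():
    cc = classify_pair_significance(_manual_map(hot_windows=(2, 7, 12, 20,
                                                             27)))
    with pytest.raises(ValueError, match="k=3"):
        cluster_cc_shapes([cc, cc], k=3, seed=0)
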