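"""Decoding elapsed ITI time from population activity, and hazard-rate
correlated terminal activity.

If units carry temporal tuning that tiles the ITI, a linear readout of the
population rate vector should recover elapsed time.  The decoder is an
optimal linear estimator (OLE): ordinary least squares mapping the
z-scored 40-bin population rate vector of a (trial, bin) sample to the
bin's center time, fit on 25 pseudorandomly chosen acquisition trials and
evaluated on the held-out 5, repeated 100 times.  Reported metrics are the
mean absolute error in seconds (RMSE alongside) and the bias curve (mean
estimate per true bin; edge bins shrink inward, a floor/ceiling effect of
any bounded least-squares readout).

The hazard analysis asks whether some units ramp with the momentary
probability that the next CS is about to occur: the empirical hazard is
the CDF of the session's ITI durations, and a unit is hazard-correlated
when its windowed rate (1 s windows, 0.5 s steps, normalized to the number
of trials still in their ITI at each window) correlates positively with
the hazard's rising phase up to 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .itimod import ITIMatrix
from .sessionio import Session, Unit


@dataclass
class DecoderFit:
    n_units: int
    n_bins: int
    bin_centers_s: np.ndarray
    train_trials: list           # per repetition: array of trial row indices
    test_trials: list            # per repetition: the held-out trial rows
    mae_s: float
    rmse_s: float
    mae_per_rep: np.ndarray
    bias_curve_s: np.ndarray     # mean estimate per true bin
    weights: np.ndarray          # from the last repetition (units + intercept)


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------

def population_tensor(matrices: list[ITIMatrix]):
    """Stack per-unit ITI matrices into (trials, bins, units) with a shared
    validity mask, z-scoring each unit over its valid samples."""
    if not matrices:
        raise ValueError("need at least one unit matrix")
    shape = matrices[0].rates.shape
    valid = matrices[0].valid
    for m in matrices[1:]:
        if m.rates.shape != shape:
            raise ValueError("all ITI matrices must share the trial grid")
    X = np.stack([m.rates for m in matrices], axis=-1).astype(float)
    mask = valid
    flat = X[mask]                       # (n_samples, n_units)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd
    return X, mask, matrices[0].bin_centers_s


def _lstsq_fit(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares weights with intercept; minimum-norm solution on
    rank-deficient designs."""
    design = np.column_stack([A, np.ones(len(A))])
    w, *_ = np.linalg.lstsq(design, y, rcond=None)
    return w


def fit_ole(matrices: list[ITIMatrix], train_trials: int = 25,
            test_trials: int = 5, reps: int = 100,
            seed: int = 0) -> DecoderFit:
    """Cross-validated OLE decoding of elapsed ITI time.

    Each repetition draws ``train_trials`` trials pseudorandomly, fits the
    linear readout on their valid (trial, bin) samples, and decodes
    ``test_trials`` held-out trials.
    """
    X, mask, centers = population_tensor(matrices)
    n_tr, n_bins, n_units = X.shape
    if n_tr < train_trials + test_trials:
        raise ValueError(f"need >= {train_trials + test_trials} trials, "
                         f"have {n_tr}")
    rng = np.random.default_rng(seed)
    times = np.broadcast_to(centers, (n_tr, n_bins))

    maes, rmses = [], []
    est_sum = np.zeros(n_bins)
    est_cnt = np.zeros(n_bins)
    train_sets, test_sets = [], []
    w = None
    for _ in range(reps):
        perm = rng.permutation(n_tr)
        tr_idx = perm[:train_trials]
        te_idx = perm[train_trials:train_trials + test_trials]
        train_sets.append(tr_idx)
        test_sets.append(te_idx)

        trm = mask[tr_idx]
        w = _lstsq_fit(X[tr_idx][trm], times[tr_idx][trm])

        tem = mask[te_idx]
        A = X[te_idx]
        pred_full = A @ w[:-1] + w[-1]
        err = pred_full - times[te_idx]
        maes.append(np.abs(err[tem]).mean())
        rmses.append(np.sqrt((err[tem] ** 2).mean()))
        for b in range(n_bins):
            sel = tem[:, b]
            est_sum[b] += pred_full[sel, b].sum()
            est_cnt[b] += sel.sum()

    bias = np.where(est_cnt > 0, est_sum / np.maximum(est_cnt, 1), np.nan)
    return DecoderFit(n_units=n_units, n_bins=n_bins, bin_centers_s=centers,
                      train_trials=train_sets, test_trials=test_sets,
                      mae_s=float(np.mean(maes)),
                      rmse_s=float(np.mean(rmses)),
                      mae_per_rep=np.array(maes), bias_curve_s=bias,
                      weights=w)


def error_vs_population_size(matrices: list[ITIMatrix], sizes: list[int],
                             reps: int = 100, seed: int = 0,
                             **fit_kwargs):
    """Decoding error as a function of the number of units used (units
    sampled without replacement, treated as independent)."""
    rng = np.random.default_rng(seed)
    out = []
    for n in sizes:
        if n > len(matrices):
            raise ValueError(f"requested {n} units, only {len(matrices)}")
        idx = rng.choice(len(matrices), size=n, replace=False)
        fit = fit_ole([matrices[i] for i in idx], reps=reps,
                      seed=int(rng.integers(2 ** 31)), **fit_kwargs)
        out.append({"n_units": n, "mae_s": fit.mae_s, "rmse_s": fit.rmse_s,
                    "mae_sem_s": float(fit.mae_per_rep.std(ddof=1)
                                       / np.sqrt(len(fit.mae_per_rep)))})
    return out


def decode_bias(fit: DecoderFit) -> np.ndarray:
    """Mean estimated time per true bin (the bias curve)."""
    return fit.bias_curve_s


# ---------------------------------------------------------------------------
# hazard rate
# ---------------------------------------------------------------------------

def empirical_hazard(session: Session, n_grid: int = 200):
    """Empirical cumulative probability of CS occurrence along the ITI,
    with a warped copy on a [0, 1] fraction-of-max-ITI axis."""
    durs = np.array([t.iti_prev_s for t in session.trials
                     if t.iti_prev_s is not None])
    if durs.size < 2:
        raise ValueError("need at least 2 ITIs")
    srt = np.sort(durs)

    def cdf(t):
        return np.searchsorted(srt, t, side="right") / srt.size

    tmax = srt[-1]
    grid = np.linspace(0.0, tmax, n_grid)
    return {"iti_durations_s": durs, "max_iti_s": float(tmax),
            "times_s": grid, "hazard": cdf(grid),
            "warped_axis": grid / tmax, "cdf": cdf}


def windowed_rate(session: Session, unit: Unit, window_s: float = 1.0,
                  step_s: float = 0.5):
    """Unit rate along the ITI in running windows, normalized by the
    number of trials whose ITI still covers each window, z-scored."""
    itis = session.iti_intervals()
    tmax = itis["duration_s"].max()
    starts = np.arange(0.0, tmax - window_s + 1e-9, step_s)
    counts = np.zeros(starts.size)
    n_cov = np.zeros(starts.size)
    for _, row in itis.iterrows():
        phases = unit.spike_times_s[
            (unit.spike_times_s >= row.start_s) &
            (unit.spike_times_s < row.start_s + row.duration_s)] - row.start_s
        cover = starts + window_s <= row.duration_s
        n_cov += cover
        if phases.size:
            for i in np.flatnonzero(cover):
                counts[i] += np.count_nonzero(
                    (phases >= starts[i]) & (phases < starts[i] + window_s))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / (n_cov * window_s)
    ok = n_cov > 0
    z = np.full_like(rate, np.nan)
    if rate[ok].std() > 0:
        z[ok] = (rate[ok] - rate[ok].mean()) / rate[ok].std()
    centers = starts + window_s / 2
    return centers, rate, z, n_cov


def hazard_correlation(session: Session, unit: Unit, alpha: float = 0.05,
                       rise_to: float = 0.75, min_windows: int = 3):
    """Pearson correlation of the unit's windowed ITI rate with the rising
    phase of the empirical hazard (from the first nonzero point up to the
    first crossing of ``rise_to``)."""
    hz = empirical_hazard(session)
    centers, rate, z, n_cov = windowed_rate(session, unit)
    h = hz["cdf"](centers)
    rising = (h > 0) & (h <= rise_to) & (n_cov > 0) & np.isfinite(z)
    # include the first window at or beyond the crossing so the phase is
    # closed on the right
    beyond = np.flatnonzero((h > rise_to) & (n_cov > 0) & np.isfinite(z))
    if beyond.size:
        rising[beyond[0]] = True
    idx = np.flatnonzero(rising)
    # adjacent half-overlapping windows share spikes; the significance
    # test runs on every other window so its samples are disjoint
    idx = idx[::2]
    if idx.size < min_windows:
        return {"unit_id": unit.unit_id, "testable": False,
                "flagged": False, "r": np.nan, "p": np.nan}
    if np.std(z[idx]) == 0 or np.std(h[idx]) == 0:
        return {"unit_id": unit.unit_id, "testable": False,
                "flagged": False, "r": np.nan, "p": np.nan}
    r, p = stats.pearsonr(z[idx], h[idx])
    flagged = bool(p < alpha and r > 0)
    out = {"unit_id": unit.unit_id, "testable": True, "flagged": flagged,
           "r": float(r), "p": float(p), "n_windows": int(idx.size)}
    if flagged:
        ok = n_cov > 0
        peak_t = centers[ok][np.nanargmax(rate[ok])]
        min_iti = hz["iti_durations_s"].min()
        out["peak_time_s"] = float(peak_t)
        out["peak_before_min_iti"] = bool(peak_t < min_iti)
    return out
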