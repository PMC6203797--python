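"""Temporal tuning during the ITI: peak, width, and center of mass.

A unit's tuning is read off its 40-bin across-trial mean ITI firing rate:
the peak is the bin with the highest mean rate; the width is the span of
contiguous bins around the peak whose rate exceeds the 95th percentile of
their own shuffle null.  Units whose supra-baseline region is a single bin
are excluded as untuned.  The center of mass (rate-weighted mean time,
``sum(FR_i * t_i) / sum(FR_i)``) summarizes each single trial's activity
and is the statistic used for trial-history analyses: does the temporal
placement of activity in the current ITI track the duration of the
previous one?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit

from .behavior import CRSeries
from .itimod import ITIMatrix, ShuffleNull
from .sessionio import Session


@dataclass
class TuningProfile:
    unit_id: str
    region: str
    peak_bin: int | None
    peak_time_s: float | None
    width_bins: int
    width_s: float
    peak_significant: bool
    excluded: bool                 # width <= 1 bin or no peak
    com_per_trial: pd.Series       # indexed by owning-trial index; seconds
    com_mean_s: float
    tie_note: str | None = None


# ---------------------------------------------------------------------------
# center of mass
# ---------------------------------------------------------------------------

def center_of_mass(rates_per_bin: np.ndarray,
                   bin_times_s: np.ndarray) -> float:
    """Rate-weighted mean time; NaN when the rate vector sums to zero."""
    r = np.asarray(rates_per_bin, dtype=float)
    t = np.asarray(bin_times_s, dtype=float)
    total = r.sum()
    if not total > 0:
        return float("nan")
    return float((r * t).sum() / total)


def _com_series(m: ITIMatrix, min_valid_bins: int = 3) -> pd.Series:
    centers = m.bin_centers_s
    out = {}
    for row in range(m.rates.shape[0]):
        v = m.valid[row]
        if v.sum() < min_valid_bins:
            continue
        com = center_of_mass(m.rates[row, v], centers[v])
        if np.isfinite(com):
            out[int(m.trial_index[row])] = com
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# peak and width
# ---------------------------------------------------------------------------

def find_peak_and_width(m: ITIMatrix, null: ShuffleNull, region: str = "",
                        upper_percentile: float = 95.0) -> TuningProfile:
    """Peak bin of the mean ITI rate, grown bidirectionally over adjacent
    bins exceeding the 95th percentile of their shuffle null."""
    mean = m.mean_rate()
    testable = np.isfinite(mean) & (m.valid.sum(0) > 0)
    if not testable.any() or np.nansum(mean) == 0:
        return TuningProfile(m.unit_id, region, None, None, 0, 0.0, False,
                             True, _com_series(m), float("nan"))
    p95 = null.percentiles.get(upper_percentile)
    if p95 is None:
        raise ValueError(f"null lacks the {upper_percentile}th percentile")

    masked = np.where(testable, mean, -np.inf)
    peak = int(np.argmax(masked))
    ties = np.flatnonzero(masked == masked[peak])
    tie_note = (f"peak tie among bins {ties.tolist()}; earliest kept"
                if ties.size > 1 else None)

    above = testable & (mean > p95)
    lo = hi = peak
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    while hi + 1 < m.n_bins and above[hi + 1]:
        hi += 1
    width_bins = (hi - lo + 1) if above[peak] else 1
    peak_sig = bool(above[peak])
    excluded = width_bins <= 1 or not peak_sig

    com = _com_series(m)
    return TuningProfile(
        unit_id=m.unit_id, region=region, peak_bin=peak,
        peak_time_s=float(m.bin_centers_s[peak]),
        width_bins=width_bins, width_s=width_bins * m.bin_width_s,
        peak_significant=peak_sig, excluded=excluded,
        com_per_trial=com,
        com_mean_s=float(com.mean()) if len(com) else float("nan"),
        tie_note=tie_note)


# ---------------------------------------------------------------------------
# trial-history correlations
# ---------------------------------------------------------------------------

def com_vs_previous_iti(profiles: list[TuningProfile], session: Session,
                        lags: tuple = (1, 2, 3, 4), alpha: float = 0.05,
                        min_trials: int = 10):
    """Per-unit Pearson correlation of the per-trial center of mass with
    the ITI duration ``lag`` intervals back, a binomial test of the
    population proportion of significant units against 5%, and a multiple
    regression over all lags jointly."""
    itis = session.iti_intervals()
    dur = itis["duration_s"]

    per_unit = []
    for prof in profiles:
        com = prof.com_per_trial
        if len(com) < min_trials:
            continue
        rec = {"unit_id": prof.unit_id, "region": prof.region}
        X = {}
        for lag in lags:
            x = dur.reindex(com.index - lag).to_numpy()
            y = com.to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_trials or np.std(x[ok]) == 0 \
                    or np.std(y[ok]) == 0:
                rec[f"r_lag{lag}"] = np.nan
                rec[f"p_lag{lag}"] = np.nan
                rec[f"sig_lag{lag}"] = False
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rec[f"r_lag{lag}"] = float(r)
            rec[f"p_lag{lag}"] = float(p)
            rec[f"sig_lag{lag}"] = bool(p < alpha)
            X[lag] = x
        # joint model over all lags with complete cases
        if len(X) == len(lags):
            xmat = np.column_stack([X[lag] for lag in lags])
            y = com.to_numpy()
            ok = np.all(np.isfinite(xmat), axis=1) & np.isfinite(y)
            if ok.sum() >= min_trials and np.std(y[ok]) > 0:
                fit = sm.OLS(y[ok], sm.add_constant(xmat[ok])).fit()
                rec["regression_p"] = float(fit.f_pvalue)
                rec["regression_sig"] = bool(fit.f_pvalue < alpha)
        per_unit.append(rec)
    table = pd.DataFrame(per_unit)

    population = {}
    for lag in lags:
        col = table.get(f"sig_lag{lag}")
        n_sig = int(col.sum()) if col is not None else 0
        n = int(table[f"p_lag{lag}"].notna().sum()) if len(table) else 0
        population[lag] = {
            "n_units": n, "n_significant": n_sig,
            "proportion": n_sig / n if n else float("nan"),
            "binomial_p": float(stats.binomtest(
                n_sig, n, alpha, alternative="greater").pvalue) if n else
            float("nan"),
        }
    return table, population


def cr_change_vs_com(profiles: list[TuningProfile], cr: CRSeries):
    """Pooled Pearson correlation between the trial-to-trial change in CR
    and the center of mass of the intervening ITI, across all units."""
    df = cr.table.sort_values("trial").reset_index(drop=True)
    consec = df["trial"].diff() == 1
    delta = pd.Series(df["cr_value"].diff().to_numpy(),
                      index=df["trial"].to_numpy())[consec.to_numpy()]

    rows = []
    for prof in profiles:
        # the ITI preceding trial n is owned by trial n-1
        for owner, com in prof.com_per_trial.items():
            nxt = owner + 1
            if nxt in delta.index:
                rows.append({"unit_id": prof.unit_id, "region": prof.region,
                             "trial": nxt, "delta_cr": delta.loc[nxt],
                             "com_s": com})
    pooled = pd.DataFrame(rows)
    out = {"n": len(pooled)}
    if len(pooled) >= 3 and pooled["com_s"].std() > 0 \
            and pooled["delta_cr"].std() > 0:
        r, p = stats.pearsonr(pooled["delta_cr"], pooled["com_s"])
        out.update(r=float(r), p=float(p))
    else:
        out.update(r=float("nan"), p=float("nan"))
    for region, g in pooled.groupby("region"):
        if len(g) >= 3 and g["com_s"].std() > 0 and g["delta_cr"].std() > 0:
            r, p = stats.pearsonr(g["delta_cr"], g["com_s"])
            out[region] = {"r": float(r), "p": float(p), "n": len(g)}
    return out, pooled


# ---------------------------------------------------------------------------
# regional peak distributions
# ---------------------------------------------------------------------------

def _two_gaussians(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def fit_two_gaussians(centers: np.ndarray, density: np.ndarray):
    """Bounded least-squares fit of a two-Gaussian mixture to a
    density-normalized histogram; initialized at the two largest modes."""
    span = centers[-1] - centers[0]
    order = np.argsort(density)[::-1]
    mu0 = [centers[order[0]], centers[order[min(1, centers.size - 1)]]]
    p0 = [max(density.max(), 1e-6), mu0[0], span / 8,
          max(density.max() / 2, 1e-6), mu0[1], span / 8]
    bounds = ([0, centers[0] - span, span / 50] * 2,
              [np.inf, centers[-1] + span, span] * 2)
    try:
        popt, _ = curve_fit(_two_gaussians, centers, density, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError:
        return {"fit_ok": False}
    resid = density - _two_gaussians(centers, *popt)
    sse = float((resid ** 2).sum())
    tss = float(((density - density.mean()) ** 2).sum())
    return {"fit_ok": True, "params": popt.tolist(), "sse": sse,
            "r2": 1.0 - sse / tss if tss > 0 else float("nan")}


def regional_peak_distributions(profiles: list[TuningProfile],
                                mean_iti_s: float, n_hist_bins: int = 20,
                                n_permutations: int = 10_000, seed: int = 0):
    """Compare peak-time distributions between regions.

    Label-permutation test with the two-sample Kolmogorov-Smirnov distance
    as statistic, plus a two-Gaussian least-squares fit per region's
    density histogram and a width-vs-peak summary.
    """
    inc = [p for p in profiles if not p.excluded]
    by_region = {}
    for p in inc:
        by_region.setdefault(p.region, []).append(p.peak_time_s)
    regions = sorted(by_region)
    if len(regions) != 2 or any(len(v) < 10 for v in by_region.values()):
        raise ValueError("need >= 10 peak-bearing units in each of 2 regions")
    a = np.array(by_region[regions[0]])
    b = np.array(by_region[regions[1]])

    obs = stats.ks_2samp(a, b).statistic
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = stats.ks_2samp(perm[:a.size], perm[a.size:]).statistic
        if d >= obs:
            count += 1
    perm_p = (count + 1) / (n_permutations + 1)

    edges = np.linspace(0.0, mean_iti_s, n_hist_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {"regions": regions, "ks_statistic": float(obs),
           "permutation_p": float(perm_p), "histograms": {}, "fits": {}}
    for name, sample in zip(regions, (a, b)):
        density = np.histogram(sample, bins=edges, density=True)[0]
        out["histograms"][name] = {"centers": centers.tolist(),
                                   "density": density.tolist()}
        if np.unique(sample).size < 3:
            out["fits"][name] = {"fit_ok": False}
        else:
            out["fits"][name] = fit_two_gaussians(centers, density)

    width_peak = pd.DataFrame(
        [{"unit_id": p.unit_id, "region": p.region,
          "peak_time_s": p.peak_time_s, "width_s": p.width_s}
         for p in inc])
    wt, wp = stats.ttest_ind(
        width_peak.loc[width_peak.region == regions[0], "width_s"],
        width_peak.loc[width_peak.region == regions[1], "width_s"])
    out["width_t_test"] = {"t": float(wt), "p": float(wp)}
    return out, width_peak


def width_stability_across_blocks(session: Session, units, n_bins: int = 40,
                                  block_size: int = 5, n_shuffles: int = 100,
                                  seed: int = 0):
    """Tuning width recomputed in consecutive acquisition-trial blocks,
    with a one-way ANOVA across blocks (stability check)."""
    from .itimod import bin_iti_rates, shuffle_null
    acq = [t.index for t in session.trials_in_phase("acquisition")]
    blocks = [np.array(acq[i:i + block_size])
              for i in range(0, len(acq) - block_size + 1, block_size)]
    rng = np.random.default_rng(seed)
    widths = {b: [] for b in range(len(blocks))}
    for unit in units:
        for b, idx in enumerate(blocks):
            m = bin_iti_rates(session, unit, n_bins, trial_subset=idx)
            null = shuffle_null(m, n_shuffles=n_shuffles, seed=rng)
            prof = find_peak_and_width(m, null)
            if not prof.excluded:
                widths[b].append(prof.width_s)
    groups = [np.array(v) for v in widths.values() if len(v) >= 2]
    if len(groups) < 2:
        return {"testable": False}
    f, p = stats.f_oneway(*groups)
    return {"testable": True, "F": float(f), "p": float(p),
            "block_means": [float(np.mean(g)) for g in groups]}
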