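"""Pairwise amygdala–dACC synchrony along the ITI.

Cross-correlograms are computed in 3-s windows advanced in 1-s steps from
trial offset until 5 s before the mean ITI, pooling trials.  Amygdala
spikes are the reference: for every amygdala spike inside a window, dACC
spikes within ±750 ms are tallied into 20 ms lag bins (75 bins, zero-lag
bin centered on 0).  Only pairs whose ITI firing rates both exceed 1 Hz
are analyzed.

Significance demands excess counts against *two* shuffle nulls at once:

* **within-ITI** — dACC spike times redrawn uniformly inside each trial's
  ITI (kills all temporal structure, keeps per-trial rates), absorbing
  trial-by-trial rate covariation;
* **across-ITI** — dACC spikes moved to a permuted trial at the same
  within-ITI phase (kills trial pairing, keeps the average temporal
  profile), absorbing shared slow tuning.

A (window, lag) cell is significant when observed counts exceed the
(1−α) quantile of both nulls; a window needs a contiguous run of ≥2
significant lag bins; a pair is synchronized when significant windows
cover ≥15% of the ITI windows.  Significant pairs are clustered by the
along-ITI profile of their correlation density (PCA then k-means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .sessionio import Session, Unit

LAG_MAX_S = 0.75
LAG_BIN_S = 0.02
N_LAGS = 75                        # [-750, 750) ms, zero-lag bin centered
WINDOW_S = 3.0
WINDOW_STEP_S = 1.0
TAIL_GUARD_S = 5.0                 # windows stop 5 s before the mean ITI
RATE_GATE_HZ = 1.0

LAG_EDGES_S = -LAG_MAX_S + LAG_BIN_S * np.arange(N_LAGS + 1)
LAG_CENTERS_S = 0.5 * (LAG_EDGES_S[:-1] + LAG_EDGES_S[1:])


class GateError(ValueError):
    """A unit fails the 1 Hz ITI firing-rate gate."""


@dataclass
class CCWindowMap:
    pair_id: tuple
    window_starts_s: np.ndarray
    counts: np.ndarray             # (n_windows, N_LAGS)
    null_within: dict = field(default_factory=dict)
    null_across: dict = field(default_factory=dict)
    sig_mask: np.ndarray | None = None
    window_significant: np.ndarray | None = None
    pair_significant: bool | None = None


@dataclass
class CCClustering:
    pair_ids: list
    profiles: np.ndarray           # (n_pairs, n_windows), z-scored
    pc_scores: np.ndarray
    labels: np.ndarray
    cluster_profiles: np.ndarray   # (k, n_windows) mean member profile
    cluster_maps: np.ndarray       # (k, n_windows, N_LAGS)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# phase extraction and counting
# ---------------------------------------------------------------------------

def _iti_phases(session: Session, unit: Unit):
    """Per-ITI spike phases (seconds from trial offset) and durations."""
    itis = session.iti_intervals()
    phases, durs = [], []
    for _, row in itis.iterrows():
        sel = (unit.spike_times_s >= row.start_s) & \
              (unit.spike_times_s < row.start_s + row.duration_s)
        phases.append(unit.spike_times_s[sel] - row.start_s)
        durs.append(row.duration_s)
    return phases, np.array(durs)


def iti_mean_rate(session: Session, unit: Unit) -> float:
    phases, durs = _iti_phases(session, unit)
    total = sum(p.size for p in phases)
    return total / durs.sum() if durs.sum() > 0 else 0.0


def window_grid(mean_iti_s: float) -> np.ndarray:
    """3-s window start times at 1-s steps, ending 5 s before mean ITI."""
    last = mean_iti_s - TAIL_GUARD_S - WINDOW_S
    if last < 0:
        return np.array([])
    return np.arange(0.0, np.floor(last) + 0.5, WINDOW_STEP_S)


def _count_map(a_phases: list, d_phases: list, durs: np.ndarray,
               windows: np.ndarray) -> np.ndarray:
    """Pooled (window, lag) coincidence counts across trials.

    For each amygdala spike at phase p in a trial, windows with
    start <= p < start+3 that fit inside that trial's ITI receive the
    lag-binned counts of dACC spikes within ±750 ms.
    """
    n_w = windows.size
    counts = np.zeros((n_w, N_LAGS))
    if n_w == 0:
        return counts
    for a, d, dur in zip(a_phases, d_phases, durs):
        if a.size == 0 or d.size == 0:
            continue
        d = np.sort(d)
        lo = np.searchsorted(d, a - LAG_MAX_S, side="left")
        hi = np.searchsorted(d, a + LAG_MAX_S, side="left")
        n_pairs = hi - lo
        if n_pairs.sum() == 0:
            continue
        ai = np.repeat(np.arange(a.size), n_pairs)
        dj = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)])
        lags = d[dj] - a[ai]
        keep = (lags >= -LAG_MAX_S) & (lags < LAG_MAX_S)
        ai, lags = ai[keep], lags[keep]
        lag_bin = np.floor((lags + LAG_MAX_S) / LAG_BIN_S).astype(int)
        lag_bin = np.clip(lag_bin, 0, N_LAGS - 1)
        p = a[ai]
        w_max = min(n_w - 1, int(np.floor(dur - WINDOW_S)))  # window must fit
        w_hi = np.floor(p).astype(int)                       # last window <= p
        for shift in range(int(WINDOW_S)):
            w = w_hi - shift
            ok = (w >= 0) & (w <= w_max) & (p - w < WINDOW_S) & (p >= w)
            if ok.any():
                np.add.at(counts, (w[ok], lag_bin[ok]), 1)
    return counts


def sliding_crosscorr(session: Session, unit_amy: Unit,
                      unit_dacc: Unit) -> CCWindowMap:
    """Observed sliding-window cross-correlogram for one pair (amygdala
    spikes as reference)."""
    for u in (unit_amy, unit_dacc):
        rate = iti_mean_rate(session, u)
        if rate <= RATE_GATE_HZ:
            raise GateError(f"unit {u.unit_id} ITI rate {rate:.2f} Hz "
                            f"below the {RATE_GATE_HZ} Hz gate")
    a_ph, durs = _iti_phases(session, unit_amy)
    d_ph, _ = _iti_phases(session, unit_dacc)
    windows = window_grid(session.mean_iti_s)
    counts = _count_map(a_ph, d_ph, durs, windows)
    return CCWindowMap(pair_id=(unit_amy.unit_id, unit_dacc.unit_id),
                       window_starts_s=windows, counts=counts)


# ---------------------------------------------------------------------------
# shuffle nulls
# ---------------------------------------------------------------------------

def _summarize_null(stack: np.ndarray, quantiles=(0.95, 0.99)) -> dict:
    return {"mean": stack.mean(0), "sd": stack.std(0),
            "quantiles": {q: np.quantile(stack, q, axis=0)
                          for q in quantiles},
            "n_shuffles": stack.shape[0]}


def within_iti_null(session: Session, unit_amy: Unit, unit_dacc: Unit,
                    n_shuffles: int = 100, seed: int = 0) -> dict:
    """Null from redrawing dACC spike times uniformly within each ITI
    (per-ITI spike counts preserved)."""
    a_ph, durs = _iti_phases(session, unit_amy)
    d_ph, _ = _iti_phases(session, unit_dacc)
    windows = window_grid(session.mean_iti_s)
    rng = np.random.default_rng(seed)
    stack = np.empty((n_shuffles, windows.size, N_LAGS))
    for s in range(n_shuffles):
        shuffled = [np.sort(rng.uniform(0.0, dur, d.size))
                    for d, dur in zip(d_ph, durs)]
        stack[s] = _count_map(a_ph, shuffled, durs, windows)
    return _summarize_null(stack)


def across_iti_null(session: Session, unit_amy: Unit, unit_dacc: Unit,
                    n_shuffles: int = 100, seed: int = 0) -> dict:
    """Null from reassigning each trial's dACC spikes to a permuted trial
    at the same within-ITI phase; phases exceeding the recipient ITI wrap
    around its duration."""
    a_ph, durs = _iti_phases(session, unit_amy)
    d_ph, _ = _iti_phases(session, unit_dacc)
    windows = window_grid(session.mean_iti_s)
    rng = np.random.default_rng(seed)
    n_trials = len(d_ph)
    if n_trials < 2:
        raise ValueError("across-ITI shuffling is the identity for a "
                         "single ITI; the null is untestable")
    stack = np.empty((n_shuffles, windows.size, N_LAGS))
    for s in range(n_shuffles):
        perm = rng.permutation(n_trials)
        shuffled = [None] * n_trials
        for src, dst in enumerate(perm):
            shuffled[dst] = np.sort(np.mod(d_ph[src], durs[dst]))
        stack[s] = _count_map(a_ph, shuffled, durs, windows)
    return _summarize_null(stack)


# ---------------------------------------------------------------------------
# significance and clustering
# ---------------------------------------------------------------------------

def _runs_of_true(mask: np.ndarray) -> int:
    """Longest run of consecutive True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def classify_pair_significance(cc: CCWindowMap, alpha: float = 0.01,
                               persistence: float = 0.15,
                               min_run: int = 2) -> CCWindowMap:
    """Flag cells exceeding the (1−α) quantile of *both* nulls, windows
    with a ≥``min_run`` contiguous significant lag run, and the pair when
    significant windows cover ≥``persistence`` of all windows."""
    if not cc.null_within or not cc.null_across:
        raise ValueError("both nulls must be computed first")
    q = 1.0 - alpha
    if q not in cc.null_within["quantiles"] \
            or q not in cc.null_across["quantiles"]:
        raise ValueError(f"nulls lack the {q} quantile")
    qw = cc.null_within["quantiles"][q]
    qa = cc.null_across["quantiles"][q]
    if qw.shape != cc.counts.shape or qa.shape != cc.counts.shape:
        raise ValueError("null quantile grids do not match the CC map")
    sig = (cc.counts > qw) & (cc.counts > qa)
    win_sig = np.array([_runs_of_true(row) >= min_run for row in sig])
    cc.sig_mask = sig
    cc.window_significant = win_sig
    cc.pair_significant = bool(
        win_sig.sum() >= persistence * max(len(win_sig), 1)
        and len(win_sig) > 0)
    return cc


def compute_pair(session: Session, unit_amy: Unit, unit_dacc: Unit,
                 n_shuffles: int = 100, seed: int = 0, alpha: float = 0.01,
                 persistence: float = 0.15) -> CCWindowMap:
    """Full per-pair pipeline: observed map, both nulls, significance."""
    cc = sliding_crosscorr(session, unit_amy, unit_dacc)
    cc.null_within = within_iti_null(session, unit_amy, unit_dacc,
                                     n_shuffles, seed)
    cc.null_across = across_iti_null(session, unit_amy, unit_dacc,
                                     n_shuffles, seed + 1)
    return classify_pair_significance(cc, alpha=alpha,
                                      persistence=persistence)


def cluster_cc_shapes(maps: list[CCWindowMap], k: int = 3, seed: int = 0,
                      variance_retained: float = 0.90) -> CCClustering:
    """Cluster significant pairs by the along-ITI profile of their
    correlation density (fraction of significant lag bins per window),
    standardized per window position, reduced by PCA, grouped by k-means
    with 50 restarts.  Clusters are relabeled in order of profile peak
    time (early < diffuse < late on the canonical families)."""
    if len(maps) < k:
        raise ValueError(f"need at least k={k} significant pairs")
    # pairs pooled across sessions can have different window counts
    # (mean ITIs differ); profiles are resampled onto a common
    # normalized-ITI axis before clustering
    n_grid = min(m.sig_mask.shape[0] for m in maps)
    grid = np.linspace(0.0, 1.0, n_grid)

    def _resample(vec):
        x = np.linspace(0.0, 1.0, vec.size)
        return np.interp(grid, x, vec)

    profiles = np.stack([_resample(m.sig_mask.mean(axis=1)) for m in maps])
    # standardize each window position across pairs, so that both the
    # placement of correlation density along the ITI and its overall level
    # (the "widespread" family) remain discriminative
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0)
    degenerate = bool(np.all(sd == 0) or
                      np.allclose(profiles, profiles[0]))
    z = (profiles - mu) / np.where(sd > 0, sd, 1.0)

    n_comp = min(len(maps), z.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, variance_retained) + 1)
    scores = scores[:, :keep]

    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict(scores)

    # stable labels: order clusters by the peak time of the mean profile
    peaks = []
    for c in range(k):
        member = z[raw == c]
        peaks.append(np.argmax(member.mean(0)) if len(member) else np.inf)
    order = np.argsort(peaks, kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])

    cluster_profiles = np.stack([
        z[labels == c].mean(0) if np.any(labels == c)
        else np.full(z.shape[1], np.nan) for c in range(k)])
    counts = np.stack([
        np.column_stack([_resample(m.counts[:, l])
                         for l in range(N_LAGS)]) for m in maps])
    cluster_maps = np.stack([
        counts[labels == c].mean(0) if np.any(labels == c)
        else np.full(counts.shape[1:], np.nan) for c in range(k)])
    return CCClustering(pair_ids=[m.pair_id for m in maps], profiles=z,
                        pc_scores=scores, labels=labels,
                        cluster_profiles=cluster_profiles,
                        cluster_maps=cluster_maps, degenerate=degenerate)
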