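"""Firing-rate modulation during the inter-trial interval.

The central question: does a unit's firing rate carry reproducible temporal
structure over the dozens-of-seconds ITI?  The test statistic is the
across-trial mean firing rate in each of 6/12/20/40 equal bins spanning
``[0, mean ITI)`` from trial offset, compared bin-by-bin against a null
obtained by permuting, independently within every trial, the spike counts
among that trial's *valid* bins (bins that end before the trial's actual
next CS).  The within-trial permutation preserves each trial's spike count
exactly, so slow rate drift across the session cannot masquerade as
temporal tuning; because late bins are valid in fewer trials, the null band
widens toward the end of the ITI.

A bin is significantly modulated when its observed mean rate deviates from
the shuffle mean by more than 2 shuffle standard deviations; a unit's
modulation strength is the fraction of valid bins flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sessionio import Session, Unit

ALLOWED_BINNINGS = (6, 12, 20, 40)


@dataclass
class ITIMatrix:
    """Trials x bins firing rates aligned forward from trial offset.

    ``valid[t, k]`` is True when bin ``k`` ends no later than trial ``t``'s
    actual ITI duration (the next CS has not yet occurred), so only
    uncontaminated bins enter any statistic.  ``trial_index`` holds the
    index of the trial *preceding* each ITI (its owner).
    """

    unit_id: str
    n_bins: int
    rates: np.ndarray          # (n_iti, n_bins), spikes/s
    counts: np.ndarray         # (n_iti, n_bins), spike counts
    valid: np.ndarray          # (n_iti, n_bins) bool
    bin_edges_s: np.ndarray    # (n_bins + 1,)
    mean_iti_s: float
    trial_index: np.ndarray    # (n_iti,)

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    def mean_rate(self) -> np.ndarray:
        """Across-trial mean rate per bin, over valid trials only (NaN for
        bins valid in no trial)."""
        with np.errstate(invalid="ignore"):
            return np.where(self.valid, self.rates, 0.0).sum(0) / \
                self.valid.sum(0)


@dataclass
class ShuffleNull:
    n_shuffles: int
    mean: np.ndarray           # (n_bins,) null mean of across-trial mean rate
    sd: np.ndarray             # (n_bins,)
    percentiles: dict          # {q: (n_bins,) array}
    mode: str = "within_trial_bins"


@dataclass
class ModulationResult:
    unit_id: str
    n_bins: int
    z: np.ndarray
    significant: np.ndarray    # bool per bin
    direction: np.ndarray      # +1 / -1 / 0 per bin
    proportion_significant: float


@dataclass
class StageRMS:
    unit_id: str
    stages: list
    rms: dict                  # stage -> observed z-curve RMS
    null_rms: dict             # stage -> shuffle-null RMS samples
    omnibus_p: float           # across-stage modulation (shuffle test)
    posthoc: dict              # acq stage -> {p, increase} vs habituation
    acquisition_responsive: bool
    extinction: dict           # comparisons of extinction vs acq / habituation


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_iti_rates(session: Session, unit: Unit, n_bins: int,
                  trial_subset: np.ndarray | None = None) -> ITIMatrix:
    """Bin a unit's ITI spikes into ``n_bins`` equal bins over
    ``[0, mean ITI)`` from each trial's offset.

    ``trial_subset`` optionally restricts to ITIs owned by those trial
    indices (e.g. one learning stage).
    """
    if n_bins not in ALLOWED_BINNINGS:
        raise ValueError(f"n_bins must be one of {ALLOWED_BINNINGS}")
    if not session.trials or len(session.trials) < 2:
        raise ValueError("session needs at least 2 trials to define an ITI")

    itis = session.iti_intervals()
    if trial_subset is not None:
        itis = itis.loc[itis.index.intersection(np.asarray(trial_subset))]
    mean_iti = session.mean_iti_s
    edges = np.linspace(0.0, mean_iti, n_bins + 1)
    width = mean_iti / n_bins

    n = len(itis)
    counts = np.zeros((n, n_bins))
    valid = np.zeros((n, n_bins), dtype=bool)
    for row, (tidx, iti) in enumerate(itis.iterrows()):
        # half-open bins [k*w, (k+1)*w); a bin is valid iff it ends within
        # this trial's actual ITI (and hence within the mean ITI)
        valid[row] = edges[1:] <= iti.duration_s + 1e-9
        phases = unit.spike_times_s - iti.start_s
        sel = (phases >= 0) & (phases < min(mean_iti, iti.duration_s))
        counts[row] = np.histogram(phases[sel], bins=edges)[0]
        counts[row, ~valid[row]] = 0.0
    return ITIMatrix(unit_id=unit.unit_id, n_bins=n_bins, rates=counts / width,
                     counts=counts, valid=valid, bin_edges_s=edges,
                     mean_iti_s=mean_iti,
                     trial_index=itis.index.to_numpy())


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def shuffle_counts(m: ITIMatrix, n_shuffles: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_shuffles, n_trials, n_bins) rates after permuting each trial's
    counts among its valid bins (per-trial totals are conserved exactly)."""
    n_trials, n_bins = m.rates.shape
    out = np.zeros((n_shuffles, n_trials, n_bins))
    for t in range(n_trials):
        v = np.flatnonzero(m.valid[t])
        if v.size <= 1:
            out[:, t, v] = m.rates[t, v]     # shuffling is the identity
            continue
        # one random permutation per shuffle via argsort of uniforms
        perm = np.argsort(rng.random((n_shuffles, v.size)), axis=1)
        out[:, t, v] = m.rates[t, v][perm]
    return out


def _shuffled_bin_means(m: ITIMatrix, n_shuffles: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_shuffles, n_bins) across-trial mean rates of shuffled data."""
    sh = shuffle_counts(m, n_shuffles, rng)
    n_valid = m.valid.sum(0)
    with np.errstate(invalid="ignore"):
        return sh.sum(axis=1) / n_valid


def shuffle_null(m: ITIMatrix, n_shuffles: int = 100,
                 seed: int | np.random.Generator = 0,
                 percentiles: tuple = (2.5, 5.0, 95.0, 97.5)) -> ShuffleNull:
    """Within-trial permutation null for the across-trial mean rate."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sh = _shuffled_bin_means(m, n_shuffles, rng)
    return ShuffleNull(
        n_shuffles=n_shuffles,
        mean=np.nanmean(sh, axis=0),
        sd=np.nanstd(sh, axis=0),
        percentiles={q: np.nanpercentile(sh, q, axis=0) for q in percentiles})


def detect_modulation(m: ITIMatrix, null: ShuffleNull,
                      z_threshold: float = 2.0) -> ModulationResult:
    """Per-bin z of the observed mean rate against the shuffle null;
    significant where |z| exceeds the threshold."""
    obs = m.mean_rate()
    testable = (m.valid.sum(0) > 0) & (null.sd > 0)
    z = np.zeros(m.n_bins)
    z[testable] = (obs[testable] - null.mean[testable]) / null.sd[testable]
    sig = np.abs(z) > z_threshold
    sig &= testable
    direction = np.sign(z) * sig
    n_valid_bins = int((m.valid.sum(0) > 0).sum())
    prop = float(sig.sum() / n_valid_bins) if n_valid_bins else 0.0
    return ModulationResult(unit_id=m.unit_id, n_bins=m.n_bins, z=z,
                            significant=sig, direction=direction.astype(int),
                            proportion_significant=prop)


def modulation_prevalence(results: list[ModulationResult],
                          threshold: float = 0.20,
                          chance_alpha: float = 2 * stats.norm.sf(2.0)):
    """Survival curve of per-unit modulated fractions plus a binomial test
    of the fraction of units above ``threshold`` against chance.

    Chance for one unit is the binomial tail P(K >= ceil(threshold * B))
    with per-bin rate ``chance_alpha`` (Gaussian two-sided at |z|>2).
    """
    if not results:
        raise ValueError("need at least one ModulationResult")
    props = np.array([r.proportion_significant for r in results])
    grid = np.unique(np.concatenate([[0.0, threshold], props]))
    survival = np.array([(props >= x).mean() for x in grid])

    n_bins = results[0].n_bins
    k_min = int(np.ceil(threshold * n_bins))
    p_unit_chance = float(stats.binom.sf(k_min - 1, n_bins, chance_alpha))
    n_above = int((props >= threshold).sum())
    test = stats.binomtest(n_above, len(props), p_unit_chance,
                           alternative="greater")
    return {
        "grid": grid, "survival": survival,
        "fraction_above_threshold": n_above / len(props),
        "chance_fraction": p_unit_chance,
        "binomial_p": float(test.pvalue),
        "proportions": props,
    }


# ---------------------------------------------------------------------------
# CS-evoked response
# ---------------------------------------------------------------------------

def cs_evoked_test(session: Session, unit: Unit, window_s: float = 0.5,
                   phases: tuple = ("acquisition",), alpha: float = 0.05):
    """Paired t-test of pre-CS vs post-CS spike counts across trials."""
    trials = [t for t in session.trials if t.phase in phases]
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    span = session.span_s
    pre, post = [], []
    for tr in trials:
        if tr.cs_onset_s - window_s < 0 or tr.cs_onset_s + window_s > span:
            raise ValueError(f"CS window outside session span at trial "
                             f"{tr.index}")
        s = unit.spike_times_s
        pre.append(np.count_nonzero(
            (s >= tr.cs_onset_s - window_s) & (s < tr.cs_onset_s)))
        post.append(np.count_nonzero(
            (s >= tr.cs_onset_s) & (s < tr.cs_onset_s + window_s)))
    pre, post = np.array(pre), np.array(post)
    diff = post - pre
    if np.all(diff == diff[0]) and diff.std() == 0:
        return {"unit_id": unit.unit_id, "testable": False, "flagged": False,
                "t": np.nan, "p": np.nan,
                "mean_pre": pre.mean(), "mean_post": post.mean()}
    t, p = stats.ttest_rel(post, pre)
    return {"unit_id": unit.unit_id, "testable": True,
            "flagged": bool(p < alpha), "t": float(t), "p": float(p),
            "mean_pre": float(pre.mean()), "mean_post": float(post.mean())}


# ---------------------------------------------------------------------------
# learning stages
# ---------------------------------------------------------------------------

def _stage_trial_indices(session: Session) -> dict:
    hab = [t.index for t in session.trials_in_phase("habituation")]
    acq = [t.index for t in session.trials_in_phase("acquisition")]
    ext = [t.index for t in session.trials_in_phase("extinction")]
    for name, lst in (("habituation", hab), ("acquisition", acq),
                      ("extinction", ext)):
        if not lst:
            raise ValueError(f"session has no {name} trials")
    a3 = max(len(acq) // 3, 1)
    e2 = max(len(ext) // 2, 1)
    return {
        "habituation": np.array(hab),
        "acq_early": np.array(acq[:a3]),
        "acq_mid": np.array(acq[a3:2 * a3]),
        "acq_late": np.array(acq[2 * a3:]),
        "ext_early": np.array(ext[:e2]),
        "ext_late": np.array(ext[e2:]),
    }


def _stage_curve_rms(session: Session, unit: Unit, trial_idx: np.ndarray,
                     n_bins: int, n_shuffles: int,
                     rng: np.random.Generator):
    """RMS of the stage's across-trial mean z-curve, plus the null RMS
    samples from the stage's own shuffle ensemble.

    The mean ITI rate curve of the stage is standardized bin-by-bin by the
    within-trial shuffle null (which tracks any baseline drift), and its
    RMS over valid bins summarizes the stage's temporal structure; every
    shuffled dataset yields one null RMS on the same footing.
    """
    m = bin_iti_rates(session, unit, n_bins, trial_subset=trial_idx)
    sh = _shuffled_bin_means(m, n_shuffles, rng)        # (S, bins)
    with np.errstate(invalid="ignore"):
        null_mean = np.nanmean(sh, axis=0)
        null_sd = np.nanstd(sh, axis=0)
    obs = m.mean_rate()
    ok = (m.valid.sum(0) > 0) & (null_sd > 0) & np.isfinite(obs)
    if not ok.any():
        return 0.0, np.zeros(n_shuffles)
    z_obs = (obs[ok] - null_mean[ok]) / null_sd[ok]
    rms_obs = float(np.sqrt(np.mean(z_obs ** 2)))
    z_null = (sh[:, ok] - null_mean[ok]) / null_sd[ok]
    rms_null = np.sqrt(np.mean(z_null ** 2, axis=1))
    return rms_obs, rms_null


def _tail_p(observed: float, null_samples: np.ndarray) -> float:
    """One-sided permutation-style p-value with the +1 correction."""
    return float((1 + np.sum(null_samples >= observed))
                 / (1 + null_samples.size))


def stage_rms(session: Session, unit: Unit, n_bins: int = 40,
              n_shuffles: int = 100, seed: int = 0,
              alpha: float = 0.05) -> StageRMS:
    """Stage-wise modulation strength and the acquisition-responsive call.

    Each stage (habituation; early/mid/late acquisition; early/late
    extinction) gets an RMS of its shuffle-normalized mean ITI rate
    curve, with a null RMS distribution from the same shuffle ensemble.
    The omnibus test asks whether the RMS varies across the four learning
    stages more than it does across paired null datasets; if so, each
    acquisition sub-stage is compared against habituation.  A unit is
    acquisition responsive when the omnibus test is significant and at
    least one sub-stage shows a significant *increase*.  Extinction
    sub-stages are then compared against acquisition (decrease) and
    habituation (residual elevation).
    """
    rng = np.random.default_rng(seed)
    stages = _stage_trial_indices(session)
    rms, null_rms = {}, {}
    for name, idx in stages.items():
        rms[name], null_rms[name] = _stage_curve_rms(
            session, unit, idx, n_bins, n_shuffles, rng)

    learn_stages = ["habituation", "acq_early", "acq_mid", "acq_late"]
    obs_spread = float(np.var([rms[s] for s in learn_stages]))
    null_spread = np.var(np.stack([null_rms[s] for s in learn_stages]),
                         axis=0)
    omnibus_p = _tail_p(obs_spread, null_spread)

    posthoc = {}
    responsive = False
    if omnibus_p < alpha:
        for s in learn_stages[1:]:
            d_obs = rms[s] - rms["habituation"]
            d_null = null_rms[s] - null_rms["habituation"]
            p = _tail_p(d_obs, d_null)
            inc = bool(p < alpha)
            posthoc[s] = {"delta_rms": float(d_obs), "p": p, "increase": inc}
            responsive = responsive or inc

    acq_mean = float(np.mean([rms[s] for s in learn_stages[1:]]))
    acq_null = np.mean(np.stack([null_rms[s] for s in learn_stages[1:]]),
                       axis=0)
    ext_mean = float(np.mean([rms["ext_early"], rms["ext_late"]]))
    ext_null = np.mean(np.stack([null_rms["ext_early"],
                                 null_rms["ext_late"]]), axis=0)
    p_decrease = _tail_p(acq_mean - ext_mean, acq_null - ext_null)
    p_residual = _tail_p(ext_mean - rms["habituation"],
                         ext_null - null_rms["habituation"])
    extinction = {
        "vs_acquisition": {"delta_rms": acq_mean - ext_mean,
                           "p": p_decrease,
                           "decrease": bool(p_decrease < alpha)},
        "vs_habituation": {"delta_rms": ext_mean - rms["habituation"],
                           "p": p_residual},
    }
    return StageRMS(unit_id=unit.unit_id, stages=list(stages),
                    rms=rms, null_rms=null_rms, omnibus_p=omnibus_p,
                    posthoc=posthoc, acquisition_responsive=responsive,
                    extinction=extinction)


def compare_reinforced_unreinforced(session: Session, unit: Unit,
                                    n_bins: int = 40, n_shuffles: int = 100,
                                    seed: int = 0, alpha: float = 0.05):
    """ITI modulation after un-reinforced (catch) vs reinforced acquisition
    trials, and catch-following vs extinction."""
    acq = session.trials_in_phase("acquisition")
    catch = np.array([t.index for t in acq if not t.reinforced])
    reinf = np.array([t.index for t in acq if t.reinforced])
    if catch.size == 0:
        raise ValueError("session contains no catch (un-reinforced) trials")
    ext = np.array([t.index for t in session.trials_in_phase("extinction")])

    rng = np.random.default_rng(seed)
    # the z-curve RMS grows with the trial count for real structure, so
    # every class is subsampled to the size of the smallest one
    n_per_class = min(idx.size for idx in (catch, reinf, ext) if idx.size)
    out = {"unit_id": unit.unit_id, "n_trials_per_class": int(n_per_class)}
    curves, rms, null_rms = {}, {}, {}
    for name, idx in (("catch", catch), ("reinforced", reinf),
                      ("extinction", ext)):
        if idx.size == 0:
            continue
        if idx.size > n_per_class:
            idx = np.sort(rng.choice(idx, size=n_per_class, replace=False))
        m = bin_iti_rates(session, unit, n_bins, trial_subset=idx)
        curves[name] = m.mean_rate()
        rms[name], null_rms[name] = _stage_curve_rms(
            session, unit, idx, n_bins, n_shuffles, rng)
    out["curves"] = curves
    out["rms"] = {k: v for k, v in rms.items()}
    d_obs = abs(rms["catch"] - rms["reinforced"])
    d_null = np.abs(null_rms["catch"] - null_rms["reinforced"])
    p = _tail_p(d_obs, d_null)
    out["catch_vs_reinforced"] = {"delta_rms": float(d_obs), "p": p,
                                  "different": bool(p < alpha)}
    if "extinction" in rms:
        p = _tail_p(rms["catch"] - rms["extinction"],
                    null_rms["catch"] - null_rms["extinction"])
        out["catch_vs_extinction"] = {
            "delta_rms": float(rms["catch"] - rms["extinction"]),
            "p": p, "decrease": bool(p < alpha)}
    return out
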