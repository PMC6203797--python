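"""Synthetic conditioning sessions with known ground truth.

Emulates a tone (CS) / aversive-odor (US) conditioning day: 10 habituation,
30 acquisition and 20 extinction trials separated by long, variable
inter-trial intervals (ITI ~ truncated Normal, mean 38.7 s, s.d. 4.4 s,
lower bound 5 s), a nasal-pressure trace with a CS-evoked inhale whose
amplitude grows across acquisition (the conditioned response), and Poisson
spike trains drawn from several response families:

* **tuned** — firing rate carries a Gaussian bump at a fixed phase of the
  ITI (a temporal "time field"),
* **acquisition-gated** — the tuning amplitude follows the learning gate
  (absent in habituation, grows over acquisition, decays in extinction),
* **hazard** — rate ramps with the empirical hazard of the next CS,
* **CS-evoked** — a transient rate increase in the 350 ms after CS onset,
* **synchronized pairs** — excess near-coincident spikes confined to one
  epoch (early / mid / late third) of each ITI.

Every random draw flows from one ``numpy`` generator seeded from the
config, so identical seeds give byte-identical sessions.  The generator is
the ground truth against which every analysis stage is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sessionio import RespTrace, Session, Trial, Unit

EPOCHS = ("early", "mid", "late", "diffuse")

CS_EVOKED_WINDOW_S = 0.35  # CR / CS-response window after CS onset


class ParameterError(ValueError):
    """A generator parameter is out of its legal range."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic session generator.

    Defaults are the study conditions: trial counts, ITI/ISI statistics and
    population fractions as observed; tuning widths 5–8 s and a 2x gain
    over a 5 Hz baseline.
    """

    n_habituation: int = 10
    n_acquisition: int = 30
    n_extinction: int = 20
    catch_fraction: float = 0.0          # un-reinforced acquisition trials
    iti_mean_s: float = 38.7
    iti_sd_s: float = 4.4
    iti_min_s: float = 5.0               # truncation lower bound
    isi_mean_s: float = 1.6
    isi_sd_s: float = 0.24
    cs_duration_s: float = 0.25
    us_duration_s: float = 0.5
    resp_rate_hz: float = 0.4
    resp_sample_rate_hz: float = 50.0
    n_units: int = 0
    tuned_fraction: float = 0.35
    acquisition_gated_fraction: float = 0.23   # subset of the tuned units
    hazard_fraction: float = 0.0
    cs_evoked_fraction: float = 0.0
    baseline_rate_hz: float = 5.0
    tuning_gain: float = 2.0             # peak rate = baseline * (1 + gain)
    tuning_width_s: float = 6.5          # time-field extent midpoint (s)
    tuning_width_jitter_s: float = 1.5   # widths uniform in midpoint +- jitter
    cs_gain: float = 2.0                 # CS-evoked additive rate, x baseline
    peak_distribution: str = "uniform"   # or "regional" (two-Gaussian mixture)
    tuning_peak_s: float | None = None   # fix all tuned peaks at this time
    cr_gain: float = 1.0                 # asymptotic CR above habituation
    cr_tau_trials: float = 8.0           # learning time constant (trials)
    cr_iti_coef: float = 0.0             # CR gain per second of previous ITI
    com_iti_coef: float = 0.0            # peak shift per second of previous ITI
    n_sync_pairs: int = 0
    sync_epoch: str = "early"
    sync_excess_hz: float = 2.0          # coincidence event rate inside epoch
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_habituation", "n_acquisition", "n_extinction",
                     "n_units", "n_sync_pairs"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("catch_fraction", "tuned_fraction",
                     "acquisition_gated_fraction", "hazard_fraction",
                     "cs_evoked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must be in [0, 1]")
        for name in ("iti_mean_s", "iti_sd_s", "isi_mean_s", "resp_rate_hz",
                     "resp_sample_rate_hz", "baseline_rate_hz",
                     "tuning_width_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name}={v} must be finite and > 0")
        for name in ("tuning_gain", "cs_gain", "sync_excess_hz", "cr_gain"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name}={v} must be finite and >= 0")
        if self.sync_epoch not in EPOCHS:
            raise ParameterError(f"unknown sync_epoch {self.sync_epoch!r}")
        if self.peak_distribution not in ("uniform", "regional"):
            raise ParameterError(
                f"unknown peak_distribution {self.peak_distribution!r}")
        if not self.iti_mean_s > self.iti_min_s:
            raise ParameterError("iti_mean_s must exceed iti_min_s")
        if self.tuning_peak_s is not None and not \
                0.0 <= self.tuning_peak_s < self.iti_mean_s:
            raise ParameterError("tuning_peak_s must lie in [0, iti_mean_s)")

    @property
    def n_trials(self) -> int:
        return self.n_habituation + self.n_acquisition + self.n_extinction


@dataclass
class UnitTruth:
    unit_id: str
    region: str
    tuned: bool = False
    peak_time_s: float | None = None
    width_s: float | None = None
    acquisition_gated: bool = False
    hazard: bool = False
    cs_evoked: bool = False


@dataclass
class PairTruth:
    unit_a: str
    unit_b: str
    synchronized: bool
    epoch: str | None = None


@dataclass
class GroundTruth:
    units: list[UnitTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)
    iti_durations_s: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def draw_itis(config: GeneratorConfig, n: int,
              rng: np.random.Generator) -> np.ndarray:
    """ITI durations: Normal(mean, sd) truncated below at ``iti_min_s``.

    Rejection sampling; at the default parameters the truncation point is
    ~7.7 s.d. below the mean, so the shift it induces is negligible.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.iti_mean_s, config.iti_sd_s, n - filled)
        keep = draw[draw > config.iti_min_s]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def _learning_gate(config: GeneratorConfig) -> np.ndarray:
    """Per-trial gate in [0, 1]: 0 in habituation, saturating-exponential
    rise over acquisition, linear decay over extinction."""
    g = np.zeros(config.n_trials)
    a0 = config.n_habituation
    e0 = a0 + config.n_acquisition
    j = np.arange(config.n_acquisition)
    g[a0:e0] = 1.0 - np.exp(-(j + 1) / config.cr_tau_trials)
    g_end = g[e0 - 1] if config.n_acquisition else 0.0
    k = np.arange(config.n_extinction)
    g[e0:] = g_end * np.maximum(0.0, 1.0 - (k + 1) / max(config.n_extinction, 1))
    return g


def _poisson_times(rate_hz: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * max(t1 - t0, 0.0))
    return np.sort(rng.uniform(t0, t1, n))


# ---------------------------------------------------------------------------
# trial / respiration scaffolding
# ---------------------------------------------------------------------------

def _build_trials(config: GeneratorConfig, rng: np.random.Generator
                  ) -> tuple[list[Trial], np.ndarray]:
    n = config.n_trials
    itis = draw_itis(config, n, rng)
    isis = np.maximum(rng.normal(config.isi_mean_s, config.isi_sd_s, n),
                      config.cs_duration_s + 0.05)

    # un-reinforced (catch) acquisition trials
    a0 = config.n_habituation
    e0 = a0 + config.n_acquisition
    catch = np.zeros(n, dtype=bool)
    n_catch = int(round(config.catch_fraction * config.n_acquisition))
    if n_catch:
        catch_idx = rng.choice(np.arange(a0, e0), size=n_catch, replace=False)
        catch[catch_idx] = True

    trials: list[Trial] = []
    t = 0.0
    for i in range(n):
        cs_on = t + itis[i]
        cs_off = cs_on + config.cs_duration_s
        if i < a0:
            phase, valence, reinforced = "habituation", "none", False
        elif i < e0:
            phase, valence, reinforced = "acquisition", "aversive", not catch[i]
        else:
            phase, valence, reinforced = "extinction", "aversive", False
        if reinforced:
            us_on = cs_on + isis[i]
            us_off = us_on + config.us_duration_s
            offset = us_off
        else:
            us_on = us_off = None
            offset = cs_off
        trials.append(Trial(
            index=i, phase=phase, cs_onset_s=cs_on, cs_offset_s=cs_off,
            us_onset_s=us_on, us_offset_s=us_off, reinforced=reinforced,
            valence=valence, trial_offset_s=offset,
            iti_prev_s=itis[i] if i > 0 else None))
        t = offset
    return trials, itis


def _raised_cosine_breath(period_s: float, amp: float, sr: float) -> np.ndarray:
    """One breath: positive raised-cosine inhale lobe followed by a smaller
    negative exhale lobe; each lobe spans 40% of the cycle."""
    n_lobe = max(int(round(0.4 * period_s * sr)), 2)
    lobe = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n_lobe) / n_lobe))
    return np.concatenate([amp * lobe, -0.3 * amp * lobe])


def _build_respiration(config: GeneratorConfig, trials: list[Trial],
                       gate: np.ndarray, rng: np.random.Generator
                       ) -> RespTrace:
    sr = config.resp_sample_rate_hz
    span = (trials[-1].trial_offset_s + 15.0) if trials else 60.0
    samples = np.zeros(int(np.ceil(span * sr)) + 1)
    period = 1.0 / config.resp_rate_hz

    cs_onsets = [tr.cs_onset_s for tr in trials]
    cr_amps = []
    for tr in trials:
        amp = 1.0 + config.cr_gain * gate[tr.index]
        if config.cr_iti_coef and tr.iti_prev_s is not None:
            amp *= max(0.1, 1.0 + config.cr_iti_coef *
                       (tr.iti_prev_s - config.iti_mean_s) * gate[tr.index])
        cr_amps.append(amp)

    def add_breath(onset: float, amp: float) -> None:
        wave = _raised_cosine_breath(period, amp, sr)
        i0 = int(round(onset * sr))
        i1 = min(i0 + wave.size, samples.size)
        if i1 > i0 >= 0:
            samples[i0:i1] += wave[:i1 - i0]

    t = 0.0
    next_cs = 0
    while t < span:
        jitter = 1.0 + 0.05 * rng.standard_normal()
        step = period * max(jitter, 0.5)
        if next_cs < len(cs_onsets) and t + step > cs_onsets[next_cs]:
            # an inhale is aligned to the CS (emulating the online trigger)
            add_breath(cs_onsets[next_cs], cr_amps[next_cs])
            t = cs_onsets[next_cs] + period
            next_cs += 1
        else:
            add_breath(t, 1.0 + 0.05 * rng.standard_normal())
            t += step
    return RespTrace(sr, samples)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _iti_table(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start, duration, owning-trial-index) for each ITI; the ITI after
    trial k runs from k's offset to trial k+1's CS onset."""
    starts = np.array([tr.trial_offset_s for tr in trials[:-1]])
    durs = np.array([trials[k + 1].cs_onset_s - trials[k].trial_offset_s
                     for k in range(len(trials) - 1)])
    owners = np.arange(len(trials) - 1)
    return starts, durs, owners


def _empirical_cdf_factory(durations: np.ndarray):
    srt = np.sort(durations)

    def cdf(t):
        return np.searchsorted(srt, t, side="right") / srt.size
    return cdf


def _generate_spike_train(config: GeneratorConfig, truth: UnitTruth,
                          trials: list[Trial], gate: np.ndarray,
                          span: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson train by thinning a homogeneous candidate
    process at the unit's maximal rate."""
    base = config.baseline_rate_hz
    starts, durs, owners = _iti_table(trials)
    cdf = _empirical_cdf_factory(durs) if truth.hazard else None

    # per-ITI tuning peak (optionally shifted by the previous ITI duration).
    # width_s is the total extent of the time field; the Gaussian rate
    # profile uses sigma = width/5, so +-2.5 sigma spans the stated width.
    sigma = truth.width_s / 5.0 if truth.tuned else None
    peaks = None
    if truth.tuned:
        peaks = np.full(durs.size, truth.peak_time_s)
        if config.com_iti_coef:
            prev = np.concatenate([[config.iti_mean_s], durs[:-1]])
            peaks = np.clip(peaks + config.com_iti_coef *
                            (prev - config.iti_mean_s), 0.5, None)

    # amplitude gate per ITI (gate of the owning trial for gated units)
    amp = np.ones(durs.size)
    if truth.acquisition_gated:
        amp = gate[owners]

    rate_max = base * (1.0 + config.tuning_gain) \
        + (base * config.cs_gain if truth.cs_evoked else 0.0)
    cand = _poisson_times(rate_max, 0.0, span, rng)
    if cand.size == 0:
        return cand

    rate = np.full(cand.size, base)
    idx = np.searchsorted(starts, cand, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(cand.size, dtype=bool)
    inside[ok] = cand[ok] < starts[idx[ok]] + durs[idx[ok]]
    if inside.any():
        u = cand[inside] - starts[idx[inside]]
        factor = np.ones(u.size)
        if truth.tuned:
            p = peaks[idx[inside]]
            a = amp[idx[inside]]
            factor += config.tuning_gain * a * np.exp(
                -0.5 * ((u - p) / sigma) ** 2)
        if truth.hazard:
            factor += config.tuning_gain * cdf(u)
        rate[inside] = base * factor
    if truth.cs_evoked:
        cs = np.array([tr.cs_onset_s for tr in trials])
        j = np.searchsorted(cs, cand, side="right") - 1
        in_cs = (j >= 0) & (cand - cs[np.clip(j, 0, None)] < CS_EVOKED_WINDOW_S)
        rate[in_cs] += base * config.cs_gain

    keep = rng.uniform(0.0, rate_max, cand.size) < rate
    return cand[keep]


def _draw_peak(config: GeneratorConfig, region: str,
               rng: np.random.Generator) -> float:
    """Peak-time distribution: uniform tiling of the ITI, or a two-Gaussian
    regional mixture (both regions early; amygdala adds mid-ITI peaks,
    dACC adds late ones)."""
    m = config.iti_mean_s
    if config.peak_distribution == "uniform":
        return float(rng.uniform(0.0, m))
    if region == "amygdala":
        mus, sds = (0.13 * m, 0.5 * m), (0.08 * m, 0.12 * m)
    else:
        mus, sds = (0.13 * m, 0.8 * m), (0.08 * m, 0.12 * m)
    k = rng.integers(2)
    return float(np.clip(rng.normal(mus[k], sds[k]), 0.5, m - 0.5))


def _assign_truths(config: GeneratorConfig,
                   rng: np.random.Generator) -> list[UnitTruth]:
    n = config.n_units
    truths = [UnitTruth(unit_id=f"u{i:04d}",
                        region="amygdala" if i % 2 == 0 else "dACC")
              for i in range(n)]
    order = rng.permutation(n)
    n_tuned = int(round(config.tuned_fraction * n))
    n_gated = min(int(round(config.acquisition_gated_fraction * n)), n_tuned)
    n_hazard = int(round(config.hazard_fraction * n))
    for i in order[:n_tuned]:
        t = truths[i]
        t.tuned = True
        t.peak_time_s = (config.tuning_peak_s if config.tuning_peak_s
                         is not None else _draw_peak(config, t.region, rng))
        t.width_s = float(rng.uniform(
            config.tuning_width_s - config.tuning_width_jitter_s,
            config.tuning_width_s + config.tuning_width_jitter_s))
    for i in order[:n_gated]:
        truths[i].acquisition_gated = True
    # hazard units drawn from the non-tuned remainder
    pool = order[n_tuned:]
    for i in pool[:n_hazard]:
        truths[i].hazard = True
    n_cs = int(round(config.cs_evoked_fraction * n))
    for i in rng.permutation(n)[:n_cs]:
        truths[i].cs_evoked = True
    return truths


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_session(config: GeneratorConfig
                     ) -> tuple[Session, GroundTruth]:
    """Generate one full synthetic conditioning session plus its ground
    truth.  Identical configs (including seed) give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    trials, _ = _build_trials(config, rng)
    gate = _learning_gate(config)
    resp = _build_respiration(config, trials, gate, rng)
    span = resp.duration_s

    truth = GroundTruth(
        iti_durations_s=[float(tr.iti_prev_s) for tr in trials
                         if tr.iti_prev_s is not None])

    units: list[Unit] = []
    for ut in _assign_truths(config, rng):
        spikes = _generate_spike_train(config, ut, trials, gate, span, rng)
        units.append(Unit(ut.unit_id, ut.region, spikes))
        truth.units.append(ut)

    # optional synchronized amygdala-dACC pairs appended after the base
    # population, so their unit ids never collide
    for p in range(config.n_sync_pairs):
        ua, ub, pt = _make_sync_pair(
            config, trials, span, config.sync_epoch,
            config.sync_excess_hz, rng, tag=f"sp{p:02d}")
        units.extend([ua, ub])
        truth.units.append(UnitTruth(ua.unit_id, ua.region))
        truth.units.append(UnitTruth(ub.unit_id, ub.region))
        truth.pairs.append(pt)

    itis = [tr.iti_prev_s for tr in trials if tr.iti_prev_s is not None]
    session = Session(
        trials=trials, units=units, resp=resp,
        mean_iti_s=float(np.mean(itis)) if itis else config.iti_mean_s,
        metadata={"seed": config.seed, "generator": asdict(config),
                  "format": "iticoder-synthetic"})
    session.validate()
    return session, truth


def generate_null_unit(config: GeneratorConfig, rate_hz: float,
                       duration_s: float | None = None,
                       unit_id: str = "null", region: str = "amygdala",
                       rng: np.random.Generator | None = None) -> Unit:
    """Homogeneous Poisson unit with no structure of any kind — the
    negative control for every detector."""
    if not (np.isfinite(rate_hz) and rate_hz > 0):
        raise ParameterError(f"rate_hz={rate_hz} must be finite and > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if duration_s is None:
        duration_s = config.n_trials * (config.iti_mean_s + 3.0)
    return Unit(unit_id, region, _poisson_times(rate_hz, 0.0, duration_s, rng))


def _epoch_bounds(epoch: str, duration: float) -> tuple[float, float]:
    third = duration / 3.0
    return {"early": (0.0, third), "mid": (third, 2 * third),
            "late": (2 * third, duration), "diffuse": (0.0, duration)}[epoch]


def _make_sync_pair(config, trials, span, epoch, excess_hz, rng, tag):
    base = config.baseline_rate_hz
    a = _poisson_times(base, 0.0, span, rng)
    b = _poisson_times(base, 0.0, span, rng)
    starts, durs, _ = _iti_table(trials)
    extra_a, extra_b = [], []
    for s, d in zip(starts, durs):
        lo, hi = _epoch_bounds(epoch, d)
        ev = _poisson_times(excess_hz, s + lo, s + hi, rng)
        extra_a.append(ev)
        extra_b.append(ev + rng.uniform(-0.02, 0.02, ev.size))
    a = np.unique(np.concatenate([a] + extra_a))
    b = np.unique(np.concatenate([b] + extra_b))
    ua = Unit(f"{tag}a", "amygdala", a)
    ub = Unit(f"{tag}b", "dACC", b)
    return ua, ub, PairTruth(ua.unit_id, ub.unit_id, True, epoch)


def generate_synchronous_pair(config: GeneratorConfig, epoch: str,
                              excess_coincidence_hz: float,
                              trials: list[Trial] | None = None,
                              rng: np.random.Generator | None = None
                              ) -> tuple[Unit, Unit, GroundTruth]:
    """Two Poisson trains sharing injected near-coincident spikes
    (|lag| <= 20 ms) confined to one epoch of every ITI."""
    if epoch not in EPOCHS:
        raise ParameterError(f"unknown epoch {epoch!r}")
    if not (np.isfinite(excess_coincidence_hz) and excess_coincidence_hz >= 0):
        raise ParameterError("excess_coincidence_hz must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if trials is None:
        trials, _ = _build_trials(config, rng)
    span = trials[-1].trial_offset_s + 15.0
    ua, ub, pt = _make_sync_pair(config, trials, span, epoch,
                                 excess_coincidence_hz, rng, tag="pair")
    gt = GroundTruth(pairs=[pt])
    gt.units = [UnitTruth(ua.unit_id, ua.region),
                UnitTruth(ub.unit_id, ub.region)]
    return ua, ub, gt
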