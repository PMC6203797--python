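"""Session data model, on-disk format, and validation.

A *session* is one day of Pavlovian conditioning: a time-ordered list of
trials (habituation, acquisition, extinction), a set of single units with
spike times, and a sampled nasal-pressure (respiration) trace.  All
timestamps are seconds from session start; all binning throughout the
package uses half-open intervals ``[start, end)``.

The inter-trial interval (ITI) preceding trial *n* runs from the offset of
trial *n − 1* (US offset if reinforced, else CS offset) to the CS onset of
trial *n*.  Neural analyses align forward from trial offset; behavioral ITI
analyses align backward to the next CS — both views of the same interval.

On disk a session is a directory of plain-text files::

    manifest.json     metadata, format version, mean ITI
    trials.csv        one row per trial
    spikes.csv        long format: unit_id, region, spike_time_s
    respiration.csv   time_s, pressure
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"

PHASES = ("habituation", "acquisition", "extinction")
REGIONS = ("amygdala", "dACC")
VALENCES = ("aversive", "appetitive", "none")

#: float formatting used for all CSV output; 17 significant digits
#: round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"


class SessionError(Exception):
    """Base class for session I/O and validation errors."""


class ValidationError(SessionError):
    """An invariant violation; ``field`` names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(SessionError):
    """A file is missing or its columns do not match the documented schema."""


class ConsistencyError(SessionError):
    """Manifest metadata disagrees with the recomputed value."""


@dataclass
class Trial:
    index: int
    phase: str
    cs_onset_s: float
    cs_offset_s: float
    us_onset_s: float | None
    us_offset_s: float | None
    reinforced: bool
    valence: str
    trial_offset_s: float
    iti_prev_s: float | None

    def validate(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError("phase", f"unknown phase {self.phase!r}")
        if self.valence not in VALENCES:
            raise ValidationError("valence", f"unknown valence {self.valence!r}")
        if not self.cs_onset_s < self.cs_offset_s:
            raise ValidationError(
                "cs_onset_s", f"cs_onset_s ({self.cs_onset_s}) must precede "
                f"cs_offset_s ({self.cs_offset_s}) in trial {self.index}")
        if self.reinforced:
            if self.us_onset_s is None or self.us_offset_s is None:
                raise ValidationError(
                    "us_onset_s", f"reinforced trial {self.index} lacks US times")
            if self.us_onset_s < self.cs_offset_s:
                raise ValidationError(
                    "us_onset_s", f"US precedes CS offset in trial {self.index}")
            if not self.us_onset_s < self.us_offset_s:
                raise ValidationError(
                    "us_offset_s", f"US interval empty in trial {self.index}")
        if self.iti_prev_s is not None and not self.iti_prev_s > 0:
            raise ValidationError(
                "iti_prev_s", f"non-positive ITI in trial {self.index}")


@dataclass
class Unit:
    unit_id: str
    region: str
    spike_times_s: np.ndarray

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                "region", f"unit {self.unit_id}: unknown region {self.region!r}")
        t = self.spike_times_s
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                "spike_times_s",
                f"unit {self.unit_id}: spike times not strictly increasing")


@dataclass
class RespTrace:
    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def validate(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz", "must be positive")

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open interval ``[t0, t1)``."""
        i0 = int(math.ceil(t0 * self.sample_rate_hz - 1e-9))
        i1 = int(math.ceil(t1 * self.sample_rate_hz - 1e-9))
        return self.samples[max(i0, 0):max(i1, 0)]


@dataclass
class Session:
    trials: list[Trial]
    units: list[Unit]
    resp: RespTrace
    mean_iti_s: float
    metadata: dict = field(default_factory=dict)

    # ---- derived views -------------------------------------------------

    def trials_in_phase(self, phase: str) -> list[Trial]:
        return [t for t in self.trials if t.phase == phase]

    def iti_intervals(self) -> pd.DataFrame:
        """One row per ITI, indexed by the trial that *precedes* it.

        Columns: ``start_s`` (preceding trial offset), ``duration_s``
        (to the next CS onset), ``phase`` (phase of the preceding trial),
        ``next_trial`` (index of the following trial).
        """
        rows = []
        for prev, nxt in zip(self.trials[:-1], self.trials[1:]):
            rows.append({
                "trial": prev.index,
                "start_s": prev.trial_offset_s,
                "duration_s": nxt.cs_onset_s - prev.trial_offset_s,
                "phase": prev.phase,
                "next_trial": nxt.index,
            })
        return pd.DataFrame(rows).set_index("trial")

    @property
    def span_s(self) -> float:
        return max(self.resp.duration_s, self.trials[-1].trial_offset_s + 1.0
                   if self.trials else 0.0)

    def compute_mean_iti(self) -> float:
        itis = [t.iti_prev_s for t in self.trials if t.iti_prev_s is not None]
        return float(np.mean(itis)) if itis else float("nan")

    def validate(self) -> None:
        last = -math.inf
        for tr in self.trials:
            tr.validate()
            if tr.cs_onset_s <= last:
                raise ValidationError(
                    "cs_onset_s", f"trials not strictly time-ordered at {tr.index}")
            last = tr.cs_onset_s
        for u in self.units:
            u.validate()
        self.resp.validate()
        if any(t.iti_prev_s is not None for t in self.trials):
            recomputed = self.compute_mean_iti()
            if not math.isclose(recomputed, self.mean_iti_s,
                                rel_tol=0.0, abs_tol=1e-9):
                raise ValidationError(
                    "mean_iti_s",
                    f"stored {self.mean_iti_s} != recomputed {recomputed}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _trial_frame(trials: list[Trial]) -> pd.DataFrame:
    return pd.DataFrame([{
        "index": t.index, "phase": t.phase,
        "cs_onset_s": t.cs_onset_s, "cs_offset_s": t.cs_offset_s,
        "us_onset_s": t.us_onset_s, "us_offset_s": t.us_offset_s,
        "reinforced": t.reinforced, "valence": t.valence,
        "trial_offset_s": t.trial_offset_s, "iti_prev_s": t.iti_prev_s,
    } for t in trials])


def write_session(session: Session, path: str | Path) -> None:
    """Write a validated session to ``path`` (created if needed)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format_version": FORMAT_VERSION,
        "mean_iti_s": session.mean_iti_s,
        "n_trials": len(session.trials),
        "n_units": len(session.units),
        "resp_sample_rate_hz": session.resp.sample_rate_hz,
        "metadata": session.metadata,
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    _trial_frame(session.trials).to_csv(
        path / "trials.csv", index=False, float_format=FLOAT_FMT)

    spikes = pd.DataFrame(
        [(u.unit_id, u.region, t) for u in session.units
         for t in u.spike_times_s],
        columns=["unit_id", "region", "spike_time_s"])
    spikes.to_csv(path / "spikes.csv", index=False, float_format=FLOAT_FMT)

    resp = pd.DataFrame({"time_s": session.resp.times_s,
                         "pressure": session.resp.samples})
    resp.to_csv(path / "respiration.csv", index=False, float_format=FLOAT_FMT)


def _require(path: Path) -> Path:
    if not path.exists():
        raise SchemaError(f"missing file: {path.name}")
    return path


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    manifest = json.loads(_require(path / "manifest.json").read_text())

    tdf = pd.read_csv(_require(path / "trials.csv"))
    expected = {"index", "phase", "cs_onset_s", "cs_offset_s", "us_onset_s",
                "us_offset_s", "reinforced", "valence", "trial_offset_s",
                "iti_prev_s"}
    if set(tdf.columns) != expected:
        raise SchemaError(f"trials.csv columns {sorted(tdf.columns)} do not "
                          f"match schema")
    trials = [
        Trial(index=int(r["index"]), phase=str(r["phase"]),
              cs_onset_s=float(r["cs_onset_s"]),
              cs_offset_s=float(r["cs_offset_s"]),
              us_onset_s=None if pd.isna(r["us_onset_s"])
              else float(r["us_onset_s"]),
              us_offset_s=None if pd.isna(r["us_offset_s"])
              else float(r["us_offset_s"]),
              reinforced=bool(r["reinforced"]), valence=str(r["valence"]),
              trial_offset_s=float(r["trial_offset_s"]),
              iti_prev_s=None if pd.isna(r["iti_prev_s"])
              else float(r["iti_prev_s"]))
        for r in tdf.to_dict("records")]

    sdf = pd.read_csv(_require(path / "spikes.csv"))
    if list(sdf.columns) != ["unit_id", "region", "spike_time_s"]:
        raise SchemaError("spikes.csv columns do not match schema")
    units = []
    if len(sdf):
        for uid, g in sdf.groupby("unit_id", sort=False):
            t = g["spike_time_s"].to_numpy()
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    "spike_times_s", f"unit {uid}: spike times out of order")
            units.append(Unit(str(uid), str(g["region"].iloc[0]), t))

    rdf = pd.read_csv(_require(path / "respiration.csv"))
    if list(rdf.columns) != ["time_s", "pressure"]:
        raise SchemaError("respiration.csv columns do not match schema")
    resp = RespTrace(float(manifest["resp_sample_rate_hz"]),
                     rdf["pressure"].to_numpy())

    session = Session(trials=trials, units=units, resp=resp,
                      mean_iti_s=float(manifest["mean_iti_s"]),
                      metadata=manifest.get("metadata", {}))
    if any(t.iti_prev_s is not None for t in trials):
        recomputed = session.compute_mean_iti()
        if not math.isclose(recomputed, session.mean_iti_s,
                            rel_tol=0.0, abs_tol=1e-9):
            raise ConsistencyError(
                f"manifest mean_iti_s {session.mean_iti_s} disagrees with "
                f"trials.csv ({recomputed})")
    session.validate()
    return session
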