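import numpy as np
import pytest

from iticoder import GeneratorConfig, generate_session
from iticoder.sessionio import RespTrace, Session, Trial, Unit


@pytest.fixture(scope="session")
def default_session():
    """One full synthetic session with a mix of unit families."""
    cfg = GeneratorConfig(n_units=12, tuned_fraction=0.5,
                          acquisition_gated_fraction=0.25,
                          hazard_fraction=0.25, cs_evoked_fraction=0.25,
                          seed=7)
    return generate_session(cfg)


@pytest.fixture
def make_session():
    """Factory for hand-built sessions with exactly specified ITIs.

    ``itis[k]`` is the interval between trial k's offset and trial k+1's
    CS onset.  Trials are un-reinforced tone-only events (habituation by
    default) so trial offset = CS offset.
    """

    def _make(itis, units=None, phases=None, cs_dur=0.25,
              resp_rate_hz=10.0):
        n = len(itis) + 1
        phases = phases or ["habituation"] * n
        trials = []
        t = 5.0
        for k in range(n):
            trials.append(Trial(
                index=k, phase=phases[k], cs_onset_s=t, cs_offset_s=t + cs_dur,
                us_onset_s=None, us_offset_s=None, reinforced=False,
                valence="none", trial_offset_s=t + cs_dur,
                iti_prev_s=None if k == 0 else itis[k - 1]))
            if k < len(itis):
                t = t + cs_dur + itis[k]
        span = trials[-1].trial_offset_s + 10.0
        resp = RespTrace(resp_rate_hz,
                         np.zeros(int(span * resp_rate_hz) + 1))
        units = units or []
        itis_arr = [tr.iti_prev_s for tr in trials if tr.iti_prev_s is not None]
        sess = Session(trials=trials, units=list(units), resp=resp,
                       mean_iti_s=float(np.mean(itis_arr)))
        sess.validate()
        return sess

    return _make


@pytest.fixture
def make_unit():
    def _make(spikes, unit_id="u", region="amygdala"):
        return Unit(unit_id, region, np.asarray(spikes, dtype=float))

    return _make
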