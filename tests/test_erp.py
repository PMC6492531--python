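"""Single-trial ERP detection, co-occurrence pairing, behavior correlation."""

import numpy as np
import pandas as pd
import pytest

from painlfp import erp, synth
from painlfp.erp import (
    ErpError,
    detect_erp,
    detect_session_erps,
    erp_cooccurrence,
    latency_behavior_correlation,
)
from painlfp.session import EpisodeWindow, RecordingSession, make_event_table

FS = 1000.0


def one_event_session(erp_amp=None, seed=0, noise_sd=10.0, erp_time=0.5):
    """12 s single-region session, optional template at onset + erp_time."""
    spec = synth.LfpGenSpec(duration=12.0, noise_sd=noise_sd, background_sd=10.0,
                            theta_amp=15.0, gamma_base_amp=8.0,
                            erp_jitter_sd=0.0, seed=seed)
    ev = None
    if erp_amp is not None:
        ev = pd.DataFrame([{"event_id": "e0", "onset_s": 6.0 + erp_time,
                            "erp_amp": erp_amp}])
    lfp, _ = synth.generate_lfp(spec, ev)
    events = make_event_table([{"event_id": "e0", "kind": "stimulus", "onset_s": 6.0}])
    return RecordingSession({"ACC": lfp}, spec.fs, [], events)


class TestDetectErp:
    def test_injected_template_recovered(self):
        sess = one_event_session(erp_amp=200.0, seed=1)
        hit = detect_erp(sess, EpisodeWindow("e0", -5.0, 5.0), "ACC", search=(0, 5))
        assert hit is not None and hit.accepted
        assert abs(hit.latency - 0.5) <= 0.02

    def test_noise_only_rarely_accepted(self):
        accepted = sum(
            detect_erp(one_event_session(seed=100 + s),
                       EpisodeWindow("e0", -5.0, 5.0), "ACC", search=(0, 5)).accepted
            for s in range(40)
        )
        assert accepted <= 2  # <= 5%

    def test_amplitude_recovery_without_noise(self):
        spec = synth.LfpGenSpec(duration=12.0, noise_sd=0.001, background_sd=0.001,
                                theta_amp=0.0, gamma_base_amp=0.0,
                                erp_jitter_sd=0.0, seed=0)
        ev = pd.DataFrame([{"event_id": "e0", "onset_s": 6.5, "erp_amp": 100.0}])
        lfp, _ = synth.generate_lfp(spec, ev)
        events = make_event_table([{"event_id": "e0", "kind": "stimulus",
                                    "onset_s": 6.0}])
        sess = RecordingSession({"ACC": lfp}, spec.fs, [], events)
        hit = detect_erp(sess, EpisodeWindow("e0", -5.0, 5.0), "ACC", search=(0, 5))
        assert hit.peak_to_trough_amp == pytest.approx(100.0, rel=0.10)

    def test_acceptance_monotone_in_amplitude(self):
        snrs = []
        for amp in (50.0, 150.0, 400.0):
            hits = [detect_erp(one_event_session(erp_amp=amp, seed=s),
                               EpisodeWindow("e0", -5.0, 5.0), "ACC", search=(0, 5)).snr
                    for s in range(5)]
            snrs.append(np.mean(hits))
        assert snrs[0] < snrs[1] < snrs[2]

    def test_unknown_region_rejected(self):
        sess = one_event_session()
        with pytest.raises(ErpError, match="region"):
            detect_erp(sess, EpisodeWindow("e0", -5.0, 5.0), "S1")


class TestCooccurrence:
    def frame(self, times, prefix):
        return pd.DataFrame({
            "event_id": [f"{prefix}{i}" for i in range(len(times))],
            "peak_time": times, "accepted": True,
        })

    def test_single_pair_lag(self):
        out = erp_cooccurrence(self.frame([1.0], "a"), self.frame([0.92], "s"))
        assert len(out) == 1
        assert out.lag.iloc[0] == pytest.approx(0.08)

    def test_events_beyond_tolerance_unpaired(self):
        out = erp_cooccurrence(self.frame([0.0], "a"), self.frame([4.0], "s"),
                               tolerance=3.0)
        assert out.lag.isna().all() and len(out) == 2

    def test_greedy_nearest_matching(self):
        out = erp_cooccurrence(self.frame([0.0, 1.0], "a"),
                               self.frame([0.9], "s"))
        paired = out.dropna(subset=["lag"])
        assert len(paired) == 1 and paired.acc_event.iloc[0] == "a1"

    def test_session_level_s1_lead(self, demo_session):
        sess, truth = demo_session
        df = detect_session_erps(sess, "stimulus", search=(0.0, 5.0))
        pairs = erp_cooccurrence(df[(df.region == "ACC") & df.accepted],
                                 df[(df.region == "S1") & df.accepted])
        lags = pairs.lag.dropna()
        assert len(lags) >= 8
        assert 0.0 < lags.mean() < 0.2  # S1 leads by ~80 ms


class TestBehaviorCorrelation:
    def make(self, slope):
        lat = np.linspace(0.3, 1.2, 10)
        erps = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(10)],
            "latency": lat, "peak_to_trough_amp": 100 - 20 * lat,
            "accepted": True,
        })
        events = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(10)],
            "paw_withdrawal_latency_s": slope * lat,
        })
        return erps, events

    def test_perfectly_linear(self):
        erps, events = self.make(2.0)
        out = latency_behavior_correlation(erps, events)
        assert out["latency"][0] == pytest.approx(1.0)
        assert out["amplitude"][0] == pytest.approx(-1.0)

    def test_anti_linear(self):
        erps, events = self.make(-2.0)
        out = latency_behavior_correlation(erps, events)
        assert out["latency"][0] == pytest.approx(-1.0)

    def test_insufficient_pairs(self):
        erps, events = self.make(1.0)
        with pytest.raises(ErpError, match=">= 3"):
            latency_behavior_correlation(erps.head(2), events)

    def test_null_p_uniform(self):
        """Independent pairs: ~5% of p-values below 0.05."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            erps = pd.DataFrame({
                "event_id": [f"e{i}" for i in range(40)],
                "latency": rng.standard_normal(40),
                "peak_to_trough_amp": rng.standard_normal(40),
                "accepted": True,
            })
            events = pd.DataFrame({
                "event_id": [f"e{i}" for i in range(40)],
                "paw_withdrawal_latency_s": rng.standard_normal(40),
            })
            hits += latency_behavior_correlation(erps, events)["latency"][1] < 0.05
        assert abs(hits / n_rep - 0.05) < 0.05


def test_session_withdrawal_correlations(demo_session):
    sess, truth = demo_session
    df = detect_session_erps(sess, "stimulus", search=(0.0, 5.0))
    out = latency_behavior_correlation(df[df.region == "ACC"], sess.events)
    assert out["latency"][0] > 0.5 and out["latency"][1] < 0.01
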