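#!/usr/bin/env python
"""Time-frequency structure of evoked and spontaneous episodes.

Finds: theta and gamma event-related synchronization after the stimulus
(Z-scored multitaper spectrogram), inter-region theta coherence during
evoked trials, and band-power changes from pre to post windows (gamma
increase confined to S1 in spontaneous episodes).

Writes results/band_power.csv, results/coherence.csv,
results/spectral_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from painlfp import spectral
from painlfp.session import load_session
from painlfp.signal_ops import CANONICAL_BANDS, dominant_component
from painlfp.spectral import TaperSpec

ROOT = Path(__file__).resolve().parents[1]


def episode_matrix(sess, onsets, region, lo, hi):
    fs = sess.fs_lfp
    sig = dominant_component(sess.region_lfp[region])[0]
    rows = [sig[int((o + lo) * fs): int((o + hi) * fs)] for o in onsets]
    n = min(map(len, rows))
    return np.stack([r[:n] for r in rows])


def main() -> None:
    sess = load_session(ROOT / "scratch" / "session")
    fs = sess.fs_lfp
    stim = sess.events[sess.events.kind == "stimulus"].onset_s.to_numpy()
    spont = sess.events[sess.events.kind == "spontaneous_behavior"].onset_s.to_numpy()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary = {}

    # Z-scored spectrogram of the first evoked trial, S1
    sig = dominant_component(
        sess.region_lfp["S1"][:, int((stim[0] - 5) * fs): int((stim[0] + 5) * fs)])[0]
    sp = spectral.mt_spectrogram(sig, fs, TaperSpec(tw=5.0, window_len=0.5,
                                                    step=0.02), t0=-5.0)
    z = spectral.zscore_spectrogram(sp, baseline=(-5.0, 0.0))
    post = (z.times > 0) & (z.times < 3)
    summary["first_trial_post_stimulus_z"] = {
        "theta_mean": round(float(z.zscore[(z.freqs >= 4) & (z.freqs < 8)][:, post].mean()), 2),
        "gamma_mean": round(float(z.zscore[(z.freqs >= 30) & (z.freqs < 80)][:, post].mean()), 2),
    }

    # trial-averaged ACC-S1 coherence, evoked vs spontaneous (2 s windows)
    coh_rows = []
    for cond, onsets, (lo, hi) in (("evoked", stim, (0.0, 2.0)),
                                   ("spontaneous", spont, (-1.0, 1.0))):
        xs = episode_matrix(sess, onsets, "ACC", lo, hi)
        ys = episode_matrix(sess, onsets, "S1", lo, hi)
        freqs, coh, se = spectral.mt_coherence(xs, ys, fs,
                                               TaperSpec(tw=5.0, window_len=2.0))
        keep = freqs <= 100
        coh_rows.append(pd.DataFrame({"condition": cond, "freq_hz": freqs[keep],
                                      "coherence": coh[keep], "jackknife_se": se[keep]}))
        theta = (freqs >= 4) & (freqs < 8)
        summary[f"coherence_theta_{cond}"] = round(float(coh[theta].mean()), 3)
    pd.concat(coh_rows).to_csv(res / "coherence.csv", index=False)

    # band power pre vs post per region and condition
    bp_rows = []
    for cond, onsets in (("evoked", stim), ("spontaneous", spont)):
        for region in sess.regions:
            sig = dominant_component(sess.region_lfp[region])[0]
            for period, (lo, hi) in (("pre", (-5.0, 0.0)), ("post", (0.0, 5.0))):
                vals = []
                for o in onsets:
                    seg = sig[int((o + lo) * fs): int((o + hi) * fs)]
                    vals.append(spectral.band_power(seg, fs))
                mean = {b.name: float(np.mean([v[b.name] for v in vals]))
                        for b in CANONICAL_BANDS}
                bp_rows.append({"condition": cond, "region": region,
                                "period": period, **mean})
    bp = pd.DataFrame(bp_rows)
    bp.to_csv(res / "band_power.csv", index=False)
    for cond in ("evoked", "spontaneous"):
        for region in sess.regions:
            sub = bp[(bp.condition == cond) & (bp.region == region)]
            delta = (sub[sub.period == "post"].iloc[0]["high_gamma"]
                     - sub[sub.period == "pre"].iloc[0]["high_gamma"])
            summary[f"high_gamma_post_minus_pre_db_{cond}_{region}"] = round(delta, 2)

    (res / "spectral_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
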