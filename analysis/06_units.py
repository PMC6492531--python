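#!/usr/bin/env python
"""Pain-modulated units and their relation to the ERP amplitude.

Classifies each unit as positively/negatively/un-modulated (post vs
baseline rates, Wilcoxon signed-rank), builds stimulus- and ERP-peak-
aligned PSTHs for one modulated unit, and regresses per-trial Z-scored
firing rates of modulated units on the ERP peak-to-trough amplitude.

Writes results/units.csv, results/psth_example.csv,
results/units_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from painlfp import erp, units
from painlfp.session import load_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sess = load_session(ROOT / "scratch" / "session")
    stim = sess.events[sess.events.kind == "stimulus"].onset_s.to_numpy()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    mods = units.classify_session_units(sess.spikes, stim)
    mods.to_csv(res / "units.csv", index=False)

    # ERP-peak-aligned PSTH (10 ms bins, 20 ms Gaussian kernel) of the most
    # strongly modulated unit
    erps = erp.detect_session_erps(sess, "stimulus", search=(0.0, 5.0))
    acc_peaks = erps[(erps.region == "ACC") & erps.accepted].peak_time.to_numpy()
    best = mods.loc[mods.z_change.abs().idxmax(), "unit_id"]
    train = next(t for t in sess.spikes if t.unit_id == best)
    p = units.psth(train, acc_peaks, window=(-2.0, 2.0), alignment="erp_peak")
    pd.DataFrame({"time_s": p.bin_edges[:-1] + p.bin_size / 2,
                  "rate_hz": p.rate}).to_csv(res / "psth_example.csv", index=False)

    # per-trial Z-scored rate of positively modulated units vs ERP amplitude
    acc_erps = erps[(erps.region == "ACC") & erps.accepted]
    onsets = (acc_erps.peak_time - acc_erps.latency).to_numpy()
    amps = acc_erps.peak_to_trough_amp.to_numpy()
    pos = mods[mods.direction == "positive"].unit_id
    pos_trains = [t for t in sess.spikes if t.unit_id in set(pos)]
    post = np.mean([units.trial_rates(t, onsets, (0.0, 3.0)) for t in pos_trains],
                   axis=0)
    base = np.mean([units.trial_rates(t, onsets, (-5.0, 0.0)) for t in pos_trains],
                   axis=0)
    z = (post - base.mean()) / base.std()
    reg = units.rate_erp_regression(z, amps)

    summary = {
        "n_units": len(mods),
        "modulation_counts": mods.direction.value_counts().to_dict(),
        "example_unit": best,
        "rate_vs_erp_amplitude": {k: round(v, 4) for k, v in reg.items()},
    }
    (res / "units_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
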