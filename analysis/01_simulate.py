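#!/usr/bin/env python
"""Generate the study's synthetic two-region session.

Writes the session (LFP HDF5 + spikes/events CSV) under scratch/session/
and a small summary of what was generated to results/session_summary.json.
Later analysis stages load the session from disk, exactly as they would a
recorded one.
"""

import json
from pathlib import Path

from painlfp import synth
from painlfp.session import save_session

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scn = synth.Scenario()  # 30 evoked trials, 10 spontaneous events, 2 regions
    sess, truth = synth.generate_session(scn, seed=SEED)
    out = ROOT / "scratch" / "session"
    save_session(sess, out)
    truth["events"].to_csv(out / "ground_truth_events.csv", index=False)

    summary = {
        "seed": SEED,
        "duration_s": sess.duration,
        "regions": sess.regions,
        "n_units": len(sess.spikes),
        "n_evoked": int((sess.events.kind == "stimulus").sum()),
        "n_spontaneous": int((sess.events.kind == "spontaneous_behavior").sum()),
        "pac_depth": {r: truth["pac"][r]["pac_depth"] for r in sess.regions},
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "session_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"session: {sess.duration:.0f} s, {len(sess.spikes)} units, "
          f"{summary['n_evoked']} evoked trials, "
          f"{summary['n_spontaneous']} spontaneous events -> {out}")


if __name__ == "__main__":
    main()
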