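"""Single-trial ERP identification and metrics.

Pipeline per episode and region: slice the window, band-pass 2-15 Hz,
take the dominant principal component across channels, and locate the
extremal trough with its flanking peak.  The SNR is the peak-to-trough
amplitude over twice the baseline SD of the band-limited component; an ERP
is accepted when SNR >= threshold (default 3, a conservative criterion).
All analyses are single-trial; no trial averaging is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import EpisodeWindow, RecordingSession, slice_window
from .signal_ops import ERP_BAND, BandDef, bandpass, dominant_component


class ErpError(ValueError):
    pass


@dataclass
class ErpEvent:
    """A detected single-trial ERP."""

    event_id: str
    region: str
    peak_time: float  # absolute session time of the trough (dominant deflection)
    latency: float  # peak_time minus the event onset
    peak_to_trough_amp: float  # µV, on the dominant component
    snr: float
    accepted: bool


def detect_erp(
    session: RecordingSession,
    window: EpisodeWindow,
    region: str,
    snr_threshold: float = 3.0,
    band: BandDef = ERP_BAND,
    max_duration: float = 0.25,
    search: tuple[float, float] | None = None,
) -> ErpEvent | None:
    """Detect the extremal single-trial ERP in one episode window.

    ``search`` optionally restricts the trough search to a sub-interval
    (relative to the event onset, e.g. (0, 5) for evoked episodes) while the
    full window still provides the SNR baseline.  Returns None when the
    window contains no usable extremum.
    """
    if region not in session.region_lfp:
        raise ErpError(f"region {region!r} not in session")
    sub = slice_window(session, window)
    lfp = sub.region_lfp[region]
    fs = sub.fs_lfp
    filtered = bandpass(lfp, band, fs)
    comp, _ = dominant_component(filtered)

    rel_t = window.t_start + np.arange(comp.size) / fs
    if search is not None:
        mask = (rel_t >= search[0]) & (rel_t < search[1])
        if not mask.any():
            raise ErpError("empty search interval")
    else:
        mask = np.ones(comp.size, bool)

    idx = np.flatnonzero(mask)
    trough_i = idx[np.argmin(comp[idx])]
    # flanking peak: largest positive deflection within one ERP duration
    span = int(round(max_duration * fs))
    left = comp[max(trough_i - span, 0) : trough_i]
    right = comp[trough_i + 1 : trough_i + 1 + span]
    flank = max(left.max() if left.size else -np.inf,
                right.max() if right.size else -np.inf)
    if not np.isfinite(flank):
        return None
    amp = float(flank - comp[trough_i])

    # baseline: window start up to 1 s before the trough; if that leaves too
    # little data, fall back to the window minus +-0.5 s around the trough
    b_hi = trough_i - int(round(1.0 * fs))
    if b_hi >= int(0.25 * fs):
        baseline = comp[:b_hi]
    else:
        guard = int(round(0.5 * fs))
        keep = np.ones(comp.size, bool)
        keep[max(trough_i - guard, 0) : trough_i + guard] = False
        baseline = comp[keep]
    sd = baseline.std()
    if sd == 0:
        raise ErpError("degenerate baseline (zero SD) in ERP window")
    snr = amp / (2.0 * sd)

    onset = session.event_onset(window.event_id)
    peak_time = onset + rel_t[trough_i]
    return ErpEvent(
        event_id=window.event_id,
        region=region,
        peak_time=float(peak_time),
        latency=float(rel_t[trough_i]),
        peak_to_trough_amp=amp,
        snr=float(snr),
        accepted=bool(snr >= snr_threshold),
    )


def detect_session_erps(
    session: RecordingSession,
    kind: str = "stimulus",
    window: tuple[float, float] = (-5.0, 5.0),
    search: tuple[float, float] | None = (0.0, 5.0),
    regions: list[str] | None = None,
    snr_threshold: float = 3.0,
) -> pd.DataFrame:
    """Run detect_erp over every event of a kind; one row per event x region."""
    rows = []
    for _, ev in session.events[session.events["kind"] == kind].iterrows():
        onset = float(ev["onset_s"])
        lo = max(window[0], session.t0 - onset)
        hi = min(window[1], session.t_end - onset)
        if hi - lo < 1.0:
            continue
        w = EpisodeWindow(ev["event_id"], lo, hi)
        for region in regions or session.regions:
            hit = detect_erp(session, w, region, snr_threshold=snr_threshold, search=search)
            if hit is not None:
                rows.append(vars(hit))
    return pd.DataFrame(rows, columns=["event_id", "region", "peak_time", "latency",
                                       "peak_to_trough_amp", "snr", "accepted"])


def erp_cooccurrence(
    erps_acc: pd.DataFrame, erps_s1: pd.DataFrame, tolerance: float = 3.0
) -> pd.DataFrame:
    """Greedy nearest-in-time pairing of ACC and S1 ERPs within a tolerance.

    Lag = ACC peak_time - S1 peak_time per pair (positive when S1 leads).
    Unpaired events are returned with the other region's columns missing.
    """
    if tolerance <= 0:
        raise ErpError("tolerance must be positive")
    acc = erps_acc.reset_index(drop=True)
    s1 = erps_s1.reset_index(drop=True)
    pairs = []
    if len(acc) and len(s1):
        cand = [
            (abs(ta - ts), i, j)
            for i, ta in enumerate(acc["peak_time"])
            for j, ts in enumerate(s1["peak_time"])
            if abs(ta - ts) <= tolerance
        ]
        used_a: set[int] = set()
        used_s: set[int] = set()
        for _, i, j in sorted(cand):
            if i in used_a or j in used_s:
                continue
            used_a.add(i)
            used_s.add(j)
            pairs.append({
                "acc_peak_time": acc.loc[i, "peak_time"],
                "s1_peak_time": s1.loc[j, "peak_time"],
                "lag": acc.loc[i, "peak_time"] - s1.loc[j, "peak_time"],
                "acc_event": acc.loc[i, "event_id"],
                "s1_event": s1.loc[j, "event_id"],
            })
    else:
        used_a, used_s = set(), set()
    for i in range(len(acc)):
        if i not in used_a:
            pairs.append({"acc_peak_time": acc.loc[i, "peak_time"], "s1_peak_time": np.nan,
                          "lag": np.nan, "acc_event": acc.loc[i, "event_id"], "s1_event": None})
    for j in range(len(s1)):
        if j not in used_s:
            pairs.append({"acc_peak_time": np.nan, "s1_peak_time": s1.loc[j, "peak_time"],
                          "lag": np.nan, "acc_event": None, "s1_event": s1.loc[j, "event_id"]})
    return pd.DataFrame(pairs, columns=["acc_peak_time", "s1_peak_time", "lag",
                                        "acc_event", "s1_event"])


def latency_behavior_correlation(
    erps: pd.DataFrame, events: pd.DataFrame
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of paw-withdrawal latency with ERP latency and amplitude.

    Returns {"latency": (r, p), "amplitude": (r, p)} over accepted ERPs joined
    to events carrying a withdrawal latency.
    """
    merged = erps[erps["accepted"]].merge(
        events[["event_id", "paw_withdrawal_latency_s"]], on="event_id"
    ).dropna(subset=["paw_withdrawal_latency_s"])
    if len(merged) < 3:
        raise ErpError(f"need >= 3 paired observations, got {len(merged)}")
    w = merged["paw_withdrawal_latency_s"].to_numpy(float)
    out = {}
    for key, col in (("latency", "latency"), ("amplitude", "peak_to_trough_amp")):
        r, p = stats.pearsonr(merged[col].to_numpy(float), w)
        out[key] = (float(r), float(p))
    return out
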