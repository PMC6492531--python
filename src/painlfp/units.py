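"""PSTH construction, pain-modulated unit classification, and firing-rate
vs ERP-amplitude regression.

Stimulus-aligned PSTHs use 50 ms bins; ERP-peak-aligned PSTHs use 10 ms
bins smoothed with a 20 ms Gaussian kernel.  A unit is pain-modulated when
its per-trial post-stimulus rate ([0, 5] s) differs from the baseline rate
([-5, 0] s) by a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .session import SpikeTrain


class UnitsError(ValueError):
    pass


@dataclass
class Psth:
    """Trial-averaged rate per bin (Hz)."""

    bin_edges: np.ndarray
    rate: np.ndarray
    alignment: str  # "stimulus_onset" or "erp_peak"
    bin_size: float
    smooth_bw: float | None
    n_trials: int


@dataclass
class UnitModulation:
    unit_id: str
    direction: str  # "positive" | "negative" | "none"
    z_change: float  # Z-scored mean rate change, post vs baseline
    p_value: float


def psth(
    train: SpikeTrain,
    event_times: np.ndarray,
    window: tuple[float, float] = (-5.0, 5.0),
    alignment: str = "stimulus_onset",
    bin_size: float | None = None,
    smooth_bw: float | None = None,
) -> Psth:
    """Peri-event time histogram, trial-averaged, optionally kernel-smoothed.

    ``bin_size`` defaults to 50 ms for stimulus alignment and 10 ms (with a
    20 ms Gaussian bandwidth) for ERP-peak alignment.  Smoothing uses
    reflecting boundaries so the total area is conserved.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise UnitsError("no events to align to")
    if bin_size is None:
        bin_size = 0.05 if alignment == "stimulus_onset" else 0.01
    if smooth_bw is None and alignment == "erp_peak":
        smooth_bw = 0.02
    edges = np.arange(window[0], window[1] + bin_size / 2, bin_size)
    counts = np.zeros(edges.size - 1)
    for t0 in event_times:
        rel = train.times - t0
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (event_times.size * bin_size)
    if smooth_bw:
        rate = gaussian_filter1d(rate, sigma=smooth_bw / bin_size, mode="reflect")
    return Psth(bin_edges=edges, rate=rate, alignment=alignment,
                bin_size=bin_size, smooth_bw=smooth_bw, n_trials=event_times.size)


def trial_rates(
    train: SpikeTrain, event_times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Firing rate (Hz) of one unit in a window around each event."""
    event_times = np.asarray(event_times, dtype=float)
    dur = window[1] - window[0]
    out = np.empty(event_times.size)
    for i, t0 in enumerate(event_times):
        out[i] = np.count_nonzero(
            (train.times >= t0 + window[0]) & (train.times < t0 + window[1])
        ) / dur
    return out


def classify_modulation(
    train: SpikeTrain,
    stim_times: np.ndarray,
    post_window: tuple[float, float] = (0.0, 5.0),
    baseline_window: tuple[float, float] = (-5.0, 0.0),
    alpha: float = 0.05,
) -> UnitModulation:
    """Positive/negative/none pain modulation of one unit.

    Per-trial post vs baseline rates are compared by a Wilcoxon signed-rank
    test; direction follows the sign of the median change.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size < 5:
        raise UnitsError(f"need >= 5 trials, got {stim_times.size}")
    post = trial_rates(train, stim_times, post_window)
    base = trial_rates(train, stim_times, baseline_window)
    diff = post - base
    sd = base.std(ddof=1)
    z_change = float(diff.mean() / sd) if sd > 0 else np.nan
    if np.allclose(diff, 0.0):
        return UnitModulation(train.unit_id, "none", 0.0, 1.0)
    p = float(stats.wilcoxon(post, base, zero_method="wilcox").pvalue)
    if p < alpha:
        direction = "positive" if np.median(diff) > 0 else "negative"
    else:
        direction = "none"
    return UnitModulation(train.unit_id, direction, z_change, p)


def classify_session_units(
    spikes: list[SpikeTrain], stim_times: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    rows = [vars(classify_modulation(tr, stim_times, alpha=alpha)) for tr in spikes]
    return pd.DataFrame(rows)


def rate_erp_regression(
    unit_rates: np.ndarray, erp_amps: np.ndarray, absolute: bool = False
) -> dict[str, float]:
    """OLS of per-episode Z-scored firing rate on ERP peak-to-trough amplitude.

    ``absolute=True`` regresses |Z-scored rate| (the population summary
    convention).  Returns slope, intercept, r2 and the Pearson p-value.
    """
    x = np.asarray(erp_amps, dtype=float)
    y = np.asarray(unit_rates, dtype=float)
    if absolute:
        y = np.abs(y)
    if x.size < 3:
        raise UnitsError(f"need >= 3 episodes, got {x.size}")
    if x.std() == 0:
        raise UnitsError("zero-variance predictor (ERP amplitudes all equal)")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }
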