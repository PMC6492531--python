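"""Shared signal primitives: band-pass filtering, analytic signal, dominant
principal component, baseline Z-scoring.

Filtering is a 4th-order Butterworth applied forward-backward, so output is
zero-phase (no group delay) and the same length as the input.  The analytic
signal reflects-pads by one second before the Hilbert transform to suppress
edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_low < self.f_high:
            raise SignalError(f"invalid band {self.name}: [{self.f_low}, {self.f_high}] Hz")


#: Canonical analysis bands for rodent cortical LFP.
CANONICAL_BANDS = (
    BandDef("theta", 4.0, 8.0),
    BandDef("alpha", 8.0, 12.0),
    BandDef("beta", 13.0, 30.0),
    BandDef("low_gamma", 30.0, 50.0),
    BandDef("high_gamma", 50.0, 80.0),
)

#: Band used for single-trial ERP extraction (removes high-frequency noise).
ERP_BAND = BandDef("erp", 2.0, 15.0)


def bandpass(x: np.ndarray, band: BandDef, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if band.f_high >= fs / 2:
        raise SignalError(f"band edge {band.f_high} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def analytic_signal(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (degrees in [0, 360)) and amplitude envelope.

    The input should already be band-limited.  One second of reflect padding
    is applied on both ends and trimmed after the transform.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 4:
        raise SignalError("analytic_signal needs at least 4 samples")
    pad = min(int(round(fs)), x.shape[-1] - 1)
    xp = np.concatenate(
        [x[..., pad:0:-1], x, x[..., -2 : -pad - 2 : -1]], axis=-1
    ) if pad else x
    z = sps.hilbert(xp, axis=-1)
    if pad:
        z = z[..., pad : pad + x.shape[-1]]
    phase_deg = np.mod(np.degrees(np.angle(z)), 360.0)
    return phase_deg, np.abs(z)


def dominant_component(
    lfp: np.ndarray, orient_negative: bool = True
) -> tuple[np.ndarray, float]:
    """First principal component score series of a channels x time matrix.

    Channels are mean-centered over the supplied window only.  The sign is
    oriented so the largest-magnitude deflection is negative-going (the
    trough-first ERP convention); pass ``orient_negative=False`` to keep the
    raw eigenvector sign.

    Returns (score series, explained-variance fraction).
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[0] < 1 or lfp.shape[1] < 2:
        raise SignalError("dominant_component needs >= 1 channel and >= 2 samples")
    centered = lfp - lfp.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        raise SignalError("degenerate covariance: all channels constant")
    # SVD of the centered data; scores = projection on the first right vector,
    # rescaled to mean-channel units so amplitudes stay comparable to µV
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    gain = np.abs(u[:, 0]).mean()
    scores = s[0] * vt[0] * gain
    var = s**2
    explained = float(var[0] / var.sum())
    if orient_negative and scores[np.argmax(np.abs(scores))] > 0:
        scores = -scores
    return scores, explained


def zscore_series(x: np.ndarray, baseline: slice | np.ndarray) -> np.ndarray:
    """Z-score a series against a baseline segment: (x - mean_b) / SD_b.

    ``baseline`` is a slice or boolean/index mask into ``x``.
    """
    x = np.asarray(x, dtype=float)
    b = x[baseline]
    if b.size < 2:
        raise SignalError("baseline too short to estimate an SD")
    sd = b.std(ddof=0)
    if sd == 0.0:
        raise SignalError("degenerate baseline: zero standard deviation")
    return (x - b.mean()) / sd
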