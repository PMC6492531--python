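"""Multitaper spectral estimation: spectrogram, Z-scored spectrogram,
LFP-LFP coherence, spike-field coherence, band power, cross-correlation.

All estimators use Slepian (DPSS) tapers with time-bandwidth product TW and
N = 2*TW - 1 tapers by default; the tapers are mutually orthogonal and give
independent spectral estimates.  Defaults follow the analysis conventions
used throughout the package: TW = 5 for spectrogram/coherence, TW = 3 for
spike-field coherence, moving windows of 0.5 s with 1 ms steps, and a
baseline of the 5 s preceding the stimulus for Z-scoring.

PSDs are one-sided with unit-energy tapers, so the integral of the PSD over
frequency recovers the signal variance (Parseval).  dB values are referenced
to 1 µV²/Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .session import SpikeTrain
from .signal_ops import BandDef, CANONICAL_BANDS, SignalError, bandpass


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class TaperSpec:
    """Multitaper setup [TW, N] with a moving-window geometry."""

    tw: float = 5.0
    n_tapers: int | None = None
    window_len: float = 0.5
    step: float = 0.001

    def __post_init__(self) -> None:
        if self.tw <= 1.0:
            raise SpectralError(f"time-bandwidth product {self.tw} must exceed 1")
        if self.window_len <= 0 or self.step <= 0:
            raise SpectralError("window_len and step must be positive")

    @property
    def k(self) -> int:
        """Number of tapers, N = 2*TW - 1 unless overridden."""
        return int(self.n_tapers) if self.n_tapers is not None else int(round(2 * self.tw - 1))

    def tapers(self, n_samples: int) -> np.ndarray:
        """Unit-energy DPSS tapers, shape (k, n_samples)."""
        return dpss(n_samples, self.tw, self.k)


@dataclass
class Spectrogram:
    """Time-frequency power. ``power`` has shape (n_freq, n_time), raw µV²/Hz."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    zscore: np.ndarray | None = None
    baseline: tuple[float, float] | None = None


def _taper_ffts(x: np.ndarray, tapers: np.ndarray, nfft: int) -> np.ndarray:
    """Tapered one-sided FFTs; x (..., n), tapers (k, n) -> (..., k, nfft//2+1)."""
    return np.fft.rfft(x[..., None, :] * tapers, n=nfft, axis=-1)


def _one_sided_scale(nfft: int) -> np.ndarray:
    scale = np.full(nfft // 2 + 1, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    return scale


def mt_psd(x: np.ndarray, fs: float, tw: float = 5.0, n_tapers: int | None = None,
           nfft: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of one segment. Returns (freqs, psd in µV²/Hz)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise SpectralError("segment too short for a multitaper PSD")
    spec = TaperSpec(tw=tw, n_tapers=n_tapers, window_len=n / fs, step=1.0)
    tapers = spec.tapers(n)
    nfft = nfft or max(256, int(2 ** np.ceil(np.log2(n))))
    xf = _taper_ffts(x - x.mean(axis=-1, keepdims=True), tapers, nfft)
    psd = (np.abs(xf) ** 2).mean(axis=-2) / fs * _one_sided_scale(nfft)
    return np.fft.rfftfreq(nfft, 1.0 / fs), psd


def mt_spectrogram(x: np.ndarray, fs: float, taper: TaperSpec | None = None,
                   t0: float = 0.0, nfft: int | None = None) -> Spectrogram:
    """Moving-window multitaper spectrogram of a single time series.

    ``t0`` is the time of the first sample; window times are window centers.
    """
    taper = taper or TaperSpec()
    x = np.asarray(x, dtype=float)
    nwin = int(round(taper.window_len * fs))
    nstep = max(1, int(round(taper.step * fs)))
    if nwin > x.size:
        raise SpectralError(f"window ({nwin} samples) longer than signal ({x.size})")
    tapers = taper.tapers(nwin)
    nfft = nfft or max(256, int(2 ** np.ceil(np.log2(nwin))))
    scale = _one_sided_scale(nfft)
    starts = np.arange(0, x.size - nwin + 1, nstep)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    power = np.empty((freqs.size, starts.size))
    # chunk over windows to bound the FFT workspace
    chunk = max(1, int(2**22 // (taper.k * nfft)))
    windows = np.lib.stride_tricks.sliding_window_view(x, nwin)[::nstep]
    for i in range(0, starts.size, chunk):
        w = windows[i : i + chunk]
        xf = _taper_ffts(w - w.mean(axis=-1, keepdims=True), tapers, nfft)
        power[:, i : i + chunk] = ((np.abs(xf) ** 2).mean(axis=-2) / fs * scale).T
    times = t0 + (starts + nwin / 2) / fs
    return Spectrogram(times=times, freqs=freqs, power=power)


def zscore_spectrogram(spec: Spectrogram,
                       baseline: tuple[float, float] = (-5.0, 0.0)) -> Spectrogram:
    """Z-score each frequency row against the pre-stimulus baseline columns."""
    lo, hi = baseline
    cols = (spec.times >= lo) & (spec.times < hi)
    if cols.sum() < 2:
        raise SpectralError(f"no baseline columns in [{lo}, {hi}] s")
    mu = spec.power[:, cols].mean(axis=1, keepdims=True)
    sd = spec.power[:, cols].std(axis=1, keepdims=True)
    dead = np.flatnonzero(sd[:, 0] == 0.0)
    if dead.size:
        raise SpectralError(
            f"zero baseline SD at frequencies {spec.freqs[dead][:10].tolist()} Hz"
        )
    return Spectrogram(times=spec.times, freqs=spec.freqs, power=spec.power,
                       zscore=(spec.power - mu) / sd, baseline=baseline)


def _coherence_from_trials(xs: np.ndarray, ys: np.ndarray, fs: float,
                           taper: TaperSpec, nfft: int | None):
    """Coherence from stacked trials (n_trials, n_samples) of x and y."""
    n = xs.shape[-1]
    tapers = taper.tapers(n)
    if tapers.shape[0] < 2:
        raise SpectralError("jackknife error bars require at least 2 tapers")
    nfft = nfft or max(256, int(2 ** np.ceil(np.log2(n))))
    xf = _taper_ffts(xs - xs.mean(-1, keepdims=True), tapers, nfft)
    yf = _taper_ffts(ys - ys.mean(-1, keepdims=True), tapers, nfft)
    xf = xf.reshape(-1, xf.shape[-1])  # (n_trials*k, nfreq)
    yf = yf.reshape(-1, yf.shape[-1])

    def coh(mask: np.ndarray) -> np.ndarray:
        sxy = (xf[mask] * np.conj(yf[mask])).mean(axis=0)
        sxx = (np.abs(xf[mask]) ** 2).mean(axis=0)
        syy = (np.abs(yf[mask]) ** 2).mean(axis=0)
        return np.abs(sxy) / np.sqrt(sxx * syy)

    m = xf.shape[0]
    full = coh(np.ones(m, bool))
    leaves = np.empty((m, full.size))
    for i in range(m):
        mask = np.ones(m, bool)
        mask[i] = False
        leaves[i] = coh(mask)
    se = np.sqrt((m - 1) / m * ((leaves - leaves.mean(axis=0)) ** 2).sum(axis=0))
    return np.fft.rfftfreq(nfft, 1.0 / fs), full, se, m


def mt_coherence(x, y, fs: float, taper: TaperSpec | None = None,
                 nfft: int | None = None):
    """Multitaper magnitude coherence with jackknife error bars.

    ``x`` and ``y`` may be single series or (n_trials, n_samples) stacks;
    trials are averaged in the cross- and auto-spectra.  The jackknife
    leaves one independent estimate (taper x trial) out at a time.

    Returns (freqs, coherence in [0, 1], jackknife SE).
    """
    taper = taper or TaperSpec(tw=5.0, window_len=2.0)
    xs = np.atleast_2d(np.asarray(x, dtype=float))
    ys = np.atleast_2d(np.asarray(y, dtype=float))
    if xs.shape != ys.shape:
        raise SpectralError(f"shape mismatch {xs.shape} vs {ys.shape}")
    freqs, coh, se, _ = _coherence_from_trials(xs, ys, fs, taper, nfft)
    return freqs, coh, se


def coherence_bias_floor(n_estimates: int, quantile: float = 0.95) -> float:
    """Analytic null quantile of magnitude coherence from n independent estimates.

    For independent signals, |C|^2 has CDF 1 - (1 - x)^(n-1), so the q-quantile
    of |C| is sqrt(1 - (1-q)^(1/(n-1))).
    """
    if n_estimates < 2:
        raise SpectralError("need at least 2 estimates")
    return float(np.sqrt(1.0 - (1.0 - quantile) ** (1.0 / (n_estimates - 1))))


def spike_field_coherence(train: SpikeTrain | np.ndarray, lfp: np.ndarray, fs: float,
                          taper: TaperSpec | None = None, t0: float = 0.0,
                          nfft: int | None = None):
    """Spike-field coherence: multitaper coherence between the binned spike
    train (1/fs bins, mean rate removed) and the LFP.

    ``lfp`` may be (n_trials, n_samples); then ``train`` must be a list of
    per-trial spike-time arrays (or a single train reused).  Returns
    (freqs, sfc, jackknife SE).
    """
    taper = taper or TaperSpec(tw=3.0, window_len=2.0)
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    n = lfp.shape[-1]

    def binned(times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            raise SpectralError("empty spike train")
        idx = np.floor((times - t0) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        counts = np.bincount(idx, minlength=n).astype(float)
        return counts - counts.mean()

    if isinstance(train, SpikeTrain):
        spike_sets = [train.times] * lfp.shape[0]
    elif isinstance(train, (list, tuple)) and len(train) == lfp.shape[0]:
        spike_sets = [np.asarray(t) for t in train]
    else:
        spike_sets = [np.asarray(train)] * lfp.shape[0]
    total = sum(len(s) for s in spike_sets)
    if total < 50:
        import warnings

        warnings.warn(f"only {total} spikes in the analysis window (< 50)", stacklevel=2)
    counts = np.stack([binned(s) for s in spike_sets])
    freqs, sfc, se, _ = _coherence_from_trials(counts, lfp, fs, taper, nfft)
    return freqs, sfc, se


def band_power(x: np.ndarray, fs: float, bands: tuple[BandDef, ...] = CANONICAL_BANDS,
               tw: float = 5.0) -> dict[str, float]:
    """Integrated multitaper band power in dB (ref 1 µV²/Hz x Hz).

    The PSD is integrated over each band and converted with 10*log10.
    """
    for b in bands:
        if b.f_high >= fs / 2:
            raise SpectralError(f"band {b.name} reaches Nyquist ({fs / 2} Hz)")
    freqs, psd = mt_psd(x, fs, tw=tw)
    df = freqs[1] - freqs[0]
    out = {}
    for b in bands:
        m = (freqs >= b.f_low) & (freqs < b.f_high)
        out[b.name] = float(10.0 * np.log10(psd[..., m].sum() * df + 1e-300))
    return out


def lfp_crosscorr(x: np.ndarray, y: np.ndarray, fs: float,
                  band: BandDef = BandDef("broad", 4.0, 80.0),
                  max_lag: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of band-pass filtered LFPs.

    Positive lag means y is delayed relative to x (x leads).
    Returns (lags in s, correlation in [-1, 1]).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise SpectralError("x and y must have equal length")
    nlag = int(round(max_lag * fs))
    if nlag >= x.size:
        raise SpectralError("max_lag at or beyond signal length")
    xb = bandpass(x, band, fs)
    yb = bandpass(y, band, fs)
    xb = xb - xb.mean()
    yb = yb - yb.mean()
    full = sps.correlate(yb, xb, mode="full")
    mid = xb.size - 1
    cc = full[mid - nlag : mid + nlag + 1]
    denom = np.sqrt((xb**2).sum() * (yb**2).sum())
    if denom == 0:
        raise SignalError("zero-variance input")
    lags = np.arange(-nlag, nlag + 1) / fs
    return lags, cc / denom
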