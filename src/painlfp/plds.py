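"""Poisson linear dynamical system for ensemble-spike pain-onset detection.

Model: a scalar latent z_t = a z_{t-1} + eps_t, eps_t ~ N(0, sigma_eps^2),
drives C Poisson units, y_it ~ Poisson(exp(c_i z_t + d_i) * delta), with the
spike count of bin t taken over the half-open interval ((t-1)delta, t delta].

* ``fit_em`` estimates {a, c, d, sigma_eps} on an evoked episode by EM with
  a Laplace (Gaussian) approximation in the E-step: a mode-finding forward
  filter followed by an RTS smoother, closed-form updates for a and
  sigma_eps, and Newton updates for each unit's (c_i, d_i).  Identifiability
  is fixed by normalizing ||c|| = 1 with mean(c) >= 0; the scale is absorbed
  into the latent and sigma_eps.
* ``filter_forward`` runs the recursive (forward, causal) filter with the
  one-step posterior-precision update, then Z-scores the filtered latent
  against a pre-stimulus baseline (default [-4, -1] s).
* ``detect_onset`` flags the first post-onset bin whose Z-score confidence
  bound clears the significance threshold theta0 (default 1.65, the Gaussian
  5% tail).

During spontaneous episodes the model parameters fitted on an evoked
episode are reused unchanged; only the filter is re-run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import SpikeTrain


class PldsError(ValueError):
    pass


@dataclass
class PldsModel:
    """Fitted (or true) PLDS parameters."""

    a: float
    c: np.ndarray
    d: np.ndarray
    sigma_eps: float
    delta: float = 0.05

    def __post_init__(self) -> None:
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if not 0.0 < abs(self.a) < 1.0:
            raise PldsError(f"a={self.a} outside (0, 1) in magnitude")
        if self.sigma_eps <= 0 or self.delta <= 0:
            raise PldsError("sigma_eps and delta must be positive")
        if self.c.shape != self.d.shape:
            raise PldsError("c and d must have equal length")


@dataclass
class FilterTrace:
    """Output of the recursive forward filter on one episode."""

    times: np.ndarray  # bin end times, s (0 = event onset)
    z_filt: np.ndarray  # filtered mean of the latent
    z_pred: np.ndarray  # one-step predicted mean
    q_filt: np.ndarray  # filtered variance
    zscore: np.ndarray  # vs the pre-stimulus baseline
    ci_low: np.ndarray
    ci_high: np.ndarray
    detection_time: float | None = None


def gaussian_tail(theta0: float) -> float:
    """P(Z > theta0) for a standard Gaussian (the filter's significance level)."""
    return float(stats.norm.sf(theta0))


# ---------------------------------------------------------------------------
# binning


def bin_counts(
    spikes: list[SpikeTrain], window: tuple[float, float], delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per unit and bin over half-open-left intervals.

    Bin t (1-based) spans (w_lo + (t-1)*delta, w_lo + t*delta]; a spike
    exactly at a bin edge belongs to the earlier bin.  Returns
    (counts C x T, bin end times relative to w_lo).
    """
    if delta <= 0:
        raise PldsError("delta must be positive")
    if not spikes:
        raise PldsError("empty unit list")
    lo, hi = window
    n_bins = int(np.floor((hi - lo) / delta + 1e-9))
    if n_bins < 1:
        raise PldsError("window shorter than one bin")
    counts = np.zeros((len(spikes), n_bins), dtype=int)
    for i, train in enumerate(spikes):
        rel = np.asarray(train.times, dtype=float) - lo
        rel = rel[(rel > 0) & (rel <= n_bins * delta + 1e-12)]
        idx = np.ceil(rel / delta - 1e-9).astype(int) - 1
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts[i], idx, 1)
    return counts, (np.arange(1, n_bins + 1) * delta)


# ---------------------------------------------------------------------------
# E-step machinery (shared with the online filter)


def _newton_mode(m_pred, q_pred, y_t, c, d, delta, n_iter=3):
    """Posterior mode and curvature of z_t given one bin of counts."""
    z = m_pred
    for _ in range(n_iter):
        lam = np.exp(np.clip(c * z + d, -50.0, 50.0)) * delta
        g1 = -(z - m_pred) / q_pred + np.sum(c * (y_t - lam))
        g2 = -1.0 / q_pred - np.sum(c**2 * lam)
        z = z - g1 / g2
    lam = np.exp(np.clip(c * z + d, -50.0, 50.0)) * delta
    q = 1.0 / (1.0 / q_pred + np.sum(c**2 * lam))
    return z, q, lam


def _laplace_filter(counts, a, c, d, sigma_eps, delta):
    """Mode-finding forward filter; returns means, variances, predicted pairs
    and the Laplace approximation of the marginal log-likelihood."""
    C, T = counts.shape
    q_stat = sigma_eps**2 / (1.0 - a**2)
    m_f = np.empty(T)
    q_f = np.empty(T)
    m_p = np.empty(T)
    q_p = np.empty(T)
    ll = 0.0
    m_prev, q_prev = 0.0, q_stat
    for t in range(T):
        mp = a * m_prev
        qp = a**2 * q_prev + sigma_eps**2
        if t == 0:
            mp, qp = 0.0, q_stat
        z, q, lam = _newton_mode(mp, qp, counts[:, t], c, d, delta)
        y = counts[:, t]
        log_joint = (
            -0.5 * (z - mp) ** 2 / qp
            - 0.5 * np.log(2 * np.pi * qp)
            + np.sum(y * np.log(np.maximum(lam, 1e-300)) - lam)
        )
        ll += log_joint + 0.5 * np.log(2 * np.pi * q)
        m_p[t], q_p[t] = mp, qp
        m_f[t], q_f[t] = z, q
        m_prev, q_prev = z, q
    return m_f, q_f, m_p, q_p, ll


def _rts_smoother(m_f, q_f, m_p, q_p, a):
    T = m_f.size
    m_s = m_f.copy()
    q_s = q_f.copy()
    cov = np.zeros(T)  # cov(z_t, z_{t+1} | y), stored at index t
    for t in range(T - 2, -1, -1):
        j = q_f[t] * a / q_p[t + 1]
        m_s[t] = m_f[t] + j * (m_s[t + 1] - m_p[t + 1])
        q_s[t] = q_f[t] + j**2 * (q_s[t + 1] - q_p[t + 1])
        cov[t] = j * q_s[t + 1]
    return m_s, q_s, cov


def _m_step_cd(counts, m_s, q_s, c, d, delta, n_newton=5):
    """Newton updates of (c_i, d_i) under E[exp(cz+d)] = exp(cm + c^2 V/2 + d)."""
    y = counts.astype(float)
    for _ in range(n_newton):
        expo = c[:, None] * m_s[None, :] + 0.5 * c[:, None] ** 2 * q_s[None, :] + d[:, None]
        lam = np.exp(np.clip(expo, -50.0, 50.0)) * delta  # (C, T)
        w = m_s[None, :] + c[:, None] * q_s[None, :]
        g_c = (y * m_s[None, :] - lam * w).sum(axis=1)
        g_d = (y - lam).sum(axis=1)
        h_cc = -(lam * (w**2 + q_s[None, :])).sum(axis=1)
        h_cd = -(lam * w).sum(axis=1)
        h_dd = -lam.sum(axis=1)
        det = h_cc * h_dd - h_cd**2
        det = np.where(np.abs(det) < 1e-12, -1e-12, det)
        dc = (h_dd * g_c - h_cd * g_d) / det
        dd = (h_cc * g_d - h_cd * g_c) / det
        step = np.maximum(1.0, np.maximum(np.abs(dc), np.abs(dd)) / 2.0)
        c = c - dc / step
        d = d - dd / step
    return c, d


def fit_em(
    counts: np.ndarray,
    delta: float = 0.05,
    n_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
) -> tuple[PldsModel, np.ndarray]:
    """EM estimation of {a, c, d, sigma_eps} from a C x T count matrix.

    Returns (model, approximate log-likelihood trace of the best restart).
    """
    counts = np.atleast_2d(np.asarray(counts))
    C, T = counts.shape
    if C < 1:
        raise PldsError("need at least one unit")
    if T < 50:
        raise PldsError(f"need >= 50 bins, got {T}")
    rng = np.random.default_rng(seed)

    mean_counts = counts.mean(axis=1)
    d_init = np.log(np.maximum(mean_counts, 0.5 / T) / delta)
    # first principal direction of square-root-transformed smoothed counts
    root = np.sqrt(counts.astype(float))
    root -= root.mean(axis=1, keepdims=True)
    if C > 1:
        u, s, _ = np.linalg.svd(root, full_matrices=False)
        c_init0 = u[:, 0]
    else:
        c_init0 = np.ones(1)
    if c_init0.mean() < 0:
        c_init0 = -c_init0

    best: tuple[float, PldsModel, np.ndarray] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            c = c_init0.copy()
        else:
            c = rng.standard_normal(C)
            c /= np.linalg.norm(c)
            if c.mean() < 0:
                c = -c
        a, sig, d = 0.9, 0.1, d_init.copy()
        trace = []
        for _ in range(n_iter):
            m_f, q_f, m_p, q_p, ll = _laplace_filter(counts, a, c, d, sig, delta)
            if not np.isfinite(ll):
                raise PldsError("non-finite likelihood during EM")
            trace.append(ll)
            m_s, q_s, cov = _rts_smoother(m_f, q_f, m_p, q_p, a)
            # closed-form AR updates from the latent second moments
            e_zz = q_s + m_s**2
            s11 = e_zz[:-1].sum()
            s10 = (cov[:-1] + m_s[1:] * m_s[:-1]).sum()
            s00 = e_zz[1:].sum()
            a = float(np.clip(s10 / max(s11, 1e-12), -0.999, 0.999))
            sig2 = (s00 - 2 * a * s10 + a**2 * s11) / max(T - 1, 1)
            sig = float(np.sqrt(max(sig2, 1e-10)))
            c, d = _m_step_cd(counts, m_s, q_s, c, d, delta)
            # identifiability: ||c|| = 1, mean(c) >= 0, scale into sigma_eps
            scale = np.linalg.norm(c)
            if scale > 1e-12:
                c = c / scale
                sig = sig * scale
            if c.mean() < 0:
                c = -c
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
                break
        model = PldsModel(a=a, c=c, d=d, sigma_eps=sig, delta=delta)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model, np.asarray(trace))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# online filter and detection


def filter_forward(
    model: PldsModel,
    counts: np.ndarray,
    times: np.ndarray | None = None,
    baseline: tuple[float, float] = (-4.0, -1.0),
    ci_factor: float = 1.96,
    z0: float = 0.0,
    q0: float | None = None,
) -> FilterTrace:
    """Recursive (forward) filter with the one-step precision update.

    Implements exactly: prediction z_{t|t-1} = a z_{t-1|t-1},
    Q_{t|t-1} = a^2 Q_{t-1|t-1} + sigma_eps^2, predicted counts
    y_hat = exp(c z_{t|t-1} + d) delta, posterior precision
    Q_{t|t}^{-1} = Q_{t|t-1}^{-1} + c' diag(y_hat) c, and mean update
    z_{t|t} = z_{t|t-1} + Q_{t|t} c' (y_t - y_hat).

    ``times`` are bin end times (0 = event onset); the Z-score is computed
    against the empirical mean/SD of the filtered latent over the baseline
    bins, and the CI is z_{t|t} +- ci_factor * sqrt(Q_{t|t}), Z-scored.
    ``z0``/``q0`` set the initial state (default: zero mean, stationary
    variance).
    """
    counts = np.atleast_2d(np.asarray(counts))
    C, T = counts.shape
    if model.c.size != C:
        raise PldsError(f"model has {model.c.size} units, counts have {C}")
    if times is None:
        times = np.arange(1, T + 1) * model.delta
    times = np.asarray(times, dtype=float)

    a, c, d, delta = model.a, model.c, model.d, model.delta
    sig2 = model.sigma_eps**2
    z_f = np.empty(T)
    z_p = np.empty(T)
    q_f = np.empty(T)
    m_prev = z0
    q_prev = sig2 / (1.0 - a**2) if q0 is None else q0
    for t in range(T):
        mp = a * m_prev
        qp = a**2 * q_prev + sig2
        y_hat = np.exp(np.clip(c * mp + d, -50.0, 50.0)) * delta
        q_post = 1.0 / (1.0 / qp + np.sum(c**2 * y_hat))
        if q_post <= 0 or not np.isfinite(q_post):
            raise PldsError(f"non-positive filtered variance at bin {t}")
        m_post = mp + q_post * np.sum(c * (counts[:, t] - y_hat))
        z_p[t], z_f[t], q_f[t] = mp, m_post, q_post
        m_prev, q_prev = m_post, q_post

    b = (times >= baseline[0]) & (times <= baseline[1])
    if b.sum() < 2:
        raise PldsError(f"no baseline bins in [{baseline[0]}, {baseline[1]}] s")
    mu_b = z_f[b].mean()
    sd_b = z_f[b].std(ddof=0)
    if sd_b == 0:
        raise PldsError("degenerate baseline: zero SD of the filtered latent")
    zscore = (z_f - mu_b) / sd_b
    half = ci_factor * np.sqrt(q_f) / sd_b
    return FilterTrace(
        times=times,
        z_filt=z_f,
        z_pred=z_p,
        q_filt=q_f,
        zscore=zscore,
        ci_low=zscore - half,
        ci_high=zscore + half,
    )


def detect_onset(
    trace: FilterTrace,
    theta0: float = 1.65,
    search: tuple[float, float] | None = (0.0, np.inf),
) -> float | None:
    """First bin whose CI clears the significance threshold.

    Onset = first bin (within the search interval, default t > 0) at which
    the lower CI bound of the Z-score exceeds +theta0 (positive modulation)
    or the upper bound falls below -theta0 (negative modulation); None if
    the threshold is never crossed.  Updates ``trace.detection_time``.
    """
    lo, hi = search if search is not None else (-np.inf, np.inf)
    m = (trace.times > lo) & (trace.times <= hi)
    crossed = m & ((trace.ci_low > theta0) | (trace.ci_high < -theta0))
    idx = np.flatnonzero(crossed)
    trace.detection_time = float(trace.times[idx[0]]) if idx.size else None
    return trace.detection_time


def detection_erp_correlation(
    detection_latencies: np.ndarray, erp_latencies: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between detection latency and ERP peak latency."""
    x = np.asarray(detection_latencies, dtype=float)
    y = np.asarray(erp_latencies, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise PldsError(f"need >= 3 trials with both a detection and an ERP, got {keep.sum()}")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p)
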