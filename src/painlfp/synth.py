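"""Synthetic two-region (ACC/S1) session generator.

Emulates the statistical structure the downstream analyses assume, with
exported ground truth:

* LFP = 1/f background + theta oscillation + gamma carrier whose envelope is
  modulated by theta phase (controllable coupling depth and preferred phase)
  + biphasic event-related potentials injected at event times + white noise.
  Channels within a region share the oscillatory components and differ by
  independent noise.
* Spikes follow a Poisson linear dynamical system: a scalar AR(1) latent
  drives per-unit Poisson counts through an exponential link; evoked
  episodes step the latent mean up transiently.  Spike times are placed
  within bins, optionally biased toward a preferred theta phase
  (von Mises weighting).
* Sessions wire both together with a consistent event schedule: a pain-free
  lead-in (control windows), evoked trials with varied stimulus intensity,
  and spontaneous behavior events with smaller, probabilistic ERPs that lead
  in S1 by ~80 ms and a gamma-power increase confined to S1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import (
    RecordingSession,
    SessionError,
    SpikeTrain,
    make_event_table,
)


class ParameterError(ValueError):
    pass


class ScheduleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ERP template


def erp_template(fs: float, duration: float = 0.225, amplitude: float = 100.0,
                 trough_first: bool = True) -> tuple[np.ndarray, int]:
    """Biphasic difference-of-Gaussians ERP waveform.

    Trough-then-peak, normalized so the peak-to-trough amplitude equals
    ``amplitude`` (µV).  Returns (waveform, index of the trough), so callers
    can align the dominant deflection to an event time.
    """
    if not 0.05 <= duration <= 1.0:
        raise ParameterError(f"unreasonable ERP duration {duration} s")
    t = np.arange(int(round(duration * fs))) / fs
    t1, s1 = 0.35 * duration, 0.11 * duration
    t2, s2 = 0.68 * duration, 0.16 * duration
    w = -np.exp(-0.5 * ((t - t1) / s1) ** 2) + 0.65 * np.exp(-0.5 * ((t - t2) / s2) ** 2)
    w *= amplitude / (w.max() - w.min())
    if not trough_first:
        w = -w[::-1]
    return w, int(np.argmin(w))


# ---------------------------------------------------------------------------
# LFP generation


@dataclass
class LfpGenSpec:
    """Parameters of one region's LFP mixture (amplitudes in µV)."""

    duration: float = 60.0
    fs: float = 1000.0
    n_channels: int = 4
    background_1f_exponent: float = 1.0
    background_sd: float = 15.0
    theta_freq: float = 6.0
    theta_amp: float = 25.0
    gamma_freq: float = 50.0
    gamma_base_amp: float = 10.0
    pac_depth: float = 0.5
    pac_preferred_phase: float = 180.0
    erp_duration: float = 0.225
    erp_amp: float = 100.0
    erp_jitter_sd: float = 0.02
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ParameterError(f"pac_depth {self.pac_depth} outside [0, 1]")
        if self.fs < 200.0:
            raise ParameterError("fs must be >= 200 Hz")
        if not 0.0 <= self.pac_preferred_phase < 360.0:
            raise ParameterError("pac_preferred_phase must lie in [0, 360)")


def one_over_f_noise(n: int, fs: float, exponent: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise, power ∝ 1/f^exponent, DC removed."""
    white = rng.standard_normal(n)
    xf = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(xf * shape, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_lfp(spec: LfpGenSpec, events: pd.DataFrame | None = None,
                 gamma_gain: np.ndarray | None = None):
    """Generate one region's channels x time LFP matrix plus ground truth.

    ``events`` rows needing an ERP must carry columns ``event_id``,
    ``onset_s`` and optionally ``erp_amp`` (µV; defaults to ``spec.erp_amp``)
    and ``erp_prob`` (occurrence probability, default 1).  ``gamma_gain`` is
    an optional per-sample multiplier of the gamma envelope (models
    event-related gamma synchronization).

    Returns ``(lfp, truth)`` where ``truth`` holds injected ERP times
    (template trough), theta phase parameters, and the coupling depth/phase.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    theta_phase0 = rng.uniform(0.0, 2 * np.pi)
    theta_phase = 2 * np.pi * spec.theta_freq * t + theta_phase0
    theta = spec.theta_amp * np.cos(theta_phase)

    # gamma envelope modulated by the *noiseless* theta phase (ground truth)
    phi0 = np.deg2rad(spec.pac_preferred_phase)
    envelope = spec.gamma_base_amp * (1.0 + spec.pac_depth * np.cos(theta_phase - phi0))
    if gamma_gain is not None:
        if gamma_gain.shape != (n,):
            raise ParameterError("gamma_gain must match the sample count")
        envelope = envelope * gamma_gain
    gamma = envelope * np.cos(2 * np.pi * spec.gamma_freq * t + rng.uniform(0, 2 * np.pi))

    background = one_over_f_noise(n, spec.fs, spec.background_1f_exponent,
                                  spec.background_sd, rng)

    shared = background + theta + gamma
    erp_rows = []
    if events is not None and len(events):
        for _, row in events.iterrows():
            amp = float(row.get("erp_amp", spec.erp_amp))
            prob = float(row.get("erp_prob", 1.0))
            if rng.uniform() > prob:
                continue
            tc = float(row["onset_s"]) + rng.normal(0.0, spec.erp_jitter_sd)
            w, trough = erp_template(spec.fs, spec.erp_duration, amp)
            i0 = int(round(tc * spec.fs)) - trough
            lo, hi = max(i0, 0), min(i0 + w.size, n)
            if hi <= lo:
                continue
            shared[lo:hi] += w[lo - i0 : hi - i0]
            erp_rows.append({
                "event_id": str(row["event_id"]),
                "time_s": (i0 + trough) / spec.fs,
                "amplitude_uv": amp,
            })

    lfp = shared[None, :] + rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n))
    truth = {
        "erp": pd.DataFrame(erp_rows, columns=["event_id", "time_s", "amplitude_uv"]),
        "theta_freq": spec.theta_freq,
        "theta_phase0": theta_phase0,
        "pac_depth": spec.pac_depth,
        "pac_preferred_phase": spec.pac_preferred_phase,
    }
    return lfp.astype(np.float32), truth


def theta_phase_series(spec: LfpGenSpec, truth: dict, n: int) -> np.ndarray:
    """Ground-truth theta phase (radians) for n samples of a generated LFP."""
    t = np.arange(n) / spec.fs
    return 2 * np.pi * truth["theta_freq"] * t + truth["theta_phase0"]


# ---------------------------------------------------------------------------
# PLDS spike generation


@dataclass
class SpikeGenSpec:
    """Poisson linear dynamical system generator for one region's units.

    The scalar latent follows z_t = a z_{t-1} + eps_t with eps ~ N(0, sigma_eps^2);
    unit i fires y_it ~ Poisson(exp(c_i z_t + d_i) * delta) counts per bin.
    """

    n_units: int = 10
    a: float = 0.9
    sigma_eps: float = 0.2
    c: float | np.ndarray = 0.5
    d: float | np.ndarray = np.log(8.0)  # log rate in Hz; exp(d)*delta = base count
    delta: float = 0.05
    theta_locking_kappa: float = 0.0
    fraction_positive: float = 0.6
    fraction_negative: float = 0.2
    evoked_offset: float = 1.5
    evoked_duration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < abs(self.a) < 1.0:
            raise ParameterError(f"AR coefficient a={self.a} must satisfy 0 < |a| < 1")
        if self.delta <= 0:
            raise ParameterError("bin width delta must be positive")
        if self.sigma_eps <= 0:
            raise ParameterError("sigma_eps must be positive")

    def loadings(self, rng: np.random.Generator) -> np.ndarray:
        """Per-unit loadings: +|c|, -|c| or 0 by the modulated fractions."""
        if np.ndim(self.c) > 0:
            c = np.asarray(self.c, dtype=float)
            if c.size != self.n_units:
                raise ParameterError("c array length must equal n_units")
            return c
        n_pos = int(round(self.fraction_positive * self.n_units))
        n_neg = int(round(self.fraction_negative * self.n_units))
        signs = np.zeros(self.n_units)
        signs[:n_pos] = 1.0
        signs[n_pos : n_pos + n_neg] = -1.0
        rng.shuffle(signs)
        return signs * float(self.c)

    def log_rates(self) -> np.ndarray:
        d = np.asarray(self.d, dtype=float)
        return np.full(self.n_units, float(d)) if d.ndim == 0 else d


def simulate_latent(spec: SpikeGenSpec, n_bins: int, rng: np.random.Generator,
                    offset: np.ndarray | None = None) -> np.ndarray:
    """AR(1) latent with stationary start plus an additive mean offset."""
    z = np.empty(n_bins)
    stat_sd = spec.sigma_eps / np.sqrt(1.0 - spec.a**2)
    z[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, spec.sigma_eps, size=n_bins)
    for tt in range(1, n_bins):
        z[tt] = spec.a * z[tt - 1] + eps[tt]
    if offset is not None:
        z = z + offset
    return z


def _place_spikes(counts: np.ndarray, edges: np.ndarray, rng: np.random.Generator,
                  kappa: float = 0.0, phase_fn=None) -> np.ndarray:
    """Spike times for one unit from per-bin counts.

    With ``kappa > 0`` and a theta ``phase_fn`` (time -> radians), times within
    each bin are drawn with von Mises weights exp(kappa*cos(phase)), which
    phase-locks spikes without changing the counts."""
    if kappa <= 0.0 or phase_fn is None:
        reps = np.repeat(np.arange(counts.size), counts)
        times = edges[reps] + rng.uniform(0.0, 1.0, reps.size) * np.diff(edges)[reps]
        return np.sort(times)
    times = []
    grid_n = 16
    for k in np.flatnonzero(counts):
        sub = edges[k] + (np.arange(grid_n) + 0.5) * (edges[k + 1] - edges[k]) / grid_n
        w = np.exp(kappa * np.cos(phase_fn(sub)))
        w /= w.sum()
        picks = rng.choice(grid_n, size=counts[k], p=w)
        times.extend(sub[picks] + rng.uniform(-0.5, 0.5, counts[k])
                     * (edges[k + 1] - edges[k]) / grid_n)
    return np.sort(np.asarray(times))


def generate_spikes_plds(spec: SpikeGenSpec, modulation_schedule: pd.DataFrame | None = None,
                         duration: float | None = None, region: str = "ACC",
                         phase_fn=None, t0: float = 0.0):
    """Generate spike trains from the latent AR(1) Poisson model.

    ``modulation_schedule`` rows with columns ``onset_s`` (and optionally
    ``offset`` and ``duration``) step the latent mean up by
    ``spec.evoked_offset`` for ``spec.evoked_duration`` after each onset.

    Returns (list of SpikeTrain, truth dict with the latent path and
    parameters).
    """
    rng = np.random.default_rng(spec.seed)
    if duration is None:
        if modulation_schedule is None or not len(modulation_schedule):
            raise ParameterError("need a duration or a schedule")
        duration = float(modulation_schedule["onset_s"].max()) + spec.evoked_duration + 5.0
    n_bins = int(np.ceil(duration / spec.delta))
    edges = t0 + np.arange(n_bins + 1) * spec.delta
    centers = 0.5 * (edges[:-1] + edges[1:])

    offset = np.zeros(n_bins)
    if modulation_schedule is not None:
        for _, row in modulation_schedule.iterrows():
            amp = float(row.get("offset", spec.evoked_offset))
            dur = float(row.get("duration", spec.evoked_duration))
            on = t0 + float(row["onset_s"])
            offset[(centers >= on) & (centers < on + dur)] += amp

    z = simulate_latent(spec, n_bins, rng, offset)
    c = spec.loadings(rng)
    d = spec.log_rates()
    log_mu = c[:, None] * z[None, :] + d[:, None]
    if np.max(log_mu) > np.log(1e5):
        raise ParameterError(
            f"divergent rate: max exp(c z + d) = {np.exp(np.max(log_mu)):.3g} Hz; "
            "reduce |c|, d or the latent offset"
        )
    counts = rng.poisson(np.exp(log_mu) * spec.delta)

    trains = []
    for i in range(spec.n_units):
        times = _place_spikes(counts[i], edges, rng, spec.theta_locking_kappa, phase_fn)
        trains.append(SpikeTrain(f"{region}_u{i:02d}", region, times))
    truth = {
        "z": z,
        "bin_centers": centers,
        "a": spec.a,
        "c": c,
        "d": d,
        "sigma_eps": spec.sigma_eps,
        "delta": spec.delta,
        "offset": offset,
        "modulation_sign": np.sign(c).astype(int),
    }
    return trains, truth


# ---------------------------------------------------------------------------
# full session scenario


@dataclass
class Scenario:
    """A complete two-region session recipe.

    Defaults emulate one recording block: a pain-free lead-in used for
    control windows, 30 evoked trials (repeated noxious stimulations at
    varied intensity), and spontaneous pain-like events between trials with
    smaller, probabilistic ERPs that appear ~80 ms earlier in S1, plus a
    gamma-power increase confined to S1.
    """

    regions: tuple[str, ...] = ("ACC", "S1")
    fs: float = 1000.0
    n_channels: int = 4
    n_evoked: int = 30
    n_spontaneous: int = 10
    iti: float = 24.0
    control_lead: float = 60.0
    intensities_mw: tuple[float, ...] = (100.0, 150.0, 200.0, 250.0)
    # ERP structure
    evoked_erp_amp: float = 250.0
    spont_erp_amp: float = 150.0
    erp_latency_mean: float = 0.8
    erp_latency_intensity_gain: float = 0.4
    withdrawal_slope: float = 1.5
    withdrawal_noise_sd: float = 0.08
    spont_erp_prob: dict = field(default_factory=lambda: {"ACC": 0.9, "S1": 0.7})
    s1_lead: float = 0.08
    s1_lead_sd: float = 0.05
    # gamma event-related synchronization
    evoked_gamma_gain: float = 2.0
    spont_gamma_gain_s1: float = 1.8
    # LFP mixture and spikes
    lfp: LfpGenSpec = field(default_factory=LfpGenSpec)
    spikes: SpikeGenSpec = field(default_factory=SpikeGenSpec)
    spont_latent_offset: float = 0.8
    seed: int = 0


def _schedule(scn: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    if scn.n_spontaneous > scn.n_evoked:
        raise ScheduleError("at most one spontaneous event per inter-trial interval")
    rows = []
    t = scn.control_lead
    n_spont = 0
    for k in range(scn.n_evoked):
        onset = t + rng.uniform(-0.9, 0.9)
        intensity = scn.intensities_mw[k % len(scn.intensities_mw)]
        rows.append({"event_id": f"stim{k:03d}", "kind": "stimulus", "onset_s": onset,
                     "stimulus_intensity_mw": intensity})
        # spread the requested spontaneous events evenly across the ITIs
        if (k + 1) * scn.n_spontaneous // max(scn.n_evoked, 1) > n_spont:
            rows.append({"event_id": f"spont{n_spont:03d}", "kind": "spontaneous_behavior",
                         "onset_s": t + scn.iti / 2 + rng.uniform(-0.9, 0.9)})
            n_spont += 1
        t += scn.iti
    df = pd.DataFrame(rows).sort_values("onset_s").reset_index(drop=True)
    onsets = df["onset_s"].to_numpy()
    if np.any(np.diff(onsets) < 10.0):
        raise ScheduleError("episode windows overlap: onsets closer than 10 s")
    return df


def generate_session(scenario: Scenario | None = None, seed: int | None = None):
    """Build a full session from a scenario. Returns (RecordingSession, truth).

    ``truth`` maps: ``erp`` (region -> injected ERP table), ``plds`` (latent
    path and parameters), ``pac`` (region -> depth/phase), ``events``
    (the schedule with per-trial ERP latencies and amplitudes).
    """
    scn = scenario or Scenario()
    if seed is not None:
        scn = replace(scn, seed=seed)
    rng = np.random.default_rng(scn.seed)
    schedule = _schedule(scn, rng)
    # whole seconds so LFP samples and spike bins cover the same extent
    duration = float(np.ceil(schedule["onset_s"].max() + scn.iti))

    stim = schedule[schedule["kind"] == "stimulus"]
    spont = schedule[schedule["kind"] == "spontaneous_behavior"]

    # per-trial nociceptive drive (stimulus intensity + trial-to-trial state)
    # sets both the ERP: stronger drive -> shorter latency, larger amplitude;
    # withdrawal latency tracks the ERP latency, so it correlates positively
    # with ERP latency and negatively with ERP amplitude
    intens = stim["stimulus_intensity_mw"].to_numpy(float)
    rel_i = intens / np.max(intens)
    drive = rel_i + rng.normal(0.0, 0.15, len(stim))
    lat = np.clip(
        rng.normal(scn.erp_latency_mean, 0.05, len(stim))
        - scn.erp_latency_intensity_gain * (drive - drive.mean()),
        0.2, 3.0,
    )
    amp = scn.evoked_erp_amp * (0.6 + 0.4 * np.clip(drive, 0.0, 1.3)) \
        * np.exp(rng.normal(0.0, 0.05, len(stim)))
    withdrawal = scn.withdrawal_slope * lat + rng.normal(0.0, scn.withdrawal_noise_sd, len(stim))

    event_rows = []
    for j, (_, row) in enumerate(stim.iterrows()):
        event_rows.append({
            "event_id": row["event_id"], "kind": "stimulus", "onset_s": row["onset_s"],
            "paw_withdrawal_latency_s": withdrawal[j],
            "stimulus_intensity_mw": row["stimulus_intensity_mw"],
        })
    for _, row in spont.iterrows():
        event_rows.append({"event_id": row["event_id"], "kind": "spontaneous_behavior",
                           "onset_s": row["onset_s"]})
    n_controls = int(scn.control_lead // 10.0)
    for k in range(n_controls):
        event_rows.append({"event_id": f"ctrl{k:03d}", "kind": "control",
                           "onset_s": 5.0 + 10.0 * k})
    events = make_event_table(event_rows)

    n_samples = int(round(duration * scn.fs))
    region_lfp: dict[str, np.ndarray] = {}
    truth: dict = {"erp": {}, "pac": {}, "events": None, "scenario_seed": scn.seed}

    for ri, region in enumerate(scn.regions):
        erp_events = []
        # S1 responds earlier than ACC in both conditions
        for j, (_, row) in enumerate(stim.iterrows()):
            lead = scn.s1_lead + rng.normal(0.0, scn.s1_lead_sd) if region == "S1" else 0.0
            erp_events.append({"event_id": row["event_id"],
                               "onset_s": row["onset_s"] + max(lat[j] - lead, 0.1),
                               "erp_amp": amp[j], "erp_prob": 1.0})
        for _, row in spont.iterrows():
            lead = scn.s1_lead + rng.normal(0.0, scn.s1_lead_sd) if region == "S1" else 0.0
            erp_events.append({"event_id": row["event_id"],
                               "onset_s": row["onset_s"] - lead,
                               "erp_amp": scn.spont_erp_amp,
                               "erp_prob": scn.spont_erp_prob.get(region, 1.0)})
        erp_events = pd.DataFrame(erp_events)

        gain = np.ones(n_samples)
        tax = np.arange(n_samples) / scn.fs
        for _, row in stim.iterrows():
            m = (tax >= row["onset_s"]) & (tax < row["onset_s"] + 3.0)
            gain[m] = scn.evoked_gamma_gain
        if region == "S1":
            for _, row in spont.iterrows():
                m = (tax >= row["onset_s"]) & (tax < row["onset_s"] + 3.0)
                gain[m] = scn.spont_gamma_gain_s1

        lspec = replace(scn.lfp, duration=duration, fs=scn.fs,
                        n_channels=scn.n_channels, seed=scn.seed + 101 + ri)
        lfp, ltruth = generate_lfp(lspec, erp_events, gamma_gain=gain)
        region_lfp[region] = lfp
        truth["erp"][region] = ltruth["erp"]
        truth["pac"][region] = {k: ltruth[k] for k in
                                ("pac_depth", "pac_preferred_phase",
                                 "theta_freq", "theta_phase0")}

    # spike schedule: latent step jittered together with the evoked ERP time,
    # step size co-varying with the ERP amplitude
    mod_rows = []
    for j, (_, row) in enumerate(stim.iterrows()):
        mod_rows.append({"onset_s": row["onset_s"] + max(lat[j] - 0.5, 0.0),
                         "offset": scn.spikes.evoked_offset * amp[j] / amp.mean(),
                         "duration": scn.spikes.evoked_duration})
    for _, row in spont.iterrows():
        mod_rows.append({"onset_s": row["onset_s"],
                         "offset": scn.spont_latent_offset,
                         "duration": scn.spikes.evoked_duration})
    mod = pd.DataFrame(mod_rows)

    spikes = []
    truth["plds"] = {}
    for ri, region in enumerate(scn.regions if scn.spikes.n_units > 0 else ()):
        sspec = replace(scn.spikes, seed=scn.seed + 301 + ri)
        pac = truth["pac"][region]
        phase_fn = (lambda tt, p=pac: 2 * np.pi * p["theta_freq"] * tt + p["theta_phase0"])
        trains, struth = generate_spikes_plds(sspec, mod, duration=duration,
                                              region=region, phase_fn=phase_fn)
        spikes.extend(trains)
        truth["plds"][region] = struth

    ev_truth = events.merge(
        pd.DataFrame({"event_id": stim["event_id"].to_numpy(),
                      "erp_latency_s": lat, "erp_amp_uv": amp}),
        on="event_id", how="left")
    truth["events"] = ev_truth

    try:
        sess = RecordingSession(
            region_lfp=region_lfp, fs_lfp=scn.fs, spikes=spikes, events=events,
            t0=0.0, provenance={"generator": "painlfp.synth", "seed": scn.seed},
        )
    except SessionError:
        raise
    return sess, truth
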