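"""Synthetic participants: cosine-tuned Poisson channels with a click state.

This module stands in for a human user's motor cortex.  Each simulated
participant is a bank of recording channels whose expected 15-ms binned
threshold-crossing count follows linear cosine tuning to intended cursor
velocity,

    rate_c = baseline_c + drift_c + depth_c * (u_c . v) + click_shift_c * [click],

where ``u_c`` is the channel's preferred direction on the unit circle and
``v`` the intended velocity in workspace units/s.  Rates are rectified at
zero before Poisson (or Gaussian) noise is applied.  An HF-LFP-like power
feature is generated from the same drive through a per-channel gain, so the
two feature families co-modulate the way band power and multiunit spiking do
on a real array.

Slow nonstationarity — the baseline drift that motivates online bias
correction and per-block baseline re-estimation — is modelled as an
Ornstein-Uhlenbeck random walk on per-channel baselines, updated once per
bin.  With ``drift_sigma = 0`` the generator is exactly stationary.

Everything is driven by explicit ``numpy.random.Generator`` state, so any
stream is bit-for-bit reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import BIN_WIDTH_S, BinnedFeatures

BROADBAND_FS = 30_000


class ConfigurationError(ValueError):
    """Raised when generator or decoder settings are internally inconsistent."""


@dataclass(frozen=True)
class SyntheticParticipant:
    """Generative model of one simulated user.

    ``preferred_direction`` is in radians; ``modulation_depth``,
    ``baseline_rate`` and ``click_shift`` are in counts per 15-ms bin (depth
    per unit speed); ``lfp_gain`` couples the HF-LFP feature to the same
    drive; ``drift_theta``/``drift_sigma`` are the per-bin OU mean-reversion
    rate and innovation s.d. on the baselines.
    """

    n_channels: int
    preferred_direction: np.ndarray
    modulation_depth: np.ndarray
    baseline_rate: np.ndarray
    click_shift: np.ndarray
    lfp_gain: np.ndarray
    hf_noise_sd: float = 0.5
    drift_sigma: float = 0.0
    drift_theta: float = 5e-5
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        for name in ("preferred_direction", "modulation_depth", "baseline_rate",
                     "click_shift", "lfp_gain"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_channels,):
                raise ConfigurationError(f"{name} must have shape ({self.n_channels},)")
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} must be finite")
            object.__setattr__(self, name, arr)
        if np.any(self.baseline_rate < 0):
            raise ConfigurationError("baseline_rate must be non-negative")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ConfigurationError("noise_model must be 'poisson' or 'gaussian'")

    @property
    def tuning_vectors(self) -> np.ndarray:
        """(C, 2) unit preferred-direction vectors."""
        return np.column_stack(
            [np.cos(self.preferred_direction), np.sin(self.preferred_direction)]
        )


@dataclass(frozen=True)
class IntentState:
    """Latent drive the decoders estimate for one bin."""

    intended_velocity: np.ndarray  # (2,) workspace units/s
    click_intent: bool
    timestamp: float  # s


def make_participant(config: dict | None = None, seed: int = 0, **kwargs) -> SyntheticParticipant:
    """Draw a simulated participant from generator settings.

    Settings (``config`` dict entries or keyword arguments):

    - ``n_channels`` (default 96)
    - ``modulation_depth`` — mean tuning depth, counts/bin per unit speed
      (default 1.5); per-channel depths are jittered uniformly by
      ``depth_jitter`` (fraction, default 0.3) unless ``depths`` is given.
    - ``baseline_rate`` — mean counts/bin at rest (default 1.0), jittered
      by ``baseline_jitter`` (default 0.3) unless ``baselines`` is given.
    - ``click_fraction`` — fraction of channels carrying the click-state
      mean shift (default 0.25); ``click_shift`` its magnitude (default 0.6).
    - ``preferred_directions`` — optional explicit angles; otherwise drawn
      uniformly on the circle.
    - ``lfp_gain`` (default 1.0), ``hf_noise_sd`` (default 0.5),
      ``drift_sigma`` (default 0.0), ``drift_theta`` (default 5e-5),
      ``noise_model`` (default "poisson").
    """
    cfg = dict(config or {})
    cfg.update(kwargs)
    n = int(cfg.get("n_channels", 96))
    if n < 2:
        raise ConfigurationError("n_channels must be >= 2")
    rng = np.random.default_rng(seed)

    if "preferred_directions" in cfg and cfg["preferred_directions"] is not None:
        pd_ = np.asarray(cfg["preferred_directions"], dtype=float)
    else:
        pd_ = rng.uniform(0.0, 2.0 * np.pi, size=n)

    depth = float(cfg.get("modulation_depth", 1.5))
    jit = float(cfg.get("depth_jitter", 0.3))
    if "depths" in cfg and cfg["depths"] is not None:
        depths = np.asarray(cfg["depths"], dtype=float)
    else:
        depths = depth * rng.uniform(1.0 - jit, 1.0 + jit, size=n)

    base = float(cfg.get("baseline_rate", 1.0))
    if base < 0:
        raise ConfigurationError("baseline_rate must be non-negative")
    bjit = float(cfg.get("baseline_jitter", 0.3))
    if "baselines" in cfg and cfg["baselines"] is not None:
        baselines = np.asarray(cfg["baselines"], dtype=float)
    else:
        baselines = base * rng.uniform(1.0 - bjit, 1.0 + bjit, size=n)

    frac = float(cfg.get("click_fraction", 0.25))
    shift = float(cfg.get("click_shift", 0.6))
    click = np.zeros(n)
    n_click = int(round(frac * n))
    if n_click > 0 and shift != 0.0:
        idx = rng.choice(n, size=n_click, replace=False)
        click[idx] = shift

    gain = np.full(n, float(cfg.get("lfp_gain", 1.0)))

    return SyntheticParticipant(
        n_channels=n,
        preferred_direction=pd_,
        modulation_depth=depths,
        baseline_rate=baselines,
        click_shift=click,
        lfp_gain=gain,
        hf_noise_sd=float(cfg.get("hf_noise_sd", 0.5)),
        drift_sigma=float(cfg.get("drift_sigma", 0.0)),
        drift_theta=float(cfg.get("drift_theta", 5e-5)),
        noise_model=str(cfg.get("noise_model", "poisson")),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Encoding


def expected_rates(
    p: SyntheticParticipant,
    velocity: np.ndarray,
    click_intent: bool | np.ndarray,
    drift: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Pre-noise expected counts per channel; rectified at zero.

    ``velocity`` may be (2,) for one bin or (T, 2) for a stream;
    ``click_intent`` a bool or a (T,) bool array; ``drift`` a (C,) offset or
    a (T, C) path.
    """
    v = np.asarray(velocity, dtype=float)
    u = p.tuning_vectors  # (C, 2)
    if v.ndim == 1:
        drive = p.baseline_rate + drift + p.modulation_depth * (u @ v)
        if click_intent:
            drive = drive + p.click_shift
    else:
        drive = (
            p.baseline_rate
            + np.atleast_2d(drift)
            + p.modulation_depth * (v @ u.T)
        )
        ci = np.asarray(click_intent, dtype=bool)
        drive = drive + np.outer(ci, p.click_shift)
    return np.maximum(drive, 0.0)


class DriftState:
    """Per-channel OU baseline drift, advanced once per 15-ms bin."""

    def __init__(self, p: SyntheticParticipant, rng: np.random.Generator):
        self.offsets = np.zeros(p.n_channels)
        self._theta = p.drift_theta
        self._sigma = p.drift_sigma
        self._rng = rng

    def step(self) -> np.ndarray:
        if self._sigma > 0.0:
            self.offsets += (
                -self._theta * self.offsets
                + self._sigma * self._rng.standard_normal(self.offsets.shape)
            )
        return self.offsets


def _sample_features(
    p: SyntheticParticipant,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the noise model to rectified rates; returns (counts, hf_power)."""
    if p.noise_model == "poisson":
        counts = rng.poisson(rates)
    else:
        counts = np.maximum(rates + rng.standard_normal(rates.shape) * np.sqrt(
            np.maximum(rates, 1e-12)), 0.0)
    hf = p.lfp_gain * rates + p.hf_noise_sd * rng.standard_normal(rates.shape)
    return counts, np.maximum(hf, 0.0)


def encode_bin(
    p: SyntheticParticipant,
    s: IntentState,
    drift_state: np.ndarray | float = 0.0,
    rng: np.random.Generator | None = None,
) -> BinnedFeatures:
    """Generate one 15-ms bin of features for one intent state."""
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    rates = expected_rates(p, s.intended_velocity, s.click_intent, drift_state)
    counts, hf = _sample_features(p, rates, rng)
    return BinnedFeatures(
        timestamps=np.array([s.timestamp]),
        crossings=counts[None, :],
        hf_power=hf[None, :],
    )


def encode_stream(
    p: SyntheticParticipant,
    velocities: np.ndarray,
    click_intents: np.ndarray,
    rng: np.random.Generator,
    t0: float = 0.0,
    drift_state: DriftState | None = None,
) -> BinnedFeatures:
    """Vectorised encoding of a whole intent stream (one row per bin)."""
    v = np.asarray(velocities, dtype=float)
    ci = np.asarray(click_intents, dtype=bool)
    T = v.shape[0]
    if drift_state is not None and drift_state._sigma > 0.0:
        drift = np.empty((T, p.n_channels))
        for t in range(T):
            drift[t] = drift_state.step()
    else:
        drift = np.zeros((1, p.n_channels))
        if drift_state is not None:
            drift = drift + drift_state.offsets
    rates = expected_rates(p, v, ci, drift)
    counts, hf = _sample_features(p, rates, rng)
    ts = t0 + BIN_WIDTH_S * np.arange(T)
    return BinnedFeatures(timestamps=ts, crossings=counts, hf_power=hf)


# ---------------------------------------------------------------------------
# Open-loop calibration trajectories


@dataclass(frozen=True)
class OpenLoopBlock:
    features: BinnedFeatures
    velocities: np.ndarray      # (T, 2) programmed intent velocity
    click_intents: np.ndarray   # (T,) bool
    positions: np.ndarray       # (T, 2) programmed cursor position
    target_positions: np.ndarray  # (T, 2) active target centre per bin


def center_out_trajectory(
    n_targets: int = 8,
    radius: float = 0.8,
    leg_duration_s: float = 0.5,
    hold_duration_s: float = 0.5,
    n_repeats: int = 8,
    with_click: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pre-programmed centre-out-and-back cursor path.

    Returns per-bin (velocities, click_intents, positions, target_positions).
    Each trial is an outbound leg to one of ``n_targets`` radial targets, a
    hold at the target (click intent high when ``with_click``), a return leg
    to the centre and a centre hold.
    """
    if n_targets < 1 or n_repeats < 1:
        raise ConfigurationError("empty trajectory")
    leg_bins = int(round(leg_duration_s / BIN_WIDTH_S))
    hold_bins = int(round(hold_duration_s / BIN_WIDTH_S))
    speed = radius / leg_duration_s
    angles = 2.0 * np.pi * np.arange(n_targets) / n_targets

    vel, click, pos, tgt = [], [], [], []
    cur = np.zeros(2)
    for rep in range(n_repeats):
        for ang in angles:
            u = np.array([np.cos(ang), np.sin(ang)])
            target = radius * u
            # outbound
            for k in range(leg_bins):
                vel.append(speed * u)
                click.append(False)
                pos.append(cur + speed * u * BIN_WIDTH_S * k)
                tgt.append(target)
            cur = target
            # hold at target (attempted selection)
            for _ in range(hold_bins):
                vel.append(np.zeros(2))
                click.append(bool(with_click))
                pos.append(cur.copy())
                tgt.append(target)
            # return
            for k in range(leg_bins):
                vel.append(-speed * u)
                click.append(False)
                pos.append(cur - speed * u * BIN_WIDTH_S * k)
                tgt.append(np.zeros(2))
            cur = np.zeros(2)
            for _ in range(hold_bins):
                vel.append(np.zeros(2))
                click.append(False)
                pos.append(cur.copy())
                tgt.append(np.zeros(2))
    return (np.array(vel), np.array(click, dtype=bool),
            np.array(pos), np.array(tgt))


def simulate_open_loop_block(
    p: SyntheticParticipant,
    trajectory: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    drift_state: DriftState | None = None,
    with_click: bool = True,
    n_repeats: int = 8,
) -> OpenLoopBlock:
    """Open-loop calibration block: programmed cursor, mirrored intent.

    The intent stream mirrors the programmed cursor velocity exactly, and
    click intent is high during the programmed hold epochs, emulating an
    attempted hand squeeze over the target.
    """
    if trajectory is None:
        trajectory = center_out_trajectory(with_click=with_click, n_repeats=n_repeats)
    vel, click, pos, tgt = trajectory
    if len(vel) == 0:
        raise ConfigurationError("empty trajectory")
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    feats = encode_stream(p, vel, click, rng, drift_state=drift_state)
    return OpenLoopBlock(feats, vel, click, pos, tgt)


# ---------------------------------------------------------------------------
# Optional raw-broadband synthesis (fixture path for the signal chain)


@dataclass
class BroadbandSegment:
    """channels x samples voltage segment at 30 kS/s, in microvolts."""

    data: np.ndarray
    fs: int
    spike_counts: np.ndarray | None = None  # (T_bins, C) injected counts


def spike_template(fs: int = BROADBAND_FS, amplitude_uv: float = -120.0) -> np.ndarray:
    """Biphasic ~1-ms extracellular spike shape, peak at ``amplitude_uv``."""
    t = np.arange(int(0.001 * fs))
    w = np.exp(-((t - 9.0) ** 2) / (2 * 2.5 ** 2)) - 0.4 * np.exp(
        -((t - 18.0) ** 2) / (2 * 5.0 ** 2)
    )
    return amplitude_uv * w / np.max(np.abs(w))


def simulate_broadband(
    p: SyntheticParticipant,
    intents: list[IntentState] | None = None,
    fs: int = BROADBAND_FS,
    rng: np.random.Generator | None = None,
    noise_rms_uv: float = 10.0,
    common_mode_uv: float = 0.0,
    common_mode_hz: float = 60.0,
    spike_amplitude_uv: float = -120.0,
    duration_s: float | None = None,
) -> BroadbandSegment:
    """Synthesize raw voltage with injected spikes, noise and common mode.

    Spike-shaped transients are injected at per-bin counts drawn from the
    participant's tuned rates (or at baseline rates when ``intents`` is
    ``None`` and ``duration_s`` is given).  All channels share a common-mode
    sinusoid of amplitude ``common_mode_uv`` so the common-average reference
    stage can be exercised.  ``noise_rms_uv = 0`` gives a noise-free segment
    for exact round-trip tests.
    """
    if fs != BROADBAND_FS:
        raise ConfigurationError(f"signal chain is specified at {BROADBAND_FS} S/s")
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    if intents is not None:
        T = len(intents)
        vel = np.array([s.intended_velocity for s in intents], dtype=float)
        clicks = np.array([s.click_intent for s in intents], dtype=bool)
    else:
        if duration_s is None or duration_s < 0.1:
            raise ConfigurationError("duration must be >= 100 ms")
        T = int(round(duration_s / BIN_WIDTH_S))
        vel = np.zeros((T, 2))
        clicks = np.zeros(T, dtype=bool)
    rates = expected_rates(p, vel, clicks)
    counts = rng.poisson(rates)  # (T, C)

    bin_samples = int(BIN_WIDTH_S * fs)
    n_samples = T * bin_samples
    data = noise_rms_uv * rng.standard_normal((p.n_channels, n_samples))
    if common_mode_uv != 0.0:
        t = np.arange(n_samples) / fs
        data += common_mode_uv * np.sin(2 * np.pi * common_mode_hz * t)[None, :]

    tmpl = spike_template(fs, spike_amplitude_uv)
    L = len(tmpl)
    win_samples = fs // 1000  # 1-ms detector windows
    wins_per_bin = bin_samples // win_samples
    # the presence detector reports at most one event per 1-ms window, so
    # injected counts are capped and each event is aligned to a window start
    counts = np.minimum(counts, wins_per_bin)
    for c in range(p.n_channels):
        for b in range(T):
            k = counts[b, c]
            if k == 0:
                continue
            wins = rng.choice(wins_per_bin, size=k, replace=False)
            for w in wins:
                s0 = (b * wins_per_bin + w) * win_samples
                end = min(s0 + L, n_samples)
                data[c, s0:end] += tmpl[: end - s0]
    return BroadbandSegment(data=data, fs=fs, spike_counts=counts)
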