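"""Closed-loop session orchestration: calibrate, run blocksets, score.

A session reproduces the evaluation protocol end to end with a synthetic
participant in place of a human:

1. a 30-s rest recording sets per-feature baselines;
2. an open-loop centre-out-and-back block (programmed cursor, mirrored
   intent) calibrates feature selection, the velocity Kalman filter, and the
   PCA/HMM click decoder;
3. a closed-loop recalibration block (optionally with error attenuation)
   relabels decoded velocities with target-directed intention and refits
   both decoders; the click threshold is set at the 93rd quantile of the
   click posterior over this block and the bias speed gate at a low quantile
   of its decoded speeds;
4. blocksets follow: each begins with a recalibration block (refit decoders)
   or a bias/baseline update block, then three two-minute evaluation blocks
   (grid + two copy-typing tasks) in randomized order with the copy-typing
   blocks adjacent.

The simulated user is a saturating proportional feedback controller with a
reaction delay and angular motor noise: intent always points from the cursor
toward the cued target, is zero while hovering over it, and click intent
turns on after a configurable hover duration (click-enabled profiles only).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BIN_WIDTH_S
from .hmm import ClickDetector, HMMParams, StateProbs, calibrate_click_threshold, \
    fit_click_decoder, forward_filter, hmm_step
from .kalman import BiasState, CalibrationError, KalmanDecoder, KalmanParams, \
    apply_bias, fit_kalman, integrate_position, refit_relabel, select_features, \
    speed_gate_from_calibration, update_bias
from .metrics import BlockResult, score_block
from .synthetic import ConfigurationError, DriftState, IntentState, \
    SyntheticParticipant, encode_stream, expected_rates, make_participant, \
    simulate_open_loop_block
from .tasks import GRID_BLOCK, SelectionEvent, SelectionRule, TaskLayout, Target, \
    draw_blockset_order, make_grid_layout, make_keyboard_layout, run_copy_typing_block, \
    run_grid_block

MS_PER_TICK = 15
INTEGRATIONS_PER_BIN = 15
DT_MS = 0.001

DEFAULT_SENTENCES = [
    "the quick brown fox jumps over the lazy dog",
    "pack my box with five dozen liquid jugs",
    "how vexingly quick daft zebras jump",
    "a glib jazz fan owns the complex words",
    "we promptly judged the five boxing wizards",
    "sixty zippers were quickly picked from the box",
    "the job requires extra pluck and zeal",
]


@dataclass(frozen=True)
class SimulatedUserPolicy:
    """Feedback-control stand-in for the human: saturating proportional intent.

    ``gain`` is intent speed per unit distance (units/s per unit), saturated
    at ``max_speed``; ``reaction_delay_s`` lags the cue the controller acts
    on; ``motor_noise_sd`` is angular jitter (radians) applied to the intent
    direction; click intent turns on after ``click_hold_s`` of hovering over
    the cued target when ``click_enabled``.
    """

    reaction_delay_s: float = 0.2
    gain: float = 4.0
    max_speed: float = 1.5
    motor_noise_sd: float = 0.12
    click_enabled: bool = True
    click_hold_s: float = 0.3
    click_pulse_s: float = 0.25   # duration of one attempted squeeze
    click_gap_s: float = 0.35     # pause before re-squeezing if nothing happened
    settle_fraction: float = 0.5  # stop driving within this fraction of the
    # target inradius from its centre (humans aim at the middle, not the edge)


def simulated_user_step(
    policy: SimulatedUserPolicy,
    cursor: np.ndarray,
    cued_target: Target,
    hover_time_s: float,
    rng: np.random.Generator,
    timestamp: float = 0.0,
) -> IntentState:
    """One bin of simulated intent toward the (possibly delayed) cue."""
    x0, y0, x1, y1 = cued_target.rect
    settle = policy.settle_fraction * 0.5 * min(x1 - x0, y1 - y0)
    d = cued_target.center - cursor
    dist = float(np.hypot(d[0], d[1]))
    # attempted squeezes come in bounded pulses: squeeze for click_pulse_s,
    # release, and retry after click_gap_s if no selection resulted
    h = hover_time_s - policy.click_hold_s
    click = (policy.click_enabled and cued_target.contains(cursor) and h >= 0.0
             and (h % (policy.click_pulse_s + policy.click_gap_s)) < policy.click_pulse_s)
    if dist < settle:
        v = np.zeros(2)
    else:
        speed = min(policy.max_speed, policy.gain * dist)
        ang = math.atan2(d[1], d[0]) + policy.motor_noise_sd * rng.standard_normal()
        v = speed * np.array([math.cos(ang), math.sin(ang)])
    return IntentState(intended_velocity=v, click_intent=bool(click),
                       timestamp=timestamp)


@dataclass
class SessionConfig:
    """One simulated participant-and-protocol recipe.

    The three shipped profiles mirror the per-participant decoder and task
    configurations: feature families per decoder, dwell time and mode, bias
    estimation, recentering, and whether blocksets refit the decoders or
    only update the bias estimate.
    """

    participant: dict = field(default_factory=dict)
    kalman_features: str = "spikes"       # spikes | hf | both
    hmm_features: str | None = "spikes"   # None -> no click decoder
    rule: SelectionRule = field(default_factory=SelectionRule)
    policy: SimulatedUserPolicy = field(default_factory=SimulatedUserPolicy)
    bias_correction: bool = True
    recalibrate_each_blockset: bool = False
    reestimate_baseline: bool = True
    error_attenuation: float | None = None   # perpendicular-error scale in [0,1]
    grid_n: int = 6
    keyboards: tuple[str, str] = ("opti2", "qwerty")
    sentences: list[str] = field(default_factory=lambda: list(DEFAULT_SENTENCES))
    n_blocksets: int = 3
    block_duration_s: float = 120.0
    calib_repeats: int = 6
    recalib_repeats: int = 4
    grid_trial_timeout_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_attenuation is not None and not (0.0 <= self.error_attenuation <= 1.0):
            raise ConfigurationError("error attenuation must lie in [0, 1]")

    @classmethod
    def profile(cls, name: str, seed: int = 0, **overrides) -> "SessionConfig":
        """Shipped decoder/protocol profiles.

        ``hybrid_refit``: hybrid spike+HF-LFP cursor features, HF-LFP click
        decoder, full decoder refit each blockset, error attenuation.
        ``dwell_recenter``: spikes only, no click decoder, 1.5-s cumulative
        dwell, recentering, bias correction, baseline drift enabled.
        ``spikes_click`` (the default elsewhere): spikes only for both
        decoders, 1-s reset dwell plus click, bias correction.
        """
        profiles = {
            # hybrid features, HMM on HF-LFP, 1-s reset dwell, no bias/recenter,
            # full decoder refit each blockset, error attenuation on
            "hybrid_refit": dict(kalman_features="both", hmm_features="hf",
                       rule=SelectionRule(mode="dwell_reset", dwell_required_s=1.0,
                                          click_enabled=True, recenter=False),
                       bias_correction=False, recalibrate_each_blockset=True,
                       error_attenuation=0.5),
            # spikes only, no click decoder, 1.5-s cumulative dwell, bias + recenter,
            # bias-update-only blocksets, error attenuation on, baseline drift on
            "dwell_recenter": dict(kalman_features="spikes", hmm_features=None,
                       rule=SelectionRule(mode="dwell_cumulative", dwell_required_s=1.5,
                                          click_enabled=False, recenter=True),
                       policy=SimulatedUserPolicy(click_enabled=False),
                       bias_correction=True, recalibrate_each_blockset=False,
                       error_attenuation=0.5,
                       participant={"drift_sigma": 0.003},
                       keyboards=("opti2", "abcdef")),
            # spikes only, HMM on spikes, 1-s reset dwell, bias on, no recenter,
            # bias-update-only blocksets, no error attenuation
            "spikes_click": dict(kalman_features="spikes", hmm_features="spikes",
                       rule=SelectionRule(mode="dwell_reset", dwell_required_s=1.0,
                                          click_enabled=True, recenter=False),
                       bias_correction=True, recalibrate_each_blockset=False,
                       error_attenuation=None),
        }
        if name not in profiles:
            raise ConfigurationError(f"unknown profile {name!r}")
        kw = dict(profiles[name])
        kw.update(overrides)
        return cls(seed=seed, **kw)

    def to_yaml(self, path: str) -> None:
        import dataclasses

        import yaml
        d = dataclasses.asdict(self)
        d["keyboards"] = list(d["keyboards"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SessionConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "rule" in d:
            d["rule"] = SelectionRule(**d["rule"])
        if "policy" in d:
            d["policy"] = SimulatedUserPolicy(**d["policy"])
        if "keyboards" in d:
            d["keyboards"] = tuple(d["keyboards"])
        return cls(**d)


@dataclass
class Decoders:
    """Fitted decoder bundle held fixed (bar bias updates) across blocksets."""

    baseline: np.ndarray
    kalman: KalmanParams
    hmm: HMMParams | None
    speed_gate: float
    heading_error_deg: float  # median closed-loop heading error at calibration

    def to_json(self) -> str:
        import json
        return json.dumps({
            "schema": "bcisim.decoders.v1",
            "baseline": self.baseline.tolist(),
            "kalman": self.kalman.to_json(),
            "hmm": None if self.hmm is None else self.hmm.to_json(),
            "speed_gate": self.speed_gate,
            "heading_error_deg": self.heading_error_deg,
        })

    @classmethod
    def from_json(cls, text: str) -> "Decoders":
        import json
        d = json.loads(text)
        if d.get("schema") != "bcisim.decoders.v1":
            raise ValueError("unrecognised decoder bundle schema")
        return cls(
            baseline=np.array(d["baseline"]),
            kalman=KalmanParams.from_json(d["kalman"]),
            hmm=None if d["hmm"] is None else HMMParams.from_json(d["hmm"]),
            speed_gate=float(d["speed_gate"]),
            heading_error_deg=float(d["heading_error_deg"]),
        )


# ---------------------------------------------------------------------------
# Closed-loop engine


class ClosedLoopEngine:
    """The simulated plant: intent -> features -> decoders -> cursor.

    Implements the task Environment protocol (``tick`` / ``set_position``).
    One engine persists for a whole session so drift, bias and HMM state
    carry across blocks the way they do in a real session.
    """

    def __init__(
        self,
        participant: SyntheticParticipant,
        decoders: Decoders,
        config: SessionConfig,
        rng: np.random.Generator,
        bounds: tuple[float, float, float, float] = (-1.0, -1.0, 1.0, 1.0),
    ):
        self.p = participant
        self.decoders = decoders
        self.config = config
        self.rng = rng
        self.bounds = bounds
        self.position = np.zeros(2)
        self.drift = DriftState(participant, rng)
        self.kalman = KalmanDecoder(decoders.kalman)
        self.bias = BiasState(speed_threshold=decoders.speed_gate)
        self.hmm_state = StateProbs(0.5, 0.5)
        self.clicker = (
            ClickDetector(decoders.hmm.click_threshold,
                          decoders.hmm.consecutive_bins_required)
            if decoders.hmm is not None else None
        )
        self.injected_bias = np.zeros(2)  # test hook: constant decoded-velocity offset
        self.attenuation: float | None = None
        self._hover_bins = 0
        self._cue_buffer: deque[Target] = deque(maxlen=max(
            1, int(round(config.policy.reaction_delay_s / BIN_WIDTH_S))))
        self._time_s = 0.0
        # per-block recording for recalibration fits
        self.recording: dict[str, list] | None = None

    # -- Environment protocol -------------------------------------------------

    def set_position(self, position: np.ndarray) -> None:
        self.position = np.asarray(position, dtype=float).copy()

    def notify_selection(self) -> None:
        """Selection feedback (the beep): the user releases the squeeze."""
        self._hover_bins = 0

    def tick(self, cue: Target, layout: TaskLayout) -> tuple[np.ndarray, bool]:
        """Advance one 15-ms bin; returns (cursor position, click fired)."""
        self._cue_buffer.append(cue)
        active = self._cue_buffer[0]  # reaction-delayed cue
        if active.contains(self.position):
            self._hover_bins += 1
        else:
            self._hover_bins = 0
        intent = simulated_user_step(
            self.config.policy, self.position, active,
            self._hover_bins * BIN_WIDTH_S, self.rng, self._time_s,
        )
        # participant encodes the intent into one bin of features
        drift = self.drift.step()
        rates = expected_rates(self.p, intent.intended_velocity,
                               intent.click_intent, drift)
        if self.p.noise_model == "poisson":
            counts = self.rng.poisson(rates)
        else:
            counts = np.maximum(
                rates + self.rng.standard_normal(rates.shape)
                * np.sqrt(np.maximum(rates, 1e-12)), 0.0)
        hf = np.maximum(
            self.p.lfp_gain * rates
            + self.p.hf_noise_sd * self.rng.standard_normal(rates.shape), 0.0)
        full = np.concatenate([counts.astype(float), hf]) - self.decoders.baseline

        # continuous decode
        z = full[self.decoders.kalman.selected_features]
        V = self.kalman.step(z) + self.injected_bias
        if self.attenuation is not None:
            V = _attenuate_error(V, self.position, active.center, self.attenuation)

        # discrete decode
        clicked = False
        p_click = 0.0
        if self.decoders.hmm is not None:
            fam = _family_slice(self.p.n_channels, self.config.hmm_features)
            y = self.decoders.hmm.projection.transform(
                full[fam] + self.decoders.baseline[fam])[0]
            self.hmm_state = hmm_step(self.decoders.hmm, y, self.hmm_state)
            p_click = self.hmm_state.p_click
            if self.clicker is not None:
                clicked = self.clicker.step(p_click)

        # 1-ms position integration with bias correction running at 1 ms
        for _ in range(INTEGRATIONS_PER_BIN):
            if self.config.bias_correction:
                update_bias(self.bias, V)
                v_out = apply_bias(self.bias, V)
            else:
                v_out = V
            self.position = integrate_position(self.position, v_out, DT_MS, self.bounds)

        self._time_s += BIN_WIDTH_S
        if self.recording is not None:
            self.recording["position"].append(self.position.copy())
            self.recording["decoded_v"].append(np.asarray(V, dtype=float).copy())
            self.recording["target"].append(active.center.copy())
            self.recording["on_target"].append(bool(active.contains(self.position)))
            self.recording["features"].append(full + self.decoders.baseline)
            self.recording["click_intent"].append(bool(intent.click_intent))
            self.recording["p_click"].append(p_click)
        return self.position.copy(), clicked

    # -- recording helpers ----------------------------------------------------

    def start_recording(self) -> None:
        self.recording = {k: [] for k in
                          ("position", "decoded_v", "target", "on_target",
                           "features", "click_intent", "p_click")}

    def stop_recording(self) -> dict[str, np.ndarray]:
        rec = {k: np.array(v) for k, v in (self.recording or {}).items()}
        self.recording = None
        return rec


def _attenuate_error(V: np.ndarray, position: np.ndarray, target: np.ndarray,
                     gamma: float) -> np.ndarray:
    """Scale the velocity component perpendicular to cursor->target by gamma.

    The assistive error attenuation used during recalibration blocks: the
    on-axis component is untouched, off-axis error is reduced.
    """
    d = target - position
    n = float(np.hypot(d[0], d[1]))
    if n == 0.0:
        return V
    u = d / n
    par = float(V @ u) * u
    return par + gamma * (V - par)


def _family_slice(n_channels: int, feature_set: str | None) -> slice:
    if feature_set == "spikes":
        return slice(0, n_channels)
    if feature_set == "hf":
        return slice(n_channels, 2 * n_channels)
    if feature_set == "both" or feature_set is None:
        return slice(0, 2 * n_channels)
    raise ConfigurationError(f"unknown feature family {feature_set!r}")


def heading_errors_deg(decoded: np.ndarray, intended: np.ndarray) -> np.ndarray:
    """Unsigned angle (degrees) between decoded and intended velocity per bin.

    Bins with zero intended velocity are skipped (heading undefined)."""
    decoded = np.asarray(decoded, dtype=float)
    intended = np.asarray(intended, dtype=float)
    sp_d = np.linalg.norm(decoded, axis=1)
    sp_i = np.linalg.norm(intended, axis=1)
    ok = (sp_d > 0) & (sp_i > 0)
    cosang = np.sum(decoded[ok] * intended[ok], axis=1) / (sp_d[ok] * sp_i[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Calibration


def _rest_baseline(p: SyntheticParticipant, rng: np.random.Generator,
                   duration_s: float = 30.0) -> np.ndarray:
    """30-s relax-period baseline over the full feature vector."""
    T = int(round(duration_s / BIN_WIDTH_S))
    feats = encode_stream(p, np.zeros((T, 2)), np.zeros(T, dtype=bool), rng)
    return feats.matrix("both").mean(axis=0)


def calibrate_session(
    config: SessionConfig,
    seed: int | None = None,
    return_diagnostics: bool = False,
):
    """Full calibration: open-loop fit, closed-loop refit, click threshold.

    Raises :class:`CalibrationError` when the synthetic participant carries
    no usable tuning (no significant features) or when closed-loop control
    is not usable (median heading error above 60 degrees — the go/no-go
    proxy for a "controllable cursor").
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = make_participant(config.participant, seed=int(rng.integers(2**31)))
    baseline = _rest_baseline(p, rng)

    # --- open-loop block -----------------------------------------------------
    block = simulate_open_loop_block(
        p, rng=rng, with_click=config.policy.click_enabled,
        n_repeats=config.calib_repeats)
    X_full = block.features.matrix("both") - baseline
    fam = _family_slice(p.n_channels, config.kalman_features)
    candidates = np.arange(2 * p.n_channels)[fam]
    picked = select_features(X_full[:, candidates], block.velocities)
    selected = candidates[picked]
    kparams = fit_kalman(X_full, block.velocities, features=selected)

    hmm = None
    if config.hmm_features is not None:
        hfam = _family_slice(p.n_channels, config.hmm_features)
        hmm = fit_click_decoder(
            block.features.matrix("both")[:, hfam],
            block.click_intents.astype(int))

    # --- closed-loop recalibration block ------------------------------------
    decoders = Decoders(baseline=baseline, kalman=kparams, hmm=hmm,
                        speed_gate=0.0, heading_error_deg=np.nan)
    engine = ClosedLoopEngine(p, decoders, config, rng)
    engine.attenuation = config.error_attenuation
    rec = _run_centerout_closed_loop(engine, n_repeats=config.recalib_repeats)
    engine.attenuation = None

    intents = refit_relabel(rec["position"], rec["decoded_v"], rec["target"],
                            rec["on_target"])
    X_rec = rec["features"] - baseline
    kparams2 = fit_kalman(X_rec, intents, features=selected)

    if hmm is not None:
        hfam = _family_slice(p.n_channels, config.hmm_features)
        hmm2 = fit_click_decoder(rec["features"][:, hfam],
                                 rec["click_intent"].astype(int))
        probs = forward_filter(
            hmm2, hmm2.projection.transform(rec["features"][:, hfam]))
        hmm2.click_threshold = calibrate_click_threshold(probs[:, 1])
    else:
        hmm2 = None

    gate = speed_gate_from_calibration(rec["decoded_v"], 0.15)
    move = ~rec["on_target"]
    herr = heading_errors_deg(rec["decoded_v"][move],
                              rec["target"][move] - rec["position"][move])
    med = float(np.median(herr)) if herr.size else 90.0
    if med > 60.0:
        raise CalibrationError(
            f"closed-loop median heading error {med:.1f} deg exceeds the 60 deg "
            "controllability gate")

    decoders = Decoders(baseline=baseline, kalman=kparams2, hmm=hmm2,
                        speed_gate=gate, heading_error_deg=med)
    engine = ClosedLoopEngine(p, decoders, config, rng)
    if return_diagnostics:
        diag = {"recalibration": rec, "initial_kalman": kparams,
                "relabeled_intents": intents, "baseline": baseline}
        return p, decoders, engine, diag
    return p, decoders, engine


def _run_centerout_closed_loop(engine: ClosedLoopEngine, n_repeats: int = 4,
                               trial_s: float = 2.5, hold_s: float = 0.6,
                               radius: float = 0.8) -> dict[str, np.ndarray]:
    """Closed-loop centre-out-and-back block driven by the simulated user."""
    angles = 2.0 * np.pi * np.arange(8) / 8
    half = 0.12
    layout = make_grid_layout(6)  # bounds only; cue rects are built ad hoc
    engine.start_recording()
    engine.set_position(np.zeros(2))
    trial_bins = int(round(trial_s / BIN_WIDTH_S))
    i = 0
    for rep in range(n_repeats):
        for ang in angles:
            c = radius * np.array([np.cos(ang), np.sin(ang)])
            for ctr in (c, np.zeros(2)):  # out, then back to centre
                cue = Target(id=i, label="cal",
                             rect=(ctr[0] - half, ctr[1] - half,
                                   ctr[0] + half, ctr[1] + half))
                for _ in range(trial_bins):
                    engine.tick(cue, layout)
                i += 1
    return engine.stop_recording()


def update_bias_block(engine: ClosedLoopEngine, duration_s: float = 60.0,
                      reestimate_baseline: bool = True) -> None:
    """Between-blockset bias/baseline update block (decoders held fixed).

    Re-estimates per-feature baselines from a fresh 30-s rest stream (the
    relax period collected before each block) and lets the online bias
    estimator run over a short closed-loop centre-out period.
    """
    if reestimate_baseline:
        # rest features include the current drift offsets
        T = int(round(30.0 / BIN_WIDTH_S))
        drift_path = np.empty((T, engine.p.n_channels))
        for t in range(T):
            drift_path[t] = engine.drift.step()
        rates = expected_rates(engine.p, np.zeros((T, 2)),
                               np.zeros(T, dtype=bool), drift_path)
        counts = engine.rng.poisson(rates) if engine.p.noise_model == "poisson" \
            else np.maximum(rates, 0.0)
        hf = np.maximum(engine.p.lfp_gain * rates
                        + engine.p.hf_noise_sd
                        * engine.rng.standard_normal(rates.shape), 0.0)
        engine.decoders.baseline = np.concatenate(
            [counts.mean(axis=0), hf.mean(axis=0)])
    n_trials = max(1, int(duration_s / 2.5))
    reps = max(1, n_trials // 16)
    _run_centerout_closed_loop(engine, n_repeats=reps)


# ---------------------------------------------------------------------------
# Session runner


@dataclass
class BlockRecord:
    blockset: int
    task: str
    events: list[SelectionEvent]
    result: BlockResult
    duration_s: float
    transcript: str | None = None
    role: str = "evaluation"  # evaluation | recalibration | bias_update


@dataclass
class SessionSummary:
    config: SessionConfig
    blocks: list[BlockRecord]
    orders: list[tuple[str, str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"blockset": b.blockset, "task": b.task, "role": b.role,
                 "N": b.result.N, "S": b.result.S, "E": b.result.E,
                 "D": b.result.D, "t_s": b.result.t_s,
                 "bitrate_bps": b.result.bitrate_bps, "ccpm": b.result.ccpm}
                for b in self.blocks if b.role == "evaluation"
            ]
        )

    def aggregate(self) -> pd.DataFrame:
        """Mean and s.d. of bitrate (grid) and ccpm (keyboards) per task."""
        df = self.to_frame()
        rows = []
        for task, grp in df.groupby("task"):
            metric = "bitrate_bps" if task.startswith("grid") else "ccpm"
            rows.append({"task": task, "metric": metric,
                         "mean": grp[metric].mean(), "sd": grp[metric].std(ddof=1),
                         "n_blocks": len(grp)})
        return pd.DataFrame(rows)


def run_session(config: SessionConfig, seed: int | None = None) -> SessionSummary:
    """Calibrate then run the configured number of blocksets; score all blocks."""
    p, decoders, engine = calibrate_session(config, seed=seed)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 10_000)
    grid_layout = make_grid_layout(config.grid_n)
    kb1, kb2 = config.keyboards
    layouts = {GRID_BLOCK: grid_layout,
               kb1: make_keyboard_layout(kb1), kb2: make_keyboard_layout(kb2)}
    blocks: list[BlockRecord] = []
    orders: list[tuple[str, str, str]] = []
    for bs in range(config.n_blocksets):
        if config.recalibrate_each_blockset and bs > 0:
            p, decoders, engine2 = calibrate_session(
                config, seed=(config.seed if seed is None else seed) + 7919 * bs)
            engine = engine2
        else:
            update_bias_block(engine, reestimate_baseline=config.reestimate_baseline)
        order = draw_blockset_order(rng, GRID_BLOCK, kb1, kb2)
        orders.append(order)
        sentence = config.sentences[bs % len(config.sentences)]
        for task in order:
            engine.set_position(layouts[task].center)
            if task == GRID_BLOCK:
                events = run_grid_block(
                    engine, grid_layout, config.rule, rng,
                    duration_s=config.block_duration_s,
                    trial_timeout_s=config.grid_trial_timeout_s)
                t = config.block_duration_s
                result = score_block(events, grid_layout.n_targets, t)
                blocks.append(BlockRecord(bs, f"grid{config.grid_n}", events,
                                          result, t))
            else:
                events, transcript = run_copy_typing_block(
                    engine, layouts[task], config.rule, sentence,
                    duration_cap_s=config.block_duration_s)
                t = min(config.block_duration_s,
                        events[-1].time_s if events else config.block_duration_s)
                result = score_block(events, layouts[task].n_targets, t)
                blocks.append(BlockRecord(bs, task, events, result, t,
                                          transcript=transcript))
    return SessionSummary(config=config, blocks=blocks, orders=orders)


def validate_session(summary: SessionSummary) -> None:
    """Protocol conformance: block counts, adjacency, durations.

    Raises ``ValueError`` on any violation; silent on a conforming log.
    """
    df = summary.to_frame()
    kb1, kb2 = summary.config.keyboards
    for bs, order in enumerate(summary.orders):
        grp = df[df["blockset"] == bs]
        if len(grp) != 3:
            raise ValueError(f"blockset {bs} has {len(grp)} evaluation blocks")
        pos = {task: i for i, task in enumerate(order)}
        if abs(pos[kb1] - pos[kb2]) != 1:
            raise ValueError(f"blockset {bs}: copy-typing blocks not adjacent")
        if (grp["t_s"] > summary.config.block_duration_s + 1e-9).any():
            raise ValueError(f"blockset {bs}: block exceeds duration cap")
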