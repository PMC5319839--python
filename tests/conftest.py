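"""Shared fixtures.

The closed-loop session fixtures are expensive (tens of seconds), so they
are session-scoped and shared between the module tests and the acceptance
suite.  Simulation sizes here (channel counts, block durations, repeat
counts) are the reduced desk-scale study conditions documented in the
methods note.
"""

from __future__ import annotations

import numpy as np
import pytest

from bcisim import SessionConfig, calibrate_session
from bcisim.session import ClosedLoopEngine
from bcisim.tasks import make_grid_layout, run_grid_block
from bcisim.metrics import score_block


def small_config(seed: int = 3, **overrides) -> SessionConfig:
    """Desk-scale default-profile configuration used across tests."""
    cfg = SessionConfig.profile("spikes_click", seed=seed, **overrides)
    cfg.participant = dict(cfg.participant, n_channels=48)
    cfg.calib_repeats = 4
    cfg.recalib_repeats = 2
    return cfg


@pytest.fixture(scope="session")
def calibrated_small():
    """One calibrated desk-scale session (participant, decoders, engine)."""
    cfg = small_config()
    p, dec, eng = calibrate_session(cfg)
    return cfg, p, dec, eng


@pytest.fixture(scope="session")
def default_profile_grid():
    """Grid-task evaluation of the shipped default profile, seeded.

    Returns (BlockResult, events) for one two-minute 6x6 grid block run
    through the full pipeline at the default (96-channel) scale.
    """
    cfg = SessionConfig.profile("spikes_click", seed=7)
    cfg.calib_repeats = 4
    cfg.recalib_repeats = 2
    p, dec, eng = calibrate_session(cfg)
    layout = make_grid_layout(6)
    engine = ClosedLoopEngine(p, dec, cfg, np.random.default_rng(70))
    events = run_grid_block(engine, layout, cfg.rule, np.random.default_rng(71),
                            duration_s=120.0)
    return score_block(events, layout.n_targets, 120.0), events


@pytest.fixture(scope="session")
def snr_bitrate_curve():
    """Mean grid bitrate vs modulation depth, 10 seeds per depth.

    Measured on the dwell-only pathway (no click decoder) with a small
    16-channel array so throughput is limited by decoding quality rather
    than by selection latency: that isolates the signal-quality effect the
    property is about.  Desk scale: shortened calibration, 60-s blocks.
    Returns {depth: [bitrate per seed]}.
    """
    from bcisim.session import SimulatedUserPolicy
    from bcisim.tasks import SelectionRule

    depths = (0.5, 1.0, 2.0, 4.0)
    out: dict[float, list[float]] = {}
    layout = make_grid_layout(6)
    for depth in depths:
        rates = []
        for seed in range(10):
            cfg = SessionConfig.profile("spikes_click", seed=100 + seed)
            cfg.participant = dict(cfg.participant, n_channels=16,
                                   modulation_depth=depth)
            cfg.hmm_features = None
            cfg.rule = SelectionRule(mode="dwell_reset", dwell_required_s=1.0,
                                     click_enabled=False)
            cfg.policy = SimulatedUserPolicy(click_enabled=False)
            cfg.calib_repeats = 3
            cfg.recalib_repeats = 1
            try:
                p, dec, eng = calibrate_session(cfg)
            except Exception:
                # a participant who cannot pass the controllability gate
                # transmits nothing in that session
                rates.append(0.0)
                continue
            engine = ClosedLoopEngine(p, dec, cfg,
                                      np.random.default_rng(500 + seed))
            events = run_grid_block(engine, layout, cfg.rule,
                                    np.random.default_rng(900 + seed),
                                    duration_s=60.0)
            rates.append(score_block(events, 36, 60.0).bitrate_bps)
        out[depth] = rates
    return out
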