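"""Calibrate the cursor and click decoders for a synthetic participant.

Runs the full calibration ladder for the default (spikes-only, click-enabled)
profile: 30-s rest baseline, open-loop centre-out-and-back block, feature
selection + velocity Kalman fit, PCA/HMM click fit, closed-loop
recalibration with intention relabeling, and unsupervised click-threshold
calibration.  Writes the fitted decoder bundle and a calibration summary.

Usage: python analysis/01_calibrate_decoders.py [--seed 7] [--out results]
"""

import argparse
import json
from pathlib import Path

from bcisim import SessionConfig, calibrate_session


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SessionConfig.profile("spikes_click", seed=args.seed)
    p, decoders, engine = calibrate_session(cfg)

    (args.out / "decoders.json").write_text(decoders.to_json())
    cfg.to_yaml(str(args.out / "session_config.yaml"))

    summary = {
        "n_channels": p.n_channels,
        "n_selected_features": int(len(decoders.kalman.selected_features)),
        "closed_loop_median_heading_error_deg": decoders.heading_error_deg,
        "click_threshold": None if decoders.hmm is None
        else decoders.hmm.click_threshold,
        "bias_speed_gate_units_per_s": decoders.speed_gate,
    }
    (args.out / "calibration_summary.json").write_text(
        json.dumps(summary, indent=2))
    print("calibration complete:")
    print(json.dumps(summary, indent=2))
    print(f"decoder bundle -> {args.out / 'decoders.json'}")


if __name__ == "__main__":
    main()
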