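"""Spatial click-accuracy analysis over the grid selection logs.

Computes the percent of click selections that landed on the cued target and
the distribution of click positions relative to the cued target's centre,
from the event logs written by 02_run_blocksets.py.

Usage: python analysis/04_click_accuracy.py [--results results]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from bcisim import click_accuracy_summary, make_grid_layout


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    events = pd.read_csv(args.results / "selection_events.csv")
    grid = events[events["task"].str.startswith("grid")]
    layout = make_grid_layout(6)
    summary = click_accuracy_summary(grid, layout)

    if summary["percent_correct"] is None:
        print("no click selections in the grid logs")
        return

    hist, edges = summary["histogram"]
    pd.DataFrame({"distance_lo": edges[:-1], "distance_hi": edges[1:],
                  "count": hist}).to_csv(
        args.results / "click_distance_histogram.csv", index=False)
    report = {
        "percent_correct": summary["percent_correct"],
        "n_correct": summary["n_correct"],
        "n_total": summary["n_total"],
        "median_distance_to_cued_center": float(np.median(summary["distances"])),
        "miss_fraction_near_target_edge": summary["edge_miss_fraction"],
    }
    (args.results / "click_accuracy.json").write_text(
        json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(f"histogram -> {args.results / 'click_distance_histogram.csv'}")


if __name__ == "__main__":
    main()
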