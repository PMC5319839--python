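"""Aggregate session performance: bitrate and typing-rate summaries.

Reads the per-block results written by 02_run_blocksets.py and reports
mean +/- s.d. achieved bitrate (grid) and correct characters per minute
(keyboards), with the wpm conversion.

Usage: python analysis/03_score_performance.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from bcisim import round1, words_per_min


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.results / "block_results.csv")
    rows = []
    for task, grp in df.groupby("task"):
        if task.startswith("grid"):
            rows.append({
                "task": task, "metric": "bitrate_bps",
                "mean": round1(grp["bitrate_bps"].mean()),
                "sd": round1(grp["bitrate_bps"].std(ddof=1)),
                "n_blocks": len(grp),
            })
        else:
            m = grp["ccpm"].mean()
            rows.append({
                "task": task, "metric": "ccpm",
                "mean": round1(m), "sd": round1(grp["ccpm"].std(ddof=1)),
                "wpm": round1(words_per_min(m)), "n_blocks": len(grp),
            })
    out = pd.DataFrame(rows)
    out.to_csv(args.results / "performance_summary.csv", index=False)
    print(out.to_string(index=False))
    print(f"\nsummary -> {args.results / 'performance_summary.csv'}")


if __name__ == "__main__":
    main()
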