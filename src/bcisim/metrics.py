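"""Communication-rate metrics: achieved bitrate and correct characters/min.

Achieved bitrate treats the grid task as a memoryless discrete channel with
uniformly random prompted targets:

    B = log2(N - 1) * max(S - 2E, 0) / t    [bits/s]

where N is the number of targets on screen, S the number of selections, E
the number of incorrect selections and t the elapsed time in seconds.  Each
error is charged one corrective selection, and the floor is 0.  Timed-out
trials contribute to t but not to S or E.

Typing throughput is measured as correct characters per minute,

    C = max(S - 2D, 0) / t_minutes,

where D is the number of delete-key selections; characters are "correct"
when not subsequently deleted, so uncorrected typos count as correct.  The
conventional words-per-minute figure divides ccpm by 5.

Reported values are rounded to one decimal with round-half-even, matching
how they are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasks import BACKSPACE, SelectionEvent


def round1(x: float) -> float:
    """One-decimal round-half-even, the convention for reported rates."""
    return float(np.round(x, 1))


@dataclass(frozen=True)
class BlockResult:
    """Evaluation ledger for one block: the S/E/D/t tallies and the rates."""

    N: int
    S: int
    E: int
    D: int
    t_s: float
    bitrate_bps: float
    ccpm: float

    def __post_init__(self) -> None:
        if not (0 <= self.E <= self.S and 0 <= self.D <= self.S):
            raise ValueError("require 0 <= E <= S and 0 <= D <= S")
        if self.t_s <= 0:
            raise ValueError("elapsed time must be positive")


def achieved_bitrate(N: int, S: int, E: int, t_s: float) -> float:
    """B = log2(N-1) * max(S - 2E, 0) / t, in bits/s (zero-floored)."""
    if N < 2:
        raise ValueError("achieved bitrate requires at least 2 targets")
    if t_s <= 0:
        raise ValueError("elapsed time must be positive")
    return float(np.log2(N - 1) * max(S - 2 * E, 0) / t_s)


def correct_chars_per_min(S: int, D: int, t_s: float) -> float:
    """C = max(S - 2D, 0) / t, in characters per minute (t given in seconds)."""
    if t_s <= 0:
        raise ValueError("elapsed time must be positive")
    return float(max(S - 2 * D, 0) / (t_s / 60.0))


def words_per_min(ccpm: float) -> float:
    """Standard 5-characters-per-word conversion."""
    if ccpm < 0:
        raise ValueError("ccpm must be non-negative")
    return ccpm / 5.0


def improvement_factor(new_rate: float, reference_rate: float) -> float:
    """Ratio of a new mean rate to a reference mean rate."""
    if reference_rate <= 0:
        raise ValueError("reference rate must be positive")
    return new_rate / reference_rate


def tally_events(events: list[SelectionEvent] | pd.DataFrame) -> tuple[int, int, int]:
    """(S, E, D) from a selection-event log; timeouts are excluded from all three."""
    if isinstance(events, pd.DataFrame):
        sel = events[events["method"] != "timeout"]
        S = len(sel)
        E = int((~sel["correct"]).sum())
        D = int((sel["selected_label"] == BACKSPACE).sum())
        return S, E, D
    sel = [e for e in events if e.method != "timeout"]
    S = len(sel)
    E = sum(1 for e in sel if not e.correct)
    D = sum(1 for e in sel if e.selected_label == BACKSPACE)
    return S, E, D


def score_block(
    events: list[SelectionEvent] | pd.DataFrame,
    n_targets: int,
    t_s: float,
) -> BlockResult:
    """Score one block's event log into a BlockResult row."""
    S, E, D = tally_events(events)
    return BlockResult(
        N=n_targets, S=S, E=E, D=D, t_s=t_s,
        bitrate_bps=achieved_bitrate(n_targets, S, E, t_s),
        ccpm=correct_chars_per_min(S, D, t_s),
    )


def click_accuracy_summary(
    events: list[SelectionEvent] | pd.DataFrame,
    layout,
    n_distance_bins: int = 20,
) -> dict:
    """Spatial accuracy of click selections relative to the cued target.

    Returns the percent of clicks landing on the cued target (one decimal),
    the raw correct/total counts, and a histogram of click-position
    distances from the cued target's centre.  With zero clicks the percent
    is reported as absent (None).  When misses occur, the summary flags
    whether they concentrate near the cued target's edge (within one cell
    diagonal of its centre).
    """
    if isinstance(events, pd.DataFrame):
        rows = events[events["method"] == "click"]
        clicks = list(rows.itertuples())
        get = lambda e: (int(e.cued_id), bool(e.correct), (e.click_x, e.click_y))
    else:
        clicks = [e for e in events if e.method == "click"]
        get = lambda e: (e.cued_id, e.correct, e.click_position)
    total = len(clicks)
    if total == 0:
        return {"percent_correct": None, "n_correct": 0, "n_total": 0,
                "distances": np.array([]), "histogram": None, "edge_miss_fraction": None}
    by_id = {t.id: t for t in layout.targets}
    dists, correct = [], 0
    half_diag = None
    for e in clicks:
        cid, ok, pos = get(e)
        tgt = by_id[cid]
        x0, y0, x1, y1 = tgt.rect
        half_diag = 0.5 * float(np.hypot(x1 - x0, y1 - y0))
        dists.append(float(np.hypot(pos[0] - tgt.center[0], pos[1] - tgt.center[1])))
        correct += int(ok)
    dists = np.array(dists)
    hist, edges = np.histogram(dists, bins=n_distance_bins)
    miss = dists[np.array([not get(e)[1] for e in clicks])]
    edge_fraction = (
        float(np.mean(miss <= 2.0 * half_diag)) if miss.size else None
    )
    return {
        "percent_correct": round1(100.0 * correct / total),
        "n_correct": correct,
        "n_total": total,
        "distances": dists,
        "histogram": (hist, edges),
        "edge_miss_fraction": edge_fraction,
    }


def percent_correct(n_correct: int, n_total: int) -> float:
    """100 * correct / total, one decimal (reported click-accuracy convention)."""
    if n_total <= 0:
        raise ValueError("need at least one click")
    return round1(100.0 * n_correct / n_total)
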