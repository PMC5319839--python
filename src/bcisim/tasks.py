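"""Selectable workspaces and selection logic: grids, keyboards, dwell, blocks.

Implements the communication tasks the decoders are evaluated on — a 6x6 or
9x9 grid of equal selectable squares and three full-alphabet keyboards
(an optimized layout, QWERTY, and an alphabetical layout sharing QWERTY's
geometry) — together with target prompting, dwell-based and click-based
selection, post-selection cursor recentering with its 500-ms lockout, and
blockset sequencing (one recalibration/bias block followed by three
two-minute evaluation blocks in randomized order with the two copy-typing
blocks adjacent).

All timing is bookkept in integer milliseconds at the 15-ms decoder tick.
A dwell selection fires on the first tick whose accumulated hold time
strictly exceeds the requirement (a full 1.0/1.5 s must elapse).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Protocol

import numpy as np
import pandas as pd

from .synthetic import ConfigurationError

TICK_MS = 15
DEFAULT_BOUNDS = (-1.0, -1.0, 1.0, 1.0)
SPACE, BACKSPACE = "_", "<"

# Letter rows of the QWERTY sheet; the alphabetical sheet permutes the 26
# letter labels in reading order onto the same key rectangles.
_QWERTY_ROWS = ["qwertyuiop", "asdfghjkl", "zxcvbnm" + BACKSPACE, SPACE]
_ABCDEF_ROWS = ["abcdefghij", "klmnopqrs", "tuvwxyz" + BACKSPACE, SPACE]


@dataclass(frozen=True)
class Target:
    id: int
    label: str
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open

    @property
    def center(self) -> np.ndarray:
        x0, y0, x1, y1 = self.rect
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])

    def contains(self, p: np.ndarray) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= p[0] < x1) and (y0 <= p[1] < y1)


@dataclass(frozen=True)
class TaskLayout:
    targets: tuple[Target, ...]
    bounds: tuple[float, float, float, float]
    layout_kind: str

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def center(self) -> np.ndarray:
        x0, y0, x1, y1 = self.bounds
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])

    def by_label(self, label: str) -> Target:
        for t in self.targets:
            if t.label == label:
                return t
        raise KeyError(f"no key labelled {label!r} on {self.layout_kind}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"id": t.id, "label": t.label, "x0": t.rect[0], "y0": t.rect[1],
                 "x1": t.rect[2], "y1": t.rect[3]}
                for t in self.targets
            ]
        )


def make_grid_layout(
    n: int = 6, bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS
) -> TaskLayout:
    """n x n tiling of equal half-open squares; every interior point maps to
    exactly one cell."""
    import warnings

    x0, y0, x1, y1 = bounds
    if not (x1 > x0 and y1 > y0):
        raise ConfigurationError("degenerate workspace bounds")
    if n not in (6, 9):
        warnings.warn(f"nonstandard grid size {n}x{n}", stacklevel=2)
    if n < 1:
        raise ConfigurationError("grid size must be positive")
    xs = x0 + (x1 - x0) * np.arange(n + 1) / n
    ys = y0 + (y1 - y0) * np.arange(n + 1) / n
    targets = []
    for r in range(n):       # rows from top
        for c in range(n):
            i = r * n + c
            targets.append(
                Target(id=i, label=f"g{i:02d}",
                       rect=(xs[c], ys[n - 1 - r], xs[c + 1], ys[n - r]))
            )
    return TaskLayout(tuple(targets), bounds, f"grid{n}")


def _rows_layout(rows: list[str], bounds, kind: str) -> TaskLayout:
    x0, y0, x1, y1 = bounds
    nrows = len(rows)
    targets = []
    i = 0
    for r, row in enumerate(rows):
        ry1 = y1 - (y1 - y0) * r / nrows
        ry0 = y1 - (y1 - y0) * (r + 1) / nrows
        for c, label in enumerate(row):
            rx0 = x0 + (x1 - x0) * c / len(row)
            rx1 = x0 + (x1 - x0) * (c + 1) / len(row)
            targets.append(Target(id=i, label=label, rect=(rx0, ry0, rx1, ry1)))
            i += 1
    return TaskLayout(tuple(targets), bounds, kind)


def _load_opti2_cells() -> list[tuple[str, int, int]]:
    """(label, row, col) cells of the synthetic optimized layout data file."""
    with resources.files("bcisim.data").joinpath("opti2_synthetic.csv").open() as fh:
        reader = csv.DictReader(fh)
        return [(r["label"], int(r["row"]), int(r["col"])) for r in reader]


def make_keyboard_layout(
    kind: str, bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS
) -> TaskLayout:
    """Keyboard layouts: ``opti2``, ``qwerty`` or ``abcdef``.

    ``qwerty`` and ``abcdef`` share identical key geometry (labels permuted
    alphabetically).  ``opti2`` is a synthetic frequency-centred optimized
    layout (most frequent characters nearest the centre) stored as a data
    file; two far-corner cells carry no key and act as dead space.  All
    layouts include a space key ("_") and a backspace key ("<").
    """
    x0, y0, x1, y1 = bounds
    if not (x1 > x0 and y1 > y0):
        raise ConfigurationError("degenerate workspace bounds")
    if kind == "qwerty":
        return _rows_layout(_QWERTY_ROWS, bounds, kind)
    if kind == "abcdef":
        return _rows_layout(_ABCDEF_ROWS, bounds, kind)
    if kind == "opti2":
        cells = _load_opti2_cells()
        ncols = max(c for _, _, c in cells) + 1
        nrows = max(r for _, r, _ in cells) + 1
        targets = []
        for i, (label, r, c) in enumerate(cells):
            rx0 = x0 + (x1 - x0) * c / ncols
            rx1 = x0 + (x1 - x0) * (c + 1) / ncols
            ry1 = y1 - (y1 - y0) * r / nrows
            ry0 = y1 - (y1 - y0) * (r + 1) / nrows
            targets.append(Target(id=i, label=label, rect=(rx0, ry0, rx1, ry1)))
        return TaskLayout(tuple(targets), bounds, kind)
    raise ConfigurationError(f"unknown keyboard kind {kind!r}")


def hit_test(layout: TaskLayout, position: np.ndarray) -> Target | None:
    """Unique containing target by half-open containment; None over dead space.

    Positions clamped to the workspace's upper edges are nudged inward by a
    relative epsilon so the cursor can still select the last row/column.
    """
    x0, y0, x1, y1 = layout.bounds
    eps_x = (x1 - x0) * 1e-12
    eps_y = (y1 - y0) * 1e-12
    p = np.array([min(position[0], x1 - eps_x), min(position[1], y1 - eps_y)])
    for t in layout.targets:
        if t.contains(p):
            return t
    return None


# ---------------------------------------------------------------------------
# Selection rules


@dataclass
class SelectionRule:
    """How selections are made: dwell mode, dwell time, clicks, recentering."""

    mode: str = "dwell_reset"  # dwell_reset | dwell_cumulative
    dwell_required_s: float = 1.0
    click_enabled: bool = True
    recenter: bool = False
    recenter_lockout_s: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("dwell_reset", "dwell_cumulative"):
            raise ConfigurationError(f"unknown dwell mode {self.mode!r}")
        if self.dwell_required_s <= 0 or self.recenter_lockout_s < 0:
            raise ConfigurationError("dwell time must be > 0 and lockout >= 0")

    @property
    def dwell_required_ms(self) -> int:
        return int(round(self.dwell_required_s * 1000))

    @property
    def lockout_ms(self) -> int:
        return int(round(self.recenter_lockout_s * 1000))


class DwellTracker:
    """Hold-time counter automaton at the 15-ms tick.

    Reset mode zeroes the (single) counter when the cursor leaves the
    target; cumulative mode keeps one counter per target across exits.  All
    counters are zeroed after any selection.  A selection fires on the tick
    where a target's accumulated hold time strictly exceeds the dwell
    requirement.
    """

    def __init__(self, rule: SelectionRule, tick_ms: int = TICK_MS):
        self.rule = rule
        self.tick_ms = tick_ms
        self._counters: dict[int, int] = {}
        self._last: int | None = None

    def reset_all(self) -> None:
        self._counters.clear()
        self._last = None

    def update(self, hovered_id: int | None) -> int | None:
        """Advance one tick with the cursor over ``hovered_id`` (or nothing)."""
        if self.rule.mode == "dwell_reset" and hovered_id != self._last:
            self._counters.pop(self._last, None)
        self._last = hovered_id
        if hovered_id is None:
            return None
        t = self._counters.get(hovered_id, 0) + self.tick_ms
        self._counters[hovered_id] = t
        if t > self.rule.dwell_required_ms:
            self.reset_all()
            return hovered_id
        return None


# ---------------------------------------------------------------------------
# Events and block runners


@dataclass(frozen=True)
class SelectionEvent:
    time_s: float
    cued_id: int
    selected_id: int | None      # None on a trial timeout
    method: str                  # "dwell" | "click" | "timeout"
    correct: bool
    cued_label: str = ""
    selected_label: str = ""
    click_position: tuple[float, float] | None = None


def events_to_frame(events: list[SelectionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"time_s": e.time_s, "cued_id": e.cued_id,
             "selected_id": -1 if e.selected_id is None else e.selected_id,
             "method": e.method, "correct": e.correct,
             "cued_label": e.cued_label, "selected_label": e.selected_label,
             "click_x": np.nan if e.click_position is None else e.click_position[0],
             "click_y": np.nan if e.click_position is None else e.click_position[1]}
            for e in events
        ]
    )


class Environment(Protocol):
    """One closed-loop plant: maps the current cue to a cursor tick.

    ``tick`` advances 15 ms and returns (cursor position, click fired);
    ``set_position`` teleports the cursor (used by recentering).
    """

    def tick(self, cue: Target, layout: TaskLayout) -> tuple[np.ndarray, bool]: ...

    def set_position(self, position: np.ndarray) -> None: ...

    def notify_selection(self) -> None: ...


class _BlockClock:
    """Shared selection/lockout bookkeeping for block runners."""

    def __init__(self, rule: SelectionRule):
        self.rule = rule
        self.dwell = DwellTracker(rule)
        self.lockout_end_ms = 0

    def locked(self, tick_end_ms: int) -> bool:
        # a bin is disabled only if it ends inside the lockout window; the
        # first bin extending past it may already select
        return tick_end_ms <= self.lockout_end_ms

    def after_selection(self, layout: TaskLayout, env: Environment, now_ms: int) -> None:
        self.dwell.reset_all()
        notify = getattr(env, "notify_selection", None)
        if notify is not None:
            notify()
        if self.rule.recenter:
            env.set_position(layout.center)
            self.lockout_end_ms = now_ms + self.rule.lockout_ms


def run_grid_block(
    env: Environment,
    layout: TaskLayout,
    rule: SelectionRule,
    rng: np.random.Generator,
    duration_s: float = 120.0,
    trial_timeout_s: float = 10.0,
) -> list[SelectionEvent]:
    """Fixed-duration grid block with uniformly random cued targets.

    A new target is prompted immediately after every selection.  Trials that
    reach ``trial_timeout_s`` without a selection are logged with no
    selected target (they count toward elapsed time but not S or E) and a
    new target is prompted.
    """
    n_ticks = int(round(duration_s * 1000)) // TICK_MS
    timeout_ms = int(round(trial_timeout_s * 1000))
    events: list[SelectionEvent] = []
    clock = _BlockClock(rule)
    cue = layout.targets[rng.integers(layout.n_targets)]
    trial_start_ms = 0
    for k in range(n_ticks):
        now_ms = (k + 1) * TICK_MS
        pos, clicked = env.tick(cue, layout)
        hovered = hit_test(layout, pos)
        hid = None if hovered is None else hovered.id
        selected: Target | None = None
        method = ""
        if not clock.locked(now_ms):
            if clicked and rule.click_enabled and hovered is not None:
                selected, method = hovered, "click"
            else:
                did = clock.dwell.update(hid)
                if did is not None:
                    selected, method = layout.targets[did], "dwell"
        if selected is not None:
            events.append(SelectionEvent(
                time_s=now_ms / 1000.0, cued_id=cue.id, selected_id=selected.id,
                method=method, correct=selected.id == cue.id,
                cued_label=cue.label, selected_label=selected.label,
                click_position=(float(pos[0]), float(pos[1])),
            ))
            clock.after_selection(layout, env, now_ms)
            cue = layout.targets[rng.integers(layout.n_targets)]
            trial_start_ms = now_ms
        elif now_ms - trial_start_ms >= timeout_ms:
            events.append(SelectionEvent(
                time_s=now_ms / 1000.0, cued_id=cue.id, selected_id=None,
                method="timeout", correct=False, cued_label=cue.label,
            ))
            cue = layout.targets[rng.integers(layout.n_targets)]
            trial_start_ms = now_ms
    return events


def run_copy_typing_block(
    env: Environment,
    layout: TaskLayout,
    rule: SelectionRule,
    sentence: str,
    duration_cap_s: float = 120.0,
) -> tuple[list[SelectionEvent], str]:
    """Copy-typing block: type a prompted sentence, backspacing after errors.

    The cued key each trial is the next character of the prompt given the
    currently committed (net-of-backspace) transcript; after an incorrect
    selection the backspace key is cued.  The block ends when the transcript
    equals the sentence or at the duration cap, whichever comes first.
    Returns the selection events and the final transcript.
    """
    if not sentence:
        raise ConfigurationError("empty prompt sentence")
    sentence = sentence.replace(" ", SPACE)
    for ch in set(sentence):
        layout.by_label(ch)  # raises at setup when a character is missing
    n_ticks = int(round(duration_cap_s * 1000)) // TICK_MS
    events: list[SelectionEvent] = []
    clock = _BlockClock(rule)
    transcript: list[str] = []

    def next_cue() -> Target:
        if sentence.startswith("".join(transcript)):
            return layout.by_label(sentence[len(transcript)])
        return layout.by_label(BACKSPACE)

    cue = next_cue()
    for k in range(n_ticks):
        now_ms = (k + 1) * TICK_MS
        pos, clicked = env.tick(cue, layout)
        hovered = hit_test(layout, pos)
        hid = None if hovered is None else hovered.id
        selected: Target | None = None
        method = ""
        if not clock.locked(now_ms):
            if clicked and rule.click_enabled and hovered is not None:
                selected, method = hovered, "click"
            else:
                did = clock.dwell.update(hid)
                if did is not None:
                    selected, method = layout.targets[did], "dwell"
        if selected is not None:
            events.append(SelectionEvent(
                time_s=now_ms / 1000.0, cued_id=cue.id, selected_id=selected.id,
                method=method, correct=selected.id == cue.id,
                cued_label=cue.label, selected_label=selected.label,
                click_position=(float(pos[0]), float(pos[1])),
            ))
            if selected.label == BACKSPACE:
                if transcript:
                    transcript.pop()
            else:
                transcript.append(selected.label)
            clock.after_selection(layout, env, now_ms)
            if "".join(transcript) == sentence:
                break
            cue = next_cue()
    return events, "".join(transcript)


# ---------------------------------------------------------------------------
# Blockset sequencing

GRID_BLOCK = "grid"


def blockset_orderings(grid: str, kb1: str, kb2: str) -> list[tuple[str, str, str]]:
    """The orderings permitted by the copy-typing adjacency constraint."""
    return [
        (grid, kb1, kb2), (grid, kb2, kb1),
        (kb1, kb2, grid), (kb2, kb1, grid),
    ]


def draw_blockset_order(
    rng: np.random.Generator, grid: str = GRID_BLOCK,
    kb1: str = "opti2", kb2: str = "qwerty",
) -> tuple[str, str, str]:
    """Randomize evaluation-block order; the two copy-typing blocks stay adjacent."""
    options = blockset_orderings(grid, kb1, kb2)
    return options[rng.integers(len(options))]
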