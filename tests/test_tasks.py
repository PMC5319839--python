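"""Task tests: layouts, hit testing, dwell/lockout automata, block runners
and blockset sequencing."""

import numpy as np
import pytest
from scipy import stats

from bcisim import (
    ConfigurationError,
    DwellTracker,
    SelectionRule,
    blockset_orderings,
    draw_blockset_order,
    hit_test,
    make_grid_layout,
    make_keyboard_layout,
    run_copy_typing_block,
    run_grid_block,
)
from bcisim.metrics import score_block, tally_events
from bcisim.tasks import BACKSPACE, SPACE

BOUNDS = (-1.0, -1.0, 1.0, 1.0)

# English letter frequencies (per mille, Lewand's ordering) plus space,
# used to weight digraph travel distances
_FREQ = {
    "e": 127, "t": 91, "a": 82, "o": 75, "i": 70, "n": 67, "s": 63, "h": 61,
    "r": 60, "d": 43, "l": 40, "c": 28, "u": 28, "m": 24, "w": 24, "f": 22,
    "g": 20, "y": 20, "p": 19, "b": 15, "v": 10, "k": 8, "j": 2, "x": 2,
    "q": 1, "z": 1, SPACE: 180,
}


class ScriptedSelector:
    """Environment stub that jumps to the cue and clicks on a schedule."""

    def __init__(self, click_times_ms=None, offset=None):
        self.click_times_ms = set(click_times_ms or [])
        self.now_ms = 0
        self.offset = np.zeros(2) if offset is None else np.asarray(offset)
        self.position = np.zeros(2)

    def tick(self, cue, layout):
        self.now_ms += 15
        self.position = cue.center + self.offset
        click = any(self.now_ms - 15 < t <= self.now_ms
                    for t in self.click_times_ms)
        return self.position.copy(), click

    def set_position(self, position):
        self.position = np.asarray(position, dtype=float)

    def notify_selection(self):
        pass


class AlwaysClicking(ScriptedSelector):
    def tick(self, cue, layout):
        self.now_ms += 15
        self.position = cue.center + self.offset
        return self.position.copy(), True


class TestGridLayout:
    def test_36_equal_cells_tile_bounds(self):
        layout = make_grid_layout(6, BOUNDS)
        assert layout.n_targets == 36
        area = (2.0 * 2.0) / 36
        for t in layout.targets:
            x0, y0, x1, y1 = t.rect
            assert (x1 - x0) * (y1 - y0) == pytest.approx(area, rel=1e-12)

    def test_shared_edge_belongs_to_one_cell(self):
        layout = make_grid_layout(6, BOUNDS)
        edge_x = layout.targets[0].rect[2]  # boundary between two columns
        t = hit_test(layout, np.array([edge_x, -0.9]))
        owners = [g for g in layout.targets if g.contains(np.array([edge_x, -0.9]))]
        assert t is not None and len(owners) == 1 and owners[0].id == t.id

    def test_random_points_hit_exactly_one_cell(self):
        layout = make_grid_layout(6, BOUNDS)
        rng = np.random.default_rng(80)
        pts = rng.uniform(-1, 1, size=(10_000, 2))
        for p in pts[:200]:
            owners = sum(t.contains(p) for t in layout.targets)
            assert owners == 1
        # full disjointness via hit_test on all 10,000 points
        assert all(hit_test(layout, p) is not None for p in pts)

    def test_grid9_bits_per_selection_ratio(self):
        ratio = np.log2(81 - 1) / np.log2(36 - 1)
        assert ratio == pytest.approx(1.232, abs=0.001)
        assert make_grid_layout(9, BOUNDS).n_targets == 81

    def test_nonstandard_size_warns(self):
        with pytest.warns(UserWarning, match="nonstandard"):
            make_grid_layout(4, BOUNDS)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            make_grid_layout(6, (0.0, 0.0, 0.0, 1.0))


class TestKeyboards:
    def test_abcdef_reading_order_is_alphabetical(self):
        layout = make_keyboard_layout("abcdef", BOUNDS)
        letters = [t.label for t in layout.targets if t.label.isalpha()]
        # targets are built row by row, left to right, top to bottom
        assert "".join(letters) == "abcdefghijklmnopqrstuvwxyz"

    def test_qwerty_abcdef_share_geometry(self):
        q = make_keyboard_layout("qwerty", BOUNDS)
        a = make_keyboard_layout("abcdef", BOUNDS)
        assert {t.rect for t in q.targets} == {t.rect for t in a.targets}

    def test_all_layouts_have_space_and_backspace(self):
        for kind in ("qwerty", "abcdef", "opti2"):
            layout = make_keyboard_layout(kind, BOUNDS)
            layout.by_label(SPACE)
            layout.by_label(BACKSPACE)
            labels = [t.label for t in layout.targets if t.label.isalpha()]
            assert sorted(labels) == sorted("abcdefghijklmnopqrstuvwxyz")

    def test_optimized_layout_shortens_expected_travel(self):
        """Frequency-weighted expected centre-to-centre digraph distance is
        smaller on the optimized layout than on QWERTY at equal bounds."""
        def expected_travel(layout):
            total_w = 0.0
            total = 0.0
            centers = {c: layout.by_label(c).center for c in _FREQ}
            for a, fa in _FREQ.items():
                for b, fb in _FREQ.items():
                    w = fa * fb
                    total += w * np.linalg.norm(centers[a] - centers[b])
                    total_w += w
            return total / total_w

        opti = expected_travel(make_keyboard_layout("opti2", BOUNDS))
        qwerty = expected_travel(make_keyboard_layout("qwerty", BOUNDS))
        assert opti < qwerty

    def test_opti2_dead_cells_hit_nothing(self):
        layout = make_keyboard_layout("opti2", BOUNDS)
        # the two far bottom corners carry no key
        assert hit_test(layout, np.array([-0.99, -0.99])) is None
        assert hit_test(layout, np.array([0.99, -0.99])) is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            make_keyboard_layout("dvorak", BOUNDS)


class TestDwell:
    def test_reset_mode_just_under_one_second(self):
        rule = SelectionRule(mode="dwell_reset", dwell_required_s=1.0)
        d = DwellTracker(rule)
        for _ in range(66):  # 0.99 s
            assert d.update(5) is None

    def test_reset_mode_fires_beyond_one_second(self):
        d = DwellTracker(SelectionRule(mode="dwell_reset", dwell_required_s=1.0))
        fired = [d.update(5) for _ in range(67)]
        assert fired[-1] == 5 and all(f is None for f in fired[:-1])

    def test_reset_mode_exit_resets_counter(self):
        d = DwellTracker(SelectionRule(mode="dwell_reset", dwell_required_s=1.0))
        for _ in range(60):
            d.update(5)
        d.update(None)
        assert all(d.update(5) is None for _ in range(66))

    def test_cumulative_mode_fires_on_101st_tick(self):
        """1.5-s cumulative rule: 50 ticks on A, 10 on B, then more on A;
        A fires on its 101st tick (50 + 51 ticks = 1.515 s, the first time
        the accumulated hold strictly exceeds 1.5 s)."""
        d = DwellTracker(SelectionRule(mode="dwell_cumulative",
                                       dwell_required_s=1.5))
        for _ in range(50):
            assert d.update(0) is None
        for _ in range(10):
            assert d.update(1) is None
        for _ in range(50):  # A-ticks 51..100 (1.500 s: not yet)
            assert d.update(0) is None
        assert d.update(0) == 0  # 101st A-tick

    def test_counters_zeroed_after_any_selection(self):
        d = DwellTracker(SelectionRule(mode="dwell_cumulative",
                                       dwell_required_s=0.3))
        for _ in range(15):
            d.update(1)
        for _ in range(21):
            r = d.update(2)
        assert r == 2
        # target 1's partial credit is gone
        assert all(d.update(1) is None for _ in range(20))

    def test_matches_independent_counter_oracle(self):
        """Random hover sequences agree with a naive dict-based oracle in
        both dwell modes."""
        rng = np.random.default_rng(81)
        for mode in ("dwell_reset", "dwell_cumulative"):
            rule = SelectionRule(mode=mode, dwell_required_s=0.5)
            d = DwellTracker(rule)
            counters: dict[int, int] = {}
            last = None
            seq = rng.integers(0, 3, size=2000)  # 0 means off-target
            for h in seq:
                hid = None if h == 0 else int(h)
                if mode == "dwell_reset" and hid != last:
                    counters.pop(last, None)
                last = hid
                expected = None
                if hid is not None:
                    counters[hid] = counters.get(hid, 0) + 15
                    if counters[hid] > 500:
                        expected = hid
                        counters.clear()
                        last = None
                assert d.update(hid) == expected


class TestGridBlock:
    def test_perfect_selector_one_per_second(self):
        """A selector that clicks exactly once per second for two minutes
        logs S = 120, E = 0."""
        layout = make_grid_layout(6, BOUNDS)
        env = ScriptedSelector(click_times_ms=range(1000, 121_000, 1000))
        rule = SelectionRule(click_enabled=True)
        events = run_grid_block(env, layout, rule, np.random.default_rng(2),
                                duration_s=120.0)
        S, E, _ = tally_events(events)
        assert S == 120 and E == 0

    def test_seeded_target_sequence_reproducible(self):
        layout = make_grid_layout(6, BOUNDS)
        rule = SelectionRule(click_enabled=True)
        runs = []
        for _ in range(2):
            env = ScriptedSelector(click_times_ms=range(500, 60_000, 500))
            events = run_grid_block(env, layout, rule,
                                    np.random.default_rng(3), duration_s=60.0)
            runs.append([e.cued_id for e in events])
        assert runs[0] == runs[1]

    def test_cued_targets_uniform_chi_square(self):
        """Cued-target draws over ~10,000 trials pass a chi-square
        uniformity test at alpha = 0.01."""
        layout = make_grid_layout(6, BOUNDS)
        rule = SelectionRule(click_enabled=True)
        cued = []
        for s in range(3):
            env = AlwaysClicking()
            events = run_grid_block(env, layout, rule,
                                    np.random.default_rng(100 + s),
                                    duration_s=60.0)
            cued.extend(e.cued_id for e in events)
        assert len(cued) > 9000
        counts = np.bincount(cued, minlength=36)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_timeouts_logged_without_selection(self):
        layout = make_grid_layout(6, BOUNDS)

        class NeverSelects(ScriptedSelector):
            def tick(self, cue, layout):
                self.now_ms += 15
                # hover alternates between two cells: dwell never accrues
                cell = layout.targets[0] if (self.now_ms // 15) % 2 else layout.targets[1]
                return cell.center.copy(), False

        env = NeverSelects()
        rule = SelectionRule(click_enabled=True)
        events = run_grid_block(env, layout, rule, np.random.default_rng(4),
                                duration_s=60.0, trial_timeout_s=5.0)
        assert all(e.method == "timeout" and e.selected_id is None
                   for e in events)
        # one per 5.01 s (first bin at or past the 5-s limit) -> 11 in 60 s
        assert len(events) == 11
        S, E, _ = tally_events(events)
        assert S == 0 and E == 0
        result = score_block(events, 36, 60.0)  # time still elapses
        assert result.bitrate_bps == 0.0


class TestRecentering:
    def test_lockout_spans_33_bins_then_allows_selection(self):
        """With recentering, the 500-ms lockout disables exactly the 33
        bins that end inside it; the 34th bin after a selection may select
        again (timing arithmetic 500/15)."""
        layout = make_grid_layout(6, BOUNDS)
        rule = SelectionRule(click_enabled=True, recenter=True)
        env = AlwaysClicking()
        events = run_grid_block(env, layout, rule, np.random.default_rng(5),
                                duration_s=30.0)
        times = [e.time_s for e in events]
        gaps = np.diff(times)
        assert times[0] == pytest.approx(0.015)
        np.testing.assert_allclose(gaps, 34 * 0.015, atol=1e-9)

    def test_no_selection_during_lockout_despite_clicks(self):
        layout = make_grid_layout(6, BOUNDS)
        rule = SelectionRule(click_enabled=True, recenter=True)
        env = AlwaysClicking()
        events = run_grid_block(env, layout, rule, np.random.default_rng(6),
                                duration_s=30.0)
        for a, b in zip(events, events[1:]):
            assert b.time_s - a.time_s > 0.5

    def test_cursor_recentered_after_selection(self):
        layout = make_grid_layout(6, BOUNDS)
        rule = SelectionRule(click_enabled=True, recenter=True)

        class Recording(AlwaysClicking):
            def __init__(self):
                super().__init__()
                self.teleports = []

            def set_position(self, position):
                self.teleports.append(np.asarray(position, dtype=float))

        env = Recording()
        events = run_grid_block(env, layout, rule, np.random.default_rng(7),
                                duration_s=5.0)
        assert len(env.teleports) == len(events) > 0
        for p in env.teleports:
            np.testing.assert_allclose(p, layout.center)


class TestCopyTyping:
    def test_error_free_typist_ends_at_final_letter(self):
        layout = make_keyboard_layout("qwerty", BOUNDS)
        env = AlwaysClicking()
        rule = SelectionRule(click_enabled=True)
        sentence = "the quick brown fox"
        events, transcript = run_copy_typing_block(env, layout, rule, sentence)
        assert transcript == sentence.replace(" ", SPACE)
        S, E, D = tally_events(events)
        assert D == 0 and E == 0 and S == len(sentence)
        assert events[-1].time_s == pytest.approx(len(sentence) * 0.015)

    def test_wrong_key_then_backspace_then_correct(self):
        """One wrong selection, the cued backspace, then the correct key:
        S = 3, D = 1, net correct characters 1 (ledger bookkeeping)."""
        layout = make_keyboard_layout("qwerty", BOUNDS)

        class WrongOnce(ScriptedSelector):
            def __init__(self):
                super().__init__()
                self.first = True

            def tick(self, cue, layout):
                self.now_ms += 15
                target = layout.by_label("z") if self.first else cue
                self.first = False
                return target.center.copy(), True

        events, transcript = run_copy_typing_block(
            WrongOnce(), layout, SelectionRule(click_enabled=True), "t")
        S, E, D = tally_events(events)
        assert (S, D) == (3, 1)
        assert transcript == "t"
        assert max(S - 2 * D, 0) == 1
        assert [e.cued_label for e in events] == ["t", BACKSPACE, "t"]

    def test_duration_cap_reached_mid_sentence(self):
        layout = make_keyboard_layout("qwerty", BOUNDS)

        class NeverSelects(ScriptedSelector):
            def tick(self, cue, layout):
                self.now_ms += 15
                key = layout.targets[0] if (self.now_ms // 15) % 2 else layout.targets[1]
                return key.center.copy(), False

        events, transcript = run_copy_typing_block(
            NeverSelects(), layout, SelectionRule(click_enabled=True),
            "hello world", duration_cap_s=120.0)
        assert events == [] and transcript == ""

    def test_missing_character_rejected_at_setup(self):
        layout = make_keyboard_layout("qwerty", BOUNDS)
        with pytest.raises(KeyError):
            run_copy_typing_block(ScriptedSelector(), layout,
                                  SelectionRule(), "naïve")


class TestBlocksets:
    def test_permitted_orderings_enumerated(self):
        orders = blockset_orderings("G", "K1", "K2")
        assert set(orders) == {("G", "K1", "K2"), ("G", "K2", "K1"),
                               ("K1", "K2", "G"), ("K2", "K1", "G")}
        assert len(orders) == 4  # of the 6 permutations

    def test_sampled_orderings_satisfy_adjacency(self):
        rng = np.random.default_rng(82)
        seen = set()
        for _ in range(10_000):
            order = draw_blockset_order(rng, "G", "K1", "K2")
            pos = {t: i for i, t in enumerate(order)}
            assert abs(pos["K1"] - pos["K2"]) == 1
            seen.add(order)
        assert len(seen) == 4

    def test_fixed_seed_fixed_ordering(self):
        a = draw_blockset_order(np.random.default_rng(9))
        b = draw_blockset_order(np.random.default_rng(9))
        assert a == b
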