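"""CA engine, glider identity and the intrinsic viability partition.

The engine cross-check uses an independently coded naive double-loop
update (here in the test, nothing shared with the convolution engine).
"""

import numpy as np
import pytest

from viadeco import (
    CAConfiguration,
    Grid,
    WindowOverflow,
    classify_configuration,
    enumerate_perturbations,
    glider_phases,
    make_gol_fixture,
    match_glider,
    read_cells,
    read_rle,
    step,
    viability_partition,
    write_cells,
    write_rle,
)


def naive_step(cells: set) -> set:
    """Independent oracle: dict-of-neighbor-counts double loop."""
    counts = {}
    for (r, c) in cells:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                counts[(r + dr, c + dc)] = counts.get((r + dr, c + dc), 0) + 1
    out = set()
    for pos, n in counts.items():
        if n == 3 or (n == 2 and pos in cells):
            out.add(pos)
    return out


class TestStep:
    def test_empty_grid_stays_empty(self):
        g = Grid(np.zeros((8, 8), dtype=bool))
        assert step(g).live_cells() == frozenset()

    def test_block_is_a_fixed_point(self):
        g = make_gol_fixture("block")
        cells = g.live_cells()
        for _ in range(10):
            g = step(g)
        assert g.live_cells() == cells

    def test_blinker_has_period_two(self):
        g = make_gol_fixture("blinker")
        start = g.live_cells()
        g1 = step(g)
        assert g1.live_cells() != start
        assert step(g1).live_cells() == start

    def test_agrees_with_naive_engine_on_random_soups(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            arr = rng.random((32, 32)) < 0.35
            arr[:2] = arr[-2:] = False
            arr[:, :2] = arr[:, -2:] = False
            grid = Grid(arr.copy())
            cells = grid.live_cells()
            for _ in range(20):
                grid = step(grid)
                cells = naive_step(cells)
                assert grid.live_cells() == cells

    def test_overflow_without_autogrow(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[0, 2] = arr[1, 2] = arr[2, 2] = True  # blinker on the edge
        with pytest.raises(WindowOverflow):
            step(Grid(arr), autogrow=False)

    def test_autogrow_preserves_world_coordinates(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[2, 1] = arr[2, 2] = arr[2, 3] = True
        g = Grid(arr, origin=(10, 10))
        stepped = step(g)
        assert stepped.live_cells() == naive_step(set(g.live_cells()))


class TestGliderPhases:
    def test_each_phase_has_five_cells_and_clean_membrane(self):
        for ph in glider_phases():
            assert len(ph.on_cells) == 5
            assert not (ph.on_cells & ph.membrane)
            # membrane is the full one-cell-thick ring
            for (r, c) in ph.on_cells:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nb = (r + dr, c + dc)
                        assert nb in ph.on_cells or nb in ph.membrane

    def test_stepping_cycles_through_phases(self):
        g = Grid.from_cells(glider_phases()[0].on_cells, margin=4)
        for k in range(1, 9):
            g = step(g)
            m = match_glider(g, mode="exact")
            assert m is not None
            assert m[0] == k % 4

    def test_four_steps_translate_by_one_one(self):
        g = Grid.from_cells(glider_phases()[0].on_cells, margin=6)
        start = match_glider(g, mode="exact")[1]
        for _ in range(4):
            g = step(g)
        phase, offset = match_glider(g, mode="exact")
        assert phase == 0
        assert (offset[0] - start[0], offset[1] - start[1]) == (1, 1)

    def test_translation_law_over_long_run(self):
        g = Grid.from_cells(glider_phases()[0].on_cells, margin=3)
        for k in range(1, 13):
            g = step(g)
            if k % 4 == 0:
                phase, offset = match_glider(g, mode="exact")
                assert phase == 0 and offset == (k // 4, k // 4)


class TestMatchGlider:
    def test_exact_match_reports_phase_and_offset(self):
        cells = {(r + 3, c + 7) for (r, c) in glider_phases()[0].on_cells}
        g = Grid.from_cells(cells)
        assert match_glider(g, mode="exact") == (0, (3, 7))

    def test_block_is_not_a_glider(self):
        assert match_glider(make_gol_fixture("block")) is None

    def test_windowed_match_tolerates_distant_debris(self):
        glider = {(r, c) for (r, c) in glider_phases()[0].on_cells}
        block = {(10, 10), (10, 11), (11, 10), (11, 11)}
        g = Grid.from_cells(glider | block)
        assert match_glider(g, mode="exact") is None
        m = match_glider(g, mode="windowed")
        assert m == (0, (0, 0))

    def test_windowed_match_requires_off_membrane(self):
        glider = set(glider_phases()[0].on_cells)
        # a live cell inside the membrane breaks the individual's boundary
        touching = glider | {(-1, 0)}
        g = Grid.from_cells(touching)
        assert match_glider(g, mode="windowed") is None


class TestEnumeration:
    @pytest.mark.parametrize("max_flips,expected", [(0, 1), (1, 10), (2, 46)])
    def test_counts_follow_binomial_sums(self, max_flips, expected):
        base = make_gol_fixture("glider")
        window = [(6 + r, 6 + c) for r in range(3) for c in range(3)]
        configs = enumerate_perturbations(base, window, max_flips)
        assert len(configs) == expected

    def test_empty_window_yields_base_only(self):
        base = make_gol_fixture("glider")
        configs = enumerate_perturbations(base, [], 3)
        assert len(configs) == 1
        assert configs[0].environment == frozenset()

    def test_window_overlapping_membrane_rejected(self):
        base = make_gol_fixture("glider")
        with pytest.raises(ValueError):
            enumerate_perturbations(base, [(0, 3)], 1)  # membrane cell

    def test_environment_overlapping_glider_rejected(self):
        with pytest.raises(ValueError):
            CAConfiguration(phase=0, position=(0, 0), environment=frozenset({(2, 1)}))


class TestClassification:
    def test_unperturbed_glider_is_interior_with_diagonal_drift(self):
        rec = classify_configuration(
            make_gol_fixture("glider"), horizon=100, mode="windowed"
        )
        assert rec.label == "interior"
        assert rec.final_offset == (25, 25)

    def test_wounded_glider_is_nonmember(self):
        # a glider missing one cell no longer contains the individual: it
        # belongs to the complement of the viable set from the start
        cells = set(glider_phases()[0].on_cells)
        cells.discard((2, 0))
        grid = Grid.from_cells(cells, margin=4)
        rec = classify_configuration(grid, horizon=16)
        assert rec.label == "nonmember"
        # and it really does disintegrate under the update rule
        for _ in range(8):
            grid = step(grid)
        assert match_glider(grid) is None

    def test_empty_grid_is_nonmember(self):
        empty = Grid(np.zeros((6, 6), dtype=bool))
        assert classify_configuration(empty, horizon=8).label == "nonmember"

    def test_collision_with_block_is_boundary(self):
        rec = classify_configuration(make_gol_fixture("glider_vs_block"), horizon=64)
        assert rec.label == "boundary"
        assert rec.steps_to_disintegration is not None
        assert rec.steps_to_disintegration % 4 == 0


class TestPartition:
    def test_counts_sum_to_total(self):
        base = make_gol_fixture("glider")
        window = [(5 + r, 5 + c) for r in range(3) for c in range(3)]
        configs = enumerate_perturbations(base, window, 2)
        summary = viability_partition(configs, horizon=32)
        assert sum(summary.counts.values()) == summary.total == len(configs)

    def test_single_flip_partition_matches_independent_oracle(self):
        base = make_gol_fixture("glider")
        window = [(4 + r, 4 + c) for r in range(3) for c in range(3)]
        configs = enumerate_perturbations(base, window, 1)
        summary = viability_partition(configs, horizon=64)

        # independent oracle: naive engine + direct phase matching
        def oracle_label(cfg):
            cells = set(cfg.glider_cells() | cfg.environment)
            checks = []
            for s in range(1, 65):
                cells = naive_step(cells)
                if s % 4 == 0:
                    checks.append(_naive_windowed_match(cells))
            if all(checks):
                return "interior"
            return "interior" if checks[-1] else "boundary"

        for rec, cfg in zip(summary.records, configs):
            assert rec.label == oracle_label(cfg)

    def test_zero_flip_partition_is_single_interior(self):
        base = make_gol_fixture("glider")
        summary = viability_partition(
            enumerate_perturbations(base, [], 0), horizon=64
        )
        assert summary.counts == {"interior": 1, "boundary": 0, "nonmember": 0}


def _naive_windowed_match(cells: set) -> bool:
    for ph in glider_phases():
        anchors = {
            (lr - pr, lc - pc)
            for (lr, lc) in cells
            for (pr, pc) in ph.on_cells
        }
        for (orow, ocol) in anchors:
            on = {(r + orow, c + ocol) for (r, c) in ph.on_cells}
            mem = {(r + orow, c + ocol) for (r, c) in ph.membrane}
            if on <= cells and not (mem & cells):
                return True
    return False


class TestPatternIO:
    def test_rle_round_trip(self):
        for ph in glider_phases():
            assert read_rle(write_rle(ph.on_cells)) == ph.on_cells

    def test_cells_round_trip(self):
        for ph in glider_phases():
            assert read_cells(write_cells(ph.on_cells)) == ph.on_cells

    def test_reads_standard_glider_rle(self):
        text = "#C standard glider\nx = 3, y = 3, rule = B3/S23\nbob$2bo$3o!\n"
        assert read_rle(text) == glider_phases()[0].on_cells

    def test_empty_pattern_round_trips(self):
        assert read_rle(write_rle(set())) == frozenset()
        assert read_cells(write_cells(set())) == frozenset()
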