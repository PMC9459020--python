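"""Founder selection, photoreceptor waves, border layers, apoptosis."""

import math

import numpy as np
import pytest

from eyevolve.epithelium import Domain, Epithelium, Fate, ParameterError
from eyevolve.fixtures import make_fixture
from eyevolve.furrow import FurrowState
from eyevolve.params import BorderParams, DeathParams, FounderParams, WaveParams
from eyevolve.specification import (
    EyeUnit,
    apoptosis_step,
    distance_to_world,
    exclusion_to_world,
    recruit_border,
    recruit_border_cohort,
    recruit_wave,
    select_founders,
)

from conftest import grid_epithelium


def line_epithelium(xs, radius=0.25, avg=0.5, y=0.0, pad=50.0):
    lo, hi = min(xs) - pad, max(xs) + pad
    ep = Epithelium(Domain(lo, hi, y - pad, y + pad), avg)
    for x in xs:
        ep.add_cell((x, y), radius)
    ep.initial_count = len(xs)
    return ep


class TestSelectFounders:
    def test_empty_band_selects_nothing(self):
        ep = make_fixture("strip", 5)
        fp = FounderParams(1, 10, 0, 0)
        assert select_founders([], [], fp, ep) == []

    def test_collinear_greedy_alternation(self):
        # five cells spaced d apart; center-distance threshold 1.5 d admits
        # every other cell: the rightmost seeds, then positions 3 and 1
        d = 10.0
        ep = line_epithelium([0, d, 2 * d, 3 * d, 4 * d], avg=0.5)
        # exclusion_to_world(v) = (v + 1) * 2 * avg = v + 1 -> want 1.5 d
        fp = FounderParams(exclusion_radius=1.5 * d - 1, target_radius=1,
                           min_distance_from_edge=0)
        got = select_founders(list(ep.cells), [], fp, ep)
        xs = sorted(ep.cell(c).pos[0] for c in got)
        assert xs == [0.0, 2 * d, 4 * d]

    def test_first_founder_is_nearest_right_edge(self):
        ep = line_epithelium([0, 5, 17], avg=0.5, pad=10)
        fp = FounderParams(0, 1, 0)
        got = select_founders(list(ep.cells), [], fp, ep)
        assert ep.cell(got[0]).pos[0] == 17

    def test_spacing_invariant_against_brute_force(self):
        ep = grid_epithelium(100, avg=5.0, jitter=3.0, seed=9)
        fp = FounderParams(exclusion_radius=2, target_radius=10,
                           min_distance_from_edge=0.5)
        got = select_founders(list(ep.cells), [], fp, ep)
        assert got  # dense tissue always yields founders
        pos = ep.pos[ep.rows_of(got)]
        excl = exclusion_to_world(2, ep)
        margin = distance_to_world(0.5, ep)
        for a in range(len(got)):
            for b in range(a + 1, len(got)):
                assert np.hypot(*(pos[a] - pos[b])) >= excl - 1e-9
            assert ep.domain.edge_distance(pos[a][None, :])[0] >= margin - 1e-9

    def test_matches_independent_greedy_oracle(self):
        ep = grid_epithelium(81, avg=5.0, jitter=3.0, seed=3)
        fp = FounderParams(exclusion_radius=1.2, target_radius=10,
                           min_distance_from_edge=0.4)
        got = select_founders(list(ep.cells), [], fp, ep)

        # independent O(n^2) re-implementation of the stated selection rule
        excl = exclusion_to_world(1.2, ep)
        margin = distance_to_world(0.4, ep)
        cells = {c: ep.cell(c) for c in sorted(ep.cells)}
        founders = []

        def eligible(c):
            cell = cells[c]
            edge = ep.domain.edge_distance(np.array(cell.pos)[None, :])[0]
            if edge < margin - 1e-9 or c in founders:
                return False
            return all(
                math.dist(cell.pos, cells[f].pos) >= excl - 1e-9 for f in founders
            )

        while True:
            elig = [c for c in cells if eligible(c)]
            if not elig:
                break
            if not founders:
                pick = max(elig, key=lambda c: (cells[c].pos[0], -c))
            else:
                pick = min(
                    elig,
                    key=lambda c: (min(math.dist(cells[c].pos, cells[f].pos) for f in founders), c),
                )
            founders.append(pick)
        assert got == founders

    def test_specified_cells_are_not_candidates(self):
        ep = make_fixture("strip", 4)
        first = int(ep.ids[3])
        ep.specify(first, Fate.R8, 10, unit_id=0)
        fp = FounderParams(0, 10, 0)
        got = select_founders(list(ep.cells), [first], fp, ep)
        assert first not in got


class TestRecruitWave:
    def _unit_on(self, ep, founder_id):
        ep.specify(founder_id, Fate.R8, 10, unit_id=0)
        return EyeUnit(unit_id=0, founder_id=founder_id)

    def test_zero_count_recruits_nothing(self):
        ep = make_fixture("hex_patch", 7)
        unit = self._unit_on(ep, int(ep.ids[0]))
        wp = WaveParams(0, 10, 5, 0)
        assert recruit_wave(unit, wp, 1, ep) == []

    def test_recruits_exactly_the_nearest_by_center_distance(self):
        ep = grid_epithelium(10, avg=5.0, jitter=2.0, seed=1)
        founder = int(ep.ids[4])
        unit = self._unit_on(ep, founder)
        wp = WaveParams(selection_count=2, target_radius=12,
                        max_distance_from_r8=50, distance_from_furrow=0)
        got = recruit_wave(unit, wp, 1, ep)
        # brute-force nearest-neighbor oracle
        fpos = ep.cell(founder).pos
        others = [(math.dist(ep.cell(c).pos, fpos), c) for c in ep.cells if c != founder]
        expect = [c for _, c in sorted(others)[:2]]
        assert sorted(got) == sorted(expect)
        for c in got:
            cell = ep.cell(c)
            assert cell.fate == Fate.PR_WAVE1 and cell.unit_id == 0
            assert cell.target_radius >= 12

    def test_range_limit_and_pool_shortage(self):
        ep = make_fixture("strip", 5)  # spacing 10, radius 5, avg 5
        unit = self._unit_on(ep, int(ep.ids[0]))
        # range one diameter: only the adjacent cell qualifies
        wp = WaveParams(3, 10, 1, 0)
        got = recruit_wave(unit, wp, 1, ep)
        assert got == [int(ep.ids[1])]

    def test_wave_cannot_run_twice(self):
        ep = make_fixture("hex_patch", 7)
        unit = self._unit_on(ep, int(ep.ids[0]))
        wp = WaveParams(1, 10, 5, 0)
        recruit_wave(unit, wp, 1, ep)
        with pytest.raises(ValueError, match="already run"):
            recruit_wave(unit, wp, 1, ep)

    def test_contested_cells_go_to_nearest_founder(self):
        # founders at x=0 and x=30; a lone precursor at x=10 is contested
        ep = line_epithelium([0, 10, 30], radius=4, avg=4)
        ep.specify(int(ep.ids[0]), Fate.R8, 4, unit_id=0)
        ep.specify(int(ep.ids[2]), Fate.R8, 4, unit_id=1)
        ua = EyeUnit(0, int(ep.ids[0]))
        ub = EyeUnit(1, int(ep.ids[2]))
        wp = WaveParams(1, 5, 10, 0)  # range 80 covers both
        from eyevolve.specification import recruit_wave_cohort

        got = recruit_wave_cohort([ub, ua], wp, 1, ep)
        assert got[0] == [int(ep.ids[1])] and got[1] == []


class TestRecruitBorder:
    def test_zero_layers(self):
        ep = make_fixture("ring_unit", 7)
        ep.specify(int(ep.ids[0]), Fate.R8, 5, unit_id=0)
        unit = EyeUnit(0, int(ep.ids[0]))
        assert recruit_border(unit, BorderParams(0, 5, 0), ep) == []

    def test_single_cell_unit_recruits_its_contact_ring(self):
        ep = make_fixture("ring_unit", 7)
        center = int(ep.ids[0])
        ep.specify(center, Fate.R8, 5, unit_id=0)
        unit = EyeUnit(0, center)
        got = recruit_border(unit, BorderParams(1, 5, 0), ep)
        assert sorted(got) == sorted(int(i) for i in ep.ids[1:7])
        assert all(ep.cell(c).fate == Fate.BORDER for c in got)

    def test_layers_match_brute_force_contact_bfs(self):
        ep = make_fixture("hex_patch", 61)  # four full rings
        center = int(ep.ids[0])
        ep.specify(center, Fate.R8, 5, unit_id=0)
        unit = EyeUnit(0, center)
        got = recruit_border(unit, BorderParams(3, 5, 0), ep)

        # oracle: BFS over the brute-force contact graph
        slack = 0.2 * ep.avg_cell_size
        cells = {c: ep.cell(c) for c in list(ep.cells)}
        def contacts(c):
            return {
                o for o in cells
                if o != c
                and math.dist(cells[o].pos, cells[c].pos)
                <= cells[o].radius + cells[c].radius + slack
            }
        seen, frontier, layers = {center}, {center}, []
        for _ in range(3):
            nxt = set().union(*(contacts(c) for c in frontier)) - seen
            layers.append(nxt)
            seen |= nxt
            frontier = nxt
        assert set(got) == set().union(*layers)
        assert len(got) == 6 + 12 + 18

    def test_cohort_contested_layer_resolves_by_distance_then_unit_id(self):
        ep = make_fixture("strip", 7)  # cells at x = 0,10,...,60
        a, b = int(ep.ids[0]), int(ep.ids[4])
        ep.specify(a, Fate.R8, 5, unit_id=0)
        ep.specify(b, Fate.R8, 5, unit_id=1)
        ua, ub = EyeUnit(0, a), EyeUnit(1, b)
        got = recruit_border_cohort([ua, ub], BorderParams(2, 5, 0), ep)
        # x=20 is layer 2 of unit 0 (founder x=0) and of unit 1 (founder
        # x=40): equidistant, so the tie goes to the lower unit id
        contested = int(ep.ids[2])
        assert contested in got[0] and contested not in got[1]
        # x=30 and x=50 are layer 1 of unit 1
        assert int(ep.ids[3]) in got[1] and int(ep.ids[5]) in got[1]


class TestApoptosis:
    def _strip_state(self, n=1000):
        ep = grid_epithelium(n, avg=5.0)
        fs = FurrowState(x=-1e9, velocity=1)
        return ep, fs

    def test_zero_chance_removes_nothing(self):
        ep, fs = self._strip_state(100)
        rng = np.random.default_rng(0)
        assert apoptosis_step(ep, fs, DeathParams(0, 0), rng) == []
        assert ep.n_alive == 100

    def test_full_chance_removes_all_precursors_behind(self):
        ep, fs = self._strip_state(100)
        keep = int(ep.ids[0])
        ep.specify(keep, Fate.R8, 10, unit_id=0)
        rng = np.random.default_rng(0)
        removed = apoptosis_step(ep, fs, DeathParams(100, 0), rng)
        assert len(removed) == 99 and keep not in removed
        assert ep.n_alive == 1

    def test_threshold_restricts_the_lottery(self):
        ep = grid_epithelium(100, avg=5.0)
        xcut = float(np.median(ep.pos[: ep.n, 0]))
        fs = FurrowState(x=xcut, velocity=1)
        rng = np.random.default_rng(0)
        removed = apoptosis_step(ep, fs, DeathParams(100, 0), rng)
        assert all(ep.pos[ep.row(c), 0] >= xcut for c in removed)
        rows = ep.alive_rows()
        assert np.all(ep.pos[rows, 0] < xcut)

    def test_removal_fraction_matches_binomial_sampling(self):
        # 30% hazard on 1,000 precursors, one step, 200 independent draws:
        # the grand mean removal fraction sits in the 99% CI of p = 0.3
        base = grid_epithelium(1000, avg=5.0)
        fs = FurrowState(x=-1e9, velocity=1)
        dp = DeathParams(30, 0)
        fractions = []
        for s in range(200):
            ep = base.copy()
            rng = np.random.default_rng(s)
            removed = apoptosis_step(ep, fs, dp, rng)
            fractions.append(len(removed) / 1000)
        mean = float(np.mean(fractions))
        se = math.sqrt(0.3 * 0.7 / (1000 * 200))
        assert abs(mean - 0.3) <= 2.576 * se

    def test_out_of_range_chance_is_parameter_error(self):
        ep, fs = self._strip_state(4)
        with pytest.raises(ParameterError, match="death_chance"):
            apoptosis_step(ep, fs, DeathParams(150, 0), np.random.default_rng(0))
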