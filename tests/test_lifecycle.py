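"""Cell growth, oriented division, fate transitions, granular removal."""

import numpy as np
import pytest

from epistrat.lifecycle import (
    LifecycleParams,
    decide_division,
    differentiate_mature,
    divide_cell,
    grow_cell,
    init_growth,
    new_cycle_length,
    remove_granular,
)
from epistrat.lineage import LineageParams
from epistrat.tissue import Cell, Tissue

from conftest import make_cell


def ready_cell(stage=0, k=6, cell_id=0):
    c = make_cell(cell_id, stage, (50.0, 50.0, 10.0), k=k)
    c.cycle_length = 24.0
    c.cycle_clock = 25.0
    c.target_elements = k
    return c


def params():
    return LifecycleParams()


class TestGrowth:
    def test_full_cell_does_not_grow(self, rng):
        c = ready_cell()
        assert not grow_cell(c, now=10.0, params=params(), rng=rng)

    def test_count_reaches_target_over_one_cycle(self, rng):
        p = params()
        c = make_cell(0, 0, (50.0, 50, 10), k=3)
        c.cycle_length = 24.0
        c.target_elements = p.target_elements
        init_growth(c, now=0.0, params=p)
        for hour in range(1, 26):
            grow_cell(c, now=float(hour), params=p, rng=rng)
        assert c.n_elements == p.target_elements

    def test_new_element_born_near_centroid(self, rng):
        p = params()
        c = make_cell(0, 0, (50.0, 50, 10), k=3)
        c.cycle_length = 24.0
        init_growth(c, now=0.0, params=p)
        centroid_before = c.centroid()
        assert grow_cell(c, now=c.next_growth, params=p, rng=rng)
        new = c.elements[-1]
        assert np.linalg.norm(new - centroid_before) < 4.5  # within one sigma

    def test_shrinking_cell_never_grows(self, rng):
        c = ready_cell(stage=3)
        c.shrinking = True
        c.elements = c.elements[:3]
        c.adherent = c.adherent[:3]
        assert not grow_cell(c, now=100.0, params=params(), rng=rng)


class TestDecideDivision:
    def lp(self, p0, p1=0.2):
        return LineageParams(p0=p0, p1=p1, v0=0.03, v1=0.03, d2=0.02, d3=0.05)

    def test_certain_self_renewal(self, rng):
        for _ in range(20):
            ev = decide_division(ready_cell(), self.lp(1.0), "base", rng)
            assert ev.daughter_stages == (0, 0)
            assert ev.mode == "symmetric"

    def test_not_ready_returns_none(self, rng):
        c = ready_cell()
        c.cycle_clock = 1.0
        assert decide_division(c, self.lp(0.7), "base", rng) is None
        c = ready_cell(k=3)
        c.target_elements = 6
        assert decide_division(c, self.lp(0.7), "base", rng) is None

    def test_non_proliferative_stages_never_divide(self, rng):
        for stage in (2, 3):
            assert decide_division(ready_cell(stage=stage), self.lp(0.7), "base", rng) is None

    def test_balanced_asym_variant_always_asymmetric(self, rng):
        for _ in range(20):
            ev = decide_division(ready_cell(), self.lp(0.5), "asym_division", rng)
            assert ev.mode == "asymmetric"
            assert set(ev.daughter_stages) == {0, 1}

    def test_base_renewal_fraction_binomial(self):
        """Self-renewal frequency matches p0 within 3-sigma binomial bounds."""
        rng = np.random.default_rng(42)
        p0, n = 0.7, 10_000
        renew = sum(
            decide_division(ready_cell(), self.lp(p0), "base", rng).daughter_stages
            == (0, 0)
            for _ in range(n)
        )
        assert abs(renew / n - p0) < 3 * np.sqrt(p0 * (1 - p0) / n)

    def test_asym_variant_preserves_offspring_composition(self):
        """Expected daughters per division match the population model."""
        rng = np.random.default_rng(7)
        p0, n = 0.8, 10_000
        basal_daughters = 0
        for _ in range(n):
            ev = decide_division(ready_cell(), self.lp(p0), "asym_division", rng)
            basal_daughters += sum(1 for s in ev.daughter_stages if s == 0)
        # E[basal daughters] = 2 p0 per division
        assert abs(basal_daughters / n - 2 * p0) < 3 * np.sqrt(2 * p0 * (1 - p0) / n) + 0.02

    def test_cycle_exit_probability(self):
        rng = np.random.default_rng(3)
        p1, n = 0.2, 5_000
        stay = sum(
            decide_division(ready_cell(stage=1), self.lp(0.7, p1), "base", rng).daughter_stages
            == (1, 1)
            for _ in range(n)
        )
        assert abs(stay / n - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)

    def test_plane_orientations(self, rng):
        for _ in range(50):
            ev = decide_division(ready_cell(), self.lp(0.5), "asym_division", rng)
            # asymmetric plane normal roughly parallel to membrane normal (z)
            assert abs(ev.plane_normal[2]) > np.cos(np.deg2rad(15.0)) - 1e-9
        for _ in range(50):
            ev = decide_division(ready_cell(), self.lp(1.0), "base", rng)
            if ev.mode == "symmetric":
                # symmetric plane normal roughly perpendicular to z
                assert abs(ev.plane_normal[2]) < np.sin(np.deg2rad(15.0)) + 1e-9


class TestDivideCell:
    def test_element_count_conserved_and_balanced(self, rng):
        t = Tissue()
        c = ready_cell(k=6)
        ev = decide_division(c, LineageParams(0.6, 0.2, 0.03, 0.03, 0.02, 0.05),
                             "base", rng)
        d1, d2 = divide_cell(t, c, ev, rng, (24.0, 24.0))
        assert d1.n_elements + d2.n_elements == 6
        assert min(d1.n_elements, d2.n_elements) >= 3
        assert d1.cycle_clock == d2.cycle_clock == 0.0

    def test_asymmetric_upper_daughter_differentiates(self, rng):
        t = Tissue()
        for _ in range(20):
            c = ready_cell(k=6)
            ev = decide_division(c, LineageParams(0.5, 0.2, 0.03, 0.03, 0.02, 0.05),
                                 "asym_division", rng)
            d1, d2 = divide_cell(t, c, ev, rng, (24.0, 24.0))
            hi = d1 if d1.centroid()[2] > d2.centroid()[2] else d2
            lo = d1 if hi is d2 else d2
            assert hi.stage == 1 and lo.stage == 0

    def test_symmetric_daughters_side_by_side(self, rng):
        t = Tissue()
        for _ in range(20):
            c = ready_cell(k=6)
            ev = decide_division(c, LineageParams(1.0, 0.2, 0.03, 0.03, 0.02, 0.05),
                                 "base", rng)
            d1, d2 = divide_cell(t, c, ev, rng, (24.0, 24.0))
            sep = d1.centroid() - d2.centroid()
            sep /= np.linalg.norm(sep)
            # separation vector roughly in-plane (perpendicular to z)
            assert abs(sep[2]) < np.sin(np.deg2rad(35.0))


class TestDifferentiation:
    def test_zero_rate_never_matures(self, rng):
        c = ready_cell(stage=2)
        c.cycle_clock = 1e9
        assert not differentiate_mature(c, 0.0, 1.0, rng, mode="hazard")
        assert not differentiate_mature(c, 0.0, 1.0, rng, mode="fixed_age")

    def test_hazard_rate_statistics(self):
        """Empirical hazard matches 1 - exp(-d2 dt) within 3-sigma bounds."""
        rng = np.random.default_rng(11)
        d2, dt, n = 0.05, 1.0, 20_000
        c = ready_cell(stage=2)
        hits = sum(differentiate_mature(c, d2, dt, rng, mode="hazard") for _ in range(n))
        p = 1.0 - np.exp(-d2 * dt)
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_fixed_age_triggers_at_mean_residence(self, rng):
        c = ready_cell(stage=2)
        c.cycle_clock = 19.9
        assert not differentiate_mature(c, 0.05, 1.0, rng, mode="fixed_age")
        c.cycle_clock = 20.1
        assert differentiate_mature(c, 0.05, 1.0, rng, mode="fixed_age")

    def test_higher_signal_never_delays_maturation(self, rng):
        """Effective d2 rises with calcium, so the maturation age shrinks."""
        from epistrat.simulator import SignalFeedback, effective_rates
        from epistrat.lineage import OvolRegulation
        fb = SignalFeedback()
        reg = OvolRegulation()
        d2s = [effective_rates(2, reg, s, fb, "signal").d2 for s in (0.0, 0.05, 0.5)]
        assert d2s[0] < d2s[1] < d2s[2]


class TestRemoval:
    def test_only_expired_granular_shrinks(self):
        c = ready_cell(stage=3)
        c.cycle_clock = 1.0
        c.cycle_length = 10.0
        removed, gone = remove_granular(c, now=50.0, params=params())
        assert (removed, gone) == (0, False)

    def test_removal_completes_after_n_ticks(self):
        p = params()
        c = ready_cell(stage=3, k=6)
        c.cycle_length = 10.0
        c.cycle_clock = 11.0
        total_removed = 0
        now = 100.0
        removed, gone = remove_granular(c, now, p)  # starts shrinking
        total_removed += removed
        while not gone:
            now += p.removal_interval / 6
            removed, gone = remove_granular(c, now, p)
            total_removed += removed
        assert total_removed == 6
        assert now - 100.0 <= p.removal_interval + 1e-9

    def test_never_applies_to_other_stages(self):
        for stage in (0, 1, 2):
            c = ready_cell(stage=stage)
            c.cycle_clock = 1e9
            assert remove_granular(c, 1e9, params()) == (0, False)

    def test_element_count_monotone_nonincreasing(self):
        p = params()
        c = ready_cell(stage=3, k=6)
        c.cycle_clock = 1e3
        counts = [c.n_elements]
        for i in range(12):
            remove_granular(c, 1e3 + i * p.removal_interval / 6, p)
            counts.append(c.n_elements)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_cycle_length_jitter_bounds(rng):
    vals = [new_cycle_length(np.log(2) / 24, rng, 0.1) for _ in range(500)]
    assert all(0.9 * 24 <= v <= 1.1 * 24 for v in vals)
    assert np.std(vals) > 0
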