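import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid

from esrwpt import (
    SimulationRecipe,
    SpinSystemSpec,
    make_benchmark,
    render,
    stick_pattern,
)
from esrwpt.peaks import G_PER_GHZ


def brute_force_sticks(a, spin, n):
    """Oracle: enumerate all (2I+1)^n nuclear quantum-number combinations."""
    m_values = np.arange(-spin, spin + 0.5, 1.0)
    tally = {}
    for combo in itertools.product(m_values, repeat=n):
        pos = round(a * sum(combo), 9)
        tally[pos] = tally.get(pos, 0) + 1
    total = sum(tally.values())
    return sorted((p, c / total) for p, c in tally.items())


class TestStickPattern:
    def test_single_nitrogen_triplet(self):
        sticks = stick_pattern(
            SpinSystemSpec(center_field_g=3300.0, couplings=[(16.0, 1.0, 1)])
        )
        positions = [p for p, _ in sticks]
        weights = [w for _, w in sticks]
        assert positions == pytest.approx([3284.0, 3300.0, 3316.0])
        assert weights == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_two_nitrogens_quintet(self):
        sticks = stick_pattern(
            SpinSystemSpec(center_field_g=0.0, couplings=[(10.0, 1.0, 2)])
        )
        weights = [w for _, w in sticks]
        assert len(sticks) == 5
        assert weights == pytest.approx(np.array([1, 2, 3, 2, 1]) / 9)

    def test_four_protons_quintet(self):
        sticks = stick_pattern(
            SpinSystemSpec(center_field_g=0.0, couplings=[(0.44, 0.5, 4)])
        )
        weights = [w for _, w in sticks]
        assert len(sticks) == 5
        assert weights == pytest.approx(np.array([1, 4, 6, 4, 1]) / 16)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.5, 40.0),
        spin=st.sampled_from([0.5, 1.0, 1.5]),
        n=st.integers(1, 6),
    )
    def test_matches_brute_force_enumeration(self, a, spin, n):
        sticks = stick_pattern(
            SpinSystemSpec(center_field_g=0.0, couplings=[(a, spin, n)])
        )
        oracle = brute_force_sticks(a, spin, n)
        assert len(sticks) == len(oracle) == int(2 * n * spin + 1)
        for (p1, w1), (p2, w2) in zip(sticks, oracle):
            assert p1 == pytest.approx(p2, abs=1e-6)
            assert w1 == pytest.approx(w2, rel=1e-9)

    def test_line_count_cap(self):
        # 14 incommensurate I=1/2 couplings: 2**14 distinct positions
        couplings = [(10.0 / 1.7 ** k, 0.5, 1) for k in range(14)]
        with pytest.raises(ValueError, match="exceeds"):
            stick_pattern(
                SpinSystemSpec(center_field_g=0.0, couplings=couplings)
            )

    def test_center_from_g_value(self):
        s = SpinSystemSpec(center_g=2.0, mw_frequency_ghz=9.5)
        assert s.center() == pytest.approx(G_PER_GHZ * 9.5 / 2.0)


class TestRender:
    def _single_line(self, lineshape, n_points=257):
        system = SpinSystemSpec(center_field_g=3300.0, lineshape=lineshape,
                                linewidth_pp=2.0)
        recipe = SimulationRecipe(
            systems=[(system, 1.0)], field_range=(3236.0, 3364.0),
            n_points=n_points, noise_sigma=0.0, seed=0,
        )
        return render(recipe)

    @pytest.mark.parametrize("lineshape", ["gaussian", "lorentzian"])
    def test_derivative_line_is_antisymmetric(self, lineshape):
        s = self._single_line(lineshape)
        mid = s.n_points // 2  # grid centered exactly on the line
        assert s.field[mid] == pytest.approx(3300.0)
        np.testing.assert_allclose(
            s.intensity[mid + 1:], -s.intensity[:mid][::-1], atol=1e-8
        )

    @pytest.mark.parametrize("lineshape", ["gaussian", "lorentzian"])
    def test_peak_to_peak_width(self, lineshape):
        s = self._single_line(lineshape, n_points=4097)
        pp = s.field[np.argmin(s.intensity)] - s.field[np.argmax(s.intensity)]
        assert pp == pytest.approx(2.0, abs=0.1)

    def test_same_seed_bit_identical(self):
        system = SpinSystemSpec(center_field_g=3300.0, linewidth_pp=2.0)
        recipe = SimulationRecipe(
            systems=[(system, 1.0)], field_range=(3200.0, 3400.0),
            n_points=512, noise_sigma=0.05, seed=42,
        )
        a, b = render(recipe), render(recipe)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_zero_amplitude_system_leaves_pure_noise(self):
        system = SpinSystemSpec(center_field_g=3300.0, linewidth_pp=2.0,
                                amplitude=0.0)
        recipe = SimulationRecipe(
            systems=[(system, 1.0)], field_range=(3200.0, 3400.0),
            n_points=4096, noise_sigma=0.02, seed=5,
        )
        s = render(recipe)
        assert np.std(s.intensity) == pytest.approx(0.02, rel=0.05)

    def test_rendering_is_linear(self):
        sys_a = SpinSystemSpec(center_field_g=3280.0, linewidth_pp=3.0)
        sys_b = SpinSystemSpec(center_field_g=3320.0, linewidth_pp=5.0)
        kw = dict(field_range=(3200.0, 3400.0), n_points=512,
                  noise_sigma=0.0, seed=0)
        sa = render(SimulationRecipe(systems=[(sys_a, 1.0)], **kw))
        sb = render(SimulationRecipe(systems=[(sys_b, 1.0)], **kw))
        sab = render(SimulationRecipe(systems=[(sys_a, 1.0), (sys_b, 1.0)],
                                      **kw))
        np.testing.assert_allclose(sab.intensity,
                                   sa.intensity + sb.intensity, atol=1e-12)

    def test_double_integral_tracks_spin_count(self):
        """Equal-amplitude systems carry equal double integrals regardless
        of linewidth (area-normalized lineshapes)."""
        kw = dict(field_range=(3100.0, 3500.0), n_points=4096,
                  noise_sigma=0.0, seed=0)

        def di(lw):
            sys_ = SpinSystemSpec(center_field_g=3300.0, linewidth_pp=lw)
            s = render(SimulationRecipe(systems=[(sys_, 1.0)], **kw))
            first = cumulative_trapezoid(s.intensity, s.field, initial=0.0)
            return abs(np.trapezoid(first, s.field))

        assert di(2.0) == pytest.approx(di(8.0), rel=0.01)

    def test_out_of_range_sticks_flagged_not_fatal(self):
        system = SpinSystemSpec(center_field_g=3390.0, linewidth_pp=5.0)
        recipe = SimulationRecipe(
            systems=[(system, 1.0)], field_range=(3200.0, 3400.0),
            n_points=256, noise_sigma=0.0, seed=0,
        )
        s = render(recipe)
        assert "range_warning" in s.meta


class TestBenchmarks:
    def test_cuqu_truth_matches_reported_values(self):
        (_, truth), = make_benchmark("cuqu_like", seed=0)
        assert truth["A_fine"] == 26.5
        assert truth["n_nuclei"] == 2
        assert truth["A_cu"] == 37.0
        assert truth["g_perp"] == 2.0427
        assert truth["h4"] - truth["h1"] == pytest.approx(3 * 37.0)

    def test_nitroxide_truths(self):
        (_, t1), = make_benchmark("tempo_like", seed=0)
        (_, t2), = make_benchmark("tempol_like", seed=0)
        assert t1["A_fine"] == 0.20
        assert t2["A_fine"] == 0.44

    def test_mixture_panel_fractions(self):
        panel = make_benchmark("mixture_panel", seed=0)
        fractions = [truth["minor_fraction"] for _, truth in panel]
        assert fractions == pytest.approx([1 / 3, 1 / 5, 1 / 11, 1 / 21])

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown benchmark"):
            make_benchmark("nope")

    def test_benchmark_reproducible(self):
        (a, _), = make_benchmark("tempo_like", seed=9)
        (b, _), = make_benchmark("tempo_like", seed=9)
        np.testing.assert_array_equal(a.intensity, b.intensity)
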