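import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk as draw_disk

from pitscan.pit_analysis import (
    BaselineError,
    PlanarMask,
    analyze_trace,
    count_dents,
    estimate_baseline,
    measure_pit,
    resorbed_area_percent,
    segment_pits,
)
from pitscan.trace_io import RunConfig, ValidationError

from conftest import DX, make_grid, piecewise_pit_trace, trace_from_heights


class TestBaseline:
    def test_flat_trace(self, config):
        x = make_grid(10.0)
        baseline = estimate_baseline(trace_from_heights(x, np.full(x.size, 5.0)), config)
        assert np.allclose(baseline.level, 5.0)
        assert baseline.noise_sigma == 0.0

    def test_single_pit_excluded(self, config):
        # triangular pit of depth 8 over 2% of a 1000 μm scan; oracle: median
        # of heights outside the pit support is exactly 0
        trace = piecewise_pit_trace(1000.0, [(100, 0), (110, -8), (120, 0)])
        baseline = estimate_baseline(trace, config)
        assert np.max(np.abs(baseline.level)) < 0.01

    def test_gaussian_noise_level_and_sigma(self, config, rng):
        x = make_grid(1000.0)
        noise = rng.normal(0, 0.05, x.size)
        baseline = estimate_baseline(trace_from_heights(x, 2.0 + noise), config)
        # oracle: sample median and scaled MAD of the generated noise
        assert abs(baseline.level[0] - (2.0 + np.median(noise))) < 0.005
        assert abs(baseline.level[0] - 2.0) < 0.005
        assert abs(baseline.noise_sigma - 0.05) < 0.01

    def test_linear_trend_followed(self, rng):
        x = make_grid(1000.0)
        true = 1.0 + 0.004 * x  # 4 μm tilt across the scan
        trace = trace_from_heights(x, true + rng.normal(0, 0.05, x.size))
        baseline = estimate_baseline(trace, RunConfig(baseline_trend="auto"))
        assert baseline.trend == "linear"
        assert np.max(np.abs(baseline.level - true)) < 0.05

    def test_heavily_eroded_scan_rejected(self, rng):
        # half the scan sits 10 μm below the surface: with a strict
        # unresorbed-fraction requirement the baseline must be refused
        x = make_grid(200.0)
        h = rng.normal(0, 0.02, x.size)
        h[(x % 100.0) < 50.0] -= 10.0  # alternating 50 μm eroded terraces
        cfg = RunConfig(min_unresorbed_fraction=0.7)
        with pytest.raises(BaselineError, match="no reliable baseline"):
            estimate_baseline(trace_from_heights(x, h), cfg)


class TestSegmentation:
    def test_flat_noisy_trace_empty(self, config, rng):
        x = make_grid(500.0)
        trace = trace_from_heights(x, rng.normal(0, 0.05, x.size))
        baseline = estimate_baseline(trace, config)
        assert segment_pits(trace, baseline, config) == []

    def test_triangle_boundaries(self, config):
        trace = piecewise_pit_trace(300.0, [(100, 0), (110, -8), (120, 0)])
        baseline = estimate_baseline(trace, config)
        extents = segment_pits(trace, baseline, config)
        assert len(extents) == 1
        assert extents[0].start_pos == pytest.approx(100, abs=DX)
        assert extents[0].end_pos == pytest.approx(120, abs=DX)

    def test_two_pits_ordered_matches_bruteforce(self, config):
        trace = piecewise_pit_trace(
            300.0, [(100, 0), (110, -6), (120, 0), (170, 0), (180, -6), (190, 0)])
        baseline = estimate_baseline(trace, config)
        extents = segment_pits(trace, baseline, config)
        assert len(extents) == 2
        assert extents[0].end_pos < extents[1].start_pos
        # brute-force oracle: contiguous sample runs with deficit > 0
        deficit = baseline.level - trace.heights
        below = deficit > 1e-12
        edges = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
        runs = list(zip(edges[::2], edges[1::2] - 1))
        assert len(runs) == 2
        for extent, (a, b) in zip(extents, runs):
            assert abs(trace.positions[a] - extent.start_pos) <= DX + 1e-9
            assert abs(trace.positions[b] - extent.end_pos) <= DX + 1e-9

    def test_min_width_against_sampling(self):
        x = np.arange(20) * 1.0
        trace = trace_from_heights(x, np.zeros(20))
        baseline = estimate_baseline(trace)
        with pytest.raises(ValidationError, match="min_width"):
            segment_pits(trace, baseline, RunConfig(min_width=1.0))


class TestDentCounting:
    def _single_extent(self, trace, config):
        baseline = estimate_baseline(trace, config)
        extents = segment_pits(trace, baseline, config)
        assert len(extents) == 1
        return extents[0], baseline

    def test_parabolic_pit_unidented(self, config):
        x = make_grid(100.0)
        deficit = np.clip(5.0 * (1 - ((x - 50) / 10) ** 2), 0, None)
        trace = trace_from_heights(x, -deficit)
        extent, baseline = self._single_extent(trace, config)
        assert count_dents(extent, trace, baseline, config) == (1, "unidented")

    def test_w_pit_shallow_ridge_bidented(self, config):
        # ridge reaching −0.1 μm on a depth-6 pit; tolerance 0.1·6 = 0.6
        trace = piecewise_pit_trace(
            240.0, [(100, 0), (110, -6), (120, -0.1), (130, -6), (140, 0)])
        extent, baseline = self._single_extent(trace, config)
        # oracle: exhaustive scan of strict local maxima rising above −0.6
        assert count_dents(extent, trace, baseline, config) == (2, "bidented")

    def test_w_pit_deep_ridge_unidented(self, config):
        trace = piecewise_pit_trace(
            240.0, [(100, 0), (110, -6), (120, -3.0), (130, -6), (140, 0)])
        extent, baseline = self._single_extent(trace, config)
        assert count_dents(extent, trace, baseline, config) == (1, "unidented")

    def test_three_dents_multidented(self, config):
        trace = piecewise_pit_trace(
            300.0, [(100, 0), (108, -5), (116, -0.2), (124, -6), (132, -0.2),
                    (140, -5), (148, 0)])
        extent, baseline = self._single_extent(trace, config)
        assert count_dents(extent, trace, baseline, config) == (3, "multidented")

    def test_degenerate_extent_rejected(self, config):
        trace = piecewise_pit_trace(100.0, [(50, 0), (55, -5), (60, 0)])
        baseline = estimate_baseline(trace, config)
        extent = segment_pits(trace, baseline, config)[0]
        extent.i1 = extent.i0 + 2
        with pytest.raises(ValidationError, match="degenerate"):
            count_dents(extent, trace, baseline, config)


class TestMetrics:
    def _pit(self, trace, config=None):
        config = config or RunConfig()
        baseline = estimate_baseline(trace, config)
        extents = segment_pits(trace, baseline, config)
        assert len(extents) == 1
        return measure_pit(extents[0], trace, baseline)

    def test_triangle_closed_form(self, config):
        # triangle width 20, depth 8: fwhm = w/2 = 10, area = w·d/2 = 80
        pit = self._pit(piecewise_pit_trace(300.0, [(100, 0), (110, -8), (120, 0)]))
        assert pit.width == pytest.approx(20, abs=2 * DX)
        # apex may fall between samples: depth off by at most slope·dx/2
        assert pit.depth == pytest.approx(8, abs=0.05)
        assert pit.fwhm == pytest.approx(10, abs=2 * DX)
        assert pit.area == pytest.approx(80, rel=0.01)

    def test_rectangle_closed_form(self):
        x = make_grid(200.0)
        deficit = np.where((x >= 50) & (x <= 62), 5.0, 0.0)
        pit = self._pit(trace_from_heights(x, -deficit))
        assert pit.width == pytest.approx(12, abs=2 * DX)
        assert pit.fwhm == pytest.approx(12, abs=2 * DX)
        assert pit.area == pytest.approx(60, rel=0.01)

    def test_gaussian_closed_form(self):
        # fwhm = 2σ√(2 ln 2) ≈ 11.774 μm; area = d·σ·√(2π) ≈ 125.33 μm²
        x = make_grid(300.0)
        sigma = 5.0
        deficit = 10.0 * np.exp(-((x - 150) ** 2) / (2 * sigma**2))
        pit = self._pit(trace_from_heights(x, -deficit))
        assert pit.fwhm == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)), abs=2 * DX)
        assert pit.area == pytest.approx(10 * sigma * np.sqrt(2 * np.pi), rel=0.01)
        assert pit.depth == pytest.approx(10, abs=0.01)


class TestAnalyzeTrace:
    VERTICES = [(100, 0), (110, -8), (120, 0),
                (300, 0), (315, -5), (320, -0.2), (330, -6), (340, 0),
                (600, 0), (610, -4), (620, 0)]

    def test_noiseless_composition(self, config):
        trace = piecewise_pit_trace(1000.0, self.VERTICES)
        pits = analyze_trace(trace, config)
        assert [p.shape_class for p in pits] == ["unidented", "bidented", "unidented"]
        assert [p.depth for p in pits] == pytest.approx([8, 6, 4], abs=0.02)

    def test_noisy_recovery_within_5pct(self, config, rng):
        clean = analyze_trace(piecewise_pit_trace(1000.0, self.VERTICES), config)
        noisy_trace = piecewise_pit_trace(1000.0, self.VERTICES,
                                          noise_sigma=0.05, rng=rng)
        noisy = analyze_trace(noisy_trace, config)
        assert len(noisy) == len(clean)
        for c, n in zip(clean, noisy):
            assert n.dent_count == c.dent_count
            assert n.depth == pytest.approx(c.depth, rel=0.05)
            assert n.width == pytest.approx(c.width, rel=0.05)
            assert n.area == pytest.approx(c.area, rel=0.05)

    def test_flat_noisy_trace_no_pits(self, config, rng):
        x = make_grid(1000.0)
        trace = trace_from_heights(x, rng.normal(1.0, 0.05, x.size))
        assert analyze_trace(trace, config) == []

    def test_shift_and_scale_equivariance(self, config):
        trace = piecewise_pit_trace(400.0, [(100, 0), (112, -6), (124, 0)])
        base = analyze_trace(trace, config)[0]
        shifted = trace_from_heights(trace.positions, trace.heights + 7.0)
        scaled = trace_from_heights(trace.positions, trace.heights * 2.0)
        p_shift = analyze_trace(shifted, config)[0]
        p_scale = analyze_trace(scaled, config)[0]
        for attr in ("width", "depth", "fwhm", "area"):
            assert getattr(p_shift, attr) == pytest.approx(getattr(base, attr), rel=1e-6)
        assert p_scale.width == pytest.approx(base.width, rel=1e-6)
        assert p_scale.depth == pytest.approx(2 * base.depth, rel=1e-6)
        assert p_scale.area == pytest.approx(2 * base.area, rel=1e-6)

    def test_reflection_invariance(self, config):
        trace = piecewise_pit_trace(500.0, [(100, 0), (110, -8), (120, 0),
                                            (300, 0), (310, -5), (315, -0.2),
                                            (325, -6), (335, 0)])
        mirrored = trace_from_heights(trace.positions,
                                      trace.heights[::-1].copy())
        fwd = analyze_trace(trace, config)
        rev = analyze_trace(mirrored, config)
        key = lambda p: (round(p.width, 3), round(p.depth, 3), round(p.fwhm, 3),
                         round(p.area, 2), p.dent_count)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    @settings(max_examples=25, deadline=None)
    @given(width=st.floats(4.0, 40.0), depth=st.floats(1.0, 20.0),
           center=st.floats(60.0, 140.0))
    def test_pit_invariants_hold(self, width, depth, center):
        trace = piecewise_pit_trace(
            200.0, [(center - width / 2, 0), (center, -depth),
                    (center + width / 2, 0)])
        pits = analyze_trace(trace, RunConfig())
        assert len(pits) == 1
        pit = pits[0]
        assert 0 < pit.fwhm <= pit.width
        assert 0 < pit.area <= pit.width * pit.depth
        assert pit.dent_count == 1


class TestPlanarArea:
    def test_empty_and_half(self):
        grid = np.zeros((10, 10), dtype=bool)
        assert resorbed_area_percent(PlanarMask(grid)) == 0.0
        grid[:5] = True
        assert resorbed_area_percent(PlanarMask(grid)) == 50.0

    def test_disc_matches_analytic_area(self):
        grid = np.zeros((500, 500), dtype=bool)
        rr, cc = draw_disk((250, 250), 50, shape=grid.shape)
        grid[rr, cc] = True
        expected = 100 * np.pi * 50**2 / 250_000
        assert resorbed_area_percent(PlanarMask(grid)) == pytest.approx(expected, abs=0.05)

    def test_fully_resorbed_mask_invalid(self):
        with pytest.raises(ValidationError, match="unresorbed"):
            PlanarMask(np.ones((4, 4), dtype=bool))
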