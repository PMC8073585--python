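"""Peak detection, coelution gating and light-to-heavy ratio estimation."""

import numpy as np
import pytest

from prmkit.quant import (
    PeakGroup,
    QuantConfig,
    XicTrace,
    call_detection,
    coelution_test,
    detect_peak,
    light_heavy_ratio,
    quantify,
    quantify_pair,
)
from prmkit.simulate import SimulationConfig, simulate_xics


def gaussian_trace(
    apex=20.0,
    height=1e6,
    sigma=0.07,
    t0=19.0,
    t1=21.0,
    step=0.01,
    channel="light",
    fragment="y3",
    peptide="GADVWFK",
    sample="S1",
):
    t = np.arange(t0, t1 + step / 2, step)
    y = height * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    return XicTrace(sample, peptide, channel, fragment, t, y)


def _group(apex, start, end, area=1.0, channel="light"):
    return PeakGroup("GADVWFK", channel, apex, (start, end), area, {"y3": area})


class TestDetectPeak:
    def test_noiseless_gaussian_area_within_2pct(self):
        height, sigma = 1e6, 0.07
        true_area = height * sigma * np.sqrt(2 * np.pi)
        peak = detect_peak([gaussian_trace(height=height, sigma=sigma)])
        assert peak is not None
        assert peak.area == pytest.approx(true_area, rel=0.02)
        assert peak.apex_time == pytest.approx(20.0, abs=0.02)

    def test_flat_zero_trace_is_absent(self):
        t = np.arange(19, 21, 0.01)
        trace = XicTrace("S1", "GADVWFK", "light", "y3", t, np.zeros_like(t))
        assert detect_peak([trace]) is None

    def test_apex_lands_on_taller_of_two_peaks(self):
        t = np.arange(10, 30, 0.02)
        y = 1e5 * np.exp(-0.5 * ((t - 14) / 0.07) ** 2)
        y += 3e5 * np.exp(-0.5 * ((t - 26) / 0.07) ** 2)
        peak = detect_peak([XicTrace("S1", "GADVWFK", "light", "y3", t, y)])
        assert peak.apex_time == pytest.approx(26.0, abs=0.05)

    def test_fragment_areas_sum_to_total(self):
        traces = [
            gaussian_trace(height=h, fragment=f)
            for h, f in [(5e5, "y3"), (3e5, "y4"), (2e5, "y5")]
        ]
        peak = detect_peak(traces)
        assert peak.area == pytest.approx(sum(peak.fragment_areas.values()), abs=1e-6)

    def test_mismatched_grids_are_resampled(self):
        a = gaussian_trace(step=0.01, fragment="y3")
        b = gaussian_trace(step=0.017, fragment="y4")
        peak = detect_peak([a, b])
        assert peak is not None and set(peak.fragment_areas) == {"y3", "y4"}


class TestCoelution:
    def test_identical_peaks_coelute_with_zero_delta(self):
        g = _group(20.0, 19.8, 20.2)
        ok, delta = coelution_test(g, _group(20.0, 19.8, 20.2, channel="heavy"))
        assert ok and delta == 0.0

    def test_far_apexes_fail(self):
        ok, delta = coelution_test(
            _group(20.0, 19.8, 20.2), _group(21.0, 20.8, 21.2, channel="heavy"),
            apex_tolerance=0.2,
        )
        assert not ok and delta == pytest.approx(1.0)

    def test_delta_exactly_at_tolerance_passes(self):
        # closed boundary on the apex tolerance (binary-exact values)
        ok, delta = coelution_test(
            _group(20.0, 19.5, 20.625), _group(20.125, 19.625, 20.75, channel="heavy"),
            apex_tolerance=0.125,
        )
        assert ok and delta == 0.125

    def test_insufficient_overlap_fails(self):
        ok, _ = coelution_test(
            _group(20.0, 19.9, 20.05), _group(20.045, 20.04, 20.6, channel="heavy"),
            apex_tolerance=0.1, min_overlap=0.5,
        )
        assert not ok

    def test_absent_peak_fails(self):
        assert coelution_test(None, _group(20.0, 19.8, 20.2)) == (False, None)
        assert coelution_test(_group(20.0, 19.8, 20.2), None) == (False, None)

    def test_apex_delta_symmetric_in_channel_order(self):
        a, b = _group(20.0, 19.8, 20.2), _group(20.07, 19.9, 20.3, channel="heavy")
        assert coelution_test(a, b)[1] == coelution_test(b, a)[1]


class TestRatio:
    def test_equal_areas_give_one(self):
        light = _group(20.0, 19.8, 20.2, area=5.0)
        heavy = _group(20.0, 19.8, 20.2, area=5.0, channel="heavy")
        assert light_heavy_ratio(light, heavy) == 1.0

    def test_zero_heavy_area_is_undefined(self):
        light = _group(20.0, 19.8, 20.2, area=5.0)
        heavy = _group(20.0, 19.8, 20.2, area=0.0, channel="heavy")
        with pytest.raises(ValueError, match="spike missing"):
            light_heavy_ratio(light, heavy)

    def test_common_scaling_invariance(self):
        light = [gaussian_trace(height=2e5)]
        heavy = [gaussian_trace(height=1e5, channel="heavy")]
        r1 = quantify_pair(light, heavy).light_to_heavy_ratio
        scale = 7.3
        light2 = [
            XicTrace(t.sample_id, t.peptide, t.channel, t.fragment_label, t.times,
                     t.intensities * scale)
            for t in light
        ]
        heavy2 = [
            XicTrace(t.sample_id, t.peptide, t.channel, t.fragment_label, t.times,
                     t.intensities * scale)
            for t in heavy
        ]
        r2 = quantify_pair(light2, heavy2).light_to_heavy_ratio
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_simulated_ratio_2_recovered_within_5pct(self):
        cfg = SimulationConfig(
            seed=11, peptides=["GADVWFK"], groups=["g"], samples_per_group=5,
            true_ratios={("g", "GADVWFK"): 2.0}, noise_cv=0.01, baseline_level=20.0,
        )
        xic, _, _ = simulate_xics(cfg)
        results = [r for r in quantify(xic) if r.detected]
        assert results
        for r in results:
            assert r.light_to_heavy_ratio == pytest.approx(2.0, abs=0.1)


class TestDetectionMonotonicity:
    def test_scaling_light_up_never_loses_detection(self):
        cfg = SimulationConfig(
            seed=5, peptides=["GADVWFK"], groups=["g"], samples_per_group=1,
            true_ratios={("g", "GADVWFK"): 0.05}, noise_cv=0.05, baseline_level=100.0,
        )
        xic, _, _ = simulate_xics(cfg)
        detected_prev = False
        for scale in (0.5, 1.0, 4.0, 20.0, 100.0):
            scaled = xic.copy()
            mask = scaled["channel"] == "light"
            scaled.loc[mask, "intensity"] = scaled.loc[mask, "intensity"] * scale
            (res,) = quantify(scaled)
            assert res.detected or not detected_prev
            detected_prev = res.detected
        assert detected_prev  # strongest signal must be detected


class TestCallDetection:
    def test_all_absent_input_gives_all_minus(self):
        import pandas as pd

        empty = pd.DataFrame(
            columns=["sample_id", "peptide", "channel", "fragment", "time_min",
                     "intensity"]
        )
        results = quantify(empty, peptides=["GADVWFK", "WESGYNTR"])
        table = call_detection(results, {}, ["GADVWFK", "WESGYNTR"])
        assert table.empty or all(
            (table[c] == "-").all() for c in table.columns if c != "peptide"
        )

    def test_group_specific_detection_pattern(self):
        cfg = SimulationConfig(
            seed=9, peptides=["DLYNFLK"], groups=["healthy", "inflamed"],
            samples_per_group=3,
            true_ratios={("inflamed", "DLYNFLK"): 1.0},  # absent in healthy
        )
        xic, _, manifest = simulate_xics(cfg)
        results = quantify(xic, peptides=["DLYNFLK"])
        table = call_detection(results, manifest, ["DLYNFLK"]).set_index("peptide")
        assert table.loc["DLYNFLK", "healthy"] == "-"
        assert table.loc["DLYNFLK", "inflamed"] == "+"


class TestReplicates:
    def test_replicates_average_at_ratio_level(self):
        cfg = SimulationConfig(
            seed=13, peptides=["GADVWFK"], groups=["g"], samples_per_group=2,
            true_ratios={("g", "GADVWFK"): 3.0}, n_replicates=2, noise_cv=0.02,
        )
        xic, _, _ = simulate_xics(cfg)
        assert "replicate" in xic.columns
        results = quantify(xic)
        assert len(results) == 2  # one averaged result per sample
        for r in results:
            assert r.detected
            assert r.light_to_heavy_ratio == pytest.approx(3.0, rel=0.05)
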