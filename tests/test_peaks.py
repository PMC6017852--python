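import math

import numpy as np
import pytest

import qamskit as qk
from qamskit.peaks import (
    Peak,
    assign_analytes,
    detect_peaks,
    estimate_baseline,
    integrate_peak,
    plates,
    resolution,
)
from qamskit.synthetic import Chromatogram

SQRT_2PI = math.sqrt(2.0 * math.pi)


def gaussian_trace(centers_areas_sigmas, run=55.0, dt=0.01, offset=0.0, slope=0.0):
    t = np.arange(0, run + dt / 2, dt)
    y = np.full_like(t, offset) + slope * t
    for center, area, sigma in centers_areas_sigmas:
        y += area * np.exp(-0.5 * ((t - center) / sigma) ** 2) / (sigma * SQRT_2PI)
    return Chromatogram(time=t, intensity=y)


def make_peak(apex=10.0, area=1000.0, sigma=0.05, height=None, half_width=None):
    hw = half_width if half_width is not None else 2.3548 * sigma
    h = height if height is not None else area / (sigma * SQRT_2PI)
    return Peak(
        apex_time=apex,
        height=h,
        area=area,
        half_width=hw,
        start=apex - 4 * sigma,
        end=apex + 4 * sigma,
        snr=float("inf"),
    )


class TestBaseline:
    def test_flat_zero_trace(self):
        chrom = gaussian_trace([])
        baseline, sd = estimate_baseline(chrom)
        assert np.allclose(baseline, 0.0, atol=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_with_noise(self, rng):
        chrom = gaussian_trace([], offset=5.0)
        chrom.intensity += rng.normal(0, 0.1, chrom.intensity.size)
        baseline, sd = estimate_baseline(chrom)
        assert 4.9 < baseline.mean() < 5.1
        assert sd == pytest.approx(0.1, rel=0.3)

    def test_linear_drift_recovered(self, rng):
        chrom = gaussian_trace([(20.0, 500.0, 0.05)], slope=0.8)
        chrom.intensity += rng.normal(0, 0.5, chrom.intensity.size)
        baseline, _ = estimate_baseline(chrom)
        slope = np.polyfit(chrom.time, baseline, 1)[0]
        assert slope == pytest.approx(0.8, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            estimate_baseline(
                Chromatogram(time=np.arange(5) * 0.01, intensity=np.zeros(5))
            )


class TestDetect:
    def test_blank_empty(self, rng):
        chrom = gaussian_trace([])
        chrom.intensity += rng.normal(0, 1.0, chrom.intensity.size)
        baseline, sd = estimate_baseline(chrom)
        assert detect_peaks(chrom, 10.0, baseline, sd) == []

    def test_six_analyte_standard(self, response, noiseless_profile):
        spec = qk.make_standard_series(response, n_levels=6)[3]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        baseline, sd = estimate_baseline(chrom)
        assert len(detect_peaks(chrom, 10.0, baseline, sd)) == 6

    def test_close_pair_with_valley_both_reported(self):
        chrom = gaussian_trace([(20.0, 500.0, 0.05), (20.2, 500.0, 0.05)])
        baseline, sd = estimate_baseline(chrom)
        assert len(detect_peaks(chrom, 10.0, baseline, sd)) == 2

    def test_invalid_min_snr(self):
        chrom = gaussian_trace([(20.0, 500.0, 0.05)])
        with pytest.raises(ValueError, match="min_snr"):
            detect_peaks(chrom, 0.0)


class TestIntegrate:
    def test_gaussian_area_within_half_percent(self):
        chrom = gaussian_trace([(20.0, 1000.0, 0.05)])
        baseline, sd = estimate_baseline(chrom)
        [apex] = detect_peaks(chrom, 10.0, baseline, sd)
        peak = integrate_peak(chrom, apex, baseline, sd)
        assert peak.area == pytest.approx(1000.0, rel=5e-3)

    def test_gaussian_half_width_identity(self):
        chrom = gaussian_trace([(20.0, 1000.0, 0.05)])
        baseline, sd = estimate_baseline(chrom)
        [apex] = detect_peaks(chrom, 10.0, baseline, sd)
        peak = integrate_peak(chrom, apex, baseline, sd)
        assert peak.half_width == pytest.approx(2.3548 * 0.05, rel=0.02)

    def test_clipped_peak_errors(self):
        chrom = gaussian_trace([(54.95, 1000.0, 0.05)])
        baseline, sd = estimate_baseline(chrom)
        apex = int(np.argmax(chrom.intensity))
        with pytest.raises(ValueError, match="clipped"):
            integrate_peak(chrom, apex, baseline, sd)

    def test_additivity_for_resolved_pair(self):
        sigma = 0.05
        single_a = gaussian_trace([(20.0, 800.0, sigma)])
        single_b = gaussian_trace([(20.0 + 8 * sigma, 400.0, sigma)])
        both = gaussian_trace(
            [(20.0, 800.0, sigma), (20.0 + 8 * sigma, 400.0, sigma)]
        )
        totals = []
        for chrom in (single_a, single_b, both):
            baseline, sd = estimate_baseline(chrom)
            apexes = detect_peaks(chrom, 10.0, baseline, sd)
            totals.append(
                sum(integrate_peak(chrom, i, baseline, sd).area for i in apexes)
            )
        assert totals[2] == pytest.approx(totals[0] + totals[1], rel=5e-3)


class TestSuitabilityMetrics:
    def test_plates_formula(self):
        peak = make_peak(apex=35.0, half_width=0.095)
        expected = 5.54 * (35.0 / 0.095) ** 2
        assert plates(peak) == pytest.approx(expected)
        assert plates(peak) == pytest.approx(751_967, rel=1e-3)

    def test_plates_inside_printed_range(self):
        peak = make_peak(apex=15.75, half_width=0.09)
        n = plates(peak)
        assert n == pytest.approx(5.54 * 175.0**2)
        assert 30_711 <= n <= 744_241

    def test_plates_requires_positive_width(self):
        peak = make_peak()
        peak.half_width = 0.0
        with pytest.raises(ValueError):
            plates(peak)

    def test_tailing_symmetric_gaussian(self):
        chrom = gaussian_trace([(20.0, 1000.0, 0.05)])
        baseline, sd = estimate_baseline(chrom)
        [apex] = detect_peaks(chrom, 10.0, baseline, sd)
        peak = integrate_peak(chrom, apex, baseline, sd)
        assert peak.tailing == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("target", [1.10, 1.19])
    def test_tailing_emg_above_one(self, target, response):
        prof = qk.InstrumentProfile(noise_sd=0.0, tailing_target=target)
        chrom = qk.simulate_injection(qk.InjectionSpec({"PQ-6": 50.0}), response, prof)
        baseline, sd = estimate_baseline(chrom)
        [apex] = detect_peaks(chrom, 10.0, baseline, sd)
        peak = integrate_peak(chrom, apex, baseline, sd)
        assert peak.tailing == pytest.approx(target, abs=0.03)
        assert peak.tailing > 1.0

    def test_tailing_fronting_below_one(self, response):
        prof = qk.InstrumentProfile(noise_sd=0.0, tailing_target=0.85)
        chrom = qk.simulate_injection(qk.InjectionSpec({"PQ-6": 50.0}), response, prof)
        baseline, sd = estimate_baseline(chrom)
        [apex] = detect_peaks(chrom, 10.0, baseline, sd)
        peak = integrate_peak(chrom, apex, baseline, sd)
        assert peak.tailing < 1.0
        assert peak.tailing == pytest.approx(0.85, abs=0.03)

    def test_resolution_identical_apexes(self):
        a = make_peak(apex=10.0)
        assert resolution(a, make_peak(apex=10.0)) == 0.0

    def test_resolution_six_sigma_separation(self):
        sigma = 0.05
        a = make_peak(apex=10.0, sigma=sigma)
        b = make_peak(apex=10.0 + 6 * sigma, sigma=sigma)
        assert resolution(a, b) == pytest.approx(1.5, rel=0.05)

    def test_default_library_peaks_resolved(self, response, noiseless_profile):
        spec = qk.make_standard_series(response, n_levels=6)[5]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        values = [
            p.resolution for p in table.peaks if p.resolution is not None
        ]
        assert len(values) == 5
        assert min(values) >= 1.5


class TestAssignment:
    def test_noiseless_standard_fully_assigned(self, response, noiseless_profile):
        spec = qk.make_standard_series(response, n_levels=6)[2]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        assert sorted(table.assignments) == sorted(qk.ANALYTES)
        assert table.rrt["PQ-6"] == 1.0
        assert table.rpa["PQ-6"] == 1.0

    def test_recovered_rrts_match_library(self, response, noiseless_profile, library):
        spec = qk.make_standard_series(response, n_levels=6)[2]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        tol = chrom.dt / noiseless_profile.reference_rt
        for analyte, (expected, _) in library.entries.items():
            assert abs(table.rrt[analyte] - expected) <= 2 * tol

    def test_tie_breaks_toward_smaller_expected_rrt(self, library):
        ref = make_peak(apex=35.0, area=4000.0)
        contested = make_peak(apex=0.735 * 35.0, area=1000.0)
        table = assign_analytes([ref, contested], library)
        # |0.735-0.72| == |0.735-0.75|: exact tie goes to PQ-5
        assert table.assignments.get("PQ-5") is not None
        assert table.peak_of("PQ-5").apex_time == pytest.approx(0.735 * 35.0)
        assert "PQ-4" not in table.assignments

    def test_rrt_outside_all_windows_unassigned(self, library):
        ref = make_peak(apex=35.0, area=4000.0)
        stray = make_peak(apex=0.60 * 35.0, area=500.0)
        table = assign_analytes([ref, stray], library)
        assert "PQ-6" in table.assignments
        assert len(table.assignments) == 1

    def test_blank_reference_not_found(self, library):
        with pytest.raises(ValueError, match="reference peak not found"):
            assign_analytes([], library)

    def test_assignment_permutation_invariant(
        self, response, noiseless_profile, library, rng
    ):
        spec = qk.make_standard_series(response, n_levels=6)[1]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        peaks = list(table.peaks)
        for _ in range(5):
            shuffled = [peaks[i] for i in rng.permutation(len(peaks))]
            again = assign_analytes(shuffled, library)
            assert {
                a: round(again.peak_of(a).apex_time, 6) for a in again.assignments
            } == {a: round(table.peak_of(a).apex_time, 6) for a in table.assignments}

    def test_rpa_is_area_ratio(self, response, noiseless_profile):
        spec = qk.make_standard_series(response, n_levels=6)[3]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        ref_area = table.area_of("PQ-6")
        for analyte in table.assignments:
            assert table.rpa[analyte] == pytest.approx(
                table.area_of(analyte) / ref_area
            )

    def test_csv_layout(self, response, noiseless_profile, tmp_path):
        from qamskit.io import peak_table_to_csv

        spec = qk.make_standard_series(response, n_levels=6)[0]
        chrom = qk.simulate_injection(spec, response, noiseless_profile)
        table = qk.build_peak_table(chrom)
        path = tmp_path / "peaks.csv"
        peak_table_to_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "analyte,rt_min,rrt,area,rpa,height,snr,plates,tailing,resolution"
        )
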