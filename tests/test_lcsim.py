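"""Forward-simulator physics: chromatographic fractionation, capture
devices, ESI bias, drift, AGC-regulated scan generation."""

import math
import warnings

import numpy as np
import pytest

from lciso import delta_pipeline as dp
from lciso.ion_stats import aggregate_block, shot_noise_limit
from lciso.lcsim import (
    CaptureOverflowError,
    EsiBiasParams,
    SimConfig,
    capture_capillary,
    capture_chamber,
    chamber_front,
    chamber_stability_time_min,
    default_esi_bias,
    direct_infusion_profile,
    esi_bias,
    instrument_drift,
    isotopologue_ratio,
    linearity_experiment,
    preset_config,
    run_experiment,
    sample_scans,
    simulate_chromatogram,
    summarize_linearity,
)


def capillary_cfg(**ov):
    return preset_config("capillary", seed=0, **ov)


class TestChromatogram:
    def test_no_offset_constant_flux_ratio(self):
        cfg = SimConfig(fragment_id="F64", retention_offset_s={})
        chrom = simulate_chromatogram(cfg)
        core = slice(len(chrom.t_s) // 4, 3 * len(chrom.t_s) // 4)
        ratio = chrom.flux_nmol_s["34S"][core] / chrom.flux_nmol_s["M0"][core]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_area_conservation(self):
        cfg = SimConfig(fragment_id="F99", true_delta_permil={"13C": 18.2})
        chrom = simulate_chromatogram(cfg)
        ratios = {
            "13C": isotopologue_ratio("F99", "13C", 18.2),
            "15N": isotopologue_ratio("F99", "15N", 0.0),
        }
        denom = 1.0 + sum(ratios.values())
        for iso, frac in [("M0", 1 / denom), ("13C", ratios["13C"] / denom)]:
            area = np.trapezoid(chrom.flux_nmol_s[iso], chrom.t_s)
            assert area == pytest.approx(cfg.injected_nmol * frac, rel=1e-6)

    def test_log_ratio_slope_is_offset_over_sigma_squared(self):
        offset, sigma = 0.075, 15.0
        cfg = SimConfig(fragment_id="F64", retention_offset_s={"34S": offset}, peak_sigma_s=sigma)
        chrom = simulate_chromatogram(cfg)
        tc = cfg.peak_center_min * 60.0
        sel = np.abs(chrom.t_s - tc) < 2 * sigma
        logr = np.log(chrom.flux_nmol_s["34S"][sel] / chrom.flux_nmol_s["M0"][sel])
        slope = np.polyfit(chrom.t_s[sel], logr, 1)[0]
        assert slope == pytest.approx(offset / sigma**2, rel=1e-6)

    def test_instantaneous_delta_spans_20_permil_across_2sigma(self):
        # 1000 * 4*sigma * offset/sigma^2 = 20 permil for offset 0.075 s,
        # sigma 15 s
        offset, sigma = 0.075, 15.0
        cfg = SimConfig(fragment_id="F64", retention_offset_s={"34S": offset}, peak_sigma_s=sigma)
        chrom = simulate_chromatogram(cfg)
        tc = cfg.peak_center_min * 60.0
        nat = isotopologue_ratio("F64", "34S", 0.0)

        def delta_at(t):
            i = np.argmin(np.abs(chrom.t_s - t))
            return dp.delta_value(chrom.flux_nmol_s["34S"][i] / chrom.flux_nmol_s["M0"][i], nat)

        span = delta_at(tc + 2 * sigma) - delta_at(tc - 2 * sigma)
        assert span == pytest.approx(20.0, rel=0.02)


class TestCaptureCapillary:
    def test_moles_conserved(self):
        cfg = capillary_cfg()
        chrom = simulate_chromatogram(cfg)
        profile = capture_capillary(chrom, cfg)
        captured = profile.captured_nmol(cfg.low_flow_uL_min)
        t0, t1 = cfg.peak_center_min * 60 - 30, cfg.peak_center_min * 60 + 30
        for iso, f in chrom.flux_nmol_s.items():
            sel = (chrom.t_s >= t0) & (chrom.t_s <= t1)
            loaded = np.trapezoid(np.where(sel, f, 0.0), chrom.t_s)
            assert captured[iso] == pytest.approx(loaded, rel=1e-5)

    def test_elution_duration_is_window_times_flow_ratio(self):
        cfg = capillary_cfg()  # 60 s at 500/4 flow ratio -> 125 min
        chrom = simulate_chromatogram(cfg)
        profile = capture_capillary(chrom, cfg)
        assert profile.t_min[-1] == pytest.approx(125.0)

    def test_overflow_errors_with_volumes_quoted(self):
        cfg = capillary_cfg(capture_window_s=80.0)  # 667 uL > 540 uL
        chrom = simulate_chromatogram(cfg)
        with pytest.raises(CaptureOverflowError, match="540"):
            capture_capillary(chrom, cfg)

    def test_symmetric_tic_but_reversed_isotope_trend(self):
        cfg = capillary_cfg()
        chrom = simulate_chromatogram(cfg)
        profile = capture_capillary(chrom, cfg)
        # symmetric Gaussian: reversal invisible in the (basepeak) TIC;
        # only the retention-shifted rare species breaks the symmetry
        base = profile.conc_uM["M0"]
        np.testing.assert_allclose(base, base[::-1], rtol=1e-6)
        # visible in the ratio: heavier retained longer elutes FIRST at the
        # source, so the delta trend decreases over elution time
        r = profile.conc_uM["34S"] / np.where(profile.conc_uM["M0"] > 0, profile.conc_uM["M0"], np.nan)
        mid = len(r) // 2
        sel = slice(mid - mid // 2, mid + mid // 2)
        slope = np.polyfit(profile.t_min[sel], r[sel], 1)[0]
        assert slope < 0

    def test_isotope_conservation_full_peak(self):
        # amount-weighted delta over the entire eluted peak equals the
        # injected material's delta: chromatography only redistributes
        cfg = capillary_cfg(
            capture_window_s=150.0, capillary_volume_uL=2000.0,
            true_delta_permil={"34S": 7.0},
        )
        chrom = simulate_chromatogram(cfg)
        profile = capture_capillary(chrom, cfg)
        captured = profile.captured_nmol(cfg.low_flow_uL_min)
        r = captured["34S"] / captured["M0"]
        assert r == pytest.approx(isotopologue_ratio("F64", "34S", 7.0), rel=1e-6)


class TestCaptureChamber:
    def test_dilution_arithmetic(self):
        # 40 uL x 100 uM fully captured into 1140 uL -> 3.51 uM
        cfg = SimConfig(capture_mode="chamber", capture_window_s=300.0)
        chrom = simulate_chromatogram(cfg)
        profile = capture_chamber(chrom, cfg)
        c0 = sum(c[0] for c in profile.conc_uM.values())
        assert c0 == pytest.approx(40 * 100 / 1140, rel=1e-3)

    def test_outlet_ratio_constant_everywhere(self):
        cfg = SimConfig(capture_mode="chamber", fragment_id="F64", retention_offset_s={"34S": 0.075})
        chrom = simulate_chromatogram(cfg)
        profile = capture_chamber(chrom, cfg)
        sel = profile.conc_uM["M0"] > profile.conc_uM["M0"][0] * 1e-6
        r = profile.conc_uM["34S"][sel] / profile.conc_uM["M0"][sel]
        assert np.max(r) - np.min(r) == pytest.approx(0.0, abs=1e-15)

    def test_tic_stable_for_three_hours(self):
        cfg = SimConfig(capture_mode="chamber")
        t_min = chamber_stability_time_min(cfg)
        assert t_min == pytest.approx(180.2, abs=1.0)
        assert chamber_front(60.0, cfg) > 0.999

    def test_moles_conserved_through_washout(self):
        cfg = SimConfig(capture_mode="chamber")
        chrom = simulate_chromatogram(cfg)
        profile = capture_chamber(chrom, cfg)
        out = profile.captured_nmol(cfg.low_flow_uL_min)
        t0, t1 = cfg.peak_center_min * 60 - 40, cfg.peak_center_min * 60 + 40
        for iso, f in chrom.flux_nmol_s.items():
            sel = (chrom.t_s >= t0) & (chrom.t_s <= t1)
            loaded = np.trapezoid(np.where(sel, f, 0.0), chrom.t_s)
            assert out[iso] == pytest.approx(loaded, rel=1e-3)


class TestSourceResponse:
    def test_bias_zero_at_reference_concentration(self):
        params = default_esi_bias()
        assert esi_bias(4.0, "34S", params) == 0.0
        assert esi_bias(4.0, "13C", params) == 0.0
        assert esi_bias(6.0, "34S", params) == 0.0  # linear range above c_lin

    def test_sulfur_bias_bounded_by_9_permil(self):
        params = default_esi_bias()
        for c in np.linspace(0.5, 3.999, 50):
            assert abs(esi_bias(c, "34S", params)) <= 9.0 + 1e-9

    def test_carbon_bias_65_permil_at_half_micromolar(self):
        assert esi_bias(0.5, "13C", default_esi_bias()) == pytest.approx(-65.0, rel=1e-9)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            esi_bias(0.0, "13C", default_esi_bias())

    def test_drift_factor_arithmetic_and_determinism(self):
        t = np.array([0.0, 30.0])
        assert np.allclose(instrument_drift(t, 0.0, 0.0), 1.0)
        assert instrument_drift(t, 2.0, 0.0)[1] == pytest.approx(1.001)
        a = instrument_drift(np.arange(100.0), 1.0, 0.5, np.random.default_rng(5))
        b = instrument_drift(np.arange(100.0), 1.0, 0.5, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestSampleScans:
    def test_noise_off_round_trip_is_transparent(self, f99_specs):
        cfg = SimConfig(
            capture_mode="none", duration_min=16.0, bracketing=False,
            poisson_noise=False, esi_bias_params={},
            drift_permil_per_hour=0.0, drift_walk_permil_sqrt_hour=0.0,
            true_delta_permil={"13C": 18.2}, injection_volume_uL=80.0,
        )
        records, _ = run_experiment(cfg)
        block = aggregate_block(records, (0.0, 15.0), f99_specs)
        expected = isotopologue_ratio("F99", "13C", 18.2)
        assert block.ratios["13C"] == pytest.approx(expected, rel=1e-12)

    def test_poisson_block_scatter_matches_shot_noise(self, f99_specs):
        # replicate 1-min blocks of a constant infusion: empirical ratio
        # RSE within 15% of the counting-statistics prediction
        cfg = SimConfig(
            capture_mode="none", duration_min=300.0, bracketing=False,
            esi_bias_params={}, drift_permil_per_hour=0.0,
            drift_walk_permil_sqrt_hour=0.0, injection_volume_uL=1200.0,
            seed=11,
        )
        records, _ = run_experiment(cfg)
        ratios, rses = [], []
        for k in range(300):
            b = aggregate_block(records, (k * 1.0, (k + 1) * 1.0), f99_specs)
            ratios.append(b.ratios["13C"])
            rses.append(b.shot_noise_rse["13C"])
        ratios = np.asarray(ratios)
        empirical = ratios.std(ddof=1) / ratios.mean()
        assert empirical == pytest.approx(np.mean(rses), rel=0.15)

    def test_agc_cap_fixes_total_counts(self, f99_specs):
        def total_first_spectrum(conc):
            cfg = SimConfig(
                capture_mode="none", duration_min=2.0, bracketing=False,
                poisson_noise=False, esi_bias_params={},
                drift_permil_per_hour=0.0, drift_walk_permil_sqrt_hour=0.0,
                injection_conc_uM=conc, injection_volume_uL=800.0,
            )
            records, _ = run_experiment(cfg)
            first = [r for r in records if r.scan_no == 1]
            from lciso.ion_stats import ions_observed

            totals = {r.isotopologue: ions_observed(r) for r in first}
            return sum(totals.values()), totals["13C"] / totals["M0"]

        total_low, ratio_low = total_first_spectrum(50.0)
        total_high, ratio_high = total_first_spectrum(100.0)
        assert total_low == pytest.approx(cfg_agc_expected(), rel=1e-9)
        assert total_high == pytest.approx(total_low, rel=1e-9)
        assert ratio_high == pytest.approx(ratio_low, rel=1e-12)

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = preset_config("chamber", seed=42, duration_min=20.0)
        run_experiment(cfg, out_dir=tmp_path / "a")
        run_experiment(cfg, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "scans.tsv").read_bytes() == (
            tmp_path / "b" / "scans.tsv"
        ).read_bytes()


def cfg_agc_expected():
    cfg = SimConfig()
    return cfg.agc_target * cfg.microscans


class TestEndToEnd:
    def test_chamber_noise_free_recovers_enrichment_exactly(self, f99_specs):
        cfg = preset_config(
            "accuracy", seed=1, esi_bias_params={}, poisson_noise=False,
            drift_permil_per_hour=0.0, drift_walk_permil_sqrt_hour=0.0,
        )
        records, truth = run_experiment(cfg)
        assert truth.injected_nmol == pytest.approx(4.0)
        sched = dp.build_schedule(180.0, 20.0, "reference", 2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blocks = dp.segment_blocks(records, sched, f99_specs)
        sb = [b for b in blocks if b.channel == "sample"]
        rb = [b for b in blocks if b.channel == "reference"]
        assert (len(sb), len(rb)) == (4, 5)
        dd = dp.drift_correct(sb, rb, "13C")
        np.testing.assert_allclose(dd, 18.2, atol=1e-9)

    def test_chamber_flat_capillary_sloped(self, f64_specs):
        # the central contrast: identical retention offsets give flat
        # chamber-mode block deltas but a clear capillary-mode trend
        nat = isotopologue_ratio("F64", "34S", 0.0)

        def block_deltas(mode, volume):
            cfg = preset_config(
                "capillary", seed=2, poisson_noise=False,
                capture_mode=mode, chamber_volume_uL=volume,
            )
            records, _ = run_experiment(cfg)
            out = []
            t_end = max(r.time_min for r in records)
            w = 0.0
            while w + 15.0 <= t_end:
                b = aggregate_block(records, (w, w + 15.0), f64_specs)
                out.append(dp.delta_value(b.ratios["34S"], nat))
                w += 15.0
            return np.asarray(out)

        chamber = block_deltas("chamber", 1140.0)
        capillary = block_deltas("capillary", 1140.0)
        assert np.max(chamber) - np.min(chamber) == pytest.approx(0.0, abs=1e-9)
        assert np.max(capillary) - np.min(capillary) > 10.0

    def test_linearity_experiment_null_and_biased(self):
        base = preset_config(
            "linearity", seed=3, esi_bias_params={},
            drift_permil_per_hour=0.0, drift_walk_permil_sqrt_hour=0.0,
        )
        null = linearity_experiment([2.0, 4.0], 2, base)
        null13 = null[null.element == "13C"]["ddelta_permil"]
        assert abs(null13.mean()) < 3 * null13.std() / math.sqrt(len(null13)) + 0.05

        biased_cfg = preset_config("linearity", seed=4)
        frame = linearity_experiment([0.5, 2.0, 4.0, 10.0], 2, biased_cfg)
        summary = summarize_linearity(frame)
        c13 = summary[summary.element == "13C"].sort_values("concentration_uM")
        assert list(c13["n"]) == [2, 2, 2, 2]
        values = c13["mean_ddelta_permil"].to_numpy()
        assert np.all(np.diff(values) > 0)  # monotone in concentration
        assert values[0] == pytest.approx(-65.0, abs=2.0)
        assert values[list(c13["concentration_uM"]).index(4.0)] == pytest.approx(0.0, abs=0.5)
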