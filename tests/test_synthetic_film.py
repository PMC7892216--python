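"""The synthetic film-response generator and its round trips."""

import numpy as np
import pandas as pd
import pytest

from filmcal import scan_io
from filmcal.features import net_optical_density
from filmcal.synthetic_film import (ChannelResponse, LotProfile, SimConfig,
                                    default_lot, default_study_design,
                                    generate_study, pdd_percent,
                                    simulate_calibration_film, simulate_pv,
                                    write_synthetic_scans)

LOT = default_lot()
NOISELESS = SimConfig(noise_sigma=0.0)


def rng():
    return np.random.default_rng(0)


class TestSimulatePV:
    def test_zero_dose_zero_noise_leaves_film_blank(self):
        pre, post = simulate_pv(0.0, "R", LOT, 0.0, rng())
        assert post == pytest.approx(pre)

    @pytest.mark.parametrize("channel", ["R", "G", "B"])
    def test_postscan_strictly_decreasing_in_dose(self, channel):
        doses = np.linspace(0, 400, 100)
        _, post = simulate_pv(doses, channel, LOT, 0.0, rng())
        assert np.all(np.diff(post) < 0)

    def test_net_od_round_trip_through_feature_definition(self):
        doses = np.array([20.0, 100.0, 250.0, 400.0])
        pre, post = simulate_pv(doses, "R", LOT, 0.0, rng())
        expected = LOT.sensitivity * LOT.channels["R"].net_od(doses)
        np.testing.assert_allclose(net_optical_density(pre, post), expected,
                                   rtol=1e-12)

    def test_red_most_sensitive_at_clinical_doses(self):
        nods = {ch: LOT.channels[ch].net_od(100.0) for ch in "RGB"}
        assert nods["R"] > nods["G"] > nods["B"]

    def test_aging_drifts_monotonically(self):
        ages = np.arange(0, 21)
        pres, posts = zip(*(simulate_pv(200.0, "R", LOT, a, rng())
                            for a in ages))
        nods = [net_optical_density(p, q) for p, q in zip(pres, posts)]
        assert np.all(np.diff(pres) < 0)       # background PV decays
        assert np.all(np.diff(nods) > 0)       # sensitivity grows

    def test_sensitivity_ordering_enforced(self):
        bad = {
            "R": ChannelResponse(alpha=0.3, beta=800.0, gamma=1e-4),
            "G": ChannelResponse(alpha=0.5, beta=600.0, gamma=1.5e-4),
            "B": ChannelResponse(alpha=0.55, beta=300.0, gamma=2e-4),
        }
        with pytest.raises(ValueError, match="ordered"):
            LotProfile(channels=bad)


class TestPDDModel:
    def test_peaks_at_dmax_then_attenuates(self):
        config = NOISELESS
        d = np.linspace(0, 245, 500)
        p = pdd_percent(d, config)
        assert p.max() == pytest.approx(100.0, abs=0.5)
        beyond = d >= config.d_max_mm
        assert np.all(np.diff(p[beyond]) < 0)

    def test_film_doses_span_dynamic_range(self):
        film = simulate_calibration_film(300.0, LOT, 0.0, NOISELESS, rng())
        doses = film["dose_cGy"].to_numpy()
        assert doses.max() == pytest.approx(300.0, rel=1e-6)
        assert doses.min() < 0.3 * 300.0
        assert np.all(np.diff(doses) < 0)


class TestStudyGeneration:
    def test_seeded_reproducibility(self):
        config = SimConfig(noise_sigma=0.003, seed=11)
        a = simulate_calibration_film(200.0, LOT, 3.0, config,
                                      np.random.default_rng(5))
        b = simulate_calibration_film(200.0, LOT, 3.0, config,
                                      np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_default_study_layout(self):
        design = default_study_design()
        assert len(design["C"]) == 17
        assert len(design["A"]) == 7 and len(design["B"]) == 3
        # the 16th-to-17th gap of the training lot is 4 months
        assert design["C"][16][1] - design["C"][15][1] == pytest.approx(4.0)
        table = generate_study(
            [default_lot("C"), default_lot("A", sensitivity=1.07)],
            [design["C"], design["A"]], SimConfig(seed=2))
        assert set(table["lot_id"]) == {"C", "A"}
        assert table[table.lot_id == "C"]["calibration_index"].max() == 17
        assert (table["dose_cGy"] >= 20.0).all()
        assert (table["dose_cGy"] <= 400.0).all()

    def test_lot_sensitivity_scales_net_od(self):
        hot = default_lot("H", sensitivity=1.07)
        pre_h, post_h = simulate_pv(200.0, "R", hot, 0.0, rng())
        pre_c, post_c = simulate_pv(200.0, "R", LOT, 0.0, rng())
        ratio = net_optical_density(pre_h, post_h) / \
            net_optical_density(pre_c, post_c)
        assert ratio == pytest.approx(1.07, rel=1e-9)


class TestScanRoundTrip:
    def test_tiff_round_trip_recovers_sample_pvs(self, tmp_path):
        # 1 mm per pixel puts image rows exactly on the sample grid
        dpi = 25.4
        film = simulate_calibration_film(300.0, LOT, 0.0, NOISELESS, rng())
        pre_path, post_path = write_synthetic_scans(film, dpi=dpi,
                                                    out_dir=tmp_path)
        pre = scan_io.read_scan(pre_path, "prescan")
        post = scan_io.read_scan(post_path, "postscan")
        prof_pre = scan_io.extract_midline_profile(pre, window_px=5, step_px=1)
        prof_post = scan_io.extract_midline_profile(post, window_px=5,
                                                    step_px=1)
        paired = scan_io.pair_profiles(prof_pre, prof_post)
        # the TIFF resolution rational reproduces dpi only to ~1e-8,
        # so align positions to the 1 mm grid before joining
        paired["position_mm"] = paired["position_mm"].round(3)
        merged = paired.merge(film, on="position_mm", suffixes=("_img", ""))
        assert len(merged) == len(film)
        for col in ("R_bpv", "G_bpv", "B_ipv", "R_ipv"):
            np.testing.assert_allclose(merged[f"{col}_img"], merged[col],
                                       atol=0.51)
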