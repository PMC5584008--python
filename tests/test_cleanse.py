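import numpy as np
import pytest
from scipy import ndimage

from ecleanse import (
    CleanseConfig,
    HUVolume,
    ThresholdTable,
    TransitionModel,
    detect_colonic_lumen,
    run_ec,
)
from ecleanse.cleanse import (
    StageError,
    edge_response_gain,
    enhance_wall,
    replace_stt,
    replace_tjunction,
)
from ecleanse.layers import ftm_vicinity
from ecleanse.material_model import FractionField
from ecleanse.preprocess import ball

M = {
    "TA": TransitionModel("TA", L=-1000.0, H=700.0),
    "TT": TransitionModel("TT", L=0.0, H=700.0),
}


def _one_voxel_setup(value):
    vol = HUVolume(np.full((3, 3, 3), value))
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    return vol, mask


class TestReplaceSTT:
    def test_pure_tissue_side_returns_tissue_base(self):
        vol, mask = _one_voxel_setup(150.0)
        tl, th = np.ones(vol.shape), np.zeros(vol.shape)
        out = replace_stt(vol, mask, (tl, th), np.full(vol.shape, 0.7), M)
        assert out.data[1, 1, 1] == pytest.approx(M["TT"].L)

    def test_blend_example(self):
        # t_L=0.8, t_H=0.2, f_ww=1, L_TT=0, L_TA=-1000 -> -200
        vol, mask = _one_voxel_setup(300.0)
        tl, th = np.full(vol.shape, 0.8), np.full(vol.shape, 0.2)
        out = replace_stt(vol, mask, (tl, th), np.ones(vol.shape), M)
        assert out.data[1, 1, 1] == pytest.approx(-200.0)

    def test_gate_blocks_low_intensity(self):
        vol, mask = _one_voxel_setup(90.0)  # below the 100 HU gate
        tl, th = np.full(vol.shape, 0.8), np.full(vol.shape, 0.2)
        out = replace_stt(vol, mask, (tl, th), np.ones(vol.shape), M)
        assert out.data[1, 1, 1] == 90.0

    def test_gate_blocks_negative_gdsd(self):
        vol, mask = _one_voxel_setup(300.0)
        tl, th = np.full(vol.shape, 0.8), np.full(vol.shape, 0.2)
        out = replace_stt(vol, mask, (tl, th), np.full(vol.shape, -0.5), M)
        assert out.data[1, 1, 1] == 300.0

    def test_missing_model_is_stage_error(self):
        vol, mask = _one_voxel_setup(300.0)
        tl, th = np.ones(vol.shape), np.zeros(vol.shape)
        with pytest.raises(StageError):
            replace_stt(vol, mask, (tl, th), np.ones(vol.shape), {"TT": M["TT"]})

    def test_untargeted_voxels_untouched(self):
        vol, mask = _one_voxel_setup(300.0)
        tl, th = np.full(vol.shape, 0.5), np.full(vol.shape, 0.5)
        out = replace_stt(vol, mask, (tl, th), np.ones(vol.shape), M)
        untouched = ~mask
        np.testing.assert_array_equal(out.data[untouched], vol.data[untouched])


class TestReplaceTJunction:
    def _frac(self, shape, a, s, t):
        return FractionField(
            t_air=np.full(shape, a), t_st=np.full(shape, s), t_tr=np.full(shape, t)
        )

    def test_pure_ftm_goes_to_air_base(self):
        vol, mask = _one_voxel_setup(700.0)
        out = replace_tjunction(vol, mask, self._frac(vol.shape, 0, 0, 1), M)
        assert out.data[1, 1, 1] == pytest.approx(-1000.0)

    def test_equal_thirds_example(self):
        vol, mask = _one_voxel_setup(0.0)
        out = replace_tjunction(vol, mask, self._frac(vol.shape, 1 / 3, 1 / 3, 1 / 3), M)
        assert out.data[1, 1, 1] == pytest.approx(-666.6667, abs=0.01)

    def test_pure_tissue_preserved_at_tissue_base(self):
        vol, mask = _one_voxel_setup(40.0)
        out = replace_tjunction(vol, mask, self._frac(vol.shape, 0, 1, 0), M)
        assert out.data[1, 1, 1] == pytest.approx(M["TT"].L)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError):
            FractionField(
                t_air=np.full((2, 2, 2), 0.5),
                t_st=np.full((2, 2, 2), 0.5),
                t_tr=np.full((2, 2, 2), 0.5),
            )


class TestEnhanceWall:
    def test_empty_band_is_identity(self):
        vol = HUVolume(np.arange(27, dtype=np.float64).reshape(3, 3, 3))
        out = enhance_wall(vol, np.zeros((3, 3, 3), dtype=bool))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_band_matches_reference_convolution(self):
        rng = np.random.default_rng(5)
        vol = HUVolume(rng.normal(0, 100, (12, 12, 12)))
        band = np.zeros((12, 12, 12), dtype=bool)
        band[5:7, 4:8, 4:8] = True
        out = enhance_wall(vol, band, sigma=0.5)
        ref = ndimage.gaussian_filter(vol.data, sigma=0.5, mode="mirror")
        np.testing.assert_allclose(out.data[band], ref[band])
        np.testing.assert_array_equal(out.data[~band], vol.data[~band])


class TestEdgeResponseGain:
    def test_normalises_step_edge_peak_to_one(self):
        cfg = CleanseConfig()
        m_tt = TransitionModel("TT", L=0.0, H=700.0)
        gain = edge_response_gain(cfg, m_tt)
        # unit-step GDSD peak at sigma=1 is 1/sqrt(2*pi*e); scaled by the
        # window-relative edge amplitude and the gain it must be 1
        peak = 1.0 / np.sqrt(2 * np.pi * np.e) * (700.0 / 2400.0)
        assert gain * peak == pytest.approx(1.0)


class TestRunEC:
    def test_empty_lumen_returns_unchanged(self):
        vol = HUVolume(np.full((12, 12, 12), 30.0))
        out, report = run_ec(vol)
        np.testing.assert_array_equal(out.data, vol.data)
        assert report.counts["lumen"] == 0
        assert any("empty lumen" in w for w in report.warnings)

    def test_locality(self, ec_result):
        vol, truth, out, report = ec_result
        thr = ThresholdTable()
        lumen = detect_colonic_lumen(vol, thr, 3).mask()
        ftm = lumen & (vol.data > thr.ftm_cut)
        band = ndimage.binary_dilation(ftm, structure=ball(1))
        allowed = lumen | band
        changed = out.data != vol.data
        assert not (changed & ~allowed).any()

    def test_report_counts_consistent(self, ec_result):
        vol, truth, out, report = ec_result
        c = report.counts
        assert all(v >= 0 for v in c.values())
        assert c["air"] + c["ftm"] <= c["lumen"]
        assert c["rewritten_removal"] > 0 and c["rewritten_peh"] > 0
        assert not (np.isnan(out.data)).any()

    def test_removes_tagging_preserves_membrane(self, scenes):
        vol, truth = scenes["att_layer"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, report = run_ec(vol)
        pure = truth.pure_ftm
        assert (out.data[pure] < -600).mean() > 0.95
        keep = truth.att & (vol.data > -300)
        assert (out.data[keep] > -300).all()

    def test_config_theta_fixed_respected(self, scenes):
        vol, _ = scenes["at_layer"]
        import warnings

        cfg = CleanseConfig(theta_mode="fixed", theta_fixed=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = run_ec(vol, cfg)
        assert all(v == 2.0 for v in report.thetas.values())
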