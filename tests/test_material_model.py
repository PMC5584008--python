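import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfinv

from ecleanse import (
    BaseEstimationError,
    EdgeSample,
    FractionField,
    HUVolume,
    TransitionModel,
    arch,
    estimate_bases,
    estimate_theta,
    project_to_arch,
    three_fractions,
)
from ecleanse.material_model import ARCH_APEX


def brute_force_x(I, y, m, n=200001):
    """Dense nearest-point oracle on the arch curve."""
    xs = np.linspace(0.0, 1.0, n)
    cx = m.L + xs * (m.H - m.L)
    cy = (m.H - m.L) * arch(xs)
    d2 = (I - cx) ** 2 + (y - cy) ** 2
    return xs[np.argmin(d2)]


class TestArch:
    def test_closed_form(self):
        x = np.linspace(0, 1, 1001)
        with np.errstate(over="ignore"):
            z = erfinv(2 * x - 1)
            ref = np.where(np.isfinite(z), np.exp(-(z**2)) / np.sqrt(2 * np.pi), 0.0)
        assert np.max(np.abs(arch(x) - ref)) <= 1e-12

    def test_endpoints_and_apex(self):
        assert arch(0.0) == 0.0
        assert arch(1.0) == 0.0
        assert arch(0.5) == pytest.approx(ARCH_APEX, abs=1e-15)

    def test_symmetry(self):
        x = np.linspace(0, 0.5, 100)
        np.testing.assert_allclose(arch(x), arch(1 - x), atol=1e-14)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            arch(1.5)


class TestProjection:
    M = TransitionModel("TT", L=0.0, H=1000.0, sigma_omega=1.0, theta=1.0)

    def test_on_curve_idempotent(self):
        xs = np.linspace(0.01, 0.99, 97)
        I = self.M.L + xs * (self.M.H - self.M.L)
        gI = (self.M.H - self.M.L) * arch(xs)  # theta=sigma_omega=1
        _, t_low, t_high = project_to_arch((I, gI), self.M)
        np.testing.assert_allclose(t_high, xs, atol=1e-9)
        np.testing.assert_allclose(t_low + t_high, 1.0, atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        I = rng.uniform(-100, 1100, size=200)
        gI = rng.uniform(0, 600, size=200)
        _, _, t_high = project_to_arch((I, gI), self.M)
        for i in range(I.size):
            ref = brute_force_x(np.clip(I[i], self.M.L, self.M.H), gI[i], self.M)
            assert abs(t_high[i] - ref) <= 1e-3

    def test_clamps_out_of_range_intensity(self):
        _, t_low, t_high = project_to_arch(EdgeSample(I=-500.0, gI=0.0), self.M)
        assert t_high == pytest.approx(0.0, abs=1e-9)
        _, t_low, t_high = project_to_arch(EdgeSample(I=5000.0, gI=0.0), self.M)
        assert t_high == pytest.approx(1.0, abs=1e-9)

    def test_scalar_sample_api(self):
        # a zero-gradient sample under the apex has two symmetric nearest
        # points straddling x=1/2, so only ~1e-3 agreement is meaningful here
        I_p, t_low, t_high = project_to_arch(EdgeSample(I=500.0, gI=0.0), self.M)
        assert isinstance(I_p, float)
        assert t_high == pytest.approx(0.5, abs=1e-3)

    def test_gradient_pulls_toward_apex(self):
        # a bright sample with a huge gradient should project nearer the apex
        _, _, flat = project_to_arch(EdgeSample(I=900.0, gI=0.0), self.M)
        _, _, steep = project_to_arch(EdgeSample(I=900.0, gI=900.0), self.M)
        assert steep < flat


class TestModels:
    def test_transition_model_validation(self):
        with pytest.raises(ValueError):
            TransitionModel("TA", L=10.0, H=10.0)
        with pytest.raises(ValueError):
            TransitionModel("TA", L=0.0, H=1.0, theta=0.0)

    def test_estimate_bases_order_and_reuse(self):
        rng = np.random.default_rng(0)
        data = np.full((6, 6, 18), 20.0)
        data[:, :, :6] = -980.0
        data[:, :, 12:] = 700.0
        vol = HUVolume(data + rng.normal(0, 5, data.shape))
        masks = {
            "air": data == -980.0,
            "ST": data == 20.0,
            "FTM": data == 700.0,
        }
        m = estimate_bases(vol, masks)
        assert m["TA"].L == pytest.approx(-980, abs=5)
        assert m["TA"].H == pytest.approx(700, abs=5)
        assert m["TT"].L == pytest.approx(20, abs=5)
        # SA reuses the air base as L and the ST base as H
        assert m["SA"].L == m["TA"].L
        assert m["SA"].H == m["TT"].L

    def test_estimate_bases_empty_mask(self):
        vol = HUVolume(np.zeros((4, 4, 4)))
        zeros = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(BaseEstimationError, match="air"):
            estimate_bases(vol, {"air": zeros, "ST": ~zeros, "FTM": ~zeros})


class TestTheta:
    def test_apex_matching_recovers_known_scale(self):
        m = TransitionModel("TA", L=-1000.0, H=0.0, sigma_omega=1.0)
        # gradients whose 95th percentile is exactly the model apex -> theta 1
        apex = (m.H - m.L) * ARCH_APEX
        g = np.linspace(0, apex / 0.95, 200)
        theta = estimate_theta(g, m)
        assert theta == pytest.approx(1.0, rel=0.02)

    def test_requires_enough_samples(self):
        m = TransitionModel("TA", L=0.0, H=100.0)
        with pytest.raises(ValueError, match="50"):
            estimate_theta(np.ones(10), m)

    def test_clamped(self):
        m = TransitionModel("TA", L=0.0, H=100.0)
        assert estimate_theta(np.full(60, 1e6), m) == 0.1
        assert estimate_theta(np.full(60, 1e-6), m) == 10.0


class TestThreeFractions:
    def test_sum_identity_random(self):
        rng = np.random.default_rng(1)
        n = 10000
        pairs = {}
        for key in ("TA", "TT", "SA"):
            t_low = rng.uniform(0, 1, n)
            pairs[key] = (t_low, 1.0 - t_low)
        fr = three_fractions(pairs)
        assert np.max(np.abs(fr.t_air + fr.t_st + fr.t_tr - 1.0)) <= 1e-12

    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
        c=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_sum_identity_property(self, a, b, c):
        pairs = {
            "TA": (np.array([a]), np.array([1 - a])),
            "TT": (np.array([b]), np.array([1 - b])),
            "SA": (np.array([c]), np.array([1 - c])),
        }
        fr = three_fractions(pairs)
        assert abs(fr.t_air[0] + fr.t_st[0] + fr.t_tr[0] - 1.0) <= 1e-12
        assert -1e-12 <= fr.t_air[0] and -1e-12 <= fr.t_st[0]

    def test_pure_materials(self):
        one = np.ones(1)
        zero = np.zeros(1)
        # pure air: SA low side + TA low side
        fr = three_fractions({"TA": (one, zero), "TT": (one, zero), "SA": (one, zero)})
        assert fr.t_air[0] == pytest.approx(2 / 3)
        # pure FTM: both tagging pairs at the high end
        fr = three_fractions({"TA": (zero, one), "TT": (zero, one), "SA": (zero, one)})
        assert fr.t_tr[0] == pytest.approx(2 / 3)

    def test_inconsistent_pair_rejected(self):
        bad = (np.array([0.5]), np.array([0.6]))
        good = (np.array([0.5]), np.array([0.5]))
        with pytest.raises(ValueError, match="TT"):
            three_fractions({"TA": good, "TT": bad, "SA": good})

    def test_missing_pair_rejected(self):
        good = (np.array([0.5]), np.array([0.5]))
        with pytest.raises(ValueError, match="SA"):
            three_fractions({"TA": good, "TT": good})


class TestFractionField:
    def test_validates_range_and_sum(self):
        ones = np.ones((2, 2, 2))
        with pytest.raises(ValueError):
            FractionField(t_air=ones, t_st=ones, t_tr=ones)
        with pytest.raises(ValueError):
            FractionField(t_air=-ones, t_st=ones, t_tr=ones)
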