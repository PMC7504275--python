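"""Linear mixing, indicator detection, and blend-fraction estimation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgoil.adulteration import (
    BlendModel,
    detect_indicators,
    estimate_blend_fraction,
    mean_profile,
    mix_profiles,
    theoretical_vs_experimental,
)
from tgoil.quant import ND, OilProfile


@pytest.fixture(scope="module")
def blend_model(profiles):
    return BlendModel(pure_a=profiles["OO"], pure_b=profiles["RRO"])


class TestMixProfiles:
    def test_endpoints_are_exact_copies(self, profiles):
        a, b = profiles["OO"], profiles["RRO"]
        assert mix_profiles(0.0, a, b).contents == b.contents
        assert mix_profiles(1.0, a, b).contents == a.contents

    def test_ten_percent_oo_lends_oolns_level(self, profiles):
        """10% RRO into OO puts the theoretical OOLn at 0.10 * 117.8."""
        blend = mix_profiles(0.10, profiles["RRO"], profiles["OO"])
        assert blend.get("OOLn") == pytest.approx(11.78)

    def test_nd_union_semantics(self):
        a = OilProfile({"X": 10.0, "Y": ND})
        b = OilProfile({"Y": ND, "Z": 4.0})
        mixed = mix_profiles(0.25, a, b)
        assert mixed.get("X") == pytest.approx(2.5)
        assert mixed.get("Y") is ND
        assert mixed.get("Z") == pytest.approx(3.0)

    def test_fraction_out_of_range(self, profiles):
        with pytest.raises(ValueError):
            mix_profiles(1.5, profiles["OO"], profiles["RRO"])

    @given(
        f=st.floats(0.0, 1.0),
        g=st.floats(0.0, 1.0),
        x=st.floats(0.0, 500.0),
        y=st.floats(0.0, 500.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mixing_is_affine(self, f, g, x, y):
        """Nested mixes compose like convex combinations of contents."""
        a = OilProfile({"T": x})
        b = OilProfile({"T": y})
        nested = mix_profiles(f, a, mix_profiles(g, a, b))
        expected = (f + g - f * g) * x + (1 - f) * (1 - g) * y
        assert nested.get("T") == pytest.approx(expected, abs=1e-9)


class TestBlendModel:
    def test_indicator_invariant_enforced(self, profiles):
        # swapping the oils breaks "indicator Nd in the opposite pure"
        with pytest.raises(ValueError):
            BlendModel(pure_a=profiles["RRO"], pure_b=profiles["OO"])

    def test_default_indicator_sets(self, blend_model):
        assert blend_model.indicators_a == {"PPO", "PPL", "PSO"}
        assert blend_model.indicators_b == {"OOLn"}


class TestDetectIndicators:
    def test_pure_oils_do_not_flag_their_own_direction(self, profiles, blend_model):
        reports = detect_indicators(profiles["RRO"], blend_model)
        assert not reports["a_in_b"].flagged  # no olive-oil markers in pure RRO
        reports = detect_indicators(profiles["OO"], blend_model)
        assert not reports["b_in_a"].flagged  # no OOLn in pure OO

    def test_one_percent_blend_flags_with_published_contents(
        self, profiles, blend_model
    ):
        reports = detect_indicators(profiles["OO_in_RRO_1.0"], blend_model)
        rep = reports["a_in_b"]
        assert rep.flagged
        assert rep.contents == pytest.approx({"PPO": 0.8, "PPL": 0.9, "PSO": 0.2})

    def test_oolns_presence_flags_rapeseed_direction(self, blend_model):
        query = OilProfile({"OOLn": 2.0, "OOO": 500.0})
        reports = detect_indicators(query, blend_model)
        assert reports["b_in_a"].flagged and not reports["a_in_b"].flagged

    def test_floor_suppresses_trace_indicator(self, blend_model):
        query = OilProfile({"OOLn": 0.1, "OOO": 500.0})
        reports = detect_indicators(query, blend_model, {"OOLn": 0.333})
        assert not reports["b_in_a"].flagged
        assert reports["b_in_a"].contents["OOLn"] == pytest.approx(0.1)


class TestEstimateFraction:
    @pytest.mark.parametrize("f", [0.01, 0.025, 0.10])
    def test_noise_free_blend_inverts_exactly(self, profiles, blend_model, f):
        blend = mix_profiles(f, profiles["OO"], profiles["RRO"])
        est = estimate_blend_fraction(blend, blend_model, "a_in_b")
        assert est.status == "ok"
        assert est.f_hat == pytest.approx(f, abs=1e-9)

    def test_pure_source_oil_estimates_unity(self, profiles, blend_model):
        est = estimate_blend_fraction(profiles["OO"], blend_model, "a_in_b")
        assert est.f_hat == pytest.approx(1.0, abs=1e-9)

    def test_reference_ten_percent_blend_indicator_ratio(
        self, profiles, blend_model
    ):
        """The measured 10% RRO-in-OO blend implies OOLn 12.2/117.8 ~ 0.104."""
        est = estimate_blend_fraction(
            profiles["RRO_in_OO_10.0"], blend_model, "b_in_a"
        )
        assert est.per_indicator["OOLn"] == pytest.approx(12.2 / 117.8, abs=1e-9)
        assert est.per_indicator["OOLn"] == pytest.approx(0.104, abs=0.001)

    def test_no_indicator_returns_zero_with_status(self, profiles, blend_model):
        est = estimate_blend_fraction(profiles["RRO"], blend_model, "a_in_b")
        assert est.status == "not_detected" and est.f_hat == 0.0

    def test_rsd_weighting_still_inverts_noise_free(self, profiles, blend_model):
        from tgoil import io as tgio

        blend = mix_profiles(0.05, profiles["RRO"], profiles["OO"])
        est = estimate_blend_fraction(
            blend, blend_model, "b_in_a", rsd_pct=tgio.reference_rsd()
        )
        assert est.f_hat == pytest.approx(0.05, abs=1e-9)


class TestTheoreticalVsExperimental:
    def test_zero_difference_on_exact_mixture(self, profiles, blend_model):
        blend = mix_profiles(0.05, profiles["OO"], profiles["RRO"])
        df = theoretical_vs_experimental(blend, 0.05, blend_model, "a_in_b")
        assert df["abs_diff_mg_g"].max() == pytest.approx(0.0, abs=1e-9)

    def test_measured_blend_deviations(self, profiles, blend_model):
        """Frozen deviations of the measured 2.5% RRO-in-OO blend from the
        linear mixing model (largest relative deviation sits on the
        low-abundance POLn, not on the major TGs)."""
        df = theoretical_vs_experimental(
            profiles["RRO_in_OO_2.5"], 0.025, blend_model, "b_in_a"
        )
        shared = ["OOP", "POL", "POLn", "OOS", "OOO", "OOL", "LLO"]
        assert df.loc[shared, "rel_diff_pct"].idxmax() == "POLn"
        assert df.loc["OOLn", "theoretical_mg_g"] == pytest.approx(0.025 * 117.8)
        assert df.loc["OOO", "rel_diff_pct"] < 2.0

    def test_fraction_out_of_range(self, profiles, blend_model):
        with pytest.raises(ValueError):
            theoretical_vs_experimental(profiles["OO"], 1.2, blend_model)


class TestMeanProfile:
    def test_mean_with_partial_nd(self):
        p1 = OilProfile({"A": 10.0, "B": ND})
        p2 = OilProfile({"A": 20.0, "B": 3.0})
        mean = mean_profile([p1, p2])
        assert mean.get("A") == pytest.approx(15.0)
        assert mean.get("B") == pytest.approx(1.5)  # Nd counts as 0

    def test_all_nd_stays_nd(self):
        mean = mean_profile([OilProfile({"B": ND}), OilProfile({"B": ND})])
        assert mean.get("B") is ND

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_profile([])
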