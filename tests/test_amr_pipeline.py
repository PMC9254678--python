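"""AMRfield interpolation algebra, activity scopes, and the per-cm
species estimate grid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_degenerate_fit
from fishamr._exceptions import InputError
from fishamr.amr_pipeline import (
    amr_field,
    fas,
    fsa,
    length_to_weight,
    species_size_estimates,
)
from fishamr.synthetic_data import SpeciesTruth

positive = st.floats(1e-4, 1e3)


class TestLengthToWeight:
    def test_unit_length_returns_coefficient(self):
        assert length_to_weight(1.0, 0.02, 3.0) == pytest.approx(0.02)

    def test_cubic_scaling(self):
        assert length_to_weight(10.0, 0.02, 3.0) == pytest.approx(20.0)

    def test_zero_exponent(self):
        assert length_to_weight(37.0, 0.02, 0.0) == pytest.approx(0.02)

    def test_non_positive_rejected(self):
        with pytest.raises(InputError):
            length_to_weight(-1.0, 0.02, 3.0)


class TestAmrField:
    def test_zero_speed_returns_smr(self):
        assert amr_field(0.01, 0.04, 100.0, 0.0) == pytest.approx(0.01, rel=1e-13)

    def test_vmax_returns_mmr(self):
        assert amr_field(0.01, 0.04, 100.0, 100.0) == pytest.approx(0.04, rel=1e-13)

    def test_midpoint_is_geometric_mean(self):
        assert amr_field(0.01, 0.04, 100.0, 50.0) == pytest.approx(0.02, rel=1e-12)

    def test_extrapolation_beyond_mmr_allowed(self):
        assert amr_field(0.01, 0.04, 100.0, 150.0) > 0.04

    def test_smr_above_mmr_rejected(self):
        with pytest.raises(InputError):
            amr_field(0.05, 0.04, 100.0, 10.0)

    @given(positive, st.floats(1.01, 50.0), st.floats(1.0, 500.0),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_vfield(self, smr, scope, vmax, r1, r2):
        lo, hi = sorted([r1, r2])
        mmr = smr * scope
        if hi > lo:
            assert amr_field(smr, mmr, vmax, lo * vmax) < amr_field(
                smr, mmr, vmax, hi * vmax
            ) * (1 + 1e-12)

    @given(positive, st.floats(1.5, 20.0), st.floats(10.0, 200.0))
    def test_log_linearity_constant_factor_per_increment(self, smr, scope, vmax):
        mmr = smr * scope
        vals = [amr_field(smr, mmr, vmax, f * vmax) for f in (0.2, 0.4, 0.6)]
        assert vals[1] / vals[0] == pytest.approx(vals[2] / vals[1], rel=1e-9)


class TestFas:
    def test_equal_rates_give_unity(self):
        assert fas(0.01, 0.01) == 1.0

    def test_ratio(self):
        assert fas(0.04, 0.01) == pytest.approx(4.0)

    def test_table_values_for_grouper_at_1g(self):
        # C. argus medians at 1 g: MMR 0.0124, SMR 0.0033 g O2/d
        assert fas(0.0124, 0.0033) == pytest.approx(3.76, abs=0.01)


class TestFsa:
    def test_amr_equal_smr_gives_unity_for_any_rest(self):
        for t in (0.0, 7.5, 12.0, 24.0):
            assert fsa(0.02, 0.02, t) == pytest.approx(1.0)

    def test_threefold_amr_at_half_day_rest(self):
        assert fsa(0.03, 0.01, 12.0) == pytest.approx(2.0)

    def test_full_day_rest_gives_unity(self):
        assert fsa(0.09, 0.01, 24.0) == pytest.approx(1.0)

    def test_rest_hours_bounds(self):
        with pytest.raises(InputError):
            fsa(0.02, 0.01, 25.0)

    @given(st.floats(1.01, 10.0), st.floats(0.0, 23.0), st.floats(0.1, 11.0))
    def test_monotone_in_amr_and_rest(self, scope, t, dt):
        smr = 0.01
        assert fsa(smr * scope * 1.1, smr, t) > fsa(smr * scope, smr, t)
        if t + dt <= 24:
            assert fsa(smr * scope, smr, t + dt) < fsa(smr * scope, smr, t)


def _truth(species_id="sp", **kw):
    base = dict(
        a_smr=math.log10(0.004), b_smr=0.70, a_mmr=math.log10(0.012),
        b_mmr=0.80, a_v=0.8, b_v=0.5, lw_a=0.02, lw_b=3.0, aspect_ratio=2.0,
        family="Fam", body_shape="fusiform", rest_hours=12.0,
        min_length_cm=5, max_length_cm=20,
    )
    base.update(kw)
    return SpeciesTruth(species_id, **base)


def _degenerate_fits(tr, b_vmax=0.5, a_vmax=1.2, c=0.0):
    """Point-mass fits matching a SpeciesTruth exactly."""
    mr_labels = [f"{tr.species_id}|mmr", f"{tr.species_id}|smr"]
    mr_fit = make_degenerate_fit(
        "mr", mr_labels, 0.0, (tr.b_smr + tr.b_mmr) / 2,
        a_offsets=[tr.a_mmr, tr.a_smr],
        b_offsets=[
            tr.b_mmr - (tr.b_smr + tr.b_mmr) / 2,
            tr.b_smr - (tr.b_smr + tr.b_mmr) / 2,
        ],
    )
    speed_fit = make_degenerate_fit("speed", [tr.species_id], tr.a_v, tr.b_v)
    maxspeed_fit = make_degenerate_fit(
        "maxspeed", [tr.group, "Other|shape"], a_vmax, b_vmax, c=c,
        a_offsets=[0.0, 0.0], b_offsets=[0.0, 0.0],
    )
    return mr_fit, speed_fit, maxspeed_fit


class TestSpeciesSizeEstimates:
    def test_degenerate_fits_collapse_to_closed_form(self):
        tr = _truth()
        grid = species_size_estimates(
            *_degenerate_fits(tr), {tr.species_id: tr}, n_iter=200, seed=0
        )
        assert len(grid) == 16
        row = grid[grid["length_cm"] == 10].iloc[0]
        mass = 0.02 * 10**3
        smr = 0.004 * mass**0.70
        mmr = 0.012 * mass**0.80
        vf = 10**0.8 * 10**0.5
        vmax = 10**1.2 * 10**0.5
        assert row["mass_g"] == pytest.approx(mass)
        assert row["smr_med"] == pytest.approx(smr, rel=1e-10)
        assert row["mmr_med"] == pytest.approx(mmr, rel=1e-10)
        assert row["amr_field_sd"] == pytest.approx(0.0, abs=1e-15)
        expected = amr_field(smr, mmr, vmax, vf)
        assert row["amr_field_mean"] == pytest.approx(expected, rel=1e-10)
        assert row["fas_mean"] == pytest.approx(mmr / smr, rel=1e-10)
        assert row["fsa_mean"] == pytest.approx(
            fsa(expected, smr, 12.0), rel=1e-10
        )

    def test_monotone_grid_when_components_increase(self):
        # FAS constant (b_smr = b_mmr) and vfield/vmax ratio constant
        tr = _truth(b_smr=0.75, b_mmr=0.75)
        fits = _degenerate_fits(tr, b_vmax=tr.b_v)
        grid = species_size_estimates(
            *fits, {tr.species_id: tr}, n_iter=50, seed=0
        )
        assert (np.diff(grid["amr_field_mean"]) > 0).all()

    def test_same_seed_identical_summaries(self, recovery_fit, recovery_data,
                                           tiny_settings, maxspeed_fit_data):
        from fishamr.hier_models import fit_speed_model
        from fishamr.synthetic_data import generate_speed_observations

        cfg, _, _ = recovery_data
        speed_fit = fit_speed_model(
            generate_speed_observations(cfg), settings=tiny_settings, seed=1
        )
        _, _, maxspeed_fit = maxspeed_fit_data
        tr = _truth("sp_1", family="Serranidae", body_shape="fusiform",
                    min_length_cm=8, max_length_cm=12)
        args = (recovery_fit, speed_fit, maxspeed_fit, {"sp_1": tr})
        g1 = species_size_estimates(*args, n_iter=300, seed=5)
        g2 = species_size_estimates(*args, n_iter=300, seed=5)
        assert g1.equals(g2)
        assert (g1["smr_med"] <= g1["mmr_med"]).all()
        assert (g1["fas_mean"] >= 1.0).all()
        assert (g1["fsa_mean"] >= 1.0).all()
        assert (g1["amr_field_ci_2.5"] <= g1["amr_field_ci_97.5"]).all()

    def test_unknown_species_rejected(self, recovery_fit, speed_fit_data,
                                      maxspeed_fit_data):
        tr = _truth("missing_sp")
        with pytest.raises(InputError):
            species_size_estimates(
                recovery_fit, speed_fit_data[2], maxspeed_fit_data[2],
                {"missing_sp": tr}, n_iter=10, seed=0,
            )


class TestScalingExponentComposition:
    """Log-log slope of AMRfield vs mass under different size-activity
    couplings, on exact closed-form grids."""

    def _grid_slope(self, ratio_fn):
        tr = _truth(b_smr=0.70, b_mmr=0.80)
        lengths = np.arange(5.0, 21.0)
        mass = length_to_weight(lengths, tr.lw_a, tr.lw_b)
        smr = 0.004 * mass**tr.b_smr
        mmr = 0.012 * mass**tr.b_mmr
        r = ratio_fn(np.log10(mass))
        amr = amr_field(smr, mmr, 100.0, 100.0 * r)
        return np.polyfit(np.log10(mass), np.log10(amr), 1)[0]

    def test_constant_activity_ratio_slope_between_smr_and_mmr(self):
        slope = self._grid_slope(lambda lm: np.full_like(lm, 0.4))
        assert 0.70 < slope < 0.80

    def test_size_increasing_activity_ratio_exceeds_mmr_exponent(self):
        lm_lo, lm_hi = math.log10(0.02 * 5**3), math.log10(0.02 * 20**3)
        slope = self._grid_slope(
            lambda lm: 0.2 + 0.6 * (lm - lm_lo) / (lm_hi - lm_lo)
        )
        assert slope > 0.80
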