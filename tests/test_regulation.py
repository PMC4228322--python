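"""Regulation functions: Z anchors, self-renewal, proliferative fraction,
characteristic functions, cytokine production and clearance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myelosim.params import default_ode_params
from myelosim.regulation import (
    ChemoApplication,
    ZSpec,
    chemo_psi,
    endogenous_production,
    gcsf_clearance_rate,
    gra_lifetime,
    proliferative_fraction,
    self_renewal_p,
    z_value,
)


@st.composite
def valid_zspecs(draw):
    """Random valid Z anchors, increasing or decreasing."""
    lo = draw(st.floats(0.01, 10.0))
    hi = draw(st.floats(0.01, 10.0))
    if abs(hi - lo) < 1e-3:
        hi = lo + 1.0
    frac = draw(st.floats(0.05, 0.95))
    nor = lo + frac * (hi - lo)
    b = draw(st.floats(0.1, 3.0))
    if draw(st.booleans()):
        return ZSpec(Y_min=lo, Y_nor=nor, Y_max=hi, b_Y=b)  # increasing
    return ZSpec(Y_min=hi, Y_nor=nor, Y_max=lo, b_Y=b)      # decreasing


class TestZFunction:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(valid_zspecs())
    def test_anchor_identities(self, spec):
        spec.validate()
        assert z_value(0.0, spec) == pytest.approx(spec.Y_min, rel=1e-12)
        assert z_value(1.0, spec) == pytest.approx(spec.Y_nor, rel=1e-9)
        assert z_value(1e30, spec) == pytest.approx(spec.Y_max, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(valid_zspecs(), st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    def test_monotone_between_bounds(self, spec, c1, c2):
        lo, hi = sorted((c1, c2))
        v_lo, v_hi = z_value(lo, spec), z_value(hi, spec)
        increasing = spec.Y_max > spec.Y_min
        if increasing:
            assert v_lo <= v_hi + 1e-12
        else:
            assert v_lo >= v_hi - 1e-12
        b_lo, b_hi = sorted((spec.Y_min, spec.Y_max))
        assert b_lo - 1e-9 <= v_lo <= b_hi + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ZSpec(Y_min=1.0, Y_nor=3.0, Y_max=2.0, b_Y=0.5).validate()


class TestChemoPsi:
    APPS = [ChemoApplication(0.0, "C750+D50+V2", is_first_cycle=True),
            ChemoApplication(504.0, "C750+D50+V2")]

    def test_first_cycle_factor_inside_first_window(self):
        assert chemo_psi(6.0, self.APPS, f_fc=1.3) == {"C750+D50+V2": 1.3}

    def test_zero_between_windows(self):
        assert chemo_psi(300.0, self.APPS) == {}

    def test_one_in_later_cycles(self):
        assert chemo_psi(510.0, self.APPS, f_fc=1.3) == {"C750+D50+V2": 1.0}

    def test_half_open_window(self):
        # (t_i, t_i + 24 h]: inactive at the application instant, active at
        # exactly one day after
        assert chemo_psi(0.0, self.APPS) == {}
        assert chemo_psi(24.0, self.APPS, f_fc=1.3) == {"C750+D50+V2": 1.3}
        assert chemo_psi(24.0 + 1e-9, self.APPS) == {}

    def test_blocks_with_different_schedules_add(self):
        apps = [ChemoApplication(0.0, "A"), ChemoApplication(12.0, "A")]
        assert chemo_psi(13.0, apps) == {"A": 2.0}


class TestPrednisone:
    WINDOWS = [(0.0, 120.0)]

    def test_lifetime_prolonged_inside_window(self):
        assert gra_lifetime(60.0, self.WINDOWS) == pytest.approx(5.0 * 1.66)

    def test_lifetime_normal_outside(self):
        assert gra_lifetime(200.0, self.WINDOWS) == pytest.approx(5.0)

    def test_no_first_cycle_effect(self):
        windows = [(0.0, 120.0), (504.0, 624.0)]
        assert gra_lifetime(60.0, windows) == gra_lifetime(560.0, windows)


class TestSelfRenewal:
    S = default_ode_params().S

    def test_equilibrium_is_one_half(self):
        assert self_renewal_p(1.0, 1.0, self.S) == pytest.approx(0.5, abs=1e-15)

    def test_stem_depletion_value(self):
        # independent scalar evaluation: -theta_S ln(0.5) = 2 ln 2
        expected = 0.1 * math.tanh(2.0 * math.log(2.0)) + 0.5
        assert self_renewal_p(0.5, 1.0, self.S) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_excess_branch(self):
        # C_S^rel > 1 uses the linear weight 0.62
        expected = 0.1 * math.tanh(-0.62 * 0.5) + 0.5
        assert self_renewal_p(1.5, 1.0, self.S) == pytest.approx(expected,
                                                                 rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(1e-15, 100.0), st.floats(1e-15, 100.0))
    def test_bounds(self, c_s, c_g):
        p = self_renewal_p(c_s, c_g, self.S)
        assert 0.4 <= p <= 0.6

    def test_feedback_directions(self):
        # stem depletion raises self-renewal; marrow depletion favours
        # differentiation (the two regulators act in contrary directions)
        assert self_renewal_p(0.01, 1.0, self.S) > 0.5
        assert self_renewal_p(1.0, 0.5, self.S) < 0.5


class TestProliferativeFraction:
    PARAMS = default_ode_params()

    @pytest.mark.parametrize("comp", ["S", "CG"])
    def test_equilibrium_gives_a_nor(self, comp):
        blk = getattr(self.PARAMS, comp)
        assert proliferative_fraction(1.0, 1.0, comp, self.PARAMS) == \
            pytest.approx(blk.a_nor, rel=1e-12)

    @pytest.mark.parametrize("comp", ["S", "CG"])
    def test_half_cellularity_coordinate_gives_a_int(self, comp):
        # choose C_G^rel so that x = omega_G ln(C_G) = -ln 2 with C_S at 1
        c_g = math.exp(-math.log(2.0) / self.PARAMS.S.omega_G)
        blk = getattr(self.PARAMS, comp)
        assert proliferative_fraction(1.0, c_g, comp, self.PARAMS) == \
            pytest.approx(blk.a_int, rel=1e-12)

    def test_depletion_saturates_at_a_max(self):
        a = proliferative_fraction(1e-12, 1e-12, "S", self.PARAMS)
        assert a == pytest.approx(self.PARAMS.S.a_max, rel=1e-6)

    def test_hypercellularity_approaches_a_min(self):
        a_mid = proliferative_fraction(2.0, 2.0, "CG", self.PARAMS)
        assert self.PARAMS.CG.a_min < a_mid < self.PARAMS.CG.a_nor
        a_far = proliferative_fraction(50.0, 50.0, "CG", self.PARAMS)
        assert a_far == pytest.approx(self.PARAMS.CG.a_min, rel=1e-6)

    def test_continuous_across_seam(self):
        # both branch forms contribute 0 at C_S^rel = 1
        below = proliferative_fraction(1.0 - 1e-9, 1.0, "S", self.PARAMS)
        above = proliferative_fraction(1.0 + 1e-9, 1.0, "S", self.PARAMS)
        assert below == pytest.approx(above, abs=1e-7)

    def test_unregulated_compartment_rejected(self):
        with pytest.raises(ValueError):
            proliferative_fraction(1.0, 1.0, "PGB", self.PARAMS)


class TestCytokineProduction:
    PARAMS = default_ode_params()
    NOR = {"CG": 50.0, "PGB": 1000.0, "G4": 2000.0, "G5": 3500.0,
           "G6": 600.0, "GRA": 80.0}

    def test_equilibrium_production_is_one(self):
        for block in (self.PARAMS.GM_CSF, self.PARAMS.G_CSF):
            assert endogenous_production(dict(self.NOR), self.NOR, block) == \
                pytest.approx(1.0, rel=1e-9)

    def test_empty_marrow_gives_maximal_production(self):
        zeros = {k: 0.0 for k in self.NOR}
        assert endogenous_production(zeros, self.NOR, self.PARAMS.GM_CSF) == \
            pytest.approx(310.0, rel=1e-9)
        assert endogenous_production(zeros, self.NOR, self.PARAMS.G_CSF) == \
            pytest.approx(410.0, rel=1e-9)

    def test_hypercellularity_decreases_production(self):
        doubled = {k: 2.0 * v for k, v in self.NOR.items()}
        for block in (self.PARAMS.GM_CSF, self.PARAMS.G_CSF):
            assert endogenous_production(doubled, self.NOR, block) < 1.0


class TestGcsfClearance:
    def test_equilibrium_rate(self):
        assert gcsf_clearance_rate(1.0) == pytest.approx(1 / 20 + 1 / 2.8)

    def test_no_granulocytes_leaves_unspecific_only(self):
        assert gcsf_clearance_rate(0.0) == pytest.approx(1 / 20)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert gcsf_clearance_rate(lo) < gcsf_clearance_rate(hi)
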