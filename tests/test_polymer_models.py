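"""Polymer elasticity and step-size arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titinmech import polymer_models as pm
from titinmech.states import (
    FOLDED_BG,
    FOLDED_RED,
    UNFOLDED_BF,
    UNFOLDED_BG,
    UNFOLDED_FG,
    UNFOLDED_RED,
    DomainState,
    Fold,
    Redox,
)


def _wlc_bisect(F, p, kT, tol=1e-12):
    """Independent oracle: plain bisection on the interpolation formula."""
    lo, hi = 0.0, 1.0 - 1e-13
    f = lambda z: (kT / p) * (0.25 / (1 - z) ** 2 - 0.25 + z) - F
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestWLC:
    def test_zero_force_limit(self, params):
        assert pm.wlc_fractional_extension(0.0, params) == 0.0

    @pytest.mark.parametrize("F,expected", [
        (100.0, 0.834), (170.0, 0.874),
    ])
    def test_matches_bisection_oracle(self, F, expected, params):
        z = pm.wlc_fractional_extension(F, params)
        assert z == pytest.approx(_wlc_bisect(F, params.p, params.kT), abs=1e-9)
        assert z == pytest.approx(expected, abs=1e-3)

    def test_negative_force_rejected(self, params):
        with pytest.raises(ValueError):
            pm.wlc_fractional_extension(-1.0, params)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(F=st.floats(min_value=1.0, max_value=500.0))
    def test_round_trip(self, F):
        params = pm.PolymerParams()
        z = pm.wlc_fractional_extension(F, params)
        assert pm.wlc_force(z, params) == pytest.approx(F, rel=1e-9)

    def test_strictly_increasing_and_bounded(self, params):
        forces = np.linspace(0, 500, 200)
        zs = [pm.wlc_fractional_extension(F, params) for F in forces]
        assert all(0 <= z < 1 for z in zs)
        assert np.all(np.diff(zs) > 0)


class TestFJC:
    def test_zero_force_limit(self, params):
        assert pm.fjc_fractional_extension(0.0, params) == 0.0

    def test_langevin_value(self, params):
        u = 30.0 * params.b / params.kT
        expected = 1.0 / math.tanh(u) - 1.0 / u
        assert pm.fjc_fractional_extension(30.0, params) == pytest.approx(expected)
        assert expected == pytest.approx(0.8755, abs=5e-4)

    def test_high_force_asymptote(self, params):
        assert pm.fjc_fractional_extension(1e5, params) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_and_vectorized(self, params):
        zs = pm.fjc_fractional_extension(np.linspace(0, 200, 100), params)
        assert np.all(np.diff(zs) > 0)
        assert np.all((zs >= 0) & (zs < 1))

    def test_negative_force_rejected(self, params):
        with pytest.raises(ValueError):
            pm.fjc_fractional_extension(-5.0, params)


class TestReleasedResidues:
    @pytest.mark.parametrize("before,after,expected", [
        (FOLDED_RED, UNFOLDED_RED, 88),
        (FOLDED_BG, UNFOLDED_BG, 31),          # 88 - 57
        (UNFOLDED_BG, UNFOLDED_FG, 51),        # B-F loop freed
        (UNFOLDED_BG, UNFOLDED_BF, 11),        # F-G loop freed
        (UNFOLDED_BG, UNFOLDED_RED, 57),
        (UNFOLDED_BF, UNFOLDED_RED, 51),
        (UNFOLDED_FG, UNFOLDED_RED, 11),
    ])
    def test_table(self, before, after, expected, topo, geom):
        assert pm.released_residues(before, after, topo, geom) == expected

    def test_disallowed_transition_named_in_error(self, topo, geom):
        with pytest.raises(ValueError, match="not allowed"):
            pm.released_residues(FOLDED_BG, UNFOLDED_RED, topo, geom)

    def test_folded_state_chemistry_forbidden(self, topo, geom):
        folded_bf = DomainState(Fold.FOLDED, Redox.SS_BF)
        with pytest.raises(ValueError):
            pm.released_residues(FOLDED_BG, folded_bf, topo, geom)


class TestPredictStepSize:
    def test_isomerization_steps_at_100pN(self, params, geom, topo):
        long_step = pm.predict_step_size(UNFOLDED_BG, UNFOLDED_FG, 100.0,
                                         params, geom, topo)
        short_step = pm.predict_step_size(UNFOLDED_BG, UNFOLDED_BF, 100.0,
                                          params, geom, topo)
        assert long_step == pytest.approx(17.0, abs=0.1)
        assert short_step == pytest.approx(3.7, abs=0.1)

    def test_reduced_unfolding_at_170pN_brackets_printed_value(
            self, params, geom, topo):
        step = pm.predict_step_size(FOLDED_RED, UNFOLDED_RED, 170.0,
                                    params, geom, topo)
        assert 25.4 <= step <= 27.4

    def test_oxidized_unfolding_near_6nm(self, params, geom, topo):
        step = pm.predict_step_size(FOLDED_BG, UNFOLDED_BG, 100.0,
                                    params, geom, topo)
        assert step == pytest.approx(6.0, abs=0.5)

    def test_tcep_reduction_near_19nm(self, params, geom, topo):
        step = pm.predict_step_size(UNFOLDED_BG, UNFOLDED_RED, 100.0,
                                    params, geom, topo)
        assert step == pytest.approx(19.2, abs=0.5)

    def test_zero_release_refused(self, params):
        geom0 = pm.DomainGeometry(n_ext=57, d_folded=4.4)
        topo = pm.DisulfideTopology(loop_BF=51, loop_FG=11, loop_BG=57)
        with pytest.raises(ValueError, match="zero residues"):
            pm.predict_step_size(FOLDED_BG, UNFOLDED_BG, 100.0, params,
                                 geom0, topo)

    def test_requires_positive_force(self, params, geom, topo):
        with pytest.raises(ValueError):
            pm.predict_step_size(FOLDED_RED, UNFOLDED_RED, 0.0, params,
                                 geom, topo)

    @pytest.mark.parametrize("F", [20.0, 100.0, 170.0, 300.0])
    def test_never_negative_at_working_forces(self, F, params, geom, topo):
        for before, after in [(FOLDED_RED, UNFOLDED_RED),
                              (FOLDED_BG, UNFOLDED_BG),
                              (UNFOLDED_BG, UNFOLDED_FG),
                              (UNFOLDED_BG, UNFOLDED_BF),
                              (UNFOLDED_BG, UNFOLDED_RED)]:
            assert pm.predict_step_size(before, after, F, params, geom, topo) >= 0


class TestPathAdditivity:
    """With a conservative topology both unfolding routes release the full
    n_ext and subtract d_folded exactly once, so the step sums agree."""

    @pytest.mark.parametrize("F", [20.0, 100.0, 170.0])
    def test_unfold_iso_reduce_equals_direct_unfold(
            self, F, params, geom, conservative_topo):
        topo = conservative_topo
        via_fg = (pm.predict_step_size(FOLDED_BG, UNFOLDED_BG, F, params, geom, topo)
                  + pm.predict_step_size(UNFOLDED_BG, UNFOLDED_FG, F, params, geom, topo)
                  + pm.predict_step_size(UNFOLDED_FG, UNFOLDED_RED, F, params, geom, topo))
        via_bf = (pm.predict_step_size(FOLDED_BG, UNFOLDED_BG, F, params, geom, topo)
                  + pm.predict_step_size(UNFOLDED_BG, UNFOLDED_BF, F, params, geom, topo)
                  + pm.predict_step_size(UNFOLDED_BF, UNFOLDED_RED, F, params, geom, topo))
        direct = pm.predict_step_size(FOLDED_RED, UNFOLDED_RED, F, params, geom, topo)
        assert via_fg == pytest.approx(direct, abs=1e-9)
        assert via_bf == pytest.approx(direct, abs=1e-9)

    def test_default_topology_is_flagged_non_conservative(self, topo):
        assert not topo.is_conservative

    def test_invariants_on_construction(self):
        with pytest.raises(ValueError):
            pm.DisulfideTopology(loop_BF=51, loop_FG=11, loop_BG=40)
        with pytest.raises(ValueError):
            pm.PolymerParams(p=-0.1)
        with pytest.raises(ValueError):
            pm.DomainGeometry(n_ext=0)
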