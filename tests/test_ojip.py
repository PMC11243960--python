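"""JIP-test engine: cardinal points, normalisations, difference curves,
derived parameters, against analytic oracles on the closed-form model."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluoromics as fm
from fluoromics._utils import log_time_grid
from fluoromics.containers import T_I, T_J, T_K
from fluoromics.errors import DegenerateTransientError, ValidationError


class TestCardinalPoints:
    def test_points_match_closed_form_on_exact_grid(self, default_params, cardinal_grid):
        # the grid contains 300 µs / 2 ms / 30 ms, so interpolation is exact
        tr = fm.gen_ojip_transient(default_params, cardinal_grid)
        pts = fm.extract_cardinal_points(tr)
        model = lambda t: fm.ojip_model(default_params, np.array([t]))[0]
        assert pts.fk == pytest.approx(model(T_K), abs=1e-9 * model(T_K))
        assert pts.fj == pytest.approx(model(T_J), abs=1e-9 * model(T_J))
        assert pts.fi == pytest.approx(model(T_I), abs=1e-9 * model(T_I))

    def test_fo_is_global_minimum_even_if_interior(self, healthy_transient):
        f = healthy_transient.fluorescence.copy()
        f[3] = f.min() - 50.0  # dip at an interior sample
        tr = fm.FluorescenceTransient(healthy_transient.time, f)
        pts = fm.extract_cardinal_points(tr)
        assert pts.fo == f[3]
        assert pts.t_fo == tr.time[3]

    def test_flat_trace_is_degenerate(self, healthy_transient):
        tr = fm.FluorescenceTransient(
            healthy_transient.time, np.full_like(healthy_transient.time, 700.0)
        )
        with pytest.raises(DegenerateTransientError):
            fm.extract_cardinal_points(tr)


class TestNormalisation:
    def test_vt_is_one_at_fm_and_zero_at_fo(self, healthy_transient):
        curves = fm.normalize_transient(healthy_transient)
        i_max = np.argmax(healthy_transient.fluorescence)
        i_min = np.argmin(healthy_transient.fluorescence)
        assert curves.vt[i_max] == pytest.approx(1.0, abs=1e-12)
        assert curves.vt[i_min] == pytest.approx(0.0, abs=1e-12)

    def test_wt_is_one_at_j_point(self, healthy_transient):
        curves = fm.normalize_transient(healthy_transient)
        from fluoromics._utils import interp_log_time

        assert interp_log_time(curves.time, curves.wt, T_J) == pytest.approx(1.0, abs=1e-9)

    def test_vt_matches_closed_form(self, default_params, cardinal_grid):
        tr = fm.gen_ojip_transient(default_params, cardinal_grid)
        curves = fm.normalize_transient(tr)
        f2 = fm.ojip_model(default_params, np.array([T_J]))[0]
        fo, fmax = tr.fluorescence.min(), tr.fluorescence.max()
        expected = (f2 - fo) / (fmax - fo)
        from fluoromics._utils import interp_log_time

        assert interp_log_time(curves.time, curves.vt, T_J) == pytest.approx(expected, rel=1e-12)


class TestDifferenceCurves:
    def test_self_difference_is_zero(self, healthy_transient):
        c = fm.normalize_transient(healthy_transient)
        d = fm.difference_curves(c, c)
        assert np.allclose(d.delta_vt, 0.0, atol=1e-14)
        assert d.delta_wk == pytest.approx(0.0, abs=1e-14)

    def test_damaged_vs_healthy_gives_positive_delta_wk(self, default_params):
        healthy = fm.normalize_transient(fm.gen_ojip_transient(default_params))
        damaged_params = fm.with_donor_side_damage(default_params)
        damaged = fm.normalize_transient(fm.gen_ojip_transient(damaged_params))
        assert fm.difference_curves(damaged, healthy).delta_wk > 0

    def test_swapping_roles_negates_everything(self, default_params):
        a = fm.normalize_transient(fm.gen_ojip_transient(default_params))
        b = fm.normalize_transient(
            fm.gen_ojip_transient(fm.with_donor_side_damage(default_params))
        )
        fwd = fm.difference_curves(b, a)
        rev = fm.difference_curves(a, b)
        np.testing.assert_allclose(fwd.delta_vt, -rev.delta_vt, atol=1e-12)
        assert fwd.delta_wk == pytest.approx(-rev.delta_wk, abs=1e-12)

    def test_non_overlapping_ranges_rejected(self, healthy_transient):
        c = fm.normalize_transient(healthy_transient)
        shifted = fm.NormalizedCurves(
            time=c.time + 10.0, ft_fo=c.ft_fo, vt=c.vt, wt=c.wt, points=c.points
        )
        with pytest.raises(ValidationError):
            fm.difference_curves(c, shifted)


class TestJIPParameters:
    def test_fv_fm_from_round_numbers(self, healthy_transient):
        pts = fm.extract_cardinal_points(healthy_transient)
        manual = dataclasses.replace(pts, fo=500.0, fm=2500.0)
        params = fm.jip_parameters(healthy_transient, points=manual)
        assert params.fv_fm == pytest.approx(0.8)

    def test_sm_matches_fine_grid_quadrature(self, default_params):
        tr = fm.gen_ojip_transient(default_params)
        sm = fm.jip_parameters(tr).sm
        fine = log_time_grid(n=200_000)
        f = fm.ojip_model(default_params, fine)
        fmax = f.max()
        sm_oracle = np.trapezoid(fmax - f, fine * 1e3) / (fmax - f.min())
        assert sm == pytest.approx(sm_oracle, rel=5e-3)

    def test_dimensionless_parameters_scale_invariant(self, default_params, cardinal_grid):
        tr = fm.gen_ojip_transient(default_params, cardinal_grid)
        scaled = fm.FluorescenceTransient(tr.time, tr.fluorescence * 3.7)
        a = fm.jip_parameters(tr).to_dict()
        b = fm.jip_parameters(scaled).to_dict()
        for key in ("Fv/Fm", "Vj", "Wk", "Mo", "Sm", "psi0", "PIabs", "TR0/RC", "ET0/RC"):
            assert b[key] == pytest.approx(a[key], rel=1e-9), key
        for key in ("RC/CS0", "TR0/CS0", "ET0/CS0"):
            assert b[key] == pytest.approx(a[key] * 3.7, rel=1e-9), key

    def test_grid_refinement_stability(self, default_params):
        coarse = fm.jip_parameters(fm.gen_ojip_transient(default_params, log_time_grid(n=120)))
        dense = fm.jip_parameters(fm.gen_ojip_transient(default_params, log_time_grid(n=240)))
        for key, v in coarse.to_dict().items():
            assert dense.to_dict()[key] == pytest.approx(v, rel=5e-3), key

    def test_mo_formula(self, default_params, cardinal_grid):
        tr = fm.gen_ojip_transient(default_params, cardinal_grid)
        pts = fm.extract_cardinal_points(tr)
        params = fm.jip_parameters(tr, points=pts)
        assert params.mo == pytest.approx(4 * (pts.fk - pts.fo) / (pts.fm - pts.fo))


def test_wk_monotone_in_k_band_weight_sweep(default_params):
    """A denser sweep of the K-band injection: Wk strictly increasing."""
    weights = np.linspace(0.0, 0.45, 10)
    wk = [
        fm.jip_parameters(
            fm.gen_ojip_transient(dataclasses.replace(default_params, k_band_weight=k))
        ).wk
        for k in weights
    ]
    assert np.all(np.diff(wk) > 0)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(
    w1=st.floats(min_value=0.1, max_value=0.7),
    w2=st.floats(min_value=0.1, max_value=0.25),
    fo=st.floats(min_value=100, max_value=900),
)
def test_normalisation_identities_hold_for_random_models(w1, w2, fo):
    """Vt(t_Fm)=1 and Wt(2 ms)=1 are algebraic identities of the definitions."""
    w3 = 1.0 - w1 - w2
    params = fm.OJIPModelParams(fo=fo, fm=fo * 5, phase_weights=(w1, w2, w3))
    tr = fm.gen_ojip_transient(params)
    curves = fm.normalize_transient(tr)
    from fluoromics._utils import interp_log_time

    assert curves.vt[np.argmax(tr.fluorescence)] == pytest.approx(1.0, abs=1e-12)
    assert interp_log_time(curves.time, curves.wt, T_J) == pytest.approx(1.0, abs=1e-9)
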