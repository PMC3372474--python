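"""Surface-warming extraction, exponential fitting and response lines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraltherm import geometry as G
from coraltherm import postprocess as PP
from coraltherm.lumped import transient_warming


def _hemisphere_mesh():
    return G.build_mesh(G.ChamberDomain(), G.CoralShape(G.HEMISPHERE, 0.0175), (50, 26, 26))


class _FakeState:
    def __init__(self, T):
        self.T = T


class TestSurfaceWarming:
    def test_isothermal_state_gives_zero(self):
        mesh = _hemisphere_mesh()
        state = _FakeState(np.full(mesh.shape, 26.0))
        assert PP.surface_warming(state, mesh) == (0.0, 0.0)

    def test_single_hot_cell_sets_max(self):
        mesh = _hemisphere_mesh()
        T = np.full(mesh.shape, 26.0)
        surf, _ = mesh.surface_cells()
        i, j, k = [a[0] for a in np.nonzero(surf)]
        T[i, j, k] = 26.5
        mean, mx = PP.surface_warming(_FakeState(T), mesh)
        assert mx == pytest.approx(0.5)
        assert 0.0 < mean < 0.5

    def test_empty_tissue_zone_rejected(self):
        mesh = G.build_empty_mesh(G.ChamberDomain(), (8, 4, 4))
        with pytest.raises(ValueError):
            PP.surface_warming(_FakeState(np.full(mesh.shape, 26.0)), mesh)


class TestTimeConstantFit:
    def test_recovers_generating_tau_exactly(self):
        t = np.arange(0.0, 1500.0, 1.0)
        traj = transient_warming(0.45, 300.0, t_on=143.0)
        series = PP.TimeSeries(t, traj(t), traj(t))
        tau, dT_ss, resid = PP.fit_time_constant(series, 143.0)
        assert tau == pytest.approx(300.0, rel=1e-3)
        assert dT_ss == pytest.approx(0.45, rel=1e-3)
        assert resid < 1e-10

    def test_fit_inverts_transient_warming_property(self):
        # fit o transient is the identity on tau across a parameter sweep
        for tau_true in (60.0, 180.0, 340.0, 900.0):
            t = np.arange(0.0, 6 * tau_true, 1.0)
            traj = transient_warming(0.3, tau_true)
            series = PP.TimeSeries(t, traj(t), traj(t))
            tau, _, _ = PP.fit_time_constant(series, 0.0)
            assert tau == pytest.approx(tau_true, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        # Monte-Carlo over seeded replicates with sigma = 0.01 K noise
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 1800.0, 1.0)
        traj = transient_warming(0.5, 300.0)
        errs = []
        for _ in range(100):
            y = traj(t) + rng.normal(0.0, 0.01, t.size)
            series = PP.TimeSeries(t, y, y)
            tau, _, _ = PP.fit_time_constant(series, 0.0)
            errs.append(abs(tau - 300.0) / 300.0)
        assert np.median(errs) < 0.05
        assert np.mean(errs) < 0.05

    def test_flat_series_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        series = PP.TimeSeries(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError):
            PP.fit_time_constant(series, 0.0)

    def test_short_series_rejected(self):
        # spans < 3 tau beyond onset
        t = np.arange(0.0, 200.0, 1.0)
        traj = transient_warming(0.5, 300.0)
        series = PP.TimeSeries(t, traj(t), traj(t))
        with pytest.raises(ValueError):
            PP.fit_time_constant(series, 0.0)


class TestIrradianceResponse:
    def test_collinear_points(self):
        pts = [(500, 0.25), (700, 0.35), (950, 0.475)]
        fit = PP.irradiance_response(pts)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(5e-4)

    def test_random_response_near_zero_r2(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([np.linspace(500, 950, 40), rng.normal(0.5, 0.2, 40)])
        assert PP.irradiance_response(pts).r_squared < 0.3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            PP.irradiance_response([(500, 0.2), (950, 0.4)])

    def test_zero_variance_undefined(self):
        fit = PP.irradiance_response([(500, 0.3), (700, 0.3), (950, 0.3)])
        assert np.isnan(fit.r_squared)

    @given(
        a=st.floats(1e-5, 1e-3),
        b=st.floats(-0.1, 0.1),
        scale_i=st.floats(0.5, 3.0),
        scale_y=st.floats(0.5, 3.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_r2_invariant_under_affine_rescaling(self, a, b, scale_i, scale_y):
        rng = np.random.default_rng(3)
        I = np.linspace(500, 950, 12)
        y = a * I + b + rng.normal(0, 0.01, 12)
        r2 = PP.irradiance_response(np.column_stack([I, y])).r_squared
        r2s = PP.irradiance_response(
            np.column_stack([I * scale_i + 5.0, y * scale_y - 1.0])
        ).r_squared
        assert r2s == pytest.approx(r2, abs=1e-9)


class TestSlices:
    def test_slice_values_equal_cell_values(self):
        mesh = _hemisphere_mesh()
        rng = np.random.default_rng(0)
        T = rng.random(mesh.shape)
        state = _FakeState(T)
        state.u = rng.random(mesh.shape)
        [sl] = PP.extract_slices(state, mesh, [float(mesh.xc[10])])
        assert np.array_equal(sl["T"], T[10])
        assert np.array_equal(sl["u"], state.u[10])

    def test_plane_outside_domain_rejected(self):
        mesh = _hemisphere_mesh()
        state = _FakeState(np.zeros(mesh.shape))
        state.u = np.zeros(mesh.shape)
        with pytest.raises(ValueError):
            PP.extract_slices(state, mesh, [1.0])


class TestStudies:
    def test_grid_study_requires_three_resolutions(self):
        with pytest.raises(ValueError):
            PP.grid_independence_study(lambda r: (100, 1.0), [(8, 4, 4), (12, 6, 6)])

    def test_identical_resolutions_give_zero_change(self):
        df = PP.grid_independence_study(
            lambda r: (int(np.prod(r)), 0.5), [(8, 4, 4), (8, 4, 4), (8, 4, 4)]
        )
        assert df["rel_change"].iloc[1:].max() == 0.0
        assert df["asymptotic"].iloc[1:].all()

    def test_sensitivity_zero_perturbation_matches_baseline(self):
        t = np.arange(0.0, 10.0)

        def run(pert):
            y = (1 + pert) * t / 10.0
            return PP.TimeSeries(t, y, y)

        df = PP.sensitivity_study(run, 0.10)
        base = df[df.volume_perturbation == 0.0]["dT_mean_K"].to_numpy()
        assert np.array_equal(base, t / 10.0)
        assert set(df.volume_perturbation.unique()) == {-0.10, 0.0, 0.10}

    def test_excessive_perturbation_rejected(self):
        with pytest.raises(ValueError):
            PP.sensitivity_study(lambda p: None, 0.5)
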