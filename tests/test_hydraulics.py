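"""Turbulence statistics, grid interpolation and nominal-velocity summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flumefish.errors import (DegenerateSeriesError, IncompleteSectionError,
                              OutOfDomainError, StructuralError)
from flumefish.hydraulics import (FIELD_QUANTITIES, HydraulicField,
                                  VelocityTimeSeries, compute_point_stats,
                                  field_from_point_stats, read_adv_field)
from flumefish.synth import gen_adv_series, gen_flow_field

from conftest import make_uniform_field


def series(u, v, w, rate=25.0):
    return VelocityTimeSeries(u=np.asarray(u, float), v=np.asarray(v, float),
                              w=np.asarray(w, float), sample_rate=rate)


class TestPointStats:
    @pytest.mark.parametrize("u,v,w,expect", [
        # constant flow carries no fluctuation energy
        ([2.0, 2.0, 2.0], [0.1, 0.1, 0.1], [0.0, 0.0, 0.0],
         {"tke": 0.0, "tau_uv": 0.0, "tau_uw": 0.0, "tau_vw": 0.0,
          "u_bar": 2.0}),
        # var_u = 1 with 1/n divisor -> TKE = 0.5
        ([1.0, 3.0], [0.0, 0.0], [0.0, 0.0],
         {"tke": 0.5, "tau_uv": 0.0, "tau_uw": 0.0, "tau_vw": 0.0}),
        # cov(u, v) = -1 -> tau_uv = -1000 * (-1) = +1000 N/m^2
        ([1.0, 3.0], [2.0, 0.0], [0.0, 0.0],
         {"tau_uv": 1000.0}),
    ])
    def test_hand_examples(self, u, v, w, expect):
        point = compute_point_stats(series(u, v, w))
        for key, val in expect.items():
            assert getattr(point, key) == pytest.approx(val, abs=1e-12)

    def test_population_divisor(self):
        # 1/n (not 1/(n-1)) variance: u=(0, 2) has var 1, not 2
        p = compute_point_stats(series([0.0, 2.0], [0, 0], [0, 0]))
        assert p.tke == pytest.approx(0.5)

    def test_degenerate_and_structural_errors(self):
        with pytest.raises(DegenerateSeriesError):
            compute_point_stats(series([1.0], [1.0], [1.0]))
        with pytest.raises(StructuralError):
            VelocityTimeSeries(u=np.zeros(3), v=np.zeros(2), w=np.zeros(3),
                               sample_rate=25)
        with pytest.raises(StructuralError):
            VelocityTimeSeries(u=np.zeros(3), v=np.zeros(3), w=np.zeros(3),
                               sample_rate=0.0)

    @given(shift=st.floats(-10, 10), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift, seed):
        """TKE and tau depend only on fluctuations, not the mean level."""
        rng = np.random.default_rng(seed)
        u, v, w = rng.normal(size=(3, 30))
        a = compute_point_stats(series(u, v, w))
        b = compute_point_stats(series(u + shift, v + shift, w + shift))
        assert b.tke == pytest.approx(a.tke, rel=1e-9, abs=1e-12)
        for tau in ("tau_uv", "tau_uw", "tau_vw"):
            assert getattr(b, tau) == pytest.approx(getattr(a, tau),
                                                    rel=1e-9, abs=1e-9)

    def test_pair_symmetry(self, rng):
        """Swapping the component pair leaves the shear stress unchanged."""
        u, v, w = rng.normal(size=(3, 50))
        a = compute_point_stats(series(u, v, w))
        b = compute_point_stats(series(v, u, w))
        assert b.tau_uv == pytest.approx(a.tau_uv, rel=1e-9)
        # uw pair becomes vw pair after the swap
        assert b.tau_uw == pytest.approx(a.tau_vw, rel=1e-9)

    def test_gaussian_moment_recovery(self, rng):
        """Estimates converge to 0.5*trace(Sigma) and -rho*Sigma_ab."""
        ts = gen_adv_series(mean=(2.0, 0.1, 0.0), tke_target=0.30,
                            tau_targets=(7.55, 0.0, 0.0), n=1500, rng=rng,
                            variances=(0.10, 0.10, 0.10))
        p = compute_point_stats(ts)
        # 3 MC SEs: SE(TKE) = sqrt(sum_ab 2 cov_ab^2 / n)/2 ~ 0.0033,
        # SE(tau) = rho*sqrt((var_u*var_v + cov_uv^2)/n) ~ 2.6
        assert p.tke == pytest.approx(0.15, abs=3 * 0.0033)
        assert p.tau_uv == pytest.approx(7.55, abs=3 * 2.6)


class TestField:
    def test_interpolation_identity_at_nodes(self, flow_field):
        i, j = 7, 2
        got = flow_field.interpolate((flow_field.x[i], flow_field.y[j]))
        for q in FIELD_QUANTITIES:
            assert got[q] == pytest.approx(flow_field.data[q][i, j], rel=1e-12)

    def test_interpolation_midpoint_linearity(self):
        f = make_uniform_field(x=[0.0, 1.0], y=[0.0, 1.0])
        f.data["tke"][:] = [[1.0, 1.0], [2.0, 2.0]]
        f.__post_init__()     # rebuild interpolators after edit
        assert f.interpolate((0.5, 0.5))["tke"] == pytest.approx(1.5)

    def test_linear_field_reproduced_exactly(self, rng):
        """Bilinear interpolation is exact for globally linear fields."""
        x = np.linspace(0, 6, 25)
        y = np.linspace(0.05, 0.45, 5)
        X, Y = np.meshgrid(x, y, indexing="ij")
        lin = 0.3 + 1.2 * X - 0.7 * Y
        f = make_uniform_field(x=x, y=y)
        f.data["tke"] = lin
        f.__post_init__()
        pts = np.column_stack([rng.uniform(0, 6, 40),
                               rng.uniform(0.05, 0.45, 40)])
        got = f.interpolate(pts)["tke"]
        want = 0.3 + 1.2 * pts[:, 0] - 0.7 * pts[:, 1]
        assert np.allclose(got, want, rtol=1e-10)

    def test_out_of_domain_raises(self, flow_field):
        with pytest.raises(OutOfDomainError):
            flow_field.interpolate((-0.5, 0.2))
        with pytest.raises(OutOfDomainError):
            flow_field.interpolate((3.0, 0.49))   # beyond last lateral point

    def test_vnom_constant_section(self):
        f = make_uniform_field(u=-2.2, v=0.0)
        assert f.compute_vnom(5) == pytest.approx(2.2)

    def test_vnom_is_arithmetic_mean(self):
        f = make_uniform_field(x=np.arange(3.0), y=np.arange(5.0))
        f.data["speed"][1, :] = [1.8, 2.0, 2.2, 2.0, 2.0]
        f.__post_init__()
        assert f.compute_vnom(2) == pytest.approx(2.0)

    def test_vnom_bad_section(self, flow_field):
        with pytest.raises(IncompleteSectionError):
            flow_field.compute_vnom(0)
        with pytest.raises(IncompleteSectionError):
            flow_field.compute_vnom(99)

    @pytest.mark.parametrize("v_nom", [1.80, 2.00, 2.20, 2.40, 2.50])
    def test_synthetic_fields_hit_trial_levels(self, v_nom):
        """Generated fields reproduce the configured nominal velocities."""
        f = gen_flow_field(v_nom, seed=3)
        assert f.compute_vnom(12) == pytest.approx(v_nom, abs=1e-12)

    def test_frame_round_trip(self, flow_field):
        rebuilt = HydraulicField.from_frame(flow_field.to_frame())
        for q in FIELD_QUANTITIES:
            assert np.allclose(rebuilt.data[q], flow_field.data[q])

    def test_incomplete_grid_rejected(self):
        pts = [compute_point_stats(series([1, 2], [0, 0], [0, 0]))]
        with pytest.raises(StructuralError):
            field_from_point_stats(pts * 3)


class TestADVIngestion:
    def test_read_adv_field(self, tmp_path, rng):
        xs, ys = [0.0, 0.25], [0.05, 0.15]
        rows = []
        for i, xv in enumerate(xs):
            for j, yv in enumerate(ys):
                ts = gen_adv_series(mean=(-(2 + 0.1 * i), 0.0, 0.0),
                                    tke_target=0.02, n=200, rng=rng)
                name = f"p{i}{j}.csv"
                pd.DataFrame({"time_s": np.arange(200) / 25.0,
                              "u_ms": ts.u, "v_ms": ts.v,
                              "w_ms": ts.w}).to_csv(tmp_path / name,
                                                    index=False)
                rows.append({"file": name, "section": i + 1, "point": j + 1,
                             "x_m": xv, "y_m": yv})
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        f = read_adv_field(tmp_path / "manifest.csv")
        assert f.n_sections == 2 and f.n_points == 2
        assert f.compute_vnom(1) == pytest.approx(2.0, abs=0.05)

    def test_manifest_missing_columns(self, tmp_path):
        pd.DataFrame({"file": ["a.csv"]}).to_csv(tmp_path / "m.csv",
                                                 index=False)
        with pytest.raises(StructuralError):
            read_adv_field(tmp_path / "m.csv")
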