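"""Bulk sac metrics, the case pipeline and the comparison table."""

import numpy as np
import pytest

import aneuflow as af
from aneuflow.errors import ConfigError, GeometryError
from aneuflow.report import AneurysmMetrics


def sac_geometry():
    return af.make_channel_aneurysm_geometry(
        4e-3, 2e-2,
        [{"diameter": 8e-3, "neck_width": 3.2e-3, "position": 1e-2,
          "name": "sac"}], 4e-4)


def synthetic_flow_on(geo, neck_v=None, period=0.5, n_t=5):
    """A hand-built FlowSeries with a prescribed neck-face velocity."""
    times = np.linspace(0, period, n_t)
    u = np.zeros((n_t, geo.nx + 1, geo.ny))
    v = np.zeros((n_t, geo.nx, geo.ny + 1))
    if neck_v is not None:
        r = geo.regions[0]
        v[:, r.neck_face_i, r.neck_face_j] = neck_v
    return af.FlowSeries(
        geometry=geo, waveform=None, rheology=None, times=times, u=u, v=v,
        p=np.zeros((n_t, geo.nx, geo.ny)),
        visc=np.full((n_t, geo.nx, geo.ny), 3.5e-3),
        div_residual=np.zeros(n_t), inlet_flux=np.zeros(n_t),
        outlet_flux=np.zeros((n_t, 1)), metadata={"u_reference": 1.0})


class TestVolume:
    def test_single_cell_region(self):
        geo = sac_geometry()
        mask = np.zeros_like(geo.fluid)
        mask[5, 5] = True
        r = af.AneurysmRegion(name="one", mask=mask, neck_axis="y",
                              neck_face_j=10, neck_face_i=np.arange(8),
                              normal_sign=1, h=geo.h)
        # h = 0.4 mm: one cell is 0.16 mm^2 x 1 mm depth
        assert af.aneurysm_volume(r, geo) == pytest.approx(0.16)

    def test_block_region_arithmetic(self):
        geo = sac_geometry()
        mask = np.zeros_like(geo.fluid)
        mask[2:12, 0:10] = True  # 100 cells of (0.4 mm)^2
        r = af.AneurysmRegion(name="block", mask=mask, neck_axis="y",
                              neck_face_j=10, neck_face_i=np.arange(8),
                              normal_sign=1, h=geo.h)
        assert af.aneurysm_volume(r, geo) == pytest.approx(16.0)

    def test_empty_region_rejected(self):
        geo = sac_geometry()
        r = af.AneurysmRegion(name="none", mask=np.zeros_like(geo.fluid),
                              neck_axis="y", neck_face_j=10,
                              neck_face_i=np.arange(8), normal_sign=1,
                              h=geo.h)
        with pytest.raises(GeometryError):
            af.aneurysm_volume(r, geo)


class TestInflowVolume:
    def test_zero_velocity_zero_inflow(self):
        geo = sac_geometry()
        flow = synthetic_flow_on(geo)
        assert af.inflow_volume_per_cycle(flow, geo.regions[0]) == 0.0

    def test_uniform_inward_speed_closed_form(self):
        geo = sac_geometry()
        U, T = 0.02, 0.5
        flow = synthetic_flow_on(geo, neck_v=U, period=T)
        r = geo.regions[0]
        area = r.neck_face_i.size * geo.h           # m, per unit depth
        expect_mm3 = U * area * T * 1e6
        assert af.inflow_volume_per_cycle(flow, r) == pytest.approx(
            expect_mm3, rel=1e-12)

    def test_recirculation_counts_only_entering_half(self):
        # inflow on one half of the neck, equal outflow on the other:
        # net flux is zero but the one-sided inflow is half the gross flux
        geo = sac_geometry()
        r = geo.regions[0]
        n = r.neck_face_i.size
        assert n % 2 == 0
        U, T = 0.02, 0.5
        flow = synthetic_flow_on(geo, period=T)
        half = r.neck_face_i[: n // 2]
        other = r.neck_face_i[n // 2:]
        flow.v[:, half, r.neck_face_j] = U
        flow.v[:, other, r.neck_face_j] = -U
        b = af.inflow_volume_per_cycle(flow, r)
        gross = U * n * geo.h * T * 1e6
        assert b == pytest.approx(gross / 2, rel=1e-12)
        assert b > 0


class TestExchangeRate:
    def test_printed_pairs(self):
        assert af.exchange_rate(83.93, 4.94) == pytest.approx(17.0, abs=0.05)
        assert af.exchange_rate(467.2, 38.6) == pytest.approx(12.1, abs=0.05)

    def test_zero_inflow(self):
        assert af.exchange_rate(0.0, 5.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            af.exchange_rate(10.0, 0.0)


class TestMeanVelocity:
    def test_uniform_speed(self):
        fx = af.make_analytic_fixture("plug", {"u": 0.1})
        geo = fx.geometry
        mask = np.zeros_like(geo.fluid)
        mask[10:20, 2:8] = True
        r = af.AneurysmRegion(name="window", mask=mask, neck_axis="y",
                              neck_face_j=5, neck_face_i=np.arange(8),
                              normal_sign=1, h=geo.h)
        t, series, mean = af.mean_velocity_in_region(fx, r)
        assert np.allclose(series, 0.1)
        assert mean == pytest.approx(0.1)

    def test_zero_flow(self):
        fx = af.make_analytic_fixture("sealed_cavity")
        mask = np.zeros_like(fx.geometry.fluid)
        mask[2:5, 2:5] = True
        r = af.AneurysmRegion(name="still", mask=mask, neck_axis="y",
                              neck_face_j=2, neck_face_i=np.arange(8),
                              normal_sign=1, h=fx.geometry.h)
        _, series, mean = af.mean_velocity_in_region(fx, r)
        assert mean == 0.0

    def test_stagnant_sac_slower_than_washed(self, twosac):
        rows = {m.name: m for m in twosac["report"].metrics}
        assert rows["stagnant"].mean_velocity_m_s \
            < rows["washed"].mean_velocity_m_s


class TestRunCase:
    @pytest.fixture(scope="class")
    def quick_straight(self):
        cfg = af.straight_channel()
        cfg.numerics = {"warmup_cycles": 1, "samples_per_cycle": 100}
        cfg.age = {"cycles": 2}
        return cfg

    def test_straight_channel_no_aneurysms(self, quick_straight, tmp_path):
        report, flow, maps, ages = af.run_case(quick_straight,
                                               outdir=tmp_path / "run",
                                               keep_fields=False)
        assert report.metrics == []
        assert report.flags == {}
        assert (tmp_path / "run" / "metrics.csv").exists()
        assert (tmp_path / "run" / "fields_final.vtk").exists()
        assert not (tmp_path / "run" / "fields.npz").exists()

    def test_report_determinism(self, quick_straight):
        r1, *_ = af.run_case(quick_straight)
        r2, *_ = af.run_case(quick_straight)
        assert r1.config_digest == r2.config_digest
        assert r1.continuity["max_divergence_scaled"] \
            == r2.continuity["max_divergence_scaled"]
        assert np.array_equal(r1.table().values, r2.table().values)

    def test_invalid_neck_names_the_sac(self):
        cfg = af.straight_channel()
        cfg.geometry["sacs"] = [{"diameter": 3e-3, "neck_width": 3.5e-3,
                                 "position": 1e-2, "name": "badsac"}]
        with pytest.raises(GeometryError, match="badsac"):
            af.run_case(cfg)

    def test_two_sac_report_structure(self, twosac):
        report = twosac["report"]
        assert len(report.metrics) == 2
        assert report.flags["stagnant"] is True
        df = report.table()
        assert set(df["aneurysm"]) == {"stagnant", "washed"}
        for m in report.metrics:
            assert m.exchange_rate_per_cycle == pytest.approx(
                m.inflow_mm3_per_cycle / m.volume_mm3)


def _metric(name, rrt, exch=1.0, slope=0.0):
    return AneurysmMetrics(
        name=name, volume_mm3=10.0, inflow_mm3_per_cycle=10.0 * exch,
        exchange_rate_per_cycle=exch, mean_velocity_m_s=0.01,
        velocity_series=np.zeros(3),
        wall_extrema={"max_rrt_per_pa": rrt, "min_tawss_pa": 1.0,
                      "max_osi": 0.2},
        age_summary={"overall_max_age": 1.0, "max_age_slope": slope},
        antiphase=False)


def _report(case_id, metrics):
    return af.CaseReport(case_id=case_id, config_digest="x", config={},
                         solver_metadata={}, continuity={
                             "max_divergence_scaled": 0.0},
                         metrics=metrics,
                         thresholds={"rrt_per_pa": 2.0},
                         flags={m.name: m.wall_extrema["max_rrt_per_pa"] > 2.0
                                for m in metrics})


class TestCompare:
    def test_flagging_and_ranking_printed_pair(self):
        # RRT 117.3 vs 0.93: first ranked 1 and flagged
        rep = _report("c", [_metric("a", 117.3), _metric("b", 0.93)])
        df = af.compare_aneurysms([rep])
        a = df[df["aneurysm"] == "a"].iloc[0]
        b = df[df["aneurysm"] == "b"].iloc[0]
        assert a["disturbed_flow"] and not b["disturbed_flow"]
        assert a["rank_by_max_rrt"] == 1 and b["rank_by_max_rrt"] == 2

    def test_single_below_threshold_unflagged(self):
        df = af.compare_aneurysms([_report("c", [_metric("a", 0.5)])])
        assert not df["disturbed_flow"].iloc[0]

    def test_ties_rank_in_name_order(self):
        rep = _report("c", [_metric("zz", 5.0), _metric("aa", 5.0)])
        df = af.compare_aneurysms([rep]).set_index("aneurysm")
        assert df.loc["aa", "rank_by_max_rrt"] == 1
        assert df.loc["zz", "rank_by_max_rrt"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            af.compare_aneurysms([])
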