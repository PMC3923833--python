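"""Unit and property tests for the soil-cohort accretion model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marshmem import (
    BioticParams,
    PhysicalParams,
    Scenario,
    SLRScenario,
    SoilColumn,
    TidalDatums,
    biomass,
    bulk_density,
    distribute_roots,
    hindcast_scenario,
    mineral_deposition,
    organic_production,
    relative_elevation,
    run_mem,
    soil_profile,
    step_year,
)
from marshmem.params import SiteParams


DATUMS = TidalDatums(msl=100.0, mhhw=180.0)


class TestRelativeElevation:
    @pytest.mark.parametrize(
        "e,expected", [(100.0, 0.0), (180.0, 1.0), (140.0, 0.5)]
    )
    def test_normalization(self, e, expected):
        assert relative_elevation(e, DATUMS) == pytest.approx(expected)


class TestBiomassParabola:
    P = BioticParams(
        z_min=-0.3, z_peak=0.6, z_max=1.1, b_max=2400.0,
        rsr=1.5, turnover=0.5, k_decay=0.3, f_ref=0.4, d95=30.0,
    )

    def test_constraint_points(self):
        assert biomass(self.P.z_min, self.P) == 0.0
        assert biomass(self.P.z_max, self.P) == 0.0
        assert biomass(self.P.z_peak, self.P) == pytest.approx(self.P.b_max)

    def test_lagrange_interpolation_oracle(self):
        """Value at an interior point equals an independent polynomial fit
        through the three defining constraints."""
        coeffs = np.polyfit(
            [self.P.z_min, self.P.z_peak, self.P.z_max],
            [0.0, self.P.b_max, 0.0],
            deg=2,
        )
        expected = float(np.polyval(coeffs, 0.2))
        assert biomass(0.2, self.P) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(z=st.floats(-2.0, 3.0))
    def test_clamped_and_bounded(self, z):
        b = biomass(z, self.P)
        assert b >= 0.0
        if z < self.P.z_min or z > self.P.z_max:
            assert b == 0.0
        # never exceeds the quadratic's vertex value
        coeffs = np.polyfit(
            [self.P.z_min, self.P.z_peak, self.P.z_max],
            [0.0, self.P.b_max, 0.0],
            deg=2,
        )
        vertex = -coeffs[1] / (2 * coeffs[0])
        assert b <= float(np.polyval(coeffs, vertex)) + 1e-9

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(Exception):
            BioticParams(
                z_min=0.5, z_peak=0.5, z_max=0.5, b_max=100.0,
                rsr=1.0, turnover=1.0, k_decay=0.1, f_ref=0.5, d95=30.0,
            )


class TestMineralDeposition:
    BIO = TestBiomassParabola.P

    def test_no_flooding(self):
        phys = PhysicalParams(ssc=50.0)
        assert mineral_deposition(185.0, DATUMS, 500.0, phys, self.BIO) == 0.0
        assert mineral_deposition(180.0, DATUMS, 500.0, phys, self.BIO) == 0.0

    def test_full_capture_limit(self):
        """With no biomass and settling depth ≥ flooding depth, every tide
        deposits its full load: M = C·D·n_tides."""
        phys = PhysicalParams(ssc=50.0, w_s=40.0, q_trap=0.2)
        d = 30.0
        m = mineral_deposition(DATUMS.mhhw - d, DATUMS, 0.0, phys, self.BIO)
        assert m == pytest.approx(50e-6 * d * phys.n_tides)

    def test_hand_evaluated_formula(self):
        """C=50 mg/L, D=30 cm, 704 tides, capture 0.2 settling + 0.2 trapping."""
        phys = PhysicalParams(ssc=50.0, w_s=6.0, q_trap=0.25, n_tides=704.0)
        b = 0.8 * self.BIO.b_max
        m = mineral_deposition(150.0, DATUMS, b, phys, self.BIO)
        assert m == pytest.approx(50e-6 * 30.0 * 704.0 * 0.4, rel=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        ssc=st.floats(1.0, 400.0),
        depth=st.floats(0.1, 80.0),
        b=st.floats(0.0, 2400.0),
    )
    def test_monotone_in_drivers(self, ssc, depth, b):
        phys = PhysicalParams(ssc=ssc, w_s=6.0, q_trap=0.25)
        phys2 = PhysicalParams(ssc=ssc * 1.5, w_s=6.0, q_trap=0.25)
        e = DATUMS.mhhw - depth
        m = mineral_deposition(e, DATUMS, b, phys, self.BIO)
        tol = 1e-12 * max(m, 1.0)  # rounding slack where M is depth-flat
        assert mineral_deposition(e, DATUMS, b, phys2, self.BIO) >= m - tol
        assert mineral_deposition(e - 5.0, DATUMS, b, phys, self.BIO) >= m - tol
        assert (
            mineral_deposition(e, DATUMS, min(b * 1.2, 2400), phys, self.BIO)
            >= m - tol
        )


class TestOrganicProduction:
    def test_zero_biomass(self):
        assert organic_production(0.0, TestBiomassParabola.P) == (0.0, 0.0)

    def test_all_refractory(self):
        p = BioticParams(
            z_min=-0.3, z_peak=0.5, z_max=1.3, b_max=2000.0,
            rsr=1.0, turnover=1.0, k_decay=0.3, f_ref=1.0, d95=30.0,
        )
        ref, lab = organic_production(1000.0, p)
        assert lab == 0.0
        assert ref == pytest.approx(0.1)

    def test_hand_arithmetic(self):
        p = BioticParams(
            z_min=-0.3, z_peak=0.5, z_max=1.3, b_max=2400.0,
            rsr=1.5, turnover=0.5, k_decay=0.3, f_ref=0.4, d95=30.0,
        )
        ref, lab = organic_production(2000.0, p)
        assert ref == pytest.approx(0.06)
        assert lab == pytest.approx(0.09)


class TestRootDistribution:
    def test_single_cohort_receives_everything(self):
        frac = distribute_roots(np.array([30.0]), d95=30.0)
        assert frac.sum() == pytest.approx(1.0)
        assert len(frac) == 1

    def test_two_cohorts_closed_form(self):
        """Equal cohorts of thickness d95/2: analytic exponential integrals
        (λ = ln20/d95), tail assigned to the bottom cohort."""
        d95 = 30.0
        frac = distribute_roots(np.array([15.0, 15.0]), d95=d95)
        f1 = 1.0 - 20.0 ** -0.5
        assert frac[0] == pytest.approx(f1, rel=1e-12)
        assert frac[1] == pytest.approx(1.0 - f1, rel=1e-12)

    def test_deep_rooting_limit_near_uniform(self):
        """As d95 → ∞ the within-column allocation becomes proportional to
        thickness (the non-bottom cohorts equalize to within 1%)."""
        frac = distribute_roots(np.array([10.0, 10.0, 10.0, 10.0]), d95=1e7)
        assert frac[0] == pytest.approx(frac[1], rel=0.01)
        assert frac[1] == pytest.approx(frac[2], rel=0.01)
        assert frac.sum() == pytest.approx(1.0)

    def test_invalid_d95(self):
        with pytest.raises(ValueError):
            distribute_roots(np.array([10.0]), d95=0.0)


class TestDecay:
    def _column(self, labile):
        phys = PhysicalParams(ssc=50.0)
        col = SoilColumn(base_cm=0.0, phys=phys)
        col.add_cohort(1, 0.0)
        col.m_labile = np.array([labile])
        return col

    def test_zero_rate_is_identity(self):
        col = self._column(1.0)
        col.decay(0.0)
        assert col.m_labile[0] == 1.0

    def test_half_life(self):
        col = self._column(1.0)
        col.decay(math.log(2.0))
        assert col.m_labile[0] == pytest.approx(0.5, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(1, 50), k=st.floats(0.01, 1.0))
    def test_repeated_decay_closed_form(self, n, k):
        col = self._column(1.0)
        for _ in range(n):
            col.decay(k)
        assert col.m_labile[0] == pytest.approx(math.exp(-n * k), rel=1e-9)


class TestBulkDensity:
    def test_endpoints(self):
        assert bulk_density(1.0, 0.085, 1.99) == pytest.approx(0.085)
        assert bulk_density(0.0, 0.085, 1.99) == pytest.approx(1.99)

    def test_ideal_mixing_midpoint(self):
        expected = 1.0 / (0.5 / 0.085 + 0.5 / 1.99)
        assert bulk_density(0.5, 0.085, 1.99) == pytest.approx(expected)
        # 0.5/0.085 + 0.5/1.99 = 5.88235 + 0.25126 = 6.13361 → ρ = 0.16304
        assert expected == pytest.approx(0.16304, abs=5e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bulk_density(1.2, 0.085, 1.99)


class TestCohortVolume:
    def test_zero_and_mineral_only(self):
        phys = PhysicalParams(ssc=50.0, k_org=0.085, k_min=1.99)
        col = SoilColumn(base_cm=0.0, phys=phys)
        col.add_cohort(1, 0.0)
        assert col.height_cm == 0.0
        col.m_mineral = np.array([1.99])
        assert col.height_cm == pytest.approx(1.0)

    def test_volume_equals_mass_over_bulk_density(self):
        """Algebraic identity: V = mass / ρ(loi) for the cohort's own loi."""
        phys = PhysicalParams(ssc=50.0)
        col = SoilColumn(
            base_cm=0.0, phys=phys,
            year=np.array([1]),
            m_mineral=np.array([0.8]),
            m_labile=np.array([0.05]),
            m_refractory=np.array([0.1]),
        )
        mass = 0.8 + 0.05 + 0.1
        loi = 0.15 / mass
        rho = bulk_density(loi, phys.k_org, phys.k_min)
        assert col.height_cm == pytest.approx(mass / rho, rel=1e-9)


def _hand_site():
    return SiteParams(
        name="hand",
        biotic=BioticParams(
            z_min=-0.3, z_peak=0.5, z_max=1.3, b_max=2000.0,
            rsr=1.5, turnover=0.5, k_decay=math.log(2.0), f_ref=0.4,
            d95=30.0,
        ),
        physical=PhysicalParams(
            ssc=50.0, w_s=6.0, q_trap=0.25, n_tides=704.0,
            k_org=0.085, k_min=1.99,
        ),
        datums=DATUMS,
    )


class TestStepYear:
    def test_single_step_hand_computed(self):
        """One step at peak biomass: increment equals independently summed
        deposition volumes (mineral + refractory + once-decayed labile)."""
        site = _hand_site()
        scen = Scenario(hindcast_scenario(), "high", site.physical.ssc)
        col = SoilColumn(base_cm=140.0, phys=site.physical)
        out = step_year(col, 1, DATUMS, scen, site)
        # z*=0.5 → biomass 2000; D=40; capture = 6/40 + 0.25·1 = 0.4
        m_dep = 50e-6 * 40.0 * 704.0 * 0.4
        ref, lab = 0.06, 0.09
        expected = m_dep / 1.99 + (ref + lab * 0.5) / 0.085
        assert out["accretion_cm"] == pytest.approx(expected, rel=1e-12)
        assert out["biomass_g_m2"] == pytest.approx(2000.0)

    def test_never_flooded_unvegetated_is_static(self):
        """Above MHHW and above the vegetation limit nothing accumulates;
        relative elevation falls by exactly the SLR increment."""
        site = _hand_site()
        scen = Scenario(hindcast_scenario(), "high", site.physical.ssc)
        traj = run_mem(250.0, scen, site, horizon=20)
        elev = traj.table["elevation_cm_navd88"]
        assert (elev == 250.0).all()
        z = traj.table["z_star"].to_numpy()
        # z* at year t measured against datums risen by s(t)
        from marshmem import sea_level

        expected_z = (250.0 - (100.0 + 0.24 * np.arange(1, 21))) / 80.0
        np.testing.assert_allclose(z[1:], expected_z, rtol=1e-12)

    def test_mineral_mass_conserved_across_steps(self):
        site = _hand_site()
        scen = Scenario(hindcast_scenario(), "high", site.physical.ssc)
        col = SoilColumn(base_cm=140.0, phys=site.physical)
        for year in (1, 2):
            step_year(col, year, DATUMS, scen, site)
        assert col.mineral_stored == pytest.approx(
            col.total_mineral_deposited, rel=1e-14
        )


class TestRunMem:
    def test_zero_horizon(self, site, hindcast):
        traj = run_mem(150.0, hindcast, site, horizon=0)
        assert len(traj.table) == 1
        assert traj.elevation_at(0) == 150.0

    def test_equilibrium_tracks_constant_slr(self, site, hindcast):
        """Under constant-rate forcing the marsh converges to accretion =
        SLR rate (the model's central feedback)."""
        traj = run_mem(176.0, hindcast, site, horizon=300)
        inc = traj.table["accretion_cm"].to_numpy()[-10:]
        assert np.all(np.abs(inc - 0.24) < 0.01)

    def test_mass_balance(self, site, hindcast):
        """Mineral conservation exact; organic production − decay = storage."""
        traj = run_mem(150.0, hindcast, site, horizon=100)
        col = traj.column
        assert col.mineral_stored == pytest.approx(
            col.total_mineral_deposited, rel=1e-12
        )
        stored = col.organic_stored
        assert (
            col.total_organic_produced - col.total_organic_decayed
        ) == pytest.approx(stored, rel=1e-9)

    def test_final_elevation_monotone_in_ssc(self, site):
        finals = []
        for level, f in (("low", 0.25), ("mid", 0.5), ("high", 1.0)):
            scen = Scenario(
                SLRScenario(0.24, 100.0), level, f * site.physical.ssc
            )
            finals.append(run_mem(168.0, scen, site, 100).elevation_at(100))
        assert finals == sorted(finals)

    def test_final_relative_elevation_antitone_in_s100(self, site):
        zf = []
        for s100 in (24.0, 52.0, 100.0, 165.0, 180.0):
            scen = Scenario(
                SLRScenario(0.24, s100), "high", site.physical.ssc
            )
            traj = run_mem(168.0, scen, site, 100)
            zf.append(traj.table["z_star"].iloc[-1])
        assert all(a >= b for a, b in zip(zf, zf[1:]))

    def test_productivity_slows_relative_elevation_loss(self, site):
        """At equal SSC under the steepest SLR curve, higher-productivity
        vegetation loses tide-relative elevation more slowly."""
        scen = Scenario(SLRScenario(0.24, 180.0, "180cm"), "low", 25.0)
        lush = run_mem(168.0, scen, site, 100)
        sparse_bio = BioticParams(
            z_min=site.biotic.z_min, z_peak=site.biotic.z_peak,
            z_max=site.biotic.z_max, b_max=600.0, rsr=site.biotic.rsr,
            turnover=site.biotic.turnover, k_decay=site.biotic.k_decay,
            f_ref=site.biotic.f_ref, d95=site.biotic.d95,
        )
        sparse_site = SiteParams(
            name="sparse", biotic=sparse_bio, physical=site.physical,
            datums=site.datums, thresholds=site.thresholds,
        )
        sparse = run_mem(168.0, scen, sparse_site, 100)
        assert (
            lush.table["z_star"].iloc[-1] > sparse.table["z_star"].iloc[-1]
        )


class TestSoilProfile:
    def test_homogeneous_column_uniform_bins(self):
        phys = PhysicalParams(ssc=50.0)
        col = SoilColumn(
            base_cm=0.0, phys=phys,
            year=np.array([1]), m_mineral=np.array([3.98]),
            m_labile=np.zeros(1), m_refractory=np.zeros(1),
        )
        prof = soil_profile(col, bin_cm=0.5)
        assert prof["bulk_density_g_cm3"].nunique() == 1
        assert (prof["pct_om"] == 0.0).all()

    def test_two_cohort_hand_computed(self):
        """Mineral cohort (1 cm at 1.99) over organic cohort (2 cm at 0.085):
        bin values equal mass-weighted means."""
        phys = PhysicalParams(ssc=50.0)
        col = SoilColumn(
            base_cm=0.0, phys=phys,
            year=np.array([2, 1]),
            m_mineral=np.array([1.99, 0.0]),
            m_labile=np.zeros(2),
            m_refractory=np.array([0.0, 0.17]),
        )
        prof = soil_profile(col, bin_cm=1.0)
        assert len(prof) == 3
        np.testing.assert_allclose(
            prof["bulk_density_g_cm3"], [1.99, 0.085, 0.085], rtol=1e-12
        )
        np.testing.assert_allclose(prof["pct_om"], [0.0, 100.0, 100.0])

    def test_mass_conservation(self, site, hindcast):
        traj = run_mem(160.0, hindcast, site, horizon=60)
        prof = soil_profile(traj.column, bin_cm=2.0)
        total = (
            prof["bulk_density_g_cm3"] * prof["height_cm"]
        ).sum()
        expected = traj.column.mineral_stored + traj.column.organic_stored
        assert total == pytest.approx(expected, rel=1e-9)

    def test_bad_inputs(self, site, hindcast):
        traj = run_mem(160.0, hindcast, site, horizon=10)
        with pytest.raises(ValueError):
            soil_profile(traj.column, bin_cm=0.0)
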