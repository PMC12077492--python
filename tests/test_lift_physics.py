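"""Lift-model unit and property tests.

The closed-form threshold velocity is cross-checked against a force-balance
oracle (numerically equating dynamic pressure force to submerged weight),
and the maximum-lift-distance closed form against the velocity criterion it
was derived from.
"""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from microlift import units
from microlift.lift_physics import (
    FluidScenario,
    LiftModelError,
    SingularQueryError,
    VelocityQuery,
    approx_axial_velocity,
    can_lift,
    d_max,
    d_max_mm,
    empirical_lift_success,
    lift_threshold_velocity,
    load_success_table,
    q_min_for_lift,
    q_min_for_lift_ul_s,
    sink_velocity,
    success_map,
)


def vmin_force_balance_oracle(scen):
    """Solve ½ρv²A = (ρc−ρ)Vc·g numerically, independent of the closed form."""
    weight = (scen.tissue_density - scen.fluid_density) * scen.volume * scen.gravity

    def net(v):
        return 0.5 * scen.fluid_density * v**2 * scen.face_area - weight

    return brentq(net, 0.0, 10.0, xtol=1e-15)


class TestThresholdVelocity:
    def test_matches_force_balance_oracle(self, cuboid400):
        v = lift_threshold_velocity(cuboid400)
        assert v == pytest.approx(vmin_force_balance_oracle(cuboid400), rel=1e-9)
        assert v == pytest.approx(2.5e-2, rel=0.01)  # ≈ 2.5 cm/s for 400 μm

    def test_neutral_buoyancy_gives_zero(self):
        scen = FluidScenario.cuboid(400.0, tissue_density_g_cm3=1.0)
        assert lift_threshold_velocity(scen) == 0.0

    def test_floating_tissue_rejected(self):
        scen = FluidScenario.cuboid(400.0, tissue_density_g_cm3=0.95)
        with pytest.raises(LiftModelError):
            lift_threshold_velocity(scen)

    def test_sqrt2_scaling_with_volume(self, cuboid400):
        doubled = dataclasses.replace(cuboid400, volume=2 * cuboid400.volume)
        ratio = lift_threshold_velocity(doubled) / lift_threshold_velocity(cuboid400)
        assert ratio == pytest.approx(math.sqrt(2), rel=1e-12)


class TestSinkVelocity:
    def test_no_flow_no_velocity(self, cuboid400):
        scen = cuboid400.with_flow(0.0)
        assert sink_velocity(scen, VelocityQuery.from_mm(0.4)) == 0.0

    def test_singular_at_sink(self, cuboid400):
        with pytest.raises(SingularQueryError):
            sink_velocity(cuboid400, VelocityQuery(x=cuboid400.sink_distance))

    def test_lateral_mirror_symmetry(self, cuboid400):
        a = sink_velocity(cuboid400, VelocityQuery.from_mm(0.4, 0.3, -0.2))
        b = sink_velocity(cuboid400, VelocityQuery.from_mm(0.4, -0.3, 0.2))
        assert a == pytest.approx(b, rel=1e-14)

    @pytest.mark.parametrize("h_over_d", [0.05, 0.1, 0.15, 0.2])
    def test_small_height_limit(self, h_over_d):
        """The full image-sink sum approaches 2Qh/d³ for h ≪ d."""
        d_mm = 1.0
        scen = FluidScenario.cuboid(h_over_d * d_mm * 1000, d_mm=d_mm)
        full = abs(sink_velocity(scen, VelocityQuery(x=scen.edge)))
        approx = approx_axial_velocity(scen)
        assert full == pytest.approx(approx, rel=0.15)

    def test_full_magnitude_at_least_axial(self, cuboid400):
        q = VelocityQuery.from_mm(0.4, 0.5, 0.0)
        assert sink_velocity(cuboid400, q, full_magnitude=True) >= abs(
            sink_velocity(cuboid400, q))


class TestDMax:
    @pytest.mark.parametrize("edge_um, expected_mm", [(400.0, 1.2), (250.0, 1.1)])
    def test_printed_operating_points(self, edge_um, expected_mm):
        scen = FluidScenario.cuboid(edge_um)
        assert round(d_max_mm(scen), 1) == expected_mm

    def test_flow_cube_root_scaling(self, cuboid400):
        assert d_max(cuboid400.with_flow(8 * 56.0)) == pytest.approx(
            2 * d_max(cuboid400), rel=1e-12)

    def test_dimensional_consistency(self, cuboid400):
        """Evaluating the closed form directly in mm/μl units agrees with SI."""
        # mm–μl–s system: Q in mm³/s (1 μl = 1 mm³), g in mm/s²; densities
        # enter only as a ratio so any consistent pair works
        h_mm = 0.4
        q_mm3 = 56.0
        g_mm = 9.81e3
        num = 2 * q_mm3**2 * h_mm**2 * 1.000 * h_mm**2
        den = (1.079 - 1.000) * h_mm**3 * g_mm
        d_mm_scaled = (num / den) ** (1 / 6)
        assert d_mm_scaled == pytest.approx(d_max_mm(cuboid400), rel=1e-9)

    def test_monotone_in_flow_and_density_contrast(self, cuboid400):
        assert d_max(cuboid400.with_flow(70)) > d_max(cuboid400)
        denser = FluidScenario.cuboid(400.0, tissue_density_g_cm3=1.2)
        assert d_max(denser) < d_max(cuboid400)

    @pytest.mark.parametrize("param", ["suction_flow", "gravity", "edge"])
    def test_sixth_power_insensitivity(self, cuboid400, param):
        """±10% in any single factor moves d_max by ≲ 2%."""
        bumped = dataclasses.replace(
            cuboid400, **{param: 1.1 * getattr(cuboid400, param)})
        rel = abs(d_max(bumped) / d_max(cuboid400) - 1)
        assert rel <= 0.035  # 1.1^(1/3) − 1 for the Q² term, less for others

    def test_requires_excess_density_and_flow(self):
        neutral = FluidScenario.cuboid(400.0, tissue_density_g_cm3=1.0)
        with pytest.raises(LiftModelError):
            d_max(neutral)
        with pytest.raises(LiftModelError):
            d_max(FluidScenario.cuboid(400.0).with_flow(0.0))


class TestCanLift:
    def test_operating_height_liftable(self):
        assert can_lift(FluidScenario.cuboid(400.0, d_mm=0.8))

    def test_too_far_not_liftable(self):
        assert not can_lift(FluidScenario.cuboid(400.0, d_mm=2.0))

    def test_vanishing_flow_not_liftable(self, cuboid400):
        assert not can_lift(cuboid400.with_flow(1e-12))

    def test_distance_and_velocity_criteria_agree(self):
        """100 random far-field scenarios: d ≤ d_max iff u_x(top) ≥ v_min."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            edge_um = rng.uniform(150, 500)
            d_mm = rng.uniform(5.1 * edge_um / 1000, 20 * edge_um / 1000)
            scen = FluidScenario.cuboid(
                edge_um,
                q_ul_s=rng.uniform(5, 120),
                d_mm=d_mm,
                tissue_density_g_cm3=rng.uniform(1.01, 1.2),
            )
            assert scen.edge / scen.sink_distance < 0.2
            assert can_lift(scen, "distance") == can_lift(scen, "velocity")


class TestQMin:
    def test_round_trip(self, cuboid400):
        d = units.mm_to_m(1.0)
        q = q_min_for_lift(cuboid400, d)
        scen = dataclasses.replace(cuboid400, suction_flow=q)
        assert d_max(scen) == pytest.approx(d, rel=1e-9)

    def test_distance_cubed_scaling(self, cuboid400):
        r = q_min_for_lift(cuboid400, 2e-3) / q_min_for_lift(cuboid400, 1e-3)
        assert r == pytest.approx(8.0, rel=1e-12)

    def test_operating_point_inversion(self, cuboid400):
        # inverting at the (2 s.f.) printed max distance recovers the peak
        # flow within the pump's own measured spread (56 ± 6.1 μl/s)
        assert abs(q_min_for_lift_ul_s(cuboid400, 1.2) - 56.0) <= 6.1

    def test_rejects_nonpositive_distance(self, cuboid400):
        with pytest.raises(LiftModelError):
            q_min_for_lift(cuboid400, 0.0)


class TestSpheroidPreset:
    def test_sphere_geometry(self):
        scen = FluidScenario.spheroid(400.0)
        h = units.um_to_m(400.0)
        assert scen.face_area == pytest.approx(math.pi * (h / 2) ** 2, rel=1e-12)
        assert scen.volume == pytest.approx(math.pi / 6 * h**3, rel=1e-12)

    def test_similar_max_distance_to_cube(self):
        # same 1/6-power structure: sphere and cube of equal size differ little
        ratio = d_max(FluidScenario.spheroid(400.0)) / d_max(FluidScenario.cuboid(400.0))
        assert 0.8 < ratio < 1.2


class TestSuccessMap:
    def test_model_on_axis_reduces_to_can_lift(self, cuboid400):
        z = np.array([0.5, 0.8, 1.1, 1.4, 2.0])
        grid = success_map(cuboid400, np.array([0.0, 0.1]), z, mode="model")
        dm = d_max_mm(cuboid400)
        for i, zi in enumerate(z):
            assert grid[i, 0] == (1.0 if zi <= dm else 0.0)

    def test_model_success_shrinks_with_height_on_axis(self, cuboid400):
        z = np.arange(0.5, 2.6, 0.1)
        grid = success_map(cuboid400, np.array([0.0, 0.2]), z, mode="model")
        on_axis = grid[:, 0]
        assert np.all(np.diff(on_axis) <= 0)  # once lost, never regained

    def test_empirical_zero_beyond_reach(self):
        assert empirical_lift_success(2.0, 0.8) == 0.0

    def test_empirical_radius_widens_above_tissue(self):
        # narrow stem near the tissue, wide cap above ~0.6 mm
        assert empirical_lift_success(0.8, 0.3) == 0.0
        assert empirical_lift_success(0.8, 0.8) == 1.0
        assert empirical_lift_success(0.35, 0.3) == 1.0

    def test_empirical_requires_table_rows(self, cuboid400):
        import pandas as pd

        with pytest.raises(ValueError):
            success_map(cuboid400, [0.0, 1.0], [0.5, 0.8], mode="empirical",
                        table=pd.DataFrame(columns=["z_mm", "r_mm", "success"]))

    def test_table_schema(self):
        table = load_success_table()
        assert {"z_mm", "r_mm", "success"} <= set(table.columns)
        assert table["success"].between(-0.001, 1.001).all()
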