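"""Point-sink model of microfluidic lift.

A glass capillary held a distance ``d`` above a submerged microtissue and
driven by a suction flow ``Q`` is idealized as a point sink near a rigid
no-penetration wall (the dish bottom). The method of images places a second
sink mirrored across the wall, so the axial velocity at an offset
``(x, y, z)`` from the tissue is the two-term sum

    u_x(x, y, z) = (Q/2) * [ (x-d)/R1³ + (x+d)/R2³ ],
    R1² = (x-d)² + y² + z²,   R2² = (x+d)² + y² + z²

normalized so that on axis, for a tissue of height ``h`` with ``h ≪ d``,
the speed over the tissue's top face reduces to ``2Qh/d³`` — the limit that
the closed-form lifting condition below is built on.

Lift occurs when the Bernoulli pressure drop over the top face beats the
submerged weight: ``½ ρ v² A ≥ (ρc − ρ) Vc g``, i.e. ``v ≥ v_min``. In the
small-``h`` limit this yields a maximum sink-to-tissue distance

    d_max = [ 2 Q² h² ρ A / ((ρc − ρ) Vc g) ]^(1/6)

which scales like ``Q^(1/3) h^(1/6)`` for a cube (``A ≈ h²``, ``Vc ≈ h³``)
and is therefore insensitive to every parameter — the physical reason the
platform needs no proximity sensing in ``z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import units


class SingularQueryError(ValueError):
    """The query point coincides with the sink or its image."""


class LiftModelError(ValueError):
    """The scenario violates a precondition of the lift model."""


@dataclass(frozen=True)
class FluidScenario:
    """All physical quantities of the lift model, in SI units.

    fluid_density and tissue_density in kg/m³, gravity in m/s²,
    edge (the tissue's characteristic height h), face_area and volume in
    m/m²/m³, suction_flow in m³/s, sink_distance d (point sink to the
    tissue's bottom surface) in m.
    """

    fluid_density: float
    tissue_density: float
    gravity: float
    edge: float
    face_area: float
    volume: float
    suction_flow: float
    sink_distance: float

    def __post_init__(self) -> None:
        for name in (
            "fluid_density",
            "tissue_density",
            "gravity",
            "edge",
            "face_area",
            "volume",
            "sink_distance",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise LiftModelError(f"{name} must be strictly positive, got {v!r}")
        if not math.isfinite(self.suction_flow):
            raise LiftModelError("suction_flow must be finite")

    @classmethod
    def cuboid(
        cls,
        edge_um: float,
        q_ul_s: float = 56.0,
        d_mm: float = 0.8,
        tissue_density_g_cm3: float = 1.079,
        fluid_density_g_cm3: float = 1.000,
        gravity: float = 9.81,
    ) -> "FluidScenario":
        """Cube preset: face area h², volume h³ (exactly)."""
        h = units.um_to_m(edge_um)
        return cls(
            fluid_density=units.g_cm3_to_kg_m3(fluid_density_g_cm3),
            tissue_density=units.g_cm3_to_kg_m3(tissue_density_g_cm3),
            gravity=gravity,
            edge=h,
            face_area=h * h,
            volume=h**3,
            suction_flow=units.ul_s_to_m3_s(q_ul_s),
            sink_distance=units.mm_to_m(d_mm),
        )

    @classmethod
    def spheroid(
        cls,
        diameter_um: float,
        q_ul_s: float = 56.0,
        d_mm: float = 0.8,
        tissue_density_g_cm3: float = 1.079,
        fluid_density_g_cm3: float = 1.000,
        gravity: float = 9.81,
    ) -> "FluidScenario":
        """Sphere preset: cross-section π(h/2)², volume (π/6)h³."""
        h = units.um_to_m(diameter_um)
        return cls(
            fluid_density=units.g_cm3_to_kg_m3(fluid_density_g_cm3),
            tissue_density=units.g_cm3_to_kg_m3(tissue_density_g_cm3),
            gravity=gravity,
            edge=h,
            face_area=math.pi * (h / 2.0) ** 2,
            volume=math.pi / 6.0 * h**3,
            suction_flow=units.ul_s_to_m3_s(q_ul_s),
            sink_distance=units.mm_to_m(d_mm),
        )

    def with_flow(self, q_ul_s: float) -> "FluidScenario":
        return replace(self, suction_flow=units.ul_s_to_m3_s(q_ul_s))

    def with_sink_distance(self, d_mm: float) -> "FluidScenario":
        return replace(self, sink_distance=units.mm_to_m(d_mm))


@dataclass(frozen=True)
class VelocityQuery:
    """Offsets (m) from the coordinate system located at the tissue."""

    x: float
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise LiftModelError("query offsets must be finite")

    @classmethod
    def from_mm(cls, x_mm: float, y_mm: float = 0.0, z_mm: float = 0.0) -> "VelocityQuery":
        return cls(units.mm_to_m(x_mm), units.mm_to_m(y_mm), units.mm_to_m(z_mm))


def sink_velocity(
    scenario: FluidScenario, query: VelocityQuery, full_magnitude: bool = False
) -> float:
    """Axial velocity u_x (m/s) of the image-sink pair at the query point.

    Negative values point toward the wall frame's -x (flow drawn up into
    the capillary gives u_x < 0 below the sink); the lift criterion uses the
    magnitude. With ``full_magnitude=True`` returns |u| including the lateral
    components instead of u_x alone.
    """
    q = scenario.suction_flow
    d = scenario.sink_distance
    x, y, z = query.x, query.y, query.z
    r1_sq = (x - d) ** 2 + y**2 + z**2
    r2_sq = (x + d) ** 2 + y**2 + z**2
    if r1_sq == 0.0 or r2_sq == 0.0:
        raise SingularQueryError("query point coincides with the sink or its image")
    r1_3 = r1_sq**1.5
    r2_3 = r2_sq**1.5
    ux = 0.5 * q * ((x - d) / r1_3 + (x + d) / r2_3)
    if not full_magnitude:
        return ux
    uy = 0.5 * q * (y / r1_3 + y / r2_3)
    uz = 0.5 * q * (z / r1_3 + z / r2_3)
    return math.sqrt(ux**2 + uy**2 + uz**2)


def approx_axial_velocity(scenario: FluidScenario) -> float:
    """Small-h on-axis speed over the tissue top, 2Qh/d³."""
    return (
        2.0
        * scenario.suction_flow
        * scenario.edge
        / scenario.sink_distance**3
    )


def lift_threshold_velocity(scenario: FluidScenario) -> float:
    """Minimum speed v_min over the top face for lift: √(2(ρc−ρ)Vc·g/(ρA)).

    Zero iff the tissue is neutrally buoyant. Raises if the tissue is less
    dense than the medium (it floats; the criterion is vacuous).
    """
    drho = scenario.tissue_density - scenario.fluid_density
    if drho < 0:
        raise LiftModelError(
            "tissue is less dense than the fluid; it floats and no lift threshold exists"
        )
    return math.sqrt(
        2.0 * drho * scenario.volume * scenario.gravity
        / (scenario.fluid_density * scenario.face_area)
    )


def d_max(scenario: FluidScenario) -> float:
    """Largest sink-to-bottom distance (m) at which suction can lift the tissue."""
    drho = scenario.tissue_density - scenario.fluid_density
    if drho <= 0:
        raise LiftModelError("d_max requires tissue denser than the fluid")
    if scenario.suction_flow <= 0:
        raise LiftModelError("d_max requires a positive suction flow")
    num = 2.0 * scenario.suction_flow**2 * scenario.edge**2 * scenario.fluid_density * scenario.face_area
    den = drho * scenario.volume * scenario.gravity
    return (num / den) ** (1.0 / 6.0)


def d_max_mm(scenario: FluidScenario) -> float:
    return units.m_to_mm(d_max(scenario))


def can_lift(scenario: FluidScenario, criterion: str = "distance") -> bool:
    """Whether the configured sink distance permits lift.

    criterion="distance" checks d ≤ d_max; criterion="velocity" compares the
    full image-sink axial speed at the tissue top against v_min. The two
    agree in the h ≪ d regime.
    """
    if scenario.suction_flow <= 0:
        return False
    if criterion == "distance":
        return scenario.sink_distance <= d_max(scenario)
    if criterion == "velocity":
        u = sink_velocity(scenario, VelocityQuery(x=scenario.edge))
        return abs(u) >= lift_threshold_velocity(scenario)
    raise ValueError(f"unknown criterion {criterion!r}")


def q_min_for_lift(scenario: FluidScenario, d: float | None = None) -> float:
    """Smallest suction flow (m³/s) that lifts at distance d (default: the
    scenario's own sink distance). Inverse of the d_max closed form, so
    d_max(scenario with Q=q_min) == d to rounding."""
    if d is None:
        d = scenario.sink_distance
    if d <= 0:
        raise LiftModelError("distance must be positive")
    drho = scenario.tissue_density - scenario.fluid_density
    if drho <= 0:
        raise LiftModelError("q_min requires tissue denser than the fluid")
    num = d**6 * drho * scenario.volume * scenario.gravity
    den = 2.0 * scenario.edge**2 * scenario.fluid_density * scenario.face_area
    return math.sqrt(num / den)


def q_min_for_lift_ul_s(scenario: FluidScenario, d_mm: float | None = None) -> float:
    d = None if d_mm is None else units.mm_to_m(d_mm)
    return units.m3_s_to_ul_s(q_min_for_lift(scenario, d))


# --- picking-success maps -------------------------------------------------

_SUCCESS_TABLE_RESOURCE = "mushroom_success.csv"


def load_success_table() -> pd.DataFrame:
    """Packaged picking-success table (synthetic surrogate).

    Long-format columns ``z_mm`` (capillary height above the tissue top),
    ``r_mm`` (lateral offset of the capillary axis from the tissue center)
    and ``success`` in [0, 1]. The table is a constructed stand-in encoding
    the measured behavior of a 400-μm tissue: a narrow stem (lift radius
    0.4 mm) below ~0.6 mm above the tissue, an abrupt widening to 1.2 mm
    above that, decay to zero success beyond r = 1.5 mm at the 0.8-mm
    operating height, and loss of lift at large heights.
    """
    with resources.files("microlift.data").joinpath(_SUCCESS_TABLE_RESOURCE).open() as fh:
        return pd.read_csv(fh)


def success_map(
    scenario: FluidScenario,
    r_grid_mm,
    z_grid_mm,
    mode: str = "model",
    table: pd.DataFrame | None = None,
):
    """Grid of lift success over lateral offset r and capillary height z.

    Returns an array of shape (len(z_grid_mm), len(r_grid_mm)).

    mode="model": thresholds the full image-sink axial speed at the tissue
    top (offset laterally by r, sink at distance z above the tissue bottom)
    against v_min; entries are 0.0/1.0. Off-axis prediction is an
    extrapolation of the on-axis model. mode="empirical": bilinear
    interpolation of a measured success table (``table`` or the packaged
    one); there z is height above the *tissue top*, matching the table.
    """
    r = np.asarray(r_grid_mm, dtype=float)
    z = np.asarray(z_grid_mm, dtype=float)
    if r.ndim != 1 or z.ndim != 1 or np.any(r < 0) or np.any(z <= 0):
        raise ValueError("grids must be 1-D with r ≥ 0 and z > 0")
    if np.any(np.diff(r) <= 0) or np.any(np.diff(z) <= 0):
        raise ValueError("grids must be strictly increasing")

    if mode == "model":
        vmin = lift_threshold_velocity(scenario)
        out = np.zeros((z.size, r.size))
        for i, z_mm in enumerate(z):
            scen = scenario.with_sink_distance(z_mm)
            for j, r_mm in enumerate(r):
                u = sink_velocity(scen, VelocityQuery.from_mm(
                    units.m_to_mm(scenario.edge), r_mm, 0.0))
                out[i, j] = 1.0 if abs(u) >= vmin else 0.0
        return out
    if mode == "empirical":
        if table is None:
            table = load_success_table()
        if table is None or len(table) == 0:
            raise ValueError("empirical mode requires a success table")
        pivot = table.pivot(index="z_mm", columns="r_mm", values="success")
        interp = RegularGridInterpolator(
            (pivot.index.to_numpy(), pivot.columns.to_numpy()),
            pivot.to_numpy(),
            bounds_error=False,
            fill_value=None,
        )
        zz, rr = np.meshgrid(z, r, indexing="ij")
        out = interp(np.stack([zz.ravel(), rr.ravel()], axis=1)).reshape(zz.shape)
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown mode {mode!r}")


def empirical_lift_success(r_mm: float, z_above_tissue_mm: float,
                           table: pd.DataFrame | None = None) -> float:
    """Interpolated success probability at a single (r, z-above-tissue) point."""
    if table is None:
        table = load_success_table()
    pivot = table.pivot(index="z_mm", columns="r_mm", values="success")
    interp = RegularGridInterpolator(
        (pivot.index.to_numpy(), pivot.columns.to_numpy()),
        pivot.to_numpy(),
        bounds_error=False,
        fill_value=None,
    )
    val = float(interp([[z_above_tissue_mm, r_mm]])[0])
    return float(np.clip(val, 0.0, 1.0))
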