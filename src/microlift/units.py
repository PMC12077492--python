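"""Unit conversion helpers.

All internal computation is in SI (m, kg, s, m³/s). Public constructors
accept the bench-convenient units used throughout the platform: μm and mm
for lengths, μl/s for flow rates, g/cm³ for densities.
"""

from __future__ import annotations

UM_PER_M = 1e6
MM_PER_M = 1e3
UL_PER_M3 = 1e9  # 1 m³ = 1e9 μl
G_CM3_PER_KG_M3 = 1e-3  # 1 kg/m³ = 1e-3 g/cm³


def um_to_m(x: float) -> float:
    return x / UM_PER_M


def m_to_um(x: float) -> float:
    return x * UM_PER_M


def mm_to_m(x: float) -> float:
    return x / MM_PER_M


def m_to_mm(x: float) -> float:
    return x * MM_PER_M


def ul_s_to_m3_s(q: float) -> float:
    return q / UL_PER_M3


def m3_s_to_ul_s(q: float) -> float:
    return q * UL_PER_M3


def g_cm3_to_kg_m3(rho: float) -> float:
    return rho / G_CM3_PER_KG_M3


def kg_m3_to_g_cm3(rho: float) -> float:
    return rho * G_CM3_PER_KG_M3
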