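"""Stochastic simulator of the pick-and-transfer workflow.

Each destination well triggers one or more pick attempts drawn from an
error model with the platform's observed failure modes:

* ``adhered pair`` — two small tissues fused into one apparent blob are
  lifted together and separate in the well (a double that image checks
  cannot prevent);
* ``stick`` — the lifted tissue lodges on the capillary's inner wall: its
  well stays empty, and the tissue is dislodged into the *next* well that
  receives a successful ejection (an empty immediately followed by a
  double — the carryover signature seen with sticky human tissues);
* ``unpickable`` — the tissue never leaves the dish; before/after image
  comparison detects it in place and the robot retries;
* ``float`` — the tissue is dislodged and drifts, so the after image no
  longer shows it at the target position and the error goes uncorrected.

Outcomes are classified per well as single / empty / double (≥2). Presets
named "mouse" and "human" carry per-attempt probabilities calibrated so the
expected outcome rates match the platform's measured plate statistics; they
are reproductions of observed behavior, not predictions.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import lift_physics

# --- plate layout ---------------------------------------------------------


@dataclass(frozen=True)
class PlateLayout:
    """Destination wells in fill (row-major) order."""

    wells: tuple[str, ...]
    target_count: int = 1
    transfer_volume_ul: float = 10.0
    format_name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.wells)) != len(self.wells):
            raise ValueError("well names must be unique")
        if self.target_count < 1:
            raise ValueError("target count must be ≥ 1")
        if self.transfer_volume_ul <= 0:
            raise ValueError("transfer volume must be positive")

    @classmethod
    def standard(cls, fmt: int, target_count: int = 1,
                 transfer_volume_ul: float | None = None) -> "PlateLayout":
        """96-well (8×12, 10 μl/trip) or 384-well (16×24, 6.4 μl/trip)."""
        if fmt == 96:
            rows, cols, vol = 8, 12, 10.0
        elif fmt == 384:
            rows, cols, vol = 16, 24, 6.4
        else:
            raise ValueError("standard formats are 96 and 384")
        names = tuple(
            f"{string.ascii_uppercase[r]}{c + 1}" for r in range(rows) for c in range(cols)
        )
        return cls(names, target_count,
                   vol if transfer_volume_ul is None else transfer_volume_ul,
                   format_name=str(fmt))


# --- error model ----------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Per-attempt failure probabilities; the remainder is a clean single pick."""

    p_unpickable: float = 0.0
    p_float: float = 0.0
    p_stick: float = 0.0
    p_adhered_pair: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_unpickable, self.p_float, self.p_stick, self.p_adhered_pair)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(probs) > 1.0:
            raise ValueError("failure probabilities sum above 1")

    @classmethod
    def preset(cls, name: str) -> "ErrorModel":
        try:
            return cls(**_PRESETS[name])
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; have {sorted(_PRESETS)}") from None


# Calibrated so that, with one retry per well, the expected single/empty/
# double rates and the empty→double adjacency reproduce the measured plate
# statistics (mouse: 98.4/0.5/1.0 with no adjacency; human: 92.8/4.1/3.2
# with ~56% of doubles preceded by an empty).
_PRESETS: dict[str, dict[str, float]] = {
    "mouse": dict(p_unpickable=0.045, p_float=0.003, p_stick=0.0, p_adhered_pair=0.010),
    "human": dict(p_unpickable=0.095, p_float=0.012, p_stick=0.0175, p_adhered_pair=0.0145),
}


# --- transfer log ---------------------------------------------------------


@dataclass(frozen=True)
class AttemptRecord:
    attempt: int
    well: str
    source_id: int
    event: str  # single | pair | stick | unpickable | float | carryover_drop | auto_pause
    delivered: int  # tissues ejected into the well on this attempt
    well_count: int  # well content after the attempt
    dish_remaining: int
    capillary_queue: int
    elapsed_s: float


@dataclass
class TransferLog:
    records: list[AttemptRecord]
    n_initial: int
    layout: PlateLayout
    auto_paused: bool = False
    retries: int = 0

    def well_counts(self) -> dict[str, int]:
        counts = {w: 0 for w in self.layout.wells}
        for r in self.records:
            if r.event != "auto_pause":
                counts[r.well] = r.well_count
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --- simulation -----------------------------------------------------------


def simulate_fill(
    candidates,
    layout: PlateLayout,
    error_model: ErrorModel,
    seed: int,
    retry: bool = True,
    max_retries: int = 1,
    lift_check: "lift_physics.FluidScenario | None" = None,
    timing: "TimingParams | None" = None,
    rescan_s: float = 3.0,
) -> tuple[TransferLog, dict[str, int]]:
    """Fill the layout well by well; returns the log and final well contents.

    ``candidates`` is a candidate count or a list with one entry per
    pickable tissue. Wells are visited in layout order; each draws attempts
    until a tissue is ejected or retries are exhausted. Only failures the
    before/after image check can see (tissue still in place) are retried —
    a retry rescans, so the failed tissue rejoins the candidate pool.
    Deterministic for a fixed seed. If ``lift_check`` is given and its
    configured sink distance exceeds the model's maximum lift distance, no
    attempt can succeed and the run auto-pauses immediately.
    """
    n0 = candidates if isinstance(candidates, int) else len(candidates)
    rng = np.random.default_rng(seed)
    timing = timing or default_timing()
    em = error_model

    liftable = True
    if lift_check is not None:
        liftable = lift_physics.can_lift(lift_check)

    pool = list(range(n0))
    records: list[AttemptRecord] = []
    counts = {w: 0 for w in layout.wells}
    queue = 0  # tissues stuck in the capillary (≤ 1)
    elapsed = 0.0
    attempt = 0
    auto_paused = False
    retries = 0

    for well in layout.wells:
        tries = 0
        while True:
            if not pool or not liftable:
                records.append(AttemptRecord(
                    attempt, well, -1, "auto_pause", 0, counts[well],
                    len(pool), queue, elapsed))
                auto_paused = True
                break
            src = pool.pop(0)
            attempt += 1
            elapsed += timing.t_trip_s + timing.t_pick_s
            u = rng.random()
            if u < em.p_adhered_pair:
                delivered = 2 + queue  # ejection dislodges any stuck tissue
                queue = 0
                counts[well] += delivered
                records.append(AttemptRecord(
                    attempt, well, src, "pair", delivered, counts[well],
                    len(pool), queue, elapsed))
                break
            if u < em.p_adhered_pair + em.p_stick:
                # lifted but lodged in the capillary; the ejection flushes
                # only a previously stuck tissue, if any
                delivered = queue
                queue = 1
                counts[well] += delivered
                records.append(AttemptRecord(
                    attempt, well, src, "stick", delivered, counts[well],
                    len(pool), queue, elapsed))
                if delivered:
                    break
                # nothing reached the well, and the after image shows the
                # tissue gone from the dish, so the error goes undetected
                break
            if u < em.p_adhered_pair + em.p_stick + em.p_unpickable:
                # never left the dish; the after image sees it → retry
                pool.append(src)
                records.append(AttemptRecord(
                    attempt, well, src, "unpickable", 0, counts[well],
                    len(pool), queue, elapsed))
                if retry and tries < max_retries:
                    tries += 1
                    retries += 1
                    elapsed += rescan_s
                    continue
                break
            if u < em.p_adhered_pair + em.p_stick + em.p_unpickable + em.p_float:
                # drifted away; after image shows it gone → looks picked
                pool.append(src)
                records.append(AttemptRecord(
                    attempt, well, src, "float", 0, counts[well],
                    len(pool), queue, elapsed))
                break
            delivered = 1 + queue
            queue = 0
            counts[well] += delivered
            records.append(AttemptRecord(
                attempt, well, src,
                "carryover_drop" if delivered > 1 else "single",
                delivered, counts[well], len(pool), queue, elapsed))
            break
        if auto_paused:
            break

    log = TransferLog(records, n0, layout, auto_paused=auto_paused, retries=retries)
    return log, counts


def check_conservation(log: TransferLog) -> bool:
    """Picked objects delivered + remaining in dish + stuck in the capillary
    == initial candidate count, at every step of the log. An adhered pair is
    one picked object (the extra tissue was never a separate candidate)."""
    delivered = 0
    for r in log.records:
        if r.event == "auto_pause":
            continue
        objects = r.delivered - (1 if r.event == "pair" else 0)
        delivered += objects
        if delivered + r.dish_remaining + r.capillary_queue != log.n_initial:
            return False
    return True


# --- statistics -----------------------------------------------------------


@dataclass(frozen=True)
class SuccessStats:
    wells: int
    single: int
    empty: int
    double: int
    attempts: int = 0
    retries: int = 0

    def __post_init__(self) -> None:
        if self.single + self.empty + self.double != self.wells:
            raise ValueError("single + empty + double must equal total wells")

    @property
    def single_pct(self) -> float:
        return round(100.0 * self.single / self.wells, 1)

    @property
    def empty_pct(self) -> float:
        return round(100.0 * self.empty / self.wells, 1)

    @property
    def double_pct(self) -> float:
        return round(100.0 * self.double / self.wells, 1)


def success_stats(log: TransferLog | dict[str, int]) -> SuccessStats:
    """Per-well outcome tallies; success = a well holding exactly one tissue.

    Accepts a TransferLog or a {well: count} mapping. Wells holding two or
    more tissues count as doubles."""
    if isinstance(log, TransferLog):
        counts = log.well_counts()
        attempts = sum(1 for r in log.records if r.event != "auto_pause")
        retries = log.retries
    else:
        counts = dict(log)
        attempts = retries = 0
    if not counts:
        raise ValueError("empty log")
    vals = list(counts.values())
    return SuccessStats(
        wells=len(vals),
        single=sum(v == 1 for v in vals),
        empty=sum(v == 0 for v in vals),
        double=sum(v >= 2 for v in vals),
        attempts=attempts,
        retries=retries,
    )


def stats_from_counts(single: int, empty: int, double: int) -> SuccessStats:
    """Build stats straight from a printed plate breakdown."""
    return SuccessStats(wells=single + empty + double, single=single,
                        empty=empty, double=double)


def doubles_preceded_by_empty_fraction(log: TransferLog) -> float | None:
    """Among double-filled wells, the fraction whose immediately preceding
    well (in fill order) ended empty. None if the run produced no doubles."""
    counts = log.well_counts()
    order = log.layout.wells
    doubles = 0
    preceded = 0
    for i, w in enumerate(order):
        if counts.get(w, 0) >= 2:
            doubles += 1
            if i > 0 and counts.get(order[i - 1], 0) == 0:
                preceded += 1
    return preceded / doubles if doubles else None


# --- timing ---------------------------------------------------------------


@dataclass(frozen=True)
class TimingParams:
    """Two-parameter trip model: t(n) = t_trip + n·t_pick for a trip
    carrying n tissues."""

    t_trip_s: float
    t_pick_s: float
    capacity: int = 6

    def trip_time(self, n: int) -> float:
        if not 1 <= n <= self.capacity:
            raise ValueError(f"n must be in [1, {self.capacity}]")
        return self.t_trip_s + n * self.t_pick_s


#: measured speedups of an n-tissue trip vs. n single trips
REFERENCE_SPEEDUPS = {2: 1.35, 4: 1.66, 6: 1.8}
#: single-transfer duration anchor (s): one 384-well plate in ~65 min
SINGLE_TRANSFER_S = 65.0 * 60.0 / 384.0


def fit_timing(speedups: dict[int, float] = None,
               single_transfer_s: float = SINGLE_TRANSFER_S,
               capacity: int = 6) -> TimingParams:
    """Least-squares fit of the pick/trip cost ratio to measured speedups,
    scaled so a single transfer takes ``single_transfer_s``."""
    speedups = speedups or REFERENCE_SPEEDUPS
    ns = np.array(sorted(speedups))
    target = np.array([speedups[n] for n in ns])

    def loss(a: float) -> float:
        pred = ns * (1 + a) / (1 + ns * a)
        return float(np.sum((pred - target) ** 2))

    res = minimize_scalar(loss, bounds=(1e-3, 100.0), method="bounded")
    a = float(res.x)
    t_trip = single_transfer_s / (1 + a)
    return TimingParams(t_trip_s=t_trip, t_pick_s=a * t_trip, capacity=capacity)


def default_timing() -> TimingParams:
    return fit_timing()


def multi_pick_time(n_per_well: int, timing: TimingParams | None = None
                    ) -> tuple[float, float]:
    """Duration of one n-tissue trip and its speedup vs. n single trips."""
    timing = timing or default_timing()
    t_n = timing.trip_time(n_per_well)
    t_1 = timing.trip_time(1)
    return t_n, n_per_well * t_1 / t_n


# --- placement noise ------------------------------------------------------

#: repeatability of localization (per-axis jitter sd, μm)
DEFAULT_JITTER_SD_UM = 26.0
#: per-calibration systematic offset: per-axis sd chosen so the mean bias
#: magnitude (Rayleigh mean, sd·√(π/2)) is the measured ~129 μm accuracy
DEFAULT_BIAS_SD_UM = 129.0 * math.sqrt(2.0 / math.pi)


def placement_noise(
    seed: int,
    n: int = 1,
    jitter_sd_um: float = DEFAULT_JITTER_SD_UM,
    bias_sd_um: float = DEFAULT_BIAS_SD_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Capillary landing offsets: one per-calibration 2-D bias plus
    per-attempt isotropic jitter. Returns (offsets (n, 2) μm, bias (2,) μm)."""
    if jitter_sd_um < 0 or bias_sd_um < 0:
        raise ValueError("spreads must be nonnegative")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, bias_sd_um, size=2)
    jitter = rng.normal(0.0, jitter_sd_um, size=(n, 2))
    return bias + jitter, bias


def placement_success(
    offsets_um: np.ndarray,
    z_above_tissue_mm: float = 0.4,
    table: pd.DataFrame | None = None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Whether each landing offset still lifts, per the measured success
    profile at the given height above the tissue."""
    offs = np.atleast_2d(np.asarray(offsets_um, dtype=float))
    if table is None:
        table = lift_physics.load_success_table()
    r_mm = np.hypot(offs[:, 0], offs[:, 1]) / 1000.0
    return np.array([
        lift_physics.empirical_lift_success(r, z_above_tissue_mm, table) >= threshold
        for r in r_mm
    ])
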