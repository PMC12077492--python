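"""Well-plate readout quantification and drug-response analysis.

Viability is read repeatedly and nondestructively (luminescent reagent), so
drug response is expressed per well as the ratio of the corrected signal at
a later day to the day-1 baseline. Well signals come either from a plate
image (mean intensity inside each well ROI minus a background estimate) or
from a pre-extracted table. Filtering of anomalous wells — no baseline
signal, implausibly low, or implausibly high at late timepoints — is
non-destructive: rows are flagged, never dropped.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

READOUT_COLUMNS = ["well", "day", "raw", "background", "corrected", "flags"]

FLAG_EMPTY = "empty_well"
FLAG_LOW = "low_viability_excluded"
FLAG_HIGH = "high_viability_excluded"
FLAG_DOUBLE = "double_fill"
FLAG_RATIO_UNDEF = "ratio_undefined"


def _add_flag(flags: str, new: str) -> str:
    current = set(str(flags).split(";")) - {"", "nan"}
    current.add(new)
    return ";".join(sorted(current))


def has_flag(flags, name: str) -> bool:
    return name in set(str(flags).split(";"))


# --- plate-image quantification ------------------------------------------


@dataclass(frozen=True)
class PlateGrid:
    """Registration of a plate image: well-center lattice in pixels."""

    origin_x_px: float
    origin_y_px: float
    pitch_px: float
    radius_px: float
    rows: int
    cols: int

    def well_names(self) -> list[str]:
        return [f"{string.ascii_uppercase[r]}{c + 1}"
                for r in range(self.rows) for c in range(self.cols)]

    def center(self, name: str) -> tuple[float, float]:
        row = string.ascii_uppercase.index(name[0])
        col = int(name[1:]) - 1
        return (self.origin_x_px + col * self.pitch_px,
                self.origin_y_px + row * self.pitch_px)


def quantify_wells(
    plate_image: np.ndarray,
    grid: PlateGrid,
    day,
    background_mode: str = "blank_median",
    blank_wells: tuple[str, ...] = (),
    annulus_width_px: float = 3.0,
) -> pd.DataFrame:
    """Mean signal per well ROI, background-subtracted (floored at zero).

    background_mode="blank_median" uses the median ROI mean of the listed
    blank wells (or, with none listed, the median intensity outside all
    ROIs); "annulus" estimates a local background per well from a ring just
    outside its ROI. Deterministic.
    """
    img = np.asarray(plate_image, dtype=float)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    means: dict[str, float] = {}
    annulus_bg: dict[str, float] = {}
    union = np.zeros(img.shape, dtype=bool)
    for name in grid.well_names():
        cx, cy = grid.center(name)
        dist = np.hypot(xx - cx, yy - cy)
        roi = dist <= grid.radius_px
        if not roi.any():
            raise ValueError(f"well {name} ROI lies outside the image")
        union |= roi
        means[name] = float(img[roi].mean())
        ring = (dist > grid.radius_px) & (dist <= grid.radius_px + annulus_width_px)
        annulus_bg[name] = float(np.median(img[ring])) if ring.any() else 0.0

    if background_mode == "blank_median":
        if blank_wells:
            bg_global = float(np.median([means[w] for w in blank_wells]))
        else:
            bg_global = float(np.median(img[~union])) if (~union).any() else 0.0
        background = {w: bg_global for w in means}
    elif background_mode == "annulus":
        background = annulus_bg
    else:
        raise ValueError(f"unknown background mode {background_mode!r}")

    rows = []
    for name in grid.well_names():
        raw = means[name]
        bg = background[name]
        rows.append({"well": name, "day": day, "raw": raw, "background": bg,
                     "corrected": max(raw - bg, 0.0), "flags": ""})
    return pd.DataFrame(rows, columns=READOUT_COLUMNS)


# --- filtering ------------------------------------------------------------


def flag_no_baseline_signal(readouts: pd.DataFrame, baseline_day,
                            threshold: float = 0.0) -> pd.DataFrame:
    """Flag wells with no viability signal at baseline (all their rows)."""
    out = readouts.copy()
    base = out[out["day"] == baseline_day]
    dead = set(base.loc[base["corrected"] <= threshold, "well"])
    mask = out["well"].isin(dead)
    out.loc[mask, "flags"] = out.loc[mask, "flags"].map(
        lambda f: _add_flag(f, FLAG_EMPTY))
    return out


def filter_outlier_wells(
    readouts: pd.DataFrame,
    low_threshold: float,
    high_threshold: float,
    applicable_days=(7, 12),
) -> pd.DataFrame:
    """Flag implausible wells, keeping every row.

    The low cut applies at every timepoint: a well whose corrected signal
    ever falls below it is flagged throughout. The high cut applies only on
    the listed later days (overgrown/double-seeded wells reveal themselves
    late); wells exceeding it on one of those days are flagged throughout.
    """
    if low_threshold >= high_threshold:
        raise ValueError("low threshold must be below high threshold")
    out = readouts.copy()
    low_wells = set(out.loc[out["corrected"] < low_threshold, "well"])
    late = out[out["day"].isin(set(applicable_days))]
    high_wells = set(late.loc[late["corrected"] > high_threshold, "well"])
    for wells, flag in ((low_wells, FLAG_LOW), (high_wells, FLAG_HIGH)):
        mask = out["well"].isin(wells)
        out.loc[mask, "flags"] = out.loc[mask, "flags"].map(
            lambda f, fl=flag: _add_flag(f, fl))
    return out


# --- response ratios ------------------------------------------------------


def viability_ratio(
    readouts: pd.DataFrame,
    day_n,
    day_1,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well day_n / day_1 corrected-signal ratios plus group summaries.

    Wells flagged at either timepoint are excluded (their exclusion reason
    propagates); an unflagged zero baseline is flagged ratio_undefined and
    excluded. Returns (per-well table, per-condition summary with mean,
    SEM and n over included wells).
    """
    d1 = readouts[readouts["day"] == day_1].set_index("well")
    dn = readouts[readouts["day"] == day_n].set_index("well")
    common = [w for w in d1.index if w in dn.index]
    if not common:
        raise ValueError("no wells shared between the two timepoints")
    rows = []
    for w in common:
        flags = set(str(d1.loc[w, "flags"]).split(";")) | set(
            str(dn.loc[w, "flags"]).split(";"))
        flags -= {"", "nan"}
        base = float(d1.loc[w, "corrected"])
        if not flags and base <= 0:
            flags.add(FLAG_RATIO_UNDEF)
        included = not flags
        ratio = float(dn.loc[w, "corrected"]) / base if included else math.nan
        rows.append({
            "well": w,
            "condition": (groups or {}).get(w, "all"),
            "ratio": ratio,
            "included": included,
            "flags": ";".join(sorted(flags)),
        })
    per_well = pd.DataFrame(rows)
    inc = per_well[per_well["included"]]
    summary = (
        inc.groupby("condition")["ratio"]
        .agg(mean="mean", sem=lambda x: x.sem(ddof=1), n="count")
        .reset_index()
    )
    return per_well, summary


# --- sample size ----------------------------------------------------------


def sample_size(
    effect_fraction: float,
    group_sd: float,
    power: float = 0.8,
    alpha: float = 0.05,
    method: str = "normal",
) -> int:
    """Minimum n per group to detect a mean difference at the given power.

    Two-sample, two-sided, equal variances: n = 2·(z₁₋α/2 + z₁₋β)²·(sd/Δ)²,
    rounded up. method="t" iterates the same formula with t quantiles for a
    small-sample correction.
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if effect_fraction <= 0 or group_sd <= 0:
        raise ValueError("effect and sd must be positive")
    ratio = group_sd / effect_fraction
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    n = 2 * z**2 * ratio**2
    if method == "normal":
        return math.ceil(n)
    if method == "t":
        cur = max(math.ceil(n), 2)
        for _ in range(50):
            df = 2 * cur - 2
            tq = sps.t.ppf(1 - alpha / 2, df) + sps.t.ppf(power, df)
            nxt = max(math.ceil(2 * tq**2 * ratio**2), 2)
            if nxt == cur:
                return cur
            cur = nxt
        return cur
    raise ValueError(f"unknown method {method!r}")


# --- synthetic readout generation ----------------------------------------


def generate_readouts(
    wells: list[str],
    conditions: dict[str, str],
    effects: dict[str, float],
    seed: int,
    days=(1, 6),
    baseline_mean: float = 1000.0,
    well_cv: float = 0.30,
    noise_cv: float = 0.05,
    background: float = 100.0,
) -> pd.DataFrame:
    """Synthetic per-well viability table with programmed drug effects.

    Each well gets a lognormal baseline (CV ``well_cv``, emulating tissue-
    to-tissue heterogeneity); on later days the latent signal is scaled by
    its condition's effect ratio; every measurement adds a flat background
    and multiplicative read noise (CV ``noise_cv``). Raw = background +
    latent·(1 + noise), so the generator's own background is the correct
    subtraction oracle.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + well_cv**2))
    latent = {
        w: baseline_mean * math.exp(rng.normal(-sigma**2 / 2, sigma)) for w in wells
    }
    rows = []
    for day in days:
        for w in wells:
            eff = 1.0 if day == days[0] else effects[conditions[w]]
            signal = latent[w] * eff * (1 + rng.normal(0, noise_cv))
            raw = background + max(signal, 0.0)
            rows.append({"well": w, "day": day, "raw": raw,
                         "background": background,
                         "corrected": max(raw - background, 0.0), "flags": ""})
    return pd.DataFrame(rows, columns=READOUT_COLUMNS)


def generate_plate_image(
    grid: PlateGrid,
    well_values: dict[str, float],
    background: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render a plate image with uniform disks of the given mean values on a
    flat background (optional Gaussian noise); oracle for quantify_wells."""
    if shape is None:
        ny = int(grid.origin_y_px + (grid.rows - 1) * grid.pitch_px + 3 * grid.radius_px)
        nx = int(grid.origin_x_px + (grid.cols - 1) * grid.pitch_px + 3 * grid.radius_px)
        shape = (ny, nx)
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for name, val in well_values.items():
        cx, cy = grid.center(name)
        img[np.hypot(xx - cx, yy - cy) <= grid.radius_px] = val
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, shape)
    return img
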