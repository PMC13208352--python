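"""Peptide signal quantification: from per-cycle/per-exposure intensities to
one kinetic slope per peptide per array, with QC status.

A PamChip run images every peptide spot at several camera exposures
(10/20/50/100 ms) on every pumping cycle (every 5 min over 60 min).  The
reduction is two-stage:

1. *Exposure stage* — per cycle, ordinary least squares of intensity on
   exposure time; the slope times 100 is the cycle's signal at the 100 ms
   reference exposure.  This removes camera-exposure dependence and, because
   saturated readings (at or above the detector ceiling) are dropped before
   the fit, recovers the true signal for bright spots.
2. *Kinetic stage* — OLS of the per-cycle signal on cycle time; the slope
   (units/min) is the peptide's phosphorylation intensity and the fit's R²
   its linearity score.

QC then labels each (peptide, array): peptides left with fewer than two
usable exposures on too many cycles are ``excluded_saturated``; flat or dim
peptides are ``excluded_undetectable``; fits with R² strictly below
``r2_min`` (default 0.80) are ``excluded_nonlinear``; the rest are
``included``.  R² exactly at the threshold is included.
"""

from __future__ import annotations

import csv
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    IntegrityError,
    ReplicationError,
    SchemaError,
)
from .simulate import REFERENCE_EXPOSURE_MS, DEFAULT_SATURATION

logger = logging.getLogger(__name__)

READING_FIELDS = (
    "chip_id", "array_id", "group", "assay",
    "cycle_index", "time_min", "exposure_ms", "peptide_id", "intensity",
)
READING_KEY = ("chip_id", "array_id", "cycle_index", "exposure_ms", "peptide_id")

STATUS_INCLUDED = "included"
STATUS_NONLINEAR = "excluded_nonlinear"
STATUS_UNDETECTABLE = "excluded_undetectable"
STATUS_SATURATED = "excluded_saturated"
STATUSES = (
    STATUS_INCLUDED, STATUS_NONLINEAR, STATUS_UNDETECTABLE, STATUS_SATURATED,
)

DEFAULT_R2_MIN = 0.80
DEFAULT_DETECT_MIN = 2.0


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in head else ","


def read_cycle_readings(path) -> pd.DataFrame:
    """Read and validate a long-format cycle-reading table (CSV or TSV).

    Rows with non-numeric intensity are dropped with a row-addressed warning;
    a missing column raises :class:`SchemaError`; duplicated
    (chip, array, cycle, exposure, peptide) keys raise :class:`IntegrityError`.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"intensity": object})
    missing = [c for c in READING_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.isna() & df["intensity"].notna() | df["intensity"].isna()
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:10]]  # 1-based incl. header
        logger.warning(
            "%s: dropping %d row(s) with non-numeric intensity (file rows %s%s)",
            path, int(bad.sum()), rows, "..." if bad.sum() > 10 else "",
        )
        df = df[~bad].copy()
        intensity = intensity[~bad]
    df["intensity"] = intensity.astype(float)
    for col in ("time_min", "exposure_ms"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["cycle_index"] = pd.to_numeric(df["cycle_index"], errors="raise").astype(int)
    dup = df.duplicated(subset=list(READING_KEY))
    if dup.any():
        first = df.loc[dup.idxmax(), list(READING_KEY)].tolist()
        raise IntegrityError(
            f"{path}: {int(dup.sum())} duplicate reading key(s), first {first}"
        )
    return df.reset_index(drop=True)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS with free intercept: returns (slope, r_squared).

    r_squared is NaN when y has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    if syy == 0.0:
        return slope, float("nan")
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, r2


def exposure_slope(exposures_ms: Sequence[float], intensities: Sequence[float]) -> float:
    """Per-cycle signal: OLS slope of intensity on exposure, scaled to 100 ms.

    Requires at least two distinct exposures; all-equal exposures raise
    :class:`DegenerateDesignError`.
    """
    x = np.asarray(exposures_ms, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError("need >= 2 distinct exposures")
    slope, _ = _ols(x, y)
    return slope * REFERENCE_EXPOSURE_MS


def kinetic_slope(times_min: Sequence[float], signals: Sequence[float]) -> tuple[float, float]:
    """Phosphorylation rate: OLS slope of per-cycle signal on time, plus R².

    Needs >= 3 strictly increasing time points.  R² is NaN (undefined) when
    the signal has zero variance; such peptides are later excluded as
    undetectable.
    """
    t = np.asarray(times_min, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 cycles, got {len(t)}")
    if not np.all(np.diff(t) > 0):
        raise DegenerateDesignError("cycle times must be strictly increasing")
    return _ols(t, s)


def _masked_ols(y: np.ndarray, x: np.ndarray, valid: np.ndarray):
    """Vectorized OLS of y on x along the last axis under a validity mask.

    Returns (slope, r_squared, n_valid); slope is NaN where n_valid < 2 or x
    has no spread, r_squared NaN where y has no spread.
    """
    n = valid.sum(axis=-1)
    xw = np.where(valid, x, 0.0)
    yw = np.where(valid, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xw.sum(-1)
        sy = yw.sum(-1)
        sxx = (xw * xw).sum(-1)
        syy = (yw * yw).sum(-1)
        sxy = (xw * yw).sum(-1)
        vx = sxx - sx * sx / np.maximum(n, 1)
        vy = syy - sy * sy / np.maximum(n, 1)
        cxy = sxy - sx * sy / np.maximum(n, 1)
        slope = np.where((n >= 2) & (vx > 0), cxy / np.where(vx > 0, vx, 1.0), np.nan)
        # guard tiny negative vy from cancellation
        vy = np.where(vy < 0, 0.0, vy)
        r2 = np.where(
            (n >= 2) & (vx > 0) & (vy > 0),
            (cxy * cxy) / np.where((vx > 0) & (vy > 0), vx * vy, 1.0),
            np.nan,
        )
    return slope, r2, n


def quantify(
    readings: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
    detect_min: float = DEFAULT_DETECT_MIN,
    saturation_ceiling: float = DEFAULT_SATURATION,
    time_window: tuple[float, float] | None = None,
    two_stage: bool = True,
) -> pd.DataFrame:
    """Reduce a reading table to one PeptideSignal row per (array, peptide).

    Two-stage reduction by default (exposure slope per cycle, kinetic slope
    over cycles within ``time_window``); ``two_stage=False`` uses the final
    cycle's exposure regression alone.  Readings at or above
    ``saturation_ceiling`` are dropped from the exposure fits; negative
    fitted slopes are retained (flooring happens at fold-change time).

    Returns columns: chip_id, array_id, group, assay, peptide_id, slope,
    r_squared, max_intensity, n_cycles, status.
    """
    df = readings
    if time_window is not None:
        lo, hi = time_window
        df = df[(df["time_min"] >= lo) & (df["time_min"] <= hi)]
    if df.empty:
        raise InsufficientDataError("no readings in the requested time window")

    key = pd.MultiIndex.from_frame(
        df[["chip_id", "array_id", "group", "assay", "peptide_id"]]
    )
    s_codes, s_uniq = key.factorize(sort=True)
    t_codes, t_vals = pd.factorize(df["time_min"].to_numpy(), sort=True)
    e_codes, e_vals = pd.factorize(df["exposure_ms"].to_numpy(), sort=True)
    n_s, n_t, n_e = len(s_uniq), len(t_vals), len(e_vals)

    cube = np.full((n_s, n_t, n_e), np.nan)
    cube[s_codes, t_codes, e_codes] = df["intensity"].to_numpy(dtype=float)

    present = ~np.isnan(cube)
    max_int = np.where(
        present.any((1, 2)), np.nanmax(np.where(present, cube, -np.inf), axis=(1, 2)), np.nan
    )
    saturated = present & (cube >= saturation_ceiling)
    usable = present & ~saturated

    x_e = np.broadcast_to(np.asarray(e_vals, dtype=float), cube.shape)
    sig, r2_e, n_valid_e = _masked_ols(np.nan_to_num(cube), x_e, usable)
    sig = sig * REFERENCE_EXPOSURE_MS          # (n_s, n_t) per-cycle signals

    if two_stage:
        cyc_ok = n_valid_e >= 2
        x_t = np.broadcast_to(np.asarray(t_vals, dtype=float), sig.shape)
        slope, r2, n_cyc = _masked_ols(np.nan_to_num(sig), x_t, cyc_ok & ~np.isnan(sig))
        enough = n_cyc >= 3
    else:
        slope = sig[:, -1]
        r2 = r2_e[:, -1]
        n_cyc = (n_valid_e[:, -1] >= 2).astype(int)
        enough = n_cyc >= 1

    out = pd.DataFrame(
        list(s_uniq),
        columns=["chip_id", "array_id", "group", "assay", "peptide_id"],
    )
    out["slope"] = slope
    out["r_squared"] = r2
    out["max_intensity"] = max_int
    out["n_cycles"] = n_cyc
    out["_saturation_loss"] = ~enough
    out = qc_filter(out, r2_min=r2_min, detect_min=detect_min)[0]
    return out.drop(columns=["_saturation_loss"])


def qc_filter(
    signals: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
    detect_min: float = DEFAULT_DETECT_MIN,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Assign QC status and partition the signal table.

    Precedence: saturation loss, then undetectable (max intensity below
    ``detect_min`` or zero-variance/undefined R²), then nonlinear
    (``r_squared < r2_min``, strictly — R² exactly at ``r2_min`` is
    included), else included.  The partition is exhaustive and mutually
    exclusive.  Returns (table with ``status`` column, {status: subtable}).
    """
    if not (0.0 <= r2_min <= 1.0):
        raise ValueError(f"r2_min must be in [0, 1], got {r2_min}")
    out = signals.copy()
    r2 = out["r_squared"].to_numpy(dtype=float)
    sat = (
        out["_saturation_loss"].to_numpy(dtype=bool)
        if "_saturation_loss" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    undet = np.isnan(r2)
    if "max_intensity" in out.columns:
        mi = out["max_intensity"].to_numpy(dtype=float)
        undet = undet | np.isnan(mi) | (mi < detect_min)
    nonlin = ~undet & (r2 < r2_min)
    status = np.where(
        sat, STATUS_SATURATED,
        np.where(undet, STATUS_UNDETECTABLE,
                 np.where(nonlin, STATUS_NONLINEAR, STATUS_INCLUDED)),
    )
    out["status"] = status
    parts = {s: out[out["status"] == s] for s in STATUSES}
    return out, parts


def chip_cv(
    signals: pd.DataFrame,
    high_signal_quantile: float = 0.75,
) -> tuple[pd.DataFrame, float]:
    """Across-chip coefficient of variation of high signals.

    For each (group, assay, peptide) with included status on >= 2 chips and a
    mean slope above the ``high_signal_quantile`` quantile of per-peptide
    means, CV = sample SD across chips / mean across chips.  Peptides with
    mean 0 get CV NaN and are excluded from the summary.  Returns
    (per-peptide table, median CV of the high-signal peptides).
    """
    inc = signals
    if "status" in signals.columns:
        inc = signals[signals["status"] == STATUS_INCLUDED]
    if inc["chip_id"].nunique() < 2:
        raise ReplicationError("chip CV needs >= 2 technical-replicate chips")
    g = inc.groupby(["group", "assay", "peptide_id"])["slope"]
    tab = g.agg(n_chips="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    tab = tab[tab["n_chips"] >= 2].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["cv"] = np.where(tab["mean"] != 0, tab["sd"] / tab["mean"], np.nan)
    cut = tab["mean"].quantile(high_signal_quantile)
    tab["high_signal"] = tab["mean"] >= cut
    summary = float(tab.loc[tab["high_signal"], "cv"].median())
    return tab, summary


def write_signals(signals: pd.DataFrame, path) -> None:
    """Write the per-peptide signal table (delimited)."""
    signals.to_csv(path, index=False, float_format="%.10g")
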