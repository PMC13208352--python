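"""Cross-chip fold changes and differential-phosphorylation calls.

For every peptide the treatment/control signal ratio is computed per
technical-replicate chip (case and control arrays of the same chip), then
averaged across chips.  A peptide is called differential when its mean fold
change moves at least 30% in either direction: FC >= 1.30 (up) or
FC <= 0.70 (down), boundary values included.  Slopes are floored at a small
positive value before the ratio so near-zero or negative fits cannot flip
signs or blow up the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, PairingError
from .signal import STATUS_INCLUDED

logger = logging.getLogger(__name__)

DEFAULT_FC_UP = 1.30
DEFAULT_FC_DOWN = 0.70
DEFAULT_FLOOR = 1.0

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class DifferentialCounts:
    n_up: int
    n_down: int
    n_none: int


def fold_change(
    case: pd.DataFrame,
    control: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    ratio_of_means: bool = False,
    geometric: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peptide fold changes between matched signal tables.

    ``case`` and ``control`` are per-peptide signal tables (as produced by
    :func:`adipokinome.signal.quantify`) sharing chip structure.  Per chip,
    FC = max(case slope, floor) / max(control slope, floor); chip FCs are
    then averaged (arithmetic by default, geometric optionally).  With
    ``ratio_of_means`` the slopes are averaged across chips first and a
    single ratio taken (sensitivity analysis).

    Peptides excluded by QC in either group on every chip are omitted;
    returns (records, omitted) where ``records`` has columns peptide_id,
    n_chips, per_chip_fc (tuple, chip order), mean_fc, log2_fc and
    ``omitted`` lists peptide_id and reason.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")

    def _included(df):
        if "status" in df.columns:
            return df[df["status"] == STATUS_INCLUDED]
        return df

    ci, xi = _included(control), _included(case)
    merged = xi.merge(
        ci, on=["chip_id", "peptide_id"], suffixes=("_case", "_control")
    )
    all_peps = set(case["peptide_id"]) | set(control["peptide_id"])
    if merged.empty:
        raise PairingError("case and control share no included (chip, peptide) pairs")

    fc = (
        np.maximum(merged["slope_case"].to_numpy(dtype=float), floor)
        / np.maximum(merged["slope_control"].to_numpy(dtype=float), floor)
    )
    merged = merged.assign(fc=fc).sort_values(["peptide_id", "chip_id"])

    rows = []
    for pep, grp in merged.groupby("peptide_id", sort=True):
        chips = tuple(grp["fc"].to_numpy())
        if ratio_of_means:
            mean_fc = (
                np.maximum(grp["slope_case"].mean(), floor)
                / np.maximum(grp["slope_control"].mean(), floor)
            )
        elif geometric:
            mean_fc = float(np.exp(np.mean(np.log(chips))))
        else:
            mean_fc = float(np.mean(chips))
        rows.append((pep, len(chips), chips, mean_fc, float(np.log2(mean_fc))))
    records = pd.DataFrame(
        rows, columns=["peptide_id", "n_chips", "per_chip_fc", "mean_fc", "log2_fc"]
    )
    omitted_ids = sorted(all_peps - set(records["peptide_id"]))
    omitted = pd.DataFrame(
        {"peptide_id": omitted_ids, "reason": "excluded_by_qc_in_case_or_control"}
    )
    if len(omitted):
        logger.info("fold_change: omitted %d peptide(s) excluded by QC", len(omitted))
    return records, omitted


def classify_differential(
    records: pd.DataFrame,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
) -> tuple[pd.DataFrame, DifferentialCounts]:
    """Flag differential peptides: mean FC >= fc_up (up) or <= fc_down (down).

    Boundary values count as differential.  Requires fc_down < 1 < fc_up.
    Returns (records with ``differential``/``direction`` columns, counts).
    """
    if not (fc_down < 1.0 < fc_up):
        raise ValueError(f"need fc_down < 1 < fc_up, got ({fc_down}, {fc_up})")
    out = records.copy()
    mfc = out["mean_fc"].to_numpy(dtype=float)
    up = mfc >= fc_up
    down = mfc <= fc_down
    out["differential"] = up | down
    out["direction"] = np.where(up, DIRECTION_UP, np.where(down, DIRECTION_DOWN, DIRECTION_NONE))
    counts = DifferentialCounts(int(up.sum()), int(down.sum()), int((~(up | down)).sum()))
    return out, counts


def signal_matrix(
    signals: pd.DataFrame,
    columns: str = "group",
    value: str = "slope",
) -> pd.DataFrame:
    """Peptides x (group or array) matrix of mean included signals."""
    inc = signals
    if "status" in signals.columns:
        inc = signals[signals["status"] == STATUS_INCLUDED]
    return inc.pivot_table(index="peptide_id", columns=columns, values=value, aggfunc="mean")


def build_heatmap_matrix(
    values: pd.DataFrame,
    differential: set[str] | None = None,
    scope: str = "all",
    scale: str | None = None,
) -> pd.DataFrame:
    """Heatmap-ready matrix (peptides x columns).

    ``scope``: "all" or "differential" (restrict rows to the given
    differential peptide set).  ``scale``: None/"log2fc" (values pass
    through) or "zscore_rows" (per-row z-score with sample SD; zero-SD rows
    map to 0).  Raises :class:`EmptySelectionError` when scoping empties the
    matrix.
    """
    if scope not in ("all", "differential"):
        raise ValueError(f"unknown scope {scope!r}")
    mat = values.copy()
    if scope == "differential":
        diff = differential or set()
        mat = mat.loc[mat.index.isin(diff)]
        if mat.empty:
            raise EmptySelectionError(
                f"no differential rows to plot ({len(values)} candidates, "
                f"{len(diff)} differential ids)"
            )
    if mat.empty:
        raise EmptySelectionError("empty matrix")
    if scale == "zscore_rows":
        arr = mat.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        mat = pd.DataFrame(z, index=mat.index, columns=mat.columns)
    elif scale not in (None, "log2fc"):
        raise ValueError(f"unknown scale {scale!r}")
    return mat


def write_fold_changes(records: pd.DataFrame, path) -> None:
    """Write fold-change records; per-chip FCs joined with ';'."""
    out = records.copy()
    out["per_chip_fc"] = out["per_chip_fc"].map(
        lambda t: ";".join(f"{v:.10g}" for v in t)
    )
    out.to_csv(path, index=False, float_format="%.10g")
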