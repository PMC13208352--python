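"""Atlas-style presentation surfaces built from per-kinase score tables.

Waterfall tables (normalized kinase statistics, sorted), volcano tables
(mean substrate log2FC vs final score with hyper/hypo classification),
kinome-tree node attributes (family-grouped nodes sized by final score and
colored by the median kinase statistic, exported as data rather than
rendered), top-6+6 kinase selection per assay class, and depot-level
direction summaries across adipose depots.
"""

from __future__ import annotations

import json
import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptySelectionError

logger = logging.getLogger(__name__)

DEFAULT_LFC_CUT = math.log2(1.30)
DEFAULT_SCORE_CUT = 1.3
DEFAULT_DEAD_BAND = 0.1
DEFAULT_TOP_K = 6

CLASS_HYPER = "hyper"
CLASS_HYPO = "hypo"
CLASS_NS = "not_significant"

DIRECTION_HYPER = "hyperactive"
DIRECTION_HYPO = "hypoactive"
DIRECTION_MIXED = "mixed"


def waterfall_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Kinases sorted by activity change, statistics normalized to [-1, 1].

    Normalization divides by the maximum absolute kinase statistic (all-zero
    statistics stay 0); ordering is descending by statistic with
    lexicographic tie-break on kinase id.  Undefined statistics are dropped;
    an all-undefined table raises :class:`EmptySelectionError`.
    """
    tab = scores.dropna(subset=["kinase_statistic"]).copy()
    if tab.empty:
        raise EmptySelectionError("no kinase has a defined statistic")
    peak = tab["kinase_statistic"].abs().max()
    tab["normalized_statistic"] = (
        tab["kinase_statistic"] / peak if peak > 0 else 0.0
    )
    tab = tab.sort_values(
        ["kinase_statistic", "kinase"], ascending=[False, True]
    ).reset_index(drop=True)
    return tab[["kinase", "kinase_statistic", "normalized_statistic"]]


def volcano_table(
    scores: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    score_cut: float = DEFAULT_SCORE_CUT,
) -> pd.DataFrame:
    """Classify kinases on (mean substrate log2FC, final score).

    hyper: x >= lfc_cut and y >= score_cut; hypo: x <= -lfc_cut and
    y >= score_cut; otherwise not significant — both cutoffs are required.
    """
    if lfc_cut <= 0 or score_cut <= 0:
        raise ValueError("cutoffs must be positive")
    tab = scores.copy()
    x = tab["mean_log2fc"].to_numpy(dtype=float)
    y = tab["final_score"].to_numpy(dtype=float)
    passes = np.nan_to_num(y, nan=-np.inf) >= score_cut
    hyper = passes & (np.nan_to_num(x, nan=0.0) >= lfc_cut)
    hypo = passes & (np.nan_to_num(x, nan=0.0) <= -lfc_cut)
    tab["volcano_class"] = np.where(hyper, CLASS_HYPER, np.where(hypo, CLASS_HYPO, CLASS_NS))
    return tab


def coral_export(
    scores_by_run: Mapping[str, pd.DataFrame] | pd.DataFrame,
    family_map: Mapping[str, str],
    json_path=None,
) -> list[dict]:
    """Kinome-tree node attributes: one node per scored kinase.

    Node size carries both the mean and the median final score (downstream
    conventions differ on which to draw); node color carries the median
    kinase statistic.  When several score tables are given (e.g. one per
    technical grouping) the per-kinase mean/median are taken across them;
    a single table yields one value per kinase for all fields.  Kinases
    missing from ``family_map`` get family "other" with a log line.  Value
    ranges are reported per run, since display ranges are set per tissue.
    Optionally writes a JSON array of node objects.
    """
    if isinstance(scores_by_run, pd.DataFrame):
        frames = [scores_by_run]
    else:
        frames = list(scores_by_run.values())
    allscores = pd.concat(frames, ignore_index=True)
    allscores = allscores.dropna(subset=["final_score", "kinase_statistic"])
    nodes = []
    for kinase, grp in allscores.groupby("kinase", sort=True):
        family = family_map.get(kinase)
        if family is None:
            family = "other"
            logger.info("coral_export: kinase %s not in family map -> 'other'", kinase)
        nodes.append({
            "kinase": kinase,
            "family": family,
            "size_mean_final_score": float(grp["final_score"].mean()),
            "size_median_final_score": float(grp["final_score"].median()),
            "color_median_statistic": float(grp["kinase_statistic"].median()),
        })
    if nodes:
        sizes = [n["size_mean_final_score"] for n in nodes]
        colors = [n["color_median_statistic"] for n in nodes]
        logger.info(
            "coral_export: %d nodes, size range [%.4g, %.4g], color range [%.4g, %.4g]",
            len(nodes), min(sizes), max(sizes), min(colors), max(colors),
        )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(nodes, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return nodes


def read_coral_nodes(json_path) -> list[dict]:
    with open(json_path) as fh:
        return json.load(fh)


def select_top_kinases(
    scores: pd.DataFrame,
    k_per_class: int = DEFAULT_TOP_K,
    lfc_cut: float = DEFAULT_LFC_CUT,
    score_cut: float = DEFAULT_SCORE_CUT,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Top-k most-changed kinases per assay class by |MEOW|.

    Candidates must pass both volcano cutoffs; ties on |MEOW| break
    lexicographically by kinase id.  Returns (selection, {assay:
    short_selection flag}) where the flag marks assays with fewer than k
    passing kinases.
    """
    tab = volcano_table(scores, lfc_cut=lfc_cut, score_cut=score_cut)
    passing = tab[tab["volcano_class"] != CLASS_NS].copy()
    passing = passing.dropna(subset=["meow"])
    passing["abs_meow"] = passing["meow"].abs()
    selections, short = [], {}
    for assay, grp in passing.groupby("assay", sort=True):
        grp = grp.sort_values(["abs_meow", "kinase"], ascending=[False, True])
        top = grp.head(k_per_class)
        short[str(assay)] = len(top) < k_per_class
        selections.append(top)
    if not selections:
        return passing.drop(columns=["abs_meow"]), short
    out = pd.concat(selections, ignore_index=True).drop(columns=["abs_meow"])
    return out, short


def depot_pattern(
    scores_by_depot: Mapping[str, pd.DataFrame],
    dead_band: float = DEFAULT_DEAD_BAND,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depot x assay direction summary plus the cross-depot statistic matrix.

    Per (depot, assay): median kinase statistic; direction is hyperactive
    above +dead_band, hypoactive below −dead_band, mixed within the band
    (diverse per-kinase changes cancel toward 0).  The matrix is kinases x
    depot/assay columns of kinase statistics for atlas comparison.
    """
    profiles = []
    mats = {}
    for depot in sorted(scores_by_depot):
        scores = scores_by_depot[depot]
        for assay, grp in scores.groupby("assay", sort=True):
            med = float(grp["kinase_statistic"].median())
            if med > dead_band:
                direction = DIRECTION_HYPER
            elif med < -dead_band:
                direction = DIRECTION_HYPO
            else:
                direction = DIRECTION_MIXED
            profiles.append({
                "depot": depot,
                "assay": assay,
                "median_statistic": med,
                "direction": direction,
            })
            mats[f"{depot}:{assay}"] = grp.set_index("kinase")["kinase_statistic"]
    matrix = pd.DataFrame(mats)
    return pd.DataFrame(profiles), matrix
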