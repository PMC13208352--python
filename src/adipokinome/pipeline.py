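"""End-to-end pipeline: quantify → QC → fold change → kinase scoring → atlas.

One :class:`~adipokinome.config.PipelineConfig` drives the whole run.  The
master seed is split per stage in a fixed order, every output file carries a
header comment with the config hash and seed, and a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas, enrichment, foldchange, mapping, signal
from .config import PipelineConfig, config_hash
from .errors import StageError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _stamp(path: Path, cfg_hash: str, seed: int) -> None:
    text = path.read_text()
    path.write_text(f"# adipokinome config={cfg_hash} seed={seed}\n{text}")


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int, **kw) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, **kw)
    _stamp(path, cfg_hash, seed)


def analyze(
    readings: pd.DataFrame,
    kmap: mapping.KinaseSubstrateMap,
    config: PipelineConfig | None = None,
    case_group: str | None = None,
    control_group: str | None = None,
) -> dict:
    """In-memory run of quantify → fold change → kinase scoring.

    Returns {"signals", "records", "counts", "scores"}; the file-writing
    twin is :func:`run_pipeline`.
    """
    cfg = config or PipelineConfig()
    case_group = case_group or cfg.case_group
    control_group = control_group or cfg.control_group
    signals = signal.quantify(
        readings,
        r2_min=cfg.r2_min,
        detect_min=cfg.detect_min,
        saturation_ceiling=cfg.saturation_ceiling,
    )
    records, _omitted = foldchange.fold_change(
        signals[signals["group"] == case_group],
        signals[signals["group"] == control_group],
        floor=cfg.floor,
    )
    records, counts = foldchange.classify_differential(
        records, fc_up=cfg.fc_up, fc_down=cfg.fc_down
    )
    scores = enrichment.score_kinases(
        records, kmap,
        n_iterations=cfg.n_iterations,
        seed=cfg.seed,
        rank_max=cfg.rank_max,
        min_substrates=cfg.min_substrates,
    )
    return {"signals": signals, "records": records, "counts": counts, "scores": scores}


def rank_kinases(scores: pd.DataFrame, by: str = "z") -> list[str]:
    """Kinase ids ranked descending by ``z`` or by ``|meow|``; NaN last."""
    if by == "z":
        key = scores["z"]
    elif by == "meow":
        key = scores["meow"].abs()
    else:
        raise ValueError(f"unknown ranking {by!r}")
    tab = scores.assign(_key=key.fillna(-np.inf)).sort_values(
        ["_key", "kinase"], ascending=[False, True]
    )
    return tab["kinase"].tolist()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Stage order (and seed split order): quantification, fold change, kinase
    scoring, atlas exports.  Failures abort with a stage-named
    :class:`~adipokinome.errors.StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = config.seed
    stage_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(4) >> 1]

    try:
        readings = signal.read_cycle_readings(config.signals)
        signals = signal.quantify(
            readings,
            r2_min=config.r2_min,
            detect_min=config.detect_min,
            saturation_ceiling=config.saturation_ceiling,
        )
        _write(signals, out / "peptide_signals.csv", chash, seed)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise StageError("quantify", str(e)) from e

    try:
        case = signals[signals["group"] == config.case_group]
        control = signals[signals["group"] == config.control_group]
        records, omitted = foldchange.fold_change(case, control, floor=config.floor)
        records, counts = foldchange.classify_differential(
            records, fc_up=config.fc_up, fc_down=config.fc_down
        )
        foldchange.write_fold_changes(records, out / "fold_changes.csv")
        _stamp(out / "fold_changes.csv", chash, seed)
        if len(omitted):
            _write(omitted, out / "omitted_peptides.csv", chash, seed)
    except Exception as e:
        raise StageError("foldchange", str(e)) from e

    try:
        kmap = mapping.read_map(config.map_file, min_substrates=0)
        assays = sorted(signals["assay"].unique())
        scored = []
        for assay in assays:
            peps = set(signals.loc[signals["assay"] == assay, "peptide_id"])
            recs = records[records["peptide_id"].isin(peps)]
            if recs.empty:
                continue
            scored.append(enrichment.score_kinases(
                recs, kmap,
                n_iterations=config.n_iterations,
                seed=stage_seeds[2],
                rank_max=config.rank_max,
                min_substrates=config.min_substrates,
                assay=assay,
            ))
        scores = pd.concat(scored, ignore_index=True)
        _write(scores, out / "kinase_scores.csv", chash, seed)
    except Exception as e:
        raise StageError("kinases", str(e)) from e

    try:
        wf = atlas.waterfall_table(scores)
        _write(wf, out / "waterfall.csv", chash, seed)
        volc = atlas.volcano_table(
            scores, lfc_cut=config.lfc_cut, score_cut=config.score_cut
        )
        _write(volc, out / "volcano.csv", chash, seed)
        top, short = atlas.select_top_kinases(
            scores, k_per_class=config.top_k,
            lfc_cut=config.lfc_cut, score_cut=config.score_cut,
        )
        _write(top, out / "top_kinases.csv", chash, seed)
        family_map = {}
        if config.family_file:
            fam = pd.read_csv(config.family_file, sep=None, engine="python")
            family_map = dict(zip(fam["kinase"], fam["family"]))
        atlas.coral_export(scores, family_map, json_path=out / "tree_nodes.json")
        run_info = {
            "config_hash": chash,
            "seed": seed,
            "n_peptides_quantified": int(signals["peptide_id"].nunique()),
            "n_included": int((signals["status"] == signal.STATUS_INCLUDED).sum()),
            "n_fold_changes": int(len(records)),
            "n_up": counts.n_up,
            "n_down": counts.n_down,
            "n_kinases_scored": int(scores["kinase"].nunique()),
            "short_selection": short,
        }
        (out / "run_info.json").write_text(json.dumps(run_info, indent=1, sort_keys=True) + "\n")
    except Exception as e:
        raise StageError("atlas", str(e)) from e

    logger.info("pipeline complete: %s (config %s)", out, chash)
    return out
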