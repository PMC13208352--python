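"""Upstream kinase inference from differential peptides.

Given the set of differential peptides and a confidence-ranked
kinase–substrate map, each kinase is scored by comparing its observed
"hits" (mapped substrates that are differential) against a random-sampling
null: 2,000 draws of differential-set-sized peptide subsets taken uniformly
without replacement from the chip universe.  From the empirical null we
derive

* ``z``               — (observed − null mean) / null SD,
* ``delta_confidence`` — observed / null mean (undefined when the null mean
  is 0; flagged low-coverage when the null mean is tiny),
* ``specificity_score`` — −log10 of the empirical one-sided tail
  probability of the observed hits under the null, with a +1/(N+1)
  continuity correction,
* ``significance_score`` — −log10 of a sign-permutation p-value of the
  median substrate log2 fold change (2,000 sign flips),
* ``final_score``      — the mean of the two scores above (a transparent
  surrogate for the proprietary instrument-vendor scoring, with the same
  "final score = significance" semantics),
* ``kinase_statistic`` — median log2 fold change over ALL rank-filtered
  mapped substrates (sign encodes hyper/hypo activity),
* ``meow``             — mean log2 fold change over the kinase's
  DIFFERENTIAL substrates multiplied by delta_confidence (the
  winner-ranking score; per-substrate terms are kept for plotting).

Because the draws are uniform without replacement, the null hit count for a
kinase with ``m`` mapped substrates in a universe of ``P`` peptides with
``D`` differential is hypergeometric, with mean ``D*m/P``; the sampled
moments converge to that closed form and tests exploit it as an oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SizingError
from .mapping import KinaseSubstrateMap

DEFAULT_N_ITERATIONS = 2000
DEFAULT_RANK_MAX = 4
DEFAULT_MIN_SUBSTRATES = 3
LOW_COVERAGE_NULL_MEAN = 0.25


@dataclass(frozen=True)
class NullDistribution:
    """Per-kinase empirical null of hit counts under random peptide draws."""

    kinases: tuple[str, ...]
    m: np.ndarray            # mapped substrates on chip per kinase
    hits: np.ndarray         # (n_iterations, n_kinases) null hit counts
    n_differential: int
    seed: int | None

    @property
    def mean(self) -> np.ndarray:
        return self.hits.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.hits.std(axis=0, ddof=1)


def observed_hits(differential, kmap: KinaseSubstrateMap, kinase: str) -> int:
    """Number of the kinase's mapped substrates that are differential."""
    if kinase not in kmap.entries:
        raise KeyError(f"unknown kinase {kinase!r}")
    return len(set(kmap.substrates(kinase)) & set(differential))


def _membership_matrix(kmap: KinaseSubstrateMap) -> tuple[list[str], list[str], np.ndarray]:
    kinases = sorted(kmap.entries)
    universe = sorted(kmap.universe)
    idx = {p: i for i, p in enumerate(universe)}
    mem = np.zeros((len(kinases), len(universe)), dtype=bool)
    for ki, kinase in enumerate(kinases):
        for pep in kmap.substrates(kinase):
            if pep in idx:
                mem[ki, idx[pep]] = True
    return kinases, universe, mem


def sample_null(
    kmap: KinaseSubstrateMap,
    n_differential: int,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int | None = None,
) -> NullDistribution:
    """Random-sampling null: draw ``n_differential`` peptides per iteration.

    Uniform draws without replacement from the map universe; hits counted
    per kinase per iteration.  Deterministic under ``seed``.
    """
    kinases, universe, mem = _membership_matrix(kmap)
    P = len(universe)
    if n_differential > P:
        raise SizingError(f"n_differential={n_differential} > universe size {P}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed) if seed is not None else None)
    # rank the peptides per iteration; the first n_differential form the draw
    order = rng.random((n_iterations, P)).argsort(axis=1)
    drawn = np.zeros((n_iterations, P), dtype=bool)
    rows = np.arange(n_iterations)[:, None]
    drawn[rows, order[:, :n_differential]] = True
    hits = drawn.astype(np.int64) @ mem.T.astype(np.int64)  # (iters, kinases)
    return NullDistribution(
        kinases=tuple(kinases),
        m=mem.sum(axis=1),
        hits=hits,
        n_differential=n_differential,
        seed=seed,
    )


def enumerate_null(
    kmap: KinaseSubstrateMap, n_differential: int, max_universe: int = 16
) -> pd.DataFrame:
    """Exact null by enumerating all C(P, D) draws (small universes only).

    Returns per-kinase exact mean and SD of the hit count; used as an exact
    oracle against :func:`sample_null` for universes of at most
    ``max_universe`` peptides.
    """
    kinases, universe, mem = _membership_matrix(kmap)
    P = len(universe)
    if P > max_universe:
        raise SizingError(f"enumeration limited to universes <= {max_universe}")
    if n_differential > P:
        raise SizingError(f"n_differential={n_differential} > universe size {P}")
    combos = list(itertools.combinations(range(P), n_differential))
    hits = np.zeros((len(combos), len(kinases)), dtype=np.int64)
    for i, combo in enumerate(combos):
        hits[i] = mem[:, list(combo)].sum(axis=1)
    # all outcomes enumerated equally: population moments are exact
    return pd.DataFrame({
        "kinase": kinases,
        "m": mem.sum(axis=1),
        "null_mean": hits.mean(axis=0),
        "null_sd": hits.std(axis=0, ddof=0),
    })


def krsa_zscore(observed: float, null_mean: float, null_sd: float) -> tuple[float, float]:
    """(z, delta_confidence); NaN flags where the null is degenerate."""
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    delta = observed / null_mean if null_mean > 0 else float("nan")
    return z, delta


def kinase_statistic(
    log2fcs: np.ndarray, min_substrates: int = DEFAULT_MIN_SUBSTRATES
) -> float:
    """Median log2FC over all mapped substrates; NaN if coverage too thin."""
    vals = np.asarray(log2fcs, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_substrates:
        return float("nan")
    return float(np.median(vals))


def specificity_score(observed: int, null_hits: np.ndarray) -> float:
    """−log10 empirical upper-tail probability of the observed hit count.

    p = (#{null >= observed} + 1) / (N + 1); the continuity term keeps the
    score finite, capping it at log10(N + 1) when the observation exceeds
    every sampled value.
    """
    n = len(null_hits)
    p = (int((null_hits >= observed).sum()) + 1) / (n + 1)
    return -math.log10(p)


def significance_score(
    log2fcs: np.ndarray,
    n_permutations: int = DEFAULT_N_ITERATIONS,
    rng: np.random.Generator | None = None,
) -> float:
    """−log10 sign-permutation p-value of the substrate log2FC median.

    Random sign flips of the substrate log2FCs give a null for the absolute
    median; p uses the same +1/(N+1) continuity as the specificity score.
    """
    vals = np.asarray(log2fcs, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    if rng is None:
        rng = np.random.default_rng()
    obs = abs(float(np.median(vals)))
    signs = rng.integers(0, 2, size=(n_permutations, len(vals))) * 2 - 1
    null = np.abs(np.median(signs * vals[None, :], axis=1))
    p = (int((null >= obs).sum()) + 1) / (n_permutations + 1)
    return -math.log10(p)


def meow_score(
    differential_log2fcs: np.ndarray, delta_confidence: float
) -> tuple[float, np.ndarray]:
    """MEOW score and the per-substrate plot terms.

    The scalar score is the mean log2FC over the kinase's differential
    substrates times delta_confidence; the per-substrate terms
    (log2FC × delta_confidence) are the points of a MEOW plot, whose summary
    line is their mean.  NaN when the kinase has no differential substrate
    or delta_confidence is undefined.
    """
    vals = np.asarray(differential_log2fcs, dtype=float)
    vals = vals[~np.isnan(vals)]
    terms = vals * delta_confidence
    if len(vals) == 0 or math.isnan(delta_confidence):
        return float("nan"), terms
    return float(np.mean(vals)) * delta_confidence, terms


def score_kinases(
    records: pd.DataFrame,
    kmap: KinaseSubstrateMap,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int | None = 0,
    rank_max: int = DEFAULT_RANK_MAX,
    min_substrates: int = DEFAULT_MIN_SUBSTRATES,
    assay: str | None = None,
) -> pd.DataFrame:
    """Full per-kinase scoring table from classified fold-change records.

    ``records`` must carry peptide_id, log2_fc and differential columns (see
    :func:`adipokinome.foldchange.classify_differential`).  The map is
    restricted to the peptides with defined fold changes, filtered to
    ``rank <= rank_max``, and kinases with fewer than ``min_substrates``
    mapped substrates are dropped.  All resampling derives from ``seed``
    with a documented draw order (null sampling first, then per-kinase sign
    permutations in sorted kinase order).
    """
    if records.empty:
        raise InputError("no fold-change records to score")
    universe = set(records["peptide_id"])
    kmap = kmap.restrict(universe).filter(rank_max=rank_max, min_substrates=min_substrates)
    if not kmap.entries:
        raise InputError("no kinase retains enough mapped substrates on this chip")
    log2fc = records.set_index("peptide_id")["log2_fc"]
    differential = set(records.loc[records["differential"], "peptide_id"])
    D = len(differential)

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    null_seed = int(ss.generate_state(1)[0] >> 1)
    null = sample_null(kmap, D, n_iterations=n_iterations, seed=null_seed)
    perm_rngs = {
        k: np.random.default_rng(s)
        for k, s in zip(null.kinases, ss.spawn(len(null.kinases)))
    }

    rows = []
    for ki, kinase in enumerate(null.kinases):
        subs = kmap.substrates(kinase)
        sub_fcs = log2fc.reindex(subs).to_numpy(dtype=float)
        obs = len(set(subs) & differential)
        nm, nsd = float(null.mean[ki]), float(null.sd[ki])
        z, delta = krsa_zscore(obs, nm, nsd)
        stat = kinase_statistic(sub_fcs, min_substrates=min_substrates)
        spec = specificity_score(obs, null.hits[:, ki])
        sig = significance_score(
            sub_fcs, n_permutations=n_iterations, rng=perm_rngs[kinase]
        )
        final = (spec + sig) / 2.0 if not math.isnan(sig) else float("nan")
        diff_fcs = log2fc.reindex(sorted(set(subs) & differential)).to_numpy(dtype=float)
        meow, _terms = meow_score(diff_fcs, delta)
        rows.append({
            "kinase": kinase,
            "assay": assay if assay is not None else "",
            "m": int(null.m[ki]),
            "observed_hits": obs,
            "null_mean": nm,
            "null_sd": nsd,
            "z": z,
            "delta_confidence": delta,
            "low_coverage": bool(nm < LOW_COVERAGE_NULL_MEAN),
            "kinase_statistic": stat,
            "mean_log2fc": float(np.nanmean(sub_fcs)) if np.isfinite(sub_fcs).any() else float("nan"),
            "n_differential_substrates": int(len(diff_fcs)),
            "mean_diff_log2fc": float(np.mean(diff_fcs)) if len(diff_fcs) else float("nan"),
            "specificity_score": spec,
            "significance_score": sig,
            "final_score": final,
            "meow": meow,
            "n_iterations": n_iterations,
            "seed": null_seed,
        })
    return pd.DataFrame(rows)


def meow_plot_terms(
    records: pd.DataFrame,
    kmap: KinaseSubstrateMap,
    scores: pd.DataFrame,
    kinase: str,
    rank_max: int = DEFAULT_RANK_MAX,
) -> pd.DataFrame:
    """Per-substrate MEOW points (log2FC × Δ-confidence) for one kinase.

    The overall mean of the terms is the plot's summary line.
    """
    row = scores.loc[scores["kinase"] == kinase]
    if row.empty:
        raise KeyError(f"kinase {kinase!r} not in score table")
    delta = float(row["delta_confidence"].iloc[0])
    diff = set(records.loc[records["differential"], "peptide_id"])
    subs = [p for p in kmap.substrates(kinase, rank_max=rank_max) if p in diff]
    log2fc = records.set_index("peptide_id")["log2_fc"].reindex(subs)
    return pd.DataFrame({
        "kinase": kinase,
        "peptide_id": subs,
        "log2_fc": log2fc.to_numpy(dtype=float),
        "term": log2fc.to_numpy(dtype=float) * delta,
    })
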