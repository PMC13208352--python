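"""Synthetic PamChip-like two-group kinome experiments with planted truth.

The generator emulates the acquisition structure of a PamStation run: peptide
intensities recorded every 5 min over 60 min at camera exposures of 10, 20,
50 and 100 ms, on technical-triplicate chips, for a control and a treatment
group.  Ground truth is planted as per-kinase activity multipliers
(treatment rate / control rate) propagated to the peptides each kinase maps,
so every downstream stage of the pipeline can be checked against known
answers.

Model
-----
Each peptide ``p`` has a control phosphorylation rate ``b_p`` (intensity
units per minute at the 100 ms reference exposure).  Its treatment rate is

    b_p * prod_k m_k ** w(rank_kp)        over kinases k mapping p,

where ``m_k`` is the planted multiplier of kinase ``k`` and
``w(rank) = 1 - rank/13`` down-weights low-confidence mappings (rank 0 has
near-full influence, rank 12 minimal).  The exponent-weighted product keeps
rates positive, is symmetric in kinases, reduces to ``m**w`` for a single
mapping kinase (exactly ``m`` at ``w = 1``), and — unlike a normalized
geometric mean — does not dilute one kinase's effect by the number of
unrelated kinases co-mapping the peptide.

The expected intensity at cycle time ``t`` and exposure ``e`` is
``rate * t * e/100`` (linear kinetics; an exponential-approach mode
``V(1 - exp(-kt))`` with matched initial slope is available to stress-test
the nonlinearity filter), multiplied by lognormal noise with coefficient of
variation ``noise_cv`` and clipped at the detector ceiling (default 65535,
the 16-bit CCD full-well convention).

Each (chip, group) pair gets its own RNG stream split from the master seed,
so adding chips never perturbs earlier chips' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SizingError, ValidationError
from .mapping import KinaseSubstrateMap

DEFAULT_TIMES_MIN = tuple(float(t) for t in range(0, 65, 5))
DEFAULT_EXPOSURES_MS = (10.0, 20.0, 50.0, 100.0)
REFERENCE_EXPOSURE_MS = 100.0
DEFAULT_SATURATION = 65535.0

READING_COLUMNS = (
    "chip_id", "array_id", "group", "assay",
    "cycle_index", "time_min", "exposure_ms", "peptide_id", "intensity",
)


def confidence_weight(rank) -> np.ndarray:
    """Influence weight of a mapping entry: 1 - rank/13 (rank 0..12)."""
    return 1.0 - np.asarray(rank, dtype=float) / 13.0


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated experiment.

    Parameters
    ----------
    kinase_multipliers : kinase id -> treatment/control activity ratio (> 0).
    baseline_rates : peptide id -> control phosphorylation rate in intensity
        units/min at the 100 ms reference exposure (> 0).
    noise_cv : coefficient of variation of the multiplicative lognormal
        reading noise (0 disables noise).
    saturation_ceiling : detector cap applied to every reading.
    seed : master seed recorded with the truth.
    """

    kinase_multipliers: Mapping[str, float]
    baseline_rates: Mapping[str, float]
    noise_cv: float = 0.1
    saturation_ceiling: float = DEFAULT_SATURATION
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.kinase_multipliers.values()):
            raise ValidationError("kinase multipliers must be strictly positive")
        if any(b <= 0 for b in self.baseline_rates.values()):
            raise ValidationError("baseline rates must be strictly positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.saturation_ceiling <= 0:
            raise ValidationError("saturation_ceiling must be positive")


@dataclass(frozen=True)
class AcquisitionDesign:
    """Cycle times, exposures, replication and kinetic mode of a run."""

    times_min: Sequence[float] = DEFAULT_TIMES_MIN
    exposures_ms: Sequence[float] = DEFAULT_EXPOSURES_MS
    chips_per_group: int = 3
    groups: tuple[str, str] = ("control", "treatment")
    assay: str = "STK"
    kinetics: str = "linear"          # "linear" | "exponential"
    approach_rate_per_min: float = 0.05   # k of V(1-exp(-kt)); exponential mode

    def __post_init__(self):
        if self.kinetics not in ("linear", "exponential"):
            raise ValidationError(f"unknown kinetics mode {self.kinetics!r}")
        if self.chips_per_group < 1:
            raise ValidationError("chips_per_group must be >= 1")


@dataclass(frozen=True)
class SyntheticExperiment:
    """Readings plus the truth and mapping that generated them."""

    readings: pd.DataFrame
    truth: PlantedTruth
    map: KinaseSubstrateMap


def default_rank_distribution(decay: float = 0.7) -> np.ndarray:
    """Rank weights proportional to ``decay**rank``.

    Curated kinase–substrate files are dominated by experimentally supported
    (low-rank) entries; a geometric decay reproduces that shape.
    """
    w = decay ** np.arange(13, dtype=float)
    return w / w.sum()


def generate_map(
    n_kinases: int,
    n_peptides: int,
    substrates_per_kinase: tuple[int, int] = (5, 20),
    rank_distribution: Sequence[float] | None = None,
    seed: int = 0,
) -> KinaseSubstrateMap:
    """Generate a random kinase–substrate map over a synthetic peptide universe.

    Each kinase draws a substrate count uniformly from
    ``substrates_per_kinase`` (inclusive) and substrates without replacement
    from the universe; each pair gets a confidence rank 0..12 drawn from
    ``rank_distribution`` (default: geometric decay favoring low ranks).
    Deterministic under ``seed``.
    """
    lo, hi = int(substrates_per_kinase[0]), int(substrates_per_kinase[1])
    if lo < 1 or hi < lo:
        raise SizingError(f"bad substrates_per_kinase range ({lo}, {hi})")
    if n_peptides < hi:
        raise SizingError(
            f"n_peptides={n_peptides} < max substrates per kinase {hi}"
        )
    if rank_distribution is None:
        p_rank = default_rank_distribution()
    else:
        p_rank = np.asarray(rank_distribution, dtype=float)
        if len(p_rank) != 13 or (p_rank < 0).any() or p_rank.sum() <= 0:
            raise ValidationError(
                "rank_distribution must be 13 nonnegative weights, not all zero"
            )
        p_rank = p_rank / p_rank.sum()

    peptides = [f"pep{i:03d}" for i in range(1, n_peptides + 1)]
    kinases = [f"KIN{i:02d}" for i in range(1, n_kinases + 1)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    entries = {}
    for kinase in kinases:
        n_sub = int(rng.integers(lo, hi + 1))
        subs = rng.choice(n_peptides, size=n_sub, replace=False)
        ranks = rng.choice(13, size=n_sub, p=p_rank)
        entries[kinase] = tuple(
            (peptides[i], int(r)) for i, r in sorted(zip(subs, ranks))
        )
    return KinaseSubstrateMap(entries, frozenset(peptides))


def default_baseline_rates(
    peptides: Sequence[str],
    low: float = 5.0,
    high: float = 200.0,
    seed: int = 0,
) -> dict[str, float]:
    """Draw per-peptide control rates log-uniformly in [low, high] units/min."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peptides = sorted(peptides)
    rates = np.exp(rng.uniform(math.log(low), math.log(high), size=len(peptides)))
    return dict(zip(peptides, rates.tolist()))


def peptide_effects(truth: PlantedTruth, kmap: KinaseSubstrateMap) -> dict[str, float]:
    """Treatment/control rate ratio per peptide: prod_k m_k**w(rank)."""
    log_effect: dict[str, float] = {p: 0.0 for p in truth.baseline_rates}
    for kinase, subs in kmap.entries.items():
        m = truth.kinase_multipliers.get(kinase, 1.0)
        if m == 1.0:
            continue
        for pep, rank in subs:
            if pep in log_effect:
                log_effect[pep] += float(confidence_weight(rank)) * math.log(m)
    return {p: math.exp(v) for p, v in log_effect.items()}


def _kinetic_profile(rates: np.ndarray, times: np.ndarray, design: AcquisitionDesign) -> np.ndarray:
    """Noise-free signal (peptides x times) at the reference exposure."""
    if design.kinetics == "linear":
        return rates[:, None] * times[None, :]
    # exponential approach with matched initial slope: V = rate/k
    k = design.approach_rate_per_min
    return (rates[:, None] / k) * (1.0 - np.exp(-k * times[None, :]))


def simulate_experiment(
    truth: PlantedTruth,
    kmap: KinaseSubstrateMap,
    design: AcquisitionDesign | None = None,
    seed: int | None = None,
) -> SyntheticExperiment:
    """Simulate one two-group experiment; deterministic under ``seed``.

    Each reading's expected intensity is ``rate * t * e/100`` (linear mode),
    multiplied by mean-1 lognormal noise with CV ``truth.noise_cv`` and
    clipped at ``truth.saturation_ceiling``.  One RNG stream per
    (chip, group), split from the master seed.
    """
    if design is None:
        design = AcquisitionDesign()
    if seed is None:
        seed = truth.seed
    if not truth.baseline_rates:
        raise InputError("empty peptide set: no baseline rates")
    if not kmap.universe:
        raise InputError("empty map universe")

    peptides = sorted(truth.baseline_rates)
    base = np.array([truth.baseline_rates[p] for p in peptides])
    effects = peptide_effects(truth, kmap)
    eff = np.array([effects[p] for p in peptides])
    times = np.asarray(design.times_min, dtype=float)
    exposures = np.asarray(design.exposures_ms, dtype=float)
    n_p, n_t, n_e = len(peptides), len(times), len(exposures)

    cv = truth.noise_cv
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0

    frames = []
    for ci in range(design.chips_per_group):
        chip = f"chip{ci + 1}"
        for gi, group in enumerate(design.groups):
            rates = base * (eff if gi == 1 else 1.0)
            expected = (
                _kinetic_profile(rates, times, design)[:, :, None]
                * (exposures / REFERENCE_EXPOSURE_MS)[None, None, :]
            )
            if sigma > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(ci, gi))
                )
                noise = np.exp(
                    rng.normal(-sigma * sigma / 2.0, sigma, size=expected.shape)
                )
                expected = expected * noise
            intensity = np.minimum(expected, truth.saturation_ceiling)
            frames.append(pd.DataFrame({
                "chip_id": chip,
                "array_id": f"{chip}_{group}",
                "group": group,
                "assay": design.assay,
                "cycle_index": np.repeat(np.arange(1, n_t + 1), n_e)[None, :]
                    .repeat(n_p, axis=0).ravel(),
                "time_min": np.repeat(times, n_e)[None, :].repeat(n_p, axis=0).ravel(),
                "exposure_ms": np.tile(exposures, n_t)[None, :].repeat(n_p, axis=0).ravel(),
                "peptide_id": np.repeat(peptides, n_t * n_e),
                "intensity": intensity.reshape(n_p, -1).ravel(),
            }))
    readings = pd.concat(frames, ignore_index=True)[list(READING_COLUMNS)]
    return SyntheticExperiment(readings=readings, truth=truth, map=kmap)


def write_readings(readings: pd.DataFrame, path) -> None:
    """Write the long-format signal table the quantification stage reads."""
    readings.to_csv(path, index=False, float_format="%.10g")


def write_truth(truth: PlantedTruth, path) -> None:
    """Write the (kinase, multiplier) sidecar used by recovery tests."""
    pd.DataFrame(
        sorted(truth.kinase_multipliers.items()),
        columns=["kinase", "multiplier"],
    ).to_csv(path, index=False, float_format="%.10g")


def planted_experiment(
    seed: int,
    n_kinases: int = 50,
    n_peptides: int = 144,
    n_planted: int = 5,
    multiplier: float = 2.0,
    noise_cv: float = 0.1,
    chips_per_group: int = 3,
    rank_max: int = 4,
    min_mapped: int = 5,
    design: AcquisitionDesign | None = None,
) -> tuple[SyntheticExperiment, tuple[str, ...]]:
    """Build a recovery experiment with ``n_planted`` kinases at ``multiplier``.

    Planted kinases are drawn (seeded) from those retaining at least
    ``min_mapped`` substrates after the default ``rank <= rank_max`` filter:
    a kinase without high-confidence mapped substrates on the chip is
    undetectable by construction, so planting activity on it would test
    mapping coverage, not the inference.  Returns the experiment and the
    planted kinase ids.
    """
    ss = np.random.SeedSequence(seed)
    map_seed, rate_seed, pick_seed, sim_seed = (
        int(s) for s in ss.generate_state(4) >> 1
    )
    kmap = generate_map(n_kinases, n_peptides, seed=map_seed)
    filtered = kmap.filter(rank_max=rank_max, min_substrates=min_mapped)
    eligible = sorted(filtered.entries)
    if len(eligible) < n_planted:
        raise SizingError(
            f"only {len(eligible)} kinases have >= {min_mapped} rank<={rank_max} "
            f"substrates; cannot plant {n_planted}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(pick_seed))
    planted = tuple(sorted(rng.choice(eligible, size=n_planted, replace=False)))
    multipliers = {k: 1.0 for k in kmap.entries}
    multipliers.update({k: multiplier for k in planted})
    truth = PlantedTruth(
        kinase_multipliers=multipliers,
        baseline_rates=default_baseline_rates(sorted(kmap.universe), seed=rate_seed),
        noise_cv=noise_cv,
        seed=sim_seed,
    )
    if design is None:
        design = AcquisitionDesign(chips_per_group=chips_per_group)
    else:
        design = replace(design, chips_per_group=chips_per_group)
    exp = simulate_experiment(truth, kmap, design, seed=sim_seed)
    return exp, planted
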