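"""Kinase–substrate mapping with 0–12 confidence ranks.

Upstream kinase inference relies on a mapping file linking each kinase to the
array peptides it can phosphorylate.  Each (kinase, peptide) pair carries an
integer confidence rank from 0 (high confidence, experimental evidence) to 12
(low confidence, purely predicted).  Analyses normally restrict the mapping to
high-confidence entries (``rank <= rank_max``) and to the peptide universe
actually present on the chip, and drop kinases left with too few substrates to
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

RANK_MIN = 0
RANK_MAX = 12

MAP_COLUMNS = ("kinase", "peptide_id", "rank")


@dataclass(frozen=True)
class KinaseSubstrateMap:
    """Mapping kinase -> [(peptide_id, rank)], plus the chip peptide universe.

    ``universe`` is the set of peptide ids present on the chip; substrate
    lists may reference peptides outside it until :meth:`restrict` is applied.
    """

    entries: Mapping[str, tuple[tuple[str, int], ...]]
    universe: frozenset[str]

    def __post_init__(self):
        for kinase, subs in self.entries.items():
            for pep, rank in subs:
                if not (RANK_MIN <= int(rank) <= RANK_MAX):
                    raise ValidationError(
                        f"rank {rank} for ({kinase}, {pep}) outside "
                        f"{RANK_MIN}..{RANK_MAX}"
                    )

    @property
    def kinases(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def substrates(self, kinase: str, rank_max: int | None = None) -> tuple[str, ...]:
        subs = self.entries[kinase]
        if rank_max is not None:
            subs = tuple(s for s in subs if s[1] <= rank_max)
        return tuple(p for p, _ in subs)

    def restrict(self, universe: Iterable[str]) -> "KinaseSubstrateMap":
        """Drop substrate entries not in ``universe``; reset the universe."""
        uni = frozenset(universe)
        entries = {
            k: tuple((p, r) for p, r in subs if p in uni)
            for k, subs in self.entries.items()
        }
        return KinaseSubstrateMap(entries, uni)

    def filter(
        self, rank_max: int = 4, min_substrates: int = 3
    ) -> "KinaseSubstrateMap":
        """Keep entries with ``rank <= rank_max``; drop under-covered kinases."""
        if not (RANK_MIN <= rank_max <= RANK_MAX):
            raise ValidationError(f"rank_max {rank_max} outside {RANK_MIN}..{RANK_MAX}")
        entries = {}
        for kinase, subs in self.entries.items():
            kept = tuple((p, r) for p, r in subs if r <= rank_max)
            if len(kept) >= min_substrates:
                entries[kinase] = kept
            else:
                logger.info(
                    "dropping kinase %s: %d substrates at rank<=%d "
                    "(min_substrates=%d)",
                    kinase, len(kept), rank_max, min_substrates,
                )
        return KinaseSubstrateMap(entries, self.universe)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, p, r)
            for k in sorted(self.entries)
            for p, r in self.entries[k]
        ]
        return pd.DataFrame(rows, columns=list(MAP_COLUMNS))


def read_map(
    path,
    rank_max: int = RANK_MAX,
    universe: Iterable[str] | None = None,
    min_substrates: int = 3,
) -> KinaseSubstrateMap:
    """Read a delimited (kinase, peptide_id, rank) file.

    Entries are restricted to ``rank <= rank_max`` and, when given, to the
    chip ``universe``; kinases left with fewer than ``min_substrates``
    substrates are dropped with a logged reason.  Ranks outside 0..12 raise
    :class:`~adipokinome.errors.ValidationError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"map file {path} missing column(s): {missing}")
    bad = df[(df["rank"] < RANK_MIN) | (df["rank"] > RANK_MAX)]
    if len(bad):
        raise ValidationError(
            f"map file {path}: rank(s) outside 0..12 at row(s) "
            f"{list(bad.index[:5])} (values {sorted(bad['rank'].unique())})"
        )
    entries: dict[str, list[tuple[str, int]]] = {}
    for kinase, sub in df.groupby("kinase", sort=True):
        entries[str(kinase)] = [
            (str(p), int(r)) for p, r in zip(sub["peptide_id"], sub["rank"])
        ]
    uni = frozenset(universe) if universe is not None else frozenset(
        df["peptide_id"].astype(str)
    )
    kmap = KinaseSubstrateMap(
        {k: tuple(v) for k, v in entries.items()}, uni
    )
    if universe is not None:
        kmap = kmap.restrict(uni)
    kmap = kmap.filter(rank_max=rank_max, min_substrates=min_substrates)
    return kmap


def write_map(kmap: KinaseSubstrateMap, path) -> None:
    """Write the mapping as a comma-delimited (kinase, peptide_id, rank) file."""
    kmap.to_frame().to_csv(path, index=False)
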