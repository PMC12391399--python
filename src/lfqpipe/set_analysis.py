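"""Set overlap of differentially expressed proteins across isolates.

Given per-isolate up/down accession sets, compute every Venn region
(exclusive, pairwise-shared, triple-shared): the 2^k − 1 non-empty
subsets of k named sets partition the union, each accession landing in
exactly one region per direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["VennRegions", "DESetCollection", "venn_regions", "extract_sets",
           "write_region_report"]


@dataclass(frozen=True)
class VennRegions:
    """Exhaustive partition of named sets into exclusive regions.

    ``regions`` maps a frozenset of labels L to the members belonging to
    every set in L and no other — e.g. ``{"A"}`` is A-exclusive,
    ``{"A","B","C"}`` the triple overlap.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, frozenset]

    def count(self, *labels: str) -> int:
        return len(self.regions[frozenset(labels)])

    def members(self, *labels: str) -> frozenset:
        return self.regions[frozenset(labels)]

    @property
    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
            members = sorted(self.regions[r])
            rows.append({
                "region": "&".join(sorted(r)),
                "count": len(members),
                "accessions": ";".join(members),
            })
        return pd.DataFrame(rows, columns=["region", "count", "accessions"])


def venn_regions(sets: Mapping[str, Iterable] | Iterable[tuple[str, Iterable]]) -> VennRegions:
    """Partition 1–3 named sets into their exclusive Venn regions."""
    if not isinstance(sets, Mapping):
        pairs = list(sets)
        labels = [lbl for lbl, _ in pairs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate set labels")
        sets = dict(pairs)
    if any(not lbl for lbl in sets):
        raise ValueError("set labels must be non-empty strings")
    if not 1 <= len(sets) <= 3:
        raise ValueError(f"need 1-3 named sets, got {len(sets)}")
    named = {lbl: frozenset(v) for lbl, v in sets.items()}
    labels = tuple(named)
    regions: dict[frozenset, frozenset] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = frozenset.intersection(*(named[l] for l in combo))
            outside = frozenset().union(*(named[l] for l in labels if l not in combo))
            regions[frozenset(combo)] = inside - outside
    return VennRegions(labels=labels, regions=regions)


@dataclass(frozen=True)
class DESetCollection:
    """Per-isolate up/down accession sets with their Venn partitions."""

    up_sets: dict[str, frozenset]
    down_sets: dict[str, frozenset]
    up_regions: VennRegions
    down_regions: VennRegions
    thresholds: dict


def extract_sets(de_tables: Mapping[str, pd.DataFrame]) -> DESetCollection:
    """Build up/down sets from per-isolate DE tables and partition them.

    All tables must have been produced under identical thresholds
    (checked via the table attrs); mixing thresholds would make the
    Venn incoherent.
    """
    if not de_tables:
        raise ValueError("no DE tables supplied")
    thresholds = None
    for iso, t in de_tables.items():
        th = t.attrs.get("thresholds")
        if th is None:
            raise ValueError(f"DE table for {iso!r} carries no thresholds")
        if thresholds is None:
            thresholds = th
        elif th != thresholds:
            raise ValueError(
                f"threshold mismatch: {iso!r} used {th}, others used {thresholds}"
            )
    up = {iso: frozenset(t.loc[t["volcano_class"] == "up", "accession"])
          for iso, t in de_tables.items()}
    down = {iso: frozenset(t.loc[t["volcano_class"] == "down", "accession"])
            for iso, t in de_tables.items()}
    return DESetCollection(
        up_sets=up, down_sets=down,
        up_regions=venn_regions(up), down_regions=venn_regions(down),
        thresholds=dict(thresholds),
    )


def write_region_report(regions: VennRegions, path) -> None:
    regions.to_frame().to_csv(path, sep="\t", index=False)
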