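"""End-to-end convenience drivers over the individual pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .assignment import (
    AssignmentResult,
    assign_by_evalue,
    count_overlapping_clans,
    greedy_assign,
)
from .labeling import index_tracks, label_families
from .model import ClanMap, DomainHit, FamilyLabelSet, FeatureTrack, SeedRegion
from .overlap import OverlapPair, detect_overlaps


@dataclass
class OverlapAnalysis:
    """Result of running detection + assignment + clan counting."""

    threshold: float
    pairs: list[OverlapPair]
    assignment: AssignmentResult
    clan_counts: dict[str, int]

    def ranked_families(self) -> list[str]:
        """Families sorted by overlapping-clan count, descending
        (ties broken by accession) — the promiscuity ranking."""
        return [
            fam
            for fam, _ in sorted(
                self.clan_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]

    def promiscuous_families(self, min_clans: int = 2) -> list[str]:
        return sorted(f for f, c in self.clan_counts.items() if c >= min_clans)

    def overlap_regions(self) -> list[tuple[str, int, int]]:
        return [p.region for p in self.pairs]


def run_overlap_analysis(
    hits: Iterable[DomainHit],
    clans: ClanMap,
    threshold: float = 0.01,
    min_frac: float = 0.5,
    strategy: Literal["greedy", "evalue"] = "greedy",
) -> OverlapAnalysis:
    """Detect cross-clan overlaps, attribute overlapping domains to
    families, and count overlapping clans per family."""
    pairs = detect_overlaps(hits, clans, threshold, min_frac=min_frac)
    if strategy == "greedy":
        assignment = greedy_assign(pairs, clans)
    elif strategy == "evalue":
        assignment = assign_by_evalue(pairs)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    clan_counts = count_overlapping_clans(assignment, pairs, clans)
    return OverlapAnalysis(threshold, pairs, assignment, clan_counts)


def label_all_families(
    seeds: Iterable[SeedRegion], tracks: Iterable[FeatureTrack]
) -> dict[str, FamilyLabelSet]:
    """Label every family with seed members (thin wrapper)."""
    return label_families(seeds, index_tracks(tracks))
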