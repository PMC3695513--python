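"""Detection of cross-clan overlaps between domain hits.

An *overlap* is a sequence region that, at a given significance
threshold, matches two families from different clans, where the shared
region covers at least half of the alignment coordinates of at least one
of the two hits. Overlaps among three or more families are represented
as all qualifying unordered pairs; a domain is "overlapping" if it is
involved in at least one pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .intervals import intersection_length
from .model import ClanMap, DomainHit

DEFAULT_MIN_FRAC = 0.5


@dataclass(frozen=True, slots=True)
class OverlapPair:
    """A qualifying cross-clan overlap between two domain hits.

    ``inter_len`` is the intersection of the two alignment intervals in
    residues; ``frac_a``/``frac_b`` divide it by each hit's alignment
    length. Hits are stored in canonical order (by family accession,
    then coordinates) so each unordered pair has one representation.
    """

    hit_a: DomainHit
    hit_b: DomainHit
    inter_len: int
    frac_a: float
    frac_b: float

    @property
    def hits(self) -> tuple[DomainHit, DomainHit]:
        return (self.hit_a, self.hit_b)

    def partner_of(self, hit: DomainHit) -> DomainHit:
        if hit == self.hit_a:
            return self.hit_b
        if hit == self.hit_b:
            return self.hit_a
        raise ValueError("hit is not a member of this pair")

    @property
    def region(self) -> tuple[str, int, int]:
        """The shared sequence region (seq_id, start, end), 1-based inclusive."""
        start = max(self.hit_a.ali_start, self.hit_b.ali_start)
        end = min(self.hit_a.ali_end, self.hit_b.ali_end)
        return (self.hit_a.seq_id, start, end)


def filter_hits_by_evalue(hits: Iterable[DomainHit], threshold: float) -> list[DomainHit]:
    """Keep hits significant at ``threshold``: both the full-sequence and
    the per-domain E-value must be <= threshold (inclusive). Order is
    preserved.
    """
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    return [h for h in hits if h.dom_evalue <= threshold and h.seq_evalue <= threshold]


def _hit_sort_key(hit: DomainHit):
    return (hit.family_acc, hit.ali_start, hit.ali_end, hit.dom_evalue)


def pairwise_overlap(
    a: DomainHit,
    b: DomainHit,
    clans: ClanMap,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> Optional[OverlapPair]:
    """Return the OverlapPair for two hits, or None if they do not qualify.

    Qualification: same sequence, different families in different
    effective clans, intersecting alignment intervals, and the
    intersection covers >= ``min_frac`` of at least one alignment.
    Intersection is computed on alignment (not envelope) coordinates with
    closed-interval arithmetic.
    """
    if a.seq_id != b.seq_id or a.family_acc == b.family_acc:
        return None
    if clans.same_clan(a.family_acc, b.family_acc):
        return None
    inter = intersection_length(a.ali_interval, b.ali_interval)
    if inter <= 0:
        return None
    if a.family_acc > b.family_acc or (
        a.family_acc == b.family_acc and _hit_sort_key(a) > _hit_sort_key(b)
    ):
        a, b = b, a
    frac_a = inter / a.ali_length
    frac_b = inter / b.ali_length
    if max(frac_a, frac_b) < min_frac:
        return None
    return OverlapPair(a, b, inter, frac_a, frac_b)


def detect_overlaps(
    hits: Iterable[DomainHit],
    clans: ClanMap,
    threshold: float,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[OverlapPair]:
    """All qualifying cross-clan overlap pairs among threshold-filtered hits.

    Pairs are enumerated per sequence; each unordered pair is reported
    once, in deterministic order (sequence id, then family-accession
    pair, then coordinates).
    """
    kept = filter_hits_by_evalue(hits, threshold)
    by_seq: dict[str, list[DomainHit]] = {}
    for hit in kept:
        by_seq.setdefault(hit.seq_id, []).append(hit)

    pairs: list[OverlapPair] = []
    for seq_id in sorted(by_seq):
        seq_hits = sorted(by_seq[seq_id], key=_hit_sort_key)
        for a, b in combinations(seq_hits, 2):
            pair = pairwise_overlap(a, b, clans, min_frac=min_frac)
            if pair is not None:
                pairs.append(pair)
    pairs.sort(
        key=lambda p: (
            p.hit_a.seq_id,
            p.hit_a.family_acc,
            p.hit_b.family_acc,
            _hit_sort_key(p.hit_a),
            _hit_sort_key(p.hit_b),
        )
    )
    return pairs


def overlapping_domains(pairs: Iterable[OverlapPair]) -> set[DomainHit]:
    """Distinct domains involved in at least one overlap pair."""
    out: set[DomainHit] = set()
    for pair in pairs:
        out.add(pair.hit_a)
        out.add(pair.hit_b)
    return out
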