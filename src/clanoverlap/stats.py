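"""Quantitative summaries of the overlap analysis.

Covers: the expected number of false-positive domains implied by the
E-value definition; cumulative overlap-concentration curves over ranked
families; label overrepresentation (fold enrichment) along a clan-count
ranking; residue-level feature proportions inside overlap regions;
null2 bias-score flagging of families and its enrichment among
promiscuous families; and the conversion of a curated gathering
threshold to an E-value via the family's extreme-value calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import UndefinedResultError
from .intervals import intersect, merge, total_length
from .labeling import TrackIndex, index_tracks
from .model import FEATURE_KINDS, DomainHit, FamilyCalibration, FamilyLabelSet, FeatureTrack
from .assignment import AssignmentResult

LABEL_NAMES = ("cc20", "cc50", "dis20", "tmh2")


def expected_false_positives(n_families: int, e_seq: float, e_dom: float) -> float:
    """Expected number of false-positive domains for a search of
    ``n_families`` profile-HMMs at per-sequence threshold ``e_seq`` and
    per-domain threshold ``e_dom``:

        FP = N * E_seq + N * E_seq * E_dom

    The first term counts sequences expected to match by chance; the
    second counts additional chance domains within those sequences.
    """
    if n_families < 0:
        raise ValueError("n_families must be non-negative")
    if e_seq < 0 or e_dom < 0:
        raise ValueError("E-value thresholds must be non-negative")
    return n_families * e_seq + n_families * e_seq * e_dom


@dataclass(frozen=True)
class CumulativeCurve:
    """Families ranked by overlapping-domain count (descending) with the
    cumulative proportion of all attributed overlapping domains."""

    families: tuple[str, ...]
    counts: tuple[int, ...]
    cumulative: tuple[float, ...]


def cumulative_overlap_curve(result: AssignmentResult) -> CumulativeCurve:
    """Rank families by attributed overlapping-domain count (ties by
    accession) and accumulate the proportion of all overlapping domains."""
    counts = result.family_domain_counts()
    if not counts:
        return CumulativeCurve((), (), ())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    families = tuple(f for f, _ in ranked)
    ranked_counts = tuple(c for _, c in ranked)
    total = sum(ranked_counts)
    cumulative = tuple(np.cumsum(ranked_counts) / total)
    return CumulativeCurve(families, ranked_counts, cumulative)


def families_for_fraction(curve: CumulativeCurve, target: float) -> int:
    """Smallest number of top-ranked families jointly holding at least
    ``target`` of all overlapping domains."""
    if not (0 < target <= 1):
        raise ValueError("target fraction must be in (0, 1]")
    if not curve.families:
        raise UndefinedResultError("curve is empty: no overlapping domains")
    idx = int(np.searchsorted(np.asarray(curve.cumulative), target, side="left"))
    return idx + 1


@dataclass(frozen=True)
class EnrichmentCurve:
    """Per-rank label overrepresentation along a clan-count ranking.

    ``folds[label][x-1]`` is the proportion of label-positive families
    among the first x ranked families divided by the label's proportion
    in the whole family universe. Labels whose universe proportion is
    zero are absent from ``folds``.
    """

    families: tuple[str, ...]
    folds: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def fold_at(self, label: str, rank: int) -> float:
        return self.folds[label][rank - 1]


def overrepresentation_curve(
    ranked: Sequence[str],
    labels: Mapping[str, FamilyLabelSet],
    universe: Iterable[str],
) -> EnrichmentCurve:
    """Fold overrepresentation of each label among top-ranked families.

    ``ranked`` is the family list sorted by overlapping-clan count
    (descending); ``universe`` is the reference set of labelled families
    the background proportions are computed over.
    """
    universe = list(universe)
    if not universe:
        raise UndefinedResultError("empty family universe")
    missing = [f for f in ranked if f not in labels]
    if missing:
        raise KeyError(f"ranked families without labels: {missing[:5]}")

    folds: dict[str, tuple[float, ...]] = {}
    n_univ = len(universe)
    for name in LABEL_NAMES:
        base = sum(getattr(labels[f], name) for f in universe if f in labels) / n_univ
        if base == 0:
            continue  # undefined fold: reported as missing
        running = 0
        vals = []
        for x, fam in enumerate(ranked, start=1):
            running += getattr(labels[fam], name)
            vals.append((running / x) / base)
        folds[name] = tuple(vals)
    return EnrichmentCurve(tuple(ranked), folds)


Region = tuple[str, int, int]


def _region_union(regions: Iterable[Region]) -> dict[str, list[tuple[int, int]]]:
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in regions:
        per_seq.setdefault(seq_id, []).append((start, end))
    return {seq: merge(ivs) for seq, ivs in per_seq.items()}


def residue_bias_proportions(
    regions: Sequence[Region],
    tracks: Iterable[FeatureTrack] | TrackIndex,
) -> dict[str, float]:
    """Per feature kind, the fraction of region residues predicted positive.

    ``regions`` are (seq_id, start, end) intervals, 1-based inclusive —
    typically the shared regions of overlap pairs. Regions are unioned
    per sequence first, so a residue shared by several pairs counts once.
    """
    if not regions:
        raise UndefinedResultError("no regions given")
    if not isinstance(tracks, Mapping):
        tracks = index_tracks(tracks)
    union = _region_union(regions)
    total = sum(total_length(ivs) for ivs in union.values())
    if total == 0:
        raise UndefinedResultError("regions cover zero residues")
    out: dict[str, float] = {}
    for kind in FEATURE_KINDS:
        covered = 0
        for seq_id, ivs in union.items():
            track = tracks.get(seq_id, {}).get(kind)
            if track is not None:
                covered += total_length(intersect(ivs, list(track.segments)))
        out[kind] = covered / total
    return out


def conditional_track_overlap(
    regions: Sequence[Region],
    tracks: Iterable[FeatureTrack] | TrackIndex,
    given_kind: str,
    also_kind: str,
) -> float:
    """Among region residues predicted as ``given_kind``, the fraction
    also predicted as ``also_kind``."""
    for kind in (given_kind, also_kind):
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
    if not isinstance(tracks, Mapping):
        tracks = index_tracks(tracks)
    union = _region_union(regions)
    given_total = 0
    both_total = 0
    for seq_id, ivs in union.items():
        seq_tracks = tracks.get(seq_id, {})
        given = seq_tracks.get(given_kind)
        if given is None:
            continue
        given_ivs = intersect(ivs, list(given.segments))
        given_total += total_length(given_ivs)
        also = seq_tracks.get(also_kind)
        if also is not None:
            both_total += total_length(intersect(given_ivs, list(also.segments)))
    if given_total == 0:
        raise UndefinedResultError(
            f"no region residues predicted as {given_kind!r}"
        )
    return both_total / given_total


def bias_flag_families(
    hits: Iterable[DomainHit],
    ratio_cut: float = 0.1,
    domain_frac: float = 0.5,
    threshold: float = 0.01,
) -> set[str]:
    """Families whose null2 bias corrections look suspicious.

    Among each family's hits with per-domain E-value <= ``threshold``, a
    family is flagged when the fraction of domains with
    bias_score / bit_score > ``ratio_cut`` is strictly greater than
    ``domain_frac``. Families with no qualifying hits are excluded.
    """
    qualifying: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.dom_evalue <= threshold:
            qualifying.setdefault(hit.family_acc, []).append(hit)
    flagged: set[str] = set()
    for fam, fam_hits in qualifying.items():
        biased = 0
        for hit in fam_hits:
            if hit.bit_score <= 0:
                raise ValueError(
                    f"non-positive bit score for {fam} on {hit.seq_id}"
                )
            biased += hit.bias_score / hit.bit_score > ratio_cut
        if biased / len(fam_hits) > domain_frac:
            flagged.add(fam)
    return flagged


def flag_enrichment(
    flagged: Iterable[str],
    promiscuous: Iterable[str],
    universe: Iterable[str],
) -> float:
    """Fold enrichment of flagged families among promiscuous families:

        (|flagged ∩ promiscuous| / |promiscuous|) / (|flagged ∩ universe| / |universe|)
    """
    flagged = set(flagged)
    promiscuous = set(promiscuous)
    universe = set(universe)
    if not promiscuous or not universe:
        raise UndefinedResultError("empty promiscuous set or universe")
    base = len(flagged & universe) / len(universe)
    if base == 0:
        raise UndefinedResultError("no flagged families in the universe")
    return (len(flagged & promiscuous) / len(promiscuous)) / base


def flag_enrichment_from_counts(
    n_flagged_promiscuous: int,
    n_promiscuous: int,
    n_flagged: int,
    n_universe: int,
) -> float:
    """:func:`flag_enrichment` computed directly from the four counts."""
    if n_promiscuous <= 0 or n_universe <= 0:
        raise UndefinedResultError("empty promiscuous set or universe")
    if n_flagged <= 0:
        raise UndefinedResultError("no flagged families in the universe")
    return (n_flagged_promiscuous / n_promiscuous) / (n_flagged / n_universe)


def ga_to_evalue(calib: FamilyCalibration) -> float:
    """E-value of the family's gathering threshold under its extreme-value
    calibration: E = N * exp(-lam * (x - tau))."""
    return calib.db_size * math.exp(-calib.lam * (calib.ga_bits - calib.tau))
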