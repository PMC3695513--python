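"""Compositional-bias labels for families from seed-member feature tracks.

A family is labelled coiled-coil (disordered) when at least half of its
seed members carry >= 20 consecutive predicted coiled-coil (disordered)
residues inside their seed regions, and transmembrane when at least half
carry >= 2 predicted transmembrane helices there. A stricter coiled-coil
label uses >= 50 consecutive residues. Predictions outside a member's
seed region are ignored; members without any track count as negative.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .intervals import clip, length
from .model import FamilyLabelSet, FeatureTrack, SeedRegion

#: mapping seq_id -> {kind -> FeatureTrack}
TrackIndex = Mapping[str, Mapping[str, FeatureTrack]]


def index_tracks(tracks: Iterable[FeatureTrack]) -> dict[str, dict[str, FeatureTrack]]:
    """Index normalized tracks by sequence id and feature kind."""
    out: dict[str, dict[str, FeatureTrack]] = {}
    for track in tracks:
        norm = track.normalized()
        out.setdefault(norm.seq_id, {})[norm.kind] = norm
    return out


def longest_true_run(track: FeatureTrack | None, region: SeedRegion) -> int:
    """Longest contiguous run of predicted residues within the seed region.

    Segments are clipped to the region first; a missing track yields 0.
    """
    if track is None:
        return 0
    clipped = clip(track.normalized().segments, region.interval)
    return max((length(iv) for iv in clipped), default=0)


def count_tm_helices(track: FeatureTrack | None, region: SeedRegion) -> int:
    """Predicted transmembrane helices touching the seed region.

    A helix segment counts if at least one residue intersects the
    region (predictors report helices as whole segments, so a helix
    clipped at the region boundary still counts).
    """
    if track is None:
        return 0
    if track.kind != "transmembrane":
        raise ValueError(f"expected a transmembrane track, got kind {track.kind!r}")
    clipped = clip(track.normalized().segments, region.interval)
    return len(clipped)


def label_family(
    seeds: Sequence[SeedRegion],
    tracks: TrackIndex,
    member_frac: float = 0.5,
    cc_run: int = 20,
    cc_long_run: int = 50,
    dis_run: int = 20,
    tm_min: int = 2,
) -> FamilyLabelSet:
    """Compute the label set of one family from its seed members.

    Each label is true iff the fraction of seed members satisfying its
    per-member test is >= ``member_frac`` (boundary inclusive).
    """
    if not seeds:
        raise ValueError("cannot label a family with no seed members")
    family = seeds[0].family_acc
    if any(s.family_acc != family for s in seeds):
        raise ValueError("seed members belong to different families")

    n = len(seeds)
    n_cc = n_cc_long = n_dis = n_tm = 0
    for seed in seeds:
        seq_tracks = tracks.get(seed.seq_id, {})
        cc = longest_true_run(seq_tracks.get("coiled_coil"), seed)
        dis = longest_true_run(seq_tracks.get("disorder"), seed)
        tm = count_tm_helices(seq_tracks.get("transmembrane"), seed)
        n_cc += cc >= cc_run
        n_cc_long += cc >= cc_long_run
        n_dis += dis >= dis_run
        n_tm += tm >= tm_min

    def hits_quorum(k: int) -> bool:
        return k / n >= member_frac

    return FamilyLabelSet(
        family_acc=family,
        cc20=hits_quorum(n_cc),
        cc50=hits_quorum(n_cc_long),
        dis20=hits_quorum(n_dis),
        tmh2=hits_quorum(n_tm),
    )


def label_families(
    seeds: Iterable[SeedRegion],
    tracks: Iterable[FeatureTrack] | TrackIndex,
    **kwargs,
) -> dict[str, FamilyLabelSet]:
    """Label every family present in ``seeds``. Convenience wrapper."""
    if not isinstance(tracks, Mapping):
        tracks = index_tracks(tracks)
    by_family: dict[str, list[SeedRegion]] = {}
    for seed in seeds:
        by_family.setdefault(seed.family_acc, []).append(seed)
    return {
        fam: label_family(members, tracks, **kwargs)
        for fam, members in sorted(by_family.items())
    }
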