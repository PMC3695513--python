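"""Core domain types for profile-HMM clan-overlap analysis.

A *domain hit* is one alignment of a family's profile-HMM to a region of a
protein sequence, as reported by an hmmsearch-style per-domain table. The
types below carry the scores and coordinates the downstream analysis needs:
E-values for significance filtering, bit and bias scores for the null2
diagnostics, alignment coordinates for overlap arithmetic, and envelope
coordinates as a containment sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .intervals import Interval, merge

#: Recognized per-residue feature kinds (predictor output classes).
FEATURE_KINDS = ("coiled_coil", "transmembrane", "disorder")


@dataclass(frozen=True, slots=True)
class DomainHit:
    """One domain alignment of a family model to a sequence.

    Coordinates are 1-based inclusive. The alignment interval is the
    reliably aligned region; the envelope is the (equal or wider) region
    with substantial probability mass supporting homology.
    """

    seq_id: str
    family_acc: str
    seq_evalue: float
    dom_evalue: float
    bit_score: float
    bias_score: float
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValidationError(
                f"invalid alignment coordinates {self.ali_start}-{self.ali_end} "
                f"for {self.family_acc} on {self.seq_id}"
            )
        if not (self.env_start <= self.ali_start and self.ali_end <= self.env_end):
            raise ValidationError(
                f"envelope {self.env_start}-{self.env_end} does not contain "
                f"alignment {self.ali_start}-{self.ali_end} "
                f"for {self.family_acc} on {self.seq_id}"
            )
        if self.seq_evalue < 0 or self.dom_evalue < 0:
            raise ValidationError("E-values must be non-negative")
        if self.bias_score < 0:
            raise ValidationError("bias score must be non-negative")

    @property
    def ali_interval(self) -> Interval:
        return (self.ali_start, self.ali_end)

    @property
    def ali_length(self) -> int:
        return self.ali_end - self.ali_start + 1


SINGLETON_PREFIX = "SINGLETON:"


@dataclass(frozen=True)
class ClanMap:
    """Family → clan membership.

    A family belongs to at most one clan. Families without a clan are
    treated as the sole member of their own clan; :meth:`effective_clan`
    returns a deterministic singleton identifier for them, so that clan
    comparisons never have to special-case clanless families.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def effective_clan(self, family_acc: str) -> str:
        clan = self.entries.get(family_acc)
        if clan:
            return clan
        return SINGLETON_PREFIX + family_acc

    def same_clan(self, fam_a: str, fam_b: str) -> bool:
        return self.effective_clan(fam_a) == self.effective_clan(fam_b)


@dataclass(frozen=True)
class FeatureTrack:
    """Per-residue predictor output for one sequence, as a segment list.

    ``kind`` is one of :data:`FEATURE_KINDS`. Segments are 1-based
    inclusive intervals of residues predicted positive; after
    :meth:`normalized` they are sorted, non-overlapping and non-adjacent.
    """

    seq_id: str
    kind: str
    segments: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        for start, end in self.segments:
            if start > end:
                raise ValidationError(
                    f"segment {start}-{end} on {self.seq_id} has start > end"
                )
            if start < 1:
                raise ValidationError("segment coordinates are 1-based")

    def normalized(self) -> "FeatureTrack":
        return FeatureTrack(self.seq_id, self.kind, tuple(merge(self.segments)))


@dataclass(frozen=True, slots=True)
class SeedRegion:
    """The region of one seed-alignment member sequence of a family.

    Predicted residues outside the seed region are ignored when labeling
    the family.
    """

    family_acc: str
    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"seed region {self.start}-{self.end} on {self.seq_id} has start > end"
            )

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True, slots=True)
class FamilyCalibration:
    """Extreme-value calibration of one family's profile-HMM.

    ``ga_bits`` is the curated gathering threshold x (bits); ``lam`` and
    ``tau`` are the slope and location parameters of the score
    distribution; ``db_size`` is the database size N in sequences. The
    E-value of a score x is N * exp(-lam * (x - tau)).
    """

    family_acc: str
    ga_bits: float
    lam: float
    tau: float
    db_size: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError("slope parameter lam must be positive")
        if self.db_size < 1:
            raise ValidationError("database size must be >= 1")


@dataclass(frozen=True, slots=True)
class FamilyLabelSet:
    """Compositional-bias labels for one family.

    cc20/cc50: >=20 (>=50) consecutive coiled-coil residues in >=50% of
    seed members; dis20: likewise for disorder; tmh2: >=2 predicted
    transmembrane helices in >=50% of seed members. cc50 implies cc20.
    """

    family_acc: str
    cc20: bool = False
    cc50: bool = False
    dis20: bool = False
    tmh2: bool = False

    def __post_init__(self) -> None:
        if self.cc50 and not self.cc20:
            raise ValidationError("cc50 implies cc20: a 50-residue run contains a 20-residue run")
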