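"""Attribution of overlapping domains to families.

Two strategies are provided. The winner-takes-all greedy algorithm
repeatedly selects the family currently holding the most overlapping
domains, awards those domains to it, and retires the overlaps it was
involved in; a partner domain whose overlaps were *all* with the
selected family drops off the overlapping-domain list unassigned, while
a domain contested among several families stays listed under its own
family until that family is selected. The alternative E-value-based
strategy marks, within each overlap pair, the hit with the higher
per-domain E-value as the suspect overlapping domain of its own family
(the lower-E-value hit is presumed the genuine match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .model import ClanMap, DomainHit
from .overlap import OverlapPair


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of an assignment strategy.

    ``domain_to_family`` maps each attributed overlapping domain to the
    family it was awarded to (its own family, for both strategies); a
    domain appears at most once. ``selection_order`` records, for the
    greedy strategy, each selected family with its overlapping-domain
    count at selection time; for the E-value strategy it lists families
    by their suspect-domain counts.
    """

    domain_to_family: dict[DomainHit, str] = field(default_factory=dict)
    selection_order: list[tuple[str, int]] = field(default_factory=list)

    def family_domain_counts(self) -> dict[str, int]:
        """Number of attributed overlapping domains per family."""
        counts: dict[str, int] = {}
        for fam in self.domain_to_family.values():
            counts[fam] = counts.get(fam, 0) + 1
        return counts


def greedy_assign(
    pairs: Iterable[OverlapPair], clans: Optional[ClanMap] = None
) -> AssignmentResult:
    """Winner-takes-all greedy attribution of overlapping domains.

    Iteratively: count, per family, its member domains still on the
    overlapping-domain list; select the family with the highest count
    (ties broken toward the lexicographically smallest accession);
    assign its listed domains to it; remove the overlaps involving it.
    A domain all of whose overlaps were with the selected family
    disappears from the list; a domain with overlaps against other
    families remains listed under its own family. Repeat until the list
    is empty.

    ``clans`` is accepted for interface symmetry with overlap detection;
    the algorithm itself only uses family memberships.
    """
    pair_list = list(pairs)
    partner_fams: dict[DomainHit, set[str]] = {}
    active_by_family: dict[str, set[DomainHit]] = {}
    for pair in pair_list:
        for hit, other in ((pair.hit_a, pair.hit_b), (pair.hit_b, pair.hit_a)):
            partner_fams.setdefault(hit, set()).add(other.family_acc)
            active_by_family.setdefault(hit.family_acc, set()).add(hit)

    domain_to_family: dict[DomainHit, str] = {}
    selection_order: list[tuple[str, int]] = []

    while active_by_family:
        # highest count first; lexicographically smallest accession on ties
        selected = min(
            active_by_family, key=lambda fam: (-len(active_by_family[fam]), fam)
        )
        claimed = active_by_family.pop(selected)
        selection_order.append((selected, len(claimed)))
        for domain in claimed:
            domain_to_family[domain] = selected
        # partner domains whose every overlap involved the selected family
        # drop off the list unassigned
        for fam in list(active_by_family):
            survivors = {
                d for d in active_by_family[fam] if partner_fams[d] != {selected}
            }
            if survivors:
                active_by_family[fam] = survivors
            else:
                del active_by_family[fam]

    return AssignmentResult(domain_to_family, selection_order)


def assign_by_evalue(pairs: Iterable[OverlapPair]) -> AssignmentResult:
    """E-value-based attribution: in each pair the hit with the higher
    per-domain E-value is the suspect overlapping domain of its own
    family (equal E-values: the hit of the lexicographically larger
    accession). A domain losing in several pairs is marked once.
    """
    domain_to_family: dict[DomainHit, str] = {}
    for pair in pairs:
        a, b = pair.hit_a, pair.hit_b
        if a.dom_evalue > b.dom_evalue:
            loser = a
        elif b.dom_evalue > a.dom_evalue:
            loser = b
        else:
            loser = a if a.family_acc > b.family_acc else b
        domain_to_family[loser] = loser.family_acc

    counts: dict[str, int] = {}
    for fam in domain_to_family.values():
        counts[fam] = counts.get(fam, 0) + 1
    selection_order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return AssignmentResult(domain_to_family, selection_order)


def count_overlapping_clans(
    result: AssignmentResult,
    pairs: Iterable[OverlapPair],
    clans: ClanMap,
    mode: Literal["union", "sum"] = "union",
) -> dict[str, int]:
    """Number of clans each family's attributed domains overlap with.

    For every family F retaining >= 1 attributed overlapping domain, the
    effective clans of the partner domains of those domains are
    collected; a clanless partner contributes its singleton clan. With
    ``mode="union"`` (default) the count is the size of the distinct
    union over all of F's domains; ``mode="sum"`` instead sums each
    domain's distinct partner-clan count.
    """
    pair_list = list(pairs)
    per_domain: dict[DomainHit, set[str]] = {}
    for pair in pair_list:
        for hit, other in ((pair.hit_a, pair.hit_b), (pair.hit_b, pair.hit_a)):
            if hit in result.domain_to_family:
                per_domain.setdefault(hit, set()).add(
                    clans.effective_clan(other.family_acc)
                )

    counts: dict[str, int] = {}
    if mode == "union":
        unions: dict[str, set[str]] = {}
        for domain, partner_clans in per_domain.items():
            fam = result.domain_to_family[domain]
            unions.setdefault(fam, set()).update(partner_clans)
        counts = {fam: len(cl) for fam, cl in unions.items()}
    elif mode == "sum":
        for domain, partner_clans in per_domain.items():
            fam = result.domain_to_family[domain]
            counts[fam] = counts.get(fam, 0) + len(partner_clans)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts
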