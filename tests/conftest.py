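"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force or
literal step-by-step simulation, independent of the package's optimized
code paths, so that property tests compare two routes to the same
answer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from clanoverlap.model import ClanMap, DomainHit

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


def mk_hit(
    seq: str = "s1",
    fam: str = "PF00001",
    ali: tuple[int, int] = (1, 100),
    dom_e: float = 1e-5,
    seq_e: float | None = None,
    bit: float = 50.0,
    bias: float = 0.0,
    env: tuple[int, int] | None = None,
) -> DomainHit:
    env = env or ali
    return DomainHit(
        seq_id=seq,
        family_acc=fam,
        seq_evalue=dom_e if seq_e is None else seq_e,
        dom_evalue=dom_e,
        bit_score=bit,
        bias_score=bias,
        ali_start=ali[0],
        ali_end=ali[1],
        env_start=env[0],
        env_end=env[1],
    )


def brute_force_overlaps(hits, clans: ClanMap, threshold, min_frac=0.5):
    """O(n^2) re-derivation of qualifying cross-clan overlap pairs,
    returned as a set of frozensets of hits."""
    kept = [h for h in hits if h.dom_evalue <= threshold and h.seq_evalue <= threshold]
    found = set()
    for i in range(len(kept)):
        for j in range(len(kept)):
            if i == j:
                continue
            a, b = kept[i], kept[j]
            if a.seq_id != b.seq_id or a.family_acc == b.family_acc:
                continue
            clan_a = clans.entries.get(a.family_acc) or "1MEM_" + a.family_acc
            clan_b = clans.entries.get(b.family_acc) or "1MEM_" + b.family_acc
            if clan_a == clan_b:
                continue
            lo = max(a.ali_start, b.ali_start)
            hi = min(a.ali_end, b.ali_end)
            inter = hi - lo + 1
            if inter <= 0:
                continue
            len_a = a.ali_end - a.ali_start + 1
            len_b = b.ali_end - b.ali_start + 1
            if inter / len_a >= min_frac or inter / len_b >= min_frac:
                found.add(frozenset((a, b)))
    return found


def greedy_oracle(pairs):
    """Literal step-by-step simulation of the winner-takes-all rules.

    Maintains the master list of overlapping domains with each domain's
    original overlaps. Each round: pick the family with the most listed
    domains (ties: smallest accession), assign and delist its domains,
    then delist any remaining domain all of whose overlaps involved the
    selected family.
    """
    original = {}
    for pair in pairs:
        original.setdefault(pair.hit_a, []).append(pair)
        original.setdefault(pair.hit_b, []).append(pair)
    listed = set(original)
    assigned, order = {}, []
    while listed:
        per_family = {}
        for dom in listed:
            per_family.setdefault(dom.family_acc, []).append(dom)
        winner = sorted(per_family.items(), key=lambda kv: (-len(kv[1]), kv[0]))[0][0]
        members = per_family[winner]
        order.append((winner, len(members)))
        for dom in members:
            assigned[dom] = winner
            listed.discard(dom)
        for dom in list(listed):
            involved = {
                fam
                for p in original[dom]
                for fam in (p.hit_a.family_acc, p.hit_b.family_acc)
                if fam != dom.family_acc
            }
            if involved == {winner}:
                listed.discard(dom)
    return assigned, order


def random_hit_instance(rng: np.random.Generator, max_hits: int = 50):
    """A random hit table plus clan map for oracle-equivalence checks."""
    n_fams = int(rng.integers(2, 9))
    fams = [f"PF{i:03d}" for i in range(1, n_fams + 1)]
    n_clans = int(rng.integers(1, n_fams + 1))
    entries = {}
    for i, fam in enumerate(fams):
        if rng.random() < 0.2:
            continue  # clanless
        entries[fam] = f"CL{(i % n_clans) + 1:02d}"
    clans = ClanMap(entries=entries)
    seqs = [f"s{i}" for i in range(1, int(rng.integers(1, 4)) + 1)]
    hits = []
    for _ in range(int(rng.integers(0, max_hits + 1))):
        start = int(rng.integers(1, 200))
        length = int(rng.integers(1, 120))
        hits.append(
            mk_hit(
                seq=str(rng.choice(seqs)),
                fam=str(rng.choice(fams)),
                ali=(start, start + length - 1),
                dom_e=float(10 ** rng.uniform(-8, 0.5)),
                seq_e=float(10 ** rng.uniform(-8, 0.5)),
            )
        )
    return hits, clans
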