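"""Seeded synthetic scenarios with planted overlap and label structure.

The generator emulates the statistical shape of a large-scale
profile-HMM search in which a small set of *promiscuous* families
produces most cross-clan overlaps and is enriched for coiled-coil
compositional bias, over a background of well-behaved families. Every
planted quantity (per-family overlapping-clan counts, overlapping-
domain counts, label sets, bias-flagged families) is recorded as ground
truth, so the whole pipeline can be checked for exact recovery without
any real search data.

Planted structure, per promiscuous family: for each of its planned
partner clans, a fresh partner family is created and the two families
are given hit pairs on dedicated sequences whose alignment intervals
share at least half of each alignment, below the analysis E-value
threshold. Background hits are laid out in disjoint windows so they can
never overlap. Coiled-coil tracks are written as contiguous segments of
whole heptad repeats (period 7), the way a coiled-coil predictor
reports them.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import (
    write_clan_map,
    write_domain_hits,
    write_feature_tracks,
    write_seed_regions,
)
from .model import ClanMap, DomainHit, FamilyLabelSet, FeatureTrack, SeedRegion

HEPTAD = 7


@dataclass(frozen=True)
class PromiscuityPlan:
    """How promiscuous one planted family is: the number of distinct
    partner clans it overlaps with and the overlapping-domain pairs per
    partner clan."""

    n_partner_clans: int = 3
    domains_per_clan: int = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a desk-scale analogue of a family universe with a
    small promiscuous core: 160 families in 24 clans, 12 promiscuous
    families overlapping 2-4 clans each, ~10% of families carrying each
    compositional-bias label, planted hit E-values log-uniform below the
    0.01 analysis threshold and background E-values straddling it.
    """

    seed: int = 0
    n_families: int = 160
    n_clans: int = 24
    n_sequences: int = 120
    frac_cc_families: float = 0.10
    frac_dis_families: float = 0.10
    frac_tm_families: float = 0.10
    cc_long_frac: float = 0.30
    cc_fold_promiscuous: float = 1.0
    frac_bias_families: float = 0.06
    frac_clanless: float = 0.15
    promiscuity_plan: tuple[PromiscuityPlan, ...] = tuple(
        PromiscuityPlan(n_partner_clans=2 + i % 3, domains_per_clan=1 + i % 2)
        for i in range(12)
    )
    evalue_law: tuple[float, float] = (1e-10, 1e-3)
    background_evalue_law: tuple[float, float] = (1e-6, 10.0)
    region_length_law: tuple[int, int] = (60, 160)
    heptad_period: int = HEPTAD
    seeds_per_family: int = 4
    background_hits_per_family: int = 3
    analysis_threshold: float = 0.01

    def validate(self) -> None:
        for name in (
            "frac_cc_families",
            "frac_dis_families",
            "frac_tm_families",
            "cc_long_frac",
            "frac_bias_families",
            "frac_clanless",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_clans > self.n_families:
            raise ConfigError("n_clans must not exceed n_families")
        if min(self.n_families, self.n_clans, self.n_sequences) < 0:
            raise ConfigError("counts must be non-negative")
        if self.heptad_period != HEPTAD:
            raise ConfigError("heptad period is 7 residues")
        n_prom = len(self.promiscuity_plan)
        n_partners = sum(p.n_partner_clans for p in self.promiscuity_plan)
        for plan in self.promiscuity_plan:
            if plan.n_partner_clans < 1 or plan.domains_per_clan < 1:
                raise ConfigError("promiscuity plan entries must be >= 1")
            if plan.n_partner_clans > self.n_clans - 1:
                raise ConfigError(
                    f"plan wants {plan.n_partner_clans} partner clans but only "
                    f"{self.n_clans - 1} other clans exist"
                )
        if n_prom + n_partners > self.n_families:
            raise ConfigError(
                f"plan needs {n_prom + n_partners} families, "
                f"only {self.n_families} configured"
            )
        if self.cc_fold_promiscuous != 1.0 and n_prom:
            p_prom = self.frac_cc_families * self.cc_fold_promiscuous
            if p_prom > 1:
                raise ConfigError("frac_cc_families * cc_fold_promiscuous exceeds 1")
            n_bg = self.n_families - n_prom
            p_bg = (self.n_families * self.frac_cc_families - n_prom * p_prom) / n_bg
            if p_bg < 0:
                raise ConfigError(
                    "cc_fold_promiscuous too high for the configured universe proportion"
                )


@dataclass
class GroundTruth:
    """What was planted: recoverable exactly by the analysis pipeline."""

    promiscuous_clan_counts: dict[str, int] = field(default_factory=dict)
    overlapping_domain_counts: dict[str, int] = field(default_factory=dict)
    labels: dict[str, FamilyLabelSet] = field(default_factory=dict)
    bias_flagged: set[str] = field(default_factory=set)


@dataclass
class Scenario:
    """In-memory scenario: inputs plus ground truth."""

    config: ScenarioConfig
    hits: list[DomainHit]
    clans: ClanMap
    families: list[str]
    seeds: list[SeedRegion]
    tracks: list[FeatureTrack]
    truth: GroundTruth


def generate_heptad_track(
    seq_length: int,
    n_repeats: int,
    start: int,
    seq_id: str = "seq",
) -> FeatureTrack:
    """A coiled-coil predictor segment of ``n_repeats`` whole heptad
    repeats starting at ``start`` (1-based). Zero repeats yields an
    empty track; a run extending past the sequence end is a
    configuration error."""
    if n_repeats < 0 or start < 1:
        raise ConfigError("n_repeats must be >= 0 and start >= 1")
    if n_repeats == 0:
        return FeatureTrack(seq_id, "coiled_coil", ())
    end = start + HEPTAD * n_repeats - 1
    if end > seq_length:
        raise ConfigError(
            f"heptad run {start}-{end} exceeds sequence length {seq_length}"
        )
    return FeatureTrack(seq_id, "coiled_coil", ((start, end),))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _bit_score_for(evalue: float, rng: np.random.Generator) -> float:
    # loose inverse of the extreme-value relation: smaller E, higher score
    return max(12.0, 20.0 - 1.5 * math.log10(max(evalue, 1e-200)) + rng.uniform(0, 3))


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Construct a scenario in memory. Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_prom = len(config.promiscuity_plan)
    n_partners = sum(p.n_partner_clans for p in config.promiscuity_plan)
    n_bg = config.n_families - n_prom - n_partners

    # accession layout: promiscuous families take the lowest accessions so
    # greedy tie-breaks (lexicographic) favour them deterministically
    families = [f"PF{i + 1:05d}" for i in range(config.n_families)]
    prom_fams = families[:n_prom]
    partner_pool = iter(families[n_prom : n_prom + n_partners])
    bg_fams = families[n_prom + n_partners :]

    clan_ids = [f"CL{i + 1:04d}" for i in range(config.n_clans)]
    n_clanless = int(round(config.frac_clanless * n_bg))
    clan_entries: dict[str, str] = {}
    for i, fam in enumerate(prom_fams):
        clan_entries[fam] = clan_ids[i % config.n_clans]
    for i, fam in enumerate(bg_fams):
        if i >= n_bg - n_clanless:
            continue  # clanless: resolves to a singleton clan
        clan_entries[fam] = clan_ids[i % config.n_clans]

    truth = GroundTruth()
    hits: list[DomainHit] = []
    lo_e, hi_e = config.evalue_law
    len_lo, len_hi = config.region_length_law

    def planted_hit(seq_id: str, fam: str, start: int, length: int) -> DomainHit:
        dom_e = _log_uniform(rng, lo_e, hi_e)
        seq_e = dom_e * rng.uniform(0.1, 1.0)
        bit = _bit_score_for(dom_e, rng)
        end = start + length - 1
        pad = int(rng.integers(0, 6))
        return DomainHit(
            seq_id=seq_id,
            family_acc=fam,
            seq_evalue=seq_e,
            dom_evalue=dom_e,
            bit_score=bit,
            bias_score=0.0,  # ratio patched in below per family
            ali_start=start,
            ali_end=end,
            env_start=max(1, start - pad),
            env_end=end + pad,
        )

    # --- planted promiscuous overlap stars -------------------------------
    partner_fams: list[str] = []
    for p_idx, (fam, plan) in enumerate(zip(prom_fams, config.promiscuity_plan)):
        own_clan = clan_entries[fam]
        partner_clans = [c for c in clan_ids if c != own_clan]
        offset = p_idx % len(partner_clans)
        chosen = [
            partner_clans[(offset + j) % len(partner_clans)]
            for j in range(plan.n_partner_clans)
        ]
        n_dom = 0
        for clan in chosen:
            partner = next(partner_pool)
            partner_fams.append(partner)
            clan_entries[partner] = clan
            for k in range(plan.domains_per_clan):
                seq_id = f"OV{p_idx + 1:03d}_{n_dom + 1:03d}"
                length = int(rng.integers(len_lo, len_hi + 1))
                start = int(rng.integers(1, 40))
                shift = int(rng.integers(0, length // 2 + 1))
                hits.append(planted_hit(seq_id, fam, start, length))
                hits.append(planted_hit(seq_id, partner, start + shift, length))
                n_dom += 1
        truth.promiscuous_clan_counts[fam] = plan.n_partner_clans
        truth.overlapping_domain_counts[fam] = n_dom

    # --- background hits in disjoint windows -----------------------------
    seq_cursor: dict[str, int] = {}
    bg_lo, bg_hi = config.background_evalue_law
    bias_fams: set[str] = set()
    for fam in families:
        if rng.random() < config.frac_bias_families:
            bias_fams.add(fam)
    truth.bias_flagged = set(bias_fams)

    for i, fam in enumerate(bg_fams):
        for _ in range(config.background_hits_per_family):
            seq_id = f"SQ{(i % max(config.n_sequences, 1)) + 1:04d}"
            cursor = seq_cursor.get(seq_id, 1)
            length = int(rng.integers(len_lo, len_hi + 1))
            if fam in bias_fams:
                dom_e = _log_uniform(rng, lo_e, hi_e)  # must stay qualifying
            else:
                dom_e = _log_uniform(rng, bg_lo, bg_hi)
            seq_e = dom_e * rng.uniform(0.1, 1.0)
            end = cursor + length - 1
            hits.append(
                DomainHit(
                    seq_id=seq_id,
                    family_acc=fam,
                    seq_evalue=seq_e,
                    dom_evalue=dom_e,
                    bit_score=_bit_score_for(dom_e, rng),
                    bias_score=0.0,
                    ali_start=cursor,
                    ali_end=end,
                    env_start=cursor,
                    env_end=end,
                )
            )
            seq_cursor[seq_id] = end + 6  # gap so windows never touch

    # --- null2 bias ratios ------------------------------------------------
    # flagged families: every hit biased (ratio ~0.15-0.30 > 0.1, so the
    # >50%-of-domains rule fires); others stay well below the 0.1 cut
    patched: list[DomainHit] = []
    for hit in hits:
        if hit.family_acc in bias_fams:
            ratio = rng.uniform(0.15, 0.30)
        else:
            ratio = rng.uniform(0.0, 0.08)
        patched.append(
            DomainHit(
                seq_id=hit.seq_id,
                family_acc=hit.family_acc,
                seq_evalue=hit.seq_evalue,
                dom_evalue=hit.dom_evalue,
                bit_score=hit.bit_score,
                bias_score=round(ratio * hit.bit_score, 2),
                ali_start=hit.ali_start,
                ali_end=hit.ali_end,
                env_start=hit.env_start,
                env_end=hit.env_end,
            )
        )
    hits = patched

    # --- seed regions and feature tracks ---------------------------------
    p_cc_prom = config.frac_cc_families * config.cc_fold_promiscuous
    if n_prom and config.n_families > n_prom:
        p_cc_bg = (
            config.n_families * config.frac_cc_families - n_prom * p_cc_prom
        ) / (config.n_families - n_prom)
    else:
        p_cc_bg = config.frac_cc_families

    seeds: list[SeedRegion] = []
    tracks: list[FeatureTrack] = []
    seq_len, reg = 220, (11, 210)
    n_members = config.seeds_per_family
    quorum = math.ceil(n_members * 0.5)

    for fam in families:
        is_prom = fam in truth.promiscuous_clan_counts
        cc = rng.random() < (p_cc_prom if is_prom else p_cc_bg)
        cc50 = cc and (rng.random() < config.cc_long_frac)
        dis = rng.random() < config.frac_dis_families
        tmh = rng.random() < config.frac_tm_families
        truth.labels[fam] = FamilyLabelSet(fam, cc20=cc, cc50=cc50, dis20=dis, tmh2=tmh)

        def n_pos(planted: bool) -> int:
            if planted:
                return int(rng.integers(quorum, n_members + 1))
            return int(rng.integers(0, quorum))

        k_cc, k_dis, k_tm = n_pos(cc), n_pos(dis), n_pos(tmh)
        # among cc-positive members, how many carry the long (>=50) run
        k_cc50 = int(rng.integers(quorum, k_cc + 1)) if cc50 else 0

        for m in range(n_members):
            seq_id = f"SD_{fam}_{m + 1}"
            seeds.append(SeedRegion(fam, seq_id, reg[0], reg[1]))
            if m < k_cc:
                if m < k_cc50:
                    repeats = int(rng.integers(8, 13))  # 56-84 residues
                else:
                    repeats = int(rng.integers(3, 7))  # 21-42 residues
            else:
                repeats = int(rng.integers(0, 3))  # 0-14 residues: below 20
            start = reg[0] + 20 + int(rng.integers(0, 10))
            track = generate_heptad_track(seq_len, repeats, start, seq_id=seq_id)
            if track.segments:
                tracks.append(track)
            if m < k_dis:
                dlen = int(rng.integers(22, 41))
            else:
                dlen = int(rng.integers(0, 13))
            if dlen:
                dstart = reg[0] + 90 + int(rng.integers(0, 10))
                tracks.append(
                    FeatureTrack(seq_id, "disorder", ((dstart, dstart + dlen - 1),))
                )
            n_helices = int(rng.integers(2, 4)) if m < k_tm else int(rng.integers(0, 2))
            if n_helices:
                segs = []
                tstart = reg[0] + 130
                for _ in range(n_helices):
                    segs.append((tstart, tstart + 20))
                    tstart += 30
                tracks.append(FeatureTrack(seq_id, "transmembrane", tuple(segs)))

    clans = ClanMap(entries=clan_entries)
    return Scenario(config, hits, clans, families, seeds, tracks, truth)


@dataclass(frozen=True)
class ScenarioFiles:
    hits: Path
    clans: Path
    seed_regions: Path
    tracks: Path
    ground_truth: Path


def generate_scenario(
    config: ScenarioConfig, out_dir: str | os.PathLike
) -> tuple[ScenarioFiles, GroundTruth]:
    """Generate a scenario and write its four input files plus the
    ground-truth JSON to ``out_dir``. Byte-identical for a fixed seed."""
    scenario = build_scenario(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = ScenarioFiles(
        hits=out / "hits.tsv",
        clans=out / "clans.tsv",
        seed_regions=out / "seed_regions.tsv",
        tracks=out / "tracks.tsv",
        ground_truth=out / "ground_truth.json",
    )
    write_domain_hits(scenario.hits, paths.hits)
    write_clan_map(scenario.clans, paths.clans, families=scenario.families)
    write_seed_regions(scenario.seeds, paths.seed_regions)
    write_feature_tracks(scenario.tracks, paths.tracks)
    truth = scenario.truth
    payload = {
        "promiscuous_clan_counts": truth.promiscuous_clan_counts,
        "overlapping_domain_counts": truth.overlapping_domain_counts,
        "labels": {fam: asdict(ls) for fam, ls in truth.labels.items()},
        "bias_flagged": sorted(truth.bias_flagged),
    }
    paths.ground_truth.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return paths, truth


def generate_null_scenario(
    config: ScenarioConfig, out_dir: str | os.PathLike
) -> tuple[ScenarioFiles, GroundTruth]:
    """A scenario with no planted overlaps (empty promiscuity plan):
    downstream overlap detection must return nothing."""
    return generate_scenario(replace(config, promiscuity_plan=()), out_dir)
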