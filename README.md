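# clanoverlap

Cross-clan overlap analysis of profile-HMM homology search results.

Profile-HMM searches (HMMER3-style) report an E-value for every domain
hit: the number of equal-or-better matches expected by chance. When the
same stretch of a protein simultaneously matches two families that are
annotated as evolutionarily *unrelated* (different Pfam-style clans), at
least one of the annotations is suspect — an incorrectly built model, a
missing clan relationship, or a false positive whose E-value is
miscalibrated. Sequence regions with strong compositional bias, above
all coiled-coils with their 7-residue heptad repeat, are the classic
source of such miscalibration, because a non-zeroth-order bias violates
the residue-independence assumptions behind E-value estimation.

`clanoverlap` implements this overlap analysis as a reusable pipeline
for curators and method developers who want to audit a search result
set without a structure-based benchmark:

1. **Overlap detection** — two domain hits on the same sequence overlap
   when their families are in different clans (a clanless family counts
   as a singleton clan) and the intersection of their alignment
   coordinates covers ≥ 50% of at least one alignment, at a significance
   threshold E ≤ t applied to both the per-sequence and per-domain
   E-value (default thresholds 0.001, 0.01, 0.1).
2. **Winner-takes-all greedy assignment** — each overlapping domain is
   attributed to exactly one family: repeatedly select the family with
   the most overlapping domains, award them to it, and retire its
   overlaps; an alternative strategy instead blames, per pair, the hit
   with the higher E-value. Per family, the number of distinct clans its
   retained domains overlap with measures its promiscuity.
3. **Compositional-bias labels** — a family is labelled coiled-coil
   (disordered) when ≥ 50% of its seed members carry ≥ 20 consecutive
   predicted coiled-coil (disordered) residues inside the seed region,
   and transmembrane when ≥ 50% carry ≥ 2 predicted helices; a stricter
   coiled-coil label uses ≥ 50 consecutive residues.
4. **Statistics** — the expected number of chance domains
   `FP = N·E_seq + N·E_seq·E_dom` for N families; cumulative
   overlap-concentration curves over ranked families; label
   overrepresentation folds along the promiscuity ranking; residue-level
   feature proportions inside overlap regions; null2 bias-score
   flagging (families where > 50% of significant domains have
   bias/bit > 0.1) and its enrichment among promiscuous families; and
   the gathering-threshold conversion `E = N·exp[−λ(x − τ)]`.

A seeded synthetic-data generator plants promiscuous families, clan
structure, heptad-like coiled-coil tracks and bias scores with full
ground truth, so every stage is testable without running hmmsearch or
downloading databases.

## Worked example

```python
from clanoverlap import (
    ScenarioConfig, PromiscuityPlan, build_scenario, run_overlap_analysis,
    label_all_families, overrepresentation_curve, cumulative_overlap_curve,
    families_for_fraction, expected_false_positives,
)

config = ScenarioConfig(
    seed=42, n_families=120, n_clans=15,
    frac_cc_families=0.10, cc_fold_promiscuous=4.0,
    promiscuity_plan=tuple(PromiscuityPlan(2 + i % 3, 2) for i in range(10)),
)
scenario = build_scenario(config)
analysis = run_overlap_analysis(scenario.hits, scenario.clans, threshold=0.01)
print(f"overlap pairs: {len(analysis.pairs)}")
print(f"families with overlapping domains: {len(analysis.clan_counts)}")

curve = cumulative_overlap_curve(analysis.assignment)
print(f"families holding 50% of overlapping domains: {families_for_fraction(curve, 0.5)}")

labels = label_all_families(scenario.seeds, scenario.tracks)
ranked = analysis.ranked_families()
enrich = overrepresentation_curve(ranked, labels, scenario.families)
print(f"coiled-coil fold at the promiscuous boundary: {enrich.fold_at('cc20', len(ranked)):.2f}")

print(f"expected false positives, N=120 at E<=0.01: {expected_false_positives(120, 0.01, 0.01):.4f}")
```

prints

```
overlap pairs: 58
families with overlapping domains: 10
families holding 50% of overlapping domains: 4
coiled-coil fold at the promiscuous boundary: 4.00
expected false positives, N=120 at E<=0.01: 1.2120
```

The ten planted promiscuous families generate all 58 cross-clan pairs
and are the only families retaining overlapping domains after greedy
assignment; half of all overlapping domains sit in just four of them.
Coiled-coil labels were planted in promiscuous families at four times
the background rate, and the overrepresentation curve recovers exactly
that fold at the promiscuous-set boundary. The expected-false-positive
count shows how few chance domains the E-value definition predicts at
this scale — observed overlap counts far above it are the signature of
miscalibration.

The same workflow is available from the shell:

```bash
clanoverlap simulate --seed 42 --out-dir demo/
clanoverlap overlap --hits demo/hits.tsv --clans demo/clans.tsv --evalue 0.01 --out pairs.tsv
clanoverlap assign  --hits demo/hits.tsv --clans demo/clans.tsv \
    --out-domains domains.tsv --out-families families.tsv
clanoverlap label   --seeds demo/seed_regions.tsv --tracks demo/tracks.tsv --out labels.tsv
clanoverlap stats   --hits demo/hits.tsv --clans demo/clans.tsv \
    --seeds demo/seed_regions.tsv --tracks demo/tracks.tsv --out-dir stats/
```

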