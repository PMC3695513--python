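# Methods

## The overlap model

A domain hit is one alignment of a family's profile-HMM to a protein
sequence, carrying a per-sequence E-value, a per-domain E-value, a bit
score, a null2 bias-correction score, and two coordinate pairs: the
alignment interval (reliably aligned residues) and the envelope
(equal-or-wider region with substantial probability mass). All
coordinates are 1-based inclusive; an interval (s, e) covers
e − s + 1 residues. The per-domain E-value used throughout is the
*independent* E-value of the per-domain table, because it is the score
comparable across searches; the conditional E-value is meaningful only
within one sequence's set of domains.

Two hits on the same sequence form an **overlap pair** when

- their families differ and lie in different effective clans, where a
  clanless family is its own singleton clan (`SINGLETON:<accession>`),
- their alignment intervals intersect, and
- the intersection covers ≥ 50% of at least one of the two alignments
  (boundary inclusive; intersection computed on alignment coordinates
  with closed-interval arithmetic,
  `max(0, min(e₁,e₂) − max(s₁,s₂) + 1)`).

The ≥ 50% rule excludes overlaps that mere boundary adjustments could
resolve. Significance filtering applies the same threshold to both the
per-sequence and the per-domain E-value (inclusive ≤), reflecting a
universe restricted to families whose curated sequence and domain
thresholds coincide. Overlaps among three or more families are
represented as all qualifying unordered pairs; a domain is
"overlapping" when it is in at least one pair. Two hits of the same
family never pair — same-family co-occurrence is a repeat match, not a
cross-family conflict.

## Winner-takes-all greedy assignment

The analysis needs each overlapping domain attributed to at most one
family. The greedy procedure maintains the list of overlapping domains
and iterates:

1. count, per family, its member domains still listed;
2. select the family with the highest count (ties: lexicographically
   smallest accession, for determinism — the original procedure does
   not specify a tie rule);
3. assign the selected family's listed domains to it and remove them;
4. retire all overlaps involving the selected family; a listed domain
   *all* of whose overlaps involved that one family disappears
   unassigned, while a domain that had overlaps with several families
   stays listed under its own family until that family is selected.

Consequently the attributed-domain set is a subset of all overlapping
domains: the singly-contested partners of a winner are dropped, which
is exactly what makes the winner "absorb" its star of overlaps. The
procedure terminates because every iteration removes one family and at
least one domain from the list. The result is invariant under
permutation of the input pair list.

The alternative E-value-based strategy marks, within each pair, the hit
with the higher per-domain E-value as the suspect domain of its own
family (the lower-E-value hit is presumed genuine). A domain losing in
any one of its pairs is marked once — one confident partner suffices to
cast doubt. Equal E-values break toward the lexicographically larger
accession.

**Promiscuity.** Per family retaining ≥ 1 attributed domain, the number
of distinct effective clans among the partner domains of its attributed
domains (union across domains; a per-domain sum is available behind
`mode="sum"`). A single domain overlapping multiple clans contributes
all of them. Families are ranked by this count, descending.

## Compositional-bias labels

For each family, per-residue predictor output (coiled-coil,
transmembrane, disorder) is evaluated inside each seed member's region;
predictions outside seed regions are ignored so that, e.g., a soluble
domain of a membrane protein is not labelled transmembrane. Per member:

- longest contiguous run of coiled-coil residues (segments clipped to
  the region first) — thresholds 20 and 50 residues;
- longest disorder run — threshold 20;
- number of transmembrane helix segments intersecting the region in at
  least one residue (a helix clipped at the region boundary still
  counts, since predictors emit helices as whole segments).

A label is true when the fraction of members passing its test is
≥ 50% (boundary inclusive). Members with no track count as negative
rather than being skipped. The four labels are computed independently;
no exclusive precedence is applied, since a family can genuinely carry
several. `cc50 ⇒ cc20` holds structurally.

## Statistics

- **Expected false positives.** For N families searched at thresholds
  E_seq and E_dom, `FP = N·E_seq + N·E_seq·E_dom`: N·E_seq chance
  sequences plus N·E_seq·E_dom additional chance domains within them.
  Implemented exactly in this two-term form (no Bonferroni-style
  reinterpretation). Linear in N, monotone in both thresholds.
- **Cumulative curves.** Families ranked by attributed overlapping
  domains (descending, accession tie-break); cumulative proportion of
  all attributed domains; the smallest rank reaching a target fraction
  summarizes concentration ("k families hold 50% of overlaps").
- **Overrepresentation.** fold(x) = (labelled among first x ranked) / x
  ÷ (labelled in universe / |universe|). At x = |universe| the fold is
  identically 1; a label absent from the universe has no defined fold
  and is reported missing.
- **Residue proportions.** Overlap regions are the pair intersections,
  unioned per sequence so a residue in several pairs counts once; per
  feature kind, covered residues / total region residues. The
  conditional variant restricts the denominator to residues of one kind
  and asks what fraction is also predicted as another kind (the
  disorder∩coiled-coil diagnostic).
- **null2 flagging.** Among a family's hits with per-domain E ≤ 0.01,
  the family is flagged when the fraction with bias/bit > 0.1 is
  strictly greater than 0.5 (both cut-offs strict, matching the ">"
  phrasing of the rule). Families with no qualifying hits are excluded.
  Enrichment of flagged families among promiscuous families is the
  ratio of the two proportions.
- **Gathering-threshold conversion.** E = N·exp(−λ(x − τ)) with x the
  curated bit-score threshold, λ > 0 the slope and τ the location
  parameter of the family's score calibration, N the database size.
  Strictly decreasing in x, strictly increasing in N.

## Synthetic scenarios

The generator emulates the *statistical shape* of a large search — a
small promiscuous core producing nearly all cross-clan overlaps over a
quiet background — not its biology. Design:

- **Promiscuous stars.** Each planted promiscuous family gets, per
  planned partner clan, a fresh partner family and `domains_per_clan`
  hit pairs on dedicated sequences; the partner's alignment is shifted
  by at most half its length, so the coverage rule holds by
  construction. Promiscuous accessions sort lowest so greedy
  tie-breaking is deterministic. Planted hit E-values are log-uniform
  in (1e-10, 1e-3), below the 0.01 analysis threshold, so filtering
  never removes planted structure.
- **Background.** Each background family receives 3 hits in disjoint
  windows (5-residue gaps) on a shared sequence pool, so no unplanned
  overlap can arise; their E-values are log-uniform in (1e-6, 10),
  straddling the threshold to exercise filtering. A configurable
  fraction of families is clanless.
- **Labels.** Each family gets 4 seed members on 220-residue sequences
  (seed region 11–210). Planted-positive members receive coiled-coil
  tracks of whole heptad repeats (3–6 repeats → 21–42 residues for the
  20-residue label, 8–12 → 56–84 for the 50-residue label),
  disorder segments of 22–40 residues, or 2–3 helices of 21 residues;
  negatives receive sub-threshold runs (≤ 14 coiled-coil residues,
  ≤ 12 disorder, ≤ 1 helix) and sub-quorum positive counts, so labels
  are recoverable exactly. With `cc_fold_promiscuous = f`, promiscuous
  families draw the coiled-coil label at probability f·p and background
  families at the rate keeping the expected universe proportion at p —
  the planted enrichment the overrepresentation curve should recover.
- **Bias.** Flag-planted families get bias/bit ratios of 0.15–0.30 on
  every hit (and sub-threshold E-values so hits qualify); others stay
  below 0.08.
- **Determinism.** One `numpy` generator seeds everything; identifiers
  are emitted in sorted order; equal seeds give byte-identical files.

Default scale (160 families, 24 clans, 12 promiscuous) keeps a full
scenario-plus-pipeline run in well under a second while exercising every
rule, including tie-breaks and the clanless convention. What passing
recovery tests show is that the pipeline's arithmetic and bookkeeping
are exact on data with known truth; they do not show that real searches
satisfy the generator's idealizations — real overlap structure is not a
disjoint union of stars, real E-values are correlated with bias, and
real predictor tracks have ragged, probabilistic boundaries.

## Numerical and design notes

- Interval arithmetic is integral throughout; the only floating-point
  quantities are E-values, scores and proportions, and all acceptance
  identities (curve endpoints, full-rank folds, E(x=τ)=N) hold exactly
  in double precision.
- The internal hit TSV serializes E-values at 6 significant digits and
  scores at 2 decimals; round-tripping is exact for values written by
  the package.
- Ties are broken lexicographically by accession everywhere a rank or
  selection would otherwise depend on input order.
- Degenerate inputs raise typed errors rather than returning defaults:
  empty curves, empty universes, zero-residue denominators and
  non-positive thresholds are `UndefinedResultError`/`ValueError`;
  malformed files are `ParseError`/`ValidationError` with line numbers.

## Limitations

- The pipeline consumes predictor output; it does not run hmmsearch,
  ncoils, Phobius or IUPred, and it does not build profile-HMMs.
- Observed overlap counts from a real database-scale search are inputs,
  not something the package can reproduce; only the expected-FP side of
  that comparison is computable from first principles.
- An overlap is evidence of annotation error, not proof of a false
  positive: undetected true homology produces overlaps too. The
  statistics here quantify enrichment, and interpretation stays with
  the curator.
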