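# Methods

This package re-implements, as a tested library, the computational core of an
integrative species revision of the Mediterranean clingfish genus *Gouania*:
COI barcode distance analyses on one side, morphometric range diagnostics and
a dichotomous identification key on the other, plus synthetic generators so
every stage runs and can be validated without any sequence downloads.

## Distance model

All genetic distances use Kimura's two-parameter model (K2P/K80): equal base
frequencies, one rate for transitions (A↔G, C↔T) and one for transversions.
For a pair of aligned sequences with transition proportion P and transversion
proportion Q over the valid sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site].

Numerical choices:

* **Pairwise deletion.** For each pair independently, sites where either
  sequence carries `N` or `-` are excluded before counting P and Q. This is
  the standard default for pairwise barcode distances; complete deletion
  would let a single ragged sequence shorten every comparison.
* **Saturation.** When `1-2P-Q <= 0` or `1-2Q <= 0` (or no valid sites
  remain) the distance is undefined. It is flagged as NaN and *excluded from
  means with a warning*, never silently imputed: silent NaN propagation hides
  data problems, and silent zeroing biases means. Clustering refuses to run
  on matrices with undefined entries and names the offending pairs.

## Barcoding gap

For each individual, `max_intra` is the largest distance to a conspecific
(0 for singletons, matching the behaviour of the usual gap functions) and
`min_inter` the smallest distance to any heterospecific; the gap is their
difference, reported in % (distances × 100). A positive gap for every
individual means each barcode is closer to its own species than to any other
— the operational criterion for barcode-based species delimitation.

## Net between-group divergence and its bootstrap SE

For species X and Y, with d_XY the mean of all between-group pairwise
distances and d_X, d_Y the mean within-group distances,

    d_net = d_XY - (d_X + d_Y) / 2.

This is the standard "net between group mean distance": it subtracts the
within-group polymorphism expected to have been present in the common
ancestor. Within-group means over singleton groups are defined as 0 and
flagged. The standard error is a **site bootstrap**: alignment columns are
resampled with replacement, the whole statistic is recomputed per replicate
(default 1000), and the SE is the standard deviation (ddof=1) of the
replicate estimates. Resampling sites rather than individuals matches the
distance-SE bootstrap of the phylogenetics software this analysis style comes
from; it is exactly reproducible given a seed.

## Lineage clustering

`cluster_lineages` applies single-linkage agglomerative clustering to the
distance matrix and cuts at a threshold, default 0.05 substitutions/site.
The default sits in the empirical gap for this genus — intraspecific
divergence stays below ~5.4% while net interspecific divergence starts near
7.7% — so the cut is insensitive to small threshold changes. Labels are
renumbered by first occurrence, making output deterministic. Single linkage
is the natural choice here because a lineage is exactly a connected component
at small distances; ties are handled inside scipy and cannot affect the
partition at a fixed threshold.

## Morphometric system and diagnostics

Measurements are taken in mm and normalised by standard length (SL). Two
printed conventions are supported: **%SL** (value × 100 / SL, the range-table
convention) and **"times in SL"** (SL / value = 100 / %SL, the running-text
convention; note the bounds swap order). Rounding is half-up to one decimal,
the display precision of the published table.

The species range table ships as a packaged fixture transcribed at printed
precision (5 species × 25 characters, holotype value plus paratype range,
SHA-256-guarded), because the published nonoverlap claims were made from the
printed numbers; re-deriving values from raw measurements would silently
shift borderline cases. Each species' *combined range* is the union of the
name-bearing specimen's value and the paratype range. A character is
**diagnostic** between species when their combined ranges are disjoint —
with closed intervals, so ranges that merely touch (e.g. postorbital
distance at 15.2/15.2 between two of the species) count as overlapping: a
specimen at the shared value could not be assigned. That convention is
validated by the published character lists themselves, which exclude exactly
such touching cases. Characters missing for any involved species are skipped
and reported, not treated as nonoverlapping.

Known data discrepancies, carried as-is rather than "fixed":

* One species' diagnosis prints a caudal-fin upper bound of 13.4 %SL while
  the data table gives 11.5–13; the fixture follows the table.
* The published "eleven nonoverlapping characters" list for the slender
  eastern species includes vertical eye diameter, whose tabulated range
  (2.0–2.7) overlaps a comparator's (2.5–4.3). Recomputation from the table
  yields eleven characters too, but with body depth at pectoral fins
  (9.5–10.9 vs ≥11.2 in all three comparators) in place of vertical eye
  diameter. This comparison is therefore not used as a correctness check.

## Identification key

The key is a rooted binary tree of couplets shipped as a data file, so other
keys can be loaded. Evaluation is vote-based per couplet: every character
present in the profile and tested by the couplet votes for the lead whose
predicate it satisfies; a unanimous non-empty vote follows that branch, and
anything else — conflicting votes, no usable character, or a numeric value
falling in the gap between the two leads' intervals (the key is silent about
e.g. a caudal fin of 13.2 %SL between leads spanning 11.1–13.0 and
13.5–17.5) — explores both branches and unions the candidate leaves.
A candidate set is more honest than a forced answer for a genus with
sympatric, near-identical species and intermediate-looking juveniles.
Geographic statements in the key are carried as lead notes but never used as
evidence: identification is character-based, geography corroborative.

## Synthetic data

`simulate_alignment` evolves a uniform-random root sequence site-
independently under the K80 substitution process (transition probabilities in
closed form, rates normalised so branch lengths are in expected
substitutions/site) along a 5-taxon species tree, then spawns individuals
from each tip over independent terminal branches — a star within each
species, which is sufficient to produce the intra/inter divergence structure
the gap analysis needs (it deliberately omits coalescent genealogy,
rate variation among sites, indels and codon structure).

Defaults define the simulated study conditions and were chosen once, to match
the system being emulated:

* `length = 650` — a COI barcode.
* `n_per_species = 10` — the order of per-species sampling in the study.
* `kappa = 4` — transition/transversion rate ratio typical of fish COI.
* `within_depth = 0.02` — expected conspecific distance (2%), inside the
  observed 0–5.4% intraspecific spread. Terminal branches are exponential
  with mean `within_depth/2`, truncated (inverse-CDF) at
  `max_within_distance/2` with `max_within_distance = 0.05`, so true
  conspecific divergence respects the ~5% ceiling observed for the genus;
  an unbounded exponential occasionally produces within-species divergence
  of 7–8%, which the real data do not show.
* Default tree: the two stout sister species separated by a path of 0.08,
  remaining species on a ladder with paths up to 0.14 — chosen so the
  simulated net divergences land inside the 7.69–15.12% envelope reported
  for the genus. The true branching order beyond the one published sister
  relationship is not asserted by this package; the topology is
  configurable.

`simulate_specimens` draws each morphometric character inside the species'
combined published range (uniform, or normal truncated to the range with
mean at the midpoint and sd a quarter of the width), an SL uniform over the
species' published SL span, and stores mm values so %SL conversion recovers
the draws. Simulated specimens are ideal-case by construction — no
measurement error, no allometry, no values outside published ranges — so
closed-loop tests (simulate → identify, simulate → cluster) validate the
machinery, not the field difficulty of real specimens.

What passing the synthetic tests does **not** show: robustness to
misalignment, NUMTs/contamination, heterotachy, or morphometric measurement
error; and the simulated net-divergence envelope is a design target of the
generator, not an independent rediscovery of the published values.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the default
conditions (5 species × 10 individuals × 650 sites; 1000 bootstrap
replicates for the reported net divergences) and the parameter-recovery study
at sequence lengths 500/2000/8000 with 4 replicate alignments and 500
bootstrap replicates each — sizes at which the whole battery completes in
seconds while keeping Monte-Carlo noise well below the tolerances asserted.

## Limitations

* Distances only; no tree inference, dating or coalescent model.
* No multiple sequence alignment: inputs must be pre-aligned or
  equal-length.
* The key engine handles only the predicate forms used by this key
  (categorical equality, closed numeric intervals).
* Printed-precision arithmetic means diagnostics inherit any rounding
  decisions of the source table.
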