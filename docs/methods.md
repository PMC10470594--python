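# Methods

## Data model

A query or reference sequence is an rDNA operon (18S–ITS1–5.8S–ITS2–28S)
or a fragment of one, carried with 0-based half-open region annotations.
The reference database is a fixed multiple alignment of width W, a rooted
tree whose leaf set equals the alignment rows, a taxonomy table
(phylum → species rank paths plus a trophic mode per leaf), and a trim
mask marking the columns used for distance computation. Columns with
under 50% non-gap occupancy are dropped — a simple stand-in for automated
alignment trimming with the same intent (remove gap-riddled columns).
Every query is projected into the reference coordinate system and never
alters it.

## Alignment projection

Queries are aligned to the column-wise profile of the reference (base
frequencies per column) with affine gap costs; the match reward is scaled
by column occupancy so that gap-dominated columns are nearly free to
skip, and end deletions are free so partial-operon amplicons (e.g. an
18S-only OTU against a full-operon reference) align to their region.
Columns consumed by query-specific insertions are discarded: the output
width is always exactly W. The dynamic program runs in a compiled
(numba) kernel; alignment is deterministic, with ties resolved by a fixed
state preference.

## Placement

Placement is deliberately distance-based rather than likelihood-based:
deterministic, fast, and exhaustively verifiable, with the module surface
written so a likelihood scorer could be swapped in later.

For a query q, p-distances to every reference leaf are computed with
pairwise deletion over trim-masked columns (minimum overlap 100 columns;
a query failing the overlap threshold against more than half the leaves
is reported as unplaceable rather than placed badly). For every tree edge
e with length b the model predicts

    d(q, leaf_i) = pendant + distal·s_i + a_i(e),

where `distal ∈ [0, b]` locates the attachment point (distance to the
edge's child), s_i = +1 for leaves below the edge and −1 otherwise, and
a_i is the fixed path length from the corresponding edge endpoint to
leaf i. The constrained weighted least-squares problem per edge has a
closed-form interior solution plus boundary candidates; the edge with the
smallest weighted residual sum of squares wins, ties broken by postorder
edge index. Weights follow Fitch–Margoliash (1/d², with d floored at
10⁻³), so nearby leaves dominate the attachment — without this, distant
leaves swamp the local signal and placements drift by one edge around
short branches.

Two numerical choices matter here:

- **Branch-length refit.** Observed p-distances are compressed relative
  to substitution-unit branch lengths (multiple hits, rate
  heterogeneity). Mixing the two scales biases attachments rootward. The
  placement workspace therefore re-estimates all branch lengths from the
  reference alignment's own p-distances by non-negative least squares on
  the fixed topology, and all placement geometry (including the pendant
  z-statistic below) lives in that single p-distance scale. The input
  tree's lengths are never modified.
- **Saturation guard.** p-distances are capped at 0.75 when building
  distance matrices for tree reconstruction, avoiding undefined
  corrections while staying model-free.

Bootstrap support resamples trim-masked columns with replacement
(multinomial weights), re-places the query, and reports the fraction of
replicates recovering the original edge. Neighbor joining (used for
test-time tree reconstruction from distance matrices) is delegated to
scikit-bio with rows pre-sorted lexicographically for deterministic
tie-breaking and negative branch estimates clamped to zero.

## Split-placement curation

Every candidate OTU is assessed by placing the full sequence and both
halves (split at floor(L/2), the extra base going to the right half; the
halves are re-aligned independently, mirroring how original and divided
sequences are added to a reference alignment separately). Two exclusion
rules, combined as a disjunction by default because they describe
distinct artifact classes:

1. **Chimera** — the half placements are "clearly different", quantified
   two ways, either sufficient:
   - topological: the line-graph distance between the attachment edges
     reaches `topo_threshold` (default 4) **and** the patristic distance
     between the attachment points exceeds the robust outlier scale of
     the reference terminal branches (median + `pendant_k` × scaled MAD).
     The patristic gate exists because in dense clades four near-zero
     length edges separate placements that a reader of the tree would
     call identical; measured on the synthetic benchmark the two
     populations are far apart (clean jitter ≤ ~0.03, true inter-family
     chimeras ≥ ~0.11 at a gate of ~0.045).
   - taxonomic: the deepest rank shared by the two attachment clades is
     shallower than `taxo_rank_threshold` (default family). Nested
     placements — one attachment clade containing the other — count as
     agreement at the deeper clade's deepest labeled rank: lower
     resolution is not conflict.
2. **Long branch** — the full-sequence pendant length is an outlier
   against the reference terminal branch lengths: robust z (median/MAD,
   IQR fallback when MAD is zero) above `pendant_k` (default 5).

Queries whose halves cannot be placed are a separate `failed` category,
never silently excluded; the report enforces
kept + excluded + failed = input. Lowering either threshold can only
grow the excluded set (verified by a property test).

## Lineage delimitation and ecology

Single-cell records are clustered by single-linkage over pairwise
identity (pairwise deletion, trim-masked columns, default threshold
0.99) — the criterion a practitioner would call "nearly identical" —
with the extra requirement that linked members place within 2 edges of
each other, so chance similarity across clades cannot merge lineages.
Lineage ids follow the input order of each lineage's first member; the
representative is the longest member sequence.

Taxonomy is assigned from the representative's placement: a terminal-edge
placement inherits that leaf's full rank path; an internal placement is
assigned the deepest rank shared by all leaves above the edge's parent
node and reported as *novel* at the next rank down (a lineage on the stem
of a family belongs to the order, novel at family). Novelty is a report,
not an assertion of new taxa.

Ecology flags compare the placement clade's trophic annotation with the
observed metadata: a lineage in a clade of fungus parasites whose members
were recorded as epibiotic/endobiotic on a non-fungal host is a
`putative_hyperparasite` (the sequenced fungus was most plausibly
infecting the chytrid rather than the alga); a lineage in a
saprotroph-containing clade on dead/moribund host cells is a
`putative_saprotroph`. Cells whose records fall in ≥ 2 lineages are
reported as multi-lineage (two parasites in one host, or parasite plus
hyper-parasite co-isolated).

Concordance with a curated OTU set takes, per lineage, the nearest OTU by
identity over shared masked columns; `species_level` requires identity
≥ 0.995, otherwise the match level records whether the OTU's placement
shares the lineage's genus or family clade.

## Accounting

The pipeline's bookkeeping mirrors a single-cell study's attrition table:
cells processed → with sequence → on-target (fungal) → retained for
phylogeny. Percentages are of the processed total, rounded half-up to
integers (139/259 = 53.7% prints as 54%); counts must be non-increasing
through the stages.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions all
benchmarks run under.

- **Reference**: Yule (pure-birth) topology — the simplest calibrated
  prior, adequate for placement testing — with default birth rate 25 per
  lineage per unit time and 50 taxa, giving terminal branches of a few
  hundredths of a substitution per site (species-level 18S divergence).
  Sequences evolve root-to-tip under JC (or GTR) with 4-category discrete
  gamma rates (shape 0.5, typical of rRNA) times per-region rate
  multipliers (ITS fastest, 5.8S slowest, length-normalised to mean 1).
  The reference alignment is the gap-free true homology. Taxonomy ranks
  follow clade depth (root children are phyla, then order/family/genus);
  trophic modes cycle over family clades so every guild exists.
- **Queries** (18S): clean descendants of reference leaves at divergence
  0.02; two-parent chimeras (default 20% of queries) joining clean
  descendants of leaves from *different families* at the midpoint
  breakpoint (optionally jittered ±10%); long-branch artifacts (default
  5%) re-evolved at 20× the clean divergence. Short geometric-length
  insertions (rate 0.002/site) exercise the keeplength projection.
- **Cells**: 30 hidden lineage founders diverge from reference leaves by
  half the inter-lineage divergence (0.05); members diverge from their
  founder by half the intra-lineage divergence (0.002). 60 cells draw one
  lineage each (every lineage is covered before reuse) or two with
  probability 0.1. Lineages are hyper-parasitic with probability 0.1:
  their founder comes from a fungus-parasite clade while the metadata
  records an epibiotic habit on an algal host. Two off-target cells from
  a reserved non-target phylum mirror by-catch that the off-target filter
  must remove. A sequencing-success probability (default 1) supports
  attrition-style runs.
- **Determinism**: one seed; sub-streams are spawned per stage, so
  identical parameters give byte-identical outputs.

What the generator does *not* emulate: indel evolution in the reference
(insertions appear only in queries), read-level error profiles,
intragenomic rDNA variation, chimeras with more than two parents or
off-midpoint template switches beyond the ±10% option, and uneven taxon
sampling. Passing benchmarks therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not performance on
raw environmental reads.

## Problem sizes and thresholds used by the test suite

The curation benchmark uses 200 queries against the 50-leaf default
reference for each of seeds 1–5; lineage recovery uses the default cell
set (30 lineages, 60 cells) for seeds 1–5; placement optimality is
checked exhaustively on 8-leaf references and leave-one-out recovery is
pooled over the five default references (250 removals); neighbor joining
is checked on 100 random additive matrices of up to 12 taxa. All default
thresholds (identity 0.99, topo 4, pendant k 5, min overlap 100) are the
package defaults described above.

## Known limitations

- Distance-based placement resolves poorly around very short internal
  edges; a few percent of leave-one-out replacements land one edge away
  from the optimum (attachment at the correct junction, wrong incident
  edge). Likelihood scoring would sharpen this at substantial cost.
- The pendant z long-branch rule assumes the reference terminal branch
  lengths are representative; a reference of mixed very-long and
  very-short branches weakens it.
- Single-linkage identity clustering is sensitive to the threshold when
  true intra/inter-lineage divergences are not separated by an order of
  magnitude; the placement-coherence split mitigates but does not remove
  this.
- The hyper-parasite flag depends on the host-guild lookup (which host
  taxa are themselves fungi); hosts missing from the lookup default to
  non-fungal.
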