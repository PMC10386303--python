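# Methods

## Data model

The pipeline consumes per-read taxonomic classifications in the Kaiju
dialect: one row per read with a status flag (`C`/`U`), a read id, a taxon
id, and — when clade names have been attached — a semicolon-delimited
lineage over the seven canonical ranks (superkingdom, phylum, class, order,
family, genus, species). Only classified reads enter any analysis. A read
whose lineage does not resolve the analysis rank (it was attributed to a
higher node of the taxonomy, as happens when an identical protein sequence
matches several species of one genus) is tallied separately as
*unassigned at rank* so that read totals are always conserved:
`sum(counts) + unassigned = classified reads`. Reads flagged classified but
carrying taxon id 0 are demoted to unclassified with a warning. The reserved
missing-value token in all emitted TSVs is `NA`.

## Diversity indices

For sample *j* with proportions *p₍ᵢⱼ₎* over its *Sⱼ* observed taxa,

- SWI: *Hⱼ* = −Σᵢ *pᵢⱼ* ln *pᵢⱼ*, computed with the natural log and reported
  in nats. The choice of base cancels in the normalised index (asserted as a
  property test for bases e, 2, 10).
- Normalised SWI: *H′ⱼ* = *Hⱼ* / ln *M*, where *M* is the number of distinct
  taxon names with positive count in the union of all samples in the table
  (the observed universe, never a database size). *M* ≥ 2 is required.
  The index is non-negative by construction; a definition with a leading
  minus sign would make it non-positive, which is incompatible with the
  convention that diversity lies in [0, 1], so the positive form is used.
- Abundance index: the sample's total attributed reads at the analysis rank.
  Reads unassigned at that rank are excluded from proportions, from *M* and —
  by default — from the abundance index; `count_unassigned_in_abundance`
  flips the last choice for users who want the raw classified total.

The analysis rank defaults to species and is configurable; with it, *M*
counts species-level taxa only, the documented default.

## Clustering and the stopping rule

Samples are embedded as their scalar normalised SWI (default) or as their
per-taxon relative-abundance vectors (`cluster_features: taxon_profile`) —
both modes are exposed because scalar diversity values and multivariate
diversity profiles are each defensible readings of "clustering samples by
diversity", and they can give different group structures. Euclidean
distances feed a hand-written UPGMA: at each step the pair of clusters with
minimal average-linkage distance merges, with the deterministic tie-break
"smallest (left id, right id) pair"; the linkage update is the size-weighted
mean, which makes fusion heights non-decreasing. scipy's
`linkage(method="average")` and an independent naive quadratic-scan
re-implementation serve as oracles in the tests (heights agree to 1e-9 on
random instances).

The Mojena rule computes θₖ = ᾱ + k·σ̂_α over the n−1 fusion heights, with
the sample standard deviation (ddof = 1, i.e. an n−2 denominator; isolated
in `fusion_sd` so an alternative estimator is a one-line change, since some
formulations standardise the fusion levels first — the unstandardised form
is implemented). k defaults to 1.25. Scanning merges in order, the first
height strictly exceeding θₖ at merge j* (1-based) fixes the partition
immediately before it: n_groups = n − j* + 1; if no height exceeds θₖ the
result is one group. With two leaves there is a single height, its sd is
defined as 0, and the strict inequality yields one group. Group labels
G1..Gg follow dendrogram leaf order.

A practical caveat established by simulation: the rule needs enough
below-threshold fusion heights to estimate ᾱ and σ̂_α; with very small
samples (≈3 points per planted cluster) θₖ overshoots the between-cluster
jumps and the rule under-segments. With ≥ 8 points per cluster and
between-cluster gaps an order of magnitude above the within-cluster spread,
recovery of 2–4 planted 1-D clusters exceeds 95% over seeded draws, which is
the regime the recovery simulations use.

Cophenetic matrices (fusion height of the lowest common merge) are provided
as a test instrument — they are ultrametric for UPGMA — and trees are
exported as rooted Newick with leaf-to-ancestor path lengths equal to half
the fusion height.

## Group comparisons

Two-sided Wilcoxon rank-sum tests compare a per-sample statistic between
depth layers. `mode=auto` enumerates the exact null when min(n₁, n₂) ≤ 10
and the pooled data are tie-free, otherwise it uses the normal approximation
with tie-corrected variance and continuity correction (both routed through
`scipy.stats.mannwhitneyu`; tests cross-check the exact branch against a
full enumeration oracle and the two branches against each other). Constant
data across both groups returns p = 1 with a warning. The reported statistic
is the rank sum W of the first group.

Bonferroni adjustment is min(1, m·p) with the family m = the comparisons
actually performed for one response variable (the three layer pairs form one
family; a pair skipped for want of ≥ 2 samples per group shrinks the
family). Each response — normalised SWI, abundance index, each domain
proportion — is its own family. The annotation ladder is
ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥ ****. All tests are
two-sided; directional claims are read off the group means.

Domain proportions are computed over the closed set {Archaea, Bacteria,
Viruses}; counts outside it are dropped and the remainder renormalised with
a warning (other superkingdoms are out of scope for the domain panel).
Top-N species are ranked by total count over all samples, ties broken
lexicographically, with an `other` bucket completing each sample's simplex.

## Functional profiles

A term's layer frequency is its raw occurrence count: annotation rows of the
layer's pooled reads, one occurrence per row (a read with two annotations
contributes twice — the per-row convention is documented because counting
per read is equally defensible). Counts are not normalised by sequencing
depth by default; `normalize_per_million` rescales display values only. The
top-term matrix shows log10(count + 1) — the +1 keeps the transform total
when a top term is absent from some layer — and raw counts are always
emitted alongside. Term selection is `overall` (largest summed count) by
default with `per_layer` (union of each layer's top n) available, because
"most common overall" and "most common in each layer" are both natural
panels. A term is layer-exclusive when its count is positive in exactly one
layer.

## Synthetic community generator

The generator emulates the statistical structure of a multi-station ocean
survey; its defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| stations × layers × replicates | 8 × 3 × 3 (72 samples) | matches the scale of the surveyed station set |
| read totals | log-uniform on [5·10⁴, 4·10⁷] | spans the observed per-sample attributed-read range; only the extremes are constrained, so a log-uniform stand-in is used |
| species pools | 300 bacteria, 80 archaea, 150 viruses | a compact universe giving M ≈ 530 |
| per-sample richness | SRF 60, DCM 60, MES 150 | plants the mesopelagic diversity excess (2.5×) with a null SRF–DCM contrast |
| species abundances | log-normal, σ = 1.5 | a standard species-abundance distribution; one parameter controls unevenness |
| domain mix (B, A, V) | SRF (0.71, 0.05, 0.24); DCM (0.745, 0.10, 0.155); MES (0.70, 0.25, 0.05) | archaeal share increases and viral share decreases with depth; SRF and DCM mixes have near-equal mixing entropy so the mix itself does not leak a diversity difference between the photic layers |
| unclassified rows | 10% of emitted rows | exercises the classified-only rule; the rate is otherwise unconstrained |
| GO terms | 300 shared + 24/53/10 exclusive to SRF/DCM/MES | exclusive counts mirror the reported layer-exclusive term counts |
| annotation density | 0–2 terms per classified read | sparse multi-annotation |

Per sample, the read total is drawn log-uniformly, per-domain richness is
the layer richness allocated proportionally to the domain mix, species are
drawn uniformly from the domain pool, relative abundances are log-normal
within domains and scaled by the mix, and read counts follow a single
multinomial — so emitted per-read rows aggregate exactly to the drawn
total. The first sample of each layer is guaranteed at least one occurrence
of every term in its layer's set, making planted exclusivity exactly
recoverable; remaining annotations are uniform over the layer set.
Per-sample RNG streams are derived from (seed, sample index, purpose), so a
fixed seed gives byte-identical datasets and the in-memory profile path
(`simulate_profiles`) equals the on-disk per-read path.

With default conditions at a fixed depth of 10⁴ reads/sample, normalised
SWI lands in ≈ [0.33, 0.70] with layer means ≈ 0.51/0.51/0.65, inside the
plausible range for this kind of survey.

What the generator does **not** emulate: sequence-level error, phylogenetic
correlation between species, station- or season-level structure beyond the
layer effects, taxon-dependent classification bias, and any coupling between
taxonomic and functional composition. Passing tests therefore demonstrate
that the pipeline recovers effects of the planted form and magnitude from
multinomial sampling noise — not that real surveys satisfy these models.

## Problem sizes and numerical conventions

Simulation studies run at a fixed reduced depth of 10⁴ reads/sample (2·10³
for tiny end-to-end fixtures): multinomial proportions at that depth carry
per-category standard errors below 0.005, ample for the planted effects,
while keeping any test or script run to seconds. The rank-sum calibration
uses 2000 null replicates at n₁ = n₂ = 10 (true size of the exact two-sided
test there ≈ 0.043); cluster-recovery simulations use 8 points per planted
cluster (see the Mojena caveat above). TSV floats are written with 6
significant digits; distance-matrix symmetry is enforced at 1e-12; oracle
agreement is asserted at 1e-9. Ties in UPGMA merging, species ranking and
term ordering all break deterministically (documented above), so every
product is byte-reproducible under a fixed seed.

## Known limitations

- The Mojena rule is sensitive to the shape of the fusion-height
  distribution; with many singleton merges at similar heights it can cut
  shallower or deeper than a visual reading of the dendrogram would.
- Exact rank-sum enumeration is limited to small tie-free groups; with ties
  the normal approximation is used even for small n.
- No rarefaction or coverage correction: abundance and diversity are
  computed on raw attributed-read counts, so samples differing by orders of
  magnitude in depth are compared on unequal footing (the normalisation by
  ln M bounds but does not depth-correct the index).
- GO terms are treated as opaque identifiers: no ontology-graph propagation,
  namespace filtering (beyond what the caller pre-filters) or enrichment
  testing.
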