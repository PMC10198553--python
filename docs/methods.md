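# Methods

## Scope and data model

`barcodekit` validates single-marker DNA barcode reference libraries. A
library is an ordered set of records, each with a unique accession/process
ID, a family/genus/species taxonomy (one species string maps to exactly one
genus/family pair), voucher and herbarium metadata, and an IUPAC nucleotide
sequence. Sequences are normalised to uppercase with U mapped to T. Libraries
are *aligned* when all sequences share one length; the toolkit consumes
pre-aligned FASTA and the simulator emits gapless alignments — multiple
sequence alignment itself is out of scope.

## Curation rules

Candidates are ranked per species by (voucher present, fewer ambiguous bases,
lexicographic record ID) and taken greedily up to `max_per_species`
(default 3), skipping candidates whose non-empty herbarium string was already
used. The priority order among the three quality criteria is this package's
choice (voucher-backed taxonomy weighs most, since the voucher anchors the
identification); it is configurable. The herbarium-duplicate rule applies
within a species by default (`herbarium_scope="species"`); a global scope is
available because either reading of "no two records from the same herbarium"
is defensible. Ranking is content-based, so selection is invariant to input
order. Singletons are retained: dropping them would silently remove whole
families from a library. The curation step only selects among supplied
candidates; it never searches for replacements — replacement candidates are
inputs.

## Distances

All distances use pairwise deletion: a site is compared only when both
sequences carry an unambiguous A/C/G/T there. Complete deletion would discard
most columns of gap-rich markers such as *trn*L. From the compared sites the
transition proportion P (A↔G, C↔T) and transversion proportion Q give

    K2P: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)
    JC:  d = −¾ ln(1 − 4p/3),  p = P + Q

A pair is *undefined* when a log argument is ≤ 0 (saturation) or no sites are
comparable. Undefined pairs are listed on the matrix and excluded from every
downstream minimum/maximum — substituting a large constant would corrupt
per-sequence minima, so it is never done. For per-family alignments, a
`within_family_only` mode computes distances inside families and marks
cross-family pairs undefined, since columns of independently aligned families
are not comparable; cross-family analyses require one global alignment.

## Neighbor-Joining

Saitou–Nei agglomeration with the Studier–Keppler criterion
`Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`; the joined pair minimises
Q with ties broken by the first minimal (i, j) in scan order (deterministic
and content-independent of everything but the matrix). Limb lengths are
`½·d(i,j) ± (row-sum difference)/(2(r−2))`; reduced distances
`d(u,k) = ½(d(i,k) + d(j,k) − d(i,j))`. The tree is returned unrooted as a
trifurcating root. NJ is exact on additive matrices (tested by inducing
distances from random trees and requiring Robinson–Foulds distance 0 and path
lengths reproduced to 1e−9). Negative limb lengths — possible on non-additive
input — are retained by default; an optional clamp sets them to zero and
transfers the deficit to the sister edge (at the terminal trifurcation, to
the other two star edges), preserving total branch length.

Bootstrap support resamples alignment columns with replacement; each
replicate rebuilds the tree (JC distances by default, matching common
practice for tree-level QC) and each internal bipartition of the point tree
is scored by the fraction of replicates containing it. The resampling stream
depends only on the seed and alignment length, never on leaf order.
Replicates producing a saturated pair are skipped and counted; support is
over completed replicates. Note that on non-additive replicate matrices NJ
does not guarantee that identical sequences form a cherry, so even
"obvious" clades can receive support below 1 — the between-cluster edges are
the stable signal.

## Outlier flagging

Reference-library assembly traditionally includes manual review of the NJ
tree for records that cluster away from their family. The automated
surrogate: compute patristic distances on the tree, and flag a leaf when a
strict majority of its k nearest leaves (default k = 5) carry a different
label at the chosen rank (default family). Leaves whose label has no second
member cannot be assessed and are reported separately. Flagging never
deletes: removal/replacement decisions are judgment calls that belong to
curation inputs, not to the algorithm.

## Barcode gap

Two complementary analyses:

* **Distributions** — every defined pair is classified intraspecific or
  interspecific; medians and ranges are summarised and compared with a
  Wilcoxon rank-sum test. The test uses midranks for ties; for combined
  sample sizes ≤ 12 the p-value is an exact enumeration over all rank
  assignments (needed because ties invalidate the classical exact tables);
  larger samples use the normal approximation with tie-corrected variance and
  continuity correction (delegated to `scipy.stats.mannwhitneyu`).
* **Per-sequence gap** — for each record with at least one defined
  conspecific and one defined heterospecific distance, the gap is
  `min_inter − max_intra`. A gap exists only when strictly positive: a point
  exactly on the 1:1 line of the scatter does not separate the species. The
  species-level proportion calls a species gapped when the minimum of its
  members' `min_inter` exceeds the maximum within-species distance. Both
  levels are reported, because "proportion of sequences" and "proportion of
  taxa" with a gap are both in common use and differ on real data.

## Identification simulations

Leave-one-out on the distance matrix: each record is a query against the
rest. Distance ties are recognised at relative tolerance 1e−9 (identical
sequences must tie despite floating-point rounding).

* **k-NN**: true iff a tied-nearest record shares the query's label
  (`tie_policy="any"`; `"strict"` requires all tied records to). No
  threshold. A rank singleton can never be true, so success rates are also
  reported excluding singletons — exclusion drops singletons as queries but
  keeps them in the reference.
* **Best close match**: no_id if the nearest distance exceeds the threshold;
  otherwise correct/incorrect/ambiguous according to whether all/none/some of
  the tied-nearest records share the label.
* **Threshold-ID**: same verdicts computed over *all* records within the
  threshold. Hence BCM correct ⇒ threshold-ID ∈ {correct, ambiguous}, and
  threshold-ID correct ⇒ BCM correct (property-tested).

Threshold optimization sweeps a grid (default 0.1%–2% in 0.1% steps,
configurable) and counts per query: any other-label record within the
threshold → FP (ambiguous matches are errors); otherwise a non-empty
neighbourhood → TP; an empty neighbourhood with an existing conspecific → FN;
empty with no conspecific (singleton) → TN. The optimum is the smallest
threshold attaining minimal cumulative error FP + FN. The outcome grid report
crosses {singletons included, excluded} × {default 1%, optimized} ×
{k-NN, BCM, threshold-ID}, with k-NN reported once per singleton setting
since it takes no threshold.

## Simulator

Sequences evolve down a fixed star-within-level hierarchy (root → family →
genus → species → individual) under the exact K2P transition probabilities:
with transition rate κβ and each transversion at β, a branch of length d
(expected substitutions/site) has βt = d/(κ+2), and per site

    P(transition)        = ¼ + ¼e^{−4βt} − ½e^{−2(α+β)t}
    P(each transversion) = ¼ − ¼e^{−4βt}

Defaults: 5 families × 2 genera × 5 species × 3 individuals at 600 bp,
d_family = 0.004, d_genus = 0.002, d_species = 0.001, d_intra = 0.0003,
κ = 2, singleton fraction 0.1. Two conspecifics diverge through their species
ancestor, so expected intraspecific distance is 2·d_intra ≈ 0.0006 (median 0
at 600 bp — most conspecific pairs are identical), while the typical
(cross-family) interspecific distance is ≈ 2(d_family + d_genus + d_species +
d_intra) ≈ 0.015: these defaults emulate a conserved plant barcode where the
intraspecific median is 0 and the interspecific median is of order 0.01.
Mislabels are injected by giving a record the full taxonomy of a donor record
from another family; the truth table keeps the original labels, and exactly
`round(fraction × n)` records are mislabeled. A strict-hierarchy flag
(default on) enforces d_family > d_genus > d_species ≥ d_intra.

What the simulator does **not** emulate: indels and alignment uncertainty
(alignments are gapless; pairwise-deletion code paths are tested by masking
sites to N/“-” post hoc), rate heterogeneity across sites, base-composition
bias, within-species coalescent structure, and non-ultrametric real
phylogenies (the hierarchy is star-shaped per level). Passing end-to-end
tests therefore demonstrates correctness of the pipeline's logic under
controlled divergences, not performance on any real marker.

## Numerical and design choices

* Ambiguity codes never count as matches or mismatches anywhere; they are
  excluded sites (and counted per record as `ambiguous_count`).
* Identical-site columns require ≥ 2 unambiguous residues; an all-gap or
  single-residue column is not evidence of conservation. Pairwise identity
  excludes gap-vs-residue sites by default (`gap_policy="exclude"`), with a
  `"mismatch"` alternative, since conventions differ between tools.
* All grids, thresholds and tolerances are explicit parameters; the 1e−9 tie
  tolerance is relative with a 1e−12 absolute floor.
* All randomness (simulation, bootstrap, pipeline) flows through
  `numpy.random.default_rng(seed)`; identical config + seed reproduce every
  output file byte for byte.
* Problem sizes in the test-suite simulations (e.g. 20 seeds of 50 species ×
  3 individuals at 600 bp; 60-leaf trees for mislabel recall) were chosen as
  the smallest libraries that exercise multi-family, multi-genus structure
  with stable statistics.

## Known limitations

* NJ is O(n³) in pure numpy-backed Python; libraries beyond a few thousand
  records will be slow, and bootstrap multiplies that by the replicate count.
* The Wilcoxon exact path enumerates all C(n, n_x) assignments and is
  restricted to combined n ≤ 12 by design.
* Cross-family distances are meaningless under per-family alignment mode;
  the pipeline assumes one global alignment per marker unless told otherwise.
* The identification grid treats ambiguous matches as false positives during
  optimization; a cost-sensitive variant is not provided.
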