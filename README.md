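# barcodekit

Tools for building and validating DNA barcode reference libraries.

Metabarcoding studies (e.g. identifying plants in herbivore faeces from short
*rbc*L or *trn*L fragments) are only as reliable as the reference library the
queries are matched against. `barcodekit` implements the standard validation
workflow for such libraries:

1. **Curation** — select records under explicit quality rules: at most
   *k* individuals per species (default 3), no two records of a species from
   the same herbarium, preference for vouchered records with the fewest
   ambiguous bases. Every rejection carries a machine-readable reason.
2. **Distances** — Kimura two-parameter distances with pairwise deletion,
   `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` where `P` and `Q` are the observed
   transition and transversion proportions, plus Jukes–Cantor
   `d = −¾ ln(1 − 4p/3)`. Saturated pairs are reported as undefined, never
   coerced to a large value.
3. **Phylogeny** — Saitou–Nei Neighbor-Joining (exact on additive matrices),
   bootstrap support by column resampling, and automated taxonomic-outlier
   flagging: a leaf is flagged when most of its *k* nearest leaves by
   patristic distance carry a different family (or other rank) label.
4. **Barcode gap** — both standard views: the intra- vs interspecific
   distance distributions compared with a Wilcoxon rank-sum test, and the
   per-sequence gap `min(interspecific) − max(intraspecific)`, summarised as
   the proportion of sequences (and species) with a strictly positive gap.
5. **Identification** — leave-one-out simulations with three distance-based
   criteria: nearest neighbour (*k*-NN), best close match (only the closest
   records, within a threshold), and threshold-ID (all records within the
   threshold, BOLD-style); plus threshold optimization by sweeping a grid and
   minimising cumulative error (false positives + false negatives).
6. **Simulation** — reference libraries with known family/genus/species
   structure evolved under the K2P substitution process, with controllable
   divergences, singleton fraction and injected mislabels, so every stage is
   testable against ground truth.

## Worked example

Simulate a library of 50 species (10 genera, 5 families, up to 3 individuals
per species, 600 bp) and validate it:

```python
import numpy as np
import barcodekit as bk
import barcodekit.gap_analysis as ga
from barcodekit.synthetic_data import SimulationParams, simulate_library

lib, truth = simulate_library(SimulationParams(seed=7))
print("counts:", lib.counts())

dm = bk.distance_matrix(lib, model="K2P")
labels = lib.labels("species")

dist = ga.split_distances(dm, labels)
print("intra median:", float(np.median(dist.intra)),
      " inter median:", round(float(np.median(dist.inter)), 4))
u, p = ga.rank_sum_test(dist.inter, dist.intra, "greater")
print("wilcoxon p:", f"{p:.3g}")

records, singletons = ga.per_sequence_gap(dm, labels)
print("gap proportion (sequences):", round(ga.gap_proportion(records, "sequence"), 3))

table = bk.optimize_threshold(dm, labels)
print("optimal threshold:", table.optimum)
outcomes, rate = bk.knn_identify(dm, labels)
print("knn success:", round(rate, 4))
```

which prints

```
counts: {'n_records': 140, 'n_species': 50, 'n_genera': 10, 'n_families': 5}
intra median: 0.0  inter median: 0.0152
wilcoxon p: 2.7e-84
gap proportion (sequences): 0.481
optimal threshold: 0.001
knn success: 0.9429
```

Read: conspecific sequences are mostly identical (median intraspecific K2P
distance 0) while heterospecific ones differ (median 0.0152, Wilcoxon
p ≈ 3e-84); still, only 48% of sequences show a strictly positive barcode gap
— closely related congeners overlap — yet nearest-neighbour identification
succeeds for 94% of leave-one-out queries, and the error-minimising
identification threshold is 0.1% K2P distance. Real libraries are read from
FASTA with pipe-delimited taxonomy headers
(`>id|marker|family|genus|species|voucher|herbarium`) or a tab-separated
sidecar via `bk.parse_reference_fasta`.

The same workflow is available from the shell:

```sh
barcodekit simulate --out lib.fasta --seed 7
barcodekit gap lib.fasta --scatter-out scatter.tsv --aligned
barcodekit optimize lib.fasta --out thresholds.tsv --aligned
barcodekit report config.json --outdir results/
```

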