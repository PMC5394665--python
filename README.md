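# floramorph

Morphospace and disparity analysis of mixed-type discrete morphological
character matrices, built around the workflow used to quantify floral
morphological diversity across a large plant order: hundreds of species
scored for a few dozen typed characters (binary, unordered/ordered
categorical, discrete numeric) describing four floral functional modules —
general features, perianth, androecium and gynoecium.

It is aimed at researchers in comparative morphology and macroevolution who
want to go from a taxon × character matrix (with missing and polymorphic
entries) to quantitative statements about which clades occupy which parts of
morphospace, how disparity is distributed among clades, and whether
functionally defined subsets of characters are more or less variable than
the organism as a whole.

## The statistics at its core

**Mean character difference.** For taxa *A*, *B* scored on *N* characters,
each character contributes a difference *d*<sub>ABi</sub> ∈ [0, 1]: numeric
characters use |*x*<sub>A</sub> − *x*<sub>B</sub>| divided by the character's
observed range; ordered categorical characters use the step count divided by
the maximum observed step count; binary and unordered characters contribute
0 if the states match and 1 otherwise. Characters missing in either taxon
are dropped, leaving *N*′ ≤ *N*, and

&nbsp;&nbsp;&nbsp;&nbsp;*D*<sub>AB</sub> = (1/*N*′) Σ *d*<sub>ABi</sub>.

Heavy-tailed counts (stamen numbers, ovules per carpel) are log-transformed
before range normalisation. Polymorphic cells ("4–6 petals") are resolved by
a seeded uniform draw before analysis.

**Morphospace and disparity.** The *D* matrix is ordinated by principal
coordinates analysis (Gower double-centring; negative eigenvalues dropped,
their mass reported; axis variance shares taken over the positive
eigenvalues). Per group the package reports the mean pairwise dissimilarity
D̄, the range *R* = max *D* (plain and rarefied to *n* = 10 taxa), bootstrap
standard errors, and Foote partial disparity
PDiv<sub>g</sub> = Σ<sub>taxa ∈ g</sub> Σ<sub>axes</sub> coord² / *N*<sub>total</sub>,
which sums exactly to total disparity over a partition of the taxa.

**Tests.** Group separation uses PERMANOVA (pseudo-*F* over squared
dissimilarities, label permutations, Bonferroni-corrected pairwise post
hoc); module-versus-whole coupling uses Mantel tests with masked undefined
pairs; differential module disparity uses the random-character-subset test:
the observed D̄ over a module's *k* characters is compared with D̄ over 1000
random *k*-subsets, flagged at the 97.5% criterion, with a pseudo *p* equal
to the extreme-tail fraction plus 0.025 (two-tailed correction).

A synthetic-data generator emulates the study conditions (22 families in 10
clades, 381 extant + 9 fossil taxa, 37 characters split 5/12/13/7 across
modules, 13.4% missing and 2.2% polymorphic cells, fossils near the
morphospace centroid) with every generating parameter recoverable, so the
whole pipeline is exercisable without any data download.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/05_module_disparity.py
```

prints (abridged):

```
dataset: 390 taxa (381 extant + 9 fossil), 37 characters in 4 modules
missing cells: 1937 (13.4%); polymorphic cells: 304 (2.1%)
...
Dchar: min 0.036 (perianth_01_bin), max 0.669 (androecium_06_cat); ...
module test perianth:   observed D-bar = 0.185, null mean = 0.326, pseudo-p = 0.025 -> significantly less variable
module test androecium: observed D-bar = 0.443, null mean = 0.328, pseudo-p = 0.025 -> significantly more variable
module test gynoecium:  observed D-bar = 0.287, null mean = 0.329, pseudo-p = 0.273 -> not significantly less variable
```

Reading this: the perianth's 12 characters vary far less across the dataset
than a random 12-character subset would (its observed mean pairwise
dissimilarity 0.185 falls below the 2.5th percentile of the null, so the
pseudo *p* hits its 0.025 floor), the androecium's 13 characters vary
significantly more, and the gynoecium is indistinguishable from a random
7-character subset — the mosaic of constrained and labile floral modules the
generator was configured to emulate. The numbered drivers `02`–`06` cover
the remaining stages (morphospace, per-clade disparity and its correlates,
PERMANOVA separation, fossil placement) and write their tables under
`results/`.

The same pipeline runs on real data from the standard file formats
(delimited matrix + YAML character typing + metadata tables), either through
the library (`floramorph.run_full_analysis`) or the CLI:

```bash
floramorph run-all --matrix matrix.csv --config characters.yaml \
    --meta taxa.csv --family-meta families.csv --seed 1 --out results/
```

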