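# calscope

Hi-C 3D-genome analysis for multi-cell-type comparisons: ICE matrix
balancing, A/B compartment calling, directionality-index TAD calling, and
**compartment-associating loops (CALs)** — chromatin loops contained within a
single contiguous A/B compartment interval, split into *active* (aCALs) and
*repressed* CALs by the compartment class of the interval they live in.

## Who this is for

Groups comparing chromatin architecture across several cell types — for
example a reference stem-cell population (such as female germline stem
cells, FGSCs) against related stem cells and somatic cells — who want a
single tested pipeline from binned contact matrices to the loop/compartment
signature of the reference cell type, together with CTCF-peak and
RNA-expression integration. Every stage is also usable as a plain library
function, and a synthetic-data generator with planted ground truth makes the
whole pipeline testable at desk scale.

## The analysis

Starting from per-chromosome raw contact matrices *C* (HiC-Pro sparse
triplet text + BED bin table; two replicates per cell type, merged by count
summation):

- **ICE balancing** — iterative correction equalizes bin marginals,
  removing coverage bias; low-coverage bins (bottom 2% of marginals) are
  masked.
- **Contact probability** *p(s)* — mean contact frequency per genomic
  separation *s*, normalized to sum to 1; replicate QC is the Pearson
  correlation of matrix entries at separations ≤ 2 Mb.
- **A/B compartments** — per chromosome at 400-kb bins, the
  observed/expected matrix *O/E(i,j) = C(i,j) / E(|i−j|)* is turned into a
  Pearson correlation matrix; its leading eigenvector (PC1) is oriented so
  it correlates positively with an activity covariate, and the sign gives
  the label: PC1 > 0 ⇒ A, PC1 < 0 ⇒ B. A bin *switches* between cell types
  only when both replicates of both cell types agree in sign pattern.
- **Compartment classes** — k-means (k = 2) on the per-bin PC1 profile
  across cell types, restricted to switching bins; the cluster with higher
  mean reference-cell PC1 is the *activation* class, the other *repression*.
- **Concordant genes** — per gene, the covariance between its FPKM vector
  and its PC1 vector across cell types, ranked against covariances from
  randomly shuffled FPKM vectors (1000 permutations); genes with p < 0.01
  are concordant.
- **TADs** — the directionality index per bin *i* over a 2-Mb window, with
  A/B the upstream/downstream contact sums and E = (A+B)/2:

      DI(i) = sign(B − A) · ((A−E)²/E + (B−E)²/E)

  segmented by a 3-state Gaussian HMM (Viterbi); a TAD runs from a
  downstream-biased run to the end of the next upstream-biased run, and
  inter-TAD gaps < 400 kb are boundaries. The insulation score (log2 mean
  contact crossing each bin in a 500-kb square window, relative to the
  chromosome mean) profiles TAD interiors; TADs are compared across cell
  types as stable / merged / split / reorganized / unique (stable ⇔
  reciprocal overlap > 0.70).
- **Loops, APA, CALs** — loop lists (BEDPE) are scored by aggregate peak
  analysis (APA: center pixel over lower-left corner block of the averaged
  O/E submatrix). A loop is a **CAL** when both anchors fall in the same
  contiguous compartment interval; CALs in activation-class intervals are
  **aCALs**. Gene sets in aCALs / repressed CALs / outside CALs feed
  rank-sum expression comparisons, and aCAL anchors are tested for CTCF-peak
  enrichment against shuffled length-matched controls (Fisher's exact test).

## Worked example

Generate the standard synthetic bundle (2 × 20-Mb chromosomes at 40-kb
bins, five cell types × two replicates, planted compartments, TADs, loops,
expression and CTCF-like peaks) and run the full pipeline:

```bash
calscope simulate --profile small --seed 0 --depth 5e6 --outdir demo
calscope run --bundle demo --outdir demo_out --seed 0
```

or in Python:

```python
from calscope.simulate import write_fixture_bundle
from calscope.pipeline import run_bundle

write_fixture_bundle("demo", profile="small", seed=0, depth=5e6)
res = run_bundle("demo", "demo_out", seed=0)
```

This prints a report (`demo_out/report.md`) whose numbers, for seed 0, are:

```
replicate correlation (FGSC): 0.998
p(s) log-log slope: -1.25
TAD coverage (FGSC): 0.99
APA score: 3.64
loops / CALs / aCAL genes / repressed-CAL genes: 30 5 58 14
concordant genes: 40
aCAL anchor CTCF overlap: 1.00 (control 0.92)
```

Reading them: technical replicates are nearly identical at short range
(r = 0.998); contact frequency decays roughly as s⁻¹ on the log–log scale;
called TADs tile ~99% of the genome; the averaged O/E submatrix at loop
anchors is 3.6-fold enriched over background (the planted focal boost was
3×); 5 of 30 loops sit inside classified switching compartment intervals,
and the 58 genes in aCAL spans are the pipeline's candidate signature gene
set for the reference cell type. Per-stage tables (compartments, switches,
classes, concordance, TADs, types, CALs, gene lists, signal and peak
summaries) are written as TSV next to the report.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main analysis from scratch: it generates the
standard synthetic bundle from the given seed, runs every pipeline stage on
it (matrix QC → compartments → switches → classes → concordance → TADs →
classification → CALs → aCAL split → overlap tests → ChIP/expression
summaries), verifies all stages completed, and writes the acceptance JSON
to `--out`.
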