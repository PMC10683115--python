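# mmplocus

Analysis pipeline for an insulator-partitioned gene cluster: the nine matrix
metalloproteinase (MMP) genes at Chr11q22.2 are split by a CTCF insulator
element downstream of *MMP8* (IE8) into two anti-correlated expression
blocks — a 5' cluster (*MMP7, MMP8, MMP20, MMP27*) and a 3' cluster
(*MMP1, MMP3, MMP10, MMP12, MMP13*). `mmplocus` implements the statistics
that connect this partition to tumor biology, for computational biologists
studying breast-cancer invasion and for anyone who needs a compact,
fully-testable reference implementation of the underlying methods:

- **Signature scoring** — cohort normalization (non-detected replacement by
  the minimal detected signal per gene, log2(count + 1), per-gene
  cohort-median standardization) and the locus scores
  `ratio = mean(3' genes) − mean(5' genes)` and `MMP1 − MMP8` on the
  standardized log2 scale (the log of a geometric-mean expression ratio).
- **Coexpression boundary detection** — a scan statistic over the gene-gene
  correlation matrix: for each split k of the coordinate-ordered genes,
  `score(k) = mean(within-block r) − mean(between-block r)`, with an exact
  max-statistic permutation test.
- **Outcome association** — Kaplan–Meier product-limit curves, the
  two-group log-rank test `χ² = (O₁ − E₁)²/V`, the O/E (Pike) hazard ratio
  `HR = (O₁/E₁)/(O₂/E₂)` with `SE(log HR) = √(1/E₁ + 1/E₂)`, and ROC/AUC as
  the midrank Mann–Whitney concordance probability with a class-stratified
  bootstrap CI — all implemented from first principles and verified against
  brute-force oracles and independent libraries.
- **Differential chromatin accessibility** — consensus-peak classification
  by unique presence or intensity shift (Welch t on log2 CPM +
  Benjamini–Hochberg), anchor-centric windowed enrichment via the
  representation factor `RF = (k/n)/(K/N)` with an exact hypergeometric
  upper-tail p, and ±2 kb TSS accessibility-delta profiles by gene cluster.
- **Chromatin architecture** — sliding-square insulation scores on binned
  contact matrices, TAD-boundary calling, anchor colocalization, CTCF motif
  annotation with convergent-pair enumeration, and the eQTL
  "same-side-of-boundary" statistic with an exact permutation test.
- **Synthetic data** — seedable generators for every input (correlated
  expression via a Gaussian copula, survival/progression outcomes,
  replicate ATAC peak sets with planted boundary-proximal differentials,
  two-domain contact matrices with distance decay, eQTL links with
  same-side preference), so the whole pipeline is verifiable at desk scale
  without any external download.

The four fit-shaped stages are scikit-learn estimators
(`SignatureScorer`, `CoexpressionBoundaryScanner`,
`DifferentialPeakClassifier`, `InsulationBoundaryCaller`) that compose with
sklearn pipelines; everything else is plain functions.

## Worked example

Simulate an invasive-cohort dataset (417 samples, study-scale defaults) and
run the pipeline:

```bash
mmplocus simulate --preset tnbc --seed 7 --out data
mmplocus score --expression data/expression.tsv --out scores
mmplocus survival --scores scores/scores.tsv --outcomes data/outcomes.csv --out surv
mmplocus coexpression --expression data/expression.tsv --seed 7 --out coexp
mmplocus insulation --contacts data/contacts.tsv \
    --anchor "chr11:102,732,801-102,733,900" --out ins
mmplocus eqtl --links data/eqtl.tsv --seed 7 --out eqtl
```

which prints

```
wrote synthetic dataset to data
wrote scores for 417 samples to scores
log-rank p = 0.0001381, HR = 1.78 [1.32, 2.39]
split between MMP8 and MMP10 (score 0.550, p 0.00468)
boundaries at bins [50]
same-side fraction = 0.905 (p = 0.000853)
```

Reading the output: samples with an above-median 3'/5' ratio relapse faster
(hazard ratio 1.78 against the low-ratio group, log-rank p ≈ 1.4 × 10⁻⁴);
the coexpression scan places the expression partition between *MMP8* and
*MMP10*, exactly where the IE8 insulator sits; the insulation profile of
the simulated contact matrix calls one TAD boundary at bin 50, the bin
containing IE8 (the `insulation` summary reports
`anchor_colocalized: true`); and 90.5% of simulated eQTL links stay on one
side of the boundary, far more than the permutation null allows
(p ≈ 8.5 × 10⁻⁴). Each output directory also contains tidy TSV tables and
a JSON summary with the seed and SHA-256 of every input, so runs chain by
content hash and are byte-reproducible.

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generators and what they do and do not emulate, the numerical conventions
(coordinate systems, tie rules, permutation tests), and known limitations.
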