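# ligandsweep

Peptide-level FDR sweeping and HLA-binding filtering for immunopeptidomics,
with a ground-truthed synthetic ligandome generator.

## The problem

HLA class I immunopeptidomics identifies the peptides presented to CD8 T
cells by eluting them from HLA and matching MS/MS spectra against a
proteome database. The search engine controls false discoveries with a
target-decoy FDR threshold — conventionally 1%, inherited from tryptic
proteomics. But HLA ligands are non-tryptic, and candidate epitopes are
precious: many labs therefore relax the peptide FDR toward 5% and then
filter the surplus identifications by *predicted HLA binding* (IC50 ≤ 500 nM
or percent rank ≤ 2% for an allele the source cells express). The empirical
questions this package quantifies, end to end and with known ground truth:

* how does the accepted peptide set grow as the FDR threshold α is relaxed,
  and does the fraction of predicted HLA-binders among 9–11mers stay stable
  while it grows?
* do scrambled (composition-matched) peptide sets and mismatched HLA alleles
  stay at the Monte-Carlo chance rate, confirming the binding filter responds
  to motif content and not composition?
* are binders found only in the relaxed 1–5% band of a low-input sample
  recovered at a strict 1% FDR when cell input increases?
* how strongly do identified peptides favour abundant source proteins, as a
  cumulative coverage curve over the abundance-ranked proteome?

Because deep ligandome datasets with per-peptide truth are not public, the
package ships a simulator that generates PSM tables with the statistical
structure these analyses assume — log-normal protein abundances,
anchor-motif binders (P2/C-terminal), copy-number-dependent scores
`score = μ_true + log₂(input_scale · c) + ε`, exchangeable decoy/false score
populations, and an ALC-style de novo substitution channel — so every
pipeline property (FDR calibration, rank uniformity, control behaviour,
rescue monotonicity) is *tested*, not assumed. The same functions accept any
external TSV of scored PSMs.

## Core statistics

* **Target-decoy FDR.** After collapsing PSMs to peptides (best score per
  sequence), `FDR(c) = D(c)/T(c)`; the cutoff for level α is the smallest
  observed target score with `FDR ≤ α`. Accepted sets are nested in α.
* **Binder call.** Per allele and length ∈ {9,10,11}, a PSSM raw score; a
  percent rank against a 5000-peptide random background; an IC50 from
  `50000^(1−s)` nM with `s` affine-calibrated so rank 2% ↔ 500 nM. Binder ⇔
  IC50 ≤ 500 nM **or** rank ≤ 2%, for ≥1 expressed allele.
* **Controls.** Dataset-level scrambling (pool → permute → repartition,
  exact composition conservation) and mismatch-allele prediction, both
  compared one-sidedly against a composition-matched Monte-Carlo chance rate.
* **Rescue.** Band = binders accepted at α_relaxed but not α_strict in the
  low-input sample; recovery = fraction of the band accepted at α_strict in
  the high-input sample.
* **Abundance coverage.** Barcode of immunopeptidome hits along the
  abundance-ranked proteome; cumulative hit percentage vs the diagonal;
  half-coverage rank (top-% of proteins yielding 50% of hits); proteome
  coverage and mapped-source percentages.

## Worked example

```bash
ligandsweep replay --out out/ --seed 0
```

runs simulate → FDR sweep → binder calls → controls → rescue → abundance on
the default synthetic experiment (1000 proteins, 2000 true PSMs, 10%
false-match rate, alleles A\*02:01 + B\*07:02, mismatch A\*03:01) and prints:

```
FDR sweep (low-input sample):
 fdr_threshold  score_cutoff  n_total_peptides  n_9_11  n_binders  pct_binders
         0.001      2.633733              1035     928        773    83.297414
         0.010      1.485365              1676    1503       1241    82.568197
         0.050      0.210983              2068    1847       1472    79.696806

Rescue: 230 of 231 band binders (99.6%) recovered at the strict threshold in
the high-input sample; 0 more in its relaxed band.

Abundance-rank coverage:
  fdr_0.01: half-coverage at top 19.80% of ranked proteins; proteome coverage 33.40%; ...
  fdr_0.05: half-coverage at top 23.60% of ranked proteins; proteome coverage 40.60%; ...
```

Reading it: doubling the accepted peptides (1035 → 2068) by relaxing α from
0.1% to 5% moves the binder percentage by < 4 points — the extra
identifications are overwhelmingly motif-bearing, not noise. The controls
table in the same run shows scrambled and mismatch fractions at ~6% and
~0.5% (at or below the composition-matched chance rate of ~5.9%), and nearly
all band binders reappear at 1% FDR when input is 9×. The coverage numbers
say half of all source-protein hits come from the top ~20% most abundant
proteins — an abundance bias that relaxing α dilutes slightly.

The same stages are available piecewise (`ligandsweep simulate / fdr / bind /
controls / sweep / rescue / abundance`) on external TSV/FASTA inputs, and as
library functions (`ligandsweep.build_sweep`, `rescue_analysis`,
`abundance_ranking`, …).

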