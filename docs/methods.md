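# Methods

`ligandsweep` studies a question that comes up whenever HLA class I
ligandomes are read out by LC-MS/MS: how permissive may the peptide-level
false-discovery-rate (FDR) threshold be before the extra identifications stop
being real HLA ligands, and how much can HLA-binding prediction recover from
the sub-threshold pool? Because deep ligandome datasets with per-peptide
ground truth are not generally available, the package pairs the analysis code
with a generator that produces ligandome-shaped PSM tables *with* ground
truth, so every statistical property of the pipeline can be verified rather
than assumed.

## The synthetic ligandome model

**Proteome.** `n_proteins` random amino-acid sequences of length 100–1000,
with relative abundances drawn log-normal(0, `abundance_sigma`). The default
`abundance_sigma = 2` (natural-log scale) spreads abundances over roughly
four orders of magnitude, the dynamic range a deep cell-line proteome
quantification typically spans. Setting `abundance_sigma = 0` degenerates to
a flat proteome and therefore to abundance-indifferent peptide sampling — the
null condition for the coverage-curve analysis.

**True peptides.** Each of `n_true_psms` true identifications picks a source
protein with probability proportional to abundance and a length from
`length_weights` (default: 88% of mass on 9–11mers, small shoulders at 8 and
12–13). Windows inside a protein are placed without overlap by
stars-and-bars gap sampling: the protein's unoccupied residues are split
into random gaps between consecutive windows. When an abundant protein is
asked for more residues than it has, the excess peptides are re-drawn from
the abundance-weighted pool (capping how many peptides one hot protein can
host; the rank correlation between abundance and peptide yield remains
strong). A fraction `true_binder_fraction` (default 0.85) of true peptides
receives the anchor motif of a uniformly chosen cell allele: the P2 and
C-terminal residues are overwritten *in the source protein*, and peptides
are then re-extracted, so every true peptide is an exact substring of the
emitted proteome FASTA and every implanted peptide provably carries its
motif.

**Scores.** PSM scores live on an arbitrary "−10lgP-like" axis. A true
peptide with copy number `c ~ Geometric(1/2)` scores

    score = score_shift_true + log2(input_scale · c) + ε,   ε ~ N(0, 1)

while false matches (random sequences credited to a random database protein)
and decoys score `score_shift_false + ε`. The defaults
(`score_shift_true = 2`, `score_shift_false = 0`) overlap the two
populations enough that FDR thresholds between 0.1% and 5% carve out
meaningfully different peptide sets. `input_scale` is the cell-input
analogue: using more input multiplies every copy number, shifting true
scores up by `log2(scale)` while leaving the noise populations untouched —
this is what lets borderline peptides be "rescued" at stricter thresholds in
high-input runs. Because the peptide skeleton (identities, sources, copy
numbers, implants) and the score noise flow from separate named random
substreams, two configs differing only in `input_scale` share their
skeleton, and an explicit `score_seed` re-draws only the acquisition noise
(an independent MS run of the same sample).

**Decoys.** Decoy PSMs are within-peptide shuffles of target sequences
(composition-preserving), scored from the same distribution as false
matches, and equal in *count* to the false matches. This mirrors competitive
target-decoy searching, where a noise spectrum is equally likely to land in
the target or the decoy database, so the decoy count tracks the
false-target count. That choice — rather than one decoy per target — is what
makes the plain decoy-count estimator below unbiased on this simulator, and
it is verified empirically by the calibration test.

**De novo channel.** Per-residue substitution with probability
`(100 − ALC)/200`, uniform over the 19 alternative residues, no indels. Full
confidence (ALC = 100) is the identity; the linear slope is a stand-in, as
no quantitative confidence-to-error mapping is published for de novo
sequencing scores — only the direction of the relationship is meaningful
here, and only the direction is asserted anywhere.

## FDR estimation

PSMs are collapsed to peptides (best score per sequence, targets and decoys
kept separate). At cutoff `c` the estimated FDR is `D(c)/T(c)`, the decoy
count over the target count at or above `c`; the threshold for level `α` is
the smallest observed target score whose estimate does not exceed `α`, with
ties at the cutoff accepted. No +1 correction, no π₀ correction, no q-value
monotonisation: the plain estimator is the canonical published form and the
grid scan is verified against exhaustive cutoff enumeration. Accepted sets
are provably nested across `α` (the feasible cutoff set only grows), which
the sweep relies on. Realized false-discovery proportions at α = 1% and 5%
match the nominal level within 3 binomial standard errors over 20
simulations.

## HLA-binding prediction

One position-specific scoring matrix per allele and length (9, 10, 11): small
Gaussian position/residue preferences (sd 0.25) plus weight 3.0 on the
allowed residues at the two anchors. The raw score is the sum over
positions. Two derived quantities reproduce the output contract of
affinity-prediction tools:

* **percent rank** — the raw score's rank within 5000 random background
  peptides of the same length (ties counted as ≥); by the
  probability-integral transform a background-distributed peptide's rank is
  Uniform(0, 100), which the suite verifies (2% ± 0.5% below rank 2).
* **IC50** — `50000^(1−s)` nM on an affine-normalised score `s`, clamped to
  [0, 1]. The normalisation is calibrated per length from the background so
  that the median background score maps to ≈30000 nM and the top-2%
  background quantile maps to 500 nM. This makes the two conventional binder
  criteria — IC50 ≤ 500 nM, rank ≤ 2% — coincide at the same operating
  point, the weak-binder convention of the NetMHC family. (Anchoring the
  normalisation instead to extreme background percentiles would drag the
  500 nM point into the single-anchor score region and call ~20% of random
  peptides binders, which no affinity predictor does.)

A peptide is a binder if either criterion holds; at the dataset level, if it
binds any allele of the panel. 10/11mers get their own matrices with anchors
at P2 and the C-terminus — no 9mer-core alignment as in production
pan-length predictors; this keeps the scoring exactly specified and
testable. Mismatch alleles are ordinary profiles whose anchor-residue sets
are disjoint from the expressed panel at both anchors; no special code path.

## Negative controls

The scrambled control pools all residues of a 9–11mer set, permutes the
pool, and re-partitions it into the original lengths in order — conserving
count, length multiset and pooled composition *exactly* (dataset-level
conservation; per-peptide shuffling would conserve a stronger, unstated
property). The chance reference is Monte-Carlo: random peptides with i.i.d.
residues at the pooled frequencies. Control comparisons are one-sided
(control fraction must not *exceed* chance): a motif-stripped or
mismatch-typed dataset sitting below chance is fully consistent with what
the control is for, and the mismatch arm in fact sits systematically
slightly below the composition-matched rate because implanted peptides hold
fixed non-mismatch residues at the anchor positions that composition
matching redistributes. Across simulations the pooled comparison uses a
one-sided binomial test at α = 0.01; per simulation, a 3-standard-error
bound whose SE combines peptide-set and Monte-Carlo sampling error.

## Rescue analysis

Band = predicted binders among 9–11mers accepted at the relaxed threshold
but not the strict one, evaluated in the low-input sample only. The
high-input lookup matches exact sequences (I/L distinct). Reported:
how many band peptides the high-input run recovers already at the strict
threshold, how many only in its own relaxed band, and the recovery
fraction (tagged missing when the band is empty). At the defaults
(strict 1%, relaxed 5%, 9× input, independent score noise) recovery is
~99%, and it exceeds the equal-input technical-replicate baseline in every
paired simulation.

## Abundance-rank coverage

Proteins are ranked by mean abundance across replicate columns, descending,
ties broken lexicographically; duplicate accessions are aggregated by mean
with a logged notice; UniProt-style `sp|…|` prefixes are stripped before
matching. The barcode marks ranked proteins contributing ≥1 accepted 9–11mer
(every listed accession of a shared peptide gets credit; no parsimony).
The cumulative curve reports, at each rank, the percentage of all hits found
so far; the half-coverage statistic is the percentage of top-ranked proteins
needed to reach 50% of hits (<50 means abundance bias; ≈50 under uniform
sampling, where the whole curve stays inside a 99%
Dvoretzky–Kiefer–Wolfowitz band of the diagonal). Source proteins absent
from the ranked list are reported separately as unmapped, never silently
dropped.

## Numerical and interface choices

* All randomness derives from a root seed through named substreams
  (`proteome`, `peptides`, `scores`, `noise`, `profiles`, `scramble`,
  `chance`), so stages can be re-run independently and full replays are
  byte-identical.
* Tables are TSV, UTF-8, '.' decimals, fixed column order; floats round-trip
  exactly (`float_precision="round_trip"` on read). Peptides are uppercase;
  I/L are never collapsed.
* Undefined statistics are tagged, not zeroed: binder percentage with no
  9–11mers is NaN; recovery fraction with an empty band is NaN; a zero-hit
  barcode or empty source list raises.
* Degenerate inputs raise typed errors (`InvalidArgumentError`,
  `LengthError`, `AlphabetError`, `ConfigurationError`,
  `UndefinedStatisticError`); configuration validation reports all
  violations at once.

## Default problem sizes

The shipped defaults — 1000 proteins, 2000 true PSMs, 10% false-match rate,
two expressed alleles, one mismatch allele, 5000-peptide backgrounds,
20 000-draw Monte-Carlo chance estimates, 10–20 simulations per statistical
check — were chosen so that every binomial/KS comparison in the test suite
has comfortable power while a full test run stays in the low minutes on one
CPU. They are the package's study conditions, fixed once; analyses of real
PSM tables are unaffected by them.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* the analysis assumes:
overlapping true/false score populations, exchangeable decoy and false
scores, motif-bearing true binders, abundance-biased sampling, and
input-scaled score shifts. It does not model spectra (m/z, fragmentation,
chimeras), retention time, post-translational modifications, peptide length
effects on fragmentation quality, shared peptides across proteins, or
engine-specific score distributions. Tests passing here therefore certify
the pipeline's correctness and calibration under its stated assumptions —
not that any particular real dataset satisfies those assumptions. In
particular, the binding predictor shares its anchor-motif family with the
generator by design; on real data a production predictor should stand in
behind the same interface.
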