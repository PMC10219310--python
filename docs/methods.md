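# Methods

## Problem and model

A somatic missense SNV substitutes one residue in a protein. The
resulting neoantigen candidates are the peptide windows that contain
the substituted residue. `neovax` works with two window conventions:

- **comparison arm** — contexts of length 17 with the mutation at the
  9th residue, so that every 9-mer sliding window (the classical HLA-I
  epitope length) covers the mutation, and every Class II 15-mer window
  does too;
- **design arm** — contexts of length 15 with the mutation at the 8th
  residue (centered), the optimal input length for the Class II
  predictor and the length of the final vaccine constituents.

Genomic coordinates are 1-based (VCF convention); all within-peptide
offsets are 0-based; intervals are half-open internally. Somatic status
is presence/absence on the (chrom, pos, ref, alt) key — variant allele
fraction (VAF) plays no role in filtering and is carried through as the
variant-frequency score. Stop-gain and stop-loss variants are flagged
and excluded from context extraction rather than silently dropped;
contexts clipped at a protein terminus are retained at their true
shorter length and simply yield fewer (possibly zero) windows
downstream. Each SNV is treated independently: co-occurring mutations
within one codon or one window are not merged, a known limitation.

Coding models carry no chromosome field; a variant is matched to the
model whose contig label (the transcript id) equals its CHROM. This
suits the one-CDS-per-contig layout the synthetic generator emits; real
annotations would need a thin adapter.

## Window enumeration

For a context of length C with mutation offset m (0-based), the windows
of length L are the starts s with max(0, m−L+1) ≤ s ≤ min(m, C−L).
Class I uses L ∈ {9,…,14}, Class II L = 15. A full 17-mer context with
m = 8 therefore yields 39 Class I windows (9+8+7+6+5+4) and 3 Class II
windows; the default cohort (6 patients × 24 mutations = 144 contexts)
yields 5616, 432 and 6048 windows in total. Windows are never
deduplicated across contexts by sequence identity: totals are
per-(context, window), the only convention consistent with those
counts. Output order is (parent, class, length, start), so emitted
files are byte-reproducible.

## Scoring

Per 15-mer candidate the seven raw variables are gathered as:

| variable | source | reduction | direction |
|---|---|---|---|
| imm | Class I immunogenicity over the 7 nine-mers | max | higher better |
| hlaI | HLA-I percentile rank, 9-mers × Class I alleles | min | lower better |
| hlaII | HLA-II percentile rank, the 15-mer × Class II alleles | min | lower better |
| vf | variant allele fraction | pass-through | higher better |
| ap | VaxiJen antigen probability of the 15-mer | max | higher better |
| hpl | GRAVY of the 15-mer (mean Kyte–Doolittle hydropathy) | — | lower better |
| tap | TAP/proteasome score over the 9-mers | max | higher better |

Best-case reduction (min for ranks, max for scores) is standard
epitope-pipeline practice; directions are configurable since reasonable
alternatives exist (e.g. rewarding hydrophobic rather than hydrophilic
candidates). Low GRAVY means hydrophilic, hence "lower better" when the
goal is surface exposure.

Each variable is min–max normalized over the full candidate set of one
patient run — the only population available — so the best candidate
maps to 1 and the worst to 0; a constant column maps to 0.5 everywhere,
keeping the variable neutral rather than uniformly (un)favorable.
Candidates with missing predictor values are excluded and logged, never
imputed with zeros, which would bias f. The aggregate is the weighted
sum with default weights (0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1): the three
binding/immunogenicity variables carry double weight. Weights must be
non-negative and sum to 1.

Because F(S) = Σ f(n) is additive, the cardinality-k maximizer is
exactly the k candidates with the highest f; ties are broken
lexicographically by sequence for determinism. Assembly concatenates
consecutive groups (default trios) **in the caller-supplied order** —
selection order and input order generally differ, and the pipeline uses
input (genomic) order, which reproduces published peptide layouts when
fed tables in their printed order. No junctional-epitope screening is
performed on the fused 45-mers; the properties of a concatenated
peptide can differ from those of its parts.

## Cohort statistics

A window "passes" when its best (minimum) percentile rank over the
patient's alleles of the class meets the cutoff (1% for Class I, 10%
for Class II); per-(window, allele) counting is available behind a
switch. Class I counting pools all lengths 9–14. Percent summaries use
the sample standard deviation (n−1).

Normality is checked with Shapiro–Wilk for n ≤ 30 and a
Kolmogorov–Smirnov-type test for larger samples; since mean and
variance are estimated from the data, the large-n branch applies the
Lilliefors correction rather than the plain KS distribution, which
would be anticonservative. The group comparison is a two-sided
independent t-test (Student's by default, Welch behind a flag); the
per-patient comparison is a one-sided paired t-test of
H1: mean(mutated − wild-type) > 0 at α = 0.05, reported with the
one-sided CI (lower bound, ∞). Degenerate conventions: identical
two-sample inputs report (t = 0, p = 1); all-zero paired differences
report (t = 0, p = 0.5); constant non-zero differences have zero
variance and are flagged with p → 0 (or 1) and an infinite statistic.
No multiple-testing correction is applied across the three comparisons,
and no non-parametric fallback is provided.

## Synthetic cohorts

The generator's defaults are the study layout: 6 patients × 24 somatic
missense SNVs, 17/9 contexts, 2 alleles per MHC class, and a germline
duplication fraction of 0.25 (one quarter of each tumor list also
appears in the germline, so somatic filtering demonstrably removes
exactly that quarter). Each SNV gets its own uniform-codon CDS with the
mutation placed so the full-length context always fits; the edit is
drawn from the codon's missense, non-stop single-base substitutions.
VAFs are Uniform(0.05, 0.95). Allele strings follow the
`HLA-locus*GG:PP:01` nomenclature shape with diploid-like pairs per
class. Everything is deterministic under (spec, seed) down to file
bytes.

Predictor tables use the natural null for a rank-transformed predictor:
percentile ranks i.i.d. Uniform(0, 100) per (window, allele), score
metrics i.i.d. Uniform(0, 1). The mutated-vs-wild-type Class II effect
is a multiplicative shrinkage — mutated ranks × (1 − δ) — which keeps
ranks in range without truncation artifacts; the per-draw pass
probability at threshold t is min(1, t / (100(1 − δ))): 10% at δ = 0
and 20% at δ = 0.5 for t = 10. What the generator does **not** emulate:
mutational signatures, linkage between mutations, realistic HLA allele
frequencies, and any sequence-dependence of predictor values — so
passing tests demonstrate the correctness and calibration of the
machinery, not predictive performance on real tumors.

`plant_optimum` rewrites a raw score table so a chosen candidate set
provably wins selection: planted rows move to each column's best value
(normalizing to 1, f = 1) and the rest shrink toward the worst by
(1 − margin) in normalized space, capping their f at 1 − margin. If the
planted set already clears the margin the table is returned unchanged.

## Calibration experiments and problem sizes

The type-I error of the paired Class II test is estimated on 2000
simulated 6-patient cohorts (null δ = 0) and its power on 800 cohorts
per δ ∈ {0.2, 0.4, 0.6}; these sizes put the Monte-Carlo standard error
of the null rate near 0.005 while the whole experiment stays in the
seconds range, thanks to a vectorized rank-cohort generator
(`simulate_hla2_counts`) that draws from exactly the same distributional
model as the table writer — a unit test feeds one identical rank
tensor through both the vectorized counter and the DataFrame counting
path to prove they agree. Each simulated cohort's p-value still goes
through the package's own paired-test implementation.

Selection optimality is verified against exhaustive enumeration of all
C(12, 6) = 924 subsets on 100 random instances; GRAVY against a literal
Kyte–Doolittle table (and Biopython's independent implementation);
translation against a literal codon-table oracle; t-tests against the
closed-form formulas on 6-element vectors.

## Known limitations

- Single-nucleotide missense variants only: no indels, MNVs,
  splice-aware transcript models, or genome-build liftover.
- Published cohort-level test statistics depend on the original study's
  raw predictor tables and are validated here at the procedure level
  (formula oracles + calibration), not reproduced numerically.
- The concatenation order of selected neoantigens within the final
  peptides is an input convention, not an optimized quantity.
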