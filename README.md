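# neovax

Neoantigen prioritization and vaccine-peptide design from somatic
variants, for immunoinformaticians building personalized cancer
vaccines from small tumor/germline sequencing panels.

Tumor-specific missense mutations give rise to neoantigens — mutated
peptides that the patient's HLA molecules may present to T cells.
`neovax` implements the full in-silico path from variant calls to
synthesis-ready vaccine peptides:

1. **Somatic filtering** — keep tumor variants absent from the
   patient's germline, by (chrom, pos, ref, alt) identity.
2. **Mutation-centered contexts** — translate each missense SNV and cut
   the surrounding peptide window: 17-mers with the mutation at the 9th
   residue for the cohort-comparison arm, 15-mers with the mutation at
   the 8th residue for the vaccine-design arm.
3. **Window enumeration** — every sliding window covering the mutation:
   MHC Class I lengths 9–14, Class II length 15, and the seven 9-mer
   sub-windows of each 15-mer, always paired with the wild-type
   counterpart.
4. **Cohort comparison** — count mutated vs wild-type windows whose
   best percentile rank over the patient's alleles passes the IEDB
   cutoffs (≤ 1% for Class I, ≤ 10% for Class II), then run
   normality-gated two-sample and one-sided paired t-tests per class.
5. **Seven-variable scoring** — per 15-mer candidate *n*, gather Class I
   immunogenicity, HLA-I and HLA-II percentile ranks, variant
   frequency, VaxiJen antigen probability, GRAVY hydrophilicity and
   TAP/proteasome processing; min–max normalize each variable over the
   candidate set (direction-aware) and aggregate

   f(n) = 0.2·(N_imm + N_HLAI + N_HLAII) + 0.1·(N_vf + N_ap + N_hpl + N_TAP)

6. **Selection and assembly** — maximize F(S) = Σ_{n∈S} f(n) over
   subsets of cardinality k = 6 (exactly the top-6 by f, since the
   objective is additive) and concatenate consecutive trios of 15-mers
   into two 45-mer vaccine peptides.

External predictors (IEDB MHC-I/II, Class I immunogenicity,
TAP/proteasome, VaxiJen) are consumed as TSV tables, never re-run; a
seeded synthetic-cohort generator (`neovax.simulate`) emulates variant
sets, HLA genotypes and predictor tables so the whole pipeline is
testable offline.

## Worked example

The score-table bypass runs selection and assembly straight from a
table of normalized variables. With the published six-candidate table
for one melanoma patient (`neovax.examples`):

```python
from neovax.examples import worked_example_table
from neovax.pipeline import design_from_score_table

scores, selection, design = design_from_score_table(worked_example_table())
print([round(s.f, 4) for s in scores])
print(round(selection.objective, 4))
print(design.peptides)
```

prints

```
[0.6665, 0.4486, 0.5955, 0.4681, 0.4961, 0.5587]
3.2335
('DWLEWLRQLSLELLKFRDQSLSYHHTMVVQIGRFANYFRNLLPSN', 'MRHSFFSEVNWQDVYRLFMHHVFLEPITCVCSRRFYQFTKLLDSV')
```

— the per-candidate aggregate scores f(n), the objective F(S) of the
selected six, and the two 45-mer vaccine peptides assembled from them
in table order.

The same flow is available from the shell:

```sh
neovax simulate --seed 1 --out cohort/          # synthetic patient cohort
neovax compare  --cohort cohort/ --out cmp/     # binder counts + t-tests
neovax design   --cohort cohort/ --out design/  # scores, top-6, 45-mers
```

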