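# fragmeth

Fragment-unit differential-methylation analysis for reduced-representation
bisulfite sequencing (RRBS), with a clinical biomarker stage.

RRBS enriches a genome for CpG-dense DNA by sequencing size-selected MspI
fragments. `fragmeth` mirrors that design end to end, for studies that
compare a small patient group against controls (the motivating design is
five myelodysplastic-syndrome patients vs four healthy donors) and then
carry a candidate methylation marker into a clinical cohort:

1. **Digest** — in-silico MspI digestion (CCGG, cut C^CGG) and 40–220 bp
   size selection; the retained fragments are the analysis units.
2. **Regions** — promoter (±2,000 bp around the TSS), gene-body and
   CpG-island units (external BED track, or a Gardiner–Garden detector:
   GC ≥ 0.5, observed/expected CpG ≥ 0.6, ≥ 200 bp).
3. **Differential methylation** — per-unit methylation fractions from
   Bismark-style coverage files; a unit is a differentially methylated
   fragment (DMF) when *P* < 0.05, BH *Q* < 0.05 **and** the group means
   differ by more than 25 percentage points:

   hyper: Δ = x̄_case − x̄_ctrl > 0.25, hypo: Δ < −0.25, both with P < 0.05 ∧ Q < 0.05.

   The per-unit test is a pooled-variance t-test on per-sample fractions
   (a pooled-count Fisher exact test is available for no-replicate designs,
   but it is anticonservative under the overdispersion real bisulfite data
   show — see `docs/methods.md`).
4. **Candidates** — DMFs are annotated to genes by ≥ 1 bp overlap with
   promoters/gene bodies; genes with promoter-associated DMFs become
   candidates, labelled hyper/hypo by unanimity of signs (mixed → ambiguous).
5. **Clinical stage** — dichotomization of a continuous marker at the
   control **mean + 2 SD** cutoff; group comparisons by Mann–Whitney U,
   Pearson chi-square or Fisher exact (expected-cell < 5 rule);
   Kaplan–Meier / log-rank; univariate and multivariate Cox
   proportional-hazards regression (Efron ties, Newton–Raphson), with
   covariates entering the multivariate model at univariate *P* < 0.200.

A synthetic-data module (`fragmeth.synthdata`) generates toy genomes,
beta-binomial RRBS count files with planted effects of known size and
direction, and survival cohorts with a known log-hazard, so the whole chain
is testable with no external data.

## Worked example

Generate a synthetic study (60 kb genome, 6 genes, 40 fragments carrying
planted ±0.4 methylation shifts, 5 cases vs 4 controls at ~30× depth) and
run the pipeline on it:

```bash
fragmeth simulate --out demo --contig-len 60000 --n-genes 6 --n-planted 40 --seed 7
fragmeth run --fasta demo/genome.fa --genes demo/genes.tsv \
             --samples demo/samples.tsv --covdir demo/coverage \
             --cgi-bed demo/cgi.bed --out demo/out --seed 7
```

The run manifest (`demo/out/manifest.json`) reports

```
{'candidates': 1, 'dmf_hyper': 21, 'dmf_hypo': 18,
 'fragments': 387, 'tested_units': 405, 'units': 405}
```

i.e. the digest yielded 387 size-selected fragments (405 units with
promoters, gene bodies and CGIs), and DMF calling flagged 39 units — 37 of
the 40 planted fragments plus 2 false positives among the ~365 null units
(0.5%, consistent with Q < 0.05 control). `demo/out/dmf.tsv` holds one row
per tested unit:

```
unit_id              kind      mean_case  mean_ctrl  diff    p         q         status
frag:chr1:76-122     fragment  0.869      0.362      0.507   8.3e-04   1.1e-02   hyper
frag:chr1:122-250    fragment  0.104      0.492     -0.388   6.4e-06   3.7e-04   hypo
```

and `demo/out/candidates.tsv` shows the unanimity rule at work: the one gene
whose promoter overlaps planted fragments of *both* signs is reported with
direction `ambiguous` rather than silently assigned:

```
gene_id  direction  n_supporting  kinds_hit  best_diff  best_q
g001     ambiguous  18            fragment   -0.538     5.2e-05
```

The same stages are available as library functions (`fragmeth.digest`,
`fragmeth.regions`, `fragmeth.diffmeth`, `fragmeth.candidates`,
`fragmeth.clinstats`, `fragmeth.survival`) — see the module docstrings.

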