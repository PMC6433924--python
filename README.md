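# lekscan

Analysis toolkit for **evolve-and-resequence experiments with pooled
sequencing**, built around a bidirectional selection design: replicate
lines selected for and against a trait (here, male mating success in
*Drosophila melanogaster*), plus unselected controls, each pool-sequenced
after selection.  The toolkit answers the question at the core of the lek
paradox: does selection for success *erode* genetic variation, and was
that variation carried by rare alleles, as mutation–selection balance
predicts?

It is a library first (everything is importable from `lekscan`), with an
`examples/` directory of narrative scripts and a thin `lekscan` CLI for
running the stages from a shell.

## What it computes

Input is a loci × lines table of (minor, major) allele **read counts**
(native TSV or popoolation2 `sync` format) with a line → regimen design
(4 success-selected, 4 failure-selected, ≥1 control).  From this:

- **Screening** — keep loci with 5 ≤ coverage ≤ 250 in every line and a
  pooled minor-allele frequency ≥ 0.05 across all lines.
- **DiffStat scan** — per locus, the minimum frequency difference between
  any success/failure line pair; nonzero only when the two regimens'
  frequency ranges are disjoint.  A locus is *significant* when DiffStat
  exceeds the drift statistic (the larger within-regimen range).
- **Quasibinomial GLM scan** — logit-link binomial GLM of read counts on
  the regimen factor with Pearson-estimated dispersion φ̂; per-locus
  F = (D₀ − D₁)/φ̂ on (1, 6) df, converted to Storey q-values at FDR 0.05.
  **SDVs** (significantly diverged variants) pass both criteria.
- **Heterozygosity windows** — He = 2pq averaged in 50 kb windows stepped
  by 10 kb; hypergeometric SDV-enrichment per window against its arm's
  totals; line-median t tests; P_S<F (the fraction of DiffStat loci with
  less variation in success lines); a resampling null for the starting
  (control-line) frequency of SDVs; an LD-decay profile of p-values
  around SDVs.
- **F_ST** — Weir–Cockerham (1984) pairwise estimator with reads as
  sampled alleles (`hudson` switch available); within-regimen means and
  their difference DF_ST.
- **Neutral drift study** — Wright–Fisher lines (binomial resampling of
  2N alleles for 14 generations, pool-seq read sampling, the same MAF
  screen) over a grid of effective sizes, testing whether unequal Nₑ
  alone can mimic the observed He asymmetry without inflating DF_ST.
- **Synthetic experiment generator** — the same machinery plus genic
  selection p′ = p(1+s)/(1+ps) at planted causal loci, giving ground
  truth for end-to-end parameter-recovery tests.

## Worked example

`examples/02_windows_and_tests.py` generates a 5,000-locus experiment
with 3% of loci under bidirectional selection (s = 0.45) planted among
the rarer base alleles, scans it, and runs the regimen comparisons:

```
windows (50 kb / 10 kb)       : 975
windows with >=1 SDV          : 419
line-median t test            : t=7.60, df=6, p=0.000
P_S<F over DiffStat loci      : 0.774
P_S<F over SDVs only          : 0.976
SDV median start frequency    : 0.042
background median (95% CI)    : 0.114 (0.094-0.133), low=True
```

Reading the numbers: the positive t on the eight line medians says
failure-selected lines are significantly more heterozygous genome-wide;
P_S<F far above 0.5 says diverged loci lost variation preferentially in
the success direction; and the SDV starting-frequency median (0.042)
falls below the resampled genome background (0.094–0.133), i.e. the
selected alleles were rare in the base population — the mutation–
selection-balance signature.

The other examples cover the candidate scan itself (`01`), the neutral
drift study (`03`), and F_ST plus parameter recovery (`04`).  The same
stages are available from the shell:

```bash
lekscan filter --counts counts.tsv --out filtered.tsv
lekscan scan   --counts filtered.tsv --design design.tsv --out stats.tsv
lekscan run    --config config.yaml --out-dir results/
```

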