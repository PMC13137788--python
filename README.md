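# midriver

Detection of **mutation-intolerant genes (MIGs)** — genes that tolerate
somatic mutations in healthy tissue yet are depleted of mutations in
matched tumors, a signature of negative selection and tumor-specific
essentiality — together with the companion statistics used to characterize
them: permutation enrichment in synthetic-lethal gene pairs, a penalized-Cox
prognostic score with median-split log-rank testing, and a phenotype caller
for pooled CRISPR base-editing screens with single-cell readout.

Intended for cancer-genomics analysts who have per-cohort somatic mutation
tables (MAF-like), a gene-dependence matrix (DepMap-style), and optionally
expression/survival tables and screen outputs. Every stage is also
exercisable end to end on synthetic cohorts with planted ground truth.

## The core statistic

For each gene in a matched tumor–healthy pair, mutation tolerance in
healthy tissue is quantified by the healthy-cohort enrichment p-value
*P_H*, and intolerance in the tumor by 1 − *P_T*. The pair is combined by
Fisher's method,

    combined = −2 (ln P_H + ln (1 − P_T))  ~  χ²_4,

BH-adjusted across genes, and a gene is called a MIG when

    FDR < 0.1   and   mean CRISPR dependence (lineage-matched lines) > 0.9.

Top MIGs are triaged by three further strict rules: tumor FDR > 0.6,
healthy FDR < 0.1, and log2 mutation-burden ratio (healthy/tumor, per
sample, pseudocount 1) > 1. The per-cohort p-values come from a built-in
exact binomial test against a robustly estimated uniform background, or
from any external engine via a p-value table.

See `docs/methods.md` for the full model description, the screen GLM
(`logit(p) = β0 + β1·I_gRNA + β2·log F_D0` with likelihood-ratio testing),
and the synthetic-data generators.

## Worked example

```python
from midriver import core, gene_significance as gs, synthetic

# A synthetic tumor-healthy pair: 100 genes, 500 samples per cohort,
# 10 planted MIGs (10x healthy mutation rate, tumor mutation-free).
migs = [f"G{i:04d}" for i in range(10)]
spec = synthetic.CohortSpec(planted_migs=migs, seed=1)
healthy, tumor, truth, lengths = synthetic.simulate_cohort_pair(spec)

healthy_sig = gs.score_catalog(healthy, lengths)
cancer_sig = gs.score_catalog(tumor, lengths)
dep = synthetic.simulate_dependence(spec.gene_names(),
                                    planted_essential=migs, seed=2)

table = core.run_pair(healthy_sig, cancer_sig, dep, "synthetic",
                      healthy=healthy, tumor=tumor)
print(sorted(table.migs))
print(core.rank_top_migs(table)[:3])
```

prints

```
['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'G0006', 'G0007', 'G0008', 'G0009']
['G0007', 'G0004', 'G0001']
```

— all ten planted genes are recovered as MIGs (combined FDR < 0.1 with
mean dependence > 0.9), and the triage ranks them by burden ratio; G0007
leads because its healthy-cohort excess is largest relative to its
tumor-mutation-free state.

The same pipeline is available from the shell:

```bash
midriver simulate --kind cohort --seed 1 --out sim/
midriver run --tumor-maf sim/tumor.maf.tsv --healthy-maf sim/healthy.maf.tsv \
             --lengths sim/gene_lengths.tsv --dependence dep.tsv \
             --lineage LUAD --out migs.tsv
midriver enrich --genes migs.txt --universe universe.txt \
                --sl-pairs sl.tsv --stat pairs_within --iters 1000000 --seed 7
midriver screen --cells cells.tsv --day0 day0_counts.tsv --map grna_map.tsv \
                --out screen_results.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole framework from scratch on
synthetic data derived from a single seed — cohort simulation, MIG calling
and triage, synthetic-lethal permutation enrichment, prognostic-score
fitting/stratification with a log-rank test, and screen phenotype
calling — and writes its JSON output to `--out` (with a human-readable
stage summary alongside):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/midriver/io_formats.py` — MAF/TSV readers and validated containers
- `src/midriver/gene_significance.py` — background model, binomial test, BH
- `src/midriver/core.py` — pairing, Fisher combination, MIG call, triage
- `src/midriver/enrichment.py` — permutation / hypergeometric / co-expression
- `src/midriver/prognosis.py` — lasso-Cox score, median split, log-rank
- `src/midriver/screen_glm.py` — QC, Day-0 frequencies, fitness GLM
- `src/midriver/synthetic.py` — generators with planted ground truth
- `src/midriver/cli.py` — `midriver` command-line entry points
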