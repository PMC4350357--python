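# accsig

Paired tumor-vs-normal expression signature analysis for adenoid cystic
carcinoma (ACC) cohorts, with exon-level calling of MYB 3' rearrangement
status, MYB-dependence classification of target genes, gene-set enrichment and
miRNA–mRNA inverse-target integration — plus a synthetic cohort generator that
makes the whole pipeline testable end to end without any data download.

## The scientific problem

ACC is an aggressive salivary-gland tumor driven by activation of the MYB
transcription factor, typically through a t(6;9) MYB–NFIB fusion that truncates
MYB's 3' end. Three analysis questions recur in this setting:

1. **Signature derivation.** Which genes distinguish tumors from their matched
   normal tissues? With matched pairs the natural test is a per-probe paired
   t-test on log2 intensities, `t = mean(d) / (sd(d)/√n)` with `d` the paired
   tumor−normal log2 differences, after a baseline intensity filter
   (max across samples ≥ 50; ≥ 800 for miRNA arrays) and a variation filter
   (|mean paired fold change| ≥ 2), with Benjamini–Hochberg step-up control of
   the false discovery rate at α = 0.05
   (`q_(i) = min_{j≥i} m·p_(j)/j`).
2. **Fusion status from expression alone.** A 3' truncation leaves the
   retained 5' exons strongly over-expressed while the lost 3' exons fall back
   to normal baseline. On the per-exon delta vector
   `d_e = log2(tumor_e + c) − log2(normal_e + c)` the package maximizes a
   two-segment scan statistic
   `S(k) = (mean(d₁..k) − mean(d_{k+1}..E)) / (s_p(k)·√(1/k + 1/(E−k)))`
   over candidate breakpoints k and calls a tumor fusion-positive when
   S(k̂) ≥ τ, the 5' segment is elevated (≥ 1 log2) and the 3' segment sits at
   baseline (≤ 0.5 log2). Uniform over-expression without a 3' drop is
   explicitly a *negative* call, and a strong changepoint with an elevated 3'
   segment is *indeterminate*.
3. **MYB-dependent vs MYB-independent targets.** Some tumors express almost no
   MYB yet keep the full signature. Stratifying tumors by marker level
   (marker-low ⇔ value ≤ mean(normals) + 2·sd(normals)) and intersecting the
   per-stratum signatures with a ChIP-Seq MYB target list labels each
   activated gene MYB-independent (up in both strata), MYB-dependent-candidate
   (up only with high MYB, MYB-bound) or MYB-associated-unclassified.

Downstream integration covers Fisher's exact-test enrichment of annotation
sets (hypergeometric 2×2, BH across sets), the fraction of the signature in a
ChIP target list, intersection of up-regulated genes with somatic mutation
tables, and (miRNA, target) links where both are significant with opposite
directions.

Because the original cohorts require downloads, the package ships a generator
(`accsig.simulate`) that plants all of this structure — 12 tumor/normal pairs,
a 160-gene signature with MYB fixed at 18-fold, ECM genes up to 30-fold, one
MYB-low tumor retaining all MYB-independent effects, exon profiles with
planted breakpoints, and a miRNA matrix with planted inverse regulators — and
returns the ground truth for scoring.

## Worked example

```bash
python examples/01_cohort_and_signature.py
```

```
probes tested: 160 of 5000
significant at FDR 0.05: 160 (planted: 160)

top 8 rows (q ascending, |fold| descending):
          log2_fc  fold_change direction    q  significant
DOWN_051  -4.2334       0.0532      down  0.0         True
UP_042     4.5035      22.6823        up  0.0         True
...
MYB measured fold change: 19.3 (planted 18-fold; ...)
```

All 160 planted genes (and nothing else) are recovered at FDR 0.05; MYB's
paired fold change lands near its planted 18-fold. The other examples print
the per-tumor fusion calls against planted truth (`02_fusion_calls.py`, 100%
status agreement with exact breakpoints), the MYB-low stratification and
dependence labels (`03_myb_dependence.py`), and enrichment / mutation /
miRNA-link integration (`04_enrichment_mutations_mirna.py` — the ECM set is
the top localization enrichment, 50% of the signature overlaps the ChIP
target list, RUNX1 and NOTCH1 are the mutated-and-up-regulated candidates,
and miR-150→MYB / miR-29→HAPLN1 emerge as inverse links).

The same stages are scriptable from a shell:

```bash
accsig all --config config.yaml --seed 1 --out out/
accsig simulate|preprocess|signature|fusion-call|integrate --config ... --out ...
```

Two runs with the same config and seed produce byte-identical outputs.

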