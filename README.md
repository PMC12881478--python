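# epiloop

Integrative analysis of promoter epigenomes and enhancer looping in
white vs. beige adipocyte differentiation, built as a tested, fully
synthetic-verifiable pipeline. Written for computational biologists who
want to (a) quantify how much of a transcriptional program is encoded in
promoter chromatin, and (b) characterise condition-specific chromatin
loops, without touching raw sequencing data.

The package has two halves:

1. **Promoter epigenome → expression.** For each promoter (TSS −2 kb /
   +300 bp), seven epigenetic log2 fold changes (ATAC accessibility and
   ChIP of H3K4me3, H3K4me1, H3K27ac, H3K27me3, H3K36me3, H3K9me3;
   beige over white) predict the RNA log2 fold change with from-scratch
   leaf-wise, histogram-binned gradient-boosted regression trees
   (squared-error loss, prediction = base + η·Σ trees). 10-fold
   cross-validation yields out-of-fold predictions; the prediction
   error e = ŷ − y splits variably expressed transcripts (|y| > 0.5)
   into *promoter-explained* (|e| < 0.5) and *unexplained* (|e| > 0.5,
   read as enhancer-driven) sets. Each prediction is decomposed into
   exact interventional Shapley values φ over the 2⁷ feature
   coalitions, φ satisfying base + Σφ = ŷ identically; hierarchical
   clustering of φ profiles recovers regulatory modules, each named by
   its dominant feature.

2. **H3K27ac Hi-ChIP loop annotation.** Loops are pairs of 5-kb anchor
   bins with two-condition, two-replicate counts. A loop is retained if
   some condition has both replicates > 6 reads and a total > 18.
   Anchors classify as Promoter (overlaps a 2-kb TSS-upstream window
   and an H3K4me3 peak), Enhancer (overlaps an H3K27ac peak) or Other;
   loops take the unordered class pair. A beige-loop anchor is *de
   novo* if its bin occurs in no common loop. Group contrasts use
   Wilcoxon rank-sum / signed-rank tests and Cohen's D
   ((m₁−m₂)/pooled SD) for anchor signal.

A synthetic-data generator (`epiloop.synthetic`) plants known modules,
effect sizes, de-novo fractions and count distributions so that every
stage of the pipeline is checked against recoverable ground truth.

## Worked example

```python
from epiloop import (SyntheticConfig, GbmParams,
                     generate_promoter_table, PromoterExpressionModel)

table = generate_promoter_table(SyntheticConfig(seed=1))   # 2000 promoters
model = PromoterExpressionModel(table, params=GbmParams.desk(seed=1))
res = model.fit()
print(res.summary())
```

prints

```
Promoter expression model
=========================
promoters: 2000
features:  H3K4me3, H3K4me1, H3K27ac, H3K27me3, H3K36me3, H3K9me3, ATAC
estimators: 500  (lr=0.05, max_leaves=50)
CV r2 (Pearson^2): 0.604
CV r2 (coef. of determination): 0.601
CV RMSE: 0.834
kept (|lfc|>0.5, |err|<0.5): 788
unexplained: 746
well-predicted fraction: 0.514
  cluster down_1: n=121, top feature ATAC
  cluster down_2: n=68, top feature H3K27ac
  cluster down_3: n=145, top feature H3K27ac
  cluster up_1: n=109, top feature ATAC
  cluster up_2: n=116, top feature H3K4me3
  cluster up_3: n=51, top feature H3K4me3
  cluster up_4: n=178, top feature H3K4me3
```

Out-of-fold r² of 0.60 means the seven promoter features explain about
60 % of expression-change variance; 788 variably expressed transcripts
are promoter-explained and enter module discovery, while 746 (the
planted enhancer-driven class plus noisy nulls) are not predictable
from promoter chromatin. Up-regulated (beige) clusters are dominated by
H3K4me3, down-regulated (white) clusters by H3K27ac, with an
accessibility-linear module in both directions — exactly the planted
structure.

The loop half mirrors this:

```python
from epiloop import SyntheticConfig, generate_loop_fixture
from epiloop.model import LoopArchitectureModel

fx = generate_loop_fixture(SyntheticConfig(seed=1))
res = LoopArchitectureModel(fx.loops, fx.context,
                            anchor_signal=fx.anchor_signal,
                            tss_lfc=fx.tss_lfc).fit()
print(res.summary())
```

reports 3000 of 3300 loops retained, 35.4 % of beige loops formed by de
novo contacts, de-novo loops markedly shorter than common-anchor loops
(medians 65 kb vs 185 kb, rank-sum p ≈ 1e-65), and an anchor-signal
Cohen's D of 0.96 between beige-unique and common anchors.

There is also a CLI (`epiloop synth|features|train|explain|modules|
loops|all`) writing flat TSV/BEDPE/JSON outputs with a deterministic
run manifest; see `epiloop --help`.

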