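# panelcnv

Read-depth copy-number variant (CNV) flagging for targeted hereditary-cancer
gene panels.

Clinical laboratories that sequence capture panels (e.g. a 34-gene inherited
cancer predisposition panel covering *BRCA1/2*, the Lynch-syndrome genes,
*TP53*, *CDH1*, ...) need to detect exon-level deletions and duplications from
the same NGS data used for SNV/indel calling. Coverage depth is proportional
to copy number only after aggressive normalization: library size, capture
efficiency, and batch-level technical structure all distort it. `panelcnv`
implements a complete flagging pipeline for this setting — binning, target
grouping, a staged normalization chain with PCA denoising, robust Z-scoring
against a trained model, event merging — together with a coverage simulator
and the validation metrics (sensitivity, trial-level specificity, intra/
inter-assay precision) used to qualify such an assay. Flagged specimens are
intended to be reflexed to an orthogonal method (aCGH/MLPA) for confirmation;
calls carry an explicit confirmation status.

## The statistic

Capture targets are partitioned into non-overlapping bins of ~200 bp; bins are
joined into *target groups* at several levels (single bin, exon, sliding
2/4/8-exon windows, whole gene) so that large events concentrate their signal.
Each group is scored independently. For specimen *s* and group *g*:

1. **RDr** = RD / mean RD over the specimen's unmasked single bins
   (removes library size),
2. **RDrp** = RDr with the top *k* principal components of the training
   cohort's specimen-centered RDr removed (removes systematic technical
   structure; projection scores are estimated on winsorized data so sparse
   CNV signal is not absorbed),
3. **X** = RDrp / median RDrp over the specimen's single bins,
4. **Z = (X − μ)/σ**, with μ the median X across the specimen's batch
   (typically 92 specimens) and σ the scaled MAD of X across a training
   cohort,
5. **Z.adj** = Z divided by the standard deviation of the specimen's Z over
   the other groups of the same level — cancels specimen-level noisiness.

A group is flagged when |Z| and/or |Z.adj| exceeds its level's cutoff;
cutoffs are calibrated on the training cohort to a target specimen-level
specificity (default 98%). Flagged groups are projected onto bins and merged
into DEL/DUP calls. Pseudogene-confounded regions (*PMS2* and *CHEK2* exons
11–15) are masked throughout.

## Worked example

Train on a simulated CNV-free cohort of 300 specimens, then call a 92-specimen
batch containing one carrier of a *BRCA1* exon 16–17 deletion:

```python
from panelcnv import (demo_panel, SimulationConfig, simulate_depth,
                      simulate_trial_cohort, CnvEvent, ReadDepthCnvModel)

panel = demo_panel()                      # 34 genes, synthetic coordinates
train_depth, _ = simulate_depth(
    SimulationConfig(n_specimens=300, batch_size=75, seed=11), panel)
results = ReadDepthCnvModel(train_depth, panel).fit()

trials = [("case1", CnvEvent("case1", "BRCA1", (16, 17), "het_del"))]
trials += [(f"ctrl{i:02d}", None) for i in range(91)]
batch, truth = simulate_trial_cohort(
    panel, SimulationConfig(batch_size=92, seed=12), trials)
for c in results.call(batch).calls:
    print(f"{c.specimen_id:7s} {c.gene:6s} exons {c.first_exon}-{c.last_exon}  "
          f"{c.cnv_type}  best={c.best_group_id}  |Z|max={c.max_abs_Z:.1f}")
```

prints

```
case1   BRCA1  exons 1-24  DEL  best=BRCA1|ex15-18|w4  |Z|max=13.4
ctrl27  MUTYH  exons 4-4  DUP  best=MUTYH|ex4|b2|G  |Z|max=5.9
ctrl85  POLD1  exons 25-25  DUP  best=POLD1|ex25|b2|G  |Z|max=6.3
```

The carrier is flagged in the right gene with the right type: the exon 16–17
bins score Z ≈ −9 to −13 and every window overlapping them clears its cutoff,
so the merged span is the maximal flagged extent while `best_group`
(exons 15–18, |Z| = 13.4) localizes the event. The two control calls
illustrate the assay's design: this is a *flagging* algorithm tuned for
sensitivity, and every call is `flagged_pending_confirmation` until the
orthogonal reflex test resolves it (`set_confirmation`, and
`confirmation_adjusted_specificity` for the post-reflex rate).

`results.summary()` reports the fitted model: per-level cutoffs (here
|Z| > 4.8–5.8), the σ distribution (median 0.047), and the panel fingerprint
that guards against scoring a mismatched design.

A `panelcnv` console script exposes the same workflow
(`simulate` / `train` / `call` / `evaluate` / `evaluate-counts`) with
TSV/JSON/VCF outputs and mandatory seeds.

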