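# Methods

## Panel model

A capture panel is represented as genes → exons → bins → target groups, with
0-based half-open coordinates (BED convention) throughout; 1-based positions
appear only in display/VCF output. Exons of length L are partitioned into
⌈L/200⌉ non-overlapping bins whose lengths differ by at most one base, so the
bins tile each exon exactly; bins never span introns, where capture coverage
collapses. Target groups joining contiguous bins are built per gene at a
fixed hierarchy: every single bin, every exon, sliding exon windows of sizes
2/4/8 (step one exon), and the whole gene. This covers the motivating event
shapes (multi-exon deletions, whole-gene del/dup) with O(#exons) groups
rather than all O(n²) contiguous runs. Promoter targets are carried in the
panel model but excluded from grouping — the copy-number analysis is
exon-level. Windows never bridge a masked exon; the whole-gene group is the
one level allowed to skip a masked interior gap, so that e.g. a gene with
exons 11–15 masked is still scored as a whole over exons 1–10.

Pseudogene masking: read depth over *PMS2* and *CHEK2* exons 11–15 is
uninterpretable because of highly homologous pseudogene sequence, so those
exons are masked by default. Masked bins keep their coordinates (events may
biologically cover them) but contribute to no group, no normalization
statistic and no flag; truth sets for evaluation use only unmasked bins.

The shipped 34-gene demo panel has realistic per-gene exon counts and
chromosome assignments, but its coordinates and exon lengths are synthetic
(deterministically generated, including a few multi-kilobase internal exons
that exercise multi-bin exons). It is a geometry fixture, not a genome
annotation.

## Normalization chain

Bin depth is the arithmetic mean per-base depth; group depth is the
length-weighted mean of member bins, which equals the per-base mean over the
group. The staged transforms are:

* **RDr** — group depth divided by the specimen's mean depth over unmasked
  single-bin groups. The same denominator serves all group levels, keeping
  them on one per-specimen scale. Specimens with zero mean depth are marked
  unscorable.
* **RDrp** — RDr minus the component of (RDr − m) spanned by the top-k
  principal components of the training cohort's specimen-centered RDr
  (m = per-group training mean). PCA is interpreted as *denoising*: the top
  components capture systematic capture/batch structure shared across
  specimens, and removing them leaves CNV signal in the residual. Projecting
  *onto* the components instead would discard the signal. k defaults to 5,
  capped at the component count explaining ≥ 90% of training variance; the
  basis is fit once on the training cohort and applied unchanged to
  production batches, because σ and the cutoffs are calibrated under exactly
  that normalization. Projection scores are estimated on data winsorized at
  3 robust SDs per group (training MAD): a heterozygous deletion sits ~10
  MADs out, so without clipping a large sparse event leaks into the
  estimated technical component and smears small biases across every other
  gene of that specimen — measurably inflating false flags in event
  carriers. Technical structure itself lives well inside the clip bounds.
* **X** — RDrp divided by the specimen's median RDrp over unmasked
  single-bin groups. X retains each target's capture-efficiency footprint;
  the per-target diploid reference is the batch median μ, not 1. The
  copy-ratio proxy reported on calls is therefore X/μ (≈ 0.5 het del,
  1.5 dup).

All transforms are on the natural ratio scale (no log), and X is exactly
invariant to rescaling a specimen's raw depths.

## Scoring and flagging

Z = (X − μ)/σ with μ the per-group median X over QC-passing specimens of the
specimen's batch (≥ 3 required; typical batch 92) and σ the per-group MAD of
X across the training cohort, scaled by 1.4826 so Z is in approximate
standard-normal units (the Z.adj construction implicitly assumes a common
scale; the scaling is switchable). Groups with σ = 0 are unscorable and
reported as such. Z.adj divides Z by the n−1 standard deviation of the
specimen's Z over the *other* groups of the same stratum — strata are
single_bin, exon, window2/4/8, whole_gene, so bins are compared to bins and
windows to windows; mixing levels would let the low-variance whole-gene
groups dominate the denominator. Z.adj cancels specimen-level noisiness
(scaling all of a specimen's Z by a constant leaves it unchanged).

Flagging is two-sided — the validation set contains both deletions and
duplications — with the sign preserved: a group is flagged when |Z| > z_cut
and/or |Z.adj| > zadj_cut for its stratum ("and/or" is implemented as OR,
switchable to AND; OR maximizes sensitivity, which suits a design where
every flag is reflexed to orthogonal confirmation). Flagged groups are
projected onto bins; per specimen and gene, maximal runs of contiguous
flagged bins (in the gene's unmasked bin order) become one call each, typed
DEL iff the run's mean X/μ < 1, carrying the maximal-|Z| flagged group as
`best_group`, and statused `flagged_pending_confirmation`. Confirmation is
always an external annotation; nothing is auto-confirmed.

## Training and calibration

σ comes from the training cohort's X matrix as described. Cutoff calibration
targets a *specimen-level* (family-wise) false-flag budget
α = 1 − target_specificity (default 0.02), because the assay's specificity is
tallied per trial, not per target. The training cohort is replayed exactly as
production is scored (within-batch median μ, training σ; the self-inclusion
bias of one specimen in a ~92-wide batch median is negligible). Per stratum
and statistic the per-specimen max |Z| and |Z.adj| are collected; α is split
across the 12 stat-strata (Bonferroni) and each cutoff is placed at the
corresponding tail quantile of a Gumbel distribution moment-fitted to the
replayed maxima, plus a one-sided 95% allowance for quantile-estimation
error. A parametric tail is used deliberately: a training cohort of a few
hundred specimens cannot resolve a 2% family-wise tail across a dozen
dependent max-statistics empirically (cutting at empirical maxima makes the
fresh-cohort flag rate an extreme-value lottery). The positive dependence
among strata makes the Bonferroni split conservative; since real events
score far above any plausible cutoff (a het del at 380× scores |Z| ≈ 7–35),
the conservatism costs no sensitivity, and the realized fresh-cohort flag
rate lands at or below budget. The empirical replay acts as a floor: cutoffs
are scaled up if the replayed rate still exceeds α. At target specificity
1.0 the cutoffs sit strictly above all observed null scores.

Because roughly 1 in 100 clinical specimens genuinely carries a CNV, an
optional robust iteration (default on) drops specimens flagged in a first
pass and refits σ and cutoffs once; the PCA basis is kept, as a handful of
carriers does not move a dense component.

The fitted model (basis, σ, cutoffs, metadata) serializes to JSON with a
panel-geometry fingerprint; scoring a panel whose fingerprint differs is a
hard error.

## Coverage simulator

The generator produces the structure the algorithm assumes, nothing more:
expected depth m(s,b) = D · d_s · e_b · exp(Σ_k u_{sk} v_{bk}) · c_{sb} with
counts NegBinom(mean = m, var = m + φ·m²). Defaults define the simulated
operating point: D = 380× mean depth, batches of 92, lognormal specimen size
factors (sd_log 0.15), lognormal capture efficiencies (sd_log 0.40, so the
e_b range spans roughly 5-fold, matching a tuned capture design whose coding
targets all clear ~100× at 380× median), two low-rank technical factors
(loading sd 0.05), and overdispersion φ = 0.002, which puts the residual
per-bin CV at ~7% at 380× — the 3–8% residual CV reported for well-behaved
clinical capture panels. Assay-level structure (e_b and the technical
*loadings* v) is drawn from a panel-derived stream and shared across cohorts
and seeds, because it is a property of the bait design — this is exactly
what makes a training-fixed PCA basis and trained σ transferable to
production batches. Cohort-level randomness (size factors, factor *scores*
u, counting noise) comes from the user seed; everything is deterministic
given (panel, config, seed).

CNV spike-ins multiply the expected depth of the event's bins by the
germline copy ratio (0.5 het del, 0 hom del, 1.5 dup — all panel genes are
autosomal) and re-draw those cells under the same noise law; all other cells
are preserved bit-exactly. Replication of a positive specimen is simulated
as independent re-draws with fresh seeds, mirroring a
replicate-within-and-across-runs design.

What the simulator does **not** model: GC/mappability covariates, read-level
artifacts, pseudogene cross-mapping, mosaicism, sample-quality gradients,
and real inter-batch protocol drift. Passing the simulated validation
studies therefore demonstrates that the *algorithm* recovers events and
holds its false-flag budget under the assumed noise structure; it is not a
claim about wet-lab performance on real specimens.

## Validation studies and problem sizes

The packaged studies run at deliberately modest but faithful sizes: training
cohorts of 300 simulated null specimens (the production assay would use
thousands; 300 is where the parametric calibration already stabilizes),
42 positive trials from the 18 known event shapes with their printed
replication counts, 457 negative trials, and 94×3 replicate draws with 9
carriers. Detection matching is gene + type + ≥ 1 overlapping assayable bin
(events are exon-granular, so reciprocal-overlap thresholds are unnecessary;
wrong-type overlaps never count). Sensitivity is detected positive trials /
positive trials; specificity is trials without any false call / trials;
precision is specimens whose replicate call sets are pairwise concordant
(same gene, type, overlapping span — empty sets are concordant negatives) /
replicated specimens. Reported percentages use the conventional display
rounding (one decimal for rates, integer shares in cohort tables; integer
shares may sum to slightly over 100, as printed summaries do).

## Numerical and degenerate-input choices

Medians of even-length samples are midpoints of the central order
statistics. NaN scores (σ = 0 groups, undefined Z.adj denominators) never
flag. Batches with < 3 QC-passing specimens are rejected with advice to
pool. QC follows the 20× coverage rule per unmasked bin (fraction
configurable); failed specimens are excluded from μ but still scored.
Specimens with zero or non-positive normalization denominators are marked
unscorable rather than propagating infinities. The Gumbel calibration floors
template quantiles at ε = 1e-9 to survive degenerate all-zero scores.

## Known limitations

* Call spans are unions of flagged groups, so a strong event typically
  drags its containing windows (sometimes the whole-gene group) over
  cutoff and the reported span overreaches the true event; `best_group`
  localizes it. Breakpoint refinement is out of scope — the assay flags for
  orthogonal confirmation.
* Per-batch μ assumes events are rare within a batch; a recurrent event in
  > half a batch would be absorbed into the reference.
* The Z.adj denominator uses same-stratum groups genome-wide; a specimen
  carrying many true events has inflated denominators and slightly
  conservative Z.adj.
* No GC or mappability regression; on real data the PCA step shoulders that
  burden only to the extent such biases are low-rank across specimens.
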