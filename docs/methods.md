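# Methods

## The problem and the model

Sorafenib is a multi-target tyrosine kinase inhibitor used in advanced
renal cell carcinoma (RCC); only a minority of patients respond, and no
routine biomarker guides its prescription. The hypothesis implemented
here is that the tumor's pre-treatment expression of the drug's own
molecular targets carries predictive information: a tumor that expresses
the kinases sorafenib inhibits should be more likely to respond to
inhibition.

The pipeline formalizes this as follows.

**Response label.** RECIST best response is collapsed to a binary label:
progressive disease (PD) → *poor responder*; partial response (PR) and
stable disease (SD) → *responder*. Complete response, never observed in
the packaged cohorts, maps to responder with a warning — a strictly
better outcome than PR cannot be a poor response.

**Candidate genes.** The ten tyrosine kinases sorafenib is known to
inhibit: RAF1, BRAF, RET, FLT1, FGFR1, KIT, PDGFRB, FLT3, FLT4, KDR.
Restricting the feature space to prior-knowledge targets is the
overfitting control: no data-driven feature search is performed.

**Normalization.** Platform-specific, with no cross-platform
calibration (scores are only compared within one cohort):

* *Microarray* — quantile normalization. Every sample is mapped onto the
  common reference distribution (row means of the column-sorted matrix).
  Ties receive the mean of the reference values their ranks span, the
  convention of the standard implementation.
* *RNA-seq* — median-of-ratios size factors. With counts k(g, j) over m
  samples, s(j) = median over tie-free, all-positive genes g of
  k(g, j) / (∏_v k(g, v))^(1/m); normalized values are k/s. Exact
  property worth knowing: scaling one sample by λ multiplies its factor
  by λ^((m−1)/m) and every other factor by λ^(−1/m), so factor *ratios*
  scale by exactly λ and normalized values move only by a global
  λ^(1/m). The implementation is verified against pydeseq2's
  `deseq2_norm` in the test suite.
* *qRT-PCR* — ΔCt(g, s) = geometric mean over housekeeping genes h of
  Ct(h, s) − Ct(g, s), computed via mean of log Ct for stability.
  Higher ΔCt ⇒ higher expression; one ΔCt unit is one PCR cycle, i.e.
  one doubling, so ΔCt is a log2-scale quantity. Replicate wells are
  aggregated to one Ct (arithmetic mean by default, median available)
  before ΔCt. The default housekeeping set is the one on the shipped
  primer panel — ACTB, VCP, DIABLO, EIF3B, PSMB2, POLR2C — and is fully
  configurable.

**Signature selection.** Per candidate gene, a two-sided Student t-test
(pooled variance; Welch behind a flag) between responders and poor
responders, and the log2 fold-change of group means. Fold change is
computed on linear-scale group means by default (log-scale averaging is
available); for ΔCt input it is the plain difference of means. The rule
is purely directional: every measured candidate with log2FC > 0 enters
the signature; down-regulated candidates are excluded. On the packaged
reference screen this keeps eight of the ten targets, excluding RET and
FLT4. No multiple-testing correction is applied at this stage — the
selection does not condition on significance, only on sign.

**Score.** Unweighted: score(s) = Σ_g log10(x(g, s) + ε) over the
signature genes (microarray ε = 0, normalized RNA-seq ε = 1 because
zeros occur), or Σ_g ΔCt(g, s) for qPCR. Higher score ⇒ predicted
responder. A signature gene missing from a matrix is a hard error:
an unweighted sum over fewer genes is not comparable.

**Evaluation.** AUC is the tie-corrected Mann–Whitney probability that
a random responder outscores a random poor responder, computed via
mid-ranks. The operating threshold assumes equally frequent type I and
type II errors: candidates are midpoints between adjacent distinct
scores plus one point beyond each extreme; the threshold minimizing
|FPR − FNR| wins, with ties broken by maximal MCC and then by the lowest
threshold (favoring sensitivity). "Equal frequency" is enforced on
*rates* by default; balancing absolute counts (FP vs FN) is a config
option — the two differ only by group-size weighting. The
classification rule is score strictly greater than threshold ⇒
responder. MCC is defined as 0 when any factor under its root is zero.
Because the threshold is calibrated on the scored cohort, published
cut-offs from other datasets are not expected to reproduce; the
procedure, not the number, is the artifact.

**In-vitro arm.** Against a cell-line panel (per-line score, log10 IC50
in µM, binary mutation matrix): (i) Spearman correlation of score and
log10 IC50 — negative if the signature tracks sensitivity; (ii)
extreme-responder classification: the bottom 5% of lines by IC50 are
labeled responders, the top 5% poor responders (floor(f·n) per tail,
boundary ties broken by stable sort on line id), middle discarded, AUC
computed; (iii) per-gene mutation association: two-sided Mann–Whitney U
of IC50 between mutant and wild-type lines (exact when both groups have
≤ 20 tie-free values, otherwise the normal approximation with tie and
continuity correction), Benjamini–Hochberg FDR across tested genes
(each needing ≥ 3 mutant and ≥ 3 wild-type lines). Effect size is the
difference of group means of log2 IC50 (mutant − wild-type), so
|effect| > 1 means a more-than-2-fold IC50 difference; a gene is
*significant* iff FDR < 0.1 and |effect| > 1.

## Synthetic data

The generator produces the two-group structure the analysis assumes,
not a forward model of any assay's physics:

| platform | model | defaults |
|---|---|---|
| microarray | intensity = 2^(b + e·resp + N(0, σ)), b ~ U(6, 12) | σ = 0.5 (log2) |
| RNA-seq | NB via gamma–Poisson, mean = m·2^(e·resp)·d(s) | dispersion 0.1, m log-uniform 10–10⁴, depth d lognormal(0, 0.3) |
| qRT-PCR | Ct = b − e·resp + N(0, σ), b ~ U(18, 30), clipped to [15, 35] | σ = 0.3 cycles |

Default effect sizes e are the reference screen's estimates for the ten
targets (FLT1 +1.155 down to FLT4 −0.010); housekeeping and background
genes have e = 0. Default group sizes are the discovery cohort's
(12 responders / 10 poor responders). The noise defaults were chosen
once so that at these sizes the signature AUC falls broadly in the
0.7–0.95 band observed across real cohorts of this kind — a
calibration, not ground truth.

Cell-line panels: per-line true score z ~ N(0, 1);
log10 IC50 = −c·z + Σ mutation shifts + N(0, σ), with σ = 0.2 and
c = 0.043 calibrated analytically (Pearson r = c/√(c² + σ²), Spearman
ρ_s = (6/π)·asin(r/2)) to give ρ_s ≈ −0.2 at 732 lines, the magnitude a
heterogeneous pan-cancer panel plausibly shows. Mutation shifts are
specified in log2 units and converted to log10 internally.

Random-stream design: every gene draws from a substream keyed by
(seed, CRC32 of gene name); sample-level draws (depth, panel noise) use
separate named substreams. Adding genes to a spec therefore never
perturbs existing genes' values. All outputs are byte-identical for
identical specs and seeds.

**What the generator does not emulate:** probe-level artifacts, batch
effects, FFPE RNA degradation, GC bias, correlated co-expression between
targets, cancer-type structure among cell lines, or qPCR efficiency
differences. Passing recovery tests therefore demonstrates that the
*statistics* behave correctly under the assumed model at the study's
sample sizes — not that the biological signal exists in real tumors.

## Simulation studies (sizes used)

* *Signature vs single genes*: 500 replicates at 12/10, each replicate
  selecting on a discovery cohort and evaluating on an independently
  simulated validation cohort. Selection and evaluation are separated
  deliberately: after data-driven gene selection, in-sample AUC is
  optimistically biased, and the null calibration below would fail.
  Expected outcome: the signature's median AUC (~0.81) exceeds every
  single-gene median except FLT1 (~0.95), whose planted effect dominates
  the sum.
* *Null calibration*: 200 replicates with all effects 0; mean
  out-of-sample AUC within 0.5 ± 0.03.
* *Mutation screen power*: 100 panels of 700 lines, one gene shifted by
  −1.46 log2 units in 11 lines among 30 null genes; flagged in ≥ 90% of
  panels, with the effect estimate recovered near −1.46. 100
  IC50-permuted panels average < 0.2 false flags (the 2-fold effect
  filter makes false flags at n_altered ≥ 5 essentially impossible).

## Numerical and design choices

* Pooled-variance t-test is the default because the method is defined
  by the plain Student test; groups of 3 vs 10 make Welch df small and
  noisy anyway.
* Zero within-gene variance in both groups yields p = 1 with a
  `degenerate` flag rather than NaN propagation.
* Quantile-normalization tie groups get the mean of spanned reference
  values; this preserves column sums (hence the grand mean) exactly but
  means tied columns do not share the reference multiset exactly — the
  multiset identity is exact only for tie-free columns.
* Size-factor estimation excludes genes with any zero count; those genes
  are still normalized.
* BH-FDR, Spearman, Mann–Whitney and the t-test are delegated to
  statsmodels/scipy; ROC, threshold search, MCC, quantile and
  median-of-ratios normalization and ΔCt are implemented here and
  cross-checked against independent references (scikit-learn, pydeseq2,
  brute-force oracles) in the tests.
* Errors are typed (config / data / degeneracy) and surface as CLI exit
  codes 2 / 3 / 4; stage names are attached to errors raised inside
  workflows.

## Known limitations

* The equal-error threshold is cohort-specific by construction; the
  package reproduces the calibration procedure, not any published
  cut-off.
* The score presumes all signature genes measured; panels lacking a gene
  must re-derive a signature rather than renormalize the sum.
* ΔCt shift-cancellation under a uniform Ct offset is approximate
  (geometric mean of shifted cycles ≠ shifted geometric mean), a
  sub-0.1-cycle effect at realistic Ct ranges.
* Treatment-line semantics (first-line vs later-line therapy) are not
  modeled; the cohort tables carry no such field.
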