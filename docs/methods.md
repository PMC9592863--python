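# Methods

This note documents the statistical model, the numeric choices, and the
design decisions behind `triadscreen`, and states what the synthetic-data
experiments do and do not demonstrate about real data.

## Differential expression

Counts for each layer (mRNA, lncRNA, miRNA) are modeled as negative
binomial with variance μ + αμ². Within one genotype, drought is contrasted
against control:

1. **Normalization.** Median-of-ratios size factors are computed on the
   genotype's six samples: for every feature with no zero count, the ratio
   of each sample's count to the feature's geometric mean is formed, and a
   sample's factor is the median of those linear-scale ratios. This assumes
   most features are not differential — a matrix in which every feature
   shifts will have the shift absorbed into the factors (this is exercised
   deliberately in the tests).
2. **Effect size.** log₂FC = log₂((m_drought + c)/(m_CK + c)) on
   size-factor-normalized condition means, with pseudocount c = 0.5
   normalized counts so that low-count features do not explode.
3. **Dispersion.** Per-feature method of moments: α̂ = (v − m)/m² computed
   per condition and averaged, floored at 10⁻⁸ (the NB variance never drops
   below Poisson). No shrinkage across features — the estimator is
   transparent and auditable, which is what the downstream screens need,
   at the price of noisy per-feature α at n = 3.
4. **Test.** Wald statistic log₂FC / SE, where SE comes from the delta
   method, Var(log₂ m) ≈ (1/m + α)/(n·ln²2) per condition. The statistic is
   referred to a **t distribution with n₁+n₂−2 df**, not a normal. With
   moment-based dispersion at three replicates per condition a normal
   reference is strongly anticonservative (empirical type-I error ≈ 0.12 at
   nominal 0.05 in our null simulations); the t reference restores
   calibration (≈ 0.05 ± 0.005 over 2500 null features). This is the one
   place the implementation deviates from a textbook Wald test, and it is a
   deliberate small-sample correction.
5. **Calling.** p < 0.05 and |log₂FC| > 1, strict inequalities. The p
   threshold is applied to raw p-values by default; Benjamini–Hochberg
   adjusted p-values are available behind `ThresholdConfig.use_adjusted_p`.
   The raw-p default reflects the screening character of the procedure —
   the thresholds define a candidate set that downstream constraints
   (targeting, direction, pair links) filter much harder.

miRNA differential expression uses the same NB machinery on miRNA counts;
read-count TPM (count/total × 10⁶, no length term — mature miRNAs are
effectively constant-length) is a reporting unit only. FPKM
(count × 10⁹ / (total × length)) is the abundance unit fed to the trans
correlation.

## lncRNA filtering and classification

A transcript is accepted as a lncRNA when it has unknown/novel biotype,
length > 200 nt, **≥ 2 exons**, and all four coding-potential verdicts
(CPC, CNCI, CPAT, Pfam stand-ins, supplied as a 0/1 table) are noncoding.
The exon rule is stated ambiguously in parts of the literature ("more than
two" vs the conventional multi-exon ≥ 2); the default here is ≥ 2, with the
threshold exposed as `ThresholdConfig.min_lnc_exons` for the strict > 2
reading.

Positional classes are assigned with a fixed precedence: no gene-body
overlap → lincRNA; any opposite-strand overlap → antisense; full
containment in a same-strand intron → intronic; any other same-strand
overlap → sense. Antisense outranks intronic because strand disagreement is
the stronger signal when both could apply. Overlap means ≥ 1 bp
intersection of gene-body intervals. A lncRNA on a chromosome absent from
the gene models is intergenic by definition and logged.

## Target edges

* **cis**: boundary-to-boundary gap ≤ 100 000 bp on the same chromosome,
  inclusive at exactly 100 kb, gap 0 for overlapping features, strand
  ignored (the most permissive literal reading of "within 100 kb upstream
  and downstream"; both the boundary convention and the window are
  configurable).
* **trans**: Pearson correlation of FPKM across all 12 samples, edge when
  |r| > 0.9 and p < 0.01 with p from t = r√((n−2)/(1−r²)) on n−2 df. No
  multiple-testing correction is applied to trans p-values (the rule is a
  plain per-pair threshold); at n = 12 the |r| > 0.9 condition dominates
  (r = 0.9 ⇒ p ≈ 6 × 10⁻⁵). Per-genotype subsetting is possible by passing
  subset matrices.
* **miRNA targets**: either ingested from a precomputed edge table, or
  scored with a plant-style complementarity penalty: the miRNA is aligned
  antiparallel to a same-length site; mismatches cost 1, G:U wobbles 0.5,
  and penalties double at miRNA positions 2–13 from the 5′ end; an edge is
  emitted when the score ≤ 4. This is a deliberately simple position-wise
  rubric (no bulges or gapped alignment) — sufficient for declared-edge
  workflows and for testing, not a full target-prediction tool.

## The screens

**Drought-resistance DEG classes.** With calls from both genotypes, classes
are assigned with mutually exclusive predicates evaluated in order:
A/B — called in DT, not called in DS, |log₂FC(DT)| > 2 (sign picks A/B);
C/D — called in both with the same sign and log₂FC(DT)/log₂FC(DS) > 3
(the both-called guard means |log₂FC(DS)| > 1, so the ratio is well
defined and positive); E/F — called in both with opposite signs.
"Specifically regulated in DT" is read literally as called in DT and not
called in DS at the base thresholds, not as "small DS effect".

**Triad modules.** Per genotype, for every DEM with direction d: candidate
DELs are its mir2lnc targets with direction opposite to d, candidate DEGs
its mir2mrna targets with direction opposite to d; only DEL/DEG members
participating in ≥ 1 (DEL, DEG) pair joined by a cis or trans edge are
retained (the stricter per-member reading of the mutual-targeting retention
rule; a flag relaxes it to module-level). One module per DEM (DEM-centered
stars), type 1 when the DEM is up, type 2 when down. Module invariants are
asserted at runtime on every emitted module.

## The synthetic-data generator

The generator emulates post-quantification data of the 2 × 2 × 3 design:

* Counts are NB with a single shared dispersion α (default 0.05) and a
  common baseline mean (default 500); per-feature baselines and dispersions
  are a deliberate simplification — the screens consume only (log₂FC, p,
  direction), which this structure exercises fully.
* Library depths vary log-uniformly within ±20% of nominal, so size-factor
  estimation is non-trivial.
* Each genotype carries `n_planted_triads_per_genotype` triads (default 3,
  alternating type 1 and type 2), each with 1 lncRNA and 2 mRNAs — roughly
  the star sizes seen in DEM-centered module reports. Planted members' means
  are multiplied/divided by 2^planted_log2fc (default 2) in that genotype's
  drought samples.
* Each planted (lncRNA, mRNA) pair is realized cis with probability
  `cis_fraction` (default 0.5) — the gene is placed on the lncRNA's
  chromosome at a gap ≤ 80 kb, safely inside the 100 kb window — or trans:
  placed > 100 kb away (or on another chromosome) with counts coupled
  through a Gaussian copula at ρ = 0.99. The copula is necessary: the
  shared condition effect alone yields an expected across-sample r ≈ 0.7 at
  the default noise level, below the 0.9 trans threshold, so trans
  recoverability is built in explicitly rather than left to chance.
* Sampling is uniform across features: standard-normal variates (mixed for
  copula pairs) are pushed through the NB quantile function, which makes
  one deterministic code path per seed. Identical seeds give bit-identical
  output.
* A fraction of non-planted features (default 5%) receive a background
  differential effect with random genotype and direction; 40 decoy
  mir2lnc and 40 decoy mir2mrna edges are added so the screen must reject
  structure, not merely accept it.
* Coding verdicts are noncoding ×4 for simulated lncRNAs and coding ×4 for
  mRNAs, with a configurable per-cell flip rate (default 0) to exercise the
  consensus filter.

**What passing tests show — and don't.** Recovery of planted triads at the
default settings (sensitivity ≥ 0.95, module precision/recall ≥ 0.9 over
20 seeds; in practice ≈ 1.0) demonstrates that the pipeline's logic is
correct and that its thresholds are mutually consistent under the stated
noise model. It does not demonstrate performance on real data, where
dispersions vary per feature, effects are smaller and correlated,
annotation is incomplete, and miRNA-target edges are themselves predictions
with error. The generator deliberately omits read-level artifacts,
per-feature mean/dispersion heterogeneity, batch effects, and sequence-level
binding-site placement.

## Problem sizes and numerics

The default simulation (300 genes, 80 lncRNAs, 40 miRNAs, 12 samples) keeps
a full pipeline run near 0.1 s, so recovery statistics are aggregated over
20 independent seeds and calibration checks use 2 500 null features and
10 000–20 000 correlation trials — enough for standard errors of a few
thousandths on the estimated rates. Degenerate inputs fail loudly:
all-zero matrices, zero library totals, constant vectors in correlations,
and conditions with fewer than two replicates all raise typed errors rather
than propagating NaNs. Ties and boundaries are resolved as stated above
(strict DE inequalities, inclusive 100 kb gap, 5′-most best site in the
complementarity scan).

## Known limitations

* No shrinkage of dispersions or fold changes; per-feature moment estimates
  are noisy at n = 3 and the t reference compensates only on average.
* The complementarity scorer is ungapped and penalty-based; it is not a
  replacement for dedicated miRNA target predictors.
* The trans rule tests each pair marginally; no correction for the number
  of pairs is applied, matching the screening convention it implements.
* GO/KEGG annotation, degradome validation, and tissue-specificity
  cross-checks are out of scope.
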