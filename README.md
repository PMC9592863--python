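# triadscreen

Direction-constrained lncRNA–miRNA–mRNA (ceRNA) regulatory-module screening
for two-genotype stress transcriptomics.

## The problem

Comparative whole-transcriptome studies of stress tolerance — here modeled on
a drought experiment contrasting a drought-tolerant (DT) and a
drought-sensitive (DS) wheat variety, each under control (CK) and drought
conditions with three biological replicates — produce three layers of
expression data: mRNAs, long noncoding RNAs (lncRNAs), and miRNAs. The
downstream question is which lncRNA–miRNA–mRNA triads act as competing
endogenous RNA (ceRNA) modules: a lncRNA that sponges a miRNA relieves the
miRNA's repression of its mRNA targets, so the three members should move in
opposite directions under stress (miRNA up with lncRNA and mRNA down, or the
mirror pattern).

`triadscreen` is a tested, reusable implementation of that downstream
inference:

* **Differential expression** per RNA layer and genotype (drought vs CK): a
  negative-binomial Wald test on median-of-ratios–normalized counts, with
  method-of-moments dispersion and a t reference with n₁+n₂−2 df. A feature
  is called when p < 0.05 and |log₂FC| > 1.
* **lncRNA identification**: consensus filtering (unknown biotype, > 200 nt,
  ≥ 2 exons, noncoding by all four of CPC/CNCI/CPAT/Pfam — consumed as a
  verdict table) and positional classification into lincRNA / antisense /
  intronic / sense against the gene models.
* **Target assignment**: cis targets (genes within 100 kb of a lncRNA),
  trans targets (|Pearson r| > 0.9 and p < 0.01 across samples), and miRNA
  targets (precomputed tables or a plant-miRNA complementarity penalty
  scorer).
* **Drought-resistance DEG screen**: six mutually exclusive classes — DT-only
  response with |log₂FC(DT)| > 2 (A up / B down), shared response with
  log₂FC(DT)/log₂FC(DS) > 3 (C / D), and opposite responses (E / F).
* **Triad module screen**: for each differentially expressed miRNA (DEM),
  its opposite-direction targeted DELs and DEGs are collected, and only
  DEL/DEG members linked pairwise by a cis or trans edge are retained; every
  DEM with non-empty retained sets yields one module.
* **Synthetic data with planted truth**: a negative-binomial simulator
  (variance μ + αμ²) for all three layers across the 12-sample design, with
  planted triads, cis/trans pair realization, depth variation, and a
  `PlantedTruth` record, so every stage is testable end-to-end with known
  ground truth.

## Worked example

```python
from triadscreen import SimulationConfig, run_pipeline

result = run_pipeline(sim_config=SimulationConfig(seed=1))
s = result.summary
print("mRNA venn:", s["venn"]["mRNA"])
print("drought classes:", s["drought_classes"])
print("n_modules:", s["n_modules"])
print("recovery:", s["recovery"])
```

prints (exactly, for seed 1):

```
mRNA venn: {'common': 0, 'ds_specific': 13, 'dt_specific': 17, 'union': 30}
drought classes: {'A': 4, 'B': 5, 'C': 0, 'D': 0, 'E': 0, 'F': 0, 'none': 291}
n_modules: 6
recovery: {'de_sensitivity': 1.0, 'de_false_call_rate': 0.0,
           'module_precision': 1.0, 'module_recall': 1.0,
           'n_planted_triads': 6, 'n_emitted_modules': 6}
```

Reading this: of 300 simulated genes, 13 were differentially expressed only
in DS and 17 only in DT (30 in the union, none shared); nine genes fell into
the DT-specific strong-response classes A/B; all six planted triads (three
per genotype) were recovered as modules with no false modules, and every
planted differential feature was called in its planted direction.

The same pipeline is available from the shell:

```bash
triadscreen run --out results/ --seed 1          # full pipeline + summary.json
triadscreen simulate --out sim/ --seed 7         # write simulated inputs only
triadscreen de --counts sim/counts_mRNA.tsv --design sim/design.tsv \
    --layer mrna --genotype DT --out de_mrna_DT.tsv
```

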