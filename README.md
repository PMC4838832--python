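# snactiv

Single-nucleus RNA-seq analysis of neuronal activation states.

When neurons fire in a behaving animal, immediate early genes (IEGs such as
*Fos*, *Arc* and *Egr1*) are rapidly induced. Sequencing single **nuclei**
sorted by FOS protein immunostain makes it possible to compare activated
(FOS+) and non-activated (FOS−) dentate granule cells without the spurious
activation that whole-cell dissociation itself induces. `snactiv`
implements the statistical pipeline for this kind of experiment:

- **QC** — three sample-exclusion criteria: uniquely mapped reads > 50,000,
  ERCC spike-in TPM significantly positively correlated with the known input
  concentrations (α = 0.05, one-sided on log₂ scale), and detected-gene
  count ≥ batch mean − 2σ.
- **Detection statistics** — per-group detection proportions (TPM > 1) and
  the 2×2 test of equal proportions with Yates' continuity correction,
  χ² = Σ max(0, |O−E|−½)² / E on 1 df; exact hypergeometric enrichment;
  and the a-priori two-sample t-test sample-size calculation using exact
  noncentral-t power.
- **Synthetic pooling** — repeatedly pool nuclei without replacement (≤ 25
  distinct subsets per pool size), call a gene pool-detected at TPM > 0 in
  ≥ 1 member, and track overlap with the bulk-detected set (bulk TPM > 1),
  with Fisher's exact test and Pearson correlation of log₂(TPM+1) profiles.
- **Differential expression** — a negative-binomial conditional exact test
  on median-of-ratios-normalized expected counts: group sums S₁, S₂ are NB
  with moderated method-of-moments dispersion φ; conditional on S₁+S₂ the
  law of S₁ is free of the mean, and the two-sided p sums all outcomes no
  more likely than the observed one (Binomial at φ = 0). BH FDR across genes.
- **Pseudotime** — supervised ordering: genes at adjusted p < 0.01 between
  stain groups are z-scored, reduced to two independent components
  (PCA whitening + fixed-point ICA, reported on the data scale), a minimum
  spanning tree is built over the nuclei, its diameter path becomes the main
  trajectory, and pseudotime is the normalized distance from the root (the
  endpoint with lower IEG-panel expression). Cluster assignment by cutting
  the longest tree edges, pseudo-FOS+ flagging, per-gene pseudotime
  regression, and leave-one-out ordering robustness.
- **Retrotransposons** — count reads whose template-switch oligo (TSO) is
  directly adjacent to the start of a RepeatMasker consensus (evidence of
  transcription from the element's own promoter) and normalize by all reads
  aligned to that consensus (promoter-normalized count).
- **GO networks** — gene–gene weighted cosine similarity over binary GO
  annotation vectors, each term weighted by its number of parents; edges
  kept at similarity > 0.5, exported as edge-list TSV or GraphML with
  distance 1 − similarity.
- **Synthetic data** — a generator that emulates the study design (36 FOS+
  vs 43 FOS− nuclei, ~6,000 detected genes per nucleus, a latent activation
  continuum driving a 500-gene program, NB noise with logistic dropout,
  ERCC spike-ins, pseudo-FOS+ label noise, TSO-prefixed TE reads) so the
  entire pipeline is testable without downloads.

## Worked example

```python
from snactiv import (SimulationConfig, generate_cohort, generate_ercc, run_de,
                     order_nuclei, prop_test_yates, min_sample_size, PowerSpec)
from snactiv.qc import apply_qc

cfg = SimulationConfig(seed=1)                  # 36 FOS+ vs 43 FOS- nuclei
counts, tpm, meta, truth = generate_cohort(cfg)
expected, observed, _ = generate_ercc(cfg, seed=1)

kept, report = apply_qc(tpm, meta, observed, expected)
print(int(report["overall_pass"].sum()), "of", len(report), "nuclei pass QC")
# 77 of 79 nuclei pass QC

exclude = list(truth.pseudo_positive.index[truth.pseudo_positive])
de = run_de(counts, meta, group_field="stain", exclude=exclude)
print(int(de["significant"].sum()), "genes at q<0.05")
# 451 genes at q<0.05

res = order_nuclei(tpm, de, meta, seed=0)
print(int(res.samples["on_main_path"].sum()), "of", len(res.samples),
      "nuclei on the main trajectory")
# 33 of 79 nuclei on the main trajectory
```

The inferred pseudotime recovers the generator's latent activation time with
Spearman |ρ| = 0.92 on this cohort. The classical statistics reproduce
textbook behaviour, e.g. a detection comparison of 30/38 vs 32/34 nuclei
gives χ² = 2.301, p = 0.129 under the Yates-corrected equal-proportion
test, and

```python
min_sample_size(PowerSpec(effect_size=1, alpha=0.05, power=0.95, ratio=1.14))
# (26, 30)
```

is the minimum pair of group sizes reaching 95% power for a standardized
difference of 1 at an allocation ratio of 1.14.

Every stage is also exposed as a CLI subcommand:

```sh
snactiv simulate --out-dir cohort --seed 1
snactiv qc --tpm cohort/tpm.tsv --metadata cohort/metadata.tsv \
    --ercc-observed cohort/ercc_observed.tsv \
    --ercc-expected cohort/ercc_expected.tsv --report qc.tsv
snactiv de --counts cohort/counts.tsv --metadata cohort/metadata.tsv --out de.tsv
snactiv power --effect-size 1 --alpha 0.05 --power 0.95 --ratio 1.14
```

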