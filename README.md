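# strainflow

Strain-resolved colonization tracking and fecal community typing for
infant probiotic trials.

When a *Bifidobacterium longum* subsp. *infantis* strain is given to
infants, shotgun metagenomics can tell whether the bacteria detected in a
stool sample *are* the supplemented strain or a naturally acquired
(autochthonous) resident. `strainflow` implements the full analysis
chain for a three-arm, four-visit supplementation trial:

- **SNV-based strain typing** over a 100-gene *B. infantis* signature-gene
  catalog: per-position consensus calling (base called when its allele
  frequency is ≥ 90% at sufficient depth), sample filters (≥ 250 reads on
  ≥ 10 signature genes), per-sample exclusion of genes with > 20%
  noisy positions, concatenated profiles, pairwise SNV distances,
  neighbor-joining tree rooted on *B. longum* subsp. *longum*, and a
  five-way categorization per sample — probiotic clade (`LMG11588`),
  `OtherInfantis`, `UntypedLow` (*B. infantis* below 0.16% relative
  abundance), `UntypedHet` (heterogeneous profile), `NotDetected`.
- **Longitudinal tracking**: per-infant trajectories, detection at
  baseline, colonization during supplementation (V2 and/or V3),
  persistence four weeks after cessation (V4), strain replacement events,
  and feeding-mode associations (chi-square).
- **Fecal community types (FCT)**: Dirichlet-multinomial mixture fit by
  EM over K = 1..15 components with 10 restarts, model choice by the
  Laplace approximation to the model evidence (AIC/BIC always reported),
  chronological relabeling, transition tables, and group-trajectory
  comparisons.
- **Ecology statistics**: richness/Shannon diversity, Bray–Curtis
  dissimilarity, PCoA, PERMANOVA with marginal terms and 1,000
  permutations, Procrustes association between microbiome and biomarker
  ordinations, Kendall tau-b taxon–biomarker matrices with
  Benjamini–Hochberg adjustment, and pathogen prevalence at sample and
  infant grain.
- **Trial statistics**: ANCOVA-adjusted weight-gain comparison (baseline
  weight + sex covariates, Tukey-adjusted CIs), non-inferiority decisions
  against a −3.6 g/day margin, closed-form sample size, relative risk,
  Freeman–Halton exact r×c tests, and LLD/LOD biomarker censoring rules.
- **Synthetic cohort generator**: every stage is exercised on a generated
  trial (228 infants, three arms, four visits) with machine-readable
  ground truth — planted strain genomes and SNVs, per-sample allele-count
  pileups whose depth scales with *B. infantis* abundance, genus tables
  drawn from a known Dirichlet-multinomial mixture, biomarkers with
  signed monotone coupling to abundance, and weight trajectories with
  configurable group effects.

The core statistical model for community typing is the
Dirichlet-multinomial: counts x with total N drawn from component k have

    log DM(x | α_k) = log N! − Σ_j log x_j! + log Γ(A_k) − log Γ(N + A_k)
                      + Σ_j [log Γ(x_j + α_kj) − log Γ(α_kj)],  A_k = Σ_j α_kj

and the mixture is fit by EM with Minka fixed-point updates for α.

## Worked example

```python
from strainflow.io import RunConfig
from strainflow.pipeline import run_pipeline

cfg = RunConfig(
    outdir="demo_out", seed=11, kmax=7, restarts=3, n_perm=99,
    simulate={"arm_sizes": [20, 20, 20], "n_genes": 30,
              "length_range": [300, 600]},
)
state = run_pipeline(cfg)
print(state["tracking_summary"]["intervention_colonization"])
print(state["tracking_summary"]["persistence"])
```

prints (60-infant demo cohort, seed 11):

```
{'n_colonized': 31, 'n_total': 40, 'rate': 0.775}
{'n_persisting': 21, 'n_total': 31, 'rate': 0.6774193548387096}
```

i.e. the probiotic strain was detected in 77.5% of experimental-arm
infants during supplementation and persisted at the post-cessation visit
in 67.7% of those — the pipeline recovered the generator's planted colonization
dynamics from raw allele counts. Every stage writes tidy TSV/JSON
outputs plus a manifest carrying the resolved configuration and its
hash.

The same pipeline is available from a shell:

```bash
strainflow run --config cohort.yaml --seed 11 --outdir demo_out
strainflow simulate --config cohort.yaml --outdir sim
strainflow type-strains --pileups sim/pileups.tsv --abundances sim/metadata.csv \
    --refs sim/references.fasta --catalog sim/catalog.json --outdir typed
```

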