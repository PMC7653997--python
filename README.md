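# feednet

Shared and specific genetic determinism of feed-efficiency criteria in
growing beef cattle, analysed through mixed-model GWAS and
association-weight-matrix (AWM) co-association gene networks.

Feed efficiency in fattening bulls is assessed by three criteria with
different constructions but overlapping genetics:

* **RFI** (residual feed intake): the residual of
  `FI = year + β₁·MMW + β₂·ADG + β₃·final_age + RFI`, where `MMW` is the
  metabolic mid-test weight (mid-test weight^0.75) and `ADG` the average
  daily gain. Negative RFI = efficient.
* **RG** (residual gain): the residual of
  `ADG = year + β₁·MMW + β₂·FI + β₃·final_age + RG`. Positive RG = efficient.
* **FE** (feed efficiency ratio): `ADG / FI`, the gain per kg of feed.

`feednet` implements the full analysis chain a geneticist would run to
dissect which genes the three criteria share:

1. **Trait derivation & precorrection** — ADG/MMW/RFI/RG/FE from raw
   test records; all six traits (plus FI, final weight FW, ADG)
   precorrected for contemporary-group year, dam-age class, twinning
   and final age.
2. **Mixed-linear-model association (MLMA)** — per variant,
   `y = 1μ + xb + u + e` with `u ~ N(0, G·σu²)`; `G` is the VanRaden
   genomic relationship matrix and `(σu², σe²)` are REML estimates
   under the null model, fixed during testing. Outputs per-variant
   effect, SE, z-score and P-value per trait.
3. **AWM network** — keyed on RFI, RG or FE: key SNPs at P ≤ 0.001,
   trait retention at |r| ≥ 0.25 between z-score vectors, secondary
   SNPs associated with ≥ 2 retained traits, then one SNP per gene
   (most associated traits, ties by lowest cumulated P).
4. **Panel quantification** — z-score genomic correlations between
   traits over the AWM rows, and GREML SNP heritability of the
   selected panel vs an equal-size random panel.

Because individual feed-intake records are rarely public, the package
includes a first-class synthetic-population generator
(`feednet.simulate`) emulating a genotyped Charolais fattening
population: 789 animals by default, block-LD dosages, base traits with
heritability 0.35 and genetic correlations r_g(FI,ADG)=0.44,
r_g(FI,FW)=0.76, r_g(ADG,FW)=0.80, a 22-year contemporary-group
structure, dam-age classes, twinning, and a synthetic gene annotation.

## Worked example

```python
from feednet import (SimConfig, simulate_population, derive_traits,
                     precorrect_phenotypes, compute_grm, fit_null_reml,
                     run_mlma, AWMConfig, build_awm, assign_genes,
                     select_snp_per_gene, summarize_network,
                     genomic_correlation, heritability_contrast, TRAITS)
from feednet.gwas import GRMEigen

pop = simulate_population(SimConfig(n_individuals=600, n_variants=4000,
                                    n_causal=40, n_chromosomes=8, seed=1))
traits = derive_traits(pop.traits)
corrected = precorrect_phenotypes(traits)
eig = GRMEigen(compute_grm(pop.genotypes))

results = {}
for t in TRAITS:
    y = corrected[t].to_numpy(float)
    vc = fit_null_reml(y, eig)
    results[t] = run_mlma(pop.genotypes, y, eig, vc)

awm = build_awm(results, AWMConfig(key_trait="RFI"))
gene_map = assign_genes(awm.variants.reset_index(), pop.annotation)
table, _ = select_snp_per_gene(awm, gene_map)
summary = summarize_network(table, "RFI")
```

Output on this configuration:

```
RFI: h2 = 0.17 +/- 0.10
AWM rows: 15 (10 key, 5 secondary); retained traits: ['RFI', 'RG', 'FE', 'FI', 'FW']
genes: 5 total = 0 RFI-only + 3 RFI-and-other + 2 other-only
z-score genomic correlation RFI-FE: -0.89
h2 from 15 AWM SNPs: 0.14 +/- 0.05; random panel: 0.00 +/- 0.01
```

Reading this: the null-model REML attributes 17% of the corrected RFI
variance to the genome-wide relationship matrix (residual criteria
carry less genetic variance than the base traits they are built from).
The RFI-keyed AWM keeps 15 co-associated variants; the retained-trait
list says every trait except ADG co-varies with RFI at the SNP-effect
level here. Gene reduction leaves 5 genes, partitioned exactly into
RFI-only / RFI-and-other / other-only. The z-score genomic correlation
between RFI and FE is strongly negative, as their constructions imply
(eating more than expected lowers gain per kg feed), and the selected
panel captures far more phenotypic variance than an equal random panel
— the signature of a co-association network enriched for causal
variation.

The same workflow runs from the shell:

```bash
feednet --seed 1 run-all --out-dir runs/demo
feednet --seed 1 simulate -n 600 -m 4000 --out-prefix runs/sim
```

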