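# contactzone

Population-genetic and phenotypic analysis of a stickleback contact zone:
when divergent freshwater-resident and anadromous three-spined sticklebacks
(*Gasterosteus aculeatus*) meet in one catchment, is the striking lateral
plate polymorphism the product of ongoing hybridisation, or of reproductive
isolation maintained by divergent selection?  This package implements the
quantitative toolkit needed to answer that question from codominant
microsatellite genotypes and morphological trait tables:

- **Diversity and differentiation** — observed/expected heterozygosity with
  the 2n/(2n−1) correction, chi-squared and Monte-Carlo exact
  Hardy–Weinberg tests, Bonferroni correction, and the two pairwise
  differentiation statistics: Weir–Cockerham's θ (the moment estimator of
  F_ST, combined across alleles and loci as a ratio of component sums) and
  Jost's D = [(H_T − H_S)/(1 − H_S)]·r/(r−1), each with 95% locus-bootstrap
  confidence intervals, on the full, neutral-only or QTL-only marker panel.
- **Selection inference** — P_ST = σ²_GB/(σ²_GB + 2σ²_GW) from REML variance
  components of a one-way random-effects model, bootstrap CIs over
  individuals within groups, and the P_ST–F_ST comparison
  (Pearson r, t = r√df/√(1−r²), df = pairs − 2).
- **Hybrid detection** — Mendelian simulation of the six two-generation
  genotype classes (parents, F1, F2, both backcrosses), a
  plug-in-frequency likelihood classifier over those classes, supervised
  admixture proportions q with the q ≥ 0.9 purity rule, and a power
  analysis that measures how reliably a marker panel recovers simulated
  hybrids.
- **Phenotype tools** — ANCOVA-style size correction, plate-morph
  classification (low ≤ 9 < partial < 29 ≤ complete), defensive-spine PCA
  (PC_AP), one-way ANOVA genotype–phenotype association, and HWE-expected
  phenotype-class fractions under an explicit penetrance model.
- **Synthetic data** — a Balding–Nichols three-ecotype generator (two
  resident populations and one anadromous, neutral F ≈ 0.12, a diallelic
  major plate locus fixed between ecotypes, correlated morphology) so the
  entire pipeline is testable without access to the original field data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import contactzone as cz

# synthetic contact zone: 3 ecotypes x 50 fish, 9 neutral + 5 QTL loci
ds = cz.simulate_three_ecotype_scenario(cz.ScenarioConfig(seed=0))

theta = cz.wc_theta(ds.genotypes, panel="neutral")
print(round(theta.value, 3))            # 0.156  multi-locus neutral theta

pst = cz.pairwise_pst(ds.phenotypes, ds.groups, trait="mean_plates",
                      n_boot=1000, seed=0)
e = pst[("resident1", "anadromous")]
print(round(e.point, 3), round(e.ci_low, 3), round(e.ci_high, 3))
                                        # 0.986 0.982 0.99

print(round(cz.t_from_r(0.83, 4), 2))   # 2.98
```

The neutral multi-locus θ of 0.156 says roughly 16% of allele-frequency
variance lies among the three ecotypes — strong neutral structure for
populations in physical contact.  The plate-number P_ST of 0.986 between a
resident and the anadromous population towers over that neutral baseline
(its 95% CI [0.982, 0.990] excludes every pairwise θ), the signature of
divergent selection on plate armour rather than drift.  The last line is the
t statistic for a P_ST–F_ST correlation of r = 0.83 across six group pairs
(df = 4): t = 2.98, p ≈ 0.04.

The same analyses run as numbered drivers over the synthetic dataset:

```sh
cd analysis
python 01_simulate_dataset.py       # writes results/data/
python 02_diversity_differentiation.py
python 03_pst_fst_selection.py
python 04_hybrid_power.py
python 05_genotype_phenotype.py
```

and as CLI subcommands over your own files (GenePop genotypes, phenotype
CSV, grouping TSV): `contactzone synth | stats | pst | simulate-hybrids |
power | associate`, each with `--seed` and `--out-dir`; identical seeds give
byte-identical output tables.

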