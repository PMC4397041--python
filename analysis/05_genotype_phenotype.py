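"""Phenotype processing and genotype-phenotype association.

Size-corrects the linear traits to mean body size (pooled within-population
ANCOVA slope), summarises the three defensive spines with a PCA (PC_AP),
classifies plate morphs, tests plate number against major-locus genotype with
a one-way ANOVA, and evaluates the HWE-expected fraction of complete-plated
fish implied by a recessive complete allele at a given frequency.
"""
import numpy as np
import pandas as pd

import contactzone as cz
from _common import ensure_dataset, write_table

if __name__ == "__main__":
    gt, pheno = ensure_dataset()

    traits = pheno.df[["BD", "DS1", "DS2", "PS", "GRL"]].astype(float)
    model = cz.size_correct(traits, pheno.trait("centroid_size"), gt.groups)
    slopes = pd.DataFrame({"trait": list(model.slopes),
                           "slope": list(model.slopes.values()),
                           "r2_size": [model.r_squared[t] for t in model.slopes]})
    write_table(slopes, "size_correction.tsv")
    print("allometric slopes on centroid size:")
    print(slopes.round(4).to_string(index=False))

    pca = cz.spine_pca(model.adjusted[["DS1", "DS2", "PS"]])
    print(f"\nspine PCA: axis 1 explains {100 * pca.variance_fractions[0]:.1f}% "
          f"of variance; loadings {np.round(pca.loadings['PC1'].to_numpy(), 3)}")
    write_table(pca.loadings, "spine_pca_loadings.tsv", index=True)

    morphs = cz.classify_plate_morphs(pheno.trait("mean_plates"))
    write_table(pd.DataFrame({"individual": morphs.index, "morph": morphs.values}),
                "plate_morphs.tsv")

    genos = cz.genotype_labels(gt, "EDA")
    assoc = cz.trait_anova(pheno.trait("mean_plates"), genos,
                           locus="EDA", trait="mean_plates", posthoc=True)
    print(f"\nplate number ~ EDA genotype: R2 = {assoc.r_squared:.2f}, "
          f"F_{assoc.df_between},{assoc.df_within} = {assoc.f_statistic:.1f}, "
          f"p = {assoc.p_value:.2g}")
    write_table(pd.DataFrame([{
        "locus": "EDA", "trait": "mean_plates", "F": assoc.f_statistic,
        "df_between": assoc.df_between, "df_within": assoc.df_within,
        "R2": assoc.r_squared, "p": assoc.p_value}]), "association.tsv")

    # if completes were a recessive class of a segregating diallelic locus,
    # what fraction of residents should be complete under HWE?
    pen = {"AA": 1.0, "Aa": 0.0, "aa": 0.0}
    frac = cz.expected_phenotype_fraction(0.283, pen)
    print(f"\nHWE-expected complete fraction at C-allele frequency 0.283 "
          f"(recessive model): {frac:.3f}")
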