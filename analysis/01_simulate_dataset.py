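"""Generate the synthetic three-ecotype contact-zone dataset.

Two freshwater-resident populations and one anadromous population, 50 fish
each: nine neutral microsatellites at F = 0.12, four QTL-linked markers at
F = 0.23, a diallelic major plate locus (fixed C in the anadromous fish, L in
both residents), plate counts driven by that locus plus polygenic noise, and
correlated body/spine/raker traits.  Writes GenePop + phenotype CSV + group
TSV under results/data/.
"""
import pandas as pd

import contactzone as cz
from _common import DATA, ensure_dataset

if __name__ == "__main__":
    gt, pheno = ensure_dataset()
    print(f"wrote {DATA}")
    print(gt)
    counts = pd.Series(gt.groups).value_counts()
    print("individuals per group:")
    print(counts.to_string())
    morphs = cz.classify_plate_morphs(pheno.trait("mean_plates"))
    tab = pd.crosstab(pd.Series(gt.groups), morphs)
    print("plate morphs by population:")
    print(tab.to_string())
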