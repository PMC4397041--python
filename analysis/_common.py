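"""Shared plumbing for the analysis drivers: canonical dataset location and
the default study conditions (three ecotypes, 50 fish per population, seed 0)."""
from pathlib import Path

import contactzone as cz

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"
FIGURES = ROOT / "results" / "figures"

SEED = 0
FLOAT_FMT = "%.10g"


def ensure_dataset():
    """Load the synthetic contact-zone dataset, generating it if absent."""
    DATA.mkdir(parents=True, exist_ok=True)
    gen = DATA / "genotypes.gen"
    if not gen.exists():
        ds = cz.simulate_three_ecotype_scenario(cz.ScenarioConfig(seed=SEED))
        cz.write_genepop(ds.genotypes, gen, title=f"synthetic contact zone seed={SEED}")
        cz.write_groups(ds.groups, DATA / "groups.tsv")
        cz.write_phenotypes(ds.phenotypes, DATA / "phenotypes.csv")
    qtl = [f"QTL{j:02d}" for j in range(1, 5)] + ["EDA"]
    gt = cz.read_genepop(gen, qtl_markers=qtl)
    gt = gt.with_groups(cz.read_groups(DATA / "groups.tsv"))
    pheno = cz.read_phenotypes(DATA / "phenotypes.csv")
    return gt, pheno


def write_table(df, name, index=False):
    TABLES.mkdir(parents=True, exist_ok=True)
    path = TABLES / name
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path
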