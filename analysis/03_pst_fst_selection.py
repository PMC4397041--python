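"""P_ST-F_ST comparison: is plate divergence stronger than neutral drift?

Individuals are grouped by population x plate morph (the contact-zone
grouping: resident1 low, resident2 low, resident2 partial, anadromous
complete), giving four groups and six pairs.  Pairwise P_ST for mean lateral
plate number (1000-replicate bootstrap over individuals within groups) is
compared against pairwise theta from each marker panel; P_ST exceeding
neutral theta in every pair with a positive P_ST-theta correlation is the
signature of divergent selection on plates.
"""
import numpy as np
import pandas as pd

import contactzone as cz
from _common import FIGURES, SEED, ensure_dataset, write_table


def morph_grouping(gt, pheno, min_size=5):
    """population x plate-morph labels, dropping tiny classes."""
    morphs = cz.classify_plate_morphs(pheno.trait("mean_plates"))
    labels = {i: f"{gt.groups[i]}_{morphs[i]}" for i in gt.individuals
              if not pd.isna(morphs[i])}
    counts = pd.Series(labels).value_counts()
    keep = set(counts[counts >= min_size].index)
    return {i: g for i, g in labels.items() if g in keep}


if __name__ == "__main__":
    gt, pheno = ensure_dataset()
    grouping = morph_grouping(gt, pheno)
    gt_m = gt.subset_individuals(sorted(grouping)).with_groups(grouping)
    print("plate-morph groups:",
          pd.Series(grouping).value_counts().to_dict())

    pst_mat = cz.pairwise_pst(pheno, grouping, trait="mean_plates",
                              n_boot=1000, seed=SEED)
    fst_mats = {
        panel: cz.pairwise_matrix(gt_m, statistic="theta_WC", panel=panel,
                                  n_boot=1000, seed=SEED)
        for panel in ("all", "neutral", "qtl")
    }
    report = cz.pst_fst_report(pst_mat, fst_mats)
    write_table(report.rows, "pst_fst_long.tsv")
    write_table(report.comparisons, "pst_fst_comparisons.tsv")

    print("\npairwise P_ST (mean_plates):")
    for (a, b), e in pst_mat.items():
        print(f"  {a} vs {b}: {e.point:.3f} [{e.ci_low:.3f}, {e.ci_high:.3f}]")
    print("\nP_ST-theta correlations per panel (df = n_pairs - 2):")
    print(report.comparisons.round(3).to_string(index=False))

    wide = report.rows.pivot_table(index=["group_a", "group_b"],
                                   columns="statistic", values="point",
                                   aggfunc="first")
    n_exceed = int((wide["P_ST"] >= wide["theta_WC"]).sum())
    print(f"\nP_ST is the largest differentiation measure in "
          f"{n_exceed}/{len(wide)} pairwise comparisons")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        FIGURES.mkdir(parents=True, exist_ok=True)
        rows = report.rows.copy()
        rows["pair"] = rows.group_a + "\nvs " + rows.group_b
        labels = sorted(rows.pair.unique())
        series = list(rows.groupby(["statistic", "panel"]))
        width = 0.8 / len(series)
        fig, ax = plt.subplots(figsize=(9, 4))
        for k, ((statistic, panel), sub) in enumerate(series):
            sub = sub.set_index("pair").reindex(labels)
            x = np.arange(len(labels)) + (k - (len(series) - 1) / 2) * width
            ax.bar(x, sub.point, width,
                   yerr=[(sub.point - sub.ci_low).clip(lower=0),
                         (sub.ci_high - sub.point).clip(lower=0)],
                   label=f"{statistic} ({panel})", capsize=2)
        ax.set_xticks(np.arange(len(labels)))
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_ylabel("differentiation")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(FIGURES / "pst_fst_barplot.png", dpi=120)
        print(f"barplot written to {FIGURES / 'pst_fst_barplot.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the barplot")
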