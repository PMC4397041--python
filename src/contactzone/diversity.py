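"""Heterozygosity and Hardy-Weinberg equilibrium tests per group x marker.

Observed heterozygosity H_O is the fraction of typed individuals that are
heterozygous.  Expected heterozygosity H_E carries the small-sample
correction 2n/(2n-1) applied to the gene-diversity term 1 - sum(p_a^2).

Two HWE tests are provided: a chi-squared goodness-of-fit of genotype counts
against the expectations implied by the observed allele frequencies, and a
Monte-Carlo exact test that permutes the 2n gene copies into random diploid
pairings and uses the chi-squared statistic as discrepancy measure (add-one
corrected p-value).  Bonferroni correction treats all tests supplied in one
call as a single family.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeTable, allele_frequencies


@dataclass
class DiversityResult:
    """Per group x marker H_O/H_E plus per-group panel means."""

    per_locus: pd.DataFrame        # group, marker, panel, n_typed, H_O, H_E
    group_panel_means: pd.DataFrame  # group, panel, mean_HO, mean_HE, n_loci


@dataclass
class HWEResult:
    """HWE test table; one row per group x marker."""

    table: pd.DataFrame  # group, marker, n_typed, statistic, df, p_value,
    #                      method, n_perm, significant_after_bonferroni
    alpha: float
    family_size: int


def heterozygosity(gt: GenotypeTable, grouping: dict | None = None) -> DiversityResult:
    """Observed and unbiased expected heterozygosity per group x marker.

    Undefined cells (no typed individuals) are reported as NaN.
    """
    if grouping is None:
        grouping = gt.groups
    labels = np.array([grouping[i] for i in gt.individuals])
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)

    rows = []
    for g in order:
        calls = gt.calls[labels == g]
        for j, m in enumerate(gt.markers):
            pair = calls[:, j, :]
            typed = pair[:, 0] != MISSING
            n = int(typed.sum())
            if n == 0:
                rows.append((g, m.name, m.panel, 0, np.nan, np.nan))
                continue
            p_obs = pair[typed]
            ho = float((p_obs[:, 0] != p_obs[:, 1]).mean())
            _, counts = np.unique(p_obs.ravel(), return_counts=True)
            p = counts / counts.sum()
            he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2))) if n > 0 else np.nan
            rows.append((g, m.name, m.panel, n, ho, he))
    per_locus = pd.DataFrame(
        rows, columns=["group", "marker", "panel", "n_typed", "H_O", "H_E"]
    )
    means = (
        per_locus.dropna(subset=["H_O", "H_E"])
        .groupby(["group", "panel"], sort=False)
        .agg(mean_HO=("H_O", "mean"), mean_HE=("H_E", "mean"), n_loci=("marker", "count"))
        .reset_index()
    )
    return DiversityResult(per_locus, means)


def _genotype_codes(pairs: np.ndarray, k: int, index: dict) -> np.ndarray:
    a = np.vectorize(index.__getitem__, otypes=[np.int64])(pairs[:, 0])
    b = np.vectorize(index.__getitem__, otypes=[np.int64])(pairs[:, 1])
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return lo * k + hi


def _chi2_parts(obs_pairs: np.ndarray, n: int):
    """Observed genotype counts, HWE expected counts and allele index."""
    alleles, copy_counts = np.unique(obs_pairs.ravel(), return_counts=True)
    k = len(alleles)
    p = copy_counts / copy_counts.sum()
    index = {int(a): i for i, a in enumerate(alleles)}
    codes = _genotype_codes(obs_pairs, k, index)
    obs = np.bincount(codes, minlength=k * k).astype(float)
    # expected counts for ordered-canonical codes i<=j
    exp = np.zeros(k * k)
    for i in range(k):
        for j in range(i, k):
            exp[i * k + j] = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
    keep = exp > 0
    return obs[keep], exp[keep], alleles, p, index, k, codes


def _chi2_stat(obs: np.ndarray, exp: np.ndarray) -> float:
    return float(np.sum((obs - exp) ** 2 / exp))


def hwe_test(
    gt: GenotypeTable,
    grouping: dict | None = None,
    method: str = "exact_mc",
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> HWEResult:
    """Hardy-Weinberg tests per group x marker.

    ``method='chi2'`` pools genotype classes with expected count < 1 into an
    "other" class and uses df = #classes - #alleles (floored at 1).
    ``method='exact_mc'`` permutes gene copies into random pairings;
    p = (1 + #{permuted chi2 >= observed}) / (1 + n_perm).

    Monomorphic markers get p = 1 by convention; fewer than two typed
    individuals gives a missing p.
    """
    if method not in ("chi2", "exact_mc"):
        raise ValueError("method must be 'chi2' or 'exact_mc'")
    if grouping is None:
        grouping = gt.groups
    labels = np.array([grouping[i] for i in gt.individuals])
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    rng = np.random.default_rng(seed)

    rows = []
    for g in order:
        calls = gt.calls[labels == g]
        for j, m in enumerate(gt.markers):
            pair = calls[:, j, :]
            typed = pair[:, 0] != MISSING
            n = int(typed.sum())
            if n < 2:
                rows.append((g, m.name, n, np.nan, np.nan, np.nan, method, 0))
                continue
            obs_pairs = pair[typed]
            obs, exp, alleles, p, index, k, codes = _chi2_parts(obs_pairs, n)
            if k == 1:
                rows.append((g, m.name, n, 0.0, np.nan, 1.0, method, 0))
                continue
            stat = _chi2_stat(obs, exp)
            if method == "chi2":
                # pool rare classes (expected < 1) into a single "other" class
                rare = exp < 1.0
                if rare.sum() > 1:
                    obs_p = np.append(obs[~rare], obs[rare].sum())
                    exp_p = np.append(exp[~rare], exp[rare].sum())
                else:
                    obs_p, exp_p = obs, exp
                stat_p = _chi2_stat(obs_p, exp_p)
                df = max(len(exp_p) - k, 1)
                pval = float(stats.chi2.sf(stat_p, df))
                rows.append((g, m.name, n, stat_p, df, pval, "chi2", 0))
            else:
                copies = obs_pairs.ravel()
                perm = np.tile(copies, (n_perm, 1))
                perm = rng.permuted(perm, axis=1).reshape(n_perm, n, 2)
                idx = np.vectorize(index.__getitem__, otypes=[np.int64])(perm)
                lo = idx.min(axis=2)
                hi = idx.max(axis=2)
                codes_perm = lo * k + hi
                offset = np.arange(n_perm)[:, None] * (k * k)
                flat = np.bincount(
                    (codes_perm + offset).ravel(), minlength=n_perm * k * k
                ).reshape(n_perm, k * k).astype(float)
                keep = np.zeros(k * k, dtype=bool)
                for i in range(k):
                    for jj in range(i, k):
                        keep[i * k + jj] = True
                exp_full = np.zeros(k * k)
                for i in range(k):
                    for jj in range(i, k):
                        exp_full[i * k + jj] = n * (p[i] ** 2 if i == jj else 2 * p[i] * p[jj])
                sel = keep & (exp_full > 0)
                stats_perm = ((flat[:, sel] - exp_full[sel]) ** 2 / exp_full[sel]).sum(axis=1)
                pval = float((1 + np.sum(stats_perm >= stat - 1e-12)) / (1 + n_perm))
                rows.append((g, m.name, n, stat, np.nan, pval, "exact_mc", n_perm))
    table = pd.DataFrame(
        rows,
        columns=["group", "marker", "n_typed", "statistic", "df", "p_value", "method", "n_perm"],
    )
    flags = bonferroni(table["p_value"].to_numpy(), alpha=alpha)
    table["significant_after_bonferroni"] = flags
    family = int(table["p_value"].notna().sum())
    return HWEResult(table, alpha, family)


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni flags: p_i < alpha / m with m = family size of this call.

    NaN p-values do not count toward the family and are flagged False.
    An empty family returns an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    m = int(np.sum(~np.isnan(p)))
    if m == 0:
        return np.zeros(p.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags = p < alpha / m
    return np.where(np.isnan(p), False, flags)
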