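"""Pairwise and multi-group differentiation: Weir-Cockerham theta and Jost's D.

theta is the moment estimator of F_ST built from three variance components per
allele per locus -- a (among populations), b (among individuals within
populations) and c (within individuals) -- combined across alleles and loci as
a ratio of sums.  Jost's D measures allelic differentiation from
sample-size-corrected within- (H_S) and total (H_T) expected heterozygosity:

    D_locus = [(H_T - H_S) / (1 - H_S)] * r / (r - 1)

with r the number of groups, H_S corrected by 2*nh/(2*nh - 1) (nh the harmonic
mean group size) and H_T by the matching + H_S/(2*nh*r) term.  The multi-locus
D averages the H_S and H_T components across loci before forming the ratio
(the behaviour of the diveRsity estimator); an alternative ``mean_of_loci``
combination is available.

Bootstrap confidence intervals resample loci with replacement by default (the
standard unit for multi-locus differentiation); resampling individuals within
groups is available as an alternative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable

log = logging.getLogger(__name__)

STATISTICS = ("theta_WC", "D_Jost")


@dataclass
class DiffEstimate:
    """A differentiation statistic with per-locus and multi-locus values."""

    statistic: str
    panel: str
    groups: tuple
    per_locus: pd.Series          # locus name -> value (NaN where undefined)
    value: float                  # multi-locus value
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    excluded_loci: tuple = ()
    # per-locus building blocks kept for the locus bootstrap
    _components: dict = field(default_factory=dict, repr=False)


def _locus_arrays(gt: GenotypeTable, labels: np.ndarray, groups: list[str], j: int):
    """Per-group sample sizes, allele-copy counts and heterozygote-carry counts
    for locus j.  Returns None when fewer than two groups are typed."""
    n_g, counts, hets = [], [], []
    pooled = []
    per_group_pairs = []
    for g in groups:
        pair = gt.calls[labels == g][:, j, :]
        typed = pair[pair[:, 0] != MISSING]
        if len(typed):
            pooled.append(typed.ravel())
        per_group_pairs.append(typed)
    if not pooled:
        return None
    alleles = np.unique(np.concatenate(pooled))
    index = {int(a): k for k, a in enumerate(alleles)}
    k = len(alleles)
    for typed in per_group_pairs:
        n = len(typed)
        if n == 0:
            continue
        idx = np.vectorize(index.__getitem__, otypes=[np.int64])(typed)
        cnt = np.bincount(idx.ravel(), minlength=k).astype(float)
        het_mask = typed[:, 0] != typed[:, 1]
        het = np.zeros(k)
        if het_mask.any():
            het_idx = idx[het_mask].ravel()
            het = np.bincount(het_idx, minlength=k).astype(float)
        n_g.append(n)
        counts.append(cnt)
        hets.append(het)
    if len(n_g) < 2:
        return None
    return np.array(n_g, float), np.array(counts), np.array(hets), alleles


def _wc_components_locus(n_g: np.ndarray, counts: np.ndarray, hets: np.ndarray):
    """Summed a, b, c over alleles at one locus (Weir & Cockerham 1984)."""
    r = len(n_g)
    nbar = n_g.mean()
    if nbar <= 1:
        return np.nan, np.nan
    n_c = (r * nbar - (n_g**2).sum() / (r * nbar)) / (r - 1)
    if n_c <= 0:
        return np.nan, np.nan
    p = counts / (2 * n_g[:, None])         # (r, k) allele freqs
    h = hets / n_g[:, None]                 # observed het-carry proportions
    pbar = (n_g[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_g[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_g[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / n_c) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def _jost_components_locus(n_g: np.ndarray, counts: np.ndarray):
    """(H_S, H_T, r) at one locus with Nei-Chesser sample-size corrections."""
    r = len(n_g)
    p = counts / (2 * n_g[:, None])
    nh = r / (1.0 / n_g).sum()              # harmonic mean sample size
    hs_raw = (1.0 - (p**2).sum(axis=1)).mean()
    hs = (2 * nh / (2 * nh - 1)) * hs_raw
    pbar = p.mean(axis=0)                   # unweighted across groups
    ht_raw = 1.0 - (pbar**2).sum()
    ht = ht_raw + hs / (2 * nh * r)
    return hs, ht, r


def _resolve_groups(gt, grouping, groups):
    if grouping is None:
        grouping = gt.groups
    labels = np.array([grouping[i] for i in gt.individuals])
    if groups is None:
        order: dict[str, None] = {}
        for lab in labels:
            order.setdefault(lab, None)
        groups = list(order)
    return labels, list(groups)


def wc_theta(
    gt: GenotypeTable,
    grouping: dict | None = None,
    panel: str = "all",
    groups: list | None = None,
) -> DiffEstimate:
    """Multi-group Weir-Cockerham theta (ratio of component sums across loci).

    Loci monomorphic across all groups (zero denominator) are excluded with a
    logged note.  Negative estimates are reported, never clamped.
    """
    gt = gt.subset_panel(panel)
    labels, groups = _resolve_groups(gt, grouping, groups)
    a_l, abc_l, names, excluded = [], [], [], []
    for j, m in enumerate(gt.markers):
        arrs = _locus_arrays(gt, labels, groups, j)
        if arrs is None:
            excluded.append(m.name)
            continue
        n_g, counts, hets, _ = arrs
        a, abc = _wc_components_locus(n_g, counts, hets)
        if not np.isfinite(abc) or abc == 0:
            excluded.append(m.name)
            continue
        a_l.append(a)
        abc_l.append(abc)
        names.append(m.name)
    if excluded:
        log.info("theta: excluded loci with undefined components: %s", excluded)
    if not a_l:
        raise ValueError("no informative loci for theta")
    a_arr, abc_arr = np.array(a_l), np.array(abc_l)
    per_locus = pd.Series(a_arr / abc_arr, index=names, name="theta_WC")
    value = float(a_arr.sum() / abc_arr.sum())
    return DiffEstimate(
        "theta_WC", panel, tuple(groups), per_locus, value,
        excluded_loci=tuple(excluded),
        _components={"a": a_arr, "abc": abc_arr},
    )


def jost_d(
    gt: GenotypeTable,
    grouping: dict | None = None,
    panel: str = "all",
    groups: list | None = None,
    combine: str = "components",
) -> DiffEstimate:
    """Jost's D across groups, per locus and multi-locus.

    ``combine='components'`` (default) averages H_S and H_T across loci before
    the ratio; ``combine='mean_of_loci'`` averages per-locus D values.  Loci
    with H_S = 1 exactly (D undefined) are excluded with a note; loci
    monomorphic in every group yield D = 0/0 and are likewise excluded.
    """
    if combine not in ("components", "mean_of_loci"):
        raise ValueError("combine must be 'components' or 'mean_of_loci'")
    gt = gt.subset_panel(panel)
    labels, groups = _resolve_groups(gt, grouping, groups)
    hs_l, ht_l, d_l, names, excluded = [], [], [], [], []
    r_seen = None
    for j, m in enumerate(gt.markers):
        arrs = _locus_arrays(gt, labels, groups, j)
        if arrs is None:
            excluded.append(m.name)
            continue
        n_g, counts, _, alleles = arrs
        hs, ht, r = _jost_components_locus(n_g, counts)
        if len(alleles) < 2:
            # monomorphic across all groups: no allelic differentiation signal
            excluded.append(m.name)
            continue
        if hs >= 1.0 - 1e-12:
            excluded.append(m.name)
            continue
        r_seen = r
        d = (ht - hs) / (1 - hs) * r / (r - 1)
        hs_l.append(hs)
        ht_l.append(ht)
        d_l.append(d)
        names.append(m.name)
    if excluded:
        log.info("jost_d: excluded loci: %s", excluded)
    if not d_l:
        raise ValueError("no informative loci for Jost's D")
    hs_arr, ht_arr = np.array(hs_l), np.array(ht_l)
    per_locus = pd.Series(d_l, index=names, name="D_Jost")
    if combine == "components":
        hs_m, ht_m = hs_arr.mean(), ht_arr.mean()
        value = float((ht_m - hs_m) / (1 - hs_m) * r_seen / (r_seen - 1))
    else:
        value = float(per_locus.mean())
    return DiffEstimate(
        "D_Jost", panel, tuple(groups), per_locus, value,
        excluded_loci=tuple(excluded),
        _components={"hs": hs_arr, "ht": ht_arr, "r": r_seen, "combine": combine},
    )


def _boot_from_components(est: DiffEstimate, rng: np.random.Generator, n_boot: int):
    L = len(est.per_locus)
    idx = rng.integers(0, L, size=(n_boot, L))
    if est.statistic == "theta_WC":
        a = est._components["a"][idx].sum(axis=1)
        abc = est._components["abc"][idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = a / abc
    else:
        hs = est._components["hs"][idx]
        ht = est._components["ht"][idx]
        r = est._components["r"]
        if est._components["combine"] == "components":
            hs_m, ht_m = hs.mean(axis=1), ht.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = (ht_m - hs_m) / (1 - hs_m) * r / (r - 1)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = ((ht - hs) / (1 - hs) * r / (r - 1)).mean(axis=1)
    return vals[np.isfinite(vals)]


def with_bootstrap_ci(
    est_fn,
    gt: GenotypeTable,
    grouping: dict | None,
    panel: str,
    groups: list | None,
    n_boot: int = 1000,
    seed: int | None = None,
    boot_unit: str = "loci",
) -> DiffEstimate:
    """Attach a 95% percentile bootstrap CI to a differentiation estimate.

    ``boot_unit='loci'`` resamples loci with replacement (default);
    ``'individuals'`` resamples individuals with replacement within groups and
    recomputes the statistic in full.
    """
    est = est_fn(gt, grouping=grouping, panel=panel, groups=groups)
    rng = np.random.default_rng(seed)
    if boot_unit == "loci":
        vals = _boot_from_components(est, rng, n_boot)
    elif boot_unit == "individuals":
        if grouping is None:
            grouping = gt.groups
        labels = np.array([grouping[i] for i in gt.individuals])
        vals = []
        for _ in range(n_boot):
            pick: list[int] = []
            for g in est.groups:
                where = np.flatnonzero(labels == g)
                pick.extend(rng.choice(where, size=len(where), replace=True))
            # rebuild with duplicated individuals under fresh ids
            sub_ids = [f"b{t}" for t in range(len(pick))]
            sub = GenotypeTable(
                sub_ids, gt.markers, gt.calls[pick],
                {f"b{t}": labels[k] for t, k in enumerate(pick)},
            )
            try:
                vals.append(est_fn(sub, grouping=None, panel="all", groups=list(est.groups)).value)
            except ValueError:
                continue
        vals = np.array(vals)
    else:
        raise ValueError("boot_unit must be 'loci' or 'individuals'")
    if len(vals) == 0:
        ci_low = ci_high = np.nan
    else:
        ci_low, ci_high = np.percentile(vals, [2.5, 97.5])
        if len(est.per_locus) == 1:
            log.info("single informative locus: degenerate bootstrap CI")
    est.ci_low, est.ci_high, est.n_boot = float(ci_low), float(ci_high), n_boot
    return est


@dataclass
class PairwiseResult:
    """All unordered group pairs for one statistic and panel."""

    statistic: str
    panel: str
    groups: tuple
    estimates: dict  # (gA, gB) sorted-by-group-order tuple -> DiffEstimate

    @property
    def mean_value(self) -> float:
        return float(np.mean([e.value for e in self.estimates.values()]))

    def value(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.estimates else (b, a)
        return self.estimates[key].value

    def to_frame(self) -> pd.DataFrame:
        g = list(self.groups)
        mat = pd.DataFrame(np.nan, index=g, columns=g)
        for (a, b), e in self.estimates.items():
            mat.loc[a, b] = e.value
            mat.loc[b, a] = e.value
        return mat

    def long_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "statistic": self.statistic,
             "panel": self.panel, "value": e.value,
             "ci_low": e.ci_low, "ci_high": e.ci_high}
            for (a, b), e in self.estimates.items()
        ]
        return pd.DataFrame(rows)


def pairwise_matrix(
    gt: GenotypeTable,
    grouping: dict | None = None,
    statistic: str = "theta_WC",
    panel: str = "all",
    n_boot: int = 1000,
    seed: int | None = None,
    boot_unit: str = "loci",
) -> PairwiseResult:
    """Pairwise differentiation with bootstrap CIs for all group pairs."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    est_fn = wc_theta if statistic == "theta_WC" else jost_d
    if grouping is None:
        grouping = gt.groups
    labels = [grouping[i] for i in gt.individuals]
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    groups = list(order)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ss = np.random.SeedSequence(seed)
    estimates = {}
    for (a, b), child in zip(
        combinations(groups, 2), ss.spawn(len(groups) * (len(groups) - 1) // 2)
    ):
        keep = {i for i in gt.individuals if grouping[i] in (a, b)}
        sub = gt.subset_individuals([i for i in gt.individuals if i in keep])
        estimates[(a, b)] = with_bootstrap_ci(
            est_fn, sub, grouping, panel, [a, b],
            n_boot=n_boot, seed=child, boot_unit=boot_unit,
        )
    return PairwiseResult(statistic, panel, tuple(groups), estimates)
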