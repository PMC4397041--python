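"""P_ST: phenotypic divergence from trait variance components, and its
comparison against F_ST.

P_ST is the phenotypic analogue of Q_ST computed from a one-way random-effects
decomposition of a heritable trait:

    P_ST = sigma2_GB / (sigma2_GB + 2 * sigma2_GW)

where sigma2_GB is the among-population trait variance and sigma2_GW the mean
within-population variance.  The general literature inserts a c/h^2 scalar in
front of sigma2_GB; the formula above takes it as 1, and ``scalar`` is exposed
for sensitivity analyses.

Variance components are REML estimates of the one-way random-intercept model.
For balanced designs REML coincides with the ANOVA method-of-moments solution
sigma2_GB = max(0, (MSB - MSW)/n), sigma2_GW = MSW, and a closed form is used;
unbalanced designs profile the restricted likelihood over the variance ratio
with a 1-D bounded optimisation.  Negative boundary estimates are reported as
zero and flagged.

Confidence intervals are 95% percentile bootstrap over individuals resampled
with replacement within groups (the natural unit for a trait-variance
statistic); 1000 replicates by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents", "PstEstimate", "PstFstComparison",
    "variance_components", "pst", "pst_with_ci", "pairwise_pst",
    "t_from_r", "pst_fst_correlation", "pst_fst_report",
]


@dataclass
class VarianceComponents:
    """REML variance components of a one-way random-intercept model."""

    sigma2_gb: float
    sigma2_gw: float
    n_groups: int
    n_total: int
    boundary: bool = False  # True when the among-group component hit zero


@dataclass
class PstEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    trait: str
    groups: tuple
    components: VarianceComponents | None = None


@dataclass
class PstFstComparison:
    pairs: list
    pst_values: np.ndarray
    fst_values: np.ndarray
    r: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# variance components


def _group_summaries(values, groups):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    uniq: dict = {}
    for lab in labels:
        uniq.setdefault(lab, None)
    n_g, means, ssw = [], [], []
    used = []
    for g in uniq:
        v = values[labels == g]
        if len(v) < 2:
            warnings.warn(f"group {g!r} has <2 values; excluded from variance components")
            continue
        n_g.append(len(v))
        means.append(v.mean())
        ssw.append(((v - v.mean()) ** 2).sum())
        used.append(g)
    if len(used) < 2:
        raise ValueError("need at least two groups with >=2 non-missing values")
    return np.array(n_g, float), np.array(means), np.array(ssw), used


def _vc_balanced(n_g, means, ssw):
    """Closed-form REML (= ANOVA method of moments) for balanced designs."""
    k, n = len(n_g), n_g[0]
    N = k * n
    msw = ssw.sum() / (N - k)
    ssb = n * ((means - means.mean()) ** 2).sum()
    msb = ssb / (k - 1)
    if msb > msw:
        return (msb - msw) / n, msw, False
    # boundary: single-variance model over all observations
    return 0.0, (ssw.sum() + ssb) / (N - 1), True


def _vc_reml_unbalanced(n_g, means, ssw):
    N = n_g.sum()
    ssw_tot = ssw.sum()

    def profile(lam):
        w = n_g / (1.0 + lam * n_g)
        sw = w.sum()
        mu = (w * means).sum() / sw
        q = ssw_tot + (w * (means - mu) ** 2).sum()
        crit = (N - 1) * np.log(q) + np.log1p(lam * n_g).sum() + np.log(sw)
        return crit, q

    res = optimize.minimize_scalar(
        lambda t: profile(np.exp(t))[0], bounds=(-30.0, 15.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = float(np.exp(res.x))
    crit_hat, q_hat = profile(lam_hat)
    crit0, q0 = profile(0.0)
    if crit0 <= crit_hat or lam_hat < 1e-9:
        s2w = q0 / (N - 1)
        return 0.0, s2w, True
    s2w = q_hat / (N - 1)
    return lam_hat * s2w, s2w, False


def variance_components(values, groups) -> VarianceComponents:
    """REML components of trait variance among and within populations.

    Parameters
    ----------
    values : array-like of float
        Per-individual trait values; NaN allowed.
    groups : array-like
        Population label per individual, aligned with ``values``.
    """
    n_g, means, ssw, used = _group_summaries(values, groups)
    if np.all(n_g == n_g[0]):
        gb, gw, boundary = _vc_balanced(n_g, means, ssw)
    else:
        gb, gw, boundary = _vc_reml_unbalanced(n_g, means, ssw)
    return VarianceComponents(float(gb), float(gw), len(used), int(n_g.sum()), boundary)


def pst(vc: VarianceComponents, scalar: float = 1.0) -> float:
    """P_ST = scalar*sigma2_GB / (scalar*sigma2_GB + 2*sigma2_GW)."""
    num = scalar * vc.sigma2_gb
    den = num + 2.0 * vc.sigma2_gw
    if den == 0:
        raise ValueError("P_ST undefined: both variance components are zero")
    return float(num / den)


def _pst_from_summaries(n_g, means, ssw, scalar):
    if np.all(n_g == n_g[0]):
        gb, gw, _ = _vc_balanced(n_g, means, ssw)
    else:
        gb, gw, _ = _vc_reml_unbalanced(n_g, means, ssw)
    den = scalar * gb + 2 * gw
    if den == 0:
        return 0.0  # degenerate resample: no variance at all
    return scalar * gb / den


def pst_with_ci(
    values,
    groups,
    n_boot: int = 1000,
    seed: int | None = None,
    scalar: float = 1.0,
    trait: str = "",
) -> PstEstimate:
    """Point P_ST plus a 95% percentile bootstrap CI.

    Individuals are resampled with replacement within their own group, so
    group sizes are preserved across replicates.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    vc = variance_components(values, labels)
    point = pst(vc, scalar=scalar)

    rng = np.random.default_rng(seed)
    uniq: dict = {}
    for lab in labels:
        uniq.setdefault(lab, None)
    group_vals = [values[labels == g] for g in uniq if (labels == g).sum() >= 2]
    k = len(group_vals)
    # vectorised resampling: per group an (n_boot, n_g) matrix of draws
    boot_means = np.empty((n_boot, k))
    boot_ssw = np.empty((n_boot, k))
    n_g = np.empty(k)
    for gi, v in enumerate(group_vals):
        n = len(v)
        n_g[gi] = n
        draw = v[rng.integers(0, n, size=(n_boot, n))]
        m = draw.mean(axis=1)
        boot_means[:, gi] = m
        boot_ssw[:, gi] = ((draw - m[:, None]) ** 2).sum(axis=1)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = _pst_from_summaries(n_g, boot_means[b], boot_ssw[b], scalar)
    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    return PstEstimate(point, float(ci_low), float(ci_high), n_boot, trait,
                       tuple(uniq), vc)


def pairwise_pst(
    phenotypes,
    grouping: dict,
    trait: str = "mean_plates",
    n_boot: int = 1000,
    seed: int | None = None,
    scalar: float = 1.0,
) -> dict:
    """P_ST for every unordered group pair, components refit per pair.

    ``phenotypes`` is a :class:`~contactzone.data.PhenotypeTable` or a
    DataFrame indexed by individual id.  Returns {(gA, gB) -> PstEstimate}.
    """
    df = phenotypes.df if hasattr(phenotypes, "df") else phenotypes
    vals = pd.to_numeric(df[trait], errors="coerce")
    ids = [i for i in df.index if i in grouping]
    values = vals.loc[ids].to_numpy(dtype=float)
    labels = np.array([grouping[i] for i in ids])
    order: dict = {}
    for lab in labels:
        order.setdefault(lab, None)
    groups = list(order)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ss = np.random.SeedSequence(seed)
    out = {}
    for (a, b), child in zip(combinations(groups, 2),
                             ss.spawn(len(groups) * (len(groups) - 1) // 2)):
        sel = (labels == a) | (labels == b)
        out[(a, b)] = pst_with_ci(
            values[sel], labels[sel], n_boot=n_boot, seed=child,
            scalar=scalar, trait=trait,
        )
    return out


# ---------------------------------------------------------------------------
# P_ST vs F_ST


def t_from_r(r: float, df: int) -> float:
    """t statistic of a Pearson correlation: t = r*sqrt(df)/sqrt(1-r^2)."""
    if not -1.0 < r < 1.0:
        raise ValueError("|r| = 1: t statistic diverges (degenerate correlation)")
    return float(r * np.sqrt(df) / np.sqrt(1.0 - r * r))


def _pair_values(matrix) -> dict:
    """Normalise a pairwise container to {sorted pair tuple -> float}."""
    if hasattr(matrix, "estimates"):  # PairwiseResult
        return {tuple(k): e.value for k, e in matrix.estimates.items()}
    out = {}
    for k, v in dict(matrix).items():
        key = tuple(k)
        out[key] = v.point if hasattr(v, "point") else (v.value if hasattr(v, "value") else float(v))
    return out


def pst_fst_correlation(pst_matrix, fst_matrix) -> PstFstComparison:
    """Pearson correlation between matched pairwise P_ST and F_ST values.

    The pairwise values are treated as independent observations, so df equals
    (number of pairs) - 2; with the study's four groups and six pairs this
    gives df = 4.  Fewer than four pairs or a constant vector is an error.
    """
    p_vals = _pair_values(pst_matrix)
    f_vals = _pair_values(fst_matrix)
    pairs = sorted(set(map(frozenset, p_vals)) & set(map(frozenset, f_vals)), key=sorted)
    if len(pairs) < 4:
        raise ValueError("need at least 4 matching group pairs (df >= 2)")

    def pick(d, fs):
        for k, v in d.items():
            if frozenset(k) == fs:
                return v
        raise KeyError(fs)

    x = np.array([pick(p_vals, fs) for fs in pairs])
    y = np.array([pick(f_vals, fs) for fs in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant pairwise vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = len(pairs) - 2
    t = t_from_r(r, df)
    p = float(2 * stats.t.sf(abs(t), df))
    return PstFstComparison([tuple(sorted(fs)) for fs in pairs], x, y, r, t, df, p)


@dataclass
class PstFstReport:
    rows: pd.DataFrame          # pair, statistic, panel, point, ci_low, ci_high
    comparisons: pd.DataFrame   # panel, r, t, df, p


def pst_fst_report(pst_matrix: dict, fst_matrices: dict) -> PstFstReport:
    """Long-format comparison table suitable for a barplot, plus one
    correlation row per marker panel."""
    rows = []
    for (a, b), e in pst_matrix.items():
        a, b = sorted((a, b))
        rows.append({"group_a": a, "group_b": b, "statistic": "P_ST",
                     "panel": "trait", "point": e.point,
                     "ci_low": e.ci_low, "ci_high": e.ci_high})
    for panel, mat in fst_matrices.items():
        ests = mat.estimates if hasattr(mat, "estimates") else mat
        for (a, b), e in ests.items():
            a, b = sorted((a, b))   # canonical pair order across matrices
            rows.append({"group_a": a, "group_b": b, "statistic": e.statistic,
                         "panel": panel, "point": e.value,
                         "ci_low": e.ci_low, "ci_high": e.ci_high})
    comps = []
    for panel, mat in fst_matrices.items():
        try:
            c = pst_fst_correlation(pst_matrix, mat)
            comps.append({"panel": panel, "r": c.r, "t": c.t, "df": c.df, "p": c.p})
        except ValueError:
            comps.append({"panel": panel, "r": np.nan, "t": np.nan,
                          "df": np.nan, "p": np.nan})
    return PstFstReport(pd.DataFrame(rows), pd.DataFrame(comps))
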