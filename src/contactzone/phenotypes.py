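"""Trait size-correction, plate-morph classification, spine PCA and
genotype-phenotype association tests.

Size correction follows the common-within-group-slope ANCOVA convention: a
single slope per trait is estimated by pooling within-group covariances, and
every observation is adjusted to the grand mean of the size covariate,
``adjusted = observed - b * (size - mean(size))``.  This removes allometric
scaling without erasing group mean differences.

Lateral plate morphs are classed on the mean of left and right plate counts:
low (<= 9), partial (9, 29), complete (>= 29).  The printed class limits
overlap at 9, so 9 resolves to low; the partial exemplar of 10.5 and the
complete floor of 29 are preserved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PLATE_MORPHS = ("low", "partial", "complete")


@dataclass
class SizeCorrectionModel:
    slopes: dict          # trait -> common within-group slope b
    r_squared: dict       # trait -> within-group variance explained by size
    grand_mean_size: float
    adjusted: pd.DataFrame


@dataclass
class SpinePcaResult:
    loadings: pd.DataFrame        # traits x axes, unit-norm columns
    variance_fractions: np.ndarray
    scores: pd.Series             # axis-1 scores (PC_AP) per individual


@dataclass
class AssociationResult:
    locus: str
    trait: str
    f_statistic: float
    df_between: int
    df_within: int
    r_squared: float
    p_value: float
    group_means: pd.Series
    posthoc: pd.DataFrame | None = None


def size_correct(traits: pd.DataFrame, size: pd.Series, grouping: dict) -> SizeCorrectionModel:
    """Adjust traits to mean body size with a pooled within-group slope.

    Parameters
    ----------
    traits : DataFrame indexed by individual id, one column per trait.
    size : Series of the size covariate (e.g. centroid size), same index.
    grouping : individual -> group label; groups need >= 3 individuals.
    """
    ids = [i for i in traits.index if i in grouping]
    traits = traits.loc[ids]
    size = pd.to_numeric(size.loc[ids], errors="coerce")
    labels = pd.Series([grouping[i] for i in ids], index=ids)
    counts = labels.value_counts()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("size correction needs >=2 groups with >=3 individuals each")
    if (size <= 0).any():
        raise ValueError("size covariate must be positive")

    grand = float(size.mean())
    slopes: dict = {}
    r2: dict = {}
    adjusted = {}
    for col in traits.columns:
        y = pd.to_numeric(traits[col], errors="coerce")
        sxy = sxx = syy = 0.0
        for g, idx in labels.groupby(labels).groups.items():
            xs, ys = size.loc[idx], y.loc[idx]
            ok = xs.notna() & ys.notna()
            xs, ys = xs[ok], ys[ok]
            if len(xs) < 2:
                continue
            xd, yd = xs - xs.mean(), ys - ys.mean()
            sxy += float((xd * yd).sum())
            sxx += float((xd * xd).sum())
            syy += float((yd * yd).sum())
        if sxx == 0:
            raise ValueError(f"zero within-group size variance for trait {col}")
        b = sxy / sxx
        slopes[col] = b
        r2[col] = (sxy * sxy / sxx) / syy if syy > 0 else 0.0
        adjusted[col] = y - b * (size - grand)
    return SizeCorrectionModel(slopes, r2, grand, pd.DataFrame(adjusted, index=traits.index))


def classify_plate_morph(mean_plates: float) -> str:
    """Plate-morph class from the mean lateral plate count.

    low: 0 <= x <= 9; partial: 9 < x < 29; complete: x >= 29.
    """
    x = float(mean_plates)
    if np.isnan(x):
        raise ValueError("mean_plates is missing")
    if x < 0:
        raise ValueError("mean_plates must be non-negative")
    if x <= 9:
        return "low"
    if x < 29:
        return "partial"
    return "complete"


def classify_plate_morphs(mean_plates: pd.Series) -> pd.Series:
    """Vectorised morph classification; missing values stay missing."""
    v = pd.to_numeric(mean_plates, errors="coerce")
    if (v.dropna() < 0).any():
        raise ValueError("mean_plates must be non-negative")
    out = pd.Series(pd.NA, index=v.index, dtype="object")
    out[v <= 9] = "low"
    out[(v > 9) & (v < 29)] = "partial"
    out[v >= 29] = "complete"
    return out


def spine_pca(spines: pd.DataFrame, use_correlation: bool = False) -> SpinePcaResult:
    """PCA of the (size-corrected) defensive spine lengths DS1, DS2, PS.

    Works on the covariance matrix by default.  The first axis (PC_AP) is the
    anti-predator summary score; its sign is fixed so that all spine loadings
    are non-negative when the loadings share a sign, otherwise so that the
    largest-magnitude loading is positive.
    """
    X = spines.dropna().astype(float)
    if len(X) < 3:
        raise ValueError("need >=3 complete cases for the spine PCA")
    mat = np.corrcoef(X.T) if use_correlation else np.cov(X.T)
    if not np.isfinite(mat).all() or np.allclose(mat, 0):
        raise ValueError("degenerate spine covariance (all traits constant?)")
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for k in range(evecs.shape[1]):
        v = evecs[:, k]
        if np.all(v <= 0):
            evecs[:, k] = -v
        elif not np.all(v >= 0) and v[np.argmax(np.abs(v))] < 0:
            evecs[:, k] = -v
    fractions = evals / evals.sum()
    loadings = pd.DataFrame(
        evecs, index=list(spines.columns),
        columns=[f"PC{k + 1}" for k in range(evecs.shape[1])],
    )
    centred = X - X.mean(axis=0)
    scores = pd.Series(centred.to_numpy() @ evecs[:, 0], index=X.index, name="PC_AP")
    return SpinePcaResult(loadings, fractions, scores)


def trait_anova(values, labels, posthoc: bool = False,
                locus: str = "", trait: str = "") -> AssociationResult:
    """One-way fixed-effects ANOVA of a trait across genotype classes.

    Reports F, p, R^2 = SS_between / SS_total and the per-class trait means.
    With ``posthoc=True`` a Tukey HSD table of pairwise class comparisons is
    attached.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    lab = pd.Series(np.asarray(labels, dtype=object), index=v.index)
    ok = v.notna() & lab.notna()
    v, lab = v[ok], lab[ok]
    counts = lab.value_counts()
    usable = counts[counts >= 2].index
    v, lab = v[lab.isin(usable)], lab[lab.isin(usable)]
    k = len(usable)
    if k < 2:
        raise ValueError("need >=2 classes with >=2 values for ANOVA")
    grand = v.mean()
    means = v.groupby(lab).mean()
    ns = v.groupby(lab).count()
    ssb = float((ns * (means - grand) ** 2).sum())
    sst = float(((v - grand) ** 2).sum())
    ssw = sst - ssb
    dfb, dfw = k - 1, len(v) - k
    if ssw == 0:
        f = np.inf
        p = 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
    r2 = ssb / sst if sst > 0 else np.nan
    post = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(v.to_numpy(), lab.to_numpy())
        post = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return AssociationResult(locus, trait, float(f), dfb, dfw, float(r2), p,
                             means.sort_index(), post)


def genotype_labels(gt, locus: str) -> pd.Series:
    """Genotype-class label per individual at one locus (e.g. '172/240')."""
    j = gt.marker_names.index(locus)
    pair = gt.calls[:, j, :]
    out = {}
    for k, ind in enumerate(gt.individuals):
        a1, a2 = pair[k]
        out[ind] = np.nan if a1 < 0 else f"{a1}/{a2}"
    return pd.Series(out, name=locus)


def expected_phenotype_fraction(p_allele: float, penetrance: dict) -> float:
    """HWE-expected fraction of a phenotype class at a diallelic locus.

    ``p_allele`` is the frequency of the focal allele (e.g. the 'complete'
    allele C); ``penetrance`` maps each genotype class 'AA', 'Aa', 'aa' (focal
    homozygote, heterozygote, other homozygote) to the probability of showing
    the phenotype.  A recessive complete phenotype is ``{'AA': 1, 'Aa': 0,
    'aa': 0}``, giving p^2.
    """
    if not 0.0 <= p_allele <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    required = {"AA", "Aa", "aa"}
    if set(penetrance) != required:
        raise ValueError(f"penetrance map must have exactly the keys {sorted(required)}")
    for k, w in penetrance.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"penetrance[{k!r}] = {w} outside [0, 1]")
    p, q = p_allele, 1.0 - p_allele
    return float(p * p * penetrance["AA"] + 2 * p * q * penetrance["Aa"]
                 + q * q * penetrance["aa"])


def allele_freq_from_phenotype(fraction: float, model: str = "recessive") -> float:
    """Invert a phenotype-class frequency to an allele frequency under HWE.

    ``model='recessive'``: phenotype expressed only by focal homozygotes, so
    p = sqrt(fraction).  ``model='dominant'``: expressed by carriers, so
    p = 1 - sqrt(1 - fraction).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if model == "recessive":
        return float(np.sqrt(fraction))
    if model == "dominant":
        return float(1.0 - np.sqrt(1.0 - fraction))
    raise ValueError("model must be 'recessive' or 'dominant'")
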