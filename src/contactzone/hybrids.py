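"""Likelihood classification into the six genotype classes, supervised
admixture proportions, the q >= 0.9 purity rule, and the power analysis.

The classifier is a plug-in-frequency simplification of the Bayesian genotype
-class samplers used for hybrid detection: baseline allele frequencies are
point estimates with a Laplace-style pseudo-count (0.5 per allele of the
observed universe) rather than being integrated over, loci are treated as
unlinked, and the class prior is uniform.  Per locus, with p the smoothed
frequencies of baseline A and q of baseline B, a genotype {i, j} has

    P({i,j} | class) = phi_AA * P_AA + phi_AB * P_AB + phi_BB * P_BB
    P_AA = p_i^2 (i = j)  or  2 p_i p_j
    P_BB analogous with q
    P_AB = p_i q_i (i = j) or  p_i q_j + p_j q_i

with (phi_AA, phi_AB, phi_BB) the ancestry-pair frequencies of the class.
Missing loci are skipped per individual.

The supervised admixture proportion q maximises the likelihood of a per-copy
mixture x_a = q p_a + (1-q) q_a over q in [0, 1]; the log-likelihood is
concave, so the optimum is found by bisection on its derivative with endpoint
checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, allele_frequencies
from .crosses import (ANCESTRY_FREQS, CLASS_ORDER, PARENT_CLASSES, CrossSpec,
                      simulate_cross)
from .differentiation import wc_theta


def smooth_frequencies(freqs: dict, n_typed, universe: dict, pseudo: float = 0.5) -> dict:
    """Add ``pseudo`` to every allele count of the observed universe and
    renormalise.  ``freqs`` maps marker -> {allele -> frequency}; ``n_typed``
    is a per-marker dict (or scalar) of typed diploid individuals; ``universe``
    maps marker -> iterable of alleles observed in either baseline."""
    out = {}
    for m, fr in freqs.items():
        n = n_typed[m] if isinstance(n_typed, dict) else n_typed
        copies = 2.0 * n
        alleles = sorted(universe[m])
        counts = {a: fr.get(a, 0.0) * copies + pseudo for a in alleles}
        total = sum(counts.values())
        out[m] = {a: c / total for a, c in counts.items()}
    return out


@dataclass
class ClassPosterior:
    """Per-individual log-likelihoods and posteriors over the six classes."""

    table: pd.DataFrame  # index individual; loglik_<c>, post_<c>, assigned

    @property
    def assigned(self) -> pd.Series:
        return self.table["assigned"]


@dataclass
class AdmixtureEstimate:
    q: float
    loglik: float
    pure_flag: bool
    threshold: float = 0.9


@dataclass
class PurifiedBaselines:
    cohort_a: GenotypeTable
    cohort_b: GenotypeTable
    excluded: list
    q_values: pd.Series


@dataclass
class PowerReport:
    """Assignment accuracy of the simulated-cross pipeline."""

    per_class: pd.DataFrame       # class x (mean accuracy, per-rep columns)
    confusion: pd.DataFrame       # true class x assigned class, summed over reps
    dichotomy_accuracy: float     # parent-vs-hybrid coarse accuracy (mean over reps)
    panel: str
    baseline_theta: float
    n_per_class: int
    n_reps: int


class ClassifierModel:
    """Plug-in-frequency classifier for two baselines over shared loci."""

    def __init__(self, freqsA: dict, freqsB: dict, nA=50, nB=50, pseudo: float = 0.5,
                 markers: list | None = None):
        loci = list(freqsA)
        if list(freqsB) != loci:
            raise ValueError("baselines defined on different loci")
        universe = {m: set(freqsA[m]) | set(freqsB[m]) for m in loci}
        self.loci = loci
        self.pA = smooth_frequencies(freqsA, nA, universe, pseudo)
        self.pB = smooth_frequencies(freqsB, nB, universe, pseudo)
        self._index = {m: {a: k for k, a in enumerate(sorted(universe[m]))} for m in loci}
        self._pa = {m: np.array([self.pA[m][a] for a in sorted(universe[m])]) for m in loci}
        self._pb = {m: np.array([self.pB[m][a] for a in sorted(universe[m])]) for m in loci}

    @classmethod
    def from_tables(cls, tableA: GenotypeTable, tableB: GenotypeTable,
                    pseudo: float = 0.5) -> "ClassifierModel":
        afA = allele_frequencies(tableA)
        afB = allele_frequencies(tableB)
        gA, gB = afA.groups[0], afB.groups[0]
        if tableA.marker_names != tableB.marker_names:
            raise ValueError("baseline tables have different loci")
        return cls(afA.marker_freqs(gA), afB.marker_freqs(gB),
                   nA=afA.marker_n(gA), nB=afB.marker_n(gB), pseudo=pseudo,
                   markers=tableA.markers)

    # -- internals ----------------------------------------------------------
    def _genotype_probs(self, gt: GenotypeTable):
        """Per locus: (P_AA, P_AB, P_BB) arrays over individuals; NaN = missing."""
        if gt.marker_names != self.loci:
            raise ValueError("cohort loci do not match the classifier baselines")
        n = gt.n_individuals
        paa = np.full((n, len(self.loci)), np.nan)
        pab = np.full_like(paa, np.nan)
        pbb = np.full_like(paa, np.nan)
        for j, m in enumerate(self.loci):
            pair = gt.calls[:, j, :]
            typed = pair[:, 0] != MISSING
            if not typed.any():
                continue
            idx = self._index[m]
            try:
                i1 = np.array([idx[int(a)] for a in pair[typed, 0]])
                i2 = np.array([idx[int(a)] for a in pair[typed, 1]])
            except KeyError as e:
                raise ValueError(
                    f"allele {e} at locus {m} absent from both baselines"
                ) from None
            p, q = self._pa[m], self._pb[m]
            hom = i1 == i2
            aa = np.where(hom, p[i1] * p[i2], 2 * p[i1] * p[i2])
            bb = np.where(hom, q[i1] * q[i2], 2 * q[i1] * q[i2])
            ab = np.where(hom, p[i1] * q[i1], p[i1] * q[i2] + p[i2] * q[i1])
            paa[typed, j], pab[typed, j], pbb[typed, j] = aa, ab, bb
        return paa, pab, pbb

    def loglik_matrix(self, gt: GenotypeTable) -> pd.DataFrame:
        """(n_individuals x 6) class log-likelihoods over non-missing loci."""
        paa, pab, pbb = self._genotype_probs(gt)
        if np.all(np.isnan(paa), axis=1).any():
            bad = [gt.individuals[k] for k in np.flatnonzero(np.all(np.isnan(paa), axis=1))]
            raise ValueError(f"individuals with zero non-missing loci: {bad[:5]}")
        cols = {}
        for c in CLASS_ORDER:
            fa, fab, fb = ANCESTRY_FREQS[c]
            probs = fa * paa + fab * pab + fb * pbb
            with np.errstate(divide="ignore"):
                ll = np.log(probs)
            cols[c] = np.nansum(np.where(np.isnan(probs), 0.0, ll), axis=1)
        return pd.DataFrame(cols, index=gt.individuals)

    def class_likelihood(self, gt: GenotypeTable, label: str) -> np.ndarray:
        """Log-likelihood of one class for every individual."""
        return self.loglik_matrix(gt)[label].to_numpy()

    def classify(self, gt: GenotypeTable) -> ClassPosterior:
        """Posterior over the six classes under a uniform prior.

        Ties in the argmax break by the fixed class order PA, PB, F1, F2,
        BXA, BXB.
        """
        ll = self.loglik_matrix(gt)
        m = ll.to_numpy()
        stab = m - m.max(axis=1, keepdims=True)
        w = np.exp(stab)
        post = w / w.sum(axis=1, keepdims=True)
        out = pd.DataFrame(index=ll.index)
        for k, c in enumerate(CLASS_ORDER):
            out[f"loglik_{c}"] = m[:, k]
        for k, c in enumerate(CLASS_ORDER):
            out[f"post_{c}"] = post[:, k]
        out["assigned"] = [CLASS_ORDER[k] for k in np.argmax(m, axis=1)]
        return ClassPosterior(out)

    # -- admixture ----------------------------------------------------------
    def _q_loglik_and_deriv(self, gt: GenotypeTable):
        """Per-individual callables are avoided: returns gathered (p, b) allele
        arrays for the derivative of the admixture log-likelihood."""
        if gt.marker_names != self.loci:
            raise ValueError("cohort loci do not match the classifier baselines")
        gath_p, gath_b, owner = [], [], []
        for j, m in enumerate(self.loci):
            pair = gt.calls[:, j, :]
            typed = np.flatnonzero(pair[:, 0] != MISSING)
            if typed.size == 0:
                continue
            idx = self._index[m]
            p, b = self._pa[m], self._pb[m]
            for col in (0, 1):
                ia = np.array([idx[int(a)] for a in pair[typed, col]])
                gath_p.append(p[ia])
                gath_b.append(b[ia])
                owner.append(typed)
        return np.concatenate(gath_p), np.concatenate(gath_b), np.concatenate(owner)

    def admixture_q(self, gt: GenotypeTable, threshold: float = 0.9) -> list[AdmixtureEstimate]:
        """Maximum-likelihood ancestry proportion toward baseline A, per
        individual.  Optimised by bisection on the concave profile derivative
        (tolerance far below 1e-6); boundary optima return exactly 0 or 1."""
        p_all, b_all, owner = self._q_loglik_and_deriv(gt)
        n = gt.n_individuals
        d_all = p_all - b_all
        results = []
        for k in range(n):
            sel = owner == k
            if not sel.any():
                raise ValueError(f"individual {gt.individuals[k]} has zero informative loci")
            p, b, d = p_all[sel], b_all[sel], d_all[sel]

            def deriv(q):
                return float(np.sum(d / (q * p + (1 - q) * b)))

            def loglik(q):
                # per gene copy log(x); genotype constants (factor 2 for hets)
                # do not depend on q and are omitted from the reported optimum
                return float(np.sum(np.log(q * p + (1 - q) * b)))

            if deriv(0.0) <= 0:
                qhat = 0.0
            elif deriv(1.0) >= 0:
                qhat = 1.0
            else:
                lo, hi = 0.0, 1.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if deriv(mid) > 0:
                        lo = mid
                    else:
                        hi = mid
                qhat = 0.5 * (lo + hi)
            pure = qhat >= threshold or qhat <= 1.0 - threshold
            results.append(AdmixtureEstimate(qhat, loglik(qhat), bool(pure), threshold))
        return results


def purity_filter(
    gt: GenotypeTable,
    group_a: str,
    group_b: str,
    threshold: float = 0.9,
    pseudo: float = 0.5,
) -> PurifiedBaselines:
    """Keep individuals whose admixture proportion toward their own labelled
    baseline is at least ``threshold``; recompute baselines from the kept fish.

    ``threshold=0`` is the identity filter.  A baseline reduced below two
    individuals raises an error advising threshold relaxation.
    """
    tabA = gt.subset_groups([group_a])
    tabB = gt.subset_groups([group_b])
    model = ClassifierModel.from_tables(tabA, tabB, pseudo=pseudo)
    qa = model.admixture_q(tabA, threshold)
    qb = model.admixture_q(tabB, threshold)
    keep_a = [i for i, e in zip(tabA.individuals, qa) if e.q >= threshold]
    keep_b = [i for i, e in zip(tabB.individuals, qb) if (1.0 - e.q) >= threshold]
    excluded = [i for i in tabA.individuals if i not in set(keep_a)]
    excluded += [i for i in tabB.individuals if i not in set(keep_b)]
    if len(keep_a) < 2 or len(keep_b) < 2:
        raise ValueError(
            "purity filter left a baseline with <2 individuals; relax the threshold"
        )
    qs = pd.Series(
        {i: e.q for i, e in zip(tabA.individuals, qa)}
        | {i: e.q for i, e in zip(tabB.individuals, qb)}
    )
    return PurifiedBaselines(tabA.subset_individuals(keep_a),
                             tabB.subset_individuals(keep_b), excluded, qs)


def power_analysis(
    baselineA: GenotypeTable,
    baselineB: GenotypeTable,
    spec: CrossSpec,
    panel: str = "all",
    threshold: float = 0.9,
    pseudo: float = 0.5,
) -> PowerReport:
    """Hybrid-detection power of a marker panel between two baselines.

    Pipeline: purify both baselines with the q-threshold rule, recompute
    baseline frequencies from the purified fish, then per replicate simulate
    the cross design, classify every simulated individual, and score per-class
    correct-assignment proportions.  Reports per-class accuracies averaged
    across replicates, the summed confusion matrix, and a coarse
    parent-vs-hybrid dichotomy accuracy.
    """
    baselineA = baselineA.subset_panel(panel)
    baselineB = baselineB.subset_panel(panel)
    ga = baselineA.group_order[0]
    gb = baselineB.group_order[0]
    if ga == gb:
        gb = f"{gb}_b"
        baselineB = baselineB.with_groups({i: gb for i in baselineB.individuals})
    merged = baselineA.concat(baselineB)
    pure = purity_filter(merged, ga, gb, threshold=threshold, pseudo=pseudo)
    model = ClassifierModel.from_tables(pure.cohort_a, pure.cohort_b, pseudo=pseudo)
    afA = allele_frequencies(pure.cohort_a)
    afB = allele_frequencies(pure.cohort_b)
    fA = afA.marker_freqs(afA.groups[0])
    fB = afB.marker_freqs(afB.groups[0])

    theta = wc_theta(pure.cohort_a.concat(pure.cohort_b)).value

    cohorts = simulate_cross(spec, fA, fB, markers=baselineA.markers)
    classes = list(cohorts[0].table.group_order)
    acc = {c: [] for c in classes}
    confusion = pd.DataFrame(0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    dich = []
    for cohort in cohorts:
        post = model.classify(cohort.table)
        truth = pd.Series(cohort.truth)
        assigned = post.assigned
        for c in classes:
            mask = truth == c
            acc[c].append(float((assigned[mask.index[mask]] == c).mean()))
        for t_cls, a_cls in zip(truth[assigned.index], assigned):
            confusion.loc[t_cls, a_cls] += 1
        is_parent_true = truth[assigned.index].isin(PARENT_CLASSES)
        is_parent_assigned = assigned.isin(PARENT_CLASSES)
        dich.append(float((is_parent_true == is_parent_assigned).mean()))
    per_class = pd.DataFrame(
        {"accuracy": [float(np.mean(acc[c])) for c in classes]},
        index=classes,
    )
    for r in range(spec.n_reps):
        per_class[f"rep{r}"] = [acc[c][r] for c in classes]
    return PowerReport(per_class, confusion, float(np.mean(dich)), panel,
                       float(theta), spec.n_per_class, spec.n_reps)
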