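"""Independent reference implementations used as test oracles.

These deliberately use plain Python loops and transcribe the published
formulas directly, sharing no code with the package implementation.
"""
from __future__ import annotations

import numpy as np


def wc_components_bruteforce(pops):
    """Summed Weir-Cockerham (1984) variance components at one locus.

    ``pops`` is a list of populations, each a list of (a1, a2) genotype
    tuples (no missing data).  Returns (sum_a, sum_{a+b+c}) over alleles.
    """
    r = len(pops)
    n = [len(p) for p in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    alleles = sorted({a for pop in pops for g in pop for a in g})
    sum_a = sum_abc = 0.0
    for u in alleles:
        p = []
        h = []
        for pop, ni in zip(pops, n):
            copies = sum((g[0] == u) + (g[1] == u) for g in pop)
            het = sum(1 for g in pop if (g[0] == u) != (g[1] == u))
            p.append(copies / (2 * ni))
            h.append(het / ni)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def class_genotype_prob_enum(genotype, pA, pB, phi):
    """P(unordered genotype | class) by enumerating gene-copy ancestries.

    ``genotype`` is an (i, j) allele tuple, ``pA``/``pB`` allele -> frequency
    maps, ``phi`` the (phi_AA, phi_AB, phi_BB) ancestry-pair frequencies.
    The AB ancestry state is split over both copy orders.
    """
    i, j = genotype
    states = [
        (("A", "A"), phi[0]),
        (("A", "B"), phi[1] / 2),
        (("B", "A"), phi[1] / 2),
        (("B", "B"), phi[2]),
    ]
    total = 0.0
    for (o1, o2), w in states:
        f1 = pA if o1 == "A" else pB
        f2 = pA if o2 == "A" else pB
        # ordered draws (x, y) whose unordered set equals {i, j}
        if i == j:
            total += w * f1.get(i, 0.0) * f2.get(j, 0.0)
        else:
            total += w * (f1.get(i, 0.0) * f2.get(j, 0.0)
                          + f1.get(j, 0.0) * f2.get(i, 0.0))
    return total


def admixture_q_grid(genotypes, pA, pB, step=1e-4):
    """Grid-search MLE of the admixture proportion toward baseline A.

    ``genotypes`` is a list of per-locus (i, j) tuples; ``pA``/``pB`` are
    lists of allele -> frequency maps aligned with the loci.
    """
    qs = np.arange(0.0, 1.0 + step, step)
    best_q, best_ll = 0.0, -np.inf
    for q in qs:
        ll = 0.0
        for (i, j), fa, fb in zip(genotypes, pA, pB):
            alleles = set(fa) | set(fb)
            x = {a: q * fa.get(a, 0.0) + (1 - q) * fb.get(a, 0.0) for a in alleles}
            prob = x[i] * x[i] if i == j else 2 * x[i] * x[j]
            if prob <= 0:
                ll = -np.inf
                break
            ll += np.log(prob)
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q
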