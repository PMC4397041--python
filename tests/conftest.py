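import numpy as np
import pytest

from contactzone import GenotypeTable, MarkerDef


def make_table(pop_calls: dict, marker_panels=None) -> GenotypeTable:
    """Build a GenotypeTable from {group -> list of per-individual call lists}.

    Each individual's calls are a list of (a1, a2) pairs (one per locus);
    ``None`` marks a missing genotype.
    """
    first = next(iter(pop_calls.values()))
    n_loci = len(first[0])
    if marker_panels is None:
        marker_panels = ["neutral"] * n_loci
    markers = [MarkerDef(f"L{j}", marker_panels[j]) for j in range(n_loci)]
    ids, groups, rows = [], {}, []
    for g, inds in pop_calls.items():
        for k, ind in enumerate(inds):
            iid = f"{g}_{k}"
            ids.append(iid)
            groups[iid] = g
            rows.append([(-1, -1) if p is None else p for p in ind])
    return GenotypeTable(ids, markers, np.array(rows), groups)


def random_table(rng, n_groups=None, n_loci=None, max_alleles=6,
                 n_range=(5, 20)) -> GenotypeTable:
    """A random multi-allelic diploid dataset for property tests."""
    n_groups = n_groups or int(rng.integers(2, 5))
    n_loci = n_loci or int(rng.integers(1, 4))
    pop = {}
    for g in range(n_groups):
        n = int(rng.integers(*n_range))
        inds = []
        for _ in range(n):
            calls = []
            for j in range(n_loci):
                k = int(rng.integers(2, max_alleles + 1))
                freqs = rng.dirichlet(np.ones(k))
                a = rng.choice(np.arange(1, k + 1), size=2, p=freqs)
                calls.append((int(a[0]), int(a[1])))
            inds.append(calls)
        pop[f"g{g}"] = inds
    return make_table(pop)


@pytest.fixture
def fixed_disjoint_table():
    """Two populations of 20, each fixed for a different allele at 3 loci."""
    return make_table({
        "A": [[(1, 1)] * 3 for _ in range(20)],
        "B": [[(2, 2)] * 3 for _ in range(20)],
    })
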