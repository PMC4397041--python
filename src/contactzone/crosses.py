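"""Mendelian simulation of parental, F1, F2 and backcross cohorts.

Six genotype categories cover all ancestry states reachable within two
generations of hybridisation between two parental gene pools A and B.  Each
class is characterised by the frequencies of the per-locus ancestry pair
(AA, AB, BB):

    PA  = (1, 0, 0)        parents A
    PB  = (0, 0, 1)        parents B
    F1  = (0, 1, 0)
    F2  = (1/4, 1/2, 1/4)
    BXA = (1/2, 1/2, 0)    F1 x parent A
    BXB = (0, 1/2, 1/2)

Simulation is mechanistic rather than marginal: F2 individuals are formed by
mating two independently simulated F1 parents, each transmitting one of its
two alleles chosen uniformly at each locus, and backcrosses mate a simulated
F1 with a parental gamete.  Marginally this matches drawing from the class
frequencies above, but it preserves within-individual Mendelian sampling.
Loci are unlinked and simulated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeTable, MarkerDef

CLASS_ORDER = ("PA", "PB", "F1", "F2", "BXA", "BXB")

#: ancestry-pair frequencies (phi_AA, phi_AB, phi_BB) per class
ANCESTRY_FREQS = {
    "PA": (1.0, 0.0, 0.0),
    "PB": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BXA": (0.5, 0.5, 0.0),
    "BXB": (0.0, 0.5, 0.5),
}

HYBRID_CLASSES = ("F1", "F2", "BXA", "BXB")
PARENT_CLASSES = ("PA", "PB")


@dataclass
class CrossSpec:
    """Design of a simulated-cross experiment.

    Defaults follow the study design: 30 individuals in each of the four
    hybrid genotype categories, each simulated cross repeated five times,
    with the parental cohorts included alongside the hybrids.
    """

    n_per_class: int = 30
    classes: tuple = HYBRID_CLASSES
    n_reps: int = 5
    include_parents: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class <= 0 or self.n_reps <= 0:
            raise ValueError("counts must be positive")
        bad = [c for c in self.classes if c not in CLASS_ORDER]
        if bad:
            raise ValueError(f"unknown classes: {bad}")


@dataclass
class SimulatedCohort:
    """One replicate of a simulated cross, with its truth labels."""

    table: GenotypeTable
    rep: int
    seed_entropy: tuple
    truth: dict = field(default_factory=dict)  # individual -> true class


def _freq_arrays(freqs: dict) -> tuple[np.ndarray, np.ndarray]:
    if not freqs:
        raise ValueError("empty allele-frequency map")
    alleles = np.array(sorted(freqs), dtype=np.int64)
    probs = np.array([freqs[int(a)] for a in alleles], dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"allele frequencies sum to {total}, expected ~1")
    return alleles, probs / total


def sample_gamete(freqs: dict, rng: np.random.Generator) -> int:
    """Draw a single allele from an allele -> frequency map."""
    alleles, probs = _freq_arrays(freqs)
    return int(rng.choice(alleles, p=probs))


def _gametes(freqs: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    alleles, probs = _freq_arrays(freqs)
    return rng.choice(alleles, size=n, p=probs)


def _transmit(parent_a: np.ndarray, parent_b: np.ndarray, rng) -> np.ndarray:
    """Each simulated parent passes one of its two alleles, chosen uniformly."""
    pick = rng.integers(0, 2, size=len(parent_a))
    return np.where(pick == 0, parent_a, parent_b)


def simulate_class(
    label: str,
    freqsA: dict,
    freqsB: dict,
    n: int,
    rng: np.random.Generator,
    markers: list | None = None,
    id_prefix: str = "",
) -> GenotypeTable:
    """Simulate ``n`` individuals of one genotype class.

    ``freqsA``/``freqsB`` map marker name -> {allele -> frequency} and must be
    defined on the same loci.  The returned table's group label is the true
    class.
    """
    if label not in CLASS_ORDER:
        raise ValueError(f"unknown class {label!r}")
    loci = list(freqsA)
    if list(freqsB) != loci:
        raise ValueError("baselines defined on different loci")
    for m in loci:
        if not freqsA[m] or not freqsB[m]:
            raise ValueError(f"locus {m!r} has an empty frequency map")
    if markers is None:
        markers = [MarkerDef(m) for m in loci]
    calls = np.empty((n, len(loci), 2), dtype=np.int64)
    for j, m in enumerate(loci):
        fA, fB = freqsA[m], freqsB[m]
        if label == "PA":
            a1, a2 = _gametes(fA, n, rng), _gametes(fA, n, rng)
        elif label == "PB":
            a1, a2 = _gametes(fB, n, rng), _gametes(fB, n, rng)
        elif label == "F1":
            a1, a2 = _gametes(fA, n, rng), _gametes(fB, n, rng)
        elif label == "F2":
            p1a, p1b = _gametes(fA, n, rng), _gametes(fB, n, rng)
            p2a, p2b = _gametes(fA, n, rng), _gametes(fB, n, rng)
            a1 = _transmit(p1a, p1b, rng)
            a2 = _transmit(p2a, p2b, rng)
        elif label == "BXA":
            p1a, p1b = _gametes(fA, n, rng), _gametes(fB, n, rng)
            a1 = _transmit(p1a, p1b, rng)
            a2 = _gametes(fA, n, rng)
        else:  # BXB
            p1a, p1b = _gametes(fA, n, rng), _gametes(fB, n, rng)
            a1 = _transmit(p1a, p1b, rng)
            a2 = _gametes(fB, n, rng)
        calls[:, j, 0] = a1
        calls[:, j, 1] = a2
    ids = [f"{id_prefix}{label}_{i}" for i in range(n)]
    return GenotypeTable(ids, markers, calls, {i: label for i in ids})


def simulate_cross(
    spec: CrossSpec,
    freqsA: dict,
    freqsB: dict,
    markers: list | None = None,
) -> list[SimulatedCohort]:
    """Simulate all replicates of a cross design.

    Each replicate gets a distinct sub-seed derived deterministically from the
    master seed, simulates every requested class at ``n_per_class``, and
    (by default) appends parental cohorts of the same size.  Identical seeds
    produce identical cohorts.
    """
    classes = tuple(spec.classes)
    if spec.include_parents:
        classes = tuple(PARENT_CLASSES) + tuple(c for c in classes if c not in PARENT_CLASSES)
    ss = np.random.SeedSequence(spec.seed)
    out = []
    for rep, child in enumerate(ss.spawn(spec.n_reps)):
        rng = np.random.default_rng(child)
        tables = [
            simulate_class(c, freqsA, freqsB, spec.n_per_class, rng,
                           markers=markers, id_prefix=f"r{rep}_")
            for c in classes
        ]
        table = tables[0]
        for t in tables[1:]:
            table = table.concat(t)
        out.append(SimulatedCohort(table, rep, (spec.seed, rep), dict(table.groups)))
    return out
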