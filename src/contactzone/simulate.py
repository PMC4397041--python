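"""Synthetic three-ecotype datasets with the statistical structure the
analysis pipeline assumes.

Populations are generated under the Balding-Nichols F-model: each
population's allele-frequency vector at a locus is a Dirichlet draw with
parameters ``ancestral * (1 - F) / F``, independently per population and
locus, which gives expected differentiation approximately F.  Genotypes are
drawn in Hardy-Weinberg proportions within populations.

The default scenario mirrors a contact zone with two freshwater-resident
populations and one anadromous population: nine neutral microsatellites at
F = 0.12, five QTL-linked markers of lower allelic diversity at higher F, a
diallelic major-effect plate locus fixed for the C allele in the anadromous
population and for L in both residents, plate phenotypes driven by that
genotype plus Gaussian polygenic-modifier noise (the second resident carries
a low/partial mixture, emulating plate variation that the major locus does
not explain), and linear body/spine/raker traits with population-specific
means and a shared allometric dependence on body size.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import GenotypeTable, MarkerDef, PhenotypeTable

#: allele codes of the major plate locus (fragment sizes of the C and L alleles)
MAJOR_C, MAJOR_L = 240, 172

DEFAULT_PLATE_GENOTYPE_MODEL = {
    "CC": (31.5, 0.8),   # complete
    "CL": (29.5, 1.0),   # heterozygotes plate high where the major locus rules
}

#: per-population mixture of (mean, sd, weight) for LL fish
DEFAULT_PLATE_LL_MODEL = {
    "resident1": ((5.0, 2.0, 1.0),),
    "resident2": ((7.0, 2.0, 0.5), (13.0, 3.0, 0.5)),
    "anadromous": ((5.0, 2.0, 1.0),),
}

#: trait -> per-population (mean, sd); sizes in mm, GRN a count
DEFAULT_TRAIT_MODEL = {
    "SL": {"resident1": (35.0, 4.0), "resident2": (39.0, 5.0), "anadromous": (59.0, 2.0)},
    "BD": {"resident1": (9.0, 1.0), "resident2": (10.5, 1.2), "anadromous": (15.0, 1.5)},
    "DS1": {"resident1": (3.2, 0.4), "resident2": (3.6, 0.5), "anadromous": (5.5, 0.5)},
    "DS2": {"resident1": (3.0, 0.4), "resident2": (3.4, 0.5), "anadromous": (5.2, 0.5)},
    "PS": {"resident1": (7.0, 0.8), "resident2": (7.8, 0.9), "anadromous": (11.5, 1.0)},
    "GRL": {"resident1": (0.86, 0.12), "resident2": (0.95, 0.17), "anadromous": (1.26, 0.15)},
    "GRN": {"resident1": (19.0, 1.5), "resident2": (20.0, 1.5), "anadromous": (21.0, 1.5)},
}

#: shared within-population allometric slope per mm of centroid size
DEFAULT_ALLOMETRY = {"BD": 0.15, "DS1": 0.05, "DS2": 0.05, "PS": 0.10, "GRL": 0.01}

#: spine traits share a latent factor so that pairwise correlations are high
SPINE_TRAITS = ("DS1", "DS2", "PS")
SPINE_SHARED_VARIANCE = 0.95


@dataclass
class ScenarioConfig:
    """Tunable description of the synthetic contact zone."""

    pops: tuple = ("resident1", "resident2", "anadromous")
    n_per_pop: int = 50
    n_neutral_loci: int = 9
    n_qtl_loci: int = 5              # the first QTL locus is the major plate locus
    neutral_alleles: int = 6
    qtl_alleles: tuple = (2, 3, 4, 2, 3)
    f_neutral: float = 0.12
    f_qtl: float = 0.23
    major_c_freq: tuple = (0.0, 0.0, 1.0)   # per-pop frequency of the C allele
    plate_genotype_model: dict = field(default_factory=lambda: dict(DEFAULT_PLATE_GENOTYPE_MODEL))
    plate_ll_model: dict = field(default_factory=lambda: dict(DEFAULT_PLATE_LL_MODEL))
    trait_model: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_MODEL.items()})
    allometry: dict = field(default_factory=lambda: dict(DEFAULT_ALLOMETRY))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.f_neutral < 1 or not 0 < self.f_qtl < 1:
            raise ValueError("F must lie in (0, 1)")
        if len(self.major_c_freq) != len(self.pops):
            raise ValueError("major_c_freq needs one entry per population")
        for pop, mix in self.plate_ll_model.items():
            w = sum(m[2] for m in mix)
            if not np.isclose(w, 1.0):
                raise ValueError(f"plate LL mixture weights for {pop} sum to {w}, expected 1")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeTable
    phenotypes: PhenotypeTable
    groups: dict
    truth: dict  # echoes the generating configuration


def balding_nichols_freqs(ancestral, F: float, n_pops: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    Returns an (n_pops, n_alleles) array.  ``F = 0`` short-circuits to exact
    copies of the ancestral vector; F outside [0, 1) is an error.
    """
    ancestral = np.asarray(ancestral, dtype=float)
    if ancestral.ndim != 1 or not np.isclose(ancestral.sum(), 1.0):
        raise ValueError("ancestral frequencies must be a vector summing to 1")
    if F == 0:
        return np.tile(ancestral, (n_pops, 1))
    if not 0 < F < 1:
        raise ValueError("F must lie in (0, 1)")
    conc = ancestral * (1.0 - F) / F
    return rng.dirichlet(conc, size=n_pops)


def simulate_genotypes(
    pop_freqs: dict,
    n_per_pop,
    rng: np.random.Generator,
    markers: list | None = None,
    missing_rate: float = 0.0,
    id_prefix: str = "",
) -> GenotypeTable:
    """Draw HWE genotypes within populations.

    ``pop_freqs`` maps population label -> {marker -> {allele -> frequency}};
    ``n_per_pop`` is an int or a per-population dict.  Two gene copies are
    drawn independently per individual per locus; ``missing_rate`` knocks out
    whole genotypes at random.
    """
    pops = list(pop_freqs)
    loci = list(pop_freqs[pops[0]])
    if markers is None:
        markers = [MarkerDef(m) for m in loci]
    ids, groups, blocks = [], {}, []
    for pop in pops:
        n = n_per_pop[pop] if isinstance(n_per_pop, dict) else n_per_pop
        calls = np.empty((n, len(loci), 2), dtype=np.int64)
        for j, m in enumerate(loci):
            fr = pop_freqs[pop][m]
            alleles = np.array(sorted(fr), dtype=np.int64)
            probs = np.array([fr[int(a)] for a in alleles])
            probs = probs / probs.sum()
            calls[:, j, 0] = rng.choice(alleles, size=n, p=probs)
            calls[:, j, 1] = rng.choice(alleles, size=n, p=probs)
        if missing_rate > 0:
            mask = rng.random((n, len(loci))) < missing_rate
            calls[mask] = -1
        pop_ids = [f"{id_prefix}{pop}_{i}" for i in range(n)]
        ids.extend(pop_ids)
        groups.update({i: pop for i in pop_ids})
        blocks.append(calls)
    return GenotypeTable(ids, markers, np.concatenate(blocks), groups)


def _microsat_alleles(rng: np.random.Generator, k: int, base: int) -> np.ndarray:
    """k distinct fragment sizes in a plausible dinucleotide ladder."""
    steps = rng.choice(np.arange(1, 2 * k + 1), size=k, replace=False)
    return base + 2 * np.sort(steps)


def _bn_panel(pops, n_loci, n_alleles, F, rng, name_fmt, base_size=100):
    """Balding-Nichols frequencies for a whole marker panel."""
    freqs = {pop: {} for pop in pops}
    names = []
    for j in range(n_loci):
        k = n_alleles if np.isscalar(n_alleles) else n_alleles[j]
        alleles = _microsat_alleles(rng, k, base_size + 40 * j)
        ancestral = rng.dirichlet(np.full(k, 1.0))
        per_pop = balding_nichols_freqs(ancestral, F, len(pops), rng)
        name = name_fmt.format(j + 1)
        names.append(name)
        for pi, pop in enumerate(pops):
            freqs[pop][name] = {int(a): float(p) for a, p in zip(alleles, per_pop[pi])}
    return freqs, names


def simulate_three_ecotype_scenario(config: ScenarioConfig | None = None) -> SimulatedDataset:
    """Generate the default two-resident + anadromous contact-zone dataset."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    pops = list(cfg.pops)

    neutral_freqs, neutral_names = _bn_panel(
        pops, cfg.n_neutral_loci, cfg.neutral_alleles, cfg.f_neutral, rng,
        "NEU{:02d}", base_size=100,
    )
    n_other_qtl = cfg.n_qtl_loci - 1
    qtl_allele_counts = list(cfg.qtl_alleles[1:cfg.n_qtl_loci])
    while len(qtl_allele_counts) < n_other_qtl:
        qtl_allele_counts.append(3)
    qtl_freqs, qtl_names = _bn_panel(
        pops, n_other_qtl, qtl_allele_counts, cfg.f_qtl, rng,
        "QTL{:02d}", base_size=300,
    )

    major_name = "EDA"
    pop_freqs = {}
    for pi, pop in enumerate(pops):
        pc = float(cfg.major_c_freq[pi])
        major = {}
        if pc > 0:
            major[MAJOR_C] = pc
        if pc < 1:
            major[MAJOR_L] = 1.0 - pc
        pop_freqs[pop] = {**neutral_freqs[pop], major_name: major, **qtl_freqs[pop]}

    markers = (
        [MarkerDef(n, "neutral") for n in neutral_names]
        + [MarkerDef(major_name, "qtl", notes="diallelic major plate locus")]
        + [MarkerDef(n, "qtl") for n in qtl_names]
    )
    gt = simulate_genotypes(pop_freqs, cfg.n_per_pop, rng, markers=markers,
                            missing_rate=cfg.missing_rate)

    # ---- phenotypes -------------------------------------------------------
    j_major = gt.marker_names.index(major_name)
    rows = {}
    for k, ind in enumerate(gt.individuals):
        pop = gt.groups[ind]
        a1, a2 = gt.calls[k, j_major]
        n_c = int(a1 == MAJOR_C) + int(a2 == MAJOR_C) if a1 > 0 else -1
        if n_c == 2:
            mu, sd = cfg.plate_genotype_model["CC"]
        elif n_c == 1:
            mu, sd = cfg.plate_genotype_model["CL"]
        else:
            # LL (or untyped, which defaults to the population's LL mixture)
            mix = cfg.plate_ll_model[pop]
            weights = [m[2] for m in mix]
            mu, sd, _ = mix[rng.choice(len(mix), p=weights)]
        plates = float(np.clip(rng.normal(mu, sd), 0.0, 32.0))
        total = int(round(2 * plates))
        left, right = total // 2, total - total // 2
        row = {"plates_left": left, "plates_right": right}

        sl_mu, sl_sd = cfg.trait_model["SL"][pop]
        sl = rng.normal(sl_mu, sl_sd)
        centroid = sl * (1.0 + rng.normal(0.0, 0.02))
        row["SL"] = sl
        row["centroid_size"] = centroid
        spine_factor = rng.normal()
        for trait, per_pop in cfg.trait_model.items():
            if trait == "SL":
                continue
            mu_t, sd_t = per_pop[pop]
            slope = cfg.allometry.get(trait, 0.0)
            value = mu_t + slope * (sl - sl_mu)
            if trait in SPINE_TRAITS:
                lam = sd_t * np.sqrt(SPINE_SHARED_VARIANCE)
                eps = sd_t * np.sqrt(1.0 - SPINE_SHARED_VARIANCE)
                value += lam * spine_factor + eps * rng.normal()
            else:
                value += sd_t * rng.normal()
            row[trait] = round(value) if trait == "GRN" else value
        rows[ind] = row
    pheno = PhenotypeTable(pd.DataFrame.from_dict(rows, orient="index"))

    truth = {
        "config": asdict(cfg),
        "pop_freqs": pop_freqs,
        "major_locus": major_name,
    }
    return SimulatedDataset(gt, pheno, dict(gt.groups), truth)


def make_power_baselines(
    F: float = 0.5,
    n_loci: int = 14,
    n_per_pop: int = 50,
    alleles_per_locus: int = 6,
    seed: int = 0,
    labels: tuple = ("A", "B"),
) -> tuple[GenotypeTable, GenotypeTable]:
    """Two baseline populations at a configurable divergence level.

    The default emits 14 loci (the study's panel size) at F = 0.5 --
    strongly divergent, near-diagnostic baselines for the hybrid-detection
    power analysis.  Lower F values give the weaker rungs of a theta ladder.
    """
    rng = np.random.default_rng(seed)
    freqs, names = _bn_panel(list(labels), n_loci, alleles_per_locus, F, rng,
                             "PWR{:02d}", base_size=120)
    gt = simulate_genotypes(freqs, n_per_pop, rng)
    return gt.subset_groups([labels[0]]), gt.subset_groups([labels[1]])
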