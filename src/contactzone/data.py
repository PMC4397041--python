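"""Core containers: genotype tables, phenotype tables and allele frequencies.

Genotypes are diploid, codominant microsatellite calls: an unordered pair of
positive integer fragment sizes per individual per locus.  Missing data are
whole-genotype (a half-called genotype is demoted to missing with a warning,
because every downstream estimator assumes complete diploid calls).  Each
individual carries exactly one group label (a sampling site, a plate-morph
class, or a simulated truth class).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANELS = ("neutral", "qtl")

#: sentinel for a missing allele in the calls array
MISSING = -1

#: phenotype columns understood by the tools in :mod:`contactzone.phenotypes`
TRAIT_COLUMNS = (
    "SL", "BD", "DS1", "DS2", "PS",
    "plates_left", "plates_right", "mean_plates",
    "GRN", "GRL", "centroid_size",
)


@dataclass(frozen=True)
class MarkerDef:
    """A microsatellite locus with its marker-panel assignment.

    ``panel`` is ``"neutral"`` or ``"qtl"`` and is always explicit -- QTL
    linkage is biological knowledge, never inferred from the data.
    """

    name: str
    panel: str = "neutral"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}, got {self.panel!r}")


class GenotypeTable:
    """Individuals x loci diploid allele-pair matrix with group labels.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers.
    markers : sequence of MarkerDef
        Locus definitions, order preserved.
    calls : array-like, shape (n_individuals, n_loci, 2)
        Integer allele pairs; any non-positive entry marks the genotype
        missing.  Pairs are stored canonically smaller-first.
    groups : mapping str -> str
        Group label for every individual.
    """

    __slots__ = ("individuals", "markers", "calls", "groups")

    def __init__(self, individuals, markers, calls, groups):
        individuals = [str(i) for i in individuals]
        if len(set(individuals)) != len(individuals):
            dupes = sorted({i for i in individuals if individuals.count(i) > 1})
            raise ValueError(f"duplicate individual IDs: {dupes[:5]}")
        markers = list(markers)
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        calls = np.array(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(markers), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(individuals)}, {len(markers)}, 2)"
            )
        half = (calls <= 0).any(axis=2) & (calls > 0).any(axis=2)
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-called genotypes demoted to missing",
                stacklevel=2,
            )
        miss = (calls <= 0).any(axis=2)
        calls = np.sort(calls, axis=2)
        calls[miss] = MISSING
        calls.setflags(write=False)

        groups = {str(k): str(v) for k, v in dict(groups).items()}
        lacking = [i for i in individuals if i not in groups]
        if lacking:
            raise ValueError(f"individuals without a group label: {lacking[:5]}")

        self.individuals = individuals
        self.markers = markers
        self.calls = calls
        self.groups = {i: groups[i] for i in individuals}

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def group_array(self) -> np.ndarray:
        """Group label per individual, aligned with ``individuals``."""
        return np.array([self.groups[i] for i in self.individuals])

    @property
    def group_order(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(self.groups[i], None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    # -- subsetting ----------------------------------------------------------
    def subset_panel(self, panel: str) -> "GenotypeTable":
        """Restrict to one marker panel; ``"all"`` is the identity."""
        if panel == "all":
            return self
        if panel not in PANELS:
            raise ValueError(f"unknown panel {panel!r}")
        idx = [k for k, m in enumerate(self.markers) if m.panel == panel]
        if not idx:
            raise ValueError(f"no markers in panel {panel!r}")
        return GenotypeTable(
            self.individuals,
            [self.markers[k] for k in idx],
            self.calls[:, idx, :],
            self.groups,
        )

    def subset_markers(self, names) -> "GenotypeTable":
        pos = {m.name: k for k, m in enumerate(self.markers)}
        idx = [pos[n] for n in names]
        return GenotypeTable(
            self.individuals, [self.markers[k] for k in idx],
            self.calls[:, idx, :], self.groups,
        )

    def subset_individuals(self, ids) -> "GenotypeTable":
        pos = {i: k for k, i in enumerate(self.individuals)}
        idx = [pos[i] for i in ids]
        return GenotypeTable(
            [self.individuals[k] for k in idx], self.markers,
            self.calls[idx], {i: self.groups[i] for i in ids},
        )

    def subset_groups(self, labels) -> "GenotypeTable":
        labels = set(labels)
        keep = [i for i in self.individuals if self.groups[i] in labels]
        return self.subset_individuals(keep)

    def with_groups(self, groups) -> "GenotypeTable":
        """Replace group labels (e.g. from a sidecar mapping file)."""
        return GenotypeTable(self.individuals, self.markers, self.calls, groups)

    def concat(self, other: "GenotypeTable") -> "GenotypeTable":
        """Stack two tables over the same loci."""
        if self.marker_names != other.marker_names:
            raise ValueError("tables have different loci")
        return GenotypeTable(
            self.individuals + other.individuals,
            self.markers,
            np.concatenate([self.calls, other.calls], axis=0),
            {**self.groups, **other.groups},
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
            and self.groups == other.groups
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeTable {self.n_individuals} individuals x {self.n_loci} loci, "
            f"{len(self.group_order)} groups>"
        )


class PhenotypeTable:
    """Per-individual morphological traits backed by a pandas DataFrame.

    The frame is indexed by individual id.  Standard columns are listed in
    :data:`TRAIT_COLUMNS`; unknown columns are carried along untouched.
    ``mean_plates`` is filled in as ``(plates_left + plates_right) / 2``
    whenever absent and both sides are present.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate individual IDs in phenotype table")
        left = df.get("plates_left")
        right = df.get("plates_right")
        if left is not None and right is not None:
            implied = (pd.to_numeric(left, errors="coerce")
                       + pd.to_numeric(right, errors="coerce")) / 2.0
            if "mean_plates" not in df.columns:
                df["mean_plates"] = implied
            else:
                df["mean_plates"] = df["mean_plates"].fillna(implied)
        # enforce simple range invariants by demoting violations to missing
        for col in ("SL", "BD", "DS1", "DS2", "PS", "GRL", "centroid_size"):
            if col in df.columns:
                bad = pd.to_numeric(df[col], errors="coerce") <= 0
                if bad.any():
                    warnings.warn(f"{int(bad.sum())} non-positive {col} values set missing")
                    df.loc[bad, col] = np.nan
        for col in ("plates_left", "plates_right", "mean_plates"):
            if col in df.columns:
                v = pd.to_numeric(df[col], errors="coerce")
                bad = (v < 0) | (v > 40)
                if bad.any():
                    warnings.warn(f"{int(bad.sum())} out-of-range {col} values set missing")
                    df.loc[bad, col] = np.nan
        self.df = df

    @property
    def individuals(self) -> list[str]:
        return list(self.df.index)

    def trait(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"trait {name!r} not present")
        return pd.to_numeric(self.df[name], errors="coerce")

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenotypeTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"<PhenotypeTable {len(self.df)} individuals x {self.df.shape[1]} columns>"


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per group x marker.

    ``freqs[(group, marker)]`` maps allele -> relative frequency among typed
    gene copies; ``n_typed[(group, marker)]`` counts diploid individuals with a
    non-missing call.  A group with no typed individuals at a marker has an
    empty frequency map and ``n_typed == 0``.
    """

    groups: tuple
    markers: tuple
    freqs: dict = field(default_factory=dict)
    n_typed: dict = field(default_factory=dict)

    def marker_freqs(self, group: str) -> dict:
        """{marker -> {allele -> freq}} for one group (baseline export)."""
        return {m: dict(self.freqs[(group, m)]) for m in self.markers}

    def marker_n(self, group: str) -> dict:
        return {m: self.n_typed[(group, m)] for m in self.markers}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g, m), fr in self.freqs.items():
            for allele, p in sorted(fr.items()):
                rows.append({"group": g, "marker": m, "allele": allele,
                             "frequency": p, "n_typed": self.n_typed[(g, m)]})
        return pd.DataFrame(rows, columns=["group", "marker", "allele", "frequency", "n_typed"])


def allele_frequencies(gt: GenotypeTable, grouping: dict | None = None) -> AlleleFrequencyTable:
    """Observed allele frequencies per group x marker from non-missing calls.

    ``grouping`` optionally overrides the table's own labels; it must assign
    every individual to exactly one group.
    """
    if grouping is None:
        grouping = gt.groups
    lacking = [i for i in gt.individuals if i not in grouping]
    if lacking:
        raise ValueError(f"grouping misses individuals: {lacking[:5]}")
    labels = np.array([grouping[i] for i in gt.individuals])
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    groups = tuple(order)
    markers = tuple(gt.marker_names)

    freqs: dict = {}
    n_typed: dict = {}
    for g in groups:
        sel = labels == g
        calls = gt.calls[sel]
        for j, m in enumerate(markers):
            pair = calls[:, j, :]
            typed = pair[:, 0] != MISSING
            n = int(typed.sum())
            n_typed[(g, m)] = n
            if n == 0:
                freqs[(g, m)] = {}
                continue
            alleles, counts = np.unique(pair[typed].ravel(), return_counts=True)
            total = counts.sum()
            freqs[(g, m)] = {int(a): c / total for a, c in zip(alleles, counts)}
    return AlleleFrequencyTable(groups, markers, freqs, n_typed)
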