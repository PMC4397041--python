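"""Readers and writers: GenePop genotype files, grouping sidecars, phenotype tables.

GenePop is the de-facto interchange format for codominant microsatellite data.
Both the 2-digit (4 characters per genotype) and 3-digit (6 characters)
dialects are accepted on input; output is always 3-digit.  ``000``/``00``
allele codes mark missing data.  Group labels are not part of the format, so
they come from either the leading alphabetic prefix of the first individual id
in each POP block (falling back to the block index) or, preferably, from an
explicit sidecar TSV mapping (individual_id, group).
"""
from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, MarkerDef, PhenotypeTable

log = logging.getLogger(__name__)

_ID_COLUMN_CANDIDATES = ("id", "ID", "Id", "individual", "individual_id", "ind")


def _pop_label(first_id: str, block_index: int) -> str:
    m = re.match(r"(.+?)[_\- ]\d+$", first_id)
    if m:
        return m.group(1)
    m = re.match(r"[A-Za-z]+", first_id)
    return m.group(0) if m else f"pop{block_index + 1}"


def read_genepop(path, qtl_markers=()) -> GenotypeTable:
    """Parse a GenePop 4-style file into a :class:`GenotypeTable`.

    Parameters
    ----------
    path : path-like
    qtl_markers : sequence of str, optional
        Locus names to tag with the ``qtl`` panel; all others are ``neutral``.

    Raises
    ------
    ValueError
        On malformed genotype counts (with the offending line number), empty
        POP blocks, or duplicate individual IDs.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    # title line is free text and ignored
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if not locus_names:
        raise ValueError(f"{path}: no locus names before first POP")
    if i == len(lines):
        raise ValueError(f"{path}: no POP block found")

    qtl = set(qtl_markers)
    markers = [MarkerDef(n, "qtl" if n in qtl else "neutral") for n in locus_names]
    n_loci = len(locus_names)

    individuals: list[str] = []
    groups: dict[str, str] = {}
    calls_rows: list[np.ndarray] = []
    width: int | None = None  # characters per allele, detected from data

    block = -1
    block_sizes: list[int] = []
    current_label = ""
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        text = raw.strip()
        if not text:
            continue
        if text.lower() == "pop":
            if block >= 0 and block_sizes[block] == 0:
                raise ValueError(f"{path}: empty POP block ending at line {lineno + 1}")
            block += 1
            block_sizes.append(0)
            continue
        if "," not in text:
            raise ValueError(f"{path} line {lineno + 1}: expected 'id , genotypes'")
        ind_id, _, geno_part = text.partition(",")
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise ValueError(
                f"{path} line {lineno + 1}: expected {n_loci} genotypes, found {len(tokens)}"
            )
        if ind_id in groups:
            raise ValueError(f"{path} line {lineno + 1}: duplicate individual ID {ind_id!r}")
        row = np.empty((n_loci, 2), dtype=np.int64)
        for j, tok in enumerate(tokens):
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise ValueError(
                    f"{path} line {lineno + 1}: malformed genotype {tok!r} at locus "
                    f"{locus_names[j]}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ValueError(
                    f"{path} line {lineno + 1}: mixed 2- and 3-digit genotype dialects"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            row[j] = (a1, a2) if a1 and a2 else (MISSING, MISSING)
        if block_sizes[block] == 0:
            current_label = _pop_label(ind_id, block)
        individuals.append(ind_id)
        groups[ind_id] = current_label
        calls_rows.append(row)
        block_sizes[block] += 1

    if block >= 0 and block_sizes[block] == 0:
        raise ValueError(f"{path}: empty trailing POP block")
    return GenotypeTable(individuals, markers, np.stack(calls_rows), groups)


def write_genepop(gt: GenotypeTable, path, title: str = "contactzone export") -> None:
    """Write a table in the 3-digit GenePop dialect, POP blocks in group order.

    Output is deterministic.  Allele codes above 999 cannot be represented and
    raise ``ValueError``; missing genotypes are emitted as ``000000``.
    """
    if gt.n_loci == 0:
        raise ValueError("cannot write a GenePop file with no loci")
    valid = gt.calls[gt.calls != MISSING]
    if valid.size and valid.max() > 999:
        raise ValueError("allele codes > 999 cannot be written in the 3-digit dialect")
    lines = [title]
    lines.extend(gt.marker_names)
    by_group: dict[str, list[int]] = {}
    for k, ind in enumerate(gt.individuals):
        by_group.setdefault(gt.groups[ind], []).append(k)
    for g in gt.group_order:
        lines.append("POP")
        for k in by_group[g]:
            toks = []
            for j in range(gt.n_loci):
                a1, a2 = gt.calls[k, j]
                if a1 == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{a1:03d}{a2:03d}")
            lines.append(f"{gt.individuals[k]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_groups(path) -> dict[str, str]:
    """Read a sidecar grouping TSV (individual_id <tab> group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (individual_id, group)")
    id_col, grp_col = df.columns[:2]
    if df[id_col].duplicated().any():
        raise ValueError(f"{path}: duplicate individual IDs")
    return dict(zip(df[id_col], df[grp_col]))


def write_groups(groups: dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"individual_id": list(groups), "group": [groups[k] for k in groups]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, id_column: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype table (comma or tab separated).

    The header must name an ID column (one of ``id``, ``individual``, ...),
    or pass ``id_column`` explicitly.  Known trait columns are coerced to
    numeric; non-numeric cells become missing with a logged warning.  Unknown
    columns are preserved untouched.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if id_column is None:
        for cand in _ID_COLUMN_CANDIDATES:
            if cand in df.columns:
                id_column = cand
                break
    if id_column is None or id_column not in df.columns:
        raise ValueError(f"{path}: no ID column found (looked for {_ID_COLUMN_CANDIDATES})")
    df = df.set_index(id_column)
    from .data import TRAIT_COLUMNS

    for col in df.columns:
        if col in TRAIT_COLUMNS:
            coerced = pd.to_numeric(df[col], errors="coerce")
            n_bad = int((coerced.isna() & df[col].notna()).sum())
            if n_bad:
                log.warning("%s: %d non-numeric %s cells recorded as missing", path, n_bad, col)
                warnings.warn(f"{n_bad} non-numeric {col} cells recorded as missing")
            df[col] = coerced
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.df.to_csv(path, index_label="id", float_format="%.10g")
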