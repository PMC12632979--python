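"""Readers and writers for every external table the pipeline touches.

All matrices and result tables are tab-separated with a decimal point and no
locale dependence; missing protein intensities are written as empty cells and
read from empty cells or ``NA``.  Assay replicate tables are CSV (their usual
plate-reader export form).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BiodomainMap, GeneSetCollection, ProteinMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file did not conform to its expected format."""


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a duplicated set id is an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning(
                    "%s: line %d: set %r contained %d duplicate gene(s); deduplicated",
                    path, lineno, set_id, dups,
                )
            if set_id in coll:
                raise ParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            if not genes:
                raise ParseError(f"{path}: line {lineno}: set {set_id!r} has no genes")
            coll.add(set_id, description, genes)
    return coll


def write_gmt(path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for set_id in collection:
            desc = collection.description(set_id)
            genes = collection.genes(set_id)
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Biodomain term mapping
# ---------------------------------------------------------------------------

def read_biodomain_map(path, vocabulary=None) -> BiodomainMap:
    """Read a TSV with columns ``term`` and ``domain`` (one row per pair).

    Multi-domain terms appear on several rows.  An empty file yields an empty
    map.  When ``vocabulary`` is given, unknown domain names are an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return BiodomainMap({}, tuple(vocabulary) if vocabulary else None)
    for col in ("term", "domain"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    entries: dict[str, tuple[str, ...]] = {}
    for term, sub in df.groupby("term", sort=False):
        domains = tuple(dict.fromkeys(sub["domain"]))
        entries[str(term)] = domains
    return BiodomainMap(entries, tuple(vocabulary) if vocabulary else None)


def write_biodomain_map(path, bdmap: BiodomainMap) -> None:
    rows = [
        {"term": term, "domain": d}
        for term, domains in bdmap.entries.items()
        for d in domains
    ]
    pd.DataFrame(rows, columns=["term", "domain"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein abundance matrices
# ---------------------------------------------------------------------------

def read_protein_matrix(path, metadata_path) -> ProteinMatrix:
    """Read a proteins x samples log2-intensity TSV plus its sample metadata.

    First matrix column is the protein id; remaining headers are sample ids.
    Empty cells and ``NA`` are missing values.  Every sample column must have
    a metadata row (TSV with a ``sample`` column).
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                      keep_default_na=False)
    mat = mat.apply(pd.to_numeric, errors="raise")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ParseError(f"{metadata_path}: missing required column 'sample'")
    meta = meta.set_index("sample")
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise ParseError(
            f"{path}: samples absent from metadata {metadata_path}: {sorted(missing)!r}"
        )
    return ProteinMatrix(mat, meta)


def write_protein_matrix(path, metadata_path, pm: ProteinMatrix) -> None:
    out = pm.values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="")
    meta = pm.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Assay replicate tables (CSV), qPCR Ct tables, effect vectors, ortholog maps
# ---------------------------------------------------------------------------

ASSAY_COLUMNS = ["assay", "target", "cell_line", "dose", "batch", "replicate", "value"]


def read_assay_table(path) -> pd.DataFrame:
    """Read a replicate-level assay CSV.

    Columns: assay, target, cell_line, dose (empty where not applicable),
    batch, replicate, value.  Readouts must be positive.
    """
    df = pd.read_csv(path, dtype={"assay": str, "target": str, "cell_line": str,
                                  "batch": str, "replicate": str})
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing!r}")
    df["dose"] = pd.to_numeric(df["dose"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if (df["value"] <= 0).any():
        bad = df.loc[df["value"] <= 0]
        raise ParseError(
            f"{path}: {len(bad)} non-positive readout(s); first offending row: "
            f"{bad.iloc[0].to_dict()!r}"
        )
    return df[ASSAY_COLUMNS]


def write_assay_table(path, table: pd.DataFrame) -> None:
    table[ASSAY_COLUMNS].to_csv(path, index=False)


CT_COLUMNS = ["gene", "condition", "replicate", "ct_gene", "ct_reference"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct TSV: gene, condition (target|control), replicate,
    ct_gene, ct_reference (cycles)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str,
                                            "replicate": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing!r}")
    for col in ("ct_gene", "ct_reference"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if not np.isfinite(df[col]).all():
            raise ParseError(f"{path}: non-finite values in {col!r}")
    return df[CT_COLUMNS]


def write_ct_table(path, table: pd.DataFrame) -> None:
    table[CT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_disease_effects(path) -> pd.DataFrame:
    """Read a disease effect-size TSV: gene, effect (signed, e.g. a
    meta-analysis treatment effect per protein)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "effect"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["effect"] = pd.to_numeric(df["effect"], errors="raise")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ParseError(f"{path}: duplicated gene id(s) {dups[:5]!r}")
    return df[["gene", "effect"]]


def write_disease_effects(path, table: pd.DataFrame) -> None:
    table[["gene", "effect"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    """Read an ortholog TSV with columns ``human`` and ``mouse`` (one pair per
    row; one-to-many pairs are retained here and resolved downstream)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("human", "mouse"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df[["human", "mouse"]].drop_duplicates()


def write_ortholog_map(path, table: pd.DataFrame) -> None:
    table[["human", "mouse"]].to_csv(path, sep="\t", index=False)


def read_ranking(path) -> pd.Series:
    """Read a ranking TSV (gene, stat) into a gene-indexed float Series."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "stat"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["stat"] = pd.to_numeric(df["stat"], errors="raise")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicated gene ids in ranking")
    return df.set_index("gene")["stat"]


def write_ranking(path, ranking: pd.Series) -> None:
    out = ranking.rename("stat").rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False)


def write_table(path, table: pd.DataFrame, columns=None) -> None:
    """Write a result table as TSV with a stable column order."""
    if columns is not None:
        table = table[list(columns)]
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
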