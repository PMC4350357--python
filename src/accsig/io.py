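"""Readers and writers for the pipeline's external formats.

All files are UTF-8, tab-separated; lines starting with ``#`` are comments and
are ignored on read. Readers reject malformed input with an error naming the
offending identifier or cell coordinates rather than silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .types import ExonIntensityProfile, ExpressionMatrix, GeneSetCollection, SampleSheet

# pandas str() formatting of float64 is the shortest round-tripping repr, so
# write->read is the identity for expression matrices.


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)


def _header_fields(path) -> list[str]:
    """First non-comment line split on tabs (pandas mangles duplicate headers)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return line.rstrip("\n").split("\t")
    raise FormatError(f"{path}: empty file")


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if out.isna().to_numpy().any():
        i, j = np.argwhere(out.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}")
    return out


def read_expression_matrix(path, scale: str, assay: str = "mRNA") -> ExpressionMatrix:
    """Read a probe x sample TSV (first column probe IDs, header row sample IDs)."""
    header = _header_fields(path)
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dup = next(s for i, s in enumerate(samples) if s in samples[:i])
        raise FormatError(f"{path}: duplicate sample identifier: {dup!r}")
    raw = _read_table(path)
    raw = raw.set_index(raw.columns[0])
    raw.columns = samples
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe identifier: {dup!r}")
    return ExpressionMatrix(_to_numeric(raw, path), scale=scale, assay=assay)


def write_expression_matrix(matrix: ExpressionMatrix, path, float_format=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


def read_sample_sheet(path) -> SampleSheet:
    df = _read_table(path)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sheet.data.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not any(f for f in fields[2:]):
                raise FormatError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = [f for f in fields[2:] if f]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_exon_profile(path, sheet: SampleSheet | None = None, drop_missing: bool = True) -> ExonIntensityProfile:
    """Read an exon profile TSV: columns gene, exon_id, then one per sample.

    Exon rows with missing values (e.g. an exon absent from the array, like MYB
    exon 10) are dropped with re-indexing when ``drop_missing`` is true; they are
    never imputed.
    """
    header = _header_fields(path)
    raw = _read_table(path)
    if header[:2] != ["gene", "exon_id"]:
        raise FormatError(f"{path}: expected columns gene, exon_id, <samples...>")
    genes = raw["gene"].unique()
    if len(genes) != 1:
        raise FormatError(f"{path}: expected a single focal gene, found {list(genes)}")
    raw = raw.set_index("exon_id").drop(columns="gene")
    if drop_missing:
        raw = raw.dropna(axis=0, how="any")
    return ExonIntensityProfile(genes[0], _to_numeric(raw, path), sheet=sheet)


def write_exon_profile(profile: ExonIntensityProfile, path, float_format=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = profile.data.reset_index(names="exon_id")
    df.insert(0, "gene", profile.gene)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_mutation_table(path) -> pd.DataFrame:
    """Read a somatic mutation TSV with columns gene, sample_id, mutation_class."""
    df = _read_table(path)
    required = ["gene", "sample_id", "mutation_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mutation table missing column(s): {', '.join(missing)}")
    allowed = {"missense", "truncating", "other"}
    bad = set(df["mutation_class"]) - allowed
    if bad:
        raise FormatError(f"{path}: invalid mutation_class value(s) {sorted(bad)}")
    if (df["gene"].fillna("") == "").any() or (df["sample_id"].fillna("") == "").any():
        raise FormatError(f"{path}: empty gene or sample_id in mutation table")
    return df[required].reset_index(drop=True)


def write_mutation_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_mirna_target_map(path) -> pd.DataFrame:
    """Read a two-column miRNA -> target-gene TSV; duplicate pairs are dropped."""
    df = _read_table(path)
    if list(df.columns[:2]) != ["mirna_id", "target_gene"]:
        raise FormatError(f"{path}: expected columns mirna_id, target_gene")
    return df[["mirna_id", "target_gene"]].drop_duplicates().reset_index(drop=True)


def write_mirna_target_map(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path) -> dict[str, str]:
    """Optional explicit probe-set -> gene-symbol mapping (two-column TSV)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe->gene map needs two columns")
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate probe identifier: {dup!r}")
    return dict(zip(probes, df.iloc[:, 1]))


def write_table(df: pd.DataFrame, path, header_comment: str | None = None,
                float_format: str | None = "%.10g", index: bool = False) -> None:
    """Write an analysis result table with an optional '#' parameter header.

    A fixed float format keeps repeated runs byte-identical.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def write_run_summary(path, **fields) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
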