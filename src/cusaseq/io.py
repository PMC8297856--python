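"""Tab-separated readers/writers for the pipeline's artifacts.

All on-disk formats are plain text: counts and normalized matrices as
genes x samples TSV, the sample sheet and gene catalog as TSV tables, DE
tables with fixed column names, the region x gene Z matrix as TSV, and an
optional GTF export of the catalog (gene features, 1-based closed
coordinates, ``gene_biotype`` attribute).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import (
    CountMatrix,
    NormalizedMatrix,
    ValidationError,
    validate_catalog,
)

FLOAT_FORMAT = "%.10g"


def write_counts(m: CountMatrix, counts_path, samples_path) -> None:
    m.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    m.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts=counts, samples=samples).validate()


def write_catalog(catalog: pd.DataFrame, path) -> None:
    validate_catalog(catalog)
    catalog.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_catalog(path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", index_col=0, dtype={"chromosome": str})
    return validate_catalog(catalog)


def write_catalog_gtf(catalog: pd.DataFrame, path) -> None:
    """Export the catalog as GTF gene features (1-based closed coordinates)."""
    validate_catalog(catalog)
    lines = []
    for gene_id, row in catalog.iterrows():
        attrs = f'gene_id "{gene_id}"; gene_biotype "{row["biotype"]}";'
        lines.append(
            "\t".join(
                [
                    str(row["chromosome"]),
                    "cusaseq",
                    "gene",
                    "1",
                    str(int(row["length_nt"])),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix(values: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    values.rename_axis(index_name).to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path, index_name: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(index_name)


def write_normalized(nm: NormalizedMatrix, values_path, samples_path=None) -> None:
    write_matrix(nm.values, values_path)
    if samples_path is not None:
        nm.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def read_normalized(values_path, samples_path) -> NormalizedMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    if not values.columns.equals(samples.index):
        raise ValidationError("normalized matrix columns and sample sheet differ")
    return NormalizedMatrix(values=values, samples=samples, provenance=["loaded"])


def write_de_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_de_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    required = {"base_mean", "log2fc", "wald_stat", "p_raw", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"DE table is missing columns: {sorted(missing)}")
    return table


def write_zmatrix(z: pd.DataFrame, path) -> None:
    z.rename_axis("region").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_zmatrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis("region")
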