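"""Core in-memory containers and domain constants.

The pipeline works at the gene-count level: a :class:`CountMatrix` carries a
genes x samples integer matrix together with the sample sheet (patient,
tissue, grade group), and a :class:`NormalizedMatrix` carries the real-valued
matrix produced by within-sample GC normalization plus a provenance trail.
Gene annotation (a "catalog") is a plain :class:`pandas.DataFrame` indexed by
gene id with columns ``chromosome``, ``length_nt``, ``gc_fraction`` and
``biotype``; :func:`validate_catalog` enforces the schema.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven glioblastoma anatomic compartments of the Ivy GAP atlas, in the
#: conventional outside-in order: leading edge, infiltrating tumour, cellular
#: tumour, perinecrotic zone, pseudopalisading cells around necrosis,
#: hyperplastic blood vessels, microvascular proliferation.
REGIONS = ("LE", "IT", "CT", "pnz", "pan", "hbv", "mvp")

#: Peripheral compartments (tumour boundary, high normal-cell content).
PERIPHERAL_REGIONS = ("LE", "IT")

#: Vascularised / necrosis-adjacent compartments.
VASCULAR_REGIONS = ("pan", "hbv", "mvp")

BIOTYPES = ("protein_coding", "pseudogene", "long_noncoding", "small_rna", "other")

TISSUES = ("TCR", "aspirate")
GRADE_GROUPS = ("IV", "LGG")

CATALOG_COLUMNS = ("chromosome", "length_nt", "gc_fraction", "biotype")

#: Columns of a differential-expression table (gene id is the index).
DE_COLUMNS = ("base_mean", "log2fc", "wald_stat", "p_raw", "p_adj", "direction")


class ValidationError(ValueError):
    """Raised when an input violates a container contract."""


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene catalog and return it unchanged.

    Parameters
    ----------
    catalog
        DataFrame indexed by gene id with columns ``chromosome``,
        ``length_nt``, ``gc_fraction``, ``biotype``.

    Raises
    ------
    ValidationError
        On duplicate gene ids, GC fractions outside [0, 1], non-positive
        lengths, or unknown biotypes.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValidationError(f"catalog is missing columns: {missing}")
    if catalog.index.duplicated().any():
        dupes = catalog.index[catalog.index.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate gene ids in catalog, e.g. {dupes}")
    gc = catalog["gc_fraction"].to_numpy(dtype=float)
    finite = np.isfinite(gc)
    if ((gc[finite] < 0) | (gc[finite] > 1)).any():
        raise ValidationError("gc_fraction values must lie in [0, 1]")
    ln = catalog["length_nt"].to_numpy(dtype=float)
    if (ln[np.isfinite(ln)] < 1).any():
        raise ValidationError("length_nt values must be >= 1")
    bad = set(catalog["biotype"].dropna().unique()) - set(BIOTYPES)
    if bad:
        raise ValidationError(f"unknown biotypes: {sorted(bad)}")
    return catalog


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Attributes
    ----------
    counts
        DataFrame, genes in rows (index = gene ids), samples in columns.
    samples
        Sample sheet indexed by sample id; conventional columns are
        ``patient_id``, ``tissue`` ("TCR" | "aspirate") and ``grade_group``
        ("IV" | "LGG"), but arbitrary extra metadata columns are allowed and
        usable as grouping keys.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "CountMatrix":
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        if not self.counts.columns.equals(self.samples.index):
            raise ValidationError("count columns and sample sheet index differ")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integral")
        return self

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, gene_ids) -> "CountMatrix":
        """Return a new matrix restricted to ``gene_ids`` (order preserved)."""
        return CountMatrix(self.counts.loc[gene_ids], self.samples)


@dataclass
class NormalizedMatrix:
    """Real-valued expression matrix with the same axes as its source counts.

    ``provenance`` records, in order, the filters and normalization steps
    that produced the matrix (human-readable strings).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
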