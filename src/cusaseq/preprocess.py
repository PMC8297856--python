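"""Count-matrix preparation: filtering, GC normalization, biotype report.

The preparation mirrors standard practice for degraded archival (FFPE)
RNA-seq: drop genes with fewer than 10 reads summed over all samples, keep
only genes with consensus length/GC annotation, then correct the
within-sample GC-content bias by median-matching across equal-occupancy GC
bins (the "median" flavour of within-lane count normalization).  Between-
sample depth scaling is deliberately left to the DE module's size factors so
that the two corrections stay separately testable.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import (
    BIOTYPES,
    CountMatrix,
    NormalizedMatrix,
    ValidationError,
    validate_catalog,
)

logger = logging.getLogger(__name__)


def filter_low_counts(m: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across all samples is below ``min_total``.

    A gene with row sum exactly ``min_total`` is retained.  Sample axis and
    gene order are unchanged; an empty result is allowed.
    """
    totals = m.counts.sum(axis=1)
    keep = totals >= min_total
    removed = int((~keep).sum())
    logger.info("filter_low_counts: removed %d/%d genes (row sum < %d)",
                removed, len(keep), min_total)
    return CountMatrix(m.counts.loc[keep], m.samples)


def filter_annotation_consensus(m: CountMatrix, catalog: pd.DataFrame) -> CountMatrix:
    """Keep genes with consensus length and GC annotation in the catalog.

    Retains genes that are present in ``catalog`` with finite ``length_nt``
    and ``gc_fraction``; gene order is preserved.  The retained fraction is
    logged (retained / total genes in the input matrix).
    """
    validate_catalog(catalog)
    annotated = catalog.index[
        catalog["length_nt"].notna() & catalog["gc_fraction"].notna()
    ]
    keep = m.counts.index.isin(annotated)
    if not keep.any():
        raise ValidationError(
            "no gene of the count matrix has consensus annotation; nothing to analyze"
        )
    frac = keep.sum() / len(keep)
    logger.info(
        "filter_annotation_consensus: retained %d/%d genes (%.1f%% of the input)",
        int(keep.sum()), len(keep), 100.0 * frac,
    )
    return CountMatrix(m.counts.loc[keep], m.samples)


def _gc_bins(gc: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy bin index per gene, ties broken by stable gene order."""
    order = np.argsort(gc, kind="stable")
    bins = np.empty(len(gc), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def gc_normalize_median(
    m: CountMatrix, catalog: pd.DataFrame, n_bins: int = 10
) -> NormalizedMatrix:
    """Within-sample GC normalization by bin-median matching.

    Per sample, genes are stratified into ``n_bins`` equal-occupancy bins by
    GC fraction (ties broken by stable gene order); every count in a bin is
    scaled by (global median of the sample's positive counts) / (median of
    the bin's positive counts).  Zeros stay zero, scaling is monotone within
    a bin, and after normalization the per-bin medians of positive values
    agree with the global median.  A bin with no positive count keeps scale
    factor 1 (with a warning).
    """
    validate_catalog(catalog)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    gc = catalog["gc_fraction"].reindex(m.counts.index)
    if gc.isna().any():
        missing = m.counts.index[gc.isna()][:5].tolist()
        raise ValidationError(f"genes without GC annotation, e.g. {missing}")
    if n_bins > len(gc):
        raise ValidationError("more GC bins than genes")
    bins = _gc_bins(gc.to_numpy(dtype=float), n_bins)

    counts = m.counts.to_numpy(dtype=float)
    out = np.zeros_like(counts)
    for j, sample in enumerate(m.counts.columns):
        col = counts[:, j]
        pos = col > 0
        if not pos.any():
            warnings.warn(f"sample {sample}: all counts are zero; left unscaled")
            out[:, j] = col
            continue
        global_med = np.median(col[pos])
        for b in range(n_bins):
            in_bin = bins == b
            pos_bin = in_bin & pos
            if not pos_bin.any():
                warnings.warn(
                    f"sample {sample}: GC bin {b} has no positive count; scale factor 1"
                )
                factor = 1.0
            else:
                factor = global_med / np.median(col[pos_bin])
            out[in_bin, j] = col[in_bin] * factor

    values = pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)
    return NormalizedMatrix(
        values=values,
        samples=m.samples,
        provenance=[f"gc_normalize_median(n_bins={n_bins})"],
    )


def biotype_proportions(
    m: CountMatrix, catalog: pd.DataFrame, group_by: str = "tissue"
) -> pd.DataFrame:
    """Percentage of detected genes per biotype, per sample group.

    A gene counts as detected in a group when its summed count over the
    group's samples is positive.  Rows are groups (levels of the
    ``group_by`` sample-metadata column), columns the biotype categories;
    each row sums to 100 (the ``other`` category closes the budget).
    """
    validate_catalog(catalog)
    if group_by not in m.samples.columns:
        raise ValidationError(f"unknown sample metadata key: {group_by!r}")
    biotype = catalog["biotype"].reindex(m.counts.index)
    if biotype.isna().any():
        raise ValidationError("count matrix contains genes absent from the catalog")
    rows = {}
    for group, sub in m.samples.groupby(group_by, sort=True):
        detected = m.counts[sub.index].sum(axis=1) > 0
        if detected.sum() == 0:
            rows[group] = {b: np.nan for b in BIOTYPES}
            continue
        pct = (
            biotype[detected].value_counts(normalize=True)
            .reindex(BIOTYPES)
            .fillna(0.0)
            * 100.0
        )
        rows[group] = pct.to_dict()
    table = pd.DataFrame.from_dict(rows, orient="index")[list(BIOTYPES)]
    table.index.name = group_by
    return table
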