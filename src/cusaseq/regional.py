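"""Regional Z-score profiles and subtype-signature comparisons.

Given a region x gene Z-score matrix over the seven glioma anatomic
compartments, this module profiles gene sets across compartments
(mean +/- s.e.m. of Z), compares two disjoint sets per compartment with a
two-sided Mann-Whitney U test, and scores proneural/mesenchymal marker
signatures in normalized expression matrices: median signature expression
per sample, proneural-vs-mesenchymal within a sample, and a signature's
aspirate-vs-TCR comparison within a patient.

Mann-Whitney uses the exact null distribution whenever both sets are small
(at most 25 values each) and tie-free, and the tie-corrected normal
approximation otherwise; the method used is recorded in every result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import REGIONS, NormalizedMatrix, ValidationError
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25


def validate_zmatrix(z: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Check that each row of an ingested Z matrix is standardized across
    regions (mean 0, population SD 1) up to ``tol``, excepting constant
    (all-zero) rows; returns the matrix unchanged."""
    if len(z.index) < 2:
        raise ValidationError("Z matrix needs at least two regions")
    vals = z.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    nonconstant = sd > tol
    if (np.abs(mean[nonconstant]) > tol).any() or (
        np.abs(sd[nonconstant] - 1.0) > max(tol, 1e-6)
    ).any():
        raise ValidationError(
            "Z matrix rows are not standardized (mean 0, SD 1 across regions)"
        )
    return z


def mannwhitney_u(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; returns (U of the first sample, p, method).

    Exact null distribution when both samples have <= 25 values and no
    ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def region_profile(z: pd.DataFrame, genes) -> pd.DataFrame:
    """Mean and s.e.m. of Z per region over a gene set.

    Genes absent from the matrix are reported (logged) but not fatal; an
    empty intersection is an error.  Returns a DataFrame indexed by region
    with columns ``n``, ``mean_z``, ``sem``.
    """
    genes = list(genes)
    present = [g for g in genes if g in z.columns]
    missing = len(genes) - len(present)
    if missing:
        logger.info("region_profile: %d/%d genes absent from the Z matrix",
                    missing, len(genes))
    if not present:
        raise ValidationError("no gene of the set is present in the Z matrix")
    sub = z[present].to_numpy(dtype=float)
    n = sub.shape[1]
    mean = sub.mean(axis=1)
    sem = sub.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(z.index))
    return pd.DataFrame({"n": n, "mean_z": mean, "sem": sem}, index=z.index)


def compare_sets_by_region(
    z: pd.DataFrame, set_a, set_b, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-region two-sided Mann-Whitney between two disjoint gene sets.

    Returns a DataFrame indexed by region with the set sizes, mean Z of each
    set, U, p, the method used and a significance flag at ``alpha``.
    """
    set_a, set_b = list(set_a), list(set_b)
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise ValidationError(f"gene sets must be disjoint; overlap e.g. {sorted(overlap)[:5]}")
    pa = [g for g in set_a if g in z.columns]
    pb = [g for g in set_b if g in z.columns]
    if len(pa) < 2 or len(pb) < 2:
        raise ValidationError("both sets need >= 2 genes present in the Z matrix")
    rows = []
    for region in z.index:
        xa = z.loc[region, pa].to_numpy(dtype=float)
        xb = z.loc[region, pb].to_numpy(dtype=float)
        u, p, method = mannwhitney_u(xa, xb)
        rows.append(
            {
                "region": region,
                "n_a": len(pa),
                "n_b": len(pb),
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "U": u,
                "p": p,
                "method": method,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def _signature_values(nm: NormalizedMatrix, sig: SignatureSet, sample_id) -> np.ndarray:
    if sample_id not in nm.values.columns:
        raise ValidationError(f"unknown sample id: {sample_id!r}")
    present = sig.present_in(nm.values.index)
    missing = len(sig) - len(present)
    if missing:
        logger.info("signature %s: %d/%d genes absent from the matrix",
                    sig.name, missing, len(sig))
    if not present:
        raise ValidationError(
            f"no gene of signature '{sig.name}' is present in the matrix"
        )
    return nm.values.loc[present, sample_id].to_numpy(dtype=float)


def signature_median_expression(
    nm: NormalizedMatrix, sig: SignatureSet, sample_id
) -> float:
    """Median normalized expression of the signature's present genes in one sample."""
    return float(np.median(_signature_values(nm, sig, sample_id)))


@dataclass
class SignatureComparison:
    """Result of a Mann-Whitney comparison of two per-gene value vectors."""

    u: float
    p: float
    method: str
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_signatures_within_sample(
    nm: NormalizedMatrix, a: SignatureSet, b: SignatureSet, sample_id
) -> SignatureComparison:
    """Two-sided Mann-Whitney between two signatures' per-gene values in one sample."""
    if set(a.genes) & set(b.genes):
        raise ValidationError("signatures must be disjoint")
    xa = _signature_values(nm, a, sample_id)
    xb = _signature_values(nm, b, sample_id)
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("both signatures need >= 2 present genes")
    u, p, method = mannwhitney_u(xa, xb)
    return SignatureComparison(
        u=u, p=p, method=method,
        median_a=float(np.median(xa)), median_b=float(np.median(xb)),
        n_a=len(xa), n_b=len(xb),
    )


@dataclass
class TissueComparison:
    """A signature's aspirate-vs-TCR comparison within one patient."""

    p: float
    u: float
    method: str
    direction: str  # "TCR" | "aspirate" | "tie" (tissue with the higher median)
    median_tcr: float
    median_aspirate: float
    n_genes: int


def compare_signature_between_tissues(
    nm: NormalizedMatrix, sig: SignatureSet, patient_id
) -> TissueComparison:
    """Compare a signature between a patient's aspirate and TCR samples.

    The patient must have exactly one sample of each tissue.  The two
    matched columns are compared over the signature's present genes with a
    two-sided Mann-Whitney; ``direction`` names the tissue with the higher
    median.
    """
    if "patient_id" not in nm.samples.columns or "tissue" not in nm.samples.columns:
        raise ValidationError("sample sheet needs 'patient_id' and 'tissue' columns")
    sub = nm.samples[nm.samples["patient_id"] == patient_id]
    if len(sub) == 0:
        raise ValidationError(f"unknown patient id: {patient_id!r}")
    by_tissue = {}
    for tissue in ("TCR", "aspirate"):
        ids = sub.index[sub["tissue"] == tissue]
        if len(ids) != 1:
            raise ValidationError(
                f"patient {patient_id!r} must have exactly one {tissue} sample, got {len(ids)}"
            )
        by_tissue[tissue] = ids[0]
    x_tcr = _signature_values(nm, sig, by_tissue["TCR"])
    x_asp = _signature_values(nm, sig, by_tissue["aspirate"])
    if len(x_tcr) < 2:
        raise ValidationError("signature needs >= 2 present genes")
    u, p, method = mannwhitney_u(x_tcr, x_asp)
    med_t, med_a = float(np.median(x_tcr)), float(np.median(x_asp))
    if med_t > med_a:
        direction = "TCR"
    elif med_a > med_t:
        direction = "aspirate"
    else:
        direction = "tie"
    return TissueComparison(
        p=p, u=u, method=method, direction=direction,
        median_tcr=med_t, median_aspirate=med_a, n_genes=len(x_tcr),
    )
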