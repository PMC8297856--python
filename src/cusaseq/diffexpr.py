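"""Simplified negative-binomial Wald differential expression.

A self-contained, oracle-testable NB Wald engine in the DESeq-style
convention: median-of-ratios size factors, method-of-moments gene-wise
dispersions shrunk halfway toward a fitted mean-dispersion trend
``alpha(mu) = a0 + a1/mu``, fold changes from normalized group means with a
0.5 pseudo-count, and a Wald statistic from the NB Fisher information.
There is no outlier refitting, Cook's filtering, independent filtering or
shrinkage estimator: the engine exists to drive the downstream comparison
procedure, not to reproduce a full DE tool.

The selection rules of the study design are implemented in
:func:`select_top_degs`: optional exclusion of X/Y genes (for the grade
contrast, where grade groups are sex-confounded), ranking by raw p-value
with deterministic tie-breaks, a top-N cap with an unadjusted p ceiling,
and an optional BH-adjusted ceiling (used for the tissue contrast).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ValidationError, validate_catalog

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
PSEUDO_COUNT = 0.5


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Using genes positive in every sample, each sample's factor is the median
    of its counts divided by the gene-wise geometric mean.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene is positive in all samples; consider a pseudo-reference "
            "(e.g. filter samples or genes first)"
        )
    logc = np.log(counts[all_pos])
    geo = np.exp(logc.mean(axis=1, keepdims=True))
    factors = np.median(counts[all_pos] / geo, axis=0)
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``phi = a0 + a1/mu`` with non-negative clipping."""
    ok = (mu > 0) & np.isfinite(phi)
    if ok.sum() < 2:
        a0 = float(np.median(phi[ok])) if ok.any() else DISPERSION_FLOOR
        return max(a0, DISPERSION_FLOOR), 0.0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, phi[ok], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, DISPERSION_FLOOR), max(a1, 0.0)


def nb_wald_test(
    m: CountMatrix, group_key: str, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Two-group NB Wald test; log2 fold changes are group B over group A.

    Returns a DataFrame indexed by gene id with columns ``base_mean``,
    ``log2fc``, ``wald_stat``, ``p_raw``, ``p_adj`` and ``direction``.
    Genes with all-zero counts in both groups are excluded (logged).
    """
    if group_key not in m.samples.columns:
        raise ValidationError(f"unknown sample metadata key: {group_key!r}")
    a, b = contrast
    mask_a = (m.samples[group_key] == a).to_numpy()
    mask_b = (m.samples[group_key] == b).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {a}: {n_a}, {b}: {n_b})"
        )

    sf = size_factors(m).to_numpy()
    norm = m.counts.to_numpy(dtype=float) / sf

    na, nb = norm[:, mask_a], norm[:, mask_b]
    nonzero = (na.sum(axis=1) + nb.sum(axis=1)) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("nb_wald_test: excluded %d all-zero genes", dropped)
    na, nb = na[nonzero], nb[nonzero]
    genes = m.counts.index[nonzero]

    mean_a, mean_b = na.mean(axis=1), nb.mean(axis=1)
    var_a = na.var(axis=1, ddof=1)
    var_b = nb.var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled_mean = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (pooled_var - pooled_mean) / pooled_mean**2
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, DISPERSION_FLOOR)
    phi_raw = np.maximum(phi_raw, DISPERSION_FLOOR)
    a0, a1 = _fit_dispersion_trend(pooled_mean, phi_raw)
    phi_trend = np.maximum(a0 + a1 / np.maximum(pooled_mean, 1e-12), DISPERSION_FLOOR)
    phi = 0.5 * phi_raw + 0.5 * phi_trend

    mu_a, mu_b = mean_a + PSEUDO_COUNT, mean_b + PSEUDO_COUNT
    log2fc = np.log2(mu_b) - np.log2(mu_a)
    # Var(ln mean) from NB Fisher information at the estimated parameters
    var_log = (1.0 / mu_a + phi) / n_a + (1.0 / mu_b + phi) / n_b
    se_log2 = np.sqrt(var_log) / np.log(2.0)
    wald = log2fc / se_log2
    p = np.clip(2.0 * stats.norm.sf(np.abs(wald)), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "base_mean": pooled_mean,
            "log2fc": log2fc,
            "wald_stat": wald,
            "p_raw": p,
            "p_adj": benjamini_hochberg(p),
        },
        index=genes,
    )
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return table


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DEGSelection:
    """Ordered down/up DEG lists plus the selection rule that produced them."""

    down: tuple
    up: tuple
    rule: dict

    @property
    def all_genes(self) -> tuple:
        return self.down + self.up

    def __len__(self) -> int:
        return len(self.down) + len(self.up)


def select_top_degs(
    t: pd.DataFrame,
    top_n: int = 500,
    p_max: float = 0.05,
    adj_p_max: float | None = None,
    exclude_chromosomes: frozenset = frozenset(),
    catalog: pd.DataFrame | None = None,
    per_direction: bool = False,
) -> DEGSelection:
    """Apply the DEG selection rule to a DE table.

    Genes on excluded chromosomes are dropped first (``catalog`` must then
    cover the table); the rest are ranked by ascending raw p (ties by
    descending \\|Wald\\|, then gene id), filtered at ``p_raw < p_max`` (and
    ``p_adj < adj_p_max`` if given) and capped at ``top_n`` overall — or
    ``top_n`` per direction when ``per_direction`` is set.  Genes with a
    log2 fold change of exactly 0 have no direction and are never selected.
    """
    t = t.copy()
    if exclude_chromosomes:
        if catalog is None:
            raise ValidationError("exclude_chromosomes requires a catalog")
        validate_catalog(catalog)
        chrom = catalog["chromosome"].reindex(t.index)
        if chrom.isna().any():
            missing = t.index[chrom.isna()][:5].tolist()
            raise ValidationError(f"catalog does not cover DE genes, e.g. {missing}")
        t = t[~chrom.isin(list(exclude_chromosomes))]

    t = t[t["p_raw"] < p_max]
    if adj_p_max is not None:
        t = t[t["p_adj"] < adj_p_max]
    t = t[t["log2fc"] != 0.0]

    t = t.assign(_abs_w=t["wald_stat"].abs(), _gene=t.index)
    t = t.sort_values(
        ["p_raw", "_abs_w", "_gene"], ascending=[True, False, True], kind="stable"
    )
    if per_direction:
        down = t[t["log2fc"] < 0].head(top_n)
        up = t[t["log2fc"] > 0].head(top_n)
        picked = pd.concat([down, up])
    else:
        picked = t.head(top_n)
    rule = {
        "top_n": top_n,
        "p_max": p_max,
        "adj_p_max": adj_p_max,
        "excluded_chromosomes": sorted(exclude_chromosomes),
        "per_direction": per_direction,
    }
    return DEGSelection(
        down=tuple(picked.index[picked["log2fc"] < 0]),
        up=tuple(picked.index[picked["log2fc"] > 0]),
        rule=rule,
    )
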