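"""Cross-cohort DEG concordance.

A reference transcriptome is ranked by signed significance,
``sign(log2fc) * (-log10 p_raw)``, so the strongest up-regulation comes
first and the strongest down-regulation last.  A DEG set from another
cohort is then located in that ranking, the rank positions are binned into
fixed-size windows (2000 genes by default), the bin occupancy is compared
against uniform placement with a Pearson chi-square goodness-of-fit test,
and direction-aware overlap fractions quantify how many DEGs replicate in
the reference cohort with the same sign of change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexpr import DEGSelection

P_FLOOR = 1e-300


@dataclass
class RankedTranscriptome:
    """Genes ordered by descending signed significance."""

    genes: pd.Index
    scores: pd.Series  # aligned with genes, descending

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BinDistribution:
    """DEG occupancy of consecutive rank windows."""

    bin_size: int
    counts: np.ndarray
    percents: np.ndarray
    n_degs_in_ranking: int
    ranking_length: int
    n_dropped: int  # DEGs absent from the ranking


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    merged_tail_bins: int  # bins merged from the tail to keep expected >= 1


@dataclass
class OverlapResult:
    down_frac: float
    up_frac: float
    n_down: int
    n_up: int
    missing_down: int  # selection genes absent from the cohort table
    missing_up: int


def rank_transcriptome(t: pd.DataFrame) -> RankedTranscriptome:
    """Rank a DE table by signed significance.

    The score is ``sign(log2fc) * (-log10 p_raw)`` with p floored at 1e-300;
    ties are broken by gene id so the ordering is deterministic.
    """
    if len(t) == 0:
        raise ValidationError("cannot rank an empty DE table")
    score = np.sign(t["log2fc"].to_numpy()) * (
        -np.log10(np.maximum(t["p_raw"].to_numpy(), P_FLOOR))
    )
    frame = pd.DataFrame({"score": score, "_gene": t.index}, index=t.index)
    frame = frame.sort_values(["score", "_gene"], ascending=[False, True], kind="stable")
    return RankedTranscriptome(genes=frame.index, scores=frame["score"])


def bin_deg_distribution(
    r: RankedTranscriptome, degs, bin_size: int = 2000
) -> BinDistribution:
    """Count DEGs in consecutive rank windows of ``bin_size`` genes.

    Windows are [0, bin_size), [bin_size, 2 bin_size), ...; the last window
    may be short.  DEGs absent from the ranking are dropped (tallied in
    ``n_dropped``); an empty intersection is an error.
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    degs = set(degs)
    pos = pd.Series(np.arange(len(r.genes)), index=r.genes)
    in_ranking = [g for g in degs if g in pos.index]
    n_dropped = len(degs) - len(in_ranking)
    if not in_ranking:
        raise ValidationError("no DEG is present in the ranking")
    ranks = pos.loc[in_ranking].to_numpy()
    n_bins = int(np.ceil(len(r.genes) / bin_size))
    counts = np.bincount(ranks // bin_size, minlength=n_bins)
    percents = 100.0 * counts / counts.sum()
    return BinDistribution(
        bin_size=bin_size,
        counts=counts,
        percents=percents,
        n_degs_in_ranking=int(counts.sum()),
        ranking_length=len(r.genes),
        n_dropped=n_dropped,
    )


def chi2_uniform_test(b: BinDistribution) -> Chi2Result:
    """Pearson goodness-of-fit of the bin occupancy against uniform placement.

    Expected counts are proportional to bin width (the terminal bin may be
    short).  Bins are merged from the tail until every expected count is at
    least 1; the number of merges is reported.  df = (#bins after merging) - 1.
    """
    n = b.n_degs_in_ranking
    if n == 0:
        raise ValidationError("no DEGs to test")
    k = len(b.counts)
    widths = np.full(k, b.bin_size, dtype=float)
    widths[-1] = b.ranking_length - (k - 1) * b.bin_size
    counts = b.counts.astype(float).copy()
    expected = n * widths / b.ranking_length
    merged = 0
    while len(counts) > 2 and expected[-1] < 1.0:
        counts[-2] += counts[-1]
        expected[-2] += expected[-1]
        counts, expected = counts[:-1], expected[:-1]
        merged += 1
    if len(counts) < 2:
        raise ValidationError("need at least two bins for a chi-square test")
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    p = float(stats.chi2.sf(chi2, df))
    return Chi2Result(chi2=chi2, df=df, p=p, merged_tail_bins=merged)


def directional_overlap(
    sel: DEGSelection, cohort: pd.DataFrame, alpha: float = 0.05
) -> OverlapResult:
    """Fraction of selected DEGs replicating in a cohort with the same sign.

    A down-DEG is concordant when the cohort table contains it with
    ``p_raw < alpha`` and a negative log2 fold change (analogously for up).
    Selection genes absent from the cohort count as non-concordant and are
    tallied separately.
    """
    if len(sel) == 0:
        raise ValidationError("empty DEG selection")

    def _frac(genes, sign):
        if not genes:
            return np.nan, 0
        present = [g for g in genes if g in cohort.index]
        missing = len(genes) - len(present)
        if not present:
            return 0.0, missing
        sub = cohort.loc[present]
        hit = (sub["p_raw"] < alpha) & (np.sign(sub["log2fc"]) == sign)
        return float(hit.sum() / len(genes)), missing

    down_frac, miss_d = _frac(list(sel.down), -1)
    up_frac, miss_u = _frac(list(sel.up), +1)
    return OverlapResult(
        down_frac=down_frac,
        up_frac=up_frac,
        n_down=len(sel.down),
        n_up=len(sel.up),
        missing_down=miss_d,
        missing_up=miss_u,
    )
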