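"""Statistical validation harness.

Reusable simulation studies that measure, on freshly generated synthetic
cohorts, the operating characteristics of the pipeline: type-I error of the
NB Wald test, level of the per-compartment Mann-Whitney flags, recovery of
cross-cohort DEG concordance, calibration of the binned chi-square test,
recovery of the regional Z structure and of the mesenchymal tissue contrast,
and removal of the injected GC bias.  Both the test suite and the
acceptance script drive these functions; every one is deterministic given
its seed.
"""
from __future__ import annotations

import filecmp
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import (
    bin_deg_distribution,
    chi2_uniform_test,
    directional_overlap,
    rank_transcriptome,
)
from .containers import CountMatrix
from .diffexpr import nb_wald_test, select_top_degs
from .preprocess import filter_annotation_consensus, filter_low_counts, gc_normalize_median
from .regional import (
    compare_sets_by_region,
    compare_signature_between_tissues,
)
from .signatures import MESENCHYMAL
from .simulate import (
    ASPIRATE_MIXING,
    TCR_MIXING,
    SampleDesign,
    make_gene_catalog,
    make_region_model,
    make_region_zmatrix,
    simulate_counts,
    simulate_study,
)

# aspirate mixing variant with the vascular compartments down-weighted to a
# total of 0.05 (pan, hbv, mvp) for tissue-contrast recovery studies
ASPIRATE_MIXING_LOW_VASCULAR = (0.27, 0.27, 0.36, 0.05, 0.02, 0.02, 0.01)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def type1_error_rate(
    seed: int = 0,
    n_genes: int = 5000,
    n_per_group: int = 8,
    dispersion: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the NB Wald test on a null cohort.

    Two arms of ``n_per_group`` samples are simulated identically (same
    mixing, grade and sex, distinct patients) and tested against each other;
    returns the fraction of genes with raw p below ``alpha``.
    """
    s_cat, s_model, s_counts = _sub_seeds(seed, 3)
    catalog = make_gene_catalog(n_genes, seed=s_cat)
    model = make_region_model(catalog, seed=s_model)
    designs = [
        SampleDesign(
            sample_id=f"S{i:02d}",
            patient_id=f"P{i:02d}",
            tissue="TCR",
            grade_group="IV",
            mixing=np.asarray(TCR_MIXING),
        )
        for i in range(2 * n_per_group)
    ]
    cm, _ = simulate_counts(model, designs, dispersion=dispersion, seed=s_counts)
    cm.samples["arm"] = ["A"] * n_per_group + ["B"] * n_per_group
    table = nb_wald_test(cm, "arm", ("A", "B"))
    return float((table["p_raw"] < alpha).mean())


def mannwhitney_null_flag_rate(
    seed: int = 0,
    n_reps: int = 200,
    n_genes: int = 2000,
    set_size: int = 20,
    noise_sd: float = 0.3,
    alpha: float = 0.05,
) -> float:
    """Per-compartment Mann-Whitney flag rate under zero regional effect.

    The region model carries no regional effect (effect_log2 = 0) so the Z
    matrix is pure standardized noise; two disjoint random gene sets are
    compared per compartment and the overall flag fraction at ``alpha`` is
    returned.
    """
    s_cat, s_model, s_rest = _sub_seeds(seed, 3)
    catalog = make_gene_catalog(n_genes, seed=s_cat)
    model = make_region_model(catalog, effect_log2=0.0, seed=s_model)
    rng = np.random.default_rng(s_rest)
    flags = 0
    total = 0
    genes = np.asarray(catalog.index)
    for rep in range(n_reps):
        z = make_region_zmatrix(
            model, noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        picks = rng.choice(genes, size=2 * set_size, replace=False)
        res = compare_sets_by_region(z, picks[:set_size], picks[set_size:], alpha=alpha)
        flags += int(res["significant"].sum())
        total += len(res)
    return flags / total


def gc_bias_correlations(
    seed: int = 0, n_genes: int = 20000, gc_bias_fold: float = 2.0
) -> dict:
    """Per-sample Spearman correlation between GC and log expression,
    before and after GC normalization, on a default matched cohort.

    Returns ``min_abs_pre`` (weakest pre-normalization bias signal over
    samples), ``max_abs_post`` (strongest residual), and the maximum
    relative spread of the per-bin positive-count medians after
    normalization (should be ~0).
    """
    study = simulate_study(n_genes=n_genes, gc_bias_fold=gc_bias_fold, seed=seed)
    cm = filter_annotation_consensus(
        filter_low_counts(study.counts), study.catalog
    )
    nm = gc_normalize_median(cm, study.catalog, n_bins=10)
    gc = study.catalog["gc_fraction"].reindex(cm.counts.index).to_numpy()

    pre, post = [], []
    for s in cm.counts.columns:
        c = cm.counts[s].to_numpy(dtype=float)
        v = nm.values[s].to_numpy(dtype=float)
        pos = c > 0
        pre.append(abs(stats.spearmanr(gc[pos], np.log(c[pos])).statistic))
        posv = v > 0
        post.append(abs(stats.spearmanr(gc[posv], np.log(v[posv])).statistic))

    # residual spread of bin medians (positive values) after normalization
    from .preprocess import _gc_bins

    bins = _gc_bins(gc, 10)
    spreads = []
    for s in nm.values.columns:
        v = nm.values[s].to_numpy(dtype=float)
        meds = []
        for b in range(10):
            vb = v[(bins == b) & (v > 0)]
            if len(vb):
                meds.append(np.median(vb))
        meds = np.asarray(meds)
        spreads.append(float(np.max(np.abs(meds / meds[0] - 1.0))))
    return {
        "min_abs_pre": float(min(pre)),
        "max_abs_post": float(max(post)),
        "max_bin_median_spread": float(max(spreads)),
    }


def concordance_recovery(
    seed: int = 0,
    n_iv: int = 8,
    n_lgg: int = 8,
    n_genes: int = 20000,
    top_n: int = 500,
    bin_size: int = 2000,
) -> dict:
    """Directional overlap and bin concentration against the emulated
    external cohort, for a grade contrast sharing ground truth with it.

    Runs the aspirate grade-IV-vs-LGG DE on a synthetic cohort, selects the
    top DEGs (X/Y excluded), and measures the directional overlap with the
    external table (and with a gene-label-permuted copy), plus the binned
    chi-square p-values of both DEG directions in the external ranking.
    """
    study = simulate_study(n_genes=n_genes, n_iv=n_iv, n_lgg=n_lgg, seed=seed)
    cm = filter_annotation_consensus(filter_low_counts(study.counts), study.catalog)
    asp = cm.samples[cm.samples["tissue"] == "aspirate"]
    sub = CountMatrix(cm.counts[asp.index], asp)
    table = nb_wald_test(sub, "grade_group", ("LGG", "IV"))
    sel = select_top_degs(
        table,
        top_n=top_n,
        p_max=0.05,
        exclude_chromosomes=frozenset({"X", "Y"}),
        catalog=study.catalog,
    )
    external = study.external_de
    ov = directional_overlap(sel, external)

    rng = np.random.default_rng(_sub_seeds(seed, 1)[0])
    permuted = external.copy()
    permuted.index = pd.Index(
        rng.permutation(np.asarray(external.index)), name=external.index.name
    )
    ov_perm = directional_overlap(sel, permuted)

    ranking = rank_transcriptome(external)
    chi_p = {}
    for direction, genes in (("down", sel.down), ("up", sel.up)):
        dist = bin_deg_distribution(ranking, genes, bin_size=bin_size)
        chi_p[direction] = chi2_uniform_test(dist).p
    return {
        "down_frac": ov.down_frac,
        "up_frac": ov.up_frac,
        "permuted_down_frac": ov_perm.down_frac,
        "permuted_up_frac": ov_perm.up_frac,
        "chi2_p_down": chi_p["down"],
        "chi2_p_up": chi_p["up"],
        "n_down": ov.n_down,
        "n_up": ov.n_up,
    }


def chi2_calibration(
    seed: int = 0,
    n_uniform: int = 300,
    n_concentrated: int = 200,
    ranking_length: int = 20000,
    n_degs_uniform: int = 500,
    n_degs_concentrated: int = 150,
    bin_size: int = 2000,
) -> dict:
    """Calibration of the binned chi-square under uniform and concentrated
    DEG placement.

    Returns the KS p-value of the uniform-placement p-values against
    U(0, 1) and the fraction of concentrated replicates (DEGs drawn from the
    top bin) reaching p < 1e-5.
    """
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"R{i:05d}" for i in range(ranking_length)])
    scores = pd.Series(np.linspace(1.0, -1.0, ranking_length), index=gene_ids)
    from .concordance import RankedTranscriptome

    ranking = RankedTranscriptome(genes=gene_ids, scores=scores)

    uniform_p = []
    for _ in range(n_uniform):
        degs = rng.choice(gene_ids, size=n_degs_uniform, replace=False)
        dist = bin_deg_distribution(ranking, degs, bin_size=bin_size)
        uniform_p.append(chi2_uniform_test(dist).p)
    ks_p = float(stats.kstest(uniform_p, "uniform").pvalue)

    hits = 0
    for _ in range(n_concentrated):
        degs = rng.choice(gene_ids[:bin_size], size=n_degs_concentrated, replace=False)
        dist = bin_deg_distribution(ranking, degs, bin_size=bin_size)
        if chi2_uniform_test(dist).p < 1e-5:
            hits += 1
    return {
        "uniform_ks_p": ks_p,
        "concentrated_signif_frac": hits / n_concentrated,
    }


def regional_recovery_rate(
    seed: int = 0,
    n_seeds: int = 50,
    n_genes: int = 4000,
    effect_log2: float = 1.0,
    noise_sd: float = 0.3,
    alpha: float = 0.05,
) -> float:
    """Fraction of seeds recovering the regional placement of the tissue DEGs.

    Per seed, a fresh region model and Z matrix are generated; the genes
    truly elevated in aspirates (peripheral set) are compared against the
    genes truly elevated in cores (vascular set).  A seed succeeds when the
    peripheral set's mean Z exceeds the vascular set's in LE and IT, is
    below it in hbv and mvp, and all four comparisons reach p < ``alpha``.
    """
    seeds = _sub_seeds(seed, n_seeds * 3)
    hits = 0
    for k in range(n_seeds):
        s_cat, s_model, s_z = seeds[3 * k : 3 * k + 3]
        catalog = make_gene_catalog(n_genes, seed=s_cat)
        model = make_region_model(catalog, effect_log2=effect_log2, seed=s_model)
        z = make_region_zmatrix(model, noise_sd=noise_sd, seed=s_z)
        res = compare_sets_by_region(
            z, model.peripheral_genes, model.vascular_genes, alpha=alpha
        )
        ok = (
            all(
                res.loc[r, "significant"] and res.loc[r, "mean_a"] > res.loc[r, "mean_b"]
                for r in ("LE", "IT")
            )
            and all(
                res.loc[r, "significant"] and res.loc[r, "mean_a"] < res.loc[r, "mean_b"]
                for r in ("hbv", "mvp")
            )
        )
        hits += ok
    return hits / n_seeds


def mesenchymal_tissue_recovery_rate(
    seed: int = 0,
    n_seeds: int = 50,
    n_genes: int = 2000,
    effect_log2: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of seeds in which the mesenchymal signature is detected
    higher in TCR than in the matched aspirate.

    Per seed, a 4-patient matched cohort is simulated with the aspirate
    vascular weight lowered to 0.05 (vs 0.30 in cores); after filtering and
    GC normalization, the signature is compared between tissues within each
    patient.  A seed succeeds when at least one patient shows the TCR-higher
    direction at p < ``alpha`` and no patient is significant in the reverse
    direction.
    """
    seeds = _sub_seeds(seed, n_seeds * 3)
    hits = 0
    for k in range(n_seeds):
        s_cat, s_model, s_counts = seeds[3 * k : 3 * k + 3]
        catalog = make_gene_catalog(n_genes, seed=s_cat)
        model = make_region_model(catalog, effect_log2=effect_log2, seed=s_model)
        designs = []
        for i in range(4):
            pid = f"P{i + 1:02d}"
            grade = "IV" if i < 2 else "LGG"
            designs.append(
                SampleDesign(f"{pid}-C", pid, "TCR", grade, np.asarray(TCR_MIXING))
            )
            designs.append(
                SampleDesign(
                    f"{pid}-A", pid, "aspirate", grade,
                    np.asarray(ASPIRATE_MIXING_LOW_VASCULAR),
                )
            )
        cm, _ = simulate_counts(model, designs, seed=s_counts)
        cm = filter_annotation_consensus(filter_low_counts(cm), catalog)
        nm = gc_normalize_median(cm, catalog)
        tcr_hits, reversals = 0, 0
        for pid in ("P01", "P02", "P03", "P04"):
            comp = compare_signature_between_tissues(nm, MESENCHYMAL, pid)
            if comp.p < alpha and comp.direction == "TCR":
                tcr_hits += 1
            elif comp.p < alpha and comp.direction == "aspirate":
                reversals += 1
        hits += tcr_hits >= 1 and reversals == 0
    return hits / n_seeds


def pipeline_determinism(seed: int, base_dir, n_genes: int = 5000) -> dict:
    """Run the default pipeline twice with the same config; byte-compare
    every numeric report and measure the wall time of one run."""
    from .pipeline import RunConfig, run_pipeline

    base = Path(base_dir)
    t0 = time.perf_counter()
    cfg_a = RunConfig(out_dir=str(base / "run_a"), seed=seed, n_genes=n_genes)
    out_a = run_pipeline(cfg_a)
    elapsed = time.perf_counter() - t0
    cfg_b = RunConfig(out_dir=str(base / "run_b"), seed=seed, n_genes=n_genes)
    out_b = run_pipeline(cfg_b)
    numeric = [
        p.name
        for p in out_a.glob("*.tsv")
    ]
    identical = all(
        filecmp.cmp(out_a / name, out_b / name, shallow=False) for name in numeric
    )
    return {
        "identical": bool(identical),
        "n_files_compared": len(numeric),
        "seconds": elapsed,
    }
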