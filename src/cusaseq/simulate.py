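"""Synthetic matched-cohort generator.

This module emulates the data structure of a matched surgical-aspirate /
tumour-core-resection (TCR) glioma RNA-seq study:

* a gene catalog with biotype composition, GC content, length and a small
  sex-chromosome contingent;
* a region-mixture expression model over the seven Ivy-GAP-like anatomic
  compartments, in which a "peripheral" gene set (containing the proneural
  markers) is elevated at the leading edge / infiltrating tumour and a
  "vascular" gene set (containing the mesenchymal markers) is elevated in the
  vascularised compartments;
* negative-binomial counts per sample, where each sample is a mixture over
  compartments (aspirates over-weight peripheral compartments, cores
  vascular ones), with GC bias, per-patient random effects, a grade-IV
  expression contrast and a deliberate sex/grade confound on X/Y genes;
* an emulated external grade-IV-vs-lower-grade cohort sharing the same
  ground-truth grade effects; and
* a region x gene Z-score matrix mirroring the regional atlas format.

Every generated artifact is deterministic given its seed, and the latent
parameters are returned in a :class:`GroundTruth` record so downstream
recovery can be tested.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    BIOTYPES,
    GRADE_GROUPS,
    PERIPHERAL_REGIONS,
    REGIONS,
    TISSUES,
    VASCULAR_REGIONS,
    CountMatrix,
    ValidationError,
    validate_catalog,
)
from .signatures import MESENCHYMAL, PRONEURAL

# -- Default study conditions -------------------------------------------------

#: Biotype composition used as generator defaults (protein-coding,
#: pseudogene, long non-coding and small-RNA fractions as observed in
#: archival glioma tissue; "other" closes the budget to 1).
DEFAULT_BIOTYPE_PROPS = {
    "protein_coding": 0.636,
    "pseudogene": 0.177,
    "long_noncoding": 0.113,
    "small_rna": 0.024,
    "other": 0.05,
}

DEFAULT_GC_RANGE = (0.30, 0.70)

#: Region mixing proportions over (LE, IT, CT, pnz, pan, hbv, mvp).
#: Aspirates over-weight the peripheral compartments (surface fragmentation),
#: tumour cores the internal/vascularised ones.
ASPIRATE_MIXING = (0.25, 0.25, 0.35, 0.05, 0.05, 0.03, 0.02)
TCR_MIXING = (0.05, 0.05, 0.50, 0.10, 0.10, 0.10, 0.10)

#: Log-normal spread (natural-log sd) of the per-gene baseline expression.
#: Kept moderate so that an injected 2-fold GC bias is the dominant
#: secondary structure of the matrix and remains identifiable; see the
#: methods note for the calculation.
BASELINE_LOG_SD = 0.25

#: NB dispersion phi in Var = mu + phi mu^2 (global default; per-gene allowed).
DEFAULT_DISPERSION = 0.2

#: Per-patient, per-gene log-normal random-effect scale (natural-log sd),
#: shared by the two tissues of a patient.
DEFAULT_SIGMA_PATIENT = 0.15

DEFAULT_LIBRARY_SIZE = 5_000_000

#: Sex-linked expression multipliers; grade-IV patients default to female and
#: lower-grade patients to male, recreating the sex/grade confound that makes
#: the X/Y DEG-exclusion rule necessary.
X_FEMALE_FOLD = 1.5
Y_FEMALE_FOLD = 0.02

_AUTOSOMES = tuple(str(i) for i in range(1, 23))


# -- Domain types -------------------------------------------------------------


@dataclass
class RegionExpressionModel:
    """Region x gene mean-expression model on the linear scale.

    ``mu[r, g] = baseline[g] * multiplier[r, g]`` where the multiplier is
    ``2**effect_log2`` for peripheral genes in LE/IT and vascular genes in
    pan/hbv/mvp, and 1 otherwise.
    """

    regions: tuple
    mu: pd.DataFrame  # regions x genes, strictly positive
    baseline: pd.Series  # per-gene lambda_g
    peripheral_genes: tuple
    vascular_genes: tuple
    effect_log2: float
    catalog: pd.DataFrame

    def validate(self) -> "RegionExpressionModel":
        if tuple(self.mu.index) != tuple(REGIONS):
            raise ValidationError(f"model regions must be exactly {REGIONS}")
        if not (self.mu.to_numpy() > 0).all():
            raise ValidationError("mu must be strictly positive")
        if set(self.peripheral_genes) & set(self.vascular_genes):
            raise ValidationError("peripheral and vascular gene sets overlap")
        return self


@dataclass
class SampleDesign:
    """Design of one simulated library.

    ``mixing`` gives the proportions of the seven compartments contributing
    to the sample (non-negative, summing to 1); ``sigma_patient`` is the
    log-normal scale of the patient random effect shared by both tissues of
    the patient.
    """

    sample_id: str
    patient_id: str
    tissue: str  # "TCR" | "aspirate"
    grade_group: str  # "IV" | "LGG"
    mixing: np.ndarray
    library_size: int = DEFAULT_LIBRARY_SIZE
    sex: str = ""  # "F" | "M"; defaults from grade group if empty
    sigma_patient: float = DEFAULT_SIGMA_PATIENT

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (len(REGIONS),):
            raise ValidationError(
                f"mixing must have {len(REGIONS)} entries, got {self.mixing.shape}"
            )
        if (self.mixing < 0).any() or abs(self.mixing.sum() - 1.0) > 1e-9:
            raise ValidationError("mixing must be >= 0 and sum to 1 (tol 1e-9)")
        if self.library_size < 1:
            raise ValidationError("library_size must be >= 1")
        if self.tissue not in TISSUES:
            raise ValidationError(f"tissue must be one of {TISSUES}")
        if self.grade_group not in GRADE_GROUPS:
            raise ValidationError(f"grade_group must be one of {GRADE_GROUPS}")
        if not self.sex:
            self.sex = "F" if self.grade_group == "IV" else "M"


@dataclass
class GroundTruth:
    """Latent values behind a simulated count matrix.

    ``weights`` are the pre-normalization intensities ``w(g, s)`` (affine in
    the mixing vector); ``expected`` the library-size-normalised expected
    counts actually used for NB sampling.
    """

    grade_effects: pd.Series  # per-gene log2 effect, IV over LGG (0 = null)
    mixing: pd.DataFrame  # samples x regions
    peripheral_genes: tuple
    vascular_genes: tuple
    dispersion: pd.Series  # per-gene phi
    gc_log_slope: float
    weights: pd.DataFrame  # genes x samples
    expected: pd.DataFrame  # genes x samples
    patient_effects: pd.DataFrame  # genes x patients (multipliers)

    @property
    def true_de_genes_grade(self) -> tuple:
        eff = self.grade_effects
        return tuple(eff.index[eff != 0.0])


# -- Operations ---------------------------------------------------------------


def make_gene_catalog(
    n_genes: int,
    biotype_props: dict | None = None,
    gc_range: tuple = DEFAULT_GC_RANGE,
    seed: int = 0,
    seed_signature_symbols: bool = True,
) -> pd.DataFrame:
    """Generate a synthetic gene catalog.

    Biotypes are assigned multinomially at ``biotype_props``; GC fractions
    are uniform on ``gc_range``; lengths log-normal; about 2% of genes land
    on the sex chromosomes (1% X, 1% Y).  When ``seed_signature_symbols`` is
    true and the catalog is transcriptome-scale (>= 200 genes), the built-in
    proneural and mesenchymal marker symbols replace the ids of randomly
    chosen autosomal protein-coding genes so that signature-level analyses
    can run on generated data.

    Returns a DataFrame indexed by gene id with columns ``chromosome``,
    ``length_nt``, ``gc_fraction``, ``biotype``.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    props = dict(DEFAULT_BIOTYPE_PROPS if biotype_props is None else biotype_props)
    unknown = set(props) - set(BIOTYPES)
    if unknown:
        raise ValidationError(f"unknown biotypes in proportions: {sorted(unknown)}")
    p = np.array([props.get(b, 0.0) for b in BIOTYPES], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("biotype proportions must be >= 0 and sum to 1")
    lo, hi = gc_range
    if not (0 <= lo < hi <= 1):
        raise ValidationError("gc_range must satisfy 0 <= lo < hi <= 1")

    rng = np.random.default_rng(seed)
    biotype = rng.choice(len(BIOTYPES), size=n_genes, p=p)
    gc = rng.uniform(lo, hi, size=n_genes)
    length = np.maximum(1, np.round(rng.lognormal(np.log(1300.0), 0.6, size=n_genes))).astype(int)
    # chromosome: ~1% X, ~1% Y, remainder uniform over autosomes
    chrom_draw = rng.uniform(size=n_genes)
    chrom = np.array(rng.choice(_AUTOSOMES, size=n_genes), dtype=object)
    chrom[chrom_draw < 0.01] = "X"
    chrom[(chrom_draw >= 0.01) & (chrom_draw < 0.02)] = "Y"

    gene_ids = np.array([f"G{i:06d}" for i in range(n_genes)], dtype=object)
    if seed_signature_symbols and n_genes >= 200:
        symbols = list(PRONEURAL.genes) + list(MESENCHYMAL.genes)
        eligible = np.flatnonzero(
            (biotype == BIOTYPES.index("protein_coding"))
            & (chrom != "X")
            & (chrom != "Y")
        )
        if len(eligible) >= len(symbols):
            picks = rng.choice(eligible, size=len(symbols), replace=False)
            gene_ids[picks] = symbols
        else:  # pragma: no cover - requires extreme biotype proportions
            warnings.warn("too few autosomal protein-coding genes; signature symbols not seeded")

    catalog = pd.DataFrame(
        {
            "chromosome": chrom,
            "length_nt": length,
            "gc_fraction": gc,
            "biotype": [BIOTYPES[i] for i in biotype],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return validate_catalog(catalog)


def make_region_model(
    catalog: pd.DataFrame,
    n_peripheral: int = 150,
    n_vascular: int = 150,
    effect_log2: float = 1.0,
    seed: int = 0,
    baseline_log_sd: float = BASELINE_LOG_SD,
) -> RegionExpressionModel:
    """Build the region x gene mean-expression model.

    A log-normal baseline lambda_g is drawn per gene; ``n_peripheral`` genes
    (forced to include any proneural markers present in the catalog) receive
    a ``2**effect_log2`` multiplier in LE and IT, and ``n_vascular`` genes
    (forced to include any mesenchymal markers present) the same multiplier
    in pan, hbv and mvp.  Peripheral and vascular sets are disjoint and drawn
    from autosomal genes so the regional structure is not entangled with the
    sex/grade confound.
    """
    validate_catalog(catalog)
    if effect_log2 < 0:
        raise ValidationError("effect_log2 must be >= 0")
    genes = catalog.index
    if n_peripheral + n_vascular > len(genes):
        raise ValidationError("n_peripheral + n_vascular exceeds the catalog size")
    rng = np.random.default_rng(seed)
    baseline = pd.Series(
        rng.lognormal(np.log(100.0), baseline_log_sd, size=len(genes)),
        index=genes,
        name="baseline",
    )

    autosomal = genes[~catalog["chromosome"].isin(["X", "Y"])]
    all_symbols = set(PRONEURAL.genes) | set(MESENCHYMAL.genes)

    def _seeded(signature, pool, n_target, taken):
        present = [g for g in signature.genes if g in genes]
        absent = [g for g in signature.genes if g not in genes]
        if absent:
            warnings.warn(
                f"{len(absent)} {signature.name} marker(s) absent from catalog, skipped: "
                + ", ".join(absent[:5])
            )
        chosen = list(present)
        # random picks avoid every signature symbol so the two sets stay disjoint
        candidates = [g for g in pool if g not in taken and g not in all_symbols]
        extra = max(0, n_target - len(chosen))
        if extra:
            chosen += list(rng.choice(candidates, size=min(extra, len(candidates)), replace=False))
        return tuple(chosen)

    peripheral = _seeded(PRONEURAL, autosomal, n_peripheral, set())
    vascular = _seeded(MESENCHYMAL, autosomal, n_vascular, set(peripheral))

    mult = pd.DataFrame(1.0, index=list(REGIONS), columns=genes)
    fold = 2.0 ** effect_log2
    mult.loc[list(PERIPHERAL_REGIONS), list(peripheral)] = fold
    mult.loc[list(VASCULAR_REGIONS), list(vascular)] = fold
    mu = mult.mul(baseline, axis=1)
    return RegionExpressionModel(
        regions=tuple(REGIONS),
        mu=mu,
        baseline=baseline,
        peripheral_genes=peripheral,
        vascular_genes=vascular,
        effect_log2=float(effect_log2),
        catalog=catalog,
    ).validate()


def make_grade_effects(
    catalog: pd.DataFrame,
    n_effect: int = 500,
    effect_log2: float = 1.5,
    seed: int = 0,
) -> pd.Series:
    """Draw the set of genes carrying a grade-IV expression effect.

    ``n_effect`` autosomal genes receive a log2 effect of +/-``effect_log2``
    (random sign); all other genes are 0.  Effects are expressed as grade IV
    over lower grade.
    """
    validate_catalog(catalog)
    rng = np.random.default_rng(seed)
    autosomal = catalog.index[~catalog["chromosome"].isin(["X", "Y"])]
    if n_effect > len(autosomal):
        raise ValidationError("n_effect exceeds the number of autosomal genes")
    chosen = rng.choice(autosomal, size=n_effect, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_effect)
    eff = pd.Series(0.0, index=catalog.index, name="grade_log2fc")
    eff.loc[chosen] = signs * effect_log2
    return eff


def matched_cohort_designs(
    n_iv: int = 2,
    n_lgg: int = 2,
    aspirate_mixing: tuple = ASPIRATE_MIXING,
    tcr_mixing: tuple = TCR_MIXING,
    library_size: int = DEFAULT_LIBRARY_SIZE,
    sigma_patient: float = DEFAULT_SIGMA_PATIENT,
) -> list:
    """Designs for a matched cohort: each patient contributes one aspirate
    and one TCR library.  Grade-IV patients default to female and lower-grade
    patients to male (the sex/grade confound of the emulated study design).
    """
    designs = []
    grades = ["IV"] * n_iv + ["LGG"] * n_lgg
    for i, grade in enumerate(grades):
        pid = f"P{i + 1:02d}"
        for tissue, mixing, suffix in (
            ("TCR", tcr_mixing, "C"),
            ("aspirate", aspirate_mixing, "A"),
        ):
            designs.append(
                SampleDesign(
                    sample_id=f"{pid}-{suffix}",
                    patient_id=pid,
                    tissue=tissue,
                    grade_group=grade,
                    mixing=np.asarray(mixing, dtype=float),
                    library_size=library_size,
                    sigma_patient=sigma_patient,
                )
            )
    return designs


def simulate_counts(
    model: RegionExpressionModel,
    designs: list,
    dispersion=DEFAULT_DISPERSION,
    gc_bias_fold: float = 2.0,
    seed: int = 0,
    grade_effects: pd.Series | None = None,
    sex_effects: bool = True,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB counts for a list of sample designs.

    The expected count of gene g in sample s is
    ``library_size_s * w(g, s) / sum_g' w(g', s)`` with

    ``w = (sum_r mixing_r mu[r, g]) * gcmult(gc_g) * patient(g, p(s))
    * 2**(grade_effect_g [if s is grade IV]) * sexmult(g, sex(s))``

    and counts are NB with variance ``mu + phi mu^2`` (Poisson when phi is
    ~0).  ``gcmult`` is exp-linear in GC content, spans ``gc_bias_fold``-fold
    across the catalog's GC range and is normalised to mean 1.

    Returns the count matrix together with a :class:`GroundTruth` recording
    every latent quantity.
    """
    model.validate()
    if not designs:
        raise ValidationError("designs must be non-empty")
    if gc_bias_fold < 1:
        raise ValidationError("gc_bias_fold must be >= 1")
    genes = model.mu.columns
    n_genes = len(genes)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    if (phi < 0).any():
        raise ValidationError("dispersion must be >= 0")

    rng = np.random.default_rng(seed)

    # GC bias multiplier, mean-normalised
    gc = model.catalog.loc[genes, "gc_fraction"].to_numpy(dtype=float)
    if gc_bias_fold > 1.0 and gc.max() > gc.min():
        slope = np.log(gc_bias_fold) / (gc.max() - gc.min())
    else:
        slope = 0.0
    gcmult = np.exp(slope * gc)
    gcmult /= gcmult.mean()

    # per-patient random effects, one draw per patient in order of first appearance
    patients = list(dict.fromkeys(d.patient_id for d in designs))
    sigma_by_patient = {}
    for d in designs:
        sigma_by_patient.setdefault(d.patient_id, d.sigma_patient)
    pat_eff = {}
    for pid in patients:
        s = sigma_by_patient[pid]
        pat_eff[pid] = np.exp(rng.normal(0.0, s, size=n_genes)) if s > 0 else np.ones(n_genes)
    patient_effects = pd.DataFrame(pat_eff, index=genes)

    grade_mult = np.ones(n_genes)
    if grade_effects is not None:
        grade_mult = 2.0 ** grade_effects.reindex(genes).fillna(0.0).to_numpy()
    chrom = model.catalog.loc[genes, "chromosome"].to_numpy(dtype=object)
    x_mask, y_mask = chrom == "X", chrom == "Y"

    mu_mat = model.mu.to_numpy()  # regions x genes
    weights = np.empty((n_genes, len(designs)))
    for j, d in enumerate(designs):
        w = d.mixing @ mu_mat
        w = w * gcmult * patient_effects[d.patient_id].to_numpy()
        if d.grade_group == "IV":
            w = w * grade_mult
        if sex_effects and d.sex == "F":
            w = w.copy()
            w[x_mask] *= X_FEMALE_FOLD
            w[y_mask] *= Y_FEMALE_FOLD
        weights[:, j] = w

    if not np.isfinite(weights).all():
        raise ValidationError("non-finite expected counts")
    lib = np.array([d.library_size for d in designs], dtype=float)
    expected = lib * weights / weights.sum(axis=0)

    # NB with Var = mu + phi mu^2 via size n = 1/phi, p = n / (n + mu);
    # genes with phi ~ 0 fall back to Poisson.
    counts = np.empty_like(expected, dtype=np.int64)
    nb_rows = phi >= 1e-12
    if nb_rows.any():
        size = (1.0 / phi[nb_rows])[:, None]
        mu_nb = expected[nb_rows]
        counts[nb_rows] = rng.negative_binomial(size, size / (size + mu_nb))
    if (~nb_rows).any():
        counts[~nb_rows] = rng.poisson(expected[~nb_rows])

    sample_ids = [d.sample_id for d in designs]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=pd.DataFrame(
            {
                "patient_id": [d.patient_id for d in designs],
                "tissue": [d.tissue for d in designs],
                "grade_group": [d.grade_group for d in designs],
                "sex": [d.sex for d in designs],
                "library_size": [d.library_size for d in designs],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    ).validate()
    truth = GroundTruth(
        grade_effects=(
            grade_effects.reindex(genes).fillna(0.0)
            if grade_effects is not None
            else pd.Series(0.0, index=genes)
        ),
        mixing=pd.DataFrame(
            [d.mixing for d in designs], index=sample_ids, columns=list(REGIONS)
        ),
        peripheral_genes=model.peripheral_genes,
        vascular_genes=model.vascular_genes,
        dispersion=pd.Series(phi, index=genes),
        gc_log_slope=slope,
        weights=pd.DataFrame(weights, index=genes, columns=sample_ids),
        expected=pd.DataFrame(expected, index=genes, columns=sample_ids),
        patient_effects=patient_effects,
    )
    return cm, truth


def simulate_external_ranking(
    model: RegionExpressionModel,
    truth: GroundTruth,
    n_per_group: int = 200,
    power_scale: float = 1.0,
    seed: int = 0,
    log2_sd: float = 1.0,
) -> pd.DataFrame:
    """Emulate a large external grade-IV-vs-lower-grade cohort.

    Per-gene log2 expression is normal with sd ``log2_sd`` around the model
    baseline, with the ground-truth grade effect (attenuated by
    ``power_scale``) added to the grade-IV group; a Welch t-test per gene
    yields a full-transcriptome DE table with the same columns as the
    internal NB Wald tables (``wald_stat`` holds the t statistic).
    """
    if not (0 < power_scale <= 1):
        raise ValidationError("power_scale must be in (0, 1]")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    genes = model.mu.columns
    base = np.log2(model.baseline.to_numpy())
    eff = truth.grade_effects.reindex(genes).fillna(0.0).to_numpy() * power_scale

    lgg = rng.normal(base, log2_sd, size=(n_per_group, len(genes)))
    iv = rng.normal(base + eff, log2_sd, size=(n_per_group, len(genes)))

    m1, m2 = iv.mean(axis=0), lgg.mean(axis=0)
    v1, v2 = iv.var(axis=0, ddof=1), lgg.var(axis=0, ddof=1)
    n = float(n_per_group)
    se2 = v1 / n + v2 / n
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    from .diffexpr import benjamini_hochberg  # local import to avoid a cycle

    table = pd.DataFrame(
        {
            "base_mean": (2.0**m1 + 2.0**m2) / 2.0,
            "log2fc": m1 - m2,
            "wald_stat": t,
            "p_raw": p,
            "p_adj": benjamini_hochberg(p),
        },
        index=genes,
    )
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return table


def make_region_zmatrix(
    model: RegionExpressionModel, noise_sd: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Region x gene Z-score matrix emulating the regional atlas format.

    Per gene, the log mean expression across regions (plus Gaussian noise of
    sd ``noise_sd``) is standardised to mean 0 and population SD 1 across the
    seven regions.  Genes constant across regions with zero noise yield an
    all-zero row (0/0 is defined as 0).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if len(model.mu.index) < 2:
        raise ValidationError("Z-scores require at least two regions")
    rng = np.random.default_rng(seed)
    v = np.log(model.mu.to_numpy())  # regions x genes
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    mean = v.mean(axis=0)
    sd = v.std(axis=0)  # population SD across regions
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v - mean) / sd
    z[:, sd < 1e-12] = 0.0
    return pd.DataFrame(z, index=model.mu.index, columns=model.mu.columns)


# -- Convenience: one call generates a whole study ----------------------------


@dataclass
class StudyData:
    """Bundle of every synthetic input the pipeline consumes."""

    catalog: pd.DataFrame
    model: RegionExpressionModel
    designs: list
    counts: CountMatrix
    truth: GroundTruth
    zmatrix: pd.DataFrame
    external_de: pd.DataFrame


def simulate_study(
    n_genes: int = 20000,
    n_iv: int = 2,
    n_lgg: int = 2,
    effect_log2: float = 1.0,
    n_peripheral: int = 150,
    n_vascular: int = 150,
    grade_n_effect: int = 500,
    grade_effect_log2: float = 1.5,
    dispersion: float = DEFAULT_DISPERSION,
    gc_bias_fold: float = 2.0,
    sigma_patient: float = DEFAULT_SIGMA_PATIENT,
    library_size: int = DEFAULT_LIBRARY_SIZE,
    noise_sd_z: float = 0.3,
    external_n_per_group: int = 200,
    external_power_scale: float = 1.0,
    seed: int = 0,
) -> StudyData:
    """Generate a full matched-cohort study with its external reference.

    Sub-seeds for the independent stages (catalog, model, grade effects,
    counts, Z matrix, external cohort) are spawned deterministically from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    catalog = make_gene_catalog(n_genes, seed=seeds[0])
    model = make_region_model(
        catalog,
        n_peripheral=n_peripheral,
        n_vascular=n_vascular,
        effect_log2=effect_log2,
        seed=seeds[1],
    )
    grade_effects = make_grade_effects(
        catalog, n_effect=grade_n_effect, effect_log2=grade_effect_log2, seed=seeds[2]
    )
    designs = matched_cohort_designs(
        n_iv=n_iv,
        n_lgg=n_lgg,
        library_size=library_size,
        sigma_patient=sigma_patient,
    )
    counts, truth = simulate_counts(
        model,
        designs,
        dispersion=dispersion,
        gc_bias_fold=gc_bias_fold,
        seed=seeds[3],
        grade_effects=grade_effects,
    )
    zmatrix = make_region_zmatrix(model, noise_sd=noise_sd_z, seed=seeds[4])
    external = simulate_external_ranking(
        model,
        truth,
        n_per_group=external_n_per_group,
        power_scale=external_power_scale,
        seed=seeds[5],
    )
    return StudyData(catalog, model, designs, counts, truth, zmatrix, external)
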