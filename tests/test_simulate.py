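"""Contracts of the synthetic matched-cohort generator."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cusaseq as cq
from cusaseq.simulate import ASPIRATE_MIXING, TCR_MIXING

PURE_LE = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _design(sample_id, patient, mixing, tissue="TCR", grade="LGG", **kw):
    return cq.SampleDesign(sample_id, patient, tissue, grade, np.asarray(mixing), **kw)


class TestGeneCatalog:
    def test_biotype_proportions_recovered(self):
        props = {"protein_coding": 0.636, "pseudogene": 0.177,
                 "long_noncoding": 0.113, "small_rna": 0.024, "other": 0.05}
        cat = cq.make_gene_catalog(20000, biotype_props=props, seed=3)
        emp = cat["biotype"].value_counts(normalize=True)
        for b, p in props.items():
            assert abs(emp.get(b, 0.0) - p) < 0.01

    def test_single_gene_degenerate(self):
        cat = cq.make_gene_catalog(1, biotype_props={"protein_coding": 1.0}, seed=0)
        assert len(cat) == 1 and cat["biotype"].iloc[0] == "protein_coding"

    def test_deterministic(self):
        a = cq.make_gene_catalog(500, seed=42)
        b = cq.make_gene_catalog(500, seed=42)
        assert a.to_csv() == b.to_csv()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(cq.ValidationError):
            cq.make_gene_catalog(10, biotype_props={"protein_coding": 0.5}, seed=0)
        with pytest.raises(cq.ValidationError):
            cq.make_gene_catalog(10, gc_range=(0.7, 0.3), seed=0)

    def test_sex_chromosome_fraction_and_gc_range(self):
        cat = cq.make_gene_catalog(20000, seed=5)
        sex_frac = cat["chromosome"].isin(["X", "Y"]).mean()
        assert 0.01 < sex_frac < 0.03
        assert cat["gc_fraction"].between(0.30, 0.70).all()

    def test_signature_symbols_seeded(self, catalog2k):
        for sym in cq.PRONEURAL.genes + cq.MESENCHYMAL.genes:
            assert sym in catalog2k.index
            assert catalog2k.loc[sym, "biotype"] == "protein_coding"
            assert catalog2k.loc[sym, "chromosome"] not in ("X", "Y")


class TestRegionModel:
    def test_zero_effect_constant_mu(self, catalog2k):
        model = cq.make_region_model(catalog2k, effect_log2=0.0, seed=1)
        assert np.allclose(model.mu.to_numpy(), model.mu.to_numpy()[0], rtol=0, atol=0)

    def test_peripheral_fold_exact(self, model2k):
        g = model2k.peripheral_genes[0]
        assert model2k.mu.loc["LE", g] / model2k.mu.loc["CT", g] == pytest.approx(
            2.0 ** model2k.effect_log2, abs=0
        )

    def test_mean_peripheral_log2_ratio(self, catalog2k):
        model = cq.make_region_model(catalog2k, n_peripheral=200, effect_log2=1.0, seed=7)
        ratios = np.log2(
            model.mu.loc["LE", list(model.peripheral_genes)]
            / model.mu.loc["CT", list(model.peripheral_genes)]
        )
        assert abs(ratios.mean() - 1.0) < 1e-12

    def test_signature_placement_and_disjointness(self, model2k):
        assert set(cq.PRONEURAL.genes) <= set(model2k.peripheral_genes)
        assert set(cq.MESENCHYMAL.genes) <= set(model2k.vascular_genes)
        assert not set(model2k.peripheral_genes) & set(model2k.vascular_genes)

    def test_absent_signature_gene_warns_and_skips(self):
        cat = cq.make_gene_catalog(300, seed=2, seed_signature_symbols=False)
        with pytest.warns(UserWarning, match="absent from catalog"):
            model = cq.make_region_model(cat, seed=2)
        assert not set(cq.PRONEURAL.genes) & set(model.peripheral_genes)


class TestSimulateCounts:
    def test_pure_region_expected_proportional_to_mu(self, model2k):
        d = [_design("S1", "P1", PURE_LE, sigma_patient=0.0)]
        _, truth = cq.simulate_counts(model2k, d, dispersion=0.0, gc_bias_fold=1.0, seed=0)
        expected = truth.expected["S1"]
        ratio = expected / model2k.mu.loc["LE"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_library_size_scaling(self, model2k):
        designs = [
            _design("A", "P1", TCR_MIXING, library_size=1_000_000),
            _design("B", "P1", TCR_MIXING, library_size=2_000_000),
        ]
        cm, truth = cq.simulate_counts(model2k, designs, seed=4)
        assert np.allclose(2 * truth.expected["A"], truth.expected["B"])
        colsum = cm.counts.sum(axis=0)
        assert abs(colsum["B"] / colsum["A"] - 2.0) < 0.06  # 2x within 3% each

    def test_nb_variance_contract(self, catalog2k):
        """Across 200 replicate libraries, per-gene variance tracks mu + phi mu^2."""
        model = cq.make_region_model(catalog2k, effect_log2=0.0, seed=9)
        designs = [
            _design(f"S{i}", f"P{i}", TCR_MIXING, sigma_patient=0.0,
                    library_size=500_000)
            for i in range(200)
        ]
        cm, truth = cq.simulate_counts(model, designs, dispersion=0.2, seed=9)
        mu = truth.expected.mean(axis=1)
        big = mu >= 50
        emp_var = cm.counts.loc[big].var(axis=1, ddof=1)
        theo = mu[big] + 0.2 * mu[big] ** 2
        ratio = emp_var / theo
        assert abs(np.median(ratio) - 1.0) < 0.15
        assert (np.abs(ratio - 1.0) < 0.40).mean() >= 0.90

    def test_mixing_affine_in_weights(self, model2k):
        mix_a = np.asarray(PURE_LE)
        mix_b = np.zeros(7); mix_b[2] = 1.0  # pure CT
        mix_half = 0.5 * mix_a + 0.5 * mix_b
        designs = [
            _design("A", "P1", mix_a),
            _design("B", "P1", mix_b),
            _design("H", "P1", mix_half),
        ]
        _, truth = cq.simulate_counts(model2k, designs, dispersion=0.0,
                                      gc_bias_fold=1.0, seed=1)
        w = truth.weights
        assert np.allclose(w["H"], 0.5 * (w["A"] + w["B"]), rtol=1e-12)

    def test_deterministic(self, model2k):
        designs = [_design("A", "P1", TCR_MIXING), _design("B", "P2", ASPIRATE_MIXING)]
        a, _ = cq.simulate_counts(model2k, designs, seed=5)
        b, _ = cq.simulate_counts(model2k, designs, seed=5)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_patient_effect_shared_across_tissues(self, model2k):
        designs = [
            _design("P1-C", "P1", TCR_MIXING),
            _design("P1-A", "P1", ASPIRATE_MIXING, tissue="aspirate"),
        ]
        _, truth = cq.simulate_counts(model2k, designs, seed=6)
        assert truth.patient_effects.shape[1] == 1  # one effect vector per patient

    def test_gc_bias_injection_recoverable(self, small_study):
        """Spearman(GC, log mean count) exceeds 0.3 at a 2-fold GC bias."""
        counts = small_study.counts.counts
        gc = small_study.catalog["gc_fraction"]
        mean = counts.mean(axis=1)
        pos = mean > 0
        rho = stats.spearmanr(gc[pos], np.log(mean[pos])).statistic
        assert rho > 0.3

    def test_sex_confound_on_y_genes(self, small_study):
        """Y genes are near-silent in grade-IV (female) libraries."""
        counts = small_study.counts.counts
        samples = small_study.counts.samples
        y_genes = small_study.catalog.index[small_study.catalog["chromosome"] == "Y"]
        female = samples.index[samples["sex"] == "F"]
        male = samples.index[samples["sex"] == "M"]
        assert counts.loc[y_genes, female].to_numpy().mean() < (
            0.1 * counts.loc[y_genes, male].to_numpy().mean()
        )


class TestExternalRanking:
    def test_power_at_full_scale(self, small_study):
        table = small_study.external_de
        truth = small_study.truth
        eff = truth.grade_effects[truth.grade_effects != 0]
        sub = table.loc[eff.index]
        hit = (sub["p_raw"] < 0.05) & (np.sign(sub["log2fc"]) == np.sign(eff))
        assert hit.mean() >= 0.95

    def test_null_pvalues_uniform(self, model2k, catalog2k):
        designs = [_design("A", "P1", TCR_MIXING), _design("B", "P2", TCR_MIXING)]
        _, truth = cq.simulate_counts(model2k, designs, seed=3)  # no grade effects
        table = cq.simulate_external_ranking(model2k, truth, n_per_group=50, seed=3)
        assert stats.kstest(table["p_raw"], "uniform").pvalue > 0.01

    def test_deterministic(self, model2k, small_study):
        t1 = cq.simulate_external_ranking(model2k, small_study.truth, seed=8)
        t2 = cq.simulate_external_ranking(model2k, small_study.truth, seed=8)
        pd.testing.assert_frame_equal(t1, t2)


class TestRegionZMatrix:
    def test_rows_standardized(self, model2k):
        z = cq.make_region_zmatrix(model2k, noise_sd=0.3, seed=2)
        vals = z.to_numpy()
        nonconstant = vals.std(axis=0) > 0
        assert np.abs(vals.mean(axis=0)[nonconstant]).max() < 1e-9
        assert np.abs(vals.std(axis=0)[nonconstant] - 1).max() < 1e-9

    def test_constant_gene_zero_row(self, catalog2k):
        model = cq.make_region_model(catalog2k, effect_log2=0.0, seed=1)
        z = cq.make_region_zmatrix(model, noise_sd=0.0, seed=0)
        assert (z.to_numpy() == 0).all()

    def test_peripheral_symmetry_without_noise(self, model2k):
        z = cq.make_region_zmatrix(model2k, noise_sd=0.0, seed=0)
        g = model2k.peripheral_genes[0]
        assert z.loc["LE", g] == pytest.approx(z.loc["IT", g], abs=1e-12)
        assert z.loc["LE", g] > 0

    def test_single_region_error(self, model2k):
        clipped = dataclasses.replace(model2k, mu=model2k.mu.iloc[:1])
        with pytest.raises(cq.ValidationError):
            cq.make_region_zmatrix(clipped, seed=0)
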