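"""Generator contracts: determinism, planted structure, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from depscreen.synthetic import (
    ConfigurationError,
    SyntheticConfig,
    build_truth,
    generate_drug_response,
    generate_gene_effects,
    generate_omics_features,
    generate_reagent_lfc,
    generate_related_priors,
)


def tiny_config(**kw):
    base = dict(
        n_cell_lines=40,
        n_genes=60,
        mechanism_counts={},
        n_modules=0,
        module_size=0,
        n_drugs=4,
        reagents_per_gene={"A": 2, "B": 2},
        seed=7,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            tiny_config(fractions={"pan": 0.5, "non_dependent": 0.4})

    def test_negative_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(
                fractions={
                    "pan": -0.1,
                    "strongly_selective": 0.3,
                    "high_variance": 0.2,
                    "weakly_selective": 0.1,
                    "non_dependent": 0.5,
                }
            )

    def test_archetype_proportions_match_config(self):
        cfg = tiny_config(n_genes=100)
        truth = build_truth(cfg)
        counts = pd.Series(truth.archetype).value_counts()
        for arch, frac in cfg.fractions.items():
            assert abs(counts.get(arch, 0) - frac * 100) <= 1


class TestGeneEffects:
    def test_zero_noise_pan_is_exact(self):
        cfg = tiny_config(noise_sd=0.0)
        eff, truth = generate_gene_effects(cfg, "A")
        pan = truth.genes_of("pan")
        assert (eff[pan] == cfg.pan_effect_mean).all().all()

    def test_seed_reproducibility_bitwise(self):
        cfg = tiny_config()
        a1, _ = generate_gene_effects(cfg, "A")
        a2, _ = generate_gene_effects(cfg, "A")
        pd.testing.assert_frame_equal(a1, a2)

    def test_modalities_differ_but_share_structure(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        a, _ = generate_gene_effects(cfg, "A", truth=truth)
        b, _ = generate_gene_effects(cfg, "B", truth=truth)
        pan = truth.genes_of("pan")
        # attenuation: shrunken mean, inflated variance for pan genes
        assert b[pan].to_numpy().mean() > a[pan].to_numpy().mean()
        assert b[pan].to_numpy().std() > a[pan].to_numpy().std()

    def test_pan_mean_within_sampling_error(self):
        cfg = SyntheticConfig(n_cell_lines=400, n_genes=1000, seed=5)
        eff, truth = generate_gene_effects(cfg, "A")
        vals = eff[truth.genes_of("pan")].to_numpy().ravel()
        se = cfg.noise_sd / np.sqrt(vals.size)
        assert abs(vals.mean() - cfg.pan_effect_mean) < 3 * se

    def test_adding_genes_keeps_existing_columns(self):
        small, _ = generate_gene_effects(tiny_config(n_genes=60), "A")
        big, _ = generate_gene_effects(tiny_config(n_genes=80), "A")
        pd.testing.assert_frame_equal(big[small.columns], small)

    def test_missing_masks_identical_across_modalities(self):
        cfg = tiny_config(missing_rate=0.1)
        truth = build_truth(cfg)
        a, _ = generate_gene_effects(cfg, "A", truth=truth)
        b, _ = generate_gene_effects(cfg, "B", truth=truth)
        pd.testing.assert_frame_equal(a.isna(), b.isna())


class TestReagents:
    def test_noiseless_reagents_identical_up_to_bias(self):
        cfg = tiny_config()
        eff, truth = generate_gene_effects(cfg, "A")
        lfc, rmap = generate_reagent_lfc(eff, 2, reagent_noise_sd=0.0, offtarget_rate=0.0)
        gene = truth.genes_of("strongly_selective")[0]
        reagents = rmap.index[rmap == gene]
        r = np.corrcoef(lfc[reagents[0]], lfc[reagents[1]])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_full_offtarget_rate_destroys_concordance(self):
        cfg = SyntheticConfig(
            n_cell_lines=400, n_genes=100, mechanism_counts={}, n_modules=0,
            module_size=0, seed=2,
        )
        eff, _ = generate_gene_effects(cfg, "A")
        lfc, rmap = generate_reagent_lfc(eff, 2, reagent_noise_sd=0.1, offtarget_rate=1.0, seed=4)
        rs = []
        for gene, grp in rmap.groupby(rmap).groups.items():
            rs.append(np.corrcoef(lfc[grp[0]], lfc[grp[1]])[0, 1])
        assert abs(np.median(rs)) < 0.2

    def test_reagent_determinism_and_map(self):
        cfg = tiny_config()
        eff, _ = generate_gene_effects(cfg, "A")
        l1, m1 = generate_reagent_lfc(eff, 2, seed=9)
        l2, m2 = generate_reagent_lfc(eff, 2, seed=9)
        pd.testing.assert_frame_equal(l1, l2)
        assert (m1 == m2).all()
        assert set(m1) == set(eff.columns)

    def test_bad_offtarget_rate_rejected(self):
        eff, _ = generate_gene_effects(tiny_config(), "A")
        with pytest.raises(ConfigurationError):
            generate_reagent_lfc(eff, 2, offtarget_rate=1.5)


@pytest.fixture(scope="module")
def coupled():
    cfg = SyntheticConfig(
        n_cell_lines=400, n_genes=120,
        fractions={"pan": 0.05, "strongly_selective": 0.30, "high_variance": 0.25,
                   "weakly_selective": 0.05, "non_dependent": 0.35},
        mechanism_counts={"genetic_driver": 3, "expression_addiction": 3,
                          "paralog": 3, "cyclops": 3},
        n_modules=0, module_size=0, seed=13,
    )
    eff, truth = generate_gene_effects(cfg, "A")
    return eff, truth, generate_omics_features(truth, eff, seed=13)


class TestOmics:
    def test_cyclops_copy_number_positively_correlated(self, coupled):
        eff, truth, fm = coupled
        for g in truth.genes_with_mechanism("cyclops"):
            r = pearsonr(eff[g], fm.values[f"{g}_cn"]).statistic
            assert r > 0.5

    def test_driver_mutation_negative_point_biserial(self, coupled):
        eff, truth, fm = coupled
        for g in truth.genes_with_mechanism("genetic_driver"):
            r = pearsonr(eff[g], fm.values[f"{g}_mut"]).statistic
            assert r < -0.5

    def test_expression_addiction_negative_correlation(self, coupled):
        eff, truth, fm = coupled
        for g in truth.genes_with_mechanism("expression_addiction"):
            assert pearsonr(eff[g], fm.values[f"{g}_expr"]).statistic < -0.5

    def test_uncoupled_gene_features_near_null(self, coupled):
        eff, truth, fm = coupled
        rs = [
            abs(pearsonr(eff[g], fm.values[f"{g}_expr"]).statistic)
            for g in truth.genes_of("strongly_selective")
            if truth.mechanism[g] == "none"
        ]
        # null |r| at n=400 is below 0.2 with overwhelming probability
        assert np.mean(np.array(rs) < 0.2) > 0.9

    def test_non_expressed_genes_form_low_mode(self, coupled):
        _, truth, fm = coupled
        silent = truth.non_expressed
        expressed = [g for g in truth.archetype if g not in set(silent)]
        lo = np.nanmax(fm.values[[f"{g}_expr" for g in silent]].to_numpy())
        hi = np.nanmin(
            fm.values[[f"{g}_expr" for g in expressed[:20]]].to_numpy().mean(axis=0)
        )
        assert lo < 1.0 < hi

    def test_missing_mechanism_annotation_rejected(self, coupled):
        eff, truth, _ = coupled
        bad = dict(truth.mechanism)
        bad.pop(eff.columns[0])
        broken = type(truth)(
            archetype=truth.archetype, mechanism=bad,
            dependent_lines=truth.dependent_lines,
            paralog_partner=truth.paralog_partner,
            non_expressed=truth.non_expressed,
        )
        with pytest.raises(ConfigurationError):
            generate_omics_features(broken, eff)


class TestDrugs:
    def test_zero_noise_middle_dose_perfect_correlation(self):
        cfg = tiny_config()
        eff, truth = generate_gene_effects(cfg, "A")
        tensor = generate_drug_response(
            truth, eff, n_doses=8, n_drugs=3, confound_weight=0.0, drug_noise_sd=1e-12
        )
        mid = len(tensor.doses) // 2
        for i, drug in enumerate(tensor.drugs):
            tgt = tensor.targets[drug][0]
            r = pearsonr(tensor.values[i, mid], eff[tgt]).statistic
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_lowest_dose_is_pure_noise(self):
        cfg = SyntheticConfig(n_cell_lines=300, n_genes=80, mechanism_counts={},
                              n_modules=0, module_size=0, seed=3)
        eff, truth = generate_gene_effects(cfg, "A")
        tensor = generate_drug_response(truth, eff, n_doses=8, n_drugs=20,
                                        confound_weight=0.0, seed=3)
        rs = [
            abs(pearsonr(tensor.values[i, 0], eff[tensor.targets[d][0]]).statistic)
            for i, d in enumerate(tensor.drugs)
        ]
        assert np.median(rs) < 0.15

    def test_dose_count_validated(self):
        cfg = tiny_config()
        eff, truth = generate_gene_effects(cfg, "A")
        with pytest.raises(ConfigurationError):
            generate_drug_response(truth, eff, n_doses=2)


class TestPriors:
    def test_pairs_when_module_size_two(self):
        cfg = tiny_config(
            n_genes=100,
            fractions={"pan": 0.1, "strongly_selective": 0.1, "high_variance": 0.3,
                       "weakly_selective": 0.1, "non_dependent": 0.4},
            n_modules=5, module_size=2,
        )
        truth = build_truth(cfg)
        priors = generate_related_priors(truth, n_modules=5, module_size=2)
        module_genes = set().union(*truth.modules)
        for g in module_genes:
            assert len(priors[g]) == 1

    def test_disjoint_modules_give_disjoint_relations(self, small_bundle):
        mods = small_bundle.truth.modules
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                assert not (a & b)

    def test_module_request_beyond_planted_rejected(self, small_bundle):
        with pytest.raises(ConfigurationError):
            generate_related_priors(small_bundle.truth, n_modules=99)

    def test_planted_module_correlation_exceeds_background(self, small_bundle):
        eff = small_bundle.gene_effects["A"]
        mod = sorted(small_bundle.truth.modules[0])
        corr = eff.corr()
        within = corr.loc[mod, mod].to_numpy()[np.triu_indices(len(mod), 1)]
        background = corr.loc[mod, small_bundle.truth.genes_of("non_dependent")].to_numpy()
        assert np.abs(within).mean() > np.abs(background).mean() + 0.2
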