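"""Family energy model: encoding, fitting, gauge, CV, LOHO, rescaling and
prediction for unseen homologues."""

from __future__ import annotations

import numpy as np
import pytest

import domstab as ds
from domstab.datatypes import AA_INDEX
from domstab.energy import (
    N_AA,
    FamilyEnergyRegressor,
    alignment_distances,
    encode_family,
    loho,
    predict_new_homologue,
    rescale_energies,
)
from tests.conftest import observed_feature_mask


def tiny_alignment():
    return ds.FamilyAlignment(
        family_id="F", columns=4,
        rows={"A": "ACDE", "B": "ACDE", "C": "GCDE"},
    )


def tiny_variant(domain, pos, wt, mut, fitness=0.2):
    return ds.VariantFitness(
        domain_id=domain, position=pos, wt_aa=wt, mut_aa=mut,
        growth_rates=np.array([fitness] * 3), counts=np.array([50] * 3),
        fitness=fitness, sigma=0.01,
    )


class TestEncoding:
    def test_identical_rows_identical_baselines(self):
        aln = tiny_alignment()
        enc = encode_family(aln, [tiny_variant("A", 1, "A", "V"),
                                  tiny_variant("B", 1, "A", "V")])
        iA, iB = enc.hom_ids.index("A"), enc.hom_ids.index("B")
        np.testing.assert_array_equal(enc.comp[iA], enc.comp[iB])

    def test_shared_mutation_feature_across_homologues(self):
        """The same (column, mutant) in homologues with different wild
        types activates the same shared energy feature."""
        aln = tiny_alignment()
        enc = encode_family(aln, [tiny_variant("A", 1, "A", "V"),
                                  tiny_variant("C", 1, "G", "V")])
        assert enc.mut_feat[0] == enc.mut_feat[1] == AA_INDEX["V"]

    def test_synonymous_has_no_mutation_feature(self):
        enc = encode_family(tiny_alignment(),
                            [tiny_variant("A", 1, "A", "A")])
        assert enc.mut_feat[0] == -1

    def test_gap_column_is_hard_error(self):
        aln = ds.FamilyAlignment(family_id="F", columns=4,
                                 rows={"A": "A-DE", "B": "ACDE"})
        with pytest.raises(ValueError, match="gapped"):
            encode_family(aln, [tiny_variant("A", 4, "E", "V")])

    def test_alignment_level_wt_match_warns(self):
        aln = tiny_alignment()
        with pytest.warns(UserWarning, match="synonymous"):
            enc = encode_family(aln, [tiny_variant("C", 1, "G", "A")
                                      if False else
                                      ds.VariantFitness(
                                          domain_id="C", position=1,
                                          wt_aa="G", mut_aa="G",
                                          growth_rates=np.array([0.2] * 3),
                                          counts=np.array([50] * 3),
                                          fitness=0.2, sigma=0.01,
                                          variant_class="missense",
                                      )])
        assert enc.mut_feat[0] == -1

    def test_nonsense_excluded_and_count_filter(self, family):
        enc_all = encode_family(family.alignment, family.variants)
        n_stop = sum(v.variant_class == "nonsense" for v in family.variants)
        assert n_stop > 0
        assert enc_all.n_variants == len(family.variants) - n_stop
        enc_filtered = encode_family(family.alignment, family.variants,
                                     min_mean_count=1e9)
        assert enc_filtered.n_variants == 0


class TestFitting:
    def test_noise_free_exact_recovery(self):
        """Noise-free data, uniform errors, no ridge: training r >= 0.999
        and planted-vs-fitted shared energies correlate >= 0.99."""
        cfg = ds.SimulationConfig(noise_sigma=0.0)
        fam = ds.simulate_family(8, 25, cfg, seed=5)
        enc = encode_family(fam.alignment, fam.variants,
                            error_moderation_df=None)
        enc.sigma[:] = 1.0
        model = FamilyEnergyRegressor(lambda_reg=0.0, random_state=1,
                                      max_iter=100000).fit(enc)
        pred = model.predict(enc)
        assert np.corrcoef(pred, enc.fitness)[0, 1] >= 0.999
        obs = observed_feature_mask(enc)
        r = np.corrcoef(model.D_.reshape(-1)[obs],
                        fam.truth.D_true.reshape(-1)[obs])[0, 1]
        assert r >= 0.99

    def test_default_parameter_recovery(self, family, encoding,
                                        fitted_model):
        """At default noise the shared mutation energies correlate >= 0.95
        with truth and per-homologue baselines >= 0.9."""
        obs = observed_feature_mask(encoding)
        D_r = np.corrcoef(
            fitted_model.D_.reshape(-1)[obs],
            family.truth.D_true.reshape(-1)[obs],
        )[0, 1]
        assert D_r >= 0.95
        baselines = fitted_model.b0_ + \
            encoding.comp @ fitted_model.U_.reshape(-1)
        truth = np.array([family.truth.dG_wt[d] for d in encoding.hom_ids])
        assert np.corrcoef(baselines, truth)[0, 1] >= 0.9

    def test_single_homologue_dose_response(self):
        """With one mutagenized homologue each mutation feature has a
        single observation, so the model reduces to a per-variant
        dose-response and interpolates the data within the output range."""
        cfg = ds.SimulationConfig(noise_sigma=0.0)
        fam = ds.simulate_family(2, 10, cfg, seed=6)
        first = next(iter(fam.domains))
        variants = [v for v in fam.variants if v.domain_id == first]
        enc = encode_family(fam.alignment, variants,
                            error_moderation_df=None)
        enc.sigma[:] = 1.0
        model = FamilyEnergyRegressor(lambda_reg=0.0, random_state=1,
                                      max_iter=300000, tol=1e-16).fit(enc)
        pred = model.predict(enc)
        lo = model.gamma0_
        hi = model.gamma0_ + model.gamma1_
        inside = (enc.fitness > lo + 1e-2) & (enc.fitness < hi - 1e-2)
        assert inside.sum() > 20
        np.testing.assert_allclose(pred[inside], enc.fitness[inside],
                                   atol=1e-4)

    def test_uniform_sigma_scaling_invariance(self, small_family):
        """Doubling every measurement error rescales the loss but not the
        optimum."""
        enc = encode_family(small_family.alignment, small_family.variants)
        m1 = FamilyEnergyRegressor(random_state=1, lambda_reg=0.0,
                                   tol=1e-12).fit(enc)
        enc2 = enc.subset(np.ones(enc.n_variants, dtype=bool))
        enc2.sigma = enc.sigma * 2.0
        m2 = FamilyEnergyRegressor(random_state=1, lambda_reg=0.0,
                                   tol=1e-12).fit(enc2)
        assert np.corrcoef(m1.predict(enc), m2.predict(enc))[0, 1] > 0.999

    def test_gauge_invariance(self, encoding, fitted_model):
        """Adding a constant to a U column and subtracting it from b0
        leaves every prediction unchanged."""
        import copy

        shifted = copy.deepcopy(fitted_model)
        shifted.U_[3, :] += 1.7
        shifted.b0_ -= 1.7
        np.testing.assert_allclose(
            fitted_model.predict(encoding), shifted.predict(encoding),
            rtol=0, atol=1e-10,
        )

    def test_gauge_fixing_centres_observed_residues(self, encoding,
                                                    fitted_model):
        observed = encoding.comp.reshape(encoding.n_homologues,
                                         encoding.n_columns, N_AA)
        for c in range(encoding.n_columns):
            present = observed[:, c, :].sum(axis=0) > 0
            if observed[:, c, :].sum() == encoding.n_homologues:
                assert fitted_model.U_[c, present].mean() == \
                    pytest.approx(0.0, abs=1e-9)

    def test_predictions_bounded(self, encoding, fitted_model):
        pred = fitted_model.predict(encoding)
        assert pred.min() >= fitted_model.gamma0_
        assert pred.max() <= fitted_model.gamma0_ + fitted_model.gamma1_

    def test_linear_limit_matches_lsq_oracle(self):
        """Near the transition midpoint p_f ~ 1/2 - dG/4 and the Boltzmann
        fit agrees with an independent weighted linear least squares."""
        cfg = ds.SimulationConfig(
            dG_wt_mean=0.0, u_scale=0.015, core_ddg_mean=0.08,
            core_ddg_sd=0.03, surface_ddg_mean=0.03, surface_ddg_sd=0.02,
            noise_sigma=0.0, wt_dG_halfwidth=None, include_nonsense=False,
        )
        fam = ds.simulate_family(5, 10, cfg, seed=7)
        enc = encode_family(fam.alignment, fam.variants,
                            error_moderation_df=None)
        enc.sigma[:] = 1.0
        model = FamilyEnergyRegressor(lambda_reg=1e-8, random_state=1,
                                      max_iter=300000, tol=1e-16).fit(enc)
        # independent oracle: explicit design matrix (separate blocks for
        # composition and mutation energies), numpy lstsq
        n = enc.n_variants
        nf = enc.n_columns * N_AA
        X = np.zeros((n, 2 * nf + 1))
        X[:, 0] = 1.0
        for i in range(n):
            X[i, 1:1 + nf] = enc.comp[enc.hom_idx[i]]
            if enc.mut_feat[i] >= 0:
                X[i, 1 + nf + enc.mut_feat[i]] = 1.0
        coef, *_ = np.linalg.lstsq(X, enc.fitness, rcond=None)
        oracle = X @ coef
        assert np.corrcoef(model.predict(enc), oracle)[0, 1] > 0.999

    def test_linear_transform_energies_correlate(self):
        """The discarded linear-output variant infers energies that track
        the Boltzmann model on the same family."""
        cfg = ds.SimulationConfig(noise_sigma=0.02)
        fam = ds.simulate_family(6, 15, cfg, seed=8)
        enc = encode_family(fam.alignment, fam.variants)
        mb = FamilyEnergyRegressor(random_state=1).fit(enc)
        ml = FamilyEnergyRegressor(random_state=1,
                                   transform="linear").fit(enc)
        obs = observed_feature_mask(enc)
        r = np.corrcoef(mb.D_.reshape(-1)[obs],
                        ml.D_.reshape(-1)[obs])[0, 1]
        assert r > 0.9


class TestCrossValidation:
    def test_fold_assignment_deterministic(self, encoding):
        rng_folds = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            rng_folds.append(rng.permutation(encoding.n_variants) % 10)
        np.testing.assert_array_equal(*rng_folds)

    def test_folds_partition_variants(self, encoding):
        rng = np.random.default_rng(3)
        folds = rng.permutation(encoding.n_variants) % 10
        assert set(folds) == set(range(10))
        assert len(folds) == encoding.n_variants


class TestLoho:
    def test_identical_homologue_distance_zero(self):
        aln = ds.FamilyAlignment(family_id="F", columns=4,
                                 rows={"A": "ACDE", "B": "ACDE"})
        ham, blo = alignment_distances(aln, "A", ["B"])
        assert ham == 0.0
        assert blo == 0.0

    def test_blosum_distance_positive_for_mismatch(self):
        aln = ds.FamilyAlignment(family_id="F", columns=4,
                                 rows={"A": "ACDE", "B": "GCDE"})
        ham, blo = alignment_distances(aln, "A", ["B"])
        assert ham == 1.0
        assert blo > 0.0

    def test_duplicate_homologue_matches_training_r(self, family):
        """Leaving out an exact duplicate of a training homologue scores
        within 0.02 of the full model's training r on that homologue."""
        first = next(iter(family.domains))
        dup_variants = list(family.variants)
        rows = dict(family.alignment.rows)
        rows["DUP"] = rows[first]
        for v in family.variants:
            if v.domain_id == first:
                dup_variants.append(
                    ds.VariantFitness(
                        domain_id="DUP", position=v.position, wt_aa=v.wt_aa,
                        mut_aa=v.mut_aa, growth_rates=v.growth_rates,
                        counts=v.counts, fitness=v.fitness, sigma=v.sigma,
                        variant_class=v.variant_class,
                    )
                )
        aln = ds.FamilyAlignment(family_id=family.alignment.family_id,
                                 columns=family.alignment.columns,
                                 rows=rows)
        enc = encode_family(aln, dup_variants)
        dup_idx = enc.hom_ids.index("DUP")
        test = enc.hom_idx == dup_idx
        model = FamilyEnergyRegressor(random_state=1).fit(enc.subset(~test))
        pred = model.predict(enc.subset(test))
        r_heldout = np.corrcoef(enc.fitness[test], pred)[0, 1]
        # training r of the same model on the original copy
        orig_idx = enc.hom_ids.index(first)
        train_mask = enc.hom_idx == orig_idx
        r_train = np.corrcoef(
            enc.fitness[train_mask],
            model.predict(enc.subset(train_mask)),
        )[0, 1]
        assert r_heldout == pytest.approx(r_train, abs=0.02)

    def test_minimum_homologues_enforced(self, small_family):
        enc = encode_family(small_family.alignment, small_family.variants)
        with pytest.raises(ValueError, match=">= 10"):
            loho(enc, small_family.alignment)


class TestRescaling:
    def test_anchor_and_orientation(self, encoding, fitted_model):
        """The 2.5th percentile of the fitness-oriented energies maps to
        magnitude 1 and destabilizing mutations get positive scaled ddG."""
        table, meta = rescale_energies(fitted_model, encoding)
        oriented = -table["ddG"].to_numpy()
        scale = abs(np.percentile(oriented, 2.5))
        assert meta["scale_constant"] == pytest.approx(scale)
        assert np.percentile(-table["scaled_ddG"], 2.5) == \
            pytest.approx(-1.0)
        # destabilizing (ddG > 0) maps to positive scaled values
        assert (np.sign(table["scaled_ddG"]) ==
                np.sign(table["ddG"])).all()

    def test_scaling_is_monotone(self, encoding, fitted_model):
        table, _ = rescale_energies(fitted_model, encoding)
        order_raw = np.argsort(table["ddG"].to_numpy())
        order_scaled = np.argsort(table["scaled_ddG"].to_numpy())
        np.testing.assert_array_equal(order_raw, order_scaled)

    def test_degenerate_distribution_errors(self, fitted_model):
        import copy

        degenerate = copy.deepcopy(fitted_model)
        degenerate.D_ = np.zeros_like(degenerate.D_)
        with pytest.raises(ValueError, match="degenerate"):
            rescale_energies(degenerate)


class TestPredictNewHomologue:
    def test_training_homologue_reproduced_exactly(self, family, encoding,
                                                   fitted_model):
        first = encoding.hom_ids[0]
        row = family.alignment.rows[first]
        mask = encoding.hom_idx == 0
        # mutation list built directly from the encoding subset
        muts = []
        for i in np.where(mask)[0]:
            if encoding.mut_feat[i] >= 0:
                muts.append((int(encoding.columns[i]),
                             encoding.keys[i][3]))
        table = predict_new_homologue(fitted_model, row, muts)
        sub = encoding.subset(mask)
        keep = sub.mut_feat >= 0
        np.testing.assert_allclose(
            table["predicted_fitness"].to_numpy(),
            fitted_model.predict(sub)[keep], rtol=0, atol=1e-10,
        )

    def test_wild_type_variant_is_zero_and_never_called(self, family,
                                                        fitted_model):
        first = next(iter(family.domains))
        row = family.alignment.rows[first]
        table = predict_new_homologue(fitted_model, row,
                                      [(1, row[0]), (2, "W")])
        wt_row = table.iloc[0]
        assert wt_row["scaled_ddG"] == 0.0
        assert not wt_row["destabilizing"]

    def test_held_out_homologue_fraction_folded(self, family, encoding):
        """Predictions for a homologue excluded from training track its
        true fraction folded (r >= 0.9)."""
        held = 0
        test = encoding.hom_idx == held
        model = FamilyEnergyRegressor(random_state=1).fit(
            encoding.subset(~test))
        domain_id = encoding.hom_ids[held]
        row = family.alignment.rows[domain_id]
        muts, truth_pf = [], []
        for i in np.where(test)[0]:
            if encoding.mut_feat[i] < 0:
                continue
            key = encoding.keys[i]
            muts.append((int(encoding.columns[i]), key[3]))
            truth_pf.append(
                ds.fraction_folded(family.truth.dG_variant[key]))
        table = predict_new_homologue(model, row, muts)
        pf_pred = (table["predicted_fitness"] - model.gamma0_) / \
            model.gamma1_
        assert np.corrcoef(pf_pred, truth_pf)[0, 1] >= 0.9

    def test_row_length_validated(self, fitted_model):
        with pytest.raises(ValueError, match="length"):
            predict_new_homologue(fitted_model, "ACD", [(1, "V")])
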