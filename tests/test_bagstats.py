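"""BAG computation, demographic tests, Williams's test, linear models,
group contrasts, biomarker associations, positivity and the composite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brainage import bagstats as bs
from brainage.synthetic_cohort import BiomarkerPanel, generate_cohort_full
from conftest import tiny_spec


# -- BAG --------------------------------------------------------------------

def _pred_frame(ids, ages, preds, tag="S"):
    return pd.DataFrame({"id": ids, "model_tag": tag, "age": ages,
                         "pred_age": preds})


class TestComputeBag:
    def test_definition_predicted_minus_chronological(self):
        out = bs.compute_bag(_pred_frame(["a"], [70.0], [75.0]))
        assert out["bag"].iloc[0] == pytest.approx(5.0)

    def test_perfect_predictions_give_zero_bags(self):
        out = bs.compute_bag(_pred_frame(list("abc"), [50, 60, 70], [50, 60, 70]))
        assert np.allclose(out["bag"], 0) and np.allclose(out["residual_bag"], 0)

    def test_residualization_matches_hand_ols(self):
        # ages (60,70,80), bags (1,2,6): slope 0.25, intercept -14.5
        out = bs.compute_bag(_pred_frame(list("abc"), [60, 70, 80],
                                         [61, 72, 86]))
        np.testing.assert_allclose(out["residual_bag"], [0.5, -1.0, 0.5],
                                   atol=1e-12)

    def test_residual_bag_uncorrelated_with_age(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(50, 90, 200)
        preds = ages + 0.3 * (ages - 70) + rng.normal(0, 3, 200)
        out = bs.compute_bag(_pred_frame([f"p{i}" for i in range(200)],
                                         ages, preds))
        assert abs(np.corrcoef(out["age"], out["residual_bag"])[0, 1]) < 1e-10

    def test_reference_sample_defines_the_line(self):
        ids = [f"p{i}" for i in range(6)]
        out = bs.compute_bag(
            _pred_frame(ids, [60, 65, 70, 75, 80, 85],
                        [62, 66, 73, 74, 83, 84]),
            reference_ids=ids[:4])
        ref = out[out["id"].isin(ids[:4])]
        assert abs(np.corrcoef(ref["age"], ref["residual_bag"])[0, 1]) < 1e-10

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            bs.compute_bag(pd.DataFrame({"id": ["a"], "age": [70.0]}))


# -- demographic statistics -------------------------------------------------

class TestWelchFromSummary:
    @pytest.mark.parametrize("g1,g2,expected", [
        ((72.56, 7.15, 154), (66.93, 8.53, 144), 6.15),   # age, CN/A+ vs CN/A-
        ((75.67, 6.86, 154), (66.93, 8.53, 144), 9.71),   # age, CI vs CN/A-
        ((15.05, 2.97, 154), (15.71, 2.65, 144), -2.03),  # education, CI
    ])
    def test_published_group_summaries(self, g1, g2, expected):
        t, df, p = bs.welch_t_from_summary(*g1, *g2)
        assert t == pytest.approx(expected, abs=0.01)
        assert p < 0.05

    def test_identical_summaries_give_zero(self):
        t, df, p = bs.welch_t_from_summary(10, 2, 50, 10, 2, 50)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, *_ = bs.welch_t_from_summary(12, 2, 40, 10, 3, 50)
        t2, *_ = bs.welch_t_from_summary(10, 3, 50, 12, 2, 40)
        assert t1 == pytest.approx(-t2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bs.welch_t_from_summary(1, 1, 1, 2, 1, 50)
        with pytest.raises(ValueError):
            bs.welch_t_from_summary(1, 0, 50, 2, 0, 50)


class TestChi2Yates:
    @pytest.mark.parametrize("table,expected", [
        ([[115, 29], [71, 83]], 34.73),   # APOE, CN/A+ vs CN/A-
        ([[115, 29], [55, 98]], 56.67),   # APOE, CI vs CN/A-
        ([[89, 55], [68, 86]], 8.60),     # sex, CI vs CN/A-
    ])
    def test_published_contingency_tables(self, table, expected):
        chi2, df, p = bs.chi2_yates(table)
        assert chi2 == pytest.approx(expected, abs=0.01)
        assert df == 1

    def test_proportional_table_gives_exact_zero(self):
        chi2, _, p = bs.chi2_yates([[50, 50], [50, 50]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            bs.chi2_yates([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            bs.chi2_yates([[-1, 2], [3, 4]])


class TestWilliams:
    def test_equal_correlations_give_zero(self):
        t, df, p = bs.williams_t(0.5, 0.5, 0.3, 100)
        assert t == 0.0 and df == 97 and p == pytest.approx(1.0)

    def test_swapping_flips_sign(self):
        t1, *_ = bs.williams_t(0.6, 0.4, 0.3, 80)
        t2, *_ = bs.williams_t(0.4, 0.6, 0.3, 80)
        assert t1 == pytest.approx(-t2)

    def test_high_precision_reference_value(self):
        # independent evaluation of the statistic at r12=.9, r13=.825,
        # r23=.6, n=487 gives 5.829896 (30-digit arithmetic)
        t, df, p = bs.williams_t(0.9, 0.825, 0.6, 487)
        assert t == pytest.approx(5.829896, abs=1e-5)
        assert df == 484

    def test_invalid_triples_rejected(self):
        with pytest.raises(ValueError):
            bs.williams_t(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValueError):
            bs.williams_t(0.5, 0.4, 0.3, 3)
        with pytest.raises(ValueError, match="positive semidefinite"):
            bs.williams_t(0.9, -0.9, 0.9, 50)

    def test_type_one_error_calibrated_under_null(self):
        """r12 = r13 in the population: rejection rate ~ alpha."""
        rng = np.random.default_rng(0)
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.3], [0.5, 0.3, 1.0]])
        chol = np.linalg.cholesky(cov)
        n, reps, hits = 50, 2000, 0
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ chol.T
            r = np.corrcoef(x, rowvar=False)
            _, _, p = bs.williams_t(r[0, 1], r[0, 2], r[1, 2], n)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.02


# -- effect sizes and FDR ---------------------------------------------------

class TestEffectSizes:
    @pytest.mark.parametrize("beta,se,df,expected", [
        (2.169, 0.997, 348, 0.013),   # impairment term, FC model
        (5.105, 1.287, 349, 0.043),   # impairment term, structural model
    ])
    def test_partial_eta_sq_consistent_with_published_terms(self, beta, se,
                                                            df, expected):
        t = beta / se
        assert bs.partial_eta_sq_from_t(t, df) == pytest.approx(expected,
                                                                abs=5e-4)

    def test_eta_identity_matches_ss_decomposition(self, rng):
        """t²/(t²+df) equals SS_effect/(SS_effect+SS_resid) for 1-df terms."""
        import statsmodels.formula.api as smf
        for _ in range(5):
            n = 60
            d = pd.DataFrame({"x": rng.normal(size=n),
                              "z": rng.normal(size=n)})
            d["y"] = 0.4 * d["x"] + 0.2 * d["z"] + rng.normal(size=n)
            full = smf.ols("y ~ x + z", data=d).fit()
            reduced = smf.ols("y ~ z", data=d).fit()
            ss_effect = reduced.ssr - full.ssr
            eta_ss = ss_effect / (ss_effect + full.ssr)
            eta_t = bs.partial_eta_sq_from_t(float(full.tvalues["x"]),
                                             int(full.df_resid))
            assert eta_t == pytest.approx(eta_ss, abs=1e-10)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(bs.bh_fdr([0.01, 0.02, 0.9]),
                                   [0.03, 0.03, 0.9])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_bh_adjusted_monotone_and_capped(self, ps):
        adj = bs.bh_fdr(ps)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


# -- linear BAG models ------------------------------------------------------

def _null_participants(rng, n=120):
    idx = pd.Index([f"p{i}" for i in range(n)], name="id")
    return pd.DataFrame({
        "age": rng.uniform(55, 85, n),
        "sex": rng.choice(["female", "male"], n),
        "education": rng.uniform(10, 20, n),
        "cdr": rng.choice([0.0, 0.5], n),
        "amyloid_positive": rng.choice([True, False], n),
        "mean_fd": rng.uniform(0.05, 0.25, n),
        "group": rng.choice(["CN_Aneg", "CN_Apos", "CI"], n),
    }, index=idx)


class TestFitBagModel:
    def test_recovers_a_planted_cdr_effect(self, rng):
        part = _null_participants(rng, n=400)
        bags = _pred_frame(part.index, part["age"],
                           part["age"] + 4.0 * (part["cdr"] > 0)
                           + rng.normal(0, 2, 400))
        effects, n = bs.fit_bag_model(bs.compute_bag(bags), part, "S")
        terms = {e.term: e for e in effects}
        assert terms["cdr_pos"].beta == pytest.approx(4.0, abs=0.5)
        assert n == 400

    def test_fd_covariate_only_in_fc_models(self, rng):
        part = _null_participants(rng)
        bags = bs.compute_bag(_pred_frame(part.index, part["age"],
                                          part["age"] + rng.normal(0, 2, 120)))
        fc_terms = {e.term for e in bs.fit_bag_model(
            bags.assign(model_tag="FC"), part, "FC")[0]}
        s_terms = {e.term for e in bs.fit_bag_model(bags, part, "S")[0]}
        assert "mean_fd" in fc_terms and "mean_fd" not in s_terms

    def test_type_one_error_of_cdr_term_under_null(self):
        """No planted effect: the CDR-term test rejects at ~5%."""
        rng = np.random.default_rng(1)
        hits = 0
        reps = 200
        for _ in range(reps):
            part = _null_participants(rng, n=80)
            bags = bs.compute_bag(_pred_frame(
                part.index, part["age"], part["age"] + rng.normal(0, 3, 80)))
            effects, _ = bs.fit_bag_model(bags, part, "S")
            p = {e.term: e.p for e in effects}["cdr_pos"]
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.02


class TestGroupShiftModel:
    def test_recovers_planted_group_shifts(self, rng):
        part = _null_participants(rng, n=450)
        shift = part["group"].map({"CN_Aneg": 0.0, "CN_Apos": -2.0, "CI": 5.0})
        bags = bs.compute_bag(_pred_frame(
            part.index, part["age"], part["age"] + shift + rng.normal(0, 2, 450)))
        shifts = bs.fit_group_shift_model(bags, part, "S")
        assert shifts["CN_Apos"].beta == pytest.approx(-2.0, abs=0.7)
        assert shifts["CI"].beta == pytest.approx(5.0, abs=0.7)


# -- group contrasts --------------------------------------------------------

class TestGroupContrasts:
    def test_identical_groups_are_a_complete_null(self):
        vals = np.tile(np.arange(10.0), 3)
        groups = np.repeat(["CN_Aneg", "CN_Apos", "CI"], 10)
        res = bs.group_contrasts(vals, groups)
        assert res.omnibus_f == 0.0
        assert np.all(res.pairwise["p_fdr"] == 1.0)
        assert res.levene_stat == 0.0

    def test_planted_ci_shift_detected_reliably(self):
        """+5.1 y planted in CI: CI vs CN/A- significant in >=90% of seeds."""
        hits = 0
        seeds = 20
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            c = generate_cohort_full(tiny_spec(
                seed=seed, n_train=10, n_per_group=(150, 150, 150),
                n_roi=4, n_struct_thickness=4, n_struct_volume=2))
            an = c.frame[c.frame["role"] == "analysis"]
            # residual BAG surrogate: latent structural gap + estimation noise
            resid = c.latents.loc[an.index, "gap_s"] + rng.normal(0, 2, len(an))
            res = bs.group_contrasts(
                bs.residualize(resid, an["age"]), an["group"])
            row = res.pairwise.set_index("pair").loc["CN_Aneg vs CI"]
            hits += row["p_fdr"] < 0.01
        assert hits >= 0.9 * seeds

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bs.group_contrasts([1, 2, 3, 4], ["a", "a", "a", "b"])


# -- biomarker associations --------------------------------------------------

def _cohort_bags(cohort, noise_sd=1.5, seed=0):
    """BAG table from the latent structural gap plus estimation noise, i.e.
    the output of a near-ideal structural age model."""
    rng = np.random.default_rng(seed)
    an = cohort.frame[cohort.frame["role"] == "analysis"]
    preds = an["age"] + cohort.latents.loc[an.index, "gap_s"] \
        + rng.normal(0, noise_sd, len(an))
    return bs.compute_bag(_pred_frame(an.index, an["age"], preds))


class TestBiomarkerAssociation:
    def test_recovers_ci_tau_slope(self):
        hits = 0
        for seed in range(20):
            c = generate_cohort_full(tiny_spec(
                seed=seed, n_train=10, n_per_group=(120, 120, 120),
                n_roi=4, n_struct_thickness=4, n_struct_volume=2))
            an = c.frame[c.frame["role"] == "analysis"]
            eff = bs.biomarker_association(_cohort_bags(c, seed=seed), an,
                                           "tau_pet_suvr", "S")
            slope = eff["simple_slopes"]["CI"].beta
            hits += abs(slope - 0.02) < 0.01
        assert hits >= 0.8 * 20

    def test_cognition_slope_sign_recovered(self):
        negs = 0
        for seed in range(20):
            c = generate_cohort_full(tiny_spec(
                seed=seed, n_train=10, n_per_group=(120, 120, 120),
                n_roi=4, n_struct_thickness=4, n_struct_volume=2))
            an = c.frame[c.frame["role"] == "analysis"]
            eff = bs.biomarker_association(_cohort_bags(c, seed=seed), an,
                                           "cognition", "S")
            negs += eff["simple_slopes"]["CI"].beta < 0
        assert negs >= 0.95 * 20

    def test_amyloid_models_exclude_amyloid_negative_controls(self):
        c = generate_cohort_full(tiny_spec(seed=3, n_per_group=(60, 60, 60),
                                           n_roi=4, n_struct_thickness=4,
                                           n_struct_volume=2, n_train=10))
        an = c.frame[c.frame["role"] == "analysis"]
        eff = bs.biomarker_association(_cohort_bags(c), an,
                                       "amyloid_centiloid", "S")
        assert eff["reference_group"] == "CN_Apos"
        assert "CN_Aneg" not in eff["simple_slopes"]

    def test_null_outcome_is_not_systematically_significant(self):
        ps = []
        for seed in range(10):
            c = generate_cohort_full(tiny_spec(
                seed=seed + 50, n_train=10, n_per_group=(80, 80, 80),
                n_roi=4, n_struct_thickness=4, n_struct_volume=2))
            an = c.frame[c.frame["role"] == "analysis"].copy()
            rng = np.random.default_rng(10_000 + seed)   # independent stream
            an["cognition"] = rng.normal(size=len(an))   # decoupled outcome
            eff = bs.biomarker_association(_cohort_bags(c, seed=seed), an,
                                           "cognition", "S")
            ps.append(eff["main"].p)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.3

    def test_too_few_observations_rejected(self, rng):
        part = _null_participants(rng, n=30)
        part["cognition"] = np.nan
        bags = bs.compute_bag(_pred_frame(part.index, part["age"], part["age"]))
        with pytest.raises(ValueError, match="need >="):
            bs.biomarker_association(bags, part, "cognition", "S")


# -- positivity and composite ------------------------------------------------

class TestAmyloidPositivity:
    @pytest.mark.parametrize("panel,expected,src", [
        (BiomarkerPanel(pib_suvr=1.50, csf_ab42_ab40=0.08), True, ["pib_suvr"]),
        (BiomarkerPanel(av45_suvr=1.10), False, []),
        (BiomarkerPanel(csf_ab42_ab40=0.0673), False, []),   # strict "<"
        (BiomarkerPanel(csf_ab42_ab40=0.0672), True, ["csf_ab42_ab40"]),
        (BiomarkerPanel(pib_suvr=1.42), False, []),          # strict ">"
        (BiomarkerPanel(pib_suvr=1.30, av45_suvr=1.25), True, ["av45_suvr"]),
    ])
    def test_cutoffs_and_discordance(self, panel, expected, src):
        positive, sources = bs.amyloid_positivity(panel)
        assert positive is expected and sources == src

    def test_no_measure_is_an_error(self):
        with pytest.raises(ValueError):
            bs.amyloid_positivity(BiomarkerPanel(tau_pet_suvr=1.3))


class TestCognitiveComposite:
    REF = {"trails_a": (30.0, 10.0), "trails_b": (75.0, 25.0),
           "animal_naming": (21.0, 5.0), "free_recall": (30.0, 6.0)}

    def test_reference_mean_scores_give_zero(self):
        scores = {k: v[0] for k, v in self.REF.items()}
        assert bs.cognitive_composite(scores, self.REF) == pytest.approx(0.0)

    def test_slower_trails_lower_composite(self):
        scores = {k: v[0] for k, v in self.REF.items()}
        scores["trails_b"] = 100.0   # slower than reference
        assert bs.cognitive_composite(scores, self.REF) < 0

    def test_equal_weight_average_after_sign_handling(self):
        scores = {"trails_a": 20.0,       # z = -1, negated -> +1
                  "trails_b": 50.0,       # z = -1, negated -> +1
                  "animal_naming": 26.0,  # z = +1
                  "free_recall": 36.0}    # z = +1
        assert bs.cognitive_composite(scores, self.REF) == pytest.approx(1.0)

    def test_partial_availability_and_empty(self):
        assert bs.cognitive_composite({"animal_naming": 26.0},
                                      self.REF) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            bs.cognitive_composite({}, self.REF)
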