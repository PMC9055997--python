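import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from crownforge.cw_models import ModelForm, fit_nls
from crownforge.nlme import (
    FittedMixedModel,
    RandomSpec,
    VarianceFunction,
    enumerate_random_structures,
    nlme_fit,
    predict_mixed,
    select_structure,
)
from crownforge.stem_map import ConfigurationError, ValidationError

GROUPS = list("ABCDEF")


def power_mixed_data(
    rng, n=1200, beta=(0.9, 0.5), u_sd=0.06, noise_sd=0.15, n_groups=6
):
    """CW = phi1 * D^(phi2 + u2_g) + eps with homoscedastic noise."""
    d = rng.uniform(1, 40, n)
    g = rng.choice(GROUPS[:n_groups], n)
    u = dict(zip(GROUPS, rng.normal(0, u_sd, len(GROUPS))))
    u = {k: v - np.mean(list(u.values())) for k, v in u.items()}
    expo = beta[1] + np.array([u[k] for k in g])
    cw = beta[0] * d**expo + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"cw": cw, "d": d, "species_group": g}), u


class TestEnumerate:
    def test_five_parameter_form_has_31_structures(self):
        specs = enumerate_random_structures("G")
        assert len(specs) == 31
        assert len({s.random_subset for s in specs}) == 31

    def test_two_parameter_form_has_3(self):
        assert len(enumerate_random_structures("F2")) == 3

    def test_order_smallest_first(self):
        specs = enumerate_random_structures("G")
        assert specs[0].random_subset == (0,)
        assert specs[0].names == ("phi1",)
        sizes = [s.q for s in specs]
        assert sizes == sorted(sizes)


class TestRandomSpec:
    def test_names_and_indices_equivalent(self):
        assert RandomSpec(("phi2", "phi5")).random_subset == RandomSpec((1, 4)).random_subset

    def test_empty_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            RandomSpec(())

    def test_subset_beyond_arity_rejected(self, rng):
        fr, _ = power_mixed_data(rng, n=100)
        with pytest.raises(ConfigurationError):
            nlme_fit("F2", fr, RandomSpec((4,)))


class TestVarianceFunction:
    def test_power_at_unit_diameter_is_one(self):
        vf = VarianceFunction("power", delta=-2.0)
        assert vf.lam(np.array([1.0]))[0] == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            VarianceFunction("cauchy")


class TestNlmeFit:
    def test_zero_between_group_variance_matches_pooled_nls(self, rng):
        # no group effects, homoscedastic noise: the mixed fit must collapse
        # onto unweighted pooled nonlinear least squares
        fr, _ = power_mixed_data(rng, n=1000, u_sd=0.0)
        pooled = fit_nls("F2", fr)
        mixed = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        assert mixed.converged
        np.testing.assert_allclose(mixed.fixed, pooled.model.phi, atol=1e-4)
        assert all(abs(v[0]) < 1e-3 for v in mixed.blups.values())

    def test_single_group_rejected(self, rng):
        fr, _ = power_mixed_data(rng, n=50, n_groups=1)
        with pytest.raises(ValidationError):
            nlme_fit("F2", fr, RandomSpec((1,)))

    def test_deterministic_given_data(self, rng):
        fr, _ = power_mixed_data(rng, n=400)
        a = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        b = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        np.testing.assert_array_equal(a.fixed, b.fixed)
        assert a.loglik == b.loglik

    def test_recovers_group_exponents(self, rng):
        fr, u = power_mixed_data(rng, n=2400, u_sd=0.08, noise_sd=0.1)
        fit = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        assert fit.converged
        assert fit.fixed[1] == pytest.approx(0.5, abs=0.02)
        for g, true_u in u.items():
            assert fit.blups[g][0] == pytest.approx(true_u, abs=0.02)

    def test_blups_approach_per_group_nls_for_large_groups(self, rng):
        fr, u = power_mixed_data(rng, n=3000, u_sd=0.08, noise_sd=0.05, n_groups=3)
        fit = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        for g in "ABC":
            own = fit_nls("F2", fr[fr["species_group"] == g]).model.phi[1]
            assert fit.fixed[1] + fit.blups[g][0] == pytest.approx(own, abs=5e-3)

    def test_mixed_aic_beats_pooled_when_effects_real(self, rng):
        fr, _ = power_mixed_data(rng, n=1500, u_sd=0.1, noise_sd=0.1)
        pooled = fit_nls("F2", fr)
        mixed = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
        assert mixed.aic < pooled.stats.aic

    def test_aic_counts_all_estimated_quantities(self, rng):
        fr, _ = power_mixed_data(rng, n=400)
        fit = nlme_fit("F2", fr, RandomSpec((1,)), varfn="power")
        # 2 fixed + 1 psi entry + sigma^2 + delta
        assert fit.n_params == 5
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)


class TestPredictMixed:
    @pytest.fixture()
    def hand_model(self):
        return FittedMixedModel(
            form=ModelForm("G", [0.967, 0.417, -0.001, 0.059, -0.028], ci_kind="SRD"),
            random_spec=RandomSpec((1, 4)),
            varfn=VarianceFunction("power", delta=-3.012),
            psi=np.array([[0.002, -0.0009], [-0.0009, 0.0004]]),
            sigma2=0.733,
            blups={g: np.zeros(2) for g in GROUPS},
            converged=True,
        )

    def test_population_intercept_at_unit_diameter(self, hand_model):
        fr = pd.DataFrame({"d": [1.0], "th": [0.0], "hcb": [0.0], "ci": [0.0]})
        assert predict_mixed(hand_model, fr)[0] == pytest.approx(0.967)

    def test_group_mode_with_zero_blups_equals_population(self, hand_model):
        fr = pd.DataFrame(
            {"d": [8.0, 12.0], "th": [7.0, 9.0], "hcb": [2.0, 3.0],
             "ci": [40.0, 50.0], "species_group": ["A", "B"]}
        )
        np.testing.assert_allclose(
            predict_mixed(hand_model, fr, mode="group"),
            predict_mixed(hand_model, fr, mode="population"),
        )

    def test_unseen_species_falls_back_to_population(self, hand_model):
        hand_model.blups = {"A": np.array([0.05, 0.01])}
        fr = pd.DataFrame(
            {"d": [8.0], "th": [7.0], "hcb": [2.0], "ci": [40.0],
             "species_group": ["ZZ"]}
        )
        np.testing.assert_allclose(
            predict_mixed(hand_model, fr, mode="group"),
            predict_mixed(hand_model, fr, mode="population"),
        )

    def test_nonzero_blup_changes_group_prediction(self, hand_model):
        hand_model.blups = {"A": np.array([0.05, 0.0])}
        fr = pd.DataFrame(
            {"d": [8.0], "th": [7.0], "hcb": [2.0], "ci": [40.0],
             "species_group": ["A"]}
        )
        g = predict_mixed(hand_model, fr, mode="group")[0]
        p = predict_mixed(hand_model, fr, mode="population")[0]
        assert g > p  # positive exponent bump at d > 1


class TestSelectStructure:
    def test_report_covers_structures_times_kinds(self, rng):
        fr, _ = power_mixed_data(rng, n=300)
        best, report = select_structure("F2", fr, varfn_kinds=("constant", "power"))
        assert len(report) == 3 * 2
        assert best is not None
        assert report.loc[~report["converged"], "aic"].isna().all()

    def test_best_is_minimum_aic_converged(self, rng):
        fr, _ = power_mixed_data(rng, n=600, u_sd=0.08)
        best, report = select_structure("F2", fr, varfn_kinds=("constant",))
        assert best.aic == pytest.approx(report["aic"].min())


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_fixed_effects_agree_with_reference_r_implementation(tmp_path, rng):
    """Independent cross-check of the estimation engine against nlme::nlme."""
    fr, _ = power_mixed_data(rng, n=800, u_sd=0.06, noise_sd=0.12)
    csv = tmp_path / "data.csv"
    fr.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        library(nlme)
        df <- read.csv("{csv}")
        fit <- nlme(cw ~ p1 * d^p2, data = df,
                    fixed = p1 + p2 ~ 1, random = p2 ~ 1 | species_group,
                    start = c(p1 = 1.0, p2 = 0.45), method = "ML",
                    control = nlmeControl(returnObject = TRUE))
        cat(fixef(fit)["p1"], fixef(fit)["p2"], sigma(fit), sep = ",")
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    p1_r, p2_r, sigma_r = map(float, out.stdout.strip().split(","))
    ours = nlme_fit("F2", fr, RandomSpec((1,)), varfn="constant")
    assert ours.fixed[0] == pytest.approx(p1_r, rel=1e-3)
    assert ours.fixed[1] == pytest.approx(p2_r, rel=1e-3)
    assert np.sqrt(ours.sigma2) == pytest.approx(sigma_r, rel=0.02)
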