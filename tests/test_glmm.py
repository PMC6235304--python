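import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln, logsumexp

from conftest import small_config
from hipposurvey.glmm import (ConvergenceError, CrossedMixedLogit, ModelSpec,
                              backward_select, encode_covariates, fit_glmm,
                              regroup, standardize)
from hipposurvey.simulate import (GlmmTruth, generate_counts, generate_design)


class TestEncoding:
    def test_standardize_three_points(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_standardize_idempotent(self, rng):
        x = rng.normal(2.0, 3.0, 200)
        z = standardize(x)
        assert np.allclose(standardize(z), z, atol=1e-12)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_standardize_height_classes(self):
        x = np.repeat([40, 60, 80, 100, 120, 140], 42)
        z = standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_standardize_degenerate(self):
        with pytest.raises(ValueError):
            standardize([5, 5, 5])

    @pytest.mark.parametrize(
        "factor,response,mapping",
        [
            ("cloud", "dr", {0: 0, 1: 0, 2: 1}),
            ("cloud", "lc", {0: 0, 1: 0, 2: 1}),
            ("sun", "dr", {0: 0, 1: 0, 2: 1}),
            ("sun", "lc", {0: 0, 1: 1, 2: 1}),
        ],
    )
    def test_regroup_schemes(self, factor, response, mapping):
        """Scattered clouds count as clear; minor sun matters only for LC."""
        vals = np.array(list(mapping))
        assert regroup(vals, factor, response).tolist() == \
            [float(mapping[v]) for v in vals]

    def test_regroup_range_check(self):
        with pytest.raises(ValueError):
            regroup([0, 3], "cloud", "dr")


def _make_model(units, **spec_kw):
    return CrossedMixedLogit.from_units(units, ModelSpec("dr", **spec_kw))


def _single_factor_units(denominator, seed=7):
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(5):
        for j in range(6):
            n_def = int(rng.integers(denominator // 2, denominator * 9 // 10))
            rows.append(dict(
                photo_id=f * 6 + j, flight_id=f, observer_id=0,
                height_m=[40, 60, 80, 100, 120, 140][j % 6],
                wind_ms=1 + (f % 5), cloud_class=f % 3, sun_class=j % 3,
                experienced=j % 2, est_pop=denominator,
                n_definite=n_def,
                n_possible=int(rng.integers(0, max(denominator // 12, 2))),
            ))
    return pd.DataFrame(rows)


def _quad_oracle_single_factor(model, beta, sig):
    """Exact marginal log-likelihood for one random factor via scipy.quad.

    The likelihood factorizes over the factor's levels; each level needs a
    1-D integral of the binomial likelihood against the N(0, sig^2) prior.
    """
    eta0 = model.X @ beta
    y, n, codes = model.y, model.n, model.codes[0]
    logC = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    total = 0.0
    for g in range(model.block_sizes[0]):
        idx = codes == g

        def logf(u):
            e = eta0[idx] + u
            return (float(np.sum(y[idx] * e - n[idx] * np.log1p(np.exp(e))
                                 + logC[idx]))
                    - 0.5 * u**2 / sig**2 - np.log(sig)
                    - 0.5 * np.log(2 * np.pi))

        shift = max(logf(v) for v in np.linspace(-5 * sig, 5 * sig, 101))
        val, _ = quad(lambda u: np.exp(logf(u) - shift),
                      -8 * sig, 8 * sig, limit=200)
        total += shift + np.log(val)
    return total


class TestLikelihoodOracles:
    beta = np.array([0.4, -0.1, -0.3])
    sig = 0.35

    def test_agq_matches_quadrature_oracle_single_factor(self):
        m = _make_model(_single_factor_units(60),
                        fixed=("height", "experience"), random=("flight",))
        oracle = _quad_oracle_single_factor(m, self.beta, self.sig)
        agq = m.loglik(self.beta, np.array([self.sig]), "agq", nodes=15)
        assert agq == pytest.approx(oracle, abs=1e-6)

    def test_laplace_matches_oracle_at_high_information(self):
        """Laplace error is O(1/trials per level): negligible at denom 500."""
        m = _make_model(_single_factor_units(500),
                        fixed=("height", "experience"), random=("flight",))
        oracle = _quad_oracle_single_factor(m, self.beta, self.sig)
        lap = m.loglik(self.beta, np.array([self.sig]), "laplace")
        assert lap == pytest.approx(oracle, abs=1e-3)

    def test_laplace_error_shrinks_with_information(self):
        errs = []
        for denom in (5, 60, 500):
            m = _make_model(_single_factor_units(denom),
                            fixed=("height", "experience"),
                            random=("flight",))
            oracle = _quad_oracle_single_factor(m, self.beta, self.sig)
            errs.append(abs(m.loglik(self.beta, np.array([self.sig]),
                                     "laplace") - oracle))
        assert errs[0] > errs[1] > errs[2]


def _tiny_crossed_units(seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(2):
        for o in range(2):
            n_def = int(rng.integers(1, 5))
            rows.append(dict(
                photo_id=f, flight_id=f, observer_id=o,
                height_m=40 + 100 * f, wind_ms=1 + 3 * f, cloud_class=2 * f,
                sun_class=o, experienced=o, est_pop=5,
                n_definite=n_def, n_possible=min(1, 5 - n_def),
            ))
    return pd.DataFrame(rows)


def _brute_force_crossed(model, beta, sigmas, nodes=10):
    """Dense prior-scaled product Gauss-Hermite over all latent dimensions.

    Independent of the fitter's adaptive rule: nodes are centered at zero
    and scaled by the prior SD only, which converges for the weak
    likelihoods of tiny binomial instances.
    """
    z, w = np.polynomial.hermite.hermgauss(nodes)
    q = model.q
    sig = np.repeat(sigmas, model.block_sizes)
    grids = np.meshgrid(*([z] * q), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    wg = np.meshgrid(*([np.log(w)] * q), indexing="ij")
    logw = np.sum([g.ravel() for g in wg], axis=0)
    U = np.sqrt(2.0) * Z * sig[None, :]
    Zd = model.Z.toarray()
    logC = float(np.sum(gammaln(model.n + 1) - gammaln(model.y + 1)
                        - gammaln(model.n - model.y + 1)))
    vals = np.empty(len(U))
    for i in range(0, len(U), 200_000):
        eta = (model.X @ beta)[None, :] + U[i:i + 200_000] @ Zd.T
        vals[i:i + 200_000] = eta @ model.y - np.log1p(np.exp(eta)) @ model.n
    return float(logsumexp(logw + vals) - q / 2 * np.log(np.pi) + logC)


class TestTinyCrossedInstance:
    def test_agq_loglik_matches_brute_force(self):
        m = _make_model(_tiny_crossed_units(),
                        fixed=("height", "experience"),
                        random=("flight", "photo", "observer"))
        beta = np.array([0.5, -0.2, -0.4])
        sig = np.array([0.4, 0.3, 0.5])
        brute = _brute_force_crossed(m, beta, sig)
        agq = m.loglik(beta, sig, "agq", nodes=9)
        assert agq == pytest.approx(brute, abs=1e-3)

    def test_fitted_loglik_matches_brute_force(self):
        """The quadrature fit's reported logLik is exact to < 1e-3."""
        m = _make_model(_tiny_crossed_units(),
                        fixed=("height", "experience"),
                        random=("flight", "photo", "observer"))
        fit = m.fit(method="agq", nodes=5, compute_se=False)
        beta = np.array([fit.coefficients[n] for n in m.fixed_names])
        sig = np.array([max(fit.random_sd[n], 2.5e-3)
                        for n in m.factor_names])
        brute = _brute_force_crossed(m, beta, sig)
        refined = m.loglik(beta, sig, "agq", nodes=9)
        assert refined == pytest.approx(brute, abs=1e-3)


class TestReductionToOrdinaryLogistic:
    def test_no_random_effects_matches_statsmodels(self, small_units):
        import statsmodels.api as sm

        spec = ModelSpec("dr", fixed=("height", "cloud", "sun", "experience"),
                         random=())
        ours = fit_glmm(small_units, spec, compute_se=False)
        X, names = encode_covariates(small_units, "dr",
                                     ("height", "cloud", "sun", "experience"))
        tot = (small_units["n_definite"]
               + small_units["n_possible"]).to_numpy(float)
        n = small_units["est_pop"].to_numpy(float)
        ref = sm.GLM(np.column_stack([tot, n - tot]), X,
                     family=sm.families.Binomial()).fit()
        for j, name in enumerate(names):
            assert ours.coefficients[name] == pytest.approx(ref.params[j],
                                                            abs=2e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)

    def test_recovers_truth_when_random_sds_zero(self):
        truth = {"intercept": 1.5, "height": -0.3, "wind": 0.0,
                 "cloud": -0.6, "sun": -0.5, "experience": -0.4}
        cfg = small_config(seed=5, dr=GlmmTruth(truth, {}),
                           lc=GlmmTruth({"intercept": 2.0}, {}))
        units = generate_counts(generate_design(cfg), cfg)
        fit = fit_glmm(units,
                       ModelSpec("dr",
                                 fixed=("height", "cloud", "sun",
                                        "experience")))
        for name in ("intercept", "height", "cloud", "sun", "experience"):
            assert abs(fit.coefficients[name] - truth[name]) < \
                2 * fit.se[name] + 1e-6


class TestAgainstLme4:
    def test_crossed_fit_matches_lme4(self, small_units, tmp_path):
        """lme4's Laplace glmer is the external oracle for the crossed fit."""
        fixed = ("height", "cloud", "sun", "experience")
        X, names = encode_covariates(small_units, "dr", fixed)
        df = pd.DataFrame(X[:, 1:], columns=names[1:])
        df["y"] = (small_units["n_definite"]
                   + small_units["n_possible"]).to_numpy()
        df["n"] = small_units["est_pop"].to_numpy()
        for c in ("flight_id", "photo_id", "observer_id"):
            df[c] = small_units[c].to_numpy()
        csv = tmp_path / "units.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(cbind(y, n - y) ~ height + cloud + sun + experience"
            " + (1|flight_id) + (1|photo_id) + (1|observer_id),"
            " data = d, family = binomial)\n"
            "co <- fixef(m)\n"
            "vc <- as.data.frame(VarCorr(m))\n"
            "cat(co, '\\n')\n"
            "cat(vc$sdcor[match(c('flight_id','photo_id','observer_id'),"
            " vc$grp)], '\\n')\n"
            "cat(as.numeric(logLik(m)), '\\n')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        ref_coef = np.array(lines[-3].split(), float)
        ref_sd = np.array(lines[-2].split(), float)
        ref_ll = float(lines[-1])

        ours = fit_glmm(small_units, ModelSpec("dr", fixed=fixed),
                        compute_se=False)
        for j, name in enumerate(names):
            assert ours.coefficients[name] == pytest.approx(ref_coef[j],
                                                            abs=0.02)
        for j, name in enumerate(("flight", "photo", "observer")):
            assert ours.random_sd[name] == pytest.approx(ref_sd[j], abs=0.02)
        assert ours.loglik == pytest.approx(ref_ll, abs=0.05)


class TestBackwardSelection:
    def test_dropping_zero_wind_lowers_aic_on_average(self):
        """Wind's generating coefficient is 0: the AIC gap between the full
        model and the model without wind is positive in expectation."""
        gaps = []
        for seed in range(20):
            cfg = small_config(seed=300 + seed)
            units = generate_counts(generate_design(cfg), cfg)
            full = fit_glmm(units, ModelSpec("dr"), compute_se=False)
            nowind = fit_glmm(units, ModelSpec("dr").drop_fixed("wind"),
                              compute_se=False)
            gaps.append(full.aic - nowind.aic)
        assert np.mean(gaps) > 0

    def test_strong_effects_all_retained(self):
        # wind and cloud vary only across 7 flights and compete with the
        # flight intercept, so "strong" means large on that scale too
        strong = {"intercept": 2.0, "height": -0.5, "wind": -1.5,
                  "cloud": -2.0, "sun": -1.2, "experience": -1.0}
        cfg = small_config(seed=77, dr=GlmmTruth(strong, {"flight": 0.1,
                                                          "photo": 0.2,
                                                          "observer": 0.2}))
        units = generate_counts(generate_design(cfg), cfg)
        final, _ = backward_select(units, ModelSpec("dr"), test_random=False)
        assert set(final.spec.fixed) == {"height", "wind", "cloud", "sun",
                                         "experience"}

    def test_random_effects_retained_when_present(self, small_units):
        final, trace = backward_select(small_units, ModelSpec(
            "dr", fixed=("height", "experience")), test_random=True)
        random_steps = [t for t in trace if t["kind"] == "random"]
        assert random_steps, "random-effect stage must be traced"
        assert set(final.spec.random) == {"flight", "photo", "observer"}


class TestFitContract:
    def test_lc_response_excludes_zero_count_units(self, small_units):
        units = small_units.copy()
        units.loc[units.index[:5], ["n_definite", "n_possible"]] = 0
        fit = fit_glmm(units, ModelSpec("lc", fixed=("height",)),
                       compute_se=False)
        assert fit.n_units == len(units) - 5

    def test_overcount_capped_for_dr_fit(self, small_units):
        units = small_units.copy()
        units.loc[units.index[0], "n_possible"] = 10_000
        fit = fit_glmm(units, ModelSpec("dr", fixed=("height",)),
                       compute_se=False)
        assert np.isfinite(fit.loglik)

    def test_aic_consistency(self, small_units):
        fit = fit_glmm(small_units, ModelSpec("dr", fixed=("height",)),
                       compute_se=False)
        k = len(fit.coefficients) + len(fit.random_sd)
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)

    def test_needs_two_levels_per_factor(self, small_units):
        one_flight = small_units[small_units["flight_id"] == 1]
        with pytest.raises(ValueError):
            fit_glmm(one_flight, ModelSpec("dr", fixed=("height",),
                                           random=("flight",)))
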