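"""Gibbs sampler correctness: truncated normals, joint-distribution checks,
determinism, diagnostics, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import modmind as mm
from modmind.model import Priors
from modmind.sampler import GibbsSampler, sample_truncated_normal
from tests.conftest import make_design


class TestTruncatedNormal:
    def test_half_normal_mean(self):
        rng = np.random.default_rng(1)
        x = sample_truncated_normal(0.0, 1.0, np.zeros(100_000), np.inf, rng)
        assert abs(x.mean() - np.sqrt(2 / np.pi)) < 0.01

    def test_untruncated_matches_normal(self):
        rng = np.random.default_rng(2)
        x = sample_truncated_normal(
            0.0, 1.0, np.full(20_000, -np.inf), np.inf, rng
        )
        assert stats.kstest(x, "norm").pvalue > 0.01

    def test_far_tail_is_robust(self):
        rng = np.random.default_rng(3)
        x = sample_truncated_normal(0.0, 1.0, np.full(5_000, 8.0), np.inf, rng)
        assert np.all(np.isfinite(x)) and np.all(x >= 8.0)
        # and the far lower tail, mirrored
        y = sample_truncated_normal(0.0, 1.0, -np.inf, np.full(5_000, -8.0), rng)
        assert np.all(np.isfinite(y)) and np.all(y <= -8.0)

    def test_matches_scipy_on_generic_interval(self):
        """Independent cross-check against the reference truncated normal."""
        rng = np.random.default_rng(4)
        x = sample_truncated_normal(
            1.5, 2.0, np.full(100_000, -1.0), 4.0, rng
        )
        ref = stats.truncnorm((-1 - 1.5) / 2, (4 - 1.5) / 2, loc=1.5, scale=2)
        assert abs(x.mean() - ref.mean()) < 0.02
        assert abs(x.std() - ref.std()) < 0.02

    def test_invalid_bounds_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(mm.ModelSpecError):
            sample_truncated_normal(0.0, 1.0, 2.0, 2.0, rng)
        with pytest.raises(mm.ModelSpecError):
            sample_truncated_normal(0.0, 0.0, 0.0, 1.0, rng)


def _geweke_design():
    return make_design(
        {"A": 2, "B": 2, "C": 2},
        [("b1", "d1", "binomial", 3), ("r1", "d2", "rank", 1)],
    )


class TestJointDistribution:
    def test_successive_conditional_simulation(self):
        """'Getting it right' check: alternating the Gibbs kernel with a
        data-regeneration step must preserve the prior marginals of every
        parameter.  Moments of the successive-conditional chain are
        compared with their exact prior values via batch-mean errors."""
        design = _geweke_design()
        # integrable prior moments: IG(3, 3) has mean 1.5 and second moment 4.5
        priors = Priors(
            effect_var_prior="inv_gamma",
            effect_var_shape=3.0, effect_var_scale=3.0,
            error_var_shape=3.0, error_var_scale=3.0,
            task_intercept_var=1.0,
        )
        spec = mm.ModelSpec(frozenset({"species", "species_domain"}))
        cfg = mm.GenConfig.from_proportions(
            design, {"species": 0.3, "species_domain": 0.2, "error": 0.5}, seed=0
        )
        dataset, _ = mm.generate(cfg)
        sampler = GibbsSampler(dataset, spec, priors)
        rng = np.random.default_rng(2024)
        sampler.init_state(rng, "prior_draw")
        sampler.resample_data(rng)
        n_iter, warmup, skip = 30_000, 500, 2
        rows = []
        for i in range(n_iter):
            sampler.sweep(rng)
            sampler.resample_data(rng)
            if i >= warmup and i % skip == 0:
                st = sampler.state
                rows.append([
                    st.var["species"], st.var["species_domain"],
                    float(st.var_error), st.mu[0], st.mu[0] ** 2,
                    st.effects["species"][0] ** 2,
                ])
        chain = np.array(rows)
        # exact prior moments: E[sig2]=1.5; E[mu]=0; E[mu^2]=1;
        # E[a^2]=E[sig2_S]=1.5
        exact = [1.5, 1.5, 1.5, 0.0, 1.0, 1.5]
        n_batches = 30
        batches = np.array_split(chain, n_batches)
        bmeans = np.array([b.mean(axis=0) for b in batches])
        se = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches)
        z = (chain.mean(axis=0) - exact) / se
        assert np.all(np.abs(z) < 3.5), f"z-scores {np.round(z, 2)}"
        sampler.check_consistency()

    def test_successive_conditional_task_specific_errors(self):
        """Same joint-distribution check for the hierarchical per-task
        error structure (variances and their shared scale)."""
        design = _geweke_design()
        priors = Priors(
            effect_var_prior="inv_gamma",
            effect_var_shape=3.0, effect_var_scale=3.0,
            task_intercept_var=1.0,
            task_error_shape=3.0,
            error_scale_hyper_shape=4.0, error_scale_hyper_rate=2.0,
        )
        spec = mm.ModelSpec(frozenset({"species"}), "task_specific")
        cfg = mm.GenConfig.from_proportions(
            design, {"species": 0.3, "error": 0.7}, seed=1
        )
        dataset, _ = mm.generate(cfg)
        sampler = GibbsSampler(dataset, spec, priors)
        rng = np.random.default_rng(7)
        sampler.init_state(rng, "prior_draw")
        sampler.resample_data(rng)
        rows = []
        for i in range(15_000):
            sampler.sweep(rng)
            sampler.resample_data(rng)
            if i >= 500:
                st = sampler.state
                rows.append([st.error_scale, st.error_scale ** 2,
                             float(st.var_error[0]),
                             1.0 / float(st.var_error[0])])
        chain = np.array(rows)
        # bE ~ Gamma(4, rate 2): E=2, E[bE^2]=5; sig2_k ~ IG(3, bE):
        # E[sig2] = E[bE]/2 = 1; 1/sig2 ~ Gamma(3, rate bE) so
        # E[1/sig2] = 3 E[1/bE] = 3 * 2/3 = 2  (all moments finite)
        exact = [2.0, 5.0, 1.0, 2.0]
        n_batches = 30
        bmeans = np.array([b.mean(axis=0)
                           for b in np.array_split(chain, n_batches)])
        se = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches)
        z = (chain.mean(axis=0) - exact) / se
        assert np.all(np.abs(z) < 3.5), f"z-scores {np.round(z, 2)}"

    def test_successive_conditional_half_cauchy(self):
        """Joint-distribution check for the default half-Cauchy effect-SD
        prior.  Half-Cauchy variances have no finite moments, so the chain
        is compared with the exact prior through tail probabilities
        P(sig2 < c).  The design is deliberately tiny (4 subjects, one
        single-trial task): under a Cauchy tail, excursions to huge
        variances build up through a slow data-feedback spiral, and with
        an informative design those excursions mix too slowly for any
        CI-scale chain to average; the weakly coupled design keeps the
        prior cycle dominant while still exercising the full kernel."""
        design = make_design({"A": 2, "B": 2}, [("b1", "d1", "binomial", 1)])
        priors = Priors(effect_var_prior="half_cauchy",
                        task_intercept_var=1.0, effect_sd_scale=1.0,
                        error_var_shape=3.0, error_var_scale=3.0)
        spec = mm.ModelSpec(frozenset({"species"}))
        cfg = mm.GenConfig.from_proportions(
            design, {"species": 0.3, "error": 0.7}, seed=2)
        dataset, _ = mm.generate(cfg)
        sampler = GibbsSampler(dataset, spec, priors)
        rng = np.random.default_rng(31)
        sampler.init_state(rng, "prior_draw")
        sampler.resample_data(rng)
        cuts = np.array([0.05, 0.5, 2.0, 20.0])
        chain = []
        for i in range(25_000):
            sampler.sweep(rng)
            sampler.resample_data(rng)
            if i >= 500:
                chain.append(sampler.state.var["species"] < cuts)
        chain = np.array(chain, dtype=float)
        # exact prior tail: sigma ~ half-Cauchy(1), P(sig2 < c) =
        # (2/pi) arctan(sqrt(c))
        exact = 2.0 / np.pi * np.arctan(np.sqrt(cuts))
        nb = 35
        bmeans = np.array([b.mean(axis=0)
                           for b in np.array_split(chain, nb)])
        se = bmeans.std(axis=0, ddof=1) / np.sqrt(nb)
        z = (chain.mean(axis=0) - exact) / se
        assert np.all(np.abs(z) < 3.5), f"z-scores {np.round(z, 2)}"


class TestFitBasics:
    def test_m0_gates_out_species_draws(self, toy_design):
        cfg = mm.GenConfig.from_proportions(toy_design, {"error": 1.0}, seed=1)
        dataset, _ = mm.generate(cfg)
        samples = mm.fit(dataset, mm.ModelSpec.from_name("M0"),
                         mm.McmcConfig(n_burnin=50, n_iter=200, thin=1, seed=2))
        assert "species" not in samples.draws
        assert "var_species" not in samples.draws
        assert set(samples.draws) >= {"task_intercept", "var_error", "theta"}
        assert samples.n_draws == 200

    def test_stored_variances_positive(self, m3_fit_small):
        for name in m3_fit_small.active_variance_names():
            assert np.all(m3_fit_small.draws[name] > 0)

    def test_posterior_concentrates_on_success_rate(self):
        """600/1000 successes for a single subject and task pins
        Phi(theta) near 0.6."""
        design = make_design({"A": 1}, [("b1", "d1", "binomial", 1000)])
        obs = {("A1", "b1", j): (1 if j < 600 else 0) for j in range(1000)}
        dataset = mm.Dataset(design=design, binomial_obs=obs)
        samples = mm.fit(dataset, mm.ModelSpec.from_name("M0"),
                         mm.McmcConfig(n_burnin=500, n_iter=4_000, thin=2, seed=3))
        from scipy.special import ndtr

        p = ndtr(samples.draws["theta"][:, 0])
        assert abs(p.mean() - 0.6) < 0.02

    def test_determinism_and_row_order_invariance(self, toy_design, tmp_path):
        cfg = mm.GenConfig.from_proportions(
            toy_design, {"species": 0.3, "error": 0.7}, seed=4
        )
        dataset, _ = mm.generate(cfg)
        mcmc = mm.McmcConfig(n_burnin=100, n_iter=400, thin=2, seed=11)
        spec = mm.ModelSpec.from_name("M1")
        a = mm.fit(dataset, spec, mcmc)
        b = mm.fit(dataset, spec, mcmc)
        assert np.array_equal(a.draws["var_species"], b.draws["var_species"])
        # shuffle the CSV rows: identical posterior, canonical iteration order
        path = tmp_path / "obs.csv"
        mm.write_dataset(dataset, path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df.sample(frac=1.0, random_state=0).to_csv(path, index=False)
        shuffled = mm.read_dataset(path, toy_design)
        c = mm.fit(shuffled, spec, mcmc)
        assert np.array_equal(a.draws["var_species"], c.draws["var_species"])

    def test_infeasible_effect_rejected(self):
        design = make_design({"A": 3}, [("b1", "d1", "binomial", 2)])
        cfg = mm.GenConfig.from_proportions(design, {"error": 1.0}, seed=0)
        dataset, _ = mm.generate(cfg)
        with pytest.raises(mm.ModelSpecError):
            mm.fit(dataset, mm.ModelSpec.from_name("M1"),
                   mm.McmcConfig(n_burnin=10, n_iter=20, thin=1, seed=0))

    def test_augmentation_consistency_checks(self, toy_design):
        cfg = mm.GenConfig.from_proportions(
            toy_design, {"species": 0.3, "error": 0.7}, seed=4
        )
        dataset, _ = mm.generate(cfg)
        mm.fit(dataset, mm.ModelSpec.from_name("M1"),
               mm.McmcConfig(n_burnin=50, n_iter=100, thin=1, seed=1),
               check_every=10)

    def test_save_load_round_trip(self, tmp_path, m3_fit_small):
        path = tmp_path / "samples.npz"
        m3_fit_small.save(path)
        back = mm.PosteriorSamples.load(path)
        assert back.spec == m3_fit_small.spec
        assert back.dataset_hash == m3_fit_small.dataset_hash
        for k, v in m3_fit_small.draws.items():
            assert np.array_equal(back.draws[k], v)


class TestDiagnostics:
    def test_white_noise_is_clean(self, m3_fit_small):
        # inject i.i.d. draws for one parameter name via a shallow copy
        samples = m3_fit_small
        rng = np.random.default_rng(0)
        fake = mm.PosteriorSamples(
            spec=mm.ModelSpec.from_name("M0"), mcmc=samples.mcmc,
            draws={
                "task_intercept": rng.normal(size=(2_000, 1)),
                "var_error": rng.gamma(2.0, 1.0, size=2_000),
                "theta": np.zeros((2_000, 1)),
            },
            subject_ids=["s"], task_ids=["t"], species=["A"], domains=["d"],
            cells=[("s", "t")],
        )
        report = mm.diagnostics(fake)
        assert abs(report["parameters"]["var_error"]["rhat"] - 1.0) < 0.02
        assert not report["warnings"]

    def test_constant_chain_is_flagged(self, m3_fit_small):
        fake = mm.PosteriorSamples(
            spec=mm.ModelSpec.from_name("M0"), mcmc=m3_fit_small.mcmc,
            draws={
                "task_intercept": np.ones((500, 1)),
                "var_error": np.ones(500),
                "theta": np.zeros((500, 1)),
            },
            subject_ids=["s"], task_ids=["t"], species=["A"], domains=["d"],
            cells=[("s", "t")],
        )
        report = mm.diagnostics(fake)
        assert report["parameters"]["var_error"]["ess"] <= 1.0
        assert report["warnings"]

    def test_too_few_draws_rejected(self, m3_fit_small):
        fake = mm.PosteriorSamples(
            spec=mm.ModelSpec.from_name("M0"), mcmc=m3_fit_small.mcmc,
            draws={"task_intercept": np.ones((50, 1)), "var_error": np.ones(50),
                   "theta": np.zeros((50, 1))},
            subject_ids=["s"], task_ids=["t"], species=["A"], domains=["d"],
            cells=[("s", "t")],
        )
        with pytest.raises(mm.ModmindError):
            mm.diagnostics(fake)


class TestRecovery:
    def test_error_variance_resists_degenerate_collapse(self):
        """Short chains on strong-interaction data must not fall into the
        degenerate mode where the error variance collapses toward zero
        (the marginalized error-variance update plus the fixed unit scale
        of rank-task latents remove that trap)."""
        cfg = mm.GenConfig.from_proportions(
            mm.paper_design(),
            {"species": 0.10, "species_domain": 0.30, "error": 0.60},
            seed=3, calibrate_realized=True)
        dataset, _ = mm.generate(cfg)
        for seed in (5, 8):
            samples = mm.fit(dataset, mm.ModelSpec.from_name("M3"),
                             mm.McmcConfig(n_burnin=300, n_iter=1_500,
                                           thin=3, seed=seed))
            assert samples.draws["var_error"].min() > 0.2


    def test_recovery_insensitive_to_prior_settings(self):
        """The recovered species share moves little across weakly
        informative prior choices (two inverse-gamma settings and the
        half-Cauchy mixture)."""
        cfg = mm.GenConfig.from_proportions(
            mm.paper_design(), {"species": 0.2, "error": 0.8}, seed=14,
            calibrate_realized=True)
        dataset, _ = mm.generate(cfg)
        mcmc = mm.McmcConfig(n_burnin=300, n_iter=1_500, thin=3, seed=15)
        priors = [
            Priors(),  # half-Cauchy(1) default
            Priors(effect_var_prior="inv_gamma",
                   effect_var_shape=1.0, effect_var_scale=0.01),
            Priors(effect_var_prior="inv_gamma",
                   effect_var_shape=0.5, effect_var_scale=0.05),
        ]
        shares = []
        for pr in priors:
            samples = mm.fit(dataset, mm.ModelSpec.from_name("M1"), mcmc, pr)
            shares.append(mm.variance_proportions(samples).mean["species"])
        assert max(shares) - min(shares) < 0.08, shares
        for s in shares:
            assert abs(s - 0.2) < 0.1, shares


    def test_error_shrinks_with_design_size(self):
        """Posterior means of variance proportions approach the generating
        truth as the design grows (three nested sizes, averaged over
        seeds)."""
        truth = {"species": 0.25, "error": 0.75}
        sizes = [
            ({"A": 2, "B": 2, "C": 2, "D": 2, "E": 2}, 2),
            ({"A": 5, "B": 5, "C": 5, "D": 5, "E": 5}, 4),
            ({"A": 12, "B": 12, "C": 12, "D": 12, "E": 12}, 8),
        ]
        errs = []
        for counts, n_trials in sizes:
            tasks = [(f"b{j}", "d1", "binomial", n_trials) for j in range(6)]
            design = make_design(counts, tasks)
            errors = []
            for seed in range(3):
                cfg = mm.GenConfig.from_proportions(design, truth, seed=seed)
                dataset, latent = mm.generate(cfg)
                samples = mm.fit(
                    dataset, mm.ModelSpec.from_name("M1"),
                    mm.McmcConfig(n_burnin=300, n_iter=1_500, thin=3,
                                  seed=50 + seed),
                )
                row = mm.variance_proportions(samples)
                emp = mm.empirical_decomposition(latent)
                errors.append(abs(row.mean["species"] - emp["species"]))
            errs.append(float(np.mean(errors)))
        assert errs[2] < errs[0] + 0.02
        assert errs[2] < 0.12


def test_desk_preset_mixes_well(m3_dataset):
    """Desk-scale M3 fit: split R-hat below 1.05 for every variance."""
    dataset, _ = m3_dataset
    samples = mm.fit(dataset, mm.ModelSpec.from_name("M3"),
                     mm.McmcConfig.desk(seed=42))
    report = mm.diagnostics(samples)
    for name in samples.active_variance_names():
        assert report["parameters"][name]["rhat"] < 1.05, name
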