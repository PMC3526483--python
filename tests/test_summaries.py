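"""Combined effects, dominance matrices, and the two re-analyses."""

import numpy as np
import pytest
from scipy.special import ndtr

import modmind as mm
from modmind.summaries import (
    CombinedEffectSamples,
    SPECIES_DISPLAY_ORDER,
    species_task_means,
)
from tests.conftest import make_design


def _samples_with_effects(a, b, spec_name="M3"):
    """Hand-build posterior samples with given species / species*domain draws."""
    nd, S = a.shape
    D = b.shape[2]
    spec = mm.ModelSpec.from_name(spec_name)
    species = list("ABCDEFG"[:S])
    domains = [f"d{j}" for j in range(D)]
    return mm.PosteriorSamples(
        spec=spec, mcmc=mm.McmcConfig(n_burnin=0, n_iter=nd, thin=1, seed=0),
        draws={
            "species": a,
            "species_domain": b.reshape(nd, S * D),
            "var_species": np.ones(nd),
            "var_species_domain": np.ones(nd),
            "var_error": np.ones(nd),
            "task_intercept": np.zeros((nd, 1)),
            "theta": np.zeros((nd, 1)),
        },
        subject_ids=["x"], task_ids=["t"], species=species, domains=domains,
        cells=[("x", "t")],
    )


class TestCombinedEffects:
    def test_zero_interaction_reduces_to_species_effect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(600, 3))
        b = np.zeros((600, 3, 2))
        comb = mm.combined_effects(_samples_with_effects(a, b))
        assert np.allclose(comb.draws[:, :, 0], a)
        assert np.allclose(comb.draws[:, :, 1], a)

    def test_linearity_in_scaling(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(600, 3))
        b = rng.normal(size=(600, 3, 2))
        g1 = mm.combined_effects(_samples_with_effects(a, b)).draws
        g2 = mm.combined_effects(_samples_with_effects(3 * a, 3 * b)).draws
        assert np.allclose(g2, 3 * g1)

    def test_requires_species_domain(self, toy_design):
        cfg = mm.GenConfig.from_proportions(
            toy_design, {"species": 0.3, "error": 0.7}, seed=2)
        dataset, _ = mm.generate(cfg)
        samples = mm.fit(dataset, mm.ModelSpec.from_name("M1"),
                         mm.McmcConfig(n_burnin=50, n_iter=200, thin=1, seed=0))
        with pytest.raises(mm.AssessmentError):
            mm.combined_effects(samples)


class TestDominance:
    def test_identical_draws_give_half(self):
        a = np.zeros((600, 2))
        b = np.zeros((600, 2, 1))
        comb = mm.combined_effects(_samples_with_effects(a, b))
        dm = mm.dominance_matrix(comb, "d0", species_order=["A", "B"])
        assert dm.prob("A", "B") == 0.5

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(900, 4))
        b = rng.normal(size=(900, 4, 2))
        comb = mm.combined_effects(_samples_with_effects(a, b))
        dm = mm.dominance_matrix(comb, "d1", species_order=list("ABCD"))
        assert np.allclose(dm.matrix + dm.matrix.T, 1.0)
        assert np.all((dm.matrix >= 0) & (dm.matrix <= 1))

    def test_separated_species_dominates(self):
        rng = np.random.default_rng(4)
        a = 0.1 * rng.normal(size=(800, 3))
        b = 0.1 * rng.normal(size=(800, 3, 2))
        b[:, 1, 0] += 3.0  # species B three SDs ahead in domain d0
        comb = mm.combined_effects(_samples_with_effects(a, b))
        dm = mm.dominance_matrix(comb, "d0", species_order=list("ABC"))
        for other in ("A", "C"):
            assert dm.prob("B", other) > 0.99

    def test_needs_enough_draws(self):
        a = np.zeros((100, 2))
        b = np.zeros((100, 2, 1))
        comb = mm.combined_effects(_samples_with_effects(a, b))
        with pytest.raises(mm.AssessmentError):
            mm.dominance_matrix(comb, "d0")

    def test_recovers_engineered_specialist(self):
        """A species with a large engineered domain advantage comes out on
        top of that domain's combined-effect ranking after a real fit."""
        design = mm.paper_design()
        rng = np.random.default_rng(5)
        sp_of = design.species_of
        domains = {t.task_id: t.domain_id for t in design.tasks}
        binom, scores = {}, {}
        for sid, tid in sorted(design.participation):
            boost = 1.5 if (sp_of[sid] == "SM" and domains[tid] == "support") else 0.0
            theta = boost + 0.5 * rng.standard_normal()
            task = design.task(tid)
            if task.response_type == "binomial":
                for j in range(task.n_trials):
                    binom[(sid, tid, j)] = int(rng.random() < ndtr(theta))
            else:
                scores[(sid, tid)] = theta
        dataset = mm.Dataset(design=design, binomial_obs=binom, score_obs=scores)
        samples = mm.fit(dataset, mm.ModelSpec.from_name("M3"),
                         mm.McmcConfig(n_burnin=400, n_iter=2_500, thin=5, seed=6))
        comb = mm.combined_effects(samples)
        j = comb.domains.index("support")
        means = comb.draws[:, :, j].mean(axis=0)
        assert comb.species[int(np.argmax(means))] == "SM"
        dm = mm.dominance_matrix(comb, "support")
        for other in SPECIES_DISPLAY_ORDER:
            if other != "SM":
                assert dm.prob("SM", other) > 0.99


class TestSubsetReanalysis:
    def test_single_species_rejected(self, m3_dataset):
        dataset, _ = m3_dataset
        with pytest.raises(mm.ModelSpecError):
            mm.subset_reanalysis(dataset, ["CH"], mm.ModelSpec.from_name("M3"),
                                 mm.McmcConfig(n_burnin=10, n_iter=20, thin=1,
                                               seed=0))

    def test_full_subset_equals_full_fit(self, toy_design):
        cfg = mm.GenConfig.from_proportions(
            toy_design, {"species": 0.3, "error": 0.7}, seed=7)
        dataset, _ = mm.generate(cfg)
        mcmc = mm.McmcConfig(n_burnin=100, n_iter=500, thin=1, seed=8)
        spec = mm.ModelSpec.from_name("M1")
        full = mm.variance_proportions(mm.fit(dataset, spec, mcmc))
        sub = mm.subset_reanalysis(dataset, ["A", "B", "C"], spec, mcmc)
        assert full.mean == sub.mean

    def test_three_species_recovery(self):
        """Refit restricted to the three monkey species recovers that
        subset's realized species*domain share within the wider tolerance
        a 3-level species factor allows."""
        monkeys = ["SM", "CM", "LM"]
        errs = []
        for seed in (1, 2):
            cfg = mm.GenConfig.from_proportions(
                mm.paper_design(),
                {"species": 0.17, "species_domain": 0.17, "error": 0.66},
                seed=seed)
            dataset, truth = mm.generate(cfg)
            # realized decomposition within the subset (its 12 interaction
            # draws can land far from the nominal 0.17)
            keep_sp = [truth.species.index(sp) for sp in monkeys]
            keep_subj = [i for i, s in enumerate(truth.subject_ids)
                         if s[:2] in monkeys]
            keep_cells = [i for i, (s, _) in enumerate(truth.cells)
                          if s[:2] in monkeys]
            parts = {
                "species": np.var(truth.effects["species"][keep_sp], ddof=1),
                "species_domain": np.var(
                    truth.effects["species_domain"][keep_sp], ddof=1),
                "error": np.var(truth.eps[keep_cells], ddof=1),
            }
            total = sum(parts.values())
            realized_sd = parts["species_domain"] / total
            row = mm.subset_reanalysis(
                dataset, monkeys, mm.ModelSpec.from_name("M3"),
                mm.McmcConfig(n_burnin=500, n_iter=4_000, thin=4, seed=9 + seed))
            errs.append(row.mean["species_domain"] - realized_sd)
        assert abs(np.mean(errs)) < 0.10


class TestRanksOfMeans:
    def test_individual_effects_rejected(self, m3_dataset):
        dataset, _ = m3_dataset
        with pytest.raises(mm.ModelSpecError):
            mm.ranks_of_means_analysis(dataset, mm.ModelSpec.from_name("M5"),
                                       mm.McmcConfig(n_burnin=10, n_iter=20,
                                                     thin=1, seed=0))

    def test_species_task_means(self):
        design = make_design({"A": 2}, [("b1", "d1", "binomial", 2),
                                        ("r1", "d1", "rank", 1)])
        dataset = mm.Dataset(
            design=design,
            binomial_obs={("A1", "b1", 0): 1, ("A1", "b1", 1): 1,
                          ("A2", "b1", 0): 0, ("A2", "b1", 1): 1},
            score_obs={("A1", "r1"): 2.0, ("A2", "r1"): 4.0},
        )
        means = species_task_means(dataset)
        assert means[("A", "b1")] == pytest.approx(0.75)
        assert means[("A", "r1")] == pytest.approx(3.0)

    def test_affine_rescaling_of_scores_is_invariant(self, m3_dataset):
        dataset, _ = m3_dataset
        mcmc = mm.McmcConfig(n_burnin=200, n_iter=1_000, thin=2, seed=12)
        spec = mm.ModelSpec.from_name("M3")
        base = mm.ranks_of_means_analysis(dataset, spec, mcmc)
        rescaled = mm.Dataset(
            design=dataset.design,
            binomial_obs=dataset.binomial_obs,
            score_obs={k: 5.0 * v + 2.0 for k, v in dataset.score_obs.items()},
        )
        again = mm.ranks_of_means_analysis(rescaled, spec, mcmc)
        assert base.mean == again.mean

    def test_means_level_shrinks_error_share(self, m3_dataset, m3_fit_small):
        """Averaging to species level removes the subject-level noise, so
        the error share of the latent variance drops relative to the
        trial-level fit (and the structured shares grow)."""
        dataset, _ = m3_dataset
        trial_row = mm.variance_proportions(m3_fit_small)
        means_row = mm.ranks_of_means_analysis(
            dataset, mm.ModelSpec.from_name("M3"),
            mm.McmcConfig(n_burnin=500, n_iter=4_000, thin=4, seed=13))
        assert means_row.mean["error"] < trial_row.mean["error"]
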