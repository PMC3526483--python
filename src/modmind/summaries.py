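"""Inferential outputs beyond the variance table.

* combined species + species-by-domain effect draws ``g[s, d] = a_s + b_{s,d}``
  (the quantity whose per-domain posterior densities show which species a
  domain favours);
* per-domain pairwise dominance matrices ``P[s, s'] = Pr(g_{s,d} > g_{s',d})``;
* the reduced-species re-analysis (a robustness check against experimenter
  confounding: refit on a species subset);
* the ranks-of-species-level-means re-analysis, which collapses the data to
  one mean per species and task, ranks species within each task, and fits
  the rank-likelihood-only model at the species level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import Dataset, StudyDesign, TaskDef
from .errors import AssessmentError, ModelSpecError
from .model import ModelSpec, Priors
from .sampler import McmcConfig, PosteriorSamples, fit
from .assess import VarianceProportionRow, variance_proportions

__all__ = [
    "SPECIES_DISPLAY_ORDER",
    "CombinedEffectSamples",
    "DominanceMatrix",
    "combined_effects",
    "dominance_matrix",
    "subset_reanalysis",
    "ranks_of_means_analysis",
    "species_task_means",
    "plot_combined_effect_densities",
    "plot_dominance_matrices",
]

#: Display order for pairwise matrices: chimpanzees, bonobos, gorillas,
#: orangutans, spider monkeys, capuchin monkeys, long-tailed macaques.
SPECIES_DISPLAY_ORDER = ("CH", "BO", "GO", "OR", "SM", "CM", "LM")


@dataclass
class CombinedEffectSamples:
    """Draws of the combined species + species*domain effect per (s, d)."""

    species: list[str]
    domains: list[str]
    draws: np.ndarray  # (n_draws, S, D)

    def for_domain(self, domain: str) -> np.ndarray:
        return self.draws[:, :, self.domains.index(domain)]

    def summary(self) -> dict[tuple[str, str], dict[str, float]]:
        out = {}
        for i, sp in enumerate(self.species):
            for j, d in enumerate(self.domains):
                g = self.draws[:, i, j]
                out[(sp, d)] = {
                    "mean": float(g.mean()),
                    "ci_low": float(np.quantile(g, 0.025)),
                    "ci_high": float(np.quantile(g, 0.975)),
                }
        return out


@dataclass
class DominanceMatrix:
    """P[s, s'] = posterior probability the row species beats the column one."""

    domain: str
    species: list[str]
    matrix: np.ndarray  # (S, S), diagonal 0.5 by convention

    def prob(self, row_species: str, col_species: str) -> float:
        return float(self.matrix[self.species.index(row_species),
                                 self.species.index(col_species)])


def combined_effects(samples: PosteriorSamples) -> CombinedEffectSamples:
    """Per-draw sums ``a_s + b_{s,d}``; needs species and species*domain on."""
    spec = samples.spec
    if "species" not in spec.effects or "species_domain" not in spec.effects:
        raise AssessmentError(
            "combined effects need both species and species*domain effects")
    S, D = len(samples.species), len(samples.domains)
    a = samples.draws["species"]                     # (nd, S)
    b = samples.draws["species_domain"].reshape(-1, S, D)
    return CombinedEffectSamples(
        species=list(samples.species), domains=list(samples.domains),
        draws=a[:, :, None] + b,
    )


def dominance_matrix(combined: CombinedEffectSamples, domain: str,
                     species_order=None) -> DominanceMatrix:
    """Empirical pairwise dominance probabilities within one domain.

    Exact ties (possible only for degenerate draws) split as one half to
    each side, preserving antisymmetry; the diagonal is 0.5 by convention.
    """
    if combined.draws.shape[0] < 500:
        raise AssessmentError("dominance matrices need >= 500 draws")
    order = [sp for sp in (species_order or SPECIES_DISPLAY_ORDER)
             if sp in combined.species]
    if not order:
        order = list(combined.species)
    g = combined.for_domain(domain)
    cols = [combined.species.index(sp) for sp in order]
    g = g[:, cols]
    S = len(order)
    P = np.full((S, S), 0.5)
    for i in range(S):
        for j in range(i + 1, S):
            gt = float(np.mean(g[:, i] > g[:, j]))
            eq = float(np.mean(g[:, i] == g[:, j]))
            P[i, j] = gt + 0.5 * eq
            P[j, i] = 1.0 - P[i, j]
    return DominanceMatrix(domain=domain, species=order, matrix=P)


def subset_reanalysis(dataset: Dataset, species_subset, spec: ModelSpec,
                      mcmc: McmcConfig, priors: Priors = Priors(),
                      ) -> VarianceProportionRow:
    """Refit on a species subset and return its variance-proportion row."""
    subset = [sp for sp in dataset.design.species if sp in set(species_subset)]
    if spec.active("species") and len(subset) < 2:
        raise ModelSpecError("species effects need a subset of >= 2 species")
    if not subset:
        raise ModelSpecError("empty species subset")
    filtered = dataset.filter_species(subset)
    samples = fit(filtered, spec, mcmc, priors)
    return variance_proportions(samples)


def species_task_means(dataset: Dataset) -> dict[tuple[str, str], float]:
    """Species-level mean performance per task.

    Unweighted mean over subjects of the per-subject success proportion
    (binomial tasks) or score (rank tasks).
    """
    design = dataset.design
    species_of = design.species_of
    acc: dict[tuple[str, str], list[float]] = {}
    per_subject: dict[tuple[str, str], list[int]] = {}
    for (sid, tid, _), y in dataset.binomial_obs.items():
        per_subject.setdefault((sid, tid), []).append(y)
    for (sid, tid), ys in per_subject.items():
        acc.setdefault((species_of[sid], tid), []).append(
            float(np.mean(ys)))
    for (sid, tid), x in dataset.score_obs.items():
        acc.setdefault((species_of[sid], tid), []).append(float(x))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _species_level_dataset(dataset: Dataset) -> Dataset:
    """Collapse to one pseudo-subject per species with all tasks rank-type."""
    design = dataset.design
    means = species_task_means(dataset)
    tasks = tuple(replace(t, response_type="rank", n_trials=1)
                  for t in design.tasks)
    subjects = tuple((sp, sp) for sp in design.species)
    participation = frozenset(means)
    sl_design = StudyDesign(species=design.species, subjects=subjects,
                            tasks=tasks, participation=participation)
    return Dataset(design=sl_design, binomial_obs={}, score_obs=dict(means))


def ranks_of_means_analysis(dataset: Dataset, spec: ModelSpec,
                            mcmc: McmcConfig, priors: Priors = Priors(),
                            ) -> VarianceProportionRow:
    """Fit the rank-likelihood-only model to ranks of species-level means.

    Species mean performance per task is ranked across species within each
    task (ties allowed) and modelled at the species level; individual
    effects make no sense here (one pseudo-subject per species) and raise
    a :class:`ModelSpecError`.  Invariant to monotone rescaling of
    rank-task scores, since only within-task orderings survive the
    collapse.
    """
    if spec.active("individual") or spec.active("individual_domain"):
        raise ModelSpecError(
            "ranks-of-means analysis has no individual-level data; "
            "individual effects are not allowed")
    collapsed = _species_level_dataset(dataset)
    samples = fit(collapsed, spec, mcmc, priors)
    row = variance_proportions(samples)
    row.model = f"{spec.name} [ranks of species means]"
    return row


# ---------------------------------------------------------------------------
# Figure-style outputs (plotting only; inference always uses raw draws)
# ---------------------------------------------------------------------------

def plot_combined_effect_densities(combined: CombinedEffectSamples, path) -> None:
    """Kernel-density panels of g[s, d] per domain (Silverman bandwidth)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    D = len(combined.domains)
    fig, axes = plt.subplots(1, D, figsize=(4 * D, 3.2), squeeze=False)
    for j, dom in enumerate(combined.domains):
        ax = axes[0, j]
        for i, sp in enumerate(combined.species):
            g = combined.draws[:, i, j]
            kde = gaussian_kde(g)
            xs = np.linspace(g.min() - 0.5, g.max() + 0.5, 200)
            ax.plot(xs, kde(xs), label=sp)
        ax.set_title(dom)
        ax.set_xlabel("combined effect")
    axes[0, 0].set_ylabel("posterior density")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dominance_matrices(matrices: list[DominanceMatrix], path) -> None:
    """Image plots of the per-domain pairwise dominance probabilities."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    D = len(matrices)
    fig, axes = plt.subplots(1, D, figsize=(3.4 * D, 3.2), squeeze=False)
    for j, dm in enumerate(matrices):
        ax = axes[0, j]
        im = ax.imshow(dm.matrix, vmin=0, vmax=1, cmap="PiYG")
        ax.set_xticks(range(len(dm.species)), dm.species, fontsize=7)
        ax.set_yticks(range(len(dm.species)), dm.species, fontsize=7)
        ax.set_title(dm.domain)
    fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.8,
                 label="P(row beats column)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
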