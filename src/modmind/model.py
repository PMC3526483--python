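"""Latent-variable model for mixed binomial/rank task batteries.

Each observed response is driven by a latent performance variable

    theta[i, k] = mu_k + a_s(i) + b_s(i),d(k) + c_i + e_i,d(k) + eps[i, k]

with task intercepts ``mu_k`` (task difficulty), Gaussian random effects for
species (``a``), species-by-domain (``b``), individual (``c``) and
individual-by-domain (``e``), and a Gaussian error term ``eps`` whose
variance is either shared across tasks ("constant", label ``0``) or
task-specific with a common hierarchical scale (label ``J``).

Binomial tasks observe ``n_trials`` Bernoulli outcomes with success
probability ``Phi(theta)`` (probit link; each trial carries unit latent
noise, which fixes the scale).  Rank tasks observe only the weak ordering
of ``theta`` across subjects: higher latent value means better rank, and
tied ranks impose no ordering constraint.

The nine model variants M0-M8 switch random-effect subsets
({}, {S}, {S,SD}, {S,I}, {S,SD,I,ID}) against the two error structures,
minus the no-effect/task-specific combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

from .design import Dataset, RankVector, scores_to_ranks
from .errors import DatasetError, InactiveEffectError, ModelSpecError

__all__ = [
    "EFFECTS",
    "ModelSpec",
    "Priors",
    "CellIndex",
    "ModelState",
    "model_grid",
    "loglik_binomial",
    "rank_consistent",
    "full_conditional_effect",
    "linear_predictor",
    "gaussian_layer_logpdf",
]

#: Random-effect levels in canonical order.
EFFECTS = ("species", "species_domain", "individual", "individual_domain")

_EFFECT_LABELS = {
    frozenset(): "0",
    frozenset({"species"}): "S",
    frozenset({"species", "species_domain"}): "SD",
    frozenset({"species", "individual"}): "SI",
    frozenset(EFFECTS): "SDID",
}
_ERROR_LABELS = {"constant": "0", "task_specific": "J"}


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects are on, and the error-variance structure."""

    effects: frozenset[str]
    error_structure: str = "constant"

    def __post_init__(self):
        bad = self.effects - set(EFFECTS)
        if bad:
            raise ModelSpecError(f"unknown effects {sorted(bad)}")
        if self.error_structure not in _ERROR_LABELS:
            raise ModelSpecError(
                f"error_structure must be 'constant' or 'task_specific', "
                f"got {self.error_structure!r}"
            )

    @property
    def effect_label(self) -> str:
        lab = _EFFECT_LABELS.get(self.effects)
        if lab is None:
            lab = "+".join(e for e in EFFECTS if e in self.effects)
        return lab

    @property
    def name(self) -> str:
        """Canonical name, e.g. ``"M3 (SD,0)"`` for grid members."""
        key = (self.effect_label, _ERROR_LABELS[self.error_structure])
        for i, spec in enumerate(model_grid()):
            if spec == self:
                return f"M{i} ({key[0]},{key[1]})"
        return f"custom ({key[0]},{key[1]})"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        """Parse ``"M3 (SD,0)"`` or the bare ``"M3"``."""
        token = name.strip().split(" ")[0]
        grid = model_grid()
        if token.startswith("M") and token[1:].isdigit():
            idx = int(token[1:])
            if 0 <= idx < len(grid):
                spec = grid[idx]
                if name.strip() not in (token, spec.name):
                    raise ModelSpecError(f"{name!r} does not match {spec.name!r}")
                return spec
        raise ModelSpecError(f"unknown model name {name!r}")

    def active(self, level: str) -> bool:
        return level in self.effects


def model_grid() -> list[ModelSpec]:
    """The nine fitted variants M0-M8, in canonical (Table-style) order."""
    subsets = [
        frozenset(),
        frozenset({"species"}),
        frozenset({"species", "species_domain"}),
        frozenset({"species", "individual"}),
        frozenset(EFFECTS),
    ]
    grid = [ModelSpec(subsets[0], "constant")]
    for sub in subsets[1:]:
        grid.append(ModelSpec(sub, "constant"))
        grid.append(ModelSpec(sub, "task_specific"))
    return grid


@dataclass(frozen=True)
class Priors:
    """Prior settings (all on the latent theta scale).

    Effect variances default to a half-Cauchy prior on each effect
    standard deviation (scale ``effect_sd_scale``, default 1 = the total
    latent scale), implemented as a conjugate inverse-gamma scale
    mixture.  The battery mixes components living on very different
    scales — a 7-level species variance near 0.17 next to individual
    terms near 0.01 — and no single inverse-gamma scale calibrates both:
    a small scale lets the weakly identified species variance collapse
    into the interaction row-means, a large one inflates the near-zero
    components.  The half-Cauchy's mass at zero plus slow tail keeps
    both honest in recovery experiments.
    ``effect_var_prior="inv_gamma"`` switches to a plain
    Inverse-Gamma(shape, scale) prior.

    The error variance is well identified (one scale pooled over every
    observation) and keeps a conjugate Inverse-Gamma(shape, scale) prior
    with a small scale.  Task intercepts get a diffuse
    Normal(0, task_intercept_var) prior.  Under the task-specific error
    structure each sigma2_E[k] is Inverse-Gamma with a shared scale
    hyperparameter carrying a conjugate Gamma hyperprior.
    """

    effect_var_prior: str = "half_cauchy"
    effect_sd_scale: float = 1.0
    effect_var_shape: float = 1.0
    effect_var_scale: float = 0.01
    error_var_shape: float = 1.0
    error_var_scale: float = 0.01
    task_intercept_var: float = 100.0
    task_error_shape: float = 2.0
    error_scale_hyper_shape: float = 1.0
    error_scale_hyper_rate: float = 1.0

    def __post_init__(self):
        if self.effect_var_prior not in ("half_cauchy", "inv_gamma"):
            raise ModelSpecError(
                f"unknown effect_var_prior {self.effect_var_prior!r}")


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def loglik_binomial(theta: float, outcomes) -> float:
    """Log-likelihood of i.i.d. probit trials at a common latent value.

    ``sum_t [y_t log Phi(theta) + (1 - y_t) log(1 - Phi(theta))]``,
    evaluated through ``log_ndtr`` so it stays finite and accurate for
    latent values far into either tail.
    """
    y = np.asarray(outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float(n1 * log_ndtr(theta) + n0 * log_ndtr(-theta))


def rank_consistent(w: dict[str, float], ranks: RankVector) -> bool:
    """True iff latent values respect the observed weak ordering.

    Rank 1 is best and corresponds to the largest latent value; tied
    subjects impose no constraint on each other.
    """
    if set(w) != set(ranks.ranks):
        raise DatasetError("latent values and ranks cover different subjects")
    items = list(ranks.ranks.items())
    for i, (si, ri) in enumerate(items):
        for sj, rj in items[i + 1:]:
            if ri < rj and not w[si] > w[sj]:
                return False
            if rj < ri and not w[sj] > w[si]:
                return False
    return True


# ---------------------------------------------------------------------------
# Canonical indexing of a dataset (shared by full conditionals and sampler)
# ---------------------------------------------------------------------------

@dataclass
class CellIndex:
    """Flat canonical arrays for one dataset.

    Subjects and tasks are sorted lexicographically, and observed
    (subject, task) cells are enumerated in sorted order, so every update
    iterates in a canonical order independent of input row order.
    """

    subject_ids: list[str]
    task_ids: list[str]
    species: list[str]
    domains: list[str]
    subj_species: np.ndarray        # (N,) species index per subject
    task_domain: np.ndarray         # (K,) domain index per task
    task_is_rank: np.ndarray        # (K,) bool
    cell_subj: np.ndarray           # (Nc,)
    cell_task: np.ndarray           # (Nc,)
    trial_cell: np.ndarray          # (Nt,) cell index of each binomial trial
    trial_y: np.ndarray             # (Nt,) outcomes 0/1
    rank_orders: dict[int, tuple[np.ndarray, np.ndarray]]
    # task index -> (cell indices in rank order best-first, group start offsets)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.task_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_cells(self) -> int:
        return len(self.cell_subj)

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "CellIndex":
        design = dataset.design
        subject_ids = sorted(design.subject_ids)
        task_ids = sorted(design.task_ids)
        species = list(design.species)
        domains = list(design.domains)
        sidx = {s: i for i, s in enumerate(subject_ids)}
        tidx = {t: i for i, t in enumerate(task_ids)}
        spidx = {s: i for i, s in enumerate(species)}
        didx = {d: i for i, d in enumerate(domains)}
        species_of = design.species_of
        dom_map = design.domain_map
        subj_species = np.array([spidx[species_of[s]] for s in subject_ids])
        task_domain = np.array([didx[dom_map[t]] for t in task_ids])
        task_is_rank = np.array(
            [design.task(t).response_type == "rank" for t in task_ids]
        )
        pairs = sorted(dataset.observed_pairs())
        cell_of = {p: i for i, p in enumerate(pairs)}
        cell_subj = np.array([sidx[s] for s, _ in pairs], dtype=np.intp)
        cell_task = np.array([tidx[t] for _, t in pairs], dtype=np.intp)
        trials = sorted(dataset.binomial_obs.items())
        trial_cell = np.array(
            [cell_of[(s, t)] for (s, t, _), _ in trials], dtype=np.intp
        )
        trial_y = np.array([y for _, y in trials], dtype=np.int8)
        rank_orders: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for t in task_ids:
            if design.task(t).response_type != "rank":
                continue
            scored = [s for (s, tt) in dataset.score_obs if tt == t]
            if not scored:
                continue
            rv = scores_to_ranks(dataset, t)
            order = []
            starts = [0]
            for group in rv.groups():
                order.extend(cell_of[(s, t)] for s in group)
                starts.append(len(order))
            rank_orders[tidx[t]] = (
                np.array(order, dtype=np.intp),
                np.array(starts, dtype=np.intp),
            )
        return cls(
            subject_ids, task_ids, species, domains, subj_species, task_domain,
            task_is_rank, cell_subj, cell_task, trial_cell, trial_y, rank_orders,
        )

    # Per-cell group indices for each effect level.
    def cell_group(self, level: str) -> np.ndarray:
        if level == "species":
            return self.subj_species[self.cell_subj]
        if level == "species_domain":
            return (
                self.subj_species[self.cell_subj] * self.n_domains
                + self.task_domain[self.cell_task]
            )
        if level == "individual":
            return self.cell_subj
        if level == "individual_domain":
            return self.cell_subj * self.n_domains + self.task_domain[self.cell_task]
        if level == "task_intercept":
            return self.cell_task
        raise ModelSpecError(f"unknown level {level!r}")

    def n_coefficients(self, level: str) -> int:
        return {
            "species": self.n_species,
            "species_domain": self.n_species * self.n_domains,
            "individual": self.n_subjects,
            "individual_domain": self.n_subjects * self.n_domains,
            "task_intercept": self.n_tasks,
        }[level]


@dataclass
class ModelState:
    """One full parameter configuration (a Gibbs-sampler state)."""

    mu: np.ndarray                          # (K,) task intercepts
    effects: dict[str, np.ndarray]          # flat coefficient vectors per level
    var: dict[str, float]                   # effect variances
    var_error: float | np.ndarray           # scalar or per-task (K,)
    error_scale: float                      # shared scale hyperparameter (J)
    theta: np.ndarray                       # (Nc,) latent performance per cell
    z: np.ndarray | None = None             # (Nt,) trial augmentation variables
    lam: dict[str, float] | None = None     # half-Cauchy mixing scales per level

    def error_var_by_task(self, index: CellIndex) -> np.ndarray:
        v = self.var_error
        if np.ndim(v) == 0:
            return np.full(index.n_tasks, float(v))
        return np.asarray(v, dtype=float)

    def cell_error_var(self, index: CellIndex) -> np.ndarray:
        """Per-cell latent error variance.

        Rank tasks observe only an ordering, which carries no scale
        information; their latent scale is therefore fixed at 1 (the
        standard rank-likelihood convention), while binomial cells use
        the estimated error variance.  Without the fixed scale the
        order-constrained latent block can compress onto the linear
        predictor and certify an arbitrarily small error variance — a
        degenerate mode the augmented sampler cannot leave.
        """
        v = self.error_var_by_task(index)[index.cell_task]
        return np.where(index.task_is_rank[index.cell_task], 1.0, v)

    def copy(self) -> "ModelState":
        return ModelState(
            mu=self.mu.copy(),
            effects={k: v.copy() for k, v in self.effects.items()},
            var=dict(self.var),
            var_error=(
                float(self.var_error)
                if np.ndim(self.var_error) == 0
                else np.array(self.var_error)
            ),
            error_scale=self.error_scale,
            theta=self.theta.copy(),
            z=None if self.z is None else self.z.copy(),
            lam=None if self.lam is None else dict(self.lam),
        )


def linear_predictor(state: ModelState, index: CellIndex,
                     exclude: str | None = None) -> np.ndarray:
    """Per-cell model mean mu_k + active effects, optionally omitting one level."""
    m = state.mu[index.cell_task].astype(float).copy()
    if exclude == "task_intercept":
        m[:] = 0.0
    for level, coefs in state.effects.items():
        if level == exclude:
            continue
        m += coefs[index.cell_group(level)]
    return m


def full_conditional_effect(level: str, state: ModelState, dataset: Dataset,
                            priors: Priors = Priors(),
                            index: CellIndex | None = None):
    """Exact conjugate Normal full conditional for every coefficient at one level.

    Returns ``(mean, variance)`` arrays over the level's coefficients:
    precision = prior precision + sum of residual precisions over the
    coefficient's observed cells; mean = precision-weighted residual
    average.  A coefficient with no attached observations returns its
    prior.  Raises :class:`InactiveEffectError` if the level is not in the
    state.

    For ``task_intercept`` this is the unconstrained Gaussian-layer
    conditional for every task; the sampler additionally pins rank-task
    intercepts at zero (an ordering carries no location information).
    """
    if index is None:
        index = CellIndex.from_dataset(dataset)
    if level == "task_intercept":
        prior_var = priors.task_intercept_var
    elif level in state.effects:
        prior_var = state.var[level]
    else:
        raise InactiveEffectError(f"effect level {level!r} is not active")
    n_coef = index.n_coefficients(level)
    group = index.cell_group(level)
    resid = state.theta - linear_predictor(state, index, exclude=level)
    w = 1.0 / state.cell_error_var(index)
    prec = 1.0 / prior_var + np.bincount(group, weights=w, minlength=n_coef)
    mean = np.bincount(group, weights=w * resid, minlength=n_coef) / prec
    return mean, 1.0 / prec


def gaussian_layer_logpdf(state: ModelState, dataset: Dataset,
                          priors: Priors = Priors(),
                          index: CellIndex | None = None) -> float:
    """Joint log-density of the Gaussian layers (theta | effects, effects, mu).

    Conditional on theta, the trial-augmentation and rank-constraint terms
    do not involve the effects, so this is the exact target whose full
    conditionals :func:`full_conditional_effect` must match — the
    finite-difference oracle in the tests differentiates this function.
    """
    if index is None:
        index = CellIndex.from_dataset(dataset)
    m = linear_predictor(state, index)
    s2 = state.cell_error_var(index)
    out = float(np.sum(-0.5 * np.log(2 * np.pi * s2) - 0.5 * (state.theta - m) ** 2 / s2))
    for level, coefs in state.effects.items():
        v = state.var[level]
        out += float(np.sum(-0.5 * np.log(2 * np.pi * v) - 0.5 * coefs ** 2 / v))
    tau2 = priors.task_intercept_var
    out += float(np.sum(-0.5 * np.log(2 * np.pi * tau2) - 0.5 * state.mu ** 2 / tau2))
    return out
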