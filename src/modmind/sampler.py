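"""Blocked Gibbs sampler for the probit/rank latent-variable model.

One sweep updates, in a fixed documented order:

1. trial augmentation variables ``z`` from truncated normals given theta
   and the 0/1 outcomes (sign of ``z`` matches the outcome);
2. rank-task latent values from truncated normals respecting the observed
   weak ordering (tied subjects impose no constraint on each other; the
   chain of rank groups is updated in two alternating blocks, which are
   conditionally independent given the other parity);
3. binomial-cell latents theta from their conjugate normal conditional
   given the trial augmentation and the model mean;
4. each active random-effect block from its conjugate normal conditional;
5. task intercepts mu_k;
6. each effect variance from its conjugate inverse-gamma conditional;
7. the error variance (scalar, or per-task plus the shared scale
   hyperparameter under the task-specific structure).

Entities are iterated in sorted canonical order, so results are
bit-reproducible for a given seed regardless of input row order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .design import Dataset
from .errors import ModelSpecError, ModmindError
from .model import (
    EFFECTS,
    CellIndex,
    ModelSpec,
    ModelState,
    Priors,
    linear_predictor,
)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "GibbsSampler",
    "fit",
    "sample_truncated_normal",
    "diagnostics",
]


# ---------------------------------------------------------------------------
# Truncated-normal sampling
# ---------------------------------------------------------------------------

_FAR_TAIL = 36.0  # beyond this, ndtr underflows; switch to rejection


def _tail_rejection(rng, a, b):
    """Draws from the standard normal truncated to (a, b) with a huge.

    Robert's method: propose ``a + Exp(1)/a`` and accept with probability
    ``exp(-(x - a)^2 / 2)``; exact for any a > 0 and essentially
    rejection-free for large a.
    """
    out = np.empty_like(a)
    todo = np.arange(a.size)
    for _ in range(10_000):
        if not todo.size:
            break
        aa = a[todo]
        x = aa + rng.exponential(size=todo.size) / aa
        ok = (x < b[todo]) & (rng.random(todo.size)
                              <= np.exp(-0.5 * (x - aa) ** 2))
        out[todo[ok]] = x[ok]
        todo = todo[~ok]
    if todo.size:  # pathologically narrow far-tail interval
        out[todo] = a[todo] + 0.5 * (np.minimum(b[todo], a[todo] + 1) - a[todo])
    return out


def _truncnorm_std(rng, a, b):
    """Standard-normal draws truncated to (a, b), elementwise.

    Inverse-CDF, evaluated in whichever tail keeps the CDF values well
    away from 1 (``ndtr(-x)`` resolves tail probabilities down to
    ~1e-308, i.e. ~37 standard deviations); regions even further out are
    drawn exactly by an exponential rejection sampler.
    """
    a, b = np.broadcast_arrays(np.asarray(a, dtype=float),
                               np.asarray(b, dtype=float))
    shape = a.shape
    a = np.atleast_1d(a).ravel()
    b = np.atleast_1d(b).ravel()
    u = rng.random(a.shape)
    out = np.empty_like(u)
    upper_tail = a >= 0
    lower_tail = (~upper_tail) & (b <= 0)
    central = ~(upper_tail | lower_tail)
    if np.any(upper_tail):
        aa, bb, uu = a[upper_tail], b[upper_tail], u[upper_tail]
        res = np.empty_like(aa)
        far = aa > _FAR_TAIL
        if np.any(far):
            res[far] = _tail_rejection(rng, aa[far], bb[far])
        near = ~far
        if np.any(near):
            pa = ndtr(-aa[near])
            pb = ndtr(-bb[near])  # 0 when bb = +inf
            p = np.clip(pb + uu[near] * (pa - pb), 1e-300, 1.0)
            res[near] = -ndtri(p)
        out[upper_tail] = res
    if np.any(lower_tail):
        aa, bb, uu = a[lower_tail], b[lower_tail], u[lower_tail]
        res = np.empty_like(aa)
        far = bb < -_FAR_TAIL
        if np.any(far):
            res[far] = -_tail_rejection(rng, -bb[far], -aa[far])
        near = ~far
        if np.any(near):
            pa = ndtr(aa[near])  # 0 when aa = -inf
            pb = ndtr(bb[near])
            p = np.clip(pa + uu[near] * (pb - pa), 1e-300, 1.0)
            res[near] = ndtri(p)
        out[lower_tail] = res
    if np.any(central):
        aa, bb, uu = a[central], b[central], u[central]
        pa = ndtr(aa)
        pb = ndtr(bb)
        p = np.clip(pa + uu * (pb - pa), 1e-300, 1 - 1e-16)
        out[central] = ndtri(p)
    return out.reshape(shape)


def sample_truncated_normal(mean, sd, lower, upper, rng):
    """Exact draws from Normal(mean, sd^2) truncated to (lower, upper).

    Bounds may be infinite; shapes broadcast.  Raises
    :class:`ModelSpecError` unless ``lower < upper`` and ``sd > 0``
    everywhere.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not np.all(lower < upper):
        raise ModelSpecError("truncation requires lower < upper")
    if not np.all(sd > 0):
        raise ModelSpecError("sd must be > 0")
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    draw = mean + sd * _truncnorm_std(rng, a, b)
    if draw.ndim == 0:
        return float(draw)
    return draw


def _inv_gamma(rng, shape, scale):
    """Inverse-Gamma(shape, scale) draw: scale / Gamma(shape, 1)."""
    return float(scale / rng.gamma(shape, 1.0))


def _slice_sample(logpdf, x0: float, rng, width: float = 1.0,
                  max_steps: int = 30) -> float:
    """Univariate slice sampler (stepping out + shrinkage)."""
    y = logpdf(x0) + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - width * u, x0 + width * (1.0 - u)
    steps = max_steps
    while steps > 0 and logpdf(lo) > y:
        lo -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and logpdf(hi) > y:
        hi += width
        steps -= 1
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logpdf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


# ---------------------------------------------------------------------------
# Configuration and output containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """MCMC run settings; ``init`` is ``data_informed`` or ``prior_draw``."""

    n_burnin: int = 2_000
    n_iter: int = 20_000
    thin: int = 5
    seed: int = 0
    init: str = "data_informed"

    def __post_init__(self):
        if self.n_burnin < 0 or self.n_iter <= 0 or self.thin < 1:
            raise ModelSpecError("invalid MCMC sizes")
        if self.init not in ("data_informed", "prior_draw"):
            raise ModelSpecError(f"unknown init {self.init!r}")

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcConfig":
        """Desktop-scale preset: 2,000 burn-in + 20,000 iterations, thin 5."""
        return cls(n_burnin=2_000, n_iter=20_000, thin=5, seed=seed)

    @classmethod
    def full(cls, seed: int = 0) -> "McmcConfig":
        """Full-precision preset: 50,000 burn-in + 3,000,000 iterations."""
        return cls(n_burnin=50_000, n_iter=3_000_000, thin=300, seed=seed)

    @property
    def n_stored(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorSamples:
    """Stored MCMC draws with provenance.

    ``draws`` maps parameter names to arrays whose leading axis is the
    draw index: ``task_intercept`` (nd, K), each active effect level
    (nd, n_coefficients), ``var_<level>`` (nd,), ``var_error`` (nd,) or
    (nd, K), ``error_scale`` (nd,) for the task-specific structure, and
    ``theta`` (nd, Nc).
    """

    spec: ModelSpec
    mcmc: McmcConfig
    draws: dict[str, np.ndarray]
    subject_ids: list[str]
    task_ids: list[str]
    species: list[str]
    domains: list[str]
    cells: list[tuple[str, str]]
    dataset_hash: str = ""
    rank_task_ids: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def active_variance_names(self) -> list[str]:
        names = [f"var_{lvl}" for lvl in EFFECTS if lvl in self.spec.effects]
        return names + ["var_error"]

    def error_variance_draws(self) -> np.ndarray:
        """Per-draw error variance entering the variance proportions.

        Task-specific variances average over the binomial tasks.  If the
        fit contained only rank tasks the error variance is the fixed
        unit latent scale of the rank likelihood (the sampled parameter
        is then prior-only and meaningless).
        """
        binom = [t for t in self.task_ids if t not in set(self.rank_task_ids)]
        v = self.draws["var_error"]
        if not binom:
            return np.ones(v.shape[0])
        if v.ndim == 1:
            return v
        cols = [self.task_ids.index(t) for t in binom]
        return v[:, cols].mean(axis=1)

    def save(self, path) -> None:
        """Self-describing .npz archive (arrays + JSON metadata)."""
        meta = {
            "model": self.spec.name,
            "effects": sorted(self.spec.effects),
            "error_structure": self.spec.error_structure,
            "mcmc": {
                "n_burnin": self.mcmc.n_burnin,
                "n_iter": self.mcmc.n_iter,
                "thin": self.mcmc.thin,
                "seed": self.mcmc.seed,
                "init": self.mcmc.init,
            },
            "subject_ids": self.subject_ids,
            "task_ids": self.task_ids,
            "species": self.species,
            "domains": self.domains,
            "cells": [list(c) for c in self.cells],
            "dataset_hash": self.dataset_hash,
            "rank_task_ids": list(self.rank_task_ids),
        }
        np.savez_compressed(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.draws)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path) as zf:
            meta = json.loads(bytes(zf["_meta"]).decode())
            draws = {k: zf[k] for k in zf.files if k != "_meta"}
        spec = ModelSpec(frozenset(meta["effects"]), meta["error_structure"])
        mcmc = McmcConfig(**meta["mcmc"])
        return cls(
            spec=spec, mcmc=mcmc, draws=draws,
            subject_ids=meta["subject_ids"], task_ids=meta["task_ids"],
            species=meta["species"], domains=meta["domains"],
            cells=[tuple(c) for c in meta["cells"]],
            dataset_hash=meta["dataset_hash"],
            rank_task_ids=tuple(meta.get("rank_task_ids", ())),
        )


def dataset_hash(dataset: Dataset) -> str:
    h = hashlib.sha256()
    for key in sorted(dataset.binomial_obs):
        h.update(repr((key, dataset.binomial_obs[key])).encode())
    for key2 in sorted(dataset.score_obs):
        h.update(repr((key2, dataset.score_obs[key2])).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class GibbsSampler:
    """Reusable Gibbs kernel bound to one dataset and model specification.

    ``fit`` drives it for routine use; the kernel itself (``init_state``,
    ``sweep``, ``resample_data``) is public so joint-distribution
    correctness checks (successive-conditional simulation) can alternate
    parameter and data updates.
    """

    def __init__(self, dataset: Dataset, spec: ModelSpec,
                 priors: Priors = Priors()):
        self.dataset = dataset
        self.spec = spec
        self.priors = priors
        self.idx = CellIndex.from_dataset(dataset)
        idx = self.idx
        for level in spec.effects:
            if level == "species" and idx.n_species < 2:
                raise ModelSpecError("species effect needs >= 2 species")
            if level == "species_domain" and (idx.n_species < 2 or idx.n_domains < 2):
                raise ModelSpecError("species*domain effect needs >= 2 of each")
            if level == "individual" and idx.n_subjects < 2:
                raise ModelSpecError("individual effect needs >= 2 subjects")
            if level == "individual_domain" and (
                    idx.n_subjects < 2 or idx.n_domains < 2):
                raise ModelSpecError("individual*domain effect needs >= 2 of each")
        self.levels = [lvl for lvl in EFFECTS if lvl in spec.effects]
        self._groups = {lvl: idx.cell_group(lvl) for lvl in self.levels}
        self._groups["task_intercept"] = idx.cell_group("task_intercept")
        self._ncoef = {lvl: idx.n_coefficients(lvl)
                       for lvl in self.levels + ["task_intercept"]}
        self._trials_per_cell = np.bincount(
            idx.trial_cell, minlength=idx.n_cells).astype(float)
        self._binom_cells = np.flatnonzero(~idx.task_is_rank[idx.cell_task])
        self._cells_per_task = np.bincount(
            idx.cell_task, minlength=idx.n_tasks).astype(float)
        self._ysign = np.where(idx.trial_y > 0, 1.0, -1.0)
        # rank parity structures: per task, member positions and group ids
        self._rank_parity = {}
        for t, (order, starts) in idx.rank_orders.items():
            n_groups = len(starts) - 1
            grp_of_pos = np.repeat(np.arange(n_groups), np.diff(starts))
            parts = []
            for parity in (0, 1):
                sel = np.flatnonzero(grp_of_pos % 2 == parity)
                parts.append((sel, grp_of_pos[sel]))
            self._rank_parity[t] = (order, starts, parts)
        # cell grouping by trial count, for the marginalized error-variance
        # update (binomial cells with equal T share the same likelihood form)
        bc = self._binom_cells
        t_of_bc = self._trials_per_cell[bc].astype(int)
        self._binom_T_values = np.unique(t_of_bc)
        self._binom_T_group = np.searchsorted(self._binom_T_values, t_of_bc)
        self._rank_cells = np.flatnonzero(idx.task_is_rank[idx.cell_task])
        self.state: ModelState | None = None

    # -- initialisation ----------------------------------------------------
    def init_state(self, rng, mode: str = "data_informed") -> ModelState:
        idx, pr = self.idx, self.priors
        K, Nc = idx.n_tasks, idx.n_cells
        if mode == "data_informed":
            mu = np.zeros(K)
            ysum = np.bincount(idx.trial_cell, weights=idx.trial_y.astype(float),
                               minlength=Nc)
            tsum = np.bincount(idx.cell_task, weights=ysum, minlength=K)
            ttr = np.bincount(idx.cell_task, weights=self._trials_per_cell,
                              minlength=K)
            has = ttr > 0
            rate = np.clip(np.divide(tsum, ttr, out=np.full(K, 0.5), where=has),
                           0.02, 0.98)
            mu[has] = ndtri(rate[has])
            effects = {lvl: np.zeros(self._ncoef[lvl]) for lvl in self.levels}
            var = {lvl: 0.5 for lvl in self.levels}
            lam = {lvl: 1.0 for lvl in self.levels}
            var_error = (0.5 if self.spec.error_structure == "constant"
                         else np.full(K, 0.5))
            error_scale = 1.0
            theta = np.empty(Nc)
            with np.errstate(divide="ignore"):
                cell_rate = np.clip(
                    np.divide(ysum, self._trials_per_cell,
                              out=np.full(Nc, 0.5),
                              where=self._trials_per_cell > 0),
                    0.05, 0.95)
            theta[:] = ndtri(cell_rate)
        elif mode == "prior_draw":
            rng_ = rng
            if pr.effect_var_prior == "half_cauchy":
                lam = {lvl: _inv_gamma(rng_, 0.5, 1.0 / pr.effect_sd_scale ** 2)
                       for lvl in self.levels}
                var = {lvl: _inv_gamma(rng_, 0.5, 1.0 / lam[lvl])
                       for lvl in self.levels}
            else:
                lam = {lvl: 1.0 for lvl in self.levels}
                var = {lvl: _inv_gamma(rng_, pr.effect_var_shape,
                                       pr.effect_var_scale)
                       for lvl in self.levels}
            if self.spec.error_structure == "constant":
                var_error = _inv_gamma(rng_, pr.error_var_shape, pr.error_var_scale)
                error_scale = 1.0
            else:
                error_scale = rng_.gamma(pr.error_scale_hyper_shape,
                                         1.0 / pr.error_scale_hyper_rate)
                var_error = error_scale / rng_.gamma(
                    pr.task_error_shape, 1.0, size=K)
            mu = rng_.normal(0.0, np.sqrt(pr.task_intercept_var), size=K)
            mu[self.idx.task_is_rank] = 0.0
            effects = {lvl: rng_.normal(0.0, np.sqrt(var[lvl]),
                                        size=self._ncoef[lvl])
                       for lvl in self.levels}
            theta = None  # set below from the linear predictor
        else:
            raise ModelSpecError(f"unknown init mode {mode!r}")
        state = ModelState(mu=mu, effects=effects, var=var, var_error=var_error,
                           error_scale=error_scale,
                           theta=np.zeros(Nc) if theta is None else theta,
                           lam=lam)
        if mode == "prior_draw":
            m = linear_predictor(state, idx)
            sd = np.sqrt(state.cell_error_var(idx))
            state.theta = m + sd * rng.standard_normal(Nc)
        # make rank-task latents consistent with the observed weak ordering
        for t, (order, starts) in idx.rank_orders.items():
            vals = np.sort(state.theta[order])[::-1]
            state.theta[order] = vals
        self.state = state
        return state

    # -- one sweep ---------------------------------------------------------
    def sweep(self, rng) -> None:
        st = self.state
        idx, pr = self.idx, self.priors
        Nc, K = idx.n_cells, idx.n_tasks
        s2e_cell = st.cell_error_var(idx)

        # (1) trial augmentation: z ~ N(theta, 1) truncated by the outcome sign
        if idx.trial_cell.size:
            th_t = st.theta[idx.trial_cell]
            # y=1 -> (0, inf); y=0 -> (-inf, 0); in standardized units the
            # draw is sign * TN(-sign*theta, inf)
            zstd = _truncnorm_std(rng, -self._ysign * th_t,
                                  np.full(th_t.shape, np.inf))
            st.z = th_t + self._ysign * zstd

        m = linear_predictor(st, idx)

        # (2) rank-task latents: alternating-parity truncated normals
        # (unit latent scale: an ordering carries no scale information)
        for t, (order, starts, parts) in self._rank_parity.items():
            sd = 1.0
            mean_ord = m[order]
            for sel, grp in parts:
                w = st.theta[order]
                gmax = np.maximum.reduceat(w, starts[:-1])
                gmin = np.minimum.reduceat(w, starts[:-1])
                ub = np.concatenate(([np.inf], gmin[:-1]))[grp]
                lb = np.concatenate((gmax[1:], [-np.inf]))[grp]
                a = (lb - mean_ord[sel]) / sd
                b = (ub - mean_ord[sel]) / sd
                st.theta[order[sel]] = mean_ord[sel] + sd * _truncnorm_std(rng, a, b)

        # (3) error variance from its conditional with the binomial-cell
        # latents integrated out (see _update_error_variance_marginal),
        # then those latents from their conjugate normal given z-sums.
        # Sampling sigma2_E marginally and theta afterwards is one blocked
        # update; the naive conditional pair is a near-absorbing feedback
        # loop (small sigma2_E pins theta to the mean, which keeps
        # sigma2_E small) that can trap whole chains in a degenerate mode.
        bc = self._binom_cells
        zsum = np.bincount(idx.trial_cell, weights=st.z, minlength=Nc)[bc] \
            if bc.size else np.zeros(0)
        self._update_error_variance_marginal(rng, m, zsum)
        s2e_cell = st.cell_error_var(idx)
        if bc.size:
            prec = 1.0 / s2e_cell[bc] + self._trials_per_cell[bc]
            mean = (m[bc] / s2e_cell[bc] + zsum) / prec
            st.theta[bc] = mean + rng.standard_normal(bc.size) / np.sqrt(prec)

        # (4) active random-effect blocks, canonical order
        w_cell = 1.0 / s2e_cell
        for level in self.levels:
            group = self._groups[level]
            n = self._ncoef[level]
            old = st.effects[level]
            prec = 1.0 / st.var[level] + np.bincount(group, weights=w_cell,
                                                     minlength=n)
            r = st.theta - m + old[group]
            mean = np.bincount(group, weights=w_cell * r, minlength=n) / prec
            new = mean + rng.standard_normal(n) / np.sqrt(prec)
            m += new[group] - old[group]
            st.effects[level] = new

        # (5) task intercepts; rank tasks observe only an ordering, which
        # carries no location information, so their intercepts are fixed
        # at zero (otherwise they random-walk across the diffuse prior and
        # drag the order-constrained latent block with them)
        group = self._groups["task_intercept"]
        prec = 1.0 / pr.task_intercept_var + np.bincount(
            group, weights=w_cell, minlength=K)
        r = st.theta - m + st.mu[group]
        mean = np.bincount(group, weights=w_cell * r, minlength=K) / prec
        new_mu = mean + rng.standard_normal(K) / np.sqrt(prec)
        new_mu[idx.task_is_rank] = 0.0
        m += new_mu[group] - st.mu[group]
        st.mu = new_mu

        # (6) effect variances (plus half-Cauchy mixing scales by default)
        for level in self.levels:
            coefs = st.effects[level]
            ss = 0.5 * float(coefs @ coefs)
            if pr.effect_var_prior == "half_cauchy":
                shape = 0.5 + 0.5 * coefs.size
                scale = 1.0 / st.lam[level] + ss
                st.var[level] = scale / rng.gamma(shape, 1.0)
                st.lam[level] = (1.0 / pr.effect_sd_scale ** 2
                                 + 1.0 / st.var[level]) / rng.gamma(1.0, 1.0)
            else:
                shape = pr.effect_var_shape + 0.5 * coefs.size
                scale = pr.effect_var_scale + ss
                st.var[level] = scale / rng.gamma(shape, 1.0)

        # (7) shared error-scale hyperparameter under the J structure
        # (the per-task variances themselves were updated in step 3)
        if self.spec.error_structure == "task_specific":
            hyper_shape = (pr.error_scale_hyper_shape
                           + K * pr.task_error_shape)
            hyper_rate = (pr.error_scale_hyper_rate
                          + float(np.sum(1.0 / st.var_error)))
            st.error_scale = rng.gamma(hyper_shape, 1.0 / hyper_rate)

    def _update_error_variance_marginal(self, rng, m: np.ndarray,
                                        zsum: np.ndarray) -> None:
        """Draw the error variance given z (binomial-cell theta integrated out).

        For a binomial cell with T trials the augmentation vector is
        ``z ~ N(m 1, I + v J)`` once theta is marginalized (v = error
        variance, J the all-ones matrix), so with ``S = sum(z) - T m`` its
        contribution to the log-likelihood of v is
        ``-0.5 [log(1 + T v) - v S^2 / (1 + T v)]``.  Rank cells keep their
        explicit latent and contribute plain Gaussian residual terms.  The
        resulting one-dimensional posterior is sampled by slice sampling in
        log v (per task under the task-specific structure).
        """
        st, pr, idx = self.state, self.priors, self.idx
        bc = self._binom_cells
        S1 = zsum - self._trials_per_cell[bc] * m[bc] if bc.size else zsum

        if self.spec.error_structure == "constant":
            a0, b0 = pr.error_var_shape, pr.error_var_scale
            if not bc.size:
                # no binomial cells (rank latents have fixed unit scale):
                # the error variance reduces to its prior
                st.var_error = _inv_gamma(rng, a0, b0)
                return
            Tvals = self._binom_T_values.astype(float)
            SS1 = np.bincount(self._binom_T_group, weights=S1 * S1,
                              minlength=len(Tvals))
            nT = np.bincount(self._binom_T_group, minlength=len(Tvals)
                             ).astype(float)

            def logp(x):
                v = np.exp(x)
                opt = 1.0 + Tvals * v
                out = -a0 * x - b0 / v
                out -= 0.5 * float(np.sum(nT * np.log(opt) - v * SS1 / opt))
                return out

            x0 = float(np.log(st.var_error))
            st.var_error = float(np.exp(_slice_sample(logp, x0, rng)))
        else:
            K = idx.n_tasks
            new_v = np.asarray(st.error_var_by_task(idx)).copy()
            task_of_bc = idx.cell_task[bc]
            aE, bE = pr.task_error_shape, st.error_scale
            for k in range(K):
                in_k = task_of_bc == k
                if not in_k.any():
                    # rank task (fixed unit latent scale) or no data
                    new_v[k] = _inv_gamma(rng, aE, bE)
                    continue
                Tk = self._trials_per_cell[bc][in_k]
                S1k = S1[in_k]

                def logp(x, Tk=Tk, S1k=S1k):
                    v = np.exp(x)
                    opt = 1.0 + Tk * v
                    out = -aE * x - bE / v
                    out -= 0.5 * float(np.sum(np.log(opt) - v * S1k * S1k / opt))
                    return out

                x0 = float(np.log(new_v[k]))
                new_v[k] = float(np.exp(_slice_sample(logp, x0, rng)))
            st.var_error = new_v

    # -- data resampling (for successive-conditional correctness checks) ----
    def resample_data(self, rng) -> None:
        """Redraw the observations from the current state, in place.

        Binomial trials get fresh augmentation draws ``z ~ N(theta, 1)``
        whose signs become the new outcomes.  For rank tasks the observed
        ordering is a deterministic coarsening of the latent values, so the
        latents themselves are part of the augmentation: they are redrawn
        from ``N(model mean, sigma2_E)`` and the new weak ordering is read
        off the fresh draw.  (Without that refresh the ordering would be
        absorbing — latent updates always respect the current ordering —
        and a successive-conditional chain would never mix over rankings.)
        """
        idx = self.idx
        st = self.state
        if idx.trial_cell.size:
            z = st.theta[idx.trial_cell] + rng.standard_normal(idx.trial_cell.size)
            st.z = z
            idx.trial_y = (z > 0).astype(np.int8)
            self._ysign = np.where(idx.trial_y > 0, 1.0, -1.0)
        m = linear_predictor(st, idx)
        new_orders = {}
        for t, (order, starts) in idx.rank_orders.items():
            st.theta[order] = m[order] + rng.standard_normal(order.size)
            vals = st.theta[order]
            perm = np.argsort(-vals, kind="stable")
            new_order = order[perm]
            starts2 = np.arange(len(order) + 1, dtype=np.intp)  # no ties a.s.
            new_orders[t] = (new_order, starts2)
        idx.rank_orders = new_orders
        self._rank_parity = {}
        for t, (order, starts) in idx.rank_orders.items():
            n_groups = len(starts) - 1
            grp_of_pos = np.repeat(np.arange(n_groups), np.diff(starts))
            parts = []
            for parity in (0, 1):
                sel = np.flatnonzero(grp_of_pos % 2 == parity)
                parts.append((sel, grp_of_pos[sel]))
            self._rank_parity[t] = (order, starts, parts)

    def check_consistency(self) -> None:
        """Assert augmentation signs and rank orderings hold (debug aid)."""
        idx, st = self.idx, self.state
        if st.z is not None and idx.trial_cell.size:
            assert np.all((st.z > 0) == (idx.trial_y > 0)), "z-sign mismatch"
        for t, (order, starts) in idx.rank_orders.items():
            w = st.theta[order]
            gmin = np.minimum.reduceat(w, starts[:-1])
            gmax = np.maximum.reduceat(w, starts[:-1])
            assert np.all(gmin[:-1] > gmax[1:]), "rank ordering violated"


def fit(dataset: Dataset, spec: ModelSpec, mcmc: McmcConfig,
        priors: Priors = Priors(), check_every: int = 0) -> PosteriorSamples:
    """Fit one model variant by Gibbs sampling; deterministic given the seed."""
    sampler = GibbsSampler(dataset, spec, priors)
    idx = sampler.idx
    rng = np.random.default_rng(mcmc.seed)
    sampler.init_state(rng, mcmc.init)
    st = sampler.state
    n_stored = mcmc.n_stored
    K, Nc = idx.n_tasks, idx.n_cells
    draws: dict[str, np.ndarray] = {
        "task_intercept": np.empty((n_stored, K)),
        "theta": np.empty((n_stored, Nc)),
    }
    for level in sampler.levels:
        draws[level] = np.empty((n_stored, sampler._ncoef[level]))
        draws[f"var_{level}"] = np.empty(n_stored)
    if spec.error_structure == "constant":
        draws["var_error"] = np.empty(n_stored)
    else:
        draws["var_error"] = np.empty((n_stored, K))
        draws["error_scale"] = np.empty(n_stored)
    stored = 0
    total = mcmc.n_burnin + mcmc.n_iter
    for it in range(total):
        sampler.sweep(rng)
        if check_every and (it + 1) % check_every == 0:
            sampler.check_consistency()
            if not (np.all(np.isfinite(st.theta))
                    and np.all(np.isfinite(st.mu))):
                raise ModmindError(f"non-finite state at sweep {it + 1}")
        post = it - mcmc.n_burnin
        if post >= 0 and (post + 1) % mcmc.thin == 0 and stored < n_stored:
            draws["task_intercept"][stored] = st.mu
            draws["theta"][stored] = st.theta
            for level in sampler.levels:
                draws[level][stored] = st.effects[level]
                draws[f"var_{level}"][stored] = st.var[level]
            draws["var_error"][stored] = st.var_error
            if spec.error_structure == "task_specific":
                draws["error_scale"][stored] = st.error_scale
            stored += 1
    cells = sorted(dataset.observed_pairs())
    return PosteriorSamples(
        spec=spec, mcmc=mcmc,
        draws={k: v[:stored] for k, v in draws.items()},
        subject_ids=idx.subject_ids, task_ids=idx.task_ids,
        species=idx.species, domains=idx.domains, cells=cells,
        dataset_hash=dataset_hash(dataset),
        rank_task_ids=tuple(np.array(idx.task_ids)[idx.task_is_rank]),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _split_chain(x: np.ndarray) -> np.ndarray:
    half = x.size // 2
    return np.stack([x[:half], x[half:2 * half]])


def diagnostics(samples: PosteriorSamples, rhat_warn: float = 1.05) -> dict:
    """Effective sample size and split-R-hat per scalar model parameter.

    Covers the variance parameters and task intercepts (the quantities the
    analysis reports).  Entries with R-hat above ``rhat_warn`` or ESS below
    100 are listed under ``"warnings"``.
    """
    import arviz as az

    if samples.n_draws < 100:
        raise ModmindError("diagnostics need >= 100 stored draws")
    report: dict[str, dict[str, float]] = {}
    warnings_list: list[str] = []

    def add(name: str, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if np.allclose(x, x[0]):
            ess, rhat = 1.0, np.inf
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess = float(az.ess(x[None, :]))
                rhat = float(az.rhat(_split_chain(x)))
            if not np.isfinite(ess):
                ess = 1.0
            if not np.isfinite(rhat):
                rhat = np.inf
        report[name] = {"ess": ess, "rhat": rhat}
        if rhat > rhat_warn or ess < 100:
            warnings_list.append(
                f"{name}: rhat={rhat:.3f}, ess={ess:.0f}")

    for name in samples.active_variance_names():
        x = samples.draws[name]
        add(name, x if x.ndim == 1 else x.mean(axis=1))
    mu = samples.draws["task_intercept"]
    for j, tid in enumerate(samples.task_ids):
        if np.all(mu[:, j] == 0.0):
            continue  # fixed at zero (rank tasks have no location)
        add(f"task_intercept[{tid}]", mu[:, j])
    return {"parameters": report, "warnings": warnings_list}
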