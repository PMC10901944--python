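"""Metropolis-within-Gibbs sampler for the shared component spatial model.

Scheme
------
* latent fields (theta, s_1, s_2, u_1, u_2), intercepts and log(delta):
  single-site random-walk Metropolis against the full conditionals of the
  joint density, swept in a fixed scan order (the inner loop is a compiled
  numba kernel; random variates are drawn from a per-chain
  ``numpy.random.Generator`` outside the kernel, so runs are deterministic
  given the seed).
* precisions: conjugate Gibbs draws from their gamma full conditionals
  (random-walk Metropolis on log tau when the uniform-on-sd sensitivity
  priors are selected).

After every sweep, theta, s_1 and s_2 are recentred to sum to zero within
each connected component and the subtracted mean is absorbed into the
corresponding intercept (times the shared-component scaling for theta), so
the likelihood is unchanged on connected graphs. Islands keep structured
effects fixed at zero.

Proposal scales adapt toward a 0.44 single-site acceptance rate during
burn-in only; retained draws come from a fixed kernel.

Convergence is monitored with the Brooks-Gelman-Rubin potential scale
reduction factor over >= 2 dispersed chains, and the retained-sample size is
checked by the rule that each parameter's Monte Carlo standard error be
below 5% of its posterior standard deviation (batch-means estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numba import njit

from .spatial_data import AdjacencyStructure, AreaTable
from .scsm_model import ModelState, PriorSpec, linear_predictor, log_joint

logger = logging.getLogger("scsm")


# ---------------------------------------------------------------------------
# Configuration / results containers
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """MCMC run settings. Defaults follow the reference protocol: two
    dispersed chains, 20,000 burn-in iterations and 10,000 retained
    iterations thinned by 100 (so 100 stored draws per chain). Burn-in and
    retained counts are raw iteration counts, before thinning."""

    n_chains: int = 2
    burn_in: int = 20_000
    retained: int = 10_000
    thin: int = 100
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.44
    adapt_batch: int = 50
    init_spread: float = 1.0
    likelihood_weight: float = 1.0
    compute_diagnostics: bool = True

    def __post_init__(self):
        if self.burn_in <= 0 or self.retained <= 0 or self.thin <= 0:
            raise ValueError("burn_in, retained and thin must be positive")
        if self.retained % self.thin != 0:
            raise ValueError("retained must be a multiple of thin")
        if self.compute_diagnostics and self.n_chains < 2:
            raise ValueError("diagnostics require at least 2 chains")

    @property
    def n_draws_per_chain(self) -> int:
        return self.retained // self.thin


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws from all chains.

    ``params`` maps parameter names to arrays with leading axes
    (n_chains, n_draws): ``alpha`` (c,d,2), ``log_delta`` (c,d),
    ``theta`` (c,d,n), ``s``/``u`` (c,d,2,n), ``tau_theta`` (c,d),
    ``tau_s``/``tau_u`` (c,d,2).
    """

    params: dict
    area_ids: list
    config: SamplerConfig
    seeds: list
    acceptance: dict = dc_field(default_factory=dict)
    rhat: pd.DataFrame | None = None
    converged: bool | None = None

    @property
    def n_chains(self) -> int:
        return self.params["log_delta"].shape[0]

    @property
    def n_draws(self) -> int:
        """Total stored draws pooled over chains."""
        return int(np.prod(self.params["log_delta"].shape[:2]))

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (n_draws, ...)."""
        a = self.params[name]
        return a.reshape((-1,) + a.shape[2:])

    def scalar_draws(self) -> dict:
        """Every scalar component, keyed by a flat name, as (chains, draws)."""
        out = self.hyper_draws()
        for i in range(self.params["theta"].shape[2]):
            out[f"theta[{i}]"] = self.params["theta"][:, :, i]
        for k in (0, 1):
            for i in range(self.params["s"].shape[3]):
                out[f"s[{k + 1},{i}]"] = self.params["s"][:, :, k, i]
                out[f"u[{k + 1},{i}]"] = self.params["u"][:, :, k, i]
        return out

    def hyper_draws(self) -> dict:
        """The non-field scalar parameters only (intercepts, log delta,
        precisions), as (chains, draws)."""
        out = {}
        for k in (0, 1):
            out[f"alpha[{k + 1}]"] = self.params["alpha"][:, :, k]
            out[f"tau_s[{k + 1}]"] = self.params["tau_s"][:, :, k]
            out[f"tau_u[{k + 1}]"] = self.params["tau_u"][:, :, k]
        out["log_delta"] = self.params["log_delta"]
        out["tau_theta"] = self.params["tau_theta"]
        return out

    # -- I/O ----------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalar_draws().items():
            c, d = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(rows, ignore_index=True)

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, area_ids=np.array(self.area_ids),
                            seeds=np.array(self.seeds), **self.params)

    @classmethod
    def load_npz(cls, path, config: SamplerConfig | None = None) -> "PosteriorSamples":
        z = np.load(path, allow_pickle=False)
        params = {k: z[k] for k in
                  ("alpha", "log_delta", "theta", "s", "u", "tau_theta", "tau_s", "tau_u")}
        return cls(params=params, area_ids=[str(a) for a in z["area_ids"]],
                   config=config, seeds=list(z["seeds"]))


# ---------------------------------------------------------------------------
# Gibbs precision updates
# ---------------------------------------------------------------------------

def update_precision_conjugate(field_values: np.ndarray,
                               structure: AdjacencyStructure | None,
                               gamma_prior: tuple,
                               rng: np.random.Generator) -> float:
    """Gibbs draw of a precision from its gamma full conditional.

    ICAR field (``structure`` given): Gamma(shape + (n - c)/2,
    rate + pairwise-difference-sum / 2). iid normal field (``structure``
    None): Gamma(shape + n/2, rate + sum(x^2)/2).
    """
    a, b = gamma_prior
    x = np.asarray(field_values, dtype=float)
    if structure is not None:
        dof = structure.n - structure.n_components
        q = structure.pairwise_diff_sum(x)
    else:
        dof = x.size
        q = float(x @ x)
    return float(rng.gamma(a + 0.5 * dof, 1.0 / (b + 0.5 * q)))


def _update_precision_uniform_sd(tau: float, dof: float, q: float,
                                 bounds: tuple, rng: np.random.Generator,
                                 scale: float = 0.6) -> float:
    """RW Metropolis on log tau under a uniform prior on the sd scale.

    Target over log tau: (dof/2) log tau - (q/2) tau + log p(tau) + log tau
    (change-of-variable Jacobian), with p(tau) ~ tau^{-3/2} restricted to
    the image of the sd bounds.
    """
    lo, hi = bounds

    def logp(lt):
        t = np.exp(lt)
        sd = np.exp(-0.5 * lt)
        if not (lo < sd < hi):
            return -np.inf
        return 0.5 * dof * lt - 0.5 * q * t - 0.5 * lt

    lt0 = float(np.log(tau))
    lt1 = lt0 + scale * rng.standard_normal()
    if np.log(rng.uniform()) < logp(lt1) - logp(lt0):
        return float(np.exp(lt1))
    return tau


# ---------------------------------------------------------------------------
# Compiled sweep kernel
# ---------------------------------------------------------------------------
#
# Sequential single-site random-walk Metropolis over all latent quantities.
# ``eta`` caches the linear predictors log r_ik and is updated in place on
# acceptance. Besides the plain coordinate updates, three likelihood-
# invariant "transfer" moves redistribute risk between components along the
# weakly identified directions (theta vs s_1/s_2, and s_k vs u_k): they
# leave both linear predictors unchanged, so only the prior terms enter the
# accept ratio. Slot order for scales / acceptance counters:
# 0 theta, 1 s1, 2 s2, 3 u1, 4 u2, 5 alpha1, 6 alpha2, 7 log_delta,
# 8 theta<->s transfer, 9 s1<->u1 transfer, 10 s2<->u2 transfer,
# 11 joint delta rescale (log delta += eps, theta *= exp(-eps),
#    s2 += (theta/delta) (1 - exp(-2 eps)); likelihood-invariant, accepted
#    on the priors plus the exp(-eps * (n - c)) Jacobian of the theta scaling
#    restricted to the sum-to-zero subspace).

@njit(cache=True)
def _sweep_kernel(O, e, eta, theta, s, u, alpha, log_delta_box,
                  tau_theta, tau_s, tau_u,
                  indptr, indices, m, sites, edges, icar_dof,
                  scales, w, ld_mean, ld_prec, intercept_prec,
                  zf, uf, zs, us, acc, tries):
    n = theta.shape[0]
    delta = np.exp(log_delta_box[0])
    inv_delta = 1.0 / delta

    # theta: enters outcome 1 with coefficient delta, outcome 2 with 1/delta
    for t in range(sites.shape[0]):
        i = sites[t]
        d = scales[0] * zf[0, i]
        prop = theta[i] + d
        nbr = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            nbr += theta[indices[p]]
        dlp = -0.5 * tau_theta * (m[i] * (prop * prop - theta[i] * theta[i])
                                  - 2.0 * d * nbr)
        if w != 0.0:
            d1 = delta * d
            d2 = inv_delta * d
            dlp += w * (O[i, 0] * d1 - e[i, 0] * (np.exp(eta[i, 0] + d1) - np.exp(eta[i, 0])))
            dlp += w * (O[i, 1] * d2 - e[i, 1] * (np.exp(eta[i, 1] + d2) - np.exp(eta[i, 1])))
        tries[0] += 1
        if np.log(uf[0, i]) < dlp:
            theta[i] = prop
            eta[i, 0] += delta * d
            eta[i, 1] += inv_delta * d
            acc[0] += 1

    # s_k: ICAR field entering only outcome k with unit coefficient
    for k in range(2):
        slot = 1 + k
        tau = tau_s[k]
        for t in range(sites.shape[0]):
            i = sites[t]
            d = scales[slot] * zf[slot, i]
            prop = s[k, i] + d
            nbr = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                nbr += s[k, indices[p]]
            dlp = -0.5 * tau * (m[i] * (prop * prop - s[k, i] * s[k, i])
                                - 2.0 * d * nbr)
            if w != 0.0:
                dlp += w * (O[i, k] * d
                            - e[i, k] * (np.exp(eta[i, k] + d) - np.exp(eta[i, k])))
            tries[slot] += 1
            if np.log(uf[slot, i]) < dlp:
                s[k, i] = prop
                eta[i, k] += d
                acc[slot] += 1

    # u_k: iid normal effects, all areas
    for k in range(2):
        slot = 3 + k
        tau = tau_u[k]
        for i in range(n):
            d = scales[slot] * zf[slot, i]
            prop = u[k, i] + d
            dlp = -0.5 * tau * (prop * prop - u[k, i] * u[k, i])
            if w != 0.0:
                dlp += w * (O[i, k] * d
                            - e[i, k] * (np.exp(eta[i, k] + d) - np.exp(eta[i, k])))
            tries[slot] += 1
            if np.log(uf[slot, i]) < dlp:
                u[k, i] = prop
                eta[i, k] += d
                acc[slot] += 1

    # intercepts
    for k in range(2):
        slot = 5 + k
        d = scales[slot] * zs[k]
        a0 = alpha[k]
        dlp = -0.5 * intercept_prec * ((a0 + d) * (a0 + d) - a0 * a0)
        if w != 0.0:
            for i in range(n):
                dlp += w * (O[i, k] * d
                            - e[i, k] * (np.exp(eta[i, k] + d) - np.exp(eta[i, k])))
        tries[slot] += 1
        if np.log(us[k]) < dlp:
            alpha[k] = a0 + d
            for i in range(n):
                eta[i, k] += d
            acc[slot] += 1

    # transfer move: theta_i += t, s1_i -= delta * t, s2_i -= t / delta.
    # Both linear predictors are unchanged; accept on the three ICAR priors.
    for t_ in range(sites.shape[0]):
        i = sites[t_]
        t = scales[8] * zf[5, i]
        nb_t = 0.0
        nb_1 = 0.0
        nb_2 = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            nb_t += theta[j]
            nb_1 += s[0, j]
            nb_2 += s[1, j]
        d1 = -delta * t
        d2 = -inv_delta * t
        p_t = theta[i] + t
        p_1 = s[0, i] + d1
        p_2 = s[1, i] + d2
        dlp = (-0.5 * tau_theta * (m[i] * (p_t * p_t - theta[i] * theta[i]) - 2.0 * t * nb_t)
               - 0.5 * tau_s[0] * (m[i] * (p_1 * p_1 - s[0, i] * s[0, i]) - 2.0 * d1 * nb_1)
               - 0.5 * tau_s[1] * (m[i] * (p_2 * p_2 - s[1, i] * s[1, i]) - 2.0 * d2 * nb_2))
        tries[8] += 1
        if np.log(uf[5, i]) < dlp:
            theta[i] = p_t
            s[0, i] = p_1
            s[1, i] = p_2
            acc[8] += 1

    # transfer move: s_k,i += t, u_k,i -= t (structured vs unstructured split)
    for k in range(2):
        slot = 9 + k
        tau = tau_s[k]
        tauu = tau_u[k]
        for t_ in range(sites.shape[0]):
            i = sites[t_]
            t = scales[slot] * zf[6 + k, i]
            nbr = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                nbr += s[k, indices[p]]
            p_s = s[k, i] + t
            p_u = u[k, i] - t
            dlp = (-0.5 * tau * (m[i] * (p_s * p_s - s[k, i] * s[k, i]) - 2.0 * t * nbr)
                   - 0.5 * tauu * (p_u * p_u - u[k, i] * u[k, i]))
            tries[slot] += 1
            if np.log(uf[6 + k, i]) < dlp:
                s[k, i] = p_s
                u[k, i] = p_u
                acc[slot] += 1

    # log delta: rescales theta's contribution to both outcomes
    ld0 = log_delta_box[0]
    ld1 = ld0 + scales[7] * zs[2]
    dlp = -0.5 * ld_prec * ((ld1 - ld_mean) ** 2 - (ld0 - ld_mean) ** 2)
    if w != 0.0:
        d0 = np.exp(ld0)
        d1 = np.exp(ld1)
        c1 = d1 - d0
        c2 = 1.0 / d1 - 1.0 / d0
        for i in range(n):
            de1 = c1 * theta[i]
            de2 = c2 * theta[i]
            dlp += w * (O[i, 0] * de1 - e[i, 0] * (np.exp(eta[i, 0] + de1) - np.exp(eta[i, 0])))
            dlp += w * (O[i, 1] * de2 - e[i, 1] * (np.exp(eta[i, 1] + de2) - np.exp(eta[i, 1])))
    tries[7] += 1
    if np.log(us[2]) < dlp:
        d0 = np.exp(ld0)
        d1 = np.exp(ld1)
        c1 = d1 - d0
        c2 = 1.0 / d1 - 1.0 / d0
        log_delta_box[0] = ld1
        for i in range(n):
            eta[i, 0] += c1 * theta[i]
            eta[i, 1] += c2 * theta[i]
        acc[7] += 1

    # joint delta rescale (slot 11): leaves both linear predictors intact
    eps = scales[11] * zs[3]
    ld0 = log_delta_box[0]
    ld1 = ld0 + eps
    d_old = np.exp(ld0)
    shrink = np.exp(-eps)
    shear = (1.0 - np.exp(-2.0 * eps)) / d_old
    q_t0 = 0.0
    q_t1 = 0.0
    q_s0 = 0.0
    q_s1 = 0.0
    for r in range(edges.shape[0]):
        i = edges[r, 0]
        j = edges[r, 1]
        dt = theta[i] - theta[j]
        q_t0 += dt * dt
        ds = s[1, i] - s[1, j]
        q_s0 += ds * ds
        ds1 = (s[1, i] + shear * theta[i]) - (s[1, j] + shear * theta[j])
        q_s1 += ds1 * ds1
    q_t1 = q_t0 * shrink * shrink
    dlp = (-0.5 * tau_theta * (q_t1 - q_t0)
           - 0.5 * tau_s[1] * (q_s1 - q_s0)
           - 0.5 * ld_prec * ((ld1 - ld_mean) ** 2 - (ld0 - ld_mean) ** 2)
           - eps * icar_dof)
    tries[11] += 1
    if np.log(us[3]) < dlp:
        log_delta_box[0] = ld1
        for i in range(n):
            s[1, i] = s[1, i] + shear * theta[i]
            theta[i] = theta[i] * shrink
        acc[11] += 1


class _ChainWorkspace:
    """Mutable per-chain state: parameter values, cached linear predictors,
    proposal scales and acceptance counters."""

    SLOTS = ("theta", "s1", "s2", "u1", "u2", "alpha1", "alpha2", "log_delta",
             "xfer_theta_s", "xfer_s1_u1", "xfer_s2_u2", "delta_rescale")

    def __init__(self, state: ModelState, areas: AreaTable,
                 adjacency: AdjacencyStructure, priors: PriorSpec,
                 likelihood_weight: float = 1.0):
        self.state = state.copy()
        self.areas = areas
        self.adj = adjacency
        self.priors = priors
        self.w = float(likelihood_weight)
        A = adjacency.sparse().tocsr()
        self.indptr = A.indptr.astype(np.int64)
        self.indices = A.indices.astype(np.int64)
        self.m = adjacency.neighbor_counts.astype(float)
        island_set = set(adjacency.islands.tolist())
        self.sites = np.array([i for i in range(adjacency.n) if i not in island_set],
                              dtype=np.int64)
        self.edges = np.ascontiguousarray(adjacency.edges, dtype=np.int64).reshape(-1, 2)
        self.icar_dof = float(adjacency.n - adjacency.n_components)
        self.O = np.ascontiguousarray(areas.observed, dtype=float)
        self.e = np.ascontiguousarray(areas.expected, dtype=float)
        self.scales = np.full(12, 0.5)
        self.acc = np.zeros(12, dtype=np.int64)
        self.tries = np.zeros(12, dtype=np.int64)
        self.log_delta_box = np.array([self.state.log_delta])
        self.refresh_eta()

    def refresh_eta(self):
        self.state.log_delta = float(self.log_delta_box[0])
        self.eta = np.ascontiguousarray(
            np.column_stack([linear_predictor(self.state, 1),
                             linear_predictor(self.state, 2)]))

    def sweep(self, rng: np.random.Generator):
        st = self.state
        n = st.n
        zf = rng.standard_normal((8, n))
        uf = rng.uniform(size=(8, n))
        zs = rng.standard_normal(4)
        us = rng.uniform(size=4)
        ld_mean, ld_prec = self.priors.log_delta_normal
        _sweep_kernel(self.O, self.e, self.eta, st.theta, st.s, st.u, st.alpha,
                      self.log_delta_box, float(st.tau_theta),
                      st.tau_s, st.tau_u,
                      self.indptr, self.indices, self.m, self.sites,
                      self.edges, self.icar_dof,
                      self.scales, self.w, float(ld_mean), float(ld_prec),
                      1.0 / self.priors.intercept_variance,
                      zf, uf, zs, us, self.acc, self.tries)
        st.log_delta = float(self.log_delta_box[0])
        self.recenter()

    def recenter(self):
        """Sum-to-zero per component for theta, s1, s2; the (area-weighted)
        global mean is absorbed into the intercepts, which leaves the
        likelihood unchanged on connected graphs."""
        st = self.state
        delta = st.delta
        for vec, absorb in ((st.theta, (delta, 1.0 / delta)),
                            (st.s[0], (1.0, None)),
                            (st.s[1], (None, 1.0))):
            g = 0.0
            for comp in self.adj.components:
                if comp.size > 1:
                    mc = vec[comp].mean()
                    vec[comp] -= mc
                    g += mc * comp.size
                else:
                    vec[comp] = 0.0
            g /= self.adj.n
            if absorb[0] is not None:
                st.alpha[0] += absorb[0] * g
            if absorb[1] is not None:
                st.alpha[1] += absorb[1] * g
        self.refresh_eta()

    def update_precisions(self, rng: np.random.Generator):
        st, pri = self.state, self.priors
        if pri.precision_prior == "gamma":
            st.tau_theta = update_precision_conjugate(
                st.theta, self.adj, pri.structured_precision_gamma, rng)
            st.tau_s[0] = update_precision_conjugate(
                st.s[0], self.adj, pri.structured_precision_gamma, rng)
            st.tau_s[1] = update_precision_conjugate(
                st.s[1], self.adj, pri.structured_precision_gamma, rng)
            st.tau_u[0] = update_precision_conjugate(
                st.u[0], None, pri.unstructured_precision_gamma, rng)
            st.tau_u[1] = update_precision_conjugate(
                st.u[1], None, pri.unstructured_precision_gamma, rng)
        else:
            dof_icar = self.adj.n - self.adj.n_components
            bs = pri.uniform_sd_bounds_structured
            bu = pri.uniform_sd_bounds_unstructured
            st.tau_theta = _update_precision_uniform_sd(
                float(st.tau_theta), dof_icar,
                self.adj.pairwise_diff_sum(st.theta), bs, rng)
            for k0 in (0, 1):
                st.tau_s[k0] = _update_precision_uniform_sd(
                    float(st.tau_s[k0]), dof_icar,
                    self.adj.pairwise_diff_sum(st.s[k0]), bs, rng)
                st.tau_u[k0] = _update_precision_uniform_sd(
                    float(st.tau_u[k0]), st.n,
                    float(st.u[k0] @ st.u[k0]), bu, rng)

    def adapt(self, batch_number: int, target: float):
        step = 1.0 / np.sqrt(1.0 + batch_number)
        for j in range(12):
            if self.tries[j] == 0:
                continue
            rate = self.acc[j] / self.tries[j]
            self.scales[j] = float(np.clip(
                self.scales[j] * np.exp(step * (rate - target)), 1e-4, 20.0))
        self.acc[:] = 0
        self.tries[:] = 0

    def acceptance_rates(self) -> dict:
        return {name: (self.acc[j] / self.tries[j] if self.tries[j] else np.nan)
                for j, name in enumerate(self.SLOTS)}


def update_latent_fields(state: ModelState, areas: AreaTable,
                         adjacency: AdjacencyStructure, priors: PriorSpec,
                         rng: np.random.Generator,
                         scales: dict | None = None,
                         likelihood_weight: float = 1.0) -> ModelState:
    """One Metropolis sweep over theta, s, u, alpha and log delta, followed
    by sum-to-zero recentring. Returns the updated state (a copy).

    Convenience wrapper around the workspace used by :func:`run_chains`; a
    long-running loop should construct the workspace once instead.
    """
    ws = _ChainWorkspace(state, areas, adjacency, priors, likelihood_weight)
    if scales:
        for j, name in enumerate(_ChainWorkspace.SLOTS):
            if name in scales:
                ws.scales[j] = scales[name]
    ws.sweep(rng)
    lj = log_joint(areas, adjacency, ws.state, priors, likelihood_weight)
    if not np.isfinite(lj):
        raise FloatingPointError(f"non-finite log joint after update; state={ws.state!r}")
    return ws.state


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

def _dispersed_init(n: int, spread: float, rng: np.random.Generator,
                    adjacency: AdjacencyStructure) -> ModelState:
    s = spread
    state = ModelState(
        alpha=0.5 * s * rng.standard_normal(2),
        log_delta=float(0.3 * s * rng.standard_normal()),
        theta=0.3 * s * rng.standard_normal(n),
        s=0.3 * s * rng.standard_normal((2, n)),
        u=0.3 * s * rng.standard_normal((2, n)),
        tau_theta=float(np.exp(0.5 * s * rng.standard_normal())),
        tau_s=np.exp(0.5 * s * rng.standard_normal(2)),
        tau_u=np.exp(0.5 * s * rng.standard_normal(2)),
    )
    for comp in adjacency.components:
        if comp.size > 1:
            state.theta[comp] -= state.theta[comp].mean()
            state.s[:, comp] -= state.s[:, comp].mean(axis=1, keepdims=True)
        else:
            state.theta[comp] = 0.0
            state.s[:, comp] = 0.0
    return state


def run_chains(areas: AreaTable, adjacency: AdjacencyStructure,
               priors: PriorSpec, config: SamplerConfig) -> PosteriorSamples:
    """Fit the SCSM: burn-in with adaptation, then retention with thinning,
    for each chain; then convergence diagnostics."""
    areas.validate_for_model()
    n = areas.n
    n_draws = config.n_draws_per_chain
    shapes = {"alpha": (2,), "log_delta": (), "theta": (n,), "s": (2, n),
              "u": (2, n), "tau_theta": (), "tau_s": (2,), "tau_u": (2,)}
    params = {k: np.empty((config.n_chains, n_draws) + shp)
              for k, shp in shapes.items()}
    seeds, acceptance = [], {}

    for c in range(config.n_chains):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(c,))
        rng = np.random.default_rng(ss)
        seeds.append(int(ss.entropy))
        init = _dispersed_init(n, config.init_spread * (1.0 + 0.5 * c), rng, adjacency)
        ws = _ChainWorkspace(init, areas, adjacency, priors, config.likelihood_weight)
        batch = 0
        for it in range(config.burn_in):
            ws.sweep(rng)
            ws.update_precisions(rng)
            if config.adapt and (it + 1) % config.adapt_batch == 0:
                batch += 1
                ws.adapt(batch, config.target_accept)
        ws.acc[:] = 0
        ws.tries[:] = 0
        d = 0
        for it in range(config.retained):
            ws.sweep(rng)
            ws.update_precisions(rng)
            if (it + 1) % config.thin == 0:
                st = ws.state
                params["alpha"][c, d] = st.alpha
                params["log_delta"][c, d] = st.log_delta
                params["theta"][c, d] = st.theta
                params["s"][c, d] = st.s
                params["u"][c, d] = st.u
                params["tau_theta"][c, d] = st.tau_theta
                params["tau_s"][c, d] = st.tau_s
                params["tau_u"][c, d] = st.tau_u
                d += 1
        lj = log_joint(areas, adjacency, ws.state, priors, config.likelihood_weight)
        if not np.isfinite(lj):
            raise FloatingPointError(f"chain {c} ended with non-finite log joint")
        acceptance[c] = ws.acceptance_rates()
        logger.info("SCSM-I01 chain %d done; acceptance %s", c,
                    {k: round(float(v), 3) for k, v in acceptance[c].items()})

    samples = PosteriorSamples(params=params, area_ids=list(areas.area_ids),
                               config=config, seeds=seeds, acceptance=acceptance)
    if config.compute_diagnostics and config.n_chains >= 2:
        samples.rhat = gelman_rubin_table(samples)
        worst = float(samples.rhat["rhat"].max())
        samples.converged = bool(worst < 1.1)
        if not samples.converged:
            logger.warning("SCSM-W05 BGR diagnostic above 1.1 (max %.3f)", worst)
    return samples


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(per_chain_draws: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor for one scalar
    parameter, from an (n_chains, n_draws) array."""
    x = np.asarray(per_chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains")
    m, nlen = x.shape
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (nlen - 1) / nlen * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin_table(samples: PosteriorSamples, fields: bool = True) -> pd.DataFrame:
    """BGR statistic for every monitored scalar (hyperparameters and,
    optionally, every field coordinate)."""
    draws = samples.scalar_draws() if fields else samples.hyper_draws()
    rows = [(name, gelman_rubin(arr)) for name, arr in draws.items()]
    return pd.DataFrame(rows, columns=["parameter", "rhat"])


def batch_means_mcse(draws: np.ndarray, n_batches: int = 20) -> float:
    """Monte Carlo standard error of the mean by the batch-means method."""
    x = np.asarray(draws, dtype=float).reshape(-1)
    if n_batches < 10:
        raise ValueError("need at least 10 batches")
    if x.size < 2 * n_batches:
        raise ValueError("too few draws for batch means")
    bsize = x.size // n_batches
    means = x[: bsize * n_batches].reshape(n_batches, bsize).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))


def monte_carlo_error_check(samples: PosteriorSamples, frac: float = 0.05,
                            n_batches: int = 20, fields: bool = False) -> pd.DataFrame:
    """Per-parameter rule: Monte Carlo error < ``frac`` x posterior SD.

    Degenerate (constant) chains have SD = 0 and pass automatically with a
    warning flag. Returns a table with columns parameter, mcse, sd, passed.
    """
    draws = samples.scalar_draws() if fields else samples.hyper_draws()
    rows = []
    for name, arr in draws.items():
        pooled = arr.reshape(-1)
        sd = float(np.std(pooled, ddof=1))
        if sd == 0.0:
            logger.warning("SCSM-W06 parameter %s has zero posterior SD", name)
            rows.append((name, 0.0, 0.0, True))
            continue
        mcse = batch_means_mcse(pooled, n_batches=n_batches)
        rows.append((name, mcse, sd, bool(mcse < frac * sd)))
    return pd.DataFrame(rows, columns=["parameter", "mcse", "sd", "passed"])
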