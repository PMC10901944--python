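"""The shared component spatial model (SCSM) for two areal count outcomes.

Observed counts O_ik in area i for outcome k = 1, 2 are Poisson with mean
e_ik * r_ik, where e_ik is the indirectly standardized expected count and
r_ik the relative risk:

    r_i1 = exp(alpha_1 + delta * theta_i + s_i1 + u_i1)
    r_i2 = exp(alpha_2 + (1/delta) * theta_i + s_i2 + u_i2)

theta is a latent spatial field shared by the two outcomes (a surrogate for
unmeasured common risk factors), entering with reciprocal scaling delta and
1/delta for identifiability; s_k are outcome-specific spatially structured
fields and u_k outcome-specific unstructured (iid normal) effects, the usual
BYM convolution pair. theta, s_1, s_2 carry intrinsic CAR (ICAR) priors on
the contiguity graph; the joint ICAR kernel is the pairwise-difference form

    ((n - c)/2) log(tau) - (tau/2) * sum_{i~j} (x_i - x_j)^2

with c the number of connected components (the rank deficiency of the graph
Laplacian). Identifiability of the intercepts requires sum-to-zero
constraints on theta, s_1, s_2 within each connected component; the sampler
enforces them by recentring.

Hyperpriors: Gamma(0.1, 0.1) on the three structured precisions,
Gamma(0.01, 0.01) on the two unstructured precisions, flat normal intercepts
realized as N(0, 1e6), and N(0, 1/5.9) on log(delta) — the precision 5.9
calibrated so the ratio of the two risk gradients (delta and 1/delta, i.e.
delta^2) lies between 1/5 and 5 with 95% prior probability. A uniform-on-sd
alternative is provided for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .spatial_data import AdjacencyStructure, AreaTable

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# State and priors
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """One full parameter configuration of the SCSM."""

    alpha: np.ndarray            # (2,) baseline log-risks
    log_delta: float             # log of the scaling parameter delta > 0
    theta: np.ndarray            # (n,) shared spatial field
    s: np.ndarray                # (2, n) outcome-specific structured fields
    u: np.ndarray                # (2, n) outcome-specific unstructured effects
    tau_theta: float             # precision of theta (1 / omega_theta^2)
    tau_s: np.ndarray            # (2,) precisions of s_1, s_2 (1 / sigma_k^2)
    tau_u: np.ndarray            # (2,) precisions of u_1, u_2

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(2)
        self.theta = np.asarray(self.theta, dtype=float)
        self.s = np.asarray(self.s, dtype=float).reshape(2, -1)
        self.u = np.asarray(self.u, dtype=float).reshape(2, -1)
        self.tau_s = np.asarray(self.tau_s, dtype=float).reshape(2)
        self.tau_u = np.asarray(self.tau_u, dtype=float).reshape(2)
        if not (self.tau_theta > 0 and np.all(self.tau_s > 0) and np.all(self.tau_u > 0)):
            raise ValueError("all precisions must be positive")

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    @property
    def n(self) -> int:
        return self.theta.size

    def scaling(self, k: int) -> float:
        """delta for outcome 1, 1/delta for outcome 2 (k is 1-based)."""
        if k not in (1, 2):
            raise ValueError(f"outcome index must be 1 or 2, got {k}")
        return self.delta if k == 1 else 1.0 / self.delta

    def copy(self) -> "ModelState":
        return replace(
            self,
            alpha=self.alpha.copy(),
            theta=self.theta.copy(),
            s=self.s.copy(),
            u=self.u.copy(),
            tau_s=self.tau_s.copy(),
            tau_u=self.tau_u.copy(),
        )

    @classmethod
    def zeros(cls, n: int) -> "ModelState":
        return cls(
            alpha=np.zeros(2), log_delta=0.0, theta=np.zeros(n),
            s=np.zeros((2, n)), u=np.zeros((2, n)),
            tau_theta=1.0, tau_s=np.ones(2), tau_u=np.ones(2),
        )


@dataclass
class PriorSpec:
    """Prior and hyperprior settings.

    The gamma pairs are (shape, rate). ``precision_prior`` selects either the
    conjugate gamma hyperpriors (default) or the uniform-on-standard-deviation
    sensitivity alternative with the given bounds.
    """

    structured_precision_gamma: tuple = (0.1, 0.1)
    unstructured_precision_gamma: tuple = (0.01, 0.01)
    log_delta_normal: tuple = (0.0, 5.9)      # (mean, precision)
    intercept_variance: float = 1e6
    precision_prior: str = "gamma"            # "gamma" | "uniform_sd"
    uniform_sd_bounds_structured: tuple = (0.0, 10.0)
    uniform_sd_bounds_unstructured: tuple = (0.0, 100.0)

    def __post_init__(self):
        for pair in (self.structured_precision_gamma, self.unstructured_precision_gamma):
            if not (pair[0] > 0 and pair[1] > 0):
                raise ValueError("gamma shape/rate must be positive")
        if self.log_delta_normal[1] <= 0 or self.intercept_variance <= 0:
            raise ValueError("prior precisions/variances must be positive")
        if self.precision_prior not in ("gamma", "uniform_sd"):
            raise ValueError(f"unknown precision prior {self.precision_prior!r}")
        for lo, hi in (self.uniform_sd_bounds_structured, self.uniform_sd_bounds_unstructured):
            if not lo < hi:
                raise ValueError("uniform sd bounds must be ordered")

    @classmethod
    def sensitivity(cls) -> "PriorSpec":
        """Uniform-on-sd hyperpriors: U(0,10) structured, U(0,100) unstructured."""
        return cls(precision_prior="uniform_sd")


# ---------------------------------------------------------------------------
# Predictors and likelihood
# ---------------------------------------------------------------------------

def linear_predictor(state: ModelState, k: int) -> np.ndarray:
    """log r_ik = alpha_k + c_k * theta_i + s_ik + u_ik, with c_1 = delta,
    c_2 = 1/delta."""
    c = state.scaling(k)
    return state.alpha[k - 1] + c * state.theta + state.s[k - 1] + state.u[k - 1]


def relative_risk(state: ModelState, k: int) -> np.ndarray:
    return np.exp(linear_predictor(state, k))


def poisson_log_likelihood(areas: AreaTable, state: ModelState) -> float:
    """Sum over areas and outcomes of the Poisson log-pmf at mean e_ik r_ik."""
    areas.validate_for_model()
    if state.n != areas.n:
        raise ValueError("state dimension does not match area table")
    total = 0.0
    for k in (1, 2):
        O = areas.observed[:, k - 1]
        lam = areas.expected[:, k - 1] * relative_risk(state, k)
        total += float(np.sum(O * np.log(lam) - lam - gammaln(O + 1.0)))
    return total


def icar_log_density_kernel(field: np.ndarray, adjacency: AdjacencyStructure,
                            precision: float) -> float:
    """Joint ICAR kernel (up to a constant):
    ((n - c)/2) log(tau) - (tau/2) * sum over neighbour pairs of (x_i - x_j)^2.

    ``n - c`` (areas minus connected components) is the rank of the graph
    Laplacian, the effective degrees of freedom of the improper density.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    q = adjacency.pairwise_diff_sum(field)
    dof = adjacency.n - adjacency.n_components
    return 0.5 * dof * np.log(precision) - 0.5 * precision * q


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _normal_logpdf(x, mean, precision):
    return 0.5 * (np.log(precision) - _LOG_2PI) - 0.5 * precision * (x - mean) ** 2


def _precision_log_prior(tau: float, priors: PriorSpec, structured: bool) -> float:
    """Log hyperprior on a precision, under either the gamma priors or the
    uniform-on-sd sensitivity priors (density transformed to the tau scale:
    sigma ~ U(lo,hi) implies p(tau) proportional to tau^{-3/2} on the image)."""
    if priors.precision_prior == "gamma":
        a, b = (priors.structured_precision_gamma if structured
                else priors.unstructured_precision_gamma)
        return _gamma_logpdf(tau, a, b)
    lo, hi = (priors.uniform_sd_bounds_structured if structured
              else priors.uniform_sd_bounds_unstructured)
    sd = 1.0 / np.sqrt(tau)
    if not (lo < sd < hi):
        return -np.inf
    return -np.log(hi - lo) - 1.5 * np.log(tau) - np.log(2.0)


def log_joint(areas: AreaTable, adjacency: AdjacencyStructure,
              state: ModelState, priors: PriorSpec,
              likelihood_weight: float = 1.0) -> float:
    """Unnormalized log posterior density of the full SCSM.

    ``likelihood_weight`` tempers the Poisson term (0 gives the prior alone);
    it exists for prior-recovery checks of the sampler.
    """
    total = 0.0
    if likelihood_weight != 0.0:
        total += likelihood_weight * poisson_log_likelihood(areas, state)
    total += icar_log_density_kernel(state.theta, adjacency, state.tau_theta)
    total += icar_log_density_kernel(state.s[0], adjacency, float(state.tau_s[0]))
    total += icar_log_density_kernel(state.s[1], adjacency, float(state.tau_s[1]))
    for k in range(2):
        tau = float(state.tau_u[k])
        total += float(np.sum(_normal_logpdf(state.u[k], 0.0, tau)))
        total += _precision_log_prior(tau, priors, structured=False)
    total += _precision_log_prior(float(state.tau_theta), priors, structured=True)
    total += _precision_log_prior(float(state.tau_s[0]), priors, structured=True)
    total += _precision_log_prior(float(state.tau_s[1]), priors, structured=True)
    m0, p0 = priors.log_delta_normal
    total += float(_normal_logpdf(state.log_delta, m0, p0))
    total += float(np.sum(_normal_logpdf(state.alpha, 0.0, 1.0 / priors.intercept_variance)))
    return float(total)


# ---------------------------------------------------------------------------
# Prior calibration
# ---------------------------------------------------------------------------

def precision_for_ratio_bounds(bound: float, coverage_prob: float) -> float:
    """Precision of the zero-mean normal prior on log(delta) such that the
    risk-gradient ratio delta / (1/delta) = delta^2 lies in [1/bound, bound]
    with the given probability.

    The ratio condition is |log delta| <= log(bound)/2, so with
    log delta ~ N(0, 1/p) the solution is p = (z_{(1+q)/2} / (log(bound)/2))^2.
    """
    if bound <= 1:
        raise ValueError("bound must exceed 1")
    if not 0 < coverage_prob < 1:
        raise ValueError("coverage probability must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + coverage_prob))
    half_width = 0.5 * np.log(bound)
    return float((z / half_width) ** 2)
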