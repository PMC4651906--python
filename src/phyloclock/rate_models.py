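"""Relaxed molecular clock priors on branch rates.

Two rate models are supported, matching common practice in Bayesian dating:

* IR (independent rates): each branch rate is an i.i.d. lognormal draw with
  mean ``mu_r`` (substitutions/site/100 Myr) and log-variance ``sigma2``.
  The rate variance is independent of divergence time.
* AR (autocorrelated rates): node log-rates evolve by geometric Brownian
  motion with drift correction, so that a lineage evolving for time t has
  log-rate variance ``t * nu`` while the expected rate stays at the
  ancestral rate.  The branch rate is the arithmetic mean of the rates at
  its two end nodes.

Both parameterizations are expectation-preserving: the log-rate mean is
``log(mu) - variance / 2`` so that E[rate] = mu exactly.  On a star
phylogeny of depth 1 (100 Myr) the AR tip-rate distribution coincides with
the IR distribution at ``sigma2 = nu``.

Hyperpriors are gamma: the mean (or ancestral) rate defaults to G(2, 40)
(prior mean 0.05/100 Myr = 5e-10 substitutions/site/year) and the rate
variance to G(1, 10).  Across partitions the hyperparameters are shared
via a gamma-Dirichlet construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trees import TimeTree

__all__ = [
    "GammaPrior",
    "ClockHyperParams",
    "BranchRates",
    "ir_logprior",
    "ar_logprior",
    "hyperprior_logpdf",
    "gamma_dirichlet_split",
    "gamma_dirichlet_logprior",
    "rate_prior_from_distance",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma distribution in shape/rate form; mean = shape / rate."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return (
            self.shape * math.log(self.rate)
            - math.lgamma(self.shape)
            + (self.shape - 1.0) * math.log(x)
            - self.rate * x
        )

    def rvs(self, size, rng: np.random.Generator):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


@dataclass
class ClockHyperParams:
    """Clock hyperparameters and their gamma hyperpriors.

    ``mu`` is the mean rate under IR or the ancestral (root) rate under AR,
    in substitutions/site/100 Myr.  ``sigma2`` is the log-variance of the
    branch rates under IR, or the drift (variance accumulated per 100 Myr)
    ``nu`` under AR.
    """

    mu: float = 0.05
    sigma2: float = 0.1
    mu_prior: GammaPrior = field(default_factory=lambda: GammaPrior(2.0, 40.0))
    sigma2_prior: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 10.0))

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass
class BranchRates:
    """Per-branch rates (IR) or per-node log-rates with derived branch rates (AR)."""

    model: str  # "ir" or "ar"
    rates: np.ndarray  # per-node: branch rate to parent (IR) / node rate (AR)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.model not in ("ir", "ar"):
            raise ValueError("model must be 'ir' or 'ar'")

    def branch_rates(self, top) -> np.ndarray:
        """Rate applying along the branch above each node (root entry unused)."""
        if self.model == "ir":
            return self.rates
        out = np.zeros_like(self.rates)
        for v in range(top.n_nodes):
            p = top.parent[v]
            if p != -1:
                out[v] = 0.5 * (self.rates[v] + self.rates[p])
        return out


def _lognorm_logpdf(r: float, mu: float, s2: float) -> float:
    """Lognormal with E[r] = mu and log-variance s2 (mean-preserving)."""
    if r <= 0:
        return -math.inf
    m = math.log(mu) - 0.5 * s2
    z = math.log(r) - m
    return -0.5 * (_LOG_2PI + math.log(s2)) - math.log(r) - 0.5 * z * z / s2


def ir_logprior(rates: BranchRates, h: ClockHyperParams, top=None) -> float:
    """Joint log-density of i.i.d. lognormal branch rates.

    When a topology is given, the root entry (which has no branch) is
    excluded; otherwise every entry of ``rates.rates`` is treated as a
    branch rate.
    """
    if rates.model != "ir":
        raise ValueError("ir_logprior called with a non-IR BranchRates")
    r = rates.rates
    if top is not None:
        r = np.delete(r, top.root)
    if (r <= 0).any():
        return -math.inf
    s2 = h.sigma2
    if s2 == 0:
        return 0.0 if np.allclose(r, h.mu) else -math.inf
    m = math.log(h.mu) - 0.5 * s2
    z = np.log(r) - m
    return float(
        -0.5 * len(r) * (_LOG_2PI + math.log(s2))
        - np.log(r).sum()
        - 0.5 * (z * z).sum() / s2
    )


def ar_logprior(tree: TimeTree, log_rates: np.ndarray, h: ClockHyperParams) -> float:
    """Geometric-Brownian log-density of per-node log-rates.

    For each non-root node v with parent u separated by time dt, the
    log-rate satisfies ``x_v ~ Normal(x_u - dt * nu / 2, dt * nu)``; the
    drift term keeps E[rate] constant along lineages.  The root log-rate is
    pinned to ``log(h.mu)`` (the ancestral rate carries the gamma
    hyperprior); a root entry differing from it makes the density -inf.
    """
    top = tree.topology
    nu = h.sigma2
    x = np.asarray(log_rates, dtype=float)
    if abs(x[top.root] - math.log(h.mu)) > 1e-9:
        return -math.inf
    total = 0.0
    for v in range(top.n_nodes):
        u = top.parent[v]
        if u == -1:
            continue
        dt = tree.ages[u] - tree.ages[v]
        if dt <= 0:
            raise ValueError(f"non-positive branch duration at node {v}")
        if nu == 0:
            if abs(x[v] - x[u]) > 1e-12:
                return -math.inf
            continue
        s2 = dt * nu
        z = x[v] - (x[u] - 0.5 * s2)
        total += -0.5 * (_LOG_2PI + math.log(s2)) - 0.5 * z * z / s2
    return total


def hyperprior_logpdf(h: ClockHyperParams) -> float:
    """Gamma hyperprior log-density of (mu, sigma2)."""
    return h.mu_prior.logpdf(h.mu) + h.sigma2_prior.logpdf(h.sigma2)


def gamma_dirichlet_split(
    overall: float, k: int, rng: np.random.Generator, concentration: float = 1.0
) -> np.ndarray:
    """Split an overall hyperparameter value across ``k`` partitions.

    Draw w ~ Dirichlet(concentration * 1_k) and return ``k * overall * w``,
    so the per-partition values average exactly to ``overall``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w = rng.dirichlet(np.full(k, concentration))
    return k * overall * w


def gamma_dirichlet_logprior(
    values: np.ndarray, prior: GammaPrior, concentration: float = 1.0
) -> float:
    """Joint log-density (up to a constant) of per-partition values.

    The construction places the gamma prior on the across-partition mean
    and a Dirichlet(concentration) on the proportions; the Jacobian of the
    (mean, proportions) -> values map contributes ``-(k-1) log(k * mean)``.
    """
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        return -math.inf
    k = len(v)
    m = float(v.mean())
    lp = prior.logpdf(m)
    if k > 1:
        w = v / (k * m)
        lp += float((concentration - 1.0) * np.log(w).sum())
        lp -= (k - 1) * math.log(k * m)
    return lp


def rate_prior_from_distance(dist: float, age: float, shape: float = 2.0) -> GammaPrior:
    """Gamma hyperprior for the mean rate from a pairwise distance.

    A pairwise path between two taxa diverging ``age`` (100 Myr) ago spans
    ``2 * age`` time units, so the implied mean rate is ``dist / (2 * age)``;
    the returned prior has the given shape and that mean.
    """
    if age <= 0:
        raise ValueError("age must be > 0")
    if dist <= 0:
        raise ValueError("dist must be > 0")
    mean = dist / (2.0 * age)
    return GammaPrior(shape, shape / mean)
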