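"""The joint prior on node ages.

Calibrated nodes carry their fossil-calibration densities; every other
internal node carries the birth-death node-age kernel conditional on the
root age; the root must carry an explicit calibration (otherwise the prior
is improper).  Parent-older-than-child ordering is enforced by truncating
the support, and it is exactly this truncation that can make the effective
(marginal) prior at a node differ from the density the user specified —
the diagnostic exposed by prior-only MCMC runs.

With birth rate = death rate and sampling fraction -> 0 the kernel reduces
to the uniform density 1/t_root on (0, t_root), the configuration used for
the metazoan analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibrations import CalibrationSet
from .trees import TimeTree, Topology

__all__ = [
    "BirthDeathParams",
    "bd_kernel_logpdf",
    "bd_kernel_cdf",
    "bd_kernel_ppf",
    "joint_time_logprior",
    "sample_effective_prior",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth-death process parameters (rates per 100 Myr)."""

    birth: float = 1.0  # lambda
    death: float = 1.0  # mu
    sampling: float = 0.0  # rho; 0 is taken as the limit rho -> 0

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.sampling <= 1.0:
            raise ValueError("sampling fraction must be in [0, 1]")


def _kernel_parts(bd: BirthDeathParams):
    lam, mu, rho = bd.birth, bd.death, bd.sampling
    r = lam - mu
    a = rho * lam
    b = lam * (1.0 - rho) - mu
    return lam, mu, rho, r, a, b


def _cumulative(t: float, bd: BirthDeathParams) -> float:
    """V(t) = integral_0^t lambda * p1(s) ds (unnormalized kernel mass)."""
    lam, mu, rho, r, a, b = _kernel_parts(bd)
    if rho < _EPS:
        if abs(r) < _EPS:
            return t
        return (math.exp(r * t) - 1.0) / r
    if abs(r) < _EPS:
        return 1.0 - 1.0 / (1.0 + rho * lam * t)
    if abs(b) < _EPS:
        # lambda (1 - rho) = mu: the denominator a + b e^{-rt} is constant
        return lam * rho * r * (-math.expm1(-r * t)) / (a * a)
    D = r + b * math.expm1(-r * t)  # a + b e^{-rt}, stable near r = 0
    return (lam * rho * r / b) * (1.0 / D - 1.0 / r)


def bd_kernel_logpdf(t: float, t_root: float, bd: BirthDeathParams) -> float:
    """Log-density of a non-root node age conditional on the root age.

    The birth-death node-age kernel of the reconstructed process; at
    birth = death and sampling -> 0 it is the uniform density 1/t_root.
    Returns -inf outside (0, t_root).
    """
    if not 0.0 < t < t_root:
        return -math.inf
    lam, mu, rho, r, a, b = _kernel_parts(bd)
    if rho < _EPS:
        if abs(r) < _EPS:
            return -math.log(t_root)
        return math.log(abs(r) / abs(math.expm1(r * t_root))) + r * t
    if abs(r) < _EPS:
        p1 = rho / (1.0 + rho * lam * t) ** 2
    else:
        D = r + b * math.expm1(-r * t)
        p1 = rho * r * r * math.exp(-r * t) / (D * D)
    return math.log(lam * p1) - math.log(_cumulative(t_root, bd))


def bd_kernel_cdf(t: float, t_root: float, bd: BirthDeathParams) -> float:
    if t <= 0:
        return 0.0
    if t >= t_root:
        return 1.0
    return _cumulative(t, bd) / _cumulative(t_root, bd)


def bd_kernel_ppf(q: float, t_root: float, bd: BirthDeathParams) -> float:
    """Quantile of the node-age kernel (inverse CDF)."""
    lam, mu, rho, r, a, b = _kernel_parts(bd)
    if rho < _EPS:
        if abs(r) < _EPS:
            return q * t_root
        return math.log1p(q * math.expm1(r * t_root)) / r
    target = q * _cumulative(t_root, bd)
    if abs(r) < _EPS:
        # 1 - 1/(1 + rho lam t) = target
        return (1.0 / (1.0 - target) - 1.0) / (rho * lam)
    if abs(b) < _EPS:
        # V(t) = lam rho r (1 - e^{-rt}) / a^2
        return -math.log1p(-target * a * a / (lam * rho * r)) / r
    # invert V(t) = (lam rho r / b)(1/D - 1/r) with D = a + b e^{-rt}
    D = 1.0 / (target * b / (lam * rho * r) + 1.0 / r)
    x = (D - a) / b  # e^{-rt}
    if x <= 0:
        from scipy.optimize import brentq

        return brentq(lambda s: bd_kernel_cdf(s, t_root, bd) - q, 0.0, t_root)
    return -math.log(x) / r


def _bd_logpdf_array(ts: np.ndarray, t_root: float, bd: BirthDeathParams) -> float:
    """Sum of kernel log-densities for an array of ages (vector fast path)."""
    if len(ts) == 0:
        return 0.0
    if (ts <= 0).any() or (ts >= t_root).any():
        return -math.inf
    lam, mu, rho, r, a, b = _kernel_parts(bd)
    if rho < _EPS:
        if abs(r) < _EPS:
            return -len(ts) * math.log(t_root)
        return float(
            len(ts) * math.log(abs(r) / abs(math.expm1(r * t_root))) + r * ts.sum()
        )
    logV = math.log(_cumulative(t_root, bd))
    if abs(r) < _EPS:
        p1 = rho / (1.0 + rho * lam * ts) ** 2
    else:
        D = r + b * np.expm1(-r * ts)
        p1 = rho * r * r * np.exp(-r * ts) / (D * D)
    return float(np.log(lam * p1).sum() - len(ts) * logV)


class CompiledTimePrior:
    """Calibration densities and kernel terms bound to one topology."""

    def __init__(self, top: Topology, cal: CalibrationSet, bd: BirthDeathParams,
                 cauchy_long=None, cauchy_short=None):
        self.top = top
        self.bd = bd
        self.densities = cal.compile(top, cauchy_long, cauchy_short)
        if top.root not in self.densities:
            raise ValueError(
                "the root must carry a calibration (an unbounded root age "
                "makes the time prior improper)"
            )
        self.calibrated = sorted(self.densities)
        self.uncalibrated = [
            v for v in top.internal_nodes if v not in self.densities
        ]

    def logpdf(self, ages: np.ndarray) -> float:
        """Joint log-prior of a full age vector; -inf on ordering violations."""
        top = self.top
        for v in top.internal_nodes:
            av = ages[v]
            for c in top.children[v]:
                if av <= ages[c]:
                    return -math.inf
        t_root = ages[top.root]
        total = 0.0
        for v, dens in self.densities.items():
            lp = dens.logpdf(float(ages[v]))
            if lp == -math.inf:
                return -math.inf
            total += lp
        total += _bd_logpdf_array(ages[self.uncalibrated], t_root, self.bd)
        return total


def joint_time_logprior(tree: TimeTree, cal: CalibrationSet, bd: BirthDeathParams) -> float:
    """Log-density of the time prior at the ages of ``tree``.

    Sum of calibration log-densities at calibrated nodes (root included),
    birth-death kernel log-densities at uncalibrated internal nodes, with
    -inf whenever a parent is not strictly older than a child.  This
    support truncation is what distorts the per-node marginals.
    """
    return CompiledTimePrior(tree.topology, cal, bd).logpdf(tree.ages)


def sample_effective_prior(
    top: Topology,
    cal: CalibrationSet,
    bd: BirthDeathParams,
    n: int = 10_000,
    seed: int = 0,
    burnin: int | None = None,
    thin: int = 2,
    chains: int = 1,
    cauchy_long=None,
    cauchy_short=None,
):
    """MCMC sample from the time prior alone (no sequence data).

    Returns an :class:`~phyloclock.mcmc.McmcTrace` whose per-node marginals
    are the *effective* priors: the user-specified calibration densities as
    truncated by the tree's ordering constraints.  With several chains, a
    list of traces is returned.
    """
    from .mcmc import McmcConfig, run_chain, PriorModel

    model = PriorModel(top, cal, bd, cauchy_long=cauchy_long, cauchy_short=cauchy_short)
    if burnin is None:
        burnin = max(500, n // 10)
    cfg = McmcConfig(
        iterations=burnin + n * thin, burnin=burnin, thin=thin, seed=seed
    )
    traces = [
        run_chain(model, McmcConfig(
            iterations=cfg.iterations, burnin=cfg.burnin, thin=cfg.thin,
            seed=seed + 1000 * i,
        ))
        for i in range(chains)
    ]
    return traces[0] if chains == 1 else traces
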