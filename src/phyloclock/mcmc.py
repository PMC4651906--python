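"""Metropolis-within-Gibbs sampler over node ages, rates and hyperparameters.

Each iteration sweeps all internal node ages (sliding-window proposals
reflected into the interval bounded by the oldest child and the parent; the
root uses a positive multiplier move), then all branch/node rates and the
clock hyperparameters, and finishes with a mixing move that rescales all
ages by c and all rates by 1/c — branch lengths, and hence the likelihood,
are invariant under this rescaling, which decorrelates the confounded times
and rates.  Proposal step sizes are auto-tuned toward a target acceptance
rate during burn-in only, preserving detailed balance afterwards.

The same engine serves prior-only runs (no likelihood term; the marginal
samples are the *effective* priors) and posterior runs with either the
quadratic approximate likelihood or the exact pruning likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrations import CalibrationSet
from .rate_models import GammaPrior, gamma_dirichlet_logprior
from .substitution import Alignment, ApproxLikelihood, SubstitutionModel, _Pruner
from .time_prior import BirthDeathParams, CompiledTimePrior, bd_kernel_logpdf, _bd_logpdf_array
from .trees import Topology

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "ClockSpec",
    "PriorModel",
    "PosteriorModel",
    "ApproxAdapter",
    "ExactAdapter",
    "run_chain",
    "run_chains",
    "check_convergence",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class McmcConfig:
    """Chain length and proposal settings.

    ``iterations`` counts full sweeps; ``burnin`` sweeps are discarded and
    the rest thinned by ``thin``.  Step sizes are tuned during burn-in
    toward ``target_accept`` and frozen afterwards.
    """

    iterations: int = 20_000
    burnin: int = 2_000
    thin: int = 2
    seed: int = 0
    tune_interval: int = 100
    target_accept: float = 0.30
    store_rates: bool = False

    def __post_init__(self):
        if not self.iterations > self.burnin >= 0:
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ClockSpec:
    """Relaxed-clock choice and hyperpriors (shared across partitions)."""

    model: str = "ir"  # "ir" or "ar"
    mu_prior: GammaPrior = field(default_factory=lambda: GammaPrior(2.0, 40.0))
    sigma2_prior: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 10.0))
    concentration: float = 1.0

    def __post_init__(self):
        if self.model not in ("ir", "ar"):
            raise ValueError("clock model must be 'ir' or 'ar'")


class PriorModel:
    """Bundle for prior-only (no sequence data) sampling."""

    def __init__(self, top: Topology, cal: CalibrationSet, bd: BirthDeathParams,
                 cauchy_long=None, cauchy_short=None):
        self.top = top
        self.timeprior = CompiledTimePrior(top, cal, bd, cauchy_long, cauchy_short)
        self.bd = bd
        self.clock = None
        self.adapters: list | None = None

    @property
    def n_partitions(self) -> int:
        return 0


class PosteriorModel(PriorModel):
    """Bundle for posterior sampling: time prior + clock + likelihood."""

    def __init__(self, top, cal, bd, clock: ClockSpec, adapters,
                 cauchy_long=None, cauchy_short=None):
        super().__init__(top, cal, bd, cauchy_long, cauchy_short)
        self.clock = clock
        self.adapters = list(adapters)
        if not self.adapters:
            raise ValueError("posterior model needs at least one likelihood")

    @property
    def n_partitions(self) -> int:
        return len(self.adapters)


class ApproxAdapter:
    """Quadratic-surface likelihood with O(n) single-branch updates."""

    def __init__(self, surface: ApproxLikelihood):
        self.surface = surface
        self.node_order = list(surface.node_order)
        self._pending = None

    def reset(self, b: np.ndarray) -> float:
        s = self.surface
        self.d = np.asarray(b, float) - s.bhat
        self.Hd = s.hess @ self.d
        self.ll = float(s.ll0 + s.grad @ self.d + 0.5 * self.d @ self.Hd)
        return self.ll

    def propose(self, idx: np.ndarray, newb: np.ndarray) -> float:
        if (newb < 0).any():
            self._pending = None
            return -math.inf
        s = self.surface
        delta = newb - (s.bhat[idx] + self.d[idx])
        dll = float(
            s.grad[idx] @ delta
            + delta @ self.Hd[idx]
            + 0.5 * delta @ s.hess[np.ix_(idx, idx)] @ delta
        )
        self._pending = (idx, delta, dll)
        return dll

    def accept(self) -> None:
        idx, delta, dll = self._pending
        self.d[idx] += delta
        self.Hd += self.surface.hess[:, idx] @ delta
        self.ll += dll
        self._pending = None

    def reject(self) -> None:
        self._pending = None


class ExactAdapter:
    """Exact pruning likelihood with incremental path updates.

    Per-node messages are cached; a proposal touching a few branches only
    recomputes those edges and the partials on the paths to the root.
    """

    def __init__(self, aln: Alignment, top: Topology, model: SubstitutionModel):
        self._pruner = _Pruner(aln, top, model)
        self.top = top
        self.model = model
        self.node_order = list(self._pruner.nonroot)
        self._n_nodes = top.n_nodes
        self._post_pos = {v: i for i, v in enumerate(top.postorder)}
        self._pending = None

    def _edge_pmats(self, b_v: float) -> np.ndarray:
        m = self.model
        ts = max(b_v, self._pruner.BL_FLOOR) * m.rates
        e = np.exp(np.multiply.outer(ts, m.eigval))
        return np.einsum("ik,ck,jk->cij", m._right.T, e, m._left)

    def _message(self, v: int, b_v: float, msgs, scal):
        from .substitution import _tip_message

        top = self.top
        P = self._edge_pmats(b_v)
        if top.is_tip[v]:
            return _tip_message(P, self._pruner.data.tip_codes[v]), np.zeros(
                (self._pruner.data.n_patterns, self.model.ncat)
            )
        L, c = self._partial(v, msgs, scal)
        K = self.model.ncat
        out = np.stack([L[:, k, :] @ P[k].T for k in range(K)], axis=1)
        return out, c

    def _partial(self, v: int, msgs, scal):
        top = self.top
        kids = top.children[v]
        L = msgs[kids[0]]
        c = scal[kids[0]]
        for w in kids[1:]:
            L = L * msgs[w]
            c = c + scal[w]
        mx = np.maximum(L.max(axis=2), 1e-300)
        return L / mx[:, :, None], c + np.log(mx)

    def _root_ll(self, msgs, scal) -> float:
        from scipy.special import logsumexp

        m = self.model
        L, c = self._partial(self.top.root, msgs, scal)
        lik = L @ m.freqs
        site_ll = logsumexp(np.log(np.maximum(lik, 1e-300)) + c, axis=1) - math.log(
            m.ncat
        )
        return float(site_ll @ self._pruner.data.weights)

    def reset(self, b: np.ndarray) -> float:
        self.bfull = np.zeros(self._n_nodes)
        self.bfull[self.node_order] = b
        self._msgs: dict[int, np.ndarray] = {}
        self._scal: dict[int, np.ndarray] = {}
        for v in self.top.postorder:
            if v == self.top.root:
                continue
            self._msgs[v], self._scal[v] = self._message(
                v, self.bfull[v], self._msgs, self._scal
            )
        self.ll = self._root_ll(self._msgs, self._scal)
        return self.ll

    def propose(self, idx, newb) -> float:
        newb = np.asarray(newb, dtype=float)
        if (newb < 0).any():
            self._pending = None
            return -math.inf
        changed = [self.node_order[i] for i in np.atleast_1d(idx)]
        affected: set[int] = set()
        for v in changed:
            u = v
            while u != -1 and u not in affected:
                affected.add(u)
                u = self.top.parent[u]
        affected.discard(self.top.root)
        btmp = dict(zip(changed, np.atleast_1d(newb)))
        new_msgs = dict(self._msgs)
        new_scal = dict(self._scal)
        for v in sorted(affected, key=lambda u: self._post_pos[u]):
            b_v = btmp.get(v, self.bfull[v])
            new_msgs[v], new_scal[v] = self._message(v, b_v, new_msgs, new_scal)
        ll_new = self._root_ll(new_msgs, new_scal)
        self._pending = (btmp, new_msgs, new_scal, ll_new)
        return ll_new - self.ll

    def accept(self) -> None:
        btmp, new_msgs, new_scal, ll_new = self._pending
        for v, b_v in btmp.items():
            self.bfull[v] = b_v
        self._msgs, self._scal = new_msgs, new_scal
        self.ll = ll_new
        self._pending = None

    def reject(self) -> None:
        self._pending = None


@dataclass
class McmcTrace:
    """Retained MCMC samples with per-move acceptance statistics."""

    node_ids: list[int]
    labels: list[str]
    ages: np.ndarray  # (n_samples, n_internal), 100 Myr units
    mu: np.ndarray  # (n_samples, k) or (n_samples, 0)
    sigma2: np.ndarray
    log_prior: np.ndarray
    log_lik: np.ndarray
    accept_rates: dict
    seed: int
    rates_mean: np.ndarray | None = None  # (n_samples, k) mean branch rate

    def __len__(self) -> int:
        return self.ages.shape[0]

    def age_column(self, label_or_id) -> np.ndarray:
        if isinstance(label_or_id, str):
            i = self.labels.index(label_or_id)
        else:
            i = self.node_ids.index(label_or_id)
        return self.ages[:, i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ages, columns=self.labels)
        for j in range(self.mu.shape[1]):
            df[f"mu_{j}"] = self.mu[:, j]
            df[f"sigma2_{j}"] = self.sigma2[:, j]
        df["log_prior"] = self.log_prior
        df["log_lik"] = self.log_lik
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class Sampler:
    """One MCMC chain over (ages, rates, hyperparameters)."""

    def __init__(self, model: PriorModel, cfg: McmcConfig):
        self.model = model
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        top = model.top
        if not top.is_binary:
            raise ValueError("sampling requires a binary topology")
        self.top = top
        self.tp = model.timeprior
        self.internal = [v for v in top.internal_nodes if v != top.root]
        self.nonroot = [v for v in range(top.n_nodes) if top.parent[v] != -1]
        self.branch_pos = {v: i for i, v in enumerate(self.nonroot)}
        self.k = model.n_partitions
        self.clock = model.clock
        self.adapters = model.adapters
        if self.adapters:
            for a in self.adapters:
                if list(a.node_order) != self.nonroot:
                    raise ValueError("likelihood branch order mismatch")
        # tunable steps (log-scale multiplicative tuning)
        self.steps = {
            "age": 0.5,  # fraction of the local interval
            "root": 0.2,  # log-multiplier half-width
            "rate": 0.5,  # log-rate window half-width
            "hyper": 0.4,
            "mix": 0.1,
            "lmix": 0.2,  # local time/rate rescale half-width (IR)
        }
        self.acc = {k: [0, 0] for k in self.steps}
        # preorder node lists of each subtree (node first), for AR updates
        self.subtree: list[list[int]] = [[] for _ in range(top.n_nodes)]
        for v in reversed(top.preorder):
            self.subtree[v] = [v]
            for c in top.children[v]:
                self.subtree[v].extend(self.subtree[c])
        self._init_state()

    # -- initialization --------------------------------------------------

    def _init_state(self):
        top, rng = self.top, self.rng
        self.ages = feasible_ages(top, self.tp.densities, rng)
        if self.clock is not None:
            k = self.k
            self.mu = np.full(k, self.clock.mu_prior.mean)
            self.sigma2 = np.full(k, self.clock.sigma2_prior.mean)
            if self.clock.model == "ir":
                self.rates = np.tile(self.mu[:, None], (1, top.n_nodes))
            else:
                # non-centered parameterization: standardized increments eps
                # with derived node log-rates (root pinned to log mu); this
                # avoids the funnel between nu and the log-rates
                self.eps = np.zeros((k, top.n_nodes))
                self.logr = np.tile(np.log(self.mu)[:, None], (1, top.n_nodes))
                for j in range(k):
                    new = self._ar_recompute(j, top.root, self.ages)
                    for v, x in new.items():
                        self.logr[j, v] = x
            self._reset_likelihood()
        else:
            self.mu = np.zeros(0)
            self.sigma2 = np.zeros(0)

    def _ar_recompute(
        self,
        j: int,
        start: int,
        ages: np.ndarray,
        eps_override: tuple[int, float] | None = None,
        nu: float | None = None,
        x_start_parent: float | None = None,
    ) -> dict[int, float]:
        """Derived log-rates for the subtree rooted at ``start``.

        ``x_v = x_parent - nu dt / 2 + sqrt(nu dt) eps_v`` walked in
        preorder; the root log-rate is pinned to ``log mu_j``.
        """
        top = self.top
        nu_j = self.sigma2[j] if nu is None else nu
        out: dict[int, float] = {}
        for w in self.subtree[start]:
            u = top.parent[w]
            if u == -1:
                out[w] = math.log(self.mu[j])
                continue
            x_u = out[u] if u in out else (
                x_start_parent if (w == start and x_start_parent is not None)
                else self.logr[j, u]
            )
            dt = ages[u] - ages[w]
            s2 = nu_j * dt
            e = self.eps[j, w]
            if eps_override is not None and eps_override[0] == w:
                e = eps_override[1]
            out[w] = x_u - 0.5 * s2 + math.sqrt(max(s2, 0.0)) * e
        return out

    def _branch_rate(self, j: int, v: int) -> float:
        if self.clock.model == "ir":
            return self.rates[j, v]
        u = self.top.parent[v]
        return 0.5 * (math.exp(self.logr[j, v]) + math.exp(self.logr[j, u]))

    def _branch_length(self, j: int, v: int) -> float:
        u = self.top.parent[v]
        return (self.ages[u] - self.ages[v]) * self._branch_rate(j, v)

    def _reset_likelihood(self):
        self.b = np.zeros((self.k, len(self.nonroot)))
        for j in range(self.k):
            for i, v in enumerate(self.nonroot):
                self.b[j, i] = self._branch_length(j, v)
            self.adapters[j].reset(self.b[j])

    @property
    def log_lik(self) -> float:
        return sum(a.ll for a in self.adapters) if self.adapters else 0.0

    # -- prior pieces ----------------------------------------------------

    def _time_term(self, v: int, t: float, t_root: float) -> float:
        dens = self.tp.densities.get(v)
        if dens is not None:
            return dens.logpdf(t)
        return bd_kernel_logpdf(t, t_root, self.model.bd)

    def _ln_term(self, r: float, mu: float, s2: float) -> float:
        if r <= 0:
            return -math.inf
        m = math.log(mu) - 0.5 * s2
        z = math.log(r) - m
        return -0.5 * (_LOG_2PI + math.log(s2)) - math.log(r) - 0.5 * z * z / s2

    def total_log_prior(self) -> float:
        """Joint log-prior of the sampled variables.

        For AR these are the standardized increments (standard normal), not
        the derived log-rates.
        """
        lp = self.tp.logpdf(self.ages)
        if self.clock is None:
            return lp
        c = self.clock
        lp += gamma_dirichlet_logprior(self.mu, c.mu_prior, c.concentration)
        lp += gamma_dirichlet_logprior(self.sigma2, c.sigma2_prior, c.concentration)
        for j in range(self.k):
            if c.model == "ir":
                r = self.rates[j, self.nonroot]
                s2 = self.sigma2[j]
                m = math.log(self.mu[j]) - 0.5 * s2
                z = np.log(r) - m
                lp += float(
                    -0.5 * len(r) * (_LOG_2PI + math.log(s2))
                    - np.log(r).sum()
                    - 0.5 * (z * z).sum() / s2
                )
            else:
                e = self.eps[j, self.nonroot]
                lp += float(-0.5 * len(e) * _LOG_2PI - 0.5 * (e * e).sum())
        return lp

    # -- likelihood helpers ----------------------------------------------

    def _propose_lik(self, j: int, nodes: list[int], newb: list[float]) -> float:
        idx = np.array([self.branch_pos[v] for v in nodes])
        return self.adapters[j].propose(idx, np.array(newb))

    def _mh(self, kind: str, logratio: float) -> bool:
        self.acc[kind][1] += 1
        if logratio >= 0 or self.rng.random() < math.exp(max(logratio, -700)):
            self.acc[kind][0] += 1
            return True
        return False

    # -- moves ------------------------------------------------------------

    def step_node_age(self, v: int, window: float | None = None) -> bool:
        """Sliding-window update of one internal (non-root) node age."""
        top = self.top
        t = self.ages[v]
        lo = max(self.ages[c] for c in top.children[v])
        hi = self.ages[top.parent[v]]
        w = (window if window is not None else self.steps["age"]) * (hi - lo)
        tnew = t + self.rng.uniform(-w, w)
        # reflect into (lo, hi)
        for _ in range(100):
            if tnew < lo:
                tnew = 2 * lo - tnew
            elif tnew > hi:
                tnew = 2 * hi - tnew
            else:
                break
        t_root = self.ages[top.root]
        logratio = self._time_term(v, tnew, t_root) - self._time_term(v, t, t_root)
        pending = []
        if self.clock is not None:
            if self.clock.model == "ar":
                # the derived log-rates of the whole subtree shift with t_v
                ages_new = self.ages.copy()
                ages_new[v] = tnew
                for j in range(self.k):
                    newx = self._ar_recompute(j, v, ages_new)
                    nodes = self.subtree[v]
                    newb = self._ar_branches(j, nodes, ages_new, newx)
                    dll = self._propose_lik(j, nodes, newb)
                    pending.append((j, nodes, newb, newx))
                    logratio += dll
                    if logratio == -math.inf:
                        break
            else:
                for j in range(self.k):
                    nodes = [v] + list(top.children[v])
                    newb = []
                    for w_ in nodes:
                        u = top.parent[w_]
                        dur = (tnew if u == v else self.ages[u]) - (
                            tnew if w_ == v else self.ages[w_]
                        )
                        newb.append(dur * self._branch_rate(j, w_))
                    dll = self._propose_lik(j, nodes, newb)
                    pending.append((j, nodes, newb, None))
                    logratio += dll
                    if logratio == -math.inf:
                        break
        if self._mh("age", logratio):
            self.ages[v] = tnew
            self._commit(pending, accept=True)
            return True
        self._commit(pending, accept=False)
        return False

    def _ar_branches(self, j, nodes, ages, newx) -> list[float]:
        """Branch lengths above each node in ``nodes`` under updated ages
        and log-rates (``newx`` maps node -> new log-rate)."""
        top = self.top
        out = []
        for w in nodes:
            u = top.parent[w]
            x_w = newx.get(w, self.logr[j, w])
            x_u = newx.get(u, self.logr[j, u])
            out.append((ages[u] - ages[w]) * 0.5 * (math.exp(x_w) + math.exp(x_u)))
        return out

    def step_root_age(self) -> bool:
        top = self.top
        root = top.root
        t = self.ages[root]
        lo = max(self.ages[c] for c in top.children[root])
        c = math.exp(self.steps["root"] * (self.rng.random() - 0.5))
        tnew = t * c
        if tnew <= lo:
            self.acc["root"][1] += 1
            return False
        dens = self.tp.densities[root]
        logratio = dens.logpdf(tnew) - dens.logpdf(t) + math.log(c)
        # the kernel of every uncalibrated node conditions on the root age
        uncal_ages = self.ages[self.tp.uncalibrated]
        logratio += _bd_logpdf_array(uncal_ages, tnew, self.model.bd)
        logratio -= _bd_logpdf_array(uncal_ages, t, self.model.bd)
        pending = []
        if self.clock is not None:
            if self.clock.model == "ar":
                ages_new = self.ages.copy()
                ages_new[root] = tnew
                for j in range(self.k):
                    newx = self._ar_recompute(j, root, ages_new)
                    newx.pop(root, None)
                    nodes = self.nonroot
                    newb = self._ar_branches(j, nodes, ages_new, newx)
                    dll = self._propose_lik(j, nodes, newb)
                    pending.append((j, nodes, newb, newx))
                    logratio += dll
                    if logratio == -math.inf:
                        break
            else:
                for j in range(self.k):
                    nodes = list(top.children[root])
                    newb = [
                        (tnew - self.ages[w_]) * self._branch_rate(j, w_) for w_ in nodes
                    ]
                    dll = self._propose_lik(j, nodes, newb)
                    pending.append((j, nodes, newb, None))
                    logratio += dll
                    if logratio == -math.inf:
                        break
        if self._mh("root", logratio):
            self.ages[root] = tnew
            self._commit(pending, accept=True)
            return True
        self._commit(pending, accept=False)
        return False

    def _commit(self, pending, accept: bool):
        for j, nodes, newb, newx in pending:
            if accept:
                for v, nb in zip(nodes, newb):
                    self.b[j, self.branch_pos[v]] = nb
                if newx is not None:
                    for v, x in newx.items():
                        self.logr[j, v] = x
                self.adapters[j].accept()
            else:
                self.adapters[j].reject()

    def step_rate(self, j: int, v: int) -> bool:
        """Update one branch rate (IR) or node log-rate (AR)."""
        top = self.top
        if self.clock.model == "ir":
            r = self.rates[j, v]
            x = math.log(r)
            xnew = x + self.rng.uniform(-self.steps["rate"], self.steps["rate"])
            rnew = math.exp(xnew)
            logratio = (
                self._ln_term(rnew, self.mu[j], self.sigma2[j])
                - self._ln_term(r, self.mu[j], self.sigma2[j])
                + (xnew - x)  # Jacobian of the log-space walk in rate space
            )
            dur = self.ages[top.parent[v]] - self.ages[v]
            dll = self._propose_lik(j, [v], [dur * rnew])
            logratio += dll
            if self._mh("rate", logratio):
                self.rates[j, v] = rnew
                self.b[j, self.branch_pos[v]] = dur * rnew
                self.adapters[j].accept()
                return True
            self.adapters[j].reject()
            return False
        # AR (non-centered): update one standardized increment eps_v; the
        # derived log-rates of the whole subtree below v move with it
        e = self.eps[j, v]
        enew = e + self.rng.uniform(-self.steps["rate"], self.steps["rate"])
        logratio = -0.5 * (enew * enew - e * e)
        newx = self._ar_recompute(j, v, self.ages, eps_override=(v, enew))
        nodes = self.subtree[v]
        newb = self._ar_branches(j, nodes, self.ages, newx)
        dll = self._propose_lik(j, nodes, newb)
        logratio += dll
        if self._mh("rate", logratio):
            self.eps[j, v] = enew
            for w_, x in newx.items():
                self.logr[j, w_] = x
            for w_, nb in zip(nodes, newb):
                self.b[j, self.branch_pos[w_]] = nb
            self.adapters[j].accept()
            return True
        self.adapters[j].reject()
        return False

    def _rate_prior_partition(self, j, mu=None, sigma2=None) -> float:
        """IR lognormal rate prior of one partition (vectorized)."""
        mu = self.mu[j] if mu is None else mu
        s2 = self.sigma2[j] if sigma2 is None else sigma2
        r = self.rates[j, self.nonroot]
        m = math.log(mu) - 0.5 * s2
        z = np.log(r) - m
        return float(
            -0.5 * len(r) * (_LOG_2PI + math.log(s2))
            - np.log(r).sum()
            - 0.5 * (z * z).sum() / s2
        )

    def step_hyper(self, j: int, which: str) -> bool:
        """Multiplier update of mu_j or sigma2_j."""
        c = self.clock
        step = self.steps["hyper"]
        f = math.exp(step * (self.rng.random() - 0.5))
        if which == "mu":
            new = self.mu.copy()
            new[j] = self.mu[j] * f
            logratio = (
                gamma_dirichlet_logprior(new, c.mu_prior, c.concentration)
                - gamma_dirichlet_logprior(self.mu, c.mu_prior, c.concentration)
                + math.log(f)
            )
            if c.model == "ir":
                logratio += self._rate_prior_partition(j, mu=new[j])
                logratio -= self._rate_prior_partition(j)
                if self._mh("hyper", logratio):
                    self.mu = new
                    return True
                return False
            # AR: all derived log-rates shift by log f, branch lengths scale
            idx = np.arange(len(self.nonroot))
            newb = self.b[j] * f
            dll = self.adapters[j].propose(idx, newb)
            logratio += dll
            if self._mh("hyper", logratio):
                self.mu = new
                self.logr[j] += math.log(f)
                self.b[j] = newb
                self.adapters[j].accept()
                return True
            self.adapters[j].reject()
            return False
        new = self.sigma2.copy()
        new[j] = self.sigma2[j] * f
        logratio = (
            gamma_dirichlet_logprior(new, c.sigma2_prior, c.concentration)
            - gamma_dirichlet_logprior(self.sigma2, c.sigma2_prior, c.concentration)
            + math.log(f)
        )
        if c.model == "ir":
            logratio += self._rate_prior_partition(j, sigma2=new[j])
            logratio -= self._rate_prior_partition(j)
            if self._mh("hyper", logratio):
                self.sigma2 = new
                return True
            return False
        # AR: the drift changes every derived log-rate (eps held fixed)
        root = self.top.root
        newx = self._ar_recompute(j, root, self.ages, nu=new[j])
        newx.pop(root, None)
        nodes = self.nonroot
        newb = self._ar_branches(j, nodes, self.ages, newx)
        dll = self._propose_lik(j, nodes, newb)
        logratio += dll
        if self._mh("hyper", logratio):
            self.sigma2 = new
            for w_, x in newx.items():
                self.logr[j, w_] = x
            for w_, nb in zip(nodes, newb):
                self.b[j, self.branch_pos[w_]] = nb
            self.adapters[j].accept()
            return True
        self.adapters[j].reject()
        return False

    def step_local_mix(self, v: int) -> bool:
        """Local time/rate rescale at one internal non-root node (IR only).

        Proposes ``t_v -> c t_v`` with the rates of the branches to v's
        children divided by c, keeping those branch lengths fixed; only the
        branch above v changes in the likelihood.  This moves directly
        along the local time-rate ridge that single-variable updates cross
        slowly.
        """
        top = self.top
        t = self.ages[v]
        c = math.exp(self.steps["lmix"] * (self.rng.random() - 0.5))
        tnew = t * c
        lo = max(self.ages[w] for w in top.children[v])
        hi = self.ages[top.parent[v]]
        if not lo < tnew < hi:
            self.acc["lmix"][1] += 1
            return False
        kids = top.children[v]
        # child rates rescale to keep each child branch length invariant
        ratios = [(t - self.ages[w]) / (tnew - self.ages[w]) for w in kids]
        t_root = self.ages[top.root]
        logratio = self._time_term(v, tnew, t_root) - self._time_term(v, t, t_root)
        logratio += math.log(c) + self.k * sum(math.log(x) for x in ratios)
        pending = []
        for j in range(self.k):
            for w, x in zip(kids, ratios):
                r = self.rates[j, w]
                logratio += self._ln_term(r * x, self.mu[j], self.sigma2[j])
                logratio -= self._ln_term(r, self.mu[j], self.sigma2[j])
            dur_new = self.ages[top.parent[v]] - tnew
            newb = [dur_new * self.rates[j, v]]
            dll = self._propose_lik(j, [v], newb)
            pending.append((j, [v], newb, None))
            logratio += dll
            if logratio == -math.inf:
                break
        if self._mh("lmix", logratio):
            self.ages[v] = tnew
            for j in range(self.k):
                for w, x in zip(kids, ratios):
                    self.rates[j, w] = self.rates[j, w] * x
            self._commit(pending, accept=True)
            return True
        self._commit(pending, accept=False)
        return False

    def step_mixing(self) -> bool:
        """Rescale ages by c and rates by 1/c (branch lengths invariant)."""
        c = math.exp(self.steps["mix"] * (self.rng.random() - 0.5))
        logc = math.log(c)
        n_int = len(self.internal) + 1  # internal nodes incl. root
        old_lp = self.total_log_prior()
        saved = (self.ages.copy(), self.mu.copy(), self.sigma2.copy())
        saved_rates = None
        self.ages = self.ages * c
        njac = n_int
        if self.clock is not None:
            if self.clock.model == "ir":
                saved_rates = self.rates.copy()
                self.rates = self.rates / c
                njac -= self.k * len(self.nonroot) + self.k  # rates and mu
            else:
                # sampled variables are (eps, mu, nu); eps is scale-free, the
                # derived log-rates shift so that dt * nu and hence every
                # branch length is invariant
                saved_rates = self.logr.copy()
                self.logr = self.logr - logc
                self.sigma2 = self.sigma2 / c
                njac -= 2 * self.k  # mu and nu scale down
            self.mu = self.mu / c
        new_lp = self.total_log_prior()
        logratio = new_lp - old_lp + njac * logc
        if self._mh("mix", logratio):
            return True
        self.ages, self.mu, self.sigma2 = saved
        if saved_rates is not None:
            if self.clock.model == "ir":
                self.rates = saved_rates
            else:
                self.logr = saved_rates
        return False

    # -- main loop ---------------------------------------------------------

    def sweep(self):
        for v in self.internal:
            self.step_node_age(v)
        self.step_root_age()
        if self.clock is not None:
            if self.clock.model == "ir":
                rate_nodes = self.nonroot
            else:
                rate_nodes = [v for v in range(self.top.n_nodes) if v != self.top.root]
            for j in range(self.k):
                for v in rate_nodes:
                    self.step_rate(j, v)
                self.step_hyper(j, "mu")
                self.step_hyper(j, "sigma2")
            if self.clock.model == "ir":
                for v in self.internal:
                    self.step_local_mix(v)
        self.step_mixing()

    def _tune(self):
        for kind, (a, n) in self.acc.items():
            if n < 20:
                continue
            rate = a / n
            factor = math.exp(np.clip(rate - self.cfg.target_accept, -0.5, 0.5))
            self.steps[kind] = float(np.clip(self.steps[kind] * factor, 1e-3, 20.0))
            if kind == "age":
                self.steps[kind] = min(self.steps[kind], 1.0)
            self.acc[kind] = [0, 0]

    def run(self) -> McmcTrace:
        cfg = self.cfg
        top = self.top
        n_keep = (cfg.iterations - cfg.burnin + cfg.thin - 1) // cfg.thin
        internal_all = [v for v in top.internal_nodes]
        ages_out = np.empty((n_keep, len(internal_all)))
        mu_out = np.empty((n_keep, self.k))
        s2_out = np.empty((n_keep, self.k))
        lp_out = np.empty(n_keep)
        ll_out = np.empty(n_keep)
        rmean_out = np.empty((n_keep, self.k)) if self.clock is not None else None
        kept = 0
        for sweep in range(cfg.iterations):
            self.sweep()
            if sweep < cfg.burnin:
                if (sweep + 1) % cfg.tune_interval == 0:
                    self._tune()
                if sweep + 1 == cfg.burnin:
                    self.acc = {k: [0, 0] for k in self.steps}
                continue
            if (sweep - cfg.burnin) % cfg.thin == 0 and kept < n_keep:
                ages_out[kept] = self.ages[internal_all]
                mu_out[kept] = self.mu
                s2_out[kept] = self.sigma2
                lp_out[kept] = self.total_log_prior()
                ll_out[kept] = self.log_lik
                if rmean_out is not None:
                    if self.clock.model == "ir":
                        rmean_out[kept] = self.rates[:, self.nonroot].mean(axis=1)
                    else:
                        rmean_out[kept] = np.exp(self.logr).mean(axis=1)
                kept += 1
        labels = [
            top.labels[v] if top.labels[v] else f"node_{v}" for v in internal_all
        ]
        rates = {
            k: (a / n if n else 0.0) for k, (a, n) in self.acc.items()
        }
        return McmcTrace(
            node_ids=internal_all,
            labels=labels,
            ages=ages_out[:kept],
            mu=mu_out[:kept],
            sigma2=s2_out[:kept],
            log_prior=lp_out[:kept],
            log_lik=ll_out[:kept],
            accept_rates=rates,
            seed=cfg.seed,
        )


def feasible_ages(top: Topology, densities: dict, rng: np.random.Generator) -> np.ndarray:
    """Draw an age vector satisfying ordering and all hard minimum bounds."""
    # effective lower bound: max of own and descendant calibration minima
    lower = np.zeros(top.n_nodes)
    for v in top.postorder:
        own = 0.0
        d = densities.get(v)
        if d is not None and getattr(d, "t_min", None):
            own = d.t_min
        lower[v] = max([own] + [lower[c] for c in top.children[v]])
    ages = np.zeros(top.n_nodes)
    root = top.root
    droot = densities[root]
    for _ in range(1000):
        t = float(droot.rvs(1, rng)[0])
        if t > lower[root]:
            ages[root] = t
            break
    else:
        raise RuntimeError("could not draw a feasible root age")
    for v in top.preorder:
        if v == root or top.is_tip[v]:
            continue
        hi = ages[top.parent[v]]
        lo = lower[v]
        d = densities.get(v)
        if d is not None and getattr(d, "t_max", None) and d.t_max < hi:
            hi_draw = min(hi, d.t_max)
        else:
            hi_draw = hi
        if hi_draw <= lo:
            hi_draw = hi  # soft bounds allow exceeding a conflicting maximum
        ages[v] = rng.uniform(lo + 1e-9 * (hi_draw - lo), hi_draw)
        if ages[v] >= hi:
            ages[v] = lo + 0.999 * (hi - lo)
    return ages


def run_chain(model: PriorModel, cfg: McmcConfig) -> McmcTrace:
    """Run one chain; deterministic for a fixed seed."""
    return Sampler(model, cfg).run()


def run_chains(model: PriorModel, cfg: McmcConfig, n_chains: int = 2) -> list[McmcTrace]:
    out = []
    for i in range(n_chains):
        c = McmcConfig(
            iterations=cfg.iterations, burnin=cfg.burnin, thin=cfg.thin,
            seed=cfg.seed + 1000 * i, tune_interval=cfg.tune_interval,
            target_accept=cfg.target_accept,
        )
        out.append(run_chain(model, c))
    return out


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a 1-D chain (autocorrelation-time estimate via ArviZ)."""
    import arviz as az

    return float(az.ess(np.asarray(x)[None, :]))


def check_convergence(traces: list[McmcTrace], tol_factor: float = 2.0) -> dict:
    """Compare per-parameter posterior means between independent chains.

    Each pair of chains passes for a parameter when the difference of means
    is below ``tol_factor`` times the combined Monte-Carlo standard error
    (SE from the effective sample size).  Returns a report dict with a
    per-parameter table and an overall verdict.
    """
    if len(traces) < 2:
        raise ValueError("convergence check needs at least two chains")
    if len({len(t) for t in traces}) != 1:
        raise ValueError("traces must have equal retained lengths")
    ref = traces[0]
    rows = []
    for i, lab in enumerate(ref.labels):
        cols = [t.ages[:, i] for t in traces]
        means = [c.mean() for c in cols]
        ses = []
        for c in cols:
            ess = max(effective_sample_size(c), 1.0)
            ses.append(c.std(ddof=1) / math.sqrt(ess))
        diff = max(means) - min(means)
        se = math.sqrt(sum(s * s for s in ses) / len(ses) * 2)
        rows.append(
            {
                "parameter": lab,
                "mean_diff": diff,
                "se": se,
                "ess_min": min(
                    effective_sample_size(c) for c in cols
                ),
                "pass": bool(diff <= tol_factor * se or diff < 1e-12),
            }
        )
    table = pd.DataFrame(rows)
    return {"pass": bool(table["pass"].all()), "table": table}
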